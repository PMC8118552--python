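"""Run configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` captures every hyperparameter of the
preprocess -> train-autoencoder -> train-cgan -> trace pipeline (defaults are
the published operating point: 64-d latent, encoder hidden sizes 512/256,
decoder 256/512, dropout 0.3, L2 1e-5, learning rates 1e-4 and 5e-5,
patience 100, 32-d noise, 100 replicates, 1% trajectory step). One master
seed derives a fixed per-stage seed so stages can be re-run independently
yet reproducibly. Each stage checkpoints its outputs in the run directory;
re-running skips completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from .autoencoder import (DecoderSpec, EarlyStopConfig, EncoderSpec,
                          train_decoder, train_supervised_encoder)
from .cgan import DiscriminatorSpec, GanTrainConfig, GeneratorSpec, train_cgan
from .persistence import load_model, save_model
from .pseudospace import (TrajectorySpec, build_trajectory, generate_pseudocells,
                          phase_cluster, summarize_trajectory)

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "STAGE_SEED_OFFSETS"]

STAGE_SEED_OFFSETS = {"simulate": 11, "preprocess": 23, "autoencoder": 37,
                      "cgan": 53, "trace": 71}


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed by a fixed offset."""
    return (int(master_seed) * 100 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    input_path: str = ""
    input_format: str | None = None
    channels: list = field(default_factory=lambda: list(pp.DEFAULT_CHANNELS))
    top_genes: int | None = None  # optional variable-gene filter before training
    master_seed: int = 0
    # autoencoder hyperparameters
    latent_dim: int = 64
    encoder_hidden: list = field(default_factory=lambda: [512, 256])
    decoder_hidden: list = field(default_factory=lambda: [256, 512])
    head_hidden: int = 128
    dropout: float = 0.3
    l2_weight: float = 1e-5
    ae_learning_rate: float = 1e-4
    patience: int = 100
    post_restore_epochs: int = 5
    validation_fraction: float = 0.10
    max_epochs: int = 10_000
    batch_size: int = 128
    # cgan hyperparameters
    noise_dim: int = 32
    gan_learning_rate: float = 5e-5
    gan_max_epochs: int = 50_000
    gan_batch_size: int = 128
    # trace parameters
    source_channel: str = "Ighm"
    target_channel: str = "Ighg1"
    step: float = 0.01
    replicates: int = 100
    trace_genes: list | None = None

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        source = str(source)
        text = Path(source).read_text() if "\n" not in source and Path(source).exists() else source
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def validate(self) -> None:
        if not self.channels:
            raise ValueError("config must list the condition channel genes")
        if not self.input_path:
            raise ValueError("config must name an input expression matrix")
        for ch in (self.source_channel, self.target_channel):
            if ch not in self.channels:
                raise ValueError(f"trace channel {ch!r} not in channel list")


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig, run_dir) -> Path:
    """Execute preprocess -> autoencoder -> cgan -> trace with checkpointing.

    Each stage writes its outputs (and a ``.done`` marker) under ``run_dir``;
    a rerun with the same directory resumes after the last completed stage.
    On stage failure a ``failure_manifest.yaml`` records the stage and error.
    """
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(run_dir / "config.yaml")
    stage = "preprocess"
    try:
        # ---- stage 1: preprocess ------------------------------------------
        done = run_dir / "preprocess.done"
        if not done.exists():
            expr = pp.load_expression(config.input_path, config.input_format)
            expr = pp.filter_zero_genes(expr)
            expr = pp.normalize_log2_tpm1(expr)
            profiles = pp.compute_adjacent_profiles(expr, config.channels)
            if config.top_genes:
                selected = pp.select_variable_genes(expr, config.top_genes)
                # condition genes stay in the encoder input by default
                keep = set(selected.gene_ids) | set(config.channels)
                idx = [i for i, g in enumerate(expr.gene_ids) if g in keep]
                expr = pp.ExpressionMatrix(expr.values[:, idx],
                                           [expr.gene_ids[i] for i in idx],
                                           expr.cell_ids, expr.normalization_tag)
            import h5py

            with h5py.File(run_dir / "normalized.h5", "w") as f:
                f.attrs["config_hash"] = cfg_hash
                f.attrs["normalization_tag"] = expr.normalization_tag
                f.create_dataset("matrix", data=expr.values)
                f.create_dataset("gene_ids", data=np.array(expr.gene_ids, dtype="S"))
                f.create_dataset("cell_ids", data=np.array(expr.cell_ids, dtype="S"))
            _write_tsv(profiles.to_frame(), run_dir / "adjacent_profiles.tsv", cfg_hash)
            labels, _ = pp.cluster_adjacent_profiles(profiles)
            _write_tsv(pd.DataFrame({"cell_id": expr.cell_ids, "cluster": labels}),
                       run_dir / "profile_clusters.tsv", cfg_hash, index=False)
            done.touch()

        expr = pp.load_expression(run_dir / "normalized.h5", "h5",
                                  normalization_tag=pp.LOG2_TPM1)
        profiles_df = pd.read_csv(run_dir / "adjacent_profiles.tsv", sep="\t",
                                  comment="#", index_col=0)
        profiles = pp.AdjacentProfiles(profiles_df.to_numpy(),
                                       list(profiles_df.columns),
                                       list(profiles_df.index.astype(str)))

        # ---- stage 2: supervised autoencoder ------------------------------
        stage = "autoencoder"
        done = run_dir / "autoencoder.done"
        seed = stage_seed(config.master_seed, "autoencoder")
        stop = EarlyStopConfig(validation_fraction=config.validation_fraction,
                               patience_epochs=config.patience,
                               post_restore_epochs=config.post_restore_epochs,
                               max_epochs=config.max_epochs)
        if not done.exists():
            espec = EncoderSpec(input_dim=expr.n_genes,
                                hidden_dims=tuple(config.encoder_hidden),
                                latent_dim=config.latent_dim,
                                head_hidden_dim=config.head_hidden,
                                output_dim=profiles.n_channels,
                                dropout_rate=config.dropout,
                                l2_weight=config.l2_weight,
                                learning_rate=config.ae_learning_rate,
                                batch_size=config.batch_size)
            encoder = train_supervised_encoder(expr, profiles, espec, stop, seed=seed)
            latents = encoder.encode(expr.values)
            dspec = DecoderSpec(output_dim=expr.n_genes,
                                latent_dim=config.latent_dim,
                                hidden_dims=tuple(config.decoder_hidden),
                                l2_weight=config.l2_weight,
                                learning_rate=config.ae_learning_rate,
                                batch_size=config.batch_size)
            decoder = train_decoder(latents, expr, dspec, stop, seed=seed + 1,
                                    stratify_labels=profiles.dominant_channel())
            save_model(encoder, run_dir / "encoder.h5", {"config_hash": cfg_hash})
            save_model(decoder, run_dir / "decoder.h5", {"config_hash": cfg_hash})
            _write_tsv(encoder.training_log, run_dir / "encoder_training.tsv", cfg_hash)
            _write_tsv(decoder.training_log, run_dir / "decoder_training.tsv", cfg_hash)
            done.touch()
        encoder = load_model(run_dir / "encoder.h5")
        decoder = load_model(run_dir / "decoder.h5")

        # ---- stage 3: conditional GAN -------------------------------------
        stage = "cgan"
        done = run_dir / "cgan.done"
        if not done.exists():
            latents = encoder.encode(expr.values)
            gcfg = GanTrainConfig(learning_rate=config.gan_learning_rate,
                                  max_epochs=config.gan_max_epochs,
                                  batch_size=config.gan_batch_size,
                                  seed=stage_seed(config.master_seed, "cgan"))
            gspec = GeneratorSpec(noise_dim=config.noise_dim,
                                  condition_dim=profiles.n_channels,
                                  output_dim=config.latent_dim)
            dspec = DiscriminatorSpec(latent_dim=config.latent_dim,
                                      condition_dim=profiles.n_channels)
            gen, disc, history = train_cgan(latents, profiles, gspec, dspec, gcfg)
            save_model(gen, run_dir / "generator.h5", {"config_hash": cfg_hash})
            save_model(disc, run_dir / "discriminator.h5", {"config_hash": cfg_hash})
            _write_tsv(history, run_dir / "cgan_training.tsv", cfg_hash, index=False)
            done.touch()
        gen = load_model(run_dir / "generator.h5")

        # ---- stage 4: trace -----------------------------------------------
        stage = "trace"
        done = run_dir / "trace.done"
        if not done.exists():
            tspec = TrajectorySpec(config.source_channel, config.target_channel,
                                   list(profiles.channel_ids), config.step)
            traj = build_trajectory(tspec)
            pc = generate_pseudocells(traj, gen, decoder, tspec,
                                      replicates=config.replicates,
                                      seed=stage_seed(config.master_seed, "trace"))
            summary = summarize_trajectory(pc, genes=config.trace_genes, zscore=True)
            _write_tsv(summary.to_frame(), run_dir / "trajectory_summary.tsv",
                       cfg_hash, index=False)
            try:
                labels, order = phase_cluster(summary, seed=stage_seed(
                    config.master_seed, "trace"))
                _write_tsv(labels.to_frame(), run_dir / "phase_labels.tsv", cfg_hash)
            except ValueError:
                pass  # too few non-constant genes to cluster (e.g. tiny gene panels)
            import h5py

            with h5py.File(run_dir / "pseudocells.h5", "w") as f:
                f.attrs["config_hash"] = cfg_hash
                f.create_dataset("expression", data=pc.expression)
                f.create_dataset("latents", data=pc.latents)
                f.create_dataset("profiles", data=pc.profiles)
                f.create_dataset("gene_ids", data=np.array(pc.gene_ids, dtype="S"))
            done.touch()
    except Exception as exc:
        with open(run_dir / "failure_manifest.yaml", "w") as fh:
            yaml.safe_dump({"stage": stage, "error": str(exc),
                            "traceback": traceback.format_exc()}, fh)
        raise
    return run_dir
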