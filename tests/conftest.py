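"""Shared fixtures: simulated datasets and trained models.

The expensive pieces (supervised encoder, decoder, conditional GAN on the
tiny simulated dataset) are trained once per session and reused by every
test that needs a fitted pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import pseudocell_tracer as pct


@dataclass
class TinyData:
    expr_counts: pct.ExpressionMatrix
    expr: pct.ExpressionMatrix          # log2(TPM+1)
    profiles: pct.AdjacentProfiles      # computed from the data
    planted: pct.AdjacentProfiles       # simulator ground truth
    truth: pct.GroundTruth
    cfg: pct.SimulationConfig


@dataclass
class TrainedModels:
    data: TinyData
    encoder: pct.EncoderModel
    decoder: pct.DecoderModel
    generator: pct.GeneratorModel
    discriminator: pct.DiscriminatorModel
    gan_history: "object"
    latents: np.ndarray


def _make_tiny(seed: int = 1) -> TinyData:
    cfg = pct.SimulationConfig(n_cells=200, n_genes=300, module_sizes=(25, 25, 25),
                               n_confounder_genes=50, seed=seed)
    counts, planted, truth = pct.simulate_csr_dataset(cfg)
    expr = pct.normalize_log2_tpm1(pct.filter_zero_genes(counts))
    profiles = pct.compute_adjacent_profiles(expr)
    return TinyData(counts, expr, profiles, planted, truth, cfg)


@pytest.fixture(scope="session")
def tiny_data() -> TinyData:
    return _make_tiny()


@pytest.fixture(scope="session")
def clean_data() -> TinyData:
    """Low-noise dataset where expression is driven by the planted axis:
    nearly every gene belongs to a trajectory-responsive module, negative
    binomial dispersion is negligible and dropout is off."""
    cfg = pct.SimulationConfig(n_cells=150, n_genes=110, module_sizes=(30, 30, 30),
                               n_confounder_genes=0, nb_dispersion=0.0,
                               dropout=False, mean_library_size=5e6, seed=7)
    counts, planted, truth = pct.simulate_csr_dataset(cfg)
    expr = pct.normalize_log2_tpm1(pct.filter_zero_genes(counts))
    profiles = pct.compute_adjacent_profiles(expr)
    return TinyData(counts, expr, profiles, planted, truth, cfg)


@dataclass
class CleanTrained:
    data: TinyData
    train_idx: np.ndarray
    test_idx: np.ndarray
    encoder: pct.EncoderModel
    decoder: pct.DecoderModel


@pytest.fixture(scope="session")
def clean_trained(clean_data: TinyData) -> CleanTrained:
    """Encoder + decoder fitted on 120 of the 150 clean cells; the other 30
    form a blind test set."""
    n = clean_data.expr.n_cells
    rng = np.random.default_rng(0)
    test_idx = np.sort(rng.choice(n, 30, replace=False))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    expr = clean_data.expr
    sub = pct.ExpressionMatrix(expr.values[train_idx], expr.gene_ids,
                               [expr.cell_ids[i] for i in train_idx],
                               expr.normalization_tag)
    prof = pct.AdjacentProfiles(clean_data.profiles.weights[train_idx],
                                clean_data.profiles.channel_ids,
                                [clean_data.profiles.cell_ids[i] for i in train_idx])
    espec = pct.EncoderSpec(input_dim=sub.n_genes, output_dim=8, batch_size=32)
    enc = pct.train_supervised_encoder(
        sub, prof, espec,
        pct.EarlyStopConfig(patience_epochs=150, max_epochs=3000), seed=2)
    z = enc.encode(sub.values)
    dspec = pct.DecoderSpec(output_dim=sub.n_genes, batch_size=32)
    dec = pct.train_decoder(
        z, sub, dspec, pct.EarlyStopConfig(patience_epochs=300, max_epochs=4000),
        seed=8, stratify_labels=prof.dominant_channel())
    return CleanTrained(clean_data, train_idx, test_idx, enc, dec)


@pytest.fixture(scope="session")
def trained(tiny_data: TinyData) -> TrainedModels:
    stop = pct.EarlyStopConfig(patience_epochs=100, max_epochs=1500)
    encoder = pct.train_supervised_encoder(tiny_data.expr, tiny_data.profiles,
                                           stop=stop, seed=3)
    latents = encoder.encode(tiny_data.expr.values)
    decoder = pct.train_decoder(latents, tiny_data.expr, stop=stop, seed=4,
                                stratify_labels=tiny_data.profiles.dominant_channel())
    gen, disc, history = pct.train_cgan(
        latents, tiny_data.profiles,
        cfg=pct.GanTrainConfig(seed=5, max_epochs=4500))
    return TrainedModels(tiny_data, encoder, decoder, gen, disc, history, latents)
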