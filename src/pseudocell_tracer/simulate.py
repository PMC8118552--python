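"""Synthetic scRNA-seq generator with planted class-switch trajectories.

Emulates the statistical structure of an antigen-induced germinal-center
B-cell dataset so the full pipeline can be exercised with known ground truth:

* per-cell relative isotype profiles dominated by one isotype, plus a
  minority of *transitioning* cells at intermediate positions ``t`` along a
  source -> target switch axis (IgM -> IgG1/IgG2b/IgG3);
* condition-correlated gene modules whose mean expression follows early /
  middle / late response curves in ``t``;
* a cell-cycle-like confounding program (low-rank oscillation, independent
  of ``t``) that dominates unsupervised variance when strong — the failure
  mode that motivates supervised latent shaping;
* negative-binomial counts with mean-dependent dropout.

Isotype (channel) genes are planted so that the *relative isotype
expression* computed downstream — per-channel log2(TPM+1) divided by the
cumulative log2(TPM+1) over channels — recovers the planted simplex weights:
a cell at coordinate ``t`` on a source->target axis has log-scale channel
means proportional to ``(1-t, t)`` on its two active channels. Isotype
transcripts are simulated as highly abundant (as they are in plasmablasts
and germinal-center B cells), which keeps the planted profile recoverable
from counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import (
    DEFAULT_CHANNELS,
    AdjacentProfiles,
    ExpressionMatrix,
    save_expression_mtx,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_csr_dataset", "make_fixture",
           "FIXTURE_PRESETS", "phase_curve"]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror a single-lane droplet experiment on switched B cells:
    ~1000 cells, 2000 genes, eight isotype channels with most cells stably
    switched and ~18% caught mid-transition.
    """

    n_cells: int = 1000
    n_genes: int = 2000
    channel_names: tuple = DEFAULT_CHANNELS
    #: fraction of cells stably expressing each channel (order = channel_names)
    channel_dominance: tuple = (0.30, 0.14, 0.10, 0.05, 0.09, 0.06, 0.05, 0.03)
    #: fraction of cells at intermediate t on a source->target axis
    transitioning_fraction: float = 0.18
    #: switch targets available to transitioning cells (IgM is always source)
    transition_targets: tuple = ("Ighg1", "Ighg2b", "Ighg3")
    #: genes per early/middle/late condition-driven module
    module_sizes: tuple = (60, 60, 60)
    #: response-curve peak positions for the early/middle/late modules
    phase_peaks: tuple = (0.1, 0.5, 0.9)
    phase_width: float = 0.18
    module_amplitude: float = 3.0  # log2 units
    n_confounder_genes: int = 200
    confounder_strength: float = 1.5  # log2 units
    #: cumulative log2(TPM+1) budget spread across isotype channels
    isotype_log_budget: float = 18.0
    nb_dispersion: float = 0.1
    dropout: bool = True
    mean_library_size: float = 50_000.0
    t_distribution: str = "uniform"  # or "beta" for sparse intermediate sampling
    t_beta_params: tuple = (0.4, 0.4)
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.channel_dominance) + self.transitioning_fraction
        if any(f < 0 for f in self.channel_dominance) or not 0 <= self.transitioning_fraction <= 1:
            raise ValueError("fractions must be non-negative")
        if total > 1 + 1e-9:
            raise ValueError(f"cell fractions sum to {total:.3f} > 1")
        if len(self.channel_dominance) != len(self.channel_names):
            raise ValueError("channel_dominance must match channel_names")
        reserved = len(self.channel_names) + sum(self.module_sizes) + self.n_confounder_genes
        if self.n_genes < reserved:
            raise ValueError(
                f"n_genes={self.n_genes} < {reserved} channel+module+confounder genes")
        if any(t not in self.channel_names for t in self.transition_targets):
            raise ValueError("transition targets must be channel names")


@dataclass
class GroundTruth:
    """Per-cell and per-gene truth records for a simulated dataset."""

    cells: pd.DataFrame   # index cell_id: t, source, target, confounder_phase, dominant
    genes: pd.DataFrame   # index gene_id: role, module, peak
    config: SimulationConfig

    def true_curve(self, gene_id: str, t_grid: np.ndarray) -> np.ndarray:
        """Planted mean log2-expression response of a module gene along t."""
        row = self.genes.loc[gene_id]
        if row["role"] != "module":
            raise KeyError(f"{gene_id} is not a module gene")
        return row["baseline"] + row["amplitude"] * phase_curve(
            np.asarray(t_grid, dtype=float), row["peak"], self.config.phase_width)


def phase_curve(t: np.ndarray, peak: float, width: float) -> np.ndarray:
    """Unimodal response in t; near-monotone when the peak sits at a boundary."""
    return np.exp(-((t - peak) ** 2) / (2.0 * width ** 2))


def _assign_cells(cfg: SimulationConfig, rng: np.random.Generator):
    """Draw (source, target, t) per cell. Stable cells sit at an endpoint."""
    n = cfg.n_cells
    names = list(cfg.channel_names)
    source_name = names[0]  # IgM: every switch trajectory starts here
    fracs = list(cfg.channel_dominance) + [cfg.transitioning_fraction]
    counts = np.floor(np.array(fracs) * n).astype(int)
    counts[0] += n - counts.sum()  # remainder goes to the source-dominant pool
    source = np.empty(n, dtype=object)
    target = np.empty(n, dtype=object)
    t = np.zeros(n)
    pos = 0
    for k, name in enumerate(names):
        m = counts[k]
        source[pos:pos + m] = source_name
        target[pos:pos + m] = name
        # stably switched = endpoint of its trajectory; stable IgM = origin
        t[pos:pos + m] = 0.0 if name == source_name else 1.0
        pos += m
    m = counts[-1]
    target[pos:] = rng.choice(list(cfg.transition_targets), size=m)
    source[pos:] = source_name
    if cfg.t_distribution == "beta":
        a, b = cfg.t_beta_params
        t[pos:] = rng.beta(a, b, size=m)
    else:
        t[pos:] = rng.uniform(0.0, 1.0, size=m)
    transitioning = np.zeros(n, dtype=bool)
    transitioning[pos:] = True
    perm = rng.permutation(n)
    return source[perm], target[perm], t[perm], transitioning[perm]


def simulate_csr_dataset(cfg: SimulationConfig):
    """Simulate counts with planted trajectories.

    Returns
    -------
    (expr, profiles, truth):
        ``expr`` — raw-count :class:`ExpressionMatrix`;
        ``profiles`` — the *planted* per-cell :class:`AdjacentProfiles`
        (what relative isotype expression is designed to recover);
        ``truth`` — :class:`GroundTruth` with per-cell/per-gene records.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_cells, cfg.n_genes
    K = len(cfg.channel_names)
    names = list(cfg.channel_names)

    source, target, t, transitioning = _assign_cells(cfg, rng)

    # planted simplex weights: (1-t) on source, t on target
    W = np.zeros((n, K))
    src_idx = np.array([names.index(s) for s in source])
    tgt_idx = np.array([names.index(x) for x in target])
    W[np.arange(n), src_idx] += 1.0 - t
    W[np.arange(n), tgt_idx] += t

    # --- mean log2-expression matrix ---------------------------------------
    log_mean = np.zeros((n, g))
    log_mean[:, :K] = cfg.isotype_log_budget * W

    phases = ("early", "middle", "late")
    gene_role = np.array(["background"] * g, dtype=object)
    gene_module = np.array([""] * g, dtype=object)
    gene_peak = np.full(g, np.nan)
    gene_baseline = np.zeros(g)
    gene_amplitude = np.zeros(g)
    gene_role[:K] = "channel"

    col = K
    for phase, size, peak in zip(phases, cfg.module_sizes, cfg.phase_peaks):
        cols = slice(col, col + size)
        base = rng.uniform(1.0, 3.0, size=size)
        amp = cfg.module_amplitude * rng.uniform(0.8, 1.2, size=size)
        log_mean[:, cols] = base + amp * phase_curve(t, peak, cfg.phase_width)[:, None]
        gene_role[cols] = "module"
        gene_module[cols] = phase
        gene_peak[cols] = peak
        gene_baseline[cols] = base
        gene_amplitude[cols] = amp
        col += size

    conf_cols = slice(col, col + cfg.n_confounder_genes)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    loadings = rng.normal(0.0, 1.0, size=(2, cfg.n_confounder_genes))
    conf_base = rng.uniform(2.0, 4.0, size=cfg.n_confounder_genes)
    oscillation = np.sin(phi)[:, None] * loadings[0] + np.cos(phi)[:, None] * loadings[1]
    log_mean[:, conf_cols] = conf_base + cfg.confounder_strength * oscillation
    gene_role[conf_cols] = "confounder"
    gene_baseline[conf_cols] = conf_base
    col += cfg.n_confounder_genes

    bg_base = rng.uniform(0.5, 4.0, size=g - col)
    log_mean[:, col:] = bg_base + rng.normal(0.0, 0.1, size=(n, g - col))
    gene_baseline[col:] = bg_base

    np.clip(log_mean, 0.0, None, out=log_mean)
    mean_tpm = np.exp2(log_mean) - 1.0

    # --- counts: gamma-poisson with mean-dependent dropout ------------------
    lib = rng.lognormal(np.log(cfg.mean_library_size), 0.1, size=n)
    mu = mean_tpm * (lib / 1e6)[:, None]
    if cfg.nb_dispersion > 0:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mu * cfg.nb_dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)
    if cfg.dropout:
        keep = rng.random((n, g)) >= np.exp(-np.maximum(mu, 1e-12))
        counts *= keep

    gene_ids = names + [f"gene_{i:05d}" for i in range(K, g)]
    cell_ids = [f"cell_{i:05d}" for i in range(n)]
    expr = ExpressionMatrix(counts, gene_ids, cell_ids, "raw_counts")
    profiles = AdjacentProfiles(W, names, cell_ids)

    cells = pd.DataFrame({
        "t": t, "source": source, "target": target,
        "transitioning": transitioning,
        "confounder_phase": phi, "confounder_score": np.sin(phi),
        "dominant": [names[i] for i in np.argmax(W, axis=1)],
    }, index=pd.Index(cell_ids, name="cell_id"))
    genes = pd.DataFrame({
        "role": gene_role, "module": gene_module, "peak": gene_peak,
        "baseline": gene_baseline, "amplitude": gene_amplitude,
    }, index=pd.Index(gene_ids, name="gene_id"))
    return expr, profiles, GroundTruth(cells, genes, cfg)


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

FIXTURE_PRESETS = {
    "tiny": dict(n_cells=200, n_genes=300, module_sizes=(25, 25, 25),
                 n_confounder_genes=50),
    "small": dict(n_cells=1000, n_genes=2000, module_sizes=(60, 60, 60),
                  n_confounder_genes=200),
    "paper_scale": dict(n_cells=7065, n_genes=6617, module_sizes=(150, 150, 150),
                        n_confounder_genes=400),
}


def make_fixture(size: str, out_dir, seed: int = 0) -> Path:
    """Write a simulated dataset bundle (MTX + TSVs + truth + config YAML)."""
    if size not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {size!r}; choose from {sorted(FIXTURE_PRESETS)}")
    cfg = SimulationConfig(seed=seed, **FIXTURE_PRESETS[size])
    expr, profiles, truth = simulate_csr_dataset(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_expression_mtx(expr, out_dir)
    profiles.to_frame().to_csv(out_dir / "planted_profiles.tsv", sep="\t")
    truth.cells.to_csv(out_dir / "ground_truth_cells.tsv", sep="\t")
    truth.genes.to_csv(out_dir / "ground_truth_genes.tsv", sep="\t")
    with open(out_dir / "simulation_config.yaml", "w") as fh:
        yaml.safe_dump({k: _yamlable(v) for k, v in vars(cfg).items()}, fh)
    return out_dir


def _yamlable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
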