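"""Pseudospace trajectories: conditioning axes, pseudocell generation, summaries.

A trajectory is a sequence of conditioning profiles interpolating linearly
from a source channel (e.g. Ighm at 100%) to a target channel (e.g. Ighg1),
stepping the source down and the target up by a fixed increment. For each
point the trained generator simulates replicate latent encodings, which the
trained decoder maps to full expression profiles — *pseudocells*. Per-gene
dynamics are summarized as mean curves with empirical 95% confidence bands,
optionally z-scored across the axis, and clustered into transcriptional
phases (early / middle / late) by the position of their peak response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .autoencoder import DecoderModel
from .cgan import GeneratorModel, generate_latents
from .preprocess import ExpressionMatrix

__all__ = [
    "TrajectorySpec", "PseudocellSet", "TrajectorySummary",
    "build_trajectory", "generate_pseudocells", "summarize_trajectory",
    "phase_cluster", "nearest_real_cell", "PHASE_NAMES",
]

PHASE_NAMES = ("early", "middle", "late")


@dataclass
class TrajectorySpec:
    """Linear source -> target conditioning axis.

    ``step`` is the per-point increment moved from source to target; it must
    divide 1 evenly, giving ``1/step + 1`` profiles. All other channels are
    held at zero.
    """

    source_channel: str
    target_channel: str
    channel_ids: list
    step: float = 0.01

    def __post_init__(self):
        if self.source_channel == self.target_channel:
            raise ValueError("source and target channels must differ")
        for ch in (self.source_channel, self.target_channel):
            if ch not in self.channel_ids:
                raise ValueError(f"{ch!r} not among channel ids {list(self.channel_ids)}")
        if not 0.0 < self.step <= 1.0:
            raise ValueError("step must be in (0, 1]")
        n = 1.0 / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"step={self.step} does not divide 1 evenly")

    @property
    def n_points(self) -> int:
        return int(round(1.0 / self.step)) + 1


@dataclass
class PseudocellSet:
    """Generated cells along a trajectory: points x replicates x genes."""

    profiles: np.ndarray    # points x K conditioning vectors
    latents: np.ndarray     # points x replicates x latent_dim
    expression: np.ndarray  # points x replicates x genes
    gene_ids: list
    channel_ids: list
    spec: TrajectorySpec

    @property
    def n_points(self) -> int:
        return self.expression.shape[0]

    @property
    def replicates(self) -> int:
        return self.expression.shape[1]

    @property
    def n_pseudocells(self) -> int:
        return self.n_points * self.replicates

    @property
    def axis(self) -> np.ndarray:
        """Trajectory coordinate t in [0, 1] per point."""
        return np.linspace(0.0, 1.0, self.n_points)


@dataclass
class TrajectorySummary:
    """Per-gene mean curves with 95% confidence bands along the axis."""

    axis: np.ndarray
    mean: pd.DataFrame    # points x genes
    lower: pd.DataFrame
    upper: pd.DataFrame
    zscored: pd.DataFrame | None = None

    @property
    def gene_ids(self) -> list:
        return list(self.mean.columns)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: gene, point, t, mean, lower, upper."""
        rows = []
        for g in self.mean.columns:
            rows.append(pd.DataFrame({
                "gene": g, "point": np.arange(len(self.axis)), "t": self.axis,
                "mean": self.mean[g].to_numpy(),
                "lower": self.lower[g].to_numpy(),
                "upper": self.upper[g].to_numpy(),
            }))
        return pd.concat(rows, ignore_index=True)


def build_trajectory(spec: TrajectorySpec) -> np.ndarray:
    """Conditioning profiles along the axis: point j has source ``1 - j*step``
    and target ``j*step``; exact simplex rows by construction."""
    n = spec.n_points
    K = len(spec.channel_ids)
    out = np.zeros((n, K))
    s = spec.channel_ids.index(spec.source_channel)
    t = spec.channel_ids.index(spec.target_channel)
    frac = np.linspace(0.0, 1.0, n)
    out[:, s] = 1.0 - frac
    out[:, t] = frac
    return out


def generate_pseudocells(trajectory: np.ndarray, generator: GeneratorModel,
                         decoder: DecoderModel, spec: TrajectorySpec,
                         replicates: int = 100, seed: int = 0) -> PseudocellSet:
    """Generate and decode ``replicates`` pseudocells per trajectory point."""
    trajectory = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if generator.spec.output_dim != decoder.spec.latent_dim:
        raise ValueError(
            f"generator latent dim {generator.spec.output_dim} != decoder "
            f"latent dim {decoder.spec.latent_dim}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    latents = generate_latents(generator, trajectory, replicates, seed=seed)
    p, r, d = latents.shape
    expr = decoder.decode(latents.reshape(p * r, d)).reshape(p, r, -1)
    return PseudocellSet(trajectory, latents, expr, list(decoder.gene_ids),
                         list(generator.channel_ids), spec)


def summarize_trajectory(pc: PseudocellSet, genes=None, zscore: bool = False,
                         ci: str = "percentile", clip_negative: bool = False
                         ) -> TrajectorySummary:
    """Mean and 95% CI per (point, gene) over generator replicates.

    The default confidence band is the empirical 2.5th-97.5th percentile of
    the replicates (distribution-free); ``ci="normal"`` uses mean ± 1.96·SE.
    With ``zscore=True`` each gene's *mean curve* is additionally standardized
    across trajectory points (constant curves are left at zero).
    """
    if pc.replicates < 2:
        raise ValueError("confidence intervals require at least 2 replicates")
    expr = pc.expression
    if clip_negative:
        expr = np.maximum(expr, 0.0)
    gene_ids = list(pc.gene_ids)
    if genes is not None:
        genes = list(genes)
        missing = [g for g in genes if g not in gene_ids]
        if missing:
            raise KeyError(f"unknown genes: {missing}")
        cols = [gene_ids.index(g) for g in genes]
        expr = expr[:, :, cols]
        gene_ids = genes
    mean = expr.mean(axis=1)
    if ci == "percentile":
        lower = np.percentile(expr, 2.5, axis=1)
        upper = np.percentile(expr, 97.5, axis=1)
    elif ci == "normal":
        se = expr.std(axis=1, ddof=1) / np.sqrt(pc.replicates)
        lower, upper = mean - 1.96 * se, mean + 1.96 * se
    else:
        raise ValueError(f"unknown ci method {ci!r}")
    idx = pd.RangeIndex(pc.n_points, name="point")
    summary = TrajectorySummary(
        pc.axis,
        pd.DataFrame(mean, index=idx, columns=gene_ids),
        pd.DataFrame(lower, index=idx, columns=gene_ids),
        pd.DataFrame(upper, index=idx, columns=gene_ids),
    )
    if zscore:
        mu = mean.mean(axis=0)
        sd = mean.std(axis=0, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (mean - mu) / sd, 0.0)
        summary.zscored = pd.DataFrame(z, index=idx, columns=gene_ids)
    return summary


def phase_cluster(summary: TrajectorySummary, n_phases: int = 3, seed: int = 0):
    """Cluster z-scored mean curves into transcriptional phases.

    k-means (10 restarts, seeded) on the per-gene standardized curves;
    clusters are labelled by the trajectory position of their mean peak, the
    earliest peak becoming phase ``early`` (then ``middle``, ``late``; with
    other ``n_phases`` the labels are ``phase_0`` ... ordered by peak).

    Returns ``(labels, order)``: a gene -> phase-name Series and a heatmap
    row ordering (genes grouped contiguously by phase, by peak position
    within a phase).
    """
    curves = summary.zscored
    if curves is None:
        mean = summary.mean.to_numpy()
        sd = mean.std(axis=0, ddof=0)
        keep = sd > 0
        z = np.zeros_like(mean)
        z[:, keep] = (mean[:, keep] - mean[:, keep].mean(axis=0)) / sd[keep]
        curves = pd.DataFrame(z, columns=summary.mean.columns)
        nonconstant = keep
    else:
        nonconstant = curves.to_numpy().std(axis=0) > 0
    if nonconstant.sum() < n_phases:
        raise ValueError(
            f"need >= {n_phases} genes with non-constant curves, "
            f"found {int(nonconstant.sum())}")
    genes = np.array(summary.gene_ids)[nonconstant]
    X = curves.to_numpy().T[nonconstant]  # genes x points
    km = KMeans(n_clusters=n_phases, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    # order clusters by the axis position of their mean-curve peak
    peaks = np.array([summary.axis[np.argmax(km.cluster_centers_[c])]
                      for c in range(n_phases)])
    rank = {c: i for i, c in enumerate(np.argsort(peaks, kind="stable"))}
    names = (list(PHASE_NAMES) if n_phases == 3
             else [f"phase_{i}" for i in range(n_phases)])
    labels = pd.Series([names[rank[c]] for c in raw], index=genes, name="phase")
    gene_peak = summary.axis[np.argmax(X, axis=1)]
    order_idx = np.lexsort((gene_peak, [rank[c] for c in raw]))
    return labels, list(genes[order_idx])


def nearest_real_cell(pc: PseudocellSet, expr: ExpressionMatrix,
                      metric: str = "euclidean") -> pd.DataFrame:
    """Exact nearest real cell for every pseudocell under ``metric``.

    Pseudocells and reference cells must share the gene space. Returns a
    DataFrame with point, replicate, nearest cell id and distance.
    """
    if expr.n_cells == 0:
        raise ValueError("empty reference matrix")
    if list(expr.gene_ids) != list(pc.gene_ids):
        raise ValueError("pseudocells and reference are in different gene spaces")
    flat = pc.expression.reshape(pc.n_pseudocells, -1)
    dists = cdist(flat, expr.values, metric=metric)
    nn = dists.argmin(axis=1)
    points, reps = np.divmod(np.arange(pc.n_pseudocells), pc.replicates)
    return pd.DataFrame({
        "point": points, "replicate": reps,
        "nearest_cell": [expr.cell_ids[i] for i in nn],
        "distance": dists[np.arange(len(nn)), nn],
    })
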