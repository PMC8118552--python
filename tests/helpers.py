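"""Shared test utilities."""

import numpy as np
import pandas as pd

from pseudocell_tracer.pseudospace import TrajectorySummary


def planted_phase_summary(n_per_phase=40, peaks=(0.1, 0.5, 0.9), noise=0.05,
                          seed=0, n_points=101):
    """Trajectory summary with gene curves peaking early/middle/late plus
    noise, and the planted phase labels."""
    rng = np.random.default_rng(seed)
    axis = np.linspace(0, 1, n_points)
    curves, names, truth = [], [], []
    for phase, peak in zip(("early", "middle", "late"), peaks):
        for j in range(n_per_phase):
            c = np.exp(-((axis - peak) ** 2) / (2 * 0.15**2))
            curves.append(c + rng.normal(0, noise, n_points))
            names.append(f"{phase}_{j}")
            truth.append(phase)
    mean = pd.DataFrame(np.array(curves).T, columns=names)
    z = (mean - mean.mean()) / mean.std(ddof=0)
    summary = TrajectorySummary(axis, mean, mean, mean, zscored=z)
    return summary, pd.Series(truth, index=names)
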