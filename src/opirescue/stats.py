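"""Bootstrap summary of cardiac-arrest incidence.

The virtual trial reports the percentage of subjects with cardiac arrest;
uncertainty is summarized by repeatedly drawing subsamples of size ``m``
from the N per-subject outcomes and taking the median and the 2.5th/97.5th
percentiles of the resampled incidences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BootstrapSummary:
    median: float  # %
    p2_5: float  # %
    p97_5: float  # %
    n_resamples: int
    resample_size: int

    def to_dict(self) -> dict:
        return {
            "incidence_median_pct": self.median,
            "ci95": [self.p2_5, self.p97_5],
            "m": self.resample_size,
            "B": self.n_resamples,
        }


def bootstrap_incidence(
    outcomes,
    m: int = 400,
    b: int = 2500,
    seed: int = 0,
    replace: bool = True,
) -> BootstrapSummary:
    """Percentile bootstrap of the arrest percentage.

    Draws ``b`` subsamples of size ``m`` (with replacement by default) from
    the binary outcome vector and summarizes the resampled percentages.
    Deterministic given ``seed``.
    """
    x = np.asarray(outcomes, dtype=float)
    if x.size == 0:
        raise ValueError("empty outcome vector")
    n = x.size
    if not 1 <= m <= n:
        raise ValueError(f"resample size m={m} must lie in [1, {n}]")
    if b < 1:
        raise ValueError("number of resamples must be >= 1")
    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(0, n, size=(b, m))
    else:
        idx = np.array([rng.permutation(n)[:m] for _ in range(b)])
    pct = 100.0 * x[idx].mean(axis=1)
    lo, med, hi = np.percentile(pct, [2.5, 50.0, 97.5])
    return BootstrapSummary(
        median=float(med), p2_5=float(lo), p97_5=float(hi), n_resamples=b, resample_size=m
    )
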