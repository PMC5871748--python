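"""Pre-classification feature filters: near-zero-variance and collinearity.

Both filters run once on the full cohort, outside cross-validation, before
any labels are seen.  They are unsupervised, but because they precede the
train/test splitting they are a (mild, label-free) leakage trade-off; see
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix

DEFAULT_FREQ_RATIO_CUTOFF = 19.0
DEFAULT_UNIQUE_FRACTION_CUTOFF = 0.10
DEFAULT_R_CUTOFF = 0.70


@dataclass
class ReductionReport:
    """Audit trail of one filtering pass."""

    removed_nzv: dict[str, float] = field(default_factory=dict)  # name -> freq ratio
    removed_collinear: dict[str, tuple[str, float]] = field(default_factory=dict)
    # name -> (other member of the offending pair, |r| that triggered removal)
    retained: list[str] = field(default_factory=list)


def _round_sig(x: np.ndarray, sig: int = 8) -> np.ndarray:
    """Round to `sig` significant digits so continuous values can tie."""
    x = np.asarray(x, dtype=float)
    out = x.copy()
    nz = (x != 0) & np.isfinite(x)
    mag = np.floor(np.log10(np.abs(x[nz])))
    out[nz] = np.round(x[nz] / 10**mag, sig - 1) * 10**mag
    return out


def frequency_ratio(values: np.ndarray) -> tuple[float, float]:
    """(most-frequent count / second-most-frequent count, unique fraction).

    Values are compared after rounding to 8 significant digits; a constant
    column has an infinite ratio (second-most-frequent count is 0).
    """
    rounded = _round_sig(values)
    _, counts = np.unique(rounded, return_counts=True)
    counts = np.sort(counts)[::-1]
    ratio = float("inf") if len(counts) < 2 else counts[0] / counts[1]
    unique_fraction = len(counts) / len(rounded)
    return float(ratio), float(unique_fraction)


def near_zero_variance_filter(
    m: FeatureMatrix,
    freq_ratio_cutoff: float = DEFAULT_FREQ_RATIO_CUTOFF,
    unique_fraction_cutoff: float = DEFAULT_UNIQUE_FRACTION_CUTOFF,
) -> tuple[FeatureMatrix, ReductionReport]:
    """Remove features with near-zero between-subject variance.

    A feature goes when its frequency ratio (count of the most prevalent
    value over the second most prevalent) exceeds the cutoff AND its
    distinct-value fraction falls below the cutoff.  Constant features are
    always removed.
    """
    if m.data.shape[0] < 2:
        raise ValueError("need at least 2 subjects to assess variance")
    report = ReductionReport()
    keep = []
    for name in m.data.columns:
        ratio, uniq = frequency_ratio(m.data[name].to_numpy())
        constant = not np.isfinite(ratio) and uniq <= 1 / m.data.shape[0] + 1e-12
        if constant or (ratio > freq_ratio_cutoff and uniq < unique_fraction_cutoff):
            report.removed_nzv[name] = ratio
        else:
            keep.append(name)
    report.retained = keep
    filtered = FeatureMatrix(data=m.data[keep], blocks=m.blocks[keep])
    return filtered, report


def collinearity_filter(
    m: FeatureMatrix, r_cutoff: float = DEFAULT_R_CUTOFF
) -> tuple[FeatureMatrix, ReductionReport]:
    """Greedy removal of highly collinear features.

    While any pair exceeds ``r_cutoff`` in absolute Pearson correlation,
    take the worst offending pair and remove the member with the larger
    mean absolute correlation with all other currently retained features
    (i.e. retain the one with least).  Mean-correlation ties are broken by
    removing the lexicographically later name.  The output matrix has max
    pairwise |r| <= r_cutoff.
    """
    report = ReductionReport()
    names = list(m.data.columns)
    if len(names) < 2:
        report.retained = names
        return m, report

    corr = np.abs(np.corrcoef(m.data.to_numpy(), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr, nan=0.0)
    alive = np.ones(len(names), dtype=bool)

    while True:
        sub = np.where(np.outer(alive, alive), corr, 0.0)
        worst = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[worst] <= r_cutoff:
            break
        i, j = worst
        n_alive = alive.sum()
        mean_i = (sub[i].sum()) / (n_alive - 1)
        mean_j = (sub[j].sum()) / (n_alive - 1)
        if np.isclose(mean_i, mean_j):
            drop = i if names[i] > names[j] else j
        else:
            drop = i if mean_i > mean_j else j
        other = j if drop == i else i
        report.removed_collinear[names[drop]] = (names[other], float(sub[worst]))
        alive[drop] = False

    report.retained = [n for n, a in zip(names, alive) if a]
    filtered = FeatureMatrix(
        data=m.data[report.retained], blocks=m.blocks[report.retained]
    )
    return filtered, report


def reduce_features(
    m: FeatureMatrix,
    freq_ratio_cutoff: float = DEFAULT_FREQ_RATIO_CUTOFF,
    unique_fraction_cutoff: float = DEFAULT_UNIQUE_FRACTION_CUTOFF,
    r_cutoff: float = DEFAULT_R_CUTOFF,
) -> tuple[FeatureMatrix, ReductionReport, ReductionReport]:
    """Near-zero-variance filter followed by the collinearity filter."""
    m1, nzv_report = near_zero_variance_filter(
        m, freq_ratio_cutoff, unique_fraction_cutoff
    )
    m2, col_report = collinearity_filter(m1, r_cutoff)
    return m2, nzv_report, col_report
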