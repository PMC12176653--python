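"""Phenotype-composition tables and treatment-shift statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


@dataclass
class CompositionShift:
    counts: pd.DataFrame        # conditions x phenotypes
    percentages: pd.DataFrame   # rows sum to 100
    jsd_vs_control: pd.Series   # Jensen-Shannon divergence (base 2) per condition
    chi2_statistic: float
    chi2_p_value: float
    control: str


def jensen_shannon_divergence(p, q, base: float = 2.0) -> float:
    """JSD(p, q) in bits by default; 0 iff p == q, max 1 (base 2)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * (np.log(a[mask] / b[mask]) / np.log(base))))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def occupancy_shift(
    phenotype_labels,
    condition_labels,
    control: str | None = None,
) -> CompositionShift:
    """Per-condition phenotype percentages plus divergence from control.

    The chi-square test of homogeneity is computed on the raw count
    table; Jensen-Shannon divergence (base 2) is reported per condition
    against ``control`` (default: first condition encountered).  Empty
    conditions are dropped with a warning.
    """
    df = pd.DataFrame({
        "phenotype": np.asarray(phenotype_labels),
        "condition": np.asarray(condition_labels),
    })
    counts = pd.crosstab(df["condition"], df["phenotype"])
    empty = counts.index[counts.sum(axis=1) == 0]
    if len(empty):
        warnings.warn(f"conditions with no organoids dropped: {list(empty)}",
                      stacklevel=2)
        counts = counts.drop(index=empty)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 non-empty conditions")
    control = control if control is not None else str(counts.index[0])
    if control not in counts.index:
        raise ValueError(f"control condition {control!r} not present")

    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    ctrl = counts.loc[control].to_numpy(float)
    jsd = pd.Series({
        str(c): jensen_shannon_divergence(counts.loc[c].to_numpy(float), ctrl)
        for c in counts.index
    }, name="jsd_vs_control")

    # chi-square needs no all-zero columns
    tbl = counts.loc[:, counts.sum(axis=0) > 0].to_numpy(float)
    if tbl.shape[1] < 2:
        stat, p = 0.0, 1.0  # a single phenotype: no shift testable
    else:
        stat, p, *_ = chi2_contingency(tbl)
    return CompositionShift(counts, pct, jsd, float(stat), float(p), control)
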