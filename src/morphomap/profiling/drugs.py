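"""Dose-response summarization: AUC, GI50 and per-drug z-scores.

AUC is the trapezoid of relative viability over log10 concentration,
normalized by the log-range, so a drug with no effect (viability 1
everywhere) scores exactly 1 and a fully lethal drug approaches 0.  GI50
is the concentration at which viability first crosses 0.5, interpolated
log-linearly between the bracketing dilution points; curves that never
cross are censored at the boundary concentration.  z-scores of AUC
across clones use the population (ddof=0) convention, so a two-clone
contrast yields exactly {-1, +1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DrugResponseSummary:
    auc: pd.DataFrame           # drugs x clones
    gi50: pd.DataFrame          # drugs x clones (NaN where curve skipped)
    gi50_censored: pd.DataFrame  # bool: no 0.5 crossing observed
    zscore: pd.DataFrame        # drugs x clones, per-drug population z of AUC
    skipped: list[tuple[str, str]]


def curve_auc(concentrations, viability) -> float:
    c = np.log10(np.asarray(concentrations, float))
    v = np.asarray(viability, float)
    if len(c) < 2:
        raise ValueError("need >= 2 concentrations")
    return float(np.trapezoid(v, c) / (c[-1] - c[0]))


def curve_gi50(concentrations, viability) -> tuple[float, bool]:
    """First downward 0.5 crossing, log-linear in concentration.

    Returns (gi50, censored).  Censored at the top concentration when the
    curve never reaches 0.5, at the bottom when it starts below 0.5.
    """
    c = np.asarray(concentrations, float)
    v = np.asarray(viability, float)
    lc = np.log10(c)
    if v[0] < 0.5:
        return float(c[0]), True
    for i in range(len(v) - 1):
        if v[i] >= 0.5 > v[i + 1]:
            t = (v[i] - 0.5) / (v[i] - v[i + 1])
            return float(10 ** (lc[i] + t * (lc[i + 1] - lc[i]))), False
    return float(c[-1]), True


def drug_response_summary(curves: dict) -> DrugResponseSummary:
    """Summarize a {(drug, clone): curve} mapping.

    ``curve`` is anything with ``concentrations`` and ``viability``
    attributes, or a (concentrations, viability) pair.  Curves with fewer
    than 2 finite viability points are skipped and reported.
    """
    drugs = sorted({d for d, _ in curves})
    clones = sorted({c for _, c in curves})
    auc = pd.DataFrame(np.nan, index=drugs, columns=clones)
    gi = pd.DataFrame(np.nan, index=drugs, columns=clones)
    cen = pd.DataFrame(False, index=drugs, columns=clones)
    skipped = []
    for (d, cl), curve in curves.items():
        if hasattr(curve, "concentrations"):
            conc, viab = curve.concentrations, curve.viability
        else:
            conc, viab = curve
        conc = np.asarray(conc, float)
        viab = np.asarray(viab, float)
        ok = np.isfinite(viab) & np.isfinite(conc)
        if ok.sum() < 2:
            skipped.append((d, cl))
            warnings.warn(f"curve ({d}, {cl}) skipped: <2 finite points",
                          stacklevel=2)
            continue
        auc.loc[d, cl] = curve_auc(conc[ok], viab[ok])
        g, flag = curve_gi50(conc[ok], viab[ok])
        gi.loc[d, cl] = g
        cen.loc[d, cl] = flag

    z = auc.copy()
    for d in drugs:
        row = auc.loc[d].to_numpy(float)
        m = np.nanmean(row)
        s = np.nanstd(row)  # population sd
        z.loc[d] = (row - m) / s if s > 0 else 0.0
    return DrugResponseSummary(auc, gi, cen, z, skipped)
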