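"""Per-organoid feature matrices.

The default "classical" backend concatenates the standardized
morphometric descriptors with simple intensity/texture summaries — a
deterministic, CPU-cheap stand-in that feeds the same embedding /
clustering chain as a learned extractor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..morphometry.measure import MorphometricRecord


@dataclass
class FeatureMatrix:
    values: np.ndarray              # organoids x features, z-scored
    feature_names: list[str]
    backend: str = "classical"
    zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature count does not match names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def intensity_stats(image: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Simple foreground intensity/texture summaries."""
    vals = np.asarray(image, float)[mask] if mask.any() else np.zeros(1)
    q10, q50, q90 = np.percentile(vals, [10, 50, 90])
    return {
        "int_mean": float(vals.mean()),
        "int_sd": float(vals.std()),
        "int_p10": float(q10),
        "int_p50": float(q50),
        "int_p90": float(q90),
        "fg_area_px": float(mask.sum()),
    }


def extract_features_classical(
    records: list[MorphometricRecord],
    texture: list[dict[str, float]] | None = None,
    log_counts: bool = True,
) -> FeatureMatrix:
    """Build a z-scored feature matrix from morphometric records.

    Count-valued descriptors are log1p-compressed by default.  Features
    with zero variance across the cohort are flagged and set to 0.
    Raises if any record is missing.
    """
    for i, r in enumerate(records):
        if r is None:
            raise ValueError(f"missing morphometric record for organoid {i}")
    rows = []
    count_fields = {
        "n_main_branches", "n_nodes", "n_endpoints", "n_terminal_end_buds",
        "n_spiky_branches", "n_lumens", "n_components",
    }
    for i, r in enumerate(records):
        row = {}
        for f in MorphometricRecord.FEATURE_FIELDS:
            v = float(getattr(r, f))
            if log_counts and f in count_fields:
                v = np.log1p(v)
            elif f in ("total_lumen_area_um2", "core_area_um2"):
                v = np.log1p(v)
            row[f] = v
        if texture is not None:
            row.update(texture[i])
        rows.append(row)
    df = pd.DataFrame(rows)
    X = df.to_numpy(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd < 1e-12
    zero_var = [c for c, z in zip(df.columns, dead) if z]
    if zero_var:
        warnings.warn(f"zero-variance features: {zero_var}", stacklevel=2)
    sd_safe = np.where(dead, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, dead] = 0.0
    return FeatureMatrix(Z, list(df.columns), "classical", zero_var)
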