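"""Seven-point three-fold dose-response viability curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def default_concentrations(c_max: float = 10.0, n: int = 7, fold: float = 3.0):
    """Serial n-point `fold`-fold dilution ending at ``c_max`` (ascending)."""
    return tuple(c_max / fold ** k for k in range(n - 1, -1, -1))


@dataclass(frozen=True)
class DoseResponseCurve:
    concentrations: tuple[float, ...]
    viability: tuple[float, ...]
    true_gi50: float
    noise_sd: float

    def __post_init__(self):
        c = np.asarray(self.concentrations)
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        v = np.asarray(self.viability)
        if np.any(v < 0) or np.any(v > 1.2):
            raise ValueError("viability must lie in [0, 1.2]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "concentration": self.concentrations, "viability": self.viability,
        })


def generate_dose_response(
    gi50: float,
    hill: float = 1.0,
    floor: float = 0.0,
    noise_sd: float = 0.0,
    concentrations: tuple[float, ...] | None = None,
    seed: int = 0,
) -> DoseResponseCurve:
    """Four-parameter logistic viability curve with seeded noise.

    ``viability(c) = floor + (1 - floor) / (1 + (c / gi50)**hill)``,
    plus N(0, noise_sd) noise, clipped to [0, 1.2] (values slightly above
    1 occur in vehicle-normalized screens).
    """
    if gi50 <= 0:
        raise ValueError("gi50 must be positive")
    if hill <= 0:
        raise ValueError("hill must be positive")
    if not 0 <= floor < 1:
        raise ValueError("floor must be in [0, 1)")
    c = np.asarray(concentrations if concentrations is not None
                   else default_concentrations(), float)
    v = floor + (1.0 - floor) / (1.0 + (c / gi50) ** hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    v = np.clip(v, 0.0, 1.2)
    return DoseResponseCurve(tuple(c), tuple(v), float(gi50), float(noise_sd))
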