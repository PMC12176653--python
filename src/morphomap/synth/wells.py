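"""Limiting-dilution well tables under the single-hit Poisson model.

A well (collagen gel) seeded with ``dose`` cells responds — contains at
least one branched structure after culture — iff at least one seeded cell
is structure-forming.  With active-cell frequency ``f`` the response
probability is ``1 - exp(-f * dose)``.  The default design matches the
assay: doses of 20, 10, 3 and 1 cells per gel, at least 8 gels per dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_DOSES = (20, 10, 3, 1)
DEFAULT_WELLS_PER_DOSE = 8


@dataclass(frozen=True)
class LimitingDilutionTable:
    """Rows of (dose in cells, wells tested, wells responding)."""

    dose_cells: tuple[int, ...]
    n_wells: tuple[int, ...]
    n_responding: tuple[int, ...]

    def __post_init__(self):
        if len(self.dose_cells) < 1:
            raise ValueError("need at least one dose row")
        if not (len(self.dose_cells) == len(self.n_wells) == len(self.n_responding)):
            raise ValueError("ragged table")
        if len(set(self.dose_cells)) != len(self.dose_cells):
            raise ValueError("doses must be distinct")
        for d, n, r in zip(self.dose_cells, self.n_wells, self.n_responding):
            if d <= 0 or n <= 0:
                raise ValueError("doses and well counts must be positive")
            if not 0 <= r <= n:
                raise ValueError("n_responding must lie in [0, n_wells]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose": self.dose_cells, "tested": self.n_wells,
            "responding": self.n_responding,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LimitingDilutionTable":
        return cls(tuple(int(x) for x in df["dose"]),
                   tuple(int(x) for x in df["tested"]),
                   tuple(int(x) for x in df["responding"]))


def generate_limiting_dilution(
    true_frequency: float,
    doses: tuple[int, ...] = DEFAULT_DOSES,
    wells_per_dose: int = DEFAULT_WELLS_PER_DOSE,
    seed: int = 0,
) -> LimitingDilutionTable:
    """Simulate a seeded limiting-dilution experiment."""
    if not 0.0 < true_frequency <= 1.0:
        raise ValueError("true_frequency must be in (0, 1]")
    if wells_per_dose < 1:
        raise ValueError("wells_per_dose must be >= 1")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    p = 1.0 - np.exp(-true_frequency * np.asarray(doses, float))
    resp = rng.binomial(wells_per_dose, p)
    return LimitingDilutionTable(
        tuple(int(d) for d in doses),
        tuple([wells_per_dose] * len(doses)),
        tuple(int(r) for r in resp),
    )
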