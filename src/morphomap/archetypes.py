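"""Phenotype archetypes for branched-organoid rendering.

Each archetype describes one of the morphological families observed in
single-cell-derived branched PDAC organoids: four epithelial families
(terminal-end-bud branching organoid "TEBBO", cystic branched, thick
branched, tree-like), three mesenchymal families (branched mesenchymal,
firework, star-like), plus two auxiliary forms (clump: an unbranched
spheroid; scattered: disconnected single cells / small clusters that never
formed an organoid).

All lengths are in micrometres.  The numeric defaults are the generator's
study conditions: they are chosen so that each family carries the
structural features that define it in brightfield images (end buds,
micro-lumens, a near-circular invasive core, a net of thin branches, ...)
at sizes loosely matched to reported organoid dimensions (major axes of
several hundred µm up to ~1.5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

PHENOTYPES = (
    "TEBBO",
    "cystic_branched",
    "thick_branched",
    "tree_like",
    "branched_mesenchymal",
    "firework",
    "star_like",
    "clump",
    "scattered",
)

#: The eight families rendered as a single connected organoid body; the
#: "scattered" form is auxiliary (disconnected debris).
MURINE_FAMILIES = PHENOTYPES[:8]

#: Surrogate "cell line" identity used for extractor training: epithelial
#: vs mesenchymal vs auxiliary, mirroring the subtype the organoid grew from.
LINE_OF = {
    "TEBBO": "epithelial",
    "cystic_branched": "epithelial",
    "thick_branched": "epithelial",
    "tree_like": "epithelial",
    "branched_mesenchymal": "mesenchymal",
    "firework": "mesenchymal",
    "star_like": "mesenchymal",
    "clump": "auxiliary",
    "scattered": "auxiliary",
}


@dataclass(frozen=True)
class PhenotypeArchetype:
    """Parametric description of one morphological family.

    A zero value disables the corresponding feature (e.g. ``n_lumens = 0``
    means no micro-lumens are carved).  ``trunk_*`` fields describe the core
    branch for trunk-built families and are ignored for core-built ones
    (``core_radius_um > 0``), where branches radiate from a central disk.
    """

    name: str
    trunk_length_um: float = 0.0
    trunk_thickness_um: float = 0.0
    n_main_branches: int = 0
    n_sub_branches: int = 0
    n_terminal_end_buds: int = 0
    bud_radius_um: float = 0.0
    n_lumens: int = 0
    lumen_radius_um: float = 0.0
    core_radius_um: float = 0.0
    n_spiky_branches: int = 0
    granularity_sigma: float = 0.0
    # secondary geometry (branch sizes); exposed for completeness
    main_branch_length_um: float = 0.0
    main_branch_thickness_um: float = 0.0
    sub_branch_length_um: float = 0.0
    sub_branch_thickness_um: float = 0.0
    spike_length_um: float = 0.0
    spike_thickness_um: float = 6.0
    # scattered-only
    n_fragments: int = 0
    fragment_radius_um: tuple[float, float] = (4.0, 8.0)

    def __post_init__(self):
        if self.name not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.name!r}")
        for f in (
            "trunk_length_um", "trunk_thickness_um", "bud_radius_um",
            "lumen_radius_um", "core_radius_um", "granularity_sigma",
            "main_branch_length_um", "main_branch_thickness_um",
            "sub_branch_length_um", "sub_branch_thickness_um",
            "spike_length_um", "spike_thickness_um",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        for f in (
            "n_main_branches", "n_sub_branches", "n_terminal_end_buds",
            "n_lumens", "n_spiky_branches", "n_fragments",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be a non-negative integer")
        if self.name == "TEBBO" and self.n_terminal_end_buds < 1:
            raise ValueError("TEBBO requires at least one terminal end bud")
        if self.name == "clump" and (self.n_main_branches or self.n_sub_branches):
            raise ValueError("clump has zero branches")
        if self.name == "star_like" and not (
            self.core_radius_um > 0 and self.n_main_branches >= 3
        ):
            raise ValueError("star_like needs a core and >= 3 branches")
        if self.name == "scattered" and self.n_fragments < 2:
            raise ValueError("scattered renders >= 2 disconnected components")


def _a(**kw) -> PhenotypeArchetype:
    return PhenotypeArchetype(**kw)


DEFAULT_ARCHETYPES: dict[str, PhenotypeArchetype] = {
    # epithelial: trunk + sub-branches ending in bulbous terminal end buds
    "TEBBO": _a(
        name="TEBBO", trunk_length_um=600, trunk_thickness_um=30,
        n_main_branches=4, n_sub_branches=2, n_terminal_end_buds=5,
        bud_radius_um=25,
        main_branch_length_um=180, main_branch_thickness_um=18,
        sub_branch_length_um=110, sub_branch_thickness_um=13,
        granularity_sigma=0.04,
    ),
    # epithelial: large cystic core carved by micro-lumens, a few branches
    "cystic_branched": _a(
        name="cystic_branched", core_radius_um=110,
        n_main_branches=3, n_lumens=4, lumen_radius_um=20,
        main_branch_length_um=150, main_branch_thickness_um=24,
        granularity_sigma=0.04,
    ),
    # epithelial: short thick trunk, few thick branches, high granularity
    "thick_branched": _a(
        name="thick_branched", trunk_length_um=500, trunk_thickness_um=50,
        n_main_branches=3,
        main_branch_length_um=170, main_branch_thickness_um=32,
        granularity_sigma=0.20,
    ),
    # epithelial: thin trunk, many branch generations, invasive spikes
    "tree_like": _a(
        name="tree_like", trunk_length_um=700, trunk_thickness_um=16,
        n_main_branches=4, n_sub_branches=5, n_spiky_branches=2,
        main_branch_length_um=200, main_branch_thickness_um=13,
        sub_branch_length_um=110, sub_branch_thickness_um=11,
        spike_length_um=70, spike_thickness_um=6,
        granularity_sigma=0.04,
    ),
    # mesenchymal: dense cellular core with thick invasive branches
    "branched_mesenchymal": _a(
        name="branched_mesenchymal", core_radius_um=65,
        n_main_branches=5,
        main_branch_length_um=180, main_branch_thickness_um=36,
        granularity_sigma=0.12,
    ),
    # mesenchymal: small core bursting into a net of many thin branches
    "firework": _a(
        name="firework", core_radius_um=32,
        n_main_branches=12, n_sub_branches=6,
        main_branch_length_um=220, main_branch_thickness_um=9,
        sub_branch_length_um=90, sub_branch_thickness_um=8,
        granularity_sigma=0.06,
    ),
    # mesenchymal: near-perfect circular core with thin radiating branches
    "star_like": _a(
        name="star_like", core_radius_um=120,
        n_main_branches=8,
        main_branch_length_um=250, main_branch_thickness_um=14,
        granularity_sigma=0.06,
    ),
    # auxiliary: unbranched spheroid
    "clump": _a(
        name="clump", core_radius_um=140, granularity_sigma=0.10,
    ),
    # auxiliary: disconnected single cells / debris
    "scattered": _a(
        name="scattered", n_fragments=15, fragment_radius_um=(4.0, 8.0),
        granularity_sigma=0.0,
    ),
}


_JITTER_REAL_FIELDS = (
    "trunk_length_um", "trunk_thickness_um", "bud_radius_um",
    "lumen_radius_um", "core_radius_um",
    "main_branch_length_um", "main_branch_thickness_um",
    "sub_branch_length_um", "sub_branch_thickness_um",
    "spike_length_um", "spike_thickness_um", "granularity_sigma",
)
_JITTER_COUNT_FIELDS = (
    "n_main_branches", "n_sub_branches", "n_terminal_end_buds",
    "n_lumens", "n_spiky_branches", "n_fragments",
)
# hard minimums that keep a jittered archetype a member of its family
_COUNT_FLOORS = {
    "TEBBO": {"n_terminal_end_buds": 1, "n_main_branches": 2},
    "cystic_branched": {"n_main_branches": 3, "n_lumens": 1},
    "star_like": {"n_main_branches": 3},
    "firework": {"n_main_branches": 8},
    "scattered": {"n_fragments": 5},
}


def jitter_archetype(
    archetype: PhenotypeArchetype, jitter: float, rng: np.random.Generator
) -> PhenotypeArchetype:
    """Draw a per-organoid variant of ``archetype``.

    Each positive real parameter is multiplied by ``1 + jitter*z`` with
    ``z ~ N(0,1)`` truncated to ±2.5; counts are perturbed the same way and
    rounded, with family-defining floors enforced (a star always keeps >= 3
    branches, a TEBBO >= 1 bud, ...).
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    kw = {}
    for f in _JITTER_REAL_FIELDS:
        v = getattr(archetype, f)
        if v > 0 and jitter > 0:
            z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
            kw[f] = v * (1.0 + jitter * z)
    floors = _COUNT_FLOORS.get(archetype.name, {})
    for f in _JITTER_COUNT_FIELDS:
        v = getattr(archetype, f)
        if v > 0 and jitter > 0:
            z = float(np.clip(rng.standard_normal(), -2.5, 2.5))
            kw[f] = max(floors.get(f, 0), int(round(v * (1.0 + jitter * z))))
    return replace(archetype, **kw) if kw else archetype
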