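"""Rule-based phenotype assignment from a morphometric record.

A fixed-order decision list mirroring how the morphological families are
told apart by eye: disconnected debris first, then the unbranched clump,
then the mesenchymal core-built families (star-like, firework, branched
mesenchymal), then the epithelial families (cystic branched by its
micro-lumens, TEBBO by its end buds, tree-like by its many terminals,
thick branched as the branched remainder).  The first matching rule wins;
its margin is the distance of the discriminating feature from the rule
threshold.  Ties between intermediate morphologies are resolved by this
declared order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .measure import MorphometricRecord

UNCLASSIFIED = "unclassified"


@dataclass
class ClassifierThresholds:
    scattered_min_components: int = 5
    star_min_circularity: float = 0.85
    star_min_branches: int = 3
    star_min_core_thickness_um: float = 170.0
    firework_min_endpoints: int = 12
    firework_core_thickness_um: tuple[float, float] = (40.0, 100.0)
    bm_min_circularity: float = 0.60
    bm_min_core_thickness_um: float = 85.0
    cystic_min_lumens: int = 1
    tebbo_min_buds: int = 2
    tree_min_endpoints: int = 8
    thick_min_branches: int = 1


def classify_rule_based(
    record: MorphometricRecord,
    thresholds: ClassifierThresholds | None = None,
) -> tuple[str, float]:
    """Return (phenotype label, margin on the discriminating feature)."""
    t = thresholds or ClassifierThresholds()
    r = record

    if r.n_components >= t.scattered_min_components:
        return "scattered", float(r.n_components - t.scattered_min_components)

    if r.n_endpoints == 0 and r.n_components <= 2:
        return "clump", 1.0

    if (r.core_circularity >= t.star_min_circularity
            and r.n_main_branches >= t.star_min_branches
            and r.core_thickness_um >= t.star_min_core_thickness_um):
        return "star_like", float(r.core_thickness_um - t.star_min_core_thickness_um)

    lo, hi = t.firework_core_thickness_um
    if r.n_endpoints >= t.firework_min_endpoints and lo <= r.core_thickness_um <= hi:
        return "firework", float(r.n_endpoints - t.firework_min_endpoints)

    if (r.core_circularity >= t.bm_min_circularity
            and r.core_thickness_um >= t.bm_min_core_thickness_um):
        return "branched_mesenchymal", float(
            r.core_thickness_um - t.bm_min_core_thickness_um)

    if r.n_lumens >= t.cystic_min_lumens:
        return "cystic_branched", float(r.n_lumens - t.cystic_min_lumens)

    if r.n_terminal_end_buds >= t.tebbo_min_buds:
        return "TEBBO", float(r.n_terminal_end_buds - t.tebbo_min_buds)

    if r.n_endpoints >= t.tree_min_endpoints:
        return "tree_like", float(r.n_endpoints - t.tree_min_endpoints)

    if r.n_main_branches >= t.thick_min_branches:
        return "thick_branched", float(r.n_main_branches - t.thick_min_branches)

    return UNCLASSIFIED, 0.0
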