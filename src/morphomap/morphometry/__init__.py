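"""Automated skeleton-graph morphometry of organoid images."""

from .segment import SegmentationMask, segment
from .skeleton import SkeletonGraph, skeleton_graph
from .measure import MeasureConfig, MorphometricRecord, measure
from .classify import UNCLASSIFIED, ClassifierThresholds, classify_rule_based

__all__ = [
    "SegmentationMask", "segment", "SkeletonGraph", "skeleton_graph",
    "MeasureConfig", "MorphometricRecord", "measure",
    "UNCLASSIFIED", "ClassifierThresholds", "classify_rule_based",
]


def measure_image(image, pixel_size_um, config=None, **segment_kw):
    """Convenience: segment -> skeleton graph -> morphometric record."""
    seg = segment(image, pixel_size_um, **segment_kw)
    graph = skeleton_graph(seg)
    return measure(seg, graph, image=image, config=config)
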