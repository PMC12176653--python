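"""End-to-end helpers tying the generator to measurement and mapping."""

from __future__ import annotations

import pandas as pd

from .morphometry import classify_rule_based, measure, segment, skeleton_graph
from .profiling.features import extract_features_classical, intensity_stats


def measure_cohort(cohort, config=None, classify=True):
    """Segment, skeletonize and measure every organoid of a cohort.

    Returns (records, table): the list of morphometric records plus a
    DataFrame with one row per organoid (all record fields, the intensity
    summaries, and the rule-based label if requested).
    """
    records, rows = [], []
    for img, gt in zip(cohort.images, cohort.truths):
        seg = segment(img, gt.pixel_size_um)
        graph = skeleton_graph(seg)
        rec = measure(seg, graph, image=img, config=config)
        records.append(rec)
        row = rec.as_dict()
        row.update(intensity_stats(img, seg.mask))
        if classify:
            label, margin = classify_rule_based(rec)
            row["predicted_phenotype"] = label
            row["rule_margin"] = margin
        rows.append(row)
    return records, pd.DataFrame(rows)


def cohort_features(cohort, config=None):
    """Classical feature matrix for a cohort (records + texture stats)."""
    records, table = measure_cohort(cohort, config=config, classify=False)
    texture_cols = ["int_mean", "int_sd", "int_p10", "int_p50", "int_p90", "fg_area_px"]
    texture = table[texture_cols].to_dict("records")
    return extract_features_classical(records, texture), records, table
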