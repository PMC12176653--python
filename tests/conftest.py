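import numpy as np
import pytest

from morphomap.archetypes import MURINE_FAMILIES
from morphomap.synth import generate_cohort
from morphomap.pipeline import cohort_features, measure_cohort


@pytest.fixture(scope="session")
def standard_cohort():
    """The 8-family x 40 study cohort (jitter 0.1, noise-free)."""
    return generate_cohort({f: 40 for f in MURINE_FAMILIES}, jitter=0.1, seed=11)


@pytest.fixture(scope="session")
def measured_cohort(standard_cohort):
    """Cohort plus its morphometric records / cohort table / features.

    Measured once per session; the wall time of the measurement pass is
    attached for the runtime acceptance check.
    """
    import time

    t0 = time.time()
    records, table = measure_cohort(standard_cohort)
    measure_seconds = time.time() - t0
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from morphomap.profiling.features import extract_features_classical

            texture_cols = ["int_mean", "int_sd", "int_p10", "int_p50",
                            "int_p90", "fg_area_px"]
            texture = table[texture_cols].to_dict("records")
            features = extract_features_classical(records, texture)
    return {
        "cohort": standard_cohort,
        "records": records,
        "table": table,
        "features": features,
        "measure_seconds": measure_seconds,
    }


@pytest.fixture(scope="session")
def two_class_cohort():
    """200-image, 2-family cohort for surrogate-extractor training."""
    return generate_cohort({"clump": 100, "tree_like": 100}, jitter=0.1, seed=3)
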