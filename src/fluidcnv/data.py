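"""Packaged reference data: published cohort summaries used as inputs.

The shipped table ``cytology_negative_cohort.tsv`` lists, for a published
cohort of 29 body-fluid specimens from patients ultimately diagnosed with
malignancy but negative by cytology/flow cytometry, the capped CNV count
category and the estimated tumor fraction of each specimen.  The
contingency counts below are the printed detection outcomes of the two
clinical cohorts (a case-control test-performance study and a consecutive
verification series) plus their pooled totals; they are study-design
inputs for the diagnostic-accuracy statistics, not quantities this
package re-derives from raw sequence data.
"""

from __future__ import annotations

import importlib.resources as _resources

import pandas as pd

__all__ = ["load_cytology_negative_cohort", "CONTINGENCY_COUNTS"]

#: (detected, total) per cohort stratum.  Sensitivity strata count
#: CNV-positive calls among true malignancies; specificity strata count
#: negative calls among controls without malignancy.
CONTINGENCY_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "study1": {
        "cytology_positive": (31, 36),
        "cytology_negative": (19, 29),
        "negative_control": (59, 59),
    },
    "study2": {
        "cytology_positive": (24, 27),
        "negative_control": (18, 18),
    },
    "combined": {
        "cytology_positive": (55, 63),
        "cytology_negative": (23, 34),
        "negative_control": (77, 77),
    },
}


def load_cytology_negative_cohort() -> pd.DataFrame:
    """The published cytology-negative cohort table.

    Columns: ``sample_id``, ``cnv_count_display`` (capped category,
    "0".."4" or "5+"), ``tumor_fraction`` (fraction in [0, 1]).
    """
    ref = _resources.files("fluidcnv").joinpath("data/cytology_negative_cohort.tsv")
    with _resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"cnv_count_display": str})
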