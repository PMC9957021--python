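"""Published clinical reference values shipped as constants.

These numbers come from a 180-patient clinical evaluation of the
two-compartment vBMD method (105-subject experimental cohort used to
derive thresholds, 75-subject test cohort used to verify them).  The
underlying patient data are not available, so none of these values can
be recomputed here; they are shipped as reference constants for
comparison and for the published-table self-consistency check
(:func:`check_published_tables`), NOT as claims this package
re-derives.
"""

from __future__ import annotations

import pandas as pd

from .cohort import accuracy_from_sens_spec

__all__ = [
    "VBMD_THRESHOLDS",
    "AUC_BY_VERTEBRA",
    "AVERAGE_AUC",
    "VBMD_ABMD_PEARSON_R_RANGE",
    "GROUP_SIZES",
    "EXPERIMENTAL_PERFORMANCE",
    "TEST_PERFORMANCE",
    "check_published_tables",
]

#: Youden-optimal vBMD thresholds (g/cm3), experimental cohort;
#: a subject tests positive when vBMD <= threshold.
VBMD_THRESHOLDS = {
    "osteoporosis": {"L1": 0.121, "L2": 0.103, "L3": 0.107, "L4": 0.114, "average": 0.116},
    "osteopenia": {"L1": 0.134, "L2": 0.125, "L3": 0.129, "L4": 0.141, "average": 0.126},
}

AUC_BY_VERTEBRA = {
    "osteoporosis": {"L1": 0.928, "L2": 0.921, "L3": 0.937, "L4": 0.924},
}
AVERAGE_AUC = {"osteoporosis": 0.930, "osteopenia": 0.897}

#: Observed per-vertebra Pearson correlation of CT vBMD vs DXA aBMD.
VBMD_ABMD_PEARSON_R_RANGE = (0.655, 0.723)

#: (normal, osteopenia, osteoporosis) subject counts per cohort.
GROUP_SIZES = {
    "experimental": {"normal": 57, "osteopenia": 25, "osteoporosis": 23},
    "test": {"normal": 43, "osteopenia": 18, "osteoporosis": 14},
}

#: Published operating-point performance, experimental cohort
#: (sensitivity %, specificity %, accuracy %).
EXPERIMENTAL_PERFORMANCE = {
    "osteoporosis": {
        "L1": (95.7, 78.0, 81.9),
        "L2": (87.0, 81.7, 82.9),
        "L3": (87.0, 76.8, 79.0),
        "L4": (95.7, 75.6, 80.0),
        "average": (95.7, 75.6, 80.0),
    },
    "osteopenia": {
        "L1": (81.3, 84.2, 82.9),
        "L2": (83.3, 82.5, 84.6),
        "L3": (83.3, 75.4, 79.8),
        "L4": (89.6, 73.7, 81.7),
        "average": (81.3, 82.5, 82.7),
    },
}

#: Published performance on the independent test cohort.
TEST_PERFORMANCE = {
    "osteoporosis": {
        "L1": (100.0, 75.4, 80.0),
        "L2": (85.7, 83.6, 84.0),
        "L3": (100.0, 72.1, 77.3),
        "L4": (85.7, 75.4, 77.3),
        "average": (100.0, 73.8, 78.7),
    },
    "osteopenia": {
        "L1": (84.4, 83.7, 84.0),
        "L2": (81.3, 83.7, 82.7),
        "L3": (81.3, 79.1, 80.0),
        "L4": (87.5, 72.1, 78.7),
        "average": (81.3, 83.7, 82.7),
    },
}


def _class_sizes(cohort: str, endpoint: str) -> tuple[int, int]:
    g = GROUP_SIZES[cohort]
    if endpoint == "osteoporosis":
        n_pos = g["osteoporosis"]
    else:  # reduced bone mass: osteopenia plus osteoporosis vs normal
        n_pos = g["osteopenia"] + g["osteoporosis"]
    total = sum(g.values())
    return n_pos, total - n_pos


def check_published_tables() -> pd.DataFrame:
    """Self-consistency of the published performance tables.

    For every published row, reconstruct the accuracy implied by the
    printed sensitivity/specificity and the cohort class sizes, and
    compare with the printed accuracy.  Returns one row per table cell
    with the implied value and a ``consistent`` flag.  (A handful of
    published experimental-cohort osteopenia rows are known not to be
    reproducible from their own printed operating points.)
    """
    rows = []
    for cohort, table in (
        ("experimental", EXPERIMENTAL_PERFORMANCE),
        ("test", TEST_PERFORMANCE),
    ):
        for endpoint, verts in table.items():
            n_pos, n_neg = _class_sizes(cohort, endpoint)
            for vert, (sens, spec, acc) in verts.items():
                implied = accuracy_from_sens_spec(sens, spec, n_pos, n_neg)
                rows.append(
                    {
                        "cohort": cohort,
                        "endpoint": endpoint,
                        "vertebra": vert,
                        "sensitivity": sens,
                        "specificity": spec,
                        "published_accuracy": acc,
                        "implied_accuracy": implied,
                        "consistent": implied == acc,
                    }
                )
    return pd.DataFrame(rows)
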