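"""Published contingency tables used as fixed inputs.

The TCGA colorectal study this pipeline follows reports, for TP53 and
BCL9L, 2 x 3 tables of patient counts (clonal / subclonal / WT carriers)
against binarized clinical variables, with Fisher exact p-values. The
counts below are those published tables; they serve as deterministic
inputs for re-running the Freeman-Halton test, not as expected outputs of
any simulation.
"""

from __future__ import annotations

import numpy as np

#: gene -> variable -> ((row1 counts), (row2 counts), published p-value).
#: Columns are (clonal, subclonal, WT); rows are the printed clinical split.
PUBLISHED_CLONALITY_TABLES: dict[str, dict[str, dict]] = {
    "TP53": {
        "age": {
            "rows": ("<67.5", ">=67.5"),
            "counts": np.array([[153, 9, 103], [139, 14, 113]]),
            "published_p": 0.346,
        },
        "sex": {
            "rows": ("female", "male"),
            "counts": np.array([[129, 17, 108], [163, 6, 108]]),
            "published_p": 0.015,
        },
        "t_stage": {
            "rows": ("T1/T2", "T3/T4"),
            "counts": np.array([[54, 5, 54], [238, 18, 160]]),
            "published_p": 0.176,
        },
        "m_stage": {
            "rows": ("M0", "M1"),
            "counts": np.array([[206, 15, 169], [50, 0, 22]]),
            "published_p": 0.016,
        },
    },
    "BCL9L": {
        "tumour_site": {
            "rows": ("right-sided", "left-sided"),
            "counts": np.array([[25, 3, 191], [12, 4, 281]]),
            "published_p": 0.004,
        },
        "t_stage": {
            "rows": ("T1/T2", "T3/T4"),
            "counts": np.array([[6, 3, 104], [32, 4, 383]]),
            "published_p": 0.26,
        },
        "sex": {
            "rows": ("female", "male"),
            "counts": np.array([[17, 3, 237], [21, 4, 252]]),
            "published_p": 0.89,
        },
    },
}

COLUMNS = ("clonal", "subclonal", "WT")


def iter_published_tables():
    """Yield (gene, variable, counts, published_p) over all stored tables."""
    for gene, tables in PUBLISHED_CLONALITY_TABLES.items():
        for variable, spec in tables.items():
            yield gene, variable, spec["counts"], spec["published_p"]
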