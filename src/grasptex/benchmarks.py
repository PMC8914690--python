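"""Published benchmark confusion matrices for the basic-hand-movement datasets.

These 6x6 matrices (class order C, H, L, P, S, T; rows = true labels)
are the reported cross-validated results of this pipeline on the public
"sEMG for Basic Hand movements" datasets: DB1 (900 trials, 5 subjects),
DB2 (1800 trials, 1 subject) and DB3 (their 2700-trial fusion). They
serve as regression fixtures: every percentage metric in the reported
results tables is recomputable from them with
:func:`grasptex.classify.report_from_confusion`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["REFERENCE_CONFUSIONS", "REFERENCE_ACCURACY"]

REFERENCE_CONFUSIONS: dict[str, np.ndarray] = {
    "DB1": np.array(
        [
            [150, 0, 0, 0, 0, 0],
            [0, 149, 0, 1, 0, 0],
            [0, 0, 147, 1, 0, 2],
            [0, 0, 1, 149, 0, 0],
            [0, 0, 0, 0, 150, 0],
            [1, 1, 1, 2, 0, 145],
        ]
    ),
    "DB2": np.array(
        [
            [297, 1, 0, 0, 2, 0],
            [3, 291, 0, 2, 0, 4],
            [1, 1, 273, 18, 0, 7],
            [0, 2, 19, 273, 0, 6],
            [1, 0, 0, 0, 299, 0],
            [0, 1, 11, 12, 0, 276],
        ]
    ),
    "DB3": np.array(
        [
            [442, 5, 0, 0, 3, 0],
            [4, 431, 0, 7, 2, 6],
            [0, 0, 421, 19, 0, 10],
            [0, 2, 14, 425, 0, 9],
            [5, 1, 0, 0, 444, 0],
            [2, 6, 18, 14, 0, 410],
        ]
    ),
}

#: Reported overall accuracies (%), as printed for the three datasets.
REFERENCE_ACCURACY: dict[str, float] = {"DB1": 98.89, "DB2": 94.94, "DB3": 95.30}
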