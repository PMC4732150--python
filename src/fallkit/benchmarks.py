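"""Published per-subject reference results for the reporting operations.

These tables transcribe the per-subject results of a published ten-subject
smartphone fall-detection study comparing personalized and generic
nearest-neighbor and SVM detectors (variants PNN, GNN, PSVM, GSVM).  They
serve as worked-example inputs for the aggregation and reporting
operations: feeding them through ``win_count``, ``cell_fraction``,
``false_alarm_factor`` and the mean/difference summaries reproduces the
study's printed across-subject rows.  They are inputs to the reporting
pipeline, never outputs of this package's detectors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VARIANTS = ("PNN", "GNN", "PSVM", "GSVM")

# per-subject mean AUC (10-fold CV means), subjects 1..10
_AUC = {
    "PNN": [0.9770, 0.9877, 0.9900, 0.9878, 0.9760,
            0.9903, 0.9780, 0.9863, 0.9909, 0.9967],
    "GNN": [0.9463, 0.9829, 0.9713, 0.9744, 0.9720,
            0.8460, 0.9554, 0.9591, 0.9894, 0.9855],
    "PSVM": [0.9881, 0.9929, 0.9948, 0.9930, 0.9766,
             0.9967, 0.9870, 0.9957, 0.9949, 0.9942],
    "GSVM": [0.9667, 0.9905, 0.9912, 0.9845, 0.9745,
             0.9405, 0.9905, 0.9724, 0.9952, 0.9892],
}

# per-subject AUC standard deviations over folds
_AUC_STD = {
    "PNN": [0.0058, 0.0101, 0.0060, 0.0067, 0.0074,
            0.0072, 0.0108, 0.0032, 0.0099, 0.0009],
    "GNN": [0.0097, 0.0092, 0.0059, 0.0064, 0.0069,
            0.0341, 0.0140, 0.0048, 0.0087, 0.0036],
    "PSVM": [0.0039, 0.0069, 0.0043, 0.0053, 0.0068,
             0.0030, 0.0065, 0.0054, 0.0072, 0.0014],
    "GSVM": [0.0063, 0.0079, 0.0067, 0.0046, 0.0095,
             0.0127, 0.0028, 0.0037, 0.0054, 0.0023],
}

# per-subject SE and SP at the geometric-mean operating point
_SE = {
    "PNN": [0.9216, 0.9906, 0.9737, 0.9648, 0.9154,
            0.9880, 0.9815, 0.9623, 0.9882, 0.9787],
    "GNN": [0.8980, 0.9774, 0.9105, 0.9500, 0.9019,
            0.9560, 0.9704, 0.9113, 0.9824, 0.9574],
    "PSVM": [0.9510, 1.0000, 0.9816, 0.9907, 0.9346,
             1.0000, 0.9815, 0.9811, 0.9980, 0.9787],
    "GSVM": [0.9333, 0.9962, 0.9763, 0.9648, 0.9212,
             0.9960, 0.9759, 0.9509, 0.9863, 0.9468],
}

_SP = {
    "PNN": [0.9817, 0.9682, 0.9740, 0.9689, 0.9316,
            0.9728, 0.9577, 0.9878, 0.9772, 0.9950],
    "GNN": [0.9656, 0.9429, 0.9625, 0.9661, 0.9377,
            0.7990, 0.9240, 0.9443, 0.9590, 0.9825],
    "PSVM": [0.9655, 0.9627, 0.9750, 0.9605, 0.9304,
             0.9852, 0.9859, 0.9895, 0.9863, 0.9925],
    "GSVM": [0.9742, 0.9594, 0.9625, 0.9717, 0.9450,
             0.8365, 0.9690, 0.9827, 0.9795, 0.9925],
}

# pooled 10-fold CV comparison of the three novelty detectors (mean, std)
NOVELTY_AUC = {
    "NN": (0.9809, 0.0028),
    "LOF": (0.9784, 0.0048),
    "OneClass-SVM": (0.9644, 0.0051),
}

SUBJECTS = list(range(1, 11))


def published_auc_by_subject() -> pd.DataFrame:
    """Per-subject mean AUC for PNN/GNN/PSVM/GSVM (subjects 1..10)."""
    return pd.DataFrame(_AUC, index=pd.Index(SUBJECTS, name="subject"))


def published_auc_std_by_subject() -> pd.DataFrame:
    """Per-subject AUC standard deviations over the 10 CV folds."""
    return pd.DataFrame(_AUC_STD, index=pd.Index(SUBJECTS, name="subject"))


def published_operating_points() -> pd.DataFrame:
    """Per-subject SE, SP and sqrt(SE*SP), MultiIndex (variant, metric)."""
    data = {}
    for variant in VARIANTS:
        se = np.array(_SE[variant])
        sp = np.array(_SP[variant])
        data[(variant, "se")] = se
        data[(variant, "sp")] = sp
        data[(variant, "gmean")] = np.sqrt(se * sp)
    frame = pd.DataFrame(data, index=pd.Index(SUBJECTS, name="subject"))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["variant", "metric"])
    return frame
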