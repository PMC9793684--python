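"""The seven behavioral scales and random-forest imputation of missing entries.

Scales: SRS (social responsiveness), RBS (repetitive behavior), SSP (sensory
profile), the two DSM ADHD components (hyperactivity/impulsivity and
inattentiveness), the Vineland adaptive-behavior composite and full-scale
IQ.  SRS/RBS/SSP/ADHD increase with impairment; Vineland and IQ decrease
(the impairment-direction metadata used for CCA sign checks).

Missing cells are imputed with chained random-forest regression
(missForest-style): initialize with column medians, then repeatedly regress
each scale on the other six over its observed rows and predict its missing
rows, until cell changes fall below tolerance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

BEHAVIOR_SCALES = ("SRS", "RBS", "SSP", "ADHD_hyperimpulsive",
                   "ADHD_inattentive", "Vineland", "IQ")

#: +1 if the scale increases with impairment, -1 if it decreases.
IMPAIRMENT_SIGN = {"SRS": 1, "RBS": 1, "SSP": 1, "ADHD_hyperimpulsive": 1,
                   "ADHD_inattentive": 1, "Vineland": -1, "IQ": -1}

MIN_SUBJECTS = 20


def impute_behavior_rf(behavior: pd.DataFrame, seed: int = 0,
                       max_sweeps: int = 10, tol: float = 1e-3,
                       n_estimators: int = 50) -> pd.DataFrame:
    """Impute missing behavior cells with chained random-forest regression.

    Observed cells are never altered.  Deterministic for a fixed seed.
    """
    if len(behavior) < MIN_SUBJECTS:
        raise ValueError(f"need at least {MIN_SUBJECTS} subjects, got {len(behavior)}")
    fully_missing = [c for c in behavior.columns if behavior[c].isna().all()]
    if fully_missing:
        raise ValueError(f"column(s) fully missing: {fully_missing}")
    miss = behavior.isna()
    if not miss.any().any():
        return behavior.copy()

    filled = behavior.copy()
    for c in behavior.columns:
        filled.loc[miss[c], c] = behavior[c].median()

    cols_with_missing = [c for c in behavior.columns if miss[c].any()]
    for sweep in range(max_sweeps):
        max_change = 0.0
        for j, col in enumerate(cols_with_missing):
            others = [c for c in behavior.columns if c != col]
            obs = ~miss[col]
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=(int(seed) * 100 + sweep * 10 + j) % (2**31 - 1),
                n_jobs=1)
            rf.fit(filled.loc[obs, others].to_numpy(float),
                   filled.loc[obs, col].to_numpy(float))
            pred = rf.predict(filled.loc[miss[col], others].to_numpy(float))
            old = filled.loc[miss[col], col].to_numpy(float)
            if old.size:
                max_change = max(max_change, float(np.max(np.abs(pred - old))))
            filled.loc[miss[col], col] = pred
        if max_change < tol:
            break
    return filled
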