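"""Cross-task similarity of the spatial atypicality pattern.

For each diagnostic group and task, the group-level pattern is the per-edge
mean absolute deviation |Z|; a task x task Pearson correlation matrix of
these patterns measures how similar atypicality topography is across
cognitive domains.  The group difference over the unique task-pair
correlations is tested with the Wilcoxon signed-rank test (exact for small
pair counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normative import DevianceTable


@dataclass
class SimilarityMatrix:
    """Task x task Pearson correlations of group-mean edge atypicality patterns."""

    group: str
    tasks: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.tasks), len(self.tasks)):
            raise ValueError("similarity matrix shape inconsistent with tasks")
        self.values = v

    def off_diagonal(self) -> np.ndarray:
        """The T(T-1)/2 unique task-pair correlations, row-major upper triangle."""
        iu, ju = np.triu_indices(len(self.tasks), k=1)
        return self.values[iu, ju]

    def mean_off_diagonal(self) -> float:
        return float(self.off_diagonal().mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tasks, columns=self.tasks)


@dataclass
class WilcoxonResult:
    statistic: float
    p: float
    n_pairs: int
    differences: np.ndarray


def group_mean_pattern(dev: DevianceTable, group_subjects,
                       signed: bool = False) -> np.ndarray:
    """Per-edge mean atypicality (|Z| by default) over a group's subjects."""
    idx = [dev.subject_ids.index(s) for s in group_subjects]
    if not idx:
        raise ValueError("empty subject group")
    z = dev.z[idx]
    return z.mean(axis=0) if signed else np.abs(z).mean(axis=0)


def task_similarity_matrix(patterns: dict, group: str = "") -> SimilarityMatrix:
    """Pearson correlation matrix of per-task edge patterns.

    ``patterns`` maps task label -> edge vector; all vectors must have the
    same length and none may be constant.
    """
    tasks = list(patterns)
    if len(tasks) < 2:
        raise ValueError("need at least 2 tasks")
    lengths = {len(np.ravel(patterns[t])) for t in tasks}
    if len(lengths) != 1:
        raise ValueError("edge patterns have inconsistent lengths")
    for t in tasks:
        if np.ptp(np.ravel(patterns[t])) == 0:
            raise ValueError(f"pattern for task {t!r} is constant")
    mat = np.corrcoef(np.stack([np.ravel(patterns[t]) for t in tasks]))
    np.fill_diagonal(mat, 1.0)
    return SimilarityMatrix(group, tasks, mat)


def compare_similarity(sim_a: SimilarityMatrix,
                       sim_b: SimilarityMatrix) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired task-pair correlations.

    Pairs are the T(T-1)/2 unique off-diagonal entries; zero differences
    are dropped per the exact method.  For 5 tasks (10 pairs) complete
    separation gives the exact two-sided floor p = 2/2^10.
    """
    if sim_a.tasks != sim_b.tasks:
        raise ValueError("similarity matrices cover different task sets")
    da = sim_a.off_diagonal()
    db = sim_b.off_diagonal()
    diff = da - db
    n_pairs = diff.size
    if np.all(diff == 0):
        warnings.warn("all task-pair differences are zero; p set to 1")
        return WilcoxonResult(0.0, 1.0, n_pairs, diff)
    mode = "exact" if n_pairs <= 25 else "approx"
    res = stats.wilcoxon(da, db, zero_method="wilcox", alternative="two-sided",
                         mode=mode)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), n_pairs, diff)
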