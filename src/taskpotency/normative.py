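"""Normative modelling of task-potency edges against age and sex.

A per-edge Bayesian linear regression is fit on typically developing (TD)
subjects with basis [1, age_c, age_c^2, sex] (age centered on the training
mean; a simpler [1, age_c, sex] basis is available).  The posterior
coefficient covariance feeds the predictive variance, so an out-of-sample
subject's deviation is

    Z = (y - x*'beta) / sqrt(sigma^2 (1 + x*' (X'X)^-1 x*)),

a Z-score quantifying per-edge atypicality relative to the normative range,
inherently corrected for age and sex.  TD subjects are scored strictly
out-of-sample via k-fold cross-validation; clinical subjects are scored
with the model trained on all TD.  A subject's global atypicality is the
percentage of edges with |Z| above a threshold (default 2.571, the
two-tailed 1% normal cut-off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome import EdgeTable

logger = logging.getLogger(__name__)

MIN_TRAINING_SUBJECTS = 20
VARIANCE_FLOOR = 1e-6
DEFAULT_Z_THRESHOLD = 2.571


@dataclass
class DevianceTable:
    """Subjects x edges normative deviation Z-scores for one task."""

    task: str
    subject_ids: list
    z: np.ndarray
    provenance: list = field(default_factory=list)  # per row

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("deviation table contains non-finite Z-scores")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.subject_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "subject_id"
        df.to_csv(path, sep="\t")


@dataclass
class GroupComparison:
    """Case-control comparison of the percent-atypical statistic for one task."""

    task: str
    t: float
    df: float
    p: float
    q: float | None
    cohens_d: float
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    n_case: int
    n_control: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("task", "t", "df", "p", "q", "cohens_d", "mean_case", "sd_case",
                 "mean_control", "sd_control", "n_case", "n_control")}


def _design(covariates: pd.DataFrame, age_center: float, basis: str):
    """Build the regression design; returns (X, column names)."""
    age = covariates["age"].to_numpy(float)
    sex = (covariates["sex"].astype(str).str.lower() == "male").to_numpy(float)
    age_c = age - age_center
    cols = [np.ones_like(age), age_c]
    names = ["intercept", "age"]
    if basis == "age2":
        cols.append(age_c**2)
        names.append("age2")
    elif basis != "age":
        raise ValueError(f"unknown basis {basis!r}")
    cols.append(sex)
    names.append("sex_male")
    return np.column_stack(cols), names


class NormativePotencyModel:
    """Per-edge normative regression of potency on age and sex.

    Parameters
    ----------
    endog : ndarray or EdgeTable
        Training edge values, subjects x E (typically TD subjects only).
    covariates : DataFrame
        Must contain ``age`` (years) and ``sex`` ({"female", "male"}),
        aligned row-wise with ``endog``.
    basis : {"age2", "age"}
        "age2" fits [1, age_c, age_c^2, sex]; "age" drops the quadratic.
    """

    def __init__(self, endog, covariates: pd.DataFrame, basis: str = "age2"):
        y = endog.values if isinstance(endog, EdgeTable) else np.asarray(endog, float)
        if y.ndim == 1:
            y = y[:, None]
        if len(covariates) != y.shape[0]:
            raise ValueError("covariates do not align with training rows")
        if y.shape[0] < MIN_TRAINING_SUBJECTS:
            raise ValueError(
                f"need at least {MIN_TRAINING_SUBJECTS} training subjects, "
                f"got {y.shape[0]}")
        if covariates[["age", "sex"]].isna().any().any():
            raise ValueError("training covariates contain missing values")
        self.endog = y
        self.covariates = covariates.reset_index(drop=True)
        self.basis = basis
        self.age_center = float(covariates["age"].mean())

    def fit(self) -> "NormativeResults":
        x, names = _design(self.covariates, self.age_center, self.basis)
        # drop rank-deficient columns (e.g. single-sex training set)
        keep = []
        for j in range(x.shape[1]):
            sub = x[:, keep + [j]]
            if np.linalg.matrix_rank(sub) == len(keep) + 1:
                keep.append(j)
            else:
                logger.warning("dropping rank-deficient design column %r", names[j])
        x = x[:, keep]
        names = [names[j] for j in keep]
        n, p = x.shape
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ (x.T @ self.endog)
        resid = self.endog - x @ beta
        dof = max(n - p, 1)
        sigma2 = np.maximum((resid**2).sum(axis=0) / dof, VARIANCE_FLOOR)
        return NormativeResults(self, beta, sigma2, xtx_inv, names, n)


class NormativeResults:
    """Fitted per-edge normative model: coefficients, noise variance, posterior."""

    def __init__(self, model, params, sigma2, cov_unscaled, param_names, n_train):
        self.model = model
        self.params = params            # p x E
        self.sigma2 = sigma2            # E
        self.cov_unscaled = cov_unscaled  # (X'X)^-1, shared across edges
        self.param_names = param_names
        self.n_train = n_train

    def _design_for(self, covariates: pd.DataFrame) -> np.ndarray:
        x, names = _design(covariates, self.model.age_center, self.model.basis)
        keep = [names.index(n) for n in self.param_names]
        return x[:, keep]

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        return self._design_for(covariates) @ self.params

    def deviation_scores(self, endog, covariates: pd.DataFrame,
                         provenance: str = "autism_full_model") -> DevianceTable:
        """Out-of-sample deviation Z-scores for new subjects."""
        y = endog.values if isinstance(endog, EdgeTable) else np.asarray(endog, float)
        subject_ids = endog.subject_ids if isinstance(endog, EdgeTable) else \
            [f"row{i}" for i in range(y.shape[0])]
        ok = ~covariates[["age", "sex"]].isna().any(axis=1).to_numpy()
        if not ok.all():
            dropped = [subject_ids[i] for i in np.flatnonzero(~ok)]
            logger.info("excluding %d subject(s) with missing covariates: %s",
                        len(dropped), dropped)
        y = y[ok]
        subject_ids = [s for s, k in zip(subject_ids, ok) if k]
        x = self._design_for(covariates.loc[ok].reset_index(drop=True))
        yhat = x @ self.params
        leverage = np.einsum("ij,jk,ik->i", x, self.cov_unscaled, x)
        pred_var = self.sigma2[None, :] * (1.0 + leverage[:, None])
        z = (y - yhat) / np.sqrt(np.maximum(pred_var, VARIANCE_FLOOR))
        task = endog.task if isinstance(endog, EdgeTable) else ""
        return DevianceTable(task, subject_ids, z, [provenance] * len(subject_ids))

    def to_frame(self) -> pd.DataFrame:
        """Per-edge coefficients and noise variance, one row per edge."""
        df = pd.DataFrame(self.params.T, columns=self.param_names)
        df["sigma2"] = self.sigma2
        df.index.name = "edge"
        return df

    def dump(self, tsv_path, json_path=None) -> None:
        """Binary-free dump: coefficients/variances as TSV, metadata as JSON."""
        self.to_frame().to_csv(tsv_path, sep="\t")
        if json_path is not None:
            import json
            meta = {"basis": self.param_names, "n_train": int(self.n_train),
                    "age_center": self.model.age_center,
                    "cov_unscaled": self.cov_unscaled.tolist()}
            with open(json_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    def summary(self) -> str:
        lines = [
            "Normative potency model",
            "=" * 47,
            f"basis: {self.param_names}   training subjects: {self.n_train}",
            f"edges: {self.params.shape[1]}   age centered at "
            f"{self.model.age_center:.2f} y",
            "-" * 47,
            f"{'coef':<12}{'mean':>10}{'sd across edges':>20}",
        ]
        for i, name in enumerate(self.param_names):
            lines.append(f"{name:<12}{self.params[i].mean():>10.4f}"
                         f"{self.params[i].std():>20.4f}")
        lines.append(f"{'sigma2':<12}{self.sigma2.mean():>10.4f}"
                     f"{self.sigma2.std():>20.4f}")
        return "\n".join(lines)


def td_crossval_deviations(td_edges: EdgeTable, covariates: pd.DataFrame,
                           k: int = 10, seed: int = 0,
                           basis: str = "age2") -> DevianceTable:
    """Score every TD subject out-of-sample by k-fold cross-validation.

    Each subject's Z-scores come from the normative model fit on the other
    k-1 folds; every subject is scored exactly once and rows keep the input
    subject order.
    """
    n = td_edges.values.shape[0]
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} TD subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    z = np.empty_like(td_edges.values)
    cov = covariates.reset_index(drop=True)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        model = NormativePotencyModel(td_edges.values[mask],
                                      cov.loc[mask].reset_index(drop=True),
                                      basis=basis)
        res = model.fit()
        dt = res.deviation_scores(td_edges.values[fold],
                                  cov.loc[fold].reset_index(drop=True),
                                  provenance="td_crossval")
        z[fold] = dt.z
    return DevianceTable(td_edges.task, list(td_edges.subject_ids), z,
                         ["td_crossval"] * n)


def atypicality_percentage(z_row: np.ndarray,
                           z_threshold: float = DEFAULT_Z_THRESHOLD) -> float:
    """Percentage of edges whose |Z| exceeds the threshold."""
    z = np.asarray(z_row, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty Z-score row")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite Z-scores present")
    return 100.0 * float(np.count_nonzero(np.abs(z) > z_threshold)) / z.size


def atypicality_percentages(dev: DevianceTable,
                            z_threshold: float = DEFAULT_Z_THRESHOLD) -> np.ndarray:
    return np.array([atypicality_percentage(row, z_threshold) for row in dev.z])


def compare_groups(perc_case: np.ndarray, perc_control: np.ndarray,
                   task: str = "", welch: bool = False) -> GroupComparison:
    """Two-sample t-test and Cohen's d on percent-atypical scores.

    Default is the pooled-variance Student t, matching the pooled-SD
    Cohen's d; Welch's t is available.
    """
    a = np.asarray(perc_case, float)
    b = np.asarray(perc_control, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    n1, n2 = a.size, b.size
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    diff = a.mean() - b.mean()
    d = diff / pooled if pooled > 0 else 0.0
    if pooled == 0 and diff == 0:
        t, df, p = 0.0, float(n1 + n2 - 2), 1.0
    elif welch:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p, df = res.statistic, res.pvalue, res.df
    else:
        se = pooled * np.sqrt(1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)
        t = diff / se if se > 0 else np.inf * np.sign(diff)
        p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(task, float(t), float(df), float(p), None, float(d),
                           float(a.mean()), float(s1), float(b.mean()), float(s2),
                           n1, n2)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
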