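"""Out-of-sample canonical correlation between deviation patterns and behavior.

The brain side (subjects x edges deviation Z-scores, clinical group only)
is reduced to its top principal components; CCA then finds paired linear
combinations of brain components and the seven behavior scales maximizing
their correlation.  Robustness is assessed three ways:

* a *test* distribution of the first canonical correlation over many
  repeated k-fold out-of-sample cross-validations (dimensionality
  reduction and standardization are fit on training folds only; held-out
  variates are pooled across folds into one correlation per split);
* weight stability: correlation of fold-level behavior weights with the
  all-data weights;
* a permutation *null*: behavior rows shuffled within scanner site to
  preserve site structure while destroying brain-behavior coupling, each
  permutation followed by one full k-fold out-of-sample pass.

The relationship is declared significant when the mean of the test
distribution exceeds the 95th percentile of the null.  The sign of every
fit is fixed so the first behavior weight (SRS) is non-negative, making
weights and loadings comparable across folds and splits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import svd

logger = logging.getLogger(__name__)


@dataclass
class ReducedBrain:
    """PCA reduction of the subjects x edges matrix, kept for back-projection."""

    scores: np.ndarray         # n x k
    basis: np.ndarray          # E x k, orthonormal columns
    explained_variance: np.ndarray  # fractions, decreasing
    mean: np.ndarray           # E, centering vector


@dataclass
class CCAFit:
    """Canonical weight pairs and correlations with training standardization."""

    x_weights: np.ndarray      # k x m
    y_weights: np.ndarray      # q x m
    corrs: np.ndarray          # m
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray

    def transform(self, x: np.ndarray, y: np.ndarray):
        u = ((x - self.x_mean) / self.x_sd) @ self.x_weights
        v = ((y - self.y_mean) / self.y_sd) @ self.y_weights
        return u, v


def reduce_dimensionality(values: np.ndarray, k: int = 10) -> ReducedBrain:
    """Column-centered principal decomposition keeping the top-k components."""
    x = np.asarray(values, dtype=float)
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} components require more than k subjects, got n={n}")
    mean = x.mean(axis=0)
    xc = x - mean
    if xc.shape[1] > n:
        # Gram-matrix route: same top-k subspace, much cheaper for wide data
        g = xc @ xc.T
        w, v = np.linalg.eigh(g)
        order = np.argsort(w)[::-1]
        w = np.maximum(w[order], 0.0)
        v = v[:, order]
        s = np.sqrt(w)
        k_eff = min(k, int(np.count_nonzero(s > 1e-10)))
        u = v[:, :k_eff]
        basis = xc.T @ (u / s[:k_eff])
        scores = u * s[:k_eff]
        var = w
    else:
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        k_eff = min(k, s.size)
        basis = vt[:k_eff].T
        scores = u[:, :k_eff] * s[:k_eff]
        var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    return ReducedBrain(scores=scores, basis=basis,
                        explained_variance=frac[:k_eff], mean=mean)


def _inv_sqrt(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    if w.min() <= 1e-10:
        raise ValueError("rank-deficient block after standardization")
    return (v / np.sqrt(w)) @ v.T


def cca_fit(x: np.ndarray, y: np.ndarray) -> CCAFit:
    """Canonical correlation via whitened cross-covariance SVD.

    Columns are standardized internally on the data given (training
    statistics are stored on the fit).  Sign fixed so y_weights[0, m] >= 0
    for every mode m.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.shape[0]
    if y.shape[0] != n:
        raise ValueError("x and y have different numbers of rows")
    if n <= x.shape[1] + y.shape[1]:
        raise ValueError("need n > p + q subjects for a well-posed CCA")
    x_mean, y_mean = x.mean(axis=0), y.mean(axis=0)
    x_sd = x.std(axis=0, ddof=1)
    y_sd = y.std(axis=0, ddof=1)
    if np.any(x_sd == 0) or np.any(y_sd == 0):
        raise ValueError("zero-variance column; CCA undefined")
    xs = (x - x_mean) / x_sd
    ys = (y - y_mean) / y_sd
    cxx = xs.T @ xs / (n - 1)
    cyy = ys.T @ ys / (n - 1)
    cxy = xs.T @ ys / (n - 1)
    wx = _inv_sqrt(cxx)
    wy = _inv_sqrt(cyy)
    u, s, vt = svd(wx @ cxy @ wy, full_matrices=False)
    a = wx @ u
    b = wy @ vt.T
    # sign convention: first behavior weight (SRS) non-negative per mode
    flip = np.where(b[0] < 0, -1.0, 1.0)
    return CCAFit(a * flip, b * flip, np.clip(s, 0.0, 1.0),
                  x_mean, x_sd, y_mean, y_sd)


def canonical_loadings(fit: CCAFit, x: np.ndarray, y: np.ndarray):
    """Structure correlations of each variable with its side's first variate."""
    u, v = fit.transform(np.asarray(x, float), np.asarray(y, float))
    u1, v1 = u[:, 0], v[:, 0]
    def _corr_cols(mat, variate):
        sd = mat.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance variable; loading undefined")
        mc = mat - mat.mean(axis=0)
        vc = variate - variate.mean()
        denom = np.sqrt((mc**2).sum(axis=0) * (vc**2).sum())
        return (mc.T @ vc) / denom
    return _corr_cols(np.asarray(x, float), u1), _corr_cols(np.asarray(y, float), v1)


def backproject_brain_weights(fit: CCAFit, basis: ReducedBrain) -> np.ndarray:
    """Map first-mode brain component weights back to edge space."""
    w = fit.x_weights[:, 0]
    if basis.basis.shape[1] != w.size:
        raise ValueError("reduction basis does not match fitted weight dimension")
    return basis.basis @ w


def _fold_assignment(n: int, k_folds: int, rng) -> np.ndarray:
    order = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(order, k_folds)):
        if idx.size < 2:
            raise ValueError("fold with fewer than 2 subjects")
        assign[idx] = f
    return assign


def _oos_pass(brain: np.ndarray, behavior: np.ndarray, k: int, k_folds: int,
              assign: np.ndarray, global_pca: bool,
              ref_y_weights: np.ndarray | None = None):
    """One k-fold out-of-sample pass.

    Returns the pooled held-out first canonical correlation and, when a
    reference behavior weight vector is given, the mean correlation of
    fold-level behavior weights with it.
    """
    n = brain.shape[0]
    u_all = np.empty(n)
    v_all = np.empty(n)
    stab = []
    if global_pca:
        red_full = reduce_dimensionality(brain, k)
    for f in range(k_folds):
        test = assign == f
        train = ~test
        if global_pca:
            xtr = red_full.scores[train]
            xte = red_full.scores[test]
        else:
            red = reduce_dimensionality(brain[train], k)
            xtr = red.scores
            xte = (brain[test] - red.mean) @ red.basis
        fit = cca_fit(xtr, behavior[train])
        u, v = fit.transform(xte, behavior[test])
        u_all[test] = u[:, 0]
        v_all[test] = v[:, 0]
        if ref_y_weights is not None:
            w = fit.y_weights[:, 0]
            stab.append(float(np.corrcoef(w, ref_y_weights)[0, 1]))
    r = float(np.corrcoef(u_all, v_all)[0, 1])
    return r, (float(np.mean(stab)) if stab else None)


def crossval_cca(brain: np.ndarray, behavior: np.ndarray, k: int = 10,
                 n_splits: int = 1000, k_folds: int = 10, seed: int = 0,
                 global_pca: bool = False):
    """Test distribution of the out-of-sample first canonical correlation.

    Returns (test_dist, weight_stability): one pooled out-of-sample
    correlation per split and the per-split mean correlation of fold-level
    behavior weights with the all-data weights.
    """
    brain = np.asarray(brain, float)
    behavior = np.asarray(behavior, float)
    n = brain.shape[0]
    if n_splits <= 0:
        raise ValueError("n_splits must be positive")
    if n < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} subjects for {k_folds} folds")
    red_ref = reduce_dimensionality(brain, k)
    ref_fit = cca_fit(red_ref.scores, behavior)
    ref_w = ref_fit.y_weights[:, 0]
    rng = np.random.default_rng(seed)
    test_dist = np.empty(n_splits)
    stability = np.empty(n_splits)
    for s in range(n_splits):
        assign = _fold_assignment(n, k_folds, rng)
        r, stab = _oos_pass(brain, behavior, k, k_folds, assign, global_pca, ref_w)
        test_dist[s] = r
        stability[s] = stab
    return test_dist, stability


def permutation_null_cca(brain: np.ndarray, behavior: np.ndarray,
                         site_labels, k: int = 10, n_permutations: int = 1000,
                         k_folds: int = 10, seed: int = 0,
                         global_pca: bool = False) -> np.ndarray:
    """Within-site permutation null of the out-of-sample first canonical correlation.

    Behavior rows are shuffled only within scanner-site strata (singleton
    sites stay unpermuted, with a warning), then one full k-fold
    out-of-sample pass is scored, for each of ``n_permutations`` draws.
    """
    brain = np.asarray(brain, float)
    behavior = np.asarray(behavior, float)
    site = np.asarray(site_labels)
    n = brain.shape[0]
    if site.shape[0] != n:
        raise ValueError("site labels do not align with subjects")
    strata = {lab: np.flatnonzero(site == lab) for lab in pd.unique(site)}
    for lab, idx in strata.items():
        if idx.size == 1:
            warnings.warn(f"site {lab!r} has a single subject; left unpermuted")
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = np.arange(n)
        for idx in strata.values():
            if idx.size > 1:
                perm[idx] = idx[rng.permutation(idx.size)]
        yp = behavior[perm]
        assign = _fold_assignment(n, k_folds, rng)
        null[p], _ = _oos_pass(brain, yp, k, k_folds, assign, global_pca)
    return null


@dataclass
class SignificanceDecision:
    significant: bool
    test_mean: float
    null_percentile: float
    percentile: float
    exceedance: float  # fraction of null values below the test mean

    def to_dict(self) -> dict:
        return {"significant": self.significant, "test_mean": self.test_mean,
                "null_percentile": self.null_percentile,
                "percentile": self.percentile, "exceedance": self.exceedance}


def assess_significance(test_dist, null_dist,
                        percentile: float = 95.0) -> SignificanceDecision:
    """Significant iff mean(test) exceeds the given percentile of the null."""
    t = np.asarray(test_dist, float)
    n = np.asarray(null_dist, float)
    if t.size == 0 or n.size == 0:
        raise ValueError("empty distribution")
    tm = float(t.mean())
    cut = float(np.percentile(n, percentile))
    return SignificanceDecision(bool(tm > cut), tm, cut, percentile,
                                float(np.mean(n < tm)))


class BrainBehaviorCCA:
    """Brain-behavior canonical correlation model (one task, clinical group).

    Parameters
    ----------
    brain_edges : ndarray or EdgeTable
        Deviation Z-scores, subjects x edges, for the group analysed.
    behavior : DataFrame or ndarray
        Subjects x 7 behavior scales (imputed; no missing cells).
    site : array-like, optional
        Per-subject site labels for the within-site permutation null.
    k : int
        Principal components kept on the brain side.
    """

    def __init__(self, brain_edges, behavior, site=None, k: int = 10,
                 n_splits: int = 1000, k_folds: int = 10,
                 n_permutations: int = 1000, percentile: float = 95.0,
                 global_pca: bool = False, task: str = ""):
        from .connectome import EdgeTable
        self.brain = brain_edges.values if isinstance(brain_edges, EdgeTable) \
            else np.asarray(brain_edges, float)
        if isinstance(behavior, pd.DataFrame):
            if behavior.isna().any().any():
                raise ValueError("behavior table has missing cells; impute first")
            self.behavior_columns = list(behavior.columns)
            self.behavior = behavior.to_numpy(float)
        else:
            self.behavior = np.asarray(behavior, float)
            self.behavior_columns = [f"y{i}" for i in range(self.behavior.shape[1])]
        if self.behavior.shape[0] != self.brain.shape[0]:
            raise ValueError("brain and behavior subject counts differ")
        self.site = np.asarray(site) if site is not None \
            else np.zeros(self.brain.shape[0], dtype=int)
        self.k = k
        self.n_splits = n_splits
        self.k_folds = k_folds
        self.n_permutations = n_permutations
        self.percentile = percentile
        self.global_pca = global_pca
        self.task = task

    def fit(self, seed: int = 0) -> "CCAResults":
        red = reduce_dimensionality(self.brain, self.k)
        full = cca_fit(red.scores, self.behavior)
        brain_load, behav_load = canonical_loadings(full, red.scores, self.behavior)
        edge_weights = backproject_brain_weights(full, red)
        test_dist, stability = crossval_cca(
            self.brain, self.behavior, self.k, self.n_splits, self.k_folds,
            seed=seed, global_pca=self.global_pca)
        null_dist = permutation_null_cca(
            self.brain, self.behavior, self.site, self.k, self.n_permutations,
            self.k_folds, seed=seed + 1, global_pca=self.global_pca)
        decision = assess_significance(test_dist, null_dist, self.percentile)
        return CCAResults(self, red, full, behav_load, brain_load, edge_weights,
                          test_dist, stability, null_dist, decision)


class CCAResults:
    """Fitted brain-behavior CCA: weights, loadings, test/null distributions."""

    def __init__(self, model, reduction, full_fit, behavioral_loadings,
                 brain_loadings, edge_weights, test_dist, weight_stability,
                 null_dist, decision):
        self.model = model
        self.reduction = reduction
        self.full_fit = full_fit
        self.behavioral_loadings = behavioral_loadings
        self.brain_loadings = brain_loadings
        self.edge_weights = edge_weights
        self.test_dist = test_dist
        self.weight_stability = weight_stability
        self.null_dist = null_dist
        self.decision = decision

    @property
    def significant(self) -> bool:
        return self.decision.significant

    @property
    def brain_weights(self) -> np.ndarray:
        return self.full_fit.x_weights[:, 0]

    @property
    def behavior_weights(self) -> np.ndarray:
        return self.full_fit.y_weights[:, 0]

    @property
    def canonical_corrs(self) -> np.ndarray:
        return self.full_fit.corrs

    def to_dict(self) -> dict:
        return {
            "task": self.model.task,
            "canonical_corrs": self.canonical_corrs.tolist(),
            "behavior_weights": self.behavior_weights.tolist(),
            "behavioral_loadings": self.behavioral_loadings.tolist(),
            "brain_weights": self.brain_weights.tolist(),
            "test_mean": self.decision.test_mean,
            "null_95": self.decision.null_percentile,
            "significant": self.decision.significant,
            "weight_stability_mean": float(np.mean(self.weight_stability)),
            "test_dist": np.asarray(self.test_dist).tolist(),
            "null_dist": np.asarray(self.null_dist).tolist(),
        }

    def summary(self) -> str:
        d = self.decision
        lines = [
            f"Brain-behavior CCA ({self.model.task or 'unnamed task'})",
            "=" * 56,
            f"subjects: {self.model.brain.shape[0]}   brain components: "
            f"{self.reduction.scores.shape[1]}   behavior scales: "
            f"{len(self.model.behavior_columns)}",
            f"first canonical correlation (in-sample): "
            f"{self.canonical_corrs[0]:.3f}",
            f"out-of-sample test mean: {d.test_mean:.3f}   "
            f"null {d.percentile:.0f}th pct: {d.null_percentile:.3f}   "
            f"significant: {d.significant}",
            f"weight stability (mean corr with all-data weights): "
            f"{np.mean(self.weight_stability):.3f}",
            "-" * 56,
            f"{'scale':<22}{'weight':>10}{'loading':>10}",
        ]
        for name, w, l in zip(self.model.behavior_columns,
                              self.behavior_weights, self.behavioral_loadings):
            lines.append(f"{name:<22}{w:>10.3f}{l:>10.3f}")
        return "\n".join(lines)
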