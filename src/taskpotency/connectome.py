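"""From region time series to normalized partial-correlation connectomes and task potency.

The per-subject, per-condition pipeline is: Ledoit-Wolf shrinkage covariance
of the region time series -> partial correlations from the inverse
covariance -> Fisher-Z transform -> normalization by the main Gaussian of a
Gaussian-gamma mixture fitted to the matrix's own edge distribution.  Task
potency is the elementwise difference between a subject's normalized task
matrix and their normalized rest matrix: the connectivity modulation the
task induces away from the resting baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from sklearn.covariance import LedoitWolf

logger = logging.getLogger(__name__)

MIN_TIMEPOINTS = 30
MIN_MIXTURE_VALUES = 500


@dataclass
class ConnectivityMatrix:
    """R x R symmetric zero-diagonal connectivity matrix for one subject/condition."""

    subject_id: str
    condition: str
    values: np.ndarray
    state: str = "raw_fisher_z"  # or "normalized"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix has non-finite entries")
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValueError("connectivity matrix must be symmetric")
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class MixtureFit:
    """Parameters of the Gaussian-gamma edge-distribution mixture.

    The central Gaussian (weight_gauss, mean_gauss, sd_gauss) models the
    null bulk of edge values; a positive gamma above the Gaussian mean and a
    mirrored negative gamma below it absorb the signal tails.
    """

    weight_gauss: float
    mean_gauss: float
    sd_gauss: float
    weight_pos: float
    shape_pos: float
    scale_pos: float
    weight_neg: float
    shape_neg: float
    scale_neg: float
    loglik: float
    converged: bool
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "weight_gauss": float(self.weight_gauss),
            "mean_gauss": float(self.mean_gauss),
            "sd_gauss": float(self.sd_gauss),
            "weight_pos": float(self.weight_pos),
            "shape_pos": float(self.shape_pos),
            "scale_pos": float(self.scale_pos),
            "weight_neg": float(self.weight_neg),
            "shape_neg": float(self.shape_neg),
            "scale_neg": float(self.scale_neg),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


@dataclass
class PotencyMatrix:
    """Task-minus-rest modulation matrix for one subject and task."""

    subject_id: str
    task: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        self.values = v


@dataclass
class EdgeTable:
    """Vectorized upper-triangle edge values: subjects x E.

    Edge ordering is frozen: upper triangle (i < j), row-major in the 0-based
    region order of the atlas; edge labels are "i_j".
    """

    task: str
    subject_ids: list
    edge_index: list  # list of (i, j) tuples, i < j
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.edge_index)):
            raise ValueError("values shape inconsistent with subjects/edges")

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    @property
    def edge_labels(self) -> list:
        return [f"{i}_{j}" for i, j in self.edge_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.edge_labels)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "subject_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, task: str) -> "EdgeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        edge_index = [tuple(int(p) for p in c.split("_")) for c in df.columns]
        return cls(task=task, subject_ids=list(df.index.astype(str)),
                   edge_index=edge_index, values=df.to_numpy(float))


def edge_index_pairs(n_regions: int) -> list:
    """Frozen edge ordering: (0,1), (0,2), ..., row-major upper triangle."""
    iu, ju = np.triu_indices(n_regions, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def shrinkage_covariance(ts: np.ndarray) -> tuple[np.ndarray, float]:
    """Ledoit-Wolf shrinkage covariance of a T x R time-series matrix.

    Returns the regularized covariance and the estimated shrinkage intensity
    (recorded per subject for audit).  Shrinkage is toward the scaled
    identity, guaranteeing a positive-definite estimate.
    """
    x = np.asarray(ts, dtype=float)
    if x.ndim != 2:
        raise ValueError("time series must be a T x R matrix")
    t, r = x.shape
    if t < MIN_TIMEPOINTS:
        raise ValueError(f"need at least {MIN_TIMEPOINTS} timepoints, got {t}")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"region column {bad} is constant")
    lw = LedoitWolf(assume_centered=False).fit(x)
    return lw.covariance_, float(lw.shrinkage_)


def partial_correlation(cov: np.ndarray) -> np.ndarray:
    """Partial correlations from a covariance matrix.

    p_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj) with Theta the precision
    (inverse covariance); the diagonal is set to 0.
    """
    c = np.asarray(cov, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("covariance must be square")
    if np.max(np.abs(c - c.T)) > 1e-8:
        raise ValueError("covariance must be symmetric")
    try:
        theta = np.linalg.inv(0.5 * (c + c.T))
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance matrix is singular") from err
    d = np.sqrt(np.diag(theta))
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("covariance matrix is not positive-definite")
    p = -theta / np.outer(d, d)
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, 0.0)
    return np.clip(p, -1.0, 1.0)


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Elementwise Fisher-Z (arctanh) of a correlation matrix; diagonal stays 0."""
    v = np.asarray(values, dtype=float)
    off = ~np.eye(v.shape[0], dtype=bool) if v.ndim == 2 and v.shape[0] == v.shape[1] \
        else np.ones_like(v, dtype=bool)
    if np.any(np.abs(v[off]) >= 1.0):
        raise ValueError("off-diagonal correlation with |r| >= 1; arctanh undefined")
    z = np.arctanh(np.where(off, v, 0.0))
    return z


def _gamma_mle_shape(mean: float, mean_log: float, max_newton: int = 50) -> float:
    """Weighted gamma shape MLE: solve log(k) - digamma(k) = log(mean) - mean_log."""
    s = np.log(mean) - mean_log
    if s <= 0:
        return 0.1
    k = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(max_newton):
        f = np.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < 1e-10 * k:
            k = k_new
            break
        k = k_new
    return float(np.clip(k, 0.1, 1e6))


def _gamma_pdf(z, k, theta):
    out = np.zeros_like(z)
    pos = z > 0
    zp = z[pos]
    out[pos] = np.exp((k - 1.0) * np.log(zp) - zp / theta
                      - special.gammaln(k) - k * np.log(theta))
    return out


def _mixture_loglik(x, w0, mu, sd, wp, kp, tp, wn, kn, tn):
    dens = w0 * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    dp = _gamma_pdf(x - mu, kp, tp) if wp > 0 else np.zeros_like(x)
    dn = _gamma_pdf(mu - x, kn, tn) if wn > 0 else np.zeros_like(x)
    total = dens + wp * dp + wn * dn
    return np.log(np.maximum(total, 1e-300)), dens, wp * dp, wn * dn


def fit_edge_mixture(values: np.ndarray, max_iter: int = 1000,
                     tol: float = 1e-6) -> MixtureFit:
    """EM fit of the Gaussian-gamma mixture to a subject's edge values.

    Three components: a central Gaussian carrying the null bulk, a gamma on
    the positive excursions above the Gaussian mean, and a mirrored gamma on
    the negative excursions below it.  The main Gaussian must end up
    dominant (weight > 0.5) for the fit to count as converged; otherwise a
    robust location/scale fallback (median, 1.4826*MAD) is returned with
    converged=False.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < MIN_MIXTURE_VALUES:
        raise ValueError(f"need at least {MIN_MIXTURE_VALUES} values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("edge values are constant; mixture undefined")

    med = float(np.median(x))
    mad_sd = float(1.4826 * np.median(np.abs(x - med)))
    if mad_sd == 0:
        mad_sd = float(x.std())

    def _fallback(loglik, n_iter):
        logger.warning("mixture fit degenerate; falling back to median/MAD")
        return MixtureFit(1.0, med, mad_sd, 0.0, 1.0, 1.0, 0.0, 1.0, 1.0,
                          loglik, False, n_iter)

    # init: Gaussian at (median, MAD); gammas method-of-moments on the tails
    mu, sd = med, mad_sd
    w0, wp, wn = 0.90, 0.05, 0.05

    def _mom(tail):
        if tail.size < 5:
            return 2.0, mad_sd
        m, v = tail.mean(), tail.var()
        if m <= 0 or v <= 0:
            return 2.0, mad_sd
        return max(m * m / v, 0.1), max(v / m, 1e-8)

    kp, tp = _mom(x[x > mu + 2 * mad_sd] - mu)
    kn, tn = _mom(mu - x[x < mu - 2 * mad_sd])

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logd, d0, dp, dn = _mixture_loglik(x, w0, mu, sd, wp, kp, tp, wn, kn, tn)
        ll = float(logd.sum())
        total = np.exp(logd)
        r0 = d0 / total
        rp = dp / total
        rn = dn / total

        n0, np_, nn = r0.sum(), rp.sum(), rn.sum()
        w0, wp, wn = n0 / x.size, np_ / x.size, nn / x.size
        # prune vanishing tail components so EM can terminate cleanly
        if 0 < wp < 1e-3:
            w0, wp = w0 + wp, 0.0
        if 0 < wn < 1e-3:
            w0, wn = w0 + wn, 0.0
        mu_new = float((r0 * x).sum() / max(n0, 1e-12))
        var_new = float((r0 * (x - mu_new) ** 2).sum() / max(n0, 1e-12))
        mu, sd = mu_new, max(np.sqrt(var_new), 1e-12)
        # gamma M-step: responsibility-weighted maximum likelihood
        for sign, rw in ((+1, rp), (-1, rn)):
            z = sign * (x - mu)
            mask = z > 0
            wsum = rw[mask].sum()
            if wsum < 1e-8:
                continue
            m1 = float((rw[mask] * z[mask]).sum() / wsum)
            mlog = float((rw[mask] * np.log(z[mask])).sum() / wsum)
            k_new = _gamma_mle_shape(m1, mlog)
            t_new = max(m1 / k_new, 1e-10)
            if sign > 0:
                kp, tp = k_new, t_new
            else:
                kn, tn = k_new, t_new

        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    if w0 <= 0.5 or not np.isfinite(sd) or sd <= 0 or not np.isfinite(mu):
        return _fallback(prev_ll, it)
    if not converged:
        # healthy dominant Gaussian but tolerance not reached at the
        # iteration cap: keep the EM estimates, flag the fit
        logger.info("mixture EM hit iteration cap (last ll %.3f); keeping estimates",
                    prev_ll)
    return MixtureFit(w0, mu, sd, wp, kp, tp, wn, kn, tn, prev_ll,
                      converged and w0 > 0.5, it)


def normalize_connectivity(m: ConnectivityMatrix, fit: MixtureFit) -> ConnectivityMatrix:
    """Center/scale a Fisher-Z matrix by its own main-Gaussian (mu0, sigma0)."""
    if m.state != "raw_fisher_z":
        raise ValueError(f"expected raw_fisher_z state, got {m.state!r}")
    if fit.sd_gauss <= 0:
        raise ValueError("main-Gaussian SD must be positive")
    v = (m.values - fit.mean_gauss) / fit.sd_gauss
    np.fill_diagonal(v, 0.0)
    return ConnectivityMatrix(m.subject_id, m.condition, v, state="normalized")


def task_potency(task_m: ConnectivityMatrix, rest_m: ConnectivityMatrix) -> PotencyMatrix:
    """Task potency: normalized task connectivity minus normalized rest connectivity."""
    if task_m.subject_id != rest_m.subject_id:
        raise ValueError("task and rest matrices belong to different subjects")
    if task_m.values.shape != rest_m.values.shape:
        raise ValueError("task and rest matrices have different region counts")
    for m in (task_m, rest_m):
        if m.state != "normalized":
            raise ValueError("task potency requires normalized matrices")
    return PotencyMatrix(task_m.subject_id, task_m.condition,
                         task_m.values - rest_m.values)


def vectorize_edges(matrices: list, task: str | None = None) -> EdgeTable:
    """Stack symmetric zero-diagonal matrices into a subjects x E edge table."""
    if not matrices:
        raise ValueError("no matrices to vectorize")
    r = matrices[0].values.shape[0]
    for m in matrices:
        if m.values.shape[0] != r:
            raise ValueError("inconsistent region counts across matrices")
    iu, ju = np.triu_indices(r, k=1)
    values = np.stack([m.values[iu, ju] for m in matrices])
    task_label = task if task is not None else getattr(matrices[0], "task",
                                                       getattr(matrices[0], "condition", ""))
    return EdgeTable(task=task_label,
                     subject_ids=[m.subject_id for m in matrices],
                     edge_index=list(zip(iu.tolist(), ju.tolist())),
                     values=values)


def unvectorize_edges(edge_row: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of vectorize_edges for one subject: E-vector -> symmetric matrix."""
    e = np.asarray(edge_row, dtype=float).ravel()
    expected = n_regions * (n_regions - 1) // 2
    if e.size != expected:
        raise ValueError(f"expected {expected} edges for R={n_regions}, got {e.size}")
    m = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    m[iu, ju] = e
    m[ju, iu] = e
    return m


def timeseries_to_connectivity(ts: np.ndarray, subject_id: str,
                               condition: str) -> tuple[ConnectivityMatrix, float]:
    """Full raw step: shrinkage covariance -> partial correlation -> Fisher-Z."""
    cov, shrinkage = shrinkage_covariance(ts)
    pc = partial_correlation(cov)
    z = fisher_z(pc)
    return ConnectivityMatrix(subject_id, condition, z), shrinkage


def normalized_connectivity(ts: np.ndarray, subject_id: str,
                            condition: str) -> tuple[ConnectivityMatrix, MixtureFit, float]:
    """Raw step plus mixture normalization of the matrix's own edge distribution."""
    raw, shrinkage = timeseries_to_connectivity(ts, subject_id, condition)
    iu, ju = np.triu_indices(raw.n_regions, k=1)
    fit = fit_edge_mixture(raw.values[iu, ju])
    return normalize_connectivity(raw, fit), fit, shrinkage
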