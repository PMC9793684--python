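"""Empirical-Bayes site harmonization of edge tables (parametric ComBat).

Removes per-site additive (location) and multiplicative (scale) effects per
edge while protecting biological covariates: covariate effects (age, sex,
diagnostic group) are estimated jointly with site, removed before the
empirical-Bayes step and re-added afterwards, so case-control and
development effects are not absorbed as site effects.  Site location/scale
estimates are shrunk toward pooled priors (normal for locations,
inverse-gamma for scales), the original parametric formulation.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd

from .connectome import EdgeTable

logger = logging.getLogger(__name__)


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    """Numeric design from the covariate frame: categoricals dummy-coded, no intercept."""
    if covariates is None or covariates.shape[1] == 0:
        return np.zeros((0 if covariates is None else len(covariates), 0))
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_numpy(float)[:, None])
        else:
            d = pd.get_dummies(s, drop_first=True)
            parts.append(d.to_numpy(float))
    return np.hstack(parts) if parts else np.zeros((len(covariates), 0))


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative solution for the empirical-Bayes batch adjustments."""
    n = sdat.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                     np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)))
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_harmonize(edges: EdgeTable, site: pd.Series | np.ndarray,
                     covariates: pd.DataFrame | None = None,
                     return_model: bool = False):
    """Harmonize a subjects x edges table across sites.

    Parameters
    ----------
    edges : EdgeTable
        Potency (or connectivity) edge values, subjects x E.
    site : array-like of str
        Per-subject site labels, aligned with ``edges.subject_ids``.
    covariates : DataFrame, optional
        Biological covariates to protect (e.g. age, sex, group); categorical
        columns are dummy-coded.
    return_model : bool
        Also return the fitted per-site location/scale model for audit.
    """
    y = edges.values.copy()
    n, e = y.shape
    site = np.asarray(site)
    if site.shape[0] != n:
        raise ValueError("site labels do not align with edge-table subjects")
    batches = pd.unique(site)
    counts = {b: int((site == b).sum()) for b in batches}
    singletons = [b for b, c in counts.items() if c < 2]
    if singletons:
        raise ValueError(f"sites with a single subject cannot be harmonized: {singletons}")

    if len(batches) == 1:
        model = {"sites": list(map(str, batches)), "note": "single site; identity"}
        out = EdgeTable(edges.task, list(edges.subject_ids),
                        list(edges.edge_index), y)
        return (out, model) if return_model else out

    batch_design = np.stack([(site == b).astype(float) for b in batches], axis=1)
    x_cov = _covariate_design(covariates) if covariates is not None else \
        np.zeros((n, 0))
    design = np.hstack([batch_design, x_cov])

    # constant edges carry no information to harmonize; pass through
    const = y.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant edge(s) passed through unchanged")
    work = ~const
    yw = y[:, work]

    b_hat, *_ = np.linalg.lstsq(design, yw, rcond=None)
    n_batch = len(batches)
    props = np.array([counts[b] for b in batches], dtype=float) / n
    grand_mean = props @ b_hat[:n_batch]
    var_pooled = ((yw - design @ b_hat) ** 2).mean(axis=0)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[None, :] + x_cov @ b_hat[n_batch:]
    s_data = (yw - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_star = np.zeros((n_batch, s_data.shape[1]))
    delta_star = np.ones((n_batch, s_data.shape[1]))
    gamma_hat_all = np.zeros_like(gamma_star)
    for i, b in enumerate(batches):
        rows = site == b
        sdat = s_data[rows]
        g_hat = sdat.mean(axis=0)
        d_hat = sdat.var(axis=0, ddof=1)
        gamma_hat_all[i] = g_hat
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        m, s2 = float(d_hat.mean()), float(d_hat.var(ddof=1))
        if s2 <= 0 or t2 <= 0:
            gamma_star[i], delta_star[i] = g_hat, np.maximum(d_hat, 1e-12)
            continue
        a = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        gamma_star[i], delta_star[i] = _it_sol(sdat, g_hat, d_hat, g_bar, t2,
                                               a, b_prior)

    adjusted = s_data.copy()
    for i, b in enumerate(batches):
        rows = site == b
        adjusted[rows] = (s_data[rows] - gamma_star[i][None, :]) / \
            np.sqrt(np.maximum(delta_star[i], 1e-12))[None, :]
    out_w = adjusted * np.sqrt(var_pooled)[None, :] + stand_mean

    out_vals = y.copy()
    out_vals[:, work] = out_w
    out = EdgeTable(edges.task, list(edges.subject_ids),
                    list(edges.edge_index), out_vals)
    model = {
        "sites": [str(b) for b in batches],
        "n_per_site": {str(b): counts[b] for b in batches},
        "gamma_star_mean": gamma_star.mean(axis=1).tolist(),
        "delta_star_mean": delta_star.mean(axis=1).tolist(),
        "covariate_columns": list(covariates.columns) if covariates is not None else [],
    }
    return (out, model) if return_model else out


def dump_model(model: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(model, fh, indent=2)
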