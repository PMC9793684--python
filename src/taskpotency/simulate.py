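"""Synthetic multi-site, multi-task cohort generator.

Generates everything the analysis consumes: a cohort table (site, age, sex,
diagnostic group, latent impairment severity), a connectivity ground truth
(block-structured rest precision, per-task modulations, one deviating edge
set shared by all tasks, age/sex/site edge effects), per-subject
per-condition region time series drawn from the implied multivariate
normal, and a seven-scale behavior table driven by the latent severity
with missing entries.

Rows of the time series are i.i.d. multivariate-normal draws: the analysis
consumes only covariance structure, so hemodynamics, autocorrelation and
scanner drift are deliberately not modelled.  Age, sex, site, task and
deviation effects enter as symmetric perturbations of the *task* precision
matrices (the rest matrix stays at baseline), so they propagate into task
potency, which is where the downstream stages look for them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .connectome import edge_index_pairs

logger = logging.getLogger(__name__)

MIN_TIMEPOINTS = 30

SEX_LEVELS = ("female", "male")
GROUP_LEVELS = ("autism", "td")


@dataclass
class GroundTruth:
    """Latent connectivity structure of the simulated cohort.

    All edge-level vectors follow the frozen upper-triangle edge ordering.
    ``deviation_support`` is the single edge set, identical in every task,
    on which autism connectivity deviates: the structure the cross-task
    similarity analysis is meant to recover.
    """

    rest_precision: np.ndarray          # R x R positive-definite
    task_modulations: dict              # task -> E-vector of precision shifts
    deviation_support: np.ndarray       # sorted edge indices
    deviation_weights: np.ndarray       # E-vector, nonzero only on support
    td_pattern_weights: np.ndarray      # E-vector, weak shared TD pattern (optional)
    age_slopes: np.ndarray              # E-vector, per-year precision shift
    sex_offsets: np.ndarray             # E-vector (applied for male subjects)
    site_offsets: dict                  # site label -> E-vector


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def generate_cohort(cfg: SimConfig, seed: int) -> pd.DataFrame:
    """Sample the subject metadata table.

    Sites are assigned uniformly at random, ages uniform over the configured
    range, sex Bernoulli(sex_balance) male.  Latent severity is unit-variance
    normal, centered ``severity_group_offset`` higher in the autism group
    (near zero in TD), so behavior generation is uniform across groups.
    """
    rng = _rng(seed, 0)
    n = cfg.n_autism + cfg.n_td
    groups = np.array(["autism"] * cfg.n_autism + ["td"] * cfg.n_td)
    sites = np.array([f"site{i % cfg.n_sites}" for i in rng.permutation(n)])
    lo, hi = cfg.age_range
    ages = rng.uniform(lo, hi, size=n)
    sexes = np.where(rng.random(n) < cfg.sex_balance, "male", "female")
    severity = rng.normal(0.0, 1.0, size=n)
    severity[groups == "autism"] += cfg.severity_group_offset
    return pd.DataFrame({
        "subject_id": [f"sub-{i:04d}" for i in range(n)],
        "site": sites,
        "age": ages,
        "sex": sexes,
        "group": groups,
        "severity": severity,
    })


def _block_partial_target(cfg: SimConfig, rng) -> np.ndarray:
    """Block-structured target partial-correlation matrix (within > between)."""
    r, k = cfg.n_regions, cfg.n_networks
    block = r // k
    labels = np.minimum(np.arange(r) // max(block, 1), k - 1)
    same = labels[:, None] == labels[None, :]
    p = np.where(same, cfg.within_network_strength, cfg.between_network_strength)
    p = p * (1.0 + 0.2 * rng.standard_normal((r, r)))
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, 0.0)
    # shrink until I - P is positive-definite with a wide margin, so
    # subject-level modulations rarely need rescaling
    ev = np.linalg.eigvalsh(p)
    m = max(ev.max(), -ev.min())
    if m >= 0.6:
        p *= 0.6 / m
    return p


def _edge_matrix(vec: np.ndarray, n_regions: int) -> np.ndarray:
    m = np.zeros((n_regions, n_regions))
    iu, ju = np.triu_indices(n_regions, k=1)
    m[iu, ju] = vec
    m[ju, iu] = vec
    return m


def generate_ground_truth(cfg: SimConfig, seed: int) -> GroundTruth:
    rng = _rng(seed, 1)
    r = cfg.n_regions
    e = cfg.n_edges
    p_target = _block_partial_target(cfg, rng)
    rest_precision = np.eye(r) - p_target  # unit diagonal: -Theta_ij == partial corr

    task_mod = {}
    for task in cfg.tasks:
        n_mod = int(round(cfg.task_modulation_frac * e))
        idx = rng.choice(e, size=n_mod, replace=False)
        vec = np.zeros(e)
        vec[idx] = cfg.task_modulation_scale * rng.standard_normal(n_mod)
        task_mod[task] = vec

    n_dev = int(round(cfg.deviation_support_frac * e))
    support = np.sort(rng.choice(e, size=n_dev, replace=False)) if n_dev else \
        np.array([], dtype=int)
    dev_w = np.zeros(e)
    if n_dev:
        dev_w[support] = rng.standard_normal(n_dev)

    td_w = np.zeros(e)
    if n_dev:
        td_w[support] = cfg.td_pattern_amplitude * rng.standard_normal(n_dev)

    age_slopes = cfg.age_slope_scale * rng.standard_normal(e)
    sex_offsets = cfg.sex_offset_scale * rng.standard_normal(e)
    site_offsets = {f"site{i}": cfg.site_effect_scale * rng.standard_normal(e)
                    for i in range(cfg.n_sites)}
    return GroundTruth(rest_precision, task_mod, support, dev_w, td_w,
                       age_slopes, sex_offsets, site_offsets)


def subject_precision(subject: pd.Series, condition: str, gt: GroundTruth,
                      cfg: SimConfig) -> np.ndarray:
    """Assemble and PD-guarantee the precision matrix for one subject/condition."""
    if condition not in cfg.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    r = cfg.n_regions
    theta = gt.rest_precision.copy()
    if condition == "rest":
        return theta

    lo, hi = cfg.age_range
    age_c = subject["age"] - 0.5 * (lo + hi)
    delta = gt.task_modulations[condition].copy()
    delta += gt.age_slopes * age_c
    if subject["sex"] == "male":
        delta += gt.sex_offsets
    delta += gt.site_offsets[subject["site"]]
    if subject["group"] == "autism":
        delta += cfg.deviation_amplitude * (1.0 + subject["severity"]) * gt.deviation_weights
    else:
        delta += gt.td_pattern_weights * (1.0 + subject["severity"])

    dmat = _edge_matrix(delta, r)
    theta = gt.rest_precision + dmat
    # modulation must never break positive-definiteness; rescale if it would
    for _ in range(60):
        if np.linalg.eigvalsh(theta)[0] > 1e-3:
            return theta
        dmat *= 0.5
        theta = gt.rest_precision + dmat
        logger.warning("rescaled modulation for %s/%s to keep precision PD",
                       subject["subject_id"], condition)
    return gt.rest_precision


def simulate_condition_timeseries(subject: pd.Series, condition: str,
                                  gt: GroundTruth, cfg: SimConfig, seed: int,
                                  n_timepoints: int | None = None) -> np.ndarray:
    """Draw T i.i.d. rows from N(0, precision^-1) for one subject/condition."""
    t = cfg.n_timepoints if n_timepoints is None else int(n_timepoints)
    if t < MIN_TIMEPOINTS:
        raise ValueError(f"need at least {MIN_TIMEPOINTS} timepoints, got {t}")
    theta = subject_precision(subject, condition, gt, cfg)
    cov = np.linalg.inv(theta)
    chol = np.linalg.cholesky(cov)
    sub_idx = int(subject["subject_id"].split("-")[-1])
    cond_idx = cfg.conditions.index(condition)
    rng = _rng(seed, 2, sub_idx, cond_idx)
    return rng.standard_normal((t, cfg.n_regions)) @ chol.T


def generate_behavior(cohort: pd.DataFrame, cfg: SimConfig,
                      seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the seven behavior scales from latent severity.

    Each scale is loading * severity + noise; loadings are signed in each
    scale's impairment direction (SRS/RBS/SSP/ADHD up with impairment,
    Vineland/IQ down).  Cells go missing completely at random at
    ``missing_rate``.  Returns (observed-with-NaN, pre-masking truth); the
    truth table exists so imputation can be scored against it.
    """
    from .behavior import BEHAVIOR_SCALES
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = _rng(seed, 3)
    sev = cohort["severity"].to_numpy()
    loadings = np.asarray(cfg.behavior_loadings, dtype=float)
    vals = sev[:, None] * loadings[None, :] + \
        cfg.behavior_noise_sd * rng.standard_normal((len(cohort), 7))
    truth = pd.DataFrame(vals, columns=list(BEHAVIOR_SCALES),
                         index=cohort["subject_id"].to_numpy())
    mask = rng.random(truth.shape) < cfg.missing_rate
    observed = truth.mask(mask)
    return observed, truth


def simulate_cohort_timeseries(cohort: pd.DataFrame, gt: GroundTruth,
                               cfg: SimConfig, seed: int) -> dict:
    """All time series: {condition: {subject_id: T x R array}}."""
    out = {}
    for condition in cfg.conditions:
        out[condition] = {
            row["subject_id"]: simulate_condition_timeseries(row, condition, gt, cfg, seed)
            for _, row in cohort.iterrows()
        }
    return out


def simulate_potency_edges(n_td: int, n_autism: int, n_edges: int,
                           seed: int, support_frac: float = 0.05,
                           amplitude: float = 0.0, n_tasks: int = 1,
                           age_slope_sd: float = 0.01, sex_offset_sd: float = 0.1,
                           noise_sd: float = 1.0,
                           heterogeneity: tuple = (2.0, 0.5)):
    """Edge-level potency cohort with a known shared deviation structure.

    Draws per-edge normative structure (intercept, linear age slope, sex
    offset, Gaussian noise) for TD and autism subjects, then adds the
    autism deviation ``amplitude * gain_i * w_e`` on one support edge set
    shared by all tasks, with per-edge signs ``w_e`` in {-1, +1} and a
    per-subject gamma-distributed gain (mean 1) supplying the individual
    heterogeneity real cohorts show.  Returns a dict with per-task edge
    matrices, covariates, group labels and the generating ground truth, for
    analyses that start downstream of the time-series stage.
    """
    rng = _rng(seed, 4)
    n = n_td + n_autism
    group = np.array(["td"] * n_td + ["autism"] * n_autism)
    age = rng.uniform(6.0, 30.0, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    covariates = pd.DataFrame({"age": age, "sex": sex, "group": group})

    beta0 = rng.normal(0.0, 0.5, n_edges)
    beta_age = rng.normal(0.0, age_slope_sd, n_edges)
    beta_sex = rng.normal(0.0, sex_offset_sd, n_edges)
    n_sup = int(round(support_frac * n_edges))
    support = np.sort(rng.choice(n_edges, n_sup, replace=False)) if n_sup else \
        np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], n_sup)
    shape, scale = heterogeneity
    gains = np.where(group == "autism", rng.gamma(shape, scale, n), 0.0)

    mean = (beta0[None, :] + (age - age.mean())[:, None] * beta_age[None, :]
            + (sex == "male").astype(float)[:, None] * beta_sex[None, :])
    tasks = {}
    for t in range(n_tasks):
        y = mean + noise_sd * rng.standard_normal((n, n_edges))
        if n_sup:
            y[:, support] += amplitude * gains[:, None] * signs[None, :]
        tasks[f"task{t}"] = y
    truth = {"beta0": beta0, "beta_age": beta_age, "beta_sex": beta_sex,
             "support": support, "signs": signs, "gains": gains,
             "noise_sd": noise_sd, "age_center": float(age.mean())}
    return tasks, covariates, truth


def write_ground_truth(gt: GroundTruth, cfg: SimConfig, out_dir) -> None:
    """Dump the ground truth as JSON + TSV for test oracles and audit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "rest_precision.tsv", gt.rest_precision, delimiter="\t")
    edges = edge_index_pairs(cfg.n_regions)
    df = pd.DataFrame({
        "edge": [f"{i}_{j}" for i, j in edges],
        "deviation_weight": gt.deviation_weights,
        "age_slope": gt.age_slopes,
        "sex_offset": gt.sex_offsets,
    })
    for task, vec in gt.task_modulations.items():
        df[f"mod_{task}"] = vec
    for site, vec in gt.site_offsets.items():
        df[f"site_{site}"] = vec
    df.to_csv(out / "edge_effects.tsv", sep="\t", index=False)
    meta = {
        "deviation_support": [int(i) for i in gt.deviation_support],
        "n_regions": cfg.n_regions,
        "conditions": list(cfg.conditions),
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))


def write_timeseries(ts: np.ndarray, path, region_ids=None) -> None:
    cols = region_ids if region_ids is not None else \
        [f"region{i}" for i in range(ts.shape[1])]
    pd.DataFrame(ts, columns=cols).to_csv(path, sep="\t", index=False)
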