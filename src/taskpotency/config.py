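"""Configuration objects for the simulator and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Condition labels: rest baseline plus the five task conditions.
DEFAULT_CONDITIONS = ("rest", "hariri", "flanker", "reward_s", "reward_ns", "tom")

#: Default linkage of the latent impairment axis to the seven behavior scales.
#: SRS/RBS/SSP and the two ADHD scales increase with impairment; Vineland
#: (adaptive functioning) and IQ decrease.
DEFAULT_BEHAVIOR_LOADINGS = (1.0, 0.8, 0.7, 0.6, 0.6, -0.8, -0.5)


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-site, multi-task cohort.

    The defaults emulate a multi-site autism case-control cohort: two
    diagnostic groups (autism and typically developing controls), ages 6-30,
    several scanner sites, a rest condition plus five task conditions, an
    atlas of regions grouped into networks, additive site effects and
    age/sex trends on connectivity, a single autism-specific set of
    deviating edges shared across all tasks, and seven behavioral scales
    driven by a latent impairment axis with missing entries.
    """

    n_autism: int = 282
    n_td: int = 221
    n_sites: int = 6
    n_regions: int = 168
    n_networks: int = 11
    n_timepoints: int = 180
    conditions: tuple = DEFAULT_CONDITIONS
    age_range: tuple = (6.0, 30.0)
    sex_balance: float = 0.5
    site_effect_scale: float = 0.02
    age_slope_scale: float = 0.002
    sex_offset_scale: float = 0.01
    deviation_support_frac: float = 0.05
    deviation_amplitude: float = 0.05
    severity_group_offset: float = 1.5
    td_pattern_amplitude: float = 0.0
    behavior_loadings: tuple = DEFAULT_BEHAVIOR_LOADINGS
    behavior_noise_sd: float = 1.0
    missing_rate: float = 0.1
    master_seed: int = 0

    # connectivity strengths of the latent rest network structure
    within_network_strength: float = 0.25
    between_network_strength: float = 0.02
    task_modulation_scale: float = 0.08
    task_modulation_frac: float = 0.05

    def __post_init__(self):
        for name in ("n_autism", "n_td"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_sites", "n_regions", "n_networks", "n_timepoints"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_networks > self.n_regions:
            raise ValueError("n_networks cannot exceed n_regions")
        for name in ("sex_balance", "missing_rate", "deviation_support_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        conditions = tuple(self.conditions)
        if conditions.count("rest") != 1:
            raise ValueError("conditions must contain 'rest' exactly once")
        self.conditions = conditions
        if len(self.behavior_loadings) != 7:
            raise ValueError("behavior_loadings must have length 7")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be an increasing interval")

    @property
    def tasks(self) -> tuple:
        return tuple(c for c in self.conditions if c != "rest")

    @property
    def n_edges(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2


@dataclass
class PipelineConfig:
    """End-to-end analysis settings; every printed analysis constant lives here.

    z_threshold 2.571 is the two-tailed 1% normal cut-off as used in the
    normative-deviation thresholding; pca_components, cv_splits, cv_folds,
    permutations and significance_percentile parameterize the out-of-sample
    CCA; top_region_fraction controls region reporting.
    """

    out_dir: str = "taskpotency_out"
    z_threshold: float = 2.571
    pca_components: int = 10
    cv_splits: int = 1000
    cv_folds: int = 10
    permutations: int = 1000
    significance_percentile: float = 95.0
    top_region_fraction: float = 0.10
    normative_folds: int = 10
    normative_basis: str = "age2"  # "age2" = [1, age, age^2, sex]; "age" = [1, age, sex]
    welch: bool = False
    global_pca: bool = False
    signed_pattern: bool = False
    master_seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if not 0 < self.top_region_fraction <= 1:
            raise ValueError("top_region_fraction must be in (0, 1]")
        if not 0 < self.significance_percentile < 100:
            raise ValueError("significance_percentile must be in (0, 100)")
        for name in ("pca_components", "cv_splits", "cv_folds", "permutations",
                     "normative_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.normative_basis not in ("age2", "age"):
            raise ValueError("normative_basis must be 'age2' or 'age'")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"]["conditions"] = list(d["sim"]["conditions"])
        d["sim"]["age_range"] = list(d["sim"]["age_range"])
        d["sim"]["behavior_loadings"] = list(d["sim"]["behavior_loadings"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def stage_seed(master_seed: int, stage: str) -> int:
    """Fan a master seed out to a per-stage seed (documented counter scheme).

    Stages are numbered in pipeline order; the per-stage seed is
    ``master_seed * 1000 + stage_index``, kept below 2**31.
    """
    stages = ("simulate", "connectome", "harmonize", "normative",
              "crosstask", "behavior", "cca", "report")
    if stage not in stages:
        raise ValueError(f"unknown stage {stage!r}")
    return (master_seed * 1000 + stages.index(stage)) % (2**31 - 1)
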