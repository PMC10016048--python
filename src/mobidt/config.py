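"""Cohort-simulation and analysis configuration.

Every experimental constant is a named default here rather than a magic
number in the stage code: block composition (240 trials, 13% NoGo, 1017-ms
SOA, 67-ms stimuli), the 183-ms response gate, the 0.1-m heel-strike
prominence cutoff, the 100-sample stride resampling, the epoch windows and
baselines, the artifact-rejection thresholds, 5000 permutations at alpha
0.05, and q = 0.05 for the combined FDR.

The group-level generator defaults encode the study conditions the analysis
is meant to recover: improvers (IMP) gain d' while walking (lower false-alarm
rate), respond faster, and walk less variably than non-improvers (nIMP);
ERP amplitude deltas between walking and sitting are injected for improvers
only, inside the canonical N2/P3/ERN/PMP windows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import InvalidConfigError

__all__ = ["SimCohortConfig", "validate_config", "load_config"]


def _default_rt_params() -> dict:
    # (mean_ms, sd_ms) per group x motor condition; cohort-weighted means
    # land near 382 ms sitting / 389 ms walking with improvers faster.
    return {
        "imp": {"sitting": [365.0, 55.0], "walking": [370.0, 45.0]},
        "nimp": {"sitting": [400.0, 62.0], "walking": [412.0, 50.0]},
    }


def _default_rates() -> dict:
    # (hit_rate, fa_rate) per group x condition; sitting d' ~= 2.26 for
    # both groups, improvers rise to ~3.3 while walking.
    return {
        "imp": {"sitting": [0.95, 0.27], "walking": [0.97, 0.08]},
        "nimp": {"sitting": [0.95, 0.27], "walking": [0.95, 0.27]},
    }


def _default_gait_jitter() -> dict:
    # meters of pointwise stride jitter per group x cognitive load (ST =
    # walking alone, DT = walking + task).  With the smooth displacement
    # field the generator uses, mean DTW ~= 150 * jitter; these cells place
    # the four group x load means in the 2.0-2.8 m range, improvers less
    # variable than non-improvers and DT below ST.
    return {
        "imp": {"ST": 0.0165, "DT": 0.014},
        "nimp": {"ST": 0.019, "DT": 0.0175},
    }


def _default_erp_effects() -> list:
    # (component, electrodes, window_ms, delta_uv): walking-minus-sitting
    # deltas injected for improvers only.  Signs follow the reported
    # directions: reduced frontocentral negativities (N2, ERN) appear as
    # positive walking-minus-sitting differences, reduced positivities
    # (P3, premovement positivity) as negative/positive per topography.
    fc = ["FCz", "Fz", "FC1", "FC2", "Cz", "AFz"]
    cp = ["CPz", "Pz", "CP1", "CP2", "P1", "P2"]
    ct = ["Cz", "FCz", "C1", "C2", "FC1", "FC2"]
    return [
        ["N2", fc, [200.0, 350.0], 1.5],
        ["P3", cp, [350.0, 600.0], -1.5],
        ["ERN", fc, [-50.0, 100.0], 2.0],
        ["PMP", ct, [-210.0, -50.0], 1.5],
    ]


@dataclass
class SimCohortConfig:
    """Full synthetic-cohort + analysis configuration."""

    n_imp: int = 14
    n_nimp: int = 12
    blocks_per_condition: int = 7
    trials_per_block: int = 240
    nogo_fraction: float = 0.13
    soa_ms: float = 1017.0
    stim_duration_ms: float = 67.0
    min_rt_ms: float = 183.0
    rt_floor_ms: float = 100.0
    rt_params: dict = field(default_factory=_default_rt_params)
    rates: dict = field(default_factory=_default_rates)

    gait_duration_s: float = 60.0
    stride_period_s: float = 1.1
    gait_jitter: dict = field(default_factory=_default_gait_jitter)
    heel_prominence_m: float = 0.1
    resample_n: int = 100

    erp_sfreq: float = 512.0
    n_cr_epochs: int = 100
    n_fa_epochs: int = 40
    erp_effect_map: list = field(default_factory=_default_erp_effects)
    noise_pink_sd_uv: float = 6.0
    noise_white_sd_uv: float = 4.0
    noise_exponent: float = 1.0
    noise_spatial_sigma_rad: float = 0.6

    n_permutations: int = 5000
    cluster_alpha: float = 0.05
    perm_alpha: float = 0.05
    neighbor_radius_rad: float = 0.55
    fdr_q: float = 0.05
    classify_alpha: float = 0.05
    seed: int = 0

    @property
    def n_participants(self) -> int:
        return self.n_imp + self.n_nimp


_FIELDS = {f.name for f in dataclasses.fields(SimCohortConfig)}


def validate_config(raw: dict | None) -> SimCohortConfig:
    """Fill defaults, reject unknown keys, and range-check the values.

    All violations are collected and reported together.
    """
    raw = dict(raw or {})
    errors = [f"unknown config key: {k!r}" for k in raw if k not in _FIELDS]
    cfg = SimCohortConfig(**{k: v for k, v in raw.items() if k in _FIELDS})

    if cfg.n_imp < 0 or cfg.n_nimp < 0 or cfg.n_participants < 2:
        errors.append("need n_imp + n_nimp >= 2 participants (each >= 0)")
    if cfg.trials_per_block < 2:
        errors.append("trials_per_block must be >= 2")
    if not 0.0 < cfg.nogo_fraction < 1.0:
        errors.append("nogo_fraction must lie strictly inside (0, 1)")
    if cfg.soa_ms <= cfg.stim_duration_ms:
        errors.append("soa_ms must exceed stim_duration_ms")
    if cfg.min_rt_ms <= 0 or cfg.rt_floor_ms <= 0:
        errors.append("RT gate and floor must be positive")
    for grp, conds in cfg.rates.items():
        for cond, (hr, far) in conds.items():
            if not (0.0 <= hr <= 1.0 and 0.0 <= far <= 1.0):
                errors.append(f"rates[{grp}][{cond}] must lie in [0, 1]")
    if cfg.gait_duration_s < 3 * cfg.stride_period_s:
        errors.append("gait_duration_s must cover >= 3 stride periods")
    if cfg.heel_prominence_m <= 0:
        errors.append("heel_prominence_m must be positive")
    if cfg.resample_n < 2:
        errors.append("resample_n must be >= 2")
    if cfg.n_permutations < 1:
        errors.append("n_permutations must be >= 1")
    for name in ("cluster_alpha", "perm_alpha", "fdr_q", "classify_alpha"):
        v = getattr(cfg, name)
        if not 0.0 < v < 1.0:
            errors.append(f"{name} must lie strictly inside (0, 1)")
    if errors:
        raise InvalidConfigError("; ".join(errors))
    return cfg


def load_config(path) -> SimCohortConfig:
    """Load and validate a YAML config file; an empty file means defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise InvalidConfigError("config file must contain a YAML mapping")
    return validate_config(raw)


def config_to_dict(cfg: SimCohortConfig) -> dict:
    return dataclasses.asdict(cfg)
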