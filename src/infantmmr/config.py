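"""Hierarchical pipeline configuration with study defaults.

Every analysis parameter lives here with the study's value as default, so an
empty config file reproduces the canonical pipeline: 1-18 Hz order-4 filter,
-200..+799 ms epochs, +-150 uV / 50 uV-step / 5-SD-kurtosis rejection, 250 Hz
resample, 95%-variance spatial PCA, 10,007 bootstrap iterations, the
component search windows, 80 ms minimum peak distance, and the center-of-mass
displacement bins.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Config", "load_config", "default_config", "COMPONENT_WINDOWS"]

# component-specific peak search windows (ms)
COMPONENT_WINDOWS = {
    "P1": (100.0, 300.0),
    "N1": (200.0, 450.0),
    "P2": (500.0, 800.0),
    "MMR": (150.0, 450.0),
}


@dataclass
class FilterConfig:
    low_hz: float = 1.0
    high_hz: float = 18.0
    order: int = 4


@dataclass
class EpochConfig:
    tmin_ms: float = -200.0
    tmax_ms: float = 799.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)


@dataclass
class RejectConfig:
    volt_thresh_uv: float = 150.0
    step_thresh_uv: float = 50.0
    kurt_sd: float = 5.0
    flat_tol_uv: float = 1e-3
    z_var_thresh: float = 3.0


@dataclass
class ResampleConfig:
    intermediate_rate_hz: float = 1000.0
    target_rate_hz: float = 250.0


@dataclass
class PcaConfig:
    var_retained: float = 0.95


@dataclass
class BootstrapConfig:
    n_boot: int = 10007


@dataclass
class PeaksConfig:
    min_distance_ms: float = 80.0
    windows: dict = field(default_factory=lambda: {k: list(v) for k, v in COMPONENT_WINDOWS.items()})


@dataclass
class BayesConfig:
    cauchy_scale: float = 0.7071067811865476  # sqrt(2)/2, default JZS prior
    substantial: float = 3.0
    strong: float = 10.0


@dataclass
class FdrConfig:
    q_level: float = 0.05


@dataclass
class ComConfig:
    # left-closed displacement bins (normalized units)
    minimal_max: float = 0.02
    small_max: float = 0.05
    moderate_max: float = 0.10


@dataclass
class MatchingConfig:
    strategy: str = "preceding"  # or "random"


@dataclass
class ParadigmConfig:
    n_trials: int = 600
    deviant_prob: float = 0.15
    stim_ms: float = 400.0
    isi_ms: float = 1200.0


@dataclass
class CohortConfig:
    n_subjects_pool: int = 83
    n_per_session: dict = field(default_factory=lambda: {"T1": 59, "T2": 72, "T3": 46})
    noise_sd_uv: float = 15.0
    artifact_rate: float = 0.05
    amplitude_sd_uv: float = 8.0
    latency_jitter_sd_ms: float = 15.0
    seed: int = 0


@dataclass
class StatsConfig:
    alpha: float = 0.05


@dataclass
class Config:
    filter: FilterConfig = field(default_factory=FilterConfig)
    epoch: EpochConfig = field(default_factory=EpochConfig)
    reject: RejectConfig = field(default_factory=RejectConfig)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    pca: PcaConfig = field(default_factory=PcaConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    peaks: PeaksConfig = field(default_factory=PeaksConfig)
    bayes: BayesConfig = field(default_factory=BayesConfig)
    fdr: FdrConfig = field(default_factory=FdrConfig)
    com: ComConfig = field(default_factory=ComConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)


def _apply(obj, overrides: dict, prefix: str = "") -> None:
    for key, value in overrides.items():
        if not dataclasses.is_dataclass(obj) or key not in {f.name for f in dataclasses.fields(obj)}:
            raise KeyError(f"unknown config key: {prefix}{key}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, dict):
                raise TypeError(f"config section {prefix}{key} must be a mapping")
            _apply(current, value, prefix=f"{prefix}{key}.")
        else:
            if isinstance(current, tuple) and isinstance(value, (list, tuple)):
                value = tuple(value)
            if isinstance(current, bool) is not isinstance(value, bool) and isinstance(current, bool):
                raise TypeError(f"config key {prefix}{key} must be boolean")
            if isinstance(current, (int, float)) and not isinstance(current, bool):
                if not isinstance(value, (int, float)) or isinstance(value, bool):
                    raise TypeError(f"config key {prefix}{key} must be numeric")
                value = type(current)(value) if isinstance(current, int) and float(value).is_integer() else value
            setattr(obj, key, value)


def _validate(cfg: Config) -> None:
    errors = []
    if not 0 < cfg.filter.low_hz < cfg.filter.high_hz:
        errors.append("filter.low_hz must satisfy 0 < low < high")
    if cfg.filter.order < 1:
        errors.append("filter.order must be >= 1")
    if cfg.epoch.tmin_ms >= cfg.epoch.tmax_ms:
        errors.append("epoch.tmin_ms must be < epoch.tmax_ms")
    b0, b1 = cfg.epoch.baseline_ms
    if not (cfg.epoch.tmin_ms <= b0 < b1 <= cfg.epoch.tmax_ms):
        errors.append("epoch.baseline_ms must lie within the epoch window")
    for key in ("volt_thresh_uv", "step_thresh_uv", "kurt_sd"):
        if getattr(cfg.reject, key) <= 0:
            errors.append(f"reject.{key} must be positive")
    if not cfg.resample.target_rate_hz <= cfg.resample.intermediate_rate_hz:
        errors.append("resample.target_rate_hz must not exceed the intermediate rate")
    if cfg.filter.high_hz >= cfg.resample.target_rate_hz / 2:
        errors.append("filter.high_hz must be below the target-rate Nyquist frequency")
    if not 0 < cfg.pca.var_retained <= 1:
        errors.append("pca.var_retained must be in (0, 1]")
    if cfg.bootstrap.n_boot < 2:
        errors.append("bootstrap.n_boot must be >= 2")
    for comp, win in cfg.peaks.windows.items():
        if comp not in COMPONENT_WINDOWS:
            errors.append(f"peaks.windows has unknown component {comp}")
        elif not win[0] < win[1]:
            errors.append(f"peaks.windows.{comp} must be increasing")
    if cfg.bayes.cauchy_scale <= 0:
        errors.append("bayes.cauchy_scale must be positive")
    if not 0 < cfg.fdr.q_level < 1:
        errors.append("fdr.q_level must be in (0, 1)")
    if not 0 < cfg.com.minimal_max < cfg.com.small_max < cfg.com.moderate_max:
        errors.append("com bins must be increasing and positive")
    if cfg.matching.strategy not in ("preceding", "random"):
        errors.append("matching.strategy must be 'preceding' or 'random'")
    if not 0 < cfg.paradigm.deviant_prob < 0.5:
        errors.append("paradigm.deviant_prob must be in (0, 0.5)")
    if not 0 <= cfg.cohort.artifact_rate <= 1:
        errors.append("cohort.artifact_rate must be in [0, 1]")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))


def default_config() -> Config:
    cfg = Config()
    _validate(cfg)
    return cfg


def load_config(path: str | Path | None = None) -> Config:
    """Resolve the full parameter set from a YAML file (defaults if empty/None)."""
    cfg = Config()
    if path is not None:
        text = Path(path).read_text()
        overrides = yaml.safe_load(text) or {}
        if not isinstance(overrides, dict):
            raise TypeError("config file must contain a mapping at top level")
        _apply(cfg, overrides)
    _validate(cfg)
    return cfg
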