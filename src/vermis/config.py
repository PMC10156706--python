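"""Run configuration: every numeric threshold used by the pipeline.

All analysis stages take their thresholds from a :class:`RunConfig` so that a
run is fully described by one config document.  The defaults are the
constants of the standard oculomotor-vermis analysis protocol (velocity
threshold 30 deg/s, 50 deg/s peak-velocity bins, 1.5x/3x/5x SD modulation
criteria, 85% variance cut for manifold dimensionality, post-saccadic
complex-spike windows [50,140) and [140,250) ms, ...).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace

import yaml

log = logging.getLogger("vermis")


@dataclass(frozen=True)
class RunConfig:
    # --- behavior ------------------------------------------------------
    sample_rate_hz: float = 1000.0
    velocity_threshold: float = 30.0          # deg/s, saccade detection
    velocity_smoothing_ms: float = 5.0        # boxcar on differentiated trace
    merge_gap_ms: float = 20.0                # merge threshold crossings
    min_saccade_duration_ms: float = 10.0
    primary_amplitude_min: float = 13.0       # deg, primary-saccade filter
    primary_amplitude_max: float = 17.0
    error_floor_deg: float = 0.25             # |error| below this -> "none"
    pv_bin_size: float = 50.0                 # deg/s
    min_trials_per_bin: int = 5
    early_late_n: int = 30

    # --- peri-event grids (ms relative to saccade onset) ---------------
    grid_start_ms: float = -250.0
    grid_stop_ms: float = 400.0
    bin_ms: float = 1.0
    mf_grid_start_ms: float = -450.0          # covers the [-400,-200] baseline
    mf_grid_stop_ms: float = 500.0            # covers post-offset baselines
    ss_smoothing_sd_ms: float = 5.0           # Gaussian kernel for PC simple spikes

    # --- unit classification -------------------------------------------
    bt_sd_factor: float = 1.5                 # burst-tonic rate-step criterion
    onset_sd_factor: float = 3.0              # modulation on/offset criterion
    onset_consecutive_bins: int = 3           # sustained-crossing requirement
    pc_sd_factor: float = 5.0                 # SS peak significance criterion
    lead_threshold_ms: float = 15.0           # long- vs short-lead boundary
    mf_baseline_window: tuple = (-400.0, -200.0)
    mf_post_baseline_from_offset: tuple = (200.0, 400.0)
    bt_pre_window: tuple = (-250.0, -150.0)
    bt_post_window: tuple = (150.0, 250.0)
    pc_baseline_window: tuple = (-250.0, -100.0)
    pc_peri_window_from_offset: tuple = (-50.0, 150.0)
    peak_min_distance_ms: float = 10.0
    peak_min_prominence: float = 2.0          # spikes/s

    # --- rate models / manifolds ---------------------------------------
    baseline_window: tuple = (-250.0, -100.0) # rate-model baseline subtraction
    rate_smoothing_sd_ms: float = 5.0         # per-trial rates for model fits
    variance_threshold: float = 0.85
    eig_gap_rtol: float = 1e-6
    trajectory_smoothing_sd_ms: float = 15.0  # before phase-based statistics

    # --- complex-spike analysis ----------------------------------------
    cs_window_early: tuple = (50.0, 140.0)    # ms from saccade offset, half-open
    cs_window_late: tuple = (140.0, 250.0)
    cs_min_trials_per_direction: int = 10
    min_pool_trials: int = 30
    pv_grid_points: int = 5
    pv_grid_percentiles: tuple = (10.0, 90.0)

    # --- statistics -----------------------------------------------------
    bootstrap_reps: int = 500
    seed: int = 0

    # --- unit inclusion lists (None = all) ------------------------------
    include_mf_units: tuple | None = None
    include_pc_units: tuple | None = None

    def replace(self, **overrides) -> "RunConfig":
        """Return a copy with overrides applied; overrides are logged."""
        valid = {f.name for f in fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key, value in overrides.items():
            old = getattr(self, key)
            if old != value:
                log.info("config override: %s = %r (default %r)", key, value, old)
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        for key, value in list(raw.items()):
            if isinstance(value, list):
                raw[key] = tuple(value)
        return cls().replace(**raw)


DEFAULT_CONFIG = RunConfig()
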