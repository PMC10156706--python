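"""Synthetic saccade-session generator with known ground truth.

Emulates the statistical structure of primate oculomotor-vermis recordings
during a fatigue-inducing repetitive saccade task:

* gradual peak-velocity (PV) decline over the session (second-order
  polynomial drift, ~10% by default) with a compensatory increase in
  saccade duration that preserves the 15-deg amplitude (velocity-duration
  tradeoff), plus trial-to-trial endpoint noise producing inward
  (overshoot) and outward (undershoot) errors;
* three mossy-fiber (MF) response classes (burst-tonic, long-lead burst,
  short-lead burst) whose per-trial peak intensity is exactly linear in PV
  and whose burst offset tracks the saccade offset linearly;
* four Purkinje-cell simple-spike (SS) classes (burst, pause, burst-pause,
  pause-burst) whose modulation extremum is linear in PV and whose
  extremum time shifts with duration;
* complex spikes (CS) driven by a shared climbing-fiber volley that an
  endpoint error evokes with probability ``cf_event_prob``; per trial the
  conditional marginals are preserved exactly (probability ``p_on`` in the
  50-140 ms post-saccadic window when the error direction matches the
  unit's CS-ON direction, ``p_off`` otherwise), and each CS suppresses SS
  firing for 10-20 ms;
* optional CS-contingent next-trial effects used to probe error-driven
  plasticity: after an outward-error volley the next same-type trial gets
  +PV and a transient gain on the PC population's PV coding; after an
  inward-error volley it gets -duration and amplified duration-time
  coding.

Spikes are drawn from an inhomogeneous Poisson process by thinning.  All
outputs are a pure function of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import RunConfig, DEFAULT_CONFIG
from .io import SessionBundle

log = logging.getLogger("vermis")

__all__ = [
    "SessionConfig",
    "GroundTruth",
    "UnitRecording",
    "InfeasibleProfileError",
    "velocity_profile",
    "profile_skewness",
    "generate_kinematics_sequence",
    "generate_mf_unit",
    "generate_pc_unit",
    "sample_spikes",
    "generate_session",
]

#: mean-to-peak velocity ratio of the nominal saccade: the velocity-duration
#: tradeoff sets duration so that amplitude = TRADEOFF_RATIO * PV * duration.
TRADEOFF_RATIO = 0.62

#: integral fraction (over the full pulse base) at which the pulse is
#: symmetric; smaller required fractions shift the peak earlier, producing
#: the longer deceleration phase (positive skew) of slow saccades.
C_SYM_SHAPE = 0.55


class InfeasibleProfileError(ValueError):
    """Raised when (PV, duration, amplitude) admit no velocity profile."""


@dataclass(frozen=True)
class SessionConfig:
    """Ground-truth parameters of one synthetic session."""

    n_trials: int = 300
    target_eccentricity: float = 15.0      # deg
    fixation_window: float = 2.0           # deg (metadata only)
    pv_start: float = 500.0                # deg/s, fatigue drift endpoints
    pv_end: float = 450.0
    pv_noise_cv: float = 0.05              # i.i.d. Gaussian noise on log-PV
    endpoint_noise_sd: float = 0.75        # deg
    duration_gamma: float = 0.25           # extra duration compensation exponent
    direction_schedule: str = "alternating"  # or "centrifugal_only"
    direction: str = "right"               # centrifugal direction
    sample_rate: float = 1000.0            # Hz
    saccade_onset_ms: float = 300.0        # within the per-trial trace
    trace_len_ms: int = 1100
    error_floor_deg: float = 0.25
    # climbing-fiber (CF) volleys and contingent next-trial effects.  An
    # endpoint error evokes a shared CF event with probability
    # cf_event_prob; the next same-type trial then carries the planted
    # behavioral change (+PV after an outward event, -duration after an
    # inward event) together with the matching encoding modulation of the
    # PC population (stronger PV-gain coding after outward, amplified
    # duration-time sensitivity after inward).
    cf_event_prob: float = 0.5
    contingent_pv_gain: float = 0.0        # e.g. 0.05: +5% PV after outward
    contingent_duration_gain: float = 0.0  # e.g. 0.10: -10% duration after inward
    contingent_pv_coding_gain: float = 0.0       # e.g. 0.5: +50% PC PV slope
    contingent_duration_coding_gain: float = 0.0 # e.g. 1.0: doubled time sensitivity
    # unit counts per class (paper-like class proportions at desk scale)
    n_mf_bt: int = 5
    n_mf_llb: int = 12
    n_mf_slb: int = 7
    n_pc_burst: int = 6
    n_pc_pause: int = 5
    n_pc_burst_pause: int = 3
    n_pc_pause_burst: int = 2
    # complex-spike tuning
    p_cs_on: float = 0.4                   # per-trial CS probability, matching error
    p_cs_off: float = 0.1
    p_cs_late: float = 0.02                # untuned late-window [140,250) CS rate
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.pv_end > self.pv_start:
            raise ValueError("pv_end must be <= pv_start")
        if self.endpoint_noise_sd < 0:
            raise ValueError("endpoint_noise_sd must be >= 0")
        if self.p_cs_on <= self.p_cs_off:
            raise ValueError("p_cs_on must exceed p_cs_off")


@dataclass
class GroundTruth:
    """Generator parameters serialized alongside the session output."""

    config: dict
    trial_latents: dict            # pv/duration before noise & contingency
    unit_params: dict              # per-unit encoding slopes/intercepts etc.
    unit_classes: dict             # unit_id -> class label
    cs_on_directions: dict         # PC unit_id -> {left, right}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class UnitRecording:
    """One unit's per-trial event times plus class metadata.

    ``spikes[i]`` holds spike times in ms relative to saccade onset of
    trial ``trial_index[i]``; ``cs_times[i]`` (PCs only) holds complex-spike
    times in ms relative to saccade *offset*.
    """

    unit_id: str
    kind: str                      # "MF" or "PC"
    trial_index: np.ndarray
    spikes: list
    cs_times: list | None = None
    class_label: str | None = None
    cs_on_direction: str | None = None
    preferred_direction: str | None = None


# ----------------------------------------------------------------------
# velocity profiles
# ----------------------------------------------------------------------

_XGRID = np.linspace(0.0, 1.0, 2001)


def _pulse_shape(x: np.ndarray, xstar: float, s: float) -> np.ndarray:
    """Unimodal pulse on [0,1] with maximum 1 at ``xstar``; sharpness ``s``."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lh = xstar * np.log(x / xstar) + (1.0 - xstar) * np.log((1.0 - x) / (1.0 - xstar))
    lh = np.where((x <= 0.0) | (x >= 1.0), -np.inf, lh)
    return np.exp(s * lh)


def _integral_fraction(xstar: float, s: float) -> float:
    return float(np.trapezoid(_pulse_shape(_XGRID, xstar, s), _XGRID))


def _solve_sharpness(xstar: float, c_req: float) -> float:
    """Find s such that the pulse's integral fraction equals ``c_req``."""
    lo, hi = 1e-4, 2000.0
    if _integral_fraction(xstar, lo) < c_req:
        raise InfeasibleProfileError(
            f"required integral fraction {c_req:.3f} too close to 1"
        )
    if _integral_fraction(xstar, hi) > c_req:
        raise InfeasibleProfileError(
            f"required integral fraction {c_req:.4f} too small for the pulse family"
        )
    return brentq(lambda s: _integral_fraction(xstar, s) - c_req, lo, hi, xtol=1e-6)


def velocity_profile(
    pv: float,
    duration: float,
    amplitude: float,
    sample_rate: float = 1000.0,
    threshold: float = 30.0,
) -> np.ndarray:
    """Sampled velocity trace (deg/s) of a saccade.

    The trace is a unimodal pulse with maximum ``pv``, whose support at the
    ``threshold`` (30 deg/s) detection criterion has length ``duration``
    (ms) and whose time integral equals ``amplitude`` (deg).  Skewness (a
    longer deceleration phase, peak before midpoint) increases as the
    required mean-to-peak velocity ratio drops, i.e. with duration at
    fixed PV and amplitude.
    """
    if pv <= 0 or duration <= 0 or amplitude <= 0:
        raise ValueError("pv, duration and amplitude must be positive")
    if amplitude >= 0.98 * pv * duration / 1000.0:
        raise InfeasibleProfileError(
            f"amplitude {amplitude} deg not reachable with pv={pv} deg/s "
            f"and duration={duration} ms"
        )
    if pv <= threshold:
        raise InfeasibleProfileError("peak velocity at or below detection threshold")

    # Solve for the support fraction beta = duration / base such that the
    # threshold-crossing width of the pulse equals `duration`.  For each
    # candidate beta the required integral fraction fixes the pulse shape
    # (asymmetry and sharpness); the residual is the mismatch between the
    # shape's crossing width and beta.
    r = amplitude * 1000.0 / (pv * duration)
    level = threshold / pv

    def shape_at(beta: float) -> tuple[float, float]:
        c_req = r * beta
        xstar = float(np.clip(0.5 * c_req / C_SYM_SHAPE, 0.25, 0.5))
        return xstar, _solve_sharpness(xstar, c_req)

    def residual(beta: float) -> float:
        xstar, s = shape_at(beta)
        f = lambda x: _pulse_shape(np.array([x]), xstar, s)[0] - level
        x1 = brentq(f, 1e-9, xstar)
        x2 = brentq(f, xstar, 1.0 - 1e-9)
        return (x2 - x1) - beta

    hi = min(0.999, 0.995 / r)
    try:
        lo = None
        for cand in (0.05, 0.1, 0.2, 0.3, 0.5, 0.7):
            if cand >= hi:
                break
            try:
                res_lo = residual(cand)
            except InfeasibleProfileError:
                continue  # shape unsolvable at this support fraction
            if res_lo > 0:
                lo = cand
                break
        if lo is None or residual(hi) > 0:
            raise ValueError
        beta = brentq(residual, lo, hi, xtol=1e-5)
    except (ValueError, InfeasibleProfileError) as exc:
        raise InfeasibleProfileError(
            f"no pulse with peak {pv:.1f} deg/s, {threshold:.0f} deg/s support "
            f"{duration:.1f} ms and integral {amplitude:.2f} deg in this "
            "profile family"
        ) from exc
    xstar, s = shape_at(beta)
    base = duration / beta

    dt_ms = 1000.0 / sample_rate
    n = int(np.floor(base / dt_ms)) + 1
    x = np.arange(n) * dt_ms / base
    v = pv * _pulse_shape(x, xstar, s)
    v[0] = v[-1] = 0.0
    # absorb the residual quadrature error into the amplitude constraint
    area = np.trapezoid(v) * dt_ms / 1000.0
    v *= amplitude / area
    return v


def profile_skewness(v: np.ndarray, sample_rate: float = 1000.0) -> float:
    """Skewness of a velocity profile treated as a density over time."""
    t = np.arange(v.size) / sample_rate
    w = v / np.trapezoid(v, t)
    mu = np.trapezoid(w * t, t)
    var = np.trapezoid(w * (t - mu) ** 2, t)
    m3 = np.trapezoid(w * (t - mu) ** 3, t)
    return float(m3 / var**1.5)


# ----------------------------------------------------------------------
# kinematics sequences
# ----------------------------------------------------------------------

def _tradeoff_duration(cfg: SessionConfig, pv: float) -> float:
    """Duration (ms) implied by the velocity-duration tradeoff at ``pv``."""
    base = cfg.target_eccentricity / (TRADEOFF_RATIO * pv) * 1000.0
    return base * (cfg.pv_start / pv) ** cfg.duration_gamma


def generate_kinematics_sequence(
    cfg: SessionConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-trial saccade kinematics (PV, duration, amplitude, labels).

    PV follows a monotone second-order polynomial drift from ``pv_start``
    to ``pv_end`` plus i.i.d. log-normal trial noise; duration follows the
    velocity-duration tradeoff (slightly over-compensating via
    ``duration_gamma`` so slow saccades lengthen and skew as observed);
    amplitude is the target eccentricity plus Gaussian endpoint noise,
    which defines inward (overshoot) / outward (undershoot) error labels.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials
    other = {"right": "left", "left": "right"}
    rows = []
    last_event_by_type: dict[str, str] = {}
    n_resampled = 0
    for i in range(n):
        u = i / max(n - 1, 1)
        pv_lat = cfg.pv_end + (cfg.pv_start - cfg.pv_end) * (1.0 - u) ** 2
        if cfg.direction_schedule == "centrifugal_only":
            ttype = "centrifugal"
            direction = cfg.direction
        else:
            ttype = "centrifugal" if i % 2 == 0 else "centripetal"
            direction = cfg.direction if ttype == "centrifugal" else other[cfg.direction]
        prev = last_event_by_type.get(ttype, "none")
        for _attempt in range(100):
            pv = pv_lat * float(np.exp(cfg.pv_noise_cv * rng.standard_normal()))
            dur_lat = _tradeoff_duration(cfg, pv)
            dur = dur_lat
            if prev == "outward" and cfg.contingent_pv_gain:
                pv = pv * (1.0 + cfg.contingent_pv_gain)
            elif prev == "inward" and cfg.contingent_duration_gain:
                dur = dur * (1.0 - cfg.contingent_duration_gain)
            # endpoint noise acts as a gain error on the velocity command:
            # undershoots are slower, overshoots faster, duration unchanged
            gain = 1.0 + cfg.endpoint_noise_sd * rng.standard_normal() / cfg.target_eccentricity
            amp = cfg.target_eccentricity * gain
            pv = pv * gain
            if pv > 30.0 and dur > 0 and 0 < amp < 0.98 * pv * dur / 1000.0:
                break
            n_resampled += 1
        else:  # pragma: no cover - pathological configs only
            raise RuntimeError("could not draw feasible kinematics in 100 attempts")
        err = amp - cfg.target_eccentricity  # >0 overshoot, <0 undershoot
        if abs(err) < cfg.error_floor_deg:
            etype, edir = "none", "none"
        elif err > 0:
            etype, edir = "inward", other[direction]
        else:
            etype, edir = "outward", direction
        # shared climbing-fiber volley reporting the error
        if etype != "none" and rng.uniform() < cfg.cf_event_prob:
            cf_event, cf_type = edir, etype
        else:
            cf_event, cf_type = "none", "none"
        last_event_by_type[ttype] = cf_type
        rows.append(
            dict(
                trial_index=i,
                type=ttype,
                direction=direction,
                pv=pv,
                duration_ms=dur,
                amplitude=amp,
                pv_latent=pv_lat,
                duration_latent=dur_lat,
                endpoint_error=err,
                error_type=etype,
                error_direction=edir,
                cf_event=cf_event,
                post_outward_event=prev == "outward",
                post_inward_event=prev == "inward",
            )
        )
    if n_resampled:
        log.info("kinematics: %d draws rejected and resampled", n_resampled)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# spike sampling
# ----------------------------------------------------------------------

def sample_spikes(
    intensity: np.ndarray, t_ms: np.ndarray, rng: np.random.Generator | int = 0
) -> np.ndarray:
    """Event times (ms) from an inhomogeneous Poisson process by thinning."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative everywhere")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lam_max = intensity.max() if intensity.size else 0.0
    if lam_max == 0.0:
        return np.empty(0)
    span_s = (t_ms[-1] - t_ms[0]) / 1000.0
    n = rng.poisson(lam_max * span_s)
    ts = rng.uniform(t_ms[0], t_ms[-1], size=n)
    accept = rng.uniform(0.0, 1.0, size=n) < np.interp(ts, t_ms, intensity) / lam_max
    return np.sort(ts[accept])


# ----------------------------------------------------------------------
# unit generators
# ----------------------------------------------------------------------

def _rise_fall_envelope(
    t: np.ndarray, lead: float, t_off: float, ramp: bool
) -> np.ndarray:
    """Envelope rising over [-lead, 0] and falling to zero at ``t_off``."""
    env = np.zeros_like(t)
    rise = (t >= -lead) & (t < 0)
    frac = (t[rise] + lead) / lead
    env[rise] = frac if ramp else 0.5 * (1.0 - np.cos(np.pi * frac))
    fall = (t >= 0) & (t <= t_off)
    env[fall] = 0.5 * (1.0 + np.cos(np.pi * t[fall] / t_off))
    return env


def _draw_mf_params(klass: str, rng: np.random.Generator) -> dict:
    if klass not in ("BT", "LLB", "SLB"):
        raise ValueError(f"unknown MF class {klass!r}")
    p = dict(
        klass=klass,
        baseline=float(rng.uniform(5.0, 15.0)),
        pv_slope=float(rng.uniform(0.3, 0.6)),          # (sp/s)/(deg/s)
        peak_at_500=float(rng.uniform(150.0, 280.0)),
        offset_lag=float(rng.uniform(2.0, 10.0)),       # burst offset - saccade end
    )
    if klass == "BT":
        p["lead"] = float(rng.uniform(5.0, 15.0))
        p["tonic"] = float(rng.uniform(20.0, 60.0))
    elif klass == "SLB":
        p["lead"] = float(rng.uniform(5.0, 12.0))
    else:  # LLB: ramping onset well before the saccade
        p["lead"] = float(np.clip(rng.normal(150.0, 40.0), 50.0, 350.0))
    return p


def mf_intensity(
    params: dict, pv: float, duration: float, t_ms: np.ndarray
) -> np.ndarray:
    """Per-trial MF intensity: peak exactly linear in PV, offset tracks
    saccade end linearly, class-appropriate pre/post structure."""
    b = params["baseline"]
    peak = params["peak_at_500"] + params["pv_slope"] * (pv - 500.0)
    t_off = duration + params["offset_lag"]
    env = _rise_fall_envelope(t_ms, params["lead"], t_off, ramp=params["klass"] == "LLB")
    lam = b + (peak - b) * env
    if params["klass"] == "BT":
        tonic = b + params["tonic"]
        post = t_ms > 0
        # decay to the tonic level instead of baseline after the burst
        lam[post] = tonic + (peak - tonic) * env[post]
        lam[t_ms > t_off] = tonic
    return np.maximum(lam, 0.0)


def generate_mf_unit(
    klass: str,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    unit_id: str,
    cfg: SessionConfig,
    grid: np.ndarray,
) -> tuple[UnitRecording, dict]:
    """Generate one MF unit's spikes for every trial in ``trials``.

    The unit fires its class template in the preferred (centrifugal)
    direction and baseline-only activity otherwise.
    """
    params = _draw_mf_params(klass, rng)
    spikes = []
    for tr in trials.itertuples(index=False):
        if tr.type == "centrifugal":
            lam = mf_intensity(params, tr.pv, tr.duration_ms, grid)
        else:
            lam = np.full_like(grid, params["baseline"])
        spikes.append(sample_spikes(lam, grid, rng))
    rec = UnitRecording(
        unit_id=unit_id,
        kind="MF",
        trial_index=trials["trial_index"].to_numpy(),
        spikes=spikes,
        class_label=klass,
        preferred_direction=cfg.direction,
    )
    return rec, params


_PC_CLASSES = ("burst", "pause", "burst-pause", "pause-burst")


def _draw_pc_params(klass: str, rng: np.random.Generator,
                    dur_ref: float = 48.4) -> dict:
    if klass not in _PC_CLASSES:
        raise ValueError(f"unknown PC class {klass!r}")
    return dict(
        klass=klass,
        baseline=float(rng.uniform(55.0, 90.0)),
        mod_at_500=float(rng.uniform(50.0, 90.0)),      # |extremum| at PV=500
        pv_slope=float(rng.uniform(0.10, 0.25)),        # (sp/s)/(deg/s)
        # temporal shape in units of saccade duration: the response is a
        # pure time-warp of a per-unit waveform, so duration scales the
        # population trajectory's time axis without changing its geometry
        t_frac=float(rng.uniform(0.6, 0.9)),            # extremum time / duration
        sd_frac=float(rng.uniform(0.25, 0.37)),         # lobe width / duration
        gap_frac=float(rng.uniform(0.55, 0.8)),         # biphasic lobe gap / duration
        biphasic_ratio=float(rng.uniform(0.7, 0.95)),
        cs_suppression_ms=float(rng.uniform(10.0, 20.0)),
        dur_ref=float(dur_ref),
    )


def pc_intensity(
    params: dict,
    pv: float,
    duration: float,
    t_ms: np.ndarray,
    pv_coding_gain: float = 0.0,
    duration_coding_gain: float = 0.0,
) -> np.ndarray:
    """Per-trial PC simple-spike intensity.

    The modulation extremum magnitude is linear in PV and all temporal
    parameters scale with saccade duration (extremum time shifts linearly
    with duration).  ``pv_coding_gain`` transiently amplifies the PV slope
    (post-outward-CS state); ``duration_coding_gain`` amplifies the
    sensitivity of the response time scale to duration (post-inward-CS
    state): the effective time scale is duration*(duration/dur_ref)^gain.
    """
    b = params["baseline"]
    slope = params["pv_slope"] * (1.0 + pv_coding_gain)
    amp = params["mod_at_500"] + slope * (pv - 500.0)
    nd = duration * (duration / params["dur_ref"]) ** duration_coding_gain
    t1 = params["t_frac"] * nd
    sd = params["sd_frac"] * nd
    klass = params["klass"]
    if klass == "burst":
        lam = b + amp * np.exp(-0.5 * ((t_ms - t1) / sd) ** 2)
    elif klass == "pause":
        lam = b - amp * np.exp(-0.5 * ((t_ms - t1) / sd) ** 2)
    else:
        # biphasic lobes straddle the extremum time (zero crossing near t1),
        # giving the quadrature temporal structure of real PC populations
        half = params["gap_frac"] * nd / 2.0
        ga = np.exp(-0.5 * ((t_ms - (t1 - half)) / sd) ** 2)
        gb = np.exp(-0.5 * ((t_ms - (t1 + half)) / sd) ** 2)
        r = params["biphasic_ratio"]
        if klass == "burst-pause":
            lam = b + amp * ga - r * amp * gb
        else:
            lam = b - amp * ga + r * amp * gb
    return np.maximum(lam, 0.0)


def generate_pc_unit(
    klass: str,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    unit_id: str,
    cfg: SessionConfig,
    grid: np.ndarray,
    cs_on: str | None = None,
) -> tuple[UnitRecording, dict]:
    """Generate one PC's simple spikes and complex spikes for all trials.

    CS events fall in the [50,140) ms post-saccadic window with probability
    ``p_cs_on`` when the trial's error direction matches ``cs_on`` and
    ``p_cs_off`` otherwise (plus a small untuned late-window rate); SS
    intensity is suppressed for 10-20 ms after each CS.
    """
    if cfg.p_cs_on <= cfg.p_cs_off:
        raise ValueError("p_cs_on must exceed p_cs_off")
    dur_ref = cfg.target_eccentricity / (TRADEOFF_RATIO * cfg.pv_start) * 1000.0
    params = _draw_pc_params(klass, rng, dur_ref)
    if cs_on is None:
        cs_on = "right" if rng.uniform() < 0.5 else "left"
    params["cs_on"] = cs_on
    q = cfg.cf_event_prob
    # per-PC CS probability given a matching shared CF event, chosen so the
    # conditional marginals P(CS | error matches CS-ON) = p_cs_on and
    # P(CS | otherwise) = p_cs_off hold exactly
    c_hi = (cfg.p_cs_on - (1.0 - q) * cfg.p_cs_off) / q if q > 0 else cfg.p_cs_on
    if not 0.0 <= c_hi <= 1.0:
        raise ValueError(
            f"cf_event_prob={q} incompatible with p_cs_on/p_cs_off "
            f"(implied per-event CS probability {c_hi:.2f})"
        )
    has_cf = "cf_event" in trials.columns
    has_flags = "post_outward_event" in trials.columns
    spikes, cs_lists = [], []
    for tr in trials.itertuples(index=False):
        dur = tr.duration_ms
        lam = pc_intensity(
            params,
            tr.pv,
            dur,
            grid,
            pv_coding_gain=(
                cfg.contingent_pv_coding_gain
                if has_flags and tr.post_outward_event else 0.0
            ),
            duration_coding_gain=(
                cfg.contingent_duration_coding_gain
                if has_flags and tr.post_inward_event else 0.0
            ),
        )
        cs_rel = []  # times relative to saccade offset
        if q > 0 and has_cf:
            p = c_hi if tr.cf_event == cs_on else cfg.p_cs_off
        else:  # no shared-event bookkeeping: draw at the marginal rates
            p = cfg.p_cs_on if tr.error_direction == cs_on else cfg.p_cs_off
        if rng.uniform() < p:
            cs_rel.append(float(rng.uniform(50.0, 140.0)))
        if cfg.p_cs_late > 0 and rng.uniform() < cfg.p_cs_late:
            cs_rel.append(float(rng.uniform(140.0, 250.0)))
        for c in cs_rel:
            t_cs = dur + c  # relative to saccade onset
            lam[(grid >= t_cs) & (grid < t_cs + params["cs_suppression_ms"])] = 0.0
        spikes.append(sample_spikes(lam, grid, rng))
        cs_lists.append(np.array(sorted(cs_rel)))
    rec = UnitRecording(
        unit_id=unit_id,
        kind="PC",
        trial_index=trials["trial_index"].to_numpy(),
        spikes=spikes,
        cs_times=cs_lists,
        class_label=klass,
        cs_on_direction=cs_on,
    )
    return rec, params


# ----------------------------------------------------------------------
# full sessions
# ----------------------------------------------------------------------

def _build_traces(cfg: SessionConfig, kin: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    """1-kHz position/velocity traces per trial plus onset/target columns."""
    n_samp = int(cfg.trace_len_ms)
    onset = int(round(cfg.saccade_onset_ms))
    sign = {"right": 1.0, "left": -1.0}
    traces = {}
    pos0 = 0.0
    extra = []
    for _, tr in kin.iterrows():
        d = sign[tr["direction"]]
        prof = velocity_profile(
            tr["pv"], tr["duration_ms"], tr["amplitude"], cfg.sample_rate
        )
        v = np.zeros(n_samp)
        m = min(prof.size, n_samp - onset)
        v[onset : onset + m] = d * prof[:m]
        pos = pos0 + np.cumsum(v) / cfg.sample_rate
        traces[int(tr["trial_index"])] = {"position": pos, "velocity": v}
        extra.append(
            dict(
                trial_index=int(tr["trial_index"]),
                onset_ms=float(onset),
                offset_ms=float(onset + tr["duration_ms"]),
                start_position=pos0,
                target_position=pos0 + d * cfg.target_eccentricity,
                end_position=float(pos[-1]),
            )
        )
        pos0 = float(pos[-1])
    return traces, kin.merge(pd.DataFrame(extra), on="trial_index")


def generate_session(
    cfg: SessionConfig, config: RunConfig = DEFAULT_CONFIG, with_traces: bool = True
) -> tuple[SessionBundle, list[UnitRecording], GroundTruth]:
    """Generate a full synthetic session bundle with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    kin = generate_kinematics_sequence(cfg, rng)
    if with_traces:
        traces, trials = _build_traces(cfg, kin)
    else:
        traces, trials = {}, kin.copy()
        trials["onset_ms"] = cfg.saccade_onset_ms
        trials["offset_ms"] = cfg.saccade_onset_ms + trials["duration_ms"]

    grid = np.arange(config.mf_grid_start_ms, config.mf_grid_stop_ms + config.bin_ms,
                     config.bin_ms)
    units: list[UnitRecording] = []
    unit_params, unit_classes, cs_dirs = {}, {}, {}
    mf_plan = [("BT", cfg.n_mf_bt), ("LLB", cfg.n_mf_llb), ("SLB", cfg.n_mf_slb)]
    k = 0
    for klass, count in mf_plan:
        for _ in range(count):
            uid = f"mf{k:03d}"
            rec, params = generate_mf_unit(klass, trials, rng, uid, cfg, grid)
            units.append(rec)
            unit_params[uid] = params
            unit_classes[uid] = klass
            k += 1
    pc_plan = [
        ("burst", cfg.n_pc_burst),
        ("pause", cfg.n_pc_pause),
        ("burst-pause", cfg.n_pc_burst_pause),
        ("pause-burst", cfg.n_pc_pause_burst),
    ]
    k = 0
    for klass, count in pc_plan:
        for _ in range(count):
            uid = f"pc{k:03d}"
            rec, params = generate_pc_unit(klass, trials, rng, uid, cfg, grid)
            units.append(rec)
            unit_params[uid] = params
            unit_classes[uid] = klass
            cs_dirs[uid] = rec.cs_on_direction
            k += 1

    truth = GroundTruth(
        config=asdict(cfg),
        trial_latents=dict(
            pv=kin["pv_latent"].tolist(), duration=kin["duration_latent"].tolist()
        ),
        unit_params=unit_params,
        unit_classes=unit_classes,
        cs_on_directions=cs_dirs,
    )

    events = []
    for rec in units:
        for ti, sp in zip(rec.trial_index, rec.spikes):
            kind = "SS" if rec.kind == "PC" else "MF"
            for t in sp:
                events.append((rec.unit_id, kind, int(ti), float(t)))
        if rec.cs_times is not None:
            for ti, cs in zip(rec.trial_index, rec.cs_times):
                for t in cs:
                    events.append((rec.unit_id, "CS", int(ti), float(t)))
    events_df = pd.DataFrame(
        events, columns=["unit_id", "event_kind", "trial_index", "time_ms"]
    )
    units_df = pd.DataFrame(
        [
            dict(
                unit_id=r.unit_id,
                kind=r.kind,
                class_label=r.class_label or "",
                cs_on_direction=r.cs_on_direction or "",
            )
            for r in units
        ]
    )
    bundle = SessionBundle(
        trials=trials,
        events=events_df,
        units=units_df,
        traces=traces,
        ground_truth=truth.to_dict(),
        manifest=dict(
            format_version=1,
            seed=int(cfg.seed),
            config_hash=config.config_hash(),
        ),
    )
    return bundle, units, truth
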