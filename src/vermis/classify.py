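"""Peri-event rates and MF / PC-SS response classification.

Mossy fibers are labeled burst-tonic (BT), long-lead burst (LLB) or
short-lead burst (SLB) from unsmoothed trial-averaged rates: BT by a
post- minus pre-saccadic rate step exceeding 1.5x the pre-saccadic SD with
statistically indistinguishable pre/post regression slopes; the phasic
classes by whether the burst-modulation onset (first crossing of 3x the
baseline SD) leads saccade onset by more or less than 15 ms.

Purkinje-cell simple-spike responses (Gaussian-smoothed, SD 5 ms) are
labeled burst / pause / burst-pause / pause-burst from significant local
extrema (minimum peak distance 10 ms, minimum topographic prominence
2 spikes/s, significance +-5x baseline SD) in the peri-saccadic window,
then refined by a PCA(2) + LDA classifier trained on the threshold labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .config import RunConfig, DEFAULT_CONFIG

__all__ = [
    "PeriEventRate",
    "perievent_rate",
    "gaussian_smooth",
    "find_local_extrema",
    "classify_mf_unit",
    "detect_modulation_bounds",
    "label_pc_by_threshold",
    "SimpleSpikeClassifier",
    "classify_pc_pca_lda",
]


@dataclass
class PeriEventRate:
    """Trial-binned firing rates on a uniform peri-event grid."""

    time_ms: np.ndarray          # bin centers
    mean_rate: np.ndarray        # spikes/s, averaged over trials
    per_trial: np.ndarray        # (n_trials, T)
    smoothing_sd_ms: float = 0.0

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.time_ms >= lo) & (self.time_ms < hi)


def gaussian_smooth(rates: np.ndarray, sd_ms: float, bin_ms: float) -> np.ndarray:
    """Convolve along the last axis with a normalized Gaussian kernel."""
    from scipy.ndimage import convolve1d

    if sd_ms <= 0:
        return rates
    sd = sd_ms / bin_ms
    half = int(np.ceil(4 * sd))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sd) ** 2)
    kernel /= kernel.sum()
    return convolve1d(np.asarray(rates, float), kernel, axis=-1, mode="constant")


def perievent_rate(
    spike_trains: list,
    start_ms: float,
    stop_ms: float,
    bin_ms: float = 1.0,
    smoothing_sd_ms: float = 0.0,
) -> PeriEventRate:
    """Binned spike counts -> spikes/s, optional Gaussian smoothing, mean.

    ``spike_trains`` holds one array of aligned event times (ms) per trial.
    """
    if len(spike_trains) == 0:
        raise ValueError("need at least one trial")
    edges = np.arange(start_ms, stop_ms + bin_ms, bin_ms)
    centers = edges[:-1] + bin_ms / 2.0
    per_trial = np.stack(
        [np.histogram(np.asarray(sp, float), bins=edges)[0] for sp in spike_trains]
    ).astype(float) / (bin_ms / 1000.0)
    per_trial = gaussian_smooth(per_trial, smoothing_sd_ms, bin_ms)
    return PeriEventRate(
        time_ms=centers,
        mean_rate=per_trial.mean(axis=0),
        per_trial=per_trial,
        smoothing_sd_ms=smoothing_sd_ms,
    )


# ----------------------------------------------------------------------
# local extrema with distance / prominence semantics
# ----------------------------------------------------------------------

def find_local_extrema(
    y: np.ndarray,
    min_distance: int = 1,
    min_prominence: float = 0.0,
    kind: str = "max",
) -> np.ndarray:
    """Indices of local maxima (or minima) filtered by topographic
    prominence and a minimum separation; higher extrema win ties."""
    y = np.asarray(y, float)
    if kind == "min":
        return find_local_extrema(-y, min_distance, min_prominence, "max")
    cand = [
        i
        for i in range(1, y.size - 1)
        if y[i] >= y[i - 1] and y[i] >= y[i + 1] and (y[i] > y[i - 1] or y[i] > y[i + 1])
    ]
    peaks = []
    for i in cand:
        # topographic prominence: lowest saddle toward the nearest higher point
        left = y[: i + 1]
        higher = np.flatnonzero(left[:-1] > y[i])
        lo_l = left[higher[-1] :].min() if higher.size else left.min()
        right = y[i:]
        higher = np.flatnonzero(right[1:] > y[i])
        lo_r = right[: higher[0] + 2].min() if higher.size else right.min()
        prom = y[i] - max(lo_l, lo_r)
        if prom >= min_prominence:
            peaks.append((i, y[i]))
    peaks.sort(key=lambda p: -p[1])
    kept: list[int] = []
    for i, _ in peaks:
        if all(abs(i - j) >= min_distance for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


# ----------------------------------------------------------------------
# mossy-fiber classification
# ----------------------------------------------------------------------

def _sustained_crossing(mask: np.ndarray, n_consecutive: int) -> int | None:
    """First index opening a run of >= n_consecutive True values."""
    if n_consecutive <= 1:
        hits = np.flatnonzero(mask)
        return int(hits[0]) if hits.size else None
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= n_consecutive:
            return i - n_consecutive + 1
    return None


def _slopes_differ(t: np.ndarray, y_pre: np.ndarray, t_post: np.ndarray,
                   y_post: np.ndarray) -> bool:
    """True when the 95% CIs of the two regression slopes do not overlap."""
    r1 = sps.linregress(t, y_pre)
    r2 = sps.linregress(t_post, y_post)
    ci1 = (r1.slope - 1.96 * r1.stderr, r1.slope + 1.96 * r1.stderr)
    ci2 = (r2.slope - 1.96 * r2.stderr, r2.slope + 1.96 * r2.stderr)
    return ci1[1] < ci2[0] or ci2[1] < ci1[0]


def classify_mf_unit(
    rate: PeriEventRate, config: RunConfig = DEFAULT_CONFIG
) -> str:
    """Label an unsmoothed MF response as BT, LLB, SLB or unclassified.

    All criteria are relative to within-response baselines, so the label is
    invariant to adding a constant to the rate.
    """
    t, r = rate.time_ms, rate.mean_rate
    for lo, hi in (config.bt_pre_window, config.bt_post_window, config.mf_baseline_window):
        if not rate.window_mask(lo, hi).any():
            raise ValueError(f"rate grid does not cover window [{lo}, {hi}) ms")
    pre = rate.window_mask(*config.bt_pre_window)
    post = rate.window_mask(*config.bt_post_window)
    if (r[post].mean() - r[pre].mean()) > config.bt_sd_factor * r[pre].std(ddof=0):
        if not _slopes_differ(t[pre], r[pre], t[post], r[post]):
            return "BT"
    base = rate.window_mask(*config.mf_baseline_window)
    thresh = r[base].mean() + config.onset_sd_factor * r[base].std(ddof=0)
    search = t >= config.mf_baseline_window[1]
    crossing = _sustained_crossing(
        (r >= thresh) & search, config.onset_consecutive_bins
    )
    if crossing is None:
        return "unclassified"
    onset = t[crossing]
    lead = -onset
    if lead > config.lead_threshold_ms:
        return "LLB"
    if lead >= 0:
        return "SLB"
    return "unclassified"


def detect_modulation_bounds(
    rate: PeriEventRate,
    saccade_end_ms: float,
    config: RunConfig = DEFAULT_CONFIG,
) -> tuple[float, float] | None:
    """Burst modulation (onset, offset) in ms, or None if no modulation.

    Onset: first up-crossing of mean + 3 SD of the pre-saccadic baseline.
    Offset: first post-peak drop below mean + 3 SD of the post-saccadic
    baseline (200-400 ms after saccade end).
    """
    t, r = rate.time_ms, rate.mean_rate
    base_pre = rate.window_mask(*config.mf_baseline_window)
    lo = saccade_end_ms + config.mf_post_baseline_from_offset[0]
    hi = saccade_end_ms + config.mf_post_baseline_from_offset[1]
    base_post = rate.window_mask(lo, hi)
    if not base_pre.any() or not base_post.any():
        raise ValueError("rate grid does not cover the baseline windows")
    thr_on = r[base_pre].mean() + config.onset_sd_factor * r[base_pre].std(ddof=0)
    thr_off = r[base_post].mean() + config.onset_sd_factor * r[base_post].std(ddof=0)
    search = t >= config.mf_baseline_window[1]
    onset_idx = _sustained_crossing((r >= thr_on) & search,
                                    config.onset_consecutive_bins)
    if onset_idx is None:
        return None
    peak_idx = onset_idx + int(np.argmax(r[onset_idx:]))
    down = _sustained_crossing(r[peak_idx:] < thr_off,
                               config.onset_consecutive_bins)
    if down is None:
        return None
    return float(t[onset_idx]), float(t[peak_idx + down])


# ----------------------------------------------------------------------
# Purkinje-cell simple-spike classification
# ----------------------------------------------------------------------

def label_pc_by_threshold(
    rate: PeriEventRate,
    saccade_end_ms: float,
    config: RunConfig = DEFAULT_CONFIG,
) -> str:
    """Threshold label for a smoothed SS response.

    Significant local extrema (distance >= 10 ms, prominence >= 2 sp/s,
    beyond +-5 SD of the [-250,-100] ms baseline) in the peri-saccadic
    window (-50 to +150 ms from saccade end) determine the polarity
    sequence: burst / pause / burst-pause / pause-burst, else unlabeled.
    """
    t, r = rate.time_ms, rate.mean_rate
    base = rate.window_mask(*config.pc_baseline_window)
    mu, sd = r[base].mean(), r[base].std(ddof=0)
    lo = saccade_end_ms + config.pc_peri_window_from_offset[0]
    hi = saccade_end_ms + config.pc_peri_window_from_offset[1]
    peri = rate.window_mask(lo, hi)
    if not peri.any():
        raise ValueError("rate grid does not cover the peri-saccadic window")
    seg = r[peri]
    bin_ms = float(np.median(np.diff(t)))
    dist = int(round(config.peak_min_distance_ms / bin_ms))
    maxima = find_local_extrema(seg, dist, config.peak_min_prominence, "max")
    minima = find_local_extrema(seg, dist, config.peak_min_prominence, "min")
    ups = [i for i in maxima if seg[i] > mu + config.pc_sd_factor * sd]
    downs = [i for i in minima if seg[i] < mu - config.pc_sd_factor * sd]
    if ups and not downs:
        return "burst"
    if downs and not ups:
        return "pause"
    if ups and downs:
        return "burst-pause" if min(ups) < min(downs) else "pause-burst"
    return "unlabeled"


class SimpleSpikeClassifier(BaseEstimator, ClassifierMixin):
    """PCA(2) + LDA classifier over SS response wave forms.

    Trained on threshold-rule labels; assigns every response (including
    threshold-unlabeled ones) to one of the four categories and exposes
    the LDA decision boundaries in PC space.
    """

    def __init__(self, n_components: int = 2, min_per_class: int = 4):
        self.n_components = n_components
        self.min_per_class = min_per_class

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be (n_responses, n_timepoints)")
        classes, counts = np.unique(y, return_counts=True)
        if (counts < self.min_per_class).any():
            lacking = classes[counts < self.min_per_class]
            raise ValueError(
                f"need >= {self.min_per_class} labeled responses per class; "
                f"short: {list(lacking)}"
            )
        self.pca_ = PCA(n_components=self.n_components).fit(X)
        # deterministic sign convention: largest-|loading| coordinate positive
        comps = self.pca_.components_
        flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
        self.pca_.components_ = comps * flip[:, None]
        scores = self.pca_.transform(X)
        if np.linalg.matrix_rank(np.cov(scores.T)) < self.n_components:
            raise np.linalg.LinAlgError(
                "degenerate covariance of PCA scores; add responses or use "
                "LDA shrinkage regularization"
            )
        self.lda_ = LinearDiscriminantAnalysis().fit(scores, y)
        self.classes_ = self.lda_.classes_
        self.scores_ = scores
        return self

    def transform(self, X):
        check_is_fitted(self, "pca_")
        return self.pca_.transform(np.asarray(X, float))

    def predict(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict(self.transform(X))

    def decision_boundaries(self) -> dict:
        """LDA linear decision functions in PC space (w.x + b per class)."""
        check_is_fitted(self, "lda_")
        return {
            str(c): dict(weights=w.tolist(), bias=float(b))
            for c, w, b in zip(self.classes_, self.lda_.coef_, self.lda_.intercept_)
        }


def classify_pc_pca_lda(responses: np.ndarray, labels: np.ndarray):
    """Fit the PCA+LDA classifier and assign every response a category."""
    responses = np.asarray(responses, float)
    labels = np.asarray(labels)
    train = labels != "unlabeled"
    clf = SimpleSpikeClassifier().fit(responses[train], labels[train])
    return clf.predict(responses), clf
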