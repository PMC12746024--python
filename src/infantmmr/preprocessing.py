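"""Continuous-to-epochs preprocessing.

Fixed stage order: resample to 1000 Hz -> bad-channel detection -> zero-phase
1-18 Hz Butterworth filtering of the continuous data -> epoching (-200..+799
ms) -> artifact rejection (+-150 uV, >50 uV step, kurtosis >5 SD) -> resample
to 250 Hz -> baseline correction -> 95%-variance spatial PCA -> re-baseline.
Filtering happens on continuous data, before epoching, to avoid edge
artifacts on short segments.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.stats import kurtosis as _kurtosis

from .config import Config, default_config
from .containers import ContinuousRecording, EpochSet, EventSequence

logger = logging.getLogger(__name__)

__all__ = [
    "resample_recording", "bandpass_filter", "detect_bad_channels",
    "segment_epochs", "reject_artifacts", "apply_manual_rejection",
    "resample_epochs", "baseline_correct", "spatial_pca_denoise", "preprocess",
]


def resample_recording(rec: ContinuousRecording, target_rate: float) -> ContinuousRecording:
    """Polyphase resampling of continuous data to a standard rate."""
    if target_rate == rec.sampling_rate:
        return rec
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return ContinuousRecording(data, target_rate, rec.montage, dict(rec.metadata))


def bandpass_filter(rec: ContinuousRecording, low: float, high: float,
                    order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth bandpass (forward-backward, so no phase shift)."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate,
                        output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return ContinuousRecording(data, rec.sampling_rate, rec.montage, dict(rec.metadata))


def detect_bad_channels(rec: ContinuousRecording, flat_tol_uv: float = 1e-3,
                        z_var_thresh: float = 3.0) -> list[str]:
    """Signal-based bad-channel proxies: flat channels (variance below
    flat_tol^2) and excessively noisy channels (log-variance z-score above
    threshold AND variance at least 4x the channel median -- the absolute
    floor keeps a homogeneous montage, where the z spread is tiny, from
    flagging the channel that happens to carry the most evoked signal).

    Raises if more than a third of channels are flagged (recording unusable).
    """
    if rec.montage.n_channels < 4:
        raise ValueError("bad-channel detection needs at least 4 channels")
    var = rec.data.var(axis=1)
    flat = var < flat_tol_uv ** 2
    logv = np.log(np.where(flat, np.nan, var))
    ok = ~np.isnan(logv)
    z = np.zeros_like(logv)
    if ok.sum() >= 2 and np.nanstd(logv[ok], ddof=1) > 0:
        z[ok] = (logv[ok] - logv[ok].mean()) / logv[ok].std(ddof=1)
    noisy = (z > z_var_thresh) & (var > 4.0 * np.median(var[ok]))
    bad = [name for name, f, nz in zip(rec.montage.channel_names, flat, noisy) if f or nz]
    if len(bad) > rec.montage.n_channels / 3:
        raise ValueError(f"{len(bad)} of {rec.montage.n_channels} channels bad "
                         f"({bad}); recording unusable")
    return bad


def drop_channels(rec: ContinuousRecording, bad: list[str]) -> ContinuousRecording:
    keep = [c for c in rec.montage.channel_names if c not in set(bad)]
    idx = [rec.montage.index(c) for c in keep]
    return ContinuousRecording(rec.data[idx], rec.sampling_rate,
                               rec.montage.subset(keep), dict(rec.metadata))


def segment_epochs(rec: ContinuousRecording, events: EventSequence,
                   window_ms: tuple[float, float] = (-200.0, 799.0)) -> EpochSet:
    """One epoch per event whose full window fits in the recording; events
    with an out-of-bounds window are dropped (and counted in the log)."""
    fs = rec.sampling_rate
    start_off = int(round(window_ms[0] * fs / 1000.0))
    n_t = int(round((window_ms[1] - window_ms[0] + 1) * fs / 1000.0))
    starts = events.onsets + start_off
    in_bounds = (starts >= 0) & (starts + n_t <= rec.n_samples)
    n_dropped = int((~in_bounds).sum())
    if n_dropped:
        logger.warning("dropped %d events with out-of-bounds epoch windows", n_dropped)
    if not in_bounds.any():
        raise ValueError("no epochs extractable: all event windows out of bounds")
    starts = starts[in_bounds]
    data = np.stack([rec.data[:, s:s + n_t] for s in starts])
    return EpochSet(
        data=data, window_ms=window_ms, sampling_rate=fs,
        trial_labels=events.labels[in_bounds],
        trial_onsets=events.onsets[in_bounds],
        channel_names=rec.montage.channel_names,
    )


def reject_artifacts(epochs: EpochSet, volt_thresh: float = 150.0,
                     step_thresh: float = 50.0, kurt_sd: float = 5.0) -> EpochSet:
    """Flag trials where ANY channel shows an extreme voltage, a step between
    consecutive samples, or outlying sample kurtosis.

    The kurtosis rule z-scores each trial/channel's excess kurtosis against
    the distribution over all trials of that channel and flags |z| > kurt_sd.
    Reason codes record the first violated rule in the order voltage, step,
    kurtosis.  Data are untouched; only the mask changes.
    """
    x = epochs.data
    volt_bad = np.abs(x).max(axis=(1, 2)) > volt_thresh
    step_bad = np.abs(np.diff(x, axis=2)).max(axis=(1, 2)) > step_thresh
    kurt = _kurtosis(x, axis=2, fisher=True, bias=True)  # trials x channels
    mu = kurt.mean(axis=0, keepdims=True)
    sd = kurt.std(axis=0, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (kurt - mu) / sd, 0.0)
    kurt_bad = np.abs(z).max(axis=1) > kurt_sd
    mask = volt_bad | step_bad | kurt_bad
    if mask.all():
        raise ValueError(
            "all trials rejected (voltage=%d, step=%d, kurtosis=%d)"
            % (volt_bad.sum(), step_bad.sum(), kurt_bad.sum())
        )
    reason = np.array([""] * epochs.n_trials, dtype=object)
    reason[kurt_bad] = "kurtosis"
    reason[step_bad] = "step"
    reason[volt_bad] = "voltage"
    # preserve pre-existing rejections (e.g. manual)
    reason[epochs.rejection_mask] = epochs.rejection_reason[epochs.rejection_mask]
    mask = mask | epochs.rejection_mask
    return epochs.copy_with(rejection_mask=mask, rejection_reason=reason)


def apply_manual_rejection(epochs: EpochSet, trial_indices) -> EpochSet:
    """Reject a user-supplied list of trial indices (reason code 'manual')."""
    mask = epochs.rejection_mask.copy()
    reason = epochs.rejection_reason.copy()
    for i in np.asarray(trial_indices, dtype=int):
        if not mask[i]:
            mask[i] = True
            reason[i] = "manual"
    return epochs.copy_with(rejection_mask=mask, rejection_reason=reason)


def resample_epochs(epochs: EpochSet, target_rate: float) -> EpochSet:
    """Polyphase downsampling of epoched data; window endpoints preserved.

    The signal is already low-passed well below the new Nyquist frequency, so
    no additional anti-alias filtering is needed.
    """
    if target_rate > epochs.sampling_rate:
        raise ValueError("target rate must not exceed the source rate")
    if target_rate == epochs.sampling_rate:
        return epochs
    frac = Fraction(target_rate / epochs.sampling_rate).limit_denominator(1000)
    data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator, axis=2)
    return epochs.copy_with(data=data, sampling_rate=target_rate)


def _baseline_indices(epochs: EpochSet, baseline_ms: tuple[float, float]) -> np.ndarray:
    t = epochs.times_ms
    idx = np.flatnonzero((t >= baseline_ms[0]) & (t <= baseline_ms[1]))
    if idx.size == 0:
        raise ValueError(f"baseline {baseline_ms} outside epoch window")
    return idx


def baseline_correct(epochs: EpochSet,
                     baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract each trial/channel's mean over the pre-stimulus interval."""
    idx = _baseline_indices(epochs, baseline_ms)
    means = epochs.data[:, :, idx].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - means)


def spatial_pca_denoise(epochs: EpochSet, var_retained: float = 0.95,
                        baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Spatial PCA noise reduction.

    Each channel is z-scored over all retained trials x time, the channel
    covariance is eigendecomposed, the smallest leading set of components
    reaching ``var_retained`` cumulative variance is kept, data are projected
    onto that subspace and back, the z-scoring is undone, and baseline
    correction is re-applied.
    """
    if not 0 < var_retained <= 1:
        raise ValueError("var_retained must be in (0, 1]")
    retained = epochs.retained_indices
    if retained.size == 0:
        raise ValueError("no retained trials to fit the PCA on")
    n_tr, n_ch, n_t = epochs.data.shape
    if n_ch < 2:
        raise ValueError("spatial PCA needs at least 2 channels")
    fit = epochs.data[retained].transpose(1, 0, 2).reshape(n_ch, -1)
    mu = fit.mean(axis=1, keepdims=True)
    sd = fit.std(axis=1, keepdims=True)
    if np.all(sd == 0):
        raise ValueError("channel covariance has rank 0")
    sd = np.where(sd == 0, 1.0, sd)
    z = (fit - mu) / sd
    cov = z @ z.T / z.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    cum = np.cumsum(np.clip(evals, 0, None))
    total = cum[-1]
    if total <= 0:
        raise ValueError("channel covariance has rank 0")
    k = int(np.searchsorted(cum / total, var_retained - 1e-12) + 1)
    proj = evecs[:, :k] @ evecs[:, :k].T
    flat = epochs.data.transpose(1, 0, 2).reshape(n_ch, -1)
    zs = (flat - mu) / sd
    recon = (proj @ zs) * sd + mu
    data = recon.reshape(n_ch, n_tr, n_t).transpose(1, 0, 2)
    out = epochs.copy_with(data=data)
    return baseline_correct(out, baseline_ms)


def preprocess(rec: ContinuousRecording, events: EventSequence,
               config: Config | None = None) -> EpochSet:
    """Run the full fixed-order preprocessing chain on one recording."""
    cfg = config or default_config()
    if rec.sampling_rate != cfg.resample.intermediate_rate_hz:
        ratio = cfg.resample.intermediate_rate_hz / rec.sampling_rate
        events = EventSequence(np.round(events.onsets * ratio).astype(int),
                               events.labels)
        rec = resample_recording(rec, cfg.resample.intermediate_rate_hz)
    bad = detect_bad_channels(rec, cfg.reject.flat_tol_uv, cfg.reject.z_var_thresh)
    if bad:
        logger.warning("dropping bad channels: %s", bad)
        rec = drop_channels(rec, bad)
    rec = bandpass_filter(rec, cfg.filter.low_hz, cfg.filter.high_hz, cfg.filter.order)
    epochs = segment_epochs(rec, events, (cfg.epoch.tmin_ms, cfg.epoch.tmax_ms))
    epochs = reject_artifacts(epochs, cfg.reject.volt_thresh_uv,
                              cfg.reject.step_thresh_uv, cfg.reject.kurt_sd)
    epochs = resample_epochs(epochs, cfg.resample.target_rate_hz)
    epochs = baseline_correct(epochs, cfg.epoch.baseline_ms)
    epochs = spatial_pca_denoise(epochs, cfg.pca.var_retained, cfg.epoch.baseline_ms)
    return epochs
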