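"""Vertex-montage construction and constrained ERP peak picking.

Components are measured on a derived vertex channel, mean(Fz, Cz) re-
referenced to the linked mastoids mean(M1, M2).  Within each component's
search window, candidate local extrema of the required polarity are thinned
under an 80 ms minimum-distance rule (the larger-prominence candidate
survives) and the winner maximizes prominence x SNR, where SNR is the
candidate amplitude magnitude over the pre-stimulus baseline SD.  Ties break
to the earliest latency.  The infant MMR may be positive or negative, so its
search runs both polarities and keeps the sign of the winner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import COMPONENT_WINDOWS, Config, default_config
from .erp import ErpEstimate, MmrSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PeakMeasurement", "make_vertex_waveform", "vertex_series",
    "detect_component_peak", "measure_all_components",
]

_VERTEX = ("Fz", "Cz")
_MASTOIDS = ("M1", "M2")


@dataclass
class PeakMeasurement:
    """One picked component peak (or an explicit not-found record)."""

    component: str
    waveform_kind: str  # standard | deviant | difference
    latency_ms: float
    amplitude_uv: float
    prominence: float
    snr: float
    found: bool

    @classmethod
    def not_found(cls, component: str, waveform_kind: str) -> "PeakMeasurement":
        nan = float("nan")
        return cls(component, waveform_kind, nan, nan, nan, nan, False)


def vertex_series(data: np.ndarray, channel_names: tuple[str, ...]) -> np.ndarray:
    """mean(Fz, Cz) - mean(M1, M2) along the channel axis (axis -2)."""
    names = list(channel_names)
    missing = [c for c in _VERTEX + _MASTOIDS if c not in names]
    if missing:
        raise ValueError(
            f"vertex montage needs channels {missing} which were dropped as bad; "
            "re-run preprocessing without dropping them or skip this subject"
        )
    data = np.asarray(data, float)
    v = data[..., [names.index(c) for c in _VERTEX], :].mean(axis=-2)
    m = data[..., [names.index(c) for c in _MASTOIDS], :].mean(axis=-2)
    return v - m


def make_vertex_waveform(est: ErpEstimate | MmrSeries) -> np.ndarray:
    """Vertex time series from an ERP estimate or MMR difference waveform."""
    wave = est.mean if isinstance(est, ErpEstimate) else est.difference
    return vertex_series(wave, est.channel_names)


def _local_extrema(x: np.ndarray) -> np.ndarray:
    """Strict interior local maxima (plateau midpoints included)."""
    peaks, _ = signal.find_peaks(x)
    return peaks


def _thin_candidates(cand_idx: np.ndarray, prominences: np.ndarray,
                     times_ms: np.ndarray, min_dist_ms: float) -> list[int]:
    """Greedy minimum-distance thinning: visit candidates in decreasing
    prominence (earlier latency wins prominence ties) and keep each one that
    is at least min_dist_ms from every already-kept candidate."""
    order = sorted(range(len(cand_idx)),
                   key=lambda i: (-prominences[i], times_ms[cand_idx[i]]))
    kept: list[int] = []
    for i in order:
        t = times_ms[cand_idx[i]]
        if all(abs(t - times_ms[cand_idx[j]]) >= min_dist_ms for j in kept):
            kept.append(i)
    return kept


def detect_component_peak(
    wave: np.ndarray,
    times_ms: np.ndarray,
    component: str,
    window_ms: tuple[float, float],
    polarity: int,
    min_dist_ms: float = 80.0,
    noise_window_ms: tuple[float, float] = (-200.0, 0.0),
    waveform_kind: str = "standard",
) -> PeakMeasurement:
    """Pick the most robust deflection of the given polarity in the window.

    A candidate is a local extremum of ``polarity * wave`` whose amplitude has
    the required sign.  ``found=False`` (not an error) when no candidate
    exists, e.g. on a monotone segment.
    """
    wave = np.asarray(wave, float)
    times_ms = np.asarray(times_ms, float)
    flipped = polarity * wave
    peaks = _local_extrema(flipped)
    in_win = peaks[(times_ms[peaks] >= window_ms[0])
                   & (times_ms[peaks] <= window_ms[1])
                   & (flipped[peaks] >= 0)]
    if in_win.size == 0:
        return PeakMeasurement.not_found(component, waveform_kind)
    prom = signal.peak_prominences(flipped, in_win)[0]
    base_mask = (times_ms >= noise_window_ms[0]) & (times_ms <= noise_window_ms[1])
    noise_sd = wave[base_mask].std()
    kept = _thin_candidates(in_win, prom, times_ms, min_dist_ms)
    best, best_score, best_t = None, -np.inf, np.inf
    for i in kept:
        amp = abs(wave[in_win[i]])
        snr = amp / noise_sd if noise_sd > 0 else np.inf
        score = prom[i] * snr
        t = times_ms[in_win[i]]
        if score > best_score or (score == best_score and t < best_t):
            best, best_score, best_t = i, score, t
    idx = in_win[best]
    snr = abs(wave[idx]) / noise_sd if noise_sd > 0 else np.inf
    return PeakMeasurement(
        component=component, waveform_kind=waveform_kind,
        latency_ms=float(times_ms[idx]), amplitude_uv=float(wave[idx]),
        prominence=float(prom[best]), snr=float(snr), found=True,
    )


_COMPONENT_POLARITY = {"P1": +1, "N1": -1, "P2": +1}


def measure_all_components(
    std_est: ErpEstimate,
    dev_est: ErpEstimate,
    mmr: MmrSeries,
    config: Config | None = None,
) -> pd.DataFrame:
    """Seven peak rows: P1/N1/P2 on standard and deviant vertex waveforms,
    plus the MMR peak (either polarity) on the difference waveform."""
    cfg = config or default_config()
    windows = {k: tuple(v) for k, v in cfg.peaks.windows.items()}
    min_dist = cfg.peaks.min_distance_ms
    baseline = cfg.epoch.baseline_ms
    rows: list[PeakMeasurement] = []
    for kind, est in (("standard", std_est), ("deviant", dev_est)):
        wave = make_vertex_waveform(est)
        t = est.times_ms
        for comp, pol in _COMPONENT_POLARITY.items():
            rows.append(detect_component_peak(
                wave, t, comp, windows.get(comp, COMPONENT_WINDOWS[comp]), pol,
                min_dist, baseline, waveform_kind=kind))
    mmr_wave = make_vertex_waveform(mmr)
    t = mmr.times_ms
    win = windows.get("MMR", COMPONENT_WINDOWS["MMR"])
    pos = detect_component_peak(mmr_wave, t, "MMR", win, +1, min_dist, baseline,
                                waveform_kind="difference")
    neg = detect_component_peak(mmr_wave, t, "MMR", win, -1, min_dist, baseline,
                                waveform_kind="difference")
    candidates = [m for m in (pos, neg) if m.found]
    if not candidates:
        rows.append(PeakMeasurement.not_found("MMR", "difference"))
    else:
        rows.append(max(candidates,
                        key=lambda m: (m.prominence * m.snr, -m.latency_ms)))
    return pd.DataFrame([vars(m) for m in rows])
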