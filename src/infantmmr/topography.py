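"""Amplitude-weighted scalp center of mass and developmental displacement.

The center of mass of a component is the weighted average of the 11 unit-
sphere electrode coordinates, weighted by the absolute peak amplitude at the
group-level component latency averaged across subjects at each channel.
Displacements between sessions are decomposed into lateral (dX), anterior-
posterior (dY) and inferior-superior (dZ) components and binned by Euclidean
magnitude: minimal (<0.02), small [0.02, 0.05), moderate [0.05, 0.10), large
(>=0.10).  These are surface-distribution summaries, not source estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import ElectrodeMontage

logger = logging.getLogger(__name__)

__all__ = [
    "CenterOfMass", "Displacement", "compute_center_of_mass",
    "component_weights", "amplitudes_at_latency", "compute_displacement",
    "categorize_displacement", "topography_report",
]

_BINS = ((0.02, "minimal"), (0.05, "small"), (0.10, "moderate"))


@dataclass
class CenterOfMass:
    """3D amplitude-weighted centroid of the scalp distribution."""

    coords: np.ndarray
    component: str
    session: str
    condition: str
    weight_total: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not self.weight_total > 0:
            raise ValueError("weight_total must be positive")
        # convex combination of unit vectors can never leave the unit ball
        if np.linalg.norm(self.coords) > 1 + 1e-9:
            raise ValueError("center of mass outside the unit sphere")


@dataclass
class Displacement:
    """Signed per-axis deltas between two centers of mass, with magnitude bin."""

    dx: float
    dy: float
    dz: float
    magnitude: float
    category: str

    def __post_init__(self) -> None:
        expected = float(np.sqrt(self.dx ** 2 + self.dy ** 2 + self.dz ** 2))
        if abs(self.magnitude - expected) > 1e-12:
            raise ValueError("magnitude inconsistent with per-axis deltas")


def categorize_displacement(magnitude: float) -> str:
    """Left-closed magnitude bins in normalized units."""
    for upper, name in _BINS:
        if magnitude < upper:
            return name
    return "large"


def compute_center_of_mass(
    weights: np.ndarray,
    montage: ElectrodeMontage,
    component: str = "",
    session: str = "",
    condition: str = "",
) -> CenterOfMass:
    """Per-axis weighted mean of channel coordinates (weights nonnegative)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (montage.n_channels,):
        raise ValueError("one weight per montage channel required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero weights: center of mass undefined")
    coords = montage.coordinates.T @ (w / total)
    return CenterOfMass(coords, component, session, condition, float(total))


def amplitudes_at_latency(mean_waveform: np.ndarray, times_ms: np.ndarray,
                          latency_ms: float) -> np.ndarray:
    """Per-channel amplitude at the (group) component latency, nearest sample."""
    idx = int(np.argmin(np.abs(np.asarray(times_ms) - latency_ms)))
    return np.asarray(mean_waveform)[:, idx]


def component_weights(subject_amplitudes: np.ndarray) -> np.ndarray:
    """Channel weights: mean over subjects of |amplitude| at each channel.

    ``subject_amplitudes`` is subjects x channels, with NaN for channels
    dropped as bad for that subject (excluded from that channel's mean).
    The absolute value is taken before averaging.
    """
    amps = np.atleast_2d(np.asarray(subject_amplitudes, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        weights = np.nanmean(np.abs(amps), axis=0)
    empty = np.isnan(weights)
    if empty.any():
        logger.warning("%d channel(s) with zero contributing subjects: weight 0",
                       int(empty.sum()))
        weights = np.where(empty, 0.0, weights)
    return weights


def compute_displacement(a: CenterOfMass, b: CenterOfMass) -> Displacement:
    """b minus a, per axis, with Euclidean magnitude and category bin."""
    if (a.component, a.condition) != (b.component, b.condition):
        raise ValueError("displacement requires matching component and condition")
    d = b.coords - a.coords
    mag = float(np.linalg.norm(d))
    return Displacement(float(d[0]), float(d[1]), float(d[2]), mag,
                        categorize_displacement(mag))


_AXIS_LABELS = {
    0: ("Left", "Right"),
    1: ("Posterior", "Anterior"),
    2: ("Inferior", "Superior"),
}


def _primary_direction(disp: Displacement) -> str:
    deltas = np.array([disp.dx, disp.dy, disp.dz])
    axis = int(np.argmax(np.abs(deltas)))
    neg, pos = _AXIS_LABELS[axis]
    return pos if deltas[axis] >= 0 else neg


def topography_report(coms: dict, sessions=("T1", "T2", "T3")) -> pd.DataFrame:
    """Displacement summary per component x condition.

    ``coms`` maps (component, condition, session) -> CenterOfMass.  Each row
    reports T1->T2, T2->T3 and total T1->T3 magnitudes, the total category,
    and the primary direction (axis of largest |delta| of the total shift).
    Missing sessions yield missing values rather than an error.
    """
    keys = sorted({(c, cond) for (c, cond, _s) in coms})
    rows = []
    for component, condition in keys:
        get = lambda s: coms.get((component, condition, s))
        row = {"component": component, "condition": condition}
        pairs = {"t1_t2": (get("T1"), get("T2")), "t2_t3": (get("T2"), get("T3")),
                 "total_t1_t3": (get("T1"), get("T3"))}
        for name, (a, b) in pairs.items():
            if a is None or b is None:
                row[name] = np.nan
                continue
            d = compute_displacement(a, b)
            row[name] = d.magnitude
            if name == "total_t1_t3":
                row["dx"], row["dy"], row["dz"] = d.dx, d.dy, d.dz
                row["category"] = d.category
                row["primary_direction"] = _primary_direction(d)
        rows.append(row)
    columns = ["component", "condition", "t1_t2", "t2_t3", "total_t1_t3",
               "dx", "dy", "dz", "category", "primary_direction"]
    return pd.DataFrame(rows).reindex(columns=columns)
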