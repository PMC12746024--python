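"""Electrode montage: the 11-channel infant cap on a unit sphere.

Axis convention: +X = right, +Y = anterior, +Z = superior.  Coordinates are
dimensionless unit vectors, so scalp positions are comparable across ages
despite head growth.  "Leftward" therefore means a negative shift along X,
"anterior" a positive shift along Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeMontage", "build_default_montage", "DEFAULT_CHANNELS"]

DEFAULT_CHANNELS = ("F5", "Fz", "F6", "C5", "Cz", "C6", "P5", "Pz", "P6", "M1", "M2")

# Standard 10-10 positions, sphere-fitted and left/right symmetrized, with the
# midline fixed at X = 0 and Cz at the vertex.  Near-unit vectors; normalized
# exactly at construction.
_DEFAULT_COORDS = {
    "F5": (-0.670362, +0.666936, +0.325286),
    "Fz": (0.0, +0.649686, +0.760203),
    "F6": (+0.670362, +0.666936, +0.325286),
    "C5": (-0.903977, +0.030186, +0.426514),
    "Cz": (0.0, 0.0, +1.0),
    "C6": (+0.903977, +0.030186, +0.426514),
    "P5": (-0.707078, -0.624781, +0.331195),
    "Pz": (0.0, -0.633965, +0.773361),
    "P6": (+0.707078, -0.624781, +0.331195),
    "M1": (-0.801077, -0.181998, -0.570222),
    "M2": (+0.801077, -0.181998, -0.570222),
}

_MIDLINE = frozenset({"Fz", "Cz", "Pz"})


@dataclass(frozen=True)
class ElectrodeMontage:
    """Ordered channel labels with unit-sphere 3D positions.

    Parameters
    ----------
    channel_names
        Unique channel labels, in data-row order.
    coordinates
        Array of shape ``(n_channels, 3)``; each row must have Euclidean
        norm 1 (checked to 1e-9).
    reference_label
        Label of the recording reference (nasion by default).
    """

    channel_names: tuple[str, ...]
    coordinates: np.ndarray = field(repr=False)
    reference_label: str = "Nz"

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (len(names), 3):
            raise ValueError(
                f"coordinates shape {coords.shape} does not match "
                f"{len(names)} channels"
            )
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        norms = np.linalg.norm(coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage coordinates must lie on the unit sphere")
        coords.setflags(write=False)
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def coordinate(self, name: str) -> np.ndarray:
        return self.coordinates[self.index(name)]

    def subset(self, names: list[str] | tuple[str, ...]) -> "ElectrodeMontage":
        """Montage restricted to `names`, preserving this montage's order."""
        keep = [n for n in self.channel_names if n in set(names)]
        missing = set(names) - set(self.channel_names)
        if missing:
            raise KeyError(f"channels not in montage: {sorted(missing)}")
        idx = [self.index(n) for n in keep]
        return ElectrodeMontage(tuple(keep), self.coordinates[idx], self.reference_label)


def build_default_montage() -> ElectrodeMontage:
    """The 11-channel infant montage (F5, Fz, F6, C5, Cz, C6, P5, Pz, P6, M1, M2).

    Midline channels have X = 0 exactly; every coordinate is normalized to
    unit radius.  Referenced to the nasion.
    """
    coords = np.array([_DEFAULT_COORDS[c] for c in DEFAULT_CHANNELS], dtype=float)
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    # enforce exact midline symmetry after normalization
    for name in _MIDLINE:
        coords[DEFAULT_CHANNELS.index(name), 0] = 0.0
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    return ElectrodeMontage(DEFAULT_CHANNELS, coords, reference_label="Nz")
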