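"""64-channel 10/20 montage with 2-D scalp coordinates.

Channel positions come from the standard 10-05 electrode set shipped with
MNE-Python and are flattened with an azimuthal-equidistant projection
(vertex Cz at the origin, nose along +y).  The montage is the spatial
substrate for the synthetic right-frontal burst source and for the
right-frontal concentration score used in spatial-filter selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: BrainProducts-style 64-channel 10/20 layout.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC2", "F4", "F8",
    "Fp2", "AF7", "AF3", "AFz", "F1", "F5", "FT7", "FC3", "C1", "C5",
    "TP7", "CP3", "P1", "P5", "PO7", "PO3", "POz", "PO4", "PO8", "P6",
    "P2", "CPz", "CP4", "TP8", "C6", "C2", "FC4", "FT8", "F6", "AF8",
    "AF4", "F2", "Iz", "FC6",
)

#: ROI used to score right-frontal concentration of a scalp pattern.
RIGHT_FRONTAL_ROI: tuple[str, ...] = ("AF4", "F4", "F6", "F8", "FC4", "FC6", "FT8")

#: Fallback ROI when no right-lateralized candidate survives (frontal row).
FRONTAL_ROI: tuple[str, ...] = (
    "AFz", "Fz", "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8",
)


@dataclass(frozen=True)
class Montage:
    """Electrode names and 2-D coordinates (azimuthal-equidistant, radians)."""

    names: tuple[str, ...]
    coords: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(self.names) != self.coords.shape[0]:
            raise ValueError("names/coords length mismatch")

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in montage") from err

    def roi_indices(self, roi: tuple[str, ...]) -> np.ndarray:
        missing = [ch for ch in roi if ch not in self.names]
        if missing:
            raise KeyError(f"ROI channels missing from montage: {missing}")
        return np.array([self.names.index(ch) for ch in roi], dtype=int)

    @property
    def n_channels(self) -> int:
        return len(self.names)


def _azimuthal_equidistant(xyz: np.ndarray) -> np.ndarray:
    """Project unit-sphere positions to the plane; Cz at origin, nose +y."""
    xyz = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
    theta = np.arccos(np.clip(xyz[:, 2], -1.0, 1.0))  # polar angle from vertex
    phi = np.arctan2(xyz[:, 1], xyz[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


@lru_cache(maxsize=4)
def load_montage(names: tuple[str, ...] = CHANNELS_64) -> Montage:
    """Build a :class:`Montage` for the given labels from the 10-05 standard."""
    import mne

    mne.set_log_level("ERROR")
    std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    missing = [ch for ch in names if ch not in pos]
    if missing:
        raise KeyError(f"labels absent from standard 10-05 set: {missing}")
    xyz = np.array([pos[ch] for ch in names], dtype=float)
    # Positions are in head coordinates relative to origin; re-center on the
    # sphere best fitting the electrodes so the projection is well behaved.
    center = xyz.mean(axis=0)
    xyz = xyz - center
    return Montage(names=tuple(names), coords=_azimuthal_equidistant(xyz))


def gaussian_mixing(
    montage: Montage, center: str, spread: float
) -> np.ndarray:
    """Spatial profile of a focal source: Gaussian in projected distance.

    Normalized so the center channel has weight 1.  ``spread`` is the
    Gaussian sigma in the projection's angular units (radians).
    """
    if spread <= 0:
        raise ValueError("spread must be > 0")
    c = montage.coords[montage.index(center)]
    d2 = np.sum((montage.coords - c) ** 2, axis=1)
    w = np.exp(-d2 / (2.0 * spread**2))
    return w / w.max()
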