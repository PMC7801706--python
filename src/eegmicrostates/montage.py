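"""Schematic 10-20 electrode layout and canonical microstate archetype maps.

The 19-channel International 10-20 montage is used throughout the package.
Electrode positions are schematic top-view coordinates on a unit-radius head
(x grows toward the right ear, y toward the nasion).  They are sufficient for
constructing and matching the four canonical microstate topographies; no
claim of anatomical precision is made.
"""

from __future__ import annotations

import numpy as np

#: Canonical channel order used for all 19-channel recordings.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8",
    "C3", "C4", "Cz", "P3", "P4", "Pz",
    "O1", "O2", "T3", "T4", "T5", "T6",
)

# Top-view schematic positions (unit head radius).  Outer-ring electrodes sit
# on the circle of radius 1; mid-ring electrodes are interpolated inward.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.309, 0.951),
    "Fp2": (0.309, 0.951),
    "F7": (-0.809, 0.588),
    "F8": (0.809, 0.588),
    "F3": (-0.400, 0.530),
    "F4": (0.400, 0.530),
    "Fz": (0.0, 0.500),
    "T3": (-1.000, 0.000),
    "T4": (1.000, 0.000),
    "C3": (-0.500, 0.000),
    "C4": (0.500, 0.000),
    "Cz": (0.0, 0.000),
    "T5": (-0.809, -0.588),
    "T6": (0.809, -0.588),
    "P3": (-0.400, -0.530),
    "P4": (0.400, -0.530),
    "Pz": (0.0, -0.500),
    "O1": (-0.309, -0.951),
    "O2": (0.309, -0.951),
}

#: The four archetype classes in fixed order.
ARCHETYPES: tuple[str, ...] = ("A", "B", "C", "D")


class MontageError(ValueError):
    """Raised for unknown channels or degenerate electrode layouts."""


def montage_positions(channels: tuple[str, ...] | list[str] = CHANNELS_1020) -> np.ndarray:
    """Return the (n_channels, 2) top-view coordinates for the given labels.

    Raises
    ------
    MontageError
        If a label is not one of the 19 standard 10-20 names, or if two
        requested electrodes coincide.
    """
    unknown = [c for c in channels if c not in _POSITIONS]
    if unknown:
        raise MontageError(f"unknown 10-20 channel label(s): {unknown}")
    pos = np.array([_POSITIONS[c] for c in channels], dtype=float)
    if len(channels) > 1:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise MontageError("degenerate montage: coincident electrodes")
    return pos


def _center_normalize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate map: zero after centering")
    return v / n


def canonical_archetype_maps(
    channels: tuple[str, ...] | list[str] = CHANNELS_1020,
) -> np.ndarray:
    """Build the four canonical archetype topographies on a montage.

    Types A and B are the two mirror-image unilateral orientations.  Their
    gradient axes are tilted 30 degrees from the left-right axis toward the
    front, so each remains predominantly lateral while keeping the classic
    posterior-to-contralateral-frontal diagonal character.  Type C is a pure
    anterior-posterior gradient and type D a fronto-central focal extremum
    (Gaussian bump centered just in front of Cz).

    Returns a (4, n_channels) array; each row zero-mean and unit-norm, in the
    archetype order A, B, C, D.
    """
    pos = montage_positions(channels)
    x, y = pos[:, 0], pos[:, 1]
    tilt = np.deg2rad(30.0)
    map_a = np.cos(tilt) * x + np.sin(tilt) * y
    map_b = -np.cos(tilt) * x + np.sin(tilt) * y
    map_c = y
    center = np.array([0.0, 0.35])
    d2 = ((pos - center) ** 2).sum(axis=1)
    map_d = np.exp(-d2 / (2 * 0.55**2))
    maps = np.vstack([_center_normalize(m) for m in (map_a, map_b, map_c, map_d)])
    return maps
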