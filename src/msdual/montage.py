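"""Electrode layout helpers and idealized canonical microstate topographies.

The built-in montage is a 32-channel subset of the international 10-20
system.  2-D scalp positions come from MNE's standard montage (projected
head coordinates, meters; +x = right, +y = anterior).

The four canonical maps are smooth dipolar patterns built from Gaussian
"blobs" centred on scalp locations:

* **A** — left-posterior vs. right-frontal diagonal gradient,
* **B** — right-posterior vs. left-frontal diagonal gradient (mirror of A),
* **C** — occipital maximum vs. broad frontal minimum (anterior-posterior),
* **D** — focal posterior-parietal maximum (peak at Pz) with bilateral
  frontal minima.

All maps are average-referenced and scaled to unit global field power.
Pairwise absolute spatial correlation is bounded by 0.7, so the archetypes
are well separated while remaining physiologically smooth.
"""

from __future__ import annotations

import warnings

import numpy as np

#: Default 32-channel 10-20 subset (order is the canonical channel order).
DEFAULT_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6", "P7", "P3",
    "Pz", "P4", "P8", "PO3", "PO4", "O1", "Oz", "O2", "AF3", "AF4",
)

# (centre-xy, width-m, weight) triplets per canonical class.
_ARCHETYPE_BLOBS = {
    "A": (((-0.055, -0.055), 0.050, 1.0), ((0.05, 0.07), 0.050, -1.0)),
    "B": (((0.055, -0.055), 0.050, 1.0), ((-0.05, 0.07), 0.050, -1.0)),
    "C": (((0.0, -0.112), 0.042, 1.0), ((0.0, 0.09), 0.065, -0.9)),
    "D": (
        ((0.0, -0.060), 0.026, 1.0),
        ((-0.07, 0.035), 0.040, -0.45),
        ((0.07, 0.035), 0.040, -0.45),
    ),
}

CANONICAL_LABELS = ("A", "B", "C", "D")


def channel_positions(ch_names=DEFAULT_32) -> np.ndarray:
    """Return (n_channels, 2) scalp xy positions for ``ch_names``."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mon = mne.channels.make_standard_montage("standard_1020")
    pos = mon.get_positions()["ch_pos"]
    missing = [c for c in ch_names if c not in pos]
    if missing:
        raise ValueError(f"channels not in the 10-20 montage: {missing}")
    return np.array([pos[c][:2] for c in ch_names], dtype=float)


def _blob(positions: np.ndarray, centre, width: float) -> np.ndarray:
    d2 = (positions[:, 0] - centre[0]) ** 2 + (positions[:, 1] - centre[1]) ** 2
    return np.exp(-d2 / (2.0 * width**2))


def _normalize_map(m: np.ndarray) -> np.ndarray:
    m = m - m.mean()
    gfp = np.sqrt(np.mean(m**2))
    if gfp == 0:
        raise ValueError("degenerate (flat) topography")
    return m / gfp


def canonical_maps(positions: np.ndarray, K: int = 4) -> np.ndarray:
    """Build K average-referenced, unit-GFP archetype maps.

    The first four are the A-D archetypes.  For K > 4 additional dipolar
    maps are generated procedurally (rotating dipole orientations) and
    accepted only when their absolute correlation with every previously
    accepted map stays at or below 0.7.
    """
    n_ch = positions.shape[0]
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n_ch:
        raise ValueError(f"K={K} exceeds the channel count {n_ch}")

    maps = []
    for label in CANONICAL_LABELS[: min(K, 4)]:
        m = np.zeros(n_ch)
        for centre, width, weight in _ARCHETYPE_BLOBS[label]:
            m = m + weight * _blob(positions, centre, width)
        maps.append(_normalize_map(m))

    if K > 4:
        # quadrupolar patterns (higher spatial frequency) decorrelate well
        # from the dipolar archetypes
        radius = 0.07
        for angle in np.linspace(0.0, np.pi / 2, 91):
            if len(maps) == K:
                break
            m = np.zeros(n_ch)
            for j in range(4):
                theta = angle + j * np.pi / 2
                pole = (radius * np.cos(theta), radius * np.sin(theta))
                m += (-1.0) ** j * _blob(positions, pole, 0.045)
            try:
                m = _normalize_map(m)
            except ValueError:
                continue
            corrs = [abs(np.corrcoef(m, prev)[0, 1]) for prev in maps]
            if max(corrs) <= 0.7:
                maps.append(m)
        if len(maps) < K:
            raise ValueError(f"could not construct {K} sufficiently distinct maps")

    return np.array(maps)
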