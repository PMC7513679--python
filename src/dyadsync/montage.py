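"""Fixed 60-channel scalp montage used by the synthetic generator.

The layout is a schematic 10-10 subset on a flattened head: rows run
anterior (y > 0) to posterior (y < 0), x runs left (< 0) to right (> 0).
Positions are unitless and only used to build smooth source topographies;
no volume conduction model is implied.
"""

from __future__ import annotations

import numpy as np

# (row y, labels left-to-right); 60 scalp labels total
_ROWS = (
    (0.9, ("Fp1", "Fpz", "Fp2")),
    (0.675, ("AF7", "AF3", "AF4", "AF8")),
    (0.45, ("F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8")),
    (0.225, ("FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8")),
    (0.0, ("T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8")),
    (-0.225, ("TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8")),
    (-0.45, ("P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8")),
    (-0.675, ("PO7", "PO3", "POz", "PO4", "PO8")),
    (-0.9, ("O1", "Oz", "O2")),
)

SCALP_CHANNELS: tuple[str, ...] = tuple(lbl for _, row in _ROWS for lbl in row)
EOG_CHANNELS: tuple[str, ...] = ("VEOG", "HEOG")

#: medial centro-parietal set reported to share power patterns across roles
CENTRO_PARIETAL: tuple[str, ...] = (
    "C1", "Cz", "C2", "CP1", "CPz", "CP2", "P3", "P1", "Pz", "P2", "POz",
)


def _positions() -> dict[str, tuple[float, float]]:
    pos = {}
    for y, row in _ROWS:
        m = len(row)
        xs = np.linspace(-0.9, 0.9, m) if m > 1 else np.array([0.0])
        # narrow rows stay near the midline
        xs = xs * (0.25 + 0.75 * (m - 1) / 8.0)
        for lbl, x in zip(row, xs):
            pos[lbl] = (float(x), float(y))
    return pos


POSITIONS: dict[str, tuple[float, float]] = _positions()

assert len(SCALP_CHANNELS) == 60
assert set(CENTRO_PARIETAL) <= set(SCALP_CHANNELS)


def channel_index(labels: tuple[str, ...] | list[str]) -> dict[str, int]:
    """Map channel label -> position in ``labels``."""
    return {lbl: i for i, lbl in enumerate(labels)}


def topography(center: str, width: float = 0.45,
               width_y: float | None = None,
               channels: tuple[str, ...] = SCALP_CHANNELS) -> np.ndarray:
    """Smooth Gaussian source topography peaked at ``center``.

    ``width`` is the lateral (x) standard deviation; ``width_y`` makes
    the blob anisotropic (defaults to ``width``). Returns one weight per
    channel in ``channels`` (peak weight 1).
    """
    cx, cy = POSITIONS[center]
    wy = width if width_y is None else width_y
    w = np.empty(len(channels))
    for i, lbl in enumerate(channels):
        x, y = POSITIONS[lbl]
        w[i] = np.exp(-((x - cx) ** 2) / (2.0 * width**2)
                      - ((y - cy) ** 2) / (2.0 * wy**2))
    return w


def set_topography(members: tuple[str, ...], width: float = 0.3,
                   channels: tuple[str, ...] = SCALP_CHANNELS) -> np.ndarray:
    """Topography covering an electrode set: max of per-member Gaussians.

    Weights are ~1 over the set and fall off smoothly outside it.
    """
    w = np.zeros(len(channels))
    for m in members:
        w = np.maximum(w, topography(m, width=width, channels=channels))
    return w
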