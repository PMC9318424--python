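"""32-channel scalp montage and electrode neighborhoods.

The montage covers frontal, central, parietal and occipital 10/20-family
positions with 24 standard labels plus eight intermediate 10-10 positions.
Coordinates are a synthetic flattened 2-D grid (arbitrary units, one unit
between adjacent electrodes in a row; nose at +y): adequate for
neighborhood queries and schematic topography, not a digitized head model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# name -> (x, y); x negative = left hemisphere.
_POSITIONS: dict[str, tuple[float, float]] = {
    # frontal row
    "F3": (-1.5, 2.0), "F1": (-0.5, 2.0), "Fz": (0.0, 2.0),
    "F2": (0.5, 2.0), "F4": (1.5, 2.0),
    # fronto-central row
    "FC3": (-1.5, 1.0), "FC1": (-0.5, 1.0), "FCz": (0.0, 1.0),
    "FC2": (0.5, 1.0), "FC4": (1.5, 1.0),
    # central row
    "C5": (-2.5, 0.0), "C3": (-1.5, 0.0), "C1": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C2": (0.5, 0.0), "C4": (1.5, 0.0), "C6": (2.5, 0.0),
    # centro-parietal row
    "CP5": (-2.5, -1.0), "CP3": (-1.5, -1.0), "CP1": (-0.5, -1.0),
    "CPz": (0.0, -1.0), "CP2": (0.5, -1.0), "CP4": (1.5, -1.0),
    "CP6": (2.5, -1.0),
    # parietal row
    "P3": (-1.5, -2.0), "P1": (-0.5, -2.0), "Pz": (0.0, -2.0),
    "P2": (0.5, -2.0), "P4": (1.5, -2.0),
    # parieto-occipital / occipital
    "PO3": (-1.0, -2.5), "PO4": (1.0, -2.5), "Oz": (0.0, -3.0),
}

CHANNEL_NAMES: tuple[str, ...] = tuple(_POSITIONS)
N_CHANNELS: int = len(CHANNEL_NAMES)
assert N_CHANNELS == 32

#: [32 x 2] electrode coordinates in CHANNEL_NAMES order.
POSITIONS: np.ndarray = np.array([_POSITIONS[c] for c in CHANNEL_NAMES], float)

#: Default neighborhood radius: captures in-row and across-row nearest
#: electrodes (spacing 1.0-1.12 grid units) without second-shell pickups.
DEFAULT_RADIUS: float = 1.2


def montage_table() -> pd.DataFrame:
    """Montage as a DataFrame with columns name, x, y."""
    return pd.DataFrame(
        {"name": CHANNEL_NAMES, "x": POSITIONS[:, 0], "y": POSITIONS[:, 1]}
    )


def channel_index(name: str) -> int:
    try:
        return CHANNEL_NAMES.index(name)
    except ValueError:
        raise KeyError(f"unknown electrode {name!r}") from None


def distances(positions: np.ndarray | None = None) -> np.ndarray:
    """Pairwise electrode distances [n x n]."""
    pos = POSITIONS if positions is None else np.asarray(positions, float)
    diff = pos[:, None, :] - pos[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def neighborhood(
    electrode: int | str,
    radius: float = DEFAULT_RADIUS,
    positions: np.ndarray | None = None,
) -> list[int]:
    """Indices of ``electrode`` and all electrodes within ``radius`` of it.

    The seed electrode is always first; neighbors follow in montage order.
    """
    idx = channel_index(electrode) if isinstance(electrode, str) else int(electrode)
    d = distances(positions)[idx]
    others = [j for j in np.flatnonzero(d <= radius) if j != idx]
    return [idx] + others
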