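"""Planar multielectrode-array geometry.

The recording substrate modelled here is the classical 8x8 TiN grid with
200 um electrode pitch in which the four corner positions are absent and one
electrode serves as internal reference, leaving 59 recording channels.
Electrode ids follow the usual column-row convention (id = 10*column + row,
both 1-based), so electrode 23 sits in column 2, row 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MEAGeometry", "standard_mea"]

#: grid positions absent on the standard 8x8 layout (corners) plus the
#: internal reference electrode.
_CORNER_IDS = (11, 18, 81, 88)
_REFERENCE_ID = 15


@dataclass(frozen=True)
class MEAGeometry:
    """Electrode ids and planar coordinates of a recording grid.

    Parameters
    ----------
    electrode_ids
        Integer labels, one per electrode.
    positions
        ``(n, 2)`` array of x/y coordinates in micrometres.
    pitch
        Nominal grid spacing in micrometres (metadata; distances are always
        computed from ``positions``).
    """

    electrode_ids: tuple[int, ...]
    positions: np.ndarray = field(repr=False)
    pitch: float = 200.0

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.electrode_ids)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of planar coordinates")
        if len(ids) != pos.shape[0]:
            raise ValueError("number of electrode ids must match number of positions")
        if len(set(ids)) != len(ids):
            raise ValueError("electrode ids must be unique")
        if len(np.unique(pos, axis=0)) != pos.shape[0]:
            raise ValueError("electrode positions must be distinct")
        object.__setattr__(self, "electrode_ids", ids)
        object.__setattr__(self, "positions", pos)

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_ids)

    def index_of(self, electrode_id: int) -> int:
        """Row index of an electrode id (raises ``KeyError`` if unknown)."""
        try:
            return self.electrode_ids.index(int(electrode_id))
        except ValueError:
            raise KeyError(f"unknown electrode id {electrode_id!r}") from None

    def position_of(self, electrode_id: int) -> np.ndarray:
        return self.positions[self.index_of(electrode_id)]

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances in micrometres, shape ``(n, n)``."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])


def standard_mea(pitch: float = 200.0) -> MEAGeometry:
    """The default 59-electrode layout: 8x8 grid minus corners and reference."""
    ids, pos = [], []
    for col in range(1, 9):
        for row in range(1, 9):
            eid = 10 * col + row
            if eid in _CORNER_IDS or eid == _REFERENCE_ID:
                continue
            ids.append(eid)
            pos.append(((col - 1) * pitch, (row - 1) * pitch))
    return MEAGeometry(tuple(ids), np.asarray(pos, dtype=float), pitch=pitch)
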