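"""64-channel 10-20 scalp montage utilities.

Electrode labels and 3D positions come from the standard BioSemi 64-channel
layout shipped with MNE-Python.  Positions are re-centred on their centroid
and projected onto the unit sphere, which is the geometry the spherical-spline
interpolation and the electrode-neighbourhood graph both assume.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .errors import UnknownChannelError

__all__ = ["get_biosemi64", "angular_distance", "load_montage_txt", "save_montage_txt"]


@lru_cache(maxsize=1)
def _biosemi64_cached() -> tuple[tuple[str, ...], np.ndarray]:
    import mne

    mont = mne.channels.make_standard_montage("biosemi64")
    ch_pos = mont.get_positions()["ch_pos"]
    names = tuple(ch_pos)
    pos = np.array([ch_pos[n] for n in names], dtype=float)
    pos -= _fit_sphere_center(pos)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return names, pos


def _fit_sphere_center(pos: np.ndarray) -> np.ndarray:
    """Least-squares sphere fit; electrodes cover only the upper head, so the
    centroid is biased upward and the algebraic fit is used instead."""
    a = np.column_stack([2 * pos, np.ones(len(pos))])
    b = (pos ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


def get_biosemi64() -> tuple[list[str], np.ndarray]:
    """Return (labels, unit-sphere positions) of the 64-channel montage."""
    names, pos = _biosemi64_cached()
    return list(names), pos.copy()


def channel_indices(names: list[str], wanted: list[str]) -> np.ndarray:
    """Map electrode labels to row indices, raising on unknown labels."""
    lookup = {n: i for i, n in enumerate(names)}
    try:
        return np.array([lookup[w] for w in wanted], dtype=int)
    except KeyError as err:
        raise UnknownChannelError(f"electrode {err.args[0]!r} not in montage") from None


def angular_distance(positions: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (radians) between unit-sphere positions."""
    cosang = np.clip(positions @ positions.T, -1.0, 1.0)
    return np.arccos(cosang)


def save_montage_txt(path, names: list[str], positions: np.ndarray) -> None:
    """Write a plain-text ``label,x,y,z`` montage file."""
    with open(path, "w") as fh:
        for n, (x, y, z) in zip(names, positions):
            fh.write(f"{n},{x:.8f},{y:.8f},{z:.8f}\n")


def load_montage_txt(path) -> tuple[list[str], np.ndarray]:
    names: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            label, x, y, z = line.split(",")
            names.append(label)
            rows.append([float(x), float(y), float(z)])
    return names, np.array(rows, dtype=float)
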