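"""Periodic snapshots of water boxes and trajectory readers/writers.

Boxes are orthorhombic throughout; all pair geometry uses the minimum-image
convention. Two on-disk formats are supported: a multi-frame XYZ dialect
whose comment line carries the box lengths (``Lx Ly Lz [t=<ps>]``) and
multi-model PDB with a CRYST1 record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Frame",
    "minimum_image",
    "minimum_image_distance",
    "read_xyz",
    "iter_xyz",
    "write_xyz",
    "read_pdb",
]


@dataclass(frozen=True)
class Frame:
    """One periodic snapshot: element symbols, coordinates and box lengths.

    Parameters
    ----------
    elements : array of str, shape (n,)
        Chemical symbols ("O", "H", ...).
    coords : array of float, shape (n, 3)
        Cartesian coordinates in Å. May lie outside the box; geometry
        helpers wrap as needed.
    box : array of float, shape (3,)
        Orthorhombic box edge lengths in Å.
    time_ps : float
        Time stamp in ps (non-negative).
    """

    elements: np.ndarray
    coords: np.ndarray
    box: np.ndarray
    time_ps: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "elements", np.asarray(self.elements, dtype=object))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        object.__setattr__(self, "box", np.asarray(self.box, dtype=float))
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"element count {len(self.elements)} != coordinate count {len(self.coords)}"
            )
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three strictly positive lengths")
        if self.time_ps < 0:
            raise ValueError("time stamp must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def wrapped_coords(self) -> np.ndarray:
        """Coordinates folded into [0, L) along each axis."""
        return np.mod(self.coords, self.box)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distance(s) between points ``a`` and ``b``."""
    d = minimum_image(np.asarray(a, float) - np.asarray(b, float), box)
    return np.linalg.norm(d, axis=-1)


def _parse_xyz_comment(comment: str) -> tuple[np.ndarray, float]:
    """Extract box lengths and optional ``t=<ps>`` stamp from a comment line."""
    time_ps = 0.0
    floats: list[float] = []
    for tok in comment.split():
        if tok.startswith("t="):
            time_ps = float(tok[2:])
            continue
        try:
            floats.append(float(tok))
        except ValueError:
            continue
    if len(floats) < 3:
        raise ValueError(
            f"XYZ comment line must carry box lengths 'Lx Ly Lz'; got {comment!r}"
        )
    return np.array(floats[:3]), time_ps


def iter_xyz(path: str | Path) -> Iterator[Frame]:
    """Stream frames from a multi-frame XYZ file with box-annotated comments."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                if not header:
                    return
                continue
            n = int(header)
            box, time_ps = _parse_xyz_comment(fh.readline())
            elements = np.empty(n, dtype=object)
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                elements[i] = parts[0]
                coords[i] = [float(x) for x in parts[1:4]]
            yield Frame(elements, coords, box, time_ps)


def read_xyz(path: str | Path) -> list[Frame]:
    """Read all frames of a box-annotated multi-frame XYZ file."""
    return list(iter_xyz(path))


def write_xyz(frames: Frame | Iterable[Frame], path: str | Path, comment_extra: str = "") -> None:
    """Write one or more frames in the box-annotated XYZ dialect."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"{fr.n_atoms}\n")
            bx = " ".join(f"{v:.6f}" for v in fr.box)
            line = f"{bx} t={fr.time_ps:.6f}"
            if comment_extra:
                line += f" {comment_extra}"
            fh.write(line + "\n")
            for el, (x, y, z) in zip(fr.elements, fr.coords):
                fh.write(f"{el} {x:.8f} {y:.8f} {z:.8f}\n")


def read_pdb(path: str | Path) -> list[Frame]:
    """Read a (multi-model) PDB trajectory via MDAnalysis; CRYST1 supplies
    the box.

    PDB carries no time axis, so ``time_ps`` is set to the 0-based model
    index; rescale with the trajectory stride if real times are needed.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda

        u = mda.Universe(str(path))
        try:
            elements = np.array([e.capitalize() for e in u.atoms.elements], dtype=object)
        except (mda.exceptions.NoDataError, AttributeError):
            elements = np.array([n.strip()[0].capitalize() for n in u.atoms.names],
                                dtype=object)
        # multi-model files often carry one global CRYST1 that per-frame
        # readers miss; fall back to the record itself
        global_box = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    global_box = np.array([float(line[6:15]), float(line[15:24]),
                                           float(line[24:33])])
                    break

        frames = []
        for i, ts in enumerate(u.trajectory):
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = ts.dimensions[:3].astype(float)
            elif global_box is not None:
                box = global_box
            else:
                raise ValueError("PDB file lacks a CRYST1 record; box unknown")
            frames.append(Frame(elements, ts.positions.astype(float).copy(),
                                box, float(i)))
    return frames
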