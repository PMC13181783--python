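"""Water perception, O–O RDFs, shell cutoffs and probe-centered clusters.

This module turns periodic water-box snapshots into the probe-centered,
minimum-image-unwrapped clusters that the frequency engine consumes, and
counts first-solvation-shell coordination numbers. Shell membership is
defined on O–O distances with strict ``<`` at every cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .errors import ShellStructureError, WaterPerceptionError
from .frames import Frame, minimum_image

__all__ = [
    "WaterMolecule",
    "ProbeSpec",
    "RadialDistribution",
    "ShellCutoffs",
    "Cluster",
    "perceive_waters",
    "compute_rdf",
    "locate_shell_cutoffs",
    "carve_cluster",
    "count_first_shell",
    "snapshot_schedule",
]

DEFAULT_OH_CUTOFF = 1.25  # Å, O–H bond perception
DEFAULT_RDF_DR = 0.05  # Å
DEFAULT_SMOOTHING_WINDOW = 5  # bins


@dataclass(frozen=True)
class WaterMolecule:
    """Atom indices of one intact water: oxygen plus its two hydrogens."""

    o: int
    h1: int
    h2: int

    def __post_init__(self):
        if len({self.o, self.h1, self.h2}) != 3:
            raise ValueError("water molecule requires three distinct atom indices")

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.o, self.h1, self.h2)


@dataclass(frozen=True)
class ProbeSpec:
    """The probe water and which of its hydrogens is treated as deuterium."""

    water: WaterMolecule
    deuterium: int

    def __post_init__(self):
        if self.deuterium not in (self.water.h1, self.water.h2):
            raise ValueError("deuterated index must be one of the probe's hydrogens")


@dataclass(frozen=True)
class RadialDistribution:
    """Binned pair distribution g(r) with uniform bin width."""

    r: np.ndarray
    g: np.ndarray
    dr: float
    pair: str = "O-O"

    def __post_init__(self):
        object.__setattr__(self, "r", np.asarray(self.r, float))
        object.__setattr__(self, "g", np.asarray(self.g, float))
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")
        dspace = np.diff(self.r)
        if np.any(dspace <= 0) or not np.allclose(dspace, self.dr, rtol=1e-6):
            raise ValueError("bin centers must increase uniformly by dr")


@dataclass(frozen=True)
class ShellCutoffs:
    """First- and third-minimum radii of the O–O RDF (Å)."""

    r_first_min: float
    r_third_min: float

    def __post_init__(self):
        if not (0 < self.r_first_min < self.r_third_min):
            raise ValueError("require 0 < first minimum < third minimum")


@dataclass(frozen=True)
class Cluster:
    """A probe water plus its unwrapped solvation environment.

    Atoms are stored O, H, H per molecule with the probe first, so atom
    indices 0–2 are always the probe. Coordinates are minimum-image
    unwrapped around the probe oxygen: the cluster is contiguous in space
    and no molecule is split across the box boundary.
    """

    elements: np.ndarray
    coords: np.ndarray
    n_first_shell: int
    time_ps: float = 0.0
    replica: int = 0
    source_indices: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "elements", np.asarray(self.elements, dtype=object))
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        if len(self.elements) % 3 != 0:
            raise ValueError("cluster atoms must form whole waters (multiple of 3)")
        if self.n_first_shell > self.n_molecules - 1:
            raise ValueError("coordination count cannot exceed environment size")

    @property
    def n_molecules(self) -> int:
        return len(self.elements) // 3

    @property
    def probe_coords(self) -> np.ndarray:
        return self.coords[:3]

    @property
    def environment_oxygen_coords(self) -> np.ndarray:
        return self.coords[3::3]


def perceive_waters(frame: Frame, oh_cutoff: float = DEFAULT_OH_CUTOFF) -> list[WaterMolecule]:
    """Assign every hydrogen to its nearest oxygen and return intact waters.

    Assignment uses minimum-image distances. Frames containing species
    other than O and H are rejected, as are stray hydrogens (no oxygen
    within ``oh_cutoff``) and oxygens with a hydrogen count other than two.
    """
    if not (0.5 < oh_cutoff < 1.5):
        raise ValueError("oh_cutoff must lie in (0.5, 1.5) Å")
    els = np.array([str(e).capitalize() for e in frame.elements], dtype=object)
    o_idx = np.flatnonzero(els == "O")
    h_idx = np.flatnonzero(els == "H")
    foreign = np.flatnonzero(~np.isin(els, ("O", "H")))
    if foreign.size:
        raise WaterPerceptionError(
            f"frame contains non-water element {els[foreign[0]]!r} at atom {foreign[0]}",
            atom_index=int(foreign[0]),
        )
    if o_idx.size == 0:
        raise WaterPerceptionError("frame contains no oxygen atoms")

    wrapped = frame.wrapped_coords()
    tree = cKDTree(wrapped[o_idx], boxsize=frame.box)
    dist, nearest = tree.query(wrapped[h_idx], distance_upper_bound=oh_cutoff)
    assigned: dict[int, list[int]] = {int(o): [] for o in o_idx}
    for h, (d, j) in zip(h_idx, zip(dist, nearest)):
        if not np.isfinite(d):
            raise WaterPerceptionError(
                f"hydrogen atom {h} has no oxygen within {oh_cutoff} Å", atom_index=int(h)
            )
        assigned[int(o_idx[j])].append(int(h))

    waters = []
    for o in o_idx:
        hs = assigned[int(o)]
        if len(hs) != 2:
            raise WaterPerceptionError(
                f"oxygen atom {o} has {len(hs)} assigned hydrogens (expected 2)",
                atom_index=int(o),
            )
        waters.append(WaterMolecule(int(o), hs[0], hs[1]))
    return waters


def compute_rdf(
    frames: list[Frame],
    waters: list[list[WaterMolecule]] | list[WaterMolecule] | None = None,
    r_max: float = 8.0,
    dr: float = DEFAULT_RDF_DR,
) -> RadialDistribution:
    """O–O radial distribution function averaged over frames.

    The pair histogram is normalized by ideal-gas shell counts at each
    frame's own oxygen density, so g(r) → 1 at large r for homogeneous
    boxes. ``r_max`` must stay below half the smallest box length for the
    minimum-image convention to be valid.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    if not frames:
        raise ValueError("need at least one frame")
    if isinstance(waters, list) and waters and isinstance(waters[0], WaterMolecule):
        waters = [waters] * len(frames)

    nbins = int(round(r_max / dr))
    edges = np.linspace(0.0, nbins * dr, nbins + 1)
    counts = np.zeros(nbins)
    ideal = np.zeros(nbins)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    for k, frame in enumerate(frames):
        if r_max >= frame.box.min() / 2:
            raise ValueError(
                f"r_max={r_max} Å violates minimum-image validity "
                f"(half smallest box = {frame.box.min() / 2:.3f} Å)"
            )
        if waters is None:
            mols = perceive_waters(frame)
        else:
            mols = waters[k]
        o_idx = np.array([w.o for w in mols])
        pos = frame.wrapped_coords()[o_idx]
        tree = cKDTree(pos, boxsize=frame.box)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if pairs.size:
            d = minimum_image(pos[pairs[:, 0]] - pos[pairs[:, 1]], frame.box)
            counts += np.histogram(np.linalg.norm(d, axis=1), bins=edges)[0]
        n = len(o_idx)
        rho = n / np.prod(frame.box)
        ideal += 0.5 * n * rho * shell_vol  # unordered pairs

    centers = 0.5 * (edges[1:] + edges[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, counts / ideal, 0.0)
    return RadialDistribution(centers, g, dr)


def _smooth(g: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window <= 1:
        return g.copy()
    kernel = np.ones(window)
    norm = np.convolve(np.ones_like(g), kernel, mode="same")
    return np.convolve(g, kernel, mode="same") / norm


def locate_shell_cutoffs(
    rdf: RadialDistribution, smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
) -> ShellCutoffs:
    """First and third RDF minima, located after moving-average smoothing.

    The first minimum is the first local minimum after the first smoothed
    maximum; the third minimum follows the third maximum. Featureless or
    monotone g(r) raises :class:`ShellStructureError`.
    """
    gs = _smooth(rdf.g, smoothing_window)
    maxima, _ = find_peaks(gs)
    if len(maxima) < 3:
        raise ShellStructureError(
            f"no shell structure: found {len(maxima)} smoothed maxima, need 3"
        )
    minima, _ = find_peaks(-gs)

    def first_min_after(peak: int) -> int:
        after = minima[minima > peak]
        if after.size == 0:
            raise ShellStructureError(f"no minimum after maximum at r={rdf.r[peak]:.2f} Å")
        return int(after[0])

    i1 = first_min_after(maxima[0])
    i3 = first_min_after(maxima[2])
    return ShellCutoffs(float(rdf.r[i1]), float(rdf.r[i3]))


def _unwrap_molecule(frame: Frame, mol: WaterMolecule, anchor: np.ndarray) -> np.ndarray:
    """Coordinates of one water, made whole and imaged next to ``anchor``."""
    o = frame.coords[mol.o]
    o_un = anchor + minimum_image(o - anchor, frame.box)
    out = np.empty((3, 3))
    out[0] = o_un
    for row, h in enumerate((mol.h1, mol.h2), start=1):
        out[row] = o_un + minimum_image(frame.coords[h] - o, frame.box)
    return out


def count_first_shell(
    frame: Frame,
    probe: ProbeSpec,
    r1: float,
    waters: list[WaterMolecule] | None = None,
) -> int:
    """Number of waters with O–O minimum-image distance strictly below ``r1``."""
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    if waters is None:
        waters = perceive_waters(frame)
    po = frame.coords[probe.water.o]
    n = 0
    for w in waters:
        if w.o == probe.water.o:
            continue
        d = minimum_image(frame.coords[w.o] - po, frame.box)
        if float(np.linalg.norm(d)) < r1:
            n += 1
    return n


def carve_cluster(
    frame: Frame,
    probe: ProbeSpec,
    cutoffs: ShellCutoffs,
    mode: str = "nearest_n",
    n: int = 29,
    waters: list[WaterMolecule] | None = None,
    replica: int = 0,
) -> Cluster:
    """Carve the probe-centered solvation cluster out of a periodic frame.

    ``radius`` mode keeps every water whose O–O minimum-image distance to
    the probe oxygen is strictly below the third-minimum radius; the
    resulting size varies frame to frame. ``nearest_n`` keeps exactly the
    ``n`` nearest waters, giving fixed-size engine inputs (n=29 environment
    molecules reproduces the conventional 30-molecule cluster).

    The coordination count always uses the first-minimum radius. All
    molecules are unwrapped around the probe so the cluster is contiguous.
    """
    if waters is None:
        waters = perceive_waters(frame)
    probe_mol = probe.water
    if not any(w.o == probe_mol.o for w in waters):
        raise ValueError(f"probe oxygen {probe_mol.o} not found among perceived waters")

    po = frame.coords[probe_mol.o]
    others = [w for w in waters if w.o != probe_mol.o]
    dists = np.array(
        [np.linalg.norm(minimum_image(frame.coords[w.o] - po, frame.box)) for w in others]
    )

    if mode == "radius":
        keep = np.flatnonzero(dists < cutoffs.r_third_min)
        order = keep[np.argsort(dists[keep], kind="stable")]
    elif mode == "nearest_n":
        if n > len(others):
            raise ValueError(f"requested {n} environment waters but only {len(others)} available")
        order = np.argsort(dists, kind="stable")[:n]
    else:
        raise ValueError(f"unknown carve mode {mode!r}")

    env = [others[i] for i in order]
    n1 = int(np.sum(dists[order] < cutoffs.r_first_min))

    mols = [probe_mol] + env
    coords = np.vstack([_unwrap_molecule(frame, m, po) for m in mols])
    # the probe O itself is kept at its original (possibly wrapped) position
    coords[0] = po
    coords[1] = po + minimum_image(frame.coords[probe_mol.h1] - po, frame.box)
    coords[2] = po + minimum_image(frame.coords[probe_mol.h2] - po, frame.box)
    elements = np.array(["O", "H", "H"] * len(mols), dtype=object)
    source = np.array([i for m in mols for i in m.indices])
    return Cluster(elements, coords, n1, time_ps=frame.time_ps, replica=replica,
                   source_indices=source)


def snapshot_schedule(
    replicas: int, usable_length_ps: float, stride_fs: float
) -> list[tuple[int, float]]:
    """Times at which snapshots are extracted, per replica.

    Within each replica the schedule is stride, 2·stride, …, up to the
    usable length. 12 replicas × 50 ps at a 50 fs stride give the
    conventional 12,000 snapshots.
    """
    if replicas <= 0 or usable_length_ps <= 0 or stride_fs <= 0:
        raise ValueError("replicas, usable_length_ps and stride_fs must be positive")
    total_fs = usable_length_ps * 1000.0
    n_per = int(math.floor(total_fs / stride_fs + 1e-9))
    if abs(n_per * stride_fs - total_fs) > 1e-6 * stride_fs:
        warnings.warn(
            f"stride {stride_fs} fs does not divide {usable_length_ps} ps; "
            f"truncating to {n_per} snapshots per replica",
            stacklevel=2,
        )
    return [(r, (k + 1) * stride_fs / 1000.0) for r in range(replicas) for k in range(n_per)]
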