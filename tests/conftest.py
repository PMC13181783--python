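"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own geometry helpers:
periodic distances are computed by explicit enumeration of the 27
neighbouring images, so cluster/coordination tests compare two independent
routes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mdifm.frames import Frame
from mdifm.kubo import SyntheticBoxParams, generate_water_box
from mdifm.shells import ProbeSpec, ShellCutoffs, WaterMolecule, perceive_waters

IMAGE_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    """Min distance between a and b over the 27 periodic images (oracle)."""
    d = np.linalg.norm(b + IMAGE_SHIFTS * box - a, axis=1)
    return float(d.min())


def single_water_frame(box: float = 20.0) -> Frame:
    """One intact water: O at the origin, H at 0.96 Å, H bent at 104.5°."""
    theta = np.deg2rad(104.5)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.96, 0.0, 0.0],
        [0.96 * np.cos(theta), 0.96 * np.sin(theta), 0.0],
    ]) + box / 2
    return Frame(np.array(["O", "H", "H"], dtype=object), coords, np.full(3, box))


@pytest.fixture
def water_box():
    """A 200-water random box at bulk density (deterministic)."""
    return generate_water_box(SyntheticBoxParams(seed=42))


@pytest.fixture
def small_box():
    """A 60-water box small enough for exhaustive oracles."""
    return generate_water_box(SyntheticBoxParams(n_waters=60, box_length=12.2, seed=7))


@pytest.fixture
def probe_and_waters(small_box):
    waters = perceive_waters(small_box)
    return ProbeSpec(waters[0], waters[0].h1), waters


def fake_water_frame(o_positions: np.ndarray, box: np.ndarray) -> tuple[Frame, list[WaterMolecule]]:
    """Frame with waters at prescribed oxygen positions (H's are dummies).

    Used for RDF tests where only O–O geometry matters; the matching
    WaterMolecule list is returned so perception can be bypassed.
    """
    n = len(o_positions)
    coords = np.empty((3 * n, 3))
    coords[0::3] = o_positions
    coords[1::3] = o_positions + np.array([0.76, 0.0, 0.0])
    coords[2::3] = o_positions + np.array([-0.19, 0.73, 0.0])
    elements = np.array(["O", "H", "H"] * n, dtype=object)
    waters = [WaterMolecule(3 * i, 3 * i + 1, 3 * i + 2) for i in range(n)]
    return Frame(elements, coords, box), waters
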