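"""Shared fixtures: normalized synthetic structures and cached envelopes."""

from __future__ import annotations

import numpy as np
import pytest

from dhtopo.structure_model import (
    classify_nonpolar_groups,
    place_amide_hydrogens,
)
from dhtopo.surface_topography import build_envelope, estimate_theta
from dhtopo.synthetic_data import make_cavity_surface, make_helix


def normalize(structure):
    place_amide_hydrogens(structure)
    classify_nonpolar_groups(structure)
    return structure


@pytest.fixture(scope="session")
def helix12():
    return normalize(make_helix(12))


@pytest.fixture(scope="session")
def cavity_225_envelope():
    """Closed pit of curvature radius 2.25 Å with estimated θ (cached)."""
    structure = make_cavity_surface(2.25)
    env = build_envelope(structure, point_spacing=0.4)
    estimate_theta(env)
    return structure, env


@pytest.fixture(scope="session")
def flat_slab_envelope():
    structure = make_cavity_surface(0.0, flat=True)
    env = build_envelope(structure)
    estimate_theta(env)
    return structure, env


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation matrix via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
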