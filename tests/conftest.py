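from __future__ import annotations

import io

import numpy as np
import pytest

import mdcoord as m
from mdcoord.synthetic import _rotation_about_axis


MINIMAL_PDB = """\
TITLE     two-atom fixture
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.500  -1.250   0.125  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB AALA A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      3  CB BALA A   1       1.200   0.000   0.000  0.50  0.00           C
ATOM      4  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      5  CG AGLY A   2       4.800   0.000   0.000  0.50  0.00           C
ATOM      6  CG CGLY A   2       5.000   0.000   0.000  0.50  0.00           C
END
"""


@pytest.fixture
def minimal_structure():
    return m.read_structure(io.StringIO(MINIMAL_PDB))


@pytest.fixture(scope="session")
def two_domain():
    return m.make_two_domain_structure()


@pytest.fixture(scope="session")
def two_domain_selections(two_domain):
    return (m.resolve_selection(two_domain, "chain A"),
            m.resolve_selection(two_domain, "chain B"))


@pytest.fixture(scope="session")
def hinge_trajectory(two_domain):
    spec = m.HingeSpec(structure=two_domain,
                       domain_b_indices=tuple(range(40, 80)),
                       axis_point=(0.0, 0.0, 0.0), axis_dir=(1.0, 0.0, 0.0),
                       amplitude_deg=30.0, n_frames=80, seed=11)
    return m.generate_hinge_trajectory(spec)


def make_switch_fixture(p_a=0.7, n_frames=200, seed=3, n_res=10):
    """Two-state switch with an internal (non-rigid) rotamer-like change:
    the last four residues rotated 120 degrees about z through residue 6."""
    base = m.make_calpha_chain(n_res)
    R = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), np.deg2rad(120.0))
    conf_b = base.coords.copy()
    pivot = conf_b[n_res // 2].copy()
    conf_b[n_res // 2 + 1:] = (conf_b[n_res // 2 + 1:] - pivot) @ R.T + pivot
    spec = m.SwitchSpec(conformer_a=base.coords, conformer_b=conf_b,
                        p_a=p_a, n_frames=n_frames, seed=seed)
    return m.generate_switch_trajectory(spec)


@pytest.fixture
def switch_fixture():
    return make_switch_fixture()


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation from a random axis and angle."""
    axis = rng.standard_normal(3)
    return _rotation_about_axis(axis, rng.uniform(0, 2 * np.pi))
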