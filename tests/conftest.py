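"""Shared fixtures and independent oracles."""

import math

import numpy as np
import pytest

from pmm_spectra.electronic_states import UnperturbedStates
from pmm_spectra.environment_field import ChargeFrame
from pmm_spectra.units import NM_TO_BOHR


@pytest.fixture
def two_state():
    """Minimal 2-level system: gap 0.105 Hartree, x-polarized transition."""
    dip = np.zeros((3, 2, 2))
    dip[0, 0, 1] = dip[0, 1, 0] = 1.5
    return UnperturbedStates(
        energies=np.array([0.0, 0.105]), dipoles=dip, total_charge=0, label="toy"
    )


def random_states(rng, n_states=11, label="rand"):
    """Random valid fixture: sorted energies, symmetric dipoles with only
    row/column 0 and the diagonal populated. Transition dipoles are kept at
    a modest 0.3 a.u. scale so second-order Stark terms stay well below the
    first-order tolerances probed by the weak-field tests."""
    energies = np.concatenate([[0.0], np.sort(rng.uniform(0.08, 0.4, n_states - 1))])
    dip = np.zeros((3, n_states, n_states))
    for a in range(3):
        row = rng.normal(0.0, 0.3, n_states - 1)
        dip[a, 0, 1:] = row
        dip[a, 1:, 0] = row
        dip[a, np.arange(n_states), np.arange(n_states)] = rng.normal(0.0, 1.0, n_states)
    return UnperturbedStates(energies=energies, dipoles=dip, label=label)


def random_charge_frame(rng, n_charges=50, qc=None):
    qc = np.zeros(3) if qc is None else np.asarray(qc, float)
    u = rng.normal(size=(n_charges, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(0.3, 2.0, n_charges)
    return ChargeFrame(
        positions=qc + u * r[:, None],
        charges=rng.uniform(-0.5, 0.5, n_charges),
        atom_ids=np.arange(n_charges),
        residue_ids=np.arange(n_charges) // 5,
        residue_names=["R%d" % (i // 5) for i in range(n_charges)],
        atom_names=["A%d" % i for i in range(n_charges)],
        qc_point=qc,
    )


def coulomb_brute_force(frame, subset=None):
    """Independent extended-precision Coulomb sum (math.fsum over a scalar loop)."""
    idx = range(frame.n_atoms) if subset is None else subset
    v_terms, ex, ey, ez = [], [], [], []
    for i in idx:
        dx = (frame.qc_point[0] - frame.positions[i, 0]) * NM_TO_BOHR
        dy = (frame.qc_point[1] - frame.positions[i, 1]) * NM_TO_BOHR
        dz = (frame.qc_point[2] - frame.positions[i, 2]) * NM_TO_BOHR
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        q = frame.charges[i]
        v_terms.append(q / r)
        ex.append(q * dx / r**3)
        ey.append(q * dy / r**3)
        ez.append(q * dz / r**3)
    return math.fsum(v_terms), np.array(
        [math.fsum(ex), math.fsum(ey), math.fsum(ez)]
    )


def torsion_oracle(p0, p1, p2, p3):
    """Independent signed torsion via the projection (praxeolitic) formulation."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))
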