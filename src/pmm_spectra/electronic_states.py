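"""Unperturbed electronic reference states of the quantum center.

The quantum center (here the lumiflavin / isoalloxazine chromophore) is
described by a truncated basis of gas-phase electronic eigenstates: state
energies plus the dipole operator expressed in that basis. These are the
quantities a TD-DFT calculation would deliver; this module only models,
validates and (de)serializes them — it never runs electronic structure.

Conventions
-----------
* Energies in Hartree, ground state first; only differences matter, so
  fixture files may set the ground-state energy to zero.
* Dipole matrix elements in atomic units, one symmetric ``n_states x
  n_states`` matrix per Cartesian axis, with origin at the quantum-center
  center of mass (the expansion point of the environment potential/field).
* Excited-to-excited transition dipoles are neglected: off-diagonal elements
  between two excited states must be exactly zero (within 1e-10); only row
  and column 0 (ground-to-excited transition dipoles) and the diagonal
  (permanent dipoles) may be nonzero. Files carrying such terms are rejected
  at validation rather than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, ValidationError

_FORMAT_MAGIC = "PMMSTATES"
_FORMAT_VERSION = 1

#: absolute tolerance for dipole-matrix symmetry and excited-excited zeroing (a.u.)
DIPOLE_ATOL = 1e-10

AXES = ("x", "y", "z")


@dataclass
class UnperturbedStates:
    """Electronic reference of the quantum center.

    Parameters
    ----------
    energies : (n_states,) array, Hartree, ground first, non-decreasing.
    dipoles : (3, n_states, n_states) array, a.u.; ``dipoles[a]`` is the
        dipole-operator matrix along axis ``a`` in the state basis.
    total_charge : net charge of the quantum center, elementary charges.
    label : free-text conformer id (e.g. ``"B1"``).
    """

    energies: np.ndarray
    dipoles: np.ndarray
    total_charge: int = 0
    label: str = ""

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        self.validate()

    @property
    def n_states(self) -> int:
        return self.energies.shape[0]

    @property
    def n_excited(self) -> int:
        return self.n_states - 1

    def validate(self) -> None:
        if self.energies.ndim != 1 or self.energies.shape[0] < 2:
            raise ValidationError("energies must be a vector of >= 2 states")
        n = self.n_states
        if self.dipoles.shape != (3, n, n):
            raise ValidationError(
                f"dipoles must have shape (3, {n}, {n}), got {self.dipoles.shape}"
            )
        if not np.all(np.isfinite(self.energies)) or not np.all(np.isfinite(self.dipoles)):
            raise ValidationError("energies and dipoles must be finite")
        if np.any(np.diff(self.energies) < 0):
            raise ValidationError("energies must be sorted non-decreasing (ground first)")
        for a, name in enumerate(AXES):
            d = self.dipoles[a]
            if not np.allclose(d, d.T, rtol=0.0, atol=DIPOLE_ATOL):
                raise ValidationError(
                    f"dipole matrix along {name} is asymmetric beyond {DIPOLE_ATOL} a.u."
                )
            off = d[1:, 1:].copy()
            np.fill_diagonal(off, 0.0)
            if np.any(np.abs(off) > DIPOLE_ATOL):
                i, j = np.unravel_index(np.argmax(np.abs(off)), off.shape)
                raise ValidationError(
                    "excited-to-excited transition dipoles must be zero; "
                    f"found {name}[{i + 1},{j + 1}] = {off[i, j]:g} a.u."
                )
        if self.total_charge != int(self.total_charge):
            raise ValidationError("total_charge must be an integer")

    # convenience views -------------------------------------------------
    @property
    def excitation_energies(self) -> np.ndarray:
        """Unperturbed vertical excitation energies, Hartree, shape (n_excited,)."""
        return self.energies[1:] - self.energies[0]

    @property
    def transition_dipoles(self) -> np.ndarray:
        """Ground-to-excited transition dipoles, a.u., shape (n_excited, 3)."""
        return self.dipoles[:, 0, 1:].T.copy()

    @property
    def permanent_dipoles(self) -> np.ndarray:
        """State permanent dipoles, a.u., shape (n_states, 3)."""
        return np.einsum("aii->ia", self.dipoles).copy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, UnperturbedStates):
            return NotImplemented
        return (
            self.label == other.label
            and self.total_charge == other.total_charge
            and np.array_equal(self.energies, other.energies)
            and np.array_equal(self.dipoles, other.dipoles)
        )


def write_states(states: UnperturbedStates, path) -> None:
    """Serialize to the plain-text fixture format (bit-exact round trip).

    Floats are written with ``repr`` precision (17 significant digits), which
    reconstructs the identical IEEE-754 double on read.
    """
    lines = [f"# {_FORMAT_MAGIC} {_FORMAT_VERSION}"]
    lines.append(f"N_STATES {states.n_states}")
    lines.append(f"CHARGE {int(states.total_charge)}")
    lines.append(f"LABEL {states.label}")
    for i, e in enumerate(states.energies):
        lines.append(f"ENERGY {i} {float(e)!r}")
    for a, name in enumerate(AXES):
        d = states.dipoles[a]
        # upper triangle incl. diagonal suffices (symmetric matrices)
        for i in range(states.n_states):
            for j in range(i, states.n_states):
                if d[i, j] != 0.0:
                    lines.append(f"DIPOLE {name} {i} {j} {float(d[i, j])!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_states(path) -> UnperturbedStates:
    """Parse and validate a states fixture file."""
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw or not raw[0].startswith(f"# {_FORMAT_MAGIC}"):
        raise ParseError(f"{path}: missing '{_FORMAT_MAGIC}' header line")
    n_states = None
    charge = 0
    label = ""
    energies: dict[int, float] = {}
    dipole_records: list[tuple[str, int, int, float]] = []
    for lineno, line in enumerate(raw[1:], start=2):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tok = line.split()
        key = tok[0]
        try:
            if key == "N_STATES":
                n_states = int(tok[1])
            elif key == "CHARGE":
                charge = int(tok[1])
            elif key == "LABEL":
                label = tok[1] if len(tok) > 1 else ""
            elif key == "ENERGY":
                energies[int(tok[1])] = float(tok[2])
            elif key == "DIPOLE":
                axis, i, j, v = tok[1], int(tok[2]), int(tok[3]), float(tok[4])
                if axis not in AXES:
                    raise ParseError(f"{path}:{lineno}: unknown axis '{axis}'")
                dipole_records.append((axis, i, j, v))
            else:
                raise ParseError(f"{path}:{lineno}: unknown record '{key}'")
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed record '{line}'") from exc
    if n_states is None:
        raise ParseError(f"{path}: missing N_STATES record")
    if sorted(energies) != list(range(n_states)):
        raise ParseError(f"{path}: ENERGY records do not cover states 0..{n_states - 1}")
    evec = np.array([energies[i] for i in range(n_states)])
    dip = np.zeros((3, n_states, n_states))
    for axis, i, j, v in dipole_records:
        a = AXES.index(axis)
        if not (0 <= i < n_states and 0 <= j < n_states):
            raise ParseError(f"{path}: DIPOLE index ({i},{j}) out of range")
        dip[a, i, j] = v
        dip[a, j, i] = v
    return UnperturbedStates(energies=evec, dipoles=dip, total_charge=charge, label=label)
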