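"""Perturbed matrix method: per-frame electronic Hamiltonians.

For each trajectory frame the electronic Hamiltonian of the quantum center is
perturbed by the environment's electrostatic potential V and field E at the
expansion point,

    H = H0 + I q V + Z,      Z[j,j'] = -E . <phi_j | mu | phi_j'>,

with H0 the diagonal matrix of unperturbed state energies, q the net charge
of the quantum center and mu the dipole operator in the unperturbed basis.
Short-range terms beyond the dipole coupling are deliberately omitted (the
type signature leaves no hook for them). Diagonalizing H per frame yields
perturbed transition energies and, by rotating the dipole matrices into the
perturbed eigenbasis, perturbed transition dipoles — the ingredients of the
ensemble spectrum.

The Born-Oppenheimer bookkeeping (one electronic reference per conformational
basin, never interpolated) lives in :func:`pmm_trajectory`, which maps a
per-frame conformer label to its reference states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .electronic_states import UnperturbedStates
from .environment_field import FrameEnvironment
from .errors import ConfigurationError, NumericError, ValidationError
from .units import HARTREE_TO_EV


@dataclass
class PerturbedFrameResult:
    """Eigen-solution of the perturbed Hamiltonian for one frame.

    ``eigenvectors`` columns are the perturbed states expressed in the
    unperturbed basis; ``transition_energies`` are differences to the
    perturbed ground state (Hartree); ``transition_dipoles`` has shape
    ``(n_excited, 3)`` in a.u.
    """

    frame_index: int
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    transition_energies: np.ndarray
    transition_dipoles: np.ndarray
    conformer_label: str = ""

    @property
    def transition_strengths(self) -> np.ndarray:
        """|mu_0n|^2 per excited state, a.u."""
        return np.sum(self.transition_dipoles**2, axis=1)


def build_perturbed_hamiltonian(
    states: UnperturbedStates, env: FrameEnvironment
) -> np.ndarray:
    """H[j,j'] = delta_jj' (E_j + q V) - sum_a E_a * mu_a[j,j']  (Hartree)."""
    E = np.asarray(env.E, dtype=float)
    if E.shape != (3,):
        raise ValidationError(f"field must be a 3-vector, got shape {E.shape}")
    H = np.diag(states.energies + states.total_charge * env.V)
    H -= np.einsum("a,ajk->jk", E, states.dipoles)
    return H


def diagonalize_frame(
    states: UnperturbedStates, env: FrameEnvironment
) -> PerturbedFrameResult:
    """Diagonalize the perturbed Hamiltonian and rotate the dipole operator.

    Eigenvalues come out ascending (so transition energies are positive and
    ascending); the eigenvector sign convention — largest-magnitude component
    positive — makes runs bit-reproducible even near degeneracies.
    """
    H = build_perturbed_hamiltonian(states, env)
    try:
        w, C = np.linalg.eigh(H)
    except np.linalg.LinAlgError as exc:
        raise NumericError(
            f"eigensolver failed on frame {env.frame_index}: {exc}"
        ) from exc
    # deterministic sign: largest-|component| entry of each eigenvector positive
    idx = np.argmax(np.abs(C), axis=0)
    signs = np.sign(C[idx, np.arange(C.shape[1])])
    signs[signs == 0] = 1.0
    C = C * signs
    # perturbed dipoles: mu~_0n,a = c_0^T mu_a c_n
    c0 = C[:, 0]
    mu0n = np.einsum("j,ajk,kn->na", c0, states.dipoles, C[:, 1:])
    return PerturbedFrameResult(
        frame_index=env.frame_index,
        eigenvalues=w,
        eigenvectors=C,
        transition_energies=w[1:] - w[0],
        transition_dipoles=mu0n,
        conformer_label=states.label,
    )


def pmm_trajectory(
    states_by_label: Mapping[str, UnperturbedStates],
    envs: Sequence[FrameEnvironment],
    labels: Sequence[str] | None = None,
) -> list[PerturbedFrameResult]:
    """Per-frame diagonalization with basin-dependent reference states.

    ``labels`` selects the electronic reference per frame; when omitted and a
    single reference is supplied, it is used throughout.
    """
    envs = list(envs)
    if labels is None:
        if len(states_by_label) != 1:
            raise ConfigurationError(
                "labels required when more than one reference state set is given"
            )
        only = next(iter(states_by_label))
        labels = [only] * len(envs)
    labels = list(labels)
    if len(labels) != len(envs):
        raise ConfigurationError(
            f"{len(labels)} labels for {len(envs)} frames"
        )
    missing = sorted(set(labels) - set(states_by_label))
    if missing:
        raise ConfigurationError(
            f"no reference states for conformer label(s): {', '.join(missing)}"
        )
    out = []
    for env, lab in zip(envs, labels):
        res = diagonalize_frame(states_by_label[lab], env)
        res.conformer_label = lab
        out.append(res)
    return out


def results_table(results: Sequence[PerturbedFrameResult]) -> pd.DataFrame:
    """Columnar view: frame, label, nu_0n (eV, unscaled), |mu_0n|^2 (a.u.)."""
    rows = []
    for r in results:
        row = {"frame": r.frame_index, "label": r.conformer_label}
        for n, (nu, s2) in enumerate(
            zip(r.transition_energies, r.transition_strengths), start=1
        ):
            row[f"nu_0{n}_eV"] = nu * HARTREE_TO_EV
            row[f"mu2_0{n}_au"] = s2
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(results: Sequence[PerturbedFrameResult], path) -> None:
    results_table(results).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> list[PerturbedFrameResult]:
    """Rebuild spectroscopy-sufficient results from a columnar table.

    The table stores per-transition energies (eV) and |mu_0n|^2 only, so the
    reconstructed results carry the squared norm on one dipole axis and no
    eigenvectors — exactly what spectrum assembly consumes.
    """
    df = pd.read_csv(path, sep="\t")
    nu_cols = sorted(
        (c for c in df.columns if c.startswith("nu_0")),
        key=lambda c: int(c.split("_")[1][1:]),
    )
    mu_cols = sorted(
        (c for c in df.columns if c.startswith("mu2_0")),
        key=lambda c: int(c.split("_")[1][1:]),
    )
    if not nu_cols or len(nu_cols) != len(mu_cols):
        raise ValidationError(f"{path}: not a PMM results table")
    out = []
    for row in df.itertuples(index=False):
        nu = np.array([getattr(row, c) for c in nu_cols]) / HARTREE_TO_EV
        mu2 = np.array([getattr(row, c) for c in mu_cols])
        dip = np.zeros((len(nu), 3))
        dip[:, 0] = np.sqrt(mu2)
        out.append(
            PerturbedFrameResult(
                frame_index=int(row.frame),
                eigenvalues=np.concatenate([[0.0], nu]),
                eigenvectors=np.empty((0, 0)),
                transition_energies=nu,
                transition_dipoles=dip,
                conformer_label=str(row.label),
            )
        )
    return out
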