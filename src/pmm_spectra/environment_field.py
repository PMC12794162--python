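"""Electrostatic potential and field of a point-charge environment.

Each trajectory frame carries the environment as point charges; the
perturbation entering the electronic Hamiltonian is the Coulomb potential V
and field E that those charges exert at the quantum-center expansion point
(its center of mass). Sums are direct (no periodic images / Ewald): the
perturbation acts on the explicit atoms provided, optionally truncated by an
inclusion cutoff.

Charge-counterfactual edits (e.g. neutralizing an arginine-like side chain,
deprotonating a cysteine-like one) replace the partial charges of a residue
selection while leaving geometry untouched, so baseline and edited analyses
differ only through V and E.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ParseError, SelectionError, ValidationError
from .units import NM_TO_BOHR

#: minimum allowed charge-to-expansion-point distance (nm)
DEFAULT_CLASH_CUTOFF_NM = 0.05


@dataclass
class ChargeFrame:
    """One frame of the point-charge environment (positions in nm, charges in e)."""

    positions: np.ndarray          # (n_atoms, 3), nm
    charges: np.ndarray            # (n_atoms,), elementary charges
    atom_ids: np.ndarray           # (n_atoms,), int
    residue_ids: np.ndarray        # (n_atoms,), int
    residue_names: list            # (n_atoms,), str
    qc_point: np.ndarray           # (3,), nm — expansion point (QC center of mass)
    atom_names: list | None = None # optional per-atom names for selections

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        self.atom_ids = np.asarray(self.atom_ids, dtype=int).ravel()
        self.residue_ids = np.asarray(self.residue_ids, dtype=int).ravel()
        self.residue_names = list(self.residue_names)
        self.qc_point = np.asarray(self.qc_point, dtype=float).reshape(3)
        n = len(self.positions)
        for name, arr in (
            ("charges", self.charges),
            ("atom_ids", self.atom_ids),
            ("residue_ids", self.residue_ids),
            ("residue_names", self.residue_names),
        ):
            if len(arr) != n:
                raise ValidationError(f"{name} has length {len(arr)}, expected {n}")
        if self.atom_names is not None:
            self.atom_names = list(self.atom_names)
            if len(self.atom_names) != n:
                raise ValidationError("atom_names length mismatch")
        if n == 0:
            raise ValidationError("ChargeFrame needs at least one atom")
        d = np.linalg.norm(self.positions - self.qc_point, axis=1)
        if np.any(d <= 0.0):
            raise ValidationError("an environment atom coincides with qc_point")

    @property
    def n_atoms(self) -> int:
        return len(self.charges)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


@dataclass
class FrameEnvironment:
    """Perturbation at the expansion point for one frame (atomic units)."""

    frame_index: int
    V: float                       # potential, a.u.
    E: np.ndarray                  # field 3-vector, a.u.
    d1: float | None = None        # bending coordinate, degrees (optional)

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.E)) or not np.isfinite(self.V):
            raise ValidationError(f"frame {self.frame_index}: non-finite V or E")

    @classmethod
    def zero(cls, frame_index: int = 0, d1: float | None = None) -> "FrameEnvironment":
        return cls(frame_index=frame_index, V=0.0, E=np.zeros(3), d1=d1)


@dataclass
class ChargeEdit:
    """Replacement of side-chain partial charges for a residue.

    ``residue_id`` of ``None`` is a wildcard (all residues with the name);
    ``atom_selection`` of ``None`` selects every atom of the residue.
    ``new_charges`` is given per selected atom (in selection order) and must
    change the selection's total charge by an integer.
    """

    residue_name: str
    new_charges: Sequence[float]
    residue_id: int | None = None
    atom_selection: Sequence[str] | None = None


def site_potential_field(
    frame: ChargeFrame,
    clash_cutoff_nm: float = DEFAULT_CLASH_CUTOFF_NM,
    inclusion_cutoff_nm: float | None = None,
    frame_index: int = 0,
    d1: float | None = None,
) -> FrameEnvironment:
    """Direct Coulomb sum at the expansion point.

    V = sum_i q_i / r_i,  E = sum_i q_i (r_qc - r_i) / r_i^3   (a.u., r in Bohr)

    Raises :class:`GeometryError` if any charge sits closer than
    ``clash_cutoff_nm`` to the expansion point. ``inclusion_cutoff_nm``
    optionally drops charges beyond a radius (default: include all).
    """
    dvec_nm = frame.qc_point[None, :] - frame.positions      # r_qc - r_i
    dist_nm = np.linalg.norm(dvec_nm, axis=1)
    if np.any(dist_nm < clash_cutoff_nm):
        i = int(np.argmin(dist_nm))
        raise GeometryError(
            f"frame {frame_index}: atom {frame.atom_ids[i]} at {dist_nm[i]:.4f} nm "
            f"from the expansion point (clash cutoff {clash_cutoff_nm} nm)"
        )
    q = frame.charges
    if inclusion_cutoff_nm is not None:
        keep = dist_nm <= inclusion_cutoff_nm
        q = q[keep]
        dvec_nm = dvec_nm[keep]
        dist_nm = dist_nm[keep]
    r = dist_nm * NM_TO_BOHR
    dvec = dvec_nm * NM_TO_BOHR
    V = float(np.sum(q / r))
    E = (q / r**3) @ dvec
    return FrameEnvironment(frame_index=frame_index, V=V, E=E, d1=d1)


def _edit_mask(frame: ChargeFrame, edit: ChargeEdit) -> np.ndarray:
    mask = np.array([rn == edit.residue_name for rn in frame.residue_names])
    if edit.residue_id is not None:
        mask &= frame.residue_ids == edit.residue_id
    if edit.atom_selection is not None:
        if frame.atom_names is None:
            raise SelectionError(
                "edit selects atoms by name but the frame carries no atom_names"
            )
        wanted = set(edit.atom_selection)
        mask &= np.array([an in wanted for an in frame.atom_names])
    return mask


def apply_charge_edit(frame: ChargeFrame, edit: ChargeEdit) -> ChargeFrame:
    """Return a frame with the selection's charges replaced (geometry untouched)."""
    mask = _edit_mask(frame, edit)
    n_sel = int(mask.sum())
    if n_sel == 0:
        raise SelectionError(
            f"charge edit matched no atoms (residue {edit.residue_name}"
            f"{'' if edit.residue_id is None else ' ' + str(edit.residue_id)})"
        )
    new = np.asarray(edit.new_charges, dtype=float).ravel()
    if len(new) != n_sel:
        raise ValidationError(
            f"edit provides {len(new)} charges for {n_sel} selected atoms"
        )
    delta = float(new.sum() - frame.charges[mask].sum())
    if abs(delta - round(delta)) > 1e-6:
        raise ValidationError(
            f"net charge change {delta:+.6f} is not an integer within 1e-6"
        )
    charges = frame.charges.copy()
    charges[mask] = new
    return replace(frame, charges=charges)


def environment_trajectory(
    frames: Iterable[ChargeFrame],
    clash_cutoff_nm: float = DEFAULT_CLASH_CUTOFF_NM,
    inclusion_cutoff_nm: float | None = None,
) -> list[FrameEnvironment]:
    """Per-frame :func:`site_potential_field` over a trajectory (order preserving)."""
    frames = list(frames)
    if not frames:
        raise ValidationError("environment_trajectory: empty frame sequence")
    out = []
    for i, fr in enumerate(frames):
        out.append(
            site_potential_field(
                fr,
                clash_cutoff_nm=clash_cutoff_nm,
                inclusion_cutoff_nm=inclusion_cutoff_nm,
                frame_index=i,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O: columnar charge-frame trajectories and precomputed (V, E, d1) tables
# ---------------------------------------------------------------------------

def write_charge_frames(frames: Sequence[ChargeFrame], path) -> None:
    """Plain-text frame blocks: QC line then one line per atom."""
    with open(path, "w") as fh:
        fh.write("# PMMCHARGES 1\n")
        fh.write("# FRAME i / QC x y z (nm) / atom_id res_id res_name atom_name x y z q\n")
        for i, fr in enumerate(frames):
            fh.write(f"FRAME {i}\n")
            fh.write("QC {:.10g} {:.10g} {:.10g}\n".format(*fr.qc_point))
            names = fr.atom_names or ["X"] * fr.n_atoms
            for a in range(fr.n_atoms):
                x, y, z = fr.positions[a]
                fh.write(
                    f"{fr.atom_ids[a]} {fr.residue_ids[a]} {fr.residue_names[a]} "
                    f"{names[a]} {float(x)!r} {float(y)!r} {float(z)!r} "
                    f"{float(fr.charges[a])!r}\n"
                )


def read_charge_frames(path) -> list[ChargeFrame]:
    frames: list[ChargeFrame] = []
    cur: dict | None = None

    def _flush():
        if cur is None:
            return
        if cur["qc"] is None:
            raise ParseError(f"{path}: frame {cur['index']} has no QC line")
        frames.append(
            ChargeFrame(
                positions=np.array(cur["pos"]),
                charges=np.array(cur["q"]),
                atom_ids=np.array(cur["aid"]),
                residue_ids=np.array(cur["rid"]),
                residue_names=cur["rname"],
                atom_names=cur["aname"],
                qc_point=np.array(cur["qc"]),
            )
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "FRAME":
                _flush()
                cur = {"index": int(tok[1]), "qc": None, "pos": [], "q": [],
                       "aid": [], "rid": [], "rname": [], "aname": []}
            elif tok[0] == "QC":
                if cur is None:
                    raise ParseError(f"{path}:{lineno}: QC line before any FRAME")
                cur["qc"] = [float(v) for v in tok[1:4]]
            else:
                if cur is None:
                    raise ParseError(f"{path}:{lineno}: atom line before any FRAME")
                try:
                    cur["aid"].append(int(tok[0]))
                    cur["rid"].append(int(tok[1]))
                    cur["rname"].append(tok[2])
                    cur["aname"].append(tok[3])
                    cur["pos"].append([float(tok[4]), float(tok[5]), float(tok[6])])
                    cur["q"].append(float(tok[7]))
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed atom line") from exc
    _flush()
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def write_environments(envs: Sequence[FrameEnvironment], path) -> None:
    """Columnar (frame, V, Ex, Ey, Ez, d1) table; d1 blank when absent."""
    df = pd.DataFrame(
        {
            "frame": [e.frame_index for e in envs],
            "V": [e.V for e in envs],
            "Ex": [e.E[0] for e in envs],
            "Ey": [e.E[1] for e in envs],
            "Ez": [e.E[2] for e in envs],
            "d1": [np.nan if e.d1 is None else e.d1 for e in envs],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_environments(path) -> list[FrameEnvironment]:
    df = pd.read_csv(path, sep="\t")
    required = {"frame", "V", "Ex", "Ey", "Ez"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df["frame"].duplicated().any():
        raise ValidationError(f"{path}: duplicate frame indices")
    out = []
    for row in df.itertuples(index=False):
        d1 = getattr(row, "d1", np.nan)
        out.append(
            FrameEnvironment(
                frame_index=int(row.frame),
                V=float(row.V),
                E=np.array([row.Ex, row.Ey, row.Ez]),
                d1=None if pd.isna(d1) else float(d1),
            )
        )
    return out
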