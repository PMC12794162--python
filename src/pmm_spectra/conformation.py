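"""Conformational analysis of the isoalloxazine ring.

Three tools:

* signed torsion angles, plus the butterfly *bend angle* d1 derived from the
  C4-N5-N10-C9 torsion. For a planar fused tricycle that raw torsion is 180
  degrees; the crystallographic convention quotes the *deviation from
  planarity* (planar = 0, bent crystal structures 11.7-17.4 degrees), so
  d1 = wrap(180 - torsion). Its magnitude is the bend, its sign the pucker
  direction.
* basin classification on |d1| with thresholds (6, 12) degrees: planar,
  partially bent (closed interval [6, 12]), bent — and the basin populations
  that weight the ensemble spectra.
* essential dynamics: PCA of the covariance matrix of the positional
  fluctuations of the ring C/N atoms, after least-squares superposition onto
  the mean structure. The leading eigenvector of a bending trajectory is the
  butterfly mode; projections onto it order conformers from planar to bent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeometryError, ParseError, ValidationError

#: basin thresholds on |d1|, degrees
DEFAULT_THRESHOLDS = (6.0, 12.0)

BASIN_NAMES = ("planar", "partially_bent", "bent")

#: which gas-phase conformer represents each basin
DEFAULT_REFERENCE_MAP = {
    "planar": "B1",
    "partially_bent": "B3",
    "bent": "B5",
}

#: torsion-defining atoms, in order
D1_ATOMS = ("C4", "N5", "N10", "C9")

_COLLINEAR_TOL = 1e-12


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Standard signed torsion about the p2-p3 axis, degrees in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if (
        b2n < _COLLINEAR_TOL
        or np.dot(n1, n1) < _COLLINEAR_TOL
        or np.dot(n2, n2) < _COLLINEAR_TOL
    ):
        raise GeometryError("collinear points: torsion undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / b2n
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def wrap_degrees(a):
    """Wrap angle(s) into (-180, 180]."""
    w = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return w


def bend_angle(p1, p2, p3, p4) -> float:
    """Butterfly bend d1: deviation of the torsion from planarity, degrees.

    d1 = wrap(180 - torsion); a planar arrangement (torsion 180) gives 0,
    a wing folded by beta gives ±beta.
    """
    return float(wrap_degrees(180.0 - dihedral(p1, p2, p3, p4)))


# ---------------------------------------------------------------------------
# ring trajectories
# ---------------------------------------------------------------------------

@dataclass
class RingTrajectory:
    """Coordinates of the ring C/N atoms over frames (nm)."""

    coordinates: np.ndarray        # (n_frames, n_atoms, 3), nm
    atom_names: list               # n_atoms strings; must include D1_ATOMS
    frame_indices: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError("coordinates must have shape (frames, atoms, 3)")
        self.atom_names = list(self.atom_names)
        if len(self.atom_names) != self.coordinates.shape[1]:
            raise ValidationError("atom_names length does not match atom count")
        for name in D1_ATOMS:
            if self.atom_names.count(name) != 1:
                raise ValidationError(f"atom '{name}' must appear exactly once")
        if self.frame_indices is None:
            self.frame_indices = np.arange(self.n_frames)
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)
            if len(self.frame_indices) != self.n_frames:
                raise ValidationError("frame_indices length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def atom_index(self, name: str) -> int:
        return self.atom_names.index(name)

    def d1_series(self) -> np.ndarray:
        """Bend angle d1 per frame, degrees."""
        idx = [self.atom_index(n) for n in D1_ATOMS]
        return np.array(
            [bend_angle(*frame[idx]) for frame in self.coordinates]
        )


# ---------------------------------------------------------------------------
# basins
# ---------------------------------------------------------------------------

@dataclass
class BasinAssignment:
    """Per-frame basin labels plus populations and the basin→conformer map."""

    labels: list
    thresholds: tuple
    populations: dict
    reference_map: dict = field(default_factory=lambda: dict(DEFAULT_REFERENCE_MAP))

    def __post_init__(self):
        total = sum(self.populations.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"basin populations sum to {total}, expected 1")

    def conformer_labels(self) -> list:
        """Per-frame conformer labels via the reference map (e.g. B1/B3/B5)."""
        return [self.reference_map[b] for b in self.labels]


def classify_basins(
    d1_series,
    thresholds: tuple = DEFAULT_THRESHOLDS,
    reference_map: dict | None = None,
) -> BasinAssignment:
    """Classify frames by bending magnitude |d1|.

    planar: |d1| < low; partially_bent: low <= |d1| <= high; bent: |d1| > high.
    Both boundary values fall in the middle basin (closed interval).
    """
    d1 = np.asarray(d1_series, dtype=float).ravel()
    if d1.size == 0:
        raise ValidationError("classify_basins: empty d1 series")
    low, high = thresholds
    if low >= high:
        raise ConfigurationError(f"thresholds must satisfy low < high, got {thresholds}")
    mag = np.abs(d1)
    labels = np.where(mag < low, "planar", np.where(mag <= high, "partially_bent", "bent"))
    populations = {b: float(np.mean(labels == b)) for b in BASIN_NAMES}
    return BasinAssignment(
        labels=list(labels),
        thresholds=(float(low), float(high)),
        populations=populations,
        reference_map=dict(reference_map or DEFAULT_REFERENCE_MAP),
    )


# ---------------------------------------------------------------------------
# essential dynamics
# ---------------------------------------------------------------------------

@dataclass
class EssentialModes:
    """PCA of positional fluctuations: modes, variances, per-frame projections."""

    mean_structure: np.ndarray     # (n_atoms, 3), nm
    eigenvectors: np.ndarray       # (3*n_atoms, n_modes), orthonormal columns
    eigenvalues: np.ndarray        # (n_modes,), nm^2, descending
    projections: np.ndarray        # (n_frames, n_modes), nm


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered P onto centered Q (proper rotation)."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose_frames(coords: np.ndarray, n_iter: int = 5) -> np.ndarray:
    """Least-squares superposition of every frame onto the iterated mean."""
    X = coords - coords.mean(axis=1, keepdims=True)
    ref = X[0]
    for _ in range(n_iter):
        fitted = np.empty_like(X)
        for i, fr in enumerate(X):
            R = _kabsch(fr, ref)
            fitted[i] = fr @ R.T
        new_ref = fitted.mean(axis=0)
        if np.allclose(new_ref, ref, atol=1e-14):
            X = fitted
            break
        ref = new_ref
        X = fitted
    return X


def essential_dynamics(traj: RingTrajectory, fit: bool = True) -> EssentialModes:
    """PCA of the 3N x 3N positional covariance after superposition.

    A trajectory with no fluctuations yields all-zero eigenvalues (no error).
    Eigenvalues descend; projections are onto mean-centered fitted frames, so
    the variance of projection k equals eigenvalue k.
    """
    if traj.n_frames < 2:
        raise ValidationError("essential_dynamics needs at least 2 frames")
    X = superpose_frames(traj.coordinates) if fit else traj.coordinates.copy()
    mean = X.mean(axis=0)
    flat = (X - mean).reshape(traj.n_frames, -1)
    cov = flat.T @ flat / traj.n_frames
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    # deterministic sign: largest-|component| entry positive
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    v = v * signs
    proj = flat @ v
    return EssentialModes(
        mean_structure=mean, eigenvectors=v, eigenvalues=w, projections=proj
    )


def extract_representatives(
    modes: EssentialModes,
    traj: RingTrajectory,
    targets: Sequence[float],
) -> list[int]:
    """Frames whose first-mode projection is nearest each target (ties: earliest).

    Returns positions into the trajectory (not frame_indices). Targets must
    lie inside the observed projection range.
    """
    p1 = modes.projections[:, 0]
    lo, hi = p1.min(), p1.max()
    picks = []
    for t in targets:
        if not (lo <= t <= hi):
            raise ValidationError(
                f"target projection {t} outside observed range [{lo:.4g}, {hi:.4g}]"
            )
        picks.append(int(np.argmin(np.abs(p1 - t))))  # argmin ties -> earliest
    return picks


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_d1_series(d1_series, path, frame_indices=None) -> None:
    d1 = np.asarray(d1_series, dtype=float)
    frames = np.arange(len(d1)) if frame_indices is None else np.asarray(frame_indices)
    pd.DataFrame({"frame": frames, "d1_deg": d1}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_d1_series(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if "d1_deg" not in df.columns:
        raise ParseError(f"{path}: missing 'd1_deg' column")
    return df["d1_deg"].to_numpy(dtype=float)


def write_ring_trajectory(traj: RingTrajectory, path) -> None:
    """Columnar frame blocks: atom_name x y z (nm)."""
    with open(path, "w") as fh:
        fh.write("# PMMRING 1\n")
        for i in range(traj.n_frames):
            fh.write(f"FRAME {traj.frame_indices[i]}\n")
            for name, (x, y, z) in zip(traj.atom_names, traj.coordinates[i]):
                fh.write(f"{name} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_ring_trajectory(path) -> RingTrajectory:
    names: list = []
    frames: list = []
    cur: list | None = None
    indices: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "FRAME":
                if cur is not None:
                    frames.append(cur)
                cur = []
                indices.append(int(tok[1]))
            else:
                if cur is None:
                    raise ParseError(f"{path}:{lineno}: atom line before any FRAME")
                try:
                    if len(frames) == 0:
                        names.append(tok[0])
                    cur.append([float(tok[1]), float(tok[2]), float(tok[3])])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed atom line") from exc
    if cur is not None:
        frames.append(cur)
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return RingTrajectory(
        coordinates=np.array(frames), atom_names=names, frame_indices=np.array(indices)
    )


def read_ring_trajectory_pdb(path, atom_names: Sequence[str] | None = None) -> RingTrajectory:
    """Ring trajectory from a multi-model PDB (coordinates converted Å → nm)."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure()  # AtomArrayStack, Å
    names = list(stack.atom_name[:])
    if atom_names is not None:
        keep = [i for i, n in enumerate(names) if n in set(atom_names)]
        if not keep:
            raise ParseError(f"{path}: none of the requested atoms found")
        stack = stack[..., keep]
        names = [names[i] for i in keep]
    coords = np.asarray(stack.coord, dtype=float) / 10.0
    return RingTrajectory(coordinates=coords, atom_names=names)
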