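"""Synthetic stand-ins for the MD and quantum-chemistry inputs.

Everything downstream of this module is agnostic to where its inputs come
from; here we build statistically controllable replacements for the three
expensive ingredients:

* **electronic reference states** — flavin-like 11-state fixtures whose two
  bright transitions sit at requested wavelengths with a requested intensity
  ratio, and whose permanent-dipole differences make them Stark-sensitive;
* **point-charge environments** — fluctuating shells of fictitious partial
  charges around the chromophore with a *controllable ensemble-mean field*
  (a fixed bias dipole pair cancels the random residual and steers the mean
  onto the target, verified by direct summation);
* **bending trajectories** — the butterfly coordinate d1 drawn from a
  three-component Gaussian mixture (planar / partially bent / bent basins),
  realized geometrically by folding an idealized planar isoalloxazine-like
  three-ring template about its N5-N10 axis.

The charges are fictitious (not force-field derived) and the ring template is
idealized: the analysis needs controllable statistics, not chemistry.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .electronic_states import UnperturbedStates
from .environment_field import ChargeFrame, site_potential_field
from .conformation import RingTrajectory
from .errors import ConfigurationError, FeasibilityError, ValidationError
from .flavin_reference import BASIN_CONFORMERS, GAS_PHASE_PEAKS
from .units import EV_TO_NM, HARTREE_TO_EV, NM_TO_BOHR, nm_to_hartree


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic environment and bending generators.

    Defaults are the study conditions: basin weights 0.27/0.44/0.29 with
    centers 2/9/16 degrees (inside the <6, 6-12, >12 classification windows),
    a ~200-charge shell of +-0.15 e partial charges between 0.8 and 2.5 nm
    from the chromophore, and 0.02 nm frame-to-frame positional jitter.
    """

    seed: int = 0
    n_frames: int = 1000
    n_charges: int = 200
    exclusion_radius: float = 0.8        # nm
    box_radius: float = 2.5              # nm
    charge_scale: float = 0.15           # e
    jitter_sigma: float = 0.02           # nm
    mean_field_target: tuple = (0.0, 0.0, 0.0)   # a.u.
    basin_centers: tuple = (2.0, 9.0, 16.0)      # degrees
    basin_sigmas: tuple = (1.2, 1.2, 1.2)        # degrees
    basin_weights: tuple = (0.27, 0.44, 0.29)
    # optional probe residue for charge-counterfactual experiments
    probe_residue_name: str | None = None
    probe_position: tuple = (0.0, 0.9, 0.0)      # nm
    probe_net_charge: float = 1.0                # e
    probe_n_atoms: int = 3

    def __post_init__(self):
        if abs(sum(self.basin_weights) - 1.0) > 1e-9:
            raise ConfigurationError("basin_weights must sum to 1")
        if not (0 < self.exclusion_radius < self.box_radius):
            raise ConfigurationError("need 0 < exclusion_radius < box_radius")
        if any(s <= 0 for s in self.basin_sigmas):
            raise ConfigurationError("basin_sigmas must be positive")
        if len(self.basin_centers) != 3 or len(self.basin_sigmas) != 3 or len(self.basin_weights) != 3:
            raise ConfigurationError("basin parameters must have 3 components")
        if self.n_frames < 1 or self.n_charges < 1:
            raise ConfigurationError("n_frames and n_charges must be >= 1")


# ---------------------------------------------------------------------------
# electronic-state fixtures
# ---------------------------------------------------------------------------

#: transition dipole magnitude of the first bright state, a.u.
BRIGHT_MU = 2.0

#: permanent-dipole difference (excited minus ground) along x for the two
#: bright states, a.u. — sets the Stark sensitivity of the fixtures.
DELTA_MU_BRIGHT = (3.0, 1.5)


def make_flavin_like_states(
    label: str,
    lambda1_nm: float,
    lambda2_nm: float,
    i_rel: float = 0.8,
    seed: int = 0,
    n_states: int = 11,
    total_charge: int = 0,
) -> UnperturbedStates:
    """11-state fixture with two bright transitions at given wavelengths.

    The first bright state absorbs at ``lambda1_nm`` (unscaled), the second
    at ``lambda2_nm``, with peak-height ratio ``i_rel`` (height ~ |mu|^2 nu,
    so |mu_02|^2 = i_rel |mu_01|^2 nu_1/nu_2). Remaining states are dark and
    higher in energy. Permanent-dipole differences along x make transition
    energies respond linearly to fields at first order. Deterministic under
    ``seed``.
    """
    if not (lambda1_nm > lambda2_nm > 0):
        raise ValidationError(
            f"need lambda1 > lambda2 > 0, got ({lambda1_nm}, {lambda2_nm}) nm"
        )
    if n_states < 3:
        raise ConfigurationError("need at least ground + 2 bright states")
    rng = np.random.default_rng(seed)
    e1 = nm_to_hartree(lambda1_nm)
    e2 = nm_to_hartree(lambda2_nm)
    energies = np.empty(n_states)
    energies[0] = 0.0
    energies[1] = e1
    energies[2] = e2
    n_dark = n_states - 3
    if n_dark:
        # dark manifold above the bright states, spread over ~0.2 Hartree
        energies[3:] = e2 + 0.02 + np.sort(rng.uniform(0.0, 0.2, size=n_dark))
    dip = np.zeros((3, n_states, n_states))
    mu1 = BRIGHT_MU
    mu2 = np.sqrt(i_rel * mu1**2 * e1 / e2)
    dip[0, 0, 1] = dip[0, 1, 0] = mu1                   # bright 1 polarized x
    dip[1, 0, 2] = dip[1, 2, 0] = mu2                   # bright 2 polarized y
    for k in range(3, n_states):
        a = int(rng.integers(0, 3))
        v = rng.uniform(0.02, 0.08)                      # weakly allowed
        dip[a, 0, k] = dip[a, k, 0] = v
    # permanent dipoles (diagonal): ground at origin of the expansion point
    dip[0, 1, 1] = DELTA_MU_BRIGHT[0]
    dip[0, 2, 2] = DELTA_MU_BRIGHT[1]
    for k in range(3, n_states):
        dip[0, k, k] = rng.uniform(-0.5, 0.5)
    return UnperturbedStates(
        energies=energies, dipoles=dip, total_charge=total_charge, label=label
    )


def default_conformer_states(seed: int = 0) -> dict:
    """The three basin references (B1/B3/B5) at their literature gas-phase
    peak positions and intensity ratios."""
    out = {}
    for i, lab in enumerate(sorted(set(BASIN_CONFORMERS.values()))):
        l1, l2, ir = GAS_PHASE_PEAKS[lab]
        out[lab] = make_flavin_like_states(
            lab, l1, l2, i_rel=ir, seed=seed + 7919 * (i + 1)
        )
    return out


def field_for_first_peak_shift(
    states: UnperturbedStates, shift_nm: float, scaling: float = 0.94
) -> np.ndarray:
    """Mean field (a.u.) that first-order Stark theory predicts will move the
    first peak of the *scaled* spectrum by ``shift_nm``.

    First-order shift of transition n under a field E is
    -E . (mu_nn - mu_00); the field is chosen along the fixture's
    permanent-dipole difference.
    """
    e1 = states.excitation_energies[0]
    lam0 = EV_TO_NM / (scaling * e1 * HARTREE_TO_EV)
    lam_target = lam0 + shift_nm
    if lam_target <= 0:
        raise FeasibilityError(f"target wavelength {lam_target} nm is unphysical")
    e1_target = (EV_TO_NM / lam_target) / scaling / HARTREE_TO_EV
    delta_e = e1_target - e1                                  # Hartree, <0 for red
    dmu = states.permanent_dipoles[1] - states.permanent_dipoles[0]
    norm2 = float(dmu @ dmu)
    if norm2 < 1e-12:
        raise FeasibilityError(
            "fixture has no permanent-dipole difference on state 1; "
            "no field can shift its transition at first order"
        )
    return -delta_e * dmu / norm2


# ---------------------------------------------------------------------------
# point-charge environments
# ---------------------------------------------------------------------------

#: maximum bias charge the mean-field steering may use, e
_MAX_BIAS_CHARGE = 100.0


def make_environment(config: GeneratorConfig) -> list[ChargeFrame]:
    """Fluctuating charge shell with the requested ensemble-mean field.

    A base configuration of ``n_charges`` signed charges is drawn uniformly
    in the shell [exclusion_radius, box_radius]; each frame adds Gaussian
    positional jitter. A fixed pair of opposite bias charges (zero net
    potential at the expansion point) is then appended so that the empirical
    mean field over the generated frames equals ``mean_field_target``
    exactly; the construction is verified by direct summation.
    """
    rng = np.random.default_rng(config.seed)
    target = np.asarray(config.mean_field_target, dtype=float).reshape(3)
    if np.linalg.norm(target) > 0.1:
        raise FeasibilityError(
            f"mean-field target |E| = {np.linalg.norm(target):.3g} a.u. is beyond "
            "what a molecular charge shell can plausibly exert"
        )
    qc = np.zeros(3)
    # base shell positions: uniform directions, radii uniform in volume
    u = rng.normal(size=(config.n_charges, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    a3, b3 = config.exclusion_radius**3, config.box_radius**3
    r = (a3 + (b3 - a3) * rng.random(config.n_charges)) ** (1.0 / 3.0)
    base_pos = u * r[:, None]
    charges = config.charge_scale * rng.choice([-1.0, 1.0], size=config.n_charges)
    res_ids = np.arange(1, config.n_charges + 1)
    res_names = ["ENV"] * config.n_charges
    atom_names = ["Q"] * config.n_charges
    # optional probe residue (a small cluster with a net integer charge)
    if config.probe_residue_name is not None:
        npr = config.probe_n_atoms
        offsets = 0.05 * rng.normal(size=(npr, 3))
        probe_pos = np.asarray(config.probe_position, dtype=float) + offsets
        probe_q = np.full(npr, config.probe_net_charge / npr)
        base_pos = np.vstack([base_pos, probe_pos])
        charges = np.concatenate([charges, probe_q])
        res_ids = np.concatenate([res_ids, np.full(npr, 9000)])
        res_names = res_names + [config.probe_residue_name] * npr
        atom_names = atom_names + [f"S{i + 1}" for i in range(npr)]
    n_atoms = len(charges)
    jitter = (
        rng.normal(0.0, config.jitter_sigma, size=(config.n_frames, n_atoms, 3))
        if config.jitter_sigma > 0
        else np.zeros((config.n_frames, n_atoms, 3))
    )
    positions = base_pos[None, :, :] + jitter
    # empirical mean field of the random part (a.u., direct summation)
    dvec = (qc[None, None, :] - positions) * NM_TO_BOHR
    dist = np.linalg.norm(dvec, axis=2)
    mean_E = np.einsum("fa,fab->b", charges[None, :] / dist**3, dvec) / config.n_frames
    dE = target - mean_E
    bias_pos = np.zeros((0, 3))
    bias_q = np.zeros(0)
    if np.linalg.norm(dE) > 0:
        n_hat = dE / np.linalg.norm(dE)
        d_nm = 0.5 * (config.exclusion_radius + config.box_radius)
        d_bohr = d_nm * NM_TO_BOHR
        # +Q at -d n and -Q at +d n each contribute Q/d^2 along n; V cancels
        Q = np.linalg.norm(dE) * d_bohr**2 / 2.0
        if Q > _MAX_BIAS_CHARGE:
            raise FeasibilityError(
                f"mean-field target needs a bias charge of {Q:.1f} e at "
                f"{d_nm:.2f} nm; tighten the geometry or lower the target"
            )
        bias_pos = np.array([-d_nm * n_hat, d_nm * n_hat])
        bias_q = np.array([Q, -Q])
    frames = []
    for f in range(config.n_frames):
        pos = np.vstack([positions[f], bias_pos])
        frames.append(
            ChargeFrame(
                positions=pos,
                charges=np.concatenate([charges, bias_q]),
                atom_ids=np.arange(len(pos)),
                residue_ids=np.concatenate(
                    [res_ids, np.full(len(bias_q), 9900)]
                ).astype(int),
                residue_names=res_names + ["BIA"] * len(bias_q),
                atom_names=atom_names + [f"B{i}" for i in range(len(bias_q))],
                qc_point=qc,
            )
        )
    # verification by direct summation over the emitted frames
    achieved = np.mean(
        [site_potential_field(fr, frame_index=i).E for i, fr in enumerate(frames)],
        axis=0,
    )
    scale = max(np.linalg.norm(target), 1e-12)
    if np.linalg.norm(achieved - target) > 0.02 * scale + 1e-9:
        raise FeasibilityError(
            f"mean-field steering missed the target: |err| = "
            f"{np.linalg.norm(achieved - target):.3g} a.u."
        )
    return frames


# ---------------------------------------------------------------------------
# ring template and bending trajectories
# ---------------------------------------------------------------------------

_BOND = 0.14  # nm, idealized aromatic bond

#: benzene-wing atoms folded about the N5-N10 axis
WING_ATOMS = ("C5A", "C6", "C7", "C8", "C9", "C9A")


def ring_template() -> tuple[list, np.ndarray]:
    """Idealized planar isoalloxazine-like scaffold (14 ring C/N atoms, nm).

    Three fused regular hexagons (pyrimidine / pyrazine / benzene) with
    0.14 nm bonds; only topology (atom names entering d1) matches the real
    chromophore. Returns (atom_names, coordinates (n_atoms, 3)).
    """
    s = _BOND
    h = s * np.sqrt(3.0) / 2.0
    # central (pyrazine) ring, hexagon about the origin
    atoms = {
        "C4A": (s, 0.0),
        "N5": (s / 2, h),
        "C5A": (-s / 2, h),
        "C9A": (-s, 0.0),
        "N10": (-s / 2, -h),
        "C10A": (s / 2, -h),
    }
    # pyrimidine ring fused on C4A-C10A
    atoms.update(
        {
            "C4": (2 * s, 0.0),
            "N3": (2.5 * s, -h),
            "C2": (2 * s, -2 * h),
            "N1": (s, -2 * h),
        }
    )
    # benzene ring fused on C5A-C9A
    atoms.update(
        {
            "C6": (-s, 2 * h),
            "C7": (-2 * s, 2 * h),
            "C8": (-2.5 * s, h),
            "C9": (-2 * s, 0.0),
        }
    )
    names = [
        "N1", "C2", "N3", "C4", "C4A", "N5",
        "C5A", "C6", "C7", "C8", "C9", "C9A", "N10", "C10A",
    ]
    coords = np.array([[*atoms[n], 0.0] for n in names])
    return names, coords


def bend_ring(names: Sequence[str], coords: np.ndarray, d1_deg) -> np.ndarray:
    """Fold the benzene wing about the N5→N10 axis so bend_angle(...) = d1.

    ``d1_deg`` may be a scalar (returns one structure) or a vector (returns
    a stack of frames). Distances to both axis atoms are preserved.
    """
    names = list(names)
    coords = np.asarray(coords, dtype=float)
    d1 = np.atleast_1d(np.asarray(d1_deg, dtype=float))
    n5 = coords[names.index("N5")]
    n10 = coords[names.index("N10")]
    axis = n10 - n5
    axis = axis / np.linalg.norm(axis)
    wing = np.array([names.index(a) for a in WING_ATOMS])
    rel = coords[wing] - n5
    par = (rel @ axis)[:, None] * axis
    perp = rel - par
    w = np.cross(np.broadcast_to(axis, perp.shape), perp)
    theta = -np.radians(d1)[:, None, None]  # fold direction chosen so bend_angle = +d1
    out = np.broadcast_to(coords, (d1.size, *coords.shape)).copy()
    out[:, wing, :] = (
        n5 + par + np.cos(theta) * perp + np.sin(theta) * w
    )
    return out[0] if np.isscalar(d1_deg) or np.ndim(d1_deg) == 0 else out


def make_bending_series(config: GeneratorConfig) -> tuple[np.ndarray, RingTrajectory]:
    """d1 series from the three-basin Gaussian mixture plus ring coordinates.

    Deterministic under the config seed (offset from the environment stream
    so the two generators are independent).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    comp = rng.choice(3, size=config.n_frames, p=np.asarray(config.basin_weights))
    centers = np.asarray(config.basin_centers)[comp]
    sigmas = np.asarray(config.basin_sigmas)[comp]
    d1 = rng.normal(centers, sigmas)
    names, template = ring_template()
    coords = bend_ring(names, template, d1)
    return d1, RingTrajectory(coordinates=coords, atom_names=names)
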