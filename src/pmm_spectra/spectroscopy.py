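"""Ensemble absorption spectra from perturbed-frame results.

The per-frame perturbed transition energies nu and squared transition-dipole
norms |mu_0n|^2 are histogrammed per transition; each occupied bin then
contributes a Gaussian of width sigma (inhomogeneous broadening standing in
for the neglected semiclassical vibrations) to the extinction coefficient:

    eps_0n(nu) = sum_ref |mu_0n|^2_ref * (eta_ref / N) * nu
                 * exp(-(nu - nu_ref)^2 / (2 sigma^2)) / (sigma sqrt(2 pi))

where eta_ref counts frames in the bin and |mu_0n|^2_ref is the bin mean.
All absolute prefactors (Planck constant, 1/(6 eps0 c hbar^2)) are folded
into one arbitrary-unit constant: only peak positions and relative
intensities are ever compared. An empirical multiplicative scaling factor
(default 0.94) is applied to the energies, in eV, before Gaussian placement;
it never changes relative intensities.

Peak analysis mirrors the two-band flavin spectrum: lambda1 is the red-most
of the two main peaks, lambda2 the second, and I_rel = height(lambda2) /
height(lambda1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateSpectrumError, ValidationError
from .pmm_core import PerturbedFrameResult
from .units import EV_TO_NM, HARTREE_TO_EV

#: default inhomogeneous broadening, a.u. of energy
DEFAULT_SIGMA_AU = 0.001

#: default empirical energy scaling (applied multiplicatively, in eV)
DEFAULT_SCALING = 0.94

#: default peak-search window, nm
DEFAULT_PEAK_WINDOW_NM = (300.0, 550.0)


@dataclass
class GridSpec:
    """Energy grid for spectrum evaluation (eV). Default resolves < 0.5 nm
    everywhere red of ~300 nm."""

    e_min: float = 1.7
    e_max: float = 5.0
    step: float = 0.002

    def energies(self) -> np.ndarray:
        n = int(round((self.e_max - self.e_min) / self.step)) + 1
        return self.e_min + self.step * np.arange(n)


@dataclass
class TransitionHistogram:
    """Binned (nu, |mu|^2) distribution for one transition (energies in eV,
    unscaled)."""

    centers: np.ndarray            # occupied bin centers, eV
    counts: np.ndarray             # eta per occupied bin
    mean_mu2: np.ndarray           # mean |mu_0n|^2 per occupied bin, a.u.
    n_frames: int
    transition: int                # 1-based excited-state index
    bin_width: float               # eV


@dataclass
class Spectrum:
    """Extinction spectrum on an energy grid with paired wavelengths."""

    grid: np.ndarray                       # energies, eV, strictly increasing
    epsilon_per_transition: np.ndarray     # (n_transitions, n_grid)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.epsilon_per_transition = np.atleast_2d(
            np.asarray(self.epsilon_per_transition, dtype=float)
        )
        if np.any(np.diff(self.grid) <= 0):
            raise ValidationError("spectrum grid must be strictly increasing")
        if self.epsilon_per_transition.shape[1] != self.grid.size:
            raise ValidationError("epsilon grid-length mismatch")
        if np.any(self.epsilon_per_transition < -1e-300):
            raise ValidationError("epsilon values must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        """Paired wavelengths, nm (decreasing along the grid)."""
        return EV_TO_NM / self.grid

    @property
    def epsilon_total(self) -> np.ndarray:
        return self.epsilon_per_transition.sum(axis=0)


@dataclass
class PeakReport:
    """Positions and relative intensity of the two main peaks."""

    lambda1: float                 # nm, red-most main peak
    lambda2: float                 # nm, second main peak
    I_rel: float                   # height(lambda2) / height(lambda1)
    height1: float = np.nan
    height2: float = np.nan

    def __post_init__(self):
        if not self.lambda1 > self.lambda2:
            raise ValidationError(
                f"lambda1 ({self.lambda1} nm) must be red of lambda2 ({self.lambda2} nm)"
            )
        if not self.I_rel > 0:
            raise ValidationError("I_rel must be positive")


# ---------------------------------------------------------------------------
# binning and assembly
# ---------------------------------------------------------------------------

def bin_transitions(
    results: Sequence[PerturbedFrameResult],
    n: int,
    bin_width: float | None = None,
    sigma_au: float = DEFAULT_SIGMA_AU,
) -> TransitionHistogram:
    """Histogram transition ``n`` (1-based) over frames.

    Default bin width is sigma/5 (in eV) so binning never dominates the
    Gaussian broadening. Bin counts sum to the frame count; each occupied bin
    carries the mean squared transition-dipole norm of its frames.
    """
    results = list(results)
    if not results:
        raise ValidationError("bin_transitions: empty results")
    if bin_width is None:
        bin_width = sigma_au * HARTREE_TO_EV / 5.0
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    nu = np.array([r.transition_energies[n - 1] for r in results]) * HARTREE_TO_EV
    mu2 = np.array([r.transition_strengths[n - 1] for r in results])
    # bins anchored at 0 so refinement nests deterministically
    k = np.floor(nu / bin_width).astype(int)
    uniq, inverse = np.unique(k, return_inverse=True)
    counts = np.bincount(inverse)
    sums = np.bincount(inverse, weights=mu2)
    return TransitionHistogram(
        centers=(uniq + 0.5) * bin_width,
        counts=counts,
        mean_mu2=sums / counts,
        n_frames=len(results),
        transition=n,
        bin_width=float(bin_width),
    )


def build_spectrum(
    histograms: Sequence[TransitionHistogram],
    sigma_au: float = DEFAULT_SIGMA_AU,
    scaling: float = DEFAULT_SCALING,
    grid: GridSpec | None = None,
    label: str = "",
) -> Spectrum:
    """Gaussian-broadened extinction spectrum from per-transition histograms.

    The scaling factor multiplies the (eV) bin centers before the Gaussians
    are placed; sigma is given in a.u. of energy and converted to the eV grid.
    """
    if sigma_au <= 0:
        raise ConfigurationError("sigma must be positive")
    if not histograms:
        raise ValidationError("build_spectrum: no histograms")
    n_frames = histograms[0].n_frames
    for h in histograms:
        if h.n_frames != n_frames:
            raise ValidationError("histograms disagree on frame count")
    grid = grid or GridSpec()
    e = grid.energies()
    sigma_ev = sigma_au * HARTREE_TO_EV
    eps = np.zeros((len(histograms), e.size))
    norm = 1.0 / (sigma_ev * np.sqrt(2.0 * np.pi))
    for t, h in enumerate(histograms):
        centers = scaling * h.centers
        weights = h.mean_mu2 * h.counts / n_frames
        g = np.exp(-((e[None, :] - centers[:, None]) ** 2) / (2.0 * sigma_ev**2))
        eps[t] = (weights @ g) * e * norm
    return Spectrum(
        grid=e,
        epsilon_per_transition=eps,
        metadata={
            "scaling": scaling,
            "sigma_au": sigma_au,
            "bin_width_ev": histograms[0].bin_width,
            "n_frames": n_frames,
            "label": label,
        },
    )


def spectrum_from_results(
    results: Sequence[PerturbedFrameResult],
    n_transitions: int | None = None,
    sigma_au: float = DEFAULT_SIGMA_AU,
    scaling: float = DEFAULT_SCALING,
    bin_width: float | None = None,
    grid: GridSpec | None = None,
    label: str = "",
) -> Spectrum:
    """Convenience: bin every transition and assemble the total spectrum."""
    results = list(results)
    if not results:
        raise ValidationError("spectrum_from_results: empty results")
    if n_transitions is None:
        n_transitions = len(results[0].transition_energies)
    hists = [
        bin_transitions(results, n, bin_width=bin_width, sigma_au=sigma_au)
        for n in range(1, n_transitions + 1)
    ]
    return build_spectrum(hists, sigma_au=sigma_au, scaling=scaling, grid=grid, label=label)


def weight_spectra(
    spectra: Mapping[str, Spectrum], populations: Mapping[str, float]
) -> Spectrum:
    """Population-weighted (convex) combination of basin spectra."""
    keys = sorted(spectra)
    if sorted(populations) != keys:
        raise ConfigurationError(
            f"spectra keys {keys} do not match population keys {sorted(populations)}"
        )
    total_p = sum(populations.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ValidationError(f"populations sum to {total_p}, expected 1 within 1e-9")
    ref = spectra[keys[0]]
    for k in keys[1:]:
        if spectra[k].grid.shape != ref.grid.shape or not np.array_equal(
            spectra[k].grid, ref.grid
        ):
            raise ValidationError(f"spectrum '{k}' is on a different grid")
    eps = sum(
        populations[k] * spectra[k].epsilon_per_transition for k in keys
    )
    meta = dict(ref.metadata)
    meta["label"] = "weighted"
    meta["weights"] = {k: float(populations[k]) for k in keys}
    return Spectrum(grid=ref.grid.copy(), epsilon_per_transition=eps, metadata=meta)


# ---------------------------------------------------------------------------
# peaks and shifts
# ---------------------------------------------------------------------------

def find_peaks(
    spec: Spectrum, window_nm: tuple = DEFAULT_PEAK_WINDOW_NM
) -> PeakReport:
    """The two highest local maxima of the total spectrum in a nm window.

    Maxima are strict grid-neighbor maxima of the raw (unsmoothed) curve;
    lambda1 is the red-most of the two, I_rel = height(lambda2)/height(lambda1).
    A spectrum with fewer than two maxima raises
    :class:`DegenerateSpectrumError` carrying the single peak, if any.
    """
    lo_nm, hi_nm = min(window_nm), max(window_nm)
    lam = spec.wavelengths
    y = spec.epsilon_total
    inside = (lam >= lo_nm) & (lam <= hi_nm)
    if inside.sum() < 3:
        raise ValidationError("grid does not cover the peak window")
    yi = y[1:-1]
    is_max = inside[1:-1] & (yi > y[:-2]) & (yi > y[2:])
    idx = np.nonzero(is_max)[0] + 1
    if idx.size < 2:
        peak = None
        if idx.size == 1:
            peak = (float(lam[idx[0]]), float(y[idx[0]]))
        raise DegenerateSpectrumError(
            f"found {idx.size} local maxima in [{lo_nm}, {hi_nm}] nm; need 2",
            peak=peak,
        )
    # two highest; ties resolved toward lower energy (larger wavelength)
    order = sorted(idx, key=lambda i: (-y[i], spec.grid[i]))
    top2 = sorted(order[:2], key=lambda i: -lam[i])
    i1, i2 = top2
    return PeakReport(
        lambda1=float(lam[i1]),
        lambda2=float(lam[i2]),
        I_rel=float(y[i2] / y[i1]),
        height1=float(y[i1]),
        height2=float(y[i2]),
    )


def peak_shift(a: PeakReport, b: PeakReport) -> float:
    """Signed first-peak shift lambda1(a) - lambda1(b), nm (report-round to int)."""
    return float(a.lambda1 - b.lambda1)


def weighted_peak_average(
    values: Mapping[str, float], populations: Mapping[str, float]
) -> float:
    """Population-weighted mean of per-basin peak positions, nm."""
    if sorted(values) != sorted(populations):
        raise ConfigurationError(
            f"value keys {sorted(values)} do not match population keys "
            f"{sorted(populations)}"
        )
    total_p = sum(populations.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ValidationError(f"populations sum to {total_p}, expected 1")
    return float(sum(populations[k] * values[k] for k in values))


def round_nm(x: float) -> int:
    """Reporting convention: nearest integer nanometer."""
    return int(round(x))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectrum(spec: Spectrum, path, per_transition: bool = False) -> None:
    """Two-column (nm, eps_total) or multi-column per-transition text file."""
    lam = spec.wavelengths
    with open(path, "w") as fh:
        fh.write("# PMMSPECTRUM 1\n")
        for key, val in spec.metadata.items():
            fh.write(f"# {key}: {val}\n")
        if per_transition:
            cols = "\t".join(
                f"eps_0{n}" for n in range(1, spec.epsilon_per_transition.shape[0] + 1)
            )
            fh.write(f"# lambda_nm\teps_total\t{cols}\n")
            for i in range(lam.size):
                parts = [f"{lam[i]:.6g}", f"{spec.epsilon_total[i]:.10g}"]
                parts += [f"{v:.10g}" for v in spec.epsilon_per_transition[:, i]]
                fh.write("\t".join(parts) + "\n")
        else:
            fh.write("# lambda_nm\teps_total\n")
            for i in range(lam.size):
                fh.write(f"{lam[i]:.6g}\t{spec.epsilon_total[i]:.10g}\n")


def read_spectrum(path) -> Spectrum:
    """Read a spectrum file written by :func:`write_spectrum`."""
    metadata: dict = {}
    lam = []
    eps_rows = []
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# PMMSPECTRUM"):
            raise ValidationError(f"{path}: not a spectrum file")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body and not body.startswith("lambda_nm"):
                    key, _, val = body.partition(":")
                    metadata[key.strip()] = val.strip()
                continue
            tok = line.split()
            lam.append(float(tok[0]))
            eps_rows.append([float(v) for v in tok[1:]])
    lam = np.array(lam)
    eps = np.array(eps_rows)
    grid = EV_TO_NM / lam
    order = np.argsort(grid)
    grid = grid[order]
    eps = eps[order]
    if eps.shape[1] > 1:
        per_transition = eps[:, 1:].T      # columns beyond eps_total
    else:
        per_transition = eps[:, :1].T
    return Spectrum(grid=grid, epsilon_per_transition=per_transition, metadata=metadata)


def peak_report_dict(report: PeakReport) -> dict:
    return {
        "lambda1_nm": round_nm(report.lambda1),
        "lambda2_nm": round_nm(report.lambda2),
        "I_rel": round(report.I_rel, 3),
        "lambda1_nm_raw": report.lambda1,
        "lambda2_nm_raw": report.lambda2,
    }
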