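"""Spectrum assembly, peak analysis, weighting and shifts."""

import numpy as np
import pytest

from pmm_spectra.environment_field import FrameEnvironment
from pmm_spectra.errors import (
    ConfigurationError,
    DegenerateSpectrumError,
    ValidationError,
)
from pmm_spectra.pmm_core import PerturbedFrameResult, diagonalize_frame
from pmm_spectra.spectroscopy import (
    GridSpec,
    PeakReport,
    Spectrum,
    bin_transitions,
    build_spectrum,
    find_peaks,
    peak_shift,
    read_spectrum,
    spectrum_from_results,
    weight_spectra,
    weighted_peak_average,
    write_spectrum,
)
from pmm_spectra.synthetic import make_flavin_like_states
from pmm_spectra.units import EV_TO_NM, HARTREE_TO_EV


def frame_result(nu_hartree, mu2, idx=0):
    nu = np.atleast_1d(np.asarray(nu_hartree, float))
    mu2 = np.atleast_1d(np.asarray(mu2, float))
    dip = np.zeros((len(nu), 3))
    dip[:, 0] = np.sqrt(mu2)
    return PerturbedFrameResult(
        frame_index=idx,
        eigenvalues=np.concatenate([[0.0], nu]),
        eigenvectors=np.eye(len(nu) + 1),
        transition_energies=nu,
        transition_dipoles=dip,
    )


def gaussian_spectrum(centers_nm, heights, sigma_ev=0.02):
    """Synthetic spectrum: unit-normalized Gaussians at given wavelengths."""
    grid = GridSpec().energies()
    eps = np.zeros((len(centers_nm), grid.size))
    for i, (lam, h) in enumerate(zip(centers_nm, heights)):
        e0 = EV_TO_NM / lam
        eps[i] = h * np.exp(-((grid - e0) ** 2) / (2 * sigma_ev**2))
    return Spectrum(grid=grid, epsilon_per_transition=eps)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_identical_frames_occupy_a_single_bin():
    results = [frame_result(0.10, 2.0, i) for i in range(7)]
    h = bin_transitions(results, 1)
    assert len(h.centers) == 1
    assert h.counts[0] == 7
    assert h.mean_mu2[0] == pytest.approx(2.0)


def test_two_well_separated_populations_get_two_bins():
    results = [frame_result(0.10, 1.0, i) for i in range(4)]
    results += [frame_result(0.20, 3.0, i + 4) for i in range(6)]
    h = bin_transitions(results, 1)
    assert len(h.centers) == 2
    assert sorted(h.counts.tolist()) == [4, 6]
    assert h.counts.sum() == 10


def test_histogram_conserves_total_squared_dipole():
    rng = np.random.default_rng(40)
    results = [
        frame_result(rng.uniform(0.09, 0.13), rng.uniform(0.5, 4.0), i)
        for i in range(500)
    ]
    h = bin_transitions(results, 1)
    total = np.sum(h.counts * h.mean_mu2)
    expected = sum(r.transition_strengths[0] for r in results)
    assert total == pytest.approx(expected, rel=1e-10)
    assert h.counts.sum() == 500


def test_empty_results_rejected():
    with pytest.raises(ValidationError):
        bin_transitions([], 1)


# ---------------------------------------------------------------------------
# spectrum assembly
# ---------------------------------------------------------------------------

def test_single_transition_gaussian_integral_matches_closed_form():
    """One frame, one transition: integral of eps over nu equals
    |mu|^2 * nu_ref for a narrow Gaussian (slowly varying prefactor)."""
    nu0, mu2 = 0.104, 2.5
    h = bin_transitions([frame_result(nu0, mu2)], 1)
    grid = GridSpec(e_min=1.5, e_max=4.5, step=0.0002)
    spec = build_spectrum([h], scaling=1.0, grid=grid)
    integral = np.trapezoid(spec.epsilon_total, spec.grid)
    nu_ref = h.centers[0]  # bin center, eV
    assert integral == pytest.approx(mu2 * nu_ref, rel=1e-6)


def test_epsilon_linear_in_squared_dipole():
    results = [frame_result(0.104, 1.3, 0), frame_result(0.100, 0.7, 1)]
    doubled = [frame_result(0.104, 2.6, 0), frame_result(0.100, 1.4, 1)]
    a = spectrum_from_results(results)
    b = spectrum_from_results(doubled)
    np.testing.assert_allclose(b.epsilon_total, 2 * a.epsilon_total,
                               rtol=1e-12, atol=1e-250)


def test_scaling_moves_peaks_but_not_relative_intensities():
    st = make_flavin_like_states("B1", 436.2, 342.8, i_rel=0.76, seed=41)
    res = diagonalize_frame(st, FrameEnvironment.zero())
    scaled = find_peaks(spectrum_from_results([res], scaling=0.94))
    raw = find_peaks(spectrum_from_results([res], scaling=1.0))
    # positions scale as 1/0.94 in wavelength
    assert scaled.lambda1 / raw.lambda1 == pytest.approx(1 / 0.94, rel=2e-3)
    assert scaled.I_rel == pytest.approx(raw.I_rel, rel=5e-3)


def test_nonpositive_sigma_rejected():
    h = bin_transitions([frame_result(0.1, 1.0)], 1)
    with pytest.raises(ConfigurationError):
        build_spectrum([h], sigma_au=0.0)


def test_integrated_epsilon_invariant_under_bin_refinement():
    rng = np.random.default_rng(42)
    results = [
        frame_result(rng.normal(0.104, 0.002), rng.uniform(1, 3), i)
        for i in range(300)
    ]
    grid = GridSpec(e_min=2.0, e_max=3.6, step=0.0005)
    default_bw = 0.001 * HARTREE_TO_EV / 5
    integrals = []
    for bw in (default_bw, default_bw / 4, default_bw / 16):
        h = bin_transitions(results, 1, bin_width=bw)
        spec = build_spectrum([h], grid=grid)
        integrals.append(np.trapezoid(spec.epsilon_total, spec.grid))
    assert integrals[1] == pytest.approx(integrals[0], rel=1e-4)
    assert integrals[2] == pytest.approx(integrals[0], rel=1e-4)


def test_total_is_sum_over_transitions():
    results = [frame_result([0.104, 0.132], [2.0, 1.5], i) for i in range(3)]
    spec = spectrum_from_results(results)
    np.testing.assert_allclose(
        spec.epsilon_total,
        spec.epsilon_per_transition.sum(axis=0),
        rtol=1e-12,
    )


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------

def _three_equal_spectra():
    s = gaussian_spectrum([458.0], [1.0])
    return {"planar": s, "partially_bent": s, "bent": s}


def test_weighting_equal_spectra_is_identity():
    spectra = _three_equal_spectra()
    pops = {"planar": 0.27, "partially_bent": 0.44, "bent": 0.29}
    w = weight_spectra(spectra, pops)
    np.testing.assert_allclose(w.epsilon_total, spectra["planar"].epsilon_total,
                               rtol=1e-12, atol=1e-250)


def test_degenerate_weighting_returns_that_spectrum():
    a = gaussian_spectrum([458.0], [1.0])
    b = gaussian_spectrum([470.0], [1.0])
    w = weight_spectra(
        {"planar": a, "bent": b}, {"planar": 1.0, "bent": 0.0}
    )
    np.testing.assert_allclose(w.epsilon_total, a.epsilon_total)


def test_grid_mismatch_rejected():
    a = gaussian_spectrum([458.0], [1.0])
    grid = GridSpec(e_min=2.0, e_max=4.0, step=0.002).energies()
    b = Spectrum(grid=grid, epsilon_per_transition=np.ones((1, grid.size)))
    with pytest.raises(ValidationError, match="grid"):
        weight_spectra({"a": a, "b": b}, {"a": 0.5, "b": 0.5})


def test_populations_must_sum_to_one():
    spectra = _three_equal_spectra()
    with pytest.raises(ValidationError, match="sum"):
        weight_spectra(
            spectra, {"planar": 0.3, "partially_bent": 0.3, "bent": 0.3}
        )


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def test_two_equal_gaussians_give_unity_ratio():
    spec = gaussian_spectrum([443.0, 370.0], [1.0, 1.0])
    pk = find_peaks(spec)
    assert pk.lambda1 == pytest.approx(443.0, abs=0.5)
    assert pk.lambda2 == pytest.approx(370.0, abs=0.5)
    assert pk.I_rel == pytest.approx(1.0, abs=5e-3)


def test_second_band_at_86_percent_height():
    spec = gaussian_spectrum([443.0, 370.0], [1.0, 0.86])
    pk = find_peaks(spec)
    assert pk.I_rel == pytest.approx(0.86, abs=5e-3)


def test_monotone_spectrum_raises_degenerate_error():
    grid = GridSpec().energies()
    spec = Spectrum(grid=grid, epsilon_per_transition=grid[None, :].copy())
    with pytest.raises(DegenerateSpectrumError):
        find_peaks(spec)


def test_single_peak_carried_on_degenerate_error():
    spec = gaussian_spectrum([443.0], [2.0])
    with pytest.raises(DegenerateSpectrumError) as err:
        find_peaks(spec)
    lam, height = err.value.peak
    assert lam == pytest.approx(443.0, abs=0.5)
    assert height == pytest.approx(2.0, rel=1e-3)


def test_peak_positions_invariant_under_uniform_rescaling():
    spec = gaussian_spectrum([443.0, 370.0], [1.0, 0.7])
    a = find_peaks(spec)
    scaled = Spectrum(
        grid=spec.grid, epsilon_per_transition=37.0 * spec.epsilon_per_transition
    )
    b = find_peaks(scaled)
    assert (a.lambda1, a.lambda2) == (b.lambda1, b.lambda2)
    assert a.I_rel == pytest.approx(b.I_rel, rel=1e-12)


def test_peak_report_orientation_enforced():
    with pytest.raises(ValidationError):
        PeakReport(lambda1=370.0, lambda2=443.0, I_rel=1.0)


# ---------------------------------------------------------------------------
# shifts and weighted averages
# ---------------------------------------------------------------------------

def test_identical_reports_shift_zero():
    a = PeakReport(lambda1=443.0, lambda2=370.0, I_rel=0.86)
    assert peak_shift(a, a) == 0.0


def test_apo_vs_water_experimental_shift():
    apo = PeakReport(lambda1=466.0, lambda2=389.0, I_rel=1.01)
    water = PeakReport(lambda1=443.0, lambda2=370.0, I_rel=0.86)
    assert round(peak_shift(apo, water)) == 23


def test_protein_vs_water_computed_shift():
    protein = PeakReport(lambda1=459.0, lambda2=352.0, I_rel=1.0)
    water = PeakReport(lambda1=443.0, lambda2=346.0, I_rel=0.86)
    assert round(peak_shift(protein, water)) == 16


def test_population_weighted_gas_phase_peaks():
    pops = {"planar": 0.27, "partially_bent": 0.44, "bent": 0.29}
    l1 = weighted_peak_average(
        {"planar": 436.2, "partially_bent": 437.2, "bent": 441.0}, pops
    )
    l2 = weighted_peak_average(
        {"planar": 342.8, "partially_bent": 343.6, "bent": 347.0}, pops
    )
    assert round(l1) == 438
    assert round(l2) == 344


def test_uniform_values_average_to_that_value():
    pops = {"a": 0.3, "b": 0.7}
    assert weighted_peak_average({"a": 455.0, "b": 455.0}, pops) == 455.0


def test_mismatched_keys_rejected():
    with pytest.raises(ConfigurationError):
        weighted_peak_average({"a": 1.0}, {"b": 1.0})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("per_transition", [False, True])
def test_spectrum_file_round_trip_preserves_peaks(tmp_path, per_transition):
    spec = gaussian_spectrum([443.0, 370.0], [1.0, 0.86])
    path = tmp_path / "spec.txt"
    write_spectrum(spec, path, per_transition=per_transition)
    back = read_spectrum(path)
    a, b = find_peaks(spec), find_peaks(back)
    assert b.lambda1 == pytest.approx(a.lambda1, abs=0.01)
    assert b.I_rel == pytest.approx(a.I_rel, rel=1e-6)
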