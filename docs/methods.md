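# Methods

## Model

The chromophore (the lumiflavin moiety of FAD; "quantum center", QC) is
described by a truncated basis of gas-phase electronic eigenstates — the
ground state plus, by default, ten excited states — with energies `E_j`
(Hartree) and the dipole operator `μ̂` expressed in that basis (a.u.). At
every trajectory frame the environment acts on the QC only through the
electrostatic potential `V` and field `E` it exerts at the QC center of
mass, and the perturbed electronic Hamiltonian is

    H[j,j'] = δ_jj' (E_j + q V) − E · ⟨φ_j| μ̂ |φ_j'⟩

with `q` the QC net charge (zero for neutral lumiflavin, so the `V` term
drops out of transition energies in the default setup). Short-range
(exchange/polarization) corrections beyond the dipole coupling are
deliberately omitted — the API leaves no hook for them. Diagonalizing `H`
per frame yields perturbed transition energies `ν_0n` and, by rotating the
dipole matrices into the perturbed eigenbasis, perturbed transition dipoles
`μ_0n`.

Assumptions inherited from this construction:

* **Born–Oppenheimer bookkeeping per basin.** The electronic reference is a
  function of the QC conformation only. Frames are classified into bending
  basins and each basin is assigned one fixed reference (planar → B1,
  partially bent → B3, bent → B5); references are never interpolated between
  basins.
* **Dipole origin.** Dipole matrix elements are assumed computed with origin
  at the QC center of mass — the same point where `V` and `E` are evaluated.
  Fixture files must honor this; it is an assumption of the method, not a
  checked invariant.
* **Excited–excited transition dipoles are zero.** Their contribution to
  the absorption spectrum is negligible; validation rejects fixtures that
  carry them rather than silently zeroing, so inconsistent inputs fail
  loudly.
* **Point-charge electrostatics, direct sum.** No periodic images or Ewald
  treatment: the perturbation is summed over the explicit environment atoms
  supplied (optionally truncated by an inclusion cutoff, default none). A
  clash cutoff (default 0.05 nm) guards against charges degenerately close
  to the expansion point.

## Spectrum assembly

Per transition `n`, the per-frame pairs `(ν_0n, |μ_0n|²)` are histogrammed
on a frequency grid (bin width defaults to σ/5 so binning never dominates
the broadening; bins are anchored at zero so refinements nest). Each
occupied bin contributes a Gaussian:

    ε_0n(ν) ∝ Σ_ref |μ_0n|²_ref · (η_ref / N) · ν ·
              exp(−(ν − ν_ref)² / 2σ²) / (σ √2π)

where `η_ref` counts frames in the bin, `N` is the total frame count and
`|μ_0n|²_ref` the bin mean. All absolute prefactors (Planck constant,
`1/(6 ε0 c ħ²)`) are folded into one arbitrary-unit constant: the analysis
only ever compares peak positions and relative intensities, never absolute
extinction. The Gaussian width σ (default 0.001 a.u. of energy ≈ 0.027 eV)
stands in for the neglected semiclassical vibrational broadening; its unit
is the working energy unit, configurable.

An empirical multiplicative scaling factor (default 0.94) is applied to the
energies, in eV, before Gaussian placement — it calibrates the first
computed peak of lumiflavin in water onto experiment and cannot change
relative intensities. Peak reports quote `λ1` (red-most main peak), `λ2`
and `I_rel = height(λ2)/height(λ1)`; peaks are strict local maxima of the
raw gridded curve (no smoothing), searched in a 300–550 nm window on a grid
of 0.002 eV (≲ 0.4 nm wavelength resolution across the window), ties broken
toward lower energy. Basin spectra are combined as convex combinations
weighted by basin populations; "weighted peak positions" in tables are the
population-weighted means of per-basin peak positions, matching the
published tabulation convention rather than the maximum of the weighted
curve (the two differ when basin peaks are well separated).

## The bending coordinate

The butterfly bend is quantified by the C4–N5–N10–C9 torsion. For a planar
fused tricycle that raw torsion is 180°, while the crystallographic
convention quotes the *deviation from planarity* (planar = 0°, bent crystal
structures 11.7–17.4°). The package therefore exposes both: `dihedral()` is
the standard signed torsion, and `bend_angle() = wrap(180° − torsion)` is
the bend d1 used everywhere downstream. Classification uses |d1| — the sign
carries the pucker direction, which the analysis does not use — with
thresholds (6°, 12°) and the boundary values assigned to the middle basin.

Essential dynamics is PCA of the 3N×3N covariance of ring-atom positional
fluctuations after iterative least-squares superposition (Kabsch) onto the
mean structure; superposition is the standard essential-dynamics convention
although the choice is not forced by the method. Coordinates are
unweighted (no atomic masses); projections carry the coordinate unit (nm).
A fluctuation-free trajectory yields all-zero eigenvalues rather than an
error.

## Synthetic data: what it emulates, what it does not

The generators replace the MD simulation and the TD-DFT reference
calculations with statistically controllable stand-ins:

* **Reference states** (`make_flavin_like_states`): 11 states, the two
  bright transitions placed at requested wavelengths (defaults: the
  published gas-phase conformer values, e.g. planar B1 at 436.2/342.8 nm
  with intensity ratio 0.76; bent B5 at 441.0/347.0 nm, 0.97), dark states
  above them with weak random transition dipoles. The first bright
  transition dipole is 2.0 a.u. (reasonable for the strong flavin ππ*
  band); permanent-dipole differences of 3.0 and 1.5 a.u. along x for the
  two bright states give the fixtures a clean linear Stark response — they
  are chosen for controllability and sensitivity, not fitted to flavin's
  measured excited-state dipoles.
* **Environments** (`make_environment`): 200 partial charges of ±0.15 e in
  a shell 0.8–2.5 nm from the chromophore, with 0.02 nm frame-to-frame
  Gaussian jitter — magnitudes typical of protein partial charges at
  first-shell-and-beyond distances, producing fields of order 10⁻³ a.u. A
  fixed pair of opposite bias charges (zero net potential at the expansion
  point) cancels the random configuration's residual mean field and steers
  the ensemble mean exactly onto the requested target; the construction is
  verified by direct summation before frames are returned.
* **Bending trajectories** (`make_bending_series`): d1 drawn from a
  three-component Gaussian mixture, centers 2°/9°/16° with σ = 1.2° and
  weights 0.27/0.44/0.29 — the published basin populations, with centers
  placed inside the classification windows and widths narrow enough that
  cross-boundary leakage stays below the ±0.01 recovery tolerance at 10⁵
  frames. Ring geometry folds an idealized planar three-hexagon template
  (0.14 nm bonds) about the N5–N10 axis; only its topology (the atom names
  entering d1) matches real isoalloxazine.

What passing tests on these inputs do **not** show about real data: the
synthetic field fluctuations are much gentler than a real protein's
(inhomogeneous widths here are dominated by the vibrational σ, not the
environment); charges are fictitious rather than force-field derived; the
single-wing fold is an idealization of the two-wing butterfly motion; and
no attempt is made to reproduce CvFAP's actual electrostatics, so absolute
peak positions from the synthetic pipeline are meaningful only relative to
each other.

## Numerical choices

* Internal units are atomic throughout (Hartree, Bohr, a.u. dipoles and
  fields); conversions (1 Hartree = 27.211386 eV, λ[nm] = 1239.84193/E[eV],
  1 nm = 18.897259886 Bohr) happen only at file and reporting boundaries.
* `numpy.linalg.eigh` provides the symmetric eigensolver; eigenvalues come
  out ascending and each eigenvector's largest-magnitude component is made
  positive, so results — including near-degenerate frames — are
  bit-reproducible.
* The default pipeline tunes the environment's mean field by *first-order*
  Stark theory (`field_for_first_peak_shift`) for a 21 nm electrostatic
  term, mirroring the published decomposition. Second-order level repulsion
  against the bright states works against the first-order prediction by
  ≲ 1 nm at these field strengths, which is why measured shifts sit just
  under their first-order targets.
* Text formats write floats at `repr` precision, so read-after-write is
  bit-exact for states fixtures, charge frames and ring trajectories.
* Problem sizes in the shipped analyses: 10⁵ frames for basin-population
  recovery (binomial standard error ≈ 0.15 %), 5 000 frames for the
  field-tuned shift, 2 000 frames for the end-to-end decomposition — sizes
  at which the measured quantities are stable to well within the tolerances
  quoted for them.

## Known limitations

* No vibronic structure; the Gaussian σ is a single catch-all width.
* No absolute extinction calibration (arbitrary ε units).
* No polarizable or short-range environment terms; the perturbation is
  strictly monopole-potential plus field–dipole.
* `weighted_peak_average` reproduces the tabulated averaging convention; it
  is not the maximum of the weighted spectrum, and the two should not be
  mixed when comparing against spectra read off a curve.
* The PCA is unweighted; a mass-weighted variant would reorder modes only
  if heavy/light atoms dominated different motions, which the C/N-only ring
  selection makes unlikely.
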