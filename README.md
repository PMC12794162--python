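# pmm-spectra

Ensemble UV–vis spectroscopy of a flavin chromophore in a fluctuating
electrostatic environment, via the perturbed matrix method (PMM).

Fatty-acid photodecarboxylase (CvFAP) absorbs unusually far to the red: its
FAD cofactor peaks near 466 nm where most flavoproteins sit at 450–455 nm,
and its isoalloxazine ring is "butterfly-bent" about the N5–N10 axis in the
crystal. Disentangling how much of the red shift comes from that bend and how
much from the protein's electrostatics requires an ensemble treatment: the
chromophore's electronic states respond frame by frame to the fluctuating
field of the environment. This package implements that analysis for anyone
who has (or wants to emulate) per-frame electrostatic perturbations and a
gas-phase electronic reference of the chromophore:

* **`electronic_states`** — the quantum-center reference: state energies and
  the dipole operator in the state basis (what a TD-DFT run would supply),
  with validation and a bit-exact text format.
* **`environment_field`** — direct Coulomb sums of the environment's point
  charges giving the potential *V* and field **E** at the chromophore's
  center of mass, plus residue-charge counterfactual edits.
* **`pmm_core`** — the per-frame perturbed Hamiltonian
  `H = H0 + I q V − E·μ` diagonalized to perturbed transition energies and
  dipoles.
* **`conformation`** — the butterfly coordinate d1 (from the C4–N5–N10–C9
  torsion), three-basin classification (planar < 6°, partially bent 6–12°,
  bent > 12°), and essential dynamics (PCA of positional fluctuations).
* **`spectroscopy`** — Gaussian-broadened extinction spectra
  `ε_0n(ν) ∝ Σ_ref |μ_0n|²_ref (η_ref/N) ν exp(−(ν−ν_ref)²/2σ²)`,
  population weighting, peak finding and shift arithmetic.
* **`synthetic`** — seeded generators for flavin-like reference states,
  charge environments with a controllable ensemble-mean field, and
  three-basin bending trajectories; these stand in for the MD and
  quantum-chemistry runs.
* **`pipeline` / `pmm-spectra` CLI** — the end-to-end analysis and
  charge-counterfactual comparison.

## Worked example

```python
from pmm_spectra import PipelineConfig, run_apo_analysis

report = run_apo_analysis(PipelineConfig(seed=1, n_frames=1000))
print(report.to_json())
```

prints (abridged):

```json
{
  "decomposition": {
    "conformational_shift_nm": 2,
    "electrostatic_shift_nm": 21,
    "planar_gas_lambda1_nm": 464,
    "total_shift_nm": 23,
    "weighted_gas_lambda1_nm": 466,
    "weighted_pmm_lambda1_nm": 486
  },
  "populations": {"planar": 0.261, "partially_bent": 0.439, "bent": 0.3}
}
```

Reading this: the synthetic trajectory visits the planar / partially bent /
bent basins with populations near 27/44/29 %. Weighting each basin's
gas-phase peak by its population moves the first absorption peak only 2 nm
red of the planar gas-phase value — bending barely tunes the spectrum. The
environment's mean field (here tuned for a 21 nm electrostatic term) moves
it a further 21 nm, for a 23 nm total first-peak red shift: the protein
electrostatics, not the bend, dominates.

The same analysis runs from the shell, one stage at a time:

```sh
pmm-spectra generate --seed 1 --n-frames 1000 --out fx   # synthetic inputs
pmm-spectra fields fx/charges.txt --out ve.tsv           # V, E per frame
pmm-spectra basins fx/d1.txt                             # populations
pmm-spectra pmm ve.tsv --states B1=fx/states_B1.txt \
    --states B3=fx/states_B3.txt --states B5=fx/states_B5.txt \
    --d1 fx/d1.txt --out res.tsv                         # diagonalization
pmm-spectra spectrum res.tsv --out spec.txt              # broadened spectrum
pmm-spectra peaks spec.txt                               # λ1, λ2, I_rel
pmm-spectra run --seed 1 --n-frames 1000                 # all of the above
```

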