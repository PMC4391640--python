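# spinhop

Trajectory surface hopping with internal conversion (IC) and intersystem
crossing (ISC) treated on the same footing, for studying how a
photoexcited pyrimidine nucleobase relaxes when singlet → triplet
transitions compete with the classic singlet deactivation funnels.

After UV excitation, a nucleobase such as uracil decays through conical
intersections back to the ground state — but spin–orbit coupling (SOC)
also lets population leak into the triplet manifold on an ultrafast time
scale.  Simulating that competition requires propagating nuclei on
surfaces that mix spin states.  `spinhop` implements the full pipeline:

* **electronic_models** — a linear vibronic coupling (LVC) model over
  4 singlets + 3 triplets (13 explicit spin components) standing in for
  an on-the-fly multiconfigurational provider.  The Hamiltonian is
  H_ii(q) = ε_i + Σ κ_{i,m} q_m + Σ ½ω_m q_m², with geometry-dependent
  interstate couplings λ·q and complex SOC constants η (El-Sayed
  consistent, ~55 cm⁻¹ for character-changing pairs).  Vertical energies
  default to the state-averaged CASSCF(14,10) spectrum of uracil
  (S₁ 5.13, S₂ 7.04, S₃ 7.07; T₁ 4.00, T₂ 4.95, T₃ 5.86 eV).  A 1D
  two-state crossing fixture with a closed-form Landau–Zener oracle is
  included for validation.
* **initial_conditions** — 0 K harmonic Wigner sampling, absorption
  spectra from oscillator strengths f = (2/3)ΔE|μ|², and δ-pulse
  initial-state selection ∝ f with optional excitation-energy windows.
* **propagation** — velocity-Verlet dynamics (Δt = 0.5 fs, 1 ps) on the
  active surface of the *diagonal, spin-mixed* basis; substepped
  (0.02 fs) unitary amplitude propagation; fewest-switches
  population-flux hopping with energy-conserving velocity rescaling;
  energy-based decoherence (α = 0.1 hartree).
* **ensemble_analysis** — population traces in diagonal / MCH /
  spectroscopic representations (bright ¹ππ* vs dark ¹nπ* vs triplet by
  transition-dipole thresholds 0.05 and 1e-6 a.u.), the 15 fs S₀/T₁
  validity filter, ISC hop statistics, and geometric descriptors.
* **kinetics** — mono/biexponential fits of population rises and decays
  with asymptotic standard errors and AICc model comparison.
* **cli_io** — YAML run configurations, XYZ and HDF5 I/O, and a
  deterministic end-to-end ensemble runner (`spinhop run-all`).

See `docs/methods.md` for the model, its parameterization and its
limitations (three effective modes, no vibrational bath — qualitative
mechanism, not quantitative yields).

## Worked example

Run a 30-trajectory ensemble on the default uracil-like model and fit
the decay constants:

```python
from spinhop import EnsembleConfig, run_ensemble
from spinhop.propagation import PropagatorSettings

config = EnsembleConfig(
    n_trajectories=30, seed=2014, n_wigner_samples=500,
    propagator=PropagatorSettings(t_max_fs=1000.0, seed=2014),
    output_dir="example_run",
)
run = run_ensemble(config)
print(run.manifest["state_counts"])
print(run.hop_summary.to_dict())
print(run.fits["s0_plus_t1_mono_rise"].summary())
```

prints (abridged):

```
initial-state split: {'S2': 18, 'S3': 12}
hop summary: { "singlet_ic": 202, "triplet_ic": 29, "isc_s_to_t": 36,
               "isc_t_to_s": 44, "frustrated": 8,
               "mean_isc_soc_cm1": 39.2, "max_isc_soc_cm1": 55.3,
               "mean_isc_gap_ev": 0.038 }
MCH populations at 1 ps: {'S0': 0.27, 'S1': 0.4, 'S2': 0.0, 'S3': 0.0,
                          'T1': 0.2, 'T2': 0.07, 'T3': 0.07}
s0_plus_t1_mono_rise: mono-rise: tau1 = 897.307 +/- 5.1 fs
bright_pipi_bi_decay: bi-decay: tau1 = 293.058 +/- 15 fs,
                      tau2 = 1e+07 +/- 3.9e+10 fs, a = 0.893 [at bounds]
```

Reading the output: both bright states are photoexcited (18/12 split by
oscillator strength); ISC hops occur at small energy gaps (0.04 eV mean)
with SOC of ~39 cm⁻¹ on average; after 1 ps a third of the ensemble sits
in the triplet manifold and a quarter has recovered the ground state.
The S₀+T₁ "dark population" rises with a sub-picosecond time constant;
the slow component of the bright-state decay is not resolvable within a
1 ps window and the fitter flags it (`[at bounds]`) instead of reporting
a spurious picosecond constant.

The same pipeline runs from the shell:

```bash
spinhop run-all --config run.yaml --output-dir out --seed 7
spinhop run-all --config run.yaml --singlets-only   # ISC switched off
spinhop run-all --config run.yaml --window 6.52 6.66  # excitation window
```

Switching the triplets off (`include_triplets: false` or
`--singlets-only`) reproduces the singlet-only reference behaviour: the
dark ¹nπ* population then overtakes the bright ¹ππ* one at late times
and ground-state recovery is faster — the signature that ISC competes
with IC when it is allowed.

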