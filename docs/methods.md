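# Methods

`spinhop` simulates the nonradiative decay of a photoexcited pyrimidine
nucleobase (uracil-like) by trajectory surface hopping in which internal
conversion (IC) and intersystem crossing (ISC) are treated on the same
footing.  This note documents the model, the numerical choices, what the
synthetic electronic structure does and does not emulate, and the known
limitations.

## Electronic model

The electronic-structure provider is a reduced-dimensional linear
vibronic coupling (LVC) model over four singlet states (closed-shell S0,
¹nπ*, ¹ππ*, ¹nπ*) and three triplet states (³ππ*, ³nπ*, ³ππ*) whose Ms
components are treated explicitly — 13 spin components in total.  In the
quasi-diabatic model basis,

    H_ii(q)  = ε_i + Σ_m κ_{i,m} q_m + Σ_m ½ ω_m q_m²
    H_ij(q)  = Σ_m λ_{ij,m} q_m          (same multiplicity, same Ms)
    H_iT(q)  = η_iT / √3                  (each Ms component)

with dimensionless normal coordinates q (effective mass 1/ω in atomic
units, so the ground-state Wigner distribution has unit variance in q and
its conjugate momentum).  The spin-free off-diagonal couplings vanish at
the reference geometry, so the vertical energies ε are exact eigenvalues
there.

A real provider would deliver energies, gradients, non-adiabatic
couplings, SOCs and transition dipoles from a multiconfigurational
calculation at every time step; the LVC model implements exactly that
interface analytically (`ModelPotential.hamiltonian`,
`hamiltonian_gradient`, `spin_free_adiabatic`, `dipoles`), so a
quantum-chemistry adapter could be substituted without touching the
propagator.

### Default parameterization

Vertical energies (eV): S1 5.13, S2 7.04, S3 7.07, T1 4.00, T2 4.95,
T3 5.86 — the state-averaged CASSCF(14,10) vertical spectrum of uracil's
diketo tautomer, which places the bright ππ* near 7 eV (the well-known
~2 eV blue shift of CASSCF against experiment/CASPT2 is inherited
deliberately, since it is the surface the original dynamics ran on).

Three effective modes:

| mode | ω (cm⁻¹) | role |
|------|----------|------|
| q1   | 400      | ππ*/nπ* tuning: the ππ* states (S2, T1, T3) are strongly displaced along it |
| q2   | 250      | interstate coupling mode: switches on the S2/S3, S1/S2, S0/S1 and triplet IC couplings |
| q3   | 200      | recovery/relaxation mode: large nπ* displacement (ring-opening-like), brings S1 down toward the S0 crossing seam |

The frequencies are in the range of the ring-deformation /
out-of-plane modes that mediate the crossing seams in pyrimidine
nucleobases; large-amplitude effective modes of reduced models are
legitimately soft.  They also keep the velocity-Verlet energy error
(≈ E·(ωΔt)²/8 per mode) below 1e-6 hartree over 1 ps at the 0.5 fs
protocol time step — the integrator tolerance and the mechanism
timescales are designed together.

Intrastate gradients κ (eV per unit q) displace each state according to
its character: ππ* states gain 1.6–2.5 eV of reorganization energy along
q1; nπ* states relax 1–2.5 eV along q3.  The resulting crossing topology
reproduces the mechanism of the full-dimensional study: S3/S2 cross
immediately outside the Franck–Condon region (ultrafast S3 → S2 IC), the
S2 diabat crosses S1 on its way to its minimum, the relaxed ¹nπ* crosses
the deeply displaced ³ππ* states (El-Sayed-allowed ISC doorway) and, at
larger q3 amplitude, the closed-shell ground state (ring-opening-like
recovery funnel).  Interstate couplings λ are 0.02–0.12 eV per unit of
the coupling mode; the S2/S3 coupling (0.12) is strong enough that both
adiabats share ππ* oscillator strength over the Wigner cloud (both are
photoexcited, as in the reference dynamics), while the S1/S2 (0.06) and
S0/S1 (0.025) couplings put those funnels in the weak-coupling
(surface-hopping) regime, giving partial S2 trapping and slow
ground-state recovery.

SOC constants η follow El-Sayed's rule: 55 cm⁻¹ for character-changing
singlet–triplet pairs (¹nπ*↔³ππ*, ¹ππ*↔³nπ*), 4–5 cm⁻¹ for
El-Sayed-forbidden pairs, 30 cm⁻¹ for S0↔³nπ*.  η is the *total*
multiplet strength: each Ms component carries η/√3 with an Ms-independent
phase (arbitrary fixed relative phases exercise the complex algebra), so
the root-sum-square SOC between a singlet and a triplet multiplet equals
η.  With this calibration the SOC magnitudes recorded *at ISC hop
geometries* come out at ≈36 cm⁻¹ mean / ≈55 cm⁻¹ maximum, matching the
scale reported for the ab initio dynamics (39 cm⁻¹ average, peaking above
60 cm⁻¹); the mean energy gap at ISC hops is ~0.05 eV.

Transition dipoles are Condon (geometry independent by default): ¹ππ*
0.55 a.u., ¹nπ* 0.02–0.04 a.u., triplets exactly zero.  The ¹nπ* states
acquire intensity only by adiabatic mixing, which is what makes S3
selectable by the δ-pulse and what drives the spectroscopic
classification during the dynamics.

## Initial conditions

Geometries and velocities are sampled from the 0 K harmonic Wigner
distribution (per mode: Gaussian q with variance ħ/2mω, Gaussian p with
variance mωħ/2, mutually independent; 2000 samples by default).  For
each sample the spin-free Hamiltonian is diagonalized; excitation
energies and oscillator strengths f = (2/3)·ΔE·|μ|² (length gauge) of
the singlet excited states feed (a) a Gaussian-broadened absorption
spectrum (default FWHM 0.1 eV — the broadening of the published spectrum
is not stated, so it is configurable) and (b) δ-pulse initial-state
selection with probability ∝ f, optionally restricted to an inclusive
excitation-energy window (the experiment-matching window analogue is
6.52–6.66 eV).  Selection draws with replacement; at the default pool
size duplicate draws are rare.

## Propagation

Nuclei move by velocity Verlet (Δt = 0.5 fs, 1 ps) on the active
eigensurface of the *full* Hamiltonian — the diagonal, spin-mixed basis —
with the exact Hellmann–Feynman gradient ⟨ψ|∂H/∂q|ψ⟩ of the LVC model.
Electronic amplitudes are propagated in the quasi-diabatic model basis
(δt = 0.02 fs substeps, midpoint-exponential integrator on the linearly
interpolated Hamiltonian; unitary to machine precision) and transformed
to the diagonal basis for all hopping decisions, which avoids numerical
differentiation of eigenvectors.  Eigenvector continuity between steps
uses overlap-maximizing column assignment with a real-positive phase
convention; through triplet Ms degeneracies the assignment is arbitrary
within the degenerate block and physically irrelevant.  For analysis the
active state is recorded by its instantaneous energy rank.

Hopping probabilities use the population-flux (fewest-switches)
prescription: the fractional loss of active-state population over a
nuclear step, apportioned among the states whose populations grew.  The
original code's exact hopping expression is not printed in the reference;
this variant is well defined in the diagonal basis without explicit
time-derivative couplings and is validated against the Landau–Zener
closed form (ensemble hop fractions within Monte-Carlo error of
exp(−2πc²/(ħv·2k)) across P ≈ 0.1–0.9).  Accepted hops conserve total
energy by uniform rescaling of the full velocity vector
(coupling-vector rescaling is ill-defined for SOC-mediated hops);
energetically frustrated upward hops leave state and velocities
unchanged.  Decoherence uses the energy-based correction with
α = 0.1 hartree: non-active amplitudes are damped with
τ_β = (ħ/|E_β−E_active|)(1 + α/E_kin) and the active amplitude is
rescaled to restore the norm; degenerate states are not damped.

Initial amplitudes are a pure state on the diagonal surface of maximal
overlap with the selected spin-free (MCH) excited state (δ-pulse).

## Analysis

Populations are classical occupations (fraction of trajectories per
class) on the nuclear time grid, in three representations: diagonal
(energy-ranked spin-mixed surfaces), MCH (spin-free eigenstates,
S0…S3/T1…T3, Ms summed), and spectroscopic, which classifies the
occupied MCH state by its ground-to-state transition dipole: > 0.05 a.u.
bright ¹ππ*, [1e-6, 0.05] a.u. dark ¹nπ* (the boundary 0.05 classifies
dark), < 1e-6 a.u. triplet, with the closed-shell ground state as its own
class.  Trajectory validity follows the protocol rule: keep trajectories
that finish the full simulation time or that end early after at least
15 fs of contiguous residence in S0 or T1; kept early-terminated
trajectories are frozen in their terminal class.  Hop statistics count
accepted hops by the multiplicities of their MCH endpoints and accumulate
|SOC| and |ΔE| over ISC hops.  Geometric descriptors (bond lengths,
out-of-plane angles against a total-least-squares ring plane) operate on
Cartesian XYZ frames for full-coordinate workflows.

## Kinetics

Population rises are fitted with P(t) = 1 − e^(−t/τ) or
P(t) = 1 − a·e^(−t/τ₁) − (1−a)·e^(−t/τ₂) (decays with the mirrored
complements), time zero fixed at excitation, by unweighted nonlinear
least squares multi-started from a log-spaced τ grid; uncertainties are
asymptotic standard errors from the scaled inverse Gauss–Newton normal
matrix.  Model selection between mono- and biexponential fits uses AICc.
A fit that cannot beat a constant raises instead of returning a spurious
τ, and estimates at the search bounds are flagged.

Calibration: on synthetic traces with independent binomial counting
noise (n = 100 trajectories per time point) the 3σ asymptotic intervals
cover the true constants in ≥ 99% of replicates.  Because the least
squares is unweighted while counting noise is heteroscedastic (variance
P(1−P)/n), true coverage is slightly below the Gaussian-nominal 99.7%
and depends on the time grid; on real surface-hopping traces the noise
is additionally time-correlated, so the asymptotic errors quantify the
fit alone, not ensemble sampling error.

## What the synthetic data do and do not show

The generator reproduces: the vertical spectrum used to parameterize the
model, the crossing-seam topology of the deactivation network, SOC
magnitudes at ISC geometries, δ-pulse ensemble preparation, and the
qualitative IC/ISC competition (dark-state population inversion only
when ISC is disabled; monotone triplet growth, suppressed dark-state
rise and reduced ground-state recovery when it is enabled).

It does not reproduce full-dimensional dynamics.  With three modes and
strict energy conservation there is no intramolecular vibrational bath:
excess energy is never dissipated, so trajectories revisit crossing
regions more often than in full dimensionality, ground-state recovery is
faster, S2 trapping weaker, and triplet populations approach a
microcanonical balance rather than being irreversibly trapped.
Quantitative yields and picosecond time constants therefore cannot be
compared to the ab initio ensembles; passing tests certify the method
implementation and the qualitative mechanism, not full-dimensional
observables.  Spectroscopic classification uses a dipole threshold only;
the ring-opened σ(n–π)π* character is not a separate class.

## Numerical choices and degenerate inputs

* Hermiticity is enforced to 1e-12 at model construction and 1e-10 at
  diagonalization entry.
* Tracked diagonalization falls back to Hungarian assignment only when
  the smallest diagonal overlap drops below 0.7 (cheap identity fast
  path otherwise).
* Hop targets are drawn by a single uniform variate against cumulative
  probabilities; ties broken by state order.
* apply_decoherence treats E_β = E_active as τ → ∞ (no damping) and is a
  no-op at zero kinetic energy; a vanished active amplitude skips the
  renormalization.
* Wigner sampling requires strictly positive frequencies; the two-state
  crossing fixture (ω = 0) is propagated from explicit initial
  conditions instead.
* Ensemble reproducibility: per-trajectory seeds derive from
  SeedSequence(master, spawn_key=(2, index)); reruns are bit-identical.

## Default problem sizes

Desk-scale study conditions used by the shipped analyses: 2000 Wigner
samples for spectra, 100–120 trajectories per production ensemble at
1 ps / 0.5 fs, 100-trajectory ensembles for the mechanism comparisons,
2000 trajectories per coupling for the Landau–Zener validation, 50,000
samples for Wigner-moment checks, and 200 replicate traces for fitter
calibration.
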