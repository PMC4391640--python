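"""Linear vibronic coupling (LVC) models of coupled singlet and triplet states.

This module plays the role of the electronic-structure provider in the
surface-hopping pipeline.  Instead of an on-the-fly multiconfigurational
calculation it evaluates a reduced-dimensional LVC Hamiltonian over the
explicit spin components of a chosen set of singlet and triplet states:

    H_ii(q) = ε_i + Σ_m κ_{i,m} q_m + Σ_m ½ ω_m q_m²          (diagonal)
    H_ij(q) = λ⁰_ij + Σ_m λ_{ij,m} q_m     (same multiplicity, same Ms)
    H_it(q) = η_it                          (singlet–triplet, any Ms)

with q the dimensionless normal-mode coordinates, ε the vertical energies
at the reference geometry, κ intrastate gradients, λ interstate vibronic
couplings and η complex spin–orbit coupling (SOC) constants.  The SOC
constant of a singlet/triplet state pair is replicated unchanged over the
three Ms components (Condon-like, Ms-independent phase convention); the
full spin-component Hamiltonian is complex Hermitian by construction.

The default "uracil-like" model couples four singlets (closed-shell S0,
¹nπ*, ¹ππ*, ¹nπ*) and three triplets (³ππ*, ³nπ*, ³ππ*), i.e. 13 spin
components, with vertical energies of 5.13, 7.04, 7.07 eV (singlets) and
4.00, 4.95, 5.86 eV (triplets) and SOC magnitudes of ~40 cm⁻¹ for
El-Sayed-allowed (character-changing) pairs and ~4 cm⁻¹ otherwise.

The provider contract (`ElectronicStructureResult` plus the
``hamiltonian`` / ``hamiltonian_gradient`` / ``spin_free_adiabatic``
methods) is deliberately minimal so that an external quantum-chemistry
adapter could replace this module without touching the propagator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .units import CM1_TO_HARTREE, EV_TO_HARTREE

__all__ = [
    "SpinComponent",
    "StateSpace",
    "ModelPotential",
    "ElectronicStructureResult",
    "make_state_space",
    "build_uracil_lvc_model",
    "build_two_state_crossing",
    "evaluate_model",
    "adiabatic_singlet_dipoles",
    "landau_zener_probability",
    "random_model",
    "URACIL_REFERENCE_ENERGIES_EV",
]

HERMITICITY_TOL = 1e-12

#: Vertical excitation energies (eV) of the default uracil-like model at the
#: reference geometry: S1(nπ*), S2(ππ*), S3(nπ*), T1(ππ*), T2(nπ*), T3(ππ*).
URACIL_REFERENCE_ENERGIES_EV: tuple[float, ...] = (5.13, 7.04, 7.07, 4.00, 4.95, 5.86)

#: Orbital character labels of the default model's spin-free states,
#: S0..S3 then T1..T3.  Used to build El-Sayed-consistent SOC defaults.
URACIL_STATE_CHARACTERS: tuple[str, ...] = (
    "closed-shell", "npi*", "pipi*", "npi*", "pipi*", "npi*", "pipi*",
)


class ModelConfigurationError(ValueError):
    """Raised when model parameters are inconsistent with the state space."""


# ---------------------------------------------------------------------------
# state space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpinComponent:
    """One explicit spin component: (multiplicity, state index within the
    multiplicity, Ms).  Singlets carry Ms = 0; triplet state j appears three
    times with Ms = -1, 0, +1."""

    multiplicity: int
    index: int
    ms: int

    def label(self) -> str:
        if self.multiplicity == 1:
            return f"S{self.index}"
        return f"T{self.index + 1}(ms={self.ms:+d})"


@dataclass(frozen=True)
class StateSpace:
    """Ordered set of spin components spanned by a model.

    Ordering convention (fixed): all singlets by energy index, then the
    triplets grouped by spin-free state with Ms ascending (-1, 0, +1).
    """

    n_singlets: int
    n_triplets: int
    components: tuple[SpinComponent, ...] = field(default=())

    @property
    def n_components(self) -> int:
        return self.n_singlets + 3 * self.n_triplets

    @property
    def n_spin_free(self) -> int:
        return self.n_singlets + self.n_triplets

    def spin_free_index(self, component: int) -> int:
        """Map a spin-component index to its spin-free state index
        (singlets 0..n_s-1, then triplets n_s..n_s+n_t-1)."""
        c = self.components[component]
        if c.multiplicity == 1:
            return c.index
        return self.n_singlets + c.index

    def component_multiplicities(self) -> np.ndarray:
        return np.array([c.multiplicity for c in self.components])


def make_state_space(n_singlets: int, n_triplets: int) -> StateSpace:
    """Build the spin-component state space for the given state counts.

    The dynamics treats triplet Ms components explicitly, so e.g. four
    singlets plus three triplets span 4 + 3·3 = 13 components.
    """
    if n_singlets < 0 or n_triplets < 0:
        raise ValueError("state counts must be non-negative")
    if n_singlets == 0 and n_triplets == 0:
        raise ValueError("state space must contain at least one state")
    comps: list[SpinComponent] = [
        SpinComponent(1, i, 0) for i in range(n_singlets)
    ]
    for j in range(n_triplets):
        for ms in (-1, 0, 1):
            comps.append(SpinComponent(3, j, ms))
    return StateSpace(n_singlets, n_triplets, tuple(comps))


# ---------------------------------------------------------------------------
# model potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelPotential:
    """An LVC model over a spin-component state space.

    All arrays are in atomic units.  Spin-free state ordering is singlets
    first (S0..S_{ns-1}) then triplets (T1..T_{nt}); arrays indexed by
    spin-free state have length ``n_singlets + n_triplets``.

    Parameters
    ----------
    omega : (n_modes,) harmonic frequency of each effective mode, hartree
        (ħω; equal to the angular frequency in atomic units).  May be zero
        for purely linear validation models.
    masses : (n_modes,) effective mass conjugate to each coordinate.  The
        default models use dimensionless coordinates with mass 1/ω so that
        kinetic plus harmonic energy is ω(p² + q²)/2.
    epsilon : (n_sf,) vertical energy of each spin-free state at q = 0.
    kappa : (n_sf, n_modes) intrastate linear coupling.
    lambda0, lambda1 : constant / linear interstate couplings between
        same-multiplicity spin-free state pairs; (n_sf, n_sf) and
        (n_sf, n_sf, n_modes), symmetric, zero across multiplicities.
    eta : (n_singlets, n_triplets) complex SOC constants.  η is the total
        multiplet coupling strength of a singlet–triplet pair: each of the
        three Ms components carries η/√3 so that the root-sum-square over
        the multiplet equals |η| (Ms-independent Condon-like phase
        convention).
    mu0, mu1 : (n_sf, 3) and (n_sf, 3, n_modes) transition dipole of each
        spin-free state from the closed-shell ground state (Condon value
        and optional linear geometry dependence); triplet rows are zero.
    """

    state_space: StateSpace
    n_modes: int
    omega: np.ndarray
    masses: np.ndarray
    epsilon: np.ndarray
    kappa: np.ndarray
    lambda0: np.ndarray
    lambda1: np.ndarray
    eta: np.ndarray
    mu0: np.ndarray
    mu1: np.ndarray

    def __post_init__(self) -> None:
        ns, nt = self.state_space.n_singlets, self.state_space.n_triplets
        nsf, nm = ns + nt, self.n_modes
        shapes = {
            "omega": (self.omega, (nm,)),
            "masses": (self.masses, (nm,)),
            "epsilon": (self.epsilon, (nsf,)),
            "kappa": (self.kappa, (nsf, nm)),
            "lambda0": (self.lambda0, (nsf, nsf)),
            "lambda1": (self.lambda1, (nsf, nsf, nm)),
            "eta": (self.eta, (ns, nt)),
            "mu0": (self.mu0, (nsf, 3)),
            "mu1": (self.mu1, (nsf, 3, nm)),
        }
        for name, (arr, shape) in shapes.items():
            if arr.shape != shape:
                raise ModelConfigurationError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
        if np.any(self.masses <= 0):
            raise ModelConfigurationError("effective masses must be positive")
        if not np.allclose(self.lambda0, self.lambda0.T, atol=HERMITICITY_TOL):
            raise ModelConfigurationError("lambda0 must be symmetric")
        if not np.allclose(
            self.lambda1, np.swapaxes(self.lambda1, 0, 1), atol=HERMITICITY_TOL
        ):
            raise ModelConfigurationError("lambda1 must be symmetric in states")
        # couplings across multiplicities belong to eta, not lambda
        sl, tl = slice(0, ns), slice(ns, nsf)
        if np.any(self.lambda0[sl, tl] != 0) or np.any(self.lambda1[sl, tl] != 0):
            raise ModelConfigurationError(
                "lambda couples states of different multiplicity; use eta"
            )

    # -- provider contract --------------------------------------------------

    @property
    def n_components(self) -> int:
        return self.state_space.n_components

    @property
    def n_spin_free(self) -> int:
        return self.state_space.n_spin_free

    def _check_coords(self, coords: np.ndarray) -> np.ndarray:
        q = np.asarray(coords, dtype=float)
        if q.shape != (self.n_modes,):
            raise ValueError(
                f"coords has shape {q.shape}, expected ({self.n_modes},)"
            )
        return q

    def spin_free_hamiltonian(self, coords: np.ndarray) -> np.ndarray:
        """Real symmetric spin-free Hamiltonian over spin-free states."""
        q = self._check_coords(coords)
        nsf = self.n_spin_free
        common = 0.5 * np.sum(self.omega * q * q)
        diag = self.epsilon + self.kappa @ q + common
        h = self.lambda0 + self.lambda1 @ q
        h[np.arange(nsf), np.arange(nsf)] = diag
        return h

    def hamiltonian(self, coords: np.ndarray, include_soc: bool = True) -> np.ndarray:
        """Complex Hermitian Hamiltonian over the explicit spin components."""
        hsf = self.spin_free_hamiltonian(coords)
        ns, nt = self.state_space.n_singlets, self.state_space.n_triplets
        n = self.n_components
        h = np.zeros((n, n), dtype=complex)
        h[:ns, :ns] = hsf[:ns, :ns]
        # triplet blocks: spin-free part diagonal in Ms, identical per Ms
        for j in range(nt):
            for k in range(nt):
                v = hsf[ns + j, ns + k]
                for m in range(3):
                    h[ns + 3 * j + m, ns + 3 * k + m] = v
        if include_soc and ns and nt:
            for s in range(ns):
                for j in range(nt):
                    e = self.eta[s, j] / np.sqrt(3.0)  # per-Ms component
                    if e != 0:
                        for m in range(3):
                            h[s, ns + 3 * j + m] = e
                            h[ns + 3 * j + m, s] = np.conj(e)
        return h

    def hamiltonian_gradient(self, coords: np.ndarray) -> np.ndarray:
        """Analytic ∂H/∂q_m over spin components, shape (n_modes, n, n).

        The SOC block is geometry independent, so only the diagonal and the
        same-multiplicity λ entries contribute.
        """
        q = self._check_coords(coords)
        ns, nt = self.state_space.n_singlets, self.state_space.n_triplets
        nsf, n = self.n_spin_free, self.n_components
        grad = np.zeros((self.n_modes, n, n), dtype=complex)
        ddiag = self.kappa + self.omega * q  # (nsf, nm) via broadcasting
        for m in range(self.n_modes):
            gsf = self.lambda1[:, :, m].astype(complex).copy()
            gsf[np.arange(nsf), np.arange(nsf)] = ddiag[:, m]
            grad[m, :ns, :ns] = gsf[:ns, :ns]
            for j in range(nt):
                for k in range(nt):
                    v = gsf[ns + j, ns + k]
                    if v != 0:
                        for mm in range(3):
                            grad[m, ns + 3 * j + mm, ns + 3 * k + mm] = v
        return grad

    def spin_free_gradients(self, coords: np.ndarray) -> np.ndarray:
        """Analytic gradients of the spin-free diagonal, (n_sf, n_modes)."""
        q = self._check_coords(coords)
        return self.kappa + self.omega * q

    def dipoles(self, coords: np.ndarray) -> np.ndarray:
        """Ground-to-state transition dipoles of the spin-free (diabatic)
        states at this geometry, (n_sf, 3)."""
        q = self._check_coords(coords)
        return self.mu0 + self.mu1 @ q

    def spin_free_adiabatic(
        self, coords: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Eigen-decomposition of the spin-free Hamiltonian, block-wise by
        multiplicity.

        Returns energies (n_sf,) and eigenvectors V (n_sf, n_sf) ordered
        singlets-ascending then triplets-ascending; these are the MCH
        (molecular Coulomb Hamiltonian) states.
        """
        hsf = self.spin_free_hamiltonian(coords)
        ns = self.state_space.n_singlets
        nsf = self.n_spin_free
        energies = np.empty(nsf)
        vecs = np.zeros((nsf, nsf))
        if ns:
            es, vs = np.linalg.eigh(hsf[:ns, :ns])
            energies[:ns], vecs[:ns, :ns] = es, vs
        if nsf > ns:
            et, vt = np.linalg.eigh(hsf[ns:, ns:])
            energies[ns:], vecs[ns:, ns:] = et, vt
        return energies, vecs

    def adiabatic_dipoles(
        self, coords: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Spin-free adiabatic excitation energies and transition dipole
        vectors from the adiabatic ground state.

        Returns (delta_e, dipoles): excitation energies (n_sf,) relative to
        the lowest singlet eigenstate and dipole vectors (n_sf, 3) computed
        by rotating the diabatic Condon dipoles into the eigenbasis.
        Triplet rows are exactly zero (spin forbidden).
        """
        if self.state_space.n_singlets == 0:
            raise ValueError("model has no singlet ground state")
        energies, vecs = self.spin_free_adiabatic(coords)
        ns = self.state_space.n_singlets
        dip = np.zeros((self.n_spin_free, 3))
        dip[:ns] = adiabatic_singlet_dipoles(vecs, self.dipoles(coords), ns)
        delta_e = energies - energies[0]
        return delta_e, dip

    # -- convenience --------------------------------------------------------

    def without_soc(self) -> "ModelPotential":
        return replace(self, eta=np.zeros_like(self.eta))

    def singlets_only(self) -> "ModelPotential":
        """Collapse the model to its singlet manifold (triplets removed)."""
        ns = self.state_space.n_singlets
        if ns == 0:
            raise ValueError("model has no singlet states")
        return ModelPotential(
            state_space=make_state_space(ns, 0),
            n_modes=self.n_modes,
            omega=self.omega,
            masses=self.masses,
            epsilon=self.epsilon[:ns].copy(),
            kappa=self.kappa[:ns].copy(),
            lambda0=self.lambda0[:ns, :ns].copy(),
            lambda1=self.lambda1[:ns, :ns].copy(),
            eta=np.zeros((ns, 0), dtype=complex),
            mu0=self.mu0[:ns].copy(),
            mu1=self.mu1[:ns].copy(),
        )


@dataclass(frozen=True)
class ElectronicStructureResult:
    """Per-geometry bundle returned by an electronic-structure provider:
    the spin-component Hamiltonian, spin-free state gradients and
    ground-to-excited transition dipoles."""

    H: np.ndarray
    gradients: np.ndarray
    dipoles: np.ndarray
    basis_tag: str = "model-diabatic"

    def __post_init__(self) -> None:
        if np.max(np.abs(self.H - self.H.conj().T)) > HERMITICITY_TOL:
            raise ValueError("Hamiltonian is not Hermitian within tolerance")


def adiabatic_singlet_dipoles(
    vecs_sf: np.ndarray, mu_diabatic: np.ndarray, n_singlets: int
) -> np.ndarray:
    """Ground-to-excited transition dipoles of the singlet eigenstates.

    In the Condon picture the diabatic dipole operator couples the
    closed-shell diabat (row 0 of ``mu_diabatic``'s state axis is its
    self-row, zero) to each excited diabat, so
    ⟨ψ₀|μ|ψᵢ⟩ = c₀⁽⁰⁾ Σ_j c_j⁽ⁱ⁾ μ_j over excited diabats j, with c the
    spin-free eigenvector coefficients.  Returns (n_singlets, 3); row 0 is
    zero.
    """
    ns = n_singlets
    weight = vecs_sf[0, 0]  # closed-shell amplitude of the ground eigenstate
    dip = np.zeros((ns, 3))
    for i in range(1, ns):
        dip[i] = weight * (vecs_sf[1:ns, i] @ mu_diabatic[1:ns])
    return dip


def evaluate_model(
    model: ModelPotential, coords: np.ndarray
) -> ElectronicStructureResult:
    """Evaluate the LVC provider at a nuclear configuration.

    Returns the complex Hermitian spin-component Hamiltonian, the analytic
    gradients of the spin-free diagonal and the diabatic transition
    dipoles, all in atomic units.
    """
    return ElectronicStructureResult(
        H=model.hamiltonian(coords),
        gradients=model.spin_free_gradients(coords),
        dipoles=model.dipoles(coords),
    )


# ---------------------------------------------------------------------------
# default uracil-like model
# ---------------------------------------------------------------------------

def _default_uracil_parameters() -> dict:
    """Default parameter groups of the uracil-like model (user units).

    Three effective modes: q1 tunes the ππ*/nπ* energy ordering (the ππ*
    states are stabilised along it), q2 is the interstate coupling /
    ISC-promoting mode, q3 is the ground-state-recovery (ring-opening-like)
    mode along which the lowest nπ* state crosses the closed-shell ground
    state.  Frequencies are in the range of the ring-deformation modes that
    mediate the crossings.  SOC magnitudes follow El-Sayed's rule: ~40 cm⁻¹
    for character-changing singlet–triplet pairs, one order of magnitude
    smaller otherwise.
    """
    # spin-free states: S0, S1(npi*), S2(pipi*), S3(npi*), T1(pipi*),
    # T2(npi*), T3(pipi*)
    epsilon_ev = [0.0, *URACIL_REFERENCE_ENERGIES_EV]
    omega_cm1 = [400.0, 250.0, 200.0]
    kappa_ev = [
        [0.00, 0.00, 0.00],    # S0
        [0.15, 0.08, -0.35],   # S1 npi*
        [-0.40, 0.00, 0.05],   # S2 pipi*
        [0.10, -0.08, 0.00],   # S3 npi*
        [-0.50, 0.00, 0.05],   # T1 pipi*
        [0.05, 0.08, -0.30],   # T2 npi*
        [-0.45, 0.00, 0.05],   # T3 pipi*
    ]
    # (i, j, mode, value eV): interstate couplings switched on linearly by
    # the coupling mode (q2) or the recovery mode (q3); zero at q = 0 so the
    # reference energies are exact eigenvalues there.
    lambda_terms = [
        (0, 1, 1, 0.025),  # S0-S1 funnel, switched on by the coupling mode
        (0, 2, 1, 0.02),   # S0-S2 weak direct (ethylenic-like) channel
        (1, 2, 1, 0.06),   # S1-S2 tuning-region funnel
        (2, 3, 1, 0.12),   # S2-S3 strong near-degenerate mixing
        (1, 3, 1, 0.03),
        (4, 5, 1, 0.10),   # T1-T2
        (5, 6, 1, 0.10),   # T2-T3
        (4, 6, 1, 0.04),
    ]
    characters = URACIL_STATE_CHARACTERS
    eta_cm1 = np.zeros((4, 3))
    for s in range(4):
        for t in range(3):
            cs, ct = characters[s], characters[4 + t]
            if cs == "closed-shell":
                eta_cm1[s, t] = 30.0 if ct == "npi*" else 5.0
            elif cs != ct:
                eta_cm1[s, t] = 55.0  # El-Sayed allowed
            else:
                eta_cm1[s, t] = 4.0   # El-Sayed forbidden
    mu0 = [
        [0.00, 0.00, 0.00],  # S0 (no self-transition)
        [0.02, 0.00, 0.00],  # S1 dark npi*
        [0.55, 0.00, 0.00],  # S2 bright pipi*
        [0.03, 0.02, 0.00],  # S3 npi*, brightens by mixing with S2
        [0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00],
    ]
    return {
        "n_singlets": 4,
        "n_triplets": 3,
        "epsilon_ev": epsilon_ev,
        "omega_cm1": omega_cm1,
        "kappa_ev": kappa_ev,
        "lambda_ev": lambda_terms,
        "eta_cm1": eta_cm1.tolist(),
        "eta_phase": 0.5235987755982988,  # pi/6 increment between pairs
        "mu0": mu0,
    }


def build_uracil_lvc_model(config: Mapping | None = None) -> ModelPotential:
    """Build the default uracil-like LVC model, optionally overriding
    parameter groups from a configuration mapping.

    Recognised keys (all optional; user units): ``n_singlets``,
    ``n_triplets``, ``epsilon_ev`` (including the ground state as entry 0),
    ``omega_cm1``, ``kappa_ev``, ``lambda_ev`` (list of
    ``[i, j, mode, value]`` entries; constant couplings use mode = -1),
    ``eta_cm1`` (magnitudes, n_singlets × n_triplets), ``eta_phase``
    (radians; pair (s, t) gets phase ``(s - t) · eta_phase``), ``mu0``,
    ``mu1``, ``masses_au``.
    """
    params = _default_uracil_parameters()
    if config:
        unknown = set(config) - set(params) - {"mu1", "masses_au"}
        if unknown:
            raise ModelConfigurationError(
                f"unknown model configuration keys: {sorted(unknown)}"
            )
        params.update(config)

    ns, nt = int(params["n_singlets"]), int(params["n_triplets"])
    space = make_state_space(ns, nt)
    nsf = ns + nt
    try:
        epsilon = np.asarray(params["epsilon_ev"], dtype=float) * EV_TO_HARTREE
        omega = np.asarray(params["omega_cm1"], dtype=float) * CM1_TO_HARTREE
        kappa = np.asarray(params["kappa_ev"], dtype=float) * EV_TO_HARTREE
        nm = omega.shape[0]
        lambda0 = np.zeros((nsf, nsf))
        lambda1 = np.zeros((nsf, nsf, nm))
        for i, j, m, val in params["lambda_ev"]:
            i, j, m = int(i), int(j), int(m)
            v = float(val) * EV_TO_HARTREE
            if m < 0:
                lambda0[i, j] = lambda0[j, i] = v
            else:
                lambda1[i, j, m] = lambda1[j, i, m] = v
        mag = np.asarray(params["eta_cm1"], dtype=float) * CM1_TO_HARTREE
        if mag.size == 0:
            mag = np.zeros((ns, nt))
        phase = float(params.get("eta_phase", 0.0))
        s_idx = np.arange(ns)[:, None]
        t_idx = np.arange(nt)[None, :]
        eta = mag * np.exp(1j * phase * (s_idx - t_idx))
        mu0 = np.asarray(params["mu0"], dtype=float)
        mu1 = np.asarray(
            params.get("mu1", np.zeros((nsf, 3, nm))), dtype=float
        )
        masses = np.asarray(
            params.get("masses_au", _default_masses(omega)), dtype=float
        )
    except (TypeError, IndexError) as exc:
        raise ModelConfigurationError(str(exc)) from exc
    return ModelPotential(
        state_space=space,
        n_modes=nm,
        omega=omega,
        masses=masses,
        epsilon=epsilon,
        kappa=kappa,
        lambda0=lambda0,
        lambda1=lambda1,
        eta=eta,
        mu0=mu0,
        mu1=mu1,
    )


def _default_masses(omega: np.ndarray) -> np.ndarray:
    """Effective mass 1/ω for dimensionless coordinates (unit mass where a
    mode is unbound, i.e. ω = 0)."""
    with np.errstate(divide="ignore"):
        m = np.where(omega > 0, 1.0 / np.where(omega > 0, omega, 1.0), 1.0)
    return m


# ---------------------------------------------------------------------------
# two-state crossing validation fixture
# ---------------------------------------------------------------------------

def build_two_state_crossing(
    slope: float,
    coupling: float,
    mass: float,
    multiplicities: tuple[int, int] = (1, 1),
) -> ModelPotential:
    """1D linear two-state crossing with constant coupling.

    Diabatic energies are ∓``slope``·x (state 0 decreasing, state 1
    increasing, crossing at x = 0) and the interstate coupling is the
    constant ``coupling``; for equal multiplicities it enters the spin-free
    block, otherwise it is an SOC constant replicated over the Ms
    components.  Adiabatic energies are ±sqrt((slope·x)² + coupling²); a
    single passage at velocity v hops with the Landau–Zener probability
    exp(−2π·coupling²/(v·2·slope)).
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if coupling < 0:
        raise ValueError("coupling must be non-negative")
    if mass <= 0:
        raise ValueError("mass must be positive")
    if tuple(sorted(multiplicities)) not in {(1, 1), (3, 3), (1, 3)}:
        raise ValueError("multiplicities must be 1 or 3")

    ns = sum(1 for m in multiplicities if m == 1)
    nt = sum(1 for m in multiplicities if m == 3)
    space = make_state_space(ns, nt)
    nsf = ns + nt
    kappa = np.zeros((nsf, 1))
    # diabat listed first keeps the -slope branch regardless of multiplicity
    # ordering in the state space (singlets precede triplets there).
    order = np.argsort([0 if m == 1 else 1 for m in multiplicities], kind="stable")
    kappa[order[0], 0] = -slope
    kappa[order[1], 0] = +slope
    lambda0 = np.zeros((nsf, nsf))
    eta = np.zeros((ns, nt), dtype=complex)
    if ns == 2:
        lambda0[0, 1] = lambda0[1, 0] = coupling
    elif nt == 2:
        lambda0[ns, ns + 1] = lambda0[ns + 1, ns] = coupling
    else:
        eta[0, 0] = coupling
    return ModelPotential(
        state_space=space,
        n_modes=1,
        omega=np.zeros(1),
        masses=np.array([mass], dtype=float),
        epsilon=np.zeros(nsf),
        kappa=kappa,
        lambda0=lambda0,
        lambda1=np.zeros((nsf, nsf, 1)),
        eta=eta,
        mu0=np.zeros((nsf, 3)),
        mu1=np.zeros((nsf, 3, 1)),
    )


def landau_zener_probability(
    slope: float, coupling: float, velocity: float
) -> float:
    """Closed-form single-passage diabatic-survival probability
    exp(−2πc²/(ħ v · 2k)) for the linear two-state crossing (a.u., ħ = 1)."""
    return float(np.exp(-2.0 * np.pi * coupling**2 / (velocity * 2.0 * slope)))


def random_model(
    rng: np.random.Generator,
    n_singlets: int | None = None,
    n_triplets: int | None = None,
    n_modes: int = 2,
) -> ModelPotential:
    """Random small LVC model, used by the test-suite oracles."""
    if n_singlets is None:
        n_singlets = int(rng.integers(1, 4))
    if n_triplets is None:
        n_triplets = int(rng.integers(0, 3))
    space = make_state_space(n_singlets, n_triplets)
    nsf = space.n_spin_free
    omega = rng.uniform(5e-4, 5e-3, n_modes)
    kappa = rng.normal(0, 5e-3, (nsf, n_modes))
    lam0 = rng.normal(0, 2e-3, (nsf, nsf))
    lam0 = 0.5 * (lam0 + lam0.T)
    lam1 = rng.normal(0, 2e-3, (nsf, nsf, n_modes))
    lam1 = 0.5 * (lam1 + np.swapaxes(lam1, 0, 1))
    # zero the cross-multiplicity and diagonal entries
    sl, tl = slice(0, n_singlets), slice(n_singlets, nsf)
    for arr in (lam0, lam1):
        arr[sl, tl] = 0
        arr[tl, sl] = 0
        arr[np.arange(nsf), np.arange(nsf)] = 0
    eta = rng.normal(0, 2e-4, (n_singlets, n_triplets)) + 1j * rng.normal(
        0, 2e-4, (n_singlets, n_triplets)
    )
    return ModelPotential(
        state_space=space,
        n_modes=n_modes,
        omega=omega,
        masses=_default_masses(omega),
        epsilon=np.sort(rng.uniform(0, 0.3, nsf)),
        kappa=kappa,
        lambda0=lam0,
        lambda1=lam1,
        eta=eta,
        mu0=rng.normal(0, 0.3, (nsf, 3)),
        mu1=np.zeros((nsf, 3, n_modes)),
    )
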