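"""Surface hopping in the fully diagonal, spin-mixed electronic basis.

Nuclei move with velocity Verlet on the active eigensurface of the full
Hamiltonian (non-adiabatic couplings and SOC included through the
diagonalization); the electronic amplitudes are integrated in the model's
quasi-diabatic basis with a finer substep and linearly interpolated
Hamiltonian, and transformed to the diagonal basis for the hopping
decision.  Hops follow a fewest-switches population-flux prescription;
accepted hops conserve total energy by uniform velocity rescaling and
energetically forbidden upward hops are recorded as frustrated with the
velocities unchanged.  Coherence damping uses the energy-based decoherence
correction (overlap-free, parameterised by α).

Eigenvector continuity between steps is maintained by overlap-maximising
column assignment with a real-positive phase convention, so the "active
state" follows a smoothly varying surface even through weakly avoided
crossings and triplet Ms degeneracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .electronic_models import ModelPotential, adiabatic_singlet_dipoles
from .units import FS_TO_AU_TIME, HARTREE_TO_CM1, HARTREE_TO_EV
from .initial_conditions import InitialCondition

__all__ = [
    "PropagatorSettings",
    "TrajectoryState",
    "Trajectory",
    "HopEvent",
    "diagonalize_tracked",
    "velocity_verlet_step",
    "propagate_amplitudes",
    "hop_probabilities",
    "attempt_hop",
    "apply_decoherence",
    "run_trajectory",
]

HERMITICITY_TOL = 1e-10


@dataclass(frozen=True)
class PropagatorSettings:
    """Numerical parameters of the surface-hopping propagation.

    Defaults follow the reference protocol: 0.5 fs nuclear steps for 1 ps,
    0.02 fs amplitude substeps and an energy-based decoherence parameter of
    α = 0.1 hartree.  ``decoherence_alpha=None`` disables the decoherence
    correction; ``hopping="off"`` propagates adiabatically on the active
    surface (amplitudes still evolve).
    """

    dt_fs: float = 0.5
    dt_electronic_fs: float = 0.02
    t_max_fs: float = 1000.0
    decoherence_alpha: Optional[float] = 0.1
    rescaling_policy: str = "uniform"
    frustrated_policy: str = "keep"
    hopping: str = "fewest-switches"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dt_fs, self.dt_electronic_fs, self.t_max_fs) <= 0:
            raise ValueError("all time parameters must be positive")
        if abs(self.n_substeps * self.dt_electronic_fs - self.dt_fs) > 1e-9:
            raise ValueError(
                "dt_electronic must divide the nuclear time step evenly"
            )
        if self.rescaling_policy != "uniform":
            raise ValueError("only uniform velocity rescaling is implemented")
        if self.frustrated_policy != "keep":
            raise ValueError("only the 'keep velocities' frustrated policy is implemented")
        if self.hopping not in ("fewest-switches", "off"):
            raise ValueError("hopping must be 'fewest-switches' or 'off'")

    @property
    def n_substeps(self) -> int:
        return max(1, round(self.dt_fs / self.dt_electronic_fs))

    @property
    def n_steps(self) -> int:
        return max(1, round(self.t_max_fs / self.dt_fs))


@dataclass
class TrajectoryState:
    """The unit of propagation: nuclear phase space, electronic amplitudes
    in the model's quasi-diabatic basis, the active diagonal state and the
    current diagonal-basis eigenvectors."""

    time_fs: float
    coordinates: np.ndarray
    velocities: np.ndarray
    amplitudes: np.ndarray
    active_state: int
    U: np.ndarray
    energies: np.ndarray
    rng: np.random.Generator


@dataclass(frozen=True)
class HopEvent:
    """One attempted surface hop.  Frustrated events record no state
    change; for accepted hops between states of different multiplicity the
    SOC magnitude between the involved MCH states is recorded."""

    time_fs: float
    from_state: int
    to_state: int
    from_mch: tuple[int, int]  # (multiplicity, spin-free index in mult.)
    to_mch: tuple[int, int]
    delta_e_ev: float
    soc_cm1: Optional[float]
    geometry: np.ndarray
    frustrated: bool


@dataclass
class Trajectory:
    """Per-step record of one surface-hopping trajectory."""

    times_fs: np.ndarray
    coordinates: np.ndarray
    velocities: np.ndarray
    energies: np.ndarray          # diagonal-basis surfaces, hartree
    total_energy: np.ndarray      # active potential + kinetic, hartree
    active: np.ndarray            # energy rank of the active diagonal state
    mch_multiplicity: np.ndarray  # multiplicity of the active MCH state
    mch_index: np.ndarray         # spin-free index within the multiplicity
    mch_dipole: np.ndarray        # |transition dipole| of the active MCH state
    populations: np.ndarray       # |c|^2 in the diagonal basis per step
    hop_events: list[HopEvent] = field(default_factory=list)
    termination_status: str = "completed"

    @property
    def n_steps(self) -> int:
        return len(self.times_fs)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def diagonalize_tracked(
    H: np.ndarray, U_prev: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Diagonalize a Hermitian matrix with eigenvector continuity.

    Without ``U_prev`` the eigenpairs come out energy-ascending.  With it,
    columns are reordered by overlap-maximising assignment against the
    previous eigenvectors and phased so that diag(U_prev† U) is real and
    positive, which keeps surfaces and amplitudes continuous through
    degeneracies (triplet Ms components) and weakly avoided crossings.
    """
    H = np.asarray(H)
    if np.max(np.abs(H - H.conj().T)) > HERMITICITY_TOL:
        raise ValueError("matrix is not Hermitian within tolerance")
    energies, U = np.linalg.eigh(H)
    if U_prev is not None:
        overlap = U_prev.conj().T @ U
        mags = np.abs(overlap)
        diag = np.abs(np.diagonal(mags))
        if np.min(diag) < 0.7:  # cheap fast path: identity unless ambiguous
            rows, cols = linear_sum_assignment(-(mags**2))
            perm = np.empty_like(cols)
            perm[rows] = cols
            U = U[:, perm]
            energies = energies[perm]
            overlap = U_prev.conj().T @ U
        phases = np.diagonal(overlap).copy()
        phases = np.where(np.abs(phases) > 1e-12, phases / np.abs(phases), 1.0)
        U = U * phases.conj()
    return energies, U


def velocity_verlet_step(
    coordinates: np.ndarray,
    velocities: np.ndarray,
    masses: np.ndarray,
    gradient: np.ndarray,
    gradient_provider: Callable[[np.ndarray], np.ndarray],
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One velocity-Verlet step on the active surface (atomic units).

    ``gradient`` is the energy gradient at the current position;
    ``gradient_provider`` returns the gradient at the updated position (it
    may diagonalize the new Hamiltonian as a side effect).  Returns the new
    coordinates, velocities and gradient.
    """
    acc = -gradient / masses
    q_new = coordinates + velocities * dt + 0.5 * acc * dt * dt
    g_new = gradient_provider(q_new)
    acc_new = -g_new / masses
    v_new = velocities + 0.5 * (acc + acc_new) * dt
    return q_new, v_new, g_new


def propagate_amplitudes(
    amplitudes: np.ndarray,
    H_start: np.ndarray,
    H_end: np.ndarray,
    dt: float,
    dt_electronic: float,
) -> np.ndarray:
    """Advance amplitudes through one nuclear step by substepped unitary
    integration of iħ ∂c/∂t = H(t)c with H linearly interpolated between
    the endpoint Hamiltonians (midpoint exponential per substep).

    Both Hamiltonians must be expressed in the same (propagation) basis;
    norm is conserved to machine precision.
    """
    n_sub = max(1, round(dt / dt_electronic))
    dH = H_end - H_start
    frac = (np.arange(n_sub) + 0.5) / n_sub
    H_mid = H_start[None, :, :] + frac[:, None, None] * dH[None, :, :]
    energies, vecs = np.linalg.eigh(H_mid)  # batched over substeps
    dt_sub = dt / n_sub
    c = amplitudes.astype(complex)
    phases = np.exp(-1j * energies * dt_sub)
    for k in range(n_sub):
        v = vecs[k]
        c = v @ (phases[k] * (v.conj().T @ c))
    return c


def hop_probabilities(
    amplitudes_before: np.ndarray,
    amplitudes_after: np.ndarray,
    active_state: int,
    dt: float | None = None,
) -> np.ndarray:
    """Fewest-switches hop probabilities from the population flux over one
    nuclear step (diagonal-basis amplitudes).

    The loss of active-state population over the step is apportioned among
    the states whose populations grew; the result is non-negative, zero for
    the active state and sums to at most one.
    """
    p0 = np.abs(amplitudes_before) ** 2
    p1 = np.abs(amplitudes_after) ** 2
    probs = np.zeros_like(p0)
    loss = p0[active_state] - p1[active_state]
    if loss <= 0 or p0[active_state] <= 0:
        return probs
    gains = np.clip(p1 - p0, 0.0, None)
    gains[active_state] = 0.0
    total_gain = gains.sum()
    if total_gain <= 0:
        return probs
    hop_total = loss / p0[active_state]
    probs = hop_total * gains / total_gain
    probs[active_state] = 0.0
    return np.clip(probs, 0.0, 1.0)


def attempt_hop(
    active_state: int,
    probabilities: np.ndarray,
    energies: np.ndarray,
    velocities: np.ndarray,
    masses: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray, Optional[tuple[int, bool]]]:
    """Draw one uniform variate against the cumulative hop probabilities.

    Returns (new_active, new_velocities, outcome) where outcome is None if
    no hop was attempted, or (target, frustrated).  Accepted hops conserve
    total energy by uniform rescaling of the full velocity vector; upward
    hops with insufficient kinetic energy are frustrated (state and
    velocities unchanged).
    """
    xi = rng.random()
    cum = np.cumsum(probabilities)
    targets = np.nonzero(xi < cum)[0]
    if len(targets) == 0:
        return active_state, velocities, None
    target = int(targets[0])
    e_kin = 0.5 * float(np.sum(masses * velocities**2))
    delta_e = float(energies[target] - energies[active_state])
    if delta_e > e_kin:
        return active_state, velocities, (target, True)
    scale = np.sqrt((e_kin - delta_e) / e_kin) if e_kin > 0 else 0.0
    return target, velocities * scale, (target, False)


def apply_decoherence(
    amplitudes: np.ndarray,
    energies: np.ndarray,
    active_state: int,
    kinetic_energy: float,
    dt: float,
    alpha: float,
) -> np.ndarray:
    """Energy-based decoherence: damp every non-active amplitude with
    time constant τ_β = (ħ/|E_β − E_active|)(1 + α/E_kin) and rescale the
    active amplitude to restore the norm.

    Degenerate states (E_β = E_active) are left untouched (τ → ∞).
    """
    if kinetic_energy <= 0:
        return amplitudes
    c = amplitudes.astype(complex).copy()
    gaps = np.abs(energies - energies[active_state])
    factor = 1.0 + alpha / kinetic_energy
    with np.errstate(divide="ignore"):
        rates = np.where(gaps > 0, gaps / factor, 0.0)
    damp = np.exp(-dt * rates)
    damp[active_state] = 1.0
    c *= damp
    p_active = np.abs(c[active_state]) ** 2
    if p_active > 0:
        p_others = np.sum(np.abs(c) ** 2) - p_active
        c[active_state] *= np.sqrt(max(1.0 - p_others, 0.0) / p_active)
    return c


# ---------------------------------------------------------------------------
# full trajectory
# ---------------------------------------------------------------------------

def _mch_component_vectors(model: ModelPotential, vecs_sf: np.ndarray) -> np.ndarray:
    """Embed the spin-free (MCH) eigenvectors into the spin-component
    space, replicating triplet eigenvectors over their Ms components.

    Column ordering follows the state-space convention: singlets ascending,
    then triplet states grouped with Ms ascending."""
    ns = model.state_space.n_singlets
    nt = model.state_space.n_triplets
    n = model.n_components
    V = np.zeros((n, n))
    V[:ns, :ns] = vecs_sf[:ns, :ns]
    vt = vecs_sf[ns:, ns:]
    for j in range(nt):        # MCH triplet eigenstate j
        for k in range(nt):    # diabatic triplet state k
            for m in range(3):
                V[ns + 3 * k + m, ns + 3 * j + m] = vt[k, j]
    return V


def _active_mch(
    model: ModelPotential,
    V_comp: np.ndarray,
    W: np.ndarray,
    active: int,
) -> tuple[int, tuple[int, int]]:
    """MCH assignment of the active diagonal state: the MCH spin component
    with maximal squared overlap.  Returns (component index, label)."""
    overlaps = np.abs(V_comp.conj().T @ W[:, active]) ** 2
    comp = int(np.argmax(overlaps))
    sc = model.state_space.components[comp]
    return comp, (sc.multiplicity, sc.index)


def run_trajectory(
    model: ModelPotential,
    initial_condition: InitialCondition,
    settings: PropagatorSettings,
) -> Trajectory:
    """Propagate one surface-hopping trajectory.

    The initial electronic state is a pure state on the diagonal surface
    with maximal overlap with the assigned spin-free (MCH) excited state
    (δ-pulse excitation).  Per step the loop is: tracked diagonalization →
    velocity Verlet on the active surface → substepped amplitude
    propagation → energy-based decoherence → fewest-switches hop attempt.
    Deterministic under a fixed seed.
    """
    dt = settings.dt_fs * FS_TO_AU_TIME
    dt_el = settings.dt_electronic_fs * FS_TO_AU_TIME
    n_steps = settings.n_steps
    masses = model.masses
    rng = np.random.default_rng(settings.seed)
    ns = model.state_space.n_singlets
    n = model.n_components

    q = np.asarray(initial_condition.sample.coordinates, dtype=float).copy()
    v = np.asarray(initial_condition.sample.velocities, dtype=float).copy()
    if q.shape != (model.n_modes,):
        raise ValueError("initial condition does not match model dimensionality")

    H = model.hamiltonian(q)
    energies, W = diagonalize_tracked(H)
    e_sf, vecs_sf = model.spin_free_adiabatic(q)
    V_comp = _mch_component_vectors(model, vecs_sf)
    target_sf = initial_condition.initial_state
    if not 0 <= target_sf < model.n_spin_free:
        raise ValueError("initial state outside the model's state space")
    psi = V_comp[:, target_sf] if target_sf < ns else V_comp[:, ns + 3 * (target_sf - ns) + 1]
    active = int(np.argmax(np.abs(W.conj().T @ psi) ** 2))
    c = W[:, active].astype(complex).copy()

    dH = model.hamiltonian_gradient(q)
    grad = np.real(np.einsum("i,mij,j->m", W[:, active].conj(), dH, W[:, active]))

    rec_t = np.empty(n_steps + 1)
    rec_q = np.empty((n_steps + 1, model.n_modes))
    rec_v = np.empty((n_steps + 1, model.n_modes))
    rec_e = np.empty((n_steps + 1, n))
    rec_etot = np.empty(n_steps + 1)
    rec_active = np.empty(n_steps + 1, dtype=np.int32)
    rec_mult = np.empty(n_steps + 1, dtype=np.int8)
    rec_mchidx = np.empty(n_steps + 1, dtype=np.int16)
    rec_dip = np.empty(n_steps + 1)
    rec_pop = np.empty((n_steps + 1, n))
    hops: list[HopEvent] = []

    def record(step: int, t_fs: float) -> None:
        rec_t[step] = t_fs
        rec_q[step] = q
        rec_v[step] = v
        rec_e[step] = energies
        rec_etot[step] = energies[active].real + 0.5 * float(np.sum(masses * v**2))
        # analysis-facing label: energy rank of the active surface (the
        # tracked column order drifts from energy order through crossings)
        order = np.argsort(energies.real, kind="stable")
        rec_active[step] = int(np.nonzero(order == active)[0][0])
        comp, label = _active_mch(model, V_comp, W, active)
        rec_mult[step], rec_mchidx[step] = label
        if label[0] == 1 and label[1] > 0:
            dips = adiabatic_singlet_dipoles(vecs_sf, model.dipoles(q), ns)
            rec_dip[step] = float(np.linalg.norm(dips[label[1]]))
        else:
            rec_dip[step] = 0.0
        c_diag = W.conj().T @ c
        rec_pop[step] = np.abs(c_diag) ** 2

    record(0, 0.0)
    status = "completed"

    for step in range(1, n_steps + 1):
        try:
            H_prev, W_prev, energies_prev = H, W, energies
            c_diag_before = W_prev.conj().T @ c

            # nuclear step; the provider closure refreshes H/W at q_new
            new_state: dict = {}

            def grad_at(q_new: np.ndarray) -> np.ndarray:
                H_new = model.hamiltonian(q_new)
                e_new, W_new = diagonalize_tracked(H_new, W_prev)
                dH_new = model.hamiltonian_gradient(q_new)
                w = W_new[:, active]
                g = np.real(np.einsum("i,mij,j->m", w.conj(), dH_new, w))
                new_state.update(H=H_new, energies=e_new, W=W_new)
                return g

            q, v, grad = velocity_verlet_step(q, v, masses, grad, grad_at, dt)
            H, energies, W = new_state["H"], new_state["energies"], new_state["W"]

            c = propagate_amplitudes(c, H_prev, H, dt, dt_el)

            e_kin = 0.5 * float(np.sum(masses * v**2))
            c_diag = W.conj().T @ c
            if settings.decoherence_alpha is not None:
                c_diag = apply_decoherence(
                    c_diag, energies.real, active, e_kin, dt,
                    settings.decoherence_alpha,
                )
                c = W @ c_diag

            e_sf, vecs_sf = model.spin_free_adiabatic(q)
            V_comp = _mch_component_vectors(model, vecs_sf)

            if settings.hopping == "fewest-switches":
                probs = hop_probabilities(c_diag_before, c_diag, active, dt)
                prev_active = active
                active, v, outcome = attempt_hop(
                    active, probs, energies.real, v, masses, rng
                )
                if outcome is not None:
                    target, frustrated = outcome
                    _, from_label = _active_mch(model, V_comp, W, prev_active)
                    _, to_label = _active_mch(model, V_comp, W, target)
                    soc = None
                    if from_label[0] != to_label[0]:
                        soc = _mch_soc_magnitude(
                            model, H, V_comp, from_label, to_label
                        )
                    hops.append(
                        HopEvent(
                            time_fs=step * settings.dt_fs,
                            from_state=prev_active,
                            to_state=target,
                            from_mch=from_label,
                            to_mch=to_label,
                            delta_e_ev=float(
                                (energies[target] - energies[prev_active]).real
                            ) * HARTREE_TO_EV,
                            soc_cm1=soc,
                            geometry=q.copy(),
                            frustrated=frustrated,
                        )
                    )
                    if not frustrated:
                        # gradient belongs to the new active surface now
                        w = W[:, active]
                        dH_here = model.hamiltonian_gradient(q)
                        grad = np.real(
                            np.einsum("i,mij,j->m", w.conj(), dH_here, w)
                        )
            record(step, step * settings.dt_fs)
        except FloatingPointError:
            status = "crashed"
            break
    else:
        step = n_steps

    last = step if status == "completed" else step - 1
    return Trajectory(
        times_fs=rec_t[: last + 1].copy(),
        coordinates=rec_q[: last + 1].copy(),
        velocities=rec_v[: last + 1].copy(),
        energies=rec_e[: last + 1].copy(),
        total_energy=rec_etot[: last + 1].copy(),
        active=rec_active[: last + 1].copy(),
        mch_multiplicity=rec_mult[: last + 1].copy(),
        mch_index=rec_mchidx[: last + 1].copy(),
        mch_dipole=rec_dip[: last + 1].copy(),
        populations=rec_pop[: last + 1].copy(),
        hop_events=hops,
        termination_status=status,
    )


def _mch_soc_magnitude(
    model: ModelPotential,
    H: np.ndarray,
    V_comp: np.ndarray,
    label_a: tuple[int, int],
    label_b: tuple[int, int],
) -> float:
    """|SOC| (cm⁻¹) between two MCH states of different multiplicity:
    root-sum-square of the full-Hamiltonian matrix elements between the
    singlet eigenvector and the three Ms components of the triplet one."""
    ns = model.state_space.n_singlets
    if label_a[0] == 1:
        s_label, t_label = label_a, label_b
    else:
        s_label, t_label = label_b, label_a
    s_col = V_comp[:, s_label[1]]
    total = 0.0
    for m in range(3):
        t_col = V_comp[:, ns + 3 * t_label[1] + m]
        total += np.abs(s_col.conj() @ H @ t_col) ** 2
    return float(np.sqrt(total) * HARTREE_TO_CM1)
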