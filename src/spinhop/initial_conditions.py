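"""Initial conditions: harmonic Wigner sampling, absorption spectra and
oscillator-strength-weighted selection of initial excited states.

Geometries and velocities are drawn from the ground-vibrational-state
Wigner distribution of each normal mode (0 K, no thermal excitation): per
mode an independent Gaussian position with variance ħ/(2mω) and Gaussian
momentum with variance mωħ/2.  A stick spectrum of (excitation energy,
oscillator strength) pairs over the sampled pool is broadened with
Gaussians, and initial excited states for the trajectory ensemble are
selected with probability proportional to the oscillator strength,
optionally restricted to an excitation-energy window (δ-pulse picture:
instantaneous excitation, no finite pulse envelope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .electronic_models import ModelPotential
from .units import CM1_TO_HARTREE, HARTREE_TO_EV

__all__ = [
    "NormalModeSet",
    "WignerSample",
    "InitialCondition",
    "SelectionResult",
    "sample_wigner",
    "oscillator_strength",
    "simulate_spectrum",
    "compute_excitations",
    "select_initial_conditions",
    "read_modes_file",
]


class EmptySelectionError(RuntimeError):
    """No (sample, state) pair is eligible under the requested window."""


@dataclass(frozen=True)
class NormalModeSet:
    """Harmonic normal modes used for Wigner sampling.

    ``displacements`` maps mode coordinates to the coordinate space of the
    provider: row m is the (mass-weighted, orthonormal) displacement vector
    of mode m.  For reduced-dimensional models this is the identity and the
    reference is the origin.
    """

    reference: np.ndarray
    frequencies_cm1: np.ndarray
    displacements: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        nm = len(self.frequencies_cm1)
        if self.displacements.shape[0] != nm or len(self.masses) != nm:
            raise ValueError("mode arrays have inconsistent lengths")
        if self.displacements.shape[1] != len(self.reference):
            raise ValueError("displacement vectors do not match the reference")

    @property
    def n_modes(self) -> int:
        return len(self.frequencies_cm1)

    @classmethod
    def from_model(cls, model: ModelPotential) -> "NormalModeSet":
        """Modes of an LVC model: identity displacements about the origin."""
        nm = model.n_modes
        return cls(
            reference=np.zeros(nm),
            frequencies_cm1=model.omega / CM1_TO_HARTREE,
            displacements=np.eye(nm),
            masses=model.masses.copy(),
        )


@dataclass(frozen=True)
class WignerSample:
    """One phase-space draw: coordinates and velocities in the provider's
    coordinate space, with provenance for reproducibility."""

    coordinates: np.ndarray
    velocities: np.ndarray
    index: int
    seed: int


@dataclass(frozen=True)
class InitialCondition:
    """A Wigner sample with its assigned initial spin-free excited state
    (MCH index), vertical excitation energy and oscillator strength."""

    sample: WignerSample
    initial_state: int
    excitation_energy_ev: float
    oscillator_strength: float

    def __post_init__(self) -> None:
        if self.oscillator_strength < 0:
            raise ValueError("oscillator strength must be non-negative")
        if self.excitation_energy_ev <= 0:
            raise ValueError("excitation energy must be positive")


def sample_wigner(
    modes: NormalModeSet, n: int, seed: int
) -> list[WignerSample]:
    """Draw ``n`` independent samples from the ground-state harmonic Wigner
    distribution of the given modes.

    Per mode, position and momentum are independent Gaussians with
    variances ħ/(2mω) and mωħ/2 (atomic units); velocities are p/m.
    Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    omega = np.asarray(modes.frequencies_cm1, dtype=float) * CM1_TO_HARTREE
    if np.any(omega <= 0):
        raise ValueError("all sampled frequencies must be positive")
    m = np.asarray(modes.masses, dtype=float)
    rng = np.random.default_rng(seed)
    sigma_q = np.sqrt(1.0 / (2.0 * m * omega))
    sigma_p = np.sqrt(m * omega / 2.0)
    q = rng.normal(0.0, 1.0, (n, modes.n_modes)) * sigma_q
    p = rng.normal(0.0, 1.0, (n, modes.n_modes)) * sigma_p
    coords = modes.reference + q @ modes.displacements
    vels = (p / m) @ modes.displacements
    return [
        WignerSample(coords[i].copy(), vels[i].copy(), i, seed)
        for i in range(n)
    ]


def oscillator_strength(delta_e: float, dipole: np.ndarray) -> float:
    """Length-gauge oscillator strength f = (2/3)·ΔE·|μ|² (atomic units)."""
    if delta_e <= 0:
        raise ValueError("excitation energy must be positive")
    mu2 = float(np.dot(dipole, dipole))
    return (2.0 / 3.0) * float(delta_e) * mu2


def simulate_spectrum(
    conditions: Sequence[tuple[float, float]],
    fwhm_ev: float = 0.1,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-broadened absorption spectrum from (ΔE [eV], f) sticks.

    Each stick contributes a Gaussian of full width at half maximum
    ``fwhm_ev`` centred at its excitation energy with area proportional to
    its oscillator strength.  Returns (energy grid [eV], intensity).
    """
    if fwhm_ev <= 0:
        raise ValueError("fwhm must be positive")
    if len(conditions) == 0:
        warnings.warn("empty condition list: returning an empty spectrum")
        return np.array([]), np.array([])
    e = np.asarray([c[0] for c in conditions], dtype=float)
    f = np.asarray([c[1] for c in conditions], dtype=float)
    sigma = fwhm_ev / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if grid is None:
        lo = e.min() - 5.0 * sigma
        hi = e.max() + 5.0 * sigma
        grid = np.linspace(lo, hi, 2001)
    grid = np.asarray(grid, dtype=float)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    intensity = np.zeros_like(grid)
    for ei, fi in zip(e, f):
        intensity += fi * norm * np.exp(-0.5 * ((grid - ei) / sigma) ** 2)
    return grid, intensity


@dataclass(frozen=True)
class ExcitationRecord:
    """One eligible (sample, state) pair in the selection pool."""

    sample_index: int
    state: int  # spin-free adiabatic (MCH) index
    delta_e_ev: float
    f: float


def compute_excitations(
    model: ModelPotential, samples: Sequence[WignerSample]
) -> list[list[ExcitationRecord]]:
    """Vertical excitations of every sample: spin-free adiabatic excitation
    energies and oscillator strengths of the excited singlet states.

    Triplet states are spin-forbidden from the closed-shell ground state
    and enter with f = 0 (they are never selected)."""
    pool: list[list[ExcitationRecord]] = []
    ns = model.state_space.n_singlets
    for s in samples:
        delta_e, dip = model.adiabatic_dipoles(s.coordinates)
        records = []
        for i in range(1, model.n_spin_free):
            de = delta_e[i]
            if de <= 0:
                continue
            f = oscillator_strength(de, dip[i]) if i < ns else 0.0
            records.append(
                ExcitationRecord(s.index, i, de * HARTREE_TO_EV, f)
            )
        pool.append(records)
    return pool


@dataclass(frozen=True)
class SelectionResult:
    """Selected initial conditions plus the per-state split of the
    selection (how many trajectories start in each excited state)."""

    conditions: tuple[InitialCondition, ...]
    state_counts: dict[int, int] = field(default_factory=dict)
    window: tuple[float, float] | None = None


def select_initial_conditions(
    pool: Sequence[Sequence[ExcitationRecord]],
    samples: Sequence[WignerSample],
    n_traj: int,
    window: tuple[float, float] | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Select initial conditions with probability proportional to the
    oscillator strength among eligible (sample, state) pairs.

    ``window`` restricts eligibility to excitation energies inside the
    closed interval [E_lo, E_hi] (eV, both endpoints inclusive).  Selection
    draws with replacement; ties in the cumulative weights are broken by
    pool order.  Raises :class:`EmptySelectionError` when nothing is
    eligible.
    """
    if len(pool) == 0:
        raise ValueError("selection pool is empty")
    if window is not None and window[0] > window[1]:
        raise ValueError("window must be ordered [E_lo, E_hi]")
    flat: list[ExcitationRecord] = []
    for records in pool:
        for r in records:
            if window is not None and not (window[0] <= r.delta_e_ev <= window[1]):
                continue
            if r.f > 0:
                flat.append(r)
    if not flat:
        raise EmptySelectionError(
            "no eligible (sample, state) pair"
            + (f" in window {window}" if window is not None else "")
        )
    weights = np.array([r.f for r in flat], dtype=float)
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(flat), size=n_traj, replace=True, p=probs)
    sample_by_index = {s.index: s for s in samples}
    conditions = []
    counts: dict[int, int] = {}
    for idx in chosen:
        r = flat[int(idx)]
        conditions.append(
            InitialCondition(
                sample=sample_by_index[r.sample_index],
                initial_state=r.state,
                excitation_energy_ev=r.delta_e_ev,
                oscillator_strength=r.f,
            )
        )
        counts[r.state] = counts.get(r.state, 0) + 1
    return SelectionResult(tuple(conditions), counts, window)


def read_modes_file(path) -> NormalModeSet:
    """Read a plain-text normal-modes file.

    Format (whitespace separated, ``#`` comments): first a line
    ``modes N DOF``, then a line with the DOF reference coordinates, then
    per mode one line ``freq_cm1 mass_au d_1 ... d_DOF``.
    """
    freqs, masses, disps = [], [], []
    reference = None
    header = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if header is None:
                tok = line.split()
                if tok[0] != "modes" or len(tok) != 3:
                    raise ValueError("modes file must start with 'modes N DOF'")
                header = (int(tok[1]), int(tok[2]))
                continue
            if reference is None:
                reference = np.array([float(x) for x in line.split()])
                if len(reference) != header[1]:
                    raise ValueError("reference length does not match DOF count")
                continue
            vals = [float(x) for x in line.split()]
            if len(vals) != 2 + header[1]:
                raise ValueError(f"bad mode line: {raw!r}")
            freqs.append(vals[0])
            masses.append(vals[1])
            disps.append(vals[2:])
    if header is None or reference is None or len(freqs) != header[0]:
        raise ValueError("incomplete modes file")
    return NormalModeSet(
        reference=reference,
        frequencies_cm1=np.array(freqs),
        displacements=np.array(disps),
        masses=np.array(masses),
    )
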