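"""Ensemble observables: population traces, trajectory filtering, hop
statistics and hop-geometry descriptors.

Populations are classical occupations (the fraction of trajectories whose
active state carries each class label at each time), reported in one of
three representations:

* ``diagonal`` — the spin-mixed eigensurfaces the nuclei actually move on;
* ``mch`` — molecular Coulomb Hamiltonian states (the familiar S0, S1,
  T1, ... labels from the spin-free Hamiltonian, Ms components summed);
* ``spectroscopic`` — classification by physical character via the
  ground-to-excited transition dipole of the occupied MCH state: bright
  ¹ππ* above 0.05 a.u., dark ¹nπ* between 1e-6 and 0.05 a.u., triplet
  below 1e-6 a.u., with the closed-shell ground state kept as its own
  class.  This approximates what pump–probe experiments monitor.

Trajectories that terminate early are kept only if their final contiguous
residence in S0 or T1 meets a threshold (15 fs by default); kept
early-terminated trajectories are frozen in their terminal class for the
remainder of the analysis grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .propagation import Trajectory

__all__ = [
    "BRIGHT_DIPOLE_THRESHOLD",
    "TRIPLET_DIPOLE_THRESHOLD",
    "CharacterLabel",
    "PopulationTrace",
    "HopSummary",
    "mch_assignment",
    "classify_spectroscopic",
    "ensemble_populations",
    "filter_trajectories",
    "hop_statistics",
    "bond_length",
    "out_of_plane_angle",
]

#: transition-dipole threshold (a.u.) above which a state is a bright ππ*
BRIGHT_DIPOLE_THRESHOLD = 0.05
#: transition-dipole threshold (a.u.) below which a state is a triplet
TRIPLET_DIPOLE_THRESHOLD = 1e-6

SPECTROSCOPIC_LABELS = ("S0-closed-shell", "bright-pipi*", "dark-npi*", "triplet")

CharacterLabel = str


def mch_assignment(U: np.ndarray, active_diagonal: int) -> int:
    """MCH spin component assigned to a diagonal state: the row of the
    MCH→diagonal transformation with maximal squared modulus in the active
    column."""
    col = U[:, active_diagonal]
    return int(np.argmax(np.abs(col) ** 2))


def classify_spectroscopic(
    transition_dipole_magnitude: float,
    multiplicity: int,
    is_ground: bool = False,
) -> CharacterLabel:
    """Character label of an occupied state from its ground-to-state
    transition dipole magnitude (a.u.).

    Strictly above 0.05 a.u. is bright ¹ππ*; [1e-6, 0.05] is dark ¹nπ*
    (the boundary value 0.05 is dark); below 1e-6 is triplet.  The
    closed-shell ground state always maps to its own class.
    """
    if transition_dipole_magnitude < 0:
        raise ValueError("dipole magnitude must be non-negative")
    if is_ground:
        return "S0-closed-shell"
    if multiplicity == 3 or transition_dipole_magnitude < TRIPLET_DIPOLE_THRESHOLD:
        return "triplet"
    if transition_dipole_magnitude > BRIGHT_DIPOLE_THRESHOLD:
        return "bright-pipi*"
    return "dark-npi*"


@dataclass(frozen=True)
class PopulationTrace:
    """Time-gridded per-class population fractions for an ensemble."""

    times_fs: np.ndarray
    labels: tuple[str, ...]
    fractions: np.ndarray  # (n_times, n_labels)
    representation: str
    n_trajectories: int

    def column(self, label: str) -> np.ndarray:
        return self.fractions[:, self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=list(self.labels))
        df.insert(0, "time_fs", self.times_fs)
        return df


def _class_indices(
    traj: Trajectory, representation: str, label_map: dict[str, int]
) -> np.ndarray:
    """Per-step class index of one trajectory under a representation."""
    if representation == "diagonal":
        keys = [f"D{a}" for a in traj.active]
    elif representation == "mch":
        keys = [
            f"S{i}" if m == 1 else f"T{i + 1}"
            for m, i in zip(traj.mch_multiplicity, traj.mch_index)
        ]
    elif representation == "spectroscopic":
        keys = [
            classify_spectroscopic(
                d, int(m), is_ground=(m == 1 and i == 0)
            )
            for d, m, i in zip(traj.mch_dipole, traj.mch_multiplicity, traj.mch_index)
        ]
    else:
        raise ValueError(f"unknown representation: {representation!r}")
    return np.array([label_map[k] for k in keys], dtype=np.int32)


def _all_labels(trajectories: Sequence[Trajectory], representation: str) -> tuple[str, ...]:
    if representation == "spectroscopic":
        return SPECTROSCOPIC_LABELS
    if representation == "diagonal":
        n = max(int(t.active.max()) for t in trajectories) + 1
        n = max(n, trajectories[0].energies.shape[1])
        return tuple(f"D{i}" for i in range(n))
    singlets = set()
    triplets = set()
    for t in trajectories:
        for m, i in zip(t.mch_multiplicity, t.mch_index):
            (singlets if m == 1 else triplets).add(int(i))
    labels = [f"S{i}" for i in sorted(singlets)]
    labels += [f"T{i + 1}" for i in sorted(triplets)]
    return tuple(labels)


def ensemble_populations(
    trajectories: Sequence[Trajectory],
    representation: str = "mch",
    grid: np.ndarray | None = None,
) -> PopulationTrace:
    """Fraction of trajectories in each class at each grid time.

    The default grid is the time grid of the longest trajectory (the
    nuclear-step grid).  A trajectory that ended before a grid time is held
    in its terminal class (early-terminated-but-valid trajectories do not
    leave S0/T1 in this model).  Fractions sum to one at every time.
    """
    if len(trajectories) == 0:
        raise ValueError("empty trajectory set")
    labels = _all_labels(trajectories, representation)
    label_map = {lab: k for k, lab in enumerate(labels)}
    if grid is None:
        grid = max((t.times_fs for t in trajectories), key=len)
    grid = np.asarray(grid, dtype=float)
    counts = np.zeros((len(grid), len(labels)))
    for traj in trajectories:
        cls = _class_indices(traj, representation, label_map)
        # map grid times onto this trajectory's own grid, clamping past its end
        idx = np.searchsorted(traj.times_fs, grid, side="right") - 1
        idx = np.clip(idx, 0, len(cls) - 1)
        counts[np.arange(len(grid)), cls[idx]] += 1.0
    fractions = counts / len(trajectories)
    return PopulationTrace(
        times_fs=grid,
        labels=labels,
        fractions=fractions,
        representation=representation,
        n_trajectories=len(trajectories),
    )


def filter_trajectories(
    trajectories: Sequence[Trajectory],
    t_max_fs: float,
    residence_threshold_fs: float = 15.0,
) -> tuple[list[Trajectory], list[Trajectory]]:
    """Validity rule for ensemble statistics: keep trajectories that
    finished the full simulation time, or that terminated early after
    residing contiguously in S0 or T1 (MCH assignment) for at least the
    threshold.

    Returns (kept, discarded).
    """
    if residence_threshold_fs < 0:
        raise ValueError("residence threshold must be non-negative")
    kept: list[Trajectory] = []
    discarded: list[Trajectory] = []
    for traj in trajectories:
        full = (
            traj.termination_status == "completed"
            and traj.times_fs[-1] >= t_max_fs - 1e-9
        )
        if full:
            kept.append(traj)
            continue
        in_terminal = (
            (traj.mch_multiplicity == 1) & (traj.mch_index == 0)
        ) | ((traj.mch_multiplicity == 3) & (traj.mch_index == 0))
        run = 0
        for flag in in_terminal[::-1]:
            if not flag:
                break
            run += 1
        if run > 0:
            residence = traj.times_fs[-1] - traj.times_fs[len(in_terminal) - run]
            if residence >= residence_threshold_fs:
                traj.termination_status = "early-stop-valid"
                kept.append(traj)
                continue
        discarded.append(traj)
    return kept, discarded


@dataclass(frozen=True)
class HopSummary:
    """Counts of accepted hops by transition class, frustrated-attempt
    count, and SOC / energy-gap statistics over the ISC hops."""

    singlet_ic: int = 0
    triplet_ic: int = 0
    isc_s_to_t: int = 0
    isc_t_to_s: int = 0
    frustrated: int = 0
    mean_isc_soc_cm1: Optional[float] = None
    max_isc_soc_cm1: Optional[float] = None
    mean_isc_gap_ev: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "singlet_ic": self.singlet_ic,
            "triplet_ic": self.triplet_ic,
            "isc_s_to_t": self.isc_s_to_t,
            "isc_t_to_s": self.isc_t_to_s,
            "frustrated": self.frustrated,
            "mean_isc_soc_cm1": self.mean_isc_soc_cm1,
            "max_isc_soc_cm1": self.max_isc_soc_cm1,
            "mean_isc_gap_ev": self.mean_isc_gap_ev,
        }


def hop_statistics(trajectories: Sequence[Trajectory]) -> HopSummary:
    """Classify every hop event by the multiplicities of its MCH
    endpoints.  ISC statistics (mean/max |SOC|, mean |ΔE|) are computed
    over accepted ISC hops only; means are absent when no ISC occurred."""
    counts = {"singlet_ic": 0, "triplet_ic": 0, "isc_s_to_t": 0, "isc_t_to_s": 0}
    frustrated = 0
    socs: list[float] = []
    gaps: list[float] = []
    for traj in trajectories:
        for hop in traj.hop_events:
            if hop.frustrated:
                frustrated += 1
                continue
            m_from, m_to = hop.from_mch[0], hop.to_mch[0]
            if m_from == m_to:
                counts["singlet_ic" if m_from == 1 else "triplet_ic"] += 1
            else:
                counts["isc_s_to_t" if m_from == 1 else "isc_t_to_s"] += 1
                if hop.soc_cm1 is not None:
                    socs.append(hop.soc_cm1)
                gaps.append(abs(hop.delta_e_ev))
    return HopSummary(
        **counts,
        frustrated=frustrated,
        mean_isc_soc_cm1=float(np.mean(socs)) if socs else None,
        max_isc_soc_cm1=float(np.max(socs)) if socs else None,
        mean_isc_gap_ev=float(np.mean(gaps)) if gaps else None,
    )


# ---------------------------------------------------------------------------
# geometric descriptors (Cartesian geometries, Å)
# ---------------------------------------------------------------------------

def bond_length(geometry: np.ndarray, i: int, j: int) -> float:
    """Euclidean distance between atoms i and j (same units as input)."""
    geometry = np.asarray(geometry, dtype=float)
    return float(np.linalg.norm(geometry[i] - geometry[j]))


def out_of_plane_angle(
    geometry: np.ndarray,
    center: int,
    plane_atoms: Sequence[int],
    anchor: int | None = None,
) -> float:
    """Angle (degrees) between a bond vector and the least-squares plane of
    ``plane_atoms``.

    The bond vector runs from ``anchor`` to ``center``; when no anchor is
    given the plane atom closest to ``center`` is used.  The plane is the
    total-least-squares fit through the plane atoms (smallest principal
    component of their centred coordinates).  Raises for (near-)collinear
    plane definitions.
    """
    geometry = np.asarray(geometry, dtype=float)
    pts = geometry[list(plane_atoms)]
    if len(pts) < 3:
        raise ValueError("need at least three atoms to define a plane")
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("plane atoms are collinear")
    normal = vt[2]
    if anchor is None:
        d = np.linalg.norm(pts - geometry[center], axis=1)
        anchor = int(list(plane_atoms)[int(np.argmin(d))])
    bond = geometry[center] - geometry[anchor]
    nb = np.linalg.norm(bond)
    if nb == 0:
        raise ValueError("zero-length bond vector")
    sin_angle = np.clip(abs(np.dot(bond, normal)) / nb, -1.0, 1.0)
    return float(np.degrees(np.arcsin(sin_angle)))
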