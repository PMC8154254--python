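"""Path scoring repeated over trajectory frames.

Small fluctuations in interatomic distances change which hydrogen-bond and
through-space jumps exist, and hence the optimal route. The covalent
topology is perceived once from the topology structure and held fixed;
hydrogen-bond and space edges are rebuilt per frame, edge distances are
re-measured from each frame's coordinates, and the optimal path recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .molecular_graph import (
    Edge,
    HBondCriteria,
    build_transfer_graph,
    detect_hbond_edges,
    perceive_covalent_bonds,
)
from .pathway_scoring import DecayParameters, PathResult, best_path
from .structure_io import Structure, Trajectory, resolve_atom

__all__ = [
    "ParticipationMap",
    "EnsembleDecaySummary",
    "per_frame_paths",
    "participation_frequencies",
    "ensemble_decay",
    "PARTICIPATION_BINS",
]

#: participation bins, left-open/right-closed on the fraction scale
PARTICIPATION_BINS: list[tuple[float, str]] = [
    (0.90, ">90%"),
    (0.80, "80–90%"),
    (0.65, "65–80%"),
    (0.50, "50–65%"),
    (0.40, "40–50%"),
    (0.30, "30–40%"),
    (0.10, "10–30%"),
]


def participation_bin(fraction: float) -> str:
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    for lo, label in PARTICIPATION_BINS:
        if fraction > lo:
            return label
    return "<10%"


@dataclass(frozen=True)
class ParticipationMap:
    """Per-atom frequency of appearing on the optimal path across frames."""

    fractions: dict[int, float]  # atom serial -> fraction of valid frames
    bins: dict[int, str]
    frames_valid: int
    frames_total: int

    def atoms_above(self, fraction: float) -> list[int]:
        return sorted(s for s, f in self.fractions.items() if f > fraction)


@dataclass(frozen=True)
class EnsembleDecaySummary:
    mean_ln_k: float
    sd_ln_k: float
    best_frame: tuple[int, float]
    worst_frame: tuple[int, float]
    frames_analyzed: int
    frames_total: int


def _refresh_distances(covalent: list[Edge], structure: Structure) -> list[Edge]:
    """Fixed covalent topology, distances re-measured from current coords."""
    pos = {a.serial: a.position for a in structure.atoms}
    return [
        replace(e, r_ij=float(np.linalg.norm(pos[e.atom_i] - pos[e.atom_j])))
        for e in covalent
    ]


def per_frame_paths(
    traj: Trajectory,
    donor,
    acceptor,
    params: DecayParameters = DecayParameters(),
    criteria: HBondCriteria = HBondCriteria(),
    space_cutoff: float = 6.0,
    forbid_fe_his: bool = False,
    subsample: int = 1,
) -> list[PathResult]:
    """Optimal path per frame (every ``subsample``-th frame analyzed).

    An acceptor unreachable in some frame yields the no-path sentinel for
    that frame; the frame still counts toward the totals.
    """
    if subsample < 1:
        raise ValueError("subsample must be >= 1")
    donor_atom = resolve_atom(traj.topology, donor)
    acceptor_atom = resolve_atom(traj.topology, acceptor)
    covalent_topo = perceive_covalent_bonds(traj.topology)

    results: list[PathResult] = []
    for k, frame_structure in enumerate(traj.iter_structures()):
        if k % subsample:
            continue
        covalent = _refresh_distances(covalent_topo, frame_structure)
        hbond = detect_hbond_edges(frame_structure, criteria, covalent=covalent)
        graph = build_transfer_graph(
            frame_structure, covalent=covalent, hbond=hbond, space_cutoff=space_cutoff
        )
        results.append(
            best_path(graph, donor_atom, acceptor_atom, params, forbid_fe_his=forbid_fe_his)
        )
    return results


def participation_frequencies(results: list[PathResult]) -> ParticipationMap:
    """Fraction of valid frames in which each atom lies on the optimal path."""
    if not results:
        raise ValueError("no path results supplied")
    valid = [r for r in results if r.found]
    if not valid:
        raise ValueError("no frame produced a valid path")
    counts: dict[int, int] = {}
    for r in valid:
        for serial in r.atoms:
            counts[serial] = counts.get(serial, 0) + 1
    fractions = {s: c / len(valid) for s, c in counts.items()}
    bins = {s: participation_bin(f) for s, f in fractions.items()}
    return ParticipationMap(
        fractions=fractions,
        bins=bins,
        frames_valid=len(valid),
        frames_total=len(results),
    )


def ensemble_decay(results: list[PathResult]) -> EnsembleDecaySummary:
    """Mean/sd of per-frame ln(k) plus the extreme frames.

    The mean of per-frame ln(k) — the geometric mean of the per-frame
    products — is the reported ensemble score; sentinel (pathless) frames
    are excluded from the statistics but reported in ``frames_total``.
    """
    if not results:
        raise ValueError("no path results supplied")
    valid = [(i, r.ln_k) for i, r in enumerate(results) if r.found]
    if not valid:
        raise ValueError("no frame produced a valid path")
    values = np.array([v for _, v in valid])
    best = max(valid, key=lambda t: t[1])
    worst = min(valid, key=lambda t: t[1])
    return EnsembleDecaySummary(
        mean_ln_k=float(values.mean()),
        sd_ln_k=float(values.std(ddof=0)),
        best_frame=best,
        worst_frame=worst,
        frames_analyzed=len(valid),
        frames_total=len(results),
    )
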