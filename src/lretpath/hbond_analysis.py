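"""Hydrogen-bond occupancy statistics over a trajectory.

For a chosen donor hydroxyl (e.g. a tyrosine OH) and a set of candidate
acceptor atoms, count the trajectory frames in which the geometric
hydrogen-bond criteria hold — hydrogen···acceptor distance below the cutoff
and donor-H···acceptor angle above it — and report per-pair occupancy with
mean geometry over the bonded frames. Distances are reported in nm, the
convention of the occupancy tables this mirrors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molecular_graph import HBondCriteria, perceive_covalent_bonds
from .structure_io import Trajectory, resolve_atom

__all__ = ["HBondRecord", "hbond_occupancy", "records_to_frame"]


@dataclass(frozen=True)
class HBondRecord:
    donor: tuple[str, int, str]     # (chain, residue number, residue name)
    donor_atom: str
    acceptor: tuple[str, int, str]
    acceptor_atom: str
    mean_distance_nm: float         # H···acceptor, over bonded frames
    mean_angle_deg: float           # donor-H···acceptor, over bonded frames
    occurrence_count: int
    occupancy_percent: float


def _angles_deg(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Vectorized donor-H···acceptor angle at H; inputs (n_frames, 3)."""
    v1 = d - h
    v2 = a - h
    cosang = np.einsum("ij,ij->i", v1, v2) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hbond_occupancy(
    traj: Trajectory,
    donor_selector,
    acceptor_selectors,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondRecord]:
    """Per-acceptor occupancy of the donor's hydrogen bond.

    The donor must carry at least one covalently attached hydrogen in the
    topology (polar hydrogen; united-atom topologies keep those). With
    several donor hydrogens each is evaluated and a frame counts once per
    donor-acceptor pair. Records are sorted by descending occupancy.
    """
    topo = traj.topology
    donor = resolve_atom(topo, donor_selector)
    covalent = perceive_covalent_bonds(topo)
    by_serial = {a.serial: a for a in topo.atoms}
    attached_h = []
    for e in covalent:
        if e.atom_i == donor.serial and by_serial[e.atom_j].element == "H":
            attached_h.append(by_serial[e.atom_j])
        elif e.atom_j == donor.serial and by_serial[e.atom_i].element == "H":
            attached_h.append(by_serial[e.atom_i])
    if not attached_h:
        raise ValueError(
            f"donor {donor.residue_name} {donor.chain_id}{donor.residue_number} "
            f"atom {donor.name} has no attached hydrogen in the topology"
        )

    acceptors = [resolve_atom(topo, sel) for sel in acceptor_selectors]
    if not acceptors:
        return []

    index = {a.serial: i for i, a in enumerate(topo.atoms)}
    coords = np.stack(traj.frames)  # (n_frames, n_atoms, 3)
    d_pos = coords[:, index[donor.serial], :]

    records = []
    n_frames = traj.frame_count
    for acc in acceptors:
        a_pos = coords[:, index[acc.serial], :]
        bonded = np.zeros(n_frames, dtype=bool)
        best_dist = np.full(n_frames, np.inf)
        best_angle = np.zeros(n_frames)
        for h in attached_h:
            h_pos = coords[:, index[h.serial], :]
            dist = np.linalg.norm(h_pos - a_pos, axis=1)
            ang = _angles_deg(d_pos, h_pos, a_pos)
            ok = (dist < criteria.max_ha_distance) & (ang > criteria.min_dha_angle)
            better = ok & (dist < best_dist)
            best_dist[better] = dist[better]
            best_angle[better] = ang[better]
            bonded |= ok
        count = int(bonded.sum())
        if count:
            mean_dist = float(best_dist[bonded].mean()) / 10.0  # Å -> nm
            mean_angle = float(best_angle[bonded].mean())
        else:
            mean_dist = math.nan
            mean_angle = math.nan
        records.append(
            HBondRecord(
                donor=donor.residue_id,
                donor_atom=donor.name,
                acceptor=acc.residue_id,
                acceptor_atom=acc.name,
                mean_distance_nm=mean_dist,
                mean_angle_deg=mean_angle,
                occurrence_count=count,
                occupancy_percent=100.0 * count / n_frames,
            )
        )
    records.sort(key=lambda r: (-r.occupancy_percent, r.acceptor, r.acceptor_atom))
    return records


def records_to_frame(records: list[HBondRecord]) -> pd.DataFrame:
    """Occupancy table with the standard columns (distances in nm)."""
    return pd.DataFrame(
        [
            {
                "donor_chain": r.donor[0],
                "donor_residue": f"{r.donor[2]}{r.donor[1]}",
                "donor_atom": r.donor_atom,
                "acceptor_residue": f"{r.acceptor[2]}{r.acceptor[1]}",
                "acceptor_atom": r.acceptor_atom,
                "distance_nm": r.mean_distance_nm,
                "angle_deg": r.mean_angle_deg,
                "occurrences": r.occurrence_count,
                "occupancy_percent": r.occupancy_percent,
            }
            for r in records
        ]
    )
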