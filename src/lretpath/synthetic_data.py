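"""Synthetic structures, graphs, and trajectories with known ground truth.

Every pipeline stage is testable without downloads: covalent chains and
bridged pairs have closed-form optimal path scores, occupancy trajectories
toggle a hydrogen bond with a prescribed Bernoulli rate, water boxes have
uniform density for rdf normalization, and random graphs feed the
brute-force path oracle. Fixtures use legal PDB vocabulary (GLY chains,
HOH waters) so they pass through the real reader; every stochastic
generator takes a mandatory seed and is bit-reproducible under it.
"""

from __future__ import annotations

import math

import numpy as np

from .molecular_graph import Edge, HBondCriteria, TransferGraph
from .pathway_scoring import DecayParameters, edge_decay
from .structure_io import Atom, Structure, Trajectory

__all__ = [
    "make_covalent_chain",
    "make_bridged_pair",
    "make_occupancy_trajectory",
    "make_water_box",
    "make_random_graph",
    "write_pdb",
]


def _chain_atoms(
    n_atoms: int,
    spacing: float,
    origin: np.ndarray,
    direction: np.ndarray,
    serial_start: int = 1,
    resnum_start: int = 1,
    chain_id: str = "A",
    element: str = "C",
    name: str = "CA",
) -> list[Atom]:
    atoms = []
    for i in range(n_atoms):
        atoms.append(
            Atom(
                serial=serial_start + i,
                name=name,
                element=element,
                residue_name="GLY",
                residue_number=resnum_start + i,
                chain_id=chain_id,
                position=origin + spacing * i * direction,
            )
        )
    return atoms


def make_covalent_chain(n_bonds: int, bond_length: float = 1.5) -> tuple[Structure, dict]:
    """Linear pseudo-molecule with a unique covalent donor→acceptor path.

    One carbon per residue along the x-axis; consecutive atoms are within
    the covalent distance rule, and with default decay parameters no
    through-space shortcut can beat the covalent route, so the optimal
    score is exactly n_bonds·ln(A_covalent).
    """
    if n_bonds < 1:
        raise ValueError("n_bonds must be >= 1")
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    atoms = _chain_atoms(n_bonds + 1, bond_length, np.zeros(3), np.array([1.0, 0, 0]))
    structure = Structure(atoms=atoms, identifier=f"chain{n_bonds}")
    params = DecayParameters()
    truth = {
        "kind": "chain",
        "n_bonds": n_bonds,
        "donor_serial": 1,
        "acceptor_serial": n_bonds + 1,
        "expected_ln_k": n_bonds * math.log(params.covalent.A),
        "expected_atom_count": n_bonds + 1,
    }
    return structure, truth


def make_bridged_pair(
    chain_a: int,
    chain_b: int,
    bridge_kind: str = "space",
    bridge_r: float = 3.4,
    bond_length: float = 1.5,
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[Structure, dict]:
    """Two covalent chains joined by exactly one hbond or space bridge.

    The optimal score is (chain_a + chain_b)·ln(A_cov) + ln(q_bridge),
    closed-form. For an hbond bridge the terminal atoms are oxygen and
    nitrogen and ``bridge_r`` must satisfy the heavy-atom detection
    criterion; for a space bridge all atoms are carbon and ``bridge_r``
    must fall in the space-only window (beyond covalent reach, within the
    default 6 Å cutoff).
    """
    if chain_a < 1 or chain_b < 1:
        raise ValueError("each chain needs at least one bond")
    if bridge_kind not in ("hbond", "space"):
        raise ValueError(f"bridge_kind must be hbond or space, got {bridge_kind!r}")
    if bridge_kind == "hbond" and not bridge_r < criteria.heavy_atom_fallback_distance:
        raise ValueError(
            f"bridge_r {bridge_r} outside the heavy-atom hydrogen-bond "
            f"criterion (< {criteria.heavy_atom_fallback_distance} Å)"
        )
    if bridge_kind == "space" and bridge_r <= 2.0:
        raise ValueError("space bridge_r must exceed covalent reach (> 2 Å)")

    x = np.array([1.0, 0, 0])
    na, nb = chain_a + 1, chain_b + 1
    atoms_a = _chain_atoms(na, bond_length, np.zeros(3), x)
    origin_b = np.array([(na - 1) * bond_length + bridge_r, 0.0, 0.0])
    atoms_b = _chain_atoms(
        nb, bond_length, origin_b, x,
        serial_start=na + 1, resnum_start=na + 1,
    )
    if bridge_kind == "hbond":  # polar termini so the fallback rule fires
        atoms_a[-1] = Atom(
            serial=atoms_a[-1].serial, name="OG", element="O",
            residue_name="GLY", residue_number=atoms_a[-1].residue_number,
            chain_id="A", position=atoms_a[-1].position,
        )
        atoms_b[0] = Atom(
            serial=atoms_b[0].serial, name="NZ", element="N",
            residue_name="GLY", residue_number=atoms_b[0].residue_number,
            chain_id="A", position=atoms_b[0].position,
        )
    structure = Structure(atoms=atoms_a + atoms_b, identifier="bridged_pair")

    params = DecayParameters()
    bridge_edge = Edge(atoms_a[-1].serial, atoms_b[0].serial, bridge_kind, bridge_r)
    q_bridge = edge_decay(bridge_edge, params)
    n_cov = chain_a + chain_b
    truth = {
        "kind": "bridged_pair",
        "bridge_kind": bridge_kind,
        "bridge_r": bridge_r,
        "donor_serial": 1,
        "acceptor_serial": na + nb,
        "expected_ln_k": n_cov * math.log(params.covalent.A) + math.log(q_bridge),
        "expected_atom_count": na + nb,
        "bridge_serials": (atoms_a[-1].serial, atoms_b[0].serial),
    }
    return structure, truth


def make_occupancy_trajectory(
    p_on: float, n_frames: int, seed: int
) -> tuple[Trajectory, np.ndarray]:
    """Donor-H···acceptor triad toggling a hydrogen bond with rate ``p_on``.

    Bonded frames place the acceptor at 1.8 Å from the hydrogen at a 165°
    donor-H···acceptor angle (inside the criteria); unbonded frames move it
    to 3.2 Å at the same angle (outside). Returns the trajectory and the
    ground-truth bonded mask.
    """
    if not 0 <= p_on <= 1:
        raise ValueError("p_on must be in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    mask = rng.random(n_frames) < p_on

    d = np.zeros(3)
    h = np.array([0.96, 0.0, 0.0])
    theta = math.radians(180.0 - 165.0)  # H->A direction, 165° from H->D

    def acceptor_pos(ha: float) -> np.ndarray:
        return h + ha * np.array([math.cos(theta), math.sin(theta), 0.0])

    atoms = [
        Atom(serial=1, name="O", element="O", residue_name="HOH",
             residue_number=1, chain_id="W", position=d, is_het=True, is_water=True),
        Atom(serial=2, name="H1", element="H", residue_name="HOH",
             residue_number=1, chain_id="W", position=h, is_het=True, is_water=True),
        Atom(serial=3, name="O", element="O", residue_name="HOH",
             residue_number=2, chain_id="W", position=acceptor_pos(1.8),
             is_het=True, is_water=True),
    ]
    topo = Structure(atoms=atoms, identifier=f"occupancy_p{p_on}")
    frames = []
    for on in mask:
        coords = np.array([d, h, acceptor_pos(1.8 if on else 3.2)])
        frames.append(coords)
    return Trajectory(topology=topo, frames=frames), mask


def make_water_box(
    density: float, box, seed: int, n_frames: int = 1
) -> tuple[Trajectory, dict]:
    """Uniform water-oxygen box around a central probe atom.

    The number of waters is Poisson-distributed about density·volume and
    positions are resampled uniformly each frame, so g(r) around the probe
    is flat at 1 (ideal-gas limit) under minimum-image distances.
    """
    box = np.asarray(box, dtype=float)
    if density <= 0 or np.any(box <= 0):
        raise ValueError("density and box edges must be positive")
    rng = np.random.default_rng(seed)
    volume = float(np.prod(box))
    n_waters = int(rng.poisson(density * volume))
    if n_waters < 1:
        raise ValueError("box too small: zero waters sampled")

    probe = Atom(
        serial=1, name="OH", element="O", residue_name="TYR",
        residue_number=1, chain_id="A", position=box / 2,
    )
    waters = [
        Atom(
            serial=2 + i, name="O", element="O", residue_name="HOH",
            residue_number=2 + i, chain_id="W",
            position=rng.uniform(0, 1, 3) * box,
            is_het=True, is_water=True,
        )
        for i in range(n_waters)
    ]
    topo = Structure(atoms=[probe] + waters, identifier="water_box")
    frames = []
    for k in range(n_frames):
        if k == 0:
            frames.append(topo.coordinates)
        else:
            coords = np.vstack([box / 2, rng.uniform(0, 1, (n_waters, 3)) * box])
            frames.append(coords)
    truth = {
        "kind": "water_box",
        "density": density,
        "box": box.tolist(),
        "n_waters": n_waters,
        "probe_serial": 1,
    }
    return Trajectory(topology=topo, frames=frames), truth


_KIND_DISTANCE_RANGES = {
    "covalent": (1.0, 1.8),
    "hbond": (2.5, 3.4),
    "space": (3.0, 6.0),
}


def make_random_graph(n_nodes: int, edge_prob: float, seed: int) -> TransferGraph:
    """Random typed graph for the path-search oracle tests.

    Each pair independently carries an edge with probability ``edge_prob``;
    kind and distance are drawn from kind-plausible ranges. Connectivity is
    not guaranteed, which exercises the no-path sentinel.
    """
    if not 2 <= n_nodes <= 14:
        raise ValueError("n_nodes must be in [2, 14]")
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    graph = TransferGraph(extra_nodes=range(1, n_nodes + 1), provenance=f"random({n_nodes},{edge_prob},{seed})")
    kinds = list(_KIND_DISTANCE_RANGES)
    for i in range(1, n_nodes + 1):
        for j in range(i + 1, n_nodes + 1):
            if rng.random() >= edge_prob:
                continue
            kind = kinds[rng.integers(len(kinds))]
            lo, hi = _KIND_DISTANCE_RANGES[kind]
            graph.add_edge(Edge(i, j, kind, float(rng.uniform(lo, hi))))
    return graph


# --- PDB writing for fixtures ----------------------------------------------

def write_pdb(structure: Structure, dest, frames: list[np.ndarray] | None = None) -> None:
    """Write a structure (optionally as a multi-model frame stack) as PDB."""
    from pathlib import Path

    def model_lines(coords: np.ndarray) -> list[str]:
        lines = []
        for i, a in enumerate(structure.atoms):
            record = "HETATM" if a.is_het else "ATOM  "
            x, y, z = coords[i]
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"{record}{a.serial:>5d} {name:<4s}{a.residue_name:>4s} "
                f"{a.chain_id:1s}{a.residue_number:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2s}"
            )
        return lines

    all_frames = frames if frames is not None else [structure.coordinates] + list(
        structure.extra_models
    )
    out: list[str] = []
    multi = len(all_frames) > 1
    for k, coords in enumerate(all_frames):
        if multi:
            out.append(f"MODEL     {k + 1:>4d}")
        out.extend(model_lines(coords))
        if multi:
            out.append("ENDMDL")
    out.append("END")
    Path(dest).write_text("\n".join(out) + "\n")
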