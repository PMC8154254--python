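"""Water structure around a target atom: radial distribution and minimum
distance.

The radial distribution function g(r) is the shell-volume-normalized
histogram of center-to-water-oxygen distances, divided by the reference
number density, averaged over frames; g -> 1 at large r for uniform
solvent. With a periodic box the minimum-image convention applies and the
reference density is N/V; without one (crystal structures) distances are
plain Euclidean and the density is estimated from the mean count inside
r_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Trajectory, resolve_atom

__all__ = ["RDFProfile", "MinDistanceSeries", "radial_distribution", "min_distance_series"]


@dataclass(frozen=True)
class RDFProfile:
    bin_centers: np.ndarray      # Å
    g_of_r: np.ndarray           # dimensionless
    raw_counts: np.ndarray       # mean count per bin (unnormalized variant)
    bin_width: float
    r_max: float
    frames_averaged: int
    reference_density: float     # waters/Å³

    def shell_integral(self) -> float:
        """∫ g(r) 4πr²ρ dr over [0, r_max] via exact shell volumes.

        Equals the mean water count within r_max.
        """
        edges = np.arange(0.0, self.r_max + self.bin_width / 2, self.bin_width)
        shells = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        return float(np.sum(self.g_of_r * shells * self.reference_density))


@dataclass(frozen=True)
class MinDistanceSeries:
    values: np.ndarray  # Å, one per frame

    def __len__(self) -> int:
        return len(self.values)


def _water_oxygen_indices(traj: Trajectory, water_selector=None) -> np.ndarray:
    topo = traj.topology
    if water_selector is None:
        idx = [
            i for i, a in enumerate(topo.atoms)
            if a.is_water and a.element == "O"
        ]
    else:
        idx = [i for i, a in enumerate(topo.atoms) if water_selector(a)]
    return np.asarray(idx, dtype=int)


def _distances(center: np.ndarray, others: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    delta = others - center
    if box is not None:
        delta -= box * np.round(delta / box)
    return np.linalg.norm(delta, axis=1)


def radial_distribution(
    traj: Trajectory,
    center_selector,
    water_selector=None,
    bin_width: float = 0.1,
    r_max: float = 10.0,
    box=None,
) -> RDFProfile:
    """Radial distribution of water oxygens around one target atom.

    ``water_selector`` may be a predicate Atom -> bool; by default all
    water-residue oxygens are used. ``box`` (3-vector, Å) activates the
    minimum-image convention and the N/V reference density.
    """
    if bin_width <= 0 or r_max <= 0:
        raise ValueError("bin_width and r_max must be positive")
    box_arr = None if box is None else np.asarray(box, dtype=float)
    if box_arr is not None and r_max > box_arr.min() / 2:
        raise ValueError(
            f"r_max {r_max} exceeds half the shortest box edge {box_arr.min() / 2}"
        )
    center = resolve_atom(traj.topology, center_selector)
    w_idx = _water_oxygen_indices(traj, water_selector)
    if w_idx.size == 0:
        raise ValueError("no water oxygens matched the selector")
    c_idx = traj.topology.atoms.index(center)

    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    inside = 0.0
    for frame in traj.frames:
        d = _distances(frame[c_idx], frame[w_idx], box_arr)
        hist, _ = np.histogram(d, bins=edges)
        counts += hist
        inside += float((d < r_max).sum())
    n_frames = traj.frame_count
    counts /= n_frames
    mean_inside = inside / n_frames

    if box_arr is not None:
        density = w_idx.size / float(np.prod(box_arr))
    else:
        density = mean_inside / (4.0 / 3.0 * np.pi * r_max**3)
    shells = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(density > 0, counts / (shells * density), 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFProfile(
        bin_centers=centers,
        g_of_r=g,
        raw_counts=counts,
        bin_width=bin_width,
        r_max=r_max,
        frames_averaged=n_frames,
        reference_density=float(density),
    )


def min_distance_series(
    traj: Trajectory,
    center_selector,
    water_selector=None,
    box=None,
) -> MinDistanceSeries:
    """Per-frame minimum distance from the target atom to any water oxygen."""
    center = resolve_atom(traj.topology, center_selector)
    w_idx = _water_oxygen_indices(traj, water_selector)
    if w_idx.size == 0:
        raise ValueError("no water oxygens matched the selector")
    c_idx = traj.topology.atoms.index(center)
    box_arr = None if box is None else np.asarray(box, dtype=float)
    values = np.array(
        [_distances(frame[c_idx], frame[w_idx], box_arr).min() for frame in traj.frames]
    )
    return MinDistanceSeries(values=values)
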