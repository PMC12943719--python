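"""Docking-pose clustering by RMSD with lowest-energy coverage selection.

Poses share the receptor frame, so RMSD is computed without superposition
(heavy atoms only by default). Clustering is the classic greedy
energy-seeded single pass: repeatedly seed a new cluster with the
lowest-energy unassigned pose and absorb every unassigned pose within the
RMSD threshold of that seed. Clusters are then taken in best-energy order
until they cover the requested fraction of all poses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import TopologyError
from .structio import PoseEnsemble


@dataclass(frozen=True)
class ClusteringConfig:
    rmsd_threshold: float = 5.0
    coverage_fraction: float = 0.70

    def __post_init__(self):
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be positive")
        if not (0 < self.coverage_fraction <= 1):
            raise ValueError("coverage_fraction must be in (0, 1]")


@dataclass
class PoseCluster:
    member_indices: list[int]
    representative_index: int
    best_energy: float

    def __post_init__(self):
        if not self.member_indices:
            raise ValueError("cluster must be non-empty")
        if self.representative_index not in self.member_indices:
            raise ValueError("representative must be a member")

    @property
    def size(self) -> int:
        return len(self.member_indices)


def pose_rmsd(
    pose_a: np.ndarray,
    pose_b: np.ndarray,
    elements: list[str] | None = None,
    heavy_only: bool = True,
) -> float:
    """Root-mean-square deviation between matched atoms, no superposition.

    If ``elements`` is supplied and ``heavy_only`` is set, hydrogens are
    excluded from the calculation.
    """
    a = np.asarray(pose_a, dtype=float)
    b = np.asarray(pose_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise TopologyError(f"pose shapes differ: {a.shape} vs {b.shape}")
    if elements is not None:
        if len(elements) != a.shape[0]:
            raise TopologyError("elements length does not match atom count")
        if heavy_only:
            mask = np.array([e != "H" for e in elements])
            if not mask.any():
                raise TopologyError("no heavy atoms to compare")
            a, b = a[mask], b[mask]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def cluster_poses(
    ensemble: PoseEnsemble,
    config: ClusteringConfig | None = None,
    heavy_only: bool = True,
) -> list[PoseCluster]:
    """Greedy energy-seeded clustering of an ensemble.

    Deterministic: energy ties are broken by pose index (file order).
    Returns clusters sorted by best_energy ascending; every pose belongs
    to exactly one cluster.
    """
    config = config or ClusteringConfig()
    n = ensemble.n_poses
    if n < 1:
        raise ValueError("ensemble has no poses")
    elements = [a.element for a in ensemble.topology.atoms]
    energies = ensemble.energies
    order = sorted(range(n), key=lambda i: (energies[i], i))
    unassigned = set(range(n))
    clusters: list[PoseCluster] = []
    for seed in order:
        if seed not in unassigned:
            continue
        members = [seed]
        unassigned.discard(seed)
        for j in sorted(unassigned):
            if (
                pose_rmsd(ensemble.poses[seed], ensemble.poses[j], elements, heavy_only)
                <= config.rmsd_threshold
            ):
                members.append(j)
        for j in members[1:]:
            unassigned.discard(j)
        rep = min(members, key=lambda i: (energies[i], i))
        clusters.append(
            PoseCluster(
                member_indices=sorted(members),
                representative_index=rep,
                best_energy=float(energies[rep]),
            )
        )
    clusters.sort(key=lambda c: (c.best_energy, c.member_indices[0]))
    return clusters


def select_covering_clusters(
    clusters: list[PoseCluster],
    config: ClusteringConfig | None = None,
    n_total: int | None = None,
) -> list[PoseCluster]:
    """Lowest-energy clusters whose cumulative size reaches the coverage.

    Clusters are taken in best-energy order until the cumulative member
    count reaches ``ceil(coverage_fraction * n_total)``; at least one
    cluster is always returned.
    """
    config = config or ClusteringConfig()
    if not clusters:
        raise ValueError("no clusters to select from")
    if n_total is None:
        n_total = sum(c.size for c in clusters)
    needed = math.ceil(config.coverage_fraction * n_total)
    selected: list[PoseCluster] = []
    covered = 0
    for cluster in sorted(clusters, key=lambda c: (c.best_energy, c.member_indices[0])):
        selected.append(cluster)
        covered += cluster.size
        if covered >= needed:
            break
    return selected
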