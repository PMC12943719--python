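"""Synthetic binding pockets, planted hydrogen bonds, pose ensembles and
two-class ligand datasets.

The toy pocket is an abstract stand-in for a phosphodiesterase-like
catalytic site: a short protein stretch containing a glutamine probe at
residue 443, a configurable number of waters (residues 1..n), one Zn and
one Mg ion, and a ligand carrying a uniquely named acetyl carbonyl oxygen
(``OAC``). Planted geometry is exact: the generator records every drawn
hydrogen-bond distance and count, and detection recovers them verbatim,
so statistical recovery can be tested end-to-end without any external
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import PlacementError, SelectorError
from .structio import Atom, Complex, PoseEnsemble, _build_covalent_map

_OH = 0.96   # covalent O-H / N-H bond length used for planted hydrogens
_MIN_D, _MAX_D = 1.60, 3.44  # planted H...A window, safely inside the criterion
_COS_LO, _COS_HI = -0.98, -0.55  # cos(theta) window ~ (123.4, 168.5) degrees


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _perpendicular(u: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, probe)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, probe))


def _cone_directions(axis: np.ndarray, n_ring: int = 6) -> list[np.ndarray]:
    """Well-separated unit vectors inside a cone around ``axis``:
    the axis itself, a ring at 55 degrees and a sparser ring at 85."""
    axis = _unit(axis)
    p = _perpendicular(axis)
    q = np.cross(axis, p)
    dirs = [axis]
    for half_angle, count, phase in ((55.0, n_ring, 0.0), (85.0, 4, 30.0)):
        s, c = math.sin(math.radians(half_angle)), math.cos(math.radians(half_angle))
        for k in range(count):
            phi = math.radians(phase + 360.0 * k / count)
            dirs.append(c * axis + s * (math.cos(phi) * p + math.sin(phi) * q))
    return dirs


# ---------------------------------------------------------------------------
# Toy pocket construction
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    for i in range(n):
        y = 1.0 - 2.0 * (i + 0.5) / n
        r = math.sqrt(max(0.0, 1.0 - y * y))
        theta = golden * i
        pts.append([r * math.cos(theta), y, r * math.sin(theta)])
    return np.array(pts)


def build_toy_pocket(seed: int = 0, n_waters: int = 14) -> Complex:
    """Deterministic synthetic pocket: ligand + 5 residues (Gln443 probe)
    + ``n_waters`` waters (residue_seq 1..n) + Zn and Mg ions."""
    rng = np.random.default_rng(seed)
    atoms: list[tuple[str, str, str, str, int, np.ndarray]] = []
    # (name, element, resname, chain, resseq, coords)

    # --- ligand: benzene-like ring + acetyl branch, resname LIG ---
    ring = []
    for k in range(6):
        ang = math.radians(60 * k)
        ring.append(np.array([1.4 * math.cos(ang), 1.4 * math.sin(ang), 0.0]))
    lig = [(f"C{k + 1}", "C", ring[k]) for k in range(6)]
    cac = np.array([2.90, 0.0, 0.0])
    oac = np.array([3.50, 1.05, 0.0])
    cme = np.array([3.65, -1.30, 0.0])
    lig += [("CAC", "C", cac), ("OAC", "O", oac), ("CME", "C", cme)]
    for k, off in enumerate(
        [np.array([0.63, -0.63, 0.63]), np.array([0.63, -0.63, -0.63]),
         np.array([0.9, 0.3, 0.0])]
    ):
        lig.append((f"HM{k + 1}", "H", cme + _unit(off) * 1.09))
    for name, elem, xyz in lig:
        atoms.append((name, elem, "LIG", "L", 900, xyz))

    # --- Gln443 probe: backbone + side-chain amide, NE2 ~4.5 A above OAC,
    # amide hydrogens pointing away from the ligand ---
    ne2 = oac + np.array([0.0, 0.0, 4.5])
    cd = ne2 + np.array([0.0, 1.33, 0.0])
    oe1 = cd + _unit(np.array([0.9, 0.3, -0.9])) * 1.23
    cg = cd + np.array([0.0, 1.00, 1.15])
    cb = cg + np.array([0.0, 0.0, 1.52])
    ca = cb + np.array([0.0, 1.00, 1.15])
    n = ca + np.array([1.20, 0.70, 0.40])
    h = n + _unit(np.array([0.5, 0.8, 0.3])) * _OH
    c = ca + np.array([-1.20, 0.80, 0.50])
    o = c + np.array([0.0, 1.00, 0.71])
    he21 = ne2 + np.array([0.0, -0.30, 0.91])
    he22 = ne2 + _unit(np.array([0.93, -0.25, 0.2])) * _OH
    for name, elem, xyz in [
        ("N", "N", n), ("H", "H", h), ("CA", "C", ca), ("C", "C", c), ("O", "O", o),
        ("CB", "C", cb), ("CG", "C", cg), ("CD", "C", cd), ("OE1", "O", oe1),
        ("NE2", "N", ne2), ("HE21", "H", he21), ("HE22", "H", he22),
    ]:
        atoms.append((name, elem, "GLN", "A", 443, xyz))

    # --- four alanine-like residues well away from the ligand ---
    for k, resseq in enumerate((440, 441, 442, 444)):
        base = np.array([-8.0, -6.0, -4.5 + 3.2 * k])
        for name, elem, off in [
            ("N", "N", np.array([0.0, 0.0, 0.0])),
            ("H", "H", _unit(np.array([-0.6, -0.75, 0.0])) * _OH),
            ("CA", "C", np.array([1.46, 0.0, 0.0])),
            ("CB", "C", np.array([1.96, 1.20, 0.80])),
            ("C", "C", np.array([2.10, -1.10, -0.80])),
            ("O", "O", np.array([2.10, -1.10, -2.03])),
        ]:
            atoms.append((name, elem, "ALA", "A", resseq, base + off))

    # --- waters on an outer shell, >= 5 A from the ligand ---
    heavy_so_far = np.array([a[5] for a in atoms if a[1] != "H"])
    shell = _fibonacci_sphere(max(n_waters, 1))
    water_o: list[np.ndarray] = []
    for i in range(n_waters):
        radius = 8.5
        pos = shell[i] * radius
        while heavy_so_far.size and np.min(
            np.linalg.norm(heavy_so_far - pos, axis=1)
        ) < 3.0:
            radius += 1.0
            pos = shell[i] * radius
        water_o.append(pos)
        heavy_so_far = np.vstack([heavy_so_far, pos])
    for i, opos in enumerate(water_o, start=1):
        u = _unit(opos)  # outward
        p = _perpendicular(u)
        h1 = opos + _OH * (math.cos(math.radians(52)) * u + math.sin(math.radians(52)) * p)
        h2 = opos + _OH * (math.cos(math.radians(52)) * u - math.sin(math.radians(52)) * p)
        atoms.append(("OW", "O", "SOL", "W", i, opos))
        atoms.append(("HW1", "H", "SOL", "W", i, h1))
        atoms.append(("HW2", "H", "SOL", "W", i, h2))

    # --- ions near waters 1 and 13 (or the last water) ---
    zn_anchor = water_o[0]
    mg_anchor = water_o[min(12, n_waters - 1)] if n_waters else np.array([0, 0, 9.0])
    atoms.append(("ZN", "ZN", "ZN", "M", 501, zn_anchor + _unit(zn_anchor) * 2.1))
    atoms.append(("MG", "MG", "MG", "M", 502, mg_anchor + _unit(mg_anchor) * 2.1))

    jitter = rng.uniform(-0.02, 0.02, size=(len(atoms), 3))
    built = [
        Atom(
            serial=i + 1, name=name, element=elem, residue_name=resname,
            residue_seq=resseq, chain=chain,
            coords=np.round(xyz + jitter[i], 3),
            role=_role_for(resname, elem),
            record="ATOM" if resname in ("GLN", "ALA") else "HETATM",
        )
        for i, (name, elem, resname, chain, resseq, xyz) in enumerate(atoms)
    ]
    cplx = Complex(atoms=built, covalent_map=_build_covalent_map(built), label="toy")
    _check_clashes(cplx)
    return cplx


def _role_for(resname: str, element: str) -> str:
    if resname in ("SOL", "HOH", "WAT"):
        return "water"
    if resname in ("ZN", "MG"):
        return "ion"
    if resname == "LIG":
        return "ligand"
    return "protein"


def _check_clashes(cplx: Complex, min_dist: float = 1.8) -> None:
    heavy = [i for i, a in enumerate(cplx.atoms) if not a.is_hydrogen]
    coords = np.array([cplx.atoms[i].coords for i in heavy])
    bonded = set(cplx.covalent_map)
    for ii in range(len(heavy)):
        d = np.linalg.norm(coords[ii + 1:] - coords[ii], axis=1)
        for off in np.nonzero(d < min_dist)[0]:
            i, j = heavy[ii], heavy[ii + 1 + int(off)]
            if (min(i, j), max(i, j)) not in bonded:
                raise PlacementError(
                    f"non-covalent heavy-atom clash: atoms {i} and {j} at "
                    f"{d[off]:.2f} A"
                )


# ---------------------------------------------------------------------------
# Planted hydrogen bonds
# ---------------------------------------------------------------------------

def _resolve_atom(cplx: Complex, spec: tuple[str, int, str]) -> int:
    resname, resseq, name = spec
    for i, a in enumerate(cplx.atoms):
        if a.residue_name == resname and a.residue_seq == resseq and a.name == name:
            return i
    raise SelectorError(f"no atom matching {resname}{resseq}:{name}")


def plant_hbond(
    cplx: Complex,
    donor_spec: tuple[str, int, str],
    acceptor_spec: tuple[str, int, str],
    distance: float,
    angle: float,
) -> Complex:
    """Reposition a donor's hydrogen and the acceptor so the recomputed
    H...A distance and D-H...A angle equal the request (within 1e-6).

    Only those two atoms move. The donor heavy atom specified by
    ``donor_spec`` must carry at least one hydrogen; the first bonded
    hydrogen is the one moved.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if not (0 <= angle <= 180):
        raise ValueError("angle must be within [0, 180] degrees")
    d_idx = _resolve_atom(cplx, donor_spec)
    a_idx = _resolve_atom(cplx, acceptor_spec)
    hydrogens = sorted(
        j for j in cplx.bonded_to(d_idx) if cplx.atoms[j].is_hydrogen
    )
    if not hydrogens:
        raise SelectorError(
            f"donor {donor_spec} carries no covalently bonded hydrogen"
        )
    h_idx = hydrogens[0]

    coords = cplx.coords
    d_pos = coords[d_idx]
    # point the hydrogen away from the donor's covalent neighborhood
    neighbors = [
        j for j in cplx.bonded_to(d_idx) if not cplx.atoms[j].is_hydrogen
    ]
    if neighbors:
        away = d_pos - np.mean([coords[j] for j in neighbors], axis=0)
    else:
        away = d_pos - np.mean(
            [a.coords for a in cplx.atoms if not a.is_hydrogen], axis=0
        )
    u0 = _unit(away) if np.linalg.norm(away) > 1e-6 else np.array([0.0, 0.0, 1.0])
    theta = math.radians(angle)
    exempt_from_h = set(cplx.bonded_to(d_idx)) | {d_idx, h_idx, a_idx}

    def _collision(pos_h, pos_a):
        moved = {d_idx, h_idx, a_idx}
        for i, atom in enumerate(cplx.atoms):
            if i in moved:
                continue
            lim = 1.0 if atom.is_hydrogen else 1.5
            if i not in exempt_from_h and np.linalg.norm(atom.coords - pos_h) < lim:
                return atom
            if np.linalg.norm(atom.coords - pos_a) < lim:
                return atom
        return None

    axes = [np.array(v, dtype=float) for v in
            ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))]
    h_new = a_new = None
    clash = None
    for u in [u0] + axes:  # candidate hydrogen directions x acceptor azimuths
        h_cand = d_pos + _OH * u
        p0 = _perpendicular(u)
        q0 = np.cross(u, p0)
        for k in range(12):
            phi = math.radians(30.0 * k)
            p = math.cos(phi) * p0 + math.sin(phi) * q0
            w = -math.cos(theta) * u + math.sin(theta) * p
            candidate = h_cand + distance * w
            clash = _collision(h_cand, candidate)
            if clash is None:
                h_new, a_new = h_cand, candidate
                break
        if a_new is not None:
            break
    if a_new is None:
        raise PlacementError(
            f"requested geometry collides with atom {clash.name!r} "
            f"({clash.residue_name}{clash.residue_seq})"
        )

    coords = coords.copy()
    coords[h_idx] = h_new
    coords[a_idx] = a_new
    out = cplx.with_coords(coords)
    # self-check the construction
    got_d = float(np.linalg.norm(a_new - h_new))
    v1, v2 = d_pos - h_new, a_new - h_new
    got_a = math.degrees(
        math.acos(
            np.clip(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
        )
    )
    if abs(got_d - distance) > 1e-6 or abs(got_a - angle) > 1e-6:
        raise PlacementError(
            f"planted geometry off target: d={got_d}, angle={got_a}"
        )
    return out


# ---------------------------------------------------------------------------
# Pose ensembles with planted cluster structure
# ---------------------------------------------------------------------------

def simulate_pose_ensemble(
    topology: Complex,
    n_poses: int = 100,
    n_clusters: int = 3,
    intra_spread: float = 1.0,
    inter_separation: float = 20.0,
    cluster_weights: list[float] | None = None,
    seed: int = 0,
) -> tuple[PoseEnsemble, np.ndarray]:
    """Poses jittered around displaced copies of the topology's ligand.

    Cluster k is displaced by ``k * inter_separation`` along x; per-atom
    jitter has norm <= ``intra_spread``. Energies are drawn so cluster 0
    has the lowest minimum. Returns (ensemble, ground-truth labels).
    """
    if n_poses < 1 or n_clusters < 1:
        raise ValueError("need at least one pose and one cluster")
    if cluster_weights is None:
        cluster_weights = [1.0 / n_clusters] * n_clusters
    if len(cluster_weights) != n_clusters:
        raise ValueError("one weight per cluster required")
    if abs(sum(cluster_weights) - 1.0) > 1e-8:
        raise ValueError(f"cluster weights must sum to 1, got {sum(cluster_weights)}")

    lig_idx = topology.indices_by_role("ligand")
    if not lig_idx:
        lig_idx = list(range(len(topology.atoms)))
    lig_atoms = [topology.atoms[i] for i in lig_idx]
    base = np.array([a.coords for a in lig_atoms])
    lig_topology = Complex(
        atoms=lig_atoms,
        covalent_map=[],
        label=topology.label,
    )

    rng = np.random.default_rng(seed)
    labels = rng.choice(n_clusters, size=n_poses, p=cluster_weights)
    poses, energies = [], []
    for lab in labels:
        shift = np.array([lab * inter_separation, 0.0, 0.0])
        if intra_spread > 0:
            direction = rng.normal(size=base.shape)
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            radius = intra_spread * rng.uniform(0, 1, size=(len(base), 1)) ** (1 / 3)
            jitter = direction * radius
        else:
            jitter = 0.0
        poses.append(base + shift + jitter)
        energies.append(-30.0 + 4.0 * lab + rng.uniform(0.0, 1.0))
    ensemble = PoseEnsemble(
        topology=lig_topology, poses=poses, energies=np.array(energies)
    )
    return ensemble, labels


# ---------------------------------------------------------------------------
# Two-class datasets
# ---------------------------------------------------------------------------

@dataclass
class ClassGeometryModel:
    """Class-dependent hydrogen-bond geometry distributions.

    Defaults encode the target effect sizes: low-active ligands make more
    and shorter water bonds; active ligands favour the glutamine probe.
    """

    water_distance_mean_A: float = 2.64
    water_distance_mean_I: float = 2.18
    water_distance_sd: float = 0.2
    bonds_per_pose_A: float = 1.47
    bonds_per_pose_I: float = 2.13
    gln_distance_mean_A: float = 2.77
    gln_distance_mean_I: float = 2.81
    gln_distance_sd: float = 0.2
    gln_bonds_per_pose_A: float = 0.8
    gln_bonds_per_pose_I: float = 0.6
    n_waters: int = 14
    poses_per_ligand: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("water_distance_mean_A", "water_distance_mean_I",
                     "gln_distance_mean_A", "gln_distance_mean_I"):
            v = getattr(self, name)
            if not (1.5 < v < 3.5):
                raise ValueError(f"{name}={v} outside the feasible (1.5, 3.5) window")
        for name in ("bonds_per_pose_A", "bonds_per_pose_I",
                     "gln_bonds_per_pose_A", "gln_bonds_per_pose_I"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.water_distance_sd <= 0 or self.gln_distance_sd <= 0:
            raise ValueError("distance sds must be positive")
        if self.poses_per_ligand < 1 or self.n_waters < 2:
            raise ValueError("need >= 1 pose per ligand and >= 2 waters")

    def params(self, class_label: str) -> dict:
        if class_label not in ("A", "I"):
            raise ValueError(f"unknown class {class_label!r}")
        s = class_label
        return {
            "water_mean": getattr(self, f"water_distance_mean_{s}"),
            "water_sd": self.water_distance_sd,
            "water_rate": getattr(self, f"bonds_per_pose_{s}"),
            "gln_mean": getattr(self, f"gln_distance_mean_{s}"),
            "gln_sd": self.gln_distance_sd,
            "gln_rate": getattr(self, f"gln_bonds_per_pose_{s}"),
        }


@dataclass
class ClassTruth:
    """Analytic expectations implied by the generator's draw laws."""

    water_distance_mean: float
    water_bonds_per_pose: float
    gln_distance_mean: float
    gln_bonds_per_pose: float


@dataclass
class LigandSample:
    ligand_id: str
    class_label: str
    water_distances: list[np.ndarray]   # one array per pose
    water_partners: list[list[int]]     # water residue_seq per planted bond
    gln_distances: list[np.ndarray]
    complexes: list[Complex] | None = None
    energies: np.ndarray | None = None

    @property
    def n_poses(self) -> int:
        return len(self.water_distances)


@dataclass
class ClassDataset:
    model: ClassGeometryModel
    ligands: list[LigandSample]
    truth: dict[str, ClassTruth]

    def pooled_water_distances(self, class_label: str) -> np.ndarray:
        vals = [
            d for lig in self.ligands if lig.class_label == class_label
            for pose in lig.water_distances for d in pose
        ]
        return np.array(vals)

    def pooled_gln_distances(self, class_label: str) -> np.ndarray:
        vals = [
            d for lig in self.ligands if lig.class_label == class_label
            for pose in lig.gln_distances for d in pose
        ]
        return np.array(vals)

    def water_bonds_per_pose(self, class_label: str) -> float:
        ligs = [l for l in self.ligands if l.class_label == class_label]
        total = sum(len(pose) for l in ligs for pose in l.water_distances)
        n_poses = sum(l.n_poses for l in ligs)
        return total / n_poses

    def gln_bonds_per_pose(self, class_label: str) -> float:
        ligs = [l for l in self.ligands if l.class_label == class_label]
        total = sum(len(pose) for l in ligs for pose in l.gln_distances)
        n_poses = sum(l.n_poses for l in ligs)
        return total / n_poses


_WATER_CAP = 8
_GLN_CAP = 2


def _truncated_poisson_probs(rate: float, cap: int) -> np.ndarray:
    if rate == 0:
        probs = np.zeros(cap + 1)
        probs[0] = 1.0
        return probs
    probs = stats.poisson.pmf(np.arange(cap + 1), rate)
    return probs / probs.sum()


def _truncated_poisson_mean(rate: float, cap: int) -> float:
    probs = _truncated_poisson_probs(rate, cap)
    return float(np.dot(np.arange(cap + 1), probs))


def _truncnorm(mean: float, sd: float):
    a, b = (_MIN_D - mean) / sd, (_MAX_D - mean) / sd
    if a >= b:
        raise ValueError("infeasible truncation window")
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def class_truth(model: ClassGeometryModel, class_label: str) -> ClassTruth:
    p = model.params(class_label)
    water_cap = min(_WATER_CAP, model.n_waters)
    return ClassTruth(
        water_distance_mean=float(_truncnorm(p["water_mean"], p["water_sd"]).mean()),
        water_bonds_per_pose=_truncated_poisson_mean(p["water_rate"], water_cap),
        gln_distance_mean=float(_truncnorm(p["gln_mean"], p["gln_sd"]).mean()),
        gln_bonds_per_pose=_truncated_poisson_mean(p["gln_rate"], _GLN_CAP),
    )


def _gln_pair_geometry(d_draws: np.ndarray) -> float | None:
    """Distance L from acceptor to the shared amide nitrogen such that every
    requested H...A distance yields a D-H...A angle inside the criterion.
    Returns None when no such L exists."""
    lo = float(np.max(_OH ** 2 + d_draws ** 2 - 2 * _OH * d_draws * _COS_HI))
    hi = float(np.min(_OH ** 2 + d_draws ** 2 - 2 * _OH * d_draws * _COS_LO))
    if lo >= hi:
        return None
    return math.sqrt((lo + hi) / 2.0)


def _place_water_bond(
    coords: np.ndarray, acceptor: np.ndarray, direction: np.ndarray,
    distance: float, angle_deg: float, o_idx: int, h1_idx: int, h2_idx: int,
) -> None:
    """Move one water rigidly so its first hydrogen donates to ``acceptor``
    at exactly (distance, angle)."""
    u = _unit(direction)
    h1 = acceptor + distance * u
    theta = math.radians(angle_deg)
    p = _perpendicular(u)
    # angle at H between H->O(w) and H->A: H->A = -u; need v . (-u) = cos(theta)
    v = -math.cos(theta) * u + math.sin(theta) * p
    o = h1 + _OH * v
    h2 = o + _OH * _unit(o - acceptor)  # points directly away: angle ~0, never detected
    coords[o_idx] = o
    coords[h1_idx] = h1
    coords[h2_idx] = h2


def _place_gln_bonds(
    coords: np.ndarray, acceptor: np.ndarray, direction: np.ndarray,
    d_draws: np.ndarray, ne2_idx: int, h_idxs: list[int],
) -> None:
    """Move the amide nitrogen and its hydrogens so each hydrogen donates to
    ``acceptor`` at exactly the requested distances (angles fall inside the
    criterion by construction of L)."""
    L = _gln_pair_geometry(d_draws)
    if L is None:
        raise PlacementError("no feasible amide placement for the drawn distances")
    u = _unit(direction)
    ne2 = acceptor + L * u
    p = _perpendicular(u)
    q = np.cross(u, p)
    coords[ne2_idx] = ne2
    azimuths = (0.0, math.pi) if len(d_draws) > 1 else (0.0,)
    for d, h_idx, phi in zip(d_draws, h_idxs, azimuths):
        # H lies on the intersection circle of spheres around A (radius d)
        # and NE2 (radius _OH)
        cos_alpha = (L * L + d * d - _OH * _OH) / (2 * L * d)
        cos_alpha = min(1.0, max(-1.0, cos_alpha))
        sin_alpha = math.sqrt(max(0.0, 1.0 - cos_alpha ** 2))
        h = acceptor + d * (
            cos_alpha * u + sin_alpha * (math.cos(phi) * p + math.sin(phi) * q)
        )
        coords[h_idx] = h
    # park unused amide hydrogens away from the acceptor
    for h_idx in h_idxs[len(d_draws):]:
        coords[h_idx] = ne2 + _OH * u


def simulate_class_dataset(
    model: ClassGeometryModel,
    n_ligands_per_class: int = 8,
    materialize: bool = False,
    count_law: str = "poisson",
) -> ClassDataset:
    """Two-class synthetic dataset of per-ligand pose sets.

    Per pose, water-partner and glutamine-partner bond counts are drawn
    from a Poisson law truncated to geometric feasibility (or fixed at the
    rounded rate with ``count_law='fixed'``), and distances from a normal
    truncated to the detectable window. With ``materialize=True`` every
    pose is built as a full :class:`Complex` with the drawn bonds planted
    exactly, ready for the detection pipeline.
    """
    if count_law not in ("poisson", "fixed"):
        raise ValueError("count_law must be 'poisson' or 'fixed'")
    rng = np.random.default_rng(model.seed)
    water_cap = min(_WATER_CAP, model.n_waters)
    truth = {c: class_truth(model, c) for c in ("A", "I")}
    ligands: list[LigandSample] = []

    for class_label in ("A", "I"):
        p = model.params(class_label)
        water_probs = _truncated_poisson_probs(p["water_rate"], water_cap)
        gln_probs = _truncated_poisson_probs(p["gln_rate"], _GLN_CAP)
        water_law = _truncnorm(p["water_mean"], p["water_sd"])
        gln_law = _truncnorm(p["gln_mean"], p["gln_sd"])
        for li in range(n_ligands_per_class):
            ligand_id = f"{class_label}{li + 1}"
            base = build_toy_pocket(
                seed=int(rng.integers(0, 2 ** 31)), n_waters=model.n_waters
            ) if materialize else None
            sample = _simulate_ligand(
                ligand_id, class_label, model, rng,
                water_probs, gln_probs, water_law, gln_law,
                base, count_law, p,
            )
            ligands.append(sample)
    return ClassDataset(model=model, ligands=ligands, truth=truth)


def _simulate_ligand(
    ligand_id, class_label, model, rng,
    water_probs, gln_probs, water_law, gln_law, base, count_law, p,
) -> LigandSample:
    water_cap = min(_WATER_CAP, model.n_waters)
    if base is not None:
        oac_idx = _resolve_atom(base, ("LIG", 900, "OAC"))
        ne2_idx = _resolve_atom(base, ("GLN", 443, "NE2"))
        he_idxs = [_resolve_atom(base, ("GLN", 443, nm)) for nm in ("HE21", "HE22")]
        water_atom_idx = {}
        for i, a in enumerate(base.atoms):
            if a.role == "water":
                water_atom_idx.setdefault(a.residue_seq, {})[a.name] = i
        lig_centroid = np.mean(
            [a.coords for a in base.atoms if a.role == "ligand" and not a.is_hydrogen],
            axis=0,
        )
        oac = base.atoms[oac_idx].coords
        outward = _unit(oac - lig_centroid)
        dirs = _cone_directions(outward)
    # preferred water order: the focus waters 1 and 13 first
    preferred = [1, min(13, model.n_waters)] + [
        k for k in range(1, model.n_waters + 1) if k not in (1, min(13, model.n_waters))
    ]

    n_poses = model.poses_per_ligand
    if count_law == "fixed":
        n_w_arr = np.full(n_poses, min(int(round(p["water_rate"])), water_cap))
        n_g_arr = np.full(n_poses, min(int(round(p["gln_rate"])), _GLN_CAP))
    else:
        n_w_arr = rng.choice(len(water_probs), size=n_poses, p=water_probs)
        n_g_arr = rng.choice(len(gln_probs), size=n_poses, p=gln_probs)
    # bulk distance draws (one rvs call per law), then split per pose
    d_w_flat = water_law.rvs(size=int(n_w_arr.sum()), random_state=rng)
    d_g_flat = gln_law.rvs(size=int(n_g_arr.sum()), random_state=rng)
    d_w_split = np.split(d_w_flat, np.cumsum(n_w_arr)[:-1])
    d_g_split = np.split(d_g_flat, np.cumsum(n_g_arr)[:-1])

    water_distances, water_partners, gln_distances, complexes = [], [], [], []
    for pose_i in range(n_poses):
        n_w = int(n_w_arr[pose_i])
        n_g = int(n_g_arr[pose_i])
        d_w = np.sort(d_w_split[pose_i]) if n_w else np.empty(0)
        d_g = d_g_split[pose_i]
        # shared amide nitrogen: redraw jointly until both angles fit
        while n_g and _gln_pair_geometry(d_g) is None:
            d_g = gln_law.rvs(size=n_g, random_state=rng)
        partners = preferred[:n_w]
        water_distances.append(d_w)
        water_partners.append(partners)
        gln_distances.append(d_g)

        if base is not None:
            coords = base.coords.copy()
            angles = rng.uniform(128.0, 162.0, size=n_w)
            for k in range(n_w):
                wi = water_atom_idx[partners[k]]
                _place_water_bond(
                    coords, oac, dirs[1 + k], float(d_w[k]), float(angles[k]),
                    wi["OW"], wi["HW1"], wi["HW2"],
                )
            if n_g:
                _place_gln_bonds(coords, oac, dirs[0], d_g, ne2_idx, he_idxs)
            complexes.append(base.with_coords(coords))

    energies = rng.uniform(-30.0, -20.0, size=model.poses_per_ligand)
    return LigandSample(
        ligand_id=ligand_id,
        class_label=class_label,
        water_distances=water_distances,
        water_partners=water_partners,
        gln_distances=gln_distances,
        complexes=complexes if base is not None else None,
        energies=energies,
    )
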