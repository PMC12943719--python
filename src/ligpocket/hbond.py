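"""Geometric hydrogen-bond survey between ligand and pocket.

A hydrogen bond is collected when the hydrogen-to-acceptor distance is
strictly below the cutoff (default 3.5 A) and the donor-hydrogen-acceptor
angle (vertex at the hydrogen) lies inclusively between the configured
bounds (default 120-170 degrees). Both directions are surveyed:
ligand-donates and ligand-accepts. Only ligand <-> (protein | water)
pairs are considered unless ligand-internal bonds are explicitly enabled.
"""

from __future__ import annotations

import fnmatch
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, SelectorError
from .structio import Atom, Complex, identify_donors_acceptors

logger = logging.getLogger(__name__)

#: Backbone atom names excluded when a focus partner is restricted to the
#: side chain.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "H", "HA", "OXT"})


@dataclass(frozen=True)
class HBondCriteria:
    """Detection thresholds: strict ``<`` on distance, inclusive angles."""

    max_h_acceptor_distance: float = 3.5
    angle_min: float = 120.0
    angle_max: float = 170.0

    def __post_init__(self):
        if self.max_h_acceptor_distance <= 0:
            raise ValueError("max_h_acceptor_distance must be positive")
        if not (0 <= self.angle_min <= self.angle_max <= 180):
            raise ValueError("angle bounds must satisfy 0 <= min <= max <= 180")

    def accepts(self, distance: float, angle: float) -> bool:
        return (
            distance < self.max_h_acceptor_distance
            and self.angle_min <= angle <= self.angle_max
        )


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond with its geometry."""

    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    h_a_distance: float
    dha_angle: float
    partner: str      # amino_acid | water | ligand-internal
    direction: str    # ligand-donates | ligand-accepts

    def partner_label(self) -> str:
        """Human-readable partner identity, e.g. ``GLN443`` or ``SOL1``."""
        side = self.acceptor if self.direction == "ligand-donates" else self.donor
        return f"{side.residue_name}{side.residue_seq}"


@dataclass
class LigandInteractionSummary:
    """Per-ligand aggregate of a pose-level hydrogen-bond survey."""

    ligand_id: str
    n_poses: int
    bonds_per_pose: float
    mean_h_a_distance: float | None
    mode: str  # vacuum | with_water
    focus_bonds_per_pose: float = 0.0
    focus_mean_distance: float | None = None
    focus_partner_breakdown: Counter = field(default_factory=Counter)


@dataclass
class FocusSpec:
    """Selectors for a focused ligand-atom interaction analysis.

    Defaults target the acetyl carbonyl oxygen of the ligand against the
    Gln443 side-chain amide and waters 1 and 13.
    """

    ligand_atom_selector: str = "OAC"
    residue_partners: list[tuple[str, int]] = field(
        default_factory=lambda: [("GLN", 443)]
    )
    water_partners: list[int] = field(default_factory=lambda: [1, 13])
    side_chain_only: bool = True


def compute_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Angle (degrees, in [0, 180]) at ``h`` between vectors h->d and h->a."""
    d = np.asarray(d, dtype=float)
    h = np.asarray(h, dtype=float)
    a = np.asarray(a, dtype=float)
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("coincident points: angle undefined")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _classify_partner(atom: Atom) -> str:
    return "water" if atom.role == "water" else "amino_acid"


def detect_hbonds(
    cplx: Complex,
    criteria: HBondCriteria | None = None,
    include_water: bool = True,
    include_ligand_internal: bool = False,
) -> list[HBond]:
    """Survey ligand <-> pocket hydrogen bonds under the geometric criterion.

    ``include_water=False`` is the vacuum mode: bonds whose partner atom
    is a water are dropped. Output ordering is deterministic: sorted by
    (donor serial, acceptor serial).
    """
    criteria = criteria or HBondCriteria()
    donors, acceptors = identify_donors_acceptors(cplx)

    no_h_candidates = [
        a for i, a in enumerate(cplx.atoms)
        if a.element in ("N", "O") and not a.is_hydrogen and a.role != "ion"
        and i not in {d for d, _ in donors}
    ]
    if no_h_candidates:
        logger.debug(
            "%d N/O atoms carry no hydrogen and are skipped as donors", len(no_h_candidates)
        )

    bonds: list[HBond] = []
    for heavy_idx, h_idx in donors:
        donor_atom = cplx.atoms[heavy_idx]
        h_atom = cplx.atoms[h_idx]
        for acc_idx in acceptors:
            acc_atom = cplx.atoms[acc_idx]
            if acc_idx == heavy_idx:
                continue
            lig_d = donor_atom.role == "ligand"
            lig_a = acc_atom.role == "ligand"
            if lig_d and lig_a:
                if not include_ligand_internal:
                    continue
                partner = "ligand-internal"
                direction = "ligand-donates"
            elif lig_d != lig_a:
                partner_atom = acc_atom if lig_d else donor_atom
                if partner_atom.role == "ion":
                    continue
                partner = _classify_partner(partner_atom)
                direction = "ligand-donates" if lig_d else "ligand-accepts"
            else:
                continue  # pocket-pocket pair: out of scope
            if partner == "water" and not include_water:
                continue
            dist = float(np.linalg.norm(h_atom.coords - acc_atom.coords))
            if dist >= criteria.max_h_acceptor_distance:
                continue
            angle = compute_angle(donor_atom.coords, h_atom.coords, acc_atom.coords)
            if criteria.angle_min <= angle <= criteria.angle_max:
                bonds.append(
                    HBond(
                        donor=donor_atom, hydrogen=h_atom, acceptor=acc_atom,
                        h_a_distance=dist, dha_angle=angle,
                        partner=partner, direction=direction,
                    )
                )
    bonds.sort(key=lambda b: (b.donor.serial, b.acceptor.serial))
    return bonds


def _resolve_focus(
    cplx: Complex, spec: FocusSpec, lenient: bool = False
) -> tuple[set[int], set[int], set[int]]:
    """Resolve the focus selectors to serial-number sets.

    Returns (ligand atom serials, residue partner serials, water partner
    serials). With ``lenient`` set, unresolvable partner selectors are
    skipped (useful for complexes stripped of waters); the ligand selector
    must always resolve.
    """
    lig_serials = {
        a.serial for a in cplx.atoms
        if a.role == "ligand" and fnmatch.fnmatch(a.name, spec.ligand_atom_selector)
    }
    if not lig_serials:
        raise SelectorError(
            f"ligand atom selector {spec.ligand_atom_selector!r} matched no atoms"
        )
    res_serials: set[int] = set()
    for resname, resseq in spec.residue_partners:
        matched = {
            a.serial for a in cplx.atoms
            if a.residue_name == resname and a.residue_seq == resseq
            and (not spec.side_chain_only or a.name not in BACKBONE_ATOM_NAMES)
        }
        if not matched and not lenient:
            raise SelectorError(f"residue partner {resname}{resseq} matched no atoms")
        res_serials |= matched
    wat_serials: set[int] = set()
    for resseq in spec.water_partners:
        matched = {
            a.serial for a in cplx.atoms
            if a.role == "water" and a.residue_seq == resseq
        }
        if not matched and not lenient:
            raise SelectorError(f"water partner with residue_seq {resseq} matched no atoms")
        wat_serials |= matched
    return lig_serials, res_serials, wat_serials


def focus_interactions(
    cplx: Complex,
    criteria: HBondCriteria | None = None,
    spec: FocusSpec | None = None,
    lenient: bool = False,
) -> list[HBond]:
    """Hydrogen bonds restricted to (selected ligand atom) x (named partners).

    Exactly ``detect_hbonds`` filtered to the selector sets; always a
    subset of the full detection result.
    """
    spec = spec or FocusSpec()
    lig_serials, res_serials, wat_serials = _resolve_focus(cplx, spec, lenient)
    partner_serials = res_serials | wat_serials
    out = []
    for bond in detect_hbonds(cplx, criteria, include_water=True):
        lig_side = bond.donor if bond.direction == "ligand-donates" else bond.acceptor
        pocket_side = bond.acceptor if bond.direction == "ligand-donates" else bond.donor
        pocket_h = bond.hydrogen
        if lig_side.serial not in lig_serials and bond.hydrogen.serial not in lig_serials:
            continue
        if pocket_side.serial in partner_serials or pocket_h.serial in partner_serials:
            out.append(bond)
    return out


def summarize_ligand(
    per_pose_bonds: list[list[HBond]],
    ligand_id: str = "",
    mode: str = "with_water",
    focus_per_pose: list[list[HBond]] | None = None,
) -> LigandInteractionSummary:
    """Aggregate pose-level bond lists into the two per-ligand parameters:
    bonds per pose and mean H...A distance (plus the focus equivalents)."""
    n_poses = len(per_pose_bonds)
    if n_poses == 0:
        raise ValueError("summarize_ligand requires at least one pose")
    all_bonds = [b for pose in per_pose_bonds for b in pose]
    bonds_per_pose = len(all_bonds) / n_poses
    mean_dist = (
        float(np.mean([b.h_a_distance for b in all_bonds])) if all_bonds else None
    )
    summary = LigandInteractionSummary(
        ligand_id=ligand_id,
        n_poses=n_poses,
        bonds_per_pose=bonds_per_pose,
        mean_h_a_distance=mean_dist,
        mode=mode,
    )
    if focus_per_pose is not None:
        if len(focus_per_pose) != n_poses:
            raise ValueError("focus results must cover the same poses")
        focus_bonds = [b for pose in focus_per_pose for b in pose]
        summary.focus_bonds_per_pose = len(focus_bonds) / n_poses
        summary.focus_mean_distance = (
            float(np.mean([b.h_a_distance for b in focus_bonds])) if focus_bonds else None
        )
        summary.focus_partner_breakdown = Counter(
            b.partner_label() for b in focus_bonds
        )
    return summary
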