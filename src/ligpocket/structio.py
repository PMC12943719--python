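"""Fixed-column PDB structure I/O and atom typing.

Reads single complexes and multi-model pose ensembles, partitions atoms
into ligand / protein / water / ion roles, infers covalent connectivity
by interatomic distance, and assigns hydrogen-bond donor/acceptor types.

Conventions:

* water residue names: ``HOH``, ``SOL``, ``WAT`` (any record type);
* ion: a single-atom residue whose element is one of Zn, Mg, Na, Cl, K, Ca;
* ligand: any other HETATM residue; protein: any other ATOM residue;
* occupancy/B-factor are ignored on read and written as ``1.00``/``0.00``;
* residue numbering is preserved verbatim (1-based, as in the file).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    AtomTypingError,
    EnergyTableError,
    PDBParseError,
    TopologyError,
)

logger = logging.getLogger(__name__)

WATER_RESIDUE_NAMES = frozenset({"HOH", "SOL", "WAT"})
ION_ELEMENTS = frozenset({"ZN", "MG", "NA", "CL", "K", "CA"})

#: Covalent radii (Angstrom) for the elements this pipeline encounters.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
    "ZN": 1.22, "MG": 1.41, "NA": 1.66, "K": 2.03, "CA": 1.76,
}

_H_MAX_DIST = 1.2       # H--heavy covalent threshold
_H_MAX_DIST_S = 1.5     # relaxed threshold when the heavy atom is sulfur
_HEAVY_SLACK = 0.4      # added to the covalent-radius sum for heavy pairs

ROLES = ("ligand", "protein", "water", "ion")


@dataclass(frozen=True)
class Atom:
    """One atom of a complex, in file order."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain: str
    coords: np.ndarray  # shape (3,), Angstrom
    role: str
    record: str = "ATOM"

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")
        if self.role not in ROLES:
            raise ValueError(f"atom {self.serial}: unknown role {self.role!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Complex:
    """An ordered collection of atoms with inferred covalent connectivity."""

    atoms: list[Atom]
    covalent_map: list[tuple[int, int]] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def indices_by_role(self, role: str) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.role == role]

    def bonded_to(self, index: int) -> list[int]:
        out = []
        for i, j in self.covalent_map:
            if i == index:
                out.append(j)
            elif j == index:
                out.append(i)
        return out

    def with_coords(self, coords: np.ndarray) -> "Complex":
        """Copy of this complex with every atom repositioned (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise TopologyError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Complex(atoms=atoms, covalent_map=list(self.covalent_map), label=self.label)

    def water_ids(self) -> list[tuple[str, int]]:
        """Distinct water identities as (residue_name, residue_seq)."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            if a.role == "water":
                seen.setdefault((a.residue_name, a.residue_seq), None)
        return list(seen)


@dataclass
class PoseEnsemble:
    """Docking poses of one ligand sharing a single topology.

    ``topology`` holds the ligand atoms only; ``poses`` are the per-model
    ligand coordinate sets; energies are kcal/mol, lower is better.
    """

    topology: Complex
    poses: list[np.ndarray]
    energies: np.ndarray

    def __post_init__(self):
        n_at = len(self.topology.atoms)
        for k, p in enumerate(self.poses):
            p = np.asarray(p, dtype=float)
            if p.shape != (n_at, 3):
                raise TopologyError(
                    f"pose {k}: expected {n_at} atoms, got shape {p.shape}"
                )
            self.poses[k] = p
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.energies) != len(self.poses):
            raise EnergyTableError(
                f"{len(self.energies)} energies for {len(self.poses)} poses"
            )

    @property
    def n_poses(self) -> int:
        return len(self.poses)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _guess_element(name: str, residue_name: str) -> str:
    """Element from the atom-name column when columns 77-78 are blank."""
    stripped = name.strip()
    if residue_name.strip().upper() in ION_ELEMENTS or stripped.upper() in ION_ELEMENTS:
        return stripped.upper()
    # PDB convention: element occupies column 13 unless the name starts in 14.
    if name[:1].strip() and name[:2].strip().upper() in COVALENT_RADII and len(stripped) > 1:
        two = name[:2].strip().upper()
        if two in {"CL", "BR", "ZN", "MG", "NA"}:
            return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _parse_atom_record(line: str, lineno: int) -> dict:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: record too short for coordinates: {line!r}")
    try:
        serial = int(line[6:11])
        name = line[12:16]
        residue_name = line[17:20].strip()
        chain = line[21].strip() or " "
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed-width field: {exc}") from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        try:
            element = _guess_element(name, residue_name)
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: {exc}") from exc
    return {
        "serial": serial,
        "name": name.strip(),
        "element": element,
        "residue_name": residue_name,
        "residue_seq": residue_seq,
        "chain": chain,
        "coords": np.array([x, y, z]),
        "record": line[:6].strip(),
    }


def _assign_roles(raw_atoms: list[dict]) -> list[str]:
    # group by residue identity to find single-atom ion residues
    groups: dict[tuple, list[int]] = {}
    for i, a in enumerate(raw_atoms):
        groups.setdefault((a["chain"], a["residue_seq"], a["residue_name"]), []).append(i)
    roles = [""] * len(raw_atoms)
    for key, members in groups.items():
        _, _, resname = key
        if resname.upper() in WATER_RESIDUE_NAMES:
            role = "water"
        elif len(members) == 1 and raw_atoms[members[0]]["element"] in ION_ELEMENTS:
            role = "ion"
        elif raw_atoms[members[0]]["record"] == "HETATM":
            role = "ligand"
        else:
            role = "protein"
        for i in members:
            roles[i] = role
    return roles


def _build_covalent_map(atoms: list[Atom]) -> list[tuple[int, int]]:
    """Distance-rule connectivity.

    Each hydrogen is bonded to its nearest heavy atom if within 1.2 A
    (1.5 A for sulfur); heavy pairs bond when closer than the sum of
    covalent radii plus 0.4 A. Ions form no covalent bonds.
    """
    n = len(atoms)
    if n == 0:
        return []
    coords = np.array([a.coords for a in atoms])
    heavy = [i for i in range(n) if not atoms[i].is_hydrogen and atoms[i].role != "ion"]
    hydrogens = [i for i in range(n) if atoms[i].is_hydrogen]
    pairs: list[tuple[int, int]] = []

    if heavy:
        htree = cKDTree(coords[heavy])
        for hi in hydrogens:
            dists, idxs = htree.query(coords[hi], k=min(4, len(heavy)))
            dists = np.atleast_1d(dists)
            idxs = np.atleast_1d(idxs)
            best = None
            for d, j in zip(dists, idxs):
                heavy_idx = heavy[int(j)]
                cutoff = _H_MAX_DIST_S if atoms[heavy_idx].element == "S" else _H_MAX_DIST
                if d <= cutoff:
                    best = heavy_idx
                    break
            if best is None:
                raise AtomTypingError(
                    f"hydrogen {atoms[hi].name!r} (serial {atoms[hi].serial}, "
                    f"{atoms[hi].residue_name} {atoms[hi].residue_seq}) has no heavy "
                    f"atom within {_H_MAX_DIST} A"
                )
            pairs.append((min(hi, best), max(hi, best)))

        # heavy-heavy bonds
        max_rad = max(COVALENT_RADII.get(atoms[i].element, 0.77) for i in heavy)
        tree = cKDTree(coords[heavy])
        for ii, jj in tree.query_pairs(r=2 * max_rad + _HEAVY_SLACK):
            i, j = heavy[ii], heavy[jj]
            ri = COVALENT_RADII.get(atoms[i].element, 0.77)
            rj = COVALENT_RADII.get(atoms[j].element, 0.77)
            if np.linalg.norm(coords[i] - coords[j]) <= ri + rj + _HEAVY_SLACK:
                pairs.append((min(i, j), max(i, j)))
    elif hydrogens:
        raise AtomTypingError("structure contains hydrogens but no heavy atoms")

    return sorted(set(pairs))


def read_structure(pdb_text: str, label: str = "") -> Complex:
    """Parse a single-model fixed-column PDB text into a :class:`Complex`."""
    raw: list[dict] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            raw.append(_parse_atom_record(line, lineno))
    if not raw:
        raise PDBParseError("no ATOM/HETATM records found")
    roles = _assign_roles(raw)
    atoms = [
        Atom(
            serial=a["serial"], name=a["name"], element=a["element"],
            residue_name=a["residue_name"], residue_seq=a["residue_seq"],
            chain=a["chain"], coords=a["coords"], role=role, record=a["record"],
        )
        for a, role in zip(raw, roles)
    ]
    return Complex(atoms=atoms, covalent_map=_build_covalent_map(atoms), label=label)


def _split_models(pdb_text: str) -> list[tuple[int, str]]:
    """Return (model_number, block_text) pairs; a file without MODEL records
    is a single model numbered 1."""
    models: list[tuple[int, str]] = []
    current: list[str] | None = None
    current_no = None
    saw_model = False
    for line in pdb_text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            try:
                current_no = int(line.split()[1])
            except (IndexError, ValueError):
                current_no = len(models) + 1
            current = []
        elif rec == "ENDMDL":
            if current is not None:
                models.append((current_no, "\n".join(current)))
            current = None
        elif current is not None:
            current.append(line)
    if not saw_model:
        return [(1, pdb_text)]
    return models


def read_models(pdb_text: str, label: str = "") -> list[tuple[int, Complex]]:
    """Parse every MODEL block as a full :class:`Complex`."""
    out = []
    for model_no, block in _split_models(pdb_text):
        out.append((model_no, read_structure(block, label=label)))
    if not out:
        raise PDBParseError("no models found")
    return out


def read_energy_table(tsv_text: str) -> dict[int, float]:
    """Parse the sidecar energies table (``model<TAB>energy_kcal_mol``)."""
    lines = [ln for ln in tsv_text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise EnergyTableError("energy table is empty")
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] != ["model", "energy_kcal_mol"]:
        raise EnergyTableError(
            f"expected header 'model\\tenergy_kcal_mol', got {lines[0]!r}"
        )
    table: dict[int, float] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        try:
            table[int(parts[0])] = float(parts[1])
        except (IndexError, ValueError) as exc:
            raise EnergyTableError(f"energy table line {lineno}: {exc}") from exc
    return table


def read_ensemble(pdb_text: str, energies: str | dict[int, float],
                  label: str = "") -> PoseEnsemble:
    """Read a multi-model PDB plus per-model energies into a pose ensemble.

    The returned topology holds the ligand atoms of the first model; each
    pose is that ligand's coordinates in the corresponding model. Models
    must agree in atom count and atom naming.
    """
    if isinstance(energies, str):
        energies = read_energy_table(energies)
    models = read_models(pdb_text, label=label)
    first = models[0][1]
    lig_idx = first.indices_by_role("ligand")
    if not lig_idx:
        raise TopologyError("ensemble contains no ligand atoms")
    ref_names = [first.atoms[i].name for i in lig_idx]
    topology = Complex(
        atoms=[first.atoms[i] for i in lig_idx],
        covalent_map=_subset_covalent_map(first.covalent_map, lig_idx),
        label=label or first.label,
    )
    poses, evals = [], []
    for model_no, cplx in models:
        idx = cplx.indices_by_role("ligand")
        names = [cplx.atoms[i].name for i in idx]
        if names != ref_names:
            raise TopologyError(
                f"model {model_no}: ligand atom set differs from model "
                f"{models[0][0]} ({len(names)} vs {len(ref_names)} atoms)"
            )
        if len(cplx.atoms) != len(first.atoms):
            raise TopologyError(
                f"model {model_no}: atom count {len(cplx.atoms)} differs from "
                f"first model ({len(first.atoms)})"
            )
        if model_no not in energies:
            raise EnergyTableError(f"no energy row for model {model_no}")
        poses.append(np.array([cplx.atoms[i].coords for i in idx]))
        evals.append(energies[model_no])
    return PoseEnsemble(topology=topology, poses=poses, energies=np.array(evals))


def _subset_covalent_map(cmap: list[tuple[int, int]], indices: list[int]):
    remap = {old: new for new, old in enumerate(indices)}
    return sorted(
        (remap[i], remap[j]) for i, j in cmap if i in remap and j in remap
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"[:4]


def _atom_line(atom: Atom) -> str:
    record = "HETATM" if atom.role in ("ligand", "water", "ion") or atom.record == "HETATM" else "ATOM"
    x, y, z = atom.coords
    return (
        f"{record:<6}{atom.serial:>5} {_format_atom_name(atom.name, atom.element)}"
        f" {atom.residue_name:<3} {atom.chain:1}{atom.residue_seq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{atom.element:>2}"
    )


def write_structure(cplx: Complex) -> str:
    """Serialize a complex as fixed-width PDB (3-decimal coordinates)."""
    buf = io.StringIO()
    for atom in cplx.atoms:
        buf.write(_atom_line(atom) + "\n")
    buf.write("END\n")
    return buf.getvalue()


def write_ensemble_models(complexes: list[Complex]) -> str:
    """Serialize a sequence of same-topology complexes as MODEL/ENDMDL blocks."""
    buf = io.StringIO()
    for k, cplx in enumerate(complexes, start=1):
        buf.write(f"MODEL     {k:>4}\n")
        for atom in cplx.atoms:
            buf.write(_atom_line(atom) + "\n")
        buf.write("ENDMDL\n")
    buf.write("END\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Donor/acceptor typing
# ---------------------------------------------------------------------------

def identify_donors_acceptors(
    cplx: Complex, include_sulfur_acceptors: bool = False
) -> tuple[list[tuple[int, int]], list[int]]:
    """Hydrogen-bond donor pairs and acceptor atoms.

    Donors: every N/O/S heavy atom paired with each covalently bound
    hydrogen. Acceptors: every N/O atom (S optionally). Carbons are never
    donors or acceptors.
    """
    donor_elements = {"N", "O", "S"}
    acceptor_elements = {"N", "O"} | ({"S"} if include_sulfur_acceptors else set())
    attached_h: dict[int, list[int]] = {}
    for i, j in cplx.covalent_map:
        ai, aj = cplx.atoms[i], cplx.atoms[j]
        if ai.is_hydrogen and not aj.is_hydrogen:
            attached_h.setdefault(j, []).append(i)
        elif aj.is_hydrogen and not ai.is_hydrogen:
            attached_h.setdefault(i, []).append(j)
    donors = []
    for heavy_idx, hs in sorted(attached_h.items()):
        if cplx.atoms[heavy_idx].element in donor_elements:
            for h in sorted(hs):
                donors.append((heavy_idx, h))
    acceptors = [
        i for i, a in enumerate(cplx.atoms)
        if not a.is_hydrogen and a.element in acceptor_elements and a.role != "ion"
    ]
    return donors, acceptors
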