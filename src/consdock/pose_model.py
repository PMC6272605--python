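"""Domain types and I/O for docked ligand poses, screening manifests and
receptor structures.

Every docking engine's output enters the platform through this module: a
pose is a molecular graph (atoms + bonds) with 3-D coordinates in the
receptor frame, tagged with its provenance (compound, engine, receptor)
and engine-native score.  Coordinates are Ångström throughout; no unit
conversion happens anywhere in the package.

Hydrogens are parsed and retained but flagged; all RMSD computations
downstream operate on heavy atoms only.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Atom",
    "MolecularGraph",
    "Pose",
    "ReceptorState",
    "ProteinStructure",
    "ScreenManifest",
    "PoseError",
    "read_poses",
    "write_poses",
    "build_manifest",
    "select_best_pose",
    "validate_compound_consistency",
    "read_manifest_csv",
    "read_receptor_yaml",
    "read_receptor_pdb",
    "PoseStore",
]

MANIFEST_COLUMNS = [
    "compound_id",
    "engine_id",
    "receptor_id",
    "pose_path",
    "score",
    "score_direction",
]

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn",
    "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr",
    "Rb", "Sr", "Mo", "Ru", "Rh", "Pd", "Ag", "Cd", "Sn", "Sb", "Te",
    "I", "Xe", "Cs", "Ba", "W", "Pt", "Au", "Hg", "Pb", "Bi",
}


class PoseError(ValueError):
    """Raised on malformed pose input or contract violations."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol and Cartesian coordinates in Å."""

    element: str
    coords: np.ndarray

    def __post_init__(self):
        el = self.element.capitalize() if len(self.element) <= 2 else self.element
        if el not in _ELEMENTS:
            raise PoseError(f"invalid element symbol: {self.element!r}")
        object.__setattr__(self, "element", el)
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise PoseError(f"coordinates must be a finite 3-vector, got {self.coords!r}")
        object.__setattr__(self, "coords", c)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class MolecularGraph:
    """An ordered atom list plus a bond set.

    Bonds are stored as a mapping ``(i, j) -> order`` with ``i < j``;
    orders are 1, 2, 3 or 1.5 (aromatic).  Bond orders are carried for
    round-tripping but collapsed (treated as equal) wherever graph
    topology is compared, so pose identity never depends on the Kekulé
    drawing chosen by a particular engine.
    """

    atoms: list[Atom]
    bonds: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.atoms)
        norm: dict[tuple[int, int], float] = {}
        for (i, j), order in self.bonds.items():
            if i == j:
                raise PoseError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise PoseError(f"bond ({i},{j}) out of range for {n} atoms")
            a, b = (i, j) if i < j else (j, i)
            norm[(a, b)] = float(order)
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        idx = self.heavy_indices
        return np.array([self.atoms[i].coords for i in idx], dtype=float)

    def heavy_elements(self) -> list[str]:
        return [self.atoms[i].element for i in self.heavy_indices]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def heavy_graph_connected(self) -> bool:
        """True if the heavy-atom subgraph forms one connected component."""
        heavy = self.heavy_indices
        if not heavy:
            return False
        heavy_set = set(heavy)
        seen = {heavy[0]}
        stack = [heavy[0]]
        while stack:
            i = stack.pop()
            for j in self.neighbors(i):
                if j in heavy_set and j not in seen:
                    seen.add(j)
                    stack.append(j)
        return seen == heavy_set

    def translated(self, vec: np.ndarray) -> "MolecularGraph":
        vec = np.asarray(vec, dtype=float)
        return MolecularGraph(
            atoms=[Atom(a.element, a.coords + vec) for a in self.atoms],
            bonds=dict(self.bonds),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "MolecularGraph":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return MolecularGraph(
            atoms=[Atom(a.element, R @ a.coords + t) for a in self.atoms],
            bonds=dict(self.bonds),
        )


@dataclass
class Pose:
    """One docked conformation of one compound, from one engine, in one
    receptor, with the engine-native score of that pose."""

    compound_id: str
    graph: MolecularGraph
    engine_id: str = ""
    receptor_id: str = ""
    score: float = float("nan")
    score_direction: str = "lower-better"

    def __post_init__(self):
        if not self.compound_id:
            raise PoseError("compound_id must be non-empty")
        if self.score_direction not in ("lower-better", "higher-better"):
            raise PoseError(f"invalid score_direction: {self.score_direction!r}")

    @property
    def n_heavy(self) -> int:
        return len(self.graph.heavy_indices)


@dataclass(frozen=True)
class ReceptorState:
    """Receptor-conformation metadata: open/closed state and whether the
    cofactor is bound.  Four canonical states cover open/closed × ±cofactor."""

    receptor_id: str
    conformation: str = "open"
    cofactor_present: bool = True
    structure: "ProteinStructure | None" = None

    def __post_init__(self):
        if not self.receptor_id:
            raise PoseError("receptor_id must be non-empty")
        if self.conformation not in ("open", "closed"):
            raise PoseError(f"conformation must be open|closed, got {self.conformation!r}")


@dataclass
class ProteinStructure:
    """Heavy-atom protein coordinates with residue labels, for the clash
    and H-bond post-filters."""

    coords: np.ndarray          # (n, 3) Å
    elements: list[str]
    residue_labels: list[str]   # e.g. "ARG169"
    atom_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if not (len(self.elements) == len(self.residue_labels) == n):
            raise PoseError("protein arrays must have equal length")
        if not self.atom_names:
            self.atom_names = [""] * n


@dataclass
class ScreenManifest:
    """The full screening task list: every (compound, engine, receptor)
    combination, plus the pose table filled in as engines report back."""

    compounds: list[str]
    receptors: list[ReceptorState]
    engines: list[str]
    pose_table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS)
    )

    @property
    def n_tasks(self) -> int:
        return len(self.compounds) * len(self.receptors) * len(self.engines)

    def tasks(self) -> Iterable[tuple[str, str, str]]:
        """Cartesian product (compound_id, engine_id, receptor_id)."""
        rec_ids = [r.receptor_id for r in self.receptors]
        return itertools.product(self.compounds, self.engines, rec_ids)

    def validate_pose_table(self) -> None:
        comp = set(self.compounds)
        eng = set(self.engines)
        rec = {r.receptor_id for r in self.receptors}
        for _, row in self.pose_table.iterrows():
            if row["compound_id"] not in comp:
                raise PoseError(f"pose table references undeclared compound {row['compound_id']!r}")
            if row["engine_id"] not in eng:
                raise PoseError(f"pose table references undeclared engine {row['engine_id']!r}")
            if row["receptor_id"] not in rec:
                raise PoseError(f"pose table references undeclared receptor {row['receptor_id']!r}")


def build_manifest(
    compounds: Sequence[str],
    receptors: Sequence[ReceptorState | str],
    engines: Sequence[str],
) -> ScreenManifest:
    """Build the cartesian-product task list.

    Task count is |compounds| × |receptors| × |engines| — a 10,000-compound
    library over 4 receptor states and 4 engines yields 160,000 tasks.
    Duplicate ids in any list are an error.
    """
    for name, ids in (("compounds", list(compounds)),
                      ("engines", list(engines))):
        if not ids:
            raise PoseError(f"{name} list is empty")
        if len(set(ids)) != len(ids):
            raise PoseError(f"duplicate ids in {name}")
    recs = [r if isinstance(r, ReceptorState) else ReceptorState(r) for r in receptors]
    if not recs:
        raise PoseError("receptors list is empty")
    rec_ids = [r.receptor_id for r in recs]
    if len(set(rec_ids)) != len(rec_ids):
        raise PoseError("duplicate ids in receptors")
    return ScreenManifest(list(compounds), recs, list(engines))


def select_best_pose(poses: Sequence[Pose]) -> Pose:
    """Return the best-scored pose of one (compound, engine, receptor) task.

    Only the best-scored pose of each engine run is carried forward into
    the consensus analysis.  Ties break deterministically to the first
    pose in file order.
    """
    if not poses:
        raise PoseError("select_best_pose: empty input")
    keys = {(p.compound_id, p.engine_id, p.receptor_id) for p in poses}
    if len(keys) != 1:
        raise PoseError(f"select_best_pose: poses span multiple tasks: {sorted(keys)}")
    directions = {p.score_direction for p in poses}
    if len(directions) != 1:
        raise PoseError("select_best_pose: mixed score directions")
    direction = directions.pop()
    best = poses[0]
    for p in poses[1:]:
        if direction == "lower-better":
            if p.score < best.score:
                best = p
        else:
            if p.score > best.score:
                best = p
    return best


def validate_compound_consistency(poses: Sequence[Pose]) -> list[str]:
    """Warn when the same compound_id has differing heavy-atom counts
    across engines — compound identity is tracked by id string, and a
    count mismatch usually means the engines disagreed about protonation
    or the id mapping is wrong."""
    counts: dict[str, dict[str, int]] = {}
    for p in poses:
        counts.setdefault(p.compound_id, {})[p.engine_id] = p.n_heavy
    msgs = []
    for cid, by_engine in counts.items():
        if len(set(by_engine.values())) > 1:
            msg = f"compound {cid!r}: heavy-atom count differs across engines {by_engine}"
            msgs.append(msg)
            warnings.warn(msg)
    return msgs


# ---------------------------------------------------------------------------
# File I/O

_BOND_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}
_BOND_TO_RDKIT = {v: k for k, v in _BOND_FROM_RDKIT.items()}


def _graph_from_rdkit(mol: Chem.Mol) -> MolecularGraph:
    if mol.GetNumConformers() == 0:
        raise PoseError("record has no coordinates")
    conf = mol.GetConformer()
    atoms = []
    for i, at in enumerate(mol.GetAtoms()):
        p = conf.GetAtomPosition(i)
        atoms.append(Atom(at.GetSymbol(), np.array([p.x, p.y, p.z])))
    bonds = {}
    for b in mol.GetBonds():
        order = _BOND_FROM_RDKIT.get(b.GetBondType(), 1.0)
        bonds[(b.GetBeginAtomIdx(), b.GetEndAtomIdx())] = order
    return MolecularGraph(atoms, bonds)


def _rdkit_from_pose(pose: Pose) -> Chem.Mol:
    em = Chem.RWMol()
    for a in pose.graph.atoms:
        at = Chem.Atom(a.element)
        at.SetNoImplicit(True)
        em.AddAtom(at)
    for (i, j), order in pose.graph.bonds.items():
        em.AddBond(i, j, _BOND_TO_RDKIT.get(order, Chem.BondType.SINGLE))
    conf = Chem.Conformer(em.GetNumAtoms())
    for i, a in enumerate(pose.graph.atoms):
        conf.SetAtomPosition(i, a.coords.tolist())
    em.AddConformer(conf)
    mol = em.GetMol()
    mol.SetProp("_Name", pose.compound_id)
    mol.SetProp("compound_id", pose.compound_id)
    if pose.engine_id:
        mol.SetProp("engine_id", pose.engine_id)
    if pose.receptor_id:
        mol.SetProp("receptor_id", pose.receptor_id)
    if np.isfinite(pose.score):
        mol.SetProp("score", repr(float(pose.score)))
        mol.SetProp("score_direction", pose.score_direction)
    mol.UpdatePropertyCache(strict=False)
    Chem.GetSSSR(mol)
    return mol


def _pose_from_rdkit(mol: Chem.Mol, index: int, fallback_id: str) -> Pose:
    graph = _graph_from_rdkit(mol)
    cid = ""
    if mol.HasProp("compound_id"):
        cid = mol.GetProp("compound_id").strip()
    if not cid and mol.HasProp("_Name"):
        cid = mol.GetProp("_Name").strip()
    if not cid:
        cid = f"{fallback_id}_{index}"
    kwargs: dict = {}
    for prop in ("engine_id", "receptor_id"):
        if mol.HasProp(prop):
            kwargs[prop] = mol.GetProp(prop).strip()
    if mol.HasProp("score"):
        kwargs["score"] = float(mol.GetProp("score"))
    if mol.HasProp("score_direction"):
        kwargs["score_direction"] = mol.GetProp("score_direction").strip()
    return Pose(compound_id=cid, graph=graph, **kwargs)


_MOL2_BOND = {"1": 1.0, "2": 2.0, "3": 3.0, "am": 1.0, "ar": 1.5, "du": 1.0, "un": 1.0}
_MOL2_BOND_OUT = {1.0: "1", 2.0: "2", 3.0: "3", 1.5: "ar"}


def _read_mol2(path: Path) -> list[Pose]:
    # SYBYL atom types are accepted but only element + connectivity are used.
    text = path.read_text()
    poses = []
    blocks = text.split("@<TRIPOS>MOLECULE")
    for rec, block in enumerate(blocks[1:]):
        lines = block.splitlines()
        name = lines[1].strip() if len(lines) > 1 else ""
        section = None
        atoms: list[Atom] = []
        bonds: dict[tuple[int, int], float] = {}
        try:
            for line in lines:
                s = line.strip()
                if s.startswith("@<TRIPOS>"):
                    section = s[9:]
                    continue
                if not s:
                    continue
                if section == "ATOM":
                    parts = s.split()
                    x, y, z = map(float, parts[2:5])
                    element = parts[5].split(".")[0]
                    atoms.append(Atom(element, np.array([x, y, z])))
                elif section == "BOND":
                    parts = s.split()
                    i, j = int(parts[1]) - 1, int(parts[2]) - 1
                    bonds[(i, j)] = _MOL2_BOND.get(parts[3].lower(), 1.0)
        except (ValueError, IndexError, PoseError) as exc:
            raise PoseError(f"unparsable MOL2 record {rec}: {exc}") from exc
        if not atoms:
            raise PoseError(f"unparsable MOL2 record {rec}: no atoms")
        cid = name or f"{path.stem}_{rec}"
        poses.append(Pose(compound_id=cid, graph=MolecularGraph(atoms, bonds)))
    if not poses:
        raise PoseError(f"no MOL2 records in {path}")
    return poses


_SYBYL = {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3", "H": "H"}


def _write_mol2(poses: Sequence[Pose], path: Path) -> None:
    out = []
    for pose in poses:
        g = pose.graph
        out.append("@<TRIPOS>MOLECULE")
        out.append(pose.compound_id)
        out.append(f"{g.n_atoms} {len(g.bonds)} 1 0 0")
        out.append("SMALL")
        out.append("NO_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for i, a in enumerate(g.atoms, 1):
            sybyl = _SYBYL.get(a.element, a.element)
            x, y, z = a.coords
            out.append(
                f"{i:>6} {a.element}{i:<4} {x:>12.4f} {y:>12.4f} {z:>12.4f} "
                f"{sybyl:<6} 1 LIG 0.0000"
            )
        out.append("@<TRIPOS>BOND")
        for k, ((i, j), order) in enumerate(sorted(g.bonds.items()), 1):
            out.append(f"{k:>6} {i + 1:>5} {j + 1:>5} {_MOL2_BOND_OUT.get(order, '1'):>4}")
        out.append("")
    path.write_text("\n".join(out))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    ext = path.suffix.lower().lstrip(".")
    if ext in ("sdf", "sd", "mol"):
        return "sdf"
    if ext in ("mol2", "ml2"):
        return "mol2"
    if ext in ("pdb", "ent"):
        return "pdb"
    raise PoseError(f"cannot infer pose format from {path.name!r}; pass format=")


def read_poses(path: str | Path, format: str | None = None) -> list[Pose]:
    """Read ligand poses from SDF (V2000), MOL2 or PDB.

    One Pose per record, atom order preserved from the file; hydrogens
    retained (flagged via ``Atom.is_heavy``).  Provenance fields are
    populated from record properties when present; a screening manifest
    normally supplies them otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise PoseError(f"pose file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        poses = []
        for i, mol in enumerate(supplier):
            if mol is None:
                raise PoseError(f"unparsable SDF record {i} in {path}")
            poses.append(_pose_from_rdkit(mol, i, path.stem))
        if not poses:
            raise PoseError(f"no SDF records in {path}")
        return poses
    if fmt == "mol2":
        return _read_mol2(path)
    if fmt == "pdb":
        mol = Chem.MolFromPDBFile(str(path), sanitize=False, removeHs=False,
                                  proximityBonding=True)
        if mol is None:
            raise PoseError(f"unparsable PDB pose file {path}")
        return [_pose_from_rdkit(mol, 0, path.stem)]
    raise PoseError(f"unknown format {fmt!r}")


def write_poses(poses: Sequence[Pose], path: str | Path, format: str | None = None) -> None:
    """Write poses to SDF, MOL2 or PDB, preserving atom order, bonds and
    coordinates (round-trip agrees to 1e-4 Å)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        writer.SetKekulize(False)
        for pose in poses:
            writer.write(_rdkit_from_pose(pose))
        writer.close()
    elif fmt == "mol2":
        _write_mol2(poses, path)
    elif fmt == "pdb":
        with open(path, "w") as fh:
            for pose in poses:
                fh.write(Chem.MolToPDBBlock(_rdkit_from_pose(pose)))
    else:
        raise PoseError(f"unknown format {fmt!r}")


class PoseStore:
    """Normalized pose store: a directory of SDF files plus a JSON index
    mapping (compound, engine, receptor) to the file holding its pose."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.index_path = self.root / "index.json"
        self._index: dict[str, str] = {}
        if self.index_path.exists():
            self._index = json.loads(self.index_path.read_text())

    @staticmethod
    def _key(compound_id: str, engine_id: str, receptor_id: str) -> str:
        return f"{compound_id}\t{engine_id}\t{receptor_id}"

    def add(self, pose: Pose) -> None:
        self.root.mkdir(parents=True, exist_ok=True)
        fname = f"{pose.compound_id}__{pose.engine_id}__{pose.receptor_id}.sdf"
        write_poses([pose], self.root / fname, "sdf")
        self._index[self._key(pose.compound_id, pose.engine_id, pose.receptor_id)] = fname

    def flush(self) -> None:
        self.root.mkdir(parents=True, exist_ok=True)
        self.index_path.write_text(json.dumps(self._index, indent=1, sort_keys=True))

    def get(self, compound_id: str, engine_id: str, receptor_id: str) -> Pose | None:
        fname = self._index.get(self._key(compound_id, engine_id, receptor_id))
        if fname is None:
            return None
        pose = read_poses(self.root / fname, "sdf")[0]
        pose.compound_id, pose.engine_id, pose.receptor_id = (
            compound_id, engine_id, receptor_id)
        return pose

    def keys(self) -> list[tuple[str, str, str]]:
        return [tuple(k.split("\t")) for k in self._index]  # type: ignore[misc]


def read_manifest_csv(path: str | Path) -> pd.DataFrame:
    """Read a manifest pose table (compound_id,engine_id,receptor_id,
    pose_path,score,score_direction)."""
    df = pd.read_csv(path, dtype={c: str for c in MANIFEST_COLUMNS if c != "score"})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise PoseError(f"manifest missing columns: {missing}")
    df["score"] = df["score"].astype(float)
    return df


def read_receptor_yaml(path: str | Path) -> list[ReceptorState]:
    """Read receptor metadata from YAML: a list of mappings with keys
    receptor_id, conformation (open|closed), cofactor_present."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, list):
        raise PoseError("receptor YAML must be a list of receptor entries")
    out = []
    for entry in data:
        allowed = {"receptor_id", "conformation", "cofactor_present", "pdb_path"}
        unknown = set(entry) - allowed
        if unknown:
            raise PoseError(f"unknown receptor keys: {sorted(unknown)}")
        structure = None
        if entry.get("pdb_path"):
            structure = read_receptor_pdb(entry["pdb_path"])
        out.append(ReceptorState(
            receptor_id=str(entry["receptor_id"]),
            conformation=entry.get("conformation", "open"),
            cofactor_present=bool(entry.get("cofactor_present", True)),
            structure=structure,
        ))
    return out


def read_receptor_pdb(path: str | Path) -> ProteinStructure:
    """Load receptor heavy atoms + residue labels from a PDB file."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("receptor", str(path))
    coords, elements, labels, names = [], [], [], []
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                resnum = residue.id[1]
                for atom in residue:
                    el = (atom.element or atom.get_name()[0]).capitalize()
                    if el == "H":
                        continue
                    coords.append(atom.coord)
                    elements.append(el)
                    labels.append(f"{resname}{resnum}")
                    names.append(atom.get_name())
        break  # first model only
    return ProteinStructure(np.array(coords, dtype=float), elements, labels, names)
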