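"""Geometric kernels: symmetry-corrected ligand RMSD, optimal
superposition, steric-clash detection and hydrogen-bond contacts.

The central quantity is the *in-place* heavy-atom RMSD between two poses
of the same ligand sharing a receptor coordinate frame: no superposition
is applied, because displacement within the binding site is exactly the
signal that distinguishes binding dispositions.  The RMSD is minimised
over all automorphisms of the ligand's heavy-atom graph so that a
symmetric ligand (a benzene rotated by 60°, a flipped carboxylate)
compares as identical to itself regardless of atom numbering.  When two
engines emit the same compound with different atom orders, the
correspondence is likewise resolved by graph matching, never by index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .pose_model import MolecularGraph, Pose, PoseError, ProteinStructure

__all__ = [
    "AtomMapping",
    "RmsdValue",
    "RmsdMatrix",
    "HBondContact",
    "enumerate_automorphisms",
    "pose_rmsd",
    "rmsd_matrix",
    "superpose",
    "kabsch_rmsd",
    "detect_clashes",
    "detect_hbonds",
    "BONDI_RADII",
]

AtomMapping = tuple[int, ...]
"""Permutation mapping heavy-atom index ``i`` of pose A to heavy-atom
index ``mapping[i]`` of pose B; bijective, element- and bond-preserving."""

#: Bondi van-der-Waals radii (Å) for the elements that occur in drug-like
#: ligands and protein heavy atoms; 1.7 Å fallback for anything else.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Se": 1.90, "B": 1.92,
}
_DEFAULT_VDW = 1.70


@dataclass(frozen=True)
class RmsdValue:
    """An RMSD in Å plus the atom mapping that attained it."""

    value: float
    mapping_used: AtomMapping
    superposed: bool = False

    def __float__(self) -> float:
        return self.value


@dataclass
class RmsdMatrix:
    """Symmetric pairwise in-place RMSD matrix for one compound's poses
    in one receptor (zero diagonal)."""

    values: np.ndarray
    poses: list[Pose] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise PoseError("RMSD matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _heavy_nx(graph: MolecularGraph) -> nx.Graph:
    """Heavy-atom topology with element labels; bond orders collapsed so
    that aromatic/single/double count as the same edge."""
    heavy = graph.heavy_indices
    pos = {atom_idx: k for k, atom_idx in enumerate(heavy)}
    g = nx.Graph()
    for atom_idx, k in pos.items():
        g.add_node(k, element=graph.atoms[atom_idx].element)
    for (i, j) in graph.bonds:
        if i in pos and j in pos:
            g.add_edge(pos[i], pos[j])
    return g


def _element_match(a: dict, b: dict) -> bool:
    return a["element"] == b["element"]


def enumerate_automorphisms(
    graph: MolecularGraph, limit: int = 10_000
) -> list[AtomMapping]:
    """All element- and bond-preserving self-mappings of the heavy-atom
    graph, identity first, capped at ``limit``.

    If the cap is exceeded (pathologically symmetric graphs) the function
    falls back to the identity alone and emits a warning: the RMSD then
    loses symmetry correction but stays well-defined.
    """
    if not graph.heavy_graph_connected():
        raise PoseError("automorphism enumeration requires a connected heavy-atom graph")
    g = _heavy_nx(graph)
    n = g.number_of_nodes()
    matcher = nx.algorithms.isomorphism.GraphMatcher(g, g, node_match=_element_match)
    identity = tuple(range(n))
    maps: list[AtomMapping] = []
    for iso in matcher.isomorphisms_iter():
        maps.append(tuple(iso[i] for i in range(n)))
        if len(maps) > limit:
            warnings.warn(
                f"automorphism count exceeds cap {limit}; "
                "falling back to identity mapping only"
            )
            return [identity]
    maps.sort()
    maps.remove(identity)
    return [identity] + maps


def _isomorphisms(
    ga: MolecularGraph, gb: MolecularGraph, limit: int = 10_000
) -> list[AtomMapping]:
    """Element-preserving isomorphisms from A's heavy graph onto B's."""
    na, nb = _heavy_nx(ga), _heavy_nx(gb)
    matcher = nx.algorithms.isomorphism.GraphMatcher(na, nb, node_match=_element_match)
    maps: list[AtomMapping] = []
    n = na.number_of_nodes()
    for iso in matcher.isomorphisms_iter():
        maps.append(tuple(iso[i] for i in range(n)))
        if len(maps) > limit:
            warnings.warn(
                f"isomorphism count exceeds cap {limit}; using the mappings found so far"
            )
            break
    maps.sort()
    return maps


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares (Kabsch) rigid fit of ``mobile`` onto ``target``.

    Returns (rotation 3×3, translation 3-vector, residual RMSD); apply as
    ``coords @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    rmsd = rssd / np.sqrt(len(mobile))
    return R, t, float(rmsd)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over rigid motions."""
    return superpose(b, a)[2]


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pose_rmsd(
    a: Pose,
    b: Pose,
    superpose_first: bool = False,
    symmetry: bool = True,
    automorphism_limit: int = 10_000,
) -> RmsdValue:
    """Heavy-atom RMSD between two poses of the same compound.

    With ``superpose_first=False`` (the consensus-clustering distance) the
    coordinates are compared in the shared receptor frame with no fitting;
    with ``superpose_first=True`` an optimal rigid fit is applied per
    candidate mapping first (used only for trajectory-style comparisons).
    The result is the minimum over all graph isomorphisms between the two
    heavy-atom graphs (symmetry correction); ``symmetry=False`` restricts
    to the identity mapping and requires identical atom ordering.
    """
    ca, cb = a.graph.heavy_coords(), b.graph.heavy_coords()
    ea, eb = a.graph.heavy_elements(), b.graph.heavy_elements()
    if sorted(ea) != sorted(eb):
        raise PoseError(
            f"element multiset mismatch between poses of {a.compound_id!r}: "
            f"{sorted(ea)} vs {sorted(eb)}"
        )
    if not symmetry:
        if ea != eb:
            raise PoseError("symmetry=False requires identical atom ordering")
        mappings: list[AtomMapping] = [tuple(range(len(ea)))]
    else:
        mappings = _isomorphisms(a.graph, b.graph, automorphism_limit)
        if not mappings:
            raise PoseError(
                f"no graph isomorphism between poses of {a.compound_id!r}; "
                "bond topology differs"
            )
    best_val, best_map = np.inf, mappings[0]
    for m in mappings:
        cb_m = cb[list(m)]
        if superpose_first:
            val = kabsch_rmsd(ca, cb_m)
        else:
            val = _plain_rmsd(ca, cb_m)
        if val < best_val - 1e-12:
            best_val, best_map = val, m
    return RmsdValue(best_val, best_map, superposed=superpose_first)


def rmsd_matrix(poses: list[Pose], **rmsd_kwargs) -> RmsdMatrix:
    """Pairwise in-place RMSD matrix of ≥2 poses of one compound in one
    receptor: symmetric, zero diagonal."""
    n = len(poses)
    if n < 2:
        raise PoseError("rmsd_matrix requires at least 2 poses")
    compounds = {p.compound_id for p in poses}
    receptors = {p.receptor_id for p in poses}
    if len(compounds) != 1 or len(receptors) != 1:
        raise PoseError(
            f"rmsd_matrix: poses must share compound and receptor, got "
            f"{sorted(compounds)} × {sorted(receptors)}"
        )
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                v = pose_rmsd(poses[i], poses[j], **rmsd_kwargs).value
            except PoseError as exc:
                raise PoseError(f"pose pair ({i},{j}): {exc}") from exc
            m[i, j] = m[j, i] = v
    return RmsdMatrix(m, poses)


def detect_clashes(
    ligand: MolecularGraph,
    protein: ProteinStructure,
    scale: float = 0.75,
) -> list[tuple[int, int, float]]:
    """Heavy-atom steric clashes between a ligand pose and the receptor.

    A pair clashes when its distance is below ``scale`` × the sum of the
    Bondi van-der-Waals radii (0.75 is the usual soft-clash convention).
    Returns (ligand_atom_index, protein_atom_index, distance) triples;
    empty means no clash.
    """
    lig_idx = ligand.heavy_indices
    if not lig_idx or len(protein.coords) == 0:
        return []
    lig_coords = ligand.heavy_coords()
    lig_r = np.array([BONDI_RADII.get(ligand.atoms[i].element, _DEFAULT_VDW)
                      for i in lig_idx])
    prot_r = np.array([BONDI_RADII.get(e, _DEFAULT_VDW) for e in protein.elements])
    max_cut = scale * (lig_r.max() + prot_r.max())
    tree = cKDTree(protein.coords)
    clashes = []
    for k, (lc, lr) in enumerate(zip(lig_coords, lig_r)):
        for p in tree.query_ball_point(lc, max_cut):
            d = float(np.linalg.norm(lc - protein.coords[p]))
            if d < scale * (lr + prot_r[p]):
                clashes.append((lig_idx[k], p, d))
    return clashes


@dataclass(frozen=True)
class HBondContact:
    """One donor–acceptor contact between ligand and receptor."""

    ligand_atom: int
    protein_atom: int
    residue: str
    distance: float
    angle: float | None     # D–H···A angle in degrees, None if no donor H
    ligand_is_donor: bool


_RES_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "E": "GLU",
    "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _normalize_residue_filter(residues, available: set[str]) -> set[str] | None:
    """Accept residue labels as either one-letter ('R169') or
    three-letter ('ARG169') forms; reject labels absent from the
    structure so that a typo never silently disables the filter."""
    if residues is None:
        return None
    out = set()
    for label in residues:
        label = str(label).strip().upper()
        if label in available:
            out.add(label)
            continue
        expanded = None
        if label and label[0] in _RES_ONE_TO_THREE and label[1:].isdigit():
            expanded = _RES_ONE_TO_THREE[label[0]] + label[1:]
        if expanded in available:
            out.add(expanded)
        else:
            raise PoseError(f"unknown residue label in filter: {label!r}")
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    ligand: MolecularGraph,
    protein: ProteinStructure,
    residues=None,
    max_distance: float = 3.5,
    min_angle: float = 120.0,
) -> list[HBondContact]:
    """Hydrogen-bond contacts between a ligand pose and receptor residues.

    Donors/acceptors are typed from elements (N, O) and connectivity: a
    ligand N/O bearing an explicit hydrogen can donate; any N/O accepts.
    A contact requires donor–acceptor heavy-atom distance ≤ 3.5 Å and,
    when the donor hydrogen is present, a D–H···A angle ≥ 120°; protein
    donors (whose hydrogens PDB files usually omit) are assessed on
    distance alone.  ``residues`` restricts contacts to named residues,
    e.g. {'R169', 'T248'}.
    """
    available = set(protein.residue_labels)
    res_filter = _normalize_residue_filter(residues, available)

    lig_polar = [i for i in ligand.heavy_indices
                 if ligand.atoms[i].element in ("N", "O")]
    prot_polar = [p for p, e in enumerate(protein.elements) if e in ("N", "O")]
    if res_filter is not None:
        prot_polar = [p for p in prot_polar
                      if protein.residue_labels[p] in res_filter]

    contacts = []
    for li in lig_polar:
        lc = ligand.atoms[li].coords
        lig_hs = [j for j in ligand.neighbors(li) if ligand.atoms[j].element == "H"]
        for p in prot_polar:
            d = float(np.linalg.norm(lc - protein.coords[p]))
            if d > max_distance:
                continue
            if lig_hs:
                # ligand donates: the D-H...A angle must be open enough
                best = max(_angle_deg(lc, ligand.atoms[j].coords, protein.coords[p])
                           for j in lig_hs)
                if best >= min_angle:
                    contacts.append(HBondContact(
                        li, p, protein.residue_labels[p], d, best, True))
            else:
                # ligand accepts (or its donor H is implicit): distance-only
                contacts.append(HBondContact(
                    li, p, protein.residue_labels[p], d, None, False))
    return contacts
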