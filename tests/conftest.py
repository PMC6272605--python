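import itertools

import numpy as np
import pytest

from consdock.fixtures import (benzene, decamer_ligand, ethane_heavy,
                               linear_chain_cno)
from consdock.pose_model import Atom, MolecularGraph, Pose


@pytest.fixture
def benzene_pose():
    return Pose("benzene", benzene(), engine_id="engine1", receptor_id="r1",
                score=-7.0)


@pytest.fixture
def decamer_pose():
    return Pose("decamer", decamer_ligand(), engine_id="engine1",
                receptor_id="r1", score=-8.0)


@pytest.fixture
def chain_pose():
    return Pose("chain", linear_chain_cno(), engine_id="engine1",
                receptor_id="r1", score=-5.0)


def square_ring():
    """4-membered carbon ring: 8 heavy-graph automorphisms (dihedral D4)."""
    atoms = [Atom("C", [np.cos(t), np.sin(t), 0.0])
             for t in np.arange(4) * np.pi / 2]
    bonds = {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0, (0, 3): 1.0}
    return MolecularGraph(atoms, bonds)


def branched_chain():
    """C(C)(N)-O: asymmetric 4-heavy-atom tree, identity only."""
    atoms = [Atom("C", [0, 0, 0]), Atom("C", [1.5, 0, 0]),
             Atom("N", [-1, 1, 0]), Atom("O", [-1, -1, 0])]
    bonds = {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0}
    return MolecularGraph(atoms, bonds)


def propane_like():
    """C-C-C: swap of the two terminal carbons, 2 automorphisms."""
    atoms = [Atom("C", [0, 0, 0]), Atom("C", [1.5, 0, 0]),
             Atom("C", [3.0, 0, 0])]
    bonds = {(0, 1): 1.0, (1, 2): 1.0}
    return MolecularGraph(atoms, bonds)


def brute_force_automorphisms(graph: MolecularGraph) -> list[tuple[int, ...]]:
    """Oracle: enumerate all heavy-atom permutations and keep those that
    preserve elements and adjacency (bond orders collapsed)."""
    heavy = graph.heavy_indices
    n = len(heavy)
    pos = {a: k for k, a in enumerate(heavy)}
    elements = [graph.atoms[a].element for a in heavy]
    adj = set()
    for (i, j) in graph.bonds:
        if i in pos and j in pos:
            adj.add(frozenset((pos[i], pos[j])))
    out = []
    for perm in itertools.permutations(range(n)):
        if any(elements[i] != elements[perm[i]] for i in range(n)):
            continue
        edges = [tuple(e) for e in adj]
        if all(frozenset((perm[i], perm[j])) in adj for i, j in edges):
            out.append(perm)
    return out


def brute_force_min_rmsd(a: Pose, b: Pose) -> float:
    """Oracle: minimum in-place RMSD over brute-force automorphisms."""
    ca, cb = a.graph.heavy_coords(), b.graph.heavy_coords()
    best = np.inf
    for perm in brute_force_automorphisms(b.graph):
        val = np.sqrt(np.mean(np.sum((ca - cb[list(perm)]) ** 2, axis=1)))
        best = min(best, val)
    return float(best)


def mann_whitney_auc(active_scores, decoy_scores) -> float:
    """Oracle: tie-corrected AUC by explicit pair counting."""
    a = np.asarray(active_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    wins = (a[:, None] > d[None, :]).sum()
    ties = (a[:, None] == d[None, :]).sum()
    return float((wins + 0.5 * ties) / (len(a) * len(d)))


def naive_complete_linkage_blocks(m: np.ndarray, threshold: float) -> set[frozenset[int]]:
    """Oracle: an independent O(n^3) complete-linkage agglomeration using
    a plain list-of-lists representation and fresh distance recomputation
    each round."""
    clusters = [[i] for i in range(len(m))]
    while len(clusters) > 1:
        best_d, best_pair = np.inf, None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = max(m[i][j] for i in clusters[x] for j in clusters[y])
                if d < best_d - 1e-15:
                    best_d, best_pair = d, (x, y)
        if best_d >= threshold:
            break
        x, y = best_pair
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return {frozenset(c) for c in clusters}
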