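"""Synthetic fixture generation: molecules with provable symmetry, pose
ensembles with planted cluster structure, labeled active/decoy libraries
with a molecular-weight window, and trajectories with prescribed ligand
drift.

Everything here is a pure function of its seed: the same FixtureSpec
always produces byte-identical output.  Pose ensembles are built from
rigid-body *translations* of a base pose, so every planted pairwise RMSD
is exact (a uniform displacement by vector t gives in-place RMSD |t|)
and the ground-truth complete-linkage partition is known by construction.
The library generator emulates a decoy collection sampled to match the
actives' molecular-weight span (the canonical window is 315–560 g/mol,
bounds inclusive); the chemistry of the generated molecules is not meant
to be realistic — only the bookkeeping that the screening metrics
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pose_model import Atom, MolecularGraph, Pose, PoseError, write_poses
from .stability import Trajectory

__all__ = [
    "FixtureSpec",
    "benzene",
    "ethane_heavy",
    "linear_chain_cno",
    "decamer_ligand",
    "make_pose_ensemble",
    "make_library",
    "make_trajectory",
    "make_screen_bundle",
]

DEFAULT_MW_RANGE = (315.0, 560.0)


@dataclass
class FixtureSpec:
    """Reproducible fixture recipe (identical seed ⇒ identical output)."""

    seed: int = 0
    n_engines: int = 4
    n_receptors: int = 4
    threshold: float = 2.0
    within_step: float = 0.5      # Å between members of one planted cluster
    between_gap: float = 5.0      # Å between planted cluster centres
    n_actives: int = 93
    n_decoys: int = 100
    mw_range: tuple[float, float] = DEFAULT_MW_RANGE


# ---------------------------------------------------------------------------
# Canned molecules with hand-written connectivity (automorphism counts
# are provable by brute force: benzene 12, ethane 2, C-N-O chain 1).

def benzene() -> MolecularGraph:
    """Benzene: 6 C + 6 H regular hexagon; heavy-graph automorphisms = 12."""
    r, rh = 1.39, 2.47
    atoms, bonds = [], {}
    for i in range(6):
        th = np.pi / 3 * i
        atoms.append(Atom("C", np.array([r * np.cos(th), r * np.sin(th), 0.0])))
    for i in range(6):
        th = np.pi / 3 * i
        atoms.append(Atom("H", np.array([rh * np.cos(th), rh * np.sin(th), 0.0])))
    for i in range(6):
        bonds[(i, (i + 1) % 6)] = 2.0 if i % 2 == 0 else 1.0  # Kekulé
        bonds[(i, i + 6)] = 1.0
    return MolecularGraph(atoms, bonds)


def ethane_heavy() -> MolecularGraph:
    """Just the C–C heavy skeleton; automorphisms = 2."""
    return MolecularGraph(
        [Atom("C", [0.0, 0.0, 0.0]), Atom("C", [1.54, 0.0, 0.0])],
        {(0, 1): 1.0},
    )


def linear_chain_cno() -> MolecularGraph:
    """C–N–O chain; no symmetry, automorphisms = 1."""
    return MolecularGraph(
        [Atom("C", [0.0, 0.0, 0.0]), Atom("N", [1.47, 0.0, 0.0]),
         Atom("O", [2.9, 0.0, 0.0])],
        {(0, 1): 1.0, (1, 2): 1.0},
    )


def decamer_ligand() -> MolecularGraph:
    """An asymmetric 10-heavy-atom branched ligand (automorphisms = 1),
    used where a drug-sized asymmetric pose is needed."""
    coords = [
        ("C", [0.00, 0.00, 0.00]), ("C", [1.52, 0.10, 0.05]),
        ("N", [2.20, 1.30, -0.30]), ("C", [3.65, 1.35, -0.20]),
        ("O", [4.30, 0.35, 0.20]), ("C", [4.35, 2.65, -0.55]),
        ("C", [5.85, 2.60, -0.40]), ("O", [6.50, 3.70, -0.80]),
        ("S", [-0.90, 1.40, 0.45]), ("C", [-0.65, -1.30, -0.55]),
    ]
    atoms = [Atom(e, np.array(c)) for e, c in coords]
    bonds = {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0, (3, 4): 2.0,
             (3, 5): 1.0, (5, 6): 1.0, (6, 7): 1.0, (0, 8): 1.0, (0, 9): 1.0}
    return MolecularGraph(atoms, bonds)


# ---------------------------------------------------------------------------

def _unit_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_pose_ensemble(
    planted_blocks: list[int],
    spec: FixtureSpec | None = None,
    base: MolecularGraph | None = None,
    compound_id: str = "CPD",
    receptor_id: str = "r1",
    engines: list[str] | None = None,
) -> tuple[list[Pose], list[frozenset[int]]]:
    """Build poses whose complete-linkage partition is known exactly.

    ``planted_blocks`` lists the sizes of the intended clusters (summing
    to the number of engines).  Cluster centres sit ``between_gap`` Å
    apart along orthogonal-ish axes; within a cluster, members are spaced
    ``within_step`` Å along one line so the cluster diameter is
    (size−1)·within_step.  The construction is validated: within-cluster
    diameter must stay below the threshold and the between-cluster floor
    (gap − diameters) at or above it, with margin — an infeasible recipe
    raises rather than silently planting the wrong truth.

    Returns (poses, ground-truth blocks of pose indices).
    """
    spec = spec or FixtureSpec()
    base = base or decamer_ligand()
    n = sum(planted_blocks)
    engines = engines or [f"engine{k + 1}" for k in range(n)]
    if len(engines) != n:
        raise PoseError("need one engine id per planted pose")

    for size in planted_blocks:
        diam = (size - 1) * spec.within_step
        if diam >= spec.threshold - 1e-9:
            raise PoseError(
                f"infeasible fixture: planted block of {size} has diameter "
                f"{diam:.2f} Å ≥ threshold {spec.threshold} Å"
            )
    max_diam = max((s - 1) * spec.within_step for s in planted_blocks)
    if len(planted_blocks) > 1 and spec.between_gap - 2 * max_diam < spec.threshold:
        raise PoseError(
            "infeasible fixture: between-cluster gap too small for the "
            "planted within-cluster spread"
        )

    rng = np.random.default_rng(spec.seed)
    # orthogonal cluster-centre axes keep between-cluster distances ≥ gap
    axes = np.eye(3)
    poses: list[Pose] = []
    truth: list[frozenset[int]] = []
    idx = 0
    for b, size in enumerate(planted_blocks):
        centre = spec.between_gap * (
            axes[b % 3] * (1 + b // 3)
        ) if b > 0 else np.zeros(3)
        direction = _unit_directions(rng, 1)[0]
        members = []
        for k in range(size):
            disp = centre + direction * (k * spec.within_step)
            poses.append(Pose(
                compound_id=compound_id,
                graph=base.translated(disp),
                engine_id=engines[idx],
                receptor_id=receptor_id,
                score=-8.0 + 0.1 * idx,
            ))
            members.append(idx)
            idx += 1
        truth.append(frozenset(members))
    return poses, truth


def make_library(
    n_actives: int,
    n_decoys: int,
    mw_range: tuple[float, float] = DEFAULT_MW_RANGE,
    pool_size: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled compound table with molecular weights.

    Actives are drawn uniformly inside ``mw_range``; decoys are sampled
    without replacement from a wider candidate pool after applying the
    inclusive MW window — mirroring how a decoy collection is pre-filtered
    to match the actives' weight span before random selection.
    """
    lo, hi = mw_range
    if not lo < hi:
        raise PoseError(f"invalid MW range {mw_range}")
    rng = np.random.default_rng(seed)
    pool_size = pool_size or max(4 * n_decoys, 1000)
    pool_mw = rng.uniform(lo - 100.0, hi + 100.0, size=pool_size)
    in_range = pool_mw[(pool_mw >= lo) & (pool_mw <= hi)]
    if len(in_range) < n_decoys:
        raise PoseError(
            f"decoy pool has only {len(in_range)} compounds in the MW window, "
            f"{n_decoys} requested"
        )
    decoy_mw = rng.choice(in_range, size=n_decoys, replace=False)
    active_mw = rng.uniform(lo, hi, size=n_actives)
    rows = [{"compound_id": f"ACT{i:05d}", "label": "active", "mw": m}
            for i, m in enumerate(active_mw)]
    rows += [{"compound_id": f"DEC{i:05d}", "label": "decoy", "mw": m}
             for i, m in enumerate(decoy_mw)]
    return pd.DataFrame(rows)


def filter_mw(table: pd.DataFrame, mw_range: tuple[float, float] = DEFAULT_MW_RANGE) -> pd.DataFrame:
    """Inclusive molecular-weight window filter."""
    lo, hi = mw_range
    return table[(table["mw"] >= lo) & (table["mw"] <= hi)].reset_index(drop=True)


def make_trajectory(
    drift: np.ndarray,
    base: MolecularGraph | None = None,
    n_protein_atoms: int = 30,
    dt: float = 10.0,
    protein_jitter: float = 0.0,
    seed: int = 0,
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory whose post-alignment ligand RMSD per frame equals
    ``drift`` exactly.

    The ligand translates rigidly by drift[f] Å along a fixed direction
    each frame (uniform translation ⇒ RMSD = displacement); the protein
    scaffold is static apart from optional Gaussian jitter.  Returns
    (trajectory, reference ligand heavy-atom coordinates) — the reference
    is frame 0's docked disposition.
    """
    drift = np.asarray(drift, dtype=float)
    if not np.all(np.isfinite(drift)):
        raise PoseError("drift series must be finite")
    base = base or decamer_ligand()
    rng = np.random.default_rng(seed)
    lig_ref = base.heavy_coords()
    n_lig = len(lig_ref)
    protein = rng.uniform(-12, 12, size=(n_protein_atoms, 3)) + np.array([20.0, 0, 0])
    direction = np.array([0.0, 0.0, 1.0])

    frames = []
    for f, d in enumerate(drift):
        lig_f = lig_ref + d * direction
        prot_f = protein.copy()
        if protein_jitter > 0:
            prot_f += rng.normal(scale=protein_jitter, size=prot_f.shape)
        frames.append(np.vstack([lig_f, prot_f]))
    traj = Trajectory(
        coords=np.stack(frames),
        times=np.arange(len(drift)) * dt,
        ligand_indices=np.arange(n_lig),
        protein_indices=np.arange(n_lig, n_lig + n_protein_atoms),
        elements=[a.element for a in base.atoms if a.is_heavy] + ["C"] * n_protein_atoms,
    )
    return traj, lig_ref


@dataclass
class ScreenBundle:
    """A desk-scale screening fixture: manifest pieces, a pose store and
    the planted ground truth."""

    compounds: list[str]
    engines: list[str]
    receptors: list[str]
    store: dict
    labels: dict[str, str]
    planted_levels: dict[str, int]    # per compound: max level over receptors

    def get(self, compound_id: str, engine_id: str, receptor_id: str):
        return self.store.get((compound_id, engine_id, receptor_id))


def make_screen_bundle(
    n_compounds: int,
    n_full_consensus: int,
    spec: FixtureSpec | None = None,
    active_fraction: float = 0.3,
) -> ScreenBundle:
    """Plant a library in which exactly ``n_full_consensus`` compounds
    reach full consensus (at receptor r1) and the rest split 2+2 there;
    other receptors get singleton-only ensembles (level 1).

    Ground-truth levels are recorded so end-to-end screening runs can be
    checked compound by compound.
    """
    spec = spec or FixtureSpec()
    if n_full_consensus > n_compounds:
        raise PoseError("cannot plant more consensus compounds than compounds")
    engines = [f"engine{k + 1}" for k in range(spec.n_engines)]
    receptors = [f"r{k + 1}" for k in range(spec.n_receptors)]
    rng = np.random.default_rng(spec.seed)
    store: dict = {}
    labels: dict[str, str] = {}
    planted: dict[str, int] = {}
    compounds = [f"CPD{i:04d}" for i in range(n_compounds)]
    full_set = set(compounds[:n_full_consensus])
    for i, cid in enumerate(compounds):
        labels[cid] = "active" if rng.random() < active_fraction else "decoy"
        sub = FixtureSpec(**{**spec.__dict__, "seed": int(spec.seed + 7919 * i + 1)})
        for r_idx, rid in enumerate(receptors):
            if rid == "r1":
                blocks = [spec.n_engines] if cid in full_set else [2, spec.n_engines - 2]
            else:
                blocks = [1] * spec.n_engines   # scattered: level 1
            poses, _ = make_pose_ensemble(
                blocks, sub, compound_id=cid, receptor_id=rid, engines=engines)
            for p in poses:
                store[(cid, p.engine_id, rid)] = p
        planted[cid] = spec.n_engines if cid in full_set else max(
            2, spec.n_engines - 2)
    return ScreenBundle(compounds, engines, receptors, store, labels, planted)


def write_bundle(bundle: ScreenBundle, out_dir: str | Path) -> None:
    """Write a bundle as SDF pose files + manifest CSV + labels CSV."""
    out = Path(out_dir)
    poses_dir = out / "poses"
    poses_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (cid, eid, rid), pose in sorted(bundle.store.items()):
        fname = f"{cid}__{eid}__{rid}.sdf"
        write_poses([pose], poses_dir / fname, "sdf")
        rows.append({
            "compound_id": cid, "engine_id": eid, "receptor_id": rid,
            "pose_path": f"poses/{fname}", "score": pose.score,
            "score_direction": pose.score_direction,
        })
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(
        [{"compound_id": c, "label": l} for c, l in sorted(bundle.labels.items())]
    ).to_csv(out / "labels.csv", index=False)
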