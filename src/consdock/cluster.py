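"""Complete-linkage consensus clustering of per-engine best poses.

Each docking engine contributes its single best-scored pose for a
compound in a receptor.  The poses are clustered agglomeratively with
complete linkage — inter-cluster distance is the *maximum* pairwise
RMSD — so every final cluster has diameter below the threshold: all of
its member poses are less than 2.0 Å (the default) away from all other
members.  The consensus level of the compound is the size of the largest
cluster, i.e. the number of engines that agree on one binding
disposition.

Merging stops when the smallest complete-linkage distance reaches the
threshold (strict ``<`` survives).  Ties on the merge distance break
deterministically by the lowest (min index of block A, min index of
block B), so consensus levels are reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RmsdMatrix, rmsd_matrix
from .pose_model import Pose, PoseError

__all__ = [
    "ClusterPartition",
    "ConsensusResult",
    "complete_linkage",
    "consensus_level",
    "pick_representative",
    "consensus_for_poses",
]


@dataclass
class ClusterPartition:
    """Disjoint blocks of pose indices covering 0..n-1, plus the merge
    history (blocks merged and the complete-linkage distance)."""

    blocks: list[frozenset[int]]
    linkage_trace: list[tuple[frozenset[int], frozenset[int], float]] = field(
        default_factory=list
    )
    n: int = 0

    def __post_init__(self):
        covered = sorted(i for b in self.blocks for i in b)
        if self.n == 0:
            self.n = len(covered)
        if covered != list(range(self.n)):
            raise PoseError("blocks must partition 0..n-1")

    def largest_block(self) -> frozenset[int]:
        return max(self.blocks, key=len)

    def block_of(self, i: int) -> frozenset[int]:
        for b in self.blocks:
            if i in b:
                return b
        raise KeyError(i)


def _complete_distance(matrix: np.ndarray, a: frozenset[int], b: frozenset[int]) -> float:
    return max(matrix[i, j] for i in a for j in b)


def complete_linkage(matrix: RmsdMatrix | np.ndarray, threshold: float = 2.0) -> ClusterPartition:
    """Agglomerate poses under complete linkage up to ``threshold`` Å.

    Starting from singletons, repeatedly merge the two clusters with the
    smallest complete-linkage (maximum pairwise) distance; stop when that
    smallest distance is ≥ threshold.  Every returned block therefore has
    all intra-block pairwise RMSDs strictly below the threshold.
    """
    m = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n) or n < 1:
        raise PoseError("distance matrix must be square and non-empty")
    if np.any(m < 0):
        raise PoseError("distance matrix has negative entries")
    if not np.allclose(m, m.T, atol=1e-8):
        raise PoseError("distance matrix is not symmetric")
    if np.any(np.abs(np.diag(m)) > 1e-8):
        raise PoseError("distance matrix diagonal must be zero")

    blocks = [frozenset([i]) for i in range(n)]
    trace: list[tuple[frozenset[int], frozenset[int], float]] = []
    while len(blocks) > 1:
        best = None  # (distance, min_a, min_b, ia, ib)
        for ia in range(len(blocks)):
            for ib in range(ia + 1, len(blocks)):
                a, b = blocks[ia], blocks[ib]
                if min(a) > min(b):
                    a, b = b, a
                d = _complete_distance(m, a, b)
                key = (d, min(a), min(b))
                if best is None or key < best[:3]:
                    best = (*key, ia, ib)
        d, _, _, ia, ib = best
        if d >= threshold:
            break
        merged = blocks[ia] | blocks[ib]
        a, b = blocks[ia], blocks[ib]
        if min(a) > min(b):
            a, b = b, a
        trace.append((a, b, d))
        blocks = [blk for k, blk in enumerate(blocks) if k not in (ia, ib)]
        blocks.append(merged)

    blocks.sort(key=min)
    part = ClusterPartition(blocks, trace, n=n)
    # diameter property asserted post-hoc on every run
    for blk in part.blocks:
        for i in blk:
            for j in blk:
                assert m[i, j] < threshold, "cluster diameter violates threshold"
    return part


def consensus_level(partition: ClusterPartition) -> int:
    """Size of the largest cluster: the number of engines agreeing on one
    binding disposition (with k engines, in [1, k])."""
    return len(partition.largest_block())


def _block_diameter(matrix: np.ndarray, block: frozenset[int]) -> float:
    if len(block) < 2:
        return 0.0
    return max(matrix[i, j] for i in block for j in block if i != j)


def pick_representative(
    partition: ClusterPartition,
    poses: list[Pose],
    matrix: RmsdMatrix | np.ndarray | None = None,
    engine_priority: list[str] | None = None,
) -> Pose:
    """Representative pose of the consensus cluster: the medoid of the
    largest block (minimum summed RMSD to the other members).

    When two blocks tie for largest, the one with smaller internal
    diameter wins (tighter consensus is stronger evidence), then engine
    priority.  Medoid ties resolve by engine priority as well; the
    default priority is lexicographic engine_id.
    """
    if matrix is None:
        m = rmsd_matrix(poses).values
    else:
        m = matrix.values if isinstance(matrix, RmsdMatrix) else np.asarray(matrix)

    def engine_rank(pose: Pose) -> tuple:
        if engine_priority and pose.engine_id in engine_priority:
            return (0, engine_priority.index(pose.engine_id))
        return (1, pose.engine_id)

    max_size = max(len(b) for b in partition.blocks)
    candidates = [b for b in partition.blocks if len(b) == max_size]
    if len(candidates) > 1:
        candidates.sort(key=lambda b: (
            _block_diameter(m, b),
            min(engine_rank(poses[i]) for i in b),
        ))
    block = candidates[0]

    members = sorted(block)
    sums = {i: sum(m[i, j] for j in members if j != i) for i in members}
    best = min(members, key=lambda i: (round(sums[i], 9), engine_rank(poses[i])))
    return poses[best]


@dataclass
class ConsensusResult:
    """Consensus outcome for one compound in one receptor."""

    compound_id: str
    receptor_id: str
    partition: ClusterPartition
    consensus_level: int
    representative: Pose
    member_engines: frozenset[str]


def consensus_for_poses(
    poses: list[Pose],
    threshold: float = 2.0,
    engine_priority: list[str] | None = None,
    **rmsd_kwargs,
) -> ConsensusResult:
    """End-to-end consensus for one compound × receptor: RMSD matrix →
    complete-linkage partition → level + representative."""
    if len(poses) == 1:
        part = ClusterPartition([frozenset([0])], n=1)
        return ConsensusResult(
            poses[0].compound_id, poses[0].receptor_id, part, 1, poses[0],
            frozenset([poses[0].engine_id]))
    m = rmsd_matrix(poses, **rmsd_kwargs)
    part = complete_linkage(m, threshold)
    rep = pick_representative(part, poses, m, engine_priority)
    block = part.largest_block()
    return ConsensusResult(
        compound_id=poses[0].compound_id,
        receptor_id=poses[0].receptor_id,
        partition=part,
        consensus_level=consensus_level(part),
        representative=rep,
        member_engines=frozenset(poses[i].engine_id for i in block),
    )
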