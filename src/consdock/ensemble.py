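"""Ensemble screening across receptor conformations.

The receptor is represented by several conformational states (canonically
four: open/closed × cofactor-bound/free), each treated as fully
independent — poses are never compared across receptors.  A compound is
shortlisted when the engines reach the required consensus level (default:
all of them) in *at least one* receptor state; a compound may therefore
be selected via different binding dispositions in different states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cluster import ConsensusResult, consensus_for_poses
from .pose_model import Pose, PoseError, ScreenManifest

__all__ = ["EnsembleDecision", "screen", "count_by_level", "decisions_to_frame"]


@dataclass
class EnsembleDecision:
    """Per-compound outcome: consensus level in each receptor state and
    whether the selection rule fired."""

    compound_id: str
    levels: dict[str, int]                 # receptor_id -> consensus level
    selected: bool
    selecting_receptors: frozenset[str]
    incomplete_receptors: frozenset[str] = frozenset()   # engines missing there
    results: dict[str, ConsensusResult] = field(default_factory=dict)

    @property
    def max_level(self) -> int:
        return max(self.levels.values()) if self.levels else 0


def screen(
    manifest: ScreenManifest,
    pose_store,
    required_level: int | None = None,
    threshold: float = 2.0,
    engine_priority: list[str] | None = None,
    keep_results: bool = False,
) -> list[EnsembleDecision]:
    """Cluster every compound independently in every receptor state and
    apply the selection rule.

    ``pose_store`` maps (compound_id, engine_id, receptor_id) to the best
    pose of that task via a ``get`` method returning ``None`` for failed
    tasks (a ``PoseStore`` or any dict-backed equivalent).  An engine
    failure at a receptor reduces the pose count there — the attainable
    level is capped by the surviving engines and the receptor is flagged
    — rather than aborting the compound.  A compound with no pose at any
    receptor is an error.
    """
    n_engines = len(manifest.engines)
    req = n_engines if required_level is None else int(required_level)
    if not (1 <= req <= n_engines):
        raise PoseError(f"required_level must be in [1, {n_engines}], got {req}")

    rec_ids = [r.receptor_id for r in manifest.receptors]
    decisions = []
    for cid in manifest.compounds:
        levels: dict[str, int] = {}
        incomplete: set[str] = set()
        results: dict[str, ConsensusResult] = {}
        any_pose = False
        for rid in rec_ids:
            poses: list[Pose] = []
            for eid in manifest.engines:
                p = pose_store.get(cid, eid, rid)
                if p is None:
                    incomplete.add(rid)
                else:
                    poses.append(p)
            if not poses:
                levels[rid] = 0
                continue
            any_pose = True
            res = consensus_for_poses(poses, threshold=threshold,
                                      engine_priority=engine_priority)
            levels[rid] = res.consensus_level
            if keep_results:
                results[rid] = res
        if not any_pose:
            raise PoseError(f"compound {cid!r} has no pose at any receptor")
        selecting = frozenset(r for r, lv in levels.items() if lv >= req)
        decisions.append(EnsembleDecision(
            compound_id=cid,
            levels=levels,
            selected=bool(selecting),
            selecting_receptors=selecting,
            incomplete_receptors=frozenset(incomplete),
            results=results,
        ))
    return decisions


def count_by_level(
    decisions: list[EnsembleDecision],
    labels: dict[str, str] | pd.Series,
    n_engines: int,
) -> pd.DataFrame:
    """Cumulative active/decoy counts by consensus level.

    Row ``k`` counts compounds whose max-over-receptor level is ≥ k, split
    by activity label ('active' / 'decoy').  Row k=1 equals the library
    totals; counts are monotone non-increasing in k.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    rows = []
    max_levels = {}
    for d in decisions:
        if d.compound_id not in labels:
            raise PoseError(f"unlabeled compound {d.compound_id!r}")
        lab = labels[d.compound_id]
        if lab not in ("active", "decoy"):
            raise PoseError(f"label must be active|decoy, got {lab!r}")
        max_levels[d.compound_id] = (d.max_level, lab)
    for k in range(1, n_engines + 1):
        actives = sum(1 for lv, lab in max_levels.values()
                      if lab == "active" and lv >= k)
        decoys = sum(1 for lv, lab in max_levels.values()
                     if lab == "decoy" and lv >= k)
        rows.append({"level": k, "actives": actives, "decoys": decoys})
    return pd.DataFrame(rows)


def decisions_to_frame(decisions: list[EnsembleDecision]) -> pd.DataFrame:
    """Flatten decisions to a table for CSV export."""
    rows = []
    for d in decisions:
        row = {"compound_id": d.compound_id}
        for rid, lv in sorted(d.levels.items()):
            row[f"level_{rid}"] = lv
        row["max_level"] = d.max_level
        row["selected"] = d.selected
        row["selecting_receptors"] = ";".join(sorted(d.selecting_receptors))
        row["incomplete_receptors"] = ";".join(sorted(d.incomplete_receptors))
        rows.append(row)
    return pd.DataFrame(rows)
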