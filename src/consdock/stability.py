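"""Pose-stability triage over MD trajectories.

Docking hits that survive consensus selection are triaged by a short
molecular-dynamics run of the complex: the ligand's heavy-atom RMSD from
its docked reference disposition is measured in every frame, averaged,
and the hit is discarded when the average reaches 2 Å (the keep rule is
strictly "average below 2 Å").  The trajectory itself is produced by any
MD engine; this module only consumes its frames (multi-model PDB or XYZ).

By default each frame is first superposed onto the starting frame via a
least-squares fit on the protein heavy atoms, so the measured quantity is
ligand drift *relative to the binding site* rather than whole-complex
tumbling; ``align='none'`` compares raw coordinates.  The ligand RMSD
itself is identity-mapped and never refit — a ligand that keeps its shape
but slides out of the pocket must register as unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import kabsch_rmsd, superpose
from .pose_model import Pose, PoseError

__all__ = [
    "Trajectory",
    "StabilityResult",
    "stability_filter",
    "protein_rmsd_series",
    "load_trajectory",
]


@dataclass
class Trajectory:
    """Ordered coordinate frames of a ligand-protein complex.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å; ``times`` is in ps,
    strictly increasing; ``ligand_indices`` / ``protein_indices`` select
    heavy atoms of each component within a frame.
    """

    coords: np.ndarray
    times: np.ndarray
    ligand_indices: np.ndarray
    protein_indices: np.ndarray
    elements: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.ligand_indices = np.asarray(self.ligand_indices, dtype=int)
        self.protein_indices = np.asarray(self.protein_indices, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise PoseError("trajectory coords must have shape (frames, atoms, 3)")
        if len(self.times) != len(self.coords):
            raise PoseError("one time per frame required")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise PoseError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def ligand_frames(self) -> np.ndarray:
        return self.coords[:, self.ligand_indices, :]

    def protein_frames(self) -> np.ndarray:
        return self.coords[:, self.protein_indices, :]


@dataclass
class StabilityResult:
    """Per-frame and average ligand RMSD vs. the docked reference, plus
    the pass/fail verdict (pass ⇔ average strictly below threshold)."""

    per_frame_rmsd: np.ndarray
    times: np.ndarray
    average_rmsd: float
    burn_in_frames: int
    threshold: float
    passed: bool


def _reference_coords(reference) -> np.ndarray:
    if isinstance(reference, Pose):
        return reference.graph.heavy_coords()
    return np.asarray(reference, dtype=float).reshape(-1, 3)


def stability_filter(
    traj: Trajectory,
    reference,
    threshold: float = 2.0,
    align: str = "protein",
    burn_in: float = 0.0,
) -> StabilityResult:
    """Average ligand drift from the docked pose over a trajectory.

    ``reference`` is the docked pose (a Pose, or a raw (n, 3) heavy-atom
    coordinate array) whose atoms correspond 1:1, in order, to the
    trajectory's ligand atoms.  With ``align='protein'`` each frame is
    rigidly superposed onto frame 0 via its protein heavy atoms before
    the ligand deviation is measured; the ligand itself is compared with
    the identity mapping and no refit.  The average runs over frames with
    t ≥ ``burn_in`` (ps); the verdict passes when it is strictly below
    ``threshold`` (an average of exactly 2.0 Å is discarded).
    """
    if align not in ("none", "protein"):
        raise PoseError(f"align must be none|protein, got {align!r}")
    ref = _reference_coords(reference)
    lig = traj.ligand_frames()
    if lig.shape[1] != ref.shape[0]:
        raise PoseError(
            f"reference has {ref.shape[0]} heavy atoms but trajectory ligand "
            f"has {lig.shape[1]}"
        )
    keep = traj.times >= burn_in
    if not np.any(keep):
        raise PoseError(f"no frames at or after burn-in of {burn_in} ps")

    prot = traj.protein_frames()
    prot_ref = prot[0] if len(traj.protein_indices) else None
    per_frame = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        lig_f = lig[f]
        if align == "protein" and prot_ref is not None and len(prot_ref) >= 3:
            R, t, _ = superpose(prot[f], prot_ref)
            lig_f = lig_f @ R.T + t
        per_frame[f] = np.sqrt(np.mean(np.sum((lig_f - ref) ** 2, axis=1)))
    avg = float(per_frame[keep].mean())
    return StabilityResult(
        per_frame_rmsd=per_frame,
        times=traj.times.copy(),
        average_rmsd=avg,
        burn_in_frames=int(np.sum(~keep)),
        threshold=threshold,
        passed=avg < threshold,
    )


def protein_rmsd_series(traj: Trajectory, reference: np.ndarray | None = None) -> np.ndarray:
    """Per-frame superposed protein heavy-atom RMSD vs. the starting
    structure (or a supplied reference coordinate set)."""
    prot = traj.protein_frames()
    if prot.shape[1] == 0:
        raise PoseError("trajectory has no protein atoms")
    ref = prot[0] if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != prot[0].shape:
        raise PoseError("protein reference atom count mismatch")
    return np.array([kabsch_rmsd(ref, prot[f]) for f in range(traj.n_frames)])


def load_trajectory(
    path: str | Path,
    ligand_resname: str | None = None,
    ligand_indices=None,
    dt: float = 1.0,
    heavy_only: bool = True,
) -> Trajectory:
    """Load a multi-model PDB or XYZ trajectory via MDAnalysis.

    For PDB input the ligand is selected by residue name (e.g. 'LIG');
    XYZ files carry no residue metadata, so explicit ``ligand_indices``
    are required there.  Frame times come from the file when present,
    otherwise 0, dt, 2·dt, … ps.
    """
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe(str(path))
    n_atoms = len(u.atoms)
    if ligand_indices is not None:
        lig_mask = np.zeros(n_atoms, dtype=bool)
        lig_mask[np.asarray(ligand_indices, dtype=int)] = True
    elif ligand_resname:
        lig_mask = np.array([a.resname.strip() == ligand_resname for a in u.atoms])
        if not lig_mask.any():
            raise PoseError(f"no atoms with residue name {ligand_resname!r}")
    else:
        raise PoseError("pass ligand_resname (PDB) or ligand_indices (XYZ)")

    elements = []
    for a in u.atoms:
        el = getattr(a, "element", "") or ""
        if not el:
            name = a.name.strip()
            el = name[:2].capitalize() if name[:2].capitalize() in ("Cl", "Br") else name[0]
        elements.append(el.capitalize())
    heavy = np.array([e != "H" for e in elements]) if heavy_only else np.ones(n_atoms, bool)

    frames, times = [], []
    for i, ts in enumerate(u.trajectory):
        frames.append(ts.positions[heavy].copy())
        t = getattr(ts, "time", None)
        times.append(float(t) if t is not None else i * dt)
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(len(frames)) * dt

    remap = np.cumsum(heavy) - 1
    lig_idx = remap[lig_mask & heavy]
    prot_idx = remap[(~lig_mask) & heavy]
    return Trajectory(
        coords=np.stack(frames),
        times=times,
        ligand_indices=lig_idx,
        protein_indices=prot_idx,
        elements=[e for e, h in zip(elements, heavy) if h],
    )
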