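"""Geometric hydrogen-bond detection, contact statistics and pi-stacking.

A hydrogen bond is accepted purely geometrically: the hydrogen-acceptor
distance must be below a threshold (default 3.0 A) and the deviation of the
donor-H...acceptor arrangement from linearity below an angular threshold
(default 35 deg). Occupancy is the percentage of trajectory frames
satisfying both criteria; mean contact distances are averaged over *all*
frames, bonded or not, so a rarely-bonded contact reports its true average
separation (e.g. a 4.4 A mean next to a 4.8% occupancy).

Aromatic ring pairs are classified from the centroid separation d and the
angle theta between best-fit ring-plane normals (folded to [0, 90] deg):
parallel-displaced for small theta, T-shaped for near-perpendicular planes,
both gated by a maximum centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from mdinteract.errors import GeometryError, SelectionError
from mdinteract.geometry import angle
from mdinteract.structure_io import Selection, Trajectory, select

__all__ = [
    "HBondCriteria",
    "HBondTriple",
    "ContactStat",
    "DistanceSeries",
    "StackingClass",
    "StackingThresholds",
    "is_hbonded",
    "hbond_occupancy",
    "distance_series",
    "classify_stacking",
    "export_series",
    "export_contact_table",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond acceptance thresholds.

    ``angle_vertex`` selects where the deviation-from-linearity angle is
    measured: at the donor (between donor->hydrogen and donor->acceptor,
    0 deg = perfectly linear) or at the acceptor (between
    acceptor->donor and acceptor->hydrogen). Both readings of a
    "donor-acceptor-hydrogen angle" criterion are near 0 for a linear bond;
    the donor vertex is the default.
    """

    max_hydrogen_acceptor_distance: float = 3.0
    max_deviation_angle: float = 35.0
    angle_vertex: str = "donor"

    def __post_init__(self) -> None:
        if self.max_hydrogen_acceptor_distance <= 0 or self.max_deviation_angle <= 0:
            raise ValueError("H-bond thresholds must be strictly positive")
        if self.angle_vertex not in ("donor", "acceptor"):
            raise ValueError("angle_vertex must be 'donor' or 'acceptor'")


@dataclass(frozen=True)
class HBondTriple:
    """Donor / hydrogen / acceptor topology indices.

    ``acceptor`` may be a single index or a set of candidate indices, in
    which case the closest candidate to the hydrogen is taken per frame
    (a carboxylate's two oxygens, for instance).
    """

    donor: int
    hydrogen: int
    acceptor: int | Sequence[int]

    def acceptor_indices(self) -> np.ndarray:
        if isinstance(self.acceptor, (int, np.integer)):
            return np.asarray([self.acceptor], dtype=int)
        idx = np.asarray(list(self.acceptor), dtype=int)
        if idx.size == 0:
            raise SelectionError("acceptor selection is empty")
        return idx


@dataclass(frozen=True)
class ContactStat:
    """Mean contact distance (all frames) and H-bond occupancy (percent)."""

    mean_distance: float
    occupancy: float
    n_frames: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 100.0:
            raise ValueError("occupancy must lie in [0, 100] percent")


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame closest-atom distance between two groups, plus its mean."""

    series: np.ndarray
    mean: float


class StackingClass(str, Enum):
    PARALLEL_DISPLACED = "parallel_displaced"
    T_SHAPED = "t_shaped"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class StackingThresholds:
    """Conventional ring-stacking gates (not derived from any one dataset)."""

    d_max: float = 6.5
    theta_parallel: float = 30.0
    theta_perpendicular: float = 60.0
    planarity_residual: float = 0.3


def _deviation_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray, vertex: str) -> float:
    if vertex == "donor":
        return angle(h, d, a)
    return angle(d, a, h)


def _closest_acceptor(frame: np.ndarray, hydrogen: int, acceptors: np.ndarray) -> int:
    dists = np.linalg.norm(frame[acceptors] - frame[hydrogen], axis=1)
    return int(acceptors[int(np.argmin(dists))])


def is_hbonded(
    frame: np.ndarray,
    triple: HBondTriple,
    criteria: HBondCriteria = HBondCriteria(),
) -> bool:
    """Whether the triple satisfies both geometric criteria in one frame."""
    frame = np.asarray(frame, dtype=float)
    n = frame.shape[0]
    acceptors = triple.acceptor_indices()
    for idx in (triple.donor, triple.hydrogen, *acceptors):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} outside frame of {n} atoms")
    acc = _closest_acceptor(frame, triple.hydrogen, acceptors)
    d_ha = float(np.linalg.norm(frame[acc] - frame[triple.hydrogen]))
    if not d_ha < criteria.max_hydrogen_acceptor_distance:
        return False
    dev = _deviation_angle(
        frame[triple.donor], frame[triple.hydrogen], frame[acc], criteria.angle_vertex
    )
    return dev < criteria.max_deviation_angle


def hbond_occupancy(
    trajectory: Trajectory,
    triple: HBondTriple,
    criteria: HBondCriteria = HBondCriteria(),
) -> ContactStat:
    """Occupancy (percent of frames bonded) and all-frame mean H...A distance."""
    d_dh = np.linalg.norm(
        trajectory.frames[0, triple.hydrogen] - trajectory.frames[0, triple.donor]
    )
    if d_dh >= 1.2:
        raise ValueError(
            f"hydrogen {triple.hydrogen} is {d_dh:.2f} A from donor {triple.donor} "
            "in the first frame; not a covalent donor-hydrogen pair"
        )
    bonded = 0
    dists = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.frames[f]
        acc = _closest_acceptor(frame, triple.hydrogen, triple.acceptor_indices())
        dists[f] = np.linalg.norm(frame[acc] - frame[triple.hydrogen])
        if is_hbonded(frame, triple, criteria):
            bonded += 1
    return ContactStat(
        mean_distance=float(dists.mean()),
        occupancy=100.0 * bonded / trajectory.n_frames,
        n_frames=trajectory.n_frames,
    )


def distance_series(
    trajectory: Trajectory,
    group_a: Selection | dict | Sequence[int],
    group_b: Selection | dict | Sequence[int],
) -> DistanceSeries:
    """Per-frame minimum distance between any atom of group A and of group B."""
    ia = _resolve_group(trajectory, group_a, "group_a")
    ib = _resolve_group(trajectory, group_b, "group_b")
    a = trajectory.frames[:, ia, :]  # (F, A, 3)
    b = trajectory.frames[:, ib, :]  # (F, B, 3)
    diff = a[:, :, None, :] - b[:, None, :, :]
    d = np.linalg.norm(diff, axis=3).reshape(trajectory.n_frames, -1)
    series = d.min(axis=1)
    return DistanceSeries(series=series, mean=float(series.mean()))


def _resolve_group(trajectory: Trajectory, group, label: str) -> np.ndarray:
    if isinstance(group, (Selection, dict)):
        idx = select(trajectory, group)
    else:
        idx = np.asarray(list(group), dtype=int)
    if idx.size == 0:
        raise SelectionError(f"{label} resolves to no atoms")
    return idx


def _ring_plane(coords: np.ndarray, max_residual: float) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a best-fit plane through ring atoms."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    residual = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    if residual >= max_residual:
        raise GeometryError(
            f"ring is not planar: best-fit-plane RMS residual {residual:.3f} A "
            f">= {max_residual} A"
        )
    return centroid, normal


def classify_stacking(
    frame: np.ndarray,
    ring_a: Sequence[int] | Selection | dict,
    ring_b: Sequence[int] | Selection | dict,
    thresholds: StackingThresholds = StackingThresholds(),
    topology=None,
) -> StackingClass:
    """Classify a ring pair as parallel-displaced, T-shaped or unclassified.

    ``ring_a``/``ring_b`` are topology index sets (or Selections, resolved
    against ``topology``); each ring needs at least 3 approximately
    coplanar atoms.
    """
    frame = np.asarray(frame, dtype=float)

    def indices(ring, label):
        if isinstance(ring, (Selection, dict)):
            if topology is None:
                raise SelectionError(f"{label}: a Selection needs a topology to resolve")
            sel = Selection.from_dict(ring) if isinstance(ring, dict) else ring
            idx = sel.resolve(topology)
        else:
            idx = np.asarray(list(ring), dtype=int)
        if idx.size < 3:
            raise SelectionError(f"{label} must contain at least 3 atoms")
        return idx

    ca, na = _ring_plane(frame[indices(ring_a, "ring_a")], thresholds.planarity_residual)
    cb, nb = _ring_plane(frame[indices(ring_b, "ring_b")], thresholds.planarity_residual)
    d = float(np.linalg.norm(cb - ca))
    cos_t = abs(float(np.clip(np.dot(na, nb), -1.0, 1.0)))
    theta = float(np.degrees(np.arccos(cos_t)))  # folded to [0, 90]
    if d > thresholds.d_max:
        return StackingClass.UNCLASSIFIED
    if theta <= thresholds.theta_parallel:
        return StackingClass.PARALLEL_DISPLACED
    if theta >= thresholds.theta_perpendicular:
        return StackingClass.T_SHAPED
    return StackingClass.UNCLASSIFIED


def export_series(series: np.ndarray, path: str | Path, label: str = "distance_angstrom") -> None:
    """Write a per-frame series as two-column (frame, value) delimited text."""
    path = Path(path)
    rows = "\n".join(f"{i}\t{v:.4f}" for i, v in enumerate(np.asarray(series)))
    path.write_text(f"# frame\t{label}\n{rows}\n")


def export_contact_table(rows: Sequence[dict], path: str | Path) -> None:
    """Write per-contact rows as a residue x {Dist., Occ.} delimited table.

    Each row is a mapping with keys ``residue``, ``group``,
    ``mean_distance`` (A) and ``occupancy`` (percent).
    """
    path = Path(path)
    lines = ["residue\tgroup\tdist_angstrom\tocc_percent"]
    for r in rows:
        lines.append(
            f"{r['residue']}\t{r['group']}\t{r['mean_distance']:.2f}\t{r['occupancy']:.1f}"
        )
    path.write_text("\n".join(lines) + "\n")
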