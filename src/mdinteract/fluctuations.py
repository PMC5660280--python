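"""Ligand RMSD series and fluctuation-corrected per-residue RMSD heatmaps.

The heatmap procedure compares a ligand-loaded trajectory against a
reference frame of an apo ("empty") simulation: per-residue heavy-atom
RMSDs are computed for every frame after a single global fit, then the apo
system's intrinsic per-residue fluctuation (its mean RMSD against its own
reference) is subtracted and the result clamped at zero, so that only
deviations *beyond* natural residue motion remain visible — e.g. a binding
groove "lid" that opens only in the loaded system.

Fitting policy: one global fit (default on shared C-alpha atoms) per
frame, never a per-residue refit — a per-residue refit would erase exactly
the collective displacements the heatmap is meant to expose. Likewise the
ligand RMSD is measured after fitting on the *protein*, so ligand drift
and dissociation remain visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mdinteract.errors import SelectionError, TopologyError
from mdinteract.geometry import kabsch_superpose, rmsd
from mdinteract.structure_io import (
    Selection,
    Trajectory,
    select,
    sidechain_heavy_indices,
)

__all__ = [
    "PerResidueRMSDMatrix",
    "CorrectedHeatmap",
    "SidechainRMSDResult",
    "ligand_rmsd_series",
    "per_residue_rmsd",
    "corrected_heatmap",
    "mean_sidechain_rmsd",
    "export_matrix",
]


@dataclass
class PerResidueRMSDMatrix:
    """Frames x residues heavy-atom RMSD values against a fixed reference."""

    matrix: np.ndarray  # (n_frames, n_residues)
    residue_numbers: list[int]
    reference: str
    skipped_residues: list[int] = field(default_factory=list)


@dataclass
class CorrectedHeatmap:
    """Per-residue RMSD with the apo system's natural fluctuation removed."""

    matrix: np.ndarray  # (n_frames, n_residues), >= 0 after clamping
    baseline: np.ndarray  # (n_residues,) mean apo self-fluctuation
    residue_numbers: list[int]


@dataclass
class SidechainRMSDResult:
    mean: float | None
    per_residue_mean: dict[int, float]
    skipped_residues: list[int]


def _heavy(indices: np.ndarray, trajectory: Trajectory) -> np.ndarray:
    return np.asarray(
        [i for i in indices if trajectory.topology[i].is_heavy], dtype=int
    )


def ligand_rmsd_series(
    trajectory: Trajectory,
    ligand: Selection | dict,
    protein_fit: Selection | dict,
    reference_frame: int = 0,
) -> np.ndarray:
    """Ligand heavy-atom RMSD per frame after a protein-only fit.

    Each frame is superposed onto the reference frame using the
    ``protein_fit`` atoms only; the transform is then applied to the ligand
    and its heavy-atom RMSD against the reference ligand reported with no
    second fit, so rigid complex motion cancels but ligand motion relative
    to the protein does not.
    """
    lig = _heavy(select(trajectory, ligand), trajectory)
    fit = select(trajectory, protein_fit)
    if lig.size == 0:
        raise SelectionError("ligand selection resolves to no heavy atoms")
    if fit.size < 3:
        raise SelectionError("protein fit selection needs at least 3 atoms")
    ref = trajectory.frames[reference_frame]
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        sup = kabsch_superpose(trajectory.frames[f][fit], ref[fit])
        moved = sup.apply(trajectory.frames[f][lig])
        out[f] = rmsd(moved, ref[lig])
    return out


def _atom_key_map(trajectory: Trajectory) -> dict[tuple[int, str], int]:
    return {
        (a.residue_number, a.name.upper()): i
        for i, a in enumerate(trajectory.topology)
    }


def per_residue_rmsd(
    trajectory: Trajectory,
    reference: Trajectory,
    reference_frame: int = 0,
    residues: Sequence[int] | None = None,
    fit: Selection | dict | None = None,
) -> PerResidueRMSDMatrix:
    """Per-residue heavy-atom RMSD of each frame against a reference system.

    Atoms are matched across the two systems by ``(residue_number,
    atom name)``; residues of the trajectory with no matchable heavy atoms
    in the reference are reported as skipped, never silently dropped. The
    fit (default: C-alpha atoms shared by both systems) is global and
    applied once per frame.
    """
    ref_map = _atom_key_map(reference)
    ref_coords = reference.frames[reference_frame]

    if fit is None:
        fit = Selection(atom_name="CA", heavy=True)
    fit_traj = select(trajectory, fit)
    fit_pairs = [
        (i, ref_map[(trajectory.topology[i].residue_number, trajectory.topology[i].name.upper())])
        for i in fit_traj
        if (trajectory.topology[i].residue_number, trajectory.topology[i].name.upper()) in ref_map
    ]
    if len(fit_pairs) < 3:
        raise SelectionError(
            "fewer than 3 fit atoms are shared between trajectory and reference"
        )
    fit_t = np.asarray([p[0] for p in fit_pairs], dtype=int)
    fit_r = np.asarray([p[1] for p in fit_pairs], dtype=int)

    traj_residues = sorted({a.residue_number for a in trajectory.topology})
    if residues is not None:
        wanted = set(residues)
        traj_residues = [r for r in traj_residues if r in wanted]

    matched: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    skipped: list[int] = []
    for resnum in traj_residues:
        ti, ri = [], []
        for i, a in enumerate(trajectory.topology):
            if a.residue_number != resnum or not a.is_heavy:
                continue
            key = (resnum, a.name.upper())
            if key in ref_map:
                ti.append(i)
                ri.append(ref_map[key])
        if ti:
            matched[resnum] = (np.asarray(ti, dtype=int), np.asarray(ri, dtype=int))
        else:
            skipped.append(resnum)

    residue_numbers = sorted(matched)
    out = np.empty((trajectory.n_frames, len(residue_numbers)))
    for f in range(trajectory.n_frames):
        sup = kabsch_superpose(trajectory.frames[f][fit_t], ref_coords[fit_r])
        moved = sup.apply(trajectory.frames[f])
        for j, resnum in enumerate(residue_numbers):
            ti, ri = matched[resnum]
            out[f, j] = rmsd(moved[ti], ref_coords[ri])
    return PerResidueRMSDMatrix(
        matrix=out,
        residue_numbers=residue_numbers,
        reference=f"frame {reference_frame} of reference system",
        skipped_residues=skipped,
    )


def corrected_heatmap(
    loaded: PerResidueRMSDMatrix, empty_self: PerResidueRMSDMatrix
) -> CorrectedHeatmap:
    """Subtract the apo self-fluctuation baseline and clamp at zero.

    The baseline is the per-residue time-mean of the apo-vs-itself matrix;
    values where the baseline exceeds the loaded RMSD clamp to zero (the
    heatmap lives on a non-negative colour scale).
    """
    if loaded.residue_numbers != empty_self.residue_numbers:
        only_l = sorted(set(loaded.residue_numbers) - set(empty_self.residue_numbers))
        only_e = sorted(set(empty_self.residue_numbers) - set(loaded.residue_numbers))
        raise TopologyError(
            "residue columns differ between loaded and empty matrices: "
            f"only in loaded {only_l}, only in empty {only_e}"
        )
    baseline = empty_self.matrix.mean(axis=0)
    corrected = np.clip(loaded.matrix - baseline[None, :], 0.0, None)
    return CorrectedHeatmap(
        matrix=corrected,
        baseline=baseline,
        residue_numbers=list(loaded.residue_numbers),
    )


def mean_sidechain_rmsd(
    trajectory: Trajectory,
    residues: Sequence[int],
    reference_frame: int = 0,
    fit: Selection | dict | None = None,
) -> SidechainRMSDResult:
    """Mean sidechain heavy-atom RMSD of selected residues vs a reference frame.

    After a global fit (default: all C-alpha atoms) of each frame onto the
    reference frame, the heavy sidechain atoms (backbone N/CA/C/O/OXT
    excluded) of each residue are compared; the result is the mean over
    frames and residues. Residues without sidechain heavy atoms (glycine)
    are skipped and reported.
    """
    if fit is None:
        fit = Selection(atom_name="CA", heavy=True)
    fit_idx = select(trajectory, fit)
    if fit_idx.size < 3:
        raise SelectionError("fit selection needs at least 3 atoms")
    side: dict[int, np.ndarray] = {}
    skipped: list[int] = []
    for resnum in residues:
        idx = sidechain_heavy_indices(trajectory.topology, resnum)
        if idx.size == 0:
            skipped.append(resnum)
        else:
            side[resnum] = idx
    if not side:
        return SidechainRMSDResult(mean=None, per_residue_mean={}, skipped_residues=skipped)

    ref = trajectory.frames[reference_frame]
    sums = {r: 0.0 for r in side}
    for f in range(trajectory.n_frames):
        sup = kabsch_superpose(trajectory.frames[f][fit_idx], ref[fit_idx])
        moved = sup.apply(trajectory.frames[f])
        for r, idx in side.items():
            sums[r] += rmsd(moved[idx], ref[idx])
    per_res = {r: s / trajectory.n_frames for r, s in sums.items()}
    return SidechainRMSDResult(
        mean=float(np.mean(list(per_res.values()))),
        per_residue_mean=per_res,
        skipped_residues=skipped,
    )


def export_matrix(
    matrix: np.ndarray, residue_numbers: Sequence[int], path: str | Path
) -> None:
    """Write a frames x residues matrix with a residue-number header row."""
    path = Path(path)
    header = "frame\t" + "\t".join(str(r) for r in residue_numbers)
    rows = [
        f"{i}\t" + "\t".join(f"{v:.4f}" for v in row)
        for i, row in enumerate(np.asarray(matrix))
    ]
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
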