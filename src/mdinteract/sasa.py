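"""Shrake-Rupley solvent-accessible surface area and summary statistics.

SASA is estimated by placing a deterministic Fibonacci lattice of test
points on each atom's probe-inflated sphere (radius r_atom + r_probe) and
counting the fraction not buried inside any other inflated sphere:

    area_i = (accessible points / total points) * 4 pi (r_i + r_probe)^2

The Fibonacci lattice is seedless and reproducible, and rotates with the
coordinates, so total SASA is rotation-invariant only up to the lattice
discretisation (~0.1% at the default 960 points).

Van der Waals radii default to the Bondi set; the probe radius defaults to
1.4 A (water). Summary statistics use the sample standard deviation and a
normal-quantile confidence half-width z * sd / sqrt(n) — the convention
that reproduces a printed "+/-0.7 A^2 (P = 95%, SD = 12.0, n = 1000)".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from mdinteract.errors import ConfigurationError, SelectionError
from mdinteract.structure_io import Selection, Trajectory, select

__all__ = [
    "BONDI_RADII",
    "RadiiTable",
    "SasaConfig",
    "SummaryStat",
    "shrake_rupley",
    "sasa_series",
    "summarize",
    "fibonacci_sphere",
]

#: Bondi van der Waals radii (A), extended with common ions.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "ZN": 1.39,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
}

_TIE_TOL = 1e-9


@dataclass(frozen=True)
class RadiiTable:
    """Element -> van der Waals radius (A)."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all van der Waals radii must be positive")

    def radius(self, element: str) -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise ConfigurationError(
                f"no van der Waals radius defined for element {element!r}"
            ) from None


@dataclass(frozen=True)
class SasaConfig:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii: RadiiTable = field(default_factory=RadiiTable)

    def __post_init__(self) -> None:
        if self.n_sphere_points < 60:
            raise ValueError("n_sphere_points must be at least 60")


@dataclass(frozen=True)
class SummaryStat:
    """Mean, sample SD and normal-quantile CI half-width of a series."""

    mean: float
    sd: float | None
    ci_half_width: float | None
    n: int
    level: float = 95.0


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (deterministic lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle increments
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def shrake_rupley(
    frame: np.ndarray,
    target: Sequence[int],
    context: Sequence[int],
    elements: Sequence[str],
    config: SasaConfig = SasaConfig(),
    orientation: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA (A^2) of ``target`` atoms, occluded by target + context.

    ``elements`` gives the element symbol of every atom in ``frame``.
    A test point lying exactly on another inflated sphere (a coincident-
    atom tie) belongs to the lowest-index atom among those whose surface
    it lies on, so duplicated atoms never double-count area.
    ``orientation`` optionally rotates the test-point lattice (a 3x3
    rotation); co-rotating it with the coordinates makes total SASA
    exactly rotation-invariant instead of invariant only up to lattice
    discretisation.
    """
    frame = np.asarray(frame, dtype=float)
    target = np.asarray(list(target), dtype=int)
    context = np.asarray(list(context), dtype=int)
    all_idx = np.concatenate([target, context]) if context.size else target
    # deduplicate while keeping deterministic order
    seen: dict[int, None] = {}
    for i in all_idx:
        seen.setdefault(int(i), None)
    all_idx = np.asarray(list(seen), dtype=int)

    inflated = np.asarray(
        [config.radii.radius(elements[i]) + config.probe_radius for i in all_idx]
    )
    centers = frame[all_idx]
    points = fibonacci_sphere(config.n_sphere_points)
    if orientation is not None:
        points = points @ np.asarray(orientation, dtype=float).T

    pos_of = {int(a): k for k, a in enumerate(all_idx)}
    areas = np.zeros(len(target))
    for t, atom in enumerate(target):
        k = pos_of[int(atom)]
        ri = inflated[k]
        sphere = centers[k] + ri * points
        # candidate occluders: inflated spheres that can reach this sphere
        gap = np.linalg.norm(centers - centers[k], axis=1)
        cand = np.nonzero((gap < ri + inflated + _TIE_TOL) & (np.arange(len(all_idx)) != k))[0]
        blocked = np.zeros(config.n_sphere_points, dtype=bool)
        for j in cand:
            d = np.linalg.norm(sphere - centers[j], axis=1)
            rj = inflated[j]
            blocked |= d < rj - _TIE_TOL
            if j < k:  # ownership tie-break: boundary points go to the lower index
                blocked |= np.abs(d - rj) <= _TIE_TOL
        frac = 1.0 - blocked.sum() / config.n_sphere_points
        areas[t] = frac * 4.0 * np.pi * ri**2
    return areas


def sasa_series(
    trajectory: Trajectory,
    target: Selection | dict | Sequence[int],
    context: Selection | dict | Sequence[int],
    config: SasaConfig = SasaConfig(),
    level: float = 95.0,
) -> tuple[np.ndarray, SummaryStat]:
    """Per-frame total target SASA plus its summary statistics.

    With a single frame the summary carries the mean only (SD and CI are
    unavailable and set to None).
    """
    tidx = _resolve(trajectory, target, "target")
    cidx = _resolve(trajectory, context, "context", allow_empty=True)
    elements = [a.element for a in trajectory.topology]
    series = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        series[f] = shrake_rupley(trajectory.frames[f], tidx, cidx, elements, config).sum()
    if trajectory.n_frames < 2:
        stat = SummaryStat(mean=float(series.mean()), sd=None, ci_half_width=None,
                           n=trajectory.n_frames, level=level)
    else:
        stat = summarize(series, level=level)
    return series, stat


def _resolve(trajectory, sel, label, allow_empty=False) -> np.ndarray:
    if isinstance(sel, (Selection, dict)):
        idx = select(trajectory, sel)
    else:
        idx = np.asarray(list(sel), dtype=int)
    if idx.size == 0 and not allow_empty:
        raise SelectionError(f"{label} selection resolves to no atoms")
    return idx


def summarize(series: Sequence[float], level: float = 95.0) -> SummaryStat:
    """Mean, sample SD (n-1) and z-quantile CI half-width of a series."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("summarize needs at least 2 values")
    sd = float(np.std(x, ddof=1))
    z = float(stats.norm.ppf(0.5 + level / 200.0))
    return SummaryStat(
        mean=float(x.mean()),
        sd=sd,
        ci_half_width=z * sd / np.sqrt(n),
        n=n,
        level=level,
    )
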