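"""QM/MM boundary utilities: link atoms, harmonic corrections, charge scaling.

When a covalent C-alpha/C-beta bond is cut by a QM/MM partition, the QM
fragment is capped with a hydrogen-like *link atom* placed at a fixed
fraction rho of the way along the C-alpha -> C-beta vector, and the link
bond is kept near its ideal length r0 by a harmonic correction potential

    E(r) = k_L * (r - r0)^2          (force-field convention, no 1/2)

with per-residue-type parameters {rho, r0, k_L} tabulated for a triple-zeta
(TZ) and a double-zeta (DZ) basis set. Electrostatic embedding feeds the MM
point charges into the QM Hamiltonian after scaling them by a fixed factor
(default 0.666) that compensates the over-polarised charges of fixed-charge
force fields — it maps a TIP3P water oxygen from -0.83 e to the -0.55 e a
bulk QM calculation assigns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mdinteract.errors import ConfigurationError
from mdinteract.structure_io import Selection, Trajectory, select

__all__ = [
    "LinkBondParams",
    "EmbeddingConfig",
    "PointChargeSet",
    "LINK_BOND_TABLE",
    "lookup_link_params",
    "place_link_atom",
    "link_correction",
    "scale_charge",
    "export_embedding_charges",
]


@dataclass(frozen=True)
class LinkBondParams:
    """Ideal link-atom placement ratio and harmonic correction parameters.

    rho is the dimensionless C-alpha -> C-beta distance ratio at which the
    link atom sits; r0 (A) and kL (kcal/mol/A^2) are the minimum and force
    constant of the harmonic link-bond correction.
    """

    residue_type: str
    basis: str
    rho: float
    r0: float
    kL: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly between 0 and 1")
        if self.r0 <= 0 or self.kL <= 0:
            raise ValueError("r0 and kL must be positive")


# (residue_type, basis) -> (rho, r0 [A], kL [kcal/mol/A^2]).
# Residue types: Hid/Hie = delta-/epsilon-protonated histidine, Glu, Asp,
# ROB1/ROB2 = the ligand's first and second link bond.
LINK_BOND_TABLE: dict[tuple[str, str], tuple[float, float, float]] = {
    ("Hid", "TZ"): (0.7140, 1.560, 139.056),
    ("Hid", "DZ"): (0.7226, 1.564, 143.739),
    ("Hie", "TZ"): (0.7155, 1.561, 145.779),
    ("Hie", "DZ"): (0.7257, 1.561, 176.663),
    ("Glu", "TZ"): (0.7241, 1.547, 170.580),
    ("Glu", "DZ"): (0.7289, 1.554, 187.240),
    ("Asp", "TZ"): (0.7251, 1.543, 145.051),
    ("Asp", "DZ"): (0.7223, 1.548, 127.987),
    ("ROB1", "TZ"): (0.7363, 1.507, 235.182),
    ("ROB1", "DZ"): (0.7435, 1.514, 242.270),
    ("ROB2", "TZ"): (0.7332, 1.515, 240.882),
    ("ROB2", "DZ"): (0.7395, 1.519, 245.840),
}


@dataclass(frozen=True)
class EmbeddingConfig:
    """Electrostatic-embedding settings: scale factor, QM region, precision."""

    scale_factor: float = 0.666
    qm_selection: Selection | None = None
    decimals: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.scale_factor <= 1.0:
            raise ValueError("scale_factor must lie in (0, 1]")


@dataclass(frozen=True)
class PointChargeSet:
    """MM point charges (already scaled) with their coordinates."""

    coordinates: np.ndarray  # (n, 3) A
    charges: np.ndarray  # (n,) e

    def __len__(self) -> int:
        return len(self.charges)


def lookup_link_params(residue_type: str, basis: str) -> LinkBondParams:
    """Link-bond parameter row for a residue type and basis-set tag."""
    key = (residue_type, basis)
    if key not in LINK_BOND_TABLE:
        valid = sorted({t for t, _ in LINK_BOND_TABLE}), sorted({b for _, b in LINK_BOND_TABLE})
        raise ConfigurationError(
            f"no link-bond parameters for ({residue_type!r}, {basis!r}); "
            f"valid residue types {valid[0]}, bases {valid[1]}"
        )
    rho, r0, kL = LINK_BOND_TABLE[key]
    return LinkBondParams(residue_type=residue_type, basis=basis, rho=rho, r0=r0, kL=kL)


def place_link_atom(c_alpha, c_beta, rho: float) -> np.ndarray:
    """Link-atom position at fraction ``rho`` along C-alpha -> C-beta."""
    a = np.asarray(c_alpha, dtype=float)
    b = np.asarray(c_beta, dtype=float)
    if np.allclose(a, b):
        raise ValueError("C-alpha and C-beta coincide; link-atom direction undefined")
    return a + rho * (b - a)


def link_correction(
    r: float, params: LinkBondParams, half_factor: bool = False
) -> tuple[float, float]:
    """Harmonic link-bond correction energy and restoring-force magnitude.

    Returns ``(E, |dE/dr|)`` in kcal/mol and kcal/mol/A; the force is
    directed toward r0. ``half_factor=True`` switches to the E = 1/2 k dr^2
    convention.
    """
    if r <= 0:
        raise ValueError("link-bond length must be positive")
    k = 0.5 * params.kL if half_factor else params.kL
    dr = r - params.r0
    return k * dr * dr, 2.0 * k * abs(dr)


def scale_charge(raw_charge: float, config: EmbeddingConfig = EmbeddingConfig()) -> float:
    """Embedding charge: raw MM charge times the global scale factor."""
    if not np.isfinite(raw_charge):
        raise ValueError("charge must be finite")
    return raw_charge * config.scale_factor


def export_embedding_charges(
    frame: np.ndarray,
    mm_atoms: Sequence[int],
    raw_charges: Sequence[float],
    config: EmbeddingConfig = EmbeddingConfig(),
    path: str | Path | None = None,
    qm_atoms: Sequence[int] = (),
) -> PointChargeSet:
    """Scaled MM point charges for electrostatic embedding, optionally to file.

    ``raw_charges`` carries one force-field charge per atom in ``mm_atoms``
    (matched by position). Atoms also present in ``qm_atoms`` are excluded —
    the QM region must not see itself as point charges. The file format is
    whitespace-delimited ``x y z q`` rows (A, e) at the configured decimal
    precision.
    """
    frame = np.asarray(frame, dtype=float)
    mm = np.asarray(list(mm_atoms), dtype=int)
    q = np.asarray(list(raw_charges), dtype=float)
    if mm.shape[0] != q.shape[0]:
        raise ValueError(
            f"{mm.shape[0]} MM atoms but {q.shape[0]} raw charges supplied"
        )
    qm = set(int(i) for i in qm_atoms)
    keep = np.asarray([k for k, i in enumerate(mm) if int(i) not in qm], dtype=int)
    coords = frame[mm[keep]] if keep.size else np.empty((0, 3))
    scaled = q[keep] * config.scale_factor if keep.size else np.empty(0)
    result = PointChargeSet(coordinates=coords, charges=scaled)
    if path is not None:
        fmt = f"%.{config.decimals}f"
        lines = [
            " ".join(fmt % v for v in (*xyz, charge))
            for xyz, charge in zip(result.coordinates, result.charges)
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return result
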