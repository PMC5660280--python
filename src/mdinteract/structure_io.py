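"""Multi-model PDB input/output and atom selection.

The internal model separates a *topology* (atom identities, taken from the
first model of a PDB file) from per-frame coordinate arrays, so that a
multi-model PDB maps onto one :class:`Trajectory`. Coordinates are always in
Angstrom and residue numbering is kept verbatim from the file — analyses
refer to residues by their original numbering (e.g. E177, H141 in a Sonic
Hedgehog system). Waters and ions (HOH, ZN, CA, CL) are ordinary residues;
nothing is special-cased at parse time.

Out of scope by design: mmCIF, binary trajectory formats, alternate
locations and insertion codes.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path

import numpy as np

from mdinteract.errors import FormatError, SelectionError, TopologyError

__all__ = [
    "AtomRecord",
    "Trajectory",
    "Selection",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select",
]

#: Atom-name tokens that always denote a two-letter element, regardless of
#: residue context.
_TWO_LETTER_ELEMENTS = {"ZN", "CL", "BR", "FE", "MG", "MN", "CU", "SE"}

#: Tokens that are two-letter elements only inside the matching monatomic-ion
#: residue; in an amino acid "CA" is the alpha carbon and "NA" is a nitrogen.
_ION_RESIDUE_ELEMENTS = {("CA", "CA"): "Ca", ("NA", "NA"): "Na", ("K", "K"): "K"}

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one topology atom (coordinates live in the frames)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str = "A"
    coordinates: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} ({self.name}): empty element")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.serial} ({self.name}): non-finite coordinates")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


class Trajectory:
    """Ordered coordinate frames sharing one topology.

    Parameters
    ----------
    topology:
        Ordered atom records; their embedded coordinates are ignored in
        favour of ``frames``.
    frames:
        Sequence of ``(n_atoms, 3)`` coordinate arrays in Angstrom.
    frame_spacing:
        Optional time per frame in picoseconds (metadata only).
    """

    def __init__(
        self,
        topology: Sequence[AtomRecord],
        frames: Sequence[np.ndarray],
        frame_spacing: float | None = None,
    ) -> None:
        self.topology: list[AtomRecord] = list(topology)
        if len(frames) == 0:
            raise ValueError("a Trajectory needs at least one frame")
        coords = []
        for i, f in enumerate(frames):
            arr = np.asarray(f, dtype=float)
            if arr.shape != (len(self.topology), 3):
                raise TopologyError(
                    f"frame {i}: expected {(len(self.topology), 3)} coordinates, "
                    f"got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"frame {i}: non-finite coordinates")
            coords.append(arr)
        self.frames: np.ndarray = np.stack(coords)  # (n_frames, n_atoms, 3)
        self.frame_spacing = frame_spacing

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame(self, index: int) -> np.ndarray:
        """Coordinates of one frame, ``(n_atoms, 3)``."""
        return self.frames[index]

    def subset(self, indices: Iterable[int]) -> "Trajectory":
        """New trajectory restricted to the given topology indices (order kept)."""
        idx = np.asarray(list(indices), dtype=int)
        topo = [self.topology[i] for i in idx]
        return Trajectory(topo, self.frames[:, idx, :], self.frame_spacing)


@dataclass(frozen=True)
class Selection:
    """Declarative atom selection; all given conditions are ANDed.

    Each field accepts a single value or a collection of admissible values;
    ``heavy=True`` restricts to non-hydrogen atoms. Resolution is
    deterministic and preserves topology order; an empty result is valid.
    """

    residue_number: int | Sequence[int] | None = None
    residue_name: str | Sequence[str] | None = None
    atom_name: str | Sequence[str] | None = None
    element: str | Sequence[str] | None = None
    heavy: bool | None = None
    serial: int | Sequence[int] | None = None

    @staticmethod
    def from_dict(spec: dict) -> "Selection":
        known = {f.name for f in dataclass_fields(Selection)}
        unknown = set(spec) - known
        if unknown:
            raise SelectionError(
                f"unknown selection field(s) {sorted(unknown)}; valid fields: {sorted(known)}"
            )
        return Selection(**spec)

    def resolve(self, topology: Sequence[AtomRecord]) -> np.ndarray:
        """Indices of matching atoms, in topology order."""

        def as_set(value, upper=False):
            if value is None:
                return None
            vals = [value] if isinstance(value, (str, int)) else list(value)
            return {v.upper() if upper and isinstance(v, str) else v for v in vals}

        resnums = as_set(self.residue_number)
        resnames = as_set(self.residue_name, upper=True)
        names = as_set(self.atom_name, upper=True)
        elements = as_set(self.element, upper=True)
        serials = as_set(self.serial)

        hits = []
        for i, atom in enumerate(topology):
            if resnums is not None and atom.residue_number not in resnums:
                continue
            if resnames is not None and atom.residue_name.upper() not in resnames:
                continue
            if names is not None and atom.name.upper() not in names:
                continue
            if elements is not None and atom.element.upper() not in elements:
                continue
            if serials is not None and atom.serial not in serials:
                continue
            if self.heavy is not None and atom.is_heavy != self.heavy:
                continue
            hits.append(i)
        return np.asarray(hits, dtype=int)


def select(trajectory: Trajectory, expression: Selection | dict) -> np.ndarray:
    """Resolve ``expression`` against the trajectory topology."""
    if isinstance(expression, dict):
        expression = Selection.from_dict(expression)
    return expression.resolve(trajectory.topology)


def infer_element(atom_name: str, residue_name: str) -> str:
    """Element from a PDB atom name when the element column is absent.

    Strips digits, takes the leading alphabetic token, and disambiguates
    two-letter elements against C/N with a fixed lookup; ``CA``/``NA`` are
    read as calcium/sodium only inside the matching ion residue.
    """
    token = "".join(c for c in atom_name.strip() if not c.isdigit()).upper()
    token = token.lstrip("'\"")
    if not token:
        raise FormatError(f"cannot infer element from atom name {atom_name!r}")
    res = residue_name.strip().upper()
    two = token[:2]
    if two in _TWO_LETTER_ELEMENTS:
        return two.capitalize()
    ion = _ION_RESIDUE_ELEMENTS.get((two, res))
    if ion is not None:
        return ion
    return token[0].upper()


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip() or "A"
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"line {lineno}: unparseable ATOM/HETATM record: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name, residue_name)
    else:
        element = element.capitalize()
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain_id=chain_id,
        coordinates=(x, y, z),
    )


def read_multimodel_pdb(path: str | Path, frame_spacing: float | None = None) -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    The topology is taken from the first model; subsequent models are
    matched by record order and must contain the same number of atoms.
    A file without MODEL records yields a single-frame trajectory.
    """
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    saw_model_record = False

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model_record = True
                if in_model:
                    raise FormatError(f"line {lineno}: nested MODEL record")
                in_model = True
                current = []
            elif record == "ENDMDL":
                if not in_model:
                    raise FormatError(f"line {lineno}: ENDMDL without MODEL")
                models.append(current)
                in_model = False
            elif record in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if in_model:
        raise FormatError(f"{path.name}: MODEL record not closed by ENDMDL")
    if not saw_model_record:
        models = [current]
    if not models or not models[0]:
        raise FormatError(f"{path.name}: no atom records found")

    topology = models[0]
    n = len(topology)
    frames = []
    for m, atoms in enumerate(models, start=1):
        if len(atoms) != n:
            raise TopologyError(
                f"model {m} has {len(atoms)} atoms but model 1 has {n}"
            )
        frames.append(np.array([a.coordinates for a in atoms], dtype=float))
    return Trajectory(topology, frames, frame_spacing=frame_spacing)


def _format_atom_name(name: str, element: str) -> str:
    # Standard PDB alignment: one-letter-element names start in column 14,
    # two-letter elements and 4-character names fill columns 13-16.
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4.4s}"
    return f" {name:<3.3s}"


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write the trajectory as a MODEL/ENDMDL multi-model PDB.

    Round-tripping through :func:`read_multimodel_pdb` preserves identities
    exactly and coordinates to the format's 0.001 A precision.
    """
    if not isinstance(trajectory, Trajectory):
        raise TypeError("write_multimodel_pdb expects a Trajectory")
    path = Path(path)
    lines: list[str] = []
    for f in range(trajectory.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        coords = trajectory.frames[f]
        for atom, (x, y, z) in zip(trajectory.topology, coords):
            for v, axis in ((x, "x"), (y, "y"), (z, "z")):
                if not -999.999 <= v <= 9999.999:
                    raise FormatError(
                        f"atom {atom.serial}: {axis}={v:.3f} A does not fit the "
                        "fixed-width %8.3f PDB coordinate field"
                    )
            lines.append(
                f"ATOM  {atom.serial % 100000:5d} {_format_atom_name(atom.name, atom.element)}"
                f" {atom.residue_name:<3.3s} {atom.chain_id:1.1s}"
                f"{atom.residue_number % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2.2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def sidechain_heavy_indices(topology: Sequence[AtomRecord], residue_number: int) -> np.ndarray:
    """Heavy sidechain atoms of one residue (backbone N/CA/C/O/OXT excluded)."""
    hits = [
        i
        for i, a in enumerate(topology)
        if a.residue_number == residue_number
        and a.is_heavy
        and a.name.upper() not in _BACKBONE_NAMES
    ]
    return np.asarray(hits, dtype=int)
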