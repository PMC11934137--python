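"""Molecular geometries: XYZ input/output and van der Waals radii.

Coordinate conventions for the whole package live here.  Atom indices are
0-based internally; functions that accept user-facing atom selections take an
``one_based`` flag because chemistry tooling conventionally prints 1-based
indices.  Element symbols are case-normalized on input ("CL" -> "Cl").
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "RadiiTable",
    "XYZParseError",
    "UnknownElementError",
    "normalize_element",
    "read_xyz",
    "write_xyz",
    "vdw_radius",
]

PathOrStream = Union[str, "io.IOBase", TextIO]


class XYZParseError(ValueError):
    """Malformed XYZ input; message carries the 1-based line number."""


class UnknownElementError(KeyError):
    """Element symbol absent from the active van der Waals radii table."""

    def __init__(self, element: str, provenance: str):
        super().__init__(element)
        self.element = element
        self.provenance = provenance

    def __str__(self) -> str:  # pragma: no cover - trivial formatting
        return (
            f"element {self.element!r} is not in the radii table "
            f"({self.provenance}); supply a custom table with this element"
        )


def normalize_element(symbol: str) -> str:
    """Case-normalize an element symbol ("CL" -> "Cl", "h" -> "H")."""
    s = symbol.strip()
    if not s:
        raise ValueError("empty element symbol")
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class Atom:
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "element", normalize_element(self.element))
        for c in (self.x, self.y, self.z):
            if not math.isfinite(c):
                raise ValueError(f"non-finite coordinate in atom {self.element}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Molecule:
    """An ordered list of atoms plus optional named atom annotations.

    ``annotations`` maps role names (``metal_center``, ``attach_atom``,
    ``substituent_root``) to 0-based atom indices.
    """

    atoms: list[Atom]
    title: str = ""
    annotations: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("a Molecule needs at least one atom")
        for name, idx in self.annotations.items():
            if not 0 <= idx < len(self.atoms):
                raise ValueError(
                    f"annotation {name!r} index {idx} out of range "
                    f"for {len(self.atoms)} atoms"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) array of Cartesian coordinates in Angstrom."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class RadiiTable:
    """Van der Waals radii (Angstrom) with a mandatory provenance label.

    Lookup of an element missing from the table raises
    :class:`UnknownElementError` -- never a silent default, because a wrong
    radius silently corrupts every steric descriptor downstream.
    """

    radii: Mapping[str, float]
    provenance: str

    def __post_init__(self) -> None:
        bad = {el: r for el, r in self.radii.items() if not r > 0}
        if bad:
            raise ValueError(f"non-positive radii: {bad}")

    def radius(self, element: str) -> float:
        el = normalize_element(element)
        try:
            return self.radii[el]
        except KeyError:
            raise UnknownElementError(el, self.provenance) from None

    @classmethod
    def from_csv(cls, path_or_stream: PathOrStream, provenance: str) -> "RadiiTable":
        close, fh = _open_for_read(path_or_stream)
        try:
            radii: dict[str, float] = {}
            header = fh.readline()
            if "element" not in header:
                raise ValueError("radii CSV must start with an 'element,...' header")
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                el, val = line.split(",")[:2]
                radii[normalize_element(el)] = float(val)
        finally:
            if close:
                fh.close()
        return cls(radii=radii, provenance=provenance)

    @classmethod
    def bondi(cls) -> "RadiiTable":
        """The Bondi (1964) van der Waals radii set, the package default."""
        ref = resources.files("qssr.data").joinpath("bondi_radii.csv")
        with ref.open("r") as fh:
            return cls.from_csv(fh, provenance="Bondi-1964")


def vdw_radius(element: str, table: RadiiTable | None = None) -> float:
    """Van der Waals radius in Angstrom; errors on unknown symbols."""
    if table is None:
        table = RadiiTable.bondi()
    return table.radius(element)


def _open_for_read(path_or_stream: PathOrStream) -> tuple[bool, TextIO]:
    if hasattr(path_or_stream, "read"):
        return False, path_or_stream  # type: ignore[return-value]
    return True, open(path_or_stream, "r")


def _open_for_write(path_or_stream: PathOrStream) -> tuple[bool, TextIO]:
    if hasattr(path_or_stream, "write"):
        return False, path_or_stream  # type: ignore[return-value]
    return True, open(path_or_stream, "w")


ANNOTATION_KEYS = ("metal_center", "attach_atom", "substituent_root")


def _parse_comment(comment: str) -> tuple[str, dict[str, int]]:
    """Split a comment line into the free-text title and role annotations.

    Recognized tokens look like ``metal_center=1`` with 1-based atom indices
    (the convention chemistry tools print); anything else stays in the title.
    """
    title_parts: list[str] = []
    annotations: dict[str, int] = {}
    for tok in comment.split():
        key, sep, val = tok.partition("=")
        if sep and key in ANNOTATION_KEYS:
            try:
                annotations[key] = int(val) - 1
                continue
            except ValueError:
                pass
        title_parts.append(tok)
    return " ".join(title_parts), annotations


def read_xyz(path_or_stream: PathOrStream) -> list[Molecule]:
    """Read a (multi-frame) XYZ file into a list of Molecules.

    Frames are concatenated standard XYZ blocks: an atom count line, a free
    text comment line (stored as the molecule title), then one
    ``element x y z`` line per atom.  ``key=index`` tokens on the comment
    line for the recognized atom roles (``metal_center``, ``attach_atom``,
    ``substituent_root``; 1-based in the file) are parsed into the molecule's
    annotations.  Parsing is locale-independent (decimal point only).
    Errors name the offending 1-based line number.
    """
    close, fh = _open_for_read(path_or_stream)
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()

    molecules: list[Molecule] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():  # tolerate blank separator lines
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if n_atoms < 1:
            raise XYZParseError(f"line {i + 1}: atom count must be >= 1")
        if i + 1 + n_atoms >= n_lines + 1 and i + 1 >= n_lines:
            raise XYZParseError(f"line {i + 1}: truncated frame (missing comment line)")
        title = lines[i + 1] if i + 1 < n_lines else ""
        atoms: list[Atom] = []
        for k in range(n_atoms):
            ln = i + 2 + k
            if ln >= n_lines:
                raise XYZParseError(
                    f"line {ln + 1}: truncated frame "
                    f"(expected {n_atoms} atoms, got {k})"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"line {ln + 1}: expected 'element x y z', got {lines[ln]!r}"
                )
            try:
                atoms.append(
                    Atom(parts[0], float(parts[1]), float(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise XYZParseError(f"line {ln + 1}: {exc}") from None
        text, annotations = _parse_comment(title)
        molecules.append(Molecule(atoms=atoms, title=text, annotations=annotations))
        i += 2 + n_atoms
    return molecules


def write_xyz(
    molecules: Iterable[Molecule],
    path_or_stream: PathOrStream,
    decimals: int = 8,
) -> None:
    """Write molecules as concatenated XYZ frames.

    Formatting is bit-stable: fixed ``decimals`` decimal places (default 8,
    comfortably below the 1e-6 Angstrom round-trip contract), so text diffs
    of output files are meaningful.  Atom-role annotations are serialized as
    1-based ``key=index`` tokens on the comment line and survive a round trip.
    """
    close, fh = _open_for_write(path_or_stream)
    try:
        for mol in molecules:
            fh.write(f"{len(mol.atoms)}\n")
            comment = mol.title
            tokens = " ".join(
                f"{k}={v + 1}" for k, v in sorted(mol.annotations.items())
            )
            if tokens:
                comment = f"{comment} {tokens}".strip()
            fh.write(f"{comment}\n")
            for a in mol.atoms:
                fh.write(
                    f"{a.element:<3s} {a.x:> {decimals + 6}.{decimals}f}"
                    f" {a.y:> {decimals + 6}.{decimals}f}"
                    f" {a.z:> {decimals + 6}.{decimals}f}\n"
                )
    finally:
        if close:
            fh.close()


def parse_atom_index(index: int, n_atoms: int, one_based: bool = False) -> int:
    """Convert a user-facing atom index to the internal 0-based convention."""
    idx = index - 1 if one_based else index
    if not 0 <= idx < n_atoms:
        raise IndexError(
            f"atom index {index} ({'1' if one_based else '0'}-based) out of "
            f"range for {n_atoms} atoms"
        )
    return idx
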