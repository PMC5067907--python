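"""Molecules, parameter sets and charge sets, and their on-disk formats.

Molecule input is MDL SDF (V2000 molfiles concatenated with ``$$$$``); this is
the only structure format supported.  Reference charges use a simple
plain-text block format and parameter sets a JSON dialect; both are this
package's own documented formats (see the format notes in the docstrings of
:func:`read_charges` and :func:`read_parameter_set`).

An *atom type* is the combination of element symbol and the maximal bond
order of the atom: ``N3`` is a nitrogen with at least one triple bond, ``C1``
a carbon with only single bonds.  A and B parameters are defined at this
granularity; kappa is global.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import numpy as np

from .errors import (
    AtomTypingError,
    ChargeFileError,
    ParameterFileError,
    SdfParseError,
)

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "ParameterSet",
    "ChargeSet",
    "parse_sdf",
    "read_sdf",
    "write_sdf",
    "assign_atom_types",
    "read_charges",
    "write_charges",
    "read_parameter_set",
    "write_parameter_set",
]

# IUPAC element symbols, H..Og.  Matched case-sensitively.
ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)


@dataclass
class Atom:
    """One atom: element, Cartesian coordinates in Angstrom, formal charge.

    ``max_bond_order`` and ``atom_type`` are unset until
    :func:`assign_atom_types` has run on the parent molecule.
    """

    element: str
    x: float
    y: float
    z: float
    formal_charge: int = 0
    max_bond_order: int | None = None
    atom_type: str | None = None

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Bond:
    """A bond between two atoms, referenced by 1-based indices."""

    i: int
    j: int
    order: int


@dataclass
class Molecule:
    name: str
    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    #: Optional real-valued override of Q for inputs lacking M CHG lines.
    total_charge_override: float | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def total_charge(self) -> float:
        """Total charge Q: the sum of formal charges, unless overridden."""
        if self.total_charge_override is not None:
            return self.total_charge_override
        return sum(a.formal_charge for a in self.atoms)

    def coordinates(self) -> np.ndarray:
        """(N, 3) coordinate array in Angstrom."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def atom_types(self) -> list[str]:
        if any(a.atom_type is None for a in self.atoms):
            raise AtomTypingError(
                f"molecule {self.name!r}: atom types not assigned; "
                "call assign_atom_types first"
            )
        return [a.atom_type for a in self.atoms]  # type: ignore[misc]


@dataclass
class ParameterSet:
    """EEM empirical parameters: global kappa plus (A, B) per atom type.

    A is the electronegativity-like offset of the type, B its hardness-like
    self-interaction, kappa the global distance-coupling scale of the
    off-diagonal kappa/R terms.  ``qm_label`` records which reference charge
    scheme the set was calibrated against (e.g. "B3LYP/6-311G/NPA").
    """

    name: str = ""
    qm_label: str = ""
    kappa: float = 0.0
    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def atom_types(self) -> list[str]:
        return sorted(self.entries)

    def a(self, atom_type: str) -> float:
        return self.entries[atom_type][0]

    def b(self, atom_type: str) -> float:
        return self.entries[atom_type][1]

    def covers(self, molecule: Molecule) -> bool:
        return all(t in self.entries for t in molecule.atom_types())

    def missing_types(self, molecule: Molecule) -> list[str]:
        """Atom types of *molecule* absent from this set, sorted, unique."""
        return sorted({t for t in molecule.atom_types() if t not in self.entries})

    def validate(self) -> None:
        if not (self.kappa > 0):
            raise ParameterFileError(f"kappa must be > 0, got {self.kappa}")
        for t, (_, b) in self.entries.items():
            if not (b > 0):
                raise ParameterFileError(f"atom type {t!r}: B must be > 0, got {b}")


# Per-molecule charge vectors keyed by molecule name, aligned to atom order.
class ChargeSet(dict):
    """Mapping molecule name -> numpy vector of per-atom charges (e units)."""

    def __setitem__(self, key: str, value) -> None:
        super().__setitem__(key, np.asarray(value, dtype=float))

    def vector_for(self, molecule: Molecule) -> np.ndarray:
        try:
            q = self[molecule.name]
        except KeyError:
            raise ChargeFileError(f"no charges for molecule {molecule.name!r}")
        if len(q) != molecule.n_atoms:
            raise ChargeFileError(
                f"molecule {molecule.name!r}: charge vector has {len(q)} "
                f"entries but the molecule has {molecule.n_atoms} atoms"
            )
        return q


# ---------------------------------------------------------------------------
# SDF V2000
# ---------------------------------------------------------------------------

def _parse_int(text: str, record: int, lineno: int, what: str) -> int:
    try:
        return int(text.strip())
    except ValueError:
        raise SdfParseError(
            f"record {record}, line {lineno}: unreadable {what}: {text.strip()!r}"
        ) from None


def _parse_float(text: str, record: int, lineno: int, what: str) -> float:
    try:
        value = float(text.strip())
    except ValueError:
        raise SdfParseError(
            f"record {record}, line {lineno}: unreadable {what}: {text.strip()!r}"
        ) from None
    if not math.isfinite(value):
        raise SdfParseError(f"record {record}, line {lineno}: non-finite {what}")
    return value


def parse_sdf(stream: IO[str] | Iterable[str]) -> list[Molecule]:
    """Parse a concatenation of V2000 molfile records delimited by ``$$$$``.

    Coordinates come from the atom block, bond orders from the bond block and
    formal charges from ``M  CHG`` property lines (their absence means every
    formal charge is 0; the deprecated per-atom charge column of the atom
    block is ignored).  Molecules retain file order.  Error messages name the
    offending record index (1-based) and line number.
    """
    lines = [ln.rstrip("\n") for ln in stream]
    molecules: list[Molecule] = []
    pos = 0
    record = 0
    while pos < len(lines):
        # skip trailing blank lines between records / at EOF
        if not any(ln.strip() for ln in lines[pos:]):
            break
        record += 1
        start = pos
        if len(lines) - start < 4:
            raise SdfParseError(f"record {record}: truncated header block")
        name = lines[start].strip() or f"MOL{record}"
        counts_lineno = start + 4  # 1-based line number of the counts line
        counts = lines[start + 3]
        version = counts[33:39].strip() if len(counts) >= 34 else ""
        if version != "V2000":
            raise SdfParseError(
                f"record {record}, line {counts_lineno}: expected V2000 "
                f"version tag, got {version!r} (V3000 records are not supported)"
            )
        n_atoms = _parse_int(counts[0:3], record, counts_lineno, "atom count")
        n_bonds = _parse_int(counts[3:6], record, counts_lineno, "bond count")
        if n_atoms < 1:
            raise SdfParseError(
                f"record {record}, line {counts_lineno}: atom count must be >= 1"
            )

        atoms: list[Atom] = []
        for k in range(n_atoms):
            lineno = counts_lineno + 1 + k
            if lineno - 1 >= len(lines):
                raise SdfParseError(f"record {record}: truncated atom block")
            ln = lines[lineno - 1]
            x = _parse_float(ln[0:10], record, lineno, "x coordinate")
            y = _parse_float(ln[10:20], record, lineno, "y coordinate")
            z = _parse_float(ln[20:30], record, lineno, "z coordinate")
            element = ln[31:34].strip()
            if element not in ELEMENTS:
                raise SdfParseError(
                    f"record {record}, line {lineno}: unknown element "
                    f"symbol {element!r}"
                )
            atoms.append(Atom(element=element, x=x, y=y, z=z))

        bonds: list[Bond] = []
        for k in range(n_bonds):
            lineno = counts_lineno + 1 + n_atoms + k
            if lineno - 1 >= len(lines):
                raise SdfParseError(f"record {record}: truncated bond block")
            ln = lines[lineno - 1]
            i = _parse_int(ln[0:3], record, lineno, "bond atom index")
            j = _parse_int(ln[3:6], record, lineno, "bond atom index")
            order = _parse_int(ln[6:9], record, lineno, "bond order")
            if not (1 <= i <= n_atoms and 1 <= j <= n_atoms):
                raise SdfParseError(
                    f"record {record}, line {lineno}: bond index out of "
                    f"range ({i}, {j}) for {n_atoms} atoms"
                )
            if i == j:
                raise SdfParseError(
                    f"record {record}, line {lineno}: bond joins atom {i} to itself"
                )
            bonds.append(Bond(i=i, j=j, order=order))

        # property block up to M  END, then data items up to $$$$
        pos = counts_lineno + n_atoms + n_bonds
        saw_end = False
        while pos < len(lines):
            ln = lines[pos]
            pos += 1
            if ln.startswith("M  END"):
                saw_end = True
                break
            if ln.startswith("M  CHG"):
                fields = ln.split()
                try:
                    count = int(fields[2])
                    pairs = [int(f) for f in fields[3:]]
                except (IndexError, ValueError):
                    raise SdfParseError(
                        f"record {record}, line {pos}: malformed M  CHG line"
                    ) from None
                if len(pairs) != 2 * count:
                    raise SdfParseError(
                        f"record {record}, line {pos}: M  CHG declares "
                        f"{count} pairs but carries {len(pairs) // 2}"
                    )
                for idx, chg in zip(pairs[0::2], pairs[1::2]):
                    if not (1 <= idx <= n_atoms):
                        raise SdfParseError(
                            f"record {record}, line {pos}: M  CHG atom index "
                            f"{idx} out of range"
                        )
                    atoms[idx - 1].formal_charge = chg
        if not saw_end:
            raise SdfParseError(f"record {record}: missing M  END line")
        while pos < len(lines) and lines[pos].strip() != "$$$$":
            pos += 1
        pos += 1  # past $$$$ (or EOF)

        molecules.append(Molecule(name=name, atoms=atoms, bonds=bonds))
    return molecules


def read_sdf(path: str | os.PathLike) -> list[Molecule]:
    with open(path) as fh:
        return parse_sdf(fh)


def write_sdf(molecules: Iterable[Molecule], stream: IO[str]) -> None:
    """Write molecules as V2000 molfile records separated by ``$$$$``."""
    for mol in molecules:
        stream.write(f"{mol.name}\n  eemkit\n\n")
        stream.write(f"{mol.n_atoms:3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000\n")
        for a in mol.atoms:
            stream.write(f"{a.x:10.4f}{a.y:10.4f}{a.z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0\n")
        for b in mol.bonds:
            stream.write(f"{b.i:3d}{b.j:3d}{b.order:3d}  0\n")
        charged = [(k + 1, a.formal_charge) for k, a in enumerate(mol.atoms) if a.formal_charge]
        for block_start in range(0, len(charged), 8):  # max 8 pairs per M CHG line
            chunk = charged[block_start:block_start + 8]
            stream.write(f"M  CHG{len(chunk):3d}")
            for idx, chg in chunk:
                stream.write(f" {idx:3d} {chg:3d}")
            stream.write("\n")
        stream.write("M  END\n$$$$\n")


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

def assign_atom_types(molecule: Molecule, map_aromatic: bool = False) -> Molecule:
    """Assign ``max_bond_order`` and ``atom_type`` to every atom, in place.

    The maximal bond order of an atom is the maximum order over its incident
    bonds; an isolated atom gets order 1 by convention.  Aromatic bond order
    4 is rejected in strict mode (the atom-type vocabulary spans orders 1-3);
    with ``map_aromatic=True`` order 4 is mapped to 2.  Returns the molecule.
    """
    orders = [1] * molecule.n_atoms
    for b in molecule.bonds:
        order = b.order
        if order == 4:
            if not map_aromatic:
                raise AtomTypingError(
                    f"molecule {molecule.name!r}: aromatic bond order 4 on "
                    f"bond {b.i}-{b.j}; provide kekulized input or enable "
                    "aromatic mapping (order 4 -> 2)"
                )
            order = 2
        if order not in (1, 2, 3):
            raise AtomTypingError(
                f"molecule {molecule.name!r}: unsupported bond order "
                f"{b.order} on bond {b.i}-{b.j}"
            )
        orders[b.i - 1] = max(orders[b.i - 1], order)
        orders[b.j - 1] = max(orders[b.j - 1], order)
    for atom, order in zip(molecule.atoms, orders):
        atom.max_bond_order = order
        atom.atom_type = f"{atom.element}{order}"
    return molecule


def dataset_atom_types(molecules: Iterable[Molecule]) -> list[str]:
    """Sorted union of atom types over a collection of typed molecules."""
    types: set[str] = set()
    for mol in molecules:
        types.update(mol.atom_types())
    return sorted(types)


# ---------------------------------------------------------------------------
# Reference-charge files
# ---------------------------------------------------------------------------

def read_charges(stream: IO[str] | Iterable[str]) -> ChargeSet:
    """Read the plain-text charge format.

    One block per molecule: line 1 the molecule name, line 2 the atom count
    N, then N lines ``<1-based index> <element> <charge>``; blocks separated
    by a blank line.  The element column is informational.
    """
    charges = ChargeSet()
    lines = [ln.rstrip("\n") for ln in stream]
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        name = lines[pos].strip()
        if name in charges:
            raise ChargeFileError(f"line {pos + 1}: duplicate molecule name {name!r}")
        if pos + 1 >= len(lines):
            raise ChargeFileError(f"line {pos + 1}: block {name!r} missing atom count")
        try:
            n = int(lines[pos + 1].strip())
        except ValueError:
            raise ChargeFileError(
                f"line {pos + 2}: unreadable atom count {lines[pos + 1].strip()!r}"
            ) from None
        vec = np.empty(n, dtype=float)
        for k in range(n):
            lineno = pos + 2 + k
            if lineno >= len(lines) or not lines[lineno].strip():
                raise ChargeFileError(
                    f"block {name!r}: declares {n} atoms but has {k} charge lines"
                )
            fields = lines[lineno].split()
            if len(fields) != 3:
                raise ChargeFileError(
                    f"line {lineno + 1}: expected '<index> <element> <charge>', "
                    f"got {lines[lineno]!r}"
                )
            try:
                idx = int(fields[0])
                value = float(fields[2])
            except ValueError:
                raise ChargeFileError(
                    f"line {lineno + 1}: non-numeric index or charge in "
                    f"{lines[lineno]!r}"
                ) from None
            if not (1 <= idx <= n):
                raise ChargeFileError(
                    f"line {lineno + 1}: atom index {idx} out of range 1..{n}"
                )
            vec[idx - 1] = value
        tail = pos + 2 + n
        if tail < len(lines) and lines[tail].strip():
            raise ChargeFileError(
                f"block {name!r}: declares {n} atoms but more charge lines follow"
            )
        charges[name] = vec
        pos = tail + 1
    return charges


def write_charges(
    charges: Mapping[str, np.ndarray],
    stream: IO[str],
    molecules: Iterable[Molecule] | None = None,
) -> None:
    """Write charges in the plain-text block format (see :func:`read_charges`).

    If *molecules* is given, element symbols are taken from them and block
    order follows molecule order; otherwise elements are written as ``X``.
    """
    if molecules is not None:
        items: Iterator[tuple[str, np.ndarray, list[str]]] = (
            (m.name, np.asarray(charges[m.name]), [a.element for a in m.atoms])
            for m in molecules
            if m.name in charges
        )
    else:
        items = ((name, np.asarray(vec), ["X"] * len(vec)) for name, vec in charges.items())
    first = True
    for name, vec, elements in items:
        if not first:
            stream.write("\n")
        first = False
        stream.write(f"{name}\n{len(vec)}\n")
        for k, (el, q) in enumerate(zip(elements, vec), start=1):
            stream.write(f"{k} {el} {q:.17g}\n")


# ---------------------------------------------------------------------------
# Parameter-set files (JSON dialect)
# ---------------------------------------------------------------------------

def read_parameter_set(stream: IO[str]) -> ParameterSet:
    """Read the JSON parameter-set dialect.

    ``{"name": ..., "qm_label": ..., "kappa": ...,
    "parameters": [{"element": ..., "order": ..., "A": ..., "B": ...}, ...]}``
    """
    try:
        doc = json.load(stream)
    except json.JSONDecodeError as exc:
        raise ParameterFileError(f"not valid JSON: {exc}") from None
    if "kappa" not in doc:
        raise ParameterFileError("missing required key 'kappa'")
    pset = ParameterSet(
        name=str(doc.get("name", "")),
        qm_label=str(doc.get("qm_label", "")),
        kappa=float(doc["kappa"]),
    )
    for entry in doc.get("parameters", []):
        try:
            atom_type = f"{entry['element']}{int(entry['order'])}"
            a, b = float(entry["A"]), float(entry["B"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ParameterFileError(f"malformed parameter entry {entry!r}: {exc}") from None
        if atom_type in pset.entries:
            raise ParameterFileError(f"duplicate atom type {atom_type!r}")
        pset.entries[atom_type] = (a, b)
    pset.validate()
    return pset


def _split_type(atom_type: str) -> tuple[str, int]:
    element = atom_type.rstrip("0123456789")
    order = atom_type[len(element):]
    if not element or not order:
        raise ParameterFileError(f"cannot split atom type {atom_type!r}")
    return element, int(order)


def write_parameter_set(pset: ParameterSet, stream: IO[str]) -> None:
    """Write the JSON dialect; numbers keep 17 significant digits so a
    write/read round trip is the identity."""
    doc = {
        "name": pset.name,
        "qm_label": pset.qm_label,
        "kappa": pset.kappa,
        "parameters": [
            {
                "element": _split_type(t)[0],
                "order": _split_type(t)[1],
                "A": a,
                "B": b,
            }
            for t, (a, b) in sorted(pset.entries.items())
        ],
    }
    json.dump(doc, stream, indent=2)
    stream.write("\n")
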