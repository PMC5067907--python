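"""Assembly and solution of the EEM linear system.

For a molecule of N atoms the electronegativity equalization method couples
the unknown charges q_1..q_N and the molecular electronegativity chi_bar
through the (N+1)x(N+1) system

    [ B_1        kappa/R_12 ... kappa/R_1N  -1 ] [ q_1 ]   [ -A_1 ]
    [ kappa/R_21 B_2        ... kappa/R_2N  -1 ] [ q_2 ]   [ -A_2 ]
    [ ...                                      ] [ ... ] = [ ...  ]
    [ kappa/R_N1 ...            B_N         -1 ] [ q_N ]   [ -A_N ]
    [ 1          1          ... 1            0 ] [ chi ]   [  Q   ]

where A_t and B_t are per-atom-type parameters, kappa a global coupling
scale, R_ij interatomic distances in Angstrom and Q the total molecular
charge.  Row i states that atom i's effective electronegativity equals the
shared chi_bar; the last row enforces charge conservation.

Charges are invariant under a uniform shift of all A (chi_bar shifts along)
and under joint positive scaling of (A, B, kappa) (chi_bar scales along);
parameters are therefore identifiable only up to these gauges.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg
import scipy.spatial.distance

from .chem_io import ChargeSet, Molecule, ParameterSet
from .errors import DegenerateGeometryError, SingularSystemError, UncoveredMoleculeError

__all__ = [
    "EemSolution",
    "distance_matrix",
    "build_system",
    "solve_charges",
    "calculate_charges",
    "MoleculeSystem",
    "precompute_systems",
    "solve_precomputed",
]

#: Off-diagonal distances below this (Angstrom) are treated as degenerate.
MIN_DISTANCE = 1e-6

#: Residual tolerance above which a solve is declared unreliable.
_RESIDUAL_TOL = 1e-7


@dataclass
class EemSolution:
    """Solved charges plus the molecular electronegativity chi_bar."""

    charges: np.ndarray
    chi_bar: float


def distance_matrix(molecule: Molecule) -> np.ndarray:
    """Symmetric N x N matrix of interatomic Euclidean distances (Angstrom)."""
    coords = molecule.coordinates()
    if not np.isfinite(coords).all():
        raise DegenerateGeometryError(
            f"molecule {molecule.name!r}: non-finite coordinates"
        )
    dist = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(coords)
    )
    if molecule.n_atoms > 1:
        off = dist[~np.eye(molecule.n_atoms, dtype=bool)]
        if off.min() < MIN_DISTANCE:
            masked = np.where(np.eye(molecule.n_atoms, dtype=bool), np.inf, dist)
            i, j = np.unravel_index(np.argmin(masked), dist.shape)
            raise DegenerateGeometryError(
                f"molecule {molecule.name!r}: atoms {i + 1} and {j + 1} are "
                f"{dist[i, j]:.2e} Angstrom apart (< {MIN_DISTANCE:g})"
            )
    return dist


def build_system(
    molecule: Molecule, parameter_set: ParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the (N+1)x(N+1) EEM matrix and right-hand side."""
    types = molecule.atom_types()
    missing = parameter_set.missing_types(molecule)
    if missing:
        raise UncoveredMoleculeError(
            f"molecule {molecule.name!r} is not covered: no parameters for "
            f"atom type(s) {', '.join(missing)}"
        )
    n = molecule.n_atoms
    dist = distance_matrix(molecule)
    matrix = np.zeros((n + 1, n + 1))
    with np.errstate(divide="ignore"):
        inv = np.where(dist > 0, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    matrix[:n, :n] = parameter_set.kappa * inv
    matrix[np.arange(n), np.arange(n)] = [parameter_set.b(t) for t in types]
    matrix[:n, n] = -1.0
    matrix[n, :n] = 1.0
    rhs = np.empty(n + 1)
    rhs[:n] = [-parameter_set.a(t) for t in types]
    rhs[n] = molecule.total_charge
    return matrix, rhs


def _solve_system(matrix: np.ndarray, rhs: np.ndarray, label: str) -> np.ndarray:
    """Solve the bordered EEM system and vet the solution.

    The matrix as laid out above is asymmetric only through the sign of the
    chi column; substituting chi -> -chi makes it symmetric indefinite, so
    an LDL^T-based symmetric solve applies.  A non-finite result or a
    residual inconsistent with a well-conditioned system raises
    SingularSystemError.
    """
    sym = matrix.copy()
    sym[:, -1] *= -1.0
    try:
        x = scipy.linalg.solve(sym, rhs, assume_a="sym", check_finite=False)
        x[-1] *= -1.0
    except (scipy.linalg.LinAlgError, ValueError) as exc:
        raise SingularSystemError(f"{label}: singular EEM system ({exc})") from None
    if not np.isfinite(x).all():
        raise SingularSystemError(f"{label}: non-finite EEM solution")
    scale = 1.0 + np.abs(matrix).max() * np.abs(x).max()
    residual = np.abs(matrix @ x - rhs).max()
    if residual > _RESIDUAL_TOL * scale:
        rcond = 1.0 / np.linalg.cond(matrix, 1)
        raise SingularSystemError(
            f"{label}: unreliable EEM solution (residual {residual:.2e}, "
            f"rcond {rcond:.2e})"
        )
    return x


def solve_charges(molecule: Molecule, parameter_set: ParameterSet) -> EemSolution:
    """Solve the EEM system for one molecule.

    The solution satisfies charge conservation (sum q = Q) and per-atom
    electronegativity equalization to ~1e-8 for well-conditioned systems.
    """
    matrix, rhs = build_system(molecule, parameter_set)
    x = _solve_system(matrix, rhs, f"molecule {molecule.name!r}")
    return EemSolution(charges=x[:-1], chi_bar=float(x[-1]))


def calculate_charges(
    molecules: Sequence[Molecule],
    parameter_set: ParameterSet,
    skip_uncovered: bool = False,
    threads: int = 1,
) -> ChargeSet:
    """EEM charges for a batch of molecules.

    Per-molecule solves are independent and share no mutable state, so the
    thread count is a pure speed knob: results are bit-identical for any
    ``threads`` and ordered by input order.  With ``skip_uncovered`` the
    molecules whose atom types the set does not cover are omitted (and
    reported via the return value's missing names); in strict mode they are
    an error listing every offending molecule.
    """
    if not skip_uncovered:
        uncovered = [m.name for m in molecules if not parameter_set.covers(m)]
        if uncovered:
            raise UncoveredMoleculeError(
                "parameter set does not cover molecule(s): " + ", ".join(uncovered)
            )
    todo = [m for m in molecules if parameter_set.covers(m)]

    def solve_one(mol: Molecule) -> tuple[str, np.ndarray]:
        return mol.name, solve_charges(mol, parameter_set).charges

    charges = ChargeSet()
    if threads > 1 and len(todo) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(solve_one, todo))
    else:
        results = [solve_one(m) for m in todo]
    for name, q in results:
        charges[name] = q
    return charges


# ---------------------------------------------------------------------------
# Precompiled fast path for parameter fitting
# ---------------------------------------------------------------------------
#
# Parameterization evaluates thousands of candidate (kappa, A, B) vectors on
# a fixed training set.  Geometry and typing never change, so the reciprocal
# distance matrix and the per-atom type indices are computed once and charges
# for a candidate are obtained by refilling and solving the dense system.
# The solve routine is the same as the production path above.


@dataclass
class MoleculeSystem:
    """Precomputed per-molecule quantities for repeated candidate solves."""

    name: str
    inv_dist: np.ndarray      # N x N, zero diagonal
    type_index: np.ndarray    # per-atom index into the dataset's sorted types
    total_charge: float
    n_atoms: int


def precompute_systems(
    molecules: Sequence[Molecule], atom_types: Sequence[str]
) -> list[MoleculeSystem]:
    """Precompute distance and typing data against a sorted type vocabulary."""
    index = {t: k for k, t in enumerate(atom_types)}
    systems = []
    for mol in molecules:
        dist = distance_matrix(mol)
        with np.errstate(divide="ignore"):
            inv = np.where(dist > 0, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
        try:
            tidx = np.array([index[t] for t in mol.atom_types()], dtype=np.intp)
        except KeyError as exc:
            raise UncoveredMoleculeError(
                f"molecule {mol.name!r}: atom type {exc.args[0]!r} not in vocabulary"
            ) from None
        systems.append(
            MoleculeSystem(
                name=mol.name,
                inv_dist=inv,
                type_index=tidx,
                total_charge=float(mol.total_charge),
                n_atoms=mol.n_atoms,
            )
        )
    return systems


def solve_precomputed(
    system: MoleculeSystem,
    kappa: float,
    a_by_type: np.ndarray,
    b_by_type: np.ndarray,
) -> EemSolution:
    """Solve one precompiled molecule under candidate parameters.

    ``a_by_type``/``b_by_type`` are indexed by the vocabulary used in
    :func:`precompute_systems`.  Same solve routine as the production path.
    """
    n = system.n_atoms
    matrix = np.zeros((n + 1, n + 1))
    matrix[:n, :n] = kappa * system.inv_dist
    matrix[np.arange(n), np.arange(n)] = b_by_type[system.type_index]
    matrix[:n, n] = -1.0
    matrix[n, :n] = 1.0
    rhs = np.empty(n + 1)
    rhs[:n] = -a_by_type[system.type_index]
    rhs[n] = system.total_charge
    x = _solve_system(matrix, rhs, f"molecule {system.name!r}")
    return EemSolution(charges=x[:-1], chi_bar=float(x[-1]))


def charges_for_parameters(
    systems: Iterable[MoleculeSystem],
    kappa: float,
    a_by_type: np.ndarray,
    b_by_type: np.ndarray,
) -> ChargeSet:
    """Batch :func:`solve_precomputed` into a ChargeSet."""
    out = ChargeSet()
    for system in systems:
        out[system.name] = solve_precomputed(system, kappa, a_by_type, b_by_type).charges
    return out
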