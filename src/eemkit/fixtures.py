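"""Synthetic molecules with self-consistent reference charges.

Real EEM calibration data are 3D structures plus quantum-mechanical charges.
This module stands in for both: it builds random connected "molecules" with
physically plausible geometry (bonded neighbours 1.0-2.0 Angstrom apart, no
pair closer than 0.9 Angstrom) and generates reference charges by solving
the EEM system under a known ground-truth parameter set, optionally
perturbed by Gaussian noise.  A parameterization method run on such data has
a known answer — it must reproduce the generating charges — which makes
every other module testable without external databases or QM software.

The geometry is plausible but not chemically optimized and the bond graph is
not valence-correct: EEM consumes only interatomic distances, and bonds
matter only through atom typing.  Do not mistake fixtures for conformers.

Ground-truth defaults mimic published magnitude ranges (kappa ~ 0.4, A in
[2, 3], B in [1, 8] in the arbitrary consistent units of the EEM system) but
carry no physical meaning.  Because EEM charges are invariant under the A
shift and (A, B, kappa) scaling gauges, ground truths are expressed in the
reference-type gauge (B = 1 for the most frequent type, H1) so that
regression recovery is exact rather than gauge-equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import eem_core
from .chem_io import Atom, Bond, ChargeSet, Molecule, ParameterSet, assign_atom_types
from .errors import UncoveredMoleculeError

__all__ = [
    "FixtureConfig",
    "default_ground_truth",
    "random_molecule",
    "make_molecules",
    "make_reference_charges",
    "make_dataset",
]

#: Small palette: four single-bond types.  Weights favour hydrogen so the
#: reference gauge type H1 is the most frequent, as in organic molecules.
PALETTE_SMALL: dict[str, tuple[float, list[int]]] = {
    "H": (0.45, [1]),
    "C": (0.25, [1]),
    "N": (0.15, [1]),
    "O": (0.15, [1]),
}

#: Heterogeneous palette producing eight types: H1 C1 C2 N1 N2 O1 O2 S1.
PALETTE_ORGANIC: dict[str, tuple[float, list[int]]] = {
    "H": (0.40, [1]),
    "C": (0.25, [1, 2]),
    "N": (0.13, [1, 2]),
    "O": (0.14, [1, 2]),
    "S": (0.08, [1]),
}


def default_ground_truth(palette: dict[str, tuple[float, list[int]]] | None = None,
                         seed: int = 20170213) -> ParameterSet:
    """A ground-truth parameter set covering every type a palette can emit.

    A is drawn uniformly from [2, 3] and B from [2, 8], except that the
    reference type H1 gets B = 1 exactly: ground truths are expressed in the
    reference-type gauge so regression recovery (which pins B(H1) = 1) is
    exact, and kappa keeps its nominal value 0.4.
    """
    palette = PALETTE_SMALL if palette is None else palette
    rng = np.random.default_rng(seed)
    entries: dict[str, tuple[float, float]] = {}
    for element, (_, orders) in sorted(palette.items()):
        for order in orders:
            a = float(rng.uniform(2.0, 3.0))
            b = float(rng.uniform(2.0, 8.0))
            entries[f"{element}{order}"] = (a, b)
    if "H1" in entries:
        entries["H1"] = (entries["H1"][0], 1.0)
    return ParameterSet(
        name="synthetic-ground-truth",
        qm_label="synthetic/EEM",
        kappa=0.4,
        entries=entries,
    )


@dataclass
class FixtureConfig:
    """Knobs of the synthetic-data generator.

    ``noise_sigma`` is the standard deviation (e) of i.i.d. Gaussian noise
    added to the reference charges; ``charged_fraction`` the fraction of
    molecules carrying a +-1 formal charge on one atom.
    """

    n_molecules: int = 30
    atoms_min: int = 4
    atoms_max: int = 10
    palette: dict[str, tuple[float, list[int]]] = field(
        default_factory=lambda: dict(PALETTE_SMALL)
    )
    ground_truth: ParameterSet | None = None
    noise_sigma: float = 0.0
    charged_fraction: float = 0.2
    extra_bond_prob: float = 0.3
    seed: int = 0

    def resolved_ground_truth(self) -> ParameterSet:
        return self.ground_truth or default_ground_truth(self.palette)


_MIN_DIST = 0.9
_PLACEMENT_RETRIES = 200


def _place_atoms(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]] | None:
    """Sequential growth: each atom 1.0-2.0 A from a random previous atom,
    rejecting pairs closer than 0.9 A.  Returns (coords, anchor index per
    atom 1..n-1) so the spanning tree can bond placement neighbours, or
    None on failure."""
    coords = np.zeros((n, 3))
    anchors: list[int] = []
    for k in range(1, n):
        for _ in range(_PLACEMENT_RETRIES):
            anchor = int(rng.integers(k))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = coords[anchor] + rng.uniform(1.0, 2.0) * direction
            if np.linalg.norm(coords[:k] - pos, axis=1).min() >= _MIN_DIST:
                coords[k] = pos
                anchors.append(anchor)
                break
        else:
            return None
    return coords, anchors


def random_molecule(
    config: FixtureConfig,
    rng: np.random.Generator,
    name: str = "mol",
    force_type: tuple[str, int] | None = None,
) -> Molecule:
    """One random molecule: spanning-tree bond graph plus optional extra
    bonds, bond orders drawn from the palette of both endpoints.

    ``force_type=(element, order)`` guarantees the molecule contains an atom
    whose maximal bond order is exactly *order* on element *element* (used to
    guarantee dataset-level atom-type coverage).  Placement failure triggers
    regeneration with fresh draws.
    """
    elements = sorted(config.palette)
    weights = np.array([config.palette[e][0] for e in elements])
    weights = weights / weights.sum()
    while True:
        n = int(rng.integers(config.atoms_min, config.atoms_max + 1))
        symbols = list(rng.choice(elements, size=n, p=weights))
        forced_idx: int | None = None
        if force_type is not None:
            f_el, f_order = force_type
            # partner must be allowed to carry a bond of the forced order
            partners = [e for e in elements if f_order in config.palette[e][1]]
            symbols[0] = f_el
            symbols[1] = str(rng.choice(partners)) if n > 1 else f_el
            forced_idx = 0
        placed = _place_atoms(n, rng)
        if placed is None:
            continue
        coords, anchors = placed

        bonds: list[Bond] = []
        pairs: set[tuple[int, int]] = set()

        def allowed_order(i: int, j: int) -> int:
            shared = sorted(
                set(config.palette[symbols[i]][1]) & set(config.palette[symbols[j]][1])
            )
            if not shared:
                shared = [1]
            order = int(rng.choice(shared))
            if forced_idx is not None and forced_idx in (i, j):
                order = min(order, force_type[1])  # cap so forced max order holds
            return order

        for k in range(1, n):
            anchor = anchors[k - 1]  # atom 1's anchor is always atom 0
            if forced_idx is not None and k == 1:
                order = force_type[1]
            else:
                order = allowed_order(anchor, k)
            bonds.append(Bond(i=anchor + 1, j=k + 1, order=order))
            pairs.add((min(anchor, k), max(anchor, k)))
        n_extra = rng.binomial(max(n - 2, 0), config.extra_bond_prob)
        for _ in range(n_extra):
            i, j = sorted(rng.choice(n, size=2, replace=False))
            if (i, j) in pairs or i == j:
                continue
            pairs.add((i, j))
            bonds.append(Bond(i=i + 1, j=j + 1, order=allowed_order(i, j)))

        atoms = [
            Atom(element=s, x=float(c[0]), y=float(c[1]), z=float(c[2]))
            for s, c in zip(symbols, coords)
        ]
        if rng.random() < config.charged_fraction:
            atoms[int(rng.integers(n))].formal_charge = int(rng.choice([-1, 1]))
        mol = assign_atom_types(Molecule(name=name, atoms=atoms, bonds=bonds))
        if force_type is not None and mol.atoms[0].atom_type != f"{f_el}{f_order}":
            continue  # a higher-order extra bond spoiled the forced type; redraw
        return mol


def make_molecules(config: FixtureConfig, rng: np.random.Generator | None = None) -> list[Molecule]:
    """Generate ``n_molecules`` molecules whose pooled atom types cover every
    type the palette can emit at least twice (forced round-robin inclusion),
    satisfying regression identifiability preconditions."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    wanted = [
        (el, order)
        for el in sorted(config.palette)
        for order in config.palette[el][1]
    ]
    molecules = []
    for k in range(config.n_molecules):
        force = wanted[k % len(wanted)] if k < 2 * len(wanted) else None
        molecules.append(
            random_molecule(config, rng, name=f"mol{k + 1:04d}", force_type=force)
        )
    return molecules


def make_reference_charges(
    molecules: list[Molecule],
    ground_truth: ParameterSet,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ChargeSet:
    """Reference charges: EEM solve under the ground truth plus optional
    i.i.d. Gaussian noise, re-centred per molecule so sum(q) = Q exactly."""
    rng = np.random.default_rng(0) if rng is None else rng
    for mol in molecules:
        if not ground_truth.covers(mol):
            raise UncoveredMoleculeError(
                f"ground truth does not cover {mol.name!r}: "
                f"{', '.join(ground_truth.missing_types(mol))}"
            )
    charges = ChargeSet()
    for mol in molecules:
        q = eem_core.solve_charges(mol, ground_truth).charges
        if noise_sigma > 0:
            noise = rng.normal(0.0, noise_sigma, size=q.size)
            noise -= noise.mean()  # preserve sum(q) = Q exactly
            q = q + noise
        charges[mol.name] = q
    return charges


def make_dataset(config: FixtureConfig) -> tuple[list[Molecule], ChargeSet, ParameterSet]:
    """Molecules + reference charges + the generating ground truth."""
    rng = np.random.default_rng(config.seed)
    ground_truth = config.resolved_ground_truth()
    molecules = make_molecules(config, rng)
    charges = make_reference_charges(
        molecules, ground_truth, config.noise_sigma, rng
    )
    return molecules, charges, ground_truth
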