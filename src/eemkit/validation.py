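"""Validation of parameter sets and of computed charges.

Two independent checks mirror the two validation questions users ask of an
EEM parameter set:

* **coverage** — which molecules of a collection consist only of atom types
  the set parameterizes (only those can be processed at all);
* **quality** — how well EEM charges agree with reference (typically QM)
  charges, reported at three granularities: pooled over all atoms
  (summary), per atom type, and per molecule.

The statistics are the Pearson coefficient R and its square, the Spearman
coefficient and its square, the root-mean-square difference RMSD, the
average absolute difference Delta and the maximal absolute difference
Delta_max.  The headline scalar for parameter fitting is avg(RMSD_a): the
unweighted mean over atom types of the per-type RMSD, which prevents
abundant types (hydrogens) from drowning out rare ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .chem_io import ChargeSet, Molecule, ParameterSet
from .errors import ChargeFileError, DataError

__all__ = [
    "ChargeStats",
    "QualityReport",
    "CoverageReport",
    "compare_charges",
    "quality",
    "coverage",
    "export_scatter",
]


@dataclass
class ChargeStats:
    """Comparison statistics between two aligned charge vectors.

    Correlations on vectors where either side is constant (or with fewer
    than two points) are undefined and reported as NaN, not 0.
    """

    n: int
    r: float
    r2: float
    spearman: float
    spearman2: float
    rmsd: float
    delta: float
    delta_max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "R": self.r,
            "R2": self.r2,
            "spearman": self.spearman,
            "spearman2": self.spearman2,
            "RMSD": self.rmsd,
            "delta": self.delta,
            "delta_max": self.delta_max,
        }


def compare_charges(ref: np.ndarray, eem: np.ndarray) -> ChargeStats:
    """Statistics between a reference and a computed charge vector."""
    ref = np.asarray(ref, dtype=float)
    eem = np.asarray(eem, dtype=float)
    if ref.shape != eem.shape:
        raise ChargeFileError(
            f"misaligned charge vectors: {ref.shape} vs {eem.shape}"
        )
    diff = eem - ref
    n = ref.size
    if n == 0:
        nan = float("nan")
        return ChargeStats(0, nan, nan, nan, nan, nan, nan, nan)
    rmsd = float(np.sqrt(np.mean(diff**2)))
    delta = float(np.mean(np.abs(diff)))
    delta_max = float(np.abs(diff).max())
    if n < 2 or np.ptp(ref) == 0 or np.ptp(eem) == 0:
        r = rho = float("nan")
    else:
        r = float(np.corrcoef(ref, eem)[0, 1])
        rho = float(scipy.stats.spearmanr(ref, eem).statistic)
    return ChargeStats(n, r, r * r, rho, rho * rho, rmsd, delta, delta_max)


@dataclass
class QualityReport:
    """Summary, per-atom-type and per-molecule comparison statistics."""

    summary: ChargeStats
    per_type: dict[str, ChargeStats] = field(default_factory=dict)
    per_molecule: dict[str, ChargeStats] = field(default_factory=dict)

    @property
    def avg_rmsd_a(self) -> float:
        """Unweighted mean of per-type RMSD over types present in the data."""
        values = [s.rmsd for s in self.per_type.values() if s.n > 0]
        return float(np.mean(values)) if values else float("nan")

    @property
    def max_rmsd_a(self) -> float:
        values = [s.rmsd for s in self.per_type.values() if s.n > 0]
        return float(max(values)) if values else float("nan")

    @property
    def max_delta_a(self) -> float:
        values = [s.delta for s in self.per_type.values() if s.n > 0]
        return float(max(values)) if values else float("nan")

    def metric(self, name: str) -> float:
        """Scalar selection metric: 'r2' (higher better) or 'rmsd_avg'."""
        if name == "r2":
            return self.summary.r2
        if name == "rmsd_avg":
            return self.avg_rmsd_a
        raise ValueError(f"unknown metric {name!r}")

    def as_dict(self) -> dict:
        return {
            "summary": self.summary.as_dict(),
            "avg_rmsd_a": self.avg_rmsd_a,
            "max_rmsd_a": self.max_rmsd_a,
            "max_delta_a": self.max_delta_a,
            "per_type": {t: s.as_dict() for t, s in sorted(self.per_type.items())},
            "per_molecule": {m: s.as_dict() for m, s in self.per_molecule.items()},
        }

    def to_json(self, stream: IO[str]) -> None:
        json.dump(self.as_dict(), stream, indent=2, allow_nan=True)
        stream.write("\n")

    def to_text(self) -> str:
        def fmt(s: ChargeStats) -> str:
            def f(x: float) -> str:
                return "   n/a" if math.isnan(x) else f"{x:6.4f}"
            return (
                f"n={s.n:6d}  R={f(s.r)}  R2={f(s.r2)}  rho={f(s.spearman)}  "
                f"RMSD={f(s.rmsd)}  D={f(s.delta)}  Dmax={f(s.delta_max)}"
            )

        lines = ["== summary ==", fmt(self.summary),
                 f"avg(RMSD_a)={self.avg_rmsd_a:.6f}  "
                 f"max(RMSD_a)={self.max_rmsd_a:.6f}  "
                 f"max(D_a)={self.max_delta_a:.6f}",
                 "== atom types =="]
        for t, s in sorted(self.per_type.items()):
            lines.append(f"{t:>6s}  {fmt(s)}")
        lines.append("== molecules ==")
        for m, s in self.per_molecule.items():
            lines.append(f"{m:>16s}  {fmt(s)}")
        return "\n".join(lines) + "\n"


def _pool(
    molecules: Sequence[Molecule],
    ref_charges: Mapping[str, np.ndarray],
    eem_charges: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, list[str], list[str], list[int]]:
    """Flatten aligned charges over all atoms; returns (ref, eem, types,
    molecule names, atom indices) in molecule-then-atom order."""
    refs, eems, types, names, indices = [], [], [], [], []
    for mol in molecules:
        r = ChargeSet.vector_for(ChargeSet(ref_charges), mol)
        e = ChargeSet.vector_for(ChargeSet(eem_charges), mol)
        refs.append(r)
        eems.append(e)
        types.extend(mol.atom_types())
        names.extend([mol.name] * mol.n_atoms)
        indices.extend(range(1, mol.n_atoms + 1))
    if not refs:
        return np.empty(0), np.empty(0), [], [], []
    return np.concatenate(refs), np.concatenate(eems), types, names, indices


def quality(
    molecules: Sequence[Molecule],
    ref_charges: Mapping[str, np.ndarray],
    eem_charges: Mapping[str, np.ndarray],
    parameter_set: ParameterSet | None = None,
) -> QualityReport:
    """Compare EEM charges with reference charges.

    Summary statistics pool every atom of every molecule; per-type statistics
    cover each atom type present in the data (plus, when *parameter_set* is
    given, its types absent from the data, listed with n=0); per-molecule
    statistics cover each molecule.  Types with a single atom or constant
    charges get NaN correlations while RMSD_a and Delta_a are still computed.
    """
    ref, eem, types, names, _ = _pool(molecules, ref_charges, eem_charges)
    report = QualityReport(summary=compare_charges(ref, eem))
    type_arr = np.array(types)
    for t in sorted(set(types)):
        mask = type_arr == t
        report.per_type[t] = compare_charges(ref[mask], eem[mask])
    if parameter_set is not None:
        nan = float("nan")
        for t in parameter_set.atom_types:
            report.per_type.setdefault(
                t, ChargeStats(0, nan, nan, nan, nan, nan, nan, nan)
            )
    name_arr = np.array(names)
    for mol in molecules:
        mask = name_arr == mol.name
        report.per_molecule[mol.name] = compare_charges(ref[mask], eem[mask])
    return report


@dataclass
class CoverageReport:
    """Which molecules of a collection a parameter set can process."""

    n_total: int
    n_covered: int
    covered_ids: list[str]
    uncovered_ids: list[str]
    missing_types: dict[str, list[str]]

    @property
    def percent_covered(self) -> float:
        return 100.0 * self.n_covered / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_covered": self.n_covered,
            "percent_covered": self.percent_covered,
            "covered_ids": self.covered_ids,
            "uncovered_ids": self.uncovered_ids,
            "missing_types": self.missing_types,
        }

    def to_json(self, stream: IO[str]) -> None:
        json.dump(self.as_dict(), stream, indent=2)
        stream.write("\n")

    def to_text(self) -> str:
        lines = [
            f"covered {self.n_covered} of {self.n_total} molecules "
            f"({self.percent_covered:.2f}%)"
        ]
        for name in self.uncovered_ids:
            lines.append(
                f"uncovered: {name} (missing {', '.join(self.missing_types[name])})"
            )
        return "\n".join(lines) + "\n"


def coverage(
    molecules: Sequence[Molecule], parameter_set: ParameterSet
) -> CoverageReport:
    """A molecule is covered iff every one of its atom types is in the set."""
    if not molecules:
        raise DataError("coverage of an empty molecule list is undefined")
    covered, uncovered, missing = [], [], {}
    for mol in molecules:
        miss = parameter_set.missing_types(mol)
        if miss:
            uncovered.append(mol.name)
            missing[mol.name] = miss
        else:
            covered.append(mol.name)
    return CoverageReport(
        n_total=len(molecules),
        n_covered=len(covered),
        covered_ids=covered,
        uncovered_ids=uncovered,
        missing_types=missing,
    )


def export_scatter(
    molecules: Sequence[Molecule],
    ref_charges: Mapping[str, np.ndarray],
    eem_charges: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Long-format table (molecule, atom_index, atom_type, ref, eem).

    One row per atom; enough to draw reference-vs-EEM correlation scatter
    plots for all atoms or filtered by atom type.
    """
    ref, eem, types, names, indices = _pool(molecules, ref_charges, eem_charges)
    return pd.DataFrame(
        {
            "molecule": names,
            "atom_index": indices,
            "atom_type": types,
            "ref_charge": ref,
            "eem_charge": eem,
        }
    )
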