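"""Linear-regression parameterization with a kappa grid scan.

For fixed kappa the EEM stationarity condition of atom i in molecule m,

    A_t(i) + B_t(i) q_i + kappa * S_i - chi_m = 0,
    S_i = sum_{j != i} q_j / R_ij,

is linear in the per-type parameters {A_t, B_t} once the charges q are taken
from the reference set.  The per-molecule electronegativities chi_m are
nuisance unknowns; they are eliminated exactly by centering each design row
within its molecule (fixed-effects absorption).  The remaining least-squares
problem is solved for {A_t, B_t}, kappa is scanned over a grid, and the grid
point whose fitted set yields the best EEM-vs-reference metric (pooled R2 or
avg(RMSD_a)) wins, ties going to the smaller kappa.

Gauge fixing: EEM charges are invariant under A -> A + c and under joint
scaling of (A, B, kappa), so an unconstrained joint fit would be flat in
kappa.  The uniform A shift survives centering as an exact null direction
and is resolved by the minimum-norm solution; the scale gauge is pinned by
constraining B of a reference atom type (the most frequent, typically H1)
to 1 during the fit.  Reported parameters are in that gauge.  This fitting
scheme — centering plus reference-type normalization — is this package's
own reconstruction of classic least-squares EEM calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import eem_core
from .chem_io import ChargeSet, Molecule, ParameterSet, dataset_atom_types
from .errors import (
    FitError,
    IdentifiabilityError,
    IdentifiabilityWarning,
    SingularSystemError,
)
from .validation import QualityReport, quality

__all__ = [
    "LrConfig",
    "LinearRegressionParameterizer",
    "electronegativity_design",
    "fit_at_kappa",
    "parameterize_lr",
    "discard_search",
]

#: A candidate must beat the incumbent metric by this much for a greedy
#: discard step to be kept (guards against float-level pseudo-improvements).
DISCARD_IMPROVEMENT_TOL = 1e-9


@dataclass
class LrConfig:
    """Grid-scan configuration.

    metric: 'r2' (maximize pooled R2) or 'rmsd_avg' (minimize avg(RMSD_a)).
    discard: 'off' or 'greedy' (iteratively drop the worst-fitting molecule
    while the metric improves, up to max_discard_fraction of the set).
    """

    kappa_min: float = 0.05
    kappa_max: float = 1.5
    kappa_step: float = 0.05
    metric: str = "rmsd_avg"
    discard: str = "off"
    max_discard_fraction: float = 0.1
    reference_type: str | None = None

    def grid(self) -> np.ndarray:
        if not (self.kappa_min > 0 and self.kappa_step > 0):
            raise FitError("kappa_min and kappa_step must be > 0")
        if self.kappa_max < self.kappa_min:
            raise FitError("kappa_max must be >= kappa_min")
        n = int(np.floor((self.kappa_max - self.kappa_min) / self.kappa_step + 1e-9)) + 1
        return self.kappa_min + self.kappa_step * np.arange(n)


def _check_identifiable(
    molecules: Sequence[Molecule], ref_charges: Mapping[str, np.ndarray]
) -> None:
    by_type: dict[str, list[float]] = {}
    for mol in molecules:
        q = ChargeSet.vector_for(ChargeSet(ref_charges), mol)
        for t, qi in zip(mol.atom_types(), q):
            by_type.setdefault(t, []).append(float(qi))
    for t, values in sorted(by_type.items()):
        if len(values) < 2:
            raise IdentifiabilityError(
                f"atom type {t!r} occurs only {len(values)} time(s); "
                "B is not identifiable"
            )
        if np.ptp(values) == 0:
            raise IdentifiabilityError(
                f"atom type {t!r} has zero reference-charge variance; "
                "A and B are confounded"
            )


def _most_frequent_type(molecules: Sequence[Molecule]) -> str:
    counts: dict[str, int] = {}
    for mol in molecules:
        for t in mol.atom_types():
            counts[t] = counts.get(t, 0) + 1
    # ties broken alphabetically for determinism
    return min(counts, key=lambda t: (-counts[t], t))


def electronegativity_design(
    molecules: Sequence[Molecule],
    ref_charges: Mapping[str, np.ndarray],
    kappa: float,
    reference_type: str | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], str]:
    """Centered design matrix and target for the {A_t, B_t} fit at *kappa*.

    Returns (X, y, atom_types, reference_type).  Unknowns are ordered as all
    A_t (sorted types) followed by B_t for every type except the reference
    type, whose B is fixed at 1 (scale gauge).  Each row is an atom; rows are
    centered within their molecule, which eliminates the per-molecule
    electronegativity unknowns exactly.
    """
    _check_identifiable(molecules, ref_charges)
    types = dataset_atom_types(molecules)
    t0 = reference_type if reference_type is not None else _most_frequent_type(molecules)
    if t0 not in types:
        raise IdentifiabilityError(f"reference type {t0!r} not present in the data")
    t_index = {t: k for k, t in enumerate(types)}
    n_types = len(types)
    b_cols = [t for t in types if t != t0]
    b_index = {t: k for k, t in enumerate(b_cols)}

    rows_x, rows_y = [], []
    for mol in molecules:
        q = np.asarray(ChargeSet.vector_for(ChargeSet(ref_charges), mol), dtype=float)
        n = mol.n_atoms
        dist = eem_core.distance_matrix(mol)
        with np.errstate(divide="ignore"):
            inv = np.where(dist > 0, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
        s = inv @ q
        x = np.zeros((n, n_types + len(b_cols)))
        y = -kappa * s
        for i, t in enumerate(mol.atom_types()):
            x[i, t_index[t]] = 1.0  # A_t coefficient
            if t == t0:
                y[i] -= q[i]  # B_{t0} = 1 contributes a known term
            else:
                x[i, n_types + b_index[t]] = q[i]
        # absorb chi_m: center every column and the target within the molecule
        x -= x.mean(axis=0, keepdims=True)
        y = y - y.mean()
        rows_x.append(x)
        rows_y.append(y)
    return np.vstack(rows_x), np.concatenate(rows_y), types, t0


def fit_at_kappa(
    molecules: Sequence[Molecule],
    ref_charges: Mapping[str, np.ndarray],
    kappa: float,
    reference_type: str | None = None,
) -> ParameterSet:
    """Minimum-norm least-squares fit of {A_t, B_t} at fixed *kappa*.

    The uniform A shift is an exact null direction of the centered design;
    the minimum-norm solution resolves it (charges are invariant either
    way).  Rank deficiency beyond that one known gauge direction raises
    FitError.  A non-positive fitted B triggers IdentifiabilityWarning but
    the set is still returned — candidate evaluation will penalize it if the
    EEM solve misbehaves.
    """
    x, y, types, t0 = electronegativity_design(
        molecules, ref_charges, kappa, reference_type
    )
    solution, _, rank, singular = np.linalg.lstsq(x, y, rcond=None)
    n_cols = x.shape[1]
    if rank < n_cols - 1:  # one deficiency (A shift) is the known gauge
        tol = max(x.shape) * np.finfo(float).eps * (singular[0] if singular.size else 1.0)
        _, _, vt = np.linalg.svd(x)
        null = vt[rank:]
        offending = sorted(
            {
                (types + [t for t in types if t != t0])[j]
                for j in np.where(np.abs(null).max(axis=0) > 1e-6)[0]
            }
        )
        raise FitError(
            f"design at kappa={kappa:g} is rank-deficient beyond the gauge "
            f"null space (rank {rank} of {n_cols}); affected types: "
            + ", ".join(offending)
        )
    n_types = len(types)
    entries: dict[str, tuple[float, float]] = {}
    b_cols = [t for t in types if t != t0]
    for k, t in enumerate(types):
        a = float(solution[k])
        b = 1.0 if t == t0 else float(solution[n_types + b_cols.index(t)])
        entries[t] = (a, b)
    bad = [t for t, (_, b) in entries.items() if b <= 0]
    if bad:
        warnings.warn(
            f"fitted hardness B is non-positive for type(s) {', '.join(sorted(bad))} "
            f"at kappa={kappa:g}; the set is likely unphysical",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    return ParameterSet(
        name=f"lr-kappa-{kappa:g}", qm_label="fitted/LR", kappa=float(kappa),
        entries=entries,
    )


def _evaluate(
    molecules: Sequence[Molecule],
    ref_charges: Mapping[str, np.ndarray],
    pset: ParameterSet,
) -> QualityReport | None:
    """QualityReport of a candidate set, or None if any EEM solve fails."""
    try:
        eem = eem_core.calculate_charges(molecules, pset)
    except SingularSystemError:
        return None
    return quality(molecules, ref_charges, eem)


def _metric_better(metric: str, candidate: float, incumbent: float) -> bool:
    if np.isnan(candidate):
        return False
    if np.isnan(incumbent):
        return True
    return candidate > incumbent if metric == "r2" else candidate < incumbent


def parameterize_lr(
    molecules: Sequence[Molecule],
    ref_charges: Mapping[str, np.ndarray],
    config: LrConfig | None = None,
) -> tuple[ParameterSet, QualityReport]:
    """Grid scan over kappa; returns the best candidate set and its report.

    See :class:`LinearRegressionParameterizer` for the estimator interface
    (which also exposes the per-kappa profile table).
    """
    est = LinearRegressionParameterizer.from_config(config or LrConfig())
    est.discard = "off"
    est.fit(molecules, ref_charges)
    return est.parameter_set_, est.report_


def discard_search(
    molecules: Sequence[Molecule],
    ref_charges: Mapping[str, np.ndarray],
    config: LrConfig | None = None,
) -> tuple[list[Molecule], ParameterSet, QualityReport]:
    """Greedy training-set pruning: repeatedly drop the molecule with the
    worst per-molecule RMSD, keep the removal only if the selection metric
    improves; finally re-scan kappa on the kept subset."""
    config = config or LrConfig()
    est = LinearRegressionParameterizer.from_config(config)
    est.discard = "greedy"
    est.fit(molecules, ref_charges)
    kept = [m for m in molecules if m.name in set(est.kept_molecule_names_)]
    return kept, est.parameter_set_, est.report_


class LinearRegressionParameterizer(BaseEstimator):
    """EEM parameter calibration by per-kappa least squares.

    scikit-learn-style estimator: ``fit(molecules, ref_charges)`` calibrates
    the set, ``predict(molecules)`` returns EEM charges under it.

    Parameters mirror :class:`LrConfig`.  Fitted attributes:

    parameter_set_ : ParameterSet
        Winning set (reference-type gauge, B[reference type] = 1).
    kappa_ : float
        Selected kappa.
    report_ : QualityReport
        Quality of the winning set on the (kept) training molecules.
    profile_ : pandas.DataFrame
        Per-kappa table: kappa, R2, RMSD, avg_rmsd_a, status.
    kept_molecule_names_ : list of str
        Training molecules retained (all of them unless discard='greedy').
    """

    def __init__(
        self,
        kappa_min: float = 0.05,
        kappa_max: float = 1.5,
        kappa_step: float = 0.05,
        metric: str = "rmsd_avg",
        discard: str = "off",
        max_discard_fraction: float = 0.1,
        reference_type: str | None = None,
    ):
        self.kappa_min = kappa_min
        self.kappa_max = kappa_max
        self.kappa_step = kappa_step
        self.metric = metric
        self.discard = discard
        self.max_discard_fraction = max_discard_fraction
        self.reference_type = reference_type

    @classmethod
    def from_config(cls, config: LrConfig) -> "LinearRegressionParameterizer":
        return cls(
            kappa_min=config.kappa_min,
            kappa_max=config.kappa_max,
            kappa_step=config.kappa_step,
            metric=config.metric,
            discard=config.discard,
            max_discard_fraction=config.max_discard_fraction,
            reference_type=config.reference_type,
        )

    def _config(self) -> LrConfig:
        return LrConfig(
            kappa_min=self.kappa_min,
            kappa_max=self.kappa_max,
            kappa_step=self.kappa_step,
            metric=self.metric,
            discard=self.discard,
            max_discard_fraction=self.max_discard_fraction,
            reference_type=self.reference_type,
        )

    # -- scan machinery ----------------------------------------------------

    def _scan(
        self,
        molecules: Sequence[Molecule],
        ref_charges: Mapping[str, np.ndarray],
    ) -> tuple[ParameterSet, QualityReport, pd.DataFrame]:
        if self.metric not in ("r2", "rmsd_avg"):
            raise FitError(f"unknown metric {self.metric!r}")
        grid = self._config().grid()
        if grid.size == 0:
            raise FitError("empty kappa grid")
        best: tuple[ParameterSet, QualityReport] | None = None
        best_value = float("nan")
        rows = []
        failures = []
        for kappa in grid:
            status = "ok"
            report = None
            try:
                pset = fit_at_kappa(
                    molecules, ref_charges, float(kappa), self.reference_type
                )
                report = _evaluate(molecules, ref_charges, pset)
                if report is None:
                    status = "solve-failed"
            except (FitError, IdentifiabilityError, SingularSystemError) as exc:
                status = f"fit-failed: {exc}"
            if report is not None:
                value = report.metric(self.metric)
                rows.append(
                    {
                        "kappa": float(kappa),
                        "R2": report.summary.r2,
                        "RMSD": report.summary.rmsd,
                        "avg_rmsd_a": report.avg_rmsd_a,
                        "status": status,
                    }
                )
                # strict improvement required: ties keep the smaller kappa
                if best is None or _metric_better(self.metric, value, best_value):
                    best = (pset, report)
                    best_value = value
            else:
                failures.append(f"kappa={kappa:g}: {status}")
                rows.append(
                    {
                        "kappa": float(kappa),
                        "R2": float("nan"),
                        "RMSD": float("nan"),
                        "avg_rmsd_a": float("nan"),
                        "status": status,
                    }
                )
        if best is None:
            raise FitError("every kappa candidate failed:\n" + "\n".join(failures))
        return best[0], best[1], pd.DataFrame(rows)

    def fit(self, X: Sequence[Molecule], y: Mapping[str, np.ndarray]):
        """Calibrate on molecules *X* against reference charges *y*."""
        molecules = list(X)
        pset, report, profile = self._scan(molecules, y)
        kept = molecules
        if self.discard == "greedy":
            kept, pset, report, profile = self._greedy_discard(
                molecules, y, pset, report, profile
            )
        elif self.discard != "off":
            raise FitError(f"unknown discard mode {self.discard!r}")
        self.parameter_set_ = pset
        self.kappa_ = pset.kappa
        self.report_ = report
        self.profile_ = profile
        self.kept_molecule_names_ = [m.name for m in kept]
        return self

    def _greedy_discard(self, molecules, ref_charges, pset, report, profile):
        kept = list(molecules)
        max_removals = int(np.floor(self.max_discard_fraction * len(molecules)))
        incumbent_value = report.metric(self.metric)
        while len(kept) - 1 >= 2 and len(molecules) - len(kept) < max_removals:
            worst = max(kept, key=lambda m: report.per_molecule[m.name].rmsd)
            trial = [m for m in kept if m.name != worst.name]
            try:
                # refit at the incumbent kappa; the full grid is re-scanned once
                # at the end
                trial_pset = fit_at_kappa(
                    trial, ref_charges, pset.kappa, self.reference_type
                )
            except (FitError, IdentifiabilityError):
                break
            trial_report = _evaluate(trial, ref_charges, trial_pset)
            if trial_report is None:
                break
            value = trial_report.metric(self.metric)
            improved = (
                _metric_better(self.metric, value, incumbent_value)
                and abs(value - incumbent_value) > DISCARD_IMPROVEMENT_TOL
            )
            if not improved:
                break
            kept, pset, report, incumbent_value = trial, trial_pset, trial_report, value
        if len(kept) < len(molecules):
            pset, report, profile = self._scan(kept, ref_charges)
        return kept, pset, report, profile

    def predict(self, X: Sequence[Molecule]) -> ChargeSet:
        """EEM charges for molecules *X* under the fitted parameter set."""
        return eem_core.calculate_charges(list(X), self.parameter_set_)

    def score(self, X: Sequence[Molecule], y: Mapping[str, np.ndarray]) -> float:
        """Pooled squared Pearson correlation of predicted vs reference."""
        return quality(list(X), y, self.predict(X)).summary.r2
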