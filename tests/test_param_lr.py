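import copy

import numpy as np
import pytest

from eemkit import eem_core, fixtures as fx
from eemkit.chem_io import ChargeSet
from eemkit.errors import FitError, IdentifiabilityError
from eemkit.param_lr import (
    LinearRegressionParameterizer,
    LrConfig,
    discard_search,
    electronegativity_design,
    fit_at_kappa,
    parameterize_lr,
)
from eemkit.validation import quality


def recovery_rmsd(molecules, ref, pset):
    eem = eem_core.calculate_charges(molecules, pset)
    return quality(molecules, ref, eem).avg_rmsd_a


class TestDesign:
    def test_column_count(self, small_dataset):
        molecules, ref, truth = small_dataset
        x, y, types, t0 = electronegativity_design(molecules, ref, truth.kappa)
        # all A columns plus B columns for every type except the reference
        assert x.shape[1] == 2 * len(types) - 1
        assert x.shape[0] == sum(m.n_atoms for m in molecules)
        assert t0 == "H1"  # hydrogen-rich palette: most frequent type

    def test_rows_centered_within_molecule(self, small_dataset):
        molecules, ref, truth = small_dataset
        x, y, _, _ = electronegativity_design(molecules, ref, truth.kappa)
        start = 0
        for mol in molecules[:5]:
            block = slice(start, start + mol.n_atoms)
            np.testing.assert_allclose(x[block].sum(axis=0), 0, atol=1e-10)
            assert y[block].sum() == pytest.approx(0, abs=1e-10)
            start += mol.n_atoms

    def test_singleton_type_rejected(self, small_dataset):
        molecules, ref, _ = small_dataset
        # one P atom in the whole pooled dataset: B_P1 unidentifiable
        from eemkit.chem_io import Atom, Bond, Molecule, assign_atom_types

        lone = assign_atom_types(
            Molecule(
                "lone",
                [Atom("P", 0, 0, 0), Atom("H", 1.4, 0, 0), Atom("H", 0, 1.4, 0)],
                [Bond(1, 2, 1), Bond(1, 3, 1)],
            )
        )
        ref2 = ChargeSet(ref)
        ref2["lone"] = np.array([0.2, -0.1, -0.1])
        with pytest.raises(IdentifiabilityError, match="P1"):
            electronegativity_design(list(molecules) + [lone], ref2, 0.4)

    def test_kappa_zero_targets_have_no_coupling_term(self, small_dataset):
        molecules, ref, _ = small_dataset
        _, y0, _, t0 = electronegativity_design(molecules, ref, 0.0)
        # with kappa = 0 the target carries only the centered reference-type
        # charge term (the fixed B_t0 = 1 contribution)
        expected = []
        for mol in molecules:
            q = np.asarray(ref[mol.name])
            contrib = np.where(np.array(mol.atom_types()) == t0, -q, 0.0)
            expected.append(contrib - contrib.mean())
        np.testing.assert_allclose(y0, np.concatenate(expected), atol=1e-12)


class TestFitAtKappa:
    def test_exact_recovery_at_true_kappa(self, small_dataset):
        molecules, ref, truth = small_dataset
        pset = fit_at_kappa(molecules, ref, truth.kappa)
        assert recovery_rmsd(molecules, ref, pset) < 1e-6
        # charge agreement atom by atom
        eem = eem_core.calculate_charges(molecules, pset)
        for mol in molecules:
            np.testing.assert_allclose(eem[mol.name], ref[mol.name], atol=1e-6)

    def test_wrong_kappa_strictly_worse(self, small_dataset):
        molecules, ref, truth = small_dataset
        at_true = recovery_rmsd(molecules, ref, fit_at_kappa(molecules, ref, truth.kappa))
        at_double = recovery_rmsd(
            molecules, ref, fit_at_kappa(molecules, ref, 2 * truth.kappa)
        )
        assert at_double > at_true

    def test_duplicated_molecules_same_fit(self, small_dataset):
        molecules, ref, truth = small_dataset
        base = fit_at_kappa(molecules, ref, truth.kappa)
        tripled = []
        ref3 = ChargeSet()
        for k in range(3):
            for mol in molecules:
                clone = copy.deepcopy(mol)
                clone.name = f"{mol.name}-copy{k}"
                tripled.append(clone)
                ref3[clone.name] = ref[mol.name]
        again = fit_at_kappa(tripled, ref3, truth.kappa)
        for t in base.entries:
            assert again.entries[t] == pytest.approx(base.entries[t], abs=1e-9)


class TestScan:
    def test_selects_true_kappa_exactly(self, small_dataset):
        molecules, ref, truth = small_dataset
        config = LrConfig(kappa_min=0.5 * truth.kappa, kappa_max=2 * truth.kappa,
                          kappa_step=0.5 * truth.kappa)
        pset, report = parameterize_lr(molecules, ref, config)
        assert pset.kappa == pytest.approx(truth.kappa)
        assert report.summary.r2 == pytest.approx(1.0, abs=1e-9)

    def test_both_metrics_agree_on_noiseless_data(self, small_dataset):
        molecules, ref, truth = small_dataset
        config = LrConfig(kappa_min=0.2, kappa_max=0.8, kappa_step=0.2, metric="r2")
        by_r2, _ = parameterize_lr(molecules, ref, config)
        config.metric = "rmsd_avg"
        by_rmsd, _ = parameterize_lr(molecules, ref, config)
        assert by_r2.kappa == by_rmsd.kappa == pytest.approx(truth.kappa)

    def test_invalid_grid_rejected(self, small_dataset):
        molecules, ref, _ = small_dataset
        with pytest.raises(FitError):
            parameterize_lr(molecules, ref, LrConfig(kappa_min=1.0, kappa_max=0.5))

    def test_selection_is_grid_optimum(self, noisy_hetero_dataset):
        molecules, ref, _ = noisy_hetero_dataset
        est = LinearRegressionParameterizer(kappa_min=0.1, kappa_max=0.9,
                                            kappa_step=0.2)
        est.fit(molecules, ref)
        profile = est.profile_.dropna(subset=["avg_rmsd_a"])
        assert est.report_.avg_rmsd_a <= profile["avg_rmsd_a"].min() + 1e-12

    def test_deterministic(self, noisy_hetero_dataset):
        molecules, ref, _ = noisy_hetero_dataset
        config = LrConfig(kappa_min=0.2, kappa_max=0.6, kappa_step=0.2)
        first, _ = parameterize_lr(molecules, ref, config)
        second, _ = parameterize_lr(molecules, ref, config)
        assert first == second


class TestDiscard:
    def corrupt_one(self, molecules, ref, sigma=0.5):
        bad = ChargeSet(ref)
        victim = molecules[0].name
        rng = np.random.default_rng(99)
        noise = rng.normal(0, sigma, size=len(ref[victim]))
        noise -= noise.mean()
        bad[victim] = np.asarray(ref[victim]) + noise
        return bad, victim

    def test_corrupted_molecule_discarded(self, small_dataset):
        molecules, ref, truth = small_dataset
        bad, victim = self.corrupt_one(molecules, ref)
        config = LrConfig(kappa_min=0.2, kappa_max=0.6, kappa_step=0.2,
                          discard="greedy", max_discard_fraction=0.1)
        kept, pset, report = discard_search(molecules, bad, config)
        assert victim not in {m.name for m in kept}
        _, full_report = parameterize_lr(molecules, bad, LrConfig(
            kappa_min=0.2, kappa_max=0.6, kappa_step=0.2))
        assert report.avg_rmsd_a < full_report.avg_rmsd_a

    def test_zero_fraction_equals_plain_scan(self, small_dataset):
        molecules, ref, truth = small_dataset
        config = LrConfig(kappa_min=0.2, kappa_max=0.6, kappa_step=0.2,
                          discard="greedy", max_discard_fraction=0.0)
        kept, pset, _ = discard_search(molecules, ref, config)
        plain, _ = parameterize_lr(molecules, ref, LrConfig(
            kappa_min=0.2, kappa_max=0.6, kappa_step=0.2))
        assert len(kept) == len(molecules)
        assert pset == plain

    def test_clean_data_keeps_everything(self, small_dataset):
        molecules, ref, _ = small_dataset
        config = LrConfig(kappa_min=0.2, kappa_max=0.6, kappa_step=0.2,
                          discard="greedy", max_discard_fraction=0.2)
        kept, _, _ = discard_search(molecules, ref, config)
        assert len(kept) == len(molecules)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        est = LinearRegressionParameterizer(kappa_min=0.1, metric="r2")
        params = est.get_params()
        clone = LinearRegressionParameterizer().set_params(**params)
        assert clone.get_params() == params

    def test_predict_and_score(self, small_dataset):
        molecules, ref, truth = small_dataset
        est = LinearRegressionParameterizer(kappa_min=0.2, kappa_max=0.6,
                                            kappa_step=0.2)
        est.fit(molecules, ref)
        predicted = est.predict(molecules)
        assert set(predicted) == {m.name for m in molecules}
        assert est.score(molecules, ref) == pytest.approx(1.0, abs=1e-9)
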