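"""Confidence-fraction curves, error metrics, strata, bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from nmrshift.evaluate import (
    bonding_partner_strata,
    bootstrap_ci,
    confidence_curve,
    error_metrics,
    prediction_table,
    shift_bin_strata,
)


def table(y, mu, sigma=None, sphere=None, mol_ids=None):
    n = len(y)
    d = {
        "molecule_id": mol_ids if mol_ids is not None else ["m"] * n,
        "atom_index": list(range(n)),
        "y": y,
        "mu": mu,
    }
    if sigma is not None:
        d["sigma"] = sigma
    if sphere is not None:
        d["matched_sphere"] = sphere
    return pd.DataFrame(d)


class TestConfidenceCurve:
    def test_uninformative_confidence_flat_curve(self):
        # equal sigmas carry no ranking information; with equal errors the
        # curve is exactly flat (ties are kept in stable input order)
        t = table([2, 2, 2, 2], [0, 0, 0, 0], sigma=[1, 1, 1, 1])
        curve = confidence_curve(t, fractions=[0.25, 0.5, 1.0])
        assert np.allclose(curve.mae, curve.mae[0])

    def test_enumerated_selection(self):
        """abs errors (1,2,3,4) ranked by matching sigma: f=0.5 -> MAE 1.5,
        f=1.0 -> 2.5."""
        t = table([1, 2, 3, 4], [0, 0, 0, 0], sigma=[0.1, 0.2, 0.3, 0.4])
        curve = confidence_curve(t, fractions=[0.5, 1.0])
        assert curve.mae[0] == pytest.approx(1.5)
        assert curve.mae[1] == pytest.approx(2.5)

    def test_full_fraction_equals_global_mae(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        mu = y + rng.normal(size=50)
        t = table(y, mu, sigma=rng.random(50))
        curve = confidence_curve(t, fractions=[1.0])
        assert curve.mae[0] == pytest.approx(np.abs(y - mu).mean(), abs=1e-12)

    def test_sphere_confidence_ranks_descending(self):
        # deep spheres are most confident; f=0.5 picks the two sphere-6 rows
        t = table([0, 0, 0, 0], [1, 5, 1, 5], sphere=[6, 2, 6, 2])
        curve = confidence_curve(t, fractions=[0.5, 1.0], confidence="matched_sphere")
        assert curve.mae[0] == pytest.approx(1.0)
        assert curve.mae[1] == pytest.approx(3.0)

    def test_oracle_confidence_curve_nondecreasing(self):
        """With sigma = true |error| the curve cannot decrease in f."""
        rng = np.random.default_rng(1)
        y = rng.normal(size=200)
        mu = y + rng.normal(size=200)
        t = table(y, mu, sigma=np.abs(y - mu))
        curve = confidence_curve(t, fractions=np.linspace(0.05, 1.0, 20))
        assert np.all(np.diff(curve.mae) >= -1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confidence_curve(table([], []))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            confidence_curve(table([1], [1], sigma=[1]), fractions=[0.0, 1.0])


class TestErrorMetrics:
    def test_single_molecule_hand_values(self):
        t = table([1, 3], [0, 0])
        m = error_metrics(t)
        assert (m.mae, m.mol_mae, m.mol_rmse) == (2.0, 2.0, 2.0)

    def test_two_molecule_aggregation(self):
        """Per-mol MAEs 1 and 3: mol MAE 2, mol RMSE sqrt(5)."""
        t = table([1, 3], [0, 0], mol_ids=["a", "b"])
        m = error_metrics(t)
        assert m.mol_mae == pytest.approx(2.0)
        assert m.mol_rmse == pytest.approx(np.sqrt(5.0))

    def test_perfect_predictions(self):
        t = table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        m = error_metrics(t)
        assert m.mae == m.mol_mae == m.mol_rmse == 0.0

    def test_mol_rmse_dominates_mol_mae(self):
        """Power-mean inequality on random tables."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(2, 40))
            t = table(
                rng.normal(size=n), rng.normal(size=n),
                mol_ids=list(rng.integers(0, 5, size=n).astype(str)),
            )
            m = error_metrics(t)
            assert m.mol_rmse >= m.mol_mae - 1e-12

    def test_grouped_breakdown_sums_to_total(self):
        rng = np.random.default_rng(3)
        n = 30
        t = table(rng.normal(size=n), rng.normal(size=n)).assign(
            grp=rng.integers(0, 3, size=n)
        )
        m = error_metrics(t, grouping="grp", n_boot=200)
        assert m.groups["n"].sum() == n
        for _, row in m.groups.iterrows():
            assert row["ci_low"] <= row["mean"] <= row["ci_high"]


class TestStrata:
    def test_chloromethane_carbon_membership(self, chloromethane):
        c_idx = next(i for i, a in enumerate(chloromethane.atoms) if a.element == "C")
        t = pd.DataFrame(
            [{"molecule_id": "chloromethane", "atom_index": c_idx, "y": 25.6, "mu": 25.0}]
        )
        strata = bonding_partner_strata({"chloromethane": chloromethane}, t)
        assert sorted(strata["partner"]) == ["Cl", "H"]

    def test_methane_carbon_single_stratum(self, methane):
        t = pd.DataFrame([{"molecule_id": "methane", "atom_index": 0, "y": 0.0, "mu": 0.0}])
        strata = bonding_partner_strata({"methane": methane}, t)
        assert list(strata["partner"]) == ["H"]

    def test_sizes_match_brute_force_bond_scan(self, small_molecule_set):
        mols = {g.mol_id: g for g in small_molecule_set[:6]}
        rows = []
        for g in mols.values():
            for i, a in enumerate(g.atoms):
                if a.element == "C":
                    rows.append({"molecule_id": g.mol_id, "atom_index": i, "y": 1.0, "mu": 0.0})
        t = pd.DataFrame(rows)
        strata = bonding_partner_strata(mols, t)
        # independent count: scan every bond of every molecule
        expected = {}
        for g in mols.values():
            for i, a in enumerate(g.atoms):
                if a.element != "C":
                    continue
                for p in {g.atoms[j].element for j, _ in g.neighbors(i)}:
                    expected[p] = expected.get(p, 0) + 1
        got = strata.groupby("partner").size().to_dict()
        assert got == expected

    def test_unknown_molecule_rejected(self, methane):
        t = pd.DataFrame([{"molecule_id": "nope", "atom_index": 0, "y": 0.0, "mu": 0.0}])
        with pytest.raises(KeyError):
            bonding_partner_strata({"methane": methane}, t)

    def test_shift_bins_fixed_width(self):
        t = table([0.3, 12.0, 19.9, 20.0], [0, 0, 0, 0])
        binned = shift_bin_strata(t, bin_width=10.0)
        assert list(binned["shift_bin"]) == [0.0, 10.0, 10.0, 20.0]


class TestBootstrap:
    def test_constant_values_collapse(self):
        lo, hi = bootstrap_ci([2.5] * 10, n_boot=500, seed=0)
        assert lo == hi == 2.5

    def test_seeded_repeatability(self):
        vals = np.random.default_rng(4).normal(size=50)
        assert bootstrap_ci(vals, n_boot=1000, seed=7) == bootstrap_ci(vals, n_boot=1000, seed=7)

    def test_normal_closed_form(self):
        """CI of the mean of 1000 standard-normal draws ~ mean +- 1.96/sqrt(1000)."""
        rng = np.random.default_rng(5)
        vals = rng.normal(size=1000)
        lo, hi = bootstrap_ci(vals, n_boot=5000, seed=1)
        se = 1.0 / np.sqrt(1000)
        mean = vals.mean()
        assert lo == pytest.approx(mean - 1.96 * se, abs=0.3 * se)
        assert hi == pytest.approx(mean + 1.96 * se, abs=0.3 * se)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0], n_boot=10, seed=0)


class TestPredictionTable:
    def test_rows_only_for_observed_atoms(self, small_molecule_set):
        from nmrshift.gnn import ShiftPrediction

        g = small_molecule_set[0]
        y = np.full(g.n_atoms, np.nan)
        y[0] = 10.0
        pred = ShiftPrediction(
            mu=np.zeros(g.n_atoms), sigma=np.ones(g.n_atoms), valid_mask=np.ones(g.n_atoms)
        )
        t = prediction_table([g], [y], [pred], nucleus="C13")
        assert len(t) == 1
        assert set(t.columns) >= {"molecule_id", "atom_index", "y", "mu", "sigma", "nucleus"}
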