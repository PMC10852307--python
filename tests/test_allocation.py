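import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from plelscape.plel_core import (
    CategoricalRaster,
    NAME_TO_CODE,
    PLEL_CODES,
    tabulate_areas,
)
from plelscape import allocation as alc
from plelscape import synthetic_data as sd


@pytest.fixture(scope="module")
def synth(small_synth_series):
    return small_synth_series


class TestFitSuitability:
    def test_probabilities_sum_to_one_per_cell(self, synth):
        suit = alc.fit_suitability(
            synth["series"][0], synth["series"][1], synth["drivers"], seed=0,
            n_samples=5000,
        )
        stack = suit.stack()
        mask = synth["series"][0].mask
        np.testing.assert_allclose(stack.sum(axis=0)[mask], 1.0, atol=1e-6)

    def test_constant_drivers_predict_class_priors(self):
        rng = np.random.default_rng(0)
        v = rng.choice([1, 6, 8], p=[0.2, 0.5, 0.3], size=(120, 120))
        r = CategoricalRaster(values=v)
        drv = sd.DriverStack(
            layers={"flat": np.zeros_like(v, dtype=float)}, cell_size=30.0
        )
        suit = alc.fit_suitability(r, r, drv, seed=1, n_samples=10_000)
        priors = tabulate_areas(r) / tabulate_areas(r).sum()
        for code, name in [(1, "APL"), (6, "GEL"), (8, "OEL")]:
            got = suit.probabilities[code][r.mask].mean()
            assert got == pytest.approx(priors[name], abs=0.02)

    def test_separable_driver_recovers_classes(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, size=(100, 100))
        v = np.where(x < 0.5, 6, 8)
        r = CategoricalRaster(values=v)
        drv = sd.DriverStack(layers={"x": x}, cell_size=30.0)
        suit = alc.fit_suitability(r, r, drv, seed=3, n_samples=5000)
        pred = np.where(suit.probabilities[6] > suit.probabilities[8], 6, 8)
        assert (pred == v).mean() >= 0.95

    def test_absent_class_gets_uniform_prior_with_warning(self):
        v = np.full((50, 50), 6)
        r = CategoricalRaster(values=v)
        drv = sd.DriverStack(
            layers={"x": np.random.default_rng(4).normal(size=(50, 50))},
            cell_size=30.0,
        )
        with pytest.warns(UserWarning, match="uniform"):
            suit = alc.fit_suitability(r, r, drv, seed=5, n_samples=1000)
        assert suit.probabilities[1].max() <= 1.0

    def test_unknown_classifier_rejected(self, synth):
        with pytest.raises(ValueError, match="classifier"):
            alc.fit_suitability(
                synth["series"][0], synth["series"][1], synth["drivers"],
                classifier="svm",
            )


@pytest.fixture(scope="module")
def fitted(synth):
    return alc.fit_suitability(
        synth["series"][0], synth["series"][1], synth["drivers"], seed=0,
        n_samples=8000,
    )


class TestAllocate:

    def test_matching_demand_changes_nothing(self, synth, fitted):
        base = synth["series"][1]
        out = alc.allocate(base, tabulate_areas(base), fitted)
        np.testing.assert_array_equal(out.values, base.values)

    def test_restricted_cells_never_change(self, synth, fitted):
        base = synth["series"][1]
        demand = tabulate_areas(synth["series"][2])
        out = alc.allocate(
            base, demand, fitted, restricted=synth["lake"],
            params=alc.CAParams(seed=4),
        )
        lake = synth["lake"]
        np.testing.assert_array_equal(out.values[lake], base.values[lake])

    def test_demand_shift_converges_and_targets_suitable_cells(self, synth, fitted):
        base = synth["series"][1]
        demand = tabulate_areas(base)
        shift = 0.05 * demand["OEL"]
        demand["OEL"] -= shift
        demand["APL"] += shift
        out = alc.allocate(
            base, demand, fitted, params=alc.CAParams(seed=7),
        )
        got = tabulate_areas(out)
        for name in ("OEL", "APL"):
            assert abs(got[name] - demand[name]) / demand[name] <= 0.005
        apl_suit = fitted.probabilities[NAME_TO_CODE["APL"]]
        new_apl = (out.values == NAME_TO_CODE["APL"]) & (
            base.values == NAME_TO_CODE["OEL"]
        )
        still_oel = (out.values == NAME_TO_CODE["OEL"]) & (
            base.values == NAME_TO_CODE["OEL"]
        )
        assert apl_suit[new_apl].mean() > apl_suit[still_oel].mean()

    def test_deterministic_under_fixed_seed(self, synth, fitted):
        base = synth["series"][1]
        demand = tabulate_areas(synth["series"][2])
        a = alc.allocate(base, demand, fitted, params=alc.CAParams(seed=9))
        b = alc.allocate(base, demand, fitted, params=alc.CAParams(seed=9))
        np.testing.assert_array_equal(a.values, b.values)

    def test_demand_below_immutable_lake_rejected(self, synth, fitted):
        base = synth["series"][1]
        demand = tabulate_areas(base)
        lake_area = synth["lake"].sum() * base.cell_area_hm2
        taken = demand["WEL"] - 0.5 * lake_area
        demand["WEL"] -= taken
        demand["OEL"] += taken
        with pytest.raises(ValueError, match="restricted"):
            alc.allocate(base, demand, fitted, restricted=synth["lake"])

    def test_demand_total_mismatch_rejected(self, synth, fitted):
        base = synth["series"][1]
        demand = tabulate_areas(base) * 1.2
        with pytest.raises(ValueError, match="total"):
            alc.allocate(base, demand, fitted)

    def test_forbidden_transitions_respected(self, synth, fitted):
        base = synth["series"][1]
        demand = tabulate_areas(base)
        shift = 0.03 * demand["OEL"]
        demand["OEL"] -= shift
        demand["APL"] += shift
        allowed = np.ones((8, 8), dtype=bool)
        allowed[7, 0] = False  # OEL may not convert to APL
        out = alc.allocate(
            base, demand, fitted,
            params=alc.CAParams(seed=2, transition_allowed=allowed),
        )
        converted = (base.values == 8) & (out.values == 1)
        assert converted.sum() == 0


class TestConfusionKappa:
    def test_perfect_agreement(self, synth):
        r = synth["series"][0]
        cm, oa, kappa = alc.confusion_kappa(r, r)
        assert oa == 1.0 and kappa == 1.0

    def test_two_class_hand_example(self):
        # truth/pred counts [[40, 10], [5, 45]]: OA 0.85, kappa 0.70
        t = np.concatenate([np.full(50, 1), np.full(50, 6)])
        p = np.concatenate(
            [np.full(40, 1), np.full(10, 6), np.full(5, 1), np.full(45, 6)]
        )
        truth = CategoricalRaster(values=t.reshape(10, 10))
        pred = CategoricalRaster(values=p.reshape(10, 10))
        cm, oa, kappa = alc.confusion_kappa(pred, truth)
        assert oa == pytest.approx(0.85)
        assert kappa == pytest.approx(0.70)

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(10)
        t = rng.integers(1, 9, size=(120, 120))
        p = rng.integers(1, 9, size=(120, 120))
        _, oa, kappa = alc.confusion_kappa(
            CategoricalRaster(values=p), CategoricalRaster(values=t)
        )
        assert kappa == pytest.approx(
            cohen_kappa_score(t.ravel(), p.ravel()), abs=1e-12
        )
        assert abs(kappa) <= 0.05  # independent labels, large n

    def test_misaligned_rasters_rejected(self):
        a = CategoricalRaster(values=np.ones((4, 4)))
        b = CategoricalRaster(values=np.ones((5, 5)))
        with pytest.raises(ValueError):
            alc.confusion_kappa(a, b)


class TestSelfValidation:
    def test_hindcast_beats_persistence_baseline(self, synth):
        res = alc.self_validation(
            synth["series"], synth["drivers"], restricted=synth["lake"], seed=3
        )
        assert res["kappa_sim"] > res["kappa_persistence"]

    def test_needs_three_epochs(self, synth):
        with pytest.raises(ValueError, match="3 epochs"):
            alc.self_validation(synth["series"][:2], synth["drivers"])
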