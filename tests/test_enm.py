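import itertools
import logging

import numpy as np
import pandas as pd
import pytest

from nicheshift import enm
from nicheshift.errors import ConfigurationError, NicheShiftError
from nicheshift.raster import Raster, RasterStack


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def auc_pair_oracle(scores, y):
    """Concordant-pair counting with half credit for ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = conc = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1
        if p > n:
            conc += 1
        elif p == n:
            conc += 0.5
    return conc / total


def thin_oracle(df, step):
    seen = set()
    keep = []
    for i, row in df.iterrows():
        cell = (int(np.floor(row.lon / step)), int(np.floor(row.lat / step)))
        if cell not in seen:
            seen.add(cell)
            keep.append(i)
    return df.loc[keep]


class TestThinRecords:
    def test_two_in_one_cell(self):
        df = pd.DataFrame({"lon": [0.001, 0.002], "lat": [0.001, 0.002]})
        assert len(enm.thin_records(df, 5.0)) == 1

    def test_distinct_cells_all_kept(self):
        df = pd.DataFrame({"lon": np.arange(5) * 1.0, "lat": np.zeros(5)})
        assert len(enm.thin_records(df, 5.0)) == 5

    def test_matches_grid_hash_oracle(self, rng):
        df = pd.DataFrame({"lon": rng.uniform(-10, 10, 1000),
                           "lat": rng.uniform(-10, 10, 1000)})
        step = 50.0 / enm.KM_PER_DEGREE
        got = enm.thin_records(df, 50.0)
        expected = thin_oracle(df, step)
        pd.testing.assert_frame_equal(got, expected)

    def test_empty_rejected(self):
        with pytest.raises(NicheShiftError):
            enm.thin_records(pd.DataFrame({"lon": [], "lat": []}), 5.0)

    def test_bad_cell_size(self):
        df = pd.DataFrame({"lon": [0.0], "lat": [0.0]})
        with pytest.raises(ConfigurationError):
            enm.thin_records(df, 0.0)


class TestCorrelationFilter:
    def test_perfectly_correlated_pair_drops_one(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": 2 * x, "z": rng.normal(size=100)})
        assert enm.correlation_filter(df) == ["x", "z"]

    def test_pair_at_exact_threshold_kept(self, rng):
        # r = 0.7 by construction from orthogonal components
        a = np.tile([1.0, 1.0, -1.0, -1.0], 25)
        b = np.tile([1.0, -1.0, 1.0, -1.0], 25)
        df = pd.DataFrame({"x": a, "y": 0.7 * a + np.sqrt(1 - 0.49) * b})
        r = np.corrcoef(df.x, df.y)[0, 1]
        assert r == pytest.approx(0.7, abs=1e-12)
        assert enm.correlation_filter(df, 0.7) == ["x", "y"]

    def test_independent_variables_all_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        assert enm.correlation_filter(df) == list("abcd")

    def test_constant_variable_rejected(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        with pytest.raises(NicheShiftError, match="'b'"):
            enm.correlation_filter(df)


class TestPseudoAbsences:
    def _bg(self, rng, n=500):
        return pd.DataFrame(rng.normal(size=(n, 2)), columns=["e1", "e2"])

    def test_no_overlap_with_presences(self, rng):
        bg = self._bg(rng)
        pres = bg.iloc[:50]
        pa = enm.sample_pseudo_absences(bg, pres, n=100, seed=0)
        keys = set(map(tuple, pres.round(9).to_numpy()))
        assert not any(tuple(r) in keys for r in pa.round(9).to_numpy())

    def test_deterministic(self, rng):
        bg = self._bg(rng)
        pres = bg.iloc[:10]
        a = enm.sample_pseudo_absences(bg, pres, n=50, seed=3)
        b = enm.sample_pseudo_absences(bg, pres, n=50, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_insufficient_cells(self, rng):
        bg = self._bg(rng, n=100)
        pres = bg.iloc[:60]
        with pytest.raises(NicheShiftError, match="40"):
            enm.sample_pseudo_absences(bg, pres, n=50, seed=0)


class TestPADatasetAndSplit:
    def _pa(self, rng, n_pres=100, n_abs=100):
        pres = pd.DataFrame(rng.normal(1, 1, size=(n_pres, 2)),
                            columns=["e1", "e2"])
        abse = pd.DataFrame(rng.normal(-1, 1, size=(n_abs, 2)),
                            columns=["e1", "e2"])
        return enm.PADataset(presences=pres, absences=abse,
                             variables=["e1", "e2"])

    def test_prevalence_weights_balance(self, rng):
        pa = self._pa(rng, 50, 200)
        w, y = pa.weights, pa.y
        assert w[y == 1].sum() == pytest.approx(w[y == 0].sum())

    def test_eval_slice_size(self, rng):
        pa = self._pa(rng)
        plan = enm.split_dataset(pa, seed=0)
        y = pa.y
        assert (y[plan.eval_idx] == 1).sum() == 30
        assert (y[plan.eval_idx] == 0).sum() == 30

    def test_inner_union_is_remainder(self, rng):
        pa = self._pa(rng)
        plan = enm.split_dataset(pa, seed=1)
        remainder = set(range(len(pa))) - set(plan.eval_idx)
        for train, test in plan.repeats:
            assert set(train) | set(test) == remainder
            assert not set(train) & set(test)

    def test_class_proportions_within_one_record(self, rng):
        pa = self._pa(rng, 73, 131)
        plan = enm.split_dataset(pa, seed=2)
        y = pa.y
        frac = 73 / 204
        for idx in [plan.eval_idx] + [t for pair in plan.repeats for t in pair]:
            expected = frac * len(idx)
            assert abs((y[idx] == 1).sum() - expected) <= 1.0

    def test_too_few_per_class(self, rng):
        pa = self._pa(rng, 5, 100)
        with pytest.raises(NicheShiftError):
            enm.split_dataset(pa, seed=0)


class TestEvaluate:
    def test_perfect_separation(self):
        y = np.array([1] * 5 + [0] * 5)
        s = np.array([0.9] * 5 + [0.1] * 5)
        res = enm.evaluate_scores(s, y)
        assert res.auc == 1.0
        assert res.tss == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.auc_band == "excellent"

    def test_constant_score(self):
        y = np.array([1, 1, 0, 0])
        res = enm.evaluate_scores(np.full(4, 0.5), y)
        assert res.auc == 0.5
        assert res.tss == pytest.approx(0.0)
        assert res.auc_band == "no-better-than-random"

    def test_hand_scored_six_points(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([0.9, 0.6, 0.4, 0.7, 0.3, 0.1])
        res = enm.evaluate_scores(s, y)
        assert res.auc == pytest.approx(auc_pair_oracle(s, y))

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_matches_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 51)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)  # force ties
        assert enm.evaluate_scores(s, y).auc == \
            pytest.approx(auc_pair_oracle(s, y), abs=1e-8)

    def test_tss_identity_at_threshold(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.random(40)
        res = enm.evaluate_scores(s, y)
        assert res.tss == pytest.approx(res.sensitivity + res.specificity - 1)
        pred = (s >= res.tss_threshold).astype(int)
        sens = ((pred == 1) & (y == 1)).sum() / (y == 1).sum()
        spec = ((pred == 0) & (y == 0)).sum() / (y == 0).sum()
        assert res.tss == pytest.approx(sens + spec - 1)

    def test_single_class_rejected(self):
        with pytest.raises(NicheShiftError):
            enm.evaluate_scores(np.array([0.5, 0.6]), np.array([1, 1]))

    def test_auc_bands(self):
        for auc, band in [(0.95, "excellent"), (0.85, "good"), (0.75, "fair"),
                          (0.65, "poor"), (0.55, "fail"),
                          (0.5, "no-better-than-random"),
                          (0.3, "no-better-than-random")]:
            assert enm.auc_band(auc) == band


class TestLearnersAndMembers:
    def _separable(self, rng, n=60):
        pres = pd.DataFrame(rng.normal(3, 0.5, size=(n, 2)), columns=["a", "b"])
        abse = pd.DataFrame(rng.normal(-3, 0.5, size=(n, 2)), columns=["a", "b"])
        return enm.PADataset(presences=pres, absences=abse, variables=["a", "b"])

    @pytest.mark.parametrize("name", enm.DEFAULT_LEARNERS)
    def test_separable_training_auc_one(self, rng, name):
        pa = self._separable(rng)
        model = enm.make_learner(name, seed=0)
        model.fit(pa.X, pa.y, pa.weights)
        assert enm.evaluate(model, pa).auc == 1.0

    def test_unknown_learner(self):
        with pytest.raises(ConfigurationError):
            enm.make_learner("kriging")

    def test_shuffled_labels_auc_half(self, rng):
        pres = pd.DataFrame(rng.normal(size=(250, 2)), columns=["a", "b"])
        abse = pd.DataFrame(rng.normal(size=(250, 2)), columns=["a", "b"])
        pa = enm.PADataset(presences=pres, absences=abse, variables=["a", "b"])
        plan = enm.split_dataset(pa, n_repeats=5, seed=0)
        members = enm.fit_members(pa, plan, learners=("glm",), seed=0)
        mean_auc = np.mean([m.inner_scores.auc for m in members])
        assert mean_auc == pytest.approx(0.5, abs=0.07)

    def test_contract_violation_rejected(self, rng, caplog):
        class BadEstimator:
            classes_ = [0, 1]

            def fit(self, X, y, sample_weight=None):
                return self

            def predict_proba(self, X):
                out = np.full((len(X), 2), 2.0)  # outside [0, 1]
                return out

        enm.LEARNER_FACTORIES["bad"] = lambda seed: BadEstimator()
        try:
            pa = self._separable(rng)
            plan = enm.split_dataset(pa, n_repeats=2, seed=0)
            with caplog.at_level(logging.WARNING):
                members = enm.fit_members(pa, plan, learners=("glm", "bad"),
                                          seed=0)
            assert all(m.learner_name == "glm" for m in members)
            assert any("bad" in r.message for r in caplog.records)
        finally:
            del enm.LEARNER_FACTORIES["bad"]

    def test_all_fail_raises(self, rng):
        class Broken:
            def fit(self, *a, **k):
                raise RuntimeError("nope")

        enm.LEARNER_FACTORIES["broken"] = lambda seed: Broken()
        try:
            pa = self._separable(rng)
            plan = enm.split_dataset(pa, n_repeats=2, seed=0)
            with pytest.raises(NicheShiftError, match="all member fits failed"):
                enm.fit_members(pa, plan, learners=("broken",), seed=0)
        finally:
            del enm.LEARNER_FACTORIES["broken"]


class TestEnsemble:
    class _Stub:
        def __init__(self, value):
            self.value = value

        def predict_suitability(self, X):
            return np.full(len(X), self.value)

    def _member(self, value, tss):
        scores = enm.EvalScores(auc=0.9, tss=tss, tss_threshold=0.5,
                                sensitivity=1, specificity=tss,
                                auc_band="excellent")
        return enm.MemberModel("stub", 0, self._Stub(value), scores)

    def test_single_member_identity(self):
        m = self._member(0.7, 0.5)
        ens = enm.build_ensemble([m])
        X = np.zeros((4, 2))
        np.testing.assert_allclose(ens.predict_suitability(X), 0.7)

    def test_equal_tss_arithmetic_mean(self):
        ens = enm.build_ensemble([self._member(0.2, 0.4),
                                  self._member(0.8, 0.4)])
        np.testing.assert_allclose(ens.predict_suitability(np.zeros((3, 2))), 0.5)

    def test_weights_spot_check(self):
        # TSS (0.6, 0.3, -0.1) -> weights (2/3, 1/3, 0)
        members = [self._member(0.9, 0.6), self._member(0.3, 0.3),
                   self._member(0.0, -0.1)]
        ens = enm.build_ensemble(members)
        expected = (2 / 3) * 0.9 + (1 / 3) * 0.3
        np.testing.assert_allclose(ens.predict_suitability(np.zeros((2, 2))),
                                   expected)
        assert len(ens.members) == 2

    def test_no_positive_tss(self):
        with pytest.raises(NicheShiftError):
            enm.build_ensemble([self._member(0.5, 0.0),
                                self._member(0.5, -0.2)])


class TestProjection:
    def _stack(self, a_values, b_values):
        return RasterStack(layers={
            "a": Raster(data=np.asarray(a_values, dtype=float), xll=0, yll=0,
                        cellsize=1.0),
            "b": Raster(data=np.asarray(b_values, dtype=float), xll=0, yll=0,
                        cellsize=1.0),
        })

    class _LinearModel:
        def predict_suitability(self, X):
            return 1 / (1 + np.exp(-(X[:, 0] - X[:, 1])))

    def test_constant_environment_constant_suitability(self):
        stack = self._stack(np.full((4, 4), 2.0), np.full((4, 4), 1.0))
        r = enm.project_suitability(self._LinearModel(), stack, ["a", "b"])
        assert np.unique(r.data).size == 1

    def test_pointwise_consistency(self, rng):
        a = rng.normal(size=(5, 6))
        b = rng.normal(size=(5, 6))
        stack = self._stack(a, b)
        r = enm.project_suitability(self._LinearModel(), stack, ["a", "b"])
        X = stack.table(["a", "b"])
        np.testing.assert_array_equal(
            r.data.ravel(), self._LinearModel().predict_suitability(X))

    def test_nodata_propagates(self, rng):
        a = rng.normal(size=(4, 4))
        a[1, 2] = -9999.0
        stack = self._stack(a, rng.normal(size=(4, 4)))
        r = enm.project_suitability(self._LinearModel(), stack, ["a", "b"])
        assert r.data[1, 2] == r.nodata

    def test_missing_layer(self, rng):
        stack = self._stack(rng.normal(size=(3, 3)), rng.normal(size=(3, 3)))
        with pytest.raises(NicheShiftError, match="missing"):
            enm.project_suitability(self._LinearModel(), stack, ["a", "c"])


class TestClamping:
    def test_target_inside_training(self, rng):
        train = pd.DataFrame({"a": [-2.0, 2.0], "b": [-2.0, 2.0]})
        target = pd.DataFrame(rng.uniform(-1, 1, size=(50, 2)),
                              columns=["a", "b"])
        rep = enm.clamping_mask(train, target)
        assert not rep.combined.any()
        assert rep.combined_fraction == 0.0

    def test_boundary_value_not_clamped(self):
        train = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        target = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
        rep = enm.clamping_mask(train, target)
        assert not rep.combined.any()

    def test_shifted_variable_fully_clamped(self, rng):
        train = pd.DataFrame({"a": rng.uniform(0, 1, 50),
                              "b": rng.uniform(0, 1, 50)})
        target = train.copy()
        target["a"] = target["a"] + 10.0
        rep = enm.clamping_mask(train, target)
        assert rep.fractions["a"] == 1.0
        assert rep.fractions["b"] == 0.0
        assert rep.combined_fraction == 1.0

    def test_mixed_case_matches_brute_force(self, rng):
        train = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        target = pd.DataFrame(rng.normal(0.5, 2.0, size=(80, 3)),
                              columns=list("abc"))
        rep = enm.clamping_mask(train, target)
        for v in "abc":
            lo, hi = train[v].min(), train[v].max()
            expected = np.array([(x < lo) or (x > hi) for x in target[v]])
            np.testing.assert_array_equal(rep.per_variable[v], expected)
            assert rep.fractions[v] == pytest.approx(expected.mean())

    def test_raster_target(self, rng):
        train = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        stack = RasterStack(layers={
            "a": Raster(data=np.array([[0.5, 2.0], [0.5, 0.5]]), xll=0, yll=0,
                        cellsize=1.0),
            "b": Raster(data=np.full((2, 2), 0.5), xll=0, yll=0, cellsize=1.0),
        })
        rep = enm.clamping_mask(train, stack)
        assert rep.per_variable["a"].shape == (2, 2)
        assert rep.per_variable["a"][0, 1]
        assert rep.combined_fraction == pytest.approx(0.25)

    def test_missing_variable(self, rng):
        train = pd.DataFrame({"a": [0.0, 1.0]})
        target = pd.DataFrame({"b": [0.5]})
        with pytest.raises(NicheShiftError):
            enm.clamping_mask(train, target, ["a"])
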