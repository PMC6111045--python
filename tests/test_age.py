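"""Clock prediction, calibration transform, deconvolution, KDM, IEAA/EEAA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import methylaccel as ma
from methylaccel.age import MAX_MISSING_CLOCK_FRACTION
from methylaccel.containers import CELL_TYPES, MethylAccelError
from methylaccel.synthetic import make_cell_reference


def _beta_matrix(beta: pd.DataFrame) -> ma.BetaMatrix:
    return ma.BetaMatrix(beta=beta, detection_p=beta * 0.0)


class TestAgeTransform:
    def test_anchor_point(self):
        assert ma.age_transform(20.0, 20.0) == 0.0
        assert ma.inverse_age_transform(0.0, 20.0) == 20.0

    @pytest.mark.parametrize("x", [1.0, 20.0, 80.0])
    def test_round_trip(self, x):
        assert ma.inverse_age_transform(ma.age_transform(x, 20.0), 20.0) == pytest.approx(x, abs=1e-10)

    def test_monotone_and_continuous_on_grid(self):
        grid = np.linspace(-0.9, 110, 3000)
        f = ma.age_transform(grid, 20.0)
        diffs = np.diff(f)
        assert (diffs > 0).all()            # strictly increasing
        assert diffs.max() < 0.5            # no jumps at the adult-age knee

    def test_rejects_age_at_or_below_minus_one(self):
        with pytest.raises(MethylAccelError):
            ma.age_transform(-1.0, 20.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=-0.99, max_value=120.0))
    def test_round_trip_property(self, x):
        assert ma.inverse_age_transform(ma.age_transform(x, 20.0), 20.0) == pytest.approx(x, abs=1e-8)


class TestPredictAge:
    def test_intercept_only_clock(self):
        beta = pd.DataFrame(np.random.default_rng(0).uniform(size=(5, 3)),
                            index=list("abcde"), columns=["p0", "p1", "p2"])
        clock = ma.ClockModel("c", 50.0, pd.Series([0.0], index=["p0"]))
        assert np.allclose(ma.predict_age(_beta_matrix(beta), clock), 50.0)

    def test_single_probe_arithmetic(self):
        beta = pd.DataFrame({"p0": [0.5]}, index=["s"])
        clock = ma.ClockModel("c", 40.0, pd.Series([10.0], index=["p0"]))
        assert ma.predict_age(_beta_matrix(beta), clock)["s"] == pytest.approx(45.0)

    def test_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(1)
        probes = [f"p{j}" for j in range(30)]
        beta = pd.DataFrame(rng.uniform(size=(20, 30)),
                            index=[f"s{i}" for i in range(20)], columns=probes)
        w = pd.Series(rng.normal(size=30), index=probes)
        clock = ma.ClockModel("c", 12.3, w)
        oracle = 12.3 + beta.to_numpy() @ w.to_numpy()
        assert np.abs(ma.predict_age(_beta_matrix(beta), clock).to_numpy() - oracle).max() < 1e-8

    def test_affine_in_betas_under_identity(self):
        rng = np.random.default_rng(2)
        probes = [f"p{j}" for j in range(10)]
        b1, b2 = rng.uniform(size=10), rng.uniform(size=10)
        lam = 0.3
        beta = pd.DataFrame([b1, b2, lam * b1 + (1 - lam) * b2],
                            index=["a", "b", "mix"], columns=probes)
        clock = ma.ClockModel("c", 5.0, pd.Series(rng.normal(size=10), index=probes))
        pred = ma.predict_age(_beta_matrix(beta), clock)
        assert pred["mix"] == pytest.approx(lam * pred["a"] + (1 - lam) * pred["b"], abs=1e-10)

    def test_refuses_too_many_missing_probes(self):
        rng = np.random.default_rng(3)
        probes = [f"p{j}" for j in range(10)]
        beta = pd.DataFrame(rng.uniform(size=(4, 10)), columns=probes)
        extra = [f"q{j}" for j in range(5)]  # 5/15 = 33% missing
        clock = ma.ClockModel("c", 0.0, pd.Series(1.0, index=probes + extra))
        assert MAX_MISSING_CLOCK_FRACTION == 0.20
        with pytest.raises(MethylAccelError):
            ma.predict_age(_beta_matrix(beta), clock)


@pytest.fixture(scope="module")
def ref():
    return make_cell_reference(np.random.default_rng(4))


class TestCellDeconvolution:

    def test_pure_sample_recovers_unit_proportion(self, ref):
        beta = pd.DataFrame([ref.reference_betas["NK"].to_numpy()],
                            index=["s"], columns=ref.probe_ids)
        props = ma.estimate_cell_proportions(_beta_matrix(beta), ref)
        assert props.loc["s", "NK"] == pytest.approx(1.0, abs=1e-6)
        assert props.drop(columns="NK").loc["s"].abs().max() < 1e-6

    def test_even_mixture_recovered_exactly(self, ref):
        mix = 0.5 * (ref.reference_betas["CD4+ T"] + ref.reference_betas["monocyte"])
        beta = pd.DataFrame([mix.to_numpy()], index=["s"], columns=ref.probe_ids)
        props = ma.estimate_cell_proportions(_beta_matrix(beta), ref)
        assert props.loc["s", "CD4+ T"] == pytest.approx(0.5, abs=1e-6)
        assert props.loc["s", "monocyte"] == pytest.approx(0.5, abs=1e-6)

    def test_noisy_mixtures_rmse_below_five_percent(self, ref):
        rng = np.random.default_rng(5)
        truth = rng.dirichlet(np.ones(7), size=100)
        beta = truth @ ref.reference_betas.to_numpy().T + rng.normal(0, 0.02, (100, len(ref.probe_ids)))
        beta = np.clip(beta, 0, 1)
        m = _beta_matrix(pd.DataFrame(beta, columns=ref.probe_ids))
        props = ma.estimate_cell_proportions(m, ref)
        rmse = np.sqrt(((props.to_numpy() - truth) ** 2).mean(axis=0))
        assert rmse.max() < 0.05

    def test_proportions_on_simplex(self, ref, small_cohort):
        props = ma.estimate_cell_proportions(small_cohort.methylation.data,
                                             small_cohort.cell_reference)
        assert (props.to_numpy() >= 0).all()
        assert np.abs(props.sum(axis=1) - 1.0).max() < 1e-6

    def test_rank_deficient_reference_refused(self, ref):
        dup = ref.reference_betas.copy()
        dup["NK"] = dup["CD4+ T"]
        bad = ma.CellReference.__new__(ma.CellReference)
        bad.reference_betas = dup
        beta = pd.DataFrame([dup["CD4+ T"].to_numpy()], columns=dup.index)
        with pytest.raises(MethylAccelError):
            ma.estimate_cell_proportions(_beta_matrix(beta), bad)


class TestIEAAandEEAA:
    def _toy(self, n=40, seed=6):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"s{i}" for i in range(n)])
        chron = pd.Series(rng.uniform(20, 80, n), index=idx)
        cells = pd.DataFrame(rng.dirichlet(np.ones(7) * 20, n),
                             index=idx, columns=list(CELL_TYPES))
        return chron, cells

    def test_identity_clock_gives_zero_ieaa(self):
        chron, cells = self._toy()
        ieaa = ma.compute_ieaa(chron.copy(), chron, cells)
        assert np.abs(ieaa).max() < 1e-8

    def test_residual_orthogonality(self):
        chron, cells = self._toy()
        rng = np.random.default_rng(7)
        clock_age = chron + pd.Series(rng.normal(0, 5, len(chron)), index=chron.index)
        ieaa = ma.compute_ieaa(clock_age, chron, cells)
        assert abs(np.corrcoef(ieaa, chron)[0, 1]) < 1e-8
        for ct in CELL_TYPES:
            assert abs(np.corrcoef(ieaa, cells[ct])[0, 1]) < 1e-6
        assert abs(ieaa.mean()) < 1e-8 * ieaa.std()

    def test_ieaa_matches_normal_equations_oracle(self):
        chron, cells = self._toy(n=10, seed=8)
        rng = np.random.default_rng(9)
        clock_age = chron + pd.Series(rng.normal(0, 3, 10), index=chron.index)
        ieaa = ma.compute_ieaa(clock_age, chron, cells)
        free = [c for c in CELL_TYPES if c != "granulocyte"]
        X = np.column_stack([np.ones(10), chron, cells[free]])
        beta = np.linalg.solve(X.T @ X, X.T @ clock_age.to_numpy())
        oracle = clock_age.to_numpy() - X @ beta
        assert np.abs(ieaa.to_numpy() - oracle).max() < 1e-10

    def test_eeaa_zero_for_affine_weighted_age(self):
        chron, _ = self._toy()
        weighted = 3.0 + 1.2 * chron
        eeaa = ma.compute_eeaa(weighted, chron)
        assert np.abs(eeaa).max() < 1e-8

    def test_eeaa_matches_simple_regression_oracle(self):
        chron, _ = self._toy(n=10, seed=10)
        rng = np.random.default_rng(11)
        weighted = chron + pd.Series(rng.normal(0, 4, 10), index=chron.index)
        eeaa = ma.compute_eeaa(weighted, chron)
        X = np.column_stack([np.ones(10), chron])
        beta = np.linalg.solve(X.T @ X, X.T @ weighted.to_numpy())
        assert np.abs(eeaa.to_numpy() - (weighted.to_numpy() - X @ beta)).max() < 1e-10

    def test_constant_age_rejected(self):
        idx = pd.Index(["a", "b", "c"])
        with pytest.raises(MethylAccelError):
            ma.compute_eeaa(pd.Series([1.0, 2.0, 3.0], index=idx),
                            pd.Series([50.0, 50.0, 50.0], index=idx))


class TestKDM:
    def test_exact_linear_biomarker(self):
        age = pd.Series(np.linspace(20, 80, 50), index=range(50))
        bio = pd.DataFrame({"b": 2.0 * age + 3.0})
        w = ma.fit_kdm_weights(bio, age)
        assert w.k[0] == pytest.approx(2.0, abs=1e-10)
        assert w.q[0] == pytest.approx(3.0, abs=1e-10)
        assert w.s[0] == pytest.approx(0.0, abs=1e-8)

    def test_constant_biomarker_rejected(self):
        age = pd.Series(np.linspace(20, 80, 50), index=range(50))
        with pytest.raises(MethylAccelError):
            ma.fit_kdm_weights(pd.DataFrame({"b": np.full(50, 7.0)}), age)

    def test_noisy_fit_matches_closed_form_ols(self):
        rng = np.random.default_rng(12)
        age = pd.Series(rng.uniform(20, 80, 200), index=range(200))
        y = 0.7 * age + 5.0 + rng.normal(0, 2.0, 200)
        w = ma.fit_kdm_weights(pd.DataFrame({"b": y}), age)
        a = age.to_numpy()
        k = np.cov(a, y, ddof=1)[0, 1] / np.var(a, ddof=1)
        q = y.mean() - k * a.mean()
        resid = y - (q + k * a)
        s = np.sqrt(resid @ resid / (200 - 2))
        assert w.k[0] == pytest.approx(k, abs=1e-10)
        assert w.q[0] == pytest.approx(q, abs=1e-10)
        assert w.s[0] == pytest.approx(s, abs=1e-10)

    def test_single_biomarker_closed_form(self):
        w = ma.KDMWeights(biomarkers=["b"], k=np.array([2.0]), q=np.array([3.0]),
                          s=np.array([1.5]))
        bio = pd.DataFrame({"b": [7.0, 11.0]})
        ba = ma.kdm_combine(bio, w)
        assert np.allclose(ba, (bio["b"] - 3.0) / 2.0, atol=1e-12)

    def test_consistent_biomarkers_fixed_point(self):
        w = ma.KDMWeights(biomarkers=list("abc"), k=np.array([1.0, -2.0, 0.5]),
                          q=np.array([0.0, 10.0, 1.0]), s=np.array([1.0, 2.0, 0.7]))
        b_true = 42.0
        bio = pd.DataFrame({c: [w.q[i] + w.k[i] * b_true] for i, c in enumerate("abc")})
        assert ma.kdm_combine(bio, w)[0] == pytest.approx(b_true, abs=1e-10)

    def test_four_biomarker_direct_formula_oracle(self):
        rng = np.random.default_rng(13)
        k = rng.uniform(0.5, 2.0, 4)
        q = rng.normal(0, 5, 4)
        s = rng.uniform(0.5, 3.0, 4)
        w = ma.KDMWeights(biomarkers=list("abcd"), k=k, q=q, s=s)
        X = rng.normal(50, 10, (6, 4))
        bio = pd.DataFrame(X, columns=list("abcd"))
        oracle = ((X - q) @ (k / s**2)) / np.sum(k**2 / s**2)
        assert np.abs(ma.kdm_combine(bio, w).to_numpy() - oracle).max() < 1e-12


class TestAccelerationTable:
    def test_noiseless_zero_acceleration_gives_zero_ieaa_eeaa(self, noiseless_parts):
        cfg, ped, pheno, truth, horvath, hannum, ref = noiseless_parts
        sim = ma.simulate_methylation(pheno, [horvath, hannum], ref, cfg, seed=9)
        acc = ma.compute_acceleration_table(sim.data, pheno["chronological_age"],
                                            horvath, hannum, ref)
        assert np.abs(acc["ieaa"]).max() < 1e-8
        assert np.abs(acc["eeaa"]).max() < 1e-8

    def test_ieaa_orthogonal_eeaa_tracks_cells(self, small_cohort):
        c = small_cohort
        m, _ = ma.run_qc(c.methylation.data, c.methylation.annotation, c.recorded_sex)
        acc = ma.compute_acceleration_table(m, c.phenotypes["chronological_age"],
                                            c.horvath_clock, c.hannum_clock,
                                            c.cell_reference)
        cells = ma.estimate_cell_proportions(m, c.cell_reference)
        assert abs(np.corrcoef(acc["ieaa"], acc["chronological_age"])[0, 1]) < 1e-8
        for ct in CELL_TYPES:
            assert abs(np.corrcoef(acc["ieaa"], cells.loc[acc.index, ct])[0, 1]) < 1e-6
        # EEAA keeps a material footprint of the age-drifting immune mixture
        naive_dev = (c.methylation.cell_truth.loc[acc.index, "naive CD8+ T"]
                     - (0.09 - 0.0010 * (acc["chronological_age"] - 50.0)))
        assert abs(np.corrcoef(acc["eeaa"], naive_dev)[0, 1]) > 0.05

    def test_clock_age_correlation_strong(self, small_cohort):
        c = small_cohort
        m, _ = ma.run_qc(c.methylation.data, c.methylation.annotation, c.recorded_sex)
        acc = ma.compute_acceleration_table(m, c.phenotypes["chronological_age"],
                                            c.horvath_clock, c.hannum_clock,
                                            c.cell_reference)
        assert np.corrcoef(acc["horvath_style_age"], acc["chronological_age"])[0, 1] > 0.9
        assert np.corrcoef(acc["hannum_style_age"], acc["chronological_age"])[0, 1] > 0.9
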