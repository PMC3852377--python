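import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linecrossqtl import line_origin as lo
from linecrossqtl import ls_scan as ls
from linecrossqtl import sim_cross as sc


@pytest.fixture(scope="module")
def std_preds(std_cross):
    cross, _ = std_cross
    probs = lo.line_origin_probs(cross, step_cM=5.0)
    return probs, ls.genetic_predictors(probs, cross)


class TestGeneticPredictors:
    def test_point_mass(self):
        cp = lo.ChromOriginProbs(positions=np.array([0.0]),
                                 probs=np.array([[[1.0, 0, 0, 0]], [[0, 0.25, 0.75, 0]]]))
        probs = lo.OriginProbTable(individuals=["i", "j"], states=lo.F2_STATES,
                                   cross_type="F2", step_cM=1.0, error_rate=0.0,
                                   chromosomes={"1": cp})
        preds = ls.genetic_predictors(probs)
        a, d = preds.at("1", 0.0)
        assert (a[0], d[0]) == (1.0, 0.0)
        assert (a[1], d[1]) == (0.0, 1.0)

    def test_uniform_prior(self):
        cp = lo.ChromOriginProbs(positions=np.array([0.0]),
                                 probs=np.full((1, 1, 4), 0.25))
        probs = lo.OriginProbTable(individuals=["i"], states=lo.F2_STATES,
                                   cross_type="F2", step_cM=1.0, error_rate=0.0,
                                   chromosomes={"1": cp})
        a, d = ls.genetic_predictors(probs).at("1", 0.0)
        assert (a[0], d[0]) == (0.0, 0.5)

    def test_consistency_with_truth(self, std_cross, std_preds):
        cross, truth = std_cross
        _, preds = std_preds
        tp = sc.true_predictors(truth, cross, "1", 50.0)
        a, d = preds.at("1", 50.0)
        ids = preds.individuals
        assert np.mean(np.abs(a - tp.loc[ids, "a"].to_numpy())) < 0.01
        assert np.mean(np.abs(d - tp.loc[ids, "d"].to_numpy())) < 0.01

    def test_invariant_bounds(self, std_preds):
        _, preds = std_preds
        cp = preds.chromosomes["1"]
        assert (np.abs(cp.a) + cp.d <= 1 + 1e-9).all()


class TestScanOne:
    def test_null_f_is_central(self):
        # with pure-noise phenotypes E[F] = df2 / (df2 - 2)
        fs = []
        for rep in range(200):
            cfg = sc.SimConfig(seed=1000 + rep, chromosomes=[("1", 20.0, 3, "autosome")],
                               n_offspring=60, residual_sd=1.0)
            cross, _ = sc.simulate_cross(cfg)
            probs = lo.line_origin_probs(cross, step_cM=10.0, validate=False)
            preds = ls.genetic_predictors(probs, cross)
            prof = ls.scan_one(cross, preds, "y")
            fs.append(prof.table["F"].iloc[1])
        df2 = 60 - 4  # mu + a + d dropped... mu,a,d -> p1 = 3
        df2 = 60 - 3
        expect = df2 / (df2 - 2)
        assert np.mean(fs) == pytest.approx(expect, abs=0.25)

    def test_perfect_fit_capped(self, std_cross):
        cross, truth = std_cross
        probs = lo.line_origin_probs(cross, step_cM=5.0, error_rate=0.0)
        preds = ls.genetic_predictors(probs, cross)
        tp = sc.true_predictors(truth, cross, "1", 0.0)  # marker at 0: fully informative
        ph = cross.phenotypes.copy()
        ph.loc[tp.index, "y"] = tp["a"].to_numpy()
        noiseless = type(cross)(pedigree=cross.pedigree, phenotypes=ph,
                                genotypes=cross.genotypes, gmap=cross.gmap,
                                cross_type=cross.cross_type)
        prof = ls.scan_one(noiseless, preds, "y")
        row = prof.table[prof.table["position"] == 0.0].iloc[0]
        assert row["F"] == ls.F_CAP
        assert row["flag"] == "perfect_fit"
        assert row["alpha"] == pytest.approx(1.0, abs=1e-6)
        assert row["delta"] == pytest.approx(0.0, abs=1e-6)

    def test_qtl_recovered(self, std_cross, std_preds):
        cross, _ = std_cross
        _, preds = std_preds
        prof = ls.scan_one(cross, preds, "y", ["sex"])
        chrom, pos, F = prof.argmax()
        assert abs(pos - 50.0) <= 10.0
        assert F > 10.0

    def test_affine_invariance(self, std_cross, std_preds):
        cross, _ = std_cross
        _, preds = std_preds
        prof1 = ls.scan_one(cross, preds, "y")
        ph = cross.phenotypes.copy()
        ph["y"] = 3.7 * ph["y"] - 11.0
        scaled = type(cross)(pedigree=cross.pedigree, phenotypes=ph,
                             genotypes=cross.genotypes, gmap=cross.gmap)
        prof2 = ls.scan_one(scaled, preds, "y")
        np.testing.assert_allclose(prof1.table["F"], prof2.table["F"], rtol=1e-8)

    def test_rank_deficient_d_column_dropped(self, std_cross):
        cross, _ = std_cross
        n = len(cross.offspring_ids)
        cp = lo.ChromOriginProbs(
            positions=np.array([0.0]),
            probs=np.tile(np.array([[1.0, 0.0, 0.0, 0.0]]), (n, 1, 1)))
        cp.probs[n // 2:, 0, :] = [0.0, 0.0, 0.0, 1.0]  # only homozygotes: d == 0
        probs = lo.OriginProbTable(individuals=list(cross.offspring_ids),
                                   states=lo.F2_STATES, cross_type="F2", step_cM=1.0,
                                   error_rate=0.0, chromosomes={"1": cp})
        preds = ls.genetic_predictors(probs)
        prof = ls.scan_one(cross, preds, "y")
        row = prof.table.iloc[0]
        assert row["flag"] == "columns_dropped"
        assert row["df1"] == 1
        assert np.isnan(row["delta"])

    def test_bc_single_df(self):
        cfg = sc.SimConfig(seed=31, chromosomes=[("1", 60.0, 13, "autosome")],
                           n_offspring=150, cross_type="BC",
                           qtl=[sc.QtlSpec("1", 30.0, a=0.6, d=0.0)])
        cross, _ = sc.simulate_cross(cfg)
        probs = lo.line_origin_probs(cross, step_cM=5.0)
        preds = ls.genetic_predictors(probs, cross)
        prof = ls.scan_one(cross, preds, "y")
        assert (prof.table["df1"] == 1).all()
        assert abs(prof.argmax()[1] - 30.0) <= 15.0

    def test_sex_chromosome_uses_homogametic_only(self, xcross_scan):
        cross, prof = xcross_scan
        n_homo = len(cross.homogametic_ids(cross.offspring_ids))
        x_rows = prof.table[prof.table["chromosome"] == "X"]
        # paternal origin is fixed on X, so a and d are collinear with the
        # intercept: one genetic column is dropped and df2 = n_homo - 2
        assert (x_rows["df2"] == n_homo - 2).all()
        assert (x_rows["df1"] == 1).all()
        assert (x_rows["flag"] == "columns_dropped").all()
        auto = prof.table[prof.table["chromosome"] == "1"]
        assert (auto["df2"] == len(cross.offspring_ids) - 3).all()


@pytest.fixture(scope="module")
def xcross_scan():
    cfg = sc.SimConfig(seed=8, chromosomes=[("1", 50.0, 6, "autosome"),
                                            ("X", 50.0, 6, "sex")], n_offspring=80)
    cross, _ = sc.simulate_cross(cfg)
    probs = lo.line_origin_probs(cross, step_cM=10.0)
    preds = ls.genetic_predictors(probs, cross)
    return cross, ls.scan_one(cross, preds, "y")


@pytest.fixture(scope="module")
def epi_cross():
    cfg = sc.SimConfig(seed=2, chromosomes=[("1", 50.0, 11, "autosome"),
                                            ("2", 50.0, 11, "autosome")],
                       n_offspring=800, residual_sd=1.0,
                       qtl=[sc.QtlSpec("1", 25.0, epistasis=(1, (1.0, 0, 0, 0))),
                            sc.QtlSpec("2", 25.0)])
    cross, _ = sc.simulate_cross(cfg)
    probs = lo.line_origin_probs(cross, step_cM=5.0)
    return cross, ls.genetic_predictors(probs, cross)


class TestEpistasis:
    def test_proximity_guard(self, epi_cross):
        cross, preds = epi_cross
        escan = ls.scan_two_epistasis(cross, preds, "y", pair_step_cM=10.0)
        same = escan.table[escan.table["chrom1"] == escan.table["chrom2"]]
        assert (np.abs(same["pos1"] - same["pos2"]) >= 20.0).all()

    def test_pure_epistasis_recovered(self, epi_cross):
        cross, preds = epi_cross
        escan = ls.scan_two_epistasis(cross, preds, "y", pair_step_cM=10.0)
        best = escan.argmax()
        assert {best["chrom1"], best["chrom2"]} == {"1", "2"}
        assert abs(best["pos1"] - 25.0) <= 10 and abs(best["pos2"] - 25.0) <= 10
        assert best["aa"] == pytest.approx(1.0, abs=0.2)
        # marginal scan shows nothing comparable
        prof = ls.scan_one(cross, preds, "y")
        assert prof.table["F"].max() < best["F"] / 3

    def test_null_interaction_f_central(self):
        fs = []
        for rep in range(60):
            cfg = sc.SimConfig(seed=4000 + rep, chromosomes=[("1", 20.0, 3, "autosome"),
                                                             ("2", 20.0, 3, "autosome")],
                               n_offspring=100, residual_sd=1.0)
            cross, _ = sc.simulate_cross(cfg)
            probs = lo.line_origin_probs(cross, step_cM=20.0, validate=False)
            preds = ls.genetic_predictors(probs, cross)
            escan = ls.scan_two_epistasis(cross, preds, "y", pair_step_cM=20.0)
            fs.extend(escan.table["F"].tolist())
        df2 = 100 - 9
        expect = df2 / (df2 - 2)
        assert np.mean(fs) == pytest.approx(expect, abs=0.2)


class TestPermutation:
    def test_quantile_arithmetic(self):
        dist = ls.PermutationDistribution(
            max_stats=np.array([1.0, 2.0, 3.0, 4.0]),
            thresholds={0.5: float(np.quantile([1.0, 2.0, 3.0, 4.0], 0.5))},
            n_perm=4, seed=0)
        assert dist.threshold(0.5) == 2.5

    def test_deterministic(self, std_cross, std_preds):
        cross, _ = std_cross
        _, preds = std_preds
        d1 = ls.permutation_thresholds(cross, preds, "y", n_perm=20, seed=5)
        d2 = ls.permutation_thresholds(cross, preds, "y", n_perm=20, seed=5)
        np.testing.assert_array_equal(d1.max_stats, d2.max_stats)
        assert d1.thresholds == d2.thresholds

    def test_thresholds_monotone(self, std_cross, std_preds):
        cross, _ = std_cross
        _, preds = std_preds
        d = ls.permutation_thresholds(cross, preds, "y", n_perm=100, seed=1,
                                      quantiles=[0.5, 0.9, 0.95])
        assert d.thresholds[0.5] <= d.thresholds[0.9] <= d.thresholds[0.95]

    def test_invalid_quantile(self, std_cross, std_preds):
        cross, _ = std_cross
        _, preds = std_preds
        with pytest.raises(ValueError):
            ls.permutation_thresholds(cross, preds, "y", n_perm=10, quantiles=[1.5])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_permutation_preserves_multiset(self, seed):
        y = np.arange(17, dtype=float)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(y)
        assert sorted(perm) == sorted(y)

    def test_qtl_signal_beats_threshold(self, std_cross, std_preds):
        cross, _ = std_cross
        _, preds = std_preds
        dist = ls.permutation_thresholds(cross, preds, "y", n_perm=100, seed=3)
        obs = ls.max_stat_scan_one(cross, preds, "y")
        assert obs[0] > dist.thresholds[0.95]


class TestIrrelevantCovariate:
    def test_rss_never_increases(self, std_cross, std_preds):
        cross, _ = std_cross
        _, preds = std_preds
        ph = cross.phenotypes.copy()
        rng = np.random.default_rng(0)
        ph["junk"] = rng.normal(size=len(ph))
        noisy = type(cross)(pedigree=cross.pedigree, phenotypes=ph,
                            genotypes=cross.genotypes, gmap=cross.gmap)
        p0 = ls.scan_one(noisy, preds, "y")
        p1 = ls.scan_one(noisy, preds, "y", ["junk"])
        rss0 = p0.table["resid_var"] * p0.table["df2"]
        rss1 = p1.table["resid_var"] * p1.table["df2"]
        assert (rss1 <= rss0 + 1e-9).all()
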