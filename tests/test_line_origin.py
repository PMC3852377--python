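import numpy as np
import pytest

from linecrossqtl import cross_data as cd
from linecrossqtl import line_origin as lo
from linecrossqtl import sim_cross as sc
from conftest import build_toy_cross


def _fb_vs_brute(cross, step=4.0, tol=1e-10):
    probs = lo.line_origin_probs(cross, step_cM=step)
    for chrom in cross.gmap.names:
        cp = probs.chromosomes[chrom]
        for iid in cross.offspring_ids:
            loci, marg = lo.brute_force_origin_posterior(cross, iid, chrom, step_cM=step)
            gi = [int(np.searchsorted(loci, p)) for p in cp.positions]
            fb = cp.probs[cross.offspring_ids.index(iid)]
            assert np.abs(fb - marg[gi]).max() < tol


class TestLineFreqs:
    def test_counting_formula(self, std_cross):
        cross, _ = std_cross
        freqs = lo.estimate_line_freqs(cross)
        m = cross.gmap.marker_names[0]
        # line A founders all 1/1, universe {1, 2}: freq = (2n + 0.5)/(2n + 1)
        n = len(cross.founders_of_line("A"))
        i = freqs.allele_index(m, 1)
        assert freqs.freq[m]["A"][i] == pytest.approx((2 * n + 0.5) / (2 * n + 1.0))

    def test_positivity(self, partial_cross):
        cross, _ = partial_cross
        freqs = lo.estimate_line_freqs(cross)
        for m in cross.gmap.marker_names:
            for line in "AB":
                assert (freqs.freq[m][line] > 0).all()
                assert freqs.freq[m][line].sum() == pytest.approx(1.0)

    def test_uniform_fallback_without_f0_data(self, std_cross):
        cross, _ = std_cross
        geno = cross.genotypes.copy()
        geno.loc[cross.founder_ids] = 0  # drop all founder genotypes
        blind = cd.CrossData(pedigree=cross.pedigree, phenotypes=cross.phenotypes,
                             genotypes=geno, gmap=cross.gmap)
        freqs = lo.estimate_line_freqs(blind)
        m = cross.gmap.marker_names[0]
        np.testing.assert_allclose(freqs.freq[m]["A"], freqs.freq[m]["B"])
        np.testing.assert_allclose(freqs.freq[m]["A"], 0.5)


class TestF1HomologDists:
    def test_fully_informative_point_mass(self, std_cross):
        cross, _ = std_cross
        freqs = lo.estimate_line_freqs(cross)
        hd = lo.infer_f1_homolog_dists(cross, freqs)
        m = cross.gmap.marker_names[0]
        for f1 in cross.f1_ids:
            h = hd.dists[f1][m]
            np.testing.assert_allclose(h[0], [1.0, 0.0])  # A homolog carries allele 1
            np.testing.assert_allclose(h[1], [0.0, 1.0])

    def test_bayes_over_phases(self):
        # F1 = {1,2}, both parents ungenotyped, freq(1|A)=0.9, freq(1|B)=0.1:
        # P(A-homolog = 1) = 0.81/0.82
        cross = build_toy_cross(genotyped=False)
        m = "m1"
        cross.genotypes.loc["F1s0", [m + "_1", m + "_2"]] = [1, 2]
        freqs = lo.LineFreqs(
            universe={mk: np.array([1, 2]) for mk in cross.gmap.marker_names},
            freq={mk: {"A": np.array([0.9, 0.1]), "B": np.array([0.1, 0.9])}
                  for mk in cross.gmap.marker_names})
        hd = lo.infer_f1_homolog_dists(cross, freqs)
        assert hd.dists["F1s0"][m][0][0] == pytest.approx(0.81 / 0.82)
        assert hd.dists["F1s0"][m][1][0] == pytest.approx(0.01 / 0.82)

    def test_missing_f1_genotype_gives_transmission_dists(self):
        cross = build_toy_cross(genotyped=True)  # founders genotyped, F1 not
        freqs = lo.estimate_line_freqs(cross)
        hd = lo.infer_f1_homolog_dists(cross, freqs)
        h = hd.dists["F1s0"]["m1"]
        i1 = freqs.allele_index("m1", 1)
        assert h[0][i1] == pytest.approx(1.0)  # A parent homozygous 1/1

    def test_non_mendelian_flagged(self):
        cross = build_toy_cross(genotyped=True)
        cross.genotypes.loc["F1s0", ["m1_1", "m1_2"]] = [1, 1]  # impossible: B parent is 2/2
        freqs = lo.estimate_line_freqs(cross)
        hd = lo.infer_f1_homolog_dists(cross, freqs)
        assert any("non-Mendelian" in f.message for f in hd.findings)


class TestLineOriginProbs:
    def test_prior_recovery_all_missing(self):
        cross = build_toy_cross(n_markers=3)
        probs = lo.line_origin_probs(cross, step_cM=5.0)
        cp = probs.chromosomes["1"]
        np.testing.assert_allclose(cp.probs, 0.25, atol=1e-12)

    def test_point_mass_at_informative_marker(self, std_cross):
        # fully informative markers pin the unordered class; the two ordered
        # heterozygote states are exchangeable (symmetric F1 parents) at 1/2
        cross, truth = std_cross
        probs = lo.line_origin_probs(cross, step_cM=5.0, error_rate=0.0)
        chrom = cross.gmap.chromosomes[0]
        pos = float(chrom.positions[4])  # a marker on the grid
        p = probs.probs_at("1", pos)
        for k, iid in enumerate(cross.offspring_ids[:30]):
            sp, sm = truth.origin_state(iid, "1", pos)
            if sp == sm:
                s = 0 if sp == "A" else 3
                assert p[k, s] == pytest.approx(1.0, abs=1e-9)
            else:
                assert p[k, 1] == pytest.approx(0.5, abs=1e-9)
                assert p[k, 2] == pytest.approx(0.5, abs=1e-9)

    def test_matches_enumeration_f2(self, partial_cross):
        cross, _ = partial_cross
        _fb_vs_brute(cross)

    def test_matches_enumeration_bc(self):
        cfg = sc.SimConfig(seed=6, chromosomes=[("1", 12.0, 4, "autosome")],
                           n_offspring=5, cross_type="BC",
                           allele_freqs={"A": {1: 0.6, 2: 0.4}, "B": {1: 0.3, 2: 0.7}})
        cross, _ = sc.simulate_cross(cfg)
        _fb_vs_brute(cross)

    def test_mirror_invariance(self, partial_cross):
        cross, _ = partial_cross
        chrom = cross.gmap.chromosomes[0]
        L = chrom.length
        mirrored_map = cd.GeneticMap([cd.ChromosomeMap(
            "1", "autosome", chrom.markers[::-1],
            np.array([L - p for p in chrom.positions[::-1]]))])
        mirrored = cd.CrossData(pedigree=cross.pedigree, phenotypes=cross.phenotypes,
                                genotypes=cross.genotypes, gmap=mirrored_map)
        p1 = lo.line_origin_probs(cross, step_cM=3.0)
        p2 = lo.line_origin_probs(mirrored, step_cM=3.0)
        g1 = p1.chromosomes["1"]
        for i, pos in enumerate(g1.positions):
            np.testing.assert_allclose(g1.probs[:, i, :],
                                       p2.probs_at("1", L - pos), atol=1e-9)

    def test_informative_markers_sharpen_posterior(self):
        scores = []
        for freqs in ({"A": {1: 1.0}, "B": {2: 1.0}},
                      {"A": {1: 0.8, 2: 0.2}, "B": {1: 0.2, 2: 0.8}},
                      {"A": {1: 1.0}, "B": {1: 1.0}}):
            cfg = sc.SimConfig(seed=21, chromosomes=[("1", 50.0, 11, "autosome")],
                               n_offspring=60, allele_freqs=freqs)
            cross, truth = sc.simulate_cross(cfg)
            probs = lo.line_origin_probs(cross, step_cM=10.0)
            cp = probs.chromosomes["1"]
            # posterior mass on the true unordered class (ordered heterozygote
            # states are exchangeable and cannot sharpen beyond 1/2 each)
            cls = np.stack([cp.probs[:, :, 0], cp.probs[:, :, 1] + cp.probs[:, :, 2],
                            cp.probs[:, :, 3]], axis=2)
            tot = []
            for k, iid in enumerate(cross.offspring_ids):
                for i, pos in enumerate(cp.positions):
                    sp, sm = truth.origin_state(iid, "1", float(pos))
                    c = 1 if sp != sm else (0 if sp == "A" else 2)
                    tot.append(cls[k, i, c])
            scores.append(np.mean(tot))
        assert scores[0] > scores[1] > scores[2]
        assert scores[0] > 0.99  # residual uncertainty only between markers

    def test_long_chromosome_is_finite(self):
        cfg = sc.SimConfig(seed=2, chromosomes=[("1", 100.0, 1000, "autosome")],
                           n_offspring=4)
        cross, _ = sc.simulate_cross(cfg)
        probs = lo.line_origin_probs(cross, step_cM=25.0)
        assert np.isfinite(probs.chromosomes["1"].probs).all()

    def test_bad_step_rejected(self, partial_cross):
        with pytest.raises(ValueError):
            lo.line_origin_probs(partial_cross[0], step_cM=0.0)

    def test_grid_includes_both_ends(self, std_cross):
        probs = lo.line_origin_probs(std_cross[0], step_cM=7.0)
        g = probs.chromosomes["1"].positions
        assert g[0] == 0.0 and g[-1] == 100.0


class TestSampler:
    def test_point_mass_paths_identical(self):
        # BC posteriors are point masses under fully informative markers
        # (no ordered-heterozygote ambiguity), so every sampled path agrees
        cfg = sc.SimConfig(seed=14, chromosomes=[("1", 60.0, 13, "autosome")],
                           n_offspring=40, cross_type="BC")
        cross, _ = sc.simulate_cross(cfg)
        rng = np.random.default_rng(0)
        paths = lo.sample_origin_paths(cross, 20, rng, "1", error_rate=0.0)
        first = paths.samples[:, :1, :]
        assert (paths.samples == first).all()

    def test_marginal_consistency(self, partial_cross):
        cross, _ = partial_cross
        rng = np.random.default_rng(3)
        n = 50_000
        paths = lo.sample_origin_paths(cross, n, rng, "1")
        chrom = cross.gmap.chromosomes[0]
        for iid in cross.offspring_ids[:3]:
            loci, marg = lo.brute_force_origin_posterior(cross, iid, "1")
            row = cross.offspring_ids.index(iid)
            for mpos in chrom.positions:
                st = paths.states_at(float(mpos))[row]
                emp = np.bincount(st, minlength=4) / n
                t = int(np.searchsorted(loci, round(float(mpos), 9)))
                se = np.sqrt(np.maximum(marg[t] * (1 - marg[t]), 1e-12) / n)
                assert (np.abs(emp - marg[t]) <= 3 * se + 1e-3).all()

    def test_deterministic_given_seed(self, partial_cross):
        cross, _ = partial_cross
        s1 = lo.sample_origin_paths(cross, 50, np.random.default_rng(9), "1")
        s2 = lo.sample_origin_paths(cross, 50, np.random.default_rng(9), "1")
        assert (s1.samples == s2.samples).all()

    def test_n_samples_validated(self, partial_cross):
        with pytest.raises(ValueError):
            lo.sample_origin_paths(partial_cross[0], 0, np.random.default_rng(0), "1")


class TestBruteForce:
    def test_uninformative_single_marker(self):
        cross = build_toy_cross(n_markers=2)
        loci, marg = lo.brute_force_origin_posterior(cross, "O1", "1")
        np.testing.assert_allclose(marg, 0.25, atol=1e-12)

    def test_normalized(self, partial_cross):
        cross, _ = partial_cross
        loci, marg = lo.brute_force_origin_posterior(cross, cross.offspring_ids[0], "1",
                                                     step_cM=4.0)
        np.testing.assert_allclose(marg.sum(axis=1), 1.0, atol=1e-12)

    def test_marker_cap(self, std_cross):
        cross, _ = std_cross
        with pytest.raises(ValueError, match="too many markers"):
            lo.brute_force_origin_posterior(cross, cross.offspring_ids[0], "1")


@pytest.fixture(scope="module")
def xcross():
    cfg = sc.SimConfig(seed=8, chromosomes=[("1", 50.0, 6, "autosome"),
                                            ("X", 50.0, 6, "sex")],
                       n_offspring=60)
    return sc.simulate_cross(cfg)


class TestSexChromosome:
    def test_heterogametic_get_nan(self, xcross):
        cross, _ = xcross
        probs = lo.line_origin_probs(cross, step_cM=10.0)
        px = probs.probs_at("X", 20.0)
        for i, iid in enumerate(probs.individuals):
            if cross.individual(iid).sex == "male":
                assert np.isnan(px[i]).all()
            else:
                assert np.isfinite(px[i]).all()

    def test_homogametic_posterior_matches_truth(self, xcross):
        cross, truth = xcross
        probs = lo.line_origin_probs(cross, step_cM=10.0)
        cp = probs.chromosomes["X"]
        for i, iid in enumerate(probs.individuals):
            if cross.individual(iid).sex != "female":
                continue
            for k, pos in enumerate(cp.positions):
                sp, sm = truth.origin_state(iid, "X", float(pos))
                s = "AB".index(sp) * 2 + "AB".index(sm)
                assert np.argmax(cp.probs[i, k]) == s
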