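import itertools
import math

import numpy as np
import pytest

from sfsdemog.gl import (
    GLMatrix,
    SAFMatrix,
    apply_site_filters,
    em_sfs,
    estimate_sfs,
    fold_saf_estimate,
    read_gl_tsv,
    saf_matrix,
    saf_per_site,
    write_gl_tsv,
)


def brute_force_saf(gl_site):
    """Enumerate all genotype configurations (oracle; n <= 5 only)."""
    n_ind = len(gl_site)
    n_chrom = 2 * n_ind
    out = np.zeros(n_chrom + 1)
    for config in itertools.product(range(3), repeat=n_ind):
        x = sum(config)
        weight = 1.0
        for j, g in enumerate(config):
            weight *= gl_site[j][g] * (2.0 if g == 1 else 1.0)
        out[x] += weight
    out /= [math.comb(n_chrom, x) for x in range(n_chrom + 1)]
    return out


class TestSiteFilters:
    def test_protocol_thresholds(self):
        # 70 individuals at depth 5: 350 total, 70 covered -> pass
        passing = np.full((1, 70), 5)
        assert apply_site_filters(passing).tolist() == [True]
        # 62 individuals at depth 10, 8 at zero: fails the 63-individual rule
        depths = np.zeros((1, 70), dtype=int)
        depths[0, :62] = 10
        assert apply_site_filters(depths).tolist() == [False]
        # everyone at 60x: pooled depth 4200 exceeds the 3600 cap
        too_deep = np.full((1, 70), 60)
        assert apply_site_filters(too_deep).tolist() == [False]

    def test_pooled_minimum(self):
        # covered count fine, but pooled depth below 315
        depths = np.full((1, 70), 4)
        assert apply_site_filters(depths, min_ind_depth=4).tolist() == [False]

    def test_min_ind_exceeding_sample_size(self):
        with pytest.raises(ValueError):
            apply_site_filters(np.ones((3, 10)), min_ind=11)


class TestSAF:
    def test_single_certain_heterozygote(self):
        saf = saf_per_site([[0.0, 1.0, 0.0]])
        assert np.allclose(saf / saf.max(), [0.0, 1.0, 0.0])

    def test_certain_genotypes_add(self):
        saf = saf_per_site([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        expected = np.zeros(5)
        expected[3] = 1.0
        assert np.allclose(saf / saf.max(), expected)

    @pytest.mark.parametrize("n_ind", [1, 2, 3, 5])
    def test_flat_likelihoods_give_constant_saf(self, n_ind):
        # with no information every sample frequency is equally likely
        saf = saf_per_site([[0.7, 0.7, 0.7]] * n_ind)
        assert np.allclose(saf, saf[0])

    @pytest.mark.parametrize("n_ind", [2, 3, 4])
    def test_matches_enumeration_oracle(self, rng, n_ind):
        for _ in range(5):
            gl_site = rng.random((n_ind, 3))
            ours = saf_per_site(gl_site)
            oracle = brute_force_saf(gl_site.tolist())
            assert np.allclose(ours / ours.sum(), oracle / oracle.sum(), atol=1e-12)

    def test_underflow_resistance(self, rng):
        # 70 individuals with tiny likelihood scales must not underflow
        gl = rng.random((3, 70, 3)) * 1e-30
        depth = np.full((3, 70), 10)
        saf = saf_matrix(GLMatrix(gl=gl, depth=depth))
        assert np.all(np.isfinite(saf.saf)) and np.all(saf.saf.max(axis=1) > 0)

    def test_all_zero_individual_rejected(self):
        with pytest.raises(ValueError):
            saf_per_site([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])


class TestEM:
    def test_certain_genotypes_collapse_to_counting(self):
        # sites with certain sample frequencies: EM = normalized counts
        freqs = [0, 0, 1, 3, 3, 3, 4]
        saf = np.zeros((len(freqs), 5))
        for s, x in enumerate(freqs):
            saf[s, x] = 1.0
        res = em_sfs(SAFMatrix(saf=saf, n_chromosomes=4))
        counts = np.bincount(freqs, minlength=5) / len(freqs)
        assert np.allclose(res.eta, counts, atol=1e-12)

    def test_single_site_first_iteration(self):
        # from a flat start, one E/M cycle lands on the normalized SAF vector
        # (further iterations sharpen toward the argmax, as mixture EM must)
        v = np.array([0.2, 0.5, 0.1, 0.15, 0.05])
        res = em_sfs(SAFMatrix(saf=v[None, :] / v.max(), n_chromosomes=4), max_iter=1)
        assert np.allclose(res.eta, v / v.sum(), atol=1e-12)
        long = em_sfs(SAFMatrix(saf=v[None, :] / v.max(), n_chromosomes=4), max_iter=500)
        assert np.all(np.diff(long.log_likelihoods) >= -1e-12)

    def test_matches_constrained_optimizer_oracle(self, rng):
        # mixed-certainty sites at 2n = 4; oracle: direct likelihood
        # maximization over the probability simplex
        from scipy.optimize import minimize

        saf = rng.random((3, 5))
        saf[0, :] = [1.0, 0.8, 0.01, 0.0, 0.0]
        saf[1, :] = [0.0, 0.3, 1.0, 0.3, 0.0]
        res = em_sfs(SAFMatrix(saf=saf, n_chromosomes=4), max_iter=5000, tol=1e-14)

        def neg_ll(z):
            eta = np.exp(z - z.max())
            eta /= eta.sum()
            return -np.log(saf @ eta + 1e-300).sum()

        best = min(
            (minimize(neg_ll, rng.normal(size=5), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
             for _ in range(4)),
            key=lambda r: r.fun,
        )
        eta_oracle = np.exp(best.x - best.x.max())
        eta_oracle /= eta_oracle.sum()
        assert np.allclose(res.eta, eta_oracle, atol=1e-3)

    def test_log_likelihood_monotone(self, rng):
        saf = rng.random((50, 9)) + 1e-3
        res = em_sfs(SAFMatrix(saf=saf, n_chromosomes=8), max_iter=200)
        assert np.all(np.diff(res.log_likelihoods) >= -1e-9)

    def test_iteration_cap_honored(self, rng):
        saf = rng.random((30, 9)) + 1e-3
        res = em_sfs(SAFMatrix(saf=saf, n_chromosomes=8), max_iter=3, tol=0.0)
        assert res.n_iter == 3 and not res.converged

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            em_sfs(SAFMatrix(saf=np.ones((0, 5)), n_chromosomes=4))


class TestFoldEstimate:
    def test_folding_rule_on_proportions(self):
        eta = np.array([10, 3, 2, 1, 4], dtype=float) / 20.0
        spectrum = fold_saf_estimate(eta, 20.0)
        assert np.allclose(spectrum.counts, [14.0, 4.0, 2.0])
        assert spectrum.folded and spectrum.total_sites == pytest.approx(20.0)

    def test_fractional_counts_allowed(self):
        eta = np.array([0.5, 0.25, 0.25])
        s = fold_saf_estimate(eta, 101.0)
        assert s.total_sites == pytest.approx(101.0)


class TestPipeline:
    def test_filter_report_totals(self, rng):
        n_sites, n_ind = 200, 10
        gl = rng.random((n_sites, n_ind, 3)) + 0.1
        depth = rng.poisson(8, size=(n_sites, n_ind))
        gl[depth == 0] = 1.0
        glm = GLMatrix(gl=gl, depth=depth)
        _, report = estimate_sfs(
            glm, min_ind=8, min_total_depth=20, max_total_depth=500, min_ind_depth=2
        )
        assert report["n_sites_retained"] + report["n_sites_removed"] == n_sites
        assert report["n_sites_retained"] > 0


class TestGLMatrixIO:
    def test_round_trip(self, tmp_path, rng):
        gl = rng.random((4, 3, 3)) + 0.01
        depth = rng.poisson(6, size=(4, 3))
        gl[depth == 0] = 1.0
        glm = GLMatrix(gl=gl, depth=depth)
        path = tmp_path / "gl.tsv"
        write_gl_tsv(glm, path)
        back = read_gl_tsv(path)
        assert np.allclose(back.gl, glm.gl)
        assert np.array_equal(back.depth, glm.depth)

    def test_missing_row_detected(self, tmp_path):
        path = tmp_path / "gl.tsv"
        path.write_text(
            "# n_sites=2 n_individuals=1\n"
            "site_id\tindividual_id\tdepth\tgl0\tgl1\tgl2\n"
            "0\t0\t5\t1.0\t0.5\t0.1\n"
        )
        with pytest.raises(ValueError, match="missing row"):
            read_gl_tsv(path)

    def test_validation_rejects_negative_gl(self):
        with pytest.raises(ValueError):
            GLMatrix(gl=-np.ones((1, 1, 3)), depth=np.ones((1, 1)))
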