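"""Component matching, thresholding, agreement plots, cutdown, pipeline."""

import copy

import numpy as np
import pytest
from scipy.stats import pearsonr

import msiagree as ma
from msiagree.agreement import AgreementPlot, MatchResult

from conftest import make_reduced


def cfg(**kw):
    return ma.AgreementConfig(**kw)


# ---------------------------------------------------------------------------
# unfolded_pearson
# ---------------------------------------------------------------------------

class TestUnfoldedPearson:
    def test_self_correlation_is_one(self):
        v = np.array([1.0, 5.0, 2.0, 8.0])
        assert ma.unfolded_pearson(v, v) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        v = np.array([1.0, 5.0, 2.0, 8.0])
        assert ma.unfolded_pearson(v, -v) == pytest.approx(-1.0)

    def test_literal_example(self):
        r = ma.unfolded_pearson(np.array([1.0, 2.0, 3.0]),
                                np.array([1.0, 2.0, 4.0]))
        assert r == pytest.approx(0.98198, abs=1e-5)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.random(30), rng.random(30)
            assert ma.unfolded_pearson(a, b) == \
                pytest.approx(pearsonr(a, b).statistic, abs=1e-12)

    def test_zero_variance_defined_as_zero(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r = ma.unfolded_pearson(np.ones(5), np.arange(5.0))
        assert r == 0.0


# ---------------------------------------------------------------------------
# threshold_image
# ---------------------------------------------------------------------------

class TestThresholdImage:
    def test_forty_percent_rule(self):
        out = ma.threshold_image(np.array([0.0, 2.0, 5.0, 10.0]), 0.4)
        assert out.tolist() == [0.0, 0.0, 1.0, 1.0]  # 5 > 4, 2 <= 4

    def test_constant_positive_image_all_ones(self):
        out = ma.threshold_image(np.full(6, 3.0), 0.4)
        assert np.all(out == 1.0)

    def test_all_zero_image_warns(self):
        with pytest.warns(UserWarning, match="non-positive"):
            out = ma.threshold_image(np.zeros(4), 0.4)
        assert np.all(out == 0.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        for frac in (0.1, 0.4, 0.9):
            img = rng.random(50)
            out = ma.threshold_image(img, frac)
            oracle = np.array([1.0 if v > frac * img.max() else 0.0
                               for v in img])
            assert np.array_equal(out, oracle)


# ---------------------------------------------------------------------------
# match_components
# ---------------------------------------------------------------------------

def _component_set(method, scores, sign_definite=None):
    k = scores.shape[1]
    return ma.ComponentSet(
        method=method, scores=scores,
        loadings=np.abs(np.random.default_rng(0).random((k, 5))) + 0.1,
        sign_definite=(method not in ("pca", "maf"))
        if sign_definite is None else sign_definite)


class TestMatchComponents:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.scores = np.clip(rng.normal(1, 1, (40, 4)), 0, None)

    def test_identical_set_matches_itself(self):
        t = _component_set("nnmf", self.scores)
        o = _component_set("plsa", self.scores.copy())
        for idx in range(4):
            m = ma.match_components(t, [o], cfg(top_k=4), idx)
            assert m.matched["plsa"][0] == idx
            assert m.matched["plsa"][1] == pytest.approx(1.0)

    def test_permutation_recovered(self):
        perm = [2, 0, 3, 1]
        t = _component_set("nnmf", self.scores)
        o = _component_set("plsa", self.scores[:, perm])
        for idx in range(4):
            m = ma.match_components(t, [o], cfg(top_k=4), idx)
            assert perm[m.matched["plsa"][0]] == idx

    def test_negated_sign_indefinite_matched_with_flip(self):
        t = _component_set("nnmf", self.scores)
        o = _component_set("pca", -self.scores)
        for idx in range(4):
            m = ma.match_components(t, [o], cfg(top_k=4), idx)
            j, r, flip = m.matched["pca"]
            assert j == idx
            assert abs(r) == pytest.approx(1.0)

    def test_differing_pixel_sets_rejected(self):
        t = _component_set("nnmf", self.scores)
        o = _component_set("plsa", self.scores[:-1])
        with pytest.raises(ValueError, match="pixel"):
            ma.match_components(t, [o], cfg(top_k=4), 0)


# ---------------------------------------------------------------------------
# build_agreement
# ---------------------------------------------------------------------------

def _plots_from_binary_stack(stack):
    """Assemble component sets whose thresholded images equal the given
    binary masks, then build the agreement plot with nnmf as template."""
    methods = ["nnmf", "pca", "maf", "fcm", "plsa"]
    comps = {m: _component_set(m, stack[i][:, None].astype(float))
             for i, m in enumerate(methods)}
    match = MatchResult(template=("nnmf", 0),
                        matched={m: (0, 1.0, False) for m in methods[1:]})
    return ma.build_agreement(match, comps, cfg())


class TestBuildAgreement:
    def test_five_identical_masks_give_five_times_mask(self):
        mask = np.array([1.0, 0, 1, 0, 1, 1, 0, 0])
        plot = _plots_from_binary_stack([mask] * 5)
        assert np.array_equal(plot.image, 5 * mask)

    def test_disjoint_masks_max_one(self):
        masks = [np.eye(5)[i] for i in range(5)]
        plot = _plots_from_binary_stack(masks)
        assert plot.image.max() == 1.0

    def test_random_stack_equals_per_pixel_sum_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            stack = [rng.integers(0, 2, 12).astype(float) for _ in range(5)]
            stack = [s if s.max() > 0 else s + 1 for s in stack]
            plot = _plots_from_binary_stack(stack)
            oracle = np.sum(stack, axis=0)
            assert np.array_equal(plot.image, oracle)

    def test_consensus_spectrum_max_is_one(self, small_agreement):
        _norm, _truth, plots, _comps = small_agreement
        for plot in plots:
            assert plot.consensus_spectrum.max() == pytest.approx(1.0)

    def test_agreement_values_bounded_by_method_count(self, small_agreement):
        _norm, _truth, plots, _comps = small_agreement
        for plot in plots:
            assert plot.image.min() >= 0
            assert plot.image.max() <= 5
            assert np.array_equal(plot.image, np.round(plot.image))
            assert plot.continuous_image.min() >= 0
            assert plot.continuous_image.max() <= 5


# ---------------------------------------------------------------------------
# cutdown
# ---------------------------------------------------------------------------

def _fake_plot(image, rank_key, mean_r=0.9):
    image = np.asarray(image, dtype=float)
    return AgreementPlot(image=np.round(image), continuous_image=image,
                         match=MatchResult(template=("nnmf", 0), matched={}),
                         consensus_spectrum=np.ones(3), rank_key=rank_key,
                         mean_match_r=mean_r)


def _cutdown_oracle(plots, corr):
    """Independent brute-force re-implementation of the greedy rule."""
    order = sorted(range(len(plots)),
                   key=lambda i: (-plots[i].rank_key, -plots[i].mean_match_r,
                                  i))
    kept = []
    for i in order:
        ok = True
        for j in kept:
            r = pearsonr(plots[i].continuous_image,
                         plots[j].continuous_image).statistic
            if r > corr:
                ok = False
        if ok:
            kept.append(i)
    return [plots[i] for i in kept]


class TestCutdown:
    def test_identical_plots_collapse_to_one(self):
        img = np.array([1.0, 2, 3, 4])
        plots = [_fake_plot(img, 4), _fake_plot(img, 3)]
        kept = ma.cutdown(plots, cfg())
        assert len(kept) == 1
        assert kept[0].rank_key == 4

    def test_uncorrelated_plots_all_survive(self):
        rng = np.random.default_rng(4)
        plots = [_fake_plot(rng.random(100), 4 - i) for i in range(4)]
        kept = ma.cutdown(plots, cfg())
        assert len(kept) == 4

    def test_constructed_triple(self):
        """A ~ B (r > 0.7), C independent, A ranked above B -> {A, C}."""
        rng = np.random.default_rng(5)
        a = rng.random(60)
        b = a + rng.normal(0, 0.1, 60)  # r ~ 0.95
        c = rng.random(60)
        assert pearsonr(a, b).statistic > 0.9
        plots = [_fake_plot(a, 4, 0.9), _fake_plot(b, 3, 0.8),
                 _fake_plot(c, 2, 0.7)]
        kept = ma.cutdown(plots, cfg())
        assert [np.array_equal(k.continuous_image, v)
                for k, v in zip(kept, (a, c))] == [True, True]

    def test_greedy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(6)
        for trial in range(10):
            base = rng.random((3, 80))
            plots = []
            for i in range(6):
                img = base[i % 3] + rng.normal(0, rng.uniform(0.05, 2.0), 80)
                plots.append(_fake_plot(img, int(rng.integers(0, 6)),
                                        float(rng.random())))
            kept = ma.cutdown(plots, cfg())
            oracle = _cutdown_oracle(plots, 0.70)
            assert len(kept) == len(oracle)
            for k, o in zip(kept, oracle):
                assert np.array_equal(k.continuous_image, o.continuous_image)

    def test_empty_input(self):
        assert ma.cutdown([], cfg()) == []


# ---------------------------------------------------------------------------
# run_agreement end-to-end
# ---------------------------------------------------------------------------

def _jaccard(a, b):
    a, b = a > 0, b > 0
    union = np.sum(a | b)
    return np.sum(a & b) / union if union else 0.0


class TestRunAgreement:
    def test_requires_tic_normalization(self, small_phantom):
        reduced, _ = small_phantom
        with pytest.raises(ValueError, match="TIC"):
            ma.run_agreement(reduced, cfg())

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_single_region_phantom_recovered(self, seed):
        spec = ma.default_nodule_spec(seed, n_features=60, n_regions=1,
                                      grid_shape=(24, 32))
        reduced, truth = ma.generate_reduced_phantom(spec, n_features=60)
        norm, _ = ma.tic_normalize(reduced)
        plots, _ = ma.run_agreement(norm, cfg(seed=seed))
        mask = truth.region_masks[0][norm.pixels[:, 1], norm.pixels[:, 0]]
        best = max(_jaccard(p.image >= 4, mask) for p in plots)
        assert best > 0.8

    def test_identical_profiles_not_separated(self):
        """Negative control: two regions with the same spectral panel must
        not be isolated from each other by any surviving plot."""
        ny, nx = 24, 32
        pixels = np.array([(x, y) for y in range(ny) for x in range(nx)])
        m_a = ma.EllipseRegion(8, 8, 4, 4).mask((ny, nx))
        m_b = ma.EllipseRegion(24, 16, 4, 4).mask((ny, nx))
        rng = np.random.default_rng(31)
        matrix = np.full((len(pixels), 40), 20.0)
        panel_cols = [5, 12, 20, 33]
        in_a = m_a[pixels[:, 1], pixels[:, 0]]
        in_b = m_b[pixels[:, 1], pixels[:, 0]]
        for c in panel_cols:  # identical profile in both regions
            matrix[in_a | in_b, c] += 80.0
        matrix += rng.normal(0, 2.0, matrix.shape)
        data = make_reduced(np.clip(matrix, 0, None), grid_cols=nx)
        norm, _ = ma.tic_normalize(data)
        plots, _ = ma.run_agreement(norm, cfg(seed=31))
        for plot in plots:
            level = plot.image >= 4
            cov_a = np.sum(level & in_a) / in_a.sum()
            cov_b = np.sum(level & in_b) / in_b.sum()
            isolates = (cov_a > 0.5 and cov_b < 0.1) or \
                (cov_b > 0.5 and cov_a < 0.1)
            assert not isolates

    def test_method_order_permutation_invariant(self, small_phantom):
        reduced, _ = small_phantom
        norm, _ = ma.tic_normalize(reduced)
        p1, _ = ma.run_agreement(norm, cfg(seed=7))
        p2, _ = ma.run_agreement(
            norm, cfg(seed=7, methods=("plsa", "maf", "pca", "fcm", "nnmf")))
        imgs1 = sorted(tuple(p.image) for p in p1)
        imgs2 = sorted(tuple(p.image) for p in p2)
        assert imgs1 == imgs2

    def test_sign_invariance_end_to_end(self, small_agreement):
        """Negating a PCA/MAF component leaves surviving plots unchanged."""
        norm, _truth, plots, comps = small_agreement
        flipped = {m: copy.deepcopy(c) for m, c in comps.items()}
        for method in ("pca", "maf"):
            flipped[method].scores[:, 0] *= -1
            flipped[method].loadings[0] *= -1
        plots2, _ = ma.run_agreement(norm, cfg(seed=7), components=flipped)
        assert len(plots) == len(plots2)
        for a, b in zip(plots, plots2):
            assert np.array_equal(a.image, b.image)
            assert np.allclose(a.continuous_image, b.continuous_image)

    def test_threshold_monotonicity(self, small_agreement):
        """Raising the intensity threshold never raises agreement values."""
        norm, _truth, _plots, comps = small_agreement
        lo, _ = ma.run_agreement(
            norm, cfg(seed=7, intensity_threshold_frac=0.3), components=comps)
        hi, _ = ma.run_agreement(
            norm, cfg(seed=7, intensity_threshold_frac=0.6), components=comps)
        # compare per template: cutdown order can differ, so rebuild raw sums
        others = {m: comps[m] for m in cfg().methods}
        for method in cfg().methods:
            t = comps[method]
            rest = [comps[m] for m in cfg().methods if m != method]
            for idx in range(min(8, t.k)):
                match = ma.match_components(t, rest, cfg(), idx)
                p_lo = ma.build_agreement(
                    match, comps, cfg(intensity_threshold_frac=0.3))
                p_hi = ma.build_agreement(
                    match, comps, cfg(intensity_threshold_frac=0.6))
                assert np.all(p_hi.image <= p_lo.image)

    def test_deterministic_under_fixed_seed(self, small_phantom):
        reduced, _ = small_phantom
        norm, _ = ma.tic_normalize(reduced)
        p1, _ = ma.run_agreement(norm, cfg(seed=5))
        p2, _ = ma.run_agreement(norm, cfg(seed=5))
        assert len(p1) == len(p2)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.image, b.image)
            assert np.array_equal(a.consensus_spectrum, b.consensus_spectrum)


# ---------------------------------------------------------------------------
# cross-validated agreement
# ---------------------------------------------------------------------------

class TestCrossValidation:
    def _replicates(self, n, identical=True):
        """Replicate 'patients' sharing the planted panels; ``identical``
        replicates carry the same noise realization too."""
        import dataclasses

        base = ma.default_nodule_spec(50, n_features=40, n_regions=1,
                                      grid_shape=(16, 20))
        out = []
        for i in range(n):
            spec = dataclasses.replace(base,
                                       seed=50 if identical else 50 + i,
                                       dataset_id=f"patient_{i}")
            red, _ = ma.generate_reduced_phantom(spec, n_features=40)
            out.append(red)
        return out

    def test_k_equal_n_is_leave_one_out(self):
        data = self._replicates(3)
        sim = ma.cross_validated_agreement(
            data, k=3, seed=0,
            config=cfg(seed=0, top_k=4, methods=("pca", "nnmf", "fcm")))
        assert sim.shape == (3, 3)
        assert np.allclose(np.diag(sim), 1.0)

    def test_replicate_phantoms_agree_across_folds(self):
        # folds i and j share the datasets of every other group, so
        # k >= 3 is needed for cross-fold comparison to be defined
        data = self._replicates(4)
        sim = ma.cross_validated_agreement(
            data, k=3, seed=1,
            config=cfg(seed=1, top_k=4, methods=("pca", "nnmf", "fcm")))
        off = sim[~np.eye(3, dtype=bool)]
        assert np.all(off[~np.isnan(off)] > 0.9)
        assert np.sum(~np.isnan(off)) >= 4

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            ma.cross_validated_agreement(self._replicates(2), k=1, seed=0)

    def test_fold_assignment_deterministic(self):
        data = self._replicates(4)
        kw = dict(k=3, seed=3,
                  config=cfg(seed=3, top_k=4, methods=("pca", "nnmf", "fcm")))
        s1 = ma.cross_validated_agreement(data, **kw)
        s2 = ma.cross_validated_agreement(data, **kw)
        assert np.array_equal(s1, s2, equal_nan=True)
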