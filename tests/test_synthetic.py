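import numpy as np
import pytest
from scipy import ndimage

from tracescore.scoring import ScoringConfig, proportion_correct, score_traces
from tracescore.stimuli import NoiseSpec, StimulusSpec, rms_contrast
from tracescore.synthetic import (
    ObserverModel,
    condition_cells,
    generate_design,
    make_scene,
    noise_spec_from_label,
    simulate_observer,
)

SIX_FAMILIES = ["white", "pink", "brown", "narrowband-0.5", "narrowband-3", "narrowband-9"]


def saturated_observer(seed=0, **kw):
    """An observer that always sees and never errs."""
    defaults = dict(jitter_sd=0.0, omission_mu=-1e3, omission_sigma=1.0,
                    fa_rate=0.0, detail_level=1.0, seed=seed)
    defaults.update(kw)
    return ObserverModel(**defaults)


class TestMakeScene:
    def test_no_shapes_uniform(self):
        sc = make_scene(0, size_px=64, seed=1, horizon=False)
        assert np.ptp(sc.scene.values) == 0
        assert sc.true_edges.n_traced == 0

    def test_single_shape_boundary_one_component(self):
        for seed in range(5):
            sc = make_scene(1, size_px=128, seed=seed, horizon=False)
            _, n_comp = ndimage.label(sc.true_edges.mask, structure=np.ones((3, 3)))
            assert n_comp == 1

    def test_deterministic(self):
        a = make_scene(5, size_px=96, seed=42)
        b = make_scene(5, size_px=96, seed=42)
        np.testing.assert_array_equal(a.scene.values, b.scene.values)
        np.testing.assert_array_equal(a.true_edges.mask, b.true_edges.mask)

    def test_luminance_sd_scales_linearly_with_amplitude(self):
        # the rendering is affine in the amplitudes, so the luminance SD
        # (and the contrast about the ground level) doubles exactly
        lo = make_scene(4, size_px=128, seed=7, contrast_range=(0.1, 0.3), horizon=False)
        hi = make_scene(4, size_px=128, seed=7, contrast_range=(0.2, 0.6), horizon=False)
        assert hi.scene.values.std() == pytest.approx(2 * lo.scene.values.std(), rel=1e-9)

    def test_edges_lie_on_discontinuities(self):
        # every true-edge pixel has a 4-neighbor with a different luminance
        sc = make_scene(6, size_px=128, seed=3)
        v = sc.scene.values
        diff = np.zeros_like(v)
        for axis, shift in [(0, 1), (0, -1), (1, 1), (1, -1)]:
            diff = np.maximum(diff, np.abs(v - np.roll(v, shift, axis=axis)))
        assert np.all(diff[sc.true_edges.mask] > 0)

    def test_edge_owner_consistent(self):
        sc = make_scene(6, size_px=128, seed=3)
        assert set(np.unique(sc.edge_owner[sc.true_edges.mask])) <= {s.label for s in sc.shapes}
        assert sum(s.n_boundary_px for s in sc.shapes) >= sc.true_edges.n_traced


class TestSimulateObserver:
    def test_noiseless_observer_reproduces_truth(self):
        sc = make_scene(5, size_px=128, seed=2)
        tm = simulate_observer(sc, StimulusSpec(0.16), saturated_observer())
        np.testing.assert_array_equal(tm.mask, sc.true_edges.mask)

    def test_deterministic_per_trial(self):
        sc = make_scene(5, size_px=128, seed=2)
        model = ObserverModel(jitter_sd=2.0, fa_rate=100.0, seed=4)
        spec = StimulusSpec(0.1, NoiseSpec("pink", 0.1, seed=0))
        a = simulate_observer(sc, spec, model, masking_strength=3.0, trial_id=9)
        b = simulate_observer(sc, spec, model, masking_strength=3.0, trial_id=9)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_uniform_omission_hit_rate(self):
        # saturate contrast so p_draw = q for every segment, check pixel-level
        # hit rate across seeds against 1 - omission
        q_omit = 0.4
        sc = make_scene(10, size_px=128, seed=6, horizon=False)
        from scipy.stats import norm
        # choose mu so that Phi((c_eff - mu)/sigma) = 1 - q_omit for all segments:
        # use a huge sigma so amplitude variation is negligible
        sigma = 1e6
        mu = -sigma * norm.ppf(1 - q_omit)
        rates = []
        for seed in range(40):
            model = ObserverModel(jitter_sd=0, omission_mu=mu, omission_sigma=sigma,
                                  fa_rate=0, detail_level=1.0, seed=seed)
            tm = simulate_observer(sc, StimulusSpec(0.2), model)
            rates.append(tm.mask[sc.true_edges.mask].mean())
        assert np.mean(rates) == pytest.approx(1 - q_omit, abs=0.06)

    def test_jitter_scored_better_with_margin(self):
        sc = make_scene(6, size_px=256, seed=8)
        model = saturated_observer(jitter_sd=3.0, seed=11)
        tm = simulate_observer(sc, StimulusSpec(0.16), model)
        p13 = proportion_correct(score_traces(sc.true_edges, tm, ScoringConfig(margin_px=13)))
        p0 = proportion_correct(score_traces(sc.true_edges, tm, ScoringConfig(margin_px=0)))
        assert p13 > p0

    def test_false_traces_budget(self):
        sc = make_scene(0, size_px=256, seed=1, horizon=False)  # empty truth
        counts = []
        for seed in range(20):
            model = ObserverModel(fa_rate=300.0, seed=seed,
                                  omission_mu=1e3, omission_sigma=1.0)
            counts.append(simulate_observer(sc, StimulusSpec(0.1), model).n_traced)
        assert np.mean(counts) == pytest.approx(300.0, rel=0.1)

    def test_fa_strokes_are_extended_not_salt_and_pepper(self):
        sc = make_scene(0, size_px=256, seed=1, horizon=False)
        model = ObserverModel(fa_rate=400.0, seed=3, omission_mu=1e3, omission_sigma=1.0)
        tm = simulate_observer(sc, StimulusSpec(0.1), model)
        labeled, n_comp = ndimage.label(tm.mask, structure=np.ones((3, 3)))
        assert tm.n_traced / max(n_comp, 1) > 5  # pixels per connected stroke

    def test_contrast_dependent_fa(self):
        sc = make_scene(0, size_px=256, seed=1, horizon=False)
        model = ObserverModel(fa_rate=400.0, fa_contrast_slope=4.0, seed=5,
                              omission_mu=1e3, omission_sigma=1.0)
        low = simulate_observer(sc, StimulusSpec(0.01), model, trial_id=0)
        high = simulate_observer(sc, StimulusSpec(0.24), model, trial_id=0)
        assert low.n_traced > high.n_traced

    def test_masking_reduces_tracing(self):
        sc = make_scene(8, size_px=128, seed=9, horizon=False)
        model = ObserverModel(omission_mu=0.06, omission_sigma=0.01, seed=2)
        spec = StimulusSpec(0.08, NoiseSpec("pink", 0.1, seed=0))
        unmasked = simulate_observer(sc, spec, model, masking_strength=0.0)
        masked = simulate_observer(sc, spec, model, masking_strength=20.0)
        assert masked.n_traced <= unmasked.n_traced

    def test_within_exceeds_between_consistency(self):
        # observers share parameters but differ in persistent seeds
        sc = make_scene(10, size_px=128, seed=12)
        cfg = ScoringConfig(margin_fraction=0.025)
        spec_gt = StimulusSpec(0.16)
        spec_hi = StimulusSpec(0.14)
        models = [ObserverModel(omission_mu=0.07, omission_sigma=0.03,
                                detail_level=0.7, seed=s) for s in range(8)]
        gts = [simulate_observer(sc, spec_gt, m, trial_id=0) for m in models]
        noisy = [simulate_observer(sc, spec_hi, m, trial_id=1) for m in models]
        within = np.mean([
            proportion_correct(score_traces(g, n, cfg)) for g, n in zip(gts, noisy)
        ])
        between = np.mean([
            proportion_correct(score_traces(gts[i], gts[j], cfg))
            for i in range(len(gts)) for j in range(len(gts)) if i != j
        ])
        assert within >= between


class TestEndToEnd:
    def test_visibility_midpoint_recovered_within_ten_percent(self):
        # unit amplitudes make the pooled curve midpoint equal the injected
        # visibility-link midpoint; median over replicate experiments < 10%
        from tracescore.synthetic import end_to_end_recovery

        mu_true = 0.05
        errs = []
        for rep_seed in range(5):
            rep = end_to_end_recovery(
                {"white": 0.0}, list(np.geomspace(0.02, 0.15, 5)),
                n_observers=8, n_images=10, size_px=128,
                model=ObserverModel(jitter_sd=1.0, fa_rate=50.0, detail_level=1.0,
                                    omission_mu=mu_true, omission_sigma=0.02),
                contrast_range=(1.0, 1.0), seed=rep_seed)
            errs.append(abs(rep["thresholds"]["white"] - mu_true) / mu_true)
        assert float(np.median(errs)) < 0.10

    def test_bias_decreases_with_contrast_given_contrast_dependent_fa(self):
        # emulates the reported negative performance-bias relationship
        from tracescore.scoring import sdt_measures

        cfg = ScoringConfig(margin_fraction=0.025)
        contrasts = np.geomspace(0.02, 0.3, 5)
        xs, cs, ps = [], [], []
        for s in range(8):
            sc = make_scene(6, size_px=192, seed=100 + s)
            model = ObserverModel(jitter_sd=1.0, fa_rate=600.0, fa_contrast_slope=3.0,
                                  omission_mu=0.05, omission_sigma=0.03, seed=s)
            gt = simulate_observer(sc, StimulusSpec(0.16), model, trial_id=99)
            for i, c in enumerate(contrasts):
                resp = simulate_observer(sc, StimulusSpec(float(c)), model, trial_id=i)
                m = sdt_measures(score_traces(gt, resp, cfg), cfg)
                xs.append(c)
                cs.append(m.c)
                ps.append(m.p)
        assert np.corrcoef(xs, cs)[0, 1] < 0  # bias falls as contrast rises
        assert np.corrcoef(ps, cs)[0, 1] < -0.5  # and tracks performance inversely


class TestGenerateDesign:
    def test_thirty_condition_cells(self):
        cells = condition_cells({f: [0.01, 0.02, 0.04, 0.08, 0.16] for f in SIX_FAMILIES})
        assert len(cells) == 30
        assert len(set(cells)) == 30

    def test_each_image_exactly_once(self):
        df = generate_design(30, {f: [0.1, 0.2, 0.3, 0.4, 0.5] for f in SIX_FAMILIES},
                             seed=3, n_observers=4)
        for _, grp in df.groupby("observer_id"):
            assert sorted(grp["image_id"]) == list(range(30))

    def test_deterministic(self):
        kw = dict(n_images=10, contrasts_per_noise={f: [0.1, 0.2] for f in SIX_FAMILIES},
                  seed=5, n_observers=2)
        assert generate_design(**kw).equals(generate_design(**kw))

    def test_cell_assignment_uniform(self):
        # chi-square over the 30-cell grid across many observers
        from scipy.stats import chisquare
        contrasts = {f: [0.01, 0.02, 0.04, 0.08, 0.16] for f in SIX_FAMILIES}
        df = generate_design(30, contrasts, seed=7, n_observers=100)
        counts = df.groupby(["noise", "image_contrast"]).size()
        assert len(counts) == 30
        _, pval = chisquare(counts.values)
        assert pval > 0.001


def test_noise_spec_from_label():
    spec = noise_spec_from_label("narrowband-3", rms_contrast=0.1)
    assert spec.family == "narrowband" and spec.center_sf == 3.0
    assert noise_spec_from_label("pink").family == "pink"
    with pytest.raises(ValueError):
        noise_spec_from_label("mauve")
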