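"""Model construction, backprop correctness, the training protocol,
sliding-window inference, ensembling, evaluation and visualization."""

import numpy as np
import pytest

from softgleason import metrics as M
from softgleason.fusion import HardLabelMap, SoftLabelMap
from softgleason.nn import AdamW, TinyUNet
from softgleason.ontology import IGNORE_LABEL, Level
from softgleason.training import (
    ImageItem,
    PredictionMap,
    TrainConfig,
    build_model,
    ensemble_average,
    evaluate_run,
    predict_sliding,
    train,
    visualize,
)


class TestBuildModel:
    def test_output_on_simplex(self, rng):
        model = build_model({"name": "tiny", "base": 4, "depth": 2}, 4)
        x = rng.random((1, 16, 16, 3))
        probs = model.forward(x)
        assert probs.shape == (1, 16, 16, 4)
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-10)

    def test_forward_deterministic(self, rng):
        model = build_model({"name": "tiny", "base": 4, "depth": 1}, 3)
        x = rng.random((1, 8, 8, 3))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_ten_class_head_builds(self):
        model = build_model({"name": "tiny", "base": 4, "depth": 2}, 10)
        probs = model.forward(np.zeros((1, 16, 16, 3)))
        assert probs.shape[-1] == 10

    def test_indivisible_shape_reports_padding(self):
        model = build_model({"name": "tiny", "base": 4, "depth": 2}, 3)
        with pytest.raises(ValueError, match="pad"):
            model.forward(np.zeros((1, 10, 10, 3)))

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            build_model({"name": "tiny"}, 1)


class TestBackprop:
    def test_gradient_matches_finite_differences(self, rng):
        """End-to-end finite-difference check of the conv/pool/skip backprop."""
        model = TinyUNet(in_channels=3, n_classes=3, base=3, depth=1, seed=2)
        x = rng.random((1, 4, 4, 3))
        tgt = rng.dirichlet(np.ones(3), size=(1, 4, 4))
        mask = np.ones((1, 4, 4), bool)

        def loss_of():
            return M.soft_cross_entropy(model.forward(x), tgt, mask)

        loss, g = M.soft_cross_entropy(model.forward(x), tgt, mask, grad=True)
        model.zero_grad()
        model.backward(g)
        eps = 1e-6
        params = model.params()
        rng2 = np.random.default_rng(0)
        for p in params[:: max(len(params) // 6, 1)]:
            idx = tuple(rng2.integers(0, s) for s in p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + eps
            up = loss_of()
            p.value[idx] = orig - eps
            down = loss_of()
            p.value[idx] = orig
            num = (up - down) / (2 * eps)
            assert num == pytest.approx(p.grad[idx], rel=1e-3, abs=1e-7)


def _toy_items(rng, n=4, side=16, n_classes=3):
    items = []
    for i in range(n):
        img = rng.random((side, side, 3))
        dist = rng.dirichlet(np.ones(n_classes), size=(side, side)).astype(np.float32)
        labels = dist.argmax(-1).astype(np.int64)
        tissue = np.ones((side, side), bool)
        items.append(ImageItem(
            image_id=f"t{i}", image=img,
            soft=SoftLabelMap(f"t{i}", Level.EXPLANATION, dist, tissue, 3),
            hard=HardLabelMap(f"t{i}", Level.EXPLANATION, labels),
            tissue=tissue,
        ))
    return items


class TestTrain:
    def test_smoke_run_selects_argmin_val(self, rng):
        items = _toy_items(rng)
        cfg = TrainConfig(epochs=2, batch_size=2, lr=1e-3, patch_size=16,
                          augment_policy="identity", seed=0)
        model = build_model({"name": "tiny", "base": 4, "depth": 2}, 3)
        run = train(model, items[:3], items[3:], cfg)
        assert len(run.val_losses) == 2
        assert run.best_epoch == int(np.argmin(run.val_losses)) + 1
        assert set(run.best_state) == set(run.last_state)

    def test_plateau_schedule_trace(self, rng, monkeypatch):
        """Validation losses [1.0, 0.9, 0.95, 0.93] trigger exactly one lr
        reduction, after the fourth epoch (two consecutive non-improvements)."""
        import softgleason.training as T

        fake = iter([1.0, 0.9, 0.95, 0.93])
        monkeypatch.setattr(T, "_val_loss", lambda *a, **k: next(fake))
        items = _toy_items(rng)
        cfg = TrainConfig(epochs=4, batch_size=2, lr=9e-4, patch_size=16,
                          plateau_patience=2, plateau_factor=1 / 3,
                          augment_policy="identity", seed=0)
        model = build_model({"name": "tiny", "base": 4, "depth": 2}, 3)
        run = T.train(model, items[:3], items[3:], cfg)
        np.testing.assert_allclose(run.lr_trace, [9e-4, 9e-4, 9e-4, 3e-4])

    def test_same_seed_identical_curves(self, rng):
        items = _toy_items(rng)
        cfg = TrainConfig(epochs=2, batch_size=2, lr=1e-3, patch_size=16,
                          augment_policy="identity", seed=5)
        runs = []
        for _ in range(2):
            model = build_model({"name": "tiny", "base": 4, "depth": 2}, 3, seed=5)
            runs.append(train(model, items[:3], items[3:], cfg))
        assert runs[0].train_losses == runs[1].train_losses
        assert runs[0].val_losses == runs[1].val_losses


class _ConstantModel:
    """Stub emitting a fixed distribution everywhere (any spatial shape)."""

    def __init__(self, dist):
        self.dist = np.asarray(dist, float)
        self.n_classes = len(dist)
        self.calls = 0

    def forward(self, x):
        self.calls += 1
        n, h, w, _ = x.shape
        return np.broadcast_to(self.dist, (n, h, w, self.n_classes)).copy()


class TestSlidingWindow:
    def test_constant_model_gives_constant_map(self, rng):
        model = _ConstantModel([0.1, 0.2, 0.7])
        img = rng.random((100, 140, 3))
        pm = predict_sliding(model, img, "pattern", window=64)
        np.testing.assert_allclose(pm.dist, np.broadcast_to([0.1, 0.2, 0.7], pm.dist.shape),
                                   atol=1e-12)

    def test_output_on_simplex(self, rng):
        model = build_model({"name": "tiny", "base": 4, "depth": 2}, 3)
        img = rng.random((70, 70, 3))
        pm = predict_sliding(model, img, "pattern", window=32)
        assert pm.dist.shape == (70, 70, 3)
        np.testing.assert_allclose(pm.dist.sum(-1), 1.0, atol=1e-9)

    def test_tile_grid_arithmetic(self):
        """A 768-px side with a 512 window at 50% overlap yields a 2×2 grid
        of tiles with stride 256."""
        model = _ConstantModel([0.5, 0.5])
        img = np.zeros((768, 768, 3))
        predict_sliding(model, img, "pattern", window=512, overlap=0.5)
        assert model.calls == 4

    def test_small_image_single_padded_tile(self):
        model = _ConstantModel([1.0, 0.0])
        pm = predict_sliding(model, np.zeros((20, 20, 3)), "pattern", window=64)
        assert model.calls == 1
        assert pm.dist.shape == (20, 20, 2)


class TestEnsemble:
    def test_single_map_unchanged(self, rng):
        d = rng.dirichlet(np.ones(3), size=(4, 4))
        pm = PredictionMap("i", Level.PATTERN, d)
        np.testing.assert_array_equal(ensemble_average([pm]).dist, d)

    def test_mean_is_midpoint(self, rng):
        d = rng.dirichlet(np.ones(3), size=(4, 4))
        a = PredictionMap("i", Level.PATTERN, d)
        b = PredictionMap("i", Level.PATTERN, d[..., ::-1].copy())
        mid = ensemble_average([a, b]).dist
        np.testing.assert_allclose(mid, (d + d[..., ::-1]) / 2)

    def test_majority_of_three_one_hot_maps(self):
        e = np.eye(3)
        maps = [PredictionMap("i", Level.PATTERN, e[c][None, None]) for c in (0, 0, 1)]
        assert ensemble_average(maps).dist.argmax(-1)[0, 0] == 0

    def test_shape_mismatch_rejected(self, rng):
        a = PredictionMap("i", Level.PATTERN, rng.dirichlet(np.ones(3), size=(2, 2)))
        b = PredictionMap("i", Level.PATTERN, rng.dirichlet(np.ones(3), size=(3, 3)))
        with pytest.raises(ValueError):
            ensemble_average([a, b])


class TestEvaluateRun:
    def _refs(self, ontology, rng, n=2, side=8):
        refs, maps = {}, {}
        c = ontology.n_classes("explanation")
        for i in range(n):
            counts = rng.multinomial(3, np.ones(c) / c, size=(side, side))
            dist = (counts / 3.0).astype(np.float32)
            fg = np.ones((side, side), bool)
            soft = SoftLabelMap(f"i{i}", Level.EXPLANATION, dist, fg, 3)
            top = counts.max(-1)
            unique = (counts == top[..., None]).sum(-1) == 1
            labels = np.where(unique, counts.argmax(-1), IGNORE_LABEL)
            hard = HardLabelMap(f"i{i}", Level.EXPLANATION, labels.astype(np.int64))
            refs[f"i{i}"] = (soft, hard)
            maps[f"i{i}"] = PredictionMap(f"i{i}", Level.EXPLANATION, dist.astype(float))
        return maps, refs

    def test_perfect_predictions_score_one(self, ontology, rng):
        maps, refs = self._refs(ontology, rng)
        reports = evaluate_run(maps, refs, ontology)
        assert set(reports) == {"explanation", "pattern"}
        for rep in reports.values():
            assert rep.dice == pytest.approx(1.0)
            assert rep.macro_soft_dice == pytest.approx(1.0)
            assert rep.l1_norm == pytest.approx(0.0)

    def test_remapped_population_unchanged(self, ontology, rng):
        maps, refs = self._refs(ontology, rng)
        reports = evaluate_run(maps, refs, ontology)
        assert reports["explanation"].n_pixels_soft == reports["pattern"].n_pixels_soft

    def test_missing_reference_lists_ids(self, ontology, rng):
        maps, refs = self._refs(ontology, rng)
        del maps["i0"]
        with pytest.raises(ValueError, match="i0"):
            evaluate_run(maps, refs, ontology)


class TestVisualize:
    def test_all_benign_legend(self, ontology):
        c = ontology.n_classes("pattern")
        dist = np.zeros((8, 8, c))
        dist[..., -1] = 1.0
        pm = PredictionMap("i", Level.PATTERN, dist)
        img = np.full((8, 8, 3), 200, np.uint8)
        tissue = np.ones((8, 8), bool)
        _, legend = visualize(pm, img, ontology, tissue)
        assert [t for t, _, _ in legend] == ["benign"]

    def test_background_fully_transparent(self, ontology, rng):
        c = ontology.n_classes("pattern")
        dist = rng.dirichlet(np.ones(c), size=(8, 8))
        pm = PredictionMap("i", Level.PATTERN, dist)
        tissue = np.zeros((8, 8), bool)
        tissue[2:5, 2:5] = True
        rgba, _ = visualize(pm, np.full((8, 8, 3), 180, np.uint8), ontology, tissue)
        assert (rgba[~tissue, 3] == 0).all()
        assert (rgba[tissue, 3] == 255).all()

    def test_pattern_palette_hue_convention(self, ontology):
        """Greens map to Gleason 3, blues to 4, reds to 5."""
        pal = ontology.palette("pattern").astype(int)
        g3, g4, g5 = pal[0], pal[1], pal[2]
        assert g3[1] > g3[0] and g3[1] > g3[2]  # green channel dominates
        assert g4[2] > g4[0] and g4[2] > g4[1]
        assert g5[0] > g5[1] and g5[0] > g5[2]
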