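"""Fusion network: fusion algebra, forward/backward, training behaviour."""

import numpy as np
import pytest

from icusurv import (
    CohortConfig,
    FusionConfig,
    c_index,
    encode_modalities,
    fit_linear_cox,
    fuse_features,
    generate_cohort,
    load_model,
    predict_survival,
    risk_forward,
    risk_forward_batch,
    save_model,
    survival_function,
    train_model,
    train_on_arrays,
)
from icusurv.cox import BaselineSurvival, breslow_baseline
from icusurv.fusion import TrainedRiskModel, _event_balanced_batches, _init_params


def test_fuse_identical_hiddens_and_order(rng):
    h = rng.normal(size=32)
    saps = rng.normal(size=15)
    fused = fuse_features(saps, {"text": h, "image": h})
    assert fused.shape == (47,)  # 32-dim averaged block + 15-dim saps block
    np.testing.assert_allclose(fused[:32], h)
    np.testing.assert_allclose(fused[32:], saps)


def test_fuse_average_elementwise(rng):
    t, i = rng.normal(size=8), rng.normal(size=8)
    fused = fuse_features(None, {"t": t, "i": i})
    manual = np.array([(t[k] + i[k]) / 2 for k in range(8)])
    np.testing.assert_allclose(fused, manual, rtol=1e-12)


def test_fuse_saps_only_and_errors(rng):
    saps = rng.normal(size=15)
    np.testing.assert_allclose(fuse_features(saps, {}), saps)
    with pytest.raises(ValueError, match="share a length"):
        fuse_features(saps, {"a": np.zeros(4), "b": np.zeros(5)})
    with pytest.raises(ValueError, match="nothing"):
        fuse_features(None, {})


def test_config_validation():
    with pytest.raises(ValueError, match="modality"):
        FusionConfig(enabled_modalities=("saps", "pixels"))
    with pytest.raises(ValueError, match="output width"):
        FusionConfig(enabled_modalities=("labels", "transformer_text"))
    with pytest.raises(ValueError, match="dropout"):
        FusionConfig(dropout=1.0)


def test_zero_network_outputs_zero(small_cohort):
    cfg = FusionConfig(enabled_modalities=("saps",), max_epochs=0)
    params = {k: np.zeros_like(v) for k, v in _init_params(cfg, np.random.default_rng(0)).items()}
    model = TrainedRiskModel(parameters=params, config=cfg, training_history=[], best_epoch=0)
    assert risk_forward(model, small_cohort[0]) == 0.0


def test_linear_saps_head_is_a_dot_product(small_cohort):
    # identity saps head without activation, no hidden risk layers: psi = w.x
    cfg = FusionConfig(
        enabled_modalities=("saps",),
        risk_hidden_layers=(),
        saps_activation=False,
        dropout=0.0,
        max_epochs=0,
    )
    params = _init_params(cfg, np.random.default_rng(0))
    w = np.random.default_rng(1).normal(size=15)
    params["head_saps_W"] = np.eye(15)
    params["head_saps_b"] = np.zeros(15)
    params["out_W"] = w[:, None]
    params["out_b"] = np.zeros(1)
    model = TrainedRiskModel(parameters=params, config=cfg, training_history=[], best_epoch=0)
    rec = small_cohort[4]
    x = encode_modalities([rec], ("saps",))["saps"][0]
    assert risk_forward(model, rec) == pytest.approx(float(w @ x), rel=1e-12)


def test_eval_mode_is_deterministic(small_cohort):
    cohort = small_cohort
    cfg = FusionConfig(enabled_modalities=("saps",), max_epochs=3, dropout=0.5, seed=0)
    model = train_model(cohort.subset(range(0, 250)), cohort.subset(range(250, 300)), cfg)
    r1 = risk_forward(model, cohort[0])
    r2 = risk_forward(model, cohort[0])
    assert r1 == r2 and np.isfinite(r1)


def test_max_epochs_zero_returns_initialized_model(small_cohort):
    cfg = FusionConfig(enabled_modalities=("saps",), max_epochs=0)
    model = train_model(small_cohort.subset(range(200)), small_cohort.subset(range(200, 300)), cfg)
    assert model.training_history == [] and model.best_epoch == 0


def test_training_requires_events():
    c = generate_cohort(CohortConfig(n_subjects=60, include_embeddings=False, seed=1))
    feats = encode_modalities(c, ("saps",))
    cfg = FusionConfig(enabled_modalities=("saps",), max_epochs=2)
    with pytest.raises(ValueError, match="no events"):
        train_on_arrays(
            feats, c.times, np.zeros(60), feats, c.times, np.zeros(60), cfg
        )


def test_every_batch_contains_an_event():
    rng = np.random.default_rng(0)
    events = np.zeros(200, dtype=bool)
    events[rng.choice(200, 7, replace=False)] = True
    batches = _event_balanced_batches(events, 32, rng)
    assert sum(len(b) for b in batches) <= 200
    for b in batches:
        assert events[b].sum() >= 1


def test_loss_decreases_during_training(small_cohort):
    cfg = FusionConfig(enabled_modalities=("saps",), max_epochs=25, early_stop_patience=25, seed=2)
    model = train_model(
        small_cohort.subset(range(0, 250)), small_cohort.subset(range(250, 300)), cfg
    )
    hist = model.training_history
    assert hist[model.best_epoch - 1][1] < hist[0][1]


def test_saps_net_matches_linear_cox_on_linear_cohort():
    # planted linear risk: the neural model should be on par with linear Cox
    c = generate_cohort(
        CohortConfig(n_subjects=2000, include_embeddings=False, seed=17)
    )
    n = len(c)
    rng = np.random.default_rng(0)
    order = rng.permutation(n)
    tr, va, te = order[:1400], order[1400:1600], order[1600:]
    feats = encode_modalities(c, ("saps",))
    times, events = c.times, c.events
    cfg = FusionConfig(
        enabled_modalities=("saps",), max_epochs=250, early_stop_patience=10, seed=0
    )
    model = train_on_arrays(
        {"saps": feats["saps"][tr]}, times[tr], events[tr],
        {"saps": feats["saps"][va]}, times[va], events[va], cfg,
    )
    ci_net = c_index(
        times[te], events[te], risk_forward_batch(model, {"saps": feats["saps"][te]})
    ).value
    lin = fit_linear_cox(feats["saps"][tr], times[tr], events[tr])
    ci_lin = c_index(times[te], events[te], feats["saps"][te] @ lin.coefficients).value
    assert ci_net >= ci_lin - 0.02


def test_training_order_permutation_is_tolerable():
    # permuting the training rows changes batch composition (stochastic path)
    # but the evaluation C-index must stay within a small tolerance
    c = generate_cohort(CohortConfig(n_subjects=900, include_embeddings=False, seed=8))
    n = len(c)
    order = np.random.default_rng(0).permutation(n)
    tr, va, te = order[:630], order[630:720], order[720:]
    feats = encode_modalities(c, ("saps",))
    times, events = c.times, c.events
    cfg = FusionConfig(enabled_modalities=("saps",), max_epochs=40, early_stop_patience=40, seed=0)
    cis = []
    for perm_seed in [None, 1]:
        idx = tr if perm_seed is None else tr[np.random.default_rng(perm_seed).permutation(len(tr))]
        m = train_on_arrays(
            {"saps": feats["saps"][idx]}, times[idx], events[idx],
            {"saps": feats["saps"][va]}, times[va], events[va], cfg,
        )
        cis.append(
            c_index(times[te], events[te], risk_forward_batch(m, {"saps": feats["saps"][te]})).value
        )
    assert abs(cis[0] - cis[1]) < 0.05


def test_predict_survival_composes_and_is_monotone(small_cohort):
    cfg = FusionConfig(enabled_modalities=("saps",), max_epochs=5, seed=3)
    model = train_model(
        small_cohort.subset(range(0, 250)), small_cohort.subset(range(250, 300)), cfg
    )
    feats = encode_modalities(small_cohort, ("saps",))
    psi = risk_forward_batch(model, feats)
    baseline = breslow_baseline(psi, small_cohort.times, small_cohort.events)
    a, b = int(np.argmin(psi)), int(np.argmax(psi))
    curve_a = predict_survival(model, baseline, small_cohort[a])
    curve_b = predict_survival(model, baseline, small_cohort[b])
    assert np.all(curve_a.values >= curve_b.values)  # lower risk -> higher survival
    manual = survival_function(baseline, risk_forward(model, small_cohort[a]))
    np.testing.assert_allclose(curve_a.values, manual.values)
    empty = BaselineSurvival(times=np.array([]), s0=np.array([]))
    assert predict_survival(model, empty, small_cohort[a]).at(50.0) == 1.0


def test_checkpoint_round_trip(tmp_path, small_cohort):
    cfg = FusionConfig(enabled_modalities=("saps",), max_epochs=4, seed=5)
    model = train_model(
        small_cohort.subset(range(0, 250)), small_cohort.subset(range(250, 300)), cfg
    )
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert back.config == model.config
    assert back.best_epoch == model.best_epoch
    for rec in small_cohort.records[:5]:
        assert risk_forward(back, rec) == pytest.approx(risk_forward(model, rec), rel=1e-12)
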