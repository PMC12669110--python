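"""VAE losses, annealing, architecture contracts, training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octcvd.errors import ConfigurationError
from octcvd.phantom import OCTVolume
from octcvd.vae import (
    ConvVAE,
    LatentCode,
    VaeConfig,
    central_slice_index,
    extract_eye_latent,
    gaussian_kl,
    kl_anneal_weight,
    split_622,
    train_vae,
    vae_loss,
)


def tiny_config(**kw):
    base = dict(
        latent_dim=4, conv_layers=2, base_channels=2, image_size=8,
        epochs=3, anneal_epochs=2, batch_size=4, seed=1,
    )
    base.update(kw)
    return VaeConfig(**base)


# ------------------------------ annealing ----------------------------------


def test_anneal_schedule_endpoints_and_midpoint():
    cfg = VaeConfig()
    assert kl_anneal_weight(0, cfg) == pytest.approx(0.001)
    assert kl_anneal_weight(20, cfg) == pytest.approx(0.01)
    assert kl_anneal_weight(57, cfg) == pytest.approx(0.01)
    # linear ramp midpoint
    assert kl_anneal_weight(10, cfg) == pytest.approx(0.0055)


def test_anneal_trace_nondecreasing_and_clamped():
    cfg = VaeConfig()
    trace = [kl_anneal_weight(e, cfg) for e in range(120)]
    assert all(b >= a for a, b in zip(trace, trace[1:]))
    assert max(trace) == pytest.approx(cfg.beta_max)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        VaeConfig(beta_start=0.02, beta_max=0.01)
    with pytest.raises(ConfigurationError):
        VaeConfig(anneal_epochs=200, epochs=100)
    with pytest.raises(ConfigurationError):
        VaeConfig(image_size=100, conv_layers=6)  # not divisible by 64


# ------------------------------ losses -------------------------------------


def test_loss_zero_at_perfect_reconstruction_and_prior():
    x = np.random.default_rng(0).random((8, 8))
    code = LatentCode(mean=np.zeros(4), logvar=np.zeros(4))
    lb = vae_loss(x, x, code, beta=0.01)
    assert lb.total == 0.0 and lb.mse == 0.0 and lb.kl == 0.0


def test_loss_closed_form_gaussian_kl():
    """mu = (1, 0), sigma^2 = (1, 1): KL = 0.5, so total = 0.5 beta."""
    x = np.ones((4, 4))
    code = LatentCode(mean=np.array([1.0, 0.0]), logvar=np.zeros(2))
    for beta in (0.001, 0.01, 1.0):
        lb = vae_loss(x, x, code, beta)
        assert lb.kl == pytest.approx(0.5)
        assert lb.total == pytest.approx(0.5 * beta)


def test_mse_matches_brute_force_pixel_loop():
    rng = np.random.default_rng(3)
    x, xhat = rng.random((8, 8)), rng.random((8, 8))
    code = LatentCode(mean=np.zeros(2), logvar=np.zeros(2))
    acc = 0.0
    for i in range(8):
        for j in range(8):
            acc += (x[i, j] - xhat[i, j]) ** 2
    assert vae_loss(x, xhat, code, 0.0).mse == pytest.approx(acc / 64)


def test_loss_shape_mismatch_raises():
    code = LatentCode(mean=np.zeros(2), logvar=np.zeros(2))
    with pytest.raises(ConfigurationError):
        vae_loss(np.zeros((4, 4)), np.zeros((4, 5)), code, 0.01)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    mean=st.lists(st.floats(-5, 5), min_size=1, max_size=6),
    logvar=st.lists(st.floats(-4, 3), min_size=1, max_size=6),
)
def test_kl_is_nonnegative_and_zero_only_at_prior(mean, logvar):
    n = min(len(mean), len(logvar))
    mu, lv = np.array(mean[:n]), np.array(logvar[:n])
    kl = gaussian_kl(mu, lv)
    assert kl >= -1e-12
    at_prior = np.allclose(mu, 0) and np.allclose(lv, 0)
    if not at_prior and (np.abs(mu).max() > 1e-3 or np.abs(lv).max() > 1e-3):
        assert kl > 0
    if at_prior:
        assert kl == pytest.approx(0.0, abs=1e-12)


def test_total_equals_mse_plus_beta_kl_on_training_log():
    rng = np.random.default_rng(5)
    imgs = rng.random((40, 8, 8)).astype(np.float32)
    _, log = train_vae(imgs, tiny_config())
    for _, row in log.iterrows():
        assert row["train_total"] == pytest.approx(
            row["train_mse"] + row["beta"] * row["train_kl"], rel=1e-5
        )


# ---------------------------- gradients ------------------------------------


def test_end_to_end_gradients_match_finite_differences():
    """Analytic backprop through the full VAE loss (reparameterised sample,
    MSE + beta KL) agrees with central finite differences."""
    cfg = tiny_config(dtype="float64")
    model = ConvVAE(cfg)
    rng = np.random.default_rng(2)
    x = rng.random((2, 8, 8))
    eps = rng.standard_normal((2, cfg.latent_dim))
    beta = 0.01
    D = cfg.latent_dim

    def full_loss():
        xb = x[:, None]
        h = model.encoder.forward(xb)
        mu, lv = h[:, :D], h[:, D:]
        z = mu + np.exp(0.5 * lv) * eps
        xhat = model.decoder.forward(z)
        return float(np.mean((xhat - xb) ** 2) + beta * gaussian_kl(mu, lv))

    xb = x[:, None]
    B, P = 2, 64
    h = model.encoder.forward(xb)
    mu, lv = h[:, :D], h[:, D:]
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    xhat = model.decoder.forward(z)
    model.encoder.zero_grad()
    model.decoder.zero_grad()
    dz = model.decoder.backward(2.0 / (B * P) * (xhat - xb))
    dmu = dz + beta * mu / B
    dlv = dz * eps * 0.5 * std + beta * 0.5 * (np.exp(lv) - 1.0) / B
    model.encoder.backward(np.concatenate([dmu, dlv], axis=1))

    check_rng = np.random.default_rng(0)
    for p, g in zip(
        model.encoder.params + model.decoder.params,
        model.encoder.grads + model.decoder.grads,
    ):
        flat, gflat = p.ravel(), g.ravel()
        for i in check_rng.choice(flat.size, size=min(4, flat.size), replace=False):
            old, h_ = flat[i], 1e-6
            flat[i] = old + h_
            fp = full_loss()
            flat[i] = old - h_
            fm = full_loss()
            flat[i] = old
            num = (fp - fm) / (2 * h_)
            assert gflat[i] == pytest.approx(num, abs=1e-7, rel=1e-4)


# ------------------------- architecture contracts ---------------------------


def test_default_encoder_emits_128_dimensional_latents():
    model = ConvVAE(VaeConfig())
    img = np.random.default_rng(1).random((128, 128)).astype(np.float32)
    code = model.encode(img)
    assert code.mean.shape == (128,)
    assert code.logvar.shape == (128,)
    assert code.D == 128


def test_decode_is_deterministic():
    model = ConvVAE(tiny_config())
    z = np.random.default_rng(2).standard_normal(4)
    np.testing.assert_array_equal(model.decode(z), model.decode(z.copy()))


def test_wrong_input_size_and_latent_length_raise():
    model = ConvVAE(tiny_config())
    with pytest.raises(ConfigurationError):
        model.encode(np.zeros((9, 9)))
    with pytest.raises(ConfigurationError):
        model.decode(np.zeros(5))


def test_weight_round_trip_and_warm_start(tmp_path):
    cfg = tiny_config()
    model = ConvVAE(cfg)
    path = tmp_path / "vae.npz"
    model.save(path)
    back = ConvVAE.load(path)
    img = np.random.default_rng(4).random((8, 8)).astype(np.float32)
    np.testing.assert_array_equal(model.encode(img).mean, back.encode(img).mean)
    # warm start: training initialised from existing weights runs
    imgs = np.random.default_rng(5).random((20, 8, 8)).astype(np.float32)
    _, log = train_vae(imgs, cfg, init_weights=model.get_weights())
    assert len(log) == cfg.epochs


# ------------------------------ training -----------------------------------


def test_loss_log_length_equals_epochs_and_beta_trace():
    rng = np.random.default_rng(6)
    imgs = rng.random((30, 8, 8)).astype(np.float32)
    cfg = tiny_config(epochs=5, anneal_epochs=3)
    _, log = train_vae(imgs, cfg)
    assert len(log) == 5
    assert log["beta"].iloc[0] == pytest.approx(cfg.beta_start)
    assert log["beta"].iloc[3] == pytest.approx(cfg.beta_max)
    assert log["beta"].iloc[-1] == pytest.approx(cfg.beta_max)


def test_training_is_deterministic_under_seed():
    rng = np.random.default_rng(7)
    imgs = rng.random((30, 8, 8)).astype(np.float32)
    _, log_a = train_vae(imgs, tiny_config())
    _, log_b = train_vae(imgs, tiny_config())
    assert log_a["val_total"].iloc[-1] == log_b["val_total"].iloc[-1]
    assert log_a["train_total"].iloc[-1] == log_b["train_total"].iloc[-1]


def test_empty_training_set_raises():
    with pytest.raises(ConfigurationError):
        train_vae(np.zeros((0, 8, 8), dtype=np.float32), tiny_config())


def test_split_622_proportions():
    tr, va, te = split_622(100, np.random.default_rng(0))
    assert (len(tr), len(va), len(te)) == (60, 20, 20)
    assert sorted(np.concatenate([tr, va, te])) == list(range(100))


def test_training_reduces_reconstruction_error(choroid_phantoms, choroid_vae):
    imgs, _, _ = choroid_phantoms
    trained, _ = choroid_vae
    untrained = ConvVAE(trained.config)
    sub = imgs[:64]
    mse_trained = float(np.mean((trained.reconstruct(sub) - sub) ** 2))
    mse_untrained = float(np.mean((untrained.reconstruct(sub) - sub) ** 2))
    assert mse_trained < mse_untrained


def test_latent_dimension_tracks_choroid_thickness(choroid_phantoms, choroid_vae):
    """Recoverability premise: on phantoms whose only systematic variation
    is choroidal thickness, some latent dimension's posterior mean
    correlates with the ground-truth thickness (|r| > 0.5)."""
    imgs, _, ths = choroid_phantoms
    model, _ = choroid_vae
    means = model.encode(imgs).mean
    rs = [abs(np.corrcoef(means[:, d], ths)[0, 1]) for d in range(means.shape[1])]
    assert max(rs) > 0.5


# --------------------------- latent extraction ------------------------------


def test_identical_bscans_give_single_scan_latent():
    model = ConvVAE(tiny_config())
    img = np.random.default_rng(9).random((8, 8)).astype(np.float32)
    volume = np.stack([img] * 6)
    per_volume = extract_eye_latent(volume, model)
    single = model.encode(img).mean
    np.testing.assert_allclose(per_volume, single, rtol=1e-5)


def test_central_slice_mode_uses_middle_bscan():
    assert central_slice_index(128) == 63  # the 64th B-scan of 128
    model = ConvVAE(tiny_config())
    volume = np.random.default_rng(10).random((16, 8, 8)).astype(np.float32)
    got = extract_eye_latent(volume, model, mode="central_slice")
    np.testing.assert_allclose(got, model.encode(volume[7]).mean, rtol=1e-6)


def test_latent_aggregation_matches_brute_force_average():
    model = ConvVAE(tiny_config())
    bscans = np.random.default_rng(11).random((12, 8, 8)).astype(np.float32)
    volume = OCTVolume("S", "L", bscans, np.zeros((12, 11, 8), dtype=np.int16))
    got = extract_eye_latent(volume, model)
    brute = np.mean([model.encode(b).mean for b in bscans], axis=0)
    np.testing.assert_allclose(got, brute, rtol=1e-5)
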