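"""Latent diffusion pathway: schedule, attention, objective, codec, sampler,
selective fine-tuning, n-way metric and null-control plumbing."""

import numpy as np
import pytest

import vepdecode.nn as nn
from vepdecode.nn import Tensor
from vepdecode.diffusion import (AutoencoderConfig, ConditionedUNet,
                                 DiffusionSchedule, DiffusionTrainConfig,
                                 FinetuneConfig, UNetConfig, cross_attention,
                                 diffusion_loss, evaluate_reconstructions,
                                 extract_intertrial_windows, finetune,
                                 n_way_top1_from_scores, normalize_channelwise,
                                 plms_timesteps, sample_plms,
                                 timestep_embedding, train_denoiser,
                                 train_latent_autoencoder, train_surrogate,
                                 trainable_finetune_parameters,
                                 upsample_windows)
from vepdecode.diffusion.autoencoder import AutoencoderNet
from vepdecode.models import EEGNetConfig, build_eegnet_plus
from vepdecode.preprocessing import EpochSet
from vepdecode.sim import SessionSpec
from vepdecode.stimuli import generate_stimulus_images

rng = np.random.default_rng(0)


class TestSchedule:
    def test_linear_schedule_invariants(self):
        sch = DiffusionSchedule.linear(T=100)
        assert sch.T == 100
        assert np.all(np.diff(sch.alpha_bar) < 0)
        assert 0 < sch.alpha_bar[-1] < sch.alpha_bar[0] <= 1
        assert sch.alpha_bar_at(0) == 1.0
        assert sch.alpha_bar_at(1) == pytest.approx(1 - sch.betas[0])

    def test_invalid_betas_rejected(self):
        with pytest.raises(ValueError):
            DiffusionSchedule(betas=np.array([0.1, -0.2]))


class TestCrossAttention:
    def test_matches_explicit_loop_oracle(self):
        B, Nq, d, M, d_tau, d_k = 2, 5, 6, 3, 4, 7
        phi = rng.standard_normal((B, Nq, d))
        ctx = rng.standard_normal((B, M, d_tau))
        wq = rng.standard_normal((d, d_k))
        wk = rng.standard_normal((d_tau, d_k))
        wv = rng.standard_normal((d_tau, d_k))
        out = cross_attention(Tensor(phi), Tensor(ctx), Tensor(wq),
                              Tensor(wk), Tensor(wv)).data
        # naive double loop
        expected = np.zeros((B, Nq, d_k))
        for b in range(B):
            q = phi[b] @ wq
            k = ctx[b] @ wk
            v = ctx[b] @ wv
            for i in range(Nq):
                scores = np.array([q[i] @ k[j] for j in range(M)]) / np.sqrt(d_k)
                e = np.exp(scores - scores.max())
                a = e / e.sum()
                expected[b, i] = sum(a[j] * v[j] for j in range(M))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_attention_rows_sum_to_one(self):
        q = Tensor(rng.standard_normal((1, 4, 8)))
        scores = nn.softmax(nn.matmul(q, q.transpose(0, 2, 1)), axis=-1)
        np.testing.assert_allclose(scores.data.sum(-1), 1.0, atol=1e-6)

    def test_single_context_token_returns_its_value_row(self):
        phi = Tensor(rng.standard_normal((1, 5, 6)))
        ctx = Tensor(rng.standard_normal((1, 1, 4)))     # M = 1
        wq = Tensor(rng.standard_normal((6, 7)))
        wk = Tensor(rng.standard_normal((4, 7)))
        wv = Tensor(rng.standard_normal((4, 7)))
        out = cross_attention(phi, ctx, wq, wk, wv).data
        value_row = (ctx.data[0] @ wv.data)[0]
        for i in range(5):
            np.testing.assert_allclose(out[0, i], value_row, atol=1e-12)


@pytest.fixture(scope="module")
def small_unet():
    return ConditionedUNet(UNetConfig(), np.random.default_rng(1))


class TestDiffusionLoss:
    def test_oracle_denoiser_recovering_injected_noise_gives_zero_loss(self):
        """An oracle that inverts z_t = sqrt(ab) z0 + sqrt(1-ab) eps
        analytically must drive the objective to zero."""
        sch = DiffusionSchedule.linear(T=50)
        z0 = rng.standard_normal((6, 4, 8, 8)).astype(np.float32)

        class Oracle:
            def __call__(self, z_t, t, y, double=True):
                ab = sch.alpha_bar_at(t).astype(np.float32)[:, None, None, None]
                eps = (z_t.data - np.sqrt(ab) * z0) / np.sqrt(1 - ab)
                return Tensor(eps)
        loss = diffusion_loss(z0, None, Oracle(), sch,
                              np.random.default_rng(3))
        assert loss.item() < 1e-8

    def test_zero_denoiser_loss_is_unit_noise_power(self):
        sch = DiffusionSchedule.linear(T=50)

        class Zero:
            def __call__(self, z_t, t, y, double=True):
                return Tensor(np.zeros_like(z_t.data))
        # 10^4 standard-normal draws: loss approximates E[eps^2] = 1
        z0 = np.zeros((10, 4, 10, 25), dtype=np.float32)
        losses = [diffusion_loss(z0, None, Zero(), sch,
                                 np.random.default_rng(s)).item()
                  for s in range(3)]
        n = np.prod(z0.shape)
        se = np.sqrt(2.0 / n)                     # var of mean of eps^2
        for val in losses:
            assert abs(val - 1.0) < 3 * se
            assert val >= 0

    def test_double_flag_changes_prediction(self, small_unet):
        sch = DiffusionSchedule.linear(T=20)
        z = Tensor(rng.standard_normal((2, 4, 8, 8)).astype(np.float32))
        y = Tensor(rng.standard_normal((2, 512)).astype(np.float32))
        t = np.array([5, 10])
        small_unet.eval()
        with nn.no_grad():
            a = small_unet(z, t, y, double=True).data
            b = small_unet(z, t, y, double=False).data
        assert a.shape == z.shape
        assert not np.allclose(a, b)


class TestAutoencoder:
    @pytest.fixture(scope="class")
    def trained_ae(self):
        spec = SessionSpec(n_classes=5, images_per_class=24)
        stim = generate_stimulus_images(spec, side_px=16, seed=2)
        images, _ = stim.flat()
        ae = train_latent_autoencoder(images, AutoencoderConfig(
            epochs=25, seed=0, max_holdout_mse=0.05))
        return ae, images

    def test_compression_factor_is_12(self, trained_ae):
        ae, images = trained_ae
        z = ae.encode(images[:4])
        assert z.shape == (4, 4, 4, 4)
        assert images[0].size / z[0].size == pytest.approx(12.0)
        assert ae.compression_factor == pytest.approx(12.0)

    def test_decode_restores_image_shape_and_range(self, trained_ae):
        ae, images = trained_ae
        out = ae.decode(ae.encode(images[:4]))
        assert out.shape == images[:4].shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_beats_mean_image_baseline(self, trained_ae):
        ae, images = trained_ae
        recon = ae.decode(ae.encode(images))
        mse = ((recon - images) ** 2).mean()
        baseline = ((images - images.mean(axis=0)) ** 2).mean()
        assert mse < baseline

    def test_divergence_guard_raises_with_history(self):
        spec = SessionSpec(n_classes=5, images_per_class=24)
        stim = generate_stimulus_images(spec, side_px=16, seed=2)
        images, _ = stim.flat()
        with pytest.raises(RuntimeError) as err:
            train_latent_autoencoder(images, AutoencoderConfig(
                epochs=1, max_holdout_mse=1e-9))
        assert hasattr(err.value, "history")

    def test_vq_variant_quantises_to_codebook(self):
        cfg = AutoencoderConfig(vq=True, codebook_size=16)
        net = AutoencoderNet(cfg, np.random.default_rng(0))
        x = Tensor(rng.standard_normal((2, 3, 16, 16)).astype(np.float32))
        z = net.encoder(x)
        zq, loss, codes = net.quantize(z)
        assert zq.shape == z.shape
        assert codes.shape == (2, 4, 4)
        assert loss.item() >= 0
        flat = zq.data.transpose(0, 2, 3, 1).reshape(-1, 4)
        dists = ((flat[:, None] - net.codebook.data[None]) ** 2).sum(-1)
        assert np.allclose(dists.min(axis=1), 0, atol=1e-10)


class TestSampler:
    def test_timestep_subsequence(self):
        ts = plms_timesteps(100, 10)
        assert ts[0] == 100 and ts[-1] == 1
        assert np.all(np.diff(ts) < 0)
        with pytest.raises(ValueError):
            plms_timesteps(100, 101)

    def test_same_seed_identical_output(self, small_unet):
        sch = DiffusionSchedule.linear(T=100)
        emb = rng.standard_normal((2, 512)).astype(np.float32)
        a = sample_plms(small_unet, sch, emb, (4, 8, 8), 8, seed=5)
        b = sample_plms(small_unet, sch, emb, (4, 8, 8), 8, seed=5)
        np.testing.assert_array_equal(a, b)
        c = sample_plms(small_unet, sch, emb, (4, 8, 8), 8, seed=6)
        assert not np.array_equal(a, c)

    def test_constant_denoiser_matches_closed_form(self):
        """For eps_theta == c independent of z_t, every multistep combination
        collapses to c and the trajectory solves in closed form."""
        sch = DiffusionSchedule.linear(T=100)
        c = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)

        class Const:
            cfg = UNetConfig()

            def eval(self):
                return self

            def __call__(self, z_t, t, y, double=True):
                return Tensor(np.broadcast_to(c, z_t.shape).copy())
        out = sample_plms(Const(), sch, None, (4, 8, 8), 10, seed=7)
        x0 = np.random.default_rng(7).standard_normal((1, 4, 8, 8)) \
            .astype(np.float32)
        ab0 = sch.alpha_bar_at(plms_timesteps(100, 10)[0])
        expected = (x0 - np.sqrt(1 - ab0) * c) / np.sqrt(ab0)
        np.testing.assert_allclose(out, expected, rtol=1e-4, atol=1e-5)

    def test_output_count_matches_embeddings(self, small_unet):
        sch = DiffusionSchedule.linear(T=50)
        emb = rng.standard_normal((3, 512)).astype(np.float32)
        out = sample_plms(small_unet, sch, emb, (4, 8, 8), 6, seed=0)
        assert out.shape == (3, 4, 8, 8)


class TestFinetune:
    @pytest.fixture(scope="class")
    def toy_setup(self):
        sch = DiffusionSchedule.linear(T=100)
        unet = ConditionedUNet(UNetConfig(), np.random.default_rng(2))
        encoder = build_eegnet_plus(
            EEGNetConfig(f1_temporal_filters=8, n_samples=100, n_classes=4),
            seed=0)
        n = 100
        data = rng.standard_normal((n, 8, 100)).astype(np.float32)
        epochs = EpochSet(data=data, labels=np.zeros(n, dtype=int),
                          retained=np.ones(n, dtype=bool))
        latents = rng.standard_normal((n, 4, 8, 8)).astype(np.float32)
        return sch, unet, encoder, epochs, latents

    def test_frozen_backbone_bitwise_unchanged(self, toy_setup):
        sch, unet, encoder, epochs, latents = toy_setup
        cond_ids = {id(p) for m in unet.conditioning_modules().values()
                    for p in m.parameters()}
        before = {k: p.data.copy() for k, p in unet.named_parameters()
                  if id(p) not in cond_ids}
        result = finetune(encoder, unet, sch, epochs, latents,
                          FinetuneConfig(epochs=2, batch_size=50, seed=0))
        after = dict(unet.named_parameters())
        for k, v in before.items():
            np.testing.assert_array_equal(v, after[k].data)
        # loss decreases over the toy run
        assert result.history[-1] < result.history[0]

    def test_trainable_inventory_names_exact_groups(self, toy_setup):
        sch, unet, encoder, _, _ = toy_setup
        names = trainable_finetune_parameters(encoder, unet).keys()
        groups = {n.split(".")[1] for n in names if n.startswith("unet.")}
        assert groups == {"tau", "sigma", "mid_attn", "up_attn"}
        assert any(n.startswith("encoder.") for n in names)

    def test_conditioning_weights_do_change(self, toy_setup):
        sch, unet, encoder, epochs, latents = toy_setup
        wq_before = unet.mid_attn.w_q.data.copy()
        finetune(encoder, unet, sch, epochs, latents,
                 FinetuneConfig(epochs=1, batch_size=50, seed=1))
        assert not np.array_equal(wq_before, unet.mid_attn.w_q.data)


class TestNWayMetric:
    def test_perfect_classifier_scores_one(self):
        scores = np.eye(10)[np.arange(10)]
        acc = n_way_top1_from_scores(scores, np.arange(10), n=5, trials=50,
                                     seed=0)
        np.testing.assert_array_equal(acc, 1.0)

    def test_random_scores_hit_chance_level(self):
        rng_local = np.random.default_rng(8)
        n_img, n_classes, n = 200, 50, 50
        scores = rng_local.random((n_img, n_classes))
        labels = rng_local.integers(0, n_classes, n_img)
        acc = n_way_top1_from_scores(scores, labels, n=n, trials=200, seed=1)
        se = np.sqrt((1 / n) * (1 - 1 / n) / n_img)
        assert abs(acc.mean() - 1 / n) < 4 * se   # analytic chance 1/n = 2%

    def test_n_equals_one_is_trivially_perfect(self):
        scores = rng.random((5, 10))
        acc = n_way_top1_from_scores(scores, np.zeros(5, dtype=int), n=1,
                                     trials=10, seed=0)
        np.testing.assert_array_equal(acc, 1.0)

    def test_invalid_n_rejected(self):
        scores = rng.random((5, 10))
        with pytest.raises(ValueError):
            n_way_top1_from_scores(scores, np.zeros(5, dtype=int), n=11,
                                   trials=10, seed=0)

    def test_best_of_samples_never_below_mean(self):
        acc = rng.random((20, 5))
        from vepdecode.diffusion import ReconstructionReport
        rep = ReconstructionReport(n_way=10, trials=100,
                                   per_image_sample_acc=acc,
                                   labels=np.zeros(20, dtype=int))
        assert rep.best_of_samples >= rep.mean_of_samples

    def test_surrogate_learns_parametric_stimuli(self):
        spec = SessionSpec(n_classes=5, images_per_class=20)
        stim = generate_stimulus_images(spec, side_px=32, seed=4)
        images, labels = stim.flat()
        clf = train_surrogate(images, labels, 5, epochs=10, seed=0)
        assert clf.accuracy(images, labels) > 0.9


class TestNullControlPlumbing:
    def test_intertrial_windows_have_isi_length_and_upsample_to_trial_length(
            self, tiny_recording):
        segs, labels = extract_intertrial_windows(tiny_recording)
        spec = tiny_recording.events.spec
        assert segs.shape[1:] == (8, spec.isi_samples)
        up = upsample_windows(segs, spec.stim_samples)
        assert up.shape[2] == 500
        # linear interpolation preserves endpoints
        np.testing.assert_allclose(up[:, :, 0], segs[:, :, 0])

    def test_fourier_upsampling_option(self, tiny_recording):
        segs, _ = extract_intertrial_windows(tiny_recording)
        up = upsample_windows(segs, 500, method="fourier")
        assert up.shape[2] == 500
        with pytest.raises(ValueError):
            upsample_windows(segs, 500, method="cubic")

    def test_channelwise_normalisation_zero_mean_unit_sd(self, tiny_recording):
        segs, _ = extract_intertrial_windows(tiny_recording)
        up = normalize_channelwise(upsample_windows(segs, 500))
        np.testing.assert_allclose(up.mean(axis=(0, 2)), 0, atol=1e-9)
        np.testing.assert_allclose(up.std(axis=(0, 2)), 1, atol=1e-9)

    def test_labels_follow_preceding_stimulus(self, tiny_recording):
        _, labels = extract_intertrial_windows(tiny_recording)
        np.testing.assert_array_equal(
            labels, tiny_recording.events.class_ids[:len(labels)])


def test_timestep_embedding_shape_and_distinctness():
    emb = timestep_embedding(np.array([1, 2, 500]), 64)
    assert emb.shape == (3, 64)
    assert not np.allclose(emb[0], emb[2])


def test_denoiser_training_reduces_loss():
    sch = DiffusionSchedule.linear(T=100)
    unet = ConditionedUNet(UNetConfig(base_channels=16),
                           np.random.default_rng(3))
    latents = rng.standard_normal((64, 4, 8, 8)).astype(np.float32) * 0.5
    hist = train_denoiser(unet, latents, sch,
                          DiffusionTrainConfig(epochs=6, seed=0))
    assert hist[-1] < hist[0]
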