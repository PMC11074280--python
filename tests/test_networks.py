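import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from debatch import (
    MODEL_FAMILIES,
    ModelConfig,
    NormalizationSpec,
    build_model,
    dann_batch_loss,
    inv_triplet_loss,
    kld_gaussian,
    label_classification_loss,
    normae_batch_loss,
    reconstruction_loss,
    rev_triplet_loss,
    total_loss,
)
from debatch import autograd as ag
from debatch.autograd import Tensor
from debatch.networks import clamped_adversarial_total, smoothed_cross_entropy


def make_cfg(family="ae", **kwargs):
    defaults = dict(n_features=8, n_classes=2, n_batches=3, layer1=6, layer2=4, seed=0)
    defaults.update(kwargs)
    return ModelConfig.for_family(family, **defaults)


# ----------------------------------------------------------------------
# model zoo
# ----------------------------------------------------------------------

class TestModelZoo:
    def test_exactly_ten_families(self):
        assert len(MODEL_FAMILIES) == 10
        combos = set(MODEL_FAMILIES.values())
        assert len(combos) == 10  # distinct (variational, strategy) pairs

    @pytest.mark.parametrize("family", sorted(MODEL_FAMILIES))
    def test_every_family_buildable(self, family):
        model = build_model(make_cfg(family))
        assert model.cfg.family == family
        x = np.random.default_rng(0).normal(size=(5, 8))
        rep = model.encode(x)
        assert rep.z.shape == (5, 4)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="valid families"):
            ModelConfig.for_family("ae-magic", n_features=4, n_classes=2, n_batches=2)

    def test_seeded_builds_identical(self):
        a = build_model(make_cfg(dropout=0.0, seed=3))
        b = build_model(make_cfg(dropout=0.0, seed=3))
        assert a.state_hash() == b.state_hash()
        c = build_model(make_cfg(dropout=0.0, seed=4))
        assert a.state_hash() != c.state_hash()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            make_cfg(layer2=0)
        with pytest.raises(ValueError):
            make_cfg(dropout=1.0)
        with pytest.raises(ValueError):
            make_cfg(label_smoothing=0.5)
        with pytest.raises(ValueError):
            ModelConfig(n_features=4, n_classes=2, n_batches=2, be_strategy="unknown")


# ----------------------------------------------------------------------
# encode / decode
# ----------------------------------------------------------------------

class TestEncodeDecode:
    def test_vae_noise_free_z_equals_mu(self):
        model = build_model(make_cfg("vae"))
        x = np.random.default_rng(1).normal(size=(6, 8))
        rep = model.encode(x, sample_noise=False)
        assert rep.mu is not None and rep.sigma is not None
        assert np.array_equal(rep.z, rep.mu)
        assert np.all(rep.sigma > 0)

    def test_vae_sampling_reproducible_after_reseed(self):
        model = build_model(make_cfg("vae"))
        x = np.random.default_rng(1).normal(size=(6, 8))
        model.reseed(99)
        z1 = model.encode(x, sample_noise=True).z
        model.reseed(99)
        z2 = model.encode(x, sample_noise=True).z
        assert np.array_equal(z1, z2)
        assert not np.array_equal(z1, model.encode(x, sample_noise=False).z)

    def test_deterministic_model_has_no_mu(self):
        model = build_model(make_cfg("ae"))
        rep = model.encode(np.zeros((2, 8)))
        assert rep.mu is None and rep.sigma is None

    def test_feature_mismatch_rejected(self):
        model = build_model(make_cfg("ae"))
        with pytest.raises(ValueError, match="features"):
            model.encode(np.zeros((2, 5)))

    def test_batch_mapping_identity_at_init(self):
        model = build_model(make_cfg("ae-bmadv"))
        z = np.random.default_rng(0).normal(size=(4, 4))
        outs = [model.decode(z, [b] * 4) for b in (0, 1, 2)]
        assert np.array_equal(outs[0], outs[1]) and np.array_equal(outs[1], outs[2])

    def test_batch_mapping_differs_once_vectors_differ(self):
        model = build_model(make_cfg("ae-bmadv"))
        model.params["batch_emb"].data[1] += 1.0
        z = np.zeros((3, 4))
        out0 = model.decode(z, [0, 0, 0])
        out1 = model.decode(z, [1, 1, 1])
        assert not np.array_equal(out0, out1)

    def test_reconstruction_shape(self):
        model = build_model(make_cfg("ae"))
        x = np.zeros((7, 8))
        rep = model.encode(x)
        assert model.decode(rep).shape == x.shape

    def test_unknown_batch_label_named_in_error(self):
        model = build_model(make_cfg("ae-bmadv"))
        model.batch_order = ["b1", "b2", "b3"]
        with pytest.raises(ValueError, match="b9"):
            model.decode(np.zeros((1, 4)), ["b9"])

    def test_batch_labels_required_for_mapping(self):
        model = build_model(make_cfg("ae-bmadv"))
        with pytest.raises(ValueError, match="batch labels"):
            model.decode(np.zeros((1, 4)))


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

class TestReconstructionLoss:
    def test_identity_is_zero(self):
        x = np.random.default_rng(0).normal(size=(4, 3))
        assert reconstruction_loss(x, x) == 0.0

    def test_constant_offset(self):
        assert reconstruction_loss(np.zeros((2, 5)), np.full((2, 5), 2.0)) == 4.0

    def test_sample_permutation_invariant(self):
        rng = np.random.default_rng(1)
        x, xh = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        assert reconstruction_loss(x, xh) == pytest.approx(
            reconstruction_loss(x[perm], xh[perm])
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 3)), np.zeros((3, 2)))


class TestKld:
    def test_prior_match_is_zero(self):
        assert kld_gaussian(np.zeros((3, 5)), np.ones((3, 5))) == pytest.approx(0.0)

    def test_unit_mean_shift(self):
        assert kld_gaussian(np.array([[1.0]]), np.array([[1.0]])) == pytest.approx(0.5)

    def test_sigma_e(self):
        expected = -0.5 * (1 + 2 - 0 - math.e**2)
        assert expected == pytest.approx(2.1945, abs=1e-4)
        assert kld_gaussian(np.array([[0.0]]), np.array([[math.e]])) == pytest.approx(expected)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kld_gaussian(np.zeros((1, 2)), np.array([[1.0, 0.0]]))

    def test_mean_over_samples(self):
        mu = np.array([[1.0], [0.0]])
        sigma = np.ones((2, 1))
        assert kld_gaussian(mu, sigma) == pytest.approx(0.25)


class TestTriplets:
    def test_coincident_embeddings_give_alpha(self):
        f = np.array([[1.0, 2.0]])
        assert inv_triplet_loss(f, f, f, 0.7) == pytest.approx(0.7)
        assert rev_triplet_loss(f, f, f, 0.7) == pytest.approx(0.7)

    def test_inv_triplet_worked_examples(self):
        fA, fP, fN = np.array([[0.0]]), np.array([[3.0]]), np.array([[1.0]])
        assert inv_triplet_loss(fA, fP, fN, 0.2) == pytest.approx(0.0, abs=1e-9)
        fP, fN = np.array([[1.0]]), np.array([[3.0]])
        assert inv_triplet_loss(fA, fP, fN, 0.2) == pytest.approx(2.2, abs=1e-9)

    def test_rev_triplet_worked_example(self):
        fA, fP, fN = np.array([[0.0]]), np.array([[1.0]]), np.array([[3.0]])
        assert rev_triplet_loss(fA, fP, fN, 0.2) == pytest.approx(0.0, abs=1e-9)
        assert rev_triplet_loss(fA, fN, fP, 0.2) == pytest.approx(2.2, abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            inv_triplet_loss(np.zeros((1, 2)), np.zeros((1, 3)), np.zeros((1, 2)), 1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_inv_triplet_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        fA, fP, fN = rng.normal(size=(3, 4, 5))
        alpha = float(rng.uniform(0, 3))
        assert inv_triplet_loss(fA, fP, fN, alpha) >= 0.0

    def test_rev_triplet_grl_flips_encoder_gradient(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 4))
        fP = Tensor(rng.normal(size=(3, 4)))
        fN = Tensor(rng.normal(size=(3, 4)))
        zA = Tensor(data, requires_grad=True)
        rev_triplet_loss(ag.gradient_reversal(zA, 1.0), fP, fN, 5.0).backward()
        zB = Tensor(data, requires_grad=True)
        rev_triplet_loss(zB, fP, fN, 5.0).backward()
        assert np.allclose(zA.grad, -zB.grad)
        assert np.any(zB.grad != 0)


class TestClassificationLoss:
    def test_confident_correct_low_loss(self):
        model = build_model(make_cfg("ae"))
        logits = Tensor(np.array([[50.0, -50.0], [-50.0, 50.0]]))
        loss = smoothed_cross_entropy(logits, np.array([0, 1]), 2, 0.0)
        assert float(loss) < 1e-6

    def test_uniform_predictor_ln_c(self):
        for C in (2, 3, 5):
            logits = Tensor(np.zeros((4, C)))
            loss = smoothed_cross_entropy(logits, np.zeros(4, dtype=int), C, 0.0)
            assert float(loss) == pytest.approx(math.log(C))

    def test_smoothing_does_not_change_uniform_loss(self):
        logits = Tensor(np.zeros((4, 2)))
        loss = smoothed_cross_entropy(logits, np.array([0, 1, 0, 1]), 2, 0.1)
        assert float(loss) == pytest.approx(math.log(2))

    def test_unknown_class_rejected(self):
        model = build_model(make_cfg("ae"))
        z = np.zeros((2, 4))
        with pytest.raises(ValueError, match="unknown class"):
            label_classification_loss(model, z, np.array([0, 5]))

    def test_wrapper_uses_model_head(self):
        model = build_model(make_cfg("ae"))
        z = np.random.default_rng(0).normal(size=(6, 4))
        val = label_classification_loss(model, z, np.array([0, 1] * 3), smoothing=0.0)
        assert float(val) > 0


class TestDannLoss:
    def test_uniform_discriminator_gives_ln_k(self):
        model = build_model(make_cfg("ae-dann"))
        model.params["disc_w"].data[:] = 0.0
        model.params["disc_b"].data[:] = 0.0
        z = np.random.default_rng(0).normal(size=(6, 4))
        val = dann_batch_loss(model, z, np.array([0, 1, 2, 0, 1, 2]), 1.0)
        assert float(val) == pytest.approx(math.log(3))

    def test_gamma_zero_blocks_encoder_gradient(self):
        model = build_model(make_cfg("ae-dann"))
        z = Tensor(np.random.default_rng(0).normal(size=(6, 4)), requires_grad=True)
        dann_batch_loss(model, z, np.array([0, 1, 2, 0, 1, 2]), 0.0).backward()
        assert np.all(z.grad == 0)

    def test_encoder_gradient_is_minus_gamma_times_plain(self):
        model = build_model(make_cfg("ae-dann"))
        codes = np.array([0, 1, 2, 0, 1, 2])
        rng = np.random.default_rng(1)
        for gamma in (0.5, 2.0):
            z1 = Tensor(rng.normal(size=(6, 4)), requires_grad=True)
            dann_batch_loss(model, z1, codes, gamma).backward()
            z2 = Tensor(z1.data, requires_grad=True)
            smoothed_cross_entropy(model.batch_logits_t(z2), codes, 3, 0.0).backward()
            assert np.allclose(z1.grad, -gamma * z2.grad, atol=1e-12)

    def test_missing_head_rejected(self):
        model = build_model(make_cfg("ae"))
        with pytest.raises(ValueError, match="batch classifier"):
            dann_batch_loss(model, np.zeros((2, 4)), np.array([0, 1]), 1.0)


class TestNormaeLoss:
    def test_detach_cuts_encoder_gradient(self):
        model = build_model(make_cfg("ae-bmadv"))
        z = Tensor(np.random.default_rng(0).normal(size=(6, 4)), requires_grad=True)
        normae_batch_loss(model, z, np.array([0, 1, 2, 0, 1, 2]), 1.0, detach=True).backward()
        assert z.grad is None

    def test_wrong_strategy_rejected(self):
        model = build_model(make_cfg("ae-dann"))
        with pytest.raises(ValueError, match="batch_mapping_adversarial"):
            normae_batch_loss(model, np.zeros((2, 4)), np.array([0, 1]), 1.0)

    def test_clamped_composite_not_negative(self):
        others = Tensor(np.array(1.0), requires_grad=True)
        disc = Tensor(np.array(5.0))
        out = clamped_adversarial_total(others, disc, gamma=1.0)
        assert float(out) == 0.0
        out2 = clamped_adversarial_total(Tensor(np.array(7.0)), disc, gamma=1.0)
        assert float(out2) == pytest.approx(2.0)

    def test_gamma_zero_reduces_to_others(self):
        out = clamped_adversarial_total(Tensor(np.array(3.0)), Tensor(np.array(9.0)), 0.0)
        assert float(out) == 3.0


class TestTotalLoss:
    def test_degenerate_weights(self):
        assert total_loss(1.5, classif=9.0, kld=9.0, be=9.0, nu=0, beta=0, gamma=0) == 1.5

    def test_arithmetic(self):
        assert total_loss(1.0, classif=2.0, nu=0.5) == pytest.approx(2.0)

    def test_linearity_in_each_weight(self):
        base = total_loss(1.0, classif=3.0, kld=2.0, be=4.0, nu=1.0, beta=1.0, gamma=1.0)
        up = total_loss(1.0, classif=3.0, kld=2.0, be=4.0, nu=1.1, beta=1.0, gamma=1.0)
        assert up - base == pytest.approx(0.1 * 3.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, classif=1.0, nu=-0.1)

    def test_random_configurations_against_term_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rec, classif, kld, be = rng.uniform(0, 5, 4)
            nu, beta, gamma = rng.uniform(0, 3, 3)
            expected = rec + nu * classif + beta * kld + gamma * be
            assert total_loss(rec, classif, kld, be, nu, beta, gamma) == pytest.approx(
                expected, abs=1e-12
            )


# ----------------------------------------------------------------------
# VAE/AE equivalence and checkpointing
# ----------------------------------------------------------------------

def test_vae_with_copied_mu_head_matches_ae_forward():
    ae = build_model(make_cfg("ae", dropout=0.0))
    vae = build_model(make_cfg("vae", dropout=0.0))
    for name in ("enc_w1", "enc_b1", "dec_w1", "dec_b1", "dec_w2", "dec_b2"):
        vae.params[name].data = ae.params[name].data.copy()
    vae.params["enc_wmu"].data = ae.params["enc_w2"].data.copy()
    vae.params["enc_bmu"].data = ae.params["enc_b2"].data.copy()
    x = np.random.default_rng(5).normal(size=(6, 8))
    assert np.allclose(vae.encode(x, sample_noise=False).z, ae.encode(x).z)


def test_checkpoint_round_trip(tmp_path):
    model = build_model(make_cfg("vae-bmadv", dropout=0.1, seed=8))
    model.batch_order = ["b1", "b2", "b3"]
    x = np.random.default_rng(2).normal(size=(5, 8))
    before = model.encode(x).z
    path = tmp_path / "ckpt.json"
    model.save(path)
    from debatch import CorrectionModel

    loaded = CorrectionModel.load(path)
    assert loaded.cfg == model.cfg
    assert loaded.batch_order == model.batch_order
    assert np.array_equal(loaded.encode(x).z, before)


def test_normalization_spec_survives_checkpoint(tmp_path):
    cfg = make_cfg("ae", normalization=NormalizationSpec(method="robust", per_batch=True))
    model = build_model(cfg)
    model.save(tmp_path / "m.json")
    from debatch import CorrectionModel

    loaded = CorrectionModel.load(tmp_path / "m.json")
    assert loaded.cfg.normalization.name == "robust_per_batch"
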