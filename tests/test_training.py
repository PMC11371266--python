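"""Unrolled denoiser, loss gradients, the training loop and lambda tuning."""

import numpy as np
import pytest

from sparl import masks, operators as ops, solvers as sol, synthetic as syn
from sparl import training as tr
from sparl._ad import val


@pytest.fixture(scope="module")
def tiny_patches():
    return syn.make_patches(80, 10, seed=7).with_noise(0.1, seed=8)


class TestUnrolledDenoise:
    def test_zero_lam_is_identity(self, rng):
        gen = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3, lam=0.0, seed=1)
        gen.lam = 0.0
        y = rng.standard_normal((8, 8))
        # lam = 0 makes the prox trivial and the gradient step lands on y
        out = tr.unrolled_denoise(gen, y, 2, 3)
        assert np.allclose(val(out), y)

    def test_deterministic_repeat(self, rng):
        gen = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3,
                                            profile_init="random", lam=0.01, seed=2)
        y = rng.standard_normal((8, 8))
        a = val(tr.unrolled_denoise(gen, y, 3, 4))
        b = val(tr.unrolled_denoise(gen, y, 3, 4))
        assert np.array_equal(a, b)

    def test_single_refinement_equals_direct_convex_solve(self, rng):
        # n1 = 1 with the all-ones initial mask is one weighted-L1 denoising
        # solve with n3 dual steps, i.e. exactly one fbs_solve call
        gen = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3,
                                            profile_init="random", lam=0.05, seed=3)
        y = rng.standard_normal((8, 8))
        n3 = 6
        l_sq = gen.W.detached().sq_norm((8, 8))
        out = tr.unrolled_denoise(gen, y, 1, n3, l_sq_norm=l_sq)
        H = ops.IdentityModel((8, 8))
        cfg = sol.SolverConfig(lam=0.05, K_FBS=1, K_prox=n3,
                               schedule=sol.ToleranceSchedule("off"), l_sq_norm=l_sq)
        direct, _ = sol.fbs_solve(H, y, ops.AnalysisOperator(gen.W), 0.05,
                                  np.zeros((8, 8)), cfg)
        assert np.allclose(val(out), val(direct), atol=1e-14)

    def test_invalid_depths(self, rng):
        gen = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3, seed=1)
        with pytest.raises(ValueError):
            tr.unrolled_denoise(gen, rng.random((4, 4)), 0, 1)


class TestTrainingLoss:
    def test_identity_denoiser_gives_half_noise_energy(self, rng):
        gen = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3, seed=1)
        gen.lam = 0.0
        clean = rng.random((3, 8, 8))
        noise = 0.1 * rng.standard_normal((3, 8, 8))
        loss = tr.training_loss(gen, clean, clean + noise, 2, 2)
        assert float(val(loss)) == pytest.approx(0.5 * np.sum(noise ** 2))

    def test_zero_on_clean_data_with_zero_lam(self, rng):
        gen = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3, seed=1)
        gen.lam = 0.0
        clean = rng.random((2, 8, 8))
        assert float(val(tr.training_loss(gen, clean, clean, 3, 2))) == pytest.approx(0.0)

    def test_empty_batch_raises(self):
        gen = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3, seed=1)
        with pytest.raises(ValueError):
            tr.training_loss(gen, np.zeros((0, 4, 4)), np.zeros((0, 4, 4)), 1, 1)

    @pytest.mark.parametrize("scheme", ["mmr", "safi"])
    def test_gradients_finite_at_random_init(self, rng, scheme):
        for seed in range(10):
            if scheme == "mmr":
                gen = masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3,
                                                    profile_init="random",
                                                    lam=0.01, seed=seed)
            else:
                gen = masks.SAFIMaskGenerator.random(n_channels=2, kernel_size=3,
                                                     spline_init="random",
                                                     lam=0.01, seed=seed)
            params = tr._wrap_parameters(gen)
            clean = rng.random((2, 6, 6))
            noisy = clean + 0.1 * rng.standard_normal((2, 6, 6))
            loss = tr.training_loss(gen, clean, noisy, 2, 3)
            loss.backward()
            for name, p in params.items():
                assert p.grad is None or np.all(np.isfinite(p.grad)), name


class TestTrainDenoiser:
    def test_fixed_seed_reproducibility(self, tiny_patches):
        cfg = tr.TrainingConfig.reduced(scheme="mmr", n_channels=2, kernel_size=3,
                                        patch_size=10, n_patches=80, epochs=1,
                                        batch_size=16, n_val=8, seed=11)
        c1 = tr.train_denoiser(tiny_patches, cfg)
        c2 = tr.train_denoiser(tiny_patches, cfg)
        assert c1.history["batch_loss"] == c2.history["batch_loss"]
        assert np.array_equal(val(c1.gen.W.kernels[0]), val(c2.gen.W.kernels[0]))
        assert c1.lam == c2.lam

    def test_constraints_hold_after_every_step(self, tiny_patches):
        cfg = tr.TrainingConfig.reduced(scheme="mmr", n_channels=3, kernel_size=3,
                                        patch_size=10, n_patches=80, epochs=1,
                                        batch_size=16, n_val=8, seed=4)
        ckpt = tr.train_denoiser(tiny_patches, cfg, max_steps=3)
        gen = ckpt.gen
        for k in gen.W.kernels:
            kv = val(k)
            assert np.all(np.abs(kv.sum(axis=(-2, -1))) < 1e-9)
        for k in gen.B.kernels:
            kv = val(k)
            assert np.all(kv >= 0)
            assert np.all(np.abs(kv.sum(axis=(-2, -1)) - 1) < 1e-9)
        d = val(gen.sigma_knots)
        assert np.allclose(d[:, 0], 1.0)
        assert np.all(np.diff(d, axis=1) <= 1e-12)
        assert ckpt.lam > 0

    def test_loss_history_recorded_and_finite(self, tiny_patches):
        cfg = tr.TrainingConfig.reduced(scheme="safi", n_channels=2, kernel_size=3,
                                        patch_size=10, n_patches=80, epochs=1,
                                        batch_size=16, n_val=8, seed=5)
        ckpt = tr.train_denoiser(tiny_patches, cfg, max_steps=4)
        assert len(ckpt.history["batch_loss"]) == 4
        assert np.all(np.isfinite(ckpt.history["batch_loss"]))


class TestTuneLambda:
    def _gen(self):
        return masks.MMRMaskGenerator.random(n_channels=2, kernel_size=3,
                                             profile_init="random", seed=6)

    def test_single_candidate_grid(self, rng):
        gen = self._gen()
        H = ops.IdentityModel((8, 8))
        clean = rng.random((8, 8))
        pairs = [(clean, syn.add_noise(clean, 0.1, seed=1))]
        assert tr.tune_lambda(gen, pairs, H, [0.02]) == 0.02

    def test_noiseless_data_prefers_least_regularization(self, rng):
        gen = self._gen()
        H = ops.IdentityModel((8, 8))
        clean = rng.random((8, 8))
        pairs = [(clean, clean)]  # noiseless: fidelity alone is optimal
        lam = tr.tune_lambda(gen, pairs, H, [1e-4, 1e-3, 1e-2, 1e-1])
        assert lam == pytest.approx(1e-4)

    def test_coarse_to_fine_close_to_exhaustive(self, rng):
        gen = self._gen()
        H = ops.IdentityModel((12, 12))
        clean = syn.make_patches(1, 12, seed=9).clean[0]
        pairs = [(clean, syn.add_noise(clean, 0.15, seed=2))]
        coarse = list(np.geomspace(1e-3, 0.3, 5))
        lam_ctf = tr.tune_lambda(gen, pairs, H, coarse)
        exhaustive = np.geomspace(1e-3, 0.3, 21)
        scores = [tr._mean_psnr(gen, "mmr", pairs, H, g, None) for g in exhaustive]
        lam_ex = float(exhaustive[int(np.argmax(scores))])
        # within one fine-grid step on the log axis
        assert abs(np.log(lam_ctf) - np.log(lam_ex)) <= np.log(exhaustive[1] / exhaustive[0]) * 3

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            tr.tune_lambda(self._gen(), [], ops.IdentityModel((4, 4)), [])
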