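"""Architecture contracts: shapes, energy preservation, spectral modules."""

import numpy as np
import pytest

from spectraseg.losses import softmax
from spectraseg.model import (NetworkConfig, build_network, count_parameters,
                              load_checkpoint, predict_labels,
                              save_checkpoint)
from spectraseg.nn.layers import EnergyFiLM, FourierGate, SpectralSE

SMALL = dict(base_channels=8, levels=3)


def _small_net(variant, seed=0):
    return build_network(NetworkConfig(variant=variant, **SMALL), seed=seed)


class TestArchitecture:
    def test_logits_shape_default_config(self):
        net = build_network(NetworkConfig(variant="spff"), seed=0)
        x = np.random.default_rng(0).standard_normal((2, 1, 5, 64, 64)
                                                     ).astype(np.float32)
        logits = net.forward(x, record_shapes=True)
        assert logits.shape == (2, 13, 64, 64)
        assert all(s[2] == 5 for s in net.last_shapes)

    @pytest.mark.parametrize("variant", ["plain", "sp", "e_sp", "fg_sp",
                                         "spff"])
    def test_energy_extent_preserved_everywhere(self, variant):
        net = _small_net(variant)
        x = np.random.default_rng(1).standard_normal((1, 1, 5, 16, 16)
                                                     ).astype(np.float32)
        logits = net.forward(x, record_shapes=True)
        assert logits.shape == (1, 13, 16, 16)
        assert net.last_shapes, "no shapes recorded"
        assert all(s[2] == 5 for s in net.last_shapes)

    def test_blind_control_collapses_energy_axis(self):
        net = _small_net("blind_control")
        x = np.random.default_rng(1).standard_normal((1, 1, 5, 16, 16)
                                                     ).astype(np.float32)
        logits = net.forward(x, record_shapes=True)
        assert logits.shape == (1, 13, 16, 16)
        assert all(s[2] == 1 for s in net.last_shapes)

    def test_plain_variant_has_no_spectral_modules(self):
        net = _small_net("plain")
        mods = [type(st).__name__ for blk in
                (*net.enc, net.bottleneck, *net.dec) for st in blk.stages]
        assert not any(m in ("SpectralSE", "EnergyFiLM", "FourierGate")
                       for m in mods)
        full = [type(st).__name__ for blk in
                (*_small_net("spff").enc,) for st in blk.stages]
        assert "SpectralSE" in full and "EnergyFiLM" in full \
            and "FourierGate" in full

    def test_invalid_inputs_rejected(self):
        net = _small_net("spff")
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 5, 18, 18), dtype=np.float32))
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 1, 4, 16, 16), dtype=np.float32))
        with pytest.raises(ValueError):
            NetworkConfig(variant="bogus")

    def test_softmax_probabilities_normalized(self):
        net = _small_net("spff")
        x = np.random.default_rng(2).standard_normal((1, 1, 5, 16, 16)
                                                     ).astype(np.float32)
        p = softmax(net.forward(x))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestPredictLabels:
    def test_one_hot_and_tie_break(self):
        logits = np.zeros((1, 4, 2, 2))
        logits[0, 2, 0, 0] = 5.0
        pred = predict_labels(logits)
        assert pred[0, 0, 0] == 2
        assert pred[0, 1, 1] == 0  # all-equal tie goes to class 0

    def test_shift_invariance(self, rng):
        logits = rng.standard_normal((2, 13, 4, 4))
        shifted = logits + rng.standard_normal((2, 1, 4, 4))
        assert np.array_equal(predict_labels(logits), predict_labels(shifted))


class TestParameterCounts:
    def test_supersets_and_seed_invariance(self):
        counts = {v: count_parameters(_small_net(v, seed=0))
                  for v in ("plain", "sp", "e_sp", "fg_sp", "spff")}
        assert counts["plain"] < counts["sp"] < counts["e_sp"]
        assert counts["sp"] < counts["fg_sp"] < counts["spff"]
        assert counts["spff"] == count_parameters(_small_net("spff", seed=99))

    def test_default_config_in_millions_corridor(self):
        n = count_parameters(build_network(NetworkConfig(variant="spff")))
        assert 1e6 < n < 9.5e6


class TestSpectralModules:
    def test_spec_se_zeroed_excitation_halves_features(self, rng):
        se = SpectralSE(8, 0, "se")
        se.w2.data[...] = 0.0
        se.b2.data[...] = 0.0
        u = rng.standard_normal((2, 8, 5, 4, 4)).astype(np.float32)
        assert np.allclose(se.forward(u), 0.5 * u, atol=1e-6)

    def test_spec_se_gate_in_unit_interval_and_spatially_uniform(self, rng):
        se = SpectralSE(8, 1, "se")
        u = rng.standard_normal((2, 8, 5, 4, 4)).astype(np.float32)
        g = se.gate(u)
        assert np.all(g > 0) and np.all(g < 1)
        # spatially constant input -> spatially constant output
        uc = np.broadcast_to(rng.standard_normal((2, 8, 5, 1, 1)),
                             (2, 8, 5, 4, 4)).astype(np.float32)
        y = se.forward(uc)
        assert np.allclose(y, y[..., :1, :1], atol=1e-6)

    def test_energy_film_identity_at_init(self, rng):
        film = EnergyFiLM(8, 5, 0, "film")
        u = rng.standard_normal((2, 8, 5, 4, 4)).astype(np.float32)
        assert np.allclose(film.forward(u), u, atol=1e-6)

    def test_energy_film_forced_affine(self, rng):
        film = EnergyFiLM(8, 5, 0, "film")
        film.w2.data[...] = 0.0
        film.b2.data[:8] = 1.0    # dgamma = 1 -> gamma = 2
        film.b2.data[8:] = -1.0   # beta = -1
        u = rng.standard_normal((2, 8, 5, 4, 4)).astype(np.float32)
        assert np.allclose(film.forward(u), 2 * u - 1, atol=1e-6)

    def test_energy_film_broadcasts_over_space(self, rng):
        film = EnergyFiLM(4, 3, 0, "film")
        film.w2.data = rng.normal(0, 0.3, film.w2.data.shape
                                  ).astype(np.float32)
        film.b2.data = rng.normal(0, 0.3, film.b2.data.shape
                                  ).astype(np.float32)
        u = rng.standard_normal((1, 4, 3, 6, 6)).astype(np.float64)
        y = film.forward(u)
        _, _, dg, beta = film._film_params(np.float64)
        ratio = (y - beta.T[None, :, :, None, None]) / u
        for c in range(4):
            for f in range(3):
                assert np.allclose(ratio[0, c, f], ratio[0, c, f, 0, 0],
                                   atol=1e-9)

    def test_fourier_gate_identity_mask_round_trip(self):
        fg = FourierGate(5, 0, "fg")
        u = np.ones((1, 3, 5, 2, 2), dtype=np.float64)
        assert np.allclose(fg.forward(u), u, atol=1e-7)
        s = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        u2 = np.broadcast_to(s[None, None, :, None, None],
                             (1, 3, 5, 2, 2)).astype(np.float64)
        w = fg.gate(u2)
        assert np.allclose(w[0], s, atol=1e-6)

    def test_fourier_gate_dc_only_mask_reconstructs_mean(self):
        fg = FourierGate(5, 0, "fg")
        fg.mask.data = np.array([1.0, 0.0, 0.0], dtype=np.float32)
        s = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        u = np.broadcast_to(s[None, None, :, None, None],
                            (1, 1, 5, 1, 1)).astype(np.float64)
        w = fg.gate(u)
        assert np.allclose(w[0], 1.8, atol=1e-6)

    def test_fourier_gate_matches_complex_dft_oracle(self, rng):
        """Gate equals mask-filtered irfft(rfft(s)) via the full complex DFT."""
        for trial in range(100):
            F = int(rng.integers(2, 8))
            fg = FourierGate(F, trial, "fg")
            fg.mask.data = rng.uniform(0, 2, F // 2 + 1).astype(np.float32)
            u = rng.standard_normal((2, 3, F, 3, 3)).astype(np.float64)
            w = fg.gate(u)
            s = u.mean(axis=(1, 3, 4))
            # oracle: full complex DFT matrix, hermitian mask extension
            Wdft = np.exp(-2j * np.pi * np.outer(np.arange(F), np.arange(F))
                          / F)
            S = s @ Wdft.T
            mask_full = np.zeros(F)
            m = np.maximum(fg.mask.data, 0)
            K = F // 2 + 1
            mask_full[:K] = m
            if F > 1:
                mask_full[K:] = m[1:(F + 1) // 2][::-1]
            w_ref = np.real((S * mask_full) @ np.conj(Wdft)) / F
            assert np.abs(w - w_ref).max() < 1e-5


class TestIdentityComposition:
    def test_e_sp_equals_sp_at_initialization(self):
        """FiLM is identity at init, so e_sp and sp agree on shared weights."""
        a = _small_net("sp", seed=3)
        b = _small_net("e_sp", seed=3)
        x = np.random.default_rng(0).standard_normal((1, 1, 5, 16, 16)
                                                     ).astype(np.float32)
        assert np.abs(a.forward(x) - b.forward(x)).max() < 1e-5


class TestCheckpoint:
    def test_round_trip_preserves_forward(self, tmp_path):
        net = _small_net("spff", seed=4)
        x = np.random.default_rng(0).standard_normal((1, 1, 5, 16, 16)
                                                     ).astype(np.float32)
        y1 = net.forward(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net, seed=4, extra={"note": "test"})
        net2, meta = load_checkpoint(path)
        assert meta["seed"] == 4 and meta["extra"]["note"] == "test"
        assert np.allclose(net2.forward(x), y1, atol=1e-6)
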