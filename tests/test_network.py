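"""Architecture contracts: shapes, determinism, attention math, parameter
accounting and the module toggles."""

import numpy as np
import pytest

from mfaunet import _autodiff as ad
from mfaunet.layers import Conv2d
from mfaunet.network import (MBDM, MSAM, PAM, ModelConfig, build_model,
                             count_parameters)


@pytest.fixture(scope="module")
def micro_model(micro_config):
    return build_model(micro_config)


class TestBuildModel:
    def test_forward_returns_three_full_resolution_maps(self, micro_model, rng):
        x = rng.normal(size=(1, 1, 32, 32))
        outs = micro_model(x)
        assert len(outs) == 3
        for o in outs:
            assert o.shape == (1, 1, 32, 32)

    def test_predict_mode_selects_single_fusion_map(self, micro_model, rng):
        x = rng.normal(size=(2, 1, 16, 16))
        assert micro_model.predict_logits(x).shape == (2, 1, 16, 16)

    def test_same_seed_builds_identical_weights(self, micro_config):
        a = build_model(micro_config)
        b = build_model(micro_config)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_forward_is_deterministic(self, micro_model, rng):
        x = rng.normal(size=(1, 1, 16, 16))
        micro_model.eval()
        a = micro_model.predict_proba(x)
        b = micro_model.predict_proba(x)
        assert np.array_equal(a, b)

    def test_disabling_all_modules_strictly_reduces_parameters(self, micro_config):
        full = count_parameters(build_model(micro_config))
        cfg = ModelConfig(**{**micro_config.as_dict(), "use_msam": False,
                             "use_pam": False, "use_mbdm": False})
        assert count_parameters(build_model(cfg)) < full

    def test_invalid_channel_list_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(encoder_channels=(64, 64, 128, 256))

    def test_input_shape_validation(self, micro_model):
        with pytest.raises(ValueError):
            micro_model(np.zeros((1, 1, 30, 30)))   # not divisible by 8
        with pytest.raises(ValueError):
            micro_model(np.zeros((1, 2, 32, 32)))   # not single-channel


class TestParameterAccounting:
    def test_lone_conv_closed_form(self, rng):
        conv = Conv2d(4, 8, 3, np.random.default_rng(0))
        n = sum(p.data.size for p in conv.parameters())
        assert n == 4 * 8 * 9 + 8

    def test_ablation_counts_strictly_increase(self):
        """Cumulative module additions order the counts as in the ablation
        study: baseline < +PAM < +MSAM < +MBDM."""
        def count(**toggles):
            cfg = ModelConfig(use_msam=False, use_pam=False, use_mbdm=False)
            cfg = ModelConfig(**{**cfg.as_dict(), **toggles})
            return count_parameters(build_model(cfg))

        baseline = count()
        plus_pam = count(use_pam=True)
        plus_msam = count(use_pam=True, use_msam=True)
        plus_mbdm = count(use_pam=True, use_msam=True, use_mbdm=True)
        assert baseline < plus_pam < plus_msam < plus_mbdm


class TestMSAM:
    def _msam(self, cfg):
        return MSAM(cfg, np.random.default_rng(3))

    def test_attention_rows_normalise(self, micro_config, rng):
        msam = self._msam(micro_config)
        c1, c2, c3 = micro_config.encoder_channels[1:]
        f1 = ad.Tensor(rng.normal(size=(2, c1, 8, 8)))
        f2 = ad.Tensor(rng.normal(size=(2, c2, 4, 4)))
        f3 = ad.Tensor(rng.normal(size=(2, c3, 2, 2)))
        msam(f1, f2, f3)
        np.testing.assert_allclose(msam.last_csa_attn.sum(-1), 1.0, atol=1e-6)
        np.testing.assert_allclose(msam.last_ssa_attn.sum(-1), 1.0, atol=1e-6)

    def test_output_shapes_replace_skips(self, micro_config, rng):
        msam = self._msam(micro_config)
        c1, c2, c3 = micro_config.encoder_channels[1:]
        f1 = ad.Tensor(rng.normal(size=(1, c1, 8, 8)))
        f2 = ad.Tensor(rng.normal(size=(1, c2, 4, 4)))
        f3 = ad.Tensor(rng.normal(size=(1, c3, 2, 2)))
        s1, s2, s3 = msam(f1, f2, f3)
        assert s1.shape == f1.shape and s2.shape == f2.shape and s3.shape == f3.shape

    def test_token_cap_guard(self, micro_config, rng):
        cfg = ModelConfig(**{**micro_config.as_dict(), "msam_token_cap": 8})
        msam = self._msam(cfg)
        c1, c2, c3 = cfg.encoder_channels[1:]
        with pytest.raises(ValueError):
            msam(ad.Tensor(rng.normal(size=(1, c1, 8, 8))),
                 ad.Tensor(rng.normal(size=(1, c2, 4, 4))),
                 ad.Tensor(rng.normal(size=(1, c3, 2, 2))))

    def test_csa_and_ssa_match_double_loop_oracle(self, micro_config, rng):
        """Recompute both attention stages with explicit python loops from
        the module's own weights (4x4 spatial grid, D = 16)."""
        msam = self._msam(micro_config)
        d = micro_config.token_dim
        n, t = 1, 16
        z = rng.normal(size=(n, t, d))
        ch = msam.ch_embed.data
        wq, wk, wv = msam.wq.weight.data, msam.wk.weight.data, msam.wv.weight.data

        # oracle CSA
        q = ch @ wq
        k = z[0] @ wk
        v = z[0] @ wv
        scores = q @ k.T / np.sqrt(d)
        attn = np.zeros_like(scores)
        for i in range(scores.shape[0]):
            e = np.exp(scores[i] - scores[i].max())
            attn[i] = e / e.sum()
        f_ch = ch + attn @ v
        gate = 1 / (1 + np.exp(-(f_ch @ msam.gate.weight.data
                                 + msam.gate.bias.data)))
        s_ch_oracle = z[0] * gate[:, 0][None, :]

        # module CSA (replicate the token pathway pieces)
        zt = ad.Tensor(z)
        kk = msam.wk(zt)
        vv = msam.wv(zt)
        qq = msam.wq(msam.ch_embed)
        a = ad.softmax(ad.matmul(qq, ad.transpose(kk, (0, 2, 1)))
                       * (1.0 / np.sqrt(d)), axis=-1)
        f_ch_mod = msam.ch_embed + ad.matmul(a, vv)
        gate_mod = ad.sigmoid(msam.gate(f_ch_mod))
        s_ch_mod = zt * ad.transpose(gate_mod, (0, 2, 1))
        np.testing.assert_allclose(s_ch_mod.data[0], s_ch_oracle, atol=1e-5)

        # oracle SSA on the gated tokens
        sq = s_ch_oracle @ msam.sq.weight.data
        sk = s_ch_oracle @ msam.sk.weight.data
        sv = s_ch_oracle @ msam.sv.weight.data
        s = msam._s
        out = np.zeros((t, s))
        for i in range(t):
            sc = np.array([sq[i] @ sk[j] / np.sqrt(s) for j in range(t)])
            e = np.exp(sc - sc.max())
            w = e / e.sum()
            out[i] = sum(w[j] * sv[j] for j in range(t))
        ssa_oracle = s_ch_oracle + (out @ msam.so.weight.data
                                    + msam.so.bias.data)

        sqm, skm, svm = msam.sq(s_ch_mod), msam.sk(s_ch_mod), msam.sv(s_ch_mod)
        am = ad.softmax(ad.matmul(sqm, ad.transpose(skm, (0, 2, 1)))
                        * (1.0 / np.sqrt(s)), axis=-1)
        ssa_mod = s_ch_mod + msam.so(ad.matmul(am, svm))
        np.testing.assert_allclose(ssa_mod.data[0], ssa_oracle, atol=1e-5)


class TestPAM:
    def test_zero_initialised_attention_passes_input_through(self, rng):
        pam = PAM(4, 2, np.random.default_rng(0))
        for lin in (pam.fc0, pam.fc1):
            lin.weight.data[...] = 0.0
            lin.bias.data[...] = 0.0
        pam.spatial.weight.data[...] = 0.0
        pam.spatial.bias.data[...] = 0.0
        x = rng.normal(size=(2, 4, 6, 6))
        out = pam(ad.Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_channel_weights_match_scalar_oracle(self, rng):
        pam = PAM(2, 1, np.random.default_rng(5))
        x = rng.normal(size=(1, 2, 2, 2))
        w0, b0 = pam.fc0.weight.data, pam.fc0.bias.data
        w1, b1 = pam.fc1.weight.data, pam.fc1.bias.data

        def mlp(vec):
            h = np.maximum(vec @ w0 + b0, 0.0)
            return h @ w1 + b1

        avg = x.mean(axis=(2, 3))[0]
        mx = x.max(axis=(2, 3))[0]
        mc_oracle = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
        out = pam(ad.Tensor(x))
        ms = 1 / (1 + np.exp(-(pam.spatial(ad.concat(
            [ad.tmean(ad.Tensor(x), 1, keepdims=True),
             ad.tmax(ad.Tensor(x), 1, keepdims=True)], 1)).data)))
        expect = x * mc_oracle[None, :, None, None] + x * ms
        np.testing.assert_allclose(out.data, expect, atol=1e-6)

    def test_gate_values_inside_unit_interval(self, rng):
        pam = PAM(8, 2, np.random.default_rng(1))
        x = ad.Tensor(rng.normal(size=(2, 8, 4, 4)) * 3)
        avg = ad.tmean(x, axis=(2, 3))
        mx = ad.tmax(ad.tmax(x, axis=3), axis=2)
        mc = ad.sigmoid(pam._mlp(avg) + pam._mlp(mx))
        assert np.all(mc.data > 0) and np.all(mc.data < 1)


class TestMBDM:
    def test_same_padding_and_three_outputs(self, rng):
        head = MBDM(4, 2, np.random.default_rng(0))
        x = ad.Tensor(rng.normal(size=(1, 4, 16, 16)))
        l1, l2, lf = head(x)
        assert l1.shape == l2.shape == lf.shape == (1, 1, 16, 16)

    def test_all_branches_receive_gradient(self, micro_config, rng):
        from mfaunet import losses

        model = build_model(micro_config)
        x = rng.normal(size=(2, 1, 16, 16))
        y = (rng.random((2, 1, 16, 16)) > 0.8).astype(float)
        outs = model(x)
        probs = tuple(ad.sigmoid(o) for o in outs)
        loss = losses.deep_supervision_loss(probs, y)
        model.zero_grad()
        loss.backward()
        for branch in (model.head.b1a.conv, model.head.b2a.conv, model.head.fa.conv):
            g = branch.weight.grad
            assert g is not None and np.any(g != 0.0)
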