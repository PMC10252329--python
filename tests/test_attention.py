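"""Attention arithmetic: hand cases, loop-oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbamhar.attention import (
    AttentionSpec,
    ChannelAttentionParams,
    ConfigurationError,
    DimensionError,
    SpatialAttentionParams,
    apply_channel_mask,
    apply_spatial_mask,
    attention_param_count,
    cbam_forward,
    channel_attention_mask,
    channel_pool,
    spatial_attention_mask,
    spatial_pool,
)

import _oracles as orc

RNG = np.random.default_rng(42)


def random_params(c, r, k, rng, activation="relu"):
    ch = ChannelAttentionParams.initialise(c, r, rng, hidden_activation=activation)
    sp = SpatialAttentionParams.initialise(k, rng)
    return ch, sp


def zero_channel_params(c, r):
    h = c // r
    return ChannelAttentionParams(
        w_hidden=np.zeros((c, h)), b_hidden=np.zeros(h),
        w_out=np.zeros((h, c)), b_out=np.zeros(c),
    )


# ---------------------------------------------------------------------------
# pooling


def test_spatial_pool_constant_channel():
    x = np.full((3, 4, 5), 0.0)
    for c, v in enumerate([1.5, -2.0, 7.0]):
        x[c] = v
    favg, fmax = spatial_pool(x)
    assert np.allclose(favg, [1.5, -2.0, 7.0])
    assert np.allclose(fmax, [1.5, -2.0, 7.0])


def test_spatial_pool_hand_case():
    x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2)
    favg, fmax = spatial_pool(x)
    assert np.allclose(favg, [2.5])
    assert np.allclose(fmax, [4.0])


def test_channel_pool_singleton_and_hand_case():
    x = RNG.normal(size=(1, 3, 4))
    favg, fmax = channel_pool(x)
    assert np.allclose(favg, x[0]) and np.allclose(fmax, x[0])
    x2 = np.stack([np.ones((2, 2)), 3 * np.ones((2, 2))])
    favg2, fmax2 = channel_pool(x2)
    assert np.allclose(favg2, 2.0) and np.allclose(fmax2, 3.0)


@pytest.mark.parametrize("shape", [(3, 4, 5), (5, 3, 2), (1, 1, 1), (8, 6, 6)])
def test_pooling_matches_loop_oracle(shape):
    x = RNG.normal(size=shape)
    favg, fmax = spatial_pool(x)
    oavg, omax = orc.spatial_pool_loop(x)
    np.testing.assert_allclose(favg, oavg, rtol=1e-6)
    np.testing.assert_allclose(fmax, omax, rtol=1e-6)
    assert np.all(fmax >= favg - 1e-12)
    cavg, cmax = channel_pool(x)
    ocavg, ocmax = orc.channel_pool_loop(x)
    np.testing.assert_allclose(cavg, ocavg, rtol=1e-6)
    np.testing.assert_allclose(cmax, ocmax, rtol=1e-6)


def test_pooling_rejects_bad_input():
    with pytest.raises(DimensionError):
        spatial_pool(np.empty((0, 2, 2)))
    with pytest.raises(DimensionError):
        channel_pool(np.ones((2, 2)))
    with pytest.raises(DimensionError):
        spatial_pool(np.full((1, 2, 2), np.nan))


# ---------------------------------------------------------------------------
# channel attention


def test_channel_mask_zero_weights_is_half():
    x = RNG.normal(size=(4, 3, 2))
    mask = channel_attention_mask(x, zero_channel_params(4, 2))
    np.testing.assert_allclose(mask, 0.5)


def test_channel_mask_constant_channels_forces_pooling_identity():
    # favg == fmax == v, so the mask is sigmoid(2 * MLP(v))
    v = np.array([0.3, -1.2, 0.8, 0.1])
    x = np.repeat(v[:, None, None], 6, axis=1).repeat(5, axis=2)
    p = ChannelAttentionParams.initialise(4, 2, np.random.default_rng(0))
    expected = 1.0 / (1.0 + np.exp(-2.0 * p.mlp(v)))
    np.testing.assert_allclose(channel_attention_mask(x, p), expected, rtol=1e-9)


def test_channel_mask_matches_loop_oracle():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(4, 3, 2))
    p = ChannelAttentionParams.initialise(4, 2, rng)
    expected = orc.channel_mask_loop(x, p.w_hidden, p.b_hidden, p.w_out, p.b_out)
    np.testing.assert_allclose(channel_attention_mask(x, p), expected, rtol=1e-6)


def test_channel_mask_dimension_mismatch():
    p = ChannelAttentionParams.initialise(4, 2, RNG)
    with pytest.raises(DimensionError):
        channel_attention_mask(np.ones((3, 2, 2)), p)


# ---------------------------------------------------------------------------
# spatial attention


def test_spatial_mask_zero_kernel_is_half():
    x = RNG.normal(size=(3, 5, 4))
    p = SpatialAttentionParams(kernel=np.zeros((2, 3, 3)))
    np.testing.assert_allclose(spatial_attention_mask(x, p), 0.5)


def test_spatial_mask_k1_is_pointwise():
    # 1x1 kernel (a, b): mask = sigmoid(a*avg + b*max), no neighbourhood
    a, b = 0.7, -1.3
    x = RNG.normal(size=(3, 4, 5))
    with pytest.warns(UserWarning):
        AttentionSpec(mode="SP", k=1, placement=1)  # diagnostic, non-canonical
    p = SpatialAttentionParams(kernel=np.array([[[a]], [[b]]]))
    favg, fmax = channel_pool(x)
    expected = 1.0 / (1.0 + np.exp(-(a * favg + b * fmax)))
    np.testing.assert_allclose(spatial_attention_mask(x, p), expected, rtol=1e-9)


def test_spatial_mask_matches_loop_oracle():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(3, 5, 4))
    p = SpatialAttentionParams.initialise(3, rng)
    expected = orc.spatial_mask_loop(x, p.kernel)
    np.testing.assert_allclose(spatial_attention_mask(x, p), expected, rtol=1e-6)


def test_even_kernel_rejected():
    with pytest.raises(ConfigurationError):
        SpatialAttentionParams.initialise(4, RNG)
    with pytest.raises(ConfigurationError):
        AttentionSpec(mode="SP", k=4, placement=1)


# ---------------------------------------------------------------------------
# mask application and the combined block


def test_apply_masks_identity_and_scaling():
    x = RNG.normal(size=(2, 3, 4))
    np.testing.assert_allclose(apply_channel_mask(x, np.ones(2)), x)
    np.testing.assert_allclose(apply_spatial_mask(x, np.ones((3, 4))), x)
    np.testing.assert_allclose(apply_channel_mask(x[:1], np.array([0.5])), x[:1] / 2)


def test_apply_spatial_mask_locality():
    x = RNG.normal(size=(3, 4, 5))
    m = np.ones((4, 5))
    m[2, 3] = 0.5
    out = apply_spatial_mask(x, m)
    np.testing.assert_allclose(out[:, 2, 3], 0.5 * x[:, 2, 3])
    mask_rest = np.ones((4, 5), dtype=bool)
    mask_rest[2, 3] = False
    np.testing.assert_allclose(out[:, mask_rest], x[:, mask_rest])


def test_apply_mask_shape_errors():
    x = RNG.normal(size=(2, 3, 4))
    with pytest.raises(DimensionError):
        apply_channel_mask(x, np.ones(3))
    with pytest.raises(DimensionError):
        apply_spatial_mask(x, np.ones((4, 3)))


def test_cbam_zero_weights_quarters_input():
    x = RNG.normal(size=(4, 5, 3))
    spec = AttentionSpec(mode="CHSP", r=2, k=3, placement=1)
    out = cbam_forward(x, spec, ch=zero_channel_params(4, 2),
                       sp=SpatialAttentionParams(kernel=np.zeros((2, 3, 3))))
    np.testing.assert_allclose(out, 0.25 * x, rtol=1e-12)


def test_cbam_channel_mode_is_definitional():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(4, 3, 5))
    p = ChannelAttentionParams.initialise(4, 4, rng)
    spec = AttentionSpec(mode="CH", r=4, placement=2)
    np.testing.assert_allclose(
        cbam_forward(x, spec, ch=p),
        apply_channel_mask(x, channel_attention_mask(x, p)),
    )


def test_cbam_missing_params_rejected():
    spec = AttentionSpec(mode="CHSP", r=2, k=3, placement=1)
    with pytest.raises(ConfigurationError):
        cbam_forward(np.ones((2, 2, 2)), spec, ch=zero_channel_params(2, 2))


def test_cbam_matches_two_stage_loop_oracle():
    rng = np.random.default_rng(19)
    x = rng.normal(size=(4, 4, 3))
    ch, sp = random_params(4, 2, 3, rng)
    spec = AttentionSpec(mode="CHSP", r=2, k=3, placement=1)
    expected = orc.cbam_loop(x, ch.w_hidden, ch.b_hidden, ch.w_out, ch.b_out,
                             sp.kernel)
    np.testing.assert_allclose(cbam_forward(x, spec, ch=ch, sp=sp),
                               expected, rtol=1e-6)


def test_randomised_oracle_equivalence_200_trials():
    """Vectorised ops agree with explicit loops on 200 random instances."""
    rng = np.random.default_rng(123)
    for _ in range(200):
        c = int(rng.integers(1, 9))
        h = int(rng.integers(1, 7))
        w = int(rng.integers(1, 7))
        x = rng.normal(size=(c, h, w))
        r = int(rng.choice([d for d in (1, 2, 4, 8) if c % d == 0]))
        ch = ChannelAttentionParams.initialise(c, r, rng)
        k = int(rng.choice([1, 3]))
        sp = SpatialAttentionParams.initialise(k, rng)
        np.testing.assert_allclose(
            channel_attention_mask(x, ch),
            orc.channel_mask_loop(x, ch.w_hidden, ch.b_hidden, ch.w_out, ch.b_out),
            rtol=1e-6,
        )
        np.testing.assert_allclose(
            spatial_attention_mask(x, sp), orc.spatial_mask_loop(x, sp.kernel),
            rtol=1e-6,
        )
        spec = AttentionSpec(mode="CHSP", r=r, k=k, placement=1) if k != 1 else None
        if spec is not None:
            np.testing.assert_allclose(
                cbam_forward(x, spec, ch=ch, sp=sp),
                orc.cbam_loop(x, ch.w_hidden, ch.b_hidden, ch.w_out, ch.b_out,
                              sp.kernel),
                rtol=1e-6,
            )


# ---------------------------------------------------------------------------
# invariants


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_masks_strictly_inside_unit_interval(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(scale=3.0, size=(4, 3, 3))
    ch = ChannelAttentionParams.initialise(4, 2, rng)
    sp = SpatialAttentionParams.initialise(3, rng)
    cm = channel_attention_mask(x, ch)
    sm = spatial_attention_mask(x, sp)
    assert np.all((cm > 0) & (cm < 1))
    assert np.all((sm > 0) & (sm < 1))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_cbam_shrinks_and_preserves_zero(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(4, 3, 3))
    ch = ChannelAttentionParams.initialise(4, 2, rng)
    sp = SpatialAttentionParams.initialise(3, rng)
    spec = AttentionSpec(mode="CHSP", r=2, k=3, placement=1)
    out = cbam_forward(x, spec, ch=ch, sp=sp)
    assert np.all(np.abs(out) <= np.abs(x) + 1e-12)
    assert np.all(np.sign(out[x != 0]) == np.sign(x[x != 0]))
    zero = cbam_forward(np.zeros_like(x), spec, ch=ch, sp=sp)
    np.testing.assert_allclose(zero, 0.0)


def test_channel_mask_invariant_to_spatial_permutation():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(4, 3, 5))
    ch = ChannelAttentionParams.initialise(4, 2, rng)
    ref = channel_attention_mask(x, ch)
    flat = x.reshape(4, -1)
    perm = rng.permutation(15)
    xp = flat[:, perm].reshape(4, 3, 5)
    np.testing.assert_allclose(channel_attention_mask(xp, ch), ref, rtol=1e-9)


def test_spatial_mask_invariant_to_channel_permutation():
    rng = np.random.default_rng(6)
    x = rng.normal(size=(5, 4, 3))
    sp = SpatialAttentionParams.initialise(3, rng)
    ref = spatial_attention_mask(x, sp)
    xp = x[rng.permutation(5)]
    np.testing.assert_allclose(spatial_attention_mask(xp, sp), ref, rtol=1e-9)


# ---------------------------------------------------------------------------
# parameter accounting


@pytest.mark.parametrize("r,expected", [(1, 8320), (2, 4192), (4, 2128),
                                        (8, 1096), (16, 580)])
def test_channel_overhead_closed_form_and_instantiated(r, expected):
    spec = AttentionSpec(mode="CH", r=r, placement=1)
    assert attention_param_count(spec, 64) == expected
    p = ChannelAttentionParams.initialise(64, r, RNG)
    assert p.n_params == expected


@pytest.mark.parametrize("k,expected", [(3, 18), (5, 50), (7, 98)])
def test_spatial_overhead_closed_form_and_instantiated(k, expected):
    spec = AttentionSpec(mode="SP", k=k, placement=1)
    assert attention_param_count(spec, 64) == expected
    assert SpatialAttentionParams.initialise(k, RNG).n_params == expected


@pytest.mark.parametrize("r", [1, 2, 4, 8, 16])
@pytest.mark.parametrize("k", [3, 5, 7])
def test_combined_overhead_is_additive(r, k):
    combined = attention_param_count(AttentionSpec(mode="CHSP", r=r, k=k,
                                                   placement=2), 64)
    ch = attention_param_count(AttentionSpec(mode="CH", r=r, placement=2), 64)
    sp = attention_param_count(AttentionSpec(mode="SP", k=k, placement=2), 64)
    assert combined == ch + sp
    p_ch = ChannelAttentionParams.initialise(64, r, RNG)
    p_sp = SpatialAttentionParams.initialise(k, RNG)
    assert combined == p_ch.n_params + p_sp.n_params


def test_all_layers_placement_multiplies_by_four():
    single = attention_param_count(AttentionSpec(mode="CH", r=2, placement=3), 64)
    all_layers = attention_param_count(AttentionSpec(mode="CH", r=2,
                                                     placement="all"), 64)
    assert all_layers == 4 * single


def test_param_count_edge_cases_and_errors():
    assert attention_param_count(AttentionSpec(mode="CH", r=1, placement=1), 1) == 4
    with pytest.raises(ConfigurationError):
        attention_param_count(AttentionSpec(mode="CH", r=16, placement=1), 24)
    with pytest.raises(ConfigurationError):
        AttentionSpec(mode="CH", r=0, placement=1)
    with pytest.raises(ConfigurationError):
        AttentionSpec(mode="CH", r=2, k=3, placement=1)  # k without spatial mode
    with pytest.raises(ConfigurationError):
        AttentionSpec(mode="SP", k=3, placement=5)
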