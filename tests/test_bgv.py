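"""Modulus-switching scheme: key identities, homomorphisms, level logic."""

import numpy as np
import pytest

from hegenome import paramsel
from hegenome.bgv import (
    BGVCiphertext,
    bgv_add,
    bgv_decrypt,
    bgv_encrypt,
    bgv_keygen,
    bgv_mult,
    bgv_noise,
    bgv_params_gen,
    bgv_sub,
    bgv_toy_params,
    mod_switch,
    switch_key,
)
from hegenome.errors import (
    DecryptionFailure,
    DepthBudgetError,
    InvalidParameterError,
)
from hegenome.ring import RingElement, centered, crt_pack, crt_unpack, ring_mul


@pytest.fixture(scope="module")
def setup():
    params = bgv_toy_params(m=85, t=512, L=4)
    rng = np.random.default_rng(3)
    keys = bgv_keygen(params, rng)
    return params, keys, rng


def random_msg(params, rng):
    return RingElement(
        tuple(centered(int(v), params.t)
              for v in rng.integers(0, params.t, params.n)),
        params.t,
    )


def canon(elem, t):
    return [c % t for c in elem.coeffs]


class TestParamsGen:
    def test_toy_profile_consistency(self):
        params = bgv_params_gen(lam=20, L=3, t=1 << 9)
        assert params.chain[0] > params.t
        for lo, hi in zip(params.chain, params.chain[1:]):
            assert hi % lo == 0
        bound = paramsel.bgv_security_min_phi(3, params.m, 20)
        assert params.n >= bound

    def test_published_scale_bound_is_met_by_8191(self):
        # the lambda=80, L=7 bound must accept phi(8191) = 8190
        assert paramsel.bgv_security_min_phi(7, 8191, 80) <= 8190

    def test_chain_divisibility(self, setup):
        params, _, _ = setup
        for lo, hi in zip(params.chain, params.chain[1:]):
            assert hi % lo == 0
        assert all(p % params.t == 1 for p in params.primes)

    def test_rejects_short_chain(self):
        with pytest.raises(InvalidParameterError):
            bgv_toy_params(m=85, t=2, L=1)


class TestKeygen:
    def test_rlwe_relation(self, setup):
        params, _, _ = setup
        rng = np.random.default_rng(9)
        for _ in range(20):
            keys = bgv_keygen(params, rng)
            a, b = keys.pk
            noise = b - ring_mul(a, keys.sk, params.ring)
            assert all(c % params.t == 0 for c in noise.coeffs)

    def test_secret_weight(self, setup):
        params, keys, _ = setup
        assert sum(1 for c in keys.sk.coeffs if c) == params.noise.h

    def test_fresh_zero_decrypts_to_zero(self, setup):
        params, keys, rng = setup
        zero = RingElement((0,) * params.n, params.t)
        assert bgv_decrypt(bgv_encrypt(zero, keys, rng), keys).is_zero()


class TestEncryptDecrypt:
    def test_roundtrip(self, setup):
        params, keys, rng = setup
        for _ in range(50):
            m = random_msg(params, rng)
            got = bgv_decrypt(bgv_encrypt(m, keys, rng), keys)
            assert canon(got, params.t) == canon(m, params.t)

    def test_encryption_is_randomized(self, setup):
        params, keys, rng = setup
        m = random_msg(params, rng)
        assert bgv_encrypt(m, keys, rng).c0 != bgv_encrypt(m, keys, rng).c0

    def test_failure_signal_flips_on_huge_noise(self, setup):
        params, keys, rng = setup
        ct = bgv_encrypt(random_msg(params, rng), keys, rng)
        q = params.chain[ct.level]
        bad = BGVCiphertext(
            c0=ct.c0 + RingElement(((q + 1) // 2,) + (0,) * (params.n - 1), q),
            c1=ct.c1, level=ct.level, noise_est=ct.noise_est,
        )
        bgv_decrypt(ct, keys)  # quiet ciphertext passes
        with pytest.raises(DecryptionFailure):
            bgv_decrypt(bad, keys)

    def test_mult_noise_exceeds_fresh_noise(self, setup):
        params, keys, rng = setup
        a = bgv_encrypt(random_msg(params, rng), keys, rng)
        b = bgv_encrypt(random_msg(params, rng), keys, rng)
        prod = bgv_mult(a, b, keys)
        fresh = mod_switch(a, prod.level, params)
        assert bgv_noise(prod, keys) > bgv_noise(fresh, keys)


class TestHomomorphisms:
    def test_add_sub(self, setup):
        params, keys, rng = setup
        for _ in range(50):
            ma, mb = random_msg(params, rng), random_msg(params, rng)
            ca, cb = bgv_encrypt(ma, keys, rng), bgv_encrypt(mb, keys, rng)
            assert canon(bgv_decrypt(bgv_add(ca, cb, params), keys), params.t) \
                == canon(ma + mb, params.t)
            assert canon(bgv_decrypt(bgv_sub(ca, cb, params), keys), params.t) \
                == canon(ma - mb, params.t)

    def test_add_zero_is_identity(self, setup):
        params, keys, rng = setup
        m = random_msg(params, rng)
        ct = bgv_encrypt(m, keys, rng)
        z = bgv_encrypt(RingElement((0,) * params.n, params.t), keys, rng)
        assert canon(bgv_decrypt(bgv_add(ct, z, params), keys), params.t) \
            == canon(m, params.t)

    def test_slotwise_addition(self):
        params = bgv_toy_params(m=85, t=512, L=3)
        rng = np.random.default_rng(21)
        keys = bgv_keygen(params, rng)
        lay = params.layout
        u = [int(v) for v in rng.integers(0, 512, lay.ell)]
        v = [int(v) for v in rng.integers(0, 512, lay.ell)]
        ca = bgv_encrypt(crt_pack(u, lay), keys, rng)
        cb = bgv_encrypt(crt_pack(v, lay), keys, rng)
        out = crt_unpack(bgv_decrypt(bgv_add(ca, cb, params), keys), lay)
        assert out == [(a + b) % 512 for a, b in zip(u, v)]

    def test_mult(self, setup):
        params, keys, rng = setup
        for _ in range(20):
            ma, mb = random_msg(params, rng), random_msg(params, rng)
            ca, cb = bgv_encrypt(ma, keys, rng), bgv_encrypt(mb, keys, rng)
            want = ring_mul(ma.to_modulus(3 * params.t), mb.to_modulus(3 * params.t),
                            params.ring, q=3 * params.t)
            got = bgv_decrypt(bgv_mult(ca, cb, keys), keys)
            assert canon(got, params.t) == [c % params.t for c in want.coeffs]

    def test_mult_by_one(self, setup):
        params, keys, rng = setup
        m = random_msg(params, rng)
        one = RingElement((1,) + (0,) * (params.n - 1), params.t)
        prod = bgv_mult(bgv_encrypt(m, keys, rng),
                        bgv_encrypt(one, keys, rng), keys)
        assert canon(bgv_decrypt(prod, keys), params.t) == canon(m, params.t)

    def test_depth_budget(self):
        params = bgv_toy_params(m=85, t=2, L=4)
        rng = np.random.default_rng(4)
        keys = bgv_keygen(params, rng)
        one = RingElement((1,) + (0,) * (params.n - 1), params.t)
        ct = bgv_encrypt(one, keys, rng)
        for _ in range(params.L - 2):  # L-2 multiplications fit
            ct = bgv_mult(ct, ct, keys)
        assert canon(bgv_decrypt(ct, keys), params.t)[0] == 1
        with pytest.raises(DepthBudgetError):
            bgv_mult(ct, ct, keys)


class TestModSwitch:
    def test_plaintext_preserved(self, setup):
        params, keys, rng = setup
        for _ in range(50):
            m = random_msg(params, rng)
            ct = bgv_encrypt(m, keys, rng)
            sw = mod_switch(ct, 0, params)
            assert canon(bgv_decrypt(sw, keys), params.t) == canon(m, params.t)

    def test_noise_scaling(self, setup):
        params, keys, rng = setup
        ct = bgv_encrypt(random_msg(params, rng), keys, rng)
        old = bgv_noise(ct, keys)
        tgt = ct.level - 1
        new = bgv_noise(mod_switch(ct, tgt, params), keys)
        ratio = params.chain[tgt] / params.chain[ct.level]
        additive = params.t * (params.noise.h + 1)
        assert new <= 2 * (old * ratio + additive)

    def test_switch_to_own_level_is_identity(self, setup):
        params, keys, rng = setup
        ct = bgv_encrypt(random_msg(params, rng), keys, rng)
        assert mod_switch(ct, ct.level, params) is ct

    def test_invalid_target(self, setup):
        params, keys, rng = setup
        ct = bgv_encrypt(random_msg(params, rng), keys, rng)
        with pytest.raises(InvalidParameterError):
            mod_switch(ct, -1, params)


class TestSwitchKey:
    def _tensor(self, params, keys, rng):
        ma, mb = random_msg(params, rng), random_msg(params, rng)
        ca = mod_switch(bgv_encrypt(ma, keys, rng), params.L - 2, params)
        cb = mod_switch(bgv_encrypt(mb, keys, rng), params.L - 2, params)
        q = params.chain[params.L - 2]
        d0 = ring_mul(ca.c0, cb.c0, params.ring, q=q)
        d1 = ring_mul(ca.c0, cb.c1, params.ring, q=q) \
            + ring_mul(ca.c1, cb.c0, params.ring, q=q)
        d2 = ring_mul(ca.c1, cb.c1, params.ring, q=q)
        return (d0, d1, d2), q

    def test_three_component_decryption_preserved(self, setup):
        params, keys, rng = setup
        for _ in range(20):
            (d0, d1, d2), q = self._tensor(params, keys, rng)
            s = keys.sk.to_modulus(q)
            # oracle: decrypt the three-component ciphertext directly
            want = d0 - ring_mul(s, d1, params.ring, q=q) \
                + ring_mul(ring_mul(s, s, params.ring, q=q), d2,
                           params.ring, q=q)
            ct = switch_key((d0, d1, d2), params.L - 2, keys)
            got = bgv_decrypt(ct, keys)
            assert canon(got, params.t) == [c % params.t for c in want.coeffs]

    def test_zero_third_component(self, setup):
        params, keys, rng = setup
        m = random_msg(params, rng)
        ct = mod_switch(bgv_encrypt(m, keys, rng), params.L - 2, params)
        q = params.chain[params.L - 2]
        zero = RingElement((0,) * params.n, q)
        sw = switch_key((ct.c0, ct.c1, zero), params.L - 2, keys)
        assert canon(bgv_decrypt(sw, keys), params.t) == canon(m, params.t)

    def test_noise_increase_bounded(self, setup):
        params, keys, rng = setup
        m = random_msg(params, rng)
        ct = mod_switch(bgv_encrypt(m, keys, rng), params.L - 2, params)
        q = params.chain[params.L - 2]
        zero = RingElement((0,) * params.n, q)
        sw = switch_key((ct.c0, ct.c1, zero), params.L - 2, keys)
        ks_add = params.t * (params.noise.h + 1) * params.n
        assert bgv_noise(sw, keys) <= bgv_noise(ct, keys) + ks_add
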