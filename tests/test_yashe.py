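"""Scale-invariant scheme: key identities, word decomposition, homomorphisms."""

import numpy as np
import pytest

from hegenome.errors import DepthBudgetError, InvalidParameterError
from hegenome.ring import RingElement, centered, ring_mul
from hegenome.yashe import (
    YASHECiphertext,
    _poly_inverse_mod,
    powers_of,
    word_decompose,
    yashe_add,
    yashe_decrypt,
    yashe_encrypt,
    yashe_keygen,
    yashe_mult,
    yashe_noise,
    yashe_params_gen,
    yashe_sub,
)


@pytest.fixture(scope="module")
def setup():
    params = yashe_params_gen(lam=0, M=2, t=257, n=32, omega=1 << 12)
    rng = np.random.default_rng(8)
    keys = yashe_keygen(params, rng)
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
    def test_q_is_prime_in_the_right_class(self, setup):
        params, _, _ = setup
        from sympy import isprime

        assert isprime(params.q) and params.q % params.m == 1

    def test_m0_profile(self):
        p = yashe_params_gen(lam=0, M=0, t=1 << 10, n=64)
        assert p.q % (2 * p.n) == 1 and p.M == 0

    def test_published_scale_bound(self):
        # 2 M log2(n t) at M=6, n=8192, t=8191 asks for ~312 bits,
        # comfortably under the deployed 384-bit modulus
        from hegenome.paramsel import yashe_per_level_bits

        assert 6 * yashe_per_level_bits(8192, 8191) == pytest.approx(312, abs=1)

    def test_default_word(self):
        p = yashe_params_gen(lam=0, M=0, t=4, n=8)
        assert p.omega == 1 << 128

    def test_rejects_negative_depth(self):
        with pytest.raises(InvalidParameterError):
            yashe_params_gen(lam=0, M=-1, t=4, n=8)


class TestKeygen:
    def test_f_inverse(self, setup):
        params, _, _ = setup
        rng = np.random.default_rng(31)
        for _ in range(20):
            keys = yashe_keygen(params, rng, make_evk=False)
            finv = _poly_inverse_mod(keys.sk, params.ring)
            prod = ring_mul(keys.sk, finv, params.ring)
            assert prod.coeffs == (1,) + (0,) * (params.n - 1)

    def test_public_key_identity(self, setup):
        # [f h_pub]_q = t g with ternary g
        params, keys, _ = setup
        fg = ring_mul(keys.sk, keys.pk, params.ring)
        assert all(c % params.t == 0 for c in fg.coeffs)
        assert all(abs(c // params.t) <= 1 for c in fg.coeffs)

    def test_zero_roundtrip(self, setup):
        params, keys, rng = setup
        zero = RingElement((0,) * params.n, params.t)
        assert yashe_decrypt(yashe_encrypt(zero, keys, rng), keys).is_zero()


class TestWordDecompose:
    def test_reconstruction(self, setup):
        params, _, rng = setup
        from hegenome.ring import sample_uniform

        for _ in range(100):
            a = sample_uniform(params.n, params.q, rng)
            digits = word_decompose(a, params)
            acc = [0] * params.n
            w_pow = 1
            for d in digits:
                assert all(-params.omega / 2 < c <= params.omega / 2
                           for c in d.coeffs)
                for j, c in enumerate(d.coeffs):
                    acc[j] += c * w_pow
                w_pow *= params.omega
            assert [centered(c, params.q) for c in acc] == list(a.coeffs)

    def test_zero(self, setup):
        params, _, _ = setup
        zero = RingElement((0,) * params.n, params.q)
        assert all(d.is_zero() for d in word_decompose(zero, params))

    def test_inner_product_identity(self, setup):
        params, _, rng = setup
        from hegenome.ring import sample_uniform

        for _ in range(25):
            a = sample_uniform(params.n, params.q, rng)
            b = sample_uniform(params.n, params.q, rng)
            acc = RingElement((0,) * params.n, params.q)
            for d, p in zip(word_decompose(a, params), powers_of(b, params)):
                acc = acc + ring_mul(d, p, params.ring)
            assert acc.coeffs == ring_mul(a, b, params.ring).coeffs


class TestEncryptDecrypt:
    def test_roundtrip(self, setup):
        params, keys, rng = setup
        for _ in range(50):
            m = random_msg(params, rng)
            assert canon(yashe_decrypt(yashe_encrypt(m, keys, rng), keys),
                         params.t) == canon(m, params.t)

    def test_inherent_noise_small(self, setup):
        params, keys, rng = setup
        ct = yashe_encrypt(random_msg(params, rng), keys, rng)
        assert yashe_noise(ct, keys) < params.delta // 4

    def test_rounding_boundary(self, setup):
        # craft f ct = Delta [m]_t + v with ||v|| just below q/(2t)
        params, keys, rng = setup
        m = random_msg(params, rng)
        finv = _poly_inverse_mod(keys.sk, params.ring)
        v_mag = params.delta // 2 - params.t
        w = RingElement(
            tuple(centered(params.delta * centered(c, params.t) + v_mag,
                           params.q) for c in m.coeffs),
            params.q,
        )
        ct = YASHECiphertext(c=ring_mul(finv, w, params.ring), noise_est=0.0)
        assert canon(yashe_decrypt(ct, keys, check=False), params.t) \
            == canon(m, params.t)


class TestHomomorphisms:
    def test_add_sub(self, setup):
        params, keys, rng = setup
        for _ in range(50):
            ma, mb = random_msg(params, rng), random_msg(params, rng)
            ca = yashe_encrypt(ma, keys, rng)
            cb = yashe_encrypt(mb, keys, rng)
            assert canon(yashe_decrypt(yashe_add(ca, cb), keys), params.t) \
                == canon(ma + mb, params.t)
            assert canon(yashe_decrypt(yashe_sub(ca, cb), keys), params.t) \
                == canon(ma - mb, params.t)

    def test_mult(self, setup):
        params, keys, rng = setup
        for _ in range(20):
            ma, mb = random_msg(params, rng), random_msg(params, rng)
            ca = yashe_encrypt(ma, keys, rng)
            cb = yashe_encrypt(mb, keys, rng)
            big = 3 * params.t
            want = ring_mul(ma.to_modulus(big), mb.to_modulus(big),
                            params.ring, q=big)
            got = yashe_decrypt(yashe_mult(ca, cb, keys), keys)
            assert canon(got, params.t) == [c % params.t for c in want.coeffs]

    def test_mult_by_one(self, setup):
        params, keys, rng = setup
        m = random_msg(params, rng)
        one = RingElement((1,) + (0,) * (params.n - 1), params.t)
        prod = yashe_mult(yashe_encrypt(m, keys, rng),
                          yashe_encrypt(one, keys, rng), keys)
        assert canon(yashe_decrypt(prod, keys), params.t) == canon(m, params.t)

    def test_depth_m_squarings_then_budget_error(self):
        params = yashe_params_gen(lam=0, M=3, t=17, n=32, omega=1 << 12)
        rng = np.random.default_rng(2)
        keys = yashe_keygen(params, rng)
        two = RingElement((2,) + (0,) * (params.n - 1), params.t)
        ct = yashe_encrypt(two, keys, rng)
        want = 2
        for _ in range(params.M):
            ct = yashe_mult(ct, ct, keys)
            want = (want * want) % params.t
        assert canon(yashe_decrypt(ct, keys), params.t)[0] == want
        with pytest.raises(DepthBudgetError):
            yashe_mult(ct, ct, keys)

    def test_ciphertext_is_single_element(self, setup):
        params, keys, rng = setup
        ct = yashe_encrypt(random_msg(params, rng), keys, rng)
        assert len(ct.c.coeffs) == params.n
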