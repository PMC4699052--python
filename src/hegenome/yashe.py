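"""Scale-invariant SHE scheme (YASHE style) over ``Z_q[x]/(x^n + 1)``.

A single prime modulus ``q = 1 (mod m)`` (``m = 2n`` a power of two) is used
throughout.  The secret key is ``f = [t f' + 1]_q`` with ternary ``f'``; the
public key is ``h_pub = [t g f^{-1}]_q``.  A ciphertext is one ring element
``ct`` with *inherent noise* ``v`` defined through
``f ct = floor(q/t) [m]_t + v (mod q)``; decryption rounds ``t/q [f ct]_q``.

Multiplication scales the exact integer product by ``t/q`` (rounding half
away from zero) and then key-switches back to ``f`` using the base-``omega``
word decomposition ``P_{omega,q}`` against the evaluation key
``gamma_i = [omega^i f + e_i + h_pub s_i]_q``.

The paper's symbol ``h`` is overloaded (public key vs. secret Hamming
weight); here the public key is ``h_pub`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sympy import isprime

from . import paramsel
from .errors import (
    DecryptionFailure,
    DepthBudgetError,
    InvalidInputError,
    InvalidParameterError,
    KeyGenError,
    ParameterSearchError,
)
from .ring import (
    NoiseProfile,
    RingElement,
    RingParams,
    SlotLayout,
    centered,
    ring_mul,
    ring_mul_integer,
    sample_gaussian,
    sample_ternary_uniform,
    slot_layout,
)

__all__ = [
    "YASHEParams",
    "YASHEKeys",
    "YASHECiphertext",
    "yashe_params_gen",
    "yashe_keygen",
    "yashe_encrypt",
    "yashe_decrypt",
    "yashe_noise",
    "yashe_add",
    "yashe_sub",
    "yashe_neg",
    "yashe_add_plain",
    "yashe_mult",
    "word_decompose",
    "powers_of",
]

_KEYGEN_RETRY_CAP = 32


@dataclass(frozen=True)
class YASHEParams:
    n: int                       # power of two; m = 2n, Phi_m = x^n + 1
    q: int                       # prime, q = 1 (mod 2n)
    t: int
    omega: int = 1 << 128
    M: int = 0                   # supported multiplicative depth
    noise: NoiseProfile = NoiseProfile(sigma=8.0)
    m: int = field(init=False)
    ell_w: int = field(init=False)
    ring: RingParams = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 2 or self.n & (self.n - 1):
            raise InvalidParameterError("n must be a power of two >= 2")
        if not (1 < self.t < self.q):
            raise InvalidParameterError("need 1 < t < q")
        if self.omega < 2:
            raise InvalidParameterError("omega must be >= 2")
        object.__setattr__(self, "m", 2 * self.n)
        ell_w = 1
        acc = self.omega
        while acc <= self.q:
            acc *= self.omega
            ell_w += 1
        object.__setattr__(self, "ell_w", ell_w)  # floor(log_w q) + 1
        object.__setattr__(self, "ring", RingParams(m=self.m, q=self.q, t=self.t))

    @property
    def delta(self) -> int:
        return self.q // self.t

    @property
    def layout(self) -> SlotLayout:
        return slot_layout(self.m, self.t)


@dataclass(frozen=True)
class YASHEKeys:
    params: YASHEParams
    sk: RingElement                       # f = [t f' + 1]_q
    pk: RingElement                       # h_pub = [t g f^{-1}]_q
    evk: tuple[RingElement, ...] | None   # gamma, length ell_w (None if M = 0)


@dataclass(frozen=True)
class YASHECiphertext:
    c: RingElement
    noise_est: float
    depth: int = 0


# ---------------------------------------------------------------------------
# parameters


def yashe_params_gen(
    lam: int,
    M: int,
    t: int,
    n: int,
    omega: int = 1 << 128,
    noise: NoiseProfile | None = None,
    adds_budget: int = 1 << 10,
) -> YASHEParams:
    """Pick the smallest prime ``q = 1 (mod 2n)`` above the noise floor.

    The floor is the printed correctness bound for ``M`` multiplicative
    levels (see :func:`hegenome.paramsel.yashe_logq_bound`).  The companion
    maximal-``q`` security table is out of scope here, so the ring degree
    ``n`` is an explicit input chosen by the caller's profile.
    """
    if M < 0:
        raise InvalidParameterError("M must be >= 0")
    noise = noise or NoiseProfile(sigma=8.0)
    bound = paramsel.yashe_logq_bound(M, n, t, sigma=noise.sigma, omega=omega,
                                      adds=adds_budget)
    bits = int(np.ceil(bound))
    if bits > 4096:
        raise ParameterSearchError(f"required modulus of {bits} bits is absurd")
    m = 2 * n
    q = (1 << bits) + 1
    q += (m - (q - 1) % m) % m  # smallest candidate = 1 (mod 2n) above 2^bits
    while not isprime(q):
        q += m
    return YASHEParams(n=n, q=q, t=t, omega=omega, M=M, noise=noise)


# ---------------------------------------------------------------------------
# polynomial inverse over Z_q[x]/(x^n + 1)


def _poly_inverse_mod(a: RingElement, params: RingParams) -> RingElement | None:
    """Extended Euclid over the field Z_q (q prime); None if not invertible."""
    q = params.q
    f = [c % q for c in a.coeffs]
    g = [c % q for c in params.phim]

    def deg(p):
        d = len(p) - 1
        while d >= 0 and p[d] % q == 0:
            d -= 1
        return d

    r0, r1 = g, f + [0]
    s0, s1 = [0], [1]
    d1 = deg(r1)
    d0 = deg(r0)
    while d1 > 0:
        inv = pow(r1[d1], -1, q)
        while d0 >= d1:
            c = (r0[d0] * inv) % q
            shift = d0 - d1
            for k in range(d1 + 1):
                r0[shift + k] = (r0[shift + k] - c * r1[k]) % q
            ls = len(s1) + shift
            if len(s0) < ls:
                s0 = s0 + [0] * (ls - len(s0))
            for k in range(len(s1)):
                s0[shift + k] = (s0[shift + k] - c * s1[k]) % q
            d0 = deg(r0)
        r0, r1 = r1, r0
        s0, s1 = s1, s0
        d0, d1 = d1, deg(r1)
    if d1 < 0:
        return None  # gcd has positive degree
    inv = pow(r1[0], -1, q)
    out = [(c * inv) % q for c in s1]
    out += [0] * (params.n - len(out))
    return RingElement(tuple(centered(c, q) for c in out[: params.n]), q)


# ---------------------------------------------------------------------------
# scheme algorithms


def yashe_keygen(params: YASHEParams, rng: np.random.Generator,
                 make_evk: bool | None = None) -> YASHEKeys:
    """Sample ``f', g`` ternary; retry while ``f = t f' + 1`` is singular."""
    q = params.q
    f = finv = None
    for _ in range(_KEYGEN_RETRY_CAP):
        fp = sample_ternary_uniform(params.n, rng, q=q)
        cand = fp.scalar_mul(params.t)
        cand = RingElement(
            tuple(centered(c + (1 if i == 0 else 0), q)
                  for i, c in enumerate(cand.coeffs)),
            q,
        )
        finv = _poly_inverse_mod(cand, params.ring)
        if finv is not None:
            f = cand
            break
    if f is None:
        raise KeyGenError("f remained non-invertible after the retry cap")
    g = sample_ternary_uniform(params.n, rng, q=q)
    h_pub = ring_mul(g, finv, params.ring).scalar_mul(params.t)
    if make_evk is None:
        make_evk = params.M > 0
    evk = None
    if make_evk:
        gammas = []
        w_pow = 1
        for _ in range(params.ell_w):
            e_i = sample_gaussian(params.n, params.noise, rng, q=q)
            s_i = sample_gaussian(params.n, params.noise, rng, q=q)
            gam = f.scalar_mul(w_pow) + e_i + ring_mul(h_pub, s_i, params.ring)
            gammas.append(gam)
            w_pow *= params.omega
        evk = tuple(gammas)
    return YASHEKeys(params=params, sk=f, pk=h_pub, evk=evk)


def yashe_encrypt(msg: RingElement, keys: YASHEKeys,
                  rng: np.random.Generator) -> YASHECiphertext:
    """``ct = [floor(q/t) [m]_t + e + h_pub s]_q``."""
    params = keys.params
    if len(msg.coeffs) != params.n:
        raise InvalidInputError("message degree does not match the ring")
    q = params.q
    e = sample_gaussian(params.n, params.noise, rng, q=q)
    s = sample_gaussian(params.n, params.noise, rng, q=q)
    mt = RingElement(tuple(centered(c, params.t) for c in msg.coeffs), q)
    c = mt.scalar_mul(params.delta) + e + ring_mul(keys.pk, s, params.ring)
    return YASHECiphertext(c=c, noise_est=float(_fresh_noise_bound(params)))


def _fresh_noise_bound(params: YASHEParams) -> int:
    n, t, B = params.n, params.t, params.noise.B
    # v = -r_t(q) f' [m] + f e + t g s  with ternary f', g and errors <= B
    return n * t * (t // 2 + 2 * B + 2)


def _round_div(num: int, den: int) -> int:
    """Round ``num/den`` half away from zero (den > 0)."""
    if num >= 0:
        return (2 * num + den) // (2 * den)
    return -((-2 * num + den) // (2 * den))


def yashe_decrypt(ct: YASHECiphertext, keys: YASHEKeys, check: bool = True
                  ) -> RingElement:
    """``round(t/q [f ct]_q) mod t`` coefficientwise.

    With ``check`` the measured inherent noise is compared against a
    ``Delta/4`` guard band; beyond it a :class:`DecryptionFailure` is raised
    (past the true ``~q/2t`` bound a wrong message is indistinguishable from
    a quieter ciphertext, so the guard is deliberately conservative).
    """
    params = keys.params
    q, t = params.q, params.t
    w = ring_mul(keys.sk, ct.c, params.ring)
    msg = RingElement(
        tuple(centered(_round_div(t * c, q), t) for c in w.coeffs), t
    )
    if check:
        v = _inherent_noise(w, msg, params)
        if 4 * v >= params.delta:
            raise DecryptionFailure(
                f"inherent noise {v} beyond Delta/4 guard"
            )
    return msg


def _inherent_noise(w: RingElement, msg: RingElement, params: YASHEParams) -> int:
    delta = params.delta
    v = max(
        abs(centered(c - delta * m, params.q))
        for c, m in zip(w.coeffs, msg.coeffs)
    )
    return v


def yashe_noise(ct: YASHECiphertext, keys: YASHEKeys) -> int:
    """Measured inherent noise ``||v||_inf`` with
    ``f ct = floor(q/t) [m]_t + v (mod q)``."""
    params = keys.params
    w = ring_mul(keys.sk, ct.c, params.ring)
    msg = RingElement(
        tuple(centered(_round_div(params.t * c, params.q), params.t)
              for c in w.coeffs),
        params.t,
    )
    return _inherent_noise(w, msg, params)


def yashe_add(ct: YASHECiphertext, ct2: YASHECiphertext) -> YASHECiphertext:
    if ct.c.q != ct2.c.q:
        raise InvalidInputError("ciphertexts under different moduli")
    return YASHECiphertext(c=ct.c + ct2.c,
                           noise_est=ct.noise_est + ct2.noise_est,
                           depth=max(ct.depth, ct2.depth))


def yashe_sub(ct: YASHECiphertext, ct2: YASHECiphertext) -> YASHECiphertext:
    return yashe_add(ct, yashe_neg(ct2))


def yashe_neg(ct: YASHECiphertext) -> YASHECiphertext:
    return replace(ct, c=-ct.c)


def yashe_add_plain(ct: YASHECiphertext, msg: RingElement,
                    params: YASHEParams) -> YASHECiphertext:
    mt = RingElement(
        tuple(centered(c, params.t) for c in msg.coeffs), params.q
    )
    return replace(ct, c=ct.c + mt.scalar_mul(params.delta))


def word_decompose(a: RingElement, params: YASHEParams) -> list[RingElement]:
    """Balanced base-``omega`` digits: ``sum_i d_i omega^i = a (mod q)`` with
    every digit coefficient in ``(-omega/2, omega/2]``."""
    w = params.omega
    digits = [[0] * params.n for _ in range(params.ell_w)]
    for j, c in enumerate(a.coeffs):
        r = c
        i = 0
        while r != 0:
            if i >= params.ell_w:
                raise InvalidInputError("coefficient outside decomposition range")
            d = centered(r, w)
            digits[i][j] = d
            r = (r - d) // w
            i += 1
    return [RingElement(tuple(d), params.q) for d in digits]


def powers_of(a: RingElement, params: YASHEParams) -> list[RingElement]:
    """``P_{omega,q}(a) = ([a omega^i]_q)`` for ``i = 0 .. ell_w - 1``."""
    out = []
    w_pow = 1
    for _ in range(params.ell_w):
        out.append(a.scalar_mul(w_pow))
        w_pow *= params.omega
    return out


def yashe_mult(ct: YASHECiphertext, ct2: YASHECiphertext, keys: YASHEKeys
               ) -> YASHECiphertext:
    """Scale-invariant multiplication with word-decomposition key switching."""
    params = keys.params
    if keys.evk is None:
        raise InvalidInputError("multiplication requires an evaluation key")
    depth = max(ct.depth, ct2.depth) + 1
    if depth > params.M:
        raise DepthBudgetError(
            f"depth {depth} exceeds the configured M={params.M}"
        )
    q, t = params.q, params.t
    prod = ring_mul_integer(ct.c, ct2.c, params.ring)  # exact over Z
    scaled = RingElement(
        tuple(centered(_round_div(t * c, q), q) for c in prod), q
    )
    digits = word_decompose(scaled, params)
    acc = None
    for d, gam in zip(digits, keys.evk):
        term = ring_mul(d, gam, params.ring)
        acc = term if acc is None else acc + term
    est = ct.noise_est * ct2.noise_est * params.n * t / q \
        + params.n * t * (ct.noise_est + ct2.noise_est) \
        + params.n * params.ell_w * params.omega * params.noise.B
    return YASHECiphertext(c=acc, noise_est=est, depth=depth)
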