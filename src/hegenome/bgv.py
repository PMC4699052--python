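"""Leveled SHE scheme with modulus switching (BGV style).

The scheme lives in ``R_q = Z_q[x]/Phi_m(x)`` for an odd ``m`` with a chain of
moduli ``q_0 < q_1 < ... < q_{L-1}``, each ``q_i`` a product of roughly
equal-size primes ``p_0 ... p_i``.  A ciphertext at level ``l`` is a pair
``(c_0, c_1)`` over ``R_{q_l}`` decrypting to ``[c_0 - s c_1]_{q_l} mod t``;
the polynomial ``[c_0 - s c_1]_{q_l}`` is the ciphertext noise.

Key switching uses the modulus-raising gadget: the evaluation key is an
encryption of ``P s^2`` over ``R_{P q_{L-2}}``.  To guarantee that exact
rescaling preserves the plaintext, every chain prime and ``P`` is chosen
``= 1 (mod t)``; scaling a ciphertext from modulus ``Q`` down to ``Q/F``
subtracts the correction ``t [t^{-1} c]_F`` (which is ``= c mod F`` and
``= 0 mod t``) and divides exactly by ``F``.

Each multiplication consumes exactly one level (tensor, key switch, modulus
switch); additions are free apart from aligning the operands' levels.
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
    ParameterSearchError,
)
from .ring import (
    NoiseProfile,
    RingElement,
    RingParams,
    SlotLayout,
    centered,
    ring_mul,
    sample_gaussian,
    sample_ternary_sparse,
    sample_uniform,
    slot_count,
    slot_layout,
)

__all__ = [
    "BGVParams",
    "BGVKeys",
    "BGVCiphertext",
    "bgv_params_gen",
    "bgv_toy_params",
    "bgv_keygen",
    "bgv_encrypt",
    "bgv_decrypt",
    "bgv_noise",
    "bgv_add",
    "bgv_sub",
    "bgv_add_plain",
    "bgv_neg",
    "bgv_mult",
    "mod_switch",
    "switch_key",
]


@dataclass(frozen=True)
class BGVParams:
    m: int
    t: int
    L: int
    primes: tuple[int, ...]          # p_0 ... p_{L-1}, each = 1 (mod t)
    P: int                           # key-switching factor, prime = 1 (mod t)
    noise: NoiseProfile
    lam: int | None = None           # security level the set was generated for
    chain: tuple[int, ...] = field(init=False)   # q_0 < ... < q_{L-1}
    ring: RingParams = field(init=False)

    def __post_init__(self) -> None:
        if self.L < 2:
            raise InvalidParameterError("need at least two levels (L >= 2)")
        if len(self.primes) != self.L:
            raise InvalidParameterError("chain length must equal L")
        chain = []
        q = 1
        for p in self.primes:
            if p % self.t != 1:
                raise InvalidParameterError("chain primes must be = 1 (mod t)")
            q *= p
            chain.append(q)
        if not chain[0] > self.t:
            raise InvalidParameterError("q_0 must exceed t")
        if self.P % self.t != 1:
            raise InvalidParameterError("P must be = 1 (mod t)")
        object.__setattr__(self, "chain", tuple(chain))
        object.__setattr__(self, "ring", RingParams(m=self.m, q=chain[-1], t=self.t))

    @property
    def n(self) -> int:
        return self.ring.n

    @property
    def layout(self) -> SlotLayout:
        return slot_layout(self.m, self.t)

    def fresh_noise_bound(self) -> int:
        # || t (v e + e0 - s e1) || with ternary v, s of weight h, errors <= B
        B, h = self.noise.B, self.noise.h
        return self.t * B * (2 * h + 1)


@dataclass(frozen=True)
class BGVKeys:
    params: BGVParams
    sk: RingElement                       # ternary sparse s
    pk: tuple[RingElement, RingElement]   # (a, b) with b = [a s + t e]_{q_{L-1}}
    evk: tuple[RingElement, RingElement]  # (a_e, b_e) over R_{P q_{L-2}}


@dataclass(frozen=True)
class BGVCiphertext:
    c0: RingElement
    c1: RingElement
    level: int
    noise_est: float

    def __post_init__(self) -> None:
        if self.c0.q != self.c1.q:
            raise InvalidInputError("ciphertext components on different moduli")


# ---------------------------------------------------------------------------
# parameter generation


def _primes_in_class(t: int, bits: int, count: int, start_mult: int = 1) -> list[int]:
    """``count`` distinct primes ``= 1 (mod t)`` just above ``2^bits``."""
    found: list[int] = []
    c = start_mult * (1 << bits)
    c += t - (c - 1) % t  # smallest value = 1 (mod t) above 2^bits
    while len(found) < count:
        if isprime(c):
            found.append(c)
        c += t
    return found


def _next_prime_in_class(t: int, lower: int) -> int:
    c = lower + (t - (lower - 1) % t)
    while not isprime(c):
        c += t
    return c


def bgv_params_gen(
    lam: int,
    L: int,
    t: int,
    target_slots: int = 1,
    noise: NoiseProfile | None = None,
    prime_bits: int = 30,
    m_cap: int = 70000,
) -> BGVParams:
    """Search the smallest odd ``m`` meeting the security floor and slot count.

    ``phi(m)`` must reach the RLWE security lower bound (see
    :func:`hegenome.paramsel.bgv_security_min_phi`) and ``Phi_m`` mod ``t``
    must provide at least ``target_slots`` slots.  The modulus chain is built
    from ``L`` primes of ``prime_bits`` bits, all ``= 1 (mod t)``.
    """
    if L < 2:
        raise InvalidParameterError("L must be >= 2")
    noise = noise or NoiseProfile(sigma=3.2, h=64)
    from sympy.functions.combinatorial.numbers import totient

    m = 3
    chosen = None
    while m < m_cap:
        if m % 2 == 1 and m % (t if t % 2 else 2) != 0:
            phi = int(totient(m))
            if phi >= paramsel.bgv_security_min_phi(L, m, lam):
                try:
                    ell, _ = slot_count(m, t)
                except Exception:
                    ell = 0
                if ell >= target_slots:
                    chosen = m
                    break
        m += 2
    if chosen is None:
        raise ParameterSearchError(
            f"no odd m < {m_cap} satisfies the security and slot constraints"
        )
    primes = _primes_in_class(t, prime_bits, L)
    q_pen = 1
    for p in primes[:-1]:
        q_pen *= p
    n = int(totient(chosen))
    P = _next_prime_in_class(t, q_pen * n * noise.B * t * 16)
    return BGVParams(m=chosen, t=t, L=L, primes=tuple(primes), P=P,
                     noise=noise, lam=lam)


def bgv_toy_params(
    m: int,
    t: int,
    L: int,
    noise: NoiseProfile | None = None,
    prime_bits: int = 30,
) -> BGVParams:
    """Insecure test-scale parameters: the ring is taken as given and the
    RLWE security floor is deliberately not enforced.  Never use outside
    tests/demos."""
    noise = noise or NoiseProfile(sigma=3.2, h=min(64, max(2, m // 16)))
    primes = _primes_in_class(t, prime_bits, L)
    q_pen = 1
    for p in primes[:-1]:
        q_pen *= p
    params_probe = RingParams(m=m, q=q_pen * primes[-1], t=t)
    P = _next_prime_in_class(t, q_pen * params_probe.n * noise.B * t * 16)
    return BGVParams(m=m, t=t, L=L, primes=tuple(primes), P=P, noise=noise)


# ---------------------------------------------------------------------------
# keys and core operations


def bgv_keygen(params: BGVParams, rng: np.random.Generator) -> BGVKeys:
    q_top = params.chain[-1]
    Q = params.P * params.chain[-2]
    s = sample_ternary_sparse(params.n, params.noise.h, rng, q=q_top)
    a = sample_uniform(params.n, q_top, rng)
    e = sample_gaussian(params.n, params.noise, rng, q=q_top)
    b = ring_mul(a, s, params.ring) + e.scalar_mul(params.t)
    # evaluation key: encryption of P s^2 over R_{P q_{L-2}}
    sQ = s.to_modulus(Q)
    s2 = ring_mul(sQ, sQ, params.ring, q=Q)
    a_e = sample_uniform(params.n, Q, rng)
    e_e = sample_gaussian(params.n, params.noise, rng, q=Q)
    b_e = ring_mul(a_e, sQ, params.ring, q=Q) \
        + e_e.scalar_mul(params.t) + s2.scalar_mul(params.P)
    return BGVKeys(params=params, sk=s, pk=(a, b), evk=(a_e, b_e))


def bgv_encrypt(msg: RingElement, keys: BGVKeys,
                rng: np.random.Generator) -> BGVCiphertext:
    """Encrypt ``msg in R_t`` at the top level.

    ``(c_0, c_1) = (m, 0) + (b v + t e_0, a v + t e_1)``.
    """
    params = keys.params
    if len(msg.coeffs) != params.n:
        raise InvalidInputError("message degree does not match the ring")
    q = params.chain[-1]
    a, b = keys.pk
    v = sample_ternary_sparse(params.n, params.noise.h, rng, q=q)
    e0 = sample_gaussian(params.n, params.noise, rng, q=q)
    e1 = sample_gaussian(params.n, params.noise, rng, q=q)
    mq = msg.to_modulus(q)
    c0 = mq + ring_mul(b, v, params.ring) + e0.scalar_mul(params.t)
    c1 = ring_mul(a, v, params.ring) + e1.scalar_mul(params.t)
    return BGVCiphertext(c0=c0, c1=c1, level=params.L - 1,
                         noise_est=float(params.fresh_noise_bound()))


def _noise_poly(ct: BGVCiphertext, keys: BGVKeys) -> RingElement:
    params = keys.params
    q_l = params.chain[ct.level]
    s = keys.sk.to_modulus(q_l)
    return ct.c0 - ring_mul(s, ct.c1, params.ring, q=q_l)


def bgv_noise(ct: BGVCiphertext, keys: BGVKeys) -> int:
    """Infinity norm of the noise polynomial ``[c_0 - s c_1]_{q_l}``."""
    return _noise_poly(ct, keys).inf_norm


def bgv_decrypt(ct: BGVCiphertext, keys: BGVKeys, check: bool = True
                ) -> RingElement:
    """``[c_0 - s c_1]_{q_l} mod t`` with centered plaintext coefficients.

    With ``check`` the measured noise is compared against a ``q_l/4`` guard
    band (half the provable wrap bound); noise beyond it raises
    :class:`DecryptionFailure` instead of silently returning garbage.
    """
    params = keys.params
    q_l = params.chain[ct.level]
    w = _noise_poly(ct, keys)
    if check and 4 * w.inf_norm >= q_l:
        raise DecryptionFailure(
            f"noise {w.inf_norm} beyond q_l/4 guard at level {ct.level}"
        )
    return RingElement(tuple(centered(c, params.t) for c in w.coeffs), params.t)


def bgv_add(ct: BGVCiphertext, ct2: BGVCiphertext, params: BGVParams
            ) -> BGVCiphertext:
    ct, ct2 = _align(ct, ct2, params)
    return BGVCiphertext(c0=ct.c0 + ct2.c0, c1=ct.c1 + ct2.c1, level=ct.level,
                         noise_est=ct.noise_est + ct2.noise_est)


def bgv_sub(ct: BGVCiphertext, ct2: BGVCiphertext, params: BGVParams
            ) -> BGVCiphertext:
    ct, ct2 = _align(ct, ct2, params)
    return BGVCiphertext(c0=ct.c0 - ct2.c0, c1=ct.c1 - ct2.c1, level=ct.level,
                         noise_est=ct.noise_est + ct2.noise_est)


def bgv_neg(ct: BGVCiphertext) -> BGVCiphertext:
    return replace(ct, c0=-ct.c0, c1=-ct.c1)


def bgv_add_plain(ct: BGVCiphertext, msg: RingElement, params: BGVParams
                  ) -> BGVCiphertext:
    q_l = params.chain[ct.level]
    return replace(ct, c0=ct.c0 + msg.to_modulus(q_l),
                   noise_est=ct.noise_est + params.t * msg.inf_norm)


def _align(ct: BGVCiphertext, ct2: BGVCiphertext, params: BGVParams):
    if ct.level > ct2.level:
        ct = mod_switch(ct, ct2.level, params)
    elif ct2.level > ct.level:
        ct2 = mod_switch(ct2, ct.level, params)
    return ct, ct2


def _scale_down(coeffs, F: int, t: int, q_new: int) -> RingElement:
    """Divide by ``F`` exactly after the plaintext-preserving correction.

    Subtracts ``t [t^{-1} c]_F`` (``= c mod F``, ``= 0 mod t``), then divides;
    since ``F = 1 (mod t)`` the result is congruent to ``c`` modulo ``t``.
    """
    t_inv = pow(t, -1, F)
    out = []
    for c in coeffs:
        delta = t * centered((c * t_inv) % F, F)
        out.append(centered((c - delta) // F, q_new))
    return RingElement(tuple(out), q_new)


def mod_switch(ct: BGVCiphertext, target_level: int, params: BGVParams
               ) -> BGVCiphertext:
    """Rescale to the (smaller) modulus at ``target_level``; the noise scales
    by ``q_target/q_level`` up to an additive rounding term."""
    if target_level == ct.level:
        return ct
    if not 0 <= target_level < ct.level:
        raise InvalidParameterError("target level must be in [0, level)")
    q_old = params.chain[ct.level]
    q_new = params.chain[target_level]
    F = q_old // q_new
    floor = params.t * (params.noise.h + 1)  # additive rounding term bound
    return BGVCiphertext(
        c0=_scale_down(ct.c0.coeffs, F, params.t, q_new),
        c1=_scale_down(ct.c1.coeffs, F, params.t, q_new),
        level=target_level,
        noise_est=ct.noise_est * q_new / q_old + floor,
    )


def switch_key(ct3: tuple[RingElement, RingElement, RingElement], level: int,
               keys: BGVKeys) -> BGVCiphertext:
    """Reduce a three-component ciphertext (decryptable under ``(1, s, s^2)``)
    back to two components at the same level."""
    params = keys.params
    q_l = params.chain[level]
    Q = params.P * q_l
    d0, d1, d2 = ct3
    a_e = keys.evk[0].to_modulus(Q)
    b_e = keys.evk[1].to_modulus(Q)
    d2Q = d2.to_modulus(Q)
    u0 = d0.to_modulus(Q).scalar_mul(params.P) + ring_mul(d2Q, b_e, params.ring, q=Q)
    u1 = d1.to_modulus(Q).scalar_mul(params.P) + ring_mul(d2Q, a_e, params.ring, q=Q)
    c0 = _scale_down(u0.coeffs, params.P, params.t, q_l)
    c1 = _scale_down(u1.coeffs, params.P, params.t, q_l)
    ks_add = params.t * (params.noise.h + 1)  # rescaled evk-error term bound
    return BGVCiphertext(c0=c0, c1=c1, level=level, noise_est=ks_add)


def bgv_mult(ct: BGVCiphertext, ct2: BGVCiphertext, keys: BGVKeys
             ) -> BGVCiphertext:
    """Homomorphic multiplication: tensor, key switch, one modulus switch."""
    params = keys.params
    ct, ct2 = _align(ct, ct2, params)
    if ct.level == params.L - 1:
        # the evk lives over P q_{L-2}: fresh ciphertexts take the initial
        # modulus switch before their first multiplication
        ct = mod_switch(ct, params.L - 2, params)
        ct2 = mod_switch(ct2, params.L - 2, params)
    if ct.level < 1:
        raise DepthBudgetError(
            "already at the smallest modulus q_0; depth budget exhausted"
        )
    q_l = params.chain[ct.level]
    d0 = ring_mul(ct.c0, ct2.c0, params.ring, q=q_l)
    d1 = ring_mul(ct.c0, ct2.c1, params.ring, q=q_l) \
        + ring_mul(ct.c1, ct2.c0, params.ring, q=q_l)
    d2 = ring_mul(ct.c1, ct2.c1, params.ring, q=q_l)
    switched = switch_key((d0, d1, d2), ct.level, keys)
    prod_est = ct.noise_est * ct2.noise_est * params.n / q_l
    switched = replace(switched, noise_est=switched.noise_est + prod_est
                       + ct.noise_est + ct2.noise_est)
    return mod_switch(switched, ct.level - 1, params)
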