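"""Cyclotomic ring arithmetic, CRT slot structure, and shared random samplers.

Everything downstream works in ``R_q = Z_q[x] / Phi_m(x)`` with centered
coefficient representatives in ``(-q/2, q/2]``.  Two ring profiles are used:

* odd ``m`` (general cyclotomic ``Phi_m``) for the modulus-switching scheme,
* power-of-two ``m`` (``Phi_m = x^n + 1`` with ``n = m/2``) for the
  scale-invariant scheme, where reduction is a negacyclic fold.

Coefficients are arbitrary-precision Python ints.  Polynomial products go
through Kronecker substitution (pack coefficients into one big integer,
multiply, unpack), which turns ring multiplication into a single big-int
multiplication; a schoolbook oracle in the test-suite checks it.

Slot structure follows the Smart-Vercauteren observation that
``R_t ~ prod_i Z_t[x]/f_i(x)`` when ``Phi_m`` factors mod ``t`` into ``ell``
irreducible degree-``d`` factors.  For ``t = p^r`` the factors of ``Phi_m``
mod ``p`` are Hensel-lifted to mod ``p^r``.  Packing uses precomputed CRT
idempotents ``b_i`` (``b_i = 1 mod f_i``, ``0 mod f_j``), so integer-valued
slots cost one scalar multiplication per slot.

Slot order is the order in which sympy's distinct-degree factorization emits
the factors of ``Phi_m mod p``; it is deterministic and fixed, but otherwise
arbitrary.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from sympy import Poly, Symbol, cyclotomic_poly, factorint
from sympy import ZZ
from sympy.functions.combinatorial.numbers import totient
from sympy.ntheory.residue_ntheory import n_order
from sympy.polys.factortools import dup_zz_hensel_lift
from sympy.polys.galoistools import gf_factor_sqf, gf_gcdex

from .errors import (
    CapacityError,
    InvalidInputError,
    InvalidParameterError,
    NoBatchingError,
)

__all__ = [
    "NoiseProfile",
    "RingParams",
    "RingElement",
    "SlotLayout",
    "cyclotomic",
    "centered",
    "ring_mul",
    "slot_count",
    "slot_layout",
    "crt_pack",
    "crt_unpack",
    "slot_residues",
    "sample_ternary_sparse",
    "sample_ternary_uniform",
    "sample_gaussian",
    "sample_uniform",
]

_X = Symbol("x")


# ---------------------------------------------------------------------------
# parameters and element containers


@dataclass(frozen=True)
class NoiseProfile:
    """Gaussian error distribution plus secret-key sparsity.

    ``sigma`` is the standard deviation of the (truncated) discrete Gaussian,
    ``B`` the truncation bound (default ``6 sigma``) and ``h`` the Hamming
    weight used for sparse ternary secrets.
    """

    sigma: float = 3.2
    B: int | None = None
    h: int = 64

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidParameterError("sigma must be positive")
        if self.B is None:
            object.__setattr__(self, "B", int(round(6 * self.sigma)))
        if self.h < 0:
            raise InvalidParameterError("h must be non-negative")


@dataclass(frozen=True)
class RingParams:
    """The ring ``Z_q[x]/Phi_m(x)`` with plaintext modulus ``t``."""

    m: int
    q: int
    t: int
    n: int = field(init=False)
    phim: tuple[int, ...] = field(init=False)  # ascending coefficients, monic

    def __post_init__(self) -> None:
        if self.m < 2:
            raise InvalidParameterError("m must be >= 2")
        if not (1 < self.t < self.q):
            raise InvalidParameterError("need 1 < t < q")
        phim = cyclotomic(self.m)
        object.__setattr__(self, "phim", tuple(phim))
        object.__setattr__(self, "n", len(phim) - 1)

    @property
    def power_of_two(self) -> bool:
        return self.m & (self.m - 1) == 0


@dataclass(frozen=True)
class RingElement:
    """Length-``n`` coefficient vector (ascending degree), centered mod ``q``."""

    coeffs: tuple[int, ...]
    q: int

    def __add__(self, other: "RingElement") -> "RingElement":
        if self.q != other.q or len(self.coeffs) != len(other.coeffs):
            raise InvalidInputError("modulus/degree mismatch in ring addition")
        return RingElement(
            tuple(centered(a + b, self.q) for a, b in zip(self.coeffs, other.coeffs)),
            self.q,
        )

    def __sub__(self, other: "RingElement") -> "RingElement":
        return self + (-other)

    def __neg__(self) -> "RingElement":
        return RingElement(tuple(centered(-a, self.q) for a in self.coeffs), self.q)

    def scalar_mul(self, k: int) -> "RingElement":
        return RingElement(tuple(centered(k * a, self.q) for a in self.coeffs), self.q)

    def to_modulus(self, q_new: int) -> "RingElement":
        """Re-center the same integer vector modulo ``q_new``."""
        return RingElement(tuple(centered(a, q_new) for a in self.coeffs), q_new)

    @property
    def inf_norm(self) -> int:
        return max((abs(c) for c in self.coeffs), default=0)

    def is_zero(self) -> bool:
        return all(c == 0 for c in self.coeffs)


def zero_element(n: int, q: int) -> RingElement:
    return RingElement((0,) * n, q)


def element_from(coeffs, params: RingParams, q: int | None = None) -> RingElement:
    """Reduce an arbitrary integer coefficient sequence into the ring."""
    q = params.q if q is None else q
    red = _reduce_mod_phim(list(coeffs), params)
    red += [0] * (params.n - len(red))
    return RingElement(tuple(centered(c, q) for c in red), q)


# ---------------------------------------------------------------------------
# basic modular/polynomial helpers


def centered(a: int, q: int) -> int:
    """Reduce ``a`` modulo ``q`` into ``(-q/2, q/2]``."""
    r = a % q
    if 2 * r > q:
        r -= q
    return r


@functools.lru_cache(maxsize=None)
def cyclotomic(m: int) -> tuple[int, ...]:
    """Coefficients of ``Phi_m(x)``, ascending degree."""
    if m < 2:
        raise InvalidParameterError("m must be >= 2")
    if m & (m - 1) == 0:  # power of two: x^(m/2) + 1
        n = m // 2
        coeffs = [0] * (n + 1)
        coeffs[0] = 1
        coeffs[n] = 1
        return tuple(coeffs)
    poly = Poly(cyclotomic_poly(m, _X), _X)
    return tuple(int(c) for c in reversed(poly.all_coeffs()))


def poly_mul_int(a: list[int], b: list[int]) -> list[int]:
    """Exact product of two integer polynomials via Kronecker substitution."""
    if not a or not b:
        return []
    ap = [c if c > 0 else 0 for c in a]
    an = [-c if c < 0 else 0 for c in a]
    bp = [c if c > 0 else 0 for c in b]
    bn = [-c if c < 0 else 0 for c in b]
    pp = _kron_mul_nonneg(ap, bp)
    nn = _kron_mul_nonneg(an, bn)
    pn = _kron_mul_nonneg(ap, bn)
    np_ = _kron_mul_nonneg(an, bp)
    return [w + x - y - z for w, x, y, z in zip(pp, nn, pn, np_)]


def _kron_mul_nonneg(a: list[int], b: list[int]) -> list[int]:
    out_len = len(a) + len(b) - 1
    ma = max(a)
    mb = max(b)
    if ma == 0 or mb == 0:
        return [0] * out_len
    bound = min(len(a), len(b)) * ma * mb
    nb = (bound.bit_length() + 8) // 8  # digit width in bytes, no carries
    buf = bytearray(nb * len(a))
    for i, c in enumerate(a):
        buf[i * nb : i * nb + nb] = c.to_bytes(nb, "little")
    abig = int.from_bytes(bytes(buf), "little")
    buf = bytearray(nb * len(b))
    for i, c in enumerate(b):
        buf[i * nb : i * nb + nb] = c.to_bytes(nb, "little")
    bbig = int.from_bytes(bytes(buf), "little")
    prod = abig * bbig
    raw = prod.to_bytes(nb * out_len + nb, "little")
    return [
        int.from_bytes(raw[i * nb : (i + 1) * nb], "little") for i in range(out_len)
    ]


def _reduce_mod_phim(coeffs: list[int], params: RingParams) -> list[int]:
    """Reduce an integer polynomial modulo ``Phi_m`` (exact, over Z)."""
    n = params.n
    m = params.m
    if params.power_of_two:
        out = [0] * n
        for i, c in enumerate(coeffs):
            j = i % n
            if (i // n) % 2 == 0:
                out[j] += c
            else:
                out[j] -= c
        return out
    # fold modulo x^m - 1 first (Phi_m divides it), then divide by Phi_m
    folded = [0] * min(m, len(coeffs))
    for i, c in enumerate(coeffs):
        folded[i % m] += c
    while len(folded) > 1 and folded[-1] == 0:
        folded.pop()
    if len(folded) - 1 < n:
        return folded
    phim = params.phim
    # schoolbook division by the monic Phi_m
    rem = list(folded)
    for top in range(len(rem) - 1, n - 1, -1):
        c = rem[top]
        if c == 0:
            continue
        off = top - n
        for k in range(n + 1):
            rem[off + k] -= c * phim[k]
    del rem[n:]
    return rem


def ring_mul(a: RingElement, b: RingElement, params: RingParams,
             q: int | None = None) -> RingElement:
    """``a * b`` reduced modulo ``Phi_m`` and centered modulo ``q``."""
    q = a.q if q is None else q
    if a.q != b.q:
        raise InvalidInputError("modulus mismatch in ring_mul")
    if len(a.coeffs) != params.n or len(b.coeffs) != params.n:
        raise InvalidInputError("degree mismatch with ring parameters")
    prod = poly_mul_int(list(a.coeffs), list(b.coeffs))
    return element_from(prod, params, q=q)


def ring_mul_integer(a: RingElement, b: RingElement, params: RingParams) -> list[int]:
    """``a * b mod Phi_m`` over the integers (no coefficient reduction).

    Needed by the scale-invariant multiplication, which rounds ``t/q`` times
    the exact integer product of the centered representatives.
    """
    prod = poly_mul_int(list(a.coeffs), list(b.coeffs))
    red = _reduce_mod_phim(prod, params)
    red += [0] * (params.n - len(red))
    return red


# ---------------------------------------------------------------------------
# slot structure (polynomial CRT batching)


@dataclass(frozen=True)
class SlotLayout:
    """Factorization of ``Phi_m`` mod ``t`` with precomputed CRT idempotents."""

    m: int
    t: int
    d: int
    ell: int
    factors: tuple[tuple[int, ...], ...]      # monic, ascending coeffs in [0, t)
    idempotents: tuple[tuple[int, ...], ...]  # b_i = 1 mod f_i, 0 mod f_j

    @property
    def n(self) -> int:
        return len(self.factors[0]) * self.ell - self.ell  # ell * d


def _prime_power(t: int) -> tuple[int, int]:
    fac = factorint(t)
    if len(fac) != 1:
        raise NoBatchingError(
            f"t={t} is not a prime power; slot structure unsupported"
        )
    ((p, r),) = fac.items()
    return int(p), int(r)


def slot_count(m: int, t: int) -> tuple[int, int]:
    """``(ell, d)`` for the factorization of ``Phi_m`` mod ``t``.

    ``d`` is the multiplicative order of the prime base of ``t`` modulo ``m``
    and ``ell = phi(m)/d``.  Cheap even for large ``m`` (no factoring of the
    cyclotomic polynomial).
    """
    p, _ = _prime_power(t)
    if m % p == 0:
        raise NoBatchingError(
            f"Phi_{m} mod {p} is a repeated-factor power; no batching"
        )
    d = int(n_order(p, m))
    n = int(totient(m))
    return n // d, d


def _poly_mod_t(c: list[int], t: int) -> list[int]:
    out = [v % t for v in c]
    while len(out) > 1 and out[-1] == 0:
        out.pop()
    return out


def _poly_mul_mod_t(a: list[int], b: list[int], t: int) -> list[int]:
    return _poly_mod_t(poly_mul_int(a, b), t)


def _poly_divmod_mod_t(num: list[int], den: list[int], t: int):
    """Division by a monic polynomial over Z_t."""
    assert den[-1] % t == 1, "divisor must be monic"
    rem = [v % t for v in num]
    dn = len(den) - 1
    quo = [0] * max(1, len(rem) - dn)
    for top in range(len(rem) - 1, dn - 1, -1):
        c = rem[top] % t
        if c:
            quo[top - dn] = c
            for k in range(dn + 1):
                rem[top - dn + k] = (rem[top - dn + k] - c * den[k]) % t
    del rem[dn:]
    return quo, _poly_mod_t(rem, t)


def _invert_mod_factor(a: list[int], f: list[int], p: int, r: int, t: int) -> list[int]:
    """Inverse of ``a`` modulo (f, p^r) via GF(p) xgcd plus Newton lifting."""
    az = [ZZ(int(v % p)) for v in reversed(a)]
    while az and az[0] == 0:
        az.pop(0)  # gf_* routines require a stripped leading coefficient
    fz = [ZZ(int(v % p)) for v in reversed(f)]
    s, _, g = gf_gcdex(az, fz, p, ZZ)
    if len(g) != 1:
        raise NoBatchingError("CRT cofactor not invertible modulo a slot factor")
    ginv = pow(int(g[0]), -1, p)
    u = [(int(c) * ginv) % p for c in reversed(s)]  # ascending, inverse mod (f, p)
    prec = 1
    while prec < r:
        prec = min(2 * prec, r)
        mod = p ** prec
        au = _poly_mod_t(poly_mul_int(a, u), mod)
        _, au = _poly_divmod_mod_t(au, f, mod)
        corr = [(-v) % mod for v in au]
        corr[0] = (corr[0] + 2) % mod
        u = _poly_mod_t(poly_mul_int(u, corr), mod)
        _, u = _poly_divmod_mod_t(u, f, mod)
    return _poly_mod_t(u, t)


@functools.lru_cache(maxsize=32)
def slot_layout(m: int, t: int) -> SlotLayout:
    """Factor ``Phi_m`` mod ``t`` and precompute the CRT packing tables."""
    p, r = _prime_power(t)
    ell, d = slot_count(m, t)  # raises NoBatchingError on degenerate cases
    phim = [int(c) for c in cyclotomic(m)]
    fz = [ZZ(int(v % p)) for v in reversed(phim)]
    _, facs = gf_factor_sqf(fz, p, ZZ)
    if r > 1:
        lifted = dup_zz_hensel_lift(ZZ(p), [ZZ(c) for c in reversed(phim)],
                                    facs, r, ZZ)
        factors = [[int(c) % t for c in reversed(f)] for f in lifted]
    else:
        factors = [[int(c) % t for c in reversed(f)] for f in facs]
    if len(factors) != ell or any(len(f) - 1 != d for f in factors):
        raise NoBatchingError("factor count inconsistent with multiplicative order")
    idempotents = []
    for f in factors:
        cof, rem = _poly_divmod_mod_t(phim, f, t)
        assert rem == [0], "slot factor does not divide Phi_m mod t"
        _, cof_mod_f = _poly_divmod_mod_t(cof, f, t)
        inv = _invert_mod_factor(cof_mod_f, f, p, r, t)
        b = _poly_mul_mod_t(cof, inv, t)
        b += [0] * (len(phim) - 1 - len(b))
        idempotents.append(tuple(b))
    return SlotLayout(
        m=m, t=t, d=d, ell=ell,
        factors=tuple(tuple(f) for f in factors),
        idempotents=tuple(idempotents),
    )


def crt_pack(values, layout: SlotLayout) -> RingElement:
    """Pack per-slot integers (or small polys) into one element of ``R_t``.

    The result satisfies ``result = values[i] (mod f_i, t)``; missing trailing
    slots are zero.
    """
    if len(values) > layout.ell:
        raise CapacityError(
            f"{len(values)} values exceed the {layout.ell} available slots"
        )
    t = layout.t
    n = len(layout.idempotents[0])
    acc = [0] * n
    for v, b in zip(values, layout.idempotents):
        if isinstance(v, int):
            if v % t == 0:
                continue
            for j, bj in enumerate(b):
                acc[j] += v * bj
        else:
            vb = poly_mul_int(list(v), list(b))
            vb = _poly_mod_t(vb, t)
            # degree may reach deg(b) + deg(v) < n + d; fold via Phi_m division
            if len(vb) > n:
                phim = [int(c) for c in cyclotomic(layout.m)]
                _, vb = _poly_divmod_mod_t(vb, phim, t)
            for j, cj in enumerate(vb):
                acc[j] += cj
    return RingElement(tuple(centered(c, t) for c in acc), t)


def slot_residues(elem: RingElement, layout: SlotLayout) -> list[list[int]]:
    """Full residues ``elem mod (f_i, t)`` per slot (ascending coefficients)."""
    out = []
    for f in layout.factors:
        _, rem = _poly_divmod_mod_t(list(elem.coeffs), list(f), layout.t)
        rem += [0] * (len(f) - 1 - len(rem))
        out.append(rem)
    return out


def crt_unpack(elem: RingElement, layout: SlotLayout, count: int | None = None):
    """Constant slot values of ``elem`` in ``[0, t)``.

    Inverse of :func:`crt_pack` on integer-valued slots (the only kind the
    genomic pipelines use).
    """
    count = layout.ell if count is None else count
    res = slot_residues(elem, layout)[:count]
    return [r[0] % layout.t for r in res]


# ---------------------------------------------------------------------------
# samplers (all driven by a numpy Generator for reproducibility)


def sample_ternary_sparse(n: int, h: int, rng: np.random.Generator, q: int = 3
                          ) -> RingElement:
    """Ternary vector with exactly ``h`` nonzero entries of uniform sign."""
    if not 0 <= h <= n:
        raise InvalidParameterError("need 0 <= h <= n")
    coeffs = [0] * n
    idx = rng.choice(n, size=h, replace=False)
    signs = rng.integers(0, 2, size=h) * 2 - 1
    for i, s in zip(idx, signs):
        coeffs[int(i)] = int(s)
    return RingElement(tuple(coeffs), q)


def sample_ternary_uniform(n: int, rng: np.random.Generator, q: int = 3
                           ) -> RingElement:
    """Each coefficient uniform over ``{-1, 0, 1}``."""
    coeffs = rng.integers(-1, 2, size=n)
    return RingElement(tuple(int(c) for c in coeffs), q)


def sample_gaussian(n: int, profile: NoiseProfile, rng: np.random.Generator,
                    q: int | None = None) -> RingElement:
    """Truncated discrete Gaussian: rounded normal draws, resampled outside
    ``[-B, B]``."""
    sigma, B = profile.sigma, profile.B
    vals = np.rint(rng.normal(0.0, sigma, size=n)).astype(np.int64)
    bad = np.abs(vals) > B
    while bad.any():
        vals[bad] = np.rint(rng.normal(0.0, sigma, size=int(bad.sum()))).astype(
            np.int64
        )
        bad = np.abs(vals) > B
    qq = (2 * B + 1) if q is None else q
    return RingElement(tuple(int(v) for v in vals), qq)


def rand_int_below(rng: np.random.Generator, q: int) -> int:
    """Uniform integer in ``[0, q)`` from the generator's byte stream."""
    k = q.bit_length()
    nbytes = (k + 7) // 8
    mask = (1 << k) - 1
    while True:
        v = int.from_bytes(rng.bytes(nbytes), "little") & mask
        if v < q:
            return v


def sample_uniform(n: int, q: int, rng: np.random.Generator) -> RingElement:
    coeffs = tuple(centered(rand_int_below(rng, q), q) for _ in range(n))
    return RingElement(coeffs, q)
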