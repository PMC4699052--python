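"""Uniform evaluation contexts over which the genomic circuits are written.

A circuit is expressed once against the tiny add/sub/mul/add_const surface
below and can then run on plaintext slot vectors (:class:`PlainEngine`), on
slot-batched modulus-switching ciphertexts (:class:`BGVEngine`) or on
slot-batched scale-invariant ciphertexts (:class:`YASHESlotEngine`); this is
what makes the three-way equality tests (plaintext circuit vs homomorphic
circuit vs reference algorithm) cheap to state.

:class:`YASHECoeffEngine` is the addition-only coefficient-packing variant
used by the GWAS pipeline.
"""

from __future__ import annotations

import numpy as np

from . import bgv as _bgv
from . import yashe as _yashe
from .errors import InvalidInputError
from .ring import RingElement, centered, crt_pack, crt_unpack

__all__ = [
    "PlainEngine",
    "BGVEngine",
    "YASHESlotEngine",
    "YASHECoeffEngine",
]


class PlainEngine:
    """Slot vectors as plain tuples of residues mod ``t``."""

    def __init__(self, t: int, slots: int):
        self.t = t
        self.slots = slots

    def encrypt_slots(self, values):
        v = list(values) + [0] * (self.slots - len(values))
        return tuple(x % self.t for x in v)

    def decrypt_slots(self, val, count=None):
        return list(val[: count if count is not None else self.slots])

    def add(self, a, b):
        return tuple((x + y) % self.t for x, y in zip(a, b))

    def sub(self, a, b):
        return tuple((x - y) % self.t for x, y in zip(a, b))

    def mul(self, a, b):
        return tuple((x * y) % self.t for x, y in zip(a, b))

    def neg(self, a):
        return tuple((-x) % self.t for x in a)

    def add_const(self, a, c: int):
        return tuple((x + c) % self.t for x in a)


class BGVEngine:
    """Slot-batched evaluation under the modulus-switching scheme."""

    def __init__(self, params: _bgv.BGVParams, rng: np.random.Generator,
                 keys: _bgv.BGVKeys | None = None):
        self.params = params
        self.keys = keys if keys is not None else _bgv.bgv_keygen(params, rng)
        self.rng = rng
        self.layout = params.layout
        self.t = params.t
        self.slots = self.layout.ell

    def encrypt_slots(self, values):
        msg = crt_pack(list(values), self.layout)
        return _bgv.bgv_encrypt(msg, self.keys, self.rng)

    def decrypt_slots(self, ct, count=None):
        msg = _bgv.bgv_decrypt(ct, self.keys)
        return crt_unpack(msg, self.layout, count)

    def encrypt_coeffs(self, coeffs):
        msg = RingElement(
            tuple(centered(c, self.t) for c in list(coeffs)
                  + [0] * (self.params.n - len(coeffs))),
            self.t,
        )
        return _bgv.bgv_encrypt(msg, self.keys, self.rng)

    def decrypt_coeffs(self, ct, count=None):
        msg = _bgv.bgv_decrypt(ct, self.keys)
        out = [c % self.t for c in msg.coeffs]
        return out[: count if count is not None else len(out)]

    def add(self, a, b):
        return _bgv.bgv_add(a, b, self.params)

    def sub(self, a, b):
        return _bgv.bgv_sub(a, b, self.params)

    def mul(self, a, b):
        return _bgv.bgv_mult(a, b, self.keys)

    def neg(self, a):
        return _bgv.bgv_neg(a)

    def add_const(self, a, c: int):
        # the constant polynomial c sits in every slot (CRT of constants)
        msg = RingElement(
            (centered(c, self.t),) + (0,) * (self.params.n - 1), self.t
        )
        return _bgv.bgv_add_plain(a, msg, self.params)

    def noise(self, ct):
        return _bgv.bgv_noise(ct, self.keys)


class YASHESlotEngine:
    """Slot-batched evaluation under the scale-invariant scheme (prime t)."""

    def __init__(self, params: _yashe.YASHEParams, rng: np.random.Generator,
                 keys: _yashe.YASHEKeys | None = None):
        self.params = params
        self.keys = keys if keys is not None else _yashe.yashe_keygen(params, rng)
        self.rng = rng
        self.layout = params.layout
        self.t = params.t
        self.slots = self.layout.ell

    def encrypt_slots(self, values):
        msg = crt_pack(list(values), self.layout)
        padded = RingElement(
            msg.coeffs + (0,) * (self.params.n - len(msg.coeffs)), msg.q
        ) if len(msg.coeffs) < self.params.n else msg
        return _yashe.yashe_encrypt(padded, self.keys, self.rng)

    def decrypt_slots(self, ct, count=None):
        msg = _yashe.yashe_decrypt(ct, self.keys)
        return crt_unpack(msg, self.layout, count)

    def add(self, a, b):
        return _yashe.yashe_add(a, b)

    def sub(self, a, b):
        return _yashe.yashe_sub(a, b)

    def mul(self, a, b):
        return _yashe.yashe_mult(a, b, self.keys)

    def neg(self, a):
        return _yashe.yashe_neg(a)

    def add_const(self, a, c: int):
        msg = RingElement(
            (centered(c, self.t),) + (0,) * (self.params.n - 1), self.t
        )
        return _yashe.yashe_add_plain(a, msg, self.params)

    def noise(self, ct):
        return _yashe.yashe_noise(ct, self.keys)


class YASHECoeffEngine:
    """Coefficient packing: one value per polynomial coefficient.

    Addition-only (polynomial addition is componentwise); the GWAS pipeline
    needs nothing else, so no evaluation key is generated.
    """

    def __init__(self, params: _yashe.YASHEParams, rng: np.random.Generator,
                 keys: _yashe.YASHEKeys | None = None):
        self.params = params
        self.keys = keys if keys is not None else _yashe.yashe_keygen(
            params, rng, make_evk=params.M > 0)
        self.rng = rng
        self.t = params.t
        self.slots = params.n  # the maximal polynomial degree plays that role

    def encrypt_coeffs(self, coeffs):
        if len(coeffs) > self.params.n:
            raise InvalidInputError("more coefficients than the ring degree")
        msg = RingElement(
            tuple(centered(c, self.t) for c in list(coeffs)
                  + [0] * (self.params.n - len(coeffs))),
            self.t,
        )
        return _yashe.yashe_encrypt(msg, self.keys, self.rng)

    def decrypt_coeffs(self, ct, count=None):
        msg = _yashe.yashe_decrypt(ct, self.keys)
        out = [c % self.t for c in msg.coeffs]
        return out[: count if count is not None else len(out)]

    def add(self, a, b):
        return _yashe.yashe_add(a, b)

    def sub(self, a, b):
        return _yashe.yashe_sub(a, b)
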