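"""Equality, Hamming, comparison, max and approximate-edit-distance circuits.

Each circuit exists in two forms sharing one code path over an engine's
add/sub/mul/add_const surface:

* the *binary* form (plaintext modulus 2): XOR is addition, AND is
  multiplication;
* the *arithmetic* form (prime plaintext modulus, inputs in {0,1}): XOR is
  ``(x - y)^2`` and AND is the product, per the identities valid on bits.

Values are slot vectors, so one circuit evaluation processes one merged
site per slot.  Lengths ``D`` enter bit-sliced (one slot vector per bit,
LSB first); the per-bit outputs are recombined as ``sum_j l_{i,j} 2^(j-1)``
after decryption.

Per-site semantics (equal to the reference algorithms for every encodable
site):

* Hamming term ``h_i = ((E(s,s') AND (e XOR e' XOR 1)) XOR 1) AND f AND f'``
* edit term   ``l_i[j] = ((E(s,s') AND (f XOR f' XOR 1)) XOR 1) AND max{D,D'}[j]``

where ``E`` is 15-bit string equality and the comparison/max circuits are
the standard ripple constructions, all products arranged in balanced trees.
"""

from __future__ import annotations

import math

from .errors import InvalidInputError
from .genoenc import SNP_BITS, EncodedSite

__all__ = [
    "eq_bits_bin",
    "eq_bits_arith",
    "eq15_bin",
    "eq15_arith",
    "hamming_term_bin",
    "hamming_term_arith",
    "cmp_bin",
    "cmp_arith",
    "max_bin",
    "max_arith",
    "edit_term_bin",
    "edit_term_arith",
    "aggregate_hamming",
    "aggregate_edit",
    "circuit_depths",
    "encode_site_columns",
    "he_hamming",
    "he_edit",
    "hamming_distance",
    "edit_distance",
]


# ---------------------------------------------------------------------------
# primitive forms


def _product_tree(ctx, terms):
    while len(terms) > 1:
        nxt = [ctx.mul(a, b) for a, b in zip(terms[::2], terms[1::2])]
        if len(terms) % 2:
            nxt.append(terms[-1])
        terms = nxt
    return terms[0]


def _xor(ctx, a, b):
    return ctx.add(a, b)          # mod 2


def _xnot(ctx, a):
    return ctx.add_const(a, 1)    # mod 2


def _sq(ctx, a):
    return ctx.mul(a, a)


def _arith_xor(ctx, a, b):
    return _sq(ctx, ctx.sub(a, b))


def _one_minus(ctx, a):
    return ctx.add_const(ctx.neg(a), 1)


def eq_bits_bin(ctx, s, sp):
    """``AND_j (s[j] XOR s'[j] XOR 1)``: 1 iff the bit strings agree."""
    if len(s) != len(sp):
        raise InvalidInputError("length mismatch in equality circuit")
    terms = [_xnot(ctx, _xor(ctx, a, b)) for a, b in zip(s, sp)]
    return _product_tree(ctx, terms)


def eq_bits_arith(ctx, s, sp):
    """``prod_j (1 - (s[j] - s'[j])^2)``."""
    if len(s) != len(sp):
        raise InvalidInputError("length mismatch in equality circuit")
    terms = [_one_minus(ctx, _arith_xor(ctx, a, b)) for a, b in zip(s, sp)]
    return _product_tree(ctx, terms)


def eq15_bin(ctx, s, sp):
    if len(s) != SNP_BITS or len(sp) != SNP_BITS:
        raise InvalidInputError("SNP-string equality expects 15 bits")
    return eq_bits_bin(ctx, s, sp)


def eq15_arith(ctx, s, sp):
    if len(s) != SNP_BITS or len(sp) != SNP_BITS:
        raise InvalidInputError("SNP-string equality expects 15 bits")
    return eq_bits_arith(ctx, s, sp)


def hamming_term_bin(ctx, e, ep, f, fp, s, sp):
    """``((E AND (e XOR e' XOR 1)) XOR 1) AND f AND f'``."""
    E = eq_bits_bin(ctx, s, sp)
    same_presence = _xnot(ctx, _xor(ctx, e, ep))
    left = _xnot(ctx, ctx.mul(E, same_presence))
    return ctx.mul(left, ctx.mul(f, fp))


def hamming_term_arith(ctx, e, ep, f, fp, s, sp):
    """``(E ((e - e')^2 - 1) + 1) f f'``."""
    E = eq_bits_arith(ctx, s, sp)
    d2 = _arith_xor(ctx, e, ep)
    left = ctx.add_const(ctx.mul(E, ctx.add_const(d2, -1)), 1)
    return ctx.mul(left, ctx.mul(f, fp))


def cmp_bin(ctx, x, y):
    """``C(x, y) = 1`` iff ``x < y`` on LSB-first bit words.

    ``c_1 = (x[1] XOR 1) AND y[1]``;
    ``c_j = ((x[j] XOR 1) AND y[j]) XOR ((x[j] XOR 1 XOR y[j]) AND c_{j-1})``.
    """
    if len(x) != len(y):
        raise InvalidInputError("comparison needs equal widths")
    c = ctx.mul(_xnot(ctx, x[0]), y[0])
    for xj, yj in zip(x[1:], y[1:]):
        strictly = ctx.mul(_xnot(ctx, xj), yj)
        equal = _xnot(ctx, _xor(ctx, xj, yj))
        c = _xor(ctx, strictly, ctx.mul(equal, c))
    return c


def cmp_arith(ctx, x, y):
    """``c_1 = (1 - x[1]) y[1]``;
    ``c_j = (1 - x[j]) y[j] + (1 - (x[j] - y[j])^2) c_{j-1}``."""
    if len(x) != len(y):
        raise InvalidInputError("comparison needs equal widths")
    c = ctx.mul(_one_minus(ctx, x[0]), y[0])
    for xj, yj in zip(x[1:], y[1:]):
        strictly = ctx.mul(_one_minus(ctx, xj), yj)
        equal = _one_minus(ctx, _arith_xor(ctx, xj, yj))
        c = ctx.add(strictly, ctx.mul(equal, c))
    return c


def max_bin(ctx, x, y):
    """``max{x,y}[j] = x[j] XOR (C(x,y) AND (x[j] XOR y[j]))``; ties -> x."""
    C = cmp_bin(ctx, x, y)
    return [_xor(ctx, xj, ctx.mul(C, _xor(ctx, xj, yj)))
            for xj, yj in zip(x, y)]


def max_arith(ctx, x, y):
    """Bit-sliced ``x[j] + C(x,y) (y[j] - x[j])``."""
    C = cmp_arith(ctx, x, y)
    return [ctx.add(xj, ctx.mul(C, ctx.sub(yj, xj)))
            for xj, yj in zip(x, y)]


def edit_term_bin(ctx, f, fp, s, sp, dx, dy):
    """Per-bit ``((E AND (f XOR f' XOR 1)) XOR 1) AND max{D, D'}[j]``."""
    E = eq_bits_bin(ctx, s, sp)
    same_class = _xnot(ctx, _xor(ctx, f, fp))
    g = _xnot(ctx, ctx.mul(E, same_class))
    mx = max_bin(ctx, dx, dy)
    return [ctx.mul(g, mj) for mj in mx]


def edit_term_arith(ctx, f, fp, s, sp, dx, dy):
    """Per-bit ``(1 + E ((f - f')^2 - 1)) max{D, D'}[j]``."""
    E = eq_bits_arith(ctx, s, sp)
    d2 = _arith_xor(ctx, f, fp)
    g = ctx.add_const(ctx.mul(E, ctx.add_const(d2, -1)), 1)
    mx = max_arith(ctx, dx, dy)
    return [ctx.mul(g, mj) for mj in mx]


def aggregate_hamming(values) -> int:
    """Sum of per-site Hamming terms (decrypted slot values)."""
    return int(sum(values))


def aggregate_edit(bit_rows, mu: int) -> int:
    """``sum_i sum_j l_{i,j} 2^(j-1)`` over per-site LSB-first bit rows."""
    total = 0
    for row in bit_rows:
        if len(row) != mu:
            raise InvalidInputError("bit row width differs from mu")
        total += sum(int(b) << j for j, b in enumerate(row))
    return total


def circuit_depths(mu: int = 4) -> dict:
    """Static multiplicative-depth accounting for both circuit forms."""
    eq_bin = math.ceil(math.log2(SNP_BITS))
    eq_arith = eq_bin + 1                      # the squarings cost one level
    return {
        "eq15_bin": eq_bin,
        "eq15_arith": eq_arith,
        "hamming_bin": eq_bin + 2,
        "hamming_arith": eq_arith + 2,
        "cmp_bin": mu,
        "cmp_arith": mu,
        "edit_bin": max(eq_bin + 1, mu + 1) + 1,
        "edit_arith": max(eq_arith + 1, mu + 1) + 1,
    }


# ---------------------------------------------------------------------------
# homomorphic orchestration over encoded sites


def encode_site_columns(encoded: list[tuple[EncodedSite, EncodedSite]],
                        mu: int) -> dict:
    """Transpose per-site encodings into per-field value columns."""
    cols = {
        "e": ([], []), "f": ([], []),
        "s": ([[] for _ in range(SNP_BITS)], [[] for _ in range(SNP_BITS)]),
        "d": ([[] for _ in range(mu)], [[] for _ in range(mu)]),
    }
    for pair in encoded:
        for side, enc in enumerate(pair):
            cols["e"][side].append(enc.e)
            cols["f"][side].append(enc.f)
            for j, b in enumerate(enc.s):
                cols["s"][side][j].append(b)
            for j, b in enumerate(enc.d_bits(mu)):
                cols["d"][side][j].append(b)
    return cols


def _encrypt_blocks(cols, engine, lo, hi):
    """Encrypt one slot block [lo, hi) of every field column."""

    def enc(vec):
        return engine.encrypt_slots(vec[lo:hi])

    return {
        "e": (enc(cols["e"][0]), enc(cols["e"][1])),
        "f": (enc(cols["f"][0]), enc(cols["f"][1])),
        "s": ([enc(v) for v in cols["s"][0]], [enc(v) for v in cols["s"][1]]),
        "d": ([enc(v) for v in cols["d"][0]], [enc(v) for v in cols["d"][1]]),
    }


def he_hamming(encoded, engine, arith: bool | None = None):
    """Evaluate the Hamming term over encrypted slot blocks.

    Returns ``(list of ciphertexts, block width)``; decrypt and pass to
    :func:`aggregate_hamming`.
    """
    if arith is None:
        arith = engine.t != 2
    term = hamming_term_arith if arith else hamming_term_bin
    mu = max(
        [1] + [max(ex.D, ey.D).bit_length() for ex, ey in encoded]
    )  # lengths are unused by the Hamming term but the columns stay valid
    cols = encode_site_columns(encoded, mu)
    out = []
    n_sites = len(encoded)
    for lo in range(0, n_sites, engine.slots):
        hi = min(lo + engine.slots, n_sites)
        blk = _encrypt_blocks(cols, engine, lo, hi)
        out.append(term(engine, blk["e"][0], blk["e"][1],
                        blk["f"][0], blk["f"][1], blk["s"][0], blk["s"][1]))
    return out, engine.slots


def he_edit(encoded, mu: int, engine, arith: bool | None = None):
    """Evaluate the per-bit edit term over encrypted slot blocks.

    Returns ``(list of per-block lists of mu ciphertexts, block width)``.
    """
    if arith is None:
        arith = engine.t != 2
    term = edit_term_arith if arith else edit_term_bin
    cols = encode_site_columns(encoded, mu)
    out = []
    n_sites = len(encoded)
    for lo in range(0, n_sites, engine.slots):
        hi = min(lo + engine.slots, n_sites)
        blk = _encrypt_blocks(cols, engine, lo, hi)
        out.append(term(engine, blk["f"][0], blk["f"][1],
                        blk["s"][0], blk["s"][1], blk["d"][0], blk["d"][1]))
    return out, engine.slots


def hamming_distance(encoded, engine, arith: bool | None = None) -> int:
    """Encrypt, evaluate, decrypt and aggregate the Hamming distance."""
    cts, width = he_hamming(encoded, engine, arith)
    n_sites = len(encoded)
    values = []
    for i, ct in enumerate(cts):
        count = min(width, n_sites - i * width)
        values.extend(engine.decrypt_slots(ct, count))
    return aggregate_hamming(values)


def edit_distance(encoded, mu: int, engine, arith: bool | None = None) -> int:
    """Encrypt, evaluate, decrypt and aggregate the approximate edit
    distance."""
    blocks, width = he_edit(encoded, mu, engine, arith)
    n_sites = len(encoded)
    rows: list[list[int]] = []
    for i, bits_cts in enumerate(blocks):
        count = min(width, n_sites - i * width)
        per_bit = [engine.decrypt_slots(ct, count) for ct in bits_cts]
        for k in range(count):
            rows.append([per_bit[j][k] for j in range(mu)])
    return aggregate_edit(rows, mu)
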