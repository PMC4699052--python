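"""Boolean/arithmetic circuits: equality, comparison, max, distance terms."""

import pytest

from hegenome.engines import PlainEngine
from hegenome.errors import InvalidInputError
from hegenome.genoenc import encode_merged_list, merge_sites, VariantRecord
from hegenome.oracle import edit_ref, hamming_ref
from hegenome.seqcirc import (
    aggregate_edit,
    aggregate_hamming,
    circuit_depths,
    cmp_arith,
    cmp_bin,
    edit_distance,
    edit_term_arith,
    edit_term_bin,
    eq15_arith,
    eq15_bin,
    eq_bits_arith,
    eq_bits_bin,
    hamming_distance,
    hamming_term_arith,
    hamming_term_bin,
    max_arith,
    max_bin,
)
from hegenome.synth import VcfPairSpec, gen_vcf_pair


def bits_of(x, mu):
    return [(x >> j) & 1 for j in range(mu)]


def columns(pairs, mu):
    """All 256 pairs at once: one integer pair per slot."""
    xcols = [[(x >> j) & 1 for x, _ in pairs] for j in range(mu)]
    ycols = [[(y >> j) & 1 for _, y in pairs] for j in range(mu)]
    return xcols, ycols


ALL_PAIRS = [(x, y) for x in range(16) for y in range(16)]


@pytest.fixture()
def bin256():
    return PlainEngine(2, 256)


@pytest.fixture()
def arith256():
    return PlainEngine(127, 256)


class TestEquality:
    @pytest.mark.parametrize("arith", [False, True])
    def test_four_bit_exhaustive(self, bin256, arith256, arith):
        ctx = arith256 if arith else bin256
        fn = eq_bits_arith if arith else eq_bits_bin
        xc, yc = columns(ALL_PAIRS, 4)
        xs = [ctx.encrypt_slots(c) for c in xc]
        ys = [ctx.encrypt_slots(c) for c in yc]
        got = ctx.decrypt_slots(fn(ctx, xs, ys))
        assert got == [int(x == y) for x, y in ALL_PAIRS]

    def test_fifteen_bit_wrappers_enforce_length(self, bin256):
        s = [bin256.encrypt_slots([0])] * 14
        with pytest.raises(InvalidInputError):
            eq15_bin(bin256, s, s)
        with pytest.raises(InvalidInputError):
            eq15_arith(PlainEngine(127, 256), s, s)

    def test_equal_and_single_bit_flip(self, bin256):
        s = [bin256.encrypt_slots([b]) for b in bits_of(0b10110_01011_00101, 15)]
        assert bin256.decrypt_slots(eq15_bin(bin256, s, s), 1) == [1]
        flipped = list(s)
        flipped[7] = bin256.add_const(s[7], 1)
        assert bin256.decrypt_slots(eq15_bin(bin256, s, flipped), 1) == [0]


class TestComparison:
    @pytest.mark.parametrize("arith", [False, True])
    def test_exhaustive_mu4(self, bin256, arith256, arith):
        ctx = arith256 if arith else bin256
        fn = cmp_arith if arith else cmp_bin
        xc, yc = columns(ALL_PAIRS, 4)
        xs = [ctx.encrypt_slots(c) for c in xc]
        ys = [ctx.encrypt_slots(c) for c in yc]
        got = ctx.decrypt_slots(fn(ctx, xs, ys))
        assert got == [int(x < y) for x, y in ALL_PAIRS]

    def test_trichotomy(self, bin256):
        # C(x,y) + C(y,x) + [x = y] = 1 for every pair
        xc, yc = columns(ALL_PAIRS, 4)
        xs = [bin256.encrypt_slots(c) for c in xc]
        ys = [bin256.encrypt_slots(c) for c in yc]
        lt = bin256.decrypt_slots(cmp_bin(bin256, xs, ys))
        gt = bin256.decrypt_slots(cmp_bin(bin256, ys, xs))
        for (x, y), a, b in zip(ALL_PAIRS, lt, gt):
            assert a + b + int(x == y) == 1

    def test_width_mismatch(self, bin256):
        with pytest.raises(InvalidInputError):
            cmp_bin(bin256, [bin256.encrypt_slots([0])],
                    [bin256.encrypt_slots([0])] * 2)


class TestMax:
    @pytest.mark.parametrize("arith", [False, True])
    def test_exhaustive_mu4(self, bin256, arith256, arith):
        ctx = arith256 if arith else bin256
        fn = max_arith if arith else max_bin
        xc, yc = columns(ALL_PAIRS, 4)
        xs = [ctx.encrypt_slots(c) for c in xc]
        ys = [ctx.encrypt_slots(c) for c in yc]
        out_bits = [ctx.decrypt_slots(b) for b in fn(ctx, xs, ys)]
        for i, (x, y) in enumerate(ALL_PAIRS):
            got = sum(out_bits[j][i] << j for j in range(4))
            assert got == max(x, y)

    def test_tie_returns_first_operand(self, bin256):
        xs = [bin256.encrypt_slots([b]) for b in bits_of(11, 4)]
        out = [bin256.decrypt_slots(b, 1)[0] for b in max_bin(bin256, xs, xs)]
        assert sum(v << j for j, v in enumerate(out)) == 11


def site(x=None, y=None):
    return merge_sites([x] if x else [], [y] if y else [])


def vr(sv="SUB", ref="A", alt="G", pos=1):
    return VariantRecord(chrom="1", pos=pos, sv=sv, ref=ref, alt=alt)


def term_inputs(ctx, merged, mu):
    encoded, _ = encode_merged_list(merged, mu)
    (ex, ey) = encoded[0]
    e = (ctx.encrypt_slots([ex.e]), ctx.encrypt_slots([ey.e]))
    f = (ctx.encrypt_slots([ex.f]), ctx.encrypt_slots([ey.f]))
    s = ([ctx.encrypt_slots([b]) for b in ex.s],
         [ctx.encrypt_slots([b]) for b in ey.s])
    d = ([ctx.encrypt_slots([b]) for b in ex.d_bits(mu)],
         [ctx.encrypt_slots([b]) for b in ey.d_bits(mu)])
    return e, f, s, d


class TestDistanceTerms:
    CASES = [
        # (x, y, hamming term, edit term)
        (vr(alt="G"), vr(alt="G"), 0, 0),
        (vr(alt="G"), vr(alt="T"), 1, 1),
        (vr(sv="INS", ref="A", alt="AG"), vr(alt="T"), 0, 2),
        (vr(alt="G"), None, 1, 1),
        (vr(sv="DEL", ref="ACGT", alt="A"), None, 0, 4),
        (vr(sv="INS", alt="AG"), vr(sv="INS", alt="AGT"), 0, 3),
    ]

    @pytest.mark.parametrize("x, y, h_want, e_want", CASES)
    @pytest.mark.parametrize("arith", [False, True])
    def test_terms_match_reference_algorithms(self, x, y, h_want, e_want,
                                              arith):
        merged = site(x, y)
        assert hamming_ref(merged) == h_want
        assert edit_ref(merged) == e_want
        mu = 4
        ctx = PlainEngine(127, 4) if arith else PlainEngine(2, 4)
        e, f, s, d = term_inputs(ctx, merged, mu)
        h_fn = hamming_term_arith if arith else hamming_term_bin
        e_fn = edit_term_arith if arith else edit_term_bin
        h = ctx.decrypt_slots(h_fn(ctx, e[0], e[1], f[0], f[1], s[0], s[1]),
                              1)[0]
        bits = [ctx.decrypt_slots(b, 1)[0]
                for b in e_fn(ctx, f[0], f[1], s[0], s[1], d[0], d[1])]
        assert h == h_want
        assert sum(v << j for j, v in enumerate(bits)) == e_want


class TestAggregation:
    def test_zeros(self):
        assert aggregate_hamming([0, 0, 0]) == 0
        assert aggregate_edit([[0, 0], [0, 0]], 2) == 0

    def test_radix_example(self):
        assert aggregate_edit([[1, 0, 1]], 3) == 5

    def test_random_lists_match_reference(self):
        for seed in range(30):
            la, lb, truth = gen_vcf_pair(VcfPairSpec(n_sites=30, seed=seed))
            merged = merge_sites(la, lb)
            encoded, mu = encode_merged_list(merged)
            pe = PlainEngine(2, 16)
            assert hamming_distance(encoded, pe) == truth["hamming"]
            assert edit_distance(encoded, mu, pe) == truth["edit"]


class TestBinaryArithAgreement:
    def test_random_full_size_inputs(self):
        import numpy as np

        rng = np.random.default_rng(10)
        nb = PlainEngine(2, 500)
        na = PlainEngine(127, 500)
        sx = rng.integers(0, 2, (15, 500))
        sy = rng.integers(0, 2, (15, 500))
        exb = nb.decrypt_slots(eq_bits_bin(
            nb, [nb.encrypt_slots(r) for r in sx],
            [nb.encrypt_slots(r) for r in sy]))
        exa = na.decrypt_slots(eq_bits_arith(
            na, [na.encrypt_slots(r) for r in sx],
            [na.encrypt_slots(r) for r in sy]))
        assert exb == exa


class TestDepthAccounting:
    def test_published_budgets(self):
        d = circuit_depths(mu=4)
        assert d["eq15_bin"] == 4
        assert d["hamming_bin"] <= 6
        assert d["edit_bin"] <= 4 + 2 + 2  # eq + ceil(log2 mu) + 2

    def test_homomorphic_runs_fit_declared_depth(self, bgv_t2_engine,
                                                 yashe_t2_engine):
        # parameters were generated for the accounted depth: a full run
        # must neither exhaust levels nor trip the noise guard
        la, lb, truth = gen_vcf_pair(VcfPairSpec(n_sites=12, seed=4))
        merged = merge_sites(la, lb)
        encoded, mu = encode_merged_list(merged)
        assert hamming_distance(encoded, bgv_t2_engine) == truth["hamming"]
        assert edit_distance(encoded, mu, yashe_t2_engine) == truth["edit"]
        d = circuit_depths(mu)
        assert d["edit_bin"] + 2 <= bgv_t2_engine.params.L
        assert d["edit_arith"] <= yashe_t2_engine.params.M
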