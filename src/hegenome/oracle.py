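"""Plaintext reference implementations (ground truth).

Literal transcriptions of the two distance algorithms over merged variant
lists, plus the allelic contingency-table chi-square and the minor allele
frequency, all in exact integer/rational arithmetic.  The homomorphic
pipelines are tested against these; nothing here is optimized.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .errors import InvalidInputError, UndefinedStatisticError
from .genoenc import MergedSite, encode_genotype, genotype_length

__all__ = [
    "ContingencyTable",
    "hamming_ref",
    "edit_ref",
    "chi2_table_ref",
    "maf_ref",
    "allele_count",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Allelic 2x2 table: rows case/control, columns alleles A/B."""

    n_A: int
    n_B: int
    n_Ap: int
    n_Bp: int

    def __post_init__(self) -> None:
        if min(self.n_A, self.n_B, self.n_Ap, self.n_Bp) < 0:
            raise InvalidInputError("allele counts must be non-negative")
        if self.n_A + self.n_B != self.n_Ap + self.n_Bp:
            raise InvalidInputError("case and control margins differ")

    @property
    def R(self) -> int:
        return self.n_A + self.n_B

    @property
    def S(self) -> int:
        return self.n_Ap + self.n_Bp

    @property
    def G(self) -> int:
        return self.n_A + self.n_Ap

    @property
    def K(self) -> int:
        return self.n_B + self.n_Bp

    @property
    def T(self) -> int:
        return self.R + self.S


def _is_indel(rec) -> bool:
    return rec is not None and rec.sv in ("INS", "DEL")


def hamming_ref(sites: list[MergedSite]) -> int:
    """Hamming distance: per site, 0 if either record is an insertion or
    deletion; else 1 if one side is missing or the ALTs differ on a shared
    REF; else 0.

    The INS/DEL branch is tested first exactly as printed, so it wins even
    when the other side is missing (an absent side contributes no sv).
    """
    h = 0
    for site in sites:
        x, y = site.x, site.y
        if _is_indel(x) or _is_indel(y):
            h_i = 0
        elif (x is None or y is None) or (x.ref == y.ref and x.alt != y.alt):
            h_i = 1
        else:
            h_i = 0
        h += h_i
    return h


def edit_ref(sites: list[MergedSite]) -> int:
    """Approximate edit distance: per site, 0 for identical records, else
    the larger of the two genotype lengths ``D`` (deletion -> REF length,
    otherwise ALT length, missing -> 0)."""
    e = 0
    for site in sites:
        x, y = site.x, site.y
        dx = genotype_length(x)
        dy = genotype_length(y)
        identical = (
            x is not None and y is not None
            and x.ref == y.ref and x.alt == y.alt
        )
        e += 0 if identical else max(dx, dy)
    return e


def chi2_table_ref(table: ContingencyTable) -> Fraction:
    """``T (n_A n_B' - n_B n_A')^2 / (R S G K)``, exact."""
    if table.G == 0 or table.K == 0:
        raise UndefinedStatisticError("zero allele margin (monomorphic site)")
    num = table.T * (table.n_A * table.n_Bp - table.n_B * table.n_Ap) ** 2
    den = table.R * table.S * table.G * table.K
    return Fraction(num, den)


def allele_count(column: list[str]) -> int:
    """``n_A = 2 n_AA + n_AB`` from raw genotype calls."""
    return sum(encode_genotype(gt) for gt in column)


def maf_ref(column: list[str]) -> Fraction:
    """``min(n_A, n_B) / (n_A + n_B)`` from one site's genotype calls."""
    n = len(column)
    n_a = allele_count(column)
    n_b = 2 * n - n_a
    return Fraction(min(n_a, n_b), 2 * n)
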