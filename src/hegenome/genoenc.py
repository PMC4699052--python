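"""Genomic encodings feeding the homomorphic circuits.

Two families of inputs are covered:

* genotype tables (persons x SNV sites) with calls ``AA/AB/BB``, encoded as
  the integer allele counts ``AA -> 2, AB -> 1, BB -> 0``;
* pairs of VCF-subset variant lists, merged position-wise into a list ``L``
  and encoded per site as a presence flag ``e``, a not-INS/DEL flag ``f``, a
  15-bit ALT string code ``s`` and a length ``D`` (``mu``-bit).

The 15-bit code concatenates 2-bit base codes ``A->00 G->01 C->10 T->11``,
appends a ``1`` marker (so ``"A"`` and ``"AA"`` stay distinct from each
other and from an absent call), and zero-pads to 15 bits; an absent call is
the all-zero string.  Because both participants are called against the same
reference, the ALT string is what identifies a substitution or insertion;
a deletion is identified by its REF (the deleted span, anchored at the
shared reference base), and its code uses a ``01`` marker instead of ``1``
so that a deletion's string can never collide with a SUB/INS string — the
marker's final ``1`` lands on an even bit position instead of an odd one.
String equality of two codes is then exactly record identity for records of
the same circuit class, which is what the edit-distance circuit needs.  A
deletion's ``D`` is its REF length; everything else uses the ALT length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import CapacityError, EncodingError, InvalidInputError

__all__ = [
    "SV_TYPES",
    "GENOTYPE_CODES",
    "VariantRecord",
    "MergedSite",
    "EncodedSite",
    "encode_genotype",
    "merge_sites",
    "encode_flags",
    "encode_snp_bits",
    "encode_del_bits",
    "snp_bits_str",
    "genotype_length",
    "length_bits",
    "encode_site",
    "encode_merged_list",
]

logger = logging.getLogger(__name__)

SV_TYPES = ("SUB", "INS", "DEL")
GENOTYPE_CODES = {"AA": 2, "AB": 1, "BB": 0}
_BASE_CODE = {"A": (0, 0), "G": (0, 1), "C": (1, 0), "T": (1, 1)}
SNP_BITS = 15
MAX_ALT_LEN = 7   # 2*7 + marker = 15 bits
MAX_DEL_REF = 6   # 2*6 + two marker bits = 14 <= 15


@dataclass(frozen=True)
class VariantRecord:
    """One VCF-subset row: position, structural-variant class, REF and ALT."""

    chrom: str
    pos: int
    sv: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidInputError(f"positions are 1-based; got {self.pos}")
        if self.sv not in SV_TYPES:
            raise InvalidInputError(f"unknown SV type {self.sv!r}")
        for name, seq in (("ref", self.ref), ("alt", self.alt)):
            if not seq or any(b not in _BASE_CODE for b in seq):
                raise InvalidInputError(
                    f"{name} must be a non-empty string over A/C/G/T; got {seq!r}"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class MergedSite:
    """One position of the merged list; an absent side is ``None``."""

    key: tuple[str, int]
    x: VariantRecord | None
    y: VariantRecord | None

    def __post_init__(self) -> None:
        if self.x is None and self.y is None:
            raise InvalidInputError("a merged site needs at least one record")


@dataclass(frozen=True)
class EncodedSite:
    e: int                    # presence flag
    f: int                    # 0 iff sv in {INS, DEL}
    s: tuple[int, ...]        # 15-bit ALT code, printed order
    D: int                    # genotype length

    def d_bits(self, mu: int) -> tuple[int, ...]:
        """``D`` as ``mu`` bits, LSB first."""
        if self.D >= 1 << mu:
            raise CapacityError(f"length {self.D} does not fit in {mu} bits")
        return tuple((self.D >> j) & 1 for j in range(mu))


def encode_genotype(gt: str, missing_code: int | None = None) -> int:
    """``AA -> 2, AB -> 1, BB -> 0`` (symbols are class labels:
    homozygous-major / het / homozygous-minor)."""
    try:
        return GENOTYPE_CODES[gt.strip().upper()]
    except (KeyError, AttributeError):
        if missing_code is not None:
            return missing_code
        raise EncodingError(f"unknown genotype {gt!r}") from None


def _chrom_sort_key(chrom: str):
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def merge_sites(file_a: list[VariantRecord], file_b: list[VariantRecord]
                ) -> list[MergedSite]:
    """Union the two position lists into the merged list ``L``.

    One site per (chrom, pos); a position present on one side only gets an
    absent marker on the other.  Numeric chromosomes sort numerically, then
    others lexicographically; duplicates within one file are an error.
    """
    by_key: dict[tuple[str, int], list] = {}
    for side, records in enumerate((file_a, file_b)):
        for rec in records:
            slot = by_key.setdefault(rec.key, [None, None])
            if slot[side] is not None:
                raise InvalidInputError(
                    f"duplicate position {rec.key} within one file"
                )
            slot[side] = rec
    out = []
    for key in sorted(by_key, key=lambda k: (_chrom_sort_key(k[0]), k[1])):
        x, y = by_key[key]
        if (
            x is not None and y is not None
            and x.sv == "SUB" and y.sv == "SUB" and x.ref != y.ref
        ):
            # Same position, both substitutions, conflicting REF strings:
            # the distance algorithms fall through to 0 here, which is almost
            # certainly an upstream data problem.
            logger.warning("conflicting REF at %s: %r vs %r", key, x.ref, y.ref)
        out.append(MergedSite(key=key, x=x, y=y))
    return out


def encode_flags(site: MergedSite) -> tuple[int, int, int, int]:
    """``(e_x, f_x, e_y, f_y)``: presence and not-INS/DEL flags per side.

    An absent side gets ``e = 0, f = 1`` — keeping ``f = 1`` is what lets the
    ``f f'`` product in the Hamming circuit preserve the "one side missing
    counts as distance 1" branch.
    """

    def flags(rec: VariantRecord | None) -> tuple[int, int]:
        if rec is None:
            return 0, 1
        return 1, 0 if rec.sv in ("INS", "DEL") else 1

    e_x, f_x = flags(site.x)
    e_y, f_y = flags(site.y)
    return e_x, f_x, e_y, f_y


def encode_snp_bits(alt: str, present: int = 1) -> tuple[int, ...]:
    """15-bit ALT code: 2 bits per base, a ``1`` marker, zero padding;
    all-zero when the call is absent."""
    if not present:
        return (0,) * SNP_BITS
    if len(alt) > MAX_ALT_LEN:
        raise CapacityError(
            f"ALT of {len(alt)} bases exceeds the {MAX_ALT_LEN}-base cap"
        )
    bits: list[int] = []
    for base in alt:
        try:
            bits.extend(_BASE_CODE[base])
        except KeyError:
            raise EncodingError(f"non-ACGT base {base!r} in ALT") from None
    bits.append(1)
    bits.extend([0] * (SNP_BITS - len(bits)))
    return tuple(bits)


def encode_del_bits(ref: str, present: int = 1) -> tuple[int, ...]:
    """15-bit code of a deletion's REF span with the ``01`` class marker."""
    if not present:
        return (0,) * SNP_BITS
    if len(ref) > MAX_DEL_REF:
        raise CapacityError(
            f"deleted span of {len(ref)} bases exceeds the {MAX_DEL_REF}-base cap"
        )
    bits: list[int] = []
    for base in ref:
        try:
            bits.extend(_BASE_CODE[base])
        except KeyError:
            raise EncodingError(f"non-ACGT base {base!r} in REF") from None
    bits.extend([0, 1])
    bits.extend([0] * (SNP_BITS - len(bits)))
    return tuple(bits)


def snp_bits_str(bits: tuple[int, ...]) -> str:
    return "".join(str(b) for b in bits)


def genotype_length(rec: VariantRecord | None) -> int:
    """Algorithmic length ``D``: 0 when absent, ``len(ref)`` for a deletion,
    ``len(alt)`` otherwise."""
    if rec is None:
        return 0
    if rec.sv == "DEL":
        return len(rec.ref)
    return len(rec.alt)


def length_bits(sites: list[MergedSite], cap: int = 4) -> int:
    """Smallest bit width covering every ``D`` in the dataset (capped)."""
    mx = 0
    for site in sites:
        mx = max(mx, genotype_length(site.x), genotype_length(site.y))
    mu = max(1, mx.bit_length())
    if mu > cap:
        raise CapacityError(f"max length {mx} needs {mu} > {cap} bits")
    return mu


def _record_bits(rec: VariantRecord | None) -> tuple[int, ...]:
    if rec is None:
        return encode_snp_bits("", 0)
    if rec.sv == "DEL":
        return encode_del_bits(rec.ref)
    return encode_snp_bits(rec.alt)


def encode_site(site: MergedSite) -> tuple[EncodedSite, EncodedSite]:
    e_x, f_x, e_y, f_y = encode_flags(site)
    return (
        EncodedSite(e=e_x, f=f_x, s=_record_bits(site.x),
                    D=genotype_length(site.x)),
        EncodedSite(e=e_y, f=f_y, s=_record_bits(site.y),
                    D=genotype_length(site.y)),
    )


def encode_merged_list(sites: list[MergedSite], mu: int | None = None
                       ) -> tuple[list[tuple[EncodedSite, EncodedSite]], int]:
    """Encode every merged site; returns the encodings and the width ``mu``."""
    if mu is None:
        mu = length_bits(sites)
    encoded = [encode_site(s) for s in sites]
    for ex, ey in encoded:
        ex.d_bits(mu)
        ey.d_bits(mu)  # validates the width
    return encoded, mu
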