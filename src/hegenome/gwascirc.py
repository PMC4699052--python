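"""Encrypted GWAS statistics: minor allele frequency and allelic chi-square.

Homomorphic work is additions only.  Each person's genotype codes go into
plaintext slots (CRT batching, one SNV per slot) or into polynomial
coefficients (one SNV per coefficient, ``n' = floor(n/s)`` persons per
polynomial); aggregating the group's ciphertexts yields the per-SNV allele
counts ``m_j = sum_i g_i^(j)``.  From the per-group counts:

* ``MAF_j = min(m_j, 2N - m_j) / 2N``;
* with ``sum_j = n_A + n_A'`` and ``diff_j = n_A - n_A'`` over case/control,
  ``chi2_j = 4N diff_j^2 / (sum_j (4N - sum_j))`` — the allelic 2x2
  contingency statistic after both margins equal ``2N``.

Division and the minimum are taken after decryption; the only requirement
on the plaintext modulus is no wrap-around, validated before running
(``2N < t`` per group for counts, ``4N < t`` for the sums).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import (
    CapacityError,
    InvalidInputError,
    PipelineError,
    UndefinedStatisticError,
)
from .ring import RingElement, SlotLayout, crt_pack

__all__ = [
    "GenotypeMatrix",
    "CountVector",
    "ChiSqPair",
    "pack_slots",
    "pack_coeffs",
    "he_sum",
    "decode_counts_slots",
    "decode_counts_coeffs",
    "maf",
    "chi2_pair",
    "decode_signed",
    "chi2",
    "validate_t_bound",
    "run_task1_slots",
    "run_task1_coeffs",
    "Task1Result",
]


@dataclass(frozen=True)
class GenotypeMatrix:
    """``N`` persons x ``s`` SNVs of allele-count codes {0,1,2}."""

    label: str
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.ndim != 2:
            raise InvalidInputError("codes must be a 2-D array")
        if codes.size and not np.isin(codes, (0, 1, 2)).all():
            raise InvalidInputError("genotype codes must be 0, 1 or 2")
        object.__setattr__(self, "codes", codes)

    @property
    def N(self) -> int:
        return self.codes.shape[0]

    @property
    def s(self) -> int:
        return self.codes.shape[1]


@dataclass(frozen=True)
class CountVector:
    counts: tuple[int, ...]
    N: int

    def __post_init__(self) -> None:
        if any(not 0 <= c <= 2 * self.N for c in self.counts):
            raise InvalidInputError("allele counts must lie in [0, 2N]")


@dataclass(frozen=True)
class ChiSqPair:
    sums: tuple[int, ...]
    diffs: tuple[int, ...]
    N: int

    def __post_init__(self) -> None:
        for sm, df in zip(self.sums, self.diffs):
            if abs(df) > sm or sm > 4 * self.N or (sm - df) % 2:
                raise InvalidInputError("inconsistent sum/diff pair")


# ---------------------------------------------------------------------------
# packing and decoding


def pack_slots(person_codes, layout: SlotLayout) -> RingElement:
    """Slot ``j`` holds the person's code at SNV ``j``; the rest are zero."""
    codes = list(person_codes)
    if len(codes) > layout.ell:
        raise CapacityError(
            f"{len(codes)} SNVs exceed the {layout.ell} slots; partition first"
        )
    return crt_pack(codes, layout)


def pack_coeffs(group: GenotypeMatrix, n: int) -> list[list[int]]:
    """Coefficient layout: person ``i`` (within a block of ``n' = n // s``)
    occupies coefficients ``[i s, (i+1) s)``; ceil(N/n') polynomials."""
    s = group.s
    if s > n:
        raise CapacityError(f"{s} SNVs exceed the ring degree {n}")
    n_prime = n // s
    polys = []
    for start in range(0, group.N, n_prime):
        block = group.codes[start : start + n_prime]
        coeffs = [0] * (len(block) * s)
        for i, row in enumerate(block):
            coeffs[i * s : (i + 1) * s] = [int(v) for v in row]
        polys.append(coeffs)
    return polys


def he_sum(cts: list, engine):
    """Aggregate ciphertexts; slot/coefficient sums of the plaintexts."""
    if not cts:
        raise InvalidInputError("nothing to aggregate")
    acc = cts[0]
    for ct in cts[1:]:
        acc = engine.add(acc, ct)
    return acc


def decode_counts_slots(values: list[int], s: int, N: int) -> CountVector:
    """Slot variant: the decrypted slot values are the counts."""
    return CountVector(counts=tuple(values[:s]), N=N)


def decode_counts_coeffs(coeff_blocks: list[list[int]], s: int, t: int,
                         signed: bool = False):
    """Coefficient variant: ``m_j = sum_i m_{j + i s}`` over the ``n'``
    persons of each polynomial, summed across polynomials.

    With ``signed`` the aggregate is re-centered into ``(-t/2, t/2]``
    (needed for the case-minus-control differences).
    """
    totals = [0] * s
    for coeffs in coeff_blocks:
        n_prime = len(coeffs) // s
        for j in range(s):
            for i in range(n_prime):
                totals[j] += coeffs[j + i * s]
    reduced = [v % t for v in totals]
    if signed:
        return [decode_signed(v, t) for v in reduced]
    return reduced


def maf(m_j: int, N: int) -> Fraction:
    """``min(m_j, 2N - m_j) / 2N``."""
    if not 0 <= m_j <= 2 * N:
        raise InvalidInputError(f"count {m_j} outside [0, {2*N}]")
    return Fraction(min(m_j, 2 * N - m_j), 2 * N)


def chi2_pair(ct_case, ct_cont, engine):
    """``(ct+, ct-) = (case + control, case - control)`` on aggregates."""
    return engine.add(ct_case, ct_cont), engine.sub(ct_case, ct_cont)


def decode_signed(v: int, t: int) -> int:
    """Map ``[0, t)`` back to a signed value: subtract ``t`` above ``t/2``."""
    if not 0 <= v < t:
        raise InvalidInputError(f"value {v} outside [0, t)")
    return v - t if 2 * v > t else v


def chi2(sum_j: int, diff_j: int, N: int) -> Fraction:
    """``4N diff^2 / (sum (4N - sum))`` — the allelic chi-square."""
    if sum_j <= 0 or sum_j >= 4 * N:
        raise UndefinedStatisticError(
            f"monomorphic site: allele-count sum {sum_j} of {4*N}"
        )
    return Fraction(4 * N * diff_j**2, sum_j * (4 * N - sum_j))


def validate_t_bound(t: int, N_case: int, N_cont: int, task: str) -> None:
    """Reject configurations whose counts could wrap modulo ``t``."""
    need = max(2 * N_case, 2 * N_cont) if task == "maf" \
        else 2 * (N_case + N_cont)
    if need >= t:
        raise PipelineError(
            f"plaintext modulus t={t} cannot hold counts up to {need}"
        )


# ---------------------------------------------------------------------------
# end-to-end pipelines


@dataclass(frozen=True)
class Task1Result:
    n_case: tuple[int, ...]
    n_cont: tuple[int, ...]
    maf_case: tuple[Fraction, ...]
    maf_cont: tuple[Fraction, ...]
    chi2: tuple[object, ...]  # Fraction, or None at a monomorphic site


def _chi2_rows(n_case, n_cont, N_case):
    out = []
    for a, b in zip(n_case, n_cont):
        try:
            out.append(chi2(a + b, a - b, N_case))
        except UndefinedStatisticError:
            out.append(None)
    return out


def _block_ranges(s: int, width: int):
    for lo in range(0, s, width):
        yield lo, min(lo + width, s)


def run_task1_slots(case: GenotypeMatrix, cont: GenotypeMatrix, engine,
                    align_level: bool = True) -> Task1Result:
    """Slot-packing pipeline (one SNV per slot, one ciphertext per person).

    SNV blocks wider than the slot count are partitioned and processed
    identically.  With ``align_level`` every fresh ciphertext is switched
    down one level before aggregation, so the modulus chain only needs
    ``L = 3`` moduli.
    """
    if case.s != cont.s:
        raise InvalidInputError("case and control must share the SNV panel")
    validate_t_bound(engine.t, case.N, cont.N, "chi2")
    from . import bgv as _bgv

    n_case: list[int] = []
    n_cont: list[int] = []
    for lo, hi in _block_ranges(case.s, engine.slots):
        aggregates = []
        for group in (case, cont):
            cts = [engine.encrypt_slots([int(v) for v in row[lo:hi]])
                   for row in group.codes]
            if align_level and hasattr(cts[0], "level") and cts[0].level > 1:
                cts = [_bgv.mod_switch(ct, cts[0].level - 1, engine.params)
                       for ct in cts]
            aggregates.append(he_sum(cts, engine))
        ct_plus, ct_minus = chi2_pair(aggregates[0], aggregates[1], engine)
        sums = engine.decrypt_slots(ct_plus, hi - lo)
        diffs = [decode_signed(v, engine.t)
                 for v in engine.decrypt_slots(ct_minus, hi - lo)]
        for sm, df in zip(sums, diffs):
            n_case.append((sm + df) // 2)
            n_cont.append((sm - df) // 2)
    return _finish(n_case, n_cont, case.N, cont.N)


def run_task1_coeffs(case: GenotypeMatrix, cont: GenotypeMatrix, engine
                     ) -> Task1Result:
    """Coefficient-packing pipeline (``n'`` persons per polynomial)."""
    if case.s != cont.s:
        raise InvalidInputError("case and control must share the SNV panel")
    validate_t_bound(engine.t, case.N, cont.N, "chi2")
    s = case.s
    agg = []
    for group in (case, cont):
        cts = [engine.encrypt_coeffs(c)
               for c in pack_coeffs(group, engine.params.n)]
        agg.append(he_sum(cts, engine))
    ct_plus, ct_minus = chi2_pair(agg[0], agg[1], engine)
    n_prime = engine.params.n // s
    used = n_prime * s
    plus = engine.decrypt_coeffs(ct_plus, used)
    minus = engine.decrypt_coeffs(ct_minus, used)
    sums = decode_counts_coeffs([plus], s, engine.t)
    diffs = decode_counts_coeffs([minus], s, engine.t, signed=True)
    n_case = [(sm + df) // 2 for sm, df in zip(sums, diffs)]
    n_cont = [(sm - df) // 2 for sm, df in zip(sums, diffs)]
    return _finish(n_case, n_cont, case.N, cont.N)


def _finish(n_case, n_cont, N_case, N_cont) -> Task1Result:
    return Task1Result(
        n_case=tuple(n_case),
        n_cont=tuple(n_cont),
        maf_case=tuple(maf(v, N_case) for v in n_case),
        maf_cont=tuple(maf(v, N_cont) for v in n_cont),
        chi2=tuple(_chi2_rows(n_case, n_cont, N_case)),
    )
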