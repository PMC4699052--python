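"""Seeded synthetic datasets shaped like the two evaluation tasks.

Case/control genotype tables: each SNV ``j`` has an allele-A frequency
``p_j``; genotype codes are ``Binomial(2, p_j)`` draws per person
(Hardy-Weinberg, no linkage or population structure).  One SNV may carry a
case-group frequency shift ``delta`` to plant an association.  Defaults
mirror the evaluation scale: 200 persons per group over 311 SNV sites.

VCF-subset pairs: a merged panel of positions on one chromosome; each
position is shared by both participants with probability ``p_shared``, and
a shared position carries byte-identical records with probability
``p_identical`` (two genomes agree on most of their variants).  Every
position has a fixed reference base, so two substitution records at the
same position always share their REF — the regime where the encoded
circuits and the reference algorithms provably agree.  Ground truth
(counts, MAFs, chi-square, distances) is attached from the plaintext
oracle so generated data is self-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .genoenc import VariantRecord, merge_sites
from .gwascirc import GenotypeMatrix, chi2, maf
from .oracle import edit_ref, hamming_ref

__all__ = ["GwasSpec", "VcfPairSpec", "gen_case_control", "gen_vcf_pair"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GwasSpec:
    N_case: int = 200
    N_control: int = 200
    s: int = 311
    maf_low: float = 0.05
    maf_high: float = 0.5
    assoc_index: int | None = None
    delta: float = 0.0
    seed: int = 0
    maf_vector: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.N_case, self.N_control, self.s) < 1:
            raise InvalidParameterError("group sizes and s must be positive")
        if self.assoc_index is not None and not 0 <= self.assoc_index < self.s:
            raise InvalidParameterError("assoc_index outside [0, s)")
        if self.maf_vector is not None and len(self.maf_vector) != self.s:
            raise InvalidParameterError("maf_vector length must equal s")


@dataclass(frozen=True)
class VcfPairSpec:
    n_sites: int = 50
    p_shared: float = 0.5
    p_identical: float = 0.5
    sv_probs: tuple[float, float, float] = (0.6, 0.2, 0.2)  # SUB, INS, DEL
    max_alt_len: int = 7
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise InvalidParameterError("n_sites must be positive")
        if abs(sum(self.sv_probs) - 1.0) > 1e-9:
            raise InvalidParameterError("sv_probs must sum to 1")
        if not 1 <= self.max_alt_len <= 7:
            raise InvalidParameterError("max_alt_len must be in [1, 7]")
        if self.max_alt_len < 2 and (self.sv_probs[1] or self.sv_probs[2]):
            raise InvalidParameterError(
                "insertions/deletions need max_alt_len >= 2"
            )


def gen_case_control(spec: GwasSpec):
    """Two genotype matrices plus exact ground truth.

    The truth dict carries the per-SNV allele counts, group MAFs and the
    allelic chi-square computed directly from the generated codes (not via
    the encrypted pipeline).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.maf_vector is not None:
        p = np.asarray(spec.maf_vector, dtype=float)
    else:
        p = rng.uniform(spec.maf_low, spec.maf_high, size=spec.s)
    p_case = p.copy()
    if spec.assoc_index is not None:
        p_case[spec.assoc_index] += spec.delta
        if not 0 < p_case[spec.assoc_index] < 1:
            raise InvalidParameterError("shifted frequency outside (0, 1)")
    case = GenotypeMatrix(
        "case", rng.binomial(2, p_case, size=(spec.N_case, spec.s))
    )
    cont = GenotypeMatrix(
        "control", rng.binomial(2, p, size=(spec.N_control, spec.s))
    )
    n_a = case.codes.sum(axis=0)
    n_ap = cont.codes.sum(axis=0)
    chi = []
    for a, b in zip(n_a, n_ap):
        try:
            chi.append(chi2(int(a + b), int(a - b), spec.N_case))
        except Exception:
            chi.append(None)
    truth = {
        "p": p.tolist(),
        "n_case": [int(v) for v in n_a],
        "n_control": [int(v) for v in n_ap],
        "maf_case": [maf(int(v), spec.N_case) for v in n_a],
        "maf_control": [maf(int(v), spec.N_control) for v in n_ap],
        "chi2": chi,
    }
    return case, cont, truth


def _random_record(chrom: str, pos: int, ref_base: str, sv: str,
                   max_alt_len: int, rng) -> VariantRecord:
    if sv == "SUB":
        alt = str(rng.choice(_BASES[_BASES != ref_base]))
        return VariantRecord(chrom, pos, "SUB", ref_base, alt)
    if sv == "INS":
        extra = rng.integers(1, max(2, max_alt_len))
        ins = "".join(rng.choice(_BASES, size=int(extra)))
        return VariantRecord(chrom, pos, "INS", ref_base, ref_base + ins)
    span = int(rng.integers(2, min(max_alt_len, 6) + 1))
    tail = "".join(rng.choice(_BASES, size=span - 1))
    return VariantRecord(chrom, pos, "DEL", ref_base + tail, ref_base)


def gen_vcf_pair(spec: VcfPairSpec):
    """Two variant lists with partially overlapping positions plus truth.

    Truth: the merged-list length, the overlap count, and the two distances
    from the reference algorithms.
    """
    rng = np.random.default_rng(spec.seed)
    positions = np.sort(
        rng.choice(np.arange(1, max(10 * spec.n_sites, 100)),
                   size=spec.n_sites, replace=False)
    )
    svs = ("SUB", "INS", "DEL")
    list_a: list[VariantRecord] = []
    list_b: list[VariantRecord] = []
    overlap = 0
    for pos in positions:
        pos = int(pos)
        ref_base = str(rng.choice(_BASES))
        shared = rng.random() < spec.p_shared
        if shared:
            overlap += 1
            sv_a = str(rng.choice(svs, p=spec.sv_probs))
            rec_a = _random_record(spec.chrom, pos, ref_base, sv_a,
                                   spec.max_alt_len, rng)
            if rng.random() < spec.p_identical:
                rec_b = rec_a
            else:
                sv_b = str(rng.choice(svs, p=spec.sv_probs))
                rec_b = _random_record(spec.chrom, pos, ref_base, sv_b,
                                       spec.max_alt_len, rng)
            list_a.append(rec_a)
            list_b.append(rec_b)
        else:
            sv = str(rng.choice(svs, p=spec.sv_probs))
            rec = _random_record(spec.chrom, pos, ref_base, sv,
                                 spec.max_alt_len, rng)
            if rng.random() < 0.5:
                list_a.append(rec)
            else:
                list_b.append(rec)
    merged = merge_sites(list_a, list_b)
    truth = {
        "merged_length": len(merged),
        "overlap": overlap,
        "hamming": hamming_ref(merged),
        "edit": edit_ref(merged),
    }
    return list_a, list_b, truth
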