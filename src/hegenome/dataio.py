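"""File formats: VCF subset, genotype CSV, results TSV, binary containers.

The VCF subset keeps the eight fixed columns with an ``SVTYPE`` INFO key in
{SUB, INS, DEL}; reading goes through :mod:`pysam` (an absent SVTYPE is
inferred from the REF/ALT length relation), writing through a small
deterministic emitter that declares the header. Genotype tables are CSV,
persons as rows and SNV sites as columns, values AA/AB/BB.

Keys and ciphertexts are serialized into a checksummed binary container: a
JSON header (magic, scheme, parameters, array directory) followed by
fixed-width little-endian signed coefficient payloads and a SHA-256 trailer.
Rewriting a read container reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import InvalidInputError
from .genoenc import VariantRecord, encode_genotype
from .gwascirc import GenotypeMatrix, Task1Result

__all__ = [
    "read_vcf_subset",
    "write_vcf_subset",
    "read_genotype_csv",
    "write_genotype_csv",
    "write_task1_tsv",
    "write_container",
    "read_container",
    "infer_svtype",
]

_MAGIC = b"HEG1"


# ---------------------------------------------------------------------------
# VCF subset


def infer_svtype(ref: str, alt: str) -> str:
    """Length rule when SVTYPE is absent: longer REF -> DEL, longer ALT ->
    INS, equal -> SUB."""
    if len(ref) > len(alt):
        return "DEL"
    if len(ref) < len(alt):
        return "INS"
    return "SUB"


def read_vcf_subset(path) -> list[VariantRecord]:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise InvalidInputError(
                    f"{path}: record {i} at {rec.chrom}:{rec.pos} is not "
                    "bi-allelic (multi-allelic ALT rejected)"
                )
            alt = rec.alts[0]
            try:
                sv = rec.info.get("SVTYPE", None)
            except ValueError:  # SVTYPE not declared in this file's header
                sv = None
            if sv is None:
                sv = infer_svtype(rec.ref, alt)
            try:
                records.append(
                    VariantRecord(chrom=str(rec.chrom), pos=int(rec.pos),
                                  sv=str(sv), ref=str(rec.ref), alt=str(alt))
                )
            except InvalidInputError as exc:
                raise InvalidInputError(f"{path}: record {i}: {exc}") from exc
    return records


def write_vcf_subset(path, records: list[VariantRecord]) -> None:
    lines = [
        "##fileformat=VCFv4.1",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description='
        '"Structural variant class relative to the reference (SUB/INS/DEL)">',
    ]
    for chrom in dict.fromkeys(r.chrom for r in records):
        length = max((r.pos + len(r.ref) for r in records if r.chrom == chrom),
                     default=1) + 1000
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in records:
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\tSVTYPE={r.sv}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# genotype CSV


def read_genotype_csv(path, label: str | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    codes = df.map(encode_genotype).to_numpy(dtype=np.int64)
    return GenotypeMatrix(label or Path(path).stem, codes)


_CODE_TO_GT = {2: "AA", 1: "AB", 0: "BB"}


def write_genotype_csv(path, matrix: GenotypeMatrix) -> None:
    df = pd.DataFrame(
        [[_CODE_TO_GT[int(v)] for v in row] for row in matrix.codes],
        index=[f"P{i+1}" for i in range(matrix.N)],
        columns=[f"SNV{j+1}" for j in range(matrix.s)],
    )
    df.to_csv(path)


def write_task1_tsv(path, result: Task1Result) -> None:
    rows = []
    for j in range(len(result.n_case)):
        c2 = result.chi2[j]
        rows.append({
            "snv": f"SNV{j+1}",
            "n_A": result.n_case[j],
            "n_A_prime": result.n_cont[j],
            "maf_case": float(result.maf_case[j]),
            "maf_control": float(result.maf_cont[j]),
            "chi2": float(c2) if c2 is not None else float("nan"),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# binary containers


def _int_width(arrays) -> int:
    mx = 1
    for arr in arrays:
        for vec in arr:
            for v in vec:
                mx = max(mx, abs(int(v)))
    return (mx.bit_length() + 8) // 8  # one sign bit guaranteed


def write_container(path, kind: str, scheme: str, params: dict,
                    arrays: dict[str, list[list[int]]]) -> None:
    """``arrays`` maps a name to a list of equal-length coefficient vectors."""
    width = _int_width(arrays.values())
    directory = []
    payload = bytearray()
    for name, arr in arrays.items():
        lengths = {len(vec) for vec in arr}
        if len(lengths) > 1:
            raise InvalidInputError(f"ragged array {name!r} in container")
        directory.append({
            "name": name,
            "count": len(arr),
            "length": lengths.pop() if lengths else 0,
        })
        for vec in arr:
            for v in vec:
                payload += int(v).to_bytes(width, "little", signed=True)
    header = json.dumps(
        {"kind": kind, "scheme": scheme, "params": params,
         "width": width, "arrays": directory},
        sort_keys=True, separators=(",", ":"),
    ).encode()
    blob = _MAGIC + struct.pack("<I", len(header)) + header + bytes(payload)
    digest = hashlib.sha256(blob).digest()
    Path(path).write_bytes(blob + digest)


def save_keys(path, keys) -> None:
    """Serialize a key set (either scheme) with its parameters."""
    from .bgv import BGVKeys

    if isinstance(keys, BGVKeys):
        p = keys.params
        params = {"m": p.m, "t": p.t, "L": p.L, "primes": list(p.primes),
                  "P": p.P, "sigma": p.noise.sigma, "B": p.noise.B,
                  "h": p.noise.h, "lam": p.lam}
        arrays = {
            "sk": [list(keys.sk.coeffs)],
            "pk": [list(keys.pk[0].coeffs), list(keys.pk[1].coeffs)],
            "evk": [list(keys.evk[0].coeffs), list(keys.evk[1].coeffs)],
        }
        write_container(path, "keys", "bgv", params, arrays)
        return
    p = keys.params
    params = {"n": p.n, "q": p.q, "t": p.t, "omega": p.omega, "M": p.M,
              "sigma": p.noise.sigma, "B": p.noise.B}
    arrays = {
        "sk": [list(keys.sk.coeffs)],
        "pk": [list(keys.pk.coeffs)],
        "evk": [list(g.coeffs) for g in (keys.evk or ())],
    }
    write_container(path, "keys", "yashe", params, arrays)


def load_keys(path):
    """Rebuild a key set; returns (scheme, params, keys)."""
    from .bgv import BGVKeys, BGVParams
    from .ring import NoiseProfile, RingElement
    from .yashe import YASHEKeys, YASHEParams

    header, arrays = read_container(path)
    if header["kind"] != "keys":
        raise InvalidInputError(f"{path}: container holds {header['kind']!r}")
    meta = header["params"]
    if header["scheme"] == "bgv":
        params = BGVParams(
            m=meta["m"], t=meta["t"], L=meta["L"],
            primes=tuple(meta["primes"]), P=meta["P"],
            noise=NoiseProfile(sigma=meta["sigma"], B=meta["B"], h=meta["h"]),
            lam=meta.get("lam"),
        )
        q = params.chain[-1]
        Q = params.P * params.chain[-2]
        keys = BGVKeys(
            params=params,
            sk=RingElement(tuple(arrays["sk"][0]), q),
            pk=(RingElement(tuple(arrays["pk"][0]), q),
                RingElement(tuple(arrays["pk"][1]), q)),
            evk=(RingElement(tuple(arrays["evk"][0]), Q),
                 RingElement(tuple(arrays["evk"][1]), Q)),
        )
        return "bgv", params, keys
    params = YASHEParams(
        n=meta["n"], q=meta["q"], t=meta["t"], omega=meta["omega"],
        M=meta["M"], noise=NoiseProfile(sigma=meta["sigma"], B=meta["B"]),
    )
    evk = tuple(RingElement(tuple(v), params.q) for v in arrays["evk"])
    keys = YASHEKeys(
        params=params,
        sk=RingElement(tuple(arrays["sk"][0]), params.q),
        pk=RingElement(tuple(arrays["pk"][0]), params.q),
        evk=evk or None,
    )
    return "yashe", params, keys


def params_fingerprint(path_or_header) -> str:
    header = path_or_header
    if not isinstance(header, dict):
        header, _ = read_container(path_or_header)
    blob = json.dumps(header["params"], sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def cts_to_arrays(cts, scheme: str):
    """Flatten a ciphertext list into container arrays plus metadata."""
    if scheme == "bgv":
        return (
            {"c0": [list(ct.c0.coeffs) for ct in cts],
             "c1": [list(ct.c1.coeffs) for ct in cts]},
            {"levels": [ct.level for ct in cts]},
        )
    return {"c": [list(ct.c.coeffs) for ct in cts]}, {}


def arrays_to_cts(arrays, meta, scheme: str, params):
    from .bgv import BGVCiphertext
    from .ring import RingElement
    from .yashe import YASHECiphertext

    if scheme == "bgv":
        out = []
        for c0, c1, lvl in zip(arrays["c0"], arrays["c1"], meta["levels"]):
            q = params.chain[lvl]
            out.append(BGVCiphertext(
                c0=RingElement(tuple(c0), q), c1=RingElement(tuple(c1), q),
                level=lvl, noise_est=0.0,
            ))
        return out
    return [YASHECiphertext(c=RingElement(tuple(c), params.q), noise_est=0.0)
            for c in arrays["c"]]


def read_container(path):
    raw = Path(path).read_bytes()
    if len(raw) < 40 or raw[:4] != _MAGIC:
        raise InvalidInputError(f"{path}: not a ciphertext/key container")
    blob, digest = raw[:-32], raw[-32:]
    if hashlib.sha256(blob).digest() != digest:
        raise InvalidInputError(f"{path}: checksum mismatch")
    (hlen,) = struct.unpack("<I", blob[4:8])
    header = json.loads(blob[8 : 8 + hlen].decode())
    width = header["width"]
    arrays = {}
    off = 8 + hlen
    for entry in header["arrays"]:
        arr = []
        for _ in range(entry["count"]):
            vec = [
                int.from_bytes(blob[off + k * width : off + (k + 1) * width],
                               "little", signed=True)
                for k in range(entry["length"])
            ]
            off += entry["length"] * width
            arr.append(vec)
        arrays[entry["name"]] = arr
    return header, arrays
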