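"""Parameter-estimation calculator for the two SHE schemes.

Closed-form budgets used when sizing a deployment: per-multiplication
modulus-switch count, modulus sizes, ciphertext sizes, the scale-invariant
noise floor, and the RLWE security lower bound on ``phi(m)``.  A small
planner assembles the per-task rows (plaintext modulus, modulus size, ring
degree, slot count, depth, ciphertext size).

Display rounding: the modulus-size constant and the scale-invariant
per-level term are rounded to the nearest integer (half up), while the
modulus-chain per-level increment is rounded *up* — a per-level budget is a
provision and rounding it down could under-build the chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError, PipelineError
from .ring import slot_count

__all__ = [
    "DepthEstimate",
    "SizeEstimate",
    "bgv_depth",
    "bgv_levels",
    "bgv_logq",
    "bgv_logq_constant",
    "bgv_logq_step",
    "bgv_ct_bytes",
    "yashe_ct_bytes",
    "ct_kilobytes",
    "yashe_per_level_bits",
    "yashe_logq_bound",
    "bgv_security_min_phi",
    "task1_plaintext_modulus",
    "plan_table",
]


@dataclass(frozen=True)
class DepthEstimate:
    d: float      # per-multiplication modulus-switch count d_{n,t}
    M: int        # multiplicative levels
    L: int        # modulus-chain length, M * ceil(d) + 2


@dataclass(frozen=True)
class SizeEstimate:
    log2_q: float
    ct_bytes: int


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


# ---------------------------------------------------------------------------
# modulus-switching scheme budgets


def bgv_depth(n: int, t: int, h: int) -> float:
    """``d_{n,t} ~ log2(h n t^4) / 36``: modulus switches per multiplication
    (assuming ~36-bit chain primes)."""
    if min(n, t, h) <= 0:
        raise InvalidParameterError("n, t, h must be positive")
    return math.log2(h * n * t**4) / 36.0


def bgv_levels(M: int, n: int, t: int, h: int) -> DepthEstimate:
    """Chain length ``L = M ceil(d_{n,t}) + 2`` for ``M`` multiplications
    (one initial switch plus the base modulus account for the +2)."""
    d = bgv_depth(n, t, h)
    return DepthEstimate(d=d, M=M, L=M * math.ceil(d) + 2)


def bgv_logq(n: int, L: int) -> float:
    """``log2 q ~ 24 + 1.5 log2 n + (L - 2)(11 + 0.5 log2 n)``."""
    if L < 2:
        raise InvalidParameterError("L must be >= 2")
    return 24 + 1.5 * math.log2(n) + (L - 2) * (11 + 0.5 * math.log2(n))


def bgv_logq_constant(n: int) -> int:
    """Displayed constant term ``24 + 1.5 log2 n``, nearest integer."""
    return _round_half_up(24 + 1.5 * math.log2(n))


def bgv_logq_step(n: int) -> int:
    """Displayed per-level increment ``11 + 0.5 log2 n``, rounded up."""
    return math.ceil(11 + 0.5 * math.log2(n))


def bgv_ct_bytes(n: int, log2_q: float) -> int:
    """Two ring elements: ``ceil(2 n log2 q / 8)`` bytes."""
    return math.ceil(2 * n * log2_q / 8)


def yashe_ct_bytes(n: int, log2_q: float) -> int:
    """One ring element: ``ceil(n log2 q / 8)`` bytes."""
    return math.ceil(n * log2_q / 8)


def ct_kilobytes(nbytes: int) -> int:
    """Displayed size in kB (1 kB = 1024 bytes, nearest integer)."""
    return _round_half_up(nbytes / 1024)


# ---------------------------------------------------------------------------
# scale-invariant scheme budgets


def yashe_per_level_bits(n: int, t: int) -> float:
    """Dominant per-level modulus cost ``2 log2(n t)``."""
    return 2 * math.log2(n * t)


def yashe_logq_bound(M: int, n: int, t: int, sigma: float = 8.0,
                     omega: int = 1 << 128, adds: int = 1 << 10) -> float:
    """Minimal ``log2 q`` so the ``M``-level noise stays below ``q/t``.

    For ``M >= 1`` this is the printed bound
    ``2 M log2(n t) + log2(12 sigma ell_{w,q} omega)`` (equivalently
    ``(n t)^{2(M-1)} 12 n^2 t sigma ell_w omega < q/t``); ``ell_{w,q}``
    depends on ``q`` itself, so the estimate is iterated twice (it converges
    immediately for omega = 2^128).  For ``M = 0`` only fresh noise and an
    addition budget of ``adds`` ciphertexts matter.
    """
    if M < 0:
        raise InvalidParameterError("M must be >= 0")
    B = 6 * sigma
    if M == 0:
        fresh = n * t * (t / 2 + 2 * B + 2)
        return math.log2(2 * t * fresh * max(1, adds))
    logq = 2 * M * math.log2(n * t) + 128
    for _ in range(2):
        ell_w = math.floor(logq / math.log2(omega)) + 1
        logq = 2 * M * math.log2(n * t) + math.log2(12 * sigma * ell_w * omega)
    return logq


# ---------------------------------------------------------------------------
# security floor


def bgv_security_min_phi(L: int, m: int, lam: int) -> float:
    """Lower bound on ``phi(m)``: ``(L (log2 m + 23) - 8.5)(lam + 110)/7.2``.

    The printed inequality's grouping is ambiguous; this is the
    Lindner-Peikert-style reading, and parameter sets are validated against
    it as a consistency check rather than an equality.
    """
    if L < 1:
        raise InvalidParameterError("L must be >= 1")
    return (L * (math.log2(m) + 23) - 8.5) * (lam + 110) / 7.2


# ---------------------------------------------------------------------------
# task-level planning


def task1_plaintext_modulus(N: int, task: str, scheme: str = "bgv") -> int:
    """Smallest power-of-two ``t`` with no wrap-around in the slots.

    Minor-allele counts reach ``2N`` per group, so the MAF pipeline needs
    ``2N < t``; the chi-square pipeline aggregates both groups and needs
    ``4N < t``.  The coefficient-packing scheme runs both statistics at the
    chi-square bound.
    """
    if task not in {"maf", "chi2"}:
        raise InvalidParameterError(f"unknown task {task!r}")
    bound = 2 * N if (task == "maf" and scheme == "bgv") else 4 * N
    t = 2
    while t <= bound:
        t <<= 1
    return t


_TASK1_PROFILES = {
    # scheme -> (m or n, ring degree n)
    "bgv": {"m": 8191, "n": 8190, "L": 3},
    "yashe": {"n": 1024, "M": 0},
}
_TASK2_PROFILES = {
    "bgv": {"m": 8191, "n": 8190, "t": 2, "L": {"hamming": 7, "edit": 8}},
    "yashe": {"n": 8192, "t": 8191, "M": 6},
}


def plan_table(task: str, scheme: str, N: int = 200, h: int = 64,
               sigma: float | None = None, log2_q: float | None = None) -> dict:
    """One parameter row for a (task, scheme) pair at the publication scale.

    Derivable columns only: plaintext modulus ``t``, modulus size, ring
    degree, slot count, depth and ciphertext size.  ``log2_q`` may be given
    explicitly (e.g. a measured library modulus) to size ciphertexts for an
    existing deployment; otherwise the closed-form budget is used.
    """
    scheme = scheme.lower()
    if scheme not in {"bgv", "yashe"}:
        raise PipelineError(f"unknown scheme {scheme!r}")
    if task in {"maf", "chi2"}:
        t = task1_plaintext_modulus(N, task, scheme)
        if scheme == "bgv":
            prof = _TASK1_PROFILES["bgv"]
            m, n, L = prof["m"], prof["n"], prof["L"]
            lq = bgv_logq(n, L) if log2_q is None else log2_q
            ell, _ = slot_count(m, t)
            nbytes = bgv_ct_bytes(n, lq)
            return {"task": task, "scheme": scheme, "t": t, "m": m, "n": n,
                    "ell": ell, "L": L, "log2_q": lq, "ct_bytes": nbytes,
                    "ct_kB": ct_kilobytes(nbytes),
                    "t_bound": f"sum of 2 over {N} persons = {2*N} < t"}
        prof = _TASK1_PROFILES["yashe"]
        n, M = prof["n"], prof["M"]
        lq = yashe_logq_bound(M, n, t, sigma=sigma or 8.0, adds=2 * N) \
            if log2_q is None else log2_q
        nbytes = yashe_ct_bytes(n, lq)
        return {"task": task, "scheme": scheme, "t": t, "n": n,
                "ell": n, "M": M, "log2_q": lq, "ct_bytes": nbytes,
                "ct_kB": ct_kilobytes(nbytes),
                "t_bound": f"2 * sum of 2 over {N} persons = {4*N} < t"}
    if task in {"hamming", "edit"}:
        if scheme == "bgv":
            prof = _TASK2_PROFILES["bgv"]
            m, n, t = prof["m"], prof["n"], prof["t"]
            L = prof["L"][task]
            lq = bgv_logq(n, L) if log2_q is None else log2_q
            ell, _ = slot_count(m, t)
            nbytes = bgv_ct_bytes(n, lq)
            return {"task": task, "scheme": scheme, "t": t, "m": m, "n": n,
                    "ell": ell, "L": L, "log2_q": lq, "ct_bytes": nbytes,
                    "ct_kB": ct_kilobytes(nbytes), "t_bound": "binary circuit"}
        prof = _TASK2_PROFILES["yashe"]
        n, t, M = prof["n"], prof["t"], prof["M"]
        lq = yashe_logq_bound(M, n, t, sigma=sigma or 8.0) \
            if log2_q is None else log2_q
        ell, _ = slot_count(2 * n, t)
        nbytes = yashe_ct_bytes(n, lq)
        return {"task": task, "scheme": scheme, "t": t, "n": n,
                "ell": ell, "M": M, "log2_q": lq, "ct_bytes": nbytes,
                "ct_kB": ct_kilobytes(nbytes),
                "t_bound": "prime t maximizing the slot count"}
    raise PipelineError(f"unknown task {task!r}")
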