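"""Named parameter profiles.

The ``*_toy`` profiles are deliberately small rings for tests, demos and the
command-line walk-through: correct and fast, but nowhere near a meaningful
RLWE security level.  Production-scale parameters are generated through
``bgv_params_gen`` / ``yashe_params_gen`` with an explicit security target.

Toy ring choices:

* ``m = 257`` (odd): ``Phi_257 mod 2`` splits into 16 degree-16 factors, so
  16 slots hold a 16-SNV panel; ``t = 2^9`` mirrors the published MAF bound.
* ``m = 85``: 8 slots of degree 8 at ``t = 2`` for the binary circuits.
* ``n = 64`` power of two with ``t = 127 = 2n - 1`` prime:
  ``x^64 + 1 mod 127`` splits into 32 quadratic factors (32 slots).
"""

from __future__ import annotations

from .bgv import BGVParams, bgv_toy_params
from .errors import InvalidParameterError
from .ring import NoiseProfile
from .yashe import YASHEParams, yashe_params_gen

__all__ = ["toy_profile", "TOY_PROFILES"]


def _bgv_task1() -> BGVParams:
    return bgv_toy_params(m=257, t=1 << 9, L=3,
                          noise=NoiseProfile(sigma=3.2, h=16))


def _bgv_task2() -> BGVParams:
    return bgv_toy_params(m=85, t=2, L=8,
                          noise=NoiseProfile(sigma=3.2, h=8), prime_bits=32)


def _yashe_task1() -> YASHEParams:
    return yashe_params_gen(lam=0, M=0, t=1 << 10, n=64, omega=1 << 16,
                            adds_budget=1 << 7)


def _yashe_task2() -> YASHEParams:
    return yashe_params_gen(lam=0, M=7, t=127, n=64, omega=1 << 16)


TOY_PROFILES = {
    ("bgv", "task1"): _bgv_task1,
    ("bgv", "task2"): _bgv_task2,
    ("yashe", "task1"): _yashe_task1,
    ("yashe", "task2"): _yashe_task2,
}


def toy_profile(scheme: str, task: str):
    """``task`` is ``task1`` (GWAS) or ``task2`` (sequence comparison)."""
    try:
        return TOY_PROFILES[(scheme.lower(), task.lower())]()
    except KeyError:
        raise InvalidParameterError(
            f"no toy profile for scheme={scheme!r}, task={task!r}"
        ) from None
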