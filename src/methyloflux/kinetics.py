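"""Forward Michaelis–Menten evaluation and enzyme-variant comparison.

Only forward evaluation of printed parameters is provided: the rate law

    v(S) = k_cat · [E] · S / (K_M + S)

and the percent activity difference between two parameter sets at a common
substrate concentration (or in the saturating limit, where it reduces to
the k_cat ratio). Parameter estimation from raw traces is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["KineticParams", "mm_rate", "relative_activity"]


@dataclass(frozen=True)
class KineticParams:
    """Turnover number k_cat (s⁻¹), Michaelis constant K_M (mM), and an
    optional enzyme concentration in arbitrary units (default 1)."""

    k_cat: float
    K_M: float
    enzyme_conc: float = 1.0

    def __post_init__(self) -> None:
        if self.k_cat < 0:
            raise ValueError("k_cat must be non-negative")
        if self.K_M <= 0:
            raise ValueError("K_M must be positive")


def mm_rate(params: KineticParams, substrate_mM: float) -> float:
    """Michaelis–Menten rate at a substrate concentration (mM)."""
    if substrate_mM < 0:
        raise ValueError("substrate concentration must be non-negative")
    return (
        params.k_cat
        * params.enzyme_conc
        * substrate_mM
        / (params.K_M + substrate_mM)
    )


def relative_activity(
    a: KineticParams,
    b: KineticParams,
    substrate_mM: float | None = None,
    saturating: bool = False,
) -> float:
    """Percent activity of variant ``b`` relative to ``a``: 100·(v_b−v_a)/v_a.

    Evaluated at equal enzyme concentration. With ``saturating=True`` the
    S→∞ limit is used and the result is the k_cat ratio, independent of
    K_M.
    """
    if saturating:
        substrate_mM = math.inf
    elif substrate_mM is None:
        raise ValueError("substrate_mM required unless saturating=True")
    if substrate_mM is math.inf:
        rate_a, rate_b = a.k_cat, b.k_cat
    else:
        rate_a = mm_rate(KineticParams(a.k_cat, a.K_M), substrate_mM)
        rate_b = mm_rate(KineticParams(b.k_cat, b.K_M), substrate_mM)
    if rate_a == 0:
        raise ValueError("reference rate is zero; relative activity undefined")
    return 100.0 * (rate_b - rate_a) / rate_a
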