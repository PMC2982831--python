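"""Combining per-method significances via Poisson database P-values.

A per-method E-value is first mapped to the probability of seeing at least
one random hit at least that good in a database of the given size; treating
high-scoring random hits as a Poisson process gives P = 1 − exp(−E).  The
database P-values of independent methods are then combined through the
exact tail probability that a product of m independent uniforms falls at or
below the observed product, and the combined P-value is inverted back to a
combined E-value.  Methods that did not report a peptide contribute P = 1.
Note the combined P-value is not always smaller than each input (e.g.
[0.5, 1.0] combines to ≈0.847).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.special import gammaln, logsumexp

__all__ = [
    "CombinedResult",
    "database_pvalue",
    "combine_db_pvalues",
    "combined_evalue",
    "combine_assignments",
]

_P_COMB_MAX = 1.0 - 1e-16  # keeps the Poisson inversion finite


def database_pvalue(E: float) -> float:
    """P = 1 − exp(−E): probability of ≥1 random hit at least as good."""
    if E < 0:
        raise ValueError("E-value must be non-negative")
    return -math.expm1(-E)


def combine_db_pvalues(P) -> float:
    """Exact tail probability that a product of m uniforms ≤ Π P_i.

    With t = Π P_i the combined value is t · Σ_{k=0}^{m−1} (−ln t)^k / k!,
    evaluated in log space for numerical safety at very small t.  Any
    P_i = 0 gives 0 (the limit); values outside (0, 1] are rejected.
    """
    P = list(P)
    if not P:
        raise ValueError("need at least one P-value")
    for p in P:
        if p == 0.0:
            return 0.0
        if not 0.0 < p <= 1.0:
            raise ValueError(f"database P-value {p!r} outside (0, 1]")
    m = len(P)
    log_t = sum(math.log(p) for p in P)
    if log_t == 0.0:
        return 1.0
    x = -log_t
    log_terms = [log_t + k * math.log(x) - gammaln(k + 1) for k in range(m)]
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def combined_evalue(P_comb: float) -> float:
    """Invert the Poisson relation: E = −ln(1 − P)."""
    if not 0.0 <= P_comb < 1.0:
        raise ValueError("combined P-value must lie in [0, 1)")
    return -math.log1p(-P_comb)


@dataclass
class CombinedResult:
    """Combined significance of one peptide across scoring functions."""

    peptide: tuple
    input_evalues: dict[str, float]
    db_pvalues: dict[str, float] = field(init=False)
    p_product: float = field(init=False)
    combined_p: float = field(init=False)
    combined_e: float = field(init=False)

    def __post_init__(self) -> None:
        self.db_pvalues = {
            tag: database_pvalue(e) if e is not None else 1.0
            for tag, e in self.input_evalues.items()
        }
        vals = list(self.db_pvalues.values())
        self.p_product = math.prod(vals)
        if not vals:
            self.combined_p = 1.0
        elif any(v == 0.0 for v in vals):
            self.combined_p = 0.0
        else:
            self.combined_p = combine_db_pvalues(vals)
        self.combined_e = combined_evalue(min(self.combined_p, _P_COMB_MAX))


def combine_assignments(
    peptide,
    evalues: dict[str, float | None],
) -> CombinedResult:
    """Build a :class:`CombinedResult`; ``None`` marks a method that did
    not report the peptide (its database P-value is set to one)."""
    return CombinedResult(peptide=tuple(peptide), input_evalues=dict(evalues))
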