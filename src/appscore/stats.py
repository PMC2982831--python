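"""Spectrum-specific p-values and E-values from APP score histograms.

The APP p-value of a score ``s`` is the weighted fraction of all possible
peptides in the parent window whose score is at least ``s`` — a tail read
off the collapsed DP histogram with no parametric model.  Candidate scores
fall between histogram bin centers, so the tail is interpolated
log-linearly (score-histogram tails are near-exponential).  The E-value
multiplies the p-value by the number of qualified database peptides.

This module also houses the PTM-aware reweighting of residue emission
probabilities (a parent's probability mass is split among its observed
modified forms with one pseudocount kept by the unmodified residue) and
the decoy calibration curve used to check E-value accuracy against the
textbook definition.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .alphabet import ROBINSON_ROBINSON
from .dp import FinalHistogram

__all__ = [
    "MethodSignificance",
    "SignificanceAssignment",
    "EmissionUpdate",
    "pvalue",
    "evalue",
    "ptm_emissions",
    "choose_base_frequencies",
    "calibration_curve",
]


@dataclass(frozen=True)
class MethodSignificance:
    score: float
    p_value: float
    e_value: float


@dataclass
class SignificanceAssignment:
    """Per-method significance for one candidate peptide of one spectrum."""

    peptide: tuple
    methods: dict[str, MethodSignificance]
    n_qualified: int
    nterm_correct: bool = True

    def __post_init__(self) -> None:
        for tag, ms in self.methods.items():
            if not 0.0 < ms.p_value <= 1.0:
                raise ValueError(f"{tag}: p-value outside (0, 1]")
            if ms.e_value < 0:
                raise ValueError(f"{tag}: negative E-value")

    def best_e(self) -> float:
        return min(ms.e_value for ms in self.methods.values())


def pvalue(
    h: FinalHistogram,
    score: float,
    floor: bool = False,
) -> float:
    """Tail probability P(S ≥ score) under the APP histogram.

    Scores at a populated bin center return that bin's exact tail mass;
    scores between centers are interpolated log-linearly on the tail.
    Scores beyond the best bin are clamped to ``1/N_total`` when ``floor``
    is on (a conservative lower bound for the best attainable p-value),
    otherwise to the smallest positive tail.
    """
    if h.total_weight <= 0:
        raise ValueError("empty histogram")
    centers = h.scores
    tail = h.tail()
    total = h.total_weight
    p_min = 1.0 / total if floor else float(tail[-1]) / total
    if score <= centers[0]:
        return 1.0
    if score >= centers[-1]:
        return min(1.0, max(float(tail[-1]) / total, 0.0)) if score == centers[-1] else p_min
    i = int(np.searchsorted(centers, score, side="right")) - 1
    if centers[i] == score:
        p = float(tail[i]) / total
    else:
        t0, t1 = float(tail[i]), float(tail[i + 1])
        x0, x1 = float(centers[i]), float(centers[i + 1])
        f = (score - x0) / (x1 - x0)
        p = math.exp(
            (1 - f) * math.log(t0 / total) + f * math.log(t1 / total)
        )
    return float(min(1.0, max(p, p_min)))


def evalue(p: float, n_qualified: int) -> float:
    """E = p × N_D: expected number of random hits at or above the score."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p-value must lie in (0, 1]")
    if n_qualified < 0:
        raise ValueError("n_qualified must be non-negative")
    return p * n_qualified


@dataclass
class EmissionUpdate:
    """Result of redistributing emission probability onto PTM variants."""

    base: dict[str, float]
    counts_unmodified: dict[str, int]
    counts_modified: dict[tuple, int]
    updated: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        updated: dict[str, float] = {}
        mods_by_parent: dict[str, dict[str, int]] = {}
        for (parent, variant), m in self.counts_modified.items():
            mods_by_parent.setdefault(parent, {})[variant] = m
        for parent, p in self.base.items():
            n = self.counts_unmodified.get(parent, 0)
            mods = mods_by_parent.get(parent, {})
            denom = (n + 1) + sum(mods.values())
            updated[parent] = p * (n + 1) / denom
            for variant, m in mods.items():
                updated[variant] = p * m / denom
        total = sum(updated.values())
        self.updated = {t: v / total for t, v in updated.items()}


def _variant_parent(token: str, base: dict[str, float]) -> str:
    """Resolve a variant token's parent: the token itself if unmodified,
    else its leading unmodified residue letter (e.g. ``M+16`` → ``M``)."""
    if token in base:
        return token
    if token and token[0] in base:
        return token[0]
    raise KeyError(f"variant token {token!r} has no known parent residue")


def ptm_emissions(
    peptide_list,
    base: dict[str, float],
    max_ptms: int = 10,
) -> EmissionUpdate:
    """Redistribute base emission probabilities over observed PTM variants.

    Occurrences of each amino acid are tallied as unmodified (``n_a``) or
    modified into variant b (``m_{a→b}``); only the ``max_ptms`` most
    abundant variants are retained.  Each parent keeps one pseudocount, so
    with no observed modification the base probabilities are returned
    unchanged.
    """
    if not peptide_list:
        raise ValueError("peptide list must be non-empty")
    total_base = sum(base.values())
    if abs(total_base - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    n_unmod: Counter = Counter()
    m_mod: Counter = Counter()
    for peptide in peptide_list:
        for token in peptide:
            parent = _variant_parent(token, base)
            if token == parent:
                n_unmod[token] += 1
            else:
                m_mod[(parent, token)] += 1
    if len(m_mod) > max_ptms:
        retained = dict(
            sorted(m_mod.items(), key=lambda kv: (-kv[1], kv[0]))[:max_ptms]
        )
    else:
        retained = dict(m_mod)
    return EmissionUpdate(
        base=dict(base),
        counts_unmodified=dict(n_unmod),
        counts_modified=retained,
    )


def choose_base_frequencies(
    qualified_peptides,
    threshold: int = 1000,
) -> dict[str, float]:
    """Background frequencies: Robinson–Robinson below ``threshold`` total
    residues, otherwise frequencies counted from the qualified list."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    counts: Counter = Counter()
    total = 0
    for peptide in qualified_peptides:
        for token in peptide:
            counts[token] += 1
            total += 1
    if total < threshold:
        return dict(ROBINSON_ROBINSON)
    return {t: c / total for t, c in counts.items()}


def calibration_curve(
    assignments,
    n_spectra: int,
    cutoffs,
    method: str | None = None,
):
    """Mean false-positive count per spectrum versus E-value cutoff.

    ``assignments`` is either a sequence of E-values (floats) or of
    :class:`SignificanceAssignment` (then ``method`` selects which E to
    read).  For accurately reported E-values the curve tracks the diagonal
    y = x up to sampling fluctuation.
    """
    if n_spectra <= 0:
        raise ValueError("n_spectra must be positive")
    evalues: list[float] = []
    for a in assignments:
        if isinstance(a, SignificanceAssignment):
            if method is None:
                raise ValueError("method required for assignment objects")
            evalues.append(a.methods[method].e_value)
        else:
            evalues.append(float(a))
    ev = np.sort(np.asarray(evalues, dtype=float))
    out = []
    for x in cutoffs:
        k = int(np.searchsorted(ev, x, side="right"))
        out.append((float(x), k / n_spectra))
    return out
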