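"""Dynamic programming over the mass grid: peptide counts and score histograms.

The all-possible-peptide (APP) ensemble at a parent mass window is far too
large to enumerate, but because every scoring function here is additive
over prefix-mass indices, the full score histogram can be propagated
exactly on the mass grid.  The table at index ``m`` is the superposition of
the tables at ``m − mass(a)`` over all residues ``a``, shifted by the local
evidence score at ``m`` and by the internal-structure increments (length
+1, matched b/y counters), and scaled by the emission probability when the
ensemble is weighted.  Terminating transitions (into the parent window)
collect no local evidence — a peptide's final index carries no fragment —
and honour the enzyme's C-terminal restriction.

Internal structure (peptide length; matched b-/y-peak counts) is carried so
that the non-additive end corrections can be applied when the structured
histogram is collapsed into the final per-method score histogram.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import Alphabet, EnzymeRule, MassWindow
from .scoring import EvidenceArray, ScoreParams, log_factorial

logger = logging.getLogger(__name__)

__all__ = [
    "AXES_BY_METHOD",
    "StructuredHistogram",
    "FinalHistogram",
    "count_peptides",
    "build_structured_histogram",
    "collapse",
    "app_histogram",
]

#: Structure axes each scoring function's end correction requires.
AXES_BY_METHOD = {
    "raid": ("length",),
    "hyperscore": ("nb", "ny"),
    "xcorr": (),
    "kscore": ("length",),
}

_AXIS_ORDER = ("length", "nb", "ny")


def count_peptides(
    alphabet: Alphabet,
    window: MassWindow,
    enzyme: EnzymeRule,
    weighted: bool = False,
):
    """(Weighted) number of all possible peptides in the mass window.

    Unweighted counts are exact integers; weighted counts multiply each
    sequence by the product of its residues' emission probabilities.  The
    enzyme's C-terminal restriction applies to the final transition; the
    empty peptide is excluded.  A window below the lightest residue gives 0.
    """
    hi, lo = window.hi_index, window.lo_index
    if hi < alphabet.min_grid_mass:
        return 0.0 if weighted else 0
    zero = 0.0 if weighted else 0
    c = [zero] * (hi + 1)
    c[0] = 1.0 if weighted else 1
    steps = [
        (r.grid_mass, r.emission_probability if weighted else 1)
        for r in alphabet
    ]
    for m in range(1, hi + 1):
        acc = zero
        for g, w in steps:
            j = m - g
            if j >= 0 and c[j]:
                acc += w * c[j]
        c[m] = acc
    term_steps = [
        (r.grid_mass, r.emission_probability if weighted else 1)
        for r in alphabet
        if enzyme.allows_cterm(r)
    ]
    total = zero
    for m in range(max(lo, 1), hi + 1):
        for g, w in term_steps:
            j = m - g
            if j >= 0 and c[j]:
                total += w * c[j]
    return total


@dataclass
class StructuredHistogram:
    """Raw-score histograms with internal structure, per terminal mass index.

    ``per_index[m]`` is a dense array over (score_bin, *axes); array score
    index 0 corresponds to ``score_offset`` on the rounded evidence scale.
    With weighting disabled the stored counts are non-negative integers
    (held in floats).
    """

    method: str
    axes: tuple[str, ...]
    score_bin_width: float
    score_offset: int
    per_index: dict[int, np.ndarray]
    window: MassWindow
    weighted: bool
    transition_ops: int = 0

    def entries(self, index: int | None = None):
        """Yield ``((score_bin, *axis_values), weight)`` for nonzero cells."""
        indices = [index] if index is not None else sorted(self.per_index)
        for m in indices:
            arr = self.per_index[m]
            for cell in zip(*np.nonzero(arr)):
                key = (int(cell[0]) + self.score_offset,) + tuple(
                    int(v) for v in cell[1:]
                )
                yield key, float(arr[cell])

    @property
    def total_weight(self) -> float:
        return float(sum(arr.sum() for arr in self.per_index.values()))


def _score_capacity(rounded: np.ndarray, max_len: int) -> tuple[int, int]:
    """Tight bounds on any path's cumulative rounded score."""
    pos = np.sort(rounded[rounded > 0])[::-1]
    neg = np.sort(rounded[rounded < 0])
    smax = int(pos[:max_len].sum()) if pos.size else 0
    smin = int(neg[:max_len].sum()) if neg.size else 0
    return smin, smax


def build_structured_histogram(
    ev: EvidenceArray,
    alphabet: Alphabet,
    window: MassWindow | None = None,
    enzyme: EnzymeRule | None = None,
    structure_axes: tuple[str, ...] | None = None,
    weighted: bool = False,
    dtype=np.float64,
) -> StructuredHistogram:
    """Propagate the APP score histogram over the mass grid.

    At each mass index the histogram is the residue-superposition of the
    histograms one residue-mass back, shifted by the local rounded evidence
    score and the structure increments.  ``structure_axes`` is any subset
    of {"length", "nb", "ny"}; defaults to what ``ev.method`` requires.
    """
    from .alphabet import NO_ENZYME

    window = window or ev.window
    enzyme = enzyme or NO_ENZYME
    if structure_axes is None:
        structure_axes = AXES_BY_METHOD[ev.method]
    structure_axes = tuple(a for a in _AXIS_ORDER if a in structure_axes)
    for ax, attr in (("nb", "b_hit"), ("ny", "y_hit")):
        if ax in structure_axes and getattr(ev, attr) is None:
            raise ValueError(f"axis {ax} requested but indicators absent")
    hi, lo = window.hi_index, window.lo_index
    if hi > ev.rounded.size - 1:
        raise ValueError("evidence array does not cover the window")
    min_g = alphabet.min_grid_mass
    max_g = alphabet.max_grid_mass
    max_len = max(1, hi // min_g)
    smin, smax = _score_capacity(ev.rounded[: hi + 1], max_len)
    n_scores = smax - smin + 1

    axis_sizes = []
    for ax in structure_axes:
        if ax == "length":
            axis_sizes.append(max_len + 1)
        elif ax == "nb":
            cap = min(max_len, int(ev.b_hit[: hi + 1].sum()) + 1)
            axis_sizes.append(cap + 1)
        else:
            cap = min(max_len, int(ev.y_hit[: hi + 1].sum()) + 1)
            axis_sizes.append(cap + 1)
    shape = (n_scores, *axis_sizes)

    def shifted(arr: np.ndarray, ds: int, axis_steps: tuple[int, ...]):
        """Shift along score axis by ds and each structure axis by its step."""
        out = np.zeros_like(arr)
        src = [slice(None)] * arr.ndim
        dst = [slice(None)] * arr.ndim
        for dim, step in enumerate((ds, *axis_steps)):
            if step > 0:
                src[dim] = slice(0, arr.shape[dim] - step)
                dst[dim] = slice(step, arr.shape[dim])
            elif step < 0:
                src[dim] = slice(-step, arr.shape[dim])
                dst[dim] = slice(0, arr.shape[dim] + step)
        out[tuple(dst)] = arr[tuple(src)]
        return out

    start = np.zeros(shape, dtype=dtype)
    start[(0 - smin,) + (0,) * len(axis_sizes)] = 1.0
    tables: list = [None] * (hi + 1)
    tables[0] = start
    steps = [
        (
            r.grid_mass,
            (r.emission_probability if weighted else 1.0),
            enzyme.allows_cterm(r),
        )
        for r in alphabet
    ]
    per_index: dict[int, np.ndarray] = {}
    transition_ops = 0
    rounded = ev.rounded
    b_hit, y_hit = ev.b_hit, ev.y_hit

    def axis_steps_at(m: int, terminal: bool) -> tuple[int, ...]:
        out = []
        for ax in structure_axes:
            if ax == "length":
                out.append(1)
            elif ax == "nb":
                out.append(0 if terminal else int(b_hit[m]))
            else:
                out.append(0 if terminal else int(y_hit[m]))
        return tuple(out)

    for m in range(1, hi + 1):
        acc = None
        term = None
        want_term = lo <= m <= hi
        for g, w, cterm_ok in steps:
            j = m - g
            if j < 0:
                continue
            transition_ops += 1
            src = tables[j]
            if src is None:
                continue
            contrib = src * w
            acc = contrib if acc is None else acc + contrib
            if want_term and cterm_ok:
                term = contrib.copy() if term is None else term + contrib
        if acc is not None:
            tables[m] = shifted(acc, int(rounded[m]), axis_steps_at(m, False))
        if term is not None:
            per_index[m] = shifted(term, 0, axis_steps_at(m, True))
        old = m - max_g
        if old >= 1 and tables[old] is not None:
            tables[old] = None
    return StructuredHistogram(
        method=ev.method,
        axes=structure_axes,
        score_bin_width=ev.score_bin_width,
        score_offset=smin,
        per_index=per_index,
        window=window,
        weighted=weighted,
        transition_ops=transition_ops,
    )


@dataclass
class FinalHistogram:
    """Collapsed per-method score histogram over the parent window.

    ``bins`` are integer bins of the corrected (final) score at
    ``bin_width`` resolution, sorted ascending; ``counts`` are the
    (weighted) peptide counts.
    """

    method: str
    bin_width: float
    bins: np.ndarray
    counts: np.ndarray
    total_weight: float = field(init=False)

    def __post_init__(self) -> None:
        order = np.argsort(self.bins)
        self.bins = np.asarray(self.bins)[order]
        self.counts = np.asarray(self.counts, dtype=float)[order]
        self.total_weight = float(self.counts.sum())

    @property
    def scores(self) -> np.ndarray:
        return self.bins * self.bin_width

    @property
    def s_max(self) -> float:
        """Best (highest) populated final score."""
        return float(self.bins[-1] * self.bin_width)

    def tail(self) -> np.ndarray:
        """N(≥ score) aligned with ``bins`` (monotone non-increasing)."""
        return np.cumsum(self.counts[::-1])[::-1]

    def to_tsv(self, path) -> None:
        tail = self.tail()
        with open(path, "w") as fh:
            fh.write("score\tweighted_count\tcumulative_tail\n")
            for s, c, t in zip(self.scores, self.counts, tail):
                fh.write(f"{s:.10g}\t{c:.10g}\t{t:.10g}\n")


def collapse(
    sh: StructuredHistogram,
    method: str | None = None,
    params: ScoreParams | None = None,
) -> FinalHistogram:
    """Apply the method's end correction and merge over window indices.

    raid: raw / 2(L−1) (L=1 entries have no fragments and are dropped,
    logged); hyperscore: raw + ln Nb! + ln Ny!; kscore: raw / L; xcorr:
    identity.  Corrected scores are re-binned at the method's final bin
    width.
    """
    method = method or sh.method
    params = params or ScoreParams()
    need = AXES_BY_METHOD[method]
    if any(ax not in sh.axes for ax in need):
        raise ValueError(
            f"method {method!r} needs axes {need}, histogram has {sh.axes}"
        )
    fw = params.final_bin_width[method]
    bw = sh.score_bin_width
    cap = params.factorial_cap
    lgf = np.array([log_factorial(n, cap) for n in range(cap + 2)])
    all_bins: list[np.ndarray] = []
    all_weights: list[np.ndarray] = []
    dropped = 0.0
    ax_pos = {ax: i + 1 for i, ax in enumerate(sh.axes)}
    for m, arr in sorted(sh.per_index.items()):
        nz = np.nonzero(arr)
        if nz[0].size == 0:
            continue
        weights = arr[nz]
        raw = (nz[0].astype(np.float64) + sh.score_offset) * bw
        if method == "raid":
            length = nz[ax_pos["length"]]
            keep = length >= 2
            if not np.all(keep):
                dropped += float(weights[~keep].sum())
                raw, weights, length = raw[keep], weights[keep], length[keep]
            corrected = raw / (2.0 * (length - 1))
        elif method == "kscore":
            length = nz[ax_pos["length"]]
            corrected = raw / length.astype(np.float64)
        elif method == "hyperscore":
            nb = np.minimum(nz[ax_pos["nb"]], cap)
            ny = np.minimum(nz[ax_pos["ny"]], cap)
            corrected = raw + lgf[nb] + lgf[ny]
        else:  # xcorr
            corrected = raw
        fbins = np.floor(corrected / fw + 0.5).astype(np.int64)
        all_bins.append(fbins)
        all_weights.append(weights)
    if dropped:
        logger.warning(
            "collapse(%s): dropped weight %g from length-1 entries "
            "(no fragments exist)",
            method,
            dropped,
        )
    if not all_bins or sum(b.size for b in all_bins) == 0:
        raise ValueError("empty structured histogram")
    cat_bins = np.concatenate(all_bins)
    cat_weights = np.concatenate(all_weights)
    bins, inverse = np.unique(cat_bins, return_inverse=True)
    counts = np.bincount(inverse, weights=cat_weights)
    return FinalHistogram(method=method, bin_width=fw, bins=bins, counts=counts)


def app_histogram(
    ev: EvidenceArray,
    alphabet: Alphabet,
    enzyme: EnzymeRule,
    weighted: bool = True,
    params: ScoreParams | None = None,
    dtype=np.float64,
) -> FinalHistogram:
    """Convenience pipeline: structured DP then collapse for ``ev.method``."""
    sh = build_structured_histogram(
        ev, alphabet, ev.window, enzyme, weighted=weighted, dtype=dtype
    )
    return collapse(sh, ev.method, params=params)
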