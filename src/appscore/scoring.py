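"""Additive scoring functions: evidence arrays and per-peptide scores.

The central trick of the whole package is additivity: each scoring function
is arranged so that a peptide's raw score is a sum of *local* contributions,
one per prefix residue-mass index.  The contribution at index ``m`` is fixed
by the spectrum alone (it pools the processed intensities at the b-type
positions implied by a prefix of mass ``m`` and at the y-type positions
implied by the complementary suffix), so it can be computed once and reused
by every peptide — and by the dynamic programming over all possible
peptides.  End-stage corrections that are *not* additive (length division,
log-factorials of matched-peak counts) are deferred to the histogram
collapse, which is why the DP carries length and matched-peak counts as
internal structure.

Evidence is stored in two precisions: a high-precision float array used for
scoring database candidates, and a rounded integer array (in units of the
per-method score-bin width) used to propagate the DP histogram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import PROTON, WATER_MONO, Alphabet, MassWindow, mass_to_index
from .spectra import METHODS, ProcessedSpectrum

__all__ = [
    "SeriesEntry",
    "IonSeriesConfig",
    "ScoreParams",
    "EvidenceArray",
    "default_ion_series",
    "build_evidence",
    "score_peptide",
    "apply_correction",
    "final_bin",
    "log_factorial",
]

_CO = 27.994915
_NH3 = 17.026549
_H2O = WATER_MONO


@dataclass(frozen=True)
class SeriesEntry:
    """One theoretical fragment series considered by a scoring function."""

    name: str
    terminus: str  # "prefix" (b-type) or "suffix" (y-type)
    delta_da: float  # mass added to the fragment residue mass
    weight: float
    main: bool = False  # main series feed the Nb/Ny hit indicators
    grid_shift: int = 0  # extra integer shift (kscore flanking bins)

    def __post_init__(self) -> None:
        if self.terminus not in ("prefix", "suffix"):
            raise ValueError("terminus must be 'prefix' or 'suffix'")
        if self.weight < 0:
            raise ValueError("series weight must be non-negative")


#: method tag → tuple of SeriesEntry
IonSeriesConfig = dict


def default_ion_series(method: str) -> tuple[SeriesEntry, ...]:
    """Theoretical series per scoring function (singly charged fragments).

    raid and hyperscore use the plain b/y series.  xcorr adds the a-series
    and b/y water/ammonia losses at reduced weight.  kscore adds ±1-bin
    flanks of b/y at half weight.
    """
    b = SeriesEntry("b", "prefix", PROTON, 1.0, main=True)
    y = SeriesEntry("y", "suffix", WATER_MONO + PROTON, 1.0, main=True)
    if method in ("raid", "hyperscore"):
        return (b, y)
    if method == "xcorr":
        return (
            b,
            y,
            SeriesEntry("a", "prefix", PROTON - _CO, 0.2),
            SeriesEntry("b-H2O", "prefix", PROTON - _H2O, 0.2),
            SeriesEntry("b-NH3", "prefix", PROTON - _NH3, 0.2),
            SeriesEntry("y-H2O", "suffix", WATER_MONO + PROTON - _H2O, 0.2),
            SeriesEntry("y-NH3", "suffix", WATER_MONO + PROTON - _NH3, 0.2),
        )
    if method == "kscore":
        return (
            b,
            y,
            SeriesEntry("b+1", "prefix", PROTON, 0.5, grid_shift=1),
            SeriesEntry("b-1", "prefix", PROTON, 0.5, grid_shift=-1),
            SeriesEntry("y+1", "suffix", WATER_MONO + PROTON, 0.5, grid_shift=1),
            SeriesEntry("y-1", "suffix", WATER_MONO + PROTON, 0.5, grid_shift=-1),
        )
    raise ValueError(f"unknown method tag {method!r}")


@dataclass(frozen=True)
class ScoreParams:
    """Numerical knobs of the scoring/DP stage.

    ``score_bin_width`` sets the DP score discretization per method
    (``rounded = round(high_precision / width)``); ``final_bin_width`` sets
    the bin width of the collapsed, corrected score histogram.  The
    factorial in the hyperscore correction is evaluated at
    ``min(n, factorial_cap)``.
    """

    score_bin_width: dict = field(
        default_factory=lambda: {
            "raid": 1.0,
            "hyperscore": 4.0,
            "xcorr": 1.0,
            "kscore": 0.02,
        }
    )
    final_bin_width: dict = field(
        default_factory=lambda: {
            "raid": 0.05,
            "hyperscore": 1.0,
            "xcorr": 1.0,
            "kscore": 0.005,
        }
    )
    factorial_cap: int = 20


def log_factorial(n: int, cap: int = 20) -> float:
    """ln n! with n capped (desk-scale peptides never exceed the cap)."""
    return math.lgamma(min(int(n), cap) + 1)


@dataclass
class EvidenceArray:
    """Per-mass-index local score contributions for one method.

    Index ``m`` runs over prefix residue masses on the grid.
    ``high_precision[m]`` is the summed, weighted processed intensity at all
    theoretical fragment positions implied by a prefix of grid mass ``m``
    and the complementary suffix; ``rounded`` is the same in integer
    score-bin units.  ``b_hit``/``y_hit`` flag indices where the main b/y
    series found nonzero intensity (they accumulate into Nb/Ny).
    """

    method: str
    parent_mass: float
    window: MassWindow
    high_precision: np.ndarray
    rounded: np.ndarray
    b_hit: np.ndarray
    y_hit: np.ndarray
    score_bin_width: float

    @property
    def hi_index(self) -> int:
        return self.window.hi_index


_MAX_GRID_CAPACITY = 200_000


def build_evidence(
    ps: ProcessedSpectrum,
    window: MassWindow,
    series: tuple[SeriesEntry, ...] | None = None,
    score_bin_width: float | None = None,
    params: ScoreParams | None = None,
) -> EvidenceArray:
    """Collect local evidence at every prefix-mass index of the window.

    The y-type (suffix) positions are computed against the window's center
    parent mass; within a typical tolerance of a few Da this is exact on
    the grid.
    """
    if ps.is_null:
        raise ValueError("cannot build evidence from a null spectrum")
    if series is None:
        series = default_ion_series(ps.method)
    params = params or ScoreParams()
    if score_bin_width is None:
        score_bin_width = params.score_bin_width[ps.method]
    res = window.resolution
    hi = window.hi_index
    if hi > _MAX_GRID_CAPACITY:
        raise ValueError(f"parent window exceeds grid capacity ({hi})")
    parent_res_grid = mass_to_index(
        max(0.0, window.center_mass - WATER_MONO), res
    )
    # raid scores the *logarithm* of the matched evidence-peak intensity;
    # the other methods use the filtered intensity as is.
    if ps.method == "raid":
        transform = lambda v: math.log(v) if v > 0 else 0.0  # noqa: E731
    else:
        transform = lambda v: v  # noqa: E731
    hp = np.zeros(hi + 1, dtype=float)
    b_hit = np.zeros(hi + 1, dtype=np.uint8)
    y_hit = np.zeros(hi + 1, dtype=np.uint8)
    m = np.arange(hi + 1)
    for entry in series:
        offset = mass_to_index(abs(entry.delta_da), res)
        offset = offset if entry.delta_da >= 0 else -offset
        offset += entry.grid_shift
        if entry.terminus == "prefix":
            pos = m + offset
        else:
            pos = (parent_res_grid - m) + offset
        vals = np.zeros(hi + 1, dtype=float)
        hit = np.zeros(hi + 1, dtype=np.uint8)
        for i, p in enumerate(pos):
            v = ps.binned.get(int(p))
            if v is not None:
                vals[i] = transform(v)
                if v > 0:
                    hit[i] = 1
        hp += entry.weight * vals
        if entry.main:
            if entry.terminus == "prefix":
                b_hit |= hit
            else:
                y_hit |= hit
    rounded = np.floor(hp / score_bin_width + 0.5).astype(np.int64)
    return EvidenceArray(
        method=ps.method,
        parent_mass=window.center_mass,
        window=window,
        high_precision=hp,
        rounded=rounded,
        b_hit=b_hit,
        y_hit=y_hit,
        score_bin_width=score_bin_width,
    )


def apply_correction(
    method: str,
    raw: float,
    length: int,
    nb: int = 0,
    ny: int = 0,
    factorial_cap: int = 20,
) -> float:
    """Map a raw additive score to the method's final score.

    raid divides by the theoretical peak-list length 2(L−1); hyperscore
    adds ln Nb! + ln Ny!; kscore divides by the peptide length; xcorr is
    the identity.
    """
    if method == "raid":
        if length < 2:
            raise ZeroDivisionError("raid correction undefined for L < 2")
        return raw / (2.0 * (length - 1))
    if method == "hyperscore":
        return raw + log_factorial(nb, factorial_cap) + log_factorial(
            ny, factorial_cap
        )
    if method == "kscore":
        return raw / float(length)
    if method == "xcorr":
        return raw
    raise ValueError(f"unknown method tag {method!r}")


def final_bin(value: float, width: float) -> int:
    """Half-up binning of a corrected score (shared by DP and oracles)."""
    return int(math.floor(value / width + 0.5))


def score_peptide(
    peptide,
    ev: EvidenceArray,
    method: str | None = None,
    alphabet: Alphabet | None = None,
    rounded: bool = False,
    params: ScoreParams | None = None,
) -> float:
    """Score an individual peptide against an evidence array.

    The raw score sums evidence at the peptide's proper prefix-mass
    indices (lengths 1..L−1); the method's end correction is then applied.
    With ``rounded=True`` the raw sum uses the integer DP scale (times the
    bin width), matching the histogram arithmetic exactly.
    """
    if method is None:
        method = ev.method
    if alphabet is None:
        raise ValueError("alphabet required to compute prefix masses")
    params = params or ScoreParams()
    table = alphabet.by_token
    unknown = [t for t in peptide if t not in table]
    if unknown:
        raise KeyError(f"residues not in alphabet: {unknown}")
    L = len(peptide)
    if L < 2:
        raise ValueError("peptides shorter than 2 residues have no fragments")
    grid = ev.window
    total_grid = alphabet.peptide_grid_mass(peptide)
    if not (grid.lo_index <= total_grid <= grid.hi_index):
        raise ValueError(
            f"peptide grid mass {total_grid} outside window "
            f"[{grid.lo_index}, {grid.hi_index}]"
        )
    raw = 0.0
    nb = ny = 0
    m = 0
    for token in peptide[:-1]:
        m += table[token].grid_mass
        if rounded:
            raw += ev.rounded[m] * ev.score_bin_width
        else:
            raw += ev.high_precision[m]
        nb += int(ev.b_hit[m])
        ny += int(ev.y_hit[m])
    return apply_correction(method, raw, L, nb, ny, params.factorial_cap)
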