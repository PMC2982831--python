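"""Database search and rescoring built on the APP statistics machinery.

Search mode digests a FASTA protein database, slices the qualified
candidates for each spectrum's mass window (with the two-counter split of
correct versus incorrect N-terminal cleavage), scores every candidate at
high precision against each selected method's evidence array, reads
p-values off the DP histogram and multiplies by the qualified count, then
combines across methods.  Rescore mode does the same for a flat peptide
list, building one histogram per distinct peptide mass index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import (
    NO_ENZYME,
    TRYPSIN,
    Alphabet,
    EnzymeRule,
    MassWindow,
    build_alphabet,
)
from .combine import CombinedResult, combine_assignments, combine_db_pvalues
from .dp import FinalHistogram, app_histogram
from .scoring import ScoreParams, build_evidence, score_peptide
from .spectra import METHODS, FilterParams, RawSpectrum, preprocess
from .stats import (
    MethodSignificance,
    SignificanceAssignment,
    choose_base_frequencies,
    evalue,
    ptm_emissions,
    pvalue,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideIndex",
    "QualifiedSet",
    "SearchConfig",
    "digest_fasta",
    "digest_protein",
    "build_index",
    "qualified",
    "search_spectrum",
    "rescore_list",
    "write_results_tsv",
]

#: Table-layout display names, in output column order.
METHOD_COLUMNS = [
    ("raid", "RAId"),
    ("hyperscore", "Hyperscore"),
    ("xcorr", "XCorr"),
    ("kscore", "K-score"),
]


@dataclass
class PeptideIndex:
    """Mass-sorted digested peptides with provenance flags.

    ``grid_masses`` (sum of rounded residue masses) is the coordinate the
    DP histogram lives on; qualification slices on it so that candidate
    scoring, the qualified-peptide counters and the APP window agree
    exactly.  Sorting is by (grid mass, exact mass).
    """

    sequences: list
    masses: np.ndarray
    grid_masses: np.ndarray
    nterm_correct: np.ndarray
    miscleavages: np.ndarray
    protein_ids: list

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.grid_masses = np.asarray(self.grid_masses, dtype=np.int64)
        order = np.lexsort((self.masses, self.grid_masses))
        self.masses = self.masses[order]
        self.grid_masses = self.grid_masses[order]
        self.nterm_correct = np.asarray(self.nterm_correct, dtype=bool)[order]
        self.miscleavages = np.asarray(self.miscleavages, dtype=np.int32)[order]
        self.sequences = [self.sequences[i] for i in order]
        self.protein_ids = [self.protein_ids[i] for i in order]

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class QualifiedSet:
    """Candidates inside a mass window plus the two N-terminal counters."""

    candidates: list  # (sequence, nterm_correct, mass)
    n_correct: int
    n_all: int

    def __post_init__(self) -> None:
        if self.n_correct > self.n_all:
            raise ValueError("n_correct cannot exceed n_all")


@dataclass
class SearchConfig:
    """Configuration shared by search and rescore modes."""

    alphabet: Alphabet = field(default_factory=build_alphabet)
    enzyme: EnzymeRule = TRYPSIN
    tol_da: float = 3.0
    top_k: int = 10
    weighted: bool = True
    pvalue_floor: bool = False
    frequency_threshold: int = 1000
    max_ptms: int = 10
    filter_params: FilterParams = field(default_factory=FilterParams)
    score_params: ScoreParams = field(default_factory=ScoreParams)
    dp_dtype: type = np.float64

    @property
    def resolution(self) -> float:
        return self.alphabet.resolution


def digest_protein(
    sequence: str,
    enzyme: EnzymeRule = TRYPSIN,
    max_miscleavages: int = 0,
    min_length: int = 6,
    max_length: int = 40,
):
    """In-silico digestion of one protein sequence.

    Tryptic cleavage cuts after every K/R.  Yields
    ``(peptide, nterm_correct, miscleavages)``; with ``enzyme=none`` all
    substrings within the length bounds are produced.  Fully cleaved
    products (and their miscleaved concatenations) always start at a
    cleavage site or the protein N-terminus, so ``nterm_correct`` is true.
    """
    n = len(sequence)
    if enzyme.none_flag:
        for i in range(n):
            for L in range(min_length, max_length + 1):
                if i + L > n:
                    break
                yield sequence[i : i + L], True, 0
        return
    cut_after = enzyme.cterm_residues
    boundaries = [0]
    for i, ch in enumerate(sequence):
        if ch in cut_after and i + 1 < n:
            boundaries.append(i + 1)
    boundaries.append(n)
    fragments = [
        sequence[a:b] for a, b in zip(boundaries, boundaries[1:]) if b > a
    ]
    for i in range(len(fragments)):
        pep = ""
        for k in range(max_miscleavages + 1):
            if i + k >= len(fragments):
                break
            pep = pep + fragments[i + k]
            if min_length <= len(pep) <= max_length:
                yield pep, True, k


def digest_fasta(
    path,
    enzyme: EnzymeRule = TRYPSIN,
    max_miscleavages: int = 0,
    min_length: int = 6,
    max_length: int = 40,
    alphabet: Alphabet | None = None,
) -> PeptideIndex:
    """Digest every protein in a FASTA file into a :class:`PeptideIndex`.

    Peptides containing residues outside the alphabet (e.g. X, B, Z) are
    skipped with a debug log.
    """
    from pyteomics import fasta

    alphabet = alphabet or build_alphabet()
    entries = []
    with fasta.read(str(path)) as reader:
        for header, sequence in reader:
            pid = header.split()[0] if header else ""
            entries.append((pid, sequence.upper()))
    return build_index(
        entries, enzyme, max_miscleavages, min_length, max_length, alphabet
    )


def build_index(
    proteins,
    enzyme: EnzymeRule = TRYPSIN,
    max_miscleavages: int = 0,
    min_length: int = 6,
    max_length: int = 40,
    alphabet: Alphabet | None = None,
) -> PeptideIndex:
    """Digest an iterable of ``(protein_id, sequence)`` pairs."""
    alphabet = alphabet or build_alphabet()
    table = alphabet.by_token
    seqs, masses, grids, nterm, mis, pids = [], [], [], [], [], []
    skipped = 0
    for pid, sequence in proteins:
        for pep, ok_nterm, k in digest_protein(
            sequence, enzyme, max_miscleavages, min_length, max_length
        ):
            if any(t not in table for t in pep):
                skipped += 1
                continue
            seqs.append(pep)
            masses.append(alphabet.peptide_mass(pep))
            grids.append(alphabet.peptide_grid_mass(pep))
            nterm.append(ok_nterm)
            mis.append(k)
            pids.append(pid)
    if skipped:
        logger.debug("skipped %d peptides with non-alphabet residues", skipped)
    return PeptideIndex(
        sequences=seqs,
        masses=np.asarray(masses, dtype=float),
        grid_masses=np.asarray(grids, dtype=np.int64),
        nterm_correct=np.asarray(nterm, dtype=bool),
        miscleavages=np.asarray(mis, dtype=np.int32),
        protein_ids=pids,
    )


def qualified(idx: PeptideIndex, window: MassWindow) -> QualifiedSet:
    """Binary-search slice of the index falling inside the mass window.

    The window is realized on the residue-mass grid (the coordinate the
    APP histogram is built on), so every qualified candidate is scorable
    against the window's evidence array.
    """
    lo = int(np.searchsorted(idx.grid_masses, window.lo_index, side="left"))
    hi = int(np.searchsorted(idx.grid_masses, window.hi_index, side="right"))
    cands = [
        (idx.sequences[i], bool(idx.nterm_correct[i]), float(idx.masses[i]))
        for i in range(lo, hi)
    ]
    n_all = hi - lo
    n_correct = int(idx.nterm_correct[lo:hi].sum())
    return QualifiedSet(candidates=cands, n_correct=n_correct, n_all=n_all)


def _method_histograms(
    raw: RawSpectrum,
    window: MassWindow,
    methods,
    cfg: SearchConfig,
    alphabet: Alphabet,
):
    """Preprocess + evidence + DP histogram per method; None when null."""
    out = {}
    for method in methods:
        ps = preprocess(raw, method, cfg.filter_params, cfg.resolution)
        if ps.is_null:
            out[method] = None
            continue
        ev = build_evidence(ps, window, params=cfg.score_params)
        hist = app_histogram(
            ev,
            alphabet,
            cfg.enzyme,
            weighted=cfg.weighted,
            params=cfg.score_params,
            dtype=cfg.dp_dtype,
        )
        out[method] = (ev, hist)
    return out


def search_spectrum(
    raw: RawSpectrum,
    idx: PeptideIndex,
    methods=METHODS,
    cfg: SearchConfig | None = None,
):
    """Mode (iv): search one spectrum against a digested database.

    Returns ``(assignments, combined)`` where ``assignments`` is the
    ranked list of :class:`SignificanceAssignment` (top-k) and ``combined``
    the matching :class:`CombinedResult` list (empty when a single method
    is selected).  Candidates are scored at high precision; their p-values
    are interpolated from the DP histogram and scaled by the two-counter
    qualified-peptide count.
    """
    cfg = cfg or SearchConfig()
    methods = list(methods)
    if not methods:
        raise ValueError("select at least one method")
    window = MassWindow(raw.parent_mass, cfg.tol_da, cfg.resolution)
    qset = qualified(idx, window)
    if not qset.candidates:
        return [], []
    frequencies = choose_base_frequencies(
        [seq for seq, _, _ in qset.candidates], cfg.frequency_threshold
    )
    alphabet = _reweighted_alphabet(
        cfg.alphabet, frequencies, [s for s, _, _ in qset.candidates], cfg
    )
    per_method = _method_histograms(raw, window, methods, cfg, alphabet)
    if all(v is None for v in per_method.values()):
        logger.info("spectrum %s null under every method", raw.spectrum_id)
        return [], []

    assignments = []
    for seq, ok_nterm, _mass in qset.candidates:
        n_d = qset.n_correct if ok_nterm else qset.n_all
        per = {}
        for method in methods:
            mh = per_method[method]
            if mh is None:
                continue
            ev, hist = mh
            s = score_peptide(
                seq, ev, method, alphabet, params=cfg.score_params
            )
            p = pvalue(hist, s, floor=cfg.pvalue_floor)
            per[method] = MethodSignificance(s, p, evalue(p, n_d))
        if per:
            assignments.append(
                SignificanceAssignment(
                    peptide=tuple(seq),
                    methods=per,
                    n_qualified=n_d,
                    nterm_correct=ok_nterm,
                )
            )
    combined = []
    if len(methods) > 1:
        combined = [
            combine_assignments(
                a.peptide,
                {m: a.methods[m].e_value if m in a.methods else None
                 for m in methods},
            )
            for a in assignments
        ]
        order = sorted(
            range(len(assignments)),
            key=lambda i: (
                combined[i].combined_e,
                assignments[i].best_e(),
                assignments[i].peptide,
            ),
        )
    else:
        order = sorted(
            range(len(assignments)),
            key=lambda i: (assignments[i].best_e(), assignments[i].peptide),
        )
    order = order[: cfg.top_k]
    assignments = [assignments[i] for i in order]
    combined = [combined[i] for i in order] if combined else []
    return assignments, combined


def _reweighted_alphabet(alphabet, frequencies, candidate_seqs, cfg):
    """Fold candidate-derived (and PTM-updated) frequencies into the DP
    alphabet used for the weighted APP ensemble."""
    has_variants = any(r.is_modified for r in alphabet)
    if has_variants:
        base = {
            r.token: frequencies.get(r.token, 0.0)
            for r in alphabet
            if not r.is_modified
        }
        total = sum(base.values())
        if total <= 0:
            return alphabet
        base = {t: v / total for t, v in base.items()}
        update = ptm_emissions(candidate_seqs, base, cfg.max_ptms)
        return alphabet.with_frequencies(update.updated)
    return alphabet.with_frequencies(frequencies)


def rescore_list(
    raw: RawSpectrum,
    peptides,
    methods=METHODS,
    n_qualified: int | None = None,
    cfg: SearchConfig | None = None,
):
    """Mode (iii): reassign significance to a flat candidate list.

    Peptides are grouped by their mass index on the grid; one histogram per
    (mass index, method) is built with that index as the terminating point.
    With ``n_qualified`` given, p→E→database-P→combined E; without it the
    p-values themselves are combined.  Returns a list of
    ``(SignificanceAssignment, CombinedResult | None)`` in input order
    (duplicates rescored identically); peptides too heavy for the grid are
    skipped with a warning.
    """
    cfg = cfg or SearchConfig()
    methods = list(methods)
    if not peptides:
        raise ValueError("peptide list must be non-empty")
    alphabet = cfg.alphabet
    groups: dict[int, list] = {}
    for i, pep in enumerate(peptides):
        try:
            g = alphabet.peptide_grid_mass(pep)
        except KeyError as exc:
            raise KeyError(f"peptide {pep!r}: {exc}") from exc
        groups.setdefault(g, []).append(i)

    results: list = [None] * len(peptides)
    for g, indices in sorted(groups.items()):
        window = MassWindow.from_grid(g, g, cfg.resolution)
        try:
            per_method = _method_histograms(
                raw, window, methods, cfg, alphabet
            )
        except ValueError as exc:
            logger.warning("skipping mass index %d: %s", g, exc)
            continue
        for i in indices:
            pep = peptides[i]
            per = {}
            for method in methods:
                mh = per_method[method]
                if mh is None:
                    continue
                ev, hist = mh
                s = score_peptide(
                    pep, ev, method, alphabet, params=cfg.score_params
                )
                p = pvalue(hist, s, floor=cfg.pvalue_floor)
                e = evalue(p, n_qualified) if n_qualified is not None else 0.0
                per[method] = MethodSignificance(s, p, e)
            if not per:
                continue
            assignment = SignificanceAssignment(
                peptide=tuple(pep),
                methods=per,
                n_qualified=n_qualified or 0,
            )
            if n_qualified is not None:
                comb = combine_assignments(
                    assignment.peptide,
                    {m: per[m].e_value if m in per else None for m in methods},
                )
            elif len(methods) > 1:
                # No database scale: combine the APP p-values directly.
                pvals = {m: per[m].p_value for m in methods if m in per}
                comb = combine_assignments(assignment.peptide, {})
                comb.db_pvalues = pvals
                comb.p_product = float(np.prod(list(pvals.values())))
                comb.combined_p = combine_db_pvalues(list(pvals.values()))
                comb.combined_e = float("nan")
            else:
                comb = None
            results[i] = (assignment, comb)
    return [r for r in results if r is not None]


def write_results_tsv(path, assignments, combined=None) -> None:
    """Write the combined-output table: E_comb, per-method E columns,
    peptide — in the standard column order."""
    combined = combined or []
    comb_by_pep = {c.peptide: c for c in combined}
    with open(path, "w") as fh:
        cols = ["E_comb"] + [name for _, name in METHOD_COLUMNS] + ["Peptide"]
        fh.write("\t".join(cols) + "\n")
        for a in assignments:
            c = comb_by_pep.get(a.peptide)
            row = [f"{c.combined_e:.6g}" if c is not None else "-"]
            for tag, _name in METHOD_COLUMNS:
                ms = a.methods.get(tag)
                row.append(f"{ms.e_value:.6g}" if ms is not None else "-")
            row.append("".join(a.peptide))
            fh.write("\t".join(row) + "\n")
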