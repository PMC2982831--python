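"""Brute-force enumeration oracles, independent of the DP engine.

Every oracle here scores peptides one at a time by walking the sequence
and reading the evidence arrays directly, applying the end corrections
with its own inline arithmetic.  Kept deliberately simple (depth-first
enumeration with mass pruning) so it can serve as ground truth for the
dynamic-programming histograms on small alphabets and windows.
"""

import math
from collections import Counter


def enumerate_peptides(alphabet, window, enzyme):
    """All token sequences whose grid mass lies in the window, respecting
    the C-terminal enzyme restriction."""
    residues = list(alphabet.residues)
    lo, hi = window.lo_index, window.hi_index
    out = []

    def extend(seq, mass):
        for r in residues:
            m = mass + r.grid_mass
            if m > hi:
                continue
            if m >= lo and enzyme.allows_cterm(r):
                out.append(tuple(s.token for s in seq) + (r.token,))
            if m + alphabet.min_grid_mass <= hi:
                extend(seq + [r], m)

    extend([], 0)
    return out


def oracle_count(alphabet, window, enzyme, weighted=False):
    peptides = enumerate_peptides(alphabet, window, enzyme)
    if not weighted:
        return len(peptides)
    probs = {r.token: r.emission_probability for r in alphabet}
    return sum(math.prod(probs[t] for t in pep) for pep in peptides)


def oracle_peptide_raw(pep, alphabet, ev):
    """Rounded raw score plus matched-peak counters for one peptide."""
    grid = {r.token: r.grid_mass for r in alphabet}
    raw = 0
    nb = ny = 0
    m = 0
    for t in pep[:-1]:
        m += grid[t]
        raw += int(ev.rounded[m])
        nb += int(ev.b_hit[m])
        ny += int(ev.y_hit[m])
    return raw, nb, ny


def oracle_corrected(method, raw_scaled, length, nb, ny, cap=20):
    if method == "raid":
        return raw_scaled / (2.0 * (length - 1))
    if method == "hyperscore":
        return (
            raw_scaled
            + math.lgamma(min(nb, cap) + 1)
            + math.lgamma(min(ny, cap) + 1)
        )
    if method == "kscore":
        return raw_scaled / float(length)
    return raw_scaled


def oracle_final_histogram(
    ev, alphabet, window, enzyme, method, weighted, final_width
):
    """score_bin → weight by scoring every enumerated sequence directly.

    raid skips single-residue sequences (no fragments, correction
    undefined) — mirroring the documented collapse behaviour.
    """
    probs = {r.token: r.emission_probability for r in alphabet}
    hist = Counter()
    for pep in enumerate_peptides(alphabet, window, enzyme):
        L = len(pep)
        if method == "raid" and L < 2:
            continue
        raw, nb, ny = oracle_peptide_raw(pep, alphabet, ev)
        corrected = oracle_corrected(
            method, raw * ev.score_bin_width, L, nb, ny
        )
        b = int(math.floor(corrected / final_width + 0.5))
        w = math.prod(probs[t] for t in pep) if weighted else 1.0
        hist[b] += w
    return dict(hist)


def oracle_tail_fraction(hist: dict, score_bin: int) -> float:
    """P(final bin ≥ score_bin) from an oracle histogram."""
    total = sum(hist.values())
    tail = sum(w for b, w in hist.items() if b >= score_bin)
    return tail / total
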