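# appscore

Spectrum-specific statistical significance for tandem-MS peptide
identification, computed from **exact score histograms over all possible
peptides** (APP).

## The problem

A database-search score for a candidate peptide means nothing on its own:
the same raw score can be outstanding for one MS/MS spectrum and mediocre
for another. Spectrum-specific statistics fix this by asking, *for this
spectrum*, what fraction of random peptides would score at least as well.
Most tools answer that question by fitting a parametric model to the
database-score distribution per spectrum; `appscore` instead computes the
score distribution of **every** peptide sequence whose mass fits the
precursor window — exactly, with no model — and reads significance off the
tail.

For a spectrum σ with parent mass M and tolerance δM, let Ω be the set of
all residue sequences with mass in [M − δM, M + δM] (optionally restricted
to a tryptic C-terminus), each weighted by its emission probability
w(π) = Π_a p_a. With N(≥ s) the weighted number of members of Ω scoring at
least s,

    p(s | σ) = N(≥ s) / N_total            (APP p-value)
    E(s)     = p(s | σ) · N_D              (E-value; N_D = qualified database peptides)

The E-value is then, by construction, the expected number of false hits at
or above the score — checkable against the textbook definition by a
decoy-only search, with no calibration step.

## The dynamic programming

|Ω| is astronomically large (≈10^10 at 1078 Da ± 3 Da, see the example
below), so Ω is never enumerated. Every scoring function implemented is
*additive over prefix-mass indices* on a discretized mass grid: the local
score contribution at grid index m is fixed by the spectrum alone. The
score histogram at index m is therefore the superposition of the
histograms one residue-mass back, shifted by the local evidence score —
one backtracking pass over the grid yields the full histogram. Extra
"internal structure" axes (peptide length; matched b/y-peak counts) ride
along so that non-additive end corrections can be applied before the final
collapse.

Four additive scoring functions are provided:

| tag          | evidence per matched fragment           | end correction            |
|--------------|-----------------------------------------|---------------------------|
| `raid`       | log intensity (b, y)                    | ÷ 2(L−1)                  |
| `hyperscore` | intensity (b, y)                        | + ln N_b! + ln N_y!       |
| `xcorr`      | background-subtracted intensity (b, y, a, neutral losses) | none    |
| `kscore`     | √(unit-normalized) intensity (b, y, ±1-bin flanks)        | ÷ L     |

Each has its own spectral filter (documented approximations of the
published preprocessing, constants in `FilterParams`). Per-method
significances are combined via Poisson database P-values
P = 1 − e^(−E), the exact product-of-uniforms tail
P_comb = t · Σ_{k<m} (−ln t)^k / k! with t = Π P_i, and
E_comb = −ln(1 − P_comb).

## Worked example

Generate a small random protein database, add a target protein containing
`LGEYGFQNAK`, simulate a noisy spectrum of that peptide, and search it:

```sh
appscore simulate --seed 42 --n-proteins 40 --fasta-out db.fasta
# (append a protein containing LGEYGFQNAK, write query.mgf for it — see docs)
appscore count 1078.55 --tol-da 3 --enzyme trypsin
# 24954534051
appscore search query.mgf db.fasta --out hits.tsv
```

`count` prints the total number of tryptic-C-terminus peptide sequences
within ±3 Da of the neutral mass 1078.55 — about 2.5 × 10^10, which is why
the histogram is built by dynamic programming rather than enumeration.
`hits.tsv` (combined E-value first, then per-method E-values):

```
E_comb       RAId         Hyperscore   XCorr        K-score      Peptide
1.12337e-23  7.74002e-06  3.96557e-07  3.99529e-09  2.04165e-08  LGEYGFQNAK
0.467886     0.593903     0.302355     1.9285       0.143015     NQCEANYQR
2.8869       1.90627      1.21075      0.751648     1.45699      LSQPPGIASKK
```

The generating peptide is recovered at rank 1 with E-values far below 1
under every scoring function; the runner-up E-values sit near 1, i.e. "one
such random hit was expected anyway", which is exactly how a false hit
should read.

Other modes: `appscore histogram` writes the APP score distribution for a
spectrum (normalized-tail TSV); `appscore rescore` reassigns p/E-values to
a flat TSV peptide list; `appscore calibrate` runs the decoy-only E-value
accuracy experiment.

## Library layout

- `appscore.alphabet` — residues, PTM variants, emission probabilities, enzyme rules, mass grid
- `appscore.spectra` — MGF/mzML reading, the four spectral filters, correlation diagnostic
- `appscore.scoring` — ion series, evidence arrays, per-peptide scoring, end corrections
- `appscore.dp` — peptide counting (mode i) and structured score-histogram DP (mode ii)
- `appscore.stats` — p-values/E-values, PTM emission updates, calibration curves
- `appscore.combine` — Poisson database P-values and cross-method combination
- `appscore.search` — digestion, qualified-peptide counting, search (mode iv), rescoring (mode iii)
- `appscore.simulate` — synthetic databases/spectra and the decoy calibration experiment

See `docs/methods.md` for the model, parameter defaults, and limitations.
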