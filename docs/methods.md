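# Methods

## Model

For a query MS/MS spectrum with neutral parent mass M and tolerance δM,
the null ensemble is the set Ω of *all possible peptides*: every finite
residue sequence whose summed residue mass lies in
[M − δM − m_water, M + δM − m_water], optionally restricted to a tryptic
C-terminus (K/R as last residue — the only position at which an enzymatic
condition is expressible for sequences without protein context). Each
sequence carries weight w(π) = Π_a p_a, the product of per-residue
emission probabilities, so Ω doubles as a background model of database
composition. The p-value of a score s is the weighted fraction of Ω
scoring ≥ s; the E-value multiplies it by the number of qualified database
peptides N_D. Because Ω plays the role of the largest conceivable decoy
database, an accurate implementation needs no per-dataset calibration —
which the decoy-only experiment below verifies directly.

## Mass grid

All DP runs on an integer grid. The default width is **1.0005079 Da per
unit** rather than exactly 1 Da: peptide and fragment monoisotopic masses
carry a positive, nearly mass-proportional defect, so on a plain 1-Da grid
the rounded residue masses drift ≈ +0.05 Da per residue and long prefixes
fall off the spectrum bins of their true fragments. At 1.0005079 (the
conventional fragment-bin width of accurate-mass search tools) the
per-residue quantization error is near zero-mean, and grid scores agree
with a literal floating-point fragment scorer to r ≈ 1.0. The width is
configurable (0.1–1.0 Da supported); every component — residue grid
masses, spectral binning, window indices, ion-series offsets — derives its
integers from the same resolution. Rounding is half-up throughout.

Conventions: neutral peptide mass = Σ residue masses + 18.010565 (water);
MH⁺ adds 1.007276 (proton); fragments are singly charged. b-type
positions are prefix mass + proton; y-type are suffix mass + water +
proton; a-ions and water/ammonia losses are fixed offsets from these. I
and L share a mass but remain distinct tokens with separate
Robinson–Robinson frequencies (the DP treats them as separate
transitions, which matters only for weighted counts).

## Scoring functions and their filters

Each method scores a peptide as a sum of *local* evidence contributions
over its proper prefix-mass indices (lengths 1..L−1; the terminal index
carries no fragment), followed by an end correction:

- **raid** — evidence is the natural log of the matched processed
  intensity at b/y positions; correction divides by the theoretical
  peak-list length 2(L−1). Filter: drop peaks at/below the median raw
  intensity, rescale max → 10 000.
- **hyperscore** — evidence is the matched intensity at b/y positions;
  correction adds ln N_b! + ln N_y! (factorials capped at 20!, far above
  any desk-scale peptide length). Filter: top 50 peaks, max → 100.
- **xcorr** — evidence is the background-subtracted intensity at b/y
  (weight 1.0), a and b/y−H₂O/−NH₃ (weight 0.2); no end correction.
  Filter: bin, normalize each of 10 equal m/z windows to max 50, then
  subtract from every bin the mean over offsets ±75 (excluding 0) — the
  additive reformulation of the cross-correlation, which is what makes
  this score DP-compatible.
- **kscore** — evidence is the square root of the Euclidean-unit-
  normalized intensity at b/y (weight 1.0) and their ±1-bin flanks
  (weight 0.5); correction divides by the peptide length L (our declared
  form of the method's length normalization).

All filter constants are config-exposed (`FilterParams`) and documented as
approximations in the spirit of the published methods, not vendor
replicas; program-specific unpublished heuristics are deliberately
omitted. A spectrum retaining fewer than 5 nonzero bins after filtering is
declared null and excluded.

## Dynamic programming

Evidence is stored twice: high-precision floats (used to score database
candidates) and integers on a per-method score-bin width
(raid 1.0 — natural log units; xcorr 1.0; hyperscore 4.0; kscore 0.02).
The per-method widths generalize plain integer rounding because kscore
evidence lives in [0, 1] (integer rounding would destroy it) and
hyperscore evidence spans 0–100 per index (integer bins would waste a
10× larger DP array for no statistical gain). Candidate p-values are
interpolated from the histogram at the high-precision score, so the
discretization touches only the histogram, where rounding errors largely
cancel.

The DP table at mass index m is a dense array over
(score bin × structure axes); it equals the residue-superposition of the
tables at m − mass(a), shifted by the rounded local evidence at m, with
length incremented and the b/y matched-peak counters incremented by the
hit indicators at m, scaled by p_a when weighted. Terminal transitions
into the parent window add no evidence and respect the enzyme's C-terminal
restriction. Structure axes per method: length for raid/kscore, (N_b, N_y)
for hyperscore, none for xcorr. Score-axis capacity is bounded by the sum
of the largest ⌊window/57⌋ positive (and most negative) rounded evidence
values — any path's cumulative score must lie inside. Tables older than
the heaviest residue are freed, so memory is O(186 × table size).

Collapse applies the end correction to each structured entry, re-bins the
corrected score (final bin widths: raid 0.05, hyperscore 1.0, xcorr 1.0,
kscore 0.005) and sums over window indices. Length-1 entries are dropped
only for raid (its correction divides by 2(L−1) = 0); they have no
fragments and never arise above 186 Da anyway. Pure counting (mode i)
uses the same recurrence with the score suppressed, in exact integer
arithmetic when unweighted.

Correctness is anchored by brute force: for small alphabets the DP
histogram is asserted *identical* to scoring every enumerated sequence
individually (exact on unweighted counts, 1e−9 relative on weighted ones,
which differ only by float summation order), and Σ histogram counts must
equal the mode-(i) count on randomized windows.

## Statistics

The p-value of a score is the histogram tail N(≥s)/N_total; between
populated bin centers the tail is interpolated **log-linearly** (score
tails are near-exponential, so linear interpolation on log-tail is the
low-bias choice). Scores beyond the best bin clamp to the smallest
positive tail, or to 1/N_total when the conservative floor option is on
(default off in search mode, on in rescoring mode). E = p · N_D with the
two-counter rule: candidates with a correct N-terminal cleavage use the
count of correct-N-terminal qualified peptides, others the count of all
qualified peptides. Qualification slices the mass-sorted peptide index on
the same grid coordinate the histogram lives on, so every qualified
candidate is scorable and the window semantics are self-consistent.

PTM-aware backgrounds: for each parent residue a with n_a unmodified and
m_{a→b} modified occurrences in the qualified list, the parent's
probability is split as p_a(n_a+1)/((n_a+1)+Σm) for the unmodified form
and p_a·m_{a→b}/((n_a+1)+Σm) per variant — one pseudocount to the
unmodified form, so no observations means no change. At most the ten most
abundant variants are retained (rare-variant weights are statistically
negligible, and each variant multiplies DP transitions by (20+q)/20).
Base frequencies are Robinson–Robinson when the qualified list holds fewer
than 1000 residues (config-exposed), else counted from the list itself —
the parent-mass- and database-specific background.

Combination across methods uses the Poisson database P-value
P = 1 − e^(−E) per method (P = 1 for methods that did not report the
peptide), the exact tail of a product of m independent uniforms
(evaluated in log space), and E_comb = −ln(1 − P_comb), clamped one ulp
below P_comb = 1 so the inversion stays finite. Method correlation is
knowingly ignored (the combination assumes independence); combining can
legitimately *increase* a p-value (e.g. [0.5, 1.0] → 0.847).

## Synthetic data

The generator stands in for real spectral datasets. Random databases are
i.i.d. Robinson–Robinson proteins (Poisson lengths, default mean 300).
Synthetic spectra emit each singly-charged b/y fragment with detection
probability 0.8, lognormal intensity (μ = ln 100, σ = 1), optional m/z
jitter, plus 20 uniform noise peaks — plausible MS2 texture. It does
**not** model fragmentation chemistry (mobile proton, loss propensities,
multiply charged fragments), isotope envelopes, or profile peaks; passing
tests therefore demonstrate the statistical machinery, not retrieval
performance on real instruments. The calibration property, however, is
noise-model-free by construction: E-value accuracy must hold for *any*
spectrum content, which is exactly what the decoy experiment probes.

The decoy calibration experiment builds a ~10^5-peptide random database
(2400 proteins, 1 miscleavage, lengths 6–40), generates 200 spectra from
random tryptic peptides verified absent from the database, searches each
with all four methods keeping every candidate, and compares the pooled
false-positive counts per spectrum against the E-value cutoff. At these
conditions each method tracks the diagonal well within the factor-of-five
band over E ∈ [0.01, 10] (worst observed ratio ≈ 2.5). The problem sizes
(200 spectra, 10^5 peptides, windows ≤ 800 Da for enumeration oracles)
were chosen as the smallest scales at which the claims are statistically
resolvable on a desktop run. The experiment's DP uses float32 tables
(p-values need far less than single precision); all exactness tests use
float64.

## Numerical choices and degenerate inputs

- Rounding is half-up everywhere a mass meets the grid (deterministic,
  monotone); score binning is half-up of value/width.
- Frequencies are renormalized to Σ = 1 on construction; emission updates
  conserve probability to 1e−12 by construction and are renormalized
  defensively.
- Spectra with no positive-intensity peaks, or too few bins after
  filtering, become null; a search where every method nulls returns an
  empty result with a logged reason.
- Windows below the lightest residue count zero peptides (not an error);
  enzyme-restricted windows with no reachable composition yield an empty
  histogram, which `collapse` rejects — callers check `per_index` first.
- Ranking ties break by (combined E, best single-method E, lexicographic
  sequence); output formatting is fixed-precision so identical inputs give
  byte-identical files.
- Missing precursor charge defaults to 2+ (logged), the most common
  tryptic charge state.
- Trypsin cuts after every K/R with no proline exception; semi-specific
  C-termini are not generated. Digestion length bounds default to 6–40.

## Known limitations

- Fragment matching is single-bin at the working resolution; there is no
  ppm-denominated fragment tolerance (precursor ppm tolerances are
  converted to Da upstream).
- The hyperscore/xcorr/kscore analogues capture the published functional
  forms, not the vendors' numeric scales; scores are comparable within a
  method, not across implementations.
- Combination assumes inter-method independence; correlated methods make
  combined E-values conservative-to-optimistic in ways this package does
  not correct.
- Mode (iii) ingests flat TSV peptide lists only (no vendor output-file
  parsers).
- Protein-level inference, FDR via decoy concatenation, and non-additive
  scoring functions are out of scope.
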