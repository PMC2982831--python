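"""Synthetic databases and spectra for end-to-end, download-free testing.

The generator emulates the study design used to check E-value accuracy:
random protein databases (i.i.d. residues under a chosen background
frequency), noisy b/y-ion spectra of known peptides, and the decoy-only
calibration experiment in which the query peptides are guaranteed absent
from the database so every reported hit is a false positive.  It emulates
peak texture (detection dropout, lognormal intensities, m/z jitter,
uniform noise peaks), not fragmentation chemistry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    PROTON,
    ROBINSON_ROBINSON,
    WATER_MONO,
    Alphabet,
    build_alphabet,
)
from .search import PeptideIndex, SearchConfig, build_index, search_spectrum
from .spectra import METHODS, RawSpectrum
from .stats import calibration_curve

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumSimConfig",
    "random_database",
    "random_tryptic_peptide",
    "synthetic_spectrum",
    "decoy_calibration_experiment",
    "write_fasta",
    "write_mgf",
]


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Noise model of the synthetic fragment spectra."""

    seed: int = 0
    fragment_detection_prob: float = 0.8
    intensity_log_mean: float = float(np.log(100.0))
    intensity_log_sd: float = 1.0
    noise_peaks: int = 20
    mz_jitter_sd: float = 0.0
    charge: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.fragment_detection_prob <= 1.0:
            raise ValueError("detection probability outside [0, 1]")
        if self.mz_jitter_sd < 0:
            raise ValueError("jitter SD must be non-negative")


def random_database(
    seed: int | np.random.Generator,
    n_proteins: int,
    mean_length: float = 300.0,
    frequencies: dict[str, float] | None = None,
) -> list[tuple[str, str]]:
    """Random proteins with i.i.d. residues; reproducible under the seed.

    Protein lengths are Poisson around ``mean_length`` (min 20).  Returns
    ``(protein_id, sequence)`` pairs ready for digestion or FASTA export.
    """
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    frequencies = frequencies or ROBINSON_ROBINSON
    tokens = sorted(frequencies)
    probs = np.array([frequencies[t] for t in tokens], dtype=float)
    probs = probs / probs.sum()
    proteins = []
    for i in range(n_proteins):
        length = max(20, int(rng.poisson(mean_length)))
        seq = "".join(rng.choice(tokens, size=length, p=probs))
        proteins.append((f"synthetic|P{i:06d}", seq))
    return proteins


def random_tryptic_peptide(
    rng: np.random.Generator,
    min_length: int = 7,
    max_length: int = 10,
    frequencies: dict[str, float] | None = None,
) -> str:
    """A random tryptic-looking peptide: i.i.d. interior, K/R C-terminus."""
    frequencies = frequencies or ROBINSON_ROBINSON
    interior = {t: f for t, f in frequencies.items() if t not in ("K", "R")}
    tokens = sorted(interior)
    probs = np.array([interior[t] for t in tokens])
    probs = probs / probs.sum()
    length = int(rng.integers(min_length, max_length + 1))
    body = "".join(rng.choice(tokens, size=length - 1, p=probs))
    tail = "K" if rng.random() < 0.5 else "R"
    return body + tail


def synthetic_spectrum(
    peptide: str,
    cfg: SpectrumSimConfig,
    alphabet: Alphabet | None = None,
    rng: np.random.Generator | None = None,
    spectrum_id: str | None = None,
) -> RawSpectrum:
    """Noisy b/y fragment spectrum of a known peptide.

    Every b_i / y_i (singly charged) is emitted with the configured
    detection probability, lognormal intensity and Gaussian m/z jitter;
    ``noise_peaks`` uniform random peaks are added over the fragment m/z
    range.  In the noiseless limit (detection 1, no noise, no jitter) the
    spectrum holds exactly 2(L−1) theoretical peaks.
    """
    if len(peptide) < 2:
        raise ValueError("peptide must have at least 2 residues")
    alphabet = alphabet or build_alphabet()
    rng = rng or np.random.default_rng(cfg.seed)
    masses = [alphabet.mass(t) for t in peptide]
    total = sum(masses)
    peaks = []

    def emit(mz: float) -> None:
        if rng.random() >= cfg.fragment_detection_prob:
            return
        intensity = float(
            rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd)
        )
        if cfg.mz_jitter_sd > 0:
            mz = mz + rng.normal(0.0, cfg.mz_jitter_sd)
        peaks.append((mz, intensity))

    prefix = 0.0
    for m in masses[:-1]:
        prefix += m
        emit(prefix + PROTON)  # b ion
        emit((total - prefix) + WATER_MONO + PROTON)  # y ion
    mz_hi = total + WATER_MONO + PROTON
    for _ in range(cfg.noise_peaks):
        mz = float(rng.uniform(100.0, mz_hi))
        intensity = float(
            rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd)
        )
        peaks.append((mz, intensity))
    neutral = total + WATER_MONO
    z = cfg.charge
    return RawSpectrum(
        spectrum_id=spectrum_id or f"synthetic_{peptide}",
        precursor_mz=(neutral + z * PROTON) / z,
        precursor_charge=z,
        peaks=tuple(sorted(peaks)),
    )


def decoy_calibration_experiment(
    n_spectra: int = 200,
    n_proteins: int = 2400,
    mean_protein_length: float = 300.0,
    cfg: SpectrumSimConfig | None = None,
    seed: int = 0,
    search_cfg: SearchConfig | None = None,
    methods=METHODS,
    cutoffs=None,
    max_miscleavages: int = 1,
    index: PeptideIndex | None = None,
):
    """Decoy-only E-value accuracy experiment.

    Builds a random database, generates spectra from random tryptic
    peptides verified absent from the database (every hit is therefore a
    false positive), searches each spectrum, and accumulates per-method
    calibration curves (mean false positives at each E cutoff).

    Returns ``(curves, evalues, n_db_peptides)`` where ``curves`` maps
    method → list of (cutoff, mean FP) and ``evalues`` maps method → list
    of all false-positive E-values.
    """
    cfg = cfg or SpectrumSimConfig(seed=seed)
    search_cfg = search_cfg or SearchConfig(dp_dtype=np.float32)
    if cutoffs is None:
        cutoffs = list(np.logspace(-2, 1, 7))
    rng = np.random.default_rng(seed)
    if index is None:
        proteins = random_database(rng, n_proteins, mean_protein_length)
        index = build_index(
            proteins, search_cfg.enzyme, max_miscleavages=max_miscleavages
        )
    db_sequences = set(index.sequences)
    evalues: dict[str, list[float]] = {m: [] for m in methods}
    made = 0
    while made < n_spectra:
        pep = random_tryptic_peptide(rng)
        if pep in db_sequences:
            continue
        spectrum = synthetic_spectrum(
            pep, cfg, search_cfg.alphabet, rng, spectrum_id=f"decoy_{made}"
        )
        big = SearchConfig(
            alphabet=search_cfg.alphabet,
            enzyme=search_cfg.enzyme,
            tol_da=search_cfg.tol_da,
            top_k=10**9,  # keep every false positive, not just the top-k
            weighted=search_cfg.weighted,
            pvalue_floor=search_cfg.pvalue_floor,
            frequency_threshold=search_cfg.frequency_threshold,
            filter_params=search_cfg.filter_params,
            score_params=search_cfg.score_params,
            dp_dtype=search_cfg.dp_dtype,
        )
        assignments, _ = search_spectrum(spectrum, index, methods, big)
        for a in assignments:
            for m, ms in a.methods.items():
                evalues[m].append(ms.e_value)
        made += 1
    curves = {
        m: calibration_curve(evalues[m], n_spectra, cutoffs)
        for m in methods
    }
    return curves, evalues, len(index)


def write_fasta(path, proteins) -> None:
    with open(path, "w") as fh:
        for pid, seq in proteins:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_mgf(path, spectra) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.5f} {inten:.4f}\n")
            fh.write("END IONS\n")
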