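"""DP engine: counting, structured histograms, collapse, conservation."""

import math

import numpy as np
import pytest

from appscore import (
    METHODS,
    MassWindow,
    NO_ENZYME,
    TRYPSIN,
    build_alphabet,
    build_structured_histogram,
    collapse,
    count_peptides,
)
from appscore.scoring import EvidenceArray, ScoreParams
from helpers_oracle import oracle_count, oracle_final_histogram


def _zero_evidence(window, method="raid", bw=1.0):
    hi = window.hi_index
    z = np.zeros(hi + 1)
    return EvidenceArray(
        method, window.center_mass, window,
        z, z.astype(np.int64),
        np.zeros(hi + 1, dtype=np.uint8), np.zeros(hi + 1, dtype=np.uint8),
        bw,
    )


def _evidence_with(window, rounded_map, method="xcorr", hits=None, bw=1.0):
    hi = window.hi_index
    r = np.zeros(hi + 1, dtype=np.int64)
    for k, v in rounded_map.items():
        r[k] = v
    b = np.zeros(hi + 1, dtype=np.uint8)
    y = np.zeros(hi + 1, dtype=np.uint8)
    for k, (hb, hy) in (hits or {}).items():
        b[k], y[k] = hb, hy
    return EvidenceArray(
        method, window.center_mass, window,
        r.astype(float) * bw, r, b, y, bw,
    )


class TestCountPeptides:
    def test_ga_analytic_values(self, ga_alphabet):
        w128 = MassWindow.from_grid(128, 128)
        assert count_peptides(ga_alphabet, w128, NO_ENZYME, False) == 2
        w114 = MassWindow.from_grid(114, 114)
        assert count_peptides(ga_alphabet, w114, NO_ENZYME, False) == 1
        assert count_peptides(
            ga_alphabet, w128, NO_ENZYME, True
        ) == pytest.approx(0.5)

    def test_unreachable_window_is_zero(self, ga_alphabet):
        w = MassWindow.from_grid(10, 20)
        assert count_peptides(ga_alphabet, w, NO_ENZYME, False) == 0

    def test_enzyme_restriction(self, small_alphabet):
        w = MassWindow.from_grid(250, 400)
        n_all = count_peptides(small_alphabet, w, NO_ENZYME, False)
        n_tryp = count_peptides(small_alphabet, w, TRYPSIN, False)
        assert 0 < n_tryp < n_all

    @pytest.mark.parametrize("enzyme", [NO_ENZYME, TRYPSIN])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_enumeration(self, small_alphabet, enzyme, weighted):
        w = MassWindow.from_grid(280, 300)
        got = count_peptides(small_alphabet, w, enzyme, weighted)
        want = oracle_count(small_alphabet, w, enzyme, weighted)
        if weighted:
            assert got == pytest.approx(want, rel=1e-12)
        else:
            assert got == want

    def test_single_residue_peptides_counted(self, ga_alphabet):
        w = MassWindow.from_grid(57, 57)
        assert count_peptides(ga_alphabet, w, NO_ENZYME, False) == 1


class TestStructuredHistogram:
    def test_zero_evidence_all_mass_at_score_zero(self, ga_alphabet):
        w = MassWindow.from_grid(128, 128)
        sh = build_structured_histogram(
            _zero_evidence(w), ga_alphabet, w, NO_ENZYME, ("length",), False
        )
        assert dict(sh.entries()) == {(0, 2): 2.0}

    def test_single_evidence_index_splits_histogram(self, ga_alphabet):
        w = MassWindow.from_grid(128, 128)
        ev = _evidence_with(w, {57: 3})
        sh = build_structured_histogram(
            ev, ga_alphabet, w, NO_ENZYME, (), False
        )
        # GA takes prefix G (index 57, score 3); AG takes prefix A (score 0)
        assert dict(sh.entries()) == {(3,): 1.0, (0,): 1.0}

    def test_missing_axis_indicators_rejected(self, ga_alphabet):
        w = MassWindow.from_grid(128, 128)
        ev = _zero_evidence(w)
        ev.b_hit = None
        with pytest.raises(ValueError, match="nb"):
            build_structured_histogram(
                ev, ga_alphabet, w, NO_ENZYME, ("nb",), False
            )

    def test_weighted_counts_scale_with_emission(self, ga_alphabet):
        w = MassWindow.from_grid(128, 128)
        sh = build_structured_histogram(
            _zero_evidence(w), ga_alphabet, w, NO_ENZYME, ("length",), True
        )
        assert dict(sh.entries()) == {(0, 2): pytest.approx(0.5)}

    def test_ptm_variants_multiply_transitions(self):
        """Adding q PTM variants scales trace-backs per index by (n+q)/n."""
        base = build_alphabet(
            {"G": 57.02146, "A": 71.03711}, {"G": 0.5, "A": 0.5}
        )
        ptm = build_alphabet(
            {"G": 57.02146, "A": 71.03711, "A+16": 87.03202},
            {"G": 0.4, "A": 0.4, "A+16": 0.2},
            parents={"A+16": "A"},
        )
        w = MassWindow.from_grid(400, 410)
        sh2 = build_structured_histogram(
            _zero_evidence(w), base, w, NO_ENZYME, (), False
        )
        sh3 = build_structured_histogram(
            _zero_evidence(w), ptm, w, NO_ENZYME, (), False
        )
        assert sh3.transition_ops / sh2.transition_ops == pytest.approx(
            3 / 2, rel=0.05
        )


class TestCollapse:
    def test_xcorr_identity(self, ga_alphabet):
        w = MassWindow.from_grid(128, 128)
        ev = _evidence_with(w, {57: 3}, method="xcorr")
        sh = build_structured_histogram(ev, ga_alphabet, w, NO_ENZYME, (), False)
        fh = collapse(sh, "xcorr")
        assert dict(zip(fh.bins, fh.counts)) == {0: 1.0, 3: 1.0}

    def test_raid_constant_length_halves_scores(self, ga_alphabet):
        # all window peptides have length 2: final = raw/2 at width 0.05
        w = MassWindow.from_grid(128, 128)
        ev = _evidence_with(w, {57: 3, 71: 2}, method="raid")
        sh = build_structured_histogram(
            ev, ga_alphabet, w, NO_ENZYME, ("length",), False
        )
        fh = collapse(sh, "raid")
        got = {b * fh.bin_width: c for b, c in zip(fh.bins, fh.counts)}
        assert got == {1.5: 1.0, 1.0: 1.0}  # GA: 3/2, AG: 2/2

    def test_hyperscore_log_factorial_shift(self, ga_alphabet):
        w = MassWindow.from_grid(185, 185)  # GGA/GAG/AGG compositions
        # raw evidence zero but b/y hits at 57 and 114 → nb/ny counted
        ev = _evidence_with(
            w, {}, method="hyperscore", hits={57: (1, 0), 114: (1, 1)}, bw=4.0
        )
        sh = build_structured_histogram(
            ev, ga_alphabet, w, NO_ENZYME, ("nb", "ny"), False
        )
        fh = collapse(sh, "hyperscore")
        want = oracle_final_histogram(
            ev, ga_alphabet, w, NO_ENZYME, "hyperscore", False, 1.0
        )
        assert dict(zip((int(b) for b in fh.bins), fh.counts)) == want
        # GGA traverses 57 and 114: Nb=2, Ny=1 → shift ln2! + ln1! ≈ 0.69 → bin 1
        assert 1 in want

    def test_raid_drops_single_residue_entries(self, ga_alphabet, caplog):
        w = MassWindow.from_grid(57, 130)
        sh = build_structured_histogram(
            _zero_evidence(w), ga_alphabet, w, NO_ENZYME, ("length",), False
        )
        with caplog.at_level("WARNING"):
            fh = collapse(sh, "raid")
        # G and A (length 1) dropped; GG, GA, AG survive at score 0
        assert fh.total_weight == 3.0
        assert any("length-1" in r.message for r in caplog.records)

    def test_final_tail_monotone(self, small_alphabet, evidence_for):
        for method in METHODS:
            ev = evidence_for(method)
            sh = build_structured_histogram(
                ev, small_alphabet, ev.window, NO_ENZYME, weighted=True
            )
            fh = collapse(sh, method)
            tail = fh.tail()
            assert np.all(np.diff(tail) <= 1e-12)
            assert tail[0] == pytest.approx(fh.total_weight)


class TestOracleEquivalence:
    """DP histogram equals brute-force enumeration on small instances."""

    @pytest.mark.parametrize("method", METHODS)
    @pytest.mark.parametrize("weighted", [False, True])
    def test_small_window_all_methods(
        self, small_alphabet, evidence_for, method, weighted
    ):
        params = ScoreParams()
        ev = evidence_for(method)
        for enzyme in (NO_ENZYME, TRYPSIN):
            sh = build_structured_histogram(
                ev, small_alphabet, ev.window, enzyme, weighted=weighted
            )
            fh = collapse(sh, method, params)
            got = dict(zip((int(b) for b in fh.bins), fh.counts))
            want = oracle_final_histogram(
                ev,
                small_alphabet,
                ev.window,
                enzyme,
                method,
                weighted,
                params.final_bin_width[method],
            )
            assert set(got) == set(want)
            for k, v in want.items():
                if weighted:
                    assert got[k] == pytest.approx(v, rel=1e-9)
                else:
                    assert got[k] == v


class TestConservation:
    @pytest.mark.parametrize("weighted", [False, True])
    def test_total_weight_equals_count(
        self, small_alphabet, evidence_for, weighted
    ):
        for method in METHODS:
            ev = evidence_for(method)
            for enzyme in (NO_ENZYME, TRYPSIN):
                sh = build_structured_histogram(
                    ev, small_alphabet, ev.window, enzyme, weighted=weighted
                )
                fh = collapse(sh, method)
                want = count_peptides(
                    small_alphabet, ev.window, enzyme, weighted
                )
                if weighted:
                    assert fh.total_weight == pytest.approx(want, rel=1e-9)
                else:
                    assert fh.total_weight == want
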