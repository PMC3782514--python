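"""Alignment, K2P distance and NG86 Ka/Ks."""

from __future__ import annotations

import math
from itertools import permutations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntevol.molevol import (
    CODON_TO_AA,
    STOP_CODONS,
    CodonAlignment,
    PairwiseAlignment,
    SaturationError,
    build_codon_alignment,
    global_align,
    k2p_distance,
    ng86_kaks,
    noncoding_rate,
    synonymous_site_fraction,
)

SENSE = sorted(set(CODON_TO_AA) - STOP_CODONS)


class TestPairwiseAlignment:
    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError, match="equal length"):
            PairwiseAlignment("ACGT", "ACG")

    def test_rejects_all_gap_columns(self):
        with pytest.raises(ValueError, match="ungapped"):
            PairwiseAlignment("AC--", "--GT")

    def test_identity_skips_gaps_and_n(self):
        aln = PairwiseAlignment("ACG-N", "ACT-A")
        # usable columns: A/A, C/C, G/T; the gap and N columns are skipped
        assert aln.identity() == pytest.approx(2 / 3)


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.seq_a == aln.seq_b == "ACGTACGT"
        assert aln.identity() == 1.0

    def test_single_deletion(self):
        aln = global_align("ACGT", "AGT")
        assert aln.seq_a == "ACGT"
        assert aln.seq_b.count("-") == 1
        assert aln.seq_b.replace("-", "") == "AGT"

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError, match="empty"):
            global_align("", "ACGT")

    def test_size_guard(self):
        with pytest.raises(ValueError, match="100 kb"):
            global_align("A" * 100_001, "ACGT")


class TestK2P:
    def test_zero_distance(self):
        est = k2p_distance(PairwiseAlignment("ACGT" * 25, "ACGT" * 25))
        assert est.K == 0.0
        assert est.n_sites == 100

    def test_closed_form_on_constructed_counts(self):
        # 100 sites: 10 transitions (A->G), 10 transversions (A->C)
        a = "A" * 100
        b = "G" * 10 + "C" * 10 + "A" * 80
        est = k2p_distance(PairwiseAlignment(a, b))
        P, Q = 0.10, 0.10
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert est.P == pytest.approx(P)
        assert est.Q == pytest.approx(Q)
        assert est.K == pytest.approx(expected)

    def test_gap_and_n_columns_excluded(self):
        est = k2p_distance(PairwiseAlignment("ACG-N", "ACT-A"))
        assert est.n_sites == 3

    def test_saturation_raises(self):
        # P = 0.5, Q = 0.25 puts 1 - 2P - Q below zero
        a = "A" * 100
        b = "G" * 50 + "C" * 25 + "A" * 25
        with pytest.raises(SaturationError):
            k2p_distance(PairwiseAlignment(a, b))

    def test_no_usable_columns(self):
        with pytest.raises(ValueError, match="usable"):
            k2p_distance(PairwiseAlignment("NNN", "ACG"))

    @given(
        n_ts=st.integers(0, 15),
        n_tv=st.integers(0, 15),
    )
    @settings(max_examples=50, deadline=None)
    def test_k_at_least_p_distance(self, n_ts, n_tv):
        """The multiple-hit correction can only increase the distance."""
        n = 200
        a = "A" * n
        b = "G" * n_ts + "C" * n_tv + "A" * (n - n_ts - n_tv)
        est = k2p_distance(PairwiseAlignment(a, b))
        p_dist = (n_ts + n_tv) / n
        assert est.K >= p_dist - 1e-12


class TestCodonAlignment:
    def test_rejects_internal_stop(self):
        with pytest.raises(ValueError, match="codon index 1"):
            CodonAlignment(("ATG", "TAA", "AAA"), ("ATG", "AAA", "AAA"))

    def test_rejects_non_triplets(self):
        with pytest.raises(ValueError):
            CodonAlignment(("ATGA",), ("ATG",))

    def test_build_strips_terminal_stop(self):
        ca = build_codon_alignment("ATGAAATGA", "ATGAAATAA")
        assert ca.n_codons == 2
        assert ca.codons_a == ("ATG", "AAA")

    def test_build_drops_gapped_codon_columns(self):
        # b is missing the middle codon; the protein alignment gaps it out
        a = "ATG" + "TGG" * 6 + "CCC" * 6 + "AAA"
        b = "ATG" + "TGG" * 6 + "CCC" * 5 + "AAA"
        ca = build_codon_alignment(a, b)
        assert ca.n_codons == 13
        assert ca.codons_a == ca.codons_b  # remaining columns are identical

    def test_build_internal_stop_reports_index(self):
        with pytest.raises(ValueError, match="CDS a at codon index 2"):
            build_codon_alignment("ATGAAATAGAAA", "ATGAAAAAGAAA")

    def test_build_length_not_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            build_codon_alignment("ATGA", "ATG")


class TestSiteCounting:
    def test_hand_example(self):
        # TTT (Phe): third position has 1 synonymous change of 3 -> 1/3
        # GCT (Ala): third position fully synonymous -> 1
        # AAA (Lys): AAA->AAG is synonymous -> 1/3; total 5/3
        s = sum(synonymous_site_fraction(c) for c in ("TTT", "GCT", "AAA"))
        assert s == pytest.approx(5 / 3)

    def test_sites_sum_to_three_per_codon(self):
        cols = tuple(SENSE[:12])
        res = ng86_kaks(CodonAlignment(cols, cols))
        assert res.S + res.N == pytest.approx(36.0)

    def test_stop_changes_count_nonsynonymous(self):
        # TGG (Trp): every single change is nonsynonymous or a stop -> S = 0
        assert synonymous_site_fraction("TGG") == 0.0


def _brute_force_pathways(ca: str, cb: str) -> tuple[float, float]:
    """Independent enumeration of NG86 pathway averaging."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur, sd, nd = ca, 0.0, 0.0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            sd += CODON_TO_AA[cur] == CODON_TO_AA[nxt]
            nd += CODON_TO_AA[cur] != CODON_TO_AA[nxt]
            cur = nxt
        return sd, nd

    paths = [w for o in permutations(diff) if (w := walk(o, False)) is not None]
    if not paths:
        paths = [walk(o, True) for o in permutations(diff)]
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


class TestNG86:
    def test_identical_codons_zero(self):
        ca = CodonAlignment(tuple(SENSE[:20]), tuple(SENSE[:20]))
        res = ng86_kaks(ca)
        assert res.Sd == res.Nd == 0.0
        assert res.Ks == res.Ka == 0.0
        assert res.omega is None

    def test_single_synonymous_difference(self):
        cols_a = ("GCT",) + tuple(SENSE[:19])
        cols_b = ("GCC",) + tuple(SENSE[:19])
        res = ng86_kaks(CodonAlignment(cols_a, cols_b))
        assert res.Sd == 1.0
        assert res.Nd == 0.0
        assert res.Ka == 0.0
        assert res.Ks > 0.0

    def test_pathway_averaging_matches_brute_force(self, rng):
        from syntevol.molevol import _pathway_counts

        idx = rng.integers(0, len(SENSE), size=(300, 2))
        for i, j in idx:
            ca, cb = SENSE[i], SENSE[j]
            assert _pathway_counts(ca, cb) == pytest.approx(
                _brute_force_pathways(ca, cb)
            ), (ca, cb)

    def test_concatenation_invariance(self, rng):
        # mostly identical codons plus a few differing pairs keeps the
        # proportions inside the Jukes-Cantor invertible range
        idx = rng.integers(0, len(SENSE), size=60)
        cols_a = tuple(SENSE[i] for i in idx)
        cols_b = ("GCC", "AAG", "TGT") + cols_a[3:]
        r1 = ng86_kaks(CodonAlignment(cols_a, cols_b))
        r2 = ng86_kaks(CodonAlignment(cols_a * 2, cols_b * 2))
        for attr in ("ps", "pn", "Ks", "Ka"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr))

    def test_ka_is_exact_zero_when_no_nonsynonymous_changes(self):
        cols_a = ("GCT",) + tuple(SENSE[:19])
        cols_b = ("GCC",) + tuple(SENSE[:19])
        res = ng86_kaks(CodonAlignment(cols_a, cols_b))
        assert res.Ka == 0.0 and not math.copysign(1, res.Ka) < 0  # not -0.0

    def test_short_alignment_warns(self):
        cols = ("GCT", "AAA", "TTT", "GGG", "CCC")
        with pytest.warns(UserWarning, match="noisy"):
            ng86_kaks(CodonAlignment(cols, ("GCC",) + cols[1:]))


class TestNoncodingRate:
    def test_equals_k2p(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        aln = PairwiseAlignment(a, b)
        assert noncoding_rate(aln) == k2p_distance(aln).K
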