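"""Conversion-tract lengths and classification, junction microhomology and
TMEJ signature scoring, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest

from meiorepair.assay import Window
from meiorepair.freqstats import compare_groups
from meiorepair.simulate import gen_junctions
from meiorepair.tracts import (
    CONVERTED,
    DEFAULT_LADDER,
    HETERODUPLEX,
    UNCONVERTED,
    UNREADABLE,
    ConversionTract,
    MutationEvent,
    PolymorphismLadder,
    classify_co,
    classify_mutation,
    classify_nco,
    has_heteroduplex,
    junction_microhomology,
    load_tract_table,
    tract_lengths,
    tract_summary,
    write_tract_table,
)

LADDER5 = PolymorphismLadder((12, 100, 209, 350, 567))


def make_tract(converted_positions, ladder=LADDER5, cls="NCO",
               window=Window.T22_34, het_positions=()):
    calls = []
    for p in ladder.positions:
        if p in het_positions:
            calls.append(HETERODUPLEX)
        elif p in converted_positions:
            calls.append(CONVERTED)
        else:
            calls.append(UNCONVERTED)
    return ConversionTract(cls, window, tuple(calls))


def min_bp_oracle(calls, positions):
    """Scan all pairs of converted/heteroduplex indices for the extremes."""
    conv = [p for p, c in zip(positions, calls) if c in (CONVERTED, HETERODUPLEX)]
    if not conv:
        return None
    return max(b - a for a in conv for b in conv) + 1


class TestTractLengths:
    def test_single_site_at_12_is_1bp(self):
        # a tract converted only at the most proximal (12 bp) polymorphism
        # has minimum length 1 bp
        assert tract_lengths(make_tract({12}), LADDER5).min_bp == 1

    def test_proximal_to_distal_distance(self):
        assert tract_lengths(make_tract({12, 209}), LADDER5).min_bp == 198

    def test_max_extends_to_flanking_unconverted(self):
        t = make_tract({100, 209})
        lengths = tract_lengths(t, LADDER5)
        # flanked by unconverted 12 proximally and 350 distally
        assert lengths.min_bp == 110
        assert lengths.max_bp == 350 - 12 - 1

    def test_max_unbounded_sides(self):
        # converted at the first and last ladder sites: proximal bound is the
        # excision site (0), distal bound one past the ladder end
        t = make_tract({12, 567})
        assert tract_lengths(t, LADDER5).max_bp == (567 + 1) - 0 - 1

    def test_unreadable_never_bounds_a_tract(self):
        calls = (UNCONVERTED, UNREADABLE, CONVERTED, UNREADABLE, UNCONVERTED)
        t = ConversionTract("NCO", Window.T22_34, calls)
        lengths = tract_lengths(t, LADDER5)
        assert lengths.min_bp == 1
        assert lengths.max_bp == 567 - 12 - 1

    def test_no_conversion_is_an_error(self):
        t = ConversionTract("NCO", Window.T22_34, (UNCONVERTED,) * 5)
        with pytest.raises(ValueError, match="no converted"):
            tract_lengths(t, LADDER5)

    def test_random_tracts_vs_pair_scan_oracle(self):
        rng = np.random.default_rng(1)
        states = (CONVERTED, UNCONVERTED, HETERODUPLEX, UNREADABLE)
        for _ in range(200):
            calls = tuple(states[i] for i in rng.integers(0, 4, size=len(DEFAULT_LADDER)))
            oracle = min_bp_oracle(calls, DEFAULT_LADDER.positions)
            t = ConversionTract("NCO", Window.T10_22, calls)
            if oracle is None:
                with pytest.raises(ValueError):
                    tract_lengths(t)
            else:
                lengths = tract_lengths(t)
                assert lengths.min_bp == oracle
                assert lengths.min_bp <= lengths.max_bp


class TestClassification:
    def test_nco_short_is_proximal_only(self):
        assert classify_nco(make_tract({12}), LADDER5) == "short"
        assert classify_nco(make_tract({12, 100}), LADDER5) == "long"
        assert classify_nco(make_tract({100}), LADDER5) == "long"

    def test_heteroduplex_counts_for_the_single_site_rule(self):
        assert classify_nco(make_tract(set(), het_positions={12}), LADDER5) == "short"
        assert classify_nco(make_tract({12}, het_positions={100}), LADDER5) == "long"

    def test_co_threshold_inclusive_at_198(self):
        ladder = PolymorphismLadder((12, 209, 210, 567))
        assert classify_co(make_tract({12, 209}, ladder, cls="CO"), ladder) == "short"
        assert classify_co(make_tract({12, 210}, ladder, cls="CO"), ladder) == "long"
        assert classify_co(make_tract({12}, ladder, cls="CO"), ladder) == "short"

    def test_class_mismatch_errors(self):
        with pytest.raises(ValueError, match="classify_nco on a CO"):
            classify_nco(make_tract({12}, cls="CO"), LADDER5)
        with pytest.raises(ValueError, match="classify_co on a NCO"):
            classify_co(make_tract({12}), LADDER5)

    def test_exhaustive_5_site_ladder_vs_oracle(self):
        """All 4^5 call vectors: min length, NCO and CO class match the
        brute-force definitions."""
        states = (CONVERTED, UNCONVERTED, HETERODUPLEX, UNREADABLE)
        pos = LADDER5.positions
        for calls in itertools.product(states, repeat=5):
            oracle_min = min_bp_oracle(calls, pos)
            nco = ConversionTract("NCO", Window.T22_34, calls)
            co = ConversionTract("CO", Window.T22_34, calls)
            if oracle_min is None:
                with pytest.raises(ValueError):
                    tract_lengths(nco, LADDER5)
                continue
            assert tract_lengths(nco, LADDER5).min_bp == oracle_min
            conv_idx = [i for i, c in enumerate(calls)
                        if c in (CONVERTED, HETERODUPLEX)]
            assert (classify_nco(nco, LADDER5) == "short") == (conv_idx == [0])
            assert (classify_co(co, LADDER5) == "short") == (oracle_min <= 198)
            # short NCO implies 1 bp minimum tract; converse needs site 12
            if classify_nco(nco, LADDER5) == "short":
                assert oracle_min == 1


class TestHeteroduplex:
    def test_flag(self):
        assert not has_heteroduplex(make_tract({12, 100}))
        assert has_heteroduplex(make_tract({12}, het_positions={100}))

    def test_all_unreadable_warns(self):
        t = ConversionTract("NCO", Window.T10_22, (UNREADABLE,) * 5)
        with pytest.warns(UserWarning, match="unreadable"):
            assert not has_heteroduplex(t)

    def test_invariant_under_unconverted_unreadable_relabel(self):
        calls = [UNCONVERTED, HETERODUPLEX, UNCONVERTED, UNREADABLE, UNCONVERTED]
        swapped = [UNREADABLE if c == UNCONVERTED else
                   UNCONVERTED if c == UNREADABLE else c for c in calls]
        a = ConversionTract("NCO", Window.T10_22, tuple(calls))
        b = ConversionTract("NCO", Window.T10_22, tuple(swapped))
        assert has_heteroduplex(a) == has_heteroduplex(b)


def mh_oracle(ref, s, e):
    if s == e:  # an empty deletion has no junction
        return 0
    best = 0
    for m in range(1, min(s, e) + 1):
        if ref[s - m:s] == ref[e - m:e]:
            best = max(best, m)
    return best


class TestJunctionMicrohomology:
    def test_worked_example(self):
        # deleting "CCGAT" from GCAT|CCGAT|GG leaves ...AT / AT... junction
        assert junction_microhomology("GCATCCGATGG", (4, 9)) == 2

    def test_no_shared_flank(self):
        assert junction_microhomology("AAAACGTTTT", (4, 6)) == 0

    def test_empty_deletion(self):
        assert junction_microhomology("ACGTACGT", (3, 3)) == 0

    def test_out_of_bounds(self):
        with pytest.raises(ValueError):
            junction_microhomology("ACGT", (2, 9))

    def test_exhaustive_deletions_on_random_sequences(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        for _ in range(5):
            ref = "".join(rng.choice(bases, size=30))
            for s in range(31):
                for e in range(s, 31):
                    assert junction_microhomology(ref, (s, e)) == mh_oracle(ref, s, e)

    def test_planted_junctions(self):
        for mh in (0, 1, 2, 3):
            df = gen_junctions(ref_len=50, del_size=8, mh_len=mh, n=50, seed=3 + mh)
            for _, row in df.iterrows():
                assert junction_microhomology(row.ref_seq, (row.s, row.e)) == mh


class TestMutationSignatures:
    def test_small_deletion_with_microhomology(self):
        ev = MutationEvent("GCATCCGATGG", (4, 9))
        sig = classify_mutation(ev)
        assert sig.mh_len == 2 and sig.size_bp == 5 and sig.tmej_like

    def test_large_deletion_fails_size_rule(self):
        ref = "AT" * 40
        sig = classify_mutation(MutationEvent(ref, (2, 62)))  # 60 bp, mh > 0
        assert sig.mh_len >= 1 and not sig.tmej_like

    def test_templated_insertion_without_deletion(self):
        sig = classify_mutation(MutationEvent("ACGTACGTAC", (5, 5),
                                              insertion_seq="ACGT", templated=True))
        assert sig.tmej_like and sig.size_bp == 4

    def test_untemplated_insertion_without_microhomology(self):
        sig = classify_mutation(MutationEvent("AAAACGTTTT", (4, 6),
                                              insertion_seq="GG", templated=False))
        assert not sig.tmej_like


class TestTractSummary:
    def _tracts(self, short, long, window=Window.T22_34, cls="NCO"):
        out = [make_tract({12}, cls=cls, window=window) for _ in range(short)]
        out += [make_tract({12, 100}, cls=cls, window=window) for _ in range(long)]
        return out

    def test_published_brc1_short_fraction(self):
        # 28 of 29 brc-1 interhomolog-window noncrossover tracts are short
        # (96.6%, CI 82.8-99.4%) vs 49/66 in wild type (74.2%), p = 0.010
        brc1 = self._tracts(28, 1)
        wt = self._tracts(49, 17)
        s = tract_summary(brc1, "NCO", "IH", reference=wt, ladder=LADDER5)
        assert round(100 * s.short_frac.point, 1) == 96.6
        assert round(100 * s.short_frac.ci_low, 1) == 82.8
        assert round(100 * s.short_frac.ci_high, 1) == 99.4
        assert round(s.p_vs_reference, 3) == 0.010

    def test_all_short_vs_all_short(self):
        s = tract_summary(self._tracts(5, 0), "NCO", "IH",
                          reference=self._tracts(9, 0), ladder=LADDER5)
        assert s.p_vs_reference == 1.0

    def test_matches_compare_groups_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            k1, m1 = int(rng.integers(0, 15)), int(rng.integers(1, 15))
            k0, m0 = int(rng.integers(0, 15)), int(rng.integers(1, 15))
            s = tract_summary(self._tracts(k1, m1), "NCO", "IH",
                              reference=self._tracts(k0, m0), ladder=LADDER5)
            oracle = compare_groups(k1, k1 + m1, k0, k0 + m0)
            assert s.p_vs_reference == pytest.approx(oracle.p, rel=1e-12)

    def test_ambiguous_tracts_excluded(self):
        tracts = self._tracts(3, 1)
        flagged = ConversionTract("NCO", Window.T22_34, tracts[0].calls,
                                  ambiguous=True)
        s = tract_summary([*tracts, flagged], "NCO", "IH",
                          reference=self._tracts(4, 4), ladder=LADDER5)
        assert s.total == 4

    def test_window_groups_partition(self):
        ih = self._tracts(2, 2, window=Window.T34_46)
        non_ih = self._tracts(3, 0, window=Window.T10_22)
        s = tract_summary(ih + non_ih, "NCO", "nonIH",
                          reference=self._tracts(1, 1, window=Window.T10_22),
                          ladder=LADDER5)
        assert (s.short, s.total) == (3, 3)


def test_tract_table_roundtrip(tmp_path):
    tracts = [
        make_tract({12, 209}, DEFAULT_LADDER, cls="CO", window=Window.T10_22),
        make_tract({12}, DEFAULT_LADDER, het_positions={77}),
    ]
    path = tmp_path / "tracts.tsv"
    write_tract_table(tracts, path)
    loaded = load_tract_table(path)
    assert [t.calls for t in loaded] == [t.calls for t in tracts]
    assert [t.window for t in loaded] == [t.window for t in tracts]
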