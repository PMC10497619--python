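"""Read mapping: trimming, local alignment, deduplication, filters, counts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from barrierscreen import mapping as mp
from barrierscreen import synthetic_screen as ss
from barrierscreen.library_design import LibraryElement, reverse_complement

from _oracles import sw_oracle, window_trim_oracle

LINKER = "ACACGACGCTCTTCCGATCT"


def _read(seq, quals=None, rid="r1"):
    q = np.full(len(seq), 38) if quals is None else np.asarray(quals)
    return mp.Read(rid, seq, q)


def _rec(read_id="r", element_id="e", score=100, mm=0, gaps=0, mlen=50, rlen=50, ev=0.0):
    return mp.AlignmentRecord(read_id, element_id, "+", score, mm, gaps, mlen, rlen, ev)


class TestTrimming:
    def test_clean_read_loses_only_linker(self):
        insert = "ACGT" * 25
        out = mp.trim_read(_read(LINKER + insert), LINKER)
        assert out.sequence == insert

    def test_uniformly_bad_read_trims_to_nothing(self):
        out = mp.trim_read(_read("ACGTACGTAC", [10] * 10), "")
        assert len(out) == 0

    def test_quality_cliff_matches_window_oracle(self):
        quals = [38] * 50 + [20] * 10
        keep = mp.quality_trim_length(np.array(quals), 25.75)
        assert 50 <= keep <= 53
        assert keep == window_trim_oracle(quals, 25.75)

    @given(
        st.lists(st.integers(min_value=2, max_value=40), min_size=0, max_size=80),
        st.floats(min_value=5, max_value=39),
    )
    def test_trim_length_equals_bruteforce_scan(self, quals, thr):
        assert mp.quality_trim_length(np.array(quals, dtype=float), thr) == (
            window_trim_oracle(quals, thr)
        )

    def test_partial_linker_overlap_stripped(self):
        # read starts inside the linker: last 12 bases of linker + insert
        insert = "TTTTCCCCGGGGAAAA"
        read = _read(LINKER[-12:] + insert)
        assert mp.remove_linker(read.sequence, LINKER) == insert

    def test_short_overlap_not_stripped(self):
        seq = LINKER[-6:] + "T" * 20  # below the 8 bp minimum overlap
        assert mp.remove_linker(seq, LINKER) == seq

    def test_qualities_follow_linker_removal(self):
        quals = list(range(len(LINKER))) + [38, 39, 40]
        out = mp.trim_read(_read(LINKER + "ACG", quals), LINKER)
        assert out.qualities.tolist() == [38, 39, 40]


@pytest.fixture(scope="module")
def element250():
    rng = np.random.default_rng(21)
    core = "".join(rng.choice(list("ACGT"), 250))
    return LibraryElement("E250", "RANDOM", core, "G" * 25 + core + "C" * 25)


class TestAlignment:

    def test_exact_core_alignment(self, element250):
        read = _read(element250.core_sequence)
        recs = mp.align_read(read, [element250])
        assert len(recs) == 1
        r = recs[0]
        assert (r.mismatches, r.gaps, r.mapped_length) == (0, 0, 250)
        assert r.score == 250 * 2
        assert r.strand == "+"

    def test_reverse_complement_scores_identically(self, element250):
        fwd = mp.align_read(_read(element250.core_sequence), [element250])[0]
        rev = mp.align_read(
            _read(reverse_complement(element250.core_sequence)), [element250]
        )[0]
        assert rev.score == fwd.score
        assert rev.strand == "-"
        assert rev.mapped_length == fwd.mapped_length

    def test_small_instance_matches_dp_oracle(self):
        rng = np.random.default_rng(33)
        ref = "".join(rng.choice(list("ACGT"), 60))
        q = list(ref[15:45])
        q[5] = "A" if q[5] != "A" else "C"
        q[20] = "G" if q[20] != "G" else "T"
        lib = [LibraryElement("e", "RANDOM", ref, ref)]
        rec = mp.align_read(_read("".join(q)), lib)[0]
        o_score, o_mm, o_gaps, _, _ = sw_oracle("".join(q), ref, 2, 3, 5, 2)
        rc = reverse_complement("".join(q))
        o2 = sw_oracle(rc, ref, 2, 3, 5, 2)
        best = max(o_score, o2[0])
        assert rec.score == best
        assert rec.mismatches == (o_mm if o_score >= o2[0] else o2[1])

    def test_random_instances_match_dp_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(50):
            q = "".join(rng.choice(list("ACGT"), rng.integers(10, 51)))
            ref = "".join(rng.choice(list("ACGT"), rng.integers(20, 101)))
            lib = [LibraryElement("e", "RANDOM", ref, ref)]
            recs = mp.align_read(_read(q), lib, min_score=1)
            of = sw_oracle(q, ref, 2, 3, 5, 2)
            orv = sw_oracle(reverse_complement(q), ref, 2, 3, 5, 2)
            best = of if of[0] >= orv[0] else orv
            if recs:
                assert (recs[0].score, recs[0].mismatches, recs[0].gaps) == best[:3]
            else:
                assert best[0] < 1

    def test_empty_read_rejected(self, element250):
        with pytest.raises(ValueError):
            mp.align_read(_read(""), [element250])

    def test_indexed_agrees_with_exhaustive_on_noisy_reads(self, small_library):
        aligner = mp.LibraryAligner(small_library)
        cfg = ss.SequencingConfig(
            read_length=60, substitution_rate=0.01, insertion_rate=0.002,
            deletion_rate=0.002, linker="", pcr_noise_sigma=0,
        )
        rng = np.random.default_rng(3)
        import pandas as pd

        cells = pd.DataFrame(
            {
                "element_id": [el.id for el in small_library for _ in range(3)],
                "intensity": 1.0,
            }
        )
        reads = ss.reads_from_population(
            cells, small_library, ss.ScreenSample("High", 15, 1, 150), cfg, seed=4
        )
        for rid, seq, qual in reads:
            read = mp.Read(rid, seq, np.frombuffer(qual.encode(), np.uint8) - 33)
            ex = mp.deduplicate(aligner.align_read(read))
            ix = mp.deduplicate(aligner.align_read_indexed(read))
            assert len(ex) == len(ix) == 1
            assert (ex[0].element_id, ex[0].score) == (ix[0].element_id, ix[0].score)


class TestDeduplicate:
    def test_highest_score_kept(self):
        recs = [_rec(element_id="e1", score=480), _rec(element_id="e2", score=300)]
        assert [r.element_id for r in mp.deduplicate(recs)] == ["e1"]

    def test_single_record_unchanged(self):
        recs = [_rec()]
        assert mp.deduplicate(recs) == recs

    def test_full_tie_broken_by_element_id(self):
        recs = [_rec(element_id="seq801"), _rec(element_id="seq268")]
        assert [r.element_id for r in mp.deduplicate(recs)] == ["seq268"]

    def test_score_tie_broken_by_evalue(self):
        recs = [
            _rec(element_id="zzz", score=100, ev=1e-10),
            _rec(element_id="aaa", score=100, ev=1e-5),
        ]
        assert [r.element_id for r in mp.deduplicate(recs)] == ["zzz"]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["r1", "r2", "r3"]),
                st.sampled_from(["e1", "e2", "e3", "e4"]),
                st.integers(min_value=10, max_value=100),
            ),
            max_size=20,
        )
    )
    def test_idempotent_and_unique_read_ids(self, triples):
        recs = [_rec(read_id=r, element_id=e, score=s) for r, e, s in triples]
        once = mp.deduplicate(recs)
        twice = mp.deduplicate(once)
        assert sorted(once, key=lambda r: r.read_id) == sorted(
            twice, key=lambda r: r.read_id
        )
        ids = [r.read_id for r in once]
        assert len(set(ids)) == len(ids)


class TestFilters:
    LIB = [LibraryElement("e", "RANDOM", "A" * 250, "G" * 25 + "A" * 250 + "C" * 25)]

    def _run(self, rec, **kw):
        return mp.apply_filters([rec], self.LIB, **kw)

    @pytest.mark.parametrize(
        "mm,gaps,mlen,kept",
        [
            (4, 0, 250, False),   # one mismatch too many
            (3, 0, 250, True),    # at the mismatch boundary
            (0, 4, 250, False),   # one gap too many
            (0, 3, 250, True),    # at the gap boundary
            (0, 0, 239, False),   # mapped length max_possible - 11
            (0, 0, 240, True),    # mapped length max_possible - 10
            (0, 0, 250, True),    # full-length perfect mapping
        ],
    )
    def test_boundary_semantics(self, mm, gaps, mlen, kept):
        # trimmed read 250 bp vs 300 bp oligo: max_possible = 250
        rec = _rec(mm=mm, gaps=gaps, mlen=mlen, rlen=250)
        assert bool(self._run(rec)) == kept

    def test_max_possible_uses_oligo_when_read_longer(self):
        # read 400 bp vs 300 bp oligo: max_possible = 300, floor = 290
        assert self._run(_rec(mm=0, gaps=0, mlen=290, rlen=400))
        assert not self._run(_rec(mm=0, gaps=0, mlen=289, rlen=400))

    def test_unknown_element_raises(self):
        with pytest.raises(KeyError):
            mp.apply_filters([_rec(element_id="ghost")], self.LIB)

    def test_rejection_log_counts_each_rule(self):
        from collections import Counter

        log = Counter()
        recs = [
            _rec(read_id="a", mm=4, mlen=250, rlen=250),
            _rec(read_id="b", gaps=4, mlen=250, rlen=250),
            _rec(read_id="c", mlen=200, rlen=250),
            _rec(read_id="d", mlen=250, rlen=250),
        ]
        kept = mp.apply_filters(recs, self.LIB, log=log)
        assert [r.read_id for r in kept] == ["d"]
        assert log["mismatches"] == 1 and log["gaps"] == 1 and log["mapped_length"] == 1

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 6), st.integers(0, 6), st.integers(200, 250)
            ),
            max_size=30,
        ),
        st.integers(0, 5),
        st.integers(0, 5),
        st.integers(0, 30),
    )
    def test_subset_and_monotone_in_thresholds(self, recs, mm_max, gap_max, slack):
        records = [
            _rec(read_id=f"r{i}", mm=m, gaps=g, mlen=L, rlen=250)
            for i, (m, g, L) in enumerate(recs)
        ]
        kept = mp.apply_filters(records, self.LIB, mm_max, gap_max, slack)
        assert set(r.read_id for r in kept) <= set(r.read_id for r in records)
        looser = mp.apply_filters(records, self.LIB, mm_max + 1, gap_max + 1, slack + 5)
        assert set(r.read_id for r in kept) <= set(r.read_id for r in looser)


class TestCounting:
    def test_counts_with_unobserved_elements(self):
        lib = [
            LibraryElement(f"e{i}", "RANDOM", "A" * 10, "A" * 10) for i in range(3)
        ]
        recs = [_rec(read_id=f"r{i}", element_id="e0") for i in range(10)]
        counts = mp.count_elements(recs, lib)
        assert counts.tolist() == [10, 0, 0]

    def test_empty_records_all_zero(self):
        lib = [LibraryElement("e", "RANDOM", "A" * 10, "A" * 10)]
        assert mp.count_elements([], lib).tolist() == [0]


class TestEndToEnd:
    def test_noiseless_sample_recovers_simulated_counts_exactly(self, small_library):
        cfg = ss.SequencingConfig(
            read_length=70, substitution_rate=0, insertion_rate=0, deletion_rate=0,
            linker=LINKER, pcr_noise_sigma=0,
        )
        phenos = ss.generate_phenotypes(
            [e.id for e in small_library], n_strong=5, n_null=5, seed=1
        )
        res = ss.simulate_screen(
            small_library, phenos, days=(15,), replicates=1, cells_per_element=200,
            reads_per_sample=3000, cfg=cfg, dropout_fraction=0.0, seed=5,
            emit_fastq=True,
        )
        sample = "Medium_d15_r1"
        reads = [
            mp.Read(rid, seq, np.frombuffer(q.encode(), np.uint8).astype(int) - 33)
            for rid, seq, q in res.reads[sample]
        ]
        out = mp.map_reads(reads, small_library, linker=LINKER, sample_name=sample)
        assert out.counts.equals(res.counts[sample].rename(sample))
        assert out.log["kept"] == 3000
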