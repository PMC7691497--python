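import numpy as np
import pytest

from conftest import random_seq
from oracles import sliding_window_hits

from matdecay.io_formats import SequenceSet, reverse_complement
from matdecay.smallrna_targeting import (
    SmallRNARecord,
    TranscriptIndex,
    find_hits,
    mirna_seed_targets,
    stage_profile,
    target_table,
)
from matdecay.synthetic_data import SynthConfig, gen_sequences


def as_tuples(hits):
    return sorted((h.transcript_id, h.start, h.orientation, h.mismatches) for h in hits)


class TestFindHits:
    def test_exact_antisense_complement(self):
        tx = SequenceSet({"t": "AAAA" + "ACGTACGTACGTACGTACGTA" + "CCCC"})
        guide = reverse_complement("ACGTACGTACGTACGTACGTA")
        res = find_hits(guide, tx, v=0, m=None)
        anti = [h for h in res.hits if h.orientation == "antisense"]
        assert len(anti) == 1
        assert (anti[0].start, anti[0].mismatches) == (4, 0)

    def test_three_mismatches_rejected_at_v2(self, rng):
        t = random_seq(rng, 80)
        tx = SequenceSet({"t": t})
        guide = list(reverse_complement(t[10:31]))
        for p in (2, 9, 16):
            guide[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[guide[p]]
        res = find_hits("".join(guide), tx, v=2, m=None)
        assert res.hits == [] and not res.suppressed

    def test_multimap_suppression_drops_query_entirely(self):
        # 25 copies of the same site -> 25 antisense placements > m=20
        site = "ACGTGCATCAGGTACCGTAGGCAT"
        tx = SequenceSet({f"t{i}": "TT" + site + "GG" for i in range(25)})
        res = find_hits(reverse_complement(site), tx, v=0, m=20)
        assert res.suppressed and res.hits == [] and res.n_alignments >= 25
        res2 = find_hits(reverse_complement(site), tx, v=0, m=None)
        assert len(res2.hits) == 25

    def test_invalid_character_rejected(self, tiny_transcripts):
        with pytest.raises(ValueError, match="ACGTN"):
            find_hits("ACGTXACGTACGTACGTACG", tiny_transcripts)

    def test_n_never_matches(self):
        site = "AACCGGTTAGATCCAGTTACG"
        tx = SequenceSet({"t": "AA" + site + "TT"})
        guide = reverse_complement(site)
        exact = [
            h
            for h in find_hits(guide, tx, v=0, m=None).hits
            if h.orientation == "antisense"
        ]
        n_guide = "N" + guide[1:]
        res0 = find_hits(n_guide, tx, v=0, m=None)
        res1 = [
            h
            for h in find_hits(n_guide, tx, v=1, m=None).hits
            if h.orientation == "antisense"
        ]
        assert len(exact) == 1
        assert res0.hits == []  # N costs a mismatch even over a match
        assert len(res1) == 1 and res1[0].mismatches == 1

    @pytest.mark.parametrize("v", [0, 1, 2])
    @pytest.mark.parametrize("m", [1, 20, None])
    def test_matches_brute_force_oracle(self, rng, v, m):
        tx = SequenceSet({f"t{i}": random_seq(rng, 100) for i in range(10)})
        idx = TranscriptIndex(tx)
        for trial in range(15):
            if trial % 2 == 0:
                tid = f"t{trial % 10}"
                k = int(rng.integers(18, 25))
                s = int(rng.integers(0, 100 - k))
                q = list(reverse_complement(tx[tid][s : s + k]))
                for p in rng.choice(k, int(rng.integers(0, 3)), replace=False):
                    q[p] = rng.choice([b for b in "ACGT" if b != q[p]])
                qseq = "".join(q)
            else:
                qseq = random_seq(rng, int(rng.integers(18, 25)))
            res = find_hits(qseq, idx, v=v, m=m)
            exp_hits, exp_sup = sliding_window_hits(qseq, tx, v, m)
            assert (as_tuples(res.hits), res.suppressed) == (exp_hits, exp_sup)

    def test_reverse_complement_symmetry(self, rng):
        """RC-ing query and transcripts swaps orientations, keeps counts."""
        tx = SequenceSet({f"t{i}": random_seq(rng, 150) for i in range(5)})
        rc_tx = SequenceSet(
            {tid: reverse_complement(s) for tid, s in tx.items()}
        )
        for _ in range(10):
            q = random_seq(rng, 20)
            a = find_hits(q, tx, v=2, m=None)
            b = find_hits(q, rc_tx, v=2, m=None)
            assert len(a.hits) == len(b.hits)
            assert sorted(h.orientation for h in a.hits) == sorted(
                "sense" if h.orientation == "antisense" else "antisense"
                for h in b.hits
            )

    def test_suppression_and_mismatch_monotonicity(self, rng):
        tx = SequenceSet({f"t{i}": random_seq(rng, 200) for i in range(5)})
        q = reverse_complement(tx["t0"][50:71])
        by_v = {
            v: as_tuples(find_hits(q, tx, v=v, m=None).hits) for v in (0, 1, 2)
        }
        assert set(by_v[0]) <= set(by_v[1]) <= set(by_v[2])
        n2 = len(by_v[2])
        assert find_hits(q, tx, v=2, m=max(n2, 1)).suppressed is False
        if n2 > 1:
            assert find_hits(q, tx, v=2, m=n2 - 1).suppressed is True


class TestTargetTable:
    def test_planted_map_recovered_exactly(self, small_synth):
        cfg, seqs = small_synth
        targets, stats = target_table(
            seqs.smallrnas, seqs.transcripts, v=2, m=20
        )
        planted = {
            (r.smallrna_id, r.transcript_id)
            for r in seqs.planted_targets.itertuples()
        }
        recovered = {(s, t) for t, ss in targets.items() for s in ss}
        assert recovered == planted

    def test_empty_pool_gives_empty_map(self, tiny_transcripts):
        targets, stats = target_table([], tiny_transcripts)
        assert targets == {} and stats["n_suppressed"] == 0

    def test_all_suppressed_logs_count(self):
        site = "ACGTGCATCAGGTACCGTAGG"
        tx = SequenceSet({f"t{i}": site for i in range(30)})
        pool = [SmallRNARecord("q", reverse_complement(site))]
        targets, stats = target_table(pool, tx, v=0, m=20)
        assert targets == {} and stats["n_suppressed"] == 1

    def test_maternal_restriction(self, small_synth):
        cfg, seqs = small_synth
        keep = set(list(seqs.transcripts.ids())[:50])
        targets, _ = target_table(
            seqs.smallrnas, seqs.transcripts, maternal_set=keep, v=2, m=20
        )
        assert set(targets) <= keep


class TestMirnaSeeds:
    def test_exact_seed_site_required(self):
        mir = SequenceSet({"m": "AACGTACGTCCCCCCCCCCCC"}, kind="smallRNA")
        seed_site = mir["m"][1:8]
        hit_tx = SequenceSet({"t1": "TTTT" + reverse_complement(seed_site) + "TTTT"})
        miss = reverse_complement(seed_site)
        miss = "G" + miss[1:] if miss[0] != "G" else "A" + miss[1:]
        miss_tx = SequenceSet({"t2": "TTTT" + miss + "TTTT"})
        assert mirna_seed_targets(mir, hit_tx) == {"t1": {"m"}}
        assert mirna_seed_targets(mir, miss_tx) == {}

    def test_short_mirna_rejected(self):
        mir = SequenceSet({"m": "ACGTACG"}, kind="transcript")
        with pytest.raises(ValueError, match="seed"):
            mirna_seed_targets(mir, SequenceSet({"t": "ACGTACGT"}))

    def test_planted_seed_sites_recovered(self, small_synth):
        cfg, seqs = small_synth
        got = mirna_seed_targets(seqs.mirnas, seqs.transcripts)
        for r in seqs.planted_mirna_targets.itertuples():
            assert r.mirna_id in got.get(r.transcript_id, set())


class TestStageProfile:
    def test_mean_and_unknown_ids(self, small_synth):
        import pandas as pd

        table = pd.DataFrame(
            {"zygote": [2.0, 4.0], "2C": [1.0, 3.0]}, index=["a", "b"]
        )
        prof = stage_profile(["a", "b", "nope"], table)
        assert prof.loc["zygote", "mean"] == 3.0
        assert prof.loc["2C", "mean"] == 2.0
        assert prof.loc["zygote", "n"] == 2

    def test_empty_ids_error(self):
        import pandas as pd

        with pytest.raises(ValueError):
            stage_profile([], pd.DataFrame({"s": [1.0]}, index=["a"]))
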