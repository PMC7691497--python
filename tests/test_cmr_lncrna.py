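import numpy as np
import pytest

from conftest import random_seq
from oracles import orf_scan_codons

from matdecay.cmr_lncrna import (
    annotate_context,
    classify_loci,
    coding_potential_filter,
    complementarity_screen,
    context_fractions,
    longest_orf_codons,
)
from matdecay.io_formats import GeneModel, SequenceSet, reverse_complement


def plant_lnc(rng, mrna, cov, L=300):
    """lncRNA of length L whose reverse complement covers `cov` of it."""
    blen = int(round(cov * L))
    t0 = int(rng.integers(0, len(mrna) - blen + 1))
    block = reverse_complement(mrna[t0 : t0 + blen])
    l0 = int(rng.integers(0, L - blen + 1))
    base = random_seq(rng, L)
    return base[:l0] + block + base[l0 + blen :]


class TestCodingPotentialFilter:
    def test_no_atg_is_retained(self):
        seq = "".join("TTC" for _ in range(100))
        s = SequenceSet({"x": seq}, kind="lncRNA")
        assert "x" in coding_potential_filter(s)

    def test_long_orf_removed(self):
        orf = "ATG" + "GCT" * 149 + "TAA"
        s = SequenceSet({"x": "TTTT" + orf + "TTTT"}, kind="lncRNA")
        assert len(coding_potential_filter(s, max_orf_codons=100)) == 0

    def test_orf_on_reverse_strand_detected(self):
        orf = "ATG" + "GCT" * 120 + "TAA"
        s = SequenceSet({"x": reverse_complement(orf)}, kind="lncRNA")
        assert len(coding_potential_filter(s, max_orf_codons=100)) == 0

    def test_agrees_with_six_frame_oracle(self, rng):
        for _ in range(40):
            seq = random_seq(rng, int(rng.integers(60, 400)))
            assert longest_orf_codons(seq) == orf_scan_codons(seq)


class TestComplementarityScreen:
    def test_single_block_coverage_arithmetic(self, rng):
        mrna = random_seq(rng, 500)
        lnc280 = plant_lnc(rng, mrna, 280 / 300)
        lnc250 = plant_lnc(rng, mrna, 250 / 300)
        tx = SequenceSet({"m": mrna})
        hits = complementarity_screen(
            SequenceSet({"a": lnc280, "b": lnc250}, kind="lncRNA"), tx
        )
        byid = {h.lncrna_id: h for h in hits}
        assert "a" in byid and byid["a"].mrna_id == "m"
        assert byid["a"].coverage == pytest.approx(280 / 300, abs=0.02)
        assert "b" not in byid  # 0.833 < 0.9

    def test_planted_threshold_straddle(self, small_synth):
        cfg, seqs = small_synth
        hits = complementarity_screen(seqs.lncrnas, seqs.transcripts)
        got = {h.lncrna_id for h in hits}
        truth = seqs.planted_cmr
        pos = set(truth[truth.is_positive].lncrna_id)
        neg = set(truth[~truth.is_positive].lncrna_id)
        assert pos <= got
        assert not (neg & got)
        assert not (set(seqs.scrambled_ids) & got)

    def test_block_intervals_consistent_with_coverage(self, small_synth):
        cfg, seqs = small_synth
        for h in complementarity_screen(seqs.lncrnas, seqs.transcripts):
            lnc_len = len(seqs.lncrnas[h.lncrna_id])
            ivs = sorted(iv for iv, _ in h.aligned_blocks)
            covered = sum(e - s for s, e in ivs)
            assert h.coverage == pytest.approx(covered / lnc_len)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2  # non-overlapping on the lncRNA
            # reported blocks really are antisense matches (>= 95% identity)
            mrna = seqs.transcripts[h.mrna_id]
            for (ls, le), (ms, me) in h.aligned_blocks:
                seg = seqs.lncrnas[h.lncrna_id][ls:le]
                assert len(seg) == me - ms
                matches = sum(
                    a == b
                    for a, b in zip(seg, reverse_complement(mrna[ms:me]))
                )
                assert matches / len(seg) >= 0.95

    def test_appending_unmatched_tail_decreases_coverage(self, rng):
        mrna = random_seq(rng, 500)
        lnc = plant_lnc(rng, mrna, 0.95)
        tx = SequenceSet({"m": mrna})
        h1 = complementarity_screen(SequenceSet({"l": lnc}, kind="lncRNA"), tx)
        longer = lnc + "A" * 10  # unlikely to extend any antisense block
        h2 = complementarity_screen(
            SequenceSet({"l": longer}, kind="lncRNA"), tx, min_coverage=0.5
        )
        assert h2[0].coverage < h1[0].coverage

    def test_symmetric_under_global_reverse_complement(self, rng):
        mrna = random_seq(rng, 400)
        lnc = plant_lnc(rng, mrna, 0.95)
        fwd = complementarity_screen(
            SequenceSet({"l": lnc}, kind="lncRNA"), SequenceSet({"m": mrna})
        )
        rev = complementarity_screen(
            SequenceSet({"l": reverse_complement(lnc)}, kind="lncRNA"),
            SequenceSet({"m": reverse_complement(mrna)}),
        )
        assert len(fwd) == len(rev) == 1
        assert fwd[0].coverage == pytest.approx(rev[0].coverage)

    def test_empty_target_set_is_empty_with_warning(self, rng, caplog):
        lnc = SequenceSet({"l": random_seq(rng, 100)}, kind="lncRNA")
        assert complementarity_screen(lnc, SequenceSet({})) == []

    def test_prescreen_equivalence_with_dense_diagonal_scan(self, rng):
        """The k-mer pre-screen must not change results vs scanning every
        diagonal of every pair."""
        from matdecay import cmr_lncrna as mod

        mrnas = SequenceSet({f"m{i}": random_seq(rng, 300) for i in range(5)})
        lncs = SequenceSet(
            {
                "hit": plant_lnc(rng, mrnas["m2"], 0.95, L=200),
                "decoy": random_seq(rng, 200),
            },
            kind="lncRNA",
        )
        fast = complementarity_screen(lncs, mrnas)

        # dense oracle: all diagonals, same block rules
        dense_hits = []
        for lid, lseq in lncs.items():
            l_enc = np.frombuffer(lseq.encode(), np.uint8)
            for mid, mseq in mrnas.items():
                rcs = reverse_complement(mseq)
                r_enc = np.frombuffer(rcs.encode(), np.uint8)
                blocks = []
                for d in range(-(len(rcs) - 1), len(lseq)):
                    li, lj = max(0, d), min(len(lseq), len(rcs) + d)
                    if lj - li < 20:
                        continue
                    match = l_enc[li:lj] == r_enc[li - d : lj - d]
                    for bs, be in mod._match_blocks(match, 20, 0.05):
                        blocks.append((li + bs, li + be, None))
                cover = mod._max_cover(blocks)
                cov = sum(e - s for s, e, _ in cover) / len(lseq)
                if cov > 0.9:
                    dense_hits.append((lid, mid, round(cov, 9)))
        assert sorted(
            (h.lncrna_id, h.mrna_id, round(h.coverage, 9)) for h in fast
        ) == sorted(dense_hits)


class TestContextAnnotation:
    GENES = [
        GeneModel(
            "g1",
            "chr1",
            "+",
            span=(1000, 3000),
            exons=[(1000, 1400), (2000, 3000)],
            cds=[(1100, 1400), (2000, 2400)],
        )
    ]

    @pytest.mark.parametrize(
        "interval,expected",
        [
            ((1500, 1900), "intron"),  # fully inside the intron
            ((5000, 5400), "intergenic"),  # outside every span
            ((1100, 1400), "coding_exon"),
            ((2500, 2900), "UTR_exon"),
            ((900, 1100), "mixed"),  # half intergenic, half gene; no majority
        ],
    )
    def test_majority_labels(self, interval, expected):
        labels = classify_loci({"x": ("chr1", *interval)}, self.GENES)
        assert labels["x"] == expected

    def test_unplaced_excluded_from_fractions(self, small_synth):
        cfg, seqs = small_synth
        hits = complementarity_screen(seqs.lncrnas, seqs.transcripts)
        annotate_context(hits, seqs.gene_models, seqs.lnc_loci)
        frac = context_fractions(hits).set_index("context")["fraction"]
        placed = [h for h in hits if h.context != "unplaced"]
        if placed:
            assert frac.dropna().sum() == pytest.approx(1.0)

    def test_planted_context_fractions_exact(self, small_synth):
        cfg, seqs = small_synth
        labels = classify_loci(dict(seqs.lnc_loci), seqs.gene_models)
        planted = dict(
            zip(
                seqs.planted_lnc_contexts.lncrna_id,
                seqs.planted_lnc_contexts.context,
            )
        )
        assert all(labels[k] == v for k, v in planted.items())
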