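"""Complementarity screen for lncRNAs against maternal mRNAs (CMR-lncRNAs).

A CMR-lncRNA is a long noncoding RNA carrying extensive antisense
complementarity to a maternal mRNA — the proposed double-stranded substrate
for endosiRNA biogenesis. The screen finds maximal ungapped antisense
blocks between each lncRNA and each candidate mRNA (minimum block length,
bounded per-block mismatch fraction), selects a non-overlapping set of
blocks on the lncRNA maximizing covered length, and reports pairs whose
coverage — covered lncRNA bases over lncRNA length — exceeds the threshold
(default 0.9, i.e. "alignment ratio > 90%").

Candidate lncRNAs are first reduced to putatively noncoding sequences by a
deliberately simple ORF-length rule (longest ORF < 100 codons), a declared
stand-in for dedicated coding-potential classifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneModel, SequenceSet, reverse_complement

__all__ = [
    "CMRHit",
    "coding_potential_filter",
    "longest_orf_codons",
    "complementarity_screen",
    "annotate_context",
    "classify_loci",
    "context_fractions",
    "cmr_hits_frame",
]

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}

CONTEXT_LABELS = ("intron", "coding_exon", "UTR_exon", "intergenic", "mixed")


@dataclass
class CMRHit:
    """One lncRNA/mRNA pair passing the complementarity screen.

    ``aligned_blocks`` pairs 0-based half-open intervals on the lncRNA with
    the corresponding intervals on the mRNA; blocks are non-overlapping on
    the lncRNA. ``coverage`` = covered lncRNA bases / lncRNA length.
    """

    lncrna_id: str
    mrna_id: str
    aligned_blocks: list[tuple[tuple[int, int], tuple[int, int]]]
    coverage: float
    context: str = "unplaced"

    def __post_init__(self):
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError(f"coverage {self.coverage} outside [0,1]")


# ---------------------------------------------------------------------------
# Coding-potential stand-in
# ---------------------------------------------------------------------------


def longest_orf_codons(seq: str) -> int:
    """Longest ORF in codons (ATG..stop, stop excluded), six frames.

    Open reading frames running off the 3' end without a stop codon are
    counted to the end — the conservative reading for noncoding filtering,
    since it removes more potentially coding sequence.
    """
    best = 0
    for strand_seq in (seq, reverse_complement(seq)):
        for frame in range(3):
            codons = [
                strand_seq[i : i + 3]
                for i in range(frame, len(strand_seq) - 2, 3)
            ]
            atg = None
            n_codons = 0
            for c in codons:
                if c in _STOPS:
                    if atg is not None:
                        best = max(best, n_codons - atg)
                    atg = None
                elif c == "ATG" and atg is None:
                    atg = n_codons
                n_codons += 1
            if atg is not None:
                best = max(best, n_codons - atg)
    return best


def coding_potential_filter(
    candidates: SequenceSet, max_orf_codons: int = 100
) -> SequenceSet:
    """Retain sequences whose longest ORF is < ``max_orf_codons`` codons."""
    keep = {
        sid: seq
        for sid, seq in candidates.items()
        if longest_orf_codons(seq) < max_orf_codons
    }
    return SequenceSet(keep, kind=candidates.kind)


# ---------------------------------------------------------------------------
# Complementarity screen
# ---------------------------------------------------------------------------


def _match_blocks(
    match: np.ndarray, min_block: int, max_mismatch_frac: float
) -> list[tuple[int, int]]:
    """Maximal blocks on one diagonal from a boolean match vector.

    Greedy left-to-right chaining of exact-match runs. A mismatch gap is
    absorbed only when (a) it is no longer than the mismatch budget of a
    minimum-length block, floor(min_block * frac) — isolated single-base
    mismatches under the defaults — and (b) the bridge, the gap plus the
    exact run that follows it, itself stays within the mismatch bound
    (a single mismatch needs a >= 19-base exact run behind it at the 5%
    default). Every absorbed segment is locally within the bound, so the
    whole block is too; a purely global bound would let one long
    near-perfect block dilute away arbitrary stretches of random
    flanking sequence. Blocks start and end on matches and must reach
    ``min_block``.
    """
    # exact-match runs as (start, end) half-open
    padded = np.concatenate([[False], match, [False]])
    diff = np.diff(padded.astype(np.int8))
    run_starts = np.nonzero(diff == 1)[0]
    run_ends = np.nonzero(diff == -1)[0]
    max_gap = max(1, int(min_block * max_mismatch_frac))
    blocks: list[tuple[int, int]] = []
    bs = be = None
    for rs, re in zip(run_starts, run_ends):
        if bs is None:
            bs, be = int(rs), int(re)
            continue
        gap = int(rs - be)  # all positions in [be, rs) are mismatches
        run = int(re - rs)
        if gap <= max_gap and gap / (gap + run) <= max_mismatch_frac:
            be = int(re)
        else:
            if be - bs >= min_block:
                blocks.append((bs, be))
            bs, be = int(rs), int(re)
    if bs is not None and be - bs >= min_block:
        blocks.append((bs, be))
    return blocks


def _max_cover(blocks: list[tuple[int, int, object]]) -> list:
    """Weighted interval scheduling: non-overlapping blocks maximizing
    total covered length on the lncRNA. Returns the selected block records.
    """
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: (b[1], b[0]))
    ends = [b[1] for b in blocks]
    import bisect

    n = len(blocks)
    best = [0] * (n + 1)
    choice: list[tuple[int, bool]] = [(0, False)] * (n + 1)
    for i in range(1, n + 1):
        s, e, _ = blocks[i - 1]
        j = bisect.bisect_right(ends, s, 0, i - 1)
        take = best[j] + (e - s)
        if take > best[i - 1]:
            best[i] = take
            choice[i] = (j, True)
        else:
            best[i] = best[i - 1]
            choice[i] = (i - 1, False)
    selected = []
    i = n
    while i > 0:
        j, taken = choice[i]
        if taken:
            selected.append(blocks[i - 1])
        i = j
    return selected[::-1]


def complementarity_screen(
    lncrnas: SequenceSet,
    target_mrnas: SequenceSet,
    min_coverage: float = 0.9,
    min_block: int = 20,
    max_block_mismatch_frac: float = 0.05,
) -> list[CMRHit]:
    """Screen every (lncRNA, mRNA) pair for antisense block coverage.

    Pairs are pre-screened by shared exact k-mers between the lncRNA and
    the reverse-complemented mRNA: any qualifying block must contain an
    exact run of length >= (min_block - mb) // (mb + 1) where
    mb = floor(min_block * max_block_mismatch_frac), so the pre-screen
    cannot drop a true hit. Multiple mRNA partners per lncRNA are allowed.
    """
    if len(target_mrnas) == 0:
        logger.warning("empty target mRNA set: no CMR hits possible")
        return []
    mb = int(min_block * max_block_mismatch_frac)
    seed_len = max(4, (min_block - mb) // (mb + 1))
    # index: seed k-mer -> list of (mrna ordinal, position in rc sequence)
    m_ids = list(target_mrnas.ids())
    rc = {mid: reverse_complement(target_mrnas[mid]) for mid in m_ids}
    rc_enc = {mid: _encode_cached(rc[mid]) for mid in m_ids}
    seed_index: dict[str, list[tuple[str, int]]] = {}
    for mid in m_ids:
        s = rc[mid]
        for i in range(len(s) - seed_len + 1):
            kmer = s[i : i + seed_len]
            if "N" not in kmer:
                seed_index.setdefault(kmer, []).append((mid, i))
    hits: list[CMRHit] = []
    for lid, lseq in lncrnas.items():
        l_enc = _encode_cached(lseq)
        llen = len(lseq)
        # candidate diagonals per mRNA from shared seeds
        diagonals: dict[str, set[int]] = {}
        for i in range(llen - seed_len + 1):
            kmer = lseq[i : i + seed_len]
            for mid, j in seed_index.get(kmer, ()):
                diagonals.setdefault(mid, set()).add(i - j)
        for mid, diags in diagonals.items():
            r_enc = rc_enc[mid]
            rlen = len(r_enc)
            blocks: list[tuple[int, int, tuple[int, int]]] = []
            for d in sorted(diags):
                li = max(0, d)
                lj = min(llen, rlen + d)
                if lj - li < min_block:
                    continue
                lw = l_enc[li:lj]
                rw = r_enc[li - d : lj - d]
                match = (lw == rw) & (lw != 4) & (rw != 4)
                for bs, be in _match_blocks(
                    match, min_block, max_block_mismatch_frac
                ):
                    # convert rc coords back to mRNA coords for reporting
                    rs, re = li + bs - d, li + be - d
                    m_iv = (rlen - re, rlen - rs)
                    blocks.append((li + bs, li + be, m_iv))
            cover = _max_cover(blocks)
            covered = sum(e - s for s, e, _ in cover)
            coverage = covered / llen
            if coverage > min_coverage:
                hits.append(
                    CMRHit(
                        lncrna_id=lid,
                        mrna_id=mid,
                        aligned_blocks=[((s, e), miv) for s, e, miv in cover],
                        coverage=coverage,
                    )
                )
    hits.sort(key=lambda h: (h.lncrna_id, h.mrna_id))
    return hits


_enc_cache: dict[str, np.ndarray] = {}


def _encode_cached(seq: str) -> np.ndarray:
    from .smallrna_targeting import _encode

    arr = _enc_cache.get(seq)
    if arr is None:
        arr = _encode(seq)
        if len(_enc_cache) > 10000:
            _enc_cache.clear()
        _enc_cache[seq] = arr
    return arr


# ---------------------------------------------------------------------------
# Genomic-context annotation
# ---------------------------------------------------------------------------


def annotate_context(
    hits: list[CMRHit],
    gene_models: list[GeneModel],
    lnc_loci: dict[str, tuple[str, int, int]],
) -> list[CMRHit]:
    """Label each hit's lncRNA locus by the feature holding its majority.

    Per-base labels use the priority coding_exon > UTR_exon > intron over
    overlapping genes; bases outside every gene span are intergenic. The
    label covering a strict majority (> 50%) of the locus wins, otherwise
    ``mixed``. LncRNAs without coordinates stay ``unplaced`` and are
    excluded from fraction summaries.
    """
    labels = classify_loci(
        {h.lncrna_id: lnc_loci.get(h.lncrna_id) for h in hits}, gene_models
    )
    for hit in hits:
        hit.context = labels[hit.lncrna_id]
    return hits


def classify_loci(
    loci: dict[str, tuple[str, int, int] | None], gene_models: list[GeneModel]
) -> dict[str, str]:
    """Majority-rule genomic-context label for each locus (or 'unplaced')."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for gm in gene_models:
        by_chrom.setdefault(gm.chrom, []).append(gm)
    return {
        name: ("unplaced" if locus is None else _classify_locus(locus, by_chrom))
        for name, locus in loci.items()
    }


def _classify_locus(
    locus: tuple[str, int, int], by_chrom: dict[str, list[GeneModel]]
) -> str:
    chrom, start, end = locus
    n = end - start
    if n <= 0:
        return "unplaced"
    # 0 intergenic < 1 intron < 2 UTR_exon < 3 coding_exon (priority order)
    labels = np.zeros(n, dtype=np.int8)
    for gm in by_chrom.get(chrom, ()):
        gs, ge = gm.span
        lo, hi = max(start, gs), min(end, ge)
        if lo >= hi:
            continue
        labels[lo - start : hi - start] = np.maximum(
            labels[lo - start : hi - start], 1
        )
        for (a, b) in gm.exons:
            lo, hi = max(start, a), min(end, b)
            if lo < hi:
                labels[lo - start : hi - start] = np.maximum(
                    labels[lo - start : hi - start], 2
                )
        for (a, b) in gm.cds:
            lo, hi = max(start, a), min(end, b)
            if lo < hi:
                labels[lo - start : hi - start] = np.maximum(
                    labels[lo - start : hi - start], 3
                )
    names = {0: "intergenic", 1: "intron", 2: "UTR_exon", 3: "coding_exon"}
    counts = np.bincount(labels, minlength=4)
    top = int(np.argmax(counts))
    if counts[top] * 2 > n:
        return names[top]
    return "mixed"


def context_fractions(hits: list[CMRHit]) -> pd.DataFrame:
    """Fraction of placed CMR-lncRNA loci per genomic-context label."""
    seen: dict[str, str] = {}
    for h in hits:
        seen.setdefault(h.lncrna_id, h.context)
    placed = {k: v for k, v in seen.items() if v != "unplaced"}
    total = len(placed)
    rows = []
    for label in CONTEXT_LABELS:
        count = sum(1 for v in placed.values() if v == label)
        rows.append(
            {
                "context": label,
                "count": count,
                "fraction": count / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def cmr_hits_frame(hits: list[CMRHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": h.lncrna_id,
                "mrna_id": h.mrna_id,
                "n_blocks": len(h.aligned_blocks),
                "coverage": h.coverage,
                "context": h.context,
            }
            for h in hits
        ],
        columns=["lncrna_id", "mrna_id", "n_blocks", "coverage", "context"],
    )
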