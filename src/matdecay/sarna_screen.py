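"""Promoter-proximal small activating RNA (saRNA) candidate screen.

Small activating RNAs direct AGO2 to promoter-proximal sequence and
up-regulate transcription (RNAa). Candidates are expressed small RNAs
(18-30 nt, RPM > 1 at the zygote or 2-cell stage) matched into the 1-kb
window upstream of the TSS of each gene in a user-supplied ZGA-gene set.
Matching reuses the mismatch-bounded antisense matcher with exact matching
(v=0) by default; hit positions are reported as the distance from the TSS
to the hit's TSS-proximal end.

Promoter windows are strand-aware: [TSS - window, TSS) on the + strand and
(TSS, TSS + window] reverse-complemented on the - strand, so every
extracted window reads 5' -> 3' toward the TSS and index ``window - 1`` is
the base adjacent to the TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import SequenceSet, reverse_complement
from .smallrna_targeting import SmallRNARecord, TranscriptIndex, find_hits

__all__ = [
    "SaRNAHit",
    "filter_sarna_candidates",
    "extract_promoters",
    "scan_promoters",
    "positional_distribution",
    "targeted_gene_fraction",
    "sarna_hits_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SaRNAHit:
    """One candidate saRNA placement in a gene's upstream window.

    ``offset_upstream`` is the distance in bp from the TSS to the hit end
    nearest the TSS (1 = immediately adjacent to the TSS).
    """

    smallrna_id: str
    gene_id: str
    offset_upstream: int
    orientation: str
    mismatches: int

    def __post_init__(self):
        if self.offset_upstream < 1:
            raise ValueError("offset_upstream must be >= 1")


def filter_sarna_candidates(
    smallrnas: list[SmallRNARecord],
    min_len: int = 18,
    max_len: int = 30,
    min_rpm: float = 1.0,
    stages: tuple[str, ...] = ("zygote", "2C"),
) -> list[SmallRNARecord]:
    """Length- and expression-filter the small-RNA pool.

    Keeps records with length in [min_len, max_len] and RPM strictly above
    ``min_rpm`` at ANY of the named stages.
    """
    for rec in smallrnas:
        missing = [s for s in stages if s not in rec.rpm_by_stage]
        if missing:
            raise ValueError(
                f"stage(s) {missing} absent from RPM table of {rec.id!r}"
            )
    return [
        rec
        for rec in smallrnas
        if min_len <= len(rec.sequence) <= max_len
        and any(rec.rpm_by_stage[s] > min_rpm for s in stages)
    ]


def extract_promoters(
    gene_models,
    genome: SequenceSet,
    window: int = 1000,
) -> tuple[SequenceSet, dict[str, bool]]:
    """Strand-aware TSS-upstream windows for every gene model.

    Returns the promoter SequenceSet (keyed by gene id) and a map of
    truncation flags for genes whose window ran into a chromosome edge.
    Genes on chromosomes absent from the genome are skipped with a warning.
    """
    out = SequenceSet({}, kind="promoter")
    truncated: dict[str, bool] = {}
    n_skipped = 0
    for gm in gene_models:
        if gm.chrom not in genome:
            n_skipped += 1
            continue
        chrom_seq = genome[gm.chrom]
        L = len(chrom_seq)
        tss = gm.tss
        if gm.strand == "+":
            lo = max(0, tss - window)
            seq = chrom_seq[lo:tss]
            trunc = (tss - window) < 0
        else:
            hi = min(L, tss + 1 + window)
            seq = reverse_complement(chrom_seq[tss + 1 : hi])
            trunc = (tss + 1 + window) > L
        if not seq:
            n_skipped += 1
            continue
        out.add(gm.gene_id, seq)
        truncated[gm.gene_id] = trunc
    if n_skipped:
        logger.warning(
            "%d genes skipped in promoter extraction (missing chromosome or "
            "empty window)",
            n_skipped,
        )
    return out, truncated


def scan_promoters(
    candidates: list[SmallRNARecord],
    promoters: SequenceSet,
    v: int = 0,
    m: int | None = 20,
    zga_genes: set[str] | None = None,
) -> list[SaRNAHit]:
    """Match candidate saRNAs into promoter windows.

    ``zga_genes`` restricts the promoter set (the screen runs against the
    supplied ZGA-gene list). Offsets are reported from the TSS to the
    TSS-proximal hit end; hits are sorted by (gene_id, offset, smallrna_id).
    """
    if zga_genes is not None:
        promoters = promoters.subset(zga_genes)
    index = TranscriptIndex(promoters)
    win_len = {gid: len(promoters[gid]) for gid in promoters.ids()}
    hits: list[SaRNAHit] = []
    for rec in candidates:
        res = find_hits(rec, index, v=v, m=m)
        if res.suppressed:
            continue
        k = len(rec.sequence)
        for h in res.hits:
            w = win_len[h.transcript_id]
            offset = w - h.start - k + 1
            hits.append(
                SaRNAHit(
                    smallrna_id=h.smallrna_id,
                    gene_id=h.transcript_id,
                    offset_upstream=offset,
                    orientation=h.orientation,
                    mismatches=h.mismatches,
                )
            )
    hits.sort(key=lambda h: (h.gene_id, h.offset_upstream, h.smallrna_id))
    return hits


def positional_distribution(hits: list[SaRNAHit], bin_bp: int = 100) -> pd.DataFrame:
    """Histogram of hit offsets in [k*bin, (k+1)*bin) bins.

    The count column sums to the number of hits; empty input yields an
    empty histogram with a warning.
    """
    if not hits:
        logger.warning("no saRNA hits: empty positional histogram")
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    offsets = np.array([h.offset_upstream for h in hits])
    top = int(offsets.max() // bin_bp) + 1
    counts = np.bincount(offsets // bin_bp, minlength=top)
    return pd.DataFrame(
        {
            "bin_start": np.arange(top) * bin_bp,
            "bin_end": (np.arange(top) + 1) * bin_bp,
            "count": counts,
        }
    )


def targeted_gene_fraction(hits: list[SaRNAHit], zga_genes: set[str]) -> float:
    """|genes with >= 1 saRNA hit| / |ZGA gene set|."""
    if not zga_genes:
        raise ValueError("empty ZGA gene set")
    targeted = {h.gene_id for h in hits} & zga_genes
    return len(targeted) / len(zga_genes)


def sarna_hits_frame(hits: list[SaRNAHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "smallrna_id": h.smallrna_id,
                "gene_id": h.gene_id,
                "offset_upstream": h.offset_upstream,
                "orientation": h.orientation,
                "mismatches": h.mismatches,
            }
            for h in hits
        ],
        columns=[
            "smallrna_id",
            "gene_id",
            "offset_upstream",
            "orientation",
            "mismatches",
        ],
    )
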