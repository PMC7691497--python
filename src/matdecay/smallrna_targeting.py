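"""Mismatch-bounded antisense matching of small RNAs onto transcripts.

This is a native reimplementation of the ungapped alignment screen used to
map endogenous siRNAs to maternal mRNAs: report ALL end-to-end placements
of a query in both orientations with Hamming distance <= v (``-a -v``
semantics), and suppress any query whose total number of valid placements
exceeds the multimap cap m (``-m`` semantics — the query is dropped
entirely, not truncated). An *antisense* hit means the reverse complement
of the query equals the transcript window up to <= v mismatches; ``N``
never matches anything.

The matcher is seed-and-verify: any placement with <= v mismatches must
contain an exact match to one of v+1 disjoint seeds of the query
(pigeonhole), so candidates come from an exact k-mer index and only
candidates are verified. Degenerate queries (too short to seed) fall back
to a dense scan. A brute-force sliding-window scan over every offset is
kept in the test suite as the independent oracle.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import SequenceSet, reverse_complement, write_tsv

__all__ = [
    "SmallRNARecord",
    "TargetHit",
    "MatchResult",
    "TranscriptIndex",
    "find_hits",
    "target_table",
    "mirna_seed_targets",
    "stage_profile",
    "read_smallrna_table",
    "write_smallrna_table",
    "hits_frame",
]

logger = logging.getLogger(__name__)

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGTN"):
    _ENC[_c] = _i
_N_CODE = 4


def _encode(seq: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains characters outside ACGTN: {bad}")
    return arr


@dataclass
class SmallRNARecord:
    """A small RNA with per-stage abundance (RPM, reads per million)."""

    id: str
    sequence: str
    rpm_by_stage: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for stage, rpm in self.rpm_by_stage.items():
            if rpm < 0:
                raise ValueError(f"negative RPM for {self.id!r} at stage {stage!r}")


@dataclass(frozen=True, order=True)
class TargetHit:
    """One ungapped placement of a small RNA on a transcript.

    ``start`` is 0-based on the transcript; ``orientation`` is 'antisense'
    when the reverse complement of the query matches the window, 'sense'
    when the query itself does.
    """

    transcript_id: str
    start: int
    orientation: str
    smallrna_id: str
    mismatches: int


@dataclass
class MatchResult:
    hits: list[TargetHit]
    suppressed: bool
    n_alignments: int


class TranscriptIndex:
    """Concatenated, encoded transcript set with lazy exact k-mer indexes."""

    def __init__(self, transcripts: SequenceSet):
        self.ids = list(transcripts.ids())
        seqs = [transcripts[t] for t in self.ids]
        self.lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        self.starts = np.concatenate([[0], np.cumsum(self.lengths)])
        self.concat = (
            np.concatenate([_encode(s) for s in seqs])
            if seqs
            else np.empty(0, dtype=np.uint8)
        )
        self._concat_str = "".join(seqs)
        self._seed_indexes: dict[int, dict[str, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.ids)

    def seed_index(self, s: int) -> dict[str, np.ndarray]:
        """Positions (concatenated coordinates) of every N-free s-mer."""
        if s not in self._seed_indexes:
            index: dict[str, list[int]] = {}
            text = self._concat_str
            for t in range(len(self.ids)):
                lo, hi = int(self.starts[t]), int(self.starts[t + 1])
                for i in range(lo, hi - s + 1):
                    kmer = text[i : i + s]
                    if "N" not in kmer:
                        index.setdefault(kmer, []).append(i)
            self._seed_indexes[s] = {
                k: np.asarray(v, dtype=np.int64) for k, v in index.items()
            }
        return self._seed_indexes[s]

    def locate(self, concat_pos: np.ndarray) -> np.ndarray:
        """Transcript ordinal containing each concatenated position."""
        return np.searchsorted(self.starts, concat_pos, side="right") - 1


def _candidate_starts(index: TranscriptIndex, pattern: str, v: int) -> np.ndarray:
    """Concatenated candidate start positions by the pigeonhole seed rule."""
    k = len(pattern)
    s = k // (v + 1)
    if s < 1:
        # query shorter than v+1: every offset is a candidate
        total = int(index.starts[-1])
        return np.arange(0, max(total - k + 1, 0), dtype=np.int64)
    seed_idx = index.seed_index(s)
    # v+1 disjoint seeds; a placement with <= v mismatches matches one exactly
    offsets = [j * s for j in range(v + 1)]
    cands = []
    for off in offsets:
        part = pattern[off : off + s]
        if "N" in part:
            continue
        pos = seed_idx.get(part)
        if pos is not None:
            cands.append(pos - off)
    if not cands:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(cands))


def _verify(
    index: TranscriptIndex, pattern: str, starts: np.ndarray, v: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hamming-verify candidate placements; returns (transcript, local, mm)."""
    k = len(pattern)
    if starts.size == 0:
        return (np.empty(0, int),) * 3
    starts = starts[starts >= 0]
    t_ord = index.locate(starts)
    # placement must lie entirely inside one transcript
    ok = (starts + k) <= index.starts[t_ord + 1]
    starts, t_ord = starts[ok], t_ord[ok]
    if starts.size == 0:
        return (np.empty(0, int),) * 3
    pat = _encode(pattern)
    windows = index.concat[starts[:, None] + np.arange(k)[None, :]]
    mm = ((windows != pat) | (windows == _N_CODE) | (pat == _N_CODE)).sum(axis=1)
    keep = mm <= v
    return t_ord[keep], (starts - index.starts[t_ord])[keep], mm[keep]


def find_hits(
    query: SmallRNARecord | str,
    transcripts: SequenceSet | TranscriptIndex,
    v: int = 2,
    m: int | None = 20,
) -> MatchResult:
    """All ungapped placements of a query across a transcript set.

    Both orientations are enumerated and count toward the multimap cap
    ``m``; ``m=None`` disables suppression. Hits are sorted by
    (transcript_id, start, orientation).
    """
    if isinstance(query, str):
        query = SmallRNARecord(id="query", sequence=query)
    if v < 0:
        raise ValueError("v must be >= 0")
    if m is not None and m < 1:
        raise ValueError("m must be >= 1 (or None for no cap)")
    if not query.sequence:
        raise ValueError("empty query sequence")
    bad = set(query.sequence) - set("ACGTN")
    if bad:
        raise ValueError(
            f"query contains characters outside ACGTN: {sorted(bad)}"
        )
    index = (
        transcripts
        if isinstance(transcripts, TranscriptIndex)
        else TranscriptIndex(transcripts)
    )
    hits: list[TargetHit] = []
    for orientation, pattern in (
        ("sense", query.sequence),
        ("antisense", reverse_complement(query.sequence)),
    ):
        cand = _candidate_starts(index, pattern, v)
        t_ord, local, mm = _verify(index, pattern, cand, v)
        for t, s, d in zip(t_ord, local, mm):
            hits.append(
                TargetHit(
                    transcript_id=index.ids[int(t)],
                    start=int(s),
                    orientation=orientation,
                    smallrna_id=query.id,
                    mismatches=int(d),
                )
            )
    n = len(hits)
    if m is not None and n > m:
        return MatchResult(hits=[], suppressed=True, n_alignments=n)
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.orientation))
    return MatchResult(hits=hits, suppressed=False, n_alignments=n)


def target_table(
    smallrnas: list[SmallRNARecord],
    transcripts: SequenceSet,
    maternal_set: set[str] | None = None,
    v: int = 2,
    m: int | None = 20,
    antisense_only: bool = True,
) -> tuple[dict[str, set[str]], dict]:
    """Inverted transcript -> small-RNA target index over non-suppressed hits.

    ``maternal_set`` restricts the transcript space (the screen runs against
    maternal mRNAs only). Returns the target map and a stats dict with
    suppression counts and the full hit list.
    """
    if maternal_set is not None:
        transcripts = transcripts.subset(maternal_set)
    index = TranscriptIndex(transcripts)
    targets: dict[str, set[str]] = {}
    all_hits: list[TargetHit] = []
    n_suppressed = 0
    for rec in smallrnas:
        res = find_hits(rec, index, v=v, m=m)
        if res.suppressed:
            n_suppressed += 1
            continue
        for h in res.hits:
            if antisense_only and h.orientation != "antisense":
                continue
            targets.setdefault(h.transcript_id, set()).add(h.smallrna_id)
            all_hits.append(h)
    if n_suppressed:
        logger.info("%d small RNAs suppressed by multimap cap m=%s", n_suppressed, m)
    stats = {
        "n_queries": len(smallrnas),
        "n_suppressed": n_suppressed,
        "n_hits": len(all_hits),
        "hits": all_hits,
        "n_targeted_transcripts": len(targets),
        "targeting_smallrnas": sorted({h.smallrna_id for h in all_hits}),
    }
    return targets, stats


def mirna_seed_targets(
    mirnas: SequenceSet,
    transcripts: SequenceSet,
    seed_span: tuple[int, int] = (2, 8),
) -> dict[str, set[str]]:
    """Seed-complementarity microRNA target stand-in.

    A transcript is a target of a miRNA iff the reverse complement of the
    miRNA seed (1-based positions ``seed_span``, default 2-8) occurs
    exactly in the transcript. This deliberately simple rule replaces
    external target-score predictors; it does not reproduce their scores.
    """
    lo, hi = seed_span
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid seed_span {seed_span}")
    targets: dict[str, set[str]] = {}
    sites = {}
    for mid, seq in mirnas.items():
        if len(seq) < hi:
            raise ValueError(
                f"miRNA {mid!r} length {len(seq)} shorter than seed span end {hi}"
            )
        sites[mid] = reverse_complement(seq[lo - 1 : hi])
    for tid, tseq in transcripts.items():
        for mid, site in sites.items():
            if site in tseq:
                targets.setdefault(tid, set()).add(mid)
    return targets


def stage_profile(ids: set[str] | list[str], table: pd.DataFrame) -> pd.DataFrame:
    """Per-stage mean and dispersion of abundance for a set of ids.

    ``table`` is indexed by id with one numeric column per stage (an RPM
    table or an expression matrix's ``.values``). Unknown ids are skipped
    with a warning.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("empty id set")
    known = [i for i in ids if i in table.index]
    unknown = sorted(set(ids) - set(known))
    if unknown:
        logger.warning("%d unknown ids skipped in stage_profile", len(unknown))
    if not known:
        raise ValueError("no known ids in stage_profile")
    sub = table.loc[known]
    return pd.DataFrame(
        {"mean": sub.mean(axis=0), "sd": sub.std(axis=0, ddof=0), "n": len(known)}
    ).rename_axis("stage")


# -- TSV plumbing ------------------------------------------------------------


def read_smallrna_table(path: str | os.PathLike) -> list[SmallRNARecord]:
    """TSV with columns id, sequence, then one RPM column per stage."""
    from .io_formats import FormatError, normalize_sequence

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    for col in ("id", "sequence"):
        if col not in df.columns:
            raise FormatError(f"small-RNA table missing column {col!r}")
    if df["id"].duplicated().any():
        dup = sorted(set(df["id"][df["id"].duplicated()]))
        raise FormatError(f"duplicate small-RNA id(s): {dup[:5]}")
    stages = [c for c in df.columns if c not in ("id", "sequence")]
    return [
        SmallRNARecord(
            id=row["id"],
            sequence=normalize_sequence(str(row["sequence"])),
            rpm_by_stage={s: float(row[s]) for s in stages},
        )
        for _, row in df.iterrows()
    ]


def write_smallrna_table(
    records: list[SmallRNARecord], path: str | os.PathLike, **kwargs
) -> None:
    stages = sorted({s for r in records for s in r.rpm_by_stage})
    rows = [
        {"id": r.id, "sequence": r.sequence, **{s: r.rpm_by_stage.get(s, 0.0) for s in stages}}
        for r in records
    ]
    write_tsv(pd.DataFrame(rows, columns=["id", "sequence", *stages]), path, **kwargs)


def hits_frame(hits: list[TargetHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "smallrna_id": h.smallrna_id,
                "transcript_id": h.transcript_id,
                "start": h.start,
                "orientation": h.orientation,
                "mismatches": h.mismatches,
            }
            for h in hits
        ],
        columns=["smallrna_id", "transcript_id", "start", "orientation", "mismatches"],
    )
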