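"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the matcher oracle is a
per-offset character-comparison sliding window (a numba-jitted variant for
large instances), and the ORF oracle enumerates every ATG in six frames.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def sliding_window_hits(qseq, transcripts, v, m):
    """Pure-Python brute force: every offset, both orientations.

    Returns (sorted hit tuples, suppressed flag); hit tuples are
    (transcript_id, start, orientation, mismatches).
    """
    hits = []
    for orient, pat in (("sense", qseq), ("antisense", rc(qseq))):
        k = len(pat)
        for tid, seq in transcripts.items():
            for s in range(len(seq) - k + 1):
                mm = 0
                for a, b in zip(pat, seq[s : s + k]):
                    if a != b or a == "N" or b == "N":
                        mm += 1
                    if mm > v:
                        break
                else:
                    hits.append((tid, s, orient, mm))
    if m is not None and len(hits) > m:
        return [], True
    return sorted(hits), False


try:
    from numba import njit

    @njit(cache=False)
    def _scan(concat, bounds, pat, v, out_t, out_s, out_mm):
        n = 0
        k = pat.shape[0]
        for t in range(bounds.shape[0] - 1):
            lo = bounds[t]
            hi = bounds[t + 1]
            for s in range(lo, hi - k + 1):
                mm = 0
                for j in range(k):
                    a = pat[j]
                    b = concat[s + j]
                    if a != b or a == 4 or b == 4:
                        mm += 1
                        if mm > v:
                            break
                if mm <= v:
                    out_t[n] = t
                    out_s[n] = s - lo
                    out_mm[n] = mm
                    n += 1
        return n

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is expected in the test env
    HAVE_NUMBA = False


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _enc(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.uint8)


class JitOracle:
    """Numba-backed sliding-window oracle for large random instances."""

    def __init__(self, transcripts):
        self.ids = list(transcripts.ids())
        seqs = [transcripts[t] for t in self.ids]
        self.bounds = np.concatenate(
            [[0], np.cumsum([len(s) for s in seqs])]
        ).astype(np.int64)
        self.concat = (
            np.concatenate([_enc(s) for s in seqs])
            if seqs
            else np.empty(0, dtype=np.uint8)
        )
        cap = int(self.bounds[-1]) * 2 + 16
        self._t = np.empty(cap, dtype=np.int64)
        self._s = np.empty(cap, dtype=np.int64)
        self._mm = np.empty(cap, dtype=np.int64)

    def hits(self, qseq: str, v: int, m):
        found = []
        for orient, pat in (("sense", qseq), ("antisense", rc(qseq))):
            n = _scan(
                self.concat, self.bounds, _enc(pat), v, self._t, self._s, self._mm
            )
            for i in range(n):
                found.append(
                    (self.ids[self._t[i]], int(self._s[i]), orient, int(self._mm[i]))
                )
        if m is not None and len(found) > m:
            return [], True
        return sorted(found), False


def orf_scan_codons(seq: str) -> int:
    """Six-frame ORF oracle: try every ATG, count codons to stop or end."""
    best = 0
    for s in (seq, rc(seq)):
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            n = 0
            j = i
            while j + 3 <= len(s):
                if s[j : j + 3] in ("TAA", "TAG", "TGA"):
                    break
                n += 1
                j += 3
            best = max(best, n)
    return best
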