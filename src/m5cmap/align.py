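"""Seed-and-extend local alignment to the reference set, with SAM output.

Two modes share one engine:

* ``standard`` — reads aligned as-is (CLIP libraries).
* ``bisulfite`` — read and reference are both collapsed C->T for seeding and
  scoring ("three-letter" alignment), so a read's chemical conversion
  pattern cannot penalize its placement; the original read sequence is kept
  for downstream per-cytosine counting.

Candidate loci come from exact k-mer seed hits.  Because the library
generators emit substitution errors only, each candidate is first scored as
a gapless overlay (equivalent to full-width banded extension with no indel
path taken); the affine-gap Smith-Waterman extension runs only when that
fast path misses the score threshold.  Reported alignments are sense-strand
by default — CLIP and amplicon reads are sense to the RNA — with
reverse-complement search behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pysam

from .preprocess import ProcessedRead, read_processed_fastq
from .synthetic_data import ReferenceSet

log = logging.getLogger("m5cmap")

__all__ = [
    "ScoringScheme",
    "AlignerParams",
    "AlignmentRecord",
    "Aligner",
    "local_align",
    "align_read",
    "align_fastq",
    "write_sam",
    "read_sam",
]

_C2T = str.maketrans("C", "T")
_RC = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ScoringScheme:
    """Affine scores; a gap of length k scores gap_open + (k-1)*gap_extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class AlignerParams:
    k: int = 12
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    min_score_fraction: float = 0.66  # of the maximum possible (match * |query|)
    max_candidates: int = 20
    search_reverse_complement: bool = False

    def min_score(self, query_length: int) -> float:
        return self.min_score_fraction * self.scoring.match * query_length

    def band(self, query_length: int) -> int:
        return 8 + math.ceil(0.1 * query_length)


@dataclass(frozen=True)
class AlignmentRecord:
    """A read placed on a reference.  ``start`` is the 0-based position of the
    leftmost aligned reference base; ``cigar`` consumes exactly
    ``aligned_length`` reference bases (M/D ops)."""

    read_id: str
    umi: str
    reference: str
    start: int
    strand: str
    aligned_length: int
    score: int
    cigar: str
    original_sequence: str

    @property
    def end(self) -> int:  # 0-based exclusive
        return self.start + self.aligned_length


# ---------------------------------------------------------------------------
# optimal local alignment (Gotoh affine DP with traceback)
# ---------------------------------------------------------------------------

def local_align(
    query: str, target: str, scoring: ScoringScheme = ScoringScheme()
) -> tuple[int, str, int, int, int]:
    """Optimal Smith-Waterman local alignment of ``query`` against ``target``.

    Returns ``(score, cigar, target_offset, query_start, query_end)`` where
    the cigar covers only the aligned core (M/I/D; I consumes query, D
    consumes target).  Ties are resolved deterministically toward the
    smallest target offset and then the shortest alignment: the endpoint
    with the smallest target column (then query row) wins, and traceback
    prefers diagonal over gap moves.  An all-negative score space yields
    ``(0, "", 0, 0, 0)``.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    m, n = len(query), len(target)
    sc = scoring
    NEG = -(10 ** 9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming target (D)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming query (I)
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            Ei[j] = max(Hi[j - 1] + sc.gap_open, Ei[j - 1] + sc.gap_extend)
            Fi[j] = max(Hi1[j] + sc.gap_open, Fi1[j] + sc.gap_extend)
            diag = Hi1[j - 1] + (sc.match if qi == target[j - 1] else sc.mismatch)
            h = diag
            if Ei[j] > h:
                h = Ei[j]
            if Fi[j] > h:
                h = Fi[j]
            if h < 0:
                h = 0
            Hi[j] = h
            # endpoint tie-break: smaller j, then smaller i (strict > keeps first)
            if h > best:
                best, bi, bj = h, i, j
    if best == 0:
        return 0, "", 0, 0, 0

    # traceback, preferring M over I over D (shortest reference span on ties)
    ops: list[str] = []
    i, j, state = bi, bj, "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] == 0:
                break
            diag = H[i - 1][j - 1] + (
                sc.match if query[i - 1] == target[j - 1] else sc.mismatch
            )
            if H[i][j] == diag:
                ops.append("M")
                i -= 1
                j -= 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ops.append("I")
            if F[i][j] == H[i - 1][j] + sc.gap_open:
                state = "H"
            i -= 1
        else:  # E
            ops.append("D")
            if E[i][j] == H[i][j - 1] + sc.gap_open:
                state = "H"
            j -= 1
    ops.reverse()
    cigar = _run_length(ops)
    return best, cigar, j, i, bi


def _run_length(ops: list[str]) -> str:
    out = []
    prev, count = None, 0
    for op in ops:
        if op == prev:
            count += 1
        else:
            if prev is not None:
                out.append(f"{count}{prev}")
            prev, count = op, 1
    if prev is not None:
        out.append(f"{count}{prev}")
    return "".join(out)


def _cigar_ref_len(cigar: str) -> int:
    total, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MD=X":
                total += int(num)
            num = ""
    return total


# ---------------------------------------------------------------------------
# seeded alignment against a ReferenceSet
# ---------------------------------------------------------------------------

class Aligner:
    """K-mer-seeded aligner over a ReferenceSet, standard or bisulfite mode."""

    def __init__(self, refs: ReferenceSet, mode: str = "standard",
                 params: AlignerParams | None = None):
        if mode not in ("standard", "bisulfite"):
            raise ValueError(f"unknown mode {mode!r}")
        self.refs = refs
        self.mode = mode
        self.params = params or AlignerParams()
        self._space: dict[str, str] = {}   # reference in scoring space
        self._codes: dict[str, np.ndarray] = {}
        self._index: dict[str, list[tuple[str, int]]] = {}
        k = self.params.k
        for name in sorted(refs.sequences):
            seq = refs.sequences[name]
            sp = seq.translate(_C2T) if mode == "bisulfite" else seq
            self._space[name] = sp
            self._codes[name] = np.frombuffer(sp.encode(), np.uint8)
            for p in range(len(sp) - k + 1):
                self._index.setdefault(sp[p : p + k], []).append((name, p))

    # -- candidate generation ----------------------------------------------

    def _candidates(self, q: str) -> list[tuple[str, int]]:
        k = self.params.k
        L = len(q)
        probes = sorted({0, (L - k) // 2, L - k})
        cand: set[tuple[str, int]] = set()
        for p in probes:
            for name, hit in self._index.get(q[p : p + k], ()):
                cand.add((name, hit - p))
        if not cand:  # dense rescue scan for reads whose probe k-mers hit errors
            for p in range(0, L - k + 1):
                for name, hit in self._index.get(q[p : p + k], ()):
                    cand.add((name, hit - p))
                if cand:
                    break
        out = sorted(cand)
        return out[: self.params.max_candidates]

    def _score_gapless(self, q_codes: np.ndarray, name: str, off: int) -> int | None:
        codes = self._codes[name]
        L = len(q_codes)
        if off < 0 or off + L > len(codes):
            return None
        mism = int(np.count_nonzero(codes[off : off + L] != q_codes))
        sc = self.params.scoring
        return sc.match * L + (sc.mismatch - sc.match) * mism

    def _align_oriented(self, q: str) -> tuple | None:
        """Best (score, ref, start, cigar, aligned_len) for one orientation."""
        p = self.params
        sp = q.translate(_C2T) if self.mode == "bisulfite" else q
        L = len(q)
        if L < p.k:
            return None
        cands = self._candidates(sp)
        if not cands:
            return None
        q_codes = np.frombuffer(sp.encode(), np.uint8)
        min_score = p.min_score(L)

        best = None  # (score, ref, start, cigar, aligned_len)
        for name, off in cands:
            s = self._score_gapless(q_codes, name, off)
            if s is None:
                continue
            key = (s, name, off)
            if best is None or (s, ) > (best[0], ) or (
                s == best[0] and (name, off) < (best[1], best[2])
            ):
                best = (s, name, off, f"{L}M", L)
        if best is not None and best[0] >= min_score:
            return best

        # banded affine extension around each candidate diagonal
        band = p.band(L)
        for name, off in cands:
            target = self._space[name]
            w0 = max(0, off - band)
            w1 = min(len(target), off + L + band)
            score, cigar, t_off, q_start, q_end = local_align(sp, target[w0:w1], p.scoring)
            if score == 0:
                continue
            start = w0 + t_off
            pre = f"{q_start}S" if q_start else ""
            post = f"{L - q_end}S" if q_end < L else ""
            full_cigar = pre + cigar + post
            alen = _cigar_ref_len(cigar)
            cand_rec = (score, name, start, full_cigar, alen)
            if best is None or score > best[0] or (
                score == best[0] and (name, start) < (best[1], best[2])
            ):
                best = cand_rec
        if best is not None and best[0] >= p.min_score(L):
            return best
        return None

    def align(self, read: ProcessedRead) -> AlignmentRecord | None:
        fwd = self._align_oriented(read.sequence)
        if fwd is not None:
            score, name, start, cigar, alen = fwd
            return AlignmentRecord(read.read_id, read.umi, name, start, "+",
                                   alen, score, cigar, read.sequence)
        if self.params.search_reverse_complement:
            rc = read.sequence.translate(_RC)[::-1]
            rev = self._align_oriented(rc)
            if rev is not None:
                score, name, start, cigar, alen = rev
                return AlignmentRecord(read.read_id, read.umi, name, start, "-",
                                       alen, score, cigar, rc)
        return None


def align_read(
    read: ProcessedRead,
    refs: ReferenceSet,
    mode: str = "standard",
    params: AlignerParams | None = None,
) -> AlignmentRecord | None:
    """One-shot convenience wrapper; builds a fresh index per call."""
    return Aligner(refs, mode, params).align(read)


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------

def _sam_header(refs: ReferenceSet) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(refs.sequences[n])} for n in refs.sequences],
    }


def write_sam(records, refs: ReferenceSet, path) -> int:
    header = pysam.AlignmentHeader.from_dict(_sam_header(refs))
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            seg.query_sequence = rec.original_sequence
            seg.flag = 16 if rec.strand == "-" else 0
            seg.reference_id = list(refs.sequences).index(rec.reference)
            seg.reference_start = rec.start
            seg.mapping_quality = 60
            seg.cigarstring = rec.cigar
            seg.set_tag("RX", rec.umi)
            seg.set_tag("AS", int(rec.score))
            out.write(seg)
            n += 1
    return n


def read_sam(path) -> list[AlignmentRecord]:
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    umi=seg.get_tag("RX") if seg.has_tag("RX") else "",
                    reference=seg.reference_name,
                    start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    aligned_length=seg.reference_length or 0,
                    score=int(seg.get_tag("AS")) if seg.has_tag("AS") else 0,
                    cigar=seg.cigarstring or "",
                    original_sequence=seg.query_sequence or "",
                )
            )
    return records


def align_fastq(
    fastq_path,
    refs: ReferenceSet,
    sam_path,
    mode: str = "standard",
    params: AlignerParams | None = None,
    umi_length: int = 10,
) -> dict[str, int]:
    """Align a preprocessed FASTQ and write SAM; returns mapped/unmapped counts."""
    aligner = Aligner(refs, mode, params)
    records = []
    n_unmapped = 0
    for read in read_processed_fastq(fastq_path, umi_length):
        rec = aligner.align(read)
        if rec is None:
            n_unmapped += 1
        else:
            records.append(rec)
    write_sam(records, refs, sam_path)
    counts = {"mapped": len(records), "unmapped": n_unmapped}
    log.info("stage=align in=%d out=%d dropped=%d",
             len(records) + n_unmapped, len(records), n_unmapped)
    return counts
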