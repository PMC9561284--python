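"""Read preparation: 3' adapter trimming, UMI extraction, length filtering.

The contract mirrors standard eCLIP read preparation: trim the 3' sequencing
adapter, move the 5' UMI from the read sequence into the read identifier
(after an underscore), and discard inserts shorter than 18 nt.  The length
cutoff applies to the insert after UMI removal, since the UMI is not
biological sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .synthetic_data import _open_text

log = logging.getLogger("m5cmap")

__all__ = [
    "ProcessedRead",
    "StageCounts",
    "trim_adapter",
    "extract_umi",
    "filter_length",
    "preprocess_fastq",
    "DEFAULT_MIN_LENGTH",
]

DEFAULT_MIN_LENGTH = 18  # inserts shorter than 18 nt are discarded
DEFAULT_MIN_OVERLAP = 3
DEFAULT_MAX_ERROR_RATE = 0.1


@dataclass(frozen=True)
class ProcessedRead:
    read_id: str
    umi: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class StageCounts:
    """in = out + dropped, per stage."""

    stage: str
    n_in: int = 0
    n_out: int = 0
    n_dropped: int = 0

    def log_line(self) -> str:
        return f"stage={self.stage} in={self.n_in} out={self.n_out} dropped={self.n_dropped}"


def trim_adapter(
    seq: str,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> str:
    """Remove the longest 3' suffix of ``seq`` matching a prefix of ``adapter``.

    A suffix of length ``ov`` (``ov >= min_overlap``) is removed when its
    Hamming distance to ``adapter[:ov]`` is at most ``max_error_rate * ov``.
    Returns ``seq`` unchanged when no qualifying suffix exists.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0.0 <= max_error_rate < 0.5:
        raise ValueError("max_error_rate must be in [0, 0.5)")
    max_ov = min(len(seq), len(adapter))
    for ov in range(max_ov, min_overlap - 1, -1):
        tail = seq[-ov:]
        mism = sum(a != b for a, b in zip(tail, adapter[:ov]))
        if mism <= max_error_rate * ov:
            return seq[:-ov]
    return seq


def extract_umi(seq: str, umi_length: int) -> tuple[str, str]:
    """Split the first ``umi_length`` bases off as the UMI."""
    if umi_length < 0:
        raise ValueError("umi_length must be >= 0")
    if len(seq) <= umi_length and umi_length > 0:
        raise ValueError("read shorter than UMI")
    return seq[:umi_length], seq[umi_length:]


def filter_length(reads, min_length: int = DEFAULT_MIN_LENGTH):
    """Keep reads whose insert length is >= ``min_length``."""
    reads = list(reads)
    kept = [r for r in reads if r.length >= min_length]
    counts = StageCounts("length_filter", len(reads), len(kept), len(reads) - len(kept))
    log.info(counts.log_line())
    return kept


def preprocess_fastq(
    in_path,
    out_path,
    adapter: str,
    umi_length: int,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> list[StageCounts]:
    """trim -> UMI-extract -> length-filter a FASTQ file.

    The UMI is appended to the read name after an underscore; output
    qualities are sliced alongside the sequence.  Returns the per-stage
    conservation counts (in = out + dropped at every stage).
    """
    trim = StageCounts("trim_adapter")
    umi_stage = StageCounts("extract_umi")
    length_stage = StageCounts("length_filter")

    with _open_text(in_path, "rt") as fin, _open_text(out_path, "wt") as fout:
        for title, seq, qual in FastqGeneralIterator(fin):
            trim.n_in += 1
            if adapter:
                seq = trim_adapter(seq, adapter, min_overlap, max_error_rate)
                qual = qual[: len(seq)]
            trim.n_out += 1

            umi_stage.n_in += 1
            if umi_length > 0 and len(seq) <= umi_length:
                umi_stage.n_dropped += 1
                continue
            umi, seq = extract_umi(seq, umi_length)
            qual = qual[umi_length:]
            umi_stage.n_out += 1

            length_stage.n_in += 1
            if len(seq) < min_length:
                length_stage.n_dropped += 1
                continue
            length_stage.n_out += 1
            name = title.split()[0]
            if umi:
                name = f"{name}_{umi}"
            fout.write(f"@{name}\n{seq}\n+\n{qual}\n")

    counts = [trim, umi_stage, length_stage]
    for c in counts:
        log.info(c.log_line())
    return counts


def read_processed_fastq(path, umi_length: int):
    """Yield ProcessedRead objects from a preprocessed FASTQ (UMI in the id)."""
    with _open_text(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            name = title.split()[0]
            umi = name.rsplit("_", 1)[1] if (umi_length > 0 and "_" in name) else ""
            yield ProcessedRead(name, umi, seq)
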