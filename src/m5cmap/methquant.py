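"""Bisulfite conversion quantification and replicate statistics.

From bisulfite-mode alignments (whose SEQ field holds the original,
chemistry-affected read) this module tallies, per reference cytosine,
reads that still show C (non-converted, i.e. protected by m5C), reads that
show T (converted), and anything else (sequencing error).  The converted
fraction n_T / (n_C + n_T) excludes the error column from its denominator.
Condition comparisons use the two-tailed independent Student's t-test over
per-replicate converted fractions (pooled variance by default; Welch via
flag).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import ReferenceSet

__all__ = [
    "SiteComparison",
    "conversion_table",
    "overall_conversion_rate",
    "compare_conditions",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

DEFAULT_MIN_COVERAGE = 10  # below this, converted_fraction is not reported


def _aligned_columns(cigar: str, start: int):
    """Yield (ref_pos0, query_idx) for match/mismatch columns of a record."""
    rpos, qpos = start, 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op in "M=X":
            for i in range(n):
                yield rpos + i, qpos + i
            rpos += n
            qpos += n
        elif op in "IS":
            qpos += n
        elif op in "DN":
            rpos += n


def conversion_table(
    records,
    refs: ReferenceSet,
    region: tuple[str, int, int],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Per-cytosine conversion counts over ``region`` (1-based inclusive).

    One row per reference C in the region: n_nonconverted (read base C),
    n_converted (read base T), n_other, coverage and converted_fraction
    (NaN when n_C + n_T == 0 or coverage < ``min_coverage``).
    """
    ref_name, r_start, r_end = region
    if ref_name not in refs.sequences:
        raise ValueError(f"region on unknown reference {ref_name!r}")
    L = refs.length(ref_name)
    if not (1 <= r_start <= r_end <= L):
        raise ValueError("region out of reference bounds")
    seq = refs.sequences[ref_name]
    c_pos0 = np.array(
        [i for i in range(r_start - 1, r_end) if seq[i] == "C"], dtype=np.int64
    )
    n_C = np.zeros(L, np.int64)
    n_T = np.zeros(L, np.int64)
    n_other = np.zeros(L, np.int64)

    # group records by placement so identically-aligned reads tally as a matrix
    groups: dict[tuple[int, str], list[str]] = {}
    odd = []
    for r in records:
        if r.reference != ref_name:
            continue
        if re.fullmatch(r"\d+M", r.cigar):
            groups.setdefault((r.start, r.cigar), []).append(r.original_sequence)
        else:
            odd.append(r)

    for (start, cigar), seqs in groups.items():
        span = int(cigar[:-1])
        cols = c_pos0[(c_pos0 >= start) & (c_pos0 < start + span)]
        if cols.size == 0:
            continue
        mat = np.frombuffer("".join(seqs).encode(), np.uint8).reshape(len(seqs), span)
        sub = mat[:, cols - start]
        n_C[cols] += (sub == ord("C")).sum(axis=0)
        n_T[cols] += (sub == ord("T")).sum(axis=0)
        n_other[cols] += ((sub != ord("C")) & (sub != ord("T"))).sum(axis=0)

    c_set = set(c_pos0.tolist())
    for r in odd:
        for rpos, qidx in _aligned_columns(r.cigar, r.start):
            if rpos in c_set:
                base = r.original_sequence[qidx]
                if base == "C":
                    n_C[rpos] += 1
                elif base == "T":
                    n_T[rpos] += 1
                else:
                    n_other[rpos] += 1

    rows = []
    for p0 in c_pos0:
        cc, tt, oo = int(n_C[p0]), int(n_T[p0]), int(n_other[p0])
        cov = cc + tt + oo
        frac = tt / (cc + tt) if (cc + tt) > 0 and cov >= min_coverage else np.nan
        rows.append((ref_name, int(p0) + 1, refs.locate(ref_name, int(p0) + 1),
                     cc, tt, oo, cov, frac))
    return pd.DataFrame(
        rows,
        columns=["reference", "position", "label", "n_nonconverted",
                 "n_converted", "n_other", "coverage", "converted_fraction"],
    )


def overall_conversion_rate(
    table: pd.DataFrame, exclude: list[tuple[str, int]] | None = None
) -> float:
    """Pooled conversion rate sum(n_T) / sum(n_T + n_C) over non-excluded rows.

    ``exclude`` lists (reference, 1-based position) pairs — typically the
    methylation target sites — to leave out of the background estimate.
    """
    excl = set(exclude or [])
    sub = table[~table.apply(lambda r: (r["reference"], r["position"]) in excl, axis=1)]
    if sub.empty:
        raise ValueError("all rows excluded")
    denom = int(sub["n_converted"].sum() + sub["n_nonconverted"].sum())
    if denom == 0:
        raise ValueError("no informative C/T calls in table")
    return float(sub["n_converted"].sum() / denom)


@dataclass
class SiteComparison:
    site: str
    label_a: str
    label_b: str
    fractions_a: tuple[float, ...]
    fractions_b: tuple[float, ...]
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def compare_conditions(
    site: str,
    fractions_a,
    fractions_b,
    label_a: str = "a",
    label_b: str = "b",
    welch: bool = False,
) -> SiteComparison:
    """Two-tailed independent t-test between per-replicate converted fractions.

    Student's pooled-variance test by default (df = n1 + n2 - 2); Welch's
    correction behind the flag.  Requires >= 2 replicates per condition.
    """
    a = np.asarray(list(fractions_a), float)
    b = np.asarray(list(fractions_b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per condition")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(a.size + b.size - 2)
    return SiteComparison(
        site=site,
        label_a=label_a,
        label_b=label_b,
        fractions_a=tuple(a),
        fractions_b=tuple(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t_statistic=float(res.statistic),
        degrees_of_freedom=df,
        p_value=float(res.pvalue),
    )
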