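"""Crosslink-site analysis from CLIP alignments.

The chain is: UMI deduplication -> per-position RT-stop and coverage
profiles -> depth-normalized (RPM) tracks and IP/SMInput ratio tracks ->
single-nucleotide crosslink-site calling (truncation mutant vs wild type)
-> windowed SMInput-normalized enrichment with Fisher/Benjamini-Hochberg
statistics -> read-class composition.

The RT stop of a read is its 5' start: in truncation-type CLIP libraries
reverse transcription terminates at the crosslinked base, so the read
starts exactly on the modified cytosine ("+1 site" convention; an
alternative start-minus-one convention is available via ``stop_offset``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import AlignmentRecord
from .synthetic_data import ReferenceSet

log = logging.getLogger("m5cmap")

__all__ = [
    "StopProfile",
    "SiteCallParams",
    "deduplicate",
    "stop_profile",
    "normalize_rpm",
    "enrichment_track",
    "call_sites",
    "window_enrichment",
    "class_summary",
    "write_bedgraph",
    "write_sites_bed",
]


@dataclass
class StopProfile:
    """Per-reference RT-stop and coverage counts (index 0 = position 1)."""

    stops: dict[str, np.ndarray]
    coverage: dict[str, np.ndarray]
    library_size: int

    def check(self) -> None:
        total = sum(int(a.sum()) for a in self.stops.values())
        if total != self.library_size:
            raise AssertionError("sum of stops != library_size")
        for name, st in self.stops.items():
            if np.any(self.coverage[name] < st):
                raise AssertionError(f"coverage < stops on {name}")


def deduplicate(records) -> list[AlignmentRecord]:
    """Collapse PCR duplicates on the (reference, start, strand, UMI,
    aligned_length) key, keeping the highest-scoring record (ties: first
    read_id).  Output order is deterministic and independent of input order."""
    records = list(records)
    ordered = sorted(
        records,
        key=lambda r: (r.reference, r.start, r.strand, r.umi, r.aligned_length,
                       -r.score, r.read_id),
    )
    kept: list[AlignmentRecord] = []
    prev_key = None
    for r in ordered:
        key = (r.reference, r.start, r.strand, r.umi, r.aligned_length)
        if key != prev_key:
            kept.append(r)
            prev_key = key
    log.info("stage=dedup in=%d out=%d dropped=%d",
             len(records), len(kept), len(records) - len(kept))
    return kept


def stop_profile(records, refs: ReferenceSet, stop_offset: int = 0) -> StopProfile:
    """Counts per position: stops at each read's 5' start (+``stop_offset``),
    coverage over the full aligned span.  Expects deduplicated records."""
    stops = {n: np.zeros(refs.length(n), dtype=np.int64) for n in refs.sequences}
    cov_diff = {n: np.zeros(refs.length(n) + 1, dtype=np.int64) for n in refs.sequences}
    n_rec = 0
    for r in records:
        L = refs.length(r.reference)
        if r.start < 0 or r.end > L:
            raise ValueError(f"record {r.read_id} outside reference bounds")
        pos = r.start + stop_offset
        pos = min(max(pos, 0), L - 1)
        stops[r.reference][pos] += 1
        cov_diff[r.reference][r.start] += 1
        cov_diff[r.reference][r.end] -= 1
        n_rec += 1
    coverage = {n: np.cumsum(d[:-1]) for n, d in cov_diff.items()}
    prof = StopProfile(stops, coverage, n_rec)
    prof.check()
    return prof


def normalize_rpm(profile: StopProfile, track: str = "stops") -> dict[str, np.ndarray]:
    """Reads-per-million track: count * 1e6 / library_size."""
    if profile.library_size <= 0:
        raise ValueError("library_size must be positive for RPM normalization")
    source = profile.stops if track == "stops" else profile.coverage
    scale = 1e6 / profile.library_size
    return {n: a * scale for n, a in source.items()}


def enrichment_track(ip: StopProfile, smi: StopProfile) -> dict[str, np.ndarray]:
    """Depth-normalized IP/SMInput coverage ratio:
    ((c_ip+1)/S_ip) / ((c_smi+1)/S_smi) per position."""
    if set(ip.coverage) != set(smi.coverage):
        raise ValueError("IP and SMInput profiles are on different references")
    if ip.library_size <= 0 or smi.library_size <= 0:
        raise ValueError("both library sizes must be positive")
    out = {}
    for name in ip.coverage:
        num = (ip.coverage[name] + 1) / ip.library_size
        den = (smi.coverage[name] + 1) / smi.library_size
        out[name] = num / den
    return out


@dataclass
class SiteCallParams:
    min_coverage: int = 20
    min_stop_fraction: float = 0.1
    min_ratio: float = 4.0
    epsilon: float = 0.5  # count pseudocount in the depth-scaled stop ratio


def call_sites(
    mutant: StopProfile,
    wt: StopProfile,
    params: SiteCallParams | None = None,
    refs: ReferenceSet | None = None,
) -> pd.DataFrame:
    """Call single-nucleotide crosslink sites from the truncation contrast.

    Every position with mutant coverage >= ``min_coverage`` is evaluated; a
    position passes when its mutant stop fraction (stops/coverage) reaches
    ``min_stop_fraction`` and the depth-normalized stop ratio
    ((stops_mutant + eps)/S_mutant) / ((stops_wt + eps)/S_wt) reaches
    ``min_ratio`` (pseudocount on counts, then library-size scaling; with
    equal library sizes this is (s + 0.5)/(w + 0.5)).  Output is
    sorted by descending ratio and includes non-passing evaluated positions.
    """
    p = params or SiteCallParams()
    if set(mutant.stops) != set(wt.stops):
        raise ValueError("profiles are on different reference sets")
    rows = []
    for name in mutant.stops:
        cov = mutant.coverage[name]
        idx = np.flatnonzero(cov >= p.min_coverage)
        if idx.size == 0:
            continue
        S_mut = max(mutant.library_size, 1)
        S_wt = max(wt.library_size, 1)
        mut_rpm = mutant.stops[name][idx] * 1e6 / S_mut
        wt_rpm = wt.stops[name][idx] * 1e6 / S_wt
        frac = mutant.stops[name][idx] / cov[idx]
        ratio = ((mutant.stops[name][idx] + p.epsilon) / S_mut) / (
            (wt.stops[name][idx] + p.epsilon) / S_wt
        )
        passed = (frac >= p.min_stop_fraction) & (ratio >= p.min_ratio)
        for i, pos0 in enumerate(idx):
            pos = int(pos0) + 1
            rows.append(
                (name, pos,
                 refs.locate(name, pos) if refs is not None else f"{name}:{pos}",
                 mut_rpm[i], wt_rpm[i], frac[i], ratio[i], bool(passed[i]))
            )
    df = pd.DataFrame(
        rows,
        columns=["reference", "position", "label", "stop_rpm_mutant",
                 "stop_rpm_wt", "stop_fraction", "ratio", "passed"],
    )
    return df.sort_values(
        ["ratio", "reference", "position"], ascending=[False, True, True]
    ).reset_index(drop=True)


def window_enrichment(
    ip: StopProfile,
    smi: StopProfile,
    window: int = 50,
    step: int = 25,
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> pd.DataFrame:
    """Windowed IP-over-SMInput enrichment on deduplicated read starts.

    Windows (0-based half-open) tile each reference.  Each window gets a
    two-sided Fisher exact test on the 2x2 table (in-window vs rest of the
    library, IP vs SMInput), Benjamini-Hochberg adjustment across all
    windows, and a library-size-scaled fold change with +1 pseudocounts.
    Significance is adjusted p < ``alpha`` AND fold change >= ``min_fold``.
    """
    if window <= 0 or window < step or step <= 0:
        raise ValueError("require window >= step > 0")
    if set(ip.stops) != set(smi.stops):
        raise ValueError("profiles are on different reference sets")
    S_ip = max(ip.library_size, 1)
    S_smi = max(smi.library_size, 1)
    rows = []
    for name in sorted(ip.stops):
        L = len(ip.stops[name])
        ip_cum = np.concatenate([[0], np.cumsum(ip.stops[name])])
        smi_cum = np.concatenate([[0], np.cumsum(smi.stops[name])])
        start = 0
        while start < L:
            end = min(start + window, L)
            ip_in = int(ip_cum[end] - ip_cum[start])
            smi_in = int(smi_cum[end] - smi_cum[start])
            ip_out = ip.library_size - ip_in
            smi_out = smi.library_size - smi_in
            fold = ((ip_in + 1) / S_ip) / ((smi_in + 1) / S_smi)
            rows.append([name, start, end, ip_in, smi_in, ip_out, smi_out, fold])
            if end == L:
                break
            start += step
    df = pd.DataFrame(
        rows, columns=["reference", "start", "end", "ip_count", "smi_count",
                       "ip_out", "smi_out", "fold_change"]
    )
    pvals = [
        stats.fisher_exact(
            [[r.ip_count, r.ip_out], [r.smi_count, r.smi_out]], "two-sided"
        )[1]
        for r in df.itertuples()
    ]
    df["p_value"] = pvals
    df["adjusted_p"] = multipletests(pvals, method="fdr_bh")[1] if len(df) else []
    df["log2_fold_change"] = np.log2(df["fold_change"])
    df["significant"] = (df["adjusted_p"] < alpha) & (df["fold_change"] >= min_fold)
    return df.drop(columns=["ip_out", "smi_out"])


def class_summary(records, refs: ReferenceSet) -> pd.DataFrame:
    """Mapped-read fraction per class, assigned by the interval containing
    each record's start (pre-rRNA regions all roll up into 'rRNA')."""
    counts: dict[str, int] = {}
    n = 0
    for r in records:
        cls = refs.class_of(r.reference, r.start + 1)
        counts[cls] = counts.get(cls, 0) + 1
        n += 1
    rows = [(cls, c, c / n if n else 0.0) for cls, c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["class", "n_reads", "fraction"])


# ---------------------------------------------------------------------------
# track / interval output
# ---------------------------------------------------------------------------

def write_bedgraph(tracks: dict[str, np.ndarray], path) -> None:
    """Per-position values as bedGraph (0-based half-open), runs collapsed."""
    with open(path, "w") as fh:
        for name in tracks:
            vals = np.asarray(tracks[name], dtype=float)
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{name}\t{s}\t{e}\t{v:.6g}\n")


def write_sites_bed(df: pd.DataFrame, path, passed_only: bool = True) -> None:
    sub = df[df["passed"]] if passed_only else df
    with open(path, "w") as fh:
        for r in sub.itertuples():
            fh.write(f"{r.reference}\t{r.position - 1}\t{r.position}\t{r.label}\t"
                     f"{r.ratio:.4g}\t+\n")
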