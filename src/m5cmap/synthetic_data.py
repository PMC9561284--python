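"""Synthetic reference sets, ground truth, and FASTQ library generation.

Everything downstream of this module (trimming, alignment, crosslink-site
calling, bisulfite conversion quantification) is exercised on libraries built
here.  The generator emulates the two experimental arms of an m5C mapping
study on ribosomal RNA:

* **miCLIP/eCLIP arm** — immunoprecipitation libraries in which a
  catalytically trapped methyltransferase mutant crosslinks covalently to its
  target cytosine, so reverse transcription stops there and the read's 5'
  end lands exactly on the modified C.  Wild-type IP libraries show binding
  enrichment (e.g. over the 5'ETS of the pre-rRNA) but no truncation signal;
  size-matched input (SMInput) libraries are a uniform background.

* **Bisulfite arm** — targeted amplicon libraries in which every unprotected
  cytosine deaminates and reads as T, while an m5C survives as C with a
  per-site protection probability that differs between knockdown conditions.

References are random-sequence mimics that preserve only the coordinate
frame of the real transcripts (region lengths, the target C positions); the
sequence content itself carries no signal, so none is copied from any
database entry.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ReferenceSet",
    "Interval",
    "CrosslinkSite",
    "BindingWindow",
    "CrosslinkModel",
    "BisulfiteModel",
    "LibraryConfig",
    "RefLayout",
    "PRE_RRNA",
    "VT_RNA",
    "RRNA_CLASSES",
    "DEFAULT_ADAPTER",
    "DEFAULT_CLASS_WEIGHTS",
    "build_reference",
    "default_crosslink_model",
    "default_bisulfite_model",
    "default_amplicon",
    "simulate_miclip_library",
    "simulate_bisulfite_library",
]

BASES = "ACGT"
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTC"  # 3' RNA adapter in DNA space

PRE_RRNA = "pre_rRNA_47S"
VT_RNA = "vtRNA1_2"

#: pre-rRNA regions in transcript order with default mimic lengths (nt)
PRE_RRNA_REGIONS: tuple[tuple[str, int], ...] = (
    ("5ETS", 3655),
    ("18S", 1869),
    ("ITS1", 1077),
    ("5.8S", 157),
    ("ITS2", 1167),
    ("28S", 5070),
    ("3ETS", 361),
)

#: interval classes that roll up into the "rRNA" read class
RRNA_CLASSES = frozenset(r for r, _ in PRE_RRNA_REGIONS)

# 28S-local C4447 / vtRNA-local C27: coordinates guaranteed by build_reference
TARGET_28S_LOCAL = 4447
TARGET_VT_LOCAL = 27


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """Annotated interval, 1-based inclusive coordinates on its reference."""

    name: str
    reference: str
    start: int
    end: int
    cls: str

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class ReferenceSet:
    """Named nucleotide sequences plus their annotated intervals."""

    sequences: dict[str, str]
    intervals: list[Interval]

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def intervals_for(self, name: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.reference == name]

    def locate(self, reference: str, pos: int) -> str:
        """Region-local label, e.g. ``locate('pre_rRNA_47S', 12372) == '28S:4447'``."""
        for iv in self.intervals:
            if iv.reference == reference and iv.contains(pos):
                return f"{iv.name}:{pos - iv.start + 1}"
        return f"{reference}:{pos}"

    def local_to_abs(self, region: str, pos: int) -> tuple[str, int]:
        """Map a region-local 1-based coordinate to (reference, absolute pos)."""
        for iv in self.intervals:
            if iv.name == region:
                if not 1 <= pos <= len(iv):
                    raise ValueError(f"position {pos} outside region {region}")
                return iv.reference, iv.start + pos - 1
        raise KeyError(f"no interval named {region!r}")

    def class_of(self, reference: str, pos: int) -> str:
        for iv in self.intervals:
            if iv.reference == reference and iv.contains(pos):
                return "rRNA" if iv.cls in RRNA_CLASSES else iv.cls
        return "other"

    # -- serialization ------------------------------------------------------

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def write_bed(self, path) -> None:
        """Intervals as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.reference}\t{iv.start - 1}\t{iv.end}\t{iv.name}\t0\t+\t{iv.cls}\n")

    @classmethod
    def from_files(cls, fasta_path, bed_path) -> "ReferenceSet":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        intervals = []
        with open(bed_path) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                intervals.append(Interval(f[3], f[0], int(f[1]) + 1, int(f[2]), f[6]))
        return cls(seqs, intervals)

    def validate(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence {name!r}")
            if set(seq) - set(BASES):
                raise ValueError(f"non-ACGT characters in {name!r}")
        for iv in self.intervals:
            if iv.reference not in self.sequences:
                raise ValueError(f"interval {iv.name} on unknown reference {iv.reference}")
            if not (1 <= iv.start <= iv.end <= self.length(iv.reference)):
                raise ValueError(f"interval {iv.name} out of bounds")


@dataclass(frozen=True)
class CrosslinkSite:
    reference: str
    position: int  # 1-based, must carry base C
    truncation_prob: float


@dataclass(frozen=True)
class BindingWindow:
    reference: str
    start: int  # 1-based inclusive
    end: int
    relative_enrichment: float


@dataclass
class CrosslinkModel:
    sites: list[CrosslinkSite] = field(default_factory=list)
    binding_windows: list[BindingWindow] = field(default_factory=list)

    def validate(self, refs: ReferenceSet) -> None:
        for s in self.sites:
            if s.reference not in refs.sequences:
                raise ValueError(f"crosslink site on unknown reference {s.reference!r}")
            if not 0.0 <= s.truncation_prob <= 1.0:
                raise ValueError("truncation_prob must be in [0, 1]")
            if refs.sequences[s.reference][s.position - 1] != "C":
                raise ValueError(f"site {s.reference}:{s.position} is not a C")
        for w in self.binding_windows:
            if w.reference not in refs.sequences:
                raise ValueError(f"window on unknown reference {w.reference!r}")
            if not (1 <= w.start <= w.end <= refs.length(w.reference)):
                raise ValueError("binding window out of bounds")
            if w.relative_enrichment < 1.0:
                raise ValueError("relative_enrichment must be >= 1")


@dataclass
class BisulfiteModel:
    """Per-cytosine deamination probabilities.

    ``default_conversion_efficiency`` is the probability an unprotected C
    reads as T; ``site_overrides`` maps (reference, 1-based position,
    condition label) to the conversion probability at a (partially) protected
    site; ``sequencing_error_rate`` substitutes a uniformly random different
    base after the chemistry is applied.
    """

    default_conversion_efficiency: float = 0.97
    site_overrides: dict[tuple[str, int, str], float] = field(default_factory=dict)
    sequencing_error_rate: float = 0.002

    def validate(self, refs: ReferenceSet) -> None:
        if not 0.0 <= self.default_conversion_efficiency <= 1.0:
            raise ValueError("conversion efficiency must be in [0, 1]")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError("sequencing_error_rate must be in [0, 1)")
        for (ref, pos, _cond), p in self.site_overrides.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError("override probabilities must be in [0, 1]")
            if refs.sequences[ref][pos - 1] != "C":
                raise ValueError(f"override at {ref}:{pos} is not a C")

    def probability(self, ref: str, pos: int, condition: str) -> float:
        return self.site_overrides.get((ref, pos, condition), self.default_conversion_efficiency)


SAMPLE_TYPES = ("IP_WT", "IP_C459A", "SMInput", "BISULFITE")

#: default read-class sampling weights, calibrated so that the mapped rRNA
#: fraction reproduces the mutant (>97%) and WT (>98%) IP compositions;
#: the WT enzyme never crosslinks vtRNA, so its vtRNA weight is 0.
DEFAULT_CLASS_WEIGHTS: dict[str, dict[str, float]] = {
    "IP_C459A": {"rRNA": 0.978, "snoRNA_CD": 0.011, "snoRNA_HACA": 0.0005,
                 "vtRNA": 0.006, "decoy": 0.0045},
    "IP_WT": {"rRNA": 0.985, "snoRNA_CD": 0.008, "snoRNA_HACA": 0.0005,
              "vtRNA": 0.003, "decoy": 0.0035},
}


@dataclass
class LibraryConfig:
    n_reads: int
    sample_type: str
    seed: int
    read_length_range: tuple[int, int] = (70, 110)
    umi_length: int = 10
    adapter: str = DEFAULT_ADAPTER
    condition: str = ""
    replicate: int = 1
    class_weights: dict[str, float] | None = None
    duplicate_fraction: float = 0.0  # injected PCR duplicates, for dedup tests

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.umi_length < 0:
            raise ValueError("umi_length must be >= 0")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        lo, hi = self.read_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid read_length_range")
        if self.class_weights is not None:
            tot = sum(self.class_weights.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError("class_weights must sum to 1")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

@dataclass
class RefLayout:
    region_lengths: dict[str, int] = field(
        default_factory=lambda: {r: n for r, n in PRE_RRNA_REGIONS}
    )
    n_snord: int = 3
    n_snora: int = 2
    snord_length: int = 90   # box C/D snoRNAs are mostly 70-90 nt
    snora_length: int = 130
    n_vtrna: int = 1
    vtrna_length: int = 88
    n_decoy: int = 2
    decoy_length: int = 2000  # mRNA-fragment-like background references


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, n)])


def build_reference(seed: int, layout: RefLayout | None = None) -> ReferenceSet:
    """Build the random-sequence reference mimics.

    The pre-rRNA mimic is tiled by the seven processing regions in transcript
    order; a C is forced at 28S-local 4447 and at vtRNA-local 27 so the
    canonical target coordinates exist regardless of the random fill.
    Deterministic for a fixed seed.
    """
    layout = layout or RefLayout()
    for region, n in layout.region_lengths.items():
        if n <= 0:
            raise ValueError(f"region {region} has non-positive length {n}")
    if layout.region_lengths["28S"] < TARGET_28S_LOCAL:
        raise ValueError("28S mimic must be at least 4447 nt")
    if layout.vtrna_length < TARGET_VT_LOCAL:
        raise ValueError("vtRNA mimic must be at least 27 nt")

    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    intervals: list[Interval] = []

    total = sum(layout.region_lengths[r] for r, _ in PRE_RRNA_REGIONS)
    pre = list(_random_seq(rng, total))
    pos = 1
    for region, _ in PRE_RRNA_REGIONS:
        n = layout.region_lengths[region]
        intervals.append(Interval(region, PRE_RRNA, pos, pos + n - 1, region))
        if region == "28S":
            pre[pos - 1 + TARGET_28S_LOCAL - 1] = "C"
        pos += n
    sequences[PRE_RRNA] = "".join(pre)

    def add_simple(name: str, length: int, cls: str) -> None:
        sequences[name] = _random_seq(rng, length)
        intervals.append(Interval(name, name, 1, length, cls))

    for i in range(layout.n_snord):
        add_simple(f"SNORD_{i + 1}", layout.snord_length, "snoRNA_CD")
    for i in range(layout.n_snora):
        add_simple(f"SNORA_{i + 1}", layout.snora_length, "snoRNA_HACA")
    for i in range(layout.n_vtrna):
        name = VT_RNA if i == 0 else f"vtRNA_{i + 1}"
        seq = list(_random_seq(rng, layout.vtrna_length))
        seq[TARGET_VT_LOCAL - 1] = "C"
        sequences[name] = "".join(seq)
        intervals.append(Interval(name, name, 1, layout.vtrna_length, "vtRNA"))
    for i in range(layout.n_decoy):
        add_simple(f"decoy_{i + 1}", layout.decoy_length, "decoy")

    refs = ReferenceSet(sequences, intervals)
    refs.validate()
    return refs


def default_crosslink_model(refs: ReferenceSet, truncation_prob: float = 0.6) -> CrosslinkModel:
    """Shipped ground truth: one crosslinked C on the 28S (local 4447), one on
    the vtRNA mimic (local 27), and a binding window in the 5'ETS."""
    ref28, abs4447 = refs.local_to_abs("28S", TARGET_28S_LOCAL)
    model = CrosslinkModel(
        sites=[
            CrosslinkSite(ref28, abs4447, truncation_prob),
            CrosslinkSite(VT_RNA, TARGET_VT_LOCAL, truncation_prob),
        ],
        binding_windows=[BindingWindow(PRE_RRNA, 1, 600, 15.0)],
    )
    model.validate(refs)
    return model


#: bisulfite conditions: non-targeting control and two knockdown siRNAs
BISULFITE_CONDITIONS = ("siC", "siNOP2_1", "siNOP2_2")

#: converted fraction of the target C per condition (protection weakens on
#: knockdown because newly made rRNA goes unmethylated)
DEFAULT_SITE_CONVERSION = {"siC": 0.16, "siNOP2_1": 0.28, "siNOP2_2": 0.34}


def default_bisulfite_model(refs: ReferenceSet) -> BisulfiteModel:
    ref28, abs4447 = refs.local_to_abs("28S", TARGET_28S_LOCAL)
    overrides = {
        (ref28, abs4447, cond): p for cond, p in DEFAULT_SITE_CONVERSION.items()
    }
    model = BisulfiteModel(site_overrides=overrides)
    model.validate(refs)
    return model


def default_amplicon(refs: ReferenceSet) -> tuple[str, int, int]:
    """The 28S amplicon, local 4178..4534, as (reference, abs start, abs end)."""
    ref, start = refs.local_to_abs("28S", 4178)
    _, end = refs.local_to_abs("28S", 4534)
    return ref, start, end


# ---------------------------------------------------------------------------
# FASTQ helpers
# ---------------------------------------------------------------------------

def _open_text(path, mode="wt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode.replace("t", ""))


def _write_fastq(fh: io.TextIOBase, read_id: str, seq: str) -> None:
    fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def _umi_strings(rng: np.random.Generator, n: int, k: int) -> list[str]:
    if k == 0:
        return [""] * n
    arr = np.array(list(BASES))[rng.integers(0, 4, size=(n, k))]
    return ["".join(row) for row in arr]


# ---------------------------------------------------------------------------
# miCLIP library simulation
# ---------------------------------------------------------------------------

def _class_members(refs: ReferenceSet) -> dict[str, list[str]]:
    """Map read class -> references carrying it (pre-rRNA regions -> rRNA)."""
    members: dict[str, list[str]] = {}
    seen = set()
    for iv in refs.intervals:
        cls = "rRNA" if iv.cls in RRNA_CLASSES else iv.cls
        if (cls, iv.reference) not in seen:
            members.setdefault(cls, []).append(iv.reference)
            seen.add((cls, iv.reference))
    return members


def _start_weights(refs: ReferenceSet, ref: str, model: CrosslinkModel | None) -> np.ndarray | None:
    """Per-position insert-start weights (None means uniform)."""
    if model is None:
        return None
    wins = [w for w in model.binding_windows if w.reference == ref]
    if not wins:
        return None
    w = np.ones(refs.length(ref))
    for win in wins:
        w[win.start - 1 : win.end] *= win.relative_enrichment
    return np.cumsum(w / w.sum())  # CDF for inverse-transform sampling


def simulate_miclip_library(
    refs: ReferenceSet,
    model: CrosslinkModel,
    cfg: LibraryConfig,
    fastq_path,
    manifest_path,
) -> dict[str, int]:
    """Simulate an IP or SMInput library.

    Read layout is UMI + insert + 3' adapter with constant quality. SMInput
    inserts are uniform over references (class-weighted, length-proportional
    within class); IP_WT inserts are additionally weighted by
    ``relative_enrichment`` inside binding windows; IP_C459A inserts that
    overlap a crosslink site are moved to start exactly at the site with
    probability ``truncation_prob`` (RT-stop truncation).

    The truth manifest (TSV) records reference, 1-based insert start/end,
    class, truncation flag and UMI per read.
    """
    cfg.validate()
    if cfg.sample_type not in ("IP_WT", "IP_C459A", "SMInput"):
        raise ValueError("simulate_miclip_library requires a CLIP sample_type")
    model.validate(refs)

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    lo, hi = cfg.read_length_range

    # class assignment
    if cfg.class_weights is not None:
        weights = dict(cfg.class_weights)
    elif cfg.sample_type in DEFAULT_CLASS_WEIGHTS:
        weights = dict(DEFAULT_CLASS_WEIGHTS[cfg.sample_type])
    else:  # SMInput: pure length-proportional background
        members = _class_members(refs)
        weights = {
            cls: float(sum(refs.length(r) for r in rs)) for cls, rs in members.items()
        }
        tot = sum(weights.values())
        weights = {c: v / tot for c, v in weights.items()}

    members = _class_members(refs)
    classes = sorted(weights)
    pvec = np.array([weights[c] for c in classes])
    pvec = pvec / pvec.sum()
    cls_idx = rng.choice(len(classes), size=n, p=pvec)

    # reference within class, length-proportional
    ref_of: list[str] = []
    for ci in cls_idx:
        refs_in = members[classes[ci]]
        if len(refs_in) == 1:
            ref_of.append(refs_in[0])
        else:
            lens = np.array([refs.length(r) for r in refs_in], float)
            ref_of.append(refs_in[rng.choice(len(refs_in), p=lens / lens.sum())])

    lengths = rng.integers(lo, hi + 1, size=n)
    umis = _umi_strings(rng, n, cfg.umi_length)

    enriched = cfg.sample_type in ("IP_WT", "IP_C459A")
    weight_cache: dict[str, np.ndarray | None] = {}
    sites_by_ref: dict[str, list[CrosslinkSite]] = {}
    if cfg.sample_type == "IP_C459A":
        for s in model.sites:
            sites_by_ref.setdefault(s.reference, []).append(s)

    rows = []
    max_insert = hi
    for i in range(n):
        ref = ref_of[i]
        L = refs.length(ref)
        if L <= max_insert:
            # small structured RNAs co-purify intact: the whole molecule is
            # the insert, so every read spans the full reference
            length, start = L, 1
            end = L
            truncated = False
            for s in sites_by_ref.get(ref, ()):
                if rng.random() < s.truncation_prob:
                    start = s.position
                    length = L - start + 1
                    truncated = True
                    break
            rows.append([ref, start, start + length - 1, classes[cls_idx[i]],
                         truncated, umis[i]])
            continue
        length = int(min(lengths[i], L))
        if ref not in weight_cache:
            weight_cache[ref] = _start_weights(refs, ref, model) if enriched else None
        w = weight_cache[ref]
        while True:  # rejection-sample starts that would run off the 3' end
            if w is None:
                start = int(rng.integers(1, L + 1))
            else:
                start = int(np.searchsorted(w, rng.random(), side="right")) + 1
                start = min(start, L)
            if start + length - 1 <= L:
                break
        end = start + length - 1
        truncated = False
        for s in sites_by_ref.get(ref, ()):
            if start <= s.position <= end and rng.random() < s.truncation_prob:
                start = s.position
                length = int(min(length, L - start + 1))
                end = start + length - 1
                truncated = True
                break
        rows.append([ref, start, end, classes[cls_idx[i]], truncated, umis[i]])

    # optional exact-duplicate injection (same insert + same UMI)
    n_dup = int(round(cfg.duplicate_fraction * n))
    if n_dup:
        src = rng.integers(0, n, size=n_dup)
        for j, s in zip(range(n - n_dup, n), src):
            rows[j] = list(rows[int(s) % (n - n_dup)])

    prefix = f"{cfg.sample_type}_{cfg.condition or 'na'}_rep{cfg.replicate}"
    with _open_text(fastq_path) as fq, open(manifest_path, "w") as mf:
        mf.write("read_id\treference\tstart\tend\tclass\ttruncated\tumi\n")
        for i, (ref, start, end, cls, truncated, umi) in enumerate(rows):
            insert = refs.sequences[ref][start - 1 : end]
            read_id = f"{prefix}_{i:06d}"
            _write_fastq(fq, read_id, umi + insert + cfg.adapter)
            mf.write(f"{read_id}\t{ref}\t{start}\t{end}\t{cls}\t{int(truncated)}\t{umi}\n")

    return {"n_reads": n, "n_duplicates_injected": n_dup}


# ---------------------------------------------------------------------------
# bisulfite library simulation
# ---------------------------------------------------------------------------

def simulate_bisulfite_library(
    refs: ReferenceSet,
    model: BisulfiteModel,
    amplicon: tuple[str, int, int],
    cfg: LibraryConfig,
    fastq_path,
    manifest_path,
    paired: bool = False,
    paired_read_length: int = 250,
) -> dict[str, int]:
    """Simulate a targeted bisulfite amplicon library.

    Every read spans the full amplicon (single-end default). Each reference C
    converts to T independently with its per-site probability (condition
    override if present, else the default efficiency); a uniform substitution
    error is then applied at ``sequencing_error_rate``. With ``paired=True``
    two mates of ``paired_read_length`` are emitted from the amplicon ends
    (mate 2 reverse-complemented) into ``<stem>_R1/_R2`` files.

    The truth manifest records the per-read conversion outcome at each
    override site inside the amplicon.
    """
    cfg.validate()
    if cfg.sample_type != "BISULFITE":
        raise ValueError("cfg.sample_type must be 'BISULFITE'")
    model.validate(refs)
    ref, a_start, a_end = amplicon
    if ref not in refs.sequences:
        raise ValueError(f"amplicon on unknown reference {ref!r}")
    if not (1 <= a_start <= a_end <= refs.length(ref)):
        raise ValueError("amplicon out of reference bounds")
    template = refs.sequences[ref][a_start - 1 : a_end]
    L = len(template)
    c_local = np.flatnonzero(np.frombuffer(template.encode(), np.uint8) == ord("C"))
    if c_local.size == 0:
        raise ValueError("amplicon contains no cytosine")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    p_conv = np.array(
        [model.probability(ref, a_start + int(j), cfg.condition) for j in c_local]
    )
    override_local = [
        int(pos - a_start)
        for (r, pos, cond) in model.site_overrides
        if r == ref and cond == cfg.condition and a_start <= pos <= a_end
    ]
    override_local.sort()

    base_codes = np.frombuffer(template.encode(), np.uint8)
    reads = np.tile(base_codes, (n, 1))
    convert = rng.random((n, c_local.size)) < p_conv
    reads[:, c_local] = np.where(convert, ord("T"), ord("C"))

    # uniform substitution errors
    e = model.sequencing_error_rate
    if e > 0:
        err_mask = rng.random((n, L)) < e
        n_err = int(err_mask.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err)  # rotate within ACGT, never same base
            order = np.frombuffer(b"ACGT", np.uint8)
            idx_of = np.zeros(256, np.int64)
            idx_of[order] = np.arange(4)
            flat = reads[err_mask]
            reads[err_mask] = order[(idx_of[flat] + shift) % 4]

    umis = _umi_strings(rng, n, cfg.umi_length)
    prefix = f"BS_{cfg.condition or 'na'}_rep{cfg.replicate}"
    site_cols = "".join(f"\tconverted_at_{ref}:{a_start + j}" for j in override_local)

    def manifest_row(i, seq_row):
        flags = "".join(
            f"\t{int(seq_row[j] == ord('T'))}" for j in override_local
        )
        return f"{prefix}_{i:06d}\t{ref}\t{a_start}\t{a_end}{flags}\n"

    with open(manifest_path, "w") as mf:
        mf.write(f"read_id\treference\tstart\tend{site_cols}\n")
        for i in range(n):
            mf.write(manifest_row(i, reads[i]))

    seqs = [r.tobytes().decode() for r in reads]
    if not paired:
        with _open_text(fastq_path) as fq:
            for i, s in enumerate(seqs):
                _write_fastq(fq, f"{prefix}_{i:06d}", umis[i] + s + cfg.adapter)
    else:
        comp = str.maketrans("ACGT", "TGCA")
        stem = str(fastq_path)
        for suf in (".fastq.gz", ".fastq", ".fq.gz", ".fq"):
            if stem.endswith(suf):
                stem = stem[: -len(suf)]
                ext = suf
                break
        else:
            ext = ".fastq"
        with _open_text(stem + "_R1" + ext) as f1, _open_text(stem + "_R2" + ext) as f2:
            for i, s in enumerate(seqs):
                _write_fastq(f1, f"{prefix}_{i:06d}", s[:paired_read_length])
                r2 = s[max(0, L - paired_read_length):].translate(comp)[::-1]
                _write_fastq(f2, f"{prefix}_{i:06d}", r2)

    return {"n_reads": n, "amplicon_length": L, "n_cytosines": int(c_local.size)}


def merge_pairs(seq1: str, seq2_revcomp: str, insert_length: int) -> str:
    """Reconstruct a full-length amplicon read from 2x paired mates.

    ``seq2_revcomp`` is mate 2 as sequenced (reverse-complement of the insert
    3' end). Where the mates overlap, mate 1 wins on disagreement.
    """
    comp = str.maketrans("ACGT", "TGCA")
    tail = seq2_revcomp.translate(comp)[::-1]  # back to insert orientation
    merged = list("N" * insert_length)
    off2 = insert_length - len(tail)
    merged[off2:] = list(tail)
    merged[: len(seq1)] = list(seq1)  # read1 wins in the overlap
    return "".join(merged)
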