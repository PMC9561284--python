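"""Shared fixtures: references, ground-truth models, and cached libraries.

Simulated libraries that several test modules reuse are built once per
session; tests that need their own study conditions build them locally.
"""

from __future__ import annotations

import pytest

import m5cmap as m
import m5cmap.align as al
import m5cmap.crosslink as cl
import m5cmap.preprocess as pp
import m5cmap.synthetic_data as sd


@pytest.fixture(scope="session")
def refs():
    return m.build_reference(1)


@pytest.fixture(scope="session")
def xmodel(refs):
    return m.default_crosslink_model(refs)


@pytest.fixture(scope="session")
def bmodel(refs):
    return m.default_bisulfite_model(refs)


@pytest.fixture(scope="session")
def workdir(tmp_path_factory):
    return tmp_path_factory.mktemp("libs")


def simulate_and_align(refs, xmodel, workdir, sample_type, seed,
                       n_reads=20_000, class_weights=None):
    """Full standard-mode chain for one miCLIP library; returns deduplicated
    alignment records."""
    cfg = sd.LibraryConfig(n_reads=n_reads, sample_type=sample_type, seed=seed,
                           class_weights=class_weights)
    stem = workdir / f"{sample_type}_{seed}_{n_reads}"
    sd.simulate_miclip_library(refs, xmodel, cfg, f"{stem}.fastq",
                               f"{stem}.manifest.tsv")
    pp.preprocess_fastq(f"{stem}.fastq", f"{stem}.trimmed.fastq", cfg.adapter,
                        cfg.umi_length)
    al.align_fastq(f"{stem}.trimmed.fastq", refs, f"{stem}.sam",
                   umi_length=cfg.umi_length)
    return cl.deduplicate(al.read_sam(f"{stem}.sam"))


@pytest.fixture(scope="session")
def c459a_records(refs, xmodel, workdir):
    return simulate_and_align(refs, xmodel, workdir, "IP_C459A", seed=1011)


@pytest.fixture(scope="session")
def wt_records(refs, xmodel, workdir):
    return simulate_and_align(refs, xmodel, workdir, "IP_WT", seed=1012)


@pytest.fixture(scope="session")
def c459a_profile(c459a_records, refs):
    return cl.stop_profile(c459a_records, refs)


@pytest.fixture(scope="session")
def wt_profile(wt_records, refs):
    return cl.stop_profile(wt_records, refs)


def manifest_records(manifest_path):
    """Build AlignmentRecords straight from a truth manifest (bypasses the
    aligner for tests that only exercise counting statistics)."""
    records = []
    with open(manifest_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            start1, end1 = int(f[idx["start"]]), int(f[idx["end"]])
            length = end1 - start1 + 1
            records.append(al.AlignmentRecord(
                read_id=f[idx["read_id"]], umi=f[idx["umi"]],
                reference=f[idx["reference"]], start=start1 - 1, strand="+",
                aligned_length=length, score=2 * length, cigar=f"{length}M",
                original_sequence=""))
    return records
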