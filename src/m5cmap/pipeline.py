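"""End-to-end orchestration of both analysis arms from one study design.

``make_fixture`` writes the complete synthetic study to disk (references,
ground truth, FASTQ libraries, truth manifests); ``run_miclip`` and
``run_bisulfite`` execute the two analysis chains over such a fixture and
emit plot-ready TSV/bedGraph/BED outputs plus a JSON-lines run log.

Per-library seeds are derived deterministically from the global seed:
``library_seed = (global_seed * 1000 + offset) % 2**31`` with a fixed
offset per (arm, condition, sample type, replicate), so the whole study is
reproducible from a single integer.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as al
from . import crosslink as cl
from . import methquant as mq
from . import preprocess as pp
from . import synthetic_data as sd

__all__ = ["StudyDesign", "make_fixture", "run_miclip", "run_bisulfite", "run_all"]

MICLIP_SAMPLES = ("IP_C459A", "IP_WT", "SMInput_C459A", "SMInput_WT")
#: per-replicate seed offsets: bisulfite libraries take 1..9, miCLIP
#: libraries take 10*rep + index within MICLIP_SAMPLES + 1
MICLIP_OFFSETS = {s: i + 1 for i, s in enumerate(MICLIP_SAMPLES)}


@dataclass
class StudyDesign:
    seed: int = 1
    miclip_replicates: int = 2
    miclip_n_reads: int = 20_000
    truncation_prob: float = 0.6
    bisulfite_conditions: tuple[str, ...] = sd.BISULFITE_CONDITIONS
    bisulfite_replicates: int = 3
    bisulfite_n_reads: int = 50_000
    read_length_range: tuple[int, int] = (70, 110)
    umi_length: int = 10
    adapter: str = sd.DEFAULT_ADAPTER

    def validate(self) -> None:
        if self.miclip_replicates < 1:
            raise ValueError("need at least one miCLIP replicate")
        if self.bisulfite_replicates < 2:
            raise ValueError("need >= 2 bisulfite replicates per condition")

    def library_seed(self, offset: int) -> int:
        return (self.seed * 1000 + offset) % (2 ** 31)

    def miclip_seed(self, sample_type: str, replicate: int) -> int:
        return self.library_seed(10 * replicate + MICLIP_OFFSETS[sample_type])

    def bisulfite_seed(self, condition: str, replicate: int) -> int:
        c = self.bisulfite_conditions.index(condition)
        return self.library_seed(1 + c * self.bisulfite_replicates + (replicate - 1))


def _jsonl(path: Path, record: dict) -> None:
    with open(path, "a") as fh:
        fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def make_fixture(design: StudyDesign, outdir, force: bool = False) -> dict:
    """Write references, ground truth and every FASTQ library of the study."""
    design.validate()
    out = Path(outdir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} exists and is not empty (use force)")
        shutil.rmtree(out)
    (out / "miclip").mkdir(parents=True, exist_ok=True)
    (out / "bisulfite").mkdir(exist_ok=True)

    refs = sd.build_reference(design.seed)
    xmodel = sd.default_crosslink_model(refs, design.truncation_prob)
    bmodel = sd.default_bisulfite_model(refs)
    amplicon = sd.default_amplicon(refs)
    refs.write_fasta(out / "refs.fasta")
    refs.write_bed(out / "refs.bed")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "crosslink_sites": [
                    {"reference": s.reference, "position": s.position,
                     "label": refs.locate(s.reference, s.position),
                     "truncation_prob": s.truncation_prob}
                    for s in xmodel.sites
                ],
                "binding_windows": [
                    {"reference": w.reference, "start": w.start, "end": w.end,
                     "relative_enrichment": w.relative_enrichment}
                    for w in xmodel.binding_windows
                ],
                "bisulfite": {
                    "default_conversion_efficiency": bmodel.default_conversion_efficiency,
                    "sequencing_error_rate": bmodel.sequencing_error_rate,
                    "site_overrides": [
                        {"reference": r, "position": p, "condition": c, "p_converted": v}
                        for (r, p, c), v in sorted(bmodel.site_overrides.items())
                    ],
                    "amplicon": {"reference": amplicon[0], "start": amplicon[1],
                                 "end": amplicon[2]},
                },
            },
            fh, indent=2,
        )

    fastqs = {"miclip": [], "bisulfite": []}
    for rep in range(1, design.miclip_replicates + 1):
        for sample in MICLIP_SAMPLES:
            base_type = "SMInput" if sample.startswith("SMInput") else sample
            cfg = sd.LibraryConfig(
                n_reads=design.miclip_n_reads,
                sample_type=base_type,
                seed=design.miclip_seed(sample, rep),
                read_length_range=design.read_length_range,
                umi_length=design.umi_length,
                adapter=design.adapter,
                condition=sample.split("_", 1)[-1] if base_type == "SMInput" else "",
                replicate=rep,
            )
            stem = out / "miclip" / f"{sample}_rep{rep}"
            sd.simulate_miclip_library(refs, xmodel, cfg,
                                       f"{stem}.fastq", f"{stem}.manifest.tsv")
            fastqs["miclip"].append(f"{stem}.fastq")
    for cond in design.bisulfite_conditions:
        for rep in range(1, design.bisulfite_replicates + 1):
            cfg = sd.LibraryConfig(
                n_reads=design.bisulfite_n_reads,
                sample_type="BISULFITE",
                seed=design.bisulfite_seed(cond, rep),
                umi_length=0,
                adapter="",
                condition=cond,
                replicate=rep,
            )
            stem = out / "bisulfite" / f"BS_{cond}_rep{rep}"
            sd.simulate_bisulfite_library(refs, bmodel, amplicon, cfg,
                                          f"{stem}.fastq", f"{stem}.manifest.tsv")
            fastqs["bisulfite"].append(f"{stem}.fastq")
    return {"outdir": out, "refs": refs, "crosslink_model": xmodel,
            "bisulfite_model": bmodel, "amplicon": amplicon, "fastqs": fastqs}


# ---------------------------------------------------------------------------
# miCLIP arm
# ---------------------------------------------------------------------------

def _process_library(fastq, refs, workdir: Path, design: StudyDesign,
                     mode: str = "standard", log_path: Path | None = None):
    """preprocess -> align -> dedup for one library; returns records + counts."""
    stem = Path(fastq).name.replace(".fastq", "").replace(".gz", "")
    trimmed = workdir / f"{stem}.trimmed.fastq"
    counts = pp.preprocess_fastq(fastq, trimmed, design.adapter if mode == "standard" else "",
                                 design.umi_length if mode == "standard" else 0)
    sam = workdir / f"{stem}.sam"
    amap = al.align_fastq(trimmed, refs, sam, mode=mode,
                          umi_length=design.umi_length if mode == "standard" else 0)
    records = cl.deduplicate(al.read_sam(sam)) if mode == "standard" else al.read_sam(sam)
    raw = counts[0].n_in
    dropped = sum(c.n_dropped for c in counts)
    if raw != amap["mapped"] + amap["unmapped"] + dropped:
        raise AssertionError("read accounting does not cross-foot")
    if log_path is not None:
        _jsonl(log_path, {"library": stem, "raw": raw, "dropped_preprocess": dropped,
                          "mapped": amap["mapped"], "unmapped": amap["unmapped"],
                          "deduplicated": len(records)})
    return records


def run_miclip(fixture: dict | str | Path, outdir, design: StudyDesign,
               site_params: cl.SiteCallParams | None = None) -> dict:
    """Run the full miCLIP chain over a fixture directory.

    Replicates of each sample type are pooled into one profile for site
    calling (truncation mutant vs WT) and window enrichment (mutant IP vs
    its paired SMInput); per-replicate RPM ratio tracks are averaged for the
    replicate-mean track.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logp = out / "run_log.jsonl"
    if isinstance(fixture, (str, Path)):
        fdir = Path(fixture)
        refs = sd.ReferenceSet.from_files(fdir / "refs.fasta", fdir / "refs.bed")
    else:
        fdir = fixture["outdir"]
        refs = fixture["refs"]
    for sample in ("IP_C459A", "SMInput_C459A"):
        if not list((fdir / "miclip").glob(f"{sample}_rep*.fastq*")):
            raise FileNotFoundError(f"missing {sample} libraries (IPs need a paired SMInput)")

    records: dict[str, list] = {s: [] for s in MICLIP_SAMPLES}
    per_rep_profiles: dict[str, list[cl.StopProfile]] = {s: [] for s in MICLIP_SAMPLES}
    for sample in MICLIP_SAMPLES:
        for fq in sorted((fdir / "miclip").glob(f"{sample}_rep*.fastq*")):
            recs = _process_library(fq, refs, out, design, "standard", logp)
            records[sample].extend(recs)
            per_rep_profiles[sample].append(cl.stop_profile(recs, refs))

    profiles = {s: cl.stop_profile(records[s], refs) for s in MICLIP_SAMPLES}

    # tracks
    for s in ("IP_C459A", "IP_WT"):
        cl.write_bedgraph(cl.normalize_rpm(profiles[s], "stops"),
                          out / f"{s}.rtstops.rpm.bedgraph")
    ratio = cl.enrichment_track(profiles["IP_C459A"], profiles["SMInput_C459A"])
    cl.write_bedgraph(ratio, out / "IP_C459A.over_smi.bedgraph")
    rep_ratios = [
        cl.enrichment_track(p, smi)
        for p, smi in zip(per_rep_profiles["IP_C459A"], per_rep_profiles["SMInput_C459A"])
    ]
    mean_ratio = {
        name: np.mean([t[name] for t in rep_ratios], axis=0) for name in ratio
    }
    cl.write_bedgraph(mean_ratio, out / "IP_C459A.over_smi.repmean.bedgraph")

    sites = cl.call_sites(profiles["IP_C459A"], profiles["IP_WT"], site_params, refs)
    sites.to_csv(out / "site_calls.tsv", sep="\t", index=False)
    cl.write_sites_bed(sites, out / "sites_passed.bed")

    windows = cl.window_enrichment(profiles["IP_C459A"], profiles["SMInput_C459A"])
    windows.to_csv(out / "window_enrichment.tsv", sep="\t", index=False)
    with open(out / "windows_significant.bed", "w") as fh:
        for r in windows[windows["significant"]].itertuples():
            fh.write(f"{r.reference}\t{r.start}\t{r.end}\twin\t{r.log2_fold_change:.4g}\t+\n")

    classes = {s: cl.class_summary(records[s], refs) for s in ("IP_C459A", "IP_WT")}
    for s, df in classes.items():
        df.to_csv(out / f"class_summary.{s}.tsv", sep="\t", index=False)

    top = sites[sites["passed"]].head(10)
    _jsonl(logp, {"top_sites": top[["label", "ratio"]].to_dict("records"),
                  "n_significant_windows": int(windows["significant"].sum())})
    return {"sites": sites, "windows": windows, "classes": classes,
            "profiles": profiles, "outdir": out}


# ---------------------------------------------------------------------------
# bisulfite arm
# ---------------------------------------------------------------------------

def run_bisulfite(fixture: dict | str | Path, outdir, design: StudyDesign,
                  control: str = "siC") -> dict:
    """Run the bisulfite chain: per-replicate conversion tables, per-condition
    means +/- SD at the override sites, knockdown-vs-control t-tests, and the
    overall conversion rate excluding the override sites."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logp = out / "run_log.jsonl"
    if isinstance(fixture, (str, Path)):
        fdir = Path(fixture)
        refs = sd.ReferenceSet.from_files(fdir / "refs.fasta", fdir / "refs.bed")
        with open(fdir / "ground_truth.json") as fh:
            gt = json.load(fh)
        amp = gt["bisulfite"]["amplicon"]
        amplicon = (amp["reference"], amp["start"], amp["end"])
        target_sites = sorted({(o["reference"], o["position"])
                               for o in gt["bisulfite"]["site_overrides"]})
    else:
        fdir = fixture["outdir"]
        refs = fixture["refs"]
        amplicon = fixture["amplicon"]
        target_sites = sorted({(r, p)
                               for (r, p, _c) in fixture["bisulfite_model"].site_overrides})

    tables: dict[str, list[pd.DataFrame]] = {}
    for fq in sorted((fdir / "bisulfite").glob("BS_*_rep*.fastq*")):
        stem = fq.name.replace(".fastq", "").replace(".gz", "")
        cond, rep = stem[3:].rsplit("_rep", 1)
        trimmed = out / f"{stem}.trimmed.fastq"
        pp.preprocess_fastq(fq, trimmed, "", 0)
        sam = out / f"{stem}.sam"
        amap = al.align_fastq(trimmed, refs, sam, mode="bisulfite", umi_length=0)
        recs = al.read_sam(sam)
        table = mq.conversion_table(recs, refs, amplicon)
        table.to_csv(out / f"conversion.{stem}.tsv", sep="\t", index=False)
        tables.setdefault(cond, []).append(table)
        _jsonl(logp, {"library": stem, "mapped": amap["mapped"],
                      "unmapped": amap["unmapped"],
                      "overall_conversion_rate":
                          mq.overall_conversion_rate(table, target_sites)})

    conditions = sorted(tables)
    for cond, tabs in tables.items():
        if len(tabs) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 replicates")

    def site_fracs(cond: str, ref: str, pos: int) -> list[float]:
        out_f = []
        for t in tables[cond]:
            row = t[(t["reference"] == ref) & (t["position"] == pos)]
            out_f.append(float(row["converted_fraction"].iloc[0]))
        return out_f

    summary_rows, comparisons = [], []
    for ref, pos in target_sites:
        label = refs.locate(ref, pos)
        for cond in conditions:
            fr = site_fracs(cond, ref, pos)
            summary_rows.append((label, cond, len(fr), float(np.mean(fr)),
                                 float(np.std(fr, ddof=1))))
        if control in tables:
            ctrl = site_fracs(control, ref, pos)
            for cond in conditions:
                if cond == control:
                    continue
                cmp_res = mq.compare_conditions(label, site_fracs(cond, ref, pos),
                                                ctrl, cond, control)
                comparisons.append(
                    (label, cond, control, cmp_res.mean_a, cmp_res.mean_b,
                     cmp_res.sd_a, cmp_res.sd_b, cmp_res.t_statistic,
                     cmp_res.degrees_of_freedom, cmp_res.p_value)
                )
    site_summary = pd.DataFrame(
        summary_rows, columns=["site", "condition", "n_replicates",
                               "mean_converted_fraction", "sd"]
    )
    site_summary.to_csv(out / "site_summary.tsv", sep="\t", index=False)
    cmp_df = pd.DataFrame(
        comparisons, columns=["site", "condition", "control", "mean_condition",
                              "mean_control", "sd_condition", "sd_control",
                              "t_statistic", "df", "p_value"]
    )
    cmp_df.to_csv(out / "comparisons.tsv", sep="\t", index=False)

    overall = {
        cond: float(np.mean([mq.overall_conversion_rate(t, target_sites)
                             for t in tables[cond]]))
        for cond in conditions
    }
    _jsonl(logp, {"overall_conversion_rate_by_condition": overall})
    return {"tables": tables, "site_summary": site_summary,
            "comparisons": cmp_df, "overall_conversion": overall, "outdir": out}


def run_all(design: StudyDesign, outdir, force: bool = False) -> dict:
    out = Path(outdir)
    fixture = make_fixture(design, out / "fixture", force=force)
    miclip = run_miclip(fixture, out / "miclip_out", design)
    bisulfite = run_bisulfite(fixture, out / "bisulfite_out", design)
    return {"fixture": fixture, "miclip": miclip, "bisulfite": bisulfite}
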