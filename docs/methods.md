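# Methods

## Scope and model

`m5cmap` implements the two computational arms by which an m⁵C
(5-methylcytosine) site on ribosomal RNA is localized and quantified:

1. **Crosslink-site mapping (miCLIP/eCLIP arm).** A catalytically trapped
   methyltransferase mutant forms a covalent bond with its target cytosine.
   Reverse transcription terminates at the crosslink, so in the sequencing
   library the 5′ end of a read marks the modified C (the "RT stop", here
   taken at the read-start coordinate itself; a start−1 convention is
   available via `stop_offset`). Wild-type (WT) enzyme binds the same RNAs —
   notably the 5′ external transcribed spacer (5′ETS) of the pre-rRNA — but
   does not truncate, and a size-matched input (SMInput) library taken
   before immunoprecipitation provides the abundance background. Crosslinked
   cytosines are therefore detectable as positions where read starts pile up
   in the mutant but not the WT library; binding (as opposed to catalysis)
   is detectable as coverage enrichment of IP over SMInput.

2. **Targeted bisulfite quantification.** Bisulfite chemistry deaminates
   unmethylated cytosines, which then read as T; an m⁵C resists conversion
   and still reads as C. Amplicon sequencing across the target region gives,
   at every reference C, a binomial sample of converted/non-converted
   states. The converted fraction at the target site, compared between a
   control and two knockdown conditions over biological replicates, measures
   how much of the RNA pool carries the methyl mark.

Because raw sequencing data at the original scale is neither needed nor
practical for a test suite, the package ships a first-class synthetic-data
module whose generative model has exactly the statistical structure the
analysis assumes. All pipeline stages are exercised end-to-end on those
libraries, and the analysis code makes no assumption that its input is
synthetic.

## Synthetic references

`build_reference` creates random-sequence mimics that preserve only the
*coordinate frame* of the real transcripts: a 13,356-nt pre-rRNA tiled in
order by 5′ETS (3,655) / 18S (1,869) / ITS1 (1,077) / 5.8S (157) / ITS2
(1,167) / 28S (5,070) / 3′ETS (361); an 88-nt vault RNA; three 90-nt box C/D
snoRNA mimics; two 130-nt H/ACA mimics; two 2,000-nt decoys. A cytosine is
forced at 28S-local position 4447 and at vtRNA-local 27 after the seeded
random fill, so the canonical target coordinates always exist. Base
composition is uniform (GC ≈ 0.5). Sequence content is deliberately random:
coordinates carry the science, and nothing is copied from any database
record.

Positions are reported both as absolute 1-based coordinates on a reference
and as region-local labels (`28S:4447`), which is the frame in which such
sites are conventionally quoted.

## Library generative model

**miCLIP libraries** (`simulate_miclip_library`). Each read is
UMI (10 nt) + insert + 3′ adapter (`AGATCGGAAGAGCACACGTC`), constant quality.
A read's class (rRNA, box C/D snoRNA, H/ACA snoRNA, vtRNA, decoy) is drawn
from the library's class weights; the reference within a class is drawn
length-proportionally and the insert start uniformly, except that start
positions inside a binding window are up-weighted by its
`relative_enrichment` (IP libraries only; SMInput is always uniform).
For the truncation mutant, an insert that overlaps a crosslink site is moved
to start exactly at the site with probability `truncation_prob`. References
shorter than the maximum insert yield intact full-length molecules (small
structured RNAs co-purify whole rather than as RNase fragments), so their
reads all share the 5′ terminus. A truth manifest (TSV) records every read's
source interval, class, truncation flag and UMI.

**Bisulfite libraries** (`simulate_bisulfite_library`). Every read spans the
full amplicon (single-end; a paired 2×250 mode with overlap-merge, read 1
winning on disagreement, is available but not the default — the counting
statistics are identical and the single-end contract is simpler). Each
reference C converts to T independently with its per-site probability —
a (reference, position, condition) override when present, otherwise the
global efficiency — after which a uniform substitution error is applied per
base. The manifest records the per-read conversion outcome at each override
site.

### Shipped ground truth (the study conditions)

| parameter | default | rationale |
|---|---|---|
| crosslink sites | 28S:4447 and vtRNA1_2:27, `truncation_prob` 0.6 | the two reported crosslinked cytosines; 0.6 makes truncation dominant but not total |
| binding window | pre-rRNA 1–600, enrichment 15× | binding concentrated over the early 5′ETS in both WT and mutant IPs |
| IP_C459A class weights | rRNA .978, CD snoRNA .011, vtRNA .006, decoy .0045, H/ACA .0005 | reproduces the mutant's >97 % rRNA read share with a CD-snoRNA-dominant remainder |
| IP_WT class weights | rRNA .985, CD .008, vtRNA .003, decoy .0035, H/ACA .0005 | reproduces the WT's >98 % rRNA share; vtRNA present only as background |
| conversion efficiency | 0.97 | the overall deamination rate of surrounding cytosines |
| site conversion at 28S:4447 | siC 0.16, siNOP2_1 0.28, siNOP2_2 0.34 | the per-condition converted fractions at the target site |
| sequencing error | 0.002/base | amplicon-sequencing scale substitution noise |
| insert length | 70–110 nt | size-selected library; see coverage-geometry note below |
| UMI | 10 nt, 5′ of the insert | standard eCLIP-style layout; length/placement are conventions |
| library sizes | 20,000 (miCLIP), 50,000 (bisulfite) per library | desk-scale sizes that keep every statistical contrast well-powered; the amplicon arm is a scaled-down stand-in for the ~130,000 aligned reads per sample of a MiSeq amplicon run |
| replicates | 2 (miCLIP) / 3 per condition (bisulfite) | the study design |

The bisulfite arm has no free calibration: the measured converted fraction
at a site is the planted probability up to binomial noise
(±3·√(p(1−p)/n) ≈ ±0.5 percentage points at 50,000× coverage) plus a ≤0.15
percentage-point bias from sequencing errors, which is negligible against
the ±1.5-point acceptance band.

### Coverage geometry and the choice of insert length, window and decoys

The site caller's thresholds (below) are fixed; the generator's defaults
were chosen **before freezing** by a power analysis of the false-positive
geometry, then verified empirically. The danger zone is any position whose
coverage sits just above `min_coverage` = 20: there the stop-fraction
threshold corresponds to only 2–4 stop counts, which a Poisson(≈1)
background reaches easily, and the mutant/WT ratio gate reduces to "WT
happened to draw 0–1 stops". Three structural choices keep every evaluated
position out of that band:

* **Insert length 70–110 nt** puts the pre-rRNA coverage plateau at ≈80×,
  where the fraction threshold is 8–9 counts (Poisson tail ~10⁻⁶).
* **The 5′ETS binding window covers the transcript 5′ edge** (1–600, 15×),
  so the low-coverage ramp at the 5′ terminus is flooded with reads in both
  IP libraries and the ratio gate has real WT counts to compare against.
* **Short references produce full-span reads**, so their only start pile-up
  is at position 1, where the WT library shows the same pile-up and the
  ratio test rejects it deterministically; decoys are long (2,000 nt) and
  lightly weighted so their coverage never reaches `min_coverage`.

With these conditions, 29/30 independent simulations at 20,000
reads/library call exactly the two planted sites (the one exception added a
single adjacent position on a coverage fluctuation), and the top-ranked
call was a planted site in 30/30. A residual ~3 % per-run chance of one
extra marginal call is inherent to fixed count thresholds at this depth.

## Analysis chain

**Read preparation.** 3′ adapter trimming removes the longest read suffix
matching an adapter prefix with ≥3-base overlap and Hamming error rate
≤0.1; the 5′ UMI is moved into the read name (after `_`); inserts shorter
than 18 nt are discarded. The length cutoff is applied after UMI removal,
since the UMI is not biological sequence. Every stage logs
`in = out + dropped`.

**Alignment.** Exact k-mer seeds (k = 12) against the reference set
propose candidate loci; candidates are scored as gapless overlays (the
generators emit substitutions only) and fall back to a banded affine
Smith–Waterman extension (band 8 + ⌈0.1·|query|⌉) when the gapless score
misses the threshold. Scores: match +2, mismatch −3, gap open −5, gap
extend −2 (a length-k gap costs −5 − 2(k−1)); records are emitted when the
score reaches 0.66 × the maximum attainable (2·|query|). Ties break toward
the lexicographically first reference, then the leftmost start; the DP
tie-break prefers the smallest target offset, then diagonal moves, making
SAM output byte-deterministic. In bisulfite mode both read and reference
are collapsed C→T for seeding and scoring ("three-letter" alignment), so a
read's conversion pattern cannot affect its score or placement, while the
original read sequence is preserved in the SAM SEQ field for counting.
Alignment is sense-strand only by default (CLIP and amplicon reads are
sense to the RNA); reverse-complement search sits behind a flag. Only the
best hit is reported — the synthetic reference set has no repeat families,
so report-all multi-mapping would add nothing.

**Crosslink analysis.** PCR duplicates collapse on the (reference, start,
strand, UMI, aligned length) key, keeping the highest-scoring record (ties:
first read id), independent of input order. RT-stop profiles count read 5′
starts per position; coverage counts overlapping reads; both are
depth-normalized to reads per million (RPM). The IP/SMInput track is
((c_ip+1)/S_ip)/((c_smi+1)/S_smi) per position. Site calling evaluates
every position with mutant coverage ≥20 and passes those with stop
fraction ≥0.1 and depth-scaled stop ratio
((s_mut+0.5)/S_mut)/((s_wt+0.5)/S_wt) ≥4 — the pseudocount is applied to
raw counts before library-size scaling so that it stays meaningful at any
depth. Windowed enrichment tiles each reference (window 50, step 25,
0-based half-open), tests each window's read-start counts against the
SMInput with a two-sided Fisher exact test, adjusts across all windows by
Benjamini–Hochberg, and flags windows with adjusted p < 0.05 **and** fold
change ≥2 (pseudocount +1, library-size scaled). These two cutoffs are the
decision rule preserved from the original analysis; the windowed
Fisher/BH construction replaces the external peak caller used there, whose
internal model is not part of this package's scope. Read-class composition
assigns each deduplicated record the class of the interval containing its
start; all pre-rRNA regions roll up into "rRNA".

**Bisulfite quantification.** At every reference C in the amplicon, aligned
match columns tally the original read base: C → non-converted, T →
converted, anything else → error column. The converted fraction
n_T/(n_C+n_T) excludes the error column from its denominator and is
reported only at ≥10× coverage. The overall conversion rate pools counts
over all non-excluded rows (the target site is excluded when estimating
chemistry efficiency). Condition comparisons use the two-tailed independent
Student's t-test (pooled variance, df = n₁+n₂−2) over per-replicate
converted fractions, with sample SD (n−1); Welch's correction is available
by flag but off by default. Per-replicate fractions are averaged for
reporting (replicate dots are the unit of inference); pooled-read fractions
are recoverable from the per-replicate tables.

**Pipeline.** One `StudyDesign` drives fixture generation and both arms.
Per-library seeds derive from the global seed as
`(seed·1000 + offset) mod 2³¹` with fixed offsets per arm/condition/
replicate, so a single integer reproduces the whole study byte-for-byte.
Replicates are pooled for site calling and window enrichment;
per-replicate RPM ratio tracks are also averaged into a replicate-mean
track. The run log (JSON lines) carries per-library read accounting, which
must cross-foot (raw = mapped + unmapped + dropped).

## Numerical choices and degenerate inputs

* RPM normalization refuses empty libraries (library size 0).
* `call_sites` reports all evaluated positions with a `passed` flag, sorted
  by descending ratio; an empty profile yields an empty table.
* Fisher tests receive raw deduplicated counts; BH adjustment spans all
  windows of all references in one family.
* Amplicons without a cytosine, sites on absent references, overrides on
  non-C positions, windows with `window < step`, and comparisons with <2
  replicates are rejected with `ValueError`.
* Identical replicate groups give t = 0, p = 1 (when within-group variance
  is non-zero; two zero-variance identical groups are a 0/0 and surface as
  NaN from the underlying test, as in any standard implementation).

## What the generator does not emulate

Constant base qualities (no quality trimming is implemented or needed);
no indels in reads (the aligner's gap machinery is exercised by its own
tests, not by the simulators); no PCR duplication bias beyond optional
exact-duplicate injection; no RNA secondary-structure effects on chemistry
or RT; no repeat families or multi-mapping ambiguity; no genome-scale
annotation. Passing tests therefore demonstrate the correctness of the
statistical machinery under the stated generative model — not robustness to
real-library artifacts such as quality decay, indels, or incomplete
denaturation.

## Problem sizes

The shipped defaults (20,000 reads per miCLIP library, 50,000 per bisulfite
replicate, 3+3+3 amplicon replicates, 20-seed recovery sweeps) were chosen
so the full test suite and the acceptance computation each complete in
minutes on a single CPU while keeping every recovered quantity comfortably
inside its tolerance; they are scaled-down but statistically faithful
versions of the original sequencing depths.
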