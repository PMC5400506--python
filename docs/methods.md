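# Methods

## Scope and model

The package quantifies karyotype evolution in chromosome-instability (CIN)
tumor models at three observational scales — bulk aCGH, shallow single-cell
sequencing, and cross-tumor CNV comparison — and supplies a generative
simulator so that every estimator can be validated against known truth.
Coordinates are 0-based half-open everywhere; the default genome is the 19
mouse autosomes (approximate mm10 lengths). Sex chromosomes are excluded by
default because the bulk workflow assumes sex-mismatched normal reference
DNA, which makes X/Y log2 ratios uninterpretable without a correction we do
not attempt.

## Lineage simulator

A tumor is the terminal population of `divisions` synchronous division
rounds from a single euploid founder (ploidy P, default 2). At every
division each chromosome of each cell independently mis-segregates with
probability `p_mis`; an event is reciprocal — one daughter gains one copy,
the other loses one. This is the simplest generative model consistent with
spindle-checkpoint loss: events are independent across chromosomes and
divisions, and there is no whole-genome doubling, breakage or point
mutation. The full binary tree (2^divisions cells) is simulated, so early
events correctly dominate the terminal clone structure; single-tree
euploid fractions therefore have large variance even though the mean obeys
the closed-form per-lineage random-walk law (verified in the tests by pmf
convolution).

Selection: cells that reach zero copies of any chromosome (nullisomy) are
removed; an optional fitness map re-weights the surviving terminal
karyotypes (a single terminal re-weighting, not compounding per-division
growth-rate differences). The default is neutral-except-nullisomy-lethal.

Focal CNVs are layered on the clone table: each clone lineage receives a
Poisson(`focal_rate`) number of private segments (exponential sizes, mean
`focal_size_bp` = 3 Mb, floored at 0.5 Mb, placed uniformly per chromosome
weighted by length), plus an optional ancestral set present in every clone.

### Rendering

*Pseudo-bulk aCGH.* A probe at position x reports
log2((f·Σ_c w_c s_{c,x} + (1−f)·P)/P) + ε with tumor purity f, clone
weights w, per-clone copy number s and ε ~ N(0, σ²) i.i.d. on the log2
scale (the standard aCGH error model). Zero numerators are floored at 0.05
copies before the log, which keeps homozygous deletions strongly negative
(≈ −5.3) without producing −∞.

*Single cells.* Each cell draws its clone from the clone weights and
scatters `reads_per_cell` reads over bins multinomially, with probability
proportional to bin copy number × bin width. The default depth (20 000
reads, 1 Mb bins) emulates shallow single-cell whole-genome sequencing and
yields roughly 8 reads per bin, a regime where per-bin integer state calling
is shot-noise dominated: real pipelines at this depth pool information
across bins with an HMM, which is deliberately out of scope here. The
renderer therefore also offers `sampling="expected"` (rounded expected
counts, the noise-free limit), and the caller-recovery guarantees below are
stated for that mode. What the multinomial mode adds is realistic count
dispersion for exercising IO and the score pipeline, not a substrate on
which per-bin rounding could be expected to recover truth.

*Relatedness cohorts.* Every simulated mouse carries one benign and one
malignant tumor; each tumor holds `segments_per_tumor` (default 20) focal
segments drawn without replacement from a shared catalog of `n_cnv_loci`
(default 200) non-overlapping recurrent loci, of which
round(shared_fraction × segments_per_tumor) are ancestral (identical in
both tumors of a mouse). A finite catalog is a deliberate design choice:
cross-mouse tumors must coincide occasionally for the per-tumor Jaccard
null to have nonzero variance — with private segments drawn from a
continuum every cross-mouse Jaccard is zero and the Z-score is undefined.
The defaults put within-mouse Jaccard at shared fraction 0.15 near 0.13,
i.e. in the 10–20% overlap regime reported for benign/malignant liver tumor
pairs in Mad2l1-null mice, while the expected within-mouse matched-segment
count follows the closed form k + (n−k)²/(N−k).

All generators are deterministic given `SimConfig.seed`; independent RNG
streams are derived per operation so that, e.g., adding probe noise does not
perturb the clone structure.

## Bulk aCGH scoring

Per-chromosome mean R_c of the probe log2 ratios, called gain at R_c ≥ +τ
and loss at R_c ≤ −τ with τ = 0.3 (inclusive at the boundary — "±0.3
cut-off" is read inclusively; boundary cases are measure-zero under noise).
The mean, not the median, is used deliberately. Chromosomes with no probes
are reported absent rather than zero. From the call rule and the purity
mixture follows the detectability closed form: with σ = 0, a clonal
single-copy gain is callable iff f ≥ 2^1.3 − 2 ≈ 0.4623 and a clonal
single-copy loss iff f ≥ 2 − 2^0.7 ≈ 0.3755; both are confirmed by
bisection sweeps in the tests and the acceptance script.

Focal events are scored on the chromosome-normalized ratio g_p = r_p − R_c
(whose per-chromosome mean is zero by construction), smoothed with a
centered 3-probe moving average truncated at chromosome ends (window 1
disables smoothing; smoothing is never applied to chromosome means). A
segment is a maximal run of ≥ 3 consecutive probes all ≥ +τ or all ≤ −τ,
spanning the first to last probe interval of the run. The implementation is
checked against an independent run-enumeration oracle on random profiles.
Gene counts per segment use ≥ 1 bp overlap against an optional BED gene map.

Aneuploidy burden B = Σ_c |R_c| (log2 units); dosage–expression coupling is
an ordinary Pearson correlation across chromosomes (≥ 3 paired chromosomes,
nonzero variance required). The cohort overlay maps each profile onto a
shared bin grid (mean of probes per bin) and counts tumors ≥ +τ and ≤ −τ
per bin.

The three-probe recombination test classifies a conditional locus from the
inside-probe mean and the nearest flanking probe on each side: recombined if
the inside mean ≤ −τ_del with neutral flanks, unrecombined if the inside
mean is within ±τ, otherwise partially recombined. τ_del = 0.8 separates
homozygous deletion at plausible purity (inside values ≤ −1) from
whole-chromosome loss (≈ −0.4).

## Single-cell karyotypes

States are called per cell as ŝ_b = P·count_b/e_b with e_b = total reads ×
bin width / genome width, rounded half-away-from-zero and clamped to
[0, 10] (the clamp guards near-empty-bin division artifacts). The caller is
exact on noise-free data whenever a cell's genome-wide mean copy number is
near P; strongly aneuploid cells violate that normalization — a real
limitation shared by any total-count normalization. Zero-read cells are
dropped with an explicit warning.

Whole-chromosome karyotypes take the modal bin state per chromosome, with
ties broken toward the state closest to P and then toward the lower state.
Population scores over n ≥ 2 cells:

* A = mean over cells and bins of |s − P| (copies);
* H = mean over bins of the Gini–Simpson index 1 − Σ_k p_k² of the state
  distribution across cells, in [0, 1);
* U = fraction of cells whose whole-chromosome karyotype occurs exactly
  once.

H and A are intentionally separable: a clonal aneuploid population has
A > 0 with H = 0, while ongoing instability raises H (and U). These
definitions are stated openly because published single-cell heterogeneity
and aneuploidy scores vary between pipelines; only qualitative ordering
(unstable tumors ≫ euploid controls), not numeric equality with any
particular pipeline, is claimed. U is defined at whole-chromosome, not bin,
resolution.

## Clonal relatedness

Segments are merged within a tumor, then matched across a pair greedily in
descending reciprocal-overlap order (same chromosome, same sign, reciprocal
overlap ≥ 0.5, one-to-one). Greedy matching equals exhaustive maximum
matching on all tested instances (≤ 6 segments brute-forced over
permutations). J = m/(|a|+|b|−m); a pair of two empty CNV sets is an error
rather than J = 0, since silent zeros would bias nulls.

Each tumor t of a pair gets Z_t = (J(t, partner) − mean N_t)/sd(N_t) where
N_t = {J(t, v): v from other mice} pools both tumor classes (stratification
by class is available as an option) and sd is the sample (n − 1) standard
deviation; N_t needs ≥ 2 members and nonzero spread, otherwise the test is
refused rather than silently degenerate. Classification: strong if both
Z > 1.96 (strictly), weak if exactly one, unrelated otherwise. The test is
run in both directions because J is shared but the nulls are not — a small
tumor nested in a larger one can be exceptional from its own side only.
The normal approximation behind the 1.96 cutoff is approximate for Jaccard
nulls; the simulated type-I strong-call rate is checked against
0.05 + 3·SE rather than 0.05 exactly.

The bundled `liver_pair_zscores` table (ten printed two-way Z-score rows
from a published Mad2l1-conditional mouse liver cohort) is the worked
example for the classifier: it yields exactly two strongly related HCA–HCC
pairs and one weakly related HCC–HCC pair. The published text describes
that HCC pair as strongly related while the printed table stars it once
(weak); the package follows the printed two-way rule and surfaces the
discrepancy rather than resolving it.

## Growth

T_d = ln 2/β from OLS of ln(volume) on time in days (equivalent to log2
regression with T_d = 1/β). β ≤ 0 yields an explicitly undefined doubling
time, never a negative one. Tumors are fitted separately and summarized by
the mean across tumors.

## Numerical and design notes

* Copy floor 0.05 before log2; threshold comparisons inclusive; moving
  average truncated, never wrapped.
* Seeds: all randomness flows from `SimConfig.seed` through named
  `numpy.random.default_rng` streams; rerunning any generator or CLI
  subcommand reproduces outputs bit-identically (checksummed in tests).
* Problem sizes in the test suite and acceptance script — 5×10-Mb toy
  genomes for arithmetic checks, the full 19-autosome layout for recovery
  checks, 200 simulated cohorts of 10 mice for the error-rate estimates,
  500 random profiles for the detection oracle — were chosen so the whole
  suite completes in well under a minute while keeping Monte-Carlo standard
  errors small relative to the tolerances asserted.
* The simulator's defaults (20 000 reads/cell, 45 cells, 1 Mb bins, 20
  segments/tumor, 200-locus catalog, purity 0.7) mirror the data scales of
  the motivating study design: ~45 sorted cells per animal at low coverage,
  44K-style array density, resected liver tumors with substantial normal
  contamination. No claim is made that `p_mis` defaults estimate the in
  vivo mis-segregation rate; they exist to exercise the estimators.

## Known limitations

* No GC/mappability correction, background normalization, or HMM/CBS
  segmentation: bulk input is assumed pre-normalized, and single-cell
  calling is per-bin (hence the noise-free recovery guarantee only).
* The synthetic data lack real-data features — wavy aCGH baselines,
  replication-timing and GC coverage bias, doublets, variable per-cell
  depth — so passing tests demonstrate correctness of the estimators, not
  robustness to those artifacts.
* Fitness acts as a terminal re-weighting, not per-division differential
  proliferation; strongly selective regimes would need the latter.
* Jaccard matching is interval-based; gene-level matching would need a gene
  map and may differ near segment boundaries.
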