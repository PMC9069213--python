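# Methods

## Coordinate scaffold

All statistics live on fixed-width bins (default 200 kb) tiled
independently within each autosomal chromosome arm, 0-based half-open.
Per-arm tiling guarantees no bin straddles a centromere, which matters
because every downstream quantity is aggregated per arm. Trailing
remainders shorter than one bin are dropped, so an arm of length $L$
contributes $\lfloor L/\text{bin\_size}\rfloor$ bins. The packaged hg19 arm
table is derived from the standard UCSC cytoBand centromere (acen)
boundaries and contains all 44 autosomal arms; sex chromosomes are out of
scope. Short or poorly covered arms are not excluded here but fall out
later via the panel's `min_bins_per_arm` filter (default 10 usable bins) —
on real data the acrocentric p-arms (13p, 14p, 15p, 21p, 22p) have
essentially no uniquely mappable 200-kb bins and drop out of the retained
set, which is why arm-level reports typically cover fewer than 44 arms.

## Coverage

Reads are assigned to the bin containing the fragment midpoint (template
span for proper pairs; read span otherwise), counting each fragment once,
after a MAPQ ≥ 30 filter and duplicate exclusion. At 200-kb bins midpoint
assignment is equivalent in expectation to per-base coverage averaging and
much cheaper. Bins are masked when their median count across the panel is
below 10 or more than 20% of panel samples have a zero count; these are
ordinary low-pass hygiene defaults, configurable. Depth normalization
divides by the mean count over usable bins, making $V_b$ exactly
scale-free (doubling every count changes nothing) with mean 1. A
LOESS-style GC correction hook exists in the simulator's bias model but no
GC correction is applied in the pipeline by default.

## Quality control

The noise metric is the scaled MAD of first differences of per-bin log2
copy ratios against the panel mean, pooled genome-wide but never across an
arm boundary (boundary jumps are copy-number structure, not noise). The
MAD uses the 1.4826 consistency constant (configurable): "MAD of copy
ratios" in low-pass CNV practice refers to the scaled estimator. A sample
is excluded when its MAD *exceeds* 0.38 — the published rule is phrased as
a point equality ("was 0.38"), which is meaningless for continuous data,
so the threshold is read as an upper bound. Read depth below 15 M pairs is
recorded as a warning, not an exclusion, so that small simulated cohorts
remain usable; the flag is in the QC report for production use.

## Panel Z-scores

Panel statistics are per-bin and per-arm means and SDs across controls
with the $n-1$ denominator (panels are small; the reference design uses 9
benign controls). Arm-level scoring defaults to "arm-mean" mode — $V_a$ is
the mean of $V_b$ over the arm and $Z_a=(V_a-\mu_a)/\sigma_a$ — because
the source formula is stated for a generic coverage $V$ and results are
reported as one Z per arm. A Stouffer mode ($Z_a=\sum Z_b/\sqrt{n}$) is
provided for sensitivity analysis; both agree in sign on uniform shifts.

**Scoring panel members.** With a 9-control panel, a held-out control's
score is distributed as $\sqrt{1+1/n}\,\cdot t_{n-2}$ per arm, so
leave-one-out scoring puts ≈ 4–5% of control-arm scores beyond |Z| = 2.5
purely by chance — a 9×(arms) control grid would then almost surely show a
false positive. Scoring a member against statistics that include itself
bounds its studentized score at $(n-1)/\sqrt{n}\approx 2.67$ and makes
false control calls rare; this self-inclusion behaviour is what the
evaluation path uses for the control group by default (it is also the only
reading consistent with the assay's published 100% specificity on 9
controls). Leave-one-out scoring remains available and is the correct
choice for null-calibration studies, where it gives pooled bin-level Z with
mean ≈ 0 and SD ≈ 1.1 (the mild inflation is exactly the t-tail effect).

## Segmentation

Circular binary segmentation is implemented from scratch. The arc
statistic compares the mean inside an arc $(i,j]$ to the mean outside,
standardized by the segment SD; the maximizer is found by vectorized
enumeration of all admissible arcs (min width 2), ties broken to the
smallest $i$ then $j$. Significance uses a permutation test with the
add-one estimator $p=(1+\#\{\text{perm max}|T|\ge\text{obs}\})/(1+B)$,
$B=1000$ by default (a desk-scale compromise; configurable). Significant
interior arcs yield ternary splits, boundary arcs binary splits, and the
procedure recurses. Per-sub-segment RNG streams are derived
deterministically from (seed, segment offset, length), so a given
sub-segment's p-value is independent of the recursion path — this makes
the breakpoint set monotone in $\alpha$ for a fixed seed and the whole
segmentation bit-reproducible. Segmentation runs per arm (consistent with
arm-level diagnosis; per-chromosome available). No "undo splits" pruning is
performed: at arm-scale signal it changes nothing, and it is noted as an
extension.

## Diagnosis and evaluation

The diagnostic score is $\max_a|Z_a|$ with positivity at score ≥ cutoff
(boundary inclusive; default 2.50, the Youden-optimal operating point of
the reference confusion tables, with ties broken toward the larger, more
specific cutoff). Arm-level event calls use $|Z_a|\ge$ cutoff with
direction by sign. Proportion CIs are Wilson score intervals with
continuity correction — this is the construction that reproduces the
reference cohort's printed CIs (13/16 → 53.7–95.0%, 10/11 → 57.1–99.5%,
3/5 → 17.0–92.7%) exactly at one decimal, which plain Wilson and
Clopper–Pearson do not. Percentages are displayed rounded half-up to one
decimal (81.25 → 81.3). AUCs are computed by pair counting (ties = 1/2,
the Mann–Whitney identity) with DeLong variance for CIs and the paired
DeLong normal test for comparing correlated markers; the f/t PSA marker is
oriented "low is positive". Fisher's exact test (conditional two-sided)
and the Mann–Whitney U test wrap scipy, except that exact small-sample
Mann–Whitney p-values (total n ≤ 12) are computed by full enumeration with
midranks, which handles ties exactly. The combined test is a plain OR of
CNV positivity and f/t PSA < 16% (missing PSA is non-informative).

## Synthetic cohorts

The generator emulates binned low-pass WGS counts, not reads. Per sample:
a read total is drawn (normal, CV 0.1, around 15 M pairs — the depth the
assay design collects per sample), then distributed over bins by a
multinomial whose weights multiply (i) a shared lognormal per-bin bias
(σ = 0.1) common to all samples, standing in for mappability/GC structure,
(ii) i.i.d. per-bin gamma noise with variance 0.02 (the Poisson-gamma
mixture gives negative-binomial marginal overdispersion — low-pass panels
are overdispersed relative to Poisson, and the panel SD in the Z
denominator must reflect it), and (iii) the event ratio
$r=(1-f)+f\cdot\text{copy\_state}/2$ on arms carrying a simulated CNV at
tumor fraction $f$. Counts therefore sum exactly to the drawn total. The
per-bin dispersion of 0.02 (CV ≈ 14%) is a stated assumption — the true
inter-sample dispersion of urine panels is not published — chosen so that
a typical profile's adjacent-bin MAD (~0.30) sits below the 0.38 QC
threshold, as a passing clinical sample's should. Default cohort shape
mirrors the reference design: 9 benign controls and one arm-level event
per case.

What the generator does *not* model: GC at fragment level, mappability
holes (every toy bin is usable), arm-correlated biological noise in
controls, and subclonal mixtures. Consequently, simulated panels are
"cleaner" than real urine panels: passing recovery tests demonstrates the
statistical machinery (normalization, panel estimation, thresholding)
works as specified, not that real urine sediment at a given tumor fraction
will be detected at the same rate. Toy genomes (4 chromosomes × 20 Mb, 50
bins per arm) are used throughout the tests for speed; the full hg19 grid
(~14,000 bins) runs identically.

## Problem sizes and numerical choices

The test suite and acceptance script run on toy genomes with 9–20 control
panels, 500 k–15 M reads per sample, 100-instance brute-force CBS
cross-checks at n ≤ 50, 200 seeded null CBS runs, and 200-instance
AUC-vs-trapezoid checks — sizes chosen so the whole suite completes in
well under a minute apart from the permutation batteries. Epsilon 1e-9
guards log ratios; zero-SD bins/arms are dropped from panels with a
warning; a degenerate (all-identical) panel raises. "Arm-identity
accuracy" in recovery runs is defined as the fraction of positive cases
whose top-scoring arm equals the simulated event arm — the quantity the
max-|Z| classifier actually reports; per-call accuracy over all
supra-threshold arms is necessarily lower with a 9-control panel because
null-arm scores have $t_8$ tails (≈ 4% of null case-arms exceed 2.5
regardless of sequencing depth).

## Known limitations

* No GC/mappability correction is applied by default; supply pre-filtered
  count tables or a custom arm table for difficult regions.
* The max-|Z| score ignores multi-arm evidence; a count-of-arms score is
  trivially derivable from `summarize_cnv_events` but is not the default.
* Tumor-fraction estimation and focal (sub-arm) CNV calling are out of
  scope: segmentation output is descriptive, not diagnostic.
* With panels this small the Z denominators are noisy (t tails); treat
  per-arm p-value-like interpretations of Z with caution.
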