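# Methods

## Screening model

Expression values are log2 intensities; all statistics operate on that
scale. For probe *p* with control values x and case values y, the screen
computes Δ = mean(y) − mean(x), the absolute linear fold change
FC = 2^|Δ|, and a two-sided two-sample t-test. The default test is the
pooled-variance (equal-variance) unpaired t:

    sp² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁+n₂−2),
    t = Δ / sqrt(sp²(1/n₁ + 1/n₂)),  df = n₁+n₂−2.

The pooled form was chosen because recomputing the bundled worked example
from its printed triplicates reproduces every printed p-value under pooled
degrees of freedom (df = 4 at n = 3 + 3) but not under Welch; case and
control subjects are unpaired, so the paired mode exists only for designs
that need it. A probe is significant when FC ≥ 2 and raw p < 0.05 — the
filter uses raw p deliberately, to match the screening convention this
design follows; BH-adjusted FDR is computed across all tested probes and
reported in the same table for readers who want the stricter view. With
n = 3 per group this screen has no variance moderation and limited power;
that is a property of the design being reproduced, not an oversight.

Ranking is by FC descending, ties by ascending p then probe id, making
output tables byte-reproducible. Degenerate inputs: both groups constant
and equal gives p = 1 by convention; constant but different gives the
p → 0 limit. Probe → gene collapsing (needed before set enrichment when
multiple probes share a symbol) keeps the probe with the largest FC.
Gene-symbol matching is exact and case-sensitive by default, with an
opt-in upper-casing flag.

## Clustering

Distance between profiles is d = 1 − r with r the centered Pearson
coefficient (means subtracted — the ordinary r; the uncentered variant is
available as a flag). Zero-variance profiles make r undefined and are a
hard error naming the probes. Agglomeration uses average linkage by
default (single/complete available): the linkage choice is an assumption,
documented as such, since classic clustering tools default differently.
Correlation is scale-invariant, so clustering runs on raw log2 values;
row standardization (mean 0, population sd 1) is applied only to the
exported heatmap table. Trees are written as Newick with branch lengths
equal to merge-height differences.

## Set enrichment

Both the functional-term analysis and the TF association use the same
statistic: the upper-tail hypergeometric probability of drawing at least
k annotated genes when n query genes are drawn from a universe of M
containing K, identical to a one-sided Fisher's exact test. The universe
defaults to all genes annotated in the collection; a custom universe (the
array's measured genes) can be supplied and is the default in the TF stage,
so unmeasured genes never deflate p-values. Term sets are flat — no
ontology parent propagation — and BH correction is applied within one
collection at a time. Implementation rides on scipy's hypergeometric
survival function and statsmodels' BH routine; tests pin both against
brute-force enumeration over all draws for small universes, one-sided
Fisher on random 2×2 tables, and hand-computed step-up vectors.

## Co-expression network

Pearson r is computed across all samples, both groups pooled, between
every (significant lncRNA, significant mRNA) pair, and an edge is kept at
|r| ≥ 0.99. The magnitude reading of "no less than 0.99" is the default
because negative co-expression is biologically meaningful; a signed-only
mode is a flag. With six samples the null tail is
P(|r| ≥ t) = 1 − 3t/2 + t³/2 (from the null density ∝ (1−r²)^((n−4)/2)),
so P(|r| ≥ 0.99) ≈ 1.5 × 10⁻⁴ — the threshold admits essentially only
near-deterministic linear relationships, and the test suite checks the
observed null edge rate against this closed form. Zero-variance probes are
excluded with a warning rather than silently assigned r = 0.

## TF association and the tripartite network

Each lncRNA's set of co-expressed mRNA symbols is tested against each TF's
target set; k is the partner/target overlap, n the partner-set size within
the universe, K the target-set size, M the universe (TF-collection genes ∩
measured mRNA symbols). BH runs jointly over all (lncRNA, TF) pairs —
one FDR over the whole discovery set — with a per-lncRNA option; a pair is
accepted when p < 0.01 and FDR < 0.01. Accepted pairs assemble the
tripartite graph: TF→lncRNA per association, TF→mRNA for each overlap gene
that drove the association (full-target mode would clutter the graph),
lncRNA–mRNA from co-expression. Node degree attributes are stamped at
write time and equal incident-edge counts; hub ranking is TFs by degree.
No differential-expression filter is applied to TFs themselves.

## qPCR quantification

ΔCt = mean(target Ct) − mean(reference Ct) per sample; ΔΔCt references the
*control-group mean* ΔCt rather than a single calibrator sample — the
group-mean Livak variant, the only one compatible with mean ± SEM group
bar plots; RQ = 2^−ΔΔCt with amplification efficiency fixed at perfect
doubling. The case/control comparison is an unpaired pooled t-test on
ΔΔCt, not on RQ: under additive Ct noise ΔΔCt is Gaussian while 2^x skews
the variance. Since the calibrator is a constant shift, the test on ΔΔCt
is identical to the test on ΔCt, and control log2 RQ has mean exactly 0 by
construction.

## Synthetic data

The generator emulates a two-group array study at desk scale (defaults:
1000 lncRNA + 1000 mRNA probes, 3 samples per group). Per-probe baselines
are Normal(8, 2.5) on the log2 scale — matching the dynamic range of the
worked-example intensities (~2.6 to 17) — with within-group noise sd 0.5.
Differential probes add ±de_shift (default 2.5 log2 units, ≈ 5.7-fold, the
regime of the top published probes) to all case samples, signs split
50/50, mirroring the roughly balanced up/down discovery split. Each
co-expression module has one latent factor z_s ~ Normal(0, 1) per sample;
members take μ_p + β·z_s + Normal(0, σ_m) with β = 3, σ_m = 0.15. The
β/σ_m ratio of 20 puts the population within-module correlation at
β²/(β²+σ_m²) ≈ 0.9975; a direct bivariate simulation of that law shows
~95% of module pairs exceed a sample |r| of 0.99 at n = 6, which is what
the recovery tests check against. TF sets take 90% of their matched
module's mRNA symbols plus random fill to a fixed size (40); surplus TFs
are pure-decoy sets. qPCR simulation places reference Ct at
Normal(20, ct_sd), target Ct a fixed 5 cycles above minus the planted
log2 ratio for cases, replicate noise Normal(0, ct_sd), so the expected
case RQ is exactly 2^ratio.

What the generator does *not* emulate: dye/batch effects, spatial
artifacts, probe cross-hybridization, intensity-dependent variance, and
heavy-tailed noise. Passing recovery tests therefore demonstrates that the
statistics behave correctly under their own assumptions, not that the
thresholds are well-calibrated for any particular real array platform.

DE probes and module members are drawn disjointly: module latent factors
have no group mean difference, so module membership and differential
expression are separate planted properties with separate truth tables.

## Problem sizes and determinism

Recovery experiments run at 2000 probes for the screen (200 planted) and
400 + 400 probes with three 3×10 modules for the network stages — sizes
chosen so the full suite and the reproduction script each run in seconds
while leaving binomial error bars far smaller than the margins being
checked. All randomness flows from explicit integer seeds
(numpy default_rng); identical config and seed give bit-identical outputs,
including GMT files and pipeline result tables.

## Known limitations

- The |r| ≥ 0.99 edge threshold at n = 6 is extreme; with so few samples a
  sample correlation near 1 can still arise from a shared group shift
  (differential probes of matching sign correlate across pooled groups).
  The pipeline reproduces this behaviour faithfully rather than correcting
  it; interpret edges accordingly.
- p-values printed as 0.00 in legacy tables are treated as "< 0.005 after
  rounding"; the rounding convention is assumed.
- The screen's raw-p filter does not control FDR across ~10⁵ probes; the
  reported BH column is the rigorous alternative.
- No moderated-variance (limma-style) estimator is offered; the plain
  t-test is the method being reproduced.
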