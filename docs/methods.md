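# Methods

This note documents the statistical model behind `drynet`, the synthetic
data generator that stands in for the original measurements, the numerical
choices that matter, and what the package's passing tests do and do not show
about real data.

## Statistical procedures

**Stage-wise treatment response.** For each feature at each developmental
stage, the deficit/control contrast is log₂(mean_D / mean_C) of *raw*
concentrations (arithmetic group means, not log-means) and a two-group
one-way ANOVA: F = SS_between / (SS_within / (n−2)) with df (1, n−2), which
for two groups equals the squared pooled-variance t statistic. Significance
uses the per-sampling-point rule P < α (default 0.05) with **no**
multiple-testing correction across the table — the per-point usage is
deliberate and matches how such response heatmaps are annotated. Zero
within-group variance with unequal means is reported as F = ∞, p = 0 and
flagged `degenerate`; a stage present in only one arm yields p = NaN rather
than an abort.

**Condition networks.** Within one condition's samples, every metabolite
pair is scored by the sample Pearson correlation; a pair becomes an edge
when |r| > r_min (0.8) *and* its two-sided permutation p < α (0.001). The
permutation null permutes one variable's sample labels B = 2000 times per
pair and uses the add-one estimate p = (#{|r_b| ≥ |r_obs|} + 1)/(B+1); ties
count as exceedances (conservative), and the smallest attainable p, 1/2001 ≈
5·10⁻⁴, is what makes the P < 0.001 gate satisfiable at B = 2000 — the
config validator warns when α ≤ 1/(B+1). Each pair draws its permutations
from an RNG stream keyed by (seed, unordered feature pair), so the edge set
cannot depend on evaluation order or parallel scheduling. Since an edge
requires both conditions and the p-gate can never admit a pair that fails
the r-gate, permutations are evaluated only for pairs with |r| > r_min.
Zero-variance features are kept as isolated nodes and logged. Correlations
are computed on raw concentrations by default; a log-scale flag is provided
because the original transform is not knowable.

**Topology.** Cytoscape-NetworkAnalyzer conventions: average degree and the
mean local clustering coefficient are taken over connected (degree ≥ 1)
nodes, nodes of degree < 2 contribute clustering 0, and density is
2E / (n_c(n_c−1)) over the n_c connected nodes. Note a consequence used
below: a network consisting of a single edge has density 1.0.

**Integration.** The metabolite (2×6×4) and transcript (2×3×3) designs are
merged by *replicate pairing*: within each shared (treatment, stage) cell,
replicate i pairs with replicate i up to the smaller replicate count, giving
18 aligned samples; *stage means* (6 cell-mean samples) is available as an
alternative. Correlation is computed jointly across the merged C+D samples
(a per-condition flag exists). For a target metabolite, genes are first
gated at permutation p < 0.001 (same null as above) and then the top k = 100
by |r| are reported with ranks; ties break by gene id, and signed-r ranking
is available. Overlap accounting is an exact Venn: genes in exactly one
target's list, in exactly two, and in all.

**Promoter enrichment.** Promoters are scanned with degenerate IUPAC
consensus matching on the forward strand plus the reverse complement of the
consensus (equivalent to the reverse strand); overlapping matches count, a
promoter is "associated" with a motif if it has ≥ 1 match anywhere, and an
`N` in the sequence matches only a motif `N`. Enrichment of a gene set of
size n against the N-promoter background with K associated promoters and k
in-set hits is the exact hypergeometric upper tail P(X ≥ k). A motif is
significant when raw p < 0.01 **and** k ≥ 10; no FDR is applied at this
stage, whereas GO-slim terms are tested with the same tail and
Benjamini–Hochberg control at FDR 0.05 — the asymmetry between the two
stages is intentional and mirrors the source procedures. The enrichment
score is −log₁₀ p (2 at p = 0.01, 4 at p = 10⁻⁴).

## The synthetic generator

`drynet.simulate` emulates the study conditions, not merely a smoke-test
input. Defaults: 74 metabolites over 2 treatments × 6 stages (27–93 days
after anthesis) × 4 replicates; 2000 genes over 2 × 3 stages (41, 68, 93) ×
3 replicates; 1000-nt promoters at GC 0.35; log-normal noise σ = 0.15 on the
log scale; module loading 0.9; a 100-gene regulon with motif plant rates
0.8 (regulon) / 0.05 (background).

**Abundance model.** log X = baseline + signal + ε, ε ~ N(0, σ²), so all
abundances are strictly positive and right-skewed. The default planted
structure is four modules: a phenylpropanoid core (6 members) and VOC core
(5) coupled in both conditions, and a phenylpropanoid-drought module (8) and
monoterpene-drought module (10) coupled **only under D** — deficit-only
coupling is how the generator encodes the paper-style observation that the
deficit network is denser. Drought modules also carry true treatment
effects (log₂FC(D/C) = 1) in disjoint stage windows: before veraison
(27–54 DAA) for the phenolic responders, late ripening (82–93 DAA) for the
monoterpene-like ones. The windows are disjoint on purpose: a shift shared
by two modules is itself a common signal and, on the raw (exponentiated)
scale, was measured to push cross-module sample correlations past the 0.8
gate.

**Trajectories.** Latent developmental trajectories are smooth low-order
polynomials over the stage grid. Raw monomials (t, t², t³) are nearly
collinear on [0,1] — two independent random cubics correlate at ≈ 0.9, which
would flood the networks with false edges — so trajectories are random unit
combinations of a Gram–Schmidt-orthonormalized polynomial basis (degrees
1..min(5, stages−1), zero mean, unit sd per stage grid), and the coefficient
vectors of distinct modules are QR-orthogonalized so distinct module latents
are *exactly* uncorrelated across stages. A module member's log-signal is
loading × latent in its coupled condition. In the uncoupled condition each
member keeps only a weak private trajectory (amplitude 0.25 vs loading 0.9,
again orthogonalized within the module), so an uncoupled pair's attainable
|PCC| stays well below the 0.8 gate (≈ a²/(a²+σ²) ≈ 0.74 at most, ≈ 0 in
population after orthogonalization). Background features — metabolites
outside every module, genes without a planted link — are exchangeable noise
around their baselines with no developmental signal at all.

That last choice is a deliberate idealization, and the main caveat when
transferring conclusions to real data: real berry metabolites *all* follow
developmental trajectories, and with only 3–6 distinct stages two unrelated
smooth profiles can correlate arbitrarily well. On real data the |r| > 0.8 ∧
p < 0.001 gate therefore admits developmentally co-varying but mechanistically
unrelated pairs; the generator's exchangeable background makes "false edge"
a well-defined, measurable category instead. Passing recovery tests show the
machinery finds exactly what was planted under the stated noise model — they
do not certify specificity against shared-trajectory confounding.

**Gene coupling.** Each linked gene is assigned to a specific partner
metabolite (round-robin within its module) and tracks that metabolite's full
deterministic log-signal — shared latent in the coupled condition, the weak
private trajectory otherwise, treatment effect included — plus its own
noise. This is the profile of a biosynthetic gene whose expression drives
its product, and it keeps planted links recoverable under the default
*joint* C+D correlation even for deficit-only modules (measured top-100
recovery ≈ 87–98% across seeds, vs ≈ 78% if the uncoupled arm were pure
noise). DE flags are the linked genes plus a random 10% of the gene
universe — the pipeline only annotates DE status, it never calls it.

**Promoters and motifs.** Sequences are i.i.d. with the configured GC
content; each planted motif is inserted (uniform position, random strand,
replacing the underlying bases, one concrete realization of the degenerate
consensus) into each regulon promoter with probability 0.8 and each
background promoter with probability 0.05. The default library is
*synthetic* and PLACE-style: three plantable drought/MYB/ABA-like elements
and 22 decoys, all 8–10 nt with at most one degenerate position. Consensi of
that length were chosen because genuine plant cis-element catalogs list 5–6
nt degenerate cores whose spontaneous rate in 1-kb sequence is ≥ 0.5
matches/promoter — presence/absence enrichment has no power against such
saturation, so a desk-scale study needs rarer elements (a fully specified
6-mer already averages 2·995/4⁶ ≈ 0.486 spontaneous matches per promoter,
verified against simulation in the tests).

**Determinism.** All randomness flows from one seed through named
substreams (module latents, member trajectories, metabolite noise,
transcript noise, per-gene promoters, annotations), so regenerating with
more genes never perturbs metabolite draws, and identical configs are
bit-identical. Per-pair permutation streams are keyed by feature labels as
described above.

## Numerical choices and edge cases

- Permutation p-values count ties (|r_b| ≥ |r_obs| − 10⁻¹²) as exceedances.
- Hypergeometric tails use the exact survival function
  (`scipy.stats.hypergeom.sf`), dual-checked in the tests against explicit
  binomial-coefficient sums for N ≤ 20; BH adjustment delegates to
  `statsmodels` and is dual-checked against a hand step-up oracle.
- Enrichment scores cap p at 10⁻³⁰⁰ before −log₁₀ to avoid infinities.
- TSV readers use round-trip float parsing so write→read→write is
  byte-identical; pipeline manifests store outdir-relative paths so two runs
  of the same config hash identically anywhere on disk.
- `stage_means` alignment refuses designs yielding < 3 aligned samples
  (correlation undefined); pairing uses min(reps) and drops the surplus
  metabolite replicate (replicate 4 has no transcript partner).
- Gate monotonicity (raising r_min or lowering α never adds edges) holds by
  construction and is property-tested.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo checks run at the design sizes stated above: permutation-null
calibration uses 1000 Gaussian pairs at n = 24, B = 500; the deficit-density
contrast uses 100 seeds of a 20-metabolite, one-drought-module design at
B = 2000; recovery checks use the full default dataset (74 × 48, 2000 × 18,
2000 promoters) at the study thresholds. These sizes make the whole suite
complete in well under a minute of Monte-Carlo per check while leaving the
binomial error of each estimated rate far below the margins asserted.

## Known limitations

- The generator's background features are exchangeable noise (see above);
  no shared-trajectory confounding, no batch effects, no missing values.
- Promoter sequences are i.i.d.; no dinucleotide structure, CpG/ATA islands,
  or positional bias of cis-elements relative to the TSS.
- The ANOVA is the plain two-group fixed-effects test; no repeated-measures
  structure across stages is modeled, matching the per-point analysis.
- Motif scanning is consensus matching only — no PWMs, no conservation; a
  match is binary and counts do not enter the enrichment statistic.
- The pipeline annotates, but never computes, differential expression.
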