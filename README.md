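# drynet

Condition-specific correlation networks, metabolite–transcript integration,
and promoter motif enrichment for two-treatment developmental multi-omics
designs — with a ground-truthed synthetic data generator so every stage of
the analysis can be exercised and scored at desk scale.

## The problem

When grapevine berries develop under water deficit (D) versus full
irrigation (C), secondary metabolism is rewired: metabolite–metabolite
correlation networks become denser under deficit, drought-induced
monoterpenes acquire strong transcript correlates, and the promoters of
those correlated genes are enriched for drought-responsive cis-regulatory
elements. `drynet` implements that analysis chain as a tested, reusable
pipeline for anyone working with a *two treatments × developmental stages ×
replicates* metabolite matrix plus a matching transcript matrix and promoter
set:

1. **Treatment response** — per (metabolite, stage): log₂FC(D/C) of group
   means and a one-way ANOVA (two groups, so F = t²), the table behind a
   response heatmap.
2. **Condition networks** — for each condition separately, an edge joins
   metabolites *i, j* when |PCC(xᵢ, xⱼ)| > 0.8 **and** the two-sided
   permutation p < 0.001 (B = 2000 label permutations, p = (#{|r_b| ≥
   |r_obs|} + 1)/(B + 1), so min p = 1/2001). Topology is summarized
   NetworkAnalyzer-style: average degree, mean local clustering coefficient,
   and density, all over connected nodes.
3. **Integration** — metabolite and transcript matrices are merged on shared
   (treatment, stage) cells (replicate pairing → 18 aligned samples, or
   stage means → 6); per target metabolite the top-100 genes by |r| among
   those passing permutation p < 0.001 form a bipartite gene–metabolite
   network with DE and pathway annotations, Venn overlap counts, and
   per-pathway positive/negative link tallies.
4. **Promoter enrichment** — 1-kb promoters are scanned on both strands for
   degenerate IUPAC consensus motifs; a motif is enriched in a gene set when
   the hypergeometric upper tail P(X ≥ k | N, K, n) is < 0.01 and the motif
   occurs in ≥ 10 of the set's promoters (score = −log₁₀ p: 2 ↔ p = 0.01,
   4 ↔ p = 10⁻⁴). GO-slim terms use the same tail with Benjamini–Hochberg
   control at FDR 0.05.

Because the original raw measurements are not available at desk scale, the
package ships a synthetic generator (`drynet.simulate`) that emulates the
study design — log-normal abundances, smooth latent developmental
trajectories shared within planted modules, deficit-only module coupling,
gene–metabolite links through shared latents, and motif instances planted in
a regulon's promoters — and records every planted fact in a truth object so
recovery can be measured exactly.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic design (74 metabolites × 48 samples; 2000 genes × 18 samples;
2000 × 1-kb promoters):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_treatment_response.py
python analysis/03_metabolite_networks.py --seed 1
python analysis/04_gene_metabolite_network.py --seed 1
python analysis/05_promoter_enrichment.py
```

which prints (seed 1):

```
planted edges     : C=25, D=98
...
444 (feature, stage) records (74 metabolites x 6 stages)
91 significant at alpha=0.05 (20.5%)
...
C: 25 edges over 11 connected nodes; avg degree 4.55, clustering 1.00, density 0.455
D: 104 edges over 29 connected nodes; avg degree 7.17, clustering 0.92, density 0.256
edge contrast: 25 shared, 0 C-only, 79 D-only (deficit adds connectivity)
...
  met_020: 47 links pass P<0.001 (planted recovered 5/6)
  met_021: 53 links pass P<0.001 (planted recovered 5/6)
  met_022: 37 links pass P<0.001 (planted recovered 6/6)
network: 63 genes, 60 DE (95%)
...
3 significantly enriched motifs (P < 0.01, >= 10 promoters):
  ABRE_LIKE       k= 51 K= 185 score=  43.7 [planted]
  DRE_CRT_LIKE    k= 48 K= 223 score=  34.4 [planted]
  MYB_CORE_LIKE   k= 44 K= 192 score=  31.7 [planted]
1 GO-slim terms significant at FDR 0.05: secondary_metabolic_process
```

Reading this: the deficit network carries ~4× the control's edges (the
planted drought modules cohere only under D), every planted metabolite edge
passes the study gate, the drought-responsive monoterpene-like metabolites
recover 16 of their 18 planted gene links inside their top-100 correlator
lists, and the three motifs planted in the regulon promoters are exactly the
three significantly enriched motifs, with all 22 decoys null.

The same pipeline runs from one config via the CLI
(`drynet run --config cfg.yaml --seed 1 --out DIR`), and each stage is
available as a subcommand (`drynet simulate|response|corrnet|integrate|motifs`)
for use with real TSV/FASTA inputs.

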