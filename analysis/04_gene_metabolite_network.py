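#!/usr/bin/env python
"""Gene-metabolite integration: top-100 correlators per target metabolite.

Merges the metabolite and transcript matrices on shared (treatment, stage)
cells (replicate pairing, 18 aligned samples), extracts for each target
metabolite the top-100 genes by |PCC| among those passing the permutation
P < 0.001 gate, and summarizes target-specific vs shared links and
pathway-level positive/negative edge counts. Targets default to the planted
drought-responsive monoterpene-like module members, the analogue of
linalool / nerol / alpha-terpineol.
"""

import argparse
import json
from pathlib import Path

from drynet.containers import OmicsMatrix
from drynet.integrate import (align_samples, build_gene_metabolite_network,
                              overlap_summary, pathway_edge_summary,
                              top_correlators, write_links_tsv,
                              write_network_sif, write_overlap_json)
from drynet.simulate import SyntheticTruth


def read_map(path: Path) -> dict[str, str]:
    out = {}
    for line in path.read_text().splitlines()[1:]:
        gene, pw = line.split("\t")
        out[gene] = pw
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--k", type=int, default=100)
    ap.add_argument("--alpha", type=float, default=0.001)
    ap.add_argument("--perms", type=int, default=2000)
    ap.add_argument("--targets", default="auto",
                    help="Comma-separated metabolite ids, or 'auto'.")
    ap.add_argument("--out", type=Path, default=Path("results/integration"))
    args = ap.parse_args()

    metab = OmicsMatrix.read_tsv(args.data / "metabolites.tsv",
                                 args.data / "metabolite_samples.tsv")
    trans = OmicsMatrix.read_tsv(args.data / "transcripts.tsv",
                                 args.data / "transcript_samples.tsv")
    truth = SyntheticTruth.from_json(args.data / "truth.json")
    de_flags = set((args.data / "de_flags.txt").read_text().split())
    pathway_map = read_map(args.data / "pathway_map.tsv")

    if args.targets == "auto":
        targets = sorted({m for m, mod in truth.module_membership.items()
                          if mod == "monoterpene_drought"})[:3]
    else:
        targets = args.targets.split(",")

    merged = align_samples(metab, trans)
    print(f"merged matrix: {merged.values.shape[0]} features x "
          f"{merged.values.shape[1]} aligned samples; targets: {', '.join(targets)}")

    links = {}
    for met in targets:
        links[met] = top_correlators(merged, met, k=args.k, alpha=args.alpha,
                                     B=args.perms, seed=args.seed,
                                     de_flags=de_flags, pathway_map=pathway_map)
        planted = {g for g, m in truth.planted_gene_metabolite_links if m == met}
        got = {l.gene_id for l in links[met]}
        print(f"  {met}: {len(links[met])} links pass P<{args.alpha} "
              f"(planted recovered {len(planted & got)}/{len(planted)})")

    args.out.mkdir(parents=True, exist_ok=True)
    write_links_tsv(links, args.out / "gene_metabolite_links.tsv")
    overlap = overlap_summary(links)
    write_overlap_json(overlap, args.out / "overlap_summary.json")
    graph = build_gene_metabolite_network(links, de_flags=de_flags,
                                          pathway_map=pathway_map)
    write_network_sif(graph, args.out / "network.sif", args.out / "nodes.tsv")

    genes = {l.gene_id for ls in links.values() for l in ls}
    n_de = sum(1 for g in genes if g in de_flags)
    print(f"network: {len(genes)} genes, {n_de} DE "
          f"({100 * n_de / len(genes):.0f}%)")
    print("overlap:", json.dumps(overlap.as_dict(), sort_keys=True))
    for s in pathway_edge_summary([l for ls in links.values() for l in ls],
                                  pathway_map):
        print(f"  pathway {s.pathway}: {s.n_positive} positive / "
              f"{s.n_negative} negative links")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
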