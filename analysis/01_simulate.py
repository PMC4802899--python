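#!/usr/bin/env python
"""Generate the synthetic two-treatment developmental multi-omics study.

Emulates the measured design the downstream analyses expect: 74 metabolites
over 2 treatments (C = irrigated control, D = deficit) x 6 stages x 4
replicates, 2000 transcripts over 2 x 3 x 3, 1-kb promoters, a PLACE-style
motif library, and ground truth for every planted structure. Writes
everything as plain text under results/synthetic/.
"""

import argparse
import json
from pathlib import Path

from drynet.simulate import SynthConfig, generate_dataset, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()

    config = SynthConfig(seed=args.seed)
    dataset = generate_dataset(config)
    manifest = write_dataset(dataset, args.out)

    truth = dataset.truth
    print(f"metabolite matrix : {dataset.metabolites.values.shape[0]} x "
          f"{dataset.metabolites.values.shape[1]} (2 treatments x 6 stages x 4 reps)")
    print(f"transcript matrix : {dataset.transcripts.values.shape[0]} x "
          f"{dataset.transcripts.values.shape[1]} (2 x 3 x 3)")
    print(f"promoters         : {len(dataset.promoters)} x 1000 nt")
    print(f"planted edges     : C={len(truth.planted_edges['C'])}, "
          f"D={len(truth.planted_edges['D'])}")
    print(f"planted links     : {len(truth.planted_gene_metabolite_links)} "
          f"gene-metabolite pairs; regulon of {len(truth.regulon_genes)} genes")
    print(f"planted motifs    : {sorted(truth.planted_motif_ids)}")
    print(json.dumps(manifest, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
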