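"""Metabolite-transcript integration: merged matrices, top-k gene correlators
per target metabolite, annotated bipartite networks, and overlap / pathway
edge accounting.

The merge aligns the metabolite design (6 stages x 4 replicates) with the
transcript design (3 stages x 3 replicates) either by replicate pairing
(replicate i of a shared (treatment, stage) cell in one assay is paired with
replicate i in the other, up to the smaller replicate count; default, 18
aligned samples) or by stage means (one aligned sample per shared cell, 6).
Gene-metabolite links are gated at a permutation P < alpha and then ranked
by |r| ("top 100 correlating genes" rule).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .stats import permutation_pvalues_bulk

__all__ = [
    "MergedMatrix", "GeneMetaboliteLink", "OverlapSummary", "PathwayEdgeSummary",
    "align_samples", "top_correlators", "build_gene_metabolite_network",
    "overlap_summary", "pathway_edge_summary", "write_links_tsv",
    "write_overlap_json", "write_network_sif",
]

STRATEGIES = ("replicate_pairing", "stage_means")


@dataclass
class MergedMatrix:
    """Metabolite and transcript features over a common aligned sample axis."""

    values: pd.DataFrame            # features x aligned samples
    origin: pd.Series               # feature -> 'metabolite' | 'transcript'
    alignment_strategy: str
    aligned_meta: pd.DataFrame      # aligned sample -> treatment, stage_daa

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.origin.index[self.origin == "metabolite"])

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.origin.index[self.origin == "transcript"])

    def subset_condition(self, condition: str) -> "MergedMatrix":
        keep = list(self.aligned_meta.index[self.aligned_meta["treatment"] == condition])
        return MergedMatrix(values=self.values.loc[:, keep],
                            origin=self.origin,
                            alignment_strategy=self.alignment_strategy,
                            aligned_meta=self.aligned_meta.loc[keep])


@dataclass(frozen=True)
class GeneMetaboliteLink:
    gene_id: str
    metabolite_id: str
    r: float
    p: float
    rank: int
    is_de: bool = False
    pathway: str | None = None


@dataclass
class OverlapSummary:
    """Exact Venn counts of per-metabolite link gene sets."""

    per_metabolite_specific: dict[str, int]
    pairwise_shared: dict[tuple[str, str], int]
    shared_by_all: int

    def as_dict(self) -> dict:
        return {
            "per_metabolite_specific": dict(self.per_metabolite_specific),
            "pairwise_shared": {" & ".join(k): v for k, v in self.pairwise_shared.items()},
            "shared_by_all": self.shared_by_all,
        }


@dataclass(frozen=True)
class PathwayEdgeSummary:
    pathway: str
    n_positive: int
    n_negative: int
    condition: str


def align_samples(metab: OmicsMatrix, trans: OmicsMatrix,
                  strategy: str = "replicate_pairing") -> MergedMatrix:
    """Merge the two assays onto a shared (treatment, stage) sample axis."""
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    cells_m = {(t, s) for t, s in zip(metab.metadata.loc[metab.sample_ids, "treatment"],
                                      metab.metadata.loc[metab.sample_ids, "stage_daa"])}
    cells_t = {(t, s) for t, s in zip(trans.metadata.loc[trans.sample_ids, "treatment"],
                                      trans.metadata.loc[trans.sample_ids, "stage_daa"])}
    shared = sorted(cells_m & cells_t, key=lambda c: (c[0], c[1]))
    if len(shared) < 2:
        raise ValueError("matrices share fewer than 2 (treatment, stage) cells")
    overlap = set(metab.feature_ids) & set(trans.feature_ids)
    if overlap:
        raise ValueError(f"feature id collision between assays: {sorted(overlap)[:3]}")

    cols_m: list[np.ndarray] = []
    cols_t: list[np.ndarray] = []
    ids: list[str] = []
    meta_rows: list[dict] = []
    if strategy == "replicate_pairing":
        for t, s in shared:
            sm = metab.samples_for(treatment=t, stage_daa=int(s))
            st = trans.samples_for(treatment=t, stage_daa=int(s))
            for i in range(min(len(sm), len(st))):
                cols_m.append(metab.values[sm[i]].to_numpy(dtype=float))
                cols_t.append(trans.values[st[i]].to_numpy(dtype=float))
                ids.append(f"{t}_{s}_r{i + 1}")
                meta_rows.append({"treatment": t, "stage_daa": int(s)})
    else:
        for t, s in shared:
            sm = metab.samples_for(treatment=t, stage_daa=int(s))
            st = trans.samples_for(treatment=t, stage_daa=int(s))
            cols_m.append(metab.values[sm].to_numpy(dtype=float).mean(axis=1))
            cols_t.append(trans.values[st].to_numpy(dtype=float).mean(axis=1))
            ids.append(f"{t}_{s}_mean")
            meta_rows.append({"treatment": t, "stage_daa": int(s)})
        if len(ids) < 3:
            raise ValueError("stage_means alignment yields < 3 samples; "
                             "correlation undefined downstream")

    top = np.column_stack(cols_m)
    bottom = np.column_stack(cols_t)
    values = pd.DataFrame(np.vstack([top, bottom]),
                          index=list(metab.feature_ids) + list(trans.feature_ids),
                          columns=ids)
    origin = pd.Series(["metabolite"] * metab.n_features
                       + ["transcript"] * trans.n_features, index=values.index)
    aligned_meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="aligned_sample"))
    return MergedMatrix(values=values, origin=origin,
                        alignment_strategy=strategy, aligned_meta=aligned_meta)


def top_correlators(merged: MergedMatrix, metabolite_id: str, k: int = 100,
                    alpha: float = 0.001, B: int = 2000, seed: int = 0,
                    de_flags: set[str] | None = None,
                    pathway_map: dict[str, str] | None = None,
                    rank_by: str = "abs_r") -> list[GeneMetaboliteLink]:
    """Top-k transcripts correlating with one metabolite at the P < alpha gate.

    Genes are first gated by permutation p < alpha, then the k largest by
    |r| (or signed r with ``rank_by='signed_r'``) are returned with ranks
    1..k; ties break by gene id. Fewer than k are returned if fewer pass.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metabolite_id not in set(merged.metabolite_ids):
        raise ValueError(f"unknown metabolite {metabolite_id!r}")
    genes = merged.transcript_ids
    if not genes:
        raise ValueError("no transcript features in merged matrix")
    x = merged.values.loc[metabolite_id].to_numpy(dtype=float)
    Y = merged.values.loc[genes].to_numpy(dtype=float)
    r, p = permutation_pvalues_bulk(x, Y, B=B, seed=seed,
                                    x_id=metabolite_id, y_ids=genes)
    passing = [(g, float(rv), float(pv)) for g, rv, pv in zip(genes, r, p)
               if np.isfinite(rv) and pv < alpha]
    keyfun = ((lambda t: (-abs(t[1]), t[0])) if rank_by == "abs_r"
              else (lambda t: (-t[1], t[0])))
    passing.sort(key=keyfun)
    de = de_flags or set()
    paths = pathway_map or {}
    return [GeneMetaboliteLink(gene_id=g, metabolite_id=metabolite_id,
                               r=rv, p=pv, rank=i + 1,
                               is_de=g in de, pathway=paths.get(g))
            for i, (g, rv, pv) in enumerate(passing[:k])]


def build_gene_metabolite_network(links_by_metabolite: dict[str, list[GeneMetaboliteLink]],
                                  de_flags: set[str] | None = None,
                                  pathway_map: dict[str, str] | None = None) -> nx.Graph:
    """Annotated bipartite gene-metabolite graph from per-target link lists."""
    de = de_flags or set()
    paths = pathway_map or {}
    g = nx.Graph()
    for met, links in links_by_metabolite.items():
        g.add_node(met, kind="metabolite")
        for link in links:
            g.add_node(link.gene_id, kind="transcript",
                       is_de=link.gene_id in de,
                       pathway=paths.get(link.gene_id, "unannotated"))
            g.add_edge(link.gene_id, met, r=link.r, p=link.p, rank=link.rank)
    return g


def overlap_summary(links_by_metabolite: dict[str, list[GeneMetaboliteLink] | set[str]]
                    ) -> OverlapSummary:
    """Venn counts of the gene sets linked to each metabolite.

    'Specific' counts genes in exactly one set; a pairwise count is the
    number of genes in exactly those two sets; ``shared_by_all`` counts genes
    in every set.
    """
    if len(links_by_metabolite) < 2:
        raise ValueError("need >= 2 metabolites for an overlap summary")
    sets = {m: ({l.gene_id for l in ls} if not isinstance(ls, set) else set(ls))
            for m, ls in links_by_metabolite.items()}
    mets = sorted(sets)
    membership: dict[str, set[str]] = {}
    for m in mets:
        for gene in sets[m]:
            membership.setdefault(gene, set()).add(m)
    specific = {m: sum(1 for g, owners in membership.items() if owners == {m})
                for m in mets}
    pairwise = {pair: sum(1 for g, owners in membership.items() if owners == set(pair))
                for pair in combinations(mets, 2)}
    shared_all = sum(1 for owners in membership.values() if owners == set(mets))
    return OverlapSummary(per_metabolite_specific=specific,
                          pairwise_shared=pairwise, shared_by_all=shared_all)


def pathway_edge_summary(links: list[GeneMetaboliteLink],
                         pathway_map: dict[str, str],
                         condition: str = "joint") -> list[PathwayEdgeSummary]:
    """Positive/negative link tallies per pathway; unmapped genes pooled
    under 'unannotated'."""
    pos: dict[str, int] = {}
    neg: dict[str, int] = {}
    for link in links:
        pw = pathway_map.get(link.gene_id, "unannotated")
        if link.r > 0:
            pos[pw] = pos.get(pw, 0) + 1
        elif link.r < 0:
            neg[pw] = neg.get(pw, 0) + 1
    pathways = sorted(set(pos) | set(neg))
    return [PathwayEdgeSummary(pathway=pw, n_positive=pos.get(pw, 0),
                               n_negative=neg.get(pw, 0), condition=condition)
            for pw in pathways]


# --------------------------------------------------------------------------- I/O


def write_links_tsv(links_by_metabolite: dict[str, list[GeneMetaboliteLink]],
                    path: str | Path) -> None:
    rows = [{"metabolite": l.metabolite_id, "gene": l.gene_id, "r": l.r,
             "p": l.p, "rank": l.rank, "is_de": l.is_de,
             "pathway": l.pathway if l.pathway is not None else ""}
            for met in sorted(links_by_metabolite)
            for l in links_by_metabolite[met]]
    pd.DataFrame(rows, columns=["metabolite", "gene", "r", "p", "rank",
                                "is_de", "pathway"]) \
        .to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_overlap_json(summary: OverlapSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.as_dict(), indent=1, sort_keys=True) + "\n")


def write_network_sif(graph: nx.Graph, sif_path: str | Path,
                      attrs_path: str | Path | None = None) -> None:
    """Bipartite network as SIF plus an optional node-attribute TSV."""
    with open(sif_path, "w") as fh:
        for a, b, d in sorted(graph.edges(data=True)):
            rel = "pcc_pos" if d.get("r", 0) > 0 else "pcc_neg"
            fh.write(f"{a}\t{rel}\t{b}\n")
    if attrs_path is not None:
        rows = [{"node": n, "kind": d.get("kind", ""),
                 "is_de": d.get("is_de", ""), "pathway": d.get("pathway", "")}
                for n, d in sorted(graph.nodes(data=True))]
        pd.DataFrame(rows, columns=["node", "kind", "is_de", "pathway"]) \
            .to_csv(attrs_path, sep="\t", index=False, lineterminator="\n")
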