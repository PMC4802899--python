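"""Promoter motif scanning and hypergeometric set enrichment.

Promoters (1 kb upstream regions) are scanned for degenerate IUPAC consensus
motifs on both strands; a promoter is "associated" with a motif when it
carries at least one match anywhere. Motif enrichment in a gene set uses the
exact hypergeometric upper tail with the study rule: significant when raw
P < 0.01 AND at least ``min_promoters`` set promoters carry the motif, score
= -log10 P (score 2 at P = 0.01, 4 at P = 1e-4). GO-slim enrichment uses the
same tail with Benjamini-Hochberg control at FDR 0.05 — the raw-p/FDR
asymmetry between the two stages is deliberate.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .simulate import IUPAC, IUPACMotif, PromoterSet, reverse_complement
from .stats import bh_adjust, hypergeometric_upper_tail

__all__ = [
    "MotifHitIndex", "EnrichmentResult", "scan_promoter", "build_hit_index",
    "motif_enrichment", "go_slim_enrichment", "write_enrichment_tsv",
    "enrichment_score_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class MotifHitIndex:
    """motif_id -> set of genes whose promoter carries >= 1 match."""

    hits: dict[str, set[str]]
    background_size: int
    background: set[str]


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric set-enrichment record (motif or GO term).

    k: annotated genes in the set; K: annotated in the background; n: set
    size; N: background size; score = -log10 p.
    """

    id: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adjusted: float | None
    score: float
    significant: bool


def _motif_regex(consensus: str) -> re.Pattern:
    # sequence N matches nothing except a motif N (which matches any base
    # including N); overlapping matches found via lookahead
    parts = []
    for ch in consensus.upper():
        allowed = IUPAC[ch]
        parts.append("[" + allowed + ("N" if ch == "N" else "") + "]")
    return re.compile("(?=" + "".join(parts) + ")")


def scan_promoter(sequence: str, motif: IUPACMotif, both_strands: bool = True) -> int:
    """Count motif matches in a promoter under IUPAC degeneracy.

    Counts forward-strand matches of the consensus plus, when
    ``both_strands``, matches of its reverse complement (equivalent to
    scanning the reverse strand); overlapping matches all count.
    """
    seq = sequence.upper()
    if len(seq) < len(motif.consensus):
        raise ValueError("sequence shorter than motif")
    count = len(_motif_regex(motif.consensus).findall(seq))
    if both_strands:
        count += len(_motif_regex(reverse_complement(motif.consensus)).findall(seq))
    return count


def build_hit_index(promoters: PromoterSet, motifs: list[IUPACMotif],
                    both_strands: bool = True) -> MotifHitIndex:
    """Per-motif promoter association sets over the whole promoter universe."""
    if len(promoters) == 0:
        raise ValueError("empty promoter set")
    hits: dict[str, set[str]] = {}
    for motif in motifs:
        fwd = _motif_regex(motif.consensus)
        rev = _motif_regex(reverse_complement(motif.consensus)) if both_strands else None
        got: set[str] = set()
        for gene, seq in promoters.sequences.items():
            if fwd.search(seq) or (rev is not None and rev.search(seq)):
                got.add(gene)
        hits[motif.motif_id] = got
    return MotifHitIndex(hits=hits, background_size=len(promoters),
                         background=set(promoters.sequences))


def _score(p: float) -> float:
    return -math.log10(max(p, 1e-300))


def motif_enrichment(gene_set: set[str], hit_index: MotifHitIndex,
                     alpha: float = 0.01, min_promoters: int = 10,
                     ) -> list[EnrichmentResult]:
    """Hypergeometric motif enrichment of a gene set against all promoters.

    Study rule: significant iff raw p < alpha AND the motif is present in at
    least ``min_promoters`` promoters of the gene set. No FDR here (the
    GO-slim stage applies BH; the asymmetry is intentional). Results sorted
    by p then motif id.
    """
    unknown = set(gene_set) - hit_index.background
    if unknown:
        raise ValueError(f"genes not in promoter background: {sorted(unknown)[:5]}")
    n, N = len(gene_set), hit_index.background_size
    results = []
    for motif_id in sorted(hit_index.hits):
        hit = hit_index.hits[motif_id]
        K = len(hit)
        k = len(hit & gene_set)
        p = hypergeometric_upper_tail(k, K, n, N)
        results.append(EnrichmentResult(
            id=motif_id, k=k, K=K, n=n, N=N, p=p, p_adjusted=None,
            score=_score(p), significant=bool(p < alpha and k >= min_promoters)))
    results.sort(key=lambda r: (r.p, r.id))
    return results


def go_slim_enrichment(gene_set: set[str], background: set[str],
                       term_map: dict[str, set[str]], fdr: float = 0.05,
                       ) -> list[EnrichmentResult]:
    """GO-slim hypergeometric enrichment with BH control across terms."""
    if not set(gene_set) <= set(background):
        raise ValueError("gene_set must be a subset of background")
    if not term_map:
        log.warning("empty GO term map; no enrichment computed")
        return []
    n, N = len(gene_set), len(background)
    terms = sorted(term_map)
    raw: list[tuple[str, int, int, float]] = []
    for term in terms:
        annotated = term_map[term] & background
        K = len(annotated)
        k = len(annotated & gene_set)
        p = hypergeometric_upper_tail(k, K, n, N)
        raw.append((term, k, K, p))
    adjusted = bh_adjust([p for _, _, _, p in raw])
    results = [EnrichmentResult(
        id=term, k=k, K=K, n=n, N=N, p=p, p_adjusted=float(padj),
        score=_score(p), significant=bool(padj < fdr))
        for (term, k, K, p), padj in zip(raw, adjusted)]
    results.sort(key=lambda r: (r.p, r.id))
    return results


# --------------------------------------------------------------------------- I/O


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    rows = [{"id": r.id, "k": r.k, "K": r.K, "n": r.n, "N": r.N, "p": r.p,
             "p_adjusted": "" if r.p_adjusted is None else r.p_adjusted,
             "score": r.score, "significant": r.significant} for r in results]
    pd.DataFrame(rows, columns=["id", "k", "K", "n", "N", "p", "p_adjusted",
                                "score", "significant"]) \
        .to_csv(path, sep="\t", index=False, lineterminator="\n")


def enrichment_score_matrix(results_by_set: dict[str, list[EnrichmentResult]],
                            ) -> pd.DataFrame:
    """Heatmap-ready motif x gene-set score matrix; non-significant cells empty."""
    ids = sorted({r.id for rs in results_by_set.values() for r in rs})
    cols = sorted(results_by_set)
    mat = pd.DataFrame("", index=pd.Index(ids, name="id"), columns=cols, dtype=object)
    for col, rs in results_by_set.items():
        for r in rs:
            if r.significant:
                mat.loc[r.id, col] = f"{r.score:.3f}"
    return mat
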