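"""End-to-end pipeline: simulate or ingest -> stage-wise response table ->
condition networks -> gene-metabolite integration -> motif and GO enrichment.

A single :class:`PipelineConfig` (YAML-loadable) carries every threshold; all
randomness flows from one seed; re-running an identical config reproduces
byte-identical text outputs. The manifest in the returned
:class:`PipelineReport` only ever lists completed artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .containers import OmicsMatrix
from .corrnet import (build_condition_network, compare_conditions,
                      topology_summary, write_edges_sif, write_edges_tsv)
from .integrate import (align_samples, build_gene_metabolite_network,
                        overlap_summary, pathway_edge_summary, top_correlators,
                        write_links_tsv, write_network_sif, write_overlap_json)
from .motifs import (build_hit_index, enrichment_score_matrix, go_slim_enrichment,
                     motif_enrichment, write_enrichment_tsv)
from .response import response_table, write_response_table
from .simulate import (PromoterSet, SynthConfig, SyntheticDataset,
                       generate_dataset, read_motif_table, write_dataset)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending key."""


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Either ``simulate`` is set (synthetic mode) or the input paths are. The
    default thresholds are the study gate: r_min 0.8, network alpha 0.001
    with B = 2000 permutations, top k = 100 correlators, motif alpha 0.01
    with >= 10 promoters, GO FDR 0.05, ANOVA alpha 0.05.
    """

    seed: int = 0
    outdir: str = "results/pipeline"
    simulate: SynthConfig | None = field(default_factory=SynthConfig)
    metabolite_tsv: str | None = None
    metabolite_meta_tsv: str | None = None
    transcript_tsv: str | None = None
    transcript_meta_tsv: str | None = None
    promoter_fasta: str | None = None
    motif_tsv: str | None = None
    r_min: float = 0.8
    alpha_network: float = 0.001
    B: int = 2000
    k_top: int = 100
    alpha_motif: float = 0.01
    min_promoters: int = 10
    fdr_go: float = 0.05
    alpha_anova: float = 0.05
    target_metabolites: list[str] | str = "auto"
    alignment_strategy: str = "replicate_pairing"
    log_transform_network: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            mods = sim.pop("modules", None)
            if mods is not None:
                from .simulate import ModuleSpec
                for m in mods:
                    if "effect_stages" in m:
                        m["effect_stages"] = tuple(m["effect_stages"])
                sim["modules"] = tuple(ModuleSpec(**m) for m in mods)
            for key in ("stages_metab", "stages_trans"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            cfg.simulate = SynthConfig(**sim)
        elif "simulate" in (yaml.safe_load(Path(path).read_text()) or {}):
            cfg.simulate = None
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, SynthConfig):
                return asdict(o)
            if isinstance(o, (set, tuple)):
                return list(o)
            return str(o)
        fields = asdict(self)
        fields.pop("outdir", None)  # analysis identity, not output location
        payload = json.dumps(fields, default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    manifest: dict[str, str]
    topology: dict[str, dict]
    overlap: dict
    n_response_records: int
    n_enriched_motifs: int
    n_enriched_go_terms: int
    provenance: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")


def validate_config(config: PipelineConfig) -> list[str]:
    """Human-readable findings, one per violation; empty when valid."""
    findings: list[str] = []
    for name, lo, hi in (("r_min", 0.0, 1.0), ("alpha_network", 0.0, 1.0),
                         ("alpha_motif", 0.0, 1.0), ("fdr_go", 0.0, 1.0),
                         ("alpha_anova", 0.0, 1.0)):
        v = getattr(config, name)
        if not (lo <= v <= hi):
            findings.append(f"{name} = {v} out of [{lo}, {hi}]")
    if config.B < 1:
        findings.append(f"B = {config.B} must be >= 1")
    elif 1.0 / (config.B + 1) >= config.alpha_network > 0:
        findings.append(
            f"alpha_network = {config.alpha_network} unattainable: minimum "
            f"permutation p is 1/(B+1) = {1.0 / (config.B + 1):.4g} at B = {config.B}")
    if config.k_top < 1:
        findings.append(f"k_top = {config.k_top} must be >= 1")
    if config.min_promoters < 0:
        findings.append("min_promoters must be >= 0")
    if config.alignment_strategy not in ("replicate_pairing", "stage_means"):
        findings.append(f"unknown alignment_strategy {config.alignment_strategy!r}")
    if config.simulate is None:
        for key in ("metabolite_tsv", "metabolite_meta_tsv", "transcript_tsv",
                    "transcript_meta_tsv", "promoter_fasta", "motif_tsv"):
            p = getattr(config, key)
            if p is None:
                findings.append(f"no simulate block and {key} not provided")
            elif not Path(p).exists():
                findings.append(f"{key}: file not found: {p}")
        if config.target_metabolites == "auto":
            findings.append("target_metabolites 'auto' requires simulate mode")
    else:
        try:
            config.simulate.validate()
        except ValueError as exc:
            findings.append(f"simulate: {exc}")
    return findings


def _pick_targets(config: PipelineConfig, dataset: SyntheticDataset | None,
                  metab: OmicsMatrix) -> list[str]:
    if config.target_metabolites != "auto":
        targets = list(config.target_metabolites)
        missing = set(targets) - set(metab.feature_ids)
        if missing:
            raise PipelineError(f"integrate: unknown target metabolites {sorted(missing)}")
        return targets
    # auto: first three members of the largest deficit-coupled module, the
    # analogue of the drought-induced monoterpenes
    truth = dataset.truth
    by_module: dict[str, list[str]] = {}
    for met, mod in truth.module_membership.items():
        by_module.setdefault(mod, []).append(met)
    candidates = [m for m in by_module
                  if any(a != b and (min(a, b), max(a, b)) in truth.planted_edges["D"]
                         and (min(a, b), max(a, b)) not in truth.planted_edges["C"]
                         for a in by_module[m] for b in by_module[m])]
    pool = max(candidates or by_module, key=lambda m: len(by_module[m]))
    return sorted(by_module[pool])[:3]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages in order; abort with a stage-named error on failure."""
    findings = validate_config(config)
    if findings:
        raise PipelineError("config: " + "; ".join(findings))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    # ---------------------------------------------------------------- inputs
    stage = "simulate" if config.simulate is not None else "ingest"
    try:
        if config.simulate is not None:
            sim_cfg = SynthConfig(**{**asdict(config.simulate), "seed": config.seed,
                                     "modules": config.simulate.modules})
            dataset: SyntheticDataset | None = generate_dataset(sim_cfg)
            manifest.update(write_dataset(dataset, out / "inputs"))
            metab, trans = dataset.metabolites, dataset.transcripts
            promoters, library = dataset.promoters, dataset.motif_library
            de_flags, pathway_map, go_map = (dataset.de_flags, dataset.pathway_map,
                                             dataset.go_map)
        else:
            dataset = None
            metab = OmicsMatrix.read_tsv(config.metabolite_tsv, config.metabolite_meta_tsv)
            trans = OmicsMatrix.read_tsv(config.transcript_tsv, config.transcript_meta_tsv)
            promoters = PromoterSet.read_fasta(config.promoter_fasta)
            library = read_motif_table(config.motif_tsv)
            de_flags, pathway_map, go_map = set(), {}, {}
        log.info("stage %s: %d metabolites x %d samples, %d genes x %d samples",
                 stage, metab.n_features, metab.n_samples,
                 trans.n_features, trans.n_samples)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage}: {exc}") from exc

    # ---------------------------------------------------------------- response
    try:
        records = response_table(metab, alpha=config.alpha_anova)
        write_response_table(records, out / "response_table.tsv")
        manifest["response_table"] = str(out / "response_table.tsv")
    except Exception as exc:
        raise PipelineError(f"response: {exc}") from exc

    # ---------------------------------------------------------------- networks
    topology: dict[str, dict] = {}
    try:
        nets = {}
        for cond in ("C", "D"):
            net = build_condition_network(
                metab, cond, r_min=config.r_min, alpha=config.alpha_network,
                B=config.B, seed=config.seed,
                log_transform=config.log_transform_network)
            nets[cond] = net
            write_edges_tsv(net, out / f"network_{cond}_edges.tsv")
            write_edges_sif(net, out / f"network_{cond}.sif")
            manifest[f"network_{cond}_edges"] = str(out / f"network_{cond}_edges.tsv")
            manifest[f"network_{cond}_sif"] = str(out / f"network_{cond}.sif")
            topology[cond] = topology_summary(net).as_dict()
        comparison = compare_conditions(nets["C"], nets["D"])
        topology["difference"] = comparison.differences
        (out / "topology.json").write_text(
            json.dumps(topology, indent=1, sort_keys=True) + "\n")
        manifest["topology"] = str(out / "topology.json")
        log.info("stage corrnet: %d C edges, %d D edges",
                 len(nets["C"].edges), len(nets["D"].edges))
    except Exception as exc:
        raise PipelineError(f"corrnet: {exc}") from exc

    # ---------------------------------------------------------------- integration
    try:
        merged = align_samples(metab, trans, strategy=config.alignment_strategy)
        targets = _pick_targets(config, dataset, metab)
        links = {met: top_correlators(
            merged, met, k=config.k_top, alpha=config.alpha_network,
            B=config.B, seed=config.seed, de_flags=de_flags,
            pathway_map=pathway_map) for met in targets}
        write_links_tsv(links, out / "gene_metabolite_links.tsv")
        manifest["gene_metabolite_links"] = str(out / "gene_metabolite_links.tsv")
        overlap = overlap_summary(links) if len(links) >= 2 else None
        if overlap is not None:
            write_overlap_json(overlap, out / "overlap_summary.json")
            manifest["overlap_summary"] = str(out / "overlap_summary.json")
        graph = build_gene_metabolite_network(links, de_flags=de_flags,
                                              pathway_map=pathway_map)
        write_network_sif(graph, out / "gene_metabolite_network.sif",
                          out / "gene_metabolite_nodes.tsv")
        manifest["gene_metabolite_network"] = str(out / "gene_metabolite_network.sif")
        manifest["gene_metabolite_nodes"] = str(out / "gene_metabolite_nodes.tsv")
        all_links = [l for ls in links.values() for l in ls]
        pw = pathway_edge_summary(all_links, pathway_map)
        with open(out / "pathway_edge_summary.tsv", "w") as fh:
            fh.write("pathway\tn_positive\tn_negative\tcondition\n")
            for s in pw:
                fh.write(f"{s.pathway}\t{s.n_positive}\t{s.n_negative}\t{s.condition}\n")
        manifest["pathway_edge_summary"] = str(out / "pathway_edge_summary.tsv")
        network_genes = sorted({l.gene_id for l in all_links})
        log.info("stage integrate: %d targets, %d network genes",
                 len(targets), len(network_genes))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"integrate: {exc}") from exc

    # ---------------------------------------------------------------- enrichment
    try:
        hit_index = build_hit_index(promoters, library)
        gene_set = set(network_genes) & hit_index.background
        motif_results = motif_enrichment(gene_set, hit_index,
                                         alpha=config.alpha_motif,
                                         min_promoters=config.min_promoters)
        write_enrichment_tsv(motif_results, out / "motif_enrichment.tsv")
        manifest["motif_enrichment"] = str(out / "motif_enrichment.tsv")
        score_mat = enrichment_score_matrix({"network_genes": motif_results})
        score_mat.to_csv(out / "motif_score_matrix.tsv", sep="\t", lineterminator="\n")
        manifest["motif_score_matrix"] = str(out / "motif_score_matrix.tsv")
        go_results = []
        if go_map:
            go_results = go_slim_enrichment(gene_set, hit_index.background,
                                            go_map, fdr=config.fdr_go)
            write_enrichment_tsv(go_results, out / "go_enrichment.tsv")
            manifest["go_enrichment"] = str(out / "go_enrichment.tsv")
        n_sig_motifs = sum(r.significant for r in motif_results)
        n_sig_go = sum(r.significant for r in go_results)
        log.info("stage motifs: %d significant motifs, %d significant GO terms",
                 n_sig_motifs, n_sig_go)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"motifs: {exc}") from exc

    # manifest paths are stored relative to outdir so identical runs in
    # different directories produce byte-identical reports
    manifest = {k: str(Path(p).relative_to(out)) for k, p in manifest.items()}
    report = PipelineReport(
        manifest=manifest,
        topology=topology,
        overlap=overlap.as_dict() if overlap is not None else {},
        n_response_records=len(records),
        n_enriched_motifs=n_sig_motifs,
        n_enriched_go_terms=n_sig_go,
        provenance={"config_hash": config.config_hash(), "seed": config.seed,
                    "drynet_version": __version__,
                    "thresholds": {"r_min": config.r_min,
                                   "alpha_network": config.alpha_network,
                                   "B": config.B, "k_top": config.k_top,
                                   "alpha_motif": config.alpha_motif,
                                   "min_promoters": config.min_promoters,
                                   "fdr_go": config.fdr_go,
                                   "alpha_anova": config.alpha_anova}},
    )
    report.to_json(out / "report.json")
    for key, path in report.manifest.items():
        p = out / path
        if not p.exists() or p.stat().st_size == 0:
            raise PipelineError(f"manifest: artifact {key} missing or empty: {path}")
    return report
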