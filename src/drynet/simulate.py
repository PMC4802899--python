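"""Synthetic two-treatment developmental multi-omics generator with ground truth.

Emulates the statistical structure the downstream analyses assume: log-normal
positive abundances, smooth latent developmental trajectories shared within
planted metabolite modules, treatment-dependent module coupling (modules can
cohere only under deficit irrigation, which makes the D network denser),
gene-metabolite coupling through shared latent signals, and promoter motif
instances planted preferentially in a regulon gene set. Every planted fact is
recorded in a :class:`SyntheticTruth` object so recovery can be scored.

Design (defaults): metabolites are measured over 2 treatments x 6 stages
(27..93 days after anthesis) x 4 replicates = 48 samples; transcripts over
2 x 3 stages (41, 68, 93) x 3 replicates = 18 samples.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

LN2 = float(np.log(2.0))

COUPLINGS = ("both", "D_only", "C_only")


class SynthConfigError(ValueError):
    """Raised for an inconsistent generator configuration."""


# --------------------------------------------------------------------------- config


@dataclass(frozen=True)
class ModuleSpec:
    """A planted metabolite module.

    ``loading`` scales the shared latent trajectory on the log scale;
    ``treatment_coupling`` says in which condition(s) members follow the
    shared trajectory (elsewhere members are mutually uncorrelated noise);
    ``linked_gene_count`` genes are coupled to this module's members.
    ``effect_log2fc`` is the true treatment effect (log2 D/C) planted for
    every member at each stage in ``effect_stages`` — distinct modules should
    use disjoint stage windows, mirroring phenolics responding before
    veraison and monoterpenes at late ripening, so that a shared shift does
    not induce spurious cross-module correlation.
    """

    module_id: str
    size: int
    loading: float = 0.9
    treatment_coupling: str = "both"
    linked_gene_count: int = 0
    effect_log2fc: float = 0.0
    effect_stages: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.size < 1:
            raise SynthConfigError(f"module {self.module_id}: size must be >= 1")
        if not (0.0 < self.loading <= 1.0):
            raise SynthConfigError(f"module {self.module_id}: loading must be in (0, 1]")
        if self.treatment_coupling not in COUPLINGS:
            raise SynthConfigError(
                f"module {self.module_id}: coupling must be one of {COUPLINGS}")
        if self.linked_gene_count < 0:
            raise SynthConfigError(f"module {self.module_id}: linked_gene_count < 0")


def default_modules() -> tuple[ModuleSpec, ...]:
    """Default planted structure mirroring the study's qualitative findings.

    Two always-coupled modules (a phenylpropanoid core and a VOC core) give
    both conditions some edges; two deficit-only modules (phenylpropanoid and
    monoterpene responders) make the D network denser, the way water deficit
    increased network connectedness in the berry data this design emulates.
    """
    return (
        ModuleSpec("phenylpropanoid_core", size=6, loading=0.9,
                   treatment_coupling="both", linked_gene_count=20),
        ModuleSpec("phenylpropanoid_drought", size=8, loading=0.9,
                   treatment_coupling="D_only", linked_gene_count=20,
                   effect_log2fc=1.0, effect_stages=(27, 41, 54)),
        ModuleSpec("voc_core", size=5, loading=0.9,
                   treatment_coupling="both", linked_gene_count=0),
        ModuleSpec("monoterpene_drought", size=10, loading=0.9,
                   treatment_coupling="D_only", linked_gene_count=60,
                   effect_log2fc=1.0, effect_stages=(82, 93)),
    )


MODULE_PATHWAY = {
    "phenylpropanoid_core": "phenylpropanoid",
    "phenylpropanoid_drought": "phenylpropanoid",
    "voc_core": "fatty_acid_volatile",
    "monoterpene_drought": "terpenoid",
}


@dataclass(frozen=True)
class SynthConfig:
    """Full configuration of the synthetic study design."""

    seed: int = 0
    stages_metab: tuple[int, ...] = (27, 41, 54, 68, 82, 93)
    stages_trans: tuple[int, ...] = (41, 68, 93)
    reps_metab: int = 4
    reps_trans: int = 3
    n_metabolites: int = 74
    n_genes: int = 2000
    modules: tuple[ModuleSpec, ...] = field(default_factory=default_modules)
    noise_sd: float = 0.15
    promoter_length: int = 1000
    regulon_size: int = 100
    motif_plant_rate_regulon: float = 0.8
    motif_plant_rate_background: float = 0.05
    gc_content: float = 0.35
    de_background_rate: float = 0.1
    # log-sd of the residual per-member trajectory in the uncoupled
    # condition; kept small so an uncoupled pair can never reach the
    # |PCC| > 0.8 gate (max attainable r = a^2/(a^2 + noise_sd^2))
    uncoupled_amplitude: float = 0.25
    log_values: bool = False  # expose log-scale matrices instead of raw

    def validate(self) -> None:
        if any(c < 1 for c in (self.reps_metab, self.reps_trans,
                               self.n_metabolites, self.n_genes,
                               self.promoter_length, self.regulon_size)):
            raise SynthConfigError("all counts must be positive")
        if self.noise_sd < 0:
            raise SynthConfigError("noise_sd must be >= 0")
        if self.uncoupled_amplitude < 0:
            raise SynthConfigError("uncoupled_amplitude must be >= 0")
        for name in ("motif_plant_rate_regulon", "motif_plant_rate_background",
                     "gc_content", "de_background_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SynthConfigError(f"{name} must be in [0, 1]")
        if not set(self.stages_trans) <= set(self.stages_metab):
            raise SynthConfigError("stages_trans must be a subset of stages_metab")
        if sum(m.size for m in self.modules) > self.n_metabolites:
            raise SynthConfigError("module sizes exceed n_metabolites")
        if self.regulon_size > self.n_genes:
            raise SynthConfigError("regulon_size exceeds n_genes")

    def metabolite_ids(self) -> list[str]:
        return [f"met_{i + 1:03d}" for i in range(self.n_metabolites)]

    def gene_ids(self) -> list[str]:
        return [f"gene_{i + 1:04d}" for i in range(self.n_genes)]


# --------------------------------------------------------------------------- truth


@dataclass
class SyntheticTruth:
    """Ground truth of every planted structure, for recovery scoring."""

    module_membership: dict[str, str] = field(default_factory=dict)
    # condition -> set of sorted (feature_a, feature_b) pairs expected correlated
    planted_edges: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    planted_gene_metabolite_links: set[tuple[str, str]] = field(default_factory=set)
    regulon_genes: set[str] = field(default_factory=set)
    planted_motif_ids: set[str] = field(default_factory=set)
    # (metabolite, stage) -> true log2 fold change D/C
    effect_log2fc: dict[tuple[str, int], float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_membership": self.module_membership,
            "planted_edges": {c: sorted(map(list, e)) for c, e in self.planted_edges.items()},
            "planted_gene_metabolite_links": sorted(map(list, self.planted_gene_metabolite_links)),
            "regulon_genes": sorted(self.regulon_genes),
            "planted_motif_ids": sorted(self.planted_motif_ids),
            "effect_log2fc": [[m, s, v] for (m, s), v in sorted(self.effect_log2fc.items())],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            module_membership=d["module_membership"],
            planted_edges={c: {tuple(p) for p in e} for c, e in d["planted_edges"].items()},
            planted_gene_metabolite_links={tuple(p) for p in d["planted_gene_metabolite_links"]},
            regulon_genes=set(d["regulon_genes"]),
            planted_motif_ids=set(d["planted_motif_ids"]),
            effect_log2fc={(m, int(s)): float(v) for m, s, v in d["effect_log2fc"]},
        )


# --------------------------------------------------------------------------- RNG plumbing


def _stream(seed: int, *names: str) -> np.random.Generator:
    """Named RNG substream: adding genes never perturbs metabolite draws."""
    h = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *h]))


def _poly_basis(n_stages: int) -> np.ndarray:
    """Orthonormal smooth polynomial basis over the stage grid.

    Columns are polynomials of degree 1..min(5, n_stages-1) in normalized
    stage position, Gram-Schmidt orthogonalized against the constant and each
    other and scaled to unit sd, so any unit-coefficient combination is a
    smooth zero-mean, unit-sd trajectory and orthogonal coefficient vectors
    give exactly uncorrelated trajectories.
    """
    t = np.linspace(0.0, 1.0, n_stages)
    dmax = min(5, n_stages - 1)
    cols: list[np.ndarray] = []
    for deg in range(1, dmax + 1):
        w = t ** deg - np.mean(t ** deg)
        for c in cols:
            w = w - (w @ c) / (c @ c) * c
        norm = np.sqrt((w @ w) / n_stages)
        if norm > 1e-10:
            cols.append(w / norm)
    return np.column_stack(cols)


def _unit_coef(rng: np.random.Generator, d: int) -> np.ndarray:
    while True:
        q = rng.normal(size=d)
        norm = np.linalg.norm(q)
        if norm > 1e-8:
            return q / norm


# --------------------------------------------------------------------------- planning


def _plan(config: SynthConfig) -> dict:
    """Deterministic assignment of metabolites, genes, and latent signals."""
    config.validate()
    mets = config.metabolite_ids()
    genes = config.gene_ids()
    stages = list(config.stages_metab)
    membership: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    cursor = 0
    for mod in config.modules:
        members[mod.module_id] = mets[cursor:cursor + mod.size]
        for m in members[mod.module_id]:
            membership[m] = mod.module_id
        cursor += mod.size

    # module latent trajectories over the metabolite stage grid; coefficient
    # vectors of the first d modules are QR-orthonormalized so distinct
    # modules have exactly uncorrelated latents (no chance cross-module edges)
    basis = _poly_basis(len(stages))
    d = basis.shape[1]
    latents: dict[str, dict[int, float]] = {}
    if config.modules:
        raw = np.stack([_unit_coef(_stream(config.seed, "module_latent", mod.module_id), d)
                        for mod in config.modules])
        q_ortho, _ = np.linalg.qr(raw[:min(len(raw), d)].T)
        coefs = [q_ortho[:, i] if i < q_ortho.shape[1] else raw[i]
                 for i in range(len(raw))]
        for mod, q in zip(config.modules, coefs):
            latents[mod.module_id] = dict(zip(stages, basis @ q))
    # weak residual per-member trajectory for the uncoupled condition;
    # coefficient vectors QR-orthogonalized within the module so uncoupled
    # member pairs are uncorrelated in population, not merely weakly coupled
    free: dict[tuple[str, str], dict[int, float]] = {}
    for mod in config.modules:
        if mod.treatment_coupling == "both":
            continue
        uncoupled = "C" if mod.treatment_coupling == "D_only" else "D"
        mem = members[mod.module_id]
        raw = np.stack([_unit_coef(_stream(config.seed, "member_free", m, uncoupled), d)
                        for m in mem])
        q_ortho, _ = np.linalg.qr(raw[:min(len(raw), d)].T)
        for i, m in enumerate(mem):
            q = q_ortho[:, i] if i < q_ortho.shape[1] else raw[i]
            free[(m, uncoupled)] = dict(zip(stages, basis @ q))

    # gene plan: linked genes assigned in blocks, round-robin over members
    links: list[tuple[str, str, str]] = []  # (gene, metabolite, module)
    gcursor = 0
    for mod in config.modules:
        mem = members[mod.module_id]
        for j in range(mod.linked_gene_count):
            links.append((genes[gcursor], mem[j % len(mem)], mod.module_id))
            gcursor += 1
    linked_genes = [g for g, _, _ in links]
    regulon = list(linked_genes)
    for g in genes:
        if len(regulon) >= config.regulon_size:
            break
        if g not in set(linked_genes):
            regulon.append(g)
    regulon = regulon[: config.regulon_size]

    baselines_met = dict(zip(mets, _stream(config.seed, "baseline_met")
                             .normal(4.0, 1.0, size=len(mets))))
    baselines_gene = dict(zip(genes, _stream(config.seed, "baseline_gene")
                              .normal(5.0, 1.0, size=len(genes))))
    return {
        "mets": mets, "genes": genes, "membership": membership,
        "members": members, "latents": latents, "free": free,
        "links": links, "regulon": regulon,
        "baselines_met": baselines_met, "baselines_gene": baselines_gene,
        "modules": {m.module_id: m for m in config.modules},
    }


def _log_signal(config: SynthConfig, plan: dict, met: str,
                treatment: str, stage: int) -> float:
    """Deterministic log-scale signal of a metabolite at (treatment, stage).

    Module members follow loading * shared latent in their coupled
    condition(s) plus the planted treatment effect. In the uncoupled
    condition each member keeps only a weak private trajectory
    (uncoupled_amplitude), too small for any uncoupled pair to reach the
    |PCC| > 0.8 gate; background metabolites carry no developmental signal
    at all, so unplanted pairs are uncorrelated by construction.
    """
    sig = 0.0
    mod_id = plan["membership"].get(met)
    if mod_id is not None:
        mod: ModuleSpec = plan["modules"][mod_id]
        coupled = (mod.treatment_coupling == "both"
                   or (mod.treatment_coupling == "D_only" and treatment == "D")
                   or (mod.treatment_coupling == "C_only" and treatment == "C"))
        if coupled:
            sig += mod.loading * plan["latents"][mod_id][stage]
        else:
            sig += config.uncoupled_amplitude * plan["free"][(met, treatment)][stage]
        if treatment == "D" and mod.effect_log2fc != 0.0 and stage in mod.effect_stages:
            sig += LN2 * mod.effect_log2fc
    return sig


def _planted_effects(config: SynthConfig, plan: dict) -> dict[tuple[str, int], float]:
    eff: dict[tuple[str, int], float] = {}
    for met, mod_id in plan["membership"].items():
        mod: ModuleSpec = plan["modules"][mod_id]
        if mod.effect_log2fc == 0.0:
            continue
        for stage in config.stages_metab:
            if stage in mod.effect_stages:
                # true log2FC(D/C); latent terms are common to both arms for
                # 'both' modules and absent from the uncoupled arm
                eff[(met, stage)] = mod.effect_log2fc
    return eff


# --------------------------------------------------------------------------- generators


def _sample_grid(stages: list[int], reps: int) -> list[tuple[str, int, int]]:
    return [(t, s, r) for t in ("C", "D") for s in stages for r in range(1, reps + 1)]


def generate_metabolite_matrix(config: SynthConfig) -> tuple[OmicsMatrix, SyntheticTruth]:
    """Metabolite abundances over the full 2 x stages x replicates design.

    Values are exp(baseline + signal + eps) with eps ~ Normal(0, noise_sd) on
    the log scale, so abundances are log-normal and strictly positive.
    """
    plan = _plan(config)
    grid = _sample_grid(list(config.stages_metab), config.reps_metab)
    sample_ids = [f"{t}_{s}_{r}" for t, s, r in grid]
    noise = _stream(config.seed, "metab_noise").normal(
        0.0, config.noise_sd, size=(config.n_metabolites, len(grid)))
    log_vals = np.empty_like(noise)
    for i, met in enumerate(plan["mets"]):
        base = plan["baselines_met"][met]
        for j, (t, s, _r) in enumerate(grid):
            log_vals[i, j] = base + _log_signal(config, plan, met, t, s) + noise[i, j]
    values = pd.DataFrame(log_vals if config.log_values else np.exp(log_vals),
                          index=plan["mets"], columns=sample_ids)
    metadata = pd.DataFrame(
        {"treatment": [t for t, _, _ in grid],
         "stage_daa": [s for _, s, _ in grid],
         "replicate": [r for _, _, r in grid]},
        index=pd.Index(sample_ids, name="sample_id"))

    planted_edges: dict[str, set[tuple[str, str]]] = {"C": set(), "D": set()}
    for mod in config.modules:
        mem = plan["members"][mod.module_id]
        conds = {"both": ("C", "D"), "D_only": ("D",), "C_only": ("C",)}[mod.treatment_coupling]
        for cond in conds:
            for a_i in range(len(mem)):
                for b_i in range(a_i + 1, len(mem)):
                    planted_edges[cond].add(tuple(sorted((mem[a_i], mem[b_i]))))

    truth = SyntheticTruth(
        module_membership=dict(plan["membership"]),
        planted_edges=planted_edges,
        planted_gene_metabolite_links={(g, m) for g, m, _ in plan["links"]},
        regulon_genes=set(plan["regulon"]),
        planted_motif_ids=set(),
        effect_log2fc=_planted_effects(config, plan),
    )
    return OmicsMatrix(values=values, metadata=metadata), truth


def generate_transcript_matrix(config: SynthConfig, truth: SyntheticTruth) -> OmicsMatrix:
    """Transcript abundances over the 2 x stages_trans x reps_trans design.

    Linked genes track their partner metabolite's deterministic log signal
    (module latent in the coupled condition plus the treatment effect) with
    their own noise, so a planted gene-metabolite pair stays strongly
    correlated across the merged C+D samples. Unlinked genes are
    exchangeable log-normal noise.
    """
    plan = _plan(config)
    if {g for g, m, _ in plan["links"]} != {g for g, m in truth.planted_gene_metabolite_links}:
        raise SynthConfigError("truth was not produced by generate_metabolite_matrix "
                               "with this config")
    grid = _sample_grid(list(config.stages_trans), config.reps_trans)
    sample_ids = [f"{t}_{s}_{r}" for t, s, r in grid]
    partner = {g: m for g, m, _ in plan["links"]}
    noise = _stream(config.seed, "trans_noise").normal(
        0.0, config.noise_sd, size=(config.n_genes, len(grid)))
    log_vals = np.empty_like(noise)
    for i, gene in enumerate(plan["genes"]):
        base = plan["baselines_gene"][gene]
        met = partner.get(gene)
        for j, (t, s, _r) in enumerate(grid):
            sig = _log_signal(config, plan, met, t, s) if met is not None else 0.0
            log_vals[i, j] = base + sig + noise[i, j]
    values = pd.DataFrame(log_vals if config.log_values else np.exp(log_vals),
                          index=plan["genes"], columns=sample_ids)
    metadata = pd.DataFrame(
        {"treatment": [t for t, _, _ in grid],
         "stage_daa": [s for _, s, _ in grid],
         "replicate": [r for _, _, r in grid]},
        index=pd.Index(sample_ids, name="sample_id"))
    return OmicsMatrix(values=values, metadata=metadata)


# --------------------------------------------------------------------------- promoters & motifs

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYMKSWBDHVN", "TGCAYRKMSWVHDBN")


def reverse_complement(consensus: str) -> str:
    return consensus.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate consensus motif, PLACE-style."""

    motif_id: str
    consensus: str
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC characters in {self.motif_id}: {sorted(bad)}")


def default_motif_library() -> list[IUPACMotif]:
    """Synthetic PLACE-style library: 3 plantable drought/MYB-like elements
    plus decoys. Ids are synthetic; consensi are 8-10 nt with limited
    degeneracy so spontaneous matches in 1-kb promoters stay rare enough for
    presence/absence enrichment to have power.
    """
    planted = [
        IUPACMotif("DRE_CRT_LIKE", "RCCGACAT"),
        IUPACMotif("MYB_CORE_LIKE", "TAACTGGTY"),
        IUPACMotif("ABRE_LIKE", "ACGTGGCKA"),
    ]
    decoy_cons = [
        "TGACGTCAW", "CATGCATGR", "GGCCCAWTT", "AGATCCAAY", "TTGACYCGG",
        "CCGTTAGCA", "GATAAGRCC", "AAGCTTGCW", "TGGGCYAAT", "CGTCAGACT",
        "ATCGATCGR", "GCAACTTGY", "TACGCTAGA", "CTTGATCGW", "GGATATCCR",
        "ACCTAGGTY", "TCAATTGAC", "CAGGTACCW", "GTTCGAACR", "ATGCGCATW",
        "CCATTGGAY", "TGCATGCAR",
    ]
    decoys = [IUPACMotif(f"DECOY_{i + 1:02d}", c) for i, c in enumerate(decoy_cons)]
    return planted + decoys


@dataclass
class PromoterSet:
    """gene_id -> uppercase ACGT(N) promoter sequence, nominal length 1 kb."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for g, s in self.sequences.items():
            if set(s) - set("ACGTN"):
                raise ValueError(f"promoter {g} has characters outside ACGTN")

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def to_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        records = [SeqRecord(Seq(s), id=g, description="")
                   for g, s in self.sequences.items()]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "PromoterSet":
        from Bio import SeqIO
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(sequences=seqs)


def _realize(consensus: str, rng: np.random.Generator) -> str:
    """Draw a concrete ACGT instance of a degenerate consensus."""
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in consensus.upper())


def generate_promoters(config: SynthConfig, truth: SyntheticTruth,
                       motif_library: list[IUPACMotif] | None = None,
                       planted_motif_ids: tuple[str, ...] | None = None,
                       ) -> tuple[PromoterSet, list[IUPACMotif]]:
    """Random promoters with motif instances planted into regulon promoters.

    Each promoter is ``promoter_length`` nt with the configured GC content.
    Every planted motif is inserted (uniform position, random strand,
    replacing the underlying sequence) into each regulon promoter with
    probability ``motif_plant_rate_regulon`` and into each background
    promoter with probability ``motif_plant_rate_background``. Fills
    ``truth.planted_motif_ids``.
    """
    config.validate()
    library = list(default_motif_library()) if motif_library is None else list(motif_library)
    if not library:
        raise SynthConfigError("motif library must be non-empty")
    if planted_motif_ids is None:
        planted_motif_ids = tuple(m.motif_id for m in library
                                  if not m.motif_id.startswith("DECOY_"))[:3]
    planted = [m for m in library if m.motif_id in set(planted_motif_ids)]
    longest = max(len(m.consensus) for m in library)
    if longest > config.promoter_length:
        raise SynthConfigError("motif longer than promoter")

    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    regulon = truth.regulon_genes
    seqs: dict[str, str] = {}
    for gene in config.gene_ids():
        rng = _stream(config.seed, "promoter", gene)
        seq = rng.choice(bases, size=config.promoter_length, p=probs)
        for motif in planted:
            rate = (config.motif_plant_rate_regulon if gene in regulon
                    else config.motif_plant_rate_background)
            if rng.random() < rate:
                inst = _realize(motif.consensus, rng)
                if rng.random() < 0.5:
                    inst = reverse_complement(inst)
                pos = int(rng.integers(0, config.promoter_length - len(inst) + 1))
                seq[pos:pos + len(inst)] = list(inst)
        seqs[gene] = "".join(seq)
    truth.planted_motif_ids = {m.motif_id for m in planted}
    return PromoterSet(sequences=seqs), library


# --------------------------------------------------------------------------- bundle


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus the ground truth."""

    metabolites: OmicsMatrix
    transcripts: OmicsMatrix
    promoters: PromoterSet
    motif_library: list[IUPACMotif]
    go_map: dict[str, set[str]]
    pathway_map: dict[str, str]
    de_flags: set[str]
    truth: SyntheticTruth


def _go_and_annotations(config: SynthConfig, truth: SyntheticTruth,
                        ) -> tuple[dict[str, set[str]], dict[str, str], set[str]]:
    plan = _plan(config)
    genes = plan["genes"]
    rng = _stream(config.seed, "annotations")
    go_map: dict[str, set[str]] = {}
    # the regulon-heavy category, mirroring 'secondary metabolic process'
    extra = set(rng.choice(genes, size=min(60, len(genes)), replace=False))
    go_map["secondary_metabolic_process"] = set(plan["regulon"]) | extra
    for i in range(9):
        size = min(int(rng.integers(50, 151)), len(genes))
        go_map[f"go_slim_term_{i + 1:02d}"] = set(rng.choice(genes, size=size, replace=False))
    pathway_map = {g: MODULE_PATHWAY.get(mod, mod) for g, _m, mod in plan["links"]}
    linked = {g for g, _m, _mod in plan["links"]}
    n_extra_de = int(round(config.de_background_rate * config.n_genes))
    de_flags = linked | set(rng.choice(genes, size=n_extra_de, replace=False))
    return go_map, pathway_map, de_flags


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """One call producing the full coherent multi-omics dataset with truth."""
    metab, truth = generate_metabolite_matrix(config)
    trans = generate_transcript_matrix(config, truth)
    promoters, library = generate_promoters(config, truth)
    go_map, pathway_map, de_flags = _go_and_annotations(config, truth)
    return SyntheticDataset(
        metabolites=metab, transcripts=trans, promoters=promoters,
        motif_library=library, go_map=go_map, pathway_map=pathway_map,
        de_flags=de_flags, truth=truth)


# --------------------------------------------------------------------------- writers


def write_motif_table(library: list[IUPACMotif], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tiupac_consensus\n")
        for m in library:
            fh.write(f"{m.motif_id}\t{m.consensus}\n")


def read_motif_table(path: str | Path) -> list[IUPACMotif]:
    df = pd.read_csv(path, sep="\t")
    return [IUPACMotif(str(r.motif_id), str(r.iupac_consensus))
            for r in df.itertuples(index=False)]


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write the whole dataset as plain-text files; returns a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "metabolites": out / "metabolites.tsv",
        "metabolite_metadata": out / "metabolite_samples.tsv",
        "transcripts": out / "transcripts.tsv",
        "transcript_metadata": out / "transcript_samples.tsv",
        "promoters": out / "promoters.fasta",
        "motifs": out / "motifs.tsv",
        "go_map": out / "go_map.tsv",
        "pathway_map": out / "pathway_map.tsv",
        "de_flags": out / "de_flags.txt",
        "truth": out / "truth.json",
    }
    dataset.metabolites.to_tsv(paths["metabolites"], paths["metabolite_metadata"])
    dataset.transcripts.to_tsv(paths["transcripts"], paths["transcript_metadata"])
    dataset.promoters.to_fasta(paths["promoters"])
    write_motif_table(dataset.motif_library, paths["motifs"])
    with open(paths["go_map"], "w") as fh:
        fh.write("term\tgene_id\n")
        for term in sorted(dataset.go_map):
            for g in sorted(dataset.go_map[term]):
                fh.write(f"{term}\t{g}\n")
    with open(paths["pathway_map"], "w") as fh:
        fh.write("gene_id\tpathway\n")
        for g in sorted(dataset.pathway_map):
            fh.write(f"{g}\t{dataset.pathway_map[g]}\n")
    with open(paths["de_flags"], "w") as fh:
        for g in sorted(dataset.de_flags):
            fh.write(g + "\n")
    dataset.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
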