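"""End-to-end pipeline: collapse -> eqtl -> graph -> hubs.

`run_pipeline` is the in-memory core; `run_all` wraps it with file I/O,
schema-validated configuration, artifact writing and a run log that
records every parameter actually used plus a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import graph as graph_mod
from . import hubs as hubs_mod
from . import io as io_mod
from . import ld as ld_mod
from .eqtl import EqtlResult, scan
from .graph import ContactPair, TypedEdge
from .hubs import HubReport
from .ld import Locus, Snp
from .sim import TruthTables

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineArtifacts", "StageError", "run_pipeline", "run_all", "write_report"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it, prior artifacts survive."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


class PipelineConfig(BaseModel):
    """Declarative run description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    gwas_snps: Path
    genotypes: dict[str, Path]  # population -> VCF or dosage TSV
    expression: dict[str, Path] = Field(default_factory=dict)
    contacts: Path | None = None
    genes: Path | None = None
    functional: Path | None = None
    probes: Path | None = None  # probe annotation TSV
    out_dir: Path = Path("locushub_out")

    r2_min: float = Field(0.8, ge=0.0, le=1.0)
    dprime_min: float = Field(0.8, ge=0.0, le=1.0)
    window_kb: int = Field(500, ge=1)
    alpha_rep: float = Field(0.05, gt=0.0, lt=1.0)
    k_rep: int = Field(3, ge=1)
    alpha_single: float = Field(0.001, gt=0.0, lt=1.0)
    cis_window_kb: int = Field(1000, ge=0)
    flank_kb: int = Field(10, ge=0)
    min_support: float = Field(1.0, ge=0.0)
    max_path_len: int = Field(3, ge=1)
    min_gwas: int = Field(2, ge=2)
    layers: list[str] = Field(default_factory=lambda: ["spatial", "eqtl", "functional"])
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineArtifacts:
    snps: list[Snp]
    snp_loci: list[Locus]  # haplotype-block loci from the SNP list
    loci: list[Locus]  # snp loci + annotation-only gene loci
    ld_pairs: dict
    eqtl_results: list[EqtlResult]
    spatial_edges: list[TypedEdge]
    eqtl_edge_list: list[TypedEdge]
    functional_edges: list[TypedEdge]
    graph: nx.MultiGraph
    hubs: list[HubReport]
    precision: float | None = None
    recall: float | None = None
    counts: dict = field(default_factory=dict)


def _snp_to_locus(loci: list[Locus]) -> dict[str, str]:
    return {snp: l.locus_id for l in loci for snp in l.member_snps}


def _probe_to_locus(
    probe_positions: dict[str, tuple[str, int, int]], loci: list[Locus]
) -> dict[str, str]:
    mapping = {}
    located = [l for l in loci if l.start is not None]
    located.sort(key=lambda l: (str(l.chrom), l.start))
    for probe, (chrom, start, end) in probe_positions.items():
        for l in located:
            if str(l.chrom) == str(chrom) and l.start <= end and l.end >= start:
                mapping[probe] = l.locus_id
                break
    return mapping


def run_pipeline(
    snps: list[Snp],
    panels: dict[str, pd.DataFrame],
    expression_sets: dict[str, pd.DataFrame],
    contacts: list[ContactPair],
    genes: list[tuple[str, str, int, int]],
    functional_edges: list[TypedEdge],
    probe_positions: dict[str, tuple[str, int, int]] | None = None,
    haplotypes: np.ndarray | None = None,
    haplotype_snp_ids: list[str] | None = None,
    *,
    config: PipelineConfig | None = None,
    truth: TruthTables | None = None,
) -> PipelineArtifacts:
    """Run every stage on in-memory inputs.

    LD for block collapsing is computed from phased haplotypes when
    provided (pooled over populations by the caller) and otherwise by EM
    over the pooled unphased dosages of all populations.  The eQTL scan
    tests every GWAS SNP against every probe.
    """
    cfg = config or PipelineConfig(gwas_snps=Path("-"), genotypes={})
    window_bp = cfg.window_kb * 1000

    # ---- stage: collapse
    try:
        panel_snps = [s for s in snps if all(s.rsid in p.columns for p in panels.values())]
        if haplotypes is not None and haplotype_snp_ids is not None:
            ld_pairs = ld_mod.ld_pairs_from_haplotypes(
                panel_snps, haplotypes, haplotype_snp_ids, window_bp
            )
        else:
            pooled = pd.concat([panels[p] for p in sorted(panels)], axis=0)
            ids = list(pooled.columns)
            ld_pairs = ld_mod.ld_pairs_from_genotypes(
                panel_snps, pooled.to_numpy(dtype=float), ids, window_bp
            )
        snp_loci = ld_mod.collapse_blocks(
            panel_snps, ld_pairs, cfg.r2_min, cfg.dprime_min, window_bp
        )
        for locus in snp_loci:
            ld_mod.name_locus(locus, genes)
        loci = graph_mod.augment_loci_with_genes(snp_loci, genes)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("collapse", exc) from exc

    # ---- stage: eqtl
    try:
        eqtl_results: list[EqtlResult] = []
        if expression_sets:
            probe_ids = sorted(
                set().union(*(set(e.columns) for e in expression_sets.values()))
            )
            pairs = [(s.rsid, probe) for s in panel_snps for probe in probe_ids]
            eqtl_results = scan(
                panels,
                expression_sets,
                pairs,
                snp_positions={s.rsid: (s.chrom, s.pos) for s in panel_snps},
                probe_positions=probe_positions,
                alpha_rep=cfg.alpha_rep,
                k_rep=cfg.k_rep,
                alpha_single=cfg.alpha_single,
                cis_window=cfg.cis_window_kb * 1000,
            )
    except Exception as exc:
        raise StageError("eqtl", exc) from exc

    # ---- stage: graph
    try:
        spatial = graph_mod.map_contacts_to_loci(
            contacts, loci, flank=cfg.flank_kb * 1000, min_support=cfg.min_support
        )
        probe_map = _probe_to_locus(probe_positions or {}, loci)
        eqtl_edge_list = graph_mod.eqtl_edges(eqtl_results, _snp_to_locus(snp_loci), probe_map)
        g = graph_mod.build_graph(spatial, eqtl_edge_list, functional_edges, loci)
    except Exception as exc:
        raise StageError("graph", exc) from exc

    # ---- stage: hubs
    try:
        layer_filter = set(cfg.layers) if set(cfg.layers) != {"spatial", "eqtl", "functional"} else None
        reports = hubs_mod.find_hubs(
            g, max_path_len=cfg.max_path_len, min_gwas=cfg.min_gwas, layers=layer_filter
        )
    except Exception as exc:
        raise StageError("hubs", exc) from exc

    precision = recall = None
    if truth is not None:
        precision, recall = hubs_mod.evaluate_hubs(reports, truth)

    counts = {
        "n_snps": len(panel_snps),
        "n_snp_loci": len(snp_loci),
        "n_loci": len(loci),
        "n_contacts": len(contacts),
        "n_spatial_edges": len(spatial),
        "n_eqtl_edges": len(eqtl_edge_list),
        "n_functional_edges": len(functional_edges),
        "n_eqtl_significant": sum(r.verdict == "significant" for r in eqtl_results),
        "n_hubs": len(reports),
    }
    for stage, n in counts.items():
        logger.info("%s = %d", stage, n)

    return PipelineArtifacts(
        snps=panel_snps,
        snp_loci=snp_loci,
        loci=loci,
        ld_pairs=ld_pairs,
        eqtl_results=eqtl_results,
        spatial_edges=spatial,
        eqtl_edge_list=eqtl_edge_list,
        functional_edges=functional_edges,
        graph=g,
        hubs=reports,
        precision=precision,
        recall=recall,
        counts=counts,
    )


def run_synthetic(sim_config, pipeline_config: PipelineConfig | None = None) -> PipelineArtifacts:
    """Generate a synthetic study and push it through every stage.

    SNPs falling inside a gene named as a GWAS locus in ``hub_spec`` are
    GWAS-flagged; planted truth tables ride along so the returned
    artifacts carry hub precision/recall.
    """
    from . import sim as sim_mod

    panels = sim_mod.simulate_genotypes(sim_config)
    expression = sim_mod.simulate_expression(panels, sim_config)
    contact_tuples, functional_tuples, truth = sim_mod.simulate_contacts(sim_config)

    gwas_genes = {g for hub in sim_config.hub_spec for g in hub.gwas_loci}
    gwas_spans = [
        (chrom, start, end)
        for name, chrom, start, end in sim_config.genes
        if name in gwas_genes
    ]
    snps = []
    for rsid, chrom, pos in sim_config.snp_map:
        flag = any(
            str(chrom) == str(c) and start <= pos <= end for c, start, end in gwas_spans
        )
        snps.append(Snp(rsid=rsid, chrom=str(chrom), pos=pos, gwas_flag=flag))

    pops = sim_config.population_labels
    haplotypes = np.vstack([panels[p].haplotypes for p in pops])
    contacts = [
        ContactPair(cid, str(ca), sa, ea, str(cb), sb, eb)
        for cid, ca, sa, ea, cb, sb, eb in contact_tuples
    ]
    functional = [TypedEdge(*sorted((u, v)), layer="functional", evidence=[ev]) for u, v, ev in functional_tuples]
    probe_positions = {p: (str(c), s, e) for p, c, s, e in sim_config.probe_map} or None

    return run_pipeline(
        snps,
        {p: panels[p].to_frame() for p in pops},
        expression,
        contacts,
        sim_config.genes,
        functional,
        probe_positions,
        haplotypes,
        panels[pops[0]].snp_ids,
        config=pipeline_config,
        truth=truth,
    )


def run_all(config: PipelineConfig) -> PipelineArtifacts:
    """File-based pipeline: read inputs, run all stages, write artifacts.

    Re-running with an identical config (and identical inputs) reproduces
    identical artifacts; the run log records the config hash, the seed
    and every parameter used.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        snps = io_mod.read_gwas_snps(config.gwas_snps)
        panels = {}
        hap_blocks = []
        hap_ids: list[str] | None = None
        all_phased = True
        for pop in sorted(config.genotypes):
            path = Path(config.genotypes[pop])
            if path.suffix.lower() == ".vcf":
                frame, haps, vcf_snps = io_mod.read_vcf(path)
                panels[pop] = frame
                ids = [s.rsid for s in vcf_snps]
                if haps is None:
                    all_phased = False
                else:
                    hap_blocks.append((haps, ids))
                    if hap_ids is None:
                        hap_ids = ids
            else:
                panels[pop] = io_mod.read_dosage_tsv(path)
                all_phased = False
            logger.info("genotypes[%s]: %d samples x %d SNPs", pop, *panels[pop].shape)
        expression = {
            pop: io_mod.read_expression_tsv(p) for pop, p in sorted(config.expression.items())
        }
        contacts = io_mod.read_bedpe(config.contacts) if config.contacts else []
        genes = io_mod.read_genes(config.genes) if config.genes else []
        functional = io_mod.read_functional_edges(config.functional) if config.functional else []
        probe_positions = io_mod.read_probe_annotation(config.probes) if config.probes else None
    except Exception as exc:
        raise StageError("read_inputs", exc) from exc

    haplotypes = None
    haplotype_snp_ids = None
    if all_phased and hap_blocks and hap_ids is not None:
        aligned = []
        for haps, ids in hap_blocks:
            frame = pd.DataFrame(haps, columns=ids)
            aligned.append(frame[hap_ids].to_numpy())
        haplotypes = np.vstack(aligned)
        haplotype_snp_ids = hap_ids

    artifacts = run_pipeline(
        snps,
        panels,
        expression,
        contacts,
        genes,
        functional,
        probe_positions,
        haplotypes,
        haplotype_snp_ids,
        config=config,
    )

    io_mod.write_locus_table(artifacts.loci, out / "loci.tsv")
    io_mod.write_ld_table(
        [p for p in artifacts.ld_pairs.values() if p is not None], out / "ld_pairs.tsv"
    )
    io_mod.write_eqtl_table(
        artifacts.eqtl_results, sorted(panels), out / "eqtl_results.tsv"
    )
    io_mod.write_graphml(artifacts.graph, out / "graph.graphml")
    io_mod.write_edge_list(artifacts.graph, out / "edges.tsv")
    io_mod.write_hub_reports(artifacts.hubs, out / "hubs.tsv", out / "hubs.json")

    log = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "parameters": config.model_dump(mode="json"),
        "counts": artifacts.counts,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return artifacts


def write_report(out_dir: str | Path) -> str:
    """Human-readable summary recounted from the artifact files themselves."""
    out = Path(out_dir)
    loci = io_mod.read_locus_table(out / "loci.tsv") if (out / "loci.tsv").exists() else []
    n_snps = sum(len(l.member_snps) for l in loci)
    edges_by_layer: dict[str, int] = {"spatial": 0, "eqtl": 0, "functional": 0}
    edges_path = out / "edges.tsv"
    if edges_path.exists():
        with edges_path.open() as fh:
            next(fh, None)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    edges_by_layer[parts[2]] = edges_by_layer.get(parts[2], 0) + 1
    hubs_json = out / "hubs.json"
    hubs = json.loads(hubs_json.read_text()) if hubs_json.exists() else []

    lines = [
        f"SNPs: {n_snps}",
        f"Loci: {len(loci)} ({sum(l.gwas_flag for l in loci)} GWAS-flagged)",
        "Edges: " + ", ".join(f"{k}={v}" for k, v in sorted(edges_by_layer.items())),
        f"Hubs: {len(hubs)}",
    ]
    for hub in hubs:
        lines.append(
            f"  {hub['hub_id']}: {len(hub['gwas_members'])} GWAS loci "
            f"({', '.join(hub['gwas_members'])}); intermediaries: "
            f"{', '.join(hub['intermediaries']) or 'none'}; "
            f"{len(hub['paths'])} bridging path(s)"
        )
        for path in hub["paths"]:
            steps = " -> ".join(path["nodes"])
            lines.append(f"    {steps}  [{', '.join(path['layers'])}]")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
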