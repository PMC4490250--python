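"""Multilayer locus graph: spatial, eQTL and functional edges.

Spatial edges come from proximity-ligation contact pairs whose two
anchors overlap two distinct loci; eQTL edges from significant trans
verdicts; functional edges (protein or phenotype links such as the
BCAR1-BCAR3 C-terminal interaction) from a curated table, never inferred.
The graph is a :class:`networkx.MultiGraph` so the same locus pair can
carry one edge per layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from intervaltree import IntervalTree

from .eqtl import EqtlResult
from .ld import Locus

__all__ = [
    "ContactPair",
    "TypedEdge",
    "ChromosomeNamingError",
    "normalize_chrom",
    "map_contacts_to_loci",
    "eqtl_edges",
    "build_graph",
    "augment_loci_with_genes",
]

logger = logging.getLogger(__name__)

LAYERS = ("spatial", "eqtl", "functional")


class ChromosomeNamingError(ValueError):
    """Mixed 'chr1' / '1' conventions between inputs, with auto-normalization off."""


def normalize_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class ContactPair:
    """One proximity-ligation contact; anchors 1-based inclusive internally."""

    contact_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    support: float = 1.0

    def __post_init__(self) -> None:
        if self.start_a > self.end_a or self.start_b > self.end_b:
            raise ValueError(f"{self.contact_id}: anchor start must not exceed end")


@dataclass
class TypedEdge:
    """A locus-locus connection in one layer, with its evidence records."""

    locus_u: str
    locus_v: str
    layer: str
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.locus_u == self.locus_v:
            raise ValueError(f"self-loop on {self.locus_u}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if not self.evidence:
            raise ValueError("edge must carry at least one evidence record")

    @property
    def key(self) -> tuple[frozenset, str]:
        return frozenset((self.locus_u, self.locus_v)), self.layer


def _check_chrom_conventions(
    contacts: list[ContactPair], loci: list[Locus], auto_normalize: bool
) -> None:
    def has_prefix(names):
        return {str(n).lower().startswith("chr") for n in names if n is not None}

    c_pref = has_prefix([c.chrom_a for c in contacts] + [c.chrom_b for c in contacts])
    l_pref = has_prefix([l.chrom for l in loci])
    if not auto_normalize and c_pref and l_pref and c_pref != l_pref:
        raise ChromosomeNamingError(
            "contact files and locus table use different chromosome naming "
            "('chr1' vs '1'); pass auto_normalize=True or fix the inputs"
        )


def map_contacts_to_loci(
    contacts: list[ContactPair],
    loci: list[Locus],
    flank: int = 10_000,
    min_support: float = 1.0,
    auto_normalize: bool = True,
) -> list[TypedEdge]:
    """Turn contact pairs into spatial locus-locus edges.

    A contact contributes an edge when anchor A overlaps locus X and
    anchor B overlaps locus Y (loci extended by ``flank`` bp on each
    side) with X != Y.  Contacts hitting the same locus with both anchors
    are self-loops and dropped; duplicate contacts over the same locus
    pair merge into one edge whose evidence accumulates the contact ids.
    """
    _check_chrom_conventions(contacts, loci, auto_normalize)
    trees: dict[str, IntervalTree] = {}
    for locus in loci:
        if locus.start is None or locus.end is None:
            continue
        chrom = normalize_chrom(locus.chrom)
        # IntervalTree is half-open; +1 converts the inclusive end
        trees.setdefault(chrom, IntervalTree()).addi(
            max(1, locus.start - flank), locus.end + flank + 1, locus.locus_id
        )

    merged: dict[tuple[frozenset, str], TypedEdge] = {}
    for contact in contacts:
        if contact.support < min_support:
            continue
        hits_a = trees.get(normalize_chrom(contact.chrom_a), IntervalTree()).overlap(
            contact.start_a, contact.end_a + 1
        )
        hits_b = trees.get(normalize_chrom(contact.chrom_b), IntervalTree()).overlap(
            contact.start_b, contact.end_b + 1
        )
        pairs = {
            frozenset((ia.data, ib.data))
            for ia in hits_a
            for ib in hits_b
            if ia.data != ib.data
        }
        for pair in pairs:
            u, v = sorted(pair)
            key = (pair, "spatial")
            if key in merged:
                merged[key].evidence.append(contact.contact_id)
            else:
                merged[key] = TypedEdge(u, v, "spatial", [contact.contact_id])
    return sorted(merged.values(), key=lambda e: (e.locus_u, e.locus_v))


def eqtl_edges(
    results: list[EqtlResult],
    snp_to_locus: dict[str, str],
    probe_to_locus: dict[str, str],
) -> list[TypedEdge]:
    """Edges for significant eQTL verdicts, one per (SNP locus, probe locus).

    Results whose SNP and probe fall in the same locus (cis at the locus
    scale) stay in the result table but yield no edge; probes unmapped to
    any locus are skipped with a log record.
    """
    merged: dict[tuple[frozenset, str], TypedEdge] = {}
    for res in results:
        if res.verdict != "significant":
            continue
        if res.snp_id not in snp_to_locus:
            logger.warning("eQTL result %s:%s skipped: SNP unmapped to a locus", res.snp_id, res.probe_id)
            continue
        if res.probe_id not in probe_to_locus:
            logger.warning("eQTL result %s:%s skipped: probe unmapped to a locus", res.snp_id, res.probe_id)
            continue
        lu, lv = snp_to_locus[res.snp_id], probe_to_locus[res.probe_id]
        if lu == lv:
            continue
        u, v = sorted((lu, lv))
        key = (frozenset((u, v)), "eqtl")
        record = f"{res.snp_id}:{res.probe_id}"
        if key in merged:
            merged[key].evidence.append(record)
        else:
            merged[key] = TypedEdge(u, v, "eqtl", [record])
    return sorted(merged.values(), key=lambda e: (e.locus_u, e.locus_v))


def build_graph(
    spatial: list[TypedEdge],
    eqtl: list[TypedEdge],
    functional: list[TypedEdge],
    loci: list[Locus],
) -> nx.MultiGraph:
    """Assemble the multilayer graph.

    Nodes are loci touched by at least one edge plus every GWAS locus
    (GWAS loci stay visible even when isolated).  Parallel edges across
    layers are preserved as distinct multi-edges keyed by layer.
    """
    by_id = {l.locus_id: l for l in loci}
    offenders = sorted(
        {
            e
            for edge in (*spatial, *eqtl, *functional)
            for e in (edge.locus_u, edge.locus_v)
            if e not in by_id
        }
    )
    if offenders:
        raise ValueError(f"edges reference loci absent from the locus table: {offenders}")

    g = nx.MultiGraph()
    for locus in loci:
        if locus.gwas_flag:
            g.add_node(locus.locus_id)
    for edge in (*spatial, *eqtl, *functional):
        g.add_node(edge.locus_u)
        g.add_node(edge.locus_v)
        u, v = sorted((edge.locus_u, edge.locus_v))
        g.add_edge(u, v, key=edge.layer, layer=edge.layer, evidence=list(edge.evidence))
    for node in g.nodes:
        locus = by_id[node]
        g.nodes[node]["gwas_flag"] = bool(locus.gwas_flag)
        g.nodes[node]["chrom"] = str(locus.chrom)
    return g


def augment_loci_with_genes(
    loci: list[Locus], annotation: list[tuple[str, str, int, int]]
) -> list[Locus]:
    """Extend a SNP-derived locus table with annotation-only gene loci.

    Contact anchors and probes often fall in genes that carry no GWAS
    SNP (the intermediary loci); each annotated gene not overlapping an
    existing locus becomes its own non-GWAS locus so it can appear as a
    graph node.
    """
    out = list(loci)
    for name, chrom, start, end in annotation:
        overlaps = any(
            l.start is not None
            and str(l.chrom) == str(chrom)
            and l.start <= end
            and l.end >= start
            for l in loci
        )
        if not overlaps:
            out.append(
                Locus(
                    locus_id=name,
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    gene_labels=[name],
                    gwas_flag=False,
                )
            )
    return out
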