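"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: BED and BEDPE are 0-based half-open on disk and
converted to 1-based inclusive intervals in memory; GFF3, VCF and the
plain TSV tables are 1-based already.  Chromosome names keep whatever
the file used; graph construction normalizes the "chr" prefix.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .graph import ContactPair, TypedEdge
from .hubs import HubReport
from .ld import LdPair, Locus, Snp
from .sim import GenotypePanel, TruthTables


class ParseError(ValueError):
    """Malformed input row; message names file, line and reason."""


# ---------------------------------------------------------------- SNP lists


def read_gwas_snps(path: str | Path) -> list[Snp]:
    """GWAS SNP list TSV: rsid, chrom, pos, study[, p_value]; all rows GWAS-flagged."""
    snps = []
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                snps.append(
                    Snp(
                        rsid=row["rsid"],
                        chrom=str(row["chrom"]),
                        pos=int(row["pos"]),
                        source_study=row.get("study", "") or "",
                        gwas_flag=True,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad GWAS SNP row ({exc})") from exc
    return snps


# ---------------------------------------------------------------- genotypes


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    """Dosage TSV: sample rows x SNP columns, entries in {0, 1, 2} or NA."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: dosage value {values[i, j]} at sample {df.index[i]!r}, "
            f"SNP {df.columns[j]!r} is not in {{0,1,2}}"
        )
    return df


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index_label="sample")


def write_vcf(panel: GenotypePanel, snps: list[Snp], path: str | Path) -> None:
    """Write one population's phased genotypes as a minimal VCF 4.2 file."""
    by_id = {s.rsid: s for s in snps}
    order = sorted(
        range(len(panel.snp_ids)),
        key=lambda i: (str(by_id[panel.snp_ids[i]].chrom), by_id[panel.snp_ids[i]].pos),
    )
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted({str(by_id[s].chrom) for s in panel.snp_ids}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.sample_ids) + "\n")
        for i in order:
            snp = by_id[panel.snp_ids[i]]
            hap = panel.haplotypes[:, i]
            gts = "\t".join(
                f"{hap[2 * k]}|{hap[2 * k + 1]}" for k in range(len(panel.sample_ids))
            )
            fh.write(
                f"{snp.chrom}\t{snp.pos}\t{snp.rsid}\t{snp.alleles[0]}\t{snp.alleles[1]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, np.ndarray | None, list[Snp]]:
    """Read a VCF into (dosage frame, phased haplotypes or None, SNP list).

    Haplotypes are returned only when every genotype is phased.  Requires
    GT; biallelic records only.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages, haps, snps = [], [], []
    all_phased = True
    for var in vcf:
        if "GT" not in (var.FORMAT or []):
            raise ParseError(f"{path}: record {var.ID or var.POS} has no GT field")
        if len(var.ALT) != 1:
            raise ParseError(f"{path}: record {var.ID or var.POS} is not biallelic")
        row_d, row_h = [], []
        for g in var.genotypes:  # [allele0, allele1, phased]
            a0, a1, phased = g[0], g[1], bool(g[2])
            if a0 < 0 or a1 < 0:
                row_d.append(np.nan)
                row_h.extend([0, 0])
                all_phased = False
            else:
                row_d.append(a0 + a1)
                row_h.extend([a0, a1])
                all_phased = all_phased and phased
        dosages.append(row_d)
        haps.append(row_h)
        snps.append(
            Snp(
                rsid=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                alleles=(var.REF, var.ALT[0]),
            )
        )
    frame = pd.DataFrame(
        np.array(dosages, dtype=float).T, index=samples, columns=[s.rsid for s in snps]
    )
    hap_matrix = np.array(haps, dtype=np.int8).T if all_phased else None
    return frame, hap_matrix, snps


# ---------------------------------------------------------------- expression


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression TSV: sample rows x probe columns, float values."""
    return pd.read_csv(Path(path), sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------- annotation


def read_bed_genes(path: str | Path) -> list[tuple[str, str, int, int]]:
    """BED gene annotation -> (name, chrom, start, end) 1-based inclusive."""
    genes = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: BED gene rows need chrom/start/end/name")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start0 >= end0:
                raise ParseError(f"{path}:{lineno}: empty or inverted interval")
            genes.append((parts[3], parts[0], start0 + 1, end0))
    return genes


def write_bed_genes(genes: list[tuple[str, str, int, int]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, chrom, start, end in genes:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[tuple[str, str, int, int]]:
    """GFF3 annotation -> (name, chrom, start, end); name from Name= or ID=."""
    genes = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: GFF3 rows need 9 columns")
            if parts[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID")
            if name is None:
                raise ParseError(f"{path}:{lineno}: gene feature lacks Name/ID attribute")
            genes.append((name, parts[0], int(parts[3]), int(parts[4])))
    return genes


def read_genes(path: str | Path) -> list[tuple[str, str, int, int]]:
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return read_gff3_genes(path)
    return read_bed_genes(path)


def read_probe_annotation(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Probe annotation TSV: probe_id, chrom, start, end (1-based)."""
    out = {}
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                out[row["probe_id"]] = (str(row["chrom"]), int(row["start"]), int(row["end"]))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: bad probe row ({exc})") from exc
    return out


# ---------------------------------------------------------------- contacts


def read_bedpe(path: str | Path) -> list[ContactPair]:
    """BEDPE contact list; 0-based half-open anchors become 1-based inclusive."""
    contacts = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: BEDPE rows need 6 coordinate columns")
            try:
                sa0, ea0, sb0, eb0 = int(parts[1]), int(parts[2]), int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if sa0 >= ea0 or sb0 >= eb0:
                raise ParseError(f"{path}:{lineno}: empty or inverted anchor interval")
            support = 1.0
            if len(parts) >= 8:
                try:
                    support = float(parts[7])
                except ValueError:
                    support = 1.0
            contacts.append(
                ContactPair(
                    contact_id=parts[6] if len(parts) >= 7 and parts[6] not in (".", "") else f"{path.stem}:{lineno}",
                    chrom_a=parts[0],
                    start_a=sa0 + 1,
                    end_a=ea0,
                    chrom_b=parts[3],
                    start_b=sb0 + 1,
                    end_b=eb0,
                    support=support,
                )
            )
    return contacts


def write_bedpe(contacts, path: str | Path) -> None:
    """Write (contact_id, chrom_a, start_a, end_a, chrom_b, start_b, end_b)
    tuples (1-based inclusive) as BEDPE."""
    with Path(path).open("w") as fh:
        for cid, ca, sa, ea, cb, sb, eb in contacts:
            fh.write(f"{ca}\t{sa - 1}\t{ea}\t{cb}\t{sb - 1}\t{eb}\t{cid}\t1\n")


# ---------------------------------------------------------------- functional


def read_functional_edges(path: str | Path) -> list[TypedEdge]:
    """Curated functional-edge TSV: locus_u, locus_v[, evidence]."""
    edges: dict[frozenset, TypedEdge] = {}
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                u, v = row["locus_u"], row["locus_v"]
                ev = row.get("evidence") or "curated"
            except KeyError as exc:
                raise ParseError(f"{path}:{lineno}: bad functional edge row ({exc})") from exc
            if u == v:
                raise ParseError(f"{path}:{lineno}: functional self-loop on {u}")
            key = frozenset((u, v))
            if key in edges:
                edges[key].evidence.append(ev)
            else:
                a, b = sorted((u, v))
                edges[key] = TypedEdge(a, b, "functional", [ev])
    return sorted(edges.values(), key=lambda e: (e.locus_u, e.locus_v))


def write_functional_edges(edges, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("locus_u\tlocus_v\tevidence\n")
        for u, v, ev in edges:
            fh.write(f"{u}\t{v}\t{ev}\n")


# ---------------------------------------------------------------- tables


def write_locus_table(loci: list[Locus], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tmember_snps\tgene_labels\tgwas_flag\n")
        for l in loci:
            fh.write(
                f"{l.locus_id}\t{l.chrom}\t{l.start if l.start is not None else ''}"
                f"\t{l.end if l.end is not None else ''}\t{','.join(l.member_snps)}"
                f"\t{','.join(l.gene_labels)}\t{int(l.gwas_flag)}\n"
            )


def read_locus_table(path: str | Path) -> list[Locus]:
    loci = []
    path = Path(path)
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            loci.append(
                Locus(
                    locus_id=row["locus_id"],
                    chrom=str(row["chrom"]),
                    start=int(row["start"]) if row.get("start") else None,
                    end=int(row["end"]) if row.get("end") else None,
                    member_snps=[s for s in (row.get("member_snps") or "").split(",") if s],
                    gene_labels=[s for s in (row.get("gene_labels") or "").split(",") if s],
                    gwas_flag=bool(int(row.get("gwas_flag") or 0)),
                )
            )
    return loci


def write_ld_table(pairs: list[LdPair], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("snp_a\tsnp_b\tp_a\tp_b\tp_ab\tD\td_prime\tr2\n")
        for p in pairs:
            fh.write(
                f"{p.snp_a}\t{p.snp_b}\t{p.p_a:.6g}\t{p.p_b:.6g}\t{p.p_ab:.6g}"
                f"\t{p.d:.6g}\t{p.d_prime:.6g}\t{p.r2:.6g}\n"
            )


def write_eqtl_table(results, populations: list[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        cols = [f"{pop}_{x}" for pop in populations for x in ("rho", "p")]
        fh.write("snp\tprobe\t" + "\t".join(cols) + "\tverdict\trule\tcis_trans\n")
        for r in results:
            by_pop = {s.population: s for s in r.per_population}
            cells = []
            for pop in populations:
                s = by_pop.get(pop)
                if s is None or not s.testable:
                    cells.extend(["NA", "NA"])
                else:
                    cells.extend([f"{s.rho:.6g}", f"{s.p:.6g}"])
            fh.write(
                f"{r.snp_id}\t{r.probe_id}\t" + "\t".join(cells)
                + f"\t{r.verdict}\t{r.rule_fired}\t{r.cis_trans}\n"
            )


# ---------------------------------------------------------------- graph


def write_graphml(graph: nx.MultiGraph, path: str | Path) -> None:
    g = nx.MultiGraph()
    g.add_nodes_from((n, dict(d)) for n, d in graph.nodes(data=True))
    for u, v, k, d in graph.edges(keys=True, data=True):
        attrs = dict(d)
        if isinstance(attrs.get("evidence"), list):
            attrs["evidence"] = ";".join(attrs["evidence"])
        g.add_edge(u, v, key=k, **attrs)
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.MultiGraph:
    g = nx.read_graphml(str(path), force_multigraph=True)
    for _, _, d in g.edges(data=True):
        if isinstance(d.get("evidence"), str):
            d["evidence"] = d["evidence"].split(";")
    return g


def write_edge_list(graph: nx.MultiGraph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("locus_u\tlocus_v\tlayer\tevidence\n")
        rows = sorted(
            (min(u, v), max(u, v), d.get("layer", k), ";".join(d.get("evidence", [])))
            for u, v, k, d in graph.edges(keys=True, data=True)
        )
        for u, v, layer, ev in rows:
            fh.write(f"{u}\t{v}\t{layer}\t{ev}\n")


# ---------------------------------------------------------------- hubs


def write_hub_reports(reports: list[HubReport], tsv_path: str | Path, json_path: str | Path) -> None:
    with Path(tsv_path).open("w") as fh:
        fh.write("hub_id\tn_gwas\tgwas_members\tintermediaries\tn_paths\tn_layers\n")
        for r in reports:
            fh.write(
                f"{r.hub_id}\t{len(r.gwas_members)}\t{','.join(r.gwas_members)}"
                f"\t{','.join(r.intermediaries)}\t{len(r.paths)}\t{r.n_layers_used}\n"
            )
    payload = [
        {
            "hub_id": r.hub_id,
            "gwas_members": r.gwas_members,
            "intermediaries": r.intermediaries,
            "paths": [
                {"nodes": list(p.nodes), "layers": list(p.layers)} for p in r.paths
            ],
            "n_layers_used": r.n_layers_used,
        }
        for r in reports
    ]
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def write_dot(graph: nx.MultiGraph, path: str | Path) -> None:
    """Minimal DOT export for figure drafts (GWAS nodes boxed, layer styles)."""
    style = {"spatial": "dashed", "eqtl": "solid", "functional": "bold"}
    with Path(path).open("w") as fh:
        fh.write("graph locushub {\n")
        for n, d in sorted(graph.nodes(data=True)):
            shape = "box" if d.get("gwas_flag") else "ellipse"
            fh.write(f'  "{n}" [shape={shape}];\n')
        for u, v, k, d in sorted(graph.edges(keys=True, data=True)):
            layer = d.get("layer", k)
            fh.write(f'  "{u}" -- "{v}" [style={style.get(layer, "solid")}, label="{layer}"];\n')
        fh.write("}\n")


# ---------------------------------------------------------------- truth


def write_truth_tables(truth: TruthTables, path: str | Path) -> None:
    payload = {
        "planted_blocks": truth.planted_blocks,
        "planted_eqtl_pairs": sorted(list(p) for p in truth.planted_eqtl_pairs),
        "planted_hub_members": sorted(sorted(h) for h in truth.planted_hub_members),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth_tables(path: str | Path) -> TruthTables:
    payload = json.loads(Path(path).read_text())
    return TruthTables(
        planted_blocks=payload["planted_blocks"],
        planted_eqtl_pairs={tuple(p) for p in payload["planted_eqtl_pairs"]},
        planted_hub_members={frozenset(h) for h in payload["planted_hub_members"]},
    )


# ---------------------------------------------------------------- fixtures


def _fixture_path(name: str):
    return resources.files("locushub.data").joinpath(name)


def load_worked_example(name: str) -> tuple[list[Locus], list[TypedEdge]]:
    """Load a packaged worked-example fixture by name.

    Available: ``"tm6sf2_hub"`` (the three-way TM6SF2 / CTRB1-BCAR1 /
    CELSR2-PSRC1 hub bridged by KCNIP3 and BCAR3), ``"pank1_wfs1"`` (the
    direct PANK1-WFS1 connection) and ``"grm5_bridge"`` (IGF2BP2 and
    HNF1A sharing the GRM5 intermediary).
    """
    loci = []
    with _fixture_path(f"{name}_loci.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            loci.append(
                Locus(
                    locus_id=row["locus_id"],
                    chrom=str(row["chrom"]),
                    start=None,
                    end=None,
                    gene_labels=[s for s in (row.get("gene_labels") or "").split(",") if s],
                    member_snps=[s for s in (row.get("member_snps") or "").split(",") if s],
                    gwas_flag=bool(int(row["gwas_flag"])),
                )
            )
    edges: dict[tuple, TypedEdge] = {}
    with _fixture_path(f"{name}_edges.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            u, v = sorted((row["locus_u"], row["locus_v"]))
            key = (frozenset((u, v)), row["layer"])
            if key in edges:
                edges[key].evidence.append(row["evidence"])
            else:
                edges[key] = TypedEdge(u, v, row["layer"], [row["evidence"]])
    return loci, sorted(edges.values(), key=lambda e: (e.locus_u, e.locus_v, e.layer))


def load_gwas_snp_fixture() -> list[Snp]:
    """The packaged meta-analysis T2D SNP list (rsid, chrom, pos, gene, study)."""
    snps = []
    with _fixture_path("gwas_snps.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            snps.append(
                Snp(
                    rsid=row["rsid"],
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    source_study=row["study"],
                    gwas_flag=True,
                )
            )
    return snps
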