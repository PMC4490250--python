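# locushub

Connect GWAS loci into regulatory hubs.

Many disease-associated SNPs — type 2 diabetes is the motivating case —
sit outside genes and explain nothing by themselves. `locushub`
implements the analysis that asks whether such variants are linked
through the 3D organization of the genome: it collapses SNPs into
linkage-disequilibrium (LD) loci, tests trans expression associations
across population panels with a replication rule, layers spatial
(chromatin contact), eQTL and curated functional edges into one locus
graph, and reports **hubs** — sets of ≥2 GWAS loci connected directly or
through intermediary loci — with the bridging paths that explain them.

The stages, in the field's standard notation:

1. **Loci.** SNPs with pairwise LD **r² ≥ 0.8 or D′ ≥ 0.8** (D = p_AB −
   p_A·p_B, D′ = |D|/D_max, r² = D²/(p_A q_A p_B q_B); EM haplotype
   frequencies for unphased input) are merged by connected components
   into haplotype-block loci named after their genes (`CELSR2/PSRC1`).
2. **Trans-eQTLs.** Spearman rank association of dosage vs expression
   per population; a SNP-probe pair is significant when *p* < 0.05 in ≥3
   populations (replication) or *p* < 0.001 in one. Trans = different
   chromosome or >1 Mb.
3. **Graph.** Contact anchors overlapping two distinct loci (±10 kb
   flank) give spatial edges; significant trans verdicts give eqtl
   edges; curated protein/phenotype links give functional edges.
4. **Hubs.** Connected components of the graph restricted to
   GWAS-to-GWAS bridging paths (simple, non-GWAS interiors, ≤3 edges),
   reported with minimal paths and per-step layers.

A synthetic-data module generates population genotype panels with
planted LD blocks, additive eQTL effects and planted hubs so the whole
pipeline is testable offline, with truth tables for precision/recall.

## Worked example

The package ships the transcribed edge list of the three-way diabetes
hub (loci `TM6SF2`, `CTRB1/BCAR1`, `CELSR2/PSRC1`; spatial edges to
SUGP1, LPP, KCNIP3, SORT1, NOTCH2, BCAR3, 21q22.3; one curated
functional edge CTRB1/BCAR1–BCAR3):

```python
from locushub import build_graph, find_hubs
from locushub.io import load_worked_example

loci, edges = load_worked_example("tm6sf2_hub")
g = build_graph(
    [e for e in edges if e.layer == "spatial"], [],
    [e for e in edges if e.layer == "functional"], loci,
)
(hub,) = find_hubs(g, max_path_len=3, min_gwas=2)
print(hub.gwas_members)
print(hub.intermediaries)
for p in hub.paths:
    print(" -> ".join(p.nodes), p.layers)
```

prints

```
['CELSR2/PSRC1', 'CTRB1/BCAR1', 'TM6SF2']
['BCAR3', 'KCNIP3']
CELSR2/PSRC1 -> BCAR3 -> CTRB1/BCAR1 ('spatial', 'functional')
CTRB1/BCAR1 -> KCNIP3 -> TM6SF2 ('spatial', 'spatial')
```

i.e. the three GWAS loci form a single hub: two of them bridge through
the KCNIP3 locus in space, and the third joins through a spatial contact
to BCAR3 whose product binds BCAR1 — one hub, two intermediaries, two
bridging paths mixing the spatial and functional layers.

The same objects drive full runs from files:

```sh
locushub run-all --config config.yaml   # collapse -> eqtl -> graph -> hubs
locushub report --out out/              # counts recounted from artifacts
```

with `simulate`, `collapse`, `eqtl`, `graph` and `hubs` subcommands for
individual stages.

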