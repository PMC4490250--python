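"""Synthetic genotype / expression / contact data with planted ground truth.

The generator emulates the study design the pipeline targets: eight
reference population panels with haplotype-block LD structure, additive
SNP effects on expression with Gaussian noise, and proximity-ligation
contact lists containing planted GWAS-intermediary-GWAS hubs on top of
random background contacts.  Every stage is deterministic given the
config seed, and a :class:`TruthTables` record of what was planted rides
along so downstream recovery can be scored.

Block LD is planted through a latent haplotype per block: each member
SNP copies the latent allele with probability sqrt(level) and otherwise
redraws from the block's allele frequency, giving pairwise haplotype
correlation ``level`` (so ``r^2 = level^2``, and ``level = 1`` duplicates
the column exactly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PlantedEqtl",
    "PlantedHub",
    "GenotypePanel",
    "TruthTables",
    "SimulationError",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_contacts",
]

# sub-stream tags so genotype / expression / contact draws never collide
_STREAM_GENO, _STREAM_EXPR, _STREAM_CONTACT = 11, 13, 17


class SimulationError(RuntimeError):
    """The generator could not satisfy its constraints (e.g. background
    contact placement kept colliding with loci after bounded retries)."""


@dataclass(frozen=True)
class PlantedEqtl:
    snp_id: str
    probe_id: str
    beta: float  # expression units per alt-allele copy
    populations: tuple[str, ...] | None = None  # None = all populations


@dataclass(frozen=True)
class PlantedHub:
    """GWAS loci to connect, the shared intermediary, and per-leg layers.

    ``intermediary`` of ``None`` plants a direct connection between the
    two GWAS loci instead.  ``edge_types`` has one entry per GWAS locus
    (per leg), each ``"spatial"`` or ``"functional"``.
    """

    gwas_loci: tuple[str, ...]
    intermediary: str | None
    edge_types: tuple[str, ...]


@dataclass
class GenotypePanel:
    population: str
    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # (n_samples, n_snps) in {0,1,2}
    haplotypes: np.ndarray  # (2*n_samples, n_snps) in {0,1}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


@dataclass
class TruthTables:
    """What was planted, for downstream recovery scoring."""

    planted_blocks: list[list[str]]  # partition of SNP rsids
    planted_eqtl_pairs: set[tuple[str, str]]
    planted_hub_members: set[frozenset]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for block in self.planted_blocks:
            for rsid in block:
                if rsid in seen:
                    raise ValueError(f"planted blocks are not a partition: {rsid} repeated")
                seen.add(rsid)


@dataclass
class SimulationConfig:
    """Full description of one synthetic study.

    Defaults mirror the design the pipeline emulates: 8 population
    panels, additive eQTL effects with unit-variance Gaussian noise, and
    allele frequencies drawn uniformly in [0.05, 0.95] per population.
    """

    snp_map: list[tuple[str, str, int]]  # (rsid, chrom, pos 1-based)
    n_populations: int = 8
    n_samples_per_pop: int = 60
    block_spec: list[tuple[list[int], float]] = field(default_factory=list)
    eqtl_spec: list[PlantedEqtl] = field(default_factory=list)
    noise_sd: float = 1.0
    genes: list[tuple[str, str, int, int]] = field(default_factory=list)
    probe_map: list[tuple[str, str, int, int]] = field(default_factory=list)
    hub_spec: list[PlantedHub] = field(default_factory=list)
    n_background_contacts: int = 0
    n_null_probes: int = 0
    maf_range: tuple[float, float] = (0.05, 0.95)
    anchor_width: int = 1000
    background_flank: int = 20_000
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if self.n_samples_per_pop < 1:
            raise ValueError("n_samples_per_pop must be >= 1")
        if not 0.0 < self.maf_range[0] <= self.maf_range[1] < 1.0:
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        rsids = [r for r, _, _ in self.snp_map]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsids in snp_map")
        seen_idx: set[int] = set()
        for indices, level in self.block_spec:
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"block correlation level {level} outside [0, 1]")
            for i in indices:
                if not 0 <= i < len(self.snp_map):
                    raise ValueError(f"block SNP index {i} out of range")
                if i in seen_idx:
                    raise ValueError(f"block_spec groups overlap at SNP index {i}")
                seen_idx.add(i)
        pops = set(self.population_labels)
        snp_ids = set(rsids)
        per_probe_snps: dict[str, set[str]] = {}
        for eff in self.eqtl_spec:
            if eff.snp_id not in snp_ids:
                raise ValueError(f"eqtl_spec references unknown SNP {eff.snp_id}")
            if eff.populations is not None and not set(eff.populations) <= pops:
                raise ValueError(f"eqtl_spec references undeclared populations: {eff.populations}")
            prior = per_probe_snps.setdefault(eff.probe_id, set())
            if eff.snp_id in prior:
                raise ValueError(
                    f"probe {eff.probe_id} has two planted effects from SNP {eff.snp_id}"
                )
            prior.add(eff.snp_id)
        gene_names = {name for name, *_ in self.genes}
        for hub in self.hub_spec:
            referenced = set(hub.gwas_loci) | ({hub.intermediary} - {None})
            missing = referenced - gene_names
            if missing:
                raise ValueError(f"hub_spec references loci absent from annotation: {sorted(missing)}")
            n_legs = len(hub.gwas_loci) if hub.intermediary is not None else len(hub.gwas_loci) - 1
            if len(hub.edge_types) != n_legs:
                raise ValueError("hub edge_types must have one entry per leg")
            for et in hub.edge_types:
                if et not in ("spatial", "functional"):
                    raise ValueError(f"unsupported planted edge type {et!r}")
            if hub.intermediary is None and len(hub.gwas_loci) != 2:
                raise ValueError("direct hubs (no intermediary) must have exactly 2 GWAS loci")

    @property
    def population_labels(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    @property
    def probe_ids(self) -> list[str]:
        planted = []
        for eff in self.eqtl_spec:
            if eff.probe_id not in planted:
                planted.append(eff.probe_id)
        nulls = [f"null_probe_{i + 1}" for i in range(self.n_null_probes)]
        return planted + nulls

    def truth_blocks(self) -> list[list[str]]:
        rsids = [r for r, _, _ in self.snp_map]
        in_block = set()
        blocks = []
        for indices, _ in self.block_spec:
            blocks.append([rsids[i] for i in sorted(indices)])
            in_block.update(indices)
        for i, rsid in enumerate(rsids):
            if i not in in_block:
                blocks.append([rsid])
        return blocks


def _rng(config: SimulationConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, *extra])


def simulate_genotypes(config: SimulationConfig) -> dict[str, GenotypePanel]:
    """Draw phased haplotypes and dosages for every population.

    Within a block all member SNPs share the block's allele frequency and
    copy a latent haplotype (see module docstring); SNPs outside any
    block are drawn independently.  Identical config + seed reproduce the
    panels bit for bit.
    """
    m = len(config.snp_map)
    rsids = [r for r, _, _ in config.snp_map]
    block_of = {}
    for b, (indices, level) in enumerate(config.block_spec):
        for i in indices:
            block_of[i] = (b, level)

    panels = {}
    for p, pop in enumerate(config.population_labels):
        rng = _rng(config, _STREAM_GENO, p)
        n_hap = 2 * config.n_samples_per_pop
        lo, hi = config.maf_range
        freqs = rng.uniform(lo, hi, size=m)
        # block members share their block's frequency (first member's draw)
        for indices, _ in config.block_spec:
            freqs[indices] = freqs[indices[0]]
        latents = {
            b: rng.random(n_hap) < freqs[indices[0]]
            for b, (indices, _) in enumerate(config.block_spec)
        }
        hap = np.empty((n_hap, m), dtype=np.int8)
        for j in range(m):
            indep = rng.random(n_hap) < freqs[j]
            if j in block_of:
                b, level = block_of[j]
                copy = rng.random(n_hap) < math.sqrt(level)
                hap[:, j] = np.where(copy, latents[b], indep)
            else:
                hap[:, j] = indep
        dosages = hap[0::2] + hap[1::2]
        panels[pop] = GenotypePanel(
            population=pop,
            sample_ids=[f"{pop}_s{i + 1}" for i in range(config.n_samples_per_pop)],
            snp_ids=list(rsids),
            dosages=dosages.astype(np.int8),
            haplotypes=hap,
        )
    return panels


def simulate_expression(
    panels: dict[str, GenotypePanel], config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Additive-model expression: expr = sum(beta * dosage) + N(0, noise_sd).

    Probes without a planted effect (and all ``null_probe_*`` probes) are
    pure noise; a planted effect restricted to a population subset adds
    its beta term only there.
    """
    probe_ids = config.probe_ids
    effects_by_probe: dict[str, list[PlantedEqtl]] = {}
    for eff in config.eqtl_spec:
        effects_by_probe.setdefault(eff.probe_id, []).append(eff)

    out = {}
    for p, pop in enumerate(config.population_labels):
        panel = panels[pop]
        rng = _rng(config, _STREAM_EXPR, p)
        n = len(panel.sample_ids)
        expr = np.zeros((n, len(probe_ids)))
        if config.noise_sd > 0:
            expr += rng.normal(0.0, config.noise_sd, size=expr.shape)
        col = {s: i for i, s in enumerate(panel.snp_ids)}
        for j, probe in enumerate(probe_ids):
            for eff in effects_by_probe.get(probe, []):
                if eff.populations is not None and pop not in eff.populations:
                    continue
                expr[:, j] += eff.beta * panel.dosages[:, col[eff.snp_id]]
        out[pop] = pd.DataFrame(expr, index=panel.sample_ids, columns=probe_ids)
    return out


def _gene_span(config: SimulationConfig, name: str) -> tuple[str, int, int]:
    for gname, chrom, start, end in config.genes:
        if gname == name:
            return str(chrom), start, end
    raise KeyError(name)


def _anchor_in(config: SimulationConfig, name: str, rng: np.random.Generator):
    chrom, start, end = _gene_span(config, name)
    width = min(config.anchor_width, end - start + 1)
    a0 = int(rng.integers(start, max(start, end - width + 1) + 1))
    return chrom, a0, a0 + width - 1


def simulate_contacts(config: SimulationConfig):
    """Planted hub contacts + functional edges + uniform background.

    Returns ``(contacts, functional_edges, truth)`` where contacts are
    (contact_id, chrom_a, start_a, end_a, chrom_b, start_b, end_b)
    tuples (1-based inclusive) and functional edges are
    (locus_u, locus_v, evidence) tuples.  Each planted spatial leg emits
    one contact anchored inside the GWAS gene and the intermediary gene;
    functional legs emit curated-table rows instead.  Background contacts
    are placed uniformly outside all annotated genes (± background_flank)
    by rejection sampling, so they can never add locus-locus edges;
    persistent rejection failure raises :class:`SimulationError`.
    """
    rng = _rng(config, _STREAM_CONTACT)
    contacts = []
    functional = []
    counter = 0
    for hub in config.hub_spec:
        if hub.intermediary is not None:
            legs = [(g, hub.intermediary, et) for g, et in zip(hub.gwas_loci, hub.edge_types)]
        else:
            legs = [(hub.gwas_loci[0], hub.gwas_loci[1], hub.edge_types[0])]
        for u, v, edge_type in legs:
            if edge_type == "spatial":
                counter += 1
                ca, sa, ea = _anchor_in(config, u, rng)
                cb, sb, eb = _anchor_in(config, v, rng)
                contacts.append((f"contact{counter}", ca, sa, ea, cb, sb, eb))
            else:
                functional.append((u, v, "planted_curated"))

    # chromosome sizes default to generous bounds past every feature
    sizes = dict(config.chrom_sizes)
    for _, chrom, _, end in config.genes:
        sizes.setdefault(str(chrom), 0)
        sizes[str(chrom)] = max(sizes[str(chrom)], end + 1_000_000)
    for _, chrom, pos in config.snp_map:
        sizes.setdefault(str(chrom), 0)
        sizes[str(chrom)] = max(sizes[str(chrom)], pos + 1_000_000)
    if not sizes:
        sizes = {"1": 10_000_000}
    chroms = sorted(sizes)

    def clear_of_genes(chrom: str, start: int, end: int) -> bool:
        for _, gchrom, gstart, gend in config.genes:
            if str(gchrom) == chrom and start <= gend + config.background_flank and end >= gstart - config.background_flank:
                return False
        return True

    def random_anchor() -> tuple[str, int, int]:
        for _ in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            a0 = int(rng.integers(1, sizes[chrom] - config.anchor_width))
            a1 = a0 + config.anchor_width - 1
            if clear_of_genes(chrom, a0, a1):
                return chrom, a0, a1
        raise SimulationError(
            "could not place a background contact anchor clear of all loci "
            "after 200 attempts; reduce gene density or background_flank"
        )

    for _ in range(config.n_background_contacts):
        counter += 1
        ca, sa, ea = random_anchor()
        cb, sb, eb = random_anchor()
        contacts.append((f"contact{counter}", ca, sa, ea, cb, sb, eb))

    truth = TruthTables(
        planted_blocks=config.truth_blocks(),
        planted_eqtl_pairs={(e.snp_id, e.probe_id) for e in config.eqtl_spec},
        planted_hub_members={frozenset(h.gwas_loci) for h in config.hub_spec},
    )
    return contacts, functional, truth
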