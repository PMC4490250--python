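"""Pairwise linkage disequilibrium and haplotype-block locus collapsing.

SNPs in strong mutual LD are treated as a single regulatory unit (a
*locus*): any pair reaching ``r^2 >= 0.8`` or ``D' >= 0.8`` is linked, and
connected components of that link graph become loci.  A locus is named
after the genes its span overlaps (``"CELSR2/PSRC1"``) or, when no gene
overlaps, after its coordinates (``"10:91352000-91353000"``).

Haplotype frequencies come from direct counting when phased haplotypes
are available, and otherwise from the standard two-locus EM over
genotype counts (only the double heterozygote is ambiguous).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Snp",
    "LdPair",
    "Locus",
    "LdUndefinedError",
    "MissingLdError",
    "haplotype_freqs_phased",
    "estimate_haplotype_freqs",
    "ld_pair",
    "ld_pairs_from_haplotypes",
    "ld_pairs_from_genotypes",
    "collapse_blocks",
    "name_locus",
]


class LdUndefinedError(ValueError):
    """LD is undefined (a SNP is monomorphic in the data at hand).

    Raised distinctly from numeric failures so callers can treat the pair
    as "no information" rather than as an error in the computation.
    """


class MissingLdError(KeyError):
    """A same-chromosome SNP pair inside the window has no LD entry."""


@dataclass(frozen=True)
class Snp:
    """A biallelic variant with provenance.

    ``pos`` is 1-based.  ``gwas_flag`` marks variants drawn from a GWAS
    (meta-analysis) hit list; the flag propagates to any locus the SNP
    joins.
    """

    rsid: str
    chrom: str
    pos: int
    alleles: tuple[str, str] = ("A", "G")
    source_study: str = ""
    gwas_flag: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"{self.rsid}: ref and alt alleles must differ")


@dataclass(frozen=True)
class LdPair:
    """Two-locus disequilibrium summary.

    D = p_AB - p_A p_B;  D' = |D| / D_max;  r2 = D^2 / (p_A q_A p_B q_B).
    Both normalized coefficients lie in [0, 1] and satisfy r2 <= D'^2.
    """

    snp_a: str
    snp_b: str
    p_a: float
    p_b: float
    p_ab: float
    d: float
    d_prime: float
    r2: float


@dataclass
class Locus:
    """A haplotype block (or annotated gene region) acting as a graph node.

    ``start``/``end`` are 1-based inclusive and may be ``None`` for loci
    defined only by name (e.g. transcribed figure fixtures).
    """

    locus_id: str
    chrom: str
    start: int | None
    end: int | None
    member_snps: list[str] = field(default_factory=list)
    gene_labels: list[str] = field(default_factory=list)
    gwas_flag: bool = False


def haplotype_freqs_phased(hap_a: np.ndarray, hap_b: np.ndarray) -> tuple[float, float, float]:
    """Directly count (p_A, p_B, p_AB) from two phased haplotype vectors.

    Vectors hold 0/1 allele indicators over the same 2n chromosomes.
    """
    hap_a = np.asarray(hap_a, dtype=float)
    hap_b = np.asarray(hap_b, dtype=float)
    if hap_a.shape != hap_b.shape or hap_a.ndim != 1 or hap_a.size < 2:
        raise ValueError("haplotype vectors must be equal-length 1-D with >= 2 entries")
    keep = ~(np.isnan(hap_a) | np.isnan(hap_b))
    hap_a, hap_b = hap_a[keep], hap_b[keep]
    if hap_a.size < 2:
        raise ValueError("fewer than two complete haplotype pairs")
    p_a = float(hap_a.mean())
    p_b = float(hap_b.mean())
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise LdUndefinedError("monomorphic SNP: LD undefined")
    p_ab = float((hap_a * hap_b).mean())
    return p_a, p_b, p_ab


def estimate_haplotype_freqs(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[float, float, float]:
    """EM estimate of (p_A, p_B, p_AB) from unphased dosage vectors.

    Dosages are alt-allele counts in {0, 1, 2}; pairs with a missing value
    (NaN) are dropped (pairwise complete-case).  Allele frequencies are
    fully observed, so the EM has a single free parameter, the AB
    haplotype frequency, initialised at linkage equilibrium.  Only double
    heterozygotes are phase-ambiguous; their expected AB/ab vs Ab/aB split
    is recomputed each iteration until ``p_AB`` moves by less than ``tol``.

    Raises
    ------
    LdUndefinedError
        If either SNP is monomorphic among the complete cases.
    """
    geno_a = np.asarray(geno_a, dtype=float)
    geno_b = np.asarray(geno_b, dtype=float)
    if geno_a.shape != geno_b.shape or geno_a.ndim != 1 or geno_a.size < 2:
        raise ValueError("dosage vectors must be equal-length 1-D with >= 2 entries")
    keep = ~(np.isnan(geno_a) | np.isnan(geno_b))
    geno_a, geno_b = geno_a[keep], geno_b[keep]
    n = geno_a.size
    if n < 2:
        raise ValueError("fewer than two complete genotype pairs")
    for name, g in (("first", geno_a), ("second", geno_b)):
        bad = ~np.isin(g, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError(f"{name} dosage vector contains values outside {{0,1,2}}")

    # 3x3 genotype table
    counts = np.zeros((3, 3), dtype=float)
    for i, j in zip(geno_a.astype(int), geno_b.astype(int)):
        counts[i, j] += 1

    p_a = float(geno_a.sum()) / (2 * n)
    p_b = float(geno_b.sum()) / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise LdUndefinedError("monomorphic SNP: LD undefined")

    # unambiguous haplotype counts (double hets excluded)
    n_ab = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    n_Ab = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    n_aB = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    n_00 = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    n_dh = counts[1, 1]

    p_ab = p_a * p_b  # equilibrium start biases ties toward small |D|
    for _ in range(max_iter):
        f_ab = p_ab
        f_Ab = p_a - p_ab
        f_aB = p_b - p_ab
        f_00 = 1.0 - p_a - p_b + p_ab
        denom = f_ab * f_00 + f_Ab * f_aB
        frac = 0.5 if denom <= 0 else f_ab * f_00 / denom
        new = (n_ab + frac * n_dh) / (2 * n)
        # respect Frechet bounds against numeric drift
        new = min(max(new, max(0.0, p_a + p_b - 1.0)), min(p_a, p_b))
        if abs(new - p_ab) < tol:
            p_ab = new
            break
        p_ab = new
    return p_a, p_b, float(p_ab)


def ld_pair(
    p_a: float, p_b: float, p_ab: float, snp_a: str = "a", snp_b: str = "b"
) -> LdPair:
    """Compute D, D' and r2 from a frequency triple.

    D_max is min(p_A q_B, q_A p_B) for D > 0 and min(p_A p_B, q_A q_B)
    for D < 0; D = 0 yields D' = r2 = 0.
    """
    for name, p in (("p_a", p_a), ("p_b", p_b), ("p_ab", p_ab)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise LdUndefinedError("monomorphic SNP: LD undefined")
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if not lo - 1e-12 <= p_ab <= hi + 1e-12:
        raise ValueError(f"p_ab={p_ab} violates Frechet bounds [{lo}, {hi}]")
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, q_a * q_b)
    else:
        d_max = 1.0
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * q_a * p_b * q_b)
    return LdPair(
        snp_a=snp_a,
        snp_b=snp_b,
        p_a=p_a,
        p_b=p_b,
        p_ab=p_ab,
        d=d,
        d_prime=min(d_prime, 1.0),
        r2=min(r2, 1.0),
    )


def _window_pairs(snps: list[Snp], window_bp: int) -> list[tuple[Snp, Snp]]:
    out = []
    for a, b in itertools.combinations(snps, 2):
        if a.chrom == b.chrom and abs(a.pos - b.pos) <= window_bp:
            out.append((a, b))
    return out


def ld_pairs_from_haplotypes(
    snps: list[Snp],
    haplotypes: np.ndarray,
    snp_ids: list[str],
    window_bp: int = 500_000,
) -> dict[frozenset, LdPair | None]:
    """All within-window same-chromosome LdPairs from a phased 2n x m matrix.

    Monomorphic pairs are stored as ``None`` (present but undefined) so
    that :func:`collapse_blocks` can distinguish "no information" from a
    genuinely missing entry.
    """
    col = {s: i for i, s in enumerate(snp_ids)}
    out: dict[frozenset, LdPair | None] = {}
    for a, b in _window_pairs(snps, window_bp):
        key = frozenset((a.rsid, b.rsid))
        try:
            freqs = haplotype_freqs_phased(haplotypes[:, col[a.rsid]], haplotypes[:, col[b.rsid]])
            out[key] = ld_pair(*freqs, snp_a=a.rsid, snp_b=b.rsid)
        except LdUndefinedError:
            out[key] = None
    return out


def ld_pairs_from_genotypes(
    snps: list[Snp],
    dosages: np.ndarray,
    snp_ids: list[str],
    window_bp: int = 500_000,
) -> dict[frozenset, LdPair | None]:
    """As :func:`ld_pairs_from_haplotypes` but via EM on unphased dosages."""
    col = {s: i for i, s in enumerate(snp_ids)}
    out: dict[frozenset, LdPair | None] = {}
    for a, b in _window_pairs(snps, window_bp):
        key = frozenset((a.rsid, b.rsid))
        try:
            freqs = estimate_haplotype_freqs(dosages[:, col[a.rsid]], dosages[:, col[b.rsid]])
            out[key] = ld_pair(*freqs, snp_a=a.rsid, snp_b=b.rsid)
        except LdUndefinedError:
            out[key] = None
    return out


def collapse_blocks(
    snps: list[Snp],
    ld: dict[frozenset, LdPair | None],
    r2_min: float = 0.8,
    dprime_min: float = 0.8,
    window_bp: int = 500_000,
) -> list[Locus]:
    """Partition SNPs into haplotype-block loci.

    Two SNPs are linked when their pair reaches ``r2 >= r2_min`` OR
    ``d_prime >= dprime_min``; loci are the connected components of the
    link graph, so the 0.8-threshold relation is closed transitively.
    Cross-chromosome merging cannot occur because LD is only defined for
    same-chromosome pairs within the window.

    Raises
    ------
    MissingLdError
        If a same-chromosome pair within ``window_bp`` has no entry in
        ``ld`` (an entry of ``None`` -- undefined LD -- is acceptable and
        contributes no edge).
    """
    if not 0.0 <= r2_min <= 1.0 or not 0.0 <= dprime_min <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    parent = {s.rsid: s.rsid for s in snps}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in _window_pairs(snps, window_bp):
        key = frozenset((a.rsid, b.rsid))
        if key not in ld:
            raise MissingLdError(
                f"no LD entry for same-chromosome pair {a.rsid}/{b.rsid} within window"
            )
        pair = ld[key]
        if pair is None:
            continue
        if pair.r2 >= r2_min or pair.d_prime >= dprime_min:
            parent[find(a.rsid)] = find(b.rsid)

    groups: dict[str, list[Snp]] = {}
    for s in snps:
        groups.setdefault(find(s.rsid), []).append(s)

    loci = []
    for members in groups.values():
        members = sorted(members, key=lambda s: (s.chrom, s.pos, s.rsid))
        chrom = members[0].chrom
        start = min(s.pos for s in members)
        end = max(s.pos for s in members)
        loci.append(
            Locus(
                locus_id=f"{chrom}:{start}-{end}",
                chrom=chrom,
                start=start,
                end=end,
                member_snps=[s.rsid for s in members],
                gwas_flag=any(s.gwas_flag for s in members),
            )
        )
    loci.sort(key=lambda l: (str(l.chrom), l.start if l.start is not None else 0, l.locus_id))
    return loci


def name_locus(
    locus: Locus, annotation: list[tuple[str, str, int, int]]
) -> str:
    """Name a locus after the genes overlapping its span.

    ``annotation`` rows are (gene_name, chrom, start, end), 1-based
    inclusive.  Overlapping gene names are joined with "/" in genomic
    order; a locus overlapping no gene keeps its coordinate-style id.
    The locus's ``gene_labels`` and ``locus_id`` are updated in place and
    the id returned.
    """
    if locus.start is None or locus.end is None:
        return locus.locus_id
    hits = [
        (start, end, name)
        for name, chrom, start, end in annotation
        if str(chrom) == str(locus.chrom) and start <= locus.end and end >= locus.start
    ]
    hits.sort()
    names = []
    for _, _, name in hits:
        if name not in names:  # a gene listed twice should not repeat
            names.append(name)
    if names:
        locus.gene_labels = names
        locus.locus_id = "/".join(names)
    else:
        locus.locus_id = f"{locus.chrom}:{locus.start}-{locus.end}"
    return locus.locus_id
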