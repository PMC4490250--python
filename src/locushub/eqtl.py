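"""Per-population Spearman eQTL testing with a cross-population verdict.

A SNP-probe pair is declared significant when the association replicates
(p < 0.05 in at least three testable populations) or is very strong in a
single population (p < 0.001).  No further multiple-testing correction is
applied: the compound rule is itself the replication filter.  An optional
Benjamini-Hochberg column can be attached to result tables for reporting,
but it never feeds the verdict.

Spearman rho uses average ranks (tie-corrected).  The two-sided p-value
is computed by exhaustive permutation enumeration for n <= 9 and by the
usual t-distribution approximation for larger n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UntestableAssociationError",
    "PopulationStat",
    "EqtlResult",
    "spearman_assoc",
    "compound_verdict",
    "classify_cis_trans",
    "scan",
    "bh_adjust",
]

MIN_SAMPLES = 5
EXACT_PERMUTATION_MAX_N = 9


class UntestableAssociationError(ValueError):
    """The association cannot be tested (constant vector or n too small).

    Deliberately not reported as p = 1: an untestable population carries
    no evidence either way and must be excluded from the verdict count.
    """


@dataclass(frozen=True)
class PopulationStat:
    population: str
    rho: float | None
    p: float | None
    testable: bool


@dataclass
class EqtlResult:
    """One SNP-probe pair: per-population statistics plus the verdict."""

    snp_id: str
    probe_id: str
    per_population: list[PopulationStat]
    verdict: str  # significant | not_significant | untestable
    rule_fired: str  # replication | single_pop | none
    cis_trans: str = "unclassified"  # cis | trans | unclassified


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rho_from_ranks(ra: np.ndarray, rb: np.ndarray) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = math.sqrt(float(ra @ ra) * float(rb @ rb))
    if denom == 0.0:
        raise UntestableAssociationError("constant ranks")
    return float(ra @ rb) / denom


def _exact_permutation_p(ra: np.ndarray, rb: np.ndarray, rho_obs: float) -> float:
    """Two-sided p over all n! permutations of one rank vector.

    Permutations whose |rho| matches |rho_obs| to within 1e-12 count as
    at-least-as-extreme (ties included, so p > 0 always).
    """
    n = ra.size
    perms = np.array(list(itertools.permutations(range(n))))
    rb_perm = rb[perms]  # (n!, n)
    ra_c = ra - ra.mean()
    rb_c = rb_perm - rb_perm.mean(axis=1, keepdims=True)
    num = rb_c @ ra_c
    denom = np.sqrt(float(ra_c @ ra_c) * (rb_c * rb_c).sum(axis=1))
    rhos = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    count = int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return count / len(perms)


def spearman_assoc(dosage: np.ndarray, expression: np.ndarray) -> tuple[float, float]:
    """Spearman rank association between a dosage and an expression vector.

    Missing values are removed pairwise (complete case).  Returns
    ``(rho, p)`` with a two-sided p-value: exact permutation enumeration
    for n <= 9, t-approximation with df = n - 2 otherwise.

    Raises
    ------
    UntestableAssociationError
        If fewer than 5 complete pairs remain or either vector is
        constant.
    """
    dosage = np.asarray(dosage, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if dosage.shape != expression.shape or dosage.ndim != 1:
        raise ValueError("dosage and expression must be equal-length 1-D vectors")
    keep = ~(np.isnan(dosage) | np.isnan(expression))
    dosage, expression = dosage[keep], expression[keep]
    n = dosage.size
    if n < MIN_SAMPLES:
        raise UntestableAssociationError(f"only {n} complete pairs (need >= {MIN_SAMPLES})")
    if np.all(dosage == dosage[0]):
        raise UntestableAssociationError("dosage is constant")
    if np.all(expression == expression[0]):
        raise UntestableAssociationError("expression is constant")
    ra, rb = _rank(dosage), _rank(expression)
    rho = _rho_from_ranks(ra, rb)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(ra, rb, rho)
    else:
        r2 = min(rho * rho, 1.0)
        if r2 >= 1.0:
            p = 0.0
        else:
            t = abs(rho) * math.sqrt((n - 2) / (1.0 - r2))
            p = 2.0 * float(stats.t.sf(t, df=n - 2))
    return rho, min(p, 1.0)


def compound_verdict(
    p_values: list[float],
    alpha_rep: float = 0.05,
    k_rep: int = 3,
    alpha_single: float = 0.001,
) -> tuple[str, str]:
    """Cross-population significance rule.

    ``p_values`` holds only the testable populations' p-values.  The pair
    is significant when at least ``k_rep`` populations reach
    ``p < alpha_rep`` (rule ``replication``) or any single population
    reaches ``p < alpha_single`` (rule ``single_pop``); replication takes
    precedence when both hold.  An empty list is untestable.
    """
    ps = [float(p) for p in p_values]
    if not ps:
        return "untestable", "none"
    for p in ps:
        if not (0.0 <= p <= 1.0) or math.isnan(p):
            raise ValueError(f"p-value {p} outside [0, 1]")
    if sum(p < alpha_rep for p in ps) >= k_rep:
        return "significant", "replication"
    if min(ps) < alpha_single:
        return "significant", "single_pop"
    return "not_significant", "none"


def classify_cis_trans(
    snp_chrom: str,
    snp_pos: int,
    probe_chrom: str | None,
    probe_start: int | None,
    probe_end: int | None = None,
    cis_window: int = 1_000_000,
) -> str:
    """Label a SNP-probe pair cis or trans.

    Trans means a different chromosome or a distance greater than
    ``cis_window`` (1 Mb default) from the SNP to the nearest edge of the
    probe's interval; a distance exactly equal to the window is cis.
    A probe without a genomic location is ``unclassified``.
    """
    if probe_chrom is None or probe_start is None:
        return "unclassified"
    if probe_end is None:
        probe_end = probe_start
    if str(snp_chrom) != str(probe_chrom):
        return "trans"
    if probe_start <= snp_pos <= probe_end:
        return "cis"
    dist = min(abs(snp_pos - probe_start), abs(snp_pos - probe_end))
    return "cis" if dist <= cis_window else "trans"


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reporting only)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def scan(
    panels: dict[str, pd.DataFrame],
    expression_sets: dict[str, pd.DataFrame],
    pairs: list[tuple[str, str]] | None = None,
    *,
    snp_positions: dict[str, tuple[str, int]] | None = None,
    probe_positions: dict[str, tuple[str, int, int]] | None = None,
    alpha_rep: float = 0.05,
    k_rep: int = 3,
    alpha_single: float = 0.001,
    cis_window: int = 1_000_000,
) -> list[EqtlResult]:
    """Run the per-population Spearman scan and compound verdict.

    Parameters
    ----------
    panels
        Per-population dosage DataFrames (samples x SNPs, index = sample
        ids).
    expression_sets
        Per-population expression DataFrames (samples x probes).
    pairs
        SNP-probe pairs to test; ``None`` tests the full cross product.
    snp_positions, probe_positions
        Optional genomic locations used to classify cis vs trans.

    Samples are aligned by id within each population; a population where
    the SNP is monomorphic (or too few shared samples remain) is marked
    untestable and excluded from the verdict count.  If no population
    shares any samples between genotypes and expression, that is an
    error: the inputs cannot belong to the same cohort.
    """
    pops = sorted(set(panels) & set(expression_sets))
    if not pops:
        raise ValueError("no population present in both panels and expression sets")

    aligned = {}
    any_shared = False
    for pop in pops:
        shared = panels[pop].index.intersection(expression_sets[pop].index)
        if len(shared):
            any_shared = True
        aligned[pop] = (
            panels[pop].loc[shared],
            expression_sets[pop].loc[shared],
        )
    if not any_shared:
        raise ValueError("no shared sample ids between genotype and expression in any population")

    if pairs is None:
        snp_ids = sorted(set().union(*(set(panels[p].columns) for p in pops)))
        probe_ids = sorted(set().union(*(set(expression_sets[p].columns) for p in pops)))
        pairs = [(s, pr) for s in snp_ids for pr in probe_ids]

    # pull raw arrays once: per-pair pandas indexing dominates runtime otherwise
    arrays = {}
    for pop in pops:
        geno, expr = aligned[pop]
        arrays[pop] = (
            {s: geno[s].to_numpy(dtype=float) for s in geno.columns},
            {pr: expr[pr].to_numpy(dtype=float) for pr in expr.columns},
        )

    results = []
    for snp_id, probe_id in pairs:
        stats_out = []
        p_values = []
        for pop in pops:
            geno_cols, expr_cols = arrays[pop]
            if snp_id not in geno_cols or probe_id not in expr_cols:
                continue
            try:
                rho, p = spearman_assoc(geno_cols[snp_id], expr_cols[probe_id])
            except UntestableAssociationError:
                stats_out.append(PopulationStat(pop, None, None, False))
                continue
            stats_out.append(PopulationStat(pop, rho, p, True))
            p_values.append(p)
        verdict, rule = compound_verdict(
            p_values, alpha_rep=alpha_rep, k_rep=k_rep, alpha_single=alpha_single
        )
        cis_trans = "unclassified"
        if snp_positions and probe_positions and snp_id in snp_positions:
            loc = probe_positions.get(probe_id)
            chrom, pos = snp_positions[snp_id]
            if loc is not None:
                cis_trans = classify_cis_trans(chrom, pos, *loc, cis_window=cis_window)
        results.append(
            EqtlResult(
                snp_id=snp_id,
                probe_id=probe_id,
                per_population=stats_out,
                verdict=verdict,
                rule_fired=rule,
                cis_trans=cis_trans,
            )
        )
    return results
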