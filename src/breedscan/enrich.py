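"""Interval-based gene-set enrichment with matched permutations, plus
Fisher combination of GWAS and RRV enrichment against an empirical
cross-breed background.

The enrichment statistic for a set is the number of query intervals
that overlap at least one of the set's genes.  Null interval sets are
placed on the SNP-covered genome, each placement matched to one of the
original intervals by physical length, contained-SNP count, and
contained-gene count, so the test is conditional on the interval
geometry produced by LD clumping rather than assuming uniform gene
density.  Empirical p-values use the add-one rule and are never exactly
zero; the experiment-wide correction is the min-p permutation method on
the same replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCatalog, IntervalSet

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# matched-placement machinery
# ----------------------------------------------------------------------

def _gene_overlap_counts(chrom, a, b, genes_by_chrom):
    """Number of genes overlapping [a, b] for vectors a, b on one chrom.

    Uses #(start <= b) - #(end < a) on coordinate-sorted gene arrays.
    """
    if chrom not in genes_by_chrom:
        return np.zeros(len(a), dtype=np.int64)
    starts, ends = genes_by_chrom[chrom]
    return (
        np.searchsorted(starts, b, side="right")
        - np.searchsorted(ends, a, side="left")
    )


def _genes_by_chrom(gene_map: pd.DataFrame, members=None):
    out = {}
    gm = gene_map if members is None else gene_map.loc[list(members)]
    for chrom, sub in gm.groupby("chrom"):
        out[chrom] = (
            np.sort(sub["start_bp"].to_numpy()),
            np.sort(sub["end_bp"].to_numpy()),
        )
    return out


@dataclass
class _Candidates:
    """All matched placements for one query interval."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray


def _enumerate_candidates(
    length, n_snps, n_genes, snp_pos_by_chrom, all_genes,
    length_tol, snp_tol, gene_tol,
):
    """Every SNP-anchored window matching one interval's geometry.

    A placement spans k' consecutive SNPs (k' within the SNP-count
    tolerance), starts and ends at SNP positions, and must match the
    original physical length and overlapping-gene count within
    tolerance.
    """
    k_lo = max(2, int(np.ceil(n_snps * (1 - snp_tol))))
    k_hi = int(np.floor(n_snps * (1 + snp_tol)))
    len_lo, len_hi = length * (1 - length_tol), length * (1 + length_tol)
    chroms_out, starts_out, ends_out = [], [], []
    for chrom, pos in snp_pos_by_chrom.items():
        m = len(pos)
        for k in range(k_lo, k_hi + 1):
            if k > m:
                continue
            a = pos[: m - k + 1]
            b = pos[k - 1:]
            span = b - a + 1
            ok = (span >= len_lo) & (span <= len_hi)
            if not ok.any():
                continue
            a_ok, b_ok = a[ok], b[ok]
            gcount = _gene_overlap_counts(chrom, a_ok, b_ok, all_genes)
            tol = gene_tol if n_genes <= 10 else max(gene_tol, int(round(0.2 * n_genes)))
            gok = np.abs(gcount - n_genes) <= tol
            if gok.any():
                chroms_out.append(np.full(gok.sum(), chrom, dtype=object))
                starts_out.append(a_ok[gok])
                ends_out.append(b_ok[gok])
    if not chroms_out:
        return None
    return _Candidates(
        np.concatenate(chroms_out), np.concatenate(starts_out), np.concatenate(ends_out)
    )


@dataclass
class EnrichmentResult:
    """Per-set empirical enrichment over matched random interval sets."""

    table: pd.DataFrame          # set-indexed: overlap, p, p_corr
    n_permutations: int
    matching: dict
    null_overlap: np.ndarray = None     # (n_perm, n_sets) null statistics


def interval_set_enrichment(
    intervals: IntervalSet,
    catalog: GeneSetCatalog,
    snp_map: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
    length_tol: float = 0.2,
    snp_tol: float = 0.2,
    gene_tol: int = 1,
    max_relax: int = 5,
) -> EnrichmentResult:
    """Empirical gene-set enrichment of a query interval set.

    ``snp_map`` needs columns ``chrom``/``bp`` (a ``GenotypeDataset.snps``
    frame works).  For each replicate, every query interval is replaced
    by a random placement matched on length (within ``length_tol``),
    SNP count (within ``snp_tol``) and gene count (within ``gene_tol``,
    widened proportionally for gene-rich intervals); the per-set
    statistic is the number of placements hitting >= 1 set gene.  When
    an interval has no admissible placement the tolerances are relaxed
    stepwise (x1.5, up to ``max_relax`` times) with a warning.
    """
    rng = np.random.default_rng(seed)
    snp_pos_by_chrom = {
        chrom: np.sort(sub["bp"].to_numpy())
        for chrom, sub in snp_map.groupby("chrom")
    }
    all_genes = _genes_by_chrom(catalog.gene_map)
    set_names = list(catalog.sets)
    set_genes = {name: _genes_by_chrom(catalog.gene_map, catalog.sets[name])
                 for name in set_names}

    ivs = intervals.sorted()
    n_int = len(ivs)
    if n_int == 0:
        raise ValueError("empty interval set")

    # observed statistic
    observed = np.zeros(len(set_names), dtype=np.int64)
    for rec in ivs:
        for s_i, name in enumerate(set_names):
            hit = _gene_overlap_counts(
                rec.chrom, np.array([rec.start_bp]), np.array([rec.end_bp]),
                set_genes[name],
            )[0] > 0
            observed[s_i] += int(hit)

    # candidate placements per interval + per-candidate set-hit matrix
    hit_mats = []
    for rec in ivs:
        length = rec.end_bp - rec.start_bp + 1
        pos = snp_pos_by_chrom.get(rec.chrom, np.array([], dtype=np.int64))
        k = int(((pos >= rec.start_bp) & (pos <= rec.end_bp)).sum())
        k = max(k, 2)
        g = _gene_overlap_counts(
            rec.chrom, np.array([rec.start_bp]), np.array([rec.end_bp]), all_genes
        )[0]
        lt, st, gt = length_tol, snp_tol, gene_tol
        cand = None
        for attempt in range(max_relax + 1):
            cand = _enumerate_candidates(
                length, k, g, snp_pos_by_chrom, all_genes, lt, st, gt
            )
            if cand is not None:
                break
            lt, st, gt = lt * 1.5, st * 1.5, gt + 1
            warnings.warn(
                f"no matched placement for interval {rec.chrom}:{rec.start_bp}-"
                f"{rec.end_bp}; relaxing tolerances (step {attempt + 1})"
            )
        if cand is None:
            raise RuntimeError("matching failed even after relaxation")
        hits = np.zeros((len(cand.start), len(set_names)), dtype=bool)
        for s_i, name in enumerate(set_names):
            for chrom in np.unique(cand.chrom):
                mask = cand.chrom == chrom
                hits[mask, s_i] = _gene_overlap_counts(
                    chrom, cand.start[mask], cand.end[mask], set_genes[name]
                ) > 0
        hit_mats.append(hits)

    # null statistics: each replicate draws one placement per interval
    null_stats = np.zeros((n_perm, len(set_names)), dtype=np.int32)
    for hits in hit_mats:
        idx = rng.integers(0, hits.shape[0], size=n_perm)
        null_stats += hits[idx].astype(np.int32)

    p = (1 + (null_stats >= observed[None, :]).sum(axis=0)) / (n_perm + 1)

    # min-p correction sharing the same replicates
    p_reps = np.empty((n_perm, len(set_names)))
    for s_i in range(len(set_names)):
        col = np.sort(null_stats[:, s_i])
        ge = n_perm - np.searchsorted(col, null_stats[:, s_i], side="left")
        p_reps[:, s_i] = (1 + ge) / (n_perm + 1)
    min_p = p_reps.min(axis=1)
    p_corr = np.array([(1 + (min_p <= pv).sum()) / (n_perm + 1) for pv in p])
    p_corr = np.maximum(p_corr, p)

    table = pd.DataFrame(
        {"overlap": observed, "p": p, "p_corr": p_corr},
        index=pd.Index(set_names, name="set"),
    )
    return EnrichmentResult(
        table, n_perm,
        {"length_tol": length_tol, "snp_tol": snp_tol, "gene_tol": gene_tol},
        null_overlap=null_stats,
    )


# ----------------------------------------------------------------------
# Fisher combination
# ----------------------------------------------------------------------

def fisher_combined(p_gwas: float, p_rrv: float, p_floor: float | None = None):
    """Fisher's combined probability of two independent enrichment tests.

    ``X2 = -2 (ln p_gwas + ln p_rrv)`` referred to a chi-square with 4
    degrees of freedom.  Zero inputs are clamped to ``p_floor`` (or
    machine tiny) with a warning, since empirical p-values should never
    be exactly zero under the add-one rule.
    """
    ps = []
    for p in (p_gwas, p_rrv):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            floor = p_floor if p_floor is not None else np.finfo(float).tiny
            warnings.warn(f"p=0 clamped to {floor}")
            p = floor
        ps.append(p)
    x2 = -2.0 * (np.log(ps[0]) + np.log(ps[1]))
    return float(x2), float(stats.chi2.sf(x2, df=4))


@dataclass
class CombinedEnrichment:
    """Observed GWAS+RRV Fisher combinations against the cross-breed
    empirical background."""

    table: pd.DataFrame          # (gwas_breed, set)-indexed
    background: np.ndarray       # pooled background combined p-values
    quantile: float


def combined_background(
    gwas_ps: dict,
    own_rrv_ps: dict,
    panel_rrv_ps: dict,
    quantile: float = 0.99,
) -> CombinedEnrichment:
    """Score observed GWAS x own-RRV combinations against a background of
    GWAS x reference-breed-RRV combinations.

    ``gwas_ps`` and ``own_rrv_ps`` map GWAS breed name to a per-set
    p-value Series; ``panel_rrv_ps`` maps each reference breed to the
    same.  The background pools, over every set and every (GWAS breed,
    reference breed) pair, the Fisher-combined p of the GWAS enrichment
    with the reference breed's RRV enrichment.  Each observed
    combination is reported with its quantile in that pooled background
    (fraction of background combinations it beats); sets beyond
    ``quantile`` are flagged inflated.
    """
    if not gwas_ps:
        raise ValueError("need at least one GWAS breed")
    if len(panel_rrv_ps) < 2:
        raise ValueError("need at least two reference breeds")
    background = []
    for g_breed, g_series in gwas_ps.items():
        for r_breed, r_series in panel_rrv_ps.items():
            shared = g_series.index.intersection(r_series.index)
            missing = g_series.index.difference(r_series.index)
            if len(missing):
                log.info("background pair (%s, %s): %d sets missing, dropped",
                         g_breed, r_breed, len(missing))
            for name in shared:
                _, cp = fisher_combined(float(g_series[name]), float(r_series[name]))
                background.append(cp)
    background = np.sort(np.array(background))

    rows = []
    for g_breed, g_series in gwas_ps.items():
        r_series = own_rrv_ps[g_breed]
        for name in g_series.index.intersection(r_series.index):
            x2, cp = fisher_combined(float(g_series[name]), float(r_series[name]))
            # extremeness quantile: fraction of background combinations at
            # least as non-significant (p >= observed)
            n_below = np.searchsorted(background, cp, side="left")
            q = (len(background) - n_below) / len(background)
            rows.append((g_breed, name, float(g_series[name]), float(r_series[name]),
                         x2, cp, q, bool(q > quantile)))
    table = pd.DataFrame(
        rows,
        columns=["gwas_breed", "set", "p_gwas", "p_rrv", "x2", "p_combined",
                 "background_quantile", "inflated"],
    ).set_index(["gwas_breed", "set"])
    return CombinedEnrichment(table, background, quantile)
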