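"""Fixed-region detection, reduced-relative-variability (RRV) scans
against a multi-breed panel, and cross-breed risk-allele fixation checks.

Breeds carry large runs of near-fixed SNPs — products of founder
bottlenecks and artificial selection — which hide risk alleles from
association testing.  These scans surface such regions: maximal runs of
low-MAF SNPs above a length cutoff, and 150-kb windows whose expected
heterozygosity is in the lowest percentile relative to a reference
panel of other breeds.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import GenotypeDataset, IntervalSet


def fixed_regions(
    dataset: GenotypeDataset,
    maf_threshold: float = 0.05,
    min_length_bp: int = 250_000,
):
    """Maximal runs of consecutive SNPs with MAF below the threshold.

    A run is reported when (last bp - first bp) >= ``min_length_bp``.
    Returns ``(intervals, genome_fraction)``; the fraction is relative
    to the SNP-covered span of the map.
    """
    maf = dataset.maf()
    low = np.nan_to_num(maf, nan=0.0) < maf_threshold
    chroms = dataset.snps["chrom"].to_numpy()
    bps = dataset.snps["bp"].to_numpy()
    records = []
    genome_bp = 0
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        pos = bps[idx]
        genome_bp += int(pos.max() - pos.min() + 1) if len(pos) else 0
        flags = low[idx].astype(int)
        edges = np.diff(np.concatenate([[0], flags, [0]]))
        run_starts = np.where(edges == 1)[0]
        run_ends = np.where(edges == -1)[0] - 1
        for s, e in zip(run_starts, run_ends):
            if pos[e] - pos[s] >= min_length_bp:
                records.append((chrom, int(pos[s]), int(pos[e]), "fixed", np.nan))
    intervals = IntervalSet.from_records(records)
    fraction = intervals.total_bp() / genome_bp if genome_bp else 0.0
    return intervals, fraction


def _window_heterozygosity(
    dataset: GenotypeDataset, window_bp: int
) -> pd.DataFrame:
    """Mean expected heterozygosity 2p(1-p) per non-overlapping window.

    Windows tile each chromosome from position 1 in ``window_bp`` steps.
    """
    p = dataset.allele1_freq()
    het = 2.0 * p * (1.0 - p)
    chroms = dataset.snps["chrom"].to_numpy()
    bps = dataset.snps["bp"].to_numpy()
    win = (bps - 1) // window_bp
    df = pd.DataFrame({"chrom": chroms, "win": win, "het": het})
    grouped = df.groupby(["chrom", "win"], observed=True)["het"].agg(["mean", "count"])
    grouped = grouped.reset_index()
    grouped["start_bp"] = grouped["win"] * window_bp + 1
    grouped["end_bp"] = (grouped["win"] + 1) * window_bp
    return grouped.rename(columns={"mean": "het_mean", "count": "n_snps"})


def rrv_scan(
    target: GenotypeDataset,
    panel: list,
    window_bp: int = 150_000,
    quantile: float = 0.01,
    min_snps: int = 10,
    panel_floor: float = 1e-4,
):
    """Windows of reduced variability in the target breed relative to a panel.

    Per window the statistic is mean expected heterozygosity in the
    target divided by the panel-mean of the same quantity (floored at
    ``panel_floor`` so windows fixed in every breed score ~1 rather than
    blowing up).  The RRV set is the ``ceil(quantile * retained)``
    lowest-ratio windows, ties broken by (chrom, start).

    Returns ``(table, rrv_intervals)`` where the table has one row per
    retained window.
    """
    if not panel:
        raise ValueError("reference panel is empty")
    tgt = _window_heterozygosity(target, window_bp)
    tgt = tgt[tgt["n_snps"] >= min_snps].copy()
    panel_het = None
    for breed_ds in panel:
        w = _window_heterozygosity(breed_ds, window_bp)[["chrom", "win", "het_mean"]]
        w = w.rename(columns={"het_mean": "panel_het"})
        if panel_het is None:
            panel_het = w
        else:
            panel_het = panel_het.merge(w, on=["chrom", "win"], how="outer",
                                        suffixes=("", "_x"))
            cols = [c for c in panel_het.columns if c.startswith("panel_het")]
            panel_het["panel_het"] = panel_het[cols].mean(axis=1)
            panel_het = panel_het[["chrom", "win", "panel_het"]]
    table = tgt.merge(panel_het, on=["chrom", "win"], how="inner")
    # floor both sides: a window fixed in every breed scores ~1 rather
    # than 0/0 or an infinite ratio
    table["ratio"] = (
        np.maximum(table["het_mean"], panel_floor)
        / np.maximum(table["panel_het"], panel_floor)
    )
    table = table.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)
    table["rank_pct"] = table["ratio"].rank(method="first", pct=True)
    n_rrv = math.ceil(quantile * len(table))
    picked = table.sort_values(
        ["ratio", "chrom", "start_bp"], kind="stable"
    ).head(n_rrv)
    table["is_rrv"] = table.index.isin(picked.index)
    rrv = IntervalSet.from_records(
        [
            (row.chrom, int(row.start_bp), int(row.end_bp), "rrv", float(row.ratio))
            for row in picked.itertuples()
        ]
    ).sorted()
    cols = ["chrom", "start_bp", "end_bp", "n_snps", "het_mean",
            "panel_het", "ratio", "rank_pct", "is_rrv"]
    return table[cols], rrv


def fixation_check(
    regions: list,
    other_breeds: dict,
    freq_threshold: float = 0.95,
) -> pd.DataFrame:
    """Risk-allele frequency of each region's peak SNP in other breeds.

    ``regions`` are :class:`~breedscan.assoc.AssociatedRegion` objects
    (peak SNP + risk allele); ``other_breeds`` maps breed name to
    :class:`GenotypeDataset`.  A region is flagged fixed in a breed when
    the risk-allele frequency strictly exceeds ``freq_threshold``; a
    missing peak SNP yields NaN frequency and no flag.
    """
    rows = []
    for reg in regions:
        for breed, ds in other_breeds.items():
            if reg.peak_snp not in ds.snps.index:
                rows.append((reg.peak_snp, breed, np.nan, False, True))
                continue
            j = ds.snps.index.get_loc(reg.peak_snp)
            p1 = ds.allele1_freq()[j]
            a1 = ds.snps["a1"].iloc[j]
            freq = p1 if reg.risk_allele == a1 else 1.0 - p1
            rows.append((reg.peak_snp, breed, float(freq), bool(freq > freq_threshold), False))
    return pd.DataFrame(
        rows, columns=["peak_snp", "breed", "risk_allele_freq", "fixed", "snp_missing"]
    )
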