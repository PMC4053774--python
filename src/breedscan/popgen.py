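"""Population-genetic primitives: GRM, inbreeding, PCA, LD decay, and
age-aware relatedness pruning of case/control cohorts."""

from __future__ import annotations

from dataclasses import dataclass
import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset, KinshipMatrix

log = logging.getLogger(__name__)


def _standardized_genotypes(dataset: GenotypeDataset):
    """Return (Z, valid, keep): per-SNP standardized dosages with missing
    set to 0, the missingness mask, and the polymorphic-SNP mask."""
    g = dataset.genotypes.astype(float)
    valid = dataset.genotypes != MISSING
    g[~valid] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (g - 2.0 * p) / np.where(keep, denom, 1.0)
    z[~valid] = 0.0
    return z[:, keep], valid[:, keep], keep


def compute_grm(dataset: GenotypeDataset) -> KinshipMatrix:
    """Genetic relationship matrix of standardized genotype cross-products.

    Entry (j, k) averages ``(x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))``
    over the SNPs non-missing in both samples; monomorphic SNPs are
    excluded from the sum.
    """
    if dataset.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    z, valid, keep = _standardized_genotypes(dataset)
    if z.shape[1] == 0:
        raise ValueError("all SNPs monomorphic; GRM undefined")
    counts = valid.astype(float) @ valid.astype(float).T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (z @ z.T) / counts
    values[counts == 0] = 0.0
    return KinshipMatrix(dataset.sample_ids, values, method="grm")


def inbreeding_coefficients(dataset: GenotypeDataset) -> pd.Series:
    """Heterozygosity-deficit inbreeding coefficient per sample.

    ``theta_j = 1 - H_obs_j / H_exp_j`` where ``H_exp_j`` sums the
    Hardy-Weinberg expectation ``2 p_i (1 - p_i)`` over the SNPs
    non-missing in sample j.  Negative values (heterozygote excess) are
    reported as-is.  Samples with no usable genotypes get NaN.
    """
    g = dataset.genotypes
    valid = g != MISSING
    gf = g.astype(float)
    gf[~valid] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        p = np.nanmean(gf, axis=0) / 2.0
    exp_het_snp = 2.0 * p * (1.0 - p)
    exp_het_snp[~np.isfinite(exp_het_snp)] = 0.0
    h_obs = ((g == 1) & valid).sum(axis=1).astype(float)
    h_exp = valid.astype(float) @ exp_het_snp
    theta = np.full(dataset.n_samples, np.nan)
    usable = h_exp > 0
    theta[usable] = 1.0 - h_obs[usable] / h_exp[usable]
    n_flagged = int((~usable).sum())
    if n_flagged:
        log.warning("%d samples had no informative genotypes; theta set to NaN", n_flagged)
    return pd.Series(theta, index=dataset.samples.index, name="theta")


def pca_top_components(kinship: KinshipMatrix, k: int):
    """Top-k principal components of the (double-centered) kinship matrix.

    Returns ``(coords, eigenvalues)`` with components ordered by
    descending eigenvalue.  Sign convention: the largest-magnitude
    loading of each component is positive.
    """
    if k > kinship.n:
        raise ValueError(f"k={k} exceeds sample count {kinship.n}")
    n = kinship.n
    j = np.eye(n) - np.ones((n, n)) / n
    centered = j @ kinship.values @ j
    eigvals, eigvecs = np.linalg.eigh(centered)
    order = np.argsort(eigvals)[::-1][:k]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for i in range(k):
        top = np.argmax(np.abs(eigvecs[:, i]))
        if eigvecs[top, i] < 0:
            eigvecs[:, i] = -eigvecs[:, i]
    coords = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))
    return pd.DataFrame(
        coords, index=pd.Index(kinship.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    ), eigvals


@dataclass
class LdProfile:
    """Binned decay of pairwise r-squared with distance for one breed."""

    bin_edges_bp: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    breed: str = ""
    r2_threshold: float = 0.2

    @property
    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_bp[:-1] + self.bin_edges_bp[1:])

    @property
    def decay_distance(self) -> float:
        """Midpoint of the first distance bin whose mean r2 drops below
        the threshold.  +inf when LD stays above the threshold over the
        whole measured range; NaN for an empty profile."""
        finite = np.isfinite(self.mean_r2)
        if not finite.any():
            return float("nan")
        below = np.where(finite & (self.mean_r2 < self.r2_threshold))[0]
        return float(self.bin_midpoints[below[0]]) if len(below) else float("inf")


def _imputed_dosages(dataset: GenotypeDataset) -> np.ndarray:
    g = dataset.genotypes.astype(float)
    miss = dataset.genotypes == MISSING
    if miss.any():
        g[miss] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            means = np.nanmean(g, axis=0)
        means[~np.isfinite(means)] = 0.0
        g = np.where(np.isnan(g), means[None, :], g)
    return g


def ld_decay(
    dataset: GenotypeDataset,
    max_distance_bp: int = 3_000_000,
    bins: int = 30,
    r2_threshold: float = 0.2,
    breed: str = "",
) -> LdProfile:
    """Composite (genotype-correlation) r-squared binned by pair distance.

    Pairs are taken within ``max_distance_bp`` on the same chromosome;
    the profile is invariant to SNP ordering within a chromosome.
    """
    edges = np.linspace(0, max_distance_bp, bins + 1)
    sums = np.zeros(bins)
    counts = np.zeros(bins, dtype=np.int64)
    g = _imputed_dosages(dataset)
    chroms = dataset.snps["chrom"].to_numpy()
    bps = dataset.snps["bp"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        if len(idx) < 2:
            continue
        sub = g[:, idx]
        sd = sub.std(axis=0)
        poly = sd > 0
        sub = sub[:, poly]
        pos = bps[idx][poly]
        if sub.shape[1] < 2:
            continue
        corr = np.corrcoef(sub.T)
        r2 = corr**2
        iu, ju = np.triu_indices(sub.shape[1], k=1)
        dist = np.abs(pos[ju] - pos[iu])
        inside = dist <= max_distance_bp
        which = np.clip(np.digitize(dist[inside], edges) - 1, 0, bins - 1)
        np.add.at(sums, which, r2[iu[inside], ju[inside]])
        np.add.at(counts, which, 1)
    if counts.sum() == 0:
        warnings.warn("no qualifying SNP pairs for LD decay; empty profile")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdProfile(edges, mean_r2, counts, breed=breed, r2_threshold=r2_threshold)


def prune_related(
    dataset: GenotypeDataset,
    kinship: KinshipMatrix,
    threshold: float = 0.25,
):
    """Drop one dog from each concordant-phenotype pair that is closer
    than ``threshold``, preferring to keep the younger case and the
    older control.

    Pairs are processed greedily in descending relatedness (ties broken
    by sample-id order); a pair is acted on only if both members are
    still retained.  Discordant (case-control) pairs are never touched.
    Missing ages sort as oldest.  Returns ``(retained_ids, removal_log)``
    where the log is a DataFrame of (removed, kept, relatedness, reason).
    """
    ids = list(kinship.sample_ids)
    pheno = dataset.samples.loc[ids, "phenotype"]
    age = dataset.samples.loc[ids, "age_years"].to_numpy(dtype=float)
    k = kinship.values
    n = len(ids)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if k[i, j] > threshold and pd.notna(pheno.iloc[i]) and pheno.iloc[i] == pheno.iloc[j]:
                pairs.append((k[i, j], i, j))
    pairs.sort(key=lambda t: (-t[0], ids[t[1]], ids[t[2]]))
    removed: set = set()
    records = []
    for rel, i, j in pairs:
        if i in removed or j in removed:
            continue
        age_i = age[i] if np.isfinite(age[i]) else np.inf       # missing age = oldest
        age_j = age[j] if np.isfinite(age[j]) else np.inf
        status = pheno.iloc[i]
        if status == "case":
            # keep the younger case
            drop = i if (age_i, ids[i]) > (age_j, ids[j]) else j
            reason = "older of case pair"
        else:
            # keep the older control
            drop = i if (age_i, ids[i]) < (age_j, ids[j]) else j
            reason = "younger of control pair"
        keep = j if drop == i else i
        removed.add(drop)
        records.append((ids[drop], ids[keep], rel, reason))
    retained = [s for idx, s in enumerate(ids) if idx not in removed]
    # post-condition: no concordant pair above threshold survives
    kept_idx = [idx for idx in range(n) if idx not in removed]
    for a_pos, i in enumerate(kept_idx):
        for j in kept_idx[a_pos + 1:]:
            assert not (
                k[i, j] > threshold
                and pd.notna(pheno.iloc[i])
                and pheno.iloc[i] == pheno.iloc[j]
            ), "pruning left a concordant related pair"
    log_df = pd.DataFrame(records, columns=["removed", "kept", "relatedness", "reason"])
    return retained, log_df
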