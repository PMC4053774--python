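"""Mixed-model association scan with permutation-envelope significance.

The scan follows the two-step variance-component approximation common in
breed and livestock GWAS: a single REML fit of the polygenic null model
``y = X b + u + e`` with ``u ~ N(0, sg2 K)`` and ``e ~ N(0, se2 I)``,
then per-SNP generalized-least-squares t-tests with the covariance held
fixed.  Case/control status is analyzed as a 0/1 quantitative trait.
Genome-wide significance comes from an empirical envelope: the scan is
re-run on permuted phenotypes and per-order-statistic quantiles of the
-log10 p distribution bound the region where 95% of null QQ curves fall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import MISSING, GenotypeDataset, IntervalSet, KinshipMatrix
from .popgen import _imputed_dosages

log = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# null-model REML
# ----------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML estimates of the polygenic null model."""

    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    iterations: int
    converged: bool
    eigenvalues: np.ndarray = field(repr=False, default=None)
    eigenvectors: np.ndarray = field(repr=False, default=None)
    h2_se: float = float("nan")


def _reml_pieces(lam: float, s: np.ndarray, y_r: np.ndarray, x_r: np.ndarray):
    """Profile-REML residual sum and determinant terms at ratio lam=sg2/se2."""
    d = lam * s + 1.0
    xtdx = (x_r.T / d) @ x_r
    xtdy = (x_r.T / d) @ y_r
    beta = np.linalg.solve(xtdx, xtdy)
    resid = y_r - x_r @ beta
    rss = float(resid @ (resid / d))
    sign, logdet_x = np.linalg.slogdet(xtdx)
    return d, rss, logdet_x


def _reml_loglik(lam: float, s, y_r, x_r, n: int, p: int) -> float:
    d, rss, logdet_x = _reml_pieces(lam, s, y_r, x_r)
    if rss <= 0:
        return -np.inf
    se2 = rss / (n - p)
    return -0.5 * (
        (n - p) * np.log(2.0 * np.pi * se2)
        + np.log(d).sum()
        + logdet_x
        + (n - p)
    )


def fit_null_mixed(
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    kinship: KinshipMatrix,
    max_iter: int = 100,
) -> VarianceComponents:
    """REML fit of ``y = X b + u + e`` by spectral decomposition of K.

    ``phenotype`` is the 0/1-coded trait; ``covariates`` an optional
    ``(n, c)`` matrix (an intercept is always added).  The variance
    ratio is profiled out and optimized in one dimension, which makes
    the fit deterministic.  Negative kinship eigenvalues are floored at
    zero to keep K positive semidefinite.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    x = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        x = np.hstack([x, cov])
    p = x.shape[1]
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("covariate matrix is rank deficient")
    s, u = np.linalg.eigh(kinship.values)
    s = np.maximum(s, 0.0)                     # eigen-floor: enforce PSD
    y_r = u.T @ y
    x_r = u.T @ x

    grid = np.concatenate([[0.0], np.logspace(-5, 5, 41)])
    lls = np.array([_reml_loglik(l, s, y_r, x_r, n, p) for l in grid])
    best = int(np.nanargmax(lls))
    iterations = len(grid)
    if best == 0:
        lam_hat = 0.0
    else:
        lo = grid[max(best - 1, 0)] if best > 1 else 1e-8
        hi = grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -_reml_loglik(np.exp(t), s, y_r, x_r, n, p),
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"maxiter": max_iter},
        )
        lam_hat = float(np.exp(res.x))
        iterations += int(res.nfev)
        if -res.fun < lls[0]:                  # boundary beats interior
            lam_hat = 0.0
    ll = _reml_loglik(lam_hat, s, y_r, x_r, n, p)
    _, rss, _ = _reml_pieces(lam_hat, s, y_r, x_r)
    se2 = rss / (n - p)
    sg2 = lam_hat * se2
    h2 = sg2 / (sg2 + se2) if (sg2 + se2) > 0 else 0.0

    # curvature-based SE of h2 via the profile log-likelihood
    h2_se = _h2_curvature_se(h2, s, y_r, x_r, n, p)
    converged = bool(np.isfinite(ll))
    if not converged:
        log.warning("REML did not reach a finite optimum")
    return VarianceComponents(
        sigma2_g=sg2, sigma2_e=se2, h2=h2, loglik=ll,
        iterations=iterations, converged=converged,
        eigenvalues=s, eigenvectors=u, h2_se=h2_se,
    )


def _h2_curvature_se(h2: float, s, y_r, x_r, n: int, p: int) -> float:
    """SE from the numeric second derivative of the profile REML in h2."""

    def ll_of_h2(h):
        if h <= 0.0:
            return _reml_loglik(0.0, s, y_r, x_r, n, p)
        if h >= 1.0:
            return -np.inf
        return _reml_loglik(h / (1.0 - h), s, y_r, x_r, n, p)

    eps = 1e-3
    h = min(max(h2, eps), 1.0 - eps)
    try:
        d2 = (ll_of_h2(h + eps) - 2.0 * ll_of_h2(h) + ll_of_h2(h - eps)) / eps**2
    except np.linalg.LinAlgError:
        return float("nan")
    if not np.isfinite(d2) or d2 >= 0:
        return float("nan")
    return float(1.0 / np.sqrt(-d2))


# ----------------------------------------------------------------------
# scan
# ----------------------------------------------------------------------

@dataclass
class AssocResult:
    """Per-SNP mixed-model association statistics."""

    table: pd.DataFrame                        # snp-indexed
    covariates: list = field(default_factory=list)
    threshold_neglog10: float = float("nan")   # genome-wide envelope threshold

    def significant(self, p_max: float) -> pd.DataFrame:
        return self.table[self.table["p"] < p_max]


def _rotation(vc: VarianceComponents):
    """Whitening transform A with A Sigma A' = I for Sigma = sg2 K + se2 I."""
    d = vc.sigma2_g * vc.eigenvalues + vc.sigma2_e
    if np.any(d <= 0):
        raise ValueError("singular covariance; cannot whiten")
    return (vc.eigenvectors / np.sqrt(d)).T


def _residualize(mat: np.ndarray, x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return mat - q @ (q.T @ mat)


def _scan_stats(y_t: np.ndarray, g_t: np.ndarray, df: int):
    """Vectorized per-SNP slope t-tests in the whitened, residualized space."""
    gg = (g_t * g_t).sum(axis=0)
    gy = g_t.T @ y_t
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gy / gg
        rss = (y_t * y_t).sum() - beta * gy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return beta, se, tstat, p


def _allele_tables(dataset: GenotypeDataset, snp_idx: np.ndarray):
    """Case/control A1-allele counts per SNP (missing genotypes dropped)."""
    y = dataset.phenotype01()
    case = y == 1.0
    ctrl = y == 0.0
    g = dataset.genotypes[:, snp_idx]
    valid = g != MISSING
    gv = np.where(valid, g, 0)
    a1_case = (gv * case[:, None]).sum(axis=0).astype(float)
    tot_case = 2.0 * (valid & case[:, None]).sum(axis=0)
    a1_ctrl = (gv * ctrl[:, None]).sum(axis=0).astype(float)
    tot_ctrl = 2.0 * (valid & ctrl[:, None]).sum(axis=0)
    return a1_case, tot_case, a1_ctrl, tot_ctrl


def mixed_model_scan(
    dataset: GenotypeDataset,
    vc: VarianceComponents,
    covariates: np.ndarray | None = None,
    maf_min: float = 0.05,
    covariate_names: list | None = None,
) -> AssocResult:
    """EMMAX-style scan: GLS slope t-test per SNP with Sigma held fixed.

    Only SNPs with minor allele frequency at least ``maf_min`` are
    tested; missing genotypes are mean-imputed per SNP.  The risk allele
    is the allele enriched in cases; the reported OR is the allelic odds
    ratio from the case/control 2x2 allele table, and fA/fU are the
    risk-allele frequencies in cases and controls.
    """
    if not vc.converged:
        raise ValueError("null model did not converge; refusing to scan")
    maf = dataset.maf()
    keep = np.where(maf >= maf_min)[0]
    skipped = dataset.n_snps - len(keep)
    if skipped:
        log.info("scan skips %d SNPs below MAF %.3g (monomorphic or rare)", skipped, maf_min)
    y = dataset.phenotype01()
    if np.isnan(y).any():
        raise ValueError("missing phenotypes; subset the dataset first")
    a = _rotation(vc)
    n = dataset.n_samples
    x = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        x = np.hstack([x, cov])
    g = _imputed_dosages(dataset.subset(snp_ids=dataset.snps.index[keep]))
    y_t = _residualize(a @ y, a @ x)
    g_t = _residualize(a @ g, a @ x)
    df = n - x.shape[1] - 1
    beta, se, tstat, p = _scan_stats(y_t, g_t, df)

    a1_case, tot_case, a1_ctrl, tot_ctrl = _allele_tables(dataset, keep)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_case = a1_case / tot_case
        f_ctrl = a1_ctrl / tot_ctrl
    risk_is_a1 = beta > 0
    fa = np.where(risk_is_a1, f_case, 1.0 - f_case)
    fu = np.where(risk_is_a1, f_ctrl, 1.0 - f_ctrl)
    ra1 = np.where(risk_is_a1, a1_case, tot_case - a1_case)
    ra0 = tot_case - ra1
    ru1 = np.where(risk_is_a1, a1_ctrl, tot_ctrl - a1_ctrl)
    ru0 = tot_ctrl - ru1
    with np.errstate(invalid="ignore", divide="ignore"):
        odds = (ra1 * ru0) / (ra0 * ru1)

    snps = dataset.snps.iloc[keep]
    table = pd.DataFrame(
        {
            "chrom": snps["chrom"].to_numpy(),
            "bp": snps["bp"].to_numpy(),
            "beta": beta,
            "se": se,
            "t": tstat,
            "p": p,
            "risk_allele": np.where(risk_is_a1, snps["a1"].to_numpy(), snps["a2"].to_numpy()),
            "fA": fa,
            "fU": fu,
            "OR": odds,
        },
        index=snps.index,
    )
    return AssocResult(table, covariates=covariate_names or [])


# ----------------------------------------------------------------------
# permutation envelope
# ----------------------------------------------------------------------

@dataclass
class PermutationEnvelope:
    """Per-order-statistic empirical confidence band of -log10 p."""

    n_permutations: int
    lower: np.ndarray          # 2.5% quantile per rank (rank 0 = most extreme)
    upper: np.ndarray          # 97.5% quantile per rank
    seed: int = 0

    @property
    def threshold(self) -> float:
        """Genome-wide significance: upper envelope at the top rank."""
        return float(self.upper[0])


def permutation_envelope(
    dataset: GenotypeDataset,
    vc: VarianceComponents,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    maf_min: float = 0.05,
) -> PermutationEnvelope:
    """Empirical null envelope from scans of permuted phenotypes.

    Phenotypes are permuted ``n_perm`` times with the kinship rotation
    and covariates held fixed; for each permutation the full scan's
    sorted -log10 p values are recorded, and the envelope is the
    per-rank 2.5%/97.5% quantile band across permutations.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: envelope quantiles will be unstable")
    rng = np.random.default_rng(seed)
    y = dataset.phenotype01()
    a = _rotation(vc)
    n = dataset.n_samples
    x = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        x = np.hstack([x, cov])
    maf = dataset.maf()
    keep = np.where(maf >= maf_min)[0]
    g = _imputed_dosages(dataset.subset(snp_ids=dataset.snps.index[keep]))
    x_t = a @ x
    g_t = _residualize(a @ g, x_t)
    df = n - x.shape[1] - 1
    m = g_t.shape[1]
    neglogs = np.empty((n_perm, m))
    for r in range(n_perm):
        y_perm = y[rng.permutation(n)]
        y_t = _residualize(a @ y_perm, x_t)
        _, _, _, p = _scan_stats(y_t, g_t, df)
        neglogs[r] = np.sort(-np.log10(p))[::-1]
    lower = np.quantile(neglogs, 0.025, axis=0)
    upper = np.quantile(neglogs, 0.975, axis=0)
    return PermutationEnvelope(n_perm, lower, upper, seed=seed)


# ----------------------------------------------------------------------
# LD clumping
# ----------------------------------------------------------------------

@dataclass
class AssociatedRegion:
    """An LD-defined association region around one index SNP."""

    peak_snp: str
    peak_p: float
    chrom: str
    peak_bp: int
    wide_start: int
    wide_end: int
    narrow_start: int
    narrow_end: int
    wide_members: list
    narrow_members: list
    odds_ratio: float = float("nan")
    risk_allele: str = ""


def clump_regions(
    result: AssocResult,
    dataset: GenotypeDataset,
    p_max: float = 0.0005,
    wide_r2: float = 0.2,
    wide_window_bp: int = 5_000_000,
    narrow_r2: float = 0.8,
    narrow_window_bp: int = 1_000_000,
) -> list:
    """Two-stage LD clumping of significant SNPs into regions.

    Stage 1 groups SNPs in weak LD with each index SNP (r2 > 0.2 within
    5 Mb); stage 2 narrows to the peak of SNPs in strong LD (r2 > 0.8
    within 1 Mb).  Index SNPs are visited by ascending p (ties broken by
    chromosome and position, so output is independent of input order);
    claimed SNPs cannot seed further regions.
    """
    sig = result.table[result.table["p"] < p_max]
    sig = sig.sort_values(["p", "chrom", "bp"], kind="stable")
    if sig.empty:
        return []
    # index columns directly: the container would re-sort a subset by
    # position, desynchronizing columns from the p-ordered table
    cols = dataset.snps.index.get_indexer(sig.index)
    g = _imputed_dosages(dataset)[:, cols]
    sd = g.std(axis=0)
    centered = (g - g.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    nobs = g.shape[0]
    chroms = sig["chrom"].to_numpy()
    bps = sig["bp"].to_numpy()
    claimed = np.zeros(len(sig), dtype=bool)
    regions = []
    for i in range(len(sig)):
        if claimed[i]:
            continue
        same = (chroms == chroms[i]) & ~claimed
        near_wide = same & (np.abs(bps - bps[i]) <= wide_window_bp)
        r = (centered[:, near_wide].T @ centered[:, i]) / nobs
        r2 = r**2
        members_idx = np.where(near_wide)[0][r2 > wide_r2]
        members_idx = np.union1d(members_idx, [i])
        near_narrow = np.abs(bps[members_idx] - bps[i]) <= narrow_window_bp
        rn = (centered[:, members_idx].T @ centered[:, i]) / nobs
        narrow_idx = members_idx[near_narrow & (rn**2 > narrow_r2)]
        narrow_idx = np.union1d(narrow_idx, [i])
        claimed[members_idx] = True
        wide_ids = list(sig.index[members_idx])
        narrow_ids = list(sig.index[narrow_idx])
        regions.append(
            AssociatedRegion(
                peak_snp=sig.index[i],
                peak_p=float(sig["p"].iloc[i]),
                chrom=chroms[i],
                peak_bp=int(bps[i]),
                wide_start=int(bps[members_idx].min()),
                wide_end=int(bps[members_idx].max()),
                narrow_start=int(bps[narrow_idx].min()),
                narrow_end=int(bps[narrow_idx].max()),
                wide_members=wide_ids,
                narrow_members=narrow_ids,
                odds_ratio=float(sig["OR"].iloc[i]),
                risk_allele=str(sig["risk_allele"].iloc[i]),
            )
        )
    return regions


def regions_to_intervals(regions: list, stage: str = "wide") -> IntervalSet:
    recs = []
    for reg in regions:
        if stage == "wide":
            recs.append((reg.chrom, reg.wide_start, reg.wide_end, reg.peak_snp, reg.peak_p))
        else:
            recs.append((reg.chrom, reg.narrow_start, reg.narrow_end, reg.peak_snp, reg.peak_p))
    return IntervalSet.from_records(recs)


# ----------------------------------------------------------------------
# regional variance explained
# ----------------------------------------------------------------------

def region_variance_explained(
    dataset: GenotypeDataset,
    regions: list,
    covariates: np.ndarray | None = None,
    wide_r2: float = 0.2,
    wide_window_bp: int = 5_000_000,
):
    """Observed-scale phenotype variance explained by the associated loci.

    The regional SNP set is every SNP with r2 above ``wide_r2`` within
    ``wide_window_bp`` of a region's peak SNP (the broad definition used
    for clumping's first stage, but over all scanned SNPs).  A GRM built
    from those SNPs alone enters a single-component REML fit; the
    returned ``(h2, se)`` is the regional heritability on the observed
    0/1 scale with a likelihood-curvature SE.
    """
    from .popgen import compute_grm

    if not regions:
        raise ValueError("no regions supplied")
    y = dataset.phenotype01()
    if np.nanvar(y) == 0:
        raise ValueError("phenotype has zero variance")
    g = _imputed_dosages(dataset)
    sd = g.std(axis=0)
    centered = (g - g.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    nobs = g.shape[0]
    chroms = dataset.snps["chrom"].to_numpy()
    bps = dataset.snps["bp"].to_numpy()
    chosen = np.zeros(dataset.n_snps, dtype=bool)
    for reg in regions:
        peak_pos = dataset.snps.index.get_loc(reg.peak_snp)
        near = (chroms == reg.chrom) & (np.abs(bps - bps[peak_pos]) <= wide_window_bp)
        r = (centered[:, near].T @ centered[:, peak_pos]) / nobs
        idx = np.where(near)[0][r**2 > wide_r2]
        chosen[idx] = True
        chosen[peak_pos] = True
    n_region = int(chosen.sum())
    if n_region < 10:
        warnings.warn(f"only {n_region} SNPs in the regional GRM; estimate will be noisy")
    sub = dataset.subset(snp_ids=dataset.snps.index[chosen])
    grm = compute_grm(sub)
    vc = fit_null_mixed(y, covariates, grm)
    return vc.h2, vc.h2_se


# ----------------------------------------------------------------------
# per-dog genotype relative risk
# ----------------------------------------------------------------------

def genotype_relative_risk(dataset: GenotypeDataset, regions: list):
    """Aggregate per-dog risk from the peak SNP of each region.

    ``score_j = sum_l c_jl log(OR_l)`` over risk-allele counts at the
    peak SNPs; reported as ``exp(score)`` normalized by its population
    mean.  Missing genotypes drop the locus for that dog, with the sum
    rescaled to the full locus count.  Returns ``(scores, rank_p)``
    where ``rank_p`` is the two-sided rank-sum p for cases vs controls
    (NaN if either group is absent).
    """
    peaks = [(reg.peak_snp, reg.odds_ratio) for reg in regions]
    if not peaks:
        raise ValueError("no regions supplied")
    idx = dataset.snps.index.get_indexer([p[0] for p in peaks])
    if np.any(idx < 0):
        raise ValueError("peak SNP missing from dataset")
    log_or = np.log([p[1] for p in peaks])
    g = dataset.genotypes[:, idx].astype(float)
    valid = g != MISSING
    n_skipped = int((~valid).sum())
    if n_skipped:
        log.info("risk score: %d missing peak genotypes skipped and renormalized", n_skipped)
    # dosage of the risk allele: OR is oriented to the risk allele, which
    # may be A2, in which case the count is 2 - dosage(A1)
    a1 = dataset.snps["a1"].to_numpy()[idx]
    risk_is_a1 = np.array([
        (reg.risk_allele == a or reg.risk_allele == "") for reg, a in zip(regions, a1)
    ])
    g = np.where(risk_is_a1[None, :], g, 2.0 - g)
    counts = np.where(valid, g, 0.0)
    n_loci = len(peaks)
    observed = valid.sum(axis=1)
    raw = counts @ log_or
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(observed > 0, raw * (n_loci / np.maximum(observed, 1)), 0.0)
    rel = np.exp(score)
    rel = rel / rel.mean()
    scores = pd.Series(rel, index=dataset.samples.index, name="relative_risk")
    y = dataset.phenotype01()
    case_scores = rel[y == 1.0]
    ctrl_scores = rel[y == 0.0]
    if len(case_scores) and len(ctrl_scores):
        rank_p = float(stats.mannwhitneyu(case_scores, ctrl_scores, alternative="two-sided").pvalue)
    else:
        rank_p = float("nan")
    return scores, rank_p
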