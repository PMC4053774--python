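"""Mixed model, permutation envelope, clumping, risk scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breedscan import assoc, popgen
from breedscan import simulate as sim
from breedscan.datatypes import KinshipMatrix, concat_datasets
from conftest import build_dataset


def _ols_pvalues(y, g, covariates=None):
    """Reference per-SNP OLS slope t-tests (independent of the scan path)."""
    n = len(y)
    x0 = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    ps = []
    for j in range(g.shape[1]):
        x = np.column_stack([x0, g[:, j]])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        df = n - x.shape[1]
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(x.T @ x)
        t = beta[-1] / np.sqrt(cov[-1, -1])
        ps.append(2 * stats.t.sf(abs(t), df))
    return np.array(ps)


class TestNullModel:
    def test_identity_kinship_matches_ols_variance(self):
        rng = np.random.default_rng(0)
        n = 80
        y = rng.standard_normal(n)
        k = KinshipMatrix(np.array([f"s{i}" for i in range(n)]), np.eye(n))
        vc = assoc.fit_null_mixed(y, None, k)
        # sg2 and se2 are not separately identifiable, but the total must
        # equal the OLS residual variance
        ols_var = np.var(y - y.mean(), ddof=1)
        assert vc.sigma2_g + vc.sigma2_e == pytest.approx(ols_var, rel=1e-3)

    def test_h2_recovery_block_kinship(self):
        estimates = []
        for seed in range(6):
            cfg = sim.SimulationConfig(
                n_breeds_gwas=2, n_reference_breeds=0, samples_per_breed=100,
                founders_per_breed=30, n_chromosomes=1, n_snps=400,
                generations=20, seed=seed,
            )
            ds, _ = sim.simulate_breed_panel(cfg)
            comb = concat_datasets(ds.values())
            k = popgen.compute_grm(comb)
            n = comb.n_samples
            sigma = 0.5 * k.values + 0.5 * np.eye(n)
            chol = np.linalg.cholesky(sigma + 1e-8 * np.eye(n))
            y = chol @ np.random.default_rng(seed + 100).standard_normal(n)
            estimates.append(assoc.fit_null_mixed(y, None, k).h2)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.15)

    def test_unstructured_phenotype_hits_zero_boundary(self, breed_pair):
        datasets, _ = breed_pair
        comb = concat_datasets(datasets.values())
        k = popgen.compute_grm(comb)
        at_zero = 0
        for seed in range(5):
            y = np.random.default_rng(seed).standard_normal(comb.n_samples)
            at_zero += assoc.fit_null_mixed(y, None, k).h2 < 0.1
        assert at_zero >= 3

    def test_rank_deficient_covariates_rejected(self):
        n = 20
        k = KinshipMatrix(np.array([f"s{i}" for i in range(n)]), np.eye(n))
        cov = np.ones((n, 1))          # collinear with the intercept
        with pytest.raises(ValueError, match="rank"):
            assoc.fit_null_mixed(np.zeros(n), cov, k)


class TestScan:
    def test_reduces_to_ols_when_no_genetic_variance(self, cohort):
        ds, _ = cohort
        k = popgen.compute_grm(ds)
        vc = assoc.fit_null_mixed(ds.phenotype01(), None, k)
        vc0 = assoc.VarianceComponents(
            sigma2_g=0.0, sigma2_e=vc.sigma2_e, h2=0.0, loglik=0.0,
            iterations=0, converged=True,
            eigenvalues=vc.eigenvalues, eigenvectors=vc.eigenvectors,
        )
        res = assoc.mixed_model_scan(ds, vc0)
        keep = ds.snps.index.get_indexer(res.table.index)
        ols = _ols_pvalues(ds.phenotype01(), ds.genotypes[:, keep].astype(float))
        np.testing.assert_allclose(res.table["p"].to_numpy(), ols, atol=1e-10)

    def test_planted_locus_tops_scan_in_most_seeds(self):
        # effect size set by the case/control frequency contrast (~0.14 vs
        # 0.02) seen at strongly associated breed loci
        hits = 0
        for seed in range(20):
            cfg = sim.SimulationConfig(
                n_breeds_gwas=1, n_reference_breeds=0, samples_per_breed=140,
                founders_per_breed=200, n_chromosomes=2, n_snps=1000,
                generations=10, seed=seed,
                risk_loci=[sim.RiskLocus("chr1", 25_000_000, 8.0, 0.15)],
            )
            ds, truth = sim.simulate_breed_panel(cfg)
            d = sim.assign_phenotypes(ds["gwas1"], truth, 0.5, seed=seed + 1000)
            k = popgen.compute_grm(d)
            vc = assoc.fit_null_mixed(d.phenotype01(), None, k)
            res = assoc.mixed_model_scan(d, vc)
            hits += res.table["p"].idxmin() == truth.risk_snp_ids[0]
        assert hits >= 16

    def test_null_pvalues_uniform(self):
        cfg = sim.SimulationConfig(
            n_breeds_gwas=1, n_reference_breeds=0, samples_per_breed=200,
            founders_per_breed=150, n_chromosomes=2, n_snps=2500,
            generations=8, seed=77,
        )
        ds, truth = sim.simulate_breed_panel(cfg)
        d = sim.assign_phenotypes(ds["gwas1"], truth, 0.5, seed=78)
        k = popgen.compute_grm(d)
        vc = assoc.fit_null_mixed(d.phenotype01(), None, k)
        res = assoc.mixed_model_scan(d, vc)
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_maf_filter_applied(self, cohort):
        ds, _ = cohort
        k = popgen.compute_grm(ds)
        vc = assoc.fit_null_mixed(ds.phenotype01(), None, k)
        res = assoc.mixed_model_scan(ds, vc, maf_min=0.05)
        tested = ds.snps.index.get_indexer(res.table.index)
        assert (ds.maf()[tested] >= 0.05).all()

    def test_unconverged_null_refused(self, cohort):
        ds, _ = cohort
        vc = assoc.VarianceComponents(1, 1, 0.5, 0.0, 0, converged=False)
        with pytest.raises(ValueError, match="converge"):
            assoc.mixed_model_scan(ds, vc)


@pytest.fixture(scope="module")
def null_setup():
    cfg = sim.SimulationConfig(
        n_breeds_gwas=1, n_reference_breeds=0, samples_per_breed=100,
        founders_per_breed=60, n_chromosomes=1, n_snps=500,
        generations=15, seed=21,
    )
    ds, truth = sim.simulate_breed_panel(cfg)
    d = sim.assign_phenotypes(ds["gwas1"], truth, 0.5, seed=22)
    k = popgen.compute_grm(d)
    vc = assoc.fit_null_mixed(d.phenotype01(), None, k)
    return d, vc


class TestEnvelope:
    def test_upper_dominates_lower(self, null_setup):
        d, vc = null_setup
        env = assoc.permutation_envelope(d, vc, n_perm=120, seed=1)
        assert np.all(env.upper >= env.lower)
        assert env.threshold == env.upper[0]

    def test_same_seed_identical(self, null_setup):
        d, vc = null_setup
        e1 = assoc.permutation_envelope(d, vc, n_perm=120, seed=5)
        e2 = assoc.permutation_envelope(d, vc, n_perm=120, seed=5)
        np.testing.assert_array_equal(e1.upper, e2.upper)
        np.testing.assert_array_equal(e1.lower, e2.lower)

    def test_small_n_perm_warns(self, null_setup):
        d, vc = null_setup
        with pytest.warns(UserWarning, match="unstable"):
            assoc.permutation_envelope(d, vc, n_perm=50, seed=2)


def _brute_force_clump(table, genotypes, p_max, wide_r2=0.2, wide_bp=5_000_000,
                       narrow_r2=0.8, narrow_bp=1_000_000):
    """All-pairs reference clumping, written independently of the library
    implementation: plain python loops over explicit pair correlations."""
    sig = table[table["p"] < p_max]
    order = sorted(sig.index, key=lambda s: (sig.loc[s, "p"], sig.loc[s, "chrom"],
                                             sig.loc[s, "bp"]))
    col = {s: i for i, s in enumerate(sig.index)}
    g = genotypes
    claimed = set()
    regions = []
    for idx_snp in order:
        if idx_snp in claimed:
            continue
        wide = []
        for other in sig.index:
            if other in claimed and other != idx_snp:
                continue
            if sig.loc[other, "chrom"] != sig.loc[idx_snp, "chrom"]:
                continue
            if abs(sig.loc[other, "bp"] - sig.loc[idx_snp, "bp"]) > wide_bp:
                continue
            r = np.corrcoef(g[:, col[idx_snp]], g[:, col[other]])[0, 1]
            if other == idx_snp or r**2 > wide_r2:
                wide.append(other)
        narrow = []
        for other in wide:
            if abs(sig.loc[other, "bp"] - sig.loc[idx_snp, "bp"]) > narrow_bp:
                continue
            r = np.corrcoef(g[:, col[idx_snp]], g[:, col[other]])[0, 1]
            if other == idx_snp or r**2 > narrow_r2:
                narrow.append(other)
        claimed.update(wide)
        regions.append((idx_snp, frozenset(wide), frozenset(narrow)))
    return regions


class TestClumping:
    def test_perfect_ld_pair_one_region(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=60).astype(np.int8)
        g = np.column_stack([col, col])
        ds = build_dataset(g, bp=[100_000, 110_000])
        table = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "bp": [100_000, 110_000],
             "p": [1e-6, 2e-6], "OR": [1.5, 1.5], "risk_allele": ["A", "A"]},
            index=ds.snps.index,
        )
        regions = assoc.clump_regions(assoc.AssocResult(table), ds)
        assert len(regions) == 1
        assert set(regions[0].wide_members) == {"m0", "m1"}

    def test_different_chromosomes_two_regions(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(60, 2)).astype(np.int8)
        ds = build_dataset(g, bp=[100_000, 100_000], chrom=["chr1", "chr2"])
        table = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "bp": [100_000, 100_000],
             "p": [1e-6, 2e-6], "OR": [1.5, 1.5], "risk_allele": ["A", "A"]},
            index=ds.snps.index,
        )
        regions = assoc.clump_regions(assoc.AssocResult(table), ds)
        assert len(regions) == 2

    def test_matches_brute_force_reference(self, cohort):
        ds, _ = cohort
        k = popgen.compute_grm(ds)
        vc = assoc.fit_null_mixed(ds.phenotype01(), None, k)
        res = assoc.mixed_model_scan(ds, vc)
        # take the 50 smallest p-values as the significant set
        p_max = float(np.sort(res.table["p"])[50])
        regions = assoc.clump_regions(res, ds, p_max=p_max)
        sig = res.table[res.table["p"] < p_max]
        keep = ds.snps.index.get_indexer(sig.index)
        ref = _brute_force_clump(res.table, ds.genotypes[:, keep].astype(float), p_max)
        assert len(regions) == len(ref)
        for got, (peak, wide, narrow) in zip(regions, ref):
            assert got.peak_snp == peak
            assert frozenset(got.wide_members) == wide
            assert frozenset(got.narrow_members) == narrow
            assert set(got.narrow_members) <= set(got.wide_members)

    def test_invariant_to_input_order(self, cohort):
        ds, _ = cohort
        k = popgen.compute_grm(ds)
        vc = assoc.fit_null_mixed(ds.phenotype01(), None, k)
        res = assoc.mixed_model_scan(ds, vc)
        p_max = float(np.sort(res.table["p"])[30])
        regions = assoc.clump_regions(res, ds, p_max=p_max)
        shuffled = assoc.AssocResult(res.table.sample(frac=1, random_state=0))
        regions2 = assoc.clump_regions(shuffled, ds, p_max=p_max)
        assert [r.peak_snp for r in regions] == [r.peak_snp for r in regions2]
        assert [set(r.wide_members) for r in regions] == [set(r.wide_members) for r in regions2]


class TestRegionalVariance:
    def test_all_controls_rejected(self, cohort):
        ds, _ = cohort
        d = ds.subset()
        d.samples["phenotype"] = "control"
        region = assoc.AssociatedRegion(
            peak_snp=ds.snps.index[0], peak_p=1e-6, chrom="chr1", peak_bp=1,
            wide_start=1, wide_end=2, narrow_start=1, narrow_end=2,
            wide_members=[], narrow_members=[],
        )
        with pytest.raises(ValueError, match="variance"):
            assoc.region_variance_explained(d, [region])

    def test_causal_region_recovers_signal(self):
        # phenotype driven by a strong locus; the region around it should
        # explain a clearly nonzero share of variance, while a decoy region
        # on the other chromosome explains ~none
        cfg = sim.SimulationConfig(
            n_breeds_gwas=1, n_reference_breeds=0, samples_per_breed=250,
            founders_per_breed=200, n_chromosomes=2, n_snps=800,
            generations=8, seed=31,
            risk_loci=[sim.RiskLocus("chr1", 25_000_000, 8.0, 0.2)],
        )
        ds, truth = sim.simulate_breed_panel(cfg)
        d = sim.assign_phenotypes(ds["gwas1"], truth, 0.5, seed=32)
        peak = truth.risk_snp_ids[0]

        def region_at(snp):
            row = d.snps.loc[snp]
            return assoc.AssociatedRegion(
                peak_snp=snp, peak_p=1e-6, chrom=row["chrom"], peak_bp=row["bp"],
                wide_start=row["bp"], wide_end=row["bp"],
                narrow_start=row["bp"], narrow_end=row["bp"],
                wide_members=[snp], narrow_members=[snp],
            )

        h2_causal, se_causal = assoc.region_variance_explained(d, [region_at(peak)])
        chr2_poly = d.snps.index[(d.snps["chrom"] == "chr2").to_numpy() & (d.maf() > 0.2)]
        decoy = chr2_poly[len(chr2_poly) // 2]
        h2_decoy, _ = assoc.region_variance_explained(d, [region_at(decoy)])
        assert h2_causal > 0.05
        assert h2_causal > h2_decoy


class TestRiskScore:
    def _regions(self, ds, specs):
        out = []
        for snp, odds in specs:
            row = ds.snps.loc[snp]
            out.append(assoc.AssociatedRegion(
                peak_snp=snp, peak_p=1e-6, chrom=row["chrom"], peak_bp=row["bp"],
                wide_start=row["bp"], wide_end=row["bp"],
                narrow_start=row["bp"], narrow_end=row["bp"],
                wide_members=[snp], narrow_members=[snp],
                odds_ratio=odds, risk_allele=row["a1"],
            ))
        return out

    def test_unit_odds_ratio_flat_scores(self):
        g = np.array([[0, 2], [1, 1], [2, 0]], dtype=np.int8)
        ds = build_dataset(g, phenotype=["case", "control", "case"])
        scores, _ = assoc.genotype_relative_risk(ds, self._regions(ds, [("m0", 1.0), ("m1", 1.0)]))
        assert np.allclose(scores, 1.0)

    def test_single_locus_geometric_scaling(self):
        g = np.array([[0], [1], [2]], dtype=np.int8)
        ds = build_dataset(g, phenotype=["control", "control", "case"])
        scores, _ = assoc.genotype_relative_risk(ds, self._regions(ds, [("m0", 2.0)]))
        # 1 : 2 : 4 before normalization, so ratios survive normalization
        assert scores.iloc[1] / scores.iloc[0] == pytest.approx(2.0)
        assert scores.iloc[2] / scores.iloc[0] == pytest.approx(4.0)

    def test_cases_score_higher_on_planted_architecture(self, cohort):
        ds, truth = cohort
        k = popgen.compute_grm(ds)
        vc = assoc.fit_null_mixed(ds.phenotype01(), None, k)
        res = assoc.mixed_model_scan(ds, vc)
        p_max = float(np.sort(res.table["p"])[10])
        regions = assoc.clump_regions(res, ds, p_max=p_max)
        scores, rank_p = assoc.genotype_relative_risk(ds, regions)
        y = ds.phenotype01()
        assert scores[y == 1].mean() > scores[y == 0].mean()
        assert rank_p < 0.001
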