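"""CGH calling, recurrence, and stratified 2x2 tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from breedscan import cna
from breedscan import simulate as sim
from breedscan.datatypes import StratifiedTables
from conftest import build_dataset


def _profile(ratios_by_sample, spacing=26_000, chrom="chrA"):
    n_probes = len(next(iter(ratios_by_sample.values())))
    bp = np.arange(n_probes) * spacing + spacing // 2
    df = pd.DataFrame({"chrom": [chrom] * n_probes, "bp": bp})
    for s, vals in ratios_by_sample.items():
        df[s] = vals
    df.index = pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id")
    return df


# the four replication-cohort allele tables reconstructed from cohort
# sizes and printed risk-allele frequencies
ROTTWEILER = [[180, 4], [149, 5]]      # 92 cases 0.98 / 77 controls 0.97
IWH = [[50, 4], [57, 5]]               # 27 cases 0.93 / 31 controls 0.92
LEONBERGER = [[46, 14], [31, 19]]      # 30 cases 0.77 / 25 controls 0.62
PYRENEES = [[25, 7], [26, 16]]         # 16 cases 0.78 / 21 controls 0.62


class TestCallSegments:
    def test_three_probe_gain_called(self):
        table = _profile({"t": [0.0, 0.3, 0.3, 0.3, 0.0]})
        segs = cna.call_segments(table)["t"]
        recs = list(segs)
        assert len(recs) == 1
        assert recs[0].label == "gain"
        assert recs[0].score == 3

    def test_two_probes_not_enough(self):
        table = _profile({"t": [0.3, 0.3, 0.0]})
        assert len(cna.call_segments(table)["t"]) == 0

    def test_sign_flip_breaks_run(self):
        table = _profile({"t": [0.3, -0.3, 0.3]})
        assert len(cna.call_segments(table)["t"]) == 0

    def test_threshold_boundary_inclusive(self):
        table = _profile({"t": [0.2, 0.2, 0.2]})
        assert list(cna.call_segments(table)["t"])[0].label == "gain"

    def test_unsorted_probes_rejected(self):
        table = _profile({"t": [0.3, 0.3, 0.3]})
        table = table.iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            cna.call_segments(table)

    def test_calls_idempotent_on_noiseless_truth(self):
        planted = [{"chrom": "chrA", "start_bp": 200_000, "end_bp": 500_000,
                    "direction": "loss"}]
        table, truth = sim.simulate_cgh_cohort(
            2, {"chrA": 2_000_000}, planted_segments=planted,
            noise_sd=0.0, background_aberration_rate=0.0, seed=1,
        )
        first = cna.call_segments(table)
        second = cna.call_segments(table)
        for s in first:
            assert first[s].data.equals(second[s].data)


class TestProbeRecurrence:
    def test_independent_samples_product_expectation(self):
        rng = np.random.default_rng(0)
        n = 4000
        # two samples, each with ~50% of probes aberrant, independently
        vals = {f"t{i}": np.where(rng.random(n) < 0.5, 0.6, 0.0) for i in range(2)}
        table = _profile(vals, spacing=1000)
        states = cna.call_states(table)
        out = cna.probe_recurrence(states, {"both": ["t0", "t1"]}, mode="any")
        row = out.loc["both"]
        assert row["fraction"] == pytest.approx(0.25, abs=0.03)
        assert row["expected_fraction"] == pytest.approx(0.25, abs=0.03)
        assert 0.01 < row["p_binomial"] < 0.99

    def test_planted_universal_probe_counted_once(self):
        table = _profile({"a": [0.6, 0.0], "b": [0.6, 0.0]})
        states = cna.call_states(table)
        out = cna.probe_recurrence(states, {"all": ["a", "b"]}, mode="any")
        assert out.loc["all", "n_recurrent"] == 1

    def test_direction_consistency_in_up_mode(self):
        table = _profile({"a": [0.6, 0.6], "b": [-0.6, 0.6]})
        states = cna.call_states(table)
        up = cna.probe_recurrence(states, {"g": ["a", "b"]}, mode="up")
        any_ = cna.probe_recurrence(states, {"g": ["a", "b"]}, mode="any")
        assert up.loc["g", "n_recurrent"] == 1      # second probe gained in both
        assert any_.loc["g", "n_recurrent"] == 2    # first aberrant in both, mixed signs

    def test_empty_group_rejected(self):
        table = _profile({"a": [0.6]})
        with pytest.raises(ValueError, match="empty"):
            cna.probe_recurrence(cna.call_states(table), {"g": []})


class TestAllelicAssociation:
    def test_leonberger_table_p(self):
        out = cna.allelic_association(LEONBERGER)
        assert round(out["p"], 2) == 0.09

    def test_pyrenees_table_p(self):
        out = cna.allelic_association(PYRENEES)
        assert round(out["p"], 2) == 0.14

    def test_equal_frequencies_give_p_one(self):
        out = cna.allelic_association([[30, 70], [60, 140]])
        assert out["chi2"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_zero_margin_flagged(self):
        out = cna.allelic_association([[0, 0], [10, 20]])
        assert np.isnan(out["p"]) and out["flagged"]


def _brute_cmh(tables):
    """Textbook CMH + MH odds ratio, plain loops."""
    num = 0.0
    den = 0.0
    or_num = 0.0
    or_den = 0.0
    for (a, b), (c, d) in tables:
        n = a + b + c + d
        n1, n2 = a + b, c + d
        m1, m2 = a + c, b + d
        num += a - n1 * m1 / n
        den += n1 * n2 * m1 * m2 / (n * n * (n - 1))
        or_num += a * d / n
        or_den += b * c / n
    chi2 = num * num / den
    return chi2, stats.chi2.sf(chi2, 1), or_num / or_den


class TestCmh:
    def test_four_breed_replication_rounds_to_003(self):
        t = StratifiedTables(["rott", "iwh", "leon", "pyr"],
                             np.array([ROTTWEILER, IWH, LEONBERGER, PYRENEES]))
        out = cna.cmh_test(t)
        assert round(out["p"], 2) == 0.03

    def test_single_stratum_reduces_to_chi_square(self):
        # with one stratum the CMH statistic is the Pearson chi-square up
        # to its hypergeometric variance: CMH = (N-1)/N * X^2
        t = StratifiedTables(["only"], np.array([LEONBERGER]))
        out = cna.cmh_test(t)
        ref = cna.allelic_association(LEONBERGER)
        n = np.sum(LEONBERGER)
        assert out["chi2"] == pytest.approx(ref["chi2"] * (n - 1) / n, abs=1e-12)

    def test_matches_brute_force_and_statsmodels(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            k = int(rng.integers(1, 6))
            tabs = rng.integers(1, 60, size=(k, 2, 2))
            t = StratifiedTables(list(range(k)), tabs)
            out = cna.cmh_test(t)
            chi2, p, ormh = _brute_cmh(tabs.tolist())
            assert out["chi2"] == pytest.approx(chi2, abs=1e-9)
            assert out["or_mh"] == pytest.approx(ormh, abs=1e-9)
            sm = StratifiedTable(np.transpose(tabs, (1, 2, 0)).astype(float))
            assert out["or_mh"] == pytest.approx(sm.oddsratio_pooled, abs=1e-8)
            assert out["chi2"] == pytest.approx(
                float(sm.test_null_odds(correction=False).statistic), abs=1e-8
            )


class TestBreslowDay:
    def test_identical_strata_homogeneous(self):
        t = StratifiedTables(["a", "b", "c"], np.array([LEONBERGER] * 3))
        out = cna.breslow_day(t)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-9)
        assert out["p"] == pytest.approx(1.0, abs=1e-6)

    def test_replication_cohort_no_heterogeneity(self):
        t = StratifiedTables(["rott", "iwh", "leon", "pyr"],
                             np.array([ROTTWEILER, IWH, LEONBERGER, PYRENEES]))
        out = cna.breslow_day(t)
        assert out["p"] > 0.3

    def test_discordant_odds_ratios_detected(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            # stratum 1: OR = 1; stratum 2: OR = 10, n = 200 per stratum
            a = rng.binomial(100, 0.5)
            t1 = [[a, 100 - a], [rng.binomial(100, 0.5), 0]]
            t1[1][1] = 100 - t1[1][0]
            p2 = 10 * 0.5 / (1 + 10 * 0.5 - 0.5)
            b = rng.binomial(100, p2)
            t2 = [[b, 100 - b], [rng.binomial(100, 0.5), 0]]
            t2[1][1] = 100 - t2[1][0]
            t = StratifiedTables(["s1", "s2"], np.array([t1, t2]))
            hits += cna.breslow_day(t)["p"] < 0.05
        assert hits >= 18

    def test_invariant_to_stratum_order(self):
        t1 = StratifiedTables(["a", "b"], np.array([LEONBERGER, PYRENEES]))
        t2 = StratifiedTables(["b", "a"], np.array([PYRENEES, LEONBERGER]))
        assert cna.breslow_day(t1)["chi2"] == pytest.approx(
            cna.breslow_day(t2)["chi2"], abs=1e-12
        )

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            tabs = rng.integers(5, 60, size=(k, 2, 2))
            out = cna.breslow_day(StratifiedTables(list(range(k)), tabs))
            sm = StratifiedTable(np.transpose(tabs, (1, 2, 0)).astype(float))
            ref = sm.test_equal_odds(adjust=False)
            assert out["chi2"] == pytest.approx(float(ref.statistic), rel=1e-6)


class TestGenotypeCnaAssociation:
    def _setup(self, seed, associated):
        rng = np.random.default_rng(seed)
        n = 60
        g = rng.integers(0, 3, size=(n, 1)).astype(np.int8)
        breeds = ["b1"] * (n // 2) + ["b2"] * (n - n // 2)
        ds = build_dataset(g, breed=breeds)
        n_probes = 30
        ratios = {}
        for i, sid in enumerate(ds.sample_ids):
            base = rng.normal(0, 0.05, n_probes)
            if associated:
                p_del = 0.15 + 0.35 * (g[i, 0] / 2)
            else:
                p_del = 0.3
            if rng.random() < p_del:
                base[10:16] -= 1.0          # deletion segment probes 10-15
            ratios[sid] = base
        table = _profile(ratios, spacing=26_000)
        return ds, cna.call_states(table)

    def test_planted_association_peaks_in_segment(self):
        hits = 0
        for seed in range(10):
            ds, states = self._setup(seed, associated=True)
            out = cna.genotype_cna_association(ds, states, ["m0"], direction="loss")
            best = out.loc[out["p"].idxmin(), "probe"]
            hits += best in {f"p{i}" for i in range(10, 16)}
        assert hits >= 8

    def test_single_breed_reduces_to_plain_chi_square(self):
        ds, states = self._setup(0, associated=True)
        one_breed = ds.subset()
        one_breed.samples["breed"] = "b1"
        out = cna.genotype_cna_association(one_breed, states, ["m0"], direction="loss")
        probe = "p12"
        aberrant = states.loc[probe, list(ds.sample_ids)].to_numpy() == cna.LOSS
        g = ds.genotypes[:, 0].astype(float)
        a = g[aberrant].sum(); b = 2 * aberrant.sum() - a
        c = g[~aberrant].sum(); d = 2 * (~aberrant).sum() - c
        ref = cna.allelic_association([[a, b], [c, d]])
        got = out[out["probe"] == probe].iloc[0]
        n = a + b + c + d
        assert got["chi2"] == pytest.approx(ref["chi2"] * (n - 1) / n, abs=1e-9)
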