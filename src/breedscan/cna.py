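"""Array-CGH copy-number calling, probe recurrence statistics, and the
stratified 2x2 machinery (allelic chi-square, Cochran-Mantel-Haenszel,
Breslow-Day) used for cross-breed replication and germline-to-somatic
association.

All chi-square statistics are computed without continuity correction,
which is what reproduces the printed replication p-values of the kind
of stratified allele tables this module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeDataset, IntervalSet, StratifiedTables

log = logging.getLogger(__name__)

GAIN, NEUTRAL, LOSS = 1, 0, -1


# ----------------------------------------------------------------------
# segment calling
# ----------------------------------------------------------------------

def call_states(table: pd.DataFrame, threshold: float = 0.2) -> pd.DataFrame:
    """Per-probe call track: +1 gain (log2 ratio >= threshold), -1 loss
    (<= -threshold), 0 neutral; NaN ratios stay neutral."""
    samples = [c for c in table.columns if c not in ("chrom", "bp")]
    vals = table[samples].to_numpy(dtype=float)
    states = np.zeros_like(vals, dtype=np.int8)
    states[vals >= threshold] = GAIN
    states[vals <= -threshold] = LOSS
    states[~np.isfinite(vals)] = NEUTRAL
    return pd.DataFrame(states, index=table.index, columns=samples)


def call_segments(
    table: pd.DataFrame,
    threshold: float = 0.2,
    min_probes: int = 3,
) -> dict:
    """Threshold-and-run segmentation of tumor log2-ratio profiles.

    A segment is a maximal run of at least ``min_probes`` consecutive
    probes on one chromosome whose ratios are all >= ``threshold``
    (gain) or all <= ``-threshold`` (loss); it spans first-to-last probe
    position.  Probes must already be sorted by (chrom, bp) — unsorted
    input is an error, not silently reordered.  Returns a dict mapping
    sample name to an :class:`IntervalSet` labeled gain/loss.
    """
    chroms = table["chrom"].to_numpy()
    bps = table["bp"].to_numpy()
    order_ok = all(
        np.all(np.diff(bps[chroms == c]) > 0) for c in pd.unique(chroms)
    )
    if not order_ok:
        raise ValueError("probes are not sorted by position within chromosome")
    states = call_states(table, threshold)
    out = {}
    for sample in states.columns:
        st = states[sample].to_numpy()
        records = []
        for chrom in pd.unique(chroms):
            idx = np.where(chroms == chrom)[0]
            s = st[idx]
            pos = bps[idx]
            # runs of identical non-neutral state
            change = np.concatenate([[True], s[1:] != s[:-1]])
            run_id = np.cumsum(change)
            for rid in np.unique(run_id):
                mask = run_id == rid
                state = s[mask][0]
                if state == NEUTRAL or mask.sum() < min_probes:
                    continue
                records.append((
                    chrom, int(pos[mask][0]), int(pos[mask][-1]),
                    "gain" if state == GAIN else "loss",
                    float(mask.sum()),
                ))
        out[sample] = IntervalSet.from_records(records)
    return out


# ----------------------------------------------------------------------
# probe recurrence
# ----------------------------------------------------------------------

def probe_recurrence(
    states: pd.DataFrame,
    groups: dict,
    mode: str = "any",
) -> pd.DataFrame:
    """Probes aberrant in *all* samples of a group, with a binomial
    enrichment p-value against independent per-sample aberration rates.

    ``mode``: ``"up"`` counts probes gained in all samples, ``"down"``
    lost in all, ``"any"`` aberrant (either direction) in all.  The
    expected all-sample fraction under independence is the product of
    each sample's own aberrant-probe fraction; the reported p is the
    upper binomial tail of the observed count given that expectation.
    """
    if mode not in ("up", "down", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    n_probes = len(states)
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
        sub = states[list(members)].to_numpy()
        if mode == "up":
            aberrant = sub == GAIN
        elif mode == "down":
            aberrant = sub == LOSS
        else:
            aberrant = sub != NEUTRAL
        in_all = aberrant.all(axis=1)
        count = int(in_all.sum())
        rates = aberrant.mean(axis=0)
        expected = float(np.prod(rates))
        p = float(stats.binom.sf(count - 1, n_probes, expected)) if expected > 0 else (
            1.0 if count == 0 else 0.0
        )
        rows.append((name, len(members), count, count / n_probes, expected, p))
    return pd.DataFrame(
        rows,
        columns=["group", "n_samples", "n_recurrent", "fraction", "expected_fraction",
                 "p_binomial"],
    ).set_index("group")


# ----------------------------------------------------------------------
# 2x2 and stratified tests
# ----------------------------------------------------------------------

def allelic_association(table) -> dict:
    """1-df Pearson chi-square (no continuity correction) on a single
    2x2 allele table ``[[a, b], [c, d]]`` plus the allelic OR ad/bc."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a single 2x2 table")
    if (t < 0).any():
        raise ValueError("negative counts")
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    flagged = bool((row == 0).any() or (col == 0).any())
    if flagged:
        return {"chi2": float("nan"), "p": float("nan"), "or": float("nan"),
                "flagged": True}
    expected = np.outer(row, col) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    a, b = t[0]
    c, d = t[1]
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
        flagged = True
    else:
        odds = float(a * d / (b * c))
    return {"chi2": chi2, "p": p, "or": odds, "flagged": flagged}


def _drop_empty_strata(tables: StratifiedTables) -> np.ndarray:
    t = tables.tables.astype(float)
    totals = t.sum(axis=(1, 2))
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} strata with zero total")
    return t[keep]


def cmh_test(tables: StratifiedTables) -> dict:
    """Cochran-Mantel-Haenszel common-association test across strata.

    1-df statistic ``(sum(a - E[a]))^2 / sum(Var[a])`` without continuity
    correction, plus the Mantel-Haenszel common odds ratio
    ``sum(ad/N) / sum(bc/N)``.  With a single stratum this reduces
    exactly to the unstratified allelic chi-square.
    """
    t = _drop_empty_strata(tables)
    if len(t) == 0:
        raise ValueError("no usable strata")
    a = t[:, 0, 0]
    n1 = t[:, 0, :].sum(axis=1)
    n2 = t[:, 1, :].sum(axis=1)
    m1 = t[:, :, 0].sum(axis=1)
    m2 = t[:, :, 1].sum(axis=1)
    n = t.sum(axis=(1, 2))
    expect = n1 * m1 / n
    var = n1 * n2 * m1 * m2 / (n**2 * (n - 1))
    var_sum = var[np.isfinite(var)].sum()
    if var_sum == 0:
        return {"chi2": float("nan"), "p": float("nan"), "or_mh": float("nan")}
    chi2 = float((a - expect).sum() ** 2 / var_sum)
    num = (t[:, 0, 0] * t[:, 1, 1] / n).sum()
    den = (t[:, 0, 1] * t[:, 1, 0] / n).sum()
    or_mh = float(num / den) if den > 0 else float("inf")
    return {"chi2": chi2, "p": float(stats.chi2.sf(chi2, df=1)), "or_mh": or_mh}


def _expected_a_given_or(n1, n2, m1, psi):
    """Expected top-left cell under a common odds ratio psi (fixed margins)."""
    n = n1 + n2
    if abs(psi - 1.0) < 1e-12:
        return n1 * m1 / n
    # (1-psi) a^2 + [ (n2 - m1) + psi (n1 + m1) ] a - psi n1 m1 = 0
    qa = 1.0 - psi
    qb = (n2 - m1) + psi * (n1 + m1)
    qc = -psi * n1 * m1
    disc = np.sqrt(qb * qb - 4 * qa * qc)
    roots = [(-qb + disc) / (2 * qa), (-qb - disc) / (2 * qa)]
    lo, hi = max(0.0, m1 - n2), min(n1, m1)
    for r in roots:
        if lo - 1e-9 <= r <= hi + 1e-9:
            return float(np.clip(r, lo, hi))
    raise ArithmeticError("no admissible root for expected cell count")


def breslow_day(tables: StratifiedTables, tarone: bool = False) -> dict:
    """Breslow-Day test of odds-ratio homogeneity across strata.

    The statistic compares each stratum's top-left cell with its
    expectation under the Mantel-Haenszel common OR and is referred to a
    chi-square with (K - 1) degrees of freedom (degenerate strata are
    dropped with the df reduced).  ``tarone=True`` applies Tarone's
    adjustment.
    """
    t = _drop_empty_strata(tables)
    if len(t) < 2:
        raise ValueError("Breslow-Day needs at least two usable strata")
    psi = cmh_test(StratifiedTables(list(range(len(t))), t.astype(np.int64)))["or_mh"]
    if not np.isfinite(psi) or psi <= 0:
        raise ValueError("Mantel-Haenszel common OR not finite; cannot test homogeneity")
    stat = 0.0
    resid_sum = 0.0
    var_sum = 0.0
    k_used = 0
    for a, b, c, d in t.reshape(-1, 4):
        n1, n2, m1 = a + b, c + d, a + c
        if min(n1, n2, m1, b + d) == 0:
            continue
        a_hat = _expected_a_given_or(n1, n2, m1, psi)
        b_hat, c_hat, d_hat = n1 - a_hat, m1 - a_hat, n2 - (m1 - a_hat)
        cells = np.array([a_hat, b_hat, c_hat, d_hat])
        if np.any(cells <= 0):
            continue
        var = 1.0 / (1.0 / a_hat + 1.0 / b_hat + 1.0 / c_hat + 1.0 / d_hat)
        stat += (a - a_hat) ** 2 / var
        resid_sum += a - a_hat
        var_sum += var
        k_used += 1
    if k_used < 2:
        raise ValueError("fewer than two informative strata for Breslow-Day")
    if tarone and var_sum > 0:
        stat -= resid_sum**2 / var_sum
    df = k_used - 1
    return {"chi2": float(stat), "p": float(stats.chi2.sf(stat, df=df)), "df": df}


# ----------------------------------------------------------------------
# germline genotype <-> somatic CNA association
# ----------------------------------------------------------------------

def genotype_cna_association(
    dataset: GenotypeDataset,
    states: pd.DataFrame,
    peak_snps: list,
    direction: str = "gain",
) -> pd.DataFrame:
    """CMH association of germline risk-allele counts with per-probe
    somatic gain (or loss), stratified by breed.

    Samples are matched by id between the genotype dataset and the call
    track columns; samples missing either data type are excluded (and
    logged).  For each (SNP, probe) pair the 2x2 table per breed counts
    alleles among aberrant vs non-aberrant dogs.
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    want_state = GAIN if direction == "gain" else LOSS
    shared = [s for s in states.columns if s in dataset.samples.index]
    dropped = [s for s in states.columns if s not in dataset.samples.index]
    if dropped:
        log.info("genotype/CNA association: %d samples lack genotypes, excluded",
                 len(dropped))
    if not shared:
        raise ValueError("no samples shared between genotypes and CGH calls")
    breeds = dataset.samples.loc[shared, "breed"].to_numpy()
    uniq_breeds = pd.unique(breeds)
    rows = []
    for snp in peak_snps:
        j = dataset.snps.index.get_loc(snp)
        g = dataset.genotypes[dataset.samples.index.get_indexer(shared), j].astype(float)
        ok = g != MISSING
        for probe in states.index:
            aberrant = states.loc[probe, shared].to_numpy() == want_state
            stack = []
            labels = []
            for breed in uniq_breeds:
                mask = (breeds == breed) & ok
                if mask.sum() == 0:
                    continue
                ga = g[mask & aberrant]
                gn = g[mask & ~aberrant]
                a = int(ga.sum())
                b = int(2 * len(ga) - a)
                c = int(gn.sum())
                d = int(2 * len(gn) - c)
                stack.append([[a, b], [c, d]])
                labels.append(breed)
            if not stack:
                continue
            res = cmh_test(StratifiedTables(labels, np.array(stack)))
            rows.append((snp, probe, direction, res["chi2"], res["p"], res["or_mh"]))
    return pd.DataFrame(
        rows, columns=["snp", "probe", "direction", "chi2", "p", "or_mh"]
    )
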