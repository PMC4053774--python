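"""Synthetic breed populations, phenotypes, and tumor CGH cohorts.

The generator emulates the population structure of purebred dog cohorts:
each breed is founded from a small number of individuals drawn from a
shared ancestral haplotype pool and then closed to outside mating, so
breeds are genetically distinct, carry long-range linkage
disequilibrium, and show elevated inbreeding — the features the
downstream mixed-model and selection-scan analyses are built to handle.
Risk loci with per-allele odds ratios generate binary phenotypes under a
logistic model, and a truth record accompanies every simulated dataset
so parameter-recovery tests can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from scipy import optimize, special

from .datatypes import GenotypeDataset, IntervalSet, make_samples, make_snps


@dataclass
class RiskLocus:
    """A planted causal SNP: position, per-allele odds ratio, and the
    risk-allele frequency the founder pool is seeded at (per breed or a
    single value for all breeds)."""

    chrom: str
    bp: int
    odds_ratio: float
    target_freq: dict | float = 0.2

    def freq_for(self, breed: str) -> float:
        if isinstance(self.target_freq, dict):
            return float(self.target_freq[breed])
        return float(self.target_freq)


@dataclass
class SimulationConfig:
    """Knobs of the breed-panel generator.

    Defaults mirror the study design the pipeline targets: three
    case/control GWAS breeds plus a 28-breed reference panel, each breed
    a bottlenecked population whose founder count controls inbreeding
    and LD length.  ``founders_per_breed`` may be a dict keyed by breed
    name to give breeds different bottleneck strengths (mirroring the
    greyhound < Rottweiler < Irish-wolfhound inbreeding ordering).
    """

    n_breeds_gwas: int = 3
    n_reference_breeds: int = 28
    founders_per_breed: int | dict = 50
    generations: int = 25
    samples_per_breed: int | dict = 100
    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    n_snps: int = 2000
    ancestral_pool_size: int = 200
    ancestral_maf_range: tuple = (0.05, 0.5)
    recombination_rate_per_bp: float = 1e-8
    ancestral_switch_rate_per_bp: float = 5e-8
    ancestral_mutation_prob: float = 0.2
    risk_loci: list = field(default_factory=list)
    baseline_prevalence: float = 0.5
    case_age_mean: float = 5.0
    control_age_mean: float = 9.0
    age_sd: float = 2.0
    planted_fixed_regions: dict = field(default_factory=dict)       # breed -> IntervalSet
    planted_low_variability_windows: dict = field(default_factory=dict)
    low_variability_freq: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if isinstance(self.founders_per_breed, dict):
            counts = list(self.founders_per_breed.values())
        else:
            counts = [self.founders_per_breed]
        if any(c <= 0 for c in counts):
            raise ValueError("founders_per_breed must be positive")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        for locus in self.risk_loci:
            if locus.odds_ratio <= 0:
                raise ValueError(f"odds ratio must be positive, got {locus.odds_ratio}")
            if not 1 <= locus.bp <= self.chrom_length_bp:
                raise ValueError(
                    f"risk locus bp {locus.bp} outside chromosome length "
                    f"{self.chrom_length_bp}"
                )

    def breed_names(self) -> list:
        gwas = [f"gwas{i + 1}" for i in range(self.n_breeds_gwas)]
        ref = [f"ref{i + 1}" for i in range(self.n_reference_breeds)]
        return gwas + ref

    def founders_for(self, breed: str) -> int:
        if isinstance(self.founders_per_breed, dict):
            return int(self.founders_per_breed[breed])
        return int(self.founders_per_breed)

    def samples_for(self, breed: str) -> int:
        if isinstance(self.samples_per_breed, dict):
            return int(self.samples_per_breed[breed])
        return int(self.samples_per_breed)


@dataclass
class SimulationTruth:
    """Everything needed to score recovery of planted structure."""

    risk_loci: list = field(default_factory=list)                    # RiskLocus
    risk_snp_ids: list = field(default_factory=list)
    realized_risk_freq: dict = field(default_factory=dict)           # breed -> {snp: freq}
    case_probability: dict = field(default_factory=dict)             # breed -> per-sample P(case)
    planted_fixed_regions: dict = field(default_factory=dict)        # breed -> IntervalSet
    planted_low_variability_windows: dict = field(default_factory=dict)
    cna_segments: dict = field(default_factory=dict)                 # sample -> list of dicts

    def to_json(self, path) -> None:
        def _iv(ivs: IntervalSet):
            return ivs.data.to_dict(orient="records")

        payload = {
            "risk_loci": [
                {"chrom": l.chrom, "bp": l.bp, "odds_ratio": l.odds_ratio}
                for l in self.risk_loci
            ],
            "risk_snp_ids": self.risk_snp_ids,
            "realized_risk_freq": self.realized_risk_freq,
            "case_probability": {k: list(map(float, v)) for k, v in self.case_probability.items()},
            "planted_fixed_regions": {k: _iv(v) for k, v in self.planted_fixed_regions.items()},
            "planted_low_variability_windows": {
                k: _iv(v) for k, v in self.planted_low_variability_windows.items()
            },
            "cna_segments": self.cna_segments,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ----------------------------------------------------------------------
# breed panel
# ----------------------------------------------------------------------

def _snp_positions(config: SimulationConfig, rng: np.random.Generator):
    """Shared SNP map: positions per chromosome, risk loci guaranteed present."""
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    chroms, positions = [], []
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        want = {l.bp for l in config.risk_loci if l.chrom == name}
        target = max(int(per_chrom[c]), len(want))
        pos = set(want)
        while len(pos) < target:
            for d in rng.integers(1, config.chrom_length_bp + 1, size=target - len(pos)):
                pos.add(int(d))
                if len(pos) == target:
                    break
        ordered = sorted(pos)
        chroms.extend([name] * len(ordered))
        positions.extend(ordered)
    return np.array(chroms), np.array(positions, dtype=np.int64)


def _ancestral_pool(config: SimulationConfig, chroms, positions, rng):
    """Haplotype pool built by a recombination-with-mutation copying chain.

    The first haplotype draws each allele from the ancestral frequency;
    each later haplotype copies a mosaic of earlier ones (template
    switches at a Poisson rate along the chromosome) and re-draws alleles
    at a small per-site mutation probability, creating correlated
    haplotypes with ancestral LD.
    """
    m = len(positions)
    lo, hi = config.ancestral_maf_range
    freqs = rng.uniform(lo, hi, size=m)
    pool = np.zeros((config.ancestral_pool_size, m), dtype=np.int8)
    for chrom in np.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        pos = positions[idx]
        p = freqs[idx]
        pool[0, idx] = rng.random(len(idx)) < p
        for h in range(1, config.ancestral_pool_size):
            span = pos[-1] - pos[0] + 1
            n_switch = rng.poisson(config.ancestral_switch_rate_per_bp * span)
            breaks = np.sort(rng.integers(pos[0], pos[-1] + 1, size=n_switch))
            seg_id = np.searchsorted(breaks, pos, side="right")
            templates = rng.integers(0, h, size=n_switch + 1)
            hap = pool[templates[seg_id], idx]
            mut = rng.random(len(idx)) < config.ancestral_mutation_prob
            hap[mut] = rng.random(mut.sum()) < p[mut]
            pool[h, idx] = hap
    return pool, freqs


def _plant_in_pool(config, breed, pool, chroms, positions, rng):
    """Seed breed-specific structure into that breed's founder pool copy."""
    pool = pool.copy()
    fixed = config.planted_fixed_regions.get(breed)
    if fixed is not None:
        for rec in fixed:
            mask = (chroms == rec.chrom) & (positions >= rec.start_bp) & (positions <= rec.end_bp)
            major = (pool[:, mask].mean(axis=0) >= 0.5).astype(np.int8)
            pool[:, mask] = major[None, :]
    lowvar = config.planted_low_variability_windows.get(breed)
    if lowvar is not None:
        for rec in lowvar:
            mask = (chroms == rec.chrom) & (positions >= rec.start_bp) & (positions <= rec.end_bp)
            pool[:, mask] = (
                rng.random((pool.shape[0], int(mask.sum()))) < config.low_variability_freq
            ).astype(np.int8)
    for locus in config.risk_loci:
        j = np.where((chroms == locus.chrom) & (positions == locus.bp))[0][0]
        pool[:, j] = (rng.random(pool.shape[0]) < locus.freq_for(breed)).astype(np.int8)
    return pool


def _recombine(hap_a, hap_b, positions, rate, rng):
    """One gamete: crossover mosaic of the two parental haplotypes."""
    span = positions[-1] - positions[0] + 1
    n_cross = rng.poisson(rate * span)
    if n_cross == 0:
        src = hap_a if rng.random() < 0.5 else hap_b
        return src.copy()
    breaks = np.sort(rng.integers(positions[0], positions[-1] + 1, size=n_cross))
    seg_id = np.searchsorted(breaks, positions, side="right")
    start = int(rng.integers(0, 2))
    use_a = (seg_id + start) % 2 == 0
    return np.where(use_a, hap_a, hap_b).astype(np.int8)


def _evolve_breed(config: SimulationConfig, breed: str, pool, chroms, positions, rng):
    """Found a breed from the pool and random-mate it for `generations`."""
    n_f = config.founders_for(breed)
    founder_idx = rng.integers(0, pool.shape[0], size=2 * n_f)
    haps = pool[founder_idx].copy()          # (2*n_f, m) haplotypes, paired per individual
    chrom_slices = [np.where(chroms == c)[0] for c in np.unique(chroms)]

    def _child(haps_parents, n_ind):
        mom, dad = rng.integers(0, n_ind, size=2)
        while dad == mom and n_ind > 1:
            dad = int(rng.integers(0, n_ind))
        gametes = []
        for parent in (mom, dad):
            g = np.empty(haps_parents.shape[1], dtype=np.int8)
            for idx in chrom_slices:
                g[idx] = _recombine(
                    haps_parents[2 * parent, idx], haps_parents[2 * parent + 1, idx],
                    positions[idx], config.recombination_rate_per_bp, rng,
                )
            gametes.append(g)
        return gametes

    for _ in range(config.generations):
        nxt = np.empty_like(haps[: 2 * n_f])
        for i in range(n_f):
            g1, g2 = _child(haps, n_f)
            nxt[2 * i], nxt[2 * i + 1] = g1, g2
        haps = nxt

    n_s = config.samples_for(breed)
    out = np.empty((2 * n_s, haps.shape[1]), dtype=np.int8)
    for i in range(n_s):
        g1, g2 = _child(haps, n_f)
        out[2 * i], out[2 * i + 1] = g1, g2
    return out[0::2] + out[1::2]             # (n_s, m) dosages of allele "1"


def simulate_breed_panel(config: SimulationConfig):
    """Simulate every breed in the panel.

    Returns ``(datasets, truth)`` where ``datasets`` maps breed name to a
    :class:`GenotypeDataset` (phenotypes unset; see
    :func:`assign_phenotypes`) and ``truth`` records the planted
    structure.  The same global seed always reproduces the same panel;
    each breed runs on a named substream so single breeds can be
    regenerated independently.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    map_rng = np.random.default_rng(root.spawn(1)[0])
    chroms, positions = _snp_positions(config, map_rng)
    pool, _ = _ancestral_pool(config, chroms, positions, map_rng)

    snp_ids = [f"snp_{c}_{p}" for c, p in zip(chroms, positions)]
    risk_ids = {
        (l.chrom, l.bp): f"snp_{l.chrom}_{l.bp}" for l in config.risk_loci
    }
    snps = make_snps(snp_ids, chroms, positions)

    truth = SimulationTruth(
        risk_loci=list(config.risk_loci),
        risk_snp_ids=[risk_ids[(l.chrom, l.bp)] for l in config.risk_loci],
        planted_fixed_regions=dict(config.planted_fixed_regions),
        planted_low_variability_windows=dict(config.planted_low_variability_windows),
    )

    datasets = {}
    for b_idx, breed in enumerate(config.breed_names()):
        # named substream: breed order is fixed by config, so each breed's
        # stream is reproducible in isolation
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(1 + b_idx,))
        )
        breed_pool = _plant_in_pool(config, breed, pool, chroms, positions, rng)
        dosages = _evolve_breed(config, breed, breed_pool, chroms, positions, rng)
        sample_ids = [f"{breed}_{i:04d}" for i in range(dosages.shape[0])]
        samples = make_samples(sample_ids, breed=[breed] * len(sample_ids))
        datasets[breed] = GenotypeDataset(samples, snps.copy(), dosages)
        freq = datasets[breed].allele1_freq()
        truth.realized_risk_freq[breed] = {
            sid: float(freq[snp_ids.index(sid)]) for sid in truth.risk_snp_ids
        }
    return datasets, truth


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def assign_phenotypes(
    dataset: GenotypeDataset,
    truth: SimulationTruth,
    baseline_prevalence: float = 0.5,
    case_age_mean: float = 5.0,
    control_age_mean: float = 9.0,
    age_sd: float = 2.0,
    seed: int = 0,
) -> GenotypeDataset:
    """Draw case/control status from the planted logistic risk model.

    ``P(case | g) = logistic(alpha + sum_l g_l * log OR_l)`` with the
    intercept ``alpha`` solved so the expected case fraction equals
    ``baseline_prevalence`` in this sample.  Ages are drawn so cases skew
    younger than controls (enabling the age-aware relatedness pruning
    rule).  The per-sample case probability is recorded in ``truth``.
    """
    rng = np.random.default_rng(seed)
    idx = dataset.snps.index.get_indexer(truth.risk_snp_ids)
    if np.any(idx < 0):
        missing = [s for s, i in zip(truth.risk_snp_ids, idx) if i < 0]
        raise ValueError(f"risk loci not present in dataset: {missing}")
    g = dataset.genotypes[:, idx].astype(float)
    log_or = np.log([l.odds_ratio for l in truth.risk_loci])
    score = g @ log_or if len(log_or) else np.zeros(dataset.n_samples)

    def case_frac(alpha):
        return special.expit(alpha + score).mean() - baseline_prevalence

    alpha = optimize.brentq(case_frac, -50, 50)
    prob = special.expit(alpha + score)
    is_case = rng.random(dataset.n_samples) < prob
    ages = np.where(
        is_case,
        rng.normal(case_age_mean, age_sd, dataset.n_samples),
        rng.normal(control_age_mean, age_sd, dataset.n_samples),
    )
    ages = np.clip(ages, 0.5, None)
    samples = dataset.samples.copy()
    samples["phenotype"] = np.where(is_case, "case", "control")
    samples["age_years"] = np.round(ages, 1)
    breed = samples["breed"].iloc[0] if samples["breed"].notna().any() else "breed"
    truth.case_probability[str(breed)] = prob.tolist()
    return GenotypeDataset(samples, dataset.snps, dataset.genotypes)


# ----------------------------------------------------------------------
# CGH cohort
# ----------------------------------------------------------------------

def simulate_cgh_cohort(
    n_samples: int,
    chrom_lengths: dict,
    probe_spacing_bp: int = 26_000,
    planted_segments: list | None = None,
    segment_mean_gain: float = 0.58,
    segment_mean_loss: float = -1.0,
    noise_sd: float = 0.15,
    background_aberration_rate: float = 0.002,
    background_len_probes: tuple = (3, 30),
    seed: int = 0,
):
    """Simulate tumor aCGH log2-ratio profiles on a regular probe grid.

    ``planted_segments`` is a list of dicts with keys ``chrom``,
    ``start_bp``, ``end_bp``, ``direction`` (``"gain"``/``"loss"``) and
    ``carriers`` (list of sample indices; omit for all samples) —
    recurrent aberrations shared across tumors.  On top of these a
    chaotic background is laid down: at each probe a background segment
    starts with probability ``background_aberration_rate`` per sample,
    with random direction and a random length in ``background_len_probes``.

    Returns ``(table, truth)``: a probe x sample DataFrame (columns
    probe_id/chrom/bp then one column per sample) and a
    :class:`SimulationTruth` whose ``cna_segments`` lists every planted
    segment per sample.
    """
    if probe_spacing_bp <= 0:
        raise ValueError("probe_spacing_bp must be positive")
    rng = np.random.default_rng(seed)
    chroms, bps = [], []
    for chrom, length in chrom_lengths.items():
        pos = np.arange(probe_spacing_bp // 2, length + 1, probe_spacing_bp)
        chroms.extend([chrom] * len(pos))
        bps.extend(pos.tolist())
    chroms = np.array(chroms)
    bps = np.array(bps, dtype=np.int64)
    n_probes = len(bps)
    sample_names = [f"tumor_{i:03d}" for i in range(n_samples)]
    ratios = rng.normal(0.0, noise_sd, size=(n_probes, n_samples))

    truth = SimulationTruth()
    truth.cna_segments = {s: [] for s in sample_names}
    for seg in planted_segments or []:
        mask = (chroms == seg["chrom"]) & (bps >= seg["start_bp"]) & (bps <= seg["end_bp"])
        mean = segment_mean_gain if seg["direction"] == "gain" else segment_mean_loss
        carriers = seg.get("carriers", list(range(n_samples)))
        for s in carriers:
            ratios[mask, s] += mean
            truth.cna_segments[sample_names[s]].append(
                {
                    "chrom": seg["chrom"],
                    "start_bp": int(bps[mask][0]),
                    "end_bp": int(bps[mask][-1]),
                    "direction": seg["direction"],
                    "planted": True,
                }
            )

    if background_aberration_rate > 0:
        lo, hi = background_len_probes
        chrom_end = {}
        for i, c in enumerate(chroms):
            chrom_end[c] = i + 1                # last probe index + 1 per chromosome
        for s in range(n_samples):
            starts = np.where(rng.random(n_probes) < background_aberration_rate)[0]
            for st in starts:
                ln = int(rng.integers(lo, hi + 1))
                direction = "gain" if rng.random() < 0.5 else "loss"
                mean = segment_mean_gain if direction == "gain" else segment_mean_loss
                end = min(st + ln, n_probes, chrom_end[chroms[st]])
                ratios[st:end, s] += mean

    table = pd.DataFrame(ratios, columns=sample_names)
    table.insert(0, "bp", bps)
    table.insert(0, "chrom", chroms)
    table.insert(0, "probe_id", [f"probe_{c}_{p}" for c, p in zip(chroms, bps)])
    table = table.set_index("probe_id")
    return table, truth
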