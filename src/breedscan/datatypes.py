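"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genomic coordinates are 1-based inclusive throughout (the PLINK/BIM
  convention); BED input is converted at the boundary.
* Genotypes are stored as the per-sample count of the A1 allele in
  {0, 1, 2}; missing calls use the sentinel :data:`MISSING` (never 0,
  which would silently bias allele frequencies).
* Phenotypes are categorical ``{"case", "control"}`` with NaN for
  missing; on-disk PLINK coding (2=case, 1=control, -9/0=missing) is
  translated by the readers and writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call (count-of-A1 scale)
MISSING: int = -1

SAMPLE_COLUMNS = ["breed", "phenotype", "sex", "age_years"]
SNP_COLUMNS = ["chrom", "bp", "a1", "a2"]


class FormatError(ValueError):
    """Malformed input file (dimension mismatch, bad field, bad line)."""


@dataclass
class GenotypeDataset:
    """Samples x SNPs genotype matrix with per-sample and per-SNP metadata.

    Parameters
    ----------
    samples : pandas.DataFrame
        Indexed by unique sample id with columns ``breed``, ``phenotype``
        (``"case"``/``"control"``/NaN), ``sex`` (``"F"``/``"M"``/NaN) and
        ``age_years`` (age at onset for cases, age last confirmed
        disease-free for controls; NaN when unknown).
    snps : pandas.DataFrame
        Indexed by unique SNP id with columns ``chrom``, ``bp`` (1-based),
        ``a1``, ``a2``.  Positions must be strictly increasing within each
        chromosome; :meth:`validate` sorts (with a warning) if not.
    genotypes : numpy.ndarray
        ``(n_samples, n_snps)`` int8 array of A1-allele counts, with
        :data:`MISSING` for no-calls.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples.index.to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps.index.to_numpy()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Enforce the container invariants, sorting SNPs if required."""
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise FormatError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.snps.index.has_duplicates:
            dup = self.snps.index[self.snps.index.duplicated()][0]
            raise FormatError(f"duplicate SNP id: {dup!r}")
        valid = np.isin(self.genotypes, [0, 1, 2, MISSING])
        if not valid.all():
            bad = self.genotypes[~valid][0]
            raise FormatError(f"genotype value {bad} outside {{0,1,2,missing}}")
        if self.n_snps > 1:
            order = self.snps.sort_values(["chrom", "bp"], kind="stable").index
            if not order.equals(self.snps.index):
                warnings.warn(
                    "SNPs not sorted by (chrom, bp); sorting", stacklevel=2
                )
                pos = self.snps.index.get_indexer(order)
                self.snps = self.snps.loc[order]
                self.genotypes = self.genotypes[:, pos]
            bp = self.snps["bp"].to_numpy()
            same = self.snps["chrom"].to_numpy()[1:] == self.snps["chrom"].to_numpy()[:-1]
            if np.any(same & (np.diff(bp) <= 0)):
                raise FormatError("duplicate bp position within a chromosome")

    # ------------------------------------------------------------------
    def allele1_freq(self) -> np.ndarray:
        """Per-SNP frequency of the A1 allele among non-missing calls."""
        g = self.genotypes.astype(float)
        g[self.genotypes == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return np.nanmean(g, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele1_freq()
        return np.minimum(p, 1.0 - p)

    def phenotype01(self) -> np.ndarray:
        """Phenotype as 0/1 (control/case) float with NaN for missing."""
        ph = self.samples["phenotype"]
        return ph.map({"control": 0.0, "case": 1.0}).to_numpy(dtype=float)

    def subset(self, sample_ids=None, snp_ids=None) -> "GenotypeDataset":
        """Return a copy restricted to the given samples and/or SNPs."""
        samples = self.samples if sample_ids is None else self.samples.loc[list(sample_ids)]
        snps = self.snps if snp_ids is None else self.snps.loc[list(snp_ids)]
        rows = self.samples.index.get_indexer(samples.index)
        cols = self.snps.index.get_indexer(snps.index)
        return GenotypeDataset(samples.copy(), snps.copy(), self.genotypes[np.ix_(rows, cols)].copy())


def concat_datasets(datasets) -> GenotypeDataset:
    """Stack datasets that share an identical SNP map (e.g. several
    breeds of one panel) into a single multi-breed dataset."""
    datasets = list(datasets)
    first = datasets[0]
    for ds in datasets[1:]:
        if not (
            first.snps.index.equals(ds.snps.index)
            and first.snps["chrom"].equals(ds.snps["chrom"])
            and first.snps["bp"].equals(ds.snps["bp"])
        ):
            raise ValueError("datasets do not share a SNP map")
    samples = pd.concat([ds.samples for ds in datasets])
    genotypes = np.vstack([ds.genotypes for ds in datasets])
    return GenotypeDataset(samples, first.snps.copy(), genotypes)


def make_samples(
    sample_ids,
    breed=None,
    phenotype=None,
    sex=None,
    age_years=None,
) -> pd.DataFrame:
    """Assemble a sample-metadata frame with the canonical columns."""
    n = len(sample_ids)

    def _col(x, default=np.nan):
        if x is None:
            return [default] * n
        return list(x)

    return pd.DataFrame(
        {
            "breed": _col(breed),
            "phenotype": _col(phenotype),
            "sex": _col(sex),
            "age_years": pd.array(_col(age_years), dtype=float),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def make_snps(snp_ids, chrom, bp, a1=None, a2=None) -> pd.DataFrame:
    n = len(snp_ids)
    return pd.DataFrame(
        {
            "chrom": list(chrom),
            "bp": np.asarray(bp, dtype=np.int64),
            "a1": list(a1) if a1 is not None else ["A"] * n,
            "a2": list(a2) if a2 is not None else ["G"] * n,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )


@dataclass
class IntervalSet:
    """Scored genomic intervals, 1-based inclusive on both ends."""

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start_bp", "end_bp", "label", "score"]))

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        """Build from an iterable of (chrom, start, end[, label[, score]])."""
        rows = []
        for rec in records:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            label = rec[3] if len(rec) > 3 else ""
            score = float(rec[4]) if len(rec) > 4 else np.nan
            if start > end:
                raise FormatError(f"interval start {start} > end {end} on {chrom}")
            rows.append((chrom, start, end, label, score))
        df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "label", "score"])
        return cls(df)

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self):
        return self.data.itertuples(index=False)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            self.data.sort_values(["chrom", "start_bp"], kind="stable").reset_index(drop=True)
        )

    def lengths(self) -> np.ndarray:
        """Inclusive lengths in bp."""
        return (self.data["end_bp"] - self.data["start_bp"] + 1).to_numpy()

    def total_bp(self) -> int:
        return int(self.lengths().sum())


@dataclass
class GeneSetCatalog:
    """Gene coordinates plus named gene sets with size bounds applied.

    ``sets`` holds only members present in the gene map; ``unmapped``
    records members that could not be located; ``dropped`` counts sets
    excluded by the size bounds after intersection with the map.
    """

    gene_map: pd.DataFrame            # index gene symbol; chrom, start_bp, end_bp
    sets: dict                        # name -> list of mapped gene symbols
    unmapped: dict = field(default_factory=dict)   # name -> list of unmapped symbols
    dropped: int = 0
    min_size: int = 10
    max_size: int = 2000

    def set_sizes(self) -> pd.Series:
        return pd.Series({k: len(v) for k, v in self.sets.items()}, dtype=int)


@dataclass
class KinshipMatrix:
    """Symmetric pairwise genetic-relationship estimates."""

    sample_ids: np.ndarray
    values: np.ndarray
    method: str = "grm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        # exact symmetry downstream (eigendecomposition)
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.sample_ids)


@dataclass
class StratifiedTables:
    """A stack of 2x2 count tables, one per stratum (typically breed).

    Each table is ``[[a, b], [c, d]]`` with rows = case/control (or
    gain/not-gain) and columns = risk allele / other allele.
    """

    strata: list
    tables: np.ndarray   # (K, 2, 2) non-negative integers

    def __post_init__(self) -> None:
        self.tables = np.asarray(self.tables, dtype=np.int64)
        if self.tables.ndim != 3 or self.tables.shape[1:] != (2, 2):
            raise ValueError("tables must have shape (K, 2, 2)")
        if len(self.strata) != self.tables.shape[0]:
            raise ValueError("strata labels do not match table count")
        if self.tables.shape[0] < 1:
            raise ValueError("at least one stratum required")
        if (self.tables < 0).any():
            raise ValueError("negative count in stratified table")
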