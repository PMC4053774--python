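"""Readers and writers for the interchange formats the pipeline consumes.

Supported formats: PLINK text (.ped/.map) and binary (.bed/.bim/.fam,
SNP-major), BED intervals (0-based half-open on disk, converted to the
package's 1-based inclusive convention), GMT gene sets, a 4-column gene
map TSV, and a covariates TSV carrying breed/age metadata that PLINK
files cannot hold.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    FormatError,
    GeneSetCatalog,
    GenotypeDataset,
    IntervalSet,
    make_samples,
    make_snps,
)

log = logging.getLogger(__name__)

PLINK_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


def _ext(prefix: Path, ext: str) -> Path:
    """``prefix`` + ``.ext`` without mangling dots inside the prefix name."""
    return prefix.parent / f"{prefix.name}.{ext}"


# 2-bit codes in a SNP-major .bed, low bits first within each byte:
# 00 -> A1/A1 (two copies of A1), 01 -> missing, 10 -> het, 11 -> A2/A2
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}

_PHENO_TO_DISK = {"control": "1", "case": "2"}
_DISK_TO_PHENO = {"1": "control", "2": "case", "-9": np.nan, "0": np.nan}
_SEX_TO_DISK = {"M": "1", "F": "2"}
_DISK_TO_SEX = {"1": "M", "2": "F", "0": np.nan}


# ----------------------------------------------------------------------
# PLINK
# ----------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    """Read a .map file; two trailing allele columns (A1 A2) are optional.

    The allele extension keeps the text dialect lossless: a bare 4-column
    map cannot say which allele the dosages count, so A1/A2 would have to
    be inferred from the .ped and the round trip could flip strands.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (3, 4, 6):
                raise FormatError(f"{path}: line {i}: expected 3, 4 or 6 fields, got {len(fields)}")
            chrom, snp_id = fields[0], fields[1]
            if len(fields) == 6:
                bp, a1, a2 = int(fields[3]), fields[4], fields[5]
            else:
                bp, a1, a2 = int(fields[-1]), None, None
            rows.append((snp_id, chrom, bp, a1, a2))
    return pd.DataFrame(
        rows, columns=["snp_id", "chrom", "bp", "a1", "a2"]
    ).set_index("snp_id")


def read_plink(path_prefix: str | Path, dialect: str = "binary") -> GenotypeDataset:
    """Load a PLINK fileset into a :class:`GenotypeDataset`.

    ``dialect`` selects ``"text"`` (.ped/.map) or ``"binary"``
    (.bed/.bim/.fam).  A1 is the first allele column of the map record;
    genotypes are A1-allele counts with a distinct missing sentinel.  If
    a sidecar ``<prefix>.covar`` exists its breed/age columns are merged.
    """
    prefix = Path(path_prefix)
    if dialect == "text":
        ds = _read_plink_text(prefix)
    elif dialect == "binary":
        ds = _read_plink_binary(prefix)
    else:
        raise ValueError(f"unknown PLINK dialect {dialect!r}")
    covar = _ext(prefix, "covar")
    if covar.exists():
        ds = attach_covariates(ds, covar)
    log.info("read %d samples x %d SNPs from %s (%s)", ds.n_samples, ds.n_snps, prefix, dialect)
    return ds


def _read_plink_text(prefix: Path) -> GenotypeDataset:
    snp_meta = _read_map(_ext(prefix, "map"))
    m = len(snp_meta)
    sample_ids, phenos, sexes = [], [], []
    # allele pair per SNP per sample; A1 defined as first non-missing allele seen
    allele_rows = []
    with open(_ext(prefix, "ped")) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{_ext(prefix, 'ped')}: line {i}: expected {6 + 2 * m} "
                    f"fields for {m} SNPs, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            sexes.append(_DISK_TO_SEX.get(fields[4], np.nan))
            phenos.append(_DISK_TO_PHENO.get(fields[5], np.nan))
            allele_rows.append(fields[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(max(len(sample_ids), 1), m, 2)
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    genotypes = np.full((len(sample_ids), m), MISSING, dtype=np.int8)
    map_a1 = snp_meta["a1"].to_numpy()
    map_a2 = snp_meta["a2"].to_numpy()
    for j in range(m):
        col = alleles[:, j, :] if sample_ids else np.empty((0, 2), dtype=object)
        seen = [x for x in pd.unique(col.ravel()) if x != "0"]
        if len(seen) > 2:
            raise FormatError(f"SNP {snp_meta.index[j]}: more than two alleles {seen}")
        if map_a1[j] is not None:
            a1[j], a2[j] = map_a1[j], map_a2[j]
        else:
            # bare 4-column map: fall back to order of appearance in the .ped
            a1[j] = seen[0] if seen else "A"
            a2[j] = seen[1] if len(seen) > 1 else ("G" if a1[j] != "G" else "A")
        if len(sample_ids):
            missing = (col == "0").any(axis=1)
            genotypes[:, j] = np.where(missing, MISSING, (col == a1[j]).sum(axis=1))
    samples = make_samples(sample_ids, phenotype=phenos, sex=sexes)
    snps = make_snps(snp_meta.index, snp_meta["chrom"], snp_meta["bp"], a1, a2)
    return GenotypeDataset(samples, snps, genotypes)


def _read_plink_binary(prefix: Path) -> GenotypeDataset:
    bim = []
    with open(_ext(prefix, "bim")) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6:
                raise FormatError(f"{_ext(prefix, 'bim')}: line {i}: expected 6 fields")
            bim.append((fields[1], fields[0], int(fields[3]), fields[4], fields[5]))
    fam_rows = []
    with open(_ext(prefix, "fam")) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6:
                raise FormatError(f"{_ext(prefix, 'fam')}: line {i}: expected 6 fields")
            fam_rows.append((fields[1], _DISK_TO_SEX.get(fields[4], np.nan),
                             _DISK_TO_PHENO.get(fields[5], np.nan)))
    n = len(fam_rows)
    m = len(bim)
    raw = _ext(prefix, "bed").read_bytes()
    if raw[:3] != PLINK_BED_MAGIC:
        raise FormatError(f"{_ext(prefix, 'bed')}: bad magic bytes (not SNP-major PLINK bed)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bytes_per_snp * m:
        raise FormatError(
            f"{_ext(prefix, 'bed')}: size {len(body)} bytes does not match "
            f"{m} SNPs x {bytes_per_snp} bytes"
        )
    body = body.reshape(m, bytes_per_snp)
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    genotypes = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    samples = make_samples(
        [r[0] for r in fam_rows], sex=[r[1] for r in fam_rows], phenotype=[r[2] for r in fam_rows]
    )
    snps = make_snps(
        [b[0] for b in bim], [b[1] for b in bim], [b[2] for b in bim],
        [b[3] for b in bim], [b[4] for b in bim],
    )
    return GenotypeDataset(samples, snps, genotypes)


def write_plink(dataset: GenotypeDataset, path_prefix: str | Path, dialect: str = "binary") -> None:
    """Write a dataset as PLINK files readable by :func:`read_plink`.

    Breed and age metadata go to a sidecar ``<prefix>.covar`` TSV (PLINK
    files have no fields for them).
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ph = dataset.samples["phenotype"].map(_PHENO_TO_DISK).fillna("-9")
    sex = dataset.samples["sex"].map(_SEX_TO_DISK).fillna("0")
    if dialect == "text":
        with open(_ext(prefix, "map"), "w") as fh:
            for snp_id, row in dataset.snps.iterrows():
                fh.write(f"{row['chrom']}\t{snp_id}\t0\t{row['bp']}\t{row['a1']}\t{row['a2']}\n")
        a1 = dataset.snps["a1"].to_numpy()
        a2 = dataset.snps["a2"].to_numpy()
        with open(_ext(prefix, "ped"), "w") as fh:
            for i, sid in enumerate(dataset.sample_ids):
                fields = [str(sid), str(sid), "0", "0", sex.iloc[i], ph.iloc[i]]
                g = dataset.genotypes[i]
                for j in range(dataset.n_snps):
                    fields.extend({
                        2: (a1[j], a1[j]),
                        1: (a1[j], a2[j]),
                        0: (a2[j], a2[j]),
                    }.get(int(g[j]), ("0", "0")))
                fh.write(" ".join(fields) + "\n")
    elif dialect == "binary":
        with open(_ext(prefix, "bim"), "w") as fh:
            for snp_id, row in dataset.snps.iterrows():
                fh.write(f"{row['chrom']}\t{snp_id}\t0\t{row['bp']}\t{row['a1']}\t{row['a2']}\n")
        with open(_ext(prefix, "fam"), "w") as fh:
            for i, sid in enumerate(dataset.sample_ids):
                fh.write(f"{sid} {sid} 0 0 {sex.iloc[i]} {ph.iloc[i]}\n")
        n, m = dataset.n_samples, dataset.n_snps
        bytes_per_snp = (n + 3) // 4
        code = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
        # index by dosage 0/1/2 and 3 (remapped missing sentinel)
        lut = np.array([_DOSAGE_TO_BED_CODE[0], _DOSAGE_TO_BED_CODE[1],
                        _DOSAGE_TO_BED_CODE[2], _DOSAGE_TO_BED_CODE[MISSING]], dtype=np.uint8)
        g = dataset.genotypes.T.copy()          # (m, n)
        g[g == MISSING] = 3
        code[:, :n] = lut[g]
        packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
        for k in range(4):
            packed |= code[:, k::4] << (2 * k)
        with open(_ext(prefix, "bed"), "wb") as fh:
            fh.write(PLINK_BED_MAGIC)
            fh.write(packed.tobytes())
    else:
        raise ValueError(f"unknown PLINK dialect {dialect!r}")
    write_covariates(dataset, _ext(prefix, "covar"))
    log.info("wrote %d samples x %d SNPs to %s (%s)",
             dataset.n_samples, dataset.n_snps, prefix, dialect)


# ----------------------------------------------------------------------
# Covariates sidecar
# ----------------------------------------------------------------------

def write_covariates(dataset: GenotypeDataset, path: str | Path) -> None:
    out = dataset.samples[["breed", "age_years"]].copy()
    out.to_csv(path, sep="\t", na_rep="NA")


def attach_covariates(dataset: GenotypeDataset, path: str | Path) -> GenotypeDataset:
    cov = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    missing = set(dataset.sample_ids) - set(cov.index)
    if missing:
        raise FormatError(f"covariate file {path} missing samples: {sorted(missing)[:5]}")
    cov = cov.loc[dataset.sample_ids]
    samples = dataset.samples.copy()
    for col in ("breed", "age_years"):
        if col in cov.columns:
            samples[col] = cov[col].to_numpy()
    return GenotypeDataset(samples, dataset.snps, dataset.genotypes)


# ----------------------------------------------------------------------
# BED intervals
# ----------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> IntervalSet:
    """Read a BED file, converting 0-based half-open to 1-based inclusive.

    Overlapping intervals are preserved unmerged.
    """
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i}: fewer than 3 BED columns")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            if start0 > end0:
                raise FormatError(f"{path}: line {i}: start {start0} > end {end0}")
            label = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 else np.nan
            records.append((chrom, start0 + 1, end0, label, score))
    return IntervalSet.from_records(records)


def write_bed_intervals(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in intervals:
            score = 0 if np.isnan(rec.score) else rec.score
            fh.write(f"{rec.chrom}\t{rec.start_bp - 1}\t{rec.end_bp}\t{rec.label}\t{score}\n")


# ----------------------------------------------------------------------
# Gene map + GMT
# ----------------------------------------------------------------------

def read_gene_map(path: str | Path) -> pd.DataFrame:
    """4-column TSV: gene symbol, chrom, start_bp, end_bp (1-based)."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene", "chrom", "start_bp", "end_bp"])
    if df["gene"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene symbol")
    return df.set_index("gene")


def read_gmt(path: str | Path, gene_map: pd.DataFrame,
             min_size: int = 10, max_size: int = 2000) -> GeneSetCatalog:
    """Read GMT gene sets, dropping sets outside ``[min_size, max_size]``
    after intersecting members with the gene map.

    Members absent from the map are kept on the side (``unmapped``) and do
    not count toward the size bounds.
    """
    sets: dict = {}
    unmapped: dict = {}
    dropped = 0
    seen_names: set = set()
    known = set(gene_map.index)
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i}: GMT needs name, description, members")
            name, members = fields[0], [g for g in fields[2:] if g]
            if name in seen_names:
                raise FormatError(f"{path}: duplicate set name {name!r}")
            seen_names.add(name)
            mapped = [g for g in members if g in known]
            extra = [g for g in members if g not in known]
            if not (min_size <= len(mapped) <= max_size):
                dropped += 1
                log.info("dropped set %s: %d mapped members outside [%d, %d]",
                         name, len(mapped), min_size, max_size)
                continue
            sets[name] = mapped
            if extra:
                unmapped[name] = extra
    return GeneSetCatalog(gene_map, sets, unmapped, dropped, min_size, max_size)


def write_gmt(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in catalog.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ----------------------------------------------------------------------
# CGH tables
# ----------------------------------------------------------------------

def read_cgh_table(path: str | Path) -> pd.DataFrame:
    """Probe x sample log2-ratio TSV with columns probe_id, chrom, bp, <samples...>."""
    df = pd.read_csv(path, sep="\t")
    for col in ("probe_id", "chrom", "bp"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df.set_index("probe_id")


def write_cgh_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True)
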