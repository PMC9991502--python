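"""Genotype / phenotype / map / gene-list readers and writers, plus marker QC.

Genotype tables are samples x markers dosage matrices coded 0/1/2 (fractional
after imputation), with an optional marker map (chromosome, 1-based bp
position).  Two on-disk dialects are supported: delimited text (tab or comma,
sniffed; header row mandatory; first column holds sample ids; missing cells
written as ``NA``) and the PLINK bed/bim/fam triple (SNP-major 2-bit codec,
dosage = count of the A1 allele).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeBlock",
    "GeneTable",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_gene_table",
    "filter_markers",
    "write_effect_table",
    "read_effect_table",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file is malformed."""


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with map and missing mask.

    ``dosages`` are stored as float64 with NaN at missing cells; the boolean
    ``missing_mask`` mirrors the NaN pattern.  Positions are 1-based bp.
    """

    dosages: np.ndarray  # (n, p) float, NaN where missing
    sample_ids: np.ndarray  # (n,) str
    marker_ids: np.ndarray  # (p,) str
    chromosome: np.ndarray | None = None  # (p,) str
    position_bp: np.ndarray | None = None  # (p,) int, 1-based

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.marker_ids) != p:
            raise ValueError("marker_ids length does not match dosage columns")
        if len(set(self.marker_ids)) != p:
            raise ValueError("marker ids must be unique")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValueError("observed dosages must lie in [0, 2]")
        if self.chromosome is not None:
            self.chromosome = np.asarray(self.chromosome, dtype=object)
        if self.position_bp is not None:
            self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
            if self.position_bp.size and self.position_bp.min() < 1:
                raise ValueError("positions are 1-based and must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker, missing cells ignored.

        f = mean(dosage)/2 over observed cells; MAF = min(f, 1-f).
        Fully-missing markers get NaN.
        """
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per marker."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            sample_ids=self.sample_ids,
            marker_ids=self.marker_ids[index],
            chromosome=None if self.chromosome is None else self.chromosome[index],
            position_bp=None if self.position_bp is None else self.position_bp[index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            sample_ids=self.sample_ids[index],
            marker_ids=self.marker_ids,
            chromosome=self.chromosome,
            position_bp=self.position_bp,
        )


@dataclass
class PhenotypeBlock:
    """Samples x traits observation matrix with a designated focal trait."""

    values: np.ndarray  # (n, t) float, NaN missing
    sample_ids: np.ndarray
    trait_ids: np.ndarray
    focal_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.trait_ids = np.asarray(self.trait_ids, dtype=object)
        n, t = self.values.shape
        if len(self.sample_ids) != n or len(self.trait_ids) != t:
            raise ValueError("id lengths do not match value matrix")
        if not (0 <= self.focal_index < t):
            raise ValueError(f"focal_index {self.focal_index} out of range for {t} traits")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def focal(self) -> np.ndarray:
        return self.values[:, self.focal_index]


@dataclass
class GeneTable:
    """Gene intervals: id, chromosome, start/end bp (1-based inclusive)."""

    gene_ids: np.ndarray
    chromosome: np.ndarray
    start_bp: np.ndarray
    end_bp: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.start_bp = np.asarray(self.start_bp, dtype=np.int64)
        self.end_bp = np.asarray(self.end_bp, dtype=np.int64)
        if np.any(self.start_bp > self.end_bp):
            raise ValueError("gene start must be <= end")


# ---------------------------------------------------------------------------
# delimited dialect

def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_delimited_genotypes(path: str, map_path: str | None) -> GenotypeMatrix:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"], dtype=str)
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise GenotypeParseError(f"{path}: non-numeric dosage cell ({exc})") from exc
    obs = values[~np.isnan(values)]
    bad = obs[(obs < 0) | (obs > 2)]
    if bad.size:
        raise GenotypeParseError(f"{path}: dosage {bad[0]} outside [0, 2]")
    chrom = pos = None
    if map_path is not None:
        mp = pd.read_csv(map_path, sep=_sniff_sep(map_path), dtype=str)
        mp = mp.set_index(mp.columns[0]).loc[df.columns]
        chrom = mp.iloc[:, 0].to_numpy()
        pos = mp.iloc[:, 1].astype(int).to_numpy()
    return GenotypeMatrix(
        dosages=values,
        sample_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
        chromosome=chrom,
        position_bp=pos,
    )


def _write_delimited_genotypes(G: GenotypeMatrix, path: str, map_path: str | None) -> None:
    df = pd.DataFrame(G.dosages, index=G.sample_ids, columns=G.marker_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA")
    if map_path is not None:
        if G.chromosome is None or G.position_bp is None:
            raise ValueError("genotype matrix has no map to write")
        pd.DataFrame(
            {"marker": G.marker_ids, "chromosome": G.chromosome, "position_bp": G.position_bp}
        ).to_csv(map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam codec (SNP-major; dosage counts the A1 allele)

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit genotype codes in a SNP-major .bed, value -> A1 dosage
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_BED_CODE = {2.0: 0, 1.0: 2, 0.0: 3}


def _read_plink(prefix: str) -> GenotypeMatrix:
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"PLINK triple incomplete: missing {prefix + ext}")
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None, dtype=str)
    n, p = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise GenotypeParseError(f"{prefix}.bed: bad magic bytes (not SNP-major bed)")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    stride = (n + 3) // 4
    if raw.size != stride * p:
        raise GenotypeParseError(
            f"{prefix}.bed: expected {stride * p} genotype bytes, found {raw.size}"
        )
    raw = raw.reshape(p, stride)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((p, stride * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (raw >> (2 * shift)) & 0b11
    dosages = _BED_CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=fam.iloc[:, 1].to_numpy(dtype=object),
        marker_ids=bim.iloc[:, 1].to_numpy(dtype=object),
        chromosome=bim.iloc[:, 0].to_numpy(dtype=object),
        position_bp=bim.iloc[:, 3].astype(int).to_numpy(),
    )


def _write_plink(G: GenotypeMatrix, prefix: str) -> None:
    obs = G.dosages[~np.isnan(G.dosages)]
    if obs.size and np.any(obs != np.round(obs)):
        raise ValueError("PLINK bed cannot represent fractional dosages")
    n, p = G.dosages.shape
    codes = np.full((p, n), 1, dtype=np.uint8)  # 01 = missing
    for dose, code in _DOSAGE_TO_BED_CODE.items():
        codes[(G.dosages == dose).T] = code
    stride = (n + 3) // 4
    padded = np.zeros((p, stride * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = np.zeros((p, stride), dtype=np.uint8)
    for shift in range(4):
        packed |= padded[:, shift::4] << (2 * shift)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    chrom = G.chromosome if G.chromosome is not None else np.repeat("1", p)
    pos = G.position_bp if G.position_bp is not None else np.arange(1, p + 1)
    with open(prefix + ".bim", "w") as fh:
        for i in range(p):
            fh.write(f"{chrom[i]}\t{G.marker_ids[i]}\t0\t{pos[i]}\tA\tB\n")
    with open(prefix + ".fam", "w") as fh:
        for sid in G.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")


def read_genotype_table(path: str, format: str = "delimited", map_path: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from disk.

    Parameters
    ----------
    path
        Delimited table path, or the PLINK prefix (without extension).
    format
        ``"delimited"`` or ``"plink"``.
    map_path
        Optional marker map (marker, chromosome, position_bp) for the
        delimited dialect; ignored for PLINK where the .bim carries the map.
    """
    if format == "delimited":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        return _read_delimited_genotypes(path, map_path)
    if format == "plink":
        return _read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotype_table(G: GenotypeMatrix, path: str, format: str = "delimited", map_path: str | None = None) -> None:
    if format == "delimited":
        _write_delimited_genotypes(G, path, map_path)
    elif format == "plink":
        _write_plink(G, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def read_phenotype_table(path: str, focal: str | int = 0) -> PhenotypeBlock:
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, na_values=["NA"])
    if isinstance(focal, str):
        focal = list(df.columns).index(focal)
    return PhenotypeBlock(
        values=df.to_numpy(dtype=float),
        sample_ids=df.index.to_numpy(dtype=object),
        trait_ids=df.columns.to_numpy(dtype=object),
        focal_index=int(focal),
    )


def write_phenotype_table(P: PhenotypeBlock, path: str) -> None:
    df = pd.DataFrame(P.values, index=P.sample_ids, columns=P.trait_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_gene_table(path: str) -> GeneTable:
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if df.shape[1] < 4:
        raise GenotypeParseError(f"{path}: gene table needs 4 columns (gene, chrom, start, end)")
    return GeneTable(
        gene_ids=df.iloc[:, 0].to_numpy(dtype=object),
        chromosome=df.iloc[:, 1].to_numpy(dtype=object),
        start_bp=df.iloc[:, 2].astype(int).to_numpy(),
        end_bp=df.iloc[:, 3].astype(int).to_numpy(),
    )


# ---------------------------------------------------------------------------
# marker QC

def filter_markers(G: GenotypeMatrix, rule: str = "wheat") -> GenotypeMatrix:
    """Apply per-marker QC.

    ``wheat``: drop markers with call rate <= 0.5 or MAF <= 0.05, then impute
    remaining missing dosages by the marker mean.  ``arabidopsis``: drop
    markers with MAF <= 0.05 or missing rate >= 0.1; no imputation.
    Inequalities are applied exactly as stated (boundary values removed).
    """
    maf = G.maf()
    cr = G.call_rate()
    miss_rate = G.missing_mask.mean(axis=0)  # not 1-cr: keeps the boundary exact
    with np.errstate(invalid="ignore"):
        if rule == "wheat":
            keep = (cr > 0.5) & (maf > 0.05)
        elif rule == "arabidopsis":
            keep = (maf > 0.05) & (miss_rate < 0.1)
        else:
            raise ValueError(f"unknown QC rule {rule!r}")
    keep &= ~np.isnan(maf)  # fully-missing markers out under either rule
    if not keep.any():
        raise ValueError(f"marker QC ({rule}) removed every marker")
    out = G.subset_markers(np.where(keep)[0])
    if rule == "wheat" and np.isnan(out.dosages).any():
        dos = out.dosages.copy()
        col_mean = np.nanmean(dos, axis=0)
        miss = np.isnan(dos)
        dos[miss] = np.broadcast_to(col_mean, dos.shape)[miss]
        out = replace(out, dosages=dos)
    return out


# ---------------------------------------------------------------------------
# result tables

_EFFECT_COLUMNS = [
    "marker_id",
    "chromosome",
    "position_bp",
    "estimate",
    "explained_variance",
    "explained_proportion",
    "significant",
]


def write_effect_table(results: pd.DataFrame, path: str) -> None:
    """Write a marker-effect result table (tab-delimited, fixed column order).

    NaN estimates are serialized as ``NA``.  Missing optional columns are
    filled with NA so the column order is deterministic and round-trips.
    """
    df = results.copy()
    for col in _EFFECT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[_EFFECT_COLUMNS]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_effect_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
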