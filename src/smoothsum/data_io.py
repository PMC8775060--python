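"""Readers, writers and harmonization for GWAS summary statistics and genotypes.

Supports delimited summary-statistics text with a configurable column
map, PLINK 1 bed/bim/fam triples (two-bit SNP-major encoding, read and
written directly), and a plain dosage TSV.  Also houses the
standardization used throughout (center each dosage column, scale to unit
L2 norm, so the implied LD matrix has unit diagonal and correlations are
commensurable) and the conversion of summary effect sizes to SNP-wise
correlations via the t-statistic identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import HarmonizationError, ParameterError, SchemaError, ShapeError

__all__ = [
    "SummaryStatsTable",
    "GenotypePanel",
    "Standardized",
    "HarmonizationResult",
    "read_summary_stats",
    "write_summary_stats",
    "read_genotypes",
    "write_genotypes",
    "harmonize",
    "standardize",
    "apply_standardization",
    "beta_to_correlation",
]

REQUIRED_COLUMNS = ("chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue")
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})
_BASES = {"A", "C", "G", "T"}


def _variant_key(chrom, pos, a1: str, a2: str) -> str:
    """Canonical variant key: chromosome:position:sorted-allele-pair."""
    alleles = ":".join(sorted([str(a1).upper(), str(a2).upper()]))
    return f"{chrom}:{int(pos)}:{alleles}"


@dataclass
class SummaryStatsTable:
    """Per-variant GWAS summary statistics.

    The underlying frame has columns chrom, pos (1-based), effect_allele,
    other_allele, beta, se (> 0), pvalue in (0, 1], and optionally n_gwas.
    Each record is keyed by (chromosome, position, allele pair).
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(
                f"summary statistics missing columns {missing}; "
                f"found {list(self.frame.columns)}"
            )
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def keys(self) -> pd.Series:
        return self.frame.apply(
            lambda row: _variant_key(
                row["chrom"], row["pos"], row["effect_allele"], row["other_allele"]
            ),
            axis=1,
        )


@dataclass
class GenotypePanel:
    """Sample x variant dosage matrix with variant metadata.

    ``dosages`` holds values in [0, 2] counting copies of allele ``a1``
    (hard calls or mean-imputed); ``variants`` is a frame with columns
    chrom, pos, a1 (counted allele), a2.
    """

    dosages: np.ndarray = field(repr=False)
    sample_ids: Sequence[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ShapeError("dosages must be a 2-D samples x variants matrix")
        n, p = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ShapeError(f"{len(self.sample_ids)} sample ids for {n} dosage rows")
        if len(self.variants) != p:
            raise ShapeError(f"{len(self.variants)} variant records for {p} columns")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_keys(self) -> pd.Series:
        return self.variants.apply(
            lambda row: _variant_key(row["chrom"], row["pos"], row["a1"], row["a2"]),
            axis=1,
        )


# ---------------------------------------------------------------------------
# summary statistics


def read_summary_stats(
    path: Union[str, Path],
    column_map: Optional[Dict[str, str]] = None,
    sep: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file.

    ``column_map`` maps canonical names (chrom, pos, effect_allele,
    other_allele, beta, se, pvalue, optionally n_gwas) to the file's
    column headers; canonical headers are assumed where omitted.  Rows
    failing type or range checks (se <= 0, pvalue outside (0, 1],
    non-base alleles, non-integer positions) are dropped with a counted
    warning.
    """
    raw = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"required columns {missing} not found in {path}; "
            f"file has {list(raw.columns)}"
        )
    keep = [c for c in raw.columns if c in REQUIRED_COLUMNS + ("n_gwas",)]
    df = raw[keep].copy()

    n_in = len(df)
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for col in ("beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    ok = (
        df["pos"].notna()
        & (df["pos"] == df["pos"].round())
        & (df["pos"] > 0)
        & df["beta"].notna()
        & np.isfinite(df["beta"])
        & df["se"].notna()
        & (df["se"] > 0)
        & df["pvalue"].notna()
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
        & df["effect_allele"].isin(_BASES)
        & df["other_allele"].isin(_BASES)
    )
    if "n_gwas" in df.columns:
        df["n_gwas"] = pd.to_numeric(df["n_gwas"], errors="coerce")
    dropped = int(n_in - ok.sum())
    if dropped:
        warnings.warn(
            f"dropped {dropped} of {n_in} summary-statistics rows failing "
            "type/range validation",
            stacklevel=2,
        )
    df = df.loc[ok].copy()
    df["pos"] = df["pos"].astype(int)
    return SummaryStatsTable(frame=df)


def write_summary_stats(table: SummaryStatsTable, path: Union[str, Path]) -> None:
    """Write a summary-statistics table as TSV (17 significant digits)."""
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = bytes([0x01])
# two-bit genotype codes -> dosage of allele A1; 0b01 is the missing code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _read_bed_triple(prefix: Path) -> GenotypePanel:
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None)
    sample_ids = fam_df.iloc[:, 1].astype(str).tolist()
    bim_df = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "a1": str, "a2": str},
    )
    n, p = len(sample_ids), len(bim_df)

    data = bed.read_bytes()
    if data[:2] != _BED_MAGIC:
        raise SchemaError(f"{bed} is not a PLINK bed file (bad magic bytes)")
    if data[2:3] != _BED_SNP_MAJOR:
        raise SchemaError(f"{bed} is not in SNP-major order")
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * p
    if len(data) != expected:
        raise SchemaError(
            f"{bed} has {len(data)} bytes; {expected} expected for "
            f"{n} samples x {p} variants (fam/bim row counts inconsistent?)"
        )
    body = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(p, bytes_per_variant)
    # unpack the four 2-bit codes per byte, sample 0 in the low bits
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()  # (n, p)

    variants = bim_df[["chrom", "pos", "a1", "a2"]].copy()
    return _impute_missing(GenotypePanel(dosages, sample_ids, variants))


def _impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Mean-impute missing calls per variant; reject all-missing variants."""
    X = panel.dosages
    miss = np.isnan(X)
    if miss.any():
        n_obs = (~miss).sum(axis=0)
        if np.any(n_obs == 0):
            bad = np.flatnonzero(n_obs == 0)
            raise SchemaError(f"variants {bad.tolist()} have 100% missingness")
        col_mean = np.nansum(X, axis=0) / n_obs
        idx = np.nonzero(miss)
        X[idx] = col_mean[idx[1]]
        warnings.warn(
            f"mean-imputed {int(miss.sum())} missing genotype calls",
            stacklevel=3,
        )
    return panel


def _read_dosage_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    records = []
    for col in df.columns:
        parts = str(col).split(":")
        if len(parts) != 4:
            raise SchemaError(
                f"dosage TSV column {col!r} is not a chrom:pos:a1:a2 variant key"
            )
        records.append(
            {"chrom": parts[0], "pos": int(parts[1]), "a1": parts[2], "a2": parts[3]}
        )
    panel = GenotypePanel(
        dosages=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        variants=pd.DataFrame(records),
    )
    return _impute_missing(panel)


def read_genotypes(path: Union[str, Path]) -> GenotypePanel:
    """Read a genotype panel from PLINK bed/bim/fam or a dosage TSV.

    ``path`` may be the .bed file, the triple's common prefix, or a .tsv
    dosage matrix (first column sample id, variant-key header
    chrom:pos:a1:a2).  Missing calls are imputed to the variant mean.
    """
    path = Path(path)
    if path.suffix == ".tsv":
        return _read_dosage_tsv(path)
    prefix = path.with_suffix("") if path.suffix == ".bed" else path
    if prefix.with_suffix(".bed").exists():
        return _read_bed_triple(prefix)
    raise FileNotFoundError(f"no genotype input found at {path}")


def write_genotypes(
    panel: GenotypePanel, path: Union[str, Path], fmt: Optional[str] = None
) -> None:
    """Write a panel as PLINK bed/bim/fam (hard calls) or dosage TSV.

    ``fmt`` is "bed" or "tsv"; inferred from the suffix when omitted.
    The bed writer requires hard calls in {0, 1, 2} (NaN becomes the
    missing code).
    """
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix == ".tsv" else "bed"
    if fmt == "tsv":
        cols = [
            f"{r.chrom}:{r.pos}:{r.a1}:{r.a2}" for r in panel.variants.itertuples()
        ]
        df = pd.DataFrame(panel.dosages, index=list(panel.sample_ids), columns=cols)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", float_format="%.17g")
        return
    if fmt != "bed":
        raise ParameterError(f"unknown genotype format {fmt!r}")

    prefix = path.with_suffix("") if path.suffix == ".bed" else path
    n, p = panel.n, panel.p
    X = panel.dosages
    finite = X[np.isfinite(X)]
    if not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
        raise ParameterError("bed output requires hard calls in {0, 1, 2}")

    bytes_per_variant = (n + 3) // 4
    body = np.zeros((p, bytes_per_variant), dtype=np.uint8)
    for j in range(p):
        codes = np.full(bytes_per_variant * 4, 0b01, dtype=np.uint8)
        col = X[:, j]
        for value, code in _DOSAGE_TO_CODE.items():
            codes[:n][col == value] = code
        codes[n:] = 0b00  # pad bits
        packed = (
            codes[0::4] | (codes[1::4] << 2) | (codes[2::4] << 4) | (codes[3::4] << 6)
        )
        body[j] = packed
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR + body.tobytes())

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in panel.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for i, r in enumerate(panel.variants.itertuples()):
            fh.write(f"{r.chrom}\tvar{i + 1}\t0\t{r.pos}\t{r.a1}\t{r.a2}\n")


# ---------------------------------------------------------------------------
# harmonization


@dataclass
class HarmonizationResult:
    """Summary-statistics effects aligned to a genotype panel's allele coding."""

    beta: np.ndarray = field(repr=False)  # aligned effect sizes
    kept_index: np.ndarray = field(repr=False)  # panel column indices kept
    table: pd.DataFrame = field(repr=False)  # aligned stats rows (beta flipped)
    n_flipped: int = 0
    n_ambiguous: int = 0
    n_mismatched: int = 0


def harmonize(stats: SummaryStatsTable, panel: GenotypePanel) -> HarmonizationResult:
    """Align summary-statistics effect alleles to the panel's counted allele.

    Variants are matched on (chromosome, position).  If the stats effect
    allele equals the panel's counted allele (a1) the effect size is kept;
    if the allele pair is swapped the sign is flipped; strand-ambiguous
    pairs (A/T, C/G) and allele-set mismatches are dropped with counts.
    """
    sf = stats.frame.copy()
    sf["chrom"] = sf["chrom"].astype(str)
    pv = panel.variants.copy()
    pv["chrom"] = pv["chrom"].astype(str)
    pv["panel_idx"] = np.arange(len(pv))
    merged = sf.merge(pv, on=["chrom", "pos"], how="inner", suffixes=("", "_panel"))
    if merged.empty:
        raise HarmonizationError(
            "no overlapping variants between summary statistics and panel"
        )

    ea = merged["effect_allele"].str.upper()
    oa = merged["other_allele"].str.upper()
    a1 = merged["a1"].str.upper()
    a2 = merged["a2"].str.upper()

    ambiguous = [{e, o} in _AMBIGUOUS_PAIRS for e, o in zip(ea, oa)]
    ambiguous = np.array(ambiguous, dtype=bool)
    same = (ea == a1) & (oa == a2)
    swapped = (ea == a2) & (oa == a1)
    usable = (same | swapped) & ~ambiguous
    n_ambiguous = int((ambiguous & (same | swapped)).sum())
    n_mismatched = int((~(same | swapped)).sum())
    n_flipped = int((swapped & usable).sum())
    if n_ambiguous or n_mismatched:
        warnings.warn(
            f"harmonize dropped {n_ambiguous} strand-ambiguous and "
            f"{n_mismatched} allele-mismatched variants",
            stacklevel=2,
        )
    if not usable.any():
        raise HarmonizationError("no variants left after allele harmonization")

    kept = merged.loc[usable].copy()
    flip = (kept["effect_allele"].str.upper() == kept["a2"].str.upper()).to_numpy()
    kept["beta"] = np.where(flip, -kept["beta"], kept["beta"])
    kept["effect_allele"] = kept["a1"]
    kept["other_allele"] = kept["a2"]
    # keep at most one stats record per panel column
    kept = kept.drop_duplicates(subset="panel_idx", keep="first")
    keep_cols = [c for c in kept.columns if c in REQUIRED_COLUMNS + ("n_gwas",)]
    return HarmonizationResult(
        beta=kept["beta"].to_numpy(dtype=float),
        kept_index=kept["panel_idx"].to_numpy(dtype=int),
        table=kept[keep_cols].reset_index(drop=True),
        n_flipped=n_flipped,
        n_ambiguous=n_ambiguous,
        n_mismatched=n_mismatched,
    )


# ---------------------------------------------------------------------------
# standardization and correlation conversion


@dataclass
class Standardized:
    """A column-standardized matrix with its transformation recorded.

    ``x`` has columns centered and scaled to unit L2 norm, so
    ``diag(x^T x) = 1``; ``kept`` maps the columns of ``x`` back to the
    input (zero-variance columns are dropped).
    """

    x: np.ndarray = field(repr=False)
    center: np.ndarray = field(repr=False)
    scale: np.ndarray = field(repr=False)
    kept: np.ndarray = field(repr=False)


def standardize(X: np.ndarray) -> Standardized:
    """Center each column and scale it to unit L2 norm.

    Zero-variance columns are dropped with a warning; an all-constant
    matrix raises.  The resulting implied LD matrix has unit diagonal,
    making SNP-wise correlations and LD commensurable.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError("X must be 2-D")
    center = X.mean(axis=0)
    Xc = X - center
    scale = np.linalg.norm(Xc, axis=0)
    kept = np.flatnonzero(scale > 0)
    if kept.size == 0:
        raise ShapeError("all columns are constant; nothing to standardize")
    if kept.size < X.shape[1]:
        warnings.warn(
            f"dropped {X.shape[1] - kept.size} zero-variance columns",
            stacklevel=2,
        )
    return Standardized(
        x=Xc[:, kept] / scale[kept],
        center=center[kept],
        scale=scale[kept],
        kept=kept,
    )


def apply_standardization(X_new: np.ndarray, std: Standardized) -> np.ndarray:
    """Apply stored (training) centers/scales to new data."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] < std.kept.max() + 1:
        raise ShapeError(
            f"new matrix has {X_new.shape[1] if X_new.ndim == 2 else '?'} columns; "
            f"at least {std.kept.max() + 1} required"
        )
    return (X_new[:, std.kept] - std.center) / std.scale


def beta_to_correlation(beta, se, n_gwas) -> np.ndarray:
    """Convert a marginal-regression effect size to a correlation.

    Uses the t-statistic identity ``r = t / sqrt(n - 2 + t^2)`` with
    ``t = beta / se``, which for a simple linear regression reproduces the
    Pearson correlation of the variant with the outcome exactly.  Output
    is strictly inside (-1, 1) and odd in beta.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n_gwas, dtype=float)
    if np.any(se <= 0):
        raise ParameterError("se must be positive")
    if np.any(n < 3):
        raise ParameterError("n_gwas must be at least 3")
    t = beta / se
    r = t / np.sqrt(n - 2.0 + t * t)
    return float(r) if r.ndim == 0 else r
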