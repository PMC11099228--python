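"""Reading, validating and writing GWAS summary-statistic tables and LD matrices.

All tabular input to the pipeline flows through this module.  A summary-
statistic table is a tab-separated file with one row per variant carrying the
per-SNP association with a single trait: effect size (log odds ratio for
binary traits, SD units for continuous ones), its standard error, effect-
allele frequency, p-value and sample size.  Column names default to a
GWAS-SSF-like dialect and can be remapped with ``column_map`` to accommodate
the heterogeneous exports found in public GWAS repositories.

Only biallelic SNPs are handled: alleles must be single characters from
{A, C, G, T}; indels and multi-allelic records are dropped during validation.
Positions are 1-based and used only as metadata for distance windows during
clumping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order for summary-statistic tables
COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

VALID_ALLELES = frozenset("ACGT")


class InputError(ValueError):
    """Malformed or out-of-contract input data."""


class ConfigError(ValueError):
    """Missing or inconsistent configuration (e.g. a column mapping)."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association with one trait."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int


@dataclass
class ValidationReport:
    """Counts of rows dropped per hard invariant during validation."""

    n_input: int = 0
    n_dropped: int = 0
    reasons: dict = field(default_factory=dict)
    n_pvalue_warnings: int = 0


@dataclass
class SummaryDataset:
    """A validated set of per-variant associations for one trait.

    The canonical in-memory container is a :class:`pandas.DataFrame` with the
    columns in :data:`COLUMNS`; ``records`` materialises it as
    :class:`VariantAssociation` objects when object-level access is wanted.
    """

    trait_id: str
    table: pd.DataFrame
    trait_label: str = ""
    trait_scale: str = "continuous"  # {"log_odds", "continuous"}
    validation: ValidationReport = field(default_factory=ValidationReport)

    def __post_init__(self) -> None:
        if self.trait_scale not in ("log_odds", "continuous"):
            raise ConfigError(f"unknown trait_scale {self.trait_scale!r}")
        if not self.trait_label:
            self.trait_label = self.trait_id
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"]
            raise InputError(
                f"duplicate snp_id in dataset {self.trait_id!r}: {sorted(set(dups))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> list[VariantAssociation]:
        return [
            VariantAssociation(
                snp_id=r.snp_id, chrom=str(r.chrom), pos=int(r.pos),
                effect_allele=r.effect_allele, other_allele=r.other_allele,
                eaf=float(r.eaf), beta=float(r.beta), se=float(r.se),
                pvalue=float(r.pvalue), n=int(r.n),
            )
            for r in self.table.itertuples(index=False)
        ]

    @classmethod
    def from_records(cls, trait_id: str, records: Iterable[VariantAssociation],
                     **kw) -> "SummaryDataset":
        df = pd.DataFrame([vars(r) for r in records], columns=COLUMNS)
        return cls(trait_id=trait_id, table=df, **kw)

    def subset(self, snp_ids: Sequence[str]) -> "SummaryDataset":
        """Rows for the given SNPs, in the given order."""
        idx = self.table.set_index("snp_id")
        sub = idx.loc[list(snp_ids)].reset_index()[COLUMNS]
        return SummaryDataset(self.trait_id, sub, trait_label=self.trait_label,
                              trait_scale=self.trait_scale)


def validate_table(df: pd.DataFrame, trait_id: str = "") -> tuple[pd.DataFrame, ValidationReport]:
    """Enforce the hard per-row invariants, dropping offending rows.

    Alleles are upper-cased before validation (case is presentational).  A
    p-value that disagrees with the Wald p implied by |beta/se| by more than
    two orders of magnitude raises a logged warning but does not drop the row:
    rounded p-values in public exports routinely disagree at that level.
    """
    rep = ValidationReport(n_input=len(df))
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    checks = {
        "bad_allele": ~(
            df["effect_allele"].isin(VALID_ALLELES)
            & df["other_allele"].isin(VALID_ALLELES)
        ),
        "same_alleles": df["effect_allele"] == df["other_allele"],
        "nonpositive_se": ~(df["se"] > 0),
        "eaf_out_of_range": ~((df["eaf"] >= 0) & (df["eaf"] <= 1)),
        "pvalue_out_of_range": ~((df["pvalue"] > 0) & (df["pvalue"] <= 1)),
        "nonpositive_n": ~(df["n"] > 0),
    }
    bad = pd.Series(False, index=df.index)
    for reason, mask in checks.items():
        newly = mask & ~bad
        if newly.any():
            rep.reasons[reason] = int(newly.sum())
        bad |= mask
    rep.n_dropped = int(bad.sum())
    if rep.n_dropped:
        logger.info("dataset %s: dropped %d/%d rows (%s)", trait_id,
                    rep.n_dropped, rep.n_input, rep.reasons)
    clean = df.loc[~bad].reset_index(drop=True)

    if len(clean):
        z = np.abs(clean["beta"].to_numpy() / clean["se"].to_numpy())
        implied = 2.0 * stats.norm.sf(z)
        with np.errstate(divide="ignore"):
            ratio = np.log10(np.maximum(implied, 1e-300)) - np.log10(
                clean["pvalue"].to_numpy())
        n_warn = int(np.sum(np.abs(ratio) > 2))
        rep.n_pvalue_warnings = n_warn
        if n_warn:
            logger.warning(
                "dataset %s: %d rows with p-value inconsistent with |beta/se| "
                "beyond 2 orders of magnitude", trait_id, n_warn)
    return clean, rep


def read_summary_stats(path, trait_id: str | None = None,
                       column_map: Mapping[str, str] | None = None,
                       trait_scale: str = "continuous",
                       trait_label: str = "") -> SummaryDataset:
    """Read a tab-separated summary-statistic table into a validated dataset.

    Parameters
    ----------
    path : path-like
        Tab-separated file with a header row.
    trait_id : str, optional
        Identifier for the trait; defaults to the file stem.
    column_map : mapping, optional
        ``{canonical_name: file_column_name}`` for files using another
        dialect; canonical names absent from the map are looked up verbatim.
    trait_scale : {"continuous", "log_odds"}
        Scale of ``beta``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    if df.shape[1] == 0 or (len(df) == 0 and df.shape[1] < len(COLUMNS)):
        raise InputError(f"empty or headerless summary-statistic file: {path}")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(
            f"missing mandatory column(s) {missing} in {path}; "
            "use column_map to map your dialect onto the canonical names")
    df = df[COLUMNS]
    if trait_id is None:
        from pathlib import Path
        trait_id = Path(path).stem
    clean, rep = validate_table(df, trait_id)
    clean["chrom"] = clean["chrom"].astype(str)
    clean["pos"] = clean["pos"].astype(int)
    clean["n"] = clean["n"].astype(int)
    return SummaryDataset(trait_id=trait_id, table=clean, trait_label=trait_label,
                          trait_scale=trait_scale, validation=rep)


def write_summary_stats(ds: SummaryDataset, path) -> None:
    """Write a dataset as tab-separated text, repr-faithful on numerics.

    ``read_summary_stats(write_summary_stats(ds))`` reproduces the dataset
    field-for-field (floats round-trip exactly through Python's repr).
    """
    out = ds.table[COLUMNS].copy()
    for col in ("eaf", "beta", "se", "pvalue"):
        # repr is the shortest exact round-trip representation of a float
        out[col] = out[col].map(repr)
    out.to_csv(path, sep="\t", index=False)


@dataclass
class LDMatrix:
    """Pairwise squared correlations (r²) between SNPs.

    Symmetric with unit diagonal; entries in [0, 1].
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise InputError("LD matrix shape does not match snp_ids")
        if np.nanmax(np.abs(self.r2 - self.r2.T)) > 1e-6:
            raise InputError("LD matrix asymmetric beyond 1e-6")
        if (self.r2 < 0).any() or (self.r2 > 1).any():
            raise InputError("LD r² values outside [0, 1]")
        # symmetrise exactly and pin the diagonal
        self.r2 = (self.r2 + self.r2.T) / 2.0
        np.fill_diagonal(self.r2, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, a: str, b: str) -> float | None:
        """r² between two SNPs, or None if either is absent (treated as
        independent by callers)."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def read_ld_matrix(path) -> LDMatrix:
    """Read a labeled square tab-separated r² matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise InputError("LD matrix row and column labels differ")
    return LDMatrix(snp_ids=[str(s) for s in df.index], r2=df.to_numpy(float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")
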