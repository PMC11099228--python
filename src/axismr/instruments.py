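"""Instrumental-variable selection and exposure/outcome harmonization.

A genetic instrument for a two-sample MR analysis is selected by a cascade of
filters on the exposure GWAS:

1. genome-wide sub-significance threshold on the exposure p-value
   (1e-5 for microbiome and immune-cell traits, 5e-8 when a disease outcome
   is analysed as the exposure in the reverse direction);
2. greedy LD clumping (keep the smallest-p SNP, discard neighbours with
   r² ≥ 0.001 within 10,000 kb, repeat);
3. exclusion of SNPs already associated with the outcome (p < 5e-5),
   which would violate the exclusion restriction trivially;
4. removal of palindromic (A/T, C/G) SNPs whose strand cannot be resolved
   from alleles alone;
5. strength/frequency filter: per-SNP F = (beta/se)² strictly greater than
   10 and minor allele frequency at least 0.01.

Harmonization then aligns the outcome-side effect of every retained SNP to
the exposure's effect allele, flipping the sign of the outcome beta (and
complementing the allele frequency) when the alleles are swapped, and
resolving strand flips by base-complementing before comparison.

Clumping runs against a user-supplied LD matrix; SNPs absent from the matrix
are treated as independent and counted in the filter log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import InputError, LDMatrix, SummaryDataset, VariantAssociation

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class EstimationError(RuntimeError):
    """Raised when an estimate cannot be produced from the given data."""


@dataclass
class IVConfig:
    """Thresholds governing the instrument-selection cascade.

    Defaults follow the analysis protocol this package implements; every
    value is overridable.
    """

    iv_p_threshold: float = 1e-5       # exposure/mediator instrument p
    reverse_iv_p_threshold: float = 5e-8  # disease-as-exposure instrument p
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    outcome_assoc_p: float = 5e-5
    f_min: float = 10.0                # strict: F must exceed this
    maf_min: float = 0.01
    drop_palindromic: bool = True


@dataclass(frozen=True)
class InstrumentRecord:
    """An exposure-side variant annotated with its strength statistic."""

    variant: VariantAssociation
    f_statistic: float


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a common effect allele.

    Arrays are parallel over SNPs: ``gamma``/``gamma_se`` are the exposure
    associations (γ̂), ``Gamma``/``Gamma_se`` the outcome associations (Γ̂).
    """

    exposure_id: str
    outcome_id: str
    snp_ids: list[str]
    gamma: np.ndarray
    gamma_se: np.ndarray
    Gamma: np.ndarray
    Gamma_se: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, float)
        self.gamma_se = np.asarray(self.gamma_se, float)
        self.Gamma = np.asarray(self.Gamma, float)
        self.Gamma_se = np.asarray(self.Gamma_se, float)
        k = len(self.snp_ids)
        if not (len(self.gamma) == len(self.gamma_se) == len(self.Gamma)
                == len(self.Gamma_se) == k):
            raise InputError("harmonized arrays have mismatched lengths")
        if k == 0:
            raise EstimationError("no overlapping instruments")
        if len(set(self.snp_ids)) != k:
            raise InputError("duplicate snp_id in harmonized set")
        if (self.gamma_se <= 0).any() or (self.Gamma_se <= 0).any():
            raise InputError("all standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def drop(self, snp_ids) -> "HarmonizedSet":
        """A new set with the given SNPs removed."""
        keep = [i for i, s in enumerate(self.snp_ids) if s not in set(snp_ids)]
        return HarmonizedSet(
            self.exposure_id, self.outcome_id,
            [self.snp_ids[i] for i in keep],
            self.gamma[keep], self.gamma_se[keep],
            self.Gamma[keep], self.Gamma_se[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids,
            "exposure_beta": self.gamma, "exposure_se": self.gamma_se,
            "outcome_beta": self.Gamma, "outcome_se": self.Gamma_se,
        })


# ---------------------------------------------------------------------------
# individual cascade steps

def threshold_candidates(ds: SummaryDataset, p_threshold: float) -> SummaryDataset:
    """Keep records with exposure p-value strictly below ``p_threshold``."""
    if not (0 < p_threshold <= 1):
        raise ValueError("p_threshold must lie in (0, 1]")
    keep = ds.table[ds.table["pvalue"] < p_threshold].reset_index(drop=True)
    return SummaryDataset(ds.trait_id, keep, trait_label=ds.trait_label,
                          trait_scale=ds.trait_scale)


def ld_clump(ds: SummaryDataset, ld: LDMatrix | None,
             r2_threshold: float = 0.001,
             window_kb: float = 10_000.0) -> SummaryDataset:
    """Greedy p-value-ordered LD clumping.

    SNPs are visited in ascending p-value order (ties broken by snp_id so the
    result is deterministic); a SNP is accepted iff its r² with every
    already-accepted SNP on the same chromosome within ``window_kb`` is below
    ``r2_threshold``.  Pairs absent from ``ld`` (or all pairs when ``ld`` is
    None) are treated as independent.
    """
    if not (0 < r2_threshold < 1):
        raise ValueError("r2_threshold must lie in (0, 1)")
    tab = ds.table.sort_values(["pvalue", "snp_id"], kind="mergesort")
    accepted: list[int] = []
    n_unknown = 0
    rows = list(tab.itertuples())
    for i, row in enumerate(rows):
        ok = True
        for j in accepted:
            prev = rows[j]
            if prev.chrom != row.chrom:
                continue
            if abs(prev.pos - row.pos) > window_kb * 1000.0:
                continue
            r2 = ld.get(prev.snp_id, row.snp_id) if ld is not None else None
            if r2 is None:
                n_unknown += 1
                continue
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(i)
    if n_unknown:
        logger.info("ld_clump: %d pairs absent from LD matrix, assumed independent",
                    n_unknown)
    keep = tab.iloc[accepted].reset_index(drop=True)
    return SummaryDataset(ds.trait_id, keep, trait_label=ds.trait_label,
                          trait_scale=ds.trait_scale)


def exclude_outcome_associated(instruments: SummaryDataset,
                               outcome: SummaryDataset,
                               p_cut: float = 5e-5) -> SummaryDataset:
    """Drop instruments associated with the outcome (p < ``p_cut``).

    Instruments absent from the outcome dataset are also dropped, counted
    separately as unmatched.
    """
    out_p = outcome.table.set_index("snp_id")["pvalue"]
    tab = instruments.table
    matched = tab["snp_id"].isin(out_p.index)
    p_out = tab.loc[matched, "snp_id"].map(out_p)
    excluded_ids = set(tab.loc[matched, "snp_id"][p_out.to_numpy() < p_cut])
    n_unmatched = int((~matched).sum())
    keep = tab[matched & ~tab["snp_id"].isin(excluded_ids)].reset_index(drop=True)
    logger.info("exclude_outcome_associated: %d excluded (p < %g), %d unmatched",
                len(excluded_ids), p_cut, n_unmatched)
    ds = SummaryDataset(instruments.trait_id, keep,
                        trait_label=instruments.trait_label,
                        trait_scale=instruments.trait_scale)
    ds.validation.reasons = {"outcome_associated": len(excluded_ids),
                             "unmatched": n_unmatched}
    return ds


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return {a1.upper(), a2.upper()} in ({"A", "T"}, {"C", "G"})


def compute_f_statistic(v: VariantAssociation) -> float:
    """Per-SNP instrument strength, F = (beta/se)² (squared Wald z)."""
    return (v.beta / v.se) ** 2


def filter_weak_and_rare(instruments: SummaryDataset, f_min: float = 10.0,
                         maf_min: float = 0.01) -> SummaryDataset:
    """Keep instruments with F strictly above ``f_min`` and MAF ≥ ``maf_min``.

    MAF = min(eaf, 1 − eaf).  The strength cut is strict (F = f_min exactly
    is removed).
    """
    tab = instruments.table
    f = (tab["beta"] / tab["se"]) ** 2
    maf = np.minimum(tab["eaf"], 1 - tab["eaf"])
    keep = tab[(f > f_min) & (maf >= maf_min)].reset_index(drop=True)
    return SummaryDataset(instruments.trait_id, keep,
                          trait_label=instruments.trait_label,
                          trait_scale=instruments.trait_scale)


def _orient_outcome(e_ea, e_oa, o_ea, o_oa):
    """How to align an outcome record to the exposure's alleles.

    Returns +1 (same orientation), -1 (effect/other swapped) or None
    (irreconcilable).  Strand flips are resolved by complementing the outcome
    alleles before comparison.
    """
    if (o_ea, o_oa) == (e_ea, e_oa):
        return 1
    if (o_ea, o_oa) == (e_oa, e_ea):
        return -1
    c_ea, c_oa = COMPLEMENT.get(o_ea), COMPLEMENT.get(o_oa)
    if (c_ea, c_oa) == (e_ea, e_oa):
        return 1
    if (c_ea, c_oa) == (e_oa, e_ea):
        return -1
    return None


def harmonize(exposure: SummaryDataset, outcome: SummaryDataset,
              drop_palindromic: bool = True) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per shared SNP.

    Swapped alleles negate the outcome beta; strand-complement pairs are
    complemented first and then treated the same way.  Palindromic SNPs are
    dropped unconditionally when ``drop_palindromic`` (allele frequencies are
    never used to rescue them).  Irreconcilable pairs are dropped and logged.
    """
    exp = exposure.table.set_index("snp_id")
    out = outcome.table.set_index("snp_id")
    shared = [s for s in exposure.table["snp_id"] if s in out.index]
    if not shared:
        raise EstimationError(
            f"no overlapping instruments between {exposure.trait_id!r} "
            f"and {outcome.trait_id!r}")
    ids, g, gse, G, Gse = [], [], [], [], []
    n_palin = n_bad = 0
    for s in shared:
        e = exp.loc[s]
        o = out.loc[s]
        if is_palindromic(e.effect_allele, e.other_allele):
            if drop_palindromic:
                n_palin += 1
                continue
            # without the drop rule a palindromic pair can only be taken at
            # face value: complements are indistinguishable from swaps
            sign = 1 if (o.effect_allele, o.other_allele) == (
                e.effect_allele, e.other_allele) else -1
        else:
            sign = _orient_outcome(e.effect_allele, e.other_allele,
                                   o.effect_allele, o.other_allele)
        if sign is None:
            n_bad += 1
            continue
        ids.append(s)
        g.append(e.beta)
        gse.append(e.se)
        G.append(sign * o.beta)
        Gse.append(o.se)
    if n_palin or n_bad:
        logger.info("harmonize %s->%s: dropped %d palindromic, %d irreconcilable",
                    exposure.trait_id, outcome.trait_id, n_palin, n_bad)
    if not ids:
        raise EstimationError(
            f"no overlapping instruments between {exposure.trait_id!r} and "
            f"{outcome.trait_id!r} after allele harmonization")
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, ids,
                         np.array(g), np.array(gse), np.array(G), np.array(Gse))


def select_instruments(exposure: SummaryDataset, outcome: SummaryDataset,
                       ld: LDMatrix | None = None,
                       config: IVConfig | None = None,
                       p_threshold: float | None = None) -> HarmonizedSet:
    """Run the full selection cascade and harmonize against the outcome.

    ``p_threshold`` overrides ``config.iv_p_threshold`` (used for the reverse
    direction, where the disease-as-exposure threshold is genome-wide).
    Filter-cascade counts are logged at INFO.
    """
    cfg = config or IVConfig()
    p_thr = p_threshold if p_threshold is not None else cfg.iv_p_threshold
    step = threshold_candidates(exposure, p_thr)
    counts = {"candidates": len(step)}
    step = ld_clump(step, ld, cfg.clump_r2, cfg.clump_window_kb)
    counts["post_clump"] = len(step)
    step = exclude_outcome_associated(step, outcome, cfg.outcome_assoc_p)
    counts["post_exclusion"] = len(step)
    step = filter_weak_and_rare(step, cfg.f_min, cfg.maf_min)
    counts["post_f_maf"] = len(step)
    h = harmonize(step, outcome, cfg.drop_palindromic)
    counts["post_harmonize"] = h.n_snp
    logger.info("select_instruments %s->%s: %s", exposure.trait_id,
                outcome.trait_id, counts)
    return h


def instrument_table(ds: SummaryDataset) -> pd.DataFrame:
    """Exposure-side instrument list with an added f_statistic column."""
    tab = ds.table.copy()
    tab["f_statistic"] = (tab["beta"] / tab["se"]) ** 2
    return tab
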