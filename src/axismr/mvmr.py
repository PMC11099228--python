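"""Multivariable IVW: direct effects of several exposures fitted jointly.

The multivariable model regresses the per-SNP outcome associations Γ̂ on the
matrix of per-SNP exposure associations (one column per exposure), weights
1/se(Γ̂)², no intercept.  Each coefficient is the direct effect of that
exposure on the outcome holding the co-exposures fixed — in the mediation
analysis, the mediator's coefficient adjusted for the primary exposure is β2.

Instrument assembly takes the union of each exposure's own instruments
(each selected through the standard cascade), jointly clumps the union, and
requires every retained SNP to be observed in every dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import (EstimationError, HarmonizedSet, IVConfig,
                          _orient_outcome, filter_weak_and_rare, is_palindromic,
                          ld_clump, threshold_candidates)
from .io import InputError, LDMatrix, SummaryDataset
from .uvmr import Z95, MRResults

logger = logging.getLogger(__name__)


@dataclass
class MultiHarmonizedSet:
    """Per-SNP associations with m exposures and one outcome, allele-aligned.

    ``X`` is the k×m matrix of exposure effects, ``y`` the outcome effects.
    """

    outcome_id: str
    exposure_ids: list[str]
    snp_ids: list[str]
    X: np.ndarray
    X_se: np.ndarray
    y: np.ndarray
    y_se: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.X_se = np.atleast_2d(np.asarray(self.X_se, float))
        self.y = np.asarray(self.y, float)
        self.y_se = np.asarray(self.y_se, float)
        k, m = self.X.shape
        if m != len(self.exposure_ids):
            raise InputError("X columns must match exposure_ids")
        if k < m + 1:
            raise EstimationError(
                f"multivariable IVW needs at least m+1 = {m + 1} instruments, "
                f"got {k}")

    @property
    def n_snp(self) -> int:
        return self.X.shape[0]

    @property
    def n_exposure(self) -> int:
        return self.X.shape[1]


class MVMR:
    """Multivariable IVW model; ``fit()`` returns one result per exposure."""

    def __init__(self, mh: MultiHarmonizedSet):
        self.mh = mh

    def fit(self) -> "MVMRResults":
        mh = self.mh
        k, m = mh.X.shape
        w = 1.0 / mh.y_se ** 2
        Xw = mh.X * np.sqrt(w)[:, None]
        yw = mh.y * np.sqrt(w)
        rank = np.linalg.matrix_rank(Xw)
        if rank < m:
            raise EstimationError(
                "rank-deficient exposure matrix (collinear exposures among "
                f"{mh.exposure_ids})")
        xtx = Xw.T @ Xw
        beta = np.linalg.solve(xtx, Xw.T @ yw)
        resid = yw - Xw @ beta
        df = k - m
        sigma2 = float(resid @ resid) / df
        scale2 = max(1.0, sigma2)  # multiplicative overdispersion floor
        cov = scale2 * np.linalg.inv(xtx)
        se = np.sqrt(np.diag(cov))
        tstat = beta / se
        pvals = np.minimum(1.0, 2 * stats.t.sf(np.abs(tstat), df))
        results = []
        for j, exp_id in enumerate(mh.exposure_ids):
            others = [e for e in mh.exposure_ids if e != exp_id]
            results.append(MRResults(
                "mv_ivw", float(beta[j]), float(se[j]), float(pvals[j]), k,
                exposure_id=exp_id, outcome_id=mh.outcome_id,
                extra={"adjusted_for": others, "df": df, "sigma2": sigma2}))
        return MVMRResults(self.mh, results)


@dataclass
class MVMRResults:
    """Per-exposure direct-effect estimates from one multivariable fit."""

    mh: MultiHarmonizedSet
    estimates: list[MRResults] = field(default_factory=list)

    def __iter__(self):
        return iter(self.estimates)

    def __getitem__(self, exposure_id: str) -> MRResults:
        for r in self.estimates:
            if r.exposure_id == exposure_id:
                return r
        raise KeyError(exposure_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.estimates:
            row = r.to_row()
            row["adjusted_for"] = ",".join(r.extra["adjusted_for"])
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Multivariable IVW on {self.mh.n_snp} instruments "
                 f"(outcome {self.mh.outcome_id})"]
        for r in self.estimates:
            lines.append(
                f"  {r.exposure_id}: beta = {r.beta:.6g} (se {r.se:.6g}), "
                f"95% CI [{r.ci_low:.6g}, {r.ci_high:.6g}], p = {r.pvalue:.3g}")
        return "\n".join(lines)


def assemble_mv_set(exposures: list[SummaryDataset], outcome: SummaryDataset,
                    ld: LDMatrix | None = None,
                    config: IVConfig | None = None) -> MultiHarmonizedSet:
    """Build the joint instrument set for a multivariable fit.

    Union of per-exposure instruments (threshold + F/MAF filter per
    exposure), jointly clumped using each SNP's smallest per-exposure
    p-value, aligned to the first exposure's effect allele, and restricted
    to SNPs observed in every exposure dataset and the outcome.
    """
    if len(exposures) < 2:
        raise EstimationError("multivariable MR needs at least 2 exposures")
    cfg = config or IVConfig()

    per_exp = []
    for ds in exposures:
        sel = threshold_candidates(ds, cfg.iv_p_threshold)
        sel = filter_weak_and_rare(sel, cfg.f_min, cfg.maf_min)
        per_exp.append(sel)

    # union, carrying the best (smallest) p for joint clumping order
    frames = [s.table for s in per_exp]
    union = (pd.concat(frames, ignore_index=True)
             .sort_values(["pvalue", "snp_id"], kind="mergesort")
             .drop_duplicates("snp_id", keep="first")
             .reset_index(drop=True))
    union_ds = SummaryDataset("mv_union", union)
    clumped = ld_clump(union_ds, ld, cfg.clump_r2, cfg.clump_window_kb)

    ref = exposures[0].table.set_index("snp_id")
    tables = [ds.table.set_index("snp_id") for ds in exposures]
    out_tab = outcome.table.set_index("snp_id")

    ids, X, X_se, y, y_se = [], [], [], [], []
    n_missing = n_palin = n_bad = 0
    for snp in clumped.table["snp_id"]:
        if any(snp not in t.index for t in tables) or snp not in out_tab.index:
            n_missing += 1
            continue
        e0 = tables[0].loc[snp]
        if cfg.drop_palindromic and is_palindromic(e0.effect_allele,
                                                   e0.other_allele):
            n_palin += 1
            continue
        betas, ses, ok = [], [], True
        for t in tables:
            rec = t.loc[snp]
            sign = _orient_outcome(e0.effect_allele, e0.other_allele,
                                   rec.effect_allele, rec.other_allele)
            if sign is None:
                ok = False
                break
            betas.append(sign * rec.beta)
            ses.append(rec.se)
        if ok:
            orec = out_tab.loc[snp]
            sign = _orient_outcome(e0.effect_allele, e0.other_allele,
                                   orec.effect_allele, orec.other_allele)
            if sign is None:
                ok = False
        if not ok:
            n_bad += 1
            continue
        ids.append(snp)
        X.append(betas)
        X_se.append(ses)
        y.append(sign * orec.beta)
        y_se.append(orec.se)
    if n_missing or n_palin or n_bad:
        logger.info("assemble_mv_set: dropped %d missing, %d palindromic, "
                    "%d irreconcilable SNPs", n_missing, n_palin, n_bad)
    m = len(exposures)
    if len(ids) < m + 1:
        raise EstimationError(
            f"only {len(ids)} joint instruments for {m} exposures "
            f"(need at least {m + 1})")
    return MultiHarmonizedSet(outcome.trait_id, [e.trait_id for e in exposures],
                              ids, np.array(X), np.array(X_se),
                              np.array(y), np.array(y_se))


def mv_ivw(mh: MultiHarmonizedSet) -> MVMRResults:
    """Fit the multivariable IVW model (functional surface)."""
    return MVMR(mh).fit()
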