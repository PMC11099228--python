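"""Robustness layer for a fitted exposure–outcome pair.

Four diagnostics guard the causal claims:

- Cochran's Q across per-SNP Wald ratios (heterogeneity);
- the MR-Egger intercept test (directional horizontal pleiotropy);
- MR-PRESSO: a parametric-simulation residual test that detects pleiotropic
  outlier instruments (global test), identifies them per SNP (outlier test),
  and checks whether removing them shifts the estimate (distortion test);
- leave-one-out IVW refits (single-SNP influence).

A pair is flagged invalid when heterogeneity p < 0.05 or when either
pleiotropy p (Egger intercept, PRESSO global) is < 0.05 — evidence of
pleiotropy invalidates the causal interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import EstimationError, HarmonizedSet
from .uvmr import MRResults, UVMR


def cochran_q(h: HarmonizedSet) -> tuple[float, int, float]:
    """Heterogeneity of the per-SNP Wald ratios around the IVW estimate.

    Q = Σ wⱼ (β̂ⱼ − β̂_IVW)² with β̂ⱼ = Γ̂ⱼ/γ̂ⱼ and wⱼ = γ̂ⱼ²/se(Γ̂ⱼ)²;
    p from χ² with k − 1 degrees of freedom.
    """
    if h.n_snp < 2:
        raise EstimationError("Cochran's Q needs at least 2 instruments")
    model = UVMR.from_harmonized(h)
    beta, _, q = model._ivw_core()
    df = h.n_snp - 1
    p = float(min(1.0, stats.chi2.sf(q, df)))
    return float(q), df, p


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float]:
    """MR-Egger intercept and its two-sided p (directional pleiotropy)."""
    res = UVMR.from_harmonized(h).fit("egger")
    return res.extra["intercept"], res.extra["intercept_p"]


def leave_one_out(h: HarmonizedSet) -> list[tuple[str, MRResults]]:
    """IVW refits each omitting one SNP, in input order."""
    if h.n_snp < 3:
        raise EstimationError("leave-one-out needs at least 3 instruments")
    out = []
    for s in h.snp_ids:
        out.append((s, UVMR.from_harmonized(h.drop([s])).fit("ivw")))
    return out


def _loo_slopes(g: np.ndarray, G: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every SNP at once (weights w = 1/seΓ²)."""
    num = np.sum(w * g * G)
    den = np.sum(w * g * g)
    return (num - w * g * G) / (den - w * g * g)


@dataclass
class PressoResult:
    """MR-PRESSO global/outlier/distortion results for one pair."""

    global_rss: float
    global_p: float           # empirical; 0.0 means "below resolution"
    global_p_bound: float     # 1/n_sim, the resolution of the empirical p
    outliers: list[str] = field(default_factory=list)
    outlier_pvalues: dict = field(default_factory=dict)  # Bonferroni-adjusted
    distortion_p: float | None = None
    raw_estimate: MRResults | None = None
    corrected_estimate: MRResults | None = None
    n_sim: int = 0

    @property
    def global_p_str(self) -> str:
        if self.global_p == 0.0:
            return f"<{self.global_p_bound:g}"
        return f"{self.global_p:g}"


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, outlier_p: float = 0.05,
              seed: int = 0) -> PressoResult:
    """Pleiotropy residual sum of squares and outlier test.

    Observed statistic: RSS = Σⱼ (Γ̂ⱼ − β̂₋ⱼ γ̂ⱼ)² / se(Γ̂ⱼ)², with β̂₋ⱼ the
    IVW slope fitted without SNP j.  The null distribution comes from
    ``n_sim`` parametric simulations drawing Γ̂*ⱼ ~ N(β̂₋ⱼ γ̂ⱼ, se(Γ̂ⱼ)) and
    γ̂*ⱼ ~ N(γ̂ⱼ, se(γ̂ⱼ)) and recomputing RSS the same way.  Per-SNP
    residual p-values are Bonferroni-adjusted across SNPs and compared to
    ``outlier_p``.  When outliers are found, the distortion test resamples
    their slots from the non-outlier ratios to ask whether their removal
    shifts the IVW estimate more than chance would.
    """
    if h.n_snp < 4:
        raise EstimationError("MR-PRESSO needs at least 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = np.random.default_rng(seed)
    k = h.n_snp
    g, G = h.gamma, h.Gamma
    gse, Gse = h.gamma_se, h.Gamma_se
    w = 1.0 / Gse ** 2

    loo = _loo_slopes(g, G, w)
    obs_resid = w * (G - loo * g) ** 2
    obs_rss = float(obs_resid.sum())

    # parametric null: (n_sim, k) draws
    g_star = rng.normal(g, gse, size=(n_sim, k))
    G_star = rng.normal(loo * g, Gse, size=(n_sim, k))
    num = np.sum(w * g_star * G_star, axis=1, keepdims=True)
    den = np.sum(w * g_star ** 2, axis=1, keepdims=True)
    loo_star = (num - w * g_star * G_star) / (den - w * g_star ** 2)
    sim_resid = w * (G_star - loo_star * g_star) ** 2
    sim_rss = sim_resid.sum(axis=1)

    global_p = float(np.mean(sim_rss >= obs_rss))
    per_snp_p = np.mean(sim_resid >= obs_resid[None, :], axis=0)
    adj = np.minimum(1.0, per_snp_p * k)
    out_idx = np.where(adj < outlier_p)[0]
    outliers = [h.snp_ids[i] for i in out_idx]

    raw = UVMR.from_harmonized(h).fit("ivw")
    corrected = None
    distortion_p = None
    if outliers and len(outliers) < k - 1:
        kept = h.drop(outliers)
        corrected = UVMR.from_harmonized(kept).fit("ivw")
        # distortion: refill the outlier slots with ratios resampled from
        # the non-outliers and measure the induced shift
        keep_idx = np.array([i for i in range(k) if i not in set(out_idx)])
        obs_d = (raw.beta - corrected.beta) / abs(corrected.beta) \
            if corrected.beta != 0 else np.inf
        n_d = 1000
        d = np.empty(n_d)
        wg = w * g
        for b in range(n_d):
            fill = rng.choice(keep_idx, size=len(out_idx), replace=True)
            Gb = G.copy()
            Gb[out_idx] = (G[fill] / g[fill]) * g[out_idx]
            beta_b = np.sum(wg * Gb) / np.sum(wg * g)
            d[b] = (beta_b - corrected.beta) / abs(corrected.beta) \
                if corrected.beta != 0 else np.inf
        distortion_p = float(np.mean(np.abs(d) >= abs(obs_d)))
    return PressoResult(obs_rss, global_p, 1.0 / n_sim, outliers,
                        {h.snp_ids[i]: float(adj[i]) for i in range(k)},
                        distortion_p, raw, corrected, n_sim)


@dataclass
class SensitivityReport:
    """The full robustness battery for one exposure–outcome pair."""

    exposure_id: str
    outcome_id: str
    q_statistic: float
    q_df: int
    p_heterogeneity: float
    egger_intercept: float
    p_pleiotropy: float
    presso: PressoResult | None
    loo: list[tuple[str, MRResults]]

    @property
    def heterogeneity_flag(self) -> bool:
        return self.p_heterogeneity < 0.05

    @property
    def pleiotropy_flag(self) -> bool:
        """True when the Egger intercept or PRESSO global test rejects —
        evidence that would invalidate the causal claim."""
        if self.p_pleiotropy < 0.05:
            return True
        if self.presso is not None:
            p = self.presso.global_p
            if p < 0.05:  # includes the below-resolution case p == 0
                return True
        return False

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure_id, "outcome": self.outcome_id,
            "q": self.q_statistic, "q_df": self.q_df,
            "p_heterogeneity": self.p_heterogeneity,
            "egger_intercept": self.egger_intercept,
            "p_pleiotropy": self.p_pleiotropy,
            "presso_global_p": (self.presso.global_p_str
                                if self.presso else ""),
            "presso_outliers": (";".join(self.presso.outliers)
                                if self.presso else ""),
            "presso_distortion_p": (self.presso.distortion_p
                                    if self.presso and
                                    self.presso.distortion_p is not None
                                    else np.nan),
            "heterogeneity_flag": self.heterogeneity_flag,
            "pleiotropy_flag": self.pleiotropy_flag,
        }


def sensitivity_report(h: HarmonizedSet, n_sim: int = 1000,
                       outlier_p: float = 0.05, seed: int = 0,
                       run_presso: bool = True) -> SensitivityReport:
    """Run the full robustness battery on one harmonized pair."""
    q, df, p_het = cochran_q(h)
    intercept, p_pleio = egger_intercept_test(h)
    presso = mr_presso(h, n_sim, outlier_p, seed) \
        if run_presso and h.n_snp >= 4 else None
    loo = leave_one_out(h) if h.n_snp >= 3 else []
    return SensitivityReport(h.exposure_id, h.outcome_id, q, df, p_het,
                             intercept, p_pleio, presso, loo)


def loo_table(report: SensitivityReport) -> pd.DataFrame:
    """Long-format leave-one-out table for one pair."""
    rows = []
    for snp, res in report.loo:
        rows.append({"exposure": report.exposure_id,
                     "outcome": report.outcome_id,
                     "left_out": snp, "beta": res.beta, "se": res.se,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "pvalue": res.pvalue})
    return pd.DataFrame(rows)
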