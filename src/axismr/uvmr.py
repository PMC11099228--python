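"""Univariable two-sample MR estimators.

Given harmonized per-SNP associations (γ̂ⱼ with the exposure, Γ̂ⱼ with the
outcome), each estimator combines the per-SNP Wald ratios Γ̂ⱼ/γ̂ⱼ into one
causal effect under a different assumption about invalid instruments:

- ``ivw``: inverse-variance-weighted meta-analysis, equivalently the
  zero-intercept weighted regression of Γ̂ on γ̂ with weights 1/se(Γ̂)²;
  consistent when all instruments are valid (or pleiotropy is balanced).
- ``egger``: the same regression with a free intercept; the slope is robust
  to directional pleiotropy under the InSIDE assumption and the intercept
  estimates the average pleiotropic effect.
- ``weighted_median``: consistent when instruments carrying ≥ 50% of the
  weight are valid.
- ``weighted_mode`` / ``simple_mode``: consistent when the largest cluster of
  Wald ratios is formed by valid instruments (ZEMPA).
- ``wald``: the single-instrument ratio, the degenerate k = 1 case.

The model object follows the statsmodels convention: build a :class:`UVMR`
from data, call :meth:`UVMR.fit`, and read the returned :class:`MRResults`.
Module-level functions with the same names as the methods are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import EstimationError, HarmonizedSet

Z95 = 1.959964  # two-sided 95% normal quantile, to the precision reported

METHODS = ("wald", "ivw", "egger", "weighted_median", "weighted_mode",
           "simple_mode")


@dataclass
class MRResults:
    """A causal-effect estimate from one MR estimator.

    ``beta`` is on the scale of the outcome trait per unit exposure
    (log odds ratio for binary outcomes); ``odds_ratio`` is exp(beta).
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    exposure_id: str = ""
    outcome_id: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def to_row(self) -> dict:
        row = {
            "exposure": self.exposure_id, "outcome": self.outcome_id,
            "method": self.method, "n_snp": self.n_snp,
            "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue, "odds_ratio": self.odds_ratio,
            "egger_intercept": self.extra.get("intercept", np.nan),
            "egger_intercept_p": self.extra.get("intercept_p", np.nan),
        }
        return row

    def summary(self) -> str:
        lines = [
            f"MR estimate ({self.method})",
            f"  exposure: {self.exposure_id}   outcome: {self.outcome_id}",
            f"  n_snp = {self.n_snp}",
            f"  beta  = {self.beta:.6g}  (se {self.se:.6g})",
            f"  95% CI [{self.ci_low:.6g}, {self.ci_high:.6g}]",
            f"  OR    = {self.odds_ratio:.6g}",
            f"  p     = {self.pvalue:.3g}",
        ]
        if "intercept" in self.extra:
            lines.append(
                f"  intercept = {self.extra['intercept']:.6g} "
                f"(p = {self.extra['intercept_p']:.3g})")
        return "\n".join(lines)


def _norm_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


class UVMR:
    """Univariable MR model over a set of harmonized instruments."""

    def __init__(self, gamma, gamma_se, Gamma, Gamma_se, snp_ids=None,
                 exposure_id: str = "", outcome_id: str = ""):
        self.gamma = np.asarray(gamma, float)
        self.gamma_se = np.asarray(gamma_se, float)
        self.Gamma = np.asarray(Gamma, float)
        self.Gamma_se = np.asarray(Gamma_se, float)
        self.snp_ids = list(snp_ids) if snp_ids is not None else [
            f"snp{i}" for i in range(len(self.gamma))]
        self.exposure_id = exposure_id
        self.outcome_id = outcome_id
        if (self.gamma_se <= 0).any() or (self.Gamma_se <= 0).any():
            raise EstimationError("standard errors must be positive")

    @classmethod
    def from_harmonized(cls, h: HarmonizedSet) -> "UVMR":
        return cls(h.gamma, h.gamma_se, h.Gamma, h.Gamma_se, h.snp_ids,
                   exposure_id=h.exposure_id, outcome_id=h.outcome_id)

    @property
    def n_snp(self) -> int:
        return len(self.gamma)

    @property
    def wald_ratios(self) -> np.ndarray:
        return self.Gamma / self.gamma

    @property
    def ratio_se(self) -> np.ndarray:
        """First-order (delta) SE of each Wald ratio, se(Γ̂)/|γ̂|."""
        return self.Gamma_se / np.abs(self.gamma)

    # -- fitting -----------------------------------------------------------

    def fit(self, method: str = "ivw", **kwargs) -> MRResults:
        if method == "wald":
            res = self._fit_wald()
        elif method == "ivw":
            res = self._fit_ivw(**kwargs)
        elif method == "egger":
            res = self._fit_egger()
        elif method == "weighted_median":
            res = self._fit_weighted_median(**kwargs)
        elif method == "weighted_mode":
            res = self._fit_mode(weighted=True, **kwargs)
        elif method == "simple_mode":
            res = self._fit_mode(weighted=False, **kwargs)
        else:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        res.exposure_id = self.exposure_id
        res.outcome_id = self.outcome_id
        return res

    def fit_all(self, seed: int = 0, n_boot: int = 1000) -> list[MRResults]:
        """The five-method battery used for a primary-plus-supplementary report."""
        out = [self.fit("ivw"), self.fit("egger"),
               self.fit("weighted_median", seed=seed, n_boot=n_boot),
               self.fit("weighted_mode", seed=seed, n_boot=n_boot),
               self.fit("simple_mode", seed=seed, n_boot=n_boot)]
        return out

    def _fit_wald(self) -> MRResults:
        if self.n_snp != 1:
            raise EstimationError("wald ratio is the single-instrument case")
        g, G, Gse = self.gamma[0], self.Gamma[0], self.Gamma_se[0]
        if g == 0:
            raise EstimationError("exposure effect is zero; Wald ratio undefined")
        beta = G / g
        se = Gse / abs(g)
        return MRResults("wald", float(beta), float(se), _norm_p(beta / se), 1)

    def _ivw_core(self):
        w = 1.0 / self.Gamma_se ** 2
        sxx = float(np.sum(w * self.gamma ** 2))
        beta = float(np.sum(w * self.gamma * self.Gamma)) / sxx
        se_fixed = sxx ** -0.5
        q = float(np.sum(w * (self.Gamma - beta * self.gamma) ** 2))
        return beta, se_fixed, q

    def _fit_ivw(self, model: str = "multiplicative_random") -> MRResults:
        if self.n_snp < 2:
            raise EstimationError(
                "IVW needs at least 2 instruments; use the wald method")
        if model not in ("fixed", "multiplicative_random"):
            raise ValueError(f"unknown IVW model {model!r}")
        beta, se, q = self._ivw_core()
        if model == "multiplicative_random":
            se *= max(1.0, np.sqrt(q / (self.n_snp - 1)))
        return MRResults("ivw", beta, float(se), _norm_p(beta / se),
                         self.n_snp, extra={"Q": q, "model": model})

    def _fit_egger(self) -> MRResults:
        if self.n_snp < 3:
            raise EstimationError("MR-Egger needs at least 3 instruments")
        # orient all exposure effects non-negative (the intercept is only
        # identified up to this sign convention)
        flip = np.sign(self.gamma)
        flip[flip == 0] = 1.0
        x = self.gamma * flip
        y = self.Gamma * flip
        w = 1.0 / self.Gamma_se ** 2
        # closed-form weighted least squares of y on [1, x]
        sw = w.sum()
        mx = np.sum(w * x) / sw
        my = np.sum(w * y) / sw
        sxx = np.sum(w * (x - mx) ** 2)
        slope = float(np.sum(w * (x - mx) * (y - my)) / sxx)
        intercept = float(my - slope * mx)
        resid = y - intercept - slope * x
        df = self.n_snp - 2
        sigma2 = float(np.sum(w * resid ** 2) / df)
        scale = max(1.0, np.sqrt(sigma2))
        se_slope = scale / np.sqrt(sxx)
        se_int = scale * np.sqrt(1.0 / sw + mx ** 2 / sxx)
        p_slope = float(min(1.0, 2 * stats.t.sf(abs(slope / se_slope), df)))
        p_int = float(min(1.0, 2 * stats.t.sf(abs(intercept / se_int), df)))
        return MRResults("egger", slope, float(se_slope), p_slope, self.n_snp,
                         extra={"intercept": intercept, "intercept_se": float(se_int),
                                "intercept_p": p_int, "sigma2": sigma2})

    # -- median ------------------------------------------------------------

    @staticmethod
    def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
        """Interpolated weighted median on the cumulative-weight grid.

        With normalized weights wⱼ and ratios sorted ascending, the grid
        point of ratio j is sⱼ = Σ_{i≤j} wᵢ − wⱼ/2; the estimate linearly
        interpolates the ratio at s = 0.5.
        """
        order = np.argsort(ratios, kind="mergesort")
        b = ratios[order]
        w = weights[order] / weights.sum()
        s = np.cumsum(w) - w / 2
        return float(np.interp(0.5, s, b))

    def _fit_weighted_median(self, n_boot: int = 1000, seed: int = 0) -> MRResults:
        if self.n_snp < 3:
            raise EstimationError("weighted median needs at least 3 instruments")
        ratios = self.wald_ratios
        weights = 1.0 / self.ratio_se ** 2
        beta = self._weighted_median(ratios, weights)
        se = self._bootstrap_se(
            lambda r, w: self._weighted_median(r, w), n_boot, seed)
        return MRResults("weighted_median", beta, se, _norm_p(beta / se),
                         self.n_snp)

    # -- mode --------------------------------------------------------------

    @staticmethod
    def _mode_point(ratios: np.ndarray, weights: np.ndarray,
                    bandwidth_factor: float, n_grid: int = 2001) -> float:
        """Argmax of a weighted Gaussian KDE of the Wald ratios.

        Bandwidth is a modified Silverman scale, 0.9·min(sd, mad)·k^{-1/5},
        times ``bandwidth_factor`` (mad scaled to be consistent for a
        normal).  Degenerate spreads (all ratios equal) return the common
        value.
        """
        k = len(ratios)
        sd = float(np.std(ratios, ddof=1)) if k > 1 else 0.0
        mad = float(1.4826 * np.median(np.abs(ratios - np.median(ratios))))
        scales = [s for s in (sd, mad) if s > 0]
        if not scales:
            return float(ratios[0])
        h = bandwidth_factor * 0.9 * min(scales) * k ** (-1 / 5)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
        w = weights / weights.sum()
        dens = np.sum(
            w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
            axis=0)
        return float(grid[np.argmax(dens)])

    def _fit_mode(self, weighted: bool, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRResults:
        if self.n_snp < 3:
            raise EstimationError("mode estimators need at least 3 instruments")
        ratios = self.wald_ratios
        weights = (1.0 / self.ratio_se ** 2 if weighted
                   else np.ones(self.n_snp))
        beta = self._mode_point(ratios, weights, bandwidth_factor)
        est = lambda r, w: self._mode_point(r, w if weighted else np.ones_like(w),
                                            bandwidth_factor)
        se = self._bootstrap_se(est, n_boot, seed)
        return MRResults("weighted_mode" if weighted else "simple_mode",
                         beta, se, _norm_p(beta / se), self.n_snp,
                         extra={"bandwidth_factor": bandwidth_factor})

    def _bootstrap_se(self, estimator, n_boot: int, seed: int) -> float:
        """Parametric bootstrap SE: resample (γ̂, Γ̂) from their sampling
        normals, re-estimate, take the SD.  Bit-reproducible for a seed."""
        rng = np.random.default_rng(seed)
        est = np.empty(n_boot)
        for b in range(n_boot):
            g = rng.normal(self.gamma, self.gamma_se)
            G = rng.normal(self.Gamma, self.Gamma_se)
            # re-derive ratio weights from the resampled exposure effects
            r = G / g
            w = g ** 2 / self.Gamma_se ** 2
            est[b] = estimator(r, w)
        sd = float(np.std(est, ddof=1))
        return sd if sd > 0 else np.finfo(float).tiny


# ---------------------------------------------------------------------------
# thin functional surface over the model object

def wald_ratio(h: HarmonizedSet) -> MRResults:
    return UVMR.from_harmonized(h).fit("wald")


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MRResults:
    return UVMR.from_harmonized(h).fit("ivw", model=model)


def egger(h: HarmonizedSet) -> MRResults:
    return UVMR.from_harmonized(h).fit("egger")


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResults:
    return UVMR.from_harmonized(h).fit("weighted_median", n_boot=n_boot, seed=seed)


def mode_estimator(h: HarmonizedSet, weighted: bool = True,
                   bandwidth_factor: float = 1.0, n_boot: int = 1000,
                   seed: int = 0) -> MRResults:
    m = "weighted_mode" if weighted else "simple_mode"
    return UVMR.from_harmonized(h).fit(m, bandwidth_factor=bandwidth_factor,
                                       n_boot=n_boot, seed=seed)


def estimates_table(results: list[MRResults]) -> pd.DataFrame:
    """Tidy table of estimates, one row per (pair, method)."""
    return pd.DataFrame([r.to_row() for r in results])
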