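"""Four-step mediator screen and product-of-coefficients mediation.

For a significant exposure → outcome pair with total effect β, a candidate
mediator must pass four steps:

1. the exposure causally shifts the mediator (UVMR, effect β1, p < 0.05,
   no pleiotropy flag on the fit);
2. the mediator causally shifts the outcome (UVMR, effect α, p < 0.05,
   no pleiotropy flag);
3. sign consistency: sign(β1 · α) must equal sign(β) — the mediated path
   must point the same way as the total effect;
4. the mediator retains a direct effect on the outcome after adjusting for
   the exposure in a multivariable fit (MV-IVW coefficient β2, p < 0.05).

The mediated effect is β1 × β2 (product of coefficients) and the mediation
proportion is (β1 × β2) / β; a delta-method CI for the product is provided.
The reported mediation p-value is the multivariable p of β2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .instruments import EstimationError, IVConfig, select_instruments
from .io import LDMatrix, SummaryDataset
from .mvmr import assemble_mv_set, mv_ivw
from .sensitivity import egger_intercept_test
from .uvmr import Z95, MRResults, UVMR

STEPS = ("step1", "step2", "sign", "step4")


class ScreeningError(ValueError):
    """A screening rule was applied outside its domain."""


@dataclass
class MediationResult:
    """One exposure → mediator → outcome pathway with its decomposition."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_total: float              # β: UVMR exposure → outcome
    beta1: float = np.nan          # β1: UVMR exposure → mediator
    alpha: float = np.nan          # α: UVMR mediator → outcome (marginal)
    beta2: float = np.nan          # β2: MVMR mediator → outcome | exposure
    se_beta1: float = np.nan
    se_beta2: float = np.nan
    p_mediator: float = np.nan     # MVMR p of β2
    passed_steps: frozenset = frozenset()
    fail_reason: str = ""

    @property
    def retained(self) -> bool:
        return self.passed_steps == frozenset(STEPS)

    @property
    def mediated_effect(self) -> float:
        return self.beta1 * self.beta2

    @property
    def proportion(self) -> float:
        return self.mediated_effect / self.beta_total

    @property
    def mediated_ci(self) -> tuple[float, float]:
        return _product_ci(self.beta1, self.beta2, self.se_beta1, self.se_beta2)

    @property
    def proportion_ci(self) -> tuple[float, float]:
        lo, hi = self.mediated_ci
        a, b = lo / self.beta_total, hi / self.beta_total
        return (min(a, b), max(a, b))

    @property
    def inconsistent(self) -> bool:
        """Mediated share outside [0, 1]: flagged, not dropped."""
        return not (0.0 <= self.proportion <= 1.0)

    def to_row(self) -> dict:
        row = {
            "exposure": self.exposure_id, "mediator": self.mediator_id,
            "outcome": self.outcome_id, "beta_total": self.beta_total,
            "beta1": self.beta1, "alpha": self.alpha, "beta2": self.beta2,
            "p_mediator": self.p_mediator,
        }
        if self.retained:
            lo, hi = self.proportion_ci
            row.update({"mediated_effect": self.mediated_effect,
                        "proportion": self.proportion,
                        "proportion_ci_low": lo, "proportion_ci_high": hi,
                        "inconsistent_mediation": self.inconsistent})
        row["passed_steps"] = ";".join(s for s in STEPS if s in self.passed_steps)
        row["fail_reason"] = self.fail_reason
        return row


def sign_consistent(beta_total: float, beta1: float, alpha: float) -> bool:
    """Directional-consistency rule for a candidate mediated path.

    Retained iff sign(β1 · α) equals sign(β): with a positive total effect
    β1 and α must share a sign; with a negative one they must differ.
    """
    if beta_total == 0 or beta1 == 0 or alpha == 0:
        raise ScreeningError("sign consistency undefined for a zero effect")
    return bool(np.sign(beta1 * alpha) == np.sign(beta_total))


def _product_ci(beta1, beta2, se1, se2) -> tuple[float, float]:
    var = beta2 ** 2 * se1 ** 2 + beta1 ** 2 * se2 ** 2
    half = Z95 * float(np.sqrt(var))
    med = beta1 * beta2
    return (med - half, med + half)


def mediation_effect(beta_total: float, beta1: float, beta2: float,
                     se_beta1: float, se_beta2: float
                     ) -> tuple[float, float, tuple[float, float]]:
    """Product-of-coefficients mediated effect, proportion and delta CI.

    Returns ``(mediated, proportion, proportion_ci)`` with
    mediated = β1·β2, proportion = mediated/β, and the CI of the mediated
    effect from the first-order delta variance β2²·se1² + β1²·se2²,
    rescaled by β for the proportion.
    """
    if beta_total == 0:
        raise ScreeningError("mediation proportion undefined: total effect is 0")
    mediated = beta1 * beta2
    proportion = mediated / beta_total
    lo, hi = _product_ci(beta1, beta2, se_beta1, se_beta2)
    a, b = lo / beta_total, hi / beta_total
    return mediated, proportion, (min(a, b), max(a, b))


def product_p_value(beta1, beta2, se1, se2) -> float:
    """Normal-approximation p for β1·β2 ≠ 0 via the delta-method SE.

    An extension beyond the reported screen (whose mediation p is the
    multivariable p of β2); exposed for completeness.
    """
    se = np.sqrt(beta2 ** 2 * se1 ** 2 + beta1 ** 2 * se2 ** 2)
    return float(min(1.0, 2 * stats.norm.sf(abs(beta1 * beta2) / se)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(pvalues, float)
    if len(p) == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# screening steps on summary datasets

def _uvmr_with_gate(exposure: SummaryDataset, outcome: SummaryDataset,
                    ld, cfg: IVConfig, alpha: float,
                    p_threshold: float | None = None
                    ) -> tuple[MRResults | None, str]:
    """IVW fit with the pleiotropy gate used during screening.

    Returns ``(estimate, reason)``; the estimate is None when instruments
    cannot be formed, and ``reason`` explains a failed gate.
    """
    try:
        h = select_instruments(exposure, outcome, ld, cfg,
                               p_threshold=p_threshold)
    except EstimationError as e:
        return None, f"no_instruments:{e}"
    model = UVMR.from_harmonized(h)
    if h.n_snp == 1:
        est = model.fit("wald")
    else:
        est = model.fit("ivw")
    if est.pvalue >= alpha:
        return est, "not_significant"
    if h.n_snp >= 3:
        _, p_pleio = egger_intercept_test(h)
        if p_pleio < alpha:
            return est, "pleiotropy"
    return est, ""


def screen_exposure_to_mediator(exposure: SummaryDataset,
                                mediators: list[SummaryDataset],
                                ld: LDMatrix | None = None,
                                config: IVConfig | None = None,
                                alpha: float = 0.05
                                ) -> list[tuple[str, MRResults]]:
    """Step 1: mediators causally influenced by the exposure (β1)."""
    cfg = config or IVConfig()
    kept = []
    for med in mediators:
        est, reason = _uvmr_with_gate(exposure, med, ld, cfg, alpha)
        if est is not None and not reason:
            kept.append((med.trait_id, est))
    return kept


def screen_mediator_to_outcome(mediators: list[SummaryDataset],
                               outcome: SummaryDataset,
                               ld: LDMatrix | None = None,
                               config: IVConfig | None = None,
                               alpha: float = 0.05
                               ) -> list[tuple[str, MRResults]]:
    """Step 2: mediators that causally affect the outcome (α)."""
    cfg = config or IVConfig()
    kept = []
    for med in mediators:
        est, reason = _uvmr_with_gate(med, outcome, ld, cfg, alpha)
        if est is not None and not reason:
            kept.append((med.trait_id, est))
    return kept


def adjusted_mediator_effect(exposure: SummaryDataset, mediator: SummaryDataset,
                             outcome: SummaryDataset,
                             ld: LDMatrix | None = None,
                             config: IVConfig | None = None) -> MRResults:
    """Step 4: the mediator's direct effect on the outcome adjusted for the
    exposure (β2), from the joint multivariable fit."""
    mh = assemble_mv_set([mediator, exposure], outcome, ld, config)
    return mv_ivw(mh)[mediator.trait_id]


def estimate_pathway(exposure: SummaryDataset, mediator: SummaryDataset,
                     outcome: SummaryDataset, ld: LDMatrix | None = None,
                     config: IVConfig | None = None) -> MediationResult:
    """Estimate β, β1, α, β2 and the decomposition for a single triple.

    Pure estimation: no significance or pleiotropy gates are applied.  Used
    for recovery experiments where the decomposition itself is of interest;
    the screen (:func:`run_mediation_screen`) applies the gates.
    """
    cfg = config or IVConfig()
    h_xy = select_instruments(exposure, outcome, ld, cfg)
    total = UVMR.from_harmonized(h_xy).fit(
        "wald" if h_xy.n_snp == 1 else "ivw")
    h_xm = select_instruments(exposure, mediator, ld, cfg)
    b1 = UVMR.from_harmonized(h_xm).fit("wald" if h_xm.n_snp == 1 else "ivw")
    h_my = select_instruments(mediator, outcome, ld, cfg)
    a = UVMR.from_harmonized(h_my).fit("wald" if h_my.n_snp == 1 else "ivw")
    b2 = adjusted_mediator_effect(exposure, mediator, outcome, ld, cfg)
    r = MediationResult(exposure.trait_id, mediator.trait_id,
                        outcome.trait_id, total.beta,
                        beta1=b1.beta, alpha=a.beta, beta2=b2.beta,
                        se_beta1=b1.se, se_beta2=b2.se,
                        p_mediator=b2.pvalue)
    return r


def run_mediation_screen(exposures: list[SummaryDataset],
                         mediators: list[SummaryDataset],
                         outcomes: list[SummaryDataset],
                         ld: LDMatrix | None = None,
                         config: IVConfig | None = None,
                         alpha: float = 0.05) -> list[MediationResult]:
    """Execute steps 1–4 for every (exposure, mediator, outcome) triple.

    Only pairs with a significant exposure → outcome total effect enter the
    screen; every candidate's step record is returned (retained or not) so
    nothing is silently dropped.
    """
    cfg = config or IVConfig()
    results: list[MediationResult] = []
    for exposure in exposures:
        for outcome in outcomes:
            total, reason = _uvmr_with_gate(exposure, outcome, ld, cfg, alpha)
            if total is None or reason:
                continue
            step1 = dict(screen_exposure_to_mediator(exposure, mediators,
                                                     ld, cfg, alpha))
            step2 = dict(screen_mediator_to_outcome(mediators, outcome,
                                                    ld, cfg, alpha))
            for med in mediators:
                r = MediationResult(exposure.trait_id, med.trait_id,
                                    outcome.trait_id, total.beta)
                passed = set()
                if med.trait_id in step1:
                    passed.add("step1")
                    b1 = step1[med.trait_id]
                    r.beta1, r.se_beta1 = b1.beta, b1.se
                else:
                    r.fail_reason = "step1"
                if med.trait_id in step2:
                    passed.add("step2")
                    r.alpha = step2[med.trait_id].beta
                elif not r.fail_reason:
                    r.fail_reason = "step2"
                if {"step1", "step2"} <= passed:
                    if sign_consistent(total.beta, r.beta1, r.alpha):
                        passed.add("sign")
                    else:
                        r.fail_reason = "sign"
                if "sign" in passed:
                    try:
                        b2 = adjusted_mediator_effect(exposure, med, outcome,
                                                      ld, cfg)
                        r.beta2, r.se_beta2 = b2.beta, b2.se
                        r.p_mediator = b2.pvalue
                        if b2.pvalue < alpha:
                            passed.add("step4")
                        else:
                            r.fail_reason = "step4"
                    except EstimationError as e:
                        r.fail_reason = f"step4_estimation:{e}"
                r.passed_steps = frozenset(passed)
                results.append(r)
    return results


def mediation_table(results: list[MediationResult],
                    retained_only: bool = False) -> pd.DataFrame:
    rows = [r.to_row() for r in results if r.retained or not retained_only]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture-injection screening: apply the step-4 retention rule to a table of
# precomputed candidate estimates (no per-variant data required)

def screen_candidate_table(candidates: pd.DataFrame,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Apply step-4 retention to precomputed candidate rows.

    ``candidates`` must carry columns ``outcome, mediator, exposure,
    uvmr_or, uvmr_p, mvmr_beta, mvmr_p`` — i.e. each row is a pathway that
    already passed steps 1–3 with its marginal (UVMR) and adjusted (MVMR)
    mediator-on-outcome estimates.  Rows with multivariable p < ``alpha``
    are retained.
    """
    required = {"outcome", "mediator", "exposure", "uvmr_p", "mvmr_beta",
                "mvmr_p"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns {sorted(missing)}")
    out = candidates.copy()
    out["retained"] = out["mvmr_p"] < alpha
    return out
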