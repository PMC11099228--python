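"""Repeatable simulation experiments: recovery, calibration, outlier power.

These functions define the study conditions under which the pipeline is
validated and are shared by the test suite and the acceptance script.  Each
takes an explicit seed and derives independent per-replicate seeds from it.

Problem sizes are design choices, stated here once:

- **recovery**: 100 true instruments per trait; instrument-side GWAS large
  enough (n = 400,000) that per-instrument F is in the hundreds and
  winner's curse is negligible, and downstream GWAS sized so that true
  propagated per-SNP effects stay below the outcome-association exclusion
  threshold — the regime in which the product-of-coefficients decomposition
  is expected to recover the structural truth.
- **calibration**: ~110 retained instruments (immune-cell-like counts); at
  small instrument counts the overdispersion floor max(1, σ̂) makes the IVW
  and Egger-intercept tests visibly conservative, so the nominal-level check
  is run where that finite-sample distortion is negligible.
- **outlier power**: ~25 instruments with one outcome effect displaced by
  10 outcome standard errors, the canonical gross-pleiotropy outlier.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .instruments import select_instruments
from .mediation import estimate_pathway
from .sensitivity import cochran_q, egger_intercept_test, mr_presso
from .simulate import SimConfig, generate_null_study, generate_study
from .uvmr import UVMR

#: conditions for the parameter-recovery experiment: a very precise
#: instrument-side GWAS (per-instrument F in the hundreds, negligible
#: winner's curse) feeding moderately-sized downstream GWAS, so that true
#: propagated per-SNP effects stay below the outcome-association exclusion
#: threshold — the regime of the studies this generator emulates, in which
#: that filter removes almost nothing
RECOVERY_CONFIG = SimConfig(
    n_snp_exposure=100, n_snp_mediator=100,
    n_gwas_exposure=400_000, n_gwas_mediator=13_000,
    n_gwas_outcome=20_000,
    effect_sd=0.03, mediator_effect_sd=0.15,
    eaf_range=(0.2, 0.5),
    beta1=0.5, beta2=0.2, direct_effect=0.2)

#: conditions for null-calibration runs
CALIBRATION_CONFIG = SimConfig(
    n_snp_exposure=160, n_snp_mediator=5, effect_sd=0.25)

#: conditions for the outlier-detection experiment
OUTLIER_CONFIG = SimConfig(
    n_snp_exposure=30, n_snp_mediator=5,
    n_gwas_exposure=400_000, n_gwas_mediator=13_000,
    n_gwas_outcome=20_000,
    effect_sd=0.03, mediator_effect_sd=0.15,
    eaf_range=(0.2, 0.5),
    beta1=0.5, beta2=0.2, direct_effect=0.2)


def _spawn(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit replicate seeds derived from one master seed."""
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def recovery_experiment(n_rep: int = 200, seed: int = 0,
                        config: SimConfig = RECOVERY_CONFIG) -> dict:
    """Recover the mediation decomposition over seeded replicates.

    Returns medians of the estimated total effect and mediation proportion
    together with the structural truth of the generating model.
    """
    totals, props = [], []
    for s in _spawn(seed, n_rep):
        cfg = replace(config, seed=int(s))
        exposure, mediator, outcome, truth = generate_study(cfg)
        r = estimate_pathway(exposure, mediator, outcome)
        totals.append(r.beta_total)
        props.append(r.proportion)
    return {
        "n_rep": n_rep,
        "true_total": config.total_effect,
        "true_proportion": config.beta1 * config.beta2 / config.total_effect,
        "median_total": float(np.median(totals)),
        "median_proportion": float(np.median(props)),
        "totals": np.asarray(totals), "proportions": np.asarray(props),
    }


def null_calibration(n_rep: int = 2000, seed: int = 0, alpha: float = 0.05,
                     config: SimConfig = CALIBRATION_CONFIG) -> dict:
    """Empirical type-I rates of IVW, Cochran's Q and the Egger intercept
    test on null studies (no causal effect anywhere)."""
    rej = {"ivw": 0, "q": 0, "egger": 0}
    n_snps = []
    for s in _spawn(seed, n_rep):
        cfg = replace(config, seed=int(s))
        exposure, _, outcome, _ = generate_null_study(cfg)
        h = select_instruments(exposure, outcome)
        n_snps.append(h.n_snp)
        model = UVMR.from_harmonized(h)
        if model.fit("ivw").pvalue < alpha:
            rej["ivw"] += 1
        if cochran_q(h)[2] < alpha:
            rej["q"] += 1
        if egger_intercept_test(h)[1] < alpha:
            rej["egger"] += 1
    return {
        "n_rep": n_rep, "alpha": alpha,
        "mean_n_snp": float(np.mean(n_snps)),
        "ivw_rate": rej["ivw"] / n_rep,
        "q_rate": rej["q"] / n_rep,
        "egger_rate": rej["egger"] / n_rep,
    }


def presso_outlier_experiment(n_rep: int = 200, seed: int = 0,
                              displacement_se: float = 10.0,
                              n_sim: int = 1000,
                              config: SimConfig = OUTLIER_CONFIG) -> dict:
    """Detection power for a single displaced-outcome outlier instrument.

    One instrument's outcome effect is shifted by ``displacement_se``
    outcome standard errors after harmonization; the experiment reports how
    often MR-PRESSO flags exactly that SNP and the error of the
    outlier-corrected estimate relative to the structural total effect.
    """
    detected = 0
    corrected = []
    for s in _spawn(seed, n_rep):
        cfg = replace(config, seed=int(s))
        exposure, _, outcome, truth = generate_study(cfg)
        h = select_instruments(exposure, outcome)
        rng = np.random.default_rng(int(s) + 1)
        j = int(rng.integers(0, h.n_snp))
        h.Gamma[j] += displacement_se * h.Gamma_se[j]
        res = mr_presso(h, n_sim=n_sim, seed=int(s) + 2)
        if h.snp_ids[j] in res.outliers:
            detected += 1
        if res.corrected_estimate is not None:
            corrected.append(res.corrected_estimate.beta)
    return {
        "n_rep": n_rep,
        "detection_rate": detected / n_rep,
        "true_total": config.total_effect,
        "median_corrected": float(np.median(corrected)) if corrected
        else float("nan"),
    }
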