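"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the statistical shape of the real inputs to a
microbiome → immune-cell → disease mediation analysis: three summary-
statistic tables (exposure, mediator, binary outcome on the log-odds scale)
over a shared panel of independent SNPs, with a known structural model

    exposure instruments   γⱼ ~ N(0, effect_sd²)
    mediator instruments   δⱼ ~ N(0, effect_sd²)
    mediator true effect   = β1·γⱼ   (exposure SNPs)   or δⱼ
    outcome true effect    = (direct + β1·β2)·γⱼ + pleiotropyⱼ   or   β2·δⱼ

so that the total exposure → outcome effect is direct + β1·β2 and the true
mediation proportion is β1·β2 / (direct + β1·β2).  Observed effects add
N(0, seⱼ²) noise with the standard allele-frequency-scaled standard error
seⱼ = 1/√(2·n·eafⱼ(1−eafⱼ)); p-values are two-sided normal.

Default sample sizes mirror a cohort-scale microbiome GWAS (n ≈ 7,700), a
flow-cytometry immune-phenotype GWAS (n ≈ 3,750) and a case-control lung
cancer GWAS (n ≈ 24,000 on the effective log-odds scale).  With the default
effect_sd the instrument-selection threshold of 1e-5 implies per-SNP F ≳ 19
for every retained instrument, matching the strong-instrument (F > 15)
regime of the studies emulated.

Decoy SNPs — palindromic allele pairs and sub-1% minor-allele-frequency
variants carrying real signal — are injected at configurable rates to
exercise the harmonization and frequency filters.  Linkage disequilibrium is
not simulated (instruments are independent, as they are post-clumping); a
block-diagonal LD injector is provided solely to test the clumping step.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import COLUMNS, ConfigError, LDMatrix, SummaryDataset

#: non-palindromic allele pairs used for regular SNPs
_REGULAR_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                  ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    ``beta1`` is the exposure → mediator effect, ``beta2`` the mediator →
    outcome direct effect, ``direct_effect`` the exposure → outcome path not
    through the mediator; the implied total effect is
    ``direct_effect + beta1·beta2``.
    """

    n_snp_exposure: int = 30
    n_snp_mediator: int = 25
    n_gwas_exposure: int = 7_738
    n_gwas_mediator: int = 3_757
    n_gwas_outcome: int = 24_108
    beta1: float = 0.5
    beta2: float = 0.2
    direct_effect: float = 0.2
    pleiotropy: str = "none"          # {"none", "balanced", "directional"}
    pleiotropy_sd: float = 0.0        # SD of the pleiotropic term
    pleiotropy_mean: float = 0.0      # mean (directional mode only)
    eaf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd: float = 0.15
    mediator_effect_sd: float | None = None  # defaults to effect_sd
    palindromic_rate: float = 0.1     # decoys per exposure instrument
    low_maf_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.eaf_range
        if not (0 < lo < hi <= 0.5):
            raise ConfigError("eaf_range must satisfy 0 < low < high <= 0.5")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy mode {self.pleiotropy!r}")

    @property
    def total_effect(self) -> float:
        return self.direct_effect + self.beta1 * self.beta2


@dataclass
class SimTruth:
    """Ground-truth causal parameters of one generated study."""

    total_effect: float
    beta1: float
    beta2: float
    direct_effect: float
    alpha_marginal: float
    proportion_true: float | None
    proportion_undefined: bool
    seed: int
    true_effects: dict = field(default_factory=dict)  # per-SNP truth arrays
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["true_effects"] = {k: list(map(float, v))
                                   for k, v in self.true_effects.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _se(n: int, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _dataset(trait_id: str, snp_ids, chrom, pos, pairs, eaf, true_beta,
             n_gwas: int, rng: np.random.Generator,
             trait_scale: str) -> SummaryDataset:
    from scipy import stats
    se = _se(n_gwas, eaf)
    beta = true_beta + rng.normal(0.0, se)
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    p = np.maximum(p, np.finfo(float).tiny)
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": [a for a, _ in pairs],
        "other_allele": [b for _, b in pairs],
        "eaf": eaf, "beta": beta, "se": se, "pvalue": p,
        "n": n_gwas,
    })[COLUMNS]
    return SummaryDataset(trait_id, df, trait_scale=trait_scale)


def generate_study(cfg: SimConfig
                   ) -> tuple[SummaryDataset, SummaryDataset, SummaryDataset,
                              SimTruth]:
    """Generate (exposure, mediator, outcome, truth), fully seeded.

    All three datasets cover the same SNP panel so any direction of analysis
    can be harmonized.  SNPs are placed far apart on alternating chromosomes
    (no residual LD to model).
    """
    rng = np.random.default_rng(cfg.seed)
    n_e, n_m = cfg.n_snp_exposure, cfg.n_snp_mediator
    n_pal = int(round(cfg.palindromic_rate * n_e))
    n_low = int(round(cfg.low_maf_rate * n_e))
    n_total = n_e + n_m + n_pal + n_low

    snp_ids = [f"rs{100000 + i}" for i in range(n_total)]
    chrom = [str(1 + i % 22) for i in range(n_total)]
    # > 10 Mb spacing within a chromosome: independent for clumping purposes
    pos = [1_000_000 + 20_000_000 * (i // 22) for i in range(n_total)]
    pair_idx = rng.integers(0, len(_REGULAR_PAIRS), size=n_total)
    pairs = [_REGULAR_PAIRS[i] for i in pair_idx]
    for j in range(n_pal):
        pairs[n_e + n_m + j] = _PALINDROMIC_PAIRS[int(pair_idx[n_e + n_m + j])
                                                  % len(_PALINDROMIC_PAIRS)]
    eaf = rng.uniform(*cfg.eaf_range, size=n_total)
    lo_slice = slice(n_e + n_m + n_pal, n_total)
    eaf[lo_slice] = rng.uniform(0.001, 0.009, size=n_low)

    # true per-SNP effects; decoys behave like exposure instruments so the
    # palindrome/MAF filters are what removes them, not the p threshold
    gamma = np.zeros(n_total)
    gamma[:n_e] = rng.normal(0.0, cfg.effect_sd, size=n_e)
    gamma[n_e + n_m:] = rng.normal(0.0, cfg.effect_sd, size=n_pal + n_low)
    delta = np.zeros(n_total)
    med_sd = (cfg.mediator_effect_sd if cfg.mediator_effect_sd is not None
              else cfg.effect_sd)
    delta[n_e:n_e + n_m] = rng.normal(0.0, med_sd, size=n_m)

    pleio = np.zeros(n_total)
    if cfg.pleiotropy != "none":
        is_exposure_snp = gamma != 0
        pleio[is_exposure_snp] = rng.normal(
            cfg.pleiotropy_mean if cfg.pleiotropy == "directional" else 0.0,
            cfg.pleiotropy_sd, size=int(is_exposure_snp.sum()))

    true_exposure = gamma
    true_mediator = cfg.beta1 * gamma + delta
    true_outcome = (cfg.direct_effect * gamma + cfg.beta2 * true_mediator
                    + pleio)

    exposure = _dataset("exposure", snp_ids, chrom, pos, pairs, eaf,
                        true_exposure, cfg.n_gwas_exposure, rng, "continuous")
    mediator = _dataset("mediator", snp_ids, chrom, pos, pairs, eaf,
                        true_mediator, cfg.n_gwas_mediator, rng, "continuous")
    outcome = _dataset("outcome", snp_ids, chrom, pos, pairs, eaf,
                       true_outcome, cfg.n_gwas_outcome, rng, "log_odds")

    total = cfg.total_effect
    undefined = total == 0.0
    truth = SimTruth(
        total_effect=total, beta1=cfg.beta1, beta2=cfg.beta2,
        direct_effect=cfg.direct_effect, alpha_marginal=cfg.beta2,
        proportion_true=None if undefined else cfg.beta1 * cfg.beta2 / total,
        proportion_undefined=undefined, seed=cfg.seed,
        true_effects={"exposure": true_exposure, "mediator": true_mediator,
                      "outcome": true_outcome},
        config=asdict(cfg))
    return exposure, mediator, outcome, truth


def generate_null_study(cfg: SimConfig):
    """The same generative scheme with every causal parameter set to zero.

    Instruments still carry real effects on their own trait, so selection
    works as usual, but no trait causes another.
    """
    from dataclasses import replace
    null_cfg = replace(cfg, beta1=0.0, beta2=0.0, direct_effect=0.0)
    return generate_study(null_cfg)


def block_ld_matrix(snp_ids, block_size: int = 2, r2: float = 0.5) -> LDMatrix:
    """Deterministic block-diagonal r² matrix for exercising the clumper."""
    k = len(snp_ids)
    m = np.eye(k)
    for start in range(0, k, block_size):
        stop = min(start + block_size, k)
        m[start:stop, start:stop] = r2
    np.fill_diagonal(m, 1.0)
    return LDMatrix(list(snp_ids), m)


def write_study(outdir, exposure, mediator, outcome, truth: SimTruth) -> None:
    """Write the three tables and a truth JSON sidecar into ``outdir``."""
    from pathlib import Path
    from .io import write_summary_stats
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds in (exposure, mediator, outcome):
        write_summary_stats(ds, outdir / f"{ds.trait_id}.tsv")
    truth.to_json(outdir / "truth.json")
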