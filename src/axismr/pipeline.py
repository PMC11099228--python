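"""Study orchestration: bidirectional UVMR, mediation screen, reports.

``run_full_study`` executes the two-step design end to end:

1. forward UVMR of every exposure on every outcome (instrument threshold
   1e-5) and reverse UVMR of every outcome on every exposure (threshold
   5e-8); pairs significant in both directions are flagged reverse-causal
   and excluded from mediation;
2. the four-step mediator screen on the eligible pairs, sensitivity gating
   (estimates whose pair fails the pleiotropy tests carry an ``invalidated``
   flag), per-family BH-FDR q-values, and TSV report emission.

Everything is deterministic given the config and seed; every skipped pair
or failed candidate appears in the audit output with a reason code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .instruments import EstimationError, IVConfig, select_instruments
from .io import ConfigError, LDMatrix, SummaryDataset, read_ld_matrix, \
    read_summary_stats
from .mediation import bh_fdr, mediation_table, run_mediation_screen, \
    screen_candidate_table
from .sensitivity import sensitivity_report
from .uvmr import UVMR

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_ESTIMATION = 3


@dataclass
class StudyConfig:
    """Declarative run plan for a full study."""

    exposure_paths: list = field(default_factory=list)
    mediator_paths: list = field(default_factory=list)
    outcome_paths: list = field(default_factory=list)
    ld_path: str | None = None
    injected_candidates: str | None = None  # fixture-injection mode
    iv: IVConfig = field(default_factory=IVConfig)
    alpha: float = 0.05
    fdr_family: str = "outcome"   # BH family key: "outcome" or "all"
    presso_n_sim: int = 1000
    run_presso: bool = True
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        iv = IVConfig(**raw.pop("iv", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(iv=iv, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for group in (self.exposure_paths, self.mediator_paths,
                      self.outcome_paths):
            for p in group:
                if not Path(p).exists():
                    raise ConfigError(f"referenced path does not exist: {p}")
        if self.ld_path and not Path(self.ld_path).exists():
            raise ConfigError(f"LD matrix path does not exist: {self.ld_path}")
        if self.injected_candidates and not Path(self.injected_candidates).exists():
            raise ConfigError(
                f"injected candidate table does not exist: {self.injected_candidates}")


def _load(paths, scale) -> list[SummaryDataset]:
    return [read_summary_stats(p, trait_scale=scale) for p in paths]


def run_bidirectional_uvmr(exposures: list[SummaryDataset],
                           outcomes: list[SummaryDataset],
                           ld: LDMatrix | None = None,
                           iv: IVConfig | None = None,
                           alpha: float = 0.05,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, set]:
    """Forward and reverse UVMR for every pair.

    Returns (forward table, reverse table, reverse-causal pair set); a pair
    significant in both directions is flagged and excluded from mediation.
    Pairs without usable instruments are recorded with a skip reason.
    """
    cfg = iv or IVConfig()
    fwd_rows, rev_rows = [], []
    reverse_causal: set[tuple[str, str]] = set()
    sig = {}
    for direction, pairs, p_thr in (
            ("forward", [(e, o) for e in exposures for o in outcomes],
             cfg.iv_p_threshold),
            ("reverse", [(o, e) for e in exposures for o in outcomes],
             cfg.reverse_iv_p_threshold)):
        for exp_ds, out_ds in pairs:
            row = {"exposure": exp_ds.trait_id, "outcome": out_ds.trait_id,
                   "direction": direction}
            try:
                h = select_instruments(exp_ds, out_ds, ld, cfg,
                                       p_threshold=p_thr)
                model = UVMR.from_harmonized(h)
                est = model.fit("wald" if h.n_snp == 1 else "ivw")
                row.update(est.to_row())
                row["skip_reason"] = ""
                sig[(direction, exp_ds.trait_id, out_ds.trait_id)] = \
                    est.pvalue < alpha
            except EstimationError as e:
                row["skip_reason"] = str(e)
                logger.info("%s %s->%s skipped: %s", direction,
                            exp_ds.trait_id, out_ds.trait_id, e)
            (fwd_rows if direction == "forward" else rev_rows).append(row)
    for e in exposures:
        for o in outcomes:
            if sig.get(("forward", e.trait_id, o.trait_id)) and \
               sig.get(("reverse", o.trait_id, e.trait_id)):
                reverse_causal.add((e.trait_id, o.trait_id))
    return pd.DataFrame(fwd_rows), pd.DataFrame(rev_rows), reverse_causal


def run_full_study(cfg: StudyConfig,
                   exposures: list[SummaryDataset] | None = None,
                   mediators: list[SummaryDataset] | None = None,
                   outcomes: list[SummaryDataset] | None = None) -> dict:
    """Execute the whole study and write the report bundle to cfg.out_dir.

    Datasets may be passed in memory (tests, simulations) or loaded from the
    config paths.  Returns the bundle as a dict of DataFrames.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.injected_candidates:
        candidates = pd.read_csv(cfg.injected_candidates, sep="\t")
        screened = screen_candidate_table(candidates, cfg.alpha)
        retained = screened[screened["retained"]]
        screened.to_csv(out / "mediation_candidates.tsv", sep="\t", index=False)
        retained.to_csv(out / "mediation_results.tsv", sep="\t", index=False)
        _write_log(out, cfg, {"mode": "fixture-injection",
                              "n_candidates": len(screened),
                              "n_retained": int(screened["retained"].sum())})
        return {"mediation_candidates": screened, "mediation_results": retained}

    if exposures is None:
        exposures = _load(cfg.exposure_paths, "continuous")
    if mediators is None:
        mediators = _load(cfg.mediator_paths, "continuous")
    if outcomes is None:
        outcomes = _load(cfg.outcome_paths, "log_odds")
    ld = read_ld_matrix(cfg.ld_path) if cfg.ld_path else None

    fwd, rev, reverse_causal = run_bidirectional_uvmr(
        exposures, outcomes, ld, cfg.iv, cfg.alpha)
    fwd["reverse_causal"] = [
        (r["exposure"], r["outcome"]) in reverse_causal
        for _, r in fwd.iterrows()]

    # sensitivity per estimable forward pair; gate the causal claims
    sens_rows = []
    invalidated = set()
    for e in exposures:
        for o in outcomes:
            try:
                h = select_instruments(e, o, ld, cfg.iv)
                if h.n_snp < 3:
                    continue
                rep = sensitivity_report(
                    h, n_sim=cfg.presso_n_sim, seed=cfg.seed,
                    run_presso=cfg.run_presso)
                sens_rows.append(rep.to_row())
                if rep.pleiotropy_flag:
                    invalidated.add((e.trait_id, o.trait_id))
            except EstimationError:
                continue
    sens = pd.DataFrame(sens_rows)
    if len(fwd):
        fwd["invalidated"] = [
            (r["exposure"], r["outcome"]) in invalidated
            for _, r in fwd.iterrows()]

    # FDR per configured family over the forward IVW p-values
    if len(fwd) and "pvalue" in fwd:
        est = fwd["pvalue"].notna()
        fwd["fdr_q"] = np.nan
        if cfg.fdr_family == "all":
            fwd.loc[est, "fdr_q"] = bh_fdr(fwd.loc[est, "pvalue"])
        else:
            for _, idx in fwd.loc[est].groupby("outcome").groups.items():
                fwd.loc[idx, "fdr_q"] = bh_fdr(fwd.loc[idx, "pvalue"])

    eligible_exposures = [
        e for e in exposures
        if any(((e.trait_id, o.trait_id) not in reverse_causal)
               for o in outcomes)]
    screen = run_mediation_screen(eligible_exposures, mediators, outcomes,
                                  ld, cfg.iv, cfg.alpha)
    screen = [r for r in screen
              if (r.exposure_id, r.outcome_id) not in reverse_causal
              and (r.exposure_id, r.outcome_id) not in invalidated]
    audit = mediation_table(screen, retained_only=False)
    results = mediation_table(screen, retained_only=True)

    fwd.to_csv(out / "uvmr_forward.tsv", sep="\t", index=False)
    rev.to_csv(out / "uvmr_reverse.tsv", sep="\t", index=False)
    sens.to_csv(out / "sensitivity.tsv", sep="\t", index=False)
    audit.to_csv(out / "mediation_candidates.tsv", sep="\t", index=False)
    results.to_csv(out / "mediation_results.tsv", sep="\t", index=False)
    _write_log(out, cfg, {
        "mode": "full", "n_pairs": len(fwd),
        "n_reverse_causal": len(reverse_causal),
        "n_invalidated": len(invalidated),
        "n_candidates": len(audit), "n_retained": len(results)})
    return {"uvmr_forward": fwd, "uvmr_reverse": rev, "sensitivity": sens,
            "mediation_candidates": audit, "mediation_results": results,
            "reverse_causal": reverse_causal}


def _write_log(out: Path, cfg: StudyConfig, extra: dict) -> None:
    payload = {"version": __version__, "seed": cfg.seed,
               "config": {**asdict(cfg), "iv": asdict(cfg.iv)}}
    payload.update(extra)
    with open(out / "run_log.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str)
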