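"""End-to-end pipeline: generate → match → efficacy → CEA → sensitivity.

Each stage writes plain CSV/JSON artifacts into the output directory and is
recorded in a :class:`RunManifest` (config hash, seeds, file inventory with
SHA-256 digests).  Re-running with the same configuration and seeds
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, simulate_cohort
from .config import (build_cohort_spec, build_model_config, build_psa_parameters,
                     config_hash, load_config, matching_settings,
                     tornado_parameters)
from .efficacy import compare_continuous, compare_proportions, response_rates
from .errors import ConfigurationError, DegenerateDataError, DependencyError
from .markov import run_cea, run_cohort
from .matching import balance_table, fit_propensity, match_pairs
from .records import ACRLevel, PatientRecord, read_cohort_csv, write_cohort_csv
from .sensitivity import one_way_tornado, run_psa

__all__ = ["RunManifest", "run_pipeline", "STAGES"]

STAGES = ("cohort", "match", "efficacy", "cea", "tornado", "psa")

log = logging.getLogger("racea")


@dataclass
class RunManifest:
    """What a pipeline run did, sufficient to reproduce it exactly."""

    config_hash: str
    seeds: Dict[str, int]
    stages: List[str]
    outputs: Dict[str, str]  # artifact name -> sha256 of the file
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


_DELTA_MEASURES = (
    "sjc28", "tjc28", "stiffness_min", "vas", "esr", "crp", "das28", "rf", "haq",
)


def _efficacy_tables(records: Sequence[PatientRecord]):
    """Per-patient ACR classification, cumulative rates and Δ-comparisons."""
    classified = [r for r in records if r.response is not None]
    cls = pd.DataFrame(
        {
            "id": [r.id for r in classified],
            "arm": [r.arm for r in classified],
            "level": [r.response.name for r in classified],
        }
    )
    rate_rows = []
    by_arm = {}
    for arm in ("TOF", "ADA"):
        levels = [r.response for r in classified if r.arm == arm]
        rt = response_rates(levels)
        by_arm[arm] = rt
        for lv in ("ACR20", "ACR50", "ACR70"):
            rate_rows.append(
                {"arm": arm, "level": lv, "responders": rt.counts[lv],
                 "n": rt.n, "rate_percent": rt.rates[lv]}
            )
    rates = pd.DataFrame(rate_rows)

    comp_rows = []
    for lv in ("ACR20", "ACR50", "ACR70"):
        chi2, p = compare_proportions(
            by_arm["TOF"].counts[lv], by_arm["TOF"].n,
            by_arm["ADA"].counts[lv], by_arm["ADA"].n,
        )
        comp_rows.append({"measure": f"{lv} rate", "test": "chi-square",
                          "statistic": chi2, "p_value": p,
                          "tof": by_arm["TOF"].rates[lv],
                          "ada": by_arm["ADA"].rates[lv]})
    for m in _DELTA_MEASURES:
        deltas = {
            arm: [getattr(r.baseline, m) - getattr(r.month6, m)
                  for r in classified if r.arm == arm]
            for arm in ("TOF", "ADA")
        }
        try:
            res = compare_continuous(deltas["TOF"], deltas["ADA"],
                                     measure=f"delta_{m}")
        except DegenerateDataError:
            # e.g. RF is carried forward unchanged by the simulator
            comp_rows.append({"measure": f"delta_{m}", "test": "none (constant)",
                              "statistic": float("nan"), "p_value": float("nan"),
                              "tof": "", "ada": ""})
            continue
        comp_rows.append({"measure": res.measure, "test": res.test,
                          "statistic": res.statistic, "p_value": res.p_value,
                          "tof": res.summary_a, "ada": res.summary_b})
    return cls, rates, pd.DataFrame(comp_rows)


def run_pipeline(
    config: Union[None, str, Path, Dict[str, Any]] = None,
    stages: Sequence[str] = STAGES,
    out_dir: Union[str, Path] = "racea_out",
    seed: Optional[int] = None,
) -> RunManifest:
    """Execute the requested stages in dependency order.

    ``config`` is a YAML path, an already-loaded dictionary, or None for the
    packaged defaults.  ``seed`` overrides the configured seeds (cohort uses
    ``seed``, the PSA ``seed + 1``).  Stages needing an upstream artifact
    either run after it in the same call or read it from ``out_dir``.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, Path] = {}

    cohort_spec = build_cohort_spec(cfg, seed=seed)
    psa_seed = int(seed + 1 if seed is not None
                   else cfg.get("sensitivity", {}).get("psa", {}).get("seed", 0))
    seeds = {"cohort": cohort_spec.seed, "psa": psa_seed}

    records: Optional[List[PatientRecord]] = None

    def _need_cohort(stage: str) -> List[PatientRecord]:
        nonlocal records
        if records is None:
            path = out / "cohort.csv"
            if not path.exists():
                raise DependencyError(
                    f"stage {stage!r} needs the cohort; run the 'cohort' stage "
                    f"first or place cohort.csv in {out}"
                )
            records = read_cohort_csv(path)
        return records

    for stage in stages:
        log.info("stage %s", stage)
        if stage == "cohort":
            records = simulate_cohort(cohort_spec)
            write_cohort_csv(records, out / "cohort.csv")
            outputs["cohort"] = out / "cohort.csv"

        elif stage == "match":
            recs = _need_cohort(stage)
            ms = matching_settings(cfg)
            fit = fit_propensity(recs, ms["covariates"])
            cohort = match_pairs(fit, caliper_sd=ms["caliper_sd"], order=ms["order"])
            bal = balance_table(recs, cohort, ms["covariates"])
            cohort.to_frame().to_csv(out / "pairs.csv", index=False)
            bal.to_csv(out / "balance.csv")
            outputs["pairs"] = out / "pairs.csv"
            outputs["balance"] = out / "balance.csv"

        elif stage == "efficacy":
            recs = _need_cohort(stage)
            pairs_path = out / "pairs.csv"
            if pairs_path.exists():
                pairs = pd.read_csv(pairs_path)
                keep = set(pairs["tof_id"]) | set(pairs["ada_id"])
                recs = [r for r in recs if r.id in keep]
            cls, rates, comps = _efficacy_tables(recs)
            cls.to_csv(out / "acr_classification.csv", index=False)
            rates.to_csv(out / "response_rates.csv", index=False)
            comps.to_csv(out / "comparisons.csv", index=False)
            for name in ("acr_classification", "response_rates", "comparisons"):
                outputs[name] = out / f"{name}.csv"

        elif stage == "cea":
            model = build_model_config(cfg)
            for arm in ("tof", "ada"):
                run_cohort(model, arm).to_frame().to_csv(
                    out / f"trace_{arm}.csv", index=False
                )
                outputs[f"trace_{arm}"] = out / f"trace_{arm}.csv"
            result = run_cea(model)
            summary = result.summary_frame()
            summary.to_csv(out / "cea_summary.csv", index_label="quantity")
            payload = {
                "arms": {a: dataclasses.asdict(r) for a, r in result.arm_results.items()},
                "incremental": dataclasses.asdict(result.incremental),
                "currency": result.currency,
            }
            (out / "cea_summary.json").write_text(json.dumps(payload, indent=2))
            outputs["cea_summary_csv"] = out / "cea_summary.csv"
            outputs["cea_summary_json"] = out / "cea_summary.json"

        elif stage == "tornado":
            model = build_model_config(cfg)
            rel = cfg.get("sensitivity", {}).get("tornado", {}).get("rel_change", 0.10)
            res = one_way_tornado(model, tornado_parameters(cfg), rel_change=rel)
            res.to_frame().to_csv(out / "tornado.csv", index=False)
            outputs["tornado"] = out / "tornado.csv"

        elif stage == "psa":
            model = build_model_config(cfg)
            n_iter = int(cfg.get("sensitivity", {}).get("psa", {}).get(
                "n_iterations", 5000))
            res = run_psa(model, n_iterations=n_iter, seed=psa_seed,
                          parameters=build_psa_parameters(cfg))
            res.draws.to_csv(out / "psa_draws.csv", index=False)
            res.ceac_frame().to_csv(out / "ceac.csv", index=False)
            (out / "psa_summary.json").write_text(json.dumps({
                "n_iterations": res.n_iterations,
                "seed": res.seed,
                "wtp": res.wtp,
                "p_cost_effective_at_wtp": res.p_ce_at_wtp,
                "mean_delta_cost": float(res.draws["delta_cost"].mean()),
                "mean_delta_qalys": float(res.draws["delta_qalys"].mean()),
            }, indent=2))
            outputs["psa_draws"] = out / "psa_draws.csv"
            outputs["ceac"] = out / "ceac.csv"
            outputs["psa_summary"] = out / "psa_summary.json"

    manifest = RunManifest(
        config_hash=config_hash(cfg),
        seeds=seeds,
        stages=list(stages),
        outputs={name: _sha256(path) for name, path in outputs.items()},
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
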