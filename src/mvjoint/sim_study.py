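"""Simulation-study harness: batch-simulate, fit both variants, tabulate.

For each replicate the harness simulates a joint dataset from the study
design, fits the requested model variants, and records posterior means of
the tracked population parameters together with the conditional DIC.
Aggregation reports, per parameter and variant,

    percent bias = 100 * (mean estimate - TP) / |TP|,
    percent MSE  = 100 * MSE / |TP|,

where TP is the true parameter value and the MSE is taken over replicates.
Percent MSE is non-negative by construction.

The desk-scale defaults (10 replicates, 150 subjects, 10 visits, 3 chains
of 4,000 iterations with 1,000 burn-in and thinning 5) keep a full study
within minutes on one CPU; ``paper_scale_design``/``paper_scale_config``
expose the full-size study (50 replicates, 500 subjects, 32 visits, 3
chains of 30,000 with 10,000 burn-in retaining every 20th draw), available
from the command line behind ``--paper-scale``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc_engine import MCMCConfig, PosteriorDraws, build_fit, run_mcmc
from .posterior_analysis import dic, summarize
from .simulator import SimulationDesign, SNErrors, default_design, simulate_dataset, cohort_visit_schedule

__all__ = [
    "SimStudyResult",
    "desk_design",
    "desk_config",
    "paper_scale_design",
    "paper_scale_config",
    "run_sim_study",
    "aggregate",
    "tabulate",
]

logger = logging.getLogger(__name__)


def desk_design(**overrides) -> SimulationDesign:
    """Default gamma-error design scaled to 150 subjects and 10 visits."""
    overrides.setdefault("n_subjects", 150)
    overrides.setdefault("visit_schedule", cohort_visit_schedule()[:10])
    return default_design(**overrides)


def desk_config(**overrides) -> MCMCConfig:
    overrides.setdefault("n_chains", 3)
    overrides.setdefault("n_iterations", 4000)
    overrides.setdefault("burn_in", 1000)
    overrides.setdefault("thin", 5)
    return MCMCConfig(**overrides)


def paper_scale_design(**overrides) -> SimulationDesign:
    return default_design(**overrides)


def paper_scale_config(**overrides) -> MCMCConfig:
    return MCMCConfig.paper_schedule(**overrides)


@dataclass
class SimStudyResult:
    """Replicate-level posterior means plus the study truth.

    ``estimates`` is tidy: one row per (replicate, variant, parameter);
    ``dics`` one row per (replicate, variant).  ``n_failed`` counts
    replicates excluded after a fit failure.
    """

    estimates: pd.DataFrame
    dics: pd.DataFrame
    truth: dict
    design: SimulationDesign
    variants: tuple
    n_failed: int = 0


def _truth_map(design: SimulationDesign) -> dict:
    spec = design.spec
    truth: dict[str, float] = {}
    for k in range(spec.n_outcomes):
        for t in range(spec.n_fixed):
            truth[f"beta{t}{k + 1}"] = float(design.true_beta[k, t])
    if isinstance(design.error_model, SNErrors):
        for k, d in enumerate(design.error_model.skew):
            truth[f"delta{k + 1}"] = float(d)
    for j, v in enumerate(design.true_upsilon):
        truth[f"upsilon{j + 1}"] = float(v)
    for j, a in enumerate(design.true_alpha):
        truth[f"alpha{j + 1}"] = float(a)
    return truth


def _tracked(design: SimulationDesign, variant: str) -> list[str]:
    spec = design.spec
    names = [f"beta{t}{k + 1}" for k in range(spec.n_outcomes) for t in range(spec.n_fixed)]
    if variant == "sn":
        names += [f"delta{k + 1}" for k in range(spec.n_outcomes)]
    names += [f"upsilon{j + 1}" for j in range(len(design.true_upsilon))]
    names += [f"alpha{j + 1}" for j in range(len(design.true_alpha))]
    return names


def run_sim_study(
    design: SimulationDesign,
    n_datasets: int,
    variants=("sn", "n"),
    config: MCMCConfig | None = None,
    seed: int = 0,
    checkpoint_dir=None,
) -> SimStudyResult:
    """Run the full study: simulate, fit each variant, collect estimates.

    Replicate r uses dataset seed ``seed + 1 + r`` and chain seed
    ``seed + 1 + r`` so partial runs are reproducible; with
    ``checkpoint_dir`` each finished replicate is written to JSON and
    skipped on re-run.  A replicate whose fit raises is logged, excluded,
    and counted in ``n_failed``.
    """
    config = config if config is not None else desk_config()
    ckpt = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt:
        ckpt.mkdir(parents=True, exist_ok=True)
    est_rows, dic_rows = [], []
    n_failed = 0
    for r in range(n_datasets):
        rep_seed = seed + 1 + r
        ck_file = ckpt / f"replicate_{r:03d}.json" if ckpt else None
        if ck_file and ck_file.exists():
            payload = json.loads(ck_file.read_text())
            est_rows += payload["estimates"]
            dic_rows += payload["dics"]
            continue
        try:
            long_ds, surv_ds, _ = simulate_dataset(design, rep_seed)
            fit = build_fit(long_ds, surv_ds, design.spec)
            rep_est, rep_dic = [], []
            for variant in variants:
                cfg = MCMCConfig(
                    n_chains=config.n_chains,
                    n_iterations=config.n_iterations,
                    burn_in=config.burn_in,
                    thin=config.thin,
                    seed=rep_seed,
                    proposal_scales=dict(config.proposal_scales),
                    init_strategy=config.init_strategy,
                    store_random_effects=config.store_random_effects,
                    update_order=config.update_order,
                )
                draws = run_mcmc(
                    long_ds, surv_ds, design.spec, config=cfg, model_variant=variant
                )
                summ = summarize(draws)
                for name in _tracked(design, variant):
                    rep_est.append(
                        {
                            "replicate": r,
                            "variant": variant,
                            "parameter": name,
                            "estimate": float(summ.loc[name, "PM"]),
                        }
                    )
                d = dic(draws, fit.designs, fit.sdesign)
                rep_dic.append({"replicate": r, "variant": variant, "dic": d.dic})
        except Exception:
            logger.exception("replicate %d failed; excluding it", r)
            n_failed += 1
            continue
        est_rows += rep_est
        dic_rows += rep_dic
        if ck_file:
            ck_file.write_text(json.dumps({"estimates": rep_est, "dics": rep_dic}))
        logger.info("replicate %d/%d done", r + 1, n_datasets)
    return SimStudyResult(
        estimates=pd.DataFrame(est_rows),
        dics=pd.DataFrame(dic_rows),
        truth=_truth_map(design),
        design=design,
        variants=tuple(variants),
        n_failed=n_failed,
    )


def aggregate(result: SimStudyResult) -> pd.DataFrame:
    """Per-parameter, per-variant TP, mean estimate, percent bias/MSE."""
    rows = []
    for (variant, name), grp in result.estimates.groupby(["variant", "parameter"]):
        est = grp["estimate"].to_numpy(float)
        tp = result.truth.get(name)
        row = {
            "parameter": name,
            "variant": variant,
            "TP": tp,
            "EST": float(est.mean()),
            "n_replicates": len(est),
        }
        if tp is not None and tp != 0:
            row["pct_bias"] = 100.0 * (est.mean() - tp) / abs(tp)
            row["pct_mse"] = 100.0 * float(np.mean((est - tp) ** 2)) / abs(tp)
        else:
            row["pct_bias"] = np.nan
            row["pct_mse"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    order = {n: i for i, n in enumerate(dict.fromkeys(result.estimates["parameter"]))}
    return out.sort_values(
        ["variant", "parameter"], key=lambda s: s.map(order).fillna(0)
    ).reset_index(drop=True)


def tabulate(result: SimStudyResult) -> pd.DataFrame:
    """Report table: one row per parameter, per-variant EST/Bias/MSE columns
    rounded to 2 decimals."""
    agg = aggregate(result)
    wide = agg.pivot(index="parameter", columns="variant",
                     values=["EST", "pct_bias", "pct_mse"])
    tp = agg.drop_duplicates("parameter").set_index("parameter")["TP"]
    wide.insert(0, ("TP", ""), tp)
    order = list(dict.fromkeys(result.estimates["parameter"]))
    return wide.loc[[p for p in order if p in wide.index]].round(2)
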