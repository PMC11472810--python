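"""End-to-end orchestration: simulate -> code -> describe -> fit -> report.

`run_pipeline` produces a report bundle holding every computed statistic
once (single source of truth); rendered tables are views of the same
values.  Outputs, when an output directory is configured: the cohort CSV
(if simulated), the coded-phenotype CSV, a descriptive panel TSV, a cause
tally TSV (when cause labels are present), a model-fit ladder TSV, variance
components JSON, stacked-proportion figure data (TSV + PNG) and a
machine-readable JSON of all results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import liability
from .descriptives import odds_ratio, prevalence, sex_difference_chi2
from .liability import GroupTable, fit_model_ladder, tetrachoric_ml
from .phenotype import code_cohort, pair_analysis_set, tabulate_causes
from .simulate import SimulationConfig, read_cohort_csv, simulate_cohort, write_cohort_csv

__all__ = [
    "PipelineConfig",
    "ConvergenceError",
    "run_pipeline",
    "build_group_tables",
    "pooled_zygosity_tables",
    "bootstrap_components_ci",
]

log = logging.getLogger("twinace")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class ConvergenceError(RuntimeError):
    """A model fit failed to converge."""


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    Exactly one of ``input_path`` (cohort CSV) or ``simulation`` must be
    given.  ``seed`` overrides the simulation seed when simulating.
    """

    input_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    model: int = 1
    ci_method: str = "profile"      # profile | bootstrap (twin-model CIs)
    prevalence_ci: str = "wald"     # wald | wilson
    threshold_pattern: str = "by_sex"
    pool_dz: bool = True            # pool same-sex DZ with DZOS for correlations
    n_boot: int = 200
    seed: int | None = None
    out_dir: str | Path | None = None
    make_plot: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("exactly one of input_path or simulation must be set")
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.ci_method not in ("profile", "bootstrap"):
            raise ValueError("ci_method must be 'profile' or 'bootstrap'")


def build_group_tables(pairs: pd.DataFrame) -> dict[str, GroupTable]:
    """Per zygosity-by-sex concordance tables from coded analysis pairs.

    Same-sex tables are double-entered (symmetrized); DZOS stays ordered
    male-first.
    """
    tables = {}
    for label, sub in pairs.groupby("zygosity_group", sort=False):
        tables[label] = GroupTable.from_pairs(label, sub["aff1"], sub["aff2"])
    order = [g for g in ("MZM", "MZF", "DZM", "DZF", "DZOS") if g in tables]
    return {g: tables[g] for g in order}


def pooled_zygosity_tables(pairs: pd.DataFrame, pool_dz: bool = True) -> dict[str, GroupTable]:
    """MZ and DZ concordance tables pooled across sexes (for correlations).

    ``pool_dz`` pools opposite-sex DZ pairs with same-sex DZ (the default);
    otherwise DZ same-sex and DZOS are reported separately.  Pooled tables
    ignore within-pair order, so all are symmetrized.
    """
    def key(label: str) -> str:
        if label.startswith("MZ"):
            return "MZ"
        if label == "DZOS" and not pool_dz:
            return "DZOS"
        return "DZ" if pool_dz else "DZSS"

    out: dict[str, GroupTable] = {}
    for label, sub in pairs.groupby("zygosity_group", sort=False):
        k = key(label)
        t = GroupTable.from_pairs(k, sub["aff1"], sub["aff2"], symmetrize=True)
        if k in out:
            prev = out[k]
            out[k] = GroupTable(k, prev.n00 + t.n00, prev.n01 + t.n01,
                                prev.n10 + t.n10, prev.n11 + t.n11, symmetrized=True)
        else:
            out[k] = t
    order = [g for g in ("MZ", "DZ", "DZSS", "DZOS") if g in out]
    return {g: out[g] for g in order}


def bootstrap_components_ci(
    tables: dict[str, GroupTable],
    n_boot: int = 200,
    seed: int = 0,
    threshold_pattern: str = "by_sex",
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CIs for ACE components.

    Resamples each group's concordance table from its fitted multinomial
    (parametric bootstrap at the observed proportions, which is equivalent
    to resampling pairs with replacement) and refits the ACE model.
    """
    rng = np.random.default_rng(seed)
    draws = {k: [] for k in ("a2", "c2", "e2")}
    for _ in range(n_boot):
        boot = {}
        for label, t in tables.items():
            n = int(round(t.total))
            counts = rng.multinomial(n, t.proportions)
            bt = GroupTable(label, *counts.astype(float))
            boot[label] = bt.symmetrize() if t.symmetrized else bt
        comp, fit = liability.fit_variance_model(boot, model="ACE",
                                                threshold_pattern=threshold_pattern)
        if not fit.converged:
            continue
        for k in draws:
            draws[k].append(getattr(comp, k))
    alpha = 1 - level
    out = {}
    for k, vals in draws.items():
        v = np.asarray(vals)
        out[k] = (float(np.quantile(v, alpha / 2)), float(np.quantile(v, 1 - alpha / 2)))
    return out


def _descriptive_panel(analysis, raw_coded: pd.DataFrame, prevalence_ci: str) -> dict:
    ind = analysis.individuals
    panel: dict = {"groups": {}}
    def cell(sub):
        n = len(sub)
        aff = int(sub["affected"].sum())
        res = prevalence(aff, n, method=prevalence_ci) if n else None
        return {"n": n, "affected": aff,
                "prevalence_pct": res.percent if res else None,
                "ci_pct": [100 * res.ci_low, 100 * res.ci_high] if res else None}
    panel["total"] = cell(ind)
    for sex in ("male", "female"):
        panel[sex] = cell(ind[ind["sex"] == sex])
    for (grp, sex), sub in ind.groupby(["zygosity_group", "sex"], sort=False):
        panel["groups"][f"{grp}:{sex}"] = cell(sub)
    return panel


def _panel_to_frame(panel: dict) -> pd.DataFrame:
    cols = {"total": panel["total"], "male": panel["male"], "female": panel["female"],
            **panel["groups"]}
    rows = {}
    for name, c in cols.items():
        rows[name] = {
            "n_twins": c["n"],
            "affected": c["affected"],
            "prevalence_pct": None if c["prevalence_pct"] is None else round(c["prevalence_pct"], 4),
        }
    return pd.DataFrame(rows)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and return the report bundle.

    Stages: load or simulate the cohort; code the phenotype under the
    configured exclusion model; descriptive panel with prevalence, sex
    difference (chi-square, odds ratio) and cause tally; tetrachoric twin
    correlations; the saturated/ACE/AE/CE/E model ladder with
    likelihood-ratio tests and component CIs; figure data.  Everything is
    deterministic given the configuration.
    """
    t0 = time.time()
    bundle: dict = {"config": {
        "model": config.model, "ci_method": config.ci_method,
        "prevalence_ci": config.prevalence_ci,
        "threshold_pattern": config.threshold_pattern, "pool_dz": config.pool_dz,
        "seed": config.seed,
    }}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: input -----------------------------------------------------
    try:
        if config.simulation is not None:
            sim = config.simulation
            if config.seed is not None:
                sim = dataclasses.replace(sim, seed=config.seed)
            cohort = simulate_cohort(sim)
            bundle["config"]["simulation"] = _jsonable(sim)
            if out_dir:
                write_cohort_csv(cohort, out_dir / "cohort.csv")
        else:
            cohort = read_cohort_csv(config.input_path)
    except Exception as err:
        raise type(err)(f"[input stage] {err}") from err
    log.info("input stage done: %d pairs (%.2fs)", len(cohort), time.time() - t0)

    # --- stage: phenotype coding -----------------------------------------
    t1 = time.time()
    try:
        coded = code_cohort(cohort, model=config.model)
        analysis = pair_analysis_set(cohort, model=config.model)
    except Exception as err:
        raise type(err)(f"[coding stage] {err}") from err
    bundle["flow"] = analysis.flow
    for step, count in analysis.flow.items():
        log.info("coding flow: %s = %s", step, count)
    if out_dir:
        coded.to_csv(out_dir / "coded.csv", index=False)
        (out_dir / "exclusions.json").write_text(
            json.dumps(_jsonable(analysis.flow), indent=2, sort_keys=True) + "\n")
    log.info("coding stage done (%.2fs)", time.time() - t1)

    # --- stage: descriptives ---------------------------------------------
    t2 = time.time()
    try:
        panel = _descriptive_panel(analysis, coded, config.prevalence_ci)
        bundle["descriptives"] = panel
        ind = analysis.individuals
        males = ind[ind["sex"] == "male"]
        females = ind[ind["sex"] == "female"]
        if len(males) and len(females):
            table = [
                [int(males["affected"].sum()), int((~males["affected"]).sum())],
                [int(females["affected"].sum()), int((~females["affected"]).sum())],
            ]
            chi = sex_difference_chi2(table)
            orr = odds_ratio(table)
            bundle["sex_difference"] = {
                "table": table, "chi2": chi.chi2, "df": chi.df, "p": chi.p,
                "odds_ratio": orr.odds_ratio,
                "or_ci": [orr.or_ci_low, orr.or_ci_high],
            }
        has_causes = bool((cohort["cause1"].astype(str) != "").any()
                          or (cohort["cause2"].astype(str) != "").any())
        if has_causes:
            tally = tabulate_causes(cohort)
            bundle["causes"] = {
                "n_indicated": tally.n_indicated, "n_responded": tally.n_responded,
                "responded_share_pct": tally.responded_share,
                "table": _jsonable(tally.to_frame()),
            }
            if out_dir:
                tally.to_frame().to_csv(out_dir / "table2_causes.tsv", sep="\t")
    except Exception as err:
        raise type(err)(f"[descriptives stage] {err}") from err
    if out_dir:
        _panel_to_frame(panel).to_csv(out_dir / "table1_descriptives.tsv", sep="\t")
    log.info("descriptives stage done (%.2fs)", time.time() - t2)

    # --- stage: twin correlations and model ladder ------------------------
    t3 = time.time()
    try:
        tables = build_group_tables(analysis.pairs)
        pooled = pooled_zygosity_tables(analysis.pairs, pool_dz=config.pool_dz)
        correlations = {}
        for label, t in pooled.items():
            res = tetrachoric_ml(t)
            correlations[label] = {"r": res.r, "ci": [res.ci_low, res.ci_high],
                                   "n_pairs": t.total, "boundary": res.boundary}
        bundle["twin_correlations"] = correlations

        ladder = fit_model_ladder(tables, threshold_pattern=config.threshold_pattern,
                                  ci=(config.ci_method == "profile"))
        ace = ladder["components"]["ACE"]
        ace_fit = ladder["fits"]["ACE"]
        if not ace_fit.converged:
            raise ConvergenceError(f"ACE fit did not converge: {ace_fit.diagnostics}")
        if config.ci_method == "bootstrap":
            ace.ci = bootstrap_components_ci(
                tables, n_boot=config.n_boot,
                seed=0 if config.seed is None else config.seed,
                threshold_pattern=config.threshold_pattern)
        bundle["variance_components"] = {m: c.as_dict() for m, c in ladder["components"].items()}
        bundle["model_ladder"] = [
            {"model": "saturated", "reference": None,
             "minus2ll": ladder["fits"]["saturated"].minus2ll,
             "n_parameters": ladder["fits"]["saturated"].n_parameters,
             "df": ladder["fits"]["saturated"].df,
             "delta_chi2": None, "delta_df": None, "p": None},
            *ladder["comparisons"],
        ]
        bundle["group_tables"] = {
            label: {"n00": t.n00, "n01": t.n01, "n10": t.n10, "n11": t.n11}
            for label, t in tables.items()
        }
    except ConvergenceError:
        raise
    except Exception as err:
        raise type(err)(f"[twin-model stage] {err}") from err
    log.info("twin-model stage done (%.2fs)", time.time() - t3)

    # --- stage: outputs ----------------------------------------------------
    fig_rows = [{"model": "ACE", "component": comp,
                 "proportion": bundle["variance_components"]["ACE"][comp],
                 "ci_low": (bundle["variance_components"]["ACE"].get("ci") or {}).get(comp, [None, None])[0],
                 "ci_high": (bundle["variance_components"]["ACE"].get("ci") or {}).get(comp, [None, None])[1]}
                for comp in ("a2", "c2", "e2")]
    bundle["figure_data"] = fig_rows
    if out_dir:
        pd.DataFrame(bundle["model_ladder"]).to_csv(out_dir / "table3_ladder.tsv",
                                                    sep="\t", index=False)
        (out_dir / "variance_components.json").write_text(
            json.dumps(_jsonable(bundle["variance_components"]), indent=2, sort_keys=True) + "\n")
        pd.DataFrame(fig_rows).to_csv(out_dir / "fig_variance.tsv", sep="\t", index=False)
        (out_dir / "results.json").write_text(
            json.dumps(_jsonable(bundle), indent=2, sort_keys=True) + "\n")
        if config.make_plot:
            from .plots import render_variance_figure
            comp = ladder["components"]["ACE"]
            render_variance_figure({f"Model {config.model}": comp},
                                   out_dir / "fig_variance.png")
    log.info("pipeline complete (%.2fs total)", time.time() - t0)
    return bundle
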