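"""Study orchestration: per-cohort model fits, pooled results and reports.

``run_study`` executes the full design on one or more cohorts (read from TSV
or simulated in-process from a config block): for every outcome it fits the
four model families —

* OLS/LOG of the outcome on standardized years of education,
* the same with family fixed effects (sibling-difference logit for binary),
* one-sample MR (2SLS / two-stage logit) instrumented by the polygenic score,
* one-sample MR within sibships,

each adjusted for sex and age (plus ancestry PCs when the polygenic score is
in the model), with sibship-clustered standard errors, and then pools the
per-cohort estimates with the heterogeneity-gated meta-analysis rule.
Binary-outcome coefficients are kept on the log-odds scale internally and
exponentiated only in the human-readable report.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import meta as meta_mod
from . import mr1s, pgs, regress, simcohort
from .phenotypes import standardize

__all__ = ["StudyConfig", "load_config", "run_study", "report",
           "read_results", "run"]

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["outcome", "model", "cohort", "B", "LCI", "UCI", "SE", "p",
                  "scale", "n_obs", "n_clusters", "meta_model"]

MODELS_CONTINUOUS = ["OLS EA", "OLS EA + FE", "1SMR", "1SMR + FE"]
MODELS_BINARY = ["LOG EA", "LOG EA + FE", "1SMR", "1SMR + FE"]


@dataclass
class StudyConfig:
    """Declarative description of a full study run."""

    cohorts: list[dict[str, Any]]
    outcomes: list[dict[str, str]] = field(default_factory=lambda: [
        {"name": "outcome", "column": "outcome", "type": "continuous"},
        {"name": "outcome_bin", "column": "outcome_bin", "type": "binary"},
    ])
    exposure: str = "edu_years"
    covariates: list[str] = field(default_factory=lambda: ["sex", "age"])
    n_pcs: int = 10
    q_alpha: float = 0.05
    i2_threshold: float = 50.0
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("at least one cohort is required")


def load_config(path: str | Path) -> StudyConfig:
    """Read a YAML or JSON study config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return StudyConfig(**data)


def _load_cohort(spec: dict[str, Any], seed: int, index: int
                 ) -> tuple[str, pd.DataFrame, pd.DataFrame | None]:
    """Returns (name, cohort table, PGS weight table or None)."""
    name = spec.get("name", f"cohort{index + 1}")
    if "simulate" in spec:
        block = dict(spec["simulate"])
        block.setdefault("seed", int(np.random.SeedSequence(
            [seed, index]).generate_state(1)[0] % (2**31)))
        params = simcohort.SimParams(**block)
        table = simcohort.simulate_cohort(params)
        weights = simcohort.true_weight_table(params)
    elif "path" in spec:
        table = simcohort.read_cohort(spec["path"])
        weights = (pd.read_csv(spec["weights"], sep="\t")
                   if "weights" in spec else None)
    else:
        raise ValueError(f"cohort {name!r} needs a 'simulate' block or a 'path'")
    return name, table, weights


def _restrict_to_sibships(table: pd.DataFrame) -> pd.DataFrame:
    sizes = table["family_id"].map(table["family_id"].value_counts())
    return table[sizes >= 2].reset_index(drop=True)


def _complete_case(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    sub = table.dropna(subset=[c for c in columns if c in table.columns])
    if len(sub) < len(table):
        log.info("complete-case: %d -> %d rows for %s",
                 len(table), len(sub), columns)
    return sub


def _row(outcome: str, model: str, cohort: str, est: float, se: float,
         p: float, scale: str, n_obs: int, n_clusters: int,
         meta_model: str = "") -> dict[str, Any]:
    return {
        "outcome": outcome, "model": model, "cohort": cohort,
        "B": est, "LCI": est - regress.Z975 * se, "UCI": est + regress.Z975 * se,
        "SE": se, "p": p, "scale": scale,
        "n_obs": n_obs, "n_clusters": n_clusters, "meta_model": meta_model,
    }


def _fit_cohort(name: str, table: pd.DataFrame,
                weights: pd.DataFrame | None,
                config: StudyConfig) -> list[dict[str, Any]]:
    table = _restrict_to_sibships(table)
    fam = table["family_id"]
    geno_cols = [c for c in table.columns if c.startswith("g_")]

    score = None
    pc_cols: list[str] = []
    if weights is not None and geno_cols:
        info = simcohort.variant_info(len(geno_cols))
        score = pgs.compute_pgs(table, weights, info)
        if config.n_pcs > 0:
            k = min(config.n_pcs, len(geno_cols) - 1, len(table) - 1)
            comps, _ = pgs.genotype_pca(table[geno_cols].to_numpy(), k)
            for j in range(k):
                table = table.assign(**{f"PC{j + 1}": comps[:, j]})
                pc_cols.append(f"PC{j + 1}")

    edu = standardize(table[config.exposure].astype(float))
    base_cov = [c for c in config.covariates if c in table.columns]
    rows: list[dict[str, Any]] = []

    for out in config.outcomes:
        col, kind = out["column"], out["type"]
        model_cols = [col, config.exposure, "family_id", *base_cov]
        sub = _complete_case(table, model_cols)
        idx = sub.index
        y = (standardize(sub[col].astype(float)) if kind == "continuous"
             else sub[col].astype(float).to_numpy())
        x = edu.loc[idx].to_numpy()
        W = sub[base_cov].astype(float)
        f = sub["family_id"]
        scale = "identity" if kind == "continuous" else "log"

        X = W.assign(edu=x)[["edu", *base_cov]]
        if kind == "continuous":
            res = regress.ols_cluster(np.asarray(y), X, f)
            rows.append(_row(out["name"], "OLS EA", name, res.coef("edu"),
                             float(res.se["edu"]), float(res.pvalues["edu"]),
                             scale, res.n_obs, res.n_clusters))
            res = regress.ols_fe_cluster(np.asarray(y), X, f)
            rows.append(_row(out["name"], "OLS EA + FE", name, res.coef("edu"),
                             float(res.se["edu"]), float(res.pvalues["edu"]),
                             scale, res.n_obs, res.n_clusters))
        else:
            res = regress.logistic_cluster(y, X, f)
            rows.append(_row(out["name"], "LOG EA", name, res.coef("edu"),
                             float(res.se["edu"]), float(res.pvalues["edu"]),
                             scale, res.n_obs, res.n_clusters))
            res = regress.sibling_difference_logit(y, X, f)
            rows.append(_row(out["name"], "LOG EA + FE", name, res.coef("edu"),
                             float(res.se["edu"]), float(res.pvalues["edu"]),
                             scale, res.n_obs, res.n_clusters))

        if score is None:
            continue
        z = score.loc[idx].to_numpy()
        W_mr = sub[base_cov + pc_cols].astype(float)
        if kind == "continuous":
            for tag, fe in (("1SMR", False), ("1SMR + FE", True)):
                mr = mr1s.tsls(np.asarray(y), x, z, W_mr, f, family_fe=fe)
                rows.append(_row(out["name"], tag, name, mr.estimate, mr.se,
                                 mr.pvalue, scale, mr.n_obs, mr.n_families))
        else:
            for tag, fe in (("1SMR", False), ("1SMR + FE", True)):
                mr = mr1s.tsps_logit(y, x, z, W_mr, f, family_fe=fe)
                rows.append(_row(out["name"], tag, name, mr.estimate, mr.se,
                                 mr.pvalue, scale, mr.n_obs, mr.n_families))
    return rows


def _pool(per_cohort: pd.DataFrame, config: StudyConfig) -> list[dict[str, Any]]:
    rows = []
    for (outcome, model), grp in per_cohort.groupby(["outcome", "model"],
                                                    sort=False):
        scale = grp["scale"].iloc[0]
        if len(grp) == 1:
            r = grp.iloc[0]
            rows.append(_row(outcome, model, "meta", r["B"], r["SE"], r["p"],
                             scale, int(r["n_obs"]), int(r["n_clusters"]),
                             meta_model="single-cohort"))
            continue
        pooled = meta_mod.select_and_pool(grp["B"].to_numpy(),
                                          grp["SE"].to_numpy(),
                                          q_alpha=config.q_alpha,
                                          i2_threshold=config.i2_threshold)
        rows.append(_row(outcome, model, "meta", pooled.pooled, pooled.se,
                         pooled.pvalue, scale, int(grp["n_obs"].sum()),
                         int(grp["n_clusters"].sum()),
                         meta_model=pooled.model))
    return rows


def _describe(name: str, table: pd.DataFrame,
              config: StudyConfig) -> list[dict[str, Any]]:
    table = _restrict_to_sibships(table)
    rows = [{"cohort": name, "variable": "n", "statistic": "count",
             "value": float(len(table))},
            {"cohort": name, "variable": "n_sibships", "statistic": "count",
             "value": float(table["family_id"].nunique())}]
    if "sex" in table.columns:
        rows.append({"cohort": name, "variable": "female", "statistic": "pct",
                     "value": float(100 * table["sex"].mean())})
    numeric = [config.exposure, "age"] + [
        o["column"] for o in config.outcomes if o["type"] == "continuous"]
    for var in numeric:
        if var not in table.columns:
            continue
        v = table[var].astype(float).dropna()
        q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
        rows += [
            {"cohort": name, "variable": var, "statistic": "median", "value": med},
            {"cohort": name, "variable": var, "statistic": "q1", "value": q1},
            {"cohort": name, "variable": var, "statistic": "q3", "value": q3},
            {"cohort": name, "variable": var, "statistic": "mean",
             "value": float(v.mean())},
            {"cohort": name, "variable": var, "statistic": "sd",
             "value": float(v.std())},
        ]
    for out in config.outcomes:
        if out["type"] == "binary" and out["column"] in table.columns:
            v = table[out["column"]].astype(float).dropna()
            rows += [
                {"cohort": name, "variable": out["column"], "statistic": "n_cases",
                 "value": float(v.sum())},
                {"cohort": name, "variable": out["column"], "statistic": "pct",
                 "value": float(100 * v.mean())},
            ]
    return rows


def run_study(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every model family on every cohort and pool across cohorts.

    Returns ``(results, descriptives)``: the results table has one row per
    outcome × model × cohort plus a pooled "meta" row recording which
    pooling model the heterogeneity rule selected.
    """
    all_rows: list[dict[str, Any]] = []
    desc_rows: list[dict[str, Any]] = []
    for i, spec in enumerate(config.cohorts):
        stage = f"cohort[{i}]"
        try:
            name, table, weights = _load_cohort(spec, config.seed, i)
            stage = f"fit[{name}]"
            all_rows += _fit_cohort(name, table, weights, config)
            desc_rows += _describe(name, table, config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    per_cohort = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)
    try:
        pooled = _pool(per_cohort, config)
    except Exception as exc:
        raise RuntimeError(f"stage meta failed: {exc}") from exc
    results = pd.concat([per_cohort, pd.DataFrame(pooled,
                                                  columns=RESULT_COLUMNS)],
                        ignore_index=True)
    return results, pd.DataFrame(desc_rows)


def report(results: pd.DataFrame, outdir: str | Path,
           formats: tuple[str, ...] = ("tsv", "txt"),
           descriptives: pd.DataFrame | None = None) -> list[Path]:
    """Write the results table (TSV, internal log scale) and a plain-text
    report with exponentiated odds ratios and a forest-style block per
    outcome."""
    if results.empty:
        raise ValueError("results table is empty")
    unknown = set(formats) - {"tsv", "txt"}
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "tsv" in formats:
        path = outdir / "results.tsv"
        results.to_csv(path, sep="\t", index=False, na_rep="NA",
                       float_format="%.10g")
        written.append(path)
        if descriptives is not None:
            dpath = outdir / "descriptives.tsv"
            descriptives.to_csv(dpath, sep="\t", index=False, na_rep="NA",
                                float_format="%.10g")
            written.append(dpath)
    if "txt" in formats:
        path = outdir / "report.txt"
        path.write_text(_format_report(results))
        written.append(path)
    return written


def _format_report(results: pd.DataFrame) -> str:
    lines = ["Association between educational attainment and outcomes",
             "(binary-outcome rows shown as odds ratios)", ""]
    for outcome, grp in results.groupby("outcome", sort=False):
        lines.append(f"== {outcome} ==")
        for _, r in grp.iterrows():
            b, lo, hi = r["B"], r["LCI"], r["UCI"]
            if r["scale"] == "log":
                b, lo, hi = np.exp([b, lo, hi])
            tag = f" [{r['meta_model']}]" if r["meta_model"] else ""
            lines.append(
                f"  {r['model']:<14} {r['cohort']:<10} "
                f"{b:+.3f} ({lo:+.3f}, {hi:+.3f})  p={r['p']:.3g}{tag}"
            )
        lines.append("")
    return "\n".join(lines)


def read_results(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the TSV written by :func:`report`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"],
                       keep_default_na=False)


def run(config: StudyConfig) -> pd.DataFrame:
    """All-in-one: :func:`run_study` then :func:`report` into
    ``config.outdir``; partial outputs are removed on failure."""
    outdir = Path(config.outdir or "sibmr_out")
    created = not outdir.exists()
    try:
        results, desc = run_study(config)
        report(results, outdir, descriptives=desc)
        (outdir / "config.json").write_text(
            json.dumps(config.__dict__, default=str, indent=2))
    except Exception:
        if created and outdir.exists():
            shutil.rmtree(outdir)
        raise
    return results
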