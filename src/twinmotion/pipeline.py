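"""End-to-end orchestration: motion summaries -> exclusions -> covariate
screen -> univariate heritability -> bivariate correlation grid.

A single YAML/flat-key configuration names the inputs (phenotype table
and, optionally, a directory of realignment parameter files), the
motion thresholds, the traits to analyse and the seeds.  Outputs are a
machine-readable JSON results file (lossless round-trip of every
estimate, CI, p-value and convergence flag), a human-readable markdown
summary and a structured log recording the inputs, seeds, package
version and the analysis conventions in force (natural log, mean
framewise displacement, profile-likelihood CIs).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import TwinDataset
from .inference import (
    covariate_screen,
    cross_trait_analysis,
    heritability_analysis,
    pair_correlation,
)
from .motion import read_realignment_series, summarize_cohort

__all__ = ["run_pipeline", "write_report", "load_config", "DEFAULT_CONFIG"]

logger = logging.getLogger("twinmotion")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "twinmotion_results",
    "phenotypes": None,
    "motion_dir": None,
    "motion": {"dialect": "spm", "radius": 80.0, "trans_thresh": 3.0, "rot_thresh": 2.0},
    "traits": ["hm_log"],
    "covariates": ["sex", "age"],
    "bivariate": {"base_trait": "hm_log", "traits": []},
    "alpha": 0.05,
    "ci_level": 0.95,
    "compute_ci": True,
}


class ConfigError(ValueError):
    """Raised for malformed or incomplete pipeline configurations."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a mapping")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in user.items():
        if k not in cfg:
            raise ConfigError(f"unknown config key {k!r}")
        if isinstance(cfg[k], dict) and isinstance(v, dict):
            bad = set(v) - set(cfg[k])
            if bad:
                raise ConfigError(f"unknown config key {k}.{sorted(bad)[0]}")
            cfg[k].update(v)
        else:
            cfg[k] = v
    if not cfg["phenotypes"]:
        raise ConfigError("config must name a 'phenotypes' table")
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _ci_dict(ci):
    if ci is None:
        return None
    return {
        "estimate": ci.estimate,
        "lower": ci.lower,
        "upper": ci.upper,
        "level": ci.level,
        "lower_at_boundary": ci.lower_at_boundary,
        "upper_at_boundary": ci.upper_at_boundary,
    }


def _attach_motion(table: pd.DataFrame, motion_dir: Path, motion_cfg: dict):
    """Summarise rp files, flag exclusions, merge log displacement."""
    files = sorted(motion_dir.glob("*.par" if motion_cfg["dialect"] == "fsl" else "*.txt"))
    if not files:
        raise ConfigError(f"no realignment files found in {motion_dir}")
    series = [read_realignment_series(f, dialect=motion_cfg["dialect"]) for f in files]
    summary = summarize_cohort(
        series,
        radius=motion_cfg["radius"],
        trans_thresh=motion_cfg["trans_thresh"],
        rot_thresh=motion_cfg["rot_thresh"],
    )
    excluded = summary.loc[summary["gross_motion"], "subject_id"].tolist()
    keep = summary[~summary["gross_motion"]][["subject_id", "log_displacement"]]
    table = table.drop(columns=["hm_log"], errors="ignore").merge(
        keep.rename(columns={"subject_id": "individual_id", "log_displacement": "hm_log"}),
        on="individual_id",
        how="left",
    )
    return table, summary, excluded


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis described by ``config``; returns the
    results dictionary (also written to disk by :func:`write_report`)."""
    if isinstance(config, dict):
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
        for k, v in config.items():
            if isinstance(cfg.get(k), dict) and isinstance(v, dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    else:
        cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.setLevel(logging.INFO)
    logger.addHandler(handler)
    try:
        return _run(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: dict, out: Path) -> dict:
    logger.info("twinmotion %s; seed=%s", __version__, cfg["seed"])
    logger.info(
        "conventions: natural log of mean consecutive-frame displacement; "
        "radius %.0f mm; exclusion > %.1f mm / > %.1f deg (strict); "
        "profile-likelihood CIs at %.0f%%; LRT alpha %.2f",
        cfg["motion"]["radius"],
        cfg["motion"]["trans_thresh"],
        cfg["motion"]["rot_thresh"],
        100 * cfg["ci_level"],
        cfg["alpha"],
    )
    table = pd.read_csv(cfg["phenotypes"])
    n_input = len(table)
    results: dict = {
        "config": cfg,
        "version": __version__,
        "n_input_individuals": n_input,
    }

    motion_summary = None
    excluded: list = []
    if cfg["motion_dir"]:
        table, motion_summary, excluded = _attach_motion(
            table, Path(cfg["motion_dir"]), cfg["motion"]
        )
        table = table[~table["individual_id"].isin(excluded)]
        logger.info("gross-motion exclusions: %d subjects %s", len(excluded), excluded)
    results["n_gross_motion_excluded"] = len(excluded)
    results["excluded_subjects"] = excluded
    results["n_analyzed"] = len(table)
    assert results["n_analyzed"] + results["n_gross_motion_excluded"] == n_input

    ds = TwinDataset(table)
    covs = tuple(cfg["covariates"])
    alpha = cfg["alpha"]

    screens = {}
    univariate = {}
    for trait in cfg["traits"]:
        if ds.table[trait].notna().sum() < 10:
            logger.warning("trait %s has too few observations; skipped", trait)
            continue
        desc = {
            "all": {
                "mean": float(ds.table[trait].mean()),
                "sd": float(ds.table[trait].std()),
                "n": int(ds.table[trait].notna().sum()),
            }
        }
        for sex, sub in ds.table.groupby("sex"):
            desc[f"sex_{sex}"] = {
                "mean": float(sub[trait].mean()),
                "sd": float(sub[trait].std()),
                "n": int(sub[trait].notna().sum()),
            }
        scr = covariate_screen(ds, trait, covs)
        screens[trait] = scr.to_dict(orient="records")
        kept = tuple(scr.loc[scr["p"] < alpha, "covariate"]) or ("sex",)
        logger.info("trait %s: retained covariates %s", trait, kept)
        ha = heritability_analysis(
            ds, trait, covariates=kept, compute_ci=cfg["compute_ci"], seed=cfg["seed"]
        )
        fit = ha.chosen_fit
        std = fit.standardized
        univariate[trait] = {
            "descriptives": desc,
            "chosen_model": ha.chosen,
            "covariates": list(kept),
            "tests": ha.tests.to_dict(orient="records"),
            "minus2lnl": fit.minus2lnl,
            "converged": fit.converged,
            "shares": {k: list(v) for k, v in std["components"].items()},
            "h2_ci": _ci_dict(ha.cis.get("h2")),
            "pair_correlations": {
                cls: pair_correlation(ds, trait, cls, "ml")
                for cls in ("MZ", "DZ")
                if len(ds.complete_pairs(trait, MZ_DZ[cls])) >= 3
            },
        }

    bivariate = {}
    base = cfg["bivariate"]["base_trait"]
    for trait in cfg["bivariate"]["traits"]:
        if trait == base:
            raise ConfigError("bivariate trait equals the base trait")
        ct = cross_trait_analysis(
            ds,
            (base, trait),
            covariates=covs,
            compute_ci=cfg["compute_ci"],
            compute_pvalues=True,
            seed=cfg["seed"],
        )
        bivariate[trait] = {
            "rp": ct.rp,
            "rg": ct.rg,
            "re": ct.re,
            "h2": list(ct.h2),
            "rp_ci": _ci_dict(ct.rp_ci),
            "rg_ci": _ci_dict(ct.rg_ci),
            "re_ci": _ci_dict(ct.re_ci),
            "rp_p": ct.rp_p,
            "rg_p": ct.rg_p,
            "re_p": ct.re_p,
            "converged": ct.fit.converged,
        }

    results["covariate_screen"] = screens
    results["univariate"] = univariate
    results["bivariate"] = {"base_trait": base, "traits": bivariate}
    if motion_summary is not None:
        motion_summary.to_csv(out / "motion_summary.csv", index=False)
    write_report(results, out)
    logger.info("results written to %s", out)
    return results


MZ_DZ = {"MZ": ("MZF", "MZM"), "DZ": ("DZF", "DZM", "DZOS", "SIB")}


def write_report(results: dict, out_dir: str | Path) -> dict:
    """Write results as JSON (lossless), delimited tables and a markdown
    summary; returns the JSON-safe dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    safe = _jsonable(results)
    with open(out / "results.json", "w") as fh:
        json.dump(safe, fh, indent=1, sort_keys=True)

    uni_rows = []
    for trait, res in results.get("univariate", {}).items():
        row = {"trait": trait, "model": res["chosen_model"], "converged": res["converged"]}
        for comp, vals in res["shares"].items():
            row[comp] = vals[0]
        if res.get("h2_ci"):
            row["h2_lower"], row["h2_upper"] = res["h2_ci"]["lower"], res["h2_ci"]["upper"]
        uni_rows.append(row)
    if uni_rows:
        pd.DataFrame(uni_rows).to_csv(out / "univariate.csv", index=False)

    biv = results.get("bivariate", {}).get("traits", {})
    biv_rows = []
    for trait, res in biv.items():
        biv_rows.append(
            {
                "trait": trait,
                "rp": res["rp"],
                "rg": res["rg"],
                "re": res["re"],
                "rp_p": res.get("rp_p"),
                "rg_p": res.get("rg_p"),
                "re_p": res.get("re_p"),
            }
        )
    if biv_rows:
        pd.DataFrame(biv_rows).to_csv(out / "bivariate.csv", index=False)

    lines = ["# twinmotion analysis summary", ""]
    lines.append(
        f"Input individuals: {results.get('n_input_individuals', 'NA')}; "
        f"analyzed: {results.get('n_analyzed', 'NA')}; "
        f"gross-motion excluded: {results.get('n_gross_motion_excluded', 0)}"
    )
    if uni_rows:
        lines += ["", "## Univariate decompositions", ""]
        for row in uni_rows:
            shares = ", ".join(
                f"{k}={row[k]:.3f}" for k in ("h2", "c2", "d2", "e2") if k in row and row[k] is not None
            )
            lines.append(f"- {row['trait']}: {row['model']} ({shares})")
    if biv_rows:
        base = results["bivariate"]["base_trait"]
        lines += ["", f"## Correlations with {base}", ""]
        lines.append("| trait | rp | rg | re |")
        lines.append("|---|---|---|---|")
        for row in biv_rows:
            lines.append(
                f"| {row['trait']} | {row['rp']:.3f} | {row['rg']:.3f} | {row['re']:.3f} |"
            )
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    return safe
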