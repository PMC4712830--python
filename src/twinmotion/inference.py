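"""The analysis battery: homogeneity tests, heritability, sex limitation,
and genetic/environmental correlations between head motion and ADHD scores.

Every hypothesis test is a likelihood-ratio test between a model and a
constrained version, with the chi-square reference distribution on the
parameter-count difference.  No boundary (chi-bar-square) correction is
applied by default and no multiple-testing adjustment is made across
the battery; raw p-values are reported.  Model selection among
candidate variance decompositions drops a component when removing it
does not significantly worsen fit at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .data import DZ_GROUPS, MZ_GROUPS, TwinDataset, compile_dataset
from .fitting import ProfileCI, fit_model, lrt, profile_ci
from .model import FitResult, ModelSpec, build_pair_covariance
from .saturated import SaturatedTwinModel

__all__ = [
    "homogeneity_battery",
    "covariate_screen",
    "pair_correlation",
    "heritability_analysis",
    "sex_limitation_analysis",
    "cross_trait_analysis",
    "CrossTraitResult",
]

ALPHA = 0.05


def _as_dataset(dataset) -> TwinDataset:
    return dataset if isinstance(dataset, TwinDataset) else TwinDataset(dataset)


def _sat_lrt(X, trait, full_kw, null_kw, covariates=()):
    full = SaturatedTwinModel(trait, covariates=covariates, **full_kw).fit(X)
    null = SaturatedTwinModel(trait, covariates=covariates, **null_kw).fit(X)
    stat = max(null.minus2lnl_ - full.minus2lnl_, 0.0)
    df = full.n_params_ - null.n_params_
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p, full, null


def homogeneity_battery(
    dataset,
    trait: str,
    covariates: tuple = ("sex", "age"),
) -> pd.DataFrame:
    """Saturated-model homogeneity tests for one trait.

    Runs, as LRTs against the relevant saturated model: birth-order
    equality of means/variances; sex equality of means/variances;
    quantitative sex limitation (pair covariance equal within same-sex
    zygosity groups); qualitative sex limitation (opposite-sex DZ
    covariance equal to same-sex DZ); presence of genetic factors (MZ
    covariance equal to DZ); familial aggregation (pair covariance
    null); and one test per requested covariate (effect null).  Tests
    whose groups are absent are reported as skipped.
    """
    ds = _as_dataset(dataset)
    X = ds.table[ds.table[trait].notna() | ds.table["family_id"].isin(
        ds.table.loc[ds.table[trait].notna(), "family_id"]
    )]
    groups = set(ds.groups_present(trait))
    has_mz = groups & set(MZ_GROUPS)
    has_dzss = groups & {"DZF", "DZM", "SIB"}
    has_dzos = "DZOS" in groups
    both_sexes = {"F", "M"} <= set(ds.table["sex"])
    rows = []

    def add(test, condition, reason, runner):
        if not condition:
            rows.append({"test": test, "statistic": np.nan, "df": 0, "p": np.nan,
                         "skipped": reason})
            return
        stat, df, p = runner()
        rows.append({"test": test, "statistic": stat, "df": df, "p": p, "skipped": ""})

    add(
        "birth_order",
        True,
        "",
        lambda: _sat_lrt(
            X,
            trait,
            dict(mean_by="group_member", var_by="group_member", cov_by="by_sex_zygosity"),
            dict(mean_by="group", var_by="group", cov_by="by_sex_zygosity"),
        )[:3],
    )
    add(
        "sex_groups",
        both_sexes,
        "only one sex present",
        lambda: _sat_lrt(
            X,
            trait,
            dict(mean_by="sex", var_by="sex", cov_by="mz_dzss_dzos"),
            dict(mean_by="pooled", var_by="pooled", cov_by="mz_dzss_dzos"),
        )[:3],
    )
    add(
        "quantitative_sex_limitation",
        bool(has_mz and has_dzss and both_sexes),
        "needs male and female same-sex MZ and DZ pairs",
        lambda: _sat_lrt(
            X,
            trait,
            dict(mean_by="sex", var_by="sex", cov_by="by_sex_zygosity"),
            dict(mean_by="sex", var_by="sex", cov_by="mz_dzss_dzos"),
        )[:3],
    )
    add(
        "qualitative_sex_limitation",
        bool(has_dzos and has_dzss),
        "needs both same-sex and opposite-sex DZ pairs",
        lambda: _sat_lrt(
            X,
            trait,
            dict(mean_by="sex", var_by="sex", cov_by="mz_dzss_dzos"),
            dict(mean_by="sex", var_by="sex", cov_by="mz_dz"),
        )[:3],
    )
    add(
        "presence_of_genetic_factors",
        bool(has_mz and (has_dzss or has_dzos)),
        "needs MZ and DZ pairs",
        lambda: _sat_lrt(
            X,
            trait,
            dict(mean_by="sex", var_by="sex", cov_by="mz_dz"),
            dict(mean_by="sex", var_by="sex", cov_by="pooled"),
        )[:3],
    )
    add(
        "familial_aggregation",
        True,
        "",
        lambda: _sat_lrt(
            X,
            trait,
            dict(mean_by="sex", var_by="sex", cov_by="pooled"),
            dict(mean_by="sex", var_by="sex", cov_by="none"),
        )[:3],
    )
    screen = covariate_screen(ds, trait, covariates)
    for _, r in screen.iterrows():
        rows.append(
            {
                "test": f"covariate_{r['covariate']}",
                "statistic": r["statistic"],
                "df": r["df"],
                "p": r["p"],
                "skipped": "",
            }
        )
    return pd.DataFrame(rows)


def covariate_screen(
    dataset, trait: str, covariates: tuple = ("sex", "age")
) -> pd.DataFrame:
    """ML estimates and LRT p-values for covariate effects on one trait.

    The carrier model is a saturated model with pooled means/variances,
    MZ/DZ covariances, and all requested covariates in the means; each
    covariate's test removes only that covariate (df = 1).
    """
    ds = _as_dataset(dataset)
    kw = dict(mean_by="pooled", var_by="pooled", cov_by="mz_dz")
    full = SaturatedTwinModel(trait, covariates=tuple(covariates), **kw).fit(ds)
    rows = []
    for cov in covariates:
        reduced_covs = tuple(c for c in covariates if c != cov)
        null = SaturatedTwinModel(trait, covariates=reduced_covs, **kw).fit(ds)
        stat = max(null.minus2lnl_ - full.minus2lnl_, 0.0)
        rows.append(
            {
                "covariate": cov,
                "beta": full.betas_[cov],
                "statistic": stat,
                "df": 1,
                "p": float(chi2.sf(stat, 1)),
            }
        )
    return pd.DataFrame(rows)


def pair_correlation(
    dataset, trait: str, group: str = "MZ", method: str = "ml"
) -> float:
    """Twin-pair correlation for one trait within a zygosity class.

    ``group`` may be ``"MZ"``, ``"DZ"`` (DZ plus sibling pairs) or a
    specific group code.  ``method="ml"`` is the correlation implied by
    a saturated ML fit on that class (handles lone twins by FIML);
    ``"pearson"`` is the double-entered Pearson correlation over
    complete pairs.
    """
    ds = _as_dataset(dataset)
    if group == "MZ":
        groups = list(MZ_GROUPS)
    elif group == "DZ":
        groups = list(DZ_GROUPS)
    else:
        groups = [group]
    pairs = ds.complete_pairs(trait, groups)
    if len(pairs) < 3:
        raise ValueError(f"fewer than 3 complete {group} pairs for {trait!r}")
    if method == "pearson":
        de = np.vstack([pairs, pairs[:, ::-1]])
        return float(np.clip(np.corrcoef(de.T)[0, 1], -1.0, 1.0))
    if method != "ml":
        raise ValueError("method must be 'ml' or 'pearson'")
    sub = ds.table[ds.table["zygosity"].isin(groups)]
    sat = SaturatedTwinModel(trait, mean_by="pooled", var_by="pooled", cov_by="pooled").fit(sub)
    return float(np.clip(sat.correlations_["all"], -1.0, 1.0))


@dataclass
class ModelComparison:
    fits: dict
    tests: pd.DataFrame
    chosen: str
    chosen_fit: FitResult
    cis: dict = field(default_factory=dict)


def heritability_analysis(
    dataset,
    trait: str,
    candidates: tuple = ("ACE", "ADE", "AE", "E"),
    covariates: tuple = ("sex", "age"),
    compute_ci: bool = True,
    seed: int = 0,
    **fit_kw,
) -> ModelComparison:
    """Univariate variance-decomposition comparison for one trait.

    Fits the candidate decompositions, tests the standard LRT chain
    (ACE vs AE, ADE vs AE, AE vs E) and picks the accepted model at
    alpha = 0.05: a broad component (C or D) is kept only when dropping
    it significantly worsens fit; A is dropped only when AE vs E is
    non-significant.
    """
    compiled = compile_dataset(_as_dataset(dataset), (trait,), list(covariates) or None)
    fits = {}
    for comps in candidates:
        spec = ModelSpec(traits=(trait,), components=comps, covariates=tuple(covariates))
        fits[comps] = fit_model(compiled, spec, seed=seed, **fit_kw)
    tests = []
    for full_c, nested_c, label in (
        ("ACE", "AE", "drop_C"),
        ("ADE", "AE", "drop_D"),
        ("AE", "E", "drop_A"),
    ):
        if full_c in fits and nested_c in fits:
            stat, df, p = lrt(fits[full_c], fits[nested_c])
            tests.append({"test": label, "statistic": stat, "df": df, "p": p})
    tests = pd.DataFrame(tests)

    def p_of(label):
        row = tests[tests["test"] == label]
        return float(row["p"].iloc[0]) if len(row) else 1.0

    if "ADE" in fits and p_of("drop_D") < ALPHA:
        chosen = "ADE"
    elif "ACE" in fits and p_of("drop_C") < ALPHA:
        chosen = "ACE"
    elif "AE" in fits and p_of("drop_A") < ALPHA:
        chosen = "AE"
    elif "E" in fits:
        chosen = "E"
    else:
        chosen = "AE"
    cis = {}
    if compute_ci and chosen != "E":
        fit = fits[chosen]
        cis["h2"] = profile_ci(None, fit.spec, fit, "h2")
    return ModelComparison(fits=fits, tests=tests, chosen=chosen, chosen_fit=fits[chosen], cis=cis)


@dataclass
class SexLimitationResult:
    general: FitResult
    standard: FitResult
    statistic: float
    df: int
    p: float
    implied_covariances: dict
    standardized_by_sex: dict
    rg_mf: float


def sex_limitation_analysis(
    dataset,
    trait: str,
    components: str = "ACE",
    covariates: tuple = ("sex",),
    rg_mf=1.0,
    seed: int = 0,
    **fit_kw,
) -> SexLimitationResult:
    """General sex-limitation model (sex-specific paths) versus the
    standard two-group model for one trait.

    ``rg_mf=None`` frees the cross-sex genetic correlation (qualitative
    sex limitation); without opposite-sex pairs it is unidentified and
    is pinned back to 1 with a warning.  The result reports the implied
    cross-twin covariance per zygosity group (e.g. female MZ pairs) and
    per-sex standardized components.
    """
    import warnings as _w

    ds = _as_dataset(dataset)
    if rg_mf is None and "DZOS" not in ds.groups_present(trait):
        _w.warn("no opposite-sex pairs: cross-sex genetic correlation fixed to 1")
        rg_mf = 1.0
    compiled = compile_dataset(ds, (trait,), list(covariates) or None)
    gen_spec = ModelSpec(
        traits=(trait,),
        components=components,
        covariates=tuple(covariates),
        sex_limitation="quantitative_general",
        rg_mf=rg_mf,
    )
    std_spec = ModelSpec(
        traits=(trait,), components=components, covariates=tuple(covariates)
    )
    general = fit_model(compiled, gen_spec, seed=seed, **fit_kw)
    standard = fit_model(compiled, std_spec, seed=seed, **fit_kw)
    stat = max(standard.minus2lnl - general.minus2lnl, 0.0)
    df = general.n_params - standard.n_params
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    implied = {}
    for group, sexes in (
        ("MZF", ("F", "F")),
        ("MZM", ("M", "M")),
        ("DZF", ("F", "F")),
        ("DZM", ("M", "M")),
        ("DZOS", ("F", "M")),
    ):
        sigma = build_pair_covariance(gen_spec, general.full_params, group, sexes)
        implied[group] = {
            "variance_1": float(sigma[0, 0]),
            "variance_2": float(sigma[1, 1]),
            "covariance": float(sigma[0, 1]),
        }
    return SexLimitationResult(
        general=general,
        standard=standard,
        statistic=stat,
        df=df,
        p=p,
        implied_covariances=implied,
        standardized_by_sex=general.standardized,
        rg_mf=float(general.full_params.get("rg_mf", 1.0)),
    )


@dataclass
class CrossTraitResult:
    """Bivariate AE decomposition of the association between two traits."""

    fit: FitResult
    rp: float
    rg: float
    re: float
    h2: np.ndarray
    rp_ci: ProfileCI | None = None
    rg_ci: ProfileCI | None = None
    re_ci: ProfileCI | None = None
    rg_p: float | None = None
    re_p: float | None = None
    rp_p: float | None = None
    covariate_lrt: tuple | None = None


def cross_trait_analysis(
    dataset,
    trait_pair: tuple,
    covariates: tuple = ("sex", "age"),
    compute_ci: bool = True,
    compute_pvalues: bool = True,
    covariate_addition: tuple | None = None,
    seed: int = 0,
    **fit_kw,
) -> CrossTraitResult:
    """Phenotypic, genetic and environmental correlation between two traits.

    Fits the bivariate AE Cholesky model with the requested covariates
    in the means.  Correlation p-values come from LRTs with df = 1: the
    genetic (environmental) correlation drops the corresponding cross
    path, the phenotypic correlation refits under the constraint
    rp = 0.  ``covariate_addition`` optionally runs the LRT for adding
    extra covariates (e.g. ages and the scan-to-score interval) on both
    traits.
    """
    ds = _as_dataset(dataset)
    spec = ModelSpec(traits=tuple(trait_pair), components="AE", covariates=tuple(covariates))
    fit = fit_model(ds, spec, seed=seed, **fit_kw)
    std = fit.standardized
    out = CrossTraitResult(
        fit=fit,
        rp=float(std["rp"]),
        rg=float(std["rg"]),
        re=float(std["re"]),
        h2=np.asarray(std["components"]["h2"]),
    )
    if compute_ci:
        out.rg_ci = profile_ci(None, spec, fit, "rg")
        out.re_ci = profile_ci(None, spec, fit, "re")
        out.rp_ci = profile_ci(None, spec, fit, "rp")
    if compute_pvalues:
        for quant, path, attr in (("rg", "a_21", "rg_p"), ("re", "e_21", "re_p")):
            nested_spec = spec.drop_path(path)
            nested = fit_model(fit.compiled, nested_spec, seed=seed, **fit_kw)
            stat, df, p = lrt(fit, nested)
            setattr(out, attr, p)
        from .fitting import _profiled_value, _quantity_fn

        gfun, _ = _quantity_fn(spec, fit.index, "rp")
        f0, _x = _profiled_value(fit, gfun, 0.0, fit.theta.copy())
        stat = max(f0 - fit.minus2lnl, 0.0)
        out.rp_p = float(chi2.sf(stat, 1))
    if covariate_addition:
        extra = tuple(covariates) + tuple(covariate_addition)
        spec2 = ModelSpec(traits=tuple(trait_pair), components="AE", covariates=extra)
        fit2 = fit_model(ds, spec2, seed=seed, **fit_kw)
        stat = max(fit.minus2lnl - fit2.minus2lnl, 0.0)
        df = fit2.n_params - fit.n_params
        out.covariate_lrt = (stat, df, float(chi2.sf(stat, df)) if df > 0 else 1.0)
    return out
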