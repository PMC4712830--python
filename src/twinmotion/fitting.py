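"""Maximum-likelihood fitting, likelihood-ratio tests and profile CIs.

Models are fitted by L-BFGS-B on the FIML objective with a moment-based
start (Falconer-style initial variance shares from the observed MZ/DZ
pair correlations) plus seeded perturbed restarts; the best converged
solution wins.  Profile-likelihood confidence intervals locate the
parameter values where the profiled -2 ln L rises by the chi-square(1)
quantile above the minimum, refitting all other parameters at each
probe (SLSQP with an equality constraint for derived quantities such as
h2 or a genetic correlation, with a fast reparameterized path for the
univariate AE heritability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .data import MZ_GROUPS, CompiledData, TwinDataset, compile_dataset
from .likelihood import PENALTY, minimize_neg2ll, neg2ll_and_grad
from .model import (
    FitResult,
    ModelSpec,
    build_param_index,
    make_cov_builder,
    standardize,
)

__all__ = [
    "fit_model",
    "lrt",
    "profile_ci",
    "ProfileCI",
    "VarianceComponentsModel",
]


def _ensure_compiled(dataset, spec: ModelSpec) -> CompiledData:
    if isinstance(dataset, CompiledData):
        return dataset
    return compile_dataset(dataset, spec.traits, spec.covariates)


def _individual_matrix(compiled: CompiledData) -> np.ndarray:
    """(n_individuals, p) phenotype matrix with NaN for missing cells."""
    p = len(compiled.traits)
    rows = []
    for blk in compiled.blocks:
        mat = np.full((blk.n, len(blk.sexes), p), np.nan)
        for ci, oi in enumerate(blk.obs_idx):
            mat[:, oi // p, oi % p] = blk.Y[:, ci]
        rows.append(mat.reshape(-1, p))
    return np.vstack(rows)


def _pair_correlations(compiled: CompiledData) -> dict:
    """Observed double-entry pair correlations per trait, split MZ vs DZ."""
    p = len(compiled.traits)
    out = {}
    for ti, trait in enumerate(compiled.traits):
        for zcls, groups in (("MZ", MZ_GROUPS), ("DZ", None)):
            pairs = []
            for blk in compiled.blocks:
                if len(blk.sexes) != 2:
                    continue
                in_cls = blk.group in MZ_GROUPS
                if (zcls == "MZ") != in_cls:
                    continue
                cols = {int(oi): ci for ci, oi in enumerate(blk.obs_idx)}
                c1, c2 = cols.get(ti), cols.get(p + ti)
                if c1 is None or c2 is None:
                    continue
                pairs.append(blk.Y[:, [c1, c2]])
            if pairs:
                arr = np.vstack(pairs)
                de = np.vstack([arr, arr[:, ::-1]])
                r = np.corrcoef(de.T)[0, 1] if len(de) > 2 else 0.0
            else:
                r = 0.0
            out[(trait, zcls)] = float(r)
    return out


def _moment_start(compiled: CompiledData, spec: ModelSpec, index) -> np.ndarray:
    import pandas as pd

    p = len(spec.traits)
    X = _individual_matrix(compiled)
    df = pd.DataFrame(X, columns=list(spec.traits))
    m = df.mean().to_numpy()
    S = df.cov().to_numpy()
    S = np.where(np.isfinite(S), S, 0.0)
    d = np.diag(S).copy()
    d[~np.isfinite(d) | (d <= 0)] = 1.0
    np.fill_diagonal(S, d)
    rc = _pair_correlations(compiled)
    h2 = np.array(
        [
            np.clip(2 * (rc[(t, "MZ")] - rc[(t, "DZ")]), 0.1, 0.8)
            for t in spec.traits
        ]
    )
    shares = {"A": h2}
    if "C" in spec.components:
        c2 = np.array(
            [np.clip(2 * rc[(t, "DZ")] - rc[(t, "MZ")], 0.05, 0.4) for t in spec.traits]
        )
        shares["C"] = c2
    if "D" in spec.components:
        shares["D"] = np.full(p, 0.15)
    used = sum(shares.values())
    over = used > 0.9
    for k in shares:
        shares[k] = np.where(over, shares[k] * 0.9 / used, shares[k])
    shares["E"] = 1.0 - sum(shares.values())

    Scorr = S / np.sqrt(np.outer(d, d))
    theta_full = {}
    for comp in spec.components:
        w = np.sqrt(shares[comp] * d)
        cov0 = Scorr * np.outer(w, w)
        L = np.linalg.cholesky(cov0 + 1e-6 * np.diag(d))
        vals = [L[i, j] for i in range(p) for j in range(i + 1)]
        pre = comp.lower()
        if spec.sex_limitation == "quantitative_general":
            for sx in ("f", "m"):
                names = [f"{pre}_{i+1}{j+1}_{sx}" for i in range(p) for j in range(i + 1)]
                theta_full.update(zip(names, vals))
        else:
            names = [f"{pre}_{i+1}{j+1}" for i in range(p) for j in range(i + 1)]
            theta_full.update(zip(names, vals))
    theta_full["rg_mf"] = 1.0
    for t in spec.traits:
        theta_full[f"s_{t}"] = 0.0
    for g in spec.group_variance_scaling:
        theta_full[f"log_vscale_{g}"] = 0.0

    x0 = np.zeros(index.n_free)
    for i, name in enumerate(index.names):
        if name.startswith("mu_"):
            x0[i] = m[spec.traits.index(name[3:])]
        elif name.startswith("beta_"):
            x0[i] = 0.0
        else:
            x0[i] = theta_full.get(name, 0.1)
    return x0


def fit_model(
    dataset,
    spec: ModelSpec,
    starts=None,
    seed: int = 0,
    n_starts: int = 5,
    maxiter: int = 1000,
) -> FitResult:
    """Fit a variance-component model by full-information ML.

    Runs a moment-based start plus seeded perturbations (``n_starts``
    total, all deterministic given ``seed``) and returns the best
    solution; a non-converged best fit is returned with
    ``converged=False``, never silently dropped.
    """
    compiled = _ensure_compiled(dataset, spec)
    index = build_param_index(compiled, spec)
    builder, cov_key = make_cov_builder(compiled, spec, index)
    bounds = index.bounds()
    rng = np.random.default_rng(seed)
    x0 = _moment_start(compiled, spec, index)
    start_list = [np.asarray(s, dtype=float) for s in starts] if starts else []
    if not start_list:
        start_list = [x0]
        for _ in range(max(0, n_starts - 1)):
            pert = x0.copy()
            scale = np.maximum(np.abs(x0), 0.1)
            pert += rng.normal(0.0, 0.15, size=x0.size) * scale
            start_list.append(pert)
    best = None
    tried = []
    for k, xk in enumerate(start_list):
        res = minimize_neg2ll(
            compiled.blocks, index.q_mean, builder, xk, bounds, maxiter, cov_key=cov_key
        )
        ok = bool(res.success or res.grad_norm < 1e-4)
        tried.append((ok, res.fun))
        if best is None or (res.fun < best[1].fun - 1e-9):
            best = (ok, res)
        # stop early once two converged starts re-find the same optimum
        conv_funs = sorted(f for c, f in tried if c)
        if k >= 2 and len(conv_funs) >= 2 and conv_funs[1] - conv_funs[0] < 1e-6:
            break
    ok, res = best
    estimates = index.to_dict(res.x)
    full = dict(estimates)
    full.update(index.fixed)
    if spec.sex_limitation == "quantitative_general":
        std = {sx: standardize(spec, full, sex=sx) for sx in ("F", "M")}
    else:
        std = standardize(spec, full)
    return FitResult(
        spec=spec,
        estimates=estimates,
        minus2lnl=float(res.fun),
        n_params=index.n_free,
        converged=ok and res.fun < PENALTY / 2,
        gradient_norm=res.grad_norm,
        standardized=std,
        n_families=compiled.n_families,
        index=index,
        theta=res.x,
        start_values=tried,
        compiled=compiled,
    )


def lrt(full: FitResult, nested: FitResult, refit: bool = True):
    """Likelihood-ratio test of ``nested`` (constrained) against ``full``.

    Returns ``(statistic, df, p)``; a slightly negative statistic is
    rescued by refitting the nested model from the full model's
    estimates.
    """
    stat = nested.minus2lnl - full.minus2lnl
    df = full.n_params - nested.n_params
    if stat < -1e-6 and refit and nested.compiled is not None:
        warm = [
            np.array(
                [
                    full.full_params.get(n, nested.estimates[n])
                    for n in nested.index.names
                ]
            )
        ]
        nested2 = fit_model(nested.compiled, nested.spec, starts=warm)
        if nested2.minus2lnl < nested.minus2lnl:
            nested = nested2
            stat = nested.minus2lnl - full.minus2lnl
    if stat < -1e-6:
        raise ValueError(f"negative LRT statistic {stat:.3g}: models are not nested as fitted")
    stat = max(stat, 0.0)
    if df <= 0:
        return stat, df, 1.0
    return stat, df, float(chi2.sf(stat, df))


@dataclass
class ProfileCI:
    """Profile-likelihood interval; ``*_at_boundary`` flags one-sided ends."""

    estimate: float
    lower: float
    upper: float
    level: float
    lower_at_boundary: bool = False
    upper_at_boundary: bool = False

    def __iter__(self):
        yield self.lower
        yield self.upper


_SHARE_NAMES = ("h2", "c2", "d2", "e2")
_CORR_NAMES = ("rg", "rc", "rd", "re", "rp")


def _quantity_fn(spec: ModelSpec, index, param: str):
    """Map a raw or derived parameter name to (g(theta), (lo, hi) bounds)."""
    if param in index.names:
        i = index.names.index(param)
        lo, hi = index.bounds()[i]
        return (lambda th: float(th[i])), (lo if lo is not None else -np.inf,
                                           hi if hi is not None else np.inf)
    base, _, trait = param.partition("_")
    if base in _SHARE_NAMES:
        ti = spec.traits.index(trait) if trait else 0
        key = base

        def g(th):
            full = index.to_dict(th)
            full.update(index.fixed)
            return float(standardize(spec, full)["components"][key][ti])

        return g, (0.0, 1.0)
    if param in _CORR_NAMES:

        def g(th):
            full = index.to_dict(th)
            full.update(index.fixed)
            return float(standardize(spec, full)[param])

        return g, (-1.0, 1.0)
    raise ValueError(f"unknown parameter or quantity {param!r}")


def _profiled_value(fit: FitResult, gfun, val: float, warm: np.ndarray):
    """min -2lnL subject to g(theta) = val (SLSQP, warm-started)."""
    compiled, index, spec = fit.compiled, fit.index, fit.spec
    builder, cov_key = make_cov_builder(compiled, spec, index)

    def fun(th):
        return neg2ll_and_grad(compiled.blocks, index.q_mean, builder, th, cov_key=cov_key)

    cons = {"type": "eq", "fun": lambda th: gfun(th) - val}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            fun,
            warm,
            jac=True,
            method="SLSQP",
            constraints=[cons],
            options={"maxiter": 200, "ftol": 1e-10},
        )
    return float(res.fun), res.x


def _fast_h2_profile(fit: FitResult):
    """Reparameterized profiled -2lnL for the univariate AE heritability.

    With h2 fixed, Sigma_group = v [[1, rho_A h2], [rho_A h2, 1]] leaves
    only the means and total variance free - a tiny smooth problem.
    """
    compiled, index, spec = fit.compiled, fit.index, fit.spec
    q = index.q_mean

    def profiled(h2val):
        def builder(tc, blk, want_derivs):
            v = float(np.exp(tc[0]))
            rho = (1.0 if blk.group in MZ_GROUPS else 0.5) * h2val
            sigma = v * np.array([[1.0, rho], [rho, 1.0]])
            return sigma, ([sigma] if want_derivs else None)

        key = lambda blk: "MZ" if blk.group in MZ_GROUPS else "DZ"
        full = fit.full_params
        v0 = full["a_11"] ** 2 + full["e_11"] ** 2
        x0 = np.concatenate([fit.theta[:q], [np.log(max(v0, 1e-8))]])
        res = minimize_neg2ll(compiled.blocks, q, builder, x0, cov_key=key)
        return float(res.fun), res.x

    return profiled


def profile_ci(
    dataset,
    spec: ModelSpec | None,
    fit: FitResult,
    param: str,
    level: float = 0.95,
) -> ProfileCI:
    """Profile-likelihood CI for a parameter or derived quantity.

    ``param`` may be a free parameter name, a per-trait variance share
    (``h2``, ``h2_<trait>``, ``c2``, ``d2``, ``e2``) or a correlation
    (``rg``, ``re``, ``rc``, ``rd``, ``rp``).  Correlations are clamped
    to [-1, 1]; an endpoint at a bound is flagged as one-sided.
    """
    if not fit.converged:
        raise ValueError("profile CI requires a converged fit")
    spec = spec or fit.spec
    index = fit.index
    gfun, (lo, hi) = _quantity_fn(spec, index, param)
    mle = gfun(fit.theta)
    crit = chi2.ppf(level, 1)
    target = fit.minus2lnl + crit

    fast = None
    if (
        param in ("h2", f"h2_{spec.traits[0]}")
        and spec.components == "AE"
        and spec.n_traits == 1
        and spec.sex_limitation == "none"
        and not spec.contrast
        and not spec.group_variance_scaling
    ):
        fast = _fast_h2_profile(fit)

    def profiled(val, warm):
        if fast is not None:
            f, x = fast(val)
            return f, warm
        return _profiled_value(fit, gfun, val, warm)

    results = {}
    for side, bound in (("lower", lo), ("upper", hi)):
        direction = -1.0 if side == "lower" else 1.0
        warm = fit.theta.copy()
        if np.isfinite(bound):
            fracs = [0.25, 0.5, 0.75, 0.9, 0.975, 0.997]
            probes = [mle + f * (bound - mle) for f in fracs]
        else:
            step = max(0.25 * abs(mle), 0.25)
            probes = [mle + direction * step * (2.0**k) for k in range(18)]
        prev_val, prev_f = mle, fit.minus2lnl
        endpoint, flag = None, False
        for v in probes:
            f, warm = profiled(v, warm)
            if f >= target:
                g = lambda x, w=[warm]: profiled(x, w[0])[0] - target
                a, b = (v, prev_val) if side == "lower" else (prev_val, v)
                endpoint = float(optimize.brentq(g, a, b, xtol=1e-4))
                break
            prev_val, prev_f = v, f
        if endpoint is None:
            endpoint, flag = (bound if np.isfinite(bound) else prev_val), True
        results[side] = (endpoint, flag)

    lo_v, lo_flag = results["lower"]
    hi_v, hi_flag = results["upper"]
    lo_v = min(lo_v, mle)
    hi_v = max(hi_v, mle)
    return ProfileCI(
        estimate=mle,
        lower=lo_v,
        upper=hi_v,
        level=level,
        lower_at_boundary=lo_flag,
        upper_at_boundary=hi_flag,
    )


class VarianceComponentsModel:
    """sklearn-style estimator for ACE/ADE/AE/CE/E twin models.

    ``fit`` accepts the phenotype table (DataFrame or
    :class:`~twinmotion.data.TwinDataset`) and estimates path
    coefficients, covariate effects and derived variance shares by
    full-information ML.

    Attributes set by :meth:`fit` include ``estimates_``,
    ``minus2lnl_``, ``converged_``, ``h2_`` (per-trait A shares),
    ``rg_``/``re_``/``rp_`` (bivariate models) and ``standardized_``.
    """

    def __init__(
        self,
        traits,
        components: str = "AE",
        covariates=None,
        sex_limitation: str = "none",
        group_variance_scaling=(),
        contrast: bool = False,
        rg_mf=1.0,
        fixed=None,
        n_starts: int = 5,
        seed: int = 0,
        maxiter: int = 1000,
    ):
        self.traits = traits
        self.components = components
        self.covariates = covariates
        self.sex_limitation = sex_limitation
        self.group_variance_scaling = group_variance_scaling
        self.contrast = contrast
        self.rg_mf = rg_mf
        self.fixed = fixed
        self.n_starts = n_starts
        self.seed = seed
        self.maxiter = maxiter

    _PARAM_KEYS = (
        "traits components covariates sex_limitation group_variance_scaling "
        "contrast rg_mf fixed n_starts seed maxiter"
    ).split()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._PARAM_KEYS}

    def set_params(self, **params) -> "VarianceComponentsModel":
        for k, v in params.items():
            if k not in self._PARAM_KEYS:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def to_spec(self) -> ModelSpec:
        return ModelSpec(
            traits=tuple(self.traits) if not isinstance(self.traits, str) else (self.traits,),
            components=self.components,
            covariates=self.covariates,
            sex_limitation=self.sex_limitation,
            group_variance_scaling=tuple(self.group_variance_scaling),
            contrast=self.contrast,
            rg_mf=self.rg_mf,
            fixed=dict(self.fixed or {}),
        )

    def fit(self, X, y=None) -> "VarianceComponentsModel":
        spec = self.to_spec()
        result = fit_model(X, spec, seed=self.seed, n_starts=self.n_starts, maxiter=self.maxiter)
        self.result_ = result
        self.spec_ = spec
        self.estimates_ = result.estimates
        self.minus2lnl_ = result.minus2lnl
        self.n_params_ = result.n_params
        self.converged_ = result.converged
        self.gradient_norm_ = result.gradient_norm
        self.standardized_ = result.standardized
        std = result.standardized
        if spec.sex_limitation == "none":
            self.h2_ = std["components"]["h2"] if "h2" in std["components"] else None
            if spec.n_traits >= 2:
                self.rg_ = std.get("rg")
                self.re_ = std.get("re")
                self.rp_ = std.get("rp")
        return self

    def profile_ci(self, param: str, level: float = 0.95) -> ProfileCI:
        return profile_ci(None, self.spec_, self.result_, param, level=level)

    def score(self, X, y=None) -> float:
        """Mean log-likelihood per family on new data (higher is better)."""
        from .model import fiml_neg2ll

        compiled = _ensure_compiled(X, self.spec_)
        return -0.5 * fiml_neg2ll(compiled, self.spec_, self.result_.theta) / compiled.n_families
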