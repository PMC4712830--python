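"""Variance-component model family for twin-pair data.

A trait vector is decomposed into additive genetic (A), shared
environment (C) or dominance genetic (D), and unique environment (E)
sources.  Each component contributes a p x p lower-triangular path
matrix L_X (Cholesky parameterization), so its covariance L_X L_X' is
positive semi-definite by construction; cross-twin covariance scales
each component by the biometrical relatedness of the pair: A is shared
1 in MZ and 0.5 in DZ/sibling pairs (times the cross-sex genetic
correlation r_g^mf in opposite-sex pairs), D is 1 / 0.25, C is shared
by all co-twins, E is never shared.

Optional structure used in the analysis:

* quantitative/qualitative sex limitation — sex-specific path matrices
  plus r_g^mf on opposite-sex pairs (fixed to 1 unless freed);
* sibling contrast — a reciprocal interaction path s between co-twins,
  Sigma* = (I-B)^-1 Sigma (I-B)^-T with B holding s on cross-member,
  same-trait positions;
* per-group total-variance scaling, for groups whose phenotypic
  variance is heterogeneous (e.g. females from opposite-sex pairs).

Parameters are unconstrained path entries; diagonal signs are resolved
by reporting magnitudes of derived variance shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data import CompiledData, DZ_GROUPS, MZ_GROUPS

__all__ = [
    "ModelSpec",
    "FitResult",
    "ParamIndex",
    "component_correlation",
    "build_param_index",
    "build_pair_covariance",
    "implied_pair_moments",
    "fiml_neg2ll",
    "standardize",
]

_VALID_COMPONENTS = {"A", "C", "D", "E"}


@dataclass(frozen=True)
class ModelSpec:
    """Definition of a variance-component model.

    ``components`` is a subset of ``"ACDE"`` (E mandatory, C and D
    mutually exclusive).  ``covariates`` follows the dataset dialect:
    a flat list applied to every trait, or a mapping trait -> list;
    generic names ('age', 'wave', 'design', 'interval') resolve to
    trait-appropriate columns.  ``fixed`` pins named parameters (path
    entries, contrast, r_g^mf) to constants.
    """

    traits: tuple
    components: str = "AE"
    covariates: tuple | Mapping | None = None
    sex_limitation: str = "none"  # or "quantitative_general"
    group_variance_scaling: tuple = ()
    contrast: bool = False
    rg_mf: float | None = 1.0  # None => free parameter (qualitative sex limitation)
    fixed: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "traits", tuple(self.traits))
        comps = "".join(sorted(set(self.components)))
        if "E" not in comps:
            raise ValueError("the E component is mandatory")
        if not set(comps) <= _VALID_COMPONENTS:
            raise ValueError(f"unknown components in {self.components!r}")
        if "C" in comps and "D" in comps:
            raise ValueError("C and D are mutually exclusive")
        if self.sex_limitation not in ("none", "quantitative_general"):
            raise ValueError(f"unknown sex_limitation {self.sex_limitation!r}")
        object.__setattr__(self, "components", comps.replace("E", "") + "E")
        object.__setattr__(self, "group_variance_scaling", tuple(self.group_variance_scaling))

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def drop_path(self, name: str) -> "ModelSpec":
        """Nested spec with one path (or other parameter) pinned to zero."""
        fixed = dict(self.fixed)
        fixed[name] = 0.0
        return replace(self, fixed=fixed)


def component_correlation(
    component: str, zygosity_group: str, rg_mf: float = 1.0, sexes: tuple | None = None
) -> float:
    """Cross-twin correlation of a component's factor scores for a pair.

    A: 1 in MZ, 0.5 in DZ/SIB (times r_g^mf when the pair is
    opposite-sex); D: 1 in MZ, 0.25 in DZ/SIB; C: 1 in all pairs;
    E: never shared.
    """
    opposite = (
        sexes is not None and len(sexes) == 2 and sexes[0] != sexes[1]
    ) or (sexes is None and zygosity_group == "DZOS")
    if component == "E":
        return 0.0
    if component == "C":
        return 1.0
    if zygosity_group in MZ_GROUPS:
        return 1.0
    if zygosity_group in DZ_GROUPS:
        if component == "A":
            return 0.5 * (rg_mf if opposite else 1.0)
        if component == "D":
            return 0.25
    raise ValueError(f"unknown zygosity group {zygosity_group!r}")


@dataclass
class ParamIndex:
    """Layout of the free parameter vector for (CompiledData, ModelSpec)."""

    mean_names: tuple
    cov_names_full: tuple  # covariance-side parameters incl. fixed ones
    fixed: dict  # name -> value among cov_names_full
    bounds_full: dict  # name -> (lo, hi) for bounded parameters

    @property
    def free_cov_names(self) -> tuple:
        return tuple(n for n in self.cov_names_full if n not in self.fixed)

    @property
    def names(self) -> tuple:
        return self.mean_names + self.free_cov_names

    @property
    def q_mean(self) -> int:
        return len(self.mean_names)

    @property
    def n_free(self) -> int:
        return len(self.names)

    def full_cov_vector(self, tc_free: np.ndarray) -> np.ndarray:
        out = np.empty(len(self.cov_names_full))
        it = iter(tc_free)
        for i, n in enumerate(self.cov_names_full):
            out[i] = self.fixed[n] if n in self.fixed else next(it)
        return out

    def bounds(self):
        bl = [(None, None)] * self.q_mean
        for n in self.free_cov_names:
            bl.append(self.bounds_full.get(n, (None, None)))
        return bl

    def to_dict(self, theta: np.ndarray) -> dict:
        return dict(zip(self.names, np.asarray(theta, dtype=float)))


def _tri_names(prefix: str, p: int, suffix: str = "") -> list[str]:
    return [f"{prefix}_{i + 1}{j + 1}{suffix}" for i in range(p) for j in range(i + 1)]


def build_param_index(compiled: CompiledData, spec: ModelSpec) -> ParamIndex:
    if tuple(compiled.traits) != spec.traits:
        raise ValueError("compiled data traits do not match the model spec")
    p = spec.n_traits
    cov_names: list[str] = []
    sexlim = spec.sex_limitation == "quantitative_general"
    for comp in spec.components:
        pre = comp.lower()
        if sexlim:
            cov_names += _tri_names(pre, p, "_f") + _tri_names(pre, p, "_m")
        else:
            cov_names += _tri_names(pre, p)
    fixed = dict(spec.fixed)
    bounds: dict[str, tuple] = {}
    if sexlim:
        cov_names.append("rg_mf")
        bounds["rg_mf"] = (-1.0, 1.0)
        if spec.rg_mf is not None:
            fixed.setdefault("rg_mf", float(spec.rg_mf))
    if spec.contrast:
        for t in spec.traits:
            cov_names.append(f"s_{t}")
            bounds[f"s_{t}"] = (-0.95, 0.95)
    for g in spec.group_variance_scaling:
        cov_names.append(f"log_vscale_{g}")
    unknown = set(fixed) - set(cov_names)
    if unknown:
        raise ValueError(f"fixed parameters not in this model: {sorted(unknown)}")
    return ParamIndex(
        mean_names=compiled.mean_param_names,
        cov_names_full=tuple(cov_names),
        fixed=fixed,
        bounds_full=bounds,
    )


def _tri_matrix(values: Sequence[float], p: int) -> np.ndarray:
    L = np.zeros((p, p))
    idx = 0
    for i in range(p):
        for j in range(i + 1):
            L[i, j] = values[idx]
            idx += 1
    return L


def _component_paths(spec: ModelSpec, full: Mapping[str, float]) -> dict:
    """Per-component (and per-sex, if limited) lower-triangular path matrices."""
    p = spec.n_traits
    out = {}
    sexlim = spec.sex_limitation == "quantitative_general"
    for comp in spec.components:
        pre = comp.lower()
        if sexlim:
            out[comp] = {
                sex: _tri_matrix([full[n] for n in _tri_names(pre, p, f"_{sex.lower()}")], p)
                for sex in ("F", "M")
            }
        else:
            L = _tri_matrix([full[n] for n in _tri_names(pre, p)], p)
            out[comp] = {"F": L, "M": L}
    return out


_COTWIN_SEX = {"MZF": "F", "MZM": "M", "DZF": "F", "DZM": "M"}


def build_pair_covariance(
    spec: ModelSpec, full_params: Mapping[str, float], group: str, sexes: tuple
) -> np.ndarray:
    """Implied covariance for the family members given by ``sexes``.

    For a pair this is the 2p x 2p matrix; for a lone member the p x p
    marginal (obtained from the pair matrix, so contrast effects on the
    unobserved co-twin propagate correctly).
    """
    p = spec.n_traits
    paths = _component_paths(spec, full_params)
    rg_mf = float(full_params.get("rg_mf", 1.0))
    lone = len(sexes) == 1
    if lone:
        cotwin = _COTWIN_SEX.get(group) or ("M" if sexes[0] == "F" else "F")
        pair_sexes = (sexes[0], cotwin)
    else:
        pair_sexes = tuple(sexes)
    s1, s2 = pair_sexes
    within = {
        sx: sum(paths[c][sx] @ paths[c][sx].T for c in spec.components) for sx in ("F", "M")
    }
    cross = np.zeros((p, p))
    for comp in spec.components:
        rho = component_correlation(comp, group, rg_mf=rg_mf, sexes=pair_sexes)
        if rho != 0.0:
            cross += rho * (paths[comp][s1] @ paths[comp][s2].T)
    sigma = np.block([[within[s1], cross], [cross.T, within[s2]]])
    if spec.contrast:
        s_vals = np.array([full_params[f"s_{t}"] for t in spec.traits])
        B = np.zeros((2 * p, 2 * p))
        B[np.arange(p), p + np.arange(p)] = s_vals
        B[p + np.arange(p), np.arange(p)] = s_vals
        IB = np.linalg.inv(np.eye(2 * p) - B)
        sigma = IB @ sigma @ IB.T
    scale_name = f"log_vscale_{group}"
    if scale_name in full_params:
        sigma = sigma * float(np.exp(full_params[scale_name]))
    return sigma[:p, :p] if lone else sigma


def _parse_cov_name(name: str, spec: ModelSpec):
    """Classify a covariance-side parameter name for derivative rules."""
    if name == "rg_mf":
        return ("rg",)
    if name.startswith("s_"):
        return ("contrast", spec.traits.index(name[2:]))
    if name.startswith("log_vscale_"):
        return ("vscale", name[len("log_vscale_"):])
    pre, rest = name[0], name[2:]
    sex = None
    if rest.endswith("_f") or rest.endswith("_m"):
        sex = rest[-1].upper()
        rest = rest[:-2]
    i, j = int(rest[0]) - 1, int(rest[1]) - 1
    return ("path", pre.upper(), sex, i, j)


def make_cov_builder(compiled: CompiledData, spec: ModelSpec, index: ParamIndex):
    """Compile (builder, cov_key) closures for the likelihood engine.

    The builder always returns the full two-member covariance (lone
    members are marginalized downstream) and, on request, analytic
    derivatives with respect to every free covariance parameter.
    ``cov_key`` collapses blocks with identical implied structure so
    each distinct covariance is built once per objective evaluation.
    """
    p = spec.n_traits
    sexlim = spec.sex_limitation == "quantitative_general"
    names = index.cov_names_full
    pos = {n: i for i, n in enumerate(names)}
    template = np.zeros(len(names))
    for n, v in index.fixed.items():
        template[pos[n]] = v
    free_pos = np.array([pos[n] for n in names if n not in index.fixed], dtype=int)
    free_meta = [_parse_cov_name(n, spec) for n in names if n not in index.fixed]

    comp_pos = {}
    for comp in spec.components:
        pre = comp.lower()
        if sexlim:
            for sex in ("F", "M"):
                nm = _tri_names(pre, p, f"_{sex.lower()}")
                comp_pos[(comp, sex)] = np.array([pos[n] for n in nm], dtype=int)
        else:
            nm = _tri_names(pre, p)
            comp_pos[(comp, "F")] = comp_pos[(comp, "M")] = np.array(
                [pos[n] for n in nm], dtype=int
            )
    tri_r = np.array([i for i in range(p) for _ in range(i + 1)], dtype=int)
    tri_c = np.array([j for i in range(p) for j in range(i + 1)], dtype=int)
    scaling = set(spec.group_variance_scaling)
    contrast = spec.contrast
    s_pos = (
        np.array([pos[f"s_{t}"] for t in spec.traits], dtype=int) if contrast else None
    )
    rg_free = sexlim and "rg_mf" not in index.fixed
    rg_relevant = sexlim and (rg_free or index.fixed.get("rg_mf", 1.0) != 1.0)

    def extend(group, sexes):
        if len(sexes) == 2:
            return tuple(sexes)
        cot = _COTWIN_SEX.get(group) or ("M" if sexes[0] == "F" else "F")
        return (sexes[0], cot)

    def cov_key(blk):
        group, sexes = blk.group, blk.sexes
        ps = extend(group, sexes)
        rel = "MZ" if group in MZ_GROUPS else "DZ"
        part = ps if sexlim else ((ps[0] != ps[1]) if (rg_relevant and rel == "DZ") else None)
        return (rel, part, group if group in scaling else None)

    def builder(tc, blk, want_derivs):
        group, sexes = blk.group, blk.sexes
        full = template.copy()
        full[free_pos] = tc
        ps = extend(group, sexes)
        s1, s2 = ps
        rel = "MZ" if group in MZ_GROUPS else "DZ"
        opp = s1 != s2
        rg = float(full[pos["rg_mf"]]) if sexlim else 1.0
        L = {}
        for comp in spec.components:
            for sx in {s1, s2}:
                mat = np.zeros((p, p))
                mat[tri_r, tri_c] = full[comp_pos[(comp, sx)]]
                L[(comp, sx)] = mat
        rho = {}
        for comp in spec.components:
            r = component_correlation(comp, group, rg_mf=rg, sexes=ps)
            rho[comp] = r
        W1 = sum(L[(c, s1)] @ L[(c, s1)].T for c in spec.components)
        W2 = (
            W1
            if s1 == s2
            else sum(L[(c, s2)] @ L[(c, s2)].T for c in spec.components)
        )
        C = np.zeros((p, p))
        for c in spec.components:
            if rho[c] != 0.0:
                C += rho[c] * (L[(c, s1)] @ L[(c, s2)].T)
        Sigma0 = np.empty((2 * p, 2 * p))
        Sigma0[:p, :p] = W1
        Sigma0[p:, p:] = W2
        Sigma0[:p, p:] = C
        Sigma0[p:, :p] = C.T

        derivs = None
        if want_derivs:
            derivs = []
            for m in free_meta:
                d = np.zeros((2 * p, 2 * p))
                if m[0] == "path":
                    _, comp, sex, i, j = m
                    a1 = sex is None or sex == s1
                    a2 = sex is None or sex == s2
                    L1, L2 = L[(comp, s1)], L[(comp, s2)]
                    if a1:
                        dW = np.zeros((p, p))
                        dW[i, :] += L1[:, j]
                        dW[:, i] += L1[:, j]
                        d[:p, :p] = dW
                    if a2:
                        dW = np.zeros((p, p))
                        dW[i, :] += L2[:, j]
                        dW[:, i] += L2[:, j]
                        d[p:, p:] = dW
                    if rho[comp] != 0.0:
                        dC = np.zeros((p, p))
                        if a1:
                            dC[i, :] += L2[:, j]  # E_ij @ L2'
                        if a2:
                            dC[:, i] += L1[:, j]  # L1 @ E_ij'
                        dC = rho[comp] * dC
                        d[:p, p:] = dC
                        d[p:, :p] = dC.T
                elif m[0] == "rg":
                    if rel == "DZ" and opp:
                        dC = 0.5 * (L[("A", s1)] @ L[("A", s2)].T)
                        d[:p, p:] = dC
                        d[p:, :p] = dC.T
                derivs.append(d)

        Sigma = Sigma0
        if contrast:
            s_vals = full[s_pos]
            B = np.zeros((2 * p, 2 * p))
            B[np.arange(p), p + np.arange(p)] = s_vals
            B[p + np.arange(p), np.arange(p)] = s_vals
            IB = np.linalg.inv(np.eye(2 * p) - B)  # symmetric since B is
            Sigma = IB @ Sigma0 @ IB
            if want_derivs:
                for jj, m in enumerate(free_meta):
                    if m[0] in ("path", "rg"):
                        derivs[jj] = IB @ derivs[jj] @ IB
                    elif m[0] == "contrast":
                        ti = m[1]
                        Bt = np.zeros((2 * p, 2 * p))
                        Bt[ti, p + ti] = 1.0
                        Bt[p + ti, ti] = 1.0
                        dIB = IB @ Bt @ IB
                        derivs[jj] = dIB @ Sigma0 @ IB + IB @ Sigma0 @ dIB
        if group in scaling:
            f = float(np.exp(full[pos[f"log_vscale_{group}"]]))
            Sigma = f * Sigma
            if want_derivs:
                for jj, m in enumerate(free_meta):
                    if m[0] == "vscale":
                        derivs[jj] = Sigma.copy() if m[1] == group else np.zeros_like(Sigma)
                    else:
                        derivs[jj] = f * derivs[jj]
        return Sigma, derivs

    return builder, cov_key


def fiml_neg2ll(compiled: CompiledData, spec: ModelSpec, theta: np.ndarray) -> float:
    """-2 ln L of the model at ``theta`` (mean params then free cov params).

    Families contribute the multivariate-normal density of their observed
    cells; a non-positive-definite implied covariance yields a large
    penalty value rather than an exception.
    """
    from .likelihood import neg2ll

    index = build_param_index(compiled, spec)
    builder, cov_key = make_cov_builder(compiled, spec, index)
    return neg2ll(compiled.blocks, index.q_mean, builder, theta, cov_key=cov_key)


def implied_pair_moments(
    spec: ModelSpec,
    params: Mapping[str, float],
    group: str,
    covariates: Sequence[Mapping[str, float]] | None = None,
    sexes: tuple = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Implied (mean vector, covariance matrix) for one pair.

    ``params`` maps parameter names (including ``mu_<trait>`` and
    ``beta_<cov>_<trait>``) to values; ``covariates`` gives per-member
    covariate values on the centred scale used in the mean model.
    """
    if sexes is None:
        sexes = {"MZF": ("F", "F"), "MZM": ("M", "M"), "DZF": ("F", "F"), "DZM": ("M", "M")}.get(
            group, ("F", "M")
        )
    for name, v in params.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite parameter {name!r}")
    for t in spec.traits:
        sname = f"s_{t}"
        if spec.contrast and abs(params.get(sname, 0.0)) >= 1.0:
            raise ValueError("contrast |s| >= 1 is outside the invertible regime")
    sigma = build_pair_covariance(spec, params, group, tuple(sexes))
    p = spec.n_traits
    mean = np.zeros(2 * p)
    for mi in range(2):
        covs = (covariates[mi] if covariates else {}) or {}
        for ti, t in enumerate(spec.traits):
            mu = params.get(f"mu_{t}", 0.0)
            for cname, cval in covs.items():
                mu += params.get(f"beta_{cname}_{t}", 0.0) * cval
            mean[mi * p + ti] = mu
    return mean, sigma


def standardize(
    spec: ModelSpec, params: Mapping[str, float], sex: str = "F"
) -> dict:
    """Variance shares and cross-trait correlations implied by path estimates.

    Returns per-trait shares (h2, c2/d2, e2 as proportions of total
    variance) and, for multivariate models, component-wise cross-trait
    correlations (rg, rc/rd, re) plus the phenotypic correlation rp.
    Correlations of a component with zero variance are reported as NaN.
    """
    paths = _component_paths(spec, params)
    p = spec.n_traits
    comp_cov = {c: paths[c][sex] @ paths[c][sex].T for c in spec.components}
    total = sum(comp_cov.values())
    out: dict = {"total_variance": np.diag(total).copy(), "components": {}}
    share_key = {"A": "h2", "C": "c2", "D": "d2", "E": "e2"}
    for c in spec.components:
        out["components"][share_key[c]] = np.diag(comp_cov[c]) / np.diag(total)
    corr_key = {"A": "rg", "C": "rc", "D": "rd", "E": "re"}
    if p >= 2:
        for c in spec.components:
            v = np.diag(comp_cov[c])
            denom = np.sqrt(v[0] * v[1])
            out[corr_key[c]] = float(comp_cov[c][0, 1] / denom) if denom > 0 else np.nan
        vtot = np.diag(total)
        out["rp"] = float(total[0, 1] / np.sqrt(vtot[0] * vtot[1]))
    out["covariance"] = {share_key[c]: comp_cov[c] for c in spec.components}
    return out


@dataclass
class FitResult:
    """A maximum-likelihood fit of a :class:`ModelSpec`."""

    spec: ModelSpec
    estimates: dict  # free parameter name -> value
    minus2lnl: float
    n_params: int
    converged: bool
    gradient_norm: float
    standardized: dict | None = None
    n_families: int = 0
    index: ParamIndex | None = None
    theta: np.ndarray | None = None
    start_values: list = field(default_factory=list)
    compiled: object = field(default=None, repr=False)

    @property
    def full_params(self) -> dict:
        """Estimates plus fixed parameter values."""
        out = dict(self.estimates)
        if self.index is not None:
            out.update(self.index.fixed)
        return out

    def aic(self) -> float:
        return self.minus2lnl + 2 * self.n_params
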