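"""Saturated (unstructured) univariate models for twin pairs.

The saturated model places no biometrical structure on the data: means
and variances per assignable class of individuals, one cross-twin
covariance per class of pairs, all estimated by full-information ML.
It is the reference model of the homogeneity test battery — each null
hypothesis (birth-order equality, sex equality, covariance homogeneity
across zygosity groups, null covariate effects) is a constrained
version, compared by likelihood-ratio test.

Classes are declared by mode strings:

* mean/variance modes — ``group_member`` (finest: per zygosity group
  and birth-order slot), ``group``, ``group_sex``, ``sex``, ``pooled``;
* covariance modes — ``by_sex_zygosity`` (MZF, MZM, DZF, DZM, DZOS;
  sibling pairs map to the DZ class matching their sex configuration),
  ``mz_dzss_dzos``, ``mz_dz``, ``pooled``, ``none`` (covariance 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import MZ_GROUPS, TwinDataset, compile_dataset
from .likelihood import minimize_neg2ll, neg2ll

__all__ = ["SaturatedTwinModel", "MEAN_MODES", "COV_MODES"]

MEAN_MODES = ("group_member", "group", "group_sex", "sex", "pooled")
COV_MODES = ("by_sex_zygosity", "mz_dzss_dzos", "mz_dz", "pooled", "none")


def _mean_class(mode: str, group: str, sex: str, slot: int) -> str:
    """Class label for a member; ``slot`` is the original member position
    (birth order, female-first in opposite-sex pairs)."""
    if mode == "group_member":
        return f"{group}.m{slot + 1}"
    if mode == "group":
        return group
    if mode == "group_sex":
        return f"{group}.{sex}"
    if mode == "sex":
        return sex
    if mode == "pooled":
        return "all"
    raise ValueError(f"unknown mean/variance class mode {mode!r}")


def _cov_class(mode: str, group: str, sexes: tuple) -> str | None:
    if mode == "none":
        return None
    if mode == "pooled":
        return "all"
    zyg = "MZ" if group in MZ_GROUPS else "DZ"
    same = sexes[0] == sexes[1]
    if mode == "mz_dz":
        return zyg
    if mode == "mz_dzss_dzos":
        if zyg == "MZ":
            return "MZ"
        return "DZSS" if same else "DZOS"
    if mode == "by_sex_zygosity":
        if zyg == "MZ":
            return f"MZ{sexes[0]}"
        return f"DZ{sexes[0]}" if same else "DZOS"
    raise ValueError(f"unknown covariance class mode {mode!r}")


class SaturatedTwinModel:
    """ML saturated model for one trait on pair-structured data.

    Parameters
    ----------
    trait : str
        Phenotype column to model.
    covariates : sequence of str
        Covariates entering every mean class linearly (generic names
        'age', 'wave', ... resolve per trait).
    mean_by, var_by : str
        Class modes for means and variances (see module docstring).
    cov_by : str
        Class mode for cross-twin covariances; ``"none"`` fixes them to 0.
    """

    def __init__(
        self,
        trait: str,
        covariates: tuple = (),
        mean_by: str = "group_member",
        var_by: str = "group_member",
        cov_by: str = "by_sex_zygosity",
        n_starts: int = 2,
        seed: int = 0,
    ):
        self.trait = trait
        self.covariates = tuple(covariates)
        self.mean_by = mean_by
        self.var_by = var_by
        self.cov_by = cov_by
        self.n_starts = n_starts
        self.seed = seed

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "trait": self.trait,
            "covariates": self.covariates,
            "mean_by": self.mean_by,
            "var_by": self.var_by,
            "cov_by": self.cov_by,
            "n_starts": self.n_starts,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "SaturatedTwinModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- model assembly ----------------------------------------------------
    def _compile(self, X):
        compiled = compile_dataset(X, (self.trait,), list(self.covariates) or None)
        mean_classes: list[str] = []
        var_classes: list[str] = []
        cov_classes: list[str] = []
        for blk in compiled.blocks:
            for si in range(len(blk.sexes)):
                mc = _mean_class(self.mean_by, blk.group, blk.sexes[si], blk.slots[si])
                vc = _mean_class(self.var_by, blk.group, blk.sexes[si], blk.slots[si])
                if mc not in mean_classes:
                    mean_classes.append(mc)
                if vc not in var_classes:
                    var_classes.append(vc)
            if len(blk.sexes) == 2:
                cc = _cov_class(self.cov_by, blk.group, blk.sexes)
                if cc is not None and cc not in cov_classes:
                    cov_classes.append(cc)
        mean_classes.sort()
        var_classes.sort()
        cov_classes.sort()
        n_cov_cols = len(compiled.mean_param_names) - 1  # drop single intercept
        mean_names = [f"mu.{c}" for c in mean_classes] + [
            f"beta_{c}" for c in self.covariates
        ]
        # rebuild design: class indicators + covariate columns
        blocks = []
        for blk in compiled.blocks:
            n, k, _ = blk.D.shape
            D = np.zeros((n, k, len(mean_names)))
            for ci in range(k):
                si = int(blk.obs_idx[ci])
                mc = _mean_class(self.mean_by, blk.group, blk.sexes[si], blk.slots[si])
                D[:, ci, mean_classes.index(mc)] = 1.0
                D[:, ci, len(mean_classes):] = blk.D[:, ci, 1:]
            b2 = type(blk)(
                group=blk.group,
                sexes=blk.sexes,
                slots=blk.slots,
                obs_idx=blk.obs_idx,
                Y=blk.Y,
                D=D,
                family_ids=blk.family_ids,
            )
            blocks.append(b2)
        cov_param_names = [f"logv.{c}" for c in var_classes] + [f"cov.{c}" for c in cov_classes]
        return compiled, blocks, mean_classes, var_classes, cov_classes, mean_names, cov_param_names

    def _builder(self, var_classes, cov_classes):
        nv = len(var_classes)

        def build(tc, blk, want_derivs):
            group, sexes = blk.group, blk.sexes
            vidx = [
                var_classes.index(_mean_class(self.var_by, group, sexes[si], blk.slots[si]))
                for si in range(len(sexes))
            ]
            vs = [float(np.exp(tc[i])) for i in vidx]
            lone = len(sexes) == 1
            if lone:
                sigma = np.array([[vs[0], 0.0], [0.0, 1.0]])
                cpos = None
            else:
                cc = _cov_class(self.cov_by, group, sexes)
                cpos = None if cc is None else nv + cov_classes.index(cc)
                c = 0.0 if cpos is None else float(tc[cpos])
                sigma = np.array([[vs[0], c], [c, vs[1]]])
            derivs = None
            if want_derivs:
                derivs = []
                for j in range(len(tc)):
                    d = np.zeros((2, 2))
                    for si, vi in enumerate(vidx):
                        if vi == j:
                            d[si, si] += vs[si]  # d exp(logv)/dlogv
                    if cpos is not None and j == cpos:
                        d[0, 1] = d[1, 0] = 1.0
                    derivs.append(d)
            return sigma, derivs

        return build

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None) -> "SaturatedTwinModel":
        (
            compiled,
            blocks,
            mean_classes,
            var_classes,
            cov_classes,
            mean_names,
            cov_names,
        ) = self._compile(X)
        builder = self._builder(var_classes, cov_classes)
        cov_key = lambda blk: (blk.group, blk.sexes, blk.slots)
        vals = np.concatenate([blk.Y.ravel() for blk in blocks])
        m0, v0 = float(vals.mean()), float(max(vals.var(), 1e-8))
        # class-specific moment starts (fall back to pooled moments)
        mu0 = np.full(len(mean_classes), m0)
        lv0 = np.full(len(var_classes), np.log(v0))
        cv0 = np.full(len(cov_classes), 0.3 * v0)
        acc_mu: dict = {}
        acc_var: dict = {}
        acc_cov: dict = {}
        for blk in blocks:
            for si in range(len(blk.sexes)):
                cells = [ci for ci, oi in enumerate(blk.obs_idx) if oi == si]
                if not cells:
                    continue
                y = blk.Y[:, cells[0]]
                mc = _mean_class(self.mean_by, blk.group, blk.sexes[si], blk.slots[si])
                vc = _mean_class(self.var_by, blk.group, blk.sexes[si], blk.slots[si])
                acc_mu.setdefault(mc, []).append(y)
                acc_var.setdefault(vc, []).append(y)
            if len(blk.sexes) == 2 and blk.Y.shape[1] == 2:
                cc = _cov_class(self.cov_by, blk.group, blk.sexes)
                if cc is not None:
                    acc_cov.setdefault(cc, []).append(blk.Y)
        for i, c in enumerate(mean_classes):
            if c in acc_mu:
                mu0[i] = float(np.concatenate(acc_mu[c]).mean())
        for i, c in enumerate(var_classes):
            if c in acc_var:
                lv0[i] = float(np.log(max(np.concatenate(acc_var[c]).var(), 1e-8)))
        for i, c in enumerate(cov_classes):
            if c in acc_cov:
                pairs = np.vstack(acc_cov[c])
                if len(pairs) >= 2:
                    cov = float(np.cov(pairs[:, 0], pairs[:, 1], bias=True)[0, 1])
                    cap = 0.97 * float(np.sqrt(pairs[:, 0].var() * pairs[:, 1].var()))
                    cv0[i] = float(np.clip(cov, -cap, cap)) if cap > 0 else 0.0
        x0 = np.concatenate(
            [mu0, np.zeros(len(self.covariates)), lv0, cv0]
        )
        q = len(mean_names)
        rng = np.random.default_rng(self.seed)
        best = None
        for k in range(max(1, self.n_starts)):
            xk = x0 if k == 0 else x0 + rng.normal(0, 0.1, size=x0.size) * np.maximum(
                1.0, np.abs(x0)
            ) * 0.3
            res = minimize_neg2ll(blocks, q, builder, xk, cov_key=cov_key)
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        self.param_names_ = tuple(mean_names) + tuple(cov_names)
        self.params_ = dict(zip(self.param_names_, theta))
        self.theta_ = theta
        self.minus2lnl_ = float(best.fun)
        self.n_params_ = len(theta)
        self.converged_ = bool(best.success or best.grad_norm < 1e-4)
        self.gradient_norm_ = best.grad_norm
        self.n_families_ = compiled.n_families
        self.means_ = {c: self.params_[f"mu.{c}"] for c in mean_classes}
        self.betas_ = {c: self.params_[f"beta_{c}"] for c in self.covariates}
        self.variances_ = {c: float(np.exp(self.params_[f"logv.{c}"])) for c in var_classes}
        self.covariances_ = {c: self.params_[f"cov.{c}"] for c in cov_classes}
        self._blocks = blocks
        self._builder_fn = builder
        self._cov_key = cov_key
        self._q = q
        self.correlations_ = self._correlations(blocks, var_classes, cov_classes)
        return self

    def _correlations(self, blocks, var_classes, cov_classes) -> dict:
        """Per covariance class, c / sqrt(v1 v2) using each class's member variances."""
        out = {}
        for blk in blocks:
            if len(blk.sexes) != 2:
                continue
            cc = _cov_class(self.cov_by, blk.group, blk.sexes)
            if cc is None or cc in out:
                continue
            v1 = self.variances_[_mean_class(self.var_by, blk.group, blk.sexes[0], blk.slots[0])]
            v2 = self.variances_[_mean_class(self.var_by, blk.group, blk.sexes[1], blk.slots[1])]
            r = self.covariances_[cc] / np.sqrt(v1 * v2)
            out[cc] = float(np.clip(r, -1.0, 1.0))
        return out

    def neg2ll(self, theta=None) -> float:
        theta = self.theta_ if theta is None else theta
        return neg2ll(self._blocks, self._q, self._builder_fn, theta, cov_key=self._cov_key)
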