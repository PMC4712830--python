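"""Synthetic twin cohorts with the covariance structure of the study design.

The generator runs the variance-component model forward: per family it
draws standard-normal factor scores for each source of variance —
additive genetic (shared exactly by MZ co-twins, correlated 0.5 in
DZ/sibling pairs, scaled further by the cross-sex genetic correlation
in opposite-sex pairs), shared environment (correlation 1 in all
pairs), dominance (1 / 0.25) and unique environment (independent) —
maps them through per-component (optionally sex-specific) path
matrices, applies the reciprocal sibling-contrast transform when
requested, and adds mean-model covariate effects (sex, age at the
relevant assessment).  Presets encode the cohort structure and printed
moments of the study being emulated: sub-sample sizes of ~95-101 MZ
and ~144-156 DZ pairs plus 22 sibling pairs and 149-211 singletons,
head-motion heritability 0.40, and the published phenotypic/genetic/
environmental correlations between log head motion and the SWAN
Inattention and Hyperactivity-Impulsivity scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data import TwinDataset
from .motion import RigidMotionSeries

__all__ = [
    "GeneratingConfig",
    "preset",
    "PRESET_NAMES",
    "simulate_families",
    "simulate_likert_scores",
    "simulate_motion_params",
]

_AGE_COL = {
    "hm_log": "age_scan",
    "swan_mi": "age_mother_report",
    "swan_mh": "age_mother_report",
    "swan_si": "age_self_report",
    "swan_sh": "age_self_report",
}

#: cross-member factor correlation per component and relatedness
_RHO = {"A": {"MZ": 1.0, "DZ": 0.5}, "C": {"MZ": 1.0, "DZ": 1.0}, "D": {"MZ": 1.0, "DZ": 0.25}}


@dataclass
class GeneratingConfig:
    """Full generative specification for a synthetic twin cohort.

    ``paths`` maps component letters (A, C, D, E) to p x p
    lower-triangular path matrices, or to ``{"F": L, "M": L}`` pairs for
    sex-specific structure.  ``means`` are female intercepts at the
    reference age; ``betas`` hold per-trait covariate effects
    (``sex`` as a male offset, ``age`` per year around the assessment
    mean).  ``missingness`` gives per-trait probabilities that a family
    is *observed* for the trait (sub-sample membership).
    """

    traits: tuple
    n_pairs: Mapping[str, int]
    n_singletons: int = 0
    paths: Mapping[str, object] = field(default_factory=dict)
    means: Mapping[str, float] = field(default_factory=dict)
    betas: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    contrast: Mapping[str, float] | float = 0.0
    rg_mf: float = 1.0
    missingness: Mapping[str, float] = field(default_factory=dict)
    age_scan: tuple = (22.0, 3.0, 18.0, 32.0)  # mean, sd, lo, hi
    mother_interval: tuple = (0.2, 1.2, -3.9, 3.9)  # scan-to-rating years
    self_interval: tuple = (3.1, 1.5, 0.0, 7.1)
    p_female_singleton: float = 0.63
    likert: Mapping[str, dict] | None = None
    seed: int = 0

    def __post_init__(self):
        self.traits = tuple(self.traits)
        for g, n in self.n_pairs.items():
            if n < 0:
                raise ValueError(f"negative pair count for {g}")
        for t, pr in self.missingness.items():
            if not 0.0 <= pr <= 1.0:
                raise ValueError(f"missingness probability for {t} outside [0,1]")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def path_matrix(self, component: str, sex: str) -> np.ndarray:
        entry = self.paths.get(component)
        if entry is None:
            return np.zeros((self.n_traits, self.n_traits))
        if isinstance(entry, Mapping):
            entry = entry[sex]
        return np.asarray(entry, dtype=float)

    def contrast_value(self, trait: str) -> float:
        if isinstance(self.contrast, Mapping):
            return float(self.contrast.get(trait, 0.0))
        return float(self.contrast)

    def implied_pair_covariance(self, group: str, sexes: tuple) -> np.ndarray:
        """Model-implied 2p x 2p pair covariance (before covariate effects)."""
        p = self.n_traits
        s1, s2 = sexes
        rel = "MZ" if group.startswith("MZ") else "DZ"
        within = {
            sx: sum(
                self.path_matrix(c, sx) @ self.path_matrix(c, sx).T for c in "ACDE"
            )
            for sx in ("F", "M")
        }
        cross = np.zeros((p, p))
        for c in "ACD":
            rho = _RHO[c][rel]
            if c == "A" and s1 != s2:
                rho *= self.rg_mf
            cross += rho * self.path_matrix(c, s1) @ self.path_matrix(c, s2).T
        sigma = np.block([[within[s1], cross], [cross.T, within[s2]]])
        s_vals = np.array([self.contrast_value(t) for t in self.traits])
        if np.any(s_vals != 0.0):
            B = np.zeros((2 * p, 2 * p))
            B[np.arange(p), p + np.arange(p)] = s_vals
            B[p + np.arange(p), np.arange(p)] = s_vals
            IB = np.linalg.inv(np.eye(2 * p) - B)
            sigma = IB @ sigma @ IB.T
        return sigma


# ---------------------------------------------------------------------------
# presets

#: sub-sample pair counts: (MZF, MZM, DZF, DZM, DZOS, SIB, singletons)
_MATERNAL_SIZES = dict(MZF=60, MZM=35, DZF=48, DZM=27, DZOS=69, SIB=22), 149
_SELF_SIZES = dict(MZF=62, MZM=39, DZF=50, DZM=30, DZOS=76, SIB=22), 211
_COMBINED_SIZES = dict(MZF=124, MZM=72, DZF=85, DZM=55, DZOS=116, SIB=44), 149

_HM = dict(var=0.35**2, h2=0.40, mu=-2.62, beta_sex=math.log(1.032), beta_age=math.log(0.994))
#: SWAN scale moments and male offsets; bivariate presets pair each scale
#: with log head motion using the published correlation triple (rp, rg, re).
_SWAN = {
    "swan_mi": dict(var=1.14**2, mu=-1.24, beta_sex=0.54, h2=0.72, rg=0.24, re=0.12),
    "swan_mh": dict(var=1.10**2, mu=-1.21, beta_sex=0.40, h2=0.86, rg=0.23, re=0.05),
    "swan_si": dict(var=0.59**2, mu=-0.57, beta_sex=0.17, h2=0.12, rg=0.19, re=0.07),
    "swan_sh": dict(var=0.62**2, mu=-0.57, beta_sex=0.21, h2=0.152, rg=0.40, re=0.03),
}

PRESET_NAMES = (
    "G-HM",
    "G-MI",
    "G-MH",
    "G-SI",
    "G-SH",
    "G-BIV-MI",
    "G-BIV-MH",
    "G-SEXLIM-MH",
)


def _bivariate_paths(trait: str) -> dict:
    """AE Cholesky path matrices for (hm_log, trait) from the moment targets."""
    s = _SWAN[trait]
    v = np.array([_HM["var"], s["var"]])
    h2 = np.array([_HM["h2"], s["h2"]])
    e2 = 1.0 - h2
    SA = np.array(
        [
            [h2[0] * v[0], s["rg"] * np.sqrt(h2[0] * v[0] * h2[1] * v[1])],
            [s["rg"] * np.sqrt(h2[0] * v[0] * h2[1] * v[1]), h2[1] * v[1]],
        ]
    )
    SE = np.array(
        [
            [e2[0] * v[0], s["re"] * np.sqrt(e2[0] * v[0] * e2[1] * v[1])],
            [s["re"] * np.sqrt(e2[0] * v[0] * e2[1] * v[1]), e2[1] * v[1]],
        ]
    )
    return {"A": np.linalg.cholesky(SA), "E": np.linalg.cholesky(SE)}


def _bivariate_preset(trait: str) -> GeneratingConfig:
    sizes, n_single = _MATERNAL_SIZES if trait.startswith("swan_m") else _SELF_SIZES
    s = _SWAN[trait]
    return GeneratingConfig(
        traits=("hm_log", trait),
        n_pairs=dict(sizes),
        n_singletons=n_single,
        paths=_bivariate_paths(trait),
        means={"hm_log": _HM["mu"], trait: s["mu"]},
        betas={
            "hm_log": {"sex": _HM["beta_sex"], "age": _HM["beta_age"]},
            trait: {"sex": s["beta_sex"]},
        },
    )


def preset(name: str) -> GeneratingConfig:
    """A fully specified generating configuration by name.

    * ``G-HM`` — univariate log head motion at the pooled sample size:
      AE with a2 = 0.40, total variance 0.35^2, male offset +3.2% and
      -0.6%/year age effect on the raw scale.
    * ``G-MI``/``G-MH``/``G-SI``/``G-SH`` — bivariate (log head motion,
      SWAN score) AE cohorts at the matching sub-sample sizes whose
      implied correlations reproduce the published (rp, rg, re) triple;
      ``G-BIV-MI`` and ``G-BIV-MH`` are aliases of the maternal pair.
    * ``G-SEXLIM-MH`` — univariate maternal Hyperactivity-Impulsivity
      with sex-specific structure implying female MZ/DZ pair
      covariances 0.97/0.74 and male 0.64/0.27, cross-sex genetic
      correlation 1.
    """
    if name == "G-HM":
        sizes, n_single = _COMBINED_SIZES
        v, h2 = _HM["var"], _HM["h2"]
        return GeneratingConfig(
            traits=("hm_log",),
            n_pairs=dict(sizes),
            n_singletons=n_single,
            paths={
                "A": np.array([[math.sqrt(h2 * v)]]),
                "E": np.array([[math.sqrt((1 - h2) * v)]]),
            },
            means={"hm_log": _HM["mu"]},
            betas={"hm_log": {"sex": _HM["beta_sex"], "age": _HM["beta_age"]}},
        )
    if name in ("G-MI", "G-BIV-MI"):
        return _bivariate_preset("swan_mi")
    if name in ("G-MH", "G-BIV-MH"):
        return _bivariate_preset("swan_mh")
    if name == "G-SI":
        return _bivariate_preset("swan_si")
    if name == "G-SH":
        return _bivariate_preset("swan_sh")
    if name == "G-SEXLIM-MH":
        sizes, n_single = _MATERNAL_SIZES
        # female ACE from covariances 0.97 (MZ) / 0.74 (DZ): vA = 0.46, vC = 0.51;
        # male ADE from 0.64 / 0.27: vA = 0.44, vD = 0.20; total variance 1.21 per sex
        return GeneratingConfig(
            traits=("swan_mh",),
            n_pairs=dict(sizes),
            n_singletons=n_single,
            paths={
                "A": {"F": np.array([[math.sqrt(0.46)]]), "M": np.array([[math.sqrt(0.44)]])},
                "C": {"F": np.array([[math.sqrt(0.51)]]), "M": np.array([[0.0]])},
                "D": {"F": np.array([[0.0]]), "M": np.array([[math.sqrt(0.20)]])},
                "E": {"F": np.array([[math.sqrt(0.24)]]), "M": np.array([[math.sqrt(0.57)]])},
            },
            means={"swan_mh": -1.21},
            betas={"swan_mh": {"sex": 0.40}},
            rg_mf=1.0,
        )
    raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# simulation


def _trunc_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    for _ in range(20):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def _pair_sexes(rng, group: str, p_female: float) -> tuple:
    if group in ("MZF", "DZF"):
        return ("F", "F")
    if group in ("MZM", "DZM"):
        return ("M", "M")
    if group == "DZOS":
        return ("F", "M")
    # sibling pairs: independent sexes
    return tuple(rng.choice(["F", "M"], p=[p_female, 1 - p_female]) for _ in range(2))


def _draw_pair_factors(rng, rho: float, p: int) -> tuple:
    z1 = rng.standard_normal(p)
    z2 = rho * z1 + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(p)
    return z1, z2


def simulate_families(config: GeneratingConfig, seed: int | None = None) -> TwinDataset:
    """Draw a synthetic cohort; deterministic given the seed.

    Singletons are generated as full pairs from a zygosity group sampled
    with the cohort's pair-count weights, with the co-twin then removed
    (so contrast effects propagate into lone-twin variances exactly as
    the likelihood marginalization assumes).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = config.n_traits
    traits = config.traits
    s_vals = np.array([config.contrast_value(t) for t in traits])
    IB = None
    if np.any(s_vals != 0.0):
        if np.any(np.abs(s_vals) >= 1.0):
            raise ValueError("contrast |s| must be < 1")
        B = np.zeros((2 * p, 2 * p))
        B[np.arange(p), p + np.arange(p)] = s_vals
        B[p + np.arange(p), np.arange(p)] = s_vals
        IB = np.linalg.inv(np.eye(2 * p) - B)

    groups = [g for g, n in config.n_pairs.items() for _ in range(int(n))]
    weights = np.array([max(config.n_pairs.get(g, 0), 0) for g in config.n_pairs], dtype=float)
    group_names = list(config.n_pairs)
    if config.n_singletons and weights.sum() == 0:
        raise ValueError("singletons need at least one nonzero pair-count for group weights")

    rows = []
    fam_counter = 0

    def make_family(group: str, keep: tuple = (0, 1)):
        nonlocal fam_counter
        fam_counter += 1
        fid = f"F{fam_counter:05d}"
        sexes = _pair_sexes(rng, group, config.p_female_singleton)
        rel = "MZ" if group.startswith("MZ") else "DZ"
        dev = np.zeros(2 * p)
        for comp in "ACD":
            rho = _RHO[comp][rel]
            if comp == "A" and sexes[0] != sexes[1]:
                rho *= config.rg_mf
            u1, u2 = _draw_pair_factors(rng, rho, p)
            dev[:p] += config.path_matrix(comp, sexes[0]) @ u1
            dev[p:] += config.path_matrix(comp, sexes[1]) @ u2
        dev[:p] += config.path_matrix("E", sexes[0]) @ rng.standard_normal(p)
        dev[p:] += config.path_matrix("E", sexes[1]) @ rng.standard_normal(p)
        if IB is not None:
            dev = IB @ dev

        mean_age, sd_age, lo, hi = config.age_scan
        age_scan = float(_trunc_normal(rng, mean_age, sd_age, lo, hi, 1)[0])
        ages_scan = [age_scan, age_scan]
        if group == "SIB":
            ages_scan[1] = float(np.clip(age_scan + rng.uniform(-4, 4), lo, hi))
        m_int = _trunc_normal(rng, *config.mother_interval[:2], *config.mother_interval[2:], 2)
        s_int = _trunc_normal(rng, *config.self_interval[:2], *config.self_interval[2:], 2)
        wave_mother = int(rng.choice([1, 2], p=[0.65, 0.35]))
        wave_self = int(rng.choice([1, 2, 3], p=[0.17, 0.31, 0.52]))
        design_mother = "prospective" if rng.random() < 0.65 else "retrospective"
        design_self = "retrospective" if wave_self == 1 else "prospective"
        n_sib = int(np.clip(2 + rng.poisson(1.0), 2, 7))
        observed = {
            t: rng.random() < config.missingness.get(t, 1.0) for t in traits
        }

        for slot in keep:
            vals = {}
            for ti, t in enumerate(traits):
                age_col = _AGE_COL.get(t, "age_scan")
                if age_col == "age_scan":
                    age = ages_scan[slot]
                elif age_col == "age_mother_report":
                    age = ages_scan[slot] + float(m_int[slot])
                else:
                    age = ages_scan[slot] + float(s_int[slot])
                beta = config.betas.get(t, {})
                mu = config.means.get(t, 0.0)
                mu += beta.get("sex", 0.0) * (1.0 if sexes[slot] == "M" else 0.0)
                mu += beta.get("age", 0.0) * (age - config.age_scan[0])
                mu += beta.get("n_siblings", 0.0) * (n_sib - 3.0)
                vals[t] = mu + dev[slot * p + ti] if observed[t] else np.nan
            row = {
                "family_id": fid,
                "individual_id": f"{fid}.{slot + 1}",
                "zygosity": group,
                "sex": sexes[slot],
                "birth_order": slot + 1,
                "age_scan": round(ages_scan[slot], 2),
                "age_mother_report": round(ages_scan[slot] + float(m_int[slot]), 2),
                "age_self_report": round(ages_scan[slot] + float(s_int[slot]), 2),
                "wave_mother": wave_mother,
                "wave_self": wave_self,
                "design_mother": design_mother,
                "design_self": design_self,
                "n_siblings": n_sib,
            }
            for t in ("hm_log", "swan_mi", "swan_mh", "swan_si", "swan_sh"):
                row[t] = vals.get(t, np.nan)
            for t in traits:
                row[t] = vals[t]  # custom trait names kept as extra columns
            rows.append(row)

    for g in groups:
        make_family(g)
    for _ in range(int(config.n_singletons)):
        g = str(rng.choice(group_names, p=weights / weights.sum()))
        keep = (0,) if g != "DZOS" else ((0,) if rng.random() < 0.5 else (1,))
        make_family(g, keep=keep)

    df = pd.DataFrame(rows)
    if config.likert:
        for t, spec in config.likert.items():
            df[t] = simulate_likert_scores(
                df[t].to_numpy(),
                n_items=spec.get("n_items", 9),
                levels=spec.get("levels", 7),
                thresholds=spec.get("thresholds"),
                item_noise_sd=spec.get("item_noise_sd", 1.0),
                seed=int(rng.integers(2**31 - 1)),
            )
    return TwinDataset(df)


def simulate_likert_scores(
    latent,
    n_items: int = 9,
    levels: int = 7,
    thresholds=None,
    item_noise_sd: float = 1.0,
    seed: int = 0,
):
    """Discretize latent trait values into averaged Likert item scores.

    Each item adds independent noise to the latent value and cuts it at
    the thresholds into centred codes (the middle category, "average",
    scores 0); the scale score is the item mean.  Discretization
    attenuates reliability relative to the latent value — more so for
    the 5-level (self report) than the 7-level (mother report) format.
    """
    latent = np.asarray(latent, dtype=float)
    if thresholds is None:
        half = (levels - 1) / 2.0
        thresholds = np.linspace(-half, half - 1, levels - 1) + 0.5
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (levels - 1,) or np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing with length levels-1")
    rng = np.random.default_rng(seed)
    offset = (levels - 1) / 2.0
    out = np.full(latent.shape, np.nan)
    ok = np.isfinite(latent)
    if ok.any():
        noise = rng.normal(0.0, item_noise_sd, size=(int(ok.sum()), n_items))
        codes = np.searchsorted(thresholds, latent[ok, None] + noise) - offset
        out[ok] = codes.mean(axis=1)
    return out


def simulate_motion_params(
    n_frames: int = 150,
    drift_sd: float = 0.02,
    spike_prob: float = 0.01,
    spike_scale: float = 0.3,
    seed: int = 0,
    subject_id: str = "sim",
) -> RigidMotionSeries:
    """Random-walk realignment parameters with occasional one-frame spikes.

    Translations drift with per-frame increments of ``drift_sd`` mm;
    rotations with ``drift_sd / 50`` rad.  Spiked frames add a
    transient offset of ~``spike_scale`` mm (or the equivalent small
    angle) on one random axis.  The first frame is the reference and is
    identically zero.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    inc = np.zeros((n_frames, 6))
    inc[1:, :3] = rng.normal(0.0, drift_sd, size=(n_frames - 1, 3))
    inc[1:, 3:] = rng.normal(0.0, drift_sd / 50.0, size=(n_frames - 1, 3))
    params = np.cumsum(inc, axis=0)
    spikes = rng.random(n_frames) < spike_prob
    spikes[0] = False
    for i in np.where(spikes)[0]:
        axis = int(rng.integers(6))
        scale = spike_scale if axis < 3 else spike_scale / 50.0
        params[i, axis] += scale * (1.0 + 0.2 * rng.standard_normal())
    params -= params[0]
    return RigidMotionSeries(
        subject_id=subject_id,
        translations=params[:, :3],
        rotations=params[:, 3:],
        dialect="spm",
    )
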