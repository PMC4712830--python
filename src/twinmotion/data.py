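"""Pair-structured phenotype data for twin-family likelihoods.

The canonical on-disk form is a delimited table with one row per
individual: family id, individual id, zygosity group (MZF, MZM, DZF,
DZM, DZOS, SIB), sex, birth order, assessment ages, the five phenotypes
(log head motion and four SWAN scores), and design covariates.  Missing
values are empty fields.  Sibling (SIB) pairs share the dizygotic
genetic relatedness and are pooled with DZ pairs in the model
expectations.

For likelihood evaluation the table is compiled into blocks of families
sharing a zygosity group, a member-sex configuration and a missingness
pattern; each block carries a stacked observation matrix and the mean
design tensor, so a full-information ML objective evaluates with a
handful of small linear-algebra calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ZYGOSITY_GROUPS",
    "TRAIT_COLUMNS",
    "PHENO_COLUMNS",
    "TwinDataset",
    "CompiledData",
    "compile_dataset",
    "resolve_covariate",
]

ZYGOSITY_GROUPS = ("MZF", "MZM", "DZF", "DZM", "DZOS", "SIB")
MZ_GROUPS = ("MZF", "MZM")
DZ_GROUPS = ("DZF", "DZM", "DZOS", "SIB")
TRAIT_COLUMNS = ("hm_log", "swan_mi", "swan_mh", "swan_si", "swan_sh")

PHENO_COLUMNS = (
    "family_id",
    "individual_id",
    "zygosity",
    "sex",
    "birth_order",
    "age_scan",
    "age_mother_report",
    "age_self_report",
    "hm_log",
    "swan_mi",
    "swan_mh",
    "swan_si",
    "swan_sh",
    "wave_mother",
    "wave_self",
    "design_mother",
    "design_self",
    "n_siblings",
)

# Trait-generic covariate names resolve to trait-appropriate columns.
_AGE_FOR_TRAIT = {
    "hm_log": "age_scan",
    "swan_mi": "age_mother_report",
    "swan_mh": "age_mother_report",
    "swan_si": "age_self_report",
    "swan_sh": "age_self_report",
}
_WAVE_FOR_TRAIT = {
    "swan_mi": "wave_mother",
    "swan_mh": "wave_mother",
    "swan_si": "wave_self",
    "swan_sh": "wave_self",
}
_DESIGN_FOR_TRAIT = {
    "swan_mi": "design_mother",
    "swan_mh": "design_mother",
    "swan_si": "design_self",
    "swan_sh": "design_self",
}


def resolve_covariate(name: str, trait: str) -> str:
    """Map a generic covariate name to the column used for ``trait``."""
    if name == "age":
        return _AGE_FOR_TRAIT[trait]
    if name == "wave":
        if trait not in _WAVE_FOR_TRAIT:
            raise ValueError(f"covariate 'wave' is undefined for trait {trait!r}")
        return _WAVE_FOR_TRAIT[trait]
    if name == "design":
        if trait not in _DESIGN_FOR_TRAIT:
            raise ValueError(f"covariate 'design' is undefined for trait {trait!r}")
        return _DESIGN_FOR_TRAIT[trait]
    if name == "interval":
        return f"__interval_{trait}"
    return name


class TwinDataset:
    """Phenotype table wrapper with family structure validation.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per individual, in the column dialect of
        :data:`PHENO_COLUMNS` (extra columns are kept).
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        required = {"family_id", "zygosity", "sex", "birth_order"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"phenotype table is missing columns: {sorted(missing)}")
        bad = set(df["zygosity"].dropna()) - set(ZYGOSITY_GROUPS)
        if bad:
            raise ValueError(f"unknown zygosity groups: {sorted(bad)}")
        counts = df.groupby("family_id").size()
        if (counts > 2).any():
            raise ValueError("families must have at most 2 members (one pair per family)")
        # MZ pairs same-sex; DZOS opposite-sex
        for fid, fam in df[df["family_id"].isin(counts[counts == 2].index)].groupby("family_id"):
            zyg = fam["zygosity"].iloc[0]
            sexes = set(fam["sex"])
            if zyg in MZ_GROUPS and len(sexes) != 1:
                raise ValueError(f"family {fid}: MZ pair must be same-sex")
            if zyg == "DZOS" and len(sexes) != 2:
                raise ValueError(f"family {fid}: DZOS pair must be opposite-sex")
        self.table = df

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "TwinDataset":
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        self.table.to_csv(path, sep=sep, index=False)

    @property
    def n_individuals(self) -> int:
        return len(self.table)

    @property
    def n_families(self) -> int:
        return self.table["family_id"].nunique()

    def groups_present(self, trait: str | None = None) -> list[str]:
        df = self.table
        if trait is not None:
            df = df[df[trait].notna()]
        return [g for g in ZYGOSITY_GROUPS if (df["zygosity"] == g).any()]

    def complete_pairs(self, trait: str, groups: Sequence[str]) -> np.ndarray:
        """(n, 2) array of both-observed pair values, ordered by birth order."""
        df = self.table[self.table["zygosity"].isin(groups)]
        out = []
        for _, fam in df.groupby("family_id"):
            if len(fam) != 2:
                continue
            fam = fam.sort_values("birth_order")
            vals = fam[trait].to_numpy(dtype=float)
            if np.isfinite(vals).all():
                out.append(vals)
        return np.array(out) if out else np.empty((0, 2))


@dataclass
class Block:
    """Families sharing zygosity group, member sexes and missingness pattern."""

    group: str
    sexes: tuple  # sex per member slot ('F'/'M'), length = number of members present
    slots: tuple  # original member indices (birth-order position) per slot
    obs_idx: np.ndarray  # indices into the 2p stacked (member-major) trait vector
    Y: np.ndarray  # (n, k) observations
    D: np.ndarray  # (n, k, q) mean design
    family_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def k(self) -> int:
        return self.Y.shape[1]


@dataclass
class CompiledData:
    """Likelihood-ready view of a dataset for a fixed trait/covariate choice."""

    traits: tuple
    covariates: Mapping[str, tuple]
    mean_param_names: tuple
    blocks: list
    centers: Mapping[str, float]
    n_families: int
    n_observations: int  # total observed phenotype cells

    @property
    def n_mean_params(self) -> int:
        return len(self.mean_param_names)


def _covariate_value(row: pd.Series, column: str, trait: str, centers: dict) -> float:
    if column == "sex":
        return 1.0 if row["sex"] == "M" else 0.0
    if column.startswith("__interval_"):
        age_col = _AGE_FOR_TRAIT[trait]
        v = row.get(age_col, np.nan) - row.get("age_scan", np.nan)
    elif column.startswith("design"):
        v = {"prospective": 0.0, "retrospective": 1.0}.get(row.get(column), np.nan)
        return 0.0 if not np.isfinite(v) else v
    else:
        v = row.get(column, np.nan)
    center = centers.get(column, 0.0)
    if not np.isfinite(v):
        return 0.0  # mean-imputed after centering
    return float(v - center)


def _normalize_covariates(
    traits: Sequence[str], covariates: Sequence[str] | Mapping[str, Sequence[str]] | None
) -> dict:
    if covariates is None:
        return {t: () for t in traits}
    if isinstance(covariates, Mapping):
        return {t: tuple(covariates.get(t, ())) for t in traits}
    return {t: tuple(covariates) for t in traits}


def compile_dataset(
    dataset: TwinDataset | pd.DataFrame,
    traits: Sequence[str],
    covariates: Sequence[str] | Mapping[str, Sequence[str]] | None = None,
) -> CompiledData:
    """Group families into likelihood blocks for the given traits.

    Continuous covariates (ages, intervals, wave, number of siblings) are
    centred at their sample mean; binary codes (sex: M=1, design:
    retrospective=1) are left on their natural 0/1 scale so coefficients
    read as raw offsets.  Missing covariate values are imputed at the
    centre.
    """
    if isinstance(dataset, pd.DataFrame):
        dataset = TwinDataset(dataset)
    df = dataset.table
    traits = tuple(traits)
    for t in traits:
        if t not in df.columns:
            raise ValueError(f"trait column {t!r} not in table")
    cov_map = {
        t: tuple(resolve_covariate(c, t) for c in cols)
        for t, cols in _normalize_covariates(traits, covariates).items()
    }

    # centres for continuous covariates
    centers: dict[str, float] = {}
    for t in traits:
        for col in cov_map[t]:
            if col in ("sex",) or col.startswith("design") or col in centers:
                continue
            if col.startswith("__interval_"):
                vals = df[_AGE_FOR_TRAIT[t]] - df["age_scan"]
            else:
                if col not in df.columns:
                    raise ValueError(f"covariate column {col!r} not in table")
                vals = df[col]
            vals = pd.to_numeric(vals, errors="coerce")
            centers[col] = float(vals.mean()) if vals.notna().any() else 0.0

    # mean parameter layout: per trait, intercept then covariates
    mean_names: list[str] = []
    offsets: dict[str, int] = {}
    for t in traits:
        offsets[t] = len(mean_names)
        mean_names.append(f"mu_{t}")
        mean_names.extend(f"beta_{c}_{t}" for c in cov_map[t])
    q = len(mean_names)
    p = len(traits)

    raw: dict[tuple, list] = {}
    n_fam = 0
    n_obs = 0
    for fid, fam in df.groupby("family_id", sort=True):
        fam = fam.sort_values("birth_order")
        if len(fam) == 2 and fam["zygosity"].iloc[0] == "DZOS":
            # fixed member convention: female first in opposite-sex pairs
            fam = fam.sort_values("sex")  # F < M
        members = [fam.iloc[i] for i in range(len(fam))]
        group = members[0]["zygosity"]
        obs_cells = []
        for mi, row in enumerate(members):
            for ti, t in enumerate(traits):
                if np.isfinite(row.get(t, np.nan)):
                    obs_cells.append((mi, ti))
        if not obs_cells:
            continue
        present_members = sorted({mi for mi, _ in obs_cells})
        # re-index members so slots are contiguous (a pair with one fully
        # missing member is a singleton observation)
        slot_of = {mi: si for si, mi in enumerate(present_members)}
        sexes = tuple(members[mi]["sex"] for mi in present_members)
        slots = tuple(present_members)
        obs_idx = tuple(slot_of[mi] * p + ti for mi, ti in obs_cells)
        yrow = [float(members[mi][traits[ti]]) for mi, ti in obs_cells]
        drow = np.zeros((len(obs_cells), q))
        for ci, (mi, ti) in enumerate(obs_cells):
            t = traits[ti]
            drow[ci, offsets[t]] = 1.0
            for cj, col in enumerate(cov_map[t]):
                drow[ci, offsets[t] + 1 + cj] = _covariate_value(members[mi], col, t, centers)
        key = (group, sexes, slots, obs_idx)
        raw.setdefault(key, []).append((yrow, drow, fid))
        n_fam += 1
        n_obs += len(obs_cells)

    blocks = []
    for (group, sexes, slots, obs_idx), rows in sorted(raw.items()):
        Y = np.array([r[0] for r in rows])
        D = np.stack([r[1] for r in rows])
        blocks.append(
            Block(
                group=group,
                sexes=sexes,
                slots=slots,
                obs_idx=np.array(obs_idx, dtype=int),
                Y=Y,
                D=D,
                family_ids=[r[2] for r in rows],
            )
        )
    if not blocks:
        raise ValueError("no family has any observed phenotype among the requested traits")
    return CompiledData(
        traits=traits,
        covariates=cov_map,
        mean_param_names=tuple(mean_names),
        blocks=blocks,
        centers=centers,
        n_families=n_fam,
        n_observations=n_obs,
    )
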