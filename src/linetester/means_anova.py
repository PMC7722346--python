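"""Genotype means, ANOVA, variance components, repeatability and CV.

The ANOVA is the classical balanced sequential decomposition over
environment, replicate-within-environment, incomplete block, genotype and
genotype x environment.  Variance components come from the expected-mean-
squares method of moments, which coincides with REML for the balanced
complete layouts the synthetic generator produces; negative estimates are
truncated to zero with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import TrialDataset, TrialValidationError

__all__ = [
    "MeansTable",
    "AnovaTable",
    "VarianceComponents",
    "UnbalancedDataError",
    "ls_means",
    "anova",
    "variance_components",
    "repeatability",
    "cv_percent",
    "trait_correlations",
    "genotype_trait_means",
]

LEVELS = ("per_environment", "per_condition", "across")


class UnbalancedDataError(TrialValidationError):
    """Raised when a balanced-only estimator is fed unbalanced data."""


@dataclass
class MeansTable:
    """Genotype x environment (or x condition) least-squares means for one trait.

    ``frame`` is indexed by genotype with one column per environment,
    condition or the single column ``across``; ``n`` holds the plot count
    behind each cell (0 marks a structurally missing cell, stored as NaN).
    """

    trait: str
    level: str
    frame: pd.DataFrame
    n: pd.DataFrame

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise TrialValidationError(f"unknown means level {self.level!r}")
        present = self.frame.notna()
        if (self.n.reindex_like(self.frame)[present] < 1).any().any():
            raise TrialValidationError("non-missing mean cell with n < 1")

    def to_frame(self) -> pd.DataFrame:
        long = self.frame.stack(future_stack=True).rename("mean").reset_index()
        long.columns = ["genotype", "group", "mean"]
        counts = self.n.stack(future_stack=True).rename("n").reset_index()
        counts.columns = ["genotype", "group", "n"]
        out = long.merge(counts, on=["genotype", "group"])
        out.insert(0, "trait", self.trait)
        out.insert(1, "level", self.level)
        return out


@dataclass
class AnovaTable:
    """Sequential ANOVA rows for one trait at one scope."""

    trait: str
    scope: str
    frame: pd.DataFrame  # columns: source, df, ss, mean_square, f_value, p_value
    grand_mean: float
    n_obs: int

    def _row(self, source: str) -> pd.Series:
        hit = self.frame[self.frame["source"] == source]
        if hit.empty:
            raise KeyError(f"ANOVA table has no source row {source!r}")
        return hit.iloc[0]

    def mean_square(self, source: str) -> float:
        return float(self._row(source)["mean_square"])

    def df(self, source: str) -> int:
        return int(self._row(source)["df"])

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(0, "trait", self.trait)
        out.insert(1, "scope", self.scope)
        return out


@dataclass
class VarianceComponents:
    """Method-of-moments components on the genotype basis."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_error: float
    r: int
    e: int
    method: str = "ems_mom"
    truncated: list = field(default_factory=list)


def _group_column(level: str) -> str:
    return {"per_environment": "environment", "per_condition": "condition"}.get(level, "across")


def _is_orthogonal(df: pd.DataFrame) -> bool:
    """True when every genotype occurs equally often in every nuisance cell."""
    counts = df.pivot_table(
        index="genotype", columns=["environment", "replicate", "block"],
        values="_y", aggfunc="size", fill_value=0,
    )
    return np.unique(counts.to_numpy()).size <= 1


def _ls_fit_group(df: pd.DataFrame) -> pd.Series:
    """Least-squares genotype means from an additive fixed-effect description.

    Full one-hot coding of environment, replicate-within-environment,
    block-within-replicate and genotype, solved by minimum-norm lstsq; the
    genotype LS mean is the estimable contrast averaging every nuisance
    factor over its levels.
    """
    y = df["_y"].to_numpy(float)
    factors = {}
    if df["environment"].nunique() > 1:
        factors["env"] = df["environment"].astype(str)
    factors["rep"] = df["environment"].astype(str) + "/" + df["replicate"].astype(str)
    if df["block"].nunique() > 1 or df.groupby(["environment", "replicate"])["block"].nunique().max() > 1:
        factors["blk"] = factors["rep"] + "/" + df["block"].astype(str)
    factors["geno"] = df["genotype"].astype(str)

    cols = [np.ones((len(df), 1))]
    level_index: dict[str, list] = {}
    for name, fac in factors.items():
        dummies = pd.get_dummies(fac)
        level_index[name] = list(dummies.columns)
        cols.append(dummies.to_numpy(float))
    X = np.hstack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    genos = level_index["geno"]
    means = {}
    for gi, g in enumerate(genos):
        c = [1.0]
        for name in factors:
            k = len(level_index[name])
            if name == "geno":
                w = np.zeros(k)
                w[gi] = 1.0
            else:
                w = np.full(k, 1.0 / k)
            c.append(w)
        means[g] = float(np.concatenate([[v] if np.isscalar(v) else v for v in c]) @ beta)
    return pd.Series(means)


def ls_means(data: TrialDataset, trait: str, level: str = "per_condition") -> MeansTable:
    """Genotype means at the requested level, complete-case per trait.

    Equals the arithmetic cell mean whenever genotypes are orthogonal to the
    nuisance factors (balanced case); otherwise an additive least-squares
    adjustment is applied.  A genotype absent from a group is flagged as a
    missing cell, never fabricated.
    """
    if level not in LEVELS:
        raise TrialValidationError(f"unknown means level {level!r}")
    if trait not in data.data.columns:
        raise KeyError(f"trait {trait!r} not in dataset")
    df = data.data[data.data[trait].notna()].copy()
    if df.empty:
        raise TrialValidationError(f"no non-missing observations for trait {trait!r}")
    df["_y"] = df[trait].astype(float)
    gcol = _group_column(level)
    if gcol == "across":
        df["_grp"] = "across"
    else:
        df["_grp"] = df[gcol]

    all_genos = sorted(data.data["genotype"].unique())
    groups = sorted(df["_grp"].unique())
    frame = pd.DataFrame(index=pd.Index(all_genos, name="genotype"), columns=groups, dtype=float)
    nmat = pd.DataFrame(0, index=frame.index, columns=groups, dtype=int)
    for g, sub in df.groupby("_grp"):
        counts = sub.groupby("genotype").size()
        if _is_orthogonal(sub):
            m = sub.groupby("genotype")["_y"].mean()
        else:
            m = _ls_fit_group(sub)
        frame.loc[m.index, g] = m
        nmat.loc[counts.index, g] = counts
    return MeansTable(trait=trait, level=level, frame=frame, n=nmat)


def _closed_form_ss(arr: np.ndarray) -> dict[str, tuple[int, float]]:
    """Sequential SS for a complete genotype x environment x replicate array."""
    g, e, r = arr.shape
    grand = arr.mean()
    env_m = arr.mean(axis=(0, 2))
    rep_m = arr.mean(axis=0)              # e x r
    gen_m = arr.mean(axis=(1, 2))
    ge_m = arr.mean(axis=2)               # g x e
    out = {}
    out["E"] = (e - 1, float(g * r * ((env_m - grand) ** 2).sum()))
    out["Rep(E)"] = (e * (r - 1), float(g * ((rep_m - env_m[:, None]) ** 2).sum()))
    out["G"] = (g - 1, float(r * e * ((gen_m - grand) ** 2).sum()))
    out["GxE"] = (
        (g - 1) * (e - 1),
        float(r * ((ge_m - gen_m[:, None] - env_m[None, :] + grand) ** 2).sum()),
    )
    total = float(((arr - grand) ** 2).sum())
    used = sum(v[1] for v in out.values())
    out["Error"] = ((g * e * r - 1) - sum(v[0] for v in out.values()), total - used)
    return out


def _sequential_qr_ss(df: pd.DataFrame) -> dict[str, tuple[int, float]]:
    """Sequential SS by incremental QR projection, order E, Rep(E), Block, G, GxE."""
    y = df["_y"].to_numpy(float)
    n = len(y)
    terms = [
        ("E", df["environment"].astype(str)),
        ("Rep(E)", df["environment"].astype(str) + "/" + df["replicate"].astype(str)),
        ("Block(ExRep)", df["environment"].astype(str) + "/" + df["replicate"].astype(str)
         + "/" + df["block"].astype(str)),
        ("G", df["genotype"].astype(str)),
        ("GxE", df["genotype"].astype(str) + "@" + df["environment"].astype(str)),
    ]
    Q = np.ones((n, 1)) / np.sqrt(n)
    yres = y - Q @ (Q.T @ y)
    out = {}
    for name, fac in terms:
        X = pd.get_dummies(fac).to_numpy(float)
        X = X - Q @ (Q.T @ X)
        # SVD basis: safe for the rank-deficient dummy blocks nested coding produces
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        keep = s > 1e-9 * max(1.0, s.max(initial=0.0))
        qx = u[:, keep]
        ss = float(((qx.T @ y) ** 2).sum())
        out[name] = (int(keep.sum()), ss)
        Q = np.hstack([Q, qx])
        yres = yres - qx @ (qx.T @ yres)
    df_err = n - Q.shape[1]
    out["Error"] = (df_err, float((yres ** 2).sum()))
    if out["Block(ExRep)"][0] == 0:
        del out["Block(ExRep)"]
    return out


def anova(data: TrialDataset, trait: str, scope: str = "across") -> AnovaTable:
    """Sequential ANOVA over the E / Rep(E) / Block / G / GxE / Error sources.

    Requires a balanced complete layout; unbalanced data are refused with a
    pointer to the ls_means-based stage-wise analysis.  F for genotype uses
    the GxE mean square as denominator (random-environment convention);
    every other tested source uses the error mean square.
    """
    if scope not in ("drought", "rainfed", "across"):
        raise TrialValidationError(f"unknown anova scope {scope!r}")
    df = data.data if scope == "across" else data.data[data.data["condition"] == scope]
    df = df[df[trait].notna()].copy()
    if df.empty:
        raise TrialValidationError(f"no observations for trait {trait!r} at scope {scope!r}")
    df["_y"] = df[trait].astype(float)

    genos = df["genotype"].nunique()
    envs = df["environment"].nunique()
    reps = df["replicate"].nunique()
    if genos < 2:
        raise TrialValidationError("anova needs at least 2 genotypes")
    if envs < 2:
        raise TrialValidationError("anova needs at least 2 environments")
    cells = df.groupby(["genotype", "environment", "replicate"]).size()
    if len(cells) != genos * envs * reps or cells.nunique() != 1:
        raise UnbalancedDataError(
            "unbalanced data: closed-form ANOVA refused; use ls_means for a "
            "stage-wise analysis of adjusted means"
        )

    trivial_blocks = df.groupby(["environment", "replicate"])["block"].nunique().max() == 1
    if trivial_blocks and cells.iloc[0] == 1:
        arr = (
            df.set_index(["genotype", "environment", "replicate"])["_y"]
            .sort_index()
            .to_numpy()
            .reshape(genos, envs, reps)
        )
        ss = _closed_form_ss(arr)
    else:
        ss = _sequential_qr_ss(df)

    ms_error = ss["Error"][1] / ss["Error"][0] if ss["Error"][0] > 0 else np.nan
    rows = []
    order = ["E", "Rep(E)", "Block(ExRep)", "G", "GxE", "Error"]
    for source in order:
        if source not in ss:
            continue
        d, s = ss[source]
        if d < 1:
            continue
        ms = s / d
        if source == "Error":
            f = p = np.nan
        else:
            denom_ms, denom_df = (
                (ss["GxE"][1] / ss["GxE"][0], ss["GxE"][0]) if source == "G"
                else (ms_error, ss["Error"][0])
            )
            f = ms / denom_ms if denom_ms > 0 else np.nan
            p = float(stats.f.sf(f, d, denom_df)) if np.isfinite(f) else np.nan
        rows.append({"source": source, "df": d, "ss": s, "mean_square": ms,
                     "f_value": f, "p_value": p})
    frame = pd.DataFrame(rows)
    return AnovaTable(trait=trait, scope=scope, frame=frame,
                      grand_mean=float(df["_y"].mean()), n_obs=len(df))


def variance_components(anova_table: AnovaTable, r: int, e: int) -> VarianceComponents:
    """EMS method-of-moments solve of the G / GxE / Error mean squares.

    sigma2_error = MS_Error; sigma2_ge = (MS_GxE - MS_Error) / r;
    sigma2_g = (MS_G - MS_GxE) / (r * e).  Negative solutions are truncated
    to zero and recorded.
    """
    for needed in ("G", "GxE", "Error"):
        if needed not in set(anova_table.frame["source"]):
            raise TrialValidationError(f"ANOVA table is missing the {needed!r} source row")
    ms_err = anova_table.mean_square("Error")
    ms_ge = anova_table.mean_square("GxE")
    ms_g = anova_table.mean_square("G")
    truncated = []
    s2_ge = (ms_ge - ms_err) / r
    s2_g = (ms_g - ms_ge) / (r * e)
    if s2_ge < 0:
        truncated.append("sigma2_ge")
        s2_ge = 0.0
    if s2_g < 0:
        truncated.append("sigma2_g")
        s2_g = 0.0
    if truncated:
        warnings.warn(f"variance components truncated to zero: {truncated}")
    return VarianceComponents(sigma2_g=float(s2_g), sigma2_ge=float(s2_ge),
                              sigma2_error=float(ms_err), r=r, e=e,
                              truncated=truncated)


def repeatability(vc: VarianceComponents) -> float:
    """Hybrid-mean-basis repeatability R = s2g / (s2g + s2ge/e + s2/(r e))."""
    if vc.r < 1 or vc.e < 1:
        raise TrialValidationError("repeatability needs r >= 1 and e >= 1")
    if vc.sigma2_g == 0:
        return 0.0
    denom = vc.sigma2_g + vc.sigma2_ge / vc.e + vc.sigma2_error / (vc.r * vc.e)
    return float(vc.sigma2_g / denom)


def cv_percent(anova_table: AnovaTable, grand_mean: float) -> float:
    """Coefficient of variation, 100 * sqrt(MS_Error) / grand mean."""
    if grand_mean <= 0:
        raise TrialValidationError("cv_percent needs a positive grand mean")
    return float(100.0 * np.sqrt(anova_table.mean_square("Error")) / grand_mean)


def genotype_trait_means(data: TrialDataset, traits: list[str], condition: str) -> pd.DataFrame:
    """Genotype x trait matrix of per-condition means (one condition)."""
    cols = {}
    for t in traits:
        m = ls_means(data, t, level="per_condition")
        if condition not in m.frame.columns:
            continue
        cols[t] = m.frame[condition]
    return pd.DataFrame(cols)


def trait_correlations(means: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlations between traits on genotype means.

    Zero-variance traits yield NaN off-diagonal cells and a warning; the
    diagonal is exactly 1 for any trait with at least one finite value.
    """
    frame = means[traits] if traits is not None else means
    if frame.shape[0] < 3:
        raise TrialValidationError("trait correlations need at least 3 genotypes")
    corr = frame.corr(method="pearson")
    degenerate = [c for c in frame.columns if frame[c].std(ddof=1) == 0]
    if degenerate:
        warnings.warn(f"zero-variance trait(s), correlations undefined: {degenerate}")
        for c in degenerate:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr
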