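"""Line x tester partition: GCA/SCA effects, mean squares, Baker proportion.

Effects follow the marginal-mean definitions: a parent's GCA is its
testcross marginal mean minus the grand mean, and SCA is the cell residual
after removing both marginals.  On a balanced grid every effect vector sums
to zero and SCA rows and columns sum to zero.  Incomplete grids are
estimated by two-way least squares with sum-to-zero constraints and
flagged; the Table-style mean squares then refuse to run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .means_anova import MeansTable, UnbalancedDataError, ls_means
from .core import TrialDataset, TrialValidationError

__all__ = [
    "CombiningAbilityResult",
    "lt_grid",
    "gca_effects",
    "sca_effects",
    "ca_mean_squares",
    "baker_proportion",
    "effect_standard_errors",
    "effect_significance",
    "combining_ability",
]


@dataclass
class CombiningAbilityResult:
    trait: str
    condition: str
    gca_line: pd.DataFrame    # index line, columns effect/se/p/stars
    gca_tester: pd.DataFrame
    sca: pd.DataFrame         # long: line, tester, effect, se, p, stars
    mean_squares: dict[str, tuple[int, float]]
    baker: float | None
    method: str = "marginal"  # or "ls" for incomplete grids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for line, rec in self.gca_line.iterrows():
            rows.append(("line", line, "", rec["effect"], rec["se"], rec["p"], rec["stars"]))
        for tester, rec in self.gca_tester.iterrows():
            rows.append(("tester", tester, "", rec["effect"], rec["se"], rec["p"], rec["stars"]))
        for _, rec in self.sca.iterrows():
            rows.append(("sca", rec["line"], rec["tester"], rec["effect"], rec["se"],
                         rec["p"], rec["stars"]))
        out = pd.DataFrame(rows, columns=["role", "parent", "tester", "effect", "se", "p", "stars"])
        out.insert(0, "trait", self.trait)
        out.insert(1, "condition", self.condition)
        return out

    def mean_squares_frame(self) -> pd.DataFrame:
        rows = [
            {"trait": self.trait, "condition": self.condition, "source": k,
             "df": v[0], "mean_square": v[1]}
            for k, v in self.mean_squares.items()
        ]
        rows.append({"trait": self.trait, "condition": self.condition,
                     "source": "baker_proportion", "df": 0,
                     "mean_square": np.nan if self.baker is None else self.baker})
        return pd.DataFrame(rows)


def lt_grid(means: MeansTable, hybrids: pd.DataFrame, group: str) -> pd.DataFrame:
    """Pivot a MeansTable column into a line x tester grid via the hybrid map."""
    if group not in means.frame.columns:
        raise TrialValidationError(f"means table has no column {group!r}")
    merged = hybrids.assign(mean=means.frame.loc[hybrids["genotype"], group].to_numpy())
    return merged.pivot(index="line", columns="tester", values="mean").sort_index()


def _check_complete(grid: pd.DataFrame) -> None:
    if grid.isna().any().any():
        missing = [
            (line, tester)
            for line in grid.index for tester in grid.columns
            if pd.isna(grid.loc[line, tester])
        ]
        raise UnbalancedDataError(
            f"incomplete line x tester grid; missing pairs: {missing}"
        )


def gca_effects(grid: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Line and tester GCA effects from a complete line x tester means grid.

    line effect = line marginal mean - grand mean (and likewise for
    testers); each vector sums to zero by construction.
    """
    _check_complete(grid)
    grand = grid.to_numpy().mean()
    line_eff = grid.mean(axis=1) - grand
    tester_eff = grid.mean(axis=0) - grand
    return line_eff, tester_eff


def sca_effects(grid: pd.DataFrame) -> pd.DataFrame:
    """SCA matrix: cell mean - line mean - tester mean + grand mean."""
    _check_complete(grid)
    arr = grid.to_numpy()
    grand = arr.mean()
    resid = arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0, keepdims=True) + grand
    return pd.DataFrame(resid, index=grid.index, columns=grid.columns)


def gca_sca_ls(grid: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Two-way least-squares effects for an incomplete grid (flagged "ls").

    Fits mean + line + tester with sum-to-zero constraints on the observed
    cells; SCA is the cell residual (zero-sum identities hold only in the
    balanced case).
    """
    obs = grid.stack(future_stack=True).dropna()
    lines = list(grid.index)
    testers = list(grid.columns)
    n = len(obs)
    X = np.zeros((n + 2, 1 + len(lines) + len(testers)))
    y = np.concatenate([obs.to_numpy(float), [0.0, 0.0]])
    for k, (line, tester) in enumerate(obs.index):
        X[k, 0] = 1.0
        X[k, 1 + lines.index(line)] = 1.0
        X[k, 1 + len(lines) + testers.index(tester)] = 1.0
    big = max(1.0, np.abs(obs).max()) * n
    X[n, 1:1 + len(lines)] = big
    X[n + 1, 1 + len(lines):] = big
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    line_eff = pd.Series(beta[1:1 + len(lines)], index=lines)
    tester_eff = pd.Series(beta[1 + len(lines):], index=testers)
    fitted = beta[0] + np.add.outer(line_eff.to_numpy(), tester_eff.to_numpy())
    sca = grid - fitted
    return line_eff, tester_eff, sca


def ca_mean_squares(data: TrialDataset, trait: str, condition: str) -> dict[str, tuple[int, float]]:
    """Mean squares of the hybrid partition from balanced plot-level data.

    Sources: E, REP(E), GCA_LINE, GCA_TESTER, SCA, ExGCA_LINE, ExGCA_TESTER,
    ExSCA, ERROR with the usual balanced degrees of freedom.  The line,
    tester and line x tester sums of squares add up to the hybrid SS.
    """
    sub = data.subset(condition)
    df = sub.data[sub.data[trait].notna()].copy()
    df = df[df["line"].notna() & df["tester"].notna()]
    lines = sorted(df["line"].unique())
    testers = sorted(df["tester"].unique())
    envs = sorted(df["environment"].unique())
    reps = sorted(df["replicate"].unique())
    l, t, e, r = len(lines), len(testers), len(envs), len(reps)
    if l < 2 or t < 2:
        raise TrialValidationError("line x tester partition needs >= 2 lines and >= 2 testers")
    cells = df.groupby(["line", "tester", "environment", "replicate"]).size()
    if len(cells) != l * t * e * r or cells.nunique() != 1 or cells.iloc[0] != 1:
        raise UnbalancedDataError(
            "unbalanced plot data: line x tester mean squares refused"
        )
    arr = (
        df.set_index(["line", "tester", "environment", "replicate"])[trait]
        .sort_index()
        .to_numpy(float)
        .reshape(l, t, e, r)
    )
    grand = arr.mean()
    m_l = arr.mean(axis=(1, 2, 3))
    m_t = arr.mean(axis=(0, 2, 3))
    m_e = arr.mean(axis=(0, 1, 3))
    m_lt = arr.mean(axis=(2, 3))
    m_le = arr.mean(axis=(1, 3))
    m_te = arr.mean(axis=(0, 3))
    m_lte = arr.mean(axis=3)
    m_er = arr.mean(axis=(0, 1))

    out: dict[str, tuple[int, float]] = {}

    def put(name: str, dof: int, ss: float) -> None:
        out[name] = (dof, ss / dof if dof > 0 else np.nan)

    put("E", e - 1, float(l * t * r * ((m_e - grand) ** 2).sum()))
    put("REP(E)", e * (r - 1), float(l * t * ((m_er - m_e[:, None]) ** 2).sum()))
    put("GCA_LINE", l - 1, float(t * e * r * ((m_l - grand) ** 2).sum()))
    put("GCA_TESTER", t - 1, float(l * e * r * ((m_t - grand) ** 2).sum()))
    put("SCA", (l - 1) * (t - 1), float(
        e * r * ((m_lt - m_l[:, None] - m_t[None, :] + grand) ** 2).sum()))
    put("ExGCA_LINE", (l - 1) * (e - 1), float(
        t * r * ((m_le - m_l[:, None] - m_e[None, :] + grand) ** 2).sum()))
    put("ExGCA_TESTER", (t - 1) * (e - 1), float(
        l * r * ((m_te - m_t[:, None] - m_e[None, :] + grand) ** 2).sum()))
    int3 = (m_lte - m_lt[:, :, None] - m_le[:, None, :] - m_te[None, :, :]
            + m_l[:, None, None] + m_t[None, :, None] + m_e[None, None, :] - grand)
    put("ExSCA", (l - 1) * (t - 1) * (e - 1), float(r * (int3 ** 2).sum()))
    total = float(((arr - grand) ** 2).sum())
    used_ss = sum(d * m for d, m in out.values())
    used_df = sum(d for d, _ in out.values())
    err_df = l * t * e * r - 1 - used_df
    put("ERROR", err_df, total - used_ss)
    return out


def baker_proportion(
    ms: dict[str, tuple[int, float]],
    l: int, t: int, r: int, e: int,
    method: str = "component_based",
) -> float | None:
    """Relative weight of general over specific combining ability.

    ``component_based`` (the default) solves variance components from the
    expected mean squares, subtracting the corresponding environment
    interaction mean square before scaling, then forms
    2*s2_gca / (2*s2_gca + s2_sca) with s2_gca pooled over lines and
    testers.  ``plain`` subtracts the error mean square instead (no
    interaction correction).  Negative components are truncated to zero and
    the result is clamped to [0, 1]; all-zero components give None.
    """
    if method not in ("component_based", "plain"):
        raise TrialValidationError(f"unknown baker method {method!r}")
    for k in ("GCA_LINE", "GCA_TESTER", "SCA"):
        if k not in ms:
            raise TrialValidationError(f"mean squares missing source {k!r}")
    if method == "component_based":
        sub_l = ms.get("ExGCA_LINE", ms["ERROR"])[1]
        sub_t = ms.get("ExGCA_TESTER", ms["ERROR"])[1]
        sub_s = ms.get("ExSCA", ms["ERROR"])[1]
    else:
        sub_l = sub_t = sub_s = ms["ERROR"][1]
    v_line = max(0.0, (ms["GCA_LINE"][1] - sub_l) / (r * e * t))
    v_tester = max(0.0, (ms["GCA_TESTER"][1] - sub_t) / (r * e * l))
    v_sca = max(0.0, (ms["SCA"][1] - sub_s) / (r * e))
    denom = v_line + v_tester + v_sca
    if denom == 0:
        return None
    return float(min(1.0, max(0.0, (v_line + v_tester) / denom)))


def effect_standard_errors(ms_error: float, l: int, t: int, r: int, e: int) -> dict[str, float]:
    """Standard errors of the balanced line x tester effect estimators.

    Var(line GCA) = s2 (l-1)/(l t r e), Var(tester GCA) = s2 (t-1)/(l t r e),
    Var(SCA) = s2 (l-1)(t-1)/(l t r e), with s2 the error mean square.
    """
    n = l * t * r * e
    return {
        "line": float(np.sqrt(ms_error * (l - 1) / n)),
        "tester": float(np.sqrt(ms_error * (t - 1) / n)),
        "sca": float(np.sqrt(ms_error * (l - 1) * (t - 1) / n)),
    }


def effect_significance(effects: pd.Series | np.ndarray, se: float, error_df: int) -> pd.DataFrame:
    """Two-sided t-test of effect / SE on the error degrees of freedom."""
    if se <= 0:
        raise TrialValidationError("effect_significance needs se > 0")
    if error_df < 1:
        raise TrialValidationError("effect_significance needs error_df >= 1")
    eff = pd.Series(effects, dtype=float)
    tval = eff / se
    p = 2.0 * stats.t.sf(np.abs(tval), error_df)
    stars = np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))
    return pd.DataFrame({"effect": eff, "se": se, "p": p, "stars": stars}, index=eff.index)


def combining_ability(
    data: TrialDataset, trait: str, condition: str,
    baker_method: str = "component_based",
) -> CombiningAbilityResult:
    """Full combining-ability analysis of one trait under one condition."""
    sub = data.subset(condition)
    means = ls_means(sub, trait, level="per_condition")
    grid = lt_grid(means, sub.hybrids, condition)

    l, t = grid.shape
    e = sub.data["environment"].nunique()
    r = sub.data["replicate"].nunique()

    try:
        line_eff, tester_eff = gca_effects(grid)
        sca = sca_effects(grid)
        method = "marginal"
    except UnbalancedDataError:
        line_eff, tester_eff, sca = gca_sca_ls(grid)
        method = "ls"

    try:
        ms = ca_mean_squares(data, trait, condition)
        err_df, ms_error = ms["ERROR"]
        baker = baker_proportion(ms, l=l, t=t, r=r, e=e, method=baker_method)
    except UnbalancedDataError:
        ms = {}
        baker = None
        resid = data.subset(condition).data[trait].astype(float)
        ms_error = float(resid.var(ddof=1))
        err_df = max(1, len(resid) - l * t)

    ses = effect_standard_errors(ms_error, l=l, t=t, r=r, e=e)
    gl = effect_significance(line_eff, ses["line"], err_df)
    gt = effect_significance(tester_eff, ses["tester"], err_df)
    sca_long = sca.stack(future_stack=True).rename("effect").reset_index()
    sca_long.columns = ["line", "tester", "effect"]
    sig = effect_significance(sca_long["effect"], ses["sca"], err_df)
    sca_long[["se", "p", "stars"]] = sig[["se", "p", "stars"]].to_numpy()

    return CombiningAbilityResult(
        trait=trait, condition=condition, gca_line=gl, gca_tester=gt,
        sca=sca_long, mean_squares=ms, baker=baker, method=method,
    )
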