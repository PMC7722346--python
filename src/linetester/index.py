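"""Standardized multi-trait base index for drought tolerance ranking.

I = 2*z(yield) + z(epp) - z(asi) - z(pasp) - z(easp) - z(sgc), each trait
standardized to mean 0 and unit standard deviation over the indexed
population.  Higher I is better; the stay-green term applies only under
drought because the score is recorded only on stressed plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TrialValidationError

__all__ = ["IndexTable", "standardize", "base_index", "select_extremes", "INDEX_WEIGHTS"]

#: trait -> weight in the index, in application order
INDEX_WEIGHTS = {
    "yield": 2.0,
    "epp": 1.0,
    "asi": -1.0,
    "pasp": -1.0,
    "easp": -1.0,
    "sgc": -1.0,  # drought only
}


@dataclass
class IndexTable:
    condition: str
    frame: pd.DataFrame  # index genotype; z_<trait> columns, index, rank, selected

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.reset_index()
        out.insert(0, "condition", self.condition)
        return out


def standardize(values: pd.Series | np.ndarray, name: str = "trait") -> pd.Series:
    """z = (x - mean) / sd with the sample (n-1) standard deviation."""
    x = pd.Series(values, dtype=float)
    if x.notna().sum() < 2:
        raise TrialValidationError(f"standardize needs >= 2 values for {name!r}")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise TrialValidationError(f"trait {name!r} has zero spread; cannot standardize")
    return (x - x.mean()) / sd


def base_index(means: pd.DataFrame, condition: str) -> IndexTable:
    """Index every genotype in *means* (genotype x trait matrix of raw means).

    The standardization population is all rows supplied, so include checks
    if they were part of the trial.  Under rainfed the stay-green term is
    omitted.
    """
    weights = dict(INDEX_WEIGHTS)
    if condition != "drought":
        weights.pop("sgc")
    missing = [t for t in weights if t not in means.columns]
    if missing:
        raise TrialValidationError(
            f"base index for {condition!r} needs trait column(s) {missing}"
        )
    z = pd.DataFrame({t: standardize(means[t], t) for t in weights}, index=means.index)
    idx = sum(w * z[t] for t, w in weights.items())
    frame = z.add_prefix("z_")
    frame["index"] = idx
    order = frame.sort_values(["index", "z_yield"], ascending=False, kind="mergesort")
    # deterministic tie-break: index desc, then yield z desc, then genotype id
    order = order.loc[
        sorted(order.index, key=lambda g: (-order.loc[g, "index"], -order.loc[g, "z_yield"], g))
    ]
    frame["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    frame["selected"] = "none"
    return IndexTable(condition=condition, frame=frame)


def select_extremes(table: IndexTable, n_best: int = 26, n_worst: int = 9) -> IndexTable:
    """Flag the top n_best genotypes as best and the bottom n_worst as worst."""
    n = len(table.frame)
    if n_best + n_worst > n:
        raise TrialValidationError(
            f"cannot select {n_best}+{n_worst} from {n} genotypes without overlap"
        )
    frame = table.frame.copy()
    frame["selected"] = "none"
    ranked = frame.sort_values("rank")
    if n_best:
        frame.loc[ranked.index[:n_best], "selected"] = "best"
    if n_worst:
        frame.loc[ranked.index[-n_worst:], "selected"] = "worst"
    return IndexTable(condition=table.condition, frame=frame)
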