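"""Domain types, validation and tabular I/O for line x tester trials.

The canonical on-disk layout is long ("tidy") comma-separated text: one row
per plot, one column per trait.  Required columns are ``environment``,
``condition``, ``replicate``, ``block`` and ``genotype``; ``line``,
``tester`` and ``role`` are optional (hybrids carry both parents, checks
carry neither).  Missing trait cells are empty and stay missing -- no
statistic in this package imputes them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "Genotype",
    "Design",
    "TrialDataset",
    "TrialValidationError",
    "default_traits",
    "hybrid_id",
    "read_trial",
    "write_table",
    "read_table",
]

CONDITIONS = ("drought", "rainfed")

#: columns every plot-level file must carry, in canonical order
REQUIRED_COLUMNS = ("environment", "condition", "replicate", "block", "genotype")
OPTIONAL_COLUMNS = ("line", "tester", "role")


class TrialValidationError(ValueError):
    """Raised when an input file or dataset violates a structural invariant."""


@dataclass(frozen=True)
class TraitSpec:
    """Description of one measured trait.

    ``direction`` states which way is agronomically better and is carried as
    metadata (the base index encodes its own signs).  Ordinal traits must
    have integer bounds; scores are kept inside them on read and on write.
    ``drought_only`` marks traits recorded only under moisture stress.
    """

    name: str
    units: str = ""
    direction: str = "higher_better"
    bounds: tuple[float, float] | None = None
    scale: str = "continuous"
    drought_only: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "lower_better"):
            raise TrialValidationError(
                f"trait {self.name!r}: unknown direction {self.direction!r}"
            )
        if self.scale not in ("continuous", "ordinal"):
            raise TrialValidationError(
                f"trait {self.name!r}: unknown scale {self.scale!r}"
            )
        if self.scale == "ordinal":
            if self.bounds is None:
                raise TrialValidationError(
                    f"ordinal trait {self.name!r} requires bounds"
                )
            lo, hi = self.bounds
            if lo != int(lo) or hi != int(hi):
                raise TrialValidationError(
                    f"ordinal trait {self.name!r} requires integer bounds, got {self.bounds}"
                )
        if self.bounds is not None and self.bounds[0] >= self.bounds[1]:
            raise TrialValidationError(
                f"trait {self.name!r}: bounds must satisfy lo < hi"
            )


def default_traits() -> list[TraitSpec]:
    """Trait panel of a drought testcross trial.

    Grain yield in kg/ha; flowering dates in days; anthesis-silking interval
    (asi) is the silking-anthesis difference and may be negative; aspect
    scores run 1-5, the stay-green score 1-9 (recorded under drought only).
    """
    return [
        TraitSpec("yield", units="kg/ha", direction="higher_better"),
        TraitSpec("da", units="days", direction="lower_better"),
        TraitSpec("ds", units="days", direction="lower_better"),
        TraitSpec("asi", units="days", direction="lower_better"),
        TraitSpec("epp", units="count", direction="higher_better"),
        TraitSpec("pasp", direction="lower_better", bounds=(1, 5), scale="ordinal"),
        TraitSpec("easp", direction="lower_better", bounds=(1, 5), scale="ordinal"),
        TraitSpec(
            "sgc", direction="lower_better", bounds=(1, 9), scale="ordinal",
            drought_only=True,
        ),
    ]


def hybrid_id(line: str, tester: str) -> str:
    """Canonical genotype id of a line x tester cross (female x male order)."""
    return f"{line}x{tester}"


@dataclass(frozen=True)
class Genotype:
    """An entry in the trial: either a line x tester hybrid or a check."""

    id: str
    role: str = "hybrid"
    line: str | None = None
    tester: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("hybrid", "check"):
            raise TrialValidationError(f"genotype {self.id!r}: unknown role {self.role!r}")
        if self.role == "hybrid" and not (self.line and self.tester):
            raise TrialValidationError(
                f"hybrid {self.id!r} must name both line and tester"
            )
        if self.role == "check" and (self.line or self.tester):
            raise TrialValidationError(
                f"check {self.id!r} must not name line or tester"
            )


@dataclass(frozen=True)
class Design:
    """Nominal factor counts: l lines, t testers, r reps, e environments per condition."""

    l: int
    t: int
    r: int
    e: int


@dataclass
class TrialDataset:
    """Validated plot-level observations plus trait metadata.

    ``data`` is a long-format frame with the required columns, optional
    ``line``/``tester``/``role`` columns and one float column per trait.
    """

    data: pd.DataFrame
    traits: list[TraitSpec]
    design: Design

    def __post_init__(self) -> None:
        _validate_frame(self.data, self.traits)

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.traits]

    def trait(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(f"unknown trait {name!r}")

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["environment"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    def subset(self, condition: str) -> "TrialDataset":
        sub = self.data[self.data["condition"] == condition].reset_index(drop=True)
        if sub.empty:
            raise TrialValidationError(f"no observations for condition {condition!r}")
        return TrialDataset(sub, self.traits, self.design)

    @property
    def hybrids(self) -> pd.DataFrame:
        """One row per hybrid entry with line and tester columns."""
        d = self.data
        if "line" in d.columns:
            h = d.loc[d["line"].notna() & d["tester"].notna(),
                      ["genotype", "line", "tester"]].drop_duplicates()
            return h.sort_values("genotype").reset_index(drop=True)
        return pd.DataFrame(columns=["genotype", "line", "tester"])

    @property
    def is_balanced(self) -> bool:
        """True when every line x tester x environment x replicate cell is present.

        Balance governs which estimators are allowed: the closed-form ANOVA
        and combining-ability partitions refuse unbalanced data.
        """
        h = self.hybrids
        if h.empty:
            return False
        d = self.data.merge(h, on=["genotype", "line", "tester"])
        cells = d.groupby(["line", "tester", "environment", "replicate"]).size()
        lines = h["line"].nunique()
        testers = h["tester"].nunique()
        n_env = d.groupby("environment").ngroups
        n_rep = d["replicate"].nunique()
        expected = lines * testers * n_env * n_rep
        return len(cells) == expected and (cells >= 1).all() and len(h) == lines * testers


def _validate_frame(df: pd.DataFrame, traits: Sequence[TraitSpec]) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrialValidationError(f"missing required column {col!r}")
    known = {t.name for t in traits}
    extra = [
        c for c in df.columns
        if c not in REQUIRED_COLUMNS and c not in OPTIONAL_COLUMNS and c not in known
    ]
    if extra:
        raise TrialValidationError(f"unknown trait column(s): {extra}")
    # bounds: validated with the originating row number (1-based, after header)
    for t in traits:
        if t.name not in df.columns or t.bounds is None:
            continue
        vals = pd.to_numeric(df[t.name], errors="coerce")
        bad = vals.notna() & ((vals < t.bounds[0]) | (vals > t.bounds[1]))
        if bad.any():
            row = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
            raise TrialValidationError(
                f"trait {t.name!r} out of bounds {t.bounds} at file row {row}"
            )
    dup = df.duplicated(subset=["environment", "replicate", "genotype"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise TrialValidationError(
            f"duplicate (environment, replicate, genotype) at file row {row}"
        )
    if not df["condition"].isin(CONDITIONS).all():
        bad = sorted(set(df["condition"]) - set(CONDITIONS))
        raise TrialValidationError(f"unknown condition label(s): {bad}")


def _infer_design(df: pd.DataFrame) -> Design:
    if "line" in df.columns:
        l = df["line"].dropna().nunique()
        t = df["tester"].dropna().nunique()
    else:
        l = t = 0
    r = int(df["replicate"].max()) if len(df) else 0
    e = int(df.groupby("condition")["environment"].nunique().max()) if len(df) else 0
    return Design(l=l, t=t, r=r, e=e)


def read_trial(path: str | Path, trait_config: Sequence[TraitSpec] | None = None) -> TrialDataset:
    """Read and validate a long-format trial file.

    Rejects unknown trait columns, out-of-bounds ordinal scores (naming the
    offending row) and duplicated (environment, replicate, genotype) plots.
    Missing trait cells are kept as NaN, never imputed.
    """
    traits = list(trait_config) if trait_config is not None else default_traits()
    df = pd.read_csv(path, dtype={"genotype": str})
    for col in ("line", "tester", "role"):
        if col in df.columns:
            df[col] = df[col].replace("", np.nan)
    for t in traits:
        if t.name in df.columns:
            df[t.name] = pd.to_numeric(df[t.name], errors="coerce")
    df["replicate"] = df["replicate"].astype(int)
    df["block"] = df["block"].astype(int)
    traits = [t for t in traits if t.name in df.columns]
    return TrialDataset(df.reset_index(drop=True), traits, _infer_design(df))


def write_table(result, path: str | Path) -> None:
    """Write any pipeline tabular result as delimited text with a stable column order.

    Accepts a plain DataFrame or any object exposing ``to_frame()``.
    Floats are written at full precision so that read(write(x)) round-trips
    to at least 12 significant digits.
    """
    frame = result if isinstance(result, pd.DataFrame) else result.to_frame()
    frame.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic reader for tables produced by :func:`write_table`."""
    return pd.read_csv(path)
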