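"""Tester-defined heterotic grouping from SCA effects and testcross means.

A line joins the group of a tester with which it shows a significant
NEGATIVE SCA effect, provided it also has a significant positive SCA with
at least one other tester and its testcross mean with some significant-
positive tester clears that tester's grand mean by at least one standard
error.  Lines with no significant SCA in either direction stay
unclassified.  With several qualifying negative testers the most negative
wins and the trace carries an ambiguity note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TrialValidationError

__all__ = [
    "TestcrossTable",
    "HeterosisAssignment",
    "load_testcross_table",
    "classify_lines",
    "group_summary",
    "pad_with_ns_lines",
]

SIG_LEVELS = {"ns": 1.0, "p05": 0.05, "p01": 0.01}


@dataclass
class TestcrossTable:
    """Line x tester testcross means, SCA effects and significance flags.

    ``frame`` is long with columns line, tester, mean_yield, sca, sig
    (ns/p05/p01).  ``tester_grand_mean`` and ``se_mean`` are per-tester;
    ``sca_source`` records whether the flags were computed by this package
    or digitized from a published table.
    """

    frame: pd.DataFrame
    tester_grand_mean: pd.Series
    se_mean: pd.Series
    sca_source: str = "computed"

    def __post_init__(self) -> None:
        needed = {"line", "tester", "mean_yield", "sca", "sig"}
        if not needed.issubset(self.frame.columns):
            raise TrialValidationError(f"testcross table needs columns {sorted(needed)}")
        bad = set(self.frame["sig"]) - set(SIG_LEVELS)
        if bad:
            raise TrialValidationError(f"unknown significance flag(s): {sorted(bad)}")
        if (self.se_mean <= 0).any():
            raise TrialValidationError("per-tester standard errors must be positive")
        if self.frame[["line", "tester"]].duplicated().any():
            raise TrialValidationError("duplicate (line, tester) rows in testcross table")

    @property
    def lines(self) -> list[str]:
        return sorted(self.frame["line"].unique())

    @property
    def testers(self) -> list[str]:
        return sorted(self.frame["tester"].unique())

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["tester_grand_mean"] = out["tester"].map(self.tester_grand_mean)
        out["se_mean"] = out["tester"].map(self.se_mean)
        return out


@dataclass
class HeterosisAssignment:
    """line -> (group or 'unclassified', rule trace)."""

    groups: dict[str, str]
    traces: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"line": line, "group": grp, "trace": self.traces.get(line, "")}
            for line, grp in sorted(self.groups.items())
        ]
        return pd.DataFrame(rows, columns=["line", "group", "trace"])


def load_testcross_table(path: str | Path | None = None) -> TestcrossTable:
    """Load a testcross table file (defaults to the packaged digitized fixture)."""
    if path is None:
        ref = resources.files("linetester.fixtures") / "table7_testcrosses.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
        source = "digitized"
    else:
        df = pd.read_csv(path)
        source = "digitized" if "tester_grand_mean" in df.columns else "computed"
    if "tester_grand_mean" in df.columns:
        grand = df.groupby("tester")["tester_grand_mean"].first()
        se = df.groupby("tester")["se_mean"].first()
    else:
        grand = df.groupby("tester")["mean_yield"].mean()
        n = df.groupby("tester")["mean_yield"].size()
        se = df.groupby("tester")["mean_yield"].std(ddof=1) / np.sqrt(n)
    keep = ["line", "tester", "mean_yield", "sca", "sig"]
    return TestcrossTable(frame=df[keep].copy(), tester_grand_mean=grand,
                          se_mean=se, sca_source=source)


def _significant(sig: str, alpha: float) -> bool:
    return SIG_LEVELS[sig] <= alpha + 1e-12


def classify_lines(tc: TestcrossTable, alpha: float = 0.05) -> HeterosisAssignment:
    """Apply the grouping rule to every line.

    Classified lines go to the group of the significant-negative tester
    (most negative wins when several qualify, with an ambiguity note); the
    trace records the negative tester, the positive tester and the yield
    threshold comparison.  Lines missing a tester cell have that tester
    excluded from the rule, which is logged in the trace.
    """
    groups: dict[str, str] = {}
    traces: dict[str, str] = {}
    for line, sub in tc.frame.groupby("line"):
        sub = sub.set_index("tester")
        excluded = [t for t in tc.testers if t not in sub.index]
        notes = [f"tester(s) {excluded} missing, excluded"] if excluded else []

        neg = sub[(sub["sca"] < 0) & sub["sig"].map(lambda s: _significant(s, alpha))]
        pos = sub[(sub["sca"] > 0) & sub["sig"].map(lambda s: _significant(s, alpha))]
        if neg.empty or pos.empty:
            reason = []
            if neg.empty:
                reason.append("no significant negative SCA")
            if pos.empty:
                reason.append("no significant positive SCA")
            groups[line] = "unclassified"
            traces[line] = "; ".join(reason + notes)
            continue

        # yield gate: testcross with one of the significant-positive testers
        # must clear that tester's grand mean by >= 1 SE
        passing = [
            t for t in pos.index
            if sub.loc[t, "mean_yield"]
            >= tc.tester_grand_mean[t] + tc.se_mean[t]
        ]
        if not passing:
            groups[line] = "unclassified"
            detail = ", ".join(
                f"{t}: {sub.loc[t, 'mean_yield']:.0f} < "
                f"{tc.tester_grand_mean[t]:.0f}+{tc.se_mean[t]:.0f}"
                for t in pos.index
            )
            traces[line] = f"yield gate failed ({detail})" + ("; " + "; ".join(notes) if notes else "")
            continue

        target = neg["sca"].idxmin()
        trace = (
            f"negative SCA with {target} ({neg.loc[target, 'sca']:.0f}, {neg.loc[target, 'sig']}); "
            f"positive SCA with {passing[0]} ({sub.loc[passing[0], 'sca']:.0f}, "
            f"{sub.loc[passing[0], 'sig']}); yield {sub.loc[passing[0], 'mean_yield']:.0f} >= "
            f"{tc.tester_grand_mean[passing[0]]:.0f} + {tc.se_mean[passing[0]]:.0f}"
        )
        if len(neg) > 1:
            trace += f"; ambiguous: {len(neg)} significant negative testers, most negative chosen"
        groups[line] = target
        traces[line] = trace + ("; " + "; ".join(notes) if notes else "")
    return HeterosisAssignment(groups=groups, traces=traces)


def group_summary(assign: HeterosisAssignment) -> pd.Series:
    """Counts per heterotic group plus the unclassified remainder."""
    counts: dict[str, int] = {}
    for grp in assign.groups.values():
        counts[grp] = counts.get(grp, 0) + 1
    counts.setdefault("unclassified", 0)
    return pd.Series(counts).sort_index()


def pad_with_ns_lines(tc: TestcrossTable, n_extra: int, prefix: str = "UNLISTED") -> TestcrossTable:
    """Add lines with all-ns zero SCA (stand-ins for lines a table omits)."""
    rows = []
    for i in range(n_extra):
        for t in tc.testers:
            rows.append({"line": f"{prefix}{i + 1:02d}", "tester": t,
                         "mean_yield": tc.tester_grand_mean[t], "sca": 0.0, "sig": "ns"})
    frame = pd.concat([tc.frame, pd.DataFrame(rows)], ignore_index=True)
    return TestcrossTable(frame=frame, tester_grand_mean=tc.tester_grand_mean,
                          se_mean=tc.se_mean, sca_source=tc.sca_source)
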