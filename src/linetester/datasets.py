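"""Packaged digitized fixtures.

Two small delimited-text tables ship with the package: a means-level trial
(per-condition entry means for 35 entries, one replicate, one block) and a
line x tester testcross table with SCA effects and printed significance
flags.  Decimal separators were normalized at digitization time.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .core import TraitSpec, TrialDataset, default_traits, read_trial
from .heterotic import TestcrossTable, load_testcross_table

__all__ = ["load_means_fixture", "load_testcross_table", "fixture_path"]


def fixture_path(name: str) -> Path:
    ref = resources.files("linetester.fixtures") / name
    with resources.as_file(ref) as p:
        return Path(p)


def load_means_fixture() -> TrialDataset:
    """Means-level trial fixture (r=1, block=1, one environment per condition).

    Carries the published per-entry drought index values in a
    ``base_index`` column alongside the measured traits; these are
    population-standardized values and are kept for ordering checks only.
    """
    traits = default_traits() + [TraitSpec("base_index", direction="higher_better")]
    return read_trial(fixture_path("table2_means.csv"), trait_config=traits)
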