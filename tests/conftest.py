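from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from linetester.core import Design, TraitSpec, TrialDataset
from linetester.simulate import GeneratorConfig


def build_dataset(values: dict, traits: list[TraitSpec] | None = None) -> TrialDataset:
    """Build a TrialDataset from {(env, cond, rep, line, tester): {trait: value}}."""
    rows = []
    for (env, cond, rep, line, tester), tv in values.items():
        row = {
            "environment": env, "condition": cond, "replicate": rep, "block": 1,
            "genotype": f"{line}x{tester}", "line": line, "tester": tester,
            "role": "hybrid",
        }
        row.update(tv)
        rows.append(row)
    df = pd.DataFrame(rows)
    traits = traits or [TraitSpec("yield", units="kg/ha")]
    lines = df["line"].nunique()
    testers = df["tester"].nunique()
    return TrialDataset(df, traits, Design(
        l=lines, t=testers, r=int(df["replicate"].max()),
        e=int(df.groupby("condition")["environment"].nunique().max()),
    ))


def balanced_dataset(arr: np.ndarray, lines=None, testers=None, envs=None,
                     condition: str = "drought") -> TrialDataset:
    """Dataset from an l x t x e x r array of yield values."""
    l, t, e, r = arr.shape
    lines = lines or [f"L{i+1}" for i in range(l)]
    testers = testers or [f"T{j+1}" for j in range(t)]
    envs = envs or [f"E{k+1}" for k in range(e)]
    values = {}
    for i, j, k, m in itertools.product(range(l), range(t), range(e), range(r)):
        values[(envs[k], condition, m + 1, lines[i], testers[j])] = {
            "yield": float(arr[i, j, k, m])
        }
    return build_dataset(values)


def yield_only_config(**kw) -> GeneratorConfig:
    """Single-trait generator config, drought condition only, zero mean."""
    defaults = dict(
        conditions=("drought",),
        traits=[TraitSpec("yield", units="kg/ha")],
        mu={"yield": 0.0},
        drought_yield_ratio=1.0,
        vc={"yield": {}},
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


def genotype_level_config(s2_g: float, s2_ge: float, s2_err: float,
                          l=40, t=3, r=2, e=3, seed=0) -> GeneratorConfig:
    """Config whose genotype-level components equal the requested values.

    All genetic variance is routed through the SCA and SCA x E families and
    rescaled so the genotype main effect and genotype x environment
    interaction, measured with their one-way ANOVA degrees of freedom,
    have nominal variances s2_g and s2_ge.
    """
    n = l * t
    sca = s2_g * (n - 1) / ((l - 1) * (t - 1))
    sca_env = s2_ge * (n - 1) / ((l - 1) * (t - 1))
    return yield_only_config(
        l=l, t=t, r=r, e=e, seed=seed,
        vc={"yield": {"sca": sca, "sca_env": sca_env, "error": s2_err}},
    )


@pytest.fixture
def toy_grid() -> pd.DataFrame:
    """2x2 line x tester means grid with known effects."""
    return pd.DataFrame([[10.0, 14.0], [6.0, 10.0]],
                        index=["L1", "L2"], columns=["T1", "T2"])
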