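"""End-to-end orchestration: data -> means -> ANOVA -> combining ability ->
base index -> heterotic groups -> GGE geometry, with a text report.

Every stage failure is either fatal (reported with the stage name) or, for
stages that legitimately cannot run on a given dataset (ANOVA on r=1
means-level data, GGE with missing cells), logged as a refusal and skipped.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import means_anova as manova
from . import combining as mcomb
from . import gge as mgge
from . import heterotic as mhet
from . import index as mindex
from .core import TrialDataset, TrialValidationError, read_trial, write_table
from .simulate import GeneratorConfig, generate_trial

log = logging.getLogger("linetester")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "percent_superiority",
    "yield_extremes",
]


@dataclass
class PipelineConfig:
    input: str | None = None
    generator: GeneratorConfig | None = None
    traits: list[str] = field(default_factory=lambda: ["yield"])
    alpha: float = 0.05
    n_best: int = 26
    n_worst: int = 9
    svp_mode: str = "genotype_focused"
    outdir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input is None) == (self.generator is None):
            raise TrialValidationError(
                "exactly one of input path / generator config must be set"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(generator=GeneratorConfig(**gen) if gen is not None else None, **raw)
        return cfg


def percent_superiority(a: float, b: float, denominator: str = "a") -> float:
    """100 * (a - b) / denominator-selected value.

    The default denominator is the candidate mean itself (a); pass
    ``denominator="b"`` for the reference-based convention.
    """
    if denominator not in ("a", "b"):
        raise TrialValidationError("denominator must be 'a' or 'b'")
    denom = a if denominator == "a" else b
    if denom <= 0:
        raise TrialValidationError("percent_superiority needs a positive denominator value")
    return float(100.0 * (a - b) / denom)


def yield_extremes(data: TrialDataset, trait: str = "yield") -> pd.DataFrame:
    """Lowest and highest hybrid per-condition mean, in kg/ha and t/ha."""
    rows = []
    for cond in data.conditions:
        sub = data.subset(cond)
        means = manova.ls_means(sub, trait, level="per_condition").frame[cond]
        hybrids = set(sub.hybrids["genotype"])
        means = means[means.index.isin(hybrids)].dropna()
        for which, geno in (("min", means.idxmin()), ("max", means.idxmax())):
            val = float(means.loc[geno])
            rows.append({"condition": cond, "which": which, "genotype": geno,
                         "mean_kg_ha": val, "mean_t_ha": round(val / 1000.0, 2)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write the output bundle; returns written paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    report: list[str] = []

    def emit(name: str, obj) -> None:
        path = outdir / name
        write_table(obj, path)
        written[name.split(".")[0]] = path

    # --- stage: data -----------------------------------------------------
    try:
        if config.input is not None:
            data = read_trial(config.input)
        else:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            data, truth = generate_trial(gen)
            emit("truth.csv", truth)
    except Exception as err:  # noqa: BLE001 - stage attribution
        raise TrialValidationError(f"stage 'data' failed: {err}") from err
    report.append(f"observations: {len(data.data)}  conditions: {data.conditions}")
    report.append(f"balanced design: {data.is_balanced}")

    extremes = yield_extremes(data)
    report.append("yield extremes (per-condition hybrid means):")
    for _, row in extremes.iterrows():
        report.append(
            f"  {row['condition']:8s} {row['which']}: {row['genotype']} "
            f"{row['mean_kg_ha']:.0f} kg/ha ({row['mean_t_ha']:.2f} t/ha)"
        )
    emit("extremes.csv", extremes)

    # --- stage: means ----------------------------------------------------
    means_frames = []
    per_cond_means: dict[tuple[str, str], manova.MeansTable] = {}
    for trait in config.traits:
        for cond in data.conditions:
            try:
                m = manova.ls_means(data.subset(cond), trait, level="per_condition")
            except TrialValidationError as err:
                log.info("means refused for %s/%s: %s", trait, cond, err)
                continue
            per_cond_means[(trait, cond)] = m
            means_frames.append(m.to_frame().assign(condition=cond))
    if not means_frames:
        raise TrialValidationError("stage 'means' failed: no computable trait means")
    emit("means.csv", pd.concat(means_frames, ignore_index=True))

    # --- stage: anova + variance components ------------------------------
    anova_frames, vc_rows = [], []
    for trait in config.traits:
        for scope in list(data.conditions) + (["across"] if len(data.conditions) > 1 else []):
            try:
                at = manova.anova(data, trait, scope=scope)
            except TrialValidationError as err:
                log.info("anova refused for %s/%s: %s", trait, scope, err)
                report.append(f"anova refused for {trait}/{scope}: {err}")
                continue
            anova_frames.append(at.to_frame())
            sub = data.data if scope == "across" else data.data[data.data["condition"] == scope]
            e = sub["environment"].nunique()
            r = sub["replicate"].nunique()
            try:
                vc = manova.variance_components(at, r=r, e=e)
            except TrialValidationError as err:
                log.info("variance components refused for %s/%s: %s", trait, scope, err)
                report.append(f"variance components refused for {trait}/{scope}: {err}")
                continue
            rep = manova.repeatability(vc)
            cv = manova.cv_percent(at, at.grand_mean)
            vc_rows.append({"trait": trait, "scope": scope, "sigma2_g": vc.sigma2_g,
                            "sigma2_ge": vc.sigma2_ge, "sigma2_error": vc.sigma2_error,
                            "repeatability": rep, "cv_percent": cv,
                            "truncated": ";".join(vc.truncated)})
            report.append(f"{trait}/{scope}: repeatability={rep:.3f} cv={cv:.2f}%")
    if anova_frames:
        emit("anova.csv", pd.concat(anova_frames, ignore_index=True))
        emit("varcomp.csv", pd.DataFrame(vc_rows))

    # --- stage: combining ability ----------------------------------------
    ca_frames, ms_frames = [], []
    ca_results: dict[tuple[str, str], mcomb.CombiningAbilityResult] = {}
    if not data.hybrids.empty and data.hybrids["line"].nunique() >= 2:
        for trait in config.traits:
            for cond in data.conditions:
                try:
                    res = mcomb.combining_ability(data, trait, cond)
                except TrialValidationError as err:
                    log.info("combining refused for %s/%s: %s", trait, cond, err)
                    report.append(f"combining refused for {trait}/{cond}: {err}")
                    continue
                ca_results[(trait, cond)] = res
                ca_frames.append(res.to_frame())
                ms_frames.append(res.mean_squares_frame())
                if res.baker is not None:
                    report.append(f"{trait}/{cond}: GCA/(GCA+SCA) proportion = {res.baker:.2f}")
    if ca_frames:
        emit("gca_sca.csv", pd.concat(ca_frames, ignore_index=True))
        emit("ca_anova.csv", pd.concat(ms_frames, ignore_index=True))

    # --- stage: base index ------------------------------------------------
    index_frames = {}
    for cond in data.conditions:
        needed = [t for t in mindex.INDEX_WEIGHTS if cond == "drought" or t != "sgc"]
        try:
            mat = manova.genotype_trait_means(data, needed, cond).dropna()
            table = mindex.base_index(mat, cond)
            table = mindex.select_extremes(
                table, min(config.n_best, max(0, len(mat) - config.n_worst)), config.n_worst
            )
        except (TrialValidationError, KeyError) as err:
            log.info("index refused for %s: %s", cond, err)
            report.append(f"index refused for {cond}: {err}")
            continue
        index_frames[cond] = table
    if index_frames:
        emit("index.csv", pd.concat([t.to_frame() for t in index_frames.values()],
                                    ignore_index=True).sort_values(
                                        ["condition", "index"], ascending=[True, False]))

    # --- stage: heterotic classification ----------------------------------
    if ("yield", "drought") in ca_results:
        res = ca_results[("yield", "drought")]
        means = per_cond_means.get(("yield", "drought"))
        grid = mcomb.lt_grid(means, data.subset("drought").hybrids, "drought")
        frame = res.sca.rename(columns={"effect": "sca"}).copy()
        frame["mean_yield"] = [
            grid.loc[line, tester] for line, tester in zip(frame["line"], frame["tester"])
        ]
        frame["sig"] = np.where(frame["p"] < 0.01, "p01",
                                np.where(frame["p"] < 0.05, "p05", "ns"))
        grand = grid.mean(axis=0)
        n_lines = grid.shape[0]
        se = grid.std(axis=0, ddof=1) / np.sqrt(n_lines)
        tc = mhet.TestcrossTable(
            frame=frame[["line", "tester", "mean_yield", "sca", "sig"]],
            tester_grand_mean=grand, se_mean=se, sca_source="computed",
        )
        assign = mhet.classify_lines(tc, alpha=config.alpha)
        emit("groups.csv", assign)
        counts = mhet.group_summary(assign)
        report.append("heterotic groups: " + ", ".join(f"{k}={v}" for k, v in counts.items()))

    # --- stage: GGE -------------------------------------------------------
    try:
        per_env = manova.ls_means(data, "yield", level="per_environment")
        selected = None
        if "drought" in index_frames:
            flagged = index_frames["drought"].frame
            selected = flagged.index[flagged["selected"] != "none"]
        frame = per_env.frame if selected is None else per_env.frame.loc[selected]
        frame = frame.dropna()
        sub_means = manova.MeansTable(trait="yield", level="per_environment",
                                      frame=frame, n=per_env.n.loc[frame.index])
        model = mgge.fit_gge(sub_means, n_axes=2)
        gframe, eframe = mgge.svp_scores(model, config.svp_mode)
        scores = pd.concat([
            gframe.assign(role="genotype").rename_axis("id").reset_index(),
            eframe.assign(role="environment").rename_axis("id").reset_index(),
        ], ignore_index=True)
        emit("gge_scores.csv", scores)
        geometry = mgge.which_won_where(model)
        emit("gge_sectors.csv", geometry.sectors)
        aec = mgge.aec_stability(model)
        emit("gge_aec.csv", aec.rename_axis("genotype").reset_index())
        report.append(
            "gge: PC1+PC2 variance explained = "
            f"{model.var_explained.sum() * 100:.1f}%"
        )
        report.append("gge winners: " + ", ".join(
            f"{env}->{win}" for env, win in geometry.winners.items()))
    except TrialValidationError as err:
        log.info("gge refused: %s", err)
        report.append(f"gge refused: {err}")

    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    written["report"] = outdir / "report.txt"
    return written
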