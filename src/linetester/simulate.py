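"""Synthetic multi-environment line x tester trial generator with known truth.

Every random effect family (environment, replicate, block, line GCA, tester
GCA, SCA, the genotype-by-environment interactions and plot error) is drawn
i.i.d. Gaussian on a latent scale, correlated across traits, then centered
onto the constraint surface the estimators assume (main effects sum to
zero; interaction families are centered over the genotype axes within
each environment, so their environment-means stay random as the EMS
estimators assume).  With that centering the realized variance of each
family, taken with the matching degrees of freedom as divisor, is an
unbiased draw of the nominal component, so recovery tests can target
either the nominal or the realized truth.

Gaussianity on the latent scale is an assumption of this generator, not a
property the analysis requires; ordinal scores are produced by rounding and
clipping the latent values into their bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .means_anova import MeansTable
from .core import Design, TraitSpec, TrialDataset, TrialValidationError, default_traits, hybrid_id

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "TruthEntry",
    "generate_trial",
    "make_rank2_means",
    "default_variance_components",
    "default_trait_correlation",
]

#: effect families and the axes they live on (l=line, t=tester, e=env)
VC_KEYS = (
    "gca_line", "gca_tester", "sca",
    "gca_line_env", "gca_tester_env", "sca_env",
    "env", "rep", "block", "error",
)


def default_variance_components() -> dict[str, dict[str, float]]:
    """Plausible per-trait components for a drought testcross trial (yield in kg/ha)."""
    vc = {
        "yield": dict(gca_line=40_000, gca_tester=25_000, sca=30_000,
                      gca_line_env=15_000, sca_env=15_000,
                      env=90_000, rep=5_000, block=2_000, error=140_000),
        "da": dict(gca_line=1.0, gca_tester=0.5, sca=0.5, gca_line_env=0.3,
                   sca_env=0.3, env=4.0, rep=0.2, block=0.1, error=2.0),
        "ds": dict(gca_line=1.5, gca_tester=0.8, sca=0.8, gca_line_env=0.5,
                   sca_env=0.5, env=4.0, rep=0.2, block=0.1, error=3.0),
        "epp": dict(gca_line=0.004, gca_tester=0.002, sca=0.003, gca_line_env=0.002,
                    sca_env=0.002, env=0.01, rep=0.001, block=0.0005, error=0.02),
        "pasp": dict(gca_line=0.05, gca_tester=0.03, sca=0.04, gca_line_env=0.02,
                     sca_env=0.02, env=0.1, rep=0.01, block=0.005, error=0.15),
        "easp": dict(gca_line=0.05, gca_tester=0.03, sca=0.04, gca_line_env=0.02,
                     sca_env=0.02, env=0.1, rep=0.01, block=0.005, error=0.15),
        "sgc": dict(gca_line=0.10, gca_tester=0.05, sca=0.07, gca_line_env=0.04,
                    sca_env=0.04, env=0.3, rep=0.02, block=0.01, error=0.4),
    }
    for trait in vc.values():
        for key in VC_KEYS:
            trait.setdefault(key, 0.0)
    return vc


def default_trait_correlation(traits: list[str]) -> np.ndarray:
    """Latent-scale correlation among generated traits.

    Signs follow the familiar drought-trial pattern: yield moves with ears
    per plant and against late/poor phenology scores.
    """
    base = {
        ("yield", "da"): -0.45, ("yield", "ds"): -0.55, ("yield", "epp"): 0.60,
        ("yield", "pasp"): -0.65, ("yield", "easp"): -0.65, ("yield", "sgc"): -0.45,
        ("da", "ds"): 0.85, ("da", "epp"): -0.40, ("da", "pasp"): 0.35,
        ("da", "easp"): 0.35, ("da", "sgc"): 0.20,
        ("ds", "epp"): -0.50, ("ds", "pasp"): 0.45, ("ds", "easp"): 0.45,
        ("ds", "sgc"): 0.30,
        ("epp", "pasp"): -0.50, ("epp", "easp"): -0.50, ("epp", "sgc"): -0.30,
        ("pasp", "easp"): 0.65, ("pasp", "sgc"): 0.45,
        ("easp", "sgc"): 0.40,
    }
    k = len(traits)
    C = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = base.get((traits[i], traits[j]), base.get((traits[j], traits[i]), 0.0))
            C[i, j] = C[j, i] = r
    return C


@dataclass
class GeneratorConfig:
    """Everything needed to generate one trial, with a single master seed."""

    l: int = 40
    t: int = 3
    r: int = 2
    e: int = 3
    conditions: tuple[str, ...] = ("drought", "rainfed")
    traits: list[TraitSpec] = field(default_factory=default_traits)
    mu: dict[str, float] = field(default_factory=lambda: {
        "yield": 3000.0, "da": 50.0, "ds": 51.0, "epp": 1.0,
        "pasp": 2.5, "easp": 2.7, "sgc": 4.0,
    })
    mu_drought_shift: dict[str, float] = field(default_factory=lambda: {
        "da": 1.5, "ds": 2.5, "epp": -0.2, "pasp": 0.4, "easp": 0.4,
    })
    vc: dict[str, dict[str, float]] = field(default_factory=default_variance_components)
    drought_yield_ratio: float = 0.523
    trait_correlation: np.ndarray | None = None
    n_blocks: int = 1
    drop_pairs: tuple[tuple[str, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l < 2 or self.t < 2:
            raise TrialValidationError("generator needs at least 2 lines and 2 testers")
        if not (0.0 < self.drought_yield_ratio <= 1.0):
            raise TrialValidationError("drought_yield_ratio must be in (0, 1]")
        for trait, comps in self.vc.items():
            for key, val in comps.items():
                if val < 0:
                    raise TrialValidationError(
                        f"negative variance component {key} for trait {trait!r}"
                    )
        if self.trait_correlation is not None:
            C = np.asarray(self.trait_correlation, float)
            k = len(self.latent_traits())
            if C.shape != (k, k):
                raise TrialValidationError(
                    f"trait correlation must be {k}x{k} for traits {self.latent_traits()}"
                )
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise TrialValidationError("trait correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise TrialValidationError("trait correlation matrix is not positive semi-definite")

    def latent_traits(self) -> list[str]:
        """Traits generated on the latent scale; asi is derived as ds - da."""
        names = [t.name for t in self.traits]
        if "asi" in names and "da" in names and "ds" in names:
            names.remove("asi")
        return names


@dataclass
class TruthEntry:
    """Ground truth for one (condition, trait) pair."""

    gca_line: pd.Series
    gca_tester: pd.Series
    sca: pd.DataFrame
    nominal: dict[str, float]
    realized: dict[str, float]
    baker_nominal: float
    baker_realized: float


@dataclass
class SyntheticTruth:
    """Realized effects and variance components keyed by (condition, trait)."""

    entries: dict[tuple[str, str], TruthEntry]

    def __getitem__(self, key: tuple[str, str]) -> TruthEntry:
        return self.entries[key]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cond, trait), ent in sorted(self.entries.items()):
            for line, eff in ent.gca_line.items():
                rows.append((cond, trait, "gca_line", line, "", eff))
            for tester, eff in ent.gca_tester.items():
                rows.append((cond, trait, "gca_tester", "", tester, eff))
            for line in ent.sca.index:
                for tester in ent.sca.columns:
                    rows.append((cond, trait, "sca", line, tester, ent.sca.loc[line, tester]))
            for key, val in ent.realized.items():
                rows.append((cond, trait, f"realized_{key}", "", "", val))
            rows.append((cond, trait, "baker_nominal", "", "", ent.baker_nominal))
            rows.append((cond, trait, "baker_realized", "", "", ent.baker_realized))
        return pd.DataFrame(rows, columns=["condition", "trait", "component", "line", "tester", "value"])


def _center1(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def _center2(x: np.ndarray) -> np.ndarray:
    """Double-center the first two axes (interaction residual of a 2-way array)."""
    return (x - x.mean(axis=0, keepdims=True) - x.mean(axis=1, keepdims=True)
            + x.mean(axis=(0, 1), keepdims=True))


def _correlated(rng: np.random.Generator, shape: tuple[int, ...], factor: np.ndarray) -> np.ndarray:
    """Standard normals on *shape* axes with trait correlation on the last axis."""
    z = rng.standard_normal(shape + (factor.shape[0],))
    return z @ factor.T


def _corr_factor(C: np.ndarray) -> np.ndarray:
    # eigen factor tolerates PSD-singular matrices, unlike Cholesky
    w, v = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def generate_trial(config: GeneratorConfig) -> tuple[TrialDataset, SyntheticTruth]:
    """Generate a balanced trial plus its ground truth.

    Identical config (including seed) gives bit-identical output; each
    effect family draws from its own deterministic substream of the master
    seed so adding a condition or trait does not reshuffle the others.
    """
    latent = config.latent_traits()
    C = (np.asarray(config.trait_correlation, float)
         if config.trait_correlation is not None else default_trait_correlation(latent))
    if C.shape != (len(latent), len(latent)):
        raise TrialValidationError("trait correlation shape does not match latent traits")
    factor = _corr_factor(C)

    lines = [f"L{i + 1:02d}" for i in range(config.l)]
    testers = [f"T{j + 1}" for j in range(config.t)]
    spec_by_name = {t.name: t for t in config.traits}
    l, t, r, e = config.l, config.t, config.r, config.e
    n_geno = l * t

    ss = np.random.SeedSequence(config.seed)
    cond_seeds = {cond: s for cond, s in zip(("drought", "rainfed"), ss.spawn(2))}

    frames = []
    entries: dict[tuple[str, str], TruthEntry] = {}
    for cond in config.conditions:
        rng_effects, rng_error, rng_blocks = (
            np.random.default_rng(s) for s in cond_seeds[cond].spawn(3)
        )
        envs = [f"{'DR' if cond == 'drought' else 'RF'}{k + 1}" for k in range(e)]

        sd = {name: {k: np.sqrt(config.vc.get(name, {}).get(k, 0.0)) for k in VC_KEYS}
              for name in latent}
        draw = {
            "env": _center1(_correlated(rng_effects, (e,), factor)),
            "rep": _center1(_correlated(rng_effects, (e, r), factor).reshape(e * r, -1)
                            ).reshape(e, r, -1),
            "gca_line": _center1(_correlated(rng_effects, (l,), factor)),
            "gca_tester": _center1(_correlated(rng_effects, (t,), factor)),
            "sca": _center2(_correlated(rng_effects, (l, t), factor)),
            # interaction families are centered over the genotype axes only,
            # within each environment: the random-environment convention the
            # EMS estimators assume (their environment-means stay random)
            "gca_line_env": _center1(_correlated(rng_effects, (l, e), factor)),
            "gca_tester_env": _center1(_correlated(rng_effects, (t, e), factor)),
            "sca_env": _center2(_correlated(rng_effects, (l, t, e), factor)),
        }
        block_draw = _correlated(rng_effects, (e, r, config.n_blocks), factor)
        block_draw = block_draw - block_draw.mean(axis=2, keepdims=True)
        error_draw = _correlated(rng_error, (l, t, e, r), factor)

        # block membership: genotypes split into n_blocks groups per (env, rep)
        block_of = np.zeros((e, r, n_geno), dtype=int)
        size = int(np.ceil(n_geno / config.n_blocks))
        for ke in range(e):
            for kr in range(r):
                perm = rng_blocks.permutation(n_geno) if config.n_blocks > 1 else np.arange(n_geno)
                block_of[ke, kr] = (np.argsort(perm) // size) + 1

        values: dict[str, np.ndarray] = {}
        for ti, name in enumerate(latent):
            spec = spec_by_name[name]
            if spec.drought_only and cond != "drought":
                continue
            mu = config.mu.get(name, 0.0)
            if cond == "drought":
                if name == "yield":
                    mu = mu * config.drought_yield_ratio
                else:
                    mu = mu + config.mu_drought_shift.get(name, 0.0)
            g_l = sd[name]["gca_line"] * draw["gca_line"][:, ti]
            g_t = sd[name]["gca_tester"] * draw["gca_tester"][:, ti]
            s = sd[name]["sca"] * draw["sca"][:, :, ti]
            gle = sd[name]["gca_line_env"] * draw["gca_line_env"][:, :, ti]
            gte = sd[name]["gca_tester_env"] * draw["gca_tester_env"][:, :, ti]
            se3 = sd[name]["sca_env"] * draw["sca_env"][:, :, :, ti]
            env_eff = sd[name]["env"] * draw["env"][:, ti]
            rep_eff = sd[name]["rep"] * draw["rep"][:, :, ti]
            err = sd[name]["error"] * error_draw[:, :, :, :, ti]

            val = (
                mu
                + env_eff[None, None, :, None]
                + rep_eff[None, None, :, :]
                + g_l[:, None, None, None]
                + g_t[None, :, None, None]
                + s[:, :, None, None]
                + gle[:, None, :, None]
                + gte[None, :, :, None]
                + se3[:, :, :, None]
                + err
            )
            if config.n_blocks > 1:
                blk_eff = sd[name]["block"] * block_draw[:, :, :, ti]  # e x r x b
                flat_geno = block_of - 1  # e x r x n_geno
                add = blk_eff[np.arange(e)[:, None, None],
                              np.arange(r)[None, :, None], flat_geno]  # e x r x n_geno
                val = val + add.transpose(2, 0, 1).reshape(l, t, e, r)
            values[name] = val

            # ground truth with ANOVA-df divisors
            geno_eff = g_l[:, None] + g_t[None, :] + s
            ge_eff = gle[:, None, :] + gte[None, :, :] + se3
            realized = {
                "gca_line": float((g_l ** 2).sum() / (l - 1)),
                "gca_tester": float((g_t ** 2).sum() / (t - 1)),
                "sca": float((s ** 2).sum() / ((l - 1) * (t - 1))),
                "sigma2_g": float((geno_eff ** 2).sum() / (n_geno - 1)),
                "sigma2_ge": float((ge_eff ** 2).sum() / ((n_geno - 1) * e)),
                "error": float(err.var(ddof=1)),
            }
            nominal = {k: config.vc.get(name, {}).get(k, 0.0) for k in VC_KEYS}
            entries[(cond, name)] = TruthEntry(
                gca_line=pd.Series(g_l, index=lines),
                gca_tester=pd.Series(g_t, index=testers),
                sca=pd.DataFrame(s, index=lines, columns=testers),
                nominal=nominal,
                realized=realized,
                baker_nominal=_baker(nominal["gca_line"], nominal["gca_tester"], nominal["sca"]),
                baker_realized=_baker(realized["gca_line"], realized["gca_tester"], realized["sca"]),
            )

        # assemble the long frame for this condition
        li, tj, ke, kr = np.meshgrid(
            np.arange(l), np.arange(t), np.arange(e), np.arange(r), indexing="ij"
        )
        geno_idx = li * t + tj
        rec = {
            "environment": np.array(envs)[ke.ravel()],
            "condition": cond,
            "replicate": kr.ravel() + 1,
            "block": block_of[ke.ravel(), kr.ravel(), geno_idx.ravel()],
            "genotype": np.array([hybrid_id(lines[i], testers[j])
                                  for i, j in zip(li.ravel(), tj.ravel())]),
            "line": np.array(lines)[li.ravel()],
            "tester": np.array(testers)[tj.ravel()],
            "role": "hybrid",
        }
        frame = pd.DataFrame(rec)
        for name, val in values.items():
            spec = spec_by_name[name]
            col = val.ravel()
            if spec.scale == "ordinal":
                lo, hi = spec.bounds
                col = np.clip(np.rint(col), lo, hi)
            frame[name] = col
        if "asi" in spec_by_name and "da" in values and "ds" in values:
            frame["asi"] = frame["ds"] - frame["da"]
        for name, spec in spec_by_name.items():
            if name not in frame.columns:
                frame[name] = np.nan
        frames.append(frame)

    data = pd.concat(frames, ignore_index=True)
    if config.drop_pairs:
        mask = ~data.set_index(["line", "tester"]).index.isin(config.drop_pairs)
        data = data[mask].reset_index(drop=True)
    design = Design(l=l, t=t, r=r, e=e)
    traits = [spec_by_name[name] for name in spec_by_name]
    return TrialDataset(data, traits, design), SyntheticTruth(entries)


def _baker(v_line: float, v_tester: float, v_sca: float) -> float:
    denom = v_line + v_tester + v_sca
    if denom <= 0:
        return float("nan")
    return float((v_line + v_tester) / denom)


def make_rank2_means(g: int, e: int, seed: int = 0) -> MeansTable:
    """A genotype x environment means grid whose centered form has rank exactly 2.

    Built from two orthonormal column-centered genotype vectors and a full
    rank pair of environment loadings, plus arbitrary per-environment
    offsets (which environment-centering removes).
    """
    if g < 3 or e < 3:
        raise TrialValidationError("rank-2 fixture needs g >= 3 and e >= 3")
    rng = np.random.default_rng(seed)
    u1 = rng.standard_normal(g)
    u1 -= u1.mean()
    u1 /= np.linalg.norm(u1)
    u2 = rng.standard_normal(g)
    u2 -= u2.mean()
    u2 -= (u2 @ u1) * u1
    u2 /= np.linalg.norm(u2)
    v1 = rng.standard_normal(e) * 3.0
    v2 = rng.standard_normal(e) * 2.0
    v2 -= (v2 @ v1) / (v1 @ v1) * v1
    offsets = rng.standard_normal(e) * 5.0
    grid = np.outer(u1, v1) + np.outer(u2, v2) + offsets[None, :]
    genotypes = [f"G{i + 1:02d}" for i in range(g)]
    envs = [f"E{j + 1}" for j in range(e)]
    frame = pd.DataFrame(grid, index=pd.Index(genotypes, name="genotype"), columns=envs)
    n = pd.DataFrame(1, index=frame.index, columns=frame.columns)
    return MeansTable(trait="yield", level="per_environment", frame=frame, n=n)
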