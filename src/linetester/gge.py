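"""GGE biplot computation on environment-centered genotype x environment means.

The grid is column-centered (environment main effects removed; no
transformation, no scaling) and decomposed by SVD.  Axis signs are fixed by
forcing each environment-score vector to a positive sum, making every
coordinate deterministic across numeric backends.

Singular-value partitioning: genotype coordinates are xi * lambda^f and
environment coordinates eta * lambda^(1-f), with f = 1 for
``genotype_focused``, f = 0 for ``environment_focused`` and f = 0.5 for
``symmetric``.  Published figure captions sometimes attach the focus names
to SVP numbers the other way around; both names and numbers (``svp1`` =
environment_focused, ``svp2`` = genotype_focused) are accepted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .means_anova import MeansTable
from .core import TrialValidationError

__all__ = [
    "GGEModel",
    "BiplotGeometry",
    "fit_gge",
    "svp_scores",
    "which_won_where",
    "aec_stability",
]

SVP_MODES = {
    "genotype_focused": 1.0,
    "environment_focused": 0.0,
    "symmetric": 0.5,
    "svp1": 0.0,
    "svp2": 1.0,
}


@dataclass
class GGEModel:
    genotypes: list[str]
    environments: list[str]
    centered: np.ndarray          # genotype x environment
    singular_values: np.ndarray   # non-increasing, length n_axes
    genotype_scores: np.ndarray   # xi, genotype x n_axes (unscaled)
    environment_scores: np.ndarray  # eta, environment x n_axes (unscaled)
    var_explained: np.ndarray     # per retained axis, lambda^2 / sum all lambda^2

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.genotypes):
            for a in range(self.n_axes):
                rows.append(("genotype", g, a + 1, self.genotype_scores[i, a]))
        for j, env in enumerate(self.environments):
            for a in range(self.n_axes):
                rows.append(("environment", env, a + 1, self.environment_scores[j, a]))
        out = pd.DataFrame(rows, columns=["role", "id", "axis", "score"])
        return out


@dataclass
class BiplotGeometry:
    hull_vertices: list[str]                  # counter-clockwise order
    sectors: pd.DataFrame                     # sector, vertex, environments
    winners: pd.Series                        # environment -> winning genotype

    def to_frame(self) -> pd.DataFrame:
        return self.sectors


def fit_gge(means: MeansTable, n_axes: int = 2) -> GGEModel:
    """Column-centered SVD of a complete genotype x environment means grid."""
    frame = means.frame
    g, e = frame.shape
    if g < 3 or e < 2:
        raise TrialValidationError("GGE needs >= 3 genotypes and >= 2 environments")
    if frame.isna().any().any():
        missing = [(str(i), str(c)) for i in frame.index for c in frame.columns
                   if pd.isna(frame.loc[i, c])]
        raise TrialValidationError(f"missing genotype x environment cell(s): {missing}; "
                                   "no imputation is performed")
    if n_axes > min(g - 1, e):
        raise TrialValidationError(f"n_axes={n_axes} exceeds min(g-1, e)={min(g - 1, e)}")
    arr = frame.to_numpy(float)
    centered = arr - arr.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s ** 2).sum())
    xi = u[:, :n_axes]
    eta = vt[:n_axes].T
    lam = s[:n_axes].copy()
    # deterministic sign: environment scores of each axis sum positive
    for a in range(n_axes):
        col_sum = eta[:, a].sum()
        flip = col_sum < 0 or (abs(col_sum) < 1e-12 and eta[0, a] < 0)
        if flip:
            eta[:, a] *= -1
            xi[:, a] *= -1
    var = (s[:n_axes] ** 2) / total if total > 0 else np.zeros(n_axes)
    return GGEModel(
        genotypes=[str(i) for i in frame.index],
        environments=[str(c) for c in frame.columns],
        centered=centered,
        singular_values=lam,
        genotype_scores=xi,
        environment_scores=eta,
        var_explained=var,
    )


def svp_scores(model: GGEModel, mode: str = "symmetric") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype and environment coordinates under a singular value partition.

    In every mode the product of the two coordinate matrices reproduces the
    retained-rank approximation of the centered grid.
    """
    if mode not in SVP_MODES:
        raise TrialValidationError(f"unknown svp mode {mode!r}; one of {sorted(SVP_MODES)}")
    f = SVP_MODES[mode]
    lam = model.singular_values
    gcoord = model.genotype_scores * lam[None, :] ** f
    ecoord = model.environment_scores * lam[None, :] ** (1.0 - f)
    axes = [f"pc{a + 1}" for a in range(model.n_axes)]
    return (
        pd.DataFrame(gcoord, index=model.genotypes, columns=axes),
        pd.DataFrame(ecoord, index=model.environments, columns=axes),
    )


def _require_2d(model: GGEModel) -> None:
    if model.n_axes != 2:
        raise TrialValidationError("this geometry needs a 2-axis model")


def which_won_where(model: GGEModel) -> BiplotGeometry:
    """Convex hull, perpendicular-ray sectors and per-environment winners.

    The winner of an environment is the hull vertex whose marker has the
    largest inner product with the environment marker -- exactly the vertex
    of the sector the environment falls in.  Boundary ties (within 1e-12)
    go to the counter-clockwise sector.
    """
    _require_2d(model)
    lam = model.singular_values
    if lam[1] <= 1e-9 * max(lam[0], 1e-300):
        raise TrialValidationError(
            "degenerate geometry: genotype markers are collinear through the origin"
        )
    G, E = svp_scores(model, "symmetric")
    pts = G.to_numpy()
    hull = ConvexHull(pts)
    verts = list(hull.vertices)  # counter-clockwise for 2-D
    vert_ids = [model.genotypes[v] for v in verts]
    vpts = pts[verts]

    winners = {}
    env_of_vertex: dict[str, list[str]] = {vid: [] for vid in vert_ids}
    for j, env in enumerate(model.environments):
        evec = E.to_numpy()[j]
        dots = vpts @ evec
        best = dots.max()
        tied = np.where(dots >= best - 1e-12 * max(1.0, abs(best)))[0]
        if len(tied) == 1:
            k = int(tied[0])
        else:
            # counter-clockwise sector wins on a boundary tie
            angles = np.arctan2(vpts[tied, 1], vpts[tied, 0])
            k = int(tied[np.argmax(angles)])
        winners[env] = vert_ids[k]
        env_of_vertex[vert_ids[k]].append(env)

    sectors = pd.DataFrame(
        [
            {"sector": i + 1, "vertex": vid,
             "environments": ";".join(env_of_vertex[vid])}
            for i, vid in enumerate(vert_ids)
        ]
    )
    return BiplotGeometry(hull_vertices=vert_ids, sectors=sectors,
                          winners=pd.Series(winners))


def aec_stability(model: GGEModel) -> pd.DataFrame:
    """Average-environment-axis projections, stability and ideal-genotype ranks.

    Uses genotype-focused coordinates.  mean_projection is the scalar
    projection of a genotype marker onto the unit average-environment
    direction; stability is the absolute perpendicular component (smaller =
    more stable); the ideal genotype sits on the positive axis at the
    maximal mean projection and entries are ranked by distance to it.
    """
    _require_2d(model)
    G, E = svp_scores(model, "genotype_focused")
    ecoord = E.to_numpy().copy()
    # axes with a null singular value carry arbitrary (unscaled) environment
    # directions; they contribute nothing to genotype markers and are dropped
    null = model.singular_values <= 1e-12 * max(model.singular_values[0], 1e-300)
    ecoord[:, null] = 0.0
    aec = ecoord.mean(axis=0)
    norm = np.linalg.norm(aec)
    if norm < 1e-12:
        raise TrialValidationError("average-environment vector has zero length; no mean axis")
    u = aec / norm
    perp = np.array([-u[1], u[0]])
    pts = G.to_numpy()
    mean_proj = pts @ u
    stability = np.abs(pts @ perp)
    ideal = u * mean_proj.max()
    dist = np.linalg.norm(pts - ideal[None, :], axis=1)
    out = pd.DataFrame(
        {
            "mean_projection": mean_proj,
            "stability": stability,
            "ideal_distance": dist,
        },
        index=pd.Index(model.genotypes, name="genotype"),
    )
    out["rank"] = out["ideal_distance"].rank(method="first").astype(int)
    return out.sort_values("rank")
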