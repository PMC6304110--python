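"""Size-corrected trait morphospace and species-packing metrics.

The analysis unit is the species: specimen measurements are averaged to
species means, each trait is regressed on body mass (ordinary least
squares, one fit per trait) and the residuals — size-corrected trait
values — are projected onto principal component axes. Species packing in
the resulting morphospace is summarised by three metrics:

* nearest-neighbour distance (per species, plus mean ± s.d.),
* distance to the community centroid (per species, plus mean and median),
* minimum convex polygon (MCP) area of the first two component axes.

Distances use the Euclidean metric in the full retained component space;
the hull area is two-dimensional by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .io import TRAIT_NAMES, aggregate_to_species

__all__ = [
    "ResidualTable",
    "MorphospaceCoordinates",
    "PackingMetrics",
    "Hull",
    "size_correct",
    "run_pca",
    "nn_distances",
    "centroid_distances",
    "mcp_area",
    "MorphospaceModel",
    "MorphospaceResults",
]


@dataclass
class ResidualTable:
    """Per-trait OLS fits against body mass and the resulting residuals.

    ``residuals`` is species × trait (same units as the traits, mm);
    ``fits`` is trait × (intercept, slope, r_squared) with the slope in
    mm per gram. Residuals of each trait sum to zero and are uncorrelated
    with body mass, up to rounding.
    """

    residuals: pd.DataFrame
    fits: pd.DataFrame
    mass: pd.Series


@dataclass
class MorphospaceCoordinates:
    """Species scores on principal component axes.

    ``scores`` is species × (PC1..PCk); ``loadings`` is trait × component.
    Components are eigenvectors of the residual covariance matrix ordered
    by decreasing eigenvalue, with the sign convention that each
    component's largest-magnitude loading is positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


@dataclass
class Hull:
    area: float
    vertices: np.ndarray
    degenerate: bool


@dataclass
class PackingMetrics:
    """Species-packing summary for one community's morphospace."""

    nn: pd.Series
    nn_mean: float
    nn_sd: float
    centroid: pd.Series
    centroid_mean: float
    centroid_median: float
    mcp: Hull = field(repr=False)

    @property
    def mcp_area(self) -> float:
        return self.mcp.area


def size_correct(
    species_trait_means: pd.DataFrame,
    mass: pd.Series,
    traits: tuple[str, ...] = TRAIT_NAMES,
) -> ResidualTable:
    """Regress each trait on body mass and return the residuals.

    One ordinary least-squares fit ``trait = a + b * mass`` per trait;
    species with a missing value for a trait are excluded from that
    trait's fit (pairwise deletion) and keep a missing residual.

    Raises
    ------
    ValueError
        If a trait has fewer than 3 complete (trait, mass) pairs, or the
        masses have zero variance (the slope is then undefined).
    """
    mass = pd.Series(mass, dtype=float)
    if (mass <= 0).any():
        raise ValueError("body masses must be positive")
    if np.isclose(mass.var(ddof=1) if len(mass) > 1 else 0.0, 0.0):
        raise ValueError("zero variance in body mass: allometric slope undefined")
    residuals = pd.DataFrame(index=species_trait_means.index, columns=list(traits), dtype=float)
    fit_rows = {}
    for trait in traits:
        y = pd.to_numeric(species_trait_means[trait], errors="coerce")
        ok = y.notna() & mass.notna()
        if ok.sum() < 3:
            raise ValueError(
                f"trait {trait!r}: need >=3 complete (trait, mass) pairs, got {int(ok.sum())}"
            )
        if np.allclose(y[ok], y[ok].iloc[0]):
            # constant trait: slope 0, intercept = the constant
            fit_rows[trait] = (float(y[ok].iloc[0]), 0.0, 0.0)
            residuals.loc[ok, trait] = 0.0
            continue
        fit = stats.linregress(mass[ok], y[ok])
        fit_rows[trait] = (fit.intercept, fit.slope, fit.rvalue**2)
        residuals.loc[ok, trait] = y[ok] - (fit.intercept + fit.slope * mass[ok])
    fits = pd.DataFrame.from_dict(
        fit_rows, orient="index", columns=["intercept", "slope", "r_squared"]
    )
    return ResidualTable(residuals=residuals, fits=fits, mass=mass)


def run_pca(residual_table: ResidualTable | pd.DataFrame, k: int = 10,
            scale: bool = False) -> MorphospaceCoordinates:
    """Principal component analysis of the residual matrix.

    Species with any missing residual are dropped (with a warning) since
    the decomposition needs complete vectors. Components come from the
    covariance matrix of the residuals by default (all traits share mm
    units); ``scale=True`` standardises each trait first, i.e. uses the
    correlation matrix.

    Rank-deficient input succeeds with zero-variance trailing components
    and a warning.
    """
    X = residual_table.residuals if isinstance(residual_table, ResidualTable) else residual_table
    complete = X.dropna(axis=0, how="any")
    dropped = set(X.index) - set(complete.index)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} species with incomplete residual vectors "
            f"from PCA: {sorted(map(str, dropped))}",
            stacklevel=2,
        )
    n, p = complete.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 complete species")
    if k > min(p, n - 1):
        raise ValueError(f"k={k} exceeds min(n_traits, n_species - 1) = {min(p, n - 1)}")
    M = complete.to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        M = M / sd
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    eigvals = s**2 / (n - 1)
    if np.sum(eigvals > eigvals[0] * 1e-12) < k:
        warnings.warn("rank-deficient residual matrix: trailing components have zero variance",
                      stacklevel=2)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :k] * s[:k]
    total_var = float(np.sum(M.var(axis=0, ddof=1)))
    cols = [f"PC{i + 1}" for i in range(k)]
    return MorphospaceCoordinates(
        scores=pd.DataFrame(scores, index=complete.index, columns=cols),
        loadings=pd.DataFrame(Vt[:k].T, index=complete.columns, columns=cols),
        explained_variance=eigvals[:k],
        explained_variance_ratio=eigvals[:k] / total_var if total_var > 0 else eigvals[:k],
    )


def _as_matrix(coords) -> tuple[np.ndarray, pd.Index]:
    if isinstance(coords, MorphospaceCoordinates):
        coords = coords.scores
    if isinstance(coords, pd.DataFrame):
        return coords.to_numpy(dtype=float), coords.index
    arr = np.asarray(coords, dtype=float)
    return arr, pd.RangeIndex(len(arr))


def nn_distances(coords) -> tuple[pd.Series, float, float]:
    """Euclidean nearest-neighbour distance of each species to any other.

    Returns the per-species distances plus their mean and s.d. (n−1
    denominator). Needs at least two species.
    """
    X, index = _as_matrix(coords)
    if len(X) < 2:
        raise ValueError("nearest-neighbour distances need >=2 species")
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    nn = pd.Series(D.min(axis=1), index=index, name="nn_distance")
    return nn, float(nn.mean()), float(nn.std(ddof=1))


def centroid_distances(coords) -> tuple[pd.Series, float, float]:
    """Euclidean distance of each species to the coordinate-wise centroid.

    Returns per-species distances plus their mean and median.
    """
    X, index = _as_matrix(coords)
    if len(X) == 0:
        raise ValueError("empty coordinate set")
    d = np.linalg.norm(X - X.mean(axis=0), axis=1)
    ser = pd.Series(d, index=index, name="centroid_distance")
    return ser, float(ser.mean()), float(ser.median())


def mcp_area(points_2d) -> Hull:
    """Minimum convex polygon (convex hull) area of 2-D points.

    Fewer than three points, or collinear points, yield area 0 with the
    degenerate flag set.
    """
    P = np.asarray(points_2d, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("mcp_area expects an (n, 2) array")
    if len(P) < 3:
        return Hull(area=0.0, vertices=np.unique(P, axis=0), degenerate=True)
    try:
        hull = ConvexHull(P)
    except QhullError:
        return Hull(area=0.0, vertices=np.unique(P, axis=0), degenerate=True)
    return Hull(area=float(hull.volume), vertices=P[hull.vertices], degenerate=False)


def packing_metrics(coords: MorphospaceCoordinates | pd.DataFrame) -> PackingMetrics:
    """All three packing metrics for one community's coordinates."""
    scores = coords.scores if isinstance(coords, MorphospaceCoordinates) else coords
    nn, nn_mean, nn_sd = nn_distances(scores)
    cen, cen_mean, cen_median = centroid_distances(scores)
    hull = mcp_area(scores.iloc[:, :2].to_numpy())
    return PackingMetrics(
        nn=nn, nn_mean=nn_mean, nn_sd=nn_sd,
        centroid=cen, centroid_mean=cen_mean, centroid_median=cen_median,
        mcp=hull,
    )


class MorphospaceModel:
    """Size-corrected morphospace for one community of species.

    Parameters
    ----------
    species_means
        One row per species with ``body_mass`` and the trait columns
        (typically from :func:`nichepack.io.aggregate_to_species`).
    traits
        Trait columns to use; defaults to the standard ten measurements.

    Examples
    --------
    >>> model = MorphospaceModel.from_specimens(specimen_df)   # doctest: +SKIP
    >>> res = model.fit(k=10)                                  # doctest: +SKIP
    >>> res.packing.nn_mean, res.packing.mcp_area              # doctest: +SKIP
    """

    def __init__(self, species_means: pd.DataFrame,
                 traits: tuple[str, ...] = TRAIT_NAMES,
                 mass_col: str = "body_mass"):
        if "species" in species_means.columns:
            species_means = species_means.set_index("species")
        self.data = species_means
        self.traits = tuple(traits)
        self.mass_col = mass_col

    @classmethod
    def from_specimens(cls, records: pd.DataFrame, site: str | None = None,
                       **kwargs) -> "MorphospaceModel":
        if site is not None:
            records = records[records["site"] == site]
        means = aggregate_to_species(records)
        return cls(means.drop(columns=["site"]), **kwargs)

    def fit(self, k: int = 10, scale: bool = False) -> "MorphospaceResults":
        resid = size_correct(self.data, self.data[self.mass_col], traits=self.traits)
        k_eff = min(k, len(self.traits), resid.residuals.dropna().shape[0] - 1)
        coords = run_pca(resid, k=k_eff, scale=scale)
        return MorphospaceResults(self, resid, coords)


class MorphospaceResults:
    """Fitted morphospace: residual regressions, coordinates and packing."""

    def __init__(self, model: MorphospaceModel, residual_table: ResidualTable,
                 coords: MorphospaceCoordinates):
        self.model = model
        self.residual_table = residual_table
        self.coords = coords
        self.packing = packing_metrics(coords)

    @property
    def scores(self) -> pd.DataFrame:
        return self.coords.scores

    def summary(self) -> str:
        p = self.packing
        ev = self.coords.explained_variance_ratio
        lines = [
            "Morphospace summary",
            "===================",
            f"species: {len(self.scores)}   components: {self.scores.shape[1]}",
            f"explained variance (PC1, PC2): {ev[0]:.3f}, {ev[1]:.3f}" if len(ev) > 1
            else f"explained variance (PC1): {ev[0]:.3f}",
            f"nearest-neighbour distance: {p.nn_mean:.2f} (+/-{p.nn_sd:.3g})",
            f"distance to centroid: mean {p.centroid_mean:.2f}, median {p.centroid_median:.2f}",
            f"MCP area (PC1-PC2): {p.mcp_area:.2f}"
            + ("  [degenerate]" if p.mcp.degenerate else ""),
        ]
        return "\n".join(lines)

    def plot(self, ax=None, group_col: str = "foraging_group"):
        """Scatter of PC1 vs PC2, coloured by foraging group if present."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.scores
        groups = self.model.data.get(group_col)
        if groups is not None:
            for g, idx in s.groupby(groups.reindex(s.index)).groups.items():
                ax.scatter(s.loc[idx, "PC1"], s.loc[idx, "PC2"], label=str(g), s=18)
            ax.legend(frameon=False, fontsize=8)
        else:
            ax.scatter(s["PC1"], s["PC2"], s=18)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        return ax
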