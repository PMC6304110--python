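"""Community isotopic-niche metrics in the (δ13C, δ15N) plane.

A community is a set of species-mean points in bivariate isotope space.
Six community-wide metrics summarise its structure:

* NR — range of δ15N (‰), a proxy for the span of trophic levels;
* CR — range of δ13C (‰), the diversity of basal resources (C3 vs C4);
* CD — mean Euclidean distance to the community centroid (‰);
* MNND — mean nearest-neighbour distance (‰), species clustering;
* SDNND — s.d. of nearest-neighbour distances (‰), packing evenness;
* TA — total area of the convex hull around all points (‰²).

Niche breadth is additionally estimated by the standard ellipse area
SEA = π·√(λ₁λ₂) of the sample covariance (eigenvalues λ), its
small-sample correction SEAc = SEA·(n−1)/(n−2), and a Bayesian posterior
for SEA obtained from the conjugate normal–inverse-Wishart model with a
vague proper prior, summarised by its mode and nested 50/75/95% central
credible intervals. Both δ axes are treated as commensurate (1‰ = 1‰),
the standard convention for these metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .io import FORAGING_GROUPS
from .morphospace import centroid_distances, mcp_area, nn_distances

__all__ = [
    "LaymanMetrics",
    "EllipseEstimate",
    "PosteriorSEA",
    "layman_metrics",
    "standard_ellipse",
    "bayesian_sea",
    "per_group_metrics",
    "trophic_span",
    "IsotopeNicheModel",
    "IsotopeNicheResults",
]

#: Default trophic enrichment factor: mean per-trophic-level increase in δ15N (‰).
DEFAULT_TEF = 3.4


@dataclass
class LaymanMetrics:
    """The six community-wide isotope metrics (units: ‰, TA in ‰²).

    ``mnnd``/``sdnnd`` are NaN with ``"mnnd_undefined"`` in ``flags`` when
    the community has a single species; ``sdnnd`` additionally needs three.
    TA is 0 (degenerate) below three non-collinear points.
    """

    nr: float
    cr: float
    cd: float
    mnnd: float
    sdnnd: float
    ta: float
    n_species: int
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {"NR": self.nr, "CR": self.cr, "CD": self.cd, "MNND": self.mnnd,
                "SDNND": self.sdnnd, "TA": self.ta, "n_species": self.n_species}


@dataclass
class EllipseEstimate:
    """Standard ellipse of a bivariate point set.

    ``sea`` = π·a·b where a, b are the square roots of the covariance
    eigenvalues (the ellipse semi-axes); ``theta`` is the orientation of
    the major axis in radians from the δ13C axis.
    """

    sea: float
    sea_c: float
    semi_major: float
    semi_minor: float
    theta: float
    n: int
    degenerate: bool = False


@dataclass
class PosteriorSEA:
    """Posterior draws of the standard ellipse area."""

    draws: np.ndarray = field(repr=False)
    mode: float
    intervals: dict  # {0.50: (lo, hi), 0.75: ..., 0.95: ...}
    seed: int | None


def _points(data) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data[["d13C", "d15N"]].to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def layman_metrics(community) -> LaymanMetrics:
    """Compute the six community-wide metrics for one community.

    ``community`` is a DataFrame with ``d13C``/``d15N`` columns (one row
    per species) or an (n, 2) array of (δ13C, δ15N) points.
    """
    P = _points(community)
    if len(P) == 0:
        raise ValueError("community has no species points")
    n = len(P)
    flags: list[str] = []
    cr = float(P[:, 0].max() - P[:, 0].min())
    nr = float(P[:, 1].max() - P[:, 1].min())
    _, cd_mean, _ = centroid_distances(P)
    if n >= 2:
        nn, mnnd, sdnnd = nn_distances(P)
        if n < 3:
            sdnnd = float("nan")
            flags.append("sdnnd_undefined")
    else:
        mnnd = sdnnd = float("nan")
        flags.append("mnnd_undefined")
    hull = mcp_area(P)
    if hull.degenerate:
        flags.append("ta_degenerate")
    return LaymanMetrics(nr=nr, cr=cr, cd=cd_mean, mnnd=mnnd, sdnnd=sdnnd,
                         ta=hull.area, n_species=n, flags=tuple(flags))


def standard_ellipse(points) -> EllipseEstimate:
    """Standard ellipse area (SEA) and its small-sample correction (SEAc).

    The ellipse is defined by the sample covariance (n−1 denominator) of
    the (δ13C, δ15N) points; SEA = π·√(λ₁λ₂) with λ the covariance
    eigenvalues, and SEAc = SEA·(n−1)/(n−2).
    """
    P = _points(points)
    n = len(P)
    if n < 3:
        raise ValueError("standard ellipse requires n >= 3 points")
    cov = np.cov(P.T, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    lo, hi = eigvals  # eigh: ascending
    degenerate = bool(np.isclose(lo, 0.0, atol=1e-12 * max(hi, 1.0)))
    sea = float(np.pi * np.sqrt(lo * hi))
    major = eigvecs[:, 1]
    return EllipseEstimate(
        sea=sea,
        sea_c=sea * (n - 1) / (n - 2),
        semi_major=float(np.sqrt(hi)),
        semi_minor=float(np.sqrt(lo)),
        theta=float(np.arctan2(major[1], major[0])),
        n=n,
        degenerate=degenerate,
    )


def bayesian_sea(
    points,
    n_draws: int = 10_000,
    seed=None,
    prior_df: int = 3,
    prior_scale: float = 1e-3,
) -> PosteriorSEA:
    """Posterior distribution of the standard ellipse area.

    Model: points are i.i.d. bivariate normal with a conjugate
    normal–inverse-Wishart prior, vague but proper — prior degrees of
    freedom ν₀ = ``prior_df`` (dimension + 1 = 3 by default), prior scale
    ``prior_scale``·I, and prior mean at the sample mean. The covariance
    posterior is then inverse-Wishart with df ν₀ + n and scale
    ``prior_scale``·I + S (S the centred scatter matrix), sampled
    directly (no MCMC). Each covariance draw is mapped to
    SEA = π·√det(Σ).

    The point summary is the histogram mode of the draws
    (Freedman–Diaconis bins); the 50/75/95% credible intervals are
    central quantile intervals, hence nested by construction.

    ``seed`` may be an int or a ``numpy.random.Generator``/``SeedSequence``.
    """
    P = _points(points)
    n = len(P)
    if n < 3:
        raise ValueError("Bayesian SEA requires n >= 3 points")
    if n_draws < 1:
        raise ValueError("need at least one posterior draw")
    centred = P - P.mean(axis=0)
    scatter = centred.T @ centred
    psi_n = prior_scale * np.eye(2) + scatter
    rng = np.random.default_rng(seed)
    sigma_draws = invwishart(df=prior_df + n, scale=psi_n).rvs(n_draws, random_state=rng)
    sigma_draws = sigma_draws.reshape(n_draws, 2, 2)
    sea_draws = np.pi * np.sqrt(np.linalg.det(sigma_draws))
    counts, edges = np.histogram(sea_draws, bins="fd")
    imax = int(np.argmax(counts))
    mode = float(0.5 * (edges[imax] + edges[imax + 1]))
    intervals = {
        level: tuple(np.quantile(sea_draws, [(1 - level) / 2, (1 + level) / 2]))
        for level in (0.50, 0.75, 0.95)
    }
    return PosteriorSEA(draws=sea_draws, mode=mode, intervals=intervals,
                        seed=seed if isinstance(seed, (int, np.integer)) else None)


@dataclass
class GroupNiche:
    """Per-foraging-group niche metrics; ellipse fields are None with an
    ``insufficient_n`` flag when the group has too few species."""

    group: str
    n_species: int
    layman: LaymanMetrics
    ellipse: EllipseEstimate | None
    posterior: PosteriorSEA | None
    flags: tuple[str, ...] = ()


def per_group_metrics(
    community: pd.DataFrame,
    min_n: int = 3,
    n_draws: int = 10_000,
    seed=None,
) -> dict[str, GroupNiche]:
    """Layman metrics plus (Bayesian) ellipses for each foraging group.

    Groups with fewer than ``min_n`` species get Layman metrics (with
    their own degeneracy flags) but no ellipse — an ellipse fitted to one
    or two points would be a line. Group posteriors draw from streams
    spawned deterministically from ``seed`` in group-name order.
    """
    if "foraging_group" not in community.columns:
        raise ValueError("community needs a 'foraging_group' column")
    groups = sorted(community["foraging_group"].unique())
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = dict(zip(groups, seq.spawn(len(groups))))
    out: dict[str, GroupNiche] = {}
    for g in groups:
        sub = community[community["foraging_group"] == g]
        n = len(sub)
        lay = layman_metrics(sub)
        if n >= min_n:
            ell = standard_ellipse(sub)
            post = bayesian_sea(sub, n_draws=n_draws,
                                seed=np.random.default_rng(streams[g]))
            flags: tuple[str, ...] = ("ellipse_degenerate",) if ell.degenerate else ()
        else:
            ell = post = None
            flags = ("insufficient_n",)
        out[g] = GroupNiche(group=g, n_species=n, layman=lay,
                            ellipse=ell, posterior=post, flags=flags)
    return out


def trophic_span(nr: float, tef: float = DEFAULT_TEF) -> float:
    """Number of trophic levels spanned by a δ15N range.

    ``nr / tef`` with ``tef`` the trophic enrichment factor (default
    3.4‰ per level). Interpretation ("at least two levels") is the
    caller's.
    """
    if tef <= 0:
        raise ValueError("trophic enrichment factor must be positive")
    if nr < 0:
        raise ValueError("d15N range cannot be negative")
    return nr / tef


class IsotopeNicheModel:
    """Isotopic niche of one community.

    Built from per-specimen isotope records; by default specimens are
    averaged to species means before any metric is computed (``level=
    "species"``), since community metrics describe inter-species
    structure. ``level="specimen"`` analyses raw specimens instead.
    """

    def __init__(self, records: pd.DataFrame, site: str | None = None,
                 level: str = "species"):
        if site is not None:
            records = records[records["site"] == site]
        if records.empty:
            raise ValueError(f"no isotope records{f' for site {site!r}' if site else ''}")
        if level == "species":
            grouped = records.groupby(["species", "foraging_group"], as_index=False)
            points = grouped[["d13C", "d15N"]].mean()
            points["n_specimens"] = grouped.size()["size"].to_numpy()
        elif level == "specimen":
            points = records[["species", "foraging_group", "d13C", "d15N"]].copy()
            points["n_specimens"] = 1
        else:
            raise ValueError("level must be 'species' or 'specimen'")
        self.site = site
        self.level = level
        self.data = points.reset_index(drop=True)

    def fit(self, n_draws: int = 10_000, seed=None, min_group_n: int = 3,
            tef: float = DEFAULT_TEF) -> "IsotopeNicheResults":
        seq = np.random.SeedSequence(seed)
        all_stream, group_stream = seq.spawn(2)
        layman = layman_metrics(self.data)
        n = len(self.data)
        ellipse = standard_ellipse(self.data) if n >= 3 else None
        posterior = (
            bayesian_sea(self.data, n_draws=n_draws,
                         seed=np.random.default_rng(all_stream))
            if n >= 3 else None
        )
        groups = per_group_metrics(self.data, min_n=min_group_n,
                                   n_draws=n_draws, seed=group_stream)
        return IsotopeNicheResults(self, layman, ellipse, posterior, groups,
                                   tef=tef, seed=seed)


class IsotopeNicheResults:
    """Fitted isotopic niche: community metrics, ellipses and posteriors."""

    def __init__(self, model, layman, ellipse, posterior, groups, tef, seed):
        self.model = model
        self.layman = layman
        self.ellipse = ellipse
        self.posterior = posterior
        self.groups = groups
        self.tef = tef
        self.seed = seed

    @property
    def trophic_levels(self) -> float:
        return trophic_span(self.layman.nr, self.tef)

    def to_frame(self) -> pd.DataFrame:
        """One row per group plus an 'all' row, wide metric columns."""
        rows = []

        def row(label, n, lay, ell, post, flags):
            r = {"group": label, "n_species": n, **lay.to_dict()}
            r.pop("n_species", None)
            r["n_species"] = n
            r["SEA"] = ell.sea if ell else np.nan
            r["SEAc"] = ell.sea_c if ell else np.nan
            r["SEA_mode"] = post.mode if post else np.nan
            if post:
                r["SEA_ci95_lo"], r["SEA_ci95_hi"] = post.intervals[0.95]
            else:
                r["SEA_ci95_lo"] = r["SEA_ci95_hi"] = np.nan
            r["flags"] = ";".join(tuple(lay.flags) + tuple(flags))
            return r

        rows.append(row("all", self.layman.n_species, self.layman,
                        self.ellipse, self.posterior, ()))
        for g, gr in self.groups.items():
            rows.append(row(g, gr.n_species, gr.layman, gr.ellipse,
                            gr.posterior, gr.flags))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.layman
        lines = [
            "Isotopic niche summary" + (f" — {self.model.site}" if self.model.site else ""),
            "======================",
            f"species points: {m.n_species}",
            f"NR (d15N range): {m.nr:.2f} per mil   CR (d13C range): {m.cr:.2f} per mil",
            f"CD: {m.cd:.2f}   MNND: {m.mnnd:.2f}   SDNND: {m.sdnnd:.2f}",
            f"TA (hull area): {m.ta:.2f} per mil^2",
            f"trophic levels spanned (TEF {self.tef}): {self.trophic_levels:.2f}",
        ]
        if self.ellipse is not None:
            lines.append(f"SEA: {self.ellipse.sea:.2f}   SEAc: {self.ellipse.sea_c:.2f} per mil^2")
        if self.posterior is not None:
            lo, hi = self.posterior.intervals[0.95]
            lines.append(
                f"Bayesian SEA mode: {self.posterior.mode:.2f} (95% CI {lo:.2f}-{hi:.2f})"
            )
        for g in FORAGING_GROUPS:
            if g in self.groups:
                gr = self.groups[g]
                sea = f"{gr.ellipse.sea_c:.2f}" if gr.ellipse else "--"
                lines.append(f"  {g:<9} n={gr.n_species:<3} SEAc={sea}"
                             + (f"  [{';'.join(gr.flags)}]" if gr.flags else ""))
        return "\n".join(lines)

    def plot(self, ax=None, n_std: float = 1.0):
        """Scatter of species points with per-group standard ellipses."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse as MplEllipse

        if ax is None:
            _, ax = plt.subplots()
        for g, sub in self.data_by_group():
            ax.scatter(sub["d13C"], sub["d15N"], s=20, label=g)
            gr = self.groups.get(g)
            if gr and gr.ellipse:
                centre = (sub["d13C"].mean(), sub["d15N"].mean())
                e = gr.ellipse
                ax.add_patch(MplEllipse(
                    centre, 2 * n_std * e.semi_major, 2 * n_std * e.semi_minor,
                    angle=np.degrees(e.theta), fill=False))
        ax.set_xlabel("d13C (per mil)")
        ax.set_ylabel("d15N (per mil)")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def data_by_group(self):
        return self.model.data.groupby("foraging_group")
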