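"""End-to-end two-community comparison.

Runs the full analysis on two communities' specimen tables: aggregate to
species, size-correct traits, build each community's PCA morphospace,
compute packing metrics for the whole community and for insectivores only
(excluding the fruitbat group), compare the communities with rank-sum
tests and the richness-controlled rarefied bootstrap, and compute the
isotope metrics (Layman, SEA/SEAc, Bayesian SEA) community-wide and per
foraging group. Everything is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import aggregate_to_species
from .isotope import IsotopeNicheModel, IsotopeNicheResults
from .morphospace import (
    MorphospaceCoordinates,
    PackingMetrics,
    packing_metrics,
    run_pca,
    size_correct,
)
from .resampling import BootstrapComparison, RankSumResult, rank_sum_test, rarefied_bootstrap

__all__ = ["ComparisonConfig", "ComparisonReport", "run_comparison", "PipelineError"]

VARIANTS = ("all", "insectivores")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage and community label."""


@dataclass
class ComparisonConfig:
    """Tunable parameters of the two-community comparison."""

    k: int = 22  # rarefied subsample richness
    n_reps: int = 500  # bootstrap replicates
    seed: int | None = None
    pca_components: int = 10
    exclude_group: str = "fruitbat"  # the non-insectivorous guild
    joint_pca: bool = False
    scale_pca: bool = False  # correlation- instead of covariance-matrix PCA
    residual_level: str = "species"  # or "specimen"
    with_replacement: bool = False
    bootstrap_statistics: tuple[str, ...] = ("centroid_distance",)
    n_posterior_draws: int = 10_000
    min_group_n: int = 3

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """All outputs of :func:`run_comparison`, with serialisers."""

    sites: tuple[str, str]
    config: ComparisonConfig
    packing: dict  # {(variant, site): PackingMetrics}
    coords: dict  # {(variant, site): MorphospaceCoordinates}
    rank_sum: dict  # {(variant, metric): RankSumResult}
    bootstrap: dict  # {(variant, statistic): BootstrapComparison}
    isotope: dict  # {site: IsotopeNicheResults}
    provenance: dict = field(default_factory=dict)

    def morpho_frame(self) -> pd.DataFrame:
        rows = []
        for variant in VARIANTS:
            for site in self.sites:
                p: PackingMetrics = self.packing[(variant, site)]
                boot = self.bootstrap.get((variant, "centroid_distance"))
                boot_median = None
                if boot is not None:
                    boot_median = boot.median_a if site == boot.labels[0] else boot.median_b
                rows += [
                    {"community": site, "variant": variant,
                     "metric": "nn_distance", "value": p.nn_mean, "dispersion": p.nn_sd},
                    {"community": site, "variant": variant,
                     "metric": "centroid_distance", "value": p.centroid_median,
                     "dispersion": boot_median},
                    {"community": site, "variant": variant,
                     "metric": "mcp_area", "value": p.mcp_area, "dispersion": None},
                ]
        return pd.DataFrame(rows)

    def isotope_frame(self) -> pd.DataFrame:
        frames = []
        for site in self.sites:
            f = self.isotope[site].to_frame()
            f.insert(0, "site", site)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def to_dict(self) -> dict:
        out = {
            "sites": list(self.sites),
            "provenance": self.provenance,
            "morphospace": {},
            "rank_sum": {},
            "bootstrap": {},
            "isotope": {},
        }
        for (variant, site), p in self.packing.items():
            out["morphospace"][f"{variant}/{site}"] = {
                "n_species": int(len(p.nn)),
                "nn_mean": p.nn_mean, "nn_sd": p.nn_sd,
                "centroid_mean": p.centroid_mean, "centroid_median": p.centroid_median,
                "mcp_area": p.mcp_area, "mcp_degenerate": p.mcp.degenerate,
            }
        for (variant, metric), r in self.rank_sum.items():
            out["rank_sum"][f"{variant}/{metric}"] = {
                "W_rank_sum": r.statistic, "U": r.u, "p": r.p, "method": r.method,
            }
        for (variant, statistic), b in self.bootstrap.items():
            out["bootstrap"][f"{variant}/{statistic}"] = {
                "B": b.B, "k": b.k,
                "median_" + b.labels[0]: b.median_a,
                "median_" + b.labels[1]: b.median_b,
                "median_p": b.median_p, "prop_p_le_0.05": b.prop_significant,
            }
        for site, res in self.isotope.items():
            out["isotope"][site] = json.loads(
                res.to_frame().set_index("group").to_json(orient="index")
            )
            out["isotope"][site]["trophic_levels"] = res.trophic_levels
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=_jsonable, **kwargs)

    def write(self, outdir: str | Path) -> None:
        """Write report_morpho.csv / report_isotope.csv (2-decimal rounding,
        matching tabular convention) plus full-precision report.json and
        provenance.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.morpho_frame().round(2).to_csv(outdir / "report_morpho.csv", index=False)
        iso = self.isotope_frame()
        iso[iso.select_dtypes("number").columns] = iso.select_dtypes("number").round(2)
        iso.to_csv(outdir / "report_isotope.csv", index=False)
        (outdir / "report.json").write_text(self.to_json(indent=2) + "\n")
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, sort_keys=True, indent=2, default=_jsonable) + "\n"
        )

    def summary(self) -> str:
        lines = [f"Two-community comparison: {self.sites[0]} vs {self.sites[1]}", ""]
        lines.append(self.morpho_frame().round(3).to_string(index=False))
        lines.append("")
        for key, r in self.rank_sum.items():
            lines.append(f"rank-sum {key[0]}/{key[1]}: W={r.statistic:.1f} "
                         f"(U={r.u:.1f}), p={r.p:.4g} [{r.method}]")
        for key, b in self.bootstrap.items():
            lines.append(
                f"rarefied bootstrap {key[0]}/{key[1]} (k={b.k}, B={b.B}): "
                f"medians {b.labels[0]}={b.median_a:.2f} {b.labels[1]}={b.median_b:.2f}, "
                f"median p={b.median_p:.3f}, prop p<=0.05: {b.prop_significant:.3f}"
            )
        lines.append("")
        for site in self.sites:
            lines.append(self.isotope[site].summary())
            lines.append("")
        return "\n".join(lines)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, tuple):
        return list(x)
    return str(x)


def _species_residuals(traits: pd.DataFrame, level: str) -> pd.DataFrame:
    """Species × trait residual matrix (plus foraging_group) for one site."""
    if level == "species":
        means = aggregate_to_species(traits).set_index("species")
        rt = size_correct(means, means["body_mass"])
        resid = rt.residuals
        groups = means["foraging_group"]
    elif level == "specimen":
        spec = traits.set_index("specimen_id")
        rt = size_correct(spec, spec["body_mass"])
        resid = rt.residuals.groupby(spec["species"]).mean()
        groups = traits.groupby("species")["foraging_group"].first()
    else:
        raise ValueError("residual_level must be 'species' or 'specimen'")
    resid = resid.copy()
    resid["foraging_group"] = groups.reindex(resid.index)
    return resid


def _morphospaces(residuals: dict[str, pd.DataFrame], config: ComparisonConfig
                  ) -> dict[str, MorphospaceCoordinates]:
    """Per-site coordinates, either per-community PCA or one shared space."""
    trait_cols = [c for c in next(iter(residuals.values())).columns
                  if c != "foraging_group"]
    out = {}
    if config.joint_pca:
        stacked = pd.concat(
            [r[trait_cols] for r in residuals.values()],
            keys=residuals.keys(), names=["site", "species"],
        )
        k = min(config.pca_components, len(trait_cols), stacked.dropna().shape[0] - 1)
        coords = run_pca(stacked, k=k, scale=config.scale_pca)
        for site in residuals:
            scores = coords.scores.loc[site]
            out[site] = MorphospaceCoordinates(
                scores=scores, loadings=coords.loadings,
                explained_variance=coords.explained_variance,
                explained_variance_ratio=coords.explained_variance_ratio,
            )
    else:
        for site, r in residuals.items():
            X = r[trait_cols]
            k = min(config.pca_components, len(trait_cols), X.dropna().shape[0] - 1)
            out[site] = run_pca(X, k=k, scale=config.scale_pca)
    return out


def run_comparison(
    traits_a: pd.DataFrame,
    traits_b: pd.DataFrame,
    isotopes_a: pd.DataFrame,
    isotopes_b: pd.DataFrame,
    config: ComparisonConfig | None = None,
) -> ComparisonReport:
    """Full two-community comparison.

    The two communities are identified by their ``site`` labels and
    processed in sorted label order, so the report does not depend on the
    argument order (community labels are carried through). All random
    stages draw from streams derived from ``config.seed``.
    """
    config = config or ComparisonConfig()
    trait_tables = {}
    iso_tables = {}
    for traits, isotopes in ((traits_a, isotopes_a), (traits_b, isotopes_b)):
        for df, store in ((traits, trait_tables), (isotopes, iso_tables)):
            sites = df["site"].unique()
            if len(sites) != 1:
                raise PipelineError(f"each input table must cover one site, got {list(sites)}")
            store[str(sites[0])] = df
    if len(trait_tables) != 2 or set(trait_tables) != set(iso_tables):
        raise PipelineError(
            f"need two distinct sites with both trait and isotope tables; "
            f"got traits for {sorted(trait_tables)} and isotopes for {sorted(iso_tables)}"
        )
    sites = tuple(sorted(trait_tables))

    # independent integer seeds for every stochastic stage, in fixed order
    n_stochastic = len(VARIANTS) * len(config.bootstrap_statistics) + len(sites)
    stage_seeds = iter(
        np.random.SeedSequence(config.seed).generate_state(max(n_stochastic, 1)) % (2**31)
    )

    packing: dict = {}
    coords_store: dict = {}
    rank_sum: dict = {}
    bootstrap: dict = {}
    for variant in VARIANTS:
        residuals = {}
        for site in sites:
            df = trait_tables[site]
            if variant == "insectivores":
                df = df[df["foraging_group"] != config.exclude_group]
            try:
                residuals[site] = _species_residuals(df, config.residual_level)
            except Exception as exc:
                raise PipelineError(
                    f"stage=size_correct variant={variant} community={site}: {exc}"
                ) from exc
        try:
            coords = _morphospaces(residuals, config)
        except Exception as exc:
            raise PipelineError(f"stage=pca variant={variant}: {exc}") from exc
        for site in sites:
            coords_store[(variant, site)] = coords[site]
            try:
                packing[(variant, site)] = packing_metrics(coords[site])
            except Exception as exc:
                raise PipelineError(
                    f"stage=packing variant={variant} community={site}: {exc}"
                ) from exc
        a, b = sites
        rank_sum[(variant, "nn_distance")] = rank_sum_test(
            packing[(variant, a)].nn, packing[(variant, b)].nn)
        rank_sum[(variant, "centroid_distance")] = rank_sum_test(
            packing[(variant, a)].centroid, packing[(variant, b)].centroid)
        for statistic in config.bootstrap_statistics:
            try:
                bootstrap[(variant, statistic)] = rarefied_bootstrap(
                    coords[a], coords[b], k=config.k, B=config.n_reps,
                    statistic=statistic, seed=int(next(stage_seeds)),
                    with_replacement=config.with_replacement, labels=(a, b),
                )
            except ValueError as exc:
                raise PipelineError(
                    f"stage=rarefied_bootstrap variant={variant}: {exc}"
                ) from exc

    isotope: dict[str, IsotopeNicheResults] = {}
    for site in sites:
        try:
            isotope[site] = IsotopeNicheModel(iso_tables[site], site=site).fit(
                n_draws=config.n_posterior_draws, seed=int(next(stage_seeds)),
                min_group_n=config.min_group_n,
            )
        except Exception as exc:
            raise PipelineError(f"stage=isotope community={site}: {exc}") from exc

    provenance = {
        "package": "nichepack",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_digest": config.digest(),
        "sites": list(sites),
        "n_specimens_traits": {s: int(len(trait_tables[s])) for s in sites},
        "n_specimens_isotopes": {s: int(len(iso_tables[s])) for s in sites},
    }
    return ComparisonReport(
        sites=sites, config=config, packing=packing, coords=coords_store,
        rank_sum=rank_sum, bootstrap=bootstrap, isotope=isotope,
        provenance=provenance,
    )
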