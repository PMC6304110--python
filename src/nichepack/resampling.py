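"""Rank-sum comparison and richness-controlled rarefied resampling.

Communities of unequal species richness cannot be compared directly with
richness-sensitive packing metrics, so both are repeatedly subsampled to a
common number of species k (without replacement by default — rarefaction
semantics), the per-species statistic is recomputed inside each subsample
and the two subsampled vectors are compared with a two-sided Wilcoxon
rank-sum (Mann–Whitney) test. Rather than collapsing the replicates into a
single adjusted p-value, the whole distribution of per-replicate p-values
is reported (median p and the proportion of replicates at or below 0.05).

Randomness is controlled by a single master seed; each replicate draws
from its own deterministically spawned stream, so runs are bit-reproducible
and individual replicates can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .morphospace import MorphospaceCoordinates, centroid_distances, nn_distances

__all__ = ["RankSumResult", "BootstrapComparison", "rank_sum_test", "rarefied_bootstrap"]

#: Per-replicate statistics available to :func:`rarefied_bootstrap`.
STATISTICS = ("centroid_distance", "nn_distance")


@dataclass
class RankSumResult:
    """Two-sided Wilcoxon rank-sum result.

    ``statistic`` is the rank sum R1 of the first sample (mid-ranks for
    ties); ``u`` is the equivalent Mann–Whitney U1 = R1 − n1(n1+1)/2,
    which is the "W" that R's ``wilcox.test`` prints.
    """

    statistic: float
    u: float
    p: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses the exact null distribution when n1 + n2 <= 20 and there are no
    ties, otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= 20 and not ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        if np.all(pooled == pooled[0]):
            # all observations identical: no evidence either way
            u = n1 * n2 / 2.0
            return RankSumResult(statistic=u + n1 * (n1 + 1) / 2.0, u=u, p=1.0,
                                 method="normal_approx", n1=n1, n2=n2)
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
        method = "normal_approx"
    u1 = float(res.statistic)
    p = float(min(res.pvalue, 1.0))
    if u1 == n1 * n2 / 2.0:
        p = 1.0  # statistic exactly at its null mean
    return RankSumResult(statistic=u1 + n1 * (n1 + 1) / 2.0, u=u1, p=p,
                         method=method, n1=n1, n2=n2)


@dataclass
class BootstrapComparison:
    """Replicate-level output of the rarefied community comparison."""

    statistic: str
    B: int
    k: int
    with_replacement: bool
    seed: int | None
    labels: tuple[str, str]
    values_a: np.ndarray  # (B, k) per-replicate per-species statistic
    values_b: np.ndarray
    medians_a: np.ndarray  # (B,)
    medians_b: np.ndarray
    p_values: np.ndarray  # (B,)

    @property
    def median_a(self) -> float:
        return float(np.median(self.medians_a))

    @property
    def median_b(self) -> float:
        return float(np.median(self.medians_b))

    @property
    def median_p(self) -> float:
        return float(np.median(self.p_values))

    @property
    def prop_significant(self) -> float:
        """Proportion of replicates with p <= 0.05."""
        return float(np.mean(self.p_values <= 0.05))

    def to_frame(self) -> pd.DataFrame:
        """One row per replicate: medians of both communities and the p-value."""
        return pd.DataFrame({
            "replicate": np.arange(self.B),
            f"median_{self.labels[0]}": self.medians_a,
            f"median_{self.labels[1]}": self.medians_b,
            "p": self.p_values,
        })


def _per_species_statistic(X: np.ndarray, statistic: str) -> np.ndarray:
    if statistic == "centroid_distance":
        return centroid_distances(X)[0].to_numpy()
    if statistic == "nn_distance":
        return nn_distances(X)[0].to_numpy()
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def rarefied_bootstrap(
    coords_a,
    coords_b,
    k: int = 22,
    B: int = 500,
    statistic: str = "centroid_distance",
    seed: int | None = None,
    with_replacement: bool = False,
    labels: tuple[str, str] = ("A", "B"),
) -> BootstrapComparison:
    """Compare two communities at equal richness by repeated subsampling.

    Per replicate, ``k`` species are drawn from each community (without
    replacement by default), the per-species statistic is recomputed
    within the subsample — the centroid, and each species' nearest
    neighbour, are those of the subsample — and the two statistic vectors
    are compared with :func:`rank_sum_test`.

    Parameters
    ----------
    coords_a, coords_b
        Morphospace coordinates (``MorphospaceCoordinates``, DataFrame or
        array) of the two communities.
    k
        Subsample richness; must not exceed either community's richness
        when sampling without replacement.
    B
        Number of replicates.
    statistic
        ``"centroid_distance"`` or ``"nn_distance"``.
    seed
        Master seed; per-replicate streams are spawned from it.
    """

    def as_array(c):
        if isinstance(c, MorphospaceCoordinates):
            c = c.scores
        if isinstance(c, pd.DataFrame):
            c = c.to_numpy(dtype=float)
        return np.asarray(c, dtype=float)

    A, Bm = as_array(coords_a), as_array(coords_b)
    if B < 1:
        raise ValueError("need at least one replicate")
    if not with_replacement:
        for label, X in zip(labels, (A, Bm)):
            if k > len(X):
                raise ValueError(
                    f"subsample size k={k} exceeds richness {len(X)} of community {label!r}"
                )
    if k < 2:
        raise ValueError("k must be >= 2 to compute inter-species statistics")

    streams = np.random.SeedSequence(seed).spawn(B)
    vals_a = np.empty((B, k))
    vals_b = np.empty((B, k))
    p_values = np.empty(B)
    for r in range(B):
        rng = np.random.default_rng(streams[r])
        ia = rng.choice(len(A), size=k, replace=with_replacement)
        ib = rng.choice(len(Bm), size=k, replace=with_replacement)
        vals_a[r] = _per_species_statistic(A[ia], statistic)
        vals_b[r] = _per_species_statistic(Bm[ib], statistic)
        p_values[r] = rank_sum_test(vals_a[r], vals_b[r]).p
    return BootstrapComparison(
        statistic=statistic, B=B, k=k, with_replacement=with_replacement,
        seed=seed, labels=tuple(labels),
        values_a=vals_a, values_b=vals_b,
        medians_a=np.median(vals_a, axis=1), medians_b=np.median(vals_b, axis=1),
        p_values=p_values,
    )
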