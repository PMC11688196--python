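"""Soma-diameter morphometry and the statistical test battery.

Soma diameters are derived from segmented areas under a circular-soma
assumption, d = 2 sqrt(A / pi).  Within each image and layer, the
diameter distribution is bimodal — a small-cell and a large-cell
population — and is summarized by a 2-component Gaussian mixture fitted
by expectation-maximization (quantile-split initialization plus random
restarts, components sorted by mean).  Population means are aggregated
across images per layer and compared with a two-sample t-test; density
differences across the seven layers use the Kruskal-Wallis H-test, and
the six adjacent-layer pairs use t-tests with Bonferroni-adjusted
alpha = 0.05 / 6.

Degenerate inputs (zero variance, identical constants) resolve to the
explicit p = 1 convention rather than erroring, so synthetic edge cases
cannot crash a pipeline run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "MixtureFit",
    "StatResult",
    "diameter_from_area",
    "fit_diameter_mixture",
    "aggregate_mixtures",
    "density_across_layers",
    "adjacent_layer_tests",
    "welch_ttest",
]


@dataclass
class MixtureFit:
    """A 2-component Gaussian mixture fit, components sorted by mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    n: int
    log_likelihood: float
    converged: bool

    @property
    def overlap_flag(self) -> bool:
        """True when the two components are not meaningfully separated."""
        sep = abs(self.means[1] - self.means[0])
        return bool(sep < max(self.sds))

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(), "sds": self.sds.tolist(),
            "weights": self.weights.tolist(), "n": self.n,
            "log_likelihood": self.log_likelihood, "converged": self.converged,
        }


@dataclass
class StatResult:
    """One hypothesis test: statistic, p-value, and the alpha it was judged at."""

    test_name: str
    statistic: float
    p_value: float
    alpha_used: float = 0.05
    df: float | None = None
    group_sizes: tuple[int, ...] = ()
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_used

    def asterisks(self) -> str:
        """Conventional significance rendering of the p-value."""
        p = self.p_value
        if p <= 1e-4:
            return "****"
        if p <= 1e-3:
            return "***"
        if p <= 1e-2:
            return "**"
        if p <= 0.1:
            return "*"
        return "ns"

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name, "statistic": self.statistic,
            "p_value": self.p_value, "alpha_used": self.alpha_used,
            "df": self.df, "group_sizes": list(self.group_sizes),
            "significant": self.significant, "note": self.note,
        }


def diameter_from_area(area_um2) -> np.ndarray | float:
    """Circular-equivalent diameter, d = 2 sqrt(A / pi)."""
    area = np.asarray(area_um2, float)
    if (area <= 0).any() if area.ndim else area <= 0:
        raise ValueError("area must be positive")
    d = 2.0 * np.sqrt(area / np.pi)
    return float(d) if d.ndim == 0 else d


def fit_diameter_mixture(diameters, n_components: int = 2,
                         n_restarts: int = 5, seed: int = 0) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture fit of a diameter sample.

    EM with a quantile-split initialization (components centred on the
    below/above-median halves) plus ``n_restarts`` random restarts; the
    best log-likelihood wins.  Components are returned sorted by mean.
    """
    x = np.asarray(diameters, float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("need at least 10 diameters for a mixture fit")
    rng = np.random.default_rng(seed)
    fits = []
    # quantile-split initialization
    split = np.quantile(x, np.linspace(0, 1, n_components + 1))
    means_init = np.array([
        x[(x[:, 0] >= split[i]) & (x[:, 0] <= split[i + 1])].mean()
        for i in range(n_components)
    ]).reshape(-1, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm = GaussianMixture(n_components=n_components, means_init=means_init,
                             random_state=int(rng.integers(2**31))).fit(x)
        fits.append(gm)
        for _ in range(n_restarts):
            gm = GaussianMixture(n_components=n_components, init_params="random",
                                 random_state=int(rng.integers(2**31))).fit(x)
            fits.append(gm)
    best = max(fits, key=lambda g: g.score(x))
    order = np.argsort(best.means_[:, 0])
    return MixtureFit(
        means=best.means_[order, 0],
        sds=np.sqrt(best.covariances_[order, 0, 0]),
        weights=best.weights_[order],
        n=len(x),
        log_likelihood=float(best.score(x) * len(x)),
        converged=bool(any(g.converged_ for g in fits)),
    )


def aggregate_mixtures(fits_by_image: list[MixtureFit],
                       alpha: float = 0.05) -> dict:
    """Across-image aggregation of one layer's per-image mixture fits.

    Returns the unweighted across-image mean ± sd of the small- and
    large-population means and a two-sample t-test (Welch flavored)
    between the two vectors of population means.  With fewer than two
    images, or zero spread, the test is reported as degenerate.
    """
    pop1 = np.array([f.means[0] for f in fits_by_image])
    pop2 = np.array([f.means[1] for f in fits_by_image])
    out = {
        "n_images": len(fits_by_image),
        "pop1_mean_um": float(pop1.mean()),
        "pop1_sd_um": float(pop1.std(ddof=1)) if len(pop1) > 1 else 0.0,
        "pop2_mean_um": float(pop2.mean()),
        "pop2_sd_um": float(pop2.std(ddof=1)) if len(pop2) > 1 else 0.0,
    }
    if len(fits_by_image) < 2:
        out["test"] = None
        return out
    if pop1.std() == 0 and pop2.std() == 0:
        out["test"] = StatResult(
            test_name="two_sample_t", statistic=0.0,
            p_value=1.0 if np.isclose(pop1.mean(), pop2.mean()) else 0.0,
            alpha_used=alpha, group_sizes=(len(pop1), len(pop2)),
            note="degenerate: zero variance in both samples",
        )
        return out
    out["test"] = welch_ttest(pop1, pop2, alpha=alpha,
                              test_name="two_sample_t")
    return out


def density_across_layers(densities_by_layer: dict[str, np.ndarray],
                          alpha: float = 0.05) -> StatResult:
    """Kruskal-Wallis H-test of per-image densities across layers.

    ``densities_by_layer`` maps layer label to the vector of per-image
    density values.  All-identical groups (total ties) resolve to H = 0,
    p = 1 by convention.
    """
    groups = [np.asarray(v, float) for v in densities_by_layer.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return StatResult(test_name="kruskal_wallis", statistic=0.0, p_value=1.0,
                          alpha_used=alpha, df=len(groups) - 1,
                          group_sizes=tuple(len(g) for g in groups),
                          note="degenerate: all values identical")
    h, p = stats.kruskal(*groups)
    return StatResult(test_name="kruskal_wallis", statistic=float(h),
                      p_value=float(p), alpha_used=alpha, df=len(groups) - 1,
                      group_sizes=tuple(len(g) for g in groups))


def adjacent_layer_tests(densities_by_layer: dict[str, np.ndarray],
                         layer_order: tuple[str, ...] = ("LI", "LII", "LIII",
                                                         "LIV", "LV", "LVIa",
                                                         "LVIb"),
                         family_alpha: float = 0.05) -> dict[str, StatResult]:
    """Bonferroni-adjusted t-tests between all adjacent layer pairs.

    With the seven standard layers there are six comparisons and each is
    judged at alpha = family_alpha / 6.  A pair with a missing layer is
    skipped with a warning.
    """
    pairs = list(zip(layer_order[:-1], layer_order[1:]))
    alpha_used = family_alpha / len(pairs)
    out: dict[str, StatResult] = {}
    for upper, lower in pairs:
        key = f"{upper}-{lower}"
        if upper not in densities_by_layer or lower not in densities_by_layer:
            warnings.warn(f"layer missing for adjacent pair {key}; skipped")
            continue
        out[key] = welch_ttest(densities_by_layer[upper],
                               densities_by_layer[lower],
                               alpha=alpha_used, test_name="two_sample_t")
    return out


def welch_ttest(sample_a, sample_b, alpha: float = 0.05,
                test_name: str = "welch_t") -> StatResult:
    """Two-sided Welch's t-test (unequal variances).

    Zero variance in both samples with equal means resolves to t = 0,
    p = 1 by convention.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        equal = np.isclose(a.mean(), b.mean())
        return StatResult(test_name=test_name, statistic=0.0 if equal else math.inf,
                          p_value=1.0 if equal else 0.0, alpha_used=alpha,
                          group_sizes=(len(a), len(b)),
                          note="degenerate: zero variance in both samples")
    res = stats.ttest_ind(a, b, equal_var=False)
    return StatResult(test_name=test_name, statistic=float(res.statistic),
                      p_value=float(res.pvalue), alpha_used=alpha,
                      df=float(res.df), group_sizes=(len(a), len(b)))
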