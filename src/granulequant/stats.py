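"""Distribution-level statistics for granule quantification.

Four pieces, used together by the analysis pipelines:

* **Skew-normal peak** — per-image cluster-intensity distributions are
  right-skewed; they are summarized by the mode ("peak") of a 3-parameter
  skew-normal (location xi, scale omega > 0, shape alpha) fitted by maximum
  likelihood.  The mode is located numerically on the fitted density.
* **Per-batch control normalization** — the peak fitted to the pooled
  control clusters of each experimental batch is the normalizer for every
  image of that batch, making values comparable across weeks.
* **Outlier rule** — values farther than ``k`` sample standard deviations
  (default 2) from their condition mean are removed in a single pass.
* **Bootstrap difference** — the treatment-minus-control difference of a
  group statistic (median or skew-normal peak) is resampled with replacement
  B = 10,000 times; the 2.5/97.5 percentiles give the 95% CI and the
  two-sided p-value is floored at 1/B.

A thin one-way ANOVA + Tukey HSD wrapper serves the morphometry comparisons.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "SkewNormalFit",
    "BootstrapResult",
    "fit_skew_normal",
    "skew_normal_mode",
    "peak_of_condition",
    "remove_outliers",
    "bootstrap_difference",
    "anova_tukey",
]


@dataclasses.dataclass
class SkewNormalFit:
    """Maximum-likelihood skew-normal fit and the mode of its density."""

    xi: float
    omega: float
    alpha: float
    mode: float
    n: int
    converged: bool

    def pdf(self, x):
        return sps.skewnorm.pdf(x, self.alpha, loc=self.xi, scale=self.omega)


def skew_normal_mode(xi: float, omega: float, alpha: float) -> float:
    """Numeric argmax of the skew-normal density.

    The density is unimodal; the mode lies between the location xi and
    xi + sign(alpha) * omega * sqrt(2/pi) (the mean direction), so a bounded
    scalar minimization over an enclosing bracket is reliable.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if alpha == 0:
        return float(xi)
    # mean offset m0 = sqrt(2/pi) * delta; the mode sits between 0 and the
    # mean offset (in omega units), pad the bracket generously
    delta = alpha / np.sqrt(1 + alpha**2)
    m0 = np.sqrt(2 / np.pi) * delta
    lo, hi = sorted((xi - 0.5 * omega, xi + (m0 + 0.5 * np.sign(alpha)) * omega))
    res = optimize.minimize_scalar(
        lambda x: -sps.skewnorm.pdf(x, alpha, loc=xi, scale=omega),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def fit_skew_normal(values: Sequence[float], fix_alpha: float | None = None) -> SkewNormalFit:
    """Fit a 3-parameter skew-normal by maximum likelihood.

    Parameters
    ----------
    values
        Sample of at least 10 intensities with non-zero variance.
    fix_alpha
        If given, the shape parameter is held fixed (``fix_alpha=0`` fits a
        plain normal and the mode collapses onto the location).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 10:
        raise ValueError(f"need at least 10 values, got {v.size}")
    if v.std() == 0:
        raise ValueError("zero-variance sample")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            if fix_alpha is not None:
                alpha, xi, omega = sps.skewnorm.fit(v, f0=fix_alpha)
            else:
                alpha, xi, omega = sps.skewnorm.fit(v)
        except Exception:  # scipy raises FitError on hopeless optimizations
            alpha, xi, omega = 0.0, float(v.mean()), float(v.std(ddof=1))
            converged = False
    if not np.all(np.isfinite([alpha, xi, omega])) or omega <= 0:
        alpha, xi, omega = 0.0, float(v.mean()), float(v.std(ddof=1))
        converged = False
    mode = skew_normal_mode(xi, omega, alpha)
    return SkewNormalFit(
        xi=float(xi), omega=float(omega), alpha=float(alpha),
        mode=mode, n=int(v.size), converged=converged,
    )


def peak_of_condition(
    clusters: pd.DataFrame,
    control_condition: str = "CTL-KD",
    value_column: str = "max_intensity",
) -> pd.DataFrame:
    """Per-image skew-normal peaks normalized by the batch control peak.

    Parameters
    ----------
    clusters
        One row per detected cluster with columns ``image_id``,
        ``condition``, ``batch`` and *value_column*.
    control_condition
        Label of the non-targeting control; every batch must contain it.

    Returns
    -------
    DataFrame with one row per image: ``image_id, condition, batch,
    raw_peak, normalized_peak``.  The batch normalizer is the peak of a
    skew-normal fitted to the pooled control clusters of that batch.
    """
    required = {"image_id", "condition", "batch", value_column}
    if missing := required - set(clusters.columns):
        raise ValueError(f"cluster table is missing columns: {sorted(missing)}")
    rows = []
    for batch, batch_df in clusters.groupby("batch", sort=False):
        ctl = batch_df.loc[batch_df["condition"] == control_condition, value_column]
        if ctl.empty:
            raise ValueError(f"batch {batch!r} has no {control_condition!r} images")
        normalizer = fit_skew_normal(ctl.to_numpy()).mode
        if normalizer <= 0:
            raise ValueError(f"non-positive control peak in batch {batch!r}")
        for (image_id, condition), img_df in batch_df.groupby(
            ["image_id", "condition"], sort=False
        ):
            peak = fit_skew_normal(img_df[value_column].to_numpy()).mode
            rows.append(
                dict(
                    image_id=image_id, condition=condition, batch=batch,
                    raw_peak=peak, normalized_peak=peak / normalizer,
                )
            )
    return pd.DataFrame(rows)


def remove_outliers(values: Sequence[float], k: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass removal of values beyond ``k`` sample SDs from the mean.

    The mean and (n-1) SD are computed once on the full sample; returns
    ``(kept_values, removed_flags)``.  With fewer than 3 values nothing is
    removed and a warning is issued.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 3:
        warnings.warn("fewer than 3 values: outlier rule skipped", stacklevel=2)
        return v, np.zeros(v.size, dtype=bool)
    sd = v.std(ddof=1)
    if sd == 0:
        return v, np.zeros(v.size, dtype=bool)
    removed = np.abs(v - v.mean()) > k * sd
    return v[~removed], removed


@dataclasses.dataclass
class BootstrapResult:
    """Resampled treatment-minus-control difference of a group statistic."""

    statistic: str
    B: int
    diffs: np.ndarray
    ci_low: float
    ci_high: float
    p: float
    seed: int
    observed: float   #: point difference statistic(treatment) - statistic(control)

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")
        if not (0 < self.p <= 1):
            raise ValueError("p outside (0, 1]")


_STATISTICS: Mapping[str, Callable[[np.ndarray], np.ndarray]] = {
    "median": lambda a: np.median(a, axis=-1),
    "mean": lambda a: np.mean(a, axis=-1),
}


def bootstrap_difference(
    treatment: Sequence[float],
    control: Sequence[float],
    statistic: str | Callable[[np.ndarray], np.ndarray] = "median",
    B: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Percentile-bootstrap inference on a difference of group statistics.

    Each iteration resamples both groups with replacement at their own
    sizes and records ``statistic(treatment*) - statistic(control*)``.
    The CI is the ``(1 - ci_level)/2`` and ``1 - (1 - ci_level)/2``
    percentile pair; the two-sided p-value is
    ``2 * min(#{diff <= 0}, #{diff >= 0}) / B`` floored at ``1/B`` and
    capped at 1.  Fixed seeds give bit-identical results.
    """
    a = np.asarray(treatment, dtype=np.float64)
    b = np.asarray(control, dtype=np.float64)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    if isinstance(statistic, str):
        try:
            stat_fn = _STATISTICS[statistic]
        except KeyError:
            raise ValueError(f"unknown statistic {statistic!r}") from None
        stat_name = statistic
    else:
        stat_fn, stat_name = statistic, getattr(statistic, "__name__", "custom")
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(B, a.size))
    idx_b = rng.integers(0, b.size, size=(B, b.size))
    diffs = stat_fn(a[idx_a]) - stat_fn(b[idx_b])
    alpha = (1.0 - ci_level) / 2.0
    ci_low, ci_high = np.percentile(diffs, [100 * alpha, 100 * (1 - alpha)])
    p = 2.0 * min(np.count_nonzero(diffs <= 0), np.count_nonzero(diffs >= 0)) / B
    p = float(min(max(p, 1.0 / B), 1.0))
    observed = float(stat_fn(a) - stat_fn(b))
    return BootstrapResult(
        statistic=stat_name, B=B, diffs=diffs,
        ci_low=float(ci_low), ci_high=float(ci_high), p=p, seed=seed,
        observed=observed,
    )


def anova_tukey(groups: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Returns ``{"F": .., "p": .., "pairwise": DataFrame}`` where the pairwise
    table has columns ``group_a, group_b, mean_diff, p_adj``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[name], dtype=np.float64) for name in names]
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    if all(arr.std() == 0 for arr in arrays) and len({a.mean() for a in arrays}) == 1:
        # all observations identical: no variance anywhere, nothing to test
        F, p = 0.0, 1.0
        pairwise = pd.DataFrame(
            [
                dict(group_a=names[i], group_b=names[j], mean_diff=0.0, p_adj=1.0)
                for i in range(len(names))
                for j in range(i + 1, len(names))
            ]
        )
        return {"F": F, "p": p, "pairwise": pairwise}
    F, p = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                dict(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=float(arrays[i].mean() - arrays[j].mean()),
                    p_adj=float(tukey.pvalue[i, j]),
                )
            )
    return {"F": float(F), "p": float(p), "pairwise": pd.DataFrame(rows)}
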