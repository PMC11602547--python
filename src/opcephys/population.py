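"""Conductance-state classification and cohort-level summaries.

Cortical OPC inward conductances are bimodal on a log scale: a low- and a
high-conductance state. The classification procedure histograms log₁₀ g_in,
fits one- and two-Gaussian curves to the bin counts by least squares,
compares them with the extra-sum-of-squares F-test and AIC, and derives
the state boundary as the low component's 90th percentile (where the two
fitted curves meet, ≈2.35 nS in the reference cortical cohort). Cells are
then classed high/low, and group summaries relate state to neuron
density, cell-cycle phase and proliferation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "MixtureFit",
    "TerritoryCount",
    "fit_conductance_mixture",
    "state_threshold",
    "classify_cells",
    "territory_density",
    "group_summaries",
    "DEFAULT_AGE_BINS",
]

#: default age groupings (postnatal days) for proportion tables
DEFAULT_AGE_BINS = ((6, 9), (10, 22), (25, 34), (100, 120), (180, 210))

_Z90 = float(stats.norm.ppf(0.90))


def _gauss1(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _gauss2(x, a1, mu1, s1, a2, mu2, s2):
    return _gauss1(x, a1, mu1, s1) + _gauss1(x, a2, mu2, s2)


@dataclass
class MixtureFit:
    """One- vs two-Gaussian fits to the binned log₁₀ conductance data."""

    log10_g: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    single_params: tuple  # (a, mu, sigma)
    double_params: tuple  # (a1, mu1, s1, a2, mu2, s2) with mu1 < mu2
    r2_single: float
    r2_double: float
    f_statistic: float
    f_df: tuple
    p_value: float
    aic_single: float
    aic_double: float
    preferred: str  # "single" | "double"
    n_excluded_nonpositive: int = 0

    @property
    def aic_preferred(self) -> str:
        return "double" if self.aic_double < self.aic_single else "single"


def _fit_curve(x, y, sigma, model, p0, bounds):
    popt, _ = curve_fit(model, x, y, p0=p0, bounds=bounds, sigma=sigma, maxfev=20_000)
    ss = float(np.sum(((y - model(x, *popt)) / sigma) ** 2))
    return popt, ss


def _aicc(n: int, ss: float, k: int) -> float:
    """Least-squares AIC with small-sample correction."""
    aic = n * np.log(max(ss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def fit_conductance_mixture(g_values_ns, bins: int | str = "sqrt") -> MixtureFit:
    """Fit the population curve of log₁₀-transformed inward conductance.

    Non-positive conductances are excluded (count reported). Bin counts
    (√n bins by default, which resolves both modes at cohort sizes of a
    few hundred cells) are fitted with one and two Gaussian curves by
    weighted least squares, each bin weighted by its Poisson standard
    deviation √max(count, 1); the nested models are compared with the
    extra-sum-of-squares F-test and AICc. Component σ is bounded below by
    one bin width so a component cannot collapse onto a single bin; both
    safeguards keep the F-test's type-I error near nominal on Poisson bin
    counts.
    """
    g = np.asarray(g_values_ns, dtype=float)
    n_bad = int(np.sum(~(g > 0)))
    g = g[g > 0]
    if len(g) < 10:
        raise ValueError("need at least 10 positive conductances")
    if len(g) < 30:
        import warnings

        warnings.warn(f"only {len(g)} cells; mixture fit may be unstable", stacklevel=2)
    x = np.log10(g)
    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = edges[1] - edges[0]
    n_bins = len(counts)
    y = counts.astype(float)

    lo, hi = x.min() - w, x.max() + w
    s_min, s_max = w, (hi - lo)
    a_max = 3.0 * y.max() + 1.0
    sigma = np.sqrt(np.maximum(y, 1.0))

    p1, ss1 = _fit_curve(
        centers, y, sigma, _gauss1,
        p0=[y.max(), float(np.mean(x)), max(float(np.std(x)), s_min)],
        bounds=([0, lo, s_min], [a_max, hi, s_max]),
    )

    # two-Gaussian fit: try several starts, keep the best SS
    q = np.quantile(x, [0.25, 0.5, 0.75])
    iqr_s = max((q[2] - q[0]) / 2.0, s_min)
    starts = [
        [y.max(), q[0], iqr_s, y.max(), q[2], iqr_s],
        [y.max(), q[1] - iqr_s, iqr_s, y.max() / 2, q[1] + iqr_s, iqr_s],
        [y.max() / 2, q[1] - 2 * iqr_s, iqr_s, y.max(), q[1] + iqr_s / 2, iqr_s],
    ]
    best = None
    for p0 in starts:
        try:
            p2, ss2 = _fit_curve(
                centers, y, sigma, _gauss2, p0=p0,
                bounds=([0, lo, s_min, 0, lo, s_min], [a_max, hi, s_max, a_max, hi, s_max]),
            )
        except (RuntimeError, ValueError):
            continue
        if best is None or ss2 < best[1]:
            best = (p2, ss2)
    if best is None:
        raise RuntimeError("two-Gaussian fit failed from all starting points")
    p2, ss2 = best
    if p2[1] > p2[4]:  # order components so mu1 < mu2
        p2 = np.concatenate([p2[3:], p2[:3]])

    # unweighted R^2 on the raw counts, for comparability with curve-fitting
    # software reports
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_1 = 1.0 - float(np.sum((y - _gauss1(centers, *p1)) ** 2)) / ss_tot if ss_tot > 0 else np.nan
    r2_2 = 1.0 - float(np.sum((y - _gauss2(centers, *p2)) ** 2)) / ss_tot if ss_tot > 0 else np.nan

    df_extra = 3
    df2 = n_bins - 6
    df1 = df2 + df_extra
    if df2 <= 0:
        raise ValueError(f"only {n_bins} bins; too few for the nested F-test")
    if ss2 <= 0 or ss1 <= ss2 * (1 + 1e-12):
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat = ((ss1 - ss2) / df_extra) / (ss2 / df2)
        p_val = float(stats.f.sf(f_stat, df_extra, df2))
    aic1 = _aicc(n_bins, ss1, 3)
    aic2 = _aicc(n_bins, ss2, 6)
    preferred = "double" if p_val < 0.05 else "single"
    return MixtureFit(
        log10_g=x, bin_edges=edges, counts=counts,
        single_params=tuple(float(v) for v in p1),
        double_params=tuple(float(v) for v in p2),
        r2_single=float(r2_1), r2_double=float(r2_2),
        f_statistic=float(f_stat), f_df=(df_extra, df2), p_value=float(p_val),
        aic_single=aic1, aic_double=aic2,
        preferred=preferred, n_excluded_nonpositive=n_bad,
    )


def state_threshold(fit: MixtureFit, percentile: float = 0.90) -> tuple[float, dict]:
    """State boundary in nS from the two-Gaussian fit.

    Primary reading: the low component's ``percentile`` point,
    10^(μ₁ + z_p·σ₁). The symmetric reading from the high component,
    10^(μ₂ − z_p·σ₂), is also computed and the discrepancy reported, since
    at the boundary the two population curves meet.
    """
    if fit.preferred != "double":
        raise ValueError("no state threshold: the single-Gaussian model is preferred")
    z = float(stats.norm.ppf(percentile))
    _, mu1, s1, _, mu2, s2 = fit.double_params
    thr_low = 10.0 ** (mu1 + z * s1)
    thr_high = 10.0 ** (mu2 - z * s2)
    info = {
        "threshold_low_component_ns": thr_low,
        "threshold_high_component_ns": thr_high,
        "discrepancy_ns": abs(thr_low - thr_high),
        "percentile": percentile,
    }
    return float(thr_low), info


def classify_cells(cohort: pd.DataFrame, threshold_ns: float) -> pd.DataFrame:
    """Add a ``state`` column (high iff g_in > threshold) and return a copy.

    Also attaches per-(region, age) high-state proportions as
    ``df.attrs["state_proportions"]``.
    """
    if threshold_ns <= 0:
        raise ValueError("threshold must be positive")
    df = cohort.copy()
    df["state"] = np.where(df["g_in_ns"] > threshold_ns, "high", "low")
    keys = [k for k in ("region", "age_days") if k in df.columns]
    if keys:
        prop = (
            df.assign(is_high=df["state"] == "high")
            .groupby(keys, observed=True)["is_high"]
            .agg(["mean", "count"])
            .rename(columns={"mean": "prop_high", "count": "n"})
        )
        df.attrs["state_proportions"] = prop
    return df


@dataclass
class TerritoryCount:
    """Neuron/vessel counts inside a circle around one OPC soma (µm)."""

    center_um: tuple = (0.0, 0.0)
    diameter_um: float = 80.0
    neun_count: int = 0
    vessel_count: int = 0

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.neun_count < 0 or self.vessel_count < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_points(cls, center_um, diameter_um, neun_points_um, vessel_points_um=()):
        """Count points falling inside the circle (boundary-inclusive)."""
        def count(points):
            if len(points) == 0:
                return 0
            pts = np.asarray(points, dtype=float).reshape(-1, 2)
            d = np.hypot(pts[:, 0] - center_um[0], pts[:, 1] - center_um[1])
            return int(np.sum(d <= diameter_um / 2.0))

        return cls(tuple(center_um), diameter_um, count(neun_points_um), count(vessel_points_um))

    @property
    def density_class(self) -> str:
        """'high' iff more than 5 NeuN⁺ somata lie in the territory."""
        return "high" if self.neun_count > 5 else "low"


def territory_density(territory: TerritoryCount) -> str:
    return territory.density_class


def group_summaries(
    cohort: pd.DataFrame,
    by,
    metrics=("rmp_mv", "rm_mohm", "g_in_ns"),
    proliferation_col: str = "edu_positive",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group n / mean ± SEM for the passive metrics, plus the
    proliferation fraction, and pairwise comparisons.

    Two groups: Welch t-test per metric. More: one-way ANOVA followed by
    pairwise Welch tests with Holm–Bonferroni correction. Returns
    (summary table, tests table).
    """
    by = [by] if isinstance(by, str) else list(by)
    for key in by:
        if key not in cohort.columns:
            raise ValueError(f"grouping key {key!r} not in cohort")
    grouped = cohort.groupby(by[0] if len(by) == 1 else by, observed=True)
    if any(len(g) == 0 for _, g in grouped):
        raise ValueError("empty group")
    rows = []
    for name, g in grouped:
        row = {"group": name if isinstance(name, str) else "/".join(map(str, np.atleast_1d(name)))}
        row["n"] = len(g)
        for m in metrics:
            if m in g:
                vals = g[m].dropna()
                row[f"{m}_mean"] = vals.mean()
                row[f"{m}_sem"] = vals.sem()
        if proliferation_col in g:
            row["proliferation_fraction"] = float(g[proliferation_col].mean())
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("group")

    tests = []
    names = list(grouped.groups)
    for m in metrics:
        if m not in cohort.columns:
            continue
        samples = [grouped.get_group(n)[m].dropna().to_numpy() for n in names]
        samples = [s for s in samples if len(s) > 1]
        if len(samples) < 2:
            continue
        if len(samples) > 2:
            f, p_anova = stats.f_oneway(*samples)
            tests.append({"metric": m, "comparison": "ANOVA", "stat": f, "p": p_anova, "p_adj": p_anova})
        pair_rows = []
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                t, p = stats.ttest_ind(samples[i], samples[j], equal_var=False)
                pair_rows.append({"metric": m, "comparison": f"{names[i]} vs {names[j]}",
                                  "stat": t, "p": p})
        if pair_rows:
            from statsmodels.stats.multitest import multipletests

            p_adj = multipletests([r["p"] for r in pair_rows], method="holm")[1]
            for r, pa in zip(pair_rows, p_adj):
                r["p_adj"] = pa
            tests.extend(pair_rows)
    return summary, pd.DataFrame(tests)
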