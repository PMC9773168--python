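"""Inferential battery over the stratified cohort.

The analysis proceeds in the classical planned-comparison workflow:

1. Initial pooled-variance Student's t-tests on coarsely lumped groups
   (all healthy vs all unhealthy; all male vs all female) at α = 0.05.
2. A one-way ANOVA per variable across the 12 stratification cells.
3. When the omnibus ANOVA reaches p ≤ 0.05, a fixed set of 17 planned
   contrasts is evaluated with the pooled within-group MSE, judged against
   a Bonferroni-corrected threshold (0.05/17 rounded to 3 decimals =
   0.003), each accompanied by a percentile bootstrap CI of the effect.
4. Pearson correlations of each variable with age and BSA within the four
   lumped sex × health groups, with bootstrap CIs; disagreement between the
   parametric p-value and the CI is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline import ANALYSIS_VARIABLES

__all__ = [
    "ContrastSpec",
    "TestResult",
    "CorrelationResult",
    "BatteryResult",
    "students_t",
    "oneway_anova",
    "planned_contrast",
    "bonferroni_alpha",
    "bootstrap_ci",
    "pearson",
    "default_contrasts",
    "run_battery",
]

CORRELATION_VARIABLES = ("EDV", "ESV", "ESVi", "LVEF", "ACS", "MCS", "BCS", "GCS")


@dataclass(frozen=True)
class ContrastSpec:
    """A zero-sum weighted comparison between unions of cells.

    ``weights`` maps cell labels (``sex_health_ageband``) to weights; cells
    absent from the mapping carry weight 0.
    """

    name: str
    weights: dict

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if w.size < 2 or not np.isclose(w.sum(), 0.0):
            raise ValueError(f"contrast {self.name!r}: weights must sum to 0 over >= 2 cells")
        if not ((w > 0).any() and (w < 0).any()):
            raise ValueError(f"contrast {self.name!r}: needs positive and negative weights")


@dataclass
class TestResult:
    """One hypothesis test: statistic, df, p, optional bootstrap CI."""

    variable: str
    comparison: str
    statistic: float
    df: float
    p: float
    estimate: float | None = None
    ci: tuple | None = None
    threshold: float = 0.05
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return bool(self.p <= self.threshold)


@dataclass
class CorrelationResult:
    """Pearson correlation of one variable with age or BSA in a lumped group."""

    group: str
    variable: str
    against: str
    r: float
    p: float
    n: int
    ci: tuple | None = None
    threshold: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p <= self.threshold)

    @property
    def ci_disagrees(self) -> bool:
        """True when the bootstrap CI contradicts the parametric decision."""
        if self.ci is None:
            return False
        excludes_zero = not (self.ci[0] <= 0.0 <= self.ci[1])
        return excludes_zero != self.significant


def students_t(sample_a, sample_b, *, threshold: float = 0.05,
               variable: str = "", comparison: str = "") -> TestResult:
    """Two-sample pooled-variance (Student's) t-test, two-sided.

    Degenerate inputs — zero pooled variance — give t = 0, p = 1 when the
    means agree and an infinite statistic with p = 0 (flagged) otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return TestResult(variable, comparison, 0.0, df, 1.0, estimate=0.0,
                              threshold=threshold, degenerate=True)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TestResult(variable, comparison, float(t), df, 0.0,
                          estimate=float(a.mean() - b.mean()), threshold=threshold,
                          degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(variable, comparison, float(t), float(df), float(p),
                      estimate=float(a.mean() - b.mean()), threshold=threshold)


def oneway_anova(groups) -> tuple[float, int, int, float]:
    """One-way ANOVA over a list/dict of samples → (F, df_between, df_within, p)."""
    samples = list(groups.values()) if isinstance(groups, dict) else list(groups)
    samples = [np.asarray(g, dtype=float) for g in samples if len(g) > 0]
    if len(samples) < 2:
        raise ValueError("ANOVA needs >= 2 nonempty groups")
    n_total = sum(s.size for s in samples)
    k = len(samples)
    df1, df2 = k - 1, n_total - k
    if df2 <= 0:
        raise ValueError("ANOVA undefined: no within-group degrees of freedom")
    f, p = sps.f_oneway(*samples)
    return float(f), df1, df2, float(p)


def _pooled_mse(samples: list[np.ndarray]) -> tuple[float, int]:
    df = sum(s.size - 1 for s in samples)
    if df <= 0:
        raise ValueError("no within-group degrees of freedom for pooled MSE")
    ss = sum(float(((s - s.mean()) ** 2).sum()) for s in samples)
    return ss / df, df


def planned_contrast(
    groups: dict,
    spec: ContrastSpec,
    *,
    threshold: float = 0.05,
    variable: str = "",
    use_omnibus_mse: bool = True,
) -> TestResult:
    """ANOVA planned contrast Σ wᵢ·meanᵢ with pooled within-group MSE.

    ``groups`` maps cell labels to samples; the MSE pools over every
    nonempty cell (the omnibus error term) unless ``use_omnibus_mse`` is
    False, in which case only the cells the contrast touches contribute.
    """
    touched = {k: np.asarray(groups[k], dtype=float) for k, w in spec.weights.items() if w != 0.0}
    for label, sample in touched.items():
        if label not in groups or sample.size == 0:
            raise ValueError(f"contrast {spec.name!r} touches empty cell {label!r}")
    pool = [np.asarray(g, dtype=float) for g in groups.values() if len(g) > 0] \
        if use_omnibus_mse else list(touched.values())
    mse, df = _pooled_mse(pool)
    estimate = sum(w * touched[k].mean() for k, w in spec.weights.items() if w != 0.0)
    scale = sum(w**2 / touched[k].size for k, w in spec.weights.items() if w != 0.0)
    se = np.sqrt(mse * scale)
    if se == 0.0:
        p = 1.0 if np.isclose(estimate, 0.0) else 0.0
        t = 0.0 if p == 1.0 else np.sign(estimate) * np.inf
        return TestResult(variable, spec.name, float(t), df, p, estimate=float(estimate),
                          threshold=threshold, degenerate=True)
    t = estimate / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(variable, spec.name, float(t), df, float(p),
                      estimate=float(estimate), threshold=threshold)


def bonferroni_alpha(m: int, alpha: float = 0.05, decimals: int = 3) -> float:
    """Familywise-corrected per-test threshold, rounded as reported.

    round(α/m, decimals) — e.g. 17 contrasts at α 0.05 → 0.003.
    """
    if m < 1:
        raise ValueError(f"number of comparisons must be >= 1, got {m}")
    return round(alpha / m, decimals)


def bootstrap_ci(
    data,
    statistic=np.mean,
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of ``statistic`` under case resampling."""
    x = np.asarray(data, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap needs n >= 2")
    if reps < 100:
        raise ValueError("use >= 100 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(reps, x.size))
    stats = np.apply_along_axis(statistic, 1, x[idx])
    lo, hi = np.percentile(stats, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return float(lo), float(hi)


def _bootstrap_contrast_ci(
    touched: dict, weights: dict, reps: int, rng: np.random.Generator, level: float = 0.95
) -> tuple[float, float]:
    """Percentile CI of a contrast estimate, resampling within each cell."""
    draws = np.zeros(reps)
    for label, sample in touched.items():
        idx = rng.integers(0, sample.size, size=(reps, sample.size))
        draws += weights[label] * sample[idx].mean(axis=1)
    lo, hi = np.percentile(draws, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return float(lo), float(hi)


def pearson(
    x,
    y,
    *,
    group: str = "",
    variable: str = "",
    against: str = "",
    bootstrap_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CorrelationResult:
    """Pearson r with two-sided t-transform p-value and bootstrap CI of r."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r, p = sps.pearsonr(xv, yv)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.empty(bootstrap_reps)
    for i in range(bootstrap_reps):
        idx = rng.integers(0, xv.size, size=xv.size)
        xs, ys = xv[idx], yv[idx]
        draws[i] = sps.pearsonr(xs, ys)[0] if xs.std() > 0 and ys.std() > 0 else np.nan
    lo, hi = np.nanpercentile(draws, [2.5, 97.5])
    return CorrelationResult(group=group, variable=variable, against=against,
                             r=float(r), p=float(p), n=int(xv.size), ci=(float(lo), float(hi)))


def _cell(sex: str, health: str, band: str) -> str:
    return f"{sex}_{health}_{band}"


def default_contrasts(cell_sizes: dict | None = None) -> list[ContrastSpec]:
    """The 17 planned comparisons.

    Lumped sides use equal ±1/k weights per constituent cell by default;
    passing ``cell_sizes`` (label → n) switches to per-cell-n proportional
    weights, so each lumped side estimates the pooled rather than the
    cell-averaged mean.
    """
    bands = ("45-54", "55-64", "65-74")

    def pair(name, a, b):
        return ContrastSpec(name, {a: 1.0, b: -1.0})

    def lumped(name, side_a, side_b):
        if cell_sizes is None:
            w = {c: 1.0 / len(side_a) for c in side_a}
            w.update({c: -1.0 / len(side_b) for c in side_b})
        else:
            tot_a = sum(cell_sizes[c] for c in side_a)
            tot_b = sum(cell_sizes[c] for c in side_b)
            w = {c: cell_sizes[c] / tot_a for c in side_a}
            w.update({c: -cell_sizes[c] / tot_b for c in side_b})
        return ContrastSpec(name, w)

    fh = [_cell("female", "healthy", b) for b in bands]
    mh = [_cell("male", "healthy", b) for b in bands]
    fu = [_cell("female", "unhealthy", b) for b in bands]
    mu = [_cell("male", "unhealthy", b) for b in bands]

    return [
        pair("Female Healthy 45-54 vs Female Healthy 55-64", fh[0], fh[1]),
        pair("Female Healthy 45-54 vs Female Healthy 65-74", fh[0], fh[2]),
        pair("Female Healthy 55-64 vs Female Healthy 65-74", fh[1], fh[2]),
        pair("Female Healthy 45-54 vs Male Healthy 45-54", fh[0], mh[0]),
        pair("Female Healthy 55-64 vs Male Healthy 55-64", fh[1], mh[1]),
        pair("Female Healthy 65-74 vs Male Healthy 65-74", fh[2], mh[2]),
        pair("Male Healthy 45-54 vs Male Healthy 55-64", mh[0], mh[1]),
        pair("Male Healthy 45-54 vs Male Healthy 65-74", mh[0], mh[2]),
        pair("Male Healthy 55-64 vs Male Healthy 65-74", mh[1], mh[2]),
        pair("Male Healthy 65-74 vs Male Unhealthy 65-74", mh[2], mu[2]),
        pair("Female Healthy 65-74 vs Female Unhealthy 65-74", fh[2], fu[2]),
        pair("Male Healthy 55-64 vs Male Unhealthy 55-64", mh[1], mu[1]),
        pair("Male Unhealthy 55-64 vs Male Unhealthy 65-74", mu[1], mu[2]),
        lumped("All Males Healthy vs All Females Healthy", mh, fh),
        lumped("All Females Healthy vs All Females Unhealthy", fh, fu),
        lumped("All Males Healthy vs All Males Unhealthy", mh, mu),
        lumped("All Females Unhealthy vs All Males Unhealthy", fu, mu),
    ]


@dataclass
class BatteryResult:
    """Everything the inferential battery produces, as tidy tables."""

    t_tests: pd.DataFrame
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    contrast_threshold: float
    errors: list = field(default_factory=list)

    @property
    def significant_contrasts(self) -> pd.DataFrame:
        """Contrast rows at or below the corrected threshold (report style)."""
        if self.contrasts.empty:
            return self.contrasts
        hits = self.contrasts[self.contrasts["significant"]]
        return hits[["comparison", "variable", "p"]].reset_index(drop=True)


def _result_rows(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable, "comparison": r.comparison,
                "statistic": r.statistic, "df": r.df, "p": r.p,
                "estimate": r.estimate,
                "ci_lo": r.ci[0] if r.ci else np.nan,
                "ci_hi": r.ci[1] if r.ci else np.nan,
                "threshold": r.threshold, "significant": r.significant,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )


def run_battery(
    table: pd.DataFrame,
    *,
    variables: tuple = ANALYSIS_VARIABLES,
    contrasts: list[ContrastSpec] | None = None,
    alpha: float = 0.05,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    anova_gate: bool = True,
) -> BatteryResult:
    """Run the full inferential procedure on a measured subject table.

    ``table`` needs ``sex``, ``health``, ``age_band``, ``age`` columns plus
    the analysis variables.  Per-test failures are recorded in
    ``errors`` and never abort the batch.
    """
    contrasts = contrasts if contrasts is not None else default_contrasts()
    threshold = bonferroni_alpha(len(contrasts), alpha)
    rng = np.random.default_rng(seed)
    errors: list[str] = []

    labels = table["sex"] + "_" + table["health"] + "_" + table["age_band"]

    t_rows: list[TestResult] = []
    for var in variables:
        vals = table[var].astype(float)
        lumps = [
            ("all healthy vs all unhealthy", table["health"] == "healthy", table["health"] == "unhealthy"),
            ("all male vs all female", table["sex"] == "male", table["sex"] == "female"),
        ]
        for name, mask_a, mask_b in lumps:
            try:
                t_rows.append(
                    students_t(vals[mask_a].dropna(), vals[mask_b].dropna(),
                               threshold=alpha, variable=var, comparison=name)
                )
            except Exception as exc:  # degenerate lump sizes
                errors.append(f"t-test {var} {name}: {exc}")

    anova_rows = []
    contrast_rows: list[TestResult] = []
    for var in variables:
        cells = {
            lbl: sub[var].dropna().to_numpy(dtype=float)
            for lbl, sub in table.groupby(labels)
        }
        cells = {k: v for k, v in cells.items() if v.size > 0}
        try:
            f, df1, df2, p = oneway_anova(cells)
        except Exception as exc:
            errors.append(f"ANOVA {var}: {exc}")
            continue
        anova_rows.append({"variable": var, "F": f, "df1": df1, "df2": df2, "p": p,
                           "gate_passed": (p <= alpha) or not anova_gate})
        if anova_gate and p > alpha:
            continue
        for spec in contrasts:
            try:
                res = planned_contrast(cells, spec, threshold=threshold, variable=var)
                touched = {k: cells[k] for k, w in spec.weights.items() if w != 0.0}
                res.ci = _bootstrap_contrast_ci(touched, spec.weights, bootstrap_reps, rng)
                contrast_rows.append(res)
            except Exception as exc:
                errors.append(f"contrast {var} {spec.name}: {exc}")

    corr_rows = []
    lumped_groups = {
        "healthy females": (table["health"] == "healthy") & (table["sex"] == "female"),
        "healthy males": (table["health"] == "healthy") & (table["sex"] == "male"),
        "unhealthy females": (table["health"] == "unhealthy") & (table["sex"] == "female"),
        "unhealthy males": (table["health"] == "unhealthy") & (table["sex"] == "male"),
    }
    for gname, mask in lumped_groups.items():
        sub = table[mask]
        for var in CORRELATION_VARIABLES:
            if var not in sub.columns:
                continue
            for against in ("age", "BSA"):
                pair = sub[[against, var]].dropna()
                try:
                    res = pearson(pair[against], pair[var], group=gname, variable=var,
                                  against=against, bootstrap_reps=bootstrap_reps, seed=rng)
                    corr_rows.append(
                        {"group": gname, "variable": var, "against": against,
                         "r": res.r, "p": res.p, "n": res.n,
                         "ci_lo": res.ci[0], "ci_hi": res.ci[1],
                         "significant": res.significant, "ci_disagrees": res.ci_disagrees}
                    )
                except Exception as exc:
                    errors.append(f"correlation {gname} {var}~{against}: {exc}")

    return BatteryResult(
        t_tests=_result_rows(t_rows),
        anova=pd.DataFrame(anova_rows),
        contrasts=_result_rows(contrast_rows),
        correlations=pd.DataFrame(corr_rows),
        contrast_threshold=threshold,
        errors=errors,
    )
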