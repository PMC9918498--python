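"""Tight-binding inhibitor kinetics.

A tight-binding inhibitor depletes the free-inhibitor pool, so classical
Michaelis-Menten inhibition analysis is invalid. Two estimators of the
dissociation constant K_D are provided, both operating on a residual
activity titration (fractional activity v_i/v_0 versus total inhibitor):

* the stoichiometric titration estimator: the rectilinear descending
  limb of the titration extrapolates to the equivalence point (an
  estimate of total enzyme [E]_t); the residual activity there gives the
  free-enzyme fraction and K_D = [E][I]/[EI];
* a direct weighted least-squares fit of the Morrison (tight-binding
  quadratic) activity model.

Helper operations cover percent inhibition, pre-incubation plateau
detection and unpaired two-sample comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (DegenerateTitrationError, FitError, ValidationError)

__all__ = [
    "TitrationSeries", "ProgressSeries", "KineticEstimate", "EquivalenceResult",
    "TightBindingTitration", "percent_inhibition", "morrison_activity",
    "titration_equivalence", "kd_stoichiometric", "fit_morrison",
    "preincubation_plateau", "compare_groups", "relative_potency",
    "molar_from_mass_conc",
]


@dataclass(frozen=True)
class TitrationSeries:
    """Residual-activity titration of an enzyme by a tight-binding inhibitor.

    All concentrations are held in nM internally. ``activity`` is the
    fractional residual rate v_i/v_0 (1 at zero inhibitor by
    normalization; values slightly above 1 reflect assay noise).
    """

    inhibitor_nM: np.ndarray
    activity: np.ndarray
    replicate: np.ndarray
    enzyme_total_nM: float | None = None

    def __post_init__(self):
        inh = np.asarray(self.inhibitor_nM, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        rep = np.asarray(self.replicate, dtype=int)
        if not (inh.shape == act.shape == rep.shape) or inh.ndim != 1:
            raise ValidationError("inhibitor_nM/activity/replicate: equal-length 1-d arrays required")
        if np.any(inh < 0):
            raise ValidationError("inhibitor_nM: concentrations must be >= 0")
        for r in np.unique(rep):
            grid = inh[rep == r]
            if np.any(np.diff(grid) <= 0):
                raise ValidationError(f"inhibitor_nM: grid must be strictly increasing within replicate {r}")
        if self.enzyme_total_nM is not None and self.enzyme_total_nM <= 0:
            raise ValidationError("enzyme_total_nM: must be positive")
        object.__setattr__(self, "inhibitor_nM", inh)
        object.__setattr__(self, "activity", act)
        object.__setattr__(self, "replicate", rep)

    @property
    def grid(self) -> np.ndarray:
        """Unique inhibitor concentrations, ascending."""
        return np.unique(self.inhibitor_nM)

    def mean_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-averaged activity on the common grid."""
        grid = self.grid
        mean = np.array([self.activity[self.inhibitor_nM == g].mean() for g in grid])
        return grid, mean

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, enzyme_total_nM: float | None = None):
        """Build from columns ``inhibitor_nM`` (or ``inhibitor_uM``),
        ``replicate`` and ``activity_fraction``."""
        if "inhibitor_nM" in df:
            inh = df["inhibitor_nM"].to_numpy(float)
        elif "inhibitor_uM" in df:
            inh = df["inhibitor_uM"].to_numpy(float) * 1e3
        else:
            raise ValidationError("dataframe: need an inhibitor_nM or inhibitor_uM column")
        rep = df["replicate"].to_numpy(int) if "replicate" in df else np.zeros(len(df), int)
        return cls(inh, df["activity_fraction"].to_numpy(float), rep, enzyme_total_nM)

    @classmethod
    def from_csv(cls, path, enzyme_total_nM: float | None = None):
        return cls.from_dataframe(pd.read_csv(path), enzyme_total_nM)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"inhibitor_nM": self.inhibitor_nM,
                             "replicate": self.replicate,
                             "activity_fraction": self.activity})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class ProgressSeries:
    """Residual activity as a function of pre-incubation time (minutes)."""

    time_min: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        a = np.asarray(self.activity, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValidationError("time_min/activity: equal-length 1-d arrays required")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("time_min: must be non-negative and increasing")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "activity", a)


@dataclass(frozen=True)
class EquivalenceResult:
    """Rectilinear extrapolation of a titration to the concentration axis."""

    equivalence_nM: float
    activity_at_equivalence: float
    slope: float
    intercept: float
    region: np.ndarray          # grid points used for the linear fit
    r_squared: float
    rectilinear: bool           # True when the region met the R^2 criterion


@dataclass(frozen=True)
class KineticEstimate:
    """K_D estimate with the species concentrations that imply it."""

    kd: float
    equivalence_point: float
    free_enzyme: float
    free_inhibitor: float
    complex_conc: float
    se_kd: float | None
    method: str
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Tight-binding K_D estimate ({self.method})",
            "-" * 44,
            f"K_D                 {self.kd:10.3f} nM"
            + (f"  (SE {self.se_kd:.3f})" if self.se_kd is not None else ""),
            f"equivalence point   {self.equivalence_point:10.3f} nM",
            f"[E] free            {self.free_enzyme:10.3f} nM",
            f"[I] free            {self.free_inhibitor:10.3f} nM",
            f"[EI] complex        {self.complex_conc:10.3f} nM",
        ]
        for k, v in self.diagnostics.items():
            lines.append(f"{k:<19} {v}")
        return "\n".join(lines)


def molar_from_mass_conc(ng_per_uL: float, mw_da: float) -> float:
    """Convert a mass concentration (ng/µL) to nM given the molar mass."""
    if ng_per_uL < 0 or mw_da <= 0:
        raise ValidationError("ng_per_uL must be >= 0 and mw_da > 0")
    return ng_per_uL * 1e6 / mw_da


def percent_inhibition(test_rate: float, control_rate: float) -> float:
    """Percent inhibition relative to the uninhibited control rate."""
    if control_rate <= 0:
        raise ValidationError("control_rate: must be positive")
    if test_rate < 0:
        raise ValidationError("test_rate: must be >= 0")
    return float(np.clip(100.0 * (1.0 - test_rate / control_rate), 0.0, 100.0))


def morrison_activity(enzyme_total, inhibitor_total, kd):
    """Fractional activity under the tight-binding (Morrison) equilibrium.

    a = 1 - ([E]+[I]+K - sqrt(([E]+[I]+K)^2 - 4[E][I])) / (2[E]),
    the physical root of the equilibrium mass balance. Vectorized over
    ``inhibitor_total``.
    """
    E = float(enzyme_total)
    I = np.asarray(inhibitor_total, dtype=float)
    K = float(kd)
    if E <= 0:
        raise ValidationError("enzyme_total: must be positive")
    if np.any(I < 0) or K < 0:
        raise ValidationError("inhibitor_total and kd must be >= 0")
    s = E + I + K
    a = 1.0 - (s - np.sqrt(s * s - 4.0 * E * I)) / (2.0 * E)
    a = np.clip(a, 0.0, 1.0)
    return float(a) if np.isscalar(inhibitor_total) else a


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def titration_equivalence(series: TitrationSeries, min_points: int = 4,
                          r2_min: float = 0.99) -> EquivalenceResult:
    """Extrapolate the rectilinear portion of a titration to zero activity.

    The rectilinear region defaults to the longest prefix of grid points
    (ascending inhibitor) whose linear fit achieves R^2 >= ``r2_min``
    with at least ``min_points`` points. When no prefix qualifies (a
    coarse grid samples the curved approach to equivalence), the initial
    ``min_points`` prefix is used and the result is flagged
    ``rectilinear=False``; the x-intercept then overestimates total
    enzyme and should be treated as a diagnostic, not an estimate.
    """
    grid, mean = series.mean_curve()
    if len(grid) < min_points:
        raise ValidationError(f"series: at least {min_points} grid points required")
    if mean[-1] >= mean[0]:
        raise ValidationError("series: activities must decrease overall")
    best = None
    for m in range(min_points, len(grid) + 1):
        slope, intercept, r2 = _linfit(grid[:m], mean[:m])
        if r2 >= r2_min and slope < 0:
            best = (m, slope, intercept, r2, True)
    if best is None:
        slope, intercept, r2 = _linfit(grid[:min_points], mean[:min_points])
        if slope >= 0:
            raise ValidationError("series: rectilinear fit has non-negative slope")
        best = (min_points, slope, intercept, r2, False)
    m, slope, intercept, r2, ok = best
    x_int = -intercept / slope
    a_eq = float(np.interp(x_int, grid, mean))
    return EquivalenceResult(equivalence_nM=float(x_int), activity_at_equivalence=a_eq,
                             slope=slope, intercept=intercept, region=grid[:m],
                             r_squared=r2, rectilinear=ok)


def kd_stoichiometric(series: TitrationSeries, enzyme_total: float | None = None,
                      n_boot: int = 200, seed: int = 0) -> KineticEstimate:
    """Stoichiometric titration estimate of K_D.

    The equivalence point is total enzyme [E]_t: the supplied (or
    series-attached) enzyme concentration when known, otherwise the
    rectilinear x-intercept. The residual activity there, interpolated
    from the observed curve, is the free-enzyme fraction a_eq, whence
    [E] = a_eq·[E]_t, [I] = [E] (free inhibitor equals free enzyme at
    equivalence), [EI] = [E]_t - [E] and K_D = [E][I]/[EI].

    The standard error is a nonparametric bootstrap over replicates when
    two or more are present.
    """
    eq = titration_equivalence(series)
    e_total = enzyme_total or series.enzyme_total_nM or eq.equivalence_nM

    def estimate(sub: TitrationSeries) -> float:
        grid, mean = sub.mean_curve()
        a_eq = float(np.interp(e_total, grid, mean))
        if not 0.0 < a_eq < 1.0:
            raise DegenerateTitrationError(
                f"activity at equivalence is {a_eq:.3f}; titration does not "
                "bracket the equivalence point")
        e_free = a_eq * e_total
        return e_free * e_free / (e_total - e_free)

    kd = estimate(series)
    a_eq = float(np.interp(e_total, *series.mean_curve()))
    e_free = a_eq * e_total

    se = None
    reps = np.unique(series.replicate)
    if len(reps) >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            chosen = rng.choice(reps, size=len(reps), replace=True)
            parts = [series.to_dataframe()[series.replicate == r].assign(replicate=i)
                     for i, r in enumerate(chosen)]
            sub = TitrationSeries.from_dataframe(pd.concat(parts, ignore_index=True))
            try:
                boots.append(estimate(sub))
            except DegenerateTitrationError:
                continue
        if len(boots) >= 2:
            se = float(np.std(boots, ddof=1))

    return KineticEstimate(
        kd=kd, equivalence_point=float(e_total), free_enzyme=e_free,
        free_inhibitor=e_free, complex_conc=e_total - e_free, se_kd=se,
        method="stoichiometric",
        diagnostics={"activity_at_equivalence": round(a_eq, 6),
                     "extrapolated_intercept_nM": round(eq.equivalence_nM, 3),
                     "rectilinear": eq.rectilinear,
                     "region_r_squared": round(eq.r_squared, 5)})


def fit_morrison(series: TitrationSeries, enzyme_total: float | None = None,
                 weighted: bool = False) -> KineticEstimate:
    """Least-squares fit of the Morrison activity model.

    Fits K_D alone when ``enzyme_total`` is supplied (or attached to the
    series), otherwise (K_D, [E]_t) jointly. ``weighted=True`` weights
    residuals by 1/max(a, 0.05), matching a multiplicative error model.
    """
    grid, mean = series.mean_curve()
    if len(grid) < 5:
        raise ValidationError("series: at least 5 grid points required for a Morrison fit")
    e_fixed = enzyme_total or series.enzyme_total_nM
    eq_guess = e_fixed
    if eq_guess is None:
        try:
            eq_guess = titration_equivalence(series).equivalence_nM
        except ValidationError:
            eq_guess = np.median(grid[grid > 0])
    sigma = np.maximum(mean, 0.05) if weighted else None

    if e_fixed is not None:
        def f(I, kd):
            return morrison_activity(e_fixed, I, kd)
        p0, bounds = [max(eq_guess / 10.0, 1e-6)], (0.0, np.inf)
    else:
        def f(I, kd, et):
            return morrison_activity(et, I, kd)
        p0 = [max(eq_guess / 10.0, 1e-6), eq_guess]
        bounds = ([0.0, 1e-9], [np.inf, np.inf])

    try:
        popt, pcov = optimize.curve_fit(f, grid, mean, p0=p0, sigma=sigma,
                                        bounds=bounds, maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"Morrison fit did not converge: {exc}",
                       diagnostics={"p0": p0, "n_points": len(grid)}) from exc

    kd = float(popt[0])
    e_total = float(e_fixed if e_fixed is not None else popt[1])
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None
    a_eq = morrison_activity(e_total, e_total, kd)
    e_free = a_eq * e_total
    return KineticEstimate(
        kd=kd, equivalence_point=e_total, free_enzyme=e_free,
        free_inhibitor=e_free, complex_conc=e_total - e_free, se_kd=se,
        method="morrison",
        diagnostics={"enzyme_total_fitted": e_fixed is None,
                     "rss": float(np.sum((f(grid, *popt) - mean) ** 2))})


def preincubation_plateau(series: ProgressSeries, tol: float = 0.02):
    """Smallest pre-incubation time after which activity has plateaued.

    A plateau requires every later consecutive change, and every later
    deviation from the final value, to be below ``tol``. Returns the time
    in minutes, or ``None`` when the series never plateaus.
    """
    t, a = series.time_min, series.activity
    if len(t) < 3:
        raise ValidationError("series: at least 3 time points required")
    # the final point alone is trivially flat; require at least one interval
    for i in range(len(t) - 1):
        tail = a[i:]
        if (np.all(np.abs(np.diff(tail)) < tol)
                and np.all(np.abs(tail - a[-1]) < tol)):
            return float(t[i])
    return None


def compare_groups(a, b):
    """Unpaired equal-variance two-sample t-test; returns (t, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("groups: each needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValidationError("groups: zero pooled variance (constant groups)")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def relative_potency(kd: float, reference: float) -> float:
    """Fold difference in affinity versus a reference inhibitor constant."""
    if kd <= 0 or reference <= 0:
        raise ValidationError("kd and reference must be positive")
    return kd / reference


class TightBindingTitration:
    """Model object for a tight-binding titration, statsmodels-style.

    >>> model = TightBindingTitration(series, enzyme_total=515)
    >>> res = model.fit(method="stoichiometric")
    >>> print(res.summary())
    """

    def __init__(self, series: TitrationSeries, enzyme_total: float | None = None):
        self.series = series
        self.enzyme_total = enzyme_total or series.enzyme_total_nM

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, enzyme_total: float | None = None):
        return cls(TitrationSeries.from_dataframe(df, enzyme_total), enzyme_total)

    def fit(self, method: str = "stoichiometric", **kwargs) -> KineticEstimate:
        if method == "stoichiometric":
            return kd_stoichiometric(self.series, self.enzyme_total, **kwargs)
        if method == "morrison":
            return fit_morrison(self.series, self.enzyme_total, **kwargs)
        raise ValidationError(f"method: unknown estimator {method!r}")

    def plot(self, result: KineticEstimate | None = None, ax=None):
        """Titration curve with the fitted/implied Morrison overlay."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.series.inhibitor_nM, self.series.activity, "o", alpha=0.5,
                label="observed")
        grid, mean = self.series.mean_curve()
        ax.plot(grid, mean, "-", lw=1, label="replicate mean")
        if result is not None and self.enzyme_total:
            dense = np.linspace(grid.min(), grid.max(), 300)
            ax.plot(dense, morrison_activity(self.enzyme_total, dense, result.kd),
                    "--", label=f"Morrison, K_D={result.kd:.1f} nM")
            ax.axvline(result.equivalence_point, color="grey", ls=":", lw=1)
        ax.set_xlabel("[inhibitor] (nM)")
        ax.set_ylabel("residual activity (v/v0)")
        ax.legend()
        return ax
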