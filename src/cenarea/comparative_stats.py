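"""Cross-species regression machinery.

Ordinary least squares with the usual F test of the slope, shared by every
statistical comparison in the pipeline: the three karyotype predictors of
total centromere area (chromosome number, average chromosome size, genome
size), the microtubule-count-versus-chromosome-size relationship from the
published kinetochore literature, and (through the origin) the
phylogenetic-contrasts regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .karyo_model import SpeciesPanel, load_table1

__all__ = [
    "RegressionResult",
    "PredictorRegressions",
    "fit_ols",
    "correlate_centromere_predictors",
    "positive_intercept_pvalue",
    "leave_one_out_r_squared",
    "table1_regression",
]


@dataclass
class RegressionResult:
    """Slope/intercept/r/R^2/F/p container shared by all regressions.

    ``intercept`` is None for a through-origin fit.  ``r`` is the Pearson
    correlation for an intercept fit; for a through-origin fit it is
    sign(slope) * sqrt(uncentred R^2).
    """

    slope: float
    intercept: float | None
    r: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int
    residuals: np.ndarray = field(repr=False)
    slope_se: float = float("nan")
    intercept_se: float | None = None
    df_resid: int = 0


def fit_ols(
    x, y, fit_intercept: bool = True
) -> RegressionResult:
    """Simple least-squares regression of y on x.

    With an intercept, R^2 = 1 - SSE/SST about the mean and the p-value is
    the F test of the slope on (1, n-2) degrees of freedom.  Through the
    origin, R^2 is computed about zero and the slope test uses n-1 degrees
    of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"x and y must be equal-length 1-D, got {x.shape} and {y.shape}"
        )
    n = x.size
    n_min = 3 if fit_intercept else 2
    if n < n_min:
        raise ValueError(f"need at least {n_min} points, got {n}")
    if fit_intercept and np.ptp(x) == 0:
        raise ValueError("degenerate design: predictor has zero variance")
    if not fit_intercept and np.all(x == 0):
        raise ValueError("degenerate design: predictor identically zero")

    design = sm.add_constant(x) if fit_intercept else x[:, None]
    with np.errstate(divide="ignore"):  # perfect fits give F = inf
        fit = sm.OLS(y, design).fit()
        f_statistic = float(fit.fvalue)
        p_value = float(fit.f_pvalue)
    slope = float(fit.params[-1])
    intercept = float(fit.params[0]) if fit_intercept else None

    r_squared = float(fit.rsquared)  # uncentred automatically when no const
    if fit_intercept:
        r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else 0.0
    else:
        r = float(np.sign(slope) * np.sqrt(max(r_squared, 0.0)))

    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r=r,
        r_squared=r_squared,
        f_statistic=f_statistic,
        p_value=p_value,
        n=n,
        residuals=np.asarray(fit.resid),
        slope_se=float(fit.bse[-1]),
        intercept_se=float(fit.bse[0]) if fit_intercept else None,
        df_resid=int(fit.df_resid),
    )


@dataclass
class PredictorRegressions:
    """The three karyotype predictors of total centromere area, fitted on
    one species panel, plus bookkeeping about excluded species."""

    chromosome_number: RegressionResult
    average_chromosome_size: RegressionResult
    genome_size: RegressionResult
    excluded_species: list[str]

    def as_dict(self) -> dict[str, RegressionResult]:
        return {
            "chromosome_number": self.chromosome_number,
            "average_chromosome_size": self.average_chromosome_size,
            "genome_size": self.genome_size,
        }


def correlate_centromere_predictors(panel: SpeciesPanel) -> PredictorRegressions:
    """Regress total centromere area on chromosome number, average
    chromosome size, and genome size across a species panel.

    Species without a measured area are excluded with a warning; predictors
    are used untransformed and every species carries equal weight.
    """
    complete = [r for r in panel if r.total_centromere_area is not None]
    excluded = [r.name for r in panel if r.total_centromere_area is None]
    if excluded:
        warnings.warn(
            f"excluding species without total_centromere_area: {excluded}",
            stacklevel=2,
        )
    if len(complete) < 3:
        raise ValueError(
            f"need >= 3 species with measured areas, got {len(complete)}"
        )
    area = [r.total_centromere_area for r in complete]
    return PredictorRegressions(
        chromosome_number=fit_ols([r.chromosome_number for r in complete], area),
        average_chromosome_size=fit_ols(
            [r.average_chromosome_size for r in complete], area
        ),
        genome_size=fit_ols([r.genome_size_mb for r in complete], area),
        excluded_species=excluded,
    )


def positive_intercept_pvalue(result: RegressionResult, x, y) -> float:
    """One-sided p-value for intercept > 0 — the "minimum centromere size"
    question: does the fitted line miss the origin on the high side?

    Uses the standard OLS intercept t statistic on n-2 degrees of freedom.
    ``x`` and ``y`` must be the data the result was fitted on (they are used
    to validate the pairing and recover the standard error if absent).
    """
    if result.intercept is None:
        raise ValueError("intercept test requires an intercept fit")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != result.n:
        raise ValueError(
            f"data length {x.size} does not match fitted n={result.n}"
        )
    se = result.intercept_se
    if se is None or not np.isfinite(se):
        se = fit_ols(x, y, fit_intercept=True).intercept_se
    t = result.intercept / se
    return float(stats.t.sf(t, df=result.n - 2))


def leave_one_out_r_squared(x, y) -> dict[int, float]:
    """Leverage diagnostic: R^2 of the intercept fit with each point held
    out, keyed by the held-out index."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = {}
    for i in range(x.size):
        keep = np.arange(x.size) != i
        out[i] = fit_ols(x[keep], y[keep]).r_squared
    return out


def table1_regression() -> RegressionResult:
    """OLS of microtubule number per kinetochore on average chromosome size
    across the ten published species of the packaged table."""
    panel = load_table1()
    x = [r.average_chromosome_size for r in panel]
    y = [r.microtubules_per_kinetochore for r in panel]
    if any(v is None for v in y):
        raise ValueError("packaged table is missing microtubule counts")
    return fit_ols(x, y)
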