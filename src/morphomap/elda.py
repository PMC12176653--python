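"""Extreme limiting dilution analysis: structure-forming-unit potency.

Under the single-hit Poisson model a well seeded with ``d`` cells stays
negative with probability ``exp(-f d)``, where ``f`` is the frequency of
structure-forming cells.  Equivalently, the response probability follows
a binomial GLM with complementary log-log link, ``log(d)`` as offset and
slope fixed at 1; the intercept is ``log f``.  The fit is by maximum
likelihood (IRLS via statsmodels), with a Wald confidence interval on
``log f`` transformed to the potency scale "1 in x cells" (x = 1/f), and
a likelihood-ratio test of the single-hit assumption (free slope on
log-dose vs slope = 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .synth.wells import LimitingDilutionTable


class NonEstimableError(ValueError):
    """All wells responded (or none did): the MLE sits on the boundary."""

    def __init__(self, msg: str, boundary: str):
        super().__init__(msg)
        self.boundary = boundary  # "upper" (all responding) or "lower"


@dataclass
class PotencyEstimate:
    frequency: float            # active cells per seeded cell, in (0, 1]
    potency: float              # x in "1 in x cells" == 1 / frequency
    log_f: float
    se_log_f: float
    ci_lower: float             # on the potency (x) scale, lower x
    ci_upper: float
    n_total_wells: int
    log_likelihood: float
    deviance: float
    slope_test_p: float | None  # None when untestable (single dose)

    @property
    def label(self) -> str:
        return f"1/{self.potency:.2f}"

    def __post_init__(self):
        if not (self.ci_lower <= self.potency <= self.ci_upper):
            raise ValueError("CI must bracket the potency estimate")
        if abs(self.frequency * self.potency - 1.0) > 1e-9:
            raise ValueError("frequency and potency must be reciprocal")


def _endog_exog(table: LimitingDilutionTable):
    resp = np.array(table.n_responding, float)
    tested = np.array(table.n_wells, float)
    endog = np.column_stack([resp, tested - resp])
    offset = np.log(np.array(table.dose_cells, float))
    return endog, offset


def _loglik_at(log_f: float, table: LimitingDilutionTable) -> float:
    d = np.array(table.dose_cells, float)
    r = np.array(table.n_responding, float)
    n = np.array(table.n_wells, float)
    p_neg = np.exp(-np.exp(log_f) * d)
    p_neg = np.clip(p_neg, 1e-300, 1 - 1e-12)
    return float(np.sum(r * np.log1p(-p_neg) + (n - r) * np.log(p_neg)))


def fit_single_hit(table: LimitingDilutionTable, alpha: float = 0.05,
                   ci: str = "wald") -> PotencyEstimate:
    """Maximum-likelihood single-hit fit with CI on log f.

    ``ci='wald'`` (default) uses the symmetric normal interval on log f;
    ``ci='profile'`` inverts the likelihood-ratio test.  Raises
    :class:`NonEstimableError` when every well responded (only a
    one-sided bound exists) or none did.
    """
    total_resp = sum(table.n_responding)
    total_wells = sum(table.n_wells)
    if total_resp == total_wells:
        raise NonEstimableError(
            "all wells responded: frequency is only bounded from below",
            boundary="upper")
    if total_resp == 0:
        raise NonEstimableError(
            "no well responded: frequency is only bounded from above",
            boundary="lower")

    endog, offset = _endog_exog(table)
    exog = np.ones((len(offset), 1))
    model = sm.GLM(endog, exog, family=sm.families.Binomial(
        link=sm.families.links.CLogLog()), offset=offset)
    with warnings.catch_warnings():
        # saturated single-dose tables have zero residual df; the scale
        # estimate is unused (binomial family has scale 1)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit()
    log_f = float(res.params[0])
    se = float(res.bse[0])
    z = stats.norm.ppf(1 - alpha / 2)
    f = math.exp(log_f)
    if ci == "wald":
        lf_lo, lf_hi = log_f - z * se, log_f + z * se
    elif ci == "profile":
        ll_max = _loglik_at(log_f, table)
        crit = stats.chi2.ppf(1 - alpha, df=1) / 2.0

        def root(lf):
            return ll_max - _loglik_at(lf, table) - crit

        from scipy.optimize import brentq
        lo_bracket = log_f - max(10 * se, 5.0)
        hi_bracket = log_f + max(10 * se, 5.0)
        lf_lo = brentq(root, lo_bracket, log_f)
        lf_hi = brentq(root, log_f, hi_bracket)
    else:
        raise ValueError("ci must be 'wald' or 'profile'")
    # CI on log f -> potency x = exp(-log f); higher f means lower x
    x_lo = math.exp(-lf_hi)
    x_hi = math.exp(-lf_lo)

    p_slope = None
    if len(set(table.dose_cells)) >= 2:
        try:
            p_slope = slope_test(table)
        except ValueError:
            p_slope = None

    return PotencyEstimate(
        frequency=f,
        potency=1.0 / f,
        log_f=log_f,
        se_log_f=se,
        ci_lower=x_lo,
        ci_upper=x_hi,
        n_total_wells=int(total_wells),
        log_likelihood=float(res.llf),
        deviance=float(res.deviance),
        slope_test_p=p_slope,
    )


def slope_test(table: LimitingDilutionTable) -> float:
    """Likelihood-ratio test of the single-hit assumption.

    Compares the cloglog regression with free slope on log-dose against
    the slope-1 (offset) model; a small p-value flags departure from
    single-hit kinetics (e.g. cooperativity between seeded cells).
    """
    if len(set(table.dose_cells)) < 2:
        raise ValueError("slope test needs >= 2 distinct doses")
    endog, offset = _endog_exog(table)
    fam = sm.families.Binomial(link=sm.families.links.CLogLog())
    ones = np.ones((len(offset), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res0 = sm.GLM(endog, ones, family=fam, offset=offset).fit()
        exog1 = np.column_stack([np.ones_like(offset), offset])
        res1 = sm.GLM(endog, exog1, family=fam).fit()
    lr = 2.0 * (res1.llf - res0.llf)
    lr = max(lr, 0.0)
    return float(stats.chi2.sf(lr, df=1))
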