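"""Publication bias, sensitivity analysis, funnel export and power.

Egger's regression test fits ordinary least squares of the standardized
effect y_i/se_i on precision 1/se_i; a non-zero intercept indicates funnel
asymmetry.  Leave-one-out sensitivity re-pools after omitting each study
in turn.  Power uses a two-sided normal approximation for the Wald test of
log OR = 0 at a given pooled standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .contrasts import EffectEstimate, table_effects
from .meta_engine import PooledResult, pool
from .study_io import StudyTable

__all__ = [
    "EggerResult",
    "SensitivityRow",
    "PowerResult",
    "egger_test",
    "funnel_data",
    "leave_one_out",
    "power_normal_approx",
]


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    t_statistic: float
    p_value: float
    k: int
    weighted: bool = False


@dataclass(frozen=True)
class SensitivityRow:
    omitted_study_id: str
    result: PooledResult


@dataclass(frozen=True)
class PowerResult:
    power: float
    alpha: float
    assumed_or: float
    method_note: str = (
        "two-sided normal approximation to the Wald test of log OR = 0; "
        "not a reproduction of any proprietary power software"
    )


def egger_test(
    effects: Sequence[EffectEstimate], weighted: bool = False
) -> EggerResult:
    """Egger's linear regression test for funnel-plot asymmetry.

    The classical form: unweighted OLS of the standard normal deviate
    y_i/se_i on precision 1/se_i; the intercept's t statistic has k-2
    degrees of freedom.  ``weighted=True`` uses inverse-variance WLS of
    the same regression, a common variant.
    """
    k = len(effects)
    if k < 3:
        raise ValueError(f"Egger's test needs at least 3 studies, got {k}")
    y = np.array([e.log_or for e in effects])
    se = np.array([e.se_log_or for e in effects])
    snd = y / se
    prec = 1.0 / se
    if np.ptp(prec) == 0 and np.ptp(snd) == 0:
        raise ValueError("degenerate design: identical effects and standard errors")
    X = sm.add_constant(prec)
    model = sm.WLS(snd, X, weights=prec**2) if weighted else sm.OLS(snd, X)
    fit = model.fit()
    intercept = float(fit.params[0])
    intercept_se = float(fit.bse[0])
    t = intercept / intercept_se
    p = 2.0 * float(stats.t.sf(abs(t), df=k - 2))
    return EggerResult(intercept, intercept_se, t, p, k, weighted)


def funnel_data(
    effects: Sequence[EffectEstimate], study_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Export (study_id, log_or, se) points for external funnel plotting."""
    ids = list(study_ids) if study_ids is not None else [str(i) for i in range(len(effects))]
    df = pd.DataFrame(
        {
            "study_id": ids,
            "log_or": [e.log_or for e in effects],
            "se": [e.se_log_or for e in effects],
        }
    )
    return df.sort_values("study_id", kind="stable").reset_index(drop=True)


def leave_one_out(
    table: StudyTable,
    contrast: str,
    i2_threshold: float = 50.0,
    zero_cell_policy: str = "haldane",
) -> list[SensitivityRow]:
    """Re-pool after omitting each study in turn (input order preserved)."""
    if len(table) < 2:
        raise ValueError("leave-one-out needs at least 2 studies")
    ids, effects = table_effects(table, contrast, zero_cell_policy)
    rows = []
    for i, omitted in enumerate(ids):
        rest_ids = ids[:i] + ids[i + 1:]
        rest = effects[:i] + effects[i + 1:]
        res = pool(rest, rest_ids, i2_threshold=i2_threshold, contrast=contrast)
        rows.append(SensitivityRow(omitted_study_id=omitted, result=res))
    return rows


def power_normal_approx(
    assumed_or: float, pooled_se: float, alpha: float = 0.05
) -> PowerResult:
    """Power of the two-sided Wald test of OR = 1.

    With noncentrality |log OR|/SE and critical value z_{1-alpha/2}:
    power = Phi(ncp - z) + Phi(-ncp - z).  Equals alpha at OR = 1 and is
    symmetric in OR <-> 1/OR.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if pooled_se <= 0:
        raise ValueError("pooled_se must be positive")
    if assumed_or <= 0:
        raise ValueError("assumed_or must be positive")
    z_crit = stats.norm.ppf(1 - alpha / 2)
    ncp = abs(np.log(assumed_or)) / pooled_se
    power = float(stats.norm.cdf(ncp - z_crit) + stats.norm.cdf(-ncp - z_crit))
    return PowerResult(power=power, alpha=alpha, assumed_or=assumed_or)
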