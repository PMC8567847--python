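"""Mixed-effects comparison of progesterone by pregnancy status.

The model follows the case-study specification literally:

    progesterone ~ pregnancy_status, random intercepts for whale (ID)
    and for sampling position (cm)

fitted by REML. Position-as-grouping-factor is degenerate by design:
every sampling position is a singleton within its whale, so the
position intercepts contribute sigma2_pos * I to the marginal
covariance — exactly like the residual. The two components are
aliased (only their sum is identifiable) and the position variance is
therefore constrained to zero and reported as such; the fixed-effect
estimate and its standard error are unchanged by this constraint.
With a single whale the whale intercept is absorbed by the fixed
intercept too and the model reduces to ordinary least squares.

The significance rule is the published one: |t| > 2 and p < 0.05.
Degrees of freedom use the within-group convention
(observations - groups - fixed parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import FitError

REQUIRED_COLUMNS = ("whale_id", "position_cm", "status", "progesterone_ng_g")


@dataclass
class LmmResult:
    """Fixed-effect contrast (pregnant - not pregnant) with diagnostics."""

    estimate: float  # ng/g
    se: float
    t_value: float
    df: int
    p_value: float
    significant: bool
    var_whale: float
    var_position: float  # aliased with the residual; constrained to 0
    var_residual: float
    n_obs: int
    n_whales: int
    singular: bool = False
    converged: bool = True
    position_aliased: bool = True

    def summary(self) -> str:
        lines = [
            "Pregnancy-status linear mixed model (REML)",
            "-" * 46,
            f"{'pregnant - not_pregnant (ng/g)':<34}{self.estimate:>12.3f}",
            f"{'standard error':<34}{self.se:>12.3f}",
            f"{'t value':<34}{self.t_value:>12.2f}",
            f"{'degrees of freedom':<34}{self.df:>12d}",
            f"{'p value':<34}{self.p_value:>12.3g}",
            f"{'significant (|t|>2 and p<0.05)':<34}{str(self.significant):>12}",
            f"{'var(whale intercept)':<34}{self.var_whale:>12.3f}",
            f"{'var(position intercept)':<34}{self.var_position:>12.3f}",
            f"{'var(residual)':<34}{self.var_residual:>12.3f}",
            f"{'observations / whales':<34}{f'{self.n_obs} / {self.n_whales}':>12}",
        ]
        if self.position_aliased:
            lines.append("note: position component aliased with residual (constrained to 0)")
        if self.singular:
            lines.append("note: fit is singular (a variance component is ~0)")
        return "\n".join(lines)


class PregnancyStatusLMM:
    """Model object for the status comparison, statsmodels style.

    Parameters
    ----------
    data : pandas.DataFrame
        Long table with columns ``whale_id``, ``position_cm``,
        ``status`` (pregnant / not_pregnant) and
        ``progesterone_ng_g``.
    allow_single_whale : bool
        The design degenerates with one whale (the whale intercept is
        unidentifiable); request the single-random-intercept fallback
        explicitly.
    """

    def __init__(self, data: pd.DataFrame, allow_single_whale: bool = False):
        missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
        if missing:
            raise FitError(f"missing columns {missing}")
        df = data.dropna(subset=["progesterone_ng_g"]).copy()
        levels = set(df["status"].unique())
        if not {"pregnant", "not_pregnant"} <= levels:
            raise FitError(
                f"need both status levels, got {sorted(levels)}"
            )
        n_whales = df["whale_id"].nunique()
        if n_whales < 2 and not allow_single_whale:
            raise FitError(
                "fewer than 2 whales; pass allow_single_whale=True for the "
                "degenerate single-random-intercept design"
            )
        self.data = df
        self.n_whales = n_whales
        self.single_whale = n_whales < 2

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PregnancyStatusLMM":
        return cls(data, **kwargs)

    def fit(self, reml: bool = True) -> LmmResult:
        df = self.data
        y = df["progesterone_ng_g"].to_numpy(float)
        n = len(df)
        n_fixed = 2  # intercept + status
        dfree = max(n - self.n_whales - n_fixed, 1)
        if np.ptp(y) == 0:
            return LmmResult(
                estimate=0.0, se=float("nan"), t_value=0.0, df=dfree,
                p_value=1.0, significant=False, var_whale=0.0,
                var_position=0.0, var_residual=0.0, n_obs=n,
                n_whales=self.n_whales, singular=True, converged=True,
            )
        formula = "progesterone_ng_g ~ C(status, Treatment('not_pregnant'))"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if self.single_whale:
                # whale intercept absorbed, position aliased -> plain OLS
                import statsmodels.formula.api as smf

                res = smf.ols(formula, data=df).fit()
                var_whale, converged = 0.0, True
            else:
                model = MixedLM.from_formula(formula, groups="whale_id", data=df)
                try:
                    res = model.fit(reml=reml, method=["lbfgs", "powell"])
                except Exception as exc:  # pragma: no cover - optimizer pathologies
                    raise FitError(f"mixed-model fit failed: {exc}") from exc
                var_whale = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
                converged = bool(res.converged)
        term = [name for name in res.params.index if "T.pregnant" in name][0]
        est = float(res.params[term])
        se = float(res.bse[term])
        var_resid = float(res.scale) if not self.single_whale else float(res.mse_resid)
        t = est / se if se > 0 else float("inf")
        p = float(2 * sps.t.sf(abs(t), dfree))
        singular = bool(var_whale <= 1e-8 * max(var_whale + var_resid, 1.0))
        return LmmResult(
            estimate=est, se=se, t_value=float(t), df=int(dfree), p_value=p,
            significant=bool(abs(t) > 2 and p < 0.05),
            var_whale=var_whale, var_position=0.0,
            var_residual=var_resid, n_obs=n, n_whales=self.n_whales,
            singular=singular, converged=converged,
        )


def fit_status_lmm(data: pd.DataFrame, reml: bool = True, **kwargs) -> LmmResult:
    """Convenience wrapper: build :class:`PregnancyStatusLMM` and fit it."""
    return PregnancyStatusLMM(data, **kwargs).fit(reml=reml)


# ---------------------------------------------------------------------------
# simulation helpers and recovery metrics
# ---------------------------------------------------------------------------

def simulate_status_dataset(
    rng: np.random.Generator,
    effect_ng_g: float = 300.0,
    sd_whale: float = 50.0,
    sd_position: float = 30.0,
    sd_residual: float = 100.0,
    baseline_ng_g: float = 150.0,
    samples_per_whale: tuple[int, ...] = (30, 31),
    pregnant_fraction: float = 1 / 3,
) -> pd.DataFrame:
    """Labelled two-whale dataset matching the case-study design.

    Whale intercepts, per-position effects and residuals are Gaussian;
    roughly a third of each plate is pregnant (as on the real plates).
    Used for parameter-recovery experiments on the mixed model.
    """
    rows = []
    for w, n in enumerate(samples_per_whale):
        b_whale = rng.normal(0.0, sd_whale)
        n_preg = int(round(pregnant_fraction * n))
        status = np.r_[np.ones(n_preg), np.zeros(n - n_preg)]
        rng.shuffle(status)
        for i in range(n):
            rows.append(
                {
                    "whale_id": f"W{w}",
                    "position_cm": 2.0 * i,
                    "status": "pregnant" if status[i] else "not_pregnant",
                    "progesterone_ng_g": (
                        baseline_ng_g
                        + b_whale
                        + rng.normal(0.0, sd_position)
                        + effect_ng_g * status[i]
                        + rng.normal(0.0, sd_residual)
                    ),
                }
            )
    return pd.DataFrame(rows)

def interval_overlap(a: tuple, b: tuple) -> bool:
    """Closed-interval overlap between two (start, end) date pairs."""
    return a[0] <= b[1] and b[0] <= a[1]


@dataclass
class RecoveryMetrics:
    sensitivity: float
    precision: float
    n_true: int
    n_called: int
    effect_bias: float | None = None
    effect_rmse: float | None = None


def recovery_report(
    truths: list,
    calls_per_plate: list[list],
    effect_estimates: list[float] | None = None,
    true_effect: float | None = None,
) -> RecoveryMetrics:
    """Sensitivity/precision of pregnancy calls against simulator truth.

    A true term window counts as recovered when overlapped by at least
    one full-term call on its plate; a call is correct when it overlaps
    a true term window. Only simulated inputs carry the truth records
    this needs.
    """
    from .simulate import TruthRecord  # local import to avoid cycle

    if len(truths) != len(calls_per_plate):
        raise FitError("one call list per truth record required")
    for t in truths:
        if not isinstance(t, TruthRecord):
            raise FitError("recovery_report only applies to simulated data")
    n_true = n_hit = n_called = n_correct = 0
    for truth, calls in zip(truths, calls_per_plate):
        windows = truth.term_windows
        call_iv = [(c.conception_date, c.birth_date) for c in calls]
        n_true += len(windows)
        n_called += len(call_iv)
        for w in windows:
            if any(interval_overlap(w, c) for c in call_iv):
                n_hit += 1
        for c in call_iv:
            if any(interval_overlap(w, c) for w in windows):
                n_correct += 1
    bias = rmse = None
    if effect_estimates is not None and true_effect is not None:
        err = np.asarray(effect_estimates, float) - true_effect
        bias, rmse = float(np.mean(err)), float(np.sqrt(np.mean(err**2)))
    return RecoveryMetrics(
        sensitivity=n_hit / n_true if n_true else float("nan"),
        precision=n_correct / n_called if n_called else float("nan"),
        n_true=n_true,
        n_called=n_called,
        effect_bias=bias,
        effect_rmse=rmse,
    )
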