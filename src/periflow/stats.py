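"""Statistical layer: normality screening, two-level mixed models,
likelihood-ratio model selection, Holm step-down correction, and the
generalized ESD (Rosner's) outlier test.

The experimental design this serves is a paired pre/post pharmacology
comparison with repeated measures of units (pericytes or vessels) nested
in animals: the treatment is the fixed effect, animal and unit-within-
animal carry random intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "NormalityResult",
    "MixedModelResult",
    "normality_gate",
    "fit_lmm",
    "holm_adjust",
    "generalized_esd",
]


@dataclass
class NormalityResult:
    values: np.ndarray
    transform_applied: str  # "none" | "log"
    shift: float = 0.0
    shapiro_p: float = np.nan


def normality_gate(values: Sequence[float], alpha: float = 0.05
                   ) -> NormalityResult:
    """Shapiro-Wilk screen with a natural-log fallback.

    If the Shapiro-Wilk p-value is at least ``alpha`` the sample is
    returned unchanged; otherwise it is log-transformed (and that is
    recorded). Non-positive values force a documented shift
    ``log(x + c)`` with ``c = 1 − min(x)``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values for the normality screen")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    p = float(sps.shapiro(x).pvalue)
    if p >= alpha:
        return NormalityResult(values=x, transform_applied="none", shapiro_p=p)
    shift = 0.0
    if x.min() <= 0:
        shift = 1.0 - float(x.min())
    return NormalityResult(values=np.log(x + shift), transform_applied="log",
                           shift=shift, shapiro_p=p)


@dataclass
class MixedModelResult:
    """Treatment effect from a two-level random-intercept model.

    ``estimate`` is the fixed treatment effect (post − pre) with a Wald
    CI; variance components are ML estimates for animal, unit-within-
    animal, and residual; ``lrt_statistic``/``p_value`` come from the
    likelihood-ratio test of the model with vs. without the fixed
    effect (χ², 1 df). ``holm_adjusted_p`` is filled by the caller when
    the result belongs to a correction family.
    """

    estimate: float
    ci_low: float
    ci_high: float
    var_animal: float
    var_unit: float
    var_resid: float
    lrt_statistic: float
    p_value: float
    holm_adjusted_p: Optional[float] = None
    singular: bool = False
    n_obs: int = 0
    formula: str = ""
    reml_variances: Optional[dict] = None


def _fit_ml(df: pd.DataFrame, with_treatment: bool, reml: bool = False):
    import statsmodels.formula.api as smf

    fixed = "value ~ treat" if with_treatment else "value ~ 1"
    vc = {"unit": "0 + C(unit_key)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(fixed, df, groups="animal_key",
                            re_formula="1", vc_formula=vc)
        return model.fit(reml=reml, method="lbfgs", maxiter=200)


def fit_lmm(table: pd.DataFrame, response: str = "value",
            treatment_col: str = "treatment",
            animal_col: str = "animal_id", unit_col: str = "unit_id",
            baseline_level: str = "pre",
            average_trials: bool = False,
            include_reml: bool = False) -> MixedModelResult:
    """Random-intercept LMM of a pre/post treatment effect.

    Fits ``value ~ treatment + (1|animal) + (1|unit within animal)`` by
    maximum likelihood, plus the null model without the treatment term;
    the likelihood-ratio statistic ``2·(ℓ_full − ℓ_null)`` is referred
    to χ²₁. ML is used so the two fixed-effect structures are
    comparable; set ``include_reml`` to also report REML variance
    components. A fit with a vanishing variance component is flagged
    ``singular`` rather than rejected. ``average_trials`` collapses
    repeated trials within unit × condition to their mean before
    fitting.
    """
    df = table[[animal_col, unit_col, treatment_col, response]].copy()
    df.columns = ["animal_key", "unit_raw", "treatment", "value"]
    if df["animal_key"].nunique() < 2:
        raise ValueError("need at least 2 animals")
    levels = pd.unique(df["treatment"])
    if len(levels) != 2:
        raise ValueError("need exactly 2 treatment levels")
    other = [l for l in levels if l != baseline_level]
    base = baseline_level if baseline_level in set(levels) else sorted(levels)[0]
    treat_level = other[0] if baseline_level in set(levels) else sorted(levels)[1]
    df["treat"] = (df["treatment"] == treat_level).astype(float)
    # unit keys must be unique across animals for the nested component
    df["unit_key"] = df["animal_key"].astype(str) + "//" + df["unit_raw"].astype(str)
    if average_trials:
        df = (df.groupby(["animal_key", "unit_key", "treat"], as_index=False)
                ["value"].mean())

    if np.var(df["value"].to_numpy()) < 1e-12 * max(
            1.0, abs(float(df["value"].mean()))) ** 2:
        # degenerate response (no variation): no evidence either way
        return MixedModelResult(
            estimate=0.0, ci_low=0.0, ci_high=0.0, var_animal=0.0,
            var_unit=0.0, var_resid=0.0, lrt_statistic=0.0, p_value=1.0,
            singular=True, n_obs=len(df),
            formula=f"{response} ~ {treatment_col} (degenerate: constant response)")

    full = _fit_ml(df, with_treatment=True)
    null = _fit_ml(df, with_treatment=False)
    if not (np.isfinite(full.llf) and np.isfinite(null.llf)):
        lrt, p = 0.0, 1.0
        degenerate = True
    else:
        lrt = max(2.0 * (full.llf - null.llf), 0.0)
        p = float(sps.chi2.sf(lrt, df=1))
        degenerate = False

    est = float(full.params["treat"])
    se = float(full.bse["treat"])
    z = sps.norm.ppf(0.975)
    var_animal = float(np.asarray(full.cov_re)[0, 0])
    var_unit = float(full.vcomp[0]) if len(full.vcomp) else 0.0
    var_resid = float(full.scale)
    singular = bool(min(var_animal, var_unit) < 1e-8 * max(var_resid, 1e-12)
                    or not full.converged or degenerate)

    reml_vc = None
    if include_reml:
        fr = _fit_ml(df, with_treatment=True, reml=True)
        reml_vc = {"animal": float(np.asarray(fr.cov_re)[0, 0]),
                   "unit": float(fr.vcomp[0]) if len(fr.vcomp) else 0.0,
                   "resid": float(fr.scale)}

    return MixedModelResult(
        estimate=est, ci_low=est - z * se, ci_high=est + z * se,
        var_animal=var_animal, var_unit=var_unit, var_resid=var_resid,
        lrt_statistic=lrt, p_value=p, singular=singular, n_obs=len(df),
        formula=f"{response} ~ {treatment_col} + (1|{animal_col}) "
                f"+ (1|{unit_col} in {animal_col}); baseline={base}",
        reml_variances=reml_vc)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) adjusted p-values.

    With sorted p-values p_(1) ≤ … ≤ p_(m), the adjusted value is
    ``adj_(i) = max_{j ≤ i} min(1, (m − j + 1)·p_(j))``, returned in the
    original order. Never smaller than the raw p-value and monotone in
    the sorted order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def generalized_esd(values: Sequence[float], k_max: int = 15,
                    alpha: float = 0.05) -> np.ndarray:
    """Rosner's generalized extreme studentized deviate test.

    Sequentially removes the most extreme value and compares each test
    statistic ``R_i = max|x − mean|/sd`` with the t-distribution-based
    critical value ``λ_i``; the declared outliers are the first ℓ
    removed, where ℓ is the largest i with ``R_i > λ_i`` (two-sided,
    up to ``k_max`` outliers). Returns the indices of the outliers in
    the input array (possibly empty).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    k_max = min(k_max, n - 2)
    if k_max < 1 or n < 4:
        return np.asarray([], dtype=int)
    remaining = np.arange(n)
    work = x.copy()
    removed: list[int] = []
    n_out = 0
    for i in range(1, k_max + 1):
        mu, sd = work.mean(), work.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(work - mu)
        j = int(np.argmax(dev))
        r = dev[j] / sd
        ni = n - i + 1  # sample size at this step
        p = 1.0 - alpha / (2.0 * ni)
        t = sps.t.ppf(p, ni - 2)
        lam = (ni - 1) * t / np.sqrt((ni - 2 + t**2) * ni)
        if r > lam:
            n_out = i
        removed.append(int(remaining[j]))
        remaining = np.delete(remaining, j)
        work = np.delete(work, j)
    return np.asarray(removed[:n_out], dtype=int)
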