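"""Mixed-model injection contrasts and antagonist blocking percentages.

Per receptor group, log iRatio is modelled with injection as a fixed
effect and spot as a random intercept (REML).  Treatment-versus-control
contrasts are exponentiated back to a multiplicative scale: an estimate of
1.1 means a 10 % larger response than the control injection, and an
estimate whose 95 % Wald interval excludes 1 is called significant.

The blocking percentage quantifies how much of a receptor's excess
response to an agonist disappears when a competitive antagonist is
co-injected: 100 * (E_pure - E_mix) / (E_pure - 1), where both E values
are multiplicative contrasts against the same blank injection.  A mixture
effect that has returned to 1 therefore corresponds to a 100 % block.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ContrastEstimate",
    "BlockingError",
    "fit_contrasts",
    "blocking_percent",
]

log = logging.getLogger(__name__)

#: floor applied to non-positive iRatio values before taking logs
IRATIO_FLOOR = 1e-4


class BlockingError(ValueError):
    """Raised when a blocking percentage is undefined."""


@dataclass(frozen=True)
class ContrastEstimate:
    receptor: str
    treatment: str
    control: str
    estimate: float
    ci_low: float
    ci_high: float
    significant: bool
    model: str = "mixed"  # "mixed" or "fixed" fallback


def _fit_group(sub: pd.DataFrame):
    """Injection-effect fit for one receptor group on the log scale.

    Returns (params, cov, model_kind); falls back to OLS when the random
    intercept variance is singular or the data are noiseless.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = sub.copy()
    sub["log_iratio"] = np.log(np.maximum(sub["iratio"].to_numpy(float), IRATIO_FLOOR))
    floored = int((sub["iratio"] <= IRATIO_FLOOR).sum())
    if floored:
        log.info("floored %d non-positive iRatio values", floored)
    sub["sample_id"] = pd.Categorical(sub["sample_id"])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                "log_iratio ~ 0 + sample_id", sub, groups=sub["spot_id"]
            )
            fit = md.fit(reml=True)
        if not np.isfinite(fit.bse.iloc[: len(sub["sample_id"].cat.categories)]).all():
            raise np.linalg.LinAlgError("non-finite standard errors")
        names = list(fit.model.exog_names)
        params = dict(zip(names, fit.params[: len(names)]))
        cov = pd.DataFrame(
            np.asarray(fit.cov_params())[: len(names), : len(names)],
            index=names,
            columns=names,
        )
        return params, cov, "mixed", sub
    except (np.linalg.LinAlgError, ValueError):
        log.info("mixed model singular; falling back to fixed-effects fit")
        X = pd.get_dummies(sub["sample_id"], dtype=float)
        model = sm.OLS(sub["log_iratio"], X)
        fit = model.fit()
        names = [f"sample_id[{c}]" for c in X.columns]
        params = dict(zip(names, fit.params))
        cov = pd.DataFrame(np.asarray(fit.cov_params()), index=names, columns=names)
        return params, cov, "fixed", sub


def fit_contrasts(
    iratio: pd.DataFrame,
    pairs: list[tuple[str, str]],
    receptors: list[str] | None = None,
) -> list[ContrastEstimate]:
    """Multiplicative treatment-vs-control contrasts per receptor group.

    ``iratio`` is the tidy table (spot_id, receptor, sample_id, iratio);
    ``pairs`` lists (treatment sample_id, control sample_id).  One model is
    fitted per receptor; each contrast is the difference of the two
    injection coefficients on the log scale with a Wald 95 % interval,
    exponentiated.
    """
    out: list[ContrastEstimate] = []
    todo = receptors or sorted(iratio["receptor"].unique())
    for receptor in todo:
        sub = iratio[iratio["receptor"] == receptor]
        if sub.empty:
            continue
        params, cov, kind, _ = _fit_group(sub)

        def key(sample: str) -> str:
            k = f"sample_id[{sample}]"
            if k not in params:
                raise KeyError(f"injection {sample!r} absent for {receptor}")
            return k

        # Wald interval with a t quantile on the within-spot residual df;
        # a z quantile under-covers at the 5-15 replicate level of an array
        n_obs = len(sub)
        n_fix = len(params)
        n_groups = sub["spot_id"].nunique()
        if kind == "mixed":
            df = max(n_obs - n_fix - n_groups + 1, 3)
        else:
            df = max(n_obs - n_fix, 3)
        from scipy import stats as _stats

        tq = float(_stats.t.ppf(0.975, df))
        for treatment, control in pairs:
            kt, kc = key(treatment), key(control)
            diff = params[kt] - params[kc]
            var = cov.loc[kt, kt] + cov.loc[kc, kc] - 2.0 * cov.loc[kt, kc]
            se = float(np.sqrt(max(var, 0.0)))
            lo, hi = diff - tq * se, diff + tq * se
            est, ci_low, ci_high = float(np.exp(diff)), float(np.exp(lo)), float(np.exp(hi))
            out.append(
                ContrastEstimate(
                    receptor=receptor,
                    treatment=treatment,
                    control=control,
                    estimate=est,
                    ci_low=ci_low,
                    ci_high=ci_high,
                    significant=bool(ci_low > 1.0 or ci_high < 1.0),
                    model=kind,
                )
            )
    return out


def blocking_percent(effect_pure: ContrastEstimate, effect_mix: ContrastEstimate) -> float:
    """Percent reduction of the excess agonist effect by the antagonist.

    100 * (E_pure - E_mix) / (E_pure - 1), clipped to [0, 100]; both
    effects must be contrasts of the same receptor against the same blank.
    """
    if effect_pure.receptor != effect_mix.receptor:
        raise BlockingError("contrasts are for different receptors")
    if effect_pure.control != effect_mix.control:
        raise BlockingError("contrasts use different control injections")
    if effect_pure.estimate <= 1.0:
        raise BlockingError("no agonist effect to block (pure estimate <= 1)")
    pct = 100.0 * (effect_pure.estimate - effect_mix.estimate) / (
        effect_pure.estimate - 1.0
    )
    return float(np.clip(pct, 0.0, 100.0))
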