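"""Model selection by WAIC and LCPO with forward covariate addition.

Starting from the null model (intercept, no spatial effect), covariates
are added one by one, and finally the spatial effect; at every step the
addition that most improves the combined criterion is kept.  "Lowest
WAIC and LCPO combined" is realised as the sum of within-trace ranks of
the two criteria (ties broken by WAIC); both raw values are always
reported so users can re-rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import (
    InferenceConfig,
    ModelSpec,
    fit_conditional_lognormal,
    fit_occurrence,
)
from .observations import ObservationSet
from .stack import CovariateStack


def waic(pointwise_loglik: np.ndarray) -> dict:
    """Watanabe-Akaike information criterion from an (n_obs, n_draws)
    pointwise log-likelihood matrix.

    elpd_i = log mean_d exp(ll_id); p_waic_i = var_d(ll_id);
    waic = -2 sum_i (elpd_i - p_waic_i).  Lower is better.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[1] < 2:
        raise ValueError("need an (n_obs, n_draws) matrix with at least 2 draws")
    n, s = ll.shape
    lpd = logsumexp(ll, axis=1) - np.log(s)
    p_waic = ll.var(axis=1, ddof=1)
    elpd = float((lpd - p_waic).sum())
    return {"waic": -2.0 * elpd, "p_waic": float(p_waic.sum()), "elpd": elpd}


def lcpo(pointwise_loglik: np.ndarray) -> float:
    """Mean negative log Conditional Predictive Ordinate.

    CPO_i is the harmonic mean of the per-draw likelihoods,
    CPO_i = [mean_d exp(-ll_id)]^(-1); LCPO = -(1/n) sum_i log CPO_i.
    Closer to 0 is better; non-negative for discrete likelihoods.
    Non-finite CPO estimates (a draw with zero likelihood for some
    observation) raise, naming the count, so degenerate fits are not
    silently scored.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[1] < 2:
        raise ValueError("need an (n_obs, n_draws) matrix with at least 2 draws")
    n, s = ll.shape
    log_cpo = -(logsumexp(-ll, axis=1) - np.log(s))
    if not np.isfinite(log_cpo).all():
        bad = int((~np.isfinite(log_cpo)).sum())
        raise FloatingPointError(f"{bad} observation(s) have non-finite CPO estimates")
    return float(-log_cpo.mean())


@dataclass
class SelectionTrace:
    """Every evaluated spec with its criteria, and the chosen best."""

    steps: pd.DataFrame = field(default_factory=pd.DataFrame)
    best: ModelSpec | None = None
    best_fit: object = None

    def to_csv(self, path) -> None:
        self.steps.to_csv(path, index=False)


def _fit_for(obs, covariates, spec, config, standardization):
    if spec.response_kind == "occurrence":
        return fit_occurrence(obs, covariates, spec, config, standardization)
    return fit_conditional_lognormal(obs, covariates, spec, config, standardization)


def _combined_ranks(df: pd.DataFrame) -> pd.Series:
    return df["waic"].rank(method="min") + df["lcpo"].rank(method="min")


def forward_select(
    obs: ObservationSet,
    covariates: CovariateStack,
    candidates: list[str],
    config: InferenceConfig | None = None,
    response_kind: str | None = None,
    standardization=None,
    include_spatial_step: bool = True,
    exhaustive: bool = False,
) -> SelectionTrace:
    """Greedy forward covariate addition from the null model.

    The null model is intercept-only without spatial effect.  At each
    step every remaining candidate (and, once covariate additions stop
    helping, the spatial effect) is evaluated; the addition with the
    lowest combined rank (strictly better than the incumbent) is
    accepted.  ``exhaustive=True`` evaluates every covariate subset
    (allowed for up to 5 candidates) before the spatial step.
    """
    config = config or InferenceConfig()
    response_kind = response_kind or obs.response_kind
    if response_kind != "occurrence":
        obs = obs.presence_subset()
    candidates = sorted(dict.fromkeys(candidates))

    records: list[dict] = []
    fits: dict[str, object] = {}

    def evaluate(spec: ModelSpec) -> None:
        fit = _fit_for(obs, covariates, spec, config, standardization)
        crit = waic(fit.loglik)
        records.append(
            {
                "label": spec.label(),
                "covariates": ",".join(spec.covariate_names),
                "spatial": spec.include_spatial,
                "waic": crit["waic"],
                "p_waic": crit["p_waic"],
                "lcpo": lcpo(fit.loglik),
                "accepted": False,
                "_spec": spec,
            }
        )
        fits[spec.label()] = fit

    null = ModelSpec(response_kind=response_kind, covariate_names=[], include_spatial=False)
    evaluate(null)
    current = null

    def mark_accepted(label: str) -> None:
        for r in records:
            if r["label"] == label:
                r["accepted"] = True

    mark_accepted(null.label())

    if exhaustive:
        if len(candidates) > 5:
            raise ValueError("exhaustive mode allowed for at most 5 candidates")
        from itertools import combinations

        for r in range(1, len(candidates) + 1):
            for subset in combinations(candidates, r):
                evaluate(ModelSpec(response_kind, list(subset), include_spatial=False))
    else:
        remaining = list(candidates)
        while remaining:
            trials = {c: current.with_added(covariate=c) for c in remaining}
            for c in sorted(trials):
                evaluate(trials[c])
            best_label = _pick_best(records)
            chosen = next(
                (c for c, s in trials.items() if s.label() == best_label), None
            )
            if chosen is None:
                break
            current = trials[chosen]
            remaining.remove(chosen)
            mark_accepted(best_label)

    if exhaustive:
        best_label = _pick_best(records)
        current = next(r["_spec"] for r in records if r["label"] == best_label)
        mark_accepted(best_label)

    if include_spatial_step and not current.include_spatial:
        evaluate(current.with_added(spatial=True))
        best_label = _pick_best(records)
        spat = current.with_added(spatial=True)
        if best_label == spat.label():
            current = spat
            mark_accepted(best_label)

    df = pd.DataFrame(records)
    ranks = _combined_ranks(df)
    df["combined_rank"] = ranks
    order = np.lexsort((df["waic"].to_numpy(), ranks.to_numpy()))
    best_row = df.iloc[order[0]]
    best_spec = best_row["_spec"]
    trace = SelectionTrace(
        steps=df.drop(columns="_spec"),
        best=best_spec,
        best_fit=fits.get(best_spec.label()),
    )
    return trace


def _pick_best(records: list[dict]) -> str:
    df = pd.DataFrame(records)
    ranks = _combined_ranks(df)
    order = np.lexsort((df["waic"].to_numpy(), ranks.to_numpy()))
    return str(df.iloc[order[0]]["label"])
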