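"""MAP estimation of learning parameters and BIC model comparison.

Each agent x condition is fitted independently by maximizing the posterior
of the Rescorla-Wagner/softmax model over the observed choice sequence,
with weakly informative priors regularizing the estimates: Beta(1.2, 1.2)
on every learning rate and Gaussian(0, 10) (location, standard deviation)
on the inverse temperature. The likelihood replays the observed
choices/outcomes with values resetting at each block.

Model comparison pits the one-learning-rate model against a variant with
separate rates for gains and losses, scored by BIC computed from the
likelihood at the MAP point with n = number of non-missed trials; ties go
to the simpler model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import betaln

from .model import RLParams, Variant
from .task import Condition, Trial

__all__ = [
    "PriorSpec",
    "FitResult",
    "ComparisonReport",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "fit_map",
    "fit_cohort",
    "bic",
    "compare_models",
    "DEFAULT_PRIORS",
]


# ---------------------------------------------------------------------------
# Likelihood kernel


def _replay_loglik(block, chosen, outcome, a_gain, a_loss, beta, q0, reward_value):
    """Sequential log-likelihood of a choice sequence under the RW/softmax model.

    ``block`` marks value-reset boundaries; ``chosen`` is 1 for the
    high-contingency picture. Written so numba can compile it; the
    uncompiled function doubles as the pure-Python fallback.
    """
    ll = 0.0
    q_good = q0
    q_bad = q0
    current = -1
    for i in range(block.shape[0]):
        if block[i] != current:
            current = block[i]
            q_good = q0
            q_bad = q0
        d = beta * (q_good - q_bad)
        if d >= 0.0:
            p_good = 1.0 / (1.0 + math.exp(-d))
        else:
            e = math.exp(d)
            p_good = e / (1.0 + e)
        p = p_good if chosen[i] == 1 else 1.0 - p_good
        if p < 1e-300:
            p = 1e-300
        ll += math.log(p)
        a = a_gain if outcome[i] == reward_value else a_loss
        if chosen[i] == 1:
            q_good += a * (outcome[i] - q_good)
        else:
            q_bad += a * (outcome[i] - q_bad)
    return ll


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _replay_loglik_fast = numba.njit(cache=False)(_replay_loglik)
except Exception:  # pragma: no cover
    _replay_loglik_fast = _replay_loglik


def _to_arrays(
    trials: Union[Sequence[Trial], pd.DataFrame],
    condition: Optional[Condition] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordered (block_code, chosen, outcome) arrays of the non-missed trials.

    Trials are ordered by run, block, trial index when those fields are
    present; block codes are consecutive integers in order of appearance of
    ``pair_id`` (value-reset boundaries).
    """
    if isinstance(trials, pd.DataFrame):
        frame = trials
    else:
        from .task import session_to_frame

        frame = session_to_frame(list(trials))
    if condition is not None:
        frame = frame[frame["condition"] == condition.value]
    frame = frame[~frame["missed"].astype(bool)]
    sort_cols = [c for c in ("run", "block", "trial_in_block") if c in frame.columns]
    if sort_cols:
        frame = frame.sort_values(sort_cols, kind="stable")
    block = pd.factorize(frame["pair_id"])[0].astype(np.int64)
    chosen = frame["chosen_good"].to_numpy(dtype=bool).astype(np.int64)
    outcome = frame["outcome"].to_numpy(dtype=float)
    return block, chosen, outcome


# ---------------------------------------------------------------------------
# Priors


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors for MAP regularization.

    ``alpha_prior`` are Beta shape parameters applied to every learning
    rate; ``beta_prior`` is (location, standard deviation) of a Gaussian on
    the inverse temperature.
    """

    alpha_prior: tuple[float, float] = (1.2, 1.2)
    beta_prior: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        a, b = self.alpha_prior
        if a <= 0 or b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.beta_prior[1] <= 0:
            raise ValueError("beta prior scale must be positive")

    def alpha_logpdf(self, alpha: float) -> float:
        if not 0.0 < alpha < 1.0:
            return -math.inf
        a, b = self.alpha_prior
        return (a - 1.0) * math.log(alpha) + (b - 1.0) * math.log1p(-alpha) - betaln(a, b)

    def beta_logpdf(self, beta: float) -> float:
        loc, sd = self.beta_prior
        z = (beta - loc) / sd
        return -0.5 * z * z - math.log(sd) - 0.5 * math.log(2.0 * math.pi)

    @property
    def alpha_mode(self) -> float:
        a, b = self.alpha_prior
        if a > 1.0 and b > 1.0:
            return (a - 1.0) / (a + b - 2.0)
        return 0.5

    @property
    def beta_mode(self) -> float:
        return self.beta_prior[0]


DEFAULT_PRIORS = PriorSpec()


# ---------------------------------------------------------------------------
# Objective functions


def log_likelihood(
    trials: Union[Sequence[Trial], pd.DataFrame],
    params: RLParams,
    q0: float = 0.0,
    outcome_values: tuple[int, int] = (1, -1),
    condition: Optional[Condition] = None,
) -> float:
    """Log-likelihood of observed choices under ``params`` (values reset per block).

    An empty sequence returns 0.0 with a warning (the fit is prior-only).
    """
    block, chosen, outcome = _to_arrays(trials, condition)
    if block.shape[0] == 0:
        warnings.warn("no non-missed trials: log-likelihood is 0 (prior-only fit)")
        return 0.0
    gain, loss = params.rates
    return float(
        _replay_loglik_fast(
            block, chosen, outcome, gain, loss, params.beta, q0, float(outcome_values[0])
        )
    )


def log_prior(params: RLParams, priors: PriorSpec = DEFAULT_PRIORS) -> float:
    """Log prior density at ``params`` (each rate gets the Beta prior)."""
    lp = priors.beta_logpdf(params.beta)
    if params.variant is Variant.ONE_ALPHA:
        lp += priors.alpha_logpdf(params.alpha)
    else:
        lp += priors.alpha_logpdf(params.alpha_gain)
        lp += priors.alpha_logpdf(params.alpha_loss)
    return lp


def log_posterior(
    trials: Union[Sequence[Trial], pd.DataFrame],
    params: RLParams,
    priors: PriorSpec = DEFAULT_PRIORS,
    q0: float = 0.0,
    outcome_values: tuple[int, int] = (1, -1),
    condition: Optional[Condition] = None,
) -> float:
    """Unnormalized log posterior: log-likelihood plus log prior.

    Parameters outside the prior support score -inf (a rejected point, not
    an exception).
    """
    lp = log_prior(params, priors)
    if not math.isfinite(lp):
        return -math.inf
    return lp + log_likelihood(trials, params, q0, outcome_values, condition)


# ---------------------------------------------------------------------------
# Fitting


_ALPHA_BOUND = (1e-6, 1.0 - 1e-6)
_BETA_BOUND = (-100.0, 100.0)
# Dispersed anchor grid for inverse-temperature starting points.
_BETA_STARTS = np.array([0.0, 2.0, -2.0, 5.0, 10.0, -5.0, 1.0, 3.0, 20.0, -20.0])


@dataclass
class FitResult:
    """MAP fit of one agent x condition x model variant."""

    params: RLParams
    loglik: float
    logpost: float
    n_trials: int
    k: int
    bic: float
    n_starts: int
    converged: bool
    best_start_seed: int
    prior_only: bool = False

    def to_dict(self) -> dict:
        d = {
            "variant": self.params.variant.value,
            "alpha": self.params.alpha,
            "alpha_gain": self.params.alpha_gain,
            "alpha_loss": self.params.alpha_loss,
            "beta": self.params.beta,
            "loglik": self.loglik,
            "logpost": self.logpost,
            "n_trials": self.n_trials,
            "k": self.k,
            "bic": self.bic,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "best_start_seed": self.best_start_seed,
        }
        return d


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian Information Criterion: -2*loglik + k*ln(n); lower is better."""
    if n < 1:
        raise ValueError("BIC undefined for n < 1")
    return -2.0 * loglik + k * math.log(n)


def _pack(variant: Variant, x: np.ndarray) -> RLParams:
    if variant is Variant.ONE_ALPHA:
        return RLParams.one(alpha=float(x[0]), beta=float(x[1]))
    return RLParams.two(alpha_gain=float(x[0]), alpha_loss=float(x[1]), beta=float(x[2]))


def fit_map(
    trials: Union[Sequence[Trial], pd.DataFrame],
    variant: Variant,
    priors: PriorSpec = DEFAULT_PRIORS,
    q0: float = 0.0,
    n_starts: int = 10,
    seed: int = 0,
    outcome_values: tuple[int, int] = (1, -1),
    condition: Optional[Condition] = None,
) -> FitResult:
    """Maximize the posterior by bounded L-BFGS-B with seeded multi-starts.

    Learning-rate starts are drawn from the alpha prior; inverse-temperature
    starts cycle through a dispersed anchor grid. The best start is kept;
    ``converged`` is False only if every start fails, in which case the best
    point found is still returned. With zero usable trials the prior modes
    are returned directly (BIC undefined, reported as NaN).
    """
    block, chosen, outcome = _to_arrays(trials, condition)
    n = int(block.shape[0])
    k = 2 if variant is Variant.ONE_ALPHA else 3
    if n == 0:
        warnings.warn("no non-missed trials: returning prior modes")
        if variant is Variant.ONE_ALPHA:
            params = RLParams.one(alpha=priors.alpha_mode, beta=priors.beta_mode)
        else:
            params = RLParams.two(
                alpha_gain=priors.alpha_mode,
                alpha_loss=priors.alpha_mode,
                beta=priors.beta_mode,
            )
        return FitResult(
            params=params,
            loglik=0.0,
            logpost=log_prior(params, priors),
            n_trials=0,
            k=k,
            bic=math.nan,
            n_starts=0,
            converged=True,
            best_start_seed=-1,
            prior_only=True,
        )

    reward_value = float(outcome_values[0])
    a, b = priors.alpha_prior
    loc, sd = priors.beta_prior
    log_beta_norm = betaln(a, b)
    gauss_norm = math.log(sd) + 0.5 * math.log(2.0 * math.pi)

    def neg_logpost(x: np.ndarray) -> float:
        if variant is Variant.ONE_ALPHA:
            gain = loss = x[0]
            beta_ = x[1]
            rates = (x[0],)
        else:
            gain, loss, beta_ = x[0], x[1], x[2]
            rates = (x[0], x[1])
        lp = 0.0
        for r in rates:
            if not 0.0 < r < 1.0:
                return 1e12
            lp += (a - 1.0) * math.log(r) + (b - 1.0) * math.log1p(-r) - log_beta_norm
        z = (beta_ - loc) / sd
        lp += -0.5 * z * z - gauss_norm
        ll = _replay_loglik_fast(block, chosen, outcome, gain, loss, beta_, q0, reward_value)
        return -(ll + lp)

    rng = np.random.default_rng(seed)
    n_rates = k - 1
    alpha_starts = rng.beta(a, b, size=(n_starts, n_rates))
    beta_starts = np.resize(_BETA_STARTS, n_starts)
    bounds = [_ALPHA_BOUND] * n_rates + [_BETA_BOUND]

    best_fun = math.inf
    best_x: Optional[np.ndarray] = None
    best_idx = -1
    any_success = False
    for s in range(n_starts):
        x0 = np.concatenate([alpha_starts[s], [beta_starts[s]]])
        res = optimize.minimize(
            neg_logpost,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if res.success:
            any_success = True
        if res.fun < best_fun:
            best_fun = float(res.fun)
            best_x = np.asarray(res.x, dtype=float)
            best_idx = s
    assert best_x is not None
    best_x[:n_rates] = np.clip(best_x[:n_rates], *_ALPHA_BOUND)
    params = _pack(variant, best_x)
    gain, loss = params.rates
    loglik = float(
        _replay_loglik_fast(block, chosen, outcome, gain, loss, params.beta, q0, reward_value)
    )
    return FitResult(
        params=params,
        loglik=loglik,
        logpost=-best_fun,
        n_trials=n,
        k=k,
        bic=bic(loglik, k, n),
        n_starts=n_starts,
        converged=any_success,
        best_start_seed=best_idx,
    )


def _fit_seed(seed: int, agent_idx: int, cond_idx: int, variant_idx: int) -> int:
    ss = np.random.SeedSequence([seed, agent_idx, cond_idx, variant_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_cohort(
    table: pd.DataFrame,
    variant: Variant,
    priors: PriorSpec = DEFAULT_PRIORS,
    q0: float = 0.0,
    n_starts: int = 10,
    seed: int = 0,
    conditions: Optional[Iterable[Condition]] = None,
    outcome_values: tuple[int, int] = (1, -1),
) -> pd.DataFrame:
    """Fit every agent x condition in a tidy trial table.

    Returns one row per fit with the MAP estimates, log-likelihood, BIC and
    convergence metadata. Per-fit optimizer seeds are derived
    deterministically from ``seed`` and the (agent, condition) position.
    """
    conds = list(conditions) if conditions is not None else list(Condition)
    variant_idx = 0 if variant is Variant.ONE_ALPHA else 1
    records = []
    for agent_idx, (agent_id, sub) in enumerate(table.groupby("agent_id", sort=True)):
        for cond_idx, cond in enumerate(conds):
            cond_trials = sub[sub["condition"] == cond.value]
            if len(cond_trials) == 0:
                continue
            fit = fit_map(
                cond_trials,
                variant,
                priors=priors,
                q0=q0,
                n_starts=n_starts,
                seed=_fit_seed(seed, agent_idx, cond_idx, variant_idx),
                outcome_values=outcome_values,
            )
            rec = {"agent_id": agent_id, "condition": cond.value}
            rec.update(fit.to_dict())
            records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Model comparison


@dataclass
class ComparisonReport:
    """One- vs two-learning-rate comparison across a cohort.

    ``per_fit`` holds one row per agent x condition with both BICs, their
    difference (one minus two; negative favors the one-rate model) and the
    preferred label. ``fraction_one_alpha`` is the per-condition proportion
    of agents whose BIC prefers the simpler model.
    """

    per_fit: pd.DataFrame
    fraction_one_alpha: dict[str, float] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.per_fit.to_csv(path, index=False)


def compare_models(
    table: pd.DataFrame,
    priors: PriorSpec = DEFAULT_PRIORS,
    q0: float = 0.0,
    n_starts: int = 10,
    seed: int = 0,
    conditions: Optional[Iterable[Condition]] = None,
    outcome_values: tuple[int, int] = (1, -1),
) -> ComparisonReport:
    """Fit both model variants to every agent x condition and compare by BIC.

    Ties in BIC go to the one-learning-rate model. Non-convergence flags
    from either fit propagate into the report.
    """
    kwargs = dict(
        priors=priors,
        q0=q0,
        n_starts=n_starts,
        seed=seed,
        conditions=conditions,
        outcome_values=outcome_values,
    )
    one = fit_cohort(table, Variant.ONE_ALPHA, **kwargs)
    two = fit_cohort(table, Variant.TWO_ALPHA, **kwargs)
    merged = one.merge(
        two, on=["agent_id", "condition"], suffixes=("_one", "_two"), validate="1:1"
    )
    per_fit = pd.DataFrame(
        {
            "agent_id": merged["agent_id"],
            "condition": merged["condition"],
            "alpha_one": merged["alpha_one"],
            "beta_one": merged["beta_one"],
            "alpha_gain_two": merged["alpha_gain_two"],
            "alpha_loss_two": merged["alpha_loss_two"],
            "beta_two": merged["beta_two"],
            "bic_one": merged["bic_one"],
            "bic_two": merged["bic_two"],
            "converged_one": merged["converged_one"],
            "converged_two": merged["converged_two"],
        }
    )
    per_fit["delta_bic"] = per_fit["bic_one"] - per_fit["bic_two"]
    per_fit["preferred"] = np.where(
        per_fit["bic_one"] <= per_fit["bic_two"],
        Variant.ONE_ALPHA.value,
        Variant.TWO_ALPHA.value,
    )
    fractions = (
        (per_fit["preferred"] == Variant.ONE_ALPHA.value)
        .groupby(per_fit["condition"])
        .mean()
        .to_dict()
    )
    return ComparisonReport(per_fit=per_fit, fraction_one_alpha=fractions)
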