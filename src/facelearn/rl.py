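"""Reinforcement-learning models of copy/not-copy avoidance learning.

The winning model is Rescorla-Wagner Q-learning over two actions — copy or
not copy the target interactant's expression — tracked separately per
interactant, with SoftMax choice

    P(copy) = exp((Q_copy + zeta) / beta) /
              [exp((Q_copy + zeta) / beta) + exp(Q_notcopy / beta)]

where ``zeta`` is a static copy bias and ``beta`` a temperature.  Values
update as Q <- Q + alpha * (r - Q) with r in {-1, +1} (shock / no shock);
all Q-values start at 0.  Alternative models drop the bias, replace it by a
learnable initial Q_copy offset, or let alpha or zeta depend on the target
expression.

Constraints: alpha in [0, 1] via a logistic transform, beta in (0, 2) via a
doubled logistic, zeta (and the initial-Q offset) unconstrained.  Models are
fit hierarchically on the unconstrained scale with standard-normal priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from ._mcmc import PosteriorDraws, sample_hierarchical
from .task import Expression, TrialSchedule, reinforcement

__all__ = [
    "RLParams",
    "QState",
    "ModelSpec",
    "MODELS",
    "SamplerConfig",
    "copy_probability",
    "update_q",
    "simulate_agent",
    "rl_log_likelihood",
    "fit_rl_hierarchical",
    "compare_models",
    "posterior_predict",
    "RLFit",
]

NOT_COPY, COPY = 0, 1


@dataclass(frozen=True)
class RLParams:
    """Constrained subject-level parameters of the copy-bias model."""

    alpha: float
    beta: float
    zeta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.beta < 2.0:
            raise ValueError(f"beta must be in (0, 2), got {self.beta}")


class QState:
    """Action values per (interactant, action), initialized to 0."""

    def __init__(self, q0_copy: float = 0.0) -> None:
        self.q = np.zeros((2, 2))  # (interactant-1, action)
        self.q[:, COPY] = q0_copy

    def value(self, interactant: int, action: int) -> float:
        return float(self.q[interactant - 1, action])

    def update(self, interactant: int, action: int, r: int, alpha: float) -> None:
        q = self.q[interactant - 1, action]
        self.q[interactant - 1, action] = update_q(q, r, alpha)


@dataclass(frozen=True)
class ModelSpec:
    """Parameter layout of one model variant (unconstrained parameter names)."""

    name: str
    param_names: tuple[str, ...]
    expr_dep_alpha: bool = False
    expr_dep_zeta: bool = False
    has_zeta: bool = False
    has_q0: bool = False


MODELS: dict[str, ModelSpec] = {
    "baseline_no_bias": ModelSpec("baseline_no_bias", ("alpha_u", "beta_u")),
    "copy_bias": ModelSpec("copy_bias", ("alpha_u", "beta_u", "zeta"), has_zeta=True),
    "prior_bias_only": ModelSpec(
        "prior_bias_only", ("alpha_u", "beta_u", "q0_copy"), has_q0=True
    ),
    "expr_dep_alpha": ModelSpec(
        "expr_dep_alpha",
        ("alpha_smile_u", "alpha_frown_u", "beta_u", "zeta"),
        expr_dep_alpha=True,
        has_zeta=True,
    ),
    "expr_dep_zeta": ModelSpec(
        "expr_dep_zeta",
        ("alpha_u", "beta_u", "zeta_smile", "zeta_frown"),
        expr_dep_zeta=True,
    ),
}


@dataclass(frozen=True)
class SamplerConfig:
    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int | None = None  # default: n_iter // 2
    thin: int = 1
    seed: int = 0

    def scaled(self, factor: float) -> "SamplerConfig":
        return replace(
            self,
            n_iter=max(200, int(self.n_iter * factor)),
            n_warmup=None,
        )


def copy_probability(
    q_copy: float, q_not_copy: float, zeta: float, beta: float
) -> float:
    """SoftMax probability of copying; overflow-safe."""
    if np.any(np.asarray(beta) <= 0):
        raise ValueError("beta must be positive")
    x = (np.asarray(q_copy) + zeta - np.asarray(q_not_copy)) / beta
    # clamp away from exact 0/1 so the open-interval contract survives
    # floating-point saturation at extreme value differences
    out = np.clip(expit(x), 5e-324, np.nextafter(1.0, 0.0))
    return float(out) if np.isscalar(q_copy) else out


def update_q(q: float, r: int, alpha: float) -> float:
    """Rescorla-Wagner update q + alpha * (r - q)."""
    if np.any(np.asarray(alpha) < 0) or np.any(np.asarray(alpha) > 1):
        raise ValueError("alpha must be in [0, 1]")
    return q + alpha * (r - q)


def simulate_agent(
    params: RLParams,
    schedule: TrialSchedule,
    seed: int,
    model: ModelSpec | str = "copy_bias",
    q0_copy: float = 0.0,
    zeta_by_expression: dict[Expression, float] | None = None,
    alpha_by_expression: dict[Expression, float] | None = None,
) -> pd.DataFrame:
    """Simulate one agent on a schedule.

    Returns a frame with columns choice ('copy'/'not_copy'), response,
    reinforcement, correct, plus the schedule columns.  Deterministic given
    ``seed``.
    """
    model = MODELS[model] if isinstance(model, str) else model
    rng = np.random.default_rng(seed)
    state = QState(q0_copy=q0_copy if model.has_q0 else 0.0)
    rows = []
    for trial in schedule:
        expr = trial.target_expression
        zeta = params.zeta
        if model.expr_dep_zeta and zeta_by_expression is not None:
            zeta = zeta_by_expression[expr]
        elif not (model.has_zeta or model.expr_dep_zeta):
            zeta = 0.0
        alpha = params.alpha
        if model.expr_dep_alpha and alpha_by_expression is not None:
            alpha = alpha_by_expression[expr]
        p_copy = copy_probability(
            state.value(trial.interactant, COPY),
            state.value(trial.interactant, NOT_COPY),
            zeta,
            params.beta,
        )
        action = COPY if rng.random() < p_copy else NOT_COPY
        response = expr if action == COPY else expr.opposite
        r = reinforcement(response, trial)
        state.update(trial.interactant, action, r, alpha)
        rows.append(
            {
                "participant_id": trial.participant_id,
                "trial_index": trial.index,
                "block": trial.block,
                "interactant": trial.interactant,
                "target_expression": expr.value,
                "condition": trial.condition,
                "correct_response": trial.correct_response.value,
                "choice": "copy" if action == COPY else "not_copy",
                "response": response.value,
                "reinforcement": r,
                "correct": int(r == 1),
                "shock": int(r == -1),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vectorized likelihood core
# ---------------------------------------------------------------------------


@dataclass
class _TrialArrays:
    """Padded per-subject trial arrays for vectorized likelihood evaluation."""

    choice: np.ndarray  # (S, T) 1 = copy
    r: np.ndarray  # (S, T) in {-1, +1}
    inter: np.ndarray  # (S, T) 0/1
    smile: np.ndarray  # (S, T) 1 = target smiled
    valid: np.ndarray  # (S, T) bool
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


def _records_to_arrays(records: pd.DataFrame) -> _TrialArrays:
    # Q-evolution is order-dependent: require trials already ordered per
    # participant rather than silently re-sorting
    subjects = list(records["participant_id"].unique())
    T = int(records.groupby("participant_id").size().max())
    S = len(subjects)
    shape = (S, T)
    choice = np.zeros(shape, dtype=np.int8)
    r = np.zeros(shape, dtype=np.int8)
    inter = np.zeros(shape, dtype=np.int8)
    smile = np.zeros(shape, dtype=np.int8)
    valid = np.zeros(shape, dtype=bool)
    for s, pid in enumerate(subjects):
        sub = records[records["participant_id"] == pid]
        if not sub["trial_index"].is_monotonic_increasing:
            raise ValueError("records must be ordered by trial index")
        n = len(sub)
        copy_mask = sub["response"].to_numpy() == sub["target_expression"].to_numpy()
        choice[s, :n] = copy_mask.astype(np.int8)
        r[s, :n] = np.where(sub["correct"].to_numpy() == 1, 1, -1)
        inter[s, :n] = sub["interactant"].to_numpy() - 1
        smile[s, :n] = (sub["target_expression"].to_numpy() == "smile").astype(np.int8)
        valid[s, :n] = True
    return _TrialArrays(choice, r, inter, smile, valid, subjects)


def _unpack_params(theta: np.ndarray, model: ModelSpec) -> dict[str, np.ndarray]:
    """Map unconstrained draws (..., P) to constrained parameter arrays."""
    names = model.param_names
    cols = {n: theta[..., i] for i, n in enumerate(names)}
    out: dict[str, np.ndarray] = {}
    if model.expr_dep_alpha:
        out["alpha_smile"] = expit(cols["alpha_smile_u"])
        out["alpha_frown"] = expit(cols["alpha_frown_u"])
    else:
        out["alpha"] = expit(cols["alpha_u"])
    out["beta"] = 2.0 * expit(cols["beta_u"])
    if model.expr_dep_zeta:
        out["zeta_smile"] = cols["zeta_smile"]
        out["zeta_frown"] = cols["zeta_frown"]
    elif model.has_zeta:
        out["zeta"] = cols["zeta"]
    if model.has_q0:
        out["q0_copy"] = cols["q0_copy"]
    return out


def _loglik_core(
    theta: np.ndarray,
    data: _TrialArrays,
    model: ModelSpec,
    pointwise: bool = False,
) -> np.ndarray:
    """Log-likelihood for unconstrained parameters theta (..., S, P).

    Returns (..., S) sums, or (..., S, T) per-trial terms if ``pointwise``
    (zero at padded/invalid positions).  The Q-state evolves only through
    valid (retained) trials, in trial order.
    """
    p = _unpack_params(theta, model)
    lead = theta.shape[:-2]
    S, T = data.valid.shape
    q = np.zeros(lead + (S, 2, 2))
    if model.has_q0:
        q[..., :, :, COPY] = p["q0_copy"][..., None]
    sidx = np.arange(S)
    ll = np.zeros(lead + (S, T)) if pointwise else np.zeros(lead + (S,))
    beta = p["beta"]
    for t in range(T):
        v = data.valid[:, t]
        if not v.any():
            continue
        i = data.inter[:, t]
        ch = data.choice[:, t]
        sm = data.smile[:, t].astype(bool)
        q_c = q[..., sidx, i, COPY]
        q_n = q[..., sidx, i, NOT_COPY]
        if model.expr_dep_zeta:
            zeta = np.where(sm, p["zeta_smile"], p["zeta_frown"])
        elif model.has_zeta:
            zeta = p["zeta"]
        else:
            zeta = 0.0
        x = (q_c + zeta - q_n) / beta
        lp = -np.logaddexp(0.0, np.where(ch == COPY, -x, x))
        if pointwise:
            ll[..., :, t] = np.where(v, lp, 0.0)
        else:
            ll += np.where(v, lp, 0.0)
        if model.expr_dep_alpha:
            alpha = np.where(sm, p["alpha_smile"], p["alpha_frown"])
        else:
            alpha = p["alpha"]
        q_chosen = q[..., sidx, i, ch]
        q[..., sidx, i, ch] = np.where(
            v, q_chosen + alpha * (data.r[:, t] - q_chosen), q_chosen
        )
    return ll


def rl_log_likelihood(
    params: RLParams | dict[str, float],
    records: pd.DataFrame,
    model: ModelSpec | str = "copy_bias",
) -> float:
    """Log-likelihood of one subject's observed choices under the model.

    ``records`` must be a single participant's trials ordered by trial index
    (excluded trials absent); Q-evolution uses the observed reinforcements.
    """
    model = MODELS[model] if isinstance(model, str) else model
    if records["participant_id"].nunique() != 1:
        raise ValueError("rl_log_likelihood expects a single participant")
    data = _records_to_arrays(records)
    if isinstance(params, RLParams):
        params = {"alpha": params.alpha, "beta": params.beta, "zeta": params.zeta}
    theta = np.array([[_to_unconstrained(params, n) for n in model.param_names]])
    return float(_loglik_core(theta, data, model)[0])


def _to_unconstrained(params: dict[str, float], name: str) -> float:
    def logit(x):
        x = min(max(x, 1e-12), 1 - 1e-12)
        return float(np.log(x / (1 - x)))

    if name == "alpha_u":
        return logit(params["alpha"])
    if name in ("alpha_smile_u", "alpha_frown_u"):
        key = "alpha_" + name.split("_")[1]
        return logit(params.get(key, params.get("alpha", 0.5)))
    if name == "beta_u":
        return logit(params["beta"] / 2.0)
    if name in ("zeta", "zeta_smile", "zeta_frown", "q0_copy"):
        return float(params.get(name, params.get("zeta", 0.0)))
    raise KeyError(name)


# ---------------------------------------------------------------------------
# hierarchical fitting / comparison / prediction
# ---------------------------------------------------------------------------


@dataclass
class RLFit:
    """Hierarchical fit of one RL model variant."""

    model: ModelSpec
    draws: PosteriorDraws
    data: _TrialArrays

    def population_means(self) -> dict[str, float]:
        """Posterior means of the constrained population-average parameters
        (transform applied to the population location draws)."""
        mu = self.draws.stacked("mu")  # (N, P)
        p = _unpack_params(mu, self.model)
        return {k: float(np.mean(v)) for k, v in p.items()}

    def population_intervals(self, prob: float = 0.95) -> dict[str, tuple[float, float]]:
        mu = self.draws.stacked("mu")
        p = _unpack_params(mu, self.model)
        lo, hi = (1 - prob) / 2, 1 - (1 - prob) / 2
        return {
            k: (float(np.quantile(v, lo)), float(np.quantile(v, hi)))
            for k, v in p.items()
        }

    def pointwise_loglik(self, max_draws: int = 500) -> np.ndarray:
        """Per-trial log-likelihood draws (chain, draw, n_obs) for LOO."""
        theta = self.draws.draws["theta"]  # (C, D, S, P)
        C, D = theta.shape[:2]
        step = max(1, D // max_draws)
        theta = theta[:, ::step]
        ll = _loglik_core(theta, self.data, self.model, pointwise=True)
        return ll[..., self.data.valid]  # (C, D', n_obs)


def fit_rl_hierarchical(
    records: pd.DataFrame,
    model: ModelSpec | str = "copy_bias",
    config: SamplerConfig = SamplerConfig(),
) -> RLFit:
    """Fit a model variant hierarchically to all participants in ``records``.

    Subject parameters are sampled on the unconstrained scale as deviations
    from population locations with standard-normal priors; posterior draws
    and convergence diagnostics (R-hat, ESS) are attached.
    """
    model = MODELS[model] if isinstance(model, str) else model
    data = _records_to_arrays(records)
    if len(data.subject_ids) < 2:
        raise ValueError("hierarchical fit requires >= 2 participants")

    def loglik(theta_u: np.ndarray) -> np.ndarray:
        return _loglik_core(theta_u[None], data, model)[0]

    post = sample_hierarchical(
        loglik,
        n_subjects=len(data.subject_ids),
        param_names=list(model.param_names),
        seed=config.seed,
        n_chains=config.n_chains,
        n_iter=config.n_iter,
        n_warmup=config.n_warmup,
        thin=config.thin,
        subject_ids=data.subject_ids,
    )
    post.meta["model"] = model.name
    return RLFit(model=model, draws=post, data=data)


def compare_models(
    records: pd.DataFrame,
    models: list[ModelSpec | str],
    config: SamplerConfig = SamplerConfig(),
    max_loglik_draws: int = 400,
) -> pd.DataFrame:
    """Fit all models on identical data and rank them by PSIS-LOO.

    Returns one row per model with elpd_loo, its standard error, the rank
    (0 = best), and a flag for unreliable importance weights (Pareto
    k > 0.7).  Ties (elpd difference within joint SE) are reported via the
    ``within_se_of_best`` column, not broken silently.
    """
    import arviz as az

    rows = []
    fits = {}
    for m in models:
        spec = MODELS[m] if isinstance(m, str) else m
        fit = fit_rl_hierarchical(records, spec, config)
        fits[spec.name] = fit
        ll = fit.pointwise_loglik(max_loglik_draws)
        step = max(1, fit.draws.n_draws // max_loglik_draws)
        idata = az.from_dict(
            posterior={"mu": fit.draws.draws["mu"][:, ::step]},
            log_likelihood={"obs": ll},
        )
        loo = az.loo(idata, pointwise=True)
        rows.append(
            {
                "model": spec.name,
                "elpd_loo": float(loo.elpd_loo),
                "se": float(loo.se),
                "p_loo": float(loo.p_loo),
                "n_high_pareto_k": int((loo.pareto_k.values > 0.7).sum()),
                "warning": bool(loo.warning),
            }
        )
    table = pd.DataFrame(rows).sort_values("elpd_loo", ascending=False)
    table["rank"] = range(len(table))
    best = table.iloc[0]
    table["within_se_of_best"] = (
        best["elpd_loo"] - table["elpd_loo"]
    ) <= np.sqrt(best["se"] ** 2 + table["se"] ** 2)
    return table.reset_index(drop=True)


def posterior_predict(
    fit: RLFit,
    schedule: TrialSchedule,
    n_sims_per_draw: int = 100,
    n_draws: int = 100,
    seed: int = 0,
    interval: float = 0.80,
) -> pd.DataFrame:
    """Posterior-predictive learning curves per CI/IC condition.

    CI = the interactant requiring congruent responses in block 1 (and
    incongruent after the reversal); IC the converse.  For each subject,
    ``n_draws`` posterior draws are each simulated ``n_sims_per_draw`` times
    on ``schedule``; the returned frame has, per condition and per-condition
    trial number (1..2*reps, reversal after reps), the predicted mean CR
    averaged over participants and the participant-average bounds of the
    central ``interval`` predictive band across draws.
    """
    rng = np.random.default_rng(seed)
    model = fit.model
    theta = fit.draws.draws["theta"]  # (C, D, S, P)
    C, D, S, P = theta.shape
    flat = theta.reshape(C * D, S, P)
    take = rng.choice(C * D, size=min(n_draws, C * D), replace=False)
    theta_sel = flat[take]  # (Dd, S, P)
    Dd = theta_sel.shape[0]

    trials = list(schedule)
    T = len(trials)
    inter = np.array([t.interactant - 1 for t in trials])
    smile = np.array([t.target_expression is Expression.SMILE for t in trials])
    copy_correct = np.array(
        [t.correct_response == t.target_expression for t in trials]
    )  # copy is the correct action
    ci_interactant = schedule.contingencies.copy_interactant_block1 - 1

    # batch: (Dd, S, n_sims)
    p = _unpack_params(theta_sel, model)  # arrays (Dd, S)
    B = (Dd, S, n_sims_per_draw)
    q = np.zeros(B + (2, 2))
    if model.has_q0:
        q[..., COPY] = p["q0_copy"][..., None, None]
    correct_sim = np.zeros(B + (T,), dtype=np.int8)
    beta = p["beta"][..., None]
    for t in range(T):
        i = inter[t]
        if model.expr_dep_zeta:
            zeta = (p["zeta_smile"] if smile[t] else p["zeta_frown"])[..., None]
        elif model.has_zeta:
            zeta = p["zeta"][..., None]
        else:
            zeta = 0.0
        p_copy = expit((q[..., i, COPY] + zeta - q[..., i, NOT_COPY]) / beta)
        act = (rng.random(B) < p_copy).astype(np.int8)
        corr = (act == COPY) == copy_correct[t]
        correct_sim[..., t] = corr
        r = np.where(corr, 1, -1)
        if model.expr_dep_alpha:
            alpha = (p["alpha_smile"] if smile[t] else p["alpha_frown"])[..., None]
        else:
            alpha = p["alpha"][..., None]
        q_ch = np.take_along_axis(
            q[..., i, :], act[..., None], axis=-1
        )[..., 0]
        upd = q_ch + alpha * (r - q_ch)
        np.put_along_axis(q[..., i, :], act[..., None], upd[..., None], axis=-1)

    # per-condition trial numbering: within (interactant, expression) clip,
    # then averaged over the two expressions at each relative number
    clip_key = inter * 2 + smile.astype(int)
    cond_trial = np.zeros(T, dtype=int)
    counters: dict[int, int] = {}
    for t in range(T):
        counters[clip_key[t]] = counters.get(clip_key[t], 0) + 1
        cond_trial[t] = counters[clip_key[t]]

    rows = []
    for label, i_sel in (("CI", ci_interactant), ("IC", 1 - ci_interactant)):
        for ct in range(1, cond_trial.max() + 1):
            cols = (inter == i_sel) & (cond_trial == ct)
            # per draw/subject mean CR over sims and matching trials
            per_draw = correct_sim[..., cols].mean(axis=(2, 3))  # (Dd, S)
            per_subj_mean = per_draw.mean(axis=0)  # (S,)
            lo = np.quantile(per_draw, (1 - interval) / 2, axis=0)
            hi = np.quantile(per_draw, 1 - (1 - interval) / 2, axis=0)
            rows.append(
                {
                    "condition": label,
                    "cond_trial": ct,
                    "mean_cr": float(per_subj_mean.mean()),
                    "band_low": float(lo.mean()),
                    "band_high": float(hi.mean()),
                }
            )
    return pd.DataFrame(rows)
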