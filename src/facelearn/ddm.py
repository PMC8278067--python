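"""Response-coded Wiener drift-diffusion model.

Upper boundary = smile, lower boundary = frown; unit diffusion coefficient
(boundary separation absorbs the scale).  Drift ``v`` and boundary
separation ``a`` are indexed by the 2x2 cell of target expression x required
response (cell-means parameterization); the starting-point bias ``z`` is
indexed by target expression only; non-decision time ``t0`` is a per-subject
scalar added to the first-passage time.

The first-passage density uses the classic small-time / large-time series
with adaptive truncation, switched per evaluation point at the
representation needing fewer terms for the requested tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._mcmc import PosteriorDraws, sample_hierarchical

__all__ = [
    "CELLS",
    "DDMParams",
    "ContrastSummary",
    "wiener_fpt_density",
    "prob_upper",
    "simulate_ddm",
    "sample_first_passage",
    "ddm_log_likelihood",
    "fit_ddm_hierarchical",
    "DDMFit",
    "contrast_drift_congruency",
    "contrast_expression",
]

#: (target_expression, required_response); first two cells are congruent
CELLS: tuple[tuple[str, str], ...] = (
    ("smile", "smile"),
    ("frown", "frown"),
    ("smile", "frown"),
    ("frown", "smile"),
)
CELL_INDEX = {cell: i for i, cell in enumerate(CELLS)}

PARAM_NAMES = (
    [f"v_{t}_{r}" for t, r in CELLS]
    + [f"log_a_{t}_{r}" for t, r in CELLS]
    + ["logit_z_smile", "logit_z_frown", "log_t0"]
)
_V = slice(0, 4)
_A = slice(4, 8)
_Z = slice(8, 10)
_T0 = 10


@dataclass(frozen=True)
class DDMParams:
    """Condition-indexed parameters for one subject.

    v and a are keyed by (target_expression, required_response); z by target
    expression.  Drift is in evidence units per second, positive toward the
    smile (upper) boundary.
    """

    v: dict[tuple[str, str], float]
    a: dict[tuple[str, str], float]
    z: dict[str, float]
    t0: float = 0.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.a.values()):
            raise ValueError("boundary separation must be positive")
        if any(not 0 < z < 1 for z in self.z.values()):
            raise ValueError("starting-point bias must be in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time must be non-negative")
        if any(not np.isfinite(v) for v in self.v.values()):
            raise ValueError("drift must be finite")


@dataclass(frozen=True)
class ContrastSummary:
    mean: float
    cri_95: tuple[float, float]
    fraction_positive: float

    def __post_init__(self) -> None:
        # equality only for point-mass draws (e.g. structurally zero contrasts)
        if not self.cri_95[0] <= self.cri_95[1]:
            raise ValueError("credible interval must have low <= high")

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "cri_95": list(self.cri_95),
            "fraction_positive": self.fraction_positive,
        }

    @classmethod
    def from_draws(cls, x: np.ndarray) -> "ContrastSummary":
        return cls(
            mean=float(np.mean(x)),
            cri_95=(float(np.quantile(x, 0.025)), float(np.quantile(x, 0.975))),
            fraction_positive=float(np.mean(x > 0)),
        )


# ---------------------------------------------------------------------------
# first-passage density and choice probability
# ---------------------------------------------------------------------------


def _phi_lower(w: np.ndarray, z: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Standardized lower-boundary density f(w | 0, 1, z), w = t / a^2.

    Small-time and large-time series, each truncated for absolute error
    ``tol``, evaluated where it needs fewer terms.
    """
    w = np.asarray(w, dtype=float)
    z = np.broadcast_to(np.asarray(z, dtype=float), w.shape)
    out = np.empty_like(w)

    # terms needed (Navarro & Fuss 2009)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * tol * np.sqrt(2.0 * np.pi * w)
        k_small = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * w * np.log(arg_s), 0.0)),
            2.0,
        )
        k_small = np.maximum(k_small, np.sqrt(w) + 1.0)
        arg_l = np.pi * w * tol
        k_large = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0) / (np.pi**2 * w)),
            1.0 / (np.pi * np.sqrt(np.maximum(w, 1e-300))),
        )
        k_large = np.maximum(k_large, 1.0)

    use_small = np.ceil(k_small) < np.ceil(k_large)

    if np.any(use_small):
        ws, zs = w[use_small], z[use_small]
        K = int(np.ceil(k_small[use_small].max()))
        ks = np.arange(-((K + 1) // 2), (K + 1) // 2 + 1)
        term = (zs[..., None] + 2.0 * ks) * np.exp(
            -((zs[..., None] + 2.0 * ks) ** 2) / (2.0 * ws[..., None])
        )
        out[use_small] = term.sum(axis=-1) / np.sqrt(2.0 * np.pi * ws**3)

    use_large = ~use_small
    if np.any(use_large):
        wl, zl = w[use_large], z[use_large]
        K = int(np.ceil(k_large[use_large].max()))
        ks = np.arange(1, K + 1)
        term = (
            ks
            * np.exp(-(ks**2) * np.pi**2 * wl[..., None] / 2.0)
            * np.sin(ks * np.pi * zl[..., None])
        )
        out[use_large] = np.pi * term.sum(axis=-1)

    return np.maximum(out, 0.0)


def wiener_fpt_density(
    t: np.ndarray | float,
    v: np.ndarray | float,
    a: np.ndarray | float,
    z: np.ndarray | float,
    boundary: str = "lower",
    tol: float = 1e-7,
) -> np.ndarray | float:
    """First-passage-time density of a unit-diffusion Wiener process.

    ``t`` is decision time (observed RT minus t0).  The upper-boundary
    density is the lower-boundary density under the reflection
    (v, z) -> (-v, 1 - z).
    """
    scalar = np.isscalar(t) and np.isscalar(v)
    t, v, a, z = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t, v, a, z))
    )
    if np.any(t <= 0):
        raise ValueError("decision time must be positive")
    if np.any(a <= 0) or np.any((z <= 0) | (z >= 1)):
        raise ValueError("require a > 0 and z in (0, 1)")
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(a))):
        raise ValueError("parameters must be finite")
    if boundary == "upper":
        v, z = -v, 1.0 - z
    elif boundary != "lower":
        raise ValueError("boundary must be 'upper' or 'lower'")
    w = t / a**2
    dens = np.exp(-v * a * z - v**2 * t / 2.0) / a**2 * _phi_lower(w, z, tol)
    return float(dens) if scalar else dens


def log_wiener_fpt_density(t, v, a, z, upper: np.ndarray) -> np.ndarray:
    """Vectorized log density with per-element boundary (upper True/False)."""
    t, v, a, z, upper = np.broadcast_arrays(
        np.asarray(t, float), np.asarray(v, float), np.asarray(a, float),
        np.asarray(z, float), np.asarray(upper),
    )
    v_eff = np.where(upper, -v, v)
    z_eff = np.where(upper, 1.0 - z, z)
    bad = (t <= 0) | (a <= 0) | (z_eff <= 0) | (z_eff >= 1)
    t_safe = np.where(bad, 1.0, t)
    w = t_safe / a**2
    phi = _phi_lower(w, z_eff)
    with np.errstate(divide="ignore"):
        logdens = (
            -v_eff * a * z_eff - v_eff**2 * t_safe / 2.0
            - 2.0 * np.log(a)
            + np.log(np.maximum(phi, 1e-300))
        )
    return np.where(bad, -np.inf, logdens)


def prob_upper(v: float, a: float, z: float) -> float:
    """Closed-form probability of absorption at the upper boundary."""
    if a <= 0 or not 0 < z < 1:
        raise ValueError("require a > 0 and z in (0, 1)")
    if abs(v) < 1e-12:
        return float(z)
    num = 1.0 - np.exp(-2.0 * v * a * z)
    den = 1.0 - np.exp(-2.0 * v * a)
    return float(num / den)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_ddm(
    v: float,
    a: float,
    z: float,
    t0: float,
    n: int,
    seed: int,
    dt: float = 1e-4,
    horizon_s: float = 20.0,
) -> pd.DataFrame:
    """Euler-Maruyama simulation of n first passages.

    Returns a frame with columns boundary ('upper_smile'/'lower_frown') and
    rt_s (crossing time + t0).  Walks not absorbed within ``horizon_s`` are
    excluded; their count is in ``frame.attrs['n_censored']``.
    """
    if n < 1 or dt <= 0:
        raise ValueError("require n >= 1 and dt > 0")
    rng = np.random.default_rng(seed)
    x = np.full(n, z * a)
    alive = np.ones(n, dtype=bool)
    rt = np.full(n, np.nan)
    up = np.zeros(n, dtype=bool)
    sqdt = np.sqrt(dt)
    n_steps = int(horizon_s / dt)
    for step in range(1, n_steps + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        x[idx] += v * dt + sqdt * rng.standard_normal(idx.size)
        crossed_up = x[idx] >= a
        crossed_lo = x[idx] <= 0.0
        done = crossed_up | crossed_lo
        fin = idx[done]
        rt[fin] = step * dt + t0
        up[fin] = crossed_up[done]
        alive[fin] = False
    censored = int(alive.sum())
    keep = ~alive
    frame = pd.DataFrame(
        {
            "boundary": np.where(up[keep], "upper_smile", "lower_frown"),
            "rt_s": rt[keep],
        }
    )
    frame.attrs["n_censored"] = censored
    return frame


def sample_first_passage(
    v: float,
    a: float,
    z: float,
    t0: float,
    n: int,
    rng: np.random.Generator,
    boundary: str | None = None,
    t_max: float = 12.0,
    grid: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (rt_s, is_upper) via inverse-CDF sampling of the exact density.

    If ``boundary`` is given ('upper'/'lower'), RTs are drawn from the
    first-passage distribution conditional on that boundary.
    """
    t = np.linspace(t_max / grid, t_max, grid)
    p_up = prob_upper(v, a, z)
    if boundary is None:
        is_upper = rng.random(n) < p_up
    else:
        is_upper = np.full(n, boundary == "upper")
    rts = np.empty(n)
    for upper in (True, False):
        m = is_upper == upper
        if not m.any():
            continue
        dens = wiener_fpt_density(t, v, a, z, boundary="upper" if upper else "lower")
        cdf = np.cumsum(dens)
        if cdf[-1] <= 0:
            rts[m] = t_max + t0
            continue
        cdf /= cdf[-1]
        u = rng.random(int(m.sum()))
        rts[m] = np.interp(u, cdf, t) + t0
    return rts, is_upper


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _obs_cells(observations: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cell = np.array(
        [
            CELL_INDEX[(t, r)]
            for t, r in zip(
                observations["target_expression"], observations["required_response"]
            )
        ]
    )
    upper = observations["response"].to_numpy() == "smile"
    rt = observations["rt_s"].to_numpy(dtype=float)
    return rt, upper, cell


def ddm_log_likelihood(observations: pd.DataFrame, params: DDMParams) -> float:
    """Total log-likelihood of observed (response, RT) pairs.

    Each observation uses the density at rt - t0 with the boundary matching
    the observed response and the (v, a, z) of its condition cell.  Any
    rt <= t0 contributes -inf (data/parameter conflict).
    """
    rt, upper, cell = _obs_cells(observations)
    v = np.array([params.v[c] for c in CELLS])[cell]
    a = np.array([params.a[c] for c in CELLS])[cell]
    z = np.array([params.z[c[0]] for c in CELLS])[cell]
    ll = log_wiener_fpt_density(rt - params.t0, v, a, z, upper)
    return float(ll.sum())


# ---------------------------------------------------------------------------
# hierarchical fit
# ---------------------------------------------------------------------------


@dataclass
class _DDMArrays:
    rt: np.ndarray  # (S, T)
    upper: np.ndarray  # (S, T) bool
    cell: np.ndarray  # (S, T) int 0..3
    valid: np.ndarray  # (S, T) bool
    subject_ids: list[str] = field(default_factory=list)


def _ddm_records_to_arrays(records: pd.DataFrame) -> _DDMArrays:
    rec = records.sort_values(["participant_id", "trial_index"]).copy()
    subjects = list(rec["participant_id"].unique())
    T = int(rec.groupby("participant_id").size().max())
    S = len(subjects)
    rt = np.ones((S, T))
    upper = np.zeros((S, T), dtype=bool)
    cell = np.zeros((S, T), dtype=int)
    valid = np.zeros((S, T), dtype=bool)
    for s, pid in enumerate(subjects):
        sub = rec[rec["participant_id"] == pid]
        n = len(sub)
        r, u, c = _obs_cells(sub)
        rt[s, :n], upper[s, :n], cell[s, :n] = r, u, c
        valid[s, :n] = True
    return _DDMArrays(rt, upper, cell, valid, subjects)


def _theta_to_cells(theta: np.ndarray) -> dict[str, np.ndarray]:
    """Unconstrained (..., 11) -> constrained cell arrays."""
    return {
        "v": theta[..., _V],
        "a": np.exp(theta[..., _A]),
        "z": expit(theta[..., _Z]),  # order: smile, frown
        "t0": np.exp(theta[..., _T0]),
    }


@dataclass
class DDMFit:
    draws: PosteriorDraws
    data: _DDMArrays

    def population_cell_draws(self) -> dict[str, np.ndarray]:
        """Population-level condition parameters per posterior draw.

        v: (N, 4) in CELLS order; a: (N, 4); z: (N, 2) [smile, frown];
        t0: (N,).  a, z, t0 are transforms of the population location
        (population-median scale).
        """
        mu = self.draws.stacked("mu")
        p = _theta_to_cells(mu)
        return {"v": p["v"], "a": p["a"], "z": p["z"], "t0": p["t0"]}

    def population_means(self) -> dict[str, np.ndarray]:
        d = self.population_cell_draws()
        return {k: np.mean(val, axis=0) for k, val in d.items()}


def fit_ddm_hierarchical(
    records: pd.DataFrame,
    config=None,
    seed: int = 0,
    n_chains: int | None = None,
    n_iter: int | None = None,
    n_warmup: int | None = None,
    thin: int = 1,
) -> DDMFit:
    """Hierarchical fit of the condition-indexed Wiener model.

    ``records`` is the tidy frame with columns participant_id, trial_index,
    target_expression, required_response, response, rt_s.  Defaults mirror
    the 6 chains x 10,000 iterations (1,000 warm-up) estimation scheme; pass
    a :class:`facelearn.rl.SamplerConfig` or explicit sizes for desk-scale
    runs.  Subjects vary in all parameters; populations get weakly
    informative priors on the unconstrained scale.
    """
    if config is not None:
        n_chains = config.n_chains
        n_iter = config.n_iter
        n_warmup = config.n_warmup
        thin = config.thin
        seed = config.seed
    n_chains = 6 if n_chains is None else n_chains
    n_iter = 10_000 if n_iter is None else n_iter
    if n_warmup is None:
        n_warmup = 1_000 if n_iter >= 4_000 else n_iter // 2

    data = _ddm_records_to_arrays(records)
    if len(data.subject_ids) < 2:
        raise ValueError("hierarchical fit requires >= 2 participants")
    S = len(data.subject_ids)
    min_rt = np.where(data.valid, data.rt, np.inf).min(axis=1)

    def loglik(theta_u: np.ndarray) -> np.ndarray:
        p = _theta_to_cells(theta_u)
        v = np.take_along_axis(p["v"], data.cell, axis=1)
        a = np.take_along_axis(p["a"], data.cell, axis=1)
        # cells 1 (frown,frown) and 3 (frown,smile) have frown targets
        z_idx = np.isin(data.cell, (1, 3)).astype(int)
        z = np.take_along_axis(p["z"], z_idx, axis=1)
        t = data.rt - p["t0"][:, None]
        ll = log_wiener_fpt_density(
            np.where(data.valid & (t > 0), t, 1.0), v, a, z, data.upper
        )
        ll = np.where(data.valid, np.where(t > 0, ll, -np.inf), 0.0)
        return ll.sum(axis=1)

    init = np.zeros((S, 11))
    init[:, _A] = np.log(1.5)
    init[:, _T0] = np.log(np.minimum(0.3, 0.5 * min_rt))

    prior_mean = np.zeros(11)
    prior_mean[_A] = np.log(1.5)
    prior_mean[_T0] = np.log(0.3)
    prior_sd = np.ones(11)
    prior_sd[_V] = 2.0

    post = sample_hierarchical(
        loglik,
        n_subjects=S,
        param_names=list(PARAM_NAMES),
        seed=seed,
        n_chains=n_chains,
        n_iter=n_iter,
        n_warmup=n_warmup,
        thin=thin,
        sub_blocks=[list(range(4)), list(range(4, 8)), [8, 9], [10]],
        mu_prior_mean=prior_mean,
        mu_prior_sd=prior_sd,
        sigma_prior_sd=0.5,
        init_theta=init,
        subject_ids=data.subject_ids,
    )
    post.meta["model"] = "wiener_cell_means"
    return DDMFit(draws=post, data=data)


# ---------------------------------------------------------------------------
# posterior contrasts
# ---------------------------------------------------------------------------


def contrast_drift_congruency(v_draws: np.ndarray) -> dict[str, ContrastSummary]:
    """Absolute-drift congruency contrast, computed per posterior sample.

    ``v_draws`` is (N, 4) in CELLS order (congruent smile, congruent frown,
    incongruent smile, incongruent frown).  Returns the sum-based contrast
    (|v_cs| + |v_cf|) - (|v_is| + |v_if|) and its per-condition-mean (/2)
    variant.
    """
    av = np.abs(v_draws)
    diff = (av[:, 0] + av[:, 1]) - (av[:, 2] + av[:, 3])
    return {
        "sum": ContrastSummary.from_draws(diff),
        "mean": ContrastSummary.from_draws(diff / 2.0),
    }


def contrast_expression(
    draws: dict[str, np.ndarray], parameter: str
) -> ContrastSummary:
    """Target-expression contrast (smile - frown), per posterior sample.

    parameter 'v_abs' or 'a': marginalizes over congruency (mean of the two
    cells per expression); 'z': directly z_smile - z_frown.
    """
    if parameter == "z":
        z = draws["z"]
        return ContrastSummary.from_draws(z[:, 0] - z[:, 1])
    if parameter == "v_abs":
        x = np.abs(draws["v"])
    elif parameter == "a":
        x = draws["a"]
    else:
        raise ValueError("parameter must be one of 'v_abs', 'a', 'z'")
    smile = (x[:, 0] + x[:, 2]) / 2.0  # cells with smiling target
    frown = (x[:, 1] + x[:, 3]) / 2.0
    return ContrastSummary.from_draws(smile - frown)
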