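"""Ground-truthed synthetic datasets mirroring the experiment's structure.

Default scale: 58 participants x 96 trials (4 clips x 12 repetitions x 2
blocks) = 5568 trials before artifact injection.  Choices come either from
the copy-bias RL model (``rl_choices`` mode, RTs then drawn from the
condition-matched Wiener first-passage distribution conditional on the
chosen boundary) or jointly from the condition-indexed Wiener process
(``ddm_joint`` mode).  Artifacts — fast non-compliance trials (RT resampled
uniformly below the 626 ms cutoff) and no-response trials — are injected
with known labels so the filtering rules can be scored exactly.

Truth values are generator inputs chosen for sign-realism, never estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.special import expit, logit

from . import ddm as ddm_mod
from .ddm import CELLS, sample_first_passage
from .preprocess import FAST_CUTOFF_MS
from .rl import MODELS, RLParams, simulate_agent
from .task import ContingencyMap, generate_schedule, schedule_to_frame

__all__ = ["RLPopulation", "DDMPopulation", "GeneratorConfig", "SyntheticDataset",
           "generate_dataset", "truth_report", "load_truth_report"]


class RLPopulation(BaseModel):
    """Population truth for the copy-bias RL model (constrained scale means,
    between-subject SDs on the unconstrained scale)."""

    alpha: float = 0.3
    beta: float = 0.5
    zeta: float = 0.5
    sd_alpha_u: float = 0.5
    sd_beta_u: float = 0.3
    sd_zeta: float = 0.3


class DDMPopulation(BaseModel):
    """Population truth for the Wiener model, cell order
    (smile,smile), (frown,frown), (smile,frown), (frown,smile)."""

    v: tuple[float, float, float, float] = (1.5, -1.5, -1.0, 1.0)
    a: tuple[float, float, float, float] = (1.9, 2.1, 1.6, 1.8)
    z_smile: float = 0.55
    z_frown: float = 0.50
    t0: float = 0.8
    sd_v: float = 0.25
    sd_log_a: float = 0.12
    sd_logit_z: float = 0.15
    sd_log_t0: float = 0.15


class ArtifactRates(BaseModel):
    p_fast_noncompliance: float = Field(0.10, ge=0.0, le=1.0)
    p_no_response: float = Field(0.01, ge=0.0, le=1.0)


class GeneratorConfig(BaseModel):
    n_participants: int = Field(58, ge=1)
    reps_per_clip: int = Field(12, ge=1)
    rl_population: RLPopulation = RLPopulation()
    ddm_population: DDMPopulation = DDMPopulation()
    artifact_rates: ArtifactRates = ArtifactRates()
    counterbalance: bool = True
    seed: int = 0


@dataclass
class SyntheticDataset:
    records: pd.DataFrame
    truth: dict
    artifact_labels: pd.Series  # aligned with records: clean/fast/no_response
    config: GeneratorConfig = field(repr=False, default=None)


def _draw_subject_rl(pop: RLPopulation, rng: np.random.Generator) -> RLParams:
    a_u = logit(np.clip(pop.alpha, 1e-6, 1 - 1e-6)) + pop.sd_alpha_u * rng.standard_normal()
    b_u = logit(np.clip(pop.beta / 2, 1e-6, 1 - 1e-6)) + pop.sd_beta_u * rng.standard_normal()
    zeta = pop.zeta + pop.sd_zeta * rng.standard_normal()
    return RLParams(alpha=float(expit(a_u)), beta=float(2 * expit(b_u)), zeta=float(zeta))


def _draw_subject_ddm(pop: DDMPopulation, rng: np.random.Generator) -> ddm_mod.DDMParams:
    v = {c: pop.v[i] + pop.sd_v * rng.standard_normal() for i, c in enumerate(CELLS)}
    a = {
        c: float(np.exp(np.log(pop.a[i]) + pop.sd_log_a * rng.standard_normal()))
        for i, c in enumerate(CELLS)
    }
    z = {
        "smile": float(expit(logit(pop.z_smile) + pop.sd_logit_z * rng.standard_normal())),
        "frown": float(expit(logit(pop.z_frown) + pop.sd_logit_z * rng.standard_normal())),
    }
    t0 = float(np.exp(np.log(pop.t0) + pop.sd_log_t0 * rng.standard_normal()))
    return ddm_mod.DDMParams(v=v, a=a, z=z, t0=t0)


def _rt_for_choices(
    frame: pd.DataFrame, params: ddm_mod.DDMParams, rng: np.random.Generator
) -> np.ndarray:
    """Condition-matched Wiener RTs conditional on the chosen boundary."""
    rt = np.empty(len(frame))
    cells = list(zip(frame["target_expression"], frame["correct_response"]))
    boundary = np.where(frame["response"].to_numpy() == "smile", "upper", "lower")
    keys = pd.Series([c + (b,) for c, b in zip(cells, boundary)])
    for key, idx in keys.groupby(keys).groups.items():
        t, r, b = key
        rts, _ = sample_first_passage(
            params.v[(t, r)], params.a[(t, r)], params.z[t], params.t0,
            n=len(idx), rng=rng, boundary=b,
        )
        rt[np.asarray(idx)] = rts
    return rt


def generate_dataset(config: GeneratorConfig, mode: str = "rl_choices") -> SyntheticDataset:
    """Generate a full cohort dataset with stored per-subject truth.

    Deterministic given ``config.seed``; per-participant randomness uses
    spawned substreams.
    """
    if mode not in ("rl_choices", "ddm_joint"):
        raise ValueError(f"unknown mode: {mode}")
    ss = np.random.SeedSequence(config.seed)
    sub_seeds = ss.spawn(config.n_participants + 1)
    artifact_rng = np.random.default_rng(sub_seeds[-1])

    frames = []
    truth: dict = {"mode": mode, "participants": {}}
    for i in range(config.n_participants):
        pid = f"p{i + 1:03d}"
        rng = np.random.default_rng(sub_seeds[i])
        copy_first = 1 if (not config.counterbalance or i % 2 == 0) else 2
        contingencies = ContingencyMap(copy_interactant_block1=copy_first)
        schedule = generate_schedule(
            seed=int(rng.integers(2**31)),
            reps_per_clip=config.reps_per_clip,
            participant_id=pid,
            contingencies=contingencies,
        )
        rl_params = _draw_subject_rl(config.rl_population, rng)
        ddm_params = _draw_subject_ddm(config.ddm_population, rng)

        if mode == "rl_choices":
            frame = simulate_agent(
                rl_params, schedule, seed=int(rng.integers(2**31)), model="copy_bias"
            )
            frame["rt_s"] = _rt_for_choices(frame.reset_index(drop=True), ddm_params, rng)
        else:
            frame = schedule_to_frame(schedule)
            rt = np.empty(len(frame))
            resp = np.empty(len(frame), dtype=object)
            cells = pd.Series(
                list(zip(frame["target_expression"], frame["correct_response"]))
            )
            for key, idx in cells.groupby(cells).groups.items():
                rts, is_up = sample_first_passage(
                    ddm_params.v[key], ddm_params.a[key], ddm_params.z[key[0]],
                    ddm_params.t0, n=len(idx), rng=rng,
                )
                rt[np.asarray(idx)] = rts
                resp[np.asarray(idx)] = np.where(is_up, "smile", "frown")
            frame["response"] = resp
            frame["rt_s"] = rt
            frame["correct"] = (frame["response"] == frame["correct_response"]).astype(int)
            frame["shock"] = 1 - frame["correct"]

        frame["rt_ms"] = frame["rt_s"] * 1000.0
        frame["required_response"] = frame["correct_response"]
        frames.append(frame)
        truth["participants"][pid] = {
            "rl": {"alpha": rl_params.alpha, "beta": rl_params.beta, "zeta": rl_params.zeta},
            "ddm": {
                "v": {f"{t}_{r}": ddm_params.v[(t, r)] for t, r in CELLS},
                "a": {f"{t}_{r}": ddm_params.a[(t, r)] for t, r in CELLS},
                "z": dict(ddm_params.z),
                "t0": ddm_params.t0,
            },
            "copy_interactant_block1": copy_first,
        }

    records = pd.concat(frames, ignore_index=True)

    # artifact injection: no-response takes precedence, then fast non-compliance
    u = artifact_rng.random(len(records))
    p_nr = config.artifact_rates.p_no_response
    p_fast = config.artifact_rates.p_fast_noncompliance
    labels = np.where(u < p_nr, "no_response", np.where(u < p_nr + p_fast, "fast", "clean"))
    fast_idx = labels == "fast"
    records.loc[fast_idx, "rt_ms"] = artifact_rng.uniform(
        0.0, FAST_CUTOFF_MS, fast_idx.sum()
    )
    records.loc[fast_idx, "rt_s"] = records.loc[fast_idx, "rt_ms"] / 1000.0
    nr_idx = labels == "no_response"
    records.loc[nr_idx, "response"] = pd.NA
    records.loc[nr_idx, ["rt_ms", "rt_s"]] = np.nan
    records.loc[nr_idx, "correct"] = 0
    records.loc[nr_idx, "shock"] = 1

    # artifact_labels record the ground-truth exclusion reason: genuinely
    # slow (> 5 s) or fast first passages are labelled too, so filter counts
    # match the labels exactly
    rt = records["rt_ms"].to_numpy()
    natural = labels == "clean"
    labels = np.where(natural & (rt < FAST_CUTOFF_MS), "fast", labels)
    labels = np.where(natural & (rt > 5000.0), "slow", labels)

    truth["population"] = {
        "rl": config.rl_population.model_dump(mode="json"),
        "ddm": config.ddm_population.model_dump(mode="json"),
    }
    return SyntheticDataset(
        records=records,
        truth=truth,
        artifact_labels=pd.Series(labels, index=records.index, name="artifact"),
        config=config,
    )


def truth_report(dataset: SyntheticDataset, path=None) -> dict:
    """Machine-readable ground truth keyed by participant; optionally written
    to ``path`` as JSON."""
    report = dataset.truth
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=1)
    return report


def load_truth_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
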