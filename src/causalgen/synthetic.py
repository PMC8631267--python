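"""Synthetic participants: simulate choices from any model, end to end.

A simulated participant runs one model on one experiment design, converts
each per-trial predictive distribution into choice probabilities with the
softmax (inverse temperature ``t``), and samples one choice per trial.
Participant-level random seeds are spawned from the master seed, so adding
participants never perturbs the ones already generated.

The module also provides the two simulation harnesses used to probe the
models' qualitative signatures without behavioral data: the
generalization-order effect (near-first vs far-first KR-21 consistency
under LoCaLaPro) and parameter recovery (simulate at known parameters,
refit, compare).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .categories import DPParams, gibbs_locala, locala_predict, \
    locala_single_example, localapro_predict, localapro_run
from .data import BehavioralDataset, read_trials, write_trials
from .fitstats import FitResult, fit_model, kr21, softmax_probs, taskwise_kr21
from .grammar import LawTable
from .semantics import mixture_choice_distribution, posterior_over_laws
from .stimuli import ExperimentDesign, exp1_design

__all__ = [
    "SimulatedParticipant",
    "RecoveryReport",
    "simulate_dataset",
    "order_effect_experiment",
    "parameter_recovery",
    "read_trials",
    "write_trials",
]

MODEL_TAGS = ("baseline", "uncala", "locala", "localapro")


@dataclass(frozen=True)
class SimulatedParticipant:
    participant_id: str
    condition: str
    transfer_order: str
    model: str
    seed: int
    choices: tuple  # one chosen Stone per trial


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of a simulate-then-refit exercise."""

    true_params: dict
    fitted: FitResult
    grid_steps: dict  # parameter -> distance in grid steps (alpha/beta)
    n_participants: int
    seed: int


def _participant_rng(master_seed: int, pid: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(pid,)))


def _static_predictions(model: str, design: ExperimentDesign,
                        table: LawTable, params: DPParams | None,
                        seed: int, gibbs_iter: int):
    """Per-trial predictive vectors for models without sequential state."""
    if model == "baseline":
        m = len(design.tasks[0].candidates)
        return [np.full(m, 1.0 / m) for _ in design.tasks]
    if model == "uncala":
        post = posterior_over_laws(table, design.learning_events)
        return [mixture_choice_distribution(post.probs, table, t).probs
                for t in design.tasks]
    if model == "locala":
        if len(design.learning_events) == 1:
            return [locala_single_example(design.learning_events[0], t,
                                          params, table).probs
                    for t in design.tasks]
        state = gibbs_locala(design.learning_events, params, table,
                             n_iter=gibbs_iter, seed=seed)
        return [locala_predict(state, t).probs for t in design.tasks]
    raise ValueError(f"unknown model tag {model!r}")


def simulate_dataset(model: str, design: ExperimentDesign | Sequence[ExperimentDesign],
                     n_participants: int, seed: int, *, t: float,
                     table: LawTable | None = None,
                     params: DPParams | None = None,
                     gibbs_iter: int = 400,
                     n_runs: int = 300) -> BehavioralDataset:
    """Simulate ``n_participants`` independent participants per design.

    Choices are sampled from the softmaxed per-trial predictive
    distributions of the model.  For LoCaLaPro the per-trial prediction is
    the run-averaged proportion estimate (``n_runs`` sequential runs), the
    same quantity the fitting protocol softmaxes, so simulated choice
    frequencies converge to the model's softmaxed distributions.
    """
    designs = [design] if isinstance(design, ExperimentDesign) else list(design)
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model!r}")
    if model != "baseline" and table is None:
        raise ValueError("table is required for grammar-based models")

    rows = []
    pid_counter = 0
    for d_idx, d in enumerate(designs):
        space = d.space
        if model == "localapro":
            static = [dist.probs for dist in localapro_predict(
                d, params, table, n_runs=n_runs, seed=seed + d_idx)]
        else:
            static = _static_predictions(model, d, table, params,
                                         seed + d_idx, gibbs_iter)
        for _ in range(n_participants):
            pid = pid_counter
            pid_counter += 1
            rng = _participant_rng(seed, pid)
            for trial_idx, (task, vec) in enumerate(zip(d.tasks, static), 1):
                probs = softmax_probs(vec, t)
                choice = task.candidates[int(rng.choice(len(probs), p=probs))]
                row = {
                    "participant_id": f"sim{pid:04d}",
                    "condition": d.condition,
                    "transfer_order": d.transfer_order,
                    "trial_index": trial_idx,
                }
                for role, stone in (("agent", task.agent),
                                    ("recipient", task.recipient),
                                    ("choice", choice)):
                    for f in space.features:
                        row[f"{role}_{f}"] = stone.value(f)
                if any(tk.is_catch for tk in d.tasks):
                    row["is_catch"] = task.is_catch
                rows.append(row)
    return BehavioralDataset(pd.DataFrame(rows), designs[0].space)


def order_effect_experiment(table: LawTable, alphas: Sequence[float] = (0.38,),
                            conditions: Sequence[str] = ("A1", "A2", "A3", "A4", "A5"),
                            n: int = 200, seed: int = 0, *,
                            beta: float = 1.0, t: float = 10.0,
                            n_runs: int = 300,
                            design_seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Near-first vs far-first LoCaLaPro simulation summary.

    For each condition, order and concentration value, simulates ``n``
    LoCaLaPro participants, computes the task-wise KR-21 consistency
    rho_tau, and estimates the model's predicted per-trial choice
    proportions (``n_runs`` averaged runs).  Returns a tidy summary frame
    (one row per condition x order x alpha with the mean rho_tau) and a
    dict of predicted-proportion matrices keyed (condition, order, alpha).
    """
    records = []
    matrices = {}
    for alpha in alphas:
        params = DPParams(alpha, beta, 0.5)
        for cond in conditions:
            for order in ("near-first", "far-first"):
                design = exp1_design(cond, order, feature_order_seed=design_seed)
                ds = simulate_dataset("localapro", design, n, seed,
                                      t=t, table=table, params=params)
                rho = taskwise_kr21(ds)
                dists = localapro_predict(design, params, table,
                                          n_runs=n_runs, seed=seed)
                mat = np.stack([d.probs for d in dists])
                matrices[(cond, order, alpha)] = mat
                records.append({
                    "condition": cond, "transfer_order": order,
                    "alpha": alpha,
                    "mean_rho": float(rho["rho"].replace(
                        -np.inf, np.nan).mean()),
                    "modal_share": float(mat.max(axis=1).mean()),
                })
    return pd.DataFrame(records), matrices


def _grid_distance(value: float, true: float, grid: Sequence[float]) -> int:
    """Distance, in grid steps, between the grid points nearest to the
    fitted and the true value."""
    g = np.asarray(grid, dtype=float)
    return int(abs(int(np.argmin(np.abs(g - value)))
                   - int(np.argmin(np.abs(g - true)))))


def parameter_recovery(true_alpha: float, true_beta: float, true_t: float,
                       table: LawTable, *, conditions: Sequence[str] = ("A1",),
                       orders: Sequence[str] = ("near-first", "far-first"),
                       n_participants: int = 50, seed: int = 0,
                       alpha_grid: Sequence[float],
                       beta_grid: Sequence[float],
                       n_runs: int = 200) -> RecoveryReport:
    """Simulate a LoCaLaPro population at known (alpha, beta, t), refit it
    by grid search, and report grid-step distances."""
    designs = [exp1_design(c, o) for c in conditions for o in orders]
    params = DPParams(true_alpha, true_beta, 0.5)
    ds = simulate_dataset("localapro", designs, n_participants, seed,
                          t=true_t, table=table, params=params)
    design_map = {c: exp1_design(c, "near-first") for c in conditions}
    fitted = fit_model("localapro", ds, design_map, table, seed=seed + 1,
                       alpha_grid=alpha_grid, beta_grid=beta_grid,
                       n_runs=n_runs)
    steps = {
        "alpha": _grid_distance(fitted.params["alpha"], true_alpha, alpha_grid),
        "beta": _grid_distance(fitted.params["beta"], true_beta, beta_grid),
    }
    return RecoveryReport(
        {"alpha": true_alpha, "beta": true_beta, "t": true_t},
        fitted, steps, n_participants * len(designs), seed)
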