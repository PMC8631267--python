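"""Choice noise, likelihood/BIC model comparison, grid fitting, and KR-21.

Model predictions are probability vectors over a trial's candidate panel.
They are turned into choice probabilities by a softmax that exponentiates
the *probabilities* themselves times an inverse temperature ``t`` (the
usual log-space softmax is available behind a flag).  Models are compared by maximum likelihood and
BIC = -2 LL + k ln n, with n the number of scored choices.

The Kuder-Richardson Formula 21 statistic

    rho_tau = k/(k-1) * (1 - k p (1 - p) / var(X))

measures inter-participant consistency on one task from the vector X of
aggregated per-option selection counts (k participants, chance probability
p); var(X) is the population variance of X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .categories import DPParams, gibbs_locala, locala_predict, \
    locala_single_example, localapro_run, single_example_membership
from .data import BehavioralDataset, rows_to_task
from .grammar import LawTable
from .semantics import ChoiceDistribution, mixture_choice_distribution, \
    posterior_over_laws
from .stimuli import ExperimentDesign, GeneralizationTask, Stone

__all__ = [
    "ChoiceModelParams",
    "FitResult",
    "softmax_probs",
    "softmax_choice",
    "baseline_model",
    "baseline_fit",
    "dataset_loglik",
    "bic",
    "fit_model",
    "kr21",
    "taskwise_kr21",
    "consistency_vs_random",
    "COARSE_ALPHA_GRID",
    "FINE_ALPHA_GRID",
    "BETA_GRID",
    "EXP2_ALPHA_GRID",
    "GAMMA_GRID",
]

# the fitting-protocol grids
COARSE_ALPHA_GRID = (0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
                     1.0, 1.5, 2.0, 4.0, 8.0)
FINE_ALPHA_GRID = (0.28, 0.30, 0.32, 0.34, 0.36, 0.38, 0.40, 0.42, 0.44,
                   0.46, 0.48, 0.50, 0.52)
BETA_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
             2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0, 512.0, 1024.0)
EXP2_ALPHA_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 16, 32, 64, 128, 256)
GAMMA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class ChoiceModelParams:
    """A model tag with its decision-noise and DP parameters."""

    model: str  # baseline | uncala | locala | localapro
    t: float = 1.0
    dp: DPParams | None = None

    def __post_init__(self):
        if not np.isfinite(self.t) or self.t < 0:
            raise ValueError("inverse temperature must be finite and >= 0")


@dataclass(frozen=True)
class FitResult:
    """Best-fitting parameters with their likelihood and BIC."""

    model: str
    params: dict
    log_likelihood: float
    k: int  # free-parameter count
    n: int  # number of choices
    grid: pd.DataFrame | None = None

    @property
    def bic(self) -> float:
        return bic(self.log_likelihood, self.k, self.n)


def softmax_probs(probs: np.ndarray, t: float, log_space: bool = False) -> np.ndarray:
    """Softmax over the last axis: exp(p * t) renormalized.

    With ``log_space=True`` the conventional form exp(t * log p) = p**t is
    used instead.  t = 0 gives the uniform distribution; large t
    concentrates mass on the modal candidate.
    """
    if t < 0:
        raise ValueError("inverse temperature must be >= 0")
    p = np.asarray(probs, dtype=float)
    if log_space:
        with np.errstate(divide="ignore"):
            z = t * np.log(p)
    else:
        z = t * p
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_choice(dist: ChoiceDistribution, t: float,
                   log_space: bool = False) -> ChoiceDistribution:
    return ChoiceDistribution(dist.candidates,
                              softmax_probs(dist.probs, t, log_space))


def baseline_model(panel: Sequence[Stone]) -> ChoiceDistribution:
    """The random baseline: probability 1/m per candidate, no parameters."""
    m = len(panel)
    if m < 2:
        raise ValueError("panel needs at least 2 candidates")
    return ChoiceDistribution(tuple(panel), np.full(m, 1.0 / m))


def baseline_fit(n_choices: int, panel_size: int) -> FitResult:
    """The baseline row of a model-comparison table: LL = n ln(1/m), k = 0."""
    ll = n_choices * np.log(1.0 / panel_size)
    return FitResult("baseline", {}, float(ll), 0, n_choices)


def bic(log_likelihood: float, k: int, n: int) -> float:
    return -2.0 * log_likelihood + k * np.log(n)


def loglik_given_t(pred: np.ndarray, chosen: np.ndarray, t: float,
                   log_space: bool = False) -> float:
    """Sum of log softmaxed probabilities of the chosen options.

    ``pred`` is (n_trials, m); ``chosen`` the per-trial option index.
    """
    sm = softmax_probs(pred, t, log_space)
    picked = sm[np.arange(len(chosen)), chosen]
    return float(np.sum(np.log(picked)))


def _best_t(pred: np.ndarray, chosen: np.ndarray, t_max: float = 500.0) -> tuple[float, float]:
    """Maximize LL over t (the LL is concave in t, so a bounded scalar
    search suffices)."""
    res = optimize.minimize_scalar(
        lambda t: -loglik_given_t(pred, chosen, t),
        bounds=(0.0, t_max), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), float(-res.fun)


def dataset_loglik(predictions: Sequence[ChoiceDistribution],
                   choices: Sequence[Stone], t: float,
                   log_space: bool = False) -> float:
    """LL of a sequence of observed choices under per-trial predictions."""
    lls = 0.0
    for dist, choice in zip(predictions, choices, strict=True):
        if choice not in dist.candidates:
            raise ValueError(f"chosen outcome {choice} absent from the panel")
        sm = softmax_probs(dist.probs, t, log_space)
        lls += float(np.log(sm[dist.candidates.index(choice)]))
    return lls


# ---------------------------------------------------------------------------
# KR-21 consistency


def kr21(counts: Sequence[float], p: float, k: int | None = None) -> float:
    """KR-21 inter-participant consistency for one task.

    ``counts`` aggregates how many of the k participants selected each
    option; ``p`` is the chance probability of an option under random
    responding.  Uses the population variance of the counts vector.  When
    the variance is zero (every option chosen equally often) the statistic
    is undefined; a warning is raised and -inf returned.
    """
    x = np.asarray(counts, dtype=float)
    if k is None:
        k = int(round(x.sum()))
    if k < 2:
        raise ValueError("need at least 2 participants")
    if not np.isclose(x.sum(), k):
        raise ValueError("counts must sum to the number of participants")
    if not 0.0 < p < 1.0:
        raise ValueError("chance probability must lie in (0, 1)")
    var = float(np.var(x))  # population variance
    if var == 0.0:
        warnings.warn("KR-21 undefined: zero variance in option counts")
        return float("-inf")
    return k / (k - 1.0) * (1.0 - k * p * (1.0 - p) / var)


def taskwise_kr21(dataset: BehavioralDataset, p: float | None = None) -> pd.DataFrame:
    """rho_tau per (condition, transfer_order, trial_index) over the panel
    of all configurations; catch trials excluded."""
    space = dataset.space
    panel = space.all_stones()
    if p is None:
        p = 1.0 / len(panel)
    index = {s: i for i, s in enumerate(panel)}
    rows = []
    df = dataset.scored()
    for (cond, order, trial), g in df.groupby(
            ["condition", "transfer_order", "trial_index"]):
        counts = np.zeros(len(panel))
        for _, row in g.iterrows():
            counts[index[dataset.stone(row, "choice")]] += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = kr21(counts, p)
        rows.append({"condition": cond, "transfer_order": order,
                     "trial_index": trial, "k": len(g), "rho": rho})
    return pd.DataFrame(rows)


def consistency_vs_random(counts_by_trial: np.ndarray):
    """Fisher's exact test (2 x m collapses to pairwise chi2 for m > 2 is
    not what the analyses use; this delegates to the standard routine on a
    contingency table of observed vs uniform-expected selections)."""
    observed = np.asarray(counts_by_trial)
    k = observed.sum()
    expected = np.full_like(observed, k / observed.size, dtype=float)
    table = np.vstack([observed, expected.round()]).astype(int)
    if table.shape[1] == 2:
        return stats.fisher_exact(table)
    return stats.chi2_contingency(table)


# ---------------------------------------------------------------------------
# fitting protocol


def _stack_rows(dataset: BehavioralDataset,
                predict: Callable[[str, GeneralizationTask], np.ndarray]):
    """Assemble (pred matrix, chosen index vector) over scored rows, using
    ``predict(condition, task)`` with caching per unique (condition, pair)."""
    space = dataset.space
    panel = space.all_stones()
    index = {s: i for i, s in enumerate(panel)}
    cache: dict = {}
    preds, chosen = [], []
    for _, row in dataset.scored().iterrows():
        task = rows_to_task(row, space, panel)
        key = (row["condition"], task.agent, task.recipient)
        vec = cache.get(key)
        if vec is None:
            vec = predict(row["condition"], task)
            cache[key] = vec
        preds.append(vec)
        chosen.append(index[dataset.stone(row, "choice")])
    return np.asarray(preds), np.asarray(chosen)


def fit_model(model: str, dataset: BehavioralDataset,
              designs: Mapping[str, ExperimentDesign], table: LawTable | None = None,
              *, seed: int = 0, gamma: float = 0.5,
              alpha_grid: Sequence[float] | None = None,
              beta_grid: Sequence[float] | None = None,
              gamma_grid: Sequence[float] | None = None,
              n_runs: int = 300, gibbs_iter: int = 400,
              n_starts: int = 5) -> FitResult:
    """Fit one model to a trial table by maximum likelihood.

    baseline   no free parameters.
    uncala     1-D concave optimization of the inverse temperature t.
    locala     one learning event per condition: joint continuous
               optimization of (alpha, beta, t) with gamma fixed (the
               analytic single-example path); several learning events:
               grid search over (alpha, beta, gamma) with Gibbs-estimated
               predictions and t optimized per grid point.
    localapro  grid search over (alpha, beta) with simulation-estimated
               predictions (``n_runs`` runs per unique task sequence) and
               t optimized per grid point.

    ``designs`` supplies each condition's learning events.  Results are
    reproducible bit-for-bit given the grids and ``seed``.
    """
    if len(dataset.scored()) == 0:
        raise ValueError("dataset is empty")
    n = dataset.n_choices
    space = dataset.space
    panel = space.all_stones()

    if model == "baseline":
        return baseline_fit(n, len(panel))

    if table is None:
        raise ValueError(f"model {model!r} needs a law table")

    posteriors = {c: posterior_over_laws(table, d.learning_events)
                  for c, d in designs.items()}

    if model == "uncala":
        def predict(cond, task):
            return mixture_choice_distribution(
                posteriors[cond].probs, table, task).probs
        pred, chosen = _stack_rows(dataset, predict)
        t, ll = _best_t(pred, chosen)
        return FitResult("uncala", {"t": t}, ll, 1, n)

    if model == "locala":
        single = all(len(d.learning_events) == 1 for d in designs.values())
        if single:
            return _fit_locala_single(dataset, designs, table, posteriors,
                                      gamma, seed, n_starts)
        return _fit_locala_gibbs(dataset, designs, table, seed,
                                 alpha_grid or EXP2_ALPHA_GRID,
                                 beta_grid or BETA_GRID,
                                 gamma_grid or GAMMA_GRID, gibbs_iter)

    if model == "localapro":
        return _fit_localapro(dataset, designs, table, seed, gamma,
                              alpha_grid or FINE_ALPHA_GRID,
                              beta_grid or BETA_GRID, n_runs)

    raise ValueError(f"unknown model tag {model!r}")


def _fit_locala_single(dataset, designs, table, posteriors, gamma, seed,
                       n_starts):
    """Continuous (alpha, beta, t) fit on the analytic single-example path.

    The posterior- and prior-predictive vectors per unique pair do not
    depend on (alpha, beta); only the membership probability q does, so
    the objective is cheap."""
    space = dataset.space
    panel = space.all_stones()
    index = {s: i for i, s in enumerate(panel)}
    # per scored row: condition, task pair, chosen index
    entries = []
    cache = {}
    for _, row in dataset.scored().iterrows():
        task = rows_to_task(row, space, panel)
        key = (row["condition"], task.agent, task.recipient)
        if key not in cache:
            post = mixture_choice_distribution(
                posteriors[row["condition"]].probs, table, task).probs
            prior = mixture_choice_distribution(table.priors, table, task).probs
            learning = designs[row["condition"]].learning_events[0]
            cache[key] = (post, prior, learning, task)
        entries.append((key, index[dataset.stone(row, "choice")]))

    keys = list(cache)
    key_pos = {k: i for i, k in enumerate(keys)}
    post_m = np.stack([cache[k][0] for k in keys])
    prior_m = np.stack([cache[k][1] for k in keys])
    row_key = np.array([key_pos[k] for k, _ in entries])
    chosen = np.array([c for _, c in entries])

    def q_vector(alpha, beta):
        qs = np.empty(len(keys))
        for i, k in enumerate(keys):
            _, _, learning, task = cache[k]
            qs[i] = single_example_membership(
                learning, task, DPParams(alpha, beta, gamma), space)
        return qs

    def neg_ll(x):
        alpha, beta, t = np.exp(x[0]), np.exp(x[1]), np.exp(x[2])
        q = q_vector(alpha, beta)
        pred = q[:, None] * post_m + (1 - q[:, None]) * prior_m
        return -loglik_given_t(pred[row_key], chosen, t)

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        x0 = np.array([rng.normal(0, 1.5), rng.normal(0, 1.5),
                       rng.normal(1.5, 1.0)])
        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta, t = np.exp(best.x)
    return FitResult("locala",
                     {"alpha": float(alpha), "beta": float(beta),
                      "gamma": gamma, "t": float(t)},
                     float(-best.fun), 3, dataset.n_choices)


def _grid_fit(model, dataset, grid_points, predictor, k):
    """Shared grid-search loop: per point build the prediction matrix, then
    optimize t; returns the best FitResult with the full grid attached."""
    records = []
    best = None
    for point in grid_points:
        pred, chosen = predictor(point)
        t, ll = _best_t(pred, chosen)
        rec = dict(point)
        rec.update({"t": t, "log_likelihood": ll})
        records.append(rec)
        if best is None or ll > best[0]:
            best = (ll, dict(point), t)
    ll, params, t = best
    params["t"] = t
    return FitResult(model, params, ll, k, dataset.n_choices,
                     grid=pd.DataFrame(records))


def _fit_locala_gibbs(dataset, designs, table, seed, alpha_grid, beta_grid,
                      gamma_grid, gibbs_iter):
    space = dataset.space
    panel = space.all_stones()

    def predictor(point):
        params = DPParams(point["alpha"], point["beta"], point["gamma"])
        states = {
            c: gibbs_locala(d.learning_events, params, table,
                            n_iter=gibbs_iter, seed=seed)
            for c, d in designs.items()
        }

        def predict(cond, task):
            return locala_predict(states[cond], task).probs
        return _stack_rows(dataset, predict)

    points = [{"alpha": a, "beta": b, "gamma": g}
              for a in alpha_grid for b in beta_grid for g in gamma_grid]
    return _grid_fit("locala", dataset, points, predictor, k=4)


def _fit_localapro(dataset, designs, table, seed, gamma, alpha_grid,
                   beta_grid, n_runs):
    """LoCaLaPro grid fit: predictions are simulation-estimated per unique
    participant task sequence (order matters), averaged over n_runs."""
    space = dataset.space
    panel = space.all_stones()
    index = {s: i for i, s in enumerate(panel)}

    # unique (condition, task-sequence) cells and per-row bookkeeping
    sequences: dict[tuple, ExperimentDesign] = {}
    cell_order: dict[tuple, int] = {}
    row_cell, row_pos, chosen = [], [], []
    for pid, g in dataset.iter_participants():
        if "is_catch" in g.columns:
            g = g[~g["is_catch"].astype(bool)]
        tasks = tuple(rows_to_task(row, space, panel) for _, row in g.iterrows())
        cond = g["condition"].iloc[0]
        cell = (cond, tuple((t.agent, t.recipient) for t in tasks))
        if cell not in sequences:
            base = designs[cond]
            sequences[cell] = ExperimentDesign(
                cond, space, base.learning_events, tasks,
                str(g["transfer_order"].iloc[0]))
            cell_order[cell] = len(cell_order)
        for pos, (_, row) in enumerate(g.iterrows()):
            row_cell.append(cell)
            row_pos.append(pos)
            chosen.append(index[dataset.stone(row, "choice")])
    chosen = np.asarray(chosen)

    def predictor(point):
        params = DPParams(point["alpha"], point["beta"], gamma)
        cell_pred = {}
        for cell, design in sequences.items():
            seeds = np.random.SeedSequence(
                entropy=(seed, cell_order[cell])
            ).generate_state(n_runs)
            acc = np.zeros((len(design.tasks), len(panel)))
            for s in seeds:
                dists, _ = localapro_run(design, params, table, seed=int(s))
                acc += np.stack([d.probs for d in dists])
            cell_pred[cell] = acc / n_runs
        pred = np.stack([cell_pred[c][p] for c, p in zip(row_cell, row_pos)])
        return pred, chosen

    points = [{"alpha": a, "beta": b} for a in alpha_grid for b in beta_grid]
    return _grid_fit("localapro", dataset, points, predictor, k=3)
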