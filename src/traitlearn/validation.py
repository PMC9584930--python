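"""Model validation: parameter recovery, confusion matrices, task optimality.

* **Parameter recovery** — simulate data with known parameters, refit the
  same model, and correlate generating vs recovered values; high correlations
  mean the parameters are identifiable on this design.
* **Confusion matrix** — simulate from each model in a set, refit every
  model, and credit the lowest-BIC model; the identity matrix means the
  models are perfectly distinguishable.
* **Best-performing model** — fit the models to the profiles' own feedback
  sequence (the task itself, not a participant), ranking the strategies by
  how well each could have solved the task.

Simulated responses used for fitting are the continuous noisy values; a
``discretize`` flag rounds them to the rating scale for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentDesign
from .fitting import FitResult, fit_model, fit_models
from .models import ModelSpec, RunSet, simulate_agent

#: Unit-interval parameters drawn U[param_low, param_high]; scale-unit
#: parameters (start, b0) drawn uniform on the rating scale.
_UNIT_PARAMS = ("alpha", "alpha_pos", "alpha_neg", "gamma", "b1")


@dataclass
class RecoveryReport:
    """Generating vs recovered parameters and their Pearson correlations."""

    spec: ModelSpec
    correlations: dict[str, float]  # NaN where undefined (zero variance)
    degenerate: tuple[str, ...]     # parameters with an undefined correlation
    table: pd.DataFrame             # per-rep gen_* and rec_* columns
    n_reps: int
    param_range: tuple[float, float]
    noise_sd: float
    seed: int | None


@dataclass
class ConfusionMatrix:
    """Rows = generating model, columns = best-fitting model, as proportions."""

    matrix: pd.DataFrame
    n_reps: int
    n_ties: int

    @property
    def diagonal(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix.to_numpy()), index=self.matrix.index)


def draw_params(
    spec: ModelSpec,
    design: ExperimentDesign,
    rng: np.random.Generator,
    low: float,
    high: float,
) -> dict[str, float]:
    """Random generating parameters for simulation studies."""
    out = {}
    for name in spec.param_names:
        if name in _UNIT_PARAMS:
            out[name] = float(rng.uniform(low, high))
        else:  # start, b0
            out[name] = float(rng.uniform(design.scale_min, design.scale_max))
    return out


def parameter_recovery(
    spec: ModelSpec,
    design: ExperimentDesign,
    profiles,
    rp=None,
    sim=None,
    n_reps: int = 200,
    param_low: float = 0.0,
    param_high: float = 1.0,
    noise_sd: float = 1.0,
    seed=None,
    discretize: bool = False,
) -> RecoveryReport:
    """Simulate -> refit -> correlate, ``n_reps`` times."""
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions")
    if param_low > param_high:
        raise ValueError("param_low must not exceed param_high")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for child in ss.spawn(n_reps):
        rng = np.random.default_rng(child)
        gen = draw_params(spec, design, rng, param_low, param_high)
        runs = simulate_agent(
            spec, gen, design, profiles, noise_sd=noise_sd,
            discretize=discretize, rp=rp, sim=sim, seed=rng,
        )
        fit = fit_model(spec, runs, design, rp=rp, sim=sim)
        row = {f"gen_{k}": v for k, v in gen.items()}
        row.update({f"rec_{k}": v for k, v in fit.params.items()})
        rows.append(row)
    table = pd.DataFrame(rows)

    corrs: dict[str, float] = {}
    degenerate: list[str] = []
    for name in spec.param_names:
        g = table[f"gen_{name}"].to_numpy()
        r = table[f"rec_{name}"].to_numpy()
        if np.std(g) == 0 or np.std(r) == 0:
            corrs[name] = float("nan")
            degenerate.append(name)
        else:
            corrs[name] = float(stats.pearsonr(g, r).statistic)
    return RecoveryReport(
        spec, corrs, tuple(degenerate), table, n_reps,
        (param_low, param_high), noise_sd, seed,
    )


def confusion_matrix(
    model_set: Sequence[ModelSpec],
    design: ExperimentDesign,
    profiles,
    rp=None,
    sim=None,
    n_reps: int = 200,
    param_low: float = 0.2,
    param_high: float = 0.8,
    noise_sd: float = 1.0,
    seed=None,
    discretize: bool = False,
) -> ConfusionMatrix:
    """Simulate from each model and credit the argmin-BIC refit.

    Ties on the minimum BIC go to the earliest model in ``model_set`` and are
    counted in ``n_ties``.
    """
    if len(model_set) < 1 or n_reps < 1:
        raise ValueError("need at least one model and one repetition")
    labels = [m.label for m in model_set]
    counts = np.zeros((len(model_set), len(model_set)), dtype=int)
    n_ties = 0
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    gen_seeds = ss.spawn(len(model_set))
    for gi, gen_spec in enumerate(model_set):
        for child in gen_seeds[gi].spawn(n_reps):
            rng = np.random.default_rng(child)
            gen = draw_params(gen_spec, design, rng, param_low, param_high)
            runs = simulate_agent(
                gen_spec, gen, design, profiles, noise_sd=noise_sd,
                discretize=discretize, rp=rp, sim=sim, seed=rng,
            )
            fits = fit_models(model_set, runs, design, rp=rp, sim=sim)
            bics = np.array([f.bic for f in fits])
            best = int(np.argmin(bics))
            if (bics == bics[best]).sum() > 1:
                n_ties += 1
            counts[gi, best] += 1
    matrix = pd.DataFrame(counts / n_reps, index=labels, columns=labels)
    return ConfusionMatrix(matrix, n_reps, n_ties)


def best_performing(
    model_set: Sequence[ModelSpec],
    profiles,
    design: ExperimentDesign,
    rp=None,
    sim=None,
    seed: int | None = None,
    orders: np.ndarray | None = None,
) -> list[FitResult]:
    """Fit the models to the task itself (profile feedback as the response).

    The response to predict at trial t is the feedback shown at trial t, so a
    model's SSE measures how well its history-based predictions anticipate
    the profile; BIC ranks task optimality.
    """
    if len(profiles) == 0:
        raise ValueError("profiles must be nonempty")
    rng = np.random.default_rng(seed)
    if orders is None:
        runs = RunSet.from_profiles(design, profiles, rng)
    else:
        runs = RunSet(orders, np.stack([np.asarray(p.feedback, float) for p in profiles]))
    runs.responses = runs.feedback_seq
    return fit_models(model_set, runs, design, rp=rp, sim=sim)
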