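"""The five hybrid Rescorla-Wagner learning models and agent simulation.

Model space (P = prediction, PE = F - P, RP = reference point, SIM = signed
item correlation matrix):

* **M1** (no learning): ``P = RP * b1 + b0`` — a linear transform of the
  reference point; state never changes.
* **M2** (coarse granularity): one value per Big-Five factor,
  ``P(t+1,F) = P(t,F) + alpha * PE``.
* **M3** (coarse + RP): like M2, but the expressed prediction blends the
  current item's reference value with the learned factor value,
  ``P = gamma * RP(item) + (1 - gamma) * V(F)``.
* **M4** (fine granularity): one value per item, all items updated at once,
  ``V(t+1, All) = V(t, All) + alpha * PE * SIM[:, item]``.
* **M5** (fine + RP): like M4 with the reference-point blend of M3 applied
  to the item's learned value, ``P = gamma * RP(item) + (1 - gamma) * V(item)``.

In the RP models the prediction error is taken from the expressed (blended)
prediction, and the stored values keep the pure delta-rule update; gamma
weighs reliance on the reference point (gamma = 1 reproduces the reference
point on every trial, gamma = 0 reduces M3/M5 to M2/M4 exactly).

Variants: the RP source can be the population mean, a stereotype (out-group)
mean, or the participant's own self-ratings; a dual-learning-rate flag splits
alpha into ``alpha_neg`` (used when PE < 0) and ``alpha_pos`` (PE >= 0).

The equations are linear, so state and predictions are never clipped to the
rating scale; rounding/capping happens only when an agent emits discretized
responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _engine
from .design import ExperimentDesign
from .population import Profile, ReferencePoint, SimilarityMatrix, cap_to_scale, round_half_up

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5")
RP_SOURCES = ("none", "population", "stereotype", "self")
_SUFFIX = {"population": "", "none": "", "stereotype": "-STE", "self": "-Self"}


@dataclass(frozen=True)
class ModelSpec:
    """Identity of one model: family, reference-point source, dual-alpha flag."""

    model_id: str
    rp_source: str = "none"
    dual_alpha: bool = False

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        if self.rp_source not in RP_SOURCES:
            raise ValueError(f"rp_source must be one of {RP_SOURCES}")
        if self.uses_rp and self.rp_source == "none":
            raise ValueError(f"{self.model_id} requires a reference-point source")
        if not self.uses_rp and self.rp_source != "none":
            raise ValueError(f"{self.model_id} takes no reference point")
        if self.model_id == "M1" and self.dual_alpha:
            raise ValueError("M1 has no learning rate to split")

    @property
    def uses_rp(self) -> bool:
        return self.model_id in ("M1", "M3", "M5")

    @property
    def fine(self) -> bool:
        return self.model_id in ("M4", "M5")

    @property
    def coarse(self) -> bool:
        return self.model_id in ("M2", "M3")

    @property
    def learns(self) -> bool:
        return self.model_id != "M1"

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.model_id == "M1":
            return ("b0", "b1")
        alpha = ("alpha_pos", "alpha_neg") if self.dual_alpha else ("alpha",)
        gamma = ("gamma",) if self.uses_rp else ()
        return alpha + gamma + ("start",)

    @property
    def k_free(self) -> int:
        return len(self.param_names)

    @property
    def label(self) -> str:
        lab = self.model_id + _SUFFIX[self.rp_source]
        return lab + "-2a" if self.dual_alpha else lab


def default_spec(model_id: str, rp_source: str = "population", dual_alpha: bool = False) -> ModelSpec:
    """Spec with the conventional RP source filled in where one is required."""
    needs_rp = model_id in ("M1", "M3", "M5")
    return ModelSpec(model_id, rp_source if needs_rp else "none", dual_alpha)


def standard_model_set(rp_source: str = "population") -> tuple[ModelSpec, ...]:
    """The five-model comparison set used throughout the experiments."""
    return tuple(default_spec(m, rp_source) for m in MODEL_IDS)


def param_bounds(spec: ModelSpec, design: ExperimentDesign) -> dict[str, tuple[float, float]]:
    """Fitting bounds: learning/weighting parameters in [0, 1], starting value
    on the rating scale, M1 regression coefficients unbounded."""
    lo, hi = float(design.scale_min), float(design.scale_max)
    out: dict[str, tuple[float, float]] = {}
    for name in spec.param_names:
        if name in ("alpha", "alpha_pos", "alpha_neg", "gamma"):
            out[name] = (0.0, 1.0)
        elif name == "start":
            out[name] = (lo, hi)
        else:  # b0, b1
            out[name] = (-np.inf, np.inf)
    return out


def midpoint_params(spec: ModelSpec, design: ExperimentDesign) -> dict[str, float]:
    """Optimizer start: every bounded parameter at the middle of its bounds
    (0.5 for alpha/gamma, the scale midpoint for the starting value)."""
    mid = design.scale_mid
    defaults = {"b0": mid, "b1": 0.5}
    out = {}
    for name, (lo, hi) in param_bounds(spec, design).items():
        out[name] = defaults.get(name, (lo + hi) / 2.0)
    return out


# ---------------------------------------------------------------------------
# single-step reference semantics

def compute_pe(feedback: float, prediction: float) -> float:
    """Prediction error: feedback minus prediction."""
    return feedback - prediction


def init_state(spec: ModelSpec, design: ExperimentDesign, params: Mapping[str, float]) -> np.ndarray:
    """Fresh model state for one run: the starting value everywhere
    (per factor for coarse models, per item for fine models; empty for M1)."""
    if spec.model_id == "M1":
        return np.empty(0)
    n = design.n_factors if spec.coarse else design.n_items
    return np.full(n, float(params["start"]))


def _effective_alpha(spec: ModelSpec, params: Mapping[str, float], pe: float) -> float:
    if spec.dual_alpha:
        return params["alpha_neg"] if pe < 0 else params["alpha_pos"]
    return params["alpha"]


def predict(
    state: np.ndarray,
    spec: ModelSpec,
    params: Mapping[str, float],
    item: int,
    design: ExperimentDesign,
    rp: np.ndarray | None = None,
) -> float:
    """The model's (unclipped) prediction for one item given current state."""
    if not 0 <= item < design.n_items:
        raise KeyError(f"unknown item index {item}")
    if spec.uses_rp and rp is None:
        raise ValueError(f"{spec.label} needs a reference point")
    if spec.model_id == "M1":
        return float(rp[item] * params["b1"] + params["b0"])
    value = state[design.factor_index[item]] if spec.coarse else state[item]
    if spec.uses_rp:
        gamma = params["gamma"]
        return float(gamma * rp[item] + (1.0 - gamma) * value)
    return float(value)


def update(
    state: np.ndarray,
    spec: ModelSpec,
    params: Mapping[str, float],
    item: int,
    pe: float,
    design: ExperimentDesign,
    rp: np.ndarray | None = None,
    sim: np.ndarray | None = None,
) -> np.ndarray:
    """One learning step; returns the new state (input is not mutated).

    ``pe`` must come from the current trial's expressed prediction (see
    :func:`predict`).  Reference-point blending happens at prediction time,
    so the stored state always receives the pure delta-rule update.
    """
    if spec.model_id == "M1":
        return state  # no learning
    if spec.fine and sim is None:
        raise ValueError(f"{spec.label} needs a similarity matrix")
    a = _effective_alpha(spec, params, pe)
    new = state.copy()
    if spec.coarse:
        f = design.factor_index[item]
        new[f] = state[f] + a * pe
    else:
        new = state + a * pe * sim[:, item]
    return new


# ---------------------------------------------------------------------------
# packed runs and full-run evaluation

@dataclass
class RunSet:
    """All of one participant's runs in packed array form.

    ``orders``: (R, T) item indices per run; ``feedbacks``: (R, N) item-indexed
    feedback (the profile shown in that run); ``responses``: (R, T) emitted
    ratings aligned with ``orders`` (NaN = missing), or None for model output.
    """

    orders: np.ndarray
    feedbacks: np.ndarray
    responses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.orders = np.ascontiguousarray(self.orders, dtype=np.int64)
        self.feedbacks = np.ascontiguousarray(self.feedbacks, dtype=np.float64)
        if self.orders.ndim != 2 or self.feedbacks.ndim != 2:
            raise ValueError("orders and feedbacks must be 2-D (runs x ...)")
        if self.orders.shape[0] != self.feedbacks.shape[0]:
            raise ValueError("orders and feedbacks disagree on run count")
        for row in self.orders:
            if len(set(row.tolist())) != row.size:
                raise ValueError("duplicate items within a run order")
        if self.responses is not None:
            self.responses = np.asarray(self.responses, dtype=np.float64)
            if self.responses.shape != self.orders.shape:
                raise ValueError("responses must align with orders")

    @property
    def n_runs(self) -> int:
        return self.orders.shape[0]

    @property
    def feedback_seq(self) -> np.ndarray:
        """(R, T) feedback in presentation order."""
        return np.take_along_axis(self.feedbacks, self.orders, axis=1)

    @classmethod
    def from_profiles(
        cls,
        design: ExperimentDesign,
        profiles: Sequence[Profile],
        rng: np.random.Generator,
    ) -> "RunSet":
        """One run per profile, each with a fresh random presentation order."""
        orders = np.stack([design.random_order(rng) for _ in profiles])
        feedbacks = np.stack([np.asarray(p.feedback, dtype=float) for p in profiles])
        return cls(orders, feedbacks)


def _as_vector(x, n: int, what: str) -> np.ndarray:
    if x is None:
        return np.zeros(n)
    if isinstance(x, ReferencePoint):
        x = x.rp
    if isinstance(x, SimilarityMatrix):
        x = x.sim
    return np.ascontiguousarray(x, dtype=np.float64)


def predict_series(
    spec: ModelSpec,
    params: Mapping[str, float],
    runs: RunSet,
    design: ExperimentDesign,
    rp=None,
    sim=None,
) -> np.ndarray:
    """(R, T) model predictions for every run, state reset per run."""
    if spec.uses_rp and rp is None:
        raise ValueError(f"{spec.label} needs a reference point")
    if spec.fine and sim is None:
        raise ValueError(f"{spec.label} needs a similarity matrix")
    rp_v = _as_vector(rp, design.n_items, "rp")
    if spec.model_id == "M1":
        return params["b1"] * rp_v[runs.orders] + params["b0"]
    a_pos = params["alpha_pos"] if spec.dual_alpha else params["alpha"]
    a_neg = params["alpha_neg"] if spec.dual_alpha else params["alpha"]
    gamma = params.get("gamma", 0.0) if spec.uses_rp else 0.0
    start = params["start"]
    if spec.coarse:
        return _engine.series_coarse(
            runs.orders, runs.feedbacks, design.factor_index.astype(np.int64),
            design.n_factors, rp_v, a_pos, a_neg, gamma, start, spec.uses_rp,
        )
    sim_m = _as_vector(sim, design.n_items, "sim")
    return _engine.series_fine(
        runs.orders, runs.feedbacks, sim_m, rp_v,
        a_pos, a_neg, gamma, start, spec.uses_rp,
    )


@dataclass
class TrialSequence:
    """One run's ordered trial records."""

    items: np.ndarray        # item indices in presentation order
    predictions: np.ndarray  # model (or agent-internal) predictions
    feedback: np.ndarray     # feedback shown each trial
    responses: np.ndarray | None = None  # emitted responses (NaN = missing)

    @property
    def pe(self) -> np.ndarray:
        """Prediction errors F - P against the model's own predictions."""
        return self.feedback - self.predictions

    def to_frame(self):
        import pandas as pd

        d = {
            "trial": np.arange(1, len(self.items) + 1),
            "item": self.items,
            "prediction": self.predictions,
            "feedback": self.feedback,
            "pe": self.pe,
        }
        if self.responses is not None:
            d["response"] = self.responses
        return pd.DataFrame(d)


def run_model(
    spec: ModelSpec,
    params: Mapping[str, float],
    trial_order: Sequence[int],
    feedback_by_item: Sequence[float],
    design: ExperimentDesign,
    rp=None,
    sim=None,
) -> TrialSequence:
    """Deterministic model pass over one run.

    Each trial emits the current prediction, computes PE against the shown
    feedback (using the model's own prediction) and applies the update.
    """
    order = np.asarray(trial_order, dtype=np.int64)
    runs = RunSet(order[None, :], np.asarray(feedback_by_item, float)[None, :])
    preds = predict_series(spec, params, runs, design, rp=rp, sim=sim)[0]
    fb = runs.feedback_seq[0]
    return TrialSequence(order, preds, fb)


def simulate_agent(
    spec: ModelSpec,
    params: Mapping[str, float],
    design: ExperimentDesign,
    profiles: Sequence[Profile] | Profile,
    noise_sd: float = 1.0,
    discretize: bool = False,
    rp=None,
    sim=None,
    seed: int | np.random.SeedSequence | None = None,
    orders: np.ndarray | None = None,
) -> RunSet:
    """Simulate a noisy agent playing the task (one run per profile).

    Responses are the model's noise-free internal predictions plus
    N(0, noise_sd); the agent's learning always uses the noise-free
    prediction.  With ``discretize`` the emitted responses are additionally
    rounded and capped to the rating scale.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if isinstance(profiles, Profile):
        profiles = [profiles]
    rng = np.random.default_rng(seed)
    if orders is None:
        runs = RunSet.from_profiles(design, profiles, rng)
    else:
        runs = RunSet(orders, np.stack([np.asarray(p.feedback, float) for p in profiles]))
    preds = predict_series(spec, params, runs, design, rp=rp, sim=sim)
    resp = preds + rng.normal(0.0, noise_sd, size=preds.shape) if noise_sd > 0 else preds.copy()
    if discretize:
        resp = cap_to_scale(round_half_up(resp), design)
    runs.responses = resp
    return runs
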