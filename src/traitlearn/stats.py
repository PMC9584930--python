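"""Model-free behavioural statistics.

Works on long-format session tables (one row per trial) with columns
``participant``, ``run``, ``trial``, ``item``, ``response`` (NaN = missing)
and ``feedback``.  The participant's prediction error on a trial is
``feedback - response``; accuracy analyses use its absolute value.

Pipeline:

1. :func:`apply_exclusions` — drop runs with >20% missing answers and
   participants with >10% missing overall.
2. :func:`pe_trend` — mean |PE| per trial position (averaged over runs within
   participant, then over participants) and its Pearson correlation with
   trial number; a negative trend indicates learning.
3. :func:`build_glm_regressors` / :func:`fit_participant_glm` — a per-trial
   GLM of |PE| on three learning regressors (previous trials; previous
   same-factor trials; summed |correlation| of previous items with the
   current one), fitted per participant.
4. :func:`group_ttest` — one-sided one-sample t-test of participants' slopes
   against zero in the negative direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .design import ExperimentDesign

RUN_MISSING_LIMIT = 0.20      # strict: a run is dropped only above this
PARTICIPANT_MISSING_LIMIT = 0.10

REGRESSORS = ("reg1", "reg2", "reg3")


@dataclass
class ExclusionLog:
    removed_runs: pd.DataFrame          # participant, run, missing_fraction
    removed_participants: pd.DataFrame  # participant, missing_fraction


@dataclass
class TrendResult:
    mean_abs_pe: np.ndarray  # one value per trial position
    r: float
    p: float
    degenerate: bool


@dataclass
class GlmFit:
    betas: dict[str, float]
    tvalues: dict[str, float]
    r_squared: float
    condition_number: float
    rank_deficient: bool


@dataclass
class GroupTestResult:
    mean_beta: float
    t: float
    p: float
    df: int
    degenerate: bool = False


def _abs_pe(session: pd.DataFrame) -> pd.Series:
    return (session["feedback"] - session["response"]).abs()


def apply_exclusions(session: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Missing-data exclusions, both computed on the raw table.

    A run is removed if more than 20% of its answers are missing; a
    participant is removed entirely if more than 10% of all their answers
    are missing.  Both thresholds are strict inequalities.
    """
    missing = session["response"].isna()
    by_part = missing.groupby(session["participant"]).mean()
    bad_parts = by_part[by_part > PARTICIPANT_MISSING_LIMIT]

    by_run = missing.groupby([session["participant"], session["run"]]).mean()
    bad_runs = by_run[by_run > RUN_MISSING_LIMIT]

    keep = ~session["participant"].isin(bad_parts.index)
    run_key = list(zip(session["participant"], session["run"]))
    keep &= ~pd.Series(run_key, index=session.index).isin(set(bad_runs.index))

    log = ExclusionLog(
        removed_runs=bad_runs.rename("missing_fraction").reset_index(),
        removed_participants=bad_parts.rename("missing_fraction").reset_index(),
    )
    return session[keep].copy(), log


def pe_trend(session: pd.DataFrame) -> TrendResult:
    """Mean |PE| per trial position and its Pearson trend over trials.

    |PE| is averaged over runs within each participant, then across
    participants, yielding one value per trial position; missing responses
    are ignored.  A constant trend vector is flagged degenerate with r = 0.
    """
    df = session.copy()
    df["abs_pe"] = _abs_pe(df)
    per_part = df.groupby(["participant", "trial"])["abs_pe"].mean()
    trend = per_part.groupby("trial").mean().sort_index()
    if len(trend) < 3:
        raise ValueError("need at least 3 trial positions")
    y = trend.to_numpy()
    x = trend.index.to_numpy(dtype=float)
    if np.std(y) == 0:
        return TrendResult(y, 0.0, 1.0, True)
    res = sps.pearsonr(x, y)
    return TrendResult(y, float(res.statistic), float(res.pvalue), False)


def build_glm_regressors(
    items: Sequence[int],
    design: ExperimentDesign,
    sim,
) -> pd.DataFrame:
    """Per-trial learning regressors for one run.

    reg1: number of previous trials in the run; reg2: previous trials from
    the current item's factor; reg3: summed |correlation| of previous items
    with the current item.  All three are 0 on the first trial.
    """
    sim_m = np.asarray(sim.sim if hasattr(sim, "sim") else sim, dtype=float)
    items = np.asarray(items, dtype=int)
    if items.max() >= sim_m.shape[0]:
        raise KeyError("item missing from similarity matrix")
    fidx = design.factor_index
    rows = []
    for t, cur in enumerate(items):
        prev = items[:t]
        rows.append(
            {
                "reg1": t,
                "reg2": int((fidx[prev] == fidx[cur]).sum()),
                "reg3": float(np.abs(sim_m[prev, cur]).sum()),
            }
        )
    return pd.DataFrame(rows)


def session_glm_table(
    session: pd.DataFrame, design: ExperimentDesign, sim
) -> pd.DataFrame:
    """Regressors + |PE| for every trial of every run, runs concatenated.

    ``item`` may hold item ids or integer indices; regressors restart at
    each run boundary.
    """
    parts = []
    for (part, run), grp in session.groupby(["participant", "run"], sort=True):
        grp = grp.sort_values("trial")
        items = [
            design.item_index(i) if isinstance(i, str) else int(i)
            for i in grp["item"]
        ]
        regs = build_glm_regressors(items, design, sim)
        regs["dv"] = _abs_pe(grp).to_numpy()
        regs["participant"] = part
        regs["run"] = run
        regs["trial"] = grp["trial"].to_numpy()
        parts.append(regs)
    return pd.concat(parts, ignore_index=True)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def fit_participant_glm(
    rows: pd.DataFrame,
    regressors: Sequence[str] = REGRESSORS,
    zscore: bool = True,
) -> GlmFit:
    """OLS of |PE| on the given regressors (plus intercept) for one
    participant; regressors are z-scored within participant by default.

    Single-regressor fits are obtained by passing one name in
    ``regressors``; missing-response trials (NaN dv) are dropped.
    """
    df = rows.dropna(subset=["dv"])
    if len(df) < 5:
        raise ValueError("need at least 5 usable trials")
    X = np.column_stack([
        _zscore(df[r].to_numpy(float)) if zscore else df[r].to_numpy(float)
        for r in regressors
    ])
    model = sm.OLS(df["dv"].to_numpy(float), sm.add_constant(X, has_constant="add"))
    res = model.fit()
    names = ["const", *regressors]
    rank_deficient = res.df_model < len(regressors)
    return GlmFit(
        betas=dict(zip(names, res.params)),
        tvalues=dict(zip(names, res.tvalues)),
        r_squared=float(res.rsquared),
        condition_number=float(np.linalg.cond(model.exog)),
        rank_deficient=bool(rank_deficient),
    )


def group_ttest(betas: Sequence[float], direction: str = "less") -> GroupTestResult:
    """One-sample t-test of participants' betas against zero, one-sided.

    ``direction='less'`` tests for a negative slope (PEs shrinking with the
    regressor).  Zero variance across participants is flagged with t = NaN.
    """
    b = np.asarray(betas, dtype=float)
    if len(b) < 2:
        raise ValueError("need at least 2 participants")
    if np.std(b, ddof=1) == 0:
        return GroupTestResult(float(b.mean()), float("nan"), float("nan"), len(b) - 1, True)
    res = sps.ttest_1samp(b, 0.0, alternative=direction)
    return GroupTestResult(float(b.mean()), float(res.statistic), float(res.pvalue), len(b) - 1)


def regressor_correlations(glm_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among the three regressors."""
    return glm_table[list(REGRESSORS)].corr(method="pearson")
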