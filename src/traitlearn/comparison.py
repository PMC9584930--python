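"""Fixed- and random-effects model comparison.

Fixed effects: BIC scores are summed across participants per model and
expressed relative to the worst (highest-sum) model — the log-group Bayes
factor; larger deltas mean better models.

Random effects: Bayesian model selection over the population treats each
participant's best model as a draw from an unknown multinomial with a
Dirichlet prior on model frequencies.  A variational scheme (Stephan et al.
2009) iterates

    u_nk  propto  exp( ln E_nk + psi(alpha_k) - psi(sum_j alpha_j) )
    alpha_k = alpha0 + sum_n u_nk

to convergence, where ``ln E_nk`` is subject n's log model evidence
(``-BIC/2``).  The exceedance probability of model k — the posterior
probability that it is the most frequent model in the population — is
estimated by Monte-Carlo sampling from the Dirichlet posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma


@dataclass
class ComparisonResult:
    """Fixed- and random-effects comparison of one model set."""

    bic_sums: pd.Series
    delta_vs_worst: pd.Series
    dirichlet_alpha: pd.Series
    expected_freq: pd.Series
    exceedance_prob: pd.Series
    converged: bool
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bic_sum": self.bic_sums,
                "delta_vs_worst": self.delta_vs_worst,
                "dirichlet_alpha": self.dirichlet_alpha,
                "expected_freq": self.expected_freq,
                "exceedance_prob": self.exceedance_prob,
            }
        )


def fixed_effects_compare(bic_table: pd.DataFrame) -> pd.Series:
    """Per-model summed BIC relative to the worst model (log-group BF).

    ``bic_table`` is subjects x models with no missing cells.  The worst
    model's delta is 0; every other delta is positive and larger is better.
    """
    if bic_table.size == 0:
        raise ValueError("empty BIC table")
    if bic_table.isna().any().any():
        raise ValueError("BIC table has missing cells")
    sums = bic_table.sum(axis=0)
    return sums.max() - sums


def bic_to_log_evidence(bic):
    """BIC approximates -2 ln(model evidence), so ln E = -BIC/2."""
    return -np.asarray(bic, dtype=float) / 2.0


def bms_random_effects(
    log_evidence: pd.DataFrame | np.ndarray,
    alpha0: float = 1.0,
    n_mc_samples: int = 1_000_000,
    seed: int | np.random.SeedSequence | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[pd.Series, pd.Series, pd.Series, bool, int]:
    """Variational random-effects BMS; returns (alpha, expected frequency,
    exceedance probability, converged, iterations)."""
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    le = pd.DataFrame(log_evidence)
    lnE = le.to_numpy(dtype=float)
    if not np.isfinite(lnE).all():
        raise ValueError("log evidences must be finite")
    n_sub, n_mod = lnE.shape
    # normalize per subject for numerical stability (invariant to constants)
    lnE = lnE - lnE.max(axis=1, keepdims=True)

    alpha = np.full(n_mod, alpha0, dtype=float)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = lnE + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        w = w - w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            converged = True
            break
        alpha = new_alpha

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_mc_samples))
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=n_mod) / len(winners)

    cols = le.columns
    return (
        pd.Series(alpha, index=cols),
        pd.Series(expected, index=cols),
        pd.Series(xp, index=cols),
        converged,
        it,
    )


def compare_models(
    bic_table: pd.DataFrame,
    alpha0: float = 1.0,
    n_mc_samples: int = 1_000_000,
    seed: int | np.random.SeedSequence | None = None,
) -> ComparisonResult:
    """Full comparison from a subjects x models BIC table."""
    delta = fixed_effects_compare(bic_table)
    log_ev = pd.DataFrame(
        bic_to_log_evidence(bic_table.to_numpy()),
        index=bic_table.index,
        columns=bic_table.columns,
    )
    alpha, expected, xp, converged, n_iter = bms_random_effects(
        log_ev, alpha0=alpha0, n_mc_samples=n_mc_samples, seed=seed
    )
    return ComparisonResult(
        bic_sums=bic_table.sum(axis=0),
        delta_vs_worst=delta,
        dirichlet_alpha=alpha,
        expected_freq=expected,
        exceedance_prob=xp,
        converged=converged,
        n_iter=n_iter,
    )
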