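"""Synthetic rater populations, similarity matrices, reference points, profiles.

The published experiments derived two knowledge structures from independent
rater samples: a signed item-by-item Pearson correlation matrix (SIM) of trait
self-ratings, and per-item population mean ratings used as reference points
(RP).  This module generates surrogate populations with the statistical
structure those analyses assume:

* items load on their Big-Five factor through a single latent factor score
  per rater (loading ``lambda``), so same-factor items correlate ~``lambda**2``
  and cross-factor items correlate ~0;
* items carry a valence sign: negative-valence traits (e.g. *aggressive*)
  anti-correlate with positive ones within their factor;
* per-item population means scatter around a common base (6.0 on the 1-8
  scale) with an item-level SD of ~0.69 scale units, the spread measured
  reference points show; this scatter is what makes the reference-point
  weighting identifiable;
* ratings are integers, rounded half-away-from-zero and capped to the scale.

A rater's rating of item *i* is::

    r_i = round(cap(mean_i + s_i * (lambda * f_factor(i) + mu * g)
                    + sqrt(1 - lambda**2 - mu**2) * eps_i))

with ``f`` one standard-normal factor score per factor per rater, ``g`` one
standard-normal evaluative (halo) score per rater loading on every item with
the item's valence sign, ``eps`` standard-normal item noise and ``s_i`` the
valence sign.  The evaluative factor reproduces the pervasive signed
cross-factor correlations real trait ratings show; set ``mu = 0`` for a pure
within-factor block structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .design import ExperimentDesign, build_design

#: Default within-factor latent loading (gives within-factor |r| ~ 0.3
#: before the evaluative contribution).
DEFAULT_LOADING = 0.6
#: Default evaluative (halo) loading: signed cross-factor |r| ~ 0.2.
DEFAULT_EVALUATIVE_LOADING = 0.45
#: Per-item spread of the factor and evaluative loadings (congeneric items:
#: lambda_i ~ U[lam-0.2, lam+0.2], mu_i ~ U[mu-0.15, mu+0.15]); this
#: heterogeneity is what distinguishes item-level (fine) generalization from
#: factor-level (coarse) generalization.  Set 0 for exchangeable items.
DEFAULT_LOADING_SPREAD = 0.2
DEFAULT_EVALUATIVE_SPREAD = 0.15
#: Communality cap: lambda_i**2 + mu_i**2 is rescaled to this if exceeded.
_COMMUNALITY_CAP = 0.98
#: Fraction of items per factor with negative valence, by preset family.
DEFAULT_VALENCE_FRACTION = {"exp1": 0.5, "exp2": 0.0, "exp3": 0.0, "exp4": 0.5, "exp5": 0.5}
#: Whether negative-valence items get means mirrored across the scale
#: midpoint (raw scoring: an average person rates low on negative traits).
#: exp2/exp3 use exclusively positive-valence traits, so nothing mirrors.
DEFAULT_MIRROR_MEANS = {"exp1": True, "exp2": False, "exp3": False, "exp4": True, "exp5": True}
#: Exp-4 surrogate stereotype shift/jitter (out-group RPs sit ~0.9 below
#: in-group RPs on the 1-8 scale, with item-level scatter).
STEREOTYPE_SHIFT = -0.9
STEREOTYPE_JITTER_SD = 0.3
#: Item-level SD of population means, as a fraction of the 7-unit range of
#: the 1-8 scale (student reference points spread with SD ~0.69).
ITEM_MEAN_SD_FRACTION = 0.69 / 7.0
#: Between-rater dispersion of a single item's ratings, as a fraction of the
#: range (1.5 scale units on 1-8 — typical for Likert trait ratings).
RATING_SD_FRACTION = 1.5 / 7.0


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    """Round half away from zero (positive scale): 2.5 -> 3, not 2."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def cap_to_scale(x, design: ExperimentDesign) -> np.ndarray:
    return np.clip(x, design.scale_min, design.scale_max)


@dataclass(frozen=True)
class PopulationSample:
    """Rater x item integer rating matrix plus the design it was rated on."""

    ratings: np.ndarray
    design: ExperimentDesign

    def __post_init__(self) -> None:
        r = np.asarray(self.ratings)
        if r.ndim != 2 or r.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 raters")
        if r.shape[1] != self.design.n_items:
            raise ValueError("rating columns must match design items")
        if r.min() < self.design.scale_min or r.max() > self.design.scale_max:
            raise ValueError("ratings outside scale bounds")

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[0]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Signed item x item Pearson correlation matrix (unit diagonal)."""

    sim: np.ndarray
    item_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        s = np.asarray(self.sim)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if np.abs(s).max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class ReferencePoint:
    """Per-item mean rating of a comparison group, in scale units."""

    rp: np.ndarray
    source: str = "population"  # population | stereotype | self
    item_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class Profile:
    """One target person's integer self-rating per item (the run's feedback)."""

    feedback: np.ndarray
    provenance: str  # sampled | constructed


@dataclass(frozen=True)
class TraitGenerator:
    """Latent-factor generator for integer trait ratings on a design.

    ``item_loadings`` / ``item_evaluatives`` are per-item loadings on the
    item's Big-Five factor and on the shared evaluative (halo) factor; total
    latent variance is 1 per item.
    """

    design: ExperimentDesign
    loading: float          # base factor loading the item loadings spread around
    item_means: np.ndarray  # per-item population mean, scale units
    item_signs: np.ndarray  # +1 positive valence, -1 negative
    item_loadings: np.ndarray
    item_evaluatives: np.ndarray
    rating_sd: float = 1.5  # between-rater SD of one item's ratings, scale units

    def sample(
        self,
        n_raters: int,
        rng: np.random.Generator,
        factor_shift: Mapping[str, float] | None = None,
    ) -> np.ndarray:
        """Draw integer ratings for ``n_raters`` raters.

        ``factor_shift`` moves a factor's latent mean by the given amount
        (applied with the item's valence sign), used to build profiles that
        diverge on one factor.
        """
        d = self.design
        means = self.item_means.copy()
        if factor_shift:
            shift = np.zeros(d.n_factors)
            for factor, delta in factor_shift.items():
                if factor not in d.factors:
                    raise KeyError(f"unknown factor {factor!r}")
                shift[d.factors.index(factor)] = delta
            means = means + self.item_signs * shift[d.factor_index]
        lam = self.item_loadings
        mu = self.item_evaluatives
        f = rng.standard_normal((n_raters, d.n_factors))
        g = rng.standard_normal((n_raters, 1))
        eps = rng.standard_normal((n_raters, d.n_items))
        latent = (
            self.item_signs[None, :] * (lam[None, :] * f[:, d.factor_index] + mu[None, :] * g)
            + np.sqrt(1.0 - lam**2 - mu**2)[None, :] * eps
        )
        raw = means[None, :] + self.rating_sd * latent
        return cap_to_scale(round_half_up(raw), d).astype(int)


def default_item_means(
    design: ExperimentDesign,
    factor_means: Mapping[str, float] | None = None,
    item_mean_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-item population means: a factor base plus item-level scatter.

    Without explicit ``factor_means``, the base sits at 5/7 of the scale
    range above the minimum (6.0 on 1-8, ~3.86 on 1-5), matching typical
    student trait averages.  Per-item scatter (default SD 0.69 scale units
    on 1-8, scaled with the range) reproduces the spread measured reference
    points show and is required for the reference-point weighting to be
    identifiable at all.
    """
    base = design.scale_min + 5.0 / 7.0 * (design.scale_max - design.scale_min)
    means = np.empty(design.n_items)
    for k, item in enumerate(design.item_ids):
        factor = design.factor_of[item]
        means[k] = factor_means.get(factor, base) if factor_means else base
    if item_mean_sd is None:
        item_mean_sd = ITEM_MEAN_SD_FRACTION * (design.scale_max - design.scale_min)
    if item_mean_sd > 0 and rng is not None:
        means = means + rng.normal(0.0, item_mean_sd, design.n_items)
        means = np.asarray(cap_to_scale(means, design))
    return means


def item_signs(design: ExperimentDesign, valence_fraction: float) -> np.ndarray:
    """Deterministic valence assignment: the last ``valence_fraction`` of each
    factor's items are negative-valence."""
    if not 0.0 <= valence_fraction <= 1.0:
        raise ValueError("valence_fraction must lie in [0, 1]")
    signs = np.ones(design.n_items)
    fidx = design.factor_index
    for f in range(design.n_factors):
        members = np.flatnonzero(fidx == f)
        n_neg = int(round(valence_fraction * members.size))
        if n_neg:
            signs[members[-n_neg:]] = -1.0
    return signs


def make_generator(
    design: ExperimentDesign,
    within_factor_loading: float = DEFAULT_LOADING,
    valence_fraction: float | None = None,
    factor_means: Mapping[str, float] | None = None,
    item_mean_sd: float | None = None,
    seed: int | np.random.SeedSequence | None = None,
    evaluative_loading: float | None = None,
    loading_spread: float = DEFAULT_LOADING_SPREAD,
    evaluative_spread: float = DEFAULT_EVALUATIVE_SPREAD,
    mirror_negative_means: bool | None = None,
    rating_sd: float | None = None,
) -> TraitGenerator:
    """Build the population generator.

    ``seed`` fixes the item-level draws (means and loadings); with no seed
    they are drawn from fresh entropy.  ``loading_spread``/``evaluative_spread``
    give items heterogeneous (congeneric) loadings; zero spread makes items
    within a factor exchangeable.
    """
    if not 0.0 <= within_factor_loading < 1.0:
        raise ValueError("within_factor_loading must lie in [0, 1)")
    if evaluative_loading is None:
        evaluative_loading = (
            DEFAULT_EVALUATIVE_LOADING
            if within_factor_loading**2 + DEFAULT_EVALUATIVE_LOADING**2 <= 1.0
            else 0.0
        )
    if valence_fraction is None:
        valence_fraction = DEFAULT_VALENCE_FRACTION.get(design.name, 0.5)
    signs = item_signs(design, valence_fraction)
    rng = np.random.default_rng(seed)
    means = default_item_means(design, factor_means, item_mean_sd, rng)
    if mirror_negative_means is None:
        mirror_negative_means = DEFAULT_MIRROR_MEANS.get(design.name, False)
    if mirror_negative_means:
        mirror = design.scale_min + design.scale_max - means
        means = np.where(signs > 0, means, mirror)
    lam = within_factor_loading + rng.uniform(-loading_spread, loading_spread, design.n_items)
    mu = evaluative_loading + rng.uniform(-evaluative_spread, evaluative_spread, design.n_items)
    lam = np.clip(lam, 0.0, None)
    mu = np.clip(mu, 0.0, None)
    comm = lam**2 + mu**2
    over = comm > _COMMUNALITY_CAP
    scale = np.where(over, np.sqrt(_COMMUNALITY_CAP / np.where(comm > 0, comm, 1.0)), 1.0)
    if rating_sd is None:
        rating_sd = RATING_SD_FRACTION * (design.scale_max - design.scale_min)
    return TraitGenerator(
        design, within_factor_loading, means, signs, lam * scale, mu * scale, rating_sd
    )


def generate_population(
    design: ExperimentDesign,
    within_factor_loading: float = DEFAULT_LOADING,
    valence_fraction: float | None = None,
    factor_means: Mapping[str, float] | None = None,
    n_raters: int = 300,
    seed: int | np.random.SeedSequence | None = None,
    item_mean_sd: float | None = None,
    evaluative_loading: float | None = None,
    loading_spread: float = DEFAULT_LOADING_SPREAD,
    evaluative_spread: float = DEFAULT_EVALUATIVE_SPREAD,
) -> PopulationSample:
    """Sample a structured rater population (see module docstring).

    The seed drives the item-level draws (means, loadings) and the rater
    draws, so regenerating with the same seed but shifted ``factor_means``
    shifts the means exactly while keeping the scatter.
    """
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_items, s_raters = ss.spawn(2)
    gen = make_generator(
        design, within_factor_loading, valence_fraction, factor_means,
        item_mean_sd, seed=s_items, evaluative_loading=evaluative_loading,
        loading_spread=loading_spread, evaluative_spread=evaluative_spread,
    )
    rng = np.random.default_rng(s_raters)
    return PopulationSample(gen.sample(n_raters, rng), design)


def derive_similarity(pop: PopulationSample) -> SimilarityMatrix:
    """Signed Pearson correlations between items over raters; unit diagonal."""
    r = np.asarray(pop.ratings, dtype=float)
    sd = r.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [pop.design.item_ids[k] for k in dead]
        raise ValueError(f"zero-variance items (degenerate population): {names}")
    sim = np.corrcoef(r, rowvar=False)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, pop.design.item_ids)


def derive_reference_point(pop: PopulationSample) -> ReferencePoint:
    """Per-item arithmetic mean rating (the population reference point)."""
    return ReferencePoint(
        np.asarray(pop.ratings, dtype=float).mean(axis=0),
        source="population",
        item_ids=pop.design.item_ids,
    )


def construct_profile(
    factor_means: Mapping[str, float],
    design: ExperimentDesign,
    sd: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
) -> Profile:
    """Constructed profile: factor mean + N(0, sd) per item, rounded, capped.

    This is the exp2 procedure (means of 5 or 7 on two factors, SD 1).
    """
    for factor in factor_means:
        if factor not in design.factors:
            raise KeyError(f"unknown factor {factor!r}")
    for factor in design.factors:
        if factor not in factor_means:
            raise ValueError(f"no mean given for factor {factor!r}")
    rng = np.random.default_rng(seed)
    means = np.array([factor_means[design.factor_of[i]] for i in design.item_ids], float)
    raw = means + rng.normal(0.0, sd, size=design.n_items)
    return Profile(cap_to_scale(round_half_up(raw), design).astype(int), "constructed")


def sample_profile(
    design: ExperimentDesign,
    generator: TraitGenerator | None = None,
    seed: int | np.random.SeedSequence | None = None,
    factor_shift: Mapping[str, float] | None = None,
) -> Profile:
    """Draw one 'real' profile from the population generator.

    Without an explicit ``generator`` one is built from the same seed, so a
    seeded call is fully reproducible.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if generator is None:
        s_gen, s_draw = ss.spawn(2)
        generator = make_generator(design, seed=s_gen)
        ss = s_draw
    rng = np.random.default_rng(ss)
    return Profile(generator.sample(1, rng, factor_shift)[0], "sampled")


def derive_stereotype_rp(
    rp: ReferencePoint,
    shift: float = STEREOTYPE_SHIFT,
    jitter_sd: float = STEREOTYPE_JITTER_SD,
    seed: int | np.random.SeedSequence | None = None,
) -> ReferencePoint:
    """Surrogate out-group (stereotype) reference point: shift + jitter, capped.

    Stands in for measured pre-task stereotype ratings, which cannot be
    generated from the population itself.
    """
    rng = np.random.default_rng(seed)
    vals = np.asarray(rp.rp, dtype=float) + shift + rng.normal(0.0, jitter_sd, len(rp.rp))
    return ReferencePoint(vals, source="stereotype", item_ids=rp.item_ids)


@dataclass(frozen=True)
class Surrogate:
    """Everything one synthetic experiment needs: design, SIM, RPs, profiles."""

    design: ExperimentDesign
    population: PopulationSample
    sim: SimilarityMatrix
    rp: ReferencePoint
    profiles: tuple[Profile, ...]
    stereotype_rp: ReferencePoint | None = None


#: Raters behind the surrogate SIM/RP, per preset: ~800 pooled raters for the
#: trait-adjective experiments, a large online sample for the IPIP items.
DEFAULT_N_RATERS = {"exp1": 800, "exp2": 800, "exp3": 800, "exp4": 800, "exp5": 5000}
#: Instrument-specific latent structure: IPIP items are purpose-built
#: homogeneous factor markers (higher factor loadings, tighter spread, less
#: halo under balanced keying) compared to free trait adjectives.
PRESET_STRUCTURE = {
    "exp5": {"within_factor_loading": 0.7, "loading_spread": 0.1, "evaluative_loading": 0.3},
}


def make_surrogate(
    preset: str = "exp1",
    seed: int | np.random.SeedSequence | None = None,
    n_raters: int | None = None,
    within_factor_loading: float | None = None,
) -> Surrogate:
    """Build a full synthetic experiment for one preset.

    * SIM and RP come from a fresh structured population of ``n_raters``.
    * exp1/exp3/exp4 profiles are sampled from the same population model.
    * exp2 profiles are constructed with the four factor-mean combinations
      (5&5, 5&7, 7&5, 7&7) and per-item SD-1 noise.
    * exp5 profiles each diverge by +1 latent unit on a different factor
      (average on the other four), echoing the published selection rule.
    * exp4 additionally carries a surrogate stereotype reference point.
    """
    design = build_design(preset)
    if n_raters is None:
        n_raters = DEFAULT_N_RATERS.get(design.name, 800)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_means, s_pop, s_prof, s_ste = ss.spawn(4)
    structure = dict(PRESET_STRUCTURE.get(design.name, {}))
    if within_factor_loading is not None:
        structure["within_factor_loading"] = within_factor_loading
    structure.setdefault("within_factor_loading", DEFAULT_LOADING)
    gen = make_generator(design, seed=s_means, **structure)
    pop = PopulationSample(gen.sample(n_raters, np.random.default_rng(s_pop)), design)
    sim = derive_similarity(pop)
    rp = derive_reference_point(pop)

    prof_seeds = s_prof.spawn(design.n_profiles)
    profiles: list[Profile] = []
    if design.name == "exp2":
        combos = [(5, 5), (5, 7), (7, 5), (7, 7)]
        for (m1, m2), sp in zip(combos, prof_seeds):
            fm = {design.factors[0]: float(m1), design.factors[1]: float(m2)}
            profiles.append(construct_profile(fm, design, sd=1.0, seed=sp))
    elif design.name == "exp5":
        for k, sp in enumerate(prof_seeds):
            shift = {design.factors[k % design.n_factors]: 1.0}
            profiles.append(sample_profile(design, gen, seed=sp, factor_shift=shift))
    else:
        for sp in prof_seeds:
            profiles.append(sample_profile(design, gen, seed=sp))

    ste = derive_stereotype_rp(rp, seed=s_ste) if design.name == "exp4" else None
    return Surrogate(design, pop, sim, rp, tuple(profiles), ste)


def rp_shift_ttest(rp_a: ReferencePoint, rp_b: ReferencePoint):
    """Paired t-test between two reference points over items (scipy result)."""
    return stats.ttest_rel(np.asarray(rp_a.rp), np.asarray(rp_b.rp))
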