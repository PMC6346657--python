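"""Candidate metapopulation model sets and evidence-based selection.

Builds the competing hypotheses compared on each dataset — panmixia, island
models, regional lumpings, and stepping-stone models with tied or free
parameters — and turns replicate marginal-likelihood estimates into relative
model probabilities, an ambiguity call (permutation t test between the best
and second-best model), and the posterior slope test of log Theta against an
island covariate such as habitat area.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .coalmcmc.model import ModelSpec, count_parameters

__all__ = [
    "ModelEvidence", "SelectionResult", "SlopeTestResult",
    "build_simulation_models", "build_hawaii_models", "count_parameters",
    "relative_probabilities", "permutation_t_test", "select_model",
    "posterior_slope_test",
]


# ---------------------------------------------------------------------------
# model-set builders
# ---------------------------------------------------------------------------

def _stepping_stone_ties(k: int, tied: bool):
    """(theta_ties, mig_ties) for a linear lattice of k analysis demes."""
    theta = np.zeros(k, dtype=int) if tied else np.arange(k)
    mig = {}
    g = 0
    for a in range(k - 1):
        for pair in ((a, a + 1), (a + 1, a)):
            mig[pair] = 0 if tied else g
            if not tied:
                g += 1
    return theta, mig


def _island_ties(k: int):
    theta = np.zeros(k, dtype=int)
    mig = {pair: 0 for pair in itertools.permutations(range(k), 2)}
    return theta, mig


def build_simulation_models(n_demes: int = 10) -> list[ModelSpec]:
    """The seven hypotheses compared on every simulated lattice dataset.

    Panmixia; stepping-stone over five lumped deme pairs with shared or free
    parameters (regional structure); 10-deme and 5-group island models; and
    the stepping-stone model with tied (the generating truth) or fully free
    parameters.
    """
    if n_demes % 2:
        raise ValueError("n_demes must be even for the lumped-pairs models")
    ident = np.arange(n_demes)
    pairs = np.repeat(np.arange(n_demes // 2), 2)
    models = [
        ModelSpec("panmixia", np.zeros(n_demes, dtype=int), [0], {}),
    ]
    th, mig = _stepping_stone_ties(n_demes // 2, tied=True)
    models.append(ModelSpec("stepping-stone-5-shared", pairs, th, mig))
    th, mig = _stepping_stone_ties(n_demes // 2, tied=False)
    models.append(ModelSpec("stepping-stone-5-free", pairs, th, mig))
    th, mig = _island_ties(n_demes)
    models.append(ModelSpec("island", ident, th, mig))
    th, mig = _island_ties(n_demes // 2)
    models.append(ModelSpec("island-5", pairs, th, mig))
    th, mig = _stepping_stone_ties(n_demes, tied=True)
    models.append(ModelSpec("stepping-stone-2param", ident, th, mig))
    th, mig = _stepping_stone_ties(n_demes, tied=False)
    models.append(ModelSpec("stepping-stone-full", ident, th, mig))
    return models


def build_hawaii_models(
    islands: list[str],
    region_boundaries: dict | None = None,
    custom_partition=None,
) -> list[ModelSpec]:
    """Archipelago-style model set for an ordered chain of islands.

    ``region_boundaries`` maps a hypothesis name to a list of boundary
    positions: a boundary at position i separates islands[i-1] and
    islands[i], splitting the chain into panmictic regions that exchange
    migrants at free pairwise rates.  Defaults encode the three canonical
    hypotheses for the Hawaiian chain ordered southeast to northwest: a
    main-islands/northwestern-islands break, a break at the French Frigate
    Shoals-Gardner Pinnacles current, and the two-currents hypothesis adding
    the Lisianski-Pearl & Hermes break.  An optional ``custom_partition``
    (original deme -> region) appends one empirically motivated model.
    """
    n = len(islands)
    if n < 3:
        raise ValueError("need at least three islands")
    if region_boundaries is None:
        region_boundaries = _default_hawaii_boundaries(islands)
    ident = np.arange(n)
    models = [ModelSpec("panmixia", np.zeros(n, dtype=int), [0], {})]
    for name, bounds in region_boundaries.items():
        for b in bounds:
            if not (0 < b < n):
                raise ValueError(f"boundary {b} must lie between adjacent islands")
        part = np.zeros(n, dtype=int)
        for b in sorted(bounds):
            part[b:] += 1
        k = int(part.max()) + 1
        th, mig = _island_ties(k)
        mig = {pair: g for g, pair in enumerate(sorted(mig))}
        models.append(ModelSpec(name, part, np.arange(k), mig))
    th, mig = _island_ties(n)
    models.append(ModelSpec("island", ident, th, mig))
    th, mig = _stepping_stone_ties(n, tied=True)
    models.append(ModelSpec("stepping-stone-2param", ident, th, mig))
    th, mig = _stepping_stone_ties(n, tied=False)
    models.append(ModelSpec("stepping-stone-full", ident, th, mig))
    if custom_partition is not None:
        part = np.asarray(custom_partition, dtype=int)
        k = int(part.max()) + 1
        th, mig = _island_ties(k)
        mig = {pair: g for g, pair in enumerate(sorted(mig))}
        models.append(ModelSpec("empirical-structure", part, np.arange(k), mig))
    return models


_HAWAII_BREAKS = {
    # island name (lowercased prefix) after which each oceanographic break falls
    "mhi-nwhi": "niihau",
    "ffs-gardner": "french frigate",
    "lisianski-phr": "lisianski",
}


def _default_hawaii_boundaries(islands: list[str]) -> dict:
    lowered = [s.lower() for s in islands]

    def after(key: str):
        for i, name in enumerate(lowered):
            if name.startswith(_HAWAII_BREAKS[key]):
                return i + 1
        return None

    out = {}
    mhi = after("mhi-nwhi")
    ffs = after("ffs-gardner")
    lis = after("lisianski-phr")
    if mhi:
        out["regional-mhi-nwhi"] = [mhi]
    if ffs:
        out["regional-ffs-gardner"] = [ffs]
    if ffs and lis:
        out["two-currents"] = [ffs, lis]
    if not out:
        # unnamed chain: fall back to an even two-way and three-way split
        n = len(islands)
        out["regional-2"] = [n // 2]
        out["two-currents"] = [n // 3, 2 * n // 3]
    return out


# ---------------------------------------------------------------------------
# evidence aggregation
# ---------------------------------------------------------------------------

@dataclass
class ModelEvidence:
    """Replicate marginal-likelihood estimates for one model."""

    model: str
    log_mls: list
    n_parameters: int = 0

    @property
    def mean_log_ml(self) -> float:
        return float(np.mean(self.log_mls))


@dataclass
class SelectionResult:
    best: str
    second: str
    p_value: float
    ambiguous: bool
    probabilities: dict = field(default_factory=dict)


@dataclass
class SlopeTestResult:
    fraction_positive: float
    significant: bool
    n_draws: int


def relative_probabilities(log_mls: dict) -> dict:
    """Normalize log marginal likelihoods to model probabilities (softmax)."""
    if len(log_mls) < 2:
        raise ValueError("need at least two models")
    names = list(log_mls)
    vals = np.array([log_mls[k] for k in names], dtype=float)
    vals = np.exp(vals - vals.max())
    vals /= vals.sum()
    return dict(zip(names, vals.tolist()))


def permutation_t_test(group_a, group_b, n_mc: int = 100_000,
                       rng: np.random.Generator | None = None,
                       max_exhaustive: int = 10_000,
                       alternative: str = "two-sided") -> float:
    """Permutation p-value for a difference in group means.

    Uses the pooled-variance t statistic; enumerates all C(nA+nB, nA)
    relabelings when that count is at most ``max_exhaustive``, otherwise
    Monte-Carlo resamples.  ``alternative`` is "two-sided" or "greater"
    (mean of A exceeds mean of B).  With both groups constant and equal,
    p = 1.  Note the resolution floor: with 3 + 3 values the two-sided p
    can never fall below 2/20 = 0.1.
    """
    if alternative not in ("two-sided", "greater"):
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("values must be finite")
    pooled = np.concatenate([a, b])
    na = len(a)
    n = len(pooled)

    def tstat(idx_a: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[idx_a] = True
        xa, xb = pooled[mask], pooled[~mask]
        va = xa.var(ddof=1)
        vb = xb.var(ddof=1)
        sp = math.sqrt(((na - 1) * va + (n - na - 1) * vb) / (n - 2))
        denom = sp * math.sqrt(1.0 / na + 1.0 / (n - na))
        diff = xa.mean() - xb.mean()
        if denom == 0.0:
            return 0.0 if diff == 0.0 else math.inf * np.sign(diff)
        return diff / denom

    if alternative == "two-sided":
        score = lambda idx: abs(tstat(idx))
    else:
        score = tstat
    t_obs = score(np.arange(na))
    n_comb = math.comb(n, na)
    if n_comb <= max_exhaustive:
        count = 0
        for combo in itertools.combinations(range(n), na):
            if score(np.array(combo)) >= t_obs - 1e-12:
                count += 1
        return count / n_comb
    rng = rng or np.random.default_rng()
    count = 1  # the observed labeling
    for _ in range(n_mc):
        idx = rng.permutation(n)[:na]
        if score(idx) >= t_obs - 1e-12:
            count += 1
    return count / (n_mc + 1)


def select_model(evidence: list[ModelEvidence], alpha: float = 0.05,
                 rng: np.random.Generator | None = None,
                 alternative: str = "greater") -> SelectionResult:
    """Rank models by mean log marginal likelihood and call ambiguity.

    The best and second-best models' replicate estimates are compared with
    the permutation t test; p > alpha flags the selection as ambiguous.  The
    default test is one-sided (best exceeds second): with the typical three
    replicate estimates per model the exhaustive two-sided p can never reach
    0.05, so a two-sided call would declare every selection ambiguous;
    pass ``alternative="two-sided"`` to override.  Mean ties are broken
    toward the model with fewer parameters (parsimony).
    """
    if len(evidence) < 2:
        raise ValueError("need at least two models")
    for ev in evidence:
        if len(ev.log_mls) < 2:
            raise ValueError("each model needs >= 2 replicate estimates")
    ranked = sorted(
        evidence, key=lambda ev: (-ev.mean_log_ml, ev.n_parameters, ev.model)
    )
    best, second = ranked[0], ranked[1]
    p = permutation_t_test(
        best.log_mls, second.log_mls, rng=rng, alternative=alternative
    )
    probs = relative_probabilities({ev.model: ev.mean_log_ml for ev in evidence})
    return SelectionResult(
        best=best.model, second=second.model, p_value=p,
        ambiguous=p > alpha, probabilities=probs,
    )


def posterior_slope_test(
    theta_posteriors: dict,
    covariate: dict,
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
    threshold: float = 0.95,
) -> SlopeTestResult:
    """Posterior-draw regression of log Theta on an island covariate.

    For each draw, one Theta sample is taken per island and the OLS slope of
    ln Theta against the covariate (e.g., habitat area) is recorded; the
    relationship is called significant when at least ``threshold`` of the
    draws have a positive slope.
    """
    islands = sorted(theta_posteriors)
    if len(islands) < 3:
        raise ValueError("need at least three islands")
    if sorted(covariate) != islands:
        raise ValueError("covariate must cover exactly the sampled islands")
    x = np.array([covariate[i] for i in islands], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("covariate is constant")
    rng = rng or np.random.default_rng()
    for i in islands:
        if np.any(np.asarray(theta_posteriors[i], dtype=float) <= 0):
            raise ValueError("Theta posterior samples must be positive")
    draws = np.column_stack(
        [
            np.log(rng.choice(np.asarray(theta_posteriors[i], dtype=float), n_draws))
            for i in islands
        ]
    )
    xc = x - x.mean()
    slopes = (draws - draws.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    frac = float(np.mean(slopes > 0.0))
    return SlopeTestResult(
        fraction_positive=frac, significant=frac >= threshold, n_draws=n_draws
    )
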