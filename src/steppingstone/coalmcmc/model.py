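"""Metapopulation model specifications, priors, and sampler configuration.

A :class:`ModelSpec` encodes one hypothesis about population structure as
three pieces of bookkeeping:

* ``deme_partition`` — how sampled (original) demes are lumped into analysis
  demes (e.g., adjacent pairs merged into regions, or everything merged for
  panmixia);
* ``theta_ties`` — which analysis demes share a mutation-scaled size
  parameter Theta = N_e * mu;
* ``mig_ties`` — which ordered deme pairs share a mutation-scaled migration
  rate M = m/mu, with absent pairs fixed at zero (e.g., only lattice
  neighbors in a stepping-stone model, all pairs in an island model).

The number of free parameters of a model is the number of Theta groups plus
the number of migration-rate groups; marginal-likelihood comparison between
specs of different complexity is the model-selection machinery's entire job.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TruncatedExponential:
    """Exponential with the given mean, truncated to [lower, upper].

    This is the "windowed exponential" prior shape: an exponential density
    restricted to a window and renormalized, sampled by inverse CDF.
    """

    lower: float
    upper: float
    mean: float

    def __post_init__(self):
        if not (0 < self.lower < self.upper):
            raise ValueError("need 0 < lower < upper")
        if self.mean <= 0:
            raise ValueError("mean must be positive")

    @property
    def _mass(self) -> float:
        return math.exp(-self.lower / self.mean) - math.exp(-self.upper / self.mean)

    def sample(self, rng: np.random.Generator, size=None):
        u = rng.random(size)
        el = math.exp(-self.lower / self.mean)
        return -self.mean * np.log(el - u * self._mass)

    def logpdf(self, x) -> float:
        x = np.asarray(x, dtype=float)
        out = np.where(
            (x >= self.lower) & (x <= self.upper),
            -x / self.mean - math.log(self.mean * self._mass),
            -np.inf,
        )
        return float(out) if out.ndim == 0 else out

    def cdf(self, x):
        x = np.clip(np.asarray(x, dtype=float), self.lower, self.upper)
        el = math.exp(-self.lower / self.mean)
        return (el - np.exp(-x / self.mean)) / self._mass


@dataclass(frozen=True)
class Priors:
    """Windowed exponential priors on Theta and on M = m/mu.

    Defaults encode the study's beliefs for mtDNA at a 10%/Myr mutation rate:
    per-island N_e below one million, and a migrant fraction below 10% of
    that.
    """

    theta: TruncatedExponential = field(
        default_factory=lambda: TruncatedExponential(1e-5, 1e-1, 0.01)
    )
    M: TruncatedExponential = field(
        default_factory=lambda: TruncatedExponential(1e-4, 1e6, 1e5)
    )


class ModelSpec:
    """One metapopulation hypothesis: deme lumping + parameter tying.

    Parameters
    ----------
    deme_partition
        Array mapping each original deme index to an analysis deme index.
    theta_ties
        Array of length K (number of analysis demes) giving the Theta group
        of each analysis deme (groups numbered 0..G-1, each used).
    mig_ties
        Dict mapping ordered analysis-deme pairs (from, to) — backward-in-time
        lineage movement — to migration-rate group indices.  Pairs absent from
        the dict have rate fixed at zero.
    """

    def __init__(self, name: str, deme_partition, theta_ties, mig_ties: dict):
        self.name = name
        self.deme_partition = np.asarray(deme_partition, dtype=np.int64)
        self.theta_ties = np.asarray(theta_ties, dtype=np.int64)
        self.mig_ties = dict(mig_ties)
        self.K = int(self.deme_partition.max()) + 1
        if len(self.theta_ties) != self.K:
            raise ValueError("theta_ties must cover every analysis deme")
        self.n_theta_groups = int(self.theta_ties.max()) + 1
        if sorted(set(self.theta_ties.tolist())) != list(range(self.n_theta_groups)):
            raise ValueError("theta groups must be 0..G-1, each used")
        if self.mig_ties:
            groups = sorted(set(self.mig_ties.values()))
            self.n_mig_groups = groups[-1] + 1
            if groups != list(range(self.n_mig_groups)):
                raise ValueError("migration groups must be 0..G-1, each used")
            for (a, b) in self.mig_ties:
                if a == b or not (0 <= a < self.K and 0 <= b < self.K):
                    raise ValueError(f"bad migration pair {(a, b)}")
        else:
            self.n_mig_groups = 0
        if self.K > 1 and not self._strongly_connected():
            raise ValueError("migration graph must be strongly connected")
        if self.K == 1 and self.mig_ties:
            raise ValueError("a one-deme model cannot have migration")

    def _strongly_connected(self) -> bool:
        def reach(edges):
            seen = {0}
            stack = [0]
            adj = {}
            for (a, b) in edges:
                adj.setdefault(a, []).append(b)
            while stack:
                for nxt in adj.get(stack.pop(), []):
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            return len(seen) == self.K

        edges = list(self.mig_ties)
        return reach(edges) and reach([(b, a) for (a, b) in edges])

    @property
    def theta_group_members(self) -> list:
        """Deme indices per Theta group."""
        if not hasattr(self, "_theta_members"):
            self._theta_members = [
                np.flatnonzero(self.theta_ties == g).tolist()
                for g in range(self.n_theta_groups)
            ]
        return self._theta_members

    @property
    def mig_group_members(self) -> list:
        """Ordered deme pairs per migration-rate group."""
        if not hasattr(self, "_mig_members"):
            out = [[] for _ in range(self.n_mig_groups)]
            for pair, g in self.mig_ties.items():
                out[g].append(pair)
            self._mig_members = out
        return self._mig_members

    # -- parameter expansion -------------------------------------------------
    def theta_by_deme(self, theta_groups: np.ndarray) -> np.ndarray:
        return np.asarray(theta_groups)[self.theta_ties]

    def migration_matrix(self, m_groups: np.ndarray) -> np.ndarray:
        """K x K backward migration rate matrix Lambda (zero diagonal);
        Lambda[a, b] is the rate at which a lineage in a jumps to b."""
        lam = np.zeros((self.K, self.K))
        m_groups = np.asarray(m_groups)
        for (a, b), g in self.mig_ties.items():
            lam[a, b] = m_groups[g]
        return lam

    def map_demes(self, original_demes: np.ndarray) -> np.ndarray:
        return self.deme_partition[np.asarray(original_demes, dtype=np.int64)]

    def __repr__(self):
        return (f"ModelSpec({self.name!r}, K={self.K}, "
                f"{self.n_theta_groups}+{self.n_mig_groups} parameters)")


@dataclass
class MCMCConfig:
    """Chain schedule for the Metropolis-coupled sampler.

    ``temperatures`` must start at 1 (the cold, posterior chain) and increase;
    each chain targets the power posterior with beta = 1/temperature, so a
    very hot chain (e.g., 1e5) explores essentially the prior and anchors the
    path-sampling integral near beta = 0.  ``total_steps`` counts single-move
    proposals of the cold chain (all chains advance in lockstep).
    """

    temperatures: tuple = (1.0, 1.5, 3.0, 1e5)
    total_steps: int = 200_000
    burn_in: int = 50_000
    sample_every: int = 20
    swap_every: int = 10
    move_weights: tuple = (0.3, 0.3, 0.2, 0.2)  # topology, times, migration, params
    param_step: float = 0.7          # sd of the log-scale random walk
    max_branch_events: int = 2000    # hard guard on migration events per branch
    max_expected_jumps: float = 6000.0  # reject path proposals hotter than this
    #: rungs below this inverse temperature are treated as the prior and
    #: estimated by iid prior-predictive sampling instead of a Markov chain
    prior_beta_cutoff: float = 0.2
    prior_draws: int = 150           # iid draws for those rungs

    def __post_init__(self):
        temps = tuple(float(t) for t in self.temperatures)
        if temps[0] != 1.0 or any(b >= a for a, b in zip(temps[1:], temps[:-1])):
            raise ValueError("temperatures must start at 1 and strictly increase")
        if not (0 <= self.burn_in < self.total_steps):
            raise ValueError("need 0 <= burn_in < total_steps")
        self.temperatures = temps

    @property
    def betas(self) -> tuple:
        return tuple(1.0 / t for t in self.temperatures)

    @classmethod
    def published_scale(cls, **kw) -> "MCMCConfig":
        """The full-length schedule: five million proposals, sampling every
        100, first two million discarded."""
        kw.setdefault("total_steps", 5_000_000)
        kw.setdefault("burn_in", 2_000_000)
        kw.setdefault("sample_every", 100)
        return cls(**kw)

    @classmethod
    def suite_scale(cls, **kw) -> "MCMCConfig":
        """A short schedule for smoke tests and the bundled experiment tier."""
        kw.setdefault("total_steps", 3000)
        kw.setdefault("burn_in", 1000)
        kw.setdefault("sample_every", 5)
        return cls(**kw)


def count_parameters(model: ModelSpec) -> int:
    """Free parameters of a model: Theta groups plus migration-rate groups."""
    return model.n_theta_groups + model.n_mig_groups
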