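"""Stepping-stone coalescent simulation of haploid sequence data.

Generates synthetic mtDNA-like datasets for a linear archipelago: equal-sized
demes on a one-dimensional lattice exchanging migrants only with adjacent
neighbors, an order-of-magnitude instantaneous population expansion a fixed
number of generations before sampling (emulating post-glacial demographic
growth), and sequences evolving under HKY85.

The genealogical engine is a continuous-time structured coalescent: within
deme i each lineage pair coalesces at rate 1/N_i(t) per generation, where
N_i(t) is the per-deme size (the current size more recently than the
expansion, one expansion-factor smaller earlier), and each lineage migrates
(backward in time) to each adjacent lattice neighbor at rate m per generation,
so edge demes emigrate at total rate m and interior demes at 2m.  Generations
are continuous (exponential waiting times) rather than discrete Wright-Fisher
steps; at the population sizes studied here (N_e >= 1e4) the diffusion
approximation is excellent.

The panmictic control is simulated as a single population whose samples are
then partitioned into pseudo-demes in blocks, in sampling order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .hky import BASES, HKYModel


@dataclass
class SimulationParams:
    """One simulation scenario: a Table-1 style parameter set plus constants.

    ``deme_size`` is the post-expansion (present-day) effective size per deme;
    ``mig_prop`` is the per-generation probability that a lineage migrates to
    one specific adjacent neighbor (so a neighboring deme pair exchanges
    deme_size * mig_prop effective migrants each way per generation).
    """

    n_demes: int = 10
    deme_size: float = 1e5
    mig_prop: float = 1e-4
    expansion_factor: float = 10.0
    expansion_time: float = 10_000.0
    sample_size: int = 20
    locus_length: int = 500
    mut_rate: float = 1e-7
    tstv_ratio: float = 9.0
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    panmictic: bool = False
    seed: Optional[int] = None
    name: str = ""

    def __post_init__(self):
        if self.n_demes < 1 or self.sample_size < 1 or self.locus_length < 1:
            raise ValueError("n_demes, sample_size, locus_length must be positive")
        if not (0.0 <= self.mig_prop < 1.0):
            raise ValueError("mig_prop must lie in [0, 1)")
        if self.deme_size <= 0 or self.expansion_factor <= 0:
            raise ValueError("deme_size and expansion_factor must be positive")
        if self.expansion_time <= 0:
            raise ValueError("expansion_time must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 1e-12:
            raise ValueError("base_freqs must sum to 1")
        if not self.panmictic and self.n_demes > 1 and self.mig_prop == 0.0:
            raise ValueError("mig_prop must be > 0 for a subdivided population")

    @property
    def migrants_per_generation(self) -> float:
        """N_e m, the effective number of migrants per neighboring-deme pair."""
        return self.deme_size * self.mig_prop

    @property
    def n_samples_total(self) -> int:
        return self.n_demes * self.sample_size


def parameter_set_table() -> list[SimulationParams]:
    """The ten study scenarios: nine stepping-stone (N_e x m crossed so that
    N_e m is 10, 100 or 1,000) and one panmictic control at N_e = 1e6.

    Stepping-stone sets are ordered by N_e m then N_e (set1 = 1e4/1e-3, ...,
    set9 = 1e6/1e-3); the control is last, named "panmixia".
    """
    sets = []
    k = 0
    for nem in (10.0, 100.0, 1000.0):
        for ne in (1e4, 1e5, 1e6):
            k += 1
            sets.append(
                SimulationParams(deme_size=ne, mig_prop=nem / ne, name=f"set{k}")
            )
    sets.append(
        SimulationParams(deme_size=1e6, mig_prop=0.0, panmictic=True, name="panmixia")
    )
    return sets


@dataclass
class Genealogy:
    """A realized coalescent tree over n_tips labeled samples.

    Nodes 0..n_tips-1 are tips at time 0; internal nodes follow in coalescence
    order, so node indices increase with node time.  Times are in generations
    before sampling.  ``deme`` records the deme in which each node was born
    (for tips, the sampling deme).
    """

    time: np.ndarray          # (2n-1,) float
    parent: np.ndarray        # (2n-1,) int, -1 at the root
    children: np.ndarray      # (n-1, 2) int, children of internal node n_tips+j
    deme: np.ndarray          # (2n-1,) int
    n_tips: int

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    def validate(self) -> None:
        n = self.n_tips
        if np.count_nonzero(self.parent == -1) != 1:
            raise ValueError("genealogy must have a single root")
        for node in range(2 * n - 1):
            p = self.parent[node]
            if p >= 0 and not self.time[p] > self.time[node]:
                raise ValueError("parent times must exceed child times")
        if np.any(self.time[:n] != 0.0):
            raise ValueError("tips must be contemporaneous at time 0")


def _deme_sizes_at(params: SimulationParams, t: float) -> float:
    """Per-deme N at time t generations before sampling (piecewise constant)."""
    if t < params.expansion_time:
        return params.deme_size
    return params.deme_size / params.expansion_factor


def simulate_genealogy(params: SimulationParams, rng: np.random.Generator) -> Genealogy:
    """Draw one structured-coalescent genealogy under ``params``.

    Event-driven (Gillespie) simulation: competing exponential clocks for
    within-deme coalescence and nearest-neighbor migration, with the
    coalescence rate stepped up at the expansion time (backward in time the
    per-deme size shrinks by ``expansion_factor``).
    """
    n_demes = 1 if params.panmictic else params.n_demes
    n_tips = params.n_samples_total
    per_deme = n_tips // n_demes if not params.panmictic else n_tips

    n_nodes = 2 * n_tips - 1
    time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.zeros((n_tips - 1, 2), dtype=np.int64)
    deme_of_node = np.zeros(n_nodes, dtype=np.int64)

    # active lineages per deme
    if params.panmictic:
        lineages = [list(range(n_tips))]
    else:
        lineages = [
            list(range(d * per_deme, (d + 1) * per_deme)) for d in range(n_demes)
        ]
        deme_of_node[:n_tips] = np.repeat(np.arange(n_demes), per_deme)

    n_neighbors = [
        (1 if n_demes > 1 and (d == 0 or d == n_demes - 1) else (2 if n_demes > 1 else 0))
        for d in range(n_demes)
    ]
    m = 0.0 if params.panmictic else params.mig_prop

    t = 0.0
    expanded = False  # has the backward size reduction been applied yet
    next_node = n_tips
    n_active = n_tips
    k = [len(l) for l in lineages]
    # coal weight per deme: k(k-1); mig weight per deme: k * n_neighbors
    coal_w = [ki * (ki - 1) for ki in k]
    mig_w = [ki * nb for ki, nb in zip(k, n_neighbors)]
    sum_coal = float(sum(coal_w))
    sum_mig = float(sum(mig_w))
    size = _deme_sizes_at(params, 0.0)
    T_exp = params.expansion_time
    rand = rng.random

    while n_active > 1:
        coal_rate = sum_coal / (2.0 * size)
        mig_rate = m * sum_mig
        total = coal_rate + mig_rate
        dt = -np.log(rand()) / total
        if not expanded and t + dt >= T_exp:
            # rates change at the expansion boundary; restart clocks there
            t = T_exp
            size = params.deme_size / params.expansion_factor
            expanded = True
            continue
        t += dt
        if rand() * total < coal_rate:
            # coalescence: choose deme proportional to k(k-1), then a pair
            u = rand() * sum_coal
            acc = 0.0
            for d in range(n_demes):
                acc += coal_w[d]
                if u < acc:
                    break
            ld = lineages[d]
            i = int(rand() * len(ld))
            j = int(rand() * (len(ld) - 1))
            if j >= i:
                j += 1
            a, b = ld[i], ld[j]
            # remove both (higher index first so the swap-pop stays valid)
            if i < j:
                i, j = j, i
            ld[i] = ld[-1]; ld.pop()
            ld[j] = ld[-1]; ld.pop()
            node = next_node
            next_node += 1
            time[node] = t
            deme_of_node[node] = d
            parent[a] = node
            parent[b] = node
            children[node - n_tips, 0] = a
            children[node - n_tips, 1] = b
            ld.append(node)
            n_active -= 1
            ki = len(ld)
            coal_w[d] = ki * (ki - 1)
            mig_w[d] = ki * n_neighbors[d]
            sum_coal = float(sum(coal_w))
            sum_mig = float(sum(mig_w))
        else:
            # migration: deme proportional to k * n_neighbors, uniform lineage,
            # uniform adjacent neighbor
            u = rand() * sum_mig
            acc = 0.0
            for d in range(n_demes):
                acc += mig_w[d]
                if u < acc:
                    break
            ld = lineages[d]
            i = int(rand() * len(ld))
            node = ld[i]
            ld[i] = ld[-1]
            ld.pop()
            if d == 0:
                dst = 1
            elif d == n_demes - 1:
                dst = n_demes - 2
            else:
                dst = d + 1 if rand() < 0.5 else d - 1
            lineages[dst].append(node)
            for dd in (d, dst):
                ki = len(lineages[dd])
                coal_w[dd] = ki * (ki - 1)
                mig_w[dd] = ki * n_neighbors[dd]
            sum_coal = float(sum(coal_w))
            sum_mig = float(sum(mig_w))

    return Genealogy(time=time, parent=parent, children=children,
                     deme=deme_of_node, n_tips=n_tips)


@dataclass
class LabeledAlignment:
    """Haploid sequences plus the sample -> deme assignment.

    ``codes`` holds the alignment as integers 0..3 over the A,C,G,T ordering
    (shape n_samples x locus_length); ``deme_of_sample`` maps each row to a
    deme index; ``lattice_position`` gives each deme's integer coordinate on
    the one-dimensional lattice.
    """

    codes: np.ndarray
    ids: list[str]
    deme_of_sample: np.ndarray
    lattice_position: np.ndarray
    deme_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        if len(self.ids) != self.codes.shape[0]:
            raise ValueError("one id per sequence required")
        if len(self.deme_of_sample) != self.codes.shape[0]:
            raise ValueError("one deme per sequence required")
        if not self.deme_names:
            self.deme_names = [f"deme{d}" for d in range(self.n_demes)]
        counts = np.bincount(self.deme_of_sample, minlength=self.n_demes)
        if np.any(counts == 0):
            raise ValueError("every deme must have at least one sample")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def locus_length(self) -> int:
        return self.codes.shape[1]

    @property
    def n_demes(self) -> int:
        return int(self.deme_of_sample.max()) + 1

    @property
    def sequences(self) -> list[str]:
        lut = np.array(list(BASES))
        return ["".join(lut[row]) for row in self.codes]

    @property
    def deme_of(self) -> dict:
        return dict(zip(self.ids, (int(d) for d in self.deme_of_sample)))

    def samples_in_deme(self, d: int) -> np.ndarray:
        return np.flatnonzero(self.deme_of_sample == d)

    def relabel_demes(self, mapping) -> "LabeledAlignment":
        """Return a copy with demes lumped/renamed by ``mapping[old] -> new``."""
        mapping = np.asarray(mapping)
        new_demes = mapping[self.deme_of_sample]
        n_new = int(new_demes.max()) + 1
        pos = np.zeros(n_new)
        for old, new in enumerate(mapping):
            pos[new] = self.lattice_position[old]
        return LabeledAlignment(
            codes=self.codes, ids=list(self.ids), deme_of_sample=new_demes,
            lattice_position=pos,
        )


def simulate_sequences(
    gen: Genealogy, params: SimulationParams, rng: np.random.Generator
) -> LabeledAlignment:
    """Evolve a locus of length ``params.locus_length`` down the genealogy.

    Each site evolves independently under HKY85 with branch length equal to
    branch duration (generations) times the per-site mutation rate; the root
    sequence is drawn from the stationary base frequencies.
    """
    model = HKYModel(params.tstv_ratio, params.base_freqs)
    L = params.locus_length
    n_nodes = 2 * gen.n_tips - 1
    states = np.empty((n_nodes, L), dtype=np.int8)
    root = gen.root
    states[root] = rng.choice(4, size=L, p=np.asarray(params.base_freqs))
    # parents were created in increasing time order; visit children of
    # internal nodes from the root downward
    for j in range(gen.n_tips - 2, -1, -1):
        node = gen.n_tips + j
        for child in gen.children[j]:
            t = (gen.time[node] - gen.time[child]) * params.mut_rate
            if t == 0.0:
                states[child] = states[node]
                continue
            cum = np.cumsum(model.transition(t), axis=1)
            u = rng.random(L)
            rows = cum[states[node]]
            states[child] = (u[:, None] > rows).sum(axis=1)

    n_demes = params.n_demes
    per_deme = params.sample_size if not params.panmictic else gen.n_tips // n_demes
    # pseudo-deme labels for the panmictic control: blocks in sampling order
    deme_of_sample = np.repeat(np.arange(n_demes), per_deme)
    counter = {}
    ids = []
    for d in deme_of_sample:
        counter[d] = counter.get(d, 0) + 1
        ids.append(f"deme{d}_ind{counter[d]}")
    return LabeledAlignment(
        codes=states[: gen.n_tips].astype(np.uint8),
        ids=ids,
        deme_of_sample=deme_of_sample,
        lattice_position=np.arange(n_demes, dtype=float),
    )


def simulate_dataset(
    params: SimulationParams, rng: Optional[np.random.Generator] = None
) -> LabeledAlignment:
    """Genealogy + sequences in one call (the per-replicate unit of the study)."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    gen = simulate_genealogy(params, rng)
    return simulate_sequences(gen, params, rng)


def replicate_rng(seed: int, set_index: int, replicate: int) -> np.random.Generator:
    """Derived stream for replicate ``replicate`` of parameter set ``set_index``.

    All study randomness flows from one user seed through spawned
    SeedSequences, so any replicate is reproducible in isolation.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(set_index, replicate))
    return np.random.default_rng(ss)


def proportion_variable_sites(aln: LabeledAlignment) -> float:
    """Fraction of alignment columns with more than one observed base."""
    return float(np.mean(aln.codes.min(axis=0) != aln.codes.max(axis=0)))
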