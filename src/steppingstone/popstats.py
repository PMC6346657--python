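"""F-statistics and the Mantel isolation-by-distance test.

Two pairwise differentiation estimators are provided, matching the two used
in the power study:

* ``pairwise_phi_st`` — the AMOVA Phi_ST of Excoffier, Smouse & Quattro,
  computed for each deme pair from the matrix of pairwise sequence
  differences (the molecular-distance analog of F_ST).
* ``pairwise_wc_theta`` — Weir & Cockerham's theta for haploid data, treating
  each distinct haplotype as one allele and summing variance components over
  alleles.

Both are two-population estimators applied to every deme pair; negative
estimates are retained unclipped, since the downstream Mantel correlation is
scale-free and clipping would bias it.  Isolation by distance is then assessed
by a one-tailed Mantel permutation test of the genetic matrix against lattice
distance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import LabeledAlignment, SimulationParams, simulate_dataset


@dataclass
class PairwiseMatrix:
    """Symmetric deme-by-deme matrix of a differentiation statistic."""

    values: np.ndarray
    statistic: str
    monomorphic_pairs: list = field(default_factory=list)

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if not np.allclose(v, v.T):
            raise ValueError("values must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal must be exactly zero")


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def island_model_fst(migrants_per_generation: float, nm_factor: float = 4.0) -> float:
    """Wright's equilibrium island-model expectation F_ST = 1/(1 + c*Nm).

    ``nm_factor`` is the constant c in the denominator; the classical
    (diploid, nuclear) result uses c = 4, which is the convention under which
    100 migrants per generation corresponds to F_ST of about 0.002.  For a
    strictly haploid, uniparentally inherited locus c = 2 applies.
    """
    if migrants_per_generation < 0:
        raise ValueError("migrants_per_generation must be nonnegative")
    return 1.0 / (1.0 + nm_factor * migrants_per_generation)


def _haplotype_table(aln: LabeledAlignment):
    """Unique haplotypes, per-deme count matrix, and hap-hap difference matrix."""
    uniq, inverse = np.unique(aln.codes, axis=0, return_inverse=True)
    n_hap = uniq.shape[0]
    counts = np.zeros((aln.n_demes, n_hap))
    np.add.at(counts, (aln.deme_of_sample, inverse), 1.0)
    if n_hap == 1:
        diffs = np.zeros((1, 1))
    else:
        diffs = (uniq[:, None, :] != uniq[None, :, :]).sum(axis=2).astype(float)
    return counts, diffs


def _sum_pairs(c: np.ndarray, d: np.ndarray) -> float:
    """Sum of d over unordered sample pairs, samples given as haplotype counts."""
    return 0.5 * float(c @ d @ c)


def pairwise_phi_st(aln: LabeledAlignment) -> PairwiseMatrix:
    """AMOVA Phi_ST for every deme pair.

    For each pair, the standard two-level variance-component decomposition of
    the pairwise-difference distance matrix: Phi_ST = sigma2_among /
    (sigma2_among + sigma2_within).  A pair with no sequence variation has no
    variance to partition; it is defined as 0 and flagged.
    """
    if aln.n_demes < 2:
        raise ValueError("need at least 2 demes")
    counts, diffs = _haplotype_table(aln)
    if np.any(counts.sum(axis=1) < 2):
        raise ValueError("need at least 2 samples per deme")
    K = aln.n_demes
    out = np.zeros((K, K))
    mono = []
    for a in range(K):
        for b in range(a + 1, K):
            ca, cb = counts[a], counts[b]
            n1, n2 = ca.sum(), cb.sum()
            n = n1 + n2
            ss_total = _sum_pairs(ca + cb, diffs) / n
            ss_within = _sum_pairs(ca, diffs) / n1 + _sum_pairs(cb, diffs) / n2
            if ss_total == 0.0:
                mono.append((a, b))
                continue
            ss_among = ss_total - ss_within
            ms_within = ss_within / (n - 2)
            n0 = n - (n1 * n1 + n2 * n2) / n
            sigma_among = (ss_among - ms_within) / n0
            out[a, b] = out[b, a] = sigma_among / (sigma_among + ms_within)
    return PairwiseMatrix(out, "phi_st", mono)


def pairwise_wc_theta(aln: LabeledAlignment) -> PairwiseMatrix:
    """Weir & Cockerham's theta for haploid data, for every deme pair.

    Each distinct haplotype is one allele.  Per allele, the among-population
    (MSP) and within-population (MSG) mean squares give variance components
    a = (MSP - MSG)/n_c (among) and b = MSG (within); theta is the ratio of
    summed components, theta = sum a / (sum a + sum b).
    """
    if aln.n_demes < 2:
        raise ValueError("need at least 2 demes")
    counts, _ = _haplotype_table(aln)
    if np.any(counts.sum(axis=1) < 2):
        raise ValueError("need at least 2 samples per deme")
    K = aln.n_demes
    out = np.zeros((K, K))
    mono = []
    r = 2
    for a in range(K):
        for b in range(a + 1, K):
            ca, cb = counts[a], counts[b]
            n1, n2 = ca.sum(), cb.sum()
            n = n1 + n2
            p1, p2 = ca / n1, cb / n2
            pbar = (ca + cb) / n
            keep = pbar > 0
            if np.count_nonzero(keep) < 2:
                mono.append((a, b))
                continue
            nc = (n - (n1 * n1 + n2 * n2) / n) / (r - 1)
            msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1)
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n - r)
            num = (msp - msg)[keep].sum()
            den = (msp + (nc - 1) * msg)[keep].sum()
            if den == 0.0:
                mono.append((a, b))
                continue
            out[a, b] = out[b, a] = num / den
    return PairwiseMatrix(out, "wc_theta", mono)


def lattice_distance_matrix(aln: LabeledAlignment) -> np.ndarray:
    """Geographic distance between demes: |lattice_i - lattice_j|."""
    pos = aln.lattice_position
    return np.abs(pos[:, None] - pos[None, :])


def mantel_test(gen_mat, geo_mat, n_perm: int = 999,
                rng: np.random.Generator | None = None) -> MantelResult:
    """One-tailed (greater) Mantel permutation test.

    r is the Pearson correlation of the off-diagonal upper triangles; the null
    distribution permutes rows and columns of the genetic matrix
    simultaneously, and p = (#{r_perm >= r_obs} + 1)/(n_perm + 1).  For small
    matrices (n! <= n_perm) the permutation distribution is enumerated
    exactly instead, giving p = #{r_perm >= r_obs}/n! with the identity
    permutation included.
    """
    if rng is None:
        rng = np.random.default_rng()
    g = gen_mat.values if isinstance(gen_mat, PairwiseMatrix) else np.asarray(gen_mat)
    h = np.asarray(geo_mat, dtype=float)
    if g.shape != h.shape:
        raise ValueError("matrix dimensions must match")
    n = g.shape[0]
    iu = np.triu_indices(n, k=1)
    gv, hv = g[iu], h[iu]
    if np.std(gv) == 0.0 or np.std(hv) == 0.0:
        warnings.warn("constant matrix: Mantel r undefined, returning p = 1")
        return MantelResult(r=float("nan"), p=1.0, n_perm=n_perm)
    hv_c = hv - hv.mean()
    hv_norm = np.sqrt((hv_c**2).sum())

    def corr(values):  # values: (..., n_pairs)
        vc = values - values.mean(axis=-1, keepdims=True)
        denom = np.sqrt((vc**2).sum(axis=-1)) * hv_norm
        return (vc * hv_c).sum(axis=-1) / denom

    r_obs = float(corr(gv))
    if math.factorial(n) <= n_perm:
        perms = np.array(list(itertools.permutations(range(n))))
        g_perm = g[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]
        r_perm = corr(g_perm)
        p = np.count_nonzero(r_perm >= r_obs - 1e-12) / len(perms)
        return MantelResult(r=r_obs, p=float(p), n_perm=len(perms))
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    g_perm = g[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]
    r_perm = corr(g_perm)
    p = (np.count_nonzero(r_perm >= r_obs) + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm)


def haplotype_diversity(aln: LabeledAlignment) -> float:
    """Nei's h = (n/(n-1)) (1 - sum p_i^2) over haplotype frequencies."""
    n = aln.n_samples
    if n < 2:
        raise ValueError("need at least 2 sequences")
    _, inverse = np.unique(aln.codes, axis=0, return_inverse=True)
    freqs = np.bincount(inverse) / n
    return float(n / (n - 1) * (1.0 - (freqs**2).sum()))


def ibd_power_sweep(
    param_sets: list[SimulationParams],
    n_reps: int = 100,
    alpha: float = 0.05,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Proportion of replicate datasets with a significant Mantel IBD signal.

    For each parameter set and each statistic (Phi_ST, W&C theta), simulates
    ``n_reps`` datasets and reports the fraction whose Mantel p against
    lattice distance falls below ``alpha``.  Tidy table: one row per
    (parameter set, statistic).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for params in param_sets:
        hits = {"phi_st": 0, "wc_theta": 0}
        for _ in range(n_reps):
            child = rng.spawn(1)[0]
            aln = simulate_dataset(params, child)
            geo = lattice_distance_matrix(aln)
            for fn, key in ((pairwise_phi_st, "phi_st"), (pairwise_wc_theta, "wc_theta")):
                res = mantel_test(fn(aln), geo, n_perm=n_perm, rng=child)
                if res.p < alpha:
                    hits[key] += 1
        for key, h in hits.items():
            rows.append(
                {
                    "param_set": params.name or f"Ne={params.deme_size:g},m={params.mig_prop:g}",
                    "statistic": key,
                    "prop_significant": h / n_reps,
                    "n_reps": n_reps,
                    "alpha": alpha,
                }
            )
    return pd.DataFrame(rows)
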