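"""HKY85 nucleotide substitution model.

The HKY rate matrix distinguishes transitions (A<->G, C<->T), weighted by
``kappa``, from transversions, and allows arbitrary stationary base
frequencies.  ``kappa`` here is the instantaneous-rate transition/transversion
parameter of the rate matrix, not the observed substitution-count ratio; with
uniform base frequencies the expected transition:transversion count ratio is
kappa/2 (each state has one transition partner and two transversion partners).

The matrix is normalized so the expected substitution rate at stationarity is
one, so branch lengths are in expected substitutions per site.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _assemble_transition(right, eigvals, left, t):
    out = np.empty((4, 4))
    ew = np.exp(eigvals * t)
    for i in range(4):
        for j in range(4):
            v = 0.0
            for k in range(4):
                v += right[i, k] * ew[k] * left[k, j]
            out[i, j] = v if v > 0.0 else 0.0
    return out


BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: transition partners under the A,C,G,T ordering: A<->G, C<->T
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])


def hky_rate_matrix(tstv_ratio: float, base_freqs) -> np.ndarray:
    """Normalized HKY instantaneous rate matrix Q (rows sum to zero).

    Parameters
    ----------
    tstv_ratio
        kappa, the rate-matrix transition/transversion ratio (> 0).
    base_freqs
        Stationary frequencies (pi_A, pi_C, pi_G, pi_T), summing to 1.
    """
    pi = np.asarray(base_freqs, dtype=float)
    if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-12 or np.any(pi < 0):
        raise ValueError("base_freqs must be 4 nonnegative values summing to 1")
    if tstv_ratio <= 0:
        raise ValueError("tstv_ratio must be positive")
    q = np.tile(pi, (4, 1)).astype(float)
    for a in range(4):
        q[a, _TRANSITION_PARTNER[a]] *= tstv_ratio
        q[a, a] = 0.0
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(pi * np.diag(q)).sum()
    return q / mean_rate


class HKYModel:
    """HKY transition probabilities via a cached spectral decomposition.

    Because HKY is reversible, D^{1/2} Q D^{-1/2} (D = diag(pi)) is symmetric;
    its eigendecomposition is computed once and P(t) = exp(Qt) is assembled per
    branch length with a couple of small matrix products.
    """

    def __init__(self, tstv_ratio: float = 9.0, base_freqs=(0.25, 0.25, 0.25, 0.25)):
        self.kappa = float(tstv_ratio)
        self.pi = np.asarray(base_freqs, dtype=float)
        self.Q = hky_rate_matrix(tstv_ratio, base_freqs)
        sqrt_pi = np.sqrt(self.pi)
        sym = self.Q * sqrt_pi[:, None] / sqrt_pi[None, :]
        sym = 0.5 * (sym + sym.T)  # symmetrize numerical residue
        self._eigvals, v = np.linalg.eigh(sym)
        self._right = v / sqrt_pi[:, None]          # columns: right eigvecs of Q
        self._left = v.T * sqrt_pi[None, :]         # rows: left eigvecs of Q

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for a single branch length t >= 0."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        p = (self._right * np.exp(self._eigvals * t)) @ self._left
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def transition_fast(self, t: float) -> np.ndarray:
        """P(t) without row renormalization (for inner likelihood loops);
        tiny negative eigen-reconstruction residues are clamped to zero."""
        return _assemble_transition(self._right, self._eigvals, self._left, t)

    def transitions(self, ts) -> np.ndarray:
        """Stacked P(t) for an array of branch lengths, shape (n, 4, 4)."""
        ts = np.asarray(ts, dtype=float)
        ew = np.exp(np.multiply.outer(ts, self._eigvals))  # (n, 4)
        p = np.einsum("ij,nj,jk->nik", self._right, ew, self._left)
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=2, keepdims=True)

    def expected_mismatch(self, t: float) -> float:
        """Expected per-site difference between two ends of a branch of length t.

        1 - sum_a pi_a P_aa(t); for two tips separated by total path t use the
        path length (the model is reversible, so the divergence point drops out).
        """
        return float(1.0 - (self.pi * np.diag(self.transition(t))).sum())


def hky_transition(tstv_ratio: float, base_freqs, t: float) -> np.ndarray:
    """Convenience wrapper: one HKY transition matrix P(t) = exp(Qt)."""
    return HKYModel(tstv_ratio, base_freqs).transition(t)
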