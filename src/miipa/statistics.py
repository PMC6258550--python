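"""Weighted, pseudocounted one- and two-site frequencies of a concatenated alignment.

Sequence databases oversample some clades, so near-duplicate concatenated
sequences are down-weighted: a row with m_a neighbors (rows within mean
per-site Hamming distance theta, itself included) receives weight 1/m_a, and
the effective sequence count is M_eff = sum of weights.  Finite samples also
leave many residue pairs unobserved, which would make log-ratio scores
diverge, so frequencies are mixed with a uniform pseudocount of weight
lambda:

    f~_i(a)      = lambda/q   + (1 - lambda) f_i(a)
    f~_ij(a,b)   = lambda/q^2 + (1 - lambda) f_ij(a,b)      (i != j)
    f~_ii(a,b)   = f~_i(a) delta_ab

with q = 21 states.  The raw f's are weighted counts divided by M_eff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .msa_io import ConcatenatedAlignment, N_STATES


def one_hot(X: np.ndarray, q: int = N_STATES) -> np.ndarray:
    """One-hot encode an (N, L) state matrix as (N, L*q) float64.

    The flattened axis is ordered (site, state), matching
    :meth:`miipa.scoring.ScoreModel.as_matrix`.
    """
    X = np.asarray(X)
    n, L = X.shape
    out = np.zeros((n, L * q))
    cols = np.arange(L) * q + X
    out[np.arange(n)[:, None], cols] = 1.0
    return out


def sequence_weights(
    ca: ConcatenatedAlignment | np.ndarray, theta: float
) -> tuple[np.ndarray, float]:
    """Neighbor-based weights 1/m_a and the effective count M_eff.

    m_a counts the rows (including row a itself) whose mean per-site Hamming
    distance to row a is strictly below ``theta``.  theta=0 therefore yields
    unit weights, and a set of identical rows collapses to M_eff = 1.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    rows = ca.rows if isinstance(ca, ConcatenatedAlignment) else np.asarray(ca)
    M = rows.shape[0]
    if M == 1:
        return np.ones(1), 1.0
    d = squareform(pdist(rows, metric="hamming"))
    m = 1 + np.sum((d < theta) & ~np.eye(M, dtype=bool), axis=1)
    weights = 1.0 / m
    return weights, float(weights.sum())


@dataclass
class FrequencyModel:
    """Corrected frequencies of a concatenated alignment.

    ``f1`` is (L, q); ``f2_cross`` holds the inter-protein block
    (L_a, L_b, q, q), i.e. f~_ij for i in the A segment and j in the B
    segment, which is all the pairing score needs.  ``f2_full`` (L, L, q, q),
    including intra-protein and diagonal blocks, is materialized only when
    requested (the mean-field DCA comparator needs it).
    """

    f1: np.ndarray
    f2_cross: np.ndarray
    L_a: int
    lam: float
    theta: float
    weights: np.ndarray
    M_eff: float
    f2_full: np.ndarray | None = None
    q: int = N_STATES

    @property
    def L(self) -> int:
        return self.f1.shape[0]

    @property
    def L_b(self) -> int:
        return self.L - self.L_a


def frequencies(
    ca: ConcatenatedAlignment,
    weights: np.ndarray | None = None,
    lam: float = 0.15,
    theta: float = 0.15,
    pair_scope: str = "cross",
) -> FrequencyModel:
    """Weighted, pseudocounted frequencies of ``ca``.

    If ``weights`` is None they are computed with :func:`sequence_weights` at
    ``theta``.  ``pair_scope`` is "cross" (inter-protein pairs only) or
    "full" (all site pairs, needed by the DCA comparator).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if ca.M == 0:
        raise ValueError("empty concatenated alignment")
    if weights is None:
        weights, m_eff = sequence_weights(ca, theta)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (ca.M,):
            raise ValueError("weights length must equal the CA row count")
        m_eff = float(weights.sum())
    q = N_STATES
    L_a = ca.L_a
    O = one_hot(ca.rows, q)  # (M, L*q)
    Ow = O * weights[:, None]
    raw1 = (Ow.sum(axis=0) / m_eff).reshape(ca.L, q)
    f1 = lam / q + (1.0 - lam) * raw1

    Oa = O[:, : L_a * q]
    Ob = O[:, L_a * q:]
    raw_cross = (Ow[:, : L_a * q].T @ Ob) / m_eff
    raw_cross = raw_cross.reshape(L_a, q, ca.L - L_a, q).transpose(0, 2, 1, 3)
    f2_cross = lam / q**2 + (1.0 - lam) * raw_cross

    f2_full = None
    if pair_scope == "full":
        raw_full = (Ow.T @ O) / m_eff
        raw_full = raw_full.reshape(ca.L, q, ca.L, q).transpose(0, 2, 1, 3)
        f2_full = lam / q**2 + (1.0 - lam) * raw_full
        # diagonal blocks follow the one-site rule f~_ii(a,b) = f~_i(a) delta_ab
        eye = np.eye(q)
        for i in range(ca.L):
            f2_full[i, i] = f1[i][:, None] * eye
    elif pair_scope != "cross":
        raise ValueError("pair_scope must be 'cross' or 'full'")

    return FrequencyModel(
        f1=f1,
        f2_cross=f2_cross,
        L_a=L_a,
        lam=lam,
        theta=theta,
        weights=weights,
        M_eff=m_eff,
        f2_full=f2_full,
    )
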