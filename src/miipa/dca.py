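"""Mean-field direct-coupling-analysis comparator.

The DCA route infers a pairwise maximum-entropy model of the concatenated
alignment in the mean-field approximation: the coupling matrix is minus the
inverse of the connected correlation (covariance) matrix

    C_ij(a, b) = f~_ij(a, b) - f~_i(a) f~_j(b),

built over all sites and a reduced state space of q-1 = 20 states (the gap
state is dropped, which fixes the gauge and makes C invertible once the
pseudocount regularizes it; the comparator conventionally uses theta = 0.3
and lambda = 0.5).  A candidate pair AB is scored by its effective
interaction energy, the negated sum of inter-protein couplings along the
concatenated sequence -- lower energy means a better pair.  Only energy
*differences* within a species matter for assignment, so gauge offsets
cancel and no zero-sum re-gauging is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import N_STATES
from .scoring import ScoreModel, _mi_from_frequencies
from .statistics import FrequencyModel

DCA_THETA = 0.3
DCA_LAMBDA = 0.5


@dataclass
class DcaModel:
    """Inter-protein mean-field couplings e_ij(a, b).

    ``couplings`` has shape (L_a, L_b, q, q); entries involving the gap state
    are zero (reference-state gauge).
    """

    couplings: np.ndarray
    L_a: int
    theta: float
    lam: float
    q: int = N_STATES

    @property
    def L_b(self) -> int:
        return self.couplings.shape[1]


def fit_mf_dca(freqs: FrequencyModel) -> DcaModel:
    """Invert the covariance matrix and keep the inter-protein coupling blocks.

    ``freqs`` must have been built with ``pair_scope="full"`` (the inversion
    involves intra-protein blocks too).
    """
    if freqs.f2_full is None:
        raise ValueError("fit_mf_dca needs frequencies built with pair_scope='full'")
    q = freqs.q
    r = q - 1  # reduced states: gap dropped
    L = freqs.L
    f1 = freqs.f1[:, :r]
    f2 = freqs.f2_full[:, :, :r, :r]
    C = f2 - f1[:, None, :, None] * f1[None, :, None, :]
    Cmat = C.transpose(0, 2, 1, 3).reshape(L * r, L * r)
    try:
        Cinv = np.linalg.inv(Cmat)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(Cmat)
        raise np.linalg.LinAlgError(
            f"covariance matrix is singular despite pseudocount "
            f"(lambda={freqs.lam}); condition number ~ {cond:.3g}"
        ) from exc
    e_red = -Cinv.reshape(L, r, L, r).transpose(0, 2, 1, 3)
    L_a = freqs.L_a
    couplings = np.zeros((L_a, L - L_a, q, q))
    couplings[:, :, :r, :r] = e_red[:L_a, L_a:]
    return DcaModel(couplings=couplings, L_a=L_a, theta=freqs.theta, lam=freqs.lam)


def interaction_energy(seq_a: np.ndarray, seq_b: np.ndarray, model: DcaModel) -> float:
    """Effective interaction energy of one AB pair (lower = better)."""
    seq_a = np.asarray(seq_a, dtype=int)
    seq_b = np.asarray(seq_b, dtype=int)
    cells = model.couplings[
        np.arange(model.L_a)[:, None], np.arange(model.L_b)[None, :],
        seq_a[:, None], seq_b[None, :],
    ]
    return float(-cells.sum())


def coupling_frobenius_norms(model: DcaModel) -> np.ndarray:
    """Frobenius norm of each (q-1)x(q-1) inter-protein coupling block."""
    r = model.q - 1
    return np.sqrt((model.couplings[:, :, :r, :r] ** 2).sum(axis=(2, 3)))


def score_model_from_dca(
    model: DcaModel, freqs: FrequencyModel, mask: np.ndarray | None = None
) -> ScoreModel:
    """Wrap couplings as a ScoreModel so the pairing loop can maximize -energy.

    The table stores +e_ij(a, b): maximizing its sum over site pairs is
    minimizing the interaction energy.  The MI slot is filled from the same
    frequencies so spectra remain available in DCA mode.
    """
    fa = freqs.f1[: freqs.L_a]
    fb = freqs.f1[freqs.L_a:]
    mi = _mi_from_frequencies(freqs.f2_cross, fa, fb)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
    return ScoreModel(mode="dca", table=model.couplings, mi=mi, mask=mask)
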