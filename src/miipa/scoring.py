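"""Score tables over inter-protein site pairs and pair/assignment scores.

The central object is a per-(site pair, state pair) table built from the
corrected frequencies of the current concatenated alignment.  For the default
pointwise-mutual-information mode,

    PMI_ij(a, b) = log[ f~_ij(a, b) / (f~_i(a) f~_j(b)) ]

for every inter-protein site pair (i in family A, j in family B).  A
candidate protein pair AB is scored by summing the table over all unmasked
inter-protein site pairs along its concatenated sequence (S_AB), and a whole
assignment X is scored by the mean S_X of its pair scores.  For a large,
self-consistent alignment S_X converges to the sum over site pairs of the
mutual information

    MI_ij = sum_ab f~_ij(a, b) PMI_ij(a, b),

so maximizing S_X approximately maximizes the pairwise MI between the two
family alignments.  Alternative tables: the normalized PMI
(-PMI/log f~_ij) and the covariance f~_ij - f~_i f~_j.  Natural logarithms
throughout; scores are in nats.

Pairwise MI *estimation* (as opposed to score tables for pairing) uses raw
frequencies without weights or pseudocounts, and optionally a finite-size
bias correction that extrapolates subsampled estimates to 1/M -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import ConcatenatedAlignment, N_STATES
from .statistics import FrequencyModel, one_hot

MODES = ("pmi", "npmi", "cov", "dca")


@dataclass
class ScoreModel:
    """Inter-protein score table plus per-site-pair mutual information.

    ``table`` has shape (L_a, L_b, q, q); ``mi`` has shape (L_a, L_b).
    ``mask`` is an optional boolean (L_a, L_b) array marking site pairs whose
    contributions are suppressed (e.g. structural contacts); masked pairs
    contribute exactly zero to every pair score.
    """

    mode: str
    table: np.ndarray
    mi: np.ndarray
    mask: np.ndarray | None = None
    q: int = N_STATES

    @property
    def L_a(self) -> int:
        return self.table.shape[0]

    @property
    def L_b(self) -> int:
        return self.table.shape[1]

    def masked_table(self) -> np.ndarray:
        if self.mask is None:
            return self.table
        out = self.table.copy()
        out[self.mask] = 0.0
        return out

    def as_matrix(self) -> np.ndarray:
        """Masked table as a ((L_a*q), (L_b*q)) matrix, (site, state) flattened.

        With one-hot encoded sequences x_A, x_B this gives
        S_AB = x_A @ as_matrix() @ x_B, the workhorse of bulk scoring.
        """
        t = self.masked_table()
        return t.transpose(0, 2, 1, 3).reshape(self.L_a * self.q, self.L_b * self.q)


def _mi_from_frequencies(f2: np.ndarray, fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    """MI_ij from joint (L_a, L_b, q, q) and marginals, 0 log 0 := 0."""
    prod = fa[:, None, :, None] * fb[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = f2 * np.log(f2 / prod)
    term = np.where(f2 > 0.0, term, 0.0)
    return term.sum(axis=(2, 3))


def build_score_model(
    freqs: FrequencyModel,
    mode: str = "pmi",
    mask: np.ndarray | None = None,
    on_unobserved: str = "raise",
) -> ScoreModel:
    """Build the score table for ``mode`` from corrected frequencies.

    With a pseudocount (lambda > 0) every joint frequency is positive and the
    log-ratio modes are safe.  At lambda = 0, unobserved state pairs have
    f~_ij = 0; by default this raises (naming the offending cell), since the
    corresponding PMI diverges.  ``on_unobserved="neginf"`` instead stores
    -inf there, which is valid whenever only observed cells will ever be
    looked up (e.g. scoring the very alignment the model was built from).
    """
    if mode not in ("pmi", "npmi", "cov"):
        raise ValueError(f"mode must be one of pmi/npmi/cov, got {mode!r}")
    f2 = freqs.f2_cross
    fa = freqs.f1[: freqs.L_a]
    fb = freqs.f1[freqs.L_a:]
    prod = fa[:, None, :, None] * fb[None, :, None, :]

    if mode in ("pmi", "npmi"):
        zero = f2 == 0.0
        if zero.any():
            if on_unobserved == "raise":
                i, j, a, b = (int(x[0]) for x in np.nonzero(zero))
                raise ValueError(
                    "zero joint frequency with lambda=0 at site pair "
                    f"(i={i + 1}, j={j + 1}), state pair (alpha={a + 1}, "
                    f"beta={b + 1}); use a pseudocount or on_unobserved='neginf'"
                )
            if on_unobserved != "neginf":
                raise ValueError("on_unobserved must be 'raise' or 'neginf'")
        with np.errstate(divide="ignore", invalid="ignore"):
            pmi = np.log(f2 / prod)
        pmi = np.where(zero, -np.inf, pmi) if zero.any() else pmi
        if mode == "pmi":
            table = pmi
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                table = -pmi / np.log(f2)
            # f~_ij = 1 (a single repeated row) gives 0/0; PMI is 0 there
            table = np.where(f2 == 1.0, 0.0, table)
    else:  # cov
        table = f2 - prod

    mi = _mi_from_frequencies(f2, fa, fb)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != mi.shape:
            raise ValueError(f"mask shape {mask.shape} != (L_a, L_b) {mi.shape}")
    return ScoreModel(mode=mode, table=table, mi=mi, mask=mask)


def pair_score(seq_a: np.ndarray, seq_b: np.ndarray, sm: ScoreModel) -> float:
    """S_AB: sum of the table over all unmasked inter-protein site pairs."""
    seq_a = np.asarray(seq_a)
    seq_b = np.asarray(seq_b)
    if seq_a.size != sm.L_a or seq_b.size != sm.L_b:
        raise ValueError("sequence lengths do not match the score model")
    cells = sm.table[
        np.arange(sm.L_a)[:, None], np.arange(sm.L_b)[None, :],
        seq_a[:, None].astype(int), seq_b[None, :].astype(int),
    ]
    if sm.mask is not None:
        cells = np.where(sm.mask, 0.0, cells)
    return float(cells.sum())


def assignment_score(ca: ConcatenatedAlignment, sm: ScoreModel) -> float:
    """S_X: mean pair score over the pairs of an assignment.

    Cells are gathered (not contracted through a matrix product) so that
    -inf entries for never-looked-up unobserved state pairs stay inert.
    """
    if ca.M == 0:
        raise ValueError("empty assignment")
    A = ca.rows[:, : ca.L_a].astype(int)
    B = ca.rows[:, ca.L_a:].astype(int)
    ii = np.arange(sm.L_a)[None, :, None]
    jj = np.arange(sm.L_b)[None, None, :]
    cells = sm.table[ii, jj, A[:, :, None], B[:, None, :]]
    if sm.mask is not None:
        cells = np.where(sm.mask[None, :, :], 0.0, cells)
    return float(cells.sum(axis=(1, 2)).mean())


# ---------------------------------------------------------------------------
# Pairwise MI estimation
# ---------------------------------------------------------------------------

def _naive_pairwise_mi(rows: np.ndarray, L_a: int, q: int = N_STATES) -> float:
    M = rows.shape[0]
    O = one_hot(rows, q)
    f1 = (O.sum(axis=0) / M).reshape(rows.shape[1], q)
    cross = (O[:, : L_a * q].T @ O[:, L_a * q:]) / M
    f2 = cross.reshape(L_a, q, rows.shape[1] - L_a, q).transpose(0, 2, 1, 3)
    return float(_mi_from_frequencies(f2, f1[:L_a], f1[L_a:]).sum())


def pairwise_mi(
    ca: ConcatenatedAlignment,
    correction: str = "none",
    degree: int = 3,
    n_sizes: int = 10,
    n_draws: int = 3,
    rng: int | np.random.Generator | None = None,
) -> float:
    """Pairwise MI: the sum of MI_ij over all inter-protein site pairs.

    Uses raw empirical frequencies (no sequence weighting, no pseudocount).
    The naive plug-in estimate carries a positive finite-size bias of leading
    order K/(2M) per site pair; ``correction="fit"`` removes it by
    subsampling the alignment at ``n_sizes`` sizes, fitting a polynomial of
    ``degree`` in 1/M to the estimates, and returning the intercept.  The fit
    is refused for M < 1000, where subleading terms make it unreliable.
    ``correction="nsb"`` is a recognized name for the Bayesian entropy
    estimator but is not implemented here.
    """
    if ca.M == 0:
        raise ValueError("empty concatenated alignment")
    if correction == "none":
        return _naive_pairwise_mi(ca.rows, ca.L_a)
    if correction == "nsb":
        raise NotImplementedError("NSB entropy correction is a hook, not implemented")
    if correction != "fit":
        raise ValueError("correction must be 'none', 'fit' or 'nsb'")
    M = ca.M
    if M < 1000:
        raise ValueError(
            f"correction='fit' needs M >= 1000 (got {M}): polynomial fits in "
            "1/M become unreliable for smaller datasets"
        )
    gen = np.random.default_rng(rng)
    # sizes chosen so 1/M is evenly spaced on the fit axis, from M down to M/3
    inv = np.linspace(1.0 / M, 3.0 / M, n_sizes)
    sizes = np.unique(np.round(1.0 / inv).astype(int))[::-1]
    xs: list[float] = []
    ys: list[float] = []
    for size in sizes:
        reps = 1 if size == M else n_draws
        vals = []
        for _ in range(reps):
            idx = gen.choice(M, size=size, replace=False) if size < M else np.arange(M)
            vals.append(_naive_pairwise_mi(ca.rows[idx], ca.L_a))
        xs.append(1.0 / size)
        ys.append(float(np.mean(vals)))
    coeffs = np.polyfit(xs, ys, deg=degree)
    return float(coeffs[-1])
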