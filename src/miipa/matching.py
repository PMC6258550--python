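"""Within-species one-to-one assignment and per-pair confidence scores.

Each species contributes a square matrix of pairing scores S[a, b] over its
A and B paralogs.  The biologically meaningful assignment (one-to-one
specific interactions) is the permutation maximizing the total score, solved
exactly with the Hungarian algorithm; a greedy alternative (repeatedly take
the best remaining cell and delete its row and column) is provided because
the DCA-based variant of the pipeline traditionally uses it.

The confidence of an assigned pair is Delta-S: the optimal total minus the
best total achievable when that pair is forbidden.  It is non-negative for
the exact solver and invariant under adding a constant to the whole matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class SpeciesScoreMatrix:
    """Square score matrix for one species (rows = A ids, cols = B ids)."""

    species: str
    row_ids: list[str]
    col_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        m = len(self.row_ids)
        if self.S.shape != (m, m) or len(self.col_ids) != m:
            raise ValueError("score matrix must be square with matching id lists")

    @property
    def m(self) -> int:
        return len(self.row_ids)


@dataclass
class Assignment:
    """A permutation pairing plus its total score and per-pair confidences."""

    species: str
    pairs: list[tuple[str, str]]
    perm: np.ndarray  # perm[row] = assigned column
    total_score: float
    pair_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    confidence: dict[tuple[str, str], float] = field(default_factory=dict)


def _check(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if not np.isfinite(S).all():
        raise ValueError("score matrix contains non-finite entries")
    return S


def _tie_perturbation(S: np.ndarray) -> np.ndarray:
    """Infinitesimal bias toward low (row, col) indices, for reproducible ties."""
    m = S.shape[0]
    scale = np.abs(S).max() + 1.0
    idx = np.arange(m, dtype=float)
    pert = idx[:, None] * m + idx[None, :]
    return S - 1e-12 * scale * pert


def hungarian(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximum-total-score permutation (exact), with deterministic tie-breaks."""
    S = _check(S)
    rows, cols = linear_sum_assignment(_tie_perturbation(S), maximize=True)
    perm = np.empty(S.shape[0], dtype=int)
    perm[rows] = cols
    return perm, float(S[np.arange(S.shape[0]), perm].sum())


def greedy(S: np.ndarray) -> tuple[np.ndarray, float]:
    """Greedy permutation: best remaining cell first, row and column removed."""
    S = _check(S)
    work = _tie_perturbation(S).copy()
    m = S.shape[0]
    perm = np.full(m, -1, dtype=int)
    for _ in range(m):
        flat = int(np.argmax(work))  # ties -> lowest flat index = lex (row, col)
        i, j = divmod(flat, m)
        perm[i] = j
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return perm, float(S[np.arange(m), perm].sum())


_SOLVERS = {"hungarian": hungarian, "greedy": greedy}


def _assignment_from_perm(ssm: SpeciesScoreMatrix, perm: np.ndarray, total: float) -> Assignment:
    pairs = [(ssm.row_ids[i], ssm.col_ids[perm[i]]) for i in range(ssm.m)]
    pair_scores = {p: float(ssm.S[i, perm[i]]) for i, p in enumerate(pairs)}
    return Assignment(
        species=ssm.species, pairs=pairs, perm=perm, total_score=total,
        pair_scores=pair_scores,
    )


def optimal_assignment(ssm: SpeciesScoreMatrix) -> Assignment:
    """Exact maximum-total-score assignment for one species."""
    perm, total = hungarian(ssm.S)
    return _assignment_from_perm(ssm, perm, total)


def greedy_assignment(ssm: SpeciesScoreMatrix) -> Assignment:
    """Greedy assignment (best cell first); not guaranteed optimal."""
    perm, total = greedy(ssm.S)
    return _assignment_from_perm(ssm, perm, total)


def confidence_scores(
    ssm: SpeciesScoreMatrix, asg: Assignment, solver: str = "hungarian"
) -> dict[tuple[str, str], float]:
    """Delta-S for each assigned pair: total minus best total with the pair forbidden.

    For a singleton species no alternative assignment exists; its pair gets
    +inf (it is unambiguous, so it ranks ahead of everything).  The result is
    also stored on ``asg.confidence``.
    """
    solve = _SOLVERS[solver]
    m = ssm.m
    out: dict[tuple[str, str], float] = {}
    if m == 1:
        out[asg.pairs[0]] = math.inf
    else:
        scale = np.abs(ssm.S).max() + 1.0
        forbidden = -1e9 * scale
        for i, pair in enumerate(asg.pairs):
            S2 = ssm.S.copy()
            S2[i, asg.perm[i]] = forbidden
            _, total2 = solve(S2)
            out[pair] = float(asg.total_score - total2)
    asg.confidence = out
    return out
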