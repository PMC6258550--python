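"""Benchmark statistics for partner-prediction runs.

Covers the true-positive fraction against a gold pairing and its random
within-species baseline (one expected correct pair per species), the
hypergeometric model of predictions shared between two algorithms and the
relative excess E of shared correct predictions, replication fractions
across random-restart replicates (whose bimodality is a signature that two
families really interact), the column-scrambling null that destroys
inter-protein correlations while preserving one-site frequencies, ranked MI
spectra, and candidate-partner ranking for orphan proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .msa_io import PairedAlignment
from .scoring import ScoreModel, pair_score


# ---------------------------------------------------------------------------
# TP fraction and the random baseline
# ---------------------------------------------------------------------------

def tp_fraction(
    predicted: Mapping[str, str],
    gold: Mapping[str, str],
    exclude: Iterable[str] = (),
) -> float:
    """Fraction of predicted pairs matching gold, over non-excluded A ids.

    ``exclude`` lists A ids to leave out (typically training pairs, which
    are given, not predicted).
    """
    excl = set(exclude)
    items = [(a, b) for a, b in predicted.items() if a not in excl]
    if not items:
        raise ValueError("no predictions to evaluate")
    return float(np.mean([gold.get(a) == b for a, b in items]))


def expected_random_tp(aln: PairedAlignment) -> float:
    """Expected TP fraction of a uniform random within-species pairing.

    A uniform random permutation has one expected fixed point regardless of
    size, so the expectation is (#species) / M.
    """
    return aln.n_species / aln.M


def random_pairing_tp(
    aln: PairedAlignment, n_draws: int, rng: int | np.random.Generator | None = None
) -> np.ndarray:
    """Monte-Carlo TP fractions of ``n_draws`` random within-species pairings."""
    if not aln.gold:
        raise ValueError("random baseline needs a gold pairing")
    gen = np.random.default_rng(rng)
    index = aln.species_index
    gold = aln.gold
    per_species = []
    for sp in sorted(index):
        a_idx, b_idx = index[sp]
        m = min(len(a_idx), len(b_idx))
        correct = np.array([
            [gold.get(aln.ids_a[a]) == aln.ids_b[b] for b in b_idx[:m]]
            for a in a_idx[:m]
        ])
        per_species.append(correct)
    M = sum(c.shape[0] for c in per_species)
    out = np.empty(n_draws)
    for t in range(n_draws):
        hits = 0
        for correct in per_species:
            perm = gen.permutation(correct.shape[0])
            hits += int(correct[np.arange(correct.shape[0]), perm].sum())
        out[t] = hits / M
    return out


# ---------------------------------------------------------------------------
# Excess shared predictions
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSharedStats:
    """Per-species prediction overlap between two algorithms."""

    species: str
    m: int      # pairs in the species
    p: int      # correct under algorithm 1
    q: int      # correct under algorithm 2
    k_obs: int  # correct under both

    def __post_init__(self) -> None:
        if not 0 <= self.k_obs <= min(self.p, self.q) <= self.m:
            raise ValueError(f"inconsistent shared-prediction counts for {self.species}")

    @property
    def k_expected(self) -> float:
        """Hypergeometric independence expectation p*q/m."""
        return self.p * self.q / self.m


def shared_prediction_stats(
    pred1: Mapping[str, str],
    pred2: Mapping[str, str],
    gold: Mapping[str, str],
    species_of: Mapping[str, str],
) -> list[SpeciesSharedStats]:
    """Build per-species overlap counts from two prediction maps and gold."""
    by_species: dict[str, list[str]] = {}
    for a in pred1:
        by_species.setdefault(species_of[a], []).append(a)
    out = []
    for sp in sorted(by_species):
        ids = by_species[sp]
        c1 = [gold.get(a) == pred1.get(a) for a in ids]
        c2 = [gold.get(a) == pred2.get(a) for a in ids]
        out.append(SpeciesSharedStats(
            species=sp, m=len(ids), p=int(sum(c1)), q=int(sum(c2)),
            k_obs=int(sum(a and b for a, b in zip(c1, c2))),
        ))
    return out


def excess_shared(stats: Sequence[SpeciesSharedStats]) -> float:
    """Relative excess E of shared correct predictions.

    E = sum_i (k_obs,i - <k_i>) / sum_i (min(p_i, q_i) - <k_i>) with
    <k_i> = p_i q_i / m_i.  E = 1 when the shared predictions are maximal
    (e.g. identical predictions); E ~ 0 for independent algorithms.  Returns
    NaN when the denominator is zero (no room above the null in any species).
    """
    num = sum(s.k_obs - s.k_expected for s in stats)
    den = sum(min(s.p, s.q) - s.k_expected for s in stats)
    if den == 0.0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# Replication fractions
# ---------------------------------------------------------------------------

def replication_fractions(results: Sequence) -> pd.DataFrame:
    """Fraction of replicates predicting each candidate pair.

    ``results`` are IpaResult-like objects from replicates differing only in
    their seed.  Returns a DataFrame (species, id_A, id_B, fraction,
    mean_confidence) sorted by decreasing fraction, ties broken by mean
    confidence then (species, id_A).
    """
    if len(results) < 2:
        raise ValueError("replication fractions need at least two replicates")
    counts: dict[tuple[str, str, str], list[float]] = {}
    for res in results:
        for p in res.final_pairs:
            if p.is_training:
                continue
            counts.setdefault((p.species, p.id_a, p.id_b), []).append(p.confidence)
    R = len(results)
    rows = [
        {
            "species": sp, "id_A": a, "id_B": b,
            "fraction": len(confs) / R,
            "mean_confidence": float(np.mean([c for c in confs if np.isfinite(c)]))
            if any(np.isfinite(c) for c in confs) else np.inf,
        }
        for (sp, a, b), confs in counts.items()
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["fraction", "mean_confidence", "species", "id_A"],
        ascending=[False, False, True, True],
    ).reset_index(drop=True)


def top_m_tp(table: pd.DataFrame, m: int, gold: Mapping[str, str]) -> float:
    """TP fraction among the m highest-replication-fraction pairs."""
    top = table.head(m)
    if top.empty:
        raise ValueError("empty replication table")
    return float(np.mean([gold.get(a) == b for a, b in zip(top["id_A"], top["id_B"])]))


def bimodality_mass(table: pd.DataFrame, margin: float = 0.1) -> float:
    """Fraction of replication-fraction mass in [0, margin] U [1-margin, 1].

    A descriptive bimodality summary: genuinely interacting family pairs
    concentrate replication fractions near 0 and 1.
    """
    f = table["fraction"].to_numpy()
    return float(np.mean((f <= margin) | (f >= 1.0 - margin)))


# ---------------------------------------------------------------------------
# Scrambling null and MI spectra
# ---------------------------------------------------------------------------

def scramble_columns(
    aln: PairedAlignment, rng: int | np.random.Generator | None = None
) -> PairedAlignment:
    """Independently permute each alignment column across records.

    One-site frequencies are preserved exactly while all inter-column (and
    hence inter-protein) correlations are destroyed; species labels and the
    gold mapping are untouched.
    """
    gen = np.random.default_rng(rng)
    X_a = aln.X_a.copy()
    X_b = aln.X_b.copy()
    for X in (X_a, X_b):
        for j in range(X.shape[1]):
            X[:, j] = X[gen.permutation(X.shape[0]), j]
    return PairedAlignment(
        ids_a=list(aln.ids_a), species_a=list(aln.species_a), X_a=X_a,
        ids_b=list(aln.ids_b), species_b=list(aln.species_b), X_b=X_b,
        gold=dict(aln.gold) if aln.gold is not None else None,
    )


def mi_spectrum(
    mi: np.ndarray | ScoreModel | Sequence[np.ndarray], top_k: int | None = None
) -> pd.DataFrame:
    """Ranked (i, j, MI) list, optionally averaged over replicates.

    Accepts one (L_a, L_b) MI array, a ScoreModel, or a sequence of arrays
    (averaged elementwise before ranking).  Site indices are reported
    1-based, both family-local (i, j) and on the concatenated coordinate
    (j_concat = L_a + j).
    """
    if isinstance(mi, ScoreModel):
        mats = [mi.mi]
    elif isinstance(mi, np.ndarray):
        mats = [mi]
    else:
        mats = [m.mi if isinstance(m, ScoreModel) else np.asarray(m) for m in mi]
    mean = np.mean(mats, axis=0)
    L_a, L_b = mean.shape
    ii, jj = np.meshgrid(np.arange(L_a), np.arange(L_b), indexing="ij")
    df = pd.DataFrame({
        "i": ii.ravel() + 1,
        "j": jj.ravel() + 1,
        "j_concat": jj.ravel() + 1 + L_a,
        "mi": mean.ravel(),
    })
    df = df.sort_values(["mi", "i", "j"], ascending=[False, True, True]).reset_index(drop=True)
    return df.head(top_k) if top_k is not None else df


def rank_candidate_partners(
    seq_a: np.ndarray,
    candidates: Sequence[tuple[str, np.ndarray]],
    sm: ScoreModel,
) -> list[tuple[str, float]]:
    """Rank candidate B partners of one A sequence by decreasing S_AB.

    Used for orphan/crosstalk partner prediction: ``candidates`` are
    (B id, B residues) within the focal species.  Ties keep stable id order.
    """
    scored = [(bid, pair_score(seq_a, row, sm)) for bid, row in candidates]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
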