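"""The iterative pairing algorithm (IPA).

Starting either from a small training set of known pairs or from a purely
random within-species pairing, each iteration (1) estimates a score table
from the current concatenated alignment (CA), (2) scores every candidate
within-species AB pair in the full dataset, (3) solves the one-to-one
assignment in each species and attaches a confidence Delta-S to every
assigned pair, and (4) rebuilds the CA from the globally top-confidence
pairs, growing it by N_increment pairs per iteration.  The loop ends with an
iteration whose CA contains every assigned pair; that iteration's assignment
is the prediction.

The bootstrap works because correct pairs reinforce a coherent signal in the
score table while wrong pairs add incoherent noise, so the high-confidence
pairs entering the CA early are enriched in true partners, which sharpens
the table for the next round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import dca as dca_mod
from .matching import SpeciesScoreMatrix, confidence_scores, greedy_assignment, optimal_assignment
from .msa_io import ConcatenatedAlignment, PairedAlignment, build_ca
from .scoring import MODES, build_score_model
from .statistics import frequencies, one_hot, sequence_weights


@dataclass
class IpaOptions:
    """Tunable parameters of one IPA run.

    ``theta``/``lam``/``assignment`` default to None, meaning mode-dependent
    defaults: theta=0.15, lambda=0.15, Hungarian assignment for the MI-family
    modes; theta=0.3, lambda=0.5, greedy assignment for the DCA comparator.
    ``mask`` is an optional boolean (L_a, L_b) array of site pairs to exclude
    from scoring (e.g. structural contacts).
    """

    mode: str = "mi"
    n_start: int = 0
    n_increment: int = 6
    theta: float | None = None
    lam: float | None = None
    assignment: str | None = None
    seed: int = 0
    mask: np.ndarray | None = None

    def resolved(self) -> "IpaOptions":
        if self.mode not in ("mi",) + MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_increment < 1:
            raise ValueError("n_increment must be >= 1")
        if self.n_start < 0:
            raise ValueError("n_start must be >= 0")
        is_dca = self.mode == "dca"
        return replace(
            self,
            theta=(dca_mod.DCA_THETA if is_dca else 0.15) if self.theta is None else self.theta,
            lam=(dca_mod.DCA_LAMBDA if is_dca else 0.15) if self.lam is None else self.lam,
            assignment=("greedy" if is_dca else "hungarian")
            if self.assignment is None else self.assignment,
        )


@dataclass
class IterationRecord:
    n: int
    ca_size: int
    s_x: float
    tp_fraction: float | None


@dataclass
class PredictedPair:
    species: str
    id_a: str
    id_b: str
    score: float
    confidence: float
    is_training: bool = False


@dataclass
class IpaResult:
    """Final prediction plus the per-iteration trajectory and provenance."""

    final_pairs: list[PredictedPair]
    trajectory: list[IterationRecord]
    options: IpaOptions
    seed: int

    def predicted(self, include_training: bool = False) -> dict[str, str]:
        return {
            p.id_a: p.id_b
            for p in self.final_pairs
            if include_training or not p.is_training
        }


def initialize_ca(
    aln: PairedAlignment, options: IpaOptions, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Return (training pairs, initial non-training CA pairs) as index pairs.

    With ``n_start > 0`` the initial CA is the training set alone: a random
    draw of n_start gold pairs.  Without a training set it is one uniformly
    random within-species pairing covering the whole dataset, which contains
    on average one correct pair per species.
    """
    if options.n_start > 0:
        if not aln.gold:
            raise ValueError("a training set requires a gold pairing")
        gold_items = sorted(aln.gold.items())
        if options.n_start > len(gold_items):
            raise ValueError(
                f"n_start={options.n_start} exceeds the {len(gold_items)} gold pairs"
            )
        pick = rng.choice(len(gold_items), size=options.n_start, replace=False)
        ia, ib = aln.index_a, aln.index_b
        training = [(ia[gold_items[k][0]], ib[gold_items[k][1]]) for k in sorted(pick)]
        return training, []
    ca_pairs: list[tuple[int, int]] = []
    for sp in sorted(aln.species_index):
        a_idx, b_idx = aln.species_index[sp]
        perm = rng.permutation(len(b_idx))
        ca_pairs.extend((int(a), int(b_idx[p])) for a, p in zip(a_idx, perm))
    return [], ca_pairs


def rank_predictions(assignments: list) -> list[PredictedPair]:
    """Rank all assigned pairs of all species by decreasing confidence.

    +inf confidences (singleton species) sort first; ties are broken by
    (species, A id) so the ranking is deterministic.
    """
    preds = [
        PredictedPair(
            species=asg.species, id_a=a, id_b=b,
            score=asg.pair_scores[(a, b)], confidence=asg.confidence[(a, b)],
        )
        for asg in assignments
        for a, b in asg.pairs
    ]
    preds.sort(key=lambda p: (-p.confidence, p.species, p.id_a))
    return preds


def _expected_ca_size(n: int, n_increment: int, n_start: int, m_test: int) -> int:
    if n == 1:
        return n_start if n_start > 0 else m_test
    return n_start + min((n - 1) * n_increment, m_test)


def run_ipa(aln: PairedAlignment, options: IpaOptions) -> IpaResult:
    """Run the full iterative pairing loop on a filtered, balanced alignment."""
    options = options.resolved()
    if not aln.is_balanced():
        raise ValueError("alignment must be balanced (equal A/B counts per species)")
    rng = np.random.default_rng(options.seed)
    training, ca_pairs = initialize_ca(aln, options, rng)
    train_a = {a for a, _ in training}
    train_b = {b for _, b in training}

    # candidate rows/cols per species, training members excluded
    species_cands: list[tuple[str, np.ndarray, np.ndarray]] = []
    for sp in sorted(aln.species_index):
        a_idx, b_idx = aln.species_index[sp]
        a_idx = np.array([i for i in a_idx if i not in train_a], dtype=int)
        b_idx = np.array([i for i in b_idx if i not in train_b], dtype=int)
        if len(a_idx):
            species_cands.append((sp, a_idx, b_idx))
    m_test = sum(len(a) for _, a, _ in species_cands)
    if m_test == 0:
        raise ValueError("nothing to predict: the training set covers the dataset")

    q = 21
    Oa = one_hot(aln.X_a, q)
    Ob = one_hot(aln.X_b, q)
    gold = aln.gold
    trajectory: list[IterationRecord] = []
    n = 1
    final_iteration = False
    while True:
        ca = build_ca(aln, training + ca_pairs)
        weights, _ = sequence_weights(ca, options.theta)
        if options.mode == "dca":
            freqs = frequencies(ca, weights=weights, lam=options.lam,
                               theta=options.theta, pair_scope="full")
            model = dca_mod.fit_mf_dca(freqs)
            sm = dca_mod.score_model_from_dca(model, freqs, mask=options.mask)
        else:
            freqs = frequencies(ca, weights=weights, lam=options.lam, theta=options.theta)
            sm = build_score_model(
                freqs, mode="pmi" if options.mode == "mi" else options.mode,
                mask=options.mask,
            )

        P = Oa @ sm.as_matrix()  # (N_A, L_b * q)
        assignments = []
        for sp, a_idx, b_idx in species_cands:
            S = P[a_idx] @ Ob[b_idx].T
            ssm = SpeciesScoreMatrix(
                species=sp,
                row_ids=[aln.ids_a[i] for i in a_idx],
                col_ids=[aln.ids_b[i] for i in b_idx],
                S=S,
            )
            asg = (optimal_assignment if options.assignment == "hungarian"
                   else greedy_assignment)(ssm)
            confidence_scores(ssm, asg, solver=options.assignment)
            assignments.append(asg)

        ranked = rank_predictions(assignments)
        s_x = float(np.mean([p.score for p in ranked]))
        tp = None
        if gold:
            tp = float(np.mean([gold.get(p.id_a) == p.id_b for p in ranked]))
        trajectory.append(IterationRecord(n=n, ca_size=ca.M, s_x=s_x, tp_fraction=tp))

        if final_iteration:
            break
        ia, ib = aln.index_a, aln.index_b
        next_size = n * options.n_increment
        if next_size >= m_test:
            chosen = ranked
            final_iteration = True
        else:
            chosen = ranked[:next_size]
        ca_pairs = [(ia[p.id_a], ib[p.id_b]) for p in chosen]
        n += 1

    final = [
        PredictedPair(
            species=aln.species_a[a], id_a=aln.ids_a[a], id_b=aln.ids_b[b],
            score=math.nan, confidence=math.inf, is_training=True,
        )
        for a, b in training
    ] + ranked
    return IpaResult(final_pairs=final, trajectory=trajectory,
                     options=options, seed=options.seed)
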