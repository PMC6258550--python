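"""Synthetic paired alignments with a planted one-to-one pairing.

The generator emulates the structure of real two-family benchmark datasets
(e.g. the histidine-kinase / response-regulator interaction domains): species
blocks of a few to a few tens of pairs, alignment widths 64 and 112 by
default, 21 states per site, and a known gold pairing.  Inter-protein
dependence is planted at ``n_coupled`` disjoint site pairs via a copy
mixture: for each true pair and coupled site pair, with probability
``epsilon`` both sites copy a shared latent state drawn from the background
distribution, otherwise both are drawn independently.  All other sites are
iid background.  With a uniform background the column-pair joint is

    p(a, b) = epsilon * delta_ab / q + (1 - epsilon) / q^2,

whose mutual information is available in closed form and serves as the
oracle for scoring tests (epsilon = 1 gives log q, epsilon = 0 gives 0).

The default generator has no phylogeny (pairs are iid given the species
block sizes); an optional duplication knob copies an existing pair with
per-site mutation probability mu, standing in for shared evolutionary
history.  It is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import N_STATES, PairedAlignment


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic paired alignment."""

    n_species: int = 100
    pairs_per_species: int | tuple[int, int] = (2, 10)  # fixed, or uniform inclusive
    L_a: int = 64
    L_b: int = 112
    n_coupled: int = 20
    epsilon: float = 0.9
    background: str = "uniform"  # or "dirichlet" (per-site Dirichlet(1) draws)
    duplication_prob: float = 0.0  # chance a pair is a mutated copy of an earlier pair
    mutation_prob: float = 0.1  # per-site mutation rate for duplicated pairs
    rng_seed: int = 0
    q: int = N_STATES

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.n_coupled > min(self.L_a, self.L_b):
            raise ValueError(
                "n_coupled exceeds min(L_a, L_b); coupled site pairs are disjoint"
            )

    @property
    def coupled_site_pairs(self) -> list[tuple[int, int]]:
        """Planted coupled (A site, B site) pairs: the diagonal (k, k)."""
        return [(k, k) for k in range(self.n_coupled)]


def theoretical_column_mi(spec_or_epsilon: "SyntheticSpec | float", q: int | None = None) -> float:
    """Exact MI of one coupled column pair under the uniform-background mixture.

    Accepts a :class:`SyntheticSpec` (which must use the uniform background)
    or a bare epsilon with ``q`` states.
    """
    if isinstance(spec_or_epsilon, SyntheticSpec):
        if spec_or_epsilon.background != "uniform":
            raise ValueError("closed-form column MI is only kept for the uniform background")
        eps, q = spec_or_epsilon.epsilon, spec_or_epsilon.q
    else:
        eps = float(spec_or_epsilon)
        q = N_STATES if q is None else q
    p_diag = eps / q + (1.0 - eps) / q**2
    p_off = (1.0 - eps) / q**2
    mi = 0.0
    if p_diag > 0:
        mi += q * p_diag * np.log(p_diag * q**2)
    if p_off > 0:
        mi += (q**2 - q) * p_off * np.log(p_off * q**2)
    return float(mi)


def _draw_backgrounds(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if spec.background == "uniform":
        pa = np.full((spec.L_a, spec.q), 1.0 / spec.q)
        pb = np.full((spec.L_b, spec.q), 1.0 / spec.q)
    elif spec.background == "dirichlet":
        pa = rng.dirichlet(np.ones(spec.q), size=spec.L_a)
        pb = rng.dirichlet(np.ones(spec.q), size=spec.L_b)
    else:
        raise ValueError(f"unknown background {spec.background!r}")
    return pa, pb


def _sample_sites(p: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n rows of per-site categorical states for site distributions p."""
    L = p.shape[0]
    u = rng.random((n, L))
    cdf = np.cumsum(p, axis=1)
    return (u[:, :, None] > cdf[None, :, :]).sum(axis=2).astype(np.uint8)


def generate(spec: SyntheticSpec) -> PairedAlignment:
    """Generate a paired alignment with the planted gold pairing attached.

    B records are shuffled within each species so that file order carries no
    information about the pairing.
    """
    rng = np.random.default_rng(spec.rng_seed)
    pa, pb = _draw_backgrounds(spec, rng)
    if isinstance(spec.pairs_per_species, int):
        sizes = np.full(spec.n_species, spec.pairs_per_species)
    else:
        lo, hi = spec.pairs_per_species
        sizes = rng.integers(lo, hi + 1, size=spec.n_species)
    n_total = int(sizes.sum())

    A = _sample_sites(pa, n_total, rng)
    B = _sample_sites(pb, n_total, rng)
    # plant the copy-mixture coupling on the diagonal site pairs
    for i, j in spec.coupled_site_pairs:
        couple = rng.random(n_total) < spec.epsilon
        n_c = int(couple.sum())
        latent = _sample_sites(pa[i:i + 1], n_c, rng).ravel()
        A[couple, i] = latent
        B[couple, j] = latent

    # optional duplication: overwrite some pairs with mutated copies of earlier ones
    if spec.duplication_prob > 0.0:
        offset = 0
        for m in sizes:
            for k in range(1, m):
                if rng.random() < spec.duplication_prob:
                    src = offset + int(rng.integers(k))
                    dst = offset + k
                    A[dst] = A[src].copy()
                    B[dst] = B[src].copy()
                    for X, p in ((A, pa), (B, pb)):
                        mut = rng.random(X.shape[1]) < spec.mutation_prob
                        if mut.any():
                            X[dst, mut] = _sample_sites(p[mut], 1, rng).ravel()
            offset += int(m)

    ids_a: list[str] = []
    ids_b: list[str] = []
    species_a: list[str] = []
    species_b: list[str] = []
    gold: dict[str, str] = {}
    b_order: list[int] = []
    offset = 0
    for s, m in enumerate(sizes):
        sp = f"s{s:04d}"
        for k in range(m):
            ids_a.append(f"A{s:04d}_{k}")
            species_a.append(sp)
            gold[f"A{s:04d}_{k}"] = f"B{s:04d}_{k}"
        shuffle = rng.permutation(m)
        for k in shuffle:
            ids_b.append(f"B{s:04d}_{k}")
            species_b.append(sp)
            b_order.append(offset + int(k))
        offset += int(m)
    return PairedAlignment(
        ids_a=ids_a, species_a=species_a, X_a=A,
        ids_b=ids_b, species_b=species_b, X_b=B[np.array(b_order)],
        gold=gold,
    )
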