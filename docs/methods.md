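# Methods

## Problem and model

Two protein families A and B interact; within each species, several paralogs
of each family coexist, and the task is to decide which A goes with which B.
The only input is a fixed-width multiple sequence alignment per family with a
species label per record. Gaps are treated as a 21st state, so each site
carries a categorical variable with q = 21 states.

The statistical object is the concatenated alignment (CA) of currently
assumed pairs. Its one- and two-site frequencies define, for every
inter-protein site pair (i, j), a pointwise-mutual-information table
PMI_ij(α, β) = log[f̃_ij(α, β) / (f̃_i(α) f̃_j(β))]. A candidate pair is
scored by the sum of PMIs along its concatenated sequence, an assignment by
the mean of its pair scores (S_X). For a large alignment scored against
itself, S_X equals the summed inter-protein mutual information exactly when
no reweighting or pseudocount is applied — an identity the test suite checks
to 1e-10 — so maximizing S_X approximately maximizes the pairwise MI between
the two family alignments. Logarithms are natural; all scores are in nats.

Because only within-species permutations are biologically admissible, the
global maximization is approximated by an iterative loop: estimate the table
from the CA, score all candidate pairs, solve each species' assignment
exactly with the Hungarian algorithm, rank all assigned pairs by the
confidence ΔS_AB (the species' total score minus the best total with that
pair forbidden), and rebuild the CA from the top-ranked pairs, growing it by
N_increment per iteration. Without a training set the initial CA is one
uniform random within-species pairing; its expected fraction of correct
pairs is (#species)/M, one expected fixed point per species.

## Statistics of the CA

Rows are reweighted 1/m_a, where m_a counts rows (including the row itself)
with mean per-site Hamming distance strictly below θ, computed on the
concatenated rows with the gap as an ordinary state; M_eff = Σ 1/m_a. Raw
frequencies are weighted counts divided by M_eff (the standard convention;
the alternative of dividing by M only rescales both one- and two-site
frequencies and was not adopted). The pseudocount mixes in a uniform
distribution: f̃_i = Λ/q + (1−Λ) f_i and f̃_ij = Λ/q² + (1−Λ) f_ij off the
diagonal, with the diagonal blocks tied to the one-site rule
f̃_ii(α, β) = f̃_i(α) δ_αβ. The mixture preserves marginalization exactly
(Σ_β f̃_ij = f̃_i), which the property tests exploit. Frequencies are
recomputed from scratch each iteration; CA membership changes too
irregularly for incremental updates to be worth the complexity.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| θ | 0.15 (MI modes), 0.3 (DCA mode) | neighbor-distance threshold for reweighting, fraction of differing sites |
| Λ | 0.15 (MI modes), 0.5 (DCA mode) | pseudocount weight in [0, 1] |
| N_increment | 6 | pairs added to the CA per iteration; smaller is slower but more accurate |
| N_start | 0 | training pairs (0 = random initialization) |
| solver | Hungarian (MI modes), greedy (DCA mode) | within-species assignment algorithm |

The MI-mode defaults are the empirically best-performing values for this
family of algorithms and the DCA-mode defaults are the conventional
mean-field DCA choices; performance depends only weakly on θ and Λ. Ties in
the assignment are broken toward low (row, column) indices through an
infinitesimal index-based perturbation, and ranking ties by (species, A id),
so runs are bit-reproducible given a seed. Singleton species, where the
single pair has no alternative, receive +inf confidence and enter the CA
first (the standard dataset filter removes such species from benchmarks
precisely because they act as free training pairs).

## Scoring variants

NPMI_ij(α, β) = −PMI_ij(α, β)/log f̃_ij(α, β) and the covariance
C_ij(α, β) = f̃_ij − f̃_i f̃_j are drop-in table replacements. The DCA
comparator infers mean-field couplings e = −C⁻¹ from the covariance matrix
over all sites with the gap state dropped (reference gauge; the pseudocount
at Λ = 0.5 regularizes the inversion) and scores pairs by the effective
interaction energy −Σ e_ij(α_i, β_j); no zero-sum re-gauging is applied
because only within-species energy differences matter for assignment. An
optional site-pair mask (e.g. known structural contacts) zeroes selected
(i, j) contributions in every mode, allowing contact-free pairing tests.

At Λ = 0 unobserved state pairs make the log-ratio diverge;
`build_score_model` refuses by default (naming the cell) and can instead
store −inf when the caller guarantees only observed cells are read, which is
what the S_X ≡ Σ MI identity check needs.

## Pairwise MI estimation

MI *estimation* (as opposed to score tables) uses raw frequencies with no
weights and no pseudocount. The plug-in estimate has a positive finite-size
bias of leading order K/(2M) per site pair with K ≤ (q−1)²; on iid data the
summed bias follows the 1/M law (log-log slope −1), which the acceptance
checks measure. The subsampling correction fits a degree-3 polynomial in
1/M to estimates at 10 subsample sizes (1/M evenly spaced between M and
M/3) and returns the intercept; it is refused below M = 1000, where
subleading terms corrupt the fit. The Bayesian (NSB) entropy estimator is
exposed as a named correction hook but intentionally not implemented.

## Synthetic data

The generator emulates the structure of real paired-alignment benchmarks:
species blocks of configurable size (default 2–10 pairs, uniform), family
widths 64 and 112 by default (mirroring the histidine-kinase / response-
regulator interaction-domain geometry), q = 21, and a recorded gold pairing.
Dependence between true partners is planted at n_coupled disjoint site pairs
(the diagonal (k, k), so the closed-form oracle applies per pair): with
probability ε both sites copy a shared latent state drawn from the
background, else they are independent. The coupled-column joint is
p(α, β) = ε δ_αβ/q + (1−ε)/q², whose MI is computed analytically
(`theoretical_column_mi`: 0 at ε = 0, log q at ε = 1) and used as the
oracle in convergence tests. B records are shuffled within species so file
order carries no pairing information.

What the generator does *not* emulate: phylogeny. Real alignments carry
shared-history correlations on essentially all site pairs, which is part of
why the algorithm bootstraps so well from random initializations on real
data (correct pairs have more sequence neighbors than wrong ones). In the
iid generator, all sites outside the planted set are pure noise. A
consequence we measured directly: with 20 planted pairs at ε = 0.9 among
64×112 = 7168 inter-protein site pairs, the bootstrap stalls near TP ≈ 0.4
— the 7148 signal-free pairs inject more score noise than a 6-pair CA can
average away — while the same coupling among 25×25 = 625 site pairs is
recovered at TP ≈ 0.97–0.99. The recovery benchmarks therefore use the
compact 25+25 geometry; passing them demonstrates correct mechanics of the
full loop, not performance on phylogenetically structured real data. An
optional duplication knob (copy an earlier pair, then mutate each site with
probability μ) creates sequence redundancy as a crude stand-in for shared
history; it is off by default and exercised only in unit tests.

Study conditions used by the test suite and acceptance script, chosen once:

- recovery benchmark: 100 species × 5 pairs, L = 25+25, n_coupled = 20,
  ε = 0.9, N_increment = 6, no training set;
- scrambled-column null on the same data with N_increment = 50 (larger
  steps, since no signal exists to accumulate; this mirrors the replicate
  settings used for interaction-signature scans);
- trend checks (TP non-increasing in N_increment, non-decreasing in M):
  4 pairs/species, L = 25+25, n_coupled = 10, ε = 0.5 — deliberately in the
  transition regime where TP ≈ 0.25–0.35 responds to both knobs — with
  means over 10 seeds and a 2-standard-error noise allowance;
- finite-size bias: iid data, L = 8+8, M ∈ {250, 500, 1000, 2000}.

## Evaluation statistics

TP fraction is the fraction of predicted pairs matching the gold pairing,
computed over non-training pairs. The overlap between two algorithms'
correct predictions is modeled per species by the hypergeometric law
P(p, k, m, q) with expectation ⟨k⟩ = pq/m; the relative excess of shared
predictions E = Σ(k_obs − ⟨k⟩) / Σ(min(p, q) − ⟨k⟩) is 1 for identical
predictions, ~0 for independent ones, and undefined (reported as NaN) when
the denominator vanishes. Replication fractions — how often a candidate
pair is predicted across random-restart replicates — are strongly bimodal
(masses near 0 and 1) when the families genuinely interact and unimodal
near 0 for scrambled data; bimodality is reported descriptively (fraction
of mass in [0, 0.1] ∪ [0.9, 1]) rather than through a formal test. Ranking
all candidate pairs by replication fraction (ties by mean confidence, then
species/id) and keeping the top M typically beats the mean single-replicate
TP — the consensus effect the tests verify on moderate-coupling data.

The column-scrambling null permutes each column independently across all
records, preserving one-site frequencies exactly while destroying
inter-column dependence. One subtlety: a permutation null fixes the column
marginals, so its residual pairwise MI sits one-to-two percent below a
fresh-iid null of the same size (whose marginals fluctuate); the tests
compare the two at the 5% level rather than demanding exact statistical
indistinguishability.

## Numerical choices and degenerate inputs

- Assignment matrices must be finite; forbidden cells in confidence
  computations use a large finite penalty (scale-relative) rather than −inf
  so the solver's optimality guarantees hold.
- θ = 0 yields unit weights ("distance < θ" is strict); a CA of identical
  rows collapses to M_eff = 1.
- Non-standard residue letters (B, J, O, U, X, Z) map to the gap state with
  a logged count; '.' and '-' both read as gaps; parsing is
  case-insensitive.
- When #A ≠ #B in a species, the excess records with the largest file-order
  index are dropped — deterministic, at the cost of ignoring any information
  in the dropped sequences (full injective matching is out of scope).
- Empty CAs, empty predictions, ragged alignments, unparseable headers, and
  oversized training sets raise informative errors.

## Known limitations

- The generator's iid background understates the difficulty gap between
  synthetic and real data in one direction (no phylogenetic confounding)
  and overstates it in another (no broad weak signal to help ignition); see
  above.
- The mean-field DCA comparator inverts a (L·20)² covariance matrix, which
  is memory-hungry for long concatenated sequences; the MI modes never need
  it.
- The subsampling MI correction is unreliable below M = 1000 and is refused
  there; the NSB hook is unimplemented.
- Orphan/crosstalk partner ranking scores candidates with a model trained
  on cognate pairs; it does not attempt to detect whether a protein has any
  partner at all (setting an interaction threshold is left to the user).
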