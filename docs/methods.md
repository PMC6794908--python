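# Methods

## The problem and the model

Coevolutionary analysis of an RNA family alignment recovers directly
interacting nucleotide pairs, but its ranked output mixes genuine
tertiary contacts with spurious couplings. This package combines two
independent signals:

1. **Mean-field direct coupling analysis (mfDCA).** For an alignment
   over the alphabet {A, C, G, U, −} (q = 5), sequences with more than
   50% gaps are removed, the remaining rows are reweighted by redundancy
   (weight 1/k for a sequence with k neighbors at ≥ 80% identity),
   and single/pair frequencies are regularized with a pseudocount
   λ = 0.5 mixed toward the uniform distribution. Couplings come from
   the inverse of the connected-correlation matrix built over q − 1
   states per column (the gap state is the gauge):
   e_ij(A,B) = −(C⁻¹)_ij(A,B). For every pair an isolated two-site
   model P^d_ij(A,B) ∝ exp{e_ij(A,B) + h̃_i(A) + h̃_j(B)} is fitted so
   its marginals reproduce the single-column frequencies, and the pair
   is scored by the direct information
   DI_ij = Σ_AB P^d_ij ln [P^d_ij / (f_i f_j)] (natural log).

2. **A structural contact template learned by a Restricted Boltzmann
   Machine.** Training structures of the target's structural class are
   converted to minimal-heavy-atom distance matrices, resized by
   bilinear interpolation to a fixed 100 × 100 template, thresholded at
   8 Å (strict `<`), and their strict lower triangles flattened into
   4950-bit vectors. A binary-binary RBM with energy
   E(v,h) = −bᵀv − cᵀh − hᵀWv and 100 hidden units is trained on these
   vectors by contrastive divergence (CD-1, learning rate 0.1, 10,000
   epochs by default). Gibbs sampling the trained machine (10,000 steps,
   last 5,000 kept) and averaging the kept samples gives the contact
   frequency template W ∈ [0,1]^{100×100} — the machine's belief about
   the typical contact pattern of the class.

The final score projects W onto the target length L by the same
bilinear convention and reweights elementwise:

    DIRECT(i, j) = DI(i, j) · W(i, j)²

Pairs with |i − j| ≤ 4 are excluded at ranking and evaluation time
(backbone-adjacent nucleotides are trivially in contact); prediction
quality is measured as PPV = |TP| / (|TP| + |FP|) over the top-N ranked
pairs, with breakdowns by sequence separation (short 5–12, medium
13–24, long ≥ 25) and by secondary-structure category (base pair,
stem-loop, loop-loop, intra/inter stem-stem) from a nested dot-bracket
annotation.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| contact cutoff | 8 Å | minimal heavy-atom distance; strict `<`, so exactly 8.0 Å is a non-contact |
| min separation | 4 | |i−j| ≤ 4 excluded from prediction/evaluation; training maps keep the full band (the template should represent the whole map) |
| template size | 100 | fixed RBM input grid; 4950 visible units |
| hidden units | 100 | RBM capacity |
| learning rate / epochs | 0.1 / 10,000 | CD-1 full-batch training (training families are tens of maps) |
| Gibbs total / kept | 10,000 / 5,000 | burn-in then frequency estimation |
| pseudocount λ | 0.5 | frequency regularization; also guarantees an invertible correlation matrix |
| reweighting identity | 0.8 | sequence-redundancy threshold |
| gap filter | 0.5 | strict "more than 50% gaps" row removal; columns are never filtered |
| exponent | 2 | power of W in the reweighting; configurable 1–4 |

## Numerical choices

- **Resizing convention.** Source index i ∈ [1, L] sits at target
  coordinate i·M/L; target samples are bilinear in the source grid with
  clamped edges, and the result is symmetrized by averaging with its
  transpose. The same convention maps training maps into template space
  and the template back to target length (the minimal consistent
  inverse; predictions must be reported in target coordinates). Resizing
  acts on the *distance* matrix; the 8 Å threshold is applied after.
- **Two-site fit.** Damped iterative proportional updates (step 0.5) on
  the pair of field vectors until both marginal constraints hold to
  1e-6 (tests use down to 1e-13); all L(L−1)/2 pairs are fitted as one
  vectorized batch. With zero couplings the fit reduces exactly to the
  product of marginals.
- **DI evaluation** uses `rel_entr`, so zero-support cells contribute
  exactly zero rather than NaN.
- **CD training** uses data + hidden probabilities in the positive
  phase and binary sampled states in the negative phase; weights start
  from a centered Gaussian (scale 0.01), biases at zero; full-batch
  updates. Deterministic given the seed (PCG64 throughout).
- **Gibbs chain initialization.** The trained density over 4950-bit
  vectors is sharply concentrated; a uniformly random start state mixes
  into it far too slowly for any practical chain length. Template
  extraction therefore starts the chain at a training vector. For the
  small enumerable machines used in fidelity checks, random
  initialization is retained.
- **Tie-breaks.** Equal scores rank by (smaller i, then smaller j).
- **Degenerate inputs.** Maps smaller than 2×2, empty alignments,
  all-gap rows, pseudoknotted dot-brackets, and non-binary training
  vectors are rejected with explicit errors rather than coerced.

## What the synthetic generator emulates — and what it does not

`synthetic.make_instance` builds a complete study case: a native
contact map with nested hairpin stems (anti-diagonal bands: each base
pair plus its cross-stack neighbors), square loop-loop tertiary blocks
planted between loop regions, a consistent pseudo-distance matrix
(contacts uniform in [3, 8) Å, non-contacts in (8, 30] Å), a training
family of 20 maps sharing the stems and blocks up to 10% symmetric bit
flips off the stem bands, and a 500-sequence alignment in which chosen
native contacts carry a planted pairwise coupling (strength 3.0,
favoring A-U/G-C/G-U states) while other columns are independent and
near-uniform, with 5% gaps.

This reproduces exactly the two signals the method exploits — a shared
structural template across the family, and direct pair couplings at
true contacts. It does **not** emulate phylogenetic correlation between
sequences, thermodynamically realistic stem/loop statistics,
pseudoknots, non-canonical pair geometry, or alignment errors. Passing
tests therefore demonstrate that the implementation recovers the
signals it models, not that the method attains any particular accuracy
on natural RNA families.

The mismatched-template control regenerates a family from a decoy
layout whose tertiary contact set is verified (essentially) disjoint
from the native map (Jaccard ≤ 0.10); on such families the reweighting
shows no gain, guarding against the template trivially inflating
scores.

## Problem sizes used in the test and reproduction runs

The published defaults (10,000 epochs, 10,000/5,000 Gibbs) are kept as
the library defaults. The seeded comparison suites run the same
pipeline at desk scale as the package's own choice: L = 70 targets,
20-map families, CD-1 for 1,000 epochs, 4,000 Gibbs steps keeping
2,000. At these sizes the template is already strongly enriched on the
family's shared contacts and the comparison is stable across seeds;
the enumeration, fidelity, and analytic checks are exact-scale and use
the stated values (e.g. 10,000/5,000 Gibbs samples on enumerable
machines).

## Design choices where the design was open

- Batch scheme, CD order (k = 1), initialization scale, and the
  stochastic-vs-mean-field negative phase are standard CD practice and
  exposed as arguments.
- The pseudocount (0.5) and reweighting threshold (0.8) follow the
  established mfDCA conventions for covariation analysis.
- Homology exclusion between training and test structures is delegated
  to an explicit user-supplied id list; detecting homology would drag
  in external search tools.
- Pseudoknots are rejected, not silently dropped: the category
  classifier's stem model assumes nesting.
- Modified residues are kept when they carry at least one heavy atom;
  the contact definition needs only heavy-atom geometry.
- Missing residues in crystal structures yield sequentially re-indexed
  maps (the template input must be dense).

## Known limitations

- Mean-field DCA only; pseudo-likelihood couplings are out of scope.
- No average-product correction or Frobenius-norm scoring.
- Single-chain analysis; no RNA-protein or multi-chain complexes.
- The template is a single structural class learned from one family of
  maps; no mixtures of templates.
- L1/L2 regularization of the RBM is not implemented.
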