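"""Mean-field direct coupling analysis for RNA alignments.

Pipeline: gap filtering of sequences, identity-based sequence
reweighting, pseudocounted single/pair frequency estimation, coupling
inference by inversion of the connected-correlation matrix (gauge: gap
state dropped), the isolated two-site model fitted by iterative
proportional updates, and the direct information

    DI_ij = Σ_AB P^d_ij(A,B) ln [ P^d_ij(A,B) / (f_i(A) f_j(B)) ]

where P^d_ij(A,B) ∝ exp{e_ij(A,B) + h̃_i(A) + h̃_j(B)} and the fields
h̃ are chosen so that the marginals of P^d reproduce the single-column
frequencies.

The alphabet is A, C, G, U, gap (q = 5).  Sequences with more than 50%
gaps are removed; columns are never filtered.  DI is computed for every
pair; the |i−j| separation mask is applied at ranking time, not here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr

from .io_formats import MSA

Q = 5  # A, C, G, U, gap
GAP_STATE = Q - 1


@dataclass
class FrequencyModel:
    """Reweighted, pseudocounted column and column-pair frequencies."""

    f_single: np.ndarray  # (L, q)
    f_pair: np.ndarray  # (L, L, q, q)
    sequence_weights: np.ndarray
    n_effective: float
    pseudocount_weight: float

    @property
    def length(self) -> int:
        return self.f_single.shape[0]


@dataclass
class CouplingModel:
    """Pairwise couplings e_ij(A,B) in the gap gauge (gap row/col zero)."""

    e: np.ndarray  # (L, L, q, q); e[i, j] finite, zero for gap states

    @property
    def length(self) -> int:
        return self.e.shape[0]


def preprocess_msa(msa: MSA, max_gap_fraction: float = 0.5) -> MSA:
    """Drop sequences whose gap fraction exceeds ``max_gap_fraction``.

    The boundary is strict: a row with exactly 50% gaps is retained.
    """
    enc = msa.encode()
    gap_frac = (enc == GAP_STATE).mean(axis=1)
    keep = gap_frac <= max_gap_fraction
    if not keep.any():
        raise ValueError("empty after filtering")
    return MSA(
        [i for i, k in zip(msa.ids, keep) if k],
        [r for r, k in zip(msa.rows, keep) if k],
    )


def sequence_weights(msa: MSA, identity_threshold: float = 0.8) -> np.ndarray:
    """Standard mfDCA redundancy reweighting.

    The weight of a sequence is 1 over the number of sequences (itself
    included) whose fractional identity to it is at least the threshold.
    """
    enc = msa.encode()
    n = enc.shape[0]
    counts = np.zeros(n)
    chunk = max(1, int(2e7) // max(1, n * enc.shape[1]))
    for s in range(0, n, chunk):
        ident = (enc[s : s + chunk, None, :] == enc[None, :, :]).mean(axis=2)
        counts[s : s + chunk] = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / counts


def frequencies(
    msa: MSA,
    weights: np.ndarray | None = None,
    pseudocount_weight: float = 0.5,
) -> FrequencyModel:
    """Weighted empirical frequencies mixed with the uniform distribution.

    f_i = (1−λ) f̂_i + λ/q ;  f_ij = (1−λ) f̂_ij + λ/q² for i ≠ j.
    The self-pair block stays diagonal, f_ii(A,B) = δ_AB f_i(A), so joint
    marginals match the singles exactly.
    """
    lam = pseudocount_weight
    if not 0.0 <= lam < 1.0:
        raise ValueError("invalid pseudocount")
    enc = msa.encode()
    n, L = enc.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError("weights do not match rows")
    meff = weights.sum()

    onehot = np.zeros((n, L, Q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], enc] = 1.0

    f1_emp = np.einsum("s,sia->ia", weights, onehot) / meff
    f2_emp = np.einsum("sia,sjb->ijab", weights[:, None, None] * onehot, onehot) / meff

    f1 = (1 - lam) * f1_emp + lam / Q
    f2 = (1 - lam) * f2_emp + lam / Q**2
    # self-pair blocks: diagonal, consistent with f1
    for i in range(L):
        f2[i, i] = np.diag(f1[i])
    return FrequencyModel(f1, f2, weights, float(meff), lam)


def mean_field_couplings(fm: FrequencyModel) -> CouplingModel:
    """Couplings from the inverse connected-correlation matrix.

    C is built over q−1 states per column (the gap state is the gauge and
    is dropped); e_ij(A,B) = −(C⁻¹)_ij(A,B), zero-padded back to q states.
    """
    L, q = fm.length, Q
    qr = q - 1
    C = (
        fm.f_pair[:, :, :qr, :qr]
        - fm.f_single[:, None, :qr, None] * fm.f_single[None, :, None, :qr]
    )
    Cmat = C.transpose(0, 2, 1, 3).reshape(L * qr, L * qr)
    try:
        inv = np.linalg.inv(Cmat)
    except np.linalg.LinAlgError as err:
        raise ValueError("pseudocount too small / alignment degenerate") from err
    e = np.zeros((L, L, q, q))
    e[:, :, :qr, :qr] = -inv.reshape(L, qr, L, qr).transpose(0, 2, 1, 3)
    return CouplingModel(e)


def _fit_pairs(
    expE: np.ndarray,
    fi: np.ndarray,
    fj: np.ndarray,
    tol: float,
    max_iter: int,
):
    """Fit two-site fields for a batch of pairs by iterative proportional
    updates.

    expE: (P, q, q) = exp(e_ij); fi, fj: (P, q) target marginals.
    Returns the normalized joints P^d (P, q, q).
    """
    P = expE.shape[0]
    mu1 = np.full((P, Q), 1.0 / Q)
    mu2 = np.full((P, Q), 1.0 / Q)
    for _ in range(max_iter):
        new1 = fi / np.einsum("pab,pb->pa", expE, mu2)
        new1 /= new1.sum(axis=1, keepdims=True)
        mu1 = 0.5 * mu1 + 0.5 * new1
        new2 = fj / np.einsum("pab,pa->pb", expE, mu1)
        new2 /= new2.sum(axis=1, keepdims=True)
        mu2 = 0.5 * mu2 + 0.5 * new2
        joint = expE * mu1[:, :, None] * mu2[:, None, :]
        joint /= joint.sum(axis=(1, 2), keepdims=True)
        err_i = np.abs(joint.sum(axis=2) - fi).max()
        err_j = np.abs(joint.sum(axis=1) - fj).max()
        if max(err_i, err_j) < tol:
            return joint
    raise RuntimeError("two-site fit failed to converge")


def fit_two_site(
    cm: CouplingModel,
    fm: FrequencyModel,
    i: int,
    j: int,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Isolated two-site joint P^d_ij for columns i, j (0-based).

    The fields h̃_i, h̃_j are fitted so the joint's marginals equal
    f_i and f_j within ``tol``.
    """
    expE = np.exp(cm.e[i, j])[None]
    return _fit_pairs(expE, fm.f_single[i][None], fm.f_single[j][None], tol, max_iter)[0]


def direct_information(
    fm: FrequencyModel,
    cm: CouplingModel,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Symmetric L×L matrix of DI scores (natural log), zero diagonal."""
    L = fm.length
    iu, ju = np.triu_indices(L, k=1)
    expE = np.exp(cm.e[iu, ju])
    joints = _fit_pairs(expE, fm.f_single[iu], fm.f_single[ju], tol, max_iter)
    prod = fm.f_single[iu][:, :, None] * fm.f_single[ju][:, None, :]
    di_pairs = rel_entr(joints, prod).sum(axis=(1, 2))
    di = np.zeros((L, L))
    di[iu, ju] = di_pairs
    return di + di.T


def di_from_msa(
    msa: MSA,
    max_gap_fraction: float = 0.5,
    identity_threshold: float = 0.8,
    pseudocount_weight: float = 0.5,
) -> np.ndarray:
    """Convenience wrapper: full mfDCA from an alignment to a DI matrix."""
    filtered = preprocess_msa(msa, max_gap_fraction)
    w = sequence_weights(filtered, identity_threshold)
    fm = frequencies(filtered, w, pseudocount_weight)
    cm = mean_field_couplings(fm)
    return direct_information(fm, cm)
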