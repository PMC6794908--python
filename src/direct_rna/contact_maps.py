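"""Distance matrices, binary contact maps, template-size resizing,
lower-triangle flattening, and contact classification.

Conventions used throughout: a contact is a nucleotide pair whose minimal
heavy-atom distance is strictly below the cutoff (8 Å default); tertiary
contacts are additionally separated by more than ``min_separation`` (4)
positions in sequence.  Training maps for the template model keep the
near-diagonal band (min_separation=0); the separation filter belongs to
prediction and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import SecondaryStructure, StructureChain

TEMPLATE_SIZE = 100
CONTACT_CUTOFF = 8.0
MIN_SEPARATION = 4

RANGE_EXCLUDED = "excluded"
RANGE_SHORT = "short"
RANGE_MEDIUM = "medium"
RANGE_LONG = "long"

CAT_BASE_PAIR = "base_pair"
CAT_STEM_LOOP = "stem_loop"
CAT_LOOP_LOOP = "loop_loop"
CAT_INTRA_STEM = "intra_stem_stem"
CAT_INTER_STEM = "inter_stem_stem"
CATEGORIES = (CAT_BASE_PAIR, CAT_STEM_LOOP, CAT_LOOP_LOOP, CAT_INTRA_STEM, CAT_INTER_STEM)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of minimal heavy-atom distances (Å)."""

    values: np.ndarray
    labels: list[int] | None = None

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class ContactMap:
    values: np.ndarray  # (L, L) uint8, symmetric, zero diagonal
    cutoff: float = CONTACT_CUTOFF
    min_separation: int = MIN_SEPARATION

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def n_contacts(self) -> int:
        """Number of distinct contact pairs (i < j)."""
        return int(self.values.sum()) // 2


def distance_matrix(chain: StructureChain) -> DistanceMatrix:
    """Minimal heavy-atom distance between every residue pair.

    Entry (i, j) is the minimum over all heavy-atom pairs, one atom from
    each nucleotide.
    """
    for res in chain.residues:
        if res.n_atoms == 0:
            raise ValueError(f"empty residue: {res.number}")
    coords = np.vstack([r.coords for r in chain.residues])
    owner = np.concatenate(
        [np.full(r.n_atoms, k, dtype=int) for k, r in enumerate(chain.residues)]
    )
    diff = coords[:, None, :] - coords[None, :, :]
    atom_d = np.sqrt((diff**2).sum(-1))
    L = len(chain.residues)
    values = np.full((L, L), np.inf)
    np.minimum.at(values, (owner[:, None], owner[None, :]), atom_d)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, labels=[r.number for r in chain.residues])


def contact_map(
    d: DistanceMatrix | np.ndarray,
    cutoff: float = CONTACT_CUTOFF,
    min_separation: int = MIN_SEPARATION,
) -> ContactMap:
    """Threshold a distance matrix: contact iff d < cutoff and |i-j| > min_separation."""
    if cutoff <= 0:
        raise ValueError("invalid cutoff")
    values = d.values if isinstance(d, DistanceMatrix) else np.asarray(d)
    L = values.shape[0]
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    out = ((values < cutoff) & (sep > min_separation)).astype(np.uint8)
    return ContactMap(out, cutoff=cutoff, min_separation=min_separation)


def resize_distance_matrix(
    d: DistanceMatrix | np.ndarray, target_size: int = TEMPLATE_SIZE
) -> DistanceMatrix:
    """Bilinear resize of a distance matrix to target_size × target_size.

    Continuous-index convention: source index i ∈ [1, L] sits at target
    coordinate i·M/L, so target index a samples the source at a·L/M
    (clamped to [1, L]).  The output is symmetrized by averaging with its
    transpose.  Works for both down- and up-scaling.
    """
    values = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    L = values.shape[0]
    M = int(target_size)
    if L < 2 or M < 2:
        raise ValueError("degenerate matrix")
    # fractional source coordinates (0-based) for each target index
    x = (np.arange(1, M + 1) * L / M) - 1.0
    x = np.clip(x, 0.0, L - 1.0)
    i0 = np.floor(x).astype(int)
    i1 = np.minimum(i0 + 1, L - 1)
    frac = x - i0
    # separable bilinear: interpolate rows, then columns
    rows = values[i0, :] * (1 - frac)[:, None] + values[i1, :] * frac[:, None]
    out = rows[:, i0] * (1 - frac)[None, :] + rows[:, i1] * frac[None, :]
    out = 0.5 * (out + out.T)
    return DistanceMatrix(out)


def flatten(c: ContactMap | np.ndarray) -> np.ndarray:
    """Strict lower triangle, row-major, as a 1-D 0/1 array.

    For an M×M map the vector has M(M−1)/2 entries (4950 for M=100).
    """
    values = c.values if isinstance(c, ContactMap) else np.asarray(c)
    return values[np.tril_indices(values.shape[0], k=-1)].astype(np.uint8)


def unflatten(v: np.ndarray, size: int) -> ContactMap:
    """Mirror a flattened lower triangle back into a symmetric map."""
    v = np.asarray(v)
    expected = size * (size - 1) // 2
    if v.shape != (expected,):
        raise ValueError(f"size mismatch: expected {expected} entries, got {v.shape}")
    out = np.zeros((size, size), dtype=np.asarray(v).dtype)
    out[np.tril_indices(size, k=-1)] = v
    out = out + out.T
    return ContactMap(out.astype(np.uint8) if v.dtype.kind in "iub" else out)


def unflatten_values(v: np.ndarray, size: int) -> np.ndarray:
    """Like :func:`unflatten` but for real-valued vectors (frequencies)."""
    v = np.asarray(v, dtype=float)
    expected = size * (size - 1) // 2
    if v.shape != (expected,):
        raise ValueError("size mismatch")
    out = np.zeros((size, size))
    out[np.tril_indices(size, k=-1)] = v
    return out + out.T


def classify_range(i: int, j: int) -> str:
    """Sequence-separation class: short 5–12, medium 13–24, long ≥25.

    Pairs separated by four or fewer positions are excluded from
    tertiary-contact analysis.
    """
    if i == j:
        raise ValueError("self pair")
    s = abs(i - j)
    if s <= MIN_SEPARATION:
        return RANGE_EXCLUDED
    if s <= 12:
        return RANGE_SHORT
    if s <= 24:
        return RANGE_MEDIUM
    return RANGE_LONG


def classify_category(i: int, j: int, ss: SecondaryStructure) -> str:
    """Secondary-structure category of a contact (1-based positions).

    Watson-Crick pairs are base_pair (checked first so they are never
    counted as intra-stem); otherwise the stem/loop membership of the two
    positions decides: loop_loop, stem_loop, intra_stem_stem (same stem)
    or inter_stem_stem (different stems).
    """
    L = ss.length
    if not (1 <= i <= L and 1 <= j <= L):
        raise IndexError("index out of range")
    a, b = min(i, j), max(i, j)
    if (a, b) in set(ss.pairs):
        return CAT_BASE_PAIR
    si, sj = ss.stem_id[a - 1], ss.stem_id[b - 1]
    if si < 0 and sj < 0:
        return CAT_LOOP_LOOP
    if si < 0 or sj < 0:
        return CAT_STEM_LOOP
    return CAT_INTRA_STEM if si == sj else CAT_INTER_STEM
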