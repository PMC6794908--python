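"""Combine coevolutionary and structural signals into ranked contacts.

The structural contact-frequency template W (learned at a fixed template
size) is projected onto the target sequence length by the same bilinear
convention used when resizing training maps, and the DCA direct
information is reweighted elementwise:

    DIRECT(i, j) = DI(i, j) * W(i, j)**exponent      (exponent 2 default)

Ranking keeps strict upper-triangle pairs separated by more than
``min_separation`` positions, sorted by descending score with
deterministic lexicographic tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_maps import MIN_SEPARATION, resize_distance_matrix
from .rbm import TemplateWeight

SCHEME_DI = "DI"
SCHEME_DIRECT = "DIRECT"


@dataclass
class ScoredContacts:
    """Ranked (i, j, score) predictions, 1-based, i < j, descending score."""

    entries: list[tuple[int, int, float]]
    length: int
    scheme: str = SCHEME_DI

    def top(self, n: int) -> "ScoredContacts":
        return ScoredContacts(self.entries[:n], self.length, self.scheme)

    def __len__(self) -> int:
        return len(self.entries)


def project_weight(w: TemplateWeight, target_length: int) -> np.ndarray:
    """Resize the template to target_length × target_length.

    Bilinear, same continuous-index convention as the training-map
    resize; output symmetrized, clipped to [0, 1], zero diagonal.
    """
    if target_length < 2:
        raise ValueError("invalid length")
    out = resize_distance_matrix(w.values, target_length).values
    out = np.clip(out, 0.0, 1.0)
    np.fill_diagonal(out, 0.0)
    return out


def direct_reweight(di: np.ndarray, w_projected: np.ndarray, exponent: int = 2) -> np.ndarray:
    """Elementwise DIRECT score: DI × W**exponent."""
    di = np.asarray(di, dtype=float)
    w = np.asarray(w_projected, dtype=float)
    if di.shape != w.shape:
        raise ValueError("dimension error")
    return di * w**exponent


def rank_contacts(
    scores: np.ndarray,
    min_separation: int = MIN_SEPARATION,
    top_n: int | None = None,
    scheme: str = SCHEME_DI,
) -> ScoredContacts:
    """Rank pairs by score; |i−j| > min_separation, ties broken by (i, j)."""
    scores = np.asarray(scores, dtype=float)
    L = scores.shape[0]
    iu, ju = np.triu_indices(L, k=min_separation + 1)
    vals = scores[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    entries = [(int(iu[k]) + 1, int(ju[k]) + 1, float(vals[k])) for k in order]
    if top_n is not None:
        entries = entries[:top_n]
    return ScoredContacts(entries, length=L, scheme=scheme)
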