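"""Synthetic RNA-like fixtures with the statistical structure the method
assumes.

Three generators, all deterministic given a seed:

* contact maps with nested stems (anti-diagonal bands) plus tertiary
  loop-loop blocks, together with a consistent pseudo-distance matrix and
  the dot-bracket secondary structure;
* families of such maps sharing the template's stems and tertiary blocks
  up to a symmetric bit-flip noise rate (a stand-in for a non-redundant
  set of folded RNAs of one structural class);
* alignments sampled from a pairwise model with couplings planted at
  chosen native contacts (favoring A-U, G-C and G-U states), so that
  coevolutionary analysis has a recoverable signal.

No thermodynamic or phylogenetic realism is claimed; the point is that
the generators expose exactly the signals — shared structural template,
direct pair couplings — that the pipeline is built to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import contact_maps as cmaps
from .contact_maps import ContactMap, DistanceMatrix, contact_map, flatten, resize_distance_matrix
from .io_formats import MSA, Residue, SecondaryStructure, StructureChain, read_dotbracket

# favored base pairings (A=0, C=1, G=2, U=3): A-U, G-C, G-U and reverses
PAIRED_STATES = ((0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2))


@dataclass
class SyntheticInstance:
    """One complete synthetic study case.

    ``native_map`` is the full contact map (no separation filter) of the
    target; ``family_*`` hold the perturbed training family;
    ``planted_pairs`` (1-based, i < j) are the native contacts carrying
    coevolutionary signal in ``msa``.
    """

    length: int
    native_map: ContactMap
    native_distances: DistanceMatrix
    ss: SecondaryStructure
    family_maps: list
    family_distances: list
    msa: MSA
    planted_pairs: list
    config: dict = field(default_factory=dict)


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


def pseudo_distances(cm: ContactMap | np.ndarray, rng: np.random.Generator) -> DistanceMatrix:
    """Distance matrix consistent with a binary map.

    Contacts get distances uniform in [3, 8); non-contacts in (8, 30].
    Thresholding at 8 Å (no separation filter) reproduces the map.
    """
    values = cm.values if isinstance(cm, ContactMap) else np.asarray(cm)
    L = values.shape[0]
    d_contact = rng.uniform(3.0, 8.0 - 1e-9, size=(L, L))
    d_far = rng.uniform(8.0 + 1e-6, 30.0, size=(L, L))
    d = np.where(values > 0, d_contact, d_far)
    d = np.triu(d, k=1)
    d = d + d.T
    return DistanceMatrix(d)


def _layout(length: int, n_stems: int, rng: np.random.Generator) -> str:
    """Dot-bracket layout: sequential hairpins joined by linkers.

    Drawn element sizes are shrunk toward their minima (stem 3, loop 3,
    linker 1) when the drawn total exceeds the target length; if even the
    minima do not fit, the geometry is infeasible.
    """
    min_needed = n_stems * (2 * 3 + 3) + (n_stems + 1) * 1
    if min_needed > length:
        raise ValueError("cannot place stems")
    stems = rng.integers(3, 6, size=n_stems)  # paired run lengths
    loops = rng.integers(4, 7, size=n_stems)  # hairpin loop lengths
    linkers = rng.integers(2, 5, size=n_stems + 1)  # tails and joins

    def needed_now() -> int:
        return int(2 * stems.sum() + loops.sum() + linkers.sum())

    parts_mins = [(linkers, 1), (loops, 3), (stems, 3)]
    while needed_now() > length:
        for arr, lo in parts_mins:
            k = int(np.argmax(arr))
            if arr[k] > lo:
                arr[k] -= 1
            if needed_now() <= length:
                break
    needed = needed_now()
    parts = ["." * int(linkers[0])]
    for k in range(n_stems):
        parts.append("(" * int(stems[k]) + "." * int(loops[k]) + ")" * int(stems[k]))
        parts.append("." * int(linkers[k + 1]))
    db = "".join(parts)
    return db + "." * (length - len(db))


def _loop_regions(ss: SecondaryStructure, min_len: int = 2) -> list[tuple[int, int]]:
    """Maximal unpaired runs as 1-based inclusive (start, end)."""
    regions, start = [], None
    for pos in range(1, ss.length + 1):
        if ss.stem_id[pos - 1] < 0:
            start = pos if start is None else start
        elif start is not None:
            regions.append((start, pos - 1))
            start = None
    if start is not None:
        regions.append((start, ss.length))
    return [(a, b) for a, b in regions if b - a + 1 >= min_len]


def synth_contact_map(
    length: int,
    n_stems: int = 3,
    n_tertiary_blocks: int = 2,
    seed: int = 0,
    block_size: int = 2,
):
    """Generate an RNA-like contact map.

    Returns (ContactMap, SecondaryStructure, DistanceMatrix).  Contacts:
    backbone neighbors (|i−j| ≤ 2), stem bands (each base pair plus its
    cross-stack neighbors), and ``n_tertiary_blocks`` square loop-loop
    blocks planted between distinct loop regions at sequence separation
    greater than 12.
    """
    if length < 20:
        raise ValueError("length must be at least 20")
    rng = _rng(seed)
    db = _layout(length, n_stems, rng)
    ss = read_dotbracket(db)

    m = np.zeros((length, length), dtype=np.uint8)

    def add(i: int, j: int) -> None:  # 1-based
        if i != j:
            m[i - 1, j - 1] = m[j - 1, i - 1] = 1

    for i in range(1, length):
        add(i, i + 1)
        if i + 2 <= length:
            add(i, i + 2)
    pair_set = set(ss.pairs)
    for a, b in ss.pairs:
        add(a, b)
        if (a + 1, b - 1) in pair_set:  # cross-stack
            add(a, b - 1)
            add(a + 1, b)

    # tertiary blocks between loop regions
    regions = _loop_regions(ss, min_len=block_size)
    candidates = [
        (r1, r2)
        for k1, r1 in enumerate(regions)
        for r2 in regions[k1 + 1 :]
        if r2[0] - r1[1] > 12 - block_size
    ]
    if len(candidates) < n_tertiary_blocks:
        raise ValueError("cannot place tertiary blocks")
    chosen = rng.choice(len(candidates), size=n_tertiary_blocks, replace=False)
    for idx in chosen:
        (a1, b1), (a2, b2) = candidates[idx]
        p = int(rng.integers(a1, b1 - block_size + 2))
        q = int(rng.integers(a2, b2 - block_size + 2))
        for di in range(block_size):
            for dj in range(block_size):
                if abs((p + di) - (q + dj)) > 4:
                    add(p + di, q + dj)

    cm = ContactMap(m, cutoff=cmaps.CONTACT_CUTOFF, min_separation=0)
    d = pseudo_distances(cm, rng)
    return cm, ss, d


def stem_band_mask(ss: SecondaryStructure, backbone: bool = True) -> np.ndarray:
    """Boolean mask of positions protected from family noise: stem bands
    (base pairs and cross-stack neighbors) and, optionally, the backbone
    band |i−j| ≤ 2."""
    L = ss.length
    mask = np.zeros((L, L), dtype=bool)
    pair_set = set(ss.pairs)
    for a, b in ss.pairs:
        mask[a - 1, b - 1] = mask[b - 1, a - 1] = True
        if (a + 1, b - 1) in pair_set:
            mask[a - 1, b - 2] = mask[b - 2, a - 1] = True
            mask[a, b - 1] = mask[b - 1, a] = True
    if backbone:
        idx = np.arange(L)
        mask |= np.abs(idx[:, None] - idx[None, :]) <= 2
    return mask


def synth_family(
    template: ContactMap,
    n_members: int,
    flip_rate: float,
    seed: int = 0,
    protected: np.ndarray | None = None,
) -> list[ContactMap]:
    """Perturbed copies of a template map.

    Each member applies independent symmetric bit flips at ``flip_rate``
    to the eligible lower-triangle positions (everything outside the
    ``protected`` mask), keeping the family RNA-like: stems are passed in
    as protected and survive unchanged.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = _rng(seed)
    L = template.size
    tril = np.tril(np.ones((L, L), dtype=bool), k=-1)
    eligible = tril if protected is None else (tril & ~protected)
    ei, ej = np.nonzero(eligible)
    members = []
    for _ in range(n_members):
        vals = template.values.copy()
        flips = rng.random(ei.size) < flip_rate
        vals[ei[flips], ej[flips]] ^= 1
        lower = np.tril(vals, k=-1)
        vals = lower + lower.T
        members.append(ContactMap(vals.astype(np.uint8), template.cutoff, 0))
    return members


def synth_msa(
    native_map: ContactMap | None,
    planted_pairs,
    n_sequences: int = 500,
    coupling_strength: float = 3.0,
    gap_rate: float = 0.05,
    seed: int = 0,
    length: int | None = None,
) -> MSA:
    """Alignment with pairwise couplings planted at chosen contacts.

    Planted column pairs are drawn jointly from a 4×4 table with weight
    exp(coupling_strength) on the favored pairings (A-U, G-C, G-U and
    reverses) and 1 elsewhere; other columns are i.i.d. with a
    near-uniform per-column composition; gaps are inserted i.i.d. at
    ``gap_rate``.  Each column may belong to at most one planted pair.
    """
    if length is None:
        if native_map is None:
            raise ValueError("length or native_map required")
        length = native_map.size
    used: set[int] = set()
    for i, j in planted_pairs:
        if i in used or j in used:
            raise ValueError("column reuse in planted pairs")
        used.update((i, j))
        if native_map is not None and not native_map.values[i - 1, j - 1]:
            raise ValueError(f"planted pair ({i}, {j}) is not a native contact")
    rng = _rng(seed)

    table = np.ones((4, 4))
    for a, b in PAIRED_STATES:
        table[a, b] = np.exp(coupling_strength)
    table /= table.sum()

    seqs = np.empty((n_sequences, length), dtype=np.int8)
    planted_cols = set()
    for i, j in planted_pairs:
        flat = rng.choice(16, size=n_sequences, p=table.ravel())
        seqs[:, i - 1] = flat // 4
        seqs[:, j - 1] = flat % 4
        planted_cols.update((i - 1, j - 1))
    for col in range(length):
        if col in planted_cols:
            continue
        comp = rng.dirichlet(np.full(4, 5.0))
        seqs[:, col] = rng.choice(4, size=n_sequences, p=comp)

    letters = np.array(list("ACGU-"))
    gap_mask = rng.random((n_sequences, length)) < gap_rate
    seqs = np.where(gap_mask, 4, seqs)
    rows = ["".join(letters[s]) for s in seqs]
    return MSA([f"seq{k}" for k in range(n_sequences)], rows)


def select_planted_pairs(
    native_map: ContactMap,
    ss: SecondaryStructure,
    n_pairs: int,
    seed: int = 0,
    min_separation: int = 4,
):
    """Column-disjoint native contacts to carry coevolutionary signal.

    Tertiary (non-base-pair) contacts are preferred, then long base
    pairs; all satisfy |i−j| > min_separation.
    """
    rng = _rng(seed)
    L = native_map.size
    iu, ju = np.triu_indices(L, k=min_separation + 1)
    hits = native_map.values[iu, ju] > 0
    pairs = [(int(a) + 1, int(b) + 1) for a, b in zip(iu[hits], ju[hits])]
    pair_set = set(ss.pairs)
    tertiary = [p for p in pairs if p not in pair_set]
    base = [p for p in pairs if p in pair_set]
    rng.shuffle(tertiary)
    rng.shuffle(base)
    chosen, used = [], set()
    for i, j in tertiary + base:
        if i in used or j in used:
            continue
        chosen.append((i, j))
        used.update((i, j))
        if len(chosen) == n_pairs:
            break
    return chosen


def training_vectors(
    distances,
    template_size: int = cmaps.TEMPLATE_SIZE,
    cutoff: float = cmaps.CONTACT_CUTOFF,
) -> np.ndarray:
    """Resize distance matrices to the template size, threshold, flatten.

    This is the full training-map path: linear interpolation of the
    distance matrix first, the 8 Å cutoff after, no separation filter.
    """
    vecs = [
        flatten(contact_map(resize_distance_matrix(d, template_size), cutoff, 0))
        for d in distances
    ]
    return np.asarray(vecs, dtype=float)


def make_instance(
    length: int = 70,
    n_stems: int = 3,
    n_tertiary_blocks: int = 2,
    n_members: int = 20,
    flip_rate: float = 0.1,
    n_sequences: int = 500,
    coupling_strength: float = 3.0,
    gap_rate: float = 0.05,
    n_planted: int = 10,
    seed: int = 0,
) -> SyntheticInstance:
    """Assemble a full study case: native structure, training family, MSA."""
    native_map, ss, native_d = synth_contact_map(
        length, n_stems, n_tertiary_blocks, seed=seed
    )
    protected = stem_band_mask(ss)
    family = synth_family(native_map, n_members, flip_rate, seed=seed + 1, protected=protected)
    frng = _rng(seed + 2)
    family_d = [pseudo_distances(m, frng) for m in family]
    planted = select_planted_pairs(native_map, ss, n_planted, seed=seed + 3)
    msa = synth_msa(
        native_map,
        planted,
        n_sequences=n_sequences,
        coupling_strength=coupling_strength,
        gap_rate=gap_rate,
        seed=seed + 4,
    )
    return SyntheticInstance(
        length=length,
        native_map=native_map,
        native_distances=native_d,
        ss=ss,
        family_maps=family,
        family_distances=family_d,
        msa=msa,
        planted_pairs=planted,
        config={
            "length": length,
            "n_stems": n_stems,
            "n_tertiary_blocks": n_tertiary_blocks,
            "n_members": n_members,
            "flip_rate": flip_rate,
            "n_sequences": n_sequences,
            "coupling_strength": coupling_strength,
            "gap_rate": gap_rate,
            "n_planted": n_planted,
            "seed": seed,
        },
    )


def tertiary_overlap(a: ContactMap, b: ContactMap, min_separation: int = 4) -> float:
    """Jaccard overlap of the |i−j| > min_separation contact sets."""
    L = min(a.size, b.size)
    iu, ju = np.triu_indices(L, k=min_separation + 1)
    sa = a.values[iu, ju] > 0
    sb = b.values[iu, ju] > 0
    union = (sa | sb).sum()
    return float((sa & sb).sum() / union) if union else 0.0


def mismatched_family(
    instance: SyntheticInstance,
    seed: int = 1000,
    max_overlap: float = 0.10,
    max_tries: int = 100,
):
    """Training family from a template sharing (essentially) no contacts
    with the instance's native map — the negative control for the
    template reweighting.

    Returns (family_distances, decoy_native_map).  Raises if no
    sufficiently disjoint layout is found.
    """
    cfg = instance.config
    for t in range(max_tries):
        try:
            decoy, decoy_ss, _ = synth_contact_map(
                instance.length,
                cfg.get("n_stems", 3),
                cfg.get("n_tertiary_blocks", 2),
                seed=seed + 7919 * t,
            )
        except ValueError:
            continue
        if tertiary_overlap(decoy, instance.native_map) <= max_overlap:
            protected = stem_band_mask(decoy_ss)
            family = synth_family(
                decoy,
                cfg.get("n_members", 20),
                cfg.get("flip_rate", 0.1),
                seed=seed + 1,
                protected=protected,
            )
            frng = _rng(seed + 2)
            return [pseudo_distances(m, frng) for m in family], decoy
    raise RuntimeError("could not generate a disjoint decoy template")


def synth_structure(length: int = 5, seed: int = 0, atoms_per_residue: int = 3) -> StructureChain:
    """Toy 3D chain (points on a smooth curve with per-atom jitter) for
    exercising the coordinate-file path.  No physical realism claimed."""
    rng = _rng(seed)
    t = np.linspace(0.0, 2.0 * np.pi, length)
    backbone = np.stack([8 * np.cos(t), 8 * np.sin(t), 2.5 * np.arange(length)], axis=1)
    names = ["P", "C4'", "N1", "C2", "O2'"][:atoms_per_residue]
    residues = []
    letters = "ACGU"
    for k in range(length):
        coords = backbone[k] + rng.normal(0.0, 0.8, size=(atoms_per_residue, 3))
        residues.append(
            Residue(k + 1, "", letters[k % 4], list(names), np.round(coords, 3))
        )
    return StructureChain("A", residues)
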