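"""Readers and writers for the formats the pipeline touches.

Coordinate files (PDB ATOM records), alignments (FASTA / Stockholm),
dot-bracket secondary structure, ranked contact lists (TSV), dense
matrices, and RBM model archives.  All user-facing indices are 1-based
with i < j; internal arrays are 0-based numpy.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.PDB import PDBParser

ALPHABET = "ACGU-"
GAP = "-"

_STATE = {c: i for i, c in enumerate(ALPHABET)}


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One nucleotide: heavy atoms only."""

    number: int
    icode: str
    name: str
    atom_names: list[str]
    coords: np.ndarray  # (n_atoms, 3) float, Å

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass
class StructureChain:
    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)


def read_structure(text: str, chain: str) -> StructureChain:
    """Parse one chain from PDB-format text.

    Hydrogens (and deuterium) are dropped, waters are skipped, and
    modified residues are retained as long as they carry at least one
    heavy atom.  Residue order (including insertion codes) follows the
    file.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", io.StringIO(text))
    model = next(structure.get_models())
    chain_obj = None
    for c in model.get_chains():
        if c.id == chain:
            chain_obj = c
            break
    if chain_obj is None:
        raise KeyError(f"chain not found: {chain!r}")

    residues: list[Residue] = []
    for res in chain_obj.get_residues():
        hetflag, resseq, icode = res.id
        if hetflag == "W":
            continue
        names, xyz = [], []
        for atom in res.get_atoms():
            element = (atom.element or "").strip().upper()
            if element in ("H", "D") or (not element and atom.get_name().lstrip("0123456789").startswith("H")):
                continue
            names.append(atom.get_name())
            xyz.append(atom.get_coord())
        if not names:
            continue
        coords = np.asarray(xyz, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates in residue {resseq}")
        residues.append(Residue(resseq, icode.strip(), res.get_resname().strip(), names, coords))
    if not residues:
        raise ValueError("empty chain")
    return StructureChain(chain, residues)


def write_pdb(chain: StructureChain) -> str:
    """Serialize a chain as minimal PDB ATOM records (one model)."""
    lines = []
    serial = 1
    for res in chain.residues:
        for name, (x, y, z) in zip(res.atom_names, res.coords):
            elem = name.lstrip("0123456789")[:1]
            lines.append(
                f"ATOM  {serial:>5} {name:<4.4}{'':1}{res.name:>3.3} {chain.chain_id:1}"
                f"{res.number:>4}{res.icode or '':1}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {elem:>2}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class MSA:
    """Aligned RNA sequences over {A, C, G, U, -}."""

    ids: list[str]
    rows: list[str]

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def encode(self) -> np.ndarray:
        """Integer matrix (n, L), A=0 C=1 G=2 U=3 gap=4."""
        arr = np.frombuffer("".join(self.rows).encode(), dtype=np.uint8)
        out = np.full(arr.shape, _STATE[GAP], dtype=np.int8)
        for c, k in _STATE.items():
            out[arr == ord(c)] = k
        return out.reshape(self.n, self.length)


def _normalize_row(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    return "".join(c if c in ALPHABET else GAP for c in s)


def read_msa(text: str) -> MSA:
    """Read a FASTA or Stockholm alignment (auto-detected).

    Rows are uppercased, T→U, and any symbol outside {A,C,G,U,-}
    (dots, tildes, N, ambiguity codes) becomes a gap.
    """
    stripped = text.lstrip()
    if not stripped:
        raise ValueError("no sequences")
    if stripped.startswith("# STOCKHOLM"):
        aln = AlignIO.read(io.StringIO(text), "stockholm")
        records = list(aln)
    else:
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValueError("no sequences")
    ids = [r.id for r in records]
    rows = [_normalize_row(str(r.seq)) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("unequal lengths")
    return MSA(ids, rows)


def write_msa(msa: MSA) -> str:
    return "".join(f">{i}\n{r}\n" for i, r in zip(msa.ids, msa.rows))


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructure:
    """Nested secondary structure from a dot-bracket string.

    ``pairs`` are 1-based (i, j) with i < j; ``stem_id`` is a per-position
    array, -1 for loop positions, k >= 0 for the k-th stem (a maximal run
    of stacked pairs).
    """

    dotbracket: str
    pairs: list[tuple[int, int]] = field(default_factory=list)
    stem_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def length(self) -> int:
        return len(self.dotbracket)

    @property
    def n_stems(self) -> int:
        return int(self.stem_id.max()) + 1 if self.stem_id.size and self.stem_id.max() >= 0 else 0


def read_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into pairs and stem labels.

    Only nested structures over ``( ) .`` are supported; other bracket
    types (used for pseudoknots) are rejected explicitly.
    """
    db = text.strip()
    if any(c in "[]{}<>" for c in db):
        raise ValueError("pseudoknot unsupported")
    bad = set(db) - set("().")
    if bad:
        raise ValueError(f"invalid dot-bracket characters: {sorted(bad)}")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, c in enumerate(db, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced")
            pairs.append((stack.pop(), pos))
    if stack:
        raise ValueError("unbalanced")
    pairs.sort()

    stem_id = np.full(len(db), -1, dtype=int)
    pair_set = set(pairs)
    stem = -1
    for i, j in pairs:
        if (i - 1, j + 1) not in pair_set:  # not stacked on a previous pair
            stem += 1
            cur = stem
        else:
            cur = stem_id[i - 2]
        stem_id[i - 1] = cur
        stem_id[j - 1] = cur
    return SecondaryStructure(db, pairs, stem_id)


# ---------------------------------------------------------------------------
# contact lists and dense matrices
# ---------------------------------------------------------------------------

def write_contacts(entries, include_labels: bool = False) -> str:
    """Ranked contacts as TSV; 1-based, i < j, rank order preserved.

    ``entries`` is an iterable of (i, j, score) or, with labels,
    (i, j, score, range, category, is_native).
    """
    header = ["i", "j", "score"]
    if include_labels:
        header += ["range", "category", "is_native"]
    lines = ["\t".join(header)]
    for e in entries:
        i, j, score = e[0], e[1], e[2]
        row = [str(i), str(j), f"{score:.8g}"]
        if include_labels:
            row += [str(x) for x in e[3:6]]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def read_contacts(text: str):
    """Inverse of :func:`write_contacts` (i, j, score triples)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    out = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        out.append((int(parts[0]), int(parts[1]), float(parts[2])))
    return out


def write_dense(matrix: np.ndarray) -> str:
    buf = io.StringIO()
    np.savetxt(buf, np.asarray(matrix), fmt="%.8g", delimiter="\t")
    return buf.getvalue()


def read_dense(text: str) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(io.StringIO(text), delimiter="\t"))


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Persist an RBM (weights, biases, seed, training config) as npz."""
    np.savez(
        path,
        weight=model.weight,
        visible_bias=model.visible_bias,
        hidden_bias=model.hidden_bias,
        rng_seed=np.asarray(model.rng_seed),
        config=np.asarray(json.dumps(model.config)),
    )


def load_model(path):
    from .rbm import RBMModel

    with np.load(path, allow_pickle=False) as z:
        return RBMModel(
            weight=z["weight"],
            visible_bias=z["visible_bias"],
            hidden_bias=z["hidden_bias"],
            rng_seed=int(z["rng_seed"]),
            config=json.loads(str(z["config"])),
        )
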