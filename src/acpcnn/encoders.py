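"""Fixed-shape numeric peptide encodings.

Each peptide is reduced to its k N-terminal residues (k = 15 by default,
shorter sequences post-padded with an all-zero PAD row) and converted into
up to three matrices:

* **BPF** — binary profile feature: one-hot rows over the 20 canonical
  residues in the order A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V → k x 20.
* **PHYSCHEM** — 31 membership bits per residue: 10 overlapping
  physicochemical groups followed by 7 attributes x 3 disjoint groups
  (exactly one bit per attribute is set, so the 21-bit segment always sums
  to 7) → k x 31.
* **BLO62** — the residue's row of a symmetric 20 x 20 substitution matrix
  (BLOSUM62 by default, raw integer scores) → k x 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .io import ALPHABET, Dataset

PAD = "-"

#: Representation names in canonical order.
REPRESENTATIONS = ("BPF", "PHYSCHEM", "BLO62")

#: Column widths per representation.
WIDTHS = {"BPF": 20, "PHYSCHEM": 31, "BLO62": 20}

#: Default number of N-terminal residues retained.
DEFAULT_K = 15

N_OVERLAP_GROUPS = 10
N_ATTRIBUTES = 7
ATTRIBUTE_GROUPS = 3

_RES_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Representation combinations: C1..C7 = the non-empty subsets of the three.
COMBINATIONS: dict[str, tuple[str, ...]] = {
    "C1": ("BPF",),
    "C2": ("PHYSCHEM",),
    "C3": ("BLO62",),
    "C4": ("BPF", "PHYSCHEM"),
    "C5": ("BPF", "BLO62"),
    "C6": ("PHYSCHEM", "BLO62"),
    "C7": ("BPF", "PHYSCHEM", "BLO62"),
}


def resolve_combination(combination) -> tuple[str, ...]:
    """Accept 'C1'..'C7', a representation name, or an iterable of names."""
    if isinstance(combination, str):
        key = combination.upper()
        if key in COMBINATIONS:
            return COMBINATIONS[key]
        if key in REPRESENTATIONS:
            return (key,)
        raise ValueError(
            f"unknown combination {combination!r}; expected C1..C7 or a subset of {REPRESENTATIONS}"
        )
    combo = tuple(dict.fromkeys(c.upper() for c in combination))
    if not combo:
        raise ValueError("combination must be non-empty")
    bad = [c for c in combo if c not in REPRESENTATIONS]
    if bad:
        raise ValueError(f"unknown representation(s) {bad}")
    # keep canonical order
    return tuple(r for r in REPRESENTATIONS if r in combo)


@dataclass(frozen=True)
class TokenizedPeptide:
    """Exactly k tokens: N-terminal residues then a contiguous PAD suffix."""

    tokens: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        if len(self.tokens) != self.k:
            raise ValueError("token count must equal k")


def tokenize(sequence: str, k: int = DEFAULT_K) -> TokenizedPeptide:
    """Keep the first min(len, k) N-terminal residues; post-pad to k tokens."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not sequence:
        raise ValueError("empty sequence")
    head = list(sequence[:k])
    head += [PAD] * (k - len(head))
    return TokenizedPeptide(tokens=tuple(head), k=k)


@dataclass(frozen=True)
class EncodedPeptide:
    """A k x d real matrix for one peptide under one representation."""

    matrix: np.ndarray
    representation: str

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @property
    def d(self) -> int:
        return self.matrix.shape[1]


class PropertyTableError(ValueError):
    """Raised when a property-group table violates its structural invariants."""


@dataclass(frozen=True)
class PropertyTable:
    """Group memberships backing the 31-bit physicochemical encoding.

    ``overlap_groups`` are 10 (name, residue-set) pairs that may overlap;
    ``attributes`` are 7 (name, [3 residue-sets]) pairs where each triple is
    a disjoint, exhaustive partition of the 20 canonical residues.
    """

    overlap_groups: tuple[tuple[str, frozenset], ...]
    attributes: tuple[tuple[str, tuple[frozenset, frozenset, frozenset]], ...]

    def __post_init__(self) -> None:
        if len(self.overlap_groups) != N_OVERLAP_GROUPS:
            raise PropertyTableError(
                f"expected {N_OVERLAP_GROUPS} overlapping groups, "
                f"got {len(self.overlap_groups)}"
            )
        if len(self.attributes) != N_ATTRIBUTES:
            raise PropertyTableError(
                f"expected {N_ATTRIBUTES} attributes, got {len(self.attributes)}"
            )
        full = frozenset(ALPHABET)
        for name, groups in self.attributes:
            if len(groups) != ATTRIBUTE_GROUPS:
                raise PropertyTableError(f"attribute {name!r}: needs 3 groups")
            union: set = set()
            for g in groups:
                clash = union & g
                if clash:
                    raise PropertyTableError(
                        f"attribute {name!r}: residue(s) {sorted(clash)} "
                        "appear in more than one group"
                    )
                union |= g
            missing = full - union
            if missing:
                raise PropertyTableError(
                    f"attribute {name!r}: residue(s) {sorted(missing)} "
                    "missing from all groups"
                )

    def residue_bits(self, residue: str) -> np.ndarray:
        """The 31-bit membership vector for one canonical residue."""
        bits = np.zeros(WIDTHS["PHYSCHEM"], dtype=float)
        for i, (_, members) in enumerate(self.overlap_groups):
            if residue in members:
                bits[i] = 1.0
        offset = N_OVERLAP_GROUPS
        for _, groups in self.attributes:
            for j, g in enumerate(groups):
                if residue in g:
                    bits[offset + j] = 1.0
            offset += ATTRIBUTE_GROUPS
        return bits


def load_property_table(path: Optional[str | Path] = None) -> PropertyTable:
    """Load and validate a property-group table (shipped default if no path).

    Format: one line per group, tab-separated
    ``group-id  overlap|attribute:<name>:<index>  member-residues``.
    """
    if path is None:
        text = (
            resources.files("acpcnn").joinpath("data/property_groups.tsv").read_text()
        )
        src = "<shipped default>"
    else:
        text = Path(path).read_text()
        src = str(path)
    overlap: list[tuple[str, frozenset]] = []
    attrs: dict[str, dict[int, frozenset]] = {}
    attr_order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise PropertyTableError(
                f"{src}:{lineno}: expected 3 tab-separated columns"
            )
        gid, segment, members = (p.strip() for p in parts)
        residues = frozenset(members.upper())
        bad = residues - set(ALPHABET)
        if bad:
            raise PropertyTableError(
                f"{src}:{lineno}: non-canonical residue(s) {sorted(bad)} in group {gid!r}"
            )
        if segment == "overlap":
            overlap.append((gid, residues))
        elif segment.startswith("attribute:"):
            try:
                _, name, idx_s = segment.split(":")
                idx = int(idx_s)
            except ValueError as exc:
                raise PropertyTableError(
                    f"{src}:{lineno}: malformed segment {segment!r}"
                ) from exc
            if not 1 <= idx <= ATTRIBUTE_GROUPS:
                raise PropertyTableError(
                    f"{src}:{lineno}: attribute group index must be 1..3"
                )
            if name not in attrs:
                attrs[name] = {}
                attr_order.append(name)
            if idx in attrs[name]:
                raise PropertyTableError(
                    f"{src}:{lineno}: duplicate group {idx} for attribute {name!r}"
                )
            attrs[name][idx] = residues
        else:
            raise PropertyTableError(f"{src}:{lineno}: unknown segment {segment!r}")
    attributes = []
    for name in attr_order:
        groups = attrs[name]
        if sorted(groups) != [1, 2, 3]:
            raise PropertyTableError(
                f"attribute {name!r}: groups present {sorted(groups)}, need 1,2,3"
            )
        attributes.append((name, (groups[1], groups[2], groups[3])))
    return PropertyTable(tuple(overlap), tuple(attributes))


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric integer substitution matrix over the 20 canonical residues."""

    scores: np.ndarray  # (20, 20), indexed in ALPHABET order
    name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.scores.shape != (20, 20):
            raise ValueError(f"matrix must be 20x20, got {self.scores.shape}")
        if not np.array_equal(self.scores, self.scores.T):
            i, j = np.argwhere(self.scores != self.scores.T)[0]
            raise ValueError(
                f"matrix not symmetric: ({ALPHABET[i]},{ALPHABET[j]}) = "
                f"{self.scores[i, j]} but ({ALPHABET[j]},{ALPHABET[i]}) = "
                f"{self.scores[j, i]}"
            )

    def row(self, residue: str) -> np.ndarray:
        return self.scores[_RES_INDEX[residue]].astype(float)


def identity_matrix() -> SubstitutionMatrix:
    """Diagonal-1 toy matrix; makes the substitution encoding equal one-hot."""
    return SubstitutionMatrix(np.eye(20, dtype=int), name="identity")


def load_substitution_matrix(path: Optional[str | Path] = None) -> SubstitutionMatrix:
    """Load an NCBI-format square substitution matrix (shipped BLOSUM62 default).

    Extra rows/columns (B, Z, X, ``*`` ...) are dropped; the 20 canonical
    residues are re-indexed to the A,R,N,D,... column order and symmetry is
    validated.
    """
    if path is None:
        ref = resources.files("acpcnn").joinpath("data/blosum62.txt")
        with resources.as_file(ref) as p:
            return load_substitution_matrix(p)
    path = Path(path)
    with path.open() as fh:
        mat = substitution_matrices.read(fh)
    alpha = list(mat.alphabet)
    missing = [aa for aa in ALPHABET if aa not in alpha]
    if missing:
        raise ValueError(f"{path}: matrix missing canonical residue(s) {missing}")
    idx = [alpha.index(aa) for aa in ALPHABET]
    scores = np.asarray(mat)[np.ix_(idx, idx)]
    int_scores = np.rint(scores).astype(int)
    name = path.stem.upper()
    return SubstitutionMatrix(int_scores, name=name)


def _rows(
    tokens: TokenizedPeptide, width: int, lookup, unknown: str = "error"
) -> np.ndarray:
    out = np.zeros((tokens.k, width), dtype=float)
    for i, tok in enumerate(tokens.tokens):
        if tok == PAD:
            continue  # PAD rows stay all-zero
        if tok not in _RES_INDEX:
            if unknown == "zero":
                continue
            raise KeyError(f"residue {tok!r} not encodable")
        out[i] = lookup(tok)
    return out


def encode_bpf(tokens: TokenizedPeptide, unknown: str = "error") -> EncodedPeptide:
    """One-hot k x 20 matrix in the canonical residue order."""
    def hot(tok: str) -> np.ndarray:
        row = np.zeros(20)
        row[_RES_INDEX[tok]] = 1.0
        return row

    return EncodedPeptide(_rows(tokens, 20, hot, unknown), "BPF")


def encode_physchem(
    tokens: TokenizedPeptide, table: PropertyTable, unknown: str = "error"
) -> EncodedPeptide:
    """k x 31 membership-bit matrix (10 overlap bits + 21 partition bits)."""
    return EncodedPeptide(_rows(tokens, 31, table.residue_bits, unknown), "PHYSCHEM")


def encode_blosum(
    tokens: TokenizedPeptide,
    matrix: SubstitutionMatrix,
    unknown: str = "error",
    standardize: bool = False,
) -> EncodedPeptide:
    """k x 20 matrix of raw substitution scores (one matrix row per residue).

    ``standardize`` optionally z-scores each column over the 20 residues
    (off by default: scores enter the network as published integers).
    """
    scores = matrix.scores.astype(float)
    if standardize:
        scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)

    def row(tok: str) -> np.ndarray:
        return scores[_RES_INDEX[tok]]

    return EncodedPeptide(_rows(tokens, 20, row, unknown), "BLO62")


class DatasetEncoder:
    """Encodes whole datasets into per-representation stacks.

    Holds the property table and substitution matrix so repeated calls (e.g.
    across cross-validation folds) reuse the loaded resources.
    """

    def __init__(
        self,
        property_table: Optional[PropertyTable] = None,
        substitution_matrix: Optional[SubstitutionMatrix] = None,
        unknown: str = "error",
        standardize_blosum: bool = False,
    ) -> None:
        self.property_table = property_table or load_property_table()
        self.substitution_matrix = substitution_matrix or load_substitution_matrix()
        self.unknown = unknown
        self.standardize_blosum = standardize_blosum

    def encode_one(self, tokens: TokenizedPeptide, representation: str) -> EncodedPeptide:
        if representation == "BPF":
            return encode_bpf(tokens, self.unknown)
        if representation == "PHYSCHEM":
            return encode_physchem(tokens, self.property_table, self.unknown)
        if representation == "BLO62":
            return encode_blosum(
                tokens, self.substitution_matrix, self.unknown, self.standardize_blosum
            )
        raise ValueError(f"unknown representation {representation!r}")

    def encode_dataset(
        self,
        dataset: Dataset,
        combination="C7",
        k: int | str = DEFAULT_K,
    ) -> tuple[dict[str, np.ndarray], Optional[np.ndarray]]:
        """Encode every record under each selected representation.

        ``k="max"`` switches to full-sequence mode: k becomes the longest
        sequence length in the dataset.  Returns ``(stacks, labels)`` where
        ``stacks[rep]`` has shape (n, k, width(rep)) with rows in dataset
        order; ``labels`` is None if any record is unlabeled.
        """
        combo = resolve_combination(combination)
        if k == "max":
            k_eff = max(len(r.sequence) for r in dataset)
        else:
            k_eff = int(k)
        token_list = [tokenize(r.sequence, k_eff) for r in dataset]
        stacks = {
            rep: np.stack([self.encode_one(t, rep).matrix for t in token_list])
            for rep in combo
        }
        try:
            labels: Optional[np.ndarray] = dataset.labels
        except ValueError:
            labels = None
        return stacks, labels


def encode_dataset(
    dataset: Dataset,
    combination="C7",
    k: int | str = DEFAULT_K,
    **encoder_kwargs,
) -> tuple[dict[str, np.ndarray], Optional[np.ndarray]]:
    """Functional wrapper around :class:`DatasetEncoder.encode_dataset`."""
    return DatasetEncoder(**encoder_kwargs).encode_dataset(dataset, combination, k)


def export_stacks(
    stacks: Mapping[str, np.ndarray], out_dir: str | Path, labels=None
) -> list[Path]:
    """Write each stack as a delimited dump and one compressed array container."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for rep, arr in stacks.items():
        flat = arr.reshape(arr.shape[0], -1)
        csv_path = out_dir / f"{rep.lower()}.csv"
        np.savetxt(csv_path, flat, fmt="%g", delimiter=",")
        written.append(csv_path)
    npz_path = out_dir / "encoded.npz"
    payload = {rep: arr for rep, arr in stacks.items()}
    if labels is not None:
        payload["labels"] = np.asarray(labels)
    np.savez_compressed(npz_path, **payload)
    written.append(npz_path)
    return written
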