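"""Shared domain types for comparative phosphomotif analysis.

The analysis revolves around three kinds of objects: an ordered species
ladder (most distant organism first, human last), fixed-geometry sequence
patterns around a phospho-acceptor (phosphomotifs), and species-tagged
ortholog groups holding a multiple sequence alignment.  Everything else in
the package consumes or produces these.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ACCEPTORS = frozenset("STY")
GAP = "-"
HUMAN = "hsa"

#: Window geometry: name -> (anchor offset within window, window length).
#: upstream6 is the five residues upstream plus the acceptor, centered7 the
#: acceptor with three residues on either side, downstream6 the acceptor
#: plus five residues downstream.
WINDOW_GEOMETRY: dict[str, tuple[int, int]] = {
    "upstream6": (5, 6),
    "centered7": (3, 7),
    "downstream6": (0, 6),
}

#: The nine-species ladder used throughout, ordered most distant -> human:
#: budding yeast, fission yeast, worm, fly, zebrafish, dog, mouse,
#: chimpanzee, human.
DEFAULT_SPECIES: tuple[str, ...] = (
    "sce", "spo", "cel", "dme", "dre", "cfa", "mmu", "ptr", "hsa",
)

#: Default expected amino-acid substitutions per site on each adjacent
#: branch of the ladder (same order as the species pairs, distal first).
DEFAULT_DIVERGENCE: tuple[float, ...] = (
    0.30, 0.40, 0.35, 0.35, 0.25, 0.10, 0.08, 0.01,
)


@lru_cache(maxsize=1)
def blosum62() -> dict[tuple[str, str], int]:
    """The standard BLOSUM62 substitution matrix as a symmetric dict.

    Loaded from biopython; includes the B/Z/X ambiguity rows.
    """
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out: dict[tuple[str, str], int] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            out[(a, b)] = int(mat[a, b])
    return out


@dataclass(frozen=True)
class SpeciesLadder:
    """An ordered set of genomes, most distant from human first, human last.

    ``branch_divergence[i]`` is the expected fraction of substituted sites
    between ``species[i]`` and ``species[i+1]``.
    """

    species: tuple[str, ...]
    branch_divergence: tuple[float, ...]
    human: str = HUMAN

    def __post_init__(self) -> None:
        if len(self.species) < 3:
            raise ValueError("ladder needs at least 3 species")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species codes in ladder")
        if self.human not in self.species:
            raise ValueError(f"human code {self.human!r} missing from ladder")
        if self.species[-1] != self.human:
            raise ValueError("human must be the last (least distant) species")
        if len(self.branch_divergence) != len(self.species) - 1:
            raise ValueError(
                "need one divergence per adjacent species pair "
                f"({len(self.species) - 1}), got {len(self.branch_divergence)}"
            )
        for d in self.branch_divergence:
            if not (0.0 <= d < 1.0):
                raise ValueError(f"branch divergence {d} outside [0, 1)")

    def __len__(self) -> int:
        return len(self.species)

    def index(self, code: str) -> int:
        try:
            return self.species.index(code)
        except ValueError:
            raise KeyError(f"unknown species code {code!r}") from None

    def species_from(self, code: str) -> tuple[str, ...]:
        """All species from *code* toward human, inclusive."""
        return self.species[self.index(code):]

    @classmethod
    def default(cls) -> "SpeciesLadder":
        return cls(DEFAULT_SPECIES, DEFAULT_DIVERGENCE)


_SET_TOKEN = re.compile(r"\[([A-Z]+)\]|(X)|([A-Z])")


@dataclass(frozen=True)
class MotifPattern:
    """Per-position residue constraints around an anchored phospho-acceptor.

    ``positions[i]`` is a frozenset of allowed residues, or ``None`` for a
    wildcard (X).  Exactly one position, ``anchor_offset``, is the acceptor
    and must be constrained to a subset of {S, T, Y}.
    """

    id: str
    window_type: str
    positions: tuple[frozenset | None, ...]
    anchor_offset: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.window_type not in WINDOW_GEOMETRY:
            raise ValueError(f"unknown window type {self.window_type!r}")
        anchor, length = WINDOW_GEOMETRY[self.window_type]
        if len(self.positions) != length:
            raise ValueError(
                f"{self.window_type} pattern must have {length} positions"
            )
        if self.anchor_offset == -1:
            object.__setattr__(self, "anchor_offset", anchor)
        if self.anchor_offset != anchor:
            raise ValueError(
                f"anchor offset {self.anchor_offset} does not match "
                f"{self.window_type} geometry (expected {anchor})"
            )
        acc = self.positions[self.anchor_offset]
        if acc is None or not acc or not acc <= ACCEPTORS:
            raise ValueError("anchor position must be a subset of {S,T,Y}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def anchor_set(self) -> frozenset:
        return self.positions[self.anchor_offset]

    @classmethod
    def from_string(cls, spec: str, window_type: str, id: str = "") -> "MotifPattern":
        """Build a pattern from a compact string like ``"RRX[ST]PLG"``.

        ``X`` is a wildcard, ``[..]`` a residue set, a plain letter a fixed
        residue.  The anchor offset is implied by the window type.
        """
        tokens = spec.replace("-", "")
        positions: list[frozenset | None] = []
        for m in _SET_TOKEN.finditer(tokens):
            if m.group(1):
                positions.append(frozenset(m.group(1)))
            elif m.group(2):
                positions.append(None)
            else:
                positions.append(frozenset(m.group(3)))
        return cls(id or spec, window_type, tuple(positions))

    def to_string(self) -> str:
        parts = []
        for pos in self.positions:
            if pos is None:
                parts.append("X")
            elif len(pos) == 1:
                parts.append(next(iter(pos)))
            else:
                parts.append("[" + "".join(sorted(pos)) + "]")
        return "".join(parts)

    def matches(self, window: str) -> bool:
        """Exact match of *window* (same length) against the constraints."""
        if len(window) != len(self.positions):
            return False
        for ch, allowed in zip(window, self.positions):
            if allowed is not None and ch not in allowed:
                return False
        return True

    def to_json(self) -> dict:
        return {
            "id": self.id,
            "window_type": self.window_type,
            "anchor_offset": self.anchor_offset,
            "positions": [
                None if p is None else sorted(p) for p in self.positions
            ],
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "MotifPattern":
        return cls(
            obj["id"],
            obj["window_type"],
            tuple(
                None if p is None else frozenset(p) for p in obj["positions"]
            ),
            obj.get("anchor_offset", -1),
        )


@dataclass(frozen=True)
class GroupMember:
    species: str
    protein_id: str
    aligned_seq: str

    @property
    def ungapped(self) -> str:
        return self.aligned_seq.replace(GAP, "")


@dataclass(frozen=True)
class OrthologGroup:
    """Species-tagged aligned sequences sharing common ancestry."""

    group_id: str
    members: tuple[GroupMember, ...]

    def __post_init__(self) -> None:
        lengths = {len(m.aligned_seq) for m in self.members}
        if len(lengths) > 1:
            raise ValueError(
                f"ragged alignment in group {self.group_id}: lengths {sorted(lengths)}"
            )

    @property
    def alignment_length(self) -> int:
        return len(self.members[0].aligned_seq) if self.members else 0

    def members_for(self, species: str) -> tuple[GroupMember, ...]:
        return tuple(m for m in self.members if m.species == species)

    def member(self, species: str) -> GroupMember | None:
        ms = self.members_for(species)
        return ms[0] if ms else None

    @property
    def species_present(self) -> frozenset:
        return frozenset(m.species for m in self.members)


class GroupIndex:
    """Lookup from protein id to its ortholog group and member record."""

    def __init__(self, groups: Iterable[OrthologGroup]):
        self.groups: dict[str, OrthologGroup] = {}
        self._by_protein: dict[str, tuple[OrthologGroup, GroupMember]] = {}
        for g in groups:
            self.groups[g.group_id] = g
            for m in g.members:
                self._by_protein[m.protein_id] = (g, m)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_protein

    def lookup(self, protein_id: str) -> tuple[OrthologGroup, GroupMember]:
        return self._by_protein[protein_id]

    def get(self, protein_id: str):
        return self._by_protein.get(protein_id)


def human_sequences(groups: Iterable[OrthologGroup], human: str = HUMAN) -> dict[str, str]:
    """Ungapped human protein sequences keyed by protein id."""
    out: dict[str, str] = {}
    for g in groups:
        for m in g.members_for(human):
            out[m.protein_id] = m.ungapped
    return out


def substitution_propensities() -> tuple[np.ndarray, np.ndarray]:
    """BLOSUM62-derived per-row substitution distributions.

    Returns ``(cum, idx)`` where ``cum[a]`` is the cumulative probability
    over target residues for source residue index ``a`` (diagonal excluded),
    proportional to ``2**(score/2)``; ``idx`` maps letters to indices.
    """
    b = blosum62()
    n = len(AMINO_ACIDS)
    w = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, c in enumerate(AMINO_ACIDS):
            if i != j:
                w[i, j] = 2.0 ** (b[(a, c)] / 2.0)
    w /= w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1)
    cum[:, -1] = 1.0
    idx = np.zeros(128, dtype=np.int64)
    for i, a in enumerate(AMINO_ACIDS):
        idx[ord(a)] = i
    return cum, idx


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a protein string as indices into AMINO_ACIDS (gap -> -1)."""
    lut = np.full(128, -1, dtype=np.int8)
    for i, a in enumerate(AMINO_ACIDS):
        lut[ord(a)] = i
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return lut[arr]


def codes_to_seq(codes: Sequence[int]) -> str:
    return "".join(AMINO_ACIDS[c] if c >= 0 else GAP for c in codes)
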