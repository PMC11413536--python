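"""Genomes, gene parsing, and germline mutation.

A genome is a continuous single strand of quaternary bases (integers
0-3) of fixed length (18,000 by default, the size of some RNA viruses).
It is read in a fixed, non-overlapping triplet frame anchored at base 0.
A gene opens at a START codon and closes at the next STOP codon; codons
between them form the gene body.  Within a body, only the first
part-coding codon is expressed; later part codons are recorded but
flagged unexpressed.  A gene whose body carries no part codon is a
regulatory-only gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .code_table import Category, CodeTable, PartKind

DEFAULT_GENOME_LENGTH = 18_000

__all__ = [
    "DEFAULT_GENOME_LENGTH",
    "Genome",
    "Gene",
    "random_genome",
    "mutate_genome",
    "parse_genes",
    "hamming_distance",
]


@dataclass(frozen=True)
class Genome:
    """Immutable strand of quaternary bases; length must be a multiple of 3."""

    bases: np.ndarray

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(self.bases, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("genome bases must be one-dimensional")
        if arr.size % 3 != 0:
            raise ValueError(f"genome length {arr.size} is not a multiple of 3")
        if arr.size and arr.max() > 3:
            raise ValueError("genome bases must be quaternary digits 0-3")
        object.__setattr__(self, "bases", arr)
        arr.setflags(write=False)

    def __len__(self) -> int:
        return self.bases.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return np.array_equal(self.bases, other.bases)

    def __hash__(self) -> int:
        return hash(self.bases.tobytes())

    @property
    def codons(self) -> np.ndarray:
        """View of the strand as an (L/3, 3) array of codon triples."""
        return self.bases.reshape(-1, 3)

    @property
    def codon_indices(self) -> np.ndarray:
        """Flat codon indices in [0, 64), one per triplet."""
        c = self.codons.astype(np.int64)
        return c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]

    def to_string(self) -> str:
        return "".join(chr(ord("0") + b) for b in self.bases)

    @classmethod
    def from_string(cls, s: str) -> "Genome":
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"))


@dataclass(frozen=True)
class Gene:
    """One gene: START at ``start_index``, STOP at ``stop_index`` (codon offsets).

    ``body`` holds the codons strictly between them as an (n, 3) array.
    ``expressed_part_offset`` points (within the body) at the first
    part codon, or is None for a regulatory-only gene;
    ``unexpressed_part_offsets`` flags any surplus part codons.
    """

    start_index: int
    stop_index: int
    body: np.ndarray
    expressed_part: PartKind | None
    expressed_part_offset: int | None
    unexpressed_part_offsets: tuple[int, ...] = field(default_factory=tuple)
    regulatory_offsets: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start_index >= self.stop_index:
            raise ValueError("gene START must precede its STOP")

    @property
    def n_codons(self) -> int:
        return self.body.shape[0]


def random_genome(length: int, rng: np.random.Generator) -> Genome:
    """Draw a genome of ``length`` i.i.d. uniform quaternary bases.

    Raises ``ValueError`` for negative lengths or lengths not divisible
    by 3.
    """
    if length < 0:
        raise ValueError("genome length must be non-negative")
    if length % 3 != 0:
        raise ValueError("genome length must be a multiple of 3")
    return Genome(rng.integers(0, 4, size=length, dtype=np.uint8))


def _substitute(bases: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point-substitute each base independently with probability ``rate``.

    A hit base is replaced by a uniform draw from the three *other*
    digits, so ``rate`` is the realised per-base change probability.
    Returns a new array; input untouched.
    """
    out = bases.copy()
    if rate == 0.0 or out.size == 0:
        return out
    hits = rng.random(out.size) < rate
    n = int(hits.sum())
    if n:
        shift = rng.integers(1, 4, size=n, dtype=np.uint8)
        out[hits] = (out[hits] + shift) % 4
    return out


def mutate_genome(genome: Genome, mu: float, rng: np.random.Generator) -> Genome:
    """Duplicate ``genome`` with i.i.d. per-base point mutations at rate ``mu``."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"mutation rate must lie in [0, 1], got {mu}")
    return Genome(_substitute(genome.bases, mu, rng))


def parse_genes(genome: Genome, table: CodeTable) -> list[Gene]:
    """Scan the fixed triplet frame for genes, in genomic order.

    A gene opens at each START codon not already inside an open gene and
    closes at the next STOP; a trailing START with no STOP forms no
    gene.  Nested STARTs inside an open gene are ordinary body codons.
    """
    idx = genome.codon_indices
    cats = table.categories_of(idx)
    genes: list[Gene] = []
    codons = genome.codons
    i, n = 0, idx.size
    start_code, stop_code = table.start_code, table.stop_code
    while i < n:
        if cats[i] != start_code:
            i += 1
            continue
        # find the closing STOP
        stops = np.nonzero(cats[i + 1:] == stop_code)[0]
        if stops.size == 0:
            break  # open gene runs off the strand: no gene
        j = i + 1 + int(stops[0])
        body = codons[i + 1: j]
        body_idx = idx[i + 1: j]
        body_cats = table.categories_of(body_idx)
        part_offsets = np.nonzero(body_cats == list(Category).index(Category.PART))[0]
        reg_mask = (body_cats == list(Category).index(Category.FEATURE)) | (
            body_cats == list(Category).index(Category.MAGNITUDE)
        )
        expressed_off = int(part_offsets[0]) if part_offsets.size else None
        expressed = (
            table.role(int(body_idx[expressed_off])).part_kind
            if expressed_off is not None
            else None
        )
        genes.append(
            Gene(
                start_index=i,
                stop_index=j,
                body=body,
                expressed_part=expressed,
                expressed_part_offset=expressed_off,
                unexpressed_part_offsets=tuple(int(o) for o in part_offsets[1:]),
                regulatory_offsets=tuple(int(o) for o in np.nonzero(reg_mask)[0]),
            )
        )
        i = j + 1
    return genes


def hamming_distance(a: Genome, b: Genome) -> int:
    """Number of positions at which two equal-length genomes differ."""
    if len(a) != len(b):
        raise ValueError("genomes must have equal length")
    return int(np.count_nonzero(a.bases != b.bases))
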