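"""Gene-order data model: signed permutations and genome collections.

A genome is modelled as a *linear* signed permutation of integer gene
labels: the absolute value identifies a homologous marker, the sign its
reading direction (strand). Circular genomes must be linearized by the
user before input (e.g. by dropping one copy of an inverted repeat).

On disk, genomes live in GRIMM-style text files::

    # optional comment
    >taxon_name
    1 -3 2 5 -4

A genome may span several lines, up to the next ``>`` header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator


class GenomeFormatError(ValueError):
    """Raised for malformed permutation files or invalid genome sets."""


@dataclass(frozen=True)
class SignedPermutation:
    """One genome: a taxon name and an ordered tuple of signed gene labels.

    Invariants: labels are nonzero, their absolute values pairwise
    distinct, and at least one gene is present.
    """

    name: str
    genes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(int(g) for g in self.genes))
        if len(self.genes) < 1:
            raise GenomeFormatError(f"genome {self.name!r} is empty")
        if any(g == 0 for g in self.genes):
            raise GenomeFormatError(f"genome {self.name!r} contains gene label 0")
        universe = {abs(g) for g in self.genes}
        if len(universe) != len(self.genes):
            raise GenomeFormatError(
                f"genome {self.name!r} contains a duplicated gene label"
            )

    @property
    def universe(self) -> frozenset[int]:
        """Set of absolute gene labels present in this genome."""
        return frozenset(abs(g) for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[int]:
        return iter(self.genes)


@dataclass(frozen=True)
class GenomeSet:
    """A named, ordered collection of signed permutations over one gene set.

    All member genomes must share the same universe of absolute gene
    labels and taxon names must be unique. Most downstream analyses
    additionally require at least two genomes; construction only
    requires one so that partial files can be inspected.
    """

    genomes: tuple[SignedPermutation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genomes", tuple(self.genomes))
        if not self.genomes:
            raise GenomeFormatError("a GenomeSet must contain at least one genome")
        names = [g.name for g in self.genomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GenomeFormatError(f"duplicate taxon name(s): {dupes}")
        universe = self.genomes[0].universe
        for g in self.genomes[1:]:
            if g.universe != universe:
                raise GenomeFormatError(
                    "all genomes must share the same gene set; "
                    f"{g.name!r} differs from {self.genomes[0].name!r}"
                )

    @property
    def gene_universe(self) -> frozenset[int]:
        return self.genomes[0].universe

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self) -> Iterator[SignedPermutation]:
        return iter(self.genomes)

    def __getitem__(self, key: int | str) -> SignedPermutation:
        if isinstance(key, str):
            for g in self.genomes:
                if g.name == key:
                    return g
            raise KeyError(key)
        return self.genomes[key]


def identity_permutation(n: int, name: str = "root") -> SignedPermutation:
    """The identity permutation ``(+1, +2, ..., +n)``.

    This is the canonical ancestral genome used at the root of simulated
    trees.
    """
    if n < 1:
        raise ValueError(f"gene count must be >= 1, got {n}")
    return SignedPermutation(name, tuple(range(1, n + 1)))


def read_genomes(path: str | Path) -> GenomeSet:
    """Read a GRIMM-style permutation file into a validated :class:`GenomeSet`.

    Lines beginning with ``>`` name a taxon; subsequent lines up to the
    next header hold whitespace-separated signed integers. ``#`` starts a
    comment; blank lines and extra whitespace are ignored.
    """
    path = Path(path)
    text = path.read_text()
    genomes: list[SignedPermutation] = []
    name: str | None = None
    genes: list[int] = []

    def flush() -> None:
        nonlocal name, genes
        if name is not None:
            genomes.append(SignedPermutation(name, tuple(genes)))
        name, genes = None, []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip()
            if not name:
                raise GenomeFormatError(f"{path}:{lineno}: empty taxon name")
        else:
            if name is None:
                raise GenomeFormatError(
                    f"{path}:{lineno}: gene data before any '>' header"
                )
            try:
                genes.extend(int(tok) for tok in line.split())
            except ValueError as exc:
                raise GenomeFormatError(f"{path}:{lineno}: {exc}") from None
    flush()
    if not genomes:
        raise GenomeFormatError(f"{path}: no genomes found")
    return GenomeSet(tuple(genomes))


def write_genomes(gs: GenomeSet, path: str | Path, header: str | None = None) -> None:
    """Write a GenomeSet as a GRIMM-style file (round-trips with read)."""
    path = Path(path)
    lines: list[str] = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    for g in gs:
        lines.append(f">{g.name}")
        lines.append(" ".join(str(x) for x in g.genes))
    path.write_text("\n".join(lines) + "\n")


def genome_set(perms: Iterable[SignedPermutation]) -> GenomeSet:
    """Convenience constructor from an iterable of permutations."""
    return GenomeSet(tuple(perms))
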