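"""Evolutionary conservation of phosphosites from an orthologue alignment.

Per alignment column, sequence variability is summarised as Shannon
entropy in bits, ``H = -sum_i p_i log2 p_i``, over the amino-acid
frequencies ``p_i`` of the column (gaps excluded by default).  Sites are
classed by entropy: ``H < 0.10`` highly conserved, ``0.10 <= H <= 0.50``
moderately conserved, ``H > 0.50`` poorly conserved.

The phylogenetic *origin* of a site is the lowest common ancestor (LCA),
in a user-supplied rooted taxonomy, of the species whose orthologues
conserve the site (non-gap and identical residue to the query at the
column, optionally extended to a small sequence context window).
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

GAP = "-"


class ConservationClass(str, enum.Enum):
    HIGHLY_CONSERVED = "highly_conserved"
    MODERATELY_CONSERVED = "moderately_conserved"
    POORLY_CONSERVED = "poorly_conserved"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Entropy thresholds (bits): below the first bound is highly conserved,
#: at or below the second is moderate, above it poor.
ENTROPY_HIGH_BOUND = 0.10
ENTROPY_MODERATE_BOUND = 0.50


@dataclass
class Alignment:
    """Named aligned rows plus the query row used for coordinate mapping."""

    names: list[str]
    rows: list[str]
    query_name: str
    species_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"aligned rows have unequal lengths: {sorted(lengths)}")
        if self.query_name not in self.names:
            raise ValueError(f"query row {self.query_name!r} not in alignment")
        if not self.species_of:
            self.species_of = {n: n for n in self.names}

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def query_row(self) -> str:
        return self.rows[self.names.index(self.query_name)]

    def column(self, column_index: int) -> str:
        """Residues of one 1-based column, in row order."""
        if not (1 <= column_index <= self.length):
            raise IndexError(f"column {column_index} outside alignment of length {self.length}")
        j = column_index - 1
        return "".join(row[j] for row in self.rows)


def read_alignment(
    path: str | Path,
    query_name: str,
    *,
    fmt: str | None = None,
    species_of: dict[str, str] | None = None,
) -> Alignment:
    """Load an aligned FASTA or Clustal file.

    Format is inferred from the extension (``.aln``/``.clustal`` ->
    clustal, otherwise fasta) unless given explicitly.  ``species_of``
    maps row names to species labels for origin mapping; by default each
    row name is its own species label.
    """
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal", ".clw"} else "fasta"
    msa = AlignIO.read(str(path), fmt)
    names = [rec.id for rec in msa]
    rows = [str(rec.seq).upper() for rec in msa]
    return Alignment(names=names, rows=rows, query_name=query_name, species_of=species_of or {})


def column_entropy(column: str, *, gap_policy: str = "exclude") -> float:
    """Shannon entropy (bits) of one alignment column.

    ``gap_policy="exclude"`` (default) computes frequencies over observed
    residues only; ``"as_state"`` counts the gap as a 21st state.  An
    all-gap column is undefined and returns NaN.
    """
    if not column:
        raise ValueError("column must be non-empty")
    if gap_policy not in ("exclude", "as_state"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    chars = column if gap_policy == "as_state" else column.replace(GAP, "")
    if not chars:
        return float("nan")
    counts = np.array(list(Counter(chars).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def column_frequencies(column: str, *, gap_policy: str = "exclude") -> dict[str, float]:
    """The amino-acid frequencies ``p_i`` underlying the entropy."""
    chars = column if gap_policy == "as_state" else column.replace(GAP, "")
    n = len(chars)
    return {aa: c / n for aa, c in sorted(Counter(chars).items())} if n else {}


def classify_conservation(H: float) -> ConservationClass:
    """Class a site by its column entropy (bits).

    ``H < 0.10`` highly conserved; ``0.10 <= H <= 0.50`` moderately
    conserved (both boundaries belong to the moderate class);
    ``H > 0.50`` poorly conserved.
    """
    if math.isnan(H):
        raise ValueError("entropy is undefined (NaN)")
    if H < 0:
        raise ValueError(f"entropy must be non-negative, got {H}")
    if H < ENTROPY_HIGH_BOUND:
        return ConservationClass.HIGHLY_CONSERVED
    if H <= ENTROPY_MODERATE_BOUND:
        return ConservationClass.MODERATELY_CONSERVED
    return ConservationClass.POORLY_CONSERVED


def map_site_to_column(aln: Alignment, position: int) -> int:
    """1-based alignment column holding the query's ``position``-th residue."""
    if position < 1:
        raise IndexError(f"position must be >= 1, got {position}")
    seen = 0
    for j, ch in enumerate(aln.query_row, start=1):
        if ch != GAP:
            seen += 1
            if seen == position:
                return j
    raise IndexError(
        f"position {position} beyond ungapped query length {seen} of {aln.query_name!r}"
    )


def map_column_to_site(aln: Alignment, column_index: int) -> int | None:
    """Inverse of :func:`map_site_to_column`; None if the query is gapped there."""
    if aln.query_row[column_index - 1] == GAP:
        return None
    return sum(1 for ch in aln.query_row[:column_index] if ch != GAP)


@dataclass
class TaxonomyTable:
    """A rooted taxonomy: (child -> parent) edges plus species -> leaf mapping."""

    parent_of: dict[str, str]
    leaf_of_species: dict[str, str]
    root: str = field(init=False)

    def __post_init__(self) -> None:
        children = set(self.parent_of)
        parents = set(self.parent_of.values())
        roots = parents - children
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {sorted(roots)}")
        self.root = roots.pop()
        for node in children:
            seen = {node}
            cur = node
            while cur != self.root:
                cur = self.parent_of[cur]
                if cur in seen:
                    raise ValueError(f"taxonomy contains a cycle through {node!r}")
                seen.add(cur)

    @classmethod
    def from_tables(
        cls,
        edges: pd.DataFrame | str | Path,
        species: pd.DataFrame | str | Path | None = None,
    ) -> "TaxonomyTable":
        """Build from a two-column (child, parent) TSV plus optional species->leaf TSV."""
        if isinstance(edges, (str, Path)):
            edges = pd.read_csv(edges, sep="\t", dtype=str, header=None, names=["child", "parent"], comment="#")
        parent_of = dict(zip(edges.iloc[:, 0], edges.iloc[:, 1]))
        if species is None:
            leaves = set(parent_of) - set(parent_of.values())
            leaf_of_species = {l: l for l in leaves}
        else:
            if isinstance(species, (str, Path)):
                species = pd.read_csv(species, sep="\t", dtype=str, header=None, names=["species", "leaf"], comment="#")
            leaf_of_species = dict(zip(species.iloc[:, 0], species.iloc[:, 1]))
        return cls(parent_of=parent_of, leaf_of_species=leaf_of_species)

    def lineage(self, node: str) -> list[str]:
        """Path from a node up to the root, inclusive."""
        if node != self.root and node not in self.parent_of:
            raise KeyError(f"unknown taxonomy node {node!r}")
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent_of[path[-1]])
        return path

    def lca(self, nodes: list[str]) -> str:
        """Lowest common ancestor of one or more taxonomy nodes."""
        if not nodes:
            raise ValueError("lca of an empty node set is undefined")
        common: list[str] | None = None
        for node in nodes:
            lin = self.lineage(node)
            if common is None:
                common = lin
            else:
                anc = set(lin)
                common = [n for n in common if n in anc]
        assert common
        return common[0]

    def lca_of_species(self, species: list[str]) -> str:
        missing = sorted(s for s in species if s not in self.leaf_of_species)
        if missing:
            raise KeyError(f"species missing from taxonomy: {missing}")
        return self.lca([self.leaf_of_species[s] for s in species])


def conserving_species(
    aln: Alignment,
    column_index: int,
    *,
    context_window: int = 0,
) -> list[str]:
    """Species whose row conserves the query residue at a column.

    A row conserves the site when it is non-gap and identical to the query
    at the column; with ``context_window=w`` the identity requirement
    extends to the ``+-w`` flanking columns as well.
    """
    j = column_index - 1
    query = aln.query_row
    lo = max(0, j - context_window)
    hi = min(aln.length, j + context_window + 1)
    out = []
    for name, row in zip(aln.names, aln.rows):
        if row[j] == GAP or row[j] != query[j]:
            continue
        if context_window and row[lo:hi] != query[lo:hi]:
            continue
        out.append(aln.species_of.get(name, name))
    return out


def site_origin(
    aln: Alignment,
    column_index: int,
    tax: TaxonomyTable,
    *,
    context_window: int = 0,
) -> str:
    """Phylogenetic origin of a site: LCA of the species conserving it."""
    species = conserving_species(aln, column_index, context_window=context_window)
    if not species:
        raise ValueError(f"no species conserves column {column_index}")
    return tax.lca_of_species(sorted(set(species)))


@dataclass
class ConservationResult:
    """Entropy, conservation class and origin clade for one query site."""

    site_position: int
    column_index: int
    entropy_bits: float
    conservation_class: ConservationClass
    origin_clade: str | None
    aa_frequencies: dict[str, float]
    n_species: int


def conservation_profile(
    aln: Alignment,
    positions: list[int],
    tax: TaxonomyTable | None = None,
    *,
    gap_policy: str = "exclude",
    context_window: int = 0,
) -> list[ConservationResult]:
    """Entropy, class and (optionally) origin for each query position."""
    results = []
    for pos in positions:
        col = map_site_to_column(aln, pos)
        column = aln.column(col)
        H = column_entropy(column, gap_policy=gap_policy)
        species = conserving_species(aln, col, context_window=context_window)
        origin = tax.lca_of_species(sorted(set(species))) if tax and species else None
        results.append(
            ConservationResult(
                site_position=pos,
                column_index=col,
                entropy_bits=H,
                conservation_class=classify_conservation(H),
                origin_clade=origin,
                aa_frequencies=column_frequencies(column, gap_policy=gap_policy),
                n_species=len(set(species)),
            )
        )
    return results


def results_to_frame(results: list[ConservationResult]) -> pd.DataFrame:
    """Tabulate results (`position column entropy_bits class origin_clade n_species`)."""
    return pd.DataFrame(
        [
            {
                "position": r.site_position,
                "column": r.column_index,
                "entropy_bits": r.entropy_bits,
                "class": r.conservation_class.value,
                "origin_clade": r.origin_clade if r.origin_clade is not None else "NA",
                "n_species": r.n_species,
            }
            for r in results
        ],
        columns=["position", "column", "entropy_bits", "class", "origin_clade", "n_species"],
    )
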