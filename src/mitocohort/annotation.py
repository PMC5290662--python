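"""Model of the circular human mitochondrial genome and its gene map.

The human mtDNA reference (rCRS, NC_012920.1) is a circular molecule of
16,569 bp encoding 13 respiratory-chain protein subunits, 22 tRNAs and
2 rRNAs, plus the non-coding control region (D-loop) which spans the
replication origin (positions 16024-576, wrapping the coordinate origin).
All coordinates here are 1-based inclusive rCRS positions.

Variant reporting assigns each position one *primary region* by the
precedence dloop > tRNA > rRNA > protein > other_noncoding, so that region
percentages over a variant set sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO

MT_GENOME_LENGTH = 16569

#: Primary-region precedence used when a position falls in several features.
REGION_PRECEDENCE = ("dloop", "tRNA", "rRNA", "protein", "other_noncoding")

VALID_COMPLEXES = ("I", "III", "IV", "V")


class CoordinateError(ValueError):
    """A position outside 1..16569."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One feature of the mtDNA map (gene or the D-loop).

    ``start``/``end`` are 1-based inclusive; the D-loop is the only feature
    with ``start > end`` (it wraps the origin of the circular genome).
    """

    name: str
    start: int
    end: int
    strand: str  # "H" (heavy) or "L" (light)
    category: str  # protein | tRNA | rRNA | dloop | other_noncoding
    complex: str  # I | III | IV | V | none

    def __post_init__(self) -> None:
        if not (1 <= self.start <= MT_GENOME_LENGTH and 1 <= self.end <= MT_GENOME_LENGTH):
            raise CoordinateError(
                f"{self.name}: interval [{self.start}, {self.end}] outside 1..{MT_GENOME_LENGTH}"
            )
        if self.start > self.end and self.category != "dloop":
            raise ValueError(f"{self.name}: only the D-loop may wrap the origin")

    def contains(self, pos: int) -> bool:
        if self.start <= self.end:
            return self.start <= pos <= self.end
        # origin-wrapping interval (D-loop)
        return pos >= self.start or pos <= self.end


@dataclass
class MitoGenomeModel:
    """The mtDNA reference model: length, gene map, optional reference bases.

    ``reference`` is the full sequence as an upper-case string (position ``p``
    is ``reference[p - 1]``) or ``None`` when no FASTA was supplied; pileup
    records carry their own reference base so most operations do not need it.
    """

    genes: list[GeneAnnotation]
    reference: str | None = None
    length: int = MT_GENOME_LENGTH
    _by_category: dict[str, list[GeneAnnotation]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.length != MT_GENOME_LENGTH:
            raise ValueError(f"mtDNA length must be {MT_GENOME_LENGTH}, got {self.length}")
        if self.reference is not None and len(self.reference) != self.length:
            raise ValueError(
                f"reference has {len(self.reference)} bases, expected {self.length}"
            )
        dloops = [g for g in self.genes if g.category == "dloop"]
        if len(dloops) != 1 or dloops[0].start <= dloops[0].end:
            raise ValueError("gene map must contain exactly one origin-wrapping D-loop")
        self._by_category = {}
        for g in self.genes:
            self._by_category.setdefault(g.category, []).append(g)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_gene_table(cls, path: str | Path, reference_fasta: str | Path | None = None
                        ) -> "MitoGenomeModel":
        """Load the gene map from a BED-like TSV (see the packaged file header)."""
        genes = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                name, start, end, strand, category, cplx = line.split("\t")
                genes.append(GeneAnnotation(name, int(start), int(end), strand, category, cplx))
        reference = None
        if reference_fasta is not None:
            record = next(SeqIO.parse(str(reference_fasta), "fasta"))
            reference = str(record.seq).upper()
        return cls(genes=genes, reference=reference)

    @classmethod
    def default(cls, reference_fasta: str | Path | None = None) -> "MitoGenomeModel":
        """The packaged NC_012920 gene map; reference bases optional."""
        with resources.as_file(
            resources.files("mitocohort.data").joinpath("mtdna_genes.tsv")
        ) as p:
            return cls.from_gene_table(p, reference_fasta)

    # -- queries ----------------------------------------------------------

    def classify_position(self, pos: int) -> set[tuple[str, str]]:
        """All (feature name, category) pairs whose interval contains ``pos``.

        D-loop membership is evaluated circularly. Positions covered by no
        feature return the empty set (minor intergenic spacers).
        """
        if not (1 <= pos <= self.length):
            raise CoordinateError(f"position {pos} outside 1..{self.length}")
        return {(g.name, g.category) for g in self.genes if g.contains(pos)}

    def primary_region(self, pos: int) -> str:
        """The single reporting region for ``pos`` under the precedence rule."""
        categories = {cat for _, cat in self.classify_position(pos)}
        for cat in REGION_PRECEDENCE:
            if cat in categories:
                return cat
        return "other_noncoding"

    def gene_names(self, pos: int) -> list[str]:
        """Names of genes (not the D-loop) overlapping ``pos``, map order."""
        hits = self.classify_position(pos)
        return [g.name for g in self.genes if g.category != "dloop" and (g.name, g.category) in hits]

    def genes_in_complex(self, complex_id: str) -> list[str]:
        """Protein-coding genes of one OXPHOS complex (mtDNA encodes I/III/IV/V)."""
        if complex_id not in VALID_COMPLEXES:
            raise ValueError(
                f"unknown respiratory complex {complex_id!r}; mtDNA encodes {VALID_COMPLEXES}"
            )
        return [g.name for g in self.genes if g.category == "protein" and g.complex == complex_id]

    def reference_base(self, pos: int) -> str | None:
        if self.reference is None:
            return None
        if not (1 <= pos <= self.length):
            raise CoordinateError(f"position {pos} outside 1..{self.length}")
        return self.reference[pos - 1]
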