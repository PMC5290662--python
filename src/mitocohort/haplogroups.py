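"""Haplogroup assignment, haplogroup-conditional allele frequencies, rarity.

The classifier is a transparent marker-overlap scorer: for each candidate
haplogroup the score is the mean of marker recall (matched / expected
markers) and precision (matched / observed homoplasmic variants), a
Kulczynski-style similarity between the sample's homoplasmic variant set and
the haplogroup's defining-marker set. The marker table is a configuration
input, so a full Phylotree-derived table can be dropped in.

Population frequencies are per-individual carriage fractions within a
haplogroup (MpAF): the fraction of reference-panel individuals of that
haplogroup carrying the allele. A variant is *rare* when its MpAF within the
sample's haplogroup is strictly below 0.05, *novel* when absent from the
panel and from every supplied catalog, *common* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import MT_GENOME_LENGTH
from .exact import fisher_two_sided

Variant = tuple[int, str]  # (position, allele)

RARITY_MAX_MPAF = 0.05


class MarkerTableError(ValueError):
    pass


@dataclass
class HaplogroupMarkerTable:
    """Haplogroup label -> set of defining (position, alt) markers, plus tree."""

    markers: dict[str, set[Variant]]
    parents: dict[str, str]
    ref_alleles: dict[Variant, str]

    def __post_init__(self) -> None:
        if not self.markers:
            raise MarkerTableError("marker table is empty")
        for hg, mset in self.markers.items():
            for pos, _ in mset:
                if not (1 <= pos <= MT_GENOME_LENGTH):
                    raise MarkerTableError(f"{hg}: marker position {pos} off-genome")
        # parent links must be acyclic
        for hg in self.parents:
            seen = {hg}
            cur = hg
            while cur in self.parents and self.parents[cur]:
                cur = self.parents[cur]
                if cur in seen:
                    raise MarkerTableError(f"cycle in parent links at {hg}")
                seen.add(cur)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplogroupMarkerTable":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["haplogroup", "parent", "position", "ref", "alt"],
                         dtype={"haplogroup": str, "parent": str})
        markers: dict[str, set[Variant]] = {}
        parents: dict[str, str] = {}
        refs: dict[Variant, str] = {}
        for row in df.itertuples(index=False):
            hg = row.haplogroup
            markers.setdefault(hg, set()).add((int(row.position), row.alt))
            refs[(int(row.position), row.alt)] = row.ref
            if isinstance(row.parent, str) and row.parent:
                parents[hg] = row.parent
        return cls(markers=markers, parents=parents, ref_alleles=refs)

    @classmethod
    def default(cls) -> "HaplogroupMarkerTable":
        """The packaged simplified marker table (nine major haplogroups)."""
        with resources.as_file(
            resources.files("mitocohort.data").joinpath("haplogroup_markers.tsv")
        ) as p:
            return cls.from_tsv(p)


@dataclass(frozen=True)
class HaplogroupAssignment:
    sample_id: str
    haplogroup: str
    score: float
    matched: int
    expected: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score outside [0, 1]")
        if self.matched > self.expected:
            raise ValueError("matched markers exceed expected markers")


def assign_haplogroup(homoplasmic_calls: set[Variant], table: HaplogroupMarkerTable,
                      sample_id: str = "") -> HaplogroupAssignment:
    """Best-scoring haplogroup for a set of homoplasmic (position, allele) calls.

    score = (matched/expected + matched/observed) / 2. Ties go to the
    haplogroup with more defining markers, then the lexicographically
    smallest label.
    """
    observed = len(homoplasmic_calls)
    candidates = []
    for hg, mset in table.markers.items():
        matched = len(homoplasmic_calls & mset)
        recall = matched / len(mset) if mset else 0.0
        precision = matched / observed if observed else 0.0
        score = 0.5 * (recall + precision)
        candidates.append((score, len(mset), hg, matched))
    score, n_markers, hg, matched = min(
        candidates, key=lambda t: (-t[0], -t[1], t[2])
    )
    return HaplogroupAssignment(sample_id=sample_id, haplogroup=hg, score=score,
                                matched=matched, expected=n_markers)


@dataclass
class PopulationFrequencyTable:
    """MpAF lookup: (haplogroup, position, allele) -> carriage fraction."""

    freqs: dict[tuple[str, int, str], float]
    panel_sizes: dict[str, int]
    panel_variants: set[Variant]

    def mpaf(self, haplogroup: str, position: int, allele: str) -> float:
        return self.freqs.get((haplogroup, position, allele), 0.0)


def build_frequency_table(panel: dict[str, set[Variant]],
                          haplogroups: dict[str, str]) -> PopulationFrequencyTable:
    """Per-haplogroup per-individual carriage fractions from a reference panel.

    ``panel`` maps individual id -> set of rCRS-discordant (position, allele)
    genotypes; each individual counts once per allele regardless of read
    support. Every individual must carry a haplogroup label.
    """
    missing = set(panel) - set(haplogroups)
    if missing:
        raise ValueError(f"panel individuals without haplogroup label: {sorted(missing)[:5]}")
    sizes: dict[str, int] = {}
    carriers: dict[tuple[str, int, str], int] = {}
    all_variants: set[Variant] = set()
    for ind, variants in panel.items():
        hg = haplogroups[ind]
        sizes[hg] = sizes.get(hg, 0) + 1
        for pos, allele in variants:
            key = (hg, pos, allele)
            carriers[key] = carriers.get(key, 0) + 1
            all_variants.add((pos, allele))
    freqs = {key: n / sizes[key[0]] for key, n in carriers.items()}
    return PopulationFrequencyTable(freqs=freqs, panel_sizes=sizes,
                                    panel_variants=all_variants)


def classify_rarity(position: int, allele: str, haplogroup: str,
                    freq: PopulationFrequencyTable,
                    catalogs: dict[str, set[Variant]] | None = None) -> str:
    """common / rare / novel for one allele within the sample's haplogroup.

    Novel means absent from the panel and from every supplied catalog;
    rare means carried by < 5% of panel individuals of the haplogroup
    (MpAF exactly 0.05 is common).
    """
    catalogs = catalogs or {}
    variant = (position, allele)
    in_catalog = any(variant in cat for cat in catalogs.values())
    in_panel = variant in freq.panel_variants
    if not in_catalog and not in_panel:
        return "novel"
    if freq.mpaf(haplogroup, position, allele) < RARITY_MAX_MPAF:
        return "rare"
    return "common"


def panel_from_fasta(path: str | Path, reference: str) -> dict[str, set[Variant]]:
    """Genotype sets from a multi-FASTA of coordinate-aligned full sequences.

    Sequences must already be aligned to rCRS coordinates (same length as the
    reference); each position differing from the reference (ignoring N and
    gaps) becomes a (position, allele) genotype.
    """
    from Bio import SeqIO

    panel: dict[str, set[Variant]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if len(seq) != len(reference):
            raise ValueError(
                f"{record.id}: length {len(seq)} != reference {len(reference)}; "
                "sequences must be pre-aligned coordinate-wise"
            )
        panel[record.id] = {
            (i + 1, b) for i, (b, r) in enumerate(zip(seq, reference))
            if b != r and b in "ACGT"
        }
    return panel


def compare_haplogroup_frequencies(cohort_counts: dict[str, int],
                                   reference_counts: dict[str, int]) -> pd.DataFrame:
    """Cohort-vs-reference haplogroup composition tests.

    Returns one row per haplogroup with the carrier/non-carrier Fisher exact
    p-value, plus a final ``overall`` row holding the chi-square statistic
    and p-value on the full contingency table. Both inputs must cover the
    same label set.
    """
    if set(cohort_counts) != set(reference_counts):
        raise ValueError("cohort and reference cover different haplogroup labels")
    labels = sorted(cohort_counts)
    n_cohort = sum(cohort_counts.values())
    n_ref = sum(reference_counts.values())
    rows = []
    for hg in labels:
        a, c = cohort_counts[hg], reference_counts[hg]
        table = [[a, n_cohort - a], [c, n_ref - c]]
        rows.append({"haplogroup": hg, "cohort": a, "reference": c,
                     "cohort_frac": a / n_cohort if n_cohort else np.nan,
                     "reference_frac": c / n_ref if n_ref else np.nan,
                     "p": fisher_two_sided(table)})
    observed = np.array([[cohort_counts[h] for h in labels],
                         [reference_counts[h] for h in labels]])
    nonzero = observed.sum(axis=0) > 0
    observed = observed[:, nonzero]
    if observed.shape[1] < 2:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(observed)
    rows.append({"haplogroup": "overall", "cohort": n_cohort, "reference": n_ref,
                 "cohort_frac": np.nan, "reference_frac": np.nan, "p": p,
                 "chi2": chi2})
    return pd.DataFrame(rows)
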