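"""Heteroplasmy-aware variant calling from per-base mtDNA pileups.

For every non-reference allele at a site the heteroplasmic fraction
(HF, in percent) is the variant read count over the site depth (SNVs and
deletions) or over the 5' flanking read count (insertions). Sites pass the
quality filter when mean base quality >= 25 and read depth >= 5. Zygosity is
a pure function of HF:

* HF < 10        -> homoplasmic for the reference allele; the minor allele is
                    dropped from the variant list (optionally retained,
                    tagged ``low_level``, for exploration),
* 10 <= HF <= 90 -> heteroplasmic,
* HF > 90        -> homoplasmic for the alternate allele.

The 10/90 boundaries are inclusive on the heteroplasmic side: only strictly
sub-10% and supra-90% fractions are treated as homoplasmic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .annotation import MitoGenomeModel

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

HF_LOW = 10.0
HF_HIGH = 90.0
MIN_QS = 25.0
MIN_DEPTH = 5


class PileupFormatError(ValueError):
    """Malformed pileup input (duplicate/unsorted positions, bad counts)."""


class UndefinedHFError(ZeroDivisionError):
    """HF requested with a zero denominator."""


@dataclass(frozen=True)
class PileupSite:
    """Read support at one reference position.

    ``depth`` must equal the base counts plus deletion-supporting reads;
    insertion events are anchored 3' of this base and use ``flank5_reads``
    as their HF denominator.
    """

    position: int
    ref: str
    base_counts: dict[str, int]
    del_count: int = 0
    ins_events: dict[str, int] = field(default_factory=dict)
    flank5_reads: int = 0
    mean_qs: float = 0.0

    def __post_init__(self) -> None:
        if set(self.base_counts) - set(BASES):
            raise PileupFormatError(f"pos {self.position}: unknown base in counts")
        if any(n < 0 for n in self.base_counts.values()) or self.del_count < 0:
            raise PileupFormatError(f"pos {self.position}: negative read count")
        if self.mean_qs < 0:
            raise PileupFormatError(f"pos {self.position}: negative mean quality")
        for seq, n in self.ins_events.items():
            if n > self.flank5_reads:
                raise PileupFormatError(
                    f"pos {self.position}: insertion {seq} support exceeds flank reads"
                )

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.del_count


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    position: int
    ref: str
    alt: str
    kind: str  # SNV | insertion | deletion
    hf: float  # percent, [0, 100]
    depth: int
    qs: float
    zygosity: str  # heteroplasmic | homoplasmic_alt | low_level
    gene_names: tuple[str, ...] = ()
    region: str = "other_noncoding"
    rarity: str = "unset"  # common | rare | novel | unset
    patho_score: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.hf <= 100.0):
            raise ValueError(f"HF {self.hf} outside [0, 100]")
        if self.kind == "SNV" and (self.ref == self.alt or len(self.alt) != 1):
            raise ValueError("SNV requires a single alternate base differing from ref")


@dataclass(frozen=True)
class CallParams:
    """Thresholds of the calling stage; defaults are the pipeline standard."""

    hf_low: float = HF_LOW
    hf_high: float = HF_HIGH
    min_qs: float = MIN_QS
    min_depth: int = MIN_DEPTH
    keep_low_level: bool = False


def compute_hf(variant_reads: int, denominator_reads: int, kind: str) -> float:
    """Heteroplasmic fraction in percent.

    The denominator is the site depth for SNVs and deletions, and the
    5' flanking read count for insertions; the caller supplies the right one.
    No rounding is applied here — report writers round.
    """
    if denominator_reads <= 0:
        raise UndefinedHFError(f"HF undefined with denominator {denominator_reads}")
    if variant_reads > denominator_reads:
        raise PileupFormatError(
            f"variant reads ({variant_reads}) exceed denominator ({denominator_reads})"
        )
    if variant_reads < 0:
        raise PileupFormatError("negative variant read count")
    return 100.0 * variant_reads / denominator_reads


def passes_filters(site: PileupSite, params: CallParams = CallParams()) -> bool:
    """Site-level inclusion filter: mean quality >= 25 and depth >= 5."""
    return site.mean_qs >= params.min_qs and site.depth >= params.min_depth


def classify_zygosity(hf: float, params: CallParams = CallParams()) -> str:
    """Map an HF percentage to homoplasmic_ref / heteroplasmic / homoplasmic_alt."""
    if not (0.0 <= hf <= 100.0):
        raise ValueError(f"HF {hf} outside [0, 100]")
    if hf < params.hf_low:
        return "homoplasmic_ref"
    if hf > params.hf_high:
        return "homoplasmic_alt"
    return "heteroplasmic"


def call_sample(pileup: list[PileupSite], model: MitoGenomeModel, sample_id: str,
                params: CallParams = CallParams()) -> list[VariantCall]:
    """Filtered, annotated variant calls for one sample.

    Emits one call per qualifying alternate allele (SNV per base, one per
    distinct insertion sequence, one deletion allele per site). Alleles whose
    HF classifies as homoplasmic-reference are suppressed unless
    ``params.keep_low_level``. Sites whose reference base disagrees with the
    genome model are skipped with a warning; duplicate or unsorted positions
    are an input error.
    """
    last_pos = 0
    calls: list[VariantCall] = []
    for site in pileup:
        if site.position <= last_pos:
            raise PileupFormatError(
                f"pileup not sorted or duplicate position at {site.position}"
            )
        last_pos = site.position
        model_ref = model.reference_base(site.position)
        if model_ref is not None and model_ref != site.ref:
            logger.warning("sample %s pos %d: pileup ref %s != model ref %s; site skipped",
                           sample_id, site.position, site.ref, model_ref)
            continue
        if not passes_filters(site, params):
            continue
        genes = tuple(model.gene_names(site.position))
        region = model.primary_region(site.position)

        def emit(alt: str, kind: str, reads: int, denom: int) -> None:
            hf = compute_hf(reads, denom, kind)
            zyg = classify_zygosity(hf, params)
            if zyg == "homoplasmic_ref":
                if not params.keep_low_level or reads == 0:
                    return
                zyg = "low_level"
            calls.append(VariantCall(
                sample_id=sample_id, position=site.position, ref=site.ref, alt=alt,
                kind=kind, hf=hf, depth=site.depth, qs=site.mean_qs, zygosity=zyg,
                gene_names=genes, region=region,
            ))

        for base in BASES:
            reads = site.base_counts.get(base, 0)
            if base != site.ref and reads > 0:
                emit(base, "SNV", reads, site.depth)
        if site.del_count > 0:
            emit("-", "deletion", site.del_count, site.depth)
        for seq in sorted(site.ins_events):
            reads = site.ins_events[seq]
            if reads > 0 and site.flank5_reads > 0:
                emit(site.ref + seq, "insertion", reads, site.flank5_reads)
    return calls


def annotate_rarity(calls: list[VariantCall], rarity_of) -> list[VariantCall]:
    """Return calls with ``rarity`` set by ``rarity_of(position, alt)``."""
    return [replace(c, rarity=rarity_of(c.position, c.alt)) for c in calls]


# ---------------------------------------------------------------------------
# Pileup TSV dialect
# ---------------------------------------------------------------------------

PILEUP_COLUMNS = ["position", "ref", "A", "C", "G", "T", "del", "ins_json",
                  "flank5", "mean_qs"]


def read_pileup_tsv(path) -> list[PileupSite]:
    """Read the documented pileup TSV dialect (one row per covered position)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"ins_json": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise PileupFormatError(f"pileup TSV missing columns: {sorted(missing)}")
    sites = []
    for row in df.to_dict("records"):
        raw_ins = row["ins_json"]
        ins = json.loads(raw_ins) if isinstance(raw_ins, str) and raw_ins else {}
        sites.append(PileupSite(
            position=int(row["position"]), ref=str(row["ref"]),
            base_counts={b: int(row[b]) for b in BASES},
            del_count=int(row["del"]),
            ins_events={k: int(v) for k, v in ins.items()},
            flank5_reads=int(row["flank5"]), mean_qs=float(row["mean_qs"]),
        ))
    return sites


def write_pileup_tsv(sites: list[PileupSite], path) -> None:
    rows = [{
        "position": s.position, "ref": s.ref,
        **{b: s.base_counts.get(b, 0) for b in BASES},
        "del": s.del_count,
        "ins_json": json.dumps(s.ins_events, sort_keys=True) if s.ins_events else "",
        "flank5": s.flank5_reads, "mean_qs": round(s.mean_qs, 2),
    } for s in sites]
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


CALL_COLUMNS = ["sample_id", "position", "ref", "alt", "kind", "hf", "depth",
                "qs", "zygosity", "genes", "region", "rarity", "patho_score"]


def calls_to_frame(calls: list[VariantCall]) -> pd.DataFrame:
    """Flat TSV-ready mirror of a call list."""
    if not calls:
        return pd.DataFrame(columns=CALL_COLUMNS)
    return pd.DataFrame([{
        "sample_id": c.sample_id, "position": c.position, "ref": c.ref, "alt": c.alt,
        "kind": c.kind, "hf": round(c.hf, 1), "depth": c.depth, "qs": round(c.qs, 1),
        "zygosity": c.zygosity, "genes": ",".join(c.gene_names), "region": c.region,
        "rarity": c.rarity,
        "patho_score": "" if c.patho_score is None else c.patho_score,
    } for c in calls])


def write_vcf(calls: list[VariantCall], path, sample_id: str | None = None) -> None:
    """Write calls as a minimal single-sample VCF 4.2 with pipeline INFO fields."""
    header = [
        "##fileformat=VCFv4.2",
        "##source=mitocohort",
        "##contig=<ID=chrM,length=16569>",
        '##INFO=<ID=HF,Number=1,Type=Float,Description="Heteroplasmic fraction, percent">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=QS,Number=1,Type=Float,Description="Mean base quality">',
        '##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity class">',
        '##INFO=<ID=GENE,Number=.,Type=String,Description="Overlapping genes">',
        '##INFO=<ID=REGION,Number=1,Type=String,Description="Primary region">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    lines = list(header)
    for c in sorted(calls, key=lambda c: (c.position, c.alt)):
        if sample_id is not None and c.sample_id != sample_id:
            continue
        if c.kind == "deletion":
            ref, alt = c.ref, "<DEL>"
        else:
            ref, alt = c.ref, c.alt
        info = (f"HF={c.hf:.1f};DP={c.depth};QS={c.qs:.1f};ZYG={c.zygosity};"
                f"GENE={','.join(c.gene_names) or '.'};REGION={c.region}")
        lines.append(f"chrM\t{c.position}\t.\t{ref}\t{alt}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
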