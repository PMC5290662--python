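"""Synthetic mtDNA cohorts with known ground truth.

Generates the statistical structure the analysis pipeline assumes: samples
carry a haplogroup backbone of homoplasmic markers plus private germline
homoplasmies, somatic heteroplasmies with fractions drawn from a rescaled
Beta on [0.10, 0.90], per-position read pileups with binomial allele
sampling at configurable depth, and per-group relative copy-number ratios on
a log-normal scale. Group sizes and age distributions default to the brain
cohort the pipeline was designed around (e.g. AD n=282, age at death
78.1 +/- 11.6; Controls n=351, 78.1 +/- 12.0); sequencing defaults to the
observed mean mtDNA depth of 289 (sd 169.8, floor 66) and base quality
36.8 +/- 0.25.

Every sample owns a random stream keyed by (seed, sample id), so cohorts
are reproducible under subsetting, and the same seed yields byte-identical
outputs.

The packaged reference sequence is *synthetic*: a deterministic pseudo-random
genome of rCRS length, pinned to the marker table's reference alleles at
marker positions. Analyses that need real rCRS bases should load the actual
NC_012920 FASTA via ``MitoGenomeModel.default(reference_fasta=...)``.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .annotation import MT_GENOME_LENGTH, MitoGenomeModel
from .burden import SampleMeta
from .haplogroups import HaplogroupMarkerTable
from .variants import BASES, PileupSite

_REFERENCE_SEED = 20170202  # fixed: the synthetic reference is part of the package


@dataclass(frozen=True)
class GroupSpec:
    """Per-group cohort structure: size, ages, sex mix, copy-number model.

    ``cn_mean``/``cn_sd`` are the natural-scale mean and sd of the relative
    copy-number ratio; samples draw from the log-normal with those moments.
    """

    n: int
    age_mean: float
    age_sd: float
    female_frac: float = 0.5
    cn_mean: float = 10.0
    cn_sd: float = 5.0

    def lognormal_params(self) -> tuple[float, float]:
        sigma2 = math.log(1.0 + (self.cn_sd / self.cn_mean) ** 2)
        mu = math.log(self.cn_mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2)


def default_groups() -> dict[str, GroupSpec]:
    """Cohort defaults: sizes, age-at-death distributions, and sex mix.

    Copy-number means for CJD reflect the vCJD/other split handled in
    ``generate_cohort``; groups without a published mean use the
    control-like convention (mean 10, sd 5), with AD set lower (mean 8)
    to carry a disease effect.
    """
    return {
        "AD": GroupSpec(n=282, age_mean=78.1, age_sd=11.6, female_frac=0.539,
                        cn_mean=8.0, cn_sd=5.0),
        "CJD": GroupSpec(n=181, age_mean=55.1, age_sd=19.2, female_frac=0.530,
                         cn_mean=10.03, cn_sd=7.67),
        "Control": GroupSpec(n=351, age_mean=78.1, age_sd=12.0, female_frac=0.558),
        "DLB-PD": GroupSpec(n=89, age_mean=75.1, age_sd=8.5, female_frac=0.348),
        "FTD-ALS": GroupSpec(n=236, age_mean=64.4, age_sd=11.5, female_frac=0.415),
        "YoungControl": GroupSpec(n=110, age_mean=41.4, age_sd=9.7, female_frac=0.273),
        "Other": GroupSpec(n=114, age_mean=72.7, age_sd=16.7, female_frac=0.403),
    }


#: Rough UK haplogroup mixture for the simplified marker table.
DEFAULT_HAPLOGROUP_WEIGHTS = {
    "H": 0.44, "U": 0.11, "K": 0.08, "J": 0.11, "T": 0.10,
    "V": 0.05, "W": 0.04, "X": 0.04, "I": 0.03,
}


@dataclass
class SimulationConfig:
    groups: dict[str, GroupSpec] = field(default_factory=default_groups)
    haplogroup_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOGROUP_WEIGHTS))
    # germline model: private homoplasmies per sample (Poisson mean); with
    # ~7 markers this puts total homoplasmies near the observed 22.9/sample
    private_variant_mean: float = 16.0
    # heteroplasmy model; Poisson mean 0.39 makes P(>=1) ~ 32.3%
    het_mean: float = 0.39
    het_age_slope: float = 0.0  # per year, log scale; 0 = age-independent
    het_intercept: float = math.log(0.39)  # used only when the slope is non-zero
    hf_beta_a: float = 1.2
    hf_beta_b: float = 2.4
    hf_min: float = 0.10
    hf_max: float = 0.90
    # regional placement of somatic heteroplasmies (observed cohort mix:
    # 55.7% D-loop, 33.3% coding, 4.8% rRNA, 6.2% tRNA); None = uniform
    het_region_weights: dict[str, float] | None = field(default_factory=lambda: {
        "dloop": 0.557, "protein": 0.333, "rRNA": 0.048, "tRNA": 0.062})
    # sequencing model (pileup depths and qualities)
    mt_depth_mean: float = 289.0
    mt_depth_sd: float = 169.8
    mt_depth_min: float = 66.0
    qs_mean: float = 36.8
    qs_sd: float = 0.25
    error_rate: float = 0.001
    n_reference_sites: int = 50
    # depth-summary model (copy-number input)
    nuclear_depth_mean: float = 30.0
    nuclear_depth_sd: float = 3.0
    depth_noise_sd: float = 0.02  # log-scale noise on the emitted mt mean depth
    # CJD subtype split: vCJD cases drawn with their own copy-number model
    cjd_vcjd_n: int = 40
    vcjd_cn_mean: float = 4.14
    vcjd_cn_sd: float = 2.96
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.hf_min < self.hf_max <= 1.0):
            raise ValueError("HF support must satisfy 0 <= hf_min < hf_max <= 1")
        for name, value in [("private_variant_mean", self.private_variant_mean),
                            ("het_mean", self.het_mean),
                            ("error_rate", self.error_rate),
                            ("mt_depth_mean", self.mt_depth_mean)]:
            if value < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(g.n < 0 for g in self.groups.values()):
            raise ValueError("group sizes must be non-negative")


@dataclass(frozen=True)
class TruthVariant:
    position: int
    ref: str
    alt: str
    hf: float  # fraction in (0, 1]; germline variants have 1.0
    germline: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.hf <= 1.0):
            raise ValueError("truth HF must lie in (0, 1]")
        if self.germline and self.hf != 1.0:
            raise ValueError("germline variants are homoplasmic (HF 1)")


@dataclass(frozen=True)
class TruthSet:
    sample_id: str
    haplogroup: str
    variants: tuple[TruthVariant, ...]
    cn_ratio: float
    mt_depth_mean: float  # this sample's expected per-position pileup depth


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """The sample's private random stream, stable under cohort subsetting."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])


def synthetic_reference(marker_table: HaplogroupMarkerTable | None = None) -> str:
    """Deterministic synthetic genome of rCRS length.

    Pseudo-random bases from a fixed internal seed, overwritten with the
    marker table's reference alleles at marker positions so that every
    marker is reference-discordant. A stand-in for the real NC_012920
    sequence, which users can supply as FASTA instead.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=MT_GENOME_LENGTH)
    table = marker_table or HaplogroupMarkerTable.default()
    for (pos, _alt), ref in table.ref_alleles.items():
        seq[pos - 1] = ref
    return "".join(seq)


def synthetic_model(marker_table: HaplogroupMarkerTable | None = None) -> MitoGenomeModel:
    """The packaged gene map over the synthetic reference sequence."""
    model = MitoGenomeModel.default()
    model.reference = synthetic_reference(marker_table)
    return model


_REGION_POSITIONS: dict[str, np.ndarray] | None = None


def _region_positions() -> dict[str, np.ndarray]:
    """Primary-region position bins of the packaged gene map (cached)."""
    global _REGION_POSITIONS
    if _REGION_POSITIONS is None:
        model = MitoGenomeModel.default()
        bins: dict[str, list[int]] = {}
        for pos in range(1, MT_GENOME_LENGTH + 1):
            bins.setdefault(model.primary_region(pos), []).append(pos)
        _REGION_POSITIONS = {k: np.array(v) for k, v in bins.items()}
    return _REGION_POSITIONS


def _draw_het_position(rng: np.random.Generator, config: SimulationConfig,
                       used: set[int]) -> int:
    if config.het_region_weights is None:
        pos = int(rng.integers(1, MT_GENOME_LENGTH + 1))
        while pos in used:
            pos = int(rng.integers(1, MT_GENOME_LENGTH + 1))
        return pos
    bins = _region_positions()
    regions = sorted(config.het_region_weights)
    weights = np.array([config.het_region_weights[r] for r in regions])
    weights = weights / weights.sum()
    region = regions[rng.choice(len(regions), p=weights)]
    candidates = bins[region]
    pos = int(candidates[rng.integers(len(candidates))])
    while pos in used:
        pos = int(candidates[rng.integers(len(candidates))])
    return pos


def _other_base(rng: np.random.Generator, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[rng.integers(len(choices))]


def _draw_hf(rng: np.random.Generator, config: SimulationConfig) -> float:
    return config.hf_min + (config.hf_max - config.hf_min) * rng.beta(
        config.hf_beta_a, config.hf_beta_b)


def generate_cohort(config: SimulationConfig,
                    marker_table: HaplogroupMarkerTable | None = None,
                    reference: str | None = None,
                    ) -> tuple[list[SampleMeta], list[TruthSet]]:
    """Sample metadata and ground truth for a full cohort.

    Group sizes are exact; ages are normal draws truncated at 1 year.
    Germline variants are the assigned haplogroup's markers plus Poisson
    private homoplasmies; somatic heteroplasmies follow the configured count
    and HF models (optionally age-dependent on the log scale).
    """
    table = marker_table or HaplogroupMarkerTable.default()
    ref = reference or synthetic_reference(table)
    hg_labels = sorted(config.haplogroup_weights)
    weights = np.array([config.haplogroup_weights[h] for h in hg_labels], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("haplogroup weights must sum to a positive value")
    weights = weights / weights.sum()

    # cohort-expected copy-number ratio: pileup depth scales with each
    # sample's true ratio relative to this mean
    total_n = sum(g.n for g in config.groups.values())
    expected_ratio = 0.0
    for group, spec in config.groups.items():
        mean = spec.cn_mean
        if group == "CJD" and spec.n > 0:
            v_n = min(config.cjd_vcjd_n, spec.n)
            mean = (v_n * config.vcjd_cn_mean + (spec.n - v_n) * spec.cn_mean) / spec.n
        expected_ratio += spec.n * mean
    expected_ratio = expected_ratio / total_n if total_n else 1.0

    samples: list[SampleMeta] = []
    truths: list[TruthSet] = []
    for group in sorted(config.groups):
        spec = config.groups[group]
        mu, sigma = spec.lognormal_params()
        for i in range(spec.n):
            sid = f"{group}-{i:04d}"
            rng = sample_rng(config.seed, sid)
            age = max(1.0, rng.normal(spec.age_mean, spec.age_sd))
            sex = "F" if rng.random() < spec.female_frac else "M"
            cjd_subtype = None
            if group == "CJD":
                cjd_subtype = "vCJD" if i < config.cjd_vcjd_n else "other"
                if cjd_subtype == "vCJD":
                    v_sigma2 = math.log(1 + (config.vcjd_cn_sd / config.vcjd_cn_mean) ** 2)
                    mu_i, sigma_i = (math.log(config.vcjd_cn_mean) - v_sigma2 / 2,
                                     math.sqrt(v_sigma2))
                else:
                    mu_i, sigma_i = mu, sigma
            else:
                mu_i, sigma_i = mu, sigma
            ratio = float(rng.lognormal(mu_i, sigma_i))

            hg = hg_labels[rng.choice(len(hg_labels), p=weights)]
            used = set()
            variants: list[TruthVariant] = []
            for pos, alt in sorted(table.markers[hg]):
                variants.append(TruthVariant(pos, ref[pos - 1], alt, 1.0, True))
                used.add(pos)
            n_private = rng.poisson(config.private_variant_mean)
            for _ in range(n_private):
                pos = int(rng.integers(1, MT_GENOME_LENGTH + 1))
                while pos in used:
                    pos = int(rng.integers(1, MT_GENOME_LENGTH + 1))
                used.add(pos)
                variants.append(TruthVariant(pos, ref[pos - 1],
                                             _other_base(rng, ref[pos - 1]), 1.0, True))
            lam = (config.het_mean if config.het_age_slope == 0.0
                   else math.exp(config.het_intercept + config.het_age_slope * age))
            n_het = rng.poisson(lam)
            for _ in range(n_het):
                pos = _draw_het_position(rng, config, used)
                used.add(pos)
                variants.append(TruthVariant(pos, ref[pos - 1],
                                             _other_base(rng, ref[pos - 1]),
                                             float(_draw_hf(rng, config)), False))
            depth = max(config.mt_depth_min,
                        rng.normal(config.mt_depth_mean, config.mt_depth_sd)
                        * ratio / expected_ratio)
            samples.append(SampleMeta(sample_id=sid, group=group, age_death=age,
                                      sex=sex, region="cerebellum",
                                      cjd_subtype=cjd_subtype))
            truths.append(TruthSet(sample_id=sid, haplogroup=hg,
                                   variants=tuple(sorted(variants,
                                                         key=lambda v: (v.position, v.alt))),
                                   cn_ratio=ratio, mt_depth_mean=float(depth)))
    return samples, truths


def generate_pileup(truth: TruthSet, config: SimulationConfig,
                    reference: str | None = None) -> list[PileupSite]:
    """Per-site read pileups for one sample's truth set.

    Sites are the truth variant positions plus ``n_reference_sites``
    reference-matching positions. Depth is Poisson around the sample's mean
    pileup depth; variant reads are Binomial(depth, HF); sequencing errors
    land uniformly on non-truth alleles at the configured per-read rate.
    """
    ref = reference or synthetic_reference()
    rng = sample_rng(config.seed, truth.sample_id + ":pileup")
    by_pos: dict[int, list[TruthVariant]] = {}
    for v in truth.variants:
        by_pos.setdefault(v.position, []).append(v)
    positions = set(by_pos)
    while len(positions) < len(by_pos) + config.n_reference_sites:
        positions.add(int(rng.integers(1, MT_GENOME_LENGTH + 1)))

    sites = []
    for pos in sorted(positions):
        depth = int(rng.poisson(truth.mt_depth_mean))
        ref_base = ref[pos - 1]
        counts = {b: 0 for b in BASES}
        del_count = 0
        ins_events: dict[str, int] = {}
        remaining = depth
        for v in by_pos.get(pos, []):
            n_alt = int(rng.binomial(remaining, min(v.hf, 1.0))) if remaining else 0
            if v.alt == "-":
                del_count += n_alt
            elif v.alt.startswith("+"):
                ins_events[v.alt[1:]] = n_alt
                n_alt = 0  # insertions do not consume site depth
            else:
                counts[v.alt] += n_alt
            remaining -= n_alt
        # sequencing noise on the remaining (reference) reads
        n_err = int(rng.binomial(remaining, config.error_rate)) if remaining else 0
        for _ in range(n_err):
            counts[_other_base(rng, ref_base)] += 1
        counts[ref_base] += remaining - n_err
        sites.append(PileupSite(
            position=pos, ref=ref_base, base_counts=counts, del_count=del_count,
            ins_events=ins_events, flank5_reads=depth if ins_events else 0,
            mean_qs=float(max(0.0, rng.normal(config.qs_mean, config.qs_sd))),
        ))
    return sites


def generate_depth_summary(truth: TruthSet, config: SimulationConfig
                           ) -> tuple[float, float]:
    """(mean mt depth, mean nuclear depth) whose expected ratio is the truth.

    Nuclear depth is normal (truncated positive); the emitted mt mean is
    ratio x nuclear with optional log-normal noise, so a zero-noise config
    reproduces the true ratio exactly.
    """
    rng = sample_rng(config.seed, truth.sample_id + ":depth")
    nuclear = config.nuclear_depth_mean
    if config.nuclear_depth_sd > 0:
        nuclear = max(1.0, rng.normal(config.nuclear_depth_mean, config.nuclear_depth_sd))
    mt_mean = truth.cn_ratio * nuclear
    if config.depth_noise_sd > 0:
        mt_mean *= math.exp(rng.normal(0.0, config.depth_noise_sd))
    return float(mt_mean), float(nuclear)


def generate_panel(config: SimulationConfig, n_individuals: int = 500,
                   marker_table: HaplogroupMarkerTable | None = None,
                   reference: str | None = None,
                   ) -> tuple[dict[str, set], dict[str, str]]:
    """Reference population panel: genotype sets plus haplogroup labels.

    Panel individuals carry their haplogroup's markers plus private
    homoplasmies at the germline rate, mirroring the cohort generator.
    """
    table = marker_table or HaplogroupMarkerTable.default()
    ref = reference or synthetic_reference(table)
    hg_labels = sorted(config.haplogroup_weights)
    weights = np.array([config.haplogroup_weights[h] for h in hg_labels], dtype=float)
    weights = weights / weights.sum()
    panel: dict[str, set] = {}
    labels: dict[str, str] = {}
    for i in range(n_individuals):
        pid = f"panel-{i:05d}"
        rng = sample_rng(config.seed, pid)
        hg = hg_labels[rng.choice(len(hg_labels), p=weights)]
        genotype = set(table.markers[hg])
        for _ in range(rng.poisson(config.private_variant_mean)):
            pos = int(rng.integers(1, MT_GENOME_LENGTH + 1))
            genotype.add((pos, _other_base(rng, ref[pos - 1])))
        panel[pid] = genotype
        labels[pid] = hg
    return panel, labels


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def truths_to_json(truths: list[TruthSet], path: str | Path) -> None:
    payload = [{
        "sample_id": t.sample_id, "haplogroup": t.haplogroup,
        "cn_ratio": t.cn_ratio, "mt_depth_mean": t.mt_depth_mean,
        "variants": [asdict(v) for v in t.variants],
    } for t in truths]
    Path(path).write_text(json.dumps(payload, indent=1))


def truths_from_json(path: str | Path) -> list[TruthSet]:
    payload = json.loads(Path(path).read_text())
    return [TruthSet(
        sample_id=t["sample_id"], haplogroup=t["haplogroup"],
        variants=tuple(TruthVariant(**v) for v in t["variants"]),
        cn_ratio=t["cn_ratio"], mt_depth_mean=t["mt_depth_mean"],
    ) for t in payload]
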