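"""Case-control association machinery for mtDNA variant burden.

A sample is a *carrier* of a unit (single variant, gene, or respiratory
complex) when it holds at least one qualifying call in that unit; carrier
counts form 2x2 tables tested with the two-sided Fisher exact test
(point-probability rule). The family-wise threshold for gene burden is
Bonferroni over the 37 mtDNA genes by default: 0.05 / 37 ~= 0.0014.

Heteroplasmy-vs-age uses a Poisson log-linear model
count_i ~ Poisson(exp(b0 + b1 * age_i)) fitted by IRLS with a Wald test on
the age slope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotation import MitoGenomeModel
from .exact import DegenerateTableWarning, fisher_two_sided, mann_whitney
from .variants import VariantCall

GROUPS = ("AD", "CJD", "Control", "DLB-PD", "FTD-ALS", "YoungControl", "Other")

#: Gene-burden multiple-testing family: the 37 mtDNA genes.
GENE_FAMILY_SIZE = 37


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str
    age_death: float | None = None
    age_onset: float | None = None
    sex: str = ""  # F | M
    region: str = ""
    cjd_subtype: str | None = None  # vCJD | other

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.age_death is not None and not self.age_death > 0:
            raise ValueError("age_death must be positive when present")


@dataclass(frozen=True)
class BurdenFilters:
    """Which calls qualify a sample as a carrier."""

    zygosity: frozenset[str] = frozenset({"homoplasmic_alt"})
    rarity: frozenset[str] | None = None  # None = any
    age_predicate: Callable[[SampleMeta], bool] | None = None
    nonsynonymous_only: bool = False

    def call_qualifies(self, call: VariantCall) -> bool:
        if call.zygosity not in self.zygosity:
            return False
        if self.rarity is not None and call.rarity not in self.rarity:
            return False
        if self.nonsynonymous_only and call.patho_score is None:
            # nonsynonymous calls are the scored ones in this pipeline
            return False
        return True


@dataclass(frozen=True)
class BurdenResult:
    unit: str  # variant | gene | complex
    unit_id: str
    stratum: str
    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers
    p: float
    alpha_corrected: float
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in 2x2 table")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p-value outside (0, 1]")
        object.__setattr__(self, "significant", self.p < self.alpha_corrected)


@dataclass(frozen=True)
class PoissonAgeFit:
    intercept: float
    slope: float
    slope_se: float
    p_slope: float
    n: int
    all_zero: bool = False


def _unit_matcher(unit: str, unit_id: str, model: MitoGenomeModel | None
                  ) -> Callable[[VariantCall], bool]:
    if unit == "gene":
        return lambda c: unit_id in c.gene_names
    if unit == "complex":
        if model is None:
            raise ValueError("complex-level burden needs a genome model")
        members = set(model.genes_in_complex(unit_id))
        return lambda c: bool(members.intersection(c.gene_names))
    if unit == "variant":
        pos_s, _, alt = unit_id.partition(":")
        pos = int(pos_s)
        return lambda c: c.position == pos and c.alt == alt
    raise ValueError(f"unknown burden unit {unit!r}")


def carrier_table(calls: Iterable[VariantCall], samples: Sequence[SampleMeta],
                  unit: str, unit_id: str, case_group: str, control_group: str,
                  filters: BurdenFilters = BurdenFilters(),
                  model: MitoGenomeModel | None = None) -> tuple[int, int, int, int]:
    """2x2 carrier counts (case carriers, case non, control carriers, control non).

    A sample counts once however many qualifying calls it holds. Variant
    unit ids are ``"position:alt"`` strings.
    """
    if case_group == control_group:
        raise ValueError("case and control groups must be disjoint")
    matches = _unit_matcher(unit, unit_id, model)
    carriers = {c.sample_id for c in calls if filters.call_qualifies(c) and matches(c)}
    counts = {}
    for grp in (case_group, control_group):
        members = [s for s in samples if s.group == grp
                   and (filters.age_predicate is None or filters.age_predicate(s))]
        n = len(members)
        k = sum(1 for s in members if s.sample_id in carriers)
        counts[grp] = (k, n - k)
        if n == 0:
            warnings.warn(f"group {grp} empty after filtering; burden test degenerate",
                          DegenerateTableWarning, stacklevel=2)
    a, b = counts[case_group]
    c, d = counts[control_group]
    return a, b, c, d


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def burden_test(calls, samples, unit, unit_id, case_group, control_group,
                filters: BurdenFilters = BurdenFilters(),
                model: MitoGenomeModel | None = None,
                alpha: float = 0.05, family_size: int = GENE_FAMILY_SIZE,
                stratum: str = "all") -> BurdenResult:
    a, b, c, d = carrier_table(calls, samples, unit, unit_id, case_group,
                               control_group, filters, model)
    p = fisher_two_sided([[a, b], [c, d]])
    return BurdenResult(unit=unit, unit_id=unit_id, stratum=stratum, a=a, b=b,
                        c=c, d=d, p=p,
                        alpha_corrected=bonferroni_threshold(alpha, family_size))


def gene_burden_scan(calls, samples, model: MitoGenomeModel, case_group: str,
                     control_group: str, filters: BurdenFilters = BurdenFilters(),
                     alpha: float = 0.05, stratum: str = "all") -> list[BurdenResult]:
    """One Fisher carrier test per mtDNA gene, Bonferroni over the 37 genes."""
    genes = [g.name for g in model.genes if g.category in ("protein", "tRNA", "rRNA")]
    return [burden_test(calls, samples, "gene", g, case_group, control_group,
                        filters, model, alpha, len(genes), stratum) for g in genes]


def heteroplasmy_summary(calls: Iterable[VariantCall], samples: Sequence[SampleMeta]
                         ) -> dict:
    """Cohort heteroplasmy descriptives over the given samples.

    Calls are restricted to heteroplasmic zygosity; fractions are over all
    samples in scope; the region breakdown uses primary regions and sums to
    100% of heteroplasmic calls.
    """
    if not samples:
        raise ValueError("empty sample set")
    sample_ids = {s.sample_id for s in samples}
    het = [c for c in calls if c.zygosity == "heteroplasmic" and c.sample_id in sample_ids]
    per_sample = {sid: 0 for sid in sample_ids}
    for c in het:
        per_sample[c.sample_id] += 1
    counts = np.array(list(per_sample.values()))
    out = {
        "n_samples": len(samples),
        "n_het_calls": len(het),
        "mean_het_count": float(counts.mean()),
        "sd_het_count": float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        "carrier_fraction_pct": 100.0 * float((counts > 0).mean()),
        "mean_hf": float(np.mean([c.hf for c in het])) if het else None,
    }
    breakdown = {}
    if het:
        regions = pd.Series([c.region for c in het])
        breakdown = (100.0 * regions.value_counts() / len(het)).to_dict()
    out["region_breakdown_pct"] = breakdown
    return out


def proportion_pct(carriers: int, total: int, ndigits: int = 1) -> float:
    """Carrier percentage as reported (one decimal by default)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * carriers / total, ndigits)


def poisson_age_model(counts: Sequence[int], ages: Sequence[float]) -> PoissonAgeFit:
    """Poisson log-linear fit of per-sample variant count on age.

    IRLS (relative tolerance 1e-8, max 100 iterations) with a Wald p-value
    for the slope. All-zero counts leave the slope undefined and are flagged
    rather than fitted.
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(counts) != len(ages):
        raise ValueError("counts and ages differ in length")
    if len(np.unique(ages)) < 2:
        raise ValueError("need at least 2 distinct ages for a finite fit")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be non-negative integers")
    if np.all(counts == 0):
        return PoissonAgeFit(intercept=-math.inf, slope=math.nan, slope_se=math.nan,
                             p_slope=math.nan, n=len(counts), all_zero=True)
    X = sm.add_constant(ages)
    fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-8)
    if not fit.converged:
        raise RuntimeError(f"IRLS did not converge in 100 iterations: {fit.summary()}")
    return PoissonAgeFit(intercept=float(fit.params[0]), slope=float(fit.params[1]),
                         slope_se=float(fit.bse[1]), p_slope=float(fit.pvalues[1]),
                         n=len(counts))


def score_summary(calls: Iterable[VariantCall], samples: Sequence[SampleMeta],
                  group_a: str, group_b: str) -> dict | None:
    """Mean per-sample pathogenicity score by group, with Mann-Whitney p.

    Scores are aggregated per sample (mean over that sample's scored calls)
    and the two groups of per-sample means are compared. Returns None (with
    a warning) when either group has no scored calls.
    """
    by_sample: dict[str, list[float]] = {}
    for c in calls:
        if c.patho_score is not None:
            by_sample.setdefault(c.sample_id, []).append(c.patho_score)
    means = {}
    for grp in (group_a, group_b):
        vals = [float(np.mean(by_sample[s.sample_id])) for s in samples
                if s.group == grp and s.sample_id in by_sample]
        if not vals:
            warnings.warn(f"no scored calls in group {grp}; score comparison skipped",
                          DegenerateTableWarning, stacklevel=2)
            return None
        means[grp] = vals
    _, p = mann_whitney(means[group_a], means[group_b])
    return {
        "mean_score": {grp: float(np.mean(v)) for grp, v in means.items()},
        "n": {grp: len(v) for grp, v in means.items()},
        "p": p,
    }


def burden_report(results: list[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "unit": r.unit, "unit_id": r.unit_id, "stratum": r.stratum,
        "case_carriers": r.a, "case_noncarriers": r.b,
        "control_carriers": r.c, "control_noncarriers": r.d,
        "p": float(f"{r.p:.3g}"), "alpha_corrected": float(f"{r.alpha_corrected:.3g}"),
        "significant": r.significant,
    } for r in results])
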