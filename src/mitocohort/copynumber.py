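"""Relative mtDNA copy number from sequencing depth.

The relative copy number of a sample is the ratio of its mean mtDNA read
depth (over all 16,569 positions, zero-depth positions included) to its mean
nuclear exome depth. It is a relative abundance proxy, not an absolute
genomes-per-cell figure. Group comparisons use the Mann-Whitney test (exact
for small groups), age association uses Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .annotation import MT_GENOME_LENGTH
from .burden import SampleMeta
from .exact import DegenerateTableWarning, mann_whitney, spearman


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    mean_mt_depth: float
    mean_nuclear_depth: float

    def __post_init__(self) -> None:
        if self.mean_mt_depth < 0 or self.mean_nuclear_depth <= 0:
            raise ValueError("depths must be positive (nuclear strictly)")

    @property
    def ratio(self) -> float:
        return self.mean_mt_depth / self.mean_nuclear_depth


def estimate_copy_number(mt_depths: Sequence[float], nuclear_mean_depth: float,
                         sample_id: str = "") -> CopyNumberEstimate:
    """Copy-number estimate from a per-position mtDNA depth vector.

    ``mt_depths`` must cover the full genome (length 16,569); zero-depth
    positions stay in the mean.
    """
    depths = np.asarray(mt_depths, dtype=float)
    if depths.shape != (MT_GENOME_LENGTH,):
        raise ValueError(f"expected {MT_GENOME_LENGTH} per-position depths, got {depths.shape}")
    if nuclear_mean_depth <= 0:
        raise ValueError("nuclear mean depth must be positive")
    return CopyNumberEstimate(sample_id=sample_id,
                              mean_mt_depth=float(depths.mean()),
                              mean_nuclear_depth=float(nuclear_mean_depth))


def _group_ratios(estimates: Iterable[CopyNumberEstimate],
                  samples: Sequence[SampleMeta],
                  selector: Callable[[SampleMeta], bool]) -> np.ndarray:
    by_id = {e.sample_id: e.ratio for e in estimates}
    return np.array([by_id[s.sample_id] for s in samples
                     if selector(s) and s.sample_id in by_id])


def _descriptives(values: np.ndarray) -> dict:
    return {"n": int(len(values)), "mean": float(values.mean()),
            "median": float(np.median(values)),
            "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0}


def compare_copy_number(estimates, samples, case_group: str, control_group: str,
                        log_ratios: bool = False) -> dict | None:
    """Two-sided Mann-Whitney comparison of copy-number ratios between groups.

    ``log_ratios`` applies a log transform first (a rank test is invariant to
    it; exposed for the Welch-style sensitivity path of downstream users).
    """
    x = _group_ratios(estimates, samples, lambda s: s.group == case_group)
    y = _group_ratios(estimates, samples, lambda s: s.group == control_group)
    return _compare_arrays(x, y, case_group, control_group, log_ratios)


def _compare_arrays(x: np.ndarray, y: np.ndarray, label_a: str, label_b: str,
                    log_ratios: bool = False) -> dict | None:
    if len(x) == 0 or len(y) == 0:
        warnings.warn("empty group in copy-number comparison; skipped",
                      DegenerateTableWarning, stacklevel=3)
        return None
    u, p = mann_whitney(np.log(x) if log_ratios else x,
                        np.log(y) if log_ratios else y)
    return {label_a: _descriptives(x), label_b: _descriptives(y), "U": u, "p": p}


def subgroup_copy_number(estimates, samples, predicate_a: Callable[[SampleMeta], bool],
                         predicate_b: Callable[[SampleMeta], bool],
                         labels: tuple[str, str] = ("subgroup_a", "subgroup_b"),
                         log_ratios: bool = False) -> dict | None:
    """The two-group comparison on a predicate-defined partition of samples.

    The predicates must not overlap on the selected samples.
    """
    both = [s.sample_id for s in samples if predicate_a(s) and predicate_b(s)]
    if both:
        raise ValueError(f"predicates overlap on samples {both[:5]}")
    x = _group_ratios(estimates, samples, predicate_a)
    y = _group_ratios(estimates, samples, predicate_b)
    return _compare_arrays(x, y, labels[0], labels[1], log_ratios)


def copy_number_age_correlation(estimates, samples, group: str) -> dict:
    """Spearman correlation of copy-number ratio with age at death in a group."""
    by_id = {e.sample_id: e.ratio for e in estimates}
    pairs = [(s.age_death, by_id[s.sample_id]) for s in samples
             if s.group == group and s.age_death is not None and s.sample_id in by_id]
    if len(pairs) < 3:
        raise ValueError("need at least 3 aged samples for a rank correlation")
    ages, ratios = map(np.array, zip(*pairs))
    rho, p = spearman(ages, ratios)
    return {"group": group, "n": len(pairs), "rho": rho, "p": p}
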