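"""Bespoke SNP filters, applied in a fixed, auditable order.

The pipeline order is scaffold -> quality -> depth percentiles ->
allele balance; each stage records what it removed in a
:class:`FilterReport` and per-stage removals sum to input minus output.

Conventions (documented because they shift counts at the margins):

* the allele-balance rule acts per heterozygous genotype on the minor-allele
  read fraction, with an *inclusive* boundary at the threshold (a het with
  exactly 20% minor reads is kept);
* depth percentiles use the nearest-rank convention over total site depth
  summed across samples (a per-individual mode is available);
* genotype-level failures set the genotype missing rather than dropping the
  site; a site is dropped only when no called genotype remains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, HET, MISSING


@dataclass
class FilterReport:
    """Per-filter removal counts, in application order."""

    input_sites: int = 0
    stages: list[dict] = field(default_factory=list)
    surviving_sites: int = 0

    def add(self, name: str, sites_removed: int, genotypes_removed: int = 0,
            **extra) -> None:
        self.stages.append({"filter": name, "sites_removed": int(sites_removed),
                            "genotypes_removed": int(genotypes_removed), **extra})

    def site_removals(self) -> int:
        return sum(s["sites_removed"] for s in self.stages)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"input_sites": self.input_sites, "stages": self.stages,
                       "surviving_sites": self.surviving_sites}, fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def filter_allele_balance(gm: GenotypeMatrix, min_fraction: float = 0.20,
                          report: FilterReport | None = None) -> GenotypeMatrix:
    """Set heterozygotes with minor-allele read fraction < ``min_fraction``
    to missing; drop sites left with no called genotype.

    A het with zero total depth is set missing and counted separately.
    The boundary is inclusive: fraction exactly equal to ``min_fraction``
    survives.
    """
    if not gm.has_depths:
        raise ValueError("allele-balance filter requires allele depths")
    gm = gm.copy()
    het = gm.gt == HET
    total = gm.ad_ref + gm.ad_alt
    minor = np.minimum(gm.ad_ref, gm.ad_alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, minor / np.maximum(total, 1), np.nan)
    zero_depth = het & (total == 0)
    unbalanced = het & (total > 0) & (frac < min_fraction)
    gm.gt[zero_depth | unbalanced] = MISSING
    empty = (gm.gt != MISSING).sum(axis=1) == 0
    if report is not None:
        report.add("allele_balance", int(empty.sum()),
                   int(unbalanced.sum()),
                   het_zero_depth=int(zero_depth.sum()))
    return gm.take_sites(~empty)


def _nearest_rank(sorted_vals: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: value at rank ceil(p * N) (1-based)."""
    n = len(sorted_vals)
    rank = max(1, int(np.ceil(p * n)))
    return float(sorted_vals[min(rank, n) - 1])


def filter_depth_percentiles(gm: GenotypeMatrix, low: float = 0.025,
                             high: float = 0.975, per_individual: bool = False,
                             report: FilterReport | None = None) -> GenotypeMatrix:
    """Remove sites in the tails of the site-depth distribution.

    A site is removed when its total depth (summed over samples; or, with
    ``per_individual=True``, any individual's depth) falls strictly below
    the ``low`` or strictly above the ``high`` nearest-rank percentile of
    the genome-wide distribution.  Re-filtering filtered output is NOT
    idempotent: the depth distribution shifts.
    """
    if not gm.has_depths:
        raise ValueError("depth filter requires allele depths")
    import warnings
    if gm.n_sites < 40:
        warnings.warn("fewer than 40 sites: depth percentiles are unstable; "
                      "applying nearest-rank anyway", stacklevel=2)
    if per_individual:
        depths = gm.ad_ref + gm.ad_alt
        keep = np.ones(gm.n_sites, bool)
        for j in range(gm.n_samples):
            col = depths[:, j]
            s = np.sort(col)
            lo, hi = _nearest_rank(s, low), _nearest_rank(s, high)
            keep &= (col >= lo) & (col <= hi)
    else:
        depth = gm.total_depth()
        s = np.sort(depth)
        lo, hi = _nearest_rank(s, low), _nearest_rank(s, high)
        keep = (depth >= lo) & (depth <= hi)
    if report is not None:
        report.add("depth_percentiles", int((~keep).sum()),
                   low_cut=float(lo), high_cut=float(hi))
    return gm.take_sites(keep)


def filter_quality(gm: GenotypeMatrix, min_phred: float = 20.0,
                   report: FilterReport | None = None) -> GenotypeMatrix:
    """Remove sites with base quality or mapping quality below ``min_phred``.

    Missing quality values are treated as failing and counted.
    """
    bq = gm.sites["qual"].to_numpy(float)
    mq = gm.sites["mq"].to_numpy(float)
    missing_q = np.isnan(bq) | np.isnan(mq)
    keep = ~missing_q & (bq >= min_phred) & (mq >= min_phred)
    if report is not None:
        report.add("quality", int((~keep).sum()), missing_quality=int(missing_q.sum()))
    return gm.take_sites(keep)


def filter_scaffolds(gm: GenotypeMatrix, scaffold_lengths: Mapping[str, int],
                     min_length: int = 100_000, excluded_labels: set[str] = frozenset(),
                     report: FilterReport | None = None) -> GenotypeMatrix:
    """Remove sites on short (< ``min_length``) or explicitly excluded scaffolds.

    Sex-scaffold handling is label-based: pass candidate sex scaffolds in
    ``excluded_labels``.  Unknown scaffolds raise, listing the identifiers.
    """
    scaffolds = gm.sites["scaffold"]
    unknown = sorted(set(scaffolds) - set(scaffold_lengths))
    if unknown:
        raise KeyError(f"scaffolds with unknown length: {unknown}")
    lengths = scaffolds.map(scaffold_lengths).to_numpy(float)
    keep = (lengths >= min_length) & ~scaffolds.isin(excluded_labels).to_numpy()
    if report is not None:
        report.add("scaffolds", int((~keep).sum()))
    return gm.take_sites(keep)


def run_filters(gm: GenotypeMatrix, scaffold_lengths: Mapping[str, int],
                min_length: int = 100_000, excluded_labels: set[str] = frozenset(),
                min_phred: float = 20.0, depth_low: float = 0.025,
                depth_high: float = 0.975, min_fraction: float = 0.20,
                ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full filter chain in the fixed order and return a report."""
    report = FilterReport(input_sites=gm.n_sites)
    gm = filter_scaffolds(gm, scaffold_lengths, min_length, excluded_labels, report)
    gm = filter_quality(gm, min_phred, report)
    gm = filter_depth_percentiles(gm, depth_low, depth_high, report=report)
    gm = filter_allele_balance(gm, min_fraction, report)
    report.surviving_sites = gm.n_sites
    return gm, report
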