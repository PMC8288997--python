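"""Windowed heterozygosity and between-group comparisons.

Per-individual heterozygosity is the count of heterozygous genotypes in a
fixed non-overlapping window (default 50 kb) divided by the window span —
matching the convention of dividing SNP het counts by window size rather
than by callable sites (a callable-sites denominator is available behind a
flag).  Terminal partial windows are reported but flagged, and excluded
from population means to avoid length bias.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, HET, MISSING


def windowed_heterozygosity(gm: GenotypeMatrix, window_bp: int = 50_000,
                            scaffold_lengths: Mapping[str, int] | None = None,
                            callable_denominator: bool = False) -> pd.DataFrame:
    """Per-individual, per-window heterozygosity table.

    Columns: ``individual, scaffold, start, end, het_sites, callable_bp, He,
    partial`` with 0-based half-open windows.  ``He = het_sites / span`` by
    default; with ``callable_denominator=True`` the denominator is the count
    of non-missing genotypes in the window.  A scaffold shorter than one
    window yields a single flagged terminal window.
    """
    rows = []
    pos0 = gm.sites["pos"].to_numpy(int) - 1  # 0-based
    scaffolds = gm.sites["scaffold"].to_numpy()
    for sc in dict.fromkeys(scaffolds):
        in_sc = scaffolds == sc
        sc_pos = pos0[in_sc]
        sc_gt = gm.gt[in_sc]
        length = (scaffold_lengths or {}).get(sc, int(sc_pos.max()) + 1 if len(sc_pos) else window_bp)
        n_win = max(1, -(-length // window_bp))
        win_idx = np.clip(sc_pos // window_bp, 0, n_win - 1)
        for w in range(n_win):
            start = w * window_bp
            end = min(start + window_bp, length)
            partial = (end - start) != window_bp
            sel = win_idx == w
            win_gt = sc_gt[sel]
            for k, ind in enumerate(gm.samples):
                col = win_gt[:, k]
                het = int((col == HET).sum())
                callable_n = int((col != MISSING).sum())
                denom = callable_n if callable_denominator else (end - start)
                rows.append({
                    "individual": ind, "scaffold": sc, "start": start, "end": end,
                    "het_sites": het, "callable_bp": callable_n,
                    "He": het / denom if denom else np.nan, "partial": partial,
                })
    return pd.DataFrame(rows, columns=["individual", "scaffold", "start", "end",
                                       "het_sites", "callable_bp", "He", "partial"])


def population_mean_he(windows: pd.DataFrame,
                       sample_sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean He per individual (full windows only), optionally by population."""
    full = windows[~windows["partial"]]
    per_ind = full.groupby("individual", sort=False)["He"].mean().reset_index()
    if sample_sheet is not None:
        per_ind = per_ind.merge(sample_sheet[["sample", "population"]],
                                left_on="individual", right_on="sample").drop(columns="sample")
    return per_ind


def downsample_genotypes(gm: GenotypeMatrix, keep_fraction: float,
                         seed: int) -> GenotypeMatrix:
    """Set a random fraction of called genotypes to missing.

    A genotype-level analogue of subsampling sequence reads to a lower
    coverage before re-estimating heterozygosity: it emulates the loss of
    callable genotypes, not the read-level recalling, and is intended for
    robustness checks of coverage effects on He.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    drop = (rng.random(out.gt.shape) > keep_fraction) & (out.gt != MISSING)
    out.gt[drop] = MISSING
    return out


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]
                   ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of two groups.

    Exact permutation null for tiny samples (both groups <= 9, no ties),
    normal approximation with tie correction otherwise.  Two identical
    constant groups give p = 1 by convention.  Returns ``(U, p)``.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 9 and len(b) <= 9 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
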