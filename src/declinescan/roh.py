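"""Runs of homozygosity, inbreeding age, and linkage disequilibrium.

ROH segments span the first to the last SNP of a homozygous run (not
extended to midpoints between flanking SNPs, which would shift lengths by
up to one inter-SNP gap).  Missing genotypes neither break a run nor count
towards its SNP total.

The SNP-count rule is configurable: ``snp_rule="min"`` (default) keeps
segments supported by at least ``snp_count`` SNPs, the standard convention;
``snp_rule="max"`` instead keeps segments containing fewer than
``snp_count`` SNPs — an upper-bound variant some call sets use for sparse
markers.  Both are exposed rather than hard-wiring one convention.

Inbreeding age: a homozygous tract inherited through a consanguineous loop
of g generations has expected genetic length 100/(2g) cM, so
``g = 100 / (2 * length_cM)`` dates the inbreeding event; physical length
in Mb approximates cM at 1 cM/Mb.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, HET, MISSING

ROH_COLUMNS = ["individual", "scaffold", "start", "end", "n_snps", "n_het",
               "length_bp", "length_cM"]


def _runs_for_individual(pos: np.ndarray, gt: np.ndarray, max_het: int
                         ) -> list[tuple[int, int, int, int]]:
    """Maximal windows with <= max_het embedded hets, hom SNPs at both ends.

    Returns (first_idx, last_idx, n_snps, n_het) over the called-site index.
    """
    called = gt != MISSING
    pos = pos[called]
    gt = gt[called]
    n = len(gt)
    if n == 0:
        return []
    is_het = gt == HET
    het_cum = np.concatenate([[0], np.cumsum(is_het)])
    out = []
    left = 0
    for right in range(n):
        if is_het[right]:
            continue
        while het_cum[right + 1] - het_cum[left] > max_het or is_het[left]:
            left += 1
        # maximal iff left advanced since the last emitted window
        if out and out[-1][0] == left:
            out[-1] = (left, right, right - left + 1,
                       int(het_cum[right + 1] - het_cum[left]))
        else:
            out.append((left, right, right - left + 1,
                        int(het_cum[right + 1] - het_cum[left])))
    return [(int(pos[l]), int(pos[r]), s, h) for l, r, s, h in out]


def detect_roh(gm: GenotypeMatrix, min_length_bp: int = 10_000, max_het: int = 0,
               snp_count: int = 20, snp_rule: Literal["min", "max"] = "min",
               cM_per_Mb: float = 1.0,
               individuals: Sequence[str] | None = None) -> pd.DataFrame:
    """Detect maximal homozygous runs per individual and scaffold.

    A segment is retained when it spans at least ``min_length_bp``
    (first-to-last SNP) and satisfies the configured SNP-count rule.
    Returns half-open ``[start, end)`` 0-based coordinates.
    """
    if individuals is None:
        individuals = gm.samples
    for ind in individuals:
        if ind not in gm.samples:
            raise KeyError(f"individual {ind!r} not in genotype matrix")
    pos = gm.sites["pos"].to_numpy(int)
    scaffolds = gm.sites["scaffold"].to_numpy()
    rows = []
    for ind in individuals:
        k = gm.samples.index(ind)
        for sc in dict.fromkeys(scaffolds):
            sel = scaffolds == sc
            for p1, p2, n_snps, n_het in _runs_for_individual(pos[sel], gm.gt[sel, k], max_het):
                start, end = p1 - 1, p2  # 1-based inclusive -> 0-based half-open
                length = end - start
                if length < min_length_bp:
                    continue
                if snp_rule == "min" and n_snps < snp_count:
                    continue
                if snp_rule == "max" and n_snps >= snp_count:
                    continue
                rows.append([ind, sc, start, end, n_snps, n_het, length,
                             length * cM_per_Mb / 1e6])
    return pd.DataFrame(rows, columns=ROH_COLUMNS)


def detect_roh_bruteforce(gm: GenotypeMatrix, min_length_bp: int = 10_000,
                          max_het: int = 0, snp_count: int = 20,
                          snp_rule: Literal["min", "max"] = "min",
                          cM_per_Mb: float = 1.0) -> pd.DataFrame:
    """O(n^2) all-substrings reference scan (test oracle for detect_roh)."""
    pos_all = gm.sites["pos"].to_numpy(int)
    scaffolds = gm.sites["scaffold"].to_numpy()
    rows = []
    for ind in gm.samples:
        k = gm.samples.index(ind)
        for sc in dict.fromkeys(scaffolds):
            sel = scaffolds == sc
            gt = gm.gt[sel, k]
            pos = pos_all[sel]
            called = gt != MISSING
            gt, pos = gt[called], pos[called]
            n = len(gt)
            # for every hom start, scan forward to the largest valid end
            windows = []
            for i in range(n):
                if gt[i] == HET:
                    continue
                hets = 0
                best_j, best_h = i, 0
                for j in range(i, n):
                    if gt[j] == HET:
                        hets += 1
                        if hets > max_het:
                            break
                    else:
                        best_j, best_h = j, hets
                windows.append((i, best_j, best_h))
            maximal = [
                (i, j, h) for i, j, h in windows
                if not any((i2 <= i and j <= j2 and (i2, j2) != (i, j))
                           for i2, j2, _ in windows)
            ]
            for i, j, h in maximal:
                start, end = int(pos[i]) - 1, int(pos[j])
                length = end - start
                n_snps = j - i + 1
                if length < min_length_bp:
                    continue
                if snp_rule == "min" and n_snps < snp_count:
                    continue
                if snp_rule == "max" and n_snps >= snp_count:
                    continue
                rows.append([ind, sc, start, end, n_snps, h, length,
                             length * cM_per_Mb / 1e6])
    return pd.DataFrame(rows, columns=ROH_COLUMNS)


def summarize_roh(segments: pd.DataFrame, genome_bp: int,
                  sample_sheet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-individual totals for medium [100 kb, 1 Mb) and long [>= 1 Mb) ROH.

    Returns Mb totals and genome fractions per class; raises on overlapping
    segments for one individual (a detector-contract violation).
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be > 0")
    for (ind, sc), grp in segments.groupby(["individual", "scaffold"], sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping ROH segments for {ind} on {sc}")
    rows = []
    for ind, grp in segments.groupby("individual", sort=False):
        L = grp["length_bp"]
        medium = int(L[(L >= 100_000) & (L < 1_000_000)].sum())
        long_ = int(L[L >= 1_000_000].sum())
        rows.append({
            "individual": ind,
            "medium_mb": medium / 1e6, "medium_fraction": medium / genome_bp,
            "long_mb": long_ / 1e6, "long_fraction": long_ / genome_bp,
            "total_mb_ge_100kb": (medium + long_) / 1e6,
        })
    out = pd.DataFrame(rows, columns=["individual", "medium_mb", "medium_fraction",
                                      "long_mb", "long_fraction", "total_mb_ge_100kb"])
    if sample_sheet is not None:
        out = out.merge(sample_sheet[["sample", "population"]],
                        left_on="individual", right_on="sample").drop(columns="sample")
    return out


def roh_age_generations(length_cM: float) -> float:
    """Date an inbreeding event from ROH genetic length: g = 100/(2 * cM)."""
    if length_cM <= 0:
        raise ValueError("ROH length in cM must be > 0")
    return 100.0 / (2.0 * length_cM)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def pairwise_r2_matrix(dosage: np.ndarray) -> np.ndarray:
    """All-pairs dosage r^2 for a (sites x samples) block, NaN-aware.

    Pairwise-complete observations via masked matrix products; monomorphic
    or <2-observation pairs are NaN.
    """
    V = np.isfinite(dosage).astype(float)
    X = np.nan_to_num(dosage)
    X2 = X * X
    N = V @ V.T
    Sx = X @ V.T
    Sxy = X @ X.T
    Sxx = X2 @ V.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = N * Sxy - Sx * Sx.T
        var_x = N * Sxx - Sx ** 2
        denom = var_x * var_x.T
        r2 = np.where(denom > 0, cov * cov / np.where(denom > 0, denom, 1.0), np.nan)
    r2[N < 2] = np.nan
    return r2


def r2_dosage(d1: np.ndarray, d2: np.ndarray) -> float:
    """Unphased r^2: squared correlation of alt-allele dosages (NaN-aware)."""
    ok = ~np.isnan(d1) & ~np.isnan(d2)
    x, y = d1[ok], d2[ok]
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def r2_haplotype(hap1: np.ndarray, hap2: np.ndarray) -> float:
    """Phased r^2 = D^2 / (p1 q1 p2 q2) from 0/1 haplotype vectors."""
    p1 = hap1.mean()
    p2 = hap2.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return np.nan
    D = (hap1 * hap2).mean() - p1 * p2
    return float(D * D / (p1 * (1 - p1) * p2 * (1 - p2)))


def ld_decay(gm: GenotypeMatrix | None = None, max_dist_bp: int = 100_000,
             n_bins: int = 20, haplotypes: np.ndarray | None = None,
             positions: np.ndarray | None = None,
             r2_threshold: float = 0.2) -> tuple[pd.DataFrame, float | None]:
    """Binned mean r^2 by pairwise distance, plus the LD-decay distance.

    Unphased mode takes a genotype matrix (dosage correlation); phased mode
    takes a ``(n_haplotypes, n_sites)`` 0/1 array with ``positions``.
    Monomorphic pairs are skipped and counted in the ``n_skipped`` attribute
    of the returned frame.  The second return value is the midpoint of the
    smallest distance bin whose mean r^2 drops below ``r2_threshold``
    (None if LD never decays below it within ``max_dist_bp``).
    """
    pairs_d, pairs_r2, skipped = [], [], 0
    if haplotypes is not None:
        if positions is None:
            raise ValueError("phased mode requires positions")
        pos = np.asarray(positions)
        H = np.asarray(haplotypes)
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                d = abs(int(pos[j]) - int(pos[i]))
                if d == 0 or d > max_dist_bp:
                    continue
                r2 = r2_haplotype(H[:, i], H[:, j])
                if np.isnan(r2):
                    skipped += 1
                    continue
                pairs_d.append(d)
                pairs_r2.append(r2)
    else:
        if gm is None:
            raise ValueError("need a genotype matrix or haplotypes")
        dos = gm.dosage()
        pos = gm.sites["pos"].to_numpy(int)
        scaffolds = gm.sites["scaffold"].to_numpy()
        for sc in dict.fromkeys(scaffolds):
            idx = np.flatnonzero(scaffolds == sc)
            if len(idx) < 2:
                continue
            r2m = pairwise_r2_matrix(dos[idx])
            p = pos[idx]
            iu, ju = np.triu_indices(len(idx), k=1)
            dist = np.abs(p[ju] - p[iu])
            sel = (dist > 0) & (dist <= max_dist_bp)
            vals = r2m[iu[sel], ju[sel]]
            ok = np.isfinite(vals)
            skipped += int((~ok).sum())
            pairs_d.extend(dist[sel][ok].tolist())
            pairs_r2.extend(vals[ok].tolist())
    if len(pairs_d) == 0:
        raise ValueError("no polymorphic locus pairs within max_dist_bp")
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    which = np.clip(np.digitize(pairs_d, edges) - 1, 0, n_bins - 1)
    rows = []
    decay_at = None
    r2_arr = np.asarray(pairs_r2)
    for b in range(n_bins):
        sel = which == b
        mid = (edges[b] + edges[b + 1]) / 2
        if sel.any():
            mean_r2 = float(r2_arr[sel].mean())
            rows.append({"bin_midpoint_bp": mid, "mean_r2": mean_r2,
                         "n_pairs": int(sel.sum())})
            if decay_at is None and mean_r2 < r2_threshold:
                decay_at = float(mid)
        else:
            rows.append({"bin_midpoint_bp": mid, "mean_r2": np.nan, "n_pairs": 0})
    curve = pd.DataFrame(rows)
    curve.attrs["n_skipped"] = skipped
    return curve, decay_at


def ld_thin(gm: GenotypeMatrix, r2_threshold: float = 0.2,
            window_bp: int = 50_000) -> np.ndarray:
    """Greedy left-to-right LD thinning; returns retained site indices.

    A site is dropped when its r^2 with any already-retained site within
    ``window_bp`` (same scaffold) strictly exceeds the threshold.
    """
    dos = gm.dosage()
    pos = gm.sites["pos"].to_numpy(int)
    scaffolds = gm.sites["scaffold"].to_numpy()
    retained: list[int] = []
    for sc in dict.fromkeys(scaffolds):
        idx = np.flatnonzero(scaffolds == sc)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        r2m = pairwise_r2_matrix(dos[idx]) if len(idx) <= 4000 else None
        kept_local: list[int] = []
        for a, i in enumerate(idx):
            ok = True
            for b in reversed(kept_local):
                j = idx[b]
                if pos[i] - pos[j] > window_bp:
                    break
                r2 = r2m[a, b] if r2m is not None else r2_dosage(dos[i], dos[j])
                if not np.isnan(r2) and r2 > r2_threshold:
                    ok = False
                    break
            if ok:
                kept_local.append(a)
        retained.extend(int(idx[b]) for b in kept_local)
    return np.array(sorted(retained), int)
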