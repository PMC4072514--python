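"""H3K4me3 peak proximity for eQTL SNP sets.

Each index SNP is expanded to its LD partners (r^2 >= 0.8 by default);
for the set, the distance to the nearest peak interval and that peak's
height (and summit distance) are recorded.  Two SNP sets are compared per
feature with a one-sided Mann-Whitney test (exact for small groups,
normal approximation with tie and continuity corrections otherwise).

Coordinate conventions are centralized here: peak intervals are BED-style
0-based half-open; SNP positions arrive 1-based and are converted before
comparison.  A SNP inside a peak has distance 0; outside, the distance is
the number of bases strictly between the SNP and the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .eqtl import ld_r2

__all__ = [
    "SnpLdSet",
    "validate_peaks",
    "ld_partners",
    "nearest_peak_features",
    "compare_snp_sets",
]

INF_DISTANCE = float("inf")


@dataclass
class SnpLdSet:
    index_snp: str
    partners: list[str]       # includes the index SNP
    r2_threshold: float


def validate_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Check a peak table (chrom, start, end, height[, summit offset])."""
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peak intervals must satisfy start < end (half-open)")
    for _, sub in peaks.groupby("chrom", sort=False):
        if not sub["start"].is_monotonic_increasing:
            raise ValueError("peaks must be sorted by start within chromosome")
    return peaks


def ld_partners(
    snp: str,
    genotypes: GenotypeMatrix,
    r2_threshold: float = 0.8,
) -> SnpLdSet:
    """Same-chromosome SNPs with r^2 >= threshold to ``snp``, plus ``snp``."""
    if snp not in genotypes.snps.index:
        raise KeyError(f"{snp!r} not in panel")
    a = genotypes.dosages[snp].to_numpy()
    if a.std(ddof=0) == 0:
        raise ValueError("monomorphic index SNP; LD undefined")
    chrom = genotypes.snps.loc[snp, "chrom"]
    partners = [snp]
    for other in genotypes.snps.index[genotypes.snps["chrom"] == chrom]:
        if other == snp:
            continue
        b = genotypes.dosages[other].to_numpy()
        if b.std(ddof=0) == 0:
            continue
        if ld_r2(a, b) >= r2_threshold:
            partners.append(other)
    return SnpLdSet(index_snp=snp, partners=partners, r2_threshold=r2_threshold)


def _distance_to_peak(pos0: int, start: int, end: int) -> int:
    """Bases strictly between a 0-based SNP position and a half-open peak."""
    if start <= pos0 < end:
        return 0
    if pos0 < start:
        return start - pos0 - 1
    return pos0 - end


def nearest_peak_features(
    snp_set: SnpLdSet,
    snp_positions: pd.DataFrame,
    peaks: pd.DataFrame,
) -> dict:
    """Minimum peak distance over the LD set, with that peak's height.

    ``snp_positions`` is indexed by SNP id with columns chrom and pos
    (1-based).  Ties in distance are broken by greater height.  Returns a
    dict with distance, height, summit_distance and the peak row index;
    a chromosome without peaks yields an infinite-distance sentinel.
    """
    best = {"distance": INF_DISTANCE, "height": np.nan,
            "summit_distance": np.nan, "peak": None}
    for snp in snp_set.partners:
        chrom = snp_positions.loc[snp, "chrom"]
        pos0 = int(snp_positions.loc[snp, "pos"]) - 1
        sub = peaks[peaks["chrom"] == chrom]
        if sub.empty:
            continue
        d = np.array([
            _distance_to_peak(pos0, int(s), int(e))
            for s, e in zip(sub["start"], sub["end"])
        ], dtype=float)
        h = sub["height"].to_numpy(dtype=float)
        order = np.lexsort((-h, d))
        j = order[0]
        cand_d, cand_h = d[j], h[j]
        if (cand_d, -cand_h) < (best["distance"], -(best["height"] if np.isfinite(best["distance"]) else -np.inf)):
            row = sub.iloc[j]
            summit = row.get("summit", np.nan)
            sd = abs(pos0 - (int(row["start"]) + int(summit))) if pd.notna(summit) else np.nan
            best = {"distance": float(cand_d), "height": float(cand_h),
                    "summit_distance": float(sd) if sd == sd else np.nan,
                    "peak": row.name}
    return best


def compare_snp_sets(features_a, features_b, side: str = "less"):
    """One-sided Mann-Whitney p for feature values of set A vs set B.

    ``side='less'`` tests whether A's values are stochastically smaller.
    Exact when both groups have <= 10 values, else normal approximation
    with tie and continuity corrections.  All-tied input returns p = 1
    with a degenerate flag.
    """
    a = np.asarray(features_a, dtype=float)
    b = np.asarray(features_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both SNP sets must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return {"p": 1.0, "statistic": np.nan, "degenerate": True}
    method = "exact" if (a.size <= 10 and b.size <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=side, method=method)
    return {"p": float(res.pvalue), "statistic": float(res.statistic),
            "degenerate": False}
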