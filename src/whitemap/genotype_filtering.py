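"""Reduction of a raw biallelic genotype table to the informative marker set.

An F1 outbred cross only yields linkage information at markers where at
least one parent is heterozygous.  This module classifies each marker's
segregation type from the parental genotypes, thins multi-SNP RAD loci to a
single SNP, removes markers with excessive offspring missingness, and
removes markers whose offspring counts depart significantly from their
Mendelian expectation (1:1 for single-parent-informative markers, 1:2:1 for
double heterozygotes).  Every removal is recorded in a filter log so the
marker-count funnel can be audited.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SegType,
    write_tsv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "classify_segregation",
    "informative_only",
    "thin_rad_loci",
    "filter_missingness",
    "filter_distortion",
    "FilterLog",
]


class FilterLog:
    """Accumulates (marker, fate, reason, statistic) records across filters."""

    def __init__(self) -> None:
        self.records: list = []

    def add(self, marker, fate: str, reason: str, statistic=np.nan) -> None:
        self.records.append((marker, fate, reason, statistic))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["marker", "fate", "reason", "statistic"])

    def write(self, path) -> None:
        write_tsv(self.frame(), path, "filter_log")


def classify_segregation(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Classify each marker's segregation type from its parental genotypes.

    Aa x hom -> MAT_INF, hom x Aa -> PAT_INF, Aa x Aa -> BOTH_INF; anything
    else — both parents homozygous, or a missing parental call — is
    UNINFORMATIVE.  ``n_informative`` counts offspring whose call reveals a
    transmitted allele: for single-parent-informative markers the offspring
    in the two Mendelian classes, for double heterozygotes only the
    homozygous offspring (heterozygous offspring are phase-uninformative).

    Returns a DataFrame with columns ``marker``, ``segtype``,
    ``n_informative``.
    """
    mo, fa = matrix.mother, matrix.father
    off = matrix.offspring
    seg = np.full(matrix.n_markers, SegType.UNINFORMATIVE.value, dtype=object)
    hom = (mo == HOM_REF) | (mo == HOM_ALT)
    hom_f = (fa == HOM_REF) | (fa == HOM_ALT)
    seg[(mo == HET) & hom_f] = SegType.MAT_INF.value
    seg[hom & (fa == HET)] = SegType.PAT_INF.value
    seg[(mo == HET) & (fa == HET)] = SegType.BOTH_INF.value

    n_inf = np.zeros(matrix.n_markers, dtype=int)
    for i in range(matrix.n_markers):
        g = off[i]
        if seg[i] == SegType.BOTH_INF.value:
            n_inf[i] = int(((g == HOM_REF) | (g == HOM_ALT)).sum())
        elif seg[i] == SegType.MAT_INF.value or seg[i] == SegType.PAT_INF.value:
            hom_parent = fa[i] if seg[i] == SegType.MAT_INF.value else mo[i]
            # legal classes: het, and the homozygote matching the hom parent
            n_inf[i] = int(((g == HET) | (g == hom_parent)).sum())
    return pd.DataFrame({"marker": matrix.marker_ids, "segtype": seg, "n_informative": n_inf})


def informative_only(matrix: GenotypeMatrix, segcalls: pd.DataFrame, log: FilterLog | None = None):
    """Drop UNINFORMATIVE markers; returns (matrix, segcalls) restricted."""
    keep = (segcalls["segtype"] != SegType.UNINFORMATIVE.value).to_numpy()
    if log is not None:
        for mid in matrix.marker_ids[~keep]:
            log.add(mid, "removed", "uninformative_parents")
    return matrix.take(np.flatnonzero(keep)), segcalls[keep].reset_index(drop=True)


def thin_rad_loci(matrix: GenotypeMatrix, seed=0, log: FilterLog | None = None) -> GenotypeMatrix:
    """Thin RAD loci to at most one SNP.

    Loci carrying more than three SNPs are removed entirely (likely
    paralogous assemblies); loci with two or three SNPs contribute a single
    SNP chosen uniformly at random; single-SNP loci are untouched.
    """
    rng = np.random.default_rng(seed)
    keep = np.zeros(matrix.n_markers, dtype=bool)
    locus_series = pd.Series(np.arange(matrix.n_markers), index=matrix.rad_locus)
    for locus, idx in locus_series.groupby(level=0, sort=False):
        positions = idx.to_numpy()
        if len(positions) > 3:
            if log is not None:
                for p in positions:
                    log.add(matrix.marker_ids[p], "removed", "rad_locus_gt3_snps", len(positions))
        elif len(positions) >= 2:
            chosen = positions[int(rng.integers(len(positions)))]
            keep[chosen] = True
            if log is not None:
                for p in positions:
                    if p != chosen:
                        log.add(matrix.marker_ids[p], "removed", "rad_locus_thinned", len(positions))
        else:
            keep[positions[0]] = True
    return matrix.take(np.flatnonzero(keep))


def filter_missingness(matrix: GenotypeMatrix, max_missing: float = 0.20,
                       log: FilterLog | None = None) -> GenotypeMatrix:
    """Remove markers whose offspring missing fraction strictly exceeds the cap."""
    frac = (matrix.offspring == MISSING).mean(axis=1)
    keep = frac <= max_missing
    if log is not None:
        for i in np.flatnonzero(~keep):
            log.add(matrix.marker_ids[i], "removed", "missingness", float(frac[i]))
    return matrix.take(np.flatnonzero(keep))


def _distortion_test(g: np.ndarray, segtype: str, hom_parent: int, both_inf_test: str):
    """Chi-square goodness of fit of offspring counts to the Mendelian ratio.

    Returns (chi2, p, n_used); (nan, nan, 0) when no informative offspring.
    """
    if segtype == SegType.BOTH_INF.value:
        if both_inf_test == "three_class":
            counts = np.array([(g == HOM_REF).sum(), (g == HET).sum(), (g == HOM_ALT).sum()])
            expected_ratio = np.array([0.25, 0.5, 0.25])
        else:  # homozygotes only, 1:1
            counts = np.array([(g == HOM_REF).sum(), (g == HOM_ALT).sum()])
            expected_ratio = np.array([0.5, 0.5])
    else:
        counts = np.array([(g == HET).sum(), (g == hom_parent).sum()])
        expected_ratio = np.array([0.5, 0.5])
    n = counts.sum()
    if n == 0:
        return np.nan, np.nan, 0
    chi2, p = stats.chisquare(counts, f_exp=expected_ratio * n)
    return float(chi2), float(p), int(n)


def filter_distortion(matrix: GenotypeMatrix, segcalls: pd.DataFrame, tolerance: float = 0.001,
                      both_inf_test: str = "three_class",
                      log: FilterLog | None = None):
    """Remove markers with significant segregation distortion.

    A Pearson chi-square goodness-of-fit test (no continuity correction)
    compares offspring genotype counts with the Mendelian expectation —
    1:1 for single-parent-informative markers, 1:2:1 for double
    heterozygotes (``both_inf_test="three_class"``, the default) or 1:1 over
    homozygotes only (``both_inf_test="homozygous"``).  Missing calls and
    Mendelian-impossible genotypes are excluded.  Markers with p below
    ``tolerance`` are removed; markers with zero informative offspring are
    removed with a warning.

    Returns ``(matrix, segcalls)`` restricted to retained markers.
    """
    if both_inf_test not in ("three_class", "homozygous"):
        raise ValueError("both_inf_test must be 'three_class' or 'homozygous'")
    seg = segcalls.set_index("marker")["segtype"]
    keep = np.ones(matrix.n_markers, dtype=bool)
    for i in range(matrix.n_markers):
        mid = matrix.marker_ids[i]
        st = seg.get(mid, SegType.UNINFORMATIVE.value)
        if st == SegType.UNINFORMATIVE.value:
            continue
        hom_parent = matrix.father[i] if st == SegType.MAT_INF.value else matrix.mother[i]
        chi2, p, n = _distortion_test(matrix.offspring[i], st, int(hom_parent), both_inf_test)
        if n == 0:
            keep[i] = False
            logger.warning("marker %s has no informative offspring; removed", mid)
            if log is not None:
                log.add(mid, "removed", "no_informative_offspring")
        elif p < tolerance:
            keep[i] = False
            if log is not None:
                log.add(mid, "removed", "segregation_distortion", p)
    idx = np.flatnonzero(keep)
    sc = segcalls[np.isin(segcalls["marker"].to_numpy(), matrix.marker_ids[idx])]
    return matrix.take(idx), sc.reset_index(drop=True)
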