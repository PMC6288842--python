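"""Linkage-group homology to a duplicated reference genome, and the
rediploidization-aware distribution of marker mappings over chromosome arms.

Salmonids descend from a lineage-specific whole-genome duplication (Ss4R).
Chromosome arms that returned to disomic inheritance in the common salmonid
ancestor (AORe) retain 1:1 cross-species ohnolog orthology, so markers from
a relative map there confidently; arms that rediploidized independently per
lineage (LORe) do not, which depresses high-MAPQ mappings.  This module:

* filters marker-to-reference mappings at a strict MAPQ cutoff,
* assigns each linkage group the reference chromosome with most hits and
  renames groups W01..Wk in reference order,
* computes each arm's expected mapping count from its length share and the
  expected/observed ratio, and contrasts AORe vs LORe ratios with a
  Wilcoxon rank-sum test (exact by enumeration for small tie-free samples,
  otherwise a tie- and continuity-corrected normal approximation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "load_arms",
    "load_mappings",
    "read_sam_mappings",
    "filter_mappings",
    "assign_homologs",
    "assign_arms",
    "arm_ratio_test",
    "ranksum",
    "RankSumResult",
    "ArmRatioResult",
    "plot_synteny",
]

ARM_CLASSES = ("AORe", "LORe", "mixed")


def _chrom_number(name) -> int:
    digits = "".join(c for c in str(name) if c.isdigit())
    return int(digits) if digits else 10 ** 6


def load_arms(path=None) -> pd.DataFrame:
    """Load a chromosome-arm table (arm, chrom, start, end, class).

    Coordinates are 0-based half-open bp intervals within each chromosome.
    Without ``path`` the packaged *synthetic* salmon-like arm table is used:
    it reproduces the real classification structure (30 AORe, 14 LORe and 6
    mixed arms over 29 chromosomes, with the published LORe/mixed arm names)
    but its arm lengths are invented.
    """
    if path is None:
        ref = resources.files("whitemap").joinpath("data/salmon_arms_synthetic.csv")
        with ref.open("rb") as fh:
            arms = pd.read_csv(fh)
    else:
        arms = pd.read_csv(path)
    need = {"arm", "chrom", "start", "end", "class"}
    if not need.issubset(arms.columns):
        raise InputError(f"arm table needs columns {sorted(need)}")
    if (arms["end"] <= arms["start"]).any():
        raise InputError("arm lengths must be positive")
    bad = set(arms["class"]) - set(ARM_CLASSES)
    if bad:
        raise InputError(f"unknown rediploidization classes: {sorted(bad)}")
    for chrom, sub in arms.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise InputError(f"overlapping arms on {chrom}")
    return arms.reset_index(drop=True)


def load_mappings(path) -> pd.DataFrame:
    """Load a mapping-record TSV with columns marker, chrom, pos, mapq."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"marker", "chrom", "pos", "mapq"}
    if not need.issubset(df.columns):
        raise InputError(f"mapping table needs columns {sorted(need)}")
    if (df["pos"] < 0).any():
        raise InputError("mapping positions must be >= 0")
    return df


def read_sam_mappings(path) -> pd.DataFrame:
    """Extract (marker, chrom, pos, mapq) from a SAM/BAM of marker alignments.

    Unmapped records are skipped; the query name is the marker id.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rows.append((rec.query_name, rec.reference_name, rec.reference_start, rec.mapping_quality))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "mapq"])


def filter_mappings(records: pd.DataFrame, map_table: pd.DataFrame | None = None,
                    min_mapq: int = 30) -> pd.DataFrame:
    """Retain records with MAPQ strictly above ``min_mapq`` whose marker is
    in the genetic map (when a map table is given); drops are logged."""
    out = records[records["mapq"] > min_mapq]
    logger.info("MAPQ filter: %d of %d mappings retained (MAPQ > %d)",
                len(out), len(records), min_mapq)
    if map_table is not None:
        known = set(map_table["marker"])
        in_map = out["marker"].isin(known)
        if (~in_map).any():
            logger.info("%d mappings dropped: marker not in the genetic map", int((~in_map).sum()))
        out = out[in_map]
    return out.reset_index(drop=True)


def assign_homologs(map_table: pd.DataFrame, records: pd.DataFrame):
    """Assign each linkage group its majority reference chromosome.

    The homolog is the mode of the reference chromosome over the group's
    retained hits; ties are broken toward the lower chromosome number and
    flagged ``ambiguous`` with a warning.  Groups with hits are ordered by
    (homolog chromosome number, median position of the majority hits) and
    renamed ``W01..Wk``; groups without hits get no W-name.

    Returns ``(assignments, hits)``: per-group assignment frame and the
    per-hit frame annotated with group and a ``concordant`` flag.
    """
    hits = records.merge(map_table[["marker", "group"]], on="marker", how="inner")
    rows = []
    for group in dict.fromkeys(map_table["group"]):
        sub = hits[hits["group"] == group]
        if len(sub) == 0:
            logger.warning("linkage group %s has no retained mappings; homolog NA", group)
            rows.append((group, pd.NA, 0, 0, 0, False, np.nan))
            continue
        counts = sub["chrom"].value_counts()
        top = counts.max()
        winners = sorted(counts[counts == top].index, key=_chrom_number)
        ambiguous = len(winners) > 1
        if ambiguous:
            logger.warning("group %s: homolog tie between %s; taking %s",
                           group, winners, winners[0])
        homolog = winners[0]
        maj = sub[sub["chrom"] == homolog]
        rows.append((group, homolog, int(top), int(len(sub)), int(len(sub) - top),
                     ambiguous, float(maj["pos"].median())))
    assignments = pd.DataFrame(
        rows, columns=["group", "homolog", "n_support", "n_hits", "n_discordant",
                       "ambiguous", "median_pos"],
    )
    assigned = assignments[assignments["homolog"].notna()].copy()
    assigned = assigned.sort_values(
        by=["homolog", "median_pos"], key=lambda s: s.map(_chrom_number) if s.name == "homolog" else s
    )
    wnames = {g: f"W{i + 1:02d}" for i, g in enumerate(assigned["group"])}
    assignments["w_name"] = assignments["group"].map(wnames)
    hom = assignments.set_index("group")["homolog"]
    hits["concordant"] = hits["chrom"].to_numpy() == hits["group"].map(hom).to_numpy()
    return assignments, hits


def assign_arms(records: pd.DataFrame, arms: pd.DataFrame) -> pd.DataFrame:
    """Annotate each record with the arm containing its position.

    Arms are 0-based half-open bp intervals; records outside any arm get
    arm NA (and are logged).
    """
    out = records.copy()
    out["arm"] = pd.NA
    out["arm_class"] = pd.NA
    for chrom, sub in arms.groupby("chrom"):
        sel = out["chrom"] == chrom
        if not sel.any():
            continue
        s = sub.sort_values("start")
        starts = s["start"].to_numpy()
        ends = s["end"].to_numpy()
        pos = out.loc[sel, "pos"].to_numpy()
        ix = np.searchsorted(starts, pos, side="right") - 1
        good = (ix >= 0) & (pos < ends[np.clip(ix, 0, len(ends) - 1)])
        vals = np.where(good, s["arm"].to_numpy(dtype=object)[np.clip(ix, 0, len(s) - 1)], pd.NA)
        cls = np.where(good, s["class"].to_numpy(dtype=object)[np.clip(ix, 0, len(s) - 1)], pd.NA)
        out.loc[sel, "arm"] = vals
        out.loc[sel, "arm_class"] = cls
    n_lost = int(out["arm"].isna().sum())
    if n_lost:
        logger.info("%d mappings fall outside any annotated arm and are dropped", n_lost)
    return out


@dataclass
class RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) result; ``statistic`` is the U of
    the first sample (number of pairs where x > y, ties counting 1/2)."""

    statistic: float
    p_value: float
    method: str  # exact | normal | skipped
    n1: int
    n2: int


def ranksum(x, y, max_enumeration: int = 200_000) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test comparing samples ``x`` and ``y``.

    Exact p by enumerating all C(n1+n2, n1) rank assignments when the input
    is tie-free and the enumeration is affordable (covers both samples up
    to 10, and any split with n1 + n2 <= 12); otherwise the normal
    approximation with tie correction and continuity correction.
    """
    from math import comb

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        return RankSumResult(np.nan, np.nan, "skipped", n1, n2)
    combined = np.concatenate([x, y])
    ranks = sstats.rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_free = (tie_counts == 1).all()

    if tie_free and comb(n1 + n2, n1) <= max_enumeration:
        # null distribution of U over all C(N, n1) rank subsets;
        # combinations run over 0..N-1 so the rank sum is sum(c) + n1
        N = n1 + n2
        base = n1 * (n1 + 1) / 2.0
        us = np.fromiter(
            (sum(c) + n1 - base for c in itertools.combinations(range(N), n1)),
            dtype=float,
        )
        p_le = float((us <= u + 1e-9).mean())
        p_ge = float((us >= u - 1e-9).mean())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(u, p, "exact", n1, n2)

    N = n1 + n2
    mean = n1 * n2 / 2.0
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1))) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return RankSumResult(u, 1.0, "normal", n1, n2)
    cc = 0.5 if u != mean else 0.0
    z = (u - mean - np.sign(u - mean) * cc) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sstats.norm.sf(abs(z))))
    return RankSumResult(u, p, "normal", n1, n2)


@dataclass
class ArmRatioResult:
    """Expected/observed mapping ratios per arm and the AORe-LORe contrast.

    ``arm_stats`` columns: arm, chrom, class, length, observed, expected,
    ratio (expected/observed; NaN where observed = 0).  ``statistic`` is
    the rank-sum U of the AORe ratio set against the LORe set; mixed-class
    arms are excluded throughout, so expected counts sum to ``n_total``,
    the retained hits on included arms.
    """

    arm_stats: pd.DataFrame
    n_total: int
    statistic: float
    p_value: float
    method: str


def arm_ratio_test(records: pd.DataFrame, arms: pd.DataFrame) -> ArmRatioResult:
    """Length-expected vs observed mappings per arm, with AORe/LORe contrast.

    Mixed-rediploidization arms are excluded before anything is computed:
    the expected count of an included arm is
    ``N x length_arm / sum(lengths of included arms)`` with ``N`` the
    retained hits on included arms, so expected counts sum exactly to N.
    The two-sided rank-sum test compares the AORe and LORe expected/observed
    ratio sets (arms with zero observed hits have an undefined ratio and are
    excluded from the test).
    """
    annotated = assign_arms(records, arms)
    annotated = annotated[annotated["arm"].notna()]
    included = arms[arms["class"] != "mixed"].copy()
    on_included = annotated[annotated["arm"].isin(set(included["arm"]))]
    n_total = int(len(on_included))

    included["length"] = included["end"] - included["start"]
    obs = on_included["arm"].value_counts()
    included["observed"] = included["arm"].map(obs).fillna(0).astype(int)
    total_len = float(included["length"].sum())
    included["expected"] = n_total * included["length"] / total_len
    with np.errstate(divide="ignore"):
        included["ratio"] = np.where(
            included["observed"] > 0, included["expected"] / included["observed"], np.nan
        )

    a = included.loc[(included["class"] == "AORe") & included["ratio"].notna(), "ratio"]
    l = included.loc[(included["class"] == "LORe") & included["ratio"].notna(), "ratio"]
    if len(a) == 0 or len(l) == 0:
        logger.warning("rank-sum test skipped: a rediploidization class has no defined ratios")
        res = RankSumResult(np.nan, np.nan, "skipped", len(a), len(l))
    else:
        res = ranksum(a.to_numpy(), l.to_numpy())
    stats_cols = ["arm", "chrom", "class", "length", "observed", "expected", "ratio"]
    return ArmRatioResult(
        arm_stats=included[stats_cols].reset_index(drop=True),
        n_total=n_total,
        statistic=res.statistic,
        p_value=res.p_value,
        method=res.method,
    )


def plot_synteny(assignments: pd.DataFrame, hits: pd.DataFrame, path) -> None:
    """Simple ribbon plot: linkage groups (left) linked to reference
    chromosomes (right); concordant links grey, discordant red.  SVG out."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = [g for g in assignments["group"]]
    chroms = sorted(hits["chrom"].unique(), key=_chrom_number)
    gy = {g: i for i, g in enumerate(groups)}
    cy = {c: i * len(groups) / max(len(chroms), 1) for i, c in enumerate(chroms)}
    fig, ax = plt.subplots(figsize=(6, max(4, len(groups) * 0.18)))
    for _, h in hits.iterrows():
        ax.plot([0, 1], [gy[h["group"]], cy[h["chrom"]]],
                color="0.7" if h["concordant"] else "crimson",
                lw=0.5, alpha=0.6, zorder=1)
    for g, yv in gy.items():
        ax.text(-0.02, yv, str(g), ha="right", va="center", fontsize=6)
    for c, yv in cy.items():
        ax.text(1.02, yv, str(c), ha="left", va="center", fontsize=6)
    ax.set_xlim(-0.3, 1.3)
    ax.axis("off")
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
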