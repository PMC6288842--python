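"""Synthetic F1 outbred crosses with known truth.

Generates a single full-sib family — two wild parents and their offspring —
the way a RAD-seq linkage-mapping study sees it: biallelic SNP markers on
~40 linkage groups, three segregation types (mother-informative Aa x aa,
father-informative aa x Aa, and double-heterozygous Aa x Aa), sex-specific
recombination distances, genotyping error and missing calls.  Every
downstream stage (filtering, grouping, ordering, map distances, synteny) can
therefore be checked against exact truth without any sequencing data.

Meiosis follows the Haldane model: crossovers are interference-free, so the
haplotype origin along a chromosome is a Markov chain whose switch
probability over a sex-specific distance ``d`` cM is
``r = (1 - exp(-2 d / 100)) / 2``.  Heterochiasmy is modelled as a uniform
expansion factor applied to the male distances to obtain female distances,
matching the genome-wide female:male map-length ratios the method reports.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SegType,
    write_tsv,
    write_vcf,
)

__all__ = [
    "SimConfig",
    "TrueMap",
    "haldane_r",
    "haldane_d",
    "simulate_true_map",
    "simulate_gametes",
    "simulate_offspring_genotypes",
    "simulate_cross",
    "simulate_mapping_records",
    "simulate_arm_hits",
    "write_truth",
    "write_vcf",
]


def haldane_r(d_cM):
    """Recombination fraction over ``d`` cM under Haldane (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def haldane_d(r):
    """Map distance in cM for recombination fraction ``r`` (Haldane inverse)."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


@dataclass
class SimConfig:
    """Parameters of a simulated F1 cross.

    Defaults emulate the whitefish study design: 156 offspring, 40 linkage
    groups of ~135 SNPs, sub-cM marker spacing giving ~55-60 cM groups, a
    genome-wide female map expansion, low genotyping error, and a mix of RAD
    loci carrying one to four SNPs.

    Attributes
    ----------
    n_offspring : int
    n_groups : int
    markers_per_group : int
        Number of SNP markers per linkage group.
    mean_spacing_cM : float
        Mean of the exponential male inter-locus distance.
    female_expansion : float
        Female distance = male distance x this factor.
    seg_mixture : tuple of 3 floats
        Proportions of MAT_INF, PAT_INF, BOTH_INF markers; sums to 1.
    error_rate : float
        Probability a call is replaced by a uniformly chosen other genotype.
    missing_rate : float
        Probability a call is set missing.
    rad_multi_snp : tuple of 4 floats
        Proportions of RAD loci carrying 1, 2, 3 and 4+ SNPs (4+ is
        simulated as exactly 4; the thinning filter removes it either way).
    seed : int
    """

    n_offspring: int = 156
    n_groups: int = 40
    markers_per_group: int = 135
    mean_spacing_cM: float = 0.43
    female_expansion: float = 1.09
    seg_mixture: tuple = (0.4, 0.4, 0.2)
    error_rate: float = 0.001
    missing_rate: float = 0.05
    rad_multi_snp: tuple = (0.60, 0.25, 0.10, 0.05)
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_offspring < 1 or self.n_groups < 1 or self.markers_per_group < 1:
            raise ConfigError("counts must be positive")
        if self.mean_spacing_cM < 0 or self.female_expansion < 0:
            raise ConfigError("spacing and expansion must be non-negative")
        for p in (self.error_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        if len(self.seg_mixture) != 3 or any(p < 0 for p in self.seg_mixture):
            raise ConfigError("seg_mixture needs 3 non-negative proportions")
        if abs(sum(self.seg_mixture) - 1.0) > 1e-9:
            raise ConfigError("seg_mixture must sum to 1")
        if len(self.rad_multi_snp) != 4 or any(p < 0 for p in self.rad_multi_snp):
            raise ConfigError("rad_multi_snp needs 4 non-negative proportions")
        if abs(sum(self.rad_multi_snp) - 1.0) > 1e-9:
            raise ConfigError("rad_multi_snp must sum to 1")
        return self


_SEGTYPES = np.array([SegType.MAT_INF, SegType.PAT_INF, SegType.BOTH_INF], dtype=object)


@dataclass
class TrueMap:
    """Ground-truth genetic map of a simulated cross.

    ``table`` has one row per marker in genome order with columns
    ``marker``, ``group``, ``order``, ``female_cM``, ``male_cM``,
    ``segtype``, ``rad_locus``.  Positions start at 0 in each group and are
    non-decreasing along the order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        pos = self.table[["female_cM", "male_cM"]].to_numpy()
        if (pos < 0).any():
            raise ConfigError("map positions must be non-negative")
        for _, sub in self.table.groupby("group", sort=False):
            p = sub[["female_cM", "male_cM"]].to_numpy()
            if p[0].max() != 0.0 or (np.diff(p, axis=0) < -1e-12).any():
                raise ConfigError("positions must start at 0 and be non-decreasing")
        if self.table["marker"].duplicated().any():
            raise ConfigError("marker ids must be unique genome-wide")

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["group"]))

    def group_table(self, group) -> pd.DataFrame:
        return self.table[self.table["group"] == group].reset_index(drop=True)

    def group_lengths(self) -> pd.DataFrame:
        g = self.table.groupby("group", sort=False)
        return pd.DataFrame(
            {
                "n_markers": g.size(),
                "female_cM": g["female_cM"].max(),
                "male_cM": g["male_cM"].max(),
            }
        )


def _locus_sizes(rng, n_markers: int, proportions) -> np.ndarray:
    """Sample RAD-locus SNP counts until they tile ``n_markers`` markers."""
    sizes = []
    total = 0
    while total < n_markers:
        k = int(rng.choice(4, p=np.asarray(proportions) / sum(proportions))) + 1
        k = min(k, n_markers - total)
        sizes.append(k)
        total += k
    return np.array(sizes)


def simulate_true_map(cfg: SimConfig) -> TrueMap:
    """Draw a ground-truth map per the configured cross design.

    Male inter-locus distances are exponential with mean
    ``cfg.mean_spacing_cM``; SNPs within one RAD locus sit at the same
    position; female distances are the male distances scaled by
    ``cfg.female_expansion``.  Segregation types are drawn i.i.d. from
    ``cfg.seg_mixture``.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    rows = []
    locus_counter = 0
    for g in range(cfg.n_groups):
        group = f"LG{g + 1:02d}"
        sizes = _locus_sizes(rng, cfg.markers_per_group, cfg.rad_multi_snp)
        male_pos = []
        rad = []
        marker_ids = []
        pos = 0.0
        for size in sizes:
            locus_counter += 1
            locus = f"RAD{locus_counter:06d}"
            if male_pos:  # exponential gap before each new locus
                pos += float(rng.exponential(cfg.mean_spacing_cM))
            for k in range(size):
                male_pos.append(pos)
                rad.append(locus)
                marker_ids.append(f"{locus}_{k + 1}")
        male_pos = np.array(male_pos)
        male_pos -= male_pos[0]
        female_pos = male_pos * cfg.female_expansion
        seg = rng.choice(3, size=len(male_pos), p=np.asarray(cfg.seg_mixture))
        for j in range(len(male_pos)):
            rows.append(
                (marker_ids[j], group, j, female_pos[j], male_pos[j], _SEGTYPES[seg[j]].value, rad[j])
            )
    return TrueMap(
        pd.DataFrame(
            rows,
            columns=["marker", "group", "order", "female_cM", "male_cM", "segtype", "rad_locus"],
        )
    )


def simulate_gametes(true_map: TrueMap, parent: str, n: int, seed) -> dict:
    """Simulate haplotype-origin sequences for ``n`` meioses of one parent.

    Returns ``{group: uint8 array (n, n_markers_in_group)}`` where entry 0/1
    says which parental haplotype the offspring inherited at that marker.
    Origin switches between adjacent markers independently per interval with
    the Haldane probability for the parent's sex-specific distance.
    """
    if parent not in ("mother", "father"):
        raise ConfigError("parent must be 'mother' or 'father'")
    if n < 1:
        raise ConfigError("n must be >= 1")
    col = "female_cM" if parent == "mother" else "male_cM"
    rng = np.random.default_rng(seed)
    out = {}
    for group in true_map.groups:
        pos = true_map.group_table(group)[col].to_numpy()
        m = len(pos)
        r = haldane_r(np.diff(pos))
        start = rng.integers(0, 2, size=n, dtype=np.uint8)
        if m == 1:
            out[group] = start[:, None]
            continue
        switch = (rng.random((n, m - 1)) < r[None, :]).astype(np.uint8)
        origins = np.concatenate([start[:, None], switch], axis=1)
        out[group] = np.cumsum(origins, axis=1, dtype=np.int64).astype(np.uint8) % 2
    return out


def simulate_offspring_genotypes(true_map: TrueMap, cfg: SimConfig):
    """Simulate parental and offspring genotype calls for the whole cross.

    Parents follow each marker's segregation type (the homozygous parent of a
    single-informative marker is AA or aa with equal probability, and the
    heterozygote's phase is random).  Each offspring call is the transmitted
    maternal plus paternal allele, then corrupted: with probability
    ``error_rate`` it is replaced by one of the other two genotypes uniformly,
    and with probability ``missing_rate`` it is set missing.

    Returns
    -------
    (GenotypeMatrix, dict)
        The genotype matrix (parents first) and a truth dict with the
        maternal/paternal origin matrices and parental haplotype phases.
    """
    cfg.validate()
    n = cfg.n_offspring
    mat_gam = simulate_gametes(true_map, "mother", n, np.random.SeedSequence([int(cfg.seed), 1]))
    pat_gam = simulate_gametes(true_map, "father", n, np.random.SeedSequence([int(cfg.seed), 2]))
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 3]))

    tab = true_map.table
    M = len(tab)
    segtype = tab["segtype"].to_numpy()
    mat_origin = np.vstack([mat_gam[g].T for g in true_map.groups])  # (M, n)
    pat_origin = np.vstack([pat_gam[g].T for g in true_map.groups])

    mother = np.empty(M, dtype=np.int8)
    father = np.empty(M, dtype=np.int8)
    # haplotype allele carried on haplotypes 0/1 of each parent
    mother_haps = np.empty((M, 2), dtype=np.int8)
    father_haps = np.empty((M, 2), dtype=np.int8)
    mother_phase = rng.integers(0, 2, size=M).astype(np.int8)
    father_phase = rng.integers(0, 2, size=M).astype(np.int8)
    hom_allele = rng.integers(0, 2, size=M).astype(np.int8)  # allele of the homozygous parent

    for i in range(M):
        st = segtype[i]
        if st == SegType.MAT_INF.value:
            mother[i] = HET
            mother_haps[i] = (mother_phase[i], 1 - mother_phase[i])
            father[i] = HOM_REF if hom_allele[i] == 0 else HOM_ALT
            father_haps[i] = (hom_allele[i], hom_allele[i])
        elif st == SegType.PAT_INF.value:
            father[i] = HET
            father_haps[i] = (father_phase[i], 1 - father_phase[i])
            mother[i] = HOM_REF if hom_allele[i] == 0 else HOM_ALT
            mother_haps[i] = (hom_allele[i], hom_allele[i])
        else:  # BOTH_INF
            mother[i] = HET
            father[i] = HET
            mother_haps[i] = (mother_phase[i], 1 - mother_phase[i])
            father_haps[i] = (father_phase[i], 1 - father_phase[i])

    rows = np.arange(M)[:, None]
    a_m = mother_haps[rows, mat_origin]
    a_f = father_haps[rows, pat_origin]
    geno = (a_m + a_f).astype(np.int8)

    err = rng.random((M, n)) < cfg.error_rate
    shift = rng.integers(1, 3, size=(M, n)).astype(np.int8)
    geno = np.where(err, (geno + shift) % 3, geno).astype(np.int8)
    geno = np.where(rng.random((M, n)) < cfg.missing_rate, MISSING, geno).astype(np.int8)

    matrix = GenotypeMatrix(
        marker_ids=tab["marker"].to_numpy(dtype=object),
        rad_locus=tab["rad_locus"].to_numpy(dtype=object),
        mother=mother,
        father=father,
        offspring=geno,
    )
    truth = {
        "maternal_origin": mat_origin,
        "paternal_origin": pat_origin,
        "mother_phase": mother_phase,
        "father_phase": father_phase,
    }
    return matrix, truth


def simulate_cross(cfg: SimConfig):
    """Convenience: draw a true map and genotypes in one call."""
    true_map = simulate_true_map(cfg)
    matrix, truth = simulate_offspring_genotypes(true_map, cfg)
    return true_map, matrix, truth


def write_truth(true_map: TrueMap, truth: dict, outdir) -> None:
    """Write the true map and per-offspring haplotype origins as TSVs."""
    os.makedirs(outdir, exist_ok=True)
    write_tsv(true_map.table, os.path.join(outdir, "true_map.tsv"), "true_map")
    for parent, key in (("maternal", "maternal_origin"), ("paternal", "paternal_origin")):
        df = pd.DataFrame(
            truth[key],
            columns=[f"OFF{i + 1:03d}" for i in range(truth[key].shape[1])],
        )
        df.insert(0, "marker", true_map.table["marker"].to_numpy())
        write_tsv(df, os.path.join(outdir, f"true_{parent}_origin.tsv"), f"true_{parent}_origin")


# ---------------------------------------------------------------------------
# Synthetic reference mappings (for the synteny stage)
# ---------------------------------------------------------------------------

def _chrom_number(name: str) -> int:
    digits = "".join(c for c in str(name) if c.isdigit())
    return int(digits) if digits else 0


def _arm_weights(arms: pd.DataFrame, lore_rate: float) -> np.ndarray:
    lengths = (arms["end"] - arms["start"]).to_numpy(dtype=float)
    w = lengths * np.where(arms["class"].to_numpy() == "LORe", lore_rate, 1.0)
    return w


def simulate_arm_hits(arms: pd.DataFrame, n_hits: int, lore_rate: float = 1.0,
                      mapq: int = 60, seed=0) -> pd.DataFrame:
    """Scatter ``n_hits`` marker mappings over reference arms.

    Hit probability is proportional to arm length, with LORe arms receiving
    hits at ``lore_rate`` times their length-proportional rate — emulating the
    loss of confident cross-species mappings in lineage-specifically
    rediploidized regions.
    """
    rng = np.random.default_rng(seed)
    w = _arm_weights(arms, lore_rate)
    idx = rng.choice(len(arms), size=n_hits, p=w / w.sum())
    start = arms["start"].to_numpy()[idx]
    end = arms["end"].to_numpy()[idx]
    pos = start + (rng.random(n_hits) * (end - start)).astype(np.int64)
    return pd.DataFrame(
        {
            "marker": [f"HIT{i + 1:06d}" for i in range(n_hits)],
            "chrom": arms["chrom"].to_numpy()[idx],
            "pos": pos,
            "mapq": np.full(n_hits, mapq, dtype=int),
        }
    )


def simulate_mapping_records(map_table: pd.DataFrame, arms: pd.DataFrame,
                             hits_per_group: int = 20, discordant_rate: float = 0.05,
                             lore_rate: float = 1.0, mapq_range=(0, 60), seed=0):
    """Simulate reference-genome mappings for markers of an existing map.

    Each linkage group is assigned a homologous reference chromosome (cycling
    through the chromosomes of ``arms``); a random subset of its markers maps
    there, except a ``discordant_rate`` fraction that maps to a random other
    chromosome.  Within the target chromosome the arm is chosen with
    probability proportional to length (LORe arms down-weighted by
    ``lore_rate``) and the bp position uniformly within the arm.  MAPQ is
    uniform over ``mapq_range``.

    Returns ``(records, truth)`` where truth maps group -> homolog chromosome.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(arms["chrom"].unique(), key=_chrom_number)
    groups = list(dict.fromkeys(map_table["group"]))
    truth = {g: chroms[i % len(chroms)] for i, g in enumerate(groups)}
    rows = []
    for g in groups:
        markers = map_table.loc[map_table["group"] == g, "marker"].to_numpy()
        take = rng.choice(len(markers), size=min(hits_per_group, len(markers)), replace=False)
        for t in np.sort(take):
            chrom = truth[g]
            if len(chroms) > 1 and rng.random() < discordant_rate:
                chrom = chroms[int(rng.choice([c for c in range(len(chroms)) if chroms[c] != truth[g]]))]
            sub = arms[arms["chrom"] == chrom]
            w = _arm_weights(sub, lore_rate)
            a = sub.iloc[int(rng.choice(len(sub), p=w / w.sum()))]
            pos = int(a["start"] + rng.random() * (a["end"] - a["start"]))
            mapq = int(rng.integers(mapq_range[0], mapq_range[1] + 1))
            rows.append((markers[t], chrom, pos, mapq))
    records = pd.DataFrame(rows, columns=["marker", "chrom", "pos", "mapq"])
    return records, truth
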