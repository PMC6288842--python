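"""Shared containers and genotype I/O for the whitemap pipeline.

Genotypes are hard diploid calls at biallelic SNPs, coded as small integers:
``0`` homozygous reference (AA), ``1`` heterozygous (Aa), ``2`` homozygous
alternate (aa) and ``-1`` missing.  The integer code of a non-missing call
equals its alternate-allele count, which the simulator and the transmission
logic both rely on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2

GENOTYPE_CODES = (HOM_REF, HET, HOM_ALT)

#: VCF GT strings for each internal code (unphased).
_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


class WhitemapError(Exception):
    """Base class for errors raised by this package."""


class InputError(WhitemapError):
    """Malformed input data (non-biallelic record, missing sample, ...)."""


class ConfigError(WhitemapError):
    """Invalid configuration values."""


class SegType(str, enum.Enum):
    """Segregation type of a marker in an F1 outbred cross.

    ``MAT_INF``: mother Aa x father homozygous — every offspring call reveals
    the maternal transmitted allele.  ``PAT_INF``: the mirror image.
    ``BOTH_INF``: Aa x Aa — homozygous offspring reveal both transmitted
    alleles, heterozygous offspring are phase-uninformative.
    """

    MAT_INF = "MAT_INF"
    PAT_INF = "PAT_INF"
    BOTH_INF = "BOTH_INF"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass
class GenotypeMatrix:
    """Parent + offspring genotype calls at biallelic SNP markers.

    Attributes
    ----------
    marker_ids : object ndarray, shape (M,)
        Unique marker identifiers.
    rad_locus : object ndarray, shape (M,)
        RAD locus identifier of each marker (SNPs on one RAD fragment share it).
    mother, father : int8 ndarray, shape (M,)
        Parental genotype codes.
    offspring : int8 ndarray, shape (M, N)
        Offspring genotype codes, one column per offspring.
    offspring_ids : list of str
        Column labels for ``offspring``.
    """

    marker_ids: np.ndarray
    rad_locus: np.ndarray
    mother: np.ndarray
    father: np.ndarray
    offspring: np.ndarray
    offspring_ids: list = field(default_factory=list)
    mother_id: str = "MOTHER"
    father_id: str = "FATHER"

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.rad_locus = np.asarray(self.rad_locus, dtype=object)
        self.mother = np.asarray(self.mother, dtype=np.int8)
        self.father = np.asarray(self.father, dtype=np.int8)
        self.offspring = np.asarray(self.offspring, dtype=np.int8)
        m = len(self.marker_ids)
        if self.offspring.ndim != 2 or self.offspring.shape[0] != m:
            raise InputError("offspring array must be (n_markers, n_offspring)")
        if len(self.mother) != m or len(self.father) != m:
            raise InputError("parent genotype vectors must match marker count")
        if not self.offspring_ids:
            self.offspring_ids = [f"OFF{i + 1:03d}" for i in range(self.offspring.shape[1])]
        if len(set(self.marker_ids)) != m:
            raise InputError("marker ids must be unique")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_offspring(self) -> int:
        return self.offspring.shape[1]

    def take(self, index) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given marker index array."""
        index = np.asarray(index)
        return GenotypeMatrix(
            marker_ids=self.marker_ids[index],
            rad_locus=self.rad_locus[index],
            mother=self.mother[index],
            father=self.father[index],
            offspring=self.offspring[index],
            offspring_ids=list(self.offspring_ids),
            mother_id=self.mother_id,
            father_id=self.father_id,
        )

    def marker_index(self) -> dict:
        return {mid: i for i, mid in enumerate(self.marker_ids)}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF v4.2: parents first, then offspring.

    The CHROM column carries the RAD locus id and POS the 1-based index of
    the SNP within its locus, mirroring a de novo RAD reference.  Plain-text
    output keeps runs with identical inputs byte-identical.
    """
    samples = [matrix.mother_id, matrix.father_id] + list(matrix.offspring_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##source=whitemap\n")
        for locus in dict.fromkeys(str(l) for l in matrix.rad_locus):
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        pos_in_locus: dict = {}
        for i in range(matrix.n_markers):
            locus = str(matrix.rad_locus[i])
            pos_in_locus[locus] = pos_in_locus.get(locus, 0) + 1
            gts = [_GT_STRINGS[int(matrix.mother[i])], _GT_STRINGS[int(matrix.father[i])]]
            gts += [_GT_STRINGS[int(g)] for g in matrix.offspring[i]]
            fh.write(
                f"{locus}\t{pos_in_locus[locus]}\t{matrix.marker_ids[i]}\tA\tC\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path, mother: str = "MOTHER", father: str = "FATHER") -> GenotypeMatrix:
    """Load a GT-only biallelic VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : str
        Plain or bgzipped VCF.
    mother, father : str
        Sample names of the two parents; all other samples are offspring.

    Raises
    ------
    InputError
        If a record is not a biallelic SNP or a parent sample is absent.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if mother not in samples or father not in samples:
        raise InputError(f"parent samples {mother!r}/{father!r} not found in VCF ({samples[:4]}...)")
    im, ip = samples.index(mother), samples.index(father)
    off_idx = [i for i in range(len(samples)) if i not in (im, ip)]

    marker_ids, rad_locus, mo, fa, off = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            raise InputError(f"non-biallelic-SNP record at {var.CHROM}:{var.POS}")
        # gts012: 0/1/2 = alt-allele count, 3 = unknown
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        rad_locus.append(var.CHROM)
        mo.append(g[im])
        fa.append(g[ip])
        off.append(g[off_idx])
    if not marker_ids:
        raise InputError("VCF contains no records")
    return GenotypeMatrix(
        marker_ids=np.array(marker_ids, dtype=object),
        rad_locus=np.array(rad_locus, dtype=object),
        mother=np.array(mo, dtype=np.int8),
        father=np.array(fa, dtype=np.int8),
        offspring=np.vstack(off).astype(np.int8),
        offspring_ids=[samples[i] for i in off_idx],
        mother_id=mother,
        father_id=father,
    )


def write_tsv(df: pd.DataFrame, path, schema: str, version: int = 1) -> None:
    """Write a TSV with a leading versioned schema comment line."""
    with open(path, "w") as fh:
        fh.write(f"# schema: whitemap.{schema}.v{version}: {' '.join(map(str, df.columns))}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
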