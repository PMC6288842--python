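"""Summary statistics of a genetic map: lengths, densities, heterochiasmy.

Works identically on a map built by this package and on the packaged
per-linkage-group summary of the published whitefish maps (40 groups, 5395
SNPs), so the printed totals, mean group lengths, marker densities and
female:male recombination ratios can be recomputed from either source.

The genome-wide female:male ratio is reported two ways, as in the study:
from total map lengths (insensitive to groups that are 0 cM in one sex),
and as the mean of per-group ratios over groups with positive length in
both sex maps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .core import WhitemapError
from .linkage_core import GeneticMap

__all__ = ["MapSummary", "Table1Fixture", "load_table1", "summarize"]

#: sha256 of the packaged published-map summary (fixture integrity check).
_TABLE1_SHA256 = "9510b21834ab34a1974d265a67f67ea4538c59278ac6f56ad5ad76ba0cf1b21e"

# In the published table the per-map density column equals group length
# divided by SNP count (e.g. 75.96/253 = 0.30), i.e. cM per marker; the
# fixture therefore names it `cM_per_marker`.


@dataclass
class Table1Fixture:
    """Per-group summary of the published whitefish linkage maps."""

    table: pd.DataFrame

    def column_sums(self) -> pd.Series:
        return self.table[["n_snps", "averaged_cM", "female_cM", "male_cM"]].sum()


def load_table1(path=None) -> Table1Fixture:
    """Load the packaged published-map summary (or one at ``path``).

    The packaged copy is verified against a stored sha256 before use.
    """
    if path is None:
        ref = resources.files("whitemap").joinpath("data/table1_whitefish.csv")
        raw = ref.read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE1_SHA256:
            raise WhitemapError(
                f"packaged map-summary fixture is corrupted (sha256 {digest[:12]}...)"
            )
        import io

        df = pd.read_csv(io.BytesIO(raw))
    else:
        df = pd.read_csv(path)
    if len(df) != 40:
        raise WhitemapError(f"expected 40 linkage groups, found {len(df)}")
    return Table1Fixture(table=df)


@dataclass
class MapSummary:
    """Per-group and global statistics of a genetic map.

    ``per_group`` carries one row per linkage group (SNP count, length and
    cM-per-marker for each map, female:male ratio — NaN where a sex length
    is 0).  ``totals`` is a flat dict of the global quantities; rounded
    two-decimal companions are available via :meth:`rounded`.
    """

    per_group: pd.DataFrame
    totals: dict

    def rounded(self) -> dict:
        return {k: (round(v, 2) if isinstance(v, float) and np.isfinite(v) else v)
                for k, v in self.totals.items()}

    def report(self) -> str:
        t = self.rounded()

        def fmt(v):
            return "NA" if (isinstance(v, float) and not np.isfinite(v)) else v

        lines = [
            "Genetic map summary",
            "-------------------",
            f"linkage groups:            {t['n_groups']}",
            f"SNP markers:               {t['snp_total']}",
            f"mean markers per group:    {fmt(t['mean_markers_per_group'])}",
            "",
            "                       sex-averaged    female      male",
            f"total length (cM)      {fmt(t['total_averaged_cM']):>12}  {fmt(t['total_female_cM']):>8}  {fmt(t['total_male_cM']):>8}",
            f"mean group length (cM) {fmt(t['mean_group_len_averaged']):>12}  {fmt(t['mean_group_len_female']):>8}  {fmt(t['mean_group_len_male']):>8}",
            f"mean cM per marker     {fmt(t['mean_cM_per_marker_averaged']):>12}  {fmt(t['mean_cM_per_marker_female']):>8}  {fmt(t['mean_cM_per_marker_male']):>8}",
            "",
            f"female:male ratio (total lengths):        {fmt(t['fm_ratio_total'])}",
            f"female:male ratio (per-group mean, >0 cM): {fmt(t['fm_ratio_per_group'])}",
        ]
        return "\n".join(lines)


def _per_group_frame(source) -> pd.DataFrame:
    if isinstance(source, Table1Fixture):
        df = source.table[["group", "n_snps", "averaged_cM", "female_cM", "male_cM"]].copy()
        return df.set_index("group")
    if isinstance(source, GeneticMap):
        return source.group_lengths()
    if isinstance(source, pd.DataFrame):
        need = {"n_snps", "averaged_cM", "female_cM", "male_cM"}
        if not need.issubset(source.columns):
            raise WhitemapError(f"per-group frame needs columns {sorted(need)}")
        return source.set_index("group") if "group" in source.columns else source
    raise WhitemapError(f"cannot summarize object of type {type(source).__name__}")


def summarize(source) -> MapSummary:
    """Compute the per-group and global map statistics.

    ``source`` may be a :class:`~whitemap.linkage_core.GeneticMap`, a
    :class:`Table1Fixture`, or a per-group DataFrame with columns
    ``n_snps``/``averaged_cM``/``female_cM``/``male_cM``.

    Group length is the last (maximum) marker position; cM-per-marker is
    length / SNP count; global mean spacing is the unweighted mean of the
    per-group values (the whole-map alternative, total length / total SNPs,
    is reported as ``overall_cM_per_marker_*``).  Ratios with a zero
    denominator are NaN and excluded from per-group means.
    """
    pg = _per_group_frame(source).copy()
    if len(pg) == 0:
        raise WhitemapError("cannot summarize an empty map")
    for m in ("averaged", "female", "male"):
        pg[f"{m}_cM_per_marker"] = pg[f"{m}_cM"] / pg["n_snps"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pg["female_cM"] / pg["male_cM"]
    pg["fm_ratio"] = np.where((pg["female_cM"] > 0) & (pg["male_cM"] > 0), ratio, np.nan)

    totals = {
        "n_groups": int(len(pg)),
        "snp_total": int(pg["n_snps"].sum()),
        "mean_markers_per_group": float(pg["n_snps"].mean()),
    }
    for m in ("averaged", "female", "male"):
        length = pg[f"{m}_cM"]
        totals[f"total_{m}_cM"] = float(length.sum())
        totals[f"mean_group_len_{m}"] = float(length.mean())
        totals[f"mean_cM_per_marker_{m}"] = float(pg[f"{m}_cM_per_marker"].mean())
        totals[f"overall_cM_per_marker_{m}"] = (
            float(length.sum() / pg["n_snps"].sum()) if pg["n_snps"].sum() else np.nan
        )
    totals["fm_ratio_total"] = (
        float(pg["female_cM"].sum() / pg["male_cM"].sum()) if pg["male_cM"].sum() > 0 else np.nan
    )
    ok = pg["fm_ratio"].dropna()
    totals["fm_ratio_per_group"] = float(ok.mean()) if len(ok) else np.nan
    return MapSummary(per_group=pg.reset_index(), totals=totals)
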