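"""Two-point linkage estimation, grouping, ordering and map construction.

The estimation substrate is the *transmission matrix*: for each marker and
parent, the allele that parent transmitted to each offspring (0/1) where the
offspring call reveals it, or unknown.  A mother-informative marker (Aa x
hom) reveals the maternal allele in every non-missing offspring; a double
heterozygote (Aa x Aa) reveals both transmitted alleles in homozygous
offspring only.  Phase is unknown, so two-point recombination is counted
under one arbitrary phase and folded: r_hat = min(f, 1 - f).

The two-point LOD against free recombination is

    LOD = k log10(2 r) + (n - k) log10(2 (1 - r)),   k = n r recombinants,

with the limit n log10(2) at r = 0.  Linkage groups are single-linkage
components at a LOD threshold; ordering minimizes the sum of adjacent
recombination fractions (SARF) with a seriation start plus 2-opt local
search, best of several seeded restarts; map distances use the Haldane
function d = -50 ln(1 - 2r) cM, per parent (female map from maternal
meioses, male from paternal, sex-averaged from both pooled).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .core import (
    GenotypeMatrix,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SegType,
    WhitemapError,
)

logger = logging.getLogger(__name__)

LOG10_2 = np.log10(2.0)

__all__ = [
    "PairEstimate",
    "PairwiseEstimates",
    "LinkageGroupSet",
    "GeneticMap",
    "OrderingError",
    "transmission_matrix",
    "pairwise_rf_lod",
    "pairwise_all",
    "em_rf_lod",
    "separate_groups",
    "order_markers",
    "order_exhaustive",
    "sarf",
    "map_positions",
    "build_genetic_map",
]


class OrderingError(WhitemapError):
    """Raised when a linkage group cannot be ordered (disconnected estimates)."""


# ---------------------------------------------------------------------------
# Transmission matrices and counting estimates
# ---------------------------------------------------------------------------

def transmission_matrix(matrix: GenotypeMatrix, segcalls: pd.DataFrame, parent: str) -> np.ndarray:
    """Transmitted-allele matrix (M x N) for one parent; -1 where unknown.

    Alleles are counted on the alternate-allele scale (0 = ref transmitted,
    1 = alt).  Mendelian-impossible offspring calls are treated as unknown.
    """
    if parent not in ("mother", "father"):
        raise ValueError("parent must be 'mother' or 'father'")
    seg = segcalls.set_index("marker")["segtype"].reindex(matrix.marker_ids).to_numpy()
    T = np.full(matrix.offspring.shape, -1, dtype=np.int8)
    own_inf = SegType.MAT_INF.value if parent == "mother" else SegType.PAT_INF.value
    other_hom = matrix.father if parent == "mother" else matrix.mother

    for i in range(matrix.n_markers):
        g = matrix.offspring[i]
        if seg[i] == own_inf:
            # this parent het, the other hom with allele a: offspring g = t + a
            a = 0 if other_hom[i] == HOM_REF else 1
            t = g - a
            valid = (g != MISSING) & (t >= 0) & (t <= 1)
            T[i, valid] = t[valid]
        elif seg[i] == SegType.BOTH_INF.value:
            T[i, g == HOM_REF] = 0
            T[i, g == HOM_ALT] = 1
    return T


def _pair_counts(T: np.ndarray):
    """All-pairs folded recombinant (k) and meiosis (n) counts for one parent.

    Vectorized over markers: with indicator matrices for transmitted allele
    0 and 1, ``n`` is the co-observed count and ``k`` the phase-folded
    discordance count min(diff, same).
    """
    K0 = (T == 0).astype(np.float32)
    K1 = (T == 1).astype(np.float32)
    known = K0 + K1
    n = known @ known.T
    same = K0 @ K0.T + K1 @ K1.T
    diff = n - same
    k = np.minimum(diff, same)
    return k, n


def _lod_from_counts(k, n):
    """Two-point LOD for folded counts; 0 where n = 0 or r = 0.5."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, k / np.maximum(n, 1), 0.5)
        term = np.where(
            (k > 0) & (r < 0.5),
            k * np.log10(np.maximum(2.0 * r, 1e-300)),
            0.0,
        )
        lod = term + (n - k) * np.log10(np.maximum(2.0 * (1.0 - r), 1e-300))
    lod = np.where((n == 0) | (r >= 0.5), 0.0, lod)
    return lod


def _rf_from_counts(k, n):
    with np.errstate(invalid="ignore"):
        r = np.where(np.asarray(n) > 0, np.asarray(k, float) / np.maximum(n, 1), np.nan)
    return r


@dataclass
class PairEstimate:
    """Two-point estimate for one marker pair in one parental context."""

    marker_a: str
    marker_b: str
    context: str  # maternal | paternal | joint
    rf: float
    lod: float
    n_meioses: int
    method: str = "counting"  # counting | em


@dataclass
class PairwiseEstimates:
    """All-pairs r/LOD/meiosis-count matrices per context.

    ``rf_joint`` pools recombinant and meiosis counts over the two parents;
    ``lod_joint`` is the sum of the two per-parent LODs (meioses of the two
    parents are independent).
    """

    marker_ids: np.ndarray
    rf_maternal: np.ndarray
    lod_maternal: np.ndarray
    n_maternal: np.ndarray
    rf_paternal: np.ndarray
    lod_paternal: np.ndarray
    n_paternal: np.ndarray
    rf_joint: np.ndarray
    lod_joint: np.ndarray
    n_joint: np.ndarray

    def rf(self, context: str) -> np.ndarray:
        return getattr(self, f"rf_{context}")


def _em_pairs_both(G: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    """Vectorized two-locus EM over all pairs of double-heterozygous markers.

    For Aa x Aa marker pairs the doubly homozygous offspring that the
    counting estimator relies on are nearly absent when the two loci are in
    repulsion in a parent, so counting collapses to a handful of meioses.
    The EM instead uses *every* offspring: hidden variables are the four
    transmitted alleles (phase flips map r to 1-r, so fitting r in (0, 1)
    under one phase and folding covers all phase configurations).  Because
    an offspring genotype is the sum of the maternal and paternal
    transmitted alleles, the likelihood is symmetric in the two parents'
    recombination fractions: sex-specific r is not identifiable from such
    pairs, and the EM returns the pooled estimate for both parents.

    ``G`` is the (b, N) genotype block of the double-het markers.  Returns
    folded ``(rm, rf, lod, n_obs)`` matrices (b, b), where ``lod`` is the
    joint likelihood ratio against rm = rf = 1/2 and ``n_obs`` the number
    of offspring with both genotypes observed.
    """
    b = G.shape[0]
    ind = [(G == g).astype(np.float32) for g in (HOM_REF, HET, HOM_ALT)]
    # per ordered class (a, c): number of offspring with g_i = a and g_j = c
    C = {(a, c): ind[a] @ ind[c].T for a in range(3) for c in range(3)}
    n_obs = sum(C.values())
    denom = np.maximum(n_obs, 1e-300)

    def run(phase_f: int):
        """EM under one father-phase structure; mother phase is absorbed by
        fitting r in (0, 1).  Same-phase and opposite-phase parent pairs are
        different structures, so both are fit and compared by likelihood."""
        rm = np.full((b, b), 0.25)
        rf = np.full((b, b), 0.25)
        for _ in range(max_iter):
            em = np.zeros((b, b))
            ef = np.zeros((b, b))
            for (cls, (dm, df)) in _EM_STRUCT.items():
                c = C[cls]
                s = np.zeros((b, b))
                num_m = np.zeros((b, b))
                num_f = np.zeros((b, b))
                for h in range(len(dm)):
                    dfx = df[h] ^ phase_f
                    w = (rm if dm[h] else 1 - rm) * (rf if dfx else 1 - rf)
                    s += w
                    num_m += w * dm[h]
                    num_f += w * dfx
                em += c * num_m / np.maximum(s, 1e-300)
                ef += c * num_f / np.maximum(s, 1e-300)
            rm_new = np.clip(em / denom, 1e-9, 1 - 1e-9)
            rf_new = np.clip(ef / denom, 1e-9, 1 - 1e-9)
            delta = max(np.abs(rm_new - rm).max(initial=0),
                        np.abs(rf_new - rf).max(initial=0))
            rm, rf = rm_new, rf_new
            if delta < tol:
                break
        ll = np.zeros((b, b))
        for (cls, (dm, df)) in _EM_STRUCT.items():
            s = np.zeros((b, b))
            for h in range(len(dm)):
                dfx = df[h] ^ phase_f
                s += (rm if dm[h] else 1 - rm) * (rf if dfx else 1 - rf)
            ll += C[cls] * np.log(np.maximum(s, 1e-300))
        return rm, rf, ll

    rm0, rf0, ll0 = run(0)
    rm1, rf1, ll1 = run(1)
    pick1 = ll1 > ll0
    rm = np.where(pick1, rm1, rm0)
    rf = np.where(pick1, rf1, rf0)
    ll = np.where(pick1, ll1, ll0)

    ll_null = np.zeros((b, b))
    for (cls, (dm, _)) in _EM_STRUCT.items():
        ll_null += C[cls] * np.log(0.25 * len(dm))
    lod = np.maximum((ll - ll_null) / np.log(10.0), 0.0)
    return np.minimum(rm, 1 - rm), np.minimum(rf, 1 - rf), lod, n_obs


def pairwise_all(matrix: GenotypeMatrix, segcalls: pd.DataFrame) -> PairwiseEstimates:
    """Compute folded two-point r and LOD for all marker pairs, per context.

    Single-parent contexts use the counting estimator on that parent's
    informative meioses.  Pairs of double-heterozygous (Aa x Aa) markers are
    re-estimated by the vectorized two-locus EM, which recovers maternal and
    paternal r even in repulsion phase where counting has almost no shared
    meioses; their joint LOD is the EM likelihood ratio.
    """
    Tm = transmission_matrix(matrix, segcalls, "mother")
    Tp = transmission_matrix(matrix, segcalls, "father")
    km, nm = _pair_counts(Tm)
    kp, np_ = _pair_counts(Tp)
    lod_m = _lod_from_counts(km, nm)
    lod_p = _lod_from_counts(kp, np_)
    nj = nm + np_
    est = PairwiseEstimates(
        marker_ids=matrix.marker_ids,
        rf_maternal=_rf_from_counts(km, nm),
        lod_maternal=lod_m,
        n_maternal=nm,
        rf_paternal=_rf_from_counts(kp, np_),
        lod_paternal=lod_p,
        n_paternal=np_,
        rf_joint=_rf_from_counts(km + kp, nj),
        lod_joint=lod_m + lod_p,
        n_joint=nj,
    )
    seg = segcalls.set_index("marker")["segtype"].reindex(matrix.marker_ids).to_numpy()
    both = np.flatnonzero(seg == SegType.BOTH_INF.value)
    if len(both) >= 2:
        # EM improves the *joint* estimates only: sex-specific r is not
        # identifiable from double-het pairs, so the per-parent matrices
        # keep the counting estimates with their honest meiosis counts.
        rm, rf, lod, n_obs = _em_pairs_both(matrix.offspring[both])
        ix = np.ix_(both, both)
        est.rf_joint[ix] = np.where(n_obs > 0, (rm + rf) / 2.0, np.nan)
        est.lod_joint[ix] = lod
        est.n_joint[ix] = 2 * n_obs
        np.fill_diagonal(est.rf_joint, np.nan)
        np.fill_diagonal(est.lod_joint, 0.0)
    return est


def _single_pair_counts(t1: np.ndarray, t2: np.ndarray):
    known = (t1 >= 0) & (t2 >= 0)
    n = int(known.sum())
    diff = int((t1[known] != t2[known]).sum())
    return min(diff, n - diff), n


def pairwise_rf_lod(matrix: GenotypeMatrix, segcalls: pd.DataFrame, pair,
                    context: str = "joint") -> PairEstimate | None:
    """Two-point estimate for a single marker pair.

    ``context`` selects whose meioses are used: ``maternal``, ``paternal``,
    or ``joint`` (both parents).  Double-heterozygous pairs in the joint
    context are estimated by EM over the two-locus transmission likelihood
    (double-heterozygous offspring are a phase mixture); all other cases use
    the exact folded counting estimator.  Returns ``None`` when the pair has
    no informative meioses in the requested context.
    """
    a, b = pair
    idx = matrix.marker_index()
    ia, ib = idx[a], idx[b]
    seg = segcalls.set_index("marker")["segtype"]
    sa, sb = seg[a], seg[b]

    if context == "joint" and sa == SegType.BOTH_INF.value and sb == SegType.BOTH_INF.value:
        est = em_rf_lod(matrix.offspring[ia], matrix.offspring[ib])
        if est is None:
            return None
        rf, lod, n = est
        return PairEstimate(a, b, context, rf, lod, n, method="em")

    k = n = 0
    lod = 0.0
    used = False
    sub = matrix.take([ia, ib])
    sc = segcalls[segcalls["marker"].isin([a, b])].reset_index(drop=True)
    for par in ("maternal", "paternal"):
        if context not in (par, "joint"):
            continue
        T = transmission_matrix(sub, sc, "mother" if par == "maternal" else "father")
        ki, ni = _single_pair_counts(T[0], T[1])
        if ni > 0:
            k += ki
            n += ni
            lod += float(_lod_from_counts(ki, ni))
            used = True
    if not used or n == 0:
        return None
    return PairEstimate(a, b, context, k / n, lod, n)


# ---------------------------------------------------------------------------
# EM for double-heterozygous (intercross-type) pairs, joint context
# ---------------------------------------------------------------------------

def _em_hidden_structure():
    """Per two-locus genotype class: arrays of (maternal, paternal) raw
    recombination indicators over compatible transmission combinations."""
    comp = {HOM_REF: [(0, 0)], HET: [(0, 1), (1, 0)], HOM_ALT: [(1, 1)]}
    struct = {}
    for g1 in (HOM_REF, HET, HOM_ALT):
        for g2 in (HOM_REF, HET, HOM_ALT):
            dm, df = [], []
            for (m1, f1) in comp[g1]:
                for (m2, f2) in comp[g2]:
                    dm.append(int(m1 != m2))
                    df.append(int(f1 != f2))
            struct[(g1, g2)] = (np.array(dm), np.array(df))
    return struct


_EM_STRUCT = _em_hidden_structure()


def em_rf_lod(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-6, max_iter: int = 100):
    """EM estimate of r for a pair of Aa x Aa markers using all offspring.

    Hidden variables are the four transmitted alleles per offspring; the two
    parental phase configurations (coupling/mixed) are each fit and the
    higher-likelihood one kept; the estimate is folded to [0, 0.5].

    Returns ``(rf, lod, n_meioses)`` or ``None`` when no offspring have both
    genotypes observed.
    """
    ok = (g1 != MISSING) & (g2 != MISSING)
    if not ok.any():
        return None
    pairs, counts = np.unique(np.stack([g1[ok], g2[ok]]), axis=1, return_counts=True)
    classes = [(int(a), int(b)) for a, b in pairs.T]
    N = int(counts.sum())

    def run(phase_f: int):
        r = 0.25
        for _ in range(max_iter):
            e_rec = 0.0
            for (cls, n_c) in zip(classes, counts):
                dm, df = _EM_STRUCT[cls]
                dmx = dm  # mother phase fixed at 0 (global flip is symmetric)
                dfx = df ^ phase_f
                w = (r ** dmx) * ((1 - r) ** (1 - dmx)) * (r ** dfx) * ((1 - r) ** (1 - dfx))
                s = w.sum()
                e_rec += n_c * float((w * (dmx + dfx)).sum() / s)
            r_new = min(max(e_rec / (2.0 * N), 1e-9), 1 - 1e-9)
            if abs(r_new - r) < tol:
                r = r_new
                break
            r = r_new
        ll = 0.0
        for (cls, n_c) in zip(classes, counts):
            dm, df = _EM_STRUCT[cls]
            dfx = df ^ phase_f
            w = (r ** dm) * ((1 - r) ** (1 - dm)) * (r ** dfx) * ((1 - r) ** (1 - dfx))
            ll += n_c * np.log(w.sum())
        return r, ll

    best_r, best_ll = max((run(0), run(1)), key=lambda t: t[1])
    ll_null = 0.0
    for (cls, n_c) in zip(classes, counts):
        dm, _ = _EM_STRUCT[cls]
        ll_null += n_c * np.log(len(dm) * 0.25)
    rf = min(best_r, 1.0 - best_r)
    lod = max((best_ll - ll_null) / np.log(10.0), 0.0)
    return float(rf), float(lod), 2 * N


# ---------------------------------------------------------------------------
# Linkage-group formation
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroupSet:
    """Partition of markers into linkage groups plus an unassigned pool."""

    groups: list  # list of object ndarrays of marker ids, largest first
    unassigned: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def labels(self) -> dict:
        """marker id -> group name ('LG01', ...); unassigned markers absent."""
        out = {}
        for gi, members in enumerate(self.groups):
            for mid in members:
                out[mid] = f"LG{gi + 1:02d}"
        return out


def separate_groups(estimates: PairwiseEstimates, lod_limit: float = 16.0,
                    min_markers: int = 25) -> LinkageGroupSet:
    """Single-linkage clustering of markers at a joint-LOD threshold.

    Marker pairs with LOD >= ``lod_limit`` (inclusive) are linked and the
    transitive closure taken; components smaller than ``min_markers`` are
    dissolved into the unassigned pool.  Groups are returned largest first
    (ties by their lexicographically smallest marker id).
    """
    lod = estimates.lod_joint
    adj = csr_matrix(np.triu(lod >= lod_limit, k=1))
    _, comp = connected_components(adj, directed=False)
    ids = estimates.marker_ids
    groups, singles = [], []
    for c in np.unique(comp):
        members = ids[comp == c]
        if len(members) >= min_markers:
            groups.append(members)
        else:
            singles.extend(members)
    groups.sort(key=lambda m: (-len(m), str(min(m, key=str))))
    return LinkageGroupSet(groups=groups, unassigned=np.array(sorted(singles, key=str), dtype=object))


# ---------------------------------------------------------------------------
# Marker ordering (SARF seriation + 2-opt, best of seeded restarts)
# ---------------------------------------------------------------------------

def sarf(order, R: np.ndarray) -> float:
    """Sum of adjacent recombination fractions along an order."""
    o = np.asarray(order)
    return float(R[o[:-1], o[1:]].sum())


def _greedy_insertion(R: np.ndarray, insert_seq) -> list:
    m = R.shape[0]
    if m == 1:
        return [0]
    a, b = np.unravel_index(np.argmax(R), R.shape)  # farthest pair as endpoints
    order = [int(min(a, b)), int(max(a, b))]
    for x in insert_seq:
        x = int(x)
        if x in order:
            continue
        costs = []
        for p in range(len(order) + 1):
            if p == 0:
                costs.append(R[x, order[0]])
            elif p == len(order):
                costs.append(R[order[-1], x])
            else:
                costs.append(R[order[p - 1], x] + R[x, order[p]] - R[order[p - 1], order[p]])
        pos = int(np.argmin(costs))
        order.insert(pos, x)
    return order


def _two_opt(order: list, R: np.ndarray) -> list:
    """Best-improvement 2-opt (segment reversal) until no move lowers SARF."""
    o = np.asarray(order)
    m = len(o)
    if m < 3:
        return list(o)
    while True:
        best_delta = -1e-12
        best_move = None
        for i in range(m - 1):
            js = np.arange(i + 1, m)
            left = R[o[i - 1], o[js]] - R[o[i - 1], o[i]] if i > 0 else np.zeros(len(js))
            jn = np.minimum(js + 1, m - 1)
            right = np.where(js < m - 1, R[o[i], o[jn]] - R[o[js], o[jn]], 0.0)
            delta = left + right
            jb = int(np.argmin(delta))
            if delta[jb] < best_delta:
                best_delta = float(delta[jb])
                best_move = (i, int(js[jb]))
        if best_move is None:
            break
        i, j = best_move
        o[i:j + 1] = o[i:j + 1][::-1]
    return list(o)


def _classical_mds_1d(D: np.ndarray) -> np.ndarray:
    """First principal coordinate of a (completed) distance matrix."""
    m = D.shape[0]
    J = np.eye(m) - 1.0 / m
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    return vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))


def _smacof_1d(D: np.ndarray, W: np.ndarray, p0: np.ndarray,
               max_iter: int = 300, tol: float = 1e-8) -> np.ndarray:
    """1-D weighted multidimensional scaling (SMACOF majorization).

    Fits marker coordinates so that |p_i - p_j| matches the target
    distances ``D`` under weights ``W``; the fixed-point update is the
    standard Guttman transform specialized to one dimension.
    """
    p = p0.astype(float).copy()
    row = W.sum(axis=1)
    row[row == 0] = 1.0
    for _ in range(max_iter):
        s = np.sign(p[:, None] - p[None, :])
        p_new = (W * (p[None, :] + D * s)).sum(axis=1) / row
        if np.abs(p_new - p).max() < tol:
            p = p_new
            break
        p = p_new
    return p - p.min()


def ordering_matrix(group_markers, estimates: PairwiseEstimates,
                    group_name: str = "") -> tuple:
    """Denoised within-group recombination fractions and a 1-D coordinate.

    Raw two-point estimates at study marker density are too noisy to order
    by directly: adjacent r is the same magnitude as its standard error, so
    the minimum-SARF path through the raw matrix undercuts the true order
    by chaining low-fluctuation pairs.  This builds the working matrix the
    ordering actually minimizes over:

    1. pairs without a direct estimate (mother-informative x
       father-informative) are completed with the shortest additive Haldane
       distance through markers sharing meioses with both;
    2. a 1-D coordinate per marker is fitted by weighted MDS (SMACOF,
       classical-MDS start) to the completed distances, pooling every
       pairwise estimate instead of single noisy pairs;
    3. the denoised recombination fraction of a pair is the Haldane
       transform of its coordinate gap.

    Returns ``(R_work, coord, sel)``: the denoised (m, m) matrix, the
    coordinate in sex-averaged cM, and the row indices of the group's
    markers in ``estimates``.

    Raises
    ------
    OrderingError
        If the group's estimate graph is disconnected.
    """
    ids = np.asarray(group_markers, dtype=object)
    pos = {mid: i for i, mid in enumerate(estimates.marker_ids)}
    sel = np.array([pos[m] for m in ids])
    R = estimates.rf_joint[np.ix_(sel, sel)].astype(float)
    N = estimates.n_joint[np.ix_(sel, sel)].astype(float)
    m = len(ids)
    if m == 1:
        return np.zeros((1, 1)), np.zeros(1), sel
    known = np.isfinite(R) & (N > 0)
    np.fill_diagonal(known, False)
    conn = known.copy()
    np.fill_diagonal(conn, True)
    ncomp, _ = connected_components(csr_matrix(conn), directed=False)
    if ncomp > 1:
        raise OrderingError(
            f"estimate graph disconnected in group {group_name or '<unnamed>'}"
        )
    # floor known distances: dense shortest_path treats exact zeros as
    # non-edges, which would disconnect perfectly linked pairs
    D_known = np.where(
        known,
        np.maximum(-50.0 * np.log(1.0 - 2.0 * np.clip(R, 0.0, 0.495)), 1e-6),
        np.inf,
    )
    np.fill_diagonal(D_known, 0.0)
    D_full = shortest_path(D_known, method="auto", directed=False)
    r_reg = np.where(known, (R * N + 0.5) / (N + 1.0), 0.5)
    W = np.where(known & (R < 0.4),
                 N * (1.0 - 2.0 * r_reg) ** 2 / (r_reg * (1.0 - r_reg)), 0.0)
    D0 = np.where(np.isfinite(D_known), D_known, 0.0)
    coord = _smacof_1d(D0, W, _classical_mds_1d(D_full))
    # refinement pass: refit against locally reliable distances only
    gap = np.abs(coord[:, None] - coord[None, :])
    coord = _smacof_1d(D0, np.where(gap <= 30.0, W, 0.0), coord)
    gap = np.abs(coord[:, None] - coord[None, :])
    R_work = 0.5 * (1.0 - np.exp(-2.0 * gap / 100.0))
    np.fill_diagonal(R_work, 0.0)
    return R_work, coord, sel


def order_markers(group_markers, estimates: PairwiseEstimates, n_runs: int = 3,
                  seed=0, group_name: str = "") -> tuple:
    """Order the markers of one group by minimizing SARF.

    The criterion is the sum of adjacent recombination fractions over the
    denoised working matrix of :func:`ordering_matrix`.  Each run builds a
    seriation start (farthest-pair endpoints, greedy insertion; insertion
    sequence shuffled per run) and polishes it with 2-opt; the lowest-SARF
    order over ``n_runs`` wins, ties broken by run index.  Orientation is
    canonicalized so the first marker id sorts before the last.

    Returns ``(ordered marker ids, best sarf)``.

    Raises
    ------
    OrderingError
        If the group's estimate graph is disconnected.
    """
    ids = np.asarray(group_markers, dtype=object)
    if len(ids) == 1:
        return list(ids), 0.0
    R, _, _ = ordering_matrix(ids, estimates, group_name)
    order, score = _best_order(R, ids, n_runs, seed)
    return [ids[i] for i in order], score


def _best_order(R: np.ndarray, ids, n_runs: int, seed) -> tuple:
    """Seeded greedy-insertion + 2-opt restarts; lowest SARF wins (ties by
    run index); orientation canonicalized by endpoint marker ids."""
    m = R.shape[0]
    rng = np.random.default_rng(seed)
    best = None
    for run in range(n_runs):
        seq = np.arange(m) if run == 0 else rng.permutation(m)
        order = _two_opt(_greedy_insertion(R, seq), R)
        score = sarf(order, R)
        if best is None or score < best[0] - 1e-12:
            best = (score, run, order)
    score, _, order = best
    if str(ids[order[0]]) > str(ids[order[-1]]):
        order = order[::-1]
    return order, float(score)


_PERM_CACHE: dict = {}


def order_exhaustive(R: np.ndarray) -> tuple:
    """Brute-force minimum-SARF order (indices); oracle for small groups."""
    m = R.shape[0]
    if m == 1:
        return [0], 0.0
    if m not in _PERM_CACHE:
        perms = np.array(list(itertools.permutations(range(m))))
        _PERM_CACHE[m] = perms[perms[:, 0] < perms[:, -1]]  # one orientation each
    perms = _PERM_CACHE[m]
    scores = R[perms[:, :-1], perms[:, 1:]].sum(axis=1)
    best = int(np.argmin(scores))
    return list(perms[best]), float(scores[best])


# ---------------------------------------------------------------------------
# Map distances
# ---------------------------------------------------------------------------

def _wls_increments(order_local, coord, R, N, informative,
                    span_cM: float, cap: float, mode: str, order_ids) -> np.ndarray:
    """Non-negative weighted least-squares fit of interval lengths.

    Every informative marker pair whose *structural* separation (the
    denoised 1-D coordinate gap, not the pair's own noisy estimate) is at
    most ``span_cM`` contributes one equation: the sum of the interval
    lengths between the two markers should equal the pair's Haldane
    distance.  Weights are the meiosis counts; selection by the structural
    gap rather than the pair's own estimate avoids the truncation bias of
    conditioning on noisy distances.  Intervals are solved by NNLS and
    capped at ``cap`` cM with a warning.
    """
    m = len(order_local)
    delta = np.zeros(m - 1)
    inf_idx = [a for a in range(m) if informative[order_local[a]]]
    if len(inf_idx) < 2:
        return delta
    rows, ds, ws = [], [], []
    for x in range(len(inf_idx)):
        for y in range(x + 1, len(inf_idx)):
            a, b = inf_idx[x], inf_idx[y]
            i, j = order_local[a], order_local[b]
            n = N[i, j]
            # consecutive informative markers always anchor their interval;
            # farther pairs only within the structural span
            if n <= 0 or (y != x + 1 and abs(coord[i] - coord[j]) > span_cM):
                continue
            r = min(float(R[i, j]), 0.49) if np.isfinite(R[i, j]) else None
            if r is None:
                continue
            d = -50.0 * np.log(1.0 - 2.0 * r) if r > 0 else 0.0
            rows.append((a, b))
            ds.append(d)
            ws.append(float(n))
    if not rows:
        return delta
    A = np.zeros((len(rows), m - 1))
    for row, (a, b) in enumerate(rows):
        A[row, a:b] = 1.0
    sw = np.sqrt(np.asarray(ws))
    fit, _ = nnls(A * sw[:, None], np.asarray(ds) * sw)
    over = fit > cap
    if over.any():
        for k in np.flatnonzero(over):
            logger.warning("interval %s-%s (%.1f cM) capped at %.1f cM in %s map",
                           order_ids[k], order_ids[k + 1], fit[k], cap, mode)
        fit = np.minimum(fit, cap)
    return fit


def map_positions(order_ids, matrix: GenotypeMatrix, segcalls: pd.DataFrame, mode: str,
                  max_interval_cM: float = 50.0,
                  estimates: PairwiseEstimates | None = None,
                  coord: np.ndarray | None = None,
                  span_cM: float = 20.0) -> np.ndarray:
    """Cumulative Haldane cM positions along an ordered group.

    The ``female`` map uses the mother's informative markers (Aa x hom and
    Aa x Aa, the latter through homozygous offspring only): interval
    lengths along the order are fitted by non-negative weighted least
    squares to the Haldane distances of all maternal marker pairs within
    ``span_cM`` of structural separation, and maternally uninformative
    markers sit at the running position (a 0-cM contribution).  ``male``
    is the mirror image.  The ``averaged`` position is the mean of the
    female and male positions — for a group with meioses in only one sex
    this halves that sex's map, the behaviour seen in published
    single-sex groups.  A group with no informative markers for the
    requested sex has length 0; interval lengths above ``max_interval_cM``
    (e.g. from r near 0.5) are capped there with a warning.
    """
    if mode not in ("female", "male", "averaged"):
        raise ValueError("mode must be female, male or averaged")
    if mode == "averaged":
        f = map_positions(order_ids, matrix, segcalls, "female", max_interval_cM,
                          estimates, coord, span_cM)
        ml = map_positions(order_ids, matrix, segcalls, "male", max_interval_cM,
                           estimates, coord, span_cM)
        return (f + ml) / 2.0
    order_ids = list(order_ids)
    if estimates is None:
        idx = matrix.marker_index()
        sub = matrix.take(np.array([idx[mk] for mk in order_ids]))
        sc = segcalls[segcalls["marker"].isin(set(order_ids))].reset_index(drop=True)
        estimates = pairwise_all(sub, sc)
    if coord is None:
        _, coord, _ = ordering_matrix(order_ids, estimates)
    epos = {mid: i for i, mid in enumerate(estimates.marker_ids)}
    sel = np.array([epos[mk] for mk in order_ids])
    parent = "maternal" if mode == "female" else "paternal"
    R = getattr(estimates, f"rf_{parent}")[np.ix_(sel, sel)]
    N = getattr(estimates, f"n_{parent}")[np.ix_(sel, sel)]
    seg = segcalls.set_index("marker")["segtype"].reindex(
        np.asarray(order_ids, dtype=object)
    ).to_numpy()
    own = SegType.MAT_INF.value if mode == "female" else SegType.PAT_INF.value
    informative = (seg == own) | (seg == SegType.BOTH_INF.value)
    if len(order_ids) == 1:
        return np.zeros(1)
    delta = _wls_increments(list(range(len(order_ids))), coord, R, N, informative,
                            span_cM, max_interval_cM, mode, order_ids)
    return np.concatenate([[0.0], np.cumsum(delta)])

@dataclass
class GeneticMap:
    """Ordered markers with female/male/sex-averaged cM positions per group.

    ``table`` columns: marker, group, order_index, female_cM, male_cM,
    averaged_cM.  ``scores`` maps group name to the SARF of the retained
    order.
    """

    table: pd.DataFrame
    scores: dict = field(default_factory=dict)

    @property
    def groups(self) -> list:
        return list(dict.fromkeys(self.table["group"]))

    def group_lengths(self) -> pd.DataFrame:
        g = self.table.groupby("group", sort=False)
        return pd.DataFrame(
            {
                "n_snps": g.size(),
                "averaged_cM": g["averaged_cM"].max(),
                "female_cM": g["female_cM"].max(),
                "male_cM": g["male_cM"].max(),
            }
        )


def build_genetic_map(matrix: GenotypeMatrix, segcalls: pd.DataFrame,
                      groupset: LinkageGroupSet, estimates: PairwiseEstimates | None = None,
                      n_runs: int = 3, seed=0, max_interval_cM: float = 50.0) -> GeneticMap:
    """Order every linkage group and position its markers in all three maps."""
    if estimates is None:
        estimates = pairwise_all(matrix, segcalls)
    rows = []
    scores = {}
    ss = np.random.SeedSequence([int(seed), 17])
    child_seeds = ss.spawn(len(groupset.groups))
    for gi, members in enumerate(groupset.groups):
        name = f"LG{gi + 1:02d}"
        ids = np.asarray(members, dtype=object)
        if len(ids) == 1:
            scores[name] = 0.0
            rows.append((ids[0], name, 0, 0.0, 0.0, 0.0))
            continue
        R_work, coord, _ = ordering_matrix(ids, estimates, name)
        order_idx, score = _best_order(R_work, ids, n_runs, child_seeds[gi])
        order = [ids[i] for i in order_idx]
        coord_o = coord[np.asarray(order_idx)]
        scores[name] = score
        posf = map_positions(order, matrix, segcalls, "female", max_interval_cM,
                             estimates, coord_o)
        posm = map_positions(order, matrix, segcalls, "male", max_interval_cM,
                             estimates, coord_o)
        posa = (posf + posm) / 2.0
        for j, mid in enumerate(order):
            rows.append((mid, name, j, posf[j], posm[j], posa[j]))
    table = pd.DataFrame(rows, columns=["marker", "group", "order_index",
                                        "female_cM", "male_cM", "averaged_cM"])
    return GeneticMap(table=table, scores=scores)
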