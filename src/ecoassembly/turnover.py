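"""Phylogenetic and taxonomic turnover null models.

Per sample pair: abundance-weighted beta mean nearest-taxon distance
(betaMNTD), its standardized effect size against a tip-shuffling null
(betaNTI), and the Bray-Curtis Raup-Crick metric (RC_bray) against a
probabilistic community-assembly null. The two statistics jointly classify
each pair into one of five assembly processes:

    betaNTI < -2            homogeneous selection
    betaNTI > +2            heterogeneous selection
    |betaNTI| <= 2 and
        RC_bray > +0.95     dispersal limitation
        RC_bray < -0.95     homogenizing dispersal
        |RC_bray| <= 0.95   undominated (weak selection/dispersal, drift)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from skbio import TreeNode

from .errors import InvalidArgumentError

__all__ = [
    "PROCESSES",
    "phylo_distance_matrix",
    "bmntd",
    "bmntd_matrix",
    "bnti",
    "rc_bray",
    "classify_processes",
    "ProcessSummary",
    "bnti_env_correlation",
    "AssemblyModel",
    "AssemblyResults",
]

HOMOGENEOUS_SELECTION = "homogeneous_selection"
HETEROGENEOUS_SELECTION = "heterogeneous_selection"
HOMOGENIZING_DISPERSAL = "homogenizing_dispersal"
DISPERSAL_LIMITATION = "dispersal_limitation"
UNDOMINATED = "undominated"
PROCESSES = (
    HOMOGENEOUS_SELECTION,
    HETEROGENEOUS_SELECTION,
    HOMOGENIZING_DISPERSAL,
    DISPERSAL_LIMITATION,
    UNDOMINATED,
)


def phylo_distance_matrix(tree: TreeNode, otu_ids) -> pd.DataFrame:
    """Patristic (sum of branch lengths on the tip-to-tip path) distances."""
    otu_ids = list(otu_ids)
    tips = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        raise InvalidArgumentError(f"otu ids absent from tree: {missing}")
    dm = tree.tip_tip_distances(endpoints=otu_ids)
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    return df.loc[otu_ids, otu_ids]


def bmntd(f_k: np.ndarray, f_l: np.ndarray, dist: np.ndarray) -> float:
    """Abundance-weighted betaMNTD between two relative-abundance vectors.

    0.5 * [ sum_i f_ik * min_{j in l} d_ij  +  sum_j f_jl * min_{i in k} d_ij ];
    a taxon shared by both samples contributes its zero self-distance.
    """
    f_k = np.asarray(f_k, dtype=float)
    f_l = np.asarray(f_l, dtype=float)
    d = np.asarray(dist, dtype=float)
    pk = np.flatnonzero(f_k > 0)
    pl = np.flatnonzero(f_l > 0)
    if len(pk) == 0 or len(pl) == 0:
        raise InvalidArgumentError("both samples must contain at least one taxon")
    term_k = (f_k[pk] * d[np.ix_(pk, pl)].min(axis=1)).sum()
    term_l = (f_l[pl] * d[np.ix_(pl, pk)].min(axis=1)).sum()
    return 0.5 * float(term_k + term_l)


def _bmntd_all_pairs(F: np.ndarray, D: np.ndarray, present: list[np.ndarray]) -> np.ndarray:
    """betaMNTD for all sample pairs at once.

    M[i, l] = min over taxa present in sample l of D[i, j]; then
    bMNTD = 0.5 * (A + A^T) with A = F^T M.
    """
    n_taxa, n_samp = F.shape
    M = np.empty((n_taxa, n_samp))
    for l in range(n_samp):
        M[:, l] = D[:, present[l]].min(axis=1)
    A = F.T @ M
    return 0.5 * (A + A.T)


def bmntd_matrix(rel_abund: pd.DataFrame, dist: pd.DataFrame) -> pd.DataFrame:
    """Pairwise betaMNTD over sample columns of a relative-abundance table."""
    D = dist.loc[rel_abund.index, rel_abund.index].to_numpy(dtype=float)
    F = rel_abund.to_numpy(dtype=float)
    present = [np.flatnonzero(F[:, j] > 0) for j in range(F.shape[1])]
    for j, pr in enumerate(present):
        if len(pr) == 0:
            raise InvalidArgumentError(
                f"sample {rel_abund.columns[j]!r} has no present taxa"
            )
    B = _bmntd_all_pairs(F, D, present)
    np.fill_diagonal(B, 0.0)
    return pd.DataFrame(B, index=rel_abund.columns, columns=rel_abund.columns)


def bnti(
    counts: pd.DataFrame,
    dist: pd.DataFrame,
    n_null: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise betaNTI: standardized betaMNTD against a tip-shuffling null.

    Each null draw randomizes taxon identities across the distance matrix
    (a regional-pool null) and recomputes betaMNTD for every pair. Pairs
    whose null distribution has zero spread are reported as NaN with a
    warning rather than +/- infinity.
    """
    if counts.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 samples")
    if n_null < 99:
        raise InvalidArgumentError("n_null must be >= 99")
    rng = np.random.default_rng(seed)
    rel = counts / counts.sum(axis=0)
    D = dist.loc[counts.index, counts.index].to_numpy(dtype=float)
    F = rel.to_numpy(dtype=float)
    n_taxa, n_samp = F.shape
    present = [np.flatnonzero(F[:, j] > 0) for j in range(n_samp)]
    obs = _bmntd_all_pairs(F, D, present)

    mean_acc = np.zeros_like(obs)
    m2_acc = np.zeros_like(obs)
    for r in range(n_null):
        perm = rng.permutation(n_taxa)
        Dp = D[np.ix_(perm, perm)]
        null = _bmntd_all_pairs(F, Dp, present)
        delta = null - mean_acc
        mean_acc += delta / (r + 1)
        m2_acc += delta * (null - mean_acc)
    sd = np.sqrt(m2_acc / (n_null - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean_acc) / sd
    degenerate = sd <= 1e-12
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum() // 2)} pair(s) have a degenerate null "
            "(zero spread); betaNTI reported as missing",
            stacklevel=2,
        )
        z[degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=counts.columns, columns=counts.columns)


def rc_bray(
    counts: pd.DataFrame,
    n_null: int = 999,
    seed: int | None = None,
    occupancy: np.ndarray | None = None,
    regional: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bray-Curtis Raup-Crick against a probabilistic assembly null.

    Each null replicate rebuilds every sample: its observed richness of taxa
    is drawn without replacement with probability proportional to regional
    occupancy, then its observed read total is allocated multinomially with
    probability proportional to regional relative abundance restricted to
    the drawn taxa. RC = 2 * [(#null < obs + 0.5 * #ties) / n_null - 0.5],
    bounded in [-1, 1].

    ``occupancy`` and ``regional`` override the pool statistics estimated
    from ``counts`` (e.g. to hold the regional pool fixed across subsets).
    """
    if counts.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 samples")
    arr = counts.to_numpy(dtype=np.int64)
    n_taxa, n_samp = arr.shape
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        bad = [counts.columns[j] for j in np.flatnonzero(totals == 0)]
        raise InvalidArgumentError(f"sample(s) with zero total: {bad}")
    rng = np.random.default_rng(seed)
    if occupancy is None:
        occupancy = (arr > 0).mean(axis=1)
    occ_p = np.asarray(occupancy, dtype=float)
    occ_p = occ_p / occ_p.sum()
    if regional is None:
        regional = arr.sum(axis=1).astype(float)
    regional = np.asarray(regional, dtype=float)
    richness = (arr > 0).sum(axis=0)

    obs_bc = pdist(arr.T.astype(float), metric="braycurtis")
    below = np.zeros_like(obs_bc)
    ties = np.zeros_like(obs_bc)
    null_mat = np.zeros((n_samp, n_taxa))
    for _ in range(n_null):
        null_mat[:] = 0.0
        for j in range(n_samp):
            chosen = rng.choice(n_taxa, size=int(richness[j]), replace=False, p=occ_p)
            w = regional[chosen]
            null_mat[j, chosen] = rng.multinomial(int(totals[j]), w / w.sum())
        null_bc = pdist(null_mat, metric="braycurtis")
        below += null_bc < obs_bc - 1e-12
        ties += np.abs(null_bc - obs_bc) <= 1e-12
    rc = 2.0 * ((below + 0.5 * ties) / n_null - 0.5)
    out = squareform(rc)
    return pd.DataFrame(out, index=counts.columns, columns=counts.columns)


@dataclass
class ProcessSummary:
    """Counts and fractions of sample pairs per assembly process."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n_pairs: int
    n_missing: int
    group: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "process": list(PROCESSES),
                "count": [self.counts[p] for p in PROCESSES],
                "fraction": [self.fractions[p] for p in PROCESSES],
            }
        ).assign(group=self.group)


def classify_processes(
    bnti_matrix: pd.DataFrame,
    rc_matrix: pd.DataFrame,
    bmntd_matrix_: pd.DataFrame | None = None,
    group: str = "all",
) -> tuple[pd.DataFrame, ProcessSummary]:
    """Assign every sample pair its dominant assembly process.

    Returns a long-format turnover table (sample_a, sample_b, bmntd, bnti,
    rc, process) and a :class:`ProcessSummary`; pairs with missing betaNTI
    are excluded from the fractions but counted.
    """
    if bnti_matrix.shape != rc_matrix.shape or list(bnti_matrix.index) != list(
        rc_matrix.index
    ):
        raise InvalidArgumentError("betaNTI and RC matrices must align")
    ids = list(bnti_matrix.index)
    n = len(ids)
    rows = []
    counts = {p: 0 for p in PROCESSES}
    n_missing = 0
    for i in range(n):
        for j in range(i + 1, n):
            z = float(bnti_matrix.iat[i, j])
            rc = float(rc_matrix.iat[i, j])
            bm = float(bmntd_matrix_.iat[i, j]) if bmntd_matrix_ is not None else np.nan
            if np.isnan(z):
                n_missing += 1
                rows.append((ids[i], ids[j], bm, z, rc, "missing"))
                continue
            if z < -2:
                proc = HOMOGENEOUS_SELECTION
            elif z > 2:
                proc = HETEROGENEOUS_SELECTION
            elif rc > 0.95:
                proc = DISPERSAL_LIMITATION
            elif rc < -0.95:
                proc = HOMOGENIZING_DISPERSAL
            else:
                proc = UNDOMINATED
            counts[proc] += 1
            rows.append((ids[i], ids[j], bm, z, rc, proc))
    table = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "bmntd", "bnti", "rc", "process"]
    )
    n_pairs = sum(counts.values())
    fractions = {
        p: (counts[p] / n_pairs if n_pairs else 0.0) for p in PROCESSES
    }
    return table, ProcessSummary(counts, fractions, n_pairs, n_missing, group=group)


def bnti_env_correlation(
    bnti_matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    covariate: str,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman correlation of betaNTI with pairwise environmental change.

    Environmental change for a pair is |x_k - x_l|; significance by a
    Mantel-style permutation of sample identities (two-sided).
    """
    ids = list(bnti_matrix.index)
    x = metadata.loc[ids, covariate]
    missing = x.index[x.isna()]
    if len(missing) > 0:
        raise InvalidArgumentError(
            f"covariate {covariate!r} missing for sample(s): {list(missing)}"
        )
    xv = x.to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise InvalidArgumentError(f"covariate {covariate!r} is constant; rho undefined")
    n = len(ids)
    iu = np.triu_indices(n, 1)
    denv = np.abs(xv[:, None] - xv[None, :])
    z = np.asarray(bnti_matrix, dtype=float)
    valid = ~np.isnan(z[iu])
    zz = z[iu][valid]
    rho = float(spearmanr(denv[iu][valid], zz).statistic)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        dp = denv[np.ix_(p, p)][iu][valid]
        exceed += abs(spearmanr(dp, zz).statistic) >= abs(rho)
    return rho, (1.0 + exceed) / (1.0 + n_perm)


@dataclass
class AssemblyResults:
    """Null-model outputs for one set of samples."""

    bmntd: pd.DataFrame
    bnti: pd.DataFrame
    rc: pd.DataFrame
    turnover: pd.DataFrame
    summary_: ProcessSummary

    def summary(self) -> str:
        s = self.summary_
        lines = [
            "Assembly process partition",
            "=" * 40,
            f"pairs classified {s.n_pairs:>6d}   missing {s.n_missing}",
        ]
        for p in PROCESSES:
            lines.append(f"{p:<26s} {s.counts[p]:>5d}  {100 * s.fractions[p]:6.1f}%")
        return "\n".join(lines)


class AssemblyModel:
    """Null-model analysis bound to a count table and a phylogeny."""

    def __init__(self, counts: pd.DataFrame, tree: TreeNode):
        self.counts = counts
        self.tree = tree
        self.dist = phylo_distance_matrix(tree, list(counts.index))

    def fit(
        self, n_null: int = 999, seed: int | None = None, group: str = "all"
    ) -> AssemblyResults:
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        s1, s2 = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
        rel = self.counts / self.counts.sum(axis=0)
        bm = bmntd_matrix(rel, self.dist)
        z = bnti(self.counts, self.dist, n_null=n_null, seed=s1)
        rc = rc_bray(self.counts, n_null=n_null, seed=s2)
        table, summ = classify_processes(z, rc, bm, group=group)
        return AssemblyResults(bm, z, rc, table, summ)
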