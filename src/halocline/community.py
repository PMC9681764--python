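"""Community restructuring statistics for contig/MAG abundance tables.

Covers abundance normalization to per-sample percentages, archaea:
bacteria ratios, MAG quality filtering and ANI-based species
dereplication, selection of "specialized" (site-dominant) MAGs,
Bray-Curtis dissimilarities, principal coordinates analysis, the
ANOSIM rank permutation test, and Welch's unequal-variance t-test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, ttest_ind
from skbio.stats.distance import DistanceMatrix

from .types import AbundanceTable, MAGRecord

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# normalization & ratios


def normalize_relative_abundance(
    counts: pd.DataFrame,
    sites: Mapping[str, str],
    taxonomy: Optional[pd.DataFrame] = None,
) -> AbundanceTable:
    """Scale each sample column to sum to 100 %.

    Counts are assumed already normalized to sample size (e.g. per
    million reads); this step only converts them to compositional
    percentages.  Normalization is idempotent.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    values = counts.div(totals, axis=1) * 100.0
    return AbundanceTable(values=values, sites=dict(sites), taxonomy=taxonomy)


def archaea_bacteria_ratio(table: AbundanceTable) -> tuple[pd.Series, pd.Series]:
    """Archaea:bacteria abundance ratio per sample and its mean per site.

    Features without a domain assignment are excluded from both the
    numerator and denominator (and counted in a log message).  A sample
    with zero bacterial abundance yields +inf with a warning.
    """
    if table.taxonomy is None or "domain" not in table.taxonomy.columns:
        raise ValueError("taxonomy with a 'domain' column is required")
    dom = table.taxonomy["domain"].reindex(table.features)
    unassigned = int(dom.isna().sum()) + int(
        (~dom.dropna().isin(["Archaea", "Bacteria"])).sum()
    )
    if unassigned:
        logger.info("%d features without archaea/bacteria domain excluded from ratio",
                    unassigned)
    arch = table.values.loc[dom == "Archaea"].sum(axis=0)
    bact = table.values.loc[dom == "Bacteria"].sum(axis=0)
    with np.errstate(divide="ignore"):
        ratio = arch / bact
    if np.isinf(ratio).any():
        logger.warning("samples with zero bacterial abundance: ratio reported as +inf")
    per_sample = pd.Series(ratio, index=table.samples, name="archaea_bacteria_ratio")
    per_site = per_sample.groupby(pd.Series(table.sites)).mean()
    per_site.name = "archaea_bacteria_ratio"
    return per_sample, per_site


# --------------------------------------------------------------------------
# MAG filtering / dereplication / selection


def filter_mags(
    mags: Iterable[MAGRecord],
    min_completeness: float = 70.0,
    max_contamination: float = 5.0,
) -> list[MAGRecord]:
    """Quality filter: completeness >= min and contamination <= max (inclusive)."""
    return [
        m
        for m in mags
        if m.completeness >= min_completeness and m.contamination <= max_contamination
    ]


@dataclass
class SpeciesClusters:
    """Single-linkage species clusters with quality-based representatives."""

    clusters: list[list[str]]
    representatives: list[str]

    @property
    def n_species(self) -> int:
        return len(self.clusters)


def dereplicate_species(
    mags: Sequence[MAGRecord],
    pairs: pd.DataFrame,
    min_ani: float = 95.0,
    min_coverage: float = 10.0,
) -> SpeciesClusters:
    """Cluster MAGs into species by ANI/coverage single linkage.

    ``pairs`` is a long-format table with columns id1, id2, ani,
    coverage; an (undirected) edge joins two MAGs when ANI and coverage
    both reach their thresholds (inclusive).  Missing pairs are below
    threshold.  The cluster representative maximizes
    completeness − 5·contamination, ties broken by id order.
    """
    ids = [m.id for m in mags]
    index = {i: k for k, i in enumerate(ids)}
    parent = list(range(len(ids)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for _, row in pairs.iterrows():
        a, b = str(row["id1"]), str(row["id2"])
        if a not in index or b not in index or a == b:
            continue
        if float(row["ani"]) >= min_ani and float(row["coverage"]) >= min_coverage:
            union(index[a], index[b])

    groups: dict[int, list[MAGRecord]] = {}
    for m in mags:
        groups.setdefault(find(index[m.id]), []).append(m)
    clusters, reps = [], []
    for members in groups.values():
        members = sorted(members, key=lambda m: m.id)
        best = min(members, key=lambda m: (-m.quality_score, m.id))
        clusters.append([m.id for m in members])
        reps.append(best.id)
    order = np.argsort([c[0] for c in clusters])
    return SpeciesClusters(
        clusters=[clusters[i] for i in order],
        representatives=[reps[i] for i in order],
    )


def select_specialized_mags(
    table: AbundanceTable, min_mean_abundance: float = 10.0
) -> list[str]:
    """MAGs whose per-site mean abundance exceeds the cutoff (strict >) anywhere."""
    means = table.site_means()
    mask = (means > min_mean_abundance).any(axis=1)
    return list(means.index[mask])


# --------------------------------------------------------------------------
# dissimilarity / ordination / tests


def bray_curtis(table: AbundanceTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns.

    d(i, j) = sum_k |x_ki − x_kj| / sum_k (x_ki + x_kj), in [0, 1].
    """
    values = table.values if isinstance(table, AbundanceTable) else table
    ids = list(values.columns)
    if len(ids) < 2:
        raise ValueError("need at least two samples")
    condensed = pdist(values.to_numpy().T, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids)


@dataclass
class PCoAResult:
    """Classical-scaling embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues
    negative_eigenvalues: np.ndarray  # diagnostics for non-Euclidean input


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Principal coordinates analysis (classical metric scaling).

    Double-centers −D²/2, eigendecomposes, and keeps the axes with
    positive eigenvalues ordered by eigenvalue.  Negative eigenvalues
    (non-Euclidean input) are reported separately.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals).max()) if evals.size else 0.0
    pos = evals > tol
    lam = evals[pos]
    if lam.size:
        coords = evecs[:, pos] * np.sqrt(lam)
        prop = lam / lam.sum()
    else:  # degenerate: all points coincide
        lam = np.zeros(1)
        coords = np.zeros((n, 1))
        prop = np.zeros(1)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=lam,
        proportion_explained=prop,
        negative_eigenvalues=evals[evals < -tol],
    )


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    # Clarke's R: (mean between-group rank − mean within-group rank),
    # scaled by n(n−1)/4 so that R is confined to [−1, 1]
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    dm: DistanceMatrix,
    groups: Mapping[str, str] | Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    Upper-triangle distances are ranked (midranks for ties); R contrasts
    mean between- and within-group ranks.  The p-value counts permuted
    relabelings with R >= observed, with the add-one (observed-included)
    convention: p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).  With
    ``exact=True`` all n! relabelings are enumerated instead of sampled.
    """
    ids = list(dm.ids)
    n = len(ids)
    if isinstance(groups, Mapping):
        labels = np.array([groups[i] for i in ids])
    else:
        labels = np.asarray(list(groups))
        if labels.size != n:
            raise ValueError("one group label per sample is required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 samples each")

    condensed = squareform(np.asarray(dm.data, dtype=float), checks=False)
    ranks = rankdata(condensed)  # midranks for ties
    pair_i, pair_j = np.triu_indices(n, k=1)

    def within_mask(lab: np.ndarray) -> np.ndarray:
        return lab[pair_i] == lab[pair_j]

    r_obs = _anosim_r(ranks, within_mask(labels), n)

    if exact:
        if n > 9:
            raise ValueError("exact enumeration is limited to n <= 9 samples")
        perms = itertools.permutations(labels)
        count_ge = 0
        total = 0
        for perm in perms:
            total += 1
            if _anosim_r(ranks, within_mask(np.asarray(perm)), n) >= r_obs - 1e-12:
                count_ge += 1
        return AnosimResult(
            r=r_obs, p_value=(1 + count_ge) / (1 + total), n_permutations=total
        )

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, within_mask(perm), n) >= r_obs - 1e-12:
            count_ge += 1
    return AnosimResult(
        r=r_obs,
        p_value=(1 + count_ge) / (1 + n_permutations),
        n_permutations=n_permutations,
    )


@dataclass
class WelchResult:
    t: float
    df: float
    p_value: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return WelchResult(t=0.0, df=float(x.size + y.size - 2), p_value=1.0)
        raise ValueError("degenerate zero-variance groups with unequal means")
    res = ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p_value=float(res.pvalue))
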