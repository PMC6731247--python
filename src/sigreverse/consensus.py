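"""Post-scoring analysis of hit compounds.

Given a score table of drugs against disease signatures, this module
selects hit compounds (at least ``min_signatures`` significant
anti-correlations), extracts the genes they regulate consistently by the
sum-sense-change ratio, clusters their profiles with UPGMA, summarises
within- versus between-set profile correlations, and runs hypergeometric
over-representation of gene cohorts against GMT gene-set collections.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .connectivity import regression_z
from .types import (
    ConnectivityResult,
    Dendrogram,
    GeneSetCollection,
    SenseConsensus,
    as_sense_series,
)

__all__ = [
    "select_hits",
    "sum_sense_consensus",
    "upgma_cluster",
    "set_correlation_summary",
    "ora_pathways",
]

MAX_DISTANCE = 2.0  # 1 - score at perfect anti-concordance


def select_hits(
    score_table: Mapping[str, Iterable[ConnectivityResult]],
    min_signatures: int = 2,
    alpha: float = 0.05,
) -> list[str]:
    """Drugs with at least ``min_signatures`` significant anti-correlations.

    A significant anti-correlation is a defined result with a negative
    concordance score whose enrichment probability is below ``alpha``.
    Returns the selected drug names sorted.
    """
    hits = []
    for drug, results in score_table.items():
        n_anti = sum(
            1
            for r in results
            if r.defined and r.score < 0 and r.enrichment_p < alpha
        )
        if n_anti >= min_signatures:
            hits.append(drug)
    return sorted(hits)


def sum_sense_consensus(profiles: list, min_ratio: float = 1.0 / 3.0) -> SenseConsensus:
    """Genes consistently regulated across profiles by sum-sense-change ratio.

    Per gene the ratio is (1/P) * sum_i sign(g_i) over the P profiles, a
    gene absent from a profile contributing 0. Genes with |ratio| strictly
    above ``min_ratio`` (default 1/3) are selected; the per-profile sense
    matrix of the selected genes is retained for display.
    """
    if len(profiles) < 2:
        raise ValueError("sum-sense consensus needs at least 2 profiles")
    P = len(profiles)
    senses = [as_sense_series(p) for p in profiles]
    universe = sorted(set().union(*[set(s.index) for s in senses]))
    mat = np.zeros((len(universe), P), dtype=int)
    pos = {g: i for i, g in enumerate(universe)}
    for j, s in enumerate(senses):
        s = s[s != 0]
        mat[[pos[g] for g in s.index], j] = s.to_numpy()
    ratio = mat.sum(axis=1) / P
    keep = np.abs(ratio) > min_ratio
    idx = pd.Index(np.asarray(universe, dtype=object)[keep])
    cols = [getattr(p, "drug", "") or f"profile{j}" for j, p in enumerate(profiles)]
    # de-duplicate display column names (replicate profiles share a drug)
    seen: dict[str, int] = {}
    uniq_cols = []
    for c in cols:
        seen[c] = seen.get(c, 0) + 1
        uniq_cols.append(c if seen[c] == 1 else f"{c}.{seen[c]}")
    return SenseConsensus(
        ratio=pd.Series(ratio[keep], index=idx),
        sense_matrix=pd.DataFrame(mat[keep], index=idx, columns=uniq_cols),
        n_profiles=P,
    )


def _pairwise_distance(profiles: list, metric: str) -> tuple[np.ndarray, list[str]]:
    n = len(profiles)
    labels = []
    seen: dict[str, int] = {}
    for j, p in enumerate(profiles):
        name = getattr(p, "drug", "") or f"profile{j}"
        seen[name] = seen.get(name, 0) + 1
        labels.append(name if seen[name] == 1 else f"{name}.{seen[name]}")
    D = np.zeros((n, n))
    n_undef = 0
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "concordance":
                si = as_sense_series(profiles[i])
                sj = as_sense_series(profiles[j])
                si, sj = si[si != 0], sj[sj != 0]
                ov = si.index.intersection(sj.index)
                if len(ov) == 0:
                    d = MAX_DISTANCE
                    n_undef += 1
                else:
                    agree = (si.loc[ov].to_numpy() == sj.loc[ov].to_numpy()).sum()
                    score = (2 * agree - len(ov)) / len(ov)
                    d = 1.0 - score
            elif metric == "pearson":
                vi, vj = profiles[i].values, profiles[j].values
                ov = vi.index.intersection(vj.index)
                if len(ov) < 3:
                    d = MAX_DISTANCE
                    n_undef += 1
                else:
                    x = vi.loc[ov].to_numpy(dtype=float)
                    y = vj.loc[ov].to_numpy(dtype=float)
                    if np.ptp(x) == 0 or np.ptp(y) == 0:
                        d = MAX_DISTANCE
                        n_undef += 1
                    else:
                        d = 1.0 - float(np.corrcoef(x, y)[0, 1])
            else:
                raise ValueError(f"unknown distance metric {metric!r}")
            D[i, j] = D[j, i] = d
    if n_undef:
        warnings.warn(
            f"{n_undef} profile pair(s) had undefined distance; set to the maximum"
        )
    return D, labels


def upgma_cluster(profiles: list, distance: str = "concordance") -> Dendrogram:
    """UPGMA (average-linkage) clustering of drug profiles.

    Pairwise distances are 1 - sense-concordance score (default) or
    1 - Pearson correlation over the value overlap; pairs with no usable
    overlap get the maximum distance with a warning. Merge heights follow
    the ultrametric convention: half the average inter-cluster distance at
    the merge, so two profiles at distance d join at height d/2.
    """
    if len(profiles) < 2:
        raise ValueError("clustering needs at least 2 profiles")
    D, labels = _pairwise_distance(profiles, distance)
    Z = linkage(squareform(D, checks=False), method="average")
    merges = [
        (int(a), int(b), float(h) / 2.0, int(size)) for a, b, h, size in Z
    ]
    return Dendrogram(merges=merges, labels=labels)


def set_correlation_summary(
    member_set: set[str], all_profiles: list
) -> tuple[float, float]:
    """Mean regression Z within a drug set versus over all remaining pairs.

    All unordered profile pairs are scored by :func:`regression_z`
    (self-pairs excluded); pairs with both drugs in ``member_set`` form the
    within-set mean, every other pair the outside mean. A singleton set has
    no within-set pairs: its mean is NaN, with a warning.
    """
    names = [getattr(p, "drug", "") or f"profile{j}" for j, p in enumerate(all_profiles)]
    if not member_set:
        raise ValueError("member set is empty")
    if not set(names) & member_set:
        raise ValueError("member set shares no drugs with the profile list")
    if member_set >= set(names):
        raise ValueError("member set must be a strict subset of the profiles")
    within, outside = [], []
    n = len(all_profiles)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                z = regression_z(all_profiles[i], all_profiles[j])
                if np.isnan(z):
                    continue
                if names[i] in member_set and names[j] in member_set:
                    within.append(z)
                else:
                    outside.append(z)
    if not within:
        warnings.warn("no within-set pairs (singleton set); within mean undefined")
    within_mean = float(np.mean(within)) if within else float("nan")
    outside_mean = float(np.mean(outside)) if outside else float("nan")
    return within_mean, outside_mean


def ora_pathways(
    gene_cohort: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene cohort in gene sets.

    Per set, the upper-tail hypergeometric probability of drawing at least
    the observed overlap when sampling |cohort| genes from the universe;
    Benjamini-Hochberg adjusted across sets. Returns the sets with adjusted
    p < ``alpha`` as a DataFrame (overlap, set size, p, p_adj), most
    significant first. An empty cohort yields an empty result.
    """
    if not gene_cohort <= universe:
        extra = sorted(gene_cohort - universe)[:3]
        raise ValueError(f"cohort genes outside the universe, e.g. {extra}")
    empty = pd.DataFrame(
        columns=["set", "overlap", "set_size", "p_value", "p_adjusted"]
    ).set_index("set")
    if not gene_cohort or len(collection) == 0:
        return empty
    N, n = len(universe), len(gene_cohort)
    rows = []
    for name in collection:
        members = set(collection.members(name)) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(gene_cohort & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, p))
    if not rows:
        return empty
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "p_value"]
    ).set_index("set")
    table["p_adjusted"] = stats.false_discovery_control(
        table["p_value"].to_numpy(), method="bh"
    )
    table = table[table["p_adjusted"] < alpha]
    return table.sort_values(["p_adjusted", "p_value"])
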