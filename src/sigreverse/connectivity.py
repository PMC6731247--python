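"""Scoring drug profiles against disease signatures.

The central quantity is the sense-concordance score over the gene overlap
of a categorical query signature and a signed target profile,

    score = (n_uu + n_dd - n_ud - n_du) / (n_uu + n_dd + n_ud + n_du),

with n_uu (both up), n_dd (both down), n_ud and n_du the disagreement
counts. Its significance is the exact Poisson-binomial tail probability of
a match (or mismatch) count at least as extreme, with per-gene match
probabilities either uniform (1/2) or scaled by gene regulation frequencies
observed in a reference profile database.

Continuous profile pairs are compared by :func:`regression_z` (signed Z of
the least-squares slope), databases are ranked against a query by
:func:`rank_query`, and rank lists are assessed for enrichment by the KS
running-sum statistic with a seeded Monte-Carlo null
(:func:`ks_enrichment`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import z_from_p
from .types import (
    CategoricalSignature,
    ConnectivityResult,
    DrugProfile,
    EnrichmentResult,
    SignatureProfile,
    as_sense_series,
)

__all__ = [
    "binomial_enrichment",
    "concordance_score",
    "regression_z",
    "rank_query",
    "ks_enrichment",
    "regulation_frequencies",
]


def binomial_enrichment(matches: int, trials: int, per_gene_probs) -> float:
    """Exact upper-tail probability of >= ``matches`` successes.

    ``per_gene_probs`` holds one success probability per trial (each in
    (0, 1)); the trials are independent but need not be identically
    distributed, so the tail is the Poisson-binomial upper tail, computed
    exactly by the dynamic-programming convolution of the per-trial
    Bernoulli distributions (O(n^2); intended for trials <= 10^4). With
    equal probabilities this reduces to the ordinary binomial tail.
    A scalar probability is broadcast over all trials.
    """
    if matches > trials:
        raise ValueError(f"matches ({matches}) exceed trials ({trials})")
    if matches < 0 or trials < 0:
        raise ValueError("matches and trials must be non-negative")
    probs = np.atleast_1d(np.asarray(per_gene_probs, dtype=float))
    if probs.size == 1:
        probs = np.full(trials, probs[0])
    if probs.size != trials:
        raise ValueError(f"need {trials} probabilities, got {probs.size}")
    if trials and ((probs <= 0).any() or (probs >= 1).any()):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    if matches == 0:
        return 1.0
    if trials and np.ptp(probs) == 0:
        return float(stats.binom.sf(matches - 1, trials, probs[0]))
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    tail = float(pmf[matches:].sum())
    return min(max(tail, np.finfo(float).tiny), 1.0)


def regulation_frequencies(profiles) -> pd.Series:
    """Per-gene up-regulation frequency across a profile database.

    For each gene, the fraction of profiles calling it up among those
    calling it in either sense — the background probability table for
    frequency-scaled enrichment. Genes never called keep no entry.
    """
    up: dict[str, int] = {}
    total: dict[str, int] = {}
    for prof in profiles:
        senses = as_sense_series(prof)
        for gene, s in senses.items():
            if s == 0:
                continue
            total[gene] = total.get(gene, 0) + 1
            if s > 0:
                up[gene] = up.get(gene, 0) + 1
    genes = sorted(total)
    return pd.Series(
        [up.get(g, 0) / total[g] for g in genes], index=pd.Index(genes)
    )


def _match_probs(
    query_senses: pd.Series, genes: pd.Index, background_freqs
) -> np.ndarray:
    """Per-gene probability that the target matches the query sense by chance."""
    if background_freqs is None:
        return np.full(len(genes), 0.5)
    freqs = background_freqs.reindex(genes)
    freqs = freqs.fillna(0.5).to_numpy(dtype=float)
    freqs = np.clip(freqs, 1e-6, 1 - 1e-6)
    qs = query_senses.loc[genes].to_numpy()
    return np.where(qs > 0, freqs, 1.0 - freqs)


def concordance_score(
    query: CategoricalSignature,
    target,
    background_freqs: pd.Series | None = None,
) -> ConnectivityResult:
    """Sense concordance of a categorical query with a signed target profile.

    Counts sense agreements and disagreements over the gene overlap, forms
    the concordance score, and attaches the exact enrichment probability of
    an excess at least as large in the observed direction: the
    Poisson-binomial tail over the matches when agreements dominate
    (direction ``concordant``), over the mismatches otherwise
    (``discordant``). Per-gene match probabilities default to 1/2; a
    background frequency table (see :func:`regulation_frequencies`) scales
    them by each gene's propensity to be called up.

    Zero overlap yields a result flagged undefined rather than an error.
    """
    if len(query) == 0:
        raise ValueError("empty query signature")
    t_senses = as_sense_series(target)
    t_senses = t_senses[t_senses != 0]
    if len(t_senses) == 0:
        raise ValueError("empty target profile")
    drug = getattr(target, "drug", "") or getattr(target, "source", "")
    overlap = query.genes.intersection(t_senses.index)
    if len(overlap) == 0:
        return ConnectivityResult(
            n_uu=0, n_dd=0, n_ud=0, n_du=0, score=float("nan"),
            enrichment_p=float("nan"), overlap=0, defined=False, drug=drug,
        )
    q = query.senses.loc[overlap].to_numpy()
    t = t_senses.loc[overlap].to_numpy()
    n_uu = int(((q > 0) & (t > 0)).sum())
    n_dd = int(((q < 0) & (t < 0)).sum())
    n_ud = int(((q > 0) & (t < 0)).sum())
    n_du = int(((q < 0) & (t > 0)).sum())
    total = n_uu + n_dd + n_ud + n_du
    score = (n_uu + n_dd - n_ud - n_du) / total
    p_match = _match_probs(query.senses, overlap, background_freqs)
    matches = n_uu + n_dd
    if matches >= total - matches:
        direction = "concordant"
        enrichment_p = binomial_enrichment(matches, total, p_match)
    else:
        direction = "discordant"
        enrichment_p = binomial_enrichment(total - matches, total, 1.0 - p_match)
    return ConnectivityResult(
        n_uu=n_uu, n_dd=n_dd, n_ud=n_ud, n_du=n_du,
        score=score, enrichment_p=enrichment_p, overlap=total,
        direction=direction, drug=drug,
    )


def regression_z(a: SignatureProfile, b: SignatureProfile) -> float:
    """Signed Z of the least-squares slope of profile b on profile a.

    Over the gene overlap, b's values are regressed on a's; the slope's
    two-sided t p-value is converted to a Z score via the standard-normal
    quantile, signed by the slope and capped at +/-8.2. Returns NaN
    (flagged by a warning) for overlaps below 4 genes or zero variance on
    either side.
    """
    va = a.values if hasattr(a, "values") else pd.Series(a)
    vb = b.values if hasattr(b, "values") else pd.Series(b)
    overlap = va.index.intersection(vb.index)
    if len(overlap) < 4:
        warnings.warn("profile overlap below 4 genes; regression Z undefined")
        return float("nan")
    x = va.loc[overlap].to_numpy(dtype=float)
    y = vb.loc[overlap].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance profile; regression Z undefined")
        return float("nan")
    res = stats.linregress(x, y)
    if np.isnan(res.pvalue):
        # perfect fit: residual variance underflows; evidence is maximal
        return float(np.sign(res.slope) * 8.2)
    return float(z_from_p(res.pvalue, res.slope))


def rank_query(
    query: CategoricalSignature,
    db: list,
    direction: str = "anticorrelate",
    background_freqs: pd.Series | None = None,
) -> list[tuple[str, ConnectivityResult, int]]:
    """Rank a profile database against a query signature.

    Every profile is scored by :func:`concordance_score`; profiles are
    ordered by score — ascending under ``anticorrelate`` (strongest
    reversers first), descending under ``correlate`` — with ties broken
    lexicographically by drug name and undefined-overlap profiles placed
    last. Ranks are 1-based.
    """
    if direction not in ("correlate", "anticorrelate"):
        raise ValueError(f"unknown direction {direction!r}")
    if not db:
        raise ValueError("empty profile database")
    scored = []
    for i, prof in enumerate(db):
        res = concordance_score(query, prof, background_freqs)
        name = res.drug or f"profile{i:04d}"
        scored.append((name, res))
    sign = 1.0 if direction == "anticorrelate" else -1.0
    scored.sort(
        key=lambda item: (
            not item[1].defined,
            sign * item[1].score if item[1].defined else 0.0,
            item[0],
        )
    )
    return [(name, res, rank) for rank, (name, res) in enumerate(scored, start=1)]


def ks_enrichment(
    hit_ranks,
    universe_size: int,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """KS running-sum enrichment of a hit set toward the top of a ranking.

    D is the maximal positive deviation of the cumulative hit fraction from
    the zero-enrichment diagonal: max over hit positions r_i (i-th smallest
    hit rank) of i/m - r_i/N. The Monte-Carlo null redistributes the m hits
    uniformly over the N ranks ``n_permutations`` times;
    p_mc = (1 + #{permuted D >= observed D}) / (n_permutations + 1)
    (add-one estimator, never zero).
    """
    ranks = np.asarray(sorted(hit_ranks), dtype=int)
    m = len(ranks)
    if m == 0:
        raise ValueError("no hit ranks given")
    if len(np.unique(ranks)) != m:
        raise ValueError("hit ranks must be distinct")
    if ranks[0] < 1 or ranks[-1] > universe_size:
        raise ValueError(f"hit ranks must lie in [1, {universe_size}]")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if m == universe_size:
        warnings.warn("every item is a hit; enrichment is degenerate (D = 0)")

    def peak(sorted_ranks: np.ndarray) -> float:
        dev = np.arange(1, m + 1) / m - sorted_ranks / universe_size
        return float(max(dev.max(), 0.0))

    D = peak(ranks)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = np.sort(rng.choice(universe_size, size=m, replace=False) + 1)
        if peak(perm) >= D:
            exceed += 1
    p_mc = (1 + exceed) / (n_permutations + 1)
    return EnrichmentResult(
        D=D, p_mc=p_mc, n_permutations=n_permutations, seed=seed,
        n_hits=m, universe_size=universe_size,
    )
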