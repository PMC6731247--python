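"""Drug-perturbation profile construction.

Two families of perturbation phenotype are supported:

* rank-database style: per-sample expression-change ranks linearly mapped
  to [-1, 1] (:func:`cmap_rank_transform`), averaged over replicates with a
  one-sample t filter (:func:`aggregate_replicates`) and collapsed from
  probes to genes by the largest significant change
  (:func:`collapse_probes`);
* plate-screen style: treated-vs-vehicle contrasts within a plate
  (:func:`treatment_profile`), as significance-filtered scaled folds or as
  plate-control-referenced Z scores with an |Z| threshold.

:func:`cell_identity_profile` builds the relative-rank profile that
characterises a cell culture against a large background rank compendium.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    CellIdentityProfile,
    DrugProfile,
    ExpressionMatrix,
    ProbeGeneMap,
    RankProfile,
)

__all__ = [
    "cmap_rank_transform",
    "aggregate_replicates",
    "collapse_probes",
    "cell_identity_profile",
    "treatment_profile",
]


def cmap_rank_transform(ranks: pd.Series, drug: str = "", context: str = "") -> RankProfile:
    """Map per-feature expression-change ranks linearly onto [-1, 1].

    Rank 1 (R_min, the most upregulated feature) maps to +1 and the largest
    rank (R_max, the most downregulated) to -1, via
    1 - 2 (R - R_min) / (R_max - R_min). Ranks that are not already a
    contiguous integer permutation (e.g. average ranks from ties) are
    re-ranked by stable order first.
    """
    if len(ranks) < 2:
        raise ValueError("rank transform needs at least 2 features")
    if not ranks.index.is_unique:
        raise ValueError("duplicate feature ids in rank vector")
    r = np.asarray(ranks, dtype=float)
    sorted_r = np.sort(r)
    contiguous = np.array_equal(sorted_r, np.arange(sorted_r[0], sorted_r[0] + len(r)))
    if not contiguous:
        # average ranks or gaps: re-rank by stable order
        order = np.argsort(r, kind="stable")
        r = np.empty(len(r), dtype=float)
        r[order] = np.arange(1, len(order) + 1)
    r_min, r_max = r.min(), r.max()
    values = 1.0 - 2.0 * (r - r_min) / (r_max - r_min)
    return RankProfile(
        values=pd.Series(values, index=ranks.index),
        drug=drug,
        n_replicates=1,
        context=context,
    )


def aggregate_replicates(profiles: list[RankProfile], alpha: float = 0.05) -> RankProfile:
    """Average replicate rank profiles and filter by a one-sample t-test.

    Per feature the replicate values are averaged; a feature is retained
    when the one-sample Student t-test of the replicate values against 0
    gives p < ``alpha``. Identical replicates make the t statistic
    degenerate (zero variance): such features are retained when the common
    value is nonzero — perfectly reproducible signal is maximal, not
    missing, evidence — and dropped when it is zero.

    A single profile is returned unfiltered with a warning (t undefined).
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    if len(profiles) == 1:
        warnings.warn("single replicate: one-sample t undefined, profile unfiltered")
        prof = profiles[0]
        return RankProfile(
            values=prof.values.copy(),
            drug=prof.drug,
            n_replicates=1,
            context=prof.context,
        )
    common = profiles[0].values.index
    for prof in profiles[1:]:
        common = common.intersection(prof.values.index)
    if len(common) == 0:
        raise ValueError("replicate profiles share no features")
    if any(len(prof) != len(common) for prof in profiles):
        warnings.warn("replicates differ in feature universe; using the intersection")
    mat = np.column_stack([prof.values.loc[common].to_numpy() for prof in profiles])
    mean = mat.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.asarray(stats.ttest_1samp(mat, 0.0, axis=1).pvalue)
    degenerate = np.ptp(mat, axis=1) == 0
    p = np.where(degenerate & (mean != 0), 0.0, p)
    p = np.where(degenerate & (mean == 0), 1.0, p)
    keep = p < alpha
    return RankProfile(
        values=pd.Series(mean[keep], index=common[keep]),
        drug=profiles[0].drug,
        n_replicates=len(profiles),
        context=profiles[0].context,
    )


def collapse_probes(profile, pmap: ProbeGeneMap):
    """Collapse a probe-level profile to gene level.

    Probes present in a filtered profile are its significant changes; per
    gene the probe with the largest absolute value wins (ties broken by
    probe order). Probes absent from the map are dropped with a warning and
    counted. Returns the same profile type at gene level.
    """
    if isinstance(profile, RankProfile):
        values = profile.values
    elif isinstance(profile, DrugProfile):
        values = profile.data["value"]
    else:
        raise TypeError(f"cannot collapse {type(profile).__name__}")
    mapped = values.index.isin(pmap.entries)
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        warnings.warn(f"{n_unmapped} unmapped probe(s) dropped in probe collapse")
    probes = values.index[mapped]
    genes = np.array([pmap[p] for p in probes], dtype=object)
    sub = values.loc[probes]
    order = np.argsort(-np.abs(sub.to_numpy()), kind="stable")
    best: dict[str, str] = {}
    for i in order:
        gene = genes[i]
        if gene not in best:
            best[gene] = probes[i]
    win_probes = list(best.values())
    gene_index = pd.Index(list(best.keys()))
    if isinstance(profile, RankProfile):
        return RankProfile(
            values=pd.Series(values.loc[win_probes].to_numpy(), index=gene_index),
            drug=profile.drug,
            n_replicates=profile.n_replicates,
            context=profile.context,
        )
    data = profile.data.loc[win_probes].copy()
    data.index = gene_index
    return DrugProfile(
        data=data, drug=profile.drug, plate=profile.plate, method=profile.method
    )


def cell_identity_profile(
    sample_mean_ranks: pd.Series,
    background_ranks: pd.Series,
    reference: str = "background",
) -> CellIdentityProfile:
    """Relative-rank profile of a sample set against a background compendium.

    Ranks are fractions in [0, 1] with 0 the highest-expressed feature and 1
    the lowest. Per feature, with r the sample mean rank and r0 the
    background rank, the relative rank is (r0 - r)/r0 for r < r0 and
    (r0 - r)/(1 - r0) for r > r0 (0 at r = r0): positive when the feature is
    expressed higher in the sample than in the background, and bounded in
    [-1, 1].
    """
    common = sample_mean_ranks.index.intersection(background_ranks.index)
    if len(common) == 0:
        raise ValueError("sample and background ranks share no features")
    r = sample_mean_ranks.loc[common].to_numpy(dtype=float)
    r0 = background_ranks.loc[common].to_numpy(dtype=float)
    for name, arr in (("sample", r), ("background", r0)):
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError(f"{name} ranks must lie in [0, 1]")
    degenerate = (r0 == 0) | (r0 == 1)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) with background rank exactly 0 or 1"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        below = (r0 - r) / np.where(r0 > 0, r0, 1.0)
        above = (r0 - r) / np.where(r0 < 1, 1.0 - r0, 1.0)
    values = np.where(r == r0, 0.0, np.where(r < r0, below, above))
    values = np.clip(values, -1.0, 1.0)
    return CellIdentityProfile(
        values=pd.Series(values, index=common), reference=reference
    )


def treatment_profile(
    matrix: ExpressionMatrix,
    drug_group: str,
    control_group: str = "vehicle",
    plate: str | None = None,
    method: str = "zscore",
    alpha: float = 0.05,
    z_threshold: float = 3.0,
) -> DrugProfile:
    """Treated-vs-vehicle contrast within one plate.

    Both groups must share the plate (inferred from the treated samples
    when ``plate`` is omitted), so the shared per-plate offset cancels in
    the contrast. Two methods:

    ``fold``
        scaled fold f = (<t> - <c>)/(<t> + <c>) on intensity scale (matrix
        values are log2 and are exponentiated), filtered by the two-sample
        Student t-test on the log2 values at p < ``alpha``; ``stat`` is p.
    ``zscore``
        Z = (mean_t - mean_c) / (SD_c * sqrt(1/n_t + 1/n_c)) on the log2
        values — a plate-control-referenced standardised difference —
        retained when |Z| > ``z_threshold`` (default 3); ``stat`` is |Z|.
    """
    if method not in ("fold", "zscore"):
        raise ValueError(f"unknown method {method!r}")
    if plate is None:
        if "plate" in matrix.samples.columns:
            plates = matrix.samples.loc[
                matrix.samples["group"] == drug_group, "plate"
            ].unique()
            if len(plates) == 0:
                raise ValueError(f"no samples in group {drug_group!r}")
            if len(plates) > 1:
                raise ValueError(
                    f"group {drug_group!r} spans plates {list(plates)}; pass plate="
                )
            plate = plates[0]
    treated = matrix.group_columns(drug_group, plate)
    try:
        ctrl = matrix.group_columns(control_group, plate)
    except ValueError as exc:
        raise ValueError(
            f"control group {control_group!r} absent from plate {plate!r}"
        ) from exc
    if treated.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need at least 2 samples in each group")
    t_log = treated.to_numpy()
    c_log = ctrl.to_numpy()
    n_t, n_c = t_log.shape[1], c_log.shape[1]
    if method == "zscore":
        sd_c = c_log.std(axis=1, ddof=1)
        diff = t_log.mean(axis=1) - c_log.mean(axis=1)
        scale = np.sqrt(1.0 / n_t + 1.0 / n_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = diff / (sd_c * scale)
        z = np.where((sd_c == 0) & (diff != 0), np.sign(diff) * np.inf, z)
        z = np.where((sd_c == 0) & (diff == 0), 0.0, z)
        keep = np.abs(z) > z_threshold
        data = pd.DataFrame(
            {"value": z[keep], "stat": np.abs(z[keep])},
            index=matrix.feature_ids[keep],
        )
    else:
        t_int, c_int = np.exp2(t_log), np.exp2(c_log)
        t_mean, c_mean = t_int.mean(axis=1), c_int.mean(axis=1)
        f = (t_mean - c_mean) / (t_mean + c_mean)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.asarray(stats.ttest_ind(t_log, c_log, axis=1).pvalue)
        keep = p < alpha
        data = pd.DataFrame(
            {"value": f[keep], "stat": p[keep]}, index=matrix.feature_ids[keep]
        )
    return DrugProfile(
        data=data, drug=drug_group, plate=str(plate or ""), method=method
    )
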