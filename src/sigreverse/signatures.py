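"""Disease-signature construction.

Three signature builders cover the disease side of the pipeline:

* :func:`scaled_fold_profile` — case/control contrast by the bounded scaled
  fold f = (<d> - <c>) / (<d> + <c>) on intensity-scale group means, with a
  Student t significance filter and a minimum-|fold| filter.
* :func:`stage_regression_profile` — per-gene least-squares regression of
  expression on an ordinal disease-stage variable with categorical
  covariates; the stage coefficient's two-sided p is converted to a signed
  Z score.
* :func:`representative_profile` — categorical consensus over several
  signatures: genes regulated in the same sense across a sufficient
  fraction of profiles.

:func:`reverse_profile` negates a profile, for measures that decrease with
disease progression (e.g. cognitive scores).
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    Z_CAP,
    CategoricalSignature,
    DrugProfile,
    ExpressionMatrix,
    SignatureProfile,
)

__all__ = [
    "scaled_fold_profile",
    "stage_regression_profile",
    "reverse_profile",
    "representative_profile",
    "z_from_p",
]


def z_from_p(p: np.ndarray | float, sign: np.ndarray | float) -> np.ndarray | float:
    """Signed Z from a two-sided p-value: Z = sign * Phi^-1(1 - p/2), capped.

    Perfect fits drive p to 0 and the quantile to infinity; |Z| is capped at
    ``Z_CAP`` (8.2, the p-underflow limit of double precision).
    """
    with np.errstate(divide="ignore"):
        z = stats.norm.isf(np.asarray(p, dtype=float) / 2.0)
    z = np.clip(z, -Z_CAP, Z_CAP)
    return np.sign(sign) * z


def scaled_fold_profile(
    matrix: ExpressionMatrix,
    control_group: str,
    disease_group: str,
    alpha: float = 0.05,
    min_fold: float = 0.20,
    log_scale: bool = True,
    welch: bool = False,
) -> SignatureProfile:
    """Scaled-fold contrast of two sample groups.

    Per gene, f = (<d> - <c>) / (<d> + <c>) over intensity-scale group
    means, which bounds f in (-1, 1) for positive intensities. Significance
    is the two-sample Student t-test (equal variance by default; ``welch``
    switches to unequal-variance). Genes are retained when p < ``alpha``
    and |f| >= ``min_fold``.

    When ``log_scale`` is true (the default, matching the log2-scale
    :class:`ExpressionMatrix` convention) the matrix values are exponentiated
    (2**x) before the fold is computed, while the t-test runs on the log2
    values, where the Gaussian noise assumption holds. With
    ``log_scale=False`` the values are taken as linear intensities directly
    and must be positive.
    """
    ctrl = matrix.group_columns(control_group)
    dis = matrix.group_columns(disease_group)
    if ctrl.shape[1] < 2 or dis.shape[1] < 2:
        raise ValueError("need at least 2 samples in each group")
    if log_scale:
        c_int, d_int = np.exp2(ctrl.to_numpy()), np.exp2(dis.to_numpy())
        c_test, d_test = ctrl.to_numpy(), dis.to_numpy()
    else:
        c_int, d_int = ctrl.to_numpy(), dis.to_numpy()
        if (c_int <= 0).any() or (d_int <= 0).any():
            raise ValueError("intensity-scale expression values must be positive")
        c_test, d_test = c_int, d_int
    c_mean = c_int.mean(axis=1)
    d_mean = d_int.mean(axis=1)
    denom = d_mean + c_mean
    ok = denom != 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} gene(s) with zero mean intensity dropped")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ok, (d_mean - c_mean) / np.where(ok, denom, 1.0), np.nan)
    t_res = stats.ttest_ind(d_test, c_test, axis=1, equal_var=not welch)
    p = np.asarray(t_res.pvalue)
    keep = ok & (p < alpha) & (np.abs(f) >= min_fold)
    data = pd.DataFrame(
        {"value": f[keep], "p_value": p[keep]}, index=matrix.feature_ids[keep]
    )
    return SignatureProfile(
        data=data, kind="fold", source=f"{disease_group}-vs-{control_group}"
    )


def _design_matrix(
    samples: pd.DataFrame, stage_field: str, covariate_fields
) -> tuple[np.ndarray, list[str]]:
    stage = samples[stage_field].astype(float).to_numpy()
    if np.ptp(stage) == 0:
        raise ValueError(f"stage field {stage_field!r} is constant across samples")
    cols = [np.ones_like(stage), stage]
    names = ["intercept", stage_field]
    for cov in covariate_fields:
        dummies = pd.get_dummies(samples[cov].astype(str), drop_first=True)
        block = dummies.to_numpy(dtype=float)
        trial = np.column_stack(cols + [block])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            warnings.warn(f"covariate {cov!r} collinear with the design; dropped")
            continue
        cols.append(block)
        names += [f"{cov}[{c}]" for c in dummies.columns]
    return np.column_stack(cols), names


def stage_regression_profile(
    matrix: ExpressionMatrix,
    stage_field: str = "stage",
    covariate_fields: tuple[str, ...] = (),
    alpha: float = 0.05,
) -> SignatureProfile:
    """Per-gene OLS of expression on disease stage with categorical covariates.

    Fits expression ~ stage + covariate indicators by least squares for every
    gene in one vectorised solve, converts the stage coefficient's two-sided
    t p-value to a Z score via the standard-normal quantile (signed by the
    coefficient, capped at +/-8.2) and retains genes with p < ``alpha``.
    """
    X, _ = _design_matrix(matrix.samples, stage_field, covariate_fields)
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"{n} samples cannot support a {k}-parameter model")
    Y = matrix.values.to_numpy().T  # samples x genes
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - k
    rss = np.einsum("ij,ij->j", resid, resid)
    xtx_inv = np.linalg.inv(X.T @ X)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof * xtx_inv[1, 1])
        t = np.where(se > 0, beta[1] / np.where(se > 0, se, 1.0), np.inf * np.sign(beta[1]))
    t = np.where((se == 0) & (beta[1] == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    z = z_from_p(p, beta[1])
    keep = p < alpha
    data = pd.DataFrame(
        {"value": np.asarray(z)[keep], "p_value": p[keep]},
        index=matrix.feature_ids[keep],
    )
    return SignatureProfile(data=data, kind="zscore", source=f"stage:{stage_field}")


def reverse_profile(profile):
    """Negate every value/sense of a profile; p-values are unchanged.

    An involution: applying it twice returns the original. Used for disease
    scales that decrease with progression, and for constructing reversal
    controls. Works on continuous profiles and categorical signatures.
    """
    if isinstance(profile, (SignatureProfile, DrugProfile)):
        data = profile.data.copy()
        data["value"] = -data["value"]
        return replace(profile, data=data)
    if isinstance(profile, CategoricalSignature):
        data = profile.data.copy()
        data["sense"] = -data["sense"]
        data["fraction"] = -data["fraction"]
        return replace(profile, data=data)
    raise TypeError(f"cannot reverse {type(profile).__name__}")


def representative_profile(
    profiles: list[SignatureProfile],
    min_fraction: float = 0.20,
    alpha: float = 0.05,
) -> CategoricalSignature:
    """Categorical consensus signature across several profiles.

    Per gene, the up/down sense calls of the genes retained in each profile
    are summed: fraction = (n_up - n_down) / P with P the number of input
    profiles (a gene absent from a profile contributes sense 0). Genes are
    retained when |fraction| strictly exceeds ``min_fraction`` and a
    one-sample Student t-test of the per-profile senses against 0 gives
    p < ``alpha``. Unanimous nonzero senses have zero variance; they are
    treated as maximal evidence (p = 0) rather than dropped.
    """
    if len(profiles) < 2:
        raise ValueError(
            "representative_profile needs >=2 profiles; use the single profile directly"
        )
    P = len(profiles)
    universe = sorted(set().union(*[set(p.genes) for p in profiles]))
    mat = np.zeros((len(universe), P), dtype=float)
    gene_pos = {g: i for i, g in enumerate(universe)}
    for j, prof in enumerate(profiles):
        senses = prof.senses
        mat[[gene_pos[g] for g in prof.genes], j] = senses.to_numpy()
    n_up = (mat > 0).sum(axis=1)
    n_down = (mat < 0).sum(axis=1)
    fraction = (n_up - n_down) / P
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_1samp(mat, 0.0, axis=1)
        p = np.asarray(t_res.pvalue)
    degenerate = np.ptp(mat, axis=1) == 0
    p = np.where(degenerate & (mat[:, 0] != 0), 0.0, p)
    p = np.where(degenerate & (mat[:, 0] == 0), 1.0, p)
    keep = (np.abs(fraction) > min_fraction) & (p < alpha)
    idx = pd.Index(np.asarray(universe, dtype=object)[keep])
    data = pd.DataFrame(
        {
            "sense": np.sign(fraction[keep]).astype(int),
            "fraction": fraction[keep],
            "support": (mat[keep] != 0).sum(axis=1).astype(int),
        },
        index=idx,
    )
    return CategoricalSignature(data=data, n_profiles=P, source="representative")
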