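"""Synthetic study generators with planted ground truth.

Every generator emulates one class of input the pipeline consumes in
practice — case/control brain expression series, ordinal disease-stage
series, plate-structured drug-treatment screens with vehicle controls, and
degenerate probe->gene maps — with the planted structure recorded in a
:class:`~sigreverse.types.PlantedTruth` so downstream recovery is checkable.

Noise model: expression is Gaussian on the log2 scale with unit SD around a
gene-specific baseline (log-normal intensities, the usual microarray
picture). Effects are expressed in units of that noise SD. Plate effects are
additive per-plate, per-gene offsets on the log scale, shared by every
sample on the plate, so they cancel exactly under plate-control
normalisation. All randomness flows from the explicit ``seed`` argument; no
global random state is touched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, PlantedTruth, ProbeGeneMap

__all__ = [
    "generate_disease_study",
    "generate_stage_series",
    "generate_drug_plates",
    "generate_probe_map",
]

NOISE_SD = 1.0  # log2-scale noise SD; effect sizes are multiples of this
BASELINE_MEAN = 7.0  # typical log2 intensity of an expressed probe
BASELINE_SD = 1.0  # spread of gene baselines
PLATE_SD = 0.5  # SD of the per-plate, per-gene log-scale offset


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_disease_study(
    n_genes: int,
    n_up: int,
    n_down: int,
    effect: float,
    n_control: int,
    n_disease: int,
    seed: int,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Control/disease matrix with a planted up/down signature.

    The first ``n_up`` genes are shifted up by ``effect`` x noise SD in the
    disease samples, the next ``n_down`` down; all remaining genes have zero
    group difference. Returns the matrix (log2 scale) and the planted truth.
    """
    if n_up + n_down > n_genes:
        raise ValueError(
            f"signature ({n_up}+{n_down} genes) larger than gene universe ({n_genes})"
        )
    if n_control < 2 or n_disease < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    up = genes[:n_up]
    down = genes[n_up : n_up + n_down]
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    n_samples = n_control + n_disease
    values = baseline[:, None] + rng.normal(0.0, NOISE_SD, size=(n_genes, n_samples))
    shift = np.zeros(n_genes)
    shift[:n_up] = effect * NOISE_SD
    shift[n_up : n_up + n_down] = -effect * NOISE_SD
    values[:, n_control:] += shift[:, None]
    sample_ids = [f"C{i+1:03d}" for i in range(n_control)] + [
        f"D{i+1:03d}" for i in range(n_disease)
    ]
    samples = pd.DataFrame(
        {"group": ["control"] * n_control + ["disease"] * n_disease},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes), columns=sample_ids),
        samples=samples,
    )
    truth = PlantedTruth(
        signature_genes_up=set(up),
        signature_genes_down=set(down),
        effect_size=effect,
        seed=seed,
        n_genes=n_genes,
    )
    return matrix, truth


def generate_stage_series(
    n_genes: int,
    n_samples: int,
    stage_range: int,
    n_linked: int,
    slope: float,
    covariates: dict[str, list[str]] | None = None,
    seed: int = 0,
    n_covariate_only: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Series whose samples carry an ordinal stage, with stage-linked genes.

    Stages 0..``stage_range`` are assigned near-uniformly across samples.
    The first ``n_linked`` genes depend linearly on stage (``slope`` log2
    units per stage level; half with positive, half with negative slope) and
    additionally carry random covariate-level offsets, so recovering them
    requires covariate adjustment. The next ``n_covariate_only`` genes are
    offset by the first covariate only (2 log2 units between levels) and
    have no stage dependence — a specificity control. Remaining genes are
    pure noise.
    """
    if n_samples < stage_range + 2:
        raise ValueError("need at least stage_range + 2 samples")
    covariates = covariates or {}
    n_params = 2 + sum(len(levels) - 1 for levels in covariates.values())
    if n_samples < n_params + 2:
        raise ValueError(
            f"{n_samples} samples cannot support a model with {n_params} parameters"
        )
    if n_linked + n_covariate_only > n_genes:
        raise ValueError("planted genes exceed gene universe")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    stages = np.resize(np.arange(stage_range + 1), n_samples).astype(float)
    rng.shuffle(stages)
    sample_ids = [f"S{i+1:03d}" for i in range(n_samples)]
    meta = {"group": ["series"] * n_samples, "stage": stages}
    cov_codes: dict[str, np.ndarray] = {}
    for name, levels in covariates.items():
        codes = rng.integers(0, len(levels), size=n_samples)
        cov_codes[name] = codes
        meta[name] = [levels[c] for c in codes]
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, NOISE_SD, size=(n_genes, n_samples))
    # stage-linked genes: first half up, second half down, plus covariate offsets
    n_up = n_linked - n_linked // 2
    gene_slopes = np.zeros(n_genes)
    gene_slopes[:n_up] = slope
    gene_slopes[n_up:n_linked] = -slope
    values += gene_slopes[:, None] * stages[None, :]
    for name, levels in covariates.items():
        offsets = rng.normal(0.0, NOISE_SD, size=(n_linked, len(levels)))
        values[:n_linked] += offsets[:, cov_codes[name]]
    if n_covariate_only:
        if not covariates:
            raise ValueError("n_covariate_only > 0 requires at least one covariate")
        first = next(iter(covariates))
        sl = slice(n_linked, n_linked + n_covariate_only)
        values[sl] += 2.0 * NOISE_SD * cov_codes[first][None, :]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes), columns=sample_ids),
        samples=samples,
    )
    truth = PlantedTruth(
        signature_genes_up=set(genes[:n_up]),
        signature_genes_down=set(genes[n_up:n_linked]),
        effect_size=slope,
        seed=seed,
        n_genes=n_genes,
    )
    return matrix, truth


def generate_drug_plates(
    truth: PlantedTruth,
    n_drugs: int,
    n_reversers: int,
    reversal_fraction: float,
    effect: float,
    replicates: int = 3,
    plates: int = 1,
    seed: int = 0,
) -> tuple[list[ExpressionMatrix], PlantedTruth]:
    """Plate-structured drug screen over the gene universe of ``truth``.

    Each plate carries its own vehicle-control group plus ``replicates``
    treated cultures per drug assigned to it (drugs are distributed
    round-robin over plates). Reverser drugs shift a ``reversal_fraction``
    of the planted disease signature in the sense opposite to the disease;
    every other drug perturbs a random gene set of the same size with random
    signs, so database queries can be tested for specificity as well as
    sensitivity. A per-plate, per-gene offset (SD 0.5 log2 units) is shared
    by all samples on the plate.

    Returns one matrix per plate and a copy of ``truth`` with
    ``reverser_drugs`` filled in.
    """
    if n_reversers > n_drugs:
        raise ValueError(f"n_reversers ({n_reversers}) exceeds n_drugs ({n_drugs})")
    if replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    if not 0.0 <= reversal_fraction <= 1.0:
        raise ValueError("reversal_fraction must lie in [0, 1]")
    if truth.n_genes == 0:
        raise ValueError("truth carries no gene universe (n_genes == 0)")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(truth.n_genes)
    up = sorted(truth.signature_genes_up)
    down = sorted(truth.signature_genes_down)
    sig = up + down
    n_hit = int(round(reversal_fraction * len(sig)))

    drugs = [f"drug{i+1:03d}" for i in range(n_drugs)]
    reversers = sorted(rng.choice(drugs, size=n_reversers, replace=False).tolist())
    gene_index = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=truth.n_genes)

    # per-drug perturbation vector (log2 shift per gene)
    perturbations: dict[str, np.ndarray] = {}
    for drug in drugs:
        delta = np.zeros(truth.n_genes)
        if drug in reversers:
            hit = rng.choice(len(sig), size=n_hit, replace=False)
            for j in hit:
                g = sig[j]
                sign = -1.0 if g in truth.signature_genes_up else 1.0
                delta[gene_index[g]] = sign * effect * NOISE_SD
        else:
            hit = rng.choice(truth.n_genes, size=n_hit, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_hit)
            delta[hit] = signs * effect * NOISE_SD
        perturbations[drug] = delta

    matrices: list[ExpressionMatrix] = []
    for p in range(plates):
        plate_id = f"plate{p+1:02d}"
        plate_drugs = drugs[p::plates]
        plate_offset = rng.normal(0.0, PLATE_SD, size=truth.n_genes)
        cols: list[np.ndarray] = []
        sample_ids: list[str] = []
        groups: list[str] = []
        for r in range(replicates):
            cols.append(
                baseline
                + plate_offset
                + rng.normal(0.0, NOISE_SD, size=truth.n_genes)
            )
            sample_ids.append(f"{plate_id}_veh_{r+1}")
            groups.append("vehicle")
        for drug in plate_drugs:
            for r in range(replicates):
                cols.append(
                    baseline
                    + plate_offset
                    + perturbations[drug]
                    + rng.normal(0.0, NOISE_SD, size=truth.n_genes)
                )
                sample_ids.append(f"{plate_id}_{drug}_{r+1}")
                groups.append(drug)
        values = pd.DataFrame(
            np.column_stack(cols), index=pd.Index(genes), columns=sample_ids
        )
        samples = pd.DataFrame(
            {"group": groups, "plate": plate_id},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        matrices.append(ExpressionMatrix(values=values, samples=samples))

    out_truth = PlantedTruth(
        signature_genes_up=set(truth.signature_genes_up),
        signature_genes_down=set(truth.signature_genes_down),
        reverser_drugs={d: reversal_fraction for d in reversers},
        effect_size=effect,
        seed=seed,
        n_genes=truth.n_genes,
    )
    return matrices, out_truth


def generate_probe_map(n_genes: int, max_degeneracy: int, seed: int) -> ProbeGeneMap:
    """Probe -> gene map where each gene gets 1..max_degeneracy probes.

    With ``max_degeneracy >= 2`` at least one gene is guaranteed multiple
    probes, so probe-collapse logic is exercised.
    """
    if max_degeneracy < 1:
        raise ValueError("max_degeneracy must be >= 1")
    rng = np.random.default_rng(seed)
    entries: dict[str, str] = {}
    counts = rng.integers(1, max_degeneracy + 1, size=n_genes)
    if max_degeneracy >= 2 and n_genes > 0 and counts.max() < 2:
        counts[0] = 2
    for gi, (gene, k) in enumerate(zip(_gene_ids(n_genes), counts)):
        for j in range(k):
            if max_degeneracy == 1:
                probe = f"P{gi+1:05d}"
            else:
                probe = f"P{gi+1:05d}_{j+1}"
            entries[probe] = gene
    return ProbeGeneMap(entries=entries)
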