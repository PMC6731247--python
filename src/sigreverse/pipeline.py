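"""End-to-end reversal screen on synthetic data.

Convenience driver tying the pipeline stages together: simulate several
case/control disease studies over one planted signature, build their
scaled-fold profiles and representative consensus signatures, simulate a
plate-structured drug screen over the same gene universe, profile every
drug against its plate vehicle, rank the database for anti-correlation,
select hit compounds and assess the enrichment of the planted reversers'
ranks.

Default problem sizes — 1000 genes with a 50-up/50-down signature at 3
noise-SD effect, 5 control vs 5 disease samples per study, 50 drugs (5
reversers at reversal fraction 0.8) in triplicate over 5 plates — keep a
full screen under ~10 s while leaving all statistics in their calibrated
regimes. Per-gene background match probabilities for the enrichment are
scaled by regulation frequencies observed across the drug database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectivity import ks_enrichment, rank_query, regulation_frequencies
from .consensus import select_hits
from .profiles import treatment_profile
from .signatures import representative_profile, scaled_fold_profile
from .simulate import generate_disease_study, generate_drug_plates
from .types import (
    CategoricalSignature,
    ConnectivityResult,
    DrugProfile,
    EnrichmentResult,
    PlantedTruth,
    SignatureProfile,
)
from .connectivity import concordance_score

__all__ = ["ScreenResult", "run_reversal_screen"]


@dataclass
class ScreenResult:
    """Everything a synthetic reversal screen produces."""

    truth: PlantedTruth
    study_profiles: list[SignatureProfile]
    signatures: list[CategoricalSignature]
    query: CategoricalSignature
    drug_profiles: list[DrugProfile]
    ranking: list[tuple[str, ConnectivityResult, int]]
    hits: list[str]
    reverser_ranks: list[int]
    reverser_enrichment: EnrichmentResult
    score_table: dict[str, list[ConnectivityResult]] = field(default_factory=dict)

    @property
    def reversers(self) -> set[str]:
        return set(self.truth.reverser_drugs)


def run_reversal_screen(
    seed: int,
    n_genes: int = 1000,
    n_up: int = 50,
    n_down: int = 50,
    disease_effect: float = 3.0,
    n_control: int = 5,
    n_disease: int = 5,
    n_studies: int = 4,
    n_drugs: int = 50,
    n_reversers: int = 5,
    reversal_fraction: float = 0.8,
    drug_effect: float = 3.0,
    replicates: int = 3,
    plates: int = 5,
    min_signatures: int = 2,
    alpha: float = 0.05,
    n_permutations: int = 10_000,
) -> ScreenResult:
    """Simulate and run a complete signature-reversal screen.

    The ``n_studies`` disease studies share one planted signature layout but
    have independent noise; their scaled-fold profiles are split into two
    halves yielding two representative signatures for hit selection (a drug
    is a hit with >= ``min_signatures`` significant anti-correlations), and
    the representative profile over all studies serves as the ranking
    query. All sub-seeds derive from ``seed``.
    """
    if n_studies < 4:
        raise ValueError("need >= 4 studies to build two representative signatures")
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_studies + 1)]

    studies = [
        generate_disease_study(
            n_genes, n_up, n_down, disease_effect, n_control, n_disease, seed=s
        )
        for s in sub[:n_studies]
    ]
    truth = studies[0][1]
    study_profiles = [
        scaled_fold_profile(m, "control", "disease") for m, _ in studies
    ]
    half = n_studies // 2
    signatures = [
        representative_profile(study_profiles[:half]),
        representative_profile(study_profiles[half:]),
    ]
    query = representative_profile(study_profiles)

    plate_matrices, truth = generate_drug_plates(
        truth,
        n_drugs=n_drugs,
        n_reversers=n_reversers,
        reversal_fraction=reversal_fraction,
        effect=drug_effect,
        replicates=replicates,
        plates=plates,
        seed=sub[n_studies],
    )
    drug_profiles: list[DrugProfile] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pm in plate_matrices:
            for g in pm.samples["group"].unique():
                if g != "vehicle":
                    drug_profiles.append(treatment_profile(pm, g))

    freqs = regulation_frequencies(drug_profiles)
    ranking = rank_query(
        query, drug_profiles, direction="anticorrelate", background_freqs=freqs
    )
    score_table: dict[str, list[ConnectivityResult]] = {}
    for prof in drug_profiles:
        score_table.setdefault(prof.drug, []).extend(
            concordance_score(sig, prof, background_freqs=freqs)
            for sig in signatures
        )
    hits = select_hits(score_table, min_signatures=min_signatures, alpha=alpha)
    reverser_ranks = sorted(
        r for drug, _, r in ranking if drug in truth.reverser_drugs
    )
    enrichment = ks_enrichment(
        reverser_ranks,
        universe_size=len(drug_profiles),
        n_permutations=n_permutations,
        seed=sub[n_studies],
    )
    return ScreenResult(
        truth=truth,
        study_profiles=study_profiles,
        signatures=signatures,
        query=query,
        drug_profiles=drug_profiles,
        ranking=ranking,
        hits=hits,
        reverser_ranks=reverser_ranks,
        reverser_enrichment=enrichment,
        score_table=score_table,
    )
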