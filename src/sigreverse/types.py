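"""Domain containers shared across the pipeline.

The pipeline moves expression data through a small set of typed objects:

* :class:`ExpressionMatrix` — genes/probes x samples with per-sample metadata;
  the universal input.
* :class:`SignatureProfile` — per-gene signed continuous change (scaled fold
  or Z score) with significance; a disease or drug phenotype.
* :class:`CategoricalSignature` — per-gene sense (+1/-1) with a support
  fraction; the consensus/representative form used as a query.
* :class:`RankProfile` / :class:`CellIdentityProfile` — rank-derived profiles
  in [-1, 1].
* :class:`DrugProfile` — a filtered treatment-vs-vehicle contrast.
* :class:`ConnectivityResult` / :class:`EnrichmentResult` — scoring outputs.
* :class:`PlantedTruth` — ground truth attached to synthetic data.

Gene and probe identifiers are opaque strings throughout; no symbol
translation is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SignatureProfile",
    "CategoricalSignature",
    "RankProfile",
    "CellIdentityProfile",
    "DrugProfile",
    "ConnectivityResult",
    "EnrichmentResult",
    "PlantedTruth",
    "ProbeGeneMap",
    "GeneSetCollection",
    "SenseConsensus",
    "Dendrogram",
]

#: Cap on |Z| scores converted from p-values (p underflow guard near double
#: precision; Phi^-1 of the smallest positive double is about 8.2).
Z_CAP = 8.2

RESERVED_METADATA = ("group", "plate", "stage")


@dataclass
class ExpressionMatrix:
    """Expression values (features x samples, log2 scale) plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature (probe or gene) id with one column per
        sample, log2 expression units unless stated otherwise by the caller.
    samples
        DataFrame indexed by sample id. Must carry a ``group`` column; may
        carry ``plate``, ``stage`` and arbitrary categorical covariate
        columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata must have a 'group' column")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"metadata missing for sample(s): {missing}")
        # align metadata to matrix column order, drop extraneous rows
        self.samples = self.samples.loc[list(self.values.columns)]
        if self.samples["group"].isna().any():
            bad = self.samples.index[self.samples["group"].isna()][0]
            raise ValueError(f"sample {bad!r} has no group label")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_columns(self, group: str, plate: str | None = None) -> pd.DataFrame:
        """Sub-matrix of the samples in *group* (optionally restricted to *plate*)."""
        mask = self.samples["group"] == group
        if plate is not None:
            if "plate" not in self.samples.columns:
                raise ValueError("matrix has no plate metadata")
            mask &= self.samples["plate"] == plate
        ids = self.samples.index[mask]
        if len(ids) == 0:
            where = f" on plate {plate!r}" if plate is not None else ""
            raise ValueError(f"no samples in group {group!r}{where}")
        return self.values[ids]

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.samples.equals(other.samples)


@dataclass
class SignatureProfile:
    """Per-gene signed change with significance, after filtering.

    ``data`` is indexed by gene id with columns ``value`` (scaled fold in
    [-1, 1] or a Z score, by ``kind``) and ``p_value``. Only genes that
    passed the profile's filters are present; ``sense`` is the sign of the
    value.
    """

    data: pd.DataFrame
    kind: str  # "fold" | "zscore"
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("fold", "zscore"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        required = {"value", "p_value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"profile data needs columns {sorted(required)}")
        if not self.data.index.is_unique:
            raise ValueError("duplicate gene ids in profile")
        if self.kind == "fold" and len(self.data):
            v = self.data["value"].to_numpy()
            if np.nanmax(np.abs(v)) > 1 + 1e-12:
                raise ValueError("scaled-fold values must lie in [-1, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def values(self) -> pd.Series:
        return self.data["value"]

    @property
    def senses(self) -> pd.Series:
        return np.sign(self.data["value"]).astype(int)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CategoricalSignature:
    """Consensus signature: per-gene sense with its net regulation fraction.

    ``data`` is indexed by gene with columns ``sense`` (+1/-1), ``fraction``
    (net regulation fraction in [-1, 1]) and ``support`` (number of
    contributing profiles in which the gene was retained).
    """

    data: pd.DataFrame
    n_profiles: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        required = {"sense", "fraction", "support"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"categorical signature needs columns {sorted(required)}")
        if not self.data.index.is_unique:
            raise ValueError("duplicate gene ids in signature")
        if len(self.data):
            if not set(np.unique(self.data["sense"])) <= {-1, 1}:
                raise ValueError("senses must be +1 or -1")
            if np.max(np.abs(self.data["fraction"])) > 1 + 1e-12:
                raise ValueError("fractions must lie in [-1, 1]")
            if self.n_profiles and (self.data["support"] > self.n_profiles).any():
                raise ValueError("support exceeds number of input profiles")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def senses(self) -> pd.Series:
        return self.data["sense"].astype(int)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RankProfile:
    """Scaled expression-change ranks in [-1, 1] (most upregulated = +1)."""

    values: pd.Series  # indexed by feature id
    drug: str = ""
    n_replicates: int = 1
    context: str = ""

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate feature ids in rank profile")
        if len(self.values):
            if np.max(np.abs(self.values.to_numpy())) > 1 + 1e-12:
                raise ValueError("rank-profile values must lie in [-1, 1]")

    @property
    def senses(self) -> pd.Series:
        return np.sign(self.values).astype(int)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CellIdentityProfile:
    """Relative-rank cell-identity profile against a background rank source."""

    values: pd.Series
    reference: str = "background"

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DrugProfile:
    """Filtered treatment-vs-vehicle contrast at gene (or probe) level.

    ``data`` is indexed by gene with columns ``value`` (scaled fold or Z) and
    ``stat`` (the t-test p-value for the fold method, |Z| for the Z method).
    Every retained gene passed the declared filter.
    """

    data: pd.DataFrame
    drug: str = ""
    plate: str = ""
    method: str = "zscore"  # "fold" | "zscore"

    def __post_init__(self) -> None:
        if self.method not in ("fold", "zscore"):
            raise ValueError(f"unknown treatment-profile method {self.method!r}")
        required = {"value", "stat"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"drug profile needs columns {sorted(required)}")
        if not self.data.index.is_unique:
            raise ValueError("duplicate gene ids in drug profile")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def values(self) -> pd.Series:
        return self.data["value"]

    @property
    def senses(self) -> pd.Series:
        return np.sign(self.data["value"]).astype(int)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ConnectivityResult:
    """Sense-concordance counts and enrichment for one query x profile pair."""

    n_uu: int
    n_dd: int
    n_ud: int
    n_du: int
    score: float
    enrichment_p: float
    overlap: int
    direction: str = "concordant"  # side the enrichment tail was taken on
    defined: bool = True
    drug: str = ""

    def __post_init__(self) -> None:
        counts = (self.n_uu, self.n_dd, self.n_ud, self.n_du)
        if any(c < 0 for c in counts):
            raise ValueError("concordance counts must be non-negative")
        if self.defined:
            if sum(counts) != self.overlap:
                raise ValueError("counts must sum to the overlap")
            if not -1 - 1e-12 <= self.score <= 1 + 1e-12:
                raise ValueError("concordance score must lie in [-1, 1]")
            if not 0 < self.enrichment_p <= 1:
                raise ValueError("enrichment probability must lie in (0, 1]")

    @property
    def matches(self) -> int:
        return self.n_uu + self.n_dd

    @property
    def mismatches(self) -> int:
        return self.n_ud + self.n_du


@dataclass
class EnrichmentResult:
    """KS running-sum enrichment: peak deviation D and its Monte-Carlo p."""

    D: float
    p_mc: float
    n_permutations: int
    seed: int
    n_hits: int = 0
    universe_size: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.D <= 1:
            raise ValueError("D must lie in [0, 1]")
        if self.p_mc < 1.0 / (self.n_permutations + 1) - 1e-15:
            raise ValueError("p_mc below the add-one floor")


@dataclass
class PlantedTruth:
    """Ground truth planted by the synthetic generators.

    ``reverser_drugs`` maps drug id to the fraction of the planted disease
    signature that the drug shifts in the opposite sense.
    """

    signature_genes_up: set[str] = field(default_factory=set)
    signature_genes_down: set[str] = field(default_factory=set)
    reverser_drugs: dict[str, float] = field(default_factory=dict)
    effect_size: float = 0.0
    seed: int = 0
    n_genes: int = 0

    def __post_init__(self) -> None:
        overlap = self.signature_genes_up & self.signature_genes_down
        if overlap:
            raise ValueError(f"genes planted both up and down: {sorted(overlap)[:3]}")
        for drug, frac in self.reverser_drugs.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"reversal fraction for {drug!r} outside [0, 1]")

    @property
    def signature_genes(self) -> set[str]:
        return self.signature_genes_up | self.signature_genes_down

    def to_json(self) -> str:
        return json.dumps(
            {
                "signature_genes_up": sorted(self.signature_genes_up),
                "signature_genes_down": sorted(self.signature_genes_down),
                "reverser_drugs": dict(sorted(self.reverser_drugs.items())),
                "effect_size": self.effect_size,
                "seed": self.seed,
                "n_genes": self.n_genes,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            signature_genes_up=set(d["signature_genes_up"]),
            signature_genes_down=set(d["signature_genes_down"]),
            reverser_drugs={k: float(v) for k, v in d["reverser_drugs"].items()},
            effect_size=float(d["effect_size"]),
            seed=int(d["seed"]),
            n_genes=int(d.get("n_genes", 0)),
        )


@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene map (every probe maps to exactly one gene)."""

    entries: dict[str, str]

    @property
    def probes(self) -> list[str]:
        return list(self.entries)

    @property
    def genes(self) -> set[str]:
        return set(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, probe: str) -> str:
        return self.entries[probe]

    def __contains__(self, probe: str) -> bool:
        return probe in self.entries


@dataclass
class GeneSetCollection:
    """Named gene sets: name -> (description, ordered unique member ids)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterable[str]:
        return iter(self.sets)


@dataclass
class SenseConsensus:
    """Sum-sense-change consensus over a set of profiles.

    ``ratio`` holds, per selected gene, (1/P) * sum_i sign(g_i) over the P
    profiles; ``sense_matrix`` the underlying gene x profile sense calls
    (absent gene = 0), retained for display.
    """

    ratio: pd.Series
    sense_matrix: pd.DataFrame
    n_profiles: int

    def __post_init__(self) -> None:
        if len(self.ratio) and np.max(np.abs(self.ratio.to_numpy())) > 1 + 1e-12:
            raise ValueError("sum-sense ratios must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.ratio)


@dataclass
class Dendrogram:
    """UPGMA merge history: (left, right, height, size) per internal node.

    Leaves are numbered 0..N-1 in ``labels`` order; internal node i (from 0)
    gets id N+i. Heights are ultrametric node heights (half the average
    inter-cluster distance at the merge) and non-decreasing.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError("a dendrogram over N leaves has exactly N-1 merges")
        heights = [h for _, _, h, _ in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing (ultrametricity)")

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h, _ in self.merges]

    def to_newick(self) -> str:
        """Newick string with branch lengths from ultrametric node heights."""
        n = len(self.labels)
        node_height = {i: 0.0 for i in range(n)}
        rep: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            la = h - node_height[a]
            lb = h - node_height[b]
            rep[n + k] = f"({rep[a]}:{la:g},{rep[b]}:{lb:g})"
            node_height[n + k] = h
        return rep[n + len(self.merges) - 1] + ";"


def as_sense_series(profile) -> pd.Series:
    """Per-gene sense (+1/-1/0) of any profile-like object."""
    if isinstance(profile, (SignatureProfile, CategoricalSignature, DrugProfile)):
        return profile.senses
    if isinstance(profile, RankProfile):
        return profile.senses
    if isinstance(profile, pd.Series):
        return np.sign(profile).astype(int)
    raise TypeError(f"cannot extract senses from {type(profile).__name__}")
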