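"""Readers and writers for every artifact format.

One canonical TSV dialect is used throughout: tab separator, ``.`` decimal,
no quoting. Matrices are a values TSV (first column ``feature_id``) plus a
sample-metadata TSV; signatures and profiles are TSVs with a typed ``#``
header line; gene sets are standard GMT; planted truth and profile-database
manifests are JSON. Readers reject malformed input rather than coercing it,
and every writer/reader pair is an exact inverse on valid objects.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CategoricalSignature,
    DrugProfile,
    ExpressionMatrix,
    GeneSetCollection,
    PlantedTruth,
    ProbeGeneMap,
    RankProfile,
    SignatureProfile,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_signature",
    "write_signature",
    "read_probe_map",
    "write_probe_map",
    "read_truth",
    "write_truth",
    "read_profile_db",
    "write_profile_db",
]

_FLOAT_FMT = "%.17g"  # full round-trip precision for doubles


class ParseError(ValueError):
    """Malformed input file, with row/column context in the message."""


# --------------------------------------------------------------------------
# expression matrices


def write_matrix(matrix: ExpressionMatrix, matrix_path, metadata_path) -> None:
    vals = matrix.values.copy()
    vals.index.name = "feature_id"
    vals.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT)
    meta = matrix.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read a values TSV (header row of sample ids) and its metadata TSV."""
    vals = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    if vals.index.duplicated().any():
        dup = vals.index[vals.index.duplicated()][0]
        raise ParseError(f"{matrix_path}: duplicate feature id {dup!r}")
    non_num = [c for c in vals.columns if not np.issubdtype(vals[c].dtype, np.number)]
    if non_num:
        col = non_num[0]
        bad = vals[col][pd.to_numeric(vals[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise ParseError(
            f"{matrix_path}: non-numeric cell in column {col!r}, row {row!r}"
        )
    if vals.isna().any().any():
        col = vals.columns[vals.isna().any()][0]
        row = vals.index[vals[col].isna()][0]
        raise ParseError(f"{matrix_path}: missing value at row {row!r}, column {col!r}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = [s for s in vals.columns if s not in meta.index]
    if missing:
        raise ParseError(f"{metadata_path}: metadata missing for sample(s) {missing}")
    if "group" not in meta.columns:
        raise ParseError(f"{metadata_path}: no 'group' column")
    vals.index.name = None
    meta.index.name = None
    return ExpressionMatrix(values=vals, samples=meta)


# --------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: per line, set name, description, tab-separated members."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            seen: set[str] = set()
            unique: list[str] = []
            for m in members:
                if m in seen:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate member {m!r} in set {name!r} dropped"
                    )
                    continue
                seen.add(m)
                unique.append(m)
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = (desc, unique)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# --------------------------------------------------------------------------
# signatures and profiles (typed TSV)

_TYPE_TAGS = {
    "signature": SignatureProfile,
    "categorical": CategoricalSignature,
    "drugprofile": DrugProfile,
    "rankprofile": RankProfile,
}


def _header(tag: str, **attrs: str) -> str:
    parts = [f"#sigreverse\ttype={tag}"]
    parts += [f"{k}={v}" for k, v in attrs.items() if v != ""]
    return "\t".join(parts)


def write_signature(profile, path) -> None:
    """Write any profile object as a typed TSV (lossless round-trip)."""
    path = Path(path)
    if isinstance(profile, SignatureProfile):
        head = _header("signature", kind=profile.kind, source=profile.source)
        body = profile.data[["value", "p_value"]]
    elif isinstance(profile, CategoricalSignature):
        head = _header(
            "categorical", n_profiles=str(profile.n_profiles), source=profile.source
        )
        body = profile.data[["sense", "fraction", "support"]]
    elif isinstance(profile, DrugProfile):
        head = _header(
            "drugprofile", drug=profile.drug, plate=profile.plate, method=profile.method
        )
        body = profile.data[["value", "stat"]]
    elif isinstance(profile, RankProfile):
        head = _header(
            "rankprofile",
            drug=profile.drug,
            n_replicates=str(profile.n_replicates),
            context=profile.context,
        )
        body = profile.values.to_frame("value")
    else:
        raise TypeError(f"cannot serialise {type(profile).__name__}")
    with open(path, "w") as fh:
        fh.write(head + "\n")
        body = body.copy()
        body.index.name = "gene"
        body.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)


def read_signature(path):
    path = Path(path)
    with open(path) as fh:
        head = fh.readline().rstrip("\n")
    if not head.startswith("#sigreverse"):
        raise ParseError(f"{path}: missing typed header line")
    attrs = dict(p.split("=", 1) for p in head.split("\t")[1:])
    tag = attrs.pop("type", None)
    if tag not in _TYPE_TAGS:
        raise ParseError(f"{path}: unknown header type tag {tag!r}")
    body = pd.read_csv(
        path, sep="\t", skiprows=1, index_col=0, float_precision="round_trip"
    )
    body.index = body.index.astype(str)
    body.index.name = None
    if tag == "signature":
        return SignatureProfile(
            data=body, kind=attrs.get("kind", "fold"), source=attrs.get("source", "")
        )
    if tag == "categorical":
        body["sense"] = body["sense"].astype(int)
        body["support"] = body["support"].astype(int)
        return CategoricalSignature(
            data=body,
            n_profiles=int(attrs.get("n_profiles", 0)),
            source=attrs.get("source", ""),
        )
    if tag == "drugprofile":
        return DrugProfile(
            data=body,
            drug=attrs.get("drug", ""),
            plate=attrs.get("plate", ""),
            method=attrs.get("method", "zscore"),
        )
    return RankProfile(
        values=body["value"],
        drug=attrs.get("drug", ""),
        n_replicates=int(attrs.get("n_replicates", 1)),
        context=attrs.get("context", ""),
    )


# --------------------------------------------------------------------------
# probe maps, planted truth


def write_probe_map(pmap: ProbeGeneMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("probe\tgene\n")
        for probe, gene in pmap.entries.items():
            fh.write(f"{probe}\t{gene}\n")


def read_probe_map(path) -> ProbeGeneMap:
    entries: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.rstrip("\n").split("\t") != ["probe", "gene"]:
            raise ParseError(f"{path}: expected 'probe\\tgene' header")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            probe, gene = fields
            if probe in entries:
                raise ParseError(f"{path}:{lineno}: probe {probe!r} mapped twice")
            entries[probe] = gene
    return ProbeGeneMap(entries=entries)


def write_truth(truth: PlantedTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path) -> PlantedTruth:
    return PlantedTruth.from_json(Path(path).read_text())


# --------------------------------------------------------------------------
# profile databases: a directory of typed TSVs plus a JSON manifest


def write_profile_db(profiles, directory, source: str = "") -> None:
    """Write a list of drug/rank profiles as a queryable database directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, prof in enumerate(profiles):
        drug = getattr(prof, "drug", "") or f"profile{i:04d}"
        fname = f"{i:04d}_{drug}.tsv"
        write_signature(prof, directory / fname)
        entries.append(
            {
                "file": fname,
                "drug": drug,
                "replicates": int(getattr(prof, "n_replicates", 1)),
            }
        )
    manifest = {"source": source, "profiles": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_profile_db(directory):
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise ParseError(f"{directory}: no manifest.json")
    manifest = json.loads(manifest_path.read_text())
    return [read_signature(directory / e["file"]) for e in manifest["profiles"]]
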