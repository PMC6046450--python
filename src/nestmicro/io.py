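"""Tables, validation and artifact I/O.

The pipeline revolves around three plain-TSV inputs: an OTU count table
(OTU rows x sample columns), a per-sample metadata table describing the
cross-foster design, and a taxonomy table with semicolon-delimited
lineages.  Everything read or written here is diffable text (TSV/JSON).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SAMPLE_ROLES = ("biological", "blank", "negative_control", "positive_control")

METADATA_COLUMNS = [
    "sample_id",
    "bird_id",
    "nest_of_origin",
    "nest_of_rearing",
    "age_class",
    "nest_treatment",
    "body_mass_g",
    "tarsus_mm",
    "replicate_id",
    "sample_role",
]

AGE_CLASSES = ("D8", "D15")
NEST_TREATMENTS = ("control", "crossfostered")

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class TableFormatError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass
class OtuTable:
    """OTU x sample count matrix with one role per sample.

    ``counts`` may be fractional after replicate merging or blank
    subtraction; raw and rarefied tables are integer-valued.
    """

    counts: pd.DataFrame  # index: otu_id, columns: sample_id
    roles: pd.Series  # index: sample_id -> role

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate OTU identifiers: {dupes}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample identifiers: {dupes}")
        vals = self.counts.to_numpy()
        if vals.size and (np.isnan(vals).any() or (vals < 0).any()):
            bad = np.argwhere(np.isnan(vals) | (vals < 0))[0]
            raise TableFormatError(
                "negative or non-numeric count at OTU "
                f"{self.counts.index[bad[0]]!r}, sample {self.counts.columns[bad[1]]!r}"
            )
        self.roles = self.roles.reindex(self.counts.columns)
        if self.roles.isna().any():
            missing = self.roles.index[self.roles.isna()].tolist()
            raise TableFormatError(f"samples without a role: {missing}")
        unknown = set(self.roles) - set(SAMPLE_ROLES)
        if unknown:
            raise TableFormatError(f"unknown sample roles: {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.roles.index[self.roles == role])

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        sample_ids = list(sample_ids)
        return OtuTable(self.counts[sample_ids].copy(), self.roles.loc[sample_ids].copy())

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[list(otu_ids)].copy(), self.roles.copy())

    def drop_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        keep = self.counts.index.difference(pd.Index(otu_ids), sort=False)
        return OtuTable(self.counts.loc[keep].copy(), self.roles.copy())

    def total_reads(self) -> float:
        return float(self.counts.to_numpy().sum())


@dataclass
class ValidationReport:
    findings: list[tuple[str, str]] = field(default_factory=list)

    def add(self, severity: str, message: str) -> None:
        self.findings.append((severity, message))

    @property
    def errors(self) -> list[str]:
        return [m for s, m in self.findings if s == "error"]

    @property
    def passed(self) -> bool:
        return not self.errors


def read_otu_table(
    path: str | Path,
    roles: Mapping[str, str] | pd.Series | None = None,
    metadata: pd.DataFrame | None = None,
    transpose: bool = False,
    default_role: str | None = None,
) -> OtuTable:
    """Read a TSV OTU table (OTU rows x sample columns).

    Sample roles come either from an explicit ``roles`` map or from the
    ``sample_role`` column of a metadata table; ``default_role`` fills
    samples missing from both (e.g. merged tables whose columns are
    bird/age units rather than replicate IDs).  ``transpose`` accepts
    the samples-as-rows dialect.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise TableFormatError(
                f"non-numeric count at OTU {df.index[bad.argmax()]!r}, sample {col!r}"
            )
        df[col] = coerced
    if roles is None and metadata is not None:
        roles = metadata.set_index("sample_id")["sample_role"]
    if roles is None and default_role is None:
        raise TableFormatError("either a role map, a metadata table or a default_role is required")
    if roles is None:
        role_series = pd.Series(index=df.columns, dtype=object)
    else:
        role_series = pd.Series(dict(roles) if not isinstance(roles, pd.Series) else roles, dtype=object)
    role_series = role_series.reindex(df.columns)
    if default_role is not None:
        role_series = role_series.fillna(default_role)
    return OtuTable(df.astype(float), role_series)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    out = table.counts.copy()
    vals = out.to_numpy()
    if vals.size and np.allclose(vals, np.rint(vals)):
        out = out.astype(np.int64)
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-sample design metadata TSV.

    Mass and tarsus may be empty (tarsus is only measured at D15); they are
    returned as NaN.  Structural violations raise ``TableFormatError``.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise TableFormatError(f"metadata missing columns: {missing_cols}")
    meta = meta[METADATA_COLUMNS].copy()
    for col in ("body_mass_g", "tarsus_mm"):
        meta[col] = pd.to_numeric(meta[col], errors="raise")
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    bio = meta[meta["sample_role"] == "biological"]
    bad_age = set(bio["age_class"]) - set(AGE_CLASSES)
    if bad_age:
        raise TableFormatError(f"unknown age_class values: {sorted(bad_age)}")
    bad_trt = set(bio["nest_treatment"].dropna()) - set(NEST_TREATMENTS)
    if bad_trt:
        raise TableFormatError(f"unknown nest_treatment values: {sorted(bad_trt)}")
    bad_role = set(meta["sample_role"]) - set(SAMPLE_ROLES)
    if bad_role:
        raise TableFormatError(f"unknown sample_role values: {sorted(bad_role)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableFormatError(f"duplicate sample_id values: {dupes}")
    # one rearing nest per bird within an age
    nests = bio.groupby(["bird_id", "age_class"])["nest_of_rearing"].nunique()
    split = nests[nests > 1]
    if len(split):
        raise TableFormatError(
            f"birds recorded in two nests at one age: {sorted({b for b, _ in split.index})}"
        )
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read otu_id<TAB>lineage taxonomy; lineage is semicolon-delimited."""
    tax = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "otu_id" not in tax.columns or "lineage" not in tax.columns:
        raise TableFormatError("taxonomy requires columns otu_id, lineage")
    if tax["otu_id"].duplicated().any():
        raise TableFormatError("duplicate otu_id in taxonomy")
    too_long = tax["lineage"].str.split(";").map(len) > len(TAXONOMY_RANKS)
    if too_long.any():
        raise TableFormatError(
            f"lineage with more than {len(TAXONOMY_RANKS)} ranks: "
            f"{tax.loc[too_long, 'otu_id'].tolist()}"
        )
    return tax


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax.to_csv(path, sep="\t", index=False)


def lineage_rank(lineage: str, rank: str) -> str:
    """Extract one rank from a semicolon-delimited lineage ('' if absent)."""
    parts = [p.strip() for p in str(lineage).split(";")]
    idx = TAXONOMY_RANKS.index(rank)
    if idx < len(parts) and parts[idx]:
        return parts[idx]
    return ""


def validate_dataset(table: OtuTable, meta: pd.DataFrame) -> ValidationReport:
    """Cross-check the count table against the design metadata.

    Findings are collected, never raised: sample-ID agreement, role
    consistency, the two-PCR-replicates-per-biological-sample rule, and
    D8/D15 pairing per bird.
    """
    report = ValidationReport()
    meta_ids = set(meta["sample_id"])
    table_ids = set(table.sample_ids)
    for sid in sorted(table_ids - meta_ids):
        report.add("error", f"sample {sid!r} present in counts but not in metadata")
    for sid in sorted(meta_ids - table_ids):
        report.add("warning", f"sample {sid!r} present in metadata but not in counts")

    roles_meta = meta.set_index("sample_id")["sample_role"]
    for sid in sorted(table_ids & meta_ids):
        if roles_meta[sid] != table.roles[sid]:
            report.add(
                "error",
                f"sample {sid!r} role mismatch: table={table.roles[sid]!r} "
                f"metadata={roles_meta[sid]!r}",
            )

    bio = meta[(meta["sample_role"] == "biological") & meta["sample_id"].isin(table_ids)]
    if len(bio):
        reps = bio.groupby(["bird_id", "age_class"])["replicate_id"].nunique()
        for (bird, age), n in reps.items():
            if n != 2:
                report.add("error", f"bird {bird!r} at {age} has {n} PCR replicate(s), expected 2")
        ages = bio.groupby("bird_id")["age_class"].agg(lambda s: set(s))
        for bird, seen in ages.items():
            missing = set(AGE_CLASSES) - seen
            if missing:
                report.add("warning", f"bird {bird!r} missing age class(es): {sorted(missing)}")
        d8 = bio[bio["age_class"] == "D8"]
        moved_at_d8 = d8[d8["nest_of_rearing"] != d8["nest_of_origin"]]
        for bird in moved_at_d8["bird_id"].unique():
            report.add("error", f"bird {bird!r} has rearing != origin nest at D8")
    return report


# -- result bundle -------------------------------------------------------------


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_results(bundle: Mapping[str, object], out_dir: str | Path, seed: int | None = None) -> list[str]:
    """Write a result bundle and return the file manifest.

    DataFrames become TSVs, everything else is pooled into ``results.json``
    alongside a run log carrying the seed and a hash of the configuration.
    Deterministic for fixed inputs and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    json_payload: dict[str, object] = {}
    for name, obj in bundle.items():
        if isinstance(obj, OtuTable):
            path = out / f"{name}.tsv"
            write_otu_table(obj, path)
            manifest.append(path.name)
        elif isinstance(obj, pd.DataFrame):
            path = out / f"{name}.tsv"
            obj.to_csv(path, sep="\t")
            manifest.append(path.name)
        else:
            json_payload[name] = obj
    blob = json.dumps(json_payload, indent=2, sort_keys=True, default=_json_default)
    (out / "results.json").write_text(blob + "\n")
    manifest.append("results.json")
    log = {
        "seed": seed,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "files": sorted(manifest),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    manifest.append("run_log.json")
    return sorted(manifest)
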