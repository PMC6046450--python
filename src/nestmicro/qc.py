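"""OTU-table decontamination and filtering cascade.

The cascade runs in a fixed order on per-replicate counts:

1. merge PCR replicates of each biological sample (arithmetic mean),
2. subtract the mean abundance of every OTU seen in blank tag
   combinations (mistag signal), flooring at zero,
3. remove reagent/laboratory contaminant OTUs, identified as OTUs with
   BOTH a higher maximum and a higher mean abundance in negative
   controls than in biological samples,
4. drop singleton OTUs and OTUs whose dataset-wide total is below a
   fraction (default 0.005%) of the grand total,
5. rarefy every sample to a common depth (default 1,000 reads) by
   sampling without replacement.

Every stage appends an entry to a :class:`FilterAudit` whose read
accounting balances exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OtuTable


@dataclass
class FilterParams:
    min_total_fraction: float = 0.00005  # 0.005% of the grand total
    rarefaction_depth: int = 1000
    drop_singletons: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_total_fraction < 1:
            raise ValueError("min_total_fraction must be in [0, 1)")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")


@dataclass
class FilterAudit:
    stages: list[dict] = field(default_factory=list)
    contaminant_otus: list[str] = field(default_factory=list)
    samples_dropped_at_rarefaction: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, before: OtuTable, after: OtuTable, **extra) -> None:
        reads_in = before.total_reads()
        reads_out = after.total_reads()
        self.stages.append(
            {
                "stage": stage,
                "otus_in": before.shape[0],
                "otus_out": after.shape[0],
                "reads_in": reads_in,
                "reads_out": reads_out,
                "reads_removed": reads_in - reads_out,
                **extra,
            }
        )

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "contaminant_otus": self.contaminant_otus,
            "samples_dropped_at_rarefaction": self.samples_dropped_at_rarefaction,
            "warnings": self.warnings,
        }


def merge_replicates(table: OtuTable, meta: pd.DataFrame) -> OtuTable:
    """Average PCR replicates of each biological sample into one column.

    The merged column is named after the (bird, age) biological unit:
    ``<bird_id>_<age_class>``. Non-biological samples pass through
    unchanged. Fractional means are kept (rounding happens only at
    rarefaction).
    """
    meta_idx = meta.set_index("sample_id")
    cols_bio, cols_other = [], []
    for sid in table.sample_ids:
        role = table.roles[sid]
        (cols_bio if role == "biological" else cols_other).append(sid)
    unit_of: dict[str, str] = {}
    for sid in cols_bio:
        if sid not in meta_idx.index:
            raise ValueError(f"biological sample {sid!r} missing from metadata")
        row = meta_idx.loc[sid]
        if isinstance(row, pd.DataFrame):
            raise ValueError(f"replicate {sid!r} maps to multiple biological samples")
        unit_of[sid] = f"{row['bird_id']}_{row['age_class']}"
    merged: dict[str, np.ndarray] = {}
    for sid in cols_bio:
        unit = unit_of[sid]
        merged.setdefault(unit, []).append(table.counts[sid].to_numpy(float))
    data = {unit: np.mean(np.stack(cols), axis=0) for unit, cols in merged.items()}
    out = pd.DataFrame(data, index=table.counts.index)
    for sid in cols_other:
        out[sid] = table.counts[sid]
    roles = pd.Series("biological", index=out.columns, dtype=object)
    for sid in cols_other:
        roles[sid] = table.roles[sid]
    return OtuTable(out, roles)


def subtract_blank_signal(table: OtuTable, audit: FilterAudit | None = None) -> OtuTable:
    """Subtract per-OTU mean blank abundance from every non-blank sample.

    For each OTU present in at least one blank, its mean abundance over
    blank samples is subtracted from that OTU in every other sample,
    flooring at zero; blank columns are then removed.  Without blanks the
    table passes through (minus nothing) with a warning in the audit.
    """
    blanks = table.samples_with_role("blank")
    others = [s for s in table.sample_ids if s not in blanks]
    if not blanks:
        if audit is not None:
            audit.warnings.append("no blank samples: mistag subtraction skipped")
        return table
    blank_mean = table.counts[blanks].mean(axis=1)
    adjusted = table.counts[others].sub(blank_mean, axis=0).clip(lower=0.0)
    return OtuTable(adjusted, table.roles.loc[others].copy())


def identify_contaminants(table: OtuTable, audit: FilterAudit | None = None) -> set[str]:
    """OTUs with strictly higher max AND mean abundance in negative controls.

    Means are taken over all samples of each role, zeros included.  Ties
    on either statistic keep the OTU (conservative removal).
    """
    negatives = table.samples_with_role("negative_control")
    biologicals = table.samples_with_role("biological")
    if not negatives:
        if audit is not None:
            audit.warnings.append("no negative controls: contaminant screen skipped")
        return set()
    if not biologicals:
        raise ValueError("contaminant screen requires biological samples")
    neg = table.counts[negatives].to_numpy(float)
    bio = table.counts[biologicals].to_numpy(float)
    is_contam = (neg.max(axis=1) > bio.max(axis=1)) & (neg.mean(axis=1) > bio.mean(axis=1))
    return set(np.asarray(table.otu_ids)[is_contam])


def filter_low_abundance(table: OtuTable, params: FilterParams) -> OtuTable:
    """Drop singletons and OTUs totalling < min_total_fraction of all reads."""
    totals = table.counts.sum(axis=1)
    grand = float(totals.sum())
    if grand == 0:
        return table.select_otus([])
    keep = totals >= params.min_total_fraction * grand
    if params.drop_singletons:
        keep &= totals > 1
    return OtuTable(table.counts.loc[keep].copy(), table.roles.copy())


def rarefy(table: OtuTable, params: FilterParams, audit: FilterAudit | None = None) -> OtuTable:
    """Subsample each sample to ``rarefaction_depth`` reads without replacement.

    Fractional counts are rounded half-to-even first.  Samples with fewer
    reads than the depth are dropped (and listed in the audit).  Draws are
    multivariate hypergeometric, consumed in column order from one
    generator seeded by ``params.seed``.
    """
    depth = params.rarefaction_depth
    rng = np.random.default_rng(params.seed)
    rounded = np.rint(table.counts.to_numpy(float)).astype(np.int64)
    kept_cols: list[str] = []
    dropped: list[str] = []
    out = {}
    for j, sid in enumerate(table.sample_ids):
        col = rounded[:, j]
        total = int(col.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            out[sid] = col.copy()
        else:
            out[sid] = rng.multivariate_hypergeometric(col, depth)
        kept_cols.append(sid)
    if audit is not None:
        audit.samples_dropped_at_rarefaction.extend(dropped)
    frame = pd.DataFrame(out, index=table.counts.index, dtype=np.int64)
    if not kept_cols:
        frame = pd.DataFrame(index=table.counts.index)
    return OtuTable(frame, table.roles.loc[kept_cols].copy())


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample compositions (columns sum to 1); zero-sum samples are errors."""
    sums = table.counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    return table.counts.div(sums, axis=1)


def run_qc(table: OtuTable, meta: pd.DataFrame, params: FilterParams) -> tuple[OtuTable, FilterAudit]:
    """The full cascade: merge, blank-subtract, decontaminate, filter, rarefy."""
    audit = FilterAudit()
    merged = merge_replicates(table, meta)
    audit.record("merge_replicates", table, merged)

    deblanked = subtract_blank_signal(merged, audit)
    audit.record("subtract_blank_signal", merged, deblanked)

    contaminants = identify_contaminants(deblanked, audit)
    audit.contaminant_otus = sorted(contaminants)
    decontaminated = deblanked.drop_otus(contaminants)
    reads_before = deblanked.total_reads()
    frac = (reads_before - decontaminated.total_reads()) / reads_before if reads_before else 0.0
    audit.record(
        "remove_contaminants",
        deblanked,
        decontaminated,
        n_contaminants=len(contaminants),
        fraction_of_abundance_removed=frac,
    )

    bio_only = decontaminated.select_samples(decontaminated.samples_with_role("biological"))
    audit.record("drop_control_samples", decontaminated, bio_only)
    filtered = filter_low_abundance(bio_only, params)
    audit.record("filter_low_abundance", bio_only, filtered)

    rarefied = rarefy(filtered, params, audit)
    audit.record("rarefy", filtered, rarefied, depth=params.rarefaction_depth)
    return rarefied, audit
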