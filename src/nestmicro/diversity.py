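"""Alpha diversity, presence-absence beta diversity, and taxon aggregation.

Alpha metrics are OTU richness, Shannon H' in nats, and Pielou evenness
J' = H'/ln(S).  Beta diversity is the Jaccard dissimilarity on
presence-absence profiles, the only beta metric the downstream analyses
use.  Presence means strictly positive abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import OtuTable, lineage_rank


def alpha_diversity(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats) and Pielou evenness.

    Accepts counts or compositions.  Empty samples get richness 0 and
    H' = 0; evenness is NaN whenever richness <= 1 (undefined).
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    records = []
    for sid in counts.columns:
        col = counts[sid].to_numpy(float)
        pos = col[col > 0]
        richness = int(pos.size)
        if richness == 0:
            shannon = 0.0
        else:
            p = pos / pos.sum()
            shannon = float(-(p * np.log(p)).sum())
        evenness = shannon / np.log(richness) if richness > 1 else np.nan
        records.append({"sample_id": sid, "richness": richness, "shannon": shannon, "evenness": evenness})
    return pd.DataFrame(records).set_index("sample_id")


def jaccard_matrix(table: OtuTable | pd.DataFrame) -> DistanceMatrix:
    """Jaccard dissimilarity between all sample pairs (presence-absence).

    d(A, B) = 1 - |A n B| / |A u B|; two empty samples are at distance 0.
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    presence = (counts.to_numpy(float) > 0).T  # samples x OTUs
    if presence.shape[0] < 2:
        raise ValueError("Jaccard matrix needs at least 2 samples")
    condensed = pdist(presence, metric="jaccard")  # double-empty pairs -> 0
    return DistanceMatrix(squareform(np.nan_to_num(condensed)), ids=list(counts.columns))


def aggregate_taxa(composition: pd.DataFrame, taxonomy: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum per-sample relative abundances at a taxonomic rank.

    OTUs missing from the taxonomy, or with an empty value at ``rank``,
    are pooled as ``Unassigned``.  Column sums are conserved.
    """
    lineage_of = taxonomy.set_index("otu_id")["lineage"]
    labels = []
    for otu in composition.index:
        if otu in lineage_of.index:
            taxon = lineage_rank(lineage_of[otu], rank)
            labels.append(taxon if taxon else "Unassigned")
        else:
            labels.append("Unassigned")
    if composition.empty:
        return pd.DataFrame(columns=composition.columns)
    return composition.groupby(pd.Series(labels, index=composition.index)).sum()


def otu_retention(sample_t1: pd.Series | np.ndarray, sample_t2: pd.Series | np.ndarray) -> float:
    """Proportion of OTUs present at t1 that are still present at t2.

    NaN when nothing is present at t1.
    """
    a = np.asarray(sample_t1, float) > 0
    b = np.asarray(sample_t2, float) > 0
    if a.sum() == 0:
        return float("nan")
    return float((a & b).sum() / a.sum())
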