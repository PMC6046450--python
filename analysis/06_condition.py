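#!/usr/bin/env python
"""Body condition and its coupling to the microbiota.

Scaled mass index (mass x (19.3/tarsus)^1.87), weight gain with the
non-gaining birds excluded, and random-intercept models linking
condition to diversity and to intra-individual community change.
Writes condition.json and condition_by_bird.tsv under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from nestmicro import crossfoster, diversity
from nestmicro.io import read_metadata, read_otu_table
from nestmicro.models import fit_random_intercept_model

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meta = read_metadata(ROOT / "simulated" / "metadata.tsv")
    rarefied = read_otu_table(ROOT / "filtered_table.tsv", default_role="biological")
    jdf = pd.read_csv(ROOT / "jaccard.tsv", sep="\t", index_col=0)
    jacc = DistanceMatrix(jdf.to_numpy(), ids=list(jdf.columns))
    birds = crossfoster.bird_table(meta)

    cond, smi_params = crossfoster.compute_condition(meta)
    alpha = diversity.alpha_diversity(rarefied)
    for age, suffix in (("D15", ""), ("D8", "_d8")):
        sub = alpha.loc[[i for i in alpha.index if i.endswith(f"_{age}")]].copy()
        sub.index = [i[: -(len(age) + 1)] for i in sub.index]
        cond[f"richness{suffix}"] = sub["richness"]
        cond[f"shannon{suffix}"] = sub["shannon"]
    cond["log_richness"] = np.log(cond["richness"].where(cond["richness"] > 0))
    cond["delta_richness"] = cond["richness"] - cond["richness_d8"]
    cond["delta_shannon"] = cond["shannon"] - cond["shannon_d8"]
    cond["intra_distance"] = crossfoster.intra_individual_change(jacc, meta)
    cond["nest"] = birds.loc[cond.index, "nest_of_rearing"]
    cond.to_csv(ROOT / "condition_by_bird.tsv", sep="\t")

    excluded = int((~cond["included_in_gain_models"]).sum())
    print(f"SMI uses slope {smi_params['slope']} and reference tarsus {smi_params['reference_tarsus']} mm")
    print(f"{excluded} birds excluded from gain models (non-positive weight gain)")

    smi_fit = fit_random_intercept_model(
        cond.dropna(subset=["smi_g", "log_richness"]), "smi_g", ["log_richness"], ["nest"]
    )
    gain_df = cond[cond["included_in_gain_models"]].dropna(
        subset=["weight_gain_g", "delta_richness", "delta_shannon", "intra_distance"]
    )
    gain_fit = fit_random_intercept_model(
        gain_df, "weight_gain_g", ["delta_richness", "delta_shannon", "intra_distance"], ["nest"],
        backward=True,
    )
    out = {
        "smi_parameters": smi_params,
        "n_excluded_nonpositive_gain": excluded,
        "smi_vs_log_richness": smi_fit.to_dict(),
        "gain_vs_microbiota": gain_fit.to_dict(),
    }
    (ROOT / "condition.json").write_text(json.dumps(out, indent=2, default=str) + "\n")
    print(f"SMI ~ log richness: beta = {smi_fit.params['log_richness']:.3f}, "
          f"p = {smi_fit.pvalues['log_richness']:.3f}")
    kept = [t for t in ("delta_richness", "delta_shannon", "intra_distance") if t not in gain_fit.dropped_terms]
    print(f"gain model kept terms after backward elimination: {kept or 'none'}")


if __name__ == "__main__":
    main()
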