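#!/usr/bin/env python
"""Alpha diversity, Jaccard beta diversity and phylum composition.

Richness, Shannon H' and Pielou evenness per sample; the
presence-absence Jaccard matrix all community statistics run on; and
phylum-level composition at each age.  Writes alpha_diversity.tsv,
jaccard.tsv and phylum_composition.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from nestmicro import diversity, qc
from nestmicro.io import read_otu_table, read_taxonomy

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_otu_table(ROOT / "filtered_table.tsv", default_role="biological")
    taxonomy = read_taxonomy(ROOT / "simulated" / "taxonomy.tsv")

    alpha = diversity.alpha_diversity(table)
    alpha.to_csv(ROOT / "alpha_diversity.tsv", sep="\t")
    ages = pd.Series([s.split("_")[-1] for s in alpha.index], index=alpha.index)
    means = alpha.groupby(ages).mean()
    print("alpha diversity by age:")
    print(means.round(3).to_string())
    print(f"richness declines D8 -> D15: {means.loc['D8', 'richness']:.1f} -> {means.loc['D15', 'richness']:.1f}")

    jacc = diversity.jaccard_matrix(table)
    pd.DataFrame(jacc.data, index=jacc.ids, columns=jacc.ids).to_csv(ROOT / "jaccard.tsv", sep="\t")

    comp = diversity.aggregate_taxa(qc.relative_abundance(table), taxonomy, "phylum")
    comp.to_csv(ROOT / "phylum_composition.tsv", sep="\t")
    by_age = comp.T.groupby(ages).mean().T
    print("\nmean phylum relative abundance:")
    print(by_age.round(3).to_string())


if __name__ == "__main__":
    main()
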