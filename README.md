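# nestmicro

Post-clustering analysis of cloacal (gut) microbiota in cross-fostered
great tit nestlings: a tested, reusable pipeline covering OTU-table
decontamination, alpha/beta diversity, permutation-based community
statistics, design-specific cross-foster contrasts, and body-condition
modelling — plus a synthetic-study generator with known ground truth so
every analysis runs end to end without any data download.

## The scientific problem

Nestling gut communities are shaped both by what a bird brings from its
natal nest (origin) and by the environment it is reared in.  A
cross-foster experiment separates the two: paired broods exchange half
their nestlings, producing three groups — `control` (unmanipulated
nests), `CFstay` (cross-fostered nests, bird stayed) and `CFmove`
(bird moved to the partner nest).  Each bird is sampled at two ages
(day 8 and day 15 post-hatch), with duplicate PCR replicates, blank tag
combinations (to quantify tag-switching) and negative controls (to
identify reagent contaminants).

The pipeline implements the complete analysis chain for such a design:

1. **QC cascade** (`nestmicro.qc`): merge PCR replicates (mean reads);
   subtract the mean abundance of every OTU seen in blanks; remove
   contaminant OTUs — those with a strictly higher maximum *and* mean
   abundance in negative controls than in biological samples; drop
   singletons and OTUs below 0.005% of total abundance; rarefy each
   sample to 1,000 reads (multivariate hypergeometric).
2. **Diversity** (`nestmicro.diversity`): richness *S*, Shannon
   H' = −Σ pᵢ ln pᵢ, Pielou evenness J' = H'/ln S; presence–absence
   Jaccard dissimilarity d(A,B) = 1 − |A∩B|/|A∪B|; phylum-level
   aggregation; temporal OTU retention |D8 ∩ D15| / |D8|.
3. **Permutation statistics** (`nestmicro.stats`): one-tailed Mantel
   tests; marginal-term PERMANOVA via the McArdle–Anderson partition of
   the Gower-centred inner-product matrix; PCoA retaining
   negative-eigenvalue axes as imaginary coordinates; multivariate
   dispersion (distance to group centroid with Anderson's
   real/imaginary correction); Welch's t with Benjamini–Hochberg
   q-values; standardized major axis (SMA, type-2) regression.  All
   permutation p-values use p = (#{stat* ≥ stat} + 1)/(B + 1).
4. **Cross-foster analyses** (`nestmicro.crossfoster`): intra-individual
   D8→D15 community change; foster- vs separated-true-sibling
   convergence; per-treatment Mantel D8~D15 correlations; scaled mass
   index SMI = mass × (L₀/tarsus)^b with b = 1.87 and L₀ = 19.3 mm;
   Gaussian random-intercept models (REML) for bird/nest structure.
5. **Synthetic studies** (`nestmicro.simulate`): Dirichlet-multinomial
   nest communities, cross-foster moves, an age-driven community shift
   (Firmicutes up, Proteobacteria down, diversity down), planted
   contaminants, mistag reads in blanks, and mass/tarsus allometry with
   a tunable coupling between diversity retention and weight gain.

## Worked example

Run the numbered drivers in `analysis/` (or `pipeline run --config ...`
for the one-shot equivalent).  On the default synthetic study
(26 nests / 156 nestlings, seed 1) they print:

```
$ python analysis/03_diversity.py
alpha diversity by age:
     richness  shannon  evenness
D15    29.545    2.295     0.682
D8     51.141    3.222     0.820
richness declines D8 -> D15: 51.1 -> 29.5

$ python analysis/04_community_structure.py
PERMANOVA nest identity at D8: pseudo-F = 7.07, R2 = 0.58, p = 0.001
...
Mantel D8~D15 by treatment (expected ordering control > CFstay > CFmove):
   control: r = 0.965, p = 0.001
    CFstay: r = 0.864, p = 0.001
    CFmove: r = 0.657, p = 0.001

$ python analysis/05_crossfoster_effects.py
intra-individual D8->D15 Jaccard distance (higher = more change):
    CFmove: 0.721
    CFstay: 0.545
   control: 0.556
...
sibling contrast at D15: foster 0.365 vs separated true 0.528 (one-sided convergence p = 0.0000)
```

Read: nestmates share communities (PERMANOVA on nest identity);
moved birds change most between ages; the D8~D15 correlation degrades
from control through CFstay to CFmove; and foster siblings end up more
similar than separated true siblings — the rearing environment, not
origin, dominates the day-15 community.  `analysis/06_condition.py`
adds the condition side: birds whose communities changed more gained
less mass, with four non-gaining birds excluded from the gain models.

A small pre-generated study ships under `fixtures/` (regenerable with
`nestmicro.simulate.write_fixture`); the full-size study is written by
`analysis/01_simulate_study.py`.

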