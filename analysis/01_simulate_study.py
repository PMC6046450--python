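#!/usr/bin/env python
"""Generate the synthetic cross-foster study used by the downstream analyses.

26 nests of 6 nestlings (9 cross-fostered pairs, 8 controls), sampled
at D8 and D15 with duplicate PCR replicates, plus blank tag
combinations and negative controls.  Writes the raw per-replicate OTU
table, design metadata, taxonomy and simulation truth under
results/simulated/.
"""

from pathlib import Path

from nestmicro.simulate import SimParams, write_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 1


def main() -> None:
    params = SimParams(seed=SEED)
    manifest = write_fixture(OUT, params)
    n_birds = params.n_nests * params.nestlings_per_nest
    print(f"simulated {params.n_nests} nests / {n_birds} nestlings, seed {SEED}")
    print(f"planted {params.n_contaminants} contaminant OTUs among {params.n_otus} community OTUs")
    for name in manifest:
        print(f"  wrote {OUT / name}")


if __name__ == "__main__":
    main()
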