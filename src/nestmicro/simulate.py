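"""Synthetic cross-foster study generator with known ground truth.

Emulates the statistical structure the downstream analyses assume: a
population of nests each hosting six nestlings, sampled at two ages
(D8 and D15); paired cross-fostered nests exchanging three nestlings;
nest-structured Dirichlet-multinomial OTU counts with duplicate PCR
replicates; a D8 -> D15 community shift (Firmicutes up, Proteobacteria
down, overall diversity down); reagent contaminants concentrated in
negative controls; low-level mistag reads in blank tag combinations;
and mass/tarsus allometry on the standardized-major-axis log-log scale
with a tunable coupling between diversity retention and weight gain.

All randomness flows from ``SimParams.seed`` through one generator in a
fixed order: community structure first, then counts in sample order,
then controls, then morphometrics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import OtuTable, write_metadata, write_otu_table, write_taxonomy

PHYLUM_CLASSES = {
    "Firmicutes": "Bacilli",
    "Actinobacteria": "Actinomycetia",
    "Proteobacteria": "Gammaproteobacteria",
    "Bacteroidetes": "Bacteroidia",
    "Tenericutes": "Mollicutes",
}
CONTAMINANT_PHYLA = ("Proteobacteria", "Actinobacteria")


@dataclass
class SimParams:
    """Generator settings; the defaults are the study conditions.

    26 nests of 6 nestlings (9 cross-fostered pairs + 8 controls), two
    ages per bird, duplicate PCR replicates, ~10,000 reads per
    replicate.  ``convergence`` is the weight of the rearing-nest
    environment in the D15 community; ``diversity_drop`` drives the
    D8 -> D15 richness decline; ``condition_coupling`` links a bird's
    latent diversity retention to its weight gain.
    """

    n_nests: int = 26
    n_cf_pairs: int = 9
    nestlings_per_nest: int = 6
    n_otus: int = 600
    n_contaminants: int = 50
    phyla_d8: dict[str, float] = field(
        default_factory=lambda: {
            "Firmicutes": 0.30,
            "Actinobacteria": 0.30,
            "Proteobacteria": 0.25,
            "Bacteroidetes": 0.10,
            "Tenericutes": 0.05,
        }
    )
    firmicutes_up: float = 2.0
    proteobacteria_down: float = 0.35
    diversity_drop: float = 0.4
    convergence: float = 0.85  # lambda: weight of rearing-nest environment at D15
    nest_concentration: float = 20.0  # Dirichlet concentration of nest profiles
    bird_concentration: float = 300.0  # Dirichlet concentration of birds around nests
    nest_env_weight: float = 0.6  # nest-site share of the D15 environment (vs occupants)
    sequencing_depth: int = 10000
    blank_rate: float = 200.0  # expected mistag reads per blank
    n_blanks: int = 8
    n_negative_controls: int = 4
    negative_control_depth: int = 3000
    bio_contaminant_trace: float = 5.0  # expected contaminant reads per biological replicate
    negative_real_trace: float = 2.0  # expected real-community reads per negative control
    sma_slope: float = 1.87
    mean_tarsus: float = 19.3  # mm
    size_sd: float = 0.04  # sd of latent log body size
    tarsus_noise_sd: float = 0.008  # measurement error, log tarsus
    mass_noise_sd: float = 0.012  # residual sd, log D15 mass
    condition_coupling: float = 0.04  # gamma: retention effect on log D15 mass
    mean_mass_d15: float = 18.0  # g
    mean_mass_d8: float = 12.0  # g
    negative_gain_fraction: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.n_cf_pairs > self.n_nests:
            raise ValueError("n_cf_pairs * 2 cannot exceed n_nests")
        if self.nestlings_per_nest % 2:
            raise ValueError("cross-fostering swaps half a brood: even brood size required")
        if not 0 <= self.convergence <= 1:
            raise ValueError("convergence must be in [0, 1]")
        if not 0 <= self.diversity_drop < 1:
            raise ValueError("diversity_drop must be in [0, 1)")
        total = sum(self.phyla_d8.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("phyla_d8 proportions must sum to 1")


@dataclass
class SimulationTruth:
    params: SimParams
    contaminant_otus: list[str]
    treatment: pd.Series  # bird_id -> control / CFstay / CFmove
    retention: pd.Series  # bird_id -> latent diversity-retention quality in (0,1)
    nest_profiles_d8: pd.DataFrame  # otu x nest
    nest_targets_d15: pd.DataFrame  # otu x nest
    bird_profiles_d8: pd.DataFrame  # otu x bird
    bird_profiles_d15: pd.DataFrame  # otu x bird


def _tail_downweight(profile: np.ndarray, drop: float, steepness: float = 3.0) -> np.ndarray:
    """Geometrically down-weight the rare tail of a composition.

    OTUs are ranked by abundance and scaled by
    (1 - drop)^(steepness * rank / effective_richness), where effective
    richness is the Hill number exp(H').  Common OTUs are nearly
    untouched while the rare tail is suppressed continuously, so
    detected richness falls without deleting OTUs outright.
    """
    if drop <= 0:
        return profile
    out = profile.astype(float).copy()
    nz = np.flatnonzero(out)
    p = out[nz] / out[nz].sum()
    n_eff = float(np.exp(-(p * np.log(p)).sum()))
    order = nz[np.argsort(out[nz])[::-1]]
    out[order] *= (1.0 - drop) ** (steepness * np.arange(len(order)) / max(n_eff, 1.0))
    return out / out.sum()


def _reweight_phyla(profile: np.ndarray, phylum_of: np.ndarray, params: SimParams) -> np.ndarray:
    factors = np.ones_like(profile)
    factors[phylum_of == "Firmicutes"] = params.firmicutes_up
    factors[phylum_of == "Proteobacteria"] = params.proteobacteria_down
    out = profile * factors
    return out / out.sum()


def generate_morphometrics(
    n: int,
    params: SimParams,
    rng: np.random.Generator,
    retention: np.ndarray | None = None,
    mass_noise_sd: float | None = None,
) -> pd.DataFrame:
    """Tarsus and D8/D15 mass for ``n`` birds.

    A latent log body size drives both tarsus and mass; tarsus and mass
    each carry their own measurement/residual noise, so the SMA slope
    (which assumes error in both axes) is the natural estimand.
    """
    noise_y = params.mass_noise_sd if mass_noise_sd is None else mass_noise_sd
    size = rng.normal(0.0, 1.0, n)
    log_tarsus_true = np.log(params.mean_tarsus) + params.size_sd * size
    tarsus = np.exp(log_tarsus_true + rng.normal(0.0, params.tarsus_noise_sd, n))
    if retention is None:
        retention = rng.beta(2.0, 2.0, n)
    a15 = np.log(params.mean_mass_d15) - params.sma_slope * np.log(params.mean_tarsus)
    log_mass15 = (
        a15
        + params.sma_slope * log_tarsus_true
        + params.condition_coupling * (retention - 0.5)
        + rng.normal(0.0, noise_y, n)
    )
    a8 = np.log(params.mean_mass_d8) - params.sma_slope * np.log(params.mean_tarsus)
    log_mass8 = a8 + params.sma_slope * log_tarsus_true + rng.normal(0.0, 0.03, n)
    mass15 = np.exp(log_mass15)
    mass8 = np.exp(log_mass8)
    n_negative = int(round(params.negative_gain_fraction * n))
    if n_negative:
        losers = rng.choice(n, size=n_negative, replace=False)
        mass8[losers] = mass15[losers] + np.abs(rng.normal(0.0, 0.4, n_negative))
    return pd.DataFrame(
        {"tarsus_mm": tarsus, "mass_d15_g": mass15, "mass_d8_g": mass8, "retention": retention}
    )


def generate_dataset(params: SimParams) -> tuple[OtuTable, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate one complete synthetic study.

    Returns the per-replicate OTU table (biological replicates, blanks,
    negative controls), the design metadata, the taxonomy, and the
    ground truth needed by recovery tests.
    """
    rng = np.random.default_rng(params.seed)
    phyla = list(params.phyla_d8)
    real_otus = [f"OTU_{i + 1:04d}" for i in range(params.n_otus)]
    contam_otus = [f"CONTAM_{i + 1:03d}" for i in range(params.n_contaminants)]
    all_otus = real_otus + contam_otus

    # community pool: OTUs partitioned into phyla; per-phylum lognormal weights
    phylum_of_real = rng.choice(phyla, size=params.n_otus, p=list(params.phyla_d8.values()))
    weights = rng.lognormal(0.0, 1.2, params.n_otus)
    pool = np.zeros(params.n_otus)
    for ph, prop in params.phyla_d8.items():
        mask = phylum_of_real == ph
        if mask.any():
            pool[mask] = prop * weights[mask] / weights[mask].sum()
    pool /= pool.sum()

    # nests, birds, cross-foster moves (3 of 6 nestlings swapped per pair)
    nests = [f"N{i + 1:02d}" for i in range(params.n_nests)]
    cf_nests = nests[: 2 * params.n_cf_pairs]
    half = params.nestlings_per_nest // 2
    birds, origin, rearing, treatment = [], {}, {}, {}
    for n_idx, nest in enumerate(nests):
        is_cf = nest in cf_nests
        partner = cf_nests[n_idx + 1] if is_cf and n_idx % 2 == 0 else (
            cf_nests[n_idx - 1] if is_cf else None
        )
        for k in range(params.nestlings_per_nest):
            bird = f"B{nest}_{k + 1}"
            birds.append(bird)
            origin[bird] = nest
            moved = is_cf and k < half
            rearing[bird] = partner if moved else nest
            treatment[bird] = "CFmove" if moved else ("CFstay" if is_cf else "control")
    treatment_s = pd.Series(treatment, name="treatment")

    # nest D8 profiles and bird D8 latent profiles
    nest_profiles = {}
    for nest in nests:
        alpha = np.maximum(params.nest_concentration * pool, 1e-9)
        nest_profiles[nest] = rng.dirichlet(alpha)
    bird_d8 = {}
    for bird in birds:
        alpha = params.bird_concentration * nest_profiles[origin[bird]] + 1e-9
        bird_d8[bird] = rng.dirichlet(alpha)

    # D15 environment per nest: nest site + current occupants' D8 communities
    occupants = {nest: [b for b in birds if rearing[b] == nest] for nest in nests}
    nest_targets = {}
    for nest in nests:
        occ = np.mean([bird_d8[b] for b in occupants[nest]], axis=0)
        env = params.nest_env_weight * nest_profiles[nest] + (1 - params.nest_env_weight) * occ
        target = _reweight_phyla(env / env.sum(), phylum_of_real, params)
        nest_targets[nest] = _tail_downweight(target, params.diversity_drop)

    retention = pd.Series(rng.beta(2.0, 2.0, len(birds)), index=birds, name="retention")
    bird_d15 = {}
    for bird in birds:
        lam = params.convergence
        mix = lam * nest_targets[rearing[bird]] + (1 - lam) * bird_d8[bird]
        # per-bird drop centred on diversity_drop, modulated by retention quality
        bird_drop = min(params.diversity_drop * (1.5 - retention[bird]), 0.95)
        bird_d15[bird] = _tail_downweight(mix / mix.sum(), bird_drop)

    # contaminant community (reagent profile, shared across control samples)
    contam_weights = rng.lognormal(0.0, 1.0, params.n_contaminants)
    contam_profile = contam_weights / contam_weights.sum()

    # counts: biological replicates in bird/age/replicate order
    n_total_otus = params.n_otus + params.n_contaminants
    columns: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    meta_rows: list[dict] = []
    morph = generate_morphometrics(len(birds), params, rng, retention=retention.to_numpy())
    morph.index = birds

    def biological_column(profile: np.ndarray) -> np.ndarray:
        depth = rng.poisson(params.sequencing_depth)
        real = rng.multinomial(depth, profile)
        trace = rng.poisson(params.bio_contaminant_trace * contam_profile)
        return np.concatenate([real, trace])

    for bird in birds:
        for age, profile in (("D8", bird_d8[bird]), ("D15", bird_d15[bird])):
            for rep in ("r1", "r2"):
                sid = f"{bird}_{age}_{rep}"
                columns[sid] = biological_column(profile)
                roles[sid] = "biological"
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "bird_id": bird,
                        "nest_of_origin": origin[bird],
                        "nest_of_rearing": origin[bird] if age == "D8" else rearing[bird],
                        "age_class": age,
                        "nest_treatment": "control" if treatment[bird] == "control" else "crossfostered",
                        "body_mass_g": round(morph.loc[bird, "mass_d8_g" if age == "D8" else "mass_d15_g"], 2),
                        "tarsus_mm": round(morph.loc[bird, "tarsus_mm"], 2) if age == "D15" else "",
                        "replicate_id": rep,
                        "sample_role": "biological",
                    }
                )

    pooled_bio = np.mean(list(bird_d8.values()) + list(bird_d15.values()), axis=0)
    for i in range(params.n_blanks):
        sid = f"BLANK_{i + 1:02d}"
        total = rng.poisson(params.blank_rate)
        mistags = rng.multinomial(total, pooled_bio) if total > 0 else np.zeros(params.n_otus, int)
        columns[sid] = np.concatenate([mistags, np.zeros(params.n_contaminants, int)])
        roles[sid] = "blank"
        meta_rows.append(_control_row(sid, "blank"))
    for i in range(params.n_negative_controls):
        sid = f"NEG_{i + 1:02d}"
        contam = rng.multinomial(params.negative_control_depth, contam_profile)
        cross = rng.poisson(params.negative_real_trace * pooled_bio)
        columns[sid] = np.concatenate([cross, contam])
        roles[sid] = "negative_control"
        meta_rows.append(_control_row(sid, "negative_control"))

    counts = pd.DataFrame(columns, index=all_otus, dtype=float)
    table = OtuTable(counts, pd.Series(roles))
    meta = pd.DataFrame(meta_rows)

    # taxonomy: real OTUs from their phylum, contaminants from reagent phyla
    tax_rows = []
    for otu, ph in zip(real_otus, phylum_of_real):
        tax_rows.append({"otu_id": otu, "lineage": _lineage(ph, otu)})
    for i, otu in enumerate(contam_otus):
        ph = CONTAMINANT_PHYLA[i % len(CONTAMINANT_PHYLA)]
        tax_rows.append({"otu_id": otu, "lineage": _lineage(ph, otu)})
    taxonomy = pd.DataFrame(tax_rows)

    truth = SimulationTruth(
        params=params,
        contaminant_otus=list(contam_otus),
        treatment=treatment_s,
        retention=retention,
        nest_profiles_d8=pd.DataFrame(nest_profiles, index=real_otus),
        nest_targets_d15=pd.DataFrame(nest_targets, index=real_otus),
        bird_profiles_d8=pd.DataFrame(bird_d8, index=real_otus),
        bird_profiles_d15=pd.DataFrame(bird_d15, index=real_otus),
    )
    return table, meta, taxonomy, truth


def _control_row(sid: str, role: str) -> dict:
    return {
        "sample_id": sid,
        "bird_id": "",
        "nest_of_origin": "",
        "nest_of_rearing": "",
        "age_class": "",
        "nest_treatment": "",
        "body_mass_g": "",
        "tarsus_mm": "",
        "replicate_id": "r1",
        "sample_role": role,
    }


def _lineage(phylum: str, otu: str) -> str:
    cls = PHYLUM_CLASSES.get(phylum, "")
    return f"Bacteria;{phylum};{cls};;;{phylum[:4]}_{otu.split('_')[-1]}"


#: scaled-down settings for the repository fixture (kept small so the
#: shipped TSVs stay diffable); same structure as the defaults.
FIXTURE_PARAMS = SimParams(
    n_nests=4,
    n_cf_pairs=1,
    n_otus=100,
    n_contaminants=12,
    sequencing_depth=3000,
    negative_control_depth=1500,
    n_blanks=4,
    n_negative_controls=3,
    blank_rate=80.0,
    seed=1,
)


def write_fixture(out_dir: str | Path, params: SimParams) -> list[str]:
    """Write a complete synthetic study to ``out_dir``; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, meta, taxonomy, truth = generate_dataset(params)
    write_otu_table(table, out / "otu_table.tsv")
    write_metadata(meta, out / "metadata.tsv")
    write_taxonomy(taxonomy, out / "taxonomy.tsv")
    (out / "truth.json").write_text(
        json.dumps(
            {
                "contaminant_otus": truth.contaminant_otus,
                "treatment": truth.treatment.to_dict(),
                "retention": truth.retention.round(6).to_dict(),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    (out / "params.json").write_text(json.dumps(asdict(params), indent=2, sort_keys=True) + "\n")
    return sorted(p.name for p in out.iterdir())
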