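"""Design-specific analyses for the cross-foster experiment.

Ties the generic machinery (QC cascade, diversity, permutation
statistics, mixed models) to the experimental design: treatment labels
(control / CFstay / CFmove), intra-individual community change between
ages, foster- vs separated-true-sibling convergence, per-treatment
Mantel correlations, scaled-mass-index condition, and the end-to-end
``run_pipeline`` driver producing one JSON-able report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from . import diversity, qc, simulate, stats
from .io import OtuTable, read_metadata, read_otu_table, read_taxonomy, write_results
from .models import ModelFit, fit_random_intercept_model

TREATMENT_LABELS = ("control", "CFstay", "CFmove")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, report_so_far: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report_so_far = report_so_far


def merged_sample_id(bird_id: str, age_class: str) -> str:
    """Column name of a merged biological sample (see qc.merge_replicates)."""
    return f"{bird_id}_{age_class}"


def bird_table(meta: pd.DataFrame) -> pd.DataFrame:
    """One row per bird: nests, treatment, morphometrics at both ages."""
    bio = meta[meta["sample_role"] == "biological"]
    rows = []
    for bird, grp in bio.groupby("bird_id"):
        origin = grp["nest_of_origin"].unique()
        if len(origin) != 1:
            raise ValueError(f"bird {bird!r} has inconsistent nest_of_origin: {list(origin)}")
        d8 = grp[grp["age_class"] == "D8"]
        d15 = grp[grp["age_class"] == "D15"]
        rearing = d15["nest_of_rearing"].unique() if len(d15) else d8["nest_of_rearing"].unique()
        if len(rearing) != 1:
            raise ValueError(f"bird {bird!r} has inconsistent nest_of_rearing: {list(rearing)}")
        rows.append(
            {
                "bird_id": bird,
                "nest_of_origin": origin[0],
                "nest_of_rearing": rearing[0],
                "nest_treatment": grp["nest_treatment"].iloc[0],
                "mass_d8_g": d8["body_mass_g"].dropna().iloc[0] if d8["body_mass_g"].notna().any() else np.nan,
                "mass_d15_g": d15["body_mass_g"].dropna().iloc[0] if len(d15) and d15["body_mass_g"].notna().any() else np.nan,
                "tarsus_mm": d15["tarsus_mm"].dropna().iloc[0] if len(d15) and d15["tarsus_mm"].notna().any() else np.nan,
                "has_both_ages": bool(len(d8) and len(d15)),
            }
        )
    return pd.DataFrame(rows).set_index("bird_id")


def assign_treatment(meta: pd.DataFrame) -> pd.Series:
    """Per-bird treatment label: control, CFstay, or CFmove.

    CFmove iff the D15 rearing nest differs from the origin nest; birds
    of control nests must not have moved.
    """
    birds = bird_table(meta)
    moved = birds["nest_of_rearing"] != birds["nest_of_origin"]
    in_control = birds["nest_treatment"] == "control"
    if (moved & in_control).any():
        bad = birds.index[moved & in_control].tolist()
        raise ValueError(f"control-nest birds recorded as moved: {bad}")
    labels = pd.Series(
        np.where(in_control, "control", np.where(moved, "CFmove", "CFstay")),
        index=birds.index,
        name="treatment",
    )
    return labels


def intra_individual_change(jacc: DistanceMatrix, meta: pd.DataFrame) -> pd.Series:
    """Jaccard distance between each bird's D8 and D15 samples.

    ``jacc`` must cover merged samples of both ages; birds missing one
    age are silently excluded.
    """
    birds = bird_table(meta)
    ids = set(jacc.ids)
    out = {}
    for bird in birds.index:
        s8, s15 = merged_sample_id(bird, "D8"), merged_sample_id(bird, "D15")
        if s8 in ids and s15 in ids:
            out[bird] = float(jacc[s8, s15])
    return pd.Series(out, name="intra_individual_jaccard")


def per_age_bird_matrix(jacc: DistanceMatrix, meta: pd.DataFrame, age: str) -> DistanceMatrix:
    """Restrict a merged-sample Jaccard matrix to one age, relabelled by bird."""
    birds = bird_table(meta)
    pairs = [(b, merged_sample_id(b, age)) for b in birds.index]
    pairs = [(b, s) for b, s in pairs if s in set(jacc.ids)]
    sub = jacc.filter([s for _, s in pairs])
    return DistanceMatrix(sub.data, ids=[b for b, _ in pairs])


def retention_by_bird(merged: OtuTable, meta: pd.DataFrame) -> pd.Series:
    """Proportion of each bird's D8 OTUs still present at D15."""
    birds = bird_table(meta)
    ids = set(merged.sample_ids)
    out = {}
    for bird in birds.index:
        s8, s15 = merged_sample_id(bird, "D8"), merged_sample_id(bird, "D15")
        if s8 in ids and s15 in ids:
            out[bird] = diversity.otu_retention(merged.counts[s8], merged.counts[s15])
    return pd.Series(out, name="otu_retention")


@dataclass
class SiblingContrast:
    pair_distances: pd.DataFrame  # bird_a, bird_b, pair_type, nest, distance
    nest_means: pd.DataFrame  # mean distance per (nest, pair_type)
    mean_foster: float
    mean_separated: float
    model: ModelFit
    p_two_sided: float
    p_convergence: float  # one-sided: foster siblings closer than separated true siblings

    def to_dict(self) -> dict:
        return {
            "mean_foster_sibling_distance": self.mean_foster,
            "mean_separated_true_sibling_distance": self.mean_separated,
            "p_two_sided": self.p_two_sided,
            "p_convergence": self.p_convergence,
            "n_pairs": len(self.pair_distances),
            "model": self.model.to_dict(),
        }


def sibling_similarity_contrast(jacc_d15: DistanceMatrix, meta: pd.DataFrame) -> SiblingContrast:
    """Foster-sibling vs separated-true-sibling D15 dissimilarity.

    Foster siblings share the rearing nest but not the origin nest;
    separated true siblings share the origin nest but not the rearing
    nest.  Only cross-fostered nests qualify.  The contrast is tested
    with a random-intercept model grouped by the shared nest; the
    one-sided ``p_convergence`` targets the directional hypothesis that
    shared rearing draws communities together (foster < separated).
    """
    birds = bird_table(meta)
    cf = birds[birds["nest_treatment"] == "crossfostered"]
    ids = set(jacc_d15.ids)
    cf = cf[cf.index.isin(ids)]
    rows = []
    bird_list = list(cf.index)
    for i, a in enumerate(bird_list):
        for b in bird_list[i + 1 :]:
            same_rear = cf.loc[a, "nest_of_rearing"] == cf.loc[b, "nest_of_rearing"]
            same_orig = cf.loc[a, "nest_of_origin"] == cf.loc[b, "nest_of_origin"]
            if same_rear and not same_orig:
                rows.append((a, b, "foster", cf.loc[a, "nest_of_rearing"]))
            elif same_orig and not same_rear:
                rows.append((a, b, "separated_true", cf.loc[a, "nest_of_origin"]))
    if not rows:
        raise ValueError("no qualifying sibling pairs in cross-fostered nests")
    pair_df = pd.DataFrame(rows, columns=["bird_a", "bird_b", "pair_type", "nest"])
    pair_df["distance"] = [float(jacc_d15[a, b]) for a, b in zip(pair_df["bird_a"], pair_df["bird_b"])]
    nest_means = pair_df.groupby(["nest", "pair_type"])["distance"].mean().reset_index()
    mean_f = float(pair_df.loc[pair_df["pair_type"] == "foster", "distance"].mean())
    mean_s = float(pair_df.loc[pair_df["pair_type"] == "separated_true", "distance"].mean())
    fit = fit_random_intercept_model(pair_df, "distance", ["pair_type"], ["nest"])
    # patsy codes pair_type with 'foster' as baseline: coefficient = separated - foster
    coef_name = [c for c in fit.params.index if "pair_type" in c][0]
    t = float(fit.tvalues[coef_name])
    p2 = float(fit.pvalues[coef_name])
    p_convergence = p2 / 2 if t > 0 else 1 - p2 / 2
    return SiblingContrast(pair_df, nest_means, mean_f, mean_s, fit, p2, p_convergence)


def mantel_by_treatment(
    jacc_d8_birds: DistanceMatrix,
    jacc_d15_birds: DistanceMatrix,
    labels: pd.Series,
    n_perm: int = stats.DEFAULT_PERMUTATIONS,
    seed: int = 0,
    min_group: int = 4,
) -> dict[str, stats.PermTestResult]:
    """Mantel D8~D15 correlation within each treatment group.

    Both matrices must be labelled by bird.  Groups smaller than
    ``min_group`` are skipped.
    """
    common = [b for b in jacc_d8_birds.ids if b in set(jacc_d15_birds.ids)]
    results: dict[str, stats.PermTestResult] = {}
    for g_idx, group in enumerate(TREATMENT_LABELS):
        members = [b for b in common if labels.get(b) == group]
        if len(members) < min_group:
            continue
        d8 = jacc_d8_birds.filter(members)
        d15 = jacc_d15_birds.filter(members)
        results[group] = stats.mantel(d8, d15, n_perm=n_perm, seed=seed + g_idx)
    return results


def compute_condition(
    meta: pd.DataFrame,
    slope: float = 1.87,
    reference_tarsus: float = 19.3,
    estimate_smi_params: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Scaled mass index and weight gain per bird.

    SMI = D15 mass x (L0 / tarsus)^b standardises mass to the reference
    tarsus length L0; the default exponent and reference are the
    allometric constants for this population.  When
    ``estimate_smi_params`` is set, b is re-estimated by SMA regression
    of log mass on log tarsus and L0 by the mean tarsus.  Birds that did
    not gain mass are flagged out of the gain analyses.
    """
    birds = bird_table(meta)
    used = {"slope": slope, "reference_tarsus": reference_tarsus, "estimated_from_data": False}
    if estimate_smi_params:
        ok = birds.dropna(subset=["mass_d15_g", "tarsus_mm"])
        slope, _, _ = stats.sma_slope(np.log(ok["tarsus_mm"]), np.log(ok["mass_d15_g"]))
        reference_tarsus = float(ok["tarsus_mm"].mean())
        used = {"slope": slope, "reference_tarsus": reference_tarsus, "estimated_from_data": True}
    out = birds[["nest_of_origin", "nest_of_rearing", "nest_treatment"]].copy()
    out["smi_g"] = birds["mass_d15_g"] * (reference_tarsus / birds["tarsus_mm"]) ** slope
    out["weight_gain_g"] = birds["mass_d15_g"] - birds["mass_d8_g"]
    out["included_in_gain_models"] = out["weight_gain_g"] > 0
    return out, used


# -- end-to-end driver ---------------------------------------------------------


def _load_inputs(config: dict):
    io_cfg = config.get("io", {})
    if "synthetic" in io_cfg:
        sim_cfg = dict(io_cfg["synthetic"] or {})
        sim_cfg.setdefault("seed", config.get("seed", 0))
        params = simulate.SimParams(**sim_cfg)
        table, meta, taxonomy, _ = simulate.generate_dataset(params)
        return table, meta, taxonomy
    meta = read_metadata(io_cfg["metadata"])
    table = read_otu_table(io_cfg["otu_table"], metadata=meta)
    taxonomy = read_taxonomy(io_cfg["taxonomy"]) if io_cfg.get("taxonomy") else None
    return table, meta, taxonomy


def run_pipeline(config: dict, out_dir: str | None = None) -> dict:
    """Run the full analysis and return the report (9 analysis blocks).

    ``config`` mirrors the YAML layout: sections ``io`` (file paths or a
    ``synthetic`` sub-section), ``filter``, ``stats``, ``condition``,
    and a global ``seed``.  Each block in the report records its inputs,
    parameters, estimates, p-values and sample sizes.  Fully
    deterministic for a fixed config.
    """
    seed = int(config.get("seed", 0))
    n_perm = int(config.get("stats", {}).get("n_permutations", stats.DEFAULT_PERMUTATIONS))
    report: dict = {"seed": seed}
    stage = "load_inputs"
    try:
        table, meta, taxonomy = _load_inputs(config)

        stage = "qc"
        fp_cfg = dict(config.get("filter", {}))
        fp_cfg.setdefault("seed", seed)
        params = qc.FilterParams(**fp_cfg)
        rarefied, audit = qc.run_qc(table, meta, params)
        report["qc"] = audit.to_dict()

        stage = "diversity"
        alpha = diversity.alpha_diversity(rarefied)
        bio = meta[meta["sample_role"] == "biological"].drop_duplicates(subset=["bird_id", "age_class"])
        frame = bio.set_index(bio["bird_id"] + "_" + bio["age_class"]).join(alpha, how="inner")
        frame["log_richness"] = np.log(frame["richness"].where(frame["richness"] > 0))
        alpha_models = {}
        for response in ("log_richness", "shannon", "evenness"):
            alpha_models[response] = fit_random_intercept_model(
                frame,
                response,
                ["age_class", "nest_treatment"],
                ["bird_id", "nest_of_rearing"],
                backward=True,
            ).to_dict()
        by_age = alpha.join(frame[["age_class"]]).groupby("age_class")[["richness", "shannon", "evenness"]].mean()
        report["diversity"] = {
            "per_age_means": by_age.to_dict(),
            "models": alpha_models,
            "n_samples": int(len(alpha)),
        }

        stage = "beta_diversity"
        jacc = diversity.jaccard_matrix(rarefied)
        labels = assign_treatment(meta)
        d8_birds = per_age_bird_matrix(jacc, meta, "D8")
        d15_birds = per_age_bird_matrix(jacc, meta, "D15")
        birds = bird_table(meta)

        stage = "permanova_nest"
        perma = {}
        design_all = birds.loc[list(d8_birds.ids), ["nest_of_rearing"]].rename(
            columns={"nest_of_rearing": "nest"}
        )
        perma["D8_all_nests"] = stats.permanova(
            d8_birds, design_all, ["nest"], n_perm=n_perm, seed=seed
        ).reset_index().to_dict("records")
        for grp, key in (("control", "D15_control_nests"), ("crossfostered", "D15_crossfostered_nests")):
            keep = [b for b in d15_birds.ids if birds.loc[b, "nest_treatment"] == grp]
            sub = d15_birds.filter(keep)
            design = birds.loc[keep, ["nest_of_rearing"]].rename(columns={"nest_of_rearing": "nest"})
            perma[key] = stats.permanova(sub, design, ["nest"], n_perm=n_perm, seed=seed).reset_index().to_dict("records")
        report["permanova_nest"] = perma

        stage = "dispersion"
        disp = {}
        for age, mat in (("D8", d8_birds), ("D15", d15_birds)):
            nest_groups = birds.loc[list(mat.ids), "nest_of_rearing"]
            dists, test = stats.dispersion_to_centroid(mat, nest_groups, n_perm=n_perm, seed=seed)
            disp[age] = {"mean_distance_to_nest_centroid": float(dists.mean()), "test": test.to_dict()}
        report["dispersion"] = disp

        stage = "intra_individual"
        change = intra_individual_change(jacc, meta)
        idf = pd.DataFrame({"distance": change, "treatment": labels, "moved": (labels == "CFmove").astype(float)})
        idf["nest"] = birds.loc[idf.index, "nest_of_rearing"]
        change_fit = fit_random_intercept_model(idf.dropna(), "distance", ["moved"], ["nest"])
        retention = retention_by_bird(rarefied, meta)
        rdf = pd.DataFrame({"retention": retention, "treatment": labels}).dropna()
        rdf["nest"] = birds.loc[rdf.index, "nest_of_rearing"]
        cf_only = rdf[rdf["treatment"].isin(["CFstay", "CFmove"])]
        retention_fit = fit_random_intercept_model(cf_only, "retention", ["treatment"], ["nest"])
        report["intra_individual"] = {
            "mean_change_by_treatment": idf.groupby("treatment")["distance"].mean().to_dict(),
            "change_model": change_fit.to_dict(),
            "mean_retention_by_treatment": rdf.groupby("treatment")["retention"].mean().to_dict(),
            "retention_model_cf_only": retention_fit.to_dict(),
            "n_birds": int(change.notna().sum()),
        }

        stage = "sibling_contrast"
        contrast = sibling_similarity_contrast(d15_birds, meta)
        report["sibling_contrast"] = contrast.to_dict()

        stage = "mantel_by_treatment"
        mantels = mantel_by_treatment(d8_birds, d15_birds, labels, n_perm=n_perm, seed=seed)
        report["mantel_by_treatment"] = {g: r.to_dict() for g, r in mantels.items()}

        stage = "phylum_shift"
        if taxonomy is not None:
            comp = diversity.aggregate_taxa(qc.relative_abundance(rarefied), taxonomy, "phylum")
            ph_models = {}
            means = {}
            for phylum in ("Firmicutes", "Proteobacteria"):
                if phylum not in comp.index:
                    continue
                pf = frame[["age_class", "bird_id", "nest_of_rearing"]].join(
                    comp.loc[phylum].rename("abundance"), how="inner"
                )
                ph_models[phylum] = fit_random_intercept_model(
                    pf, "abundance", ["age_class"], ["bird_id", "nest_of_rearing"]
                ).to_dict()
                means[phylum] = pf.groupby("age_class")["abundance"].mean().to_dict()
            report["phylum_shift"] = {"models": ph_models, "per_age_mean_abundance": means}
        else:
            report["phylum_shift"] = {"skipped": "no taxonomy provided"}

        stage = "condition"
        cond_cfg = config.get("condition", {})
        cond, smi_used = compute_condition(
            meta,
            slope=float(cond_cfg.get("sma_slope", 1.87)),
            reference_tarsus=float(cond_cfg.get("reference_tarsus", 19.3)),
            estimate_smi_params=bool(cond_cfg.get("estimate_smi_params", False)),
        )
        a15 = alpha.loc[[i for i in alpha.index if i.endswith("_D15")]].copy()
        a15.index = [i[: -len("_D15")] for i in a15.index]
        a8 = alpha.loc[[i for i in alpha.index if i.endswith("_D8")]].copy()
        a8.index = [i[: -len("_D8")] for i in a8.index]
        cdf = cond.join(a15[["richness", "shannon"]]).join(
            a8[["richness", "shannon"]], rsuffix="_d8"
        )
        cdf["log_richness"] = np.log(cdf["richness"].where(cdf["richness"] > 0))
        cdf["delta_richness"] = cdf["richness"] - cdf["richness_d8"]
        cdf["delta_shannon"] = cdf["shannon"] - cdf["shannon_d8"]
        cdf["intra_distance"] = change
        cdf["nest"] = birds.loc[cdf.index, "nest_of_rearing"]
        gain_df = cdf[cdf["included_in_gain_models"]].dropna(
            subset=["weight_gain_g", "delta_richness", "delta_shannon", "intra_distance"]
        )
        cond_models = {
            "smi_vs_log_richness": fit_random_intercept_model(
                cdf.dropna(subset=["smi_g", "log_richness"]), "smi_g", ["log_richness"], ["nest"]
            ).to_dict(),
            "gain_vs_microbiota": fit_random_intercept_model(
                gain_df,
                "weight_gain_g",
                ["delta_richness", "delta_shannon", "intra_distance"],
                ["nest"],
                backward=True,
            ).to_dict(),
        }
        report["condition"] = {
            "smi_parameters": smi_used,
            "n_excluded_nonpositive_gain": int((~cond["included_in_gain_models"]).sum()),
            "models": cond_models,
        }
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc, report) from exc

    if out_dir is not None:
        write_results({"report": report}, out_dir, seed=seed)
    return report
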