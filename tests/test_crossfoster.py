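import json

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from nestmicro import crossfoster, diversity
from nestmicro.crossfoster import run_pipeline
from nestmicro.io import OtuTable
from nestmicro.simulate import FIXTURE_PARAMS

from conftest import make_metadata


def meta_row(bird, origin, rearing_d15, age, treatment, rep="r1", mass=15.0, tarsus=19.3):
    return {
        "sample_id": f"{bird}_{age}_{rep}",
        "bird_id": bird,
        "nest_of_origin": origin,
        "nest_of_rearing": origin if age == "D8" else rearing_d15,
        "age_class": age,
        "nest_treatment": treatment,
        "body_mass_g": mass,
        "tarsus_mm": tarsus if age == "D15" else np.nan,
        "replicate_id": rep,
        "sample_role": "biological",
    }


def design_meta(spec):
    """spec: list of (bird, origin, rearing_d15, treatment, mass8, mass15, tarsus)."""
    rows = []
    for bird, origin, rearing, trt, m8, m15, tar in spec:
        rows.append(meta_row(bird, origin, rearing, "D8", trt, mass=m8))
        rows.append(meta_row(bird, origin, rearing, "D15", trt, mass=m15, tarsus=tar))
    return pd.DataFrame(rows)


class TestAssignTreatment:
    def test_three_label_partition(self):
        meta = design_meta(
            [
                ("b1", "N1", "N1", "control", 12, 18, 19.3),
                ("b2", "N2", "N3", "crossfostered", 12, 18, 19.3),
                ("b3", "N2", "N2", "crossfostered", 12, 18, 19.3),
            ]
        )
        labels = crossfoster.assign_treatment(meta)
        assert labels["b1"] == "control"
        assert labels["b2"] == "CFmove"
        assert labels["b3"] == "CFstay"

    def test_partition_is_exhaustive_and_disjoint(self, fixture_dataset):
        _, meta, _, truth = fixture_dataset
        labels = crossfoster.assign_treatment(meta)
        assert set(labels.index) == set(truth.treatment.index)
        assert (labels.loc[truth.treatment.index] == truth.treatment).all()

    def test_moved_control_bird_rejected(self):
        meta = design_meta([("b1", "N1", "N2", "control", 12, 18, 19.3)])
        with pytest.raises(ValueError, match="control"):
            crossfoster.assign_treatment(meta)


class TestIntraIndividualChange:
    def make_two_bird_fixture(self):
        # b1: identical communities at both ages; b2: disjoint communities
        counts = pd.DataFrame(
            {
                "b1_D8": [5, 5, 0, 0],
                "b1_D15": [2, 9, 0, 0],
                "b2_D8": [3, 3, 0, 0],
                "b2_D15": [0, 0, 4, 4],
            },
            index=["O1", "O2", "O3", "O4"],
        )
        meta = design_meta(
            [
                ("b1", "N1", "N1", "control", 12, 18, 19.3),
                ("b2", "N1", "N1", "control", 12, 18, 19.3),
            ]
        )
        return counts, meta

    def test_identical_and_disjoint_birds(self):
        counts, meta = self.make_two_bird_fixture()
        jacc = diversity.jaccard_matrix(counts)
        change = crossfoster.intra_individual_change(jacc, meta)
        assert change["b1"] == 0.0
        assert change["b2"] == 1.0

    def test_values_match_direct_jaccard_recomputation(self, fixture_dataset):
        table, meta, _, _ = fixture_dataset
        from nestmicro import qc

        merged = qc.merge_replicates(table, meta)
        jacc = diversity.jaccard_matrix(merged)
        change = crossfoster.intra_individual_change(jacc, meta)
        for bird in list(change.index)[:5]:
            a = merged.counts[f"{bird}_D8"].to_numpy() > 0
            b = merged.counts[f"{bird}_D15"].to_numpy() > 0
            expected = 1 - (a & b).sum() / (a | b).sum()
            assert change[bird] == pytest.approx(expected)

    def test_bird_missing_one_age_excluded(self):
        counts, meta = self.make_two_bird_fixture()
        counts = counts.drop(columns=["b2_D15"])
        jacc = diversity.jaccard_matrix(counts)
        change = crossfoster.intra_individual_change(jacc, meta)
        assert list(change.index) == ["b1"]


class TestSiblingContrast:
    def build_cf_fixture(self, seed=0):
        """Two cross-fostered nest pairs; foster siblings nearly identical,
        separated true siblings nearly disjoint."""
        rng = np.random.default_rng(seed)
        spec = []
        for pair, (na, nb) in enumerate([("N1", "N2"), ("N3", "N4")]):
            for k in range(2):
                spec.append((f"m{na}{k}", na, nb, "crossfostered", 12, 18, 19.3))  # moved
                spec.append((f"s{nb}{k}", nb, nb, "crossfostered", 12, 18, 19.3))  # stayed
                spec.append((f"m{nb}{k}", nb, na, "crossfostered", 12, 18, 19.3))
                spec.append((f"s{na}{k}", na, na, "crossfostered", 12, 18, 19.3))
        meta = design_meta(spec)
        birds = crossfoster.bird_table(meta)
        ids = list(birds.index)
        d = np.zeros((len(ids), len(ids)))
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                b = ids[j]
                same_rear = birds.loc[a, "nest_of_rearing"] == birds.loc[b, "nest_of_rearing"]
                base = 0.05 if same_rear else 0.95
                d[i, j] = d[j, i] = np.clip(base + rng.normal(0, 0.02), 0, 1)
        return DistanceMatrix(d, ids=ids), meta

    def test_extreme_fixture_means(self):
        dm, meta = self.build_cf_fixture()
        res = crossfoster.sibling_similarity_contrast(dm, meta)
        assert res.mean_foster < 0.15
        assert res.mean_separated > 0.85
        assert res.p_convergence < 0.05

    def test_no_qualifying_pairs_rejected(self):
        meta = make_metadata(n_nests=2, nestlings=2)  # control design only
        ids = sorted({f"{b}" for b in meta["bird_id"]})
        dm = DistanceMatrix(1 - np.eye(len(ids)), ids=ids)
        with pytest.raises(ValueError, match="no qualifying"):
            crossfoster.sibling_similarity_contrast(dm, meta)


class TestMantelByTreatment:
    def test_identical_matrices_give_r_one_everywhere(self, fixture_dataset):
        _, meta, _, truth = fixture_dataset
        labels = crossfoster.assign_treatment(meta)
        birds = list(labels.index)
        rng = np.random.default_rng(0)
        pts = rng.random((len(birds), 3))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(pts)), ids=birds)
        res = crossfoster.mantel_by_treatment(dm, dm, labels, n_perm=49, seed=0)
        assert set(res) == {"control", "CFstay", "CFmove"}
        for r in res.values():
            assert r.statistic == pytest.approx(1.0)

    def test_small_groups_skipped(self):
        labels = pd.Series({"a": "control", "b": "control", "c": "CFmove", "d": "control"})
        dm = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
        res = crossfoster.mantel_by_treatment(dm, dm, labels, n_perm=9, seed=0)
        assert "CFmove" not in res


class TestComputeCondition:
    def test_smi_identity_at_reference_tarsus(self):
        meta = design_meta([("b1", "N1", "N1", "control", 12.0, 18.0, 19.3)])
        cond, used = crossfoster.compute_condition(meta)
        assert cond.loc["b1", "smi_g"] == pytest.approx(18.0)
        assert used["slope"] == 1.87

    def test_smi_formula_for_larger_bird(self):
        meta = design_meta([("b1", "N1", "N1", "control", 12.0, 18.0, 20.0)])
        cond, _ = crossfoster.compute_condition(meta)
        # independent evaluation: 18 * (19.3/20)^1.87
        assert cond.loc["b1", "smi_g"] == pytest.approx(18.0 * (19.3 / 20.0) ** 1.87)
        assert cond.loc["b1", "smi_g"] == pytest.approx(16.84, abs=0.005)

    def test_zero_gain_excluded_from_gain_models(self):
        meta = design_meta(
            [
                ("b1", "N1", "N1", "control", 18.0, 18.0, 19.3),
                ("b2", "N1", "N1", "control", 12.0, 18.0, 19.3),
            ]
        )
        cond, _ = crossfoster.compute_condition(meta)
        assert not cond.loc["b1", "included_in_gain_models"]
        assert cond.loc["b2", "included_in_gain_models"]

    def test_missing_tarsus_keeps_bird_for_gain(self):
        meta = design_meta([("b1", "N1", "N1", "control", 12.0, 18.0, np.nan)])
        cond, _ = crossfoster.compute_condition(meta)
        assert np.isnan(cond.loc["b1", "smi_g"])
        assert cond.loc["b1", "included_in_gain_models"]

    def test_estimated_parameters_recover_allometry(self):
        rng = np.random.default_rng(7)
        spec = []
        for i in range(60):
            tarsus = 19.3 * np.exp(rng.normal(0, 0.05))
            mass15 = 18.0 * (tarsus / 19.3) ** 1.87 * np.exp(rng.normal(0, 0.01))
            spec.append((f"b{i}", "N1", "N1", "control", 12.0, mass15, tarsus))
        meta = design_meta(spec)
        _, used = crossfoster.compute_condition(meta, estimate_smi_params=True)
        assert used["estimated_from_data"]
        assert used["slope"] == pytest.approx(1.87, abs=0.15)
        assert used["reference_tarsus"] == pytest.approx(19.3, rel=0.02)


class TestRunPipeline:
    CONFIG = {
        "seed": 11,
        "io": {
            "synthetic": {
                "n_nests": 6,
                "n_cf_pairs": 2,
                "n_otus": 150,
                "n_contaminants": 15,
                "sequencing_depth": 4000,
                "negative_control_depth": 1500,
            }
        },
        "stats": {"n_permutations": 99},
    }

    def test_report_contains_all_nine_analysis_blocks(self):
        report = run_pipeline(self.CONFIG)
        blocks = [
            "qc",
            "diversity",
            "permanova_nest",
            "dispersion",
            "intra_individual",
            "sibling_contrast",
            "mantel_by_treatment",
            "phylum_shift",
            "condition",
        ]
        assert all(b in report for b in blocks)

    def test_same_seed_reproduces_identical_report(self):
        a = run_pipeline(self.CONFIG)
        b = run_pipeline(self.CONFIG)
        assert json.dumps(a, sort_keys=True, default=str) == json.dumps(
            b, sort_keys=True, default=str
        )

    def test_report_written_to_disk(self, tmp_path):
        run_pipeline(self.CONFIG, out_dir=tmp_path / "out")
        assert (tmp_path / "out" / "results.json").exists()
        assert (tmp_path / "out" / "run_log.json").exists()
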