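"""Correlations, variable probes, clustering, distances, aggressiveness, MDS."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from epiclonal import (
    CohortSpec,
    average_reference,
    categorize_aggressiveness,
    classical_mds,
    euclidean_distances,
    generate_cohort,
    hierarchical_cluster,
    pairwise_pearson,
    top_variable_probes,
)
from conftest import analytic_gaps
from oracles import brute_force_euclidean


class TestPairwisePearson:
    def test_duplicate_and_inverted_samples(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        beta = pd.DataFrame({"a": x, "b": x, "c": 1 - x})
        corr = pairwise_pearson(beta)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_same_subclone_foci_correlate_higher(self):
        """Same-subclone focus pairs beat cross-subclone pairs in >=95/100 cohorts."""
        hits = total = 0
        for rep in range(100):
            spec = CohortSpec(n_patients=1, n_probes=2000, foci_per_patient=(4, 4), seed=500 + rep)
            beta, _, sheet, truth = generate_cohort(spec)
            foci = list(sheet.loc[sheet.tissue_type == "T", "sample_id"])
            subs = {s: truth.sample_subclone[s] for s in foci}
            if len(set(subs.values())) < 2:
                continue
            corr = pairwise_pearson(beta, foci)
            same, cross = [], []
            for i, a in enumerate(foci):
                for b in foci[i + 1:]:
                    (same if subs[a] == subs[b] else cross).append(corr.loc[a, b])
            if same and cross:
                total += 1
                hits += min(same) > max(cross)
        assert hits >= 0.95 * total

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            pairwise_pearson(pd.DataFrame({"a": [0.1, 0.2]}))


class TestTopVariableProbes:
    def test_planted_high_variance_probes_found(self):
        rng = np.random.default_rng(1)
        beta = pd.DataFrame(
            0.5 + rng.normal(0, 1e-4, (200, 6)), index=[f"p{i:03d}" for i in range(200)]
        )
        beta.iloc[17] = np.linspace(0.1, 0.9, 6)
        beta.iloc[101] = np.linspace(0.9, 0.1, 6)
        assert set(top_variable_probes(beta, fraction=0.01)) == {"p017", "p101"}

    def test_fraction_one_returns_all_complete(self):
        beta = pd.DataFrame(np.random.default_rng(2).random((50, 4)))
        beta.iloc[3, 1] = np.nan
        out = top_variable_probes(beta, fraction=1.0)
        assert len(out) == 49

    def test_constant_matrix_ties_resolve_by_probe_order(self):
        beta = pd.DataFrame(0.5, index=[f"p{i}" for i in range(100)], columns=list("abc"))
        out = top_variable_probes(beta, fraction=0.05)
        assert out == [f"p{i}" for i in range(5)]  # ceil(0.05*100)=5, input order

    def test_no_complete_probes_fails(self):
        beta = pd.DataFrame({"a": [np.nan], "b": [0.2]})
        with pytest.raises(ValueError):
            top_variable_probes(beta)


class TestHierarchicalCluster:
    def test_identical_pair_merges_first_at_zero(self):
        beta = pd.DataFrame({"a": [0.1, 0.2], "b": [0.1, 0.2], "c": [0.9, 0.8]})
        res = hierarchical_cluster(beta)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_two_samples_single_merge_at_their_distance(self):
        beta = pd.DataFrame({"a": [0.0, 0.0], "b": [0.3, 0.4]})
        res = hierarchical_cluster(beta)
        assert res.linkage.shape[0] == 1
        assert res.linkage[0, 2] == pytest.approx(0.5)

    def test_pl_joins_its_seeding_subclone_clade(self):
        """The metastasis clusters with its subclone's foci before others join."""
        import scipy.cluster.hierarchy as sch

        hits = total = 0
        for rep in range(50):
            spec = CohortSpec(n_patients=1, n_probes=2000, foci_per_patient=(3, 3), seed=800 + rep)
            beta, _, sheet, truth = generate_cohort(spec)
            tum = list(sheet.loc[sheet.tissue_type.isin(["T", "PL"]), "sample_id"])
            labels = [truth.sample_subclone[s] for s in tum]
            if len(set(labels)) < 2:
                continue
            total += 1
            res = hierarchical_cluster(beta, tum)
            parts = sch.fcluster(res.linkage, t=len(set(labels)), criterion="maxclust")
            pl_idx = [i for i, s in enumerate(tum) if s.endswith("PL1")][0]
            same = [i for i, l in enumerate(labels) if l == labels[pl_idx] and i != pl_idx]
            hits += all(parts[i] == parts[pl_idx] for i in same)
        assert hits >= 0.9 * total


class TestAverageReference:
    def test_single_sample_is_identity(self):
        beta = pd.DataFrame({"a": [0.2, 0.7]})
        ref = average_reference(beta, ["a"])
        assert ref.profile.equals(beta["a"])

    def test_two_sample_mean(self):
        beta = pd.DataFrame({"a": [0.2], "b": [0.4]})
        assert average_reference(beta, ["a", "b"]).profile.iloc[0] == pytest.approx(0.3)

    def test_missing_only_if_missing_everywhere(self):
        beta = pd.DataFrame({"a": [np.nan, np.nan], "b": [0.4, np.nan]})
        prof = average_reference(beta, ["a", "b"]).profile
        assert prof.iloc[0] == pytest.approx(0.4)
        assert np.isnan(prof.iloc[1])

    def test_sd_diagnostic_fraction(self):
        """The homogeneity diagnostic counts probes with SD above threshold."""
        rng = np.random.default_rng(3)
        beta = pd.DataFrame(0.5 + rng.normal(0, 0.001, (200, 5)))
        beta.iloc[:3] = rng.random((3, 5))  # 3 high-variance probes
        beta.iloc[0] = [0.1, 0.9, 0.1, 0.9, 0.5]
        beta.iloc[1] = [0.05, 0.95, 0.5, 0.05, 0.95]
        beta.iloc[2] = [0.2, 0.8, 0.2, 0.8, 0.2]
        ref = average_reference(beta, list(beta.columns))
        assert ref.n_probes == 200
        assert ref.n_sd_above == 3
        assert ref.sd_above_percent == pytest.approx(1.5)


class TestEuclideanDistances:
    def test_identical_and_constructed_distances(self):
        base = np.full(200, 0.5)
        other = base.copy()
        other[:100] += 0.1
        beta = pd.DataFrame({"a": base, "b": base.copy(), "c": other})
        res = euclidean_distances(beta)
        assert res.dm["a", "b"] == pytest.approx(0.0)
        assert res.dm["a", "c"] == pytest.approx(1.0)  # sqrt(100 * 0.01)
        assert res.n_probes_used == 200

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(4)
        beta = pd.DataFrame(rng.random((10, 3)), columns=["x", "y", "z"])
        res = euclidean_distances(beta)
        for a in "xyz":
            for b in "xyz":
                assert res.dm[a, b] == pytest.approx(
                    brute_force_euclidean(beta[a].to_numpy(), beta[b].to_numpy())
                )

    def test_complete_case_probes_dropped(self):
        beta = pd.DataFrame({"a": [0.1, 0.5, np.nan], "b": [0.1, 0.5, 0.2]})
        res = euclidean_distances(beta)
        assert res.n_probes_used == 2


def _dm_with_pl(focus_dists, pl="PL", prefix="T"):
    ids = [pl] + [f"{prefix}{i+1}" for i in range(len(focus_dists))]
    n = len(ids)
    d = np.zeros((n, n))
    for i, dist in enumerate(focus_dists, start=1):
        d[0, i] = d[i, 0] = dist
    for i in range(1, n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = abs(focus_dists[i - 1] - focus_dists[j - 1]) + 1.0
    return DistanceMatrix(d, ids=ids)


def _sheet(n_foci, patient="P01", pls=("PL",)):
    rows = [{"sample_id": p, "patient_id": patient, "tissue_type": "PL"} for p in pls]
    rows += [
        {"sample_id": f"T{i+1}", "patient_id": patient, "tissue_type": "T"} for i in range(n_foci)
    ]
    return pd.DataFrame(rows)


class TestCategorizeAggressiveness:
    def test_published_rule_on_worked_distances(self):
        """Distances 50/55/64/75 give dist2 0/5/14/25 and the four categories."""
        dm = _dm_with_pl([50.0, 55.0, 64.0, 75.0])
        call = categorize_aggressiveness(dm, _sheet(4), "P01")
        cats = {c.sample_id: c.category for c in call.calls}
        assert cats == {
            "T1": "aggressive",
            "T2": "aggressive",
            "T3": "undecided",
            "T4": "non_aggressive",
        }
        d2 = {c.sample_id: c.t_pl_dist2 for c in call.calls}
        assert d2 == pytest.approx({"T1": 0.0, "T2": 5.0, "T3": 14.0, "T4": 25.0})

    def test_gap_boundaries_closed_on_the_left_category(self):
        dm = _dm_with_pl([50.0, 60.0, 70.0])  # dist2 = 0, 10, 20
        call = categorize_aggressiveness(dm, _sheet(3), "P01")
        cats = {c.sample_id: c.category for c in call.calls}
        assert cats["T2"] == "aggressive"  # dist2 == 10 still aggressive
        assert cats["T3"] == "undecided"  # dist2 == 20 still undecided

    def test_single_focus_is_aggressive(self):
        dm = _dm_with_pl([42.0])
        call = categorize_aggressiveness(dm, _sheet(1), "P01")
        assert call.calls[0].category == "aggressive"

    def test_reference_pl_is_the_nearest_of_several(self):
        ids = ["PL1", "PL2", "T1", "T2"]
        d = np.array(
            [
                [0.0, 5.0, 50.0, 80.0],
                [5.0, 0.0, 30.0, 70.0],
                [50.0, 30.0, 0.0, 40.0],
                [80.0, 70.0, 40.0, 0.0],
            ]
        )
        dm = DistanceMatrix(d, ids=ids)
        sheet = _sheet(2, pls=("PL1", "PL2"))
        call = categorize_aggressiveness(dm, sheet, "P01")
        assert call.chosen_pl == "PL2"
        assert call.dist1 == pytest.approx(30.0)

    def test_no_pl_fails_with_clear_message(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["T1", "T2"])
        sheet = _sheet(2, pls=())
        with pytest.raises(ValueError, match="no metastasis reference"):
            categorize_aggressiveness(dm, sheet, "P01")

    def test_scale_awareness_of_categories(self):
        """Rescaling all distances moves foci across the fixed gap boundaries."""
        dm = _dm_with_pl([50.0, 55.0])
        call = categorize_aggressiveness(dm, _sheet(2), "P01")
        assert call.calls[1].category == "aggressive"  # dist2 = 5
        dm5 = DistanceMatrix(dm.data * 5.0, ids=list(dm.ids))
        call5 = categorize_aggressiveness(dm5, _sheet(2), "P01")
        assert call5.calls[1].category == "non_aggressive"  # dist2 = 25

    def test_planted_seeding_focus_recovered_with_scaled_gaps(self):
        spec = CohortSpec(n_patients=2, n_probes=2000, seed=77)
        beta, _, sheet, truth = generate_cohort(spec)
        lo, hi = analytic_gaps(spec)
        for pid in ["P01", "P02"]:
            sub = sheet[sheet.patient_id == pid]
            res = euclidean_distances(beta, list(sub.sample_id))
            call = categorize_aggressiveness(res.dm, sheet, pid, gap_low=lo, gap_high=hi)
            for c in call.calls:
                assert c.category == truth.focus_true_class[c.sample_id]


class TestClassicalMds:
    def test_equilateral_triangle_from_unit_distances(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        coords = classical_mds(dm)
        for i, a in enumerate("abc"):
            for b in list("abc")[i + 1:]:
                d = np.linalg.norm(coords.loc[a] - coords.loc[b])
                assert d == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_recovers_known_configuration(self):
        rng = np.random.default_rng(5)
        pts = rng.random((6, 2))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(6)])
        coords = classical_mds(dm).to_numpy()
        # Procrustes alignment residual should be numerically zero
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-8

    def test_duplicated_point_coincides(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        coords = classical_mds(DistanceMatrix(d, ids=list("abc")))
        assert np.linalg.norm(coords.loc["a"] - coords.loc["b"]) == pytest.approx(0.0, abs=1e-9)

    def test_output_centered_at_origin(self):
        rng = np.random.default_rng(6)
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(rng.random((5, 3)))), ids=[str(i) for i in range(5)])
        coords = classical_mds(dm)
        np.testing.assert_allclose(coords.mean(axis=0).to_numpy(), 0.0, atol=1e-9)

    def test_needs_enough_samples(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            classical_mds(dm, dims=2)
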