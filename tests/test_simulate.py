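"""Synthetic cohort generator: determinism, planted structure, cohort layout."""

import numpy as np
import pytest

from neonet.connectome import Connectome
from neonet.simulate import (
    CohortSpec,
    DEFAULT_AFFECTED_LABELS,
    GroupEffect,
    SubjectRecord,
    generate_cohort,
    generate_edge_lengths,
    generate_planted_connectome,
    read_cohort,
    region_table,
    write_cohort,
)


class TestPlantedConnectome:
    def test_zero_noise_zero_out_gives_two_cliques(self):
        c = generate_planted_connectome(6, [3, 3], w_in=1.0, w_out=0.0, noise_sd=0.0)
        W = c.weights
        assert np.allclose(W[:3, :3] + np.eye(3), np.ones((3, 3)))
        assert np.allclose(W[3:, 3:] + np.eye(3), np.ones((3, 3)))
        assert np.all(W[:3, 3:] == 0)

    def test_block_means_match_generative_parameters(self):
        c = generate_planted_connectome(90, [22, 23, 22, 23], w_in=10.0, w_out=2.0,
                                        noise_sd=1.0, seed=1)
        m = np.repeat(np.arange(4), [22, 23, 22, 23])
        same = m[:, None] == m[None, :]
        iu = np.triu_indices(90, 1)
        within = c.weights[iu][same[iu]]
        between = c.weights[iu][~same[iu]]
        for vals, target in ((within, 10.0), (between, 2.0)):
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - target) < 3 * se

    def test_determinism(self):
        a = generate_planted_connectome(30, [15, 15], 5, 1, 0.5, seed=1).weights
        b = generate_planted_connectome(30, [15, 15], 5, 1, 0.5, seed=1).weights
        assert np.array_equal(a, b)

    def test_symmetric_hollow_nonnegative(self):
        W = generate_planted_connectome(20, [10, 10], 3, 1, 2.0, seed=3).weights
        assert np.array_equal(W, W.T)
        assert np.all(np.diag(W) == 0)
        assert np.all(W >= 0)

    def test_bad_module_sizes_rejected(self):
        with pytest.raises(ValueError, match="module_sizes"):
            generate_planted_connectome(10, [3, 3], 1, 0)


class TestEdgeLengths:
    def test_euclidean_distances(self):
        lengths, nodes = generate_edge_lengths(10, seed=0)
        coords = nodes[["x", "y", "z"]].to_numpy()
        d01 = np.linalg.norm(coords[0] - coords[1])
        assert lengths[0, 1] == pytest.approx(d01)

    def test_symmetric_positive(self):
        lengths, _ = generate_edge_lengths(20, seed=1)
        assert np.array_equal(lengths, lengths.T)
        off = ~np.eye(20, dtype=bool)
        assert np.all(lengths[off] > 0)

    def test_hemisphere_split_is_balanced_at_the_midline(self):
        lengths, nodes = generate_edge_lengths(90, seed=2)
        assert (nodes.hemisphere == "L").sum() == 45
        assert (nodes.hemisphere == "R").sum() == 45
        assert np.all(nodes.loc[nodes.hemisphere == "L", "x"] < 0)
        assert np.all(nodes.loc[nodes.hemisphere == "R", "x"] > 0)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            generate_edge_lengths(1)


class TestCohortSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_nodes=90, module_sizes=[40, 40])
        with pytest.raises(ValueError):
            CohortSpec(n_pairs=1)
        with pytest.raises(ValueError):
            CohortSpec(w_in=-1)

    def test_null_spec_removes_all_effects(self):
        null = CohortSpec(seed=1).null()
        for eff in null.group_effects.values():
            assert eff == GroupEffect()
        assert null.fa_coupling.slope == 0.0

    def test_json_round_trip(self):
        spec = CohortSpec(seed=9, n_pairs=4, n_controls=3)
        again = CohortSpec.from_json(spec.to_json())
        assert again == spec

    def test_affected_labels_form_their_own_module(self):
        spec = CohortSpec()
        labels = region_table(90)["label"].tolist()
        idx = [i for i, l in enumerate(labels) if l in spec.affected_labels]
        modules = spec.module_assignment()
        assert len(idx) == 12
        assert len(set(modules[idx])) == 1


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(seed=42, n_pairs=6, n_controls=6, n_nodes=40)
    return spec, *generate_cohort(spec)


class TestGenerateCohort:
    def test_counts_and_pairing(self):
        spec = CohortSpec(seed=0, n_pairs=28, n_controls=28, n_nodes=30)
        connectomes, records = generate_cohort(spec)
        assert len(connectomes) == 84
        groups = {}
        for r in records:
            groups.setdefault(r.group, []).append(r.pair_id)
        assert len(groups["PB-AB"]) == 28
        assert sorted(groups["PB-AB"]) == sorted(groups["PB-TEA"])
        assert sorted(groups["PB-TEA"]) == sorted(groups["TB"])

    def test_bitwise_determinism(self):
        spec = CohortSpec(seed=5, n_pairs=3, n_controls=3, n_nodes=20)
        c1, r1 = generate_cohort(spec)
        c2, r2 = generate_cohort(CohortSpec(seed=5, n_pairs=3, n_controls=3, n_nodes=20))
        for a, b in zip(c1, c2):
            assert np.array_equal(a.weights, b.weights)
        assert r1 == r2

    def test_different_seeds_differ(self):
        kw = dict(n_pairs=3, n_controls=3, n_nodes=20)
        c1, _ = generate_cohort(CohortSpec(seed=1, **kw))
        c2, _ = generate_cohort(CohortSpec(seed=2, **kw))
        assert not np.array_equal(c1[0].weights, c2[0].weights)

    def test_record_invariants(self, cohort):
        _, _, records = cohort
        for r in records:
            assert 0 < r.mean_fa < 1
            assert r.pma_scan > 0
            assert r.n_embryos in (1, 2)
        ab = [r for r in records if r.group == "PB-AB"]
        tea = [r for r in records if r.group == "PB-TEA"]
        assert all(29 <= r.pma_scan <= 37 for r in ab)
        assert all(38 <= r.pma_scan <= 45 for r in tea)

    def test_planted_modularity_decreases_ab_to_tea(self):
        """The group weight shifts plant higher modularity at preterm birth."""
        from neonet.community import modularity
        from neonet.construct import fractional_scale

        spec = CohortSpec(seed=7, n_pairs=8, n_controls=2)
        connectomes, records = generate_cohort(spec)
        truth = spec.module_assignment()
        q = {"PB-AB": [], "PB-TEA": []}
        for c, r in zip(connectomes, records):
            if r.group in q:
                q[r.group].append(modularity(fractional_scale(c.weights), truth))
        assert np.mean(q["PB-AB"]) > np.mean(q["PB-TEA"])

    def test_paired_scans_share_the_subject_random_effect(self):
        # with zero edge noise the same infant's two scans are more alike
        # (shared segregation effect) than two different infants' scans
        spec = CohortSpec(seed=3, n_pairs=6, n_controls=2, noise_sd=0.0)
        spec.group_effects["PB-AB"] = GroupEffect()  # same distribution as TEA
        connectomes, records = generate_cohort(spec)
        dens = {r.subject_id: (c.weights > 0).mean()
                for c, r in zip(connectomes, records)}
        within = []
        between = []
        recs = [r for r in records if r.group in ("PB-AB", "PB-TEA")]
        for i, a in enumerate(recs):
            for b in recs[i + 1:]:
                d = abs(dens[a.subject_id] - dens[b.subject_id])
                (within if a.pair_id == b.pair_id else between).append(d)
        assert np.mean(within) < np.mean(between)


class TestCohortIO:
    def test_write_read_round_trip(self, tmp_path):
        spec = CohortSpec(seed=11, n_pairs=2, n_controls=2, n_nodes=20)
        connectomes, records = generate_cohort(spec)
        write_cohort(tmp_path, connectomes, records, spec=spec)
        back_c, back_r = read_cohort(tmp_path)
        assert len(back_c) == len(connectomes)
        for a, b in zip(connectomes, back_c):
            assert np.allclose(a.weights, b.weights, atol=1e-12)
            assert a.node_labels == b.node_labels
        for a, b in zip(records, back_r):
            assert a.subject_id == b.subject_id and a.group == b.group
            assert a.mean_fa == pytest.approx(b.mean_fa)
        assert (tmp_path / "cohort_spec.json").exists()
        assert (tmp_path / "lengths.tsv").exists()


class TestSubjectRecord:
    def test_validation(self):
        kw = dict(subject_id="s", group="TB", pair_id="p", pma_scan=40.0,
                  head_circumference=34.0, n_embryos=1, sex="F", motion=0.5)
        with pytest.raises(ValueError):
            SubjectRecord(mean_fa=1.2, **kw)
        with pytest.raises(ValueError):
            SubjectRecord(mean_fa=0.2, **{**kw, "pma_scan": -1.0})
        with pytest.raises(ValueError):
            SubjectRecord(mean_fa=0.2, **{**kw, "group": "XX"})
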