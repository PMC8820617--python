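"""Screening cascade: consensus, IE prioritization, two-stage clustering,
candidate selection."""

import numpy as np
import pytest

from cypscreen import (
    DEFAULT_CONFORMATIONS,
    ConformationSet,
    IEProfile,
    ScreenCandidate,
    cluster_hits,
    fixture_records,
    prioritize,
    select_candidates,
)
from cypscreen.errors import EmptyInputError, IncompleteProfileError
from cypscreen.fingerprints import ClusterAssignment


def _candidate(cid, rf=True, svm=True):
    return ScreenCandidate(id=cid, rf_positive=rf, svm_positive=svm)


def _profile(cid, value):
    return IEProfile(
        molecule_id=cid, scores={c: value for c in DEFAULT_CONFORMATIONS},
        conformations=ConformationSet(),
    )


class TestConsensus:
    def test_flag_combinations(self):
        assert _candidate("a", rf=True, svm=False).consensus is False
        assert _candidate("b", rf=False, svm=True).consensus is False
        assert _candidate("c", rf=True, svm=True).consensus is True

    def test_consensus_equals_set_intersection(self, small_data, rf_svm_bundles):
        from cypscreen import INHIBITOR, consensus_predict, predict

        matrix, _ = small_data
        rf_bundle, svm_bundle = rf_svm_bundles
        candidates = consensus_predict(rf_bundle, svm_bundle, matrix)
        rf_pos = {i for i, l in zip(matrix.ids, predict(rf_bundle, matrix)[0]) if l == INHIBITOR}
        svm_pos = {i for i, l in zip(matrix.ids, predict(svm_bundle, matrix)[0]) if l == INHIBITOR}
        got = {c.id for c in candidates if c.consensus}
        assert got == rf_pos & svm_pos


@pytest.fixture(scope="module")
def rf_svm_bundles(small_data):
    from cypscreen import HyperGrid, standardize, train_rf, train_svm_rbf

    matrix, labels = small_data
    rf, _ = train_rf(matrix, labels, HyperGrid(ntree=(50,), mtry=(3,)), cv=(5, 1), seed=21)
    scaled, params = standardize(matrix)
    svm, _ = train_svm_rbf(
        scaled, labels, params, HyperGrid(costs=(1.0,), sigma_multipliers=(1.0,)),
        cv=(5, 1), seed=21,
    )
    return rf, svm


class TestPrioritize:
    def test_consensus_and_strong_ie_prioritized(self):
        cands = prioritize([_candidate("a")], [_profile("a", -9.0)])
        assert cands[0].prioritized is True

    def test_strong_ie_without_consensus_never_prioritized(self):
        cands = prioritize([_candidate("a", rf=False)], [_profile("a", -12.0)])
        assert cands[0].prioritized is False

    def test_missing_profile_for_consensus_candidate_errors(self):
        with pytest.raises(IncompleteProfileError, match="a"):
            prioritize([_candidate("a")], [])

    def test_matches_row_by_row_conjunction_oracle(self):
        rng = np.random.default_rng(0)
        cands, profiles, expected = [], [], set()
        for i in range(50):
            cid = f"m{i}"
            rf, svm = bool(rng.integers(2)), bool(rng.integers(2))
            scores = {c: float(rng.uniform(-11, -6)) for c in DEFAULT_CONFORMATIONS}
            cands.append(ScreenCandidate(id=cid, rf_positive=rf, svm_positive=svm))
            profiles.append(IEProfile(molecule_id=cid, scores=scores))
            if rf and svm and all(s < -8.5 for s in scores.values()):
                expected.add(cid)
        got = {c.id for c in prioritize(cands, profiles, threshold=-8.5) if c.prioritized}
        assert got == expected

    def test_order_invariant(self):
        rng = np.random.default_rng(1)
        cands = [
            ScreenCandidate(id=f"m{i}", rf_positive=bool(rng.integers(2)), svm_positive=True)
            for i in range(30)
        ]
        profiles = [_profile(c.id, float(rng.uniform(-11, -6))) for c in cands]
        fwd = {c.id for c in prioritize(list(cands), profiles) if c.prioritized}
        import copy

        rev = {
            c.id
            for c in prioritize(copy.deepcopy(cands)[::-1], profiles[::-1])
            if c.prioritized
        }
        assert fwd == rev

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        cands = [_candidate(f"m{i}") for i in range(40)]
        profiles = [
            IEProfile(
                molecule_id=c.id,
                scores={k: float(rng.uniform(-11, -6)) for k in DEFAULT_CONFORMATIONS},
            )
            for c in cands
        ]
        prev: set = set()
        for t in (-10.0, -9.0, -8.5, -7.5, -6.0):
            import copy

            got = {
                c.id
                for c in prioritize(copy.deepcopy(cands), profiles, threshold=t)
                if c.prioritized
            }
            assert prev <= got
            prev = got


class TestClusterHits:
    def test_identical_hits_single_cluster(self):
        from cypscreen import CompoundRecord

        recs = [CompoundRecord(id=f"m{i}", smiles="CC(=O)Oc1ccccc1C(=O)O") for i in range(5)]
        s1, s2 = cluster_hits(recs)
        assert len(s1) == 1 and len(s2) == 1

    def test_dissimilar_hits_all_singletons(self):
        keep = ("aspirin", "caffeine", "fluconazole", "haloperidol", "isoniazid")
        recs = [r for r in fixture_records(druglike_only=True) if r.id in keep]
        s1, s2 = cluster_hits(recs)
        assert len(s1) == len(recs) and len(s2) == len(recs)

    def test_stage1_matches_leader_oracle(self):
        from tests.test_clustering import brute_force_leader, _fps

        recs = fixture_records(druglike_only=True)
        s1, _ = cluster_hits(recs, stage1_cutoff=0.80)
        ids = [r.id for r in recs]
        fps = _fps(recs, "maccs")
        expected = brute_force_leader(ids, fps, 0.80)
        assert [(c.centroid_id, frozenset(c.member_ids)) for c in s1] == expected

    def test_stage2_runs_on_stage1_centroids_only(self):
        recs = fixture_records(druglike_only=True)
        s1, s2 = cluster_hits(recs)
        centroids = {c.centroid_id for c in s1}
        stage2_members = {m for c in s2 for m in c.member_ids}
        assert stage2_members == centroids

    def test_empty_errors(self):
        with pytest.raises(EmptyInputError):
            cluster_hits([])


class TestSelectCandidates:
    def _cluster(self, cid, members, cutoff=0.70):
        return ClusterAssignment(
            cluster_id=cid, member_ids=members, centroid_id=members[0], similarity_cutoff=cutoff
        )

    def test_one_pick_per_small_cluster(self):
        recs = fixture_records(druglike_only=True)
        clusters = [self._cluster(i, [r.id]) for i, r in enumerate(recs[:24])]
        picks = select_candidates(clusters, recs)
        assert picks == [r.id for r in recs[:24]]

    def test_large_cluster_extra_picks_rule(self):
        """ceil(size/15): an 18-member cluster yields 2 picks, a 37-member
        cluster 3 (the published large-cluster selections)."""
        import math

        recs = fixture_records(druglike_only=True)
        ids = [r.id for r in recs]
        for size, expected in ((18, 2), (37, 3)):
            members = [ids[i % len(ids)] for i in range(size)]
            # use unique synthetic duplicates so ids stay distinct
            from cypscreen import CompoundRecord

            uniq = [CompoundRecord(id=f"x{i}", smiles=recs[i % len(recs)].smiles) for i in range(size)]
            clusters = [self._cluster(0, [u.id for u in uniq])]
            picks = select_candidates(clusters, uniq)
            assert len(picks) == expected == math.ceil(size / 15)
            assert picks[0] == uniq[0].id  # centroid always first

    def test_extra_picks_maximize_dissimilarity(self):
        from cypscreen import CompoundRecord
        from cypscreen.fingerprints import compute_fingerprint, mol_from_smiles, tanimoto

        recs = fixture_records(druglike_only=True)
        uniq = [CompoundRecord(id=f"x{i}", smiles=recs[i].smiles) for i in range(12)]
        clusters = [self._cluster(0, [u.id for u in uniq])]
        picks = select_candidates(clusters, uniq, large_cluster_min=5, members_per_pick=6)
        assert len(picks) == 2
        # the second pick is the member farthest (min-similarity) from the centroid
        fps = {u.id: compute_fingerprint(mol_from_smiles(u.smiles), "path") for u in uniq}
        dists = {u.id: 1 - tanimoto(fps[u.id], fps[picks[0]]) for u in uniq if u.id != picks[0]}
        assert dists[picks[1]] == max(dists.values())

    def test_infinite_threshold_one_per_cluster(self):
        recs = fixture_records(druglike_only=True)
        clusters = [self._cluster(0, [r.id for r in recs])]
        picks = select_candidates(clusters, recs, large_cluster_min=None)
        assert len(picks) == 1


class TestRunScreen:
    def test_cascade_counts_monotone_and_report_written(self, small_data, rf_svm_bundles, tmp_path):
        """End-to-end screen over the fixture library with synthetic IEs."""
        from cypscreen import CompoundRecord, FixtureSpec, gen_ie_profiles, run_screen
        from cypscreen.screening import write_screen_report

        matrix, labels = small_data
        rf_bundle, svm_bundle = rf_svm_bundles
        # reuse the fixture matrix as a screening library with fake structures
        recs = fixture_records(druglike_only=True)
        ids = matrix.ids
        library = [
            CompoundRecord(id=i, smiles=recs[k % len(recs)].smiles) for k, i in enumerate(ids)
        ]
        profiles = gen_ie_profiles(ids, labels, FixtureSpec(seed=33))
        report = run_screen(library, matrix, rf_bundle, svm_bundle, profiles)
        c = report.counts
        assert c["library"] >= c["consensus"] >= c["prioritized"] >= 0
        assert c["selected"] <= c["prioritized"] or c["prioritized"] == 0
        for cand in report.candidates:
            assert cand.consensus == (cand.rf_positive and cand.svm_positive)
            assert cand.prioritized == (cand.consensus and cand.ie_pass)
        out = tmp_path / "screen.csv"
        write_screen_report(report, out)
        assert out.read_text().startswith("id,")

    def test_exclusion_list_respected(self, small_data, rf_svm_bundles):
        from cypscreen import CompoundRecord, FixtureSpec, gen_ie_profiles, run_screen

        matrix, labels = small_data
        rf_bundle, svm_bundle = rf_svm_bundles
        recs = fixture_records(druglike_only=True)
        ids = matrix.ids
        library = [
            CompoundRecord(id=i, smiles=recs[k % len(recs)].smiles) for k, i in enumerate(ids)
        ]
        profiles = gen_ie_profiles(ids, labels, FixtureSpec(seed=33))
        excluded = set(ids[:50])
        report = run_screen(
            library, matrix, rf_bundle, svm_bundle, profiles, exclude_ids=excluded
        )
        assert not excluded & {c.id for c in report.candidates}
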