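import numpy as np
import pytest

from scopemapper.chem_io import from_smiles_list
from scopemapper.selection import (
    DEFAULT_EXCLUDE_SMARTS,
    OLEFIN_SMARTS,
    FilterSpec,
    SelectionConfig,
    apply_filters,
    rank_candidates,
    select_representatives,
)


def greedy_selection_oracle(dist, top_n, unique, availability):
    """Independent selection oracle on a raw (k x m) distance table.

    Clusters sorted by their single best candidate distance; each takes the
    closest available, non-consumed candidate among its top_n closest.
    """
    k, m = dist.shape
    order = sorted(range(k), key=lambda c: dist[c].min())
    consumed = set()
    chosen = {}
    for c in order:
        ranked = sorted(range(m), key=lambda i: (dist[c, i], i))[:top_n]
        pick = None
        for i in ranked:
            if availability[i] and not (unique and i in consumed):
                pick = i
                break
        chosen[c] = pick
        if pick is not None:
            consumed.add(pick)
    return chosen


class TestFilterSpec:
    def test_bad_smarts_fails_at_construction(self):
        with pytest.raises(ValueError):
            FilterSpec(exclude_smarts={"bad": "[[["})

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(mw_max=0)


class TestApplyFilters:
    def test_heavy_molecule_rejected_by_mw(self):
        # a C60 chain: MW ~ 843 Da, above the 700 Da cutoff
        heavy = from_smiles_list(["C" * 60], ids=["heavy"])
        kept, log = apply_filters(heavy, FilterSpec(exclude_smarts={}))
        assert len(kept) == 0
        assert log[0]["rule"] == "mw"

    def test_expensive_candidate_rejected_by_price(self):
        import dataclasses

        ms = from_smiles_list(["CCO"], ids=["x"])
        ms.records[0] = dataclasses.replace(ms.records[0], price_per_g=250.0)
        kept, log = apply_filters(ms, FilterSpec(exclude_smarts={}))
        assert len(kept) == 0 and log[0]["rule"] == "price"

    def test_free_primary_amine_excluded(self):
        ms = from_smiles_list(["CCCCN"], ids=["n-butylamine"])
        kept, log = apply_filters(ms, FilterSpec())
        assert len(kept) == 0
        assert log[0]["rule"] == "exclude:free_amine"

    def test_amide_sulfonamide_aniline_not_flagged_as_free_amine(self):
        ms = from_smiles_list(["CCC(=O)NC", "CS(=O)(=O)NC", "Nc1ccccc1"])
        kept, _ = apply_filters(ms, FilterSpec())
        assert len(kept) == 3

    def test_tetrasubstituted_alkene_excluded(self):
        ms = from_smiles_list(["CC(C)=C(C)C"], ids=["tme"])
        kept, log = apply_filters(ms, FilterSpec())
        assert len(kept) == 0
        assert log[0]["rule"] == "exclude:tetrasubstituted_alkene"

    def test_trisubstituted_alkene_kept(self):
        ms = from_smiles_list(["CC(C)=CC"])
        kept, _ = apply_filters(ms, FilterSpec())
        assert len(kept) == 1

    def test_require_pattern(self):
        ms = from_smiles_list(["C=CCCC", "CCCCC"])
        kept, log = apply_filters(
            ms, FilterSpec(exclude_smarts={}, require_smarts={"olefin": OLEFIN_SMARTS})
        )
        assert kept.smiles == from_smiles_list(["C=CCCC"]).smiles
        assert log[0]["rule"] == "require:olefin"

    def test_empty_spec_is_identity(self):
        ms = from_smiles_list(["CCO", "CCCCN", "CC(C)=C(C)C"])
        kept, log = apply_filters(
            ms, FilterSpec(mw_max=None, price_max=None, exclude_smarts={})
        )
        assert kept.smiles == ms.smiles and log == []

    def test_missing_price_policy(self):
        ms = from_smiles_list(["CCO"])
        kept, _ = apply_filters(ms, FilterSpec(exclude_smarts={}))
        assert len(kept) == 1  # keep by default
        kept, log = apply_filters(
            ms, FilterSpec(exclude_smarts={}, keep_missing_price=False)
        )
        assert len(kept) == 0 and log[0]["rule"] == "price"

    def test_filtering_is_monotone_in_rules(self):
        base = FilterSpec(mw_max=None, price_max=None, exclude_smarts={})
        stricter = [
            FilterSpec(mw_max=700, price_max=None, exclude_smarts={}),
            FilterSpec(mw_max=700, price_max=100, exclude_smarts={}),
            FilterSpec(mw_max=700, price_max=100),
            FilterSpec(mw_max=700, price_max=100,
                       require_smarts={"olefin": OLEFIN_SMARTS}),
        ]
        smiles = ["C=CCCC", "CCO", "CCCCN", "CC(C)=C(C)C", "C" * 60, "C=Cc1ccccc1"]
        ms = from_smiles_list(smiles)
        survivors = [set(apply_filters(ms, base)[0].smiles)]
        for spec in stricter:
            survivors.append(set(apply_filters(ms, spec)[0].smiles))
        for wider, narrower in zip(survivors, survivors[1:]):
            assert narrower <= wider


class TestRankCandidates:
    def test_single_candidate_is_rank_one_everywhere(self):
        centers = np.array([[0, 0], [5, 5], [9, 1]], float)
        ranked = rank_candidates(centers, np.array([[1.0, 1.0]]), ["only"])
        assert all(r[0][0] == 0 for r in ranked)

    def test_candidate_at_center_has_distance_zero(self):
        centers = np.array([[2.0, 3.0]])
        ranked = rank_candidates(centers, np.array([[2.0, 3.0], [4.0, 4.0]]), ["a", "b"])
        assert ranked[0][0] == (0, 0.0)

    def test_matches_exhaustive_sort(self, rng):
        centers = rng.normal(size=(3, 2))
        coords = rng.normal(size=(8, 2))
        ids = [f"c{i}" for i in range(8)]
        ranked = rank_candidates(centers, coords, ids)
        for c in range(3):
            d = np.linalg.norm(coords - centers[c], axis=1)
            want = sorted(range(8), key=lambda i: (d[i], ids[i]))
            assert [i for i, _ in ranked[c]] == want

    def test_ties_broken_by_smiles_key(self):
        centers = np.array([[0.0, 0.0]])
        coords = np.array([[1.0, 0.0], [-1.0, 0.0]])
        ranked = rank_candidates(centers, coords, ["b", "a"], tiebreak_keys=["OCC", "CCO"])
        assert [i for i, _ in ranked[0]] == [1, 0]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates(np.zeros((2, 2)), np.empty((0, 2)), [])


class TestSelectRepresentatives:
    def run(self, centers, coords, ids=None, top_n=5, unique=True, availability=None):
        ids = ids or [f"c{i}" for i in range(len(coords))]
        ranked = rank_candidates(np.asarray(centers, float), np.asarray(coords, float), ids)
        return select_representatives(
            ranked, SelectionConfig(top_n=top_n, unique=unique), ids,
            availability=availability,
        )

    def test_enough_candidates_all_clusters_served_distinctly(self, rng):
        centers = rng.normal(size=(4, 2)) * 10
        coords = rng.normal(size=(9, 2)) * 10
        res = self.run(centers, coords)
        assert res.n_served == 4
        assert len(set(res.chosen_ids)) == 4

    def test_pigeonhole_one_candidate_three_clusters(self):
        centers = np.array([[0, 0], [5, 5], [9, 1]], float)
        res = self.run(centers, np.array([[1.0, 1.0]]))
        assert res.n_served == 1
        warnings = [c.warning for c in res.per_cluster if c.warning]
        assert len(warnings) == 2

    def test_shared_closest_candidate_goes_to_nearer_center(self):
        centers = np.array([[0.0, 0.0], [3.0, 0.0]])
        coords = np.array([[1.0, 0.0], [5.0, 0.0]])  # c0 closest to both centers
        res = self.run(centers, coords)
        by_name = {c.cluster_name: c.chosen for c in res.per_cluster}
        assert by_name["A"] == "c0"  # distance 1 beats cluster B's 2
        assert by_name["B"] == "c1"

    def test_unavailable_candidates_skipped(self):
        centers = np.array([[0.0, 0.0]])
        coords = np.array([[0.1, 0.0], [0.5, 0.0]])
        res = self.run(centers, coords, availability=[False, True])
        assert res.per_cluster[0].chosen == "c1"

    def test_nonunique_mode_allows_reuse(self):
        centers = np.array([[0.0, 0.0], [0.2, 0.0]])
        coords = np.array([[0.1, 0.0], [5.0, 0.0]])
        res = self.run(centers, coords, unique=False)
        assert [c.chosen for c in res.per_cluster] == ["c0", "c0"]

    def test_matches_independent_greedy_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            m = int(rng.integers(1, 11))
            top_n = int(rng.integers(1, 6))
            centers = rng.normal(size=(k, 2)) * 5
            coords = rng.normal(size=(m, 2)) * 5
            availability = list(rng.random(m) < 0.8)
            ids = [f"c{i}" for i in range(m)]
            ranked = rank_candidates(centers, coords, ids)
            res = select_representatives(
                ranked, SelectionConfig(top_n=top_n, unique=True), ids,
                availability=availability,
            )
            dist = np.linalg.norm(
                centers[:, None, :] - coords[None, :, :], axis=2
            )
            want = greedy_selection_oracle(dist, top_n, True, availability)
            got = {c: (None if res.per_cluster[c].chosen is None
                       else int(res.per_cluster[c].chosen[1:]))
                   for c in range(k)}
            assert got == want

    def test_greedy_optimality_contract(self, rng):
        # no unchosen available candidate (not consumed by an earlier,
        # closer cluster) may lie strictly closer to a served cluster's center
        for trial in range(20):
            centers = rng.normal(size=(4, 2)) * 5
            coords = rng.normal(size=(10, 2)) * 5
            ids = [f"c{i}" for i in range(10)]
            ranked = rank_candidates(centers, coords, ids)
            res = select_representatives(
                ranked, SelectionConfig(top_n=10, unique=True), ids
            )
            dist = np.linalg.norm(centers[:, None, :] - coords[None, :, :], axis=2)
            order = sorted(range(4), key=lambda c: dist[c].min())
            consumed = set()
            for c in order:
                sel = res.per_cluster[c]
                if sel.chosen is None:
                    continue
                chosen_idx = ids.index(sel.chosen)
                closer = [i for i in range(10)
                          if dist[c, i] < dist[c, chosen_idx] and i not in consumed]
                assert not closer
                consumed.add(chosen_idx)
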