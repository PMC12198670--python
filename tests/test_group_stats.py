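"""Profile assembly, altGower distances, PERMANOVA and NMDS."""

from itertools import permutations as iterperm

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from cmcpipe.stats import (
    alt_gower_distance,
    assemble_profiles,
    nmds,
    pairwise_group_by_task,
    permanova,
)


def _check_distance_matrix(d):
    assert np.allclose(d, d.T)
    assert np.all(np.diag(d) == 0)
    assert np.all(d >= 0)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def _cmc_table(n_trials=7, value=0.5, pairs=("C3-ExO", "Cz-ExO")):
    rows = []
    for t in range(1, n_trials + 1):
        for p in pairs:
            rows.append(
                {
                    "participant": "A01", "group": "amputee", "task": "EO",
                    "band": "alpha", "direction": "efferent",
                    "muscle_set": "trunk", "trial": t, "pair": p,
                    "cmc": value if np.isscalar(value) else value[t - 1],
                }
            )
    return pd.DataFrame(rows)


class TestAssembleProfiles:
    def test_identical_trials_average_to_trial_value(self):
        out = assemble_profiles(_cmc_table(value=0.42))
        assert out["C3-ExO"].iloc[0] == pytest.approx(0.42)
        assert out["complete"].iloc[0]

    def test_mean_over_retained_subset(self):
        table = _cmc_table(n_trials=7, value=[0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        mask = table[["participant", "task", "band", "trial", "pair"]].drop_duplicates().copy()
        mask["retained"] = mask["trial"].isin([2, 4, 6])
        out = assemble_profiles(table, mask)
        assert out["C3-ExO"].iloc[0] == pytest.approx(np.mean([0.2, 0.4, 0.6]))

    def test_all_masked_yields_empty(self):
        table = _cmc_table()
        mask = table[["trial", "pair"]].drop_duplicates().copy()
        mask["retained"] = False
        out = assemble_profiles(table, mask)
        assert out.empty

    def test_partial_pair_missing_flagged_incomplete(self):
        table = _cmc_table()
        mask = table[["trial", "pair"]].drop_duplicates().copy()
        mask["retained"] = mask["pair"] == "C3-ExO"
        out = assemble_profiles(table, mask)
        assert not out["complete"].iloc[0]


# ---------------------------------------------------------------------------
# altGower
# ---------------------------------------------------------------------------

class TestAltGower:
    def test_identity_of_indiscernibles(self, rng):
        x = rng.random((5, 6))
        d = alt_gower_distance(x)
        _check_distance_matrix(d)
        assert np.all(np.diag(d) == 0)

    def test_constant_offset(self):
        x = np.array([[0.2, 0.4, 0.6, 0.2, 0.4, 0.6]])
        y = x + 0.1
        d = alt_gower_distance(np.vstack([x, y]))
        assert d[0, 1] == pytest.approx(0.1)

    def test_matches_brute_force_loop_exactly(self, rng):
        x = rng.random((8, 6))
        d = alt_gower_distance(x)
        for i in range(8):
            for j in range(8):
                expected = np.mean(np.abs(x[i] - x[j]))
                assert d[i, j] == expected

    def test_missing_values_rejected(self):
        x = np.array([[0.1, np.nan], [0.2, 0.3]])
        with pytest.raises(ValueError):
            alt_gower_distance(x)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

class TestPermanova:
    def test_one_way_pseudo_f_matches_skbio(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        x = rng.normal(size=(24, 6))
        x[:12] += 0.8
        d = alt_gower_distance(x)
        design = pd.DataFrame({"group": ["a"] * 12 + ["b"] * 12})
        mine = permanova(d, design, terms=("group",), n_perm=999, seed=1)
        ref = sk_permanova(DistanceMatrix(d), ["a"] * 12 + ["b"] * 12, permutations=999)
        assert mine["pseudo_F"].iloc[0] == pytest.approx(
            float(ref["test statistic"]), rel=1e-10
        )
        assert mine["p_value"].iloc[0] == pytest.approx(float(ref["p-value"]), abs=0.03)

    def test_tiny_instance_matches_exhaustive_enumeration(self, rng):
        """n=6: the Monte-Carlo permutation p agrees with enumerating all
        row permutations."""
        x = rng.normal(size=(6, 4))
        x[:3] += 1.0
        d = alt_gower_distance(x)
        design = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3})
        res = permanova(d, design, terms=("group",), n_perm=9999, seed=2)
        f_obs = res["pseudo_F"].iloc[0]

        def brute_f(dist):
            n = 6
            g = (np.eye(n) - 1 / n) @ (-0.5 * dist**2) @ (np.eye(n) - 1 / n)
            xm = np.array([[1.0, 1.0 if i < 3 else 0.0] for i in range(n)])
            h = xm @ np.linalg.pinv(xm)
            ss_b = np.sum((h - np.ones((n, n)) / n) * g)
            ss_w = np.trace(g) - np.sum(h * g)
            return ss_b / (ss_w / 4)

        count = 0
        total = 0
        for p in iterperm(range(6)):
            total += 1
            if brute_f(d[np.ix_(p, p)]) >= f_obs - 1e-12:
                count += 1
        exact_p = count / total
        assert res["p_value"].iloc[0] == pytest.approx(exact_p, abs=0.02)

    def test_reordering_invariance(self, rng):
        x = rng.normal(size=(12, 6))
        d = alt_gower_distance(x)
        design = pd.DataFrame(
            {"group": ["a", "b"] * 6, "task": ["EO", "EO", "EC"] * 4}
        )
        perm = rng.permutation(12)
        a = permanova(d, design, terms=("group", "task"), n_perm=99, seed=0)
        b = permanova(
            d[np.ix_(perm, perm)],
            design.iloc[perm].reset_index(drop=True),
            terms=("group", "task"), n_perm=99, seed=0,
        )
        np.testing.assert_allclose(a["pseudo_F"], b["pseudo_F"], rtol=1e-9)

    def test_separated_clusters_hit_p_floor(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.01, (6, 6)), rng.normal(50, 0.01, (6, 6))])
        d = alt_gower_distance(x)
        design = pd.DataFrame({"group": ["a"] * 6 + ["b"] * 6})
        res = permanova(d, design, terms=("group",), n_perm=199, seed=1)
        assert res["p_value"].iloc[0] == pytest.approx(1 / 200)

    def test_singular_term_rejected(self, rng):
        x = rng.normal(size=(6, 3))
        d = alt_gower_distance(x)
        design = pd.DataFrame({"group": ["a"] * 6})  # single level
        with pytest.raises(ValueError, match="group"):
            permanova(d, design, terms=("group",), n_perm=9, seed=0)

    def test_block_exchange_used_for_between_factor(self, rng):
        """With participant strata, the group test permutes whole
        participants: a strong group split still reaches the p floor, which
        would be impossible under within-participant permutation."""
        rows, vals = [], []
        for gi, g in enumerate(("a", "b")):
            for p in range(4):
                pid = f"{g}{p}"
                for band in ("alpha", "beta"):
                    rows.append({"participant": pid, "group": g, "band": band})
                    vals.append(rng.normal(gi * 30.0, 0.1, 6))
        design = pd.DataFrame(rows)
        d = alt_gower_distance(np.array(vals))
        res = permanova(
            d, design, terms=("band", "group"), strata="participant",
            n_perm=199, seed=3,
        )
        p_group = float(res.loc[res.term == "group", "p_value"].iloc[0])
        # 8 participants -> C(8,4)=70 distinct group assignments; the observed
        # split is the most extreme, so p is small but bounded by repetition
        assert p_group < 0.05

    def test_unequal_strata_rejected_for_block_exchange(self, rng):
        rows, vals = [], []
        for g in ("a", "b"):
            for p in range(3):
                pid = f"{g}{p}"
                reps = 2 if pid != "a0" else 3
                for k in range(reps):
                    rows.append({"participant": pid, "group": g})
                    vals.append(rng.normal(size=4))
        design = pd.DataFrame(rows)
        d = alt_gower_distance(np.array(vals))
        with pytest.raises(ValueError, match="equal-sized"):
            permanova(d, design, terms=("group",), strata="participant",
                      n_perm=19, seed=0)


class TestPairwiseByTask:
    def _cohort(self, rng, effect_task=None):
        rows, vals = [], []
        for gi, g in enumerate(("a", "b")):
            for p in range(5):
                pid = f"{g}{p}"
                for task in ("EO", "EC", "DT"):
                    rows.append({"participant": pid, "group": g, "task": task})
                    shift = 2.0 if (g == "a" and task == effect_task) else 0.0
                    vals.append(rng.normal(shift, 0.3, 6))
        return alt_gower_distance(np.array(vals)), pd.DataFrame(rows)

    def test_effect_in_one_task_yields_smallest_p_there(self, rng):
        d, design = self._cohort(rng, effect_task="EC")
        res = pairwise_group_by_task(d, design, strata="participant",
                                     n_perm=199, seed=0)
        res = res.set_index("task")
        assert res.loc["EC", "p_value"] == res["p_value"].min()
        assert res.loc["EC", "p_value"] <= 0.05

    def test_single_task_matches_direct_permanova(self, rng):
        d, design = self._cohort(rng)
        sel = np.flatnonzero((design["task"] == "EO").to_numpy())
        direct = permanova(
            d[np.ix_(sel, sel)], design.iloc[sel].reset_index(drop=True),
            terms=("group",), strata="participant", n_perm=99, seed=7,
        )
        res = pairwise_group_by_task(d, design, strata="participant",
                                     n_perm=99, seed=7)
        row = res.set_index("task").loc["EO"]
        assert row["pseudo_F"] == pytest.approx(direct["pseudo_F"].iloc[0])

    def test_single_group_task_rejected(self, rng):
        d, design = self._cohort(rng)
        design.loc[design["task"] == "DT", "group"] = "a"
        with pytest.raises(ValueError, match="single group"):
            pairwise_group_by_task(d, design, n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

class TestNmds:
    def test_planar_configuration_round_trip(self, rng):
        pts = rng.random((20, 2))
        d = squareform(pdist(pts))
        coords, stress = nmds(d, k=2, n_restarts=8, seed=0)
        assert stress < 0.01
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-3

    def test_equilateral_triangle_embeds_exactly(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, stress = nmds(d, k=2, n_restarts=8, seed=1)
        assert stress < 1e-3
        side = pdist(coords)
        assert np.ptp(side) / side.mean() < 0.01
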