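"""Null-model indices: Raup-Crick, NST, occupancy-stratified NST, betaMNTD/betaNTI."""

import io as _io
import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multinomial as sp_multinomial
from skbio import TreeNode

from pond_assembly import assembly, synthetic
from pond_assembly.assembly import (
    NullModelConfig,
    beta_mntd,
    beta_nti,
    classify_rc,
    nst,
    nst_by_occupancy,
    null_dissimilarity_distribution,
    raup_crick,
    regional_pool,
)
from .conftest import sparse_random_communities


def _bray(x, y):
    return np.abs(np.asarray(x) - np.asarray(y)).sum() / (
        np.asarray(x) + np.asarray(y)
    ).sum()


def _exact_null_distribution(richness, n_ind, freq, abund):
    """Exhaustive (probability, counts) outcomes of the null for one sample.

    Species subsets of the given richness enumerate sequential weighted
    sampling without replacement; abundances seed each drawn species with one
    individual and distribute the rest multinomially.
    """
    S = len(freq)
    outcomes = []
    for subset in itertools.combinations(range(S), richness):
        p_subset = 0.0
        for order in itertools.permutations(subset):
            p, remaining = 1.0, sum(freq)
            for s in order:
                p *= freq[s] / remaining
                remaining -= freq[s]
            p_subset += p
        p_rest = np.array([abund[s] for s in subset])
        p_rest = p_rest / p_rest.sum()
        extra = n_ind - richness
        for comp in itertools.product(range(extra + 1), repeat=richness):
            if sum(comp) != extra:
                continue
            pmf = sp_multinomial.pmf(comp, extra, p_rest) if extra else 1.0
            counts = np.zeros(S)
            for s, c in zip(subset, comp):
                counts[s] = 1 + c
            outcomes.append((p_subset * pmf, counts))
    total = sum(p for p, _ in outcomes)
    assert abs(total - 1.0) < 1e-9
    return outcomes


class TestNullDistributionOracle:
    def test_monte_carlo_matches_full_enumeration(self):
        # 3-species pool, richness-2 samples with <= 6 individuals: the
        # simulated null dissimilarity distribution must match exhaustive
        # enumeration within Monte-Carlo error
        freq = np.array([1.0, 0.5, 0.5])
        abund = np.array([0.5, 0.3, 0.2])
        x = np.array([2, 2, 0])  # richness 2, 4 individuals
        y = np.array([1, 0, 2])  # richness 2, 3 individuals
        cfg = NullModelConfig(n_reps=4000, seed=12)
        dn = null_dissimilarity_distribution(x, y, freq, abund, cfg)

        out_x = _exact_null_distribution(2, 4, freq, abund)
        out_y = _exact_null_distribution(2, 3, freq, abund)
        exact_d, exact_p = [], []
        for (px, cx), (py, cy) in itertools.product(out_x, out_y):
            exact_d.append(_bray(cx, cy))
            exact_p.append(px * py)
        exact_d, exact_p = np.array(exact_d), np.array(exact_p)
        mean_exact = (exact_d * exact_p).sum()
        var_exact = ((exact_d - mean_exact) ** 2 * exact_p).sum()
        se = np.sqrt(var_exact / cfg.n_reps)
        assert abs(dn.mean() - mean_exact) < 3 * se
        # the tail probability RC uses, at a mid-range threshold
        d_obs = _bray(x, y)
        frac_exact = exact_p[exact_d < d_obs].sum() + 0.5 * exact_p[
            np.isclose(exact_d, d_obs)
        ].sum()
        frac_mc = ((dn < d_obs).sum() + 0.5 * (dn == d_obs).sum()) / dn.size
        se_frac = np.sqrt(frac_exact * (1 - frac_exact) / cfg.n_reps)
        assert abs(frac_mc - frac_exact) < 3 * se_frac + 1e-9

    def test_forced_species_identity(self):
        # pool = exactly the observed species, richness = pool size: every
        # null community contains the same species set
        freq = np.array([1.0, 1.0, 1.0])
        abund = np.array([0.5, 0.25, 0.25])
        x = np.array([3, 2, 1])
        cfg = NullModelConfig(n_reps=200, seed=0)
        rng = np.random.default_rng(0)
        nulls = assembly._null_counts_for_sample(3, 6, freq, abund, cfg, rng)
        assert (nulls > 0).all()
        assert (nulls.sum(axis=1) == 6).all()

    def test_pool_smaller_than_richness(self):
        freq = np.array([1.0, 0.0, 0.0])
        abund = np.array([1.0, 0.0, 0.0])
        cfg = NullModelConfig(n_reps=100, seed=0)
        with pytest.raises(ValueError):
            null_dissimilarity_distribution(
                np.array([1, 1, 1]), np.array([1, 1, 1]), freq, abund, cfg
            )


class TestRaupCrick:
    def test_tie_convention_exact_zero(self):
        # all-ones table: the null is forced to the observed configuration,
        # every null D ties D_obs = 0, so RC = 0 exactly
        table = pd.DataFrame(np.ones((3, 2), dtype=int),
                             index=list("xyz"), columns=["a", "b"])
        rc = raup_crick(table, NullModelConfig(n_reps=200, seed=1))
        assert rc.loc["a", "b"] == 0.0

    def test_extreme_divergence_plus_one(self):
        # maximally anti-correlated abundances: observed D exceeds every
        # plausible null draw, RC = +1
        table = pd.DataFrame({"a": [20, 1], "b": [1, 20]}, index=["x", "y"])
        rc = raup_crick(table, NullModelConfig(n_reps=500, seed=2))
        assert rc.loc["a", "b"] == 1.0

    def test_symmetry_and_bounds(self, neutral_metacommunity):
        table, _ = neutral_metacommunity
        sub = table.iloc[:, :6]
        sub = sub.loc[sub.sum(axis=1) > 0]
        rc = raup_crick(sub, NullModelConfig(n_reps=150, seed=3))
        arr = rc.to_numpy()
        assert np.allclose(arr, arr.T)
        assert (arr >= -1).all() and (arr <= 1).all()
        bins = classify_rc(rc)
        assert sum(bins.values()) == pytest.approx(100.0)

    def test_monte_carlo_sd_shrinks_with_reps(self):
        table = pd.DataFrame(
            {"a": [8, 3, 1, 2], "b": [2, 6, 3, 1], "c": [4, 4, 2, 2]},
            index=list("wxyz"),
        )
        sds = []
        for reps in (100, 400):
            vals = [
                raup_crick(table, NullModelConfig(n_reps=reps, seed=s)).loc[
                    "a", "b"
                ]
                for s in range(12)
            ]
            sds.append(np.std(vals))
        # quadrupling reps should roughly halve the Monte-Carlo sd
        assert sds[1] < sds[0] / 1.3


class TestNst:
    def test_pair_stochasticity_anchors(self):
        # observation indistinguishable from null -> ST = 1 (NST 100%);
        # maximal divergence (D = D_max) -> ST = 0 (NST 0%)
        assert assembly._pair_st(0.5, 0.5) == 1.0
        assert assembly._pair_st(1.0, 0.4) == 0.0
        assert assembly._pair_st(0.0, 0.4) == 0.0  # fully more similar

    def test_identical_samples_fully_deterministic(self):
        col = np.array([5, 3, 2, 4, 6, 1])
        table = pd.DataFrame(
            {s: col for s in ["a", "b", "c", "d"]},
            index=[f"o{i}" for i in range(6)],
        )
        groups = {"a": "G", "b": "G", "c": "G", "d": "G"}
        res = nst(table, groups, NullModelConfig(n_reps=150, seed=4))
        assert res["G"] < 15.0  # D_obs = 0 << E: selection strength ~ 1

    def test_values_bounded(self, neutral_metacommunity):
        table, meta = neutral_metacommunity
        groups = dict(zip(meta.sample_id, meta.pond_type))
        res = nst(table.iloc[:, :8],
                  groups, NullModelConfig(n_reps=120, seed=5))
        for v in res.values():
            assert 0.0 <= v <= 100.0

    def test_bootstrap_difference_selfconsistent(self):
        cfg = synthetic.MetacommunityConfig(
            pool_size=200, individuals_per_site=400, niche_weight=0.0
        )
        table, meta = synthetic.simulate_metacommunity(cfg, seed=6)
        groups = dict(zip(meta.sample_id, meta.pond_type))
        sub = table.iloc[:, [0, 1, 2, 3, 10, 11, 12, 13]]
        sub = sub.loc[sub.sum(axis=1) > 0]
        res = assembly.nst_bootstrap_difference(
            sub, groups, NullModelConfig(n_reps=120, seed=7), n_boot=30
        )
        # both groups neutral: no significant difference expected
        assert res["p_value"] > 0.05


class TestNstByOccupancy:
    def test_k1_equals_unstratified(self, neutral_metacommunity):
        table, meta = neutral_metacommunity
        sub = table.iloc[:, :8]
        sub = sub.loc[sub.sum(axis=1) > 0]
        groups = dict(zip(meta.sample_id, meta.pond_type))
        cfg = NullModelConfig(n_reps=120, seed=8)
        curve = nst_by_occupancy(sub, groups, cfg, mode="at_least")
        full = nst(sub, groups, cfg)
        for g in ("polygonal",):
            assert curve.loc[1, g] == pytest.approx(full[g])

    def test_exact_mode_partitions(self):
        table = pd.DataFrame(
            {"a": [1, 1, 0, 2], "b": [1, 0, 1, 2], "c": [1, 1, 1, 2]},
            index=list("wxyz"),
        )
        occ = assembly.occupancy(table)
        assert occ.tolist() == [3, 2, 2, 3]


class TestBetaMntdNti:
    def test_identical_communities_zero(self, balanced_tree):
        table = pd.DataFrame({"a": [1, 2, 0, 0], "b": [1, 2, 0, 0]},
                             index=list("ABCD"))
        bm = beta_mntd(table, balanced_tree)
        assert bm.loc["a", "b"] == 0.0

    def test_hand_computed_balanced_tree(self, balanced_tree):
        # {A,B} vs {C,D} equal abundance on unit-branch balanced tree: every
        # cross nearest-taxon distance is 4, so betaMNTD = 4
        table = pd.DataFrame({"k": [1, 1, 0, 0], "m": [0, 0, 1, 1]},
                             index=list("ABCD"))
        bm = beta_mntd(table, balanced_tree)
        assert bm.loc["k", "m"] == pytest.approx(4.0)

    def test_abundance_weighting(self, balanced_tree):
        # community k = {A}, m = {B, C}: nearest distances A->B=2, B->A=2,
        # C->A=4; weighted by relative abundance of m
        table = pd.DataFrame({"k": [4, 0, 0, 0], "m": [0, 3, 1, 0]},
                             index=list("ABCD"))
        bm = beta_mntd(table, balanced_tree)
        expected = 0.5 * (1.0 * 2 + (0.75 * 2 + 0.25 * 4))
        assert bm.loc["k", "m"] == pytest.approx(expected)

    def test_matches_picante_comdistnt(self, tmp_path):
        # independent oracle: R picante's comdistnt on the same inputs
        nwk = synthetic.simulate_tree(8, seed=2)
        tree = TreeNode.read(_io.StringIO(nwk))
        rng = np.random.default_rng(0)
        otus = [t.name for t in tree.tips()]
        counts = rng.integers(0, 20, size=(8, 4))
        counts[0:3, 0] = 0
        table = pd.DataFrame(counts, index=otus, columns=list("wxyz"))
        bm = beta_mntd(table, tree)
        (tmp_path / "tree.nwk").write_text(nwk + "\n")
        table.T.to_csv(tmp_path / "comm.csv")
        script = (
            'suppressMessages(library(picante));'
            'comm <- as.matrix(read.csv("comm.csv", row.names=1,'
            ' check.names=FALSE));'
            'tree <- read.tree("tree.nwk");'
            'res <- as.matrix(comdistnt(comm, cophenetic(tree),'
            ' abundance.weighted=TRUE));'
            'write.csv(res, "bmntd.csv")'
        )
        subprocess.run(["Rscript", "-e", script], cwd=tmp_path, check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "bmntd.csv", index_col=0)
        diff = (bm.loc[ref.index, ref.columns] - ref).abs().max().max()
        assert diff < 1e-10

    def test_missing_otu_raises_with_names(self, balanced_tree):
        table = pd.DataFrame({"a": [1, 1], "b": [1, 1]}, index=["A", "ZZZ"])
        with pytest.raises(ValueError, match="ZZZ"):
            beta_mntd(table, balanced_tree)

    def test_whole_matrix_null_degenerate_pair_warns(self, balanced_tree):
        table = pd.DataFrame(
            {"a": [1, 1, 1, 1], "b": [1, 1, 1, 1]}, index=list("ABCD")
        )
        with pytest.warns(UserWarning):
            z = beta_nti(table, balanced_tree, n_reps=20, seed=0,
                         shuffle="whole_matrix")
        assert np.isnan(z.loc["a", "b"])

    def test_identical_pair_strongly_negative(self):
        nwk = synthetic.simulate_tree(40, seed=3)
        tree = TreeNode.read(_io.StringIO(nwk))
        comm = sparse_random_communities(tree, n_samples=3, richness=10,
                                         seed=1)
        comm["b"] = comm["s0"]
        z = beta_nti(comm, tree, n_reps=199, seed=4)
        assert z.loc["s0", "b"] < -2.0


class TestAssemblySummary:
    def test_table2_style_output(self, neutral_metacommunity):
        table, meta = neutral_metacommunity
        sub = table.iloc[:, [0, 1, 2, 10, 11, 12]]
        sub = sub.loc[sub.sum(axis=1) > 0]
        groups = dict(zip(meta.sample_id, meta.pond_type))
        nwk = synthetic.simulate_tree(sub.shape[0], seed=5,
                                      labels=list(sub.index))
        tree = TreeNode.read(_io.StringIO(nwk))
        summary = assembly.assembly_summary(
            sub, groups, tree=tree,
            config=NullModelConfig(n_reps=120, seed=9), bnti_reps=59,
        )
        assert set(summary.index) == {"polygonal", "trough", "between"}
        for name in ("NST_pct", "RC_middle_pct", "mean_bNTI"):
            assert name in summary.columns
        rc_cols = [c for c in summary.columns if c.startswith("RC_")]
        assert np.allclose(summary[rc_cols].sum(axis=1), 100.0)
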