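"""Tests for differential lipid analysis, enrichment, and ordination."""

import numpy as np
import pandas as pd
import pytest

import actilipid as al
from actilipid import lipidomics as lip
from actilipid.simulate import LipidEffect, LipidomicsSimConfig, simulate_lipidomics


def toy_table(n_classes=2, per_class=5, n_per_group=4, seed=0, shift_class=None,
              shift=0.0):
    """Small hand-sized table: classes K0, K1, ... with 2 chains per lipid."""
    rng = np.random.default_rng(seed)
    classes = [f"K{i}" for i in range(n_classes) for _ in range(per_class)]
    chains = [["16:0", "18:1"] if c == "K0" else ["18:0", "22:6"] for c in classes]
    ids = [f"{c} #{i}" for i, c in enumerate(classes)]
    n = 2 * n_per_group
    log2 = rng.normal(10, 1, size=(len(ids), 1)) + rng.normal(0, 0.3, (len(ids), n))
    if shift_class is not None:
        mask = np.array([c == shift_class for c in classes])
        log2[mask, n_per_group:] += shift
    abundance = pd.DataFrame(
        2.0 ** log2,
        index=pd.Index(ids, name="lipid_id"),
        columns=[f"s{i}" for i in range(n)],
    )
    lipids = pd.DataFrame(
        {"lipid_class": classes, "acyl_chains": chains}, index=abundance.index
    )
    samples = pd.DataFrame(
        {
            "genotype": ["WT"] * n_per_group + ["MUT"] * n_per_group,
            "diet": ["chow", "AIN93G"] * n_per_group,
            "sex": "male",
        },
        index=pd.Index(abundance.columns, name="sample_id"),
    )
    return al.LipidTable(abundance=abundance, lipids=lipids, samples=samples)


# ---------------------------------------------------------------------------
# table I/O and validation


class TestLipidTable:
    def test_round_trip_through_files(self, tmp_path):
        table = toy_table()
        table.write(tmp_path / "toy")
        back = lip.read_lipid_table(
            tmp_path / "toy.abundance.tsv",
            tmp_path / "toy.annotations.tsv",
            tmp_path / "toy.samples.tsv",
        )
        assert back.n_lipids == table.n_lipids
        np.testing.assert_allclose(back.abundance.to_numpy(), table.abundance.to_numpy())
        assert back.lipids["acyl_chains"].iloc[0] == ["16:0", "18:1"]

    def test_duplicate_lipid_id_rejected(self):
        table = toy_table()
        dup = table.abundance.copy()
        dup.index = ["same"] * len(dup)
        with pytest.raises(ValueError):
            al.LipidTable(dup, table.lipids.set_index(dup.index), table.samples)

    def test_dimension_mismatch_rejected(self, tmp_path):
        table = toy_table()
        table.write(tmp_path / "toy")
        other = toy_table(seed=1)
        other.abundance.iloc[:3].to_csv(tmp_path / "short.abundance.tsv", sep="\t")
        with pytest.raises(ValueError, match="lipid_ids differ"):
            lip.read_lipid_table(
                tmp_path / "short.abundance.tsv",
                tmp_path / "toy.annotations.tsv",
                tmp_path / "toy.samples.tsv",
            )

    def test_unknown_class_warns_but_passes(self, tmp_path):
        table = toy_table()
        table.write(tmp_path / "toy")
        with pytest.warns(UserWarning, match="unknown lipid class"):
            back = lip.read_lipid_table(
                tmp_path / "toy.abundance.tsv",
                tmp_path / "toy.annotations.tsv",
                tmp_path / "toy.samples.tsv",
            )
        assert set(back.classes()) == {"K0", "K1"}

    def test_default_composition_counts(self, null_lipid_table):
        assert null_lipid_table.n_lipids == 464
        assert null_lipid_table.classes().nunique() == 26
        assert len(null_lipid_table.fatty_acids()) == 29


# ---------------------------------------------------------------------------
# differential abundance


class TestDifferentialLipids:
    def test_injected_class_selected(self):
        table = toy_table(shift_class="K0", shift=3.0)
        diff = lip.differential_lipids(table, "genotype", "MUT", "WT")
        by_class = diff.join(pd.Series(table.classes(), name="cls"))
        assert diff.loc[by_class["cls"] == "K0", "selected"].mean() > 0.5

    def test_gate_is_conjunction(self, effect_lipid_table):
        table, _ = effect_lipid_table
        diff = lip.differential_lipids(table, "genotype", "MUT", "WT")
        expected = diff["testable"] & (diff["p"] < 0.05) & (diff["d"].abs() > 0.8)
        assert (diff["selected"] == expected).all()

    def test_p_only_gate_grows_selection(self, effect_lipid_table):
        """Dropping the effect-size arm of the gate can only add lipids."""
        table, _ = effect_lipid_table
        strict = lip.differential_lipids(table, "genotype", "MUT", "WT")
        loose = lip.differential_lipids(
            table, "genotype", "MUT", "WT", gate=lip.DifferentialGate(0.05, 0.0)
        )
        assert set(strict.index[strict.selected]) <= set(loose.index[loose.selected])

    def test_null_selection_rate_matches_significance_level(self, null_lipid_table):
        """At n = 8/8 any lipid with p < 0.05 necessarily has |d| > 1.07, so
        under the null the joint gate admits ~5% of lipids, no fewer."""
        diff = lip.differential_lipids(null_lipid_table, "genotype", "MUT", "WT")
        n_sel = diff["selected"].sum()
        assert 8 <= n_sel <= 40  # binomial(464, 0.05) within ~3.5 sd
        # the d-gate is implied by the p-gate at this sample size
        assert diff.loc[diff["p"] < 0.05, "d"].abs().min() > 0.8

    def test_zero_variance_lipid_flagged(self):
        table = toy_table()
        table.abundance.iloc[0, :] = 8.0
        with pytest.warns(UserWarning, match="zero-variance"):
            diff = lip.differential_lipids(table, "genotype", "MUT", "WT", log=False)
        assert not diff["testable"].iloc[0]
        assert not diff["selected"].iloc[0]

    def test_bh_column_dominates_raw_p(self, effect_lipid_table):
        table, _ = effect_lipid_table
        diff = lip.differential_lipids(table, "genotype", "MUT", "WT")
        ok = diff["testable"]
        assert (diff.loc[ok, "p_adj"] >= diff.loc[ok, "p"] - 1e-12).all()

    def test_effect_size_recovery_medians(self):
        """The median estimated |d| across effect lipids and seeds lands
        within 0.3 of each injected d in {0.8, 1.5, 2.5} at n = 8/8 (the
        per-lipid sampling sd of d-hat is ~0.5 at this n, so only the
        central tendency is a meaningful recovery check)."""
        for d_target in (0.8, 1.5, 2.5):
            d_hats = []
            for seed in range(30):
                cfg = LipidomicsSimConfig(
                    n_lipids=464, seed=1000 + seed,
                    effects=[LipidEffect("PC", d_target)],
                )
                table, truth = simulate_lipidomics(cfg)
                diff = lip.differential_lipids(table, "genotype", "WT", "MUT")
                d_hats.extend(diff.loc[truth["is_effect"], "d"].abs())
            assert abs(np.median(d_hats) - d_target) <= 0.3, d_target


# ---------------------------------------------------------------------------
# enrichment


def results_frame(table, selected_ids):
    """Minimal differential-results frame with a prescribed selection."""
    return pd.DataFrame(
        {
            "selected": table.abundance.index.isin(selected_ids),
            "testable": True,
        },
        index=table.abundance.index,
    )


class TestEnrichment:
    def test_no_selection_all_p_one(self):
        table = toy_table()
        enr = lip.class_enrichment(results_frame(table, []), table)
        assert (enr["p"] == 1.0).all()

    def test_whole_class_selected_minimal_p(self):
        cfg = LipidomicsSimConfig(seed=31)
        table, _ = simulate_lipidomics(cfg)
        members = table.abundance.index[table.classes() == "PS"]
        enr = lip.class_enrichment(results_frame(table, members), table)
        import math

        n, k = table.n_lipids, len(members)
        assert enr["p"].idxmin() == "PS"
        assert enr.loc["PS", "p"] == pytest.approx(1 / (math.comb(n, k) / math.comb(n - k, 0)), rel=1e-6) or enr.loc["PS", "p"] == pytest.approx(
            math.comb(k, k) * math.comb(n - k, 0) / math.comb(n, k), rel=1e-6
        )

    def test_margins_sum_to_background(self, effect_lipid_table):
        table, _ = effect_lipid_table
        diff = lip.differential_lipids(table, "genotype", "MUT", "WT")
        enr = lip.class_enrichment(diff, table)
        background = int(diff["testable"].sum())
        assert ((enr[["a", "b", "c", "d"]].sum(axis=1)) == background).all()

    def test_module_p_equals_stats_core(self, effect_lipid_table):
        table, _ = effect_lipid_table
        diff = lip.differential_lipids(table, "genotype", "MUT", "WT")
        enr = lip.class_enrichment(diff, table)
        row = enr.iloc[0]
        res = al.fishers_exact_2x2([[row.a, row.b], [row.c, row.d]])
        assert row.p == pytest.approx(res.p_value)

    def test_fatty_acid_multi_membership_counts_once(self):
        table = toy_table()
        # give one lipid two identical chains; it must count once for 16:0
        table.lipids.at[table.lipids.index[0], "acyl_chains"] = ["16:0", "16:0"]
        enr = lip.fatty_acid_enrichment(
            results_frame(table, [table.lipids.index[0]]), table
        )
        assert enr.loc["16:0", "a"] == 1

    def test_targeted_chain_is_top_hit(self):
        cfg = LipidomicsSimConfig(seed=32)
        table, _ = simulate_lipidomics(cfg)
        members = [
            lid for lid, ch in table.lipids["acyl_chains"].items() if "20:1" in ch
        ]
        enr = lip.fatty_acid_enrichment(results_frame(table, members), table)
        assert enr["p"].idxmin() == "20:1"

    def test_single_shared_chain_uninformative(self):
        table = toy_table()
        table.lipids["acyl_chains"] = [["16:0"]] * table.n_lipids
        enr = lip.fatty_acid_enrichment(
            results_frame(table, table.abundance.index[:3]), table
        )
        assert list(enr.index) == ["16:0"]
        assert enr["p"].iloc[0] == 1.0


# ---------------------------------------------------------------------------
# ordination


class TestPca:
    def test_rank_one_data(self):
        table = toy_table()
        direction = np.linspace(-1, 1, table.n_samples)
        base = np.outer(np.ones(table.n_lipids), direction)
        table.abundance.iloc[:, :] = 2.0 ** (10 + base)
        res = lip.pca(table, n_components=2, scale=False)
        assert res.explained_variance[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, effect_lipid_table):
        table, _ = effect_lipid_table
        res = lip.pca(table, n_components=3)
        l = res.loadings.to_numpy()
        np.testing.assert_allclose(l.T @ l, np.eye(3), atol=1e-8)

    def test_full_reconstruction(self):
        table = toy_table()
        x = lip.preprocess(table, log=True, scale=True).to_numpy().T
        res = lip.pca(table, n_components=table.n_samples - 1, scale=True)
        x_hat = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.extra["mean"]
        np.testing.assert_allclose(x_hat, x, atol=1e-8)

    def test_genotype_separation_on_effect_table(self, effect_lipid_table):
        from sklearn.metrics import silhouette_score

        table, _ = effect_lipid_table
        res = lip.pca(table, n_components=2)
        labels = (table.samples["genotype"] == "MUT").astype(int)
        assert silhouette_score(res.scores.to_numpy(), labels) > 0

    def test_overlong_request_truncated(self):
        table = toy_table()
        with pytest.warns(UserWarning, match="rank"):
            res = lip.pca(table, n_components=50)
        assert res.scores.shape[1] == table.n_samples - 1


class TestHierarchicalClustering:
    def test_duplicated_blocks_recovered(self):
        table = toy_table(n_per_group=4, seed=3)
        x = table.abundance.to_numpy()
        x[:, 4:] = x[:, :4] * 50  # two blocks of identical structure
        table.abundance.iloc[:, :] = x
        clust = lip.hierarchical_clustering(table)
        ks = lip.cut_clusters(clust["linkage"], 2)
        assert len(set(ks[:4])) == 1 and len(set(ks[4:])) == 1 and ks[0] != ks[-1]

    def test_identical_samples_zero_heights(self):
        table = toy_table()
        table.abundance.iloc[:, :] = table.abundance.iloc[:, [0]].to_numpy()
        clust = lip.hierarchical_clustering(table)
        assert np.allclose(clust["linkage"][:, 2], 0.0)

    def test_newick_export_parses(self, effect_lipid_table):
        from io import StringIO

        from Bio import Phylo

        table, _ = effect_lipid_table
        clust = lip.hierarchical_clustering(table)
        nwk = lip.linkage_to_newick(clust["linkage"], clust["labels"])
        tree = Phylo.read(StringIO(nwk), "newick")
        assert tree.count_terminals() == table.n_samples

    def test_genotype_blocks_separate(self, effect_lipid_table):
        table, _ = effect_lipid_table
        clust = lip.hierarchical_clustering(table)
        ks = lip.cut_clusters(clust["linkage"], 2)
        genotype = (table.samples["genotype"] == "MUT").to_numpy()
        same = (ks == ks[genotype.argmax()]) == genotype
        assert same.all() or (~same).all()


class TestOplsda:
    def test_orthogonal_scores_uncorrelated_with_labels(self, effect_lipid_table):
        table, _ = effect_lipid_table
        res = lip.oplsda(table, "genotype", "MUT", n_orthogonal=2)
        y = (table.samples["genotype"] == "MUT").astype(float)
        for col in res.scores.columns:
            if col.startswith("orthogonal"):
                assert abs(np.corrcoef(res.scores[col], y)[0, 1]) < 1e-6

    def test_planted_discriminants_are_top_one_percent(self):
        """5 lipids carrying the whole class difference among 464 are
        exactly the top 1% by |predictive loading|."""
        cfg = LipidomicsSimConfig(seed=41)
        table, _ = simulate_lipidomics(cfg)
        planted = list(table.abundance.index[:5])
        x = table.abundance.copy()
        mut = (table.samples["genotype"] == "MUT").to_numpy()
        x.loc[planted, mut] *= 2.0 ** 4
        table = al.LipidTable(x, table.lipids, table.samples)
        res = lip.oplsda(table, "genotype", "MUT", top_fraction=0.01)
        assert res.extra["n_top"] == 5
        assert set(res.extra["top_lipids"]) == set(planted)

    def test_no_orthogonal_reduces_to_plsda(self, effect_lipid_table):
        """With zero orthogonal components the predictive weights equal
        single-component PLS weights (sklearn as independent reference)."""
        from sklearn.cross_decomposition import PLSRegression

        table, _ = effect_lipid_table
        res = lip.oplsda(table, "genotype", "MUT", n_orthogonal=0)
        x = lip.preprocess(table, log=True, scale=True).to_numpy().T
        y = np.where(table.samples["genotype"] == "MUT", 1.0, -1.0)
        pls = PLSRegression(n_components=1, scale=False).fit(x, y - y.mean())
        w_ref = pls.x_weights_[:, 0]
        w = res.extra["weights_predictive"]
        cos = abs(w @ w_ref) / (np.linalg.norm(w) * np.linalg.norm(w_ref))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_permutation_reference_below_observed(self, effect_lipid_table):
        """Cross-validated Q2Y of the true labels beats the 95th percentile
        of label-permuted Q2Y on effect-bearing data (the fitted R2Y is not
        informative at p >> n, where it saturates for any labels)."""
        table, _ = effect_lipid_table
        out = lip.oplsda_permutation_q2y(
            table, "genotype", "MUT", n_permutations=50, seed=5
        )
        assert out["q2y"] > np.percentile(out["permuted"], 95)
        assert out["q2y"] > 0.0

    def test_constant_label_rejected(self, effect_lipid_table):
        table, _ = effect_lipid_table
        mono = table.samples.copy()
        mono["genotype"] = "WT"
        with pytest.raises(ValueError):
            lip.oplsda(
                al.LipidTable(table.abundance, table.lipids, mono), "genotype", "WT"
            )


class TestDistanceAnova:
    def test_identical_samples_flagged(self):
        table = toy_table()
        table.abundance.iloc[:, :] = table.abundance.iloc[:, [0]].to_numpy()
        with pytest.raises(ValueError, match="degenerate"):
            lip.distance_anova(table, "genotype", "diet", scale=False)

    def test_genotype_shift_dominates_diet(self):
        """A genotype displacement with no diet effect yields a large
        genotype eta^2 and non-significant diet in most seeds."""
        wins = 0
        for seed in range(10):
            cfg = LipidomicsSimConfig(
                seed=600 + seed, group_sizes=(10, 10),
                effects=[LipidEffect("PC", 2.0), LipidEffect("PS", 2.0)],
            )
            table, _ = simulate_lipidomics(cfg)
            diets = np.tile(["chow", "AIN93G"], 10)
            samples = table.samples.copy()
            samples["diet"] = diets
            table = al.LipidTable(table.abundance, table.lipids, samples)
            res = {r.extra["effect_name"]: r for r in lip.distance_anova(table)}
            if (
                res["A"].effect.value > res["B"].effect.value
                and res["B"].p_value > 0.05
            ):
                wins += 1
        assert wins >= 9
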