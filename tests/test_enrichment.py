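import numpy as np
import pandas as pd
import pytest
from conftest import make_universe, random_universe
from oracles import brute_force_bh, brute_force_es

from cansys.enrichment import (EnrichmentConfig, GeneSet, _es_from_positions,
                               _pathway_seed, _sample_subsets, bh_adjust,
                               build_universe, cansys_score, enrich_gene_sets,
                               enrichment_score, normalize_es, parse_gmt,
                               permutation_test, run_sample)
from cansys.impact import DependencyTable
from cansys.variants import AnnotatedVariant, FilterPolicy


def impact_df(mapping):
    return pd.DataFrame({"gene": list(mapping), "impact": list(mapping.values())})


class TestBuildUniverse:
    def test_pads_unaltered_with_zero(self):
        table = impact_df({"a": 0.3, "b": 0.2, "c": 0.1})
        u = build_universe(table, ["a", "b", "c", "d", "e"], {})
        assert u.n_total == 5
        assert list(u.impacts) == [0.3, 0.2, 0.1, 0.0, 0.0]

    def test_tie_break_alphabetical(self):
        table = impact_df({"z": 0.5, "a": 0.5, "m": 0.5})
        u = build_universe(table, ["z", "a", "m"], {})
        assert u.genes == ("a", "m", "z")

    def test_unexpressed_excluded_entirely(self):
        table = impact_df({"a": 0.3, "b": 0.2})
        u = build_universe(table, ["a", "b", "c"], {"b": False})
        assert u.genes == ("a", "c")

    def test_exclusion_differs_from_zero_impact(self):
        # DERIVED: excluding a gene changes the P_Miss denominator, so the
        # brute-force ES differs from merely zeroing its impact.
        table = impact_df({"a": 0.5, "b": 0.45, "c": 0.4})
        members = {"b", "c"}
        excl = build_universe(table, ["a", "b", "c", "d"], {"d": False})
        incl = build_universe(table, ["a", "b", "c", "d"], {})
        es_excl = brute_force_es(excl.genes, excl.impacts, members)
        es_incl = brute_force_es(incl.genes, incl.impacts, members)
        assert es_excl != pytest.approx(es_incl)
        assert enrichment_score(excl, members)[0] == pytest.approx(es_excl)

    def test_empty_universe_fatal(self):
        with pytest.raises(ValueError):
            build_universe(impact_df({}), [], {})


class TestEnrichmentScore:
    def test_perfect_enrichment(self):
        u = make_universe([1.0, 0.0, 0.0, 0.0])
        es, trace = enrichment_score(u, {u.genes[0]})
        assert es == pytest.approx(1.0)
        assert trace[0] == pytest.approx(1.0)

    def test_hand_walk(self):
        # DERIVED: impacts [0.5,0.3,0.2,0,0], S = ranks {1,3}
        u = make_universe([0.5, 0.3, 0.2, 0.0, 0.0])
        members = {u.genes[0], u.genes[2]}
        es, trace = enrichment_score(u, members)
        np.testing.assert_allclose(
            trace, [0.5, 0.5 - 1 / 3, 0.7 - 1 / 3, 0.7 - 2 / 3, -0.3],
            atol=1e-12)
        assert es == pytest.approx(0.5)

    def test_bottom_zero_gene_pos_vs_abs(self):
        # DERIVED: S = bottom zero-impact gene; pos -> 0, abs -> 1
        u = make_universe([1.0, 1.0, 1.0, 0.0])
        members = {u.genes[3]}
        assert enrichment_score(u, members, "pos")[0] == 0.0
        assert enrichment_score(u, members, "abs")[0] == pytest.approx(1.0)

    def test_invalid_sizes(self):
        u = make_universe([0.5, 0.3])
        with pytest.raises(ValueError):
            enrichment_score(u, set())
        with pytest.raises(ValueError):
            enrichment_score(u, set(u.genes))

    def test_zero_total_rejected(self):
        u = make_universe([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            enrichment_score(u, {u.genes[0]})


class TestOracleEquivalence:
    @pytest.mark.parametrize("score_type", ["pos", "abs"])
    @pytest.mark.parametrize("p_hit_denom", ["total", "set"])
    def test_random_instances(self, score_type, p_hit_denom):
        rng = np.random.default_rng(7)
        for trial in range(60):
            n = int(rng.integers(5, 51))
            u = random_universe(rng, n)
            n_s = int(rng.integers(1, min(10, n - 1) + 1))
            members = set(rng.choice(u.genes, size=n_s, replace=False))
            expected = brute_force_es(u.genes, u.impacts, members, score_type,
                                      p_hit_denom)
            es, _ = enrichment_score(u, members, score_type, p_hit_denom)
            assert es == pytest.approx(expected, abs=1e-12)
            pos = u.positions(members)
            fast = _es_from_positions(pos[None, :], u.impacts, u.impact_total,
                                      n, score_type, p_hit_denom)[0]
            assert fast == pytest.approx(expected, abs=1e-12)

    def test_trace_conservation(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(5, 40))
            u = random_universe(rng, n, zeros_fraction=0.2)
            n_s = int(rng.integers(1, n - 1))
            members = set(rng.choice(u.genes, size=n_s, replace=False))
            _, trace = enrichment_score(u, members)
            p_hit_end = sum(u.impacts[i] for i, g in enumerate(u.genes)
                            if g in members) / u.impact_total
            assert trace[-1] == pytest.approx(p_hit_end - 1.0, abs=1e-12)


class TestSampleSubsets:
    @pytest.mark.parametrize("n,s", [(100, 4), (50, 30), (20, 19)])
    def test_rows_sorted_distinct(self, n, s):
        rng = np.random.default_rng(1)
        draws = _sample_subsets(rng, 500, n, s)
        assert draws.shape == (500, s)
        assert (np.diff(draws, axis=1) > 0).all()
        assert draws.min() >= 0 and draws.max() < n

    def test_approximately_uniform(self):
        rng = np.random.default_rng(2)
        draws = _sample_subsets(rng, 4000, 10, 3)
        counts = np.bincount(draws.ravel(), minlength=10)
        freqs = counts / counts.sum()
        assert np.abs(freqs - 0.1).max() < 0.02

    def test_subset_too_large(self):
        with pytest.raises(ValueError):
            _sample_subsets(np.random.default_rng(0), 10, 5, 5)


class TestPermutationTest:
    def test_pval_floor_for_dominant_set(self):
        impacts = np.zeros(50)
        impacts[:3] = [0.5, 0.4, 0.3]
        u = make_universe(impacts)
        res = permutation_test(u, set(u.genes[:3]), nperm=200, seed=0)
        assert res.pval == pytest.approx(1 / 201)

    def test_reproducible_and_order_independent(self):
        rng = np.random.default_rng(3)
        u = random_universe(rng, 100)
        members = set(u.genes[10:20])
        seed = _pathway_seed(42, "PATH1")
        a = permutation_test(u, members, 300, _pathway_seed(42, "PATH1"))
        b = permutation_test(u, members, 300, seed)
        assert a == b
        # a different pathway id gives a different stream
        c = permutation_test(u, members, 300, _pathway_seed(42, "PATH2"))
        assert c.null_mean != a.null_mean

    def test_nperm_minimum(self):
        u = make_universe([0.5, 0.3, 0.1])
        with pytest.raises(ValueError):
            permutation_test(u, {u.genes[0]}, nperm=50, seed=0)

    def test_doubling_nperm_keeps_es(self):
        rng = np.random.default_rng(4)
        u = random_universe(rng, 80)
        members = set(rng.choice(u.genes, size=8, replace=False))
        r1 = permutation_test(u, members, 500, seed=1)
        r2 = permutation_test(u, members, 1000, seed=1)
        assert r1.es_obs == r2.es_obs
        assert abs(r1.pval - r2.pval) < 4 * np.sqrt(0.25 / 500)


class TestNormalizeEs:
    def test_ratio(self):
        assert normalize_es(0.5, 0.25) == pytest.approx(2.0)

    def test_zero_es(self):
        assert normalize_es(0.0, 0.3) == 0.0

    def test_equal_gives_one(self):
        assert normalize_es(0.4, 0.4) == pytest.approx(1.0)

    def test_zero_null_mean(self):
        assert normalize_es(0.0, 0.0) == 0.0
        assert np.isnan(normalize_es(0.5, 0.0))


class TestBhAdjust:
    def test_closed_forms(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.5]), [0.5])
        np.testing.assert_allclose(bh_adjust([0.05, 0.01]), [0.05, 0.02])

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    def test_against_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
            ours = bh_adjust(p)
            np.testing.assert_allclose(ours, brute_force_bh(list(p)), atol=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, sm, atol=1e-12)

    def test_padj_at_least_pval(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(1e-6, 1.0, size=100)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_invalid_pvals(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestCansysScore:
    def test_mean_times_nes(self):
        assert cansys_score(2.0, [0.2, 0.0], 2) == pytest.approx(0.2)

    def test_zero_impacts(self):
        assert cansys_score(3.0, [0.0, 0.0], 2) == 0.0

    def test_ceiling_case(self):
        assert cansys_score(1.0, [0.99], 1) == pytest.approx(0.99)


def make_variants(gene_cadds):
    out = []
    pos = 100
    for gene, cadd in gene_cadds:
        pos += 1
        out.append(AnnotatedVariant(
            chrom="chr1", pos=pos, ref="A", alt="T", vtype="SNV",
            origin="somatic", allele_depth=20, total_depth=40, vaf=0.5,
            cadd_phred=cadd, gnomad_af=0.0, gene=gene))
    return out


class TestRunSample:
    def setup_method(self):
        genes = [f"g{i:02d}" for i in range(30)]
        self.sets = {
            "HOT": GeneSet("HOT", "hot", frozenset(genes[:5])),
            "COLD": GeneSet("COLD", "cold", frozenset(genes[10:20])),
        }
        self.dep = DependencyTable(
            scores=pd.Series({g: 0.9 if g in self.sets["HOT"].genes else 0.1
                              for g in genes}), lineage="x", n_cell_lines=1)
        self.variants = make_variants(
            [(g, 35.0) for g in sorted(self.sets["HOT"].genes)]
            + [("g15", 16.0)])

    def config(self, **kw):
        base = dict(nperm_somatic=300, nperm_germline=300, seed=1)
        base.update(kw)
        return EnrichmentConfig(**base)

    def test_hot_pathway_tops_ranking(self):
        results = run_sample({"somatic": self.variants}, None, self.sets,
                             self.dep, self.config())
        df = results["somatic"].sort_values("CanSys", ascending=False)
        assert df.iloc[0]["pathway_id"] == "HOT"
        assert bool(df.iloc[0]["significant"])
        assert df.iloc[0]["pval"] == pytest.approx(1 / 301)

    def test_zero_passing_variants_empty_table(self):
        results = run_sample({"somatic": []}, None, self.sets, self.dep,
                             self.config())
        assert len(results["somatic"]) == 0

    def test_deterministic(self):
        r1 = run_sample({"somatic": self.variants}, None, self.sets, self.dep,
                        self.config())
        r2 = run_sample({"somatic": self.variants}, None, self.sets, self.dep,
                        self.config())
        pd.testing.assert_frame_equal(r1["somatic"], r2["somatic"])

    def test_identity_on_every_record(self):
        results = run_sample({"somatic": self.variants}, None, self.sets,
                             self.dep, self.config())
        df = results["somatic"]
        np.testing.assert_allclose(df["CanSys"], df["NES"] * df["mean_impact"],
                                   atol=1e-12)
        assert (df["padj"] >= df["pval"] - 1e-15).all()

    def test_singleton_sets_skipped(self):
        sets = dict(self.sets)
        sets["SOLO"] = GeneSet("SOLO", "solo", frozenset({"g00"}))
        results = run_sample({"somatic": self.variants}, None, sets, self.dep,
                             self.config())
        assert "SOLO" not in set(results["somatic"]["pathway_id"])

    def test_padj_threshold_monotone(self):
        strict = run_sample({"somatic": self.variants}, None, self.sets,
                            self.dep, self.config(padj_threshold=0.05))
        loose = run_sample({"somatic": self.variants}, None, self.sets,
                           self.dep, self.config(padj_threshold=0.25))
        sig_strict = set(strict["somatic"].loc[strict["somatic"]["significant"],
                                               "pathway_id"])
        sig_loose = set(loose["somatic"].loc[loose["somatic"]["significant"],
                                             "pathway_id"])
        assert sig_strict <= sig_loose

    def test_germline_policy_applied(self):
        # germline variants need VAF > 0.20 and AF <= 0.001
        results = run_sample(
            {"germline": [AnnotatedVariant(
                chrom="chr1", pos=1, ref="A", alt="T", vtype="SNV",
                origin="germline", allele_depth=8, total_depth=80, vaf=0.1,
                cadd_phred=30.0, gnomad_af=0.0, gene="g00")]},
            None, self.sets, self.dep, self.config())
        assert len(results["germline"]) == 0


class TestParseGmt:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tfirst set\ta\tb\tc\nS2\tsecond\tx\ty\n\n")
        sets = parse_gmt(path)
        assert sets["S1"].genes == frozenset({"a", "b", "c"})
        assert sets["S2"].name == "second"

    def test_short_lines_skipped(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tonly_description\nS2\tok\tg1\tg2\n")
        sets = parse_gmt(path)
        assert list(sets) == ["S2"]
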