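"""Peptide aggregation, loess normalization, moderated t and networks."""

import numpy as np
import pandas as pd
import pytest

from avekit.proteomics import (aggregate_peptides, average_runs,
                               compare_with_rna, differential_proteins,
                               kinase_substrate_network, normalize_loess,
                               normalize_site, peptide_support)


class TestAggregatePeptides:
    def _table(self):
        return pd.DataFrame({
            "peptide": ["p1", "p2", "p3"],
            "protein": ["A", "A", "B"],
            "s1": [100, 50, 30],
            "s2": [10, 20, 5],
        })

    def test_peptides_sum_per_protein(self):
        out = aggregate_peptides(self._table())
        assert out.loc["A", "s1"] == 150 and out.loc["B", "s1"] == 30

    def test_totals_conserved(self):
        t = self._table()
        out = aggregate_peptides(t)
        assert out.to_numpy().sum() == t[["s1", "s2"]].to_numpy().sum()

    def test_row_order_irrelevant(self):
        t = self._table()
        out1 = aggregate_peptides(t)
        out2 = aggregate_peptides(t.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(out1, out2)

    def test_peptide_support_counts(self):
        sup = peptide_support(self._table())
        assert sup["A"] == 2 and sup["B"] == 1


class TestNormalizeLoess:
    def test_identical_columns_unchanged(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(5, 1, 200)
        mat = pd.DataFrame({c: base for c in "abc"})
        out = normalize_loess(mat)
        np.testing.assert_allclose(out.to_numpy(), mat.to_numpy(), atol=1e-9)

    def test_scale_factor_removed(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(5, 1, 300)
        mat = pd.DataFrame({"a": base, "b": base * 2, "c": base})
        out = normalize_loess(mat)
        ratio = out["b"].median() / out["a"].median()
        assert abs(ratio - 1.0) < 0.01

    def test_column_medians_converge_under_monotone_bias(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(5, 1, 300)
        mat = pd.DataFrame({"a": base, "b": base * 1.5, "c": base * 0.7})
        out = np.log2(normalize_loess(mat, n_cycles=40, tol=1e-9) + 1)
        med = out.median()
        assert med.max() - med.min() < 1e-6

    def test_zero_column_rejected(self):
        mat = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError):
            normalize_loess(mat)


class TestAverageRuns:
    def test_three_runs_average(self):
        m = pd.DataFrame({"r1": [10.0], "r2": [20.0], "r3": [30.0]},
                         index=["P"])
        out = average_runs(m, {"r1": "s", "r2": "s", "r3": "s"})
        assert out.loc["P", "s"] == 20.0

    def test_single_run_identity(self):
        m = pd.DataFrame({"r1": [7.0]}, index=["P"])
        out = average_runs(m, {"r1": "s"})
        assert out.loc["P", "s"] == 7.0

    def test_nan_run_skipped(self):
        m = pd.DataFrame({"r1": [10.0], "r2": [np.nan], "r3": [30.0]},
                         index=["P"])
        out = average_runs(m, {"r1": "s", "r2": "s", "r3": "s"})
        assert out.loc["P", "s"] == 20.0

    def test_all_nan_sample_rejected(self):
        m = pd.DataFrame({"r1": [np.nan], "r2": [np.nan]}, index=["P"])
        with pytest.raises(ValueError):
            average_runs(m, {"r1": "s", "r2": "s"})


class TestDifferentialProteins:
    def _groups(self, n=8):
        return {f"s{j}": ("emb" if j < n // 2 else "ab") for j in range(n)}

    def test_identical_means_not_de(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 0.3, (50, 8))
        mat = pd.DataFrame(2.0 ** x - 1, columns=[f"s{j}" for j in range(8)])
        de = differential_proteins(mat, self._groups())
        assert not de["de"].any()
        assert np.abs(de["log2fc"]).max() < 1.0

    def test_thresholds_flag_de(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 0.2, (100, 8))
        x[:10, :4] += 2.0
        mat = pd.DataFrame(2.0 ** x - 1, columns=[f"s{j}" for j in range(8)])
        de = differential_proteins(mat, self._groups())
        assert de["de"][:10].all() and not de["de"][10:].any()

    def test_planted_shift_power(self):
        """Two log2 units at within-group sd 0.3 (4 vs 4) is detected in
        at least 95% of proteins."""
        rng = np.random.default_rng(2)
        x = rng.normal(10, 0.3, (400, 8))
        x[:, :4] += 2.0
        mat = pd.DataFrame(2.0 ** x - 1, columns=[f"s{j}" for j in range(8)])
        de = differential_proteins(mat, self._groups())
        assert de["de"].mean() >= 0.95

    def test_flat_protein_p_one(self):
        mat = pd.DataFrame(np.full((1, 8), 5.0),
                           columns=[f"s{j}" for j in range(8)])
        de = differential_proteins(mat, self._groups())
        assert de["p"].iloc[0] == 1.0

    def test_welch_variant_available(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 0.4, (30, 8))
        mat = pd.DataFrame(2.0 ** x - 1, columns=[f"s{j}" for j in range(8)])
        de = differential_proteins(mat, self._groups(), test="welch")
        assert ((de["p"] > 0) & (de["p"] <= 1)).all()


class TestCompareWithRna:
    def test_identical_vectors_r_one(self):
        fc = pd.DataFrame({"log2fc": [1.0, -2.0, 0.5, 3.0]},
                          index=list("abcd"))
        _, r, _ = compare_with_rna(fc, fc)
        assert r == pytest.approx(1.0)

    def test_anticorrelated_vectors_r_minus_one(self):
        fc = pd.DataFrame({"log2fc": [1.0, -2.0, 0.5, 3.0]},
                          index=list("abcd"))
        neg = fc.copy()
        neg["log2fc"] *= -1
        _, r, _ = compare_with_rna(fc, neg)
        assert r == pytest.approx(-1.0)

    def test_mapping_table_joins_identifiers(self):
        prot = pd.DataFrame({"log2fc": [1.0, 2.0, 3.0]},
                            index=["P1", "P2", "P3"])
        rna = pd.DataFrame({"log2fc": [1.0, 2.0, 3.0]},
                           index=["g1", "g2", "g3"])
        mapping = pd.DataFrame({"gene": ["g1", "g2", "g3"],
                                "protein": ["P1", "P2", "P3"]})
        paired, r, _ = compare_with_rna(prot, rna, mapping)
        assert len(paired) == 3 and r == pytest.approx(1.0)

    def test_independent_fold_changes_uncorrelated(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(40):
            a = pd.DataFrame({"log2fc": rng.normal(0, 1, 100)},
                             index=[f"p{i}" for i in range(100)])
            b = pd.DataFrame({"log2fc": rng.normal(0, 1, 100)},
                             index=[f"p{i}" for i in range(100)])
            _, r, _ = compare_with_rna(a, b)
            hits += abs(r) < 0.3
        assert hits / 40 >= 0.95

    def test_too_few_shared_ids_rejected(self):
        a = pd.DataFrame({"log2fc": [1.0]}, index=["x"])
        with pytest.raises(ValueError):
            compare_with_rna(a, a)


class TestKinaseSubstrateNetwork:
    def _de(self):
        return pd.DataFrame({
            "protein": ["K8", "K8", "VIM"],
            "site": ["S23", "S74", "S39"],
            "side": ["embryonic", "embryonic", "abembryonic"]})

    def _interactions(self):
        return pd.DataFrame({
            "kinase": ["AKT1", "AKT1", "PKC", "CAMK2", "BAD"],
            "substrate": ["K8", "K8", "VIM", "VIM", "K8"],
            "site": ["s23", "S24", "S39", "T13", "not-a-site"]})

    def test_matching_sites_become_edges(self):
        nets = kinase_substrate_network(self._de(), self._interactions())
        assert ("AKT1", "K8@S23") in nets["embryonic"].edges()
        assert ("PKC", "VIM@S39") in nets["abembryonic"].edges()

    def test_site_mismatch_excluded(self):
        nets = kinase_substrate_network(self._de(), self._interactions())
        for g in nets.values():
            assert "K8@S24" not in g.nodes()
            assert "VIM@T13" not in g.nodes()

    def test_empty_de_list_empty_networks(self):
        de = self._de().iloc[:0]
        nets = kinase_substrate_network(de, self._interactions())
        assert all(g.number_of_edges() == 0 for g in nets.values())

    def test_bipartite_attributes_set(self):
        nets = kinase_substrate_network(self._de(), self._interactions())
        g = nets["embryonic"]
        assert g.nodes["AKT1"]["bipartite"] == 0
        assert g.nodes["K8@S23"]["bipartite"] == 1

    def test_site_normalization(self):
        assert normalize_site(" s23 ") == "S23"
        assert normalize_site("T013") == "T13"
        assert normalize_site("pS23") is None
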