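"""CNA recurrence, concordance screens and EEA derivation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eealineage import (
    CnaProfile,
    amplified_regions,
    cna_expression_association,
    cna_expression_correlation,
    derive_eea,
    generate_cohort,
    recurrently_amplified_genes,
)
from .conftest import small_config


def _cna(calls, prefix="p"):
    calls = np.asarray(calls, dtype=int)
    return CnaProfile(
        calls=pd.DataFrame(
            calls,
            index=[f"g{i}" for i in range(calls.shape[0])],
            columns=[f"{prefix}{j}" for j in range(calls.shape[1])],
        )
    )


class TestRecurrentAmplification:
    def test_boundary_forty_percent_included(self):
        cna = _cna([[1, 1, 0, 0, 0], [1, 1, 2, 0, 0]])  # 40% and 60%
        got = recurrently_amplified_genes(cna, min_frac=0.40)
        assert got == {"g0", "g1"}

    def test_rare_amplification_excluded(self):
        calls = np.zeros((1, 100), dtype=int)
        calls[0, 0] = 2
        assert recurrently_amplified_genes(_cna(calls)) == set()

    def test_matches_hand_count_on_toy_matrix(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(-2, 3, size=(5, 10))
        cna = _cna(calls)
        got = recurrently_amplified_genes(cna, min_frac=0.40)
        expected = {
            f"g{i}" for i in range(5) if (calls[i] >= 1).sum() / 10 >= 0.40
        }
        assert got == expected

    def test_high_level_threshold(self):
        cna = _cna([[1, 1, 1, 1]])
        cna.call_threshold = 2
        assert recurrently_amplified_genes(cna) == set()


class TestAmplifiedRegions:
    def _annotation(self):
        rows = []
        for i in range(10):
            rows.append((f"g{i}", "1", i * 100 + 1, i * 100 + 50, "1q1"))
        for i in range(10, 14):
            rows.append((f"g{i}", "2", i * 100 + 1, i * 100 + 50, "2q1"))
        for i in range(14, 20):
            rows.append((f"g{i}", "3", i * 100 + 1, i * 100 + 50, "3q1"))
        return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "cytoband"])

    def test_boundary_band_called(self):
        ann = self._annotation()
        amplified = {f"g{i}" for i in range(4)}  # 4 of 10 in band 1q1
        regions = amplified_regions(ann, amplified, min_frac=0.40)
        assert bool(regions.loc["1q1", "called"])

    def test_band_without_amplification_not_called(self):
        ann = self._annotation()
        regions = amplified_regions(ann, {f"g{i}" for i in range(4)}, min_frac=0.40)
        assert not regions.loc["2q1", "called"]
        assert not regions.loc["3q1", "called"]

    def test_fractions_match_brute_force(self):
        ann = self._annotation()
        rng = np.random.default_rng(1)
        amplified = set(rng.choice([f"g{i}" for i in range(20)], size=8, replace=False))
        regions = amplified_regions(ann, amplified, min_frac=0.40)
        for band, grp in ann.groupby("cytoband"):
            frac = grp["gene"].isin(amplified).mean()
            assert regions.loc[band, "fraction"] == pytest.approx(frac)
            assert regions.loc[band, "called"] == (frac >= 0.40)

    def test_invariant_under_gene_reordering(self):
        ann = self._annotation()
        amplified = {f"g{i}" for i in range(5)}
        a = amplified_regions(ann, amplified)
        b = amplified_regions(ann.sample(frac=1.0, random_state=3), amplified)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


class TestAssociation:
    def test_identical_distributions_not_flagged(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.lognormal(5, 0.3, size=(30, 20)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"p{j}" for j in range(20)],
        )
        calls = np.zeros((30, 20), dtype=int)
        calls[:, :8] = 1  # amplified group, but expression independent of it
        cna = _cna(calls)
        out = cna_expression_association(expr, cna)
        assert out.loc["g0", "fold_change"] == pytest.approx(0.0, abs=0.5)
        assert not out["flagged"].any()

    def test_gene_amplified_everywhere_is_indeterminate(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.lognormal(5, 0.3, size=(12, 10)),
            index=[f"g{i}" for i in range(12)],
            columns=[f"p{j}" for j in range(10)],
        )
        calls = np.zeros((12, 10), dtype=int)
        calls[0, :] = 2
        calls[1:, :4] = 1
        out = cna_expression_association(expr, _cna(calls))
        assert bool(out.loc["g0", "indeterminate"])

    def test_planted_cna_genes_flagged(self):
        flagged, total = 0, 0
        for seed in range(5):
            co = generate_cohort(small_config(seed=300 + seed))
            planted = co.gene_truth.loc[co.gene_truth["role"] == "cna_driven", "gene"]
            out = cna_expression_association(
                co.expression, co.cna, genes=list(planted)
            )
            flagged += int(out["flagged"].sum())
            total += len(planted)
        assert flagged / total >= 0.95

    def test_flag_implies_positive_difference(self):
        co = generate_cohort(small_config(seed=42))
        out = cna_expression_association(co.expression, co.cna,
                                         genes=list(co.expression.index[:150]))
        assert (out.loc[out["flagged"], "fold_change"] > 0).all()


class TestCorrelation:
    def test_affine_function_of_calls_gives_r1(self):
        calls = np.array([[0, 0, 1, 1, 2, 2]])
        expr = pd.DataFrame(
            2.0 ** (3.0 + 1.0 * calls.astype(float)),
            index=["g0"], columns=[f"p{j}" for j in range(6)],
        )
        out = cna_expression_correlation(expr, _cna(calls), pseudocount=0)
        assert out.loc["g0", "pearson_r"] == pytest.approx(1.0)
        assert bool(out.loc["g0", "flagged"])

    def test_constant_calls_undefined(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.lognormal(4, 0.5, size=(1, 6)),
                            index=["g0"], columns=[f"p{j}" for j in range(6)])
        out = cna_expression_correlation(expr, _cna(np.ones((1, 6), dtype=int)))
        assert np.isnan(out.loc["g0", "pearson_r"])
        assert not bool(out.loc["g0", "flagged"])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.lognormal(4, 1, size=(1, 6)),
                            index=["g0"], columns=[f"p{j}" for j in range(6)])
        calls = rng.integers(-1, 3, size=(1, 6))
        out = cna_expression_correlation(expr, _cna(calls), pseudocount=1.0)
        ref, _ = stats.pearsonr(np.log2(expr.iloc[0] + 1.0), calls[0])
        assert out.loc["g0", "pearson_r"] == pytest.approx(ref, rel=1e-12)


class TestDeriveEea:
    def test_identity_when_nothing_flagged(self):
        genes = {f"g{i}" for i in range(10)}
        der = derive_eea(genes)
        assert der.eea_genes == genes
        assert der.removal_table()["reason"].eq("kept").all()

    def test_disjoint_removals_set_arithmetic(self):
        genes = {f"g{i}" for i in range(10)}
        ann = pd.DataFrame({
            "gene": sorted(genes),
            "chrom": "1",
            "start": 1, "end": 2,
            "cytoband": ["amp"] * 2 + ["ok"] * 8,
        })
        regions = pd.DataFrame(
            {"cytoband": ["amp", "ok"], "n_genes": [2, 8], "n_amplified": [2, 0],
             "fraction": [1.0, 0.0], "called": [True, False]}
        ).set_index("cytoband", drop=False)
        corr = pd.DataFrame(
            {"gene": sorted(genes), "pearson_r": 0.0, "flagged": False}
        ).set_index("gene", drop=False)
        corr.loc["g2", "flagged"] = True
        der = derive_eea(
            genes,
            correlation=corr,
            region_calls=regions,
            gene_annotations=ann,
            mutated_list={"g3"},
            ambiguous_list={"g4"},
        )
        assert len(der.eea_genes) == 5
        assert der.primary_reason["g0"] == "region"
        assert der.primary_reason["g2"] == "correlation"
        assert der.primary_reason["g3"] == "mutated"
        assert der.primary_reason["g4"] == "ambiguous"

    def test_eea_is_subset_and_shrinks_with_exclusions(self):
        genes = {f"g{i}" for i in range(8)}
        base = derive_eea(genes)
        more = derive_eea(genes, mutated_list={"g1", "g2"})
        assert more.eea_genes <= base.eea_genes <= genes
        assert len(more.eea_genes) == len(base.eea_genes) - 2

    def test_synthetic_truth_recovery(self):
        """CNA-driven genes removed, early-burst genes kept, across seeds."""
        kept_eb = removed_cna = total_eb = total_cna = 0
        for seed in range(5):
            co = generate_cohort(small_config(seed=400 + seed))
            truth = co.gene_truth.set_index("gene")["role"]
            frequent = set(truth.index[truth.isin(["early_burst", "cna_driven"])])
            amplified = recurrently_amplified_genes(co.cna)
            regions = amplified_regions(co.genes, amplified)
            assoc = cna_expression_association(co.expression, co.cna,
                                               genes=sorted(frequent))
            corr = cna_expression_correlation(co.expression, co.cna,
                                              genes=sorted(frequent))
            der = derive_eea(frequent, association=assoc, correlation=corr,
                             region_calls=regions, gene_annotations=co.genes,
                             amplified_fraction=co.cna.amplified_fraction())
            eb = set(truth.index[truth == "early_burst"])
            cd = set(truth.index[truth == "cna_driven"])
            kept_eb += len(eb & der.eea_genes)
            removed_cna += len(cd - der.eea_genes)
            total_eb += len(eb)
            total_cna += len(cd)
        assert kept_eb / total_eb >= 0.90
        assert removed_cna / total_cna >= 0.90
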