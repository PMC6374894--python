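from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from reodeg.pairs import binomial_reo_pvalue, identify_stable_pairs, pair_support_counts
from reodeg.rankcomp import (
    RankCompV2,
    call_degs,
    fisher_exact_two_sided,
    gene_table,
    overlap_pairs,
)
from reodeg.simulate import BaselineParams, apply_fc, assign_fc_groups, generate_baseline

from conftest import make_ordered_matrix


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Independent oracle: rational enumeration of all fixed-margin tables."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, r1)
    probs = {
        x: Fraction(comb(c1, x) * comb(n - c1, r1 - x), denom)
        for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((1, 1, 1, 1), 1.0),
            ((5, 0, 0, 5), 2 / 252),
            ((2, 0, 0, 2), 2 / 6),
            ((0, 0, 0, 0), 1.0),
        ],
    )
    def test_examples(self, table, expected):
        assert fisher_exact_two_sided(*table) == pytest.approx(expected, rel=1e-9)

    def test_matches_rational_enumeration_small_margins(self):
        for a in range(7):
            for b in range(7):
                for c in range(7):
                    for d in range(7):
                        if a + b + c + d == 0:
                            continue
                        expected = float(exact_fisher_two_sided(a, b, c, d))
                        got = fisher_exact_two_sided(a, b, c, d)
                        assert got == pytest.approx(expected, rel=1e-7, abs=1e-12)

    def test_matches_scipy_on_large_tables(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        for _ in range(50):
            a, b, c, d = rng.integers(0, 400, size=4)
            if a + b + c + d == 0:
                continue
            expected = scipy_fisher([[a, b], [c, d]])[1]
            assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(expected, rel=1e-6)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 0, 0, 1)


def _stable_all(matrix):
    return identify_stable_pairs(matrix, fdr=1.0)


class TestOverlapPairs:
    def _two_gene_matrix(self, a_above_b: bool):
        hi, lo = (5.0, 1.0) if a_above_b else (1.0, 5.0)
        return pd.DataFrame({f"s{j}": [hi, lo] for j in range(10)}, index=["A", "B"])

    def test_consistent_pair(self):
        ov = overlap_pairs(_stable_all(self._two_gene_matrix(True)),
                           _stable_all(self._two_gene_matrix(True)))
        assert len(ov) == 1 and ov.n_reversed == 0

    def test_reversed_pair(self):
        ov = overlap_pairs(_stable_all(self._two_gene_matrix(True)),
                           _stable_all(self._two_gene_matrix(False)))
        assert len(ov) == 1 and ov.n_reversed == 1

    def test_disjoint_sets_error(self):
        # same universe, but phenotype B only orders C vs D while A vs B is tied
        normal = pd.DataFrame({f"s{j}": [5.0, 1.0, 3.0, 3.0] for j in range(10)},
                              index=["A", "B", "C", "D"])
        disease = pd.DataFrame({f"s{j}": [4.0, 4.0, 9.0, 2.0] for j in range(10)},
                               index=["A", "B", "C", "D"])
        sp_n = _stable_all(normal)
        sp_d = _stable_all(disease)
        sp_n.pairs = sp_n.pairs[sp_n.pairs["winner"] == "A"].reset_index(drop=True)
        sp_d.pairs = sp_d.pairs[sp_d.pairs["winner"] == "B"].reset_index(drop=True)
        with pytest.raises(ValueError, match="no stable background"):
            overlap_pairs(sp_n, sp_d)


class TestGeneTable:
    @pytest.fixture
    def overlaps(self):
        # G above P1 in both phenotypes; G above P2 in normal, below in disease
        normal = pd.DataFrame({f"s{j}": [9.0, 5.0, 7.0] for j in range(12)},
                              index=["G", "P1", "P2"])
        disease = pd.DataFrame({f"s{j}": [6.0, 2.0, 8.0] for j in range(12)},
                               index=["G", "P1", "P2"])
        return overlap_pairs(_stable_all(normal), _stable_all(disease))

    def test_manual_counts(self, overlaps):
        assert gene_table("G", overlaps) == (2, 0, 1, 1)

    def test_exclusion_drops_partner_pairs(self, overlaps):
        assert gene_table("G", overlaps, excluded={"P2"}) == (1, 0, 1, 0)

    def test_gene_without_pairs_is_degenerate(self, overlaps):
        # exclude both partners: zero usable pairs
        assert gene_table("G", overlaps, excluded={"P1", "P2"}) == (0, 0, 0, 0)

    def test_margin_conservation_random(self, rng):
        normal = pd.DataFrame(rng.random((8, 10)), index=[f"g{i}" for i in range(8)],
                              columns=[f"s{j}" for j in range(10)])
        disease = pd.DataFrame(rng.random((8, 10)), index=normal.index,
                               columns=normal.columns)
        ov = overlap_pairs(_stable_all(normal), _stable_all(disease))
        for gene in normal.index:
            a, b, c, d = gene_table(gene, ov)
            assert a + b == c + d


def brute_force_call(normal, disease, stable_fdr, deg_fdr, max_iter=20):
    """Independent re-derivation of the caller from first principles."""
    def stable(mat):
        out = {}
        sup = pair_support_counts(mat)
        tested = sup[sup["n_eff"] > 0]
        pvals = [binomial_reo_pvalue(max(r.s_ij, r.s_ji), r.n_eff)
                 for r in tested.itertuples()]
        qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else []
        for r, q in zip(tested.itertuples(), qvals):
            if q <= stable_fdr and r.s_ij != r.s_ji:
                direction = 1 if r.s_ij > r.s_ji else -1
                out[(r.gene_i, r.gene_j)] = direction
        return out

    sn, sd = stable(normal), stable(disease)
    common = sorted(set(sn) & set(sd))
    genes = sorted(normal.index)
    candidates: set[str] = set()
    for _ in range(max_iter):
        rows = []
        for gene in genes:
            a = b = c = d = 0
            for (gi, gj) in common:
                if gene == gi:
                    partner, above_n, above_d = gj, sn[(gi, gj)] > 0, sd[(gi, gj)] > 0
                elif gene == gj:
                    partner, above_n, above_d = gi, sn[(gi, gj)] < 0, sd[(gi, gj)] < 0
                else:
                    continue
                if partner in candidates:
                    continue
                a += above_n
                b += not above_n
                c += above_d
                d += not above_d
            if a + b > 0:
                p = 1.0 if a == c else float(exact_fisher_two_sided(a, b, c, d))
                rows.append((gene, p, a, c))
        q = multipletests([r[1] for r in rows], method="fdr_bh")[1]
        new = {(r[0], "up" if r[3] > r[2] else "down")
               for r, qv in zip(rows, q) if qv <= deg_fdr and r[2] != r[3]}
        if len(new) == len(candidates):
            return new
        candidates = {g for g, _ in new}
    return new


class TestCallDegs:
    def test_identical_matrices_give_no_degs(self):
        m = generate_baseline(BaselineParams(n_genes=40, n_samples=12, seed=2))
        result = call_degs(m, m.copy())
        assert len(result.degs) == 0
        assert result.n_reversed == 0

    def test_spiked_gene_called_up_with_no_false_positives(self):
        params = BaselineParams(n_genes=50, n_samples=20, seed=11)
        normal = generate_baseline(params)
        spiked = normal.index[7]
        disease = normal.copy().astype(float)
        disease.loc[spiked] *= 8.0
        result = call_degs(normal, disease)
        assert result.degs["gene"].tolist() == [spiked]
        assert result.degs["direction"].tolist() == ["up"]

    def test_agrees_with_brute_force_recomputation(self):
        params = BaselineParams(n_genes=15, n_samples=10, seed=5)
        normal = generate_baseline(params)
        truth = assign_fc_groups(normal.index, 2, 1, "uniform:4", seed=9)
        disease = apply_fc(normal, truth)
        result = call_degs(normal, disease)
        got = set(zip(result.degs["gene"], result.degs["direction"]))
        expected = brute_force_call(normal, disease, 0.05, 0.05)
        assert got == expected

    def test_margin_conservation_in_reported_tables(self):
        normal = generate_baseline(BaselineParams(n_genes=40, n_samples=15, seed=3))
        truth = assign_fc_groups(normal.index, 4, 4, "uniform:5", seed=4)
        result = call_degs(normal, apply_fc(normal, truth))
        degs = result.degs
        assert (degs["a"] + degs["b"] == degs["c"] + degs["d"]).all()
        assert ((degs["c"] > degs["a"]) == (degs["direction"] == "up")).all()

    def test_deterministic_reruns(self):
        normal = generate_baseline(BaselineParams(n_genes=30, n_samples=12, seed=21))
        truth = assign_fc_groups(normal.index, 3, 3, "four_group", seed=22)
        disease = apply_fc(normal, truth)
        r1 = call_degs(normal, disease)
        r2 = call_degs(normal, disease)
        pd.testing.assert_frame_equal(r1.degs, r2.degs)
        assert r1.iteration_counts == r2.iteration_counts

    def test_mismatched_universe_rejected(self, rng):
        a = pd.DataFrame(rng.random((5, 6)), index=list("ABCDE"), columns=range(6))
        b = pd.DataFrame(rng.random((5, 6)), index=list("ABCDF"), columns=range(6))
        with pytest.raises(ValueError, match="universe"):
            RankCompV2(a, b)

    def test_subset_property_small_cohort(self):
        """Every called DEG is a true DEG with the correct direction (FC >= 2)."""
        normal = generate_baseline(BaselineParams(n_genes=300, n_samples=20, seed=31))
        truth = assign_fc_groups(normal.index, 30, 15, "four_group", seed=32)
        from reodeg.simulate import rescale_to_common_total

        disease, _ = rescale_to_common_total(normal, apply_fc(normal, truth))
        result = call_degs(normal, disease)
        true_dir = truth.fc.apply(lambda f: "up" if f > 1 else ("down" if f < 1 else "none"))
        for r in result.degs.itertuples():
            assert true_dir[r.gene] == r.direction

    def test_summary_mentions_counts(self):
        m = make_ordered_matrix(10, 10)
        result = call_degs(m, m.copy())
        text = result.summary()
        assert "DEGs" in text and "overlap" in text
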