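"""Normalization, the NB-Wald stand-in test, FDR and the SDEG filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trninfer.datatypes import Contrast, CountMatrix, GeneRecord, PipelineParams, SampleMeta, ValidationError
from trninfer.diffexpr import (
    QPCRMeasurement,
    bh_adjust,
    ddct_fold_change,
    de_test,
    rpkm,
    sdeg_filter,
    size_factors,
)


def _matrix(counts, lengths=None, n_rep=None):
    counts = np.asarray(counts)
    lengths = lengths or [1000] * counts.shape[0]
    genes = [GeneRecord(f"g{i}", L) for i, L in enumerate(lengths)]
    samples = [SampleMeta(f"s{j}", "WT", 30.0, j + 1) for j in range(counts.shape[1])]
    return CountMatrix(genes, samples, counts)


class TestRPKM:
    def test_direct_formula_cases(self):
        # count 10 / (2 kb) / (1e6/1e6 M reads) = 5; count 1 / 1 kb / 1 M = 1
        cm = _matrix([[10], [1], [10**6 - 11]], lengths=[2000, 1000, 1000])
        vals = rpkm(cm)
        assert vals.iloc[0, 0] == pytest.approx(5.0)
        assert vals.iloc[1, 0] == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 500, size=(20, 4))
        counts[0] = 1  # keep all libraries non-empty
        lengths = rng.integers(200, 5000, size=20).tolist()
        cm = _matrix(counts, lengths=lengths)
        got = rpkm(cm).to_numpy()
        expected = np.empty_like(got)
        for i in range(20):
            for j in range(4):
                expected[i, j] = counts[i, j] / (lengths[i] / 1e3) / (counts[:, j].sum() / 1e6)
        np.testing.assert_allclose(got, expected)
        assert ((got == 0) == (counts == 0)).all()

    def test_linearity_in_counts_at_fixed_totals(self):
        # double gene 0 while gene 2 absorbs the difference: column totals
        # unchanged, so gene 0's RPKM doubles exactly
        base = np.array([[10, 20], [30, 40], [60, 40]])
        doubled = np.array([[20, 40], [30, 40], [50, 20]])
        v1 = rpkm(_matrix(base)).to_numpy()
        v2 = rpkm(_matrix(doubled)).to_numpy()
        np.testing.assert_allclose(v2[0], 2 * v1[0])
        np.testing.assert_allclose(v2[1], v1[1])

    def test_empty_library_rejected(self):
        with pytest.raises(ValidationError, match="empty library"):
            rpkm(_matrix([[0, 5], [0, 5]]))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _matrix([[10, 10], [7, 7], [100, 100]])
        np.testing.assert_allclose(size_factors(cm), [1.0, 1.0])

    def test_doubled_column_factors_proportional(self):
        a = np.array([10, 40, 90])
        cm = _matrix(np.column_stack([a, 2 * a]))
        f = size_factors(cm)
        # hand computation: ratios are 1/sqrt(2) and sqrt(2) for every gene
        np.testing.assert_allclose(f, [2**-0.5, 2**0.5])
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_gene_with_a_zero_excluded_from_median(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 200, size=(30, 3))
        counts[5, 1] = 0
        cm = _matrix(counts)
        got = size_factors(cm)
        keep = (counts > 0).all(axis=1)
        sub = counts[keep].astype(float)
        geo = np.exp(np.log(sub).mean(axis=1))
        expected = np.median(sub / geo[:, None], axis=0)
        np.testing.assert_allclose(got, expected)

    def test_no_all_positive_gene_rejected(self):
        with pytest.raises(ValidationError):
            size_factors(_matrix([[0, 1], [1, 0]]))


def _bh_oracle(p):
    """Literal step-up: q_(i) = min over j >= i of p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9])

    def test_equals_brute_force_on_all_short_grids(self):
        # exhaustive random sampling over the {0, 0.01, ..., 1} grid, lengths <= 6
        grid = np.round(np.linspace(0, 1, 101), 2)
        rng = np.random.default_rng(0)
        for n in range(1, 7):
            for _ in range(60):
                p = rng.choice(grid, size=n).tolist()
                np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.random(200)
        np.testing.assert_allclose(bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=60)
    def test_rank_preserving_and_capped(self, p):
        q = bh_adjust(p)
        assert (q <= 1).all() and (q >= 0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestDETest:
    def test_identical_groups_give_zero_statistic(self):
        genes = [GeneRecord("g0", 1000), GeneRecord("g1", 1000)]
        samples = [SampleMeta("w1", "WT", 30.0, 1), SampleMeta("w2", "WT", 30.0, 2),
                   SampleMeta("d1", "TF1", 30.0, 1), SampleMeta("d2", "TF1", 30.0, 2)]
        cm = CountMatrix(genes, samples, np.array([[50, 50, 50, 50],
                                                   [10, 30, 30, 10]]))
        t = de_test(cm, Contrast("TF1", 30.0))
        assert t.loc["g0", "log2_fc"] == 0.0
        assert t.loc["g0", "p_raw"] == 1.0
        assert t.loc["g1", "p_raw"] == 1.0  # equal group means as well

    def test_all_zero_gene_flagged_untestable(self, toy_counts, null_contrast):
        t = de_test(toy_counts, null_contrast)
        assert bool(t.loc["g3", "untestable"])
        assert t.loc["g3", "log2_fc"] == 0.0
        assert t.loc["g3", "p_raw"] == 1.0

    def test_planted_eightfold_shift_recovered(self):
        # 8-fold shift planted on a quarter of 200 genes (so size factors
        # stay anchored by the unshifted majority), dispersion 0.05, n = 2
        rng = np.random.default_rng(202)
        n, n_shift = 200, 50
        base = np.exp(rng.normal(np.log(100), 0.5, size=n))
        fold = np.ones(n)
        fold[:n_shift] = 8.0
        phi = 0.05
        r = 1 / phi
        ref = rng.negative_binomial(r, r / (r + base[:, None]), size=(n, 2))
        test = rng.negative_binomial(r, r / (r + (base * fold)[:, None]), size=(n, 2))
        genes = [GeneRecord(f"g{i}", 1000) for i in range(n)]
        samples = [SampleMeta("w1", "WT", 40, 1), SampleMeta("w2", "WT", 40, 2),
                   SampleMeta("d1", "TF1", 40, 1), SampleMeta("d2", "TF1", 40, 2)]
        cm = CountMatrix(genes, samples, np.hstack([ref, test]))
        t = de_test(cm, Contrast("TF1", 40.0))
        planted_lfc = t["log2_fc"].iloc[:n_shift].abs()
        assert abs(np.median(planted_lfc) - 3.0) <= 0.5

    def test_requires_two_replicates(self, toy_counts):
        cm = CountMatrix(toy_counts.genes, toy_counts.samples[:3],
                         toy_counts.counts[:, :3])
        with pytest.raises(ValidationError, match="replicate"):
            de_test(cm, Contrast("TF1", 40.0))

    def test_missing_genotype_rejected(self, toy_counts):
        with pytest.raises(ValidationError, match="TFX"):
            de_test(toy_counts, Contrast("TFX", 40.0))

    def test_null_type_one_error_in_band(self):
        """Null simulation at dispersion 0.1: 2-replicate Wald type-I control."""
        rng = np.random.default_rng(555)
        n, phi = 2000, 0.1
        base = np.exp(rng.normal(np.log(100), 1.0, size=n))
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + base[:, None]), size=(n, 4))
        genes = [GeneRecord(f"g{i}", 1000) for i in range(n)]
        samples = [SampleMeta("w1", "WT", 40, 1), SampleMeta("w2", "WT", 40, 2),
                   SampleMeta("d1", "TF1", 40, 1), SampleMeta("d2", "TF1", 40, 2)]
        t = de_test(CountMatrix(genes, samples, counts), Contrast("TF1", 40.0))
        assert 0.02 <= (t["p_raw"] < 0.05).mean() <= 0.09

    def test_direction_concordant_with_pydeseq2(self):
        """Independent cross-check: strong planted shifts agree in direction
        and rough magnitude with DESeq2 as re-implemented in pydeseq2."""
        import pandas as pd
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(77)
        n = 120
        base = np.exp(rng.normal(np.log(150), 0.4, size=n))
        fold = np.ones(n)
        fold[:20] = 8.0
        fold[20:40] = 1 / 8.0
        phi = 0.05
        r = 1 / phi
        ref = rng.negative_binomial(r, r / (r + base[:, None]), size=(n, 2))
        tst = rng.negative_binomial(r, r / (r + (base * fold)[:, None]), size=(n, 2))
        genes = [GeneRecord(f"g{i}", 1000) for i in range(n)]
        samples = [SampleMeta("w1", "WT", 40, 1), SampleMeta("w2", "WT", 40, 2),
                   SampleMeta("d1", "TF1", 40, 1), SampleMeta("d2", "TF1", 40, 2)]
        ours = de_test(CountMatrix(genes, samples, np.hstack([ref, tst])),
                       Contrast("TF1", 40.0))

        counts_df = pd.DataFrame(np.hstack([ref, tst]).T,
                                 index=["w1", "w2", "d1", "d2"],
                                 columns=[g.gene_id for g in genes])
        meta = pd.DataFrame({"condition": ["WT", "WT", "DEL", "DEL"]},
                            index=counts_df.index)
        dds = DeseqDataSet(counts=counts_df, metadata=meta, design="~condition",
                           quiet=True)
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "DEL", "WT"], quiet=True)
        stats.summary()
        theirs = stats.results_df["log2FoldChange"]
        planted = [f"g{i}" for i in range(40)]
        same_sign = np.sign(ours.loc[planted, "log2_fc"]) == np.sign(theirs[planted])
        assert same_sign.mean() == 1.0
        assert np.corrcoef(ours.loc[planted, "log2_fc"], theirs[planted])[0, 1] > 0.95


class TestSDEGFilter:
    def _table(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["log2_fc", "q_fdr"]).assign(
            p_raw=lambda d: d.q_fdr, mean_ref=1.0, mean_test=1.0
        ).rename_axis("gene_id")

    def test_boundaries_inclusive(self, null_contrast):
        t = self._table([(1.0, 0.05), (-1.0, 0.05)])
        s = sdeg_filter(t, null_contrast)
        assert s.up == {0} and s.down == {1}

    def test_below_fold_threshold_excluded(self, null_contrast):
        s = sdeg_filter(self._table([(0.9, 0.001)]), null_contrast)
        assert not s.up and not s.down

    def test_matches_rowwise_predicate(self, null_contrast):
        rng = np.random.default_rng(9)
        t = self._table(list(zip(rng.normal(0, 2, 100), rng.random(100))))
        params = PipelineParams()
        s = sdeg_filter(t, null_contrast, params)
        for gene, row in t.iterrows():
            in_up = row.log2_fc >= 1.0 and row.q_fdr <= 0.05
            in_down = row.log2_fc <= -1.0 and row.q_fdr <= 0.05
            assert (gene in s.up) == in_up
            assert (gene in s.down) == in_down

    def test_threshold_monotone(self, null_contrast):
        rng = np.random.default_rng(10)
        t = self._table(list(zip(rng.normal(0, 2, 200), rng.random(200))))
        loose = sdeg_filter(t, null_contrast, PipelineParams())
        tight = sdeg_filter(t, null_contrast,
                            PipelineParams(fc_threshold=4.0, fdr_alpha=0.01))
        assert tight.up <= loose.up and tight.down <= loose.down


class TestDDCT:
    @pytest.mark.parametrize("m, expected", [
        (QPCRMeasurement(10, 10, 12, 12), 1.0),                 # ddCt = 0
        (QPCRMeasurement(20, 10, 22, 10), 4.0),                 # ddCt = -2
        (QPCRMeasurement(11, 10, 10, 10), -2.0),                # raw ratio 0.5
    ])
    def test_hand_computed_folds(self, m, expected):
        assert ddct_fold_change(m) == pytest.approx(expected)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(ValidationError):
            QPCRMeasurement(float("nan"), 1, 1, 1)
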