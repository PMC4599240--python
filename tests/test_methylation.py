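import numpy as np
import pandas as pd
import pytest
from scipy import stats

from quiescreen.methylation import (
    MethylationMatrix,
    bisulfite_methylation_call,
    correlate_meth_expr,
    map_probes_to_genes,
    pick_expression_probe,
    select_candidate_genes,
    validate_probe_annotation,
)
from quiescreen.synthetic_data import CohortSpec, gen_meth_expr


def annot_df(rows):
    return pd.DataFrame(rows, columns=["probe", "chromosome", "position", "island_relation"])


def genes_df(rows):
    return pd.DataFrame(rows, columns=["symbol", "chromosome", "strand", "start", "end"])


GENE = genes_df([("TF1", "chr6", "+", 100_000, 110_000)])


class TestMapProbesToGenes:
    @pytest.mark.parametrize(
        "position,paired",
        [
            (100_000 - 9_999, True),   # 9,999 bp before body start
            (100_000 - 10_000, True),  # exactly 10 kb upstream: within
            (100_000 - 10_001, False),
            (105_000, True),           # inside body
            (110_000 + 10_000, True),
            (110_000 + 10_001, False),
        ],
    )
    def test_flank_boundary(self, position, paired):
        pairs = map_probes_to_genes(annot_df([("p1", "chr6", position, "island")]), GENE)
        assert (len(pairs) == 1) == paired

    def test_probe_may_pair_with_multiple_genes(self):
        genes = genes_df(
            [("A", "chr1", "+", 1000, 2000), ("B", "chr1", "-", 2500, 4000)]
        )
        pairs = map_probes_to_genes(annot_df([("p1", "chr1", 2200, "shore")]), genes)
        assert set(pairs["gene"]) == {"A", "B"}

    def test_chromosome_mismatch_no_pair(self):
        pairs = map_probes_to_genes(annot_df([("p1", "chr2", 105_000, "island")]), GENE)
        assert len(pairs) == 0

    def test_random_pairs_match_bruteforce_interval_scan(self, rng):
        probes = annot_df(
            [(f"p{i}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 200_000)), "open_sea") for i in range(300)]
        )
        genes = genes_df(
            [
                (f"g{i}", f"chr{rng.integers(1, 4)}", "+", int(s := rng.integers(1, 150_000)), int(s + rng.integers(500, 30_000)))
                for i in range(30)
            ]
        )
        pairs = map_probes_to_genes(probes, genes, flank=10_000)
        oracle = {
            (p.probe, g.symbol)
            for p in probes.itertuples()
            for g in genes.itertuples()
            if p.chromosome == g.chromosome and g.start - 10_000 <= p.position <= g.end + 10_000
        }
        assert set(map(tuple, pairs.to_numpy())) == oracle

    def test_annotation_validation(self):
        with pytest.raises(ValueError, match="island_relation"):
            validate_probe_annotation(pd.DataFrame({"probe": ["p"], "chromosome": ["chr1"], "position": [5]}))
        with pytest.raises(ValueError, match="1-based"):
            validate_probe_annotation(annot_df([("p", "chr1", 0, "island")]))
        with pytest.raises(ValueError, match="relation"):
            validate_probe_annotation(annot_df([("p", "chr1", 5, "lagoon")]))


class TestPickExpressionProbe:
    def test_single_probeset_selected(self):
        mat = pd.DataFrame([[1.0, 2.0]], index=["ps1"], columns=["s1", "s2"])
        out, sel = pick_expression_probe(mat, pd.Series({"ps1": "GENE"}))
        assert sel["GENE"] == "ps1"
        assert list(out.loc["GENE"]) == [1.0, 2.0]

    def test_highest_mean_probeset_wins(self):
        mat = pd.DataFrame([[5.0, 5.0], [7.0, 7.0]], index=["ps1", "ps2"], columns=["s1", "s2"])
        out, sel = pick_expression_probe(mat, pd.Series({"ps1": "GENE", "ps2": "GENE"}))
        assert sel["GENE"] == "ps2"
        assert (out.loc["GENE"] == 7.0).all()

    def test_random_selection_matches_argmax_oracle(self, rng):
        n_ps = 40
        mat = pd.DataFrame(
            rng.normal(5, 2, (n_ps, 6)),
            index=[f"ps{i}" for i in range(n_ps)],
            columns=[f"s{i}" for i in range(6)],
        )
        mapping = pd.Series({f"ps{i}": f"g{i % 10}" for i in range(n_ps)})
        _, sel = pick_expression_probe(mat, mapping)
        means = mat.mean(axis=1)
        for gene in sel.index:
            candidates = [ps for ps, g in mapping.items() if g == gene]
            assert sel[gene] == max(candidates, key=lambda ps: means[ps])


def meth_matrix(values: np.ndarray, probes, samples, tumor_prefix="T") -> MethylationMatrix:
    labels = pd.Series(["tumor" if s.startswith(tumor_prefix) else "comparator" for s in samples], index=samples)
    return MethylationMatrix(pd.DataFrame(values, index=probes, columns=samples), labels)


class TestCorrelateMethExpr:
    def samples(self, n):
        return [f"T{i}" for i in range(n // 2)] + [f"C{i}" for i in range(n - n // 2)]

    def test_perfect_negative_fit_sign_and_no_error(self):
        n = 10
        samples = self.samples(n)
        beta = np.linspace(0.1, 0.9, n)
        expr = pd.DataFrame([10.0 - 5.0 * beta], index=["g1"], columns=samples)
        meth = meth_matrix(beta[None, :], ["p1"], samples)
        res = correlate_meth_expr(meth, expr, pd.DataFrame({"probe": ["p1"], "gene": ["g1"]}))
        assert res.loc[0, "t"] < 0
        assert res.loc[0, "p"] < 1e-60  # numerically perfect fit, no error

    def test_t_equals_pearson_closed_form(self, rng):
        n = 15
        samples = self.samples(n)
        beta = rng.uniform(0, 1, n)
        y = rng.normal(5, 1, n)
        meth = meth_matrix(beta[None, :], ["p1"], samples)
        expr = pd.DataFrame([y], index=["g1"], columns=samples)
        res = correlate_meth_expr(meth, expr, pd.DataFrame({"probe": ["p1"], "gene": ["g1"]}))
        r = np.corrcoef(beta, y)[0, 1]
        t_oracle = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        assert res.loc[0, "t"] == pytest.approx(t_oracle, abs=1e-10)
        assert res.loc[0, "p"] == pytest.approx(2 * stats.t.sf(abs(t_oracle), n - 2), rel=1e-9)

    def test_missing_beta_pairwise_deleted(self, rng):
        n = 12
        samples = self.samples(n)
        beta = rng.uniform(0, 1, n)
        beta_missing = beta.copy()
        beta_missing[0] = np.nan
        y = rng.normal(5, 1, n)
        meth = meth_matrix(beta_missing[None, :], ["p1"], samples)
        expr = pd.DataFrame([y], index=["g1"], columns=samples)
        res = correlate_meth_expr(meth, expr, pd.DataFrame({"probe": ["p1"], "gene": ["g1"]}))
        assert res.loc[0, "n"] == n - 1
        r = np.corrcoef(beta[1:], y[1:])[0, 1]
        assert res.loc[0, "t"] == pytest.approx(r * np.sqrt(n - 3) / np.sqrt(1 - r * r), abs=1e-10)

    def test_probe_with_excess_missing_excluded(self, rng):
        n = 10
        samples = self.samples(n)
        beta = rng.uniform(0, 1, (1, n))
        beta[0, :3] = np.nan  # 30% missing > 20% cap
        meth = meth_matrix(beta, ["p1"], samples)
        expr = pd.DataFrame(rng.normal(5, 1, (1, n)), index=["g1"], columns=samples)
        res = correlate_meth_expr(meth, expr, pd.DataFrame({"probe": ["p1"], "gene": ["g1"]}))
        assert len(res) == 0

    def test_zero_variance_pair_skipped_counted(self, rng, caplog):
        n = 10
        samples = self.samples(n)
        meth = meth_matrix(np.full((1, n), 0.5), ["p1"], samples)
        expr = pd.DataFrame(rng.normal(5, 1, (1, n)), index=["g1"], columns=samples)
        with caplog.at_level("WARNING"):
            res = correlate_meth_expr(meth, expr, pd.DataFrame({"probe": ["p1"], "gene": ["g1"]}))
        assert len(res) == 0
        assert res.attrs["skipped_zero_variance"] == 1

    def test_invariant_to_sample_order(self, rng):
        n = 14
        samples = self.samples(n)
        beta = rng.uniform(0, 1, (3, n))
        y = rng.normal(5, 1, (3, n))
        pairs = pd.DataFrame({"probe": ["p0", "p1", "p2"], "gene": ["g0", "g1", "g2"]})
        meth1 = meth_matrix(beta, ["p0", "p1", "p2"], samples)
        expr1 = pd.DataFrame(y, index=["g0", "g1", "g2"], columns=samples)
        perm = list(rng.permutation(samples))
        meth2 = meth_matrix(meth1.values[perm].to_numpy(), ["p0", "p1", "p2"], perm)
        expr2 = expr1[perm]
        r1 = correlate_meth_expr(meth1, expr1, pairs)
        r2 = correlate_meth_expr(meth2, expr2, pairs)
        assert np.allclose(r1["t"], r2["t"])

    def test_bh_adjustment_preserves_p_order(self, rng):
        n = 12
        samples = self.samples(n)
        m = 30
        beta = rng.uniform(0, 1, (m, n))
        y = rng.normal(5, 1, (m, n))
        pairs = pd.DataFrame({"probe": [f"p{i}" for i in range(m)], "gene": [f"g{i}" for i in range(m)]})
        meth = meth_matrix(beta, [f"p{i}" for i in range(m)], samples)
        expr = pd.DataFrame(y, index=[f"g{i}" for i in range(m)], columns=samples)
        res = correlate_meth_expr(meth, expr, pairs)
        srt = res.sort_values("p")
        assert (srt["p_adj"].diff().dropna() >= -1e-12).all()
        assert (res["p_adj"] >= res["p"] - 1e-15).all()


class TestSelectCandidateGenes:
    def build(self, n_probes, t_mean, c_mean, sd=0.05, p_adj=1e-6, gene="DRV"):
        samples = [f"T{i}" for i in range(8)] + [f"C{i}" for i in range(10)]
        # deterministic jitter: empirical group means equal t_mean / c_mean
        beta = np.empty((n_probes, 18))
        beta[:, :8] = np.clip(t_mean + np.linspace(-sd, sd, 8), 0, 1)
        beta[:, 8:] = np.clip(c_mean + np.linspace(-sd, sd, 10), 0, 1)
        probes = [f"p{i}" for i in range(n_probes)]
        meth = meth_matrix(beta, probes, samples)
        results = pd.DataFrame(
            {"probe": probes, "gene": gene, "t": -8.0, "p": p_adj, "p_adj": p_adj}
        )
        return results, meth

    def test_hyper_gene_with_five_probes_selected(self):
        results, meth = self.build(5, 0.78, 0.14, sd=0.08)
        out = select_candidate_genes(results, meth, tumor_group="tumor")
        assert list(out["gene"]) == ["DRV"]
        assert out.loc[0, "direction"] == "hyper"

    def test_four_probes_not_selected(self):
        results, meth = self.build(4, 0.78, 0.14)
        out = select_candidate_genes(results, meth, tumor_group="tumor")
        assert len(out) == 0

    def test_nonsignificant_probes_gated_out(self):
        results, meth = self.build(6, 0.78, 0.14, p_adj=0.2)
        out = select_candidate_genes(results, meth, tumor_group="tumor")
        assert len(out) == 0

    def test_hypo_direction(self):
        results, meth = self.build(5, 0.10, 0.85)
        out = select_candidate_genes(results, meth, tumor_group="tumor")
        assert out.loc[0, "direction"] == "hypo"

    def test_intermediate_beta_fails_mean_gate(self):
        results, meth = self.build(6, 0.5, 0.5, sd=0.02)
        out = select_candidate_genes(results, meth, tumor_group="tumor")
        assert len(out) == 0

    def test_high_sd_fails_sd_gate(self):
        results, meth = self.build(6, 0.8, 0.1)
        # tumor mean 0.8 (> 0.75) but SD 0.37 (> 0.25): dropped on dispersion
        tumor_cols = [f"T{i}" for i in range(8)]
        meth.values.loc[:, tumor_cols] = np.tile([1, 1, 1, 1, 1, 1, 0.2, 0.2], (6, 1))
        out = select_candidate_genes(results, meth, tumor_group="tumor")
        assert len(out) == 0

    def test_generated_cohorts_match_bruteforce_reimplementation(self):
        spec = CohortSpec(n_genes=30, n_probes=40, module_size=4, seed=3)
        cohort, truth = gen_meth_expr(spec)
        meth = cohort["methylation"]
        pairs = map_probes_to_genes(cohort["probe_annotation"], cohort["gene_models"])
        results = correlate_meth_expr(meth, cohort["expression"].values, pairs)
        out = select_candidate_genes(results, meth, tumor_group="tumor")
        # independent three-step re-evaluation
        tumor_cols = [s for s in meth.values.columns if s.startswith("T")]
        kept = results[results["p_adj"] < 0.05]
        expected = set()
        for gene, sub in kept.groupby("gene"):
            n_qual = 0
            for probe in sub["probe"]:
                b = meth.values.loc[probe, tumor_cols].dropna()
                m, sd = b.mean(), b.std(ddof=1)
                if (m > 0.75 or m < 0.25) and sd < 0.25:
                    n_qual += 1
            if n_qual >= 5:
                expected.add(gene)
        assert set(out["gene"]) == expected
        assert truth.driver_gene in expected


class TestBisulfiteCall:
    @pytest.mark.parametrize(
        "c,t,ratio,call",
        [
            (0, 50, 0.0, "unmethylated"),
            (20, 80, 0.20, "unmethylated"),       # boundary inclusive low
            (21, 79, 0.21, "partially_methylated"),
            (80, 20, 0.80, "partially_methylated"),  # boundary inclusive mid
            (81, 19, 0.81, "fully_methylated"),
            (50, 0, 1.0, "fully_methylated"),
        ],
    )
    def test_ratio_classes(self, c, t, ratio, call):
        out = bisulfite_methylation_call(pd.DataFrame({"site": ["s"], "c_peak": [c], "t_peak": [t]}))
        assert out.loc[0, "ratio"] == pytest.approx(ratio)
        assert out.loc[0, "call"] == call

    def test_both_peaks_zero_is_error(self):
        with pytest.raises(ValueError, match="both peaks zero"):
            bisulfite_methylation_call(pd.DataFrame({"site": ["s"], "c_peak": [0], "t_peak": [0]}))

    def test_negative_peak_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            bisulfite_methylation_call(pd.DataFrame({"site": ["s"], "c_peak": [-1], "t_peak": [5]}))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="t_peak"):
            bisulfite_methylation_call(pd.DataFrame({"site": ["s"], "c_peak": [1]}))


class TestMethylationMatrix:
    def test_beta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            meth_matrix(np.array([[1.2, 0.5]]), ["p1"], ["T1", "C1"])

    def test_missing_tracked(self):
        m = meth_matrix(np.array([[np.nan, 0.5, 0.4, 0.2]]), ["p1"], ["T1", "T2", "C1", "C2"])
        assert m.missing_fraction()["p1"] == pytest.approx(0.25)
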