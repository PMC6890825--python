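import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regiontx.atlas_io import ExpressionDataset
from regiontx.diffexpr import (
    ModerationParams,
    bh_fdr,
    fit_region_model,
    moderate_variances,
    moderated_t_test,
    signed_ranking,
    squeeze_variances,
    summarize_genes,
)


def _dataset(values, probe_ids, sample_ids):
    return ExpressionDataset(
        pd.DataFrame(np.asarray(values, dtype=float), index=probe_ids, columns=sample_ids)
    )


def _samples(donors, regions):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(donors))],
            "donor_id": donors,
            "region_name": regions,
        }
    )


class TestFitRegionModel:
    def test_single_donor_two_group_difference(self):
        samples = _samples(["d1"] * 4, ["A", "A", "B", "B"])
        ds = _dataset([[5, 5, 3, 3]], ["p1"], samples["sample_id"])
        fits = fit_region_model(ds, samples, "A")
        assert fits.beta[0] == pytest.approx(2.0, abs=1e-12)
        assert fits.s2[0] == pytest.approx(0.0, abs=1e-12)
        assert fits.df_residual == 2  # n - n_donors - 1

    def test_matches_independent_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        samples = _samples(
            ["d1"] * 4 + ["d2"] * 4, ["A", "A", "B", "B", "A", "B", "B", "B"]
        )
        Y = rng.normal(size=(6, 8))
        ds = _dataset(Y, [f"p{i}" for i in range(6)], samples["sample_id"])
        fits = fit_region_model(ds, samples, "A")
        # independent oracle: explicit design, per-probe normal equations
        X = np.column_stack(
            [
                np.ones(8),
                (samples["donor_id"] == "d2").astype(float),
                (samples["region_name"] == "A").astype(float),
            ]
        )
        for i in range(6):
            beta = np.linalg.solve(X.T @ X, X.T @ Y[i])
            resid = Y[i] - X @ beta
            assert fits.beta[i] == pytest.approx(beta[-1], abs=1e-10)
            assert fits.s2[i] == pytest.approx(resid @ resid / (8 - 3), abs=1e-10)
        v = np.linalg.inv(X.T @ X)[-1, -1]
        assert fits.stderr_unit == pytest.approx(np.sqrt(v), abs=1e-12)

    def test_constant_probe_has_zero_beta_and_variance(self):
        samples = _samples(["d1"] * 4, ["A", "A", "B", "B"])
        ds = _dataset([[4, 4, 4, 4]], ["p1"], samples["sample_id"])
        fits = fit_region_model(ds, samples, "A")
        assert fits.beta[0] == pytest.approx(0.0, abs=1e-12)
        assert fits.s2[0] == pytest.approx(0.0, abs=1e-12)

    def test_confounded_donor_named_in_error(self):
        samples = _samples(["d1", "d1", "d2", "d2"], ["A", "A", "B", "B"])
        ds = _dataset([[1, 2, 3, 4]], ["p1"], samples["sample_id"])
        with pytest.raises(ValueError, match="d1"):
            fit_region_model(ds, samples, "A")

    def test_missing_region_errors(self):
        samples = _samples(["d1"] * 2, ["A", "B"])
        ds = _dataset([[1, 2]], ["p1"], samples["sample_id"])
        with pytest.raises(ValueError, match="no samples"):
            fit_region_model(ds, samples, "C")


class TestModeration:
    def test_equal_variances_give_infinite_prior_df(self):
        s2 = np.full(50, 0.7)
        params, s2_mod = moderate_variances(s2, df_residual=10)
        assert np.isinf(params.d0)
        np.testing.assert_allclose(s2_mod, 0.7, atol=1e-12)

    def test_parameter_recovery_from_scaled_inv_chisquare(self):
        rng = np.random.default_rng(2024)
        d0, s0_2, d_g, G = 4.0, 1.0, 10, 5000
        sigma2 = s0_2 * d0 / rng.chisquare(d0, G)
        s2 = sigma2 * rng.chisquare(d_g, G) / d_g
        params, s2_mod = moderate_variances(s2, d_g)
        assert 3.0 <= params.d0 <= 5.0
        assert 0.9 <= params.s0_2 <= 1.1
        # every moderated variance lies between the prior and the raw value
        lo = np.minimum(s2, params.s0_2)
        hi = np.maximum(s2, params.s0_2)
        assert ((s2_mod >= lo - 1e-12) & (s2_mod <= hi + 1e-12)).all()

    def test_zero_prior_df_means_no_shrinkage(self):
        s2 = np.array([0.1, 0.5, 2.0])
        out = squeeze_variances(s2, 8, ModerationParams(d0=0.0, s0_2=1.0))
        np.testing.assert_array_equal(out, s2)

    def test_moderated_variance_is_convex_combination(self):
        rng = np.random.default_rng(5)
        s2 = rng.chisquare(5, 200) / 5
        d_g = 7
        params, s2_mod = moderate_variances(s2, d_g)
        assert np.isfinite(params.d0)  # heterogeneous draw yields finite prior df
        w = params.d0 / (params.d0 + d_g)
        np.testing.assert_allclose(s2_mod, w * params.s0_2 + (1 - w) * s2, rtol=1e-12)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError, match="positive residual variance"):
            moderate_variances(np.zeros(10), 5)


class TestModeratedT:
    def _fits(self, beta, s2, stderr_unit=1.0, df=10):
        from regiontx.diffexpr import RegionModelFits

        beta = np.atleast_1d(np.asarray(beta, dtype=float))
        return RegionModelFits(
            region_name="A",
            probe_ids=np.array([f"p{i}" for i in range(beta.size)]),
            beta=beta,
            s2=np.atleast_1d(np.asarray(s2, dtype=float)),
            stderr_unit=stderr_unit,
            df_residual=df,
        )

    def test_zero_beta_gives_t_zero_p_one(self):
        out = moderated_t_test(self._fits([0.0], [1.0]), ModerationParams(5.0, 1.0))
        assert out["t"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_normal_reference_at_infinite_prior_df(self):
        out = moderated_t_test(self._fits([1.96], [1.0]), ModerationParams(np.inf, 1.0))
        assert out["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(1.96), rel=1e-12)
        assert out["p"].iloc[0] == pytest.approx(0.05, abs=1e-3)

    def test_no_shrinkage_limit_equals_classical_t(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(size=20)
        s2 = rng.chisquare(5, 20) / 5
        fits = self._fits(beta, s2, stderr_unit=0.5, df=8)
        out = moderated_t_test(fits, ModerationParams(0.0, 1.0))
        t_classic = beta / (np.sqrt(s2) * 0.5)
        p_classic = 2 * stats.t.sf(np.abs(t_classic), 8)
        np.testing.assert_allclose(out["t"], t_classic, atol=1e-10)
        np.testing.assert_allclose(out["p"], p_classic, atol=1e-10)

    def test_zero_stderr_unit_errors(self):
        with pytest.raises(ValueError, match="stderr_unit"):
            moderated_t_test(self._fits([1.0], [1.0], stderr_unit=0.0), ModerationParams(1.0, 1.0))


class TestBHFDR:
    def test_step_up_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04], atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), 0.2, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(1e-6, 1, 50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestGeneSummaryAndRanking:
    def _probe_table(self, rows):
        df = pd.DataFrame(rows, columns=["probe_id", "gene_symbol", "t", "p", "direction"])
        df["p_fdr"] = bh_fdr(df["p"].to_numpy())
        return df

    def test_representative_probe_attains_min_p(self):
        table = self._probe_table(
            [("a1", "GA", 3.0, 0.01, 1), ("a2", "GA", 4.0, 0.001, 1)]
        )
        out = summarize_genes(table)
        assert out.loc[out["gene_symbol"] == "GA", "p_min"].iloc[0] == 0.001
        assert out.loc[out["gene_symbol"] == "GA", "representative_probe"].iloc[0] == "a2"

    def test_negative_best_probe_excluded_from_up_list(self):
        table = self._probe_table(
            [("a1", "GA", 5.0, 1e-4, 1), ("a2", "GA", -6.0, 1e-6, -1)]
        )
        out = summarize_genes(table)
        row = out.loc[out["gene_symbol"] == "GA"].iloc[0]
        assert row["direction"] == -1
        assert not row["significant_up"]

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"G{i}" for i in range(10)]
        gene_of_probe = list(rng.choice(genes, size=17))
        for g in genes:  # ensure all genes covered
            if g not in gene_of_probe:
                gene_of_probe[rng.integers(17)] = g
        rows = [
            (f"p{i:02d}", gene_of_probe[i], float(rng.normal()),
             float(rng.uniform(1e-6, 1)), int(rng.choice([-1, 1])))
            for i in range(17)
        ]
        table = self._probe_table(rows)
        out = summarize_genes(table).set_index("gene_symbol")
        # oracle: plain-python enumeration per gene
        for g in set(gene_of_probe):
            probes = [r for r in table.itertuples() if r.gene_symbol == g]
            best = min(probes, key=lambda r: (r.p, r.probe_id))
            assert out.loc[g, "representative_probe"] == best.probe_id
            expected_up = best.p_fdr < 0.05 and best.direction > 0
            assert bool(out.loc[g, "significant_up"]) is expected_up
            assert out.loc[g, "n_significant_probes"] == sum(
                1 for r in probes if r.p_fdr < 0.05 and r.direction > 0
            )

    def test_signed_order_definition(self):
        gr = pd.DataFrame(
            {
                "gene_symbol": ["A", "B", "C", "D"],
                "p_min": [1e-5, 1e-3, 1e-4, 1e-6],
                "direction": [1, 1, -1, -1],
                "t": [5.0, 3.0, -4.0, -6.0],
            }
        )
        out = signed_ranking(gr)
        assert out["gene_symbol"].tolist() == ["A", "B", "C", "D"]

    def test_all_p_one_orders_by_t_then_symbol(self):
        gr = pd.DataFrame(
            {
                "gene_symbol": ["B", "A", "C"],
                "p_min": [1.0, 1.0, 1.0],
                "direction": [1, 1, 1],
                "t": [0.5, 0.5, 0.9],
            }
        )
        out1 = signed_ranking(gr)
        out2 = signed_ranking(gr.sample(frac=1, random_state=1))
        assert out1["gene_symbol"].tolist() == ["C", "A", "B"]
        assert out1["gene_symbol"].tolist() == out2["gene_symbol"].tolist()

    def test_agrees_with_independent_sort_oracle(self):
        rng = np.random.default_rng(12)
        n = 60
        gr = pd.DataFrame(
            {
                "gene_symbol": [f"G{i:03d}" for i in range(n)],
                "p_min": rng.uniform(1e-8, 1, n),
                "direction": rng.choice([-1, 1], n),
                "t": rng.normal(size=n),
            }
        )
        out = signed_ranking(gr)
        oracle = sorted(
            gr.itertuples(),
            key=lambda r: (-(r.direction * -np.log10(r.p_min)), -r.t, r.gene_symbol),
        )
        assert out["gene_symbol"].tolist() == [r.gene_symbol for r in oracle]


class TestLimmaOracle:
    """Dual-route check of the whole moderation chain against Bioconductor limma."""

    def test_moderated_statistics_match_limma(self, tmp_path):
        rng = np.random.default_rng(42)
        n_probes, n_samples = 150, 12
        samples = _samples(["d1"] * 6 + ["d2"] * 6, (["A"] * 3 + ["B"] * 3) * 2)
        sd2 = 0.2 * 4 / rng.chisquare(4, n_probes)
        Y = rng.normal(size=(n_probes, n_samples)) * np.sqrt(sd2)[:, None] \
            + rng.uniform(4, 12, n_probes)[:, None]
        ds = _dataset(Y, [f"p{i:03d}" for i in range(n_probes)], samples["sample_id"])
        fits = fit_region_model(ds, samples, "A")
        params, _ = moderate_variances(fits.s2, fits.df_residual)
        ours = moderated_t_test(fits, params)

        ds.values.to_csv(tmp_path / "expr.csv")
        samples.to_csv(tmp_path / "samples.csv", index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            expr <- read.csv(file.path(args[1], 'expr.csv'), row.names=1, check.names=FALSE)
            samples <- read.csv(file.path(args[1], 'samples.csv'))
            design <- model.matrix(~ donor_id + I(region_name == 'A'), data=samples)
            fit <- eBayes(lmFit(as.matrix(expr), design))
            i <- ncol(design)
            out <- data.frame(probe_id=rownames(expr), t=fit$t[,i], p=fit$p.value[,i])
            write.csv(out, file.path(args[1], 'limma.csv'), row.names=FALSE)
            cat(fit$df.prior, fit$s2.prior, sep='\\n')
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", str(tmp_path / "oracle.R"), str(tmp_path)],
            capture_output=True, text=True, check=True,
        )
        d0_limma, s0_2_limma = map(float, proc.stdout.split())
        assert params.d0 == pytest.approx(d0_limma, rel=1e-5)
        assert params.s0_2 == pytest.approx(s0_2_limma, rel=1e-5)
        ref = pd.read_csv(tmp_path / "limma.csv")
        merged = ours.merge(ref, on="probe_id", suffixes=("_py", "_r"))
        np.testing.assert_allclose(merged["t_py"], merged["t_r"], rtol=1e-8)
        np.testing.assert_allclose(merged["p_py"], merged["p_r"], rtol=1e-8)
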