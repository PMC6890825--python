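"""Regional differential expression with donor blocking and moderated t-statistics.

For one region of interest, every probe is fit with the linear model

    y_ps = intercept + donor_j(s) + beta_p * 1[region(s) = roi] + eps_ps

where donors enter as treatment-coded indicators (lexicographically first
donor as reference) and the region of interest as a single binary
indicator.  Per-probe residual variances are shrunk toward a prior
variance estimated across probes by the empirical-Bayes moment method:
assuming s_g^2 | sigma_g^2 ~ sigma_g^2 * chi2_d / d and a scaled
inverse-chi-square prior sigma_g^2 ~ s0^2 * d0 / chi2_d0, the marginal
distribution of log s_g^2 identifies (d0, s0^2) through digamma/trigamma
moments.  Moderated t-statistics use the shrunken variance with d0 + d
degrees of freedom.  Probe-level p-values are BH-FDR adjusted, genes are
summarized by their lowest-p probe, and a signed significance ranking
orders genes from most enriched to most depleted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from regiontx.atlas_io import ExpressionDataset

logger = logging.getLogger(__name__)

#: Floor applied to p-values before log10 transforms; deep atlas rankings
#: reach p ~ 1e-209, well within this representable range.
P_FLOOR = 1e-300

#: Probe-level FDR threshold defining the significant / up-regulated lists.
FDR_THRESHOLD = 0.05


@dataclass(frozen=True)
class RegionModelFits:
    """Vectorized least-squares fits for all probes against one region.

    ``stderr_unit`` is the design-dependent unscaled standard-error factor
    sqrt(v) for the region coefficient: se(beta) = s * stderr_unit where
    s^2 is the (possibly moderated) residual variance.
    """

    region_name: str
    probe_ids: np.ndarray
    beta: np.ndarray
    s2: np.ndarray
    stderr_unit: float
    df_residual: int

    def __post_init__(self) -> None:
        if self.df_residual < 1:
            raise ValueError(
                f"df_residual={self.df_residual} < 1: not enough samples per donor"
            )


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior: d0 prior degrees of freedom (may be inf), s0_2 prior variance.

    ``d0 = 0`` is permitted as the explicit no-shrinkage limit (moderated
    variances equal the raw per-probe variances); the estimator itself
    always returns d0 > 0.
    """

    d0: float
    s0_2: float

    def __post_init__(self) -> None:
        if self.d0 < 0 or not self.s0_2 > 0:
            raise ValueError(f"invalid moderation parameters d0={self.d0}, s0_2={self.s0_2}")


def _design_matrix(samples: pd.DataFrame, region_name: str) -> tuple[np.ndarray, list[str]]:
    donors = sorted(samples["donor_id"].unique())
    in_region = (samples["region_name"] == region_name).to_numpy(dtype=float)
    n = len(samples)
    cols = [np.ones(n)]
    names = ["intercept"]
    for d in donors[1:]:
        cols.append((samples["donor_id"] == d).to_numpy(dtype=float))
        names.append(f"donor[{d}]")
    cols.append(in_region)
    names.append("region")
    return np.column_stack(cols), names


def fit_region_model(
    dataset: ExpressionDataset, samples: pd.DataFrame, region_name: str
) -> RegionModelFits:
    """Fit the donor-blocked region-of-interest model to every probe at once.

    Raises if the region is absent, or if the design is rank-deficient —
    which happens when some donor's samples all lie inside (or the region
    consists exactly of one donor's samples); the error names the
    confounded donors.
    """
    in_region = samples["region_name"] == region_name
    if not in_region.any():
        raise ValueError(f"region {region_name!r} has no samples")
    X, _ = _design_matrix(samples, region_name)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        confounded = [
            d for d, grp in samples.groupby("donor_id")
            if (grp["region_name"] == region_name).all()
        ]
        raise ValueError(
            f"design is rank-deficient for region {region_name!r}; "
            f"donors confounded with the region indicator: {confounded}"
        )
    Y = dataset.values.to_numpy().T  # samples x probes
    xtx_inv = np.linalg.inv(X.T @ X)
    beta_all = xtx_inv @ X.T @ Y  # p x probes
    resid = Y - X @ beta_all
    df = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    s2 = np.maximum(rss / df, 0.0)
    stderr_unit = float(np.sqrt(xtx_inv[-1, -1]))
    return RegionModelFits(
        region_name=region_name,
        probe_ids=np.asarray(dataset.probe_ids),
        beta=beta_all[-1],
        s2=s2,
        stderr_unit=stderr_unit,
        df_residual=df,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0)."""
    # trigamma is strictly decreasing from +inf to 0 on (0, inf);
    # bracket using trigamma(x) ~ 1/x + 1/(2x^2) for large x, ~1/x^2 near 0.
    lo, hi = 1e-8, 1e8
    trig = lambda x: float(special.polygamma(1, x))
    while trig(lo) < y:
        lo /= 10.0
        if lo < 1e-300:
            return lo
    while trig(hi) > y:
        hi *= 10.0
        if hi > 1e300:
            return hi
    return float(brentq(lambda x: trig(x) - y, lo, hi, xtol=1e-12, rtol=1e-12))


def moderate_variances(
    s2: np.ndarray, df_residual: int
) -> tuple[ModerationParams, np.ndarray]:
    """Estimate the variance prior by moments and shrink per-probe variances.

    With e_g = log s_g^2 - digamma(d/2) + log(d/2):

    * mean(e) estimates log s0^2 + digamma(d0/2) - log(d0/2);
    * var(e) - trigamma(d/2) estimates trigamma(d0/2), solved for d0 by
      monotone root-finding.

    If the variance of e does not exceed the sampling term, dispersion is
    zero: d0 = +inf and every moderated variance equals s0^2, the
    arithmetic mean of the observed variances (the natural estimate when
    all true variances coincide).  Otherwise the moderated variance is the
    convex combination (d0*s0^2 + d*s_g^2) / (d0 + d).

    Probes with s_g^2 = 0 are excluded from estimation (their log is
    undefined) but are still shrunk; at least two positive variances are
    required.
    """
    s2 = np.asarray(s2, dtype=float)
    d = float(df_residual)
    positive = s2 > 0
    if positive.sum() < 2:
        raise ValueError("moderation requires >= 2 probes with positive residual variance")
    e = np.log(s2[positive]) - special.digamma(d / 2.0) + np.log(d / 2.0)
    G = e.size
    e_bar = float(e.mean())
    rhs = float(np.mean((e - e_bar) ** 2) * G / (G - 1) - special.polygamma(1, d / 2.0))
    if rhs <= 0:
        params = ModerationParams(d0=np.inf, s0_2=float(s2.mean()))
        return params, np.full_like(s2, params.s0_2)
    d0 = 2.0 * _trigamma_inverse(rhs)
    s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    params = ModerationParams(d0=d0, s0_2=s0_2)
    s2_mod = (d0 * s0_2 + d * s2) / (d0 + d)
    return params, s2_mod


def squeeze_variances(s2: np.ndarray, df_residual: int, params: ModerationParams) -> np.ndarray:
    """Shrink raw variances toward the prior with fixed parameters."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(params.d0):
        return np.full_like(s2, params.s0_2)
    if params.d0 == 0:
        return s2.copy()
    return (params.d0 * params.s0_2 + df_residual * s2) / (params.d0 + df_residual)


def moderated_t_test(
    fits: RegionModelFits,
    params: ModerationParams,
    probes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compute moderated t-statistics and two-sided p-values per probe.

    The reference distribution is Student t with d0 + df_residual degrees
    of freedom (standard normal when d0 is infinite).  p-values are clamped
    to be strictly positive.  Returns a DataFrame with probe_id,
    gene_symbol (if annotations given), beta, t, p, and direction.
    """
    if fits.stderr_unit == 0:
        raise ValueError("stderr_unit is zero: degenerate design")
    s2_mod = squeeze_variances(fits.s2, fits.df_residual, params)
    denom = np.sqrt(s2_mod) * fits.stderr_unit
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, fits.beta / np.where(denom > 0, denom, 1.0), 0.0)
        t = np.where((denom == 0) & (fits.beta != 0), np.sign(fits.beta) * np.inf, t)
    df_total = params.d0 + fits.df_residual
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "probe_id": fits.probe_ids,
            "beta": fits.beta,
            "t": t,
            "p": p,
            "direction": np.sign(fits.beta).astype(int),
        }
    )
    if probes is not None:
        out = out.merge(probes[["probe_id", "gene_symbol"]], on="probe_id", how="left")
    return out


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def summarize_genes(probe_results: pd.DataFrame, fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Summarize probe-level statistics to one row per gene.

    Each gene is represented by its lowest-p probe (ties broken by probe
    id for determinism).  A gene enters the up-regulated list iff its
    representative probe has p_fdr below threshold AND positive direction.
    ``n_significant_probes`` counts the gene's probes that individually
    pass the threshold with positive direction.
    """
    if "p_fdr" not in probe_results:
        raise ValueError("probe_results must carry a p_fdr column (run bh_fdr first)")
    pr = probe_results.sort_values(["p", "probe_id"], kind="mergesort")
    rep = pr.drop_duplicates("gene_symbol", keep="first")
    sig_up = (probe_results["p_fdr"] < fdr_threshold) & (probe_results["direction"] > 0)
    n_sig = (
        probe_results.assign(_sig=sig_up.astype(int))
        .groupby("gene_symbol")["_sig"]
        .sum()
    )
    out = pd.DataFrame(
        {
            "gene_symbol": rep["gene_symbol"].to_numpy(),
            "representative_probe": rep["probe_id"].to_numpy(),
            "p_min": rep["p"].to_numpy(),
            "p_fdr": rep["p_fdr"].to_numpy(),
            "t": rep["t"].to_numpy(),
            "direction": rep["direction"].to_numpy(),
        }
    )
    out["n_significant_probes"] = out["gene_symbol"].map(n_sig).astype(int)
    out["significant_up"] = (out["p_fdr"] < fdr_threshold) & (out["direction"] > 0)
    return out.reset_index(drop=True)


def signed_ranking(gene_results: pd.DataFrame) -> pd.DataFrame:
    """Order genes from most significantly enriched to most significantly depleted.

    The rank key is sign(direction) * (-log10 p_min) with p floored at
    1e-300; ties break by the representative probe's moderated t
    (descending), then gene symbol, giving a strict total order.  Returns
    a DataFrame sorted by rank (1 = most enriched) with a ``rank_key``
    column.
    """
    gr = gene_results.copy()
    logp = -np.log10(np.maximum(gr["p_min"].to_numpy(), P_FLOOR))
    direction = gr["direction"].to_numpy()
    # direction 0 (beta exactly 0) sits between up and down with key 0
    gr["rank_key"] = np.where(direction >= 0, 1.0, -1.0) * logp * (direction != 0)
    gr = gr.sort_values(
        ["rank_key", "t", "gene_symbol"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    gr["rank"] = np.arange(1, len(gr) + 1)
    return gr


def region_differential_expression(
    dataset: ExpressionDataset,
    probes: pd.DataFrame,
    samples: pd.DataFrame,
    region_name: str,
    fdr_threshold: float = FDR_THRESHOLD,
) -> dict:
    """Run the full DE stage for one region of interest.

    Fits the donor-blocked model, moderates variances, computes moderated
    t probe statistics with BH-FDR, summarizes to genes and builds the
    signed ranking.  Returns a dict with keys ``fits``, ``params``,
    ``probe_table``, ``gene_table``, ``ranking``, ``up_regulated``.
    """
    fits = fit_region_model(dataset, samples, region_name)
    params, _ = moderate_variances(fits.s2, fits.df_residual)
    probe_table = moderated_t_test(fits, params, probes)
    probe_table["p_fdr"] = bh_fdr(probe_table["p"].to_numpy())
    gene_table = summarize_genes(probe_table, fdr_threshold)
    ranking = signed_ranking(gene_table)
    up = ranking.loc[ranking["significant_up"], "gene_symbol"].tolist()
    logger.info(
        "DE %s: %d probes, %d genes, %d up-regulated (FDR < %g)",
        region_name, len(probe_table), len(gene_table), len(up), fdr_threshold,
    )
    return {
        "region_name": region_name,
        "fits": fits,
        "params": params,
        "probe_table": probe_table,
        "gene_table": gene_table,
        "ranking": ranking,
        "up_regulated": up,
    }
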