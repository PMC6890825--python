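"""Marker-gene-profile (MGP) estimation of relative cell-type proportions.

The relative abundance of a cell type across brain regions is summarized
by the first principal component of its marker genes' expression: markers
of one cell type co-vary with that type's proportion across samples, so
PC1 of the marker submatrix tracks relative abundance.  Estimation is
per donor (centering each marker across that donor's samples, covariance
PCA via SVD, sign fixed so PC1 correlates positively with mean marker
expression), scores are averaged within region, z-scored across regions
within donor, averaged across donors, and finally ranked across regions
(rank 1 = highest estimated proportion).

Estimates are relative, not absolute: no sum-to-one deconvolution is
attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from regiontx.atlas_io import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerSet:
    """Marker genes for one cell type (typically ~21 per type)."""

    cell_type: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker set for {self.cell_type!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate markers for {self.cell_type!r}")


def read_marker_tsv(path) -> list[MarkerSet]:
    """Read a two-column (cell_type, gene) TSV into marker sets."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"cell_type", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns cell_type and gene")
    return [
        MarkerSet(cell_type=str(ct), genes=tuple(grp["gene"]))
        for ct, grp in df.groupby("cell_type", sort=True)
    ]


def collapse_probes_to_genes(
    dataset: ExpressionDataset, probes: pd.DataFrame
) -> pd.DataFrame:
    """One expression profile per gene: the probe with the highest mean.

    Returns a genes x samples DataFrame indexed by gene symbol.
    """
    means = dataset.values.mean(axis=1)
    ann = probes.assign(_mean=means.loc[probes["probe_id"]].to_numpy())
    best = (
        ann.sort_values(["_mean", "probe_id"], ascending=[False, True], kind="mergesort")
        .drop_duplicates("gene_symbol", keep="first")
    )
    mat = dataset.values.loc[best["probe_id"]]
    mat.index = best["gene_symbol"].to_numpy()
    return mat.sort_index()


def _donor_pc1_scores(marker_matrix: np.ndarray) -> np.ndarray:
    """PC1 sample scores of a centered markers x samples matrix (covariance PCA).

    The sign is fixed so scores correlate non-negatively with the
    per-sample mean marker expression.
    """
    centered = marker_matrix - marker_matrix.mean(axis=1, keepdims=True)
    # samples are observations, marker genes variables: scores = S * V^T rows
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = s[0] * vt[0]
    mean_profile = marker_matrix.mean(axis=0)
    c = np.corrcoef(scores, mean_profile)[0, 1] if np.std(mean_profile) > 0 else 0.0
    if np.isfinite(c) and c < 0:
        scores = -scores
    return scores


def estimate_mgp(
    gene_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    marker_set: MarkerSet,
) -> pd.DataFrame:
    """Estimate relative regional proportions of one cell type.

    Parameters
    ----------
    gene_matrix
        Genes x samples expression (see :func:`collapse_probes_to_genes`).
    samples
        Sample annotation with ``sample_id``, ``donor_id``, ``region_name``.
    marker_set
        The cell type's marker genes; markers absent from the matrix are
        dropped with a warning, at least two must remain.

    Returns one row per region with the scaled (z-scored, donor-averaged)
    estimate.
    """
    present = [g for g in marker_set.genes if g in gene_matrix.index]
    absent = sorted(set(marker_set.genes) - set(present))
    if absent:
        warnings.warn(
            f"{marker_set.cell_type}: {len(absent)} marker genes absent and dropped: "
            f"{absent[:5]}", stacklevel=2,
        )
    if len(present) < 2:
        raise ValueError(f"{marker_set.cell_type}: fewer than 2 markers measured")

    per_donor = []
    for donor, donor_samples in samples.groupby("donor_id", sort=True):
        cols = donor_samples["sample_id"].tolist()
        sub = gene_matrix.loc[present, cols].to_numpy()
        scores = _donor_pc1_scores(sub)
        regional = (
            pd.Series(scores, index=cols)
            .groupby(donor_samples.set_index("sample_id")["region_name"])
            .mean()
        )
        sd = regional.std(ddof=1)
        scaled = (regional - regional.mean()) / sd if sd > 0 else regional * 0.0
        per_donor.append(scaled.rename(donor))
    merged = pd.concat(per_donor, axis=1)
    estimate = merged.mean(axis=1)
    out = pd.DataFrame(
        {
            "region_name": estimate.index,
            "cell_type": marker_set.cell_type,
            "scaled_estimate": estimate.to_numpy(),
            "n_markers_used": len(present),
        }
    ).reset_index(drop=True)
    return out


def rank_regions(estimates: pd.DataFrame) -> pd.DataFrame:
    """Rank regions per cell type, 1 = highest scaled estimate.

    Ties break lexicographically by region name for determinism.
    """
    out = []
    for cell_type, grp in estimates.groupby("cell_type", sort=True):
        grp = grp.sort_values(
            ["scaled_estimate", "region_name"], ascending=[False, True], kind="mergesort"
        ).copy()
        grp["rank"] = np.arange(1, len(grp) + 1)
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def estimate_all_cell_types(
    gene_matrix: pd.DataFrame,
    samples: pd.DataFrame,
    marker_sets: Sequence[MarkerSet],
) -> pd.DataFrame:
    """MGP estimates and cross-region ranks for every marker set."""
    tables = [estimate_mgp(gene_matrix, samples, ms) for ms in marker_sets]
    return rank_regions(pd.concat(tables, ignore_index=True))
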