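"""Brain-wide transcriptomic similarity to a reference region.

A reference region's identity signal is summarized by the top-k genes of
its signed differential-expression ranking (k = 20 by default, giving a
specific rather than transcriptome-wide signal).  Every region's ranking
is then scored for enriched expression of those markers by AUROC with a
one-sided Mann-Whitney p-value, BH-FDR adjusted across regions.  By
construction the reference region scores AUROC = 1.0 against its own
markers; regions sharing the marker program (e.g. insular cortex for
claustrum markers) rank next.

Markers can also be scored in a second atlas's rankings (adult markers in
fetal regions): matching is by gene symbol and markers missing from a
ranking universe raise unless ``allow_missing`` drops them with a logged
count.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from regiontx.atlas_io import GeneSet
from regiontx.diffexpr import bh_fdr
from regiontx.enrichment import _ranking_genes, auroc, mwu_one_sided_p

logger = logging.getLogger(__name__)


def top_markers(ranking, k: int = 20, set_id: str = "top_markers") -> GeneSet:
    """The first k genes of a signed ranking, as a gene set."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    genes = _ranking_genes(ranking)
    if len(genes) < k:
        raise ValueError(f"ranking has {len(genes)} genes, fewer than k={k}")
    if k == len(genes):
        logger.warning("top_markers covers the entire universe; downstream AUROCs undefined")
    return GeneSet(set_id=set_id, label=f"top {k} ranking genes", genes=frozenset(genes[:k]))


def similarity_profile(
    marker_set: GeneSet,
    rankings_by_region: Mapping[str, object],
    reference_region: str | None = None,
    fdr_threshold: float = 0.05,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Score every region's ranking for enrichment of the reference markers.

    Returns one row per region sorted by AUROC descending, with one-sided
    Mann-Whitney p, BH-FDR across regions, and a significance flag
    (p_fdr < threshold and AUROC > 0.5).  When the markers are the
    reference region's own top-k, the reference row has AUROC exactly 1.
    """
    rows = []
    for region, ranking in sorted(rankings_by_region.items()):
        genes = _ranking_genes(ranking)
        universe = set(genes)
        present = marker_set.genes & universe
        missing = len(marker_set.genes) - len(present)
        if missing and not allow_missing:
            raise ValueError(
                f"{missing} marker genes absent from the ranking universe of "
                f"{region!r}; pass allow_missing=True to drop them"
            )
        if missing:
            logger.info("%s: dropped %d markers absent from universe", region, missing)
        subset = GeneSet(marker_set.set_id, marker_set.label, frozenset(present))
        rows.append(
            {
                "region_name": region,
                "n_markers": len(present),
                "auroc": auroc(genes, subset),
                "p": mwu_one_sided_p(genes, subset),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = (out["p_fdr"] < fdr_threshold) & (out["auroc"] > 0.5)
    out = out.sort_values(
        ["auroc", "region_name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out.insert(0, "rank", range(1, len(out) + 1))
    if reference_region is not None:
        out.attrs["reference_region"] = reference_region
    return out
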