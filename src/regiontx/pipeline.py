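"""End-to-end orchestration of the regional characterization stages.

A :class:`PipelineConfig` (loadable from YAML or JSON) drives either a
synthetic run (paired atlases generated in memory, planted truth saved
alongside the results) or an Allen-style bundle run.  ``run_characterize``
executes, per region of interest: differential expression, signed
ranking, gene-set enrichment with brain-wide specificity ranks, adult/
fetal overlap tests, marker-gene proportion estimates and top-k
similarity profiles — writing one CSV per table plus a JSON run manifest
(seed, thresholds, input hashes, package version) sufficient to replay
the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from regiontx import __version__
from regiontx.atlas_io import (
    GeneSetCollection,
    filter_gene_sets,
    filter_probes_to_named_genes,
    read_atlas_bundle,
    read_gene_sets_gmt,
)
from regiontx.diffexpr import region_differential_expression
from regiontx.enrichment import enrich_with_specificity
from regiontx.overlap import compare_gene_lists, compare_top_k, hypergeom_overlap
from regiontx.proportions import collapse_probes_to_genes, estimate_all_cell_types, read_marker_tsv
from regiontx.similarity import similarity_profile, top_markers
from regiontx.synthetic import (
    PlantedEffect,
    SimulationConfig,
    simulate_atlas,
    simulate_fetal_counterpart,
    simulate_gene_sets,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration shared by all subcommands."""

    mode: str = "synthetic"  # "synthetic" | "allen-bundle"
    regions_of_interest: tuple[str, ...] = ()
    gene_set_paths: tuple[str, ...] = ()
    fdr_threshold: float = 0.05
    set_size_min: int = 10
    set_size_max: int = 200
    top_k: int = 20
    seed: int = 0
    out_dir: str = "regiontx_results"
    # allen-bundle mode inputs
    expression_path: str | None = None
    probes_path: str | None = None
    samples_path: str | None = None
    marker_tsv: str | None = None
    # synthetic mode knobs
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fdr_threshold <= 0 or self.top_k <= 0 or self.set_size_min <= 0:
            raise ValueError("thresholds must be positive")
        if self.mode not in ("synthetic", "allen-bundle"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("regions_of_interest", "gene_set_paths"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_synthetic_config(config: PipelineConfig) -> SimulationConfig:
    syn = dict(config.synthetic)
    planted = tuple(
        PlantedEffect(p["region_name"], p["n_genes"], p["delta"], tuple(p["genes"]) if p.get("genes") else None)
        for p in syn.pop("planted", [{"region_name": "region_00", "n_genes": 20, "delta": 2.0}])
    )
    regions = syn.pop("regions", None)
    kwargs = dict(planted=planted, seed=config.seed, **syn)
    if regions is not None:
        kwargs["regions"] = tuple((r, n) for r, n in regions)
    return SimulationConfig(**kwargs)


def run_characterize(config: PipelineConfig) -> dict:
    """Run the full characterization; returns in-memory results and writes CSVs."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "thresholds": {
            "fdr": config.fdr_threshold,
            "set_size": [config.set_size_min, config.set_size_max],
            "top_k": config.top_k,
        },
        "input_hashes": {},
        "outputs": [],
    }

    if config.mode == "synthetic":
        sim = _default_synthetic_config(config)
        dataset, probes, samples, truth = simulate_atlas(sim)
        fetal = simulate_fetal_counterpart(truth, sim)
        collection = simulate_gene_sets(
            truth, n_null_sets=50,
            set_size_range=(config.set_size_min, min(config.set_size_max, 50)),
            enriched_overlap=min(10, min((e.n_genes for e in sim.planted), default=0)),
            seed=config.seed,
        )
        truth.to_json(out / "truth.json")
        manifest["synthetic_config"] = dataclasses.asdict(sim)
    else:
        for key in ("expression_path", "probes_path", "samples_path"):
            if getattr(config, key) is None:
                raise ValueError(f"allen-bundle mode requires {key}")
        dataset, probes, samples = read_atlas_bundle(
            config.expression_path, config.probes_path, config.samples_path
        )
        for key in ("expression_path", "probes_path", "samples_path"):
            manifest["input_hashes"][key] = _sha256(Path(getattr(config, key)))
        fetal = None
        collection = None
        if config.gene_set_paths:
            sets = []
            for p in config.gene_set_paths:
                sets.extend(read_gene_sets_gmt(p).sets)
                manifest["input_hashes"][str(p)] = _sha256(Path(p))
            collection = GeneSetCollection(tuple(sets), source=";".join(config.gene_set_paths))

    dataset, probes = filter_probes_to_named_genes(dataset, probes)
    universe = sorted(probes["gene_symbol"].unique())

    rois = config.regions_of_interest or tuple(sorted(samples["region_name"].unique())[:1])
    all_regions = sorted(samples["region_name"].unique())

    logger.info("characterize: %d regions, %d genes, rois=%s", len(all_regions),
                len(universe), list(rois))

    de_by_region = {
        region: region_differential_expression(
            dataset, probes, samples, region, config.fdr_threshold
        )
        for region in all_regions
    }
    rankings = {r: de_by_region[r]["ranking"] for r in all_regions}

    results: dict = {"de": de_by_region, "rankings": rankings, "manifest": manifest}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    for roi in rois:
        de = de_by_region[roi]
        _write(f"de_probes_{roi}.csv", de["probe_table"].sort_values(
            ["p", "probe_id"], kind="mergesort"))
        _write(f"de_genes_{roi}.csv", de["ranking"])

    if collection is not None:
        filtered = filter_gene_sets(collection, universe, config.set_size_min, config.set_size_max)
        enrichment = {}
        for roi in rois:
            table = enrich_with_specificity(rankings, filtered, roi)
            enrichment[roi] = table
            _write(f"enrichment_{roi}.csv", table)
        results["enrichment"] = enrichment

    for roi in rois:
        markers = top_markers(rankings[roi], k=config.top_k, set_id=f"top{config.top_k}_{roi}")
        profile = similarity_profile(markers, rankings, reference_region=roi,
                                     fdr_threshold=config.fdr_threshold)
        _write(f"similarity_{roi}.csv", profile)
        results.setdefault("similarity", {})[roi] = profile

    if config.mode == "synthetic" and fetal is not None:
        f_dataset, f_probes, f_samples, f_truth = fetal
        f_dataset, f_probes = filter_probes_to_named_genes(f_dataset, f_probes)
        fetal_de = {
            region: region_differential_expression(
                f_dataset, f_probes, f_samples, region, config.fdr_threshold
            )
            for region in sorted(f_samples["region_name"].unique())
        }
        results["fetal_de"] = fetal_de
        overlap_rows = []
        for roi in rois:
            up_a = de_by_region[roi]["up_regulated"]
            up_b = fetal_de[roi]["up_regulated"] if roi in fetal_de else []
            if up_a and up_b:
                test = compare_gene_lists(up_a, up_b, universe)
                overlap_rows.append(
                    {
                        "comparison": f"adult_vs_fetal_up_{roi}",
                        "n_universe": test.n_universe, "size_a": test.size_a,
                        "size_b": test.size_b, "overlap": test.overlap,
                        "p": test.p_upper, "log10_p": test.log10_p,
                        "genes": ";".join(test.genes),
                    }
                )
            top_test = compare_top_k(rankings[roi], fetal_de[roi]["ranking"],
                                     k=config.top_k, universe_size=len(universe))
            overlap_rows.append(
                {
                    "comparison": f"adult_vs_fetal_top{config.top_k}_{roi}",
                    "n_universe": top_test.n_universe, "size_a": top_test.size_a,
                    "size_b": top_test.size_b, "overlap": top_test.overlap,
                    "p": top_test.p_upper, "log10_p": top_test.log10_p,
                    "genes": ";".join(top_test.genes),
                }
            )
        if overlap_rows:
            _write("overlap_tests.csv", pd.DataFrame(overlap_rows))
            results["overlap"] = overlap_rows

    # proportion estimates: user marker TSV, or planted markers as pseudo cell types
    gene_matrix = collapse_probes_to_genes(dataset, probes)
    if config.marker_tsv:
        marker_sets = read_marker_tsv(config.marker_tsv)
        manifest["input_hashes"][config.marker_tsv] = _sha256(Path(config.marker_tsv))
    elif config.mode == "synthetic" and truth.marker_map:
        from regiontx.proportions import MarkerSet

        marker_sets = [
            MarkerSet(cell_type=f"planted_{region}", genes=tuple(sorted(genes)))
            for region, genes in truth.marker_map.items()
            if len(genes) >= 2
        ]
    else:
        marker_sets = []
    if marker_sets:
        proportions = estimate_all_cell_types(gene_matrix, samples, marker_sets)
        _write("cell_proportions.csv", proportions)
        results["proportions"] = proportions

    manifest["runtime_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("characterize finished in %.1fs -> %s", manifest["runtime_seconds"], out)
    return results


def run_overlap_benchmarks(n_universe: int | None = None) -> pd.DataFrame:
    """Recompute the shipped adult/fetal insula-claustrum overlap configurations.

    The shipped fixture records, for each published comparison between
    up-regulated (or top-20) gene lists of the adult and fetal insular and
    claustral regions, the list sizes and observed overlap in the
    20,778-gene measured universe.  Returns the table with freshly
    computed upper-tail hypergeometric p-values and their log10.
    """
    with resources.files("regiontx.data").joinpath("overlap_benchmarks.csv").open() as fh:
        bench = pd.read_csv(fh)
    rows = []
    for _, row in bench.iterrows():
        n = int(n_universe if n_universe is not None else row["n_universe"])
        test = hypergeom_overlap(int(row["overlap"]), int(row["size_a"]),
                                 int(row["size_b"]), n)
        rows.append(
            {
                "comparison": row["comparison"],
                "n_universe": n,
                "size_a": test.size_a, "size_b": test.size_b,
                "overlap": test.overlap,
                "p": test.p_upper, "log10_p": test.log10_p,
            }
        )
    return pd.DataFrame(rows)
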