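"""Synthetic paired adult/fetal expression atlases with planted ground truth.

The generator emulates the statistical structure of a donor-blocked
microarray atlas on the log2-intensity scale:

    y(p, s) = mu_g + o_p + a_donor(s) + delta_g * 1[region(s) = target(g)] + eps

with gene baselines mu_g ~ Uniform(4, 12) log2 units, per-probe offsets
o_p ~ N(0, probe_offset_sd^2), additive donor effects
a ~ N(0, donor_sd^2), Gaussian residual noise eps ~ N(0, noise_sd^2), and
region-specific up-regulation delta for planted marker genes.  A second
("fetal") atlas can be generated sharing a configurable fraction of each
region's planted markers, and gene-set collections with known enrichment
status can be planted for calibration of the enrichment stage.

Randomness is hierarchical: one global seed feeds per-component child
streams (keyed by component name and region index), so adding a region or
planting an extra effect does not perturb unrelated draws.  Everything is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from regiontx.atlas_io import ExpressionDataset, GeneSet, GeneSetCollection

#: Default test-scale configuration: ~3,000 probes x 128 samples,
#: seconds to simulate and analyze.
DEFAULT_REGIONS: tuple[tuple[str, int], ...] = tuple(
    (f"region_{i:02d}", 4) for i in range(8)
)


def _rng(seed: int, *key: object) -> np.random.Generator:
    """Child generator keyed by component name/indices under one global seed."""
    tokens = [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *tokens]))


@dataclass(frozen=True)
class PlantedEffect:
    """Region-specific up-regulation of marker genes.

    ``genes`` may name explicit gene symbols (letting two regions share a
    marker program); otherwise ``n_genes`` fresh markers are drawn.
    """

    region_name: str
    n_genes: int
    delta: float
    genes: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SimulationConfig:
    n_donors: int = 4
    regions: tuple[tuple[str, int], ...] = DEFAULT_REGIONS  # (name, samples per donor)
    n_genes: int = 2000
    probes_per_gene: float = 1.5  # non-integer: floor + Bernoulli(frac) extra probes
    donor_sd: float = 0.5
    noise_sd: float = 0.5
    probe_offset_sd: float = 0.25
    planted: tuple[PlantedEffect, ...] = ()
    shared_marker_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1 or self.n_genes < 1 or not self.regions:
            raise ValueError("counts must be >= 1 and at least one region given")
        if min(self.donor_sd, self.noise_sd, self.probe_offset_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.shared_marker_fraction <= 1.0:
            raise ValueError("shared_marker_fraction must lie in [0, 1]")
        region_names = [r for r, _ in self.regions]
        if len(set(region_names)) != len(region_names):
            raise ValueError("duplicate region names")
        for eff in self.planted:
            if eff.region_name not in region_names:
                raise ValueError(f"planted region {eff.region_name!r} not in regions")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated atlas."""

    marker_map: dict[str, dict[str, float]]  # region -> gene -> delta (log2)
    gene_symbols: tuple[str, ...]
    shared_markers: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_sets: GeneSetCollection | None = None
    set_status: dict[str, dict] = field(default_factory=dict)  # set_id -> {region, enriched}

    def all_marker_genes(self) -> set[str]:
        return {g for genes in self.marker_map.values() for g in genes}

    def markers_of(self, region_name: str) -> set[str]:
        return set(self.marker_map.get(region_name, {}))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marker_map": self.marker_map,
            "gene_symbols": list(self.gene_symbols),
            "shared_markers": {k: list(v) for k, v in self.shared_markers.items()},
            "set_status": self.set_status,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            marker_map=payload["marker_map"],
            gene_symbols=tuple(payload["gene_symbols"]),
            shared_markers={k: tuple(v) for k, v in payload.get("shared_markers", {}).items()},
            set_status=payload.get("set_status", {}),
        )


def _gene_symbols(n: int) -> tuple[str, ...]:
    return tuple(f"G{i:05d}" for i in range(1, n + 1))


def _assign_markers(config: SimulationConfig, genes: tuple[str, ...]) -> dict[str, dict[str, float]]:
    rng = _rng(config.seed, "markers")
    taken: set[str] = set()
    for eff in config.planted:
        if eff.genes is not None:
            taken |= set(eff.genes)
    marker_map: dict[str, dict[str, float]] = {}
    for i, eff in enumerate(config.planted):
        if eff.genes is not None:
            unknown = set(eff.genes) - set(genes)
            if unknown:
                raise ValueError(f"planted genes not simulated: {sorted(unknown)[:5]}")
            chosen = tuple(eff.genes)
        else:
            pool = [g for g in genes if g not in taken]
            if eff.n_genes > len(pool):
                raise ValueError(
                    f"planted markers for {eff.region_name!r} exceed available genes"
                )
            chosen = tuple(sorted(rng.choice(pool, size=eff.n_genes, replace=False)))
            taken |= set(chosen)
        marker_map.setdefault(eff.region_name, {})
        for g in chosen:
            marker_map[eff.region_name][g] = eff.delta
    return marker_map


def simulate_atlas(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate one atlas bundle plus its ground truth.

    Returns ``(dataset, probes, samples, truth)`` in the same layout the
    atlas readers produce.  Deterministic for a fixed config.
    """
    genes = _gene_symbols(config.n_genes)
    marker_map = _assign_markers(config, genes)

    # probes per gene: constant if integral, else floor + Bernoulli(frac)
    base = int(np.floor(config.probes_per_gene))
    frac = config.probes_per_gene - base
    rng_probes = _rng(config.seed, "probes")
    n_probes_per_gene = np.full(config.n_genes, max(base, 1), dtype=int)
    if frac > 0:
        n_probes_per_gene += rng_probes.random(config.n_genes) < frac

    probe_ids, probe_gene = [], []
    for g, npb in zip(genes, n_probes_per_gene):
        for j in range(npb):
            probe_ids.append(f"{g}_p{j + 1}")
            probe_gene.append(g)
    n_probes = len(probe_ids)
    probe_gene = np.asarray(probe_gene)

    donors = [f"donor_{d + 1}" for d in range(config.n_donors)]
    rows = []
    for donor in donors:
        for region, n_per in config.regions:
            for i in range(n_per):
                rows.append((f"{donor}.{region}.{i + 1}", donor, region))
    samples = pd.DataFrame(rows, columns=["sample_id", "donor_id", "region_name"])
    structure_ids = {r: f"S{i + 1:03d}" for i, (r, _) in enumerate(config.regions)}
    samples["structure_id"] = samples["region_name"].map(structure_ids)

    mu = _rng(config.seed, "mu").uniform(4.0, 12.0, size=config.n_genes)
    mu_by_gene = dict(zip(genes, mu))
    offsets = _rng(config.seed, "offset").normal(0.0, config.probe_offset_sd, size=n_probes)
    donor_effects = dict(
        zip(donors, _rng(config.seed, "donor").normal(0.0, config.donor_sd, size=len(donors)))
    )

    gene_idx = {g: i for i, g in enumerate(genes)}
    baseline = np.array([mu_by_gene[g] for g in probe_gene]) + offsets  # per probe

    n_samples = len(samples)
    values = np.empty((n_probes, n_samples))
    # per-probe delta for each region with planted markers
    delta_by_region = {}
    for region, gene_deltas in marker_map.items():
        delta_probe = np.array([gene_deltas.get(g, 0.0) for g in probe_gene])
        delta_by_region[region] = delta_probe

    col = 0
    for donor in donors:
        for r_idx, (region, n_per) in enumerate(config.regions):
            eps = _rng(config.seed, "noise", donor, r_idx).normal(
                0.0, config.noise_sd, size=(n_probes, n_per)
            )
            block = baseline[:, None] + donor_effects[donor] + eps
            if region in delta_by_region:
                block += delta_by_region[region][:, None]
            values[:, col : col + n_per] = block
            col += n_per

    dataset = ExpressionDataset(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=samples["sample_id"].tolist())
    )
    probes = pd.DataFrame({"probe_id": probe_ids, "gene_symbol": probe_gene})
    truth = SyntheticTruth(marker_map=marker_map, gene_symbols=genes)
    return dataset, probes, samples, truth


def simulate_fetal_counterpart(
    adult_truth: SyntheticTruth, config: SimulationConfig
) -> tuple[ExpressionDataset, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a second atlas reusing a fraction of the adult planted markers.

    For each planted effect whose region also has adult markers, exactly
    ``round(shared_marker_fraction * n_genes)`` markers are reused from the
    adult set (deterministic subsample) and the remainder drawn fresh from
    genes that are not adult markers, so fraction 0 yields disjoint sets by
    construction.  The returned truth records the shared subset per region.
    """
    rng = _rng(config.seed, "fetal-share")
    genes = _gene_symbols(config.n_genes)
    adult_all = adult_truth.all_marker_genes()
    new_planted = []
    shared_markers: dict[str, tuple[str, ...]] = {}
    used: set[str] = set()
    for eff in config.planted:
        if eff.genes is not None:
            new_planted.append(eff)
            continue
        adult_markers = sorted(adult_truth.markers_of(eff.region_name))
        n_shared = int(round(config.shared_marker_fraction * eff.n_genes))
        n_shared = min(n_shared, len(adult_markers))
        shared = tuple(sorted(rng.choice(adult_markers, size=n_shared, replace=False))) \
            if n_shared else ()
        pool = [g for g in genes if g not in adult_all and g not in used]
        n_fresh = eff.n_genes - n_shared
        if n_fresh > len(pool):
            raise ValueError(f"not enough non-adult-marker genes for {eff.region_name!r}")
        fresh = tuple(sorted(rng.choice(pool, size=n_fresh, replace=False)))
        used |= set(fresh) | set(shared)
        shared_markers[eff.region_name] = shared
        new_planted.append(
            PlantedEffect(eff.region_name, eff.n_genes, eff.delta, genes=shared + fresh)
        )
    fetal_config = SimulationConfig(
        n_donors=config.n_donors,
        regions=config.regions,
        n_genes=config.n_genes,
        probes_per_gene=config.probes_per_gene,
        donor_sd=config.donor_sd,
        noise_sd=config.noise_sd,
        probe_offset_sd=config.probe_offset_sd,
        planted=tuple(new_planted),
        shared_marker_fraction=config.shared_marker_fraction,
        seed=config.seed + 1,
    )
    dataset, probes, samples, truth = simulate_atlas(fetal_config)
    truth.shared_markers = shared_markers
    return dataset, probes, samples, truth


def simulate_gene_sets(
    truth: SyntheticTruth,
    n_null_sets: int,
    set_size_range: tuple[int, int],
    enriched_overlap: int,
    seed: int = 0,
) -> GeneSetCollection:
    """Plant a gene-set collection with known enrichment status.

    Null sets are drawn uniformly from non-marker genes.  For every region
    with planted markers (and ``enriched_overlap > 0``) one enriched set is
    built containing ``enriched_overlap`` of that region's markers plus
    random non-marker fill.  Labels land in ``truth.set_status``
    (set_id -> {"region": name or None, "enriched": bool}).
    """
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid set_size_range {set_size_range}")
    rng = _rng(seed, "gene-sets")
    markers = truth.all_marker_genes()
    background = sorted(set(truth.gene_symbols) - markers)
    sets, status = [], {}
    if enriched_overlap > 0:
        for region in sorted(truth.marker_map):
            region_markers = sorted(truth.marker_map[region])
            if enriched_overlap > len(region_markers):
                raise ValueError(
                    f"requested overlap {enriched_overlap} exceeds the "
                    f"{len(region_markers)} planted markers of {region!r}"
                )
            size = int(rng.integers(max(lo, enriched_overlap), hi + 1))
            core = list(rng.choice(region_markers, size=enriched_overlap, replace=False))
            fill = list(rng.choice(background, size=size - enriched_overlap, replace=False))
            set_id = f"enriched_{region}"
            sets.append(GeneSet(set_id, f"planted enriched set for {region}",
                                frozenset(core + fill)))
            status[set_id] = {"region": region, "enriched": True}
    for i in range(n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = frozenset(rng.choice(background, size=size, replace=False))
        set_id = f"null_{i:04d}"
        sets.append(GeneSet(set_id, "planted null set", genes))
        status[set_id] = {"region": None, "enriched": False}
    collection = GeneSetCollection(tuple(sets), source="synthetic")
    truth.planted_sets = collection
    truth.set_status.update(status)
    return collection


def make_ontology(config: SimulationConfig) -> pd.DataFrame:
    """A flat two-level ontology (root -> regions) matching the simulated atlas."""
    rows = [{"structure_id": "S000", "name": "brain", "parent_structure_id": ""}]
    for i, (region, _) in enumerate(config.regions):
        rows.append(
            {"structure_id": f"S{i + 1:03d}", "name": region, "parent_structure_id": "S000"}
        )
    return pd.DataFrame(rows)


def simulate_proportion_atlas(
    n_donors: int = 3,
    n_regions: int = 10,
    samples_per_region: int = 4,
    cell_types: tuple[str, ...] = ("neuron",),
    markers_per_type: int = 21,
    n_background_genes: int = 200,
    donor_sd: float = 0.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list, pd.DataFrame]:
    """Gene-level atlas where latent regional cell proportions scale marker genes.

    For each cell type a latent proportion per region is drawn
    Uniform(0, 2); each of its markers responds with a positive loading
    Uniform(0.5, 1.5), on top of gene baseline, additive donor effect and
    Gaussian noise.  Returns ``(gene_matrix, samples, marker_sets,
    truth)`` where truth has one row per (region, cell_type) with the
    latent proportion — the target for recovery tests of the MGP
    estimator.
    """
    from regiontx.proportions import MarkerSet

    rng = _rng(seed, "proportions")
    regions = [f"region_{i:02d}" for i in range(n_regions)]
    donors = [f"donor_{d + 1}" for d in range(n_donors)]
    marker_sets, marker_rows = [], []
    gene_names: list[str] = []
    loadings: dict[str, tuple[str, float]] = {}  # gene -> (cell_type, loading)
    for ct in cell_types:
        names = [f"{ct.upper()}_M{i:02d}" for i in range(markers_per_type)]
        marker_sets.append(MarkerSet(cell_type=ct, genes=tuple(names)))
        for g in names:
            loadings[g] = (ct, float(rng.uniform(0.5, 1.5)))
        gene_names += names
    gene_names += [f"BG{i:04d}" for i in range(n_background_genes)]

    proportions = {
        (r, ct): float(rng.uniform(0.0, 2.0)) for ct in cell_types for r in regions
    }
    mu = dict(zip(gene_names, rng.uniform(4.0, 12.0, size=len(gene_names))))
    donor_eff = dict(zip(donors, rng.normal(0.0, donor_sd, size=n_donors)))

    rows, cols = [], []
    for donor in donors:
        for region in regions:
            for i in range(samples_per_region):
                cols.append((f"{donor}.{region}.{i + 1}", donor, region))
    samples = pd.DataFrame(cols, columns=["sample_id", "donor_id", "region_name"])

    values = np.empty((len(gene_names), len(samples)))
    for j, (sid, donor, region) in enumerate(cols):
        eps = rng.normal(0.0, noise_sd, size=len(gene_names))
        for i, g in enumerate(gene_names):
            signal = 0.0
            if g in loadings:
                ct, lam = loadings[g]
                signal = lam * proportions[(region, ct)]
            values[i, j] = mu[g] + donor_eff[donor] + signal + eps[i]
    gene_matrix = pd.DataFrame(values, index=gene_names, columns=samples["sample_id"].tolist())
    truth = pd.DataFrame(
        [
            {"region_name": r, "cell_type": ct, "proportion": p}
            for (r, ct), p in sorted(proportions.items())
        ]
    )
    return gene_matrix, samples, marker_sets, truth
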