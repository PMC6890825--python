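"""Reading, writing and filtering Allen-style expression atlas bundles.

An atlas bundle follows the Allen Institute file-layout convention:

``MicroarrayExpression.csv``
    No header; first column is the probe id, remaining columns are one
    log2-intensity value per sample, in the row order of the sample
    annotation file.
``Probes.csv``
    Header row; at least ``probe_id`` and ``gene_symbol`` columns.
``SampleAnnot.csv``
    Header row; at least ``sample_id``, ``donor_id``, ``region_name``
    and (optionally) ``structure_id`` columns.
``Ontology.csv``
    Header row; ``structure_id``, ``name``, ``parent_structure_id``
    (empty for roots).

Gene-set collections are read from GMT files or DisGeNET-style curated
gene-disease TSV files.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ("probe_id", "gene_symbol")
SAMPLE_COLUMNS = ("sample_id", "donor_id", "region_name")
ONTOLOGY_COLUMNS = ("structure_id", "name", "parent_structure_id")

#: Values in a gene-symbol column that mean "probe not mapped to a gene".
UNMAPPED_SYMBOLS = frozenset({"", "NA", "na", "NaN", "nan", "null", "None"})

#: Explicit region merges applied before any ontology walk: dorsal and
#: ventral claustrum are combined into a single claustrum grouping, and the
#: agranular insular samples (area Iag) are grouped with the dysgranular
#: insular cortex.
DEFAULT_MERGE_RULES: tuple[tuple[str, str], ...] = (
    (r"^(dorsal|ventral) claustrum$", "claustrum"),
    (r"^agranular insular cortex( \(area Iag\))?$", "dysgranular insular cortex"),
)

#: Region names matching this pattern are treated as fine cortical
#: zone/layer dissections and walked up the ontology to their enclosing
#: named cortical region when zone collapse is enabled.
DEFAULT_ZONE_PATTERN = r"\b(zone|layer|lamina)\b"


class AtlasFormatError(ValueError):
    """A bundle or gene-set file violates its format contract."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A probes x samples matrix of log2 intensities.

    ``values`` is indexed by probe id (unique) with one column per
    annotated sample, in annotation order.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise AtlasFormatError(f"duplicate probe ids: {dups[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise AtlasFormatError("expression matrix contains non-finite values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols."""

    set_id: str
    label: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise AtlasFormatError(f"gene set {self.set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of gene sets with a provenance tag."""

    sets: tuple[GeneSet, ...]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise AtlasFormatError(f"duplicate set_ids in collection: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: object) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise AtlasFormatError(f"{path}: missing required columns {missing}")


def read_atlas_bundle(
    expression_path: str | Path,
    probes_path: str | Path,
    samples_path: str | Path,
) -> tuple[ExpressionDataset, pd.DataFrame, pd.DataFrame]:
    """Read one atlas bundle (expression matrix, probe and sample annotations).

    Returns ``(dataset, probes, samples)`` with the matrix columns renamed to
    the annotated sample ids.  Raises :class:`AtlasFormatError` naming the
    offending file when probe or sample counts disagree.
    """
    probes = pd.read_csv(probes_path, dtype=str).fillna("")
    _require_columns(probes, PROBE_COLUMNS, probes_path)
    samples = pd.read_csv(samples_path, dtype=str)
    _require_columns(samples, SAMPLE_COLUMNS, samples_path)

    matrix = pd.read_csv(expression_path, header=None, index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "probe_id"

    if matrix.shape[1] != len(samples):
        raise AtlasFormatError(
            f"{expression_path}: matrix has {matrix.shape[1]} sample columns but "
            f"{samples_path} annotates {len(samples)} samples"
        )
    if len(matrix) != len(probes) or set(matrix.index) != set(probes["probe_id"]):
        raise AtlasFormatError(
            f"{expression_path}: matrix probes do not match {probes_path} "
            f"({len(matrix)} vs {len(probes)} rows)"
        )
    matrix.columns = samples["sample_id"].tolist()
    probes = probes.set_index("probe_id", drop=False).loc[matrix.index].reset_index(drop=True)
    dataset = ExpressionDataset(matrix.astype(float))
    logger.info(
        "read bundle: %d probes x %d samples from %s", *dataset.shape, expression_path
    )
    return dataset, probes, samples


def read_donor_bundles(
    bundle_dirs: Sequence[str | Path],
    donor_ids: Sequence[str] | None = None,
) -> tuple[ExpressionDataset, pd.DataFrame, pd.DataFrame]:
    """Read per-donor bundle directories and concatenate them column-wise.

    Each directory must contain ``MicroarrayExpression.csv``, ``Probes.csv``
    and ``SampleAnnot.csv``.  Sample ids are re-keyed to
    ``{donor_id}_{ordinal}`` so donors can be fit jointly with donor
    coefficients downstream.  All donors must share the same probe set.
    """
    parts, all_samples = [], []
    probes_ref: pd.DataFrame | None = None
    for i, d in enumerate(bundle_dirs):
        d = Path(d)
        dataset, probes, samples = read_atlas_bundle(
            d / "MicroarrayExpression.csv", d / "Probes.csv", d / "SampleAnnot.csv"
        )
        donor = donor_ids[i] if donor_ids is not None else samples["donor_id"].iloc[0]
        new_ids = [f"{donor}_{j}" for j in range(len(samples))]
        samples = samples.assign(sample_id=new_ids, donor_id=donor)
        values = dataset.values.copy()
        values.columns = new_ids
        if probes_ref is None:
            probes_ref = probes
        else:
            if not probes_ref["probe_id"].equals(probes["probe_id"]):
                raise AtlasFormatError(f"{d}: probe set differs from first donor bundle")
        parts.append(values)
        all_samples.append(samples)
    if not parts:
        raise AtlasFormatError("no bundle directories given")
    merged = pd.concat(parts, axis=1)
    samples = pd.concat(all_samples, ignore_index=True)
    return ExpressionDataset(merged), probes_ref, samples


def write_atlas_bundle(
    out_dir: str | Path,
    dataset: ExpressionDataset,
    probes: pd.DataFrame,
    samples: pd.DataFrame,
    ontology: pd.DataFrame | None = None,
) -> Path:
    """Write a bundle in the Allen file-layout convention; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.values.to_csv(out / "MicroarrayExpression.csv", header=False)
    probes.to_csv(out / "Probes.csv", index=False)
    samples.to_csv(out / "SampleAnnot.csv", index=False)
    if ontology is not None:
        ontology.to_csv(out / "Ontology.csv", index=False)
    return out


def read_ontology(path: str | Path) -> pd.DataFrame:
    """Read a region ontology CSV and check that parent links form a forest."""
    onto = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(onto, ONTOLOGY_COLUMNS, path)
    validate_ontology(onto)
    return onto


def validate_ontology(ontology: pd.DataFrame) -> None:
    """Raise if parent links contain a cycle."""
    parent = dict(zip(ontology["structure_id"], ontology["parent_structure_id"]))
    for start in parent:
        seen = {start}
        node = parent.get(start, "")
        while node:
            if node in seen:
                raise AtlasFormatError(f"ontology parent links contain a cycle at {node!r}")
            seen.add(node)
            node = parent.get(node, "")


def filter_probes_to_named_genes(
    dataset: ExpressionDataset, probes: pd.DataFrame
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Drop probes whose gene symbol is missing or unmapped.

    Symbols are whitespace-stripped and compared case-sensitively; empty
    strings and NA spellings mean unmapped.  Raises if no probe survives.
    Idempotent.
    """
    symbols = probes["gene_symbol"].astype(str).str.strip()
    keep = ~symbols.isin(UNMAPPED_SYMBOLS)
    if not keep.any():
        raise AtlasFormatError("probe filtering removed every probe: no mapped gene symbols")
    probes = probes.loc[keep.to_numpy()].assign(gene_symbol=symbols[keep].to_numpy())
    probes = probes.reset_index(drop=True)
    filtered = ExpressionDataset(dataset.values.loc[probes["probe_id"].to_numpy()])
    n_genes = probes["gene_symbol"].nunique()
    logger.info(
        "probe filter: %d -> %d probes mapping to %d gene symbols",
        dataset.shape[0], filtered.shape[0], n_genes,
    )
    return filtered, probes


def group_fetal_regions(
    samples: pd.DataFrame,
    ontology: pd.DataFrame | None = None,
    merge_rules: Iterable[tuple[str, str]] = DEFAULT_MERGE_RULES,
    collapse_zones: bool = False,
    named_regions: Sequence[str] | None = None,
    zone_pattern: str = DEFAULT_ZONE_PATTERN,
) -> pd.DataFrame:
    """Collapse fine fetal dissections into their enclosing named regions.

    Two mechanisms, applied in order:

    1. explicit ``merge_rules`` — an ordered list of (regex pattern,
       target name) pairs applied to ``region_name`` (first match wins);
       the defaults merge dorsal/ventral claustrum into a single claustrum
       grouping and fold the agranular insular samples into the
       dysgranular insular cortex;
    2. with ``collapse_zones=True``, samples whose region name matches
       ``zone_pattern`` (cortical zone/layer dissections) are walked up
       the ontology until a name in ``named_regions`` is reached (or, if
       ``named_regions`` is None, the first ancestor not matching the
       zone pattern).

    Returns a copy of ``samples`` with rewritten ``region_name``; never
    increases the number of distinct names.  Raises listing orphan samples
    whose walk finds no enclosing named region.
    """
    out = samples.copy()
    compiled = [(re.compile(p, re.IGNORECASE), target) for p, target in merge_rules]

    def apply_rules(name: str) -> str:
        for pat, target in compiled:
            if pat.search(name):
                return target
        return name

    out["region_name"] = out["region_name"].map(apply_rules)

    if collapse_zones:
        if ontology is None:
            raise ValueError("collapse_zones=True requires an ontology")
        zone_re = re.compile(zone_pattern, re.IGNORECASE)
        parent = dict(zip(ontology["structure_id"], ontology["parent_structure_id"]))
        name_of = dict(zip(ontology["structure_id"], ontology["name"]))
        named = set(named_regions) if named_regions is not None else None

        def is_named(name: str) -> bool:
            if named is not None:
                return name in named
            return not zone_re.search(name)

        resolved: dict[str, str | None] = {}

        def walk(structure_id: str) -> str | None:
            if structure_id in resolved:
                return resolved[structure_id]
            node, target = structure_id, None
            while node:
                name = name_of.get(node, "")
                if name and is_named(name):
                    target = name
                    break
                node = parent.get(node, "")
            resolved[structure_id] = target
            return target

        orphans = []
        new_names = []
        for _, row in out.iterrows():
            if zone_re.search(row["region_name"]):
                target = walk(str(row.get("structure_id", "")))
                if target is None:
                    orphans.append(row["sample_id"])
                    new_names.append(row["region_name"])
                else:
                    new_names.append(apply_rules(target))
            else:
                new_names.append(row["region_name"])
        if orphans:
            raise AtlasFormatError(
                f"{len(orphans)} samples have no enclosing named region: {orphans[:10]}"
            )
        out["region_name"] = new_names

    n_before = samples["region_name"].nunique()
    n_after = out["region_name"].nunique()
    logger.info("region grouping: %d -> %d distinct region names", n_before, n_after)
    return out


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one tab-separated ``set_id description gene...`` per line."""
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AtlasFormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            sets.append(GeneSet(set_id=fields[0], label=fields[1], genes=genes))
    return GeneSetCollection(tuple(sets), source=str(path))


def write_gene_sets_gmt(path: str | Path, collection: GeneSetCollection) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.label, *sorted(s.genes)]) + "\n")


def read_disgenet_tsv(
    path: str | Path,
    gene_col: str = "geneSymbol",
    disease_col: str = "diseaseName",
    disease_id_col: str | None = "diseaseId",
) -> GeneSetCollection:
    """Read a DisGeNET-style curated gene-disease TSV into one set per disease."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [gene_col, disease_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AtlasFormatError(f"{path}: missing required columns {missing}")
    id_col = disease_id_col if disease_id_col in df.columns else disease_col
    sets = []
    for (set_id, label), group in sorted(
        df.groupby([id_col, disease_col]), key=lambda kv: kv[0]
    ):
        genes = frozenset(g.strip() for g in group[gene_col] if str(g).strip())
        sets.append(GeneSet(set_id=str(set_id), label=str(label), genes=genes))
    return GeneSetCollection(tuple(sets), source=str(path))


def filter_gene_sets(
    collection: GeneSetCollection,
    measured_genes: Iterable[str],
    min_size: int = 10,
    max_size: int = 200,
) -> GeneSetCollection:
    """Intersect each set with the measured gene universe and size-filter.

    Sets whose intersected size falls outside ``[min_size, max_size]``
    (bounds inclusive) are dropped, matching the convention of testing only
    gene sets with 10-200 genes measured on the platform.
    """
    universe = set(measured_genes)
    if not universe:
        raise ValueError("measured_genes is empty")
    kept = []
    for s in collection:
        genes = frozenset(s.genes & universe)
        if min_size <= len(genes) <= max_size:
            kept.append(replace(s, genes=genes))
    logger.info("gene-set filter: %d -> %d sets within [%d, %d]",
                len(collection), len(kept), min_size, max_size)
    return GeneSetCollection(tuple(kept), source=collection.source)
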