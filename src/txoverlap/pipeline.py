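"""End-to-end orchestration: DE -> signatures -> (equalize) -> (translate)
-> overlaps -> overlap-proportion tests -> enrichment -> tabular reports.

A run is driven by a single YAML config so that a nine-system comparison plan
stays reviewable; every stage writes its table under the output directory and
a JSON summary collects all counts, percentages, test p-values and
translation reports. Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import io as txio
from .datatypes import ConfigError, DiseaseSignature, GeneSetCollection, HomologTable
from .diffexpr import (
    SelectionConfig,
    differential_expression,
    equalize_signatures,
    select_signature,
)
from .enrichment import enrich_gene_sets
from .homology import translate_signature
from .overlap import (
    compare_overlap_proportions,
    comparisons_to_frame,
    overlaps_to_frame,
    pairwise_overlap,
    triple_overlap,
)
from .synthetic import MultiDiseaseConfig, StudyConfig, simulate_gene_sets, simulate_multi_disease

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class DatasetSpec:
    label: str
    expression: str
    design: str
    annotation: str
    selection: SelectionConfig = field(default_factory=SelectionConfig)


@dataclass
class PipelineConfig:
    datasets: list[DatasetSpec]
    seed: int = 0
    equalize: bool = False
    target_taxon: str | None = None
    homologs: str | None = None
    gene_sets: str | None = None
    pairs: list[tuple[str, str]] | None = None
    triples: list[tuple[str, str, str]] | None = None
    overlap_tests: list[dict] | None = None

    def __post_init__(self) -> None:
        labels = [d.label for d in self.datasets]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate dataset labels in pipeline config")
        known = set(labels)
        for pair in self.pairs or []:
            if not set(pair) <= known:
                raise ConfigError(f"comparison pair {pair} references unknown dataset")
        for triple in self.triples or []:
            if not set(triple) <= known:
                raise ConfigError(f"comparison triple {triple} references unknown dataset")
        for test in self.overlap_tests or []:
            refs = {test.get("reference"), *test.get("versus", ())}
            if not refs <= known:
                raise ConfigError(f"overlap test {test} references unknown dataset")


def load_pipeline_config(path) -> PipelineConfig:
    base = Path(path).parent
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "datasets" not in raw:
        raise ConfigError(f"{path}: pipeline config must be a mapping with 'datasets'")

    def resolve(p):
        return str((base / p).resolve()) if p else None

    datasets = []
    for entry in raw["datasets"]:
        sel = SelectionConfig(**entry.get("selection", {}))
        datasets.append(
            DatasetSpec(
                label=str(entry["label"]),
                expression=resolve(entry["expression"]),
                design=resolve(entry["design"]),
                annotation=resolve(entry["annotation"]),
                selection=sel,
            )
        )
    comp = raw.get("comparisons", {}) or {}
    cfg = PipelineConfig(
        datasets=datasets,
        seed=int(raw.get("seed", 0)),
        equalize=bool(raw.get("equalize", False)),
        target_taxon=str(raw["target_taxon"]) if raw.get("target_taxon") else None,
        homologs=resolve(raw.get("homologs")),
        gene_sets=resolve(raw.get("gene_sets")),
        pairs=[tuple(p) for p in comp["pairs"]] if comp.get("pairs") else None,
        triples=[tuple(t) for t in comp["triples"]] if comp.get("triples") else None,
        overlap_tests=comp.get("overlap_tests"),
    )
    for spec in cfg.datasets:
        for path_ in (spec.expression, spec.design, spec.annotation):
            if not Path(path_).is_file():
                raise ConfigError(f"dataset {spec.label!r}: missing file {path_}")
    for path_ in (cfg.homologs, cfg.gene_sets):
        if path_ and not Path(path_).is_file():
            raise ConfigError(f"missing file {path_}")
    return cfg


def _signatures_for(config: PipelineConfig) -> tuple[dict[str, DiseaseSignature], dict, dict]:
    """DE + selection per dataset. Returns (signatures, de tables, universes)."""
    signatures: dict[str, DiseaseSignature] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    universes: dict[str, set[str]] = {}
    for spec in config.datasets:
        matrix = txio.read_expression(spec.expression)
        design = txio.read_design(spec.design)
        annotation = txio.read_annotation(spec.annotation)
        records = differential_expression(matrix, design, annotation)
        de_tables[spec.label] = records
        signatures[spec.label] = select_signature(
            records, annotation, spec.selection, spec.label
        )
        universes[spec.label] = annotation.annotated_genes
    return signatures, de_tables, universes


def run(config: PipelineConfig, out_dir) -> dict:
    """Execute the full comparison plan; returns the JSON-ready summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    logger.info("stage: differential expression")
    signatures, de_tables, universes = _signatures_for(config)
    tables: dict[str, pd.DataFrame] = {}
    for label, records in de_tables.items():
        tables[f"de_{label}"] = records
    summary["stages"]["diffexpr"] = {
        label: {"n_probes": len(t), "signature_size": len(signatures[label])}
        for label, t in de_tables.items()
    }

    if config.equalize:
        logger.info("stage: equalize signatures")
        labels = list(signatures)
        equalized = equalize_signatures([signatures[lab] for lab in labels])
        signatures = dict(zip(labels, equalized))
        summary["stages"]["equalize"] = {lab: len(sig) for lab, sig in signatures.items()}

    homologs: HomologTable | None = None
    if config.homologs:
        homologs = txio.read_homologs(config.homologs)
    if config.target_taxon:
        logger.info("stage: homolog translation to taxon %s", config.target_taxon)
        reports = {}
        for label, sig in list(signatures.items()):
            if sig.taxon != config.target_taxon:
                if homologs is None:
                    raise ConfigError(
                        f"dataset {label!r} needs translation to {config.target_taxon} "
                        "but no homolog table was given"
                    )
                translated, report = translate_signature(sig, homologs, config.target_taxon)
                signatures[label] = translated
                reports[label] = report.as_dict()
        summary["stages"]["translation"] = reports

    for label, sig in signatures.items():
        txio.write_signature(sig, out / f"signature_{label}.tsv")

    logger.info("stage: overlaps")
    pairs = config.pairs or [tuple(p) for p in combinations(signatures, 2)]
    overlap_results = []
    pair_results = {}
    for a, b in pairs:
        ov = pairwise_overlap(signatures[a], signatures[b])
        overlap_results.append(ov)
        pair_results[(a, b)] = ov
    tables["overlap_pairs"] = overlaps_to_frame(overlap_results)
    summary["stages"]["overlaps"] = [
        {
            "pair": [r.label_a, r.label_b],
            "n_a": r.n_a,
            "n_b": r.n_b,
            "n_overlap": r.n_overlap,
            "pct_wrt_a": round(r.pct_wrt_a),
            "pct_wrt_b": round(r.pct_wrt_b),
            "n_concordant_up": r.n_concordant_up,
            "n_concordant_down": r.n_concordant_down,
            "n_discordant": r.n_discordant,
        }
        for r in overlap_results
    ]

    triples = config.triples
    if triples is None and len(signatures) == 3:
        triples = [tuple(signatures)]
    venn_rows, center_rows = [], []
    for triple in triples or []:
        a, b, c = triple
        tr = triple_overlap(signatures[a], signatures[b], signatures[c])
        for region, count in tr.region_counts.items():
            venn_rows.append({"labels": "|".join(triple), "region": region, "count": count})
        for gene in sorted(tr.center_genes):
            da, db, dc = tr.center_directions[gene]
            center_rows.append(
                {"labels": "|".join(triple), "gene": gene, a: da, b: db, c: dc}
            )
    if venn_rows:
        tables["venn_regions"] = pd.DataFrame(venn_rows)
        tables["center_genes"] = pd.DataFrame(center_rows) if center_rows else pd.DataFrame(
            columns=["labels", "gene"]
        )
        summary["stages"]["triples"] = venn_rows

    logger.info("stage: overlap-proportion tests")
    test_plan = config.overlap_tests
    if test_plan is None:
        test_plan = [
            {"reference": ref, "versus": [x, y]}
            for ref in signatures
            for x, y in combinations([s for s in signatures if s != ref], 2)
        ]
    comparisons = []
    for test in test_plan:
        ref = test["reference"]
        x, y = test["versus"]
        ov_x = pair_results.get((ref, x)) or pair_results.get((x, ref)) or pairwise_overlap(
            signatures[ref], signatures[x]
        )
        ov_y = pair_results.get((ref, y)) or pair_results.get((y, ref)) or pairwise_overlap(
            signatures[ref], signatures[y]
        )
        comparisons.append(
            compare_overlap_proportions(
                ov_x.n_overlap,
                len(signatures[x]),
                ov_y.n_overlap,
                len(signatures[y]),
                label=f"{ref}: {x} vs {y}",
            )
        )
    tables["overlap_comparisons"] = comparisons_to_frame(comparisons)
    summary["stages"]["comparisons"] = [
        {
            "label": c.label,
            "table": c.table,
            "test_used": c.test_used,
            "p_two_sided": c.p_two_sided,
        }
        for c in comparisons
    ]

    if config.gene_sets:
        logger.info("stage: gene-set enrichment")
        collection: GeneSetCollection = txio.read_gmt(config.gene_sets)
        target = config.target_taxon
        universe: set[str] = set()
        for spec in config.datasets:
            # universe = annotated platform genes already in the target space
            sig = signatures[spec.label]
            if target is None or sig.taxon == target:
                universe |= universes[spec.label]
        enr_summaries = {}
        for (a, b), ov in pair_results.items():
            for category, genes in (
                ("concordant_up", ov.concordant_up),
                ("concordant_down", ov.concordant_down),
                ("discordant", ov.discordant),
            ):
                if not genes:
                    continue
                df = enrich_gene_sets(genes, collection, universe)
                tables[f"enrichment_{a}_{b}_{category}"] = df
                enr_summaries[f"{a}|{b}|{category}"] = {
                    "n_query": len(genes),
                    "n_terms_tested": len(df),
                    "min_benjamini": float(df["benjamini"].min()) if len(df) else None,
                }
        summary["stages"]["enrichment"] = enr_summaries
    else:
        summary["stages"]["enrichment"] = "skipped (no gene sets configured)"

    txio.write_tables(tables, out, summary=summary)
    return summary


def load_simulation_config(path) -> tuple[MultiDiseaseConfig, dict]:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "studies" not in raw:
        raise ConfigError(f"{path}: simulation config must be a mapping with 'studies'")
    seed = int(raw.get("seed", 0))
    studies = {
        str(lab): StudyConfig(seed=seed, **{k: v for k, v in entry.items()})
        for lab, entry in raw["studies"].items()
    }
    species = {str(k): str(v) for k, v in raw.get("species", {}).items()} or {
        lab: "9606" for lab in studies
    }
    pairwise = {}
    for key, count in (raw.get("pairwise_shared") or {}).items():
        a, b = [s.strip() for s in str(key).split(",")]
        pairwise[(a, b)] = int(count)
    concordance = raw.get("concordance_frac", 1.0)
    if isinstance(concordance, dict):
        concordance = {
            tuple(s.strip() for s in str(k).split(",")): float(v)
            for k, v in concordance.items()
        }
    cfg = MultiDiseaseConfig(
        studies=studies,
        species=species,
        pairwise_shared=pairwise,
        triple_shared=int(raw.get("triple_shared", 0)),
        concordance_frac=concordance,
        ortholog_fraction=float(raw.get("ortholog_fraction", 1.0)),
        seed=seed,
    )
    return cfg, raw


def simulate(config_path, out_dir) -> dict:
    """Generate a synthetic multi-disease study on disk, ready for ``run``.

    Writes per-study expression/design/annotation TSVs, the homolog table
    when two species are involved, truth tables, an optional GMT, a manifest
    and a ready-to-run pipeline config.
    """
    cfg, raw = load_simulation_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = simulate_multi_disease(cfg)

    dataset_entries = []
    for label, ds in result.datasets.items():
        txio.write_expression(ds.matrix, out / f"{label}_expression.tsv")
        txio.write_design(ds.design, out / f"{label}_design.tsv")
        txio.write_annotation(ds.annotation, out / f"{label}_annotation.tsv")
        entry = {
            "label": label,
            "expression": f"{label}_expression.tsv",
            "design": f"{label}_design.tsv",
            "annotation": f"{label}_annotation.tsv",
        }
        if isinstance(raw.get("selection"), dict):
            entry["selection"] = raw["selection"]
        dataset_entries.append(entry)
    if result.homologs is not None:
        txio.write_homologs(result.homologs, out / "homologs.tsv")

    truth_de = pd.DataFrame(
        [
            (gene, label, direction)
            for label, genes in result.truth.de_genes.items()
            for gene, direction in sorted(genes.items())
        ],
        columns=["gene", "dataset", "direction"],
    )
    truth_shared = pd.DataFrame(
        [
            ("|".join(pair), gene, int(conc))
            for pair, genes in result.truth.shared_pairs.items()
            for gene, conc in sorted(genes.items())
        ],
        columns=["pair", "gene", "concordant"],
    )
    tables = {"truth_de": truth_de, "truth_shared": truth_shared}

    gs_cfg = raw.get("gene_sets")
    gene_sets_path = None
    if gs_cfg:
        first = cfg.labels[0]
        universe = sorted(result.datasets[first].annotation.annotated_genes)
        planted_pair = gs_cfg.get("planted_pair")
        planted = (
            result.truth.concordant_shared(tuple(planted_pair)) if planted_pair else None
        )
        collection = simulate_gene_sets(
            universe,
            n_sets=int(gs_cfg.get("n_sets", 50)),
            size_range=tuple(gs_cfg.get("size_range", [10, 100])),
            planted_enriched_set=planted,
            seed=cfg.seed,
        )
        gene_sets_path = "gene_sets.gmt"
        txio.write_gmt(collection, out / gene_sets_path)

    species_set = sorted(set(cfg.species.values()))
    pipeline_cfg = {
        "seed": cfg.seed,
        "equalize": bool(raw.get("equalize", False)),
        "target_taxon": raw.get("target_taxon", species_set[0]),
        "datasets": dataset_entries,
    }
    if result.homologs is not None:
        pipeline_cfg["homologs"] = "homologs.tsv"
    if gene_sets_path:
        pipeline_cfg["gene_sets"] = gene_sets_path
    with open(out / "pipeline.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=False)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": raw,
        "counts": {
            "n_genes": cfg.studies[cfg.labels[0]].n_genes,
            "n_de": {lab: len(g) for lab, g in result.truth.de_genes.items()},
            "pairwise_shared": {
                "|".join(p): len(g) for p, g in result.truth.shared_pairs.items()
            },
            "triple_shared": cfg.triple_shared,
            "homolog_groups": len(result.homologs) if result.homologs else 0,
        },
    }
    txio.write_tables(tables, out, summary=manifest)
    return manifest
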