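"""Synthetic multi-dataset expression studies with planted, exactly-known truth.

The generator emulates the statistical structure of a multi-disease microarray
comparison: per-probe log2 intensities with independent Gaussian noise around
a per-gene baseline, planted differentially expressed genes whose case-group
mean is shifted by +-effect_size, planted pairwise/triple shared gene cores
with configurable direction concordance, and a two-species homolog table with
configurable ortholog coverage. All planted counts (DE, shared, concordant)
are exact by construction, so recovery tests can assert equality, not
tolerance. Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import (
    CASE,
    CONTROL,
    ConfigError,
    ExpressionMatrix,
    GeneSetCollection,
    HomologTable,
    ProbeAnnotation,
    SampleDesign,
)

_SPECIES_PREFIX = {"9606": "GENE", "10090": "MGENE"}


def gene_symbol(taxon: str, index: int) -> str:
    """Deterministic species-prefixed synthetic symbol for gene ``index``."""
    prefix = _SPECIES_PREFIX.get(taxon, f"T{taxon}G")
    return f"{prefix}{index:05d}"


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one simulated case/control expression study.

    Units are log2 intensity throughout. Defaults describe a typical
    well-behaved array study: baseline ~ N(7, 1.5) per gene, residual noise
    SD 0.4, planted shifts of 1.5 log2 units (2.8-fold), 70% of planted DE
    genes shifted up.
    """

    n_genes: int
    n_case: int
    n_control: int
    n_de: int = 300
    n_probes_per_gene: int = 1
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.4
    effect_size: float = 1.5
    frac_up: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ConfigError("n_case and n_control must be >= 2")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not (0 <= self.frac_up <= 1):
            raise ConfigError("frac_up must be in [0, 1]")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not (0 <= self.n_de <= self.n_genes):
            raise ConfigError("n_de must be in [0, n_genes]")
        if self.n_probes_per_gene < 1:
            raise ConfigError("n_probes_per_gene must be >= 1")
        if self.baseline_sd < 0:
            raise ConfigError("baseline_sd must be >= 0")


@dataclass
class SimulatedDataset:
    """One simulated study: matrix + design + annotation + planted truth."""

    label: str
    taxon: str
    matrix: ExpressionMatrix
    design: SampleDesign
    annotation: ProbeAnnotation
    de_directions: dict[str, int]  # planted truth: symbol -> +1/-1


def _build_dataset(
    config: StudyConfig,
    label: str,
    taxon: str,
    rng: np.random.Generator,
    baselines: np.ndarray,
    de_directions_idx: dict[int, int],
) -> SimulatedDataset:
    n_samples = config.n_case + config.n_control
    n_rows = config.n_genes * config.n_probes_per_gene
    gene_idx_per_row = np.repeat(np.arange(config.n_genes), config.n_probes_per_gene)

    shift = np.zeros(config.n_genes)
    for gi, d in de_directions_idx.items():
        shift[gi] = d * config.effect_size

    case_mask = np.zeros(n_samples)
    case_mask[: config.n_case] = 1.0
    values = (
        baselines[gene_idx_per_row][:, None]
        + shift[gene_idx_per_row][:, None] * case_mask[None, :]
        + rng.normal(0.0, config.noise_sd, size=(n_rows, n_samples))
    )

    symbols = [gene_symbol(taxon, i) for i in range(config.n_genes)]
    probe_ids = [
        f"{symbols[gi]}_P{p + 1}"
        for gi in range(config.n_genes)
        for p in range(config.n_probes_per_gene)
    ]
    sample_ids = [f"{label}_case_{i + 1}" for i in range(config.n_case)] + [
        f"{label}_ctrl_{i + 1}" for i in range(config.n_control)
    ]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))
    design = SampleDesign(
        pd.DataFrame(
            {
                "group": [CASE] * config.n_case + [CONTROL] * config.n_control,
                "dataset": label,
                "taxon": taxon,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    annotation = ProbeAnnotation(
        pd.Series([symbols[gi] for gi in gene_idx_per_row], index=probe_ids, dtype=object),
        taxon=taxon,
    )
    de_directions = {symbols[gi]: d for gi, d in sorted(de_directions_idx.items())}
    return SimulatedDataset(
        label=label,
        taxon=taxon,
        matrix=matrix,
        design=design,
        annotation=annotation,
        de_directions=de_directions,
    )


def simulate_dataset(
    config: StudyConfig, label: str = "study", taxon: str = "9606"
) -> SimulatedDataset:
    """Simulate one case/control study with ``n_de`` planted DE genes.

    Exactly round(frac_up * n_de) planted genes are shifted up, the rest
    down; all probes of a DE gene receive the same shift.
    """
    rng = np.random.default_rng(config.seed)
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
    n_up = round(config.frac_up * config.n_de)
    de_directions_idx = {int(gi): (1 if j < n_up else -1) for j, gi in enumerate(de_idx)}
    return _build_dataset(config, label, taxon, rng, baselines, de_directions_idx)


def simulate_homolog_table(
    universe_a: list[str],
    universe_b: list[str],
    ortholog_fraction: float,
    seed: int,
    taxon_a: str = "9606",
    taxon_b: str = "10090",
) -> HomologTable:
    """A two-species homolog table pairing the universes positionally.

    Exactly round(ortholog_fraction * min(len(a), len(b))) homolog groups are
    emitted, each with one gene per species; which positions are covered is
    drawn uniformly at random.
    """
    if not universe_a or not universe_b:
        raise ConfigError("homolog universes must be nonempty")
    if not (0 <= ortholog_fraction <= 1):
        raise ConfigError("ortholog_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pairs = min(len(universe_a), len(universe_b))
    n_map = round(ortholog_fraction * n_pairs)
    mapped = np.sort(rng.choice(n_pairs, size=n_map, replace=False))
    rows = []
    for i in mapped:
        group = f"HG{i:05d}"
        rows.append((group, taxon_a, universe_a[i].upper()))
        rows.append((group, taxon_b, universe_b[i].upper()))
    return HomologTable(pd.DataFrame(rows, columns=["group_id", "taxon_id", "symbol"]))


@dataclass
class MultiDiseaseConfig:
    """Three-study design with planted shared DE cores.

    ``pairwise_shared`` counts include the triple-shared genes (the triple
    core is a subset of every pairwise core). ``concordance_frac`` applies to
    the pair-exclusive planted genes; triple-core genes are concordant in all
    three studies. Up/down splits of shared genes use the ``frac_up`` of the
    pair's first label, so planted concordant-up / concordant-down counts are
    exact via rounding. ``ortholog_fraction`` controls homolog-table coverage
    when the studies span two species.
    """

    studies: dict[str, StudyConfig]
    species: dict[str, str]
    pairwise_shared: dict[tuple[str, str], int] = field(default_factory=dict)
    triple_shared: int = 0
    concordance_frac: dict[tuple[str, str], float] | float = 1.0
    ortholog_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = list(self.studies)
        if len(labels) != 3:
            raise ConfigError(f"need exactly 3 studies, got {len(labels)}")
        if set(self.species) != set(labels):
            raise ConfigError("species must be given for exactly the study labels")
        n_genes = {c.n_genes for c in self.studies.values()}
        if len(n_genes) != 1:
            raise ConfigError("all studies must share n_genes (positional gene universe)")
        # canonicalize pair keys to the label order of `studies`
        order = {lab: i for i, lab in enumerate(labels)}
        canon: dict[tuple[str, str], int] = {}
        for pair, count in self.pairwise_shared.items():
            a, b = pair
            if a not in order or b not in order or a == b:
                raise ConfigError(f"bad pair {pair!r}")
            key = (a, b) if order[a] < order[b] else (b, a)
            canon[key] = count
        for pair in combinations(labels, 2):
            canon.setdefault(pair, 0)
        self.pairwise_shared = canon
        if not isinstance(self.concordance_frac, dict):
            self.concordance_frac = {p: float(self.concordance_frac) for p in canon}
        else:
            cf = {}
            for pair, f in self.concordance_frac.items():
                a, b = pair
                key = (a, b) if order[a] < order[b] else (b, a)
                cf[key] = float(f)
            for pair in canon:
                cf.setdefault(pair, 1.0)
            self.concordance_frac = cf
        for pair, f in self.concordance_frac.items():
            if not (0 <= f <= 1):
                raise ConfigError(f"concordance_frac for {pair} must be in [0, 1]")
        if self.triple_shared < 0:
            raise ConfigError("triple_shared must be >= 0")
        for pair, count in self.pairwise_shared.items():
            if count < self.triple_shared:
                raise ConfigError(
                    f"pairwise_shared{pair}={count} is below triple_shared={self.triple_shared}"
                )
        if not (0 <= self.ortholog_fraction <= 1):
            raise ConfigError("ortholog_fraction must be in [0, 1]")

    @property
    def labels(self) -> list[str]:
        return list(self.studies)


@dataclass
class SyntheticTruth:
    """Planted structure of a multi-disease simulation, exact by construction.

    ``shared_pairs`` is keyed by canonical pair; each value maps a shared
    gene (spelled in the pair's *first* label's species) to its concordance
    flag. ``triple_genes`` gives the triple core spelled per label.
    """

    de_genes: dict[str, dict[str, int]]
    shared_pairs: dict[tuple[str, str], dict[str, bool]]
    triple_genes: dict[str, frozenset[str]]
    homolog_pairs: tuple[tuple[str, str], ...]

    def pair_key(self, pair) -> tuple[str, str]:
        """Canonical key for a label pair, accepting either orientation."""
        pair = tuple(pair)
        if pair in self.shared_pairs:
            return pair
        rev = (pair[1], pair[0])
        if rev in self.shared_pairs:
            return rev
        raise KeyError(pair)

    def concordant_shared(self, pair: tuple[str, str]) -> frozenset[str]:
        genes = self.shared_pairs[self.pair_key(pair)]
        return frozenset(g for g, c in genes.items() if c)


@dataclass
class MultiDiseaseResult:
    datasets: dict[str, SimulatedDataset]
    homologs: HomologTable | None
    truth: SyntheticTruth


def simulate_multi_disease(config: MultiDiseaseConfig) -> MultiDiseaseResult:
    """Simulate three studies with planted shared DE cores and a homolog table.

    Gene index i denotes the same biological gene in every study; its symbol
    is species-specific. Planted DE sets are disjoint across studies except
    for the configured shared structure, so recovered overlaps at high effect
    size equal the planted counts exactly. Per-gene baselines are drawn once
    per species and shared across that species' studies. All randomness flows
    from ``config.seed``.
    """
    labels = config.labels
    n_genes = config.studies[labels[0]].n_genes
    rng = np.random.default_rng(config.seed)
    t = config.triple_shared

    pairs = list(combinations(labels, 2))
    exclusive = {p: config.pairwise_shared[p] - t for p in pairs}

    # budget checks before any allocation
    need_total = t + sum(exclusive.values())
    for lab in labels:
        shared_lab = t + sum(e for p, e in exclusive.items() if lab in p)
        if config.studies[lab].n_de < shared_lab:
            raise ConfigError(
                f"study {lab!r}: n_de={config.studies[lab].n_de} cannot hold "
                f"{shared_lab} planted shared genes"
            )
        need_total += config.studies[lab].n_de - shared_lab
    if need_total > n_genes:
        raise ConfigError(
            f"planted structure needs {need_total} genes but universe has {n_genes}"
        )

    perm = list(rng.permutation(n_genes))
    pos = 0

    def take(k: int) -> list[int]:
        nonlocal pos
        out = perm[pos : pos + k]
        pos += k
        return [int(i) for i in out]

    triple_idx = take(t)
    exclusive_idx = {p: take(e) for p, e in exclusive.items()}
    private_idx = {}
    for lab in labels:
        shared_lab = t + sum(e for p, e in exclusive.items() if lab in p)
        private_idx[lab] = take(config.studies[lab].n_de - shared_lab)

    frac_up = {lab: config.studies[lab].frac_up for lab in labels}
    directions: dict[str, dict[int, int]] = {lab: {} for lab in labels}
    concordance: dict[tuple[str, str], dict[int, bool]] = {p: {} for p in pairs}

    # triple core: concordant across all three
    n_up = round(frac_up[labels[0]] * t)
    for j, gi in enumerate(triple_idx):
        d = 1 if j < n_up else -1
        for lab in labels:
            directions[lab][gi] = d
        for p in pairs:
            concordance[p][gi] = True

    # pair-exclusive cores: concordant fraction exact by rounding
    for p in pairs:
        a, b = p
        idx = exclusive_idx[p]
        n_conc = round(config.concordance_frac[p] * len(idx))
        conc, disc = idx[:n_conc], idx[n_conc:]
        n_conc_up = round(frac_up[a] * n_conc)
        for j, gi in enumerate(conc):
            d = 1 if j < n_conc_up else -1
            directions[a][gi] = d
            directions[b][gi] = d
            concordance[p][gi] = True
        n_disc_up = round(frac_up[a] * len(disc))
        for j, gi in enumerate(disc):
            d = 1 if j < n_disc_up else -1
            directions[a][gi] = d
            directions[b][gi] = -d
            concordance[p][gi] = False

    # private DE genes per study
    for lab in labels:
        idx = private_idx[lab]
        n_priv_up = round(frac_up[lab] * len(idx))
        for j, gi in enumerate(idx):
            directions[lab][gi] = 1 if j < n_priv_up else -1

    # per-species baselines shared across that species' studies
    species_set = sorted(set(config.species.values()))
    baselines: dict[str, np.ndarray] = {}
    for sp in species_set:
        lab0 = next(lab for lab in labels if config.species[lab] == sp)
        cfg0 = config.studies[lab0]
        baselines[sp] = rng.normal(cfg0.baseline_mean, cfg0.baseline_sd, size=n_genes)

    datasets = {
        lab: _build_dataset(
            config.studies[lab],
            lab,
            config.species[lab],
            rng,
            baselines[config.species[lab]],
            directions[lab],
        )
        for lab in labels
    }

    homologs = None
    homolog_pairs: tuple[tuple[str, str], ...] = ()
    if len(species_set) == 2:
        sp_a, sp_b = species_set
        universe_a = [gene_symbol(sp_a, i) for i in range(n_genes)]
        universe_b = [gene_symbol(sp_b, i) for i in range(n_genes)]
        homologs = simulate_homolog_table(
            universe_a,
            universe_b,
            config.ortholog_fraction,
            seed=int(rng.integers(2**31)),
            taxon_a=sp_a,
            taxon_b=sp_b,
        )
        ht = homologs.table
        by_group: dict[str, dict[str, str]] = {}
        for grp, tax, sym in zip(ht["group_id"], ht["taxon_id"], ht["symbol"]):
            by_group.setdefault(grp, {})[tax] = sym
        homolog_pairs = tuple(
            (g[sp_a], g[sp_b]) for g in by_group.values() if sp_a in g and sp_b in g
        )
    elif len(species_set) > 2:
        raise ConfigError("at most two species are supported")

    truth = SyntheticTruth(
        de_genes={lab: ds.de_directions for lab, ds in datasets.items()},
        shared_pairs={
            p: {
                gene_symbol(config.species[p[0]], gi): c
                for gi, c in sorted(concordance[p].items())
            }
            for p in pairs
        },
        triple_genes={
            lab: frozenset(gene_symbol(config.species[lab], gi) for gi in triple_idx)
            for lab in labels
        },
        homolog_pairs=homolog_pairs,
    )
    return MultiDiseaseResult(datasets=datasets, homologs=homologs, truth=truth)


def simulate_gene_sets(
    universe: list[str],
    n_sets: int,
    size_range: tuple[int, int],
    planted_enriched_set: set[str] | None = None,
    seed: int = 0,
    planted_fraction: float = 0.8,
) -> GeneSetCollection:
    """Random gene sets, optionally with one set over-representing a signature.

    Background sets are drawn uniformly without replacement from the
    universe. When ``planted_enriched_set`` is given, a set named
    ``PLANTED_SET`` takes ``planted_fraction`` of its members from it.
    """
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ConfigError(f"size_range {size_range} exceeds universe of {len(universe)}")
    rng = np.random.default_rng(seed)
    universe = [g.upper() for g in universe]
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        name = f"SET{i + 1:04d}"
        sets[name] = frozenset(universe[j] for j in members)
        descriptions[name] = "random background set"
    if planted_enriched_set is not None:
        planted = sorted(g.upper() for g in planted_enriched_set)
        size = hi
        n_from = min(round(planted_fraction * size), len(planted))
        chosen = [planted[j] for j in rng.choice(len(planted), size=n_from, replace=False)]
        rest_pool = sorted(set(universe) - set(chosen))
        n_fill = size - len(chosen)
        fill = [rest_pool[j] for j in rng.choice(len(rest_pool), size=n_fill, replace=False)]
        sets["PLANTED_SET"] = frozenset(chosen + fill)
        descriptions["PLANTED_SET"] = "set constructed to over-represent the planted signature"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
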