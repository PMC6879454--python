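"""Core data containers shared across the pipeline.

Every statistical stage consumes or produces one of these. Expression values
are log2-scale normalized intensities (post-RMA style); gene symbols are
stored upper-cased so that human (upper-case convention) and mouse
(title-case convention) annotations meet on equal footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"


class FormatError(ValueError):
    """Malformed input file or table; message carries file and line where known."""


class ConfigError(ValueError):
    """Invalid configuration; message names the offending field."""


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 intensities, probes x samples.

    ``values`` is a float DataFrame indexed by probe id with sample ids as
    columns. Validation rejects duplicates, non-finite cells and degenerate
    shapes rather than coercing.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if v.shape[0] < 1:
            raise FormatError("expression matrix needs at least 1 probe")
        if v.shape[1] < 3:
            raise FormatError("expression matrix needs at least 3 samples")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.floating):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"non-finite expression value at probe {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SampleDesign:
    """Case/control assignment with dataset label and species taxon per sample.

    ``table`` is indexed by sample id with columns ``group`` (case/control),
    ``dataset`` and ``taxon``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"group", "dataset", "taxon"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate sample id in design: {dup!r}")
        bad = set(t["group"]) - {CASE, CONTROL}
        if bad:
            raise FormatError(f"unknown group value(s): {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    @property
    def case_samples(self) -> list[str]:
        return self.samples_in(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_in(CONTROL)

    def check_against(self, matrix: ExpressionMatrix) -> None:
        """Cross-validation done at pipeline assembly, not at read time."""
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise FormatError(
                f"design samples absent from expression matrix: {sorted(missing)}"
            )
        if len(self.case_samples) < 2 or len(self.control_samples) < 2:
            raise FormatError("each dataset needs >=2 case and >=2 control samples")


@dataclass(frozen=True)
class ProbeAnnotation:
    """probe id -> gene symbol mapping for one platform; symbols upper-cased.

    Probes with no symbol (empty string) are retained and count as
    unannotated downstream.
    """

    mapping: pd.Series  # index probe_id, values gene symbol or ""
    taxon: str

    def __post_init__(self) -> None:
        if self.mapping.index.has_duplicates:
            dup = self.mapping.index[self.mapping.index.duplicated()][0]
            raise FormatError(f"duplicate probe id in annotation: {dup!r}")

    def gene_of(self, probe_id: str) -> str:
        return self.mapping.get(probe_id, "")

    @property
    def annotated_genes(self) -> set[str]:
        return {g for g in self.mapping.values if g}


@dataclass(frozen=True)
class HomologTable:
    """Rows of (group_id, taxon_id, symbol); one HomoloGene-style group per row set.

    Invariant: a (taxon, symbol) pair belongs to at most one group.
    """

    table: pd.DataFrame  # columns: group_id, taxon_id, symbol

    def __post_init__(self) -> None:
        t = self.table
        required = {"group_id", "taxon_id", "symbol"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"homolog table missing columns: {sorted(missing)}")
        key = t[["taxon_id", "symbol"]].apply(tuple, axis=1) if len(t) else pd.Series(dtype=object)
        if len(t):
            grp_per_key = t.groupby([t["taxon_id"], t["symbol"]])["group_id"].nunique()
            conflicts = grp_per_key[grp_per_key > 1]
            if len(conflicts):
                taxon, sym = conflicts.index[0]
                raise FormatError(
                    f"symbol {sym!r} (taxon {taxon}) appears in multiple homolog groups"
                )
        del key

    def __len__(self) -> int:
        return int(self.table["group_id"].nunique())

    def group_of(self, taxon: str, symbol: str):
        t = self.table
        hit = t[(t["taxon_id"] == taxon) & (t["symbol"] == symbol)]
        return None if hit.empty else hit["group_id"].iloc[0]


@dataclass
class DiseaseSignature:
    """A named, species-tagged gene -> direction map; the currency of comparisons.

    ``directions`` maps upper-cased gene symbol to +1 (up) or -1 (down);
    ``pvalues`` carries the best per-gene p-value used for ranking when
    signatures are truncated to equal sizes.
    """

    label: str
    taxon: str
    directions: dict[str, int] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.directions.items() if d not in (1, -1)}
        if bad:
            raise ConfigError(f"directions must be +1/-1, got {bad}")

    def __len__(self) -> int:
        return len(self.directions)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.directions)

    @property
    def up_genes(self) -> frozenset[str]:
        return frozenset(g for g, d in self.directions.items() if d == 1)

    @property
    def down_genes(self) -> frozenset[str]:
        return frozenset(g for g, d in self.directions.items() if d == -1)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> (description, members)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())
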