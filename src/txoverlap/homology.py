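"""Cross-species signature translation through homolog groups.

A signature called in one species is mapped into another by joining each gene
to its homolog group and replacing it with every target-taxon symbol in that
group. Genes with no group, or whose group has no target-species member, are
dropped and counted. Keeping all target symbols of a many-to-many group is
deliberate: it is conservative for overlap detection, and the report makes
the multiplicity auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import DiseaseSignature, HomologTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranslationReport:
    """Bookkeeping for one signature translation; n_mapped + n_unmapped = n_input."""

    n_input: int
    n_mapped: int
    n_unmapped: int
    n_multi: int  # source genes expanding to >1 target symbol
    n_direction_conflicts: int  # target symbols fed by sources of opposite sign
    pairs: tuple[tuple[str, str], ...]  # (source gene, target gene) emitted

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_mapped": self.n_mapped,
            "n_unmapped": self.n_unmapped,
            "n_multi": self.n_multi,
            "n_direction_conflicts": self.n_direction_conflicts,
        }


def translate_signature(
    signature: DiseaseSignature, homologs: HomologTable, target_taxon: str
) -> tuple[DiseaseSignature, TranslationReport]:
    """Map a signature into ``target_taxon`` symbol space via homolog groups.

    Direction is inherited from the source gene. When two source genes of
    opposite direction map onto one target symbol, the smaller source p-value
    wins (mirroring the probe-collapse policy) and the conflict is counted.
    Translating into the signature's own taxon is an identity with a warning.
    """
    if signature.taxon == target_taxon:
        logger.warning(
            "%s: translation target equals signature taxon (%s); identity",
            signature.label,
            target_taxon,
        )
        report = TranslationReport(
            n_input=len(signature),
            n_mapped=len(signature),
            n_unmapped=0,
            n_multi=0,
            n_direction_conflicts=0,
            pairs=tuple((g, g) for g in sorted(signature.directions)),
        )
        return (
            DiseaseSignature(
                label=signature.label,
                taxon=target_taxon,
                directions=dict(signature.directions),
                pvalues=dict(signature.pvalues),
            ),
            report,
        )

    t = homologs.table
    src = t[t["taxon_id"] == signature.taxon]
    tgt = t[t["taxon_id"] == target_taxon]
    src_groups = dict(zip(src["symbol"], src["group_id"]))
    tgt_by_group: dict[str, list[str]] = {}
    for grp, sym in zip(tgt["group_id"], tgt["symbol"]):
        tgt_by_group.setdefault(grp, []).append(sym)

    pairs: list[tuple[str, str]] = []
    n_mapped = n_multi = 0
    # best (p, direction) per target symbol; smaller p wins on conflict
    best: dict[str, tuple[float, int]] = {}
    conflicted: set[str] = set()
    for gene in sorted(signature.directions):
        grp = src_groups.get(gene)
        targets = sorted(tgt_by_group.get(grp, ())) if grp is not None else []
        if not targets:
            continue
        n_mapped += 1
        if len(targets) > 1:
            n_multi += 1
        p = signature.pvalues.get(gene, np.inf)
        d = signature.directions[gene]
        for tsym in targets:
            pairs.append((gene, tsym))
            if tsym in best:
                if best[tsym][1] != d:
                    conflicted.add(tsym)
                if p < best[tsym][0]:
                    best[tsym] = (p, d)
            else:
                best[tsym] = (p, d)

    directions = {sym: d for sym, (_, d) in best.items()}
    pvalues = {sym: p for sym, (p, _) in best.items() if np.isfinite(p)}
    report = TranslationReport(
        n_input=len(signature),
        n_mapped=n_mapped,
        n_unmapped=len(signature) - n_mapped,
        n_multi=n_multi,
        n_direction_conflicts=len(conflicted),
        pairs=tuple(pairs),
    )
    translated = DiseaseSignature(
        label=signature.label, taxon=target_taxon, directions=directions, pvalues=pvalues
    )
    return translated, report
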