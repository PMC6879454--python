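"""Direction-decomposed signature overlaps and overlap-enrichment testing.

Overlap membership ignores direction — a gene is shared when it is
dysregulated in both lists, regardless of sign; direction enters only the
concordant-up / concordant-down / discordant decomposition. Whether two
overlaps differ is tested on a 2x2 contingency table with Pearson's
chi-square (no continuity correction), falling back to the two-sided Fisher
exact test when any observed cell is below a small-sample threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from scipy import stats

from .datatypes import ConfigError, DiseaseSignature

logger = logging.getLogger(__name__)

#: observed-cell count below which the Fisher exact test replaces chi-square
SMALL_CELL_THRESHOLD = 10


@dataclass(frozen=True)
class OverlapResult:
    """Pairwise overlap of two signatures with direction decomposition."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_overlap: int
    n_concordant_up: int
    n_concordant_down: int
    n_discordant: int
    concordant_up: frozenset[str]
    concordant_down: frozenset[str]
    discordant: frozenset[str]

    @property
    def pct_wrt_a(self) -> float:
        return 100.0 * self.n_overlap / self.n_a if self.n_a else 0.0

    @property
    def pct_wrt_b(self) -> float:
        return 100.0 * self.n_overlap / self.n_b if self.n_b else 0.0

    @property
    def n_concordant(self) -> int:
        return self.n_concordant_up + self.n_concordant_down

    @property
    def members(self) -> frozenset[str]:
        return self.concordant_up | self.concordant_down | self.discordant


@dataclass(frozen=True)
class TripleOverlapResult:
    """The seven Venn regions of three signatures; 'center' = shared by all."""

    labels: tuple[str, str, str]
    region_counts: dict  # keys like 'a_only', 'ab_only', ..., 'center'
    center_genes: frozenset[str]
    center_directions: dict  # gene -> (dir in A, dir in B, dir in C)

    @property
    def n_center(self) -> int:
        return len(self.center_genes)


@dataclass(frozen=True)
class OverlapComparison:
    """2x2 test of whether overlap k_a/n_a differs from overlap k_b/n_b."""

    k_a: int
    n_a: int
    k_b: int
    n_b: int
    test_used: str  # 'chi_square' or 'fisher'
    statistic: float | None
    p_two_sided: float
    label: str = ""

    @property
    def table(self) -> list[list[int]]:
        return [[self.k_a, self.n_a - self.k_a], [self.k_b, self.n_b - self.k_b]]


def _check_common_space(sig_a: DiseaseSignature, sig_b: DiseaseSignature) -> None:
    if sig_a.taxon != sig_b.taxon:
        raise ConfigError(
            f"signatures {sig_a.label!r} (taxon {sig_a.taxon}) and {sig_b.label!r} "
            f"(taxon {sig_b.taxon}) are in different species; translate first"
        )


def pairwise_overlap(sig_a: DiseaseSignature, sig_b: DiseaseSignature) -> OverlapResult:
    """Exact set intersection of two signatures with concordance decomposition."""
    _check_common_space(sig_a, sig_b)
    shared = sig_a.genes & sig_b.genes
    up = frozenset(g for g in shared if sig_a.directions[g] == 1 and sig_b.directions[g] == 1)
    down = frozenset(g for g in shared if sig_a.directions[g] == -1 and sig_b.directions[g] == -1)
    disc = frozenset(shared - up - down)
    return OverlapResult(
        label_a=sig_a.label,
        label_b=sig_b.label,
        n_a=len(sig_a),
        n_b=len(sig_b),
        n_overlap=len(shared),
        n_concordant_up=len(up),
        n_concordant_down=len(down),
        n_discordant=len(disc),
        concordant_up=up,
        concordant_down=down,
        discordant=disc,
    )


def triple_overlap(
    sig_a: DiseaseSignature, sig_b: DiseaseSignature, sig_c: DiseaseSignature
) -> TripleOverlapResult:
    """All seven Venn regions of three signatures, center with direction triples."""
    _check_common_space(sig_a, sig_b)
    _check_common_space(sig_a, sig_c)
    A, B, C = sig_a.genes, sig_b.genes, sig_c.genes
    center = A & B & C
    regions = {
        "a_only": len(A - B - C),
        "b_only": len(B - A - C),
        "c_only": len(C - A - B),
        "ab_only": len((A & B) - C),
        "ac_only": len((A & C) - B),
        "bc_only": len((B & C) - A),
        "center": len(center),
    }
    center_dirs = {
        g: (sig_a.directions[g], sig_b.directions[g], sig_c.directions[g]) for g in center
    }
    return TripleOverlapResult(
        labels=(sig_a.label, sig_b.label, sig_c.label),
        region_counts=regions,
        center_genes=frozenset(center),
        center_directions=center_dirs,
    )


def compare_overlap_proportions(
    k_a: int,
    n_a: int,
    k_b: int,
    n_b: int,
    small_cell_threshold: int = SMALL_CELL_THRESHOLD,
    label: str = "",
) -> OverlapComparison:
    """Test whether two overlap proportions differ on the 2x2 table
    [[k_a, n_a-k_a], [k_b, n_b-k_b]].

    Pearson chi-square without continuity correction; when any observed cell
    is below ``small_cell_threshold`` the two-sided Fisher exact test is used
    instead and recorded. A degenerate table (zero margin) yields p = 1 with
    a warning.
    """
    if not (0 <= k_a <= n_a and 0 <= k_b <= n_b):
        raise ConfigError("need 0 <= k <= n for both overlaps")
    if n_a <= 0 or n_b <= 0:
        raise ConfigError("signature sizes must be positive")
    cells = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
    col_sums = (k_a + k_b, (n_a - k_a) + (n_b - k_b))
    if 0 in col_sums:
        logger.warning("degenerate 2x2 table (zero margin): %s; p = 1", cells)
        return OverlapComparison(k_a, n_a, k_b, n_b, "chi_square", 0.0, 1.0, label=label)
    if min(min(row) for row in cells) < small_cell_threshold:
        _, p = stats.fisher_exact(cells, alternative="two-sided")
        return OverlapComparison(k_a, n_a, k_b, n_b, "fisher", None, float(p), label=label)
    chi2, p, _, _ = stats.chi2_contingency(cells, correction=False)
    return OverlapComparison(k_a, n_a, k_b, n_b, "chi_square", float(chi2), float(p), label=label)


def overlap_matrix(
    signatures: list[DiseaseSignature],
) -> tuple[list[OverlapResult], list[OverlapComparison]]:
    """All pairwise overlaps, plus overlap-proportion tests for every
    pair-of-pairs sharing a reference signature.

    For reference R and two others X, Y the comparison asks whether R's
    overlap out of X's list differs from R's overlap out of Y's list (the
    '148 of the initial 1,731' construction). Ordering is deterministic in
    the input order of signatures.
    """
    if len(signatures) < 2:
        raise ConfigError("overlap_matrix needs >= 2 signatures")
    overlaps: dict[frozenset, OverlapResult] = {}
    results = []
    for sig_a, sig_b in combinations(signatures, 2):
        ov = pairwise_overlap(sig_a, sig_b)
        overlaps[frozenset((sig_a.label, sig_b.label))] = ov
        results.append(ov)
    comparisons = []
    for ref in signatures:
        others = [s for s in signatures if s.label != ref.label]
        for x, y in combinations(others, 2):
            ov_x = overlaps[frozenset((ref.label, x.label))]
            ov_y = overlaps[frozenset((ref.label, y.label))]
            comparisons.append(
                compare_overlap_proportions(
                    ov_x.n_overlap,
                    len(x),
                    ov_y.n_overlap,
                    len(y),
                    label=f"{ref.label}: {x.label} vs {y.label}",
                )
            )
    return results, comparisons


def overlaps_to_frame(results: list[OverlapResult]) -> pd.DataFrame:
    rows = [
        {
            "label_a": r.label_a,
            "label_b": r.label_b,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "n_overlap": r.n_overlap,
            "pct_wrt_a": round(r.pct_wrt_a, 1),
            "pct_wrt_b": round(r.pct_wrt_b, 1),
            "n_concordant_up": r.n_concordant_up,
            "n_concordant_down": r.n_concordant_down,
            "n_discordant": r.n_discordant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def comparisons_to_frame(comparisons: list[OverlapComparison]) -> pd.DataFrame:
    rows = [
        {
            "label": c.label,
            "k_a": c.k_a,
            "n_a": c.n_a,
            "k_b": c.k_b,
            "n_b": c.n_b,
            "test_used": c.test_used,
            "statistic": c.statistic,
            "p_two_sided": c.p_two_sided,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)
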