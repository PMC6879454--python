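"""Direction-decomposed overlaps of three disease signatures, and a test of
whether one disease shares more of its transcriptome with a second than with
a third.

Simulates three same-species studies with planted shared cores (40, 25 and
12 genes pairwise, 7 genes shared by all three), recovers the signatures and
quantifies every overlap.
"""

import txoverlap as tx

study = dict(n_genes=800, n_case=8, n_control=8, n_de=120,
             effect_size=4.0, noise_sd=0.1, seed=0)
config = tx.MultiDiseaseConfig(
    studies={lab: tx.StudyConfig(**study) for lab in ("eoe", "ad", "aa")},
    species={lab: "9606" for lab in ("eoe", "ad", "aa")},
    pairwise_shared={("eoe", "ad"): 40, ("eoe", "aa"): 25, ("ad", "aa"): 12},
    triple_shared=7,
    concordance_frac=0.8,
    seed=3,
)
result = tx.simulate_multi_disease(config)

signatures = []
for label, ds in result.datasets.items():
    records = tx.differential_expression(ds.matrix, ds.design, ds.annotation)
    signatures.append(tx.select_signature(records, ds.annotation, tx.SelectionConfig(), label))

overlaps, comparisons = tx.overlap_matrix(signatures)
for ov in overlaps:
    print(
        f"{ov.label_a}-{ov.label_b}: {ov.n_overlap} shared "
        f"({ov.pct_wrt_a:.0f}% of {ov.label_a}); "
        f"{ov.n_concordant_up} up-up, {ov.n_concordant_down} down-down, "
        f"{ov.n_discordant} discordant"
    )

triple = tx.triple_overlap(*signatures)
print(f"\nshared by all three: {triple.n_center} genes")

print("\noverlap-difference tests (2x2 chi-square / Fisher):")
for c in comparisons:
    print(f"  {c.label}: p = {c.p_two_sided:.4g} ({c.test_used})")
# The recovered overlap counts equal the planted ones at this effect size;
# the tests flag pairs whose overlap proportions genuinely differ.
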