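"""Trinucleotide mutational signatures with strand and replication-arc structure.

Heteroplasmies are collapsed to the six pyrimidine substitutions per strand
(96 contexts each) and stratified by the minor arc [m.191, m.5799) vs the
major arc; a one-tailed two-proportions Z test asks whether the favored
transitions are enriched in the major arc, as the strand-asymmetric
replication model predicts.
"""

from mthet import SimulationConfig, generate_cohort, load_annotation
from mthet.signatures import all_asymmetry_tests, build_signature_matrix

ann = load_annotation()
cohort = generate_cohort(SimulationConfig(n_cases=700, n_controls=360, seed=5))
het = cohort.calls[(cohort.calls["hf"] >= 0.05) & (cohort.calls["hf"] <= 0.95)]

mat = build_signature_matrix(het, ann.genome, ann.arcs, hf_range=(0.05, 0.95))
print(f"heteroplasmic calls counted: {mat.total()}")

agg = mat.aggregate(by=("substitution",)).set_index("substitution")["count"]
share = (agg.get("C>T", 0) + agg.get("T>C", 0)) / agg.sum()
print(f"transition share (C>T + T>C): {100 * share:.1f}% "
      "(mtDNA mutagenesis is overwhelmingly transitions)")

print("\ncounts by substitution, strand and arc:")
print(mat.aggregate().pivot_table(index="substitution",
                                  columns=["strand", "arc"], values="count",
                                  fill_value=0).to_string())

tests = all_asymmetry_tests(mat)
print("\none-tailed two-proportions Z tests (major arc > minor arc):")
cols = ["substitution", "strand", "x_major", "n_major", "x_minor", "n_minor",
        "z", "p"]
print(tests[cols].to_string(index=False,
                            float_format=lambda x: f"{x:.3g}"))
print(f"\nfamily threshold: {tests['threshold'].iloc[0]:.3g}")
print("\nInterpretation: significant C>T-on-H and T>C-on-L rows reproduce the "
      "replication-linked strand asymmetry - the major arc spends more time "
      "single-stranded during replication and accumulates more of these "
      "changes.")
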