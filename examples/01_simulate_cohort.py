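"""Generate a synthetic case-control cohort and look at its structure.

The generator emulates a deep mtDNA sequencing study at the variant-call
level: inherited homoplasmies on haplogroup-like backbones, age-dependent
somatic heteroplasmies with a replication-strand signature, NUMT
pseudo-heteroplasmies, and sequencing artifacts — each call truth-labelled.
"""

from mthet import SimulationConfig, generate_cohort

cohort = generate_cohort(SimulationConfig(n_cases=300, n_controls=150, seed=1))

n = len(cohort.samples)
print(f"samples: {n}  calls: {len(cohort.calls)}")
print("\ncalls per truth label (what each call really is):")
print(cohort.truth["label"].value_counts().to_string())

per_class = cohort.calls["hf"].map(
    lambda h: "low" if h < 0.10 else ("intermediate" if h < 0.95 else "homoplasmy"))
print("\nmean calls per individual by HF class (raw, before QC):")
print((per_class.value_counts() / n).round(2).to_string())

print("\nFirst rows of the call table (sample, position, alleles, HF, reads):")
print(cohort.calls.head(5).to_string(index=False))
print("\nInterpretation: each individual carries ~9 homoplasmies (inherited "
      "haplotype) plus a small, age- and disease-dependent number of "
      "heteroplasmies; artifact and NUMT calls are present on purpose so the "
      "QC cascade has something to remove.")
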