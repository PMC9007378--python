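"""Per-individual heteroplasmy burden and its disease association.

Counts variants per individual in each HF class (low 5-10%, intermediate
10-95%, homoplasmy >= 95%), then fits negative-binomial regressions of the
burden on case status with age, sex, mean depth and ancestry as covariates.
"""

from mthet import (SimulationConfig, build_design, fit_nb_glm,
                   generate_cohort, individual_burden, load_annotation,
                   sharing_spectrum)
from mthet.association import bonferroni_threshold, echo_threshold
from mthet.qc import QCConfig, apply_qc_cascade

ann = load_annotation()
cohort = generate_cohort(SimulationConfig(seed=3))  # 700 cases / 360 controls
report = apply_qc_cascade(cohort.calls, cohort.samples, ann.mask,
                          [cohort.panel_genbank, cohort.panel_kg],
                          QCConfig(enable_cv_filter=True))
burden = individual_burden(report.calls, report.samples, ann)

print("mean burden per individual:")
for cls in ("homoplasmy", "intermediate", "low"):
    print(f"  {cls:13s} {burden[(cls, 'total')].mean():.2f}")

for cls in ("intermediate", "low"):
    fit = fit_nb_glm(build_design(burden, report.samples, cls,
                                  case_group="HTN"))
    row = fit.params.loc["case"]
    print(f"\n{cls} burden ~ case + age + sex + depth + ancestry "
          f"({fit.model}, alpha={fit.alpha:.2f}):")
    print(f"  case-control beta = {row['beta']:.3f} (se {row['se']:.3f}, "
          f"p {row['p']:.2g})")
    age = fit.params.loc["age"]
    print(f"  age slope         = {age['beta']:.4f} (se {age['se']:.4f}, "
          f"p {age['p']:.2g})")

thr = bonferroni_threshold(0.05, 2)
print(f"\nfamily threshold for the 2 tests above: {thr:.4g} "
      f"(reported as {echo_threshold(thr)})")

sharing = sharing_spectrum(report.calls)
print("\nvariant sharing spectrum (homoplasmies dominate the shared tail):")
print(sharing.groupby("sharing_class")["mean_hf"]
      .agg(["size", "mean"]).round(2).to_string())
print("\nInterpretation: a positive case-control beta on intermediate burden "
      "means cases carry more 10-95% heteroplasmies than controls after "
      "covariate adjustment; the age slope on low-level burden reflects "
      "somatic accumulation during life.")
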