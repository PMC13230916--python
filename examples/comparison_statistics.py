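"""Nonparametric comparison statistics on the bundled reference table.

Loads the published 16-method x 12-dataset mean-accuracy comparison table
shipped with the package, runs Wilcoxon signed-rank tests (zero-splitting,
Holm-corrected) of every method against the reference method, and prints
the Friedman mean ranks.
"""

from coopfs import compare_to_reference, friedman_ranks
from coopfs.datasets import reference_accuracy_table, reference_classifier_table

table = reference_accuracy_table()
pairwise = compare_to_reference(table, "TMPA-HC")
print("Wilcoxon signed-rank vs reference (R+, R-, statistic, Holm p):")
print(pairwise[["r_plus", "r_minus", "statistic", "holm_p", "decision"]]
      .to_string(float_format=lambda v: f"{v:.4f}"))

summary, chi2, p = friedman_ranks(table)
print(f"\nFriedman chi-square {chi2:.2f} (p = {p:.2e}); top of the ranking:")
print(summary.head(4).to_string(float_format=lambda v: f"{v:.3f}"))

clf = reference_classifier_table()
print(f"\nclassifier comparison: SVM mean {clf['SVM'].mean():.2f}%, "
      f"XGBoost mean {clf['XGBoost'].mean():.2f}%")

# R+ is the rank mass where the reference beats the competitor; a rejected
# decision means the Holm-adjusted p-value is below 0.05.
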