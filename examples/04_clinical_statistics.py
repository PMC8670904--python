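"""Group-comparison statistics used for the clinical follow-up tables.

The readmission table compares two groups of 60 patients: 8 readmissions
under model-guided treatment timing versus 17 under a fixed daily scheme.
"""

from pulsebp import pearson_chi_square, two_sample_t_test

stat, df, p = pearson_chi_square([[8, 52], [17, 43]])
print("readmission 2x2 table [[8, 52], [17, 43]]:")
print(f"  chi2 = {stat:.3f}, df = {df}, p = {p:.3f}  "
      "(uncorrected Pearson statistic)")

stat_c, _, p_c = pearson_chi_square([[8, 52], [17, 43]], correction=True)
print(f"  with Yates continuity correction: chi2 = {stat_c:.3f}, p = {p_c:.3f}")

t, df, p = two_sample_t_test([62, 58, 71, 66, 60], [55, 52, 61, 57, 50])
print("\npooled-variance t test on two small score samples:")
print(f"  t = {t:.3f}, df = {df}, p = {p:.3f}")
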