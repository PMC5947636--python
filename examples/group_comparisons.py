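"""Between-group comparisons of the kind used for cohort description.

2x2 tables comparing ever-recorded clinical features and concomitant
medications between CYC-treated (n=56) and untreated (n=144) patients,
using the chi-square test with continuity correction or Fisher's exact test,
with a Bonferroni-corrected significance threshold.
"""

from jdmsm import bonferroni_threshold, two_by_two_test

rows = [
    # feature, treated yes/no, untreated yes/no, test
    ("ulceration ever", 21, 35, 21, 123, "chi2_cc"),
    ("calcinosis ever", 22, 34, 28, 116, "chi2_cc"),
    ("edema ever", 36, 20, 68, 76, "chi2_cc"),
    ("iv glucocorticoids", 36, 20, 58, 86, "chi2_cc"),
    ("iv immunoglobulin", 18, 38, 18, 126, "chi2_cc"),
    ("infliximab", 16, 40, 16, 128, "chi2_cc"),
    ("adalimumab", 7, 49, 5, 139, "fisher"),
]

threshold = bonferroni_threshold(0.05, 14)
print(f"significance threshold for 14 tests: {threshold:.4f}\n")
print(f"{'feature':22s} {'treated':>9s} {'untreated':>11s} {'p':>9s}")
for name, a, b, c, d, method in rows:
    res = two_by_two_test(a, b, c, d, method=method)
    star = " *" if res.p_value < threshold else ""
    print(f"{name:22s} {a:4d}/{a+b:<4d} {c:5d}/{c+d:<5d} {res.p_value:9.5f}{star}")

# Starred rows differ between groups after multiplicity correction: treated
# patients carry more severe-disease features and more aggressive co-therapy,
# the classic signature of confounding by indication.
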