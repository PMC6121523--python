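"""Screen directly elicited pairwise judgments for consistency.

A matrix entered judgment-by-judgment (not built from score ratios) can be
intransitive: here a > b, b > c, but c > a.  The consistency ratio flags it.
"""

from dpsir_eri import check_consistency
from dpsir_eri.ahp import ComparisonMatrix

mildly_off = ComparisonMatrix([[1, 2, 4], [1 / 2, 1, 1], [1 / 4, 1, 1]])
intransitive = ComparisonMatrix([[1, 9, 1 / 5], [1 / 9, 1, 5], [5, 1 / 5, 1]])

for name, matrix in [("mildly inconsistent", mildly_off),
                     ("intransitive", intransitive)]:
    report = check_consistency(matrix)
    print(f"{name}: lambda_max = {report.lambda_max:.4f}  CI = {report.ci:.4f}  "
          f"RI = {report.ri}  CR = {report.cr:.4f}  accepted = {report.accepted}")

# The first matrix deviates only slightly from transitivity, so CR stays
# under the 0.1 tolerance and the judgments are usable.  The second one
# cycles (a beats b beats c beats a) and is rejected: those experts would be
# asked to revisit their questionnaire before any weight is derived.
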