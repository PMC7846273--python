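"""Compare mutation frequencies between cohorts with the two-sided binomial
proportion test.

One early cohort reported UPF1 mutations in 18 of 23 adenosquamous tumors;
three later cohorts found 0 of 34. How compatible are those frequencies?
"""

from nmdmutscan.cohort_stats import CohortCounts, two_proportion_test

counts = CohortCounts(k1=0, n1=34, k2=18, n2=23)
for method in ("pooled_z", "fisher"):
    p = two_proportion_test(counts, method)
    print(f"{method:>8}: p = {p:.3e}")

# Both the pooled z-test and Fisher's exact test put the discrepancy far
# below p = 1e-8: frequencies of 0/34 and 18/23 are essentially impossible
# to reconcile as samples from one underlying mutation rate.
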