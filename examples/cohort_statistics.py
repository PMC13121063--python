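"""Cohort-level statistics across the three tumor classes.

Simulates a small phantom cohort (fit -> designate -> per-lesion region
means), then runs the nonparametric workflow: Kruskal-Wallis omnibus tests
and Dunn-Bonferroni pairwise contrasts on lesion-level means.  The printed
table shows, per tumor class, whether the inner tumor region differs from
surrounding skin for each functional parameter — the core cohort question.

Note: n = 6 lesions/class keeps this example quick; the validation suite
runs n = 15.
"""

import warnings

import pbmap

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    summary, dispersion = pbmap.simulate_cohort(n_per_class=6, size=64, seed=4)
    results = pbmap.run_group_analysis(summary)

print("inner vs skin (Dunn-Bonferroni adjusted p):")
for cls in ("sporadic_bcc", "nbccs_bcc", "scc"):
    cells = []
    for param in ("AF0", "A", "tau", "C"):
        row = results.pairwise_lookup(f"regions_within_{cls}", param, "inner", "skin")
        cells.append(f"{param}: p={row.p_adj:.3g}{row.stars}")
    print(f"  {cls:13s} " + "  ".join(cells))

tau_disp = dispersion.groupby("group")["tau_sd"].mean()
print("\nmean intra-core tau SD per lesion (heterogeneity):")
for cls, v in tau_disp.items():
    print(f"  {cls:13s} {v:6.2f} s")
print("SCC cores are programmed (and recovered) as the most heterogeneous; "
      "NBCCS tau stays close to skin, so its tau contrast is weak by design.")
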