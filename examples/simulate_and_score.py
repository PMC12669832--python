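"""Simulate a cohort and test the baseline-vs-search score contrast.

Fifteen larvae crawl with wall-hugging (thigmotactic) dynamics until the
simulated container removal, then switch to orbiting the former stimulus
location.  The pipeline repairs detection gaps, segments the phases and
computes the search score, and the paired Wilcoxon signed-rank test asks
whether the cohort's scores changed between baseline and search.
"""

from larvasearch import ArenaConfig, SimConfig, analyze_cohort, simulate_cohort
from larvasearch.calibration import REPLICATE_SIM_KWARGS

cfg = SimConfig(seed=1, n_larvae=15, mode="local_search", **REPLICATE_SIM_KWARGS)
res = analyze_cohort(simulate_cohort(cfg), ArenaConfig())

base = res.metrics[res.metrics.phase == "baseline"]["search_score"]
search = res.metrics[res.metrics.phase == "search"]["search_score"]
print(f"median search score, baseline : {base.median():+.3f}")
print(f"median search score, search   : {search.median():+.3f}")
row = res.stats[res.stats.comparison == "search_score: baseline vs search"].iloc[0]
print(f"paired Wilcoxon p = {row.p:.2e} {row.stars} (n = {row.n})")
print()
print("A negative baseline score means edge-zone preference (thigmotaxis);")
print("the positive search-phase score shows residency shifted to the")
print("8-16 mm band around the former container position - a local search.")
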