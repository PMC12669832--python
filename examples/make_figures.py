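"""Produce the standard figure set for one simulated cohort.

Writes grayscale position rasters (rows sorted by time-to-contact),
dwell-time and path-length pie charts per phase, and baseline-vs-search
box plots with significance stars to ./example_figures/.
"""

from pathlib import Path

from larvasearch import ArenaConfig, SimConfig, analyze_cohort, simulate_cohort
from larvasearch import plots
from larvasearch.calibration import REPLICATE_SIM_KWARGS

outdir = Path("example_figures")
outdir.mkdir(exist_ok=True)

arena = ArenaConfig()
cfg = SimConfig(seed=3, n_larvae=10, mode="local_search", **REPLICATE_SIM_KWARGS)
res = analyze_cohort(simulate_cohort(cfg), arena)

fig = plots.grayscale_position_plot(res.repaired, res.timelines, arena)
fig.savefig(outdir / "positions.png", dpi=150)
for fig, name in plots.zone_pie_and_box_figures(res.metrics):
    fig.savefig(outdir / f"{name}.png", dpi=150)
print(f"figures written to {outdir}/")
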