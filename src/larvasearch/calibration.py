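"""Monte-Carlo validation of the pipeline and its statistical layer.

Two questions are answered by simulation:

* power — when cohorts really switch from wall-hugging to
  center-orbiting at container removal, how often does the paired
  signed-rank test on the search-score contrast detect it at alpha?
* calibration — when nothing changes (movement regime fixed at the
  thigmotactic baseline, the no-container control), how often does the
  same contrast reject?  A well-calibrated test rejects at about alpha.

Replicate cohorts use full-length baseline and analyzed-search windows
(5 min each); the pre-search interval between them is drawn short
(60 s mean) since it only separates the two analyzed windows.
Replicate seeds derive from the master seed via
``SeedSequence(master_seed).generate_state``, masked to 31 bits.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import ArenaConfig
from .pipeline import analyze_cohort
from .simulate import SimConfig, simulate_cohort
from .stats import wilcoxon_paired

__all__ = [
    "replicate_seeds",
    "search_contrast_pvalues",
    "rejection_rate",
    "paired_test_type_i_error",
]

#: replicate configuration: study-condition analysis windows, short
#: dead time between them
REPLICATE_SIM_KWARGS = dict(
    baseline_s=300.0,
    pre_search_mean_s=60.0,
    pre_search_max_s=120.0,
    investigation_s=60.0,
    search_s=300.0,
)


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """n reproducible 31-bit child seeds from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) & 0x7FFFFFFF


def search_contrast_pvalues(
    n_replicates: int,
    master_seed: int,
    mode: str = "local_search",
    n_larvae: int = 15,
    arena: ArenaConfig | None = None,
    **sim_kwargs,
) -> np.ndarray:
    """Paired-Wilcoxon p-values for the baseline-vs-search search-score
    contrast, one per replicate cohort run through the full pipeline
    (simulation with dropout, gap repair, segmentation, metrics).

    For null calibration (``mode="baseline_thigmotaxis"``), pass
    ``initial_placement="stationary"``: starting every larva at the
    arena center makes the first baseline minute systematically more
    central than any later window (the placement artifact), so the two
    analysis windows are only exchangeable — i.e. the null hypothesis
    is only true — when tracks start from the regime's steady state.
    """
    arena = arena or ArenaConfig()
    kwargs = dict(REPLICATE_SIM_KWARGS)
    kwargs.update(sim_kwargs)
    ps = np.empty(n_replicates)
    for r, seed in enumerate(replicate_seeds(master_seed, n_replicates)):
        cfg = SimConfig(seed=int(seed), n_larvae=n_larvae, mode=mode, **kwargs)
        res = analyze_cohort(simulate_cohort(cfg), arena)
        base = res.metrics[res.metrics.phase == "baseline"].set_index("larva_id")
        search = res.metrics[res.metrics.phase == "search"].set_index("larva_id")
        common = base.index.intersection(search.index)
        ps[r] = wilcoxon_paired(
            base.loc[common, "search_score"].to_numpy(),
            search.loc[common, "search_score"].to_numpy(),
        ).p_value
    return ps


def rejection_rate(p_values: np.ndarray, alpha: float = 0.05) -> float:
    return float(np.mean(np.asarray(p_values) <= alpha))


def paired_test_type_i_error(
    n_datasets: int = 10_000,
    n: int = 15,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the paired signed-rank test under a continuous null.

    Draws ``n_datasets`` paired samples with both members from the same
    normal distribution and reports the fraction rejected at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(n_datasets):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if wilcoxon_paired(x, y).p_value <= alpha:
            rejected += 1
    return rejected / n_datasets
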