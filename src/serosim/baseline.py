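"""End-to-end reproduction of the unaffected-cohort baseline.

Samples a synthetic Hardy-Weinberg cohort at the published allele
frequencies, runs every individual through the calibrated genotype model
and the three-hour simulation, and reports the cohort means of the
per-individual time-averaged concentrations -- the quantities the model
was validated on (5-HTP, fc5-HT, v5-HT in µM; e5-HT in nM; 5-HIAA in µM;
the 5-HIAA/fc5-HT ratio; and 5-HTP as a percentage of the 100 µM
tryptophan input).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .cohort import CohortSpec, sample_cohort
from .genotype import CALIBRATED_SCALE
from .kinetics import ModelParameters
from .simulate import GridSpec, simulate_cohort

__all__ = ["baseline_cohort_means", "PUBLISHED_BASELINE"]

#: published unaffected-cohort means (and SDs) the model reproduces
PUBLISHED_BASELINE = {
    "htp5_mean_uM": (13.62, 0.22),
    "fc5ht_mean_uM": (0.88, 0.26),
    "v5ht_mean_uM": (2.47, 0.67),
    "e5ht_mean_nM": (70.0, 1.3),
    "hiaa5_mean_uM": (0.60, 0.25),
    "hiaa_fc_ratio": (0.67, 0.05),
}


def baseline_cohort_means(
    seed: int = 0,
    n: int = 140,
    params: ModelParameters | None = None,
    scale: Mapping[str, float] | None = None,
    grid: GridSpec | None = None,
    return_summaries: bool = False,
):
    """Sample an n-individual HWE cohort and compute its baseline means.

    Returns a dict of cohort-level quantities (keys as in
    :data:`PUBLISHED_BASELINE` plus ``htp5_pct_of_input``), or
    ``(means, summaries)`` when ``return_summaries`` is set.
    """
    params = params if params is not None else ModelParameters()
    scale = scale if scale is not None else CALIBRATED_SCALE
    records = sample_cohort(CohortSpec(n=n, seed=seed))
    summaries = simulate_cohort(records, params=params, scale=scale, grid=grid)
    m = summaries[[c for c in summaries.columns if c.endswith("_mean")]].mean()
    means = {
        "htp5_mean_uM": float(m["htp5_mean"]),
        "fc5ht_mean_uM": float(m["fc5ht_mean"]),
        "v5ht_mean_uM": float(m["v5ht_mean"]),
        "e5ht_mean_nM": float(m["e5ht_mean"] * 1000.0),
        "hiaa5_mean_uM": float(m["hiaa5_mean"]),
        "hiaa_fc_ratio": float(m["hiaa5_mean"] / m["fc5ht_mean"]),
        "htp5_pct_of_input": float(100.0 * m["htp5_mean"] / params.trp_serum_init),
    }
    if return_summaries:
        return means, summaries
    return means
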