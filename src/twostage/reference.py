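"""Published ARIC summary values that parameterize the worked examples.

The raw ARIC (Atherosclerosis Risk in Communities) participant data are
restricted, but the published late-midlife summary table — severity-category
by WMH-status counts for each scoring system in the N=1311 analytic sample —
is public and is all the recruitment calculator needs. These constants are
the package's reference inputs: they seed the synthetic-cohort defaults and
drive the reproduction of the published sample-size and cost tables.
"""

from __future__ import annotations

import numpy as np

from .cohort import CrossTab

__all__ = [
    "MIDLIFE_N",
    "MIDLIFE_N_SIGNIFICANT",
    "MIDLIFE_CROSSTABS",
    "MIDLIFE_FEATURE_PREVALENCE",
    "LATE_LIFE_P_WMH",
    "WEIGHTED_RETINAL_SEVERE_STAGES",
    "PUBLISHED_WEIGHTS",
]

#: Late-midlife analytic sample with gradable retinal and WMH measures.
MIDLIFE_N = 1311
#: Participants with significant WMH burden (CHS grade > 2): 130/1311 = 9.9%.
MIDLIFE_N_SIGNIFICANT = 130

# Severity (none/mild/moderate/severe) x WMH status (no/low, significant)
# counts for the three unweighted scoring systems in the midlife sample.
MIDLIFE_CROSSTABS = {
    "retinal": CrossTab(
        counts=np.array([[721, 60], [325, 38], [60, 9], [75, 23]]),
        score_kind="retinal"),
    "clinical": CrossTab(
        counts=np.array([[231, 6], [509, 45], [363, 63], [78, 16]]),
        score_kind="clinical"),
    "combined": CrossTab(
        counts=np.array([[169, 2], [367, 29], [341, 37], [304, 62]]),
        score_kind="combined"),
}

#: P(feature present | WMH status) in the midlife sample,
#: keyed feature -> (no/low burden, significant burden).
MIDLIFE_FEATURE_PREVALENCE = {
    "retinopathy": (0.062, 0.17),
    "av_nicking": (0.050, 0.15),
    "focal_narrowing": (0.11, 0.19),
    "generalized_narrowing": (0.25, 0.25),
    "age_at_or_above_cutoff": (0.63, 0.82),
    "diabetes": (0.16, 0.21),
    "hypertension": (0.45, 0.66),
}

#: Late-life prevalence of significant WMH (volume >= 9.3 cm^3): 60%.
LATE_LIFE_P_WMH = 0.60

#: Published weighted severe-retinal design stage sizes
#: (n at retinal prescreening, n at MRI screening).
WEIGHTED_RETINAL_SEVERE_STAGES = (23_406, 2_809)

#: Published normalized weights on the restricted data (reference only;
#: they are not reproducible without the participant-level records).
PUBLISHED_WEIGHTS = {
    "retinal": {"retinopathy": 1.210, "av_nicking": 1.187},
    "clinical": {"age_at_or_above_cutoff": 1.354, "hypertension": 1.314},
}
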