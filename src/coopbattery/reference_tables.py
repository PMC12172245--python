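"""Published group summaries used as worked-example inputs.

Summary statistics (mean, SD, N per group) transcribed from the result
tables of a published case-control study of cooperative decision-making in
borderline personality disorder (35 female patients, 50 matched healthy
controls).  Sample sizes below 35/50 reflect that study's consistency
screening of slider responses.  These numbers are *inputs* for the
reproduction pipeline — every statistic computed from them here is
recomputed, never copied.
"""

from __future__ import annotations

from .inferential_stats import GroupSummary

__all__ = ["TASK_SUMMARIES", "CLINICAL_SUMMARIES", "UG_GLMM_COEFS"]

# task measures: label -> (patient group, control group)
TASK_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "svo_general": (GroupSummary(32.421, 7.127, 29), GroupSummary(35.579, 5.203, 50)),
    "svo_prosocial_motivation": (GroupSummary(0.264, 0.101, 24), GroupSummary(0.287, 0.211, 44)),
    "dg_allocation": (GroupSummary(4.457, 0.980, 35), GroupSummary(4.780, 0.582, 50)),
    "ug_rejection_rate": (GroupSummary(36.190, 23.391, 35), GroupSummary(40.476, 26.571, 49)),
    "min_acceptance": (GroupSummary(4.057, 2.222, 35), GroupSummary(4.280, 1.852, 50)),
    "jpe_disadv_weight": (GroupSummary(0.023, 0.029, 35), GroupSummary(0.025, 0.026, 50)),
}

# clinical / demographic measures: label -> (patient group, control group)
CLINICAL_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "age": (GroupSummary(25.8, 5.58, 35), GroupSummary(24.88, 5.43, 50)),
    "mini_q": (GroupSummary(34.03, 12.12, 35), GroupSummary(35.74, 9.91, 50)),
    "bdi_ii": (GroupSummary(27.743, 12.363, 35), GroupSummary(3.720, 4.071, 50)),
    "bscl": (GroupSummary(1.584, 0.737, 35), GroupSummary(0.186, 0.261, 50)),
    "lpfs": (GroupSummary(35.629, 5.309, 35), GroupSummary(18.840, 5.068, 50)),
    "pid5bf": (GroupSummary(37.571, 8.859, 35), GroupSummary(13.020, 7.789, 50)),
}

# published logistic mixed-model coefficients (log-odds scale)
UG_GLMM_COEFS: dict[str, float] = {
    "offer": -1.14,
    "group": -0.335,
    "group_x_offer": -0.007,
    "offer_dissociality_model": -1.142,
    "fairness_offer2": -0.192,
}
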