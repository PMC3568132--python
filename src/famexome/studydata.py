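"""Published summary inputs from the seven-family exome study.

These are *inputs*, not expected outputs: the per-sample detected-variant
counts and per-family post-filter counts printed in the original study's
filtering-summary tables, and the carrier counts of its FANCM stopgain
case-control experiment.  The funnel summarizer and the association
statistics recompute the study's Average/Percentage-remaining rows and
OR/p-value from these raw counts at run time.

Eleven sequenced individuals span seven families: four families contributed
two members each, three contributed one.  For two-member families the
post-detection counts are family-level (variants shared by both members).
"""

from __future__ import annotations

#: member -> family, for the eleven sequenced individuals
FAMILY_MAP = {
    "07S240": "49",
    "DAD_1": "694",
    "F2887_13": "2887",
    "F2887_24": "2887",
    "F3311_5": "3311",
    "F3311_43": "3311",
    "I_1408": "531",
    "RUL036_2": "RUL036",
    "RUL036_7": "RUL036",
    "RUL153_2": "RUL153",
    "RUL153_3": "RUL153",
}

#: detected heterozygous SNVs per sequenced sample
SNV_DETECTED_PER_SAMPLE = {
    "07S240": 29549,
    "DAD_1": 28697,
    "F2887_13": 28978,
    "F2887_24": 30691,
    "F3311_5": 26774,
    "F3311_43": 26468,
    "I_1408": 28841,
    "RUL036_2": 27060,
    "RUL036_7": 27032,
    "RUL153_2": 26908,
    "RUL153_3": 27406,
}

#: per-family SNV counts after each post-detection stage:
#: shared-in-family, not-in-control-panel, not-in-dbSNP, consequence
SNV_PER_FAMILY = {
    "49": (29549, 9451, 3838, 1000),
    "694": (28697, 9144, 3666, 899),
    "2887": (9271, 1681, 404, 156),
    "3311": (8776, 1686, 328, 100),
    "531": (28841, 9022, 3553, 971),
    "RUL036": (11405, 2746, 776, 188),
    "RUL153": (8295, 1373, 197, 53),
}

#: detected INDELs per sequenced sample
INDEL_DETECTED_PER_SAMPLE = {
    "07S240": 36189,
    "DAD_1": 35606,
    "F2887_13": 34081,
    "F2887_24": 31445,
    "F3311_5": 30983,
    "F3311_43": 26441,
    "I_1408": 36131,
    "RUL036_2": 25162,
    "RUL036_7": 25652,
    "RUL153_2": 25698,
    "RUL153_3": 26045,
}

#: per-family INDEL counts after each post-detection stage
INDEL_PER_FAMILY = {
    "49": (36189, 26077, 24580, 11387),
    "694": (35606, 25741, 24204, 11046),
    "2887": (12299, 5314, 4650, 1354),
    "3311": (12442, 4982, 4340, 579),
    "531": (36131, 26082, 24591, 11352),
    "RUL036": (13042, 5087, 4398, 587),
    "RUL153": (11878, 4445, 3834, 506),
}

#: stage labels covered by the printed tables (final score+gene stage is
#: reported only as a study-wide total and is not summarized per family)
TABLE_STAGES = (
    "detected",
    "shared_in_family",
    "not_in_control_panel",
    "not_in_dbsnp",
    "consequence",
)

#: FANCM stopgain case-control experiment: carrier and sample counts
FANCM_CARRIERS_CASES = 10
FANCM_N_CASES = 3409
FANCM_CARRIERS_CONTROLS = 5
FANCM_N_CONTROLS = 3896
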