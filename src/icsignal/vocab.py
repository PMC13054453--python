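"""Shared controlled vocabulary for the synthetic dictionaries and defaults.

PT codes follow a MedDRA-like scheme (an opaque numeric-looking key); the
named terms below are the ones the analyses reference by default: the case
definition of Raynaud's phenomenon, the broadened case definition, and the
symptom terms used by the planted co-occurrence clusters.
"""

from __future__ import annotations

# --- Preferred Terms with fixed identities -------------------------------

RAYNAUDS_PT = "PT1000001"
PERIPHERAL_ISCHAEMIA_PT = "PT1000002"
CHILBLAINS_PT = "PT1000003"

NARROW_PT_SET = (RAYNAUDS_PT,)
BROAD_PT_SET = (RAYNAUDS_PT, PERIPHERAL_ISCHAEMIA_PT, CHILBLAINS_PT)

#: (pt_code, pt_name, hlt, soc) for the terms the generator always includes.
NAMED_PTS = [
    (RAYNAUDS_PT, "Raynaud's phenomenon", "HLT_PERIPH_VASC", "SOC_VASCULAR"),
    (PERIPHERAL_ISCHAEMIA_PT, "Peripheral ischaemia", "HLT_PERIPH_VASC", "SOC_VASCULAR"),
    (CHILBLAINS_PT, "Chilblains", "HLT_PERIPH_VASC", "SOC_VASCULAR"),
    ("PT1000004", "Skin discolouration", "HLT_SKIN_COLOUR", "SOC_SKIN"),
    ("PT1000005", "Peripheral coldness", "HLT_PERIPH_VASC", "SOC_VASCULAR"),
    ("PT1000006", "Cyanosis", "HLT_SKIN_COLOUR", "SOC_VASCULAR"),
    ("PT1000007", "Hypoaesthesia", "HLT_PARAESTH", "SOC_NERVOUS"),
    ("PT1000008", "Pain in extremity", "HLT_MUSC_PAIN", "SOC_MUSC"),
    ("PT1000009", "Dry mouth", "HLT_SALIVARY", "SOC_GI"),
    ("PT1000010", "Dry eye", "HLT_LACRIMAL", "SOC_EYE"),
    ("PT1000011", "Vasospasm", "HLT_PERIPH_VASC", "SOC_VASCULAR"),
    ("PT1000012", "Feeling cold", "HLT_TEMP_PERCEP", "SOC_GENERAL"),
]

# --- ATC prefixes of drug classes recommended in Raynaud treatment --------
#
# Reports carrying any drug in these classes are excluded from the case
# series: such drugs indicate pre-existing disease, so keeping them would
# distort the disproportionality comparison (protopathic/indication bias).
# Calcium channel blockers, PDE5 inhibitors, endothelin receptor
# antagonists, angiotensin receptor blockers, ACE inhibitors, alpha
# blockers, and prostanoids.
DEFAULT_RP_TREATMENT_ATC_PREFIXES = (
    "C08",      # calcium channel blockers
    "G04BE",    # PDE5 inhibitors
    "C02KX",    # endothelin receptor antagonists
    "C09C",     # ARBs, plain
    "C09D",     # ARBs, combinations
    "C09A",     # ACE inhibitors, plain
    "C09B",     # ACE inhibitors, combinations
    "C02CA",    # alpha blockers
    "B01AC09",  # epoprostenol
    "B01AC11",  # iloprost
    "B01AC21",  # treprostinil
)

#: Age band edges used both for generation strata and for Mantel-Haenszel
#: stratification: <18, 18-44, 45-64, 65-74, >=75 (unknown is its own band).
DEFAULT_AGE_BAND_EDGES = (18, 45, 65, 75)

AGE_BAND_LABELS = ("<18", "18-44", "45-64", "65-74", ">=75", "unknown")

SEX_LEVELS = ("F", "M", "unknown")
REPORTER_TYPES = ("health_professional", "consumer", "other", "unknown")
DRUG_ROLES = ("suspect", "interacting", "concomitant")
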