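"""Synthetic stand-in cohort tables for the tool-comparison arithmetic.

The published comparison of two prioritization tools on a rare-disease
cohort reports only aggregate counts: 23 vs 18 plausible genes, 10
shared across seven families (three families sharing two genes, four
sharing one), and top-5 success on five solved families of 5/5 vs 2/5.
The gene identifiers below are synthetic placeholders constructed to
realize exactly those cardinalities, so the comparison operations can be
exercised end to end.
"""

# plausible-gene sets per family; families F01-F07 carry the overlaps
GPT4_PLAUSIBLE = {
    "F01": {"OV01", "OV02"},
    "F02": {"OV03", "OV04"},
    "F03": {"OV05", "OV06"},
    "F04": {"OV07"},
    "F05": {"OV08"},
    "F06": {"OV09"},
    "F07": {"OV10"},
    # GPT-4-only plausible genes across its remaining nine families
    "F08": {"GA01", "GA02"},
    "F09": {"GA03", "GA04"},
    "F10": {"GA05", "GA06"},
    "F11": {"GA07"},
    "F12": {"GA08"},
    "F13": {"GA09"},
    "F14": {"GA10"},
    "F15": {"GA11"},
    "F16": {"GA12", "GA13"},
}

EXOMISER_PLAUSIBLE = {
    "F01": {"OV01", "OV02"},
    "F02": {"OV03", "OV04"},
    "F03": {"OV05", "OV06"},
    "F04": {"OV07"},
    "F05": {"OV08"},
    "F06": {"OV09"},
    "F07": {"OV10"},
    # Exomiser-only plausible genes across its remaining four families
    "F17": {"EX01", "EX02"},
    "F18": {"EX03", "EX04"},
    "F19": {"EX05", "EX06"},
    "F20": {"EX07", "EX08"},
}

# the five solved families and each tool's top-5 candidate lists
SOLVED = {
    "S1": "CAUS1",
    "S2": "CAUS2",
    "S3": "CAUS3",
    "S4": "CAUS4",
    "S5": "CAUS5",
}

GPT4_TOP5 = {
    "S1": ["CAUS1", "N01", "N02", "N03", "N04"],
    "S2": ["N05", "CAUS2", "N06", "N07", "N08"],
    "S3": ["N09", "N10", "CAUS3", "N11", "N12"],
    "S4": ["N13", "N14", "N15", "CAUS4", "N16"],
    "S5": ["N17", "N18", "N19", "N20", "CAUS5"],
}

EXOMISER_TOP5 = {
    "S1": ["CAUS1", "N01", "N21", "N22", "N23"],
    "S2": ["N24", "N25", "N26", "N27", "N28"],
    "S3": ["N29", "CAUS3", "N30", "N31", "N32"],
    "S4": ["N33", "N34", "N35", "N36", "N37"],
    "S5": ["N38", "N39", "N40", "N41", "N42"],
}
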