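"""Integer label codes shared between generators and the surface pipeline."""

REGION_CODES = {"entorhinal": 1, "parahippocampal": 2, "fusiform": 3}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}

SUBFIELD_CODES = {"subiculum": 11, "CA1": 12, "CA2": 13, "CA3": 14, "CA4": 15}
SUBFIELD_NAMES = {v: k for k, v in SUBFIELD_CODES.items()}

MESIOTEMPORAL_REGIONS = tuple(REGION_CODES)
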