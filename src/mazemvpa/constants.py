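"""Shared constants: stimulus categories and the binary comparisons."""

#: stimulus categories, in presentation order within an exploration block
CATEGORIES = ("faces", "buildings", "animals")

#: the three binary comparisons in fixed column order; first-named class is +1
PAIRS = (("faces", "buildings"), ("faces", "animals"), ("buildings", "animals"))

#: column labels used in tabular outputs, matching PAIRS
PAIR_LABELS = ("F-B", "F-A", "B-A")
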