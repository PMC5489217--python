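"""Published batch-fermentation reference outcomes for xylose-fermenting
yeast treated with respiratory-chain inhibitors.

Values are overall ethanol yields from xylose (Y, g/g) and volumetric
ethanol productivities (Q, g/L/h) reported for *Scheffersomyces stipitis*
batch cultures: shake-flask screens of terminal-oxidase and complex-I
inhibitors, and fermenter runs with rotenone (a complex-I inhibitor) at two
oxygen-transfer conditions. They serve as inputs to the relative-change
arithmetic in examples and in the acceptance checks; nothing in the package
fits to them.
"""

# shake-flask inhibitor screen: (Y g/g, Q g/L/h)
FLASK = {
    "control": (0.3006, 0.1576),
    "cyanide_1mM": (0.1068, 0.0359),
    "azide_0.01mM": (0.0948, 0.0330),
    "sham_1mM": (0.2240, 0.1059),
    "sham_cyanide": (0.1173, 0.0375),
    "sham_azide": (0.1186, 0.0397),
    "rotenone_0.25mM": (0.3453, 0.1169),
}

# fermenter runs with rotenone 2.5 mM at two kLa conditions: (Y g/g, Q g/L/h)
FERMENTER = {
    ("control", 25): (0.1681, 0.3026),
    ("rotenone", 25): (0.2096, 0.1766),
    ("control", 15): (0.3207, 0.4888),
    ("rotenone", 15): (0.3812, 0.3193),
}
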