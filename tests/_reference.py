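"""Published reference ANOVA tables for the sea-urchin lantern case study.

Sums of squares, degrees of freedom and F values from the published analyses
of 10 Aristotle's lanterns (5 pyramids each, 12 landmarks, 2 digitising
replicates): the rotational-matching design (A1), the bilateral-object
design (A2), the nested C_5v design (A3) and the centroid-size ANOVA.  Each
entry: effect -> (conv_df, shape_df, SS, F_published); error rows carry no F.
These serve as fixed inputs for checking df bookkeeping and the F-ratio
construction (numerators, denominators, df multipliers) against an
independent source.
"""

A1_SHAPE = {
    "individual": (9, 90, 0.111301, 125.639),
    "part": (4, 40, 0.000429, 1.090),
    "individual_x_part": (36, 360, 0.003544, 3.377),
    "error": (50, 500, 0.001457, None),
}

A2_SHAPE = {
    "part": (4, 40, 0.000429, 3.312),
    "reflection": (1, 10, 0.010059, 365.744),
    "part_x_reflection": (4, 40, 0.000605, 5.497),
    "symmetric_error": (45, 450, 0.001457, None),
    "asymmetric_error": (45, 450, 0.001238, None),
    "total_error": (45, 900, 0.002695, None),
}

A3_SHAPE = {
    "individual": (9, 90, 0.111274, 125.648),
    "part": (4, 40, 0.000429, 1.090),
    "reflection_in_part": (5, 50, 0.010664, 12.511),
    "individual_x_part": (36, 360, 0.003542, 0.577),
    "individual_x_reflection_in_part": (45, 450, 0.007671, 6.198),
    "symmetric_error": (45, 450, 0.001457, None),
    "asymmetric_error": (45, 450, 0.001238, None),
    "total_error": (45, 900, 0.002695, None),
}

SIZE = {
    "individual": (9, 9, 141.697309, 1353.196),
    "part": (4, 4, 0.037473, 0.805),
    "individual_x_part": (36, 36, 0.418852, 7.807),
    "error": (50, 50, 0.074512, None),
}

# published Pillai's-trace entries reconstructable from the tables:
# effect -> (pillai, P_param_published)
A1_PILLAI = {"part": (1.0868, 0.3149)}
A3_PILLAI = {"reflection_in_part": (1.4737, 0.0071)}

TABLES = {"A1": A1_SHAPE, "A2": A2_SHAPE, "A3": A3_SHAPE, "size": SIZE}
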