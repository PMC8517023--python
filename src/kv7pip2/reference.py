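"""Published whole-cell gating parameters for human Kv7.2 variants.

Boltzmann midpoints (V1/2, mV) and slope factors (k, mV per e-fold) reported
for homomeric Kv7.2 channels expressed in CHO hm1 cells, with and without
PIP5K co-expression (PIP5K raises membrane PIP2 and left-shifts activation).
These serve as worked-example inputs: generating a noiseless normalised-
conductance curve from a row and refitting it must return the row.
"""

GV_PARAMS: dict[str, dict[str, float]] = {
    "WT":                 {"v_half": -30.5, "k": 5.9},
    "R214Q":              {"v_half": -31.4, "k": 4.3},
    "K219N":              {"v_half": -13.7, "k": 6.5},
    "R325Q":              {"v_half": -65.1, "k": 1.2},
    "R353Q":              {"v_half": -31.7, "k": 5.0},
    "R214Q/K219N":        {"v_half": -9.7, "k": 5.6},
    "R214Q/K219N/R353Q":  {"v_half": -9.8, "k": 5.5},
    "WT+PIP5K":           {"v_half": -40.3, "k": 2.3},
    "R214Q+PIP5K":        {"v_half": -38.7, "k": 2.2},
    "K219N+PIP5K":        {"v_half": -29.4, "k": 3.2},
    "R325Q+PIP5K":        {"v_half": -33.3, "k": 8.5},
    "R353Q+PIP5K":        {"v_half": -42.4, "k": 1.2},
    "R214Q/K219N+PIP5K":  {"v_half": -20.5, "k": 3.8},
    "R214Q/K219N/R353Q+PIP5K": {"v_half": -20.8, "k": 4.3},
}

# activation-protocol voltage grid (mV): -100 to +20 in 10-mV increments
ACTIVATION_GRID = tuple(float(v) for v in range(-100, 30, 10))
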