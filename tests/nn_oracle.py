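"""Independent brute-force nearest-neighbor Tm oracle for tests.

Carries its own copy of the unified duplex parameters (the ten unique
stacks, expanded by hand below) and accumulates enthalpy/entropy term by
term, so it shares no code or data file with the implementation it
checks.
"""

from math import log

_STACKS = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_RC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _stack_params(st: str):
    if st in _STACKS:
        return _STACKS[st]
    rc = _RC[st[1]] + _RC[st[0]]
    return _STACKS[rc]


def tm_brute_force(seq: str, na: float = 1.0, ct: float = 0.25e-6, x: float = 4.0):
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = _stack_params(seq[i : i + 2])
        dh += h
        ds += s
    for term in (seq[0], seq[-1]):
        if term in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    if seq == "".join(_RC[c] for c in reversed(seq)):
        ds += -1.4
        x = 1.0
    ds += 0.368 * (len(seq) - 1) * log(na)
    return dh * 1000.0 / (ds + 1.987 * log(ct / x)) - 273.15
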