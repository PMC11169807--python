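"""Genotype-call codes shared across the package.

Calls are coded as small integers so genotype matrices can live in
compact pandas/numpy containers:

====  ==========  =======================================
code  char        meaning
====  ==========  =======================================
0     ``A``       homozygous recurrent-parent allele
1     ``H``       heterozygous
2     ``B``       homozygous donor-parent allele
-1    ``-``       missing call
====  ==========  =======================================
"""

from __future__ import annotations

import numpy as np

HOM_REC: int = 0
HET: int = 1
HOM_DON: int = 2
MISSING: int = -1

CODE_TO_CHAR = {HOM_REC: "A", HET: "H", HOM_DON: "B", MISSING: "-"}
CHAR_TO_CODE = {v: k for k, v in CODE_TO_CHAR.items()}

STATE_NAMES = {HOM_REC: "HOM_REC", HET: "HET", HOM_DON: "HOM_DON", MISSING: "MISSING"}


def codes_to_chars(arr) -> np.ndarray:
    a = np.asarray(arr)
    out = np.empty(a.shape, dtype="<U1")
    for code, ch in CODE_TO_CHAR.items():
        out[a == code] = ch
    return out


def chars_to_codes(arr) -> np.ndarray:
    a = np.asarray(arr, dtype=str)
    out = np.empty(a.shape, dtype=np.int8)
    for ch, code in CHAR_TO_CODE.items():
        out[a == ch] = code
    return out
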