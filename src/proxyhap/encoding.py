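"""Four-state diploid call encoding shared across the pipeline.

Calls are collapsed diploid genotypes stored as small integers:

====  =========  =================================================
code  name       meaning
====  =========  =================================================
0     REF_HOM    homozygous for the reference (array REF) allele
1     ALT_HOM    homozygous for the alternate (array ALT) allele
2     HET        heterozygous
-1    MISSING    no call
====  =========  =================================================

At a causal site the same codes are read as WT_HOM / MUT_HOM: the
panel VCF's REF allele is the wild-type allele by construction.  The
mapping between an array marker's REF/ALT and a causal site's WT/MUT
(the "orientation") is resolved by the proxy scorer, never assumed.
"""

from __future__ import annotations

import numpy as np

REF_HOM: int = 0
ALT_HOM: int = 1
HET: int = 2
MISSING: int = -1

# aliases used when the vector holds causal-site calls
WT_HOM: int = REF_HOM
MUT_HOM: int = ALT_HOM

CALL_NAMES = {REF_HOM: "REF_HOM", ALT_HOM: "ALT_HOM", HET: "HET", MISSING: "MISSING"}

# Array-matrix token spellings accepted on input (Illumina-style letters
# or numeric dosage) and the canonical spelling used on output.
TOKEN_TO_CODE = {
    "AA": REF_HOM,
    "BB": ALT_HOM,
    "AB": HET,
    "BA": HET,
    "--": MISSING,
    "0": REF_HOM,
    "2": ALT_HOM,
    "1": HET,
    "-1": MISSING,
}
CODE_TO_TOKEN = {REF_HOM: "AA", ALT_HOM: "BB", HET: "AB", MISSING: "--"}

VALID_CODES = frozenset((REF_HOM, ALT_HOM, HET, MISSING))


def as_call_array(calls) -> np.ndarray:
    """Coerce a sequence of call codes to a validated int8 array."""
    arr = np.asarray(calls, dtype=np.int8)
    bad = ~np.isin(arr, (REF_HOM, ALT_HOM, HET, MISSING))
    if bad.any():
        raise ValueError(f"invalid call codes: {sorted(set(arr[bad].tolist()))}")
    return arr
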