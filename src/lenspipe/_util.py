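"""Small shared helpers: alphabet constants, seeds, coordinate conventions.

Internal coordinates are 0-based half-open throughout the package; every
emitted file (GFF3, VCF, pileup TSV) uses that format's 1-based convention.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: purine<->purine or pyrimidine<->pyrimidine partner of each base
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def derive_seed(seed: int, *salt: int) -> int:
    """Derive an independent stream seed < 2**31 from a master seed."""
    ss = np.random.SeedSequence([int(seed), *[int(s) for s in salt]])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_from(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *salt))
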