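"""Synonymous divergence (Ks) by Nei-Gojobori (1986) counting, binned-mode
summarisation and divergence-time conversion.

Ks is estimated by unweighted pathway counting: per codon, synonymous site
counts are the per-position fractions of single-base changes that preserve
the amino acid (changes to stop codons count as nonsynonymous); codon pairs
differing at several positions average their synonymous/nonsynonymous
difference counts over all mutational pathways, excluding pathways that
pass through a stop codon whenever at least one stop-free pathway exists.
The proportion of synonymous differences pS = Sd/S is Jukes-Cantor
corrected, Ks = -(3/4) ln(1 - (4/3) pS).

Only equal-length, gap-free coding sequences are accepted: the indel-free
filter stands in for a multiple-alignment step, mirroring an analysis that
restricts divergence dating to ortholog alignments without indels.

Divergence time uses the standard identity Ks = 2 r T, i.e. T = Ks / (2 r),
with a default synonymous rate r = 5.17e-3 substitutions/synonymous
site/Myr for the legume lineage.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._util import BASES

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD.stop_codons)


class SaturationError(ValueError):
    """pS >= 0.75: Jukes-Cantor correction undefined (saturated pair)."""


def _translate(codon: str) -> str:
    return "*" if codon in _STOPS else _STANDARD.forward_table[codon]


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon (0..3): per position, the
    fraction of the three single-base changes that are synonymous; changes
    creating a stop codon count as nonsynonymous."""
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no defined site count")
    aa = _translate(codon)
    s = 0.0
    for p in range(3):
        syn = sum(1 for b in BASES if b != codon[p]
                  and _translate(codon[:p] + b + codon[p + 1:]) == aa)
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaged over mutational pathways.

    Pathways traversing a stop codon are excluded when a stop-free pathway
    exists; if every pathway hits a stop, all are used with the stop steps
    counted as nonsynonymous.
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, hits_stop = c1, 0.0, 0.0, False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in _STOPS or cur in _STOPS:
                hits_stop = True
                nd += 1.0
            elif _translate(cur) == _translate(nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        paths.append((hits_stop, sd, nd))
    clean = [(sd, nd) for stop, sd, nd in paths if not stop]
    use = clean if clean else [(sd, nd) for _, sd, nd in paths]
    sd = sum(x for x, _ in use) / len(use)
    nd = sum(x for _, x in use) / len(use)
    return sd, nd


@dataclass
class KsEstimate:
    label: str
    n_codons: int
    S: float          # synonymous sites (pair average)
    N: float          # nonsynonymous sites
    Sd: float         # synonymous differences
    Nd: float         # nonsynonymous differences
    pS: float
    ks: float


def ks_ng86(seq_a: str, seq_b: str, label: str = "") -> KsEstimate:
    """NG86 Ks for an equal-length, gap-free, in-frame CDS pair."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3 != 0 or len(seq_a) == 0:
        raise ValueError("sequence length must be a positive multiple of 3")
    if set(seq_a + seq_b) - set(BASES):
        raise ValueError("sequences must be gap- and ambiguity-free")
    codons_a = [seq_a[i:i + 3] for i in range(0, len(seq_a), 3)]
    codons_b = [seq_b[i:i + 3] for i in range(0, len(seq_b), 3)]
    if any(c in _STOPS for c in codons_a + codons_b):
        raise ValueError("internal stop codon in input CDS")
    S = 0.5 * (sum(map(synonymous_sites, codons_a))
               + sum(map(synonymous_sites, codons_b)))
    N = 3.0 * len(codons_a) - S
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sd, nd = _pathway_differences(ca, cb)
        Sd, Nd = Sd + sd, Nd + nd
    pS = Sd / S if S > 0 else 0.0
    if pS >= 0.75:
        raise SaturationError(f"pS={pS:.3f} >= 0.75, Ks saturated")
    ks = -0.75 * np.log(1.0 - (4.0 / 3.0) * pS)
    return KsEstimate(label, len(codons_a), S, N, Sd, Nd, pS, float(ks))


def ks_table(pairs, labels=None) -> pd.DataFrame:
    """Ks estimates for an iterable of (seq_a, seq_b) pairs; saturated pairs
    are reported with ks = NaN."""
    rows = []
    for i, (a, b) in enumerate(pairs):
        label = labels[i] if labels is not None else f"pair{i + 1}"
        try:
            rows.append(asdict(ks_ng86(a, b, label)))
        except SaturationError:
            rows.append({"label": label, "n_codons": len(a) // 3, "S": np.nan,
                         "N": np.nan, "Sd": np.nan, "Nd": np.nan,
                         "pS": np.nan, "ks": np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# binned mode and divergence time
# ---------------------------------------------------------------------------

@dataclass
class KsMode:
    mode: float        # midpoint of the most populated bin
    bin_left: float
    bin_width: float
    count: int
    n_values: int


def mode_binned(ks_values, bin_width: float = 0.01) -> KsMode:
    """Mode of Ks values on a fixed-width histogram anchored at 0; the
    midpoint of the most populated bin is returned, ties going to the
    lowest bin."""
    vals = np.asarray([v for v in np.ravel(ks_values) if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("mode_binned requires at least one finite Ks value")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bins = np.floor(vals / bin_width).astype(int)
    counts = np.bincount(bins)
    b = int(np.argmax(counts))             # argmax takes the lowest tie
    return KsMode(mode=(b + 0.5) * bin_width, bin_left=b * bin_width,
                  bin_width=bin_width, count=int(counts[b]), n_values=len(vals))


def ks_histogram(ks_values, bin_width: float = 0.01) -> pd.DataFrame:
    vals = np.asarray([v for v in np.ravel(ks_values) if np.isfinite(v)], dtype=float)
    bins = np.floor(vals / bin_width).astype(int)
    counts = np.bincount(bins)
    return pd.DataFrame({"bin_left": np.arange(len(counts)) * bin_width,
                         "count": counts})


@dataclass(frozen=True)
class DivergenceModel:
    """Synonymous molecular clock: rate in substitutions/synonymous
    site/Myr (default: legume lineage) and the Ks histogram bin width."""

    rate: float = 5.17e-3
    bin_width: float = 0.01

    def __post_init__(self):
        if self.rate <= 0 or self.bin_width <= 0:
            raise ValueError("rate and bin_width must be positive")


def divergence_time(ks_mode: float, model: DivergenceModel = DivergenceModel()
                    ) -> float:
    """Myr since divergence under Ks = 2 r T, i.e. T = Ks / (2 r)."""
    if ks_mode < 0:
        raise ValueError("Ks must be non-negative")
    return ks_mode / (2.0 * model.rate)


def divergence_report(ks_values, model: DivergenceModel = DivergenceModel()
                      ) -> dict:
    m = mode_binned(ks_values, model.bin_width)
    return {"n_pairs": m.n_values, "bin_width": model.bin_width,
            "mode_ks": m.mode, "mode_bin_left": m.bin_left,
            "mode_count": m.count, "rate_per_myr": model.rate,
            "divergence_time_myr": divergence_time(m.mode, model)}


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# per-subset impact tallies
# ---------------------------------------------------------------------------

def species_partition(annotated: pd.DataFrame, genotypes: list[str],
                      subset: list[str]) -> pd.Series:
    """Impact-class tallies restricted to SNPs segregating within a genotype
    subset (at least one confident ALT among the subset)."""
    unknown = set(subset) - set(genotypes)
    if unknown:
        raise ValueError(f"unknown genotype(s): {sorted(unknown)}")
    seg = (annotated[list(subset)] == "ALT").any(axis=1)
    return annotated.loc[seg, "impact"].value_counts().sort_index()
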