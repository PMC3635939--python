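"""SNP calling, non-redundant merging, classification, and SSR detection.

A site in one genotype's pileup is a confident ALT call iff the most
frequent non-reference base is supported by at least ``min_reads`` reads
AND by at least ``min_fraction`` of all reads at the site (defaults 3 and
0.80, boundary inclusive).  Sites failing either rule but showing at least
one non-reference read are kept as below-threshold evidence, reported only
at positions where some genotype has a confident call.  Only substitutions
are considered; the panel lines are inbred, so no heterozygous genotype
state is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import BASES

log = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

STATUS_REF = "REF"
STATUS_ALT = "ALT"
STATUS_MISSING = "MISSING"
STATUS_BELOW = "BELOW_THRESHOLD"


@dataclass
class ReferenceContig:
    id: str
    seq: str
    repeat_class: bool = False
    duplicate_of: str | None = None

    @property
    def length(self) -> int:
        return len(self.seq)


def reference_from_fasta(path, repeat_ids=(), duplicates: dict | None = None
                         ) -> dict[str, ReferenceContig]:
    from Bio import SeqIO
    duplicates = duplicates or {}
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = ReferenceContig(rec.id, str(rec.seq).upper(),
                                      repeat_class=rec.id in set(repeat_ids),
                                      duplicate_of=duplicates.get(rec.id))
    return out


def filter_reference(contigs: dict[str, ReferenceContig], min_len: int = 200
                     ) -> tuple[dict[str, ReferenceContig], pd.DataFrame]:
    """Drop repeat-class contigs and contigs shorter than ``min_len`` bp
    (a 200 bp contig is kept).  Returns (retained, removal log)."""
    if not contigs:
        log.warning("filter_reference received an empty contig set")
    kept, removed = {}, []
    for cid, c in contigs.items():
        if c.repeat_class:
            removed.append({"contig": cid, "reason": "repeat_class"})
        elif c.length < min_len:
            removed.append({"contig": cid, "reason": f"length<{min_len}"})
        else:
            kept[cid] = c
    return kept, pd.DataFrame(removed, columns=["contig", "reason"])


# ---------------------------------------------------------------------------
# per-genotype calling
# ---------------------------------------------------------------------------

def call_snps_per_genotype(pileup: pd.DataFrame,
                           reference: dict[str, ReferenceContig],
                           min_reads: int = 3,
                           min_fraction: float = 0.8) -> pd.DataFrame:
    """Evaluate the confidence rule at every covered site of one genotype.

    Returns a frame with columns contig, pos (1-based), ref, alt, alt_count,
    depth, status in {ALT, BELOW_THRESHOLD}; pure-reference sites are not
    returned.  Calling is independent of pileup row order.
    """
    bad = set(pileup.contig.unique()) - set(reference)
    if bad:
        raise ValueError(f"pileup references contigs absent from reference: {sorted(bad)}")
    frames = []
    for cid, grp in pileup.groupby("contig", sort=True):
        seq = reference[cid].seq
        pos0 = grp.pos.to_numpy() - 1
        if pos0.min() < 0 or pos0.max() >= len(seq):
            raise ValueError(f"pileup position outside contig {cid}")
        counts = grp[list(BASES)].to_numpy(dtype=np.int64)
        depth = grp.depth.to_numpy(dtype=np.int64)
        if not np.array_equal(counts.sum(axis=1), depth):
            raise ValueError(f"base counts do not sum to depth in contig {cid}")
        ref_idx = np.frombuffer(seq.encode(), dtype=np.uint8)[pos0]
        lut = np.full(256, -1, dtype=np.int64)
        for j, b in enumerate(BASES):
            lut[ord(b)] = j
        ref_j = lut[ref_idx]
        nonref = counts.copy()
        nonref[np.arange(len(grp)), ref_j] = -1     # mask the reference base
        alt_j = nonref.argmax(axis=1)
        alt_count = counts[np.arange(len(grp)), alt_j]
        # reference base masked, so alt_count==0 only at pure-ref sites
        has_alt = alt_count >= 1
        confident = (alt_count >= min_reads) & (alt_count >= min_fraction * depth)
        keep = has_alt & (depth > 0)
        if not keep.any():
            continue
        frames.append(pd.DataFrame({
            "contig": cid,
            "pos": grp.pos.to_numpy()[keep],
            "ref": np.array(list(BASES))[ref_j[keep]],
            "alt": np.array(list(BASES))[alt_j[keep]],
            "alt_count": alt_count[keep],
            "depth": depth[keep],
            "status": np.where(confident[keep], STATUS_ALT, STATUS_BELOW),
        }))
    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "ref", "alt",
                                     "alt_count", "depth", "status"])
    return pd.concat(frames, ignore_index=True).sort_values(
        ["contig", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# non-redundant merge
# ---------------------------------------------------------------------------

@dataclass
class SNPTable:
    """Non-redundant biallelic substitution records with per-genotype status.

    ``frame`` columns: contig, pos, ref, alt, class (transition/transversion)
    plus one status column per genotype (REF/ALT/MISSING/BELOW_THRESHOLD).
    """

    frame: pd.DataFrame
    genotypes: list[str]
    reference_name: str = "reference"

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_polymorphic_contigs(self) -> int:
        return self.frame.contig.nunique()


def merge_nonredundant(calls: dict[str, pd.DataFrame],
                       pileups: dict[str, pd.DataFrame],
                       reference: dict[str, ReferenceContig],
                       reference_name: str = "reference") -> SNPTable:
    """Merge per-genotype calls into one record per (contig, pos, alt) that
    is confident in at least one genotype.

    Every other genotype is assigned REF (covered, no conflicting evidence),
    MISSING (no reads at the site), or BELOW_THRESHOLD (sub-threshold
    evidence, or a confident call for a *different* alternate base at a
    multi-allelic site, which is logged).
    """
    genotypes = sorted(calls)
    confident = {}
    for g in genotypes:
        df = calls[g]
        for row in df[df.status == STATUS_ALT].itertuples(index=False):
            confident.setdefault((row.contig, row.pos, row.ref, row.alt), set()).add(g)
    multi = {}
    for (cid, pos, ref, alt), gs in confident.items():
        multi.setdefault((cid, pos), set()).add(alt)
    n_multi = sum(1 for alts in multi.values() if len(alts) > 1)
    if n_multi:
        log.warning("%d multi-allelic site(s) split into biallelic records", n_multi)

    # per-genotype lookup structures
    lowconf = {g: set(map(tuple, calls[g][["contig", "pos"]].itertuples(index=False)))
               for g in genotypes}
    alt_at = {g: {(r.contig, r.pos): r.alt
                  for r in calls[g][calls[g].status == STATUS_ALT].itertuples(index=False)}
              for g in genotypes}
    # coverage lookup is only needed at candidate sites
    cand = pd.DataFrame(sorted({(c, p) for (c, p, _, _) in confident}),
                        columns=["contig", "pos"])
    covered = {}
    for g in genotypes:
        hit = pileups[g].loc[pileups[g].depth > 0, ["contig", "pos"]].merge(
            cand, on=["contig", "pos"])
        covered[g] = set(map(tuple, hit.itertuples(index=False)))

    rows = []
    for (cid, pos, ref, alt) in sorted(confident):
        rec = {"contig": cid, "pos": pos, "ref": ref, "alt": alt,
               "class": classify_ts_tv(ref, alt)}
        for g in genotypes:
            if g in confident[(cid, pos, ref, alt)]:
                rec[g] = STATUS_ALT
            elif alt_at[g].get((cid, pos)) not in (None, alt):
                rec[g] = STATUS_BELOW          # confident for a different alt
            elif (cid, pos) in lowconf[g]:
                rec[g] = STATUS_BELOW
            elif (cid, pos) in covered[g]:
                rec[g] = STATUS_REF
            else:
                rec[g] = STATUS_MISSING
        rows.append(rec)
    frame = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "class",
                                        *genotypes])
    return SNPTable(frame, genotypes, reference_name)


def classify_ts_tv(ref: str, alt: str) -> str:
    """A<->G and C<->T are transitions; every other base pair a transversion."""
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"ambiguous or invalid alleles: {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt alleles must differ")
    same_family = ({ref, alt} <= PURINES) or ({ref, alt} <= PYRIMIDINES)
    return "transition" if same_family else "transversion"


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class SNPSummary:
    n_snps: int
    n_transitions: int
    n_transversions: int
    n_polymorphic_contigs: int
    mean_alt_allele_frequency: dict[str, float] = field(default_factory=dict)


def summarize(table: SNPTable, subsets: dict[str, list[str]] | None = None
              ) -> SNPSummary:
    f = table.frame
    n_ts = int((f["class"] == "transition").sum())
    summ = SNPSummary(len(f), n_ts, len(f) - n_ts, table.n_polymorphic_contigs)
    for name, genos in (subsets or {"all": table.genotypes}).items():
        summ.mean_alt_allele_frequency[name] = allele_frequency_summary(table, genos)
    return summ


def allele_frequency_summary(table: SNPTable, genotype_subset: list[str],
                             include_reference: bool = True) -> float:
    """Mean alternate-allele frequency over SNPs, within a genotype subset.

    Per SNP, frequency = (#ALT among subset genotypes with informative
    status) / (#informative genotypes), where informative means REF or ALT;
    the reference genotype counts as one additional REF call when
    ``include_reference`` (default, switchable).  The summary is the
    unweighted mean over SNPs with at least one informative genotype; SNPs
    with none are excluded and counted in the log.
    """
    missing = set(genotype_subset) - set(table.genotypes)
    if not genotype_subset or missing:
        raise ValueError(f"unknown or empty genotype subset: {sorted(missing)}")
    sub = table.frame[list(genotype_subset)]
    n_alt = (sub == STATUS_ALT).sum(axis=1).to_numpy(dtype=float)
    n_inf = ((sub == STATUS_ALT) | (sub == STATUS_REF)).sum(axis=1).to_numpy(dtype=float)
    if include_reference:
        n_inf = n_inf + 1.0
        informative = n_inf > 1.0  # at least one subset genotype informative
    else:
        informative = n_inf > 0.0
    n_excluded = int((~informative).sum())
    if n_excluded:
        log.info("%d SNP(s) with no informative genotype excluded from "
                 "allele-frequency summary", n_excluded)
    if not informative.any():
        return float("nan")
    return float(np.mean(n_alt[informative] / n_inf[informative]))


# ---------------------------------------------------------------------------
# SSR detection
# ---------------------------------------------------------------------------

#: minimum perfect copy number by motif length (configurable; mono-, di-,
#: tri-, and tetra- through hexa-nucleotide motifs)
DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 4, 5: 4, 6: 4}


@dataclass(frozen=True)
class SSR:
    motif: str
    start: int     # 0-based
    end: int       # half-open, full copies only
    copies: int


def _smallest_period(motif: str) -> int:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return p
    return len(motif)


def find_ssrs(seq: str, min_total_len: int = 12,
              min_repeats: dict[int, int] | None = None) -> list[SSR]:
    """Maximal perfect tandem repeats of motif length 1-6.

    A repeat is reported when its complete-copy count reaches the per-motif
    threshold and its total length reaches ``min_total_len``.  Motifs that
    are themselves periodic (e.g. ACAC as a tetramer) are suppressed in
    favour of their primitive period.
    """
    thresholds = dict(DEFAULT_MIN_REPEATS)
    thresholds.update(min_repeats or {})
    seq = seq.upper()
    n = len(seq)
    out = []
    for m in range(1, 7):
        i = 0
        while i + 2 * m <= n:
            if seq[i + m] != seq[i]:
                i += 1
                continue
            j = i + m
            while j < n and seq[j] == seq[j - m]:
                j += 1
            run = j - i
            copies = run // m
            motif = seq[i:i + m]
            if (copies >= thresholds[m] and copies * m >= min_total_len
                    and _smallest_period(motif) == m):
                out.append(SSR(motif, i, i + copies * m, copies))
            i = max(i + 1, j - m + 1)
    return sorted(out, key=lambda s: (s.start, len(s.motif)))


def find_ssrs_in_contigs(contigs: dict[str, str], **kwargs) -> pd.DataFrame:
    rows = [{"contig": cid, "motif": s.motif, "start": s.start + 1,
             "end": s.end, "copies": s.copies}
            for cid, seq in contigs.items() for s in find_ssrs(seq, **kwargs)]
    return pd.DataFrame(rows, columns=["contig", "motif", "start", "end", "copies"])


# ---------------------------------------------------------------------------
# VCF emission
# ---------------------------------------------------------------------------

def write_vcf(table: SNPTable, reference: dict[str, ReferenceContig], path) -> None:
    """Write the merged table as VCF v4.2 with per-sample GT and an FT field
    (PASS / LOWCONF / MISSING)."""
    ft_of = {STATUS_REF: "PASS", STATUS_ALT: "PASS",
             STATUS_BELOW: "LOWCONF", STATUS_MISSING: "MISSING"}
    gt_of = {STATUS_REF: "0", STATUS_ALT: "1",
             STATUS_BELOW: ".", STATUS_MISSING: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lenspipe\n")
        for cid in sorted({c for c in table.frame.contig.unique()}):
            fh.write(f"##contig=<ID={cid},length={reference[cid].length}>\n")
        fh.write('##INFO=<ID=TSTV,Number=1,Type=String,'
                 'Description="transition or transversion">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=FT,Number=1,Type=String,'
                 'Description="PASS, LOWCONF (below thresholds) or MISSING">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.genotypes) + "\n")
        for r in table.frame.to_dict("records"):
            samples = [f"{gt_of[r[g]]}:{ft_of[r[g]]}" for g in table.genotypes]
            fh.write(f"{r['contig']}\t{r['pos']}\t{r['contig']}p{r['pos']}\t"
                     f"{r['ref']}\t{r['alt']}\t.\tPASS\tTSTV={r['class']}\t"
                     "GT:FT\t" + "\t".join(samples) + "\n")
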