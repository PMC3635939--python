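"""Anchor contigs to model gene structures; classify SNPs by region and
codon impact.

A contig's anchor carries its gene structure in contig coordinates (exon
intervals, a CDS interval of complete sense codons, strand).  An exonic SNP
is classified by the codon it changes: SYNONYMOUS, non-synonymous with the
same or a different amino-acid property group, or STOP_GAIN (which
overrides the property classes).  Property groups default to acidic {D,E},
basic {H,K,R}, polar-uncharged {C,N,Q,S,T,Y} and nonpolar
{A,F,G,I,L,M,P,V,W}, and are configuration, not constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._util import BASES, revcomp

log = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

REGION_CDS = "CDS"
REGION_UTR3 = "UTR3"
REGION_UNASSIGNED = "UNASSIGNED"

IMPACT_SYN = "SYNONYMOUS"
IMPACT_SAME = "NONSYN_SAME_PROP"
IMPACT_DIFF = "NONSYN_DIFF_PROP"
IMPACT_STOP = "STOP_GAIN"
IMPACT_NA = "NA"

DEFAULT_PROPERTY_GROUPS = {
    "acidic": "DE",
    "basic": "KRH",
    "polar_uncharged": "STNQCY",
    "nonpolar": "AVLIMFWGP",
}


def property_of(aa: str, groups: dict[str, str] | None = None) -> str:
    groups = groups or DEFAULT_PROPERTY_GROUPS
    for name, members in groups.items():
        if aa in members:
            return name
    raise ValueError(f"amino acid {aa!r} not in any property group")


def load_property_groups(path) -> dict[str, str]:
    """Read property groups from a YAML mapping of group name -> residues."""
    import yaml
    with open(path) as fh:
        groups = yaml.safe_load(fh)
    seen = "".join(groups.values())
    if len(set(seen)) != len(seen):
        raise ValueError("property groups overlap")
    return {k: str(v) for k, v in groups.items()}


def translate(codon: str) -> str:
    """Single-codon translation; '*' for stop."""
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

@dataclass
class GeneAnchor:
    """Best mapping of a contig onto a model gene, in contig coordinates
    (0-based half-open intervals)."""

    contig: str
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None
    utr3: tuple[int, int] | None = None
    model_chrom: str | None = None
    model_pos: int | None = None
    align_len: int = 0
    identity: float = 1.0

    def __post_init__(self):
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exon intervals on {self.contig}")
        if self.cds is not None and (self.cds[1] - self.cds[0]) % 3 != 0:
            raise ValueError(f"CDS length not divisible by 3 on {self.contig}")

    @property
    def splice_sites(self) -> list[int]:
        return [e for _, e in self.exons[:-1]]

    @property
    def frame_known(self) -> bool:
        return self.cds is not None


def anchors_from_reference(ref) -> dict[str, GeneAnchor]:
    """Truth anchors straight from a simulated ReferenceSet."""
    by_contig = ref.anchors.set_index("contig")
    out = {}
    for cid, m in ref.models.items():
        row = by_contig.loc[cid]
        out[cid] = GeneAnchor(cid, m.gene_id, m.strand, list(m.exons), m.cds,
                              m.utr3, model_chrom=row.model_chrom,
                              model_pos=int(row.model_pos),
                              align_len=int(row.align_len),
                              identity=float(row.identity))
    return out


def anchors_from_gff3(path, anchors_tsv=None) -> dict[str, GeneAnchor]:
    """Parse anchors from a GFF3 of gene/exon/CDS/three_prime_UTR features
    keyed by contig; optionally join model-genome coordinates from an
    anchors TSV.  Malformed lines raise with their line number."""
    feats: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, "
                                 f"got {len(parts)}")
            seqid, _, ftype, start, end, _, strand, _, attrs = parts
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
            if s < 0 or e < s:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            d = feats.setdefault(seqid, {"strand": strand, "exons": [],
                                         "cds": [], "utr3": [], "gene_id": None})
            if ftype == "gene":
                d["gene_id"] = attr.get("ID")
                d["strand"] = strand
            elif ftype == "exon":
                d["exons"].append((s, e))
            elif ftype == "CDS":
                d["cds"].append((s, e))
            elif ftype == "three_prime_UTR":
                d["utr3"].append((s, e))
    coords = {}
    if anchors_tsv is not None:
        at = pd.read_csv(anchors_tsv, sep="\t")
        coords = {r.contig: r for r in at.itertuples(index=False)}
    out = {}
    for cid, d in feats.items():
        cds = (min(s for s, _ in d["cds"]), max(e for _, e in d["cds"])) if d["cds"] else None
        utr3 = ((min(s for s, _ in d["utr3"]), max(e for _, e in d["utr3"]))
                if d["utr3"] else None)
        extra = coords.get(cid)
        out[cid] = GeneAnchor(
            cid, d["gene_id"] or cid, d["strand"], d["exons"] or [(0, 0)],
            cds, utr3,
            model_chrom=getattr(extra, "model_chrom", None),
            model_pos=int(extra.model_pos) if extra is not None else None,
            align_len=int(getattr(extra, "align_len", 0) or 0),
            identity=float(getattr(extra, "identity", 1.0) or 1.0))
    return out


# ---------------------------------------------------------------------------
# built-in exact-seed anchorer (adequate for synthetic contigs)
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    """A model gene: sense mRNA sequence plus structure in mRNA coordinates."""
    gene_id: str
    mrna: str
    cds: tuple[int, int]
    exons: list[tuple[int, int]]
    utr3: tuple[int, int] | None = None
    model_chrom: str | None = None
    model_pos: int | None = None


def anchor_contigs(contigs: dict[str, str], genes: list[GeneRecord],
                   k: int = 25, min_identity: float = 0.9,
                   min_overlap: int = 100
                   ) -> tuple[dict[str, GeneAnchor], list[str]]:
    """Anchor contigs onto model genes by exact k-mer seeding and ungapped
    extension; at most one anchor per contig, best by aligned length x
    identity.  Returns (anchors, unanchored contig ids)."""
    index: dict[str, list[tuple[int, int]]] = {}
    for gi, g in enumerate(genes):
        for i in range(0, len(g.mrna) - k + 1, max(1, k // 2)):
            index.setdefault(g.mrna[i:i + k], []).append((gi, i))
    anchors, unanchored = {}, []
    for cid in sorted(contigs):
        best = None
        for strand in "+-":
            q = contigs[cid] if strand == "+" else revcomp(contigs[cid])
            offsets = set()
            for i in range(0, len(q) - k + 1, max(1, k // 2)):
                for gi, gpos in index.get(q[i:i + k], ()):
                    offsets.add((gi, i - gpos))     # query pos of gene origin
            for gi, off in offsets:
                g = genes[gi]
                qs, gs = max(0, off), max(0, -off)
                n = min(len(q) - qs, len(g.mrna) - gs)
                if n < min_overlap:
                    continue
                a = np.frombuffer(q[qs:qs + n].encode(), dtype=np.uint8)
                b = np.frombuffer(g.mrna[gs:gs + n].encode(), dtype=np.uint8)
                ident = float((a == b).mean())
                if ident < min_identity:
                    continue
                score = n * ident
                if best is None or score > best[0]:
                    best = (score, strand, gi, off, n, ident)
        if best is None:
            unanchored.append(cid)
            continue
        _, strand, gi, off, n, ident = best
        g = genes[gi]
        L = len(contigs[cid])

        def to_contig(iv):
            """Map a gene-mRNA interval into stored-contig coordinates."""
            s, e = iv[0] + off, iv[1] + off
            s, e = max(0, s), min(L, e)
            if e <= s:
                return None
            return (s, e) if strand == "+" else (L - e, L - s)

        cds = to_contig(g.cds)
        if cds is not None:
            # trim the mapped CDS to a whole-codon window in reading frame
            s, e = g.cds
            s2, e2 = max(s, -off), min(e, L - off)
            s2 += (3 - (s2 - s) % 3) % 3
            e2 -= (e2 - s) % 3
            cds = to_contig((s2, e2)) if e2 - s2 >= 3 else None
        exons = [iv for iv in (to_contig(x) for x in g.exons) if iv]
        utr3 = to_contig(g.utr3) if g.utr3 else None
        anchors[cid] = GeneAnchor(cid, g.gene_id, strand, exons or [(0, L)],
                                  cds, utr3, model_chrom=g.model_chrom,
                                  model_pos=g.model_pos, align_len=n,
                                  identity=round(ident, 4))
    return anchors, unanchored


def gene_db_from_reference(ref) -> list[GeneRecord]:
    """Model-gene records (sense mRNA + structure) from a ReferenceSet; for
    '-' strand contigs the structure is flipped into mRNA coordinates."""
    by_contig = ref.anchors.set_index("contig")
    out = []
    for cid, m in ref.models.items():
        L = m.length

        def to_mrna(iv):
            return iv if m.strand == "+" else (L - iv[1], L - iv[0])

        row = by_contig.loc[cid]
        out.append(GeneRecord(m.gene_id, ref.mrna(cid), to_mrna(m.cds),
                              sorted(to_mrna(x) for x in m.exons),
                              to_mrna(m.utr3), row.model_chrom,
                              int(row.model_pos)))
    return out


# ---------------------------------------------------------------------------
# SNP classification
# ---------------------------------------------------------------------------

def classify_region(pos: int, anchor: GeneAnchor | None) -> str:
    """Region of a 1-based contig position: CDS, UTR3 or UNASSIGNED."""
    if anchor is None:
        return REGION_UNASSIGNED
    p = pos - 1
    if anchor.cds is not None and anchor.cds[0] <= p < anchor.cds[1]:
        return REGION_CDS
    if anchor.utr3 is not None and anchor.utr3[0] <= p < anchor.utr3[1]:
        return REGION_UTR3
    return REGION_UNASSIGNED


@dataclass
class CodonImpact:
    region: str
    impact: str
    codon_ref: str | None = None
    codon_alt: str | None = None
    codon_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None


def codon_impact(contig_seq: str, pos: int, ref: str, alt: str,
                 anchor: GeneAnchor | None,
                 property_groups: dict[str, str] | None = None) -> CodonImpact:
    """Classify the codon impact of a substitution at 1-based ``pos``.

    Strand-aware: for '-' anchors the codon is read off the reverse
    complement.  STOP_GAIN overrides the property classes; codons containing
    N, or reference stop codons, yield impact NA (logged).
    """
    region = classify_region(pos, anchor)
    if region != REGION_CDS or not anchor.frame_known:
        return CodonImpact(region, IMPACT_NA)
    p = pos - 1
    s, e = anchor.cds
    if contig_seq[p] != ref:
        raise ValueError(f"reference allele mismatch at {anchor.contig}:{pos}")
    if anchor.strand == "+":
        off = p - s
        cds = contig_seq[s:e]
        a_ref, a_alt = ref, alt
    else:
        off = (e - 1) - p
        cds = revcomp(contig_seq[s:e])
        a_ref, a_alt = revcomp(ref), revcomp(alt)
    ci, cp = divmod(off, 3)
    codon_ref = cds[3 * ci:3 * ci + 3]
    codon_alt = codon_ref[:cp] + a_alt + codon_ref[cp + 1:]
    if any(b not in BASES for b in codon_ref + codon_alt):
        log.info("codon with ambiguous base at %s:%d -> impact NA",
                 anchor.contig, pos)
        return CodonImpact(region, IMPACT_NA, codon_ref, codon_alt, cp)
    aa_ref, aa_alt = translate(codon_ref), translate(codon_alt)
    if aa_ref == "*":
        log.info("reference stop codon at %s:%d -> impact NA", anchor.contig, pos)
        impact = IMPACT_NA
    elif aa_alt == "*":
        impact = IMPACT_STOP
    elif aa_ref == aa_alt:
        impact = IMPACT_SYN
    elif property_of(aa_ref, property_groups) == property_of(aa_alt, property_groups):
        impact = IMPACT_SAME
    else:
        impact = IMPACT_DIFF
    return CodonImpact(region, impact, codon_ref, codon_alt, cp, aa_ref, aa_alt)


def annotate_table(table, contigs: dict[str, str],
                   anchors: dict[str, GeneAnchor],
                   property_groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Annotate a merged SNP table: adds region, impact, codon and amino-acid
    columns.  ``contigs`` maps contig id -> sequence."""
    rows = []
    for r in table.frame.itertuples(index=False):
        anchor = anchors.get(r.contig)
        imp = codon_impact(contigs[r.contig], r.pos, r.ref, r.alt, anchor,
                           property_groups) if anchor else CodonImpact(
                               REGION_UNASSIGNED, IMPACT_NA)
        rows.append({"region": imp.region, "impact": imp.impact,
                     "codon_ref": imp.codon_ref, "codon_alt": imp.codon_alt,
                     "aa_ref": imp.aa_ref, "aa_alt": imp.aa_alt})
    ann = pd.concat([table.frame.reset_index(drop=True), pd.DataFrame(rows)],
                    axis=1)
    return ann


def class_counts(annotated: pd.DataFrame) -> pd.Series:
    """Counts of region and impact classes over an annotated SNP table."""
    out = {f"region_{k}": int(v) for k, v in annotated.region.value_counts().items()}
    out.update({f"impact_{k}": int(v) for k, v in annotated.impact.value_counts().items()})
    return pd.Series(out).sort_index()
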