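"""Fixed-content genotyping-array candidate selection and KASP flanks.

Selection pipeline for a GoldenGate-style oligo pool: keep SNPs polymorphic
between at least two cultivated genotypes and the reference, require 60 bp
of clean flank on each side (to the contig end, the nearest other SNP and
the nearest splice site; exactly 60 bp passes), drop externally-scored
candidates at design score <= 0.4 preferring > 0.6, reduce to one SNP per
contig haplotype (and per duplicated contig pair), and thin to the target
panel size by greedy farthest-point selection on model-genome coordinates.
All steps are deterministic given the input, with lexicographic SNP-id
tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snpdiscover import SNPTable, STATUS_ALT

log = logging.getLogger(__name__)


def snp_id(contig: str, pos: int) -> str:
    return f"{contig}p{pos}"


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def polymorphism_filter(table: SNPTable, cultivated: list[str],
                        reference_name: str | None = None) -> pd.DataFrame:
    """Keep SNPs with a confident ALT call in >= 2 cultivated genotypes
    (i.e. polymorphic between at least two cultivated lines and the
    reference, which carries REF by construction)."""
    ref = reference_name or table.reference_name
    if ref in cultivated:
        raise ValueError("the reference genotype is the comparison baseline; "
                         "list only the non-reference cultivated genotypes")
    missing = set(cultivated) - set(table.genotypes)
    if missing:
        raise ValueError(f"unknown cultivated genotype(s): {sorted(missing)}")
    n_alt = (table.frame[list(cultivated)] == STATUS_ALT).sum(axis=1)
    return table.frame[n_alt >= 2].reset_index(drop=True)


@dataclass
class FlankCheck:
    passed: bool
    left: int
    right: int
    reason: str | None = None


def flank_filter(pos: int, contig_len: int, other_snp_positions,
                 splice_sites=(), min_flank: int = 60) -> FlankCheck:
    """Check the clean-flank rule for a SNP at 1-based ``pos``.

    The left/right flank is the distance in bp (exclusive of the SNP base)
    to the nearest of: the contig end, another recorded SNP, or a splice
    site.  The candidate fails iff either flank is < ``min_flank``
    (exactly ``min_flank`` passes).  Splice sites are 0-based boundaries
    between adjacent bases.
    """
    left = pos - 1
    right = contig_len - pos
    for q in other_snp_positions:
        if q == pos:
            continue
        if q < pos:
            left = min(left, pos - q - 1)
        else:
            right = min(right, q - pos - 1)
    for b in splice_sites:
        # boundary b sits between 1-based positions b and b+1
        if b >= pos:
            right = min(right, b - pos)
        else:
            left = min(left, pos - 1 - b)
    if left < min_flank:
        return FlankCheck(False, left, right, "left")
    if right < min_flank:
        return FlankCheck(False, left, right, "right")
    return FlankCheck(True, left, right)


def haplotype_id(statuses) -> str:
    """A contig-local haplotype label: the per-genotype status vector."""
    return "|".join(statuses)


# ---------------------------------------------------------------------------
# candidate assembly + final selection
# ---------------------------------------------------------------------------

def build_candidates(table: SNPTable, cultivated: list[str],
                     contig_lengths: dict[str, int],
                     splice_sites: dict[str, list[int]] | None = None,
                     scores: dict[str, float] | None = None,
                     anchors: pd.DataFrame | None = None,
                     duplicate_of: dict[str, str] | None = None,
                     min_flank: int = 60) -> pd.DataFrame:
    """Run the polymorphism and flank filters and assemble the candidate
    frame consumed by :func:`select_final`.

    ``scores`` maps SNP id -> external design score in [0, 1] (optional,
    never computed here); ``anchors`` supplies model_chrom/model_pos per
    contig for the even-spread step.
    """
    surviving = polymorphism_filter(table, cultivated)
    splice_sites = splice_sites or {}
    snp_positions = table.frame.groupby("contig")["pos"].apply(list).to_dict()
    anchor_map = {}
    if anchors is not None:
        anchor_map = anchors.drop_duplicates("contig").set_index("contig")[
            ["model_chrom", "model_pos"]].to_dict("index")
    dup = duplicate_of or {}
    rows = []
    for r in surviving.itertuples(index=False):
        sid = snp_id(r.contig, r.pos)
        chk = flank_filter(r.pos, contig_lengths[r.contig],
                           snp_positions.get(r.contig, ()),
                           splice_sites.get(r.contig, ()), min_flank)
        anch = anchor_map.get(r.contig, {})
        rows.append({
            "snp_id": sid, "contig": r.contig, "pos": r.pos,
            "ref": r.ref, "alt": r.alt,
            "contig_group": dup.get(r.contig, r.contig),
            "haplotype_id": haplotype_id([getattr(r, g) for g in cultivated]),
            "left_flank": chk.left, "right_flank": chk.right,
            "flank_pass": chk.passed, "flank_fail_side": chk.reason,
            "design_score": (scores or {}).get(sid, np.nan),
            "model_chrom": anch.get("model_chrom"),
            "model_pos": anch.get("model_pos"),
        })
    return pd.DataFrame(rows)


def select_final(candidates: pd.DataFrame, n_target: int = 1536) -> pd.DataFrame:
    """Reduce flank-passing candidates to the final panel.

    Score rule: candidates with an external design score <= 0.4 are
    excluded; scores > 0.6 are preferred (unscored candidates rank between).
    One SNP per (contig group, haplotype) is kept — duplicated contigs share
    a group — then greedy farthest-point thinning on model-genome
    coordinates reaches ``n_target``.  Deterministic: ties break on
    lexicographic SNP id.
    """
    df = candidates[candidates.flank_pass].copy()
    scored = df.design_score.notna()
    df = df[~scored | (df.design_score > 0.4)]
    # preference tiers: >0.6 scored, unscored, remaining scored (0.4, 0.6]
    tier = np.where(df.design_score > 0.6, 0, np.where(df.design_score.isna(), 1, 2))
    df = df.assign(_tier=tier).sort_values(
        ["_tier", "snp_id"]).drop_duplicates(["contig_group", "haplotype_id"])
    df = df.drop(columns="_tier").sort_values("snp_id").reset_index(drop=True)
    if len(df) <= n_target:
        if len(df) < n_target:
            log.warning("only %d candidates for a target of %d; returning all",
                        len(df), n_target)
        return df
    return _farthest_point_thin(df, n_target)


def _farthest_point_thin(df: pd.DataFrame, n_target: int) -> pd.DataFrame:
    """Greedy even-spread subset on (model_chrom, model_pos); candidates
    without an anchor are appended last, in id order, if slots remain."""
    anchored = df[df.model_pos.notna()].reset_index(drop=True)
    floating = df[df.model_pos.isna()]
    chosen: list[int] = []
    in_set = np.zeros(len(anchored), dtype=bool)
    nearest = np.full(len(anchored), np.inf)
    chrom = anchored.model_chrom.to_numpy()
    pos = anchored.model_pos.to_numpy(dtype=float)
    ids = anchored.snp_id.to_numpy()
    while len(chosen) < min(n_target, len(anchored)):
        # pick the candidate farthest from the chosen set; chromosomes with
        # nothing chosen yet rank first (infinite distance), ties resolve to
        # the lexicographically smallest id
        avail = np.where(~in_set)[0]
        m = nearest[avail].max()
        tied = avail[nearest[avail] == m]
        best = int(min(tied, key=lambda i: ids[i]))
        chosen.append(best)
        in_set[best] = True
        same = chrom == chrom[best]
        d = np.where(same, np.abs(pos - pos[best]), np.inf)
        nearest = np.minimum(nearest, d)
    out = anchored.iloc[sorted(chosen)]
    if len(out) < n_target and len(floating):
        out = pd.concat([out, floating.sort_values("snp_id")
                         .head(n_target - len(out))])
    return out.sort_values("snp_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# KASP flanks
# ---------------------------------------------------------------------------

@dataclass
class KaspFlanks:
    snp_id: str
    text: str                  # LEFT[REF/ALT]RIGHT
    truncated_left: bool
    truncated_right: bool


def kasp_flanks(contig_seq: str, pos: int, ref: str, alt: str,
                window: int = 60, sid: str | None = None) -> KaspFlanks:
    """Flanking-sequence submission string ``LEFT[REF/ALT]RIGHT`` with
    ``window`` bp each side, truncated (and flagged) at contig ends."""
    p = pos - 1
    if not (0 <= p < len(contig_seq)):
        raise ValueError("SNP position outside contig")
    if contig_seq[p] != ref:
        raise ValueError(f"reference allele mismatch at pos {pos}")
    left = contig_seq[max(0, p - window):p]
    right = contig_seq[p + 1:p + 1 + window]
    return KaspFlanks(sid or snp_id("snp", pos),
                      f"{left}[{ref}/{alt}]{right}",
                      truncated_left=len(left) < window,
                      truncated_right=len(right) < window)


def parse_kasp_flanks(text: str) -> tuple[int, str, str]:
    """Invert :func:`kasp_flanks`: returns (pos within the emitted string's
    local coordinates, ref, alt).  The local 1-based position of the SNP is
    len(LEFT) + 1."""
    lb, rb = text.index("["), text.index("]")
    ref, alt = text[lb + 1:rb].split("/")
    return lb + 1, ref, alt


def write_panel(panel: pd.DataFrame, contigs: dict[str, str], path,
                window: int = 60) -> None:
    """Panel TSV with the KASP flank string per selected SNP."""
    panel = panel.copy()
    panel["kasp"] = [kasp_flanks(contigs[r.contig], r.pos, r.ref, r.alt,
                                 window, r.snp_id).text
                     for r in panel.itertuples(index=False)]
    panel.to_csv(path, sep="\t", index=False)
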