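"""Synteny chaining between linkage groups and a model genome.

Anchors (marker, linkage group, cM, model chromosome, model position,
aligned length, identity) are filtered per lg x chromosome pair by a
weighted longest-increasing-subset: the maximum total align_len x identity
subset whose model positions are strictly monotonic along the linkage
group, increasing (forward) or decreasing (inverted).  Chains of at least
``min_block`` anchors become synteny blocks; a linkage group whose blocks
span two or more model chromosomes is flagged as a translocation, and a
block running against its pair's dominant orientation as an inversion.
(A pair whose only block is inverted is not flagged: a genetic map has no
intrinsic orientation.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANCHOR_COLUMNS = ["marker", "lg", "cm", "model_chrom", "model_pos",
                  "align_len", "identity"]


def validate_anchors(anchors: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANCHOR_COLUMNS) - set(anchors.columns)
    if missing:
        raise ValueError(f"anchor table lacks columns: {sorted(missing)}")
    if (anchors.align_len <= 0).any() or ((anchors.identity <= 0)
                                          | (anchors.identity > 1)).any():
        raise ValueError("require align_len > 0 and identity in (0, 1]")
    return anchors


def anchor_weights(anchors: pd.DataFrame) -> np.ndarray:
    return (anchors.align_len * anchors.identity).to_numpy(dtype=float)


def weighted_lis(anchors: pd.DataFrame, orientation: str = "forward"
                 ) -> list[int]:
    """Maximum-weight subset with strictly monotonic model positions.

    ``anchors`` must be sorted by cM; returns positional indices of the
    retained chain, in cM order.  Dynamic programme over anchors with
    deterministic tie-breaks preferring the earliest-cM predecessor and
    chain end.
    """
    if orientation not in ("forward", "inverted"):
        raise ValueError("orientation must be 'forward' or 'inverted'")
    n = len(anchors)
    if n == 0:
        return []
    pos = anchors.model_pos.to_numpy(dtype=float)
    if orientation == "inverted":
        pos = -pos
    w = anchor_weights(anchors)
    best = w.copy()              # best chain weight ending at i
    parent = np.full(n, -1, dtype=int)
    for i in range(1, n):
        for j in range(i):
            if pos[j] < pos[i] and best[j] + w[i] > best[i]:
                best[i] = best[j] + w[i]
                parent[i] = j
    end = int(np.argmax(best))   # argmax takes the earliest tie
    chain = []
    while end != -1:
        chain.append(end)
        end = parent[end]
    return chain[::-1]


@dataclass
class SyntenyBlock:
    block_id: str
    lg: str
    model_chrom: str
    orientation: str                       # forward | inverted
    anchors: pd.DataFrame = field(repr=False)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def weight(self) -> float:
        return float(anchor_weights(self.anchors).sum())

    @property
    def cm_span(self) -> tuple[float, float]:
        return float(self.anchors.cm.min()), float(self.anchors.cm.max())

    @property
    def model_span(self) -> tuple[int, int]:
        return int(self.anchors.model_pos.min()), int(self.anchors.model_pos.max())


def _extract_chains(sub: pd.DataFrame, min_block: int) -> list[tuple[str, pd.DataFrame]]:
    """Iteratively peel maximal-weight monotonic chains off one lg x chrom
    anchor set until fewer than ``min_block`` anchors chain together."""
    chains = []
    remaining = sub.sort_values(["cm", "model_pos"]).reset_index(drop=True)
    while len(remaining) >= min_block:
        fwd = weighted_lis(remaining, "forward")
        inv = weighted_lis(remaining, "inverted")
        w = anchor_weights(remaining)
        wf, wi = w[fwd].sum(), w[inv].sum()
        take, orientation = (fwd, "forward") if wf >= wi else (inv, "inverted")
        if len(take) < min_block:
            break
        chains.append((orientation, remaining.iloc[take].copy()))
        remaining = remaining.drop(remaining.index[take]).reset_index(drop=True)
    return chains


@dataclass
class SyntenyResult:
    blocks: list[SyntenyBlock]
    dotplot: pd.DataFrame
    inversions: pd.DataFrame      # lg, model_chrom, block_id, n_anchors
    translocations: pd.DataFrame  # lg, chroms


def call_blocks(anchors: pd.DataFrame, min_block: int = 3) -> SyntenyResult:
    """Chain anchors into synteny blocks and call rearrangements."""
    anchors = validate_anchors(anchors)
    blocks: list[SyntenyBlock] = []
    dot_rows = []
    for (lg, chrom), sub in anchors.groupby(["lg", "model_chrom"], sort=True):
        chains = _extract_chains(sub, min_block)
        for ci, (orientation, chain) in enumerate(chains, 1):
            bid = f"{lg}:{chrom}:{ci}"
            blocks.append(SyntenyBlock(bid, lg, chrom, orientation, chain))
            dot_rows.append(chain.assign(block_id=bid, orientation=orientation))
    retained = pd.concat(dot_rows, ignore_index=True) if dot_rows else \
        pd.DataFrame(columns=[*ANCHOR_COLUMNS, "block_id", "orientation"])
    dropped = anchors[~anchors.marker.isin(retained.marker)].copy()
    dropped["block_id"], dropped["orientation"] = "", ""
    dotplot = pd.concat([retained, dropped], ignore_index=True).sort_values(
        ["lg", "cm"]).reset_index(drop=True)

    inv_rows = []
    for (lg, chrom), pair_blocks in _groupby_pair(blocks):
        dominant = max(pair_blocks, key=lambda b: b.weight)
        for b in pair_blocks:
            if b.orientation != dominant.orientation:
                inv_rows.append({"lg": lg, "model_chrom": chrom,
                                 "block_id": b.block_id,
                                 "n_anchors": b.n_anchors})
    tr_rows = []
    for lg in sorted({b.lg for b in blocks}):
        chroms = sorted({b.model_chrom for b in blocks
                         if b.lg == lg and b.n_anchors >= min_block})
        if len(chroms) >= 2:
            tr_rows.append({"lg": lg, "chroms": ",".join(chroms)})
    return SyntenyResult(
        blocks, dotplot,
        pd.DataFrame(inv_rows, columns=["lg", "model_chrom", "block_id", "n_anchors"]),
        pd.DataFrame(tr_rows, columns=["lg", "chroms"]))


def _groupby_pair(blocks):
    pairs: dict[tuple[str, str], list[SyntenyBlock]] = {}
    for b in blocks:
        pairs.setdefault((b.lg, b.model_chrom), []).append(b)
    return sorted(pairs.items())


def blocks_frame(result: SyntenyResult) -> pd.DataFrame:
    rows = []
    for b in result.blocks:
        cm0, cm1 = b.cm_span
        m0, m1 = b.model_span
        rows.append({"block_id": b.block_id, "lg": b.lg,
                     "model_chrom": b.model_chrom, "orientation": b.orientation,
                     "n_anchors": b.n_anchors, "weight": round(b.weight, 2),
                     "cm_start": cm0, "cm_end": cm1,
                     "model_start": m0, "model_end": m1})
    return pd.DataFrame(rows, columns=["block_id", "lg", "model_chrom",
                                       "orientation", "n_anchors", "weight",
                                       "cm_start", "cm_end", "model_start",
                                       "model_end"])


def read_anchors(path) -> pd.DataFrame:
    return validate_anchors(pd.read_csv(path, sep="\t"))
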