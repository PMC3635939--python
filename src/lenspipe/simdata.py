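"""Synthetic 3'-cDNA diversity-panel generator.

Every input the downstream stages consume — reference contigs with gene
structure, per-genotype haplotypes, base-count pileups, recombinant-inbred
genotype matrices, model-genome anchors and diverged ortholog CDS pairs —
can be generated here with full ground truth, so SNP calling, codon-impact
annotation, Ks dating, array design, linkage mapping and synteny chaining
are all testable without any external data.

The default panel emulates a 3'-transcriptome SNP-discovery study design:
one reference genotype plus eight cultivated and two wild accessions, with
the wild accessions several-fold more diverged from the reference than the
cultivated ones; a transition-biased substitution process; Poisson per-site
read depths in the 8-31x range; and an F8 recombinant-inbred population of
~147 lines segregating on seven linkage groups.

All randomness flows from explicit integer seeds; repeated runs with the
same spec are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._util import BASES, TRANSITION_PARTNER, revcomp, rng_from

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS = sorted(_STANDARD.forward_table)
STOP_CODONS = sorted(_STANDARD.stop_codons)


class ParameterError(ValueError):
    """Raised when a simulation spec violates its invariants."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSpec:
    """Composition and divergence structure of the genotype panel."""

    n_cultivated: int = 8
    n_wild: int = 2
    theta_cultivated: float = 0.002
    theta_wild: float = 0.01
    ts_tv_ratio: float = 1.5
    shared_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_cultivated < 0 or self.n_wild < 0:
            raise ParameterError("panel sizes must be non-negative")
        if not (self.theta_wild > self.theta_cultivated >= 0):
            raise ParameterError("require theta_wild > theta_cultivated >= 0")
        if self.ts_tv_ratio <= 0:
            raise ParameterError("ts_tv_ratio must be positive")
        if not (0.0 <= self.shared_fraction < 1.0):
            raise ParameterError("shared_fraction must be in [0, 1)")

    @property
    def cultivated_names(self) -> list[str]:
        return [f"cult{i + 1:02d}" for i in range(self.n_cultivated)]

    @property
    def wild_names(self) -> list[str]:
        return [f"wild{i + 1:02d}" for i in range(self.n_wild)]

    @property
    def genotype_names(self) -> list[str]:
        return self.cultivated_names + self.wild_names


@dataclass(frozen=True)
class ContigSpec:
    """Reference contig set: sizes, gene structure, repeats, duplicates."""

    n_contigs: int = 100
    length_mean: int = 600
    utr3_fraction: float = 0.3
    ssr_rate: float = 0.05
    dup_rate: float = 0.01
    n_model_chroms: int = 8
    n_inversions: int = 0
    n_translocations: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_contigs < 1:
            raise ParameterError("n_contigs must be >= 1")
        if self.length_mean < 200:
            raise ParameterError("length_mean must be >= 200")
        for name in ("utr3_fraction", "ssr_rate", "dup_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.n_model_chroms < 1:
            raise ParameterError("n_model_chroms must be >= 1")


@dataclass(frozen=True)
class RILSpec:
    """An F(1+g) recombinant-inbred population design."""

    n_lg: int = 7
    markers_per_lg: int = 70
    lg_length_cM: float = 120.0
    n_ril: int = 147
    selfing_generations: int = 7
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_lg < 1:
            raise ParameterError("n_lg must be >= 1")
        if self.lg_length_cM <= 0:
            raise ParameterError("lg_length_cM must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ParameterError("missing_rate must be in [0, 1)")
        if self.markers_per_lg < 1 or self.n_ril < 1:
            raise ParameterError("markers_per_lg and n_ril must be >= 1")
        if self.selfing_generations < 0:
            raise ParameterError("selfing_generations must be >= 0")


# ---------------------------------------------------------------------------
# reference contigs
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Truth gene structure of one contig, in contig coordinates (0-based,
    half-open).  The CDS interval covers complete sense codons only; the
    terminal stop codon is folded into the 3'-UTR feature."""

    contig: str
    gene_id: str
    strand: str                      # '+' or '-'
    length: int
    exons: list[tuple[int, int]]
    cds: tuple[int, int]
    utr3: tuple[int, int]

    @property
    def splice_sites(self) -> list[int]:
        """Exon-junction boundaries (0-based, between pos-1 and pos)."""
        return [e for _, e in self.exons[:-1]]


@dataclass
class ReferenceSet:
    """A synthetic reference assembly plus all planted truth."""

    spec: ContigSpec
    contigs: dict[str, str]
    models: dict[str, GeneModel]
    ssrs: pd.DataFrame                # contig, motif, start, end, copies (0-based half-open)
    duplicates: list[tuple[str, str]]
    anchors: pd.DataFrame             # contig, lg, cm, model_chrom, model_pos, strand, align_len, identity
    rearrangements: pd.DataFrame      # kind, lg, model_chrom, contigs

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def mrna(self, contig_id: str) -> str:
        """Sense-strand transcript sequence of a contig."""
        seq = self.contigs[contig_id]
        return seq if self.models[contig_id].strand == "+" else revcomp(seq)

    # -- emission -----------------------------------------------------------
    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for cid, seq in self.contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for cid, m in self.models.items():
                def row(ftype, s, e, attrs):
                    fh.write("\t".join([cid, "lenspipe_sim", ftype, str(s + 1),
                                        str(e), ".", m.strand, ".", attrs]) + "\n")
                row("gene", 0, m.length, f"ID={m.gene_id}")
                for i, (s, e) in enumerate(m.exons, 1):
                    row("exon", s, e, f"ID={m.gene_id}.exon{i};Parent={m.gene_id}")
                row("CDS", m.cds[0], m.cds[1], f"ID={m.gene_id}.cds;Parent={m.gene_id}")
                row("three_prime_UTR", m.utr3[0], m.utr3[1],
                    f"ID={m.gene_id}.utr3;Parent={m.gene_id}")

    def write_anchors(self, path) -> None:
        cols = ["contig", "model_chrom", "model_pos", "strand", "align_len", "identity"]
        self.anchors[cols].to_csv(path, sep="\t", index=False)

    def write_truth(self, directory) -> None:
        d = Path(directory)
        self.ssrs.to_csv(d / "truth_ssrs.tsv", sep="\t", index=False)
        self.anchors.to_csv(d / "truth_anchors.tsv", sep="\t", index=False)
        self.rearrangements.to_csv(d / "truth_rearrangements.tsv", sep="\t", index=False)
        pd.DataFrame(self.duplicates, columns=["contig", "duplicate"]).to_csv(
            d / "truth_duplicates.tsv", sep="\t", index=False)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list(BASES))[rng.integers(0, 4, n)])


_SSR_MOTIFS = ["A", "AT", "AG", "AC", "AAG", "ATC", "AAT", "AAAT", "AGAT"]
_SSR_COPIES = {1: 14, 2: 9, 3: 7, 4: 6}


def _plant_ssr(rng, seq: list[str], lo: int, hi: int):
    """Plant a perfect tandem repeat inside seq[lo:hi]; returns (motif, start,
    end) in the planted orientation, or None if the window is too short."""
    motif = _SSR_MOTIFS[rng.integers(0, len(_SSR_MOTIFS))]
    copies = _SSR_COPIES[len(motif)] + int(rng.integers(0, 4))
    tract = motif * copies
    if hi - lo < len(tract) + 2:
        return None
    start = int(rng.integers(lo + 1, hi - len(tract)))
    seq[start:start + len(tract)] = list(tract)
    # break the period on both flanks so the planted run stays maximal
    for j, ref in ((start - 1, start - 1 + len(motif)), (start + len(tract), start + len(tract) - len(motif))):
        if 0 <= j < len(seq) and seq[j] == seq[ref]:
            seq[j] = BASES[(BASES.index(seq[j]) + 1) % 4]
    return motif, start, start + len(tract)


def generate_reference(spec: ContigSpec) -> ReferenceSet:
    """Generate a reference contig set with planted gene structure, SSRs,
    duplicate pairs and collinear model-genome anchors.

    Each contig is a 3'-anchored transcript fragment: a CDS of complete sense
    codons, a stop codon, and a 3'-UTR; roughly half the contigs are stored
    reverse-complemented (strand '-').  Contigs are laid out chromosome-chunk
    by chromosome-chunk on the model genome; ``n_inversions`` /
    ``n_translocations`` segments of the layout are planted reversed or moved
    to another chromosome and recorded in the truth tables.
    """
    rng = rng_from(spec.seed, 101)
    contigs: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    ssr_rows, dup_pairs = [], []

    for i in range(spec.n_contigs):
        cid = f"LcC{i + 1:05d}"
        L = int(np.clip(rng.normal(spec.length_mean, spec.length_mean * 0.25),
                        200, 4 * spec.length_mean))
        utr_len = max(int(round(L * spec.utr3_fraction)), 20)
        n_codons = max((L - utr_len - 3) // 3, 10)
        L = 3 * n_codons + 3 + utr_len
        cds_seq = _random_cds(rng, n_codons)
        stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
        mrna = list(cds_seq + stop + _random_seq(rng, utr_len))

        ssr = None
        if rng.random() < spec.ssr_rate:
            ssr = _plant_ssr(rng, mrna, 3 * n_codons + 3, L)

        strand = "+" if rng.random() < 0.5 else "-"
        mrna_s = "".join(mrna)
        seq = mrna_s if strand == "+" else revcomp(mrna_s)

        def to_contig(s, e):
            return (s, e) if strand == "+" else (L - e, L - s)

        cds = to_contig(0, 3 * n_codons)
        utr3 = to_contig(3 * n_codons, L)   # includes the stop codon
        # 1-3 exons: splice sites placed inside the transcript
        n_exon = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(50, L - 50), size=n_exon - 1,
                                 replace=False)) if n_exon > 1 else []
        bounds = [0, *[int(c) for c in cuts], L]
        exons = sorted(to_contig(bounds[j], bounds[j + 1]) for j in range(n_exon))

        contigs[cid] = seq
        models[cid] = GeneModel(cid, f"gene_{cid}", strand, L, exons, cds, utr3)
        if ssr is not None:
            motif, s, e = ssr
            if strand == "-":
                motif, (s, e) = revcomp(motif), (L - e, L - s)
            ssr_rows.append({"contig": cid, "motif": motif, "start": s,
                             "end": e, "copies": (e - s) // len(motif)})

        if rng.random() < spec.dup_rate:
            did = cid + "d"
            dseq = list(seq)
            for p in rng.choice(L, size=max(1, int(0.005 * L)), replace=False):
                dseq[p] = BASES[(BASES.index(dseq[p]) + int(rng.integers(1, 4))) % 4]
            contigs[did] = "".join(dseq)
            models[did] = dataclasses.replace(models[cid], contig=did,
                                              gene_id=f"gene_{cid}")
            dup_pairs.append((cid, did))

    anchors, rearr = _layout_anchors(spec, contigs, models, dup_pairs, rng)
    ssrs = pd.DataFrame(ssr_rows, columns=["contig", "motif", "start", "end", "copies"])
    return ReferenceSet(spec, contigs, models, ssrs, dup_pairs, anchors, rearr)


def _layout_anchors(spec, contigs, models, dup_pairs, rng):
    """Collinear chunked layout of contigs on the model genome, with planted
    inversions and translocations; duplicates share their source's anchor."""
    primaries = [c for c in contigs if not c.endswith("d")]
    n = len(primaries)
    chunk_of = np.minimum(np.arange(n) * spec.n_model_chroms // n,
                          spec.n_model_chroms - 1)
    rows = []
    for idx, cid in enumerate(primaries):
        lg = int(chunk_of[idx]) + 1
        rank = int(idx - np.searchsorted(chunk_of, lg - 1))
        rows.append({"contig": cid, "lg": f"LG{lg}", "cm": 2.0 * rank,
                     "model_chrom": f"chr{lg}", "model_pos": 50_000 * (rank + 1),
                     "strand": models[cid].strand, "align_len": len(contigs[cid]),
                     "identity": round(float(rng.uniform(0.9, 1.0)), 4)})
    anchors = pd.DataFrame(rows)

    rearr_rows = []
    # rearranged segments span >=5 anchors: the dominant collinear chain can
    # absorb one anchor of a reversed run, so smaller segments would fall
    # under typical min-block thresholds downstream
    win = max(5, n // (10 * spec.n_model_chroms))
    used: set[int] = set()

    def pick_window(lg):
        members = anchors.index[anchors.lg == f"LG{lg}"].to_numpy()
        if len(members) < win + 4:
            return None
        interior = [i for i in members[1:-win - 1] if i not in used
                    and all(i + j not in used for j in range(win))]
        if not interior:
            return None
        start = interior[int(rng.integers(0, len(interior)))]
        w = [i for i in range(start, start + win)]
        used.update(w)
        return w

    lgs = list(rng.permutation(np.arange(1, spec.n_model_chroms + 1)))
    for _ in range(spec.n_inversions):
        lg = int(lgs.pop())
        w = pick_window(lg)
        if w is None:
            continue
        anchors.loc[w, "model_pos"] = anchors.loc[w, "model_pos"].to_numpy()[::-1]
        rearr_rows.append({"kind": "inversion", "lg": f"LG{lg}",
                           "model_chrom": f"chr{lg}",
                           "contigs": ",".join(anchors.loc[w, "contig"])})
    for _ in range(spec.n_translocations):
        lg = int(lgs.pop())
        w = pick_window(lg)
        if w is None:
            continue
        dest = 1 + (lg % spec.n_model_chroms)
        anchors.loc[w, "model_chrom"] = f"chr{dest}"
        anchors.loc[w, "model_pos"] = [10_000_000 + 50_000 * j for j in range(win)]
        rearr_rows.append({"kind": "translocation", "lg": f"LG{lg}",
                           "model_chrom": f"chr{dest}",
                           "contigs": ",".join(anchors.loc[w, "contig"])})

    dup_rows = []
    by_contig = anchors.set_index("contig")
    for src, dup in dup_pairs:
        r = by_contig.loc[src].to_dict()
        r["contig"] = dup
        dup_rows.append(r)
    if dup_rows:
        anchors = pd.concat([anchors, pd.DataFrame(dup_rows)], ignore_index=True)
    rearr = pd.DataFrame(rearr_rows, columns=["kind", "lg", "model_chrom", "contigs"])
    return anchors, rearr


def synteny_anchors(ref: ReferenceSet) -> pd.DataFrame:
    """The reference's planted anchors in the marker-anchor layout consumed
    by the synteny module (contig ids double as marker ids)."""
    df = ref.anchors.rename(columns={"contig": "marker"})
    return df[["marker", "lg", "cm", "model_chrom", "model_pos",
               "align_len", "identity"]].copy()


# ---------------------------------------------------------------------------
# panel mutation
# ---------------------------------------------------------------------------

@dataclass
class PanelResult:
    spec: PanelSpec
    haplotypes: dict[str, dict[str, str]]   # genotype -> contig -> sequence
    truth: pd.DataFrame                      # genotype, contig, pos(1-based), ref, alt, transition


def _draw_alt(rng, ref: str, p_ts: float) -> tuple[str, bool]:
    if rng.random() < p_ts:
        return TRANSITION_PARTNER[ref], True
    tvs = [b for b in BASES if b != ref and b != TRANSITION_PARTNER[ref]]
    return tvs[rng.integers(0, 2)], False


def mutate_panel(reference: ReferenceSet, panel: PanelSpec) -> PanelResult:
    """Derive one homozygous haplotype per panel genotype by planting random
    substitutions (no indels) on the reference.

    Per-site mutation probability is ``theta_cultivated`` or ``theta_wild``;
    a planted change is a transition with probability ts/(ts+1) where
    ts = ``ts_tv_ratio``, otherwise one of the two transversion partners,
    equiprobably.  A fraction ``shared_fraction`` of each genotype's
    variants is drawn from a panel-wide pool of polymorphic sites with a
    fixed alternate allele, so variants segregate across genotypes (shared
    haplotypes) rather than being exclusively private; the remainder are
    private substitutions.
    """
    thetas = ([panel.theta_cultivated] * panel.n_cultivated
              + [panel.theta_wild] * panel.n_wild)
    p_ts = panel.ts_tv_ratio / (1.0 + panel.ts_tv_ratio)

    # flattened site index over the whole contig set
    cids = list(reference.contigs)
    lengths = np.array([len(reference.contigs[c]) for c in cids])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    l_total = int(offsets[-1])

    def locate(flat: int) -> tuple[str, int]:
        ci = int(np.searchsorted(offsets, flat, side="right") - 1)
        return cids[ci], int(flat - offsets[ci])

    pool_rng = rng_from(panel.seed, 210)
    n_pool = max(8, int(np.ceil(3 * panel.shared_fraction * panel.theta_wild
                                * l_total)))
    n_pool = min(n_pool, l_total)
    pool_sites = np.sort(pool_rng.choice(l_total, size=n_pool, replace=False))
    pool_set = set(int(s) for s in pool_sites)
    pool_alts = {}
    for s in pool_sites:
        cid, p = locate(int(s))
        pool_alts[int(s)] = _draw_alt(pool_rng, reference.contigs[cid][p], p_ts)

    haplotypes, rows = {}, []
    for g, (name, theta) in enumerate(zip(panel.genotype_names, thetas)):
        rng = rng_from(panel.seed, 211, g)
        n_mut = rng.binomial(l_total, theta) if theta > 0 else 0
        n_shared = min(rng.binomial(n_mut, panel.shared_fraction), n_pool)
        shared = rng.choice(pool_sites, size=n_shared, replace=False)
        n_private = n_mut - n_shared
        margin = 4 * int(np.ceil(n_mut * n_pool / max(l_total, 1))) + 50
        draw = rng.choice(l_total, size=min(n_private + margin, l_total),
                          replace=False)
        private = [int(s) for s in draw if int(s) not in pool_set][:n_private]

        variants = {}
        for s in shared:
            variants[int(s)] = pool_alts[int(s)]
        for s in private:
            cid, p = locate(s)
            variants[s] = _draw_alt(rng, reference.contigs[cid][p], p_ts)

        seqs = {c: list(reference.contigs[c]) for c in cids}
        for s in sorted(variants):
            cid, p = locate(s)
            alt, is_ts = variants[s]
            rows.append({"genotype": name, "contig": cid, "pos": p + 1,
                         "ref": seqs[cid][p], "alt": alt, "transition": is_ts})
            seqs[cid][p] = alt
        haplotypes[name] = {c: "".join(v) for c, v in seqs.items()}
    truth = pd.DataFrame(rows, columns=["genotype", "contig", "pos", "ref",
                                        "alt", "transition"])
    return PanelResult(panel, haplotypes, truth)


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def simulate_pileup(haplotype: dict[str, str], depth_mean: float,
                    error_rate: float = 0.0, seed: int = 0,
                    min_depth: int = 0) -> pd.DataFrame:
    """Simulate a base-count pileup of one genotype's reads over its own
    haplotype (columns contig, pos, depth, A, C, G, T; pos 1-based).

    Depth is Poisson(``depth_mean``) per site; each read reports the
    haplotype base, miscalled to a uniform other base with ``error_rate``.
    ``min_depth`` optionally floors the depth (validation convenience for
    complete-coverage scenarios); the default 0 leaves the Poisson untouched.
    """
    if depth_mean <= 0:
        raise ParameterError("depth_mean must be positive")
    if not (0.0 <= error_rate <= 0.1):
        raise ParameterError("error_rate must be in [0, 0.1]")
    rng = rng_from(seed, 307)
    frames = []
    for cid in sorted(haplotype):
        seq = haplotype[cid]
        L = len(seq)
        depth = rng.poisson(depth_mean, size=L)
        if min_depth > 0:
            depth = np.maximum(depth, min_depth)
        correct = rng.binomial(depth, 1.0 - error_rate)
        errors = depth - correct
        err_split = rng.multinomial(errors, [1 / 3] * 3)
        counts = np.zeros((L, 4), dtype=np.int64)
        base_idx = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int64)
        for j, b in enumerate(BASES):
            lut[ord(b)] = j
        bi = lut[base_idx]
        counts[np.arange(L), bi] = correct
        # distribute errors over the three non-haplotype bases
        others = np.array([[j for j in range(4) if j != b] for b in range(4)])
        rowcols = others[bi]
        np.add.at(counts, (np.repeat(np.arange(L), 3), rowcols.ravel()),
                  err_split.ravel())
        df = pd.DataFrame({"contig": cid, "pos": np.arange(1, L + 1),
                           "depth": depth, "A": counts[:, 0], "C": counts[:, 1],
                           "G": counts[:, 2], "T": counts[:, 3]})
        frames.append(df[df.depth > 0])
    return pd.concat(frames, ignore_index=True)


def simulate_pileups(panel: PanelResult, depth_means: dict[str, float] | float,
                     error_rate: float = 0.0, seed: int = 0,
                     min_depth: int = 0) -> dict[str, pd.DataFrame]:
    """Pileups for every genotype in a panel; ``depth_means`` may be one
    number or a per-genotype mapping (the study design spans roughly 8-31x)."""
    out = {}
    for g, name in enumerate(panel.spec.genotype_names):
        mean = depth_means[name] if isinstance(depth_means, dict) else depth_means
        out[name] = simulate_pileup(panel.haplotypes[name], mean, error_rate,
                                    seed=np.int64(seed) * 1000 + g,
                                    min_depth=min_depth)
    return out


def write_pileup(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    expected = ["contig", "pos", "depth", "A", "C", "G", "T"]
    if list(df.columns) != expected:
        raise ValueError(f"pileup must have columns {expected}, got {list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# RIL population
# ---------------------------------------------------------------------------

def kosambi_inverse_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a Kosambi map distance: r = tanh(d/50)/2."""
    return 0.5 * np.tanh(np.asarray(d_cM, dtype=float) / 50.0)


def make_marker_map(spec: RILSpec) -> pd.DataFrame:
    """Evenly spaced truth map: columns marker, lg, cm."""
    rows = []
    for g in range(1, spec.n_lg + 1):
        step = spec.lg_length_cM / max(spec.markers_per_lg - 1, 1)
        for j in range(spec.markers_per_lg):
            rows.append({"marker": f"M{g}_{j + 1:03d}", "lg": f"LG{g}",
                         "cm": round(j * step, 6)})
    return pd.DataFrame(rows)


@dataclass
class RILResult:
    spec: RILSpec
    matrix: pd.DataFrame       # markers x (P1, P2, RIL...) calls in {A,B,H,U}
    truth_map: pd.DataFrame
    truth_calls: pd.DataFrame  # same shape as matrix, before missingness


def simulate_ril_population(marker_map: pd.DataFrame, spec: RILSpec) -> RILResult:
    """Simulate an F(1+g) RIL population by g rounds of selfing from an F1.

    Gametes follow a crossover Markov chain along each linkage group with
    adjacent-interval recombination fractions from the inverse Kosambi
    function and no interference.  Parent P1 carries allele A everywhere,
    P2 allele B; calls are A/B/H with U for simulated missing data.
    """
    missing_cols = {"marker", "lg", "cm"} - set(marker_map.columns)
    if missing_cols:
        raise ParameterError(f"marker map lacks columns: {sorted(missing_cols)}")
    if marker_map[["lg", "cm"]].isna().any().any():
        raise ParameterError("every marker needs a linkage group and cM position")
    rng = rng_from(spec.seed, 401)
    call_blocks = []
    for lg, grp in marker_map.groupby("lg", sort=True):
        grp = grp.sort_values("cm")
        d = np.diff(grp.cm.to_numpy())
        r = np.asarray(kosambi_inverse_r(d))
        m = len(grp)
        h0 = np.zeros((spec.n_ril, m), dtype=np.int8)   # F1: A haplotype
        h1 = np.ones((spec.n_ril, m), dtype=np.int8)    # F1: B haplotype

        def gamete(h0, h1):
            start = rng.integers(0, 2, size=(spec.n_ril, 1))
            switch = (rng.random((spec.n_ril, m - 1)) < r).astype(np.int8)
            choice = np.cumsum(np.hstack([start, switch]), axis=1) % 2
            return np.where(choice == 0, h0, h1)

        for _ in range(spec.selfing_generations):
            g0, g1 = gamete(h0, h1), gamete(h0, h1)
            h0, h1 = g0, g1
        calls = np.where((h0 == 0) & (h1 == 0), "A",
                         np.where((h0 == 1) & (h1 == 1), "B", "H"))
        df = pd.DataFrame(calls.T, index=grp.marker.to_numpy(),
                          columns=[f"RIL{i + 1:03d}" for i in range(spec.n_ril)])
        call_blocks.append(df)
    truth_calls = pd.concat(call_blocks)
    truth_calls.insert(0, "P1", "A")
    truth_calls.insert(1, "P2", "B")
    matrix = truth_calls.copy()
    if spec.missing_rate > 0:
        ril_cols = matrix.columns[2:]
        mask = rng.random((len(matrix), len(ril_cols))) < spec.missing_rate
        vals = matrix[ril_cols].to_numpy(dtype=object)
        vals[mask] = "U"
        matrix[ril_cols] = vals
    matrix.index.name = "marker"
    truth_calls.index.name = "marker"
    return RILResult(spec, matrix, marker_map.copy(), truth_calls)


def write_genotype_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_genotype_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


# ---------------------------------------------------------------------------
# diverged ortholog CDS pairs (for Ks calibration)
# ---------------------------------------------------------------------------

def simulate_diverged_cds_pairs(n_pairs: int, n_codons: int, t_myr: float,
                                syn_rate: float = 5.17e-3,
                                seed: int = 0) -> list[tuple[str, str]]:
    """Indel-free ortholog CDS pairs diverged ``t_myr`` ago.

    Each lineage accumulates Poisson(rate x T x S) synonymous substitutions,
    where S is the ancestor's synonymous site count; every event picks
    uniformly among the currently available synonymous single-base changes,
    so repeat hits at a site occur naturally and the Jukes-Cantor correction
    downstream is exercised.  Only synonymous change is simulated: the pairs
    calibrate Ks estimation, not protein evolution.
    """
    from .divergence import synonymous_sites  # local import avoids a cycle
    rng = rng_from(seed, 503)
    pairs = []
    for _ in range(n_pairs):
        anc = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
        s_anc = sum(synonymous_sites(c) for c in anc)
        derived = []
        for _lineage in range(2):
            seq = list(anc)
            n_events = rng.poisson(syn_rate * t_myr * s_anc)
            for _ in range(n_events):
                options = []
                for ci, codon in enumerate(seq):
                    aa = _STANDARD.forward_table[codon]
                    for p in range(3):
                        for b in BASES:
                            if b == codon[p]:
                                continue
                            new = codon[:p] + b + codon[p + 1:]
                            if _STANDARD.forward_table.get(new) == aa:
                                options.append((ci, new))
                ci, new = options[rng.integers(0, len(options))]
                seq[ci] = new
            derived.append("".join(seq))
        pairs.append((derived[0], derived[1]))
    return pairs
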