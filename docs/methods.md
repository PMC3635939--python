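# Methods

This note documents the models and estimators implemented in `lenspipe`,
the defaults and why they were chosen, the conventions that matter for
reproducing numbers, and what the synthetic-data generator does and does
not emulate.

## Coordinate and format conventions

Internal coordinates are 0-based, half-open, everywhere. Emitted files use
each format's native convention: GFF3, VCF and pileup TSVs are 1-based.
The pileup format is a plain TSV with columns
`contig  pos  depth  A  C  G  T`; base counts must sum to depth, and sites
with zero depth are omitted (absence from the file means no coverage).

In truth GFF3 written by the generator, the CDS feature covers complete
sense codons only and **excludes the terminal stop codon**, which is
folded into the 3′-UTR feature. This keeps the codon-impact classes an
exact partition of CDS SNPs: no stop-loss case can arise on truth
annotations. Anchors from external GFF3s that include the stop codon are
still handled — a SNP whose reference codon is a stop is annotated `NA`
and logged.

## SNP calling and merging

A site in one genotype's pileup is a confident ALT call iff the most
frequent non-reference base has at least `min_reads` (3) supporting reads
and at least `min_fraction` (0.80) of all reads at the site. Both
boundaries are inclusive: exactly 3 reads at exactly 80% passes, because
the failing set is defined as "below 80% or below 3 reads". The fraction
is computed over all reads at the site, not over ref+alt reads only — the
simplest reading, and the two differ only at noisy sites. Sites failing
either rule but showing ≥ 1 non-reference read are retained as
below-threshold evidence; they appear in the merged table only at
positions where some genotype is confident, and are never records of their
own.

The panel lines are inbred, so no heterozygous genotype state is modelled;
per-genotype status is REF, ALT, MISSING (no reads) or BELOW_THRESHOLD.
Two different confident alternate bases at one site produce two biallelic
records with a logged warning; on each record, a genotype confident for
the *other* base is reported BELOW_THRESHOLD (it is neither REF nor this
ALT, and the status vocabulary is deliberately closed).

The mean alternate-allele frequency is the unweighted mean over SNPs of
(#ALT)/(#informative), where informative genotypes are those with REF or
ALT status and the reference genotype counts as one additional REF
(switchable with `include_reference=False`; whether the original analysis
included the reference in the denominator is not stated).

## SSR detection

Maximal perfect tandem repeats with motif lengths 1–6 bp are reported when
they reach both a per-motif copy threshold (mono ≥ 10, di ≥ 6, tri ≥ 5,
tetra–hexa ≥ 4) and a total length of 12 bp. These thresholds are
configurable defaults, not published values — the original screen used an
external tool whose settings are unavailable. Motifs that are themselves
periodic (ACAC as a tetramer) are suppressed in favour of the primitive
period, so each repeat tract is reported once.

## Gene anchoring and codon impact

Anchors carry exon intervals, a CDS interval with known frame, and the
strand, all in contig coordinates. They can be read from GFF3 (with
model-genome coordinates joined from an anchor TSV) or computed by a
built-in exact-k-mer seed-and-extend anchorer (k = 25, ungapped extension,
min identity 0.9, min overlap 100 bp, best anchor by aligned length ×
identity). The anchorer is adequate for synthetic contigs and validated by
≥ 99% agreement with planted truth; it is not a spliced aligner and is not
intended for real cross-species mapping, where precomputed anchors should
be supplied.

Exonic SNPs are classified by strand-aware codon substitution:
STOP_GAIN if the alternate codon is a stop (this overrides everything
else), SYNONYMOUS if the amino acid is unchanged, otherwise non-synonymous
within or across amino-acid property groups. The default groups are acidic
{D,E}, basic {K,R,H}, polar-uncharged {S,T,N,Q,C,Y} and nonpolar
{A,V,L,I,M,F,W,G,P}; only the basic/acidic contrast is canonical in this
setting, so the full table is configuration (YAML-loadable), not a
constant. STOP_GAIN is disjoint from the two property classes, which makes
SYNONYMOUS + NONSYN_SAME_PROP + NONSYN_DIFF_PROP + STOP_GAIN an exact
partition of classifiable CDS SNPs. 5′-UTR is folded into UNASSIGNED:
3′-anchored cDNA data contains almost none of it.

## Synonymous divergence (Ks)

Ks uses Nei–Gojobori (1986) unweighted pathway counting rather than
maximum-likelihood estimation: it is deterministic, dependency-free, and
close to ML at the low divergences of interest here. Site counts per codon
are the per-position fractions of single-base changes that preserve the
amino acid, with changes to stop codons counted as nonsynonymous. Codon
pairs differing at k positions average their difference counts over the k!
mutational pathways; pathways that traverse a stop codon are excluded when
a stop-free pathway exists, otherwise all pathways are used with stop
steps counted as nonsynonymous. pS = Sd/S is Jukes–Cantor corrected,
`Ks = −(3/4)·ln(1 − (4/3)·pS)`; pS ≥ 0.75 raises a saturation error, and
saturated pairs appear as NaN in batch tables.

Only equal-length, gap-free, internally stop-free CDS pairs are accepted.
This is the indel-free filter: rather than re-implement a multiple
aligner, the pipeline takes the same restriction the original analysis
applied to its alignments.

The divergence summary is the **mode of binned Ks**: fixed-width bins
(default 0.01) anchored at 0, midpoint of the most populated bin, ties to
the lowest bin. Bin anchoring and midpoint reporting are conventions of
this implementation; published "mode Ks" values quote bins without stating
them, so the bin left edge is always emitted alongside. Time is
`T = Ks/(2r)` with `r = 5.17×10⁻³` substitutions/synonymous site/Myr
(legume lineage). Note one arithmetic cross-check this formula makes
visible: a mode Ks of 0.07 under this clock gives 6.77 Myr, not 0.677 Myr;
a published figure of "677,000 years" for that mode is internally
inconsistent by exactly 10× (it would correspond to mode Ks 0.007). The
implementation uses the standard identity and leaves the discrepancy
flagged here.

The Ks calibration generator evolves each lineage of an ortholog pair by a
Poisson number (rate × T × S) of synonymous substitutions, each drawn
uniformly from the currently available synonymous single-base changes, so
repeat hits occur and the JC correction is genuinely exercised. Pairs are
300 codons by default in the acceptance run — a typical full-length plant
CDS — which keeps the per-pair Ks sampling noise small enough for a
histogram mode on 500 pairs to be stable.

## Array candidate selection

Filters, in order: (1) polymorphism — a SNP must have confident ALT calls
in ≥ 2 cultivated genotypes (the reference is the comparison baseline and
is rejected if listed as cultivated); (2) flanks — ≥ 60 clean bp on each
side to the nearest contig end, other recorded SNP, or splice site, with
exactly 60 passing (the rule eliminates "less than 60"); distances exclude
the SNP base, and all recorded SNPs count as neighbours, including
below-threshold ones (stricter; switchable by passing a filtered position
list); (3) external design scores, when supplied, exclude ≤ 0.4 and prefer
> 0.6 — scores are opaque numbers from an external design tool and are
never computed here. One SNP is kept per (contig, haplotype) where the
haplotype is the exact per-cultivated-genotype status vector, and
duplicated contigs share a single group. "Even spread across the genome"
is operationalised as greedy farthest-point selection on model-genome
anchor coordinates, deterministic with lexicographic SNP-id tie-breaks;
candidates without anchors fill remaining slots last.

## Linkage mapping

Consensus haplotypes per contig fill missing calls from the contig's other
markers and mask disagreements to missing (never resolved by majority).
Dominant PRESENT/NULL markers are recoded by assigning the null allele to
whichever parent is null; markers with indistinguishable parents are
dropped and logged. Individual QC removes lines whose missing fraction
exceeds a threshold — the threshold is a parameter because the original
study reports only its outcome (5 of 144 lines removed), not the cutoff.

Pairwise statistics use only A/B calls (H is treated as non-informative:
residual heterozygotes in an F8 population carry little recombination
information and the downstream estimator assumes inbred lines). The
observed recombinant fraction R = k/n is corrected to meiotic r through
the selfed-RIL identity R = 2r/(1+2r), i.e. r = R/(2(1−R)) capped at 0.5,
and LOD = k·log10(2R) + (n−k)·log10(2(1−R)). Note the identity evaluated
at r = 0.2 gives R = 0.2857. Grouping is connected components of the
LOD ≥ 6 graph.

Ordering is deliberately a documented heuristic rather than a
re-implementation of commercial ML/regression ordering: a greedy
nearest-neighbour path through the r matrix (started from the marker with
the largest total distance, a likely terminal) refined by 2-opt on the sum
of adjacent r. Its adequacy is demonstrated by simulation recovery
(Spearman |ρ| ≥ 0.95 per group at 139 lines, 70 markers/group), not
assumed. Distances are Kosambi, cumulative from 0 at the first marker.

Two small biases are worth knowing: simulated F8 lines show a recombinant
fraction ~5% below the fully-inbred asymptote, and the asymptotic
correction therefore compresses map length slightly; the compression
shrinks as marker spacing tightens and does not affect grouping or order.

## RIL simulation

Gametes follow a crossover Markov chain along each linkage group with
adjacent-interval recombination fractions from the inverse Kosambi
function, r = tanh(d/50)/2, and no interference — the simplest process
consistent with the Kosambi function used downstream. F8 is simulated as
an F1 selfed exactly 7 times (not as fully inbred lines), so residual
heterozygosity ≈ 2⁻⁷ remains, as in a real bulked-at-F8 population.
Defaults: 7 linkage groups, 147 lines, 2% missing calls.

## Synthetic panel generator

The generator emulates the study design: 1 reference + 8 cultivated + 2
wild genotypes; per-site divergence from the reference
`theta_cultivated = 0.002` and `theta_wild = 0.01` (stated calibration
defaults — the real per-genotype divergences are unknown, only SNP counts
being published); transitions planted with probability ts/(ts+1) for
`ts_tv_ratio = 1.5`; per-site Poisson read depths, with the acceptance run
spanning the 8–31× design range; contigs with CDS/stop/3′-UTR structure on
both strands, occasional planted SSRs and near-identical duplicate pairs;
collinear model-genome anchors laid out chromosome by chromosome with
optional planted inversions and translocations (segments of ≥ 5 anchors,
since a dominant chain can absorb one anchor of a reversed run).

A fraction `shared_fraction = 0.4` of each genotype's variants is drawn
from a panel-wide pool of polymorphic sites with fixed alternate alleles.
Without sharing, every variant would be private to one genotype, no SNP
could pass the ≥ 2-cultivated-genotypes array filter, and allele-frequency
structure would be degenerate; 0.4 gives a qualitatively realistic mix of
private and segregating variation while keeping per-genotype divergence at
theta. The generator does not emulate: indels, homopolymer
(pyrosequencing-style) errors, base-quality variation, assembly errors,
paralog families beyond simple duplicate pairs, or linkage disequilibrium
between variant sites. Passing tests therefore demonstrate correctness of
the computations under clean substitution-only data, not robustness to
real 454 artefacts — the thresholds' behaviour on real noise is exactly
what the below-threshold reporting channel is for.

`simulate_pileups` accepts an optional `min_depth` floor (default 0, pure
Poisson) used in validation scenarios that require complete ≥ 3× coverage,
e.g. demonstrating 100% recall of planted homozygous variants on
error-free data.

## Numerical and degenerate-input conventions

- Seeded runs are bit-reproducible; all stream seeds derive from a master
  seed via `numpy.random.SeedSequence` and stay below 2³¹.
- Weighted-LIS chaining is an O(n²) DP with strictly monotonic model
  positions; ties prefer the earliest-cM predecessor and chain end, so
  output is deterministic. Per linkage-group × chromosome pair, chains are
  peeled iteratively (best of forward/inverted by total weight) until
  fewer than `min_block = 3` anchors chain; `min_block` is a documented
  default, no published threshold exists.
- A block is called an inversion only when its orientation differs from
  the top-weight block of its pair: a genetic map has no intrinsic
  orientation, so a wholly reversed linkage group is not a rearrangement.
  A linkage group whose blocks span ≥ 2 model chromosomes is a
  translocation.
- Whether the original chaining ran per chromosome pair or globally is
  unstated; per-pair is implemented.
- Empty inputs: an empty contig set filters to empty with a warning; an
  empty Ks list and an all-removed QC are errors; an empty anchor set
  chains to an empty result.

## Problem sizes in the acceptance run

The acceptance script uses desk-scale analogues of the study design: a
300-contig (~180 kb) discovery panel, a 600-contig panel at the study's
empirical per-line SNP density (≈ 2.5×10⁻⁴ cultivated / 8×10⁻⁴ wild,
implied by published per-line SNP counts over the assayed sequence) for
the array stage with a target of 24 assays, 500 ortholog pairs of 300
codons for Ks, a 7 × 70-marker map on 139 lines, and 240-contig anchor
sets for synteny. Published headline totals (tens of thousands of SNPs
from millions of reads) are not reproducible at this scale and are instead
covered by closed-form consistency recomputations of their ratios.
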