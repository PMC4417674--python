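# Methods

## Problem setting

A Cas9 ribonucleoprotein cuts a target locus that (a) has a
near-identical endogenous paralog a short distance away and (b) is
co-delivered with a single-stranded oligo donor carrying silent
signature substitutions. Each repaired allele, read out as a subcloned
amplicon sequence, falls into one of a small set of outcomes: unedited,
NHEJ indel, HDR templated by the oligo, HDR templated by the paralog
(gene conversion), or partial conversion. The package classifies reads,
aggregates embryos, decides crossover vs non-crossover from the paralog
locus, and screens exome variant tables for guide off-target
candidates.

## Coordinates and geometry

All internal coordinates are 0-based half-open in target coordinates;
variant tables use VCF-style 1-based positions and are converted at the
boundary. The blunt cut falls 3 bp 5′ of the PAM on the protospacer
strand: for a plus-strand guide starting at $g$ the cut boundary is
$g + 17$. Target and paralog are modeled as equal-length sequences
differing only at the discriminating positions.

## Alignment

Reads are globally aligned to the target with Biopython's
`PairwiseAligner` (affine Gotoh): match +2, mismatch −2, and a gap of
length $L$ scoring $-(6 + L)$, i.e. open −6 plus −1 per gapped base
(`open_gap_score=-7`, `extend_gap_score=-1` in Biopython's
first-residue convention; "open −6, extend −1" admits two conventions
and this package fixes this one, mirrored in the independent test
oracle). Gaps are expensive relative to mismatches, so substitution
signatures are never absorbed into spurious indels. Among co-optimal
paths the aligner's first is taken and every indel is then shifted to
its leftmost equivalent placement, giving canonical indel descriptors in
repeat context. Alignment scores are verified in the test suite against
a hand-written $O(nm)$ affine DP oracle on small random pairs.

## Classification

Informative positions are the union of donor signature positions and
target/paralog discriminating positions. Each read's state at each
informative position is `ref`, `donor`, `paralog`, or `other` (a
deleted position reads `other`). Precedence:

1. indel overlapping the cut window $[c-r, c+r)$, $r = 5$ by default →
   `NHEJ_INDEL`; if donor or tract signatures co-occur → `COMPLEX`
   (mosaic embryos genuinely contain mixed alleles, so `COMPLEX` is a
   first-class category rather than a forced choice);
2. all donor signatures present, no cut indel → `HDR_OLIGO`;
3. at least `min_tract_run` *consecutive* discriminating positions
   reading paralog → `HDR_PARALOG`. Default `min_tract_run = 2`: a
   single converted base is within reach of PCR/sequencing artifact,
   while the canonical conversion footprint in the motivating setting is
   a four-base tandem run;
4. ≥ 1 but not all donor signatures, no cut indel → `HDR_PARTIAL`;
5. otherwise `WT` iff the read equals the reference, else `COMPLEX`
   (stray substitutions, indels far from the cut).

The cut window radius is a package choice — experimental readouts of
Cas9 indels cluster within a few bases of the cut, and the simulator's
default indel spectrum stays inside it, which is exactly the condition
under which classifier-vs-truth round-trips are exact.

An embryo is *cleaved* when ≥ 1 read carries a cut-window indel or an
HDR signature (template-derived bases imply a repaired break).
Percentages are always recomputed from counts: percent cleaved =
cleaved/amplified × 100, displayed to one decimal; HDR percentages are
taken among cleaved embryos.

## Crossover assessment

For embryos with paralog-templated HDR at the target, the paralog locus
is aligned to the paralog reference. The verdict is `crossover` iff the
paralog amplified and any discriminating position reads the *target*
base in ≥ `min_support` reads (default 1 — each clone is a single
molecule; raise it for noisy data), `non_crossover` iff amplified and
clean, `indeterminate` iff the paralog failed to amplify. "Intact"
additionally considers cut-window indels on the paralog; these are
reported as a separate flag and never flip the verdict, since an indel
is not sequence exchange. The pathway report exposes both denominators
(amplified-only and all assessed embryos). Partial conversions are
annotated "SDSA-consistent" only: uni-directional exchange cannot
distinguish synthesis-dependent strand annealing from non-crossover
DSBR on sequence alone.

## Off-target screen

The scanner tests every 20-mer + PAM window on both strands. A site
qualifies iff the PAM matches (NRG = N[AG]G by default, NGG as the
stricter option) and either Hamming distance ≤ `max_mismatches`
(default 6) or the PAM-proximal `seed_len` bases (default 10) match
perfectly. The seed clause carries no cap on total mismatches — the
screen's purpose is sensitivity, and seed-perfect sites with up to 8
distal mismatches are documented cleavage substrates. Mismatch counting
is ungapped (Hamming) over the protospacer; RNA-bulge tolerance is out
of scope. `N` in the reference never matches.

The variant filter chain runs in fixed order: exon overlap → read
support → low-complexity overlap → flanking homopolymer → flank
adjudication. Thresholds printed as strict inequalities are implemented
as such: "more than two reads" keeps support ≥ 3; "homopolymer > 7 bp"
removes runs ≥ 8. Both are config-exposed. The homopolymer search runs
over the full ±100 bp flank while low-complexity regions are a supplied
interval track — the two stages are kept separate and separately
logged, since the source wording conflates them. Upstream read
alignment and variant calling are consumed as tables, never re-run. A
surviving variant is `on_target` only when a flank hit's genomic
coordinates coincide exactly with a declared target site; near misses
stay `off_target`; survivors with no hit are removed as background.
Every variant carries an ordered `FilterTrace`; evaluation stops at the
first failing stage, and per-stage removals plus survivors always sum
to the input count.

## Synthetic data

The generator encodes the study conditions rather than exposing free
dials:

- **Locus pair**: 400-bp target with the guide embedded so the cut sits
  at the center; the paralog differs at `n_discriminating` positions
  (default scenarios use 4, the tandem-footprint count) clustered
  within 50 bp of the cut but outside an 8-bp exclusion zone, so
  default NHEJ deletions can never erase them.
- **Donor**: arms of 63 bp each (126-nt span, the scale of the printed
  ssODN) with 6 signature substitutions by default, placed away from
  discriminating positions so the two HDR footprints stay separable.
- **Embryo mixtures**: clone counts per category are realized *exactly*
  via largest-remainder rounding, so scenario files state counts and
  the truth table reproduces them deterministically. Reads per embryo
  default to 50 (the study's 45–50 clones per embryo). Amplification
  dropout is a per-embryo boolean — whole-genome amplification fails for
  the embryo or it doesn't — not read subsampling. NHEJ alleles are
  single-indel events unless a scenario says otherwise, keeping truth
  labels crisp.
- **Exome plants**: each variant owns a 1-kb block of a synthetic
  chromosome; nuisance plants violate exactly one named filter and pass
  all earlier ones; background variants are exonic with support ≥ 3 and
  a clean flank so only flank adjudication removes them; blocks are
  re-drawn (bounded retries) if chance guide matches or homopolymers
  would blur the label.

What the simulator does **not** model: sequencing error, base
qualities, chromatogram double peaks, amplification bias beyond the
dropout boolean, compound alleles, or ploidy/phasing. Passing
round-trip tests therefore demonstrates the classifier's correctness on
clean clone sequences — the study's data type — not robustness to raw
next-generation read noise.

## Packaged scenarios

`embryo_cohort` (59 embryos: 5 dropout, 26 wild type, 17 NHEJ-only, 4
with oligo-HDR alleles, 7 with conversion tracts), `clones_293t` (one
pool, 29 clones of which 14 carry all six donor signatures),
`crossover_cohort` (7 converted embryos; paralog amplifies in 5, all
intact), and `demo` (a small mixed cohort plus an exome plant spec
exercising every filter stage). The headline percentages these encode
(51.9% cleavage among amplified; 14.3% and 25.0% HDR fractions among
cleaved; 48.3% donor-matched clones; 5 non-crossover / 2 indeterminate)
are arithmetic consequences of the counts and hence seed-independent,
while all sequences and per-read draws derive from the run seed.

## Numerical/engineering choices

- Determinism: every stochastic step draws from a generator seeded by
  mixing the run seed, the scenario file's seed and the item index
  through `numpy.random.SeedSequence`; outputs are byte-identical per
  seed and manifests record the config hash and seed.
- Problem sizes in the test suite (400-bp amplicons, 20–50 reads per
  embryo, 100 randomized round-trip scenarios, 50 scanner-oracle seeds
  on 0.5–2.5-kb sequences) were chosen so the whole suite characterizes
  every operation while remaining a desk-scale computation.
- Ties: among co-optimal alignments, mismatches are preferred over gaps
  by construction of the scoring scheme, and gap placement is
  canonicalized leftward after the fact.
- Degenerate inputs: empty mixtures, zero amplified embryos, empty
  variant sets and vacuous low-complexity tracks all have defined
  behaviour (errors or explicit pass-through recorded in traces) and
  are tested.

## Known limitations

Hamming-only site matching (no bulges); no off-target *scoring* (CFD
or similar) — the screen enumerates and adjudicates, it does not rank;
crossover logic assumes the paralog homology window shares the target
coordinate frame; the classifier is not quality-aware and treats every
clone sequence as an exact single-molecule readout.
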