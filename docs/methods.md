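# Methods

## Digestion model

Restriction sites are IUPAC strings of length 4–8 with a top-strand cut
offset. Substrates are linear PCR amplicons over concrete A/C/G/T bases;
degenerate bases in a substrate are rejected rather than given "maybe-cut"
semantics (enzyme sites may be degenerate, e.g. HinfI's GANTC). Scanning
covers both strands: a duplex site window found on the bottom strand maps
back to top-strand coordinates, deduplicating against top-strand hits so a
palindromic site yields exactly one cut per window. Each duplex site
produces a single cut (offset from the 5′ end of the strand the site is
read on); overhangs are not modelled because only fragment lengths are
observable on a gel. Cuts at position 0 or at sequence length would create
zero-length, gel-invisible fragments and are discarded. Fragment lengths
always sum to the amplicon length; this conservation is property-tested
against a brute-force window matcher.

## Gel observability

Two parameters model agarose resolution:

* `min_detectable_bp` (default **50 bp**) — fragments below this run off a
  2–4% gel and are dropped;
* `comigration_rel_tol` (default **0.05**) — two bands within 5% of the
  larger are indistinguishable. Relative rather than absolute tolerance,
  because agarose resolution scales with fragment size. Merging is greedy
  from the largest length down, each cluster represented by its largest
  member.

Neither value is quantified in typical gel protocols, so both are
configurable everywhere; the defaults are conservative for the 100–2,000 bp
amplicons this workflow uses. The same comparator defines band equality for
diagnostic-band set differences and for matching observed lanes, so design
and calling can never disagree about what "the same band" means.

## Genotype and expression calling

A locus is **informative** when some enzyme leaves each parent at least one
diagnostic band. Calls use at-least-one-diagnostic-band semantics per
parent: shared fragments carry no parent-of-origin information, and partial
lane dropout should not flip a call. The decision table is total: both
parents matched → additive; one side zero → loss of that parent; neither →
unscorable (an empty or alien lane; never a "double loss", which would not
amplify in the first place).

Within-parent polymorphism is screened per locus across all sampled
individuals of each diploid parent by grouping lanes into band-pattern
classes under the co-migration comparator; more than one class excludes the
locus from all loss tallies (the ambiguity makes loss indistinguishable from
segregating presence/absence). Putative losses can be confirmed by
sequencing recovered amplicons: each is assigned to the parental allele with
greater positional identity over the shared (equal-length) coordinate frame,
requiring identity ≥ 0.95 (configurable) and rejecting equidistant
sequences; one recovered haplotype confirms loss, two mean a restriction-site
polymorphism mimicked loss on the gel.

Expression calls require the genomic call for the same individual × locus.
Silencing of parent X demands genomic additivity, zero X-diagnostic cDNA
matches and ≥ 1 match for the other parent; over a genomic loss the missing
transcript is classified `absent_due_to_genomic_loss`. A cDNA-only dataset
therefore cannot produce silencing calls at all — the central methodological
point of the paired design. The optional intensity readout sums measured
intensities over each parent's matched diagnostic bands and reports the
paternal/maternal ratio with a dominance threshold (default **2.0**,
deliberately conservative since gel densitometry is semi-quantitative); it
is scale-invariant.

## AFLP scoring

A fragment present in every individual (all three species jointly) is
monomorphic; all others are polymorphic, subdivided by presence pattern:
novel (≥ 1 polyploid, no diploid), maternal-origin (≥ 1 polyploid, ≥ 1
maternal parent, no paternal parent), paternal-origin (symmetric), other
(everything else — fragments absent from all polyploids, or shared by all
three species but not all individuals). The ≥ 1-polyploid quantifier is
switchable to all-polyploids. The subdivision partitions the polymorphic
class, so counts always sum to the total. Display percentages use
round-half-up (1 decimal by default, matching how such tables are printed;
2 decimals where finer figures are quoted); raw counts are always retained.

## Synthetic studies

The generator emulates the surveyed design: **30 loci** of **600 bp**,
**3%** per-site parental divergence (congeneric diploids), **40**
allotetraploids drawn round-robin from seven named populations, **10**
individuals of each diploid parent, and a panel of twelve common 4- and
6-cutters. Per polyploid individual × locus the paternal homeolog is lost
with probability **0.005** and the maternal with **0.003**; these defaults
were chosen so that a 40-individual cohort yields loss at roughly 9 of 30
genes with a paternal bias, the regime this study design operates in. If
both draws fire, the later (maternal) one is suppressed and logged — a plant
lacking both homeologs would simply fail to amplify. Silencing is drawn per
retained homeolog (default **0.001**). F1 hybrids force all event
probabilities to zero. With probability **0.03** per locus a subset (never
all) of the paternal-parent individuals carries an extra maternal-type
amplicon, reproducing the within-parent polymorphism that forces exclusion.

Gel noise is band dropout (default **0.01** per band) plus multiplicative
size jitter (default **±1%**) applied to polyploid and F1 lanes; parent
lanes are emitted clean, as they serve as the reference patterns. No
spurious bands are simulated — dropout and jitter are the minimal model that
exercises the unscorable and false-silencing paths. One root seed feeds
per-component substreams (alleles, polymorphism, losses, silencing, noise,
AFLP), so changing the noise settings never perturbs the genotype truth, and
identical configuration + seed reproduces every output byte for byte.

Deterministic fixture builders construct datasets whose classification by
the real pipeline reproduces requested tallies exactly: the AFLP builder
fills a presence matrix with the requested class counts (remainder as
parents-only "other" rows); the CAPS builder plants a 200-bp allele pair
whose single substitution destroys the paternal EcoRI site (maternal bands
{139, 61}, paternal {200}) at every locus and assigns loss, silencing and
polymorphism events per the requested gene counts. Loss genes split as
`both = paternal + maternal − loss_genes` genes losing each parent in
different individuals, the rest one parent only — the only split consistent
with per-parent gene counts of 7 and 4 over 9 loss genes.

What the simulator does **not** model: indels or rate heterogeneity in
parental divergence, shared descent of losses within populations (a
founder-correlation would deflate individual-level counts; events are drawn
independently), methylation-sensitive digestion, partial digests, spurious
gel bands, and concerted evolution of repeated loci. Passing recovery tests
therefore show the classification logic is correct under the stated noise
model, not that real gels are this clean.

## Numerical and tie-break choices

* Percentages: `decimal`-based round-half-up, never binary-float rounding.
* Band clustering: greedy largest-first; deterministic for any input order.
* Assay ranking: informative first, then enzyme name — stable and
  reproducible.
* Equidistant recovered sequences are never assigned to a parent
  (inconclusive, flagged) — no fabricated parent calls.
* Empty band sets are legal everywhere (failed lanes → unscorable).

## Test and acceptance problem sizes

The acceptance replays use the surveyed scales directly (1,440/1,056/234/251
AFLP fragments; 30 genes × 10 polyploids for the CAPS fixture; 30 loci × 6
F1 hybrids; 30 loci × 40 individuals for the 3×3 loss-probability recovery
grid). The bias-ordering property averages 200 replicate seeds at a reduced
10 loci × 20 individuals per replicate; the silencing false-positive bound
uses ≥ 2,000 simulated homeolog readouts per dropout level. The
false-positive bound is per homeolog: a retained, expressed homeolog is
falsely called silenced only if every one of its diagnostic transcript bands
drops out, an event of probability ≤ the per-band dropout rate.
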