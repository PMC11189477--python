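# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they are what they are, what the simulator does and
does not emulate, and the numerical edge-case decisions.

## The phasing model

A sperm's genome is a mosaic of the donor's two parental haplotypes
with switch points at meiotic crossovers. At the donor's heterozygous
sites, the sperm × site call matrix therefore factorizes into (i) two
unknown parental allele sequences per chromosome and (ii) one unknown
piecewise-constant haplotype-origin track per sperm, observed through
heavy dropout (~50% of sites per cell after MALBAC-style whole-genome
amplification) and a small genotyping error rate (~1%).

Rather than fitting a hidden-Markov model, the pipeline uses the
reference-sperm construction: pick the cell with the highest site
coverage and code every other sperm as *same*/*different* relative to
it wherever both have calls. In that coordinate frame each sperm's
track switches at its own crossovers — and, crucially, at the
*reference's* crossovers, where every sperm in the population appears
to switch simultaneously. Because genuine crossovers are private to a
gamete, a population-wide switch identifies a reference crossover
("false recombination site"); toggling all states downstream of each
such site converts relative states into chromosome-level absolute
genotypes (H0 is defined as the reference sperm's starting haplotype on
each chromosome, so phase is consistent across the whole chromosome).

### Crossover detection (per sperm)

States of one sperm along one chromosome, restricted to informative
sites, are (1) passed through a centred width-3 majority filter that
erases isolated single-site flips, (2) segmented at the smoothed
transitions, and (3) segments supported by fewer than `min_support`
concordant raw sites are absorbed into their neighbours, weakest first.
Breakpoints are the boundaries between surviving segments, reported as
the interval between the two flanking informative sites together with
the concordant counts over up to `window` sites per flank.

Defaults `window = 15`, `min_support = 5`: with ~25 informative
sites/Mb (1 het site per 10 kb, 50% dropout on both the cell and the
reference), five concordant sites span ~200 kb, so the detector
resolves double crossovers down to that scale while a false breakpoint
would need five co-located errors at a per-site state-error rate of
~2% — vanishingly rare. On tracks whose segments all carry at least
`min_support` concordant sites and whose errors are isolated, this
procedure provably returns the global minimum-switch segmentation
(mismatch cost 1, switch penalty between 1 and `min_support`/2); the
test suite checks that equivalence against an exhaustive dynamic
program on small instances.

### False-recombination consensus

Each sperm's smoothed track contributes "flips" (pairs of consecutive
informative sites with different states, located at the interval
midpoint). A candidate position is supported by every sperm with a flip
within `tolerance_bp` (200 kb) and judged against the sperm whose
informative span covers it; candidates reaching `consensus_fraction`
(0.9) of that denominator are declared reference crossovers, greedily,
retiring their supporting flips. The reference itself is excluded from
the denominator — it cannot witness its own crossover (with the 8-cell
toy of the schematic, consensus is correctly 7/7, not 7/8).

Two artifact classes are recognized before declaring:

- **Anchored terminal artifacts.** A genotyping *error of the
  reference* flips the whole population at one shared site. Interior
  blips of that kind are removed by the per-sperm smoothing, but an
  error at a cell's first or last informative site survives as a
  terminal switch, and near chromosome ends the eligibility denominator
  collapses onto exactly the supporting cells. The signature is that
  all supporting flips share one endpoint site *and* are terminal in
  each sperm's own track; such consensus is flagged, never declared. A
  mid-chromosome crossover is never terminal, so even dropout-free data
  (where all flanking sites coincide) are declared correctly.
- **Crossover pairs.** Two reference crossovers within the tolerance
  window make most sperm flip twice inside it. When ≥ half of the
  supporting sperm carry two flips, the two flip groups are declared as
  two positions — toggling twice restores correct phase on both sides
  and in between. (Declaring such a pair as a single toggle would
  invert the phase of everything downstream.)

Correction recomputes corrected states from the raw states (parity of
declared positions passed), then re-detects per-sperm events. The
operation is idempotent: on corrected tracks no position reaches
consensus again.

**Identifiability limits.** Two configurations are indistinguishable
from genotyping error for *any* population-consensus method and are
deliberately out of reach: a reference crossover with fewer than two
reference-informative sites on a flank (one flanking site is exactly
the signature of an error at that site), and a reference-crossover pair
so close that most sperm lack two informative sites between them
(≈150 kb at the default simulation density). The truth-scoring helpers
exclude these; measured over twenty study-scale simulations, all
identifiable reference events are recovered and marker accuracy is
1.000 on every seed.

### Suspicious recombination

Two crossovers in one gamete a short distance apart are more plausibly
a gene-conversion tract or residual error than a genuine double
crossover; event pairs closer than `min_event_spacing_bp` are removed
(both members). The default is 2 Mb, sized for ~150-Mb chromosomes; on
the 10-Mb desk-scale chromosomes the same fraction of chromosome length
is 200 kb, which the tests and the acceptance script pass explicitly.
Noiseless analyses disable the filter, since close pairs are then real.

### Bins and markers

Detected crossover midpoints, snapped to the 100-kb grid, cut each
chromosome into bins (so adjacent bins differ in at least one sperm; a
final pass re-merges bins whose genotype vectors came out identical).
A sperm's bin genotype comes from its own event-delimited segmentation
— each segment labelled by the majority of its informative sites —
rather than a raw per-bin majority, which keeps single noisy sites in
sparse bins from fabricating extra transitions. Per site, sperm vote
`call == bin genotype` (hap0 carries allele A) versus `call != bin
genotype`; the majority pattern wins with confidence = winning
votes / total votes, and sites below `min_marker_confidence` (0.9) are
dropped rather than guessed. Sites in the sliver between a crossover
and its snapped bin edge occasionally fall just below the cutoff; that
is the confidence filter working as intended.

## Genetic map

Physical bin order is known, so no marker-ordering step exists:
r between adjacent bins = recombinant sperm / sperm informative at
both, capped at 0.4999 with a warning (the Kosambi function diverges at
0.5); d = 25·ln((1+2r)/(1−2r)) cM, inverse r = ½·tanh(d/50), round-trip
exact to 1e-12. Adjacent-pair distances accumulate into cumulative cM;
bin pairs with no jointly informative sperm are map gaps — flagged,
contributing zero rather than an interpolated distance. Map length is
invariant under a global H0/H1 swap.

## Read partitioning

Each phased site yields two probes of length 2·`flank_bp`+1 (default
21 bp), the hap0/hap1 allele centred in reference flanks; probes and
their reverse complements index into an exact-match table; probes
truncated by a contig end are kept down to `min_probe_len` (clamped to
the full probe length), and sequence-colliding probes are dropped as
ambiguous. A read is assigned hap0 when distinct-marker hits satisfy
`hap0 − hap1 ≥ min_margin` (default 1), symmetrically for hap1, and
otherwise — no markers, ties, hits on several chromosomes, or a marker
matched by both of its allele probes — duplicated into both groups, so
each group remains a complete assembly input. Exact matching suffices
because HiFi-grade reads err at ≲1% per base; raising `min_margin` can
only demote reads to "both", never flip them.

## X/Y sorting and Y-read selection

A haploid sperm shows ~1× of its autosomal coverage on the scaffolds of
the chromosome it carries and ~0 on the other; after per-cell
normalization by autosomal coverage, a cell is Y-bearing when
normalized Y coverage ≥ `min_ratio` (0.3) and X coverage < `min_ratio`
(X-bearing symmetrically, otherwise ambiguous). Y-specific short reads
are the reads of Y-bearing cells that do not align to autosomes
(unaligned reads stay — the Y is absent from the assembly). Long reads
are rescued when sharing ≥ `min_shared` (10) distinct canonical 31-mers
with that short-read set; a second pass drops candidates whose k-mers
match the assembly-without-Y at ≥ 25% of the read. The fractional
threshold mimics the read alignment it replaces: an X read matches the
assembly wholesale and is dropped, while a Y read that merely brushes a
95%-identity X/Y homologous segment shares only ~0.95³¹ ≈ 20% of its
k-mers and survives. An absolute cutoff here would discard those
boundary Y reads (measured recall 0.88 versus 0.99 across ten
planted-homology scenarios at identical precision 1.0).

## QTL scan

Gamete populations are haploid, so the genotype is 0/1 and no dominance
term exists. At each 1-cM grid point the expected haplotype given the
flanking bin genotypes (no-interference combination of inverse-Kosambi
recombination probabilities; single flank when only one side is
observed) is regressed on the phenotype, optionally with
forward-selected cofactor bins (add while conditional LOD gain > 1.5,
up to 5) excluded within 10 cM of the test position on the same
chromosome; LOD = (n/2)·log₁₀(RSS₀/RSS₁) against the cofactor-only
null. Intervals with LOD ≥ 2.5 are reported with their peak. Motility
grades enter as quantitative 1/2/3 (an ordinal-logistic variant would
be a drop-in alternative but is not the default). Missing cofactor
genotypes are mean-imputed; the scanned locus itself is never imputed —
sperm with no informative flank are excluded at that grid point. A
perfect fit caps LOD at 50 with a warning; monomorphic markers score 0.
At marker-coincident grid points with complete data the scan equals the
single-marker LOD to 1e-9.

## The simulator

Meioses draw crossover counts per chromosome from a Poisson with the
configured mean (zero-truncated when the obligate-chiasma flag is set —
the realized mean is then λ/(1−e^{−λ})), breakpoints uniform, starting
phase fair; no crossover interference is modelled. Genotype dropout is
i.i.d. per site; amplification bias between cells is approximated by an
optional per-sperm global coverage drawn uniformly from an
(0.18, 0.68)-style range, not by locus-correlated dropout. Long reads
are error-free, fixed-length, uniformly placed, and carry their source
haplotype's alleles; phenotypes are latent-normal with tertile grades
(grade 1 best). The X/Y scenario plants a homologous segment copied
from X into Y at configurable identity and emits alignment classes as
they would appear against an assembly lacking the Y.

Defaults mirror the experiment the method targets, scaled to desk size:
19 autosomes, 102 sperm, ~50% het-site coverage per cell, ~18
crossovers per gamete genome-wide, 1:1 X/Y, 1 het site per 10 kb on
10-Mb chromosomes. Consequences of what is *not* modelled: passing
tests do not certify behaviour under locus-correlated (GC-biased)
dropout, read sequencing errors, crossover interference, aneuploid or
diploid-contaminated cells, or reference-assembly errors — the
corresponding robustness margins (e.g. the 0.9 consensus threshold
against the ~0.96 observed support) are stated above so users can judge
them.

Everything derives deterministically from a single integer seed via
named child generators; identical configurations are byte-identical in
all outputs.

## Problem sizes used by the test suite and acceptance script

Study-scale phasing runs use 19 × 10 Mb chromosomes × 102 sperm
(~19,000 sites, a few seconds each); QTL localization uses 3 × 10 Mb ×
500 sperm with a planted 1-SD effect (twenty seeds in the tests, five
in the acceptance script); Y-selection scenarios use a 100-kb autosome,
60-kb X and 40-kb Y with a 4-kb homologous head. These sizes keep every
statistical check comfortably powered while the full suite runs in
about a minute.

## Known limitations

- Reference events below the identifiability limits (terminal gaps,
  sub-resolution pairs) remain uncorrected; downstream they surface as
  per-sperm double flips that the suspicious filter removes, so marker
  phase is unaffected, but the reference event list is incomplete
  there.
- Phase does not bridge chromosome spans with zero informative sperm;
  such gaps break into separate phase blocks and are reported, not
  guessed.
- The bin-level crossover count underestimates the true per-gamete mean
  by the detector's miss rate (sub-resolution pairs and track-end
  events; ~8% at default densities): the simulated truth mean and the
  pipeline estimate are reported side by side by the acceptance script.
- `select_cofactors` is O(bins² · sperm) per selection round; fine for
  thousands of bins, not engineered for hundreds of thousands.
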