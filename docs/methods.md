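# Methods

This note documents the models, numerical choices and limitations of
the pipeline, stage by stage.

## Coordinate and alphabet conventions

All genomic coordinates are 1-based and inclusive on both ends (the
GFF3 convention); the optional BED export converts to 0-based
half-open. Sequences are held internally in the DNA alphabet (U → T on
input) so there is a single comparison path; RNA is rendered only in
reports and duplex displays. Read sets are collapsed: one record per
unique sequence with a count, merged by summation and ordered
deterministically (descending count, then lexicographic).

## Read mapping and candidate windows

Mapping requires a perfect, full-length match on either strand. Reads
placed at more than `max_hits` genomic positions (default 35) are
treated as repeat/transposon-derived and dropped with their hit count
logged; a read with exactly 35 placements is kept (the bound is
strict). The default of 35 reflects a genome with roughly 2.55-fold
duplication — for a less duplicated genome a lower cap (~20) is
appropriate; the parameter is exposed everywhere.

Alignments within 30 nt of each other (per chromosome and strand)
merge into seed regions. Candidate precursor windows extend each
region by every pair of flanks from {20, 60, 100, 160, 250} nt — a
5×5 grid, deduplicated — because the duplex may sit on either arm and
the loop length is unknown. Windows longer than 320 nt are trimmed
symmetrically around the seed region rather than discarded, which
bounds folding cost without losing grid coverage. Windows are
evaluated smallest-first and the first window that annotates wins;
this prefers compact precursors and avoids folding large windows for
clean loci.

## Folding

The default backend maximizes the summed weight of nested base pairs
(G:C = 3, A:U = 2, G:U = 1) with a minimum loop of 3 nt, computed by a
Nussinov-style dynamic program (numba-compiled, O(n³)). The traceback
is fully deterministic: the 5′-most base pairs with its smallest
admissible partner achieving the optimum, otherwise it is left
unpaired. Weighted pair maximization is a deliberately simple,
dependency-free model that recovers planted inverted repeats exactly;
it is *not* a thermodynamic model, and for marginal real hairpins a
free-energy folder is preferable — any callable returning a valid pair
set can substitute, and a ViennaRNA-backed backend ships for
cross-checking. The DP score is verified against exhaustive
enumeration of all nested structures for sequences up to 20 nt.

## Duplex calling and the annotation verdict

Given the fold and the mature span (the region's most abundant read
stack), the star span is derived from the pairing partners of the
mature positions: the partner of mature position L−2 marks the star 5′
end and the partner of the mature 5′ end, extended 2 nt, marks the
star 3′ end — the 2-nt 3′-overhang geometry of dicing. No duplex is
called when fewer than 60% of mature positions pair onto a single
opposite arm (a threshold the criteria leave open; 60% separates
hairpins from chance pairing in random sequence). Between paired
anchors, min(a, b) unpaired positions count as mismatches and |a − b|
as a bulge on the longer arm; unpaired duplex ends count as
mismatches.

The verdict is the exact conjunction: duplex found ∧ both 3′ overhangs
= 2 ∧ mismatches ≤ 4 ∧ at most one bulge of ≤ 2 nt ∧ (duplex reads ≥
25% of stem-loop reads ∨ star absent ∧ mature count ≥ 10). Duplex
reads must match the mature/star spans exactly (tolerance 0, the
strictest reading of precise excision; configurable to ±1 for jittered
data). The abundance fallback is an absolute count anchored to a
library of a few hundred thousand reads; it does not scale with
library size, so deeper libraries should raise it. Conservation
(catalog mature within 3 mismatches) and predicted targets are
recorded as secondary evidence flags and never change the verdict.
Loci whose representative mature is 24 nt are excluded from downstream
analyses as ambiguous hc-siRNA/lmiRNA species.

The representative mature is the most abundant variant unless that
sequence is contained in a longer co-located variant holding ≥ 10% of
the locus total, in which case the longer variant becomes ID1 and the
shorter ID2.

One non-obvious consequence of exact-match mapping: a perfect inverted
repeat is strand-symmetric, so the same hairpin annotates on both
strands. `discover()` collapses such opposite-strand re-detections
(preferring the annotated verdict, then duplex support, then the plus
strand); with biological asymmetries (arm mismatches, dicing jitter)
the ambiguity disappears on its own.

## Families, conservation, genomic context

Family clustering is single linkage at Hamming distance ≤ 2 under the
best ungapped offset with ±2-nt end slack (overhangs within the slack
are free; longer overhangs disqualify the offset). Single linkage is
order-free and matches the transitive way family ids absorb
near-identical matures; the distance rule, not the linkage, is the
specified part, and the linkage function is swappable. A cluster
anchors to a named catalog family at distance ≤ 4; when both miR2118
and miR2218 labels land on one cluster it is named miR2118/2218.

Conservation uses catalog species labels: conserved = homolog
(distance ≤ 4) in any non-Fabaceae species; legume-specific = homologs
only in Fabaceae other than *G. max* (*G. soja* counts as another
species); otherwise soybean-specific. The catalog must carry botanical
family labels or classification raises.

Context: CDS overlap beats UTR overlap; a locus inside a gene span but
in no annotated subfeature counts as UTR-intragenic (introns are not
modeled separately). Distances are measured between nearest span
edges; proximal is strictly < 1000 bp, so exactly 1000 bp is
intergenic. Clusters chain consecutive loci ≤ 5000 bp apart with no
protein-coding gene strictly between them; arrangement is tandem (same
strands), head-to-head (divergent pair), tail-to-tail (convergent
pair) or mixed.

The per-class statistics report both the aggregate members-per-unique-
mature (class loci / class unique matures — the natural reading of
"each mature sequence encoded by N members") and the mean of
per-family ratios. The share of identical-mature families counts only
families with ≥ 2 members, since a singleton is trivially uniform.
Family-size contrasts use Welch's t with the Welch–Satterthwaite df;
the statistic and df are computed explicitly and the p-value comes
from the t distribution.

### Synthetic reconstruction of the compiled locus table

The genome-wide compiled table behind the family statistics is not
shipped; `synthetic.compiled_locus_table()` is a deterministic,
clearly-labeled synthetic reconstruction that satisfies the published
marginal structure (285 included genes in 108 families, 26/9/73 class
split, the class-wise size and diversity profiles, plus flagged rows
for the criteria-fail and 24-nt exclusions to give the inclusion
filters something to remove). Statistics computed on it therefore
reproduce the published summary values by construction of the input,
not of the code path — the value of the exercise is that the same
statistics code runs unmodified on a real compiled table.

## Target prediction

The scan is ungapped (the criteria mention no gaps; bulged targets are
out of scope). miRNA position i (from the 5′ end) faces the site base
L − i positions from the site start, i.e. position 1 pairs the site's
3′-most base. G:U wobbles count as mismatches for the positional rules
— this reproduces the customary duplex displays, where wobbles are
unpiped — but stack weakly in the energy model; `wobble_as_match`
flips the positional convention.

The bundled energy model sums nearest-neighbor stack free energies
over maximal paired runs: the standard ten Watson–Crick RNA stack
parameters (kcal/mol, 37 °C; e.g. 5′GC3′ = −3.42, 5′AU3′ = −1.10), a
flat −1.0 kcal/mol for any step involving a G:U pair, and a +0.5
kcal/mol penalty per internal helix interruption; terminal unpaired
positions neither stack nor cost. The same model scores the duplex and
the perfect complement, so the score (their ratio) is scale-free —
doubling every parameter changes no score. Under this model the six
bundled validated duplexes score 0.70–0.81, consistent with the
0.70–0.79 band reported for them, and the model's exact decimals are
not claimed to match any particular MFE engine — only the 70%
threshold behaviour is.

Cleavage is reported as the first nucleotide of the 3′ fragment: the
transcript coordinate opposite miRNA position 10 (site_end − 9). Dual
targeting lists all cross-family, non-overlapping passing-site pairs
per transcript with their start-to-start separation.

## Phasing

Register r = (pos − cleavage) mod 21 for sense 5′ ends; antisense 5′
ends get +2 before the modulus (duplex 3′-overhang geometry), so an
antisense read at cleavage − 2 is in phase. The window is 231 nt (11
cycles) downstream — typical phasiRNA reporting scale; configurable in
multiples of 21. Both count-weighted and distinct-position profiles
are computed; counts are the default ("number of reads"). The verdict
compares the in-phase register against the median of the 20 other
registers, taking "other positions" to mean the other registers.

Limitation: the median verdict is a weak test. Monte-Carlo simulation
under a uniform null (reads uniform over the window) shows the verdict
fires on roughly 42–48% of draws for n = 30–500 reads, because
register 0 only has to beat the median once; the statistic carries no
multiplicity control and is best read as a screen, not a test. (Later
phasing literature uses hypergeometric phasing scores; those are
deliberately out of scope — this package ships the median statistic.)
The mean in-phase fraction under the null is 1/21 and the suite checks
the empirical mean over 2000 seeded draws to within three standard
errors. The synthetic negative control therefore covers all 21
registers evenly with the remainder assigned to out-of-phase
registers, which fails the verdict deterministically rather than with
probability ~0.5.

## Expression

Levels are 2^(Ct_ref − Ct) per organ, assuming amplification
efficiency 2.0 per cycle and no efficiency correction. The two-fold
rule is applied against the entity's *median* over organs (robust to a
single dominant organ; switchable to the mean), inclusive at exactly
two-fold. The inverse-pair call is the deliberate operationalization
of a qualitative published pattern: at least one organ with miRNA high
and target low and at least one with the reverse; a Spearman rank
correlation over shared organs is reported for transparency but never
gates the call (it is undefined, and reported as NaN, for flat
profiles).

## Synthetic data: what it emulates and what it does not

The generators plant: inverted-repeat MIR loci (arm = 3-nt flank +
mature + 2-nt flank, loop 12–20 nt, right arm carrying a configurable
number of substitutions) whose excised duplex has exact 2-nt 3′
overhangs; tandem repeat decoys copied to 40 positions to exercise the
multimapper cap; protein-coding genes at designed relations (inside
CDS, inside UTR, 500/748/1500 bp away); locus pairs 4/4/6 kb apart for
cluster detection; transcripts with designed site patterns (perfect, 1
mismatch at position 5, 1 at position 10, 5 after position 12, and a
two-family dual-target transcript with sites 600 nt apart); a phased
read set with a stated in-phase fraction plus the even-coverage
control; and Ct tables with one constructed inverse pair and one flat
pair. Read depths are Poisson around 60 reads per locus with duplex
fraction 0.8 and star:mature ratio 0.25 — an idealized, clean library.

Not emulated: sequencing errors, adapter artifacts, expression
heterogeneity across loci, isomiR distributions beyond optional ±1-nt
end jitter, multi-locus families (each planted mature is unique), or
genomic repeat structure beyond the planted decoys. Passing the
recovery suite therefore demonstrates correctness of the criteria
logic and geometry on data that satisfies the model's assumptions; it
does not establish sensitivity on noisy real libraries, where the
jitter tolerance and the duplex-fraction threshold dominate behaviour.

All generators are pure functions of (spec, seed) through a single
named RNG; problem sizes used throughout the suite (10 loci on 2×100 kb
chromosomes, ~600 read counts, 2000-draw null simulations) keep a full
test run in well under a minute per discovery pass while leaving every
code path exercised.

## Determinism

Identical (config, inputs, seed) yield byte-identical outputs; the
run manifest records the full configuration, package version and
SHA-256 digests of every input. The suite asserts byte-level equality
of two complete pipeline runs.
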