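# Methods

## The problem

The 22q11.2 region is flanked by chromosome-22-specific low copy repeats
(LCR22A–LCR22D). LCR22A and LCR22D contain tandem 160 kbp duplicon modules
whose copy number and orientation vary between haplotypes; paralogous copies
share a nearly identical interior (>95%), so optical-map labels in the module
interior cannot tell copies apart. What does distinguish them are
*polymorphic label fingerprints* at the 5′ and 3′ module ends. Non-allelic
homologous recombination (NAHR) between an LCR22A module and an LCR22D module
deletes the intervening ~2 Mbp and causes 22q11.2 deletion syndrome. The
palindromic AT-rich repeat (PATRR) in LCR22B additionally mediates the
recurrent t(11;22) reciprocal translocation, producing der(11) and der(22).

This package models a four-member family in which the father carries the
t(11;22) and is also the parent of deletion origin: the NAHR occurred in his
quadrivalent, between LCR22A of the der(22) and LCR22D of his intact
chromosome 22. The library (i) encodes haplotype structures and the NAHR
product algebra, (ii) simulates single-molecule optical-map data from them,
(iii) reconstructs structures from molecules, and (iv) infers the parent of
origin and the donor pair/breakpoint.

## Miniature coordinate system

Everything lives on a two-chromosome miniature genome: a "chr22" of ~5.5 Mbp
(proximal unique anchor through the LCR22D distal anchor) and a "chr11" of
~1 Mbp around the 11q23 PATRR. The published positions that matter keep their
values as reference-frame coordinates: the translocation junction near
chr22:20,318,054–20,351,331 and chr11:116,811,929–116,824,680 (the model's
junction point is the midpoint of each interval), and the LCR22D flanking
inversion at 21,424,743–21,510,142. The inversion's span (85,400 bp) differs
from its commonly quoted nominal ~64 kbp size; both are stored, and the map
realization uses the printed span.

Every unique (non-duplicated) block is the same material on every homolog
and has fixed length; module arrays vary, so homolog *local* coordinates
accumulate (a five-copy LCR22A haplotype is 640 kbp longer than a one-copy
one) while each block records reference-frame provenance. Coordinates are
1-based with closed intervals throughout (CMAP convention). An earlier
design that pinned all blocks to fixed absolute coordinates and truncated
the spacers was abandoned: it made spacer content differ between homologs,
which is unphysical and breaks reference-guided alignment across homologs.

## Label model

* Core template: one label per ~6 kbp (spacing jittered uniformly in
  ±25%), identical in every module copy — this is what makes paralogs
  ambiguous. The module interior outside the fingerprint windows is
  therefore a fingerprint-free stretch where the LCR22A and LCR22D donor
  templates are identical.
* Fingerprints: six polymorphic label *slots* per 15 kbp end window at
  fixed module-local positions; each copy carries a presence pattern over
  the slots. The family fixture encodes the published counts: at the 5′
  homologous locus the father's der(22) terminal LCR22A module carries 5
  labels and his intact-chr22 LCR22D module the subset of 4 missing the
  second of those five (the only 5′ discriminating site); at the 3′ locus
  the LCR22A module carries 3 labels and the LCR22D module those 3 plus a
  fourth, first in the window (the only 3′ discriminating site). Subset
  structure means presence-based site assignment leaves no discriminating
  site inside the ambiguous interval. Exact slot positions are seeded
  synthetic choices (they are not published); only counts and ordinal
  relations are constrained. With 15 kbp windows the fingerprint-free
  stretch is ~130 kbp and the fixture's ambiguous interval comes out at
  ~143 kbp, wider than the ~90 kbp annotated in the source material —
  published data do not pin the positions needed to reproduce that width.
* Unique regions (anchors, spacers, LCR22B split at the PATRR point, the
  inversion segment) carry seeded jittered templates at the same density.

## Synthetic molecules

`simulate_molecules` shears a map at a requested fold coverage: molecule
starts are uniform; lengths follow a shifted exponential (mean 250 kbp,
truncated below at the instrument-default 150 kbp cutoff — the default
length-filter profile emits nothing shorter). Error model, applied per
molecule: each true label drops out with probability `fn_rate` (default
0.13, recommended window 0.09–0.17); false labels are added as a Poisson
count with mean `fp_rate` (default 0.04, window 0.03–0.05) times the true
label count, placed uniformly — the false-positive figure is interpreted as
a per-label rate; inter-label distances are then perturbed multiplicatively
with CV `sizing_cv` (default 0.02); finally a random strand orientation is
applied. Chimeric molecules are off by default (rate parameter exists for
robustness experiments). Quality scores are uniform [0.5, 1] for true and
[0.2, 0.8] for false labels, purely to exercise the BNX plumbing.

Desk-scale totals replace instrument-scale throughput: default 50× coverage
over the ~6.5 Mbp miniature genome rather than hundreds of Gbp. All
randomness flows through explicit integer seeds; a fixed seed reproduces
byte-identical BNX output.

STRP simulation: eight markers inside the deleted region with 4–8 distinct
allele sizes each; parents diploid, the proband hemizygous with the
transmitted allele drawn from the non-deleting parent. Draws are re-seeded
until at least three markers are informative by construction (resample
count recorded). Allele matching in the classifier is exact by default
(simulated sizes are integers); a size tolerance flag exists but is off.

## Alignment

Two layers share one scoring objective (match bonus 1.0 minus a squared
sizing z-score with σ = `tolerance_cv`·d, interior skips penalized 0.4 per
molecule label and 0.6 per map label, map ends free, empty matching = 0;
`tolerance_cv` defaults to 3× the generator's sizing CV):

* `align_labels` — exact dynamic programming over monotone matchings, both
  orientations. Optimal under the objective (verified against exhaustive
  enumeration on small instances); `max_skip` is an optional banding knob.
* the fast path — candidate placements from the densest clusters of
  molecule-minus-template position differences, followed by an elastic
  nearest-label walk whose tolerance grows with the gap since the last
  match (capped at 1.5 kbp), with score-negative end pairs trimmed off.
  Used for the bulk work (occurrence detection, homolog assignment); every
  matching it produces is scored with the same objective.

Numerical notes: chance placements at ~6 kbp label density accumulate
matches by tolerating large sizing errors; the quadratic penalty is what
rejects them, so occurrence acceptance is score-based, not count-based.
Ties everywhere resolve lexicographically (orientation `+`, leftmost,
lowest id) for determinism.

## Reconstruction

Reference-guided, not de novo: chaining is guided by a candidate module
inventory (the catalog of known copies), the same role curated haplotype
inventories play in manual consensus-map validation. Per molecule, the
shared core template (both orientations) and the unique flank templates are
detected; each module occurrence is annotated with the observed presence of
every fingerprint slot, mapped back to the module's reference frame (so the
annotation is strand- and orientation-independent).

The greedy chain seeds at the 5′ flank. At each junction the molecules whose
detections span from the current frontier to an adjacent occurrence vote;
the orientation/fingerprint consensus of the spanning votes is the
extension, and a 3′ flank (the A–B spacer for intact homologs, the LCR22D
inversion segment for deletion haplotypes, whose merged array runs straight
into LCR22D material) terminates the chain when its votes win. Slots the
votes did not cover are filled in from the best-matching inventory copy
(observations always win over the inventory) so the frontier pattern stays
complete even at low coverage; votes carrying fewer than 3 observed slots
are ignored. Equal nonzero support fails over to exhaustive
candidate-structure scoring (all sequences of distinct copies with free
orientations, each scored by total molecule alignment score); an unsupported
junction raises a chaining-gap error naming the junction. The recombinant
(chimeric) terminal module of a deletion haplotype matches two inventory
copies equally well; its *observed* slot pattern is what downstream
localization consumes, so the tie is recorded, not resolved.

Coverage validation counts, per map label, the molecules whose alignment
matches it; a call passes when all tracked labels reach `min_cov` (default
5×, after the rule that ≥5× over anchor and duplicon-overlapping labels
suffices for unambiguous haplotype determination). Tracked labels are the
interior (anchor + duplicon) labels: labels within ~300 kbp of the homolog
ends are under-covered by construction, exactly like real chromosome ends.

Inversion detection compares the segment template in both orientations —
against a call map directly, or by summed molecule alignment scores against
the two region realizations ('present' requires the mirrored template to
win by a configurable margin; both below a floor is a no-call).

Translocation detection is two-stage split alignment against the miniature
reference maps: a primary alignment on the molecule's majority chromosome,
then the unmatched remainder alone against the other chromosome (restricting
the remainder is what makes a 10–20-label minority side detectable above the
placement background). A supporting molecule needs ≥5 matched labels per
side covering ≥60% of that side, consistent orientation, and sides that
partition the read. Per molecule the chr22 breakpoint lies between the last
matched chr22 label and the next; reported intervals are intersections over
the *concordant* supporters — per-molecule intervals are stabbed with the
point the most intervals strictly contain, which drops both chance split
calls and molecules whose junction-adjacent label dropped out (their
interval is shifted by one label spacing and would otherwise collapse the
intersection).

## Inference

STRP: a marker is informative when the hemizygous proband's single allele
occurs in exactly one parent's genotype; the non-transmitting parent is the
parent of deletion origin. At least three concordant informative markers are
required; conflicts and shortfalls are errors, and an allele present in
neither parent is flagged uninformative rather than guessed.

Fingerprint localization: the proband's merged array carries k modules; the
first k−1 and the 5′ window of the terminal module must match an LCR22A
candidate, the 3′ window and the LCR22D flanking-inversion state an LCR22D
candidate — both fingerprint evidence and inversion state must agree
(two independent lines of evidence). Exactly one consistent pair is
required. Discriminating sites (present in one donor module, absent at the
homologous position of the other) confirmed present in the proband map then
bracket the breakpoint; absence is treated as weak evidence (labels drop
out at 9–17%) and never assigns a site. The partition is reported on the
proband-haplotype frame, 1-based closed.

The quadrivalent interpretation closes the loop: rebuilding the product
from the inferred donors (crossover placed at the ambiguous-interval
midpoint — any offset inside the fingerprint-free stretch yields the same
label content) must reproduce the proband's haplotype structurally,
otherwise a model-inconsistency error is raised. The report also lists the
material excluded from the product, including the chr11 segment
translocated onto the der(22) — which is why the proband carries the
deletion but not the translocation.

## What the synthetic data do and do not show

The generator emulates label dropout, false labels, sizing noise, strand
and fragmentation — the error modes that make duplicon chaining hard. It
does not emulate instrument optics, stretch miscalibration, chimeric reads
(off by default), site-specific label efficiency, or cell-line mosaicism.
Reconstruction here is also reference-guided against a catalog of known
copies rather than fully de novo. Passing tests therefore demonstrate that
the chaining/localization logic is sound under the stated error model, not
that the pipeline would assemble unknown human haplotypes from raw
instrument data.

## Problem sizes and defaults

Defaults are the study conditions: coverage 50×, fp 0.04, fn 0.13, sizing
CV 0.02, min length 150 kbp (160 kbp long-molecule profile for chaining,
which must uniquely span >160 kbp modules), min coverage 5×, min
informative markers 3, min split support 3. The property suites run 20
seeded replicates each: structure recovery at the worst-case corner of the
recommended error window (fp 0.05, fn 0.17), translocation bracketing, and
random-family parent/donor recovery. The CLI smoke test runs the whole
pipeline at a reduced desk-scale coverage (15×) to keep it fast; coverage
is a run parameter, not a model constant. The catalog architecture seed
(2211) fixes label-template positions; it is a fixture constant, not a
tuning knob.

## Known limitations

* Reference-guided: a haplotype absent from the candidate inventory is
  reported via observed patterns but cannot be named.
* Homolog assignment of a diploid pool sends tied molecules (shared
  material) to all tied homologs; coverage counts on shared segments are
  therefore optimistic.
* The breakpoint interval cannot be narrower than the fingerprint-free
  stretch (~130 kbp here); this is a property of the data model, not the
  algorithm.
* Junction intervals for the translocation are label-bounded (~6 kbp
  spacing), so sub-label precision is not available.
* Emanuel-syndrome 3:1 malsegregation outcomes, PATRR secondary structure,
  population NAHR rates and sequence-level representation are out of scope.
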