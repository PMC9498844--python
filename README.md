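# lcr22map

Optical-genome-mapping analysis of the 22q11.2 low copy repeats: haplotype
reconstruction across the LCR22 segmental duplications, t(11;22)
translocation detection, STRP parent-of-origin assignment, and label-
fingerprint localization of the NAHR event that produces the common
22q11.2 deletion.

## Who this is for

People studying structural variation at 22q11.2 — the most common human
microdeletion locus — who want a tested, reusable, fully synthetic-data-
driven implementation of the analysis usually done with proprietary
optical-mapping software plus manual curation: given single-molecule label
data from a deletion trio (or quartet), work out each parent's LCR22A/LCR22D
module haplotypes, decide which parent's germline produced the deletion,
and pin down which two haplotypes recombined and where.

## The model in brief

LCR22A and LCR22D contain tandem 160 kbp duplicon modules. Copies share a
nearly identical interior label template (paralog identity >95%) but carry
polymorphic DLE-1 label *fingerprints* in their 5′ and 3′ end windows.
A haplotype is a block structure: unique anchors, module arrays (copy
number, orientations, per-copy fingerprints), the LCR22B PATRR point where
the t(11;22) translocation joins chr22 to chr11, and the ~64 kbp LCR22D
flanking inversion (printed span 21,424,743–21,510,142).

Non-allelic homologous recombination between module *a* of one haplotype's
LCR22A and module *d* of another's LCR22D, at offset *x* inside the module,
yields the deletion product

    product = A-side[1 .. a-1] + chimera(a5′..x, d x..3′) + D-side distal of d

with everything between — including any chr11 material translocated onto
the A-side donor — absent. The chimeric module's 5′ fingerprint names the
LCR22A donor, its 3′ fingerprint and the flanking-inversion state name the
LCR22D donor, and the fingerprint-free interior bounds the breakpoint
ambiguity. The package implements this algebra forward (simulation) and
inverse (inference), with a trio STRP layer for parent-of-origin: a marker
is informative when the hemizygous proband's allele matches one parent and
neither allele of the other (≥3 concordant informative markers required).

Everything runs on a miniature two-chromosome coordinate system (~5.5 Mbp
"chr22", ~1 Mbp "chr11") that keeps the published junction and inversion
coordinates meaningful; see `docs/methods.md` for the full model, error
model, and algorithms.

## Worked example

```python
from lcr22map import (build_family_catalog, simulate_homolog, NoiseParams,
                      filter_molecules, module_inventory, region_candidates,
                      chain_modules, localize_nahr, assign_parent_of_origin,
                      simulate_strp_trio, interpret_quadrivalent)

cat = build_family_catalog()          # the published family's structures
arch = cat.arch
father = cat.individuals["father"]

# simulate molecules from the father's der(22) and re-chain its LCR22A array
mols = filter_molecules(
    simulate_homolog(arch, father["der22"], coverage=50,
                     params=NoiseParams(), seed=12),
    min_length=160_000)
call = chain_modules(mols, arch,
                     region_candidates(arch, "LCR22A",
                                       module_inventory(father.values(),
                                                        "LCR22A")))
print(call.copy_number, call.orientations, call.assignments)
# 3 ['reference', 'inverted', 'reference'] ['DA1', 'DA2', 'DA3']

# parent of origin from the trio STRP table
origin = assign_parent_of_origin(simulate_strp_trio(cat, "father", seed=3))
print(origin.parent, origin.informative_count)
# father 5

# localize the NAHR donors on the proband's deletion-containing haplotype
a = {n: h for n, h in father.items() if h.array_block("LCR22A")}
d = {n: h for n, h in father.items() if h.array_block("LCR22D")}
part = localize_nahr(cat.individuals["proband"]["del_hap"], a, d, arch)
print(part.donor_a, part.donor_d, part.fp3_label_count)
# ('der22', 3) ('chr22_intact', 1) 4
```

The chained der(22) carries three 160 kbp modules (reference, inverted,
reference from 5′ to 3′); five of eight STRP markers are informative and
all name the father; and the proband's deletion haplotype is assigned to
the der(22)'s terminal LCR22A module × the intact chromosome 22's LCR22D
module — the proband's 3′ fingerprint locus carries the LCR22D donor's 4
labels. `interpret_quadrivalent(origin, part, cat)` then verifies that the
rebuilt product matches the proband's haplotype and reports the excluded
chr11 segment (the proband inherits the deletion but not the
translocation).

## Command line

```
lcr22map simulate    --seed 7 --out run/          # BNX-mini + STRP CSV + truth
lcr22map reconstruct --in run/ --out run/         # calls.json + XMAP-like files
lcr22map infer       --in run/ --out run/         # report.json
```

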