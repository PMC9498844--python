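"""Parent-of-origin and NAHR donor/breakpoint inference.

Two independent lines of evidence identify the meiotic event behind a
22q11.2 deletion:

* STRP genetics - at a marker inside the deleted region the hemizygous
  proband carries a single allele; when that allele matches one parent and
  neither allele of the other parent, the other parent's contribution is
  missing and that parent is the parent of deletion origin (an *informative*
  marker).  A minimum number of concordant informative markers is required
  for the assignment.

* Label fingerprints - the deletion-containing haplotype is a mosaic of the
  two donor haplotypes.  Polymorphic fingerprint labels that differ between
  the candidate LCR22A and LCR22D donor modules are scored for presence in
  the proband's map: sites attributable only to an LCR22A candidate confirm
  the proximal (A) side, sites attributable only to an LCR22D candidate
  confirm the distal (D) side, and the fingerprint-free stretch in between
  remains ambiguous.  The flanking-inversion state of LCR22D is a second,
  independent marker of the D donor.

The final step checks the whole inference for self-consistency: rebuilding
the deletion product from the inferred donors must reproduce the proband's
observed haplotype (the quadrivalent interpretation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import haplotype_model as hm
from .errors import (BoundsError, DataConsistencyError, HomologyError,
                     InconsistentMarkersError, InsufficientMarkersError,
                     IrreconcilableDonorsError, ModelInconsistencyError)
from .synthetic_data import StrpTable

# --------------------------------------------------------------------------- #
# STRP parent-of-origin
# --------------------------------------------------------------------------- #

INFORMATIVE_FATHER_DELETED = "informative_father_deleted"
INFORMATIVE_MOTHER_DELETED = "informative_mother_deleted"
UNINFORMATIVE = "uninformative"


@dataclass
class MarkerCall:
    marker: str
    status: str
    rationale: str = ""
    flagged: bool = False          # atypical pattern (allele in neither parent)


@dataclass
class OriginCall:
    parent: str
    informative_count: int
    marker_calls: list[MarkerCall] = field(default_factory=list)


def classify_marker(proband: Sequence[int], mother: Sequence[int],
                    father: Sequence[int], marker: str = "marker",
                    size_tol: int = 0) -> MarkerCall:
    """Classify one STRP marker of a deletion trio.

    The proband, hemizygous across the deleted region, must show a single
    allele size (two distinct sizes raise
    :class:`DataConsistencyError`).  The marker is informative when that
    allele occurs in exactly one parent's genotype; the non-transmitting
    parent is called as deleted.  An allele present in both parents cannot
    distinguish them; an allele present in neither is atypical and is
    classified uninformative with a flag rather than guessed.

    ``size_tol`` allows near-matches in fragment size (off by default:
    simulated sizes are exact).
    """
    alleles = sorted(set(int(a) for a in proband))
    if len(alleles) != 1:
        raise DataConsistencyError(
            f"{marker}: proband shows {len(alleles)} distinct alleles in the "
            "hemizygous region")
    a = alleles[0]

    def has(genotype: Sequence[int]) -> bool:
        return any(abs(a - int(g)) <= size_tol for g in genotype)

    in_mother, in_father = has(mother), has(father)
    if in_mother and not in_father:
        return MarkerCall(marker, INFORMATIVE_FATHER_DELETED,
                          f"allele {a} matches mother, missing from father")
    if in_father and not in_mother:
        return MarkerCall(marker, INFORMATIVE_MOTHER_DELETED,
                          f"allele {a} matches father, missing from mother")
    if in_mother and in_father:
        return MarkerCall(marker, UNINFORMATIVE,
                          f"allele {a} present in both parents")
    return MarkerCall(marker, UNINFORMATIVE,
                      f"allele {a} absent from both parents (atypical)",
                      flagged=True)


def assign_parent_of_origin(table: StrpTable, min_informative: int = 3,
                            size_tol: int = 0) -> OriginCall:
    """Assign the parent of deletion origin from a trio STRP table.

    Requires at least ``min_informative`` informative markers
    (:class:`InsufficientMarkersError` otherwise) that all name the same
    parent (:class:`InconsistentMarkersError` on conflict).
    """
    calls = [classify_marker(table.alleles(m, "proband"),
                             table.alleles(m, "mother"),
                             table.alleles(m, "father"),
                             marker=m, size_tol=size_tol)
             for m in table.markers]
    n_father = sum(c.status == INFORMATIVE_FATHER_DELETED for c in calls)
    n_mother = sum(c.status == INFORMATIVE_MOTHER_DELETED for c in calls)
    if n_father > 0 and n_mother > 0:
        raise InconsistentMarkersError(
            f"informative markers conflict: {n_father} name the father, "
            f"{n_mother} the mother")
    winner, count = ("father", n_father) if n_father else ("mother", n_mother)
    if count < min_informative:
        raise InsufficientMarkersError(
            f"{count} informative markers, need {min_informative}")
    return OriginCall(parent=winner, informative_count=count,
                      marker_calls=calls)


# --------------------------------------------------------------------------- #
# fingerprint-based NAHR localization
# --------------------------------------------------------------------------- #


@dataclass
class BreakpointPartition:
    """Partition of the proband's deletion-containing haplotype.

    Intervals are 1-based closed, on the proband haplotype frame:
    ``a_confirmed`` runs from the 5' end through the last label site
    attributable only to the LCR22A donor, ``d_confirmed`` from the first
    site attributable only to the LCR22D donor through the 3' end, and
    ``ambiguous`` is the fingerprint-free gap between them, inside which the
    crossover cannot be placed.  Donor identities are (homolog name, 1-based
    module index) pairs."""

    a_confirmed: tuple[int, int]
    ambiguous: tuple[int, int]
    d_confirmed: tuple[int, int]
    donor_a: tuple[str, int]
    donor_d: tuple[str, int]
    a_sites: list[int] = field(default_factory=list)   # proband-frame positions
    d_sites: list[int] = field(default_factory=list)
    fp3_label_count: int = 0       # labels in the terminal module's 3' window
    status: str = "ok"             # 'ok' | 'fully_ambiguous'
    meta: dict = field(default_factory=dict)


def _observed_slots(arch: hm.Architecture, map_pos: np.ndarray,
                    placed_start: int, orientation: str,
                    tol: float) -> dict:
    """Presence of every fingerprint slot of a placed module on a label map."""
    obs = {}
    for window, offs in (("fp5", arch.slot5), ("fp3", arch.slot3)):
        for s, off in enumerate(offs):
            placed = placed_start + (off if orientation == hm.ORIENT_REF
                                     else hm.MODULE_LEN - off)
            k = np.searchsorted(map_pos, placed)
            present = any(0 <= c < map_pos.size and abs(map_pos[c] - placed) <= tol
                          for c in (k - 1, k))
            obs[(window, s)] = present
    return obs


def _module_pattern(mod: hm.ModuleUnit) -> dict:
    return {("fp5", s): s in mod.fingerprint5 for s in range(hm.N_SLOTS)} | \
           {("fp3", s): s in mod.fingerprint3 for s in range(hm.N_SLOTS)}


def _inversion_state(h: hm.Homolog) -> str | None:
    b = h.inversion_block()
    return b.orientation if b is not None else None


def localize_nahr(proband_hap: hm.Homolog,
                  a_candidates: Mapping[str, hm.Homolog],
                  d_candidates: Mapping[str, hm.Homolog],
                  arch: hm.Architecture,
                  tol: float = 1000.0) -> BreakpointPartition:
    """Locate the NAHR donors and breakpoint on the deletion haplotype.

    The proband's merged module array carries ``k`` modules: the first
    ``k-1`` plus the 5' part of the terminal (recombinant) module descend
    from the LCR22A donor, the 3' part of the terminal module and everything
    distal from the LCR22D donor.  A candidate pair (one homolog per side)
    is consistent when the proband's upstream modules, terminal-module
    fingerprint windows (5' for A, 3' for D) and LCR22D flanking-inversion
    state all match; exactly one consistent pair is required
    (:class:`IrreconcilableDonorsError` otherwise).  The breakpoint is then
    bracketed by the discriminating label sites - present in one donor
    module and absent at the homologous position of the other - that the
    proband's map confirms on each side.
    """
    a_block = proband_hap.array_block("LCR22A")
    if a_block is None or not a_block.modules:
        raise IrreconcilableDonorsError("proband haplotype has no module array")
    map_pos = hm.synthesize_positions(arch, proband_hap)
    k = len(a_block.modules)
    t_start = a_block.start + (k - 1) * hm.MODULE_LEN
    t_orient = a_block.modules[k - 1].orientation
    obs_term = _observed_slots(arch, map_pos, t_start, t_orient, tol)
    obs_upstream = [
        (_observed_slots(arch, map_pos, a_block.start + i * hm.MODULE_LEN,
                         a_block.modules[i].orientation, tol),
         a_block.modules[i].orientation)
        for i in range(k - 1)]
    proband_inv = _inversion_state(proband_hap)

    def window_equal(obs: Mapping, pat: Mapping, window: str) -> bool:
        return all(obs[(window, s)] == pat[(window, s)]
                   for s in range(hm.N_SLOTS))

    a_ok: list[tuple[str, int, hm.ModuleUnit]] = []
    for name, hom in a_candidates.items():
        blk = hom.array_block("LCR22A")
        if blk is None or len(blk.modules) < k:
            continue
        good = all(
            mod_obs == _module_pattern(blk.modules[i]) and
            ori == blk.modules[i].orientation
            for i, (mod_obs, ori) in enumerate(obs_upstream))
        cand_mod = blk.modules[k - 1]
        if (good and cand_mod.orientation == t_orient
                and window_equal(obs_term, _module_pattern(cand_mod), "fp5")):
            a_ok.append((name, k, cand_mod))
    d_ok: list[tuple[str, int, hm.ModuleUnit]] = []
    for name, hom in d_candidates.items():
        blk = hom.array_block("LCR22D")
        if blk is None:
            continue
        for j, cand_mod in enumerate(blk.modules, start=1):
            if (cand_mod.orientation == t_orient
                    and window_equal(obs_term, _module_pattern(cand_mod), "fp3")
                    and _inversion_state(hom) == proband_inv):
                d_ok.append((name, j, cand_mod))
    if len(a_ok) != 1 or len(d_ok) != 1:
        raise IrreconcilableDonorsError(
            f"{len(a_ok)} LCR22A and {len(d_ok)} LCR22D candidates are "
            "consistent with the proband haplotype (need exactly 1 each)")
    (a_name, module_a, a_mod), (d_name, module_d, d_mod) = a_ok[0], d_ok[0]

    def placed(off: int) -> int:
        return t_start + (off if t_orient == hm.ORIENT_REF
                          else hm.MODULE_LEN - off)

    a_sites: list[int] = []
    d_sites: list[int] = []
    a_pat, d_pat = _module_pattern(a_mod), _module_pattern(d_mod)
    for window, offs in (("fp5", arch.slot5), ("fp3", arch.slot3)):
        for s, off in enumerate(offs):
            key = (window, s)
            if a_pat[key] == d_pat[key]:
                continue  # not discriminating for this pair
            if not obs_term[key]:
                continue  # absence is weak evidence (label dropout); unused
            if a_pat[key]:
                a_sites.append(placed(off))
            else:
                d_sites.append(placed(off))
    hap_lo, hap_hi = proband_hap.start, proband_hap.end
    status = "ok"
    if not a_sites and not d_sites:
        status = "fully_ambiguous"
    a_end = max(a_sites) if a_sites else t_start
    d_start = min(d_sites) if d_sites else t_start + hm.MODULE_LEN - 1
    fp3_lo = placed(hm.MODULE_LEN - hm.FP_WINDOW)
    fp3_hi = placed(hm.MODULE_LEN)
    fp3_lo, fp3_hi = min(fp3_lo, fp3_hi), max(fp3_lo, fp3_hi)
    n_fp3 = int(np.sum((map_pos >= fp3_lo) & (map_pos <= fp3_hi)))
    return BreakpointPartition(
        a_confirmed=(hap_lo, int(a_end)),
        ambiguous=(int(a_end) + 1, int(d_start) - 1),
        d_confirmed=(int(d_start), hap_hi),
        donor_a=(a_name, module_a), donor_d=(d_name, module_d),
        a_sites=sorted(int(p) for p in a_sites),
        d_sites=sorted(int(p) for p in d_sites),
        fp3_label_count=n_fp3, status=status,
        meta={"terminal_module_start": int(t_start),
              "terminal_orientation": t_orient,
              "copy_number": k})


# --------------------------------------------------------------------------- #
# quadrivalent interpretation
# --------------------------------------------------------------------------- #


def interpret_quadrivalent(origin: OriginCall,
                           partition: BreakpointPartition,
                           catalog: hm.FamilyCatalog,
                           proband_hap: hm.Homolog | None = None
                           ) -> hm.RecombinationEvent:
    """Close the loop: rebuild the deletion product from the inferred donors
    and verify it reproduces the proband's deletion-containing haplotype.

    In the translocation-carrier quadrivalent, the exchange pairs the LCR22A
    region of one chromosome-22-bearing homolog with the LCR22D region of
    another; material between the donor loci - including any chr11 segment
    translocated onto the A-side donor - is excluded from the product.
    Raises :class:`ModelInconsistencyError` when the rebuilt product differs
    structurally from the proband haplotype.
    """
    arch = catalog.arch
    parent_homs = catalog.individuals[origin.parent]
    a_name, module_a = partition.donor_a
    d_name, module_d = partition.donor_d
    if a_name not in parent_homs or d_name not in parent_homs:
        raise ModelInconsistencyError(
            f"donors {a_name}/{d_name} not found in {origin.parent}'s catalog")
    if proband_hap is None:
        proband_hap = catalog.individuals["proband"]["del_hap"]
    t_start = partition.meta.get(
        "terminal_module_start",
        partition.a_confirmed[1])
    amb_lo, amb_hi = partition.ambiguous
    offset = int(round((amb_lo + amb_hi) / 2)) - int(t_start)
    offset = min(max(offset, 1), hm.MODULE_LEN - 1)
    try:
        event = hm.nahr_product(parent_homs[a_name], parent_homs[d_name],
                                module_a, module_d, offset, arch)
    except (HomologyError, BoundsError) as e:
        raise ModelInconsistencyError(
            f"donors {a_name} x {d_name} cannot recombine: {e}") from e
    if not hm.structure_equal(arch, event.product, proband_hap):
        raise ModelInconsistencyError(
            f"product of {a_name} x {d_name} does not match the proband's "
            "deletion-containing haplotype")
    a_hom = parent_homs[a_name]
    a_blk = a_hom.array_block("LCR22A")
    excluded = [
        {"kind": b.kind, "ref_name": b.ref_name,
         "ref_span": [b.ref_start, b.ref_end]}
        for b in a_hom.blocks if b.start > a_blk.end
    ]
    event.meta["excluded_from_product"] = excluded
    event.meta["translocation_excluded"] = any(
        b["kind"] == "chr11_segment" for b in excluded)
    return event
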