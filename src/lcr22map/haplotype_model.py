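"""Regional architecture of the 22q11.2 LCR22 repeats and the family homolog catalog.

The chromosome-22-specific low copy repeats LCR22A-LCR22D flank the common ~3 Mbp
22q11.2 deletion.  LCR22A and LCR22D contain tandem 160 kbp duplicon modules that
vary in copy number and orientation between haplotypes; paralogous copies share a
nearly identical interior label template (>95% identity) and are told apart by
polymorphic DLE-1 label "fingerprints" at their 5' and 3' ends.  The palindromic
AT-rich repeat (PATRR) in LCR22B mediates the recurrent t(11;22) reciprocal
translocation, producing the derivative chromosomes der(11) and der(22).

Everything here lives on a miniature two-chromosome coordinate system: one
"chr22" of ~5.5 Mbp spanning a centromere-proximal unique anchor through the
distal LCR22D anchor, and one "chr11" of ~1 Mbp around the 11q23 PATRR.  The
printed genomic positions that matter - the translocation junction near
chr22:20,318,054-20,351,331 / chr11:116,811,929-116,824,680 and the LCR22D
flanking inversion at 21,424,743-21,510,142 - keep their values on this
miniature system, so they stay directly comparable with the literature.

Coordinates are 1-based with closed intervals (CMAP convention).  Each homolog
carries an ordered list of :class:`Block` objects; label maps are realized from
blocks by :func:`synthesize_label_map`.  The non-allelic homologous recombination
(NAHR) product algebra is :func:`nahr_product`.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import BoundsError, HomologyError, ParseError, StructureError

# --------------------------------------------------------------------------- #
# miniature coordinate system (all positions 1-based, closed intervals)
# --------------------------------------------------------------------------- #

MODULE_LEN = 160_000            # tandem duplicon module length
FP_WINDOW = 15_000              # 5'/3' fingerprint window width within a module
N_SLOTS = 6                     # polymorphic label slots per fingerprint window

# The reference layout (single reference-orientation module in each of LCR22A
# and LCR22D, no inversion) pins the printed coordinates; every unique block
# is the same material on every homolog, so homolog lengths vary with module
# copy number while reference-frame provenance stays printed-coordinate true.
CHR22_START = 18_900_000
A_ARRAY_START = 19_300_000      # LCR22A module array (reference frame)
B_START = 20_250_000
PATRR22 = 20_334_692            # t(11;22) junction point on chr22 (in LCR22B)
B_END = 20_429_999
C_SPACER_START = 20_430_000     # LCR22B distal part + LCR22C reduced to unique anchor
INV_START = 21_424_743          # LCR22D flanking inversion, printed span
INV_END = 21_510_142
INV_NOMINAL_LEN = 64_000        # nominal size quoted for the inversion
D_ANCHOR_START = INV_END + 1
CHR22_END = 24_400_000

CHR11_START = 116_300_000
PATRR11 = 116_818_305           # t(11;22) junction point on chr11 (11q23)
CHR11_END = 117_300_000

P_ANCHOR_LEN = A_ARRAY_START - CHR22_START                    # 400 kbp
AB_SPACER_LEN = B_START - (A_ARRAY_START + MODULE_LEN)        # 790 kbp
B_PROX_LEN = PATRR22 - B_START + 1
B_DIST_LEN = B_END - PATRR22
D_ARRAY_REF_START = INV_START - MODULE_LEN                    # 21,264,743
C_SPACER_LEN = D_ARRAY_REF_START - C_SPACER_START             # 834,743
INV_LEN = INV_END - INV_START + 1                             # 85,400
D_ANCHOR_LEN = CHR22_END - D_ANCHOR_START + 1
CHR11_PROX_LEN = PATRR11 - CHR11_START
CHR11_DIST_LEN = CHR11_END - PATRR11 + 1

# printed junction intervals, kept for reference and used by tests of the
# translocation machinery
JUNCTION_CHR22 = (20_318_054, 20_351_331)
JUNCTION_CHR11 = (116_811_929, 116_824_680)

DEFAULT_ARCH_SEED = 2211

ORIENT_REF = "reference"
ORIENT_INV = "inverted"

_UNIQUE_REGIONS = {
    # name: (length, mean label spacing); 'array side' records which edge of
    # the block abuts a module array (used to window chaining flank templates)
    "p_anchor": (P_ANCHOR_LEN, 6000),
    "ab_spacer": (AB_SPACER_LEN, 6000),
    "b_prox": (B_PROX_LEN, 6000),
    "b_dist": (B_DIST_LEN, 6000),
    "c_spacer": (C_SPACER_LEN, 6000),
    "inv_seg": (INV_LEN, 6000),
    "d_anchor": (D_ANCHOR_LEN, 6000),
    "chr11_prox": (CHR11_PROX_LEN, 6000),
    "chr11_dist": (CHR11_DIST_LEN, 6000),
}

ARRAY_SIDE = {"p_anchor": "end", "ab_spacer": "start",
              "c_spacer": "end", "inv_seg": "start"}


def _jitter_offsets(rng: np.random.Generator, span: float, lo: float, hi: float,
                    start: float = 0.0) -> tuple[int, ...]:
    """Label offsets with jittered spacing, covering [start, span)."""
    out = []
    pos = start + rng.uniform(lo, hi)
    while pos < span:
        out.append(int(round(pos)))
        pos += rng.uniform(lo, hi)
    return tuple(out)


@dataclass(frozen=True)
class Architecture:
    """Seeded label templates shared by every homolog of a catalog.

    ``core_offsets`` is the non-polymorphic interior label template of the
    160 kbp module (identical in all copies, LCR22A and LCR22D alike - this is
    what makes paralogous copies ambiguous away from their fingerprint ends).
    ``slot5``/``slot3`` are the module-local positions of the polymorphic
    fingerprint label slots; a module copy's fingerprint is a presence pattern
    over these slots.  ``unique`` holds the label templates of the unique
    (non-duplicated) blocks.
    """

    seed: int
    core_offsets: tuple[int, ...]
    slot5: tuple[int, ...]
    slot3: tuple[int, ...]
    unique: Mapping[str, tuple[int, ...]]

    @classmethod
    def build(cls, seed: int = DEFAULT_ARCH_SEED) -> "Architecture":
        rng = np.random.default_rng([seed, 0])
        core = _jitter_offsets(rng, span=MODULE_LEN - FP_WINDOW - 1000,
                               lo=4500, hi=7500, start=FP_WINDOW + 1000)
        s5rng = np.random.default_rng([seed, 1])
        slot5 = tuple(int(round(p)) for p in
                      1200 + np.cumsum(s5rng.uniform(1600, 2100, N_SLOTS)))
        s3rng = np.random.default_rng([seed, 2])
        slot3 = tuple(int(round(p)) for p in
                      MODULE_LEN - FP_WINDOW + 1200
                      + np.cumsum(s3rng.uniform(1600, 2100, N_SLOTS)))
        unique = {}
        for code, (name, (length, spacing)) in enumerate(_UNIQUE_REGIONS.items()):
            urng = np.random.default_rng([seed, 10 + code])
            unique[name] = _jitter_offsets(urng, length, spacing * 0.75, spacing * 1.25)
        return cls(seed=seed, core_offsets=core, slot5=slot5, slot3=slot3, unique=unique)

    def unique_labels(self, name: str, length: int | None = None) -> np.ndarray:
        """Offsets-from-block-start of the labels of unique region ``name``
        (the same material on every homolog; ``length`` defaults to the
        region's fixed length and only truncates for sub-windows)."""
        offs = np.asarray(self.unique[name], dtype=float)
        if length is not None:
            offs = offs[offs < length]
        return offs


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class LabelSite:
    """One DLE-1 label on a realized homolog map (position in the homolog's
    local 1-based frame; ``polymorphic`` marks fingerprint-slot labels)."""

    position: int
    site_id: str
    polymorphic: bool = False


@dataclass(frozen=True)
class ModuleUnit:
    """One 160 kbp duplicon copy.

    ``fingerprint5``/``fingerprint3`` are the sorted slot indices (into
    ``Architecture.slot5``/``slot3``) at which this copy carries a label.
    ``core_sites`` is the shared interior template - identical across all
    copies by construction.
    """

    uid: str
    orientation: str = ORIENT_REF
    length: int = MODULE_LEN
    fingerprint5: tuple[int, ...] = ()
    fingerprint3: tuple[int, ...] = ()
    core_sites: tuple[int, ...] = ()

    def __post_init__(self):
        if self.orientation not in (ORIENT_REF, ORIENT_INV):
            raise StructureError(f"bad orientation {self.orientation!r}")
        for s in (*self.fingerprint5, *self.fingerprint3):
            if not 0 <= s < N_SLOTS:
                raise BoundsError(f"fingerprint slot {s} out of range")


@dataclass
class Block:
    """One structural block of a homolog.

    ``start`` is the block's local (homolog-frame) 1-based start; ``ref_name``
    and ``ref_start`` record coordinate provenance on the miniature reference
    (chr22 or chr11).  ``template`` names the unique-region label template for
    non-array blocks; ``modules`` holds the ordered duplicon copies of a
    ``module_array`` block.  Inversion blocks additionally carry the nominal
    length quoted for the LCR22D flanking inversion, which differs from the
    printed span they occupy.
    """

    kind: str                      # unique_anchor | module_array | inversion | chr11_segment | junction
    start: int
    length: int
    ref_name: str = "chr22"
    ref_start: int = 0
    orientation: str = ORIENT_REF
    template: str | None = None
    region: str | None = None      # LCR22A / LCR22D for module arrays
    modules: list[ModuleUnit] = field(default_factory=list)
    nominal_length: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length - 1


@dataclass
class Homolog:
    """An ordered block structure for one chromosome copy.

    ``identity`` is the chromosome class (chr22, chr11, der11, der22);
    ``name`` distinguishes homologs of the same class within a genome.
    ``junction`` is the (chr22 position, chr11 position) pair of the
    translocation breakpoint for derivative chromosomes, else ``None``.
    """

    identity: str
    name: str
    blocks: list[Block] = field(default_factory=list)
    junction: tuple[int, int] | None = None

    def validate(self) -> None:
        if self.identity in ("der22", "der11"):
            if self.junction is None:
                raise StructureError(f"{self.name}: derivative without junction")
        elif self.junction is not None:
            raise StructureError(f"{self.name}: non-derivative with junction")
        prev_end = None
        for b in self.blocks:
            if prev_end is not None and b.start <= prev_end:
                raise StructureError(
                    f"{self.name}: block at {b.start} overlaps previous end {prev_end}")
            prev_end = b.end

    # convenience accessors -------------------------------------------------
    def array_block(self, region: str) -> Block | None:
        for b in self.blocks:
            if b.kind == "module_array" and b.region == region:
                return b
        return None

    def inversion_block(self) -> Block | None:
        for b in self.blocks:
            if b.kind == "inversion":
                return b
        return None

    @property
    def start(self) -> int:
        return self.blocks[0].start if self.blocks else 1

    @property
    def end(self) -> int:
        return self.blocks[-1].end if self.blocks else 0


@dataclass
class RecombinationEvent:
    """An inter-homolog NAHR exchange and its deletion-bearing product.

    ``donor_a``/``donor_d`` are (homolog name, 1-based module index) pairs;
    intervals are on the product (proband-haplotype) local frame.
    ``deletion_size`` is the distance between the two breakpoint positions
    with both donor frames anchored at the shared proximal-anchor origin
    (the intact-chr22 frame for the LCR22D-side donor).
    """

    donor_a: tuple[str, int]
    donor_d: tuple[str, int]
    breakpoint_interval: tuple[int, int]
    ambiguous_interval: tuple[int, int]
    product: Homolog
    deletion_size: int = 0
    meta: dict = field(default_factory=dict)


@dataclass
class FamilyCatalog:
    """The homolog inventory of one nuclear family.

    ``individuals`` maps individual name -> homolog name -> :class:`Homolog`.
    ``meta`` records the generating truth of the deletion event (parent of
    deletion origin, donor pair, within-module offset) for evaluation.
    """

    arch: Architecture
    individuals: dict[str, dict[str, Homolog]]
    meta: dict = field(default_factory=dict)

    def homolog(self, individual: str, name: str) -> Homolog:
        return self.individuals[individual][name]


# --------------------------------------------------------------------------- #
# fixture fingerprints (family of the t(11;22) translocation carrier)
# --------------------------------------------------------------------------- #

# Slot-presence patterns per module copy, (fingerprint5, fingerprint3).
# The pair that matters for breakpoint localization is DA3 (the 3'-most LCR22A
# module of the father's der(22)) against FD1 (the LCR22D module of his intact
# chromosome 22): at the 5' locus DA3 carries 5 labels and FD1 the subset of 4
# missing slot 1 (the 2nd of DA3's five), so slot 1 is the only 5'
# discriminating site; at the 3' locus DA3 carries 3 labels and FD1 those 3
# plus slot 0 (first in the window), the only 3' discriminating site.
FIXTURE_PATTERNS: dict[str, tuple[tuple[int, ...], tuple[int, ...]]] = {
    "FA1": ((0, 4, 5), (0, 1, 4)),
    "DA1": ((0, 1, 3), (0, 2, 4)),
    "DA2": ((1, 2, 5), (1, 3, 5)),
    "DA3": ((0, 1, 2, 3, 4), (1, 2, 3)),
    "FD1": ((0, 2, 3, 4), (0, 1, 2, 3)),
    "FD2": ((1, 3, 4), (2, 3, 5)),
    "MA1": ((0, 2, 5), (0, 3, 4)),
    "MA2": ((1, 4, 5), (2, 4, 5)),
    "MA3": ((0, 3, 5), (0, 1, 5)),
    "MA4": ((2, 3, 4), (1, 2, 5)),
    "MA5": ((0, 1, 5), (0, 2, 5)),
    "MA6": ((2, 4, 5), (0, 4, 5)),
    "MD1": ((1, 2, 4), (1, 4, 5)),
    "MD2": ((0, 1, 4), (2, 3, 4)),
}

FIXTURE_NAHR_OFFSET = 80_000    # within-module offset of the fixture NAHR event


def make_module(arch: Architecture, uid: str, orientation: str = ORIENT_REF,
                fp5: Iterable[int] = (), fp3: Iterable[int] = ()) -> ModuleUnit:
    return ModuleUnit(uid=uid, orientation=orientation,
                      fingerprint5=tuple(sorted(fp5)), fingerprint3=tuple(sorted(fp3)),
                      core_sites=arch.core_offsets)


def _fixture_module(arch: Architecture, uid: str, orientation: str) -> ModuleUnit:
    fp5, fp3 = FIXTURE_PATTERNS[uid]
    return make_module(arch, uid, orientation, fp5, fp3)


# --------------------------------------------------------------------------- #
# homolog builders
# --------------------------------------------------------------------------- #


def _append(blocks: list[Block], **kw) -> Block:
    start = blocks[-1].end + 1 if blocks else kw.pop("origin")
    kw.pop("origin", None)
    b = Block(start=start, **kw)
    blocks.append(b)
    return b


def build_intact_chr22(arch: Architecture, name: str,
                       a_modules: Sequence[ModuleUnit],
                       d_modules: Sequence[ModuleUnit],
                       inversion: bool) -> Homolog:
    """An intact chromosome 22 homolog: proximal anchor, LCR22A module array,
    unique spacer, LCR22B (split at the PATRR point), LCR22C-region spacer,
    LCR22D module array, flanking-inversion segment, distal anchor.  Local
    coordinates accumulate (copy-number expansions lengthen the homolog);
    ``ref_start`` records reference-frame provenance."""
    blocks: list[Block] = []
    _append(blocks, origin=CHR22_START, kind="unique_anchor",
            length=P_ANCHOR_LEN, ref_start=CHR22_START, template="p_anchor")
    if a_modules:
        _append(blocks, kind="module_array", region="LCR22A",
                length=MODULE_LEN * len(a_modules), ref_start=A_ARRAY_START,
                modules=list(a_modules))
    _append(blocks, kind="unique_anchor", length=AB_SPACER_LEN,
            ref_start=A_ARRAY_START + MODULE_LEN, template="ab_spacer")
    _append(blocks, kind="unique_anchor", length=B_PROX_LEN,
            ref_start=B_START, template="b_prox")
    _append(blocks, kind="unique_anchor", length=B_DIST_LEN,
            ref_start=PATRR22 + 1, template="b_dist")
    _append(blocks, kind="unique_anchor", length=C_SPACER_LEN,
            ref_start=C_SPACER_START, template="c_spacer")
    if d_modules:
        _append(blocks, kind="module_array", region="LCR22D",
                length=MODULE_LEN * len(d_modules),
                ref_start=INV_START - MODULE_LEN * len(d_modules),
                modules=list(d_modules))
    _append(blocks, kind="inversion", length=INV_LEN,
            ref_start=INV_START, template="inv_seg",
            orientation=ORIENT_INV if inversion else ORIENT_REF,
            nominal_length=INV_NOMINAL_LEN)
    _append(blocks, kind="unique_anchor", length=D_ANCHOR_LEN,
            ref_start=D_ANCHOR_START, template="d_anchor")
    h = Homolog(identity="chr22", name=name, blocks=blocks)
    h.validate()
    return h


def build_deletion_haplotype(arch: Architecture, name: str,
                             a_modules: Sequence[ModuleUnit],
                             inversion: bool) -> Homolog:
    """A deletion-containing chromosome 22: proximal anchor, the merged
    module array (whose terminal copy is the recombinant module), then
    LCR22D distal material - inversion segment and distal anchor - with the
    entire LCR22A-LCR22D interior absent.  Used to realize reconstructed
    deletion haplotypes from called structures."""
    blocks: list[Block] = []
    _append(blocks, origin=CHR22_START, kind="unique_anchor",
            length=P_ANCHOR_LEN, ref_start=CHR22_START, template="p_anchor")
    _append(blocks, kind="module_array", region="LCR22A",
            length=MODULE_LEN * len(a_modules), ref_start=A_ARRAY_START,
            modules=list(a_modules))
    _append(blocks, kind="inversion", length=INV_LEN,
            ref_start=INV_START, template="inv_seg",
            orientation=ORIENT_INV if inversion else ORIENT_REF,
            nominal_length=INV_NOMINAL_LEN)
    _append(blocks, kind="unique_anchor", length=D_ANCHOR_LEN,
            ref_start=D_ANCHOR_START, template="d_anchor")
    h = Homolog(identity="chr22", name=name, blocks=blocks)
    h.validate()
    return h


def build_intact_chr11(arch: Architecture, name: str) -> Homolog:
    blocks: list[Block] = []
    _append(blocks, origin=CHR11_START, kind="chr11_segment", ref_name="chr11",
            length=CHR11_PROX_LEN, ref_start=CHR11_START,
            template="chr11_prox")
    _append(blocks, kind="chr11_segment", ref_name="chr11",
            length=CHR11_DIST_LEN, ref_start=PATRR11, template="chr11_dist")
    h = Homolog(identity="chr11", name=name, blocks=blocks)
    h.validate()
    return h


def build_der22(arch: Architecture, name: str,
                a_modules: Sequence[ModuleUnit]) -> Homolog:
    """der(22): chr22 material from the proximal anchor through LCR22A to the
    proximal part of LCR22B, joined at the PATRR to distal chr11 (11q23-qter).
    The junction is stored in reference-frame coordinates."""
    blocks: list[Block] = []
    _append(blocks, origin=CHR22_START, kind="unique_anchor",
            length=P_ANCHOR_LEN, ref_start=CHR22_START, template="p_anchor")
    _append(blocks, kind="module_array", region="LCR22A",
            length=MODULE_LEN * len(a_modules), ref_start=A_ARRAY_START,
            modules=list(a_modules))
    _append(blocks, kind="unique_anchor", length=AB_SPACER_LEN,
            ref_start=A_ARRAY_START + MODULE_LEN, template="ab_spacer")
    _append(blocks, kind="unique_anchor", length=B_PROX_LEN,
            ref_start=B_START, template="b_prox")
    _append(blocks, kind="chr11_segment", ref_name="chr11",
            length=CHR11_DIST_LEN, ref_start=PATRR11, template="chr11_dist")
    h = Homolog(identity="der22", name=name, blocks=blocks,
                junction=(PATRR22, PATRR11))
    h.validate()
    return h


def build_der11(arch: Architecture, name: str,
                d_modules: Sequence[ModuleUnit], inversion: bool) -> Homolog:
    """der(11): proximal chr11 through the 11q23 PATRR, joined to the distal
    part of LCR22B and the remainder of chr22."""
    blocks: list[Block] = []
    _append(blocks, origin=CHR11_START, kind="chr11_segment", ref_name="chr11",
            length=CHR11_PROX_LEN, ref_start=CHR11_START,
            template="chr11_prox")
    _append(blocks, kind="unique_anchor", length=B_DIST_LEN,
            ref_start=PATRR22 + 1, template="b_dist")
    _append(blocks, kind="unique_anchor", length=C_SPACER_LEN,
            ref_start=C_SPACER_START, template="c_spacer")
    _append(blocks, kind="module_array", region="LCR22D",
            length=MODULE_LEN * len(d_modules),
            ref_start=INV_START - MODULE_LEN * len(d_modules),
            modules=list(d_modules))
    _append(blocks, kind="inversion", length=INV_LEN,
            ref_start=INV_START, template="inv_seg",
            orientation=ORIENT_INV if inversion else ORIENT_REF,
            nominal_length=INV_NOMINAL_LEN)
    _append(blocks, kind="unique_anchor", length=D_ANCHOR_LEN,
            ref_start=D_ANCHOR_START, template="d_anchor")
    h = Homolog(identity="der11", name=name, blocks=blocks,
                junction=(PATRR22, PATRR11))
    h.validate()
    return h


def _renamed(h: Homolog, name: str) -> Homolog:
    out = _copy.deepcopy(h)
    out.name = name
    return out


def build_family_catalog(seed: int = DEFAULT_ARCH_SEED) -> FamilyCatalog:
    """The published family: a t(11;22) translocation-carrier father who is the
    parent of deletion origin, an unaffected mother, the 22q11.2DS proband and
    an unaffected sibling.

    Father, three chromosome-22-bearing homologs of interest: the intact chr22
    (single inverted 160 kbp LCR22A module; single reference-orientation LCR22D
    module with the flanking inversion), the der(11) (single reference LCR22D
    module, no inversion) and the der(22) (three LCR22A modules oriented
    reference, inverted, reference from 5' to 3').  Mother: homolog #1 with
    five LCR22A modules (inverted, inverted, reference, inverted, reference)
    and no LCR22D inversion; homolog #2 with a single reference LCR22A module
    and the LCR22D inversion.  The proband's deletion-containing haplotype is
    the NAHR product of the father's der(22) LCR22A (terminal module) with his
    intact chr22 LCR22D; the proband's other chr22 is the mother's homolog #1.
    The sibling inherited the father's intact chr22 (and the mother's homolog
    #2).  Module fingerprints are deterministic functions of ``seed``.
    """
    arch = Architecture.build(seed)
    fm = lambda uid, ori: _fixture_module(arch, uid, ori)

    father_intact = build_intact_chr22(
        arch, "chr22_intact",
        a_modules=[fm("FA1", ORIENT_INV)],
        d_modules=[fm("FD1", ORIENT_REF)], inversion=True)
    father_der22 = build_der22(
        arch, "der22",
        a_modules=[fm("DA1", ORIENT_REF), fm("DA2", ORIENT_INV), fm("DA3", ORIENT_REF)])
    father_der11 = build_der11(
        arch, "der11", d_modules=[fm("FD2", ORIENT_REF)], inversion=False)
    mother_h1 = build_intact_chr22(
        arch, "chr22_h1",
        a_modules=[fm("MA1", ORIENT_INV), fm("MA2", ORIENT_INV), fm("MA3", ORIENT_REF),
                   fm("MA4", ORIENT_INV), fm("MA5", ORIENT_REF)],
        d_modules=[fm("MD1", ORIENT_REF)], inversion=False)
    mother_h2 = build_intact_chr22(
        arch, "chr22_h2",
        a_modules=[fm("MA6", ORIENT_REF)],
        d_modules=[fm("MD2", ORIENT_REF)], inversion=True)

    event = nahr_product(father_der22, father_intact, 3, 1, FIXTURE_NAHR_OFFSET)
    del_hap = _renamed(event.product, "del_hap")

    individuals = {
        "father": {
            "chr22_intact": father_intact,
            "der11": father_der11,
            "der22": father_der22,
            "chr11": build_intact_chr11(arch, "chr11"),
        },
        "mother": {
            "chr22_h1": mother_h1,
            "chr22_h2": mother_h2,
            "chr11_a": build_intact_chr11(arch, "chr11_a"),
            "chr11_b": build_intact_chr11(arch, "chr11_b"),
        },
        "proband": {
            "del_hap": del_hap,
            "chr22_maternal": _renamed(mother_h1, "chr22_maternal"),
            "chr11_pat": build_intact_chr11(arch, "chr11_pat"),
            "chr11_mat": build_intact_chr11(arch, "chr11_mat"),
        },
        "sibling": {
            "chr22_paternal": _renamed(father_intact, "chr22_paternal"),
            "chr22_maternal": _renamed(mother_h2, "chr22_maternal"),
            "chr11_pat": build_intact_chr11(arch, "chr11_pat"),
            "chr11_mat": build_intact_chr11(arch, "chr11_mat"),
        },
    }
    meta = {
        "deletion_parent": "father",
        "donor_a": ["der22", 3],
        "donor_d": ["chr22_intact", 1],
        "offset": FIXTURE_NAHR_OFFSET,
    }
    return FamilyCatalog(arch=arch, individuals=individuals, meta=meta)


# --------------------------------------------------------------------------- #
# label map synthesis
# --------------------------------------------------------------------------- #


def _module_sites(arch: Architecture, mod: ModuleUnit, placed_start: int,
                  tag: str) -> list[LabelSite]:
    """Realize one module copy at local start ``placed_start``; inverted copies
    emit their template mirrored about the module midpoint."""
    sites = []

    def place(offset: int) -> int:
        if mod.orientation == ORIENT_INV:
            return placed_start + (mod.length - offset)
        return placed_start + offset

    for k, off in enumerate(mod.core_sites):
        sites.append(LabelSite(place(off), f"{tag}.core{k}", False))
    for s in mod.fingerprint5:
        sites.append(LabelSite(place(arch.slot5[s]), f"{tag}.fp5s{s}", True))
    for s in mod.fingerprint3:
        sites.append(LabelSite(place(arch.slot3[s]), f"{tag}.fp3s{s}", True))
    return sites


def synthesize_label_map(arch: Architecture, homolog: Homolog) -> list[LabelSite]:
    """Realize a homolog structure as an ordered in-silico label map.

    Positions are on the homolog's local 1-based frame (which coincides with
    miniature-chr22 coordinates for homologs that begin at the chr22 proximal
    anchor).  Inverted blocks emit their template mirrored about the block
    midpoint; each module copy contributes the shared core template plus its
    fingerprint-slot labels; derivative homologs switch coordinate provenance
    at the translocation junction, recorded per block.

    Raises :class:`StructureError` on overlapping blocks.
    """
    homolog.validate()
    sites: list[LabelSite] = []
    for bi, b in enumerate(homolog.blocks):
        if b.kind == "module_array":
            for mi, mod in enumerate(b.modules):
                placed_start = b.start + mi * MODULE_LEN
                sites.extend(_module_sites(arch, mod, placed_start,
                                           f"b{bi}.m{mi}"))
        else:
            offs = arch.unique_labels(b.template, b.length)
            if b.orientation == ORIENT_INV:
                offs = np.sort(b.length - 1 - offs)
            for k, off in enumerate(offs):
                sites.append(LabelSite(b.start + int(off), f"b{bi}.{b.template}{k}", False))
    sites.sort(key=lambda s: s.position)
    for a, bb in zip(sites, sites[1:]):
        if bb.position <= a.position:
            raise StructureError(
                f"{homolog.name}: non-increasing label positions near {a.position}")
    return sites


def synthesize_positions(arch: Architecture, homolog: Homolog) -> np.ndarray:
    """Label positions only, as a float array (convenience wrapper)."""
    return np.array([s.position for s in synthesize_label_map(arch, homolog)],
                    dtype=float)


def map_length(homolog: Homolog) -> int:
    return homolog.end - homolog.start + 1


# --------------------------------------------------------------------------- #
# NAHR product algebra
# --------------------------------------------------------------------------- #


def _chimeric_module(arch: Architecture, a_mod: ModuleUnit, d_mod: ModuleUnit,
                     offset: int) -> ModuleUnit:
    """The recombinant module: placed-proximal material (< ``offset`` in placed
    coordinates) from the LCR22A donor copy, distal material from the LCR22D
    donor copy.  For inverted donor pairs the placed offset maps to reference
    offset ``length - offset``."""
    inverted = a_mod.orientation == ORIENT_INV

    def source(ref_pos: int) -> ModuleUnit:
        placed = (a_mod.length - ref_pos) if inverted else ref_pos
        return a_mod if placed <= offset else d_mod

    fp5 = tuple(s for s in range(N_SLOTS)
                if s in source(arch.slot5[s]).fingerprint5)
    fp3 = tuple(s for s in range(N_SLOTS)
                if s in source(arch.slot3[s]).fingerprint3)
    return ModuleUnit(uid=f"{a_mod.uid}x{d_mod.uid}", orientation=a_mod.orientation,
                      fingerprint5=fp5, fingerprint3=fp3,
                      core_sites=a_mod.core_sites)


def nahr_product(homolog_a: Homolog, homolog_d: Homolog,
                 module_a: int, module_d: int, within_module_offset: int,
                 arch: Architecture | None = None,
                 region_a: str = "LCR22A",
                 region_d: str = "LCR22D") -> RecombinationEvent:
    """Homologous recombination between module ``module_a`` of
    ``homolog_a``'s ``region_a`` array and module ``module_d`` of
    ``homolog_d``'s ``region_d`` array (1-based indices), crossing over
    ``within_module_offset`` bp into the placed module.  The default
    LCR22A x LCR22D pairing is the deletion-generating NAHR; passing the
    same region on both sides expresses an allelic exchange, whose product
    between identical homologs is structurally identical to the input.

    The product keeps ``homolog_a``'s blocks from its start through the
    chosen module truncated at the offset, joined to ``homolog_d``'s
    material from the same offset of its module through its end; everything
    in between - including any translocation junction and chr11 material of
    ``homolog_a`` distal to its donor array - is absent from the product.
    The recombinant module is counted in the product's merged module array.

    Raises :class:`HomologyError` if the indexed modules differ in orientation
    and :class:`BoundsError` for bad indices or offsets.
    """
    if arch is None:
        arch = Architecture.build(DEFAULT_ARCH_SEED)
    a_block = homolog_a.array_block(region_a)
    d_block = homolog_d.array_block(region_d)
    if a_block is None or d_block is None:
        raise BoundsError("donor homolog lacks the required module array")
    if not 1 <= module_a <= len(a_block.modules):
        raise BoundsError(f"module_a={module_a} outside LCR22A array")
    if not 1 <= module_d <= len(d_block.modules):
        raise BoundsError(f"module_d={module_d} outside LCR22D array")
    if not 0 < within_module_offset < MODULE_LEN:
        raise BoundsError(f"offset {within_module_offset} outside module")
    a_mod = a_block.modules[module_a - 1]
    d_mod = d_block.modules[module_d - 1]
    if a_mod.orientation != d_mod.orientation:
        raise HomologyError(
            f"orientation mismatch at offset: {a_mod.orientation} vs {d_mod.orientation}")

    chimera = _chimeric_module(arch, a_mod, d_mod, within_module_offset)
    prod_modules = (list(a_block.modules[:module_a - 1]) + [chimera]
                    + list(d_block.modules[module_d:]))

    blocks: list[Block] = []
    for b in homolog_a.blocks:
        if b is a_block:
            break
        blocks.append(_copy.deepcopy(b))
    origin = homolog_a.blocks[0].start
    arr = Block(kind="module_array", region=region_a,
                start=(blocks[-1].end + 1 if blocks else origin),
                length=MODULE_LEN * len(prod_modules),
                ref_start=a_block.ref_start, modules=prod_modules)
    blocks.append(arr)
    passed = False
    for b in homolog_d.blocks:
        if b is d_block:
            passed = True
            continue
        if passed:
            nb = _copy.deepcopy(b)
            nb.start = blocks[-1].end + 1
            blocks.append(nb)

    product = Homolog(identity="chr22", name=f"{homolog_a.name}x{homolog_d.name}",
                      blocks=blocks, junction=None)
    product.validate()

    # breakpoint positions, each on its donor's local frame (the frames share
    # the proximal-anchor origin, so their difference is the deletion size)
    bp_a = a_block.start + (module_a - 1) * MODULE_LEN + within_module_offset
    bp_d = d_block.start + (module_d - 1) * MODULE_LEN + within_module_offset
    deletion_size = bp_d - bp_a

    # homology-identical stretch around the breakpoint on the product frame:
    # bounded by the nearest placed positions where the two donor module
    # fingerprint patterns differ
    mod_start = arr.start + (module_a - 1) * MODULE_LEN
    inverted = a_mod.orientation == ORIENT_INV

    def placed(ref_off: int) -> int:
        return (MODULE_LEN - ref_off) if inverted else ref_off

    diff_placed = sorted(
        placed(arch.slot5[s]) for s in range(N_SLOTS)
        if (s in a_mod.fingerprint5) != (s in d_mod.fingerprint5)
    ) + sorted(
        placed(arch.slot3[s]) for s in range(N_SLOTS)
        if (s in a_mod.fingerprint3) != (s in d_mod.fingerprint3)
    )
    diff_placed = sorted(diff_placed)
    lo = max([p for p in diff_placed if p <= within_module_offset], default=0)
    hi = min([p for p in diff_placed if p > within_module_offset], default=MODULE_LEN)
    bp_prod = mod_start + within_module_offset
    return RecombinationEvent(
        donor_a=(homolog_a.name, module_a),
        donor_d=(homolog_d.name, module_d),
        breakpoint_interval=(bp_prod, bp_prod),
        ambiguous_interval=(mod_start + lo + 1, mod_start + hi),
        product=product,
        deletion_size=deletion_size,
    )


# --------------------------------------------------------------------------- #
# structure comparison & reference homologs
# --------------------------------------------------------------------------- #


def structure_equal(arch: Architecture, h1: Homolog, h2: Homolog,
                    tol: float = 1.0) -> bool:
    """Structural identity of two homologs: same block kinds, lengths and
    orientations, same module counts/orientations, same junction, and label
    maps equal to within ``tol`` bp.  (Chimeric modules formed at different
    offsets inside the same fingerprint-free stretch compare equal, as they
    carry identical label content.)"""
    if len(h1.blocks) != len(h2.blocks) or h1.junction != h2.junction:
        return False
    for b1, b2 in zip(h1.blocks, h2.blocks):
        if (b1.kind, b1.length, b1.orientation) != (b2.kind, b2.length, b2.orientation):
            return False
        if b1.kind == "module_array":
            if len(b1.modules) != len(b2.modules):
                return False
            if any(m1.orientation != m2.orientation
                   for m1, m2 in zip(b1.modules, b2.modules)):
                return False
    p1 = synthesize_positions(arch, h1)
    p2 = synthesize_positions(arch, h2)
    if p1.size != p2.size:
        return False
    off1 = p1 - (h1.start - 1)
    off2 = p2 - (h2.start - 1)
    return bool(np.all(np.abs(off1 - off2) <= tol))


def reference_homologs(arch: Architecture) -> tuple[Homolog, Homolog]:
    """A miniature 'reference genome': one intact chr22 with a single
    reference-orientation module in each of LCR22A and LCR22D and no flanking
    inversion (fingerprint-free), plus one intact chr11.  Used as the fixed
    alignment target for translocation detection."""
    ref22 = build_intact_chr22(
        arch, "ref_chr22",
        a_modules=[make_module(arch, "refA", ORIENT_REF)],
        d_modules=[make_module(arch, "refD", ORIENT_REF)],
        inversion=False)
    ref11 = build_intact_chr11(arch, "ref_chr11")
    return ref22, ref11


def module_inventory(homologs: Iterable[Homolog], region: str) -> list[ModuleUnit]:
    """Distinct candidate module copies for ``region`` across ``homologs``
    (the reference-guided chaining inventory)."""
    out: list[ModuleUnit] = []
    seen = set()
    for h in homologs:
        b = h.array_block(region)
        if b is None:
            continue
        for m in b.modules:
            key = (m.uid, m.fingerprint5, m.fingerprint3)
            if key not in seen:
                seen.add(key)
                out.append(m)
    return out


# --------------------------------------------------------------------------- #
# serialization: catalog YAML and CMAP-like maps
# --------------------------------------------------------------------------- #

CATALOG_SCHEMA_VERSION = 1


def _module_to_dict(m: ModuleUnit) -> dict:
    return {"uid": m.uid, "orientation": m.orientation, "length": m.length,
            "fingerprint5": list(m.fingerprint5), "fingerprint3": list(m.fingerprint3)}


def _block_to_dict(b: Block) -> dict:
    d = {"kind": b.kind, "start": b.start, "length": b.length,
         "ref_name": b.ref_name, "ref_start": b.ref_start,
         "orientation": b.orientation}
    if b.template:
        d["template"] = b.template
    if b.region:
        d["region"] = b.region
    if b.nominal_length is not None:
        d["nominal_length"] = b.nominal_length
    if b.modules:
        d["modules"] = [_module_to_dict(m) for m in b.modules]
    return d


def catalog_to_dict(cat: FamilyCatalog) -> dict:
    return {
        "schema_version": CATALOG_SCHEMA_VERSION,
        "arch_seed": cat.arch.seed,
        "meta": cat.meta,
        "individuals": {
            ind: {
                hname: {
                    "identity": h.identity,
                    "junction": list(h.junction) if h.junction else None,
                    "blocks": [_block_to_dict(b) for b in h.blocks],
                }
                for hname, h in homs.items()
            }
            for ind, homs in cat.individuals.items()
        },
    }


def catalog_from_dict(d: dict) -> FamilyCatalog:
    arch = Architecture.build(int(d["arch_seed"]))
    individuals: dict[str, dict[str, Homolog]] = {}
    for ind, homs in d["individuals"].items():
        individuals[ind] = {}
        for hname, hd in homs.items():
            blocks = []
            for bd in hd["blocks"]:
                mods = [ModuleUnit(uid=md["uid"], orientation=md["orientation"],
                                   length=md["length"],
                                   fingerprint5=tuple(md["fingerprint5"]),
                                   fingerprint3=tuple(md["fingerprint3"]),
                                   core_sites=arch.core_offsets)
                        for md in bd.get("modules", [])]
                blocks.append(Block(kind=bd["kind"], start=bd["start"],
                                    length=bd["length"], ref_name=bd["ref_name"],
                                    ref_start=bd["ref_start"],
                                    orientation=bd["orientation"],
                                    template=bd.get("template"),
                                    region=bd.get("region"),
                                    nominal_length=bd.get("nominal_length"),
                                    modules=mods))
            junction = tuple(hd["junction"]) if hd.get("junction") else None
            h = Homolog(identity=hd["identity"], name=hname, blocks=blocks,
                        junction=junction)
            h.validate()
            individuals[ind][hname] = h
    return FamilyCatalog(arch=arch, individuals=individuals,
                         meta=dict(d.get("meta", {})))


def save_catalog(cat: FamilyCatalog, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(catalog_to_dict(cat), fh, sort_keys=False)


def load_catalog(path) -> FamilyCatalog:
    with open(path) as fh:
        return catalog_from_dict(yaml.safe_load(fh))


def write_cmap(maps: Mapping[str, tuple[int, Sequence[float]]], path) -> None:
    """CMAP-like text writer: '#'-prefixed header, then one tab-separated row
    per label site (map id, map length, label count, site index, position)."""
    with open(path, "w") as fh:
        fh.write("# CMAP-mini v1\n")
        fh.write("# map_id\tlength\tnum_sites\tsite_index\tposition\n")
        for map_id, (length, positions) in maps.items():
            n = len(positions)
            for i, p in enumerate(positions, start=1):
                fh.write(f"{map_id}\t{int(length)}\t{n}\t{i}\t{float(p):.1f}\n")


def read_cmap(path) -> dict[str, tuple[int, np.ndarray]]:
    maps: dict[str, tuple[int, list[float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"expected 5 columns, got {len(parts)}", line=ln)
            try:
                map_id, length, _n, _i, pos = (parts[0], int(parts[1]),
                                               int(parts[2]), int(parts[3]),
                                               float(parts[4]))
            except ValueError as e:
                raise ParseError(str(e), line=ln) from None
            maps.setdefault(map_id, (length, []))[1].append(pos)
    out = {}
    for map_id, (length, positions) in maps.items():
        arr = np.asarray(positions, dtype=float)
        if np.any(np.diff(arr) <= 0):
            raise ParseError(f"map {map_id}: non-increasing positions")
        out[map_id] = (length, arr)
    return out
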