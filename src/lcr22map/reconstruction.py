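"""Reference-guided reconstruction of LCR22 homolog structures from molecules.

The stages mirror the computational core of an optical-mapping workflow:
length filtering, label alignment, chaining of tandem 160 kbp duplicon
modules across their polymorphic end fingerprints, per-label coverage
validation, flanking-inversion detection, and split-alignment translocation
detection.  Full de-novo map assembly is deliberately out of scope: chaining
is guided by a candidate module inventory (the catalog of known copies), the
same way curated haplotype inventories guide manual validation of consensus
maps.

Module-array chaining works on *detections*: each molecule is scanned for
occurrences of the shared module core template (both orientations) and of
the unique flanking templates; every module occurrence is annotated with the
observed presence of each polymorphic fingerprint slot, mapped back to the
module's reference frame.  A greedy chain then starts at the 5' flank and
repeatedly extends by the fingerprint with maximal spanning-molecule
support, terminating when a 3' flank wins the vote.  Support ties fail over
to exhaustive candidate-structure scoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import haplotype_model as hm
from .alignment import (DEFAULT_FN_PENALTY, DEFAULT_FP_PENALTY,
                        DEFAULT_MATCH_BONUS, DEFAULT_TOLERANCE_CV,
                        LabelAlignment, Occurrence, align_labels,
                        candidate_lags, elastic_match, find_occurrences,
                        score_matching, score_occurrence, trim_pairs)
from .errors import ChainingGapError, ParseError
from .synthetic_data import Molecule

ORIENT_REF = hm.ORIENT_REF
ORIENT_INV = hm.ORIENT_INV


def _flip(orientation: str) -> str:
    return ORIENT_INV if orientation == ORIENT_REF else ORIENT_REF


# --------------------------------------------------------------------------- #
# molecule filtering
# --------------------------------------------------------------------------- #


def filter_molecules(molecules: Sequence[Molecule], min_length: float,
                     total_target: float | None = None) -> list[Molecule]:
    """Length filter with an optional total-data budget.

    Drops molecules below ``min_length``; if the surviving total exceeds
    ``total_target``, the longest molecules are retained first until the
    target is met (deterministic order: length descending, id ascending).
    """
    kept = [m for m in molecules if m.length >= min_length]
    if total_target is None:
        return sorted(kept, key=lambda m: (-m.length, m.molecule_id))
    kept.sort(key=lambda m: (-m.length, m.molecule_id))
    out, total = [], 0.0
    for m in kept:
        if total >= total_target:
            break
        out.append(m)
        total += m.length
    return out


# --------------------------------------------------------------------------- #
# fast whole-map molecule alignment (placement + elastic walk, DP objective)
# --------------------------------------------------------------------------- #


def align_molecule_fast(mol: Molecule, map_positions: np.ndarray,
                        map_id: str = "map",
                        tolerance_cv: float = DEFAULT_TOLERANCE_CV,
                        local: bool = False) -> LabelAlignment:
    """Best placement of a molecule on a long map: histogram placement plus
    elastic walk, both orientations, scored with the exact-DP objective.

    With ``local=True`` unmatched molecule labels outside the matched span
    carry no penalty - the mode for split (translocation) molecules, where
    the rest of the molecule belongs to the other chromosome."""
    labels = np.asarray(mol.labels, dtype=float)
    best = LabelAlignment(mol.molecule_id, map_id, "+", [], 0.0,
                          unmatched_molecule=len(labels))
    n = len(labels)
    scorer = score_occurrence if local else score_matching
    # partial-side placements of split molecules have few votes; in local
    # mode admit weak clusters and let the occurrence score arbitrate
    min_count = 5 if local else max(4, int(0.15 * n))
    max_lags = 25 if local else 6
    for orientation, q in (("+", labels), ("-", np.sort(labels[0] + labels[-1] - labels)
                                           if n else labels)):
        for lag in candidate_lags(q, map_positions, min_count=min_count,
                                  max_lags=max_lags):
            pairs = trim_pairs(q, map_positions,
                               elastic_match(q, map_positions, lag),
                               tolerance_cv=tolerance_cv)
            if len(pairs) < 4:
                continue
            score = scorer(q, map_positions, pairs,
                           tolerance_cv=tolerance_cv)
            if score > best.score:
                if orientation == "-":
                    out_pairs = [(n - 1 - i, j) for (i, j) in pairs][::-1]
                else:
                    out_pairs = pairs
                js = [j for _, j in pairs]
                best = LabelAlignment(mol.molecule_id, map_id, orientation,
                                      out_pairs, score,
                                      unmatched_molecule=n - len(pairs),
                                      unmatched_map=(max(js) - min(js) + 1
                                                     - len(pairs)))
    return best


def assign_molecules(molecules: Sequence[Molecule],
                     maps: Mapping[str, np.ndarray],
                     tie_tol: float = 1.0
                     ) -> tuple[dict[str, list[Molecule]],
                                dict[str, list[LabelAlignment]]]:
    """Partition a diploid/multi-homolog molecule pool among candidate
    homolog maps by best alignment score; molecules whose scores tie within
    ``tie_tol`` (fragments of material shared between homologs) are assigned
    to every tied candidate.  Returns per-map molecule lists and the
    corresponding alignments."""
    assigned: dict[str, list[Molecule]] = {name: [] for name in maps}
    alignments: dict[str, list[LabelAlignment]] = {name: [] for name in maps}
    for m in molecules:
        scored = [(align_molecule_fast(m, pos, name), name)
                  for name, pos in maps.items()]
        best = max(al.score for al, _ in scored)
        if best <= 0:
            continue
        for al, name in scored:
            if best - al.score <= tie_tol:
                assigned[name].append(m)
                alignments[name].append(al)
    return assigned, alignments


# --------------------------------------------------------------------------- #
# detections: module-core and flank-template occurrences within molecules
# --------------------------------------------------------------------------- #


@dataclass
class FlankTemplate:
    """A unique-region label template used to seed or terminate a chain.

    ``positions`` live on the template frame [0, length]; ``array_boundary``
    is the offset (same frame) of the edge that abuts the module array."""

    name: str
    positions: np.ndarray
    length: float
    array_boundary: float
    role: str                    # 'start' or 'stop'


@dataclass
class RegionCandidates:
    """Inventory handed to the chainer: candidate module copies for one
    region plus the flank templates on either side of its array."""

    region: str
    arch: hm.Architecture
    candidates: list[hm.ModuleUnit]
    flanks: list[FlankTemplate]


def _mirror_frame(positions: np.ndarray, length: float) -> np.ndarray:
    return np.sort(length - positions)


def _core_template(arch: hm.Architecture) -> np.ndarray:
    return np.asarray(arch.core_offsets, dtype=float)


def _flank(arch: hm.Architecture, name: str, role: str,
           window: float = 360_000.0) -> FlankTemplate:
    """Realize a unique-region template, truncated to the ``window`` bp
    adjacent to the module array, re-framed so positions start near 0."""
    length, _ = hm._UNIQUE_REGIONS[name]
    offs = np.asarray(arch.unique_labels(name), dtype=float)
    if hm.ARRAY_SIDE[name] == "end":
        keep = offs >= length - window
        pos = offs[keep] - max(0.0, length - window)
        tlen = min(window, length)
        boundary = tlen
    else:
        pos = offs[offs < window]
        tlen = min(window, length)
        boundary = 0.0
    return FlankTemplate(name=name, positions=np.sort(pos), length=tlen,
                         array_boundary=boundary, role=role)


def region_candidates(arch: hm.Architecture, region: str,
                      candidates: Iterable[hm.ModuleUnit]) -> RegionCandidates:
    """Build the chaining inventory for LCR22A or LCR22D.

    Stop flanks include every template that can legitimately follow the
    array: the A-B unique spacer for intact homologs, and the LCR22D
    flanking-inversion segment for deletion-containing haplotypes (whose
    merged module array runs straight into LCR22D material)."""
    if region == "LCR22A":
        flanks = [_flank(arch, "p_anchor", "start"),
                  _flank(arch, "ab_spacer", "stop"),
                  _flank(arch, "inv_seg", "stop")]
    elif region == "LCR22D":
        flanks = [_flank(arch, "c_spacer", "start"),
                  _flank(arch, "inv_seg", "stop")]
    else:
        raise ValueError(f"unknown region {region!r}")
    return RegionCandidates(region=region, arch=arch,
                            candidates=list(candidates), flanks=flanks)


@dataclass
class Detection:
    """One template occurrence inside a molecule.

    ``orientation`` is as observed on the molecule read (placed orientation
    XOR strand).  For module detections ``slot_obs`` maps (window, slot) to
    observed label presence, already transformed back to the module's
    reference frame, restricted to slots physically covered by the molecule.
    ``interval`` is the placed template extent in molecule coordinates."""

    kind: str                          # 'module' | 'flank'
    name: str                          # 'core' or flank name
    orientation: str
    interval: tuple[float, float]
    matched: int
    n_overlap: int
    slot_obs: dict = field(default_factory=dict)
    score: float = 0.0

    @property
    def mid(self) -> float:
        return 0.5 * (self.interval[0] + self.interval[1])


_SLOT_TOL = 800.0


def _module_detection(arch: hm.Architecture, labels: np.ndarray,
                      occ: Occurrence, orientation: str,
                      tmpl: np.ndarray, length: float) -> Detection:
    placed_tmpl = tmpl  # already in placed frame (mirrored template for inv)
    mol_matched = np.array([labels[i] for i, _ in occ.pairs])
    tmpl_matched = np.array([placed_tmpl[j] for _, j in occ.pairs])

    def expected(placed_off: float) -> float:
        return float(np.interp(placed_off, tmpl_matched, mol_matched,
                               left=mol_matched[0] + (placed_off - tmpl_matched[0]),
                               right=mol_matched[-1] + (placed_off - tmpl_matched[-1])))

    mol_lo, mol_hi = labels[0], labels[-1]
    slot_obs = {}
    for window, offs in (("fp5", arch.slot5), ("fp3", arch.slot3)):
        for s, off in enumerate(offs):
            placed = off if orientation == ORIENT_REF else hm.MODULE_LEN - off
            exp = expected(placed)
            if exp < mol_lo - 2500 or exp > mol_hi + 2500:
                continue  # slot not covered by this molecule
            k = np.searchsorted(labels, exp)
            present = any(0 <= c < len(labels) and abs(labels[c] - exp) <= _SLOT_TOL
                          for c in (k - 1, k))
            slot_obs[(window, s)] = bool(present)
    start = expected(0.0)
    end = expected(hm.MODULE_LEN)
    return Detection(kind="module", name="core", orientation=orientation,
                     interval=(start, end), matched=occ.matched,
                     n_overlap=occ.n_overlap, slot_obs=slot_obs,
                     score=occ.score)


def detect_molecule(arch: hm.Architecture, labels: np.ndarray,
                    rc: RegionCandidates,
                    min_frac: float = 0.5, min_matched: int = 6
                    ) -> list[Detection]:
    """All module-core and flank occurrences in one molecule, position sorted."""
    labels = np.asarray(labels, dtype=float)
    if labels.size < min_matched:
        return []
    dets: list[Detection] = []
    core = _core_template(rc.arch)
    for orientation, tmpl in ((ORIENT_REF, core),
                              (ORIENT_INV, _mirror_frame(core, hm.MODULE_LEN))):
        for occ in find_occurrences(labels, tmpl, min_frac=min_frac,
                                    min_matched=min_matched):
            dets.append(_module_detection(arch, labels, occ, orientation,
                                          tmpl, hm.MODULE_LEN))
    for fl in rc.flanks:
        for orientation, tmpl in (
                (ORIENT_REF, fl.positions),
                (ORIENT_INV, _mirror_frame(fl.positions, fl.length))):
            for occ in find_occurrences(labels, tmpl, min_frac=0.55,
                                        min_matched=min_matched):
                dets.append(Detection(
                    kind="flank", name=fl.name, orientation=orientation,
                    interval=occ.mol_span, matched=occ.matched,
                    n_overlap=occ.n_overlap, score=occ.score))
    # non-maximum suppression between overlapping detections
    dets.sort(key=lambda d: (-d.score, d.interval[0]))
    kept: list[Detection] = []
    for d in dets:
        clash = False
        for k in kept:
            ov = min(d.interval[1], k.interval[1]) - max(d.interval[0], k.interval[0])
            if ov > 0.5 * min(d.interval[1] - d.interval[0],
                              k.interval[1] - k.interval[0]):
                clash = True
                break
        if not clash:
            kept.append(d)
    kept.sort(key=lambda d: d.mid)
    return kept


# --------------------------------------------------------------------------- #
# module chaining
# --------------------------------------------------------------------------- #


@dataclass
class ModuleCall:
    """A called module-array structure for one region of one homolog."""

    region: str
    copy_number: int
    orientations: list[str]
    assignments: list[str | None]          # best-matching catalog copy per slot
    observed_patterns: list[dict]          # {(window, slot): bool} per copy
    junction_support: list[list[int]]      # supporting molecule ids per junction
    stopped_by: str = ""
    ambiguous: list[list[str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def pattern_tuple(self, i: int) -> tuple[tuple[int, ...], tuple[int, ...]]:
        obs = self.observed_patterns[i]
        fp5 = tuple(s for (w, s), v in sorted(obs.items()) if w == "fp5" and v)
        fp3 = tuple(s for (w, s), v in sorted(obs.items()) if w == "fp3" and v)
        return fp5, fp3

    def structure(self) -> tuple:
        """Hashable structural summary (copy number, orientations, observed
        fingerprints) for haplotype-distinctness comparisons."""
        return (self.copy_number, tuple(self.orientations),
                tuple(self.pattern_tuple(i) for i in range(self.copy_number)))


_GAP_TOL = 25_000.0
# extension votes with almost no observed fingerprint slots carry no
# identity information and are ignored
_MIN_SLOT_OBS = 3


def _pattern_agreement(obs: Mapping, ref: Mapping) -> tuple[int, int]:
    """(agreements, disagreements) over slots present in both patterns."""
    agree = disagree = 0
    for k, v in obs.items():
        if k in ref:
            if bool(v) == bool(ref[k]):
                agree += 1
            else:
                disagree += 1
    return agree, disagree


def _candidate_pattern(cand: hm.ModuleUnit) -> dict:
    out = {}
    for s in range(hm.N_SLOTS):
        out[("fp5", s)] = s in cand.fingerprint5
        out[("fp3", s)] = s in cand.fingerprint3
    return out


def _match_candidates(pattern: Mapping, candidates: Sequence[hm.ModuleUnit]
                      ) -> tuple[str | None, list[str]]:
    """Best catalog copy for an observed slot pattern; ``None`` with the tied
    list when no candidate wins by a clear margin."""
    if not candidates:
        return None, []
    scores = []
    for c in candidates:
        ref = _candidate_pattern(c)
        agree, disagree = _pattern_agreement(pattern, ref)
        scores.append((agree - disagree, c.uid))
    scores.sort(key=lambda t: (-t[0], t[1]))
    if len(scores) == 1 or scores[0][0] > scores[1][0]:
        return scores[0][1], []
    top = [uid for s, uid in scores if s == scores[0][0]]
    return None, top


def _frontier_strand(det: Detection, frontier_orient: str) -> str:
    return "+" if det.orientation == frontier_orient else "-"


def chain_modules(molecules: Sequence[Molecule], arch: hm.Architecture,
                  rc: RegionCandidates, min_cov: int = 5,
                  max_copies: int = 8,
                  detections: Mapping[int, list[Detection]] | None = None
                  ) -> ModuleCall:
    """Greedy fingerprint chaining of a tandem module array.

    Seeds at the 5' flank; at each junction collects the molecules whose
    detections span from the current frontier to an adjacent occurrence,
    takes the orientation/fingerprint consensus of those spanning votes, and
    extends by it when its support beats the stop votes; terminates when a 3'
    flank wins.  Equal nonzero support fails over to exhaustive
    candidate-structure scoring (:func:`exhaustive_chain`).  Raises
    :class:`ChainingGapError` when no molecule spans the next junction.
    """
    if detections is None:
        detections = {m.molecule_id: detect_molecule(arch, m.labels, rc)
                      for m in molecules}
    start_name = next(f.name for f in rc.flanks if f.role == "start")
    stop_names = {f.name for f in rc.flanks if f.role == "stop"}

    chained_orient: list[str] = []
    chained_patterns: list[dict] = []
    junction_support: list[list[int]] = []
    assignments: list[str | None] = []
    ambiguous: list[list[str]] = []
    stopped_by = ""

    while True:
        step = len(chained_orient)
        stop_votes: list[int] = []
        next_votes: list[tuple[int, Detection, str]] = []  # (mol id, det, placed orient)
        for m in molecules:
            dets = detections.get(m.molecule_id, [])
            for idx, d in enumerate(dets):
                # does this detection match the current frontier?
                if step == 0:
                    if d.kind != "flank" or d.name != start_name:
                        continue
                    strand = "+" if d.orientation == ORIENT_REF else "-"
                    # the flank's array-adjacent side faces the chain direction
                    frontier_edge = d.interval[1] if strand == "+" else d.interval[0]
                else:
                    if d.kind != "module":
                        continue
                    front_orient = chained_orient[-1]
                    agree, disagree = _pattern_agreement(d.slot_obs,
                                                         chained_patterns[-1])
                    # a frontier match must be decisively this copy: partial
                    # edge detections of *other* copies can tally a handful
                    # of chance agreements, so require strong net agreement
                    if disagree > max(1, agree // 4) or agree - disagree < 5:
                        continue
                    if d.orientation == front_orient:
                        strand = "+"
                    elif d.orientation == _flip(front_orient):
                        strand = "-"
                    else:
                        continue
                    frontier_edge = d.interval[1] if strand == "+" else d.interval[0]
                nxt_idx = idx + 1 if strand == "+" else idx - 1
                if not 0 <= nxt_idx < len(dets):
                    continue
                nxt = dets[nxt_idx]
                if nxt.kind == "module":
                    if len(nxt.slot_obs) < _MIN_SLOT_OBS:
                        continue
                    edge = nxt.interval[0] if strand == "+" else nxt.interval[1]
                    gap = (edge - frontier_edge) if strand == "+" \
                        else (frontier_edge - edge)
                    if abs(gap) > _GAP_TOL:
                        continue
                    placed = nxt.orientation if strand == "+" \
                        else _flip(nxt.orientation)
                    next_votes.append((m.molecule_id, nxt, placed))
                elif nxt.name in stop_names:
                    edge = nxt.interval[0] if strand == "+" else nxt.interval[1]
                    gap = (edge - frontier_edge) if strand == "+" \
                        else (frontier_edge - edge)
                    if abs(gap) > _GAP_TOL:
                        continue
                    stop_votes.append(m.molecule_id)

        stop_support = len(set(stop_votes))
        if next_votes:
            orient_counts: dict[str, set[int]] = {}
            for mol_id, _d, placed in next_votes:
                orient_counts.setdefault(placed, set()).add(mol_id)
            placed_orient = max(orient_counts,
                                key=lambda o: (len(orient_counts[o]), o))
            votes = [(mid, d) for mid, d, p in next_votes if p == placed_orient]
            slot_tally: dict[tuple, list[int]] = {}
            for _mid, d in votes:
                for k, v in d.slot_obs.items():
                    slot_tally.setdefault(k, [0, 0])[0 if v else 1] += 1
            # presence evidence is asymmetric: a seen label is near-certain
            # (chance false positives at a slot are rare) while an absent one
            # drops out ~13% of the time, so presence wins below parity
            consensus = {k: yes > 0 and yes / (yes + no) >= 0.3
                         for k, (yes, no) in slot_tally.items()}
            supporters = set()
            for mid, d in votes:
                agree, disagree = _pattern_agreement(d.slot_obs, consensus)
                if disagree <= max(1, agree // 4):
                    supporters.add(mid)
            module_support = len(supporters)
        else:
            module_support = 0

        if module_support == 0 and stop_support == 0:
            if step == 0:
                raise ChainingGapError(f"{rc.region} 5' flank -> copy 1")
            raise ChainingGapError(f"{rc.region} copy {step} -> next")
        if stop_support > module_support:
            stopped_by = "flank"
            break
        if stop_support == module_support:
            return exhaustive_chain(molecules, arch, rc, max_copies=max_copies,
                                    min_cov=min_cov, detections=detections)
        if len(chained_orient) >= max_copies:
            raise ChainingGapError(
                f"{rc.region}: runaway chain beyond {max_copies} copies")
        # identify the extension in the candidate inventory; slots the votes
        # did not cover are filled in from the matched copy (reference-guided
        # completion - observations always win over the inventory), so the
        # frontier pattern the next step matches against is complete
        unconsumed = [c for c in rc.candidates if c.uid not in
                      {u for u in assignments if u is not None}]
        uid, tied = _match_candidates(consensus, unconsumed)
        if uid is not None:
            pattern = dict(_candidate_pattern(
                next(c for c in unconsumed if c.uid == uid)))
            pattern.update(consensus)
        else:
            pattern = dict(consensus)
        assignments.append(uid)
        ambiguous.append(tied)
        chained_orient.append(placed_orient)
        chained_patterns.append(pattern)
        junction_support.append(sorted(supporters))

    chained_patterns = _refine_patterns(detections, chained_orient,
                                        chained_patterns)
    return ModuleCall(region=rc.region, copy_number=len(chained_orient),
                      orientations=chained_orient,
                      assignments=assignments,
                      observed_patterns=chained_patterns,
                      junction_support=junction_support,
                      stopped_by=stopped_by, ambiguous=ambiguous,
                      meta={"min_cov": min_cov, "method": "greedy"})


def _refine_patterns(detections: Mapping[int, list[Detection]],
                     orients: Sequence[str],
                     patterns: list[dict]) -> list[dict]:
    """Re-call every fingerprint slot of every chained copy using *all*
    molecules whose detections identify that copy, not just the
    junction-spanning chain voters.  A detection counts towards the one copy
    whose pattern it decisively matches; slots are then re-decided with the
    presence-biased rule (a seen label is near-certain, a missing one drops
    out at the false-negative rate)."""
    tallies: list[dict] = [dict() for _ in orients]
    for dets in detections.values():
        for d in dets:
            if d.kind != "module" or len(d.slot_obs) < _MIN_SLOT_OBS:
                continue
            matches = []
            for i, (orient, pat) in enumerate(zip(orients, patterns)):
                if d.orientation not in (orient, _flip(orient)):
                    continue
                agree, disagree = _pattern_agreement(d.slot_obs, pat)
                if disagree <= max(1, agree // 4) and agree - disagree >= 5:
                    matches.append(i)
            if len(matches) != 1:
                continue
            tally = tallies[matches[0]]
            for k, v in d.slot_obs.items():
                tally.setdefault(k, [0, 0])[0 if v else 1] += 1
    refined = []
    for pat, tally in zip(patterns, tallies):
        new = dict(pat)
        for k, (yes, no) in tally.items():
            new[k] = yes > 0 and yes / (yes + no) >= 0.3
        refined.append(new)
    return refined


def _realize_structure(arch: hm.Architecture, rc: RegionCandidates,
                       mods: Sequence[tuple[hm.ModuleUnit, str]]) -> np.ndarray:
    """Region map for a hypothetical structure: start flank, modules, best
    stop flank; frame anchored with the array start at 0."""
    start = next(f for f in rc.flanks if f.role == "start")
    stop = next(f for f in rc.flanks if f.role == "stop")
    pos = list(start.positions - start.array_boundary)
    off = 0.0
    for mod, orient in mods:
        mpos = [arch.slot5[s] for s in mod.fingerprint5]
        mpos += [arch.slot3[s] for s in mod.fingerprint3]
        mpos += list(mod.core_sites)
        if orient == ORIENT_INV:
            mpos = [hm.MODULE_LEN - p for p in mpos]
        pos.extend(off + p for p in mpos)
        off += hm.MODULE_LEN
    pos.extend(off + (stop.positions - stop.array_boundary))
    return np.sort(np.asarray(pos))


def exhaustive_chain(molecules: Sequence[Molecule], arch: hm.Architecture,
                     rc: RegionCandidates, max_copies: int = 5,
                     min_cov: int = 5,
                     detections: Mapping[int, list[Detection]] | None = None,
                     max_structures: int = 3000) -> ModuleCall:
    """Score every candidate structure (sequences of distinct catalog copies
    with free orientations, up to ``max_copies``) by total molecule alignment
    score against its realized region map; the optimum is the call.  Ties
    break to the lexicographically smallest structure."""
    mols = [np.asarray(m.labels, float) for m in molecules]
    best: tuple | None = None
    n_structs = 0
    cand = rc.candidates
    for k in range(0, min(max_copies, len(cand)) + 1):
        for perm in itertools.permutations(cand, k):
            for orients in itertools.product((ORIENT_REF, ORIENT_INV), repeat=k):
                n_structs += 1
                if n_structs > max_structures:
                    raise ChainingGapError(
                        f"{rc.region}: exhaustive failover exceeded "
                        f"{max_structures} structures")
                ref = _realize_structure(arch, rc, list(zip(perm, orients)))
                total = 0.0
                for q in mols:
                    s_best = 0.0
                    for orientation in ("+", "-"):
                        qq = q if orientation == "+" else np.sort(
                            q[0] + q[-1] - q)
                        for lag in candidate_lags(qq, ref,
                                                  min_count=max(5, len(qq) // 3)):
                            pairs = elastic_match(qq, ref, lag)
                            if len(pairs) >= 4:
                                s_best = max(s_best,
                                             score_matching(qq, ref, pairs))
                    total += s_best
                key = (-total, tuple(0 if o == ORIENT_REF else 1 for o in orients),
                       tuple(c.uid for c in perm))
                if best is None or key < best[0]:
                    best = (key, perm, orients, total)
    assert best is not None
    _, perm, orients, total = best
    return ModuleCall(region=rc.region, copy_number=len(perm),
                      orientations=list(orients),
                      assignments=[c.uid for c in perm],
                      observed_patterns=[_candidate_pattern(c) for c in perm],
                      junction_support=[[] for _ in range(len(perm))],
                      stopped_by="exhaustive",
                      meta={"min_cov": min_cov, "method": "exhaustive",
                            "score": total})


# --------------------------------------------------------------------------- #
# coverage validation
# --------------------------------------------------------------------------- #


@dataclass
class CoverageReport:
    """Per-label molecule coverage over a called map."""

    counts: np.ndarray
    min_cov: int
    passed: bool
    deficient: list[int]

    def __bool__(self) -> bool:
        return self.passed


def validate_coverage(map_positions: Sequence[float],
                      alignments: Iterable[LabelAlignment],
                      min_cov: int = 5,
                      tracked: Sequence[int] | None = None) -> CoverageReport:
    """Count, per map label, the molecules whose alignment matches it; the
    report passes iff every tracked label reaches ``min_cov``.  ``tracked``
    defaults to all labels (anchor and duplicon-overlapping alike)."""
    n = len(map_positions)
    counts = np.zeros(n, dtype=int)
    for al in alignments:
        for _i, j in al.pairs:
            if 0 <= j < n:
                counts[j] += 1
    idx = np.arange(n) if tracked is None else np.asarray(tracked, int)
    deficient = [int(j) for j in idx if counts[j] < min_cov]
    return CoverageReport(counts=counts, min_cov=min_cov,
                          passed=not deficient, deficient=deficient)


# --------------------------------------------------------------------------- #
# inversion detection
# --------------------------------------------------------------------------- #


@dataclass
class InversionCall:
    status: str                     # 'present' | 'absent' | 'no_call'
    interval: tuple[int, int]
    score_direct: float
    score_mirrored: float


def _segment_match_count(window: np.ndarray, tmpl: np.ndarray,
                         tol: float = 900.0) -> int:
    if window.size == 0 or tmpl.size == 0:
        return 0
    k = np.searchsorted(window, tmpl)
    n = 0
    for j, t in zip(k, tmpl):
        for c in (j - 1, j):
            if 0 <= c < window.size and abs(window[c] - t) <= tol:
                n += 1
                break
    return n


def detect_inversion(map_positions: Sequence[float], inv_span: tuple[int, int],
                     arch: hm.Architecture, margin: float = 3.0,
                     floor: float = 4.0) -> InversionCall:
    """Orientation call for the LCR22D flanking-inversion segment on a call
    map.  The segment's template is matched in both orientations against the
    map labels inside the span; 'present' (inverted) requires the mirrored
    template to beat the direct one by ``margin`` matched labels.  Both
    scores below ``floor`` yields a no-call."""
    pos = np.asarray(map_positions, dtype=float)
    lo, hi = inv_span
    window = pos[(pos >= lo - 2000) & (pos <= hi + 2000)]
    length = hi - lo
    offs = np.asarray(arch.unique_labels("inv_seg", length + 1), dtype=float)
    direct = lo + offs
    mirrored = lo + _mirror_frame(offs, length)
    s_dir = _segment_match_count(window, direct)
    s_mir = _segment_match_count(window, mirrored)
    if max(s_dir, s_mir) < floor:
        status = "no_call"
    elif s_mir - s_dir >= margin:
        status = "present"
    else:
        status = "absent"
    return InversionCall(status=status, interval=(lo, hi),
                         score_direct=float(s_dir), score_mirrored=float(s_mir))


def detect_inversion_from_molecules(molecules: Sequence[Molecule],
                                    map_direct: np.ndarray,
                                    map_mirrored: np.ndarray,
                                    inv_span: tuple[int, int],
                                    margin: float = 5.0,
                                    floor: float = 10.0) -> InversionCall:
    """Molecule-vote variant for noisy pipelines: molecules overlapping the
    segment are aligned to both region variants and the summed alignment
    scores compared."""
    s_dir = s_mir = 0.0
    for m in molecules:
        a_dir = align_molecule_fast(m, map_direct, "direct")
        a_mir = align_molecule_fast(m, map_mirrored, "mirrored")
        if max(a_dir.score, a_mir.score) <= 0:
            continue
        # only molecules informative about the segment
        touches = False
        for al, ref in ((a_dir, map_direct), (a_mir, map_mirrored)):
            for _i, j in al.pairs:
                if inv_span[0] - 2000 <= ref[j] <= inv_span[1] + 2000:
                    touches = True
        if not touches:
            continue
        s_dir += max(0.0, a_dir.score)
        s_mir += max(0.0, a_mir.score)
    if max(s_dir, s_mir) < floor:
        status = "no_call"
    elif s_mir - s_dir >= margin:
        status = "present"
    else:
        status = "absent"
    return InversionCall(status=status, interval=inv_span,
                         score_direct=s_dir, score_mirrored=s_mir)


# --------------------------------------------------------------------------- #
# translocation detection
# --------------------------------------------------------------------------- #


@dataclass
class TranslocationCall:
    chr22_interval: tuple[float, float]
    chr11_interval: tuple[float, float]
    supporting_molecules: list[int]
    map_id: str = "split_consensus"


def detect_translocation(molecules: Sequence[Molecule],
                         map22: np.ndarray, map11: np.ndarray,
                         min_support: int = 3, min_side: int = 5,
                         min_side_frac: float = 0.6
                         ) -> TranslocationCall | None:
    """Split-alignment translocation detection.

    A molecule supports the translocation when one end aligns to the chr22
    reference map and the other to the chr11 map (each side with at least
    ``min_side`` matched labels covering ``min_side_frac`` of that side's
    labels, consistent orientation, non-overlapping sides).  Per molecule the
    chr22 breakpoint lies between its last matched chr22 map label and the
    next; the reported intervals are the intersections over the concordant
    supporting molecules (split calls whose intervals miss the consensus
    point - chance partial matches, or molecules whose junction-adjacent
    label dropped out - are excluded before intersecting).  Returns ``None``
    (no-call) below ``min_support``.
    """
    per_mol: list[tuple[float, float, float, float, int]] = []
    for m in molecules:
        # primary alignment on the molecule's majority chromosome, then the
        # unmatched remainder alone against the other map (restricting the
        # search space is what makes the minority side detectable)
        n_labels = len(m.labels)
        labels = np.asarray(m.labels, dtype=float)
        prim22 = align_molecule_fast(m, map22, "chr22")
        if len(prim22.pairs) >= min_side and prim22.score > 0:
            i22s = sorted(i for i, _ in prim22.pairs)
            tails = max(i22s[0], n_labels - 1 - i22s[-1])
            if tails < min_side and len(prim22.pairs) >= 0.8 * n_labels:
                continue  # fully explained by chr22: cannot be split
        prim11 = align_molecule_fast(m, map11, "chr11")
        prim_is_22 = prim22.score >= prim11.score
        prim = prim22 if prim_is_22 else prim11
        if len(prim.pairs) < min_side or prim.score <= 0:
            continue
        idx = sorted(i for i, _ in prim.pairs)
        left = list(range(0, idx[0]))
        right = list(range(idx[-1] + 1, n_labels))
        rem = left if len(left) >= len(right) else right
        if len(rem) < min_side:
            continue
        if len(prim.pairs) / max(1, n_labels - len(rem)) < min_side_frac:
            continue
        sub = Molecule(molecule_id=m.molecule_id, length=m.length,
                       labels=labels[rem], qualities=np.zeros(len(rem)))
        sec = align_molecule_fast(sub, map11 if prim_is_22 else map22,
                                  "chr11" if prim_is_22 else "chr22",
                                  local=True)
        if (len(sec.pairs) < min_side
                or len(sec.pairs) / len(rem) < min_side_frac
                or sec.orientation != prim.orientation):
            continue
        sec_pairs = [(rem[i], j) for i, j in sec.pairs]
        if prim_is_22:
            a22, a11 = prim, LabelAlignment(m.molecule_id, "chr11",
                                            sec.orientation, sec_pairs,
                                            sec.score)
        else:
            a22 = LabelAlignment(m.molecule_id, "chr22", sec.orientation,
                                 sec_pairs, sec.score)
            a11 = prim
        i22 = sorted(i for i, _ in a22.pairs)
        i11 = sorted(i for i, _ in a11.pairs)
        # the two sides partition the molecule by construction; record which
        # comes first along the read
        if i22[-1] < i11[0]:
            first = (a22, map22)
        elif i11[-1] < i22[0]:
            first = (a11, map11)
        else:
            continue
        # orientation of the molecule on the genome decides which side of
        # each reference map abuts the junction
        js22 = sorted(j for _, j in a22.pairs)
        js11 = sorted(j for _, j in a11.pairs)
        mol_fwd = (a22.orientation == "+")
        chr22_low_side = (first[0] is a22) == mol_fwd
        if chr22_low_side:
            j = js22[-1]
            c_lo = map22[j]
            c_hi = map22[j + 1] if j + 1 < len(map22) else map22[j] + 50_000
        else:
            j = js22[0]
            c_lo = map22[j - 1] if j > 0 else map22[j] - 50_000
            c_hi = map22[j]
        chr11_low_side = (first[0] is a11) == mol_fwd
        if chr11_low_side:
            j = js11[-1]
            d_lo = map11[j]
            d_hi = map11[j + 1] if j + 1 < len(map11) else map11[j] + 50_000
        else:
            j = js11[0]
            d_lo = map11[j - 1] if j > 0 else map11[j] - 50_000
            d_hi = map11[j]
        per_mol.append((float(c_lo), float(c_hi), float(d_lo), float(d_hi),
                        m.molecule_id))
    if len(per_mol) < min_support:
        return None

    def stab_point(intervals: list[tuple[float, float]]) -> float:
        # breakpoints lie strictly between labels, so intervals are open:
        # stab with midpoints so that a dropout-shifted interval sharing an
        # endpoint with the true ones does not join the consensus group
        mids = sorted({0.5 * (lo + hi) for lo, hi in intervals})
        return max(mids, key=lambda p: (sum(lo < p < hi
                                            for lo, hi in intervals), p))

    p22 = stab_point([(c_lo, c_hi) for c_lo, c_hi, *_ in per_mol])
    p11 = stab_point([(d_lo, d_hi) for _c1, _c2, d_lo, d_hi, _m in per_mol])
    kept = [row for row in per_mol
            if row[0] < p22 < row[1] and row[2] < p11 < row[3]]
    if len(kept) < min_support:
        return None
    lo22 = max(r[0] for r in kept)
    hi22 = min(r[1] for r in kept)
    lo11 = max(r[2] for r in kept)
    hi11 = min(r[3] for r in kept)
    return TranslocationCall(chr22_interval=(lo22, hi22),
                             chr11_interval=(lo11, hi11),
                             supporting_molecules=sorted(r[4] for r in kept))


# --------------------------------------------------------------------------- #
# XMAP-like alignment output
# --------------------------------------------------------------------------- #


def write_xmap(alignments: Sequence[LabelAlignment], path) -> None:
    """XMAP-like writer: '#' header, then tab-separated rows of molecule id,
    map id, orientation, index pairs ('i,j;...'), score."""
    with open(path, "w") as fh:
        fh.write("# XMAP-mini v1\n")
        fh.write("# molecule_id\tmap_id\torientation\tpairs\tscore\n")
        for al in alignments:
            pairs = ";".join(f"{i},{j}" for i, j in al.pairs)
            fh.write(f"{al.molecule_id}\t{al.map_id}\t{al.orientation}\t"
                     f"{pairs}\t{al.score:.4f}\n")


def read_xmap(path) -> list[LabelAlignment]:
    out: list[LabelAlignment] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"expected 5 columns, got {len(parts)}", line=ln)
            try:
                pairs = [tuple(int(v) for v in p.split(","))
                         for p in parts[3].split(";") if p]
                out.append(LabelAlignment(
                    molecule_id=int(parts[0]), map_id=parts[1],
                    orientation=parts[2], pairs=pairs, score=float(parts[4])))
            except ValueError as e:
                raise ParseError(str(e), line=ln) from None
    return out
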