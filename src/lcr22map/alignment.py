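"""Restriction-map label alignment.

Two layers:

* :func:`align_labels` - exact dynamic programming over monotone matchings of
  two ordered label-position lists, under the scoring objective documented
  below.  This is the reference aligner: optimal, oracle-testable, used where
  per-pair optimality matters (split-read translocation refinement, scoring).

* :func:`find_occurrences` / :func:`elastic_match` - a coarse histogram
  placement followed by an elastic nearest-label walk.  Linear-time, used by
  the pipeline for the bulk work (module-fingerprint detection, homolog
  assignment); its matchings are scored with the same objective via
  :func:`score_matching`.

Scoring objective
-----------------
For a monotone matching ``(i1,j1) < (i2,j2) < ...`` of molecule labels to map
labels::

    score = sum over matched pairs of  [ match_bonus - size_penalty ]
            - fp_penalty * (number of unmatched molecule labels)
            - fn_penalty * (number of unmatched map labels interior to the
                            matched map span)

where for consecutive matched pairs the sizing penalty compares the implied
inter-label distances, ``size_penalty = ((d_mol - d_map) / (tolerance_cv *
d_map)) ** 2`` (zero for the first pair).  Map labels outside the matched span
are free: a molecule is a fragment of the map (semi-global alignment).  The
empty matching scores 0.  The score is invariant under global translation of
both lists and under simultaneous mirroring.

Orientation ``-`` means the molecule label list was reversed and mirrored
before matching; both orientations are tried and the higher score kept (ties
resolve to ``+``).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

DEFAULT_TOLERANCE_CV = 0.06     # 3x the default sizing noise of the generator
DEFAULT_MATCH_BONUS = 1.0
DEFAULT_FP_PENALTY = 0.4
DEFAULT_FN_PENALTY = 0.6


@dataclass
class LabelAlignment:
    """A monotone pairing of molecule labels to map labels."""

    molecule_id: int | str
    map_id: str
    orientation: str                       # '+' or '-'
    pairs: list[tuple[int, int]]           # (molecule label idx, map label idx)
    score: float
    unmatched_molecule: int = 0
    unmatched_map: int = 0


def score_matching(mol: np.ndarray, ref: np.ndarray,
                   pairs: Sequence[tuple[int, int]],
                   tolerance_cv: float = DEFAULT_TOLERANCE_CV,
                   match_bonus: float = DEFAULT_MATCH_BONUS,
                   fp_penalty: float = DEFAULT_FP_PENALTY,
                   fn_penalty: float = DEFAULT_FN_PENALTY) -> float:
    """Score an explicit monotone matching under the module objective."""
    if not pairs:
        return 0.0
    score = -fp_penalty * (len(mol) - len(pairs))
    prev = None
    for (i, j) in pairs:
        score += match_bonus
        if prev is not None:
            d_mol = mol[i] - mol[prev[0]]
            d_map = ref[j] - ref[prev[1]]
            score -= ((d_mol - d_map) / (tolerance_cv * d_map)) ** 2
            score -= fn_penalty * (j - prev[1] - 1)
        prev = (i, j)
    return float(score)


def _mirror(positions: np.ndarray) -> np.ndarray:
    """Reverse and mirror a position list (translation reference irrelevant:
    the scoring depends on distances only)."""
    if positions.size == 0:
        return positions.copy()
    return (positions[0] + positions[-1]) - positions[::-1]


def _dp_align(mol: np.ndarray, ref: np.ndarray, tolerance_cv: float,
              match_bonus: float, fp_penalty: float, fn_penalty: float,
              max_skip: int | None) -> tuple[float, list[tuple[int, int]]]:
    n, m = len(mol), len(ref)
    if n == 0 or m == 0:
        return 0.0, []
    ka = n if max_skip is None else min(max_skip, n)
    kb = m if max_skip is None else min(max_skip, m)
    NEG = -1e18
    S = np.full((n, m), NEG)
    BA = np.zeros((n, m), dtype=np.int32)
    BB = np.zeros((n, m), dtype=np.int32)
    for i in range(n):
        cur = np.full(m, match_bonus - fp_penalty * i)
        ba = np.zeros(m, dtype=np.int32)
        bb = np.zeros(m, dtype=np.int32)
        for a in range(1, min(ka, i) + 1):
            d_mol = mol[i] - mol[i - a]
            base = match_bonus - fp_penalty * (a - 1)
            prev_row = S[i - a]
            for b in range(1, kb + 1):
                if b > m - 1:
                    break
                d_map = ref[b:] - ref[:-b]
                pen = ((d_mol - d_map) / (tolerance_cv * d_map)) ** 2
                cand = prev_row[:-b] + base - pen - fn_penalty * (b - 1)
                sl = slice(b, m)
                upd = cand > cur[sl]
                if np.any(upd):
                    cur_s = cur[sl]
                    cur_s[upd] = cand[upd]
                    cur[sl] = cur_s
                    ba_s = ba[sl]; ba_s[upd] = a; ba[sl] = ba_s
                    bb_s = bb[sl]; bb_s[upd] = b; bb[sl] = bb_s
        S[i] = cur
        BA[i] = ba
        BB[i] = bb
    final = S - fp_penalty * (n - 1 - np.arange(n))[:, None]
    i, j = np.unravel_index(int(np.argmax(final)), final.shape)
    best = float(final[i, j])
    if best <= 0.0:
        return 0.0, []
    pairs = []
    while True:
        pairs.append((int(i), int(j)))
        a, b = int(BA[i, j]), int(BB[i, j])
        if a == 0:
            break
        i, j = i - a, j - b
    pairs.reverse()
    return best, pairs


def align_labels(molecule_labels: Sequence[float], map_labels: Sequence[float],
                 tolerance_cv: float = DEFAULT_TOLERANCE_CV,
                 match_bonus: float = DEFAULT_MATCH_BONUS,
                 fp_penalty: float = DEFAULT_FP_PENALTY,
                 fn_penalty: float = DEFAULT_FN_PENALTY,
                 max_skip: int | None = None,
                 molecule_id: int | str = 0,
                 map_id: str = "map") -> LabelAlignment:
    """Optimal monotone alignment of a molecule label list to a map label list.

    Both lists must be sorted.  ``max_skip`` bounds the number of consecutive
    unmatched labels considered between matched pairs (a banding speed knob;
    ``None`` searches the full matching space and is optimal under the module
    objective).  An empty map yields the defined empty alignment with score 0.

    Molecule label indices in the returned pairs always refer to the input
    order; for orientation ``-`` the molecule was reversed and mirrored before
    matching.
    """
    mol = np.asarray(molecule_labels, dtype=float)
    ref = np.asarray(map_labels, dtype=float)
    args = (tolerance_cv, match_bonus, fp_penalty, fn_penalty, max_skip)
    s_fwd, p_fwd = _dp_align(mol, ref, *args)
    s_rev, p_rev = _dp_align(_mirror(mol), ref, *args)
    n = len(mol)
    if s_rev > s_fwd:
        pairs = [(n - 1 - i, j) for (i, j) in p_rev]
        score, orientation = s_rev, "-"
    else:
        pairs, score, orientation = p_fwd, s_fwd, "+"
    unmatched_mol = n - len(pairs)
    unmatched_map = 0
    if pairs:
        js = [j for _, j in pairs]
        unmatched_map = (max(js) - min(js) + 1) - len(pairs)
    return LabelAlignment(molecule_id=molecule_id, map_id=map_id,
                          orientation=orientation, pairs=pairs, score=score,
                          unmatched_molecule=unmatched_mol,
                          unmatched_map=unmatched_map)


# --------------------------------------------------------------------------- #
# fast placement: histogram lags + elastic walk
# --------------------------------------------------------------------------- #


@dataclass
class Occurrence:
    """One placement of a template label pattern inside a molecule."""

    lag: float                              # molecule_pos - template_pos
    pairs: list[tuple[int, int]]            # (molecule idx, template idx)
    matched: int
    n_overlap: int                          # template labels within the overlap
    mol_span: tuple[float, float]
    score: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def frac(self) -> float:
        return self.matched / max(1, self.n_overlap)


def candidate_lags(mol: np.ndarray, tmpl: np.ndarray, bin_width: float = 2500.0,
                   min_count: int = 4, cluster_w: float = 1000.0,
                   max_lags: int = 6) -> np.ndarray:
    """Candidate offsets (molecule minus template) for template placement.

    A genuine placement makes many molecule-minus-template position
    differences coincide to within the sizing noise, while chance
    coincidences spread uniformly; the candidates are the centres of the
    densest ``cluster_w``-wide clusters of the pooled differences (at least
    ``min_count`` strong, at most ``max_lags`` after suppression within
    ``2 * bin_width``), strongest first when truncated."""
    if len(mol) == 0 or len(tmpl) == 0:
        return np.empty(0)
    diffs = (mol[:, None] - tmpl[None, :]).ravel()
    thresh = max(min_count, 1)
    # two half-offset histograms at the cluster width (O(n)): a tight
    # cluster lands whole in a bin of at least one grid, while the diffuse
    # spacing-comb background spreads; candidate peaks are then refined on
    # the exact differences
    sorted_diffs = np.sort(diffs)
    cand_counts = []
    cand_centres = []
    for shift in (0.0, cluster_w / 2):
        f = np.floor((diffs + shift) / cluster_w).astype(np.int64)
        f0 = int(f.min())
        counts = np.bincount(f - f0)
        sel = np.flatnonzero(counts >= thresh)
        cand_counts.append(counts[sel])
        cand_centres.append((sel + f0 + 0.5) * cluster_w - shift)
    counts_all = np.concatenate(cand_counts)
    centres_all = np.concatenate(cand_centres)
    if counts_all.size == 0:
        return np.empty(0)
    order = np.argsort(-counts_all, kind="stable")[:20 * max_lags]
    kept: list[float] = []
    for oi in order:
        centre = float(centres_all[oi])
        if len(kept) >= max_lags:
            break
        if any(abs(centre - prev) <= 2 * bin_width for prev in kept):
            continue
        lo = np.searchsorted(sorted_diffs, centre - 1.5 * cluster_w)
        hi_i = np.searchsorted(sorted_diffs, centre + 1.5 * cluster_w)
        near = sorted_diffs[lo:hi_i]
        if near.size < thresh:
            continue
        hi = np.searchsorted(near, near + cluster_w, side="right")
        k = int(np.argmax(hi - np.arange(near.size)))
        if hi[k] - k < thresh:
            continue
        lag = float(near[(k + hi[k] - 1) // 2])    # cluster median
        if all(abs(lag - prev) > 2 * bin_width for prev in kept):
            kept.append(lag)
    return np.array(sorted(kept))


def elastic_match(mol: np.ndarray, tmpl: np.ndarray, lag: float,
                  tol_abs: float = 500.0, tol_rel: float = 0.06,
                  tol_cap: float = 1500.0) -> list[tuple[int, int]]:
    """Greedy monotone walk placing template labels at ``tmpl + lag`` and
    matching each to the nearest free molecule label within a tolerance that
    grows (up to ``tol_cap``) with the distance since the last match,
    absorbing multiplicative sizing drift.  Only template labels whose
    placement falls near the molecule's span are visited."""
    pairs: list[tuple[int, int]] = []
    if len(mol) == 0 or len(tmpl) == 0:
        return pairs
    slack = 30_000.0
    j_lo = int(np.searchsorted(tmpl, mol[0] - lag - slack))
    j_hi = int(np.searchsorted(tmpl, mol[-1] - lag + slack))
    mol_list = mol.tolist()
    tmpl_list = tmpl[j_lo:j_hi].tolist()
    n_mol = len(mol_list)
    offset = lag
    last_t = None
    next_i = 0
    for jj, t in enumerate(tmpl_list):
        expect = t + offset
        gap = (t - last_t) if last_t is not None else 0.0
        tol = tol_abs + tol_rel * gap
        if tol > tol_cap:
            tol = tol_cap
        k = bisect_left(mol_list, expect)
        best = None
        best_d = tol
        for c in (k - 1, k):
            if next_i <= c < n_mol:
                dist = abs(mol_list[c] - expect)
                if dist <= best_d:
                    best_d = dist
                    best = c
        if best is not None:
            pairs.append((best, j_lo + jj))
            offset = mol_list[best] - t
            last_t = t
            next_i = best + 1
    return pairs


def score_occurrence(mol: np.ndarray, tmpl: np.ndarray,
                     pairs: Sequence[tuple[int, int]],
                     tolerance_cv: float = DEFAULT_TOLERANCE_CV,
                     match_bonus: float = DEFAULT_MATCH_BONUS,
                     fp_penalty: float = DEFAULT_FP_PENALTY,
                     fn_penalty: float = DEFAULT_FN_PENALTY) -> float:
    """Local variant of the alignment objective for a template occurrence:
    unmatched molecule labels are only penalized inside the matched molecule
    span (the rest of the molecule belongs to neighbouring templates)."""
    if not pairs:
        return 0.0
    i_lo, i_hi = pairs[0][0], pairs[-1][0]
    score = -fp_penalty * ((i_hi - i_lo + 1) - len(pairs))
    prev = None
    for (i, j) in pairs:
        score += match_bonus
        if prev is not None:
            d_mol = mol[i] - mol[prev[0]]
            d_tmpl = tmpl[j] - tmpl[prev[1]]
            score -= ((d_mol - d_tmpl) / (tolerance_cv * d_tmpl)) ** 2
            score -= fn_penalty * (j - prev[1] - 1)
        prev = (i, j)
    return float(score)


def trim_pairs(mol: np.ndarray, ref: np.ndarray,
               pairs: list[tuple[int, int]],
               tolerance_cv: float = DEFAULT_TOLERANCE_CV,
               match_bonus: float = DEFAULT_MATCH_BONUS,
               fp_penalty: float = DEFAULT_FP_PENALTY,
               fn_penalty: float = DEFAULT_FN_PENALTY) -> list[tuple[int, int]]:
    """Drop score-negative matched pairs from both ends of a matching.

    The elastic walk matches greedily within its tolerance; at a structural
    boundary (end of homologous material, a translocation junction) it can
    keep appending chance matches whose sizing penalties make them net
    losses.  Those contribute negatively under the alignment objective and
    are peeled off here, so the matched index range reflects the genuinely
    aligned segment."""

    def marginal(prev: tuple[int, int], cur: tuple[int, int]) -> float:
        d_mol = mol[cur[0]] - mol[prev[0]]
        d_map = ref[cur[1]] - ref[prev[1]]
        return (match_bonus
                - ((d_mol - d_map) / (tolerance_cv * d_map)) ** 2
                - fn_penalty * (cur[1] - prev[1] - 1)
                - fp_penalty * (cur[0] - prev[0] - 1))

    pairs = list(pairs)
    changed = True
    while changed and len(pairs) > 1:
        changed = False
        if marginal(pairs[-2], pairs[-1]) < 0:
            pairs.pop()
            changed = True
        if len(pairs) > 1 and marginal(pairs[0], pairs[1]) < 0:
            pairs.pop(0)
            changed = True
    return pairs


def find_occurrences(mol: np.ndarray, tmpl: np.ndarray,
                     min_frac: float = 0.55, min_matched: int = 5,
                     bin_width: float = 2500.0,
                     tol_abs: float = 500.0, tol_rel: float = 0.06,
                     edge_tol: float = 2000.0,
                     min_score_frac: float = 0.3) -> list[Occurrence]:
    """All non-overlapping placements of ``tmpl`` within ``mol`` with matched
    fraction >= ``min_frac`` of the template labels falling inside the
    molecule's span and a sizing-consistent occurrence score (chance
    placements match labels only by tolerating large sizing errors, which the
    quadratic penalty of :func:`score_occurrence` rejects).  Works for
    templates longer than the molecule (the molecule then sits inside the
    template).  Sorted by molecule position."""
    if len(mol) == 0 or len(tmpl) == 0:
        return []
    out: list[Occurrence] = []
    for lag in candidate_lags(mol, tmpl, bin_width=bin_width,
                              min_count=min(min_matched, len(tmpl), len(mol))):
        pairs = elastic_match(mol, tmpl, lag, tol_abs=tol_abs, tol_rel=tol_rel)
        if len(pairs) < min_matched:
            continue
        placed = tmpl + lag
        n_overlap = int(np.sum((placed >= mol[0] - edge_tol)
                               & (placed <= mol[-1] + edge_tol)))
        if n_overlap == 0 or len(pairs) / n_overlap < min_frac:
            continue
        score = score_occurrence(mol, tmpl, pairs)
        if score < max(2.0, min_score_frac * n_overlap):
            continue
        span = (float(mol[pairs[0][0]]), float(mol[pairs[-1][0]]))
        out.append(Occurrence(lag=float(lag), pairs=pairs, matched=len(pairs),
                              n_overlap=n_overlap, mol_span=span, score=score))
    # greedy non-overlap selection by score
    out.sort(key=lambda o: -o.score)
    kept: list[Occurrence] = []
    for o in out:
        if all(_span_overlap(o.mol_span, k.mol_span) < 0.5 * _span_len(o.mol_span)
               for k in kept):
            kept.append(o)
    kept.sort(key=lambda o: o.mol_span[0])
    return kept


def _span_len(s: tuple[float, float]) -> float:
    return max(1.0, s[1] - s[0])


def _span_overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
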