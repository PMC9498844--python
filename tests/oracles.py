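"""Independent reference implementations used as test oracles.

Each oracle recomputes a quantity by brute force or first principles,
sharing no code path with the implementation it checks.
"""

from itertools import combinations

import numpy as np

TOLERANCE_CV = 0.06
MATCH_BONUS = 1.0
FP_PENALTY = 0.4
FN_PENALTY = 0.6


def score_monotone_matching(mol, ref, pairs):
    """Direct evaluation of the alignment objective for one matching."""
    if not pairs:
        return 0.0
    score = -FP_PENALTY * (len(mol) - len(pairs))
    prev = None
    for i, j in pairs:
        score += MATCH_BONUS
        if prev is not None:
            d_mol = mol[i] - mol[prev[0]]
            d_map = ref[j] - ref[prev[1]]
            score -= ((d_mol - d_map) / (TOLERANCE_CV * d_map)) ** 2
            score -= FN_PENALTY * (j - prev[1] - 1)
        prev = (i, j)
    return score


def brute_force_best_score(mol, ref):
    """Optimum of the alignment objective by exhaustive enumeration of all
    monotone matchings, both molecule orientations."""
    mol = np.asarray(mol, float)
    ref = np.asarray(ref, float)

    def best_one_orientation(q):
        n, m = len(q), len(ref)
        best = 0.0
        for k in range(1, min(n, m) + 1):
            for mi in combinations(range(n), k):
                for ri in combinations(range(m), k):
                    best = max(best, score_monotone_matching(
                        q, ref, list(zip(mi, ri))))
        return best

    mirrored = (mol[0] + mol[-1]) - mol[::-1] if len(mol) else mol
    return max(best_one_orientation(mol), best_one_orientation(mirrored))


def classify_trio_marker(proband_allele, mother, father):
    """Truth-table classification of one STRP marker (hemizygous proband)."""
    in_m = proband_allele in set(mother)
    in_f = proband_allele in set(father)
    if in_m and in_f:
        return "uninformative"
    if in_m:
        return "informative_father_deleted"
    if in_f:
        return "informative_mother_deleted"
    return "uninformative"


def walk_deletion_size(homolog_a, homolog_d, module_a, module_d, offset,
                       module_len=160_000):
    """Deletion size by walking block lengths from each homolog's start to
    its breakpoint (frames share the proximal-anchor origin)."""

    def local_breakpoint(hom, region, index):
        walked = 0
        for b in hom.blocks:
            if b.kind == "module_array" and b.region == region:
                return walked + (index - 1) * module_len + offset
            walked += b.length
        raise AssertionError(f"no {region} array in {hom.name}")

    bp_a = local_breakpoint(homolog_a, "LCR22A", module_a)
    bp_d = local_breakpoint(homolog_d, "LCR22D", module_d)
    return bp_d - bp_a


def recount_label_coverage(n_labels, alignments):
    """Per-label molecule tally over alignment pairs, counted independently."""
    counts = [0] * n_labels
    for al in alignments:
        for _i, j in al.pairs:
            counts[j] += 1
    return counts
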