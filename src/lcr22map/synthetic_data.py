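"""Synthetic single-molecule and STRP data generation.

Emulates the data an optical-mapping instrument produces from the miniature
LCR22 coordinate system: BNX-like single-molecule label records with false
positive labels (3-5% per true label), false negative label dropout (9-17%
per label), multiplicative sizing noise on inter-label distances, and a
minimum-length cutoff; plus trio short-tandem-repeat-polymorphism (STRP)
genotype tables with hemizygous proband calls across the deleted region.

All randomness flows through explicit integer seeds; the same seed gives
byte-identical BNX output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import haplotype_model as hm
from .errors import ParameterError, ParseError

# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass
class NoiseParams:
    """Instrument error model.

    fp_rate: expected false labels per true label (valid range 0.03-0.05 per
    the recommended data-quality window; interpreted as a per-label rate).
    fn_rate: per-label dropout probability (window 0.09-0.17).
    sizing_cv: coefficient of variation of inter-label distances.
    mean_length / min_length: molecule length law - shifted exponential with
    the given mean, truncated below at min_length (the manufacturer-default
    150 kbp cutoff).  long_mode_min is the stricter cutoff of the
    long-molecule profile used for duplicon chaining, where molecules must
    uniquely span tandem 160 kbp modules.
    """

    fp_rate: float = 0.04
    fn_rate: float = 0.13
    sizing_cv: float = 0.02
    mean_length: float = 250_000.0
    min_length: float = 150_000.0
    long_mode_min: float = 160_000.0
    chimera_rate: float = 0.0       # off by default; exists for robustness tests

    def __post_init__(self):
        for name in ("fp_rate", "fn_rate", "sizing_cv", "chimera_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1)")
        if not self.min_length < self.mean_length:
            raise ParameterError("min_length must be below mean_length")


@dataclass(eq=False)
class Molecule:
    """One simulated single-DNA-molecule record.

    ``labels`` are observed positions on the molecule-local 1-based frame,
    strictly increasing.  ``source_homolog``, ``start``/``end`` (source-map
    frame) and ``orientation`` are hidden generator truth retained for
    evaluation only; they are not written to BNX files.  ``truth`` carries
    per-molecule error-model tallies (true/dropped/false label counts).
    """

    molecule_id: int
    length: float
    labels: np.ndarray
    qualities: np.ndarray
    source_homolog: str | None = None
    start: float | None = None
    end: float | None = None
    orientation: str | None = None
    truth: dict | None = None


@dataclass
class StrpTable:
    """Trio STRP genotype table.

    ``genotypes`` maps (marker, individual) -> tuple of allele sizes in bp
    (length 1 = hemizygous/single peak, length 2 = diploid).  ``truth`` is
    generator-only: per-marker transmitted allele and informativeness flag.
    """

    markers: list[str]
    individuals: list[str]
    genotypes: dict[tuple[str, str], tuple[int, ...]]
    positions: dict[str, int] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def alleles(self, marker: str, individual: str) -> tuple[int, ...]:
        return self.genotypes[(marker, individual)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.markers:
            for ind in self.individuals:
                g = self.genotypes[(m, ind)]
                rows.append({"marker": m, "individual": ind,
                             "allele1": g[0],
                             "allele2": g[1] if len(g) > 1 else pd.NA})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StrpTable":
        df = pd.read_csv(path)
        markers = list(dict.fromkeys(df["marker"]))
        individuals = list(dict.fromkeys(df["individual"]))
        genotypes = {}
        for _, r in df.iterrows():
            g = (int(r["allele1"]),) if pd.isna(r["allele2"]) \
                else (int(r["allele1"]), int(r["allele2"]))
            genotypes[(r["marker"], r["individual"])] = g
        return cls(markers=markers, individuals=individuals, genotypes=genotypes)


# --------------------------------------------------------------------------- #
# molecule simulation
# --------------------------------------------------------------------------- #


def simulate_molecules(map_positions: Sequence[float],
                       map_span: tuple[float, float],
                       coverage: float,
                       params: NoiseParams | None = None,
                       seed: int = 0,
                       source_homolog: str | None = None,
                       id_start: int = 1) -> list[Molecule]:
    """Shear a label map into noisy single molecules at the requested coverage.

    Molecules are emitted until their summed length reaches
    ``coverage * span``; each has a uniformly placed start and a shifted-
    exponential length (mean ``mean_length``, truncated below at
    ``min_length`` - the default length-filter profile, under which no
    sub-cutoff molecule is emitted).  Per molecule, every true label inside
    the fragment is dropped with probability ``fn_rate``; false labels are
    added as a Poisson count with mean ``fp_rate`` times the number of true
    labels, placed uniformly; inter-label distances are then perturbed
    multiplicatively with standard deviation ``sizing_cv``; finally the
    molecule is flipped to a random strand orientation.  Deterministic for a
    fixed seed.
    """
    if params is None:
        params = NoiseParams()
    if coverage <= 0:
        raise ParameterError(f"coverage must be positive, got {coverage}")
    pos = np.asarray(map_positions, dtype=float)
    lo, hi = float(map_span[0]), float(map_span[1])
    span = hi - lo + 1
    rng = np.random.default_rng([seed, 101])
    target = coverage * span
    total = 0.0
    out: list[Molecule] = []
    mol_id = id_start
    while total < target:
        length = params.min_length + rng.exponential(
            params.mean_length - params.min_length)
        length = min(length, span)
        start = rng.uniform(lo, hi - length + 1)
        end = start + length - 1
        inside = pos[(pos >= start) & (pos <= end)]
        keep = rng.random(inside.size) > params.fn_rate
        true_local = inside[keep] - start + 1
        n_false = rng.poisson(params.fp_rate * inside.size)
        false_local = rng.uniform(1, length, n_false)
        labels = np.concatenate([true_local, false_local])
        quals = np.concatenate([rng.uniform(0.5, 1.0, true_local.size),
                                rng.uniform(0.2, 0.8, n_false)])
        order = np.argsort(labels)
        labels, quals = labels[order], quals[order]
        if labels.size > 1 and params.sizing_cv > 0:
            d = np.diff(labels) * (1 + rng.normal(0, params.sizing_cv,
                                                  labels.size - 1))
            d = np.maximum(d, 1.0)
            labels = np.concatenate([[labels[0]], labels[0] + np.cumsum(d)])
        orientation = "+" if rng.random() < 0.5 else "-"
        if orientation == "-":
            labels = np.sort(length + 1 - labels)
            quals = quals[::-1].copy()
        out.append(Molecule(
            molecule_id=mol_id, length=float(length), labels=labels,
            qualities=quals, source_homolog=source_homolog,
            start=float(start), end=float(end), orientation=orientation,
            truth={"n_true": int(inside.size),
                   "n_dropped": int(inside.size - true_local.size),
                   "n_false": int(n_false)}))
        total += length
        mol_id += 1
    return out


def simulate_homolog(arch: hm.Architecture, homolog: hm.Homolog,
                     coverage: float, params: NoiseParams | None = None,
                     seed: int = 0, id_start: int = 1) -> list[Molecule]:
    """Convenience wrapper: realize a homolog's label map and shear it."""
    pos = hm.synthesize_positions(arch, homolog)
    return simulate_molecules(pos, (homolog.start, homolog.end), coverage,
                              params=params, seed=seed,
                              source_homolog=homolog.name, id_start=id_start)


# --------------------------------------------------------------------------- #
# BNX-mini dialect
# --------------------------------------------------------------------------- #

BNX_HEADER = "# BNX-mini v1"


def write_bnx(molecules: Sequence[Molecule], path) -> None:
    """Write molecules in the BNX-mini dialect: a header line, then three
    tab-separated lines per molecule - '0' (id, length), '1' (label
    positions), 'Q' (per-label quality scores).  Hidden generator truth is
    not written."""
    with open(path, "w") as fh:
        fh.write(BNX_HEADER + "\n")
        for m in molecules:
            fh.write(f"0\t{m.molecule_id}\t{m.length:.1f}\n")
            fh.write("1" + "".join(f"\t{p:.1f}" for p in m.labels) + "\n")
            fh.write("Q" + "".join(f"\t{q:.3f}" for q in m.qualities) + "\n")


def read_bnx(path) -> list[Molecule]:
    """Read a BNX-mini file.  Raises :class:`ParseError` (with the offending
    line number) on malformed records or non-monotone label positions."""
    molecules: list[Molecule] = []
    cur: dict | None = None

    def flush(ln: int):
        nonlocal cur
        if cur is None:
            return
        if "labels" not in cur or "quals" not in cur:
            raise ParseError("molecule record missing '1' or 'Q' line", line=ln)
        if len(cur["labels"]) != len(cur["quals"]):
            raise ParseError("label/quality count mismatch", line=ln)
        molecules.append(Molecule(molecule_id=cur["id"], length=cur["length"],
                                  labels=np.asarray(cur["labels"]),
                                  qualities=np.asarray(cur["quals"])))
        cur = None

    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            tag = parts[0]
            try:
                if tag == "0":
                    flush(ln)
                    if len(parts) != 3:
                        raise ParseError("'0' line needs id and length", line=ln)
                    cur = {"id": int(parts[1]), "length": float(parts[2])}
                elif tag == "1":
                    if cur is None:
                        raise ParseError("'1' line outside molecule record", line=ln)
                    vals = [float(v) for v in parts[1:]]
                    if any(b <= a for a, b in zip(vals, vals[1:])):
                        raise ParseError("non-monotone label positions", line=ln)
                    cur["labels"] = vals
                elif tag == "Q":
                    if cur is None:
                        raise ParseError("'Q' line outside molecule record", line=ln)
                    cur["quals"] = [float(v) for v in parts[1:]]
                else:
                    raise ParseError(f"unknown record tag {tag!r}", line=ln)
            except ValueError as e:
                raise ParseError(str(e), line=ln) from None
        flush(ln if molecules or cur else 0)
    return molecules


# --------------------------------------------------------------------------- #
# STRP trio simulation
# --------------------------------------------------------------------------- #

N_MARKERS = 8
_MARKER_POSITIONS = tuple(
    19_450_000 + i * 230_000 for i in range(N_MARKERS))  # inside the deletion


def simulate_strp_trio(catalog: hm.FamilyCatalog | None,
                       deletion_parent: str,
                       seed: int = 0,
                       min_informative: int = 3) -> StrpTable:
    """Simulate the eight-marker STRP genotype table of a deletion trio.

    All markers lie within the deleted region, so the proband receives a
    single allele from the non-deleting parent and none from the deleting
    parent (hemizygous at every marker).  Per-marker allele pools hold 4-8
    distinct fragment sizes.  A marker is informative when the proband's
    allele occurs in exactly one parent's genotype; draws are re-seeded until
    at least ``min_informative`` markers are informative by construction (the
    resample count is recorded in ``meta``).
    """
    if deletion_parent not in ("father", "mother"):
        raise ParameterError(f"unknown deletion parent {deletion_parent!r}")
    other = "mother" if deletion_parent == "father" else "father"
    for attempt in range(200):
        rng = np.random.default_rng([seed, 17, attempt])
        genotypes: dict[tuple[str, str], tuple[int, ...]] = {}
        truth: dict[str, dict] = {}
        markers = [f"STRP{i + 1}" for i in range(N_MARKERS)]
        n_informative = 0
        for mi, marker in enumerate(markers):
            base = int(rng.integers(30, 65)) * 4
            pool = base + 4 * np.arange(int(rng.integers(4, 9)))
            father = tuple(sorted(int(a) for a in rng.choice(pool, 2)))
            mother = tuple(sorted(int(a) for a in rng.choice(pool, 2)))
            parent_g = {"father": father, "mother": mother}
            transmitted = int(rng.choice(parent_g[other]))
            genotypes[(marker, "father")] = father
            genotypes[(marker, "mother")] = mother
            genotypes[(marker, "proband")] = (transmitted,)
            informative = (transmitted in parent_g[other]
                           and transmitted not in parent_g[deletion_parent])
            n_informative += informative
            truth[marker] = {"transmitted": transmitted,
                             "informative": bool(informative),
                             "deletion_parent": deletion_parent}
        if n_informative >= min_informative:
            table = StrpTable(
                markers=markers,
                individuals=["father", "mother", "proband"],
                genotypes=genotypes,
                positions={m: p for m, p in zip(markers, _MARKER_POSITIONS)},
                truth=truth,
                meta={"seed": seed, "resamples": attempt,
                      "deletion_parent": deletion_parent})
            return table
    raise ParameterError("could not draw an informative trio in 200 attempts")


# --------------------------------------------------------------------------- #
# random synthetic families (for end-to-end recovery experiments)
# --------------------------------------------------------------------------- #


def _sample_pattern(rng: np.random.Generator) -> tuple[int, ...]:
    k = int(rng.integers(3, 6))
    return tuple(sorted(int(s) for s in
                        rng.choice(hm.N_SLOTS, size=k, replace=False)))


def _distinct_patterns(rng: np.random.Generator, n: int,
                       taken: set) -> list[tuple[int, ...]]:
    out: list[tuple[int, ...]] = []
    while len(out) < n:
        p = _sample_pattern(rng)
        if p not in taken:
            taken.add(p)
            out.append(p)
    return out


def simulate_family(seed: int, arch: hm.Architecture | None = None
                    ) -> hm.FamilyCatalog:
    """A random two-parent family with a deletion proband.

    Both parents carry two intact chr22 homologs with 1-5 LCR22A modules of
    random orientation and family-unique fingerprints, a single LCR22D module
    and a random flanking-inversion state.  A random parent is the parent of
    deletion origin; the NAHR donors are a reference-orientation LCR22A module
    of one homolog and the LCR22D module of the *other* homolog, recombined at
    a random offset inside the fingerprint-free stretch.  The hidden truth
    (deletion parent, donor pair, offset) is recorded in ``meta``.
    """
    if arch is None:
        arch = hm.Architecture.build(hm.DEFAULT_ARCH_SEED)
    rng = np.random.default_rng([seed, 29])
    fp5_taken: set = set()
    fp3_taken: set = set()

    def build_parent(tag: str) -> dict[str, hm.Homolog]:
        homs = {}
        for hnum in (1, 2):
            n_a = int(rng.integers(1, 6))
            fp5s = _distinct_patterns(rng, n_a + 1, fp5_taken)
            fp3s = _distinct_patterns(rng, n_a + 1, fp3_taken)
            a_mods = [hm.make_module(arch, f"{tag}{hnum}A{i + 1}",
                                     hm.ORIENT_REF if rng.random() < 0.5
                                     else hm.ORIENT_INV,
                                     fp5s[i], fp3s[i])
                      for i in range(n_a)]
            d_mod = hm.make_module(arch, f"{tag}{hnum}D1", hm.ORIENT_REF,
                                   fp5s[n_a], fp3s[n_a])
            homs[f"chr22_h{hnum}"] = hm.build_intact_chr22(
                arch, f"chr22_h{hnum}", a_mods, [d_mod],
                inversion=bool(rng.random() < 0.5))
        return homs

    individuals = {"father": build_parent("F"), "mother": build_parent("M")}
    deletion_parent = "father" if rng.random() < 0.5 else "mother"
    other = "mother" if deletion_parent == "father" else "father"
    donor_a_name = f"chr22_h{int(rng.integers(1, 3))}"
    donor_d_name = "chr22_h2" if donor_a_name == "chr22_h1" else "chr22_h1"
    pa = individuals[deletion_parent]
    a_block = pa[donor_a_name].array_block("LCR22A")
    module_a = int(rng.integers(1, len(a_block.modules) + 1))
    # homology: the exchanged module must be reference orientation (as is the
    # LCR22D module); flip it if the draw landed on an inverted copy
    if a_block.modules[module_a - 1].orientation != hm.ORIENT_REF:
        a_block.modules[module_a - 1] = hm.ModuleUnit(
            uid=a_block.modules[module_a - 1].uid,
            orientation=hm.ORIENT_REF,
            fingerprint5=a_block.modules[module_a - 1].fingerprint5,
            fingerprint3=a_block.modules[module_a - 1].fingerprint3,
            core_sites=a_block.modules[module_a - 1].core_sites)
    offset = int(rng.integers(hm.FP_WINDOW + 1000,
                              hm.MODULE_LEN - hm.FP_WINDOW - 1000))
    event = hm.nahr_product(pa[donor_a_name], pa[donor_d_name],
                            module_a, 1, offset, arch)
    del_hap = event.product
    del_hap.name = "del_hap"
    maternal_name = f"chr22_h{int(rng.integers(1, 3))}"
    other_copy = _renamed_copy(individuals[other][maternal_name], "chr22_other")
    individuals["proband"] = {"del_hap": del_hap, "chr22_other": other_copy}
    individuals["sibling"] = {
        "chr22_a": _renamed_copy(individuals["father"]["chr22_h1"], "chr22_a"),
        "chr22_b": _renamed_copy(individuals["mother"]["chr22_h1"], "chr22_b"),
    }
    meta = {"deletion_parent": deletion_parent,
            "donor_a": [donor_a_name, module_a],
            "donor_d": [donor_d_name, 1],
            "offset": offset}
    return hm.FamilyCatalog(arch=arch, individuals=individuals, meta=meta)


def _renamed_copy(h: hm.Homolog, name: str) -> hm.Homolog:
    import copy as _copy
    out = _copy.deepcopy(h)
    out.name = name
    return out
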