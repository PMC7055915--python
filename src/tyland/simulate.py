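"""Synthetic yeast genomes with planted Ty elements and known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: genomes carrying full-length, truncated and solo-LTR Ty copies;
tandem arrays that share an internal LTR; divergent subfamilies (a canonical
type, a Ty1'-like type, and an S. paradoxus-like type derived from one
ancestor); mosaic recombinants with known breakpoints; raw repeat-annotation
hits carrying the error modes the curation pipeline repairs; and
Poisson-distributed colony counts for retromobility assays.

Substitutions are drawn per site from the closed-form Kimura 2-parameter
transition-probability matrix at the requested distance (no event-by-event
simulation): for divergence d and transition/transversion rate ratio kappa,
beta*t = d/(kappa+2), alpha*t = kappa*beta*t, and

    P(transition)        = 1/4 + 1/4 exp(-4 beta t) - 1/2 exp(-2 (alpha+beta) t)
    P(each transversion) = 1/4 - 1/4 exp(-4 beta t)   (two targets)

so the expected K2P estimate of the child-ancestor distance equals d exactly.
Indels default off, which keeps synthetic multiple alignments trivially
column-aligned (external aligners are out of scope).

Background (non-element) sequence is i.i.d. uniform ACGT, hence has no
homology to the Ty library and produces no spurious hits by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import RepeatHit

__all__ = [
    "EvolutionParams",
    "PlantedElement",
    "ErrorModeConfig",
    "MobilitySimParams",
    "GenomeTruth",
    "ElementSpec",
    "GenomeConfig",
    "TyReference",
    "evolve_sequence",
    "build_recombinant",
    "plant_genome",
    "simulate_mobility_counts",
    "make_reference_set",
    "random_genome_config",
    "reverse_complement",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# transition partner of code i (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])
# the two transversion partners of code i
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


@dataclass(frozen=True)
class EvolutionParams:
    """K2P evolution parameters for one branch.

    divergence: expected substitutions/site; kappa: transition/transversion
    rate ratio (``math.inf`` gives the transitions-only limit); indel_rate:
    expected indel events/site (default 0).
    """

    divergence: float
    kappa: float = 2.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.divergence) and self.divergence >= 0):
            raise ValueError("divergence must be finite and non-negative")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if not (math.isfinite(self.indel_rate) and self.indel_rate >= 0):
            raise ValueError("indel_rate must be finite and non-negative")


@dataclass(frozen=True)
class PlantedElement:
    """Ground-truth twin of a curated Ty element."""

    chrom: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str  # "+" or "-"
    family: str
    subfamily: str  # canonical | ty1prime | mosaic | sparadoxus
    structural_class: str  # full_length | truncated | solo_ltr
    true_breakpoints: tuple[int, ...] = ()  # element coordinates

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must be < end")
        length = self.end - self.start
        for bp in self.true_breakpoints:
            if not 0 < bp < length:
                raise ValueError("breakpoints must lie strictly inside the element")


@dataclass(frozen=True)
class ErrorModeConfig:
    """Raw-hit error modes that the curation pipeline is expected to repair."""

    p_mislabel_ltr: float = 0.0
    p_merge_tandem: float = 0.0
    p_fuse_solo: float = 0.0
    fp_rate: float = 0.0  # expected false-positive hits per 100 kb
    fp_divergence_range: tuple[float, float] = (25.0, 45.0)

    def __post_init__(self) -> None:
        for p in (self.p_mislabel_ltr, self.p_merge_tandem, self.p_fuse_solo):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0,1]")
        if self.fp_divergence_range[0] <= 20:
            raise ValueError("false-positive divergence range must start above 20%")


@dataclass(frozen=True)
class MobilitySimParams:
    """Poisson model of a retromobility reporter assay (events per 1 ml culture)."""

    true_frequency: float  # mobility events per viable (Ura+) cell
    n_replicates: int = 4
    cells_per_ml: float = 1e7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_frequency < 0:
            raise ValueError("true_frequency must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if not math.isfinite(self.true_frequency * self.cells_per_ml):
            raise ValueError("expected event count must be finite")


def evolve_sequence(ancestor: str, params: EvolutionParams) -> str:
    """Evolve a sequence under the K2P model to an expected distance.

    Per-site multinomial draw from the K2P transition-probability matrix; the
    expected K2P estimate of the output-to-ancestor distance equals
    ``params.divergence``.
    """
    if not ancestor:
        raise ValueError("ancestor must be non-empty")
    codes = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        codes[ord(b)] = i
    enc = codes[np.frombuffer(ancestor.encode("ascii"), dtype=np.uint8)]
    if (enc < 0).any():
        bad = ancestor[int(np.argmax(enc < 0))]
        raise ValueError(f"non-ACGT character in ancestor: {bad!r}")

    d = params.divergence
    if math.isinf(params.kappa):  # transitions-only limit
        beta_t, alpha_t = 0.0, d
    else:
        beta_t = d / (params.kappa + 2.0)
        alpha_t = params.kappa * beta_t
    p_ts = 0.25 + 0.25 * math.exp(-4 * beta_t) - 0.5 * math.exp(-2 * (alpha_t + beta_t))
    p_tv_each = 0.25 - 0.25 * math.exp(-4 * beta_t)

    rng = np.random.default_rng(params.seed)
    u = rng.random(enc.size)
    out = enc.astype(np.int64)
    ts_mask = u < p_ts
    tv1 = (~ts_mask) & (u < p_ts + p_tv_each)
    tv2 = (~ts_mask) & ~tv1 & (u < p_ts + 2 * p_tv_each)
    out[ts_mask] = _TRANSITION[enc[ts_mask]]
    out[tv1] = _TRANSVERSIONS[enc[tv1], 0]
    out[tv2] = _TRANSVERSIONS[enc[tv2], 1]
    seq = _BASES[out].tobytes().decode("ascii")

    if params.indel_rate > 0:
        seq = _apply_indels(seq, params.indel_rate, rng)
    return seq


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    for _ in range(rng.poisson(rate * len(seq))):
        pos = int(rng.integers(0, max(len(chars), 1)))
        if rng.random() < 0.5 and chars:
            del chars[pos]
        else:
            chars[pos:pos] = list(_random_dna(rng, int(rng.integers(1, 4))))
    return "".join(chars)


def build_recombinant(
    seq_a: str, seq_b: str, breakpoints
) -> tuple[str, tuple[int, ...]]:
    """Mosaic of two equal-length sequences switching source at each breakpoint.

    Segments alternate a, b, a, ... exactly at the given positions; returns the
    sequence and the recorded true breakpoints.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length (aligned coordinates)")
    bps = tuple(int(b) for b in breakpoints)
    if list(bps) != sorted(set(bps)):
        raise ValueError("breakpoints must be strictly increasing")
    if bps and not (0 < bps[0] and bps[-1] < len(seq_a)):
        raise ValueError("breakpoints must lie strictly inside the sequence")
    bounds = [0, *bps, len(seq_a)]
    parts = [
        (seq_a if k % 2 == 0 else seq_b)[bounds[k] : bounds[k + 1]]
        for k in range(len(bounds) - 1)
    ]
    return "".join(parts), bps


def simulate_mobility_counts(params: MobilitySimParams) -> tuple[np.ndarray, float]:
    """Replicate mobility-event counts and the viable-cell titer.

    Event counts per 1 ml culture are Poisson(true_frequency x cells_per_ml);
    the titer (Ura+ cells/ml) is reported alongside.
    """
    rng = np.random.default_rng(params.seed)
    lam = params.true_frequency * params.cells_per_ml
    counts = rng.poisson(lam, params.n_replicates)
    return counts, params.cells_per_ml


# ---------------------------------------------------------------------------
# Genome construction


@dataclass(frozen=True)
class TyReference:
    """A Ty family reference: LTR + internal sequence (element = LTR-I-LTR)."""

    family: str
    ltr: str
    internal: str

    @property
    def full(self) -> str:
        return self.ltr + self.internal + self.ltr

    @property
    def canonical_total_length(self) -> int:
        return 2 * len(self.ltr) + len(self.internal)


def make_reference_set(
    seed: int = 715,
    ltr_len: int = 334,
    internal_len: int = 5250,
    subfamily_divergence: float = 0.10,
    sparadoxus_divergence: float = 0.04,
) -> dict:
    """Generate the Ty1/Ty2 library and Ty1 subfamily reference sequences.

    The Ty1 canonical reference (334 bp LTRs + 5250 bp internal = 5918 bp, the
    length of the Ty1-H3 tester element) is the ancestor; the Ty1'-like and
    S. paradoxus-like internal references are evolved from it at the
    configured divergences.
    """
    rng = np.random.default_rng(seed)
    ty1 = TyReference("Ty1", _random_dna(rng, ltr_len), _random_dna(rng, internal_len))
    # a second family of similar structure (Ty2-like: 332 bp LTRs, 5960 bp total)
    ty2 = TyReference("Ty2", _random_dna(rng, 332), _random_dna(rng, 5296))
    sub_seed = int(rng.integers(0, 2**31 - 2))
    ty1prime = evolve_sequence(ty1.internal, EvolutionParams(subfamily_divergence, seed=sub_seed))
    spar = evolve_sequence(ty1.internal, EvolutionParams(sparadoxus_divergence, seed=sub_seed + 1))
    return {
        "Ty1": ty1,
        "Ty2": ty2,
        "ty1prime_internal": ty1prime,
        "sparadoxus_internal": spar,
    }


@dataclass(frozen=True)
class ElementSpec:
    """Request to plant one element (or tandem array) in a synthetic genome."""

    family: str = "Ty1"
    subfamily: str = "canonical"
    structural_class: str = "full_length"
    strand: str = "+"
    truncated_fraction: float = 0.6  # fraction of canonical length retained
    tandem_copies: int = 1  # >1 plants an array sharing internal LTRs
    breakpoints: tuple[int, ...] = ()  # internal-sequence coords, mosaic only
    with_fused_solo: bool = False  # plant a nearby solo eligible for fusion


@dataclass
class GenomeConfig:
    elements: list[ElementSpec]
    chrom: str = "chrI"
    spacing: int = 800  # background bp between planted features
    errors: ErrorModeConfig = field(default_factory=ErrorModeConfig)
    within_element_divergence: float = 0.01
    subfamily_divergence: float = 0.10
    reference_seed: int = 715


@dataclass
class GenomeTruth:
    genome: dict[str, str]
    elements: list[PlantedElement]
    raw_hits: list[RepeatHit]
    truth_counts: dict[str, dict[str, int]]  # family -> structural class -> n
    references: dict


def _truth_counts(elements: list[PlantedElement]) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {}
    for el in elements:
        fam = counts.setdefault(el.family, {"full_length": 0, "truncated": 0, "solo_ltr": 0})
        fam[el.structural_class] += 1
    return counts


# internal-sequence coordinate of the synthetic gag/pol boundary: on the
# 5918 bp element frame the boundary sits at ~1616 (gag ORF end), i.e. 1282
# past the 334 bp 5' LTR
DEFAULT_MOSAIC_BREAKPOINT = 1282


class _GenomeBuilder:
    """Accumulates sequence pieces, planted truth and raw hits left to right."""

    def __init__(self, config: GenomeConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.pieces: list[str] = []
        self.pos = 0
        self.elements: list[PlantedElement] = []
        self.hits: list[RepeatHit] = []
        self.next_group = 1

    def new_group(self) -> int:
        g = self.next_group
        self.next_group += 1
        return g

    def spacer(self, n: int | None = None) -> None:
        n = self.config.spacing if n is None else n
        self.pieces.append(_random_dna(self.rng, n))
        self.pos += n

    def place(
        self, fragments: list[tuple[str, str, list[int]]], strand: str
    ) -> list[tuple[int, int, str, list[int]]]:
        """Append a feature built from (seq, repeat_name, group_ids) fragments.

        On the minus strand the concatenated feature is reverse-complemented
        and fragment coordinates mirrored, as a repeat annotator reports them
        on the plus strand of the assembly.  Returns global fragment intervals
        (0-based half-open) with their names and hit groups, and emits hits.
        """
        start = self.pos
        local: list[tuple[int, int, str, list[int]]] = []
        cursor = 0
        for seq, name, groups in fragments:
            local.append((cursor, cursor + len(seq), name, groups))
            cursor += len(seq)
        whole = "".join(seq for seq, _, _ in fragments)
        if strand == "-":
            whole = reverse_complement(whole)
            local = [(cursor - e, cursor - s, n, g) for s, e, n, g in local][::-1]
        self.pieces.append(whole)
        self.pos += len(whole)
        placed = [(start + s, start + e, n, g) for s, e, n, g in local]
        return placed

    def emit_hit(self, s: int, e: int, strand: str, name: str, group: int, div: float) -> None:
        self.hits.append(
            RepeatHit(
                score=int(self.rng.integers(1000, 30000)),
                pct_divergence=round(div, 1),
                query_id=self.config.chrom,
                query_start=s + 1,  # 0-based half-open -> 1-based inclusive
                query_end=e,
                strand=strand,
                repeat_name=name,
                repeat_class="LTR/Copia",
                hit_group_id=group,
            )
        )


def plant_genome(config: GenomeConfig, seed: int = 0) -> GenomeTruth:
    """Build a synthetic genome with planted Ty elements and raw hits.

    Features are laid out left to right separated by ``config.spacing`` bp of
    random background; raw hits contain one fragment per LTR/internal region
    of each planted element plus the configured error modes (mislabelled
    LTRs, merged tandem arrays, fused nearby solos, false positives).
    """
    rng = np.random.default_rng(seed)
    refs = make_reference_set(
        seed=config.reference_seed, subfamily_divergence=config.subfamily_divergence
    )
    ty_by_family: dict[str, TyReference] = {"Ty1": refs["Ty1"], "Ty2": refs["Ty2"]}
    internal_by_subfamily = {
        "canonical": refs["Ty1"].internal,
        "ty1prime": refs["ty1prime_internal"],
        "sparadoxus": refs["sparadoxus_internal"],
    }
    b = _GenomeBuilder(config, rng)
    err = config.errors
    wdiv = config.within_element_divergence
    div_pct = {
        "canonical": wdiv * 100,
        "ty1prime": (config.subfamily_divergence + wdiv) * 100,
        "sparadoxus": (0.04 + wdiv) * 100,
        "mosaic": (config.subfamily_divergence / 2 + wdiv) * 100,
    }

    def drift(seq: str) -> str:
        if wdiv == 0:
            return seq
        return evolve_sequence(seq, EvolutionParams(wdiv, seed=int(rng.integers(0, 2**31 - 1))))

    for spec in config.elements:
        b.spacer()
        fam_ref = ty_by_family[spec.family]
        ltr_name, int_name = f"{spec.family}_LTR", f"{spec.family}_I"
        other_ltr = "Ty2_LTR" if spec.family == "Ty1" else "Ty1_LTR"
        d = div_pct.get(spec.subfamily, wdiv * 100)

        def ltr_label() -> str:
            # mislabelling only applies to LTRs of elements with an internal
            # region; curation can then restore the family from the internal
            return other_ltr if rng.random() < err.p_mislabel_ltr else ltr_name

        if spec.structural_class == "solo_ltr":
            g = b.new_group()
            placed = b.place([(drift(fam_ref.ltr), ltr_name, [g])], spec.strand)
            s, e, name, _ = placed[0]
            b.elements.append(PlantedElement(config.chrom, s, e, spec.strand,
                                             spec.family, spec.subfamily, "solo_ltr"))
            b.emit_hit(s, e, spec.strand, name, g, d)
            continue

        def internal_for(s: ElementSpec) -> str:
            if s.family != "Ty1":
                return fam_ref.internal
            return internal_by_subfamily.get(s.subfamily, fam_ref.internal)

        if spec.structural_class == "truncated":
            total = int(spec.truncated_fraction * fam_ref.canonical_total_length)
            keep = max(total - len(fam_ref.ltr), 200)
            internal_seq = internal_for(spec)
            g = b.new_group()
            placed = b.place(
                [
                    (drift(fam_ref.ltr), ltr_label(), [g]),
                    (drift(internal_seq[:keep]), int_name, [g]),
                ],
                spec.strand,
            )
            s0 = min(p[0] for p in placed)
            e0 = max(p[1] for p in placed)
            b.elements.append(PlantedElement(config.chrom, s0, e0, spec.strand,
                                             spec.family, spec.subfamily, "truncated"))
            for s, e, name, _gs in placed:
                b.emit_hit(s, e, spec.strand, name, g, d)
            _plant_fused_solo(b, spec, fam_ref, g, drift, d)
            continue

        # full-length, possibly a tandem array and/or a mosaic recombinant
        n_copies = max(1, spec.tandem_copies)
        internal_seq = internal_for(spec)
        breakpoints = spec.breakpoints
        if spec.family == "Ty1" and spec.subfamily == "mosaic" and not breakpoints:
            breakpoints = (DEFAULT_MOSAIC_BREAKPOINT,)
        if breakpoints:
            internal_seq, _ = build_recombinant(
                internal_by_subfamily["canonical"], internal_by_subfamily["ty1prime"],
                breakpoints,
            )

        merged = n_copies > 1 and rng.random() < err.p_merge_tandem
        groups = ([b.new_group()] * n_copies if merged
                  else [b.new_group() for _ in range(n_copies)])

        fragments: list[tuple[str, str, list[int]]] = [(drift(fam_ref.ltr), ltr_label(), [groups[0]])]
        for c in range(n_copies):
            fragments.append((drift(internal_seq), int_name, [groups[c]]))
            owners = [groups[c]] + ([groups[c + 1]] if c + 1 < n_copies else [])
            fragments.append((drift(fam_ref.ltr), ltr_label(), owners))
        placed = b.place(fragments, spec.strand)

        # per-copy truth spans: copy c = LTR_c + internal_c + LTR_{c+1}
        ltr_iv = [(s, e) for s, e, n, _ in placed if n.endswith("_LTR")]
        int_iv = [(s, e) for s, e, n, _ in placed if n.endswith("_I")]
        ltr_iv.sort()
        int_iv.sort()
        ltr_len = len(fam_ref.ltr)
        for c in range(n_copies):
            iv = int_iv[c]
            left = max(s for s, e in ltr_iv if e <= iv[0])
            right_end = min(e for s, e in ltr_iv if s >= iv[1])
            # element coordinates run along the element's own orientation, so
            # breakpoints are strand-independent: internal offset + 5' LTR
            bps = tuple(bp + ltr_len for bp in breakpoints)
            b.elements.append(
                PlantedElement(config.chrom, left, right_end, spec.strand, spec.family,
                               spec.subfamily, "full_length", true_breakpoints=bps)
            )
        for s, e, name, owners in placed:
            for g in dict.fromkeys(owners):
                b.emit_hit(s, e, spec.strand, name, g, d)
        if n_copies == 1:
            _plant_fused_solo(b, spec, fam_ref, groups[-1], drift, d)

    b.spacer()
    genome = {config.chrom: "".join(b.pieces)}

    if err.fp_rate > 0:
        glen = len(genome[config.chrom])
        lo, hi = err.fp_divergence_range
        for _ in range(rng.poisson(err.fp_rate * glen / 100_000)):
            s = int(rng.integers(0, max(glen - 400, 1)))
            e = min(s + int(rng.integers(80, 400)), glen)
            b.emit_hit(s, e, "+" if rng.random() < 0.5 else "-",
                       "Ty1_I" if rng.random() < 0.5 else "Ty1_LTR",
                       b.new_group(), float(rng.uniform(lo, hi)))

    b.hits.sort(key=lambda h: (h.query_id, h.query_start))
    return GenomeTruth(genome, b.elements, b.hits, _truth_counts(b.elements), refs)


def _plant_fused_solo(b: _GenomeBuilder, spec: ElementSpec, fam_ref: TyReference,
                      neighbour_group: int, drift, d: float) -> None:
    """Plant a solo LTR near the last element, optionally fused into its group.

    The solo sits a short distance (above any sensible gap tolerance) from the
    element body; with probability p_fuse_solo its hit is emitted under the
    neighbouring element's hit-group id, emulating incorrect joining.
    """
    if not spec.with_fused_solo:
        return
    b.spacer(250)
    fused = b.rng.random() < b.config.errors.p_fuse_solo
    g = neighbour_group if fused else b.new_group()
    placed = b.place([(drift(fam_ref.ltr), f"{spec.family}_LTR", [g])], spec.strand)
    s, e, name, _ = placed[0]
    b.elements.append(PlantedElement(b.config.chrom, s, e, spec.strand,
                                     spec.family, spec.subfamily, "solo_ltr"))
    b.emit_hit(s, e, spec.strand, name, g, d)


def random_genome_config(
    rng: np.random.Generator,
    n_elements: tuple[int, int] = (4, 9),
    all_error_modes: bool = True,
) -> GenomeConfig:
    """Draw a random valid genome layout for end-to-end oracle testing."""
    n = int(rng.integers(*n_elements))
    specs: list[ElementSpec] = []
    for _ in range(n):
        r = rng.random()
        strand = "+" if rng.random() < 0.5 else "-"
        family = "Ty1" if rng.random() < 0.8 else "Ty2"
        if r < 0.35:
            sub = ["canonical", "ty1prime", "mosaic"][int(rng.integers(0, 3))]
            if family == "Ty2":
                sub = "canonical"
            specs.append(ElementSpec(family=family, subfamily=sub, strand=strand,
                                     with_fused_solo=rng.random() < 0.4))
        elif r < 0.5:
            specs.append(ElementSpec(family=family, strand=strand,
                                     tandem_copies=int(rng.integers(2, 4))))
        elif r < 0.75:
            frac = float(rng.uniform(0.3, 0.8))
            specs.append(ElementSpec(family=family, structural_class="truncated",
                                     truncated_fraction=frac, strand=strand,
                                     with_fused_solo=rng.random() < 0.4))
        else:
            specs.append(ElementSpec(family=family, structural_class="solo_ltr",
                                     strand=strand))
    errors = (
        ErrorModeConfig(p_mislabel_ltr=0.5, p_merge_tandem=1.0, p_fuse_solo=1.0, fp_rate=5.0)
        if all_error_modes
        else ErrorModeConfig()
    )
    return GenomeConfig(elements=specs, errors=errors)
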