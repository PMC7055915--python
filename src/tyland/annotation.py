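"""Curation of raw repeat-annotation hits into structurally classified Ty elements.

Raw RepeatMasker-style hits against a Ty library (per-family LTR and internal
entries) contain characteristic errors: spurious matches to divergent
sequence, LTR fragments labelled with the wrong family, tandem arrays joined
under one hit id, and nearby solo LTRs fused to an adjacent element.  The
pipeline here applies, in order:

  (i)   remove hits with >20% divergence to the library entry;
  (ii)  relabel LTR fragments to the family of the internal region found in
        the same contiguous hit group;
  (iii) split tandem arrays sharing an internal LTR into component copies,
        the shared LTR represented in each copy;
  (iv)  split off flanking solo LTRs incorrectly joined to an element.

Each resulting hit group becomes one Ty element, classified as full-length
(internal region present, total length > 95% of the canonical element
length), truncated (internal present, below 95%) or a solo LTR (no internal
match).  Elements get ids "<strain>_<f|t|s><serial>" and are written as
BED12 records (one block per fragment).  Ty1 and Ty2 solo-LTR counts are
pooled, their LTRs being too similar to assign unambiguously.

"total length" is the sum of aligned fragment lengths, not the genomic span,
so the 95% rule measures sequence completeness and is insensitive to nested
insertions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO

__all__ = [
    "RepeatHit",
    "TyFamily",
    "TyLibrary",
    "TyElement",
    "FamilyCounts",
    "parse_rm_out",
    "write_rm_out",
    "filter_false_positives",
    "relabel_ltr_fragments",
    "group_hits",
    "split_tandem_arrays",
    "split_fused_solos",
    "classify_structure",
    "assign_element_ids",
    "write_bed12",
    "read_bed12",
    "count_by_family",
    "curate",
]


STRUCT_PREFIX = {"full_length": "f", "truncated": "t", "solo_ltr": "s"}
FULL_LENGTH_FRACTION = 0.95
DEFAULT_MAX_DIVERGENCE = 20.0
DEFAULT_GAP_TOLERANCE = 100


@dataclass(frozen=True)
class RepeatHit:
    """One row of a RepeatMasker .out file (1-based inclusive coordinates)."""

    score: float
    pct_divergence: float
    query_id: str
    query_start: int
    query_end: int
    strand: str  # "+" or "-" (parsed from "C")
    repeat_name: str
    repeat_class: str
    hit_group_id: int

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("query_start must be <= query_end")
        if not 0 <= self.pct_divergence <= 100:
            raise ValueError("pct_divergence must be in [0, 100]")

    @property
    def family(self) -> str:
        """Family part of the repeat name ("Ty1_LTR" -> "Ty1")."""
        return self.repeat_name.rsplit("_", 1)[0]

    @property
    def is_ltr(self) -> bool:
        return self.repeat_name.endswith("_LTR")

    @property
    def is_internal(self) -> bool:
        return self.repeat_name.endswith("_I")

    @property
    def length(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass(frozen=True)
class TyFamily:
    name: str
    ltr_length: int
    internal_length: int

    @property
    def canonical_total_length(self) -> int:
        return 2 * self.ltr_length + self.internal_length


class TyLibrary:
    """Per-family LTR/internal reference lengths (from a query-library FASTA).

    The library FASTA distinguishes "<family>_LTR" and "<family>_I" records.
    """

    def __init__(self, families: dict[str, TyFamily]):
        self.families = dict(families)

    @classmethod
    def from_fasta(cls, path) -> "TyLibrary":
        ltr: dict[str, int] = {}
        internal: dict[str, int] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id.endswith("_LTR"):
                ltr[rec.id[:-4]] = len(rec.seq)
            elif rec.id.endswith("_I"):
                internal[rec.id[:-2]] = len(rec.seq)
        fams = {
            name: TyFamily(name, ltr[name], internal.get(name, 0))
            for name in ltr
        }
        return cls(fams)

    def __getitem__(self, name: str) -> TyFamily:
        try:
            return self.families[name]
        except KeyError:
            raise KeyError(f"family {name!r} not in Ty library") from None

    def __contains__(self, name: str) -> bool:
        return name in self.families


@dataclass
class TyElement:
    """A curated Ty element (BED12 block model, 0-based half-open blocks)."""

    element_id: str
    structural_class: str
    family: str
    strand: str
    chrom: str
    blocks: list[tuple[int, int]]
    member_hits: list[RepeatHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.blocks != sorted(self.blocks):
            raise ValueError("blocks must be sorted")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError("blocks must not overlap within an element")
        prefix = self.element_id.rsplit("_", 1)[-1][:1]
        if prefix and prefix in "fts" and STRUCT_PREFIX[self.structural_class] != prefix:
            raise ValueError("element id prefix inconsistent with structural class")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


# ---------------------------------------------------------------------------
# RepeatMasker .out I/O

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def parse_rm_out(path) -> list[RepeatHit]:
    """Read a RepeatMasker .out file (3-line header tolerated and optional).

    Standard 15-column whitespace-delimited dialect; the "C" strand marker is
    mapped to "-"; coordinates stay 1-based inclusive.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if fields[0] in {"SW", "score"}:  # header lines
                continue
            try:
                strand = fields[8]
                hits.append(
                    RepeatHit(
                        score=float(fields[0]),
                        pct_divergence=float(fields[1]),
                        query_id=fields[4],
                        query_start=int(fields[5]),
                        query_end=int(fields[6]),
                        strand="-" if strand == "C" else strand,
                        repeat_name=fields[9],
                        repeat_class=fields[10],
                        hit_group_id=int(fields[14]),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed .out row at line {lineno}: {exc}") from exc
    return hits


def write_rm_out(hits, path) -> None:
    """Write hits in the standard 15-column .out layout (with header)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for h in hits:
            strand = "C" if h.strand == "-" else "+"
            left = 0  # remaining query length not tracked for synthetic hits
            fh.write(
                f"{h.score:>7.0f} {h.pct_divergence:>5.1f}  0.0  0.0  "
                f"{h.query_id:<10} {h.query_start:>8} {h.query_end:>8} ({left})  "
                f"{strand}  {h.repeat_name:<14} {h.repeat_class:<18} "
                f"1  {h.query_end - h.query_start + 1}  (0)  {h.hit_group_id}\n"
            )


# ---------------------------------------------------------------------------
# Curation operations


def filter_false_positives(hits, max_divergence: float = DEFAULT_MAX_DIVERGENCE):
    """Drop hits more than ``max_divergence`` percent diverged (strict >)."""
    return [h for h in hits if h.pct_divergence <= max_divergence]


def group_hits(hits) -> dict[int, list[RepeatHit]]:
    """Group hits by their annotation-run group id, position-sorted."""
    groups: dict[int, list[RepeatHit]] = {}
    for h in hits:
        groups.setdefault(h.hit_group_id, []).append(h)
    for g in groups.values():
        g.sort(key=lambda h: (h.query_id, h.query_start))
    return groups


def relabel_ltr_fragments(hits) -> list[RepeatHit]:
    """Rename mislabelled LTR fragments after the group's internal region.

    Within a hit group containing a Ty1 or Ty2 internal fragment, LTR
    fragments named for a different family are renamed to the internal
    fragment's family.  Groups with no internal fragment are untouched;
    groups with internals from two families are flagged and left unchanged.
    """
    out: list[RepeatHit] = []
    for _, group in sorted(group_hits(hits).items()):
        internal_families = {h.family for h in group if h.is_internal}
        if len(internal_families) > 1:
            warnings.warn(
                f"hit group {group[0].hit_group_id} has internal fragments from "
                f"{sorted(internal_families)}; left unchanged",
                stacklevel=2,
            )
            out.extend(group)
            continue
        if not internal_families:
            out.extend(group)
            continue
        fam = internal_families.pop()
        for h in group:
            if h.is_ltr and h.family != fam:
                h = replace(h, repeat_name=f"{fam}_LTR")
            out.append(h)
    out.sort(key=lambda h: (h.query_id, h.query_start))
    return out


def split_tandem_arrays(groups: dict[int, list[RepeatHit]]) -> list[list[RepeatHit]]:
    """Split L-I-L-I-...-L tandem groups into component L-I-L copies.

    The internal (shared) LTR is represented in each flanking copy.  Groups
    that do not match a clean alternating pattern are left unsplit (a warning
    is issued for groups with multiple internals that cannot be resolved).
    """
    out: list[list[RepeatHit]] = []
    for _, group in sorted(groups.items()):
        internals = [h for h in group if h.is_internal]
        if len(internals) < 2:
            out.append(group)
            continue
        pattern = ["I" if h.is_internal else "L" for h in group]
        expected = ["L"] + ["I", "L"] * len(internals)
        strands = {h.strand for h in group}
        if pattern != expected or len(strands) != 1:
            warnings.warn(
                f"hit group {group[0].hit_group_id}: ambiguous tandem pattern "
                f"{''.join(pattern)}; left unsplit",
                stacklevel=2,
            )
            out.append(group)
            continue
        for c in range(len(internals)):
            out.append(group[2 * c : 2 * c + 3])  # LTR, internal, LTR
    return out


def split_fused_solos(
    element_groups: list[list[RepeatHit]], gap_tolerance: int = DEFAULT_GAP_TOLERANCE
) -> list[list[RepeatHit]]:
    """Detach solo LTRs incorrectly joined to a complete or truncated element.

    An LTR fragment separated from the element body by more than
    ``gap_tolerance`` bp of non-Ty sequence, or lying beyond an already
    complete LTR-internal-LTR structure, becomes its own solo-LTR group.
    Groups without an internal fragment are left as they are.
    """
    out: list[list[RepeatHit]] = []
    for group in element_groups:
        internals = [h for h in group if h.is_internal]
        if not internals or len(group) <= 1:
            out.append(group)
            continue
        body = list(internals)
        remaining = [h for h in group if not h.is_internal]
        # grow the body by at most one adjacent LTR on each side
        changed = True
        n_left = n_right = 0
        while changed:
            changed = False
            lo = min(h.query_start for h in body)
            hi = max(h.query_end for h in body)
            for h in list(remaining):
                if n_left == 0 and h.query_end <= lo and lo - h.query_end - 1 <= gap_tolerance:
                    body.append(h)
                    remaining.remove(h)
                    n_left += 1
                    changed = True
                elif n_right == 0 and h.query_start >= hi and h.query_start - hi - 1 <= gap_tolerance:
                    body.append(h)
                    remaining.remove(h)
                    n_right += 1
                    changed = True
        body.sort(key=lambda h: h.query_start)
        out.append(body)
        for h in remaining:  # distal or supernumerary LTRs -> solos
            out.append([h])
    return out


def classify_structure(
    element_group: list[RepeatHit], library: TyLibrary
) -> tuple[str, str]:
    """Structural class and family of one curated hit group.

    Solo LTR iff no internal fragment; otherwise full-length iff total aligned
    length exceeds 95% of the canonical element length, else truncated.
    """
    internals = [h for h in element_group if h.is_internal]
    families = {h.family for h in (internals or element_group)}
    family = sorted(families)[0]
    if family not in library:
        raise KeyError(f"unknown family {family!r}")
    if not internals:
        return "solo_ltr", family
    total = sum(h.length for h in element_group)
    if total > FULL_LENGTH_FRACTION * library[family].canonical_total_length:
        return "full_length", family
    return "truncated", family


def assign_element_ids(
    element_groups: list[list[RepeatHit]], library: TyLibrary, strain: str
) -> list[TyElement]:
    """Classify groups and assign "<strain>_<f|t|s><serial>" ids.

    Serials ascend in (chrom, start) order per strain, one counter across all
    structural classes so ids are stable identifiers of genomic position.
    """
    keyed = sorted(
        element_groups, key=lambda g: (g[0].query_id, min(h.query_start for h in g))
    )
    elements: list[TyElement] = []
    serial = 0
    for group in keyed:
        serial += 1
        cls, family = classify_structure(group, library)
        strands = [h.strand for h in group]
        strand = max(set(strands), key=strands.count)
        blocks = _merge_blocks(
            (h.query_start - 1, h.query_end) for h in group
        )
        elements.append(
            TyElement(
                element_id=f"{strain}_{STRUCT_PREFIX[cls]}{serial}",
                structural_class=cls,
                family=family,
                strand=strand,
                chrom=group[0].query_id,
                blocks=blocks,
                member_hits=list(group),
            )
        )
    return elements


def _merge_blocks(intervals) -> list[tuple[int, int]]:
    """Sort 0-based half-open intervals, merging book-ended/overlapping ones."""
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


# ---------------------------------------------------------------------------
# BED12


def write_bed12(elements: list[TyElement], path) -> None:
    """One BED12 line per element (0-based half-open, blocks = fragments)."""
    with open(path, "w") as fh:
        for el in elements:
            chrom_start = el.start
            sizes = ",".join(str(e - s) for s, e in el.blocks)
            starts = ",".join(str(s - chrom_start) for s, e in el.blocks)
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            el.chrom, chrom_start, el.end, el.element_id, 0,
                            el.strand, chrom_start, el.end, "0,0,0",
                            len(el.blocks), sizes, starts,
                        ],
                    )
                )
                + "\n"
            )


def read_bed12(path) -> list[TyElement]:
    """Read BED12 records back into TyElements (member hits not recoverable)."""
    prefix_to_class = {v: k for k, v in STRUCT_PREFIX.items()}
    elements: list[TyElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED fields")
            chrom_start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            prefix = f[3].rsplit("_", 1)[-1][:1]
            elements.append(
                TyElement(
                    element_id=f[3],
                    structural_class=prefix_to_class.get(prefix, "full_length"),
                    family="Ty1",
                    strand=f[5],
                    chrom=f[0],
                    blocks=blocks,
                )
            )
    return elements


# ---------------------------------------------------------------------------
# Counting


@dataclass
class FamilyCounts:
    """Per-family full/truncated/solo tallies with the pooled Ty1/Ty2 solo row."""

    per_family: dict[str, dict[str, int]]

    @property
    def pooled_ty1_ty2_solo(self) -> int:
        return sum(
            self.per_family.get(f, {}).get("solo_ltr", 0) for f in ("Ty1", "Ty2")
        )

    def get(self, family: str, cls: str) -> int:
        return self.per_family.get(family, {}).get(cls, 0)

    def to_frame(self):
        import pandas as pd

        rows = []
        for fam in sorted(self.per_family):
            c = self.per_family[fam]
            rows.append(
                {
                    "family": fam,
                    "full_length": c.get("full_length", 0),
                    "truncated": c.get("truncated", 0),
                    "solo_ltr": c.get("solo_ltr", 0),
                }
            )
        rows.append(
            {
                "family": "Ty1/Ty2 solo LTRs",
                "full_length": 0,
                "truncated": 0,
                "solo_ltr": self.pooled_ty1_ty2_solo,
            }
        )
        return pd.DataFrame(rows)


def count_by_family(elements: list[TyElement]) -> FamilyCounts:
    counts: dict[str, dict[str, int]] = {}
    for el in elements:
        fam = counts.setdefault(
            el.family, {"full_length": 0, "truncated": 0, "solo_ltr": 0}
        )
        fam[el.structural_class] += 1
    return FamilyCounts(counts)


def curate(
    hits,
    library: TyLibrary,
    strain: str,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
) -> list[TyElement]:
    """Run the full curation pipeline (operations i-iv) and classify."""
    kept = filter_false_positives(hits, max_divergence)
    relabelled = relabel_ltr_fragments(kept)
    groups = split_tandem_arrays(group_hits(relabelled))
    groups = split_fused_solos(groups, gap_tolerance)
    return assign_element_ids(groups, library, strain)
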