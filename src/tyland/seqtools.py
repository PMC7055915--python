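"""Strand-aware sequence extraction, pairwise alignment, reference projection,
ORF capacity checks and MSA utilities.

Coordinates follow two conventions: BED12 blocks are 0-based half-open;
reference-element region annotations (the Ty1-H3 frame) are 1-based
inclusive, as in GenBank feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align, SeqIO

from .annotation import TyElement
from .simulate import reverse_complement

__all__ = [
    "OrientedSequence",
    "RegionAnnotation",
    "PairwiseAlignment",
    "OrfCall",
    "extract_sequences",
    "global_align",
    "project_truncated",
    "check_orf_capacity",
    "remove_gap_only_columns",
    "slice_msa_region",
    "ref_coordinate_map",
    "read_fasta",
    "write_fasta",
]


@dataclass(frozen=True)
class OrientedSequence:
    """An element sequence oriented 5'->3' along its own strand."""

    id: str
    seq: str
    source: tuple[str, int, int, str]  # chrom, start, end, strand


@dataclass
class RegionAnnotation:
    """Named intervals on the reference element frame (1-based inclusive).

    For Ty1-H3 the frame is 5918 bp: LTRs, the partially overlapping gag and
    pol ORFs, the p22 region (C-terminal half of gag) with its two
    alternative start codons, the +1 frameshift heptamer, and optional helix
    and antisense-RNA interval lists.
    """

    element_length: int
    ltr5: tuple[int, int]
    gag: tuple[int, int]
    pol: tuple[int, int]
    ltr3: tuple[int, int]
    p22_region: tuple[int, int]
    p22_start_codons: tuple[int, int]
    p18_start_codon: int | None = None
    frameshift_heptamer: tuple[int, int] | None = None
    helix_regions: list[tuple[int, int]] = field(default_factory=list)
    antisense_regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("ltr5", "gag", "pol", "ltr3", "p22_region"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi <= self.element_length:
                raise ValueError(f"region {name} outside element frame")

    def region(self, name: str) -> tuple[int, int]:
        try:
            value = getattr(self, name)
        except AttributeError:
            raise KeyError(f"region {name!r} not configured") from None
        if value is None:
            raise KeyError(f"region {name!r} not configured")
        return value

    @classmethod
    def from_dict(cls, d: dict) -> "RegionAnnotation":
        kwargs = dict(d)
        for key in ("ltr5", "gag", "pol", "ltr3", "p22_region",
                    "p22_start_codons", "frameshift_heptamer"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        for key in ("helix_regions", "antisense_regions"):
            if key in kwargs and kwargs[key]:
                kwargs[key] = [tuple(iv) for iv in kwargs[key]]
        return cls(**kwargs)


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    ref_intervals_covered: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class OrfCall:
    start_pos: int  # 1-based position of the start codon used (0 if none)
    frame: int
    aa_length: int
    intact: bool


# ---------------------------------------------------------------------------
# FASTA helpers


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Extraction


def extract_sequences(genome: dict[str, str], elements: list[TyElement]) -> list[OrientedSequence]:
    """Concatenate each element's block substrings, oriented to its strand.

    Minus-strand elements are reverse-complemented so every output sequence
    reads 5'->3' along the element.
    """
    out: list[OrientedSequence] = []
    for el in elements:
        if el.chrom not in genome:
            raise KeyError(f"chromosome {el.chrom!r} missing from genome FASTA")
        chrom_seq = genome[el.chrom]
        if el.end > len(chrom_seq):
            raise ValueError(f"element {el.element_id} extends past {el.chrom} end")
        seq = "".join(chrom_seq[s:e] for s, e in el.blocks)
        if el.strand == "-":
            seq = reverse_complement(seq)
        out.append(OrientedSequence(el.element_id, seq, (el.chrom, el.start, el.end, el.strand)))
    return out


# ---------------------------------------------------------------------------
# Pairwise alignment


def _make_aligner(match, mismatch, gap_open, gap_extend, free_end_gaps: bool):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # Biopython's open score applies to the first gap position (open+extend
    # elsewhere): translate from the gap_open = cost-of-opening convention.
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    if free_end_gaps:
        # free overhangs on the reference (target) only: the query must align
        # end to end, so internal reference deletions split into blocks
        # rather than being traded for dropped query ends
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    return aligner


def global_align(
    a: str,
    b: str,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -5,
    gap_extend: float = -1,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (open+extend for a 1-gap).

    Deterministic: of co-optimal alignments the aligner's first enumeration
    order is used.  N is scored as a mismatch against everything.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, free_end_gaps=False)
    aln = aligner.align(a, b)[0]
    aligned_a, aligned_b = _gapped_rows(aln)
    return PairwiseAlignment(aligned_a, aligned_b, aln.score)


def _gapped_rows(aln) -> tuple[str, str]:
    return str(aln[0]), str(aln[1])


def project_truncated(
    truncated: OrientedSequence | str,
    reference: str,
    min_block_identity: float = 0.8,
    min_block_length: int = 30,
    p22_region: tuple[int, int] | None = None,
) -> tuple[list[tuple[int, int]], bool]:
    """Reference intervals covered by a truncated element, plus p22 span flag.

    The element is aligned to the reference with free end gaps (split
    alignments appear as separate aligned blocks around internal deletions);
    aligned blocks shorter than ``min_block_length`` or below
    ``min_block_identity`` are discarded.  Returns 1-based inclusive reference
    intervals and whether they jointly cover the whole configured p22 region.
    """
    seq = truncated.seq if isinstance(truncated, OrientedSequence) else truncated
    if not seq:
        return [], False
    # near-zero gap extension: internal deletions of the reference (the
    # missing parts of a truncated element) are cheap, as in spliced mapping,
    # so retained fragments align as separate blocks instead of being dropped
    aligner = _make_aligner(1, -1, -5, -0.05, free_end_gaps=True)
    aln = aligner.align(reference, seq)[0]
    ref_blocks, qry_blocks = aln.aligned
    intervals: list[tuple[int, int]] = []
    for (rs, re_), (qs, qe) in zip(ref_blocks, qry_blocks):
        if re_ - rs < min_block_length:
            continue
        matches = sum(
            1 for i in range(re_ - rs) if reference[rs + i] == seq[qs + i]
        )
        if matches / (re_ - rs) < min_block_identity:
            continue
        intervals.append((rs + 1, re_))  # to 1-based inclusive
    intervals = _merge_adjacent(intervals)
    spans = False
    if p22_region and intervals:
        lo, hi = p22_region
        covered = set()
        for s, e in intervals:
            covered.update(range(max(s, lo), min(e, hi) + 1))
        spans = len(covered) == hi - lo + 1
    return intervals, spans


def _merge_adjacent(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


# ---------------------------------------------------------------------------
# ORF capacity


def check_orf_capacity(
    seq: str, regions: RegionAnnotation, which: str = "p22"
) -> OrfCall:
    """Can the sequence encode an intact p22 (or p18) ORF?

    The sequence must be in the reference element frame (element-oriented,
    same coordinates as ``regions``).  Each configured alternative start
    codon is checked independently; the call is intact if any start gives an
    ATG followed by an open reading frame (no internal stop) through to the
    gag region end.  Ambiguous bases invalidate the codons containing them.
    """
    if which == "p22":
        starts = list(regions.p22_start_codons)
    elif which == "p18":
        if regions.p18_start_codon is None:
            raise KeyError("p18 start codon not configured")
        starts = [regions.p18_start_codon]
    else:
        raise KeyError(f"unknown ORF {which!r}")
    _, gag_end = regions.gag
    best = OrfCall(start_pos=0, frame=0, aa_length=0, intact=False)
    for start in starts:
        i = start - 1  # to 0-based
        if i < 0 or i + 3 > len(seq) or seq[i : i + 3] != "ATG":
            continue
        aa = 0
        intact = True
        j = i
        while j + 3 <= min(gag_end, len(seq)):
            codon = seq[j : j + 3]
            if any(c not in "ACGT" for c in codon):
                intact = False
                break
            if codon in ("TAA", "TAG", "TGA"):
                # a stop before the region end truncates the ORF
                intact = j + 3 >= gag_end - 2
                break
            aa += 1
            j += 3
        call = OrfCall(start_pos=start, frame=i % 3, aa_length=aa, intact=intact)
        if intact and (not best.intact or call.aa_length > best.aa_length):
            best = call
        elif not best.intact and call.aa_length > best.aa_length:
            best = call
    return best


# ---------------------------------------------------------------------------
# MSA utilities


def _check_msa(msa: dict[str, str]) -> int:
    lengths = {len(s) for s in msa.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    return lengths.pop() if lengths else 0


def remove_gap_only_columns(msa: dict[str, str]) -> dict[str, str]:
    """Drop columns where every row is a gap; everything else kept in order."""
    width = _check_msa(msa)
    rows = list(msa.values())
    keep = [i for i in range(width) if any(r[i] != "-" for r in rows)]
    return {k: "".join(v[i] for i in keep) for k, v in msa.items()}


def ref_coordinate_map(ref_row: str) -> dict[int, int]:
    """Map reference coordinate (1-based, gaps skipped) -> alignment column (0-based)."""
    out: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_row):
        if ch != "-":
            pos += 1
            out[pos] = col
    return out


def slice_msa_region(
    msa: dict[str, str], region: tuple[int, int], ref_id: str
) -> dict[str, str]:
    """Columns whose reference-row (non-gap) coordinate falls in the region.

    ``region`` is 1-based inclusive on the ungapped reference row ``ref_id``.
    Columns where the reference row is gapped are included when they fall
    between the region's bounding reference columns (insertions relative to
    the reference belong to the region they interrupt).
    """
    if ref_id not in msa:
        raise KeyError(f"reference row {ref_id!r} not in alignment")
    cmap = ref_coordinate_map(msa[ref_id])
    lo, hi = region
    if lo < 1 or hi > len(cmap):
        raise ValueError(f"region {region} outside reference length {len(cmap)}")
    c0, c1 = cmap[lo], cmap[hi]
    return {k: v[c0 : c1 + 1] for k, v in msa.items()}
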