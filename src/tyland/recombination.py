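"""Windowed subfamily assignment and recombination breakpoint calling.

A query element aligned with two reference elements (e.g. a canonical Ty1
and a Ty1' representative) is scanned in overlapping windows (50 bp / 10 bp
step by default); each window is labelled by the nearer reference under the
K2P distance, or ambiguous when the margin falls below a threshold or either
distance is undefined.  Breakpoints are called between maximal runs of
opposite labels, giving per-region (gag/pol) type calls and the per-strain
genotype summary used to relate genomic canonical-gag content to mobility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .divergence import sliding_window_divergence
from .seqtools import RegionAnnotation, ref_coordinate_map

__all__ = [
    "WindowAssignment",
    "BreakpointCall",
    "SubfamilyCall",
    "assign_windows",
    "call_breakpoints",
    "classify_element",
    "summarize_strain",
]

DEFAULT_MARGIN_THRESHOLD = 0.02
DEFAULT_MIN_RUN = 3


@dataclass
class WindowAssignment:
    """Per-window nearest-reference labels along the alignment."""

    starts: list[int]
    ends: list[int]
    labels: list[str]  # "ref_a" | "ref_b" | "ambiguous"
    margins: list[float]  # |d_to_a - d_to_b|, NaN when either is undefined
    ref_a: str
    ref_b: str
    window: int
    step: int


@dataclass(frozen=True)
class BreakpointCall:
    position: int  # reference (or alignment) coordinate of the switch
    left_label: str
    right_label: str
    run_lengths: tuple[int, int]  # informative windows supporting each side


@dataclass
class SubfamilyCall:
    element_id: str
    gag_type: str  # canonical | ty1prime | recombinant_gag | undetermined
    pol_type: str
    overall: str  # pure_canonical | pure_ty1prime | mosaic | other_recombinant
    fraction_gag_canonical: float
    breakpoints: list[BreakpointCall] = field(default_factory=list)


def assign_windows(
    query: str,
    ref_a: str,
    ref_b: str,
    window: int = 50,
    step: int = 10,
    margin_threshold: float = DEFAULT_MARGIN_THRESHOLD,
    min_usable: int = 25,
) -> WindowAssignment:
    """Label each window by the nearer of two references (K2P distance).

    All three rows must share one alignment frame.  A window is ambiguous
    when either distance is undefined or the distance margin is below
    ``margin_threshold`` (in particular wherever the references are locally
    identical).
    """
    if not (len(query) == len(ref_a) == len(ref_b)):
        raise ValueError("query and references must share an alignment frame")
    ta = sliding_window_divergence(query, ref_a, window, step, min_usable)
    tb = sliding_window_divergence(query, ref_b, window, step, min_usable)
    starts, ends, labels, margins = [], [], [], []
    for wa, wb in zip(ta.windows, tb.windows):
        starts.append(wa.start)
        ends.append(wa.end)
        da, db = wa.result.distance, wb.result.distance
        if math.isnan(da) or math.isnan(db):
            labels.append("ambiguous")
            margins.append(math.nan)
            continue
        margin = abs(da - db)
        margins.append(margin)
        if margin < margin_threshold:
            labels.append("ambiguous")
        else:
            labels.append("ref_a" if da < db else "ref_b")
    return WindowAssignment(starts, ends, labels, margins, "ref_a", "ref_b", window, step)


def call_breakpoints(
    assignment: WindowAssignment,
    min_run: int = DEFAULT_MIN_RUN,
    coord_map: dict[int, int] | None = None,
) -> list[BreakpointCall]:
    """Breakpoints between maximal runs of opposite labels.

    Ambiguous windows do not break runs.  A breakpoint is reported where two
    successive informative runs carry different labels and each contains at
    least ``min_run`` windows; its position is the midpoint between the end
    of the last window of one run and the start of the first window of the
    next, optionally mapped through ``coord_map`` (alignment column ->
    reference coordinate).
    """
    runs: list[tuple[str, int, int]] = []  # label, first index, last index
    for idx, label in enumerate(assignment.labels):
        if label == "ambiguous":
            continue
        if runs and runs[-1][0] == label:
            runs[-1] = (label, runs[-1][1], idx)
        else:
            runs.append((label, idx, idx))

    def run_len(r) -> int:
        return sum(
            1
            for k in range(r[1], r[2] + 1)
            if assignment.labels[k] == r[0]
        )

    calls: list[BreakpointCall] = []
    for left, right in zip(runs, runs[1:]):
        if left[0] == right[0]:
            continue
        nl, nr = run_len(left), run_len(right)
        if nl < min_run or nr < min_run:
            continue
        col = (assignment.ends[left[2]] + assignment.starts[right[1]]) // 2
        pos = col
        if coord_map is not None:
            # nearest mapped reference position at or left of the column
            inv = sorted(coord_map.items())  # (ref_pos, column)
            pos = inv[0][0]
            for ref_pos, column in inv:
                if column <= col:
                    pos = ref_pos
                else:
                    break
        calls.append(BreakpointCall(pos, left[0], right[0], (nl, nr)))
    return calls


def _region_windows(assignment: WindowAssignment, lo: int, hi: int) -> list[int]:
    """Indices of windows whose midpoint falls inside [lo, hi] (0-based cols)."""
    out = []
    for idx, (s, e) in enumerate(zip(assignment.starts, assignment.ends)):
        mid = (s + e) // 2
        if lo <= mid <= hi:
            out.append(idx)
    return out


def classify_element(
    element_id: str,
    query: str,
    ref_a: str,
    ref_b: str,
    regions: RegionAnnotation,
    ref_row: str | None = None,
    window: int = 50,
    step: int = 10,
    margin_threshold: float = DEFAULT_MARGIN_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    label_a: str = "canonical",
    label_b: str = "ty1prime",
    edge_margin: int | None = None,
) -> SubfamilyCall:
    """Assign gag and pol types and an overall subfamily call for one element.

    ``ref_row`` is the alignment row carrying the reference coordinate frame
    (defaults to ``ref_a``); gag/pol regions are mapped through it onto
    alignment columns.  Within each region the type is the majority label of
    informative windows; one or more breakpoints inside a region make it
    recombinant; fewer than 50% informative windows make it undetermined.
    A fraction of exactly 0.5 is a tie and yields undetermined rather than a
    coin flip.

    Breakpoint positions are localised to about a window width; a call within
    ``edge_margin`` (default window + step) of a region edge is attributed to
    the region boundary, not the region interior — gag and pol overlap on the
    Ty1 frame, so an exchange at the gag/pol boundary (a mosaic) must not
    flag either ORF as internally recombinant.
    """
    if edge_margin is None:
        edge_margin = window + step
    frame_row = ref_row if ref_row is not None else ref_a
    cmap = ref_coordinate_map(frame_row)
    assignment = assign_windows(query, ref_a, ref_b, window, step, margin_threshold)
    bps = call_breakpoints(assignment, min_run, coord_map=cmap)

    def region_cols(name: str) -> tuple[int, int]:
        lo, hi = regions.region(name)
        return cmap[lo], cmap[min(hi, max(cmap))]

    def region_call(name: str) -> tuple[str, float]:
        lo_col, hi_col = region_cols(name)
        idxs = _region_windows(assignment, lo_col, hi_col)
        if not idxs:
            return "undetermined", math.nan
        informative = [i for i in idxs if assignment.labels[i] != "ambiguous"]
        lo_ref, hi_ref = regions.region(name)
        internal_bps = [
            b for b in bps if lo_ref + edge_margin < b.position < hi_ref - edge_margin
        ]
        frac_a = (
            sum(1 for i in informative if assignment.labels[i] == "ref_a") / len(informative)
            if informative
            else math.nan
        )
        if len(informative) < 0.5 * len(idxs):
            return "undetermined", frac_a
        if internal_bps:
            return "recombinant", frac_a
        if not informative or frac_a == 0.5:
            return "undetermined", frac_a
        return (label_a if frac_a > 0.5 else label_b), frac_a

    gag_call, frac_gag = region_call("gag")
    pol_call, _ = region_call("pol")
    gag_type = "recombinant_gag" if gag_call == "recombinant" else gag_call
    pol_type = "recombinant_pol" if pol_call == "recombinant" else pol_call

    if gag_type == label_a and pol_type == label_a and not bps:
        overall = f"pure_{label_a}"
    elif gag_type == label_b and pol_type == label_b and not bps:
        overall = f"pure_{label_b}"
    elif gag_type == label_a and pol_type == label_b:
        overall = "mosaic"
    else:
        overall = "other_recombinant"
    return SubfamilyCall(element_id, gag_type, pol_type, overall, frac_gag, bps)


def summarize_strain(
    strain: str,
    full_length_calls: list[SubfamilyCall],
    truncated_info: list[tuple[bool, str]] = (),
    label_a: str = "canonical",
    label_b: str = "ty1prime",
) -> dict:
    """Per-strain genotype row: full-length and truncated counts by gag type.

    Full-length recombinant-gag elements count toward the group contributing
    the majority of their gag sequence.  ``truncated_info`` holds
    (spans_p22, gag_type) pairs for truncated elements; only elements whose
    retained sequence spans the whole p22 region are counted.
    """
    full_a = full_b = 0
    for call in full_length_calls:
        if call.gag_type == label_a:
            full_a += 1
        elif call.gag_type == label_b:
            full_b += 1
        elif call.gag_type == "recombinant_gag" and not math.isnan(call.fraction_gag_canonical):
            if call.fraction_gag_canonical > 0.5:
                full_a += 1
            elif call.fraction_gag_canonical < 0.5:
                full_b += 1
    trunc_a = sum(1 for spans, t in truncated_info if spans and t == label_a)
    trunc_b = sum(1 for spans, t in truncated_info if spans and t == label_b)
    return {
        "strain": strain,
        "full_length_total": len(full_length_calls),
        f"full_length_{label_a}_gag": full_a,
        f"full_length_{label_b}_gag": full_b,
        f"truncated_{label_a}_gag": trunc_a,
        f"truncated_{label_b}_gag": trunc_b,
    }
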