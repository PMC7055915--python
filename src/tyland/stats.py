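"""Mobility-assay statistics, genotype-phenotype correlation, substitution
counting and NG86 dN/dS.

Mobility frequency is defined as revertant colonies (His+ Ura+ or G418-R)
divided by Ura+ colonies per ml of culture; its standard deviation is the
sample SD (n-1 denominator) of the per-replicate frequencies, an explicit
interpretation of the assay's "SD of events per 1 ml culture" convention.
Detection-limit values ("<x") are carried as bounds: a fold change over a
bound is itself a lower bound.

The dN/dS estimator is Nei & Gojobori (1986) counting with equal pathway
weighting and Jukes-Cantor correction: a self-contained analogue of
ML codon-model estimates, not a reimplementation of one.  Mutations to stop
codons count as nonsynonymous, so N_sites + S_sites = 3 x codons exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats as sps

__all__ = [
    "MobilityRecord",
    "CorrelationResult",
    "SubstitutionSummary",
    "DnDsResult",
    "mobility_frequency",
    "estimate_frequency",
    "fold_change",
    "spearman",
    "fisher_exact_2x2",
    "count_substitutions",
    "ng86_dnds",
    "interval_length",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})


@dataclass
class MobilityRecord:
    """One strain's reporter assay: replicate counts, titer, derived frequency."""

    strain: str
    reporter: str  # his3-AI | neo-AI
    replicate_events: list[int]
    uraplus_per_ml: float
    phenotype: str = ""
    bound: bool = False  # value is a "<x" detection limit

    frequency: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.replicate_events) < 1:
            raise ValueError("need at least one replicate")
        self.frequency, self.sd = mobility_frequency(self.replicate_events, self.uraplus_per_ml)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    tie_note: bool
    method: str  # "t-approximation" | "exact-permutation"


@dataclass
class SubstitutionSummary:
    aa_substitutions_total: int
    aa_substitutions_by_region: dict[str, int]
    indel_events: int
    nt_substitutions_total: int
    nt_substitutions_by_region: dict[str, int]
    n_codons: int


@dataclass(frozen=True)
class DnDsResult:
    dN: float
    dS: float
    ratio: float  # NaN when dS == 0 or saturated
    N_sites: float
    S_sites: float
    N_diffs: float
    S_diffs: float


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive coordinate interval (GenBank style)."""
    if end < start:
        raise ValueError("end must be >= start")
    return end - start + 1


# ---------------------------------------------------------------------------
# Mobility


def mobility_frequency(replicate_events, uraplus_per_ml: float) -> tuple[float, float]:
    """Frequency = mean events / Ura+ titer; SD of per-replicate frequencies."""
    if uraplus_per_ml <= 0:
        raise ValueError("Ura+ titer must be positive")
    events = np.asarray(replicate_events, dtype=float)
    if (events < 0).any():
        raise ValueError("replicate counts must be non-negative")
    freqs = events / uraplus_per_ml
    sd = float(np.std(freqs, ddof=1)) if len(freqs) > 1 else 0.0
    return float(freqs.mean()), sd


def estimate_frequency(counts, cells_per_ml: float) -> float:
    """Point estimate of the true event frequency from simulated replicates."""
    return mobility_frequency(counts, cells_per_ml)[0]


def fold_change(high: float, low: float, low_is_bound: bool = False) -> tuple[float, bool]:
    """high/low ratio; the flag marks a lower bound (low was a "<x" value or 0)."""
    if low < 0 or high < 0:
        raise ValueError("frequencies must be non-negative")
    if low == 0:
        return math.inf, True
    return high / low, low_is_bound


# ---------------------------------------------------------------------------
# Correlation


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    p-value: exact permutation enumeration when both vectors are tie-free and
    n <= 9, otherwise the two-sided t approximation
    t = rho sqrt((n-2)/(1-rho^2)) with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not allowed")
    if len(set(x)) == 1 or len(set(y)) == 1:
        return CorrelationResult(math.nan, math.nan, n, False, "degenerate")
    ties = len(set(x)) < n or len(set(y)) < n
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if not ties and n <= 9:
        # exact null distribution by enumeration over all rank permutations
        obs = abs(rho)
        count = 0
        total = 0
        base = np.arange(1, n + 1, dtype=float)
        ry_sorted = ry[np.argsort(rx)]
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(base, ry_sorted[list(perm)])[0, 1])
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        return CorrelationResult(rho, count / total, n, False, "exact-permutation")
    if abs(rho) >= 1.0:
        return CorrelationResult(rho, 0.0, n, ties, "t-approximation")
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rho, float(p), n, ties, "t-approximation")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: total hypergeometric mass of tables (same
    margins) no more probable than the observed one.  A zero margin gives 1."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum() == 0 or 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Substitution counting and NG86


def _codon_pairs(aln_a: str, aln_b: str):
    """Yield (index, codon_a, codon_b) over a codon alignment.

    Shared-gap columns are removed first; the remaining length must be a
    multiple of 3.  Codons where either sequence retains a gap are yielded
    with None markers (indel events).
    """
    if len(aln_a) != len(aln_b):
        raise ValueError("aligned sequences must be equal length")
    a = []
    b = []
    for ca, cb in zip(aln_a.upper(), aln_b.upper()):
        if ca == "-" and cb == "-":
            continue
        a.append(ca)
        b.append(cb)
    if len(a) % 3:
        raise ValueError("alignment length not a multiple of 3 after removing shared gaps")
    for i in range(0, len(a), 3):
        yield i // 3, "".join(a[i : i + 3]), "".join(b[i : i + 3])


def count_substitutions(
    aln_a: str, aln_b: str, regions: dict[str, list[tuple[int, int]]] | None = None
) -> SubstitutionSummary:
    """Amino acid and nucleotide substitutions between codon-aligned sequences.

    Codon pairs translating to different residues count as amino acid
    substitutions; gap-containing codon pairs count as indel events, not
    substitutions.  Region membership (1-based nucleotide intervals on the
    shared codon frame) is decided by the codon's first position.
    """
    regions = regions or {}
    aa_total = 0
    nt_total = 0
    indels = 0
    aa_by_region = {r: 0 for r in regions}
    nt_by_region = {r: 0 for r in regions}
    n_codons = 0
    for idx, ca, cb in _codon_pairs(aln_a, aln_b):
        n_codons += 1
        first_nt = idx * 3 + 1
        if "-" in ca or "-" in cb:
            indels += 1
            continue
        if any(c not in "ACGT" for c in ca + cb):
            continue
        nt_diffs = sum(1 for p, q in zip(ca, cb) if p != q)
        aa_diff = _CODON_TABLE[ca] != _CODON_TABLE[cb]
        nt_total += nt_diffs
        aa_total += int(aa_diff)
        for r, ivs in regions.items():
            if any(lo <= first_nt <= hi for lo, hi in ivs):
                nt_by_region[r] += nt_diffs
                aa_by_region[r] += int(aa_diff)
    return SubstitutionSummary(aa_total, aa_by_region, indels, nt_total, nt_by_region, n_codons)


def _codon_sites(codon: str) -> tuple[float, float]:
    """Expected nonsynonymous/synonymous site counts for one codon (NG86)."""
    n = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if _CODON_TABLE[mutant] != _CODON_TABLE[codon]:
                n += 1 / 3
    return n, 3.0 - n


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) differences for one codon pair."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    n_tot = s_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(positions):
        cur = ca
        n = s = 0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        n_paths += 1
        n_tot += n
        s_tot += s
    return n_tot / n_paths, s_tot / n_paths


def ng86_dnds(aln_a: str, aln_b: str) -> DnDsResult:
    """Nei-Gojobori (1986) dN/dS between two codon-aligned sequences.

    Site counts by per-codon mutation-fate enumeration (averaged over the two
    sequences), differences averaged over all mutational pathways, and the
    Jukes-Cantor correction d = -3/4 ln(1 - 4p/3).  dS saturation
    (pS >= 0.75) yields NaN.  Gap- or ambiguity-containing codons are skipped.
    """
    N_sites = S_sites = N_diffs = S_diffs = 0.0
    for _, ca, cb in _codon_pairs(aln_a, aln_b):
        if "-" in ca or "-" in cb or any(c not in "ACGT" for c in ca + cb):
            continue
        na, sa = _codon_sites(ca)
        nb, sb = _codon_sites(cb)
        N_sites += (na + nb) / 2
        S_sites += (sa + sb) / 2
        nd, sd = _pathway_diffs(ca, cb)
        N_diffs += nd
        S_diffs += sd
    if N_sites == 0 or S_sites == 0:
        return DnDsResult(math.nan, math.nan, math.nan, N_sites, S_sites, N_diffs, S_diffs)
    pN = N_diffs / N_sites
    pS = S_diffs / S_sites

    def jc(p: float) -> float:
        if p >= 0.75:
            return math.nan
        return -0.75 * math.log(1 - 4 * p / 3) + 0.0  # normalise -0.0

    dN, dS = jc(pN), jc(pS)
    # dS == 0 (including identical sequences) -> ratio NaN by the 0/0 convention
    ratio = dN / dS if (not math.isnan(dS) and dS > 0 and not math.isnan(dN)) else math.nan
    return DnDsResult(dN, dS, ratio, N_sites, S_sites, N_diffs, S_diffs)
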