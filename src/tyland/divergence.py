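"""Kimura 2-parameter divergence: global and sliding-window estimates.

The K2P model corrects observed differences between two aligned nucleotide
sequences separately for transitions (purine<->purine, pyrimidine<->pyrimidine;
proportion P) and transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

in expected substitutions per site.  Sites where either row carries a gap or an
ambiguity code are excluded pairwise ("pairwise deletion"), which keeps windowed
estimates defined over partially gapped alignment regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")

__all__ = [
    "K2PResult",
    "Window",
    "WindowTrack",
    "k2p_distance",
    "k2p_from_counts",
    "sliding_window_divergence",
    "distance_matrix",
]


@dataclass(frozen=True)
class K2PResult:
    """A single pairwise K2P estimate.

    ``distance`` is NaN when the estimate is undefined; ``reason`` then says
    why (no usable sites, or log-argument saturation).
    """

    distance: float
    P: float
    Q: float
    usable_sites: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.distance)


@dataclass(frozen=True)
class Window:
    start: int
    end: int
    result: K2PResult


@dataclass
class WindowTrack:
    """Per-window K2P distances along an alignment (default 50 bp / 10 bp step)."""

    windows: list[Window]
    window_size: int = 50
    step: int = 10

    def distances(self) -> np.ndarray:
        return np.array([w.result.distance for w in self.windows])

    def starts(self) -> np.ndarray:
        return np.array([w.start for w in self.windows])


def _encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to codes A=0 C=1 G=2 T=3, anything else -1."""
    table = np.full(256, -1, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        table[ord(base)] = i
        table[ord(base.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def site_classes(a: str, b: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean per-site masks (usable, transition, transversion) for two rows.

    Transitions are A<->G and C<->T; every other difference between two
    unambiguous bases is a transversion.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned rows differ in length: {len(a)} vs {len(b)}")
    ca, cb = _encode(a), _encode(b)
    usable = (ca >= 0) & (cb >= 0)
    diff = usable & (ca != cb)
    # purines are codes 0 (A) and 2 (G): code % 2 == 0 distinguishes the groups
    transition = diff & ((ca % 2) == (cb % 2))
    transversion = diff & ~transition
    return usable, transition, transversion


def k2p_from_counts(n_transitions: int, n_transversions: int, usable_sites: int) -> K2PResult:
    """K2P estimate from raw site counts (the formula's natural inputs)."""
    if usable_sites == 0:
        return K2PResult(math.nan, math.nan, math.nan, 0, reason="no usable sites")
    P = n_transitions / usable_sites
    Q = n_transversions / usable_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(math.nan, P, Q, usable_sites, reason="saturated (log argument <= 0)")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(d, P, Q, usable_sites)


def k2p_distance(a: str, b: str) -> K2PResult:
    """Pairwise K2P distance between two equal-length aligned rows."""
    usable, ts, tv = site_classes(a, b)
    return k2p_from_counts(int(ts.sum()), int(tv.sum()), int(usable.sum()))


def window_starts(length: int, window: int, step: int) -> list[int]:
    if step <= 0:
        raise ValueError("step must be positive")
    if window > length:
        return [0]
    return list(range(0, length - window + 1, step))


def sliding_window_divergence(
    a: str,
    b: str,
    window: int = 50,
    step: int = 10,
    min_usable: int = 25,
) -> WindowTrack:
    """K2P distance in overlapping windows along an aligned pair.

    Windows with fewer than ``min_usable`` comparable sites, or where the K2P
    logs are undefined, carry a NaN distance.  A window larger than the
    alignment yields a single truncated window.
    """
    usable, ts, tv = site_classes(a, b)
    # prefix sums give O(1) per-window counts
    cu = np.concatenate([[0], np.cumsum(usable)])
    cs = np.concatenate([[0], np.cumsum(ts)])
    cv = np.concatenate([[0], np.cumsum(tv)])
    out: list[Window] = []
    for start in window_starts(len(a), window, step):
        end = min(start + window, len(a))
        n_u = int(cu[end] - cu[start])
        res = k2p_from_counts(int(cs[end] - cs[start]), int(cv[end] - cv[start]), n_u)
        if res.defined and n_u < min_usable:
            res = K2PResult(math.nan, res.P, res.Q, n_u, reason=f"usable sites < {min_usable}")
        out.append(Window(start, end, res))
    return WindowTrack(out, window_size=window, step=step)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(path, sep="\t")


def distance_matrix(msa: dict[str, str]) -> DistanceMatrix:
    """All-pairs K2P distances for an alignment (id -> aligned row).

    Raises ``ValueError`` naming every pair whose K2P distance is undefined;
    callers may prune offending rows and retry.
    """
    labels = list(msa)
    if len(labels) < 2:
        raise ValueError("need at least two rows")
    n = len(labels)
    d = np.zeros((n, n))
    bad: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p_distance(msa[labels[i]], msa[labels[j]])
            if not res.defined:
                bad.append(f"{labels[i]}~{labels[j]}: {res.reason}")
            else:
                d[i, j] = d[j, i] = res.distance
    if bad:
        raise ValueError("undefined K2P distance for pair(s): " + "; ".join(bad))
    return DistanceMatrix(labels, d)
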