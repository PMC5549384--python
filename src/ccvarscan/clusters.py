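"""Detection of charge clusters in protein sequences.

A charge cluster is a 20–75 residue segment with a high concentration of
same-charge residues (Asp/Glu for negative clusters, Lys/Arg for positive
ones), possibly interrupted by uncharged residues but containing no residue
of the opposite charge.  Significance of a candidate segment is scored as
the binomial tail probability of observing at least the segment's count of
same-sign residues given the protein-wide frequency of that sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from scipy.stats import binom

log = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"

#: residues carrying a negative side-chain charge at physiological pH
NEGATIVE_RESIDUES = frozenset("DE")
#: residues carrying a positive side-chain charge
POSITIVE_RESIDUES = frozenset("KR")

_STANDARD = frozenset("ACDEFGHIKLMNPQRSTVWY")

MIN_CLUSTER_LEN = 20
MAX_CLUSTER_LEN = 75
DEFAULT_ALPHA = 0.01
DEFAULT_P0_FLOOR = 0.05


@dataclass(frozen=True)
class ChargeCluster:
    """A significant, opposite-charge-free segment of one protein.

    Coordinates are 1-based inclusive protein positions.
    """

    protein_id: str
    sign: str
    start_aa: int
    end_aa: int
    length_aa: int
    charged_count: int
    p_value: float

    def __post_init__(self) -> None:
        if self.sign not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown cluster sign {self.sign!r}")
        if self.length_aa != self.end_aa - self.start_aa + 1:
            raise ValueError("length_aa inconsistent with start/end")

    def overlaps(self, other: "ChargeCluster") -> bool:
        return self.start_aa <= other.end_aa and other.start_aa <= self.end_aa


def residue_charge(aa: str) -> int:
    """Return the side-chain charge of a one-letter residue code.

    D, E → −1; K, R → +1; every other standard residue → 0.  Non-standard
    or ambiguity codes (B, Z, X, U, *) also score 0 so they never block a
    window; a warning is logged for audit.
    """
    if aa in NEGATIVE_RESIDUES:
        return -1
    if aa in POSITIVE_RESIDUES:
        return +1
    if aa not in _STANDARD:
        log.warning("non-standard residue code %r treated as uncharged", aa)
    return 0


def _sign_sets(sign: str) -> Tuple[frozenset, frozenset]:
    """(same-sign residues, opposite-sign residues) for a cluster sign."""
    if sign == NEGATIVE:
        return NEGATIVE_RESIDUES, POSITIVE_RESIDUES
    if sign == POSITIVE:
        return POSITIVE_RESIDUES, NEGATIVE_RESIDUES
    raise ValueError(f"unknown sign {sign!r}")


def background_frequency(seq: str, sign: str, floor: float = DEFAULT_P0_FLOOR) -> float:
    """Protein-wide frequency of the sign's residues, floored.

    The floor prevents trivially significant windows in charge-poor
    proteins.
    """
    same, _ = _sign_sets(sign)
    freq = sum(1 for aa in seq if aa in same) / len(seq)
    return max(freq, floor)


def candidate_windows(
    seq: str,
    sign: str,
    min_len: int = MIN_CLUSTER_LEN,
    max_len: int = MAX_CLUSTER_LEN,
) -> List[Tuple[int, int]]:
    """All (start, end) 1-based inclusive windows that could be a cluster.

    A window qualifies when its length is in [min_len, max_len], it contains
    no opposite-sign residue, and both its first and last residues carry the
    cluster's sign (so reported boundaries are tight).  The list is
    exhaustive and ordered by (start, end).
    """
    if not seq:
        raise ValueError("empty sequence")
    same, opposite = _sign_sets(sign)
    n = len(seq)
    out: List[Tuple[int, int]] = []
    # next_block[i] = 0-based index of the first opposite-sign residue at or
    # after i; windows starting at i cannot reach past it.
    next_block = [n] * (n + 1)
    for i in range(n - 1, -1, -1):
        next_block[i] = i if seq[i] in opposite else next_block[i + 1]
    for i in range(n):
        if seq[i] not in same:
            continue
        limit = min(next_block[i] - 1, i + max_len - 1, n - 1)
        for j in range(i + min_len - 1, limit + 1):
            if seq[j] in same:
                out.append((i + 1, j + 1))
    return out


def window_pvalue(k: int, w: int, p0: float) -> float:
    """P(X ≥ k) for X ~ Binomial(w, p0): enrichment of same-sign residues.

    Monotonically non-increasing in k at fixed (w, p0).
    """
    if not 0 < p0 < 1:
        raise ValueError(f"background frequency p0 must be in (0,1), got {p0}")
    if not 0 <= k <= w:
        raise ValueError(f"count k={k} outside [0, {w}]")
    return float(binom.sf(k - 1, w, p0))


def find_charge_clusters(
    seq: str,
    sign: str,
    alpha: float = DEFAULT_ALPHA,
    p0_floor: float = DEFAULT_P0_FLOOR,
    protein_id: str = "",
    min_len: int = MIN_CLUSTER_LEN,
    max_len: int = MAX_CLUSTER_LEN,
) -> List[ChargeCluster]:
    """Detect significant, disjoint charge clusters of one sign.

    Every opposite-charge-free candidate window (see
    :func:`candidate_windows`) is scored with :func:`window_pvalue` against
    the protein-wide same-sign frequency (floored at ``p0_floor``).  Windows
    with p ≤ alpha enter a greedy disjoint selection: repeatedly accept the
    window with the smallest p-value (ties broken by longest, then
    leftmost) and discard everything overlapping it.  Returned clusters are
    sorted by start position.
    """
    if not seq:
        return []
    same, _ = _sign_sets(sign)
    p0 = background_frequency(seq, sign, floor=p0_floor)
    if p0 >= 1.0:  # degenerate: all residues same-sign; nothing is enriched
        p0 = 1.0 - 1e-12

    # prefix counts of same-sign residues for O(1) window tallies
    prefix = [0]
    for aa in seq:
        prefix.append(prefix[-1] + (1 if aa in same else 0))

    scored = []
    for start, end in candidate_windows(seq, sign, min_len=min_len, max_len=max_len):
        w = end - start + 1
        k = prefix[end] - prefix[start - 1]
        p = window_pvalue(k, w, p0)
        if p <= alpha:
            scored.append((p, -(w), start, end, k))

    scored.sort()  # smallest p, then longest (via negative length), then leftmost
    chosen: List[ChargeCluster] = []
    for p, neg_w, start, end, k in scored:
        cand = ChargeCluster(
            protein_id=protein_id,
            sign=sign,
            start_aa=start,
            end_aa=end,
            length_aa=-neg_w,
            charged_count=k,
            p_value=p,
        )
        if not any(cand.overlaps(c) for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c.start_aa)
    return chosen


def swap_charges(seq: str) -> str:
    """Exchange D↔K and E↔R, turning negative clusters into positive ones."""
    return seq.translate(str.maketrans("DEKRdekr", "KRDEkrde"))


def detect_in_records(
    records: Iterable[Tuple[str, str]],
    signs: Sequence[str] = (NEGATIVE, POSITIVE),
    alpha: float = DEFAULT_ALPHA,
    p0_floor: float = DEFAULT_P0_FLOOR,
) -> List[ChargeCluster]:
    """Run detection on (protein_id, sequence) pairs for the given signs."""
    out: List[ChargeCluster] = []
    for pid, seq in records:
        for sign in signs:
            out.extend(
                find_charge_clusters(
                    seq, sign, alpha=alpha, p0_floor=p0_floor, protein_id=pid
                )
            )
    return out
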