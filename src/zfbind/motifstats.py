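"""Match statistics between binding sites and predicted motifs.

A predicted motif is a per-position base-frequency table; positions where
one base exceeds 60% frequency are "defined" and matches are counted only
there, against a 0.25 per-position chance probability. Significance is an
exact binomial upper tail P(X >= k), summed from the probability mass
function rather than approximated.

Site-to-site similarity uses ungapped sliding alignment (the minimal sites
are 30-33 bp and were aligned without gaps) with a pairwise binomial test
and a three-way chi-square test on column categories.

Note on n: the sample size behind a pairwise test (defined positions,
overlap columns, or something else) materially changes the p-value, and the
analysis this package reproduces does not state its choice; ``n`` is
therefore explicit in the API and both counts and p-values are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import AlignmentError, IncompleteAlignmentError

BASES = ("A", "C", "G", "T")
UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}

#: Frequency above which a motif position is "defined" by one base.
DEFINED_FREQ = 0.60

#: Expected column-category probabilities for three independent uniform
#: sequences: all three equal (1/16), exactly one pair equal (9/16),
#: no pair equal (6/16).
THREEWAY_EXPECTED = {"triple": 1 / 16, "pair": 9 / 16, "none": 6 / 16}


@dataclass(frozen=True)
class SiteSequence:
    """A named DNA sequence (uppercase A/C/G/T only)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


class FrequencyMotif:
    """Per-position base frequencies with >60%-defined positions.

    Parameters
    ----------
    freq
        Sequence of base -> frequency maps, one per motif position. Each
        must sum to 1 within 1e-9.
    """

    def __init__(self, freq: Sequence[Mapping[str, float]]):
        self.freq = [dict(f) for f in freq]
        for i, f in enumerate(self.freq):
            total = sum(f.get(b, 0.0) for b in BASES)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"position {i + 1}: frequencies sum to {total}")
        self.defined_positions: Dict[int, str] = {}
        for i, f in enumerate(self.freq):
            for b in BASES:
                if f.get(b, 0.0) > DEFINED_FREQ:
                    self.defined_positions[i] = b
                    break  # at most one base can exceed 0.60

    def __len__(self) -> int:
        return len(self.freq)

    @classmethod
    def from_consensus(cls, consensus: str, defined_freq: float = 0.7) -> "FrequencyMotif":
        """Motif in which every position is defined by the consensus base."""
        rest = (1.0 - defined_freq) / 3.0
        return cls(
            [
                {b: (defined_freq if b == c else rest) for b in BASES}
                for c in consensus
            ]
        )


def strong_match_count(site: SiteSequence, motif: FrequencyMotif, offset: int = 0) -> int:
    """Count defined motif positions where the site carries the defining base.

    ``offset`` places motif position 1 at site index ``offset`` (0-based).
    Every defined position must fall inside the site.
    """
    n = 0
    for pos, base in motif.defined_positions.items():
        idx = offset + pos
        if idx < 0 or idx >= len(site):
            raise IncompleteAlignmentError(
                f"defined motif position {pos + 1} falls outside site {site.id}"
            )
        if site.sequence[idx] == base:
            n += 1
    return n


def expected_chance_matches(
    motif: FrequencyMotif, background: Mapping[str, float] | None = None
) -> float:
    """Expected strong matches for a random site under the background.

    Uniform background gives 0.25 per defined position (15 defined
    positions -> 3.75 expected matches).
    """
    bg = dict(background) if background is not None else dict(UNIFORM_BACKGROUND)
    total = sum(bg.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"background sums to {total}")
    return sum(bg[base] for base in motif.defined_positions.values())


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p), by pmf summation."""
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, {n}]")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p={p} outside (0, 1)")
    ks = np.arange(k, n + 1)
    return float(np.sum(stats.binom.pmf(ks, n, p)))


def best_ungapped_alignment(
    a: SiteSequence, b: SiteSequence, min_overlap: int = 10
) -> Tuple[int, int, int]:
    """Best ungapped offset of ``b`` relative to ``a``.

    Returns ``(offset, match_count, overlap_length)`` where ``offset`` is
    the index of ``b``'s first base in ``a`` coordinates (may be negative).
    Maximizes identities; ties break toward larger overlap, then smaller
    absolute offset.
    """
    if min_overlap > min(len(a), len(b)):
        raise ValueError("min_overlap exceeds the shorter sequence")
    best: Tuple[int, int, int] | None = None
    best_key: Tuple[int, int, int] | None = None
    for offset in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        lo = max(0, offset)
        hi = min(len(a), offset + len(b))
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        matches = sum(
            1 for i in range(lo, hi) if a.sequence[i] == b.sequence[i - offset]
        )
        key = (matches, overlap, -abs(offset))
        if best_key is None or key > best_key:
            best_key = key
            best = (offset, matches, overlap)
    assert best is not None
    return best


def pairwise_similarity_test(
    a: SiteSequence, b: SiteSequence, min_overlap: int = 10, p: float = 0.25
) -> Dict[str, float]:
    """Binomial similarity test on the best ungapped alignment of two sites.

    n is the overlap length of the best alignment; see the module note on
    why n is reported explicitly.
    """
    offset, matches, overlap = best_ungapped_alignment(a, b, min_overlap)
    return {
        "offset": offset,
        "matches": matches,
        "n": overlap,
        "expected": p * overlap,
        "p_value": binomial_upper_tail(matches, overlap, p),
    }


def threeway_match_test(
    a: SiteSequence,
    b: SiteSequence,
    c: SiteSequence,
    offset_b: int = 0,
    offset_c: int = 0,
) -> Dict[str, object]:
    """Chi-square test of three-way column agreement against independence.

    Columns where all three sites are aligned are scored ``triple`` (all
    equal), ``pair`` (exactly one pair equal) or ``none``; observed counts
    are tested against the uniform-independence proportions 1/16, 9/16,
    6/16 by a 2-df goodness-of-fit chi-square (upper-tail p).

    ``offset_b``/``offset_c`` give b's and c's start in a's coordinates.
    """
    lo = max(0, offset_b, offset_c)
    hi = min(len(a), offset_b + len(b), offset_c + len(c))
    if hi <= lo:
        raise AlignmentError("offsets leave no three-way aligned columns")
    counts = {"triple": 0, "pair": 0, "none": 0}
    for i in range(lo, hi):
        x, y, z = a.sequence[i], b.sequence[i - offset_b], c.sequence[i - offset_c]
        eq = (x == y) + (x == z) + (y == z)
        if eq == 3:
            counts["triple"] += 1
        elif eq == 1:
            counts["pair"] += 1
        else:  # eq == 0; eq == 2 is impossible for transitive equality
            counts["none"] += 1
    n = hi - lo
    observed = [counts[k] for k in ("triple", "pair", "none")]
    expected = [THREEWAY_EXPECTED[k] * n for k in ("triple", "pair", "none")]
    chi2, p = stats.chisquare(observed, expected)
    return {
        "counts": counts,
        "n_columns": n,
        "expected": dict(zip(("triple", "pair", "none"), expected)),
        "chi2": float(chi2),
        "p_value": float(p),
    }
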