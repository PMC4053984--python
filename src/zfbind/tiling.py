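"""Simulated binding-site localization by tiling and truncation.

Reproduces, against a pluggable binding oracle standing in for the gel
assay, the experimental strategy used to map a site: test overlapping
200-400 bp amplicons across the region, iteratively re-tile positive
fragments until the positive interval is under 100 bp, then determine the
minimal binding site by trimming unlabeled competitor oligos base by base
while they still compete away at least half of the labeled probe's signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Literal, Optional, Tuple

from .errors import NonBindingFragmentError
from .motifstats import SiteSequence

#: Oracle for labeled fragments: oligo sequence -> shifted fraction.
BindingOracle = Callable[[str], float]

#: Oracle for competitors: sequence (or None for the no-competitor
#: control) -> labeled-probe shifted fraction.
CompetitionOracle = Callable[[Optional[str]], float]

DEFAULT_CALL_THRESHOLD = 0.1   # shifted fraction calling a fragment positive
DEFAULT_EFFICACY_THRESHOLD = 0.5  # fractional signal reduction keeping a trim
FINAL_TILE_LENGTH = 90  # below the 100-bp refinement target

TrimMode = Literal["alternate", "single_end"]


@dataclass(frozen=True)
class Amplicon:
    """A tile on a region, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty amplicon")

    @property
    def length(self) -> int:
        return self.end - self.start


def design_tiles(
    region_length: int, tile_length: int = 300, overlap: int = 50
) -> List[Amplicon]:
    """Tiles covering the region, adjacent ones sharing ``overlap`` bp.

    The final tile is right-anchored at the region end, so it may overlap
    its neighbour by more than ``overlap``. A region shorter than one tile
    yields a single truncated tile (with a warning).
    """
    if tile_length <= overlap:
        raise ValueError("tile_length must exceed overlap")
    if region_length <= tile_length:
        if region_length < tile_length:
            warnings.warn(
                f"region ({region_length} bp) shorter than one tile; "
                "returning a single truncated tile"
            )
        return [Amplicon(0, region_length)]
    step = tile_length - overlap
    starts = list(range(0, region_length - tile_length, step))
    starts.append(region_length - tile_length)
    return [Amplicon(s, s + tile_length) for s in starts]


def _positive_runs(tiles: List[Amplicon], positive: List[bool]) -> List[List[Amplicon]]:
    """Group positive tiles into runs of mutually overlapping/adjacent tiles."""
    runs: List[List[Amplicon]] = []
    for tile, pos in zip(tiles, positive):
        if not pos:
            continue
        if runs and tile.start <= runs[-1][-1].end:
            runs[-1].append(tile)
        else:
            runs.append([tile])
    return runs


def localize(
    oracle: BindingOracle,
    region: SiteSequence,
    call_threshold: float = DEFAULT_CALL_THRESHOLD,
    tile_length: int = 300,
    overlap: int = 50,
) -> List[Tuple[int, int]]:
    """Narrow binding activity to sub-100-bp intervals of the region.

    Round 1 tiles the whole region at ``tile_length``; each later round
    halves the tile length (floored at 90 bp) and re-tiles the union of
    each positive run. In the final round the reported interval is the
    intersection of a run's positive tiles — every tile in the run covers
    the site, so their intersection does too, and it is under 100 bp.

    Returns a (possibly empty) list of ``(start, end)`` intervals in
    region coordinates; an empty list is the no-binding outcome.
    """
    intervals: List[Tuple[int, int]] = [(0, len(region))]
    current_length = tile_length
    while True:
        final_round = current_length < 100
        next_intervals: List[Tuple[int, int]] = []
        results: List[Tuple[int, int]] = []
        for lo, hi in intervals:
            span = hi - lo
            tl = min(current_length, span)
            ov = min(overlap, tl - 1)
            tiles = design_tiles(span, tl, ov)
            calls = [
                oracle(region.sequence[lo + t.start : lo + t.end]) >= call_threshold
                for t in tiles
            ]
            for run in _positive_runs(tiles, calls):
                if final_round:
                    start = lo + max(t.start for t in run)
                    end = lo + min(t.end for t in run)
                    if end > start:
                        results.append((start, end))
                else:
                    next_intervals.append(
                        (lo + run[0].start, lo + run[-1].end)
                    )
        if final_round:
            return sorted(set(results))
        if not next_intervals:
            return []  # no positive tile anywhere: no binding
        intervals = next_intervals
        current_length = max(FINAL_TILE_LENGTH, current_length // 2)


def _competes(
    oracle: CompetitionOracle,
    competitor: str,
    baseline: float,
    efficacy_threshold: float,
) -> bool:
    """Does the competitor cut the labeled signal by the required fraction?"""
    if baseline <= 0:
        return False
    return (1.0 - oracle(competitor) / baseline) >= efficacy_threshold


def minimal_site(
    oracle: CompetitionOracle,
    fragment: SiteSequence,
    step: int = 1,
    mode: TrimMode = "alternate",
    efficacy_threshold: float = DEFAULT_EFFICACY_THRESHOLD,
) -> SiteSequence:
    """Shortest oligo still competing for the protein.

    Starting from a binding fragment, ``step`` bases are trimmed at a time
    — alternately from each end by default, or one end to exhaustion first
    (``single_end``) — and a trim is kept only while the shortened
    unlabeled competitor still reduces the labeled probe's shifted
    fraction by at least ``efficacy_threshold``. A trim that crosses the
    threshold is rolled back and that end is frozen.

    Raises
    ------
    NonBindingFragmentError
        If the starting fragment itself fails the competition test.
    """
    baseline = oracle(None)
    seq = fragment.sequence
    if not _competes(oracle, seq, baseline, efficacy_threshold):
        raise NonBindingFragmentError(
            f"fragment {fragment.id} does not compete at the starting length"
        )
    lo, hi = 0, len(seq)
    blocked = {"left": False, "right": False}

    def try_trim(side: str) -> None:
        nonlocal lo, hi
        if blocked[side] or hi - lo <= step:
            blocked[side] = True
            return
        nlo, nhi = (lo + step, hi) if side == "left" else (lo, hi - step)
        if _competes(oracle, seq[nlo:nhi], baseline, efficacy_threshold):
            lo, hi = nlo, nhi
        else:
            blocked[side] = True

    if mode == "alternate":
        while not (blocked["left"] and blocked["right"]):
            try_trim("left")
            try_trim("right")
    elif mode == "single_end":
        while not blocked["left"]:
            try_trim("left")
        while not blocked["right"]:
            try_trim("right")
    else:
        raise ValueError(f"unknown trim mode: {mode!r}")

    return SiteSequence(f"{fragment.id}_minimal", seq[lo:hi])
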