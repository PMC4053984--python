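"""Mutagenesis-derived position weight matrix with exact p-value scanning.

The matrix is built from the competition-mutagenesis profile of a reference
site: each measured binding change B_mut becomes a relative affinity
``max(1 + B_mut, floor)`` (reference base = 1), per-position probabilities
are ``affinity**beta`` normalized, and weights are log2 odds against the
background. The sharpness exponent ``beta`` is calibrated by maximizing the
score margin of the known site over the best other window of its own
hotspot region.

P-values are exact under an i.i.d. background: the full window-score
distribution is computed by dynamic-programming convolution over positions
with scores discretized into 0.01-bit bins, and the scan keeps windows on
either strand whose upper-tail probability is below the threshold
(default 1e-5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import SiteNotFoundError
from .motifstats import BASES, SiteSequence
from .mutscan import SpecificityProfile

BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G

DEFAULT_FLOOR = 0.01
DEFAULT_BIN_WIDTH = 0.01
DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_BETA_GRID = tuple(0.25 * i for i in range(1, 17))  # 0.25 .. 4.0


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T string to integer codes 0..3."""
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"invalid base {e.args[0]!r}") from None


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class Pwm:
    """Log-odds matrix (bits) over A/C/G/T with its background model."""

    weights: np.ndarray  # shape (L, 4), bits
    background: np.ndarray  # shape (4,), sums to 1
    beta: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("weights must have shape (L, 4)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Per-position base probabilities implied by weights and background."""
        return 2.0 ** self.weights * self.background

    def reverse_complement(self) -> "Pwm":
        rc = self.weights[::-1, COMPLEMENT_INDEX]
        return Pwm(rc.copy(), self.background[COMPLEMENT_INDEX].copy(), self.beta)

    def score(self, window: str) -> float:
        """Score one window of length L, in bits."""
        codes = encode(window)
        if codes.size != len(self):
            raise ValueError("window length must equal matrix length")
        return float(self.weights[np.arange(len(self)), codes].sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))


@dataclass(frozen=True)
class ScanHit:
    """One scoring window: 0-based forward-strand start, strand, score, p."""

    sequence_id: str
    start: int
    strand: str
    score: float
    p_value: float


class ScoreDistribution:
    """Exact window-score distribution under an i.i.d. background.

    Weights are discretized to integer multiples of ``bin_width`` and the
    pmf is built by convolving one position at a time; the survival
    function gives upper-tail p-values aligned to the same binning, so
    p-values match brute-force enumeration of all 4^L windows exactly on
    the binned score.
    """

    def __init__(self, pwm: Pwm, bin_width: float = DEFAULT_BIN_WIDTH):
        self.bin_width = float(bin_width)
        self.binned = np.rint(pwm.weights / self.bin_width).astype(np.int64)
        # DP convolution: start with a point mass at score 0.
        arr = np.array([1.0])
        arr_lo = 0
        for pos in range(self.binned.shape[0]):
            offs = self.binned[pos]
            new_lo = arr_lo + int(offs.min())
            new_hi = arr_lo + arr.size - 1 + int(offs.max())
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                shift = arr_lo + int(offs[b]) - new_lo
                new[shift : shift + arr.size] += pwm.background[b] * arr
            arr, arr_lo = new, new_lo
        self.pmf = arr
        self.min_bin = arr_lo
        # Survival: P(score_bin >= s)
        self.sf = np.cumsum(arr[::-1])[::-1]

    def p_value(self, score: float) -> float:
        """Upper-tail probability of a (continuous) score, via its bin."""
        b = int(round(score / self.bin_width))
        return self.p_value_binned(b)

    def p_value_binned(self, score_bin: int) -> float:
        idx = score_bin - self.min_bin
        if idx < 0:
            return 1.0
        if idx >= self.sf.size:
            return 0.0
        return float(self.sf[idx])

    def window_score_bin(self, codes: np.ndarray) -> int:
        """Binned score of one encoded window (sums binned weights)."""
        return int(self.binned[np.arange(self.binned.shape[0]), codes].sum())


def estimate_background(seq: SiteSequence, pseudocount: float = 1.0) -> np.ndarray:
    """0th-order background base frequencies of a sequence (A,C,G,T)."""
    counts = np.bincount(encode(seq.sequence), minlength=4) + pseudocount
    return counts / counts.sum()


def affinities_from_profile(
    profile: SpecificityProfile,
    reference_site: SiteSequence,
    floor: float = DEFAULT_FLOOR,
) -> np.ndarray:
    """Relative-affinity matrix (L, 4) from a mutational-scan profile.

    Reference base -> 1; substituted base -> ``max(1 + B_mut, floor)``.
    The floor keeps complete-loss substitutions (B_mut = -1) at a small
    positive affinity so log-odds stay finite.
    """
    if profile.site_length != len(reference_site):
        raise ValueError(
            f"profile covers {profile.site_length} positions but site "
            f"{reference_site.id} is {len(reference_site)} bp"
        )
    aff = np.empty((profile.site_length, 4))
    for pos in range(1, profile.site_length + 1):
        ref = reference_site.sequence[pos - 1]
        for b in BASES:
            if b == ref:
                aff[pos - 1, BASE_INDEX[b]] = 1.0
            else:
                aff[pos - 1, BASE_INDEX[b]] = max(
                    1.0 + profile.changes[pos][b], floor
                )
    return aff


def pwm_from_affinities(
    affinities: np.ndarray,
    beta: float = 1.0,
    background: Sequence[float] | None = None,
) -> Pwm:
    """Log-odds matrix from relative affinities sharpened by exponent beta.

    Per position, base probabilities are proportional to ``affinity**beta``;
    beta -> 0 flattens the matrix toward the background, larger beta
    concentrates probability on the best base.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    probs = np.asarray(affinities, float) ** beta
    probs = probs / probs.sum(axis=1, keepdims=True)
    weights = np.log2(probs / bg)
    return Pwm(weights, bg, beta=beta)


def calibrate_beta(
    profile: SpecificityProfile,
    reference_site: SiteSequence,
    hotspot_region: SiteSequence,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    background: Sequence[float] | None = None,
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Pick the sharpness exponent that best singles out the known site.

    For each beta on the grid, the objective is the margin between the
    matrix score of the reference site at its known position in the hotspot
    region and the best score of any non-overlapping window on either
    strand. Ties (within 1e-12) go to the smallest beta.
    """
    start = hotspot_region.sequence.find(reference_site.sequence)
    if start < 0:
        raise SiteNotFoundError(
            f"site {reference_site.id} not found in region {hotspot_region.id}"
        )
    aff = affinities_from_profile(profile, reference_site, floor=floor)
    codes = encode(hotspot_region.sequence)
    L = len(reference_site)
    best_beta, best_margin = None, -np.inf
    for beta in beta_grid:
        pwm = pwm_from_affinities(aff, beta=beta, background=background)
        fwd = _window_scores(codes, pwm.weights)
        rev = _window_scores(codes, pwm.reverse_complement().weights)
        true_score = fwd[start]
        starts = np.arange(fwd.size)
        overlap = (starts > start - L) & (starts < start + L)
        others = np.concatenate([fwd[~overlap], rev[~overlap]])
        margin = true_score - (others.max() if others.size else -np.inf)
        if margin > best_margin + 1e-12:
            best_beta, best_margin = beta, margin
    assert best_beta is not None
    return best_beta


def build_pwm(
    profile: SpecificityProfile,
    reference_site: SiteSequence,
    hotspot_region: SiteSequence | None = None,
    beta: float | None = None,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    background: Sequence[float] | None = None,
    floor: float = DEFAULT_FLOOR,
) -> Pwm:
    """Profile -> calibrated PWM convenience wrapper.

    If ``beta`` is given it is used directly; otherwise a hotspot region is
    required and beta is calibrated on it.
    """
    aff = affinities_from_profile(profile, reference_site, floor=floor)
    if beta is None:
        if hotspot_region is None:
            raise ValueError("either beta or a hotspot region is required")
        beta = calibrate_beta(
            profile, reference_site, hotspot_region,
            beta_grid=beta_grid, background=background, floor=floor,
        )
    return pwm_from_affinities(aff, beta=beta, background=background)


def score_distribution(pwm: Pwm, bin_width: float = DEFAULT_BIN_WIDTH) -> ScoreDistribution:
    """Exact background score distribution of the matrix (see class docs)."""
    return ScoreDistribution(pwm, bin_width=bin_width)


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores of all forward windows of an encoded sequence (vectorized)."""
    L = weights.shape[0]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return weights[np.arange(L), windows].sum(axis=1)


def scan(
    seq: SiteSequence,
    pwm: Pwm,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    bin_width: float = DEFAULT_BIN_WIDTH,
    distributions: Tuple[ScoreDistribution, ScoreDistribution] | None = None,
) -> List[ScanHit]:
    """All windows on both strands with exact tail p below the threshold.

    Minus-strand hits report the forward-strand window start. Precomputed
    ``(forward, reverse)`` score distributions can be passed to amortize the
    DP across many sequences.
    """
    L = len(pwm)
    if len(seq) < L:
        warnings.warn(
            f"sequence {seq.id} ({len(seq)} bp) shorter than matrix ({L} bp)"
        )
        return []
    rc = pwm.reverse_complement()
    if distributions is None:
        distributions = (
            ScoreDistribution(pwm, bin_width),
            ScoreDistribution(rc, bin_width),
        )
    dist_fwd, dist_rev = distributions
    codes = encode(seq.sequence)
    hits: List[ScanHit] = []
    for strand, mat, dist in (("+", pwm, dist_fwd), ("-", rc, dist_rev)):
        scores = _window_scores(codes, mat.weights)
        binned = np.lib.stride_tricks.sliding_window_view(codes, L)
        score_bins = dist.binned[np.arange(L), binned].sum(axis=1)
        for start in range(scores.size):
            p = dist.p_value_binned(int(score_bins[start]))
            if p < p_threshold:
                hits.append(
                    ScanHit(seq.id, start, strand, float(scores[start]), p)
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def enrichment(
    sequences: Mapping[str, str],
    hotspots: pd.DataFrame,
    pwm: Pwm,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """Hit counts in hotspots and size-matched flanking controls.

    ``hotspots`` is a BED-like frame with columns ``chrom, start, end``
    (0-based half-open) and optionally ``name``; each hotspot gets two
    control regions of its own length immediately before and after it,
    truncated (with a warning) at sequence bounds.
    """
    dists = (
        ScoreDistribution(pwm),
        ScoreDistribution(pwm.reverse_complement()),
    )
    rows = []
    for i, r in hotspots.reset_index(drop=True).iterrows():
        chrom, start, end = str(r["chrom"]), int(r["start"]), int(r["end"])
        name = str(r["name"]) if "name" in hotspots.columns else f"hotspot_{i}"
        seq = sequences[chrom]
        length = end - start
        left = (max(0, start - length), start)
        right = (end, min(len(seq), end + length))
        if left[1] - left[0] < length or right[1] - right[0] < length:
            warnings.warn(f"{name}: control region truncated at sequence bounds")

        def count(lo: int, hi: int, label: str) -> int:
            if hi - lo < len(pwm):
                return 0
            sub = SiteSequence(f"{name}:{label}", seq[lo:hi])
            return len(scan(sub, pwm, p_threshold, distributions=dists))

        rows.append(
            {
                "name": name,
                "chrom": chrom,
                "start": start,
                "end": end,
                "hotspot_hits": count(start, end, "hotspot"),
                "left_control_hits": count(*left, "left"),
                "right_control_hits": count(*right, "right"),
            }
        )
    out = pd.DataFrame(rows)
    total_control = out["left_control_hits"].sum() + out["right_control_hits"].sum()
    out.attrs["hotspot_total"] = int(out["hotspot_hits"].sum())
    out.attrs["control_total"] = int(total_control)
    # Controls cover twice the hotspot length, so halve them for the ratio.
    out.attrs["enrichment_ratio"] = (
        out.attrs["hotspot_total"] / (total_control / 2.0)
        if total_control
        else float("inf") if out.attrs["hotspot_total"] else float("nan")
    )
    return out


def hits_to_bed(hits: Iterable[ScanHit], pwm_length: int) -> pd.DataFrame:
    """BED6 + score-bits + p-value frame from scan hits."""
    rows = [
        {
            "chrom": h.sequence_id,
            "start": h.start,
            "end": h.start + pwm_length,
            "name": f"{h.sequence_id}_{h.start}{h.strand}",
            "score": 0,
            "strand": h.strand,
            "score_bits": h.score,
            "p_value": h.p_value,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "score", "strand",
            "score_bits", "p_value",
        ],
    )
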