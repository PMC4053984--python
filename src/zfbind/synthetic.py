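"""Synthetic worlds for exercising the full binding-site pipeline.

No raw measurements ship with this package, so every pipeline input can be
generated here: GC-matched hotspot sequences with one planted binding site
each, noisy gel-lane densities from an equilibrium occupancy model,
competition scans over the 36-mer competitor frame, and ChIP-qPCR Ct pairs.

The binding model is a deliberately simple synthetic convention, not a
claim about zinc-finger biophysics:

* per-position, log-additive energetics: an oligo's relative affinity is
  the product over planted-site positions of a per-base relative affinity
  (reference base = 1); site positions not covered by the oligo each
  contribute a fixed contact penalty;
* hyperbolic occupancy ``f = c*a / (1 + c*a)`` with protein activity ``c``
  (default 1, so the reference labeled oligo shifts 50% of probe);
* competitor pre-incubation sequesters free protein:
  ``c' = c / (1 + ratio * a_comp * c)`` with a 20-fold molar excess;
* multiplicative lognormal noise on band densities, additive Gaussian
  noise on Ct values.

Under these defaults the competition index of a mutant with relative
affinity ``a`` is ``B = 2(a - 1) / (2 + 20 a)``: 0 for the reference, -1
for complete loss, matching the analysis-side conventions exactly in the
zero-noise limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .motifstats import BASES, SiteSequence
from .mutscan import CompetitionMeasurement, SITE_END, SITE_START
from .pwm import BASE_INDEX, encode
from .quantitation import BandPair, QpcrMeasurement, shifted_fraction

#: Target competition indices per specificity class, assigned to the three
#: substituted bases at a position. Sample SDs over {0} + template are
#: 0.065 (low), 0.256 (moderate) and 0.5 (high) — mid-band for each class.
CLASS_B_TEMPLATES: Dict[str, Tuple[float, float, float]] = {
    "low": (-0.05, -0.10, -0.15),
    "moderate": (-0.30, -0.45, -0.60),
    "high": (-1.0, -1.0, -1.0),
}


@dataclass(frozen=True)
class WorldConfig:
    """Stated conditions of a synthetic world."""

    seed: int = 0
    n_hotspots: int = 4
    hotspot_length: int = 2000
    gc_content: float = 0.42
    site_length: int = 31
    protein_activity: float = 1.0  # c: concentration x affinity scale
    noise_sigma: float = 0.02     # lognormal sigma on band densities
    competitor_ratio: float = 20.0  # molar excess of unlabeled competitor
    total_density: float = 1000.0   # arbitrary densitometry units per lane
    miss_penalty: float = 0.05      # per uncovered site position

    def __post_init__(self) -> None:
        if self.hotspot_length > 10_000:
            raise ValueError("hotspot_length must be <= 10 kb")
        if not 30 <= self.site_length <= 36:
            raise ValueError("planted sites are 30-36 bp")
        if self.site_length + 5 > self.hotspot_length:
            raise ValueError("site (plus competitor flanks) longer than hotspot")


def default_class_layout(site_length: int) -> List[str]:
    """Per-position specificity classes for a planted site.

    Mirrors the observed organization: a central 8-position high-specificity
    block (the middle fingers), 5 moderate positions on each side, and
    low-specificity ends — the weakest specificity toward the 3' end.
    """
    layout = ["low"] * site_length
    center = site_length // 2
    high = range(center - 4, center + 4)
    for i in high:
        layout[i] = "high"
    for i in range(high.start - 5, high.start):
        if i >= 0:
            layout[i] = "moderate"
    for i in range(high.stop, high.stop + 5):
        if i < site_length:
            layout[i] = "moderate"
    return layout


def expected_fraction(affinity: float, config: WorldConfig) -> float:
    """Occupancy of a labeled oligo with relative affinity ``a``."""
    x = config.protein_activity * affinity
    return x / (1.0 + x)


def competed_fraction(
    a_competitor: float, config: WorldConfig, a_labeled: float = 1.0
) -> float:
    """Labeled-oligo occupancy after competitor pre-sequestration."""
    c = config.protein_activity / (
        1.0 + config.competitor_ratio * a_competitor * config.protein_activity
    )
    x = c * a_labeled
    return x / (1.0 + x)


def competition_index(affinity: float, config: WorldConfig) -> float:
    """Noise-free B_mut implied by a competitor's relative affinity."""
    s_un = competed_fraction(1.0, config)
    s_scr = competed_fraction(0.0, config)
    s_mut = competed_fraction(affinity, config)
    return (s_un - s_mut) / (s_scr - s_un)


def affinity_from_index(b: float, config: WorldConfig) -> float:
    """Invert ``competition_index``: the affinity producing target B."""
    c, r = config.protein_activity, config.competitor_ratio
    s_un = competed_fraction(1.0, config)
    s_scr = competed_fraction(0.0, config)
    s_target = s_un - b * (s_scr - s_un)
    if not 0.0 < s_target < 1.0:
        raise ValueError(f"target index {b} outside the dynamic range")
    a = (c / s_target - 1.0 - c) / (r * c)
    return max(a, 0.0)


@dataclass
class AffinityModel:
    """Planted-site energetics of one hotspot.

    ``matrix[i, base]`` is the relative affinity of ``base`` at site
    position i (0-based); the reference base has affinity 1. Oligos are
    aligned to the site by sliding: site positions outside the oligo each
    contribute ``miss_penalty``.
    """

    site_sequence: str
    matrix: np.ndarray  # (L, 4), reference base = 1
    miss_penalty: float = 0.05

    def __post_init__(self) -> None:
        # Log-affinity matrix with a 5th "uncovered" column for overhangs.
        with np.errstate(divide="ignore"):
            log_m = np.log(np.asarray(self.matrix, dtype=float))
        miss = np.full((len(self.site_sequence), 1), math.log(self.miss_penalty))
        self._log_matrix = np.hstack([log_m, miss])

    def __len__(self) -> int:
        return len(self.site_sequence)

    def window_affinity(self, oligo: str, offset: int) -> float:
        """Affinity with site position 0 at oligo index ``offset``."""
        log_a = 0.0
        for i in range(len(self)):
            j = offset + i
            if 0 <= j < len(oligo):
                a = self.matrix[i, BASE_INDEX[oligo[j]]]
            else:
                a = self.miss_penalty
            if a <= 0.0:
                return 0.0
            log_a += math.log(a)
        return math.exp(log_a)

    def best_affinity(self, oligo: str) -> float:
        """Best sliding-alignment affinity of an oligo (forward strand)."""
        L = len(self)
        codes = encode(oligo)
        padded = np.full(codes.size + 2 * (L - 1), 4, dtype=np.int64)
        padded[L - 1 : L - 1 + codes.size] = codes
        windows = np.lib.stride_tricks.sliding_window_view(padded, L)
        scores = self._log_matrix[np.arange(L), windows].sum(axis=1)
        return float(np.exp(scores.max()))


@dataclass
class Hotspot:
    """One synthetic hotspot with its planted-site ground truth."""

    name: str
    sequence: str
    site_start: int  # 0-based
    model: AffinityModel
    classes: List[str]

    @property
    def site_end(self) -> int:
        return self.site_start + len(self.model)

    @property
    def site(self) -> SiteSequence:
        return SiteSequence(
            f"{self.name}_site",
            self.sequence[self.site_start : self.site_end],
        )

    def competitor_frame(self) -> SiteSequence:
        """The 36-mer competitor: site plus 2 bp 5' and 3 bp 3' flanks."""
        return SiteSequence(
            f"{self.name}_competitor",
            self.sequence[self.site_start - 2 : self.site_end + 3],
        )


@dataclass
class World:
    """A reproducible set of hotspots plus generator state."""

    config: WorldConfig
    hotspots: List[Hotspot]
    rng: np.random.Generator = field(repr=False, default=None)

    def bed(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": h.name,
                    "start": 0,
                    "end": len(h.sequence),
                    "name": h.name,
                }
                for h in self.hotspots
            ]
        )

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "hotspot": h.name,
                    "site_start": h.site_start,
                    "site_end": h.site_end,
                    "strand": "+",
                    "site_sequence": h.model.site_sequence,
                }
                for h in self.hotspots
            ]
        )


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=probs))


def _planted_matrix(
    site_sequence: str, classes: Sequence[str], config: WorldConfig
) -> np.ndarray:
    L = len(site_sequence)
    matrix = np.ones((L, 4))
    for i in range(L):
        ref = site_sequence[i]
        alts = [b for b in BASES if b != ref]
        for alt, b_target in zip(alts, CLASS_B_TEMPLATES[classes[i]]):
            matrix[i, BASE_INDEX[alt]] = affinity_from_index(b_target, config)
    return matrix


def make_world(config: WorldConfig) -> World:
    """Generate hotspot sequences, planted sites and their ground truth.

    Identical configs (including the seed) give byte-identical worlds. Each
    hotspot carries one planted site, centered well away from the edges so
    size-matched flanking controls stay site-free by construction.
    """
    rng = np.random.default_rng(config.seed)
    hotspots: List[Hotspot] = []
    L = config.site_length
    for i in range(config.n_hotspots):
        seq = _random_sequence(rng, config.hotspot_length, config.gc_content)
        lo = max(2, config.hotspot_length // 4)
        hi = config.hotspot_length - L - max(3, config.hotspot_length // 4)
        site_start = int(rng.integers(lo, max(lo + 1, hi)))
        site_seq = seq[site_start : site_start + L]
        classes = default_class_layout(L)
        model = AffinityModel(
            site_seq, _planted_matrix(site_seq, classes, config),
            miss_penalty=config.miss_penalty,
        )
        hotspots.append(Hotspot(f"hotspot_{i + 1}", seq, site_start, model, classes))
    return World(config, hotspots, rng)


# ---------------------------------------------------------------------------
# Simulated assays
# ---------------------------------------------------------------------------

def simulate_emsa_from_affinity(
    affinity: float,
    config: WorldConfig,
    rng: np.random.Generator,
    lane_id: str = "lane",
) -> BandPair:
    """One noisy gel lane for an oligo of known relative affinity."""
    f = expected_fraction(affinity, config)
    s = config.total_density * f * math.exp(rng.normal(0.0, config.noise_sigma))
    u = config.total_density * (1 - f) * math.exp(rng.normal(0.0, config.noise_sigma))
    return BandPair(lane_id, s, u)


def simulate_emsa(
    oligo: SiteSequence,
    hotspot: Hotspot,
    config: WorldConfig,
    rng: np.random.Generator,
) -> BandPair:
    """Noisy shifted/unshifted densities for a labeled oligo."""
    a = hotspot.model.best_affinity(oligo.sequence)
    return simulate_emsa_from_affinity(a, config, rng, lane_id=oligo.id)


def simulate_competition(
    labeled: SiteSequence,
    competitor: Optional[SiteSequence],
    hotspot: Hotspot,
    config: WorldConfig,
    rng: np.random.Generator,
) -> float:
    """Noisy labeled-oligo shifted fraction after competitor pre-incubation.

    ``competitor=None`` means no competitor (the labeled-only control).
    """
    a_lab = hotspot.model.best_affinity(labeled.sequence)
    if competitor is None:
        f = expected_fraction(a_lab, config)
    else:
        a_comp = hotspot.model.best_affinity(competitor.sequence)
        f = competed_fraction(a_comp, config, a_labeled=a_lab)
    s = config.total_density * f * math.exp(rng.normal(0.0, config.noise_sigma))
    u = config.total_density * (1 - f) * math.exp(rng.normal(0.0, config.noise_sigma))
    return shifted_fraction(BandPair("competition", s, u))


def labeled_probe(hotspot: Hotspot, length: int = 75) -> SiteSequence:
    """The labeled reference oligo: site centered in a longer fragment,
    keeping the biotin tag away from the binding sequence."""
    L = len(hotspot.model)
    pad = (length - L) // 2
    lo = max(0, hotspot.site_start - pad)
    return SiteSequence(f"{hotspot.name}_probe", hotspot.sequence[lo : lo + length])


def scrambled_competitor(
    hotspot: Hotspot, rng: np.random.Generator
) -> SiteSequence:
    """Competitor-frame oligo with a randomly shuffled site sequence."""
    frame = hotspot.competitor_frame().sequence
    scrambled = "".join(rng.permutation(list(frame)))
    return SiteSequence(f"{hotspot.name}_scrambled", scrambled)


def simulate_mutscan(
    hotspot: Hotspot,
    config: WorldConfig,
    rng: np.random.Generator,
    site_start: int = SITE_START,
    site_end: int = SITE_END,
    include_flanks: bool = False,
) -> List[CompetitionMeasurement]:
    """Full single-substitution competition scan over the 36-mer frame.

    Produces one measurement per (position, alternative base): the shifted
    fraction of the labeled probe after pre-incubation with the mutated
    competitor, alongside unmutated and scrambled controls measured in the
    same noisy batch.
    """
    frame = hotspot.competitor_frame()
    probe = labeled_probe(hotspot)
    scr = scrambled_competitor(hotspot, rng)
    positions = (
        range(1, len(frame) + 1)
        if include_flanks
        else range(site_start, site_end + 1)
    )
    out: List[CompetitionMeasurement] = []
    for pos in positions:
        ref = frame.sequence[pos - 1]
        s_un = simulate_competition(probe, frame, hotspot, config, rng)
        s_scr = simulate_competition(probe, scr, hotspot, config, rng)
        for alt in BASES:
            if alt == ref:
                continue
            mutated = SiteSequence(
                f"{frame.id}_{pos}{alt}",
                frame.sequence[: pos - 1] + alt + frame.sequence[pos:],
            )
            s_mut = simulate_competition(probe, mutated, hotspot, config, rng)
            out.append(
                CompetitionMeasurement(pos, ref, alt, s_mut, s_un, s_scr)
            )
    return out


def haplotype_affinities(
    config: WorldConfig, target_ratio: float = 2.9
) -> Tuple[float, float]:
    """Affinities of two haplotypes whose occupancy ratio equals the target.

    The stronger haplotype is the reference (affinity 1); the weaker one's
    affinity is solved so that expected shifted fractions differ by exactly
    ``target_ratio``.
    """
    f1 = expected_fraction(1.0, config)
    f2 = f1 / target_ratio
    if not 0.0 < f2 < 1.0:
        raise ValueError("target ratio outside the occupancy range")
    x2 = f2 / (1.0 - f2)
    return 1.0, x2 / config.protein_activity


def simulate_qpcr(
    fraction_bound: float,
    ct_input: float,
    noise_sd: float,
    rng: np.random.Generator,
    amplicon_id: str = "amplicon",
) -> QpcrMeasurement:
    """Invert the percent-bound formula into a noisy Ct pair.

    ``ct_chip = ct_input - log2(fraction_bound / 100) + eps`` with Gaussian
    cycle noise, so the analysis-side formula round-trips within noise.
    """
    if not 0.0 < fraction_bound <= 100.0:
        raise ValueError("fraction_bound must be in (0, 100]")
    ct_chip = ct_input - math.log2(fraction_bound / 100.0)
    if noise_sd > 0:
        ct_chip += rng.normal(0.0, noise_sd)
    return QpcrMeasurement(amplicon_id, ct_input, ct_chip)


# ---------------------------------------------------------------------------
# Oracles for the tiling/truncation localization procedure
# ---------------------------------------------------------------------------

def make_emsa_oracle(
    hotspot: Hotspot, config: WorldConfig, seed: int
) -> Callable[[str], float]:
    """Labeled-fragment binding oracle: oligo sequence -> shifted fraction."""
    rng = np.random.default_rng(seed)

    def oracle(oligo: str) -> float:
        pair = simulate_emsa(
            SiteSequence("tile", oligo), hotspot, config, rng
        )
        return shifted_fraction(pair)

    return oracle


def make_competition_oracle(
    hotspot: Hotspot, config: WorldConfig, seed: int
) -> Callable[[Optional[str]], float]:
    """Competition oracle: competitor sequence (or None) -> labeled shifted
    fraction, for the progressive-truncation minimal-site search."""
    rng = np.random.default_rng(seed)
    probe = labeled_probe(hotspot)

    def oracle(competitor: Optional[str]) -> float:
        comp = None if competitor is None else SiteSequence("competitor", competitor)
        return simulate_competition(probe, comp, hotspot, config, rng)

    return oracle
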