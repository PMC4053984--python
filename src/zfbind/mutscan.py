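"""Competition-mutagenesis analysis of a minimal binding site.

Every position of the minimal site is replaced in turn by its three
alternative bases; each mutated oligo's ability to pre-sequester protein is
read out as the shifted fraction of a subsequently added labeled reference
oligo. The binding-change index

    B_mut = (S_un - S_mut) / (S_scr - S_un)

is 0 when the mutant competes exactly like the unmutated sequence, -1 when
it competes no better than a scrambled control (complete loss of binding),
and positive when it competes better than the reference.

Per-position specificity is summarized by the standard deviation of the
binding changes at that position and classified low / moderate / high.

Coordinates: measurements are 1-based along the 36-mer competitor oligo,
which carries two extra bases 5' and three extra bases 3' of the minimal
31-bp site, so the site occupies competitor positions 3-33.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Literal, Tuple

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousInputError,
    IncompletePositionError,
    NoDynamicRangeError,
)

BASES = ("A", "C", "G", "T")

#: Competitor-oligo coordinates of the minimal binding site (1-based, inclusive).
SITE_START = 3
SITE_END = 33

#: SD thresholds separating the low/moderate and moderate/high specificity
#: classes: midpoints of the gaps between the observed group ranges
#: (0.12–0.16 and 0.36–0.45).
LOW_MODERATE_CUT = 0.14
MODERATE_HIGH_CUT = 0.405

SdMode = Literal["four_sample", "three_population"]


@dataclass(frozen=True)
class CompetitionMeasurement:
    """One mutated-oligo competition lane with its paired controls."""

    position: int  # 1-based on the 36-mer competitor
    ref_base: str
    alt_base: str
    s_mut: float  # labeled-oligo shifted fraction with the mutated competitor
    s_un: float   # ... with the unmutated competitor
    s_scr: float  # ... with the scrambled competitor

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        for name in ("s_mut", "s_un", "s_scr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a fraction in [0, 1]")


@dataclass
class SpecificityProfile:
    """Per-position binding changes, SD and class over a minimal site.

    ``changes`` maps site position (1-based within the minimal site) to a
    base -> B_mut map in which the reference base is pinned at 0.
    """

    site_length: int
    reference: str  # minimal-site sequence, 5'->3'
    changes: Dict[int, Dict[str, float]]
    sd: Dict[int, float] = field(default_factory=dict)
    classes: Dict[int, str] = field(default_factory=dict)
    flanks: pd.DataFrame | None = None  # positions outside the minimal site

    def class_counts(self) -> Dict[str, int]:
        counts = {"low": 0, "moderate": 0, "high": 0}
        for c in self.classes.values():
            counts[c] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in sorted(self.changes):
            row = {"position": pos, "ref_base": self.reference[pos - 1]}
            for b in BASES:
                row[f"b_{b}"] = self.changes[pos].get(b, np.nan)
            row["sd"] = self.sd.get(pos, np.nan)
            row["class"] = self.classes.get(pos, "")
            rows.append(row)
        return pd.DataFrame(rows)


def binding_change(s_un: float, s_mut: float, s_scr: float) -> float:
    """Relative binding change of a mutated competitor, B_mut.

    Requires dynamic range in the competition: the scrambled control must
    leave a larger labeled-oligo signal than the unmutated competitor does.
    """
    if s_scr <= s_un:
        raise NoDynamicRangeError(
            f"scrambled fraction {s_scr} must exceed unmutated fraction {s_un}"
        )
    return (s_un - s_mut) / (s_scr - s_un)


def to_site_position(competitor_position: int) -> int:
    """Convert a 1-based 36-mer competitor coordinate to a minimal-site one."""
    return competitor_position - (SITE_START - 1)


def position_sd(
    values: Iterable[float], mode: SdMode = "four_sample"
) -> float:
    """Specificity SD at one position from its three substitution B_mut values.

    ``four_sample`` (default): sample SD (n-1 denominator) over four values,
    the three substitutions plus the reference pinned at 0. A position where
    every substitution abolishes binding (all B_mut = -1) scores exactly 0.5.
    ``three_population``: population SD over the three substitution values
    only; provided for sensitivity analysis.
    """
    vals = [float(v) for v in values]
    if len(vals) != 3 or any(np.isnan(vals)):
        raise IncompletePositionError(
            "all three substitution values are required at a position"
        )
    if mode == "four_sample":
        return float(np.std([0.0] + vals, ddof=1))
    if mode == "three_population":
        return float(np.std(vals, ddof=0))
    raise ValueError(f"unknown SD mode: {mode!r}")


def classify_specificity(sd: float) -> str:
    """Classify a position's specificity SD as low, moderate or high."""
    if sd < 0:
        raise ValueError("SD must be non-negative")
    if sd < LOW_MODERATE_CUT:
        return "low"
    if sd < MODERATE_HIGH_CUT:
        return "moderate"
    return "high"


def profile_summary(
    measurements: Iterable[CompetitionMeasurement],
    site_start: int = SITE_START,
    site_end: int = SITE_END,
    sd_mode: SdMode = "four_sample",
) -> SpecificityProfile:
    """Assemble a per-position specificity profile from a full scan.

    Every minimal-site position (competitor coordinates ``site_start`` to
    ``site_end``) must carry all three substitutions. Flanking positions are
    summarized in ``profile.flanks`` but do not enter the classified site.

    Raises
    ------
    AmbiguousInputError
        On duplicate (position, alt_base) records.
    IncompletePositionError
        When a site position misses a substitution.
    """
    by_pos: Dict[int, Dict[str, float]] = {}
    ref_by_pos: Dict[int, str] = {}
    for m in measurements:
        slot = by_pos.setdefault(m.position, {})
        if m.alt_base in slot:
            raise AmbiguousInputError(
                f"duplicate record for position {m.position} alt {m.alt_base}"
            )
        slot[m.alt_base] = binding_change(m.s_un, m.s_mut, m.s_scr)
        prev = ref_by_pos.setdefault(m.position, m.ref_base)
        if prev != m.ref_base:
            raise AmbiguousInputError(
                f"conflicting reference base at position {m.position}"
            )

    site_len = site_end - site_start + 1
    changes: Dict[int, Dict[str, float]] = {}
    sds: Dict[int, float] = {}
    classes: Dict[int, str] = {}
    ref_seq = []
    for comp_pos in range(site_start, site_end + 1):
        if comp_pos not in by_pos:
            raise IncompletePositionError(f"no measurements at position {comp_pos}")
        subs = by_pos[comp_pos]
        ref = ref_by_pos[comp_pos]
        missing = [b for b in BASES if b != ref and b not in subs]
        if missing:
            raise IncompletePositionError(
                f"position {comp_pos}: missing substitutions {missing}"
            )
        site_pos = comp_pos - site_start + 1
        ref_seq.append(ref)
        changes[site_pos] = {ref: 0.0, **subs}
        sds[site_pos] = position_sd(
            [subs[b] for b in BASES if b != ref], mode=sd_mode
        )
        classes[site_pos] = classify_specificity(sds[site_pos])

    flank_rows = []
    for comp_pos in sorted(by_pos):
        if site_start <= comp_pos <= site_end:
            continue
        for alt, b in sorted(by_pos[comp_pos].items()):
            flank_rows.append(
                {
                    "position": comp_pos,
                    "ref_base": ref_by_pos[comp_pos],
                    "alt_base": alt,
                    "b_mut": b,
                }
            )
    flanks = pd.DataFrame(
        flank_rows, columns=["position", "ref_base", "alt_base", "b_mut"]
    )

    return SpecificityProfile(
        site_length=site_len,
        reference="".join(ref_seq),
        changes=changes,
        sd=sds,
        classes=classes,
        flanks=flanks,
    )


def analyze_scan_table(
    df: pd.DataFrame,
    site_start: int = SITE_START,
    site_end: int = SITE_END,
    sd_mode: SdMode = "four_sample",
) -> Tuple[pd.DataFrame, SpecificityProfile]:
    """Run the profile summary over a mutscan TSV table.

    Expects columns ``position, ref_base, alt_base, s_mut, s_un, s_scr``;
    returns the per-position output table (with ``b_*``, ``sd``, ``class``)
    alongside the profile object.
    """
    measurements = [
        CompetitionMeasurement(
            int(r.position), str(r.ref_base), str(r.alt_base),
            float(r.s_mut), float(r.s_un), float(r.s_scr),
        )
        for r in df.itertuples()
    ]
    profile = profile_summary(
        measurements, site_start=site_start, site_end=site_end, sd_mode=sd_mode
    )
    return profile.to_frame(), profile
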