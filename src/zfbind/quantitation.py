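"""Normalized quantities from raw assay readouts.

Gel densitometry, histone-methyltransferase dot blots and ChIP-qPCR all
report arbitrary instrument units; the functions here reduce them to the
dimensionless fractions the downstream analysis consumes:

* gel shift: shifted fraction ``S / (S + U)`` per lane;
* methyltransferase activity: specific H3K4me3 fraction
  ``(S_ind - S_un) / (S_H3K4me3 - S_H3K4me2)`` against commercial standards;
* ChIP-qPCR: percent chromatin bound ``2**(Ct_input - Ct_ChIP) * 100``,
  with failed IgG-control reactions imputed to 35 cycles.

Densities are taken as scored, with no background subtraction: only
ratios of densities are meaningful, so any common gain cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import (
    DegenerateComparisonError,
    IncompleteRecordError,
    InvalidCalibrationError,
    UnquantifiableLaneError,
)

#: Ct value assigned to qPCR reactions that failed to amplify.
FAILED_CT = 35.0


@dataclass(frozen=True)
class BandPair:
    """Shifted and unshifted band densities of one gel lane."""

    lane_id: str
    shifted_density: float
    unshifted_density: float

    def __post_init__(self) -> None:
        if self.shifted_density < 0 or self.unshifted_density < 0:
            raise ValueError(f"lane {self.lane_id}: band densities must be >= 0")


@dataclass(frozen=True)
class MethylationSignals:
    """Dot-blot signals of induced/uninduced extracts and the two standards."""

    s_induced: float
    s_uninduced: float
    s_me3_standard: float
    s_me2_standard: float


@dataclass(frozen=True)
class QpcrMeasurement:
    """One amplicon's input and ChIP Ct values (imputation already applied)."""

    amplicon_id: str
    ct_input: float
    ct_chip: float
    failed_flag: bool = False


def shifted_fraction(lane: BandPair) -> float:
    """Fraction of probe in the shifted (protein-bound) band, S/(S+U).

    Scale-invariant: multiplying both densities by the same positive gain
    leaves the fraction unchanged.

    Raises
    ------
    UnquantifiableLaneError
        If both band densities are zero.
    """
    total = lane.shifted_density + lane.unshifted_density
    if total <= 0:
        raise UnquantifiableLaneError(
            f"lane {lane.lane_id}: both band densities are zero"
        )
    return lane.shifted_density / total


def binding_ratio(
    fractions_a: Sequence[float], fractions_b: Sequence[float]
) -> float:
    """Ratio of mean shifted fractions between two lane groups, a / b.

    Used to compare binding strength of two haplotypes of the same site
    across replicate lanes. Uses the ratio of arithmetic means.
    """
    if not len(fractions_a) or not len(fractions_b):
        raise ValueError("both replicate groups must be non-empty")
    mean_b = sum(fractions_b) / len(fractions_b)
    if mean_b <= 0:
        raise DegenerateComparisonError("denominator group has zero mean fraction")
    mean_a = sum(fractions_a) / len(fractions_a)
    return mean_a / mean_b


def h3k4me3_fraction(sig: MethylationSignals) -> float:
    """Specific H3K4me3 fraction of a methyltransferase dot blot.

    ``(S_ind - S_un) / (S_H3K4me3 - S_H3K4me2)`` — induction signal over the
    dynamic range spanned by the trimethylated and dimethylated standards.
    Invariant under a common affine gain applied to all four signals.
    """
    denom = sig.s_me3_standard - sig.s_me2_standard
    if denom == 0:
        raise InvalidCalibrationError("me3 and me2 standards are equal")
    return (sig.s_induced - sig.s_uninduced) / denom


def chip_fraction_bound(m: QpcrMeasurement) -> float:
    """Percent chromatin bound, ``2**(Ct_input - Ct_ChIP) * 100``.

    Equal Ct values give 100%; each additional ChIP cycle halves the
    percentage. A failed reaction imputed to Ct 35 against a typical input
    of ~23 cycles lands near 2**-12 * 100 ≈ 0.024%.
    """
    if m.ct_input is None or m.ct_chip is None:
        raise IncompleteRecordError(f"amplicon {m.amplicon_id}: missing Ct value")
    return 2.0 ** (m.ct_input - m.ct_chip) * 100.0


def impute_failed_ct(raw_ct: Optional[float], failed: bool) -> float:
    """Ct for one reaction: the raw value, or 35 cycles if it failed.

    Missing values are treated as failures.
    """
    if failed or raw_ct is None or (isinstance(raw_ct, float) and math.isnan(raw_ct)):
        return FAILED_CT
    return float(raw_ct)


def mean_ct(replicates: Iterable[Optional[float]], failed: Iterable[bool]) -> float:
    """Average Ct over replicate reactions after per-reaction imputation."""
    values = [impute_failed_ct(ct, f) for ct, f in zip(replicates, failed)]
    if not values:
        raise ValueError("no replicate Ct values supplied")
    return sum(values) / len(values)


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------

def quantify_emsa_table(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``shifted_fraction`` column to a densitometry table.

    Expects columns ``lane_id``, ``shifted_density``, ``unshifted_density``
    (extra columns such as ``oligo_id``/``condition`` pass through).
    """
    out = df.copy()
    out["shifted_fraction"] = [
        shifted_fraction(BandPair(str(r.lane_id), r.shifted_density, r.unshifted_density))
        for r in df.itertuples()
    ]
    return out


def quantify_chip_table(df: pd.DataFrame) -> pd.DataFrame:
    """Percent bound per amplicon from a replicate-level qPCR table.

    Expects columns ``amplicon_id``, ``replicate``, ``ct_input``, ``ct_chip``,
    ``failed`` (0/1 applying to the ChIP reaction). Replicate Ct values are
    imputed and averaged per amplicon before the percent-bound formula.
    """
    rows = []
    for amplicon, grp in df.groupby("amplicon_id", sort=False):
        ct_in = mean_ct(grp["ct_input"], [False] * len(grp))
        ct_ch = mean_ct(grp["ct_chip"], grp["failed"].astype(bool))
        m = QpcrMeasurement(str(amplicon), ct_in, ct_ch)
        rows.append(
            {
                "amplicon_id": amplicon,
                "ct_input": ct_in,
                "ct_chip": ct_ch,
                "percent_bound": chip_fraction_bound(m),
            }
        )
    return pd.DataFrame(rows)
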