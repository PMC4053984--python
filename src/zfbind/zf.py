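"""Zinc-finger arrays: footprints, identical-finger groups, site maps.

A C2H2-type finger contacts roughly four consecutive base pairs through
residues at helix positions -1, +2, +3 and +6, with the fourth base shared
with the next finger — hence an n-finger array covers a 3n-bp core and at
most 3n+1 bp. Fingers are numbered 1..n from the N terminus, and the
default orientation maps the N-terminal finger to the 5'-most site triplet;
the reverse convention is available for sensitivity analysis.

The bundled example arrays (11 fingers with an identical-contact group at
fingers 2, 5, 7 and 9; 12 fingers with two identical pairs) are synthetic
stand-ins that reproduce the structural facts stated in the text; true
residue identities live in figures not shipped with this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Literal, Sequence, Tuple

import pandas as pd

from .motifstats import SiteSequence

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

GroupMode = Literal["contacts", "full"]


@dataclass(frozen=True)
class ZincFinger:
    """One finger's DNA-contacting residues (helix -2, -1, +2, +3, +6)."""

    index: int  # 1-based from the N terminus
    res_m2: str
    res_m1: str
    res_p2: str
    res_p3: str
    res_p6: str
    full_sequence: str | None = None

    def __post_init__(self) -> None:
        for name in ("res_m2", "res_m1", "res_p2", "res_p3", "res_p6"):
            aa = getattr(self, name)
            if aa not in VALID_AA:
                raise ValueError(f"finger {self.index}: invalid residue {aa!r}")

    @property
    def contacts(self) -> Tuple[str, str, str, str]:
        """Specificity residues at -1, +2, +3, +6 (e.g. ('A','S','N','Q'))."""
        return (self.res_m1, self.res_p2, self.res_p3, self.res_p6)


@dataclass(frozen=True)
class ZfArray:
    """An ordered zinc-finger array belonging to a named allele."""

    allele_name: str
    fingers: Tuple[ZincFinger, ...]

    def __post_init__(self) -> None:
        if not self.fingers:
            raise ValueError("a zinc-finger array needs at least one finger")

    def __len__(self) -> int:
        return len(self.fingers)


def footprint(array: ZfArray) -> Tuple[int, int]:
    """(core_bp, max_bp) DNA footprint of the array: (3n, 3n + 1)."""
    n = len(array)
    return 3 * n, 3 * n + 1


def identical_groups(array: ZfArray, mode: GroupMode = "contacts") -> List[List[int]]:
    """Partition finger indices by identical contact residues (or sequence).

    ``contacts`` compares the -1/+2/+3/+6 residues; ``full`` compares the
    full amino-acid sequence (which must then be present). Groups are
    returned in order of their first member.
    """
    keys: Dict[object, List[int]] = {}
    for f in array.fingers:
        if mode == "contacts":
            key: object = f.contacts
        elif mode == "full":
            if f.full_sequence is None:
                raise ValueError(f"finger {f.index} lacks a full sequence")
            key = f.full_sequence
        else:
            raise ValueError(f"unknown grouping mode: {mode!r}")
        keys.setdefault(key, []).append(f.index)
    return list(keys.values())


def finger_site_map(
    array: ZfArray,
    site: SiteSequence,
    anchor_offset: int = 0,
    n_to_c_is_5_to_3: bool = True,
) -> Dict[int, str]:
    """Trinucleotide bound by each finger on a site sequence.

    Finger i (N->C) takes site positions ``anchor_offset + 3(i-1) + 1`` to
    ``anchor_offset + 3i`` (1-based, 5'->3'). With
    ``n_to_c_is_5_to_3=False`` the finger order is reversed, mapping the
    C-terminal finger to the 5' end instead.
    """
    n = len(array)
    if len(site) < 3 * n + anchor_offset:
        raise ValueError(
            f"site {site.id} ({len(site)} bp) too short for {n} fingers "
            f"at anchor {anchor_offset}"
        )
    order = range(1, n + 1) if n_to_c_is_5_to_3 else range(n, 0, -1)
    out: Dict[int, str] = {}
    for slot, finger in enumerate(order):
        start = anchor_offset + 3 * slot
        out[finger] = site.sequence[start : start + 3]
    return out


def consistency_audit(
    array: ZfArray,
    sites: Sequence[Tuple[SiteSequence, int]],
    mode: GroupMode = "contacts",
    n_to_c_is_5_to_3: bool = True,
) -> pd.DataFrame:
    """Do identical fingers bind identical trinucleotides?

    For every identical-finger group (size > 1) collect the triplets its
    members bind within and across the given ``(site, anchor)`` pairs;
    a group is consistent only if all those triplets are equal.
    """
    rows = []
    for group in identical_groups(array, mode=mode):
        if len(group) < 2:
            continue
        triplets: List[str] = []
        per_site: Dict[str, List[str]] = {}
        for site, anchor in sites:
            m = finger_site_map(
                array, site, anchor_offset=anchor,
                n_to_c_is_5_to_3=n_to_c_is_5_to_3,
            )
            bound = [m[i] for i in group]
            per_site[site.id] = bound
            triplets.extend(bound)
        rows.append(
            {
                "fingers": tuple(group),
                "triplets": tuple(triplets),
                "per_site": per_site,
                "all_identical": len(set(triplets)) == 1,
            }
        )
    return pd.DataFrame(rows, columns=["fingers", "triplets", "per_site", "all_identical"])


# ---------------------------------------------------------------------------
# TSV I/O and bundled example arrays
# ---------------------------------------------------------------------------

def array_from_frame(df: pd.DataFrame, allele_name: str) -> ZfArray:
    fingers = []
    for r in df.sort_values("finger_index").itertuples():
        full = getattr(r, "full_sequence", None)
        fingers.append(
            ZincFinger(
                int(r.finger_index), str(r.res_m2), str(r.res_m1),
                str(r.res_p2), str(r.res_p3), str(r.res_p6),
                full_sequence=None if full is None or pd.isna(full) else str(full),
            )
        )
    return ZfArray(allele_name, tuple(fingers))


def read_zf_tsv(path, allele_name: str | None = None) -> ZfArray:
    """Read a finger table (finger_index, res_m2, res_m1, res_p2, res_p3,
    res_p6[, full_sequence])."""
    df = pd.read_csv(path, sep="\t")
    return array_from_frame(df, allele_name or str(path))


def load_example_array(allele: str) -> ZfArray:
    """Bundled synthetic stand-in arrays: 'cst' (11 fingers) or 'dom2' (12)."""
    name = {"cst": "prdm9_cst_zf_synthetic.tsv", "dom2": "prdm9_dom2_zf_synthetic.tsv"}[
        allele.lower()
    ]
    ref = resources.files("zfbind.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_zf_tsv(path, allele_name=allele.lower())
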