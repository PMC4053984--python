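"""Readers and writers for the package's standard file shapes.

FASTA goes through Biopython; tables (densitometry, qPCR, mutscan, PWM,
BED) are plain tab-separated files handled with pandas. Motifs are read
either from MEME minimal format or from a TSV with columns
``position, fA, fC, fG, fT``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifstats import BASES, FrequencyMotif, SiteSequence
from .pwm import Pwm

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path) -> List[SiteSequence]:
    return [
        SiteSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, sites) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in sites
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(path, df: pd.DataFrame) -> None:
    df.to_csv(str(path), sep="\t", header=False, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(str(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def read_motif_tsv(path) -> FrequencyMotif:
    """Frequency motif from a TSV with columns position, fA, fC, fG, fT."""
    df = pd.read_csv(str(path), sep="\t").sort_values("position")
    return FrequencyMotif(
        [{b: float(r[f"f{b}"]) for b in BASES} for _, r in df.iterrows()]
    )


def write_motif_tsv(path, motif: FrequencyMotif) -> None:
    rows = [
        {"position": i + 1, **{f"f{b}": f.get(b, 0.0) for b in BASES}}
        for i, f in enumerate(motif.freq)
    ]
    pd.DataFrame(rows).to_csv(str(path), sep="\t", index=False)


def read_meme_minimal(path) -> Dict[str, FrequencyMotif]:
    """All motifs of a MEME minimal-format file, keyed by name."""
    motifs: Dict[str, FrequencyMotif] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        stripped = lines[i].strip()
        if stripped.startswith("MOTIF"):
            name = stripped.split()[1]
            while i < len(lines) and not lines[i].lstrip().startswith(
                "letter-probability"
            ):
                i += 1
            rows: List[List[float]] = []
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                i += 1
            if not rows:
                raise ValueError(f"motif {name}: no probability rows found")
            motifs[name] = FrequencyMotif([dict(zip(BASES, r)) for r in rows])
        else:
            i += 1
    return motifs


def write_meme_minimal(path, name: str, motif_probs: np.ndarray, background=None) -> None:
    """Write one motif (L x 4 probability matrix) in MEME minimal format."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {p:.3f}" for b, p in zip(BASES, bg)),
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {motif_probs.shape[0]}",
    ]
    for row in motif_probs:
        lines.append(" ".join(f"{p:.6f}" for p in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PWMs
# ---------------------------------------------------------------------------

def read_pwm_tsv(path, background=None) -> Pwm:
    """Log-odds matrix from a TSV with columns position, wA, wC, wG, wT."""
    df = pd.read_csv(str(path), sep="\t").sort_values("position")
    weights = df[[f"w{b}" for b in BASES]].to_numpy(dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    return Pwm(weights, bg)


def write_pwm_tsv(path, pwm: Pwm) -> None:
    rows = [
        {"position": i + 1, **{f"w{b}": pwm.weights[i, j] for j, b in enumerate(BASES)}}
        for i in range(len(pwm))
    ]
    pd.DataFrame(rows).to_csv(str(path), sep="\t", index=False)
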