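"""Readers and writers for the plain-text formats the pipeline touches.

FASTA for reads, panels and consensus output; Newick for trees;
delimited tables for pellet measurements and IntCal-style calibration
curves (which come comma- or whitespace-delimited, with '#' comment
headers, depending on the distribution file).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .calibration import CalibrationCurve
from .compare import ReferenceHaplotype
from .consensus import Direction, ReplicateRead
from .morphometrics import PelletMeasurement
from .seq import clean_sequence
from .trees import Tree


# -- FASTA ---------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into (label, sequence) pairs.

    Labels are the full header lines, verbatim; sequences are
    uppercased with U mapped to T and validated against the nucleotide
    alphabet (offending record and position reported on failure).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    out = []
    for rec in records:
        label = rec.description
        if not len(rec.seq):
            raise ValueError(f"empty sequence for record {label!r} in {path}")
        out.append((label, clean_sequence(str(rec.seq), label=label)))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_DIR_RE = re.compile(r"\bdir=([FR])\b")


def read_replicate_fasta(path: str | Path) -> list[ReplicateRead]:
    """Replicate reads: headers ``fragment|replicate dir=F`` (or ``dir=R``)."""
    reads = []
    for label, seq in read_fasta(path):
        head = label.split()[0]
        if "|" not in head:
            raise ValueError(
                f"replicate header {label!r} must look like 'fragment|replicate'"
            )
        frag, rep = head.split("|", 1)
        m = _DIR_RE.search(label)
        if not m:
            raise ValueError(f"replicate header {label!r} lacks dir=F|R")
        direction = Direction.FORWARD if m.group(1) == "F" else Direction.REVERSE
        reads.append(ReplicateRead(frag, rep, direction, seq))
    return reads


def write_replicate_fasta(reads: list[ReplicateRead], path: str | Path) -> None:
    recs = [
        (
            f"{r.fragment_id}|{r.replicate_id} "
            f"dir={'F' if r.direction is Direction.FORWARD else 'R'}",
            r.bases,
        )
        for r in reads
    ]
    write_fasta(recs, path)


def read_panel_fasta(path: str | Path) -> list[ReferenceHaplotype]:
    """Reference panel: ``>ACCESSION taxon words`` headers, gapless bases."""
    panel = []
    seen = set()
    for label, seq in read_fasta(path):
        parts = label.split(None, 1)
        acc = parts[0]
        if acc in seen:
            raise ValueError(f"duplicate accession {acc!r} in panel {path}")
        seen.add(acc)
        panel.append(
            ReferenceHaplotype(
                accession=acc,
                taxon=parts[1] if len(parts) > 1 else "",
                bases=seq.replace("-", ""),
            )
        )
    return panel


# -- Newick --------------------------------------------------------------

def write_newick(tree: Tree, path: str | Path, with_support: bool = False) -> None:
    """Write one tree in standard Newick (unique leaf labels required)."""
    text = tree.newick(with_support=with_support)
    with open(path, "w") as fh:
        fh.write(text + "\n")


def read_newick(path: str | Path) -> Tree:
    with open(path) as fh:
        return Tree.from_newick(fh.read())


# -- calibration curve table ---------------------------------------------

def read_curve_table(path: str | Path) -> CalibrationCurve:
    """IntCal-dialect curve table: cal BP, 14C age BP, 1-sigma.

    Comma- and whitespace-delimited files are both accepted; lines
    beginning with '#' are comments.  Rows may arrive unsorted; knots
    are sorted by cal BP and must be unique.
    """
    cal, mu, sig = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.replace(",", " ").split()
            if len(toks) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(toks)}"
                )
            try:
                values = [float(t) for t in toks[:3]]
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell in {toks[:3]}"
                ) from None
            cal.append(values[0])
            mu.append(values[1])
            sig.append(values[2])
    if not cal:
        raise ValueError(f"no data rows in curve table {path}")
    order = np.argsort(cal, kind="stable")
    cal_arr = np.asarray(cal)[order]
    if (np.diff(cal_arr) == 0).any():
        dup = cal_arr[np.flatnonzero(np.diff(cal_arr) == 0)[0]]
        raise ValueError(f"duplicate cal BP knot {dup} in {path}")
    return CalibrationCurve(cal_arr, np.asarray(mu)[order], np.asarray(sig)[order])


# -- pellet table --------------------------------------------------------

def read_pellet_table(path: str | Path) -> list[PelletMeasurement]:
    """Delimited pellet table: id, length_mm, width_mm, optional weight_g."""
    df = pd.read_csv(path)
    required = {"id", "length_mm", "width_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pellet table {path} missing columns {sorted(missing)}")
    pellets = []
    for row in df.itertuples(index=False):
        weight = getattr(row, "weight_g", None)
        if weight is not None and pd.isna(weight):
            weight = None
        pellets.append(
            PelletMeasurement(
                id=str(row.id),
                length_mm=float(row.length_mm),
                width_mm=float(row.width_mm),
                weight_g=None if weight is None else float(weight),
            )
        )
    return pellets


def write_pellet_table(pellets: list[PelletMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in pellets],
            "length_mm": [p.length_mm for p in pellets],
            "width_mm": [p.width_mm for p in pellets],
            "weight_g": [p.weight_g for p in pellets],
        }
    ).to_csv(path, index=False)
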