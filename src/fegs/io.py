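"""FASTA input with sanitization, label files, and tabular output."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .aaindex import STANDARD_AMINO_ACIDS

logger = logging.getLogger("fegs")

_STANDARD = frozenset(STANDARD_AMINO_ACIDS)


@dataclass(frozen=True)
class SequenceRecord:
    """A sanitized protein sequence: uppercase, standard residues only."""

    id: str
    residues: str
    n_removed: int = 0


def sanitize(seq_id: str, raw: str, policy: str = "strip") -> SequenceRecord:
    """Uppercase and enforce the 20-letter alphabet.

    ``strip`` removes non-standard symbols (B, J, O, U, X, Z, gaps, stops)
    with a logged warning; ``reject`` raises on the first offending
    position (1-based).
    """
    if policy not in ("strip", "reject"):
        raise ValueError(f"policy must be 'strip' or 'reject', got {policy!r}")
    upper = raw.upper()
    if policy == "reject":
        for pos, ch in enumerate(upper, start=1):
            if ch not in _STANDARD:
                raise ValueError(
                    f"sequence {seq_id!r}: non-standard residue {ch!r} at "
                    f"position {pos}"
                )
        return SequenceRecord(id=seq_id, residues=upper)
    kept = "".join(ch for ch in upper if ch in _STANDARD)
    n_removed = len(upper) - len(kept)
    if n_removed:
        logger.warning(
            "sequence %s: stripped %d non-standard residue(s)", seq_id, n_removed
        )
    if not kept:
        raise ValueError(f"sequence {seq_id!r} is empty after sanitization")
    return SequenceRecord(id=seq_id, residues=kept, n_removed=n_removed)


def read_fasta(path: str | Path, policy: str = "strip") -> list[SequenceRecord]:
    """Read and sanitize a protein FASTA file.

    IDs are the first whitespace-separated token of each header and must
    be unique; an empty file or an empty post-sanitization sequence is an
    error.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(sanitize(rec.id, str(rec.seq), policy=policy))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column whitespace-separated file: sequence ID, class label."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>label', got {line!r}")
        sid, label = parts[0], parts[1].strip()
        if sid in out:
            raise ValueError(f"{path}:{lineno}: duplicate ID {sid!r}")
        out[sid] = label
    if not out:
        raise ValueError(f"no labels found in {path}")
    return out


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in labels.items()))


def write_feature_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, float_format="%.12g")


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
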