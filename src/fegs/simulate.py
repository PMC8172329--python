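"""Synthetic protein sequences and property indices for tests and demos.

Real evaluation datasets (globins, antifreeze proteins, transferrins, ...)
are pulled from public accessions and are not bundled; these generators
provide reproducible stand-ins with the same shape: i.i.d. random
sequences, mutation-derived protein families with known class labels, and
random AAindex-style property indices.
"""

from __future__ import annotations

import numpy as np

from .aaindex import STANDARD_AMINO_ACIDS, PropertyIndex, PropertySet
from .io import SequenceRecord

# typical single-domain protein length range (globins are ~140-150 aa)
DEFAULT_LENGTH_RANGE: tuple[int, int] = (120, 180)


def generate_random_proteins(
    n: int,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    seed: int | None = None,
    composition: np.ndarray | None = None,
    id_prefix: str = "seq",
) -> list[SequenceRecord]:
    """I.i.d. random protein sequences.

    Residues are drawn independently from ``composition`` (a probability
    20-vector in alphabetical A..Y order; uniform by default); lengths are
    uniform over the inclusive ``length_range``.  Fixed seed gives
    identical output.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    if composition is None:
        composition = np.full(20, 1 / 20)
    else:
        composition = np.asarray(composition, dtype=float)
        if composition.shape != (20,) or np.any(composition < 0):
            raise ValueError("composition must be a nonnegative 20-vector")
        if not np.isclose(composition.sum(), 1.0):
            raise ValueError(f"composition must sum to 1, sums to {composition.sum()}")
        composition = composition / composition.sum()
    rng = np.random.default_rng(seed)
    aa = np.array(list(STANDARD_AMINO_ACIDS))
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa, size=length, p=composition))
        records.append(SequenceRecord(id=f"{id_prefix}{i + 1}", residues=seq))
    return records


def generate_protein_families(
    n_families: int,
    members_per_family: int,
    length: int = 150,
    substitution_rate: float = 0.1,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Mutation-derived families with known class labels.

    Each family descends from an independent random ancestor; members are
    generated by substituting each site with the given probability
    (replacement drawn uniformly from the other 19 residues).  Returns the
    sequences and an ID -> family-label map for clustering evaluation.
    """
    if n_families < 1 or members_per_family < 1:
        raise ValueError("n_families and members_per_family must be >= 1")
    if not 0 <= substitution_rate < 1:
        raise ValueError(f"substitution_rate must be in [0, 1), got {substitution_rate}")
    rng = np.random.default_rng(seed)
    aa = np.array(list(STANDARD_AMINO_ACIDS))
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for f in range(n_families):
        ancestor = rng.integers(0, 20, size=length)
        family = f"fam{f + 1}"
        for m in range(members_per_family):
            member = ancestor.copy()
            hit = rng.random(length) < substitution_rate
            # substitute to a uniformly chosen *different* residue
            shift = rng.integers(1, 20, size=length)
            member[hit] = (member[hit] + shift[hit]) % 20
            sid = f"{family}_m{m + 1}"
            records.append(SequenceRecord(id=sid, residues="".join(aa[member])))
            labels[sid] = family
    return records, labels


def synthetic_property_set(
    n_properties: int, seed: int | None = None
) -> PropertySet:
    """Random AAindex-style property indices (distinct value vectors).

    Values are i.i.d. standard normal, so with probability one every index
    induces a distinct total amino-acid ordering; accessions follow the
    AAindex pattern (``SYNTH0001`` ...).
    """
    if n_properties < 1:
        raise ValueError(f"n_properties must be >= 1, got {n_properties}")
    rng = np.random.default_rng(seed)
    indices = []
    for p in range(n_properties):
        values = dict(zip(STANDARD_AMINO_ACIDS, rng.normal(size=20)))
        indices.append(
            PropertyIndex(
                accession=f"SYNTH{p + 1:04d}",
                description=f"synthetic random property {p + 1}",
                values=values,
            )
        )
    return PropertySet(indices=indices, source="synthetic")
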