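"""AAindex1 physicochemical property indices.

An AAindex1 record assigns one numerical value to each of the 20 standard
amino acids.  Each retained index induces a total ordering of the amino
acids (ascending property value), which in turn defines one cone layout
for the graphical curve construction.  Records with missing ("NA") values
cannot induce a total order and are dropped; records whose 20-value
vectors are exact duplicates of an earlier record are dropped as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

STANDARD_AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

_AA_SET = frozenset(STANDARD_AMINO_ACIDS)


class AAindexParseError(ValueError):
    """Raised when an AAindex1 record is malformed."""


@dataclass(frozen=True)
class PropertyIndex:
    """One amino-acid property index: an accession plus 20 finite values."""

    accession: str
    description: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != _AA_SET:
            missing = sorted(_AA_SET - set(self.values))
            extra = sorted(set(self.values) - _AA_SET)
            raise ValueError(
                f"{self.accession}: values must cover exactly the 20 standard "
                f"amino acids (missing {missing}, unexpected {extra})"
            )
        for aa, v in self.values.items():
            if not _is_finite(v):
                raise ValueError(f"{self.accession}: non-finite value for {aa}: {v!r}")

    def value_tuple(self) -> tuple[float, ...]:
        """The 20 values in canonical A..Y order (used for duplicate tests)."""
        return tuple(self.values[aa] for aa in STANDARD_AMINO_ACIDS)


@dataclass
class PropertySet:
    """An ordered, duplicate-free collection of property indices."""

    indices: list[PropertyIndex] = field(default_factory=list)
    source: str = "bundled"

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def accessions(self) -> list[str]:
        return [idx.accession for idx in self.indices]

    def subset(self, accessions: Iterable[str]) -> "PropertySet":
        """Restrict to the given accessions, in the order they are listed.

        Unknown accessions raise ``KeyError`` so that a pinned ID list and
        the database file it refers to cannot silently drift apart.
        """
        by_acc = {idx.accession: idx for idx in self.indices}
        picked = []
        for acc in accessions:
            if acc not in by_acc:
                raise KeyError(f"accession {acc!r} not present in property set")
            picked.append(by_acc[acc])
        return PropertySet(indices=picked, source=self.source)


def _is_finite(v: float) -> bool:
    return v == v and v not in (float("inf"), float("-inf"))


def _parse_i_header(line: str, accession: str, lineno: int) -> list[str]:
    # header tokens look like "A/L  R/K  N/M ..."; first letters give the
    # order of the first value row, second letters the second row
    tokens = line.split()[1:]
    if len(tokens) != 10 or any("/" not in t for t in tokens):
        raise AAindexParseError(
            f"{accession}: malformed I-line header at line {lineno}: {line.rstrip()!r}"
        )
    first = [t.split("/")[0] for t in tokens]
    second = [t.split("/")[1] for t in tokens]
    order = first + second
    if sorted(order) != sorted(STANDARD_AMINO_ACIDS):
        raise AAindexParseError(
            f"{accession}: I-line header is not a permutation of the 20 "
            f"standard amino acids (line {lineno})"
        )
    return order


def parse_aaindex(stream: TextIO | str) -> tuple[list[PropertyIndex], int]:
    """Parse an AAindex1 flat file.

    Parameters
    ----------
    stream:
        Open text handle or the file content itself.

    Returns
    -------
    (indices, n_skipped):
        Complete records in file order, and the number of records skipped
        because one or more of their values was missing ("NA").

    Raises
    ------
    AAindexParseError
        On a structurally malformed record (wrong token count, unparseable
        number), naming the accession and line number.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()

    indices: list[PropertyIndex] = []
    n_skipped = 0

    accession = ""
    description = ""
    aa_order: list[str] | None = None
    value_tokens: list[str] = []
    in_values = False

    def finish_record(lineno: int) -> None:
        nonlocal n_skipped, accession, description, aa_order, value_tokens, in_values
        if not accession and aa_order is None and not value_tokens:
            return  # blank record (e.g. trailing //)
        if aa_order is None:
            raise AAindexParseError(
                f"record ending at line {lineno} has no I-line (accession {accession!r})"
            )
        if len(value_tokens) != 20:
            raise AAindexParseError(
                f"{accession}: expected 20 values, found {len(value_tokens)} "
                f"(record ends at line {lineno})"
            )
        if any(t == "NA" for t in value_tokens):
            n_skipped += 1
        else:
            try:
                vals = [float(t) for t in value_tokens]
            except ValueError as exc:
                raise AAindexParseError(
                    f"{accession}: unparseable value near line {lineno}: {exc}"
                ) from None
            indices.append(
                PropertyIndex(
                    accession=accession,
                    description=description,
                    values=dict(zip(aa_order, vals)),
                )
            )
        accession, description, aa_order, value_tokens, in_values = "", "", None, [], False

    for lineno, raw in enumerate(lines, start=1):
        if raw.startswith("//"):
            finish_record(lineno)
            continue
        if raw.startswith("H "):
            accession = raw[2:].strip()
            in_values = False
        elif raw.startswith("D "):
            description = raw[2:].strip()
            in_values = False
        elif raw.startswith("I ") or raw.startswith("I\t"):
            aa_order = _parse_i_header(raw, accession, lineno)
            in_values = True
        elif in_values and (raw.startswith(" ") or raw.startswith("\t")):
            value_tokens.extend(raw.split())
        else:
            in_values = False  # R/A/T/J/C continuation lines

    if accession or value_tokens:
        raise AAindexParseError(
            f"unterminated record {accession!r} at end of file (missing //)"
        )
    return indices, n_skipped


def format_aaindex(indices: Iterable[PropertyIndex]) -> str:
    """Serialize property indices back to AAindex1 flat-file text.

    Values are written in the canonical header order (A R N D C Q E G H I /
    L K M F P S T W Y V) with full float precision, so parse -> format ->
    parse is lossless.
    """
    row1 = "ARNDCQEGHI"
    row2 = "LKMFPSTWYV"
    header = "I    " + "     ".join(f"{a}/{b}" for a, b in zip(row1, row2))
    chunks = []
    for idx in indices:
        v1 = " ".join(f"{idx.values[aa]:.17g}" for aa in row1)
        v2 = " ".join(f"{idx.values[aa]:.17g}" for aa in row2)
        chunks.append(
            f"H {idx.accession}\nD {idx.description}\n{header}\n"
            f"    {v1}\n    {v2}\n//\n"
        )
    return "".join(chunks)


def deduplicate(indices: list[PropertyIndex], source: str = "bundled") -> PropertySet:
    """Drop indices whose 20-value vector exactly duplicates an earlier one.

    Equality is bitwise on all 20 values; the first index of each duplicate
    group (in input order) is kept and input order is preserved.
    """
    seen: set[tuple[float, ...]] = set()
    kept: list[PropertyIndex] = []
    for idx in indices:
        key = idx.value_tuple()
        if key in seen:
            continue
        seen.add(key)
        kept.append(idx)
    return PropertySet(indices=kept, source=source)


def amino_acid_order(index: PropertyIndex) -> list[str]:
    """Sort the 20 amino acids by ascending property value.

    Ties are broken by ascending one-letter code so the resulting cone
    layout is deterministic.
    """
    return sorted(STANDARD_AMINO_ACIDS, key=lambda aa: (index.values[aa], aa))


def load_property_set(
    path: str | Path,
    id_list: Iterable[str] | None = None,
) -> PropertySet:
    """Load, NA-filter and deduplicate an AAindex1 flat file.

    ``id_list`` optionally pins the retained accessions (and their order),
    e.g. to reproduce a published selection exactly.
    """
    path = Path(path)
    with open(path) as fh:
        indices, _ = parse_aaindex(fh)
    pset = deduplicate(indices, source=str(path))
    if id_list is not None:
        pset = pset.subset(id_list)
    return pset


def read_id_list(path: str | Path) -> list[str]:
    """Read a plain-text accession list, one ID per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split()[0])
    return out


def write_id_list(pset: PropertySet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{acc}\n" for acc in pset.accessions()))
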