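"""Reading, validating, filtering and writing protein sequence data.

The benchmark regime this package targets is binary classification of
hormone-binding proteins (HBPs, the positive class) against non-HBPs from
primary sequence alone.  Sequences enter as FASTA; curation follows the
benchmark conventions of the field: sequences shorter than 50 residues and
sequences containing nonstandard amino-acid letters (B, J, O, U, X, Z) or any
character outside the 20-letter alphabet are removed before featurization.

Homology reduction (CD-HIT at 60% identity) is an external preprocessing step
and is deliberately not reimplemented here: the package accepts pre-clustered
input.  An optional keyword blacklist on the FASTA description line stands in
for annotation-based filters ("fragment", "by similarity"), which require
database metadata that plain FASTA does not carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino-acid one-letter codes, alphabetical.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

#: Letters with ambiguous residue interpretation; sequences containing them
#: are excluded from the benchmark regime.
NONSTANDARD_LETTERS = frozenset("BJOUXZ")

#: Minimum sequence length retained by the benchmark filters.
MIN_BENCHMARK_LENGTH = 50

#: CD-HIT identity threshold the upstream curation used (documentation only;
#: clustering itself is not performed by this package).
CDHIT_IDENTITY_THRESHOLD = 0.60

#: Annotation phrases that, when keyword filtering is enabled, exclude a
#: record based on its FASTA description line.
DEFAULT_KEYWORD_BLACKLIST = (
    "fragment",
    "by similarity",
    "probable",
    "probably",
    "potential",
    "maybe",
)


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class DuplicateIdError(ValueError):
    """Raised when two FASTA records share an identifier."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, residue string and optional binary label.

    ``label`` is 1 for the positive (hormone-binding) class, 0 for the
    negative class, ``None`` when unlabelled.  The sequence is stored
    uppercased but otherwise as read; validation against the standard
    alphabet happens in :func:`apply_benchmark_filters` or explicitly via
    :meth:`is_valid`.
    """

    id: str
    sequence: str
    description: str = ""
    label: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def is_valid(self) -> bool:
        """True iff the sequence is non-empty and uses only standard residues."""
        return bool(self.sequence) and set(self.sequence) <= ALPHABET_SET


@dataclass
class Dataset:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise DuplicateIdError(f"duplicate record id: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> ProteinRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def positives(self) -> list[int]:
        """Indices of records labelled positive (HBP)."""
        return [i for i, r in enumerate(self.records) if r.label == 1]

    @property
    def negatives(self) -> list[int]:
        """Indices of records labelled negative."""
        return [i for i, r in enumerate(self.records) if r.label == 0]

    def with_labels(self, labels: dict[str, int]) -> "Dataset":
        """Return a copy with labels attached by record id."""
        return Dataset(
            [replace(r, label=labels.get(r.id, r.label)) for r in self.records]
        )


def read_fasta(path, label: int | None = None) -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    The first whitespace-delimited token of each header becomes the record
    id; the remainder is kept as the description.  Sequences are uppercased.
    If ``label`` is given it is applied to every record.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first header (the line number is named).
    DuplicateIdError
        If two records share an id.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"line {lineno}: sequence data before first '>' header"
                )
            break
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                description=desc,
                label=label,
            )
        )
    return Dataset(records)


def write_fasta(ds: Dataset, path) -> None:
    """Write a :class:`Dataset` to FASTA; round-trips ids and sequences."""
    bio_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in ds
    ]
    with open(path, "w") as fh:
        _BioSeqIO.write(bio_records, fh, "fasta")


def read_labels(path) -> dict[str, int]:
    """Read a two-column tab-separated ``id<TAB>label`` file."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'id<TAB>label'")
            labels[parts[0]] = int(parts[1])
    return labels


def write_labels(ds: Dataset, path) -> None:
    """Write labelled records as a two-column tab-separated file."""
    with open(path, "w") as fh:
        for r in ds:
            if r.label is not None:
                fh.write(f"{r.id}\t{r.label}\n")


def apply_benchmark_filters(
    ds: Dataset,
    min_len: int = MIN_BENCHMARK_LENGTH,
    keyword_blacklist: tuple[str, ...] | None = None,
) -> tuple[Dataset, list[tuple[str, str]]]:
    """Apply the benchmark curation filters; never fails.

    Removes records shorter than ``min_len`` and records whose (uppercased)
    sequence contains any character outside the 20-letter standard alphabet —
    this covers the ambiguous letters B, J, O, U, X, Z as well as whitespace
    and special characters.  If ``keyword_blacklist`` is given, records whose
    description contains any blacklisted phrase (case-insensitive) are also
    removed; this emulates annotation filters such as "fragment" without
    database access and is off by default.

    Returns the surviving Dataset (order preserved) and a rejection log of
    ``(id, reason)`` pairs.  Idempotent: survivors pass a second application
    unchanged.
    """
    survivors: list[ProteinRecord] = []
    rejections: list[tuple[str, str]] = []
    for rec in ds:
        seq = rec.sequence.upper()
        if keyword_blacklist is not None:
            desc = rec.description.lower()
            hit = next((kw for kw in keyword_blacklist if kw.lower() in desc), None)
            if hit is not None:
                rejections.append((rec.id, f"blacklisted keyword: {hit}"))
                continue
        if len(seq) < min_len:
            rejections.append((rec.id, f"length<{min_len}"))
            continue
        bad = set(seq) - ALPHABET_SET
        if bad:
            rejections.append((rec.id, "nonstandard letter"))
            continue
        if seq != rec.sequence:
            rec = replace(rec, sequence=seq)
        survivors.append(rec)
    return Dataset(survivors), rejections


def write_rejection_log(rejections: list[tuple[str, str]], path) -> None:
    """Write the rejection log as tab-separated ``id<TAB>reason`` lines."""
    with open(path, "w") as fh:
        for rec_id, reason in rejections:
            fh.write(f"{rec_id}\t{reason}\n")
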