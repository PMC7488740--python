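"""FASTA input/output and window handling for cytosine-centred DNA samples.

All user-facing coordinates (window ids produced by :func:`extract_windows`)
are 1-based; internal indexing is 0-based throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")
DEFAULT_WINDOW_LENGTH = 41


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


class SequenceValidationError(ValueError):
    """Raised when a sequence violates the sample invariants."""


class ConfigurationError(ValueError):
    """Raised for invalid parameter values (e.g. even window length)."""


@dataclass(frozen=True)
class DnaSample:
    """A fixed-length DNA window with an optional binary label.

    Parameters
    ----------
    id : str
        Record identifier, unique within a :class:`SampleSet`.
    sequence : str
        Upper-case string over ``{A, C, G, T}``.
    label : int, optional
        1 for a methylated (positive) window, 0 for a negative window,
        ``None`` when unlabeled.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def center_base(self) -> str:
        """Base at the central position ((L+1)/2, 1-based)."""
        return self.sequence[len(self.sequence) // 2]


def validate_sample(
    sample: DnaSample,
    window_length: int,
    require_center_c: bool = True,
) -> None:
    """Check a sample against the window invariants.

    Raises :class:`SequenceValidationError` naming the offending record when
    the sequence has the wrong length, contains a non-ACGT character, or
    (when ``require_center_c``) lacks a cytosine at the central position.
    """
    seq = sample.sequence
    if len(seq) != window_length:
        raise SequenceValidationError(
            f"record '{sample.id}': length {len(seq)} != expected {window_length}"
        )
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceValidationError(
            f"record '{sample.id}': invalid character(s) {sorted(bad)} "
            "(only A, C, G, T are allowed)"
        )
    if require_center_c and window_length % 2 == 1:
        if sample.center_base != "C":
            raise SequenceValidationError(
                f"record '{sample.id}': centre base '{sample.center_base}' is not C"
            )
    if sample.label is not None and sample.label not in (0, 1):
        raise SequenceValidationError(
            f"record '{sample.id}': label {sample.label!r} is not binary"
        )


@dataclass
class SampleSet:
    """An ordered collection of same-length :class:`DnaSample` windows."""

    samples: list[DnaSample] = field(default_factory=list)
    window_length: int = DEFAULT_WINDOW_LENGTH

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise SequenceValidationError(f"duplicate sample id '{dup}'")
        for s in self.samples:
            if len(s) != self.window_length:
                raise SequenceValidationError(
                    f"record '{s.id}': length {len(s)} != window length "
                    f"{self.window_length}"
                )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[DnaSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> DnaSample:
        return self.samples[i]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def labels(self) -> list[Optional[int]]:
        return [s.label for s in self.samples]


def read_fasta(
    path: str | Path,
    label: Optional[int] = None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    require_center_c: bool = True,
    skip_invalid: bool = False,
) -> SampleSet:
    """Read fixed-length DNA windows from a FASTA file.

    Sequences are upper-cased before validation (soft-masked genomic FASTA
    is common).  ``label`` is attached to every record.  With
    ``skip_invalid`` records failing validation are dropped instead of
    raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    samples: list[DnaSample] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython is permissive
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records and path.stat().st_size > 0:
        raise FastaParseError(f"{path}: no FASTA records found")
    for rec in records:
        sample = DnaSample(id=rec.id, sequence=str(rec.seq).upper(), label=label)
        try:
            validate_sample(sample, window_length, require_center_c=require_center_c)
        except SequenceValidationError:
            if skip_invalid:
                continue
            raise
        samples.append(sample)
    return SampleSet(samples=samples, window_length=window_length)


def write_fasta(samples: SampleSet | Sequence[DnaSample], path: str | Path) -> None:
    """Write samples to a FASTA file (one record per sample, id as header)."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.id, description="") for s in samples
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def extract_windows(
    sequence: str,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    source_id: str = "seq",
) -> SampleSet:
    """Extract every cytosine-centred window from a long DNA sequence.

    One unlabeled sample is produced per cytosine at 1-based position ``p``
    with ``p >= (window_length+1)/2`` and ``p <= len - (window_length-1)/2``;
    cytosines too close to either end are skipped (no padding).  Only the
    forward strand is scanned.  Window ids are ``{source_id}_pos{p}``.
    """
    if window_length % 2 == 0:
        raise ConfigurationError(f"window_length must be odd, got {window_length}")
    sequence = sequence.upper()
    bad = set(sequence) - DNA_ALPHABET
    if bad:
        raise SequenceValidationError(
            f"sequence contains invalid character(s) {sorted(bad)}"
        )
    half = (window_length - 1) // 2
    samples = []
    for i, base in enumerate(sequence):  # i is 0-based
        if base != "C":
            continue
        if i - half < 0 or i + half >= len(sequence):
            continue
        window = sequence[i - half : i + half + 1]
        samples.append(DnaSample(id=f"{source_id}_pos{i + 1}", sequence=window))
    return SampleSet(samples=samples, window_length=window_length)
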