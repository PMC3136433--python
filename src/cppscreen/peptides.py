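"""Peptide records, validation, FASTA I/O and the bundled datasets.

The package ships three fixture collections compiled from the published
screening literature: 111 experimentally confirmed cell-penetrating
peptides (``cpp111``), 34 non-penetrating CPP analogs and peptide hormones
(``noncpp34``), and the 13 peptides used for wet-lab validation
(``validation13``). All bundled sequences use only the 20 canonical
residues; C-terminal amidation in the validation set is recorded as a flag
and ignored by every descriptor (features are computed from sequence only).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .errors import (EmptyInput, EmptySequence, InvalidResidue, ParseError,
                     UnknownDataset)

#: canonical one-letter amino-acid alphabet, alphabetical order
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHASET = frozenset(ALPHABET)


class Label(enum.Enum):
    """Class label of a peptide."""

    CPP = "CPP"
    NON_CPP = "NON_CPP"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence with label and provenance.

    Parameters
    ----------
    id : str
        Short identifier, unique within a collection.
    sequence : str
        Uppercase string over the 20 canonical one-letter codes.
    label : Label
        CPP, NON_CPP or UNKNOWN.
    source : str
        Free-text provenance tag.
    amidated : bool
        True when the source record carried a C-terminal amide; metadata
        only, never used by descriptors.
    """

    id: str
    sequence: str
    label: Label = Label.UNKNOWN
    source: str = ""
    amidated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def parse_peptide(raw: str, id: str, label: Label = Label.UNKNOWN,
                  source: str = "", amidated: bool = False) -> Peptide:
    """Validate and canonicalize a raw sequence into a :class:`Peptide`.

    Whitespace is stripped and the sequence upper-cased; any character
    outside the canonical alphabet (B, J, O, U, X, Z, digits, punctuation)
    is rejected with its 1-based position rather than dropped.
    """
    seq = "".join(raw.split()).upper()
    if not seq:
        raise EmptySequence(f"empty sequence for peptide {id!r}")
    for i, ch in enumerate(seq):
        if ch not in _ALPHASET:
            raise InvalidResidue(ch, i + 1, context=f"peptide {id!r}")
    return Peptide(id=id, sequence=seq, label=label, source=source,
                   amidated=amidated)


@dataclass
class PeptideCollection:
    """An ordered, id-unique list of peptides."""

    peptides: list[Peptide] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peptides]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate peptide ids in {self.name!r}: {dup}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def relabel(self, label: Label) -> "PeptideCollection":
        return PeptideCollection(
            [replace(p, label=label) for p in self.peptides], name=self.name)


# ---------------------------------------------------------------------------
# bundled fixture datasets

_BUNDLED = {"cpp111", "noncpp34", "validation13"}

_ROLE_LABELS = {
    "Control(+)": Label.CPP,
    "Control(-)": Label.NON_CPP,
    "Known Non-CPP-CPP Analog": Label.NON_CPP,
    "Predicted CPP": Label.UNKNOWN,
    "Predicted Non-CPP": Label.UNKNOWN,
}


def _data_text(filename: str) -> str:
    return resources.files("cppscreen.data").joinpath(filename).read_text()


def load_bundled(name: str) -> PeptideCollection:
    """Return one of the packaged fixture collections.

    ``cpp111``: 111 known CPPs, labeled CPP. ``noncpp34``: 34 known
    non-penetrating analogs, labeled NON_CPP. ``validation13``: the 13
    synthesized validation peptides, labeled by their experimental role
    (positive/negative controls and the known non-penetrating analog get
    CPP/NON_CPP; classifier-predicted candidates stay UNKNOWN).
    """
    if name not in _BUNDLED:
        raise UnknownDataset(
            f"unknown dataset {name!r}; choose from {sorted(_BUNDLED)}")
    if name == "cpp111":
        seqs = _data_text("cpp111.txt").split()
        peps = [parse_peptide(s, f"cpp_{i+1:03d}", Label.CPP, source="known CPP table")
                for i, s in enumerate(seqs)]
    elif name == "noncpp34":
        seqs = _data_text("noncpp34.txt").split()
        peps = [parse_peptide(s, f"noncpp_{i+1:02d}", Label.NON_CPP,
                              source="known non-penetrating analog table")
                for i, s in enumerate(seqs)]
    else:
        rows = list(csv.DictReader(_data_text("validation13.tsv").splitlines(),
                                   delimiter="\t"))
        peps = [parse_peptide(r["sequence"], r["name"],
                              _ROLE_LABELS[r["role"]],
                              source=f"validation set ({r['role']})",
                              amidated=r["amidated"] == "yes")
                for r in rows]
    return PeptideCollection(peps, name=name)


# ---------------------------------------------------------------------------
# FASTA and plain-text I/O

def read_fasta(path: str | Path, label: Label = Label.UNKNOWN) -> PeptideCollection:
    """Read a FASTA file into a collection; multi-line records are joined."""
    path = Path(path)
    peps: list[Peptide] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise ParseError(f"record {header!r} has no sequence", header_line)
        peps.append(parse_peptide("".join(chunks), header, label))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError("empty FASTA header", lineno)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError("sequence data before first '>' header", lineno)
                chunks.append(line)
    flush()
    if not peps:
        raise ParseError(f"no FASTA records in {path}")
    return PeptideCollection(peps, name=path.stem)


def write_fasta(collection: PeptideCollection | Iterable[Peptide],
                path: str | Path, width: int = 60) -> None:
    """Write a collection to FASTA; round-trips ids and sequences exactly."""
    peps = list(collection)
    if not peps:
        raise EmptyInput("cannot write an empty collection")
    with open(path, "w") as fh:
        for p in peps:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i:i + width] + "\n")
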