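"""Reading, writing and validating mature defensin sequences.

The unit of analysis throughout the package is the *mature* defensin
domain: the peptide that remains after the secretion signal has been
removed.  Sequences are plain 20-letter amino-acid strings; ambiguity
codes (B, J, O, U, X, Z) and stop symbols are rejected because every
downstream computation (mass, charge, scaffold detection, alignment
encoding) requires a fully determined sequence.

The four recombinantly expressed study peptides (AtD90, AtD212, CrD26,
SlD26) ship as fixtures.  Each carries the extra N-terminal alanine left
behind by signal cleavage in the Pichia pastoris expression system; all
residue numbering downstream (e.g. "Cys15") counts that alanine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FastaParseError(ValueError):
    """Raised when a file cannot be parsed as FASTA."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains a disallowed character."""


@dataclass(frozen=True)
class MatureDefensin:
    """A mature defensin domain with optional provenance metadata.

    Parameters
    ----------
    id : str
        Short unique identifier (FASTA header token before the first
        whitespace).
    sequence : str
        Amino-acid sequence, uppercase, 20-letter alphabet only.
    taxon : str, optional
        Source organism, free text.
    notes : str, optional
        Free-text annotation (e.g. the FASTA description).
    """

    id: str
    sequence: str
    taxon: str | None = None
    notes: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise SequenceValidationError(f"{self.id}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_RESIDUES:
                raise SequenceValidationError(
                    f"{self.id}: disallowed character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


# Table of the four expressed and purified study peptides.  The leading
# Ala on each is introduced by the expression system and is part of the
# mature sequence as analyzed (residue numbering includes it).
_FIXTURES: tuple[tuple[str, str, str], ...] = (
    (
        "AtD90",
        "AHCDHFLGEAPVYPCKEKACKSVCKEHYHHACKGECEYHGREVHCHCYGDYH",
        "Arabidopsis thaliana",
    ),
    (
        "AtD212",
        "ANCDTYLGEVTVYYPCRERDCEAQCYEHYPHSCKGECEHHDHVVHHDNEEEHCHC",
        "Arabidopsis thaliana",
    ),
    (
        "CrD26",
        "ANDCDRFLGEATVSYPCRERECEAQCHEHYEHSCKGECEDHDHDHGHHDHDDHHDHEEHCHCYGH",
        "Capsella rubella",
    ),
    (
        "SlD26",
        "AKHCGKHSKSWNGKCFHKKCNHWCMEKEDAKYGSCSHGDCYCYYHC",
        "Solanum lycopersicum",
    ),
)


def load_fixtures() -> list[MatureDefensin]:
    """Return the four expressed study peptides (AtD90, AtD212, CrD26, SlD26)."""
    return [
        MatureDefensin(id=i, sequence=s, taxon=t, notes="expressed study peptide")
        for i, s, t in _FIXTURES
    ]


def _check_unique_ids(records: Iterable[MatureDefensin]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise SequenceValidationError(f"duplicate id {r.id!r} in collection")
        seen.add(r.id)


def read_fasta(path: str | Path) -> list[MatureDefensin]:
    """Read mature defensins from a FASTA file.

    The header token before the first whitespace becomes the record id;
    the remainder of the header, if any, is stored in ``notes``.
    Sequences are uppercased; wrapped sequence lines and blank lines are
    accepted.  Record order is preserved.

    Raises
    ------
    FastaParseError
        If the file does not look like FASTA (first non-blank line must
        start with ``>``); the message names the offending line.
    SequenceValidationError
        If a sequence contains a character outside the 20-letter
        alphabet; the message names the record id and position.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                break

    records: list[MatureDefensin] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() or None
        records.append(MatureDefensin(id=rec.id, sequence=str(rec.seq), notes=desc))
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[MatureDefensin], path: str | Path) -> None:
    """Write records as FASTA, 60-column wrapped."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.notes or "")
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def collection_table(records: Iterable[MatureDefensin]) -> pd.DataFrame:
    """One row per sequence: id, length, taxon, notes, sequence."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "length": len(r),
                "taxon": r.taxon,
                "notes": r.notes,
                "sequence": r.sequence,
            }
            for r in records
        ]
    )


def write_report(records: Iterable[MatureDefensin], path: str | Path,
                 fmt: str = "tsv") -> None:
    """Write a tabular report of a collection as TSV or JSON."""
    df = collection_table(records)
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
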