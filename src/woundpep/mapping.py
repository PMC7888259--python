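"""Localize peptides in parent proteins and derive cleavage-site residues.

Endogenous peptides carry two pieces of positional information once placed
in their parent protein: the residues flanking each end, and whether an end
coincides with the protein's own N- or C-terminus (in which case no
protease generated it). In the per-peptide convention used throughout this
package, P1 is the peptide's last residue (the residue N-terminal of the
cut that produced the peptide's C-terminus) and P1' is the peptide's first
residue (C-terminal of the cut that produced its N-terminus). A peptide end
that is protein-inherent contributes no cleavage information and is
excluded from P1/P1' profiles.

An initiator-methionine policy (``met_tolerant``, default True) treats a
peptide starting at position 2 of a protein whose residue 1 is M as
protein-N-terminal, since mature proteins frequently lack the initiator Met.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .core_io import GroupedDataset, PeptideRecord, ProteinDatabase

AmbiguityPolicy = Literal[
    "all_locations", "first_accession", "declared_accession_only", "declared_then_all"
]


@dataclass(frozen=True)
class PeptideLocation:
    """One placement of a peptide in a parent protein (1-based inclusive)."""

    accession: str
    start: int
    end: int
    preceding_residue: str | None
    following_residue: str | None
    is_protein_n_terminal: bool
    is_protein_c_terminal: bool
    p1: str
    p1_prime: str


@dataclass
class MappedPeptide:
    """A peptide record plus all accepted placements."""

    record: PeptideRecord
    locations: list[PeptideLocation]

    @property
    def ambiguity_flag(self) -> bool:
        return len(self.locations) > 1


@dataclass
class MappedEntry:
    """One mapped peptide observation with its sample/group context."""

    group_label: str
    sample_id: str
    peptide: MappedPeptide

    @property
    def sequence(self) -> str:
        return self.peptide.record.sequence

    @property
    def spectral_count(self) -> int:
        return self.peptide.record.spectral_count


@dataclass
class MappedDataset:
    db: ProteinDatabase
    entries: list[MappedEntry]
    unmapped: list[tuple[str, str, str]] = field(default_factory=list)  # (group, sample, seq)
    warnings: list[str] = field(default_factory=list)

    def for_group(self, group_label: str | None) -> list[MappedEntry]:
        if group_label is None:
            return self.entries
        return [e for e in self.entries if e.group_label == group_label]

    def mapping_rate(self) -> float:
        total = len(self.entries) + len(self.unmapped)
        return len(self.entries) / total if total else float("nan")


def locate_peptide(
    sequence: str,
    accession: str,
    protein_sequence: str,
    met_tolerant: bool = True,
) -> list[PeptideLocation]:
    """Every occurrence of ``sequence`` in ``protein_sequence``.

    Overlapping occurrences are all reported. Returns an empty list when the
    peptide is absent.
    """
    out: list[PeptideLocation] = []
    L = len(protein_sequence)
    n = len(sequence)
    pos = protein_sequence.find(sequence)
    while pos != -1:
        start = pos + 1  # 1-based
        end = pos + n
        n_term = start == 1 or (
            met_tolerant and start == 2 and protein_sequence[0] == "M"
        )
        c_term = end == L
        out.append(
            PeptideLocation(
                accession=accession,
                start=start,
                end=end,
                preceding_residue=protein_sequence[pos - 1] if pos > 0 else None,
                following_residue=protein_sequence[end] if end < L else None,
                is_protein_n_terminal=n_term,
                is_protein_c_terminal=c_term,
                p1=sequence[-1],
                p1_prime=sequence[0],
            )
        )
        pos = protein_sequence.find(sequence, pos + 1)
    return out


def _locate_in_db(
    sequence: str,
    db: ProteinDatabase,
    accessions: Iterable[str],
    met_tolerant: bool,
) -> list[PeptideLocation]:
    locs: list[PeptideLocation] = []
    for acc in accessions:
        locs.extend(locate_peptide(sequence, acc, db.sequence(acc), met_tolerant))
    return locs


def map_dataset(
    ds: GroupedDataset,
    db: ProteinDatabase,
    policy: AmbiguityPolicy = "declared_then_all",
    met_tolerant: bool = True,
) -> MappedDataset:
    """Map every record of a grouped dataset into the protein database.

    Policies: ``all_locations`` searches every database protein;
    ``first_accession`` keeps locations from the first accession (declared
    order, else database order) that contains the peptide;
    ``declared_accession_only`` restricts the search to the record's own
    accessions field; ``declared_then_all`` (default) uses the declared
    accessions when present and falls back to a whole-database search.
    Unmapped peptides are retained in ``unmapped``.
    """
    mapped = MappedDataset(db=db, entries=[])
    all_accs = db.accessions()
    for group_label, tables in ds.groups.items():
        for table in tables:
            for rec in table.records:
                declared = [a for a in rec.accessions if a in db]
                for a in rec.accessions:
                    if a not in db:
                        mapped.warnings.append(
                            f"{table.sample_id}/{rec.sequence}: accession {a!r} not in database"
                        )
                if policy == "declared_accession_only":
                    search: list[str] = declared
                elif policy == "declared_then_all":
                    search = declared if declared else all_accs
                else:  # all_locations, first_accession
                    search = (declared + [a for a in all_accs if a not in declared]
                              if policy == "first_accession" and declared else all_accs)

                if policy == "first_accession":
                    locs = []
                    for acc in search:
                        locs = locate_peptide(rec.sequence, acc, db.sequence(acc), met_tolerant)
                        if locs:
                            break
                else:
                    locs = _locate_in_db(rec.sequence, db, search, met_tolerant)

                if locs:
                    mapped.entries.append(
                        MappedEntry(group_label, table.sample_id, MappedPeptide(rec, locs))
                    )
                else:
                    mapped.unmapped.append((group_label, table.sample_id, rec.sequence))
    return mapped


@dataclass(frozen=True)
class CleavageRecord:
    """Per-peptide cleavage-site usability and residues.

    A residue is usable when no placement of the peptide puts the
    corresponding end at a protein-inherent terminus; an ambiguous peptide
    contributes its residues once, not once per location.
    """

    group_label: str
    sample_id: str
    sequence: str
    spectral_count: int
    p1_usable: bool
    p1_prime_usable: bool
    p1: str
    p1_prime: str


def cleavage_site_records(mapped: MappedDataset) -> list[CleavageRecord]:
    """Derive P1/P1' usability from terminus flags of every mapped peptide.

    P1 (the peptide's last residue) is usable iff no location is
    protein-C-terminal; P1' (first residue) iff no location is
    protein-N-terminal (under the Met policy applied at mapping time).
    Unmapped peptides are excluded (they are listed in ``mapped.unmapped``).
    """
    out: list[CleavageRecord] = []
    for e in mapped.entries:
        locs = e.peptide.locations
        out.append(
            CleavageRecord(
                group_label=e.group_label,
                sample_id=e.sample_id,
                sequence=e.sequence,
                spectral_count=e.spectral_count,
                p1_usable=not any(l.is_protein_c_terminal for l in locs),
                p1_prime_usable=not any(l.is_protein_n_terminal for l in locs),
                p1=e.sequence[-1],
                p1_prime=e.sequence[0],
            )
        )
    return out


def export_mapped(mapped: MappedDataset, path: str | Path) -> pd.DataFrame:
    """Write the mapped dataset as delimited text (one row per location)."""
    rows = []
    for e in mapped.entries:
        for loc in e.peptide.locations:
            rows.append(
                {
                    "sequence": e.sequence,
                    "sample": e.sample_id,
                    "group": e.group_label,
                    "spectral_count": e.spectral_count,
                    "accession": loc.accession,
                    "start": loc.start,
                    "end": loc.end,
                    "preceding": loc.preceding_residue or "",
                    "following": loc.following_residue or "",
                    "n_term_flag": loc.is_protein_n_terminal,
                    "c_term_flag": loc.is_protein_c_terminal,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
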