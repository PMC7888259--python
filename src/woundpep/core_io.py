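"""Data model and I/O for label-free peptidome datasets.

The central objects are per-sample tables of endogenous peptides with
spectral counts (the number of fragmentation spectra matched to a peptide,
used throughout as a semi-quantitative abundance proxy), grouped into a
labeled study design, plus the protein sequence database used to localize
peptides in their parent proteins.

Peptide tables are delimited text (tab or comma, auto-detected) or xlsx,
with a column-name mapping (:class:`TableDialect`) translating arbitrary
export headers to the canonical ``sequence`` / ``spectral_count`` /
``accessions`` columns. Replicate injections of the same sample are
concatenated by summing per-sequence spectral counts, and a spectral-count
cutoff (default >= 4) removes low-evidence identifications.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pyteomics import mass as _pmass

logger = logging.getLogger(__name__)

#: The 20 proteinogenic amino acids (one-letter codes).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

#: Ambiguous/rare codes tolerated in protein databases (flagged, not fatal).
AMBIGUOUS_RESIDUES = frozenset("XBZU")

DEFAULT_SPECTRAL_CUTOFF = 4

_MOD_PATTERN = re.compile(r"\([^)]*\)|\[[^\]]*\]")
_NON_RESIDUE = re.compile(r"[^A-Za-z]")


class PeptideTableError(ValueError):
    """Malformed peptide table (missing column, bad spectral count, ...)."""


class FastaError(ValueError):
    """Malformed protein database (duplicate accession, empty sequence)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideRecord:
    """One observed peptide in one sample.

    Parameters
    ----------
    sequence
        Uppercase amino-acid string over the 20-letter alphabet.
    spectral_count
        Non-negative number of matched MS/MS spectra.
    accessions
        Parent protein accession(s) as assigned by the search engine;
        may be empty before mapping.
    sample_id
        Sample the observation belongs to.
    """

    sequence: str
    spectral_count: int
    accessions: tuple[str, ...] = ()
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"sequence {self.sequence!r} contains non-standard residues {sorted(bad)}"
            )
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be >= 0")


@dataclass
class SampleTable:
    """All peptides observed in one sample; sequences are unique."""

    sample_id: str
    group_label: str = ""
    records: list[PeptideRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seqs = [r.sequence for r in self.records]
        if len(seqs) != len(set(seqs)):
            raise ValueError(f"duplicate sequences in sample {self.sample_id!r}")
        for r in self.records:
            if r.sample_id and r.sample_id != self.sample_id:
                raise ValueError(
                    f"record sample_id {r.sample_id!r} != table {self.sample_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> dict[str, int]:
        """Mapping sequence -> spectral count."""
        return {r.sequence: r.spectral_count for r in self.records}

    def sequences(self) -> set[str]:
        return {r.sequence for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [r.sequence for r in self.records],
                "spectral_count": [r.spectral_count for r in self.records],
                "accessions": [";".join(r.accessions) for r in self.records],
            }
        )

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        counts: Mapping[str, int],
        group_label: str = "",
        accessions: Mapping[str, Sequence[str]] | None = None,
    ) -> "SampleTable":
        recs = [
            PeptideRecord(
                sequence=s,
                spectral_count=int(c),
                accessions=tuple((accessions or {}).get(s, ())),
                sample_id=sample_id,
            )
            for s, c in counts.items()
        ]
        return cls(sample_id=sample_id, group_label=group_label, records=recs)


@dataclass
class GroupedDataset:
    """The full study design: group label -> list of sample tables."""

    groups: dict[str, list[SampleTable]]

    def __post_init__(self) -> None:
        ids: list[str] = []
        for label, tables in self.groups.items():
            for t in tables:
                ids.append(t.sample_id)
                if t.group_label and t.group_label != label:
                    raise ValueError(
                        f"table {t.sample_id!r} carries group {t.group_label!r} "
                        f"but is filed under {label!r}"
                    )
        if len(ids) != len(set(ids)):
            raise ValueError("sample_ids must be unique across the dataset")

    def all_tables(self) -> list[SampleTable]:
        return [t for tables in self.groups.values() for t in tables]

    def sample_groups(self) -> dict[str, str]:
        return {t.sample_id: g for g, ts in self.groups.items() for t in ts}

    def map_tables(self, fn) -> "GroupedDataset":
        return GroupedDataset(
            {g: [fn(t) for t in ts] for g, ts in self.groups.items()}
        )


@dataclass
class ProteinDatabase:
    """Accession -> (description, sequence); positions 1-based inclusive."""

    entries: dict[str, tuple[str, str]]
    ambiguous_accessions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for acc, (_, seq) in self.entries.items():
            if not seq:
                raise FastaError(f"empty sequence for {acc!r}")
            extra = set(seq) - _AA_SET
            if extra - AMBIGUOUS_RESIDUES:
                raise FastaError(
                    f"{acc!r} contains invalid residues {sorted(extra - AMBIGUOUS_RESIDUES)}"
                )
            if extra:
                self.ambiguous_accessions.add(acc)
                logger.warning("protein %s contains ambiguous residues %s", acc, sorted(extra))

    def __contains__(self, accession: str) -> bool:
        return accession in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def sequence(self, accession: str) -> str:
        return self.entries[accession][1]

    def accessions(self) -> list[str]:
        return list(self.entries)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping from a source export to the canonical schema."""

    sequence: str = "sequence"
    spectral_count: str = "spectral_count"
    accessions: str | None = "accessions"


#: PEAKS-style export columns ("Peptide", "#Spec", "Accession").
PEAKS_DIALECT = TableDialect(sequence="Peptide", spectral_count="#Spec", accessions="Accession")


def _strip_modifications(raw: str) -> tuple[str, bool]:
    """Remove bracketed/parenthesized modification annotations.

    Returns the clean uppercase sequence and whether anything was removed.
    """
    clean = _MOD_PATTERN.sub("", raw)
    clean = _NON_RESIDUE.sub("", clean).upper()
    return clean, clean != raw.strip().upper()


def _read_raw_frame(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path)
    # sniff tab vs comma on the header line
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_peptide_table(
    path: str | Path,
    dialect: TableDialect = TableDialect(),
    sample_id: str | None = None,
    group_label: str = "",
) -> SampleTable:
    """Read one peptide identification table into a :class:`SampleTable`.

    Rows sharing a sequence are merged by summing their spectral counts;
    modification annotations in parentheses/brackets are stripped from
    sequences and the stripping is recorded in ``table.meta['stripped']``.
    """
    path = Path(path)
    df = _read_raw_frame(path)
    if dialect.sequence not in df.columns:
        raise PeptideTableError(f"missing sequence column {dialect.sequence!r} in {path.name}")
    if dialect.spectral_count not in df.columns:
        raise PeptideTableError(
            f"missing spectral count column {dialect.spectral_count!r} in {path.name}"
        )
    sid = sample_id if sample_id is not None else path.stem

    merged: dict[str, int] = {}
    accs: dict[str, list[str]] = {}
    stripped: list[dict] = []
    for idx, row in df.iterrows():
        raw_seq = str(row[dialect.sequence])
        seq, was_stripped = _strip_modifications(raw_seq)
        if not seq:
            raise PeptideTableError(f"row {idx}: empty sequence after stripping {raw_seq!r}")
        try:
            count_f = float(row[dialect.spectral_count])
            if math.isnan(count_f):
                raise ValueError
            count = int(round(count_f))
        except (TypeError, ValueError):
            raise PeptideTableError(
                f"row {idx}: non-numeric spectral count {row[dialect.spectral_count]!r}"
            ) from None
        if was_stripped:
            stripped.append({"row": int(idx), "raw": raw_seq, "clean": seq})
            logger.info("stripped modification annotations: %r -> %s", raw_seq, seq)
        merged[seq] = merged.get(seq, 0) + count
        if dialect.accessions and dialect.accessions in df.columns:
            val = row[dialect.accessions]
            if isinstance(val, str) and val.strip():
                lst = accs.setdefault(seq, [])
                for a in val.split(";"):
                    a = a.strip()
                    if a and a not in lst:
                        lst.append(a)

    table = SampleTable.from_counts(sid, merged, group_label=group_label, accessions=accs)
    table.meta["stripped"] = stripped
    table.meta["source"] = str(path)
    return table


def write_peptide_table(table: SampleTable, path: str | Path) -> None:
    """Write a sample table as tab-delimited text (round-trip exact)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> ProteinDatabase:
    """Load a protein FASTA; accession = first whitespace token of the header.

    Duplicate accessions and empty sequences are rejected.
    """
    from Bio import SeqIO

    entries: dict[str, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in entries:
            raise FastaError(f"duplicate accession {acc!r} in {path}")
        desc = rec.description[len(rec.id):].strip()
        entries[acc] = (desc, str(rec.seq).upper())
    return ProteinDatabase(entries)


def write_fasta(db: ProteinDatabase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for acc, (desc, seq) in db.entries.items():
            header = f">{acc} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> list[dict]:
    """Read a YAML manifest declaring sample -> group -> replicate files.

    Format::

        samples:
          - sample_id: p1
            group: infected
            files: [p1_rep1.tsv, p1_rep2.tsv]
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "samples" not in doc:
        raise PeptideTableError("manifest must contain a top-level 'samples' list")
    out = []
    for entry in doc["samples"]:
        out.append(
            {
                "sample_id": str(entry["sample_id"]),
                "group": str(entry["group"]),
                "files": [str(f) for f in entry["files"]],
            }
        )
    return out


def load_grouped_dataset(
    manifest_path: str | Path,
    dialect: TableDialect = TableDialect(),
    base_dir: str | Path | None = None,
) -> GroupedDataset:
    """Load every sample named in a manifest, concatenating its replicates."""
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    groups: dict[str, list[SampleTable]] = {}
    for entry in read_manifest(manifest_path):
        reps = [
            read_peptide_table(base / f, dialect, sample_id=entry["sample_id"],
                               group_label=entry["group"])
            for f in entry["files"]
        ]
        groups.setdefault(entry["group"], []).append(concatenate_replicates(reps))
    return GroupedDataset(groups)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------


def concatenate_replicates(tables: Sequence[SampleTable]) -> SampleTable:
    """Merge replicate injections of one sample, summing per-sequence counts."""
    if not tables:
        raise ValueError("no tables to concatenate")
    sids = {t.sample_id for t in tables}
    if len(sids) != 1:
        raise ValueError(f"mixed sample_ids in replicates: {sorted(sids)}")
    merged: dict[str, int] = {}
    accs: dict[str, list[str]] = {}
    for t in tables:
        for r in t.records:
            merged[r.sequence] = merged.get(r.sequence, 0) + r.spectral_count
            if r.accessions:
                lst = accs.setdefault(r.sequence, [])
                for a in r.accessions:
                    if a not in lst:
                        lst.append(a)
    out = SampleTable.from_counts(
        tables[0].sample_id, merged, group_label=tables[0].group_label, accessions=accs
    )
    out.meta["n_replicates"] = len(tables)
    return out


def apply_spectral_cutoff(
    table: SampleTable, min_count: int = DEFAULT_SPECTRAL_CUTOFF
) -> SampleTable:
    """Retain records with spectral_count >= min_count (input unmodified)."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    kept = [r for r in table.records if r.spectral_count >= min_count]
    out = SampleTable(
        sample_id=table.sample_id, group_label=table.group_label, records=list(kept)
    )
    out.meta = dict(table.meta)
    out.meta["spectral_cutoff"] = min_count
    return out


def total_spectral_count(table: SampleTable) -> int:
    """Sum of spectral counts over all records (0 for an empty table)."""
    return sum(r.spectral_count for r in table.records)


def peptide_monoisotopic_mass(sequence: str) -> float:
    """Monoisotopic mass in Da (residue masses + water)."""
    return float(_pmass.fast_mass(sequence))


def summarize_dataset(
    ds: GroupedDataset, cutoff: int = DEFAULT_SPECTRAL_CUTOFF
) -> pd.DataFrame:
    """Per-group general characteristics of the peptidomes.

    For each group: mean +/- sd (ddof=1) of unique-peptide counts before and
    after the spectral cutoff, unweighted mean peptide length, mean
    monoisotopic mass (Da), and the mean per-sample fraction of peptides at
    or above the cutoff. Empty groups yield explicit null statistics.
    """
    rows = []
    for label, tables in ds.groups.items():
        if not tables:
            rows.append({"group": label, "n_samples": 0})
            continue
        before = [len(t) for t in tables]
        after = [len(apply_spectral_cutoff(t, cutoff)) for t in tables]
        lengths = [
            float(np.mean([len(r.sequence) for r in t.records])) if len(t) else np.nan
            for t in tables
        ]
        masses = [
            float(np.mean([peptide_monoisotopic_mass(r.sequence) for r in t.records]))
            if len(t)
            else np.nan
            for t in tables
        ]
        frac = [a / b if b else np.nan for a, b in zip(after, before)]

        def _sd(v):
            return float(np.std(v, ddof=1)) if len(v) > 1 else np.nan

        rows.append(
            {
                "group": label,
                "n_samples": len(tables),
                "peptides_before_mean": float(np.mean(before)),
                "peptides_before_sd": _sd(before),
                "peptides_after_mean": float(np.mean(after)),
                "peptides_after_sd": _sd(after),
                "mean_length": float(np.nanmean(lengths)),
                "mean_mass_da": float(np.nanmean(masses)),
                "fraction_above_cutoff": float(np.nanmean(frac)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def run_summary_json(ds: GroupedDataset, cutoff: int, path: str | Path) -> None:
    """Write a JSON run summary: parameters, counts, stripped annotations."""
    stripped = []
    for t in ds.all_tables():
        for entry in t.meta.get("stripped", []):
            stripped.append({"sample_id": t.sample_id, **entry})
    doc = {
        "spectral_cutoff": cutoff,
        "groups": {
            g: {
                "n_samples": len(ts),
                "samples": {t.sample_id: len(t) for t in ts},
            }
            for g, ts in ds.groups.items()
        },
        "stripped_annotations": stripped,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
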