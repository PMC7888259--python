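"""Antimicrobial scoring, protein coverage profiles and region analyses.

Antimicrobial propensity comes from per-peptide prediction scores in
[0, 1] — normally loaded from an external predictor's output, otherwise
from a built-in logistic stand-in over net charge and hydrophobic fraction
(a deliberately simple, versioned composition heuristic; it is *not* a
reimplementation of any published predictor and its absolute values carry
no biological meaning). The antimicrobial score of a peptide in a sample
is prediction x spectral count; peptides below the prediction cutoff
(default 0.7, kept at >= 0.7) are dropped, as are peptides longer than 30
residues (the domain limit of short-AMP predictors).

Coverage profiles give, per residue of a parent protein, the number of
distinct peptides covering it and the summed spectral count — the data
behind peptide-alignment-map visualizations. Region sums
confine spectral counting to a stated protein region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GroupedDataset, ProteinDatabase
from .mapping import MappedDataset

DEFAULT_AMP_CUTOFF = 0.7
#: Short-AMP predictors are trained on peptides below ~30 residues.
MAX_SCOREABLE_LENGTH = 30


@dataclass(frozen=True)
class AMPPrediction:
    sequence: str
    prediction: float
    source: Literal["external_file", "builtin_heuristic"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.prediction <= 1.0:
            raise ValueError(f"prediction {self.prediction} outside [0, 1]")


class PredictionFileError(ValueError):
    """Malformed antimicrobial prediction file."""


def load_amp_predictions(path: str | Path) -> dict[str, AMPPrediction]:
    """Load per-peptide prediction scores from delimited text.

    Requires ``sequence`` and ``score`` columns (tab or comma). Scores must
    lie in [0, 1]; duplicated sequences must agree to 1e-9.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("sequence", "score"):
        if col not in df.columns:
            raise PredictionFileError(f"missing column {col!r} in {path.name}")
    out: dict[str, AMPPrediction] = {}
    for idx, row in df.iterrows():
        seq = str(row["sequence"]).upper()
        try:
            score = float(row["score"])
        except (TypeError, ValueError):
            raise PredictionFileError(f"row {idx}: non-numeric score {row['score']!r}") from None
        if not 0.0 <= score <= 1.0:
            raise PredictionFileError(f"row {idx}: score {score} outside [0, 1]")
        if seq in out:
            if abs(out[seq].prediction - score) > 1e-9:
                raise PredictionFileError(
                    f"row {idx}: conflicting scores for {seq} "
                    f"({out[seq].prediction} vs {score})"
                )
            continue
        out[seq] = AMPPrediction(seq, score, "external_file")
    return out


def builtin_amp_score(sequence: str) -> float:
    """Deterministic composition-based antimicrobial propensity in (0, 1).

    z = (#K + #R + 0.5*#H) - (#D + #E)  (approximate net charge),
    h = hydrophobic fraction over {A, I, L, M, F, W, V, C},
    score = logistic(0.5*z + 4*h - 3).

    A frozen plumbing heuristic so the scoring pipeline runs without an
    external predictor; cationic/hydrophobic peptides score high, acidic
    ones low.
    """
    if not sequence:
        raise ValueError("empty sequence")
    z = (
        sequence.count("K")
        + sequence.count("R")
        + 0.5 * sequence.count("H")
        - sequence.count("D")
        - sequence.count("E")
    )
    h = sum(1 for r in sequence if r in "AILMFWVC") / len(sequence)
    return 1.0 / (1.0 + math.exp(-(0.5 * z + 4.0 * h - 3.0)))


@dataclass
class AMPScoreResult:
    """Outputs of the antimicrobial scoring step."""

    score_matrix: pd.DataFrame  # surviving peptides x samples, prediction*count
    predictions: dict[str, float]  # surviving sequences -> prediction
    group_totals: dict[str, int]  # summed spectral counts of surviving peptides
    substrate_pies: dict[str, pd.Series] | None  # per group, if mapped supplied
    excluded_long: list[str]
    missing_predictions: list[str]
    cutoff: float


def antimicrobial_scores(
    ds: GroupedDataset,
    predictions: Mapping[str, AMPPrediction] | None = None,
    cutoff: float = DEFAULT_AMP_CUTOFF,
    mapped: MappedDataset | None = None,
    top_n: int = 10,
) -> AMPScoreResult:
    """Score every peptide and tabulate the predicted antimicrobial milieu.

    Peptides with prediction >= cutoff are kept; the heatmap-ready matrix
    holds prediction x per-sample spectral count. Group totals sum the
    surviving peptides' spectral counts (not the products). Peptides longer
    than 30 residues are excluded and reported; with an external prediction
    table, scoreable sequences lacking a prediction are reported, not fatal.
    With a mapped dataset, per-group substrate pies sum surviving peptides'
    counts per parent protein.
    """
    sample_order = [t.sample_id for t in ds.all_tables()]
    all_seqs = sorted({r.sequence for t in ds.all_tables() for r in t.records})
    excluded_long = [s for s in all_seqs if len(s) > MAX_SCOREABLE_LENGTH]
    missing: list[str] = []
    pred_of: dict[str, float] = {}
    for s in all_seqs:
        if len(s) > MAX_SCOREABLE_LENGTH:
            continue
        if predictions is None:
            pred_of[s] = builtin_amp_score(s)
        elif s in predictions:
            pred_of[s] = predictions[s].prediction
        else:
            missing.append(s)

    surviving = {s: p for s, p in pred_of.items() if p >= cutoff}

    matrix = pd.DataFrame(0.0, index=sorted(surviving), columns=sample_order)
    group_totals: dict[str, int] = {g: 0 for g in ds.groups}
    for g, tables in ds.groups.items():
        for t in tables:
            for r in t.records:
                if r.sequence in surviving:
                    matrix.loc[r.sequence, t.sample_id] = (
                        surviving[r.sequence] * r.spectral_count
                    )
                    group_totals[g] += r.spectral_count

    pies: dict[str, pd.Series] | None = None
    if mapped is not None:
        pies = {}
        for g in ds.groups:
            totals: dict[str, int] = {}
            for e in mapped.for_group(g):
                if e.sequence not in surviving:
                    continue
                for acc in sorted({l.accession for l in e.peptide.locations}):
                    totals[acc] = totals.get(acc, 0) + e.spectral_count
            ser = pd.Series(totals, dtype=float)
            ser = ser.sort_index(kind="mergesort").sort_values(
                ascending=False, kind="mergesort"
            )
            top = ser.head(top_n)
            other = float(ser.iloc[top_n:].sum())
            pies[g] = pd.concat([top, pd.Series({"other": other})]) if other > 0 else top

    return AMPScoreResult(
        score_matrix=matrix,
        predictions=surviving,
        group_totals=group_totals,
        substrate_pies=pies,
        excluded_long=excluded_long,
        missing_predictions=missing,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# coverage profiles and regions
# ---------------------------------------------------------------------------


@dataclass
class CoverageProfile:
    """Per-residue peptide count and summed spectral count along a protein."""

    accession: str
    peptide_count: np.ndarray  # distinct peptides covering each position
    spectral_count: np.ndarray  # summed spectral counts over covering peptides

    def __post_init__(self) -> None:
        if len(self.peptide_count) != len(self.spectral_count):
            raise ValueError("coverage arrays must have equal length")


def coverage_profile(
    mapped: MappedDataset, accession: str, group_label: str | None = None
) -> CoverageProfile:
    """Coverage arrays for one protein, over a group or the whole dataset.

    ``peptide_count[p]`` is the number of distinct peptide sequences with a
    location covering position p+1; ``spectral_count[p]`` sums spectral
    counts over all covering observations (each distinct location of a
    peptide observation counted once).
    """
    if accession not in mapped.db:
        raise KeyError(f"accession {accession!r} not in database")
    L = len(mapped.db.sequence(accession))
    pep_cov: dict[str, np.ndarray] = {}
    spec = np.zeros(L, dtype=np.int64)
    for e in mapped.for_group(group_label):
        locs = [l for l in e.peptide.locations if l.accession == accession]
        seen: set[tuple[int, int]] = set()
        for loc in locs:
            if (loc.start, loc.end) in seen:
                continue
            seen.add((loc.start, loc.end))
            spec[loc.start - 1 : loc.end] += e.spectral_count
            mask = pep_cov.setdefault(e.sequence, np.zeros(L, dtype=bool))
            mask[loc.start - 1 : loc.end] = True
    pep = np.zeros(L, dtype=np.int64)
    for mask in pep_cov.values():
        pep += mask
    return CoverageProfile(accession=accession, peptide_count=pep, spectral_count=spec)


def alignment_map(
    mapped: MappedDataset, accession: str
) -> pd.DataFrame:
    """Peptide alignment table for one protein: start/end + per-group mean count."""
    groups = sorted({e.group_label for e in mapped.entries})
    n_samples = {
        g: len({e.sample_id for e in mapped.entries if e.group_label == g}) for g in groups
    }
    per_pep: dict[tuple[str, int, int], dict[str, int]] = {}
    for e in mapped.entries:
        for loc in e.peptide.locations:
            if loc.accession != accession:
                continue
            key = (e.sequence, loc.start, loc.end)
            d = per_pep.setdefault(key, {g: 0 for g in groups})
            d[e.group_label] += e.spectral_count
    rows = []
    for (seq, start, end), totals in sorted(per_pep.items(), key=lambda kv: (kv[0][1], kv[0][2], kv[0][0])):
        row = {"sequence": seq, "start": start, "end": end}
        for g in groups:
            row[f"{g}_mean_count"] = totals[g] / n_samples[g] if n_samples[g] else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegionSpec:
    """A labeled protein region, 1-based inclusive."""

    accession: str
    start: int
    end: int
    label: str = ""
    reference_peptides: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region bounds {self.start}-{self.end}")

    def validate(self, db: ProteinDatabase) -> None:
        if self.accession not in db:
            raise KeyError(f"accession {self.accession!r} not in database")
        if self.end > len(db.sequence(self.accession)):
            raise ValueError(
                f"region {self.label or self.accession} end {self.end} beyond protein "
                f"length {len(db.sequence(self.accession))}"
            )


@dataclass
class RegionSum:
    region: RegionSpec
    mode: Literal["confined", "overlapping"]
    group_totals: dict[str, int]
    exact_totals: dict[str, dict[str, int]]  # reference peptide -> group -> count


def region_spectral_sum(
    mapped: MappedDataset,
    region: RegionSpec,
    mode: Literal["confined", "overlapping"] = "confined",
) -> RegionSum:
    """Summed spectral counts of peptides inside (or overlapping) a region.

    ``confined`` counts peptides with start >= region.start and
    end <= region.end; ``overlapping`` counts any overlap. Exact-match
    totals are reported for each listed reference peptide.
    """
    region.validate(mapped.db)
    groups = sorted({e.group_label for e in mapped.entries})
    group_totals = {g: 0 for g in groups}
    exact = {p: {g: 0 for g in groups} for p in region.reference_peptides}
    for e in mapped.entries:
        hit = False
        for loc in e.peptide.locations:
            if loc.accession != region.accession:
                continue
            if mode == "confined":
                ok = loc.start >= region.start and loc.end <= region.end
            else:
                ok = loc.start <= region.end and loc.end >= region.start
            if ok:
                hit = True
                break
        if hit:
            group_totals[e.group_label] += e.spectral_count
            if e.sequence in exact:
                exact[e.sequence][e.group_label] += e.spectral_count
    return RegionSum(region=region, mode=mode, group_totals=group_totals,
                     exact_totals=exact)


# ---------------------------------------------------------------------------
# literature cross-matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferencePeptide:
    sequence: str
    label: str = ""
    citation: str = ""


def literature_match(
    ds: GroupedDataset, references: Sequence[ReferencePeptide]
) -> pd.DataFrame:
    """Cross-check curated literature peptides against the dataset.

    For each reference sequence: exact matches (with per-group summed
    spectral counts) and containment matches in either direction (a dataset
    peptide containing the reference, or contained in it). Exact-substring
    only; no edit-distance similarity.
    """
    group_counts: dict[str, dict[str, int]] = {}
    for g, tables in ds.groups.items():
        for t in tables:
            for r in t.records:
                d = group_counts.setdefault(r.sequence, {gg: 0 for gg in ds.groups})
                d[g] += r.spectral_count
    rows = []
    for ref in references:
        for seq, counts in sorted(group_counts.items()):
            if seq == ref.sequence:
                match_type = "exact"
            elif ref.sequence in seq:
                match_type = "reference_in_peptide"
            elif seq in ref.sequence:
                match_type = "peptide_in_reference"
            else:
                continue
            row = {
                "reference": ref.sequence,
                "label": ref.label,
                "citation": ref.citation,
                "match_type": match_type,
                "peptide": seq,
            }
            for g in ds.groups:
                row[f"count_{g}"] = counts[g]
            rows.append(row)
    return pd.DataFrame(rows)


def load_reference_list(path: str | Path) -> list[ReferencePeptide]:
    """Read a delimited reference list with columns sequence[, label, citation]."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    if "sequence" not in df.columns:
        raise ValueError("reference list needs a 'sequence' column")
    return [
        ReferencePeptide(
            sequence=str(r["sequence"]).upper(),
            label=str(r.get("label", "") or ""),
            citation=str(r.get("citation", "") or ""),
        )
        for _, r in df.iterrows()
    ]
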