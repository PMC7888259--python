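"""Amino-acid composition and terminal-segment profiles of peptidomes.

Composition profiles are spectral-count-weighted residue frequencies, over
whole peptide sequences or restricted to the P1 / P1' cleavage-site
positions (which require cleavage records, so that protein-inherent termini
are excluded). Residues can be collapsed into side-chain classes (acidic,
basic, polar-uncharged, nonpolar).

Terminal tables aggregate spectral counts over the 4 proximal residues of
either peptide end (the MEROPS tetrapeptide convention); unlike the P1/P1'
profiles, protein-inherent termini are deliberately retained here, because
intact protein termini are themselves of biomarker interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AA_ALPHABET, ProteinDatabase, SampleTable
from .mapping import CleavageRecord

PositionMode = Literal["full", "P1", "P1_prime"]
Weighting = Literal["spectral_count", "unweighted"]

#: Default side-chain classes. H is counted as basic; C and Y as
#: polar-uncharged. Override with any residue -> label mapping.
DEFAULT_GROUPING: dict[str, str] = {
    **{r: "acidic" for r in "DE"},
    **{r: "basic" for r in "KRH"},
    **{r: "polar" for r in "STNQCY"},
    **{r: "nonpolar" for r in "GAVLIPMFW"},
}

_NORM_TOL = 1e-9


@dataclass
class CompositionProfile:
    """Residue -> fraction, with the weighting scheme and total weight used."""

    frequencies: dict[str, float]
    weighting: Weighting
    position_mode: PositionMode
    n_effective: float

    def __post_init__(self) -> None:
        if self.n_effective > 0:
            s = sum(self.frequencies.values())
            if abs(s - 1.0) > _NORM_TOL:
                raise ValueError(f"profile does not normalize: sum={s!r}")

    def as_series(self) -> pd.Series:
        return pd.Series(
            {r: self.frequencies.get(r, 0.0) for r in AA_ALPHABET}, name=self.position_mode
        )


def aa_composition(
    tables: SampleTable | Sequence[SampleTable],
    position_mode: PositionMode = "full",
    cleavage_records: Sequence[CleavageRecord] | None = None,
    weighting: Weighting = "spectral_count",
) -> CompositionProfile:
    """Spectral-count-weighted amino-acid frequency profile.

    In ``full`` mode every residue occurrence contributes the peptide's
    spectral count; in ``P1`` / ``P1_prime`` mode the single cleavage-site
    residue of each usable peptide contributes its spectral count
    (terminus-derived peptide ends are excluded via the cleavage records,
    which are required for these modes).
    """
    if isinstance(tables, SampleTable):
        tables = [tables]
    totals: dict[str, float] = {}

    if position_mode == "full":
        for t in tables:
            for r in t.records:
                w = r.spectral_count if weighting == "spectral_count" else 1
                for res in r.sequence:
                    totals[res] = totals.get(res, 0.0) + w
    else:
        if cleavage_records is None:
            raise ValueError(f"{position_mode} mode requires cleavage records")
        sample_ids = {t.sample_id for t in tables}
        for cr in cleavage_records:
            if cr.sample_id not in sample_ids:
                continue
            usable = cr.p1_usable if position_mode == "P1" else cr.p1_prime_usable
            if not usable:
                continue
            res = cr.p1 if position_mode == "P1" else cr.p1_prime
            w = cr.spectral_count if weighting == "spectral_count" else 1
            totals[res] = totals.get(res, 0.0) + w

    n_eff = float(sum(totals.values()))
    if n_eff == 0:
        import logging

        logging.getLogger(__name__).warning("zero total weight in %s profile", position_mode)
        return CompositionProfile({}, weighting, position_mode, 0.0)
    freqs = {res: v / n_eff for res, v in totals.items()}
    return CompositionProfile(freqs, weighting, position_mode, n_eff)


def group_composition(
    profile: CompositionProfile, grouping: Mapping[str, str] = DEFAULT_GROUPING
) -> dict[str, float]:
    """Collapse a residue profile into side-chain-class fractions."""
    out: dict[str, float] = {}
    for res, frac in profile.frequencies.items():
        if res not in grouping:
            raise ValueError(f"residue {res!r} missing from the side-chain grouping")
        out[grouping[res]] = out.get(grouping[res], 0.0) + frac
    return out


def reference_composition(
    source: ProteinDatabase | None = None,
) -> CompositionProfile:
    """Reference residue frequencies for comparison against peptidome profiles.

    With a :class:`ProteinDatabase`, computes unweighted frequencies over all
    of its sequences; with ``source=None``, loads the bundled published
    UniProtKB/Swiss-Prot composition table.
    """
    if source is None:
        with resources.files("woundpep.data").joinpath("swissprot_aa_freq.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#")
        vals = dict(zip(df["residue"], df["percent"].astype(float)))
        total = sum(vals.values())
        freqs = {r: v / total for r, v in vals.items()}
        return CompositionProfile(freqs, "unweighted", "full", total)
    if len(source) == 0:
        raise ValueError("empty protein database")
    counts: dict[str, float] = {}
    for acc in source.accessions():
        for res in source.sequence(acc):
            if res in AA_ALPHABET:
                counts[res] = counts.get(res, 0.0) + 1
    n = float(sum(counts.values()))
    return CompositionProfile({r: c / n for r, c in counts.items()}, "unweighted", "full", n)


# ---------------------------------------------------------------------------
# terminal tables
# ---------------------------------------------------------------------------


@dataclass
class TerminalTable:
    """Aggregated spectral counts of unique terminal k-mers.

    ``counts`` is a k-mer x sample DataFrame of aggregated spectral counts;
    ``sample_groups`` maps each sample column to its group label;
    ``n_excluded`` counts peptides shorter than k (excluded, not padded).
    """

    end: Literal["N", "C"]
    k: int
    counts: pd.DataFrame
    sample_groups: dict[str, str]
    n_excluded: int = 0

    def totals(self) -> pd.Series:
        """Pooled aggregated count per terminal, over all samples."""
        return self.counts.sum(axis=1)

    def group_stats(self) -> pd.DataFrame:
        """Per-group mean +/- sd (ddof=1) of per-sample aggregated counts."""
        cols: dict[tuple[str, str], pd.Series] = {}
        groups = sorted(set(self.sample_groups.values()))
        for g in groups:
            samples = [s for s, gg in self.sample_groups.items() if gg == g]
            sub = self.counts[samples]
            cols[(g, "mean")] = sub.mean(axis=1)
            cols[(g, "sd")] = sub.std(axis=1, ddof=1)
        return pd.DataFrame(cols)


def terminal_table(
    tables: SampleTable | Sequence[SampleTable],
    end: Literal["N", "C"] = "C",
    k: int = 4,
) -> TerminalTable:
    """Aggregate spectral counts over unique terminal k-mers (default 4)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(tables, SampleTable):
        tables = [tables]
    data: dict[str, dict[str, int]] = {}
    excluded = 0
    sample_groups: dict[str, str] = {}
    for t in tables:
        sample_groups[t.sample_id] = t.group_label
        col = data.setdefault(t.sample_id, {})
        for r in t.records:
            if len(r.sequence) < k:
                excluded += 1
                continue
            kmer = r.sequence[:k] if end == "N" else r.sequence[-k:]
            col[kmer] = col.get(kmer, 0) + r.spectral_count
    counts = pd.DataFrame(data).fillna(0).astype(int)
    counts = counts.reindex(columns=[t.sample_id for t in tables])
    counts = counts.sort_index()
    return TerminalTable(end=end, k=k, counts=counts, sample_groups=sample_groups,
                         n_excluded=excluded)


def grouped_terminal_table(
    tt: TerminalTable, grouping: Mapping[str, str] = DEFAULT_GROUPING
) -> TerminalTable:
    """Translate each terminal k-mer residue-wise into its side-chain classes.

    E.g. ``HKYH -> basic-basic-polar-basic`` under the default grouping;
    counts are aggregated over identical class strings.
    """

    def translate(kmer: str) -> str:
        parts = []
        for res in kmer:
            if res not in grouping:
                raise ValueError(f"residue {res!r} missing from the side-chain grouping")
            parts.append(grouping[res])
        return "-".join(parts)

    counts = tt.counts.groupby(translate).sum().sort_index()
    return TerminalTable(end=tt.end, k=tt.k, counts=counts,
                         sample_groups=dict(tt.sample_groups), n_excluded=tt.n_excluded)


def rank_abundance(
    tt: TerminalTable, per_group: bool = False, top_n: int | None = None
) -> pd.DataFrame:
    """Terminals sorted by descending aggregated count, with a rank index.

    Ties are broken lexicographically by terminal sequence so the ordering
    is deterministic. With ``per_group``, per-group mean +/- sd columns are
    attached (sorted by pooled total).
    """
    totals = tt.totals()
    df = totals.rename("total").reset_index()
    df.columns = ["terminal", "total"]
    df = df.sort_values(["total", "terminal"], ascending=[False, True], kind="mergesort")
    df["rank"] = range(1, len(df) + 1)
    if per_group:
        stats = tt.group_stats()
        stats.columns = [f"{g}_{stat}" for g, stat in stats.columns]
        df = df.merge(stats, left_on="terminal", right_index=True, how="left")
    if top_n is not None:
        df = df.head(top_n)
    return df.reset_index(drop=True)
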