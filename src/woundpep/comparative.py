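"""Between-sample and between-group comparisons of peptidomes.

Covers: exact Venn region partitions for 2-5 named sequence sets;
intersectional peptides (present in every sample of a group);
top-k differential peptides between two groups by absolute spectral-count
difference; protein-substrate abundance ("top 10 + other" pie data);
occurrence-based outlier flagging; Student/Welch t comparisons; and a
deliberately simple rule-based protease attribution over P1 (and optional
P1') residue specificities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core_io import SampleTable
from .mapping import MappedDataset


# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------


@dataclass
class VennCounts:
    """Exact region partition of up to five named sequence sets.

    ``region_counts`` maps each non-empty subset of set labels (a frozenset)
    to the number of sequences found in exactly those sets; the counts sum
    to the size of the union.
    """

    set_labels: list[str]
    region_counts: dict[frozenset, int]

    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(labels)), "n_sets": len(labels), "count": c}
            for labels, c in sorted(
                self.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows)


def venn_counts(sets: Mapping[str, Iterable[str]]) -> VennCounts:
    """Partition 2-5 named peptide-sequence sets into exact Venn regions."""
    labels = list(sets)
    if not 2 <= len(labels) <= 5:
        raise ValueError("venn_counts requires between 2 and 5 sets")
    material = {lab: set(s) for lab, s in sets.items()}
    regions: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = frozenset(combo)
            exact = set.intersection(*(material[l] for l in combo))
            for other in labels:
                if other not in inside:
                    exact -= material[other]
            regions[inside] = len(exact)
    return VennCounts(set_labels=labels, region_counts=regions)


def intersectional_peptides(samples: Sequence[SampleTable]) -> set[str]:
    """Sequences present in every sample of a group."""
    if not samples:
        raise ValueError("need at least one sample")
    out = samples[0].sequences()
    for t in samples[1:]:
        out &= t.sequences()
    return out


# ---------------------------------------------------------------------------
# differential peptides
# ---------------------------------------------------------------------------


@dataclass
class DifferentialPeptide:
    sequence: str
    counts_a: dict[str, int]
    counts_b: dict[str, int]
    total_a: int
    total_b: int
    difference: float
    rank: int = 0


def differential_peptides(
    group_a: Sequence[SampleTable],
    group_b: Sequence[SampleTable],
    k: int = 50,
    agg: str = "sum",
) -> list[DifferentialPeptide]:
    """Top-k peptides by absolute spectral-count difference between groups.

    The candidate pool is the union of both groups' intersectional sets;
    the difference is (aggregate in A) - (aggregate in B), where a peptide
    absent from a group contributes 0. ``agg`` is ``sum`` (default) or
    ``mean`` over per-sample counts. Ties in |difference| are broken
    lexicographically by sequence.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not group_a and not group_b:
        return []
    pool: set[str] = set()
    if group_a:
        pool |= intersectional_peptides(group_a)
    if group_b:
        pool |= intersectional_peptides(group_b)

    def agg_fn(values: list[int]) -> float:
        if agg == "sum":
            return float(sum(values))
        if agg == "mean":
            return float(np.mean(values)) if values else 0.0
        raise ValueError(f"unknown aggregation {agg!r}")

    out = []
    for seq in pool:
        ca = {t.sample_id: t.counts().get(seq, 0) for t in group_a}
        cb = {t.sample_id: t.counts().get(seq, 0) for t in group_b}
        ta = agg_fn([c for c in ca.values() if True])
        tb = agg_fn([c for c in cb.values() if True])
        out.append(
            DifferentialPeptide(
                sequence=seq, counts_a=ca, counts_b=cb,
                total_a=int(sum(ca.values())), total_b=int(sum(cb.values())),
                difference=ta - tb,
            )
        )
    out.sort(key=lambda d: (-abs(d.difference), d.sequence))
    out = out[:k]
    for i, d in enumerate(out, start=1):
        d.rank = i
    return out


def protease_ready_table(
    diffs: Sequence[DifferentialPeptide], mapped: MappedDataset
) -> pd.DataFrame:
    """Format differential peptides for protease-prediction tools.

    One row per (sequence, location): sequence, accession, start, end.
    """
    locs_by_seq: dict[str, list] = {}
    for e in mapped.entries:
        locs_by_seq.setdefault(e.sequence, [])
        for loc in e.peptide.locations:
            key = (loc.accession, loc.start, loc.end)
            if key not in [(l.accession, l.start, l.end) for l in locs_by_seq[e.sequence]]:
                locs_by_seq[e.sequence].append(loc)
    rows = []
    for d in diffs:
        for loc in locs_by_seq.get(d.sequence, []):
            rows.append(
                {
                    "sequence": d.sequence,
                    "accession": loc.accession,
                    "start": loc.start,
                    "end": loc.end,
                    "difference": d.difference,
                    "rank": d.rank,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# substrate abundance & outliers
# ---------------------------------------------------------------------------


@dataclass
class SubstrateAbundance:
    totals: pd.Series  # per-accession summed spectral count, descending
    pie_data: pd.Series  # top-n + "other"
    n_proteins: int  # proteins with >= 1 peptide
    double_counted_mass: int  # extra counts introduced by multi-protein peptides


def protein_substrate_abundance(
    mapped: MappedDataset,
    group_label: str | None = None,
    exclude_accessions: Sequence[str] = (),
    top_n: int = 10,
) -> SubstrateAbundance:
    """Cumulative spectral count per parent protein, ranked, plus pie data.

    A peptide mapping to several proteins contributes its full spectral
    count to each distinct accession (the double-counted mass is reported).
    ``exclude_accessions`` are removed before ranking (e.g. to discard
    dominating hemoglobin subunits).
    """
    excl = set(exclude_accessions)
    totals: dict[str, int] = {}
    double = 0
    for e in mapped.for_group(group_label):
        accs = sorted({l.accession for l in e.peptide.locations})
        double += e.spectral_count * max(0, len(accs) - 1)
        for acc in accs:
            totals[acc] = totals.get(acc, 0) + e.spectral_count
    n_proteins = len(totals)
    for acc in excl:
        totals.pop(acc, None)
    ser = pd.Series(totals, dtype=float).sort_values(ascending=False)
    ser = ser.sort_index(kind="mergesort").sort_values(ascending=False, kind="mergesort")
    top = ser.head(top_n)
    other = float(ser.iloc[top_n:].sum())
    pie = pd.concat([top, pd.Series({"other": other})]) if other > 0 else top
    return SubstrateAbundance(totals=ser, pie_data=pie, n_proteins=n_proteins,
                              double_counted_mass=double)


def occurrence_outliers(
    group: Sequence[SampleTable], count_quantile: float = 0.95
) -> pd.DataFrame:
    """Per-sequence summed count vs. number of samples containing it.

    Sequences above the given quantile of summed spectral count that occur
    in exactly one sample are flagged as candidate false positives (the
    retention-time confirmation the flag is meant to trigger is manual).
    """
    totals: dict[str, int] = {}
    occurs: dict[str, int] = {}
    for t in group:
        for r in t.records:
            totals[r.sequence] = totals.get(r.sequence, 0) + r.spectral_count
            occurs[r.sequence] = occurs.get(r.sequence, 0) + 1
    df = pd.DataFrame(
        {
            "sequence": list(totals),
            "total_count": [totals[s] for s in totals],
            "n_samples": [occurs[s] for s in totals],
        }
    )
    if df.empty:
        df["flagged"] = pd.Series(dtype=bool)
        return df
    threshold = df["total_count"].quantile(count_quantile)
    df["flagged"] = (df["total_count"] > threshold) & (df["n_samples"] == 1)
    return df.sort_values("total_count", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    df: float
    paired: bool
    degenerate: bool = False


def compare_group_means(
    values_a: Sequence[float], values_b: Sequence[float], paired: bool = False
) -> TTestResult:
    """Two-sided Student t comparison of two per-sample value vectors.

    Unpaired comparisons use Welch's t (no equal-variance assumption, which
    suits unequal group sizes); paired comparisons use the paired Student t.
    Standard deviations use ddof=1. A paired comparison whose differences
    have zero variance is reported with ``degenerate=True`` (t/p are NaN).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    sd_a, sd_b = float(np.std(a, ddof=1)), float(np.std(b, ddof=1))
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires equal lengths")
        diff = a - b
        if float(np.std(diff, ddof=1)) == 0.0:
            return TTestResult(float("nan"), float("nan"), mean_a, sd_a, mean_b, sd_b,
                               df=len(a) - 1, paired=True, degenerate=True)
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(res.pvalue), mean_a, sd_a,
                           mean_b, sd_b, df=float(len(a) - 1), paired=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    va, vb = sd_a**2 / len(a), sd_b**2 / len(b)
    if va + vb == 0:
        dof = float(len(a) + len(b) - 2)
    else:
        dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return TTestResult(float(res.statistic), float(res.pvalue), mean_a, sd_a,
                       mean_b, sd_b, df=float(dof), paired=False)


# ---------------------------------------------------------------------------
# protease attribution
# ---------------------------------------------------------------------------


@dataclass
class ProteaseSpecificity:
    """Allowed P1 residues (with weights) and optional P1' residues."""

    p1_weights: dict[str, float]
    p1_prime_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.p1_weights:
            raise ValueError("a protease needs at least one allowed P1 residue")
        if any(w < 0 for w in self.p1_weights.values()):
            raise ValueError("specificity weights must be >= 0")


ProteaseSpecificityTable = dict[str, ProteaseSpecificity]


def load_specificity_table(path: str | Path) -> ProteaseSpecificityTable:
    """Read a YAML protease specificity config.

    Format::

        trypsin_like:
          p1: {K: 1.0, R: 1.0}
        glutamyl_endopeptidase_like:
          p1: {D: 0.5, E: 1.0}
          p1_prime: {A: 1.0}
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    table: ProteaseSpecificityTable = {}
    for name, spec in doc.items():
        p1 = {str(r): float(w) for r, w in spec["p1"].items()}
        p1p = (
            {str(r): float(w) for r, w in spec["p1_prime"].items()}
            if "p1_prime" in spec
            else None
        )
        table[name] = ProteaseSpecificity(p1_weights=p1, p1_prime_weights=p1p)
    return table


def attribute_proteases(
    mapped: MappedDataset,
    table: ProteaseSpecificityTable,
    group_label: str | None = None,
    use_p1_prime: bool = False,
) -> pd.Series:
    """Count cleavage events compatible with each protease's P1 specificity.

    Each mapped peptide yields up to two cleavage events: the N-side event
    (P1 = the residue preceding the peptide, P1' = the peptide's first
    residue) and the C-side event (P1 = the peptide's last residue, P1' =
    the residue following it). Protein-inherent termini yield no event.
    Residues are taken from the first location, so an ambiguous peptide
    contributes each event once. A peptide may be compatible with several
    proteases; this is a deterministic presence/absence rule, not a
    database-driven prediction.
    """
    if not table:
        raise ValueError("empty protease specificity table")
    counts = {name: 0 for name in table}
    for e in mapped.for_group(group_label):
        loc = e.peptide.locations[0]
        events: list[tuple[str, str]] = []  # (p1 residue, p1' residue)
        if not loc.is_protein_n_terminal and loc.preceding_residue:
            events.append((loc.preceding_residue, e.sequence[0]))
        if not loc.is_protein_c_terminal:
            events.append((e.sequence[-1], loc.following_residue or ""))
        for p1, p1p in events:
            for name, spec in table.items():
                if spec.p1_weights.get(p1, 0.0) <= 0:
                    continue
                if use_p1_prime and spec.p1_prime_weights is not None:
                    if spec.p1_prime_weights.get(p1p, 0.0) <= 0:
                        continue
                counts[name] += 1
    return pd.Series(counts).sort_values(ascending=False, kind="mergesort")
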