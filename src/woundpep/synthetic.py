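"""Synthetic grouped peptidome datasets with known ground truth.

Endogenous peptidomes arise from endoproteolytic cleavage of substrate
proteins followed by exopeptidase trimming; abundance readouts (spectral
counts) are overdispersed small integers. The generator emulates exactly
that: per sample it (1) picks substrate proteins by relative abundance,
(2) places internal cleavage sites with probability proportional to a
planted P1 propensity (the residue N-terminal of the cut), (3) forms the
fragments between successive cuts (including the protein-terminal
fragments), trims each end geometrically, and enforces length bounds,
(4) draws spectral counts from a negative binomial (a fragment drawing 0
is unobserved), and (5) forces a planted "core" subset of the group's
peptide pool into every sample of the group.

Every emitted peptide is a substring of its recorded parent protein at its
recorded coordinates, so the mapping stage must achieve 100% localization.
Two identifiability guarantees make the planted cores an exact oracle for
the group-intersection analysis: core peptides enter every sample with a
spectral count at or above the default cutoff, and any non-core peptide
that happens to occur in all samples of a group (two or more samples) is
withheld from one pseudo-randomly chosen sample.

Seeding fans out deterministically per (group, sample) stream, so adding a
sample or group never perturbs previously generated ones, and identical
seeds give byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .amp_region import RegionSpec
from .core_io import (
    AA_ALPHABET,
    DEFAULT_SPECTRAL_CUTOFF,
    GroupedDataset,
    ProteinDatabase,
    SampleTable,
    write_fasta,
    write_peptide_table,
)

# Toy parent proteins: documented bioactive/biomarker regions of human
# hemoglobin subunits alpha/beta and fibrinogen alpha, each packaged as a
# stand-alone miniature protein (synthetic database, not the real proteome).
_TOY_PROTEINS: tuple[tuple[str, str, str], ...] = (
    ("HBB_CTERM_TOY", "hemoglobin beta C-terminal antimicrobial region (toy)",
     "LVCVLAHHFGKEFTPPVQAAYQKVVAGVANALAHKYH"),
    ("HBB_NTERM_TOY", "hemoglobin beta N-terminal region (toy)",
     "MVHLTPEEKSAVTALWGKVNV"),
    ("HBA_NTERM_TOY", "hemoglobin alpha N-terminal region (toy)",
     "MVLSPADKTNVKAAWGKVGAHAGEYGAEA"),
    ("HBA_MID_TOY", "hemoglobin alpha mid region (toy)",
     "RMFLSFPTTKTYFPHFDLSHGSAQVKGHGKKVADALTNAVAHVDDMPNALSALSDLHAHKLR"),
    ("FIBA_FPA_TOY", "fibrinopeptide A region of fibrinogen alpha (toy)",
     "ADSGEGDFLAEGGGVR"),
    ("FIBA_CTERM_TOY", "fibrinogen alpha C-terminal region (toy)",
     "SYKMADEAGSEADHEGTHSTKR"),
)

# Residue frequencies used for the deterministic filler proteins
# (approximate Swiss-Prot composition; exact values are irrelevant here).
_FILLER_FREQS = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.46, "C": 1.38, "Q": 3.93,
    "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91, "L": 9.65, "K": 5.80,
    "M": 2.41, "F": 3.86, "P": 4.74, "S": 6.64, "T": 5.35, "W": 1.10,
    "Y": 2.92, "V": 6.86,
}

_FILLER_SEED = 916801  # frozen so bundled_proteins is byte-identical


def bundled_proteins(n_filler: int = 48, filler_length: int = 600) -> ProteinDatabase:
    """Deterministic toy protein database for simulation and tests.

    Miniature proteins carrying documented hemoglobin/fibrinogen regions,
    plus pseudo-random filler proteins with Swiss-Prot-like composition.
    Byte-identical across calls.
    """
    entries: dict[str, tuple[str, str]] = {
        acc: (desc, seq) for acc, desc, seq in _TOY_PROTEINS
    }
    rng = np.random.default_rng(_FILLER_SEED)
    residues = np.array(list(_FILLER_FREQS))
    probs = np.array(list(_FILLER_FREQS.values()))
    probs = probs / probs.sum()
    for i in range(n_filler):
        seq = "".join(rng.choice(residues, size=filler_length, p=probs))
        entries[f"FILLER_{i + 1:02d}"] = ("synthetic filler protein", seq)
    return ProteinDatabase(entries)


@dataclass(frozen=True)
class DigestionModel:
    """Generative parameters of one group's peptidome.

    p1_weights: cleavage propensity per P1 residue (residue N-terminal of
    the cut); exo_trim_prob: per-end geometric trimming parameter in
    [0, 1); length_bounds: retained peptide lengths (min >= 4 so terminal
    4-mers exist); abundance_mean / abundance_dispersion: negative-binomial
    spectral-count parameters (dispersion is the NB shape r; smaller r =
    more overdispersed); substrate_weights: relative protein abundance
    (None = uniform over the database); core_fraction: fraction of the
    group's peptide pool forced into every sample; hotspots: regions whose
    confined fragments get their count mean multiplied by an enrichment
    factor.
    """

    p1_weights: Mapping[str, float] | None = None  # None = uniform
    exo_trim_prob: float = 0.15
    length_bounds: tuple[int, int] = (4, 45)
    abundance_mean: float = 1.3
    abundance_dispersion: float = 1.0
    substrate_weights: Mapping[str, float] | None = None
    core_fraction: float = 0.05
    hotspots: tuple[tuple[RegionSpec, float], ...] = ()

    def __post_init__(self) -> None:
        if self.p1_weights is not None:
            if not any(w > 0 for w in self.p1_weights.values()):
                raise ValueError("at least one P1 weight must be positive")
        if not 0.0 <= self.exo_trim_prob < 1.0:
            raise ValueError("exo_trim_prob must be in [0, 1)")
        if self.length_bounds[0] < 4:
            raise ValueError("minimum peptide length must be >= 4")
        if self.length_bounds[0] > self.length_bounds[1]:
            raise ValueError("infeasible length bounds")
        if self.abundance_mean <= 0:
            raise ValueError("abundance mean must be > 0")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")

    def p1_distribution(self) -> dict[str, float]:
        """Planted P1 propensities normalized to a distribution."""
        w = (
            dict(self.p1_weights)
            if self.p1_weights is not None
            else {r: 1.0 for r in AA_ALPHABET}
        )
        total = sum(w.values())
        return {r: v / total for r, v in w.items() if v > 0}


def plant_hotspot(
    model: DigestionModel,
    region: RegionSpec,
    enrichment: float,
    db: ProteinDatabase | None = None,
) -> DigestionModel:
    """Return a model whose fragments confined to ``region`` get their
    spectral-count mean multiplied by ``enrichment`` (>= 1)."""
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if db is not None:
        region.validate(db)
    if enrichment == 1:
        return model
    return replace(model, hotspots=model.hotspots + ((region, enrichment),))


@dataclass
class GroundTruth:
    """Everything planted by the generator, for use as a test oracle."""

    p1_distributions: dict[str, dict[str, float]]  # group -> residue -> prob
    substrate_shares: dict[str, dict[str, float]]  # group -> accession -> share
    core_peptides: dict[str, set[str]]  # group -> planted core set
    hotspots: dict[str, list[tuple[RegionSpec, float]]]
    origins: dict[str, tuple[str, int, int]]  # sequence -> (acc, start, end)


#: Mean number of cleavage sites per residue of substrate (one cut every
#: ~12 residues, giving mean fragment lengths near the observed peptidomes).
_CUT_DENSITY = 1.0 / 12.0


def _cut_probabilities(seq: str, p1_dist: dict[str, float]) -> np.ndarray:
    """Per-site cleavage probabilities realizing the planted P1 distribution.

    Cut position i (1-based, cut after residue i, i in 1..L-1) is cleaved
    independently with probability q_i proportional to the planted
    propensity of residue i divided by that residue's number of eligible
    positions, scaled to one cut per ``1/_CUT_DENSITY`` residues. The
    expected P1 composition of the realized cut set therefore equals the
    planted distribution restricted to the residues the protein contains.
    """
    L = len(seq)
    counts: dict[str, int] = {}
    for i in range(1, L):
        counts[seq[i - 1]] = counts.get(seq[i - 1], 0) + 1
    present_mass = sum(p for r, p in p1_dist.items() if r in counts)
    q = np.zeros(L - 1)
    if present_mass <= 0:
        return q
    mu = L * _CUT_DENSITY  # expected number of cuts
    for i in range(1, L):
        r = seq[i - 1]
        p = p1_dist.get(r, 0.0) / present_mass
        q[i - 1] = min(0.95, mu * p / counts[r])
    return q


def _digest(
    seq: str,
    rng: np.random.Generator,
    cut_probs: np.ndarray,
    model: DigestionModel,
) -> list[tuple[int, int]]:
    """One in-silico digestion: sorted fragment (start, end) pairs, 1-based."""
    L = len(seq)
    cuts = (np.nonzero(rng.random(L - 1) < cut_probs)[0] + 1).tolist()
    bounds = [0] + cuts + [L]
    frags = []
    min_len, max_len = model.length_bounds
    q = model.exo_trim_prob
    for a, b in zip(bounds[:-1], bounds[1:]):
        start, end = a + 1, b  # 1-based inclusive
        if q > 0:
            trim_n = int(rng.geometric(1 - q)) - 1
            trim_c = int(rng.geometric(1 - q)) - 1
            max_total = (end - start + 1) - min_len
            if max_total > 0:
                trim_n = min(trim_n, max_total)
                trim_c = min(trim_c, max_total - trim_n)
                start += trim_n
                end -= trim_c
        n = end - start + 1
        if min_len <= n <= max_len:
            frags.append((start, end))
    return frags


def _count_mean(
    model: DigestionModel, accession: str, start: int, end: int
) -> float:
    mean = model.abundance_mean
    for region, enrichment in model.hotspots:
        if (
            region.accession == accession
            and start >= region.start
            and end <= region.end
        ):
            mean *= enrichment
    return mean


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_dataset(
    db: ProteinDatabase,
    models: Mapping[str, DigestionModel],
    n_samples: Mapping[str, int] | int = 3,
    peptides_per_sample: int = 1200,
    seed: int = 0,
    spectral_cutoff: int = DEFAULT_SPECTRAL_CUTOFF,
    identifiable_cores: bool = True,
) -> tuple[GroupedDataset, GroundTruth]:
    """Generate a grouped peptidome dataset plus its full ground truth.

    ``models`` maps each group label to its digestion model; ``n_samples``
    is per group (or one integer for all). Sampling continues until at
    least ``peptides_per_sample`` unique observed peptides exist per
    sample. Core peptides enter every sample of their group with a count
    >= ``spectral_cutoff`` so the planted cores survive filtering; with
    ``identifiable_cores`` (default) a non-core peptide that would appear
    in every sample of a group is additionally withheld from one sample,
    making the planted core set exactly equal to the group intersection
    (the sample-addition-stability guarantee then holds only for the raw
    per-sample streams, not the group-level post-processing).
    """
    group_labels = sorted(models)
    if isinstance(n_samples, int):
        n_samples = {g: n_samples for g in group_labels}

    origins: dict[str, tuple[str, int, int]] = {}
    groups: dict[str, list[SampleTable]] = {}
    truth = GroundTruth(
        p1_distributions={}, substrate_shares={}, core_peptides={}, hotspots={},
        origins=origins,
    )

    for gi, label in enumerate(group_labels):
        model = models[label]
        p1_dist = model.p1_distribution()
        accs = db.accessions()
        if model.substrate_weights is not None:
            sub_w = np.array([model.substrate_weights.get(a, 0.0) for a in accs])
        else:
            sub_w = np.ones(len(accs))
        if sub_w.sum() <= 0:
            raise ValueError(f"group {label!r}: no positive substrate weight")
        sub_p = sub_w / sub_w.sum()
        truth.p1_distributions[label] = p1_dist
        truth.substrate_shares[label] = {
            a: float(p) for a, p in zip(accs, sub_p) if p > 0
        }
        truth.hotspots[label] = list(model.hotspots)
        for region, _ in model.hotspots:
            region.validate(db)
        cut_probs = {acc: _cut_probabilities(db.sequence(acc), p1_dist) for acc in accs}

        sample_counts: list[dict[str, int]] = []
        for si in range(n_samples[label]):
            rng = np.random.default_rng([seed % (2**31), gi, si])
            counts: dict[str, int] = {}
            seen: set[str] = set()  # fragments already given their abundance draw
            max_digests = 200 + 60 * peptides_per_sample
            digests = 0
            while len(counts) < peptides_per_sample:
                if digests >= max_digests:
                    if not counts:
                        raise ValueError(
                            "no fragments produced; length bounds infeasible "
                            "for this database"
                        )
                    break
                digests += 1
                acc = accs[int(rng.choice(len(accs), p=sub_p))]
                seq = db.sequence(acc)
                for start, end in _digest(seq, rng, cut_probs[acc], model):
                    frag = seq[start - 1 : end]
                    if frag in seen or any(r not in AA_ALPHABET for r in frag):
                        continue
                    # one abundance draw per unique fragment per sample; a
                    # draw of 0 means the fragment goes undetected
                    seen.add(frag)
                    mean = _count_mean(model, acc, start, end)
                    c = _draw_count(rng, mean, model.abundance_dispersion)
                    if c == 0:
                        continue
                    counts[frag] = c
                    origins.setdefault(frag, (acc, start, end))
            sample_counts.append(counts)

        # plant cores / enforce non-core exclusivity (group-level stream)
        g_rng = np.random.default_rng([seed % (2**31), gi, 999_983])
        pool = sorted(set().union(*sample_counts)) if sample_counts else []
        n_core = int(round(model.core_fraction * len(pool)))
        core = (
            set(g_rng.choice(pool, size=n_core, replace=False).tolist())
            if n_core > 0
            else set()
        )
        for counts in sample_counts:
            for seq in sorted(core):
                if counts.get(seq, 0) < spectral_cutoff:
                    counts[seq] = spectral_cutoff + _draw_count(
                        g_rng, model.abundance_mean, model.abundance_dispersion
                    )
        if identifiable_cores and len(sample_counts) >= 2:
            for seq in pool:
                if seq in core:
                    continue
                if all(seq in counts for counts in sample_counts):
                    victim = int(g_rng.integers(len(sample_counts)))
                    del sample_counts[victim][seq]
        truth.core_peptides[label] = core

        groups[label] = [
            SampleTable.from_counts(
                f"{label}_{si + 1}",
                counts,
                group_label=label,
                accessions={s: (origins[s][0],) for s in counts},
            )
            for si, counts in enumerate(sample_counts)
        ]

    return GroupedDataset(groups), truth


# ---------------------------------------------------------------------------
# the default study design
# ---------------------------------------------------------------------------

#: Planted P1 propensities of the dressing-derived groups: acidic residues
#: (D+E) carry 40% of the cleavage mass, the remaining 18 residues share 60%.
ACIDIC_P1_WEIGHTS: dict[str, float] = {
    **{r: 0.60 / 18 for r in AA_ALPHABET if r not in "DE"},
    "D": 0.20,
    "E": 0.20,
}


def study_design(
    db: ProteinDatabase | None = None,
    peptides_per_sample: int = 2500,
    hotspot_enrichment: float = 10.0,
) -> tuple[ProteinDatabase, dict[str, DigestionModel], dict[str, int]]:
    """The default three-group wound-fluid-like study.

    Groups: ``acute`` (uniform P1 propensities), ``non_infected`` and
    ``infected`` (acidic-biased P1, D+E share 0.40). The infected group gets
    a higher hemoglobin-region substrate weight and a planted abundance
    hotspot in the C-terminal hemoglobin-beta toy region. Exo-trimming is
    disabled in this design because it overwrites cut-site residues, and the
    design's purpose is recovery of the planted cleavage preference; filler
    proteins dominate the substrate mix so that the restricted residue
    availability of the miniature proteins does not distort the planted P1
    distribution.
    """
    if db is None:
        db = bundled_proteins()
    fillers = {a: 1.0 for a in db.accessions() if a.startswith("FILLER")}
    toys = {a: 0.2 for a in db.accessions() if not a.startswith("FILLER")}
    base_sub = {**fillers, **toys}

    hotspot = RegionSpec(accession="HBB_CTERM_TOY", start=12, end=37, label="hbb_amp")

    common = dict(
        exo_trim_prob=0.0,
        length_bounds=(4, 45),
        abundance_mean=1.3,
        abundance_dispersion=1.0,
        core_fraction=0.05,
    )
    acute = DigestionModel(p1_weights=None, substrate_weights=base_sub, **common)
    non_infected = DigestionModel(
        p1_weights=ACIDIC_P1_WEIGHTS, substrate_weights=base_sub, **common
    )
    infected_sub = dict(base_sub)
    infected_sub["HBB_CTERM_TOY"] = 3.0
    infected = plant_hotspot(
        DigestionModel(p1_weights=ACIDIC_P1_WEIGHTS, substrate_weights=infected_sub,
                       **common),
        hotspot,
        hotspot_enrichment,
        db=db,
    )
    models = {"acute": acute, "non_infected": non_infected, "infected": infected}
    return db, models, {g: 3 for g in models}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_simulation(
    outdir: str | Path,
    db: ProteinDatabase,
    ds: GroupedDataset,
    truth: GroundTruth,
) -> None:
    """Write FASTA, per-sample tables, manifest and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(db, outdir / "proteins.fasta")
    manifest = {"samples": []}
    for g, tables in ds.groups.items():
        for t in tables:
            fname = f"{t.sample_id}.tsv"
            write_peptide_table(t, outdir / fname)
            manifest["samples"].append(
                {"sample_id": t.sample_id, "group": g, "files": [fname]}
            )
    with open(outdir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    doc = {
        "p1_distributions": truth.p1_distributions,
        "substrate_shares": truth.substrate_shares,
        "core_peptides": {g: sorted(s) for g, s in truth.core_peptides.items()},
        "hotspots": {
            g: [
                {"accession": r.accession, "start": r.start, "end": r.end,
                 "label": r.label, "enrichment": e}
                for r, e in hs
            ]
            for g, hs in truth.hotspots.items()
        },
        "origins": {s: list(o) for s, o in truth.origins.items()},
    }
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
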