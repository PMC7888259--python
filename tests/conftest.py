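"""Shared fixtures: miniature protein databases, toy tables, and one
session-scoped simulated study reused by the recovery tests."""

from dataclasses import dataclass

import pytest

import woundpep as wp

# The hemoglobin-beta C-terminal toy protein used across mapping/region tests.
HBB_TOY_SEQ = "LVCVLAHHFGKEFTPPVQAAYQKVVAGVANALAHKYH"
HBB_NTERM_SEQ = "MVHLTPEEKSAVTALWGKVNV"


@pytest.fixture
def toy_db() -> wp.ProteinDatabase:
    return wp.ProteinDatabase(
        {
            "HBB_TOY": ("hemoglobin beta C-terminal toy", HBB_TOY_SEQ),
            "HBB_NTERM_TOY": ("hemoglobin beta N-terminal toy", HBB_NTERM_SEQ),
        }
    )


@pytest.fixture
def small_table() -> wp.SampleTable:
    return wp.SampleTable.from_counts("s1", {"NALAHKYH": 5, "AAKK": 4, "CCCW": 3})


@dataclass
class Study:
    db: wp.ProteinDatabase
    ds: wp.GroupedDataset
    truth: wp.GroundTruth
    filtered: wp.GroupedDataset
    mapped: wp.MappedDataset
    mapped_filtered: wp.MappedDataset
    cleavage: list


@pytest.fixture(scope="session")
def study() -> Study:
    """The default three-group study, simulated once per test session."""
    db, models, n_samples = wp.study_design()
    ds, truth = wp.simulate_dataset(
        db, models, n_samples, peptides_per_sample=2500, seed=1234
    )
    filtered = ds.map_tables(lambda t: wp.apply_spectral_cutoff(t, 4))
    mapped = wp.map_dataset(ds, db)
    mapped_filtered = wp.map_dataset(filtered, db)
    return Study(
        db=db,
        ds=ds,
        truth=truth,
        filtered=filtered,
        mapped=mapped,
        mapped_filtered=mapped_filtered,
        cleavage=wp.cleavage_site_records(mapped),
    )
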