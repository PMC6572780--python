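import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

import loopscape as ls

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")
from loopscape.anchor_annotation import add_dr_locations
from loopscape.io_formats import GenomicInterval, Interaction, Peak


SMALL_CONFIG = ls.SimConfig(
    n_chroms=2,
    chrom_length=8_000_000,
    n_genes=80,
    n_distal_peaks=40,
    n_loops=40,
    background_pets=8_000,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated tissue, shared across tests (read-only)."""
    return ls.simulate_dataset(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """The small dataset run through dedup -> classify -> call -> annotate."""
    ds = small_dataset
    petset = ls.classify_pets(ls.pool_and_dedup([ds.pets]))
    peaks = ds.genome.all_peaks()
    called = ls.call_interactions(petset, peaks, mark="combined")
    ann = ls.annotate_peaks(peaks, ds.genome.genes)
    ann = add_dr_locations(ann, peaks, ds.genome.genes, ds.genome.tes)
    called = ls.classify_interactions(called, ann)
    return ds, petset, peaks, called, ann


def make_interaction(
    chrom_a="chr1",
    start_a=1_000,
    end_a=3_000,
    chrom_b="chr1",
    start_b=50_000,
    end_b=52_000,
    cls=None,
    peak_a="pkA",
    peak_b="pkB",
    pet_count=5,
    tissue="",
    marks=frozenset(),
):
    return Interaction(
        anchor_a=GenomicInterval(chrom_a, start_a, end_a),
        anchor_b=GenomicInterval(chrom_b, start_b, end_b),
        pet_count=pet_count,
        p=1e-6,
        fdr=1e-4,
        cls=cls,
        peak_a=peak_a,
        peak_b=peak_b,
        tissue=tissue,
        marks=marks,
    )


def make_peak(chrom="chr1", start=1_000, end=3_000, signal=10.0, mark="combined", id="pk"):
    return Peak(GenomicInterval(chrom, start, end), signal=signal, mark=mark, id=id)
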