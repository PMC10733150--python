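import math

import numpy as np
import pytest

from coalabc.coalsim import HaplotypeDataset
from coalabc.demography import (DemographicModel, EpochSize, PopulationSpec,
                                SplitEvent)


def make_dataset(genotype_blocks, sample_pops, locus_lengths=None,
                 continents=None, sample_ids=None, masks=None):
    """Hand-built dataset from one int8 matrix (sites x haplotypes) per locus."""
    blocks = [np.asarray(g, dtype=np.int8) for g in genotype_blocks]
    n_ind = blocks[0].shape[1] // 2
    ids = sample_ids or [f"s{i:02d}" for i in range(n_ind)]
    return HaplotypeDataset(
        positions=[np.arange(1, g.shape[0] + 1, dtype=np.int64) for g in blocks],
        genotypes=blocks,
        locus_lengths=np.asarray(locus_lengths or [g.shape[0] for g in blocks],
                                 dtype=np.int64),
        sample_ids=ids,
        sample_pops=list(sample_pops),
        continents=continents or {p: "X" for p in set(sample_pops)},
        masks=masks)


def single_pop_model(ne=1000.0, name="A"):
    return DemographicModel(
        populations=[PopulationSpec(name, "X")],
        splits=[],
        sizes=[EpochSize(name, 0.0, math.inf, ne)])


def two_pop_split_model(t_split=500.0, ne=1000.0):
    return DemographicModel(
        populations=[PopulationSpec("A", "X"), PopulationSpec("B", "X"),
                     PopulationSpec("ANC", "ancestral")],
        splits=[SplitEvent(t_split, "A", "B", "ANC")],
        sizes=[EpochSize("A", 0.0, t_split, ne),
               EpochSize("B", 0.0, t_split, ne),
               EpochSize("ANC", t_split, math.inf, ne)])


def clade_model(t_inner=400.0, t_outer=1200.0, ne=1000.0):
    """((A,B),(C,D)) with no migration: a true clade on each side."""
    return DemographicModel(
        populations=[PopulationSpec(p, "X") for p in "ABCD"]
        + [PopulationSpec("AB", "ancestral"), PopulationSpec("CD", "ancestral"),
           PopulationSpec("ROOT", "ancestral")],
        splits=[SplitEvent(t_inner, "A", "B", "AB"),
                SplitEvent(t_inner, "C", "D", "CD"),
                SplitEvent(t_outer, "AB", "CD", "ROOT")],
        sizes=[EpochSize(p, 0.0, t_inner, ne) for p in "ABCD"]
        + [EpochSize("AB", t_inner, t_outer, ne),
           EpochSize("CD", t_inner, t_outer, ne),
           EpochSize("ROOT", t_outer, math.inf, ne)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
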