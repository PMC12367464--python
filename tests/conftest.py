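import numpy as np
import pandas as pd
import pytest

import spikequant as sq
from spikequant.containers import SpikeDose, SpikeStrain


def make_strain(
    name="Sp1",
    label=None,
    conc=1.0,
    vol=1.0,
    length=1000.0,
    gcn=1.0,
) -> SpikeStrain:
    return SpikeStrain(
        name=name,
        taxon_label=label or name,
        dna_concentration_ng_per_ul=conc,
        volume_added_ul=vol,
        reference_length_bp=length,
        gcn=gcn,
    )


def dose_with_copies(label: str, copies: float) -> SpikeDose:
    """A SpikeDose carrying an exact molecule count (for arithmetic fixtures)."""
    return SpikeDose(strain=make_strain(label), mass_ng=0.0, copies_added=copies)


@pytest.fixture
def single_spike_cm() -> sq.CountMatrix:
    """One endogenous taxon (500 reads) plus one spike row (100 reads)."""
    counts = pd.DataFrame({"s1": [500, 100]}, index=["TaxA", "Sp1"])
    return sq.CountMatrix(counts, spike_taxa=("Sp1",))


@pytest.fixture
def single_spike_meta() -> list[sq.SampleMeta]:
    return [
        sq.SampleMeta(
            sample_id="s1",
            group="g",
            feces_mass_g=0.2,
            elution_volume_ul=200.0,
            spiked_aliquot_volume_ul=20.0,
        )
    ]


@pytest.fixture
def baseline_run():
    """One baseline synthetic cohort quantified end to end."""
    params = sq.SimulationParams(seed=11)
    cm, meta, strains, truth, measurements = sq.simulate_experiment(params)
    doses = [sq.spike_dose(s) for s in strains]
    aam = sq.absolute_abundance(cm, meta, doses)
    return cm, meta, strains, truth, measurements, aam
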