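"""Core data containers for spike-in calibrated amplicon experiments.

The central objects are :class:`CountMatrix` (taxon x sample integer reads
in which the exogenous spike-in taxa appear as ordinary rows),
:class:`SampleMeta` (the per-sample physical accounting needed to put read
counts on a per-gram scale), :class:`SpikeStrain` (one exogenous DNA
calibrant of known mass, reference length and 16S gene copy number), and
:class:`AbsoluteAbundanceMatrix` (the calibrated output in 16S gene copies
per gram of sample, with per-sample scale factors and QC flags).

All containers validate their invariants on construction; readers in
:mod:`spikequant.io` cannot hand out an invalid object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# QC flags for the per-sample spike-read fraction window.
QC_PASS = "pass"
QC_FAIL_LOW = "fail_low"
QC_FAIL_HIGH = "fail_high"
QC_NO_SPIKE = "no_spike_reads"

#: Recommended share of total reads the spike taxa should occupy for
#: reliable calibration (0.1% - 10%).
SPIKE_FRACTION_LOW = 0.001
SPIKE_FRACTION_HIGH = 0.10


@dataclass(frozen=True)
class SampleMeta:
    """Physical accounting for one sample.

    Parameters
    ----------
    sample_id : str
        Unique sample label.
    group : str
        Cohort group label (e.g. ``"mother"`` / ``"infant"``).
    feces_mass_g : float
        Wet mass of sample material that went into DNA extraction, grams.
    elution_volume_ul : float
        Total DNA elution volume after extraction, microlitres.
    spiked_aliquot_volume_ul : float
        Volume of the eluate that was mixed with the spike DNA and taken
        into library preparation, microlitres.  Must not exceed the
        elution volume.
    """

    sample_id: str
    group: str
    feces_mass_g: float
    elution_volume_ul: float
    spiked_aliquot_volume_ul: float

    def __post_init__(self) -> None:
        for name in ("feces_mass_g", "elution_volume_ul", "spiked_aliquot_volume_ul"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: {name} must be strictly "
                    f"positive, got {value!r}"
                )
        if self.spiked_aliquot_volume_ul > self.elution_volume_ul:
            raise ValueError(
                f"sample {self.sample_id!r}: spiked aliquot "
                f"({self.spiked_aliquot_volume_ul} uL) exceeds elution volume "
                f"({self.elution_volume_ul} uL)"
            )


@dataclass(frozen=True)
class SpikeStrain:
    """One exogenous DNA calibrant.

    ``reference_length_bp`` is the double-stranded DNA length used in the
    mass-to-copies conversion; whether that is the genome or the amplicon
    is a configuration choice (``dose_basis``) carried by the spike
    configuration file, not by this record.
    """

    name: str
    taxon_label: str
    dna_concentration_ng_per_ul: float
    volume_added_ul: float
    reference_length_bp: float
    gcn: float = 1.0

    def __post_init__(self) -> None:
        if self.dna_concentration_ng_per_ul < 0:
            raise ValueError(f"spike {self.name!r}: negative DNA concentration")
        if self.volume_added_ul < 0:
            raise ValueError(f"spike {self.name!r}: negative volume")
        if self.reference_length_bp <= 0:
            raise ValueError(f"spike {self.name!r}: reference length must be > 0")
        if self.gcn < 1:
            raise ValueError(f"spike {self.name!r}: 16S gene copy number must be >= 1")

    @property
    def mass_ng(self) -> float:
        """DNA mass added per spiked aliquot, ng."""
        return self.dna_concentration_ng_per_ul * self.volume_added_ul


@dataclass(frozen=True)
class SpikeDose:
    """A spike strain together with its computed molecule dose."""

    strain: SpikeStrain
    mass_ng: float
    copies_added: float
    zero_dose: bool = False


class CountMatrix:
    """Taxon x sample integer read counts with spike-in roles.

    Parameters
    ----------
    counts : pandas.DataFrame
        Taxa on the index, samples on the columns, non-negative integer
        cells.
    spike_taxa : sequence of str
        Subset of the taxa flagged as spike-in calibrants.
    allow_empty_samples : bool
        Permit samples whose total read count is zero (e.g. a simulated
        zero-depth run).  Off by default.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        spike_taxa: Sequence[str] = (),
        allow_empty_samples: bool = False,
    ) -> None:
        counts = counts.copy()
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon labels: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)):
                bad = np.argwhere(~np.isfinite(values))[0]
                raise ValueError(
                    f"non-finite count at taxon {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}"
                )
            rounded = np.rint(values)
            if not np.array_equal(rounded, values):
                bad = np.argwhere(rounded != values)[0]
                raise ValueError(
                    f"non-integer count at taxon {counts.index[bad[0]]!r}, "
                    f"sample {counts.columns[bad[1]]!r}: {values[tuple(bad)]!r}"
                )
            values = rounded.astype(np.int64)
            counts = pd.DataFrame(values, index=counts.index, columns=counts.columns)
        if values.size and values.min() < 0:
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at taxon {counts.index[bad[0]]!r}, "
                f"sample {counts.columns[bad[1]]!r}"
            )
        missing = [t for t in spike_taxa if t not in counts.index]
        if missing:
            raise ValueError(f"spike taxon not found in count table: {missing}")
        if not allow_empty_samples and counts.shape[0]:
            totals = counts.sum(axis=0)
            empty = totals.index[totals == 0].tolist()
            if empty:
                raise ValueError(
                    f"samples with zero total reads: {empty} "
                    "(pass allow_empty_samples=True to accept)"
                )
        self.counts = counts.astype(np.int64)
        self.spike_taxa = tuple(spike_taxa)
        self.allow_empty_samples = allow_empty_samples

    # -- basic views -------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def endogenous_taxa(self) -> list[str]:
        spike = set(self.spike_taxa)
        return [t for t in self.counts.index if t not in spike]

    def endogenous(self) -> pd.DataFrame:
        """Read counts of the non-spike taxa (taxa x samples)."""
        return self.counts.loc[self.endogenous_taxa]

    def spike_reads(self) -> pd.DataFrame:
        """Reads of each spike taxon (spike taxa x samples)."""
        return self.counts.loc[list(self.spike_taxa)]

    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.spike_taxa == other.spike_taxa
        )

    def __repr__(self) -> str:
        return (
            f"CountMatrix({len(self.taxa)} taxa x {len(self.samples)} samples, "
            f"{len(self.spike_taxa)} spike)"
        )


@dataclass
class AbsoluteAbundanceMatrix:
    """Calibrated abundances in 16S gene copies per gram of sample.

    ``values`` holds endogenous taxa only (spike rows are removed); columns
    of samples flagged ``no_spike_reads`` are NaN.  ``scale_factor`` is the
    per-sample copies-per-read back-normalization factor already scaled to
    per-gram units; ``spike_fraction`` is the share of total reads assigned
    to spike taxa; ``qc_flag`` is one of ``pass`` / ``fail_low`` /
    ``fail_high`` / ``no_spike_reads``.  ``cells`` is an optional
    cells-per-gram layer after 16S gene copy number correction.
    """

    values: pd.DataFrame
    scale_factor: pd.Series
    spike_fraction: pd.Series
    qc_flag: pd.Series
    pooling: str = "sum"
    cells: pd.DataFrame | None = None
    gcn_defaulted: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for series in (self.scale_factor, self.spike_fraction, self.qc_flag):
            if not series.index.equals(self.values.columns):
                raise ValueError("per-sample series must align with value columns")
        frac = self.spike_fraction.dropna()
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("spike_fraction must lie in [0, 1]")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    def total_load(self) -> pd.Series:
        """Estimated total endogenous load per sample, copies/g."""
        return self.values.sum(axis=0, skipna=False)

    def passing_samples(self) -> list[str]:
        return list(self.qc_flag.index[self.qc_flag == QC_PASS])


def measurements_frame(records: Sequence[Mapping[str, object]]) -> pd.DataFrame:
    """Build and validate a long-form method-measurement table.

    Columns: ``sample_id``, ``method``, ``value``; one row per
    (sample, method) pair; values are per-gram loads (or ng for the
    ``total_dna`` method), all non-negative.
    """
    df = pd.DataFrame(records, columns=["sample_id", "method", "value"])
    return validate_measurements(df)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "method", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["sample_id", "method"]).any():
        dupes = df.loc[
            df.duplicated(subset=["sample_id", "method"]), ["sample_id", "method"]
        ]
        raise ValueError(f"duplicate (sample_id, method) pairs:\n{dupes}")
    if (df["value"] < 0).any():
        raise ValueError("measurement values must be non-negative")
    return df.reset_index(drop=True)
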