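"""Spike-in back-normalization: from DNA mass to copies per gram.

The calibration logic: a known number of exogenous DNA molecules is mixed
into each sample's DNA aliquot before library preparation.  After
sequencing, the ratio of known spike copies to observed spike reads is a
per-sample copies-per-read factor; multiplying every endogenous taxon's
read count by it, scaling from the spiked aliquot up to the whole eluate,
and dividing by the sample wet mass yields 16S gene copies per gram.

Mass-to-molecule conversion uses the mean molar mass of double-stranded
DNA, 660 g/mol per base pair:

    copies = mass_ng * N_A / (length_bp * 660 * 1e9)

with N_A = 6.022e23 molecules/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    QC_FAIL_HIGH,
    QC_FAIL_LOW,
    QC_NO_SPIKE,
    QC_PASS,
    SPIKE_FRACTION_HIGH,
    SPIKE_FRACTION_LOW,
    AbsoluteAbundanceMatrix,
    CountMatrix,
    SampleMeta,
    SpikeDose,
    SpikeStrain,
)

AVOGADRO = 6.022e23  # molecules / mole
DSDNA_G_PER_MOL_PER_BP = 660.0  # mean molar mass of one dsDNA base pair
NG_PER_G = 1e9


def copies_from_mass(mass_ng: float, length_bp: float) -> float:
    """Number of dsDNA molecules in ``mass_ng`` ng of DNA of ``length_bp`` bp."""
    if length_bp <= 0:
        raise ValueError(f"length_bp must be > 0, got {length_bp!r}")
    if mass_ng < 0:
        raise ValueError(f"mass_ng must be >= 0, got {mass_ng!r}")
    return mass_ng * AVOGADRO / (length_bp * DSDNA_G_PER_MOL_PER_BP * NG_PER_G)


def spike_dose(strain: SpikeStrain, dose_in_16s_copies: bool = False) -> SpikeDose:
    """Compute the molecule dose contributed by one spike strain.

    With ``dose_in_16s_copies`` the genome-molecule count is multiplied by
    the strain's 16S gene copy number, expressing the dose in 16S gene
    copies rather than genomes.
    """
    mass = strain.mass_ng
    copies = copies_from_mass(mass, strain.reference_length_bp)
    if dose_in_16s_copies:
        copies *= strain.gcn
    return SpikeDose(
        strain=strain, mass_ng=mass, copies_added=copies, zero_dose=copies == 0
    )


def spike_fraction_qc(
    cm: CountMatrix,
    low: float = SPIKE_FRACTION_LOW,
    high: float = SPIKE_FRACTION_HIGH,
) -> pd.DataFrame:
    """Per-sample spike read fraction and QC flag.

    The fraction is total spike reads over total reads; samples outside
    the ``[low, high]`` window are flagged ``fail_low`` / ``fail_high``,
    samples with zero spike reads ``no_spike_reads``.
    """
    if not cm.spike_taxa:
        raise ValueError("count matrix has no spike taxa flagged")
    totals = cm.total_reads()
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"cannot QC samples with zero total reads: {empty}")
    spike = cm.spike_reads().sum(axis=0)
    fraction = spike / totals
    flags = pd.Series(QC_PASS, index=fraction.index, dtype=object)
    flags[fraction < low] = QC_FAIL_LOW
    flags[fraction > high] = QC_FAIL_HIGH
    flags[spike == 0] = QC_NO_SPIKE
    return pd.DataFrame({"spike_fraction": fraction, "qc_flag": flags})


def _meta_by_sample(
    meta: Sequence[SampleMeta], samples: Sequence[str]
) -> dict[str, SampleMeta]:
    lookup = {}
    for m in meta:
        if m.sample_id in lookup:
            raise ValueError(f"duplicate metadata for sample {m.sample_id!r}")
        lookup[m.sample_id] = m
    missing = [s for s in samples if s not in lookup]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing}")
    return lookup


def _strain_reads(cm: CountMatrix, doses: Sequence[SpikeDose]) -> pd.DataFrame:
    """Reads of each dosed strain (strain name x samples)."""
    rows = {}
    for dose in doses:
        label = dose.strain.taxon_label
        if label not in cm.counts.index:
            raise ValueError(f"spike taxon not found: {label!r}")
        rows[dose.strain.name] = cm.counts.loc[label]
    return pd.DataFrame(rows).T


def absolute_abundance(
    cm: CountMatrix,
    meta: Sequence[SampleMeta],
    doses: Sequence[SpikeDose],
    pooling: str = "sum",
    low: float = SPIKE_FRACTION_LOW,
    high: float = SPIKE_FRACTION_HIGH,
) -> AbsoluteAbundanceMatrix:
    """Back-normalize endogenous read counts to 16S gene copies per gram.

    For sample ``s`` with pooled spike reads ``r_s`` and pooled spike
    copies ``C_s``::

        scale_factor(s) = (C_s / r_s) * (elution_volume / spiked_aliquot_volume)
                          / feces_mass
        value(t, s)     = reads(t, s) * scale_factor(s)

    ``pooling="sum"`` pools reads and copies across strains before taking
    the ratio (read-weighted); ``pooling="mean"`` averages the per-strain
    copies-per-read ratios over strains with at least one read.  Samples
    with no usable spike reads are flagged ``no_spike_reads`` and their
    values set to NaN — never imputed.  No pseudocounts are used anywhere.
    """
    if pooling not in ("sum", "mean"):
        raise ValueError(f"pooling must be 'sum' or 'mean', got {pooling!r}")
    if not doses:
        raise ValueError("at least one spike dose is required")
    lookup = _meta_by_sample(meta, cm.samples)
    qc = spike_fraction_qc(cm, low=low, high=high)
    strain_reads = _strain_reads(cm, doses)
    copies = np.array([d.copies_added for d in doses], dtype=float)

    ratios = pd.Series(np.nan, index=cm.samples, dtype=float)
    for s in cm.samples:
        r = strain_reads[s].to_numpy(dtype=float)
        if pooling == "sum":
            if r.sum() > 0:
                ratios[s] = copies.sum() / r.sum()
        else:
            seen = r > 0
            if seen.any():
                ratios[s] = np.mean(copies[seen] / r[seen])

    flags = qc["qc_flag"].copy()
    flags[ratios.isna()] = QC_NO_SPIKE

    phys = pd.Series(
        {
            s: lookup[s].elution_volume_ul
            / lookup[s].spiked_aliquot_volume_ul
            / lookup[s].feces_mass_g
            for s in cm.samples
        }
    )
    scale = ratios * phys
    values = cm.endogenous().astype(float).mul(scale, axis=1)
    values.loc[:, scale.isna()] = np.nan
    return AbsoluteAbundanceMatrix(
        values=values,
        scale_factor=scale,
        spike_fraction=qc["spike_fraction"],
        qc_flag=flags,
        pooling=pooling,
    )


@dataclass
class PoolingDiagnostic:
    """Per-strain total-load estimates and their log-ratio discordance.

    Estimates are at the spiked-aliquot scale (copies per aliquot of total
    endogenous DNA); the discordance ``ln(estimate_strain1 /
    estimate_strain2)`` is independent of the physical per-gram scaling,
    which cancels in the ratio.  Samples where any strain has zero reads
    are flagged and their discordance is NaN.
    """

    per_strain: pd.DataFrame  # strain x sample estimates
    pooled: pd.Series  # sum-pooled estimate per sample
    discordance: pd.Series  # ln(first / second strain estimate)
    flagged: pd.Series  # True where a strain had zero reads


def pooling_diagnostic(
    cm: CountMatrix, doses: Sequence[SpikeDose]
) -> PoolingDiagnostic:
    """Compare total-load estimates from each spike strain independently."""
    if len(doses) < 2:
        raise ValueError("pooling diagnostic requires >=2 strains")
    strain_reads = _strain_reads(cm, doses)
    endo_total = cm.endogenous().sum(axis=0).astype(float)
    copies = pd.Series(
        {d.strain.name: d.copies_added for d in doses}, dtype=float
    )

    per_strain = pd.DataFrame(index=strain_reads.index, columns=cm.samples, dtype=float)
    for name in strain_reads.index:
        r = strain_reads.loc[name]
        with np.errstate(divide="ignore", invalid="ignore"):
            est = endo_total * copies[name] / r.replace(0, np.nan)
        per_strain.loc[name] = est

    pooled_reads = strain_reads.sum(axis=0)
    pooled = endo_total * copies.sum() / pooled_reads.replace(0, np.nan)

    flagged = (strain_reads == 0).any(axis=0)
    first, second = per_strain.index[0], per_strain.index[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        discordance = np.log(per_strain.loc[first] / per_strain.loc[second])
    discordance[flagged] = np.nan
    return PoolingDiagnostic(
        per_strain=per_strain,
        pooled=pooled,
        discordance=discordance,
        flagged=flagged,
    )


def gcn_correct(
    aam: AbsoluteAbundanceMatrix,
    gcn_table: Mapping[str, float],
    default: float = 1.0,
) -> AbsoluteAbundanceMatrix:
    """Convert the copies-per-gram layer to cells per gram via 16S GCN.

    ``cells(t, s) = copies(t, s) / gcn(t)``.  Taxa absent from the table
    fall back to ``default`` and are recorded in ``gcn_defaulted``.
    """
    for taxon, g in gcn_table.items():
        if g <= 0:
            raise ValueError(f"GCN for {taxon!r} must be > 0, got {g!r}")
    if default <= 0:
        raise ValueError(f"default GCN must be > 0, got {default!r}")
    gcn = pd.Series(
        {t: float(gcn_table.get(t, default)) for t in aam.taxa}, dtype=float
    )
    missing = tuple(t for t in aam.taxa if t not in gcn_table)
    cells = aam.values.div(gcn, axis=0)
    return AbsoluteAbundanceMatrix(
        values=aam.values,
        scale_factor=aam.scale_factor,
        spike_fraction=aam.spike_fraction,
        qc_flag=aam.qc_flag,
        pooling=aam.pooling,
        cells=cells,
        gcn_defaulted=missing,
    )


def spike_load_correlation(
    cm: CountMatrix,
    aam: AbsoluteAbundanceMatrix,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Correlate each spike strain's reads with the estimated total load.

    At a fixed dose and sequencing depth, a sample with a higher total
    load yields a smaller spike read share, so the expected sign is
    negative — a useful sanity diagnostic for a calibrated run.  Uses the
    normality-gated correlation (Pearson when both variables pass
    Shapiro-Wilk at P > 0.05, Spearman otherwise) over QC-passing samples.
    """
    from .stats import gated_correlation

    samples = aam.passing_samples()
    if len(samples) < min_samples:
        raise ValueError(
            f"need >= {min_samples} QC-passing samples, have {len(samples)}"
        )
    totals = aam.total_load()[samples]
    rows = []
    for taxon in cm.spike_taxa:
        reads = cm.counts.loc[taxon, samples].astype(float)
        method, coef, p = gated_correlation(reads.to_numpy(), totals.to_numpy())
        rows.append(
            {"spike_taxon": taxon, "method": method, "coefficient": coef, "p_value": p}
        )
    return pd.DataFrame(rows)
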