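"""Readers and writers for count tables, metadata and spike configuration.

Count tables are dense TSV with taxa as rows and samples as columns
(orientation is auto-detected and transposed when a ``#taxon`` header
sits on the columns); a BIOM-style dense JSON table is also accepted.
Sample metadata is TSV/CSV.  Spike configuration is a single YAML file
holding the strains and the dose conventions.  Every invariant of the
in-memory containers is enforced at read time, so no invalid object can
come out of these functions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .containers import (
    AbsoluteAbundanceMatrix,
    CountMatrix,
    SampleMeta,
    SpikeStrain,
    validate_measurements,
)

_TAXON_HEADERS = {"taxon", "#taxon", "genus", "otu", "asv", "feature", "taxonomy"}
_SAMPLE_HEADERS = {"sample", "#sample", "sample_id"}

META_COLUMNS = [
    "sample_id",
    "group",
    "feces_mass_g",
    "elution_volume_ul",
    "spiked_aliquot_volume_ul",
]


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path,
    spike_labels: Sequence[str] = (),
    allow_empty_samples: bool = False,
) -> CountMatrix:
    """Read a dense taxon x sample TSV (or BIOM-style dense JSON).

    ``spike_labels`` are taxonomy labels to flag as spike-in calibrants;
    a label missing from the table is a hard error.  Non-integer or
    negative cells are rejected with their coordinates.
    """
    path = Path(path)
    if path.suffix == ".json" or path.suffix == ".biom":
        df = _read_biom_dense(path)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        header = str(df.index.name or "").strip().lower()
        if header in _SAMPLE_HEADERS or any(
            str(c).strip().lower() in _TAXON_HEADERS for c in df.columns
        ):
            # taxa were on the columns: transpose to taxa-as-rows
            df = df.T
    df.index = df.index.astype(str)
    df.index.name = "taxon"
    df.columns = df.columns.astype(str)
    return CountMatrix(df, spike_taxa=tuple(spike_labels), allow_empty_samples=allow_empty_samples)


def _read_biom_dense(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise ValueError("only dense BIOM-style JSON tables are supported")
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    return pd.DataFrame(doc["data"], index=taxa, columns=samples)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix as dense TSV; read_count_table round-trips it."""
    cm.counts.rename_axis("taxon").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read per-sample metadata from TSV or CSV.

    Required columns: sample_id, group, feces_mass_g, elution_volume_ul,
    spiked_aliquot_volume_ul (masses in grams, volumes in microlitres).
    Lines starting with ``#`` are comments.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    return [
        SampleMeta(
            sample_id=str(row.sample_id),
            group=str(row.group),
            feces_mass_g=float(row.feces_mass_g),
            elution_volume_ul=float(row.elution_volume_ul),
            spiked_aliquot_volume_ul=float(row.spiked_aliquot_volume_ul),
        )
        for row in df.itertuples()
    ]


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "group": m.group,
                "feces_mass_g": m.feces_mass_g,
                "elution_volume_ul": m.elution_volume_ul,
                "spiked_aliquot_volume_ul": m.spiked_aliquot_volume_ul,
            }
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spike configuration
# ---------------------------------------------------------------------------

def read_spike_config(path: str | Path) -> tuple[list[SpikeStrain], dict]:
    """Read the spike strain configuration (YAML).

    Schema::

        dose_basis: genome | amplicon     # what reference_length_bp means
        dose_in_16s_copies: false         # multiply genome dose by GCN
        spikes:
          - name: ...
            taxon_label: ...
            dna_concentration_ng_per_ul: ...   # ng/uL
            volume_added_ul: ...               # uL
            reference_length_bp: ...           # bp
            gcn: ...                           # 16S copies per genome

    Returns the strains plus an options dict with the dose conventions.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "spikes" not in doc:
        raise ValueError("spike config must contain a 'spikes' list")
    options = {
        "dose_basis": doc.get("dose_basis", "genome"),
        "dose_in_16s_copies": bool(doc.get("dose_in_16s_copies", False)),
    }
    if options["dose_basis"] not in ("genome", "amplicon"):
        raise ValueError(f"dose_basis must be genome|amplicon, got {options['dose_basis']!r}")
    strains = [
        SpikeStrain(
            name=str(entry["name"]),
            taxon_label=str(entry["taxon_label"]),
            dna_concentration_ng_per_ul=float(entry["dna_concentration_ng_per_ul"]),
            volume_added_ul=float(entry["volume_added_ul"]),
            reference_length_bp=float(entry["reference_length_bp"]),
            gcn=float(entry.get("gcn", 1)),
        )
        for entry in doc["spikes"]
    ]
    if not strains:
        raise ValueError("spike config lists no strains")
    return strains, options


def write_spike_config(
    strains: Sequence[SpikeStrain],
    path: str | Path,
    dose_basis: str = "genome",
    dose_in_16s_copies: bool = False,
) -> None:
    doc = {
        "dose_basis": dose_basis,
        "dose_in_16s_copies": dose_in_16s_copies,
        "spikes": [
            {
                "name": s.name,
                "taxon_label": s.taxon_label,
                "dna_concentration_ng_per_ul": s.dna_concentration_ng_per_ul,
                "volume_added_ul": s.volume_added_ul,
                "reference_length_bp": s.reference_length_bp,
                "gcn": s.gcn,
            }
            for s in strains
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# measurements and outputs
# ---------------------------------------------------------------------------

def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return validate_measurements(df)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    validate_measurements(df).to_csv(path, sep="\t", index=False)


def write_abundance_outputs(aam: AbsoluteAbundanceMatrix, outdir: str | Path) -> None:
    """Write absolute_abundance.tsv, scale_factors.tsv and qc_report.txt."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aam.values.rename_axis("taxon").to_csv(outdir / "absolute_abundance.tsv", sep="\t")
    pd.DataFrame(
        {
            "scale_factor_copies_per_read_per_g": aam.scale_factor,
            "spike_fraction": aam.spike_fraction,
            "qc_flag": aam.qc_flag,
        }
    ).rename_axis("sample_id").to_csv(outdir / "scale_factors.tsv", sep="\t")
    if aam.cells is not None:
        aam.cells.rename_axis("taxon").to_csv(outdir / "cells_per_gram.tsv", sep="\t")
    with open(outdir / "qc_report.txt", "w") as fh:
        fh.write("sample\tspike_fraction\tqc_flag\tscale_factor\n")
        for s in aam.samples:
            fh.write(
                f"{s}\t{_sig4(aam.spike_fraction[s])}\t{aam.qc_flag[s]}\t"
                f"{_sig4(aam.scale_factor[s])}\n"
            )


def _sig4(x: float) -> str:
    if x != x:  # NaN
        return "NA"
    return f"{x:.4g}"


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, entries: dict) -> None:
    """Record run parameters and input hashes for reproducibility."""
    with open(Path(outdir) / "run_manifest.json", "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")
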