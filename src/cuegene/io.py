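"""Plain-text (TSV/JSON) readers and writers for all pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CountMatrix, GeneAnnotation
from .physiology import FluxRecord, PhenotypeRecord

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "write_fluxes",
    "read_fluxes",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_metadata",
    "write_matrix",
    "read_matrix",
    "write_json",
]

_FLOAT_FMT = "%.10g"


def read_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Phenotype TSV: sample_id, B0_mg, Bt_mg, t_days, delta_co2_ppm."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "B0_mg", "Bt_mg", "t_days", "delta_co2_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return [
        PhenotypeRecord(
            sample_id=str(r.sample_id),
            B0=float(r.B0_mg),
            Bt=float(r.Bt_mg),
            t=float(r.t_days),
            delta_co2=float(r.delta_co2_ppm),
        )
        for r in df.itertuples()
    ]


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_fluxes(records: list[FluxRecord], path: str | Path) -> None:
    """Flux TSV with semicolon-separated QC flags (empty when clean)."""
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "mu_per_day": [r.mu for r in records],
            "respiration_mmolC_per_day": [r.respiration for r in records],
            "biomass_mmolC": [r.biomass_c for r in records],
            "qco2_per_day": [r.qco2 for r in records],
            "cue": [r.cue for r in records],
            "qc_flags": [";".join(sorted(r.qc_flags)) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_fluxes(path: str | Path) -> list[FluxRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan", ""])
    out = []
    for r in df.itertuples():
        flags = r.qc_flags if isinstance(r.qc_flags, str) else ""
        out.append(
            FluxRecord(
                sample_id=str(r.sample_id),
                mu=float(r.mu_per_day),
                respiration=float(r.respiration_mmolC_per_day),
                biomass_c=float(r.biomass_mmolC),
                qco2=float(r.qco2_per_day),
                cue=float(r.cue),
                qc_flags=frozenset(f for f in flags.split(";") if f),
            )
        )
    return out


def read_counts(counts_path: str | Path, annotation_path: str | Path) -> tuple[CountMatrix, GeneAnnotation]:
    """Counts TSV (gene_id + sample columns) with companion annotation TSV.

    The annotation table carries gene_id, length_bp and ec_numbers
    (comma-separated, possibly empty).
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    annot_df = pd.read_csv(annotation_path, sep="\t", dtype={"ec_numbers": str})
    annot_df = annot_df.set_index("gene_id")
    lengths = annot_df["length_bp"].astype(float)
    lengths.name = "length_bp"
    ecs = {
        str(gene): [e for e in str(row).split(",") if e and e != "nan"]
        for gene, row in annot_df["ec_numbers"].fillna("").items()
    }
    cm = CountMatrix(counts=counts, gene_lengths=lengths)
    return cm, GeneAnnotation(ecs)


def write_counts(
    counts: CountMatrix,
    annot: GeneAnnotation,
    counts_path: str | Path,
    annotation_path: str | Path,
) -> None:
    df = counts.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(counts_path, sep="\t")
    annot_df = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "length_bp": counts.gene_lengths.astype(int).to_numpy(),
            "ec_numbers": [
                ",".join(annot.ec_numbers.get(g, [])) for g in counts.gene_ids
            ],
        }
    )
    annot_df.to_csv(annotation_path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "isolate", "medium"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    return df


def write_matrix(mat: pd.DataFrame, path: str | Path, index_name: str) -> None:
    out = mat.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
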