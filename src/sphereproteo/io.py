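"""Readers/writers for the tabular dialects used by the pipeline arms.

All tables are UTF-8 TSV with "." decimal. Intensity columns follow the
upstream search-software convention that 0 means "not quantified" and is
read as missing. Flag columns (contaminant / reverse /
only_identified_by_site) use the "+" convention. Every writer embeds the
thresholds/parameters of the producing step as ``# key=value`` header
comment lines for provenance; readers skip such lines.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .datatypes import ExpressionMatrix, Peptide, FLAG_COLUMNS

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def write_table(
    df: pd.DataFrame, path: PathLike, params: Optional[Mapping] = None, index: bool = False
) -> None:
    """Write a TSV with ``# key=value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (params or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: PathLike, **kwargs) -> pd.DataFrame:
    """Read a provenance-header TSV."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_table_params(path: PathLike) -> dict:
    """Recover the ``# key=value`` provenance header of a TSV."""
    params = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            params[key.strip()] = value
    return params


def _parse_flag(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip().eq("+")


# ---------------------------------------------------------------------------
# Expression matrices (TMT arm)
# ---------------------------------------------------------------------------

def write_expression_matrix(
    matrix: ExpressionMatrix, directory: PathLike, params: Optional[Mapping] = None
) -> None:
    """Write matrix.tsv (values + flags + keywords) and design.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = matrix.values.copy()
    out.insert(0, "feature_id", out.index)
    for col in FLAG_COLUMNS:
        out[col] = np.where(matrix.flags[col], "+", "")
    out["keywords"] = [
        ";".join(sorted(matrix.annotations.get(f, set()))) for f in matrix.values.index
    ]
    write_table(out, directory / "matrix.tsv", params=params)
    design = matrix.design.copy()
    design.insert(0, "sample_id", design.index)
    write_table(design, directory / "design.tsv", params=params)


def read_protein_table(
    path: PathLike, design: Union[pd.DataFrame, PathLike]
) -> ExpressionMatrix:
    """Read a protein-level intensity TSV into an :class:`ExpressionMatrix`.

    The design (DataFrame or design.tsv path, indexed by sample id) names
    the intensity columns. Zeros are read as missing; non-numeric intensity
    cells become missing with a logged count; a duplicated feature id is an
    error.
    """
    if not isinstance(design, pd.DataFrame):
        design = read_table(design).set_index("sample_id").rename_axis(None)
    raw = read_table(path, dtype=str)
    if "feature_id" not in raw.columns:
        raise ValueError("missing mandatory column: feature_id")
    missing_samples = [s for s in design.index if s not in raw.columns]
    if missing_samples:
        raise ValueError(f"missing mandatory sample columns: {missing_samples}")
    if raw["feature_id"].duplicated().any():
        dupes = raw.loc[raw["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicated feature id(s): {dupes}")
    raw = raw.set_index("feature_id").rename_axis(None)
    sample_cols = list(design.index)
    values = raw[sample_cols].apply(pd.to_numeric, errors="coerce")
    n_malformed = int((values.isna() & raw[sample_cols].notna() & raw[sample_cols].ne("")).sum().sum())
    if n_malformed:
        log.warning("%d malformed numeric cells read as missing", n_malformed)
    values = values.mask(values == 0.0)  # 0 = not quantified in this dialect
    flags = pd.DataFrame(index=raw.index)
    for col in FLAG_COLUMNS:
        flags[col] = _parse_flag(raw[col]) if col in raw.columns else False
    annotations = {}
    if "keywords" in raw.columns:
        for fid, cell in raw["keywords"].fillna("").items():
            annotations[fid] = {k for k in str(cell).split(";") if k}
    for col in ("timepoint_days", "channel", "replicate"):
        if col in design.columns:
            design[col] = pd.to_numeric(design[col])
    return ExpressionMatrix(values=values, design=design, flags=flags, annotations=annotations)


# ---------------------------------------------------------------------------
# Phosphosite tables
# ---------------------------------------------------------------------------

SITE_META_COLUMNS = (
    "site_id",
    "protein_id",
    "position",
    "residue",
    "localization_probability",
    "sequence_window",
)


def write_site_table(sites: pd.DataFrame, path: PathLike, params: Optional[Mapping] = None) -> None:
    write_table(sites.reset_index(drop=True), path, params=params)


def read_site_table(path: PathLike) -> pd.DataFrame:
    """Read a phosphosite table with ``___m`` multiplicity ratio columns.

    Validates presence of the site metadata columns, odd sequence-window
    length, and agreement between the window's central residue and the
    site residue.
    """
    df = read_table(path)
    missing = [c for c in SITE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    for flag in ("contaminant", "reverse"):
        if flag in df.columns and df[flag].dtype == object:
            df[flag] = _parse_flag(df[flag])
    windows = df["sequence_window"].astype(str)
    lengths = windows.str.len()
    if (lengths % 2 == 0).any():
        raise ValueError("sequence windows must have odd length")
    centers = windows.str[lengths.iloc[0] // 2] if lengths.nunique() == 1 else windows.apply(
        lambda w: w[len(w) // 2]
    )
    bad = centers != df["residue"].astype(str)
    if bad.any():
        raise ValueError(
            f"window center mismatch for {df.loc[bad, 'site_id'].tolist()[:5]}"
        )
    df["position"] = df["position"].astype(int)
    df["localization_probability"] = df["localization_probability"].astype(float)
    return df.set_index("site_id", drop=False).rename_axis(None)


# ---------------------------------------------------------------------------
# SILAC records, peptides, predictions, FASTA
# ---------------------------------------------------------------------------

def write_silac_table(records: pd.DataFrame, path: PathLike, params: Optional[Mapping] = None) -> None:
    write_table(records, path, params=params)


def read_silac_table(path: PathLike) -> pd.DataFrame:
    df = read_table(path)
    required = ["feature_id", "construct", "replicate", "light", "heavy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    df["replicate"] = df["replicate"].astype(int)
    for col in ("light", "heavy"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


PEPTIDE_COLUMNS = ("protein_id", "start", "end", "specificity", "retention_time", "intensity")


def write_peptides(peptides, path: PathLike, params: Optional[Mapping] = None) -> None:
    rows = [
        {
            "protein_id": p.protein_id,
            "start": p.start,
            "end": p.end,
            "specificity": p.specificity,
            "retention_time": p.retention_time,
            "intensity": p.intensity,
        }
        for p in peptides
    ]
    write_table(pd.DataFrame(rows, columns=list(PEPTIDE_COLUMNS)), path, params=params)


def read_peptides(path: PathLike) -> list[Peptide]:
    df = read_table(path)
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    return [
        Peptide(
            protein_id=str(r.protein_id),
            start=int(r.start),
            end=int(r.end),
            specificity=str(r.specificity),
            retention_time=float(r.retention_time),
            intensity=float(r.intensity),
        )
        for r in df.itertuples()
    ]


def read_predicted_sites(path: PathLike) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in ("position", "score", "p_value") if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    df["position"] = df["position"].astype(int)
    return df


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Config and manifests
# ---------------------------------------------------------------------------

def read_config(path: PathLike) -> dict:
    """YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_manifest(directory: PathLike, manifest: Mapping) -> Path:
    """Machine-readable run manifest (inputs, thresholds, seed, version)."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = dict(manifest)
    payload.setdefault("package_version", __version__)
    out = directory / "manifest.json"
    out.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return out
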