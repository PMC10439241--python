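"""Dimethyl phosphoproteomics arm.

Site tables carry one row per phosphosite with a localization probability,
a +/-15 residue sequence window, and per-comparison, per-replicate log2
ratio columns suffixed ``___m`` for the peptide multiplicity m in {1,2,3}
(the number of phosphate groups on the quantified peptide). The pipeline
filters to class I sites, splits multiplicities into separate rows, calls
regulation with the both-replicate +/-1 log2 cutoff, and runs keyword and
position-frequency motif analyses.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .config import PHOSPHO_COMPARISONS

RATIO_RE = re.compile(r"^ratio_(?P<comparison>.+)_r(?P<replicate>\d+)___(?P<mult>[123])$")


def ratio_columns(df: pd.DataFrame) -> list[dict]:
    """Parse the multiplicity-suffixed ratio columns of a site table."""
    cols = []
    for col in df.columns:
        m = RATIO_RE.match(str(col))
        if m:
            cols.append(
                {
                    "column": col,
                    "comparison": m["comparison"],
                    "replicate": int(m["replicate"]),
                    "multiplicity": int(m["mult"]),
                }
            )
    return cols


def filter_class1(records: pd.DataFrame, threshold: float = 0.75) -> pd.DataFrame:
    """Keep class I sites: localization probability >= threshold.

    Contaminant/reverse-flagged rows are removed first. The boundary is
    inclusive, so a site at exactly 0.75 is retained while 0.7499 is not.
    """
    prob = records["localization_probability"].astype(float)
    if ((prob < 0) | (prob > 1)).any():
        raise ValueError("localization probabilities must lie in [0, 1]")
    out = records
    for flag in ("contaminant", "reverse"):
        if flag in out.columns:
            out = out[~out[flag].astype(bool)]
    return out[out["localization_probability"].astype(float) >= threshold].copy()


def split_multiplicity(records: pd.DataFrame) -> pd.DataFrame:
    """Expand each site into one row per quantified multiplicity.

    Output rows carry ``ratio_<comparison>_r<rep>`` columns for their own
    multiplicity only; (site, multiplicity) combinations without any ratio
    value are dropped. Ratio values are never altered, only reshaped.
    """
    cols = ratio_columns(records)
    if not cols:
        raise ValueError("no multiplicity-suffixed ratio columns found")
    mults = sorted({c["multiplicity"] for c in cols})
    meta_cols = [c for c in records.columns if not RATIO_RE.match(str(c))]
    out_rows = []
    for _, row in records.iterrows():
        for m in mults:
            sub = {c["column"]: row[c["column"]] for c in cols if c["multiplicity"] == m}
            if not any(pd.notna(v) for v in sub.values()):
                continue
            new = {mc: row[mc] for mc in meta_cols}
            new["multiplicity"] = m
            for c in cols:
                if c["multiplicity"] == m:
                    new[f"ratio_{c['comparison']}_r{c['replicate']}"] = row[c["column"]]
            out_rows.append(new)
    out = pd.DataFrame(out_rows).reset_index(drop=True)
    if len(out):
        base = (
            out["site_id"].astype(str)
            if "site_id" in out.columns
            else out["protein_id"].astype(str) + "_" + out["position"].astype(int).astype(str)
        )
        out["site_mult_id"] = base + "_m" + out["multiplicity"].astype(str)
    return out


def call_regulated(
    records: pd.DataFrame,
    cutoff: float = 1.0,
    comparisons: Sequence[str] = PHOSPHO_COMPARISONS,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Both-replicate regulation calls on multiplicity-split records.

    A (site, multiplicity) is ``up`` in a comparison iff every replicate
    log2 ratio is present and >= cutoff, ``down`` iff every one is
    <= -cutoff, otherwise ``ns``.
    """
    rows = []
    for _, row in records.iterrows():
        for comp in comparisons:
            ratios = [
                row.get(f"ratio_{comp}_r{rep}", np.nan)
                for rep in range(1, n_replicates + 1)
            ]
            arr = np.asarray(ratios, dtype=float)
            if np.isfinite(arr).all() and (arr >= cutoff).all():
                call = "up"
            elif np.isfinite(arr).all() and (arr <= -cutoff).all():
                call = "down"
            else:
                call = "ns"
            rows.append(
                {
                    "site_mult_id": row.get("site_mult_id"),
                    "protein_id": row["protein_id"],
                    "position": row["position"],
                    "multiplicity": row.get("multiplicity"),
                    "comparison": comp,
                    "call": call,
                    **{f"ratio_r{i + 1}": ratios[i] for i in range(n_replicates)},
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["cutoff"] = cutoff
    return out


def keyword_enrichment(
    calls: pd.DataFrame,
    records: pd.DataFrame,
    annotation_map: Mapping,
    fdr: float = 0.02,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Fisher keyword enrichment of proteins bearing regulated sites.

    For every (comparison, direction), proteins with at least one regulated
    site are tested against all proteins in the dataset; a protein counts
    once regardless of its number of sites. Terms are filtered at the BH
    ``fdr`` threshold.
    """
    background = set(records["protein_id"])
    if not background:
        raise ValueError("empty background")
    out = {}
    for comp in calls["comparison"].unique():
        for direction in ("up", "down"):
            sel = calls[(calls["comparison"] == comp) & (calls["call"] == direction)]
            proteins = set(sel["protein_id"])
            if not proteins:
                out[(comp, direction)] = pd.DataFrame()
                continue
            enr = stats.fisher_enrichment(proteins, background, annotation_map)
            out[(comp, direction)] = enr[enr["q_value"] < fdr].reset_index(drop=True)
    return out


def motif_analysis(
    foreground_windows: Iterable[str],
    background_windows: Iterable[str],
    half_width: int = 6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Position-wise residue frequency differences with two-proportion tests.

    For each position in -half_width..+half_width (0 = the phosphosite) and
    each residue, reports foreground minus background relative frequency and
    a two-sided two-proportion z-test p-value; cells with p < alpha are
    flagged significant.
    """
    fg = [str(w) for w in foreground_windows]
    bg = [str(w) for w in background_windows]
    if not fg or not bg:
        raise ValueError("foreground and background windows must be non-empty")
    lengths = {len(w) for w in fg} | {len(w) for w in bg}
    if len(lengths) != 1:
        raise ValueError("all windows must have equal length")
    length = lengths.pop()
    if length % 2 == 0:
        raise ValueError("windows must have odd length (centered on the site)")
    center = length // 2
    if half_width > center:
        raise ValueError(f"half_width {half_width} exceeds window half-length {center}")
    n_fg, n_bg = len(fg), len(bg)
    rows = []
    for offset in range(-half_width, half_width + 1):
        idx = center + offset
        fg_counts: dict[str, int] = {}
        bg_counts: dict[str, int] = {}
        for w in fg:
            fg_counts[w[idx]] = fg_counts.get(w[idx], 0) + 1
        for w in bg:
            bg_counts[w[idx]] = bg_counts.get(w[idx], 0) + 1
        for residue in sorted(set(fg_counts) | set(bg_counts)):
            k1 = fg_counts.get(residue, 0)
            k2 = bg_counts.get(residue, 0)
            p1, p2 = k1 / n_fg, k2 / n_bg
            pooled = (k1 + k2) / (n_fg + n_bg)
            se = np.sqrt(pooled * (1 - pooled) * (1 / n_fg + 1 / n_bg))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (p1 - p2) / se
                p = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {
                    "position": offset,
                    "residue": residue,
                    "freq_foreground": p1,
                    "freq_background": p2,
                    "difference": p1 - p2,
                    "z": float(z),
                    "p_value": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def match_sites(records_a: pd.DataFrame, records_b: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two site tables on (protein, position).

    Multiplicities are collapsed before matching, so a site quantified at
    several multiplicities contributes one matched pair.
    """
    a = records_a[["protein_id", "position"]].drop_duplicates()
    b = records_b[["protein_id", "position"]].drop_duplicates()
    return a.merge(b, on=["protein_id", "position"]).reset_index(drop=True)
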