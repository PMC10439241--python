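"""SILAC BioID interactome arm.

Records are long tables with columns feature_id / construct / replicate /
light / heavy (log2 intensities; NaN = not quantified). Two strictly
ordered imputation paths exist, mirroring the published pipeline order:
"min" imputation feeds only the light/heavy biotinylation-ratio calls,
while the construct-vs-construct moderated tests start from the
*non-imputed* light intensities, normalize them (cyclic LOESS for protein
tables, RLR for phosphosite tables) and then apply "MinProp" imputation.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import stats
from .config import CONSTRUCTS

REQUIRED_COLUMNS = ("feature_id", "construct", "replicate", "light", "heavy")


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"SILAC records missing columns: {missing}")


def filter_valid(records: pd.DataFrame, min_valid: int = 2) -> pd.DataFrame:
    """Keep features with >= min_valid observed light intensities in at
    least one construct group."""
    _check_records(records)
    if min_valid <= 0:
        return records.copy()
    counts = (
        records.dropna(subset=["light"])
        .groupby(["feature_id", "construct"])
        .size()
        .groupby("feature_id")
        .max()
    )
    keep = set(counts.index[counts >= min_valid])
    return records[records["feature_id"].isin(keep)].copy()


def light_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot to features x (construct, replicate) light intensities."""
    _check_records(records)
    wide = records.pivot_table(
        index="feature_id",
        columns=["construct", "replicate"],
        values="light",
        aggfunc="first",
        dropna=False,
    )
    wide.columns = [f"{c}_r{r}" for c, r in wide.columns]
    return wide


def call_biotinylated(records: pd.DataFrame, ratio_cutoff: float = 1.0, min_hits: int = 2) -> pd.DataFrame:
    """Biotinylation calls from light/heavy ratios after "min" imputation.

    Missing light values are imputed with the lowest observed light value in
    any sample; a ratio exists only where the heavy (control) value is
    present. A feature is called for a construct iff at least ``min_hits``
    replicate log2 ratios exceed ``ratio_cutoff`` in that construct.
    Returns one row per feature with a boolean column per construct and the
    called construct set.
    """
    _check_records(records)
    rec = records.copy()
    light_min = rec["light"].min(skipna=True)
    if not np.isfinite(light_min):
        raise ValueError("no observed light intensities to impute from")
    rec["light_imputed"] = rec["light"].fillna(light_min)
    rec["ratio"] = np.where(
        rec["heavy"].notna(), rec["light_imputed"] - rec["heavy"], np.nan
    )
    constructs = [c for c in CONSTRUCTS if c in set(rec["construct"])] or sorted(
        rec["construct"].unique()
    )
    hits = (
        rec.assign(hit=lambda d: d["ratio"] > ratio_cutoff)
        .groupby(["feature_id", "construct"])["hit"]
        .sum()
        .unstack(fill_value=0)
    )
    out = pd.DataFrame(index=hits.index)
    for c in constructs:
        out[c] = hits.get(c, 0) >= min_hits
    out["constructs_called"] = out[constructs].apply(
        lambda r: ",".join([c for c in constructs if r[c]]), axis=1
    )
    out["called"] = out[constructs].any(axis=1)
    return out


def differential_constructs(
    records: pd.DataFrame,
    pair: Sequence[str],
    fc_cut: float = 0.58,
    q_cut: float = 0.05,
    level: str = "protein",
    minprop: float = 1.0,
    trend: bool = True,
    min_valid: int = 2,
) -> pd.DataFrame:
    """Moderated t-test between two constructs' light channels.

    Non-imputed light intensities of all constructs are normalized together
    (cyclic LOESS for ``level='protein'``, robust linear regression for
    ``level='site'``), missing values are then MinProp-imputed, and the two
    constructs compared with an intensity-trended empirical-Bayes moderated
    t-test. Significant iff BH q < q_cut and |log2 FC| > fc_cut.

    Only features with at least ``min_valid`` observed (non-imputed) light
    values in one of the two compared constructs are tested: features seen
    solely in other constructs carry no information about this pair and
    their fully/mostly imputed rows would otherwise contaminate the
    variance-prior estimate.
    """
    _check_records(records)
    a, b = pair
    present = set(records["construct"])
    if a not in present or b not in present:
        raise ValueError(f"constructs {pair} not both present in records")
    wide = light_matrix(records)
    if level == "protein":
        norm = stats.cyclic_loess_normalize(wide)
    elif level == "site":
        norm = stats.rlr_normalize(wide)
    else:
        raise ValueError("level must be 'protein' or 'site'")
    cols_a = [c for c in norm.columns if c.startswith(f"{a}_r")]
    cols_b = [c for c in norm.columns if c.startswith(f"{b}_r")]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"need >= 2 replicates per construct, got {len(cols_a)}/{len(cols_b)}")
    sub = norm[cols_a + cols_b]
    enough = (sub[cols_a].notna().sum(axis=1) >= min_valid) | (
        sub[cols_b].notna().sum(axis=1) >= min_valid
    )
    sub = sub[enough]
    imputed = stats.impute_minprop(sub, proportion=minprop)
    design = np.column_stack(
        [np.ones(len(cols_a) + len(cols_b)), [1.0] * len(cols_a) + [0.0] * len(cols_b)]
    )
    res = stats.moderated_t_test(imputed, design, contrast=[0.0, 1.0], trend=trend)
    res = res.rename(columns={"estimate": "log2_fc"})
    res["significant"] = (res["q_value"] < q_cut) & (res["log2_fc"].abs() > fc_cut)
    res.attrs["pair"] = (a, b)
    res.attrs["fc_cut"] = fc_cut
    res.attrs["q_cut"] = q_cut
    return res


def ora(
    feature_set: Iterable,
    background: Iterable,
    annotation_map: Mapping,
    fdr_cut: float = 0.2,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Over-representation analysis with explicit background choice.

    One-sided (enrichment) Fisher tests, filtered at BH FDR < fdr_cut and
    p < p_cut. The background is the caller's choice: a global proteome
    background for classifying biotinylated proteins, or all biotinylated
    proteins as local background for construct comparisons. Features with
    several phosphosites must be collapsed to proteins first (each protein
    counts once).
    """
    rows = stats.fisher_enrichment(
        feature_set, background, annotation_map, alternative="greater"
    )
    if not len(rows):
        return rows
    return rows[(rows["q_value"] < fdr_cut) & (rows["p_value"] < p_cut)].reset_index(
        drop=True
    )


def simplify_terms(
    rows: pd.DataFrame,
    term_feature_sets: Mapping[str, set],
    jaccard_cut: float = 0.7,
) -> pd.DataFrame:
    """Collapse redundant terms by Jaccard similarity of their feature sets.

    Terms are visited in ascending adjusted-p (ties broken by term id);
    a term is dropped if its feature set has Jaccard similarity >
    ``jaccard_cut`` with an already retained (smaller adjusted-p) term.
    A single greedy pass in this order is a fixpoint.
    """
    if not len(rows):
        return rows.copy()
    ordered = rows.sort_values(["q_value", "term"], kind="mergesort")
    kept: list[str] = []
    for term in ordered["term"]:
        members = set(term_feature_sets.get(term, set()))
        redundant = False
        for other in kept:
            o = set(term_feature_sets.get(other, set()))
            union = members | o
            if union and len(members & o) / len(union) > jaccard_cut:
                redundant = True
                break
        if not redundant:
            kept.append(term)
    return ordered[ordered["term"].isin(kept)].reset_index(drop=True)
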