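"""TMT whole-proteome time-course arm.

Order of operations: contaminant/reverse filtering, per-plex cyclic LOESS
normalization, per-protein batch-effect regression across plexes, paired
t-tests of each day against day 0 (complete plex pairs only, no
imputation), BH adjustment within each comparison, fold-change/q-value
calls, z-scored mean profiles, complete-linkage Spearman clustering, and
per-cluster term enrichment against the full filtered dataset.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import stats
from .datatypes import ExpressionMatrix

log = logging.getLogger(__name__)


def filter_features(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove contaminant- and reverse-flagged features (counts logged)."""
    flags = matrix.flags
    n_cont = int(flags["contaminant"].sum())
    n_rev = int(flags["reverse"].sum())
    keep = ~(flags["contaminant"] | flags["reverse"])
    log.info("filter_features: removed %d contaminant, %d reverse", n_cont, n_rev)
    out = matrix.subset_features(matrix.feature_ids[keep])
    return out


def normalize(matrix: ExpressionMatrix, span: float = 0.7, n_cycles: int = 3) -> ExpressionMatrix:
    """Cyclic LOESS normalization applied within each plex separately."""
    values = matrix.values.copy()
    for plex, sub in matrix.design.groupby("plex_id"):
        cols = [c for c in values.columns if c in sub.index]
        if len(cols) < 2:
            log.warning("plex %s has %d sample(s); LOESS skipped", plex, len(cols))
            continue
        values[cols] = stats.cyclic_loess_normalize(values[cols], span=span, n_cycles=n_cycles)
    return matrix.with_values(values)


def correct_batch(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-protein regression removal of between-plex batch offsets."""
    design = matrix.design.loc[matrix.values.columns]
    corrected = stats.remove_batch_effects(
        matrix.values, design["plex_id"].to_numpy(), design["timepoint_days"].to_numpy()
    )
    return matrix.with_values(corrected)


def run_differential(
    matrix: ExpressionMatrix,
    q_threshold: float = 0.05,
    fc_threshold: float = 2.0,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Paired day-d vs day-0 tests per feature, BH within each comparison.

    A valid pair is a plex in which both the day-d and day-0 value are
    present; features with fewer than ``min_pairs`` such pairs are excluded
    from that comparison (no imputation). ``call`` is ``up`` iff
    q < q_threshold and log2_fc >= log2(fc_threshold), symmetric for
    ``down``.
    """
    design = matrix.design.loc[matrix.values.columns]
    days = sorted(design["timepoint_days"].unique())
    baseline = days[0]
    if len(days) < 2:
        raise ValueError("no non-baseline day to compare against")
    lfc_cut = float(np.log2(fc_threshold))
    results = []
    plexes = sorted(design["plex_id"].unique())
    base_cols = {
        p: design.index[(design["plex_id"] == p) & (design["timepoint_days"] == baseline)][0]
        for p in plexes
        if ((design["plex_id"] == p) & (design["timepoint_days"] == baseline)).any()
    }
    for day in days[1:]:
        comparison = f"day{day}_vs_day{baseline}"
        day_cols, ref_cols = [], []
        for p in plexes:
            sel = design.index[(design["plex_id"] == p) & (design["timepoint_days"] == day)]
            if len(sel) and p in base_cols:
                day_cols.append(sel[0])
                ref_cols.append(base_cols[p])
        x = matrix.values[day_cols].to_numpy(dtype=float)
        y = matrix.values[ref_cols].to_numpy(dtype=float)
        rows = []
        for i, fid in enumerate(matrix.feature_ids):
            res = stats.paired_t_test(x[i], y[i])
            if res is None or res.n_valid < min_pairs:
                continue
            rows.append(
                {
                    "feature_id": fid,
                    "comparison": comparison,
                    "log2_fc": res.estimate,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n_pairs": res.n_valid,
                }
            )
        comp = pd.DataFrame(rows)
        if len(comp):
            comp["q_value"] = stats.benjamini_hochberg(comp["p_value"].to_numpy())
            comp["call"] = "ns"
            comp.loc[
                (comp["q_value"] < q_threshold) & (comp["log2_fc"] >= lfc_cut), "call"
            ] = "up"
            comp.loc[
                (comp["q_value"] < q_threshold) & (comp["log2_fc"] <= -lfc_cut), "call"
            ] = "down"
        results.append(comp)
    out = pd.concat(results, ignore_index=True) if results else pd.DataFrame()
    out.attrs["q_threshold"] = q_threshold
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["min_pairs"] = min_pairs
    return out


def zscore_profiles(matrix: ExpressionMatrix, feature_ids) -> pd.DataFrame:
    """Per-day mean log2 intensities across plexes, z-scored per feature."""
    design = matrix.design.loc[matrix.values.columns]
    days = sorted(design["timepoint_days"].unique())
    means = pd.DataFrame(index=pd.Index(feature_ids), columns=days, dtype=float)
    for day in days:
        cols = design.index[design["timepoint_days"] == day]
        means[day] = matrix.values.loc[means.index, cols].mean(axis=1)
    centered = means.sub(means.mean(axis=1), axis=0)
    sd = means.std(axis=1, ddof=1)
    z = centered.div(sd.replace(0.0, np.nan), axis=0)
    z[sd == 0.0] = 0.0
    return z


def profile_and_cluster(
    matrix: ExpressionMatrix,
    calls: pd.DataFrame,
    k: int = 7,
    q_threshold: Optional[float] = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster z-scored mean profiles of significantly regulated features.

    Features with q below the threshold in at least one comparison enter
    complete-linkage clustering on Spearman correlation distance; returns
    (cluster assignments, z-profiles).
    """
    if q_threshold is None:
        q_threshold = calls.attrs.get("q_threshold", 0.05)
    sig = calls.loc[calls["q_value"] < q_threshold, "feature_id"].unique()
    if len(sig) < k:
        raise ValueError(
            f"only {len(sig)} significant features but k={k}; choose a smaller k"
        )
    z = zscore_profiles(matrix, sig)
    assignments = stats.hierarchical_cluster(z, k=k)
    return assignments, z


def silhouette_scan(z: pd.DataFrame, k_range=range(2, 13)) -> pd.Series:
    """Mean silhouette width (Spearman distance) per candidate k."""
    from sklearn.metrics import silhouette_score

    dist = stats.spearman_distance_matrix(z)
    out = {}
    for k in k_range:
        if k >= len(z):
            continue
        labels = stats.hierarchical_cluster(z, k=k)
        if labels.nunique() < 2:
            continue
        out[k] = float(silhouette_score(dist, labels.to_numpy(), metric="precomputed"))
    return pd.Series(out, name="mean_silhouette")


def cluster_enrichment(
    assignments: pd.Series,
    annotation_map: Mapping,
    background,
) -> dict[int, pd.DataFrame]:
    """Per-cluster Fisher term enrichment with the full filtered dataset as
    background. Empty clusters are skipped with a warning."""
    if assignments.empty:
        raise ValueError("empty cluster assignments")
    out = {}
    for cluster in sorted(assignments.unique()):
        members = assignments.index[assignments == cluster]
        if len(members) == 0:
            warnings.warn(f"cluster {cluster} is empty; skipped", RuntimeWarning)
            continue
        out[int(cluster)] = stats.fisher_enrichment(members, background, annotation_map)
    return out


def keyword_profiles(
    matrix: ExpressionMatrix,
    keyword: str,
    annotation_map: Optional[Mapping] = None,
    top_n: int = 10,
) -> dict:
    """Mean log2 fold change vs day 0 per day for features carrying a keyword.

    Returns the per-feature fold-change series plus the ``top_n`` most up-
    and down-regulated features at the final day (by signed value).
    """
    annotations = annotation_map if annotation_map is not None else matrix.annotations
    members = [f for f in matrix.feature_ids if keyword in annotations.get(f, set())]
    if not members:
        warnings.warn(f"keyword {keyword!r} matches no features", RuntimeWarning)
        return {"fold_changes": pd.DataFrame(), "top_up": [], "top_down": []}
    design = matrix.design.loc[matrix.values.columns]
    days = sorted(design["timepoint_days"].unique())
    baseline = days[0]
    plexes = sorted(design["plex_id"].unique())
    fc = pd.DataFrame(index=pd.Index(members), columns=days, dtype=float)
    for day in days:
        diffs = []
        for p in plexes:
            dsel = design.index[(design["plex_id"] == p) & (design["timepoint_days"] == day)]
            bsel = design.index[
                (design["plex_id"] == p) & (design["timepoint_days"] == baseline)
            ]
            if len(dsel) and len(bsel):
                diffs.append(
                    matrix.values.loc[members, dsel[0]] - matrix.values.loc[members, bsel[0]]
                )
        fc[day] = pd.concat(diffs, axis=1).mean(axis=1) if diffs else np.nan
    final = fc[days[-1]].dropna().sort_values()
    top_up = list(final.index[::-1][:top_n])
    top_down = list(final.index[:top_n])
    return {"fold_changes": fc, "top_up": top_up, "top_down": top_down}
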