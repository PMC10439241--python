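"""Synthetic data with known ground truth for all four pipeline arms.

The generators emulate the statistical structure the downstream analyses
assume: cluster-structured temporal archetypes with per-plex batch offsets
(TMT arm), two-replicate three-channel phosphosite ratio tables with
multiplicities and localization probabilities (dimethyl arm),
construct-specific SILAC enrichment with left-censored missingness (BioID
arm), and semi-tryptic peptide ladders in which in-source fragments co-elute
with their parent peptide while true proteolytic products elute apart
(cleavage arm). Noise is Normal on the log2 scale throughout.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as pt_parser

from .config import CONSTRUCTS, PHOSPHO_COMPARISONS, SimConfig
from .datatypes import ExpressionMatrix, Peptide, TruthTable

AMINO_ACIDS = "ACDEFGHILMNQSTVWY"  # placement pool without K/R/P (added explicitly)

# ---------------------------------------------------------------------------
# TMT time-course arm
# ---------------------------------------------------------------------------

#: Seven temporal archetypes, each a smooth profile over normalized time
#: (anchor values at t = 0, 0.2, ..., 1; linear interpolation in between),
#: mirroring the cluster shapes a differentiation time course produces:
#: sustained monotone trends, early responses with gradual decay, and
#: transient mid-course regulation. Differentiation is a continuous process
#: sampled every third day, so profiles are autocorrelated rather than
#: single-day spikes, and all seven have distinct day-mean rank orders so
#: that rank-correlation clustering can tell them apart.
ARCHETYPE_TIMES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
ARCHETYPES = {
    1: ("monotone_up", np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])),
    2: ("monotone_down", np.array([0.0, -0.2, -0.4, -0.6, -0.8, -1.0])),
    3: ("early_peak", np.array([0.0, 1.0, 0.85, 0.7, 0.55, 0.45])),
    4: ("early_dip", np.array([0.0, -1.0, -0.85, -0.7, -0.55, -0.45])),
    5: ("mid_peak", np.array([0.0, 0.3, 0.75, 1.0, 0.7, 0.35])),
    6: ("mid_dip", np.array([0.0, -0.3, -0.75, -1.0, -0.7, -0.35])),
    7: ("down_then_up", np.array([0.0, -0.45, -0.8, -0.5, 0.3, 1.0])),
}


def archetype_profile(archetype: int, timepoints: Sequence[int]) -> np.ndarray:
    """Archetype shape evaluated at ``timepoints`` (anchored to 0 at the
    first time point, maximum absolute value 1)."""
    t = np.asarray(timepoints, dtype=float)
    t = (t - t.min()) / (t.max() - t.min())
    _, anchors = ARCHETYPES[archetype]
    shape = np.interp(t, ARCHETYPE_TIMES, anchors)
    peak = np.abs(shape).max()
    if peak > 0:
        shape = shape / peak
    return shape


def simulate_tmt(config: SimConfig) -> tuple[ExpressionMatrix, TruthTable]:
    """Simulate a multi-plex TMT differentiation time course.

    One plex carries all time points of one biological replicate and an
    additive Normal(0, batch_sd) offset shared by its channels. Regulated
    features follow one of seven temporal archetypes scaled to
    ``effect_log2``; values are missing completely at random.
    """
    rng = config.rng()
    n = config.n_features
    days = config.timepoints_days
    n_reg = config.n_regulated

    feature_ids = [f"P{i:05d}" for i in range(n)]
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    archetypes = np.zeros(n, dtype=int)
    if n_reg:
        archetypes[:n_reg] = rng.integers(1, len(ARCHETYPES) + 1, size=n_reg)
    batch_offsets = rng.normal(0.0, config.batch_sd, size=config.n_plexes)

    profiles = {a: archetype_profile(a, days) for a in ARCHETYPES}
    true_lfc = np.zeros((n, len(days)))
    for i in range(n_reg):
        true_lfc[i] = config.effect_log2 * profiles[archetypes[i]]

    samples, design_rows = [], []
    for p in range(config.n_plexes):
        for ch, day in enumerate(days):
            samples.append(f"plex{p}_day{day}")
            design_rows.append({"timepoint_days": day, "plex_id": f"plex{p}", "channel": ch})
    design = pd.DataFrame(design_rows, index=samples)

    vals = np.empty((n, len(samples)))
    col = 0
    for p in range(config.n_plexes):
        for ch, _day in enumerate(days):
            vals[:, col] = (
                baseline
                + true_lfc[:, ch]
                + batch_offsets[p]
                + rng.normal(0.0, config.noise_sd, size=n)
            )
            col += 1
    if config.missing_rate > 0:
        # Isobaric quantification is per identification: one PSM set yields
        # all reporter channels of a plex, so a feature drops out of a whole
        # plex at random rather than from single channels.
        plex_mask = rng.random((n, config.n_plexes)) < config.missing_rate
        n_days = len(days)
        for p in range(config.n_plexes):
            vals[plex_mask[:, p], p * n_days : (p + 1) * n_days] = np.nan

    values = pd.DataFrame(vals, index=feature_ids, columns=samples)
    matrix = ExpressionMatrix(values=values, design=design)

    truth_rows = []
    for i, fid in enumerate(feature_ids):
        row = {
            "regulated": i < n_reg,
            "true_cluster": int(archetypes[i]) if archetypes[i] else 0,
            "archetype": ARCHETYPES[archetypes[i]][0] if archetypes[i] else "null",
        }
        for ch, day in enumerate(days):
            lfc = true_lfc[i, ch]
            row[f"true_lfc_day{day}"] = lfc
            row[f"true_direction_day{day}"] = (
                "up" if lfc > 1e-12 else ("down" if lfc < -1e-12 else "null")
            )
        truth_rows.append(row)
    truth = TruthTable(
        table=pd.DataFrame(truth_rows, index=feature_ids),
        extras={"batch_offsets": dict(zip([f"plex{p}" for p in range(config.n_plexes)], batch_offsets))},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Dimethyl phosphoproteomics arm
# ---------------------------------------------------------------------------

def _random_window(rng: np.random.Generator, center_residue: str, length: int = 31) -> str:
    pool = AMINO_ACIDS + "KRP"
    window = list(rng.choice(list(pool), size=length))
    window[length // 2] = center_residue
    return "".join(window)


def _plant_motif(window: str) -> str:
    """Plant the S-P motif: proline at +1 and a basic residue at -3."""
    c = len(window) // 2
    w = list(window)
    w[c + 1] = "P"
    w[c - 3] = "R"
    return "".join(w)


def simulate_phospho(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a multiplicity-resolved phosphosite ratio table.

    Returns a wide site table (one row per site) with localization
    probabilities, +/-15 sequence windows, and per-comparison, per-replicate
    log2 ratio columns suffixed ``___m`` for multiplicity m, plus the truth
    table. Regulated sites are shifted by +/- ``effect_log2`` in both
    replicates of the day7/day0 and day14/day0 comparisons; their windows
    carry a planted S-P motif (P at +1, basic at -3) at
    ``motif_excess`` + background frequency.
    """
    rng = config.rng()
    n = config.n_features
    n_reg = config.n_regulated
    base_motif_rate = 0.2

    protein_ids = [f"Q{1 + i // 3:05d}" for i in range(n)]
    positions = np.empty(n, dtype=int)
    for start in range(0, n, 3):  # unique positions within each protein
        block = min(3, n - start)
        positions[start : start + block] = rng.choice(
            np.arange(5, 800), size=block, replace=False
        )
    residues = rng.choice(list("STY"), size=n, p=[0.75, 0.2, 0.05])
    loc_prob = rng.uniform(0.76, 1.0, size=n)
    n_low = int(round(config.frac_low_localization * n))
    if n_low:
        low_idx = rng.choice(n, size=n_low, replace=False)
        loc_prob[low_idx] = rng.uniform(0.2, 0.7499, size=n_low)

    directions = np.array([""] * n, dtype=object)
    if n_reg:
        directions[:n_reg] = np.where(np.arange(n_reg) % 2 == 0, "up", "down")

    rows = []
    truth_rows = []
    for i in range(n):
        site_id = f"{protein_ids[i]}_{residues[i]}{positions[i]}"
        regulated = bool(directions[i])
        sign = 1.0 if directions[i] == "up" else -1.0
        window = _random_window(rng, residues[i])
        has_motif = rng.random() < (
            base_motif_rate + (config.motif_excess if regulated else 0.0)
        )
        if has_motif:
            window = _plant_motif(window)
        mults = [1] if rng.random() < 0.6 else [1, 2]
        row = {
            "site_id": site_id,
            "protein_id": protein_ids[i],
            "position": int(positions[i]),
            "residue": residues[i],
            "localization_probability": float(loc_prob[i]),
            "sequence_window": window,
            "contaminant": False,
            "reverse": False,
        }
        for comp in PHOSPHO_COMPARISONS:
            effect = 0.0
            if regulated and comp in ("day7_vs_day0", "day14_vs_day0"):
                effect = sign * config.effect_log2
            for rep in range(1, config.n_replicates + 1):
                for m in (1, 2, 3):
                    colname = f"ratio_{comp}_r{rep}___{m}"
                    if m in mults:
                        row[colname] = float(effect + rng.normal(0.0, config.noise_sd))
                    else:
                        row[colname] = np.nan
        rows.append(row)
        truth_rows.append(
            {
                "regulated": regulated,
                "true_direction": directions[i] if regulated else "null",
                "has_motif": has_motif,
                "class1": loc_prob[i] >= 0.75,
            }
        )
    sites = pd.DataFrame(rows).set_index("site_id", drop=False)
    sites.index.name = None
    truth = TruthTable(table=pd.DataFrame(truth_rows, index=sites.index))
    return sites, truth


# ---------------------------------------------------------------------------
# SILAC BioID arm
# ---------------------------------------------------------------------------

def simulate_bioid(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a SILAC proximity-biotinylation experiment.

    Four bait constructs with ``n_silac_replicates`` each; true interactors
    of a construct have light intensities elevated by ``effect_log2`` in
    that construct over the heavy (control) channel. Missingness is
    left-censored: the probability of a missing value follows a logistic
    curve that increases as intensity decreases. Returns a long table with
    columns feature_id / construct / replicate / light / heavy.
    """
    rng = config.rng()
    n = config.n_features
    n_int = config.n_regulated if config.effect_log2 > 0 else 0

    feature_ids = [f"B{i:05d}" for i in range(n)]
    baseline = rng.normal(config.baseline_mean - 3.0, config.baseline_sd, size=n)
    assigned = rng.choice(CONSTRUCTS, size=n_int) if n_int else np.array([], dtype=object)
    interactor_of = {fid: set() for fid in feature_ids}
    for i in range(n_int):
        interactor_of[feature_ids[i]].add(str(assigned[i]))

    def censor(x: np.ndarray) -> np.ndarray:
        p_missing = 1.0 / (1.0 + np.exp((x - config.censor_threshold) / config.censor_scale))
        out = x.copy()
        out[rng.random(x.shape) < p_missing] = np.nan
        return out

    rows = []
    for c in CONSTRUCTS:
        effect = np.array(
            [config.effect_log2 if c in interactor_of[f] else 0.0 for f in feature_ids]
        )
        for r in range(1, config.n_silac_replicates + 1):
            light = baseline + effect + rng.normal(0.0, config.noise_sd, size=n)
            heavy = baseline + rng.normal(0.0, config.noise_sd, size=n)
            light = censor(light)
            heavy = censor(heavy)
            for i, fid in enumerate(feature_ids):
                rows.append(
                    {
                        "feature_id": fid,
                        "construct": c,
                        "replicate": r,
                        "light": light[i],
                        "heavy": heavy[i],
                    }
                )
    records = pd.DataFrame(rows)
    truth = TruthTable(
        table=pd.DataFrame(
            {
                "regulated": [bool(interactor_of[f]) for f in feature_ids],
                "true_interactor_of": [
                    ",".join(sorted(interactor_of[f])) for f in feature_ids
                ],
            },
            index=feature_ids,
        )
    )
    return records, truth


# ---------------------------------------------------------------------------
# Semi-tryptic cleavage arm
# ---------------------------------------------------------------------------

def tryptic_peptides(
    sequence: str, missed_cleavages: int = 2, min_length: int = 1
) -> list[tuple[int, int]]:
    """Fully tryptic peptide coordinates (1-based inclusive), Trypsin/P rule
    (cleave C-terminal to K/R, including before proline)."""
    peps = []
    for start0, pep in pt_parser.icleave(
        sequence, r"[KR]", missed_cleavages=missed_cleavages, min_length=min_length
    ):
        peps.append((start0 + 1, start0 + len(pep)))
    return sorted(set(peps))


def simulate_semitryptic(
    protein_seq: str,
    true_cleavage_positions: Iterable[int],
    config: SimConfig,
    in_source_regions: Optional[Sequence[tuple[int, int]]] = None,
    protein_id: str = "SYN1",
    rt_jitter: float = 0.15,
    min_rt_offset: float = 8.0,
) -> list[Peptide]:
    """Simulate semi-tryptic peptide evidence for one protein.

    Emits (i) fully tryptic parent peptides with reference retention times,
    (ii) in-source fragment ladders over ``in_source_regions`` sharing the
    parent RT within ``rt_jitter`` minutes, and (iii) true proteolytic
    semi-tryptic peptides breaking after each position in
    ``true_cleavage_positions``, with RTs drawn at least ``min_rt_offset``
    minutes away from the parent RT. A break position p means cleavage
    between residues p and p+1.
    """
    if not protein_seq:
        raise ValueError("protein sequence must be non-empty")
    rng = config.rng()
    n_res = len(protein_seq)
    parents0 = tryptic_peptides(protein_seq, missed_cleavages=0)
    parent_rt = {pep: float(rng.uniform(20.0, 90.0)) for pep in parents0}

    def containing_parent(pos: int) -> tuple[int, int]:
        for s, e in parents0:
            if s <= pos < e:  # break inside the peptide body
                return s, e
        raise ValueError(
            f"cleavage position {pos} does not fall inside any tryptic peptide"
        )

    peptides: list[Peptide] = []
    for (s, e), rt in parent_rt.items():
        peptides.append(
            Peptide(
                protein_id=protein_id,
                start=s,
                end=e,
                specificity="full",
                retention_time=rt,
                intensity=float(rng.lognormal(10.0, 0.5)),
            )
        )

    for pos in sorted(set(int(p) for p in true_cleavage_positions)):
        if not 1 <= pos < n_res:
            raise ValueError(f"cleavage position {pos} outside sequence (1..{n_res - 1})")
        s, e = containing_parent(pos)
        rt0 = parent_rt[(s, e)]
        offset = float(rng.uniform(min_rt_offset, 3.0 * min_rt_offset))
        rt = rt0 + offset if rng.random() < 0.5 else max(1.0, rt0 - offset)
        peptides.append(
            Peptide(
                protein_id=protein_id,
                start=s,
                end=pos,
                specificity="N",
                retention_time=rt,
                intensity=float(rng.lognormal(8.0, 0.5)),
            )
        )

    for lo, hi in in_source_regions or ():
        s, e = containing_parent(lo)
        if not (s <= hi < e):
            raise ValueError(f"in-source region ({lo}, {hi}) crosses a tryptic boundary")
        rt0 = parent_rt[(s, e)]
        for pos in range(lo, hi + 1):
            peptides.append(
                Peptide(
                    protein_id=protein_id,
                    start=s,
                    end=pos,
                    specificity="N",
                    retention_time=float(rt0 + rng.normal(0.0, rt_jitter)),
                    intensity=float(rng.lognormal(7.0, 0.5)),
                )
            )
    return peptides


def make_cleavage_fixture(seed: int = 0) -> dict:
    """Deterministic synthetic protein fixture for the cleavage arm.

    Builds a synthetic 420-residue protein (labelled synthetic; it is not
    the real Dclk1 sequence) whose tryptic architecture reproduces the
    evidence classes of interest: a true proteolytic ladder at breaks
    320-323 and another at 356-359, a co-eluting in-source ladder at
    313-316 ("SVNG"), a proline-adjacent artifact break, a tryptic cut at
    R342, and a predicted site (Q384) inside a tryptic peptide shorter than
    the minimum detectable length. The externally predicted cleavage-site
    list {323, 342, 357, 384} is included.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(AMINO_ACIDS.replace("Q", "").replace("S", "")), size=420))
    # Tryptic scaffold (1-based K/R placements).
    for pos in (300, 342, 370, 380, 386, 400):
        seq[pos - 1] = "K" if pos in (300, 370, 386) else "R"
    # Named regions (1-based).
    for pos, aa in zip((313, 314, 315, 316), "SVNG"):  # in-source ladder
        seq[pos - 1] = aa
    for pos, aa in zip((320, 321, 322, 323), "SQLS"):  # true cleavage ladder 1
        seq[pos - 1] = aa
    for pos, aa in zip((356, 357, 358, 359), "LSST"):  # true cleavage ladder 2
        seq[pos - 1] = aa
    seq[384 - 1] = "Q"  # predicted site in a short (undetectable) peptide
    seq[364 - 1] = "P"  # proline-adjacent artifact break between 363 and 364
    protein_seq = "".join(seq)

    config = SimConfig(seed=seed)
    true_positions = [320, 321, 322, 323, 356, 357, 358, 359]
    peptides = simulate_semitryptic(
        protein_seq,
        true_positions,
        config,
        in_source_regions=[(313, 316)],
    )
    # Proline-adjacent in-source artifact: break between 363 (X) and 364 (P).
    parents0 = tryptic_peptides(protein_seq, missed_cleavages=0)
    host = next((s, e) for s, e in parents0 if s <= 363 < e)
    host_rt = next(
        p.retention_time
        for p in peptides
        if p.specificity == "full" and (p.start, p.end) == host
    )
    peptides.append(
        Peptide(
            protein_id="SYN1",
            start=host[0],
            end=363,
            specificity="N",
            retention_time=host_rt + 0.05,
            intensity=500.0,
        )
    )
    predicted = pd.DataFrame(
        {
            "position": [323, 342, 357, 384],
            "score": [0.96, 0.92, 0.96, 0.90],
            "p_value": [4.1e-5, 1.0e-4, 4.1e-5, 2.0e-4],
        }
    )
    return {
        "protein_seq": protein_seq,
        "peptides": peptides,
        "true_regions": [(320, 323), (356, 359)],
        "in_source_regions": [(313, 316)],
        "proline_breaks": [363],
        "predicted_sites": predicted,
    }
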