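"""Configuration objects for the synthetic-data generator and pipeline runs."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

#: BioID bait constructs: full-length Dclk1 (DSK = doublecortin + SP-rich +
#: kinase), the two doublecortin-containing and two kinase-only truncations.
CONSTRUCTS = ("DSK", "DS", "SK", "K")

#: Ratio comparisons quantified in the dimethyl phosphoproteomics arm.
PHOSPHO_COMPARISONS = ("day7_vs_day0", "day14_vs_day0", "day14_vs_day7")


def _check_positive(name: str, value: float, allow_zero: bool = True) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0 or (value == 0 and not allow_zero):
        raise ValueError(f"{name} must be {'>= 0' if allow_zero else '> 0'}, got {value!r}")


def _check_fraction(name: str, value: float) -> None:
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters shared by all four synthetic-data arms.

    Defaults mirror the study designs: a 6-timepoint (0-15 d, every third
    day) TMT time course with five biological-replicate plexes, a
    2-replicate 3-channel dimethyl phosphoproteome, and a 4-construct x
    3-replicate SILAC BioID experiment. All intensities and effects are on
    the log2 scale.

    Parameters
    ----------
    n_features : number of proteins / sites / features to simulate.
    frac_regulated : fraction of features carrying a true effect.
    effect_log2 : true absolute log2 fold change of regulated features.
    noise_sd : i.i.d. measurement noise SD (log2).
    n_plexes : number of TMT plexes (one plex = one biological replicate).
    timepoints_days : strictly increasing sampling days.
    batch_sd : SD of the additive per-plex batch offset (log2).
    missing_rate : missing-completely-at-random rate (TMT arm).
    seed : generator seed; identical config+seed reproduces output exactly.
    n_replicates : replicates per comparison in the phospho arm.
    frac_low_localization : fraction of phosphosites drawn below the class-I
        localization-probability boundary of 0.75.
    motif_excess : excess frequency of the planted S-P / basic(-3) motif in
        regulated phosphosite windows over the background rate.
    n_silac_replicates : replicates per BioID construct.
    censor_threshold : log2 intensity at which the left-censoring logistic
        gives 50% missingness (BioID arm).
    censor_scale : steepness of the censoring curve.
    baseline_mean, baseline_sd : per-feature baseline log2 abundance.
    """

    n_features: int = 500
    frac_regulated: float = 0.2
    effect_log2: float = 1.5
    noise_sd: float = 0.3
    n_plexes: int = 5
    timepoints_days: Sequence[int] = (0, 3, 6, 9, 12, 15)
    batch_sd: float = 0.5
    missing_rate: float = 0.05
    seed: int = 0
    n_replicates: int = 2
    frac_low_localization: float = 0.1
    motif_excess: float = 0.6
    n_silac_replicates: int = 3
    censor_threshold: float = 19.0
    censor_scale: float = 0.7
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_features", "n_plexes", "n_replicates", "n_silac_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("frac_regulated", "missing_rate", "frac_low_localization"):
            _check_fraction(name, getattr(self, name))
        _check_fraction("motif_excess", self.motif_excess)
        for name in ("effect_log2", "noise_sd", "batch_sd", "baseline_sd"):
            _check_positive(name, getattr(self, name))
        _check_positive("censor_scale", self.censor_scale, allow_zero=False)
        for name in ("censor_threshold", "baseline_mean"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        tp = tuple(self.timepoints_days)
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints_days must be strictly increasing with >= 2 entries")
        object.__setattr__(self, "timepoints_days", tp)

    def rng(self) -> np.random.Generator:
        """Fresh seeded generator; each simulate_* call creates its own."""
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints_days"] = list(self.timepoints_days)
        return d

    @property
    def n_regulated(self) -> int:
        return int(round(self.frac_regulated * self.n_features))
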