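"""In-memory containers shared across the pipeline arms.

All quantitative values are log2 intensities or log2 ratios. Residue
coordinates are 1-based and inclusive throughout; conversions to Python
slices happen only inside functions that index into sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FLAG_COLUMNS = ("contaminant", "reverse", "only_identified_by_site")


@dataclass
class ExpressionMatrix:
    """Features x samples log2 intensity matrix with sample design.

    Attributes
    ----------
    values : DataFrame, index = feature ids, columns = sample ids; NaN marks
        a missing (not-quantified) value.
    design : DataFrame indexed by sample id. TMT arm columns:
        ``timepoint_days``, ``plex_id``, ``channel``; BioID arm columns:
        ``construct``, ``replicate``.
    flags : boolean DataFrame per feature (contaminant / reverse /
        only_identified_by_site).
    annotations : feature id -> set of keyword / GO-term strings.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    flags: Optional[pd.DataFrame] = None
    annotations: Mapping[str, set] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples without a design entry: {missing}")
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=self.values.index, columns=list(FLAG_COLUMNS)
            )
        else:
            for col in FLAG_COLUMNS:
                if col not in self.flags.columns:
                    self.flags[col] = False
            self.flags = self.flags.reindex(self.values.index).fillna(False).astype(bool)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            design=self.design.copy(),
            flags=self.flags.copy(),
            annotations={k: set(v) for k, v in self.annotations.items()},
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        out = self.copy()
        out.values = values
        return out

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = pd.Index(feature_ids)
        return ExpressionMatrix(
            values=self.values.loc[keep],
            design=self.design.copy(),
            flags=self.flags.loc[keep],
            annotations={k: set(v) for k, v in self.annotations.items() if k in set(keep)},
        )


@dataclass
class TruthTable:
    """Ground-truth labels emitted by the synthetic generator.

    ``table`` has one immutable row per generated feature; ``extras`` holds
    auxiliary generative quantities (e.g. the drawn per-plex batch offsets)
    that recovery tests compare against.
    """

    table: pd.DataFrame
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("truth table features must be unique")

    @property
    def regulated_ids(self) -> pd.Index:
        if "regulated" in self.table.columns:
            return self.table.index[self.table["regulated"]]
        return pd.Index([])


@dataclass(frozen=True)
class Peptide:
    """A peptide observation from a (semi-)tryptic search.

    ``specificity`` is ``"full"`` for fully tryptic peptides, ``"N"`` if only
    the N-terminus is tryptic (non-tryptic C-terminus) and ``"C"`` for the
    converse. ``start``/``end`` are 1-based inclusive residue coordinates in
    the protein.
    """

    protein_id: str
    start: int
    end: int
    specificity: str  # {"full", "N", "C"}
    retention_time: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for peptide {self}")
        if self.specificity not in ("full", "N", "C"):
            raise ValueError(f"specificity must be full/N/C, got {self.specificity!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def breakpoint(self) -> Optional[int]:
        """Non-tryptic break position: the break lies between residues
        ``breakpoint`` and ``breakpoint + 1``. None for fully tryptic."""
        if self.specificity == "N":
            return self.end
        if self.specificity == "C":
            return self.start - 1
        return None


# Backwards-compatible alias used by the cleavage arm.
SemiTrypticPeptide = Peptide


@dataclass
class CleavageCandidate:
    """A run of consecutive non-tryptic break positions in one protein.

    Breaks between residues i and i+1 for i in ``breakpoints``. The run
    shares a tryptic anchor terminus (``specificity`` of its members).
    """

    protein_id: str
    breakpoints: list
    members: list  # Peptide objects
    specificity: str  # "N" or "C"
    anchor: int  # shared tryptic terminus position
    classification: Optional[str] = None  # proteolytic | in_source | excluded_proline
    low_confidence: bool = False
    matched_predicted_site: Optional[dict] = None

    @property
    def start(self) -> int:
        return min(self.breakpoints)

    @property
    def end(self) -> int:
        return max(self.breakpoints)

    @property
    def is_ladder(self) -> bool:
        return len(self.breakpoints) > 1
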