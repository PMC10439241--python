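"""Proteolytic cleavage-site inference from semi-tryptic peptide evidence.

Semi-tryptic peptides (one tryptic, one non-tryptic terminus) arise either
from genuine proteolysis or from in-source fragmentation of an intact
tryptic peptide during ionization. The two are discriminated by retention
time: in-source fragments co-elute with their fully tryptic parent, while
proteolytic products elute independently. Breaks directly adjacent to
proline are excluded as preferential gas-phase fragmentation artifacts.
Remaining proteolytic candidates are matched against an externally
predicted protease (calpain) cleavage-site list.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CleavageCandidate, Peptide
from .simulate import tryptic_peptides

MIN_PEPTIDE_LENGTH = 7


def _weighted_rt(peptides: Sequence[Peptide]) -> float:
    """Intensity-weighted mean retention time over observations."""
    rts = np.array([p.retention_time for p in peptides], dtype=float)
    w = np.array([p.intensity for p in peptides], dtype=float)
    if w.sum() <= 0:
        return float(rts.mean())
    return float(np.average(rts, weights=w))


def find_ladders(
    peptides: Iterable[Peptide],
    min_members: int = 2,
    min_length: int = MIN_PEPTIDE_LENGTH,
) -> list[CleavageCandidate]:
    """Group semi-tryptic peptides into breakpoint runs ("ladders").

    Peptides sharing a protein, a tryptic anchor terminus, and consecutive
    non-tryptic break positions form one candidate; maximal runs with at
    least ``min_members`` distinct break positions are ladders, shorter
    runs are emitted as narrow candidates (width-1 singletons included).
    Peptides below ``min_length`` residues are ignored (undetectable by the
    search). Output order is deterministic and independent of input order.
    """
    groups: dict[tuple, dict[int, list[Peptide]]] = defaultdict(lambda: defaultdict(list))
    for pep in peptides:
        if pep.specificity not in ("N", "C") or pep.length < min_length:
            continue
        anchor = pep.start if pep.specificity == "N" else pep.end
        groups[(pep.protein_id, pep.specificity, anchor)][pep.breakpoint].append(pep)
    candidates = []
    for (protein_id, spec, anchor) in sorted(groups):
        by_break = groups[(protein_id, spec, anchor)]
        positions = sorted(by_break)
        run: list[int] = []
        for pos in positions + [None]:  # sentinel flushes the last run
            if run and (pos is None or pos != run[-1] + 1):
                members = [p for b in run for p in sorted(by_break[b], key=lambda q: (q.start, q.end, q.retention_time))]
                candidates.append(
                    CleavageCandidate(
                        protein_id=protein_id,
                        breakpoints=list(run),
                        members=members,
                        specificity=spec,
                        anchor=anchor,
                    )
                )
                run = []
            if pos is not None:
                run.append(pos)
    return candidates


def exclude_proline_adjacent(
    candidates: Iterable[CleavageCandidate], protein_seq: str
) -> list[CleavageCandidate]:
    """Reclassify breaks with proline on either side as artifacts.

    A break between residues i and i+1 is proline-adjacent if residue i or
    residue i+1 is proline. Candidates whose breaks are all proline-adjacent
    become ``excluded_proline``; mixed candidates are split into retained
    (non-adjacent) runs plus an excluded candidate carrying the removed
    breaks.
    """
    n = len(protein_seq)
    out = []
    for cand in candidates:
        if any(not 1 <= b < n for b in cand.breakpoints):
            raise ValueError(
                f"breakpoint outside sequence (1..{n - 1}): {cand.breakpoints}"
            )
        adjacent = {
            b for b in cand.breakpoints
            if protein_seq[b - 1] == "P" or protein_seq[b] == "P"
        }
        if not adjacent:
            out.append(cand)
            continue
        excluded_members = [p for p in cand.members if p.breakpoint in adjacent]
        out.append(
            CleavageCandidate(
                protein_id=cand.protein_id,
                breakpoints=sorted(adjacent),
                members=excluded_members,
                specificity=cand.specificity,
                anchor=cand.anchor,
                classification="excluded_proline",
            )
        )
        keep = [b for b in cand.breakpoints if b not in adjacent]
        run: list[int] = []
        for pos in keep + [None]:
            if run and (pos is None or pos != run[-1] + 1):
                out.append(
                    CleavageCandidate(
                        protein_id=cand.protein_id,
                        breakpoints=list(run),
                        members=[p for p in cand.members if p.breakpoint in run],
                        specificity=cand.specificity,
                        anchor=cand.anchor,
                    )
                )
                run = []
            if pos is not None:
                run.append(pos)
    return out


def _find_parent(
    cand: CleavageCandidate, parents: Sequence[Peptide]
) -> Optional[list[Peptide]]:
    """Fully tryptic parent: same tryptic terminus, spanning all breaks.
    Among matches the shortest span wins; all its observations are
    returned for RT averaging."""
    matches = [
        p
        for p in parents
        if p.specificity == "full"
        and p.protein_id == cand.protein_id
        and (
            (cand.specificity == "N" and p.start == cand.anchor and p.end > cand.end)
            or (cand.specificity == "C" and p.end == cand.anchor and p.start <= cand.start)
        )
    ]
    if not matches:
        return None
    key = min((p.end - p.start) for p in matches)
    return [p for p in matches if (p.end - p.start) == key]


def classify_by_rt(
    candidates: Iterable[CleavageCandidate],
    parent_peptides: Iterable[Peptide],
    rt_tolerance: float = 1.0,
) -> list[CleavageCandidate]:
    """Split candidates into in-source fragments and proteolytic products.

    A candidate is ``in_source`` iff every member's intensity-weighted
    retention time lies within ``rt_tolerance`` minutes of its fully
    tryptic parent's (co-elution implies gas-phase fragmentation of the
    parent); otherwise ``proteolytic``. Candidates without an observed
    parent default to proteolytic with a low-confidence flag. Raising
    ``rt_tolerance`` can only move candidates from proteolytic to
    in-source, never the reverse.
    """
    parents = [p for p in parent_peptides if p.specificity == "full"]
    out = []
    for cand in candidates:
        if cand.classification == "excluded_proline":
            out.append(cand)
            continue
        parent_obs = _find_parent(cand, parents)
        if parent_obs is None:
            cand.classification = "proteolytic"
            cand.low_confidence = True
            out.append(cand)
            continue
        parent_rt = _weighted_rt(parent_obs)
        deltas = []
        for b in cand.breakpoints:
            obs = [p for p in cand.members if p.breakpoint == b]
            if obs:
                deltas.append(abs(_weighted_rt(obs) - parent_rt))
        if deltas and max(deltas) <= rt_tolerance:
            cand.classification = "in_source"
        else:
            cand.classification = "proteolytic"
        out.append(cand)
    return out


def predicted_site_context(
    protein_seq: str,
    positions: Iterable[int],
    min_peptide_length: int = MIN_PEPTIDE_LENGTH,
) -> dict[int, str]:
    """Detectability context of predicted sites in the tryptic map.

    A predicted break after position p is ``tryptic_site`` if it coincides
    with a tryptic cut (residue p is K/R), ``short_peptide`` if it falls in
    a tryptic peptide below the minimum detectable length, else
    ``detectable``.
    """
    peps = tryptic_peptides(protein_seq, missed_cleavages=0)
    out = {}
    for pos in positions:
        pos = int(pos)
        if not 1 <= pos < len(protein_seq):
            out[pos] = "outside_sequence"
        elif protein_seq[pos - 1] in "KR":
            out[pos] = "tryptic_site"
        else:
            host = next(((s, e) for s, e in peps if s <= pos <= e), None)
            if host is not None and (host[1] - host[0] + 1) < min_peptide_length:
                out[pos] = "short_peptide"
            else:
                out[pos] = "detectable"
    return out


def match_predicted(
    candidates: Iterable[CleavageCandidate],
    predicted_sites: pd.DataFrame,
    window: int = 2,
    protein_seq: Optional[str] = None,
) -> tuple[list[CleavageCandidate], pd.DataFrame]:
    """Annotate proteolytic candidates with predicted protease sites.

    A proteolytic candidate matches a predicted position if the position
    lies within ``window`` residues of the candidate's breakpoint run; the
    nearest predicted site wins, ties going to the higher score. Also
    returns a per-predicted-site report (matched / tryptic_site /
    short_peptide / unmatched), using ``protein_seq`` for detectability
    context when provided.
    """
    cands = list(candidates)
    pred = predicted_sites.reset_index(drop=True)
    context = (
        predicted_site_context(protein_seq, pred["position"])
        if protein_seq is not None and len(pred)
        else {}
    )
    matched_positions = set()
    for cand in cands:
        if cand.classification != "proteolytic":
            continue
        best = None
        for _, site in pred.iterrows():
            pos = int(site["position"])
            dist = max(0, cand.start - pos, pos - cand.end)
            if dist > window:
                continue
            key = (dist, -float(site.get("score", 0.0)))
            if best is None or key < best[0]:
                best = (key, site)
        if best is not None:
            site = best[1]
            cand.matched_predicted_site = {
                "position": int(site["position"]),
                "score": float(site.get("score", np.nan)),
                "p_value": float(site.get("p_value", np.nan)),
            }
            matched_positions.add(int(site["position"]))
    report_rows = []
    for _, site in pred.iterrows():
        pos = int(site["position"])
        if pos in matched_positions:
            status = "matched"
        else:
            status = context.get(pos, "unmatched")
            if status == "detectable":
                status = "unmatched"
        report_rows.append({"position": pos, "score": site.get("score"), "status": status})
    return cands, pd.DataFrame(report_rows)


def candidates_to_frame(candidates: Iterable[CleavageCandidate]) -> pd.DataFrame:
    """Flat report table for a candidate list."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "protein_id": c.protein_id,
                "region_start": c.start,
                "region_end": c.end,
                "n_breakpoints": len(c.breakpoints),
                "specificity": c.specificity,
                "classification": c.classification,
                "low_confidence": c.low_confidence,
                "matched_position": (
                    c.matched_predicted_site["position"]
                    if c.matched_predicted_site
                    else np.nan
                ),
                "matched_score": (
                    c.matched_predicted_site["score"] if c.matched_predicted_site else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
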