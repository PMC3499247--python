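"""Occupancy scores, polymerase classification, correlations, summaries.

A locus's occupancy score for a factor sums the factor's tags overlapping
the scored region in two components: unique-match tags contribute the number
of times they were sequenced; multi-match tags contribute their capped
weight (times sequenced / genome-wide matches, at most 1) per placement.
The fraction contributed by unique tags measures how trustworthy the score
is — multi-mapping tags may belong to another copy of the repeat family.

Most SNAPc-occupied promoters are dominated by a single polymerase; the
classifier normalizes each locus's POLR2B and POLR3D scores by the median
score of the loci dominated by that polymerase and calls a locus DUAL when
both normalized scores are substantial (default >= 0.25 of the respective
dominant-class median), the operationalization of "significant amounts of
both machineries, comparable to single-polymerase genes".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

POL2, POL3, DUAL, UNOCCUPIED = "POL2", "POL3", "DUAL", "UNOCCUPIED"

ACTIVATORS = ("POU2F1", "ZNF143", "GABPA")


@dataclass
class OccupancyScore:
    unique_component: float
    multi_component: float

    @property
    def total(self) -> float:
        return self.unique_component + self.multi_component

    @property
    def pct_unique(self) -> float:
        """Fraction of the score from unique-match tags (0 when empty)."""
        t = self.total
        return self.unique_component / t if t > 0 else 0.0


def region_score(tags: pd.DataFrame, chrom: str, start: int, end: int) -> OccupancyScore:
    """Occupancy score of one region from one factor's tag collection."""
    if end <= start:
        raise ValueError("empty or inverted region")
    sel = tags[(tags["chrom"] == chrom) & (tags["start"] < end)
               & (tags["end"] > start)]
    if len(sel) == 0:
        return OccupancyScore(0.0, 0.0)
    unique = sel["n_matches"].to_numpy() == 1
    times = sel["times_sequenced"].to_numpy(dtype=float)
    u = float(times[unique].sum())
    m = float(np.minimum(1.0, times[~unique]
                         / sel["n_matches"].to_numpy(dtype=float)[~unique]).sum())
    return OccupancyScore(u, m)


def score_table(loci: pd.DataFrame, tags_by_factor: Mapping[str, pd.DataFrame],
                pad: int = 0) -> pd.DataFrame:
    """Locus x factor table of score totals plus per-factor unique fractions.

    Rows are indexed by locus_id; per factor, ``<factor>`` holds the score
    total and ``<factor>_pct_unique`` the unique-tag fraction.  ``pad``
    widens each scored region symmetrically.
    """
    rows = {}
    for _, locus in loci.iterrows():
        row = {}
        for factor, tags in tags_by_factor.items():
            sc = region_score(tags, locus["chrom"],
                              int(locus["start"]) - pad, int(locus["end"]) + pad)
            row[factor] = sc.total
            row[f"{factor}_pct_unique"] = sc.pct_unique
        rows[locus["locus_id"]] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "locus_id"
    return table


def classify_polymerase(table: pd.DataFrame, dual_fraction: float = 0.25,
                        call_floor: float = 1.0, pol2_col: str = "POLR2B",
                        pol3_col: str = "POLR3D",
                        max_iter: int = 10) -> pd.DataFrame:
    """Classify each locus as POL2 / POL3 / DUAL / UNOCCUPIED.

    Scores are normalized by the median of the loci dominated by each
    polymerase (initial assignment by larger raw score, iterated to a fixed
    point).  DUAL iff both normalized scores reach ``dual_fraction``;
    UNOCCUPIED iff both raw scores are below ``call_floor``.  With fewer
    than 3 loci per side the classifier falls back to the raw-ratio rule
    with a warning.
    """
    raw2 = table[pol2_col].to_numpy(dtype=float)
    raw3 = table[pol3_col].to_numpy(dtype=float)
    occupied = (raw2 >= call_floor) | (raw3 >= call_floor)
    side2 = raw2 >= raw3
    norm2, norm3 = raw2.copy(), raw3.copy()
    fallback = False
    for _ in range(max_iter):
        coh2 = occupied & side2
        coh3 = occupied & ~side2
        if coh2.sum() < 3 or coh3.sum() < 3:
            fallback = True
            break
        med2 = float(np.median(raw2[coh2]))
        med3 = float(np.median(raw3[coh3]))
        if med2 <= 0 or med3 <= 0:
            fallback = True
            break
        norm2 = raw2 / med2
        norm3 = raw3 / med3
        new_side2 = norm2 >= norm3
        if np.array_equal(new_side2, side2):
            break
        side2 = new_side2
    if fallback:
        warnings.warn("fewer than 3 loci per polymerase side; "
                      "falling back to raw-ratio dual rule")
        hi = np.maximum(raw2, raw3)
        lo = np.minimum(raw2, raw3)
        with np.errstate(divide="ignore", invalid="ignore"):
            is_dual = np.where(hi > 0, lo / hi, 0.0) >= dual_fraction
        norm2, norm3 = raw2, raw3
    else:
        is_dual = np.minimum(norm2, norm3) >= dual_fraction
    cls = np.where(~occupied, UNOCCUPIED,
                   np.where(is_dual, DUAL, np.where(norm2 >= norm3, POL2, POL3)))
    minor = np.minimum(norm2, norm3)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(minor > 0, np.maximum(norm2, norm3) / minor, np.inf)
    return pd.DataFrame({"pol_class": cls, "norm_pol2": norm2,
                         "norm_pol3": norm3, "dominance_ratio": ratio},
                        index=table.index)


def correlation_matrix(table: pd.DataFrame, method: str = "spearman",
                       exclusions: Sequence[str] = ()) -> pd.DataFrame:
    """Factor x factor rank-correlation matrix of score columns.

    ``exclusions`` names rows (loci) dropped before correlating.  Constant
    columns yield missing (NaN) off-diagonal entries; the diagonal is 1.
    """
    sub = table.drop(index=list(exclusions), errors="ignore")
    cols = [c for c in sub.columns if not c.endswith("_pct_unique")]
    sub = sub[cols]
    if len(sub) < 3:
        raise ValueError("need at least 3 loci after exclusions")
    corr = sub.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def activator_presence(loci: pd.DataFrame,
                       peaks_by_factor: Mapping[str, pd.DataFrame],
                       activators: Sequence[str] = ACTIVATORS,
                       pad: int = 400) -> pd.DataFrame:
    """Boolean locus x activator table: a called peak of the activator lies
    within the locus extent padded by ``pad`` bp (the promoter window)."""
    rows = {}
    for _, locus in loci.iterrows():
        lo, hi = int(locus["start"]) - pad, int(locus["end"]) + pad
        row = {}
        for factor in activators:
            peaks = peaks_by_factor.get(factor)
            row[factor] = bool(
                peaks is not None and len(peaks) and
                ((peaks["chrom"] == locus["chrom"])
                 & (peaks["summit"] >= lo) & (peaks["summit"] < hi)).any())
        rows[locus["locus_id"]] = row
    out = pd.DataFrame.from_dict(rows, orient="index").astype(bool)
    out.index.name = "locus_id"
    return out


def activator_combo_summary(presence: pd.DataFrame,
                            activators: Sequence[str] = ACTIVATORS):
    """Per-activator percentages and the 8 combination counts.

    The denominator cohort is every row of ``presence`` (loci occupied by
    basal factors).  Returns (per-activator summary, combination table).
    """
    if len(presence) == 0:
        raise ValueError("empty locus cohort")
    n = len(presence)
    per = pd.DataFrame({
        "activator": list(activators),
        "n_loci": [int(presence[a].sum()) for a in activators],
    })
    per["pct"] = 100.0 * per["n_loci"] / n
    combos = []
    for mask in range(8):
        combo = tuple(bool(mask >> (2 - i) & 1) for i in range(3))
        sel = np.ones(n, dtype=bool)
        for a, present in zip(activators, combo):
            sel &= presence[a].to_numpy() == present
        combos.append({**{a: c for a, c in zip(activators, combo)},
                       "count": int(sel.sum()),
                       "pct": 100.0 * sel.sum() / n})
    return per, pd.DataFrame(combos)
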