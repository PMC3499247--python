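"""Assembly of candidate SNAPc-dependent loci from three evidence layers.

A locus requires (i) a polymerase peak (POLR2B or POLR3D), (ii) a matched
basal-factor peak (GTF2B for pol II, BRF2 for pol III) within 100 bp, and
(iii) a SNAPc-positive bin within 100 nt of the polymerase peak.  The two
routes are assembled independently; a dual-polymerase promoter simply
appears on both.  Distances are interval gaps (0 when overlapping), an
interpretation robust to peak width; summit-to-summit distances are
available via ``distance_mode='summit'``.

Manual visual curation of the original procedure is replaced by automatable
flags: a pooled unique-tag-fraction flag (peaks made almost entirely of
multi-mapping tags are likely mapping artifacts) and a cross-factor identity
flag (identical peak boundaries in many unrelated factors indicate regions
of artefactual tag accumulation).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

ROUTES = {
    "POL2": ("POLR2B", "GTF2B"),
    "POL3": ("POLR3D", "BRF2"),
}

LOCUS_COLUMNS = ["locus_id", "chrom", "start", "end", "route",
                 "polymerase_summit", "polymerase_support", "basal_summit",
                 "pair_distance", "snapc_bin_index", "snapc_distance", "flags"]


def _interval_gap(a_start, a_end, b_start, b_end):
    """Gap between half-open intervals; 0 when overlapping or adjacent."""
    return np.maximum(0, np.maximum(b_start - a_end, a_start - b_end))


def pair_peaks(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame,
               max_dist: int = 100, distance_mode: str = "gap") -> pd.DataFrame:
    """Pair each A-peak with its nearest B-peak within ``max_dist``.

    Distance is the interval gap (inclusive boundary: gap == max_dist still
    pairs) or ``|summit_a - summit_b|`` in summit mode.  Ties go to the
    leftmost B-peak.  Returns one row per paired A-peak with the A/B peak
    attributes and the pairing distance.
    """
    if distance_mode not in ("gap", "summit"):
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    rows = []
    for chrom, a_sub in (peaks_a.groupby("chrom", sort=True) if len(peaks_a) else []):
        b_sub = peaks_b[peaks_b["chrom"] == chrom]
        if len(b_sub) == 0:
            continue
        b_start = b_sub["start"].to_numpy()
        b_end = b_sub["end"].to_numpy()
        b_summit = b_sub["summit"].to_numpy()
        for _, a in a_sub.iterrows():
            if distance_mode == "gap":
                d = _interval_gap(a["start"], a["end"], b_start, b_end)
            else:
                d = np.abs(b_summit - a["summit"])
            j = int(np.argmin(d))  # argmin takes the leftmost tie (sorted input)
            if d[j] <= max_dist:
                b = b_sub.iloc[j]
                rows.append({
                    "chrom": chrom,
                    "a_start": int(a["start"]), "a_end": int(a["end"]),
                    "a_summit": int(a["summit"]), "a_support": float(a["support"]),
                    "b_start": int(b["start"]), "b_end": int(b["end"]),
                    "b_summit": int(b["summit"]), "b_support": float(b["support"]),
                    "distance": int(d[j]),
                })
    cols = ["chrom", "a_start", "a_end", "a_summit", "a_support",
            "b_start", "b_end", "b_summit", "b_support", "distance"]
    return pd.DataFrame(rows, columns=cols)


def assemble_loci(pairs: pd.DataFrame, snapc_bins: pd.DataFrame, route: str,
                  max_dist: int = 100, require_snapc: bool = True,
                  merge_overlapping: bool = True) -> pd.DataFrame:
    """Turn polymerase/basal peak pairs into locus candidates.

    A pair becomes a locus iff a SNAPc-positive bin lies within ``max_dist``
    nt of the polymerase (A) peak; the locus extent is the union of the
    member peak intervals and the bin.  Candidates on the same route whose
    extents overlap are merged (the polymerase termination zone can yield
    secondary downstream peaks of the same promoter); the strongest
    polymerase peak represents a merged locus.  Loci are sorted by
    coordinate with stable route-scoped ids.
    """
    if route not in ROUTES:
        raise ValueError(f"unknown route {route!r}")
    rows = []
    for _, pr in (pairs.iterrows() if len(pairs) else []):
        bins_c = snapc_bins[snapc_bins["chrom"] == pr["chrom"]]
        bin_index, bin_dist = -1, -1
        if len(bins_c):
            gaps = _interval_gap(pr["a_start"], pr["a_end"],
                                 bins_c["start"].to_numpy(),
                                 bins_c["end"].to_numpy())
            j = int(np.argmin(gaps))
            if gaps[j] <= max_dist:
                bin_index = int(bins_c.iloc[j]["bin_index"])
                bin_dist = int(gaps[j])
        if bin_index < 0 and require_snapc:
            continue
        start = min(pr["a_start"], pr["b_start"])
        end = max(pr["a_end"], pr["b_end"])
        if bin_index >= 0:
            start = min(start, int(bins_c.iloc[j]["start"]))
            end = max(end, int(bins_c.iloc[j]["end"]))
        rows.append({"chrom": pr["chrom"], "start": int(start), "end": int(end),
                     "route": route,
                     "polymerase_summit": int(pr["a_summit"]),
                     "polymerase_support": float(pr["a_support"]),
                     "basal_summit": int(pr["b_summit"]),
                     "pair_distance": int(pr["distance"]),
                     "snapc_bin_index": bin_index,
                     "snapc_distance": bin_dist, "flags": ""})
    loci = pd.DataFrame(rows)
    if len(loci) == 0:
        return pd.DataFrame(columns=LOCUS_COLUMNS)
    loci = loci.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if merge_overlapping:
        merged = []
        for _, row in loci.iterrows():
            if merged and merged[-1]["chrom"] == row["chrom"] \
                    and row["start"] < merged[-1]["end"]:
                prev = merged[-1]
                prev["end"] = max(prev["end"], row["end"])
                prev["start"] = min(prev["start"], row["start"])
                if row["polymerase_support"] > prev["polymerase_support"]:
                    for k in ("polymerase_summit", "polymerase_support",
                              "basal_summit"):
                        prev[k] = row[k]
                prev["pair_distance"] = min(prev["pair_distance"], row["pair_distance"])
                if row["snapc_bin_index"] >= 0 and (
                        prev["snapc_distance"] < 0
                        or 0 <= row["snapc_distance"] < prev["snapc_distance"]):
                    prev["snapc_bin_index"] = row["snapc_bin_index"]
                    prev["snapc_distance"] = row["snapc_distance"]
            else:
                merged.append(dict(row))
        loci = pd.DataFrame(merged)
    loci.insert(0, "locus_id",
                [f"{route}_{i + 1:03d}" for i in range(len(loci))])
    return loci[LOCUS_COLUMNS]


def flag_artifacts(locus: Mapping, polymerase_score, basal_score,
                   unique_fraction_floor: float = 0.20,
                   artifact_ceiling: float = 0.15) -> set[str]:
    """Unique-tag-fraction flags for one locus.

    The pooled unique fraction of the polymerase and basal occupancy scores
    (summed unique components over summed totals) drives the call: below
    ``artifact_ceiling`` the locus is flagged ``low_unique_fraction`` (likely
    a multi-mapping artifact); at or above ``unique_fraction_floor`` it is
    unflagged (likely genuinely occupied); in between it is flagged
    ``ambiguous_unique_fraction``.
    """
    unique = polymerase_score.unique_component + basal_score.unique_component
    total = polymerase_score.total + basal_score.total
    frac = unique / total if total > 0 else 0.0
    flags = set()
    if frac < artifact_ceiling:
        flags.add("low_unique_fraction")
    elif frac < unique_fraction_floor:
        flags.add("ambiguous_unique_fraction")
    return flags


def flag_high_background(locus: Mapping,
                         peaks_by_factor: Mapping[str, pd.DataFrame],
                         min_factors: int = 6) -> set[str]:
    """Flag loci whose exact peak boundaries recur across many factors.

    Identical peak intervals in >= ``min_factors`` distinct factors within
    the locus indicate artefactual tag accumulation rather than genuine
    factor-specific binding.
    """
    boundary_owners: dict[tuple, set[str]] = {}
    for factor, peaks in peaks_by_factor.items():
        inside = peaks[(peaks["chrom"] == locus["chrom"])
                       & (peaks["start"] < locus["end"])
                       & (peaks["end"] > locus["start"])]
        for _, p in inside.iterrows():
            boundary_owners.setdefault((p["start"], p["end"]), set()).add(factor)
    if any(len(owners) >= min_factors for owners in boundary_owners.values()):
        return {"high_background"}
    return set()


def write_loci(loci: pd.DataFrame, tsv_path: str, bed_path: str | None = None) -> None:
    loci.to_csv(tsv_path, sep="\t", index=False)
    if bed_path:
        bed = loci[["chrom", "start", "end", "locus_id"]].copy()
        bed["score"] = 0
        bed["strand"] = "."
        bed.to_csv(bed_path, sep="\t", header=False, index=False)
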