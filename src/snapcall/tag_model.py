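"""Aligned sequence tags: ingestion rules, per-tag weights, weighted coverage.

A "tag" is one collapsed mapped read: genomic interval, strand, the number of
identical reads collapsed onto it (``times_sequenced``) and its genome-wide
perfect-match count (``n_matches``).  Tag collections are plain pandas
DataFrames with the columns in :data:`TAG_COLUMNS`; downstream stages treat
them as immutable inputs.

Multi-mapping tags are the crux of snRNA-type loci, which occur in families of
near-identical copies: rather than discarding such tags, each receives a
weight ``min(1, times_sequenced / n_matches)``, so a tag's total influence
across its placements never exceeds the number of times it was actually
sequenced.  Unique tags always weigh 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical column order of a tag DataFrame (extended BED6+2 plus mismatch flag).
TAG_COLUMNS = [
    "chrom", "start", "end", "name", "times_sequenced", "strand",
    "n_matches", "source_factor", "has_mismatch",
]


@dataclass
class RetentionReport:
    """Bookkeeping for :func:`load_alignments` filtering decisions."""

    n_input: int = 0
    n_retained: int = 0
    n_dropped_matches: int = 0
    n_dropped_mismatch: int = 0
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["input", "retained", "dropped_max_matches", "dropped_mismatch"],
                "count": [self.n_input, self.n_retained,
                          self.n_dropped_matches, self.n_dropped_mismatch],
            }
        )


def tag_weight(times_sequenced, n_matches):
    """Per-placement weight of a tag: ``min(1, times_sequenced / n_matches)``.

    Accepts scalars or numpy arrays; both arguments must be >= 1.
    """
    t = np.asarray(times_sequenced, dtype=float)
    n = np.asarray(n_matches, dtype=float)
    if np.any(t < 1) or np.any(n < 1):
        raise ValueError("times_sequenced and n_matches must both be >= 1")
    w = np.minimum(1.0, t / n)
    if np.isscalar(times_sequenced) and np.isscalar(n_matches):
        return float(w)
    return w


def tag_weights(tags: pd.DataFrame) -> np.ndarray:
    """Vector of per-placement weights for a tag DataFrame."""
    return tag_weight(tags["times_sequenced"].to_numpy(),
                      tags["n_matches"].to_numpy())


def five_prime(tags: pd.DataFrame) -> np.ndarray:
    """0-based genomic position of each tag's 5' end (strand-aware)."""
    plus = tags["strand"].to_numpy() == "+"
    return np.where(plus, tags["start"].to_numpy(), tags["end"].to_numpy() - 1)


def make_tags(records: Iterable[tuple] | None = None, **columns) -> pd.DataFrame:
    """Build a tag DataFrame from records or column arrays, filling defaults."""
    if records is not None:
        records = list(records)
        ncol = len(records[0]) if records else len(TAG_COLUMNS)
        df = pd.DataFrame(records, columns=TAG_COLUMNS[:ncol])
    else:
        df = pd.DataFrame(columns)
    for col, default in (("name", ""), ("times_sequenced", 1),
                         ("n_matches", 1), ("source_factor", ""),
                         ("has_mismatch", False)):
        if col not in df.columns:
            df[col] = default
    df = df[TAG_COLUMNS]
    df = df.astype({"start": np.int64, "end": np.int64, "times_sequenced": np.int64,
                    "n_matches": np.int64, "has_mismatch": bool})
    return df


def empty_tags() -> pd.DataFrame:
    return make_tags(chrom=pd.Series([], dtype=str),
                     start=pd.Series([], dtype=np.int64),
                     end=pd.Series([], dtype=np.int64),
                     strand=pd.Series([], dtype=str))


def _parse_bed_line(line: str, lineno: int) -> tuple:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 6:
        raise ValueError(f"line {lineno}: expected >= 6 tab-separated BED fields, "
                         f"got {len(parts)}")
    chrom, start, end, name, score, strand = parts[:6]
    try:
        start_i, end_i = int(start), int(end)
        times = int(score) if score not in (".", "") else 1
        n_matches = int(parts[6]) if len(parts) > 6 and parts[6] != "" else 1
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed numeric field ({exc})") from None
    if start_i < 0 or end_i < 0:
        raise ValueError(f"line {lineno}: negative coordinate")
    if end_i <= start_i:
        raise ValueError(f"line {lineno}: end must exceed start")
    if strand not in "+-":
        raise ValueError(f"line {lineno}: strand must be + or -, got {strand!r}")
    source = parts[7] if len(parts) > 7 else ""
    has_mm = parts[8] not in ("0", "", "False", "false") if len(parts) > 8 else False
    return (chrom, start_i, end_i, name, max(times, 1), strand,
            max(n_matches, 1), source, has_mm)


def _load_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            rows.append(_parse_bed_line(line, lineno))
    if not rows:
        return empty_tags()
    return make_tags(rows)


def _load_sam(path: str) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            n_matches = rec.get_tag("NH") if rec.has_tag("NH") else 1
            has_mm = bool(rec.get_tag("NM")) if rec.has_tag("NM") else False
            rows.append((rec.reference_name, rec.reference_start, rec.reference_end,
                         rec.query_name or "", 1, "-" if rec.is_reverse else "+",
                         max(int(n_matches), 1), "", has_mm))
    if not rows:
        return empty_tags()
    return make_tags(rows)


def load_alignments(path: str, max_matches: int = 500,
                    exclude_mismatches: bool = True,
                    report: RetentionReport | None = None) -> pd.DataFrame:
    """Load aligned tags and apply the inclusion rules.

    Tags matching more than ``max_matches`` genomic locations are dropped, as
    are mismatched tags unless ``exclude_mismatches`` is False.  Input is the
    extended BED6+2 dialect (chrom, start, end, name, times_sequenced, strand,
    n_matches, source_factor[, has_mismatch]) or SAM (``.sam`` suffix;
    NH -> n_matches, NM>0 -> has_mismatch).
    """
    ext = os.path.splitext(path)[1].lower()
    tags = _load_sam(path) if ext == ".sam" else _load_bed(path)
    return filter_tags(tags, max_matches=max_matches,
                       exclude_mismatches=exclude_mismatches, report=report)


def filter_tags(tags: pd.DataFrame, max_matches: int = 500,
                exclude_mismatches: bool = True,
                report: RetentionReport | None = None) -> pd.DataFrame:
    """Apply the inclusion rules to an in-memory tag collection."""
    keep = tags["n_matches"].to_numpy() <= max_matches
    n_over = int((~keep).sum())
    n_mm = 0
    if exclude_mismatches:
        mm = tags["has_mismatch"].to_numpy().astype(bool)
        n_mm = int((keep & mm).sum())
        keep &= ~mm
    if report is not None:
        report.n_input = len(tags)
        report.n_retained = int(keep.sum())
        report.n_dropped_matches = n_over
        report.n_dropped_mismatch = n_mm
        report.params = {"max_matches": max_matches,
                         "exclude_mismatches": exclude_mismatches,
                         "multi_placement": "weight at each reported placement"}
    return tags.loc[keep].reset_index(drop=True)


def write_tags_bed(tags: pd.DataFrame, path: str) -> None:
    """Write tags in the extended BED6+2(+mismatch) dialect."""
    out = tags.copy()
    out["has_mismatch"] = out["has_mismatch"].astype(int)
    out[TAG_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def coverage(tags: pd.DataFrame, chrom_lengths: Mapping[str, int],
             resolution: int = 1, mode: str = "five_prime") -> dict[str, np.ndarray]:
    """Weighted coverage tracks, one float array per chromosome.

    ``mode='five_prime'`` adds each tag's weight at its 5'-end position;
    ``mode='interval'`` spreads the weight uniformly over [start, end).
    Total mass equals the sum of tag weights in either mode.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if mode not in ("five_prime", "interval"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    tracks = {c: np.zeros(int(np.ceil(L / resolution)), dtype=np.float64)
              for c, L in chrom_lengths.items()}
    if len(tags) == 0:
        return tracks
    w = tag_weights(tags)
    for chrom, idx in tags.groupby("chrom", sort=False).indices.items():
        if chrom not in tracks:
            raise ValueError(f"tag on unknown chromosome {chrom!r}")
        sub = tags.iloc[idx]
        L = chrom_lengths[chrom]
        if (sub["start"].min() < 0) or (sub["end"].max() > L):
            raise ValueError(f"tag beyond bounds of chromosome {chrom!r}")
        wsub = w[idx]
        if mode == "five_prime":
            pos = five_prime(sub) // resolution
            np.add.at(tracks[chrom], pos, wsub)
        else:
            per_bp = wsub / (sub["end"].to_numpy() - sub["start"].to_numpy())
            delta = np.zeros(L + 1)
            np.add.at(delta, sub["start"].to_numpy(), per_bp)
            np.add.at(delta, sub["end"].to_numpy(), -per_bp)
            bp = np.cumsum(delta[:-1])
            n_bins = tracks[chrom].shape[0]
            pad = n_bins * resolution - L
            if pad:
                bp = np.concatenate([bp, np.zeros(pad)])
            tracks[chrom] = bp.reshape(n_bins, resolution).sum(axis=1)
    return tracks


def interval_coverage(tags: pd.DataFrame, chrom_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Base-pair weighted coverage where each tag covers its full interval.

    Unlike :func:`coverage` in ``interval`` mode (mass-conserving per tag),
    every covered base receives the tag's full weight, matching browser-style
    tag-count tracks.
    """
    tracks = {c: np.zeros(L, dtype=np.float64) for c, L in chrom_lengths.items()}
    if len(tags) == 0:
        return tracks
    w = tag_weights(tags)
    for chrom, idx in tags.groupby("chrom", sort=False).indices.items():
        sub = tags.iloc[idx]
        delta = np.zeros(chrom_lengths[chrom] + 1)
        np.add.at(delta, sub["start"].to_numpy(), w[idx])
        np.add.at(delta, sub["end"].to_numpy(), -w[idx])
        tracks[chrom] = np.cumsum(delta[:-1])
    return tracks


def write_bedgraph(tracks: Mapping[str, np.ndarray], path: str,
                   resolution: int = 1) -> None:
    """Write coverage tracks as bedGraph (non-zero runs only)."""
    with open(path, "w") as fh:
        for chrom in tracks:
            vals = tracks[chrom]
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vals.size]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s * resolution}\t{e * resolution}\t{v:.6g}\n")
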