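"""200-nt bin enrichment calling for the SNAPc subunits.

ChIPs against the individual SNAPc subunits give relatively weak signals, so
instead of peak calling the genome is tiled into fixed bins (default 200 nt)
and each bin is scored per subunit with weighted tag counts.  A bin is
SNAPc-positive when at least two of the four assayed subunits (SNAPC1,
SNAPC2, SNAPC4, SNAPC5) are individually enriched, by either of two methods:

* ``threshold``: a subunit is positive when its weighted count reaches the
  Poisson-derived minimum tag count at the peak caller's FDR, evaluated with
  the bin size as the window.
* ``normal_bh``: a normal distribution is fitted to the subunit's bin counts;
  each bin gets an upper-tail p-value, Benjamini-Hochberg adjusted over all
  tested bins of that subunit, positive when adjusted p < alpha (default
  0.005).

By default the normal fit covers occupied bins only (count > 0); a genome is
dominated by empty bins and including them collapses the fit
(``fit_include_zeros=True`` restores that reading).
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tag_model import five_prime, tag_weights

SNAPC_SUBUNITS = ("SNAPC1", "SNAPC2", "SNAPC4", "SNAPC5")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bin_counts(tags_by_subunit: Mapping[str, pd.DataFrame],
               bin_size: int = 200) -> pd.DataFrame:
    """Weighted tag counts per (chrom, bin) per subunit.

    A tag belongs to the bin containing its 5' end (half-open tiling:
    position ``bin_size * i`` starts bin ``i``).  Only bins occupied by at
    least one subunit appear as rows; the column sum per subunit equals that
    subunit's total tag weight.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    frames = []
    for subunit, tags in tags_by_subunit.items():
        if len(tags) == 0:
            continue
        idx = five_prime(tags) // bin_size
        df = pd.DataFrame({"chrom": tags["chrom"].to_numpy(), "bin_index": idx,
                           "w": tag_weights(tags)})
        agg = df.groupby(["chrom", "bin_index"])["w"].sum().rename(subunit)
        frames.append(agg)
    if not frames:
        return pd.DataFrame(columns=["chrom", "bin_index", *tags_by_subunit])
    out = pd.concat(frames, axis=1).fillna(0.0)
    for subunit in tags_by_subunit:
        if subunit not in out.columns:
            out[subunit] = 0.0
    out = out[list(tags_by_subunit)].reset_index()
    return out.sort_values(["chrom", "bin_index"], kind="stable").reset_index(drop=True)


def _finalize(calls: pd.DataFrame, subunits: Sequence[str], bin_size: int,
              method: str) -> pd.DataFrame:
    pos_cols = [f"{s}_positive" for s in subunits]
    calls["n_positive_subunits"] = calls[pos_cols].sum(axis=1).astype(int)
    calls["is_snapc_positive"] = calls["n_positive_subunits"] >= 2
    calls["start"] = calls["bin_index"] * bin_size
    calls["end"] = calls["start"] + bin_size
    calls.attrs["method"] = method
    return calls


def threshold_method(counts: pd.DataFrame, min_tag_count: int,
                     bin_size: int = 200,
                     subunits: Sequence[str] = SNAPC_SUBUNITS) -> pd.DataFrame:
    """Subunit positive iff its weighted count (rounded up) reaches the
    Poisson-derived minimum; bin positive iff >= 2 subunits are."""
    calls = counts.copy()
    for s in subunits:
        calls[f"{s}_positive"] = np.ceil(calls[s] - 1e-9) >= min_tag_count
    return _finalize(calls, subunits, bin_size, "threshold")


def normal_null_method(counts: pd.DataFrame, alpha: float = 0.005,
                       bin_size: int = 200,
                       subunits: Sequence[str] = SNAPC_SUBUNITS,
                       fit_include_zeros: bool = False,
                       n_genome_bins: int | None = None) -> pd.DataFrame:
    """Fitted-normal null with Benjamini-Hochberg adjustment per subunit.

    Per subunit, (mu, sigma) are fitted over the tested bins (occupied bins
    by default; all ``n_genome_bins`` genomic bins when
    ``fit_include_zeros``), each tested bin receives the upper-tail p-value
    of its count under N(mu, sigma), p-values are BH-adjusted over the
    tested bins, and the subunit is positive when adjusted p < alpha.  A
    degenerate fit (sigma = 0) yields no positives for that subunit.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    calls = counts.copy()
    if len(calls) < 2:
        raise ValueError("need at least 2 bins with data")
    for s in subunits:
        x = calls[s].to_numpy(dtype=float)
        tested = np.ones(len(x), bool) if fit_include_zeros else x > 0
        fit_vals = x[tested]
        n_zero_pad = 0
        if fit_include_zeros and n_genome_bins is not None:
            n_zero_pad = max(0, n_genome_bins - len(x))
        n_fit = len(fit_vals) + n_zero_pad
        mu = fit_vals.sum() / n_fit if n_fit else 0.0
        var = ((np.square(fit_vals - mu).sum() + n_zero_pad * mu ** 2) / n_fit
               if n_fit else 0.0)
        sigma = math.sqrt(var)
        p_raw = np.full(len(x), np.nan)
        p_adj = np.full(len(x), np.nan)
        positive = np.zeros(len(x), bool)
        if sigma == 0:
            warnings.warn(f"{s}: degenerate normal fit (sigma = 0); "
                          "no bin called positive")
        elif tested.sum() >= 2:
            p_raw[tested] = stats.norm.sf((x[tested] - mu) / sigma)
            p_adj[tested] = bh_adjust(p_raw[tested])
            positive[tested] = p_adj[tested] < alpha
        calls[f"{s}_p_raw"] = p_raw
        calls[f"{s}_p_adj"] = p_adj
        calls[f"{s}_positive"] = positive
    return _finalize(calls, subunits, bin_size, "normal_bh")


def positive_bins(calls: pd.DataFrame) -> pd.DataFrame:
    """Rows of SNAPc-positive bins with interval coordinates."""
    return calls.loc[calls["is_snapc_positive"],
                     ["chrom", "start", "end", "bin_index"]].reset_index(drop=True)


def write_bin_calls(calls: pd.DataFrame, path: str) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")
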