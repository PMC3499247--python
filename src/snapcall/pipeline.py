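"""End-to-end orchestration: tags -> peaks -> bins -> loci -> scores ->
classification -> activator summary -> profiles -> promoter architectures.

The pipeline is deterministic and single-threaded: all randomness flows from
the configured seed (only the simulator draws random numbers), outputs are
plain TSV/BED text files, and rerunning with identical inputs reproduces
identical bytes.  A per-stage count report mirrors the reporting style of
co-occupancy studies (peaks per factor, paired peaks, positive bins, loci
per route).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import bin_enrichment, locus_assembly, motifs, peak_calling, profiles, scoring
from .bin_enrichment import SNAPC_SUBUNITS
from .synthetic_data import end3_boundary, tss_position
from .tag_model import filter_tags

POLYMERASE_FACTORS = ("POLR2B", "GTF2B", "POLR3D", "BRF2")
ALL_FACTORS = POLYMERASE_FACTORS + SNAPC_SUBUNITS + scoring.ACTIVATORS


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths for a pipeline run."""

    genome_fasta: str | None = None
    annotation_gff3: str | None = None
    tag_files: dict = field(default_factory=dict)  # factor -> path
    outdir: str = "snapcall_out"
    seed: int = 0
    max_matches: int = 500
    exclude_mismatches: bool = True
    fdr: float = 1e-5
    window_w: int = 20
    fragment_length: int = 150
    bin_size: int = 200
    bin_method: str = "threshold"  # or "normal_bh"
    alpha: float = 0.005
    max_dist: int = 100
    dual_fraction: float = 0.25
    score_pad: int = 0
    presence_pad: int = 400
    metagene_window: tuple = (-500, 2000)
    promoter_upstream: int = 400

    def config_hash(self) -> str:
        """Fingerprint of the analytic parameters (paths excluded)."""
        params = asdict(self)
        for key in ("outdir", "genome_fasta", "annotation_gff3", "tag_files"):
            params.pop(key, None)
        return hashlib.sha256(
            yaml.safe_dump(params, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "metagene_window" in data:
            data["metagene_window"] = tuple(data["metagene_window"])
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def run_pipeline(tags_by_factor: Mapping[str, pd.DataFrame],
                 genes: pd.DataFrame | None,
                 chrom_lengths: Mapping[str, int],
                 config: PipelineConfig | None = None,
                 genome: Mapping[str, str] | None = None) -> dict:
    """Run the full analysis on in-memory inputs; returns a result bundle.

    ``tags_by_factor`` maps factor name -> raw tag DataFrame (inclusion
    rules are applied here).  ``genes`` (truth or user annotation) powers the
    profile stages and may be None; ``genome`` powers promoter architecture
    annotation and may be None.
    """
    cfg = config or PipelineConfig()
    result: dict = {"counts": {}, "config_hash": cfg.config_hash()}
    stage = "ingest"
    try:
        retained = {f: filter_tags(t, cfg.max_matches, cfg.exclude_mismatches)
                    for f, t in tags_by_factor.items()}
        result["counts"]["retained_tags"] = {f: len(t) for f, t in retained.items()}

        stage = "callpeaks"
        params = peak_calling.CallerParams(window_w=cfg.window_w,
                                           fragment_length=cfg.fragment_length,
                                           fdr=cfg.fdr)
        peaks = {f: peak_calling.call_peaks(t, params, chrom_lengths, factor=f)
                 for f, t in retained.items()}
        result["peaks"] = peaks
        result["counts"]["peaks"] = {f: len(p) for f, p in peaks.items()}

        stage = "bins"
        snapc_tags = {s: retained[s] for s in SNAPC_SUBUNITS if s in retained}
        counts = bin_enrichment.bin_counts(snapc_tags, cfg.bin_size)
        if cfg.bin_method == "threshold":
            total = sum(float(np.sum(np.minimum(
                1.0, t["times_sequenced"] / t["n_matches"])))
                for t in snapc_tags.values()) / max(len(snapc_tags), 1)
            min_count = peak_calling.estimate_min_tag_count(
                total, sum(chrom_lengths.values()), cfg.bin_size, cfg.fdr)
            calls = bin_enrichment.threshold_method(counts, min_count,
                                                    cfg.bin_size)
            result["counts"]["bin_min_tag_count"] = min_count
        else:
            calls = bin_enrichment.normal_null_method(counts, cfg.alpha,
                                                      cfg.bin_size)
        pos_bins = bin_enrichment.positive_bins(calls)
        result["bin_calls"] = calls
        result["positive_bins"] = pos_bins
        result["counts"]["snapc_positive_bins"] = len(pos_bins)

        stage = "loci"
        loci_frames = []
        for route, (pol, basal) in locus_assembly.ROUTES.items():
            pairs = locus_assembly.pair_peaks(
                peaks.get(pol, pd.DataFrame(columns=peak_calling.PEAK_COLUMNS)),
                peaks.get(basal, pd.DataFrame(columns=peak_calling.PEAK_COLUMNS)),
                cfg.max_dist)
            result["counts"][f"paired_peaks_{route}"] = len(pairs)
            loci = locus_assembly.assemble_loci(pairs, pos_bins, route,
                                                cfg.max_dist)
            result["counts"][f"loci_{route}"] = len(loci)
            loci_frames.append(loci)
        route_loci = pd.concat(loci_frames, ignore_index=True)
        merged = _merge_routes(route_loci)
        result["route_loci"] = route_loci
        result["loci"] = merged
        result["counts"]["loci_total"] = len(merged)

        stage = "score"
        table = scoring.score_table(merged, retained, pad=cfg.score_pad)
        result["scores"] = table

        stage = "classify"
        classes = scoring.classify_polymerase(table,
                                              dual_fraction=cfg.dual_fraction)
        # flags need the per-route member scores
        flags = []
        for _, locus in merged.iterrows():
            pol, basal = locus_assembly.ROUTES[locus["route"].split("+")[0]]
            f = locus_assembly.flag_artifacts(
                locus,
                scoring.region_score(retained[pol], locus["chrom"],
                                     locus["start"], locus["end"]),
                scoring.region_score(retained[basal], locus["chrom"],
                                     locus["start"], locus["end"]))
            f |= locus_assembly.flag_high_background(locus, peaks)
            flags.append(",".join(sorted(f)))
        merged = merged.assign(flags=flags)
        result["loci"] = merged
        result["classes"] = classes
        result["counts"]["classified"] = dict(
            classes["pol_class"].value_counts().sort_index())

        stage = "summarize"
        presence = scoring.activator_presence(merged, peaks,
                                              pad=cfg.presence_pad)
        per_act, combos = scoring.activator_combo_summary(presence) \
            if len(presence) else (None, None)
        result["activator_presence"] = presence
        result["activator_summary"] = per_act
        result["activator_combos"] = combos
        try:
            result["correlations"] = scoring.correlation_matrix(table)
        except ValueError:
            result["correlations"] = None

        stage = "profile"
        if genes is not None and len(genes):
            result["metagene"] = {}
            for cls, factor in (("POL2", "POLR2B"), ("POL3", "POLR3D")):
                cohort = genes[genes["pol_class"] == cls]
                if len(cohort) and factor in retained:
                    result["metagene"][cls] = profiles.metagene_3prime(
                        retained[factor], cohort, window=cfg.metagene_window)
            offs, medians = profiles.summit_offsets(
                {f: peaks[f] for f in peaks if f not in ("POLR2B", "POLR3D")},
                genes)
            result["summit_offsets"] = offs
            result["summit_medians"] = medians

        stage = "motifs"
        if genome is not None and genes is not None and len(genes):
            summits = {f: list(zip(peaks[f]["chrom"], peaks[f]["summit"]))
                       for f in scoring.ACTIVATORS if f in peaks}
            archs = {}
            for _, g in genes.iterrows():
                tss = tss_position(int(g["start"]), int(g["end"]), g["strand"])
                b3 = end3_boundary(int(g["start"]), int(g["end"]), g["strand"])
                archs[g["gene_id"]] = motifs.annotate_promoter(
                    g["gene_id"], genome, g["chrom"], tss, g["strand"],
                    activator_summits=summits,
                    upstream=cfg.promoter_upstream, box3_end=b3)
            result["architectures"] = archs
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return result


def _merge_routes(route_loci: pd.DataFrame) -> pd.DataFrame:
    """Collapse overlapping POL2/POL3-route candidates into single loci.

    A dual-polymerase promoter is assembled by both routes; its two
    candidates overlap and merge into one locus carrying route 'POL2+POL3'.
    """
    if len(route_loci) == 0:
        return route_loci
    loci = route_loci.sort_values(["chrom", "start"],
                                  kind="stable").reset_index(drop=True)
    merged: list[dict] = []
    for _, row in loci.iterrows():
        if merged and merged[-1]["chrom"] == row["chrom"] \
                and row["start"] < merged[-1]["end"]:
            prev = merged[-1]
            prev["end"] = max(prev["end"], row["end"])
            if row["route"] not in prev["route"].split("+"):
                prev["route"] = "+".join(sorted(prev["route"].split("+")
                                                + [row["route"]]))
        else:
            merged.append(dict(row))
    out = pd.DataFrame(merged)
    out["locus_id"] = [f"LOC_{i + 1:03d}" for i in range(len(out))]
    return out.reset_index(drop=True)


def write_report(result: dict, config: PipelineConfig) -> None:
    """Write the result bundle as text files under ``config.outdir``."""
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    for factor, peaks in result.get("peaks", {}).items():
        peak_calling.write_peaks_bed(peaks, os.path.join(out, f"peaks_{factor}.bed"))
    if "bin_calls" in result:
        bin_enrichment.write_bin_calls(result["bin_calls"],
                                       os.path.join(out, "bin_calls.tsv"))
    if "loci" in result and len(result["loci"]):
        locus_assembly.write_loci(result["loci"],
                                  os.path.join(out, "loci.tsv"),
                                  os.path.join(out, "loci.bed"))
    for key, fname in (("scores", "scores.tsv"),
                       ("classes", "classes.tsv"),
                       ("correlations", "correlations.tsv"),
                       ("activator_summary", "activator_summary.tsv"),
                       ("activator_combos", "activator_combos.tsv"),
                       ("summit_offsets", "summit_offsets.tsv")):
        obj = result.get(key)
        if obj is not None and len(obj):
            obj.to_csv(os.path.join(out, fname), sep="\t",
                       float_format="%.6g")
    for cls, prof in result.get("metagene", {}).items():
        profiles.write_metagene_tsv(prof, os.path.join(out, f"metagene_{cls}.tsv"))
    if "architectures" in result:
        rows = []
        for gid, arch in result["architectures"].items():
            for e in arch.entries:
                rows.append({"gene_id": gid, "element": e.element,
                             "start_rel": e.start_rel, "end_rel": e.end_rel,
                             "strand": e.strand, "occupied": e.occupied,
                             "mismatches": e.mismatches})
        pd.DataFrame(rows).to_csv(os.path.join(out, "architectures.tsv"),
                                  sep="\t", index=False)
    report = {"config_hash": result.get("config_hash", ""),
              "counts": _jsonable(result.get("counts", {}))}
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
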