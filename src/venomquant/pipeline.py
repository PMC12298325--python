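"""Orchestration: the full quantification run over file inputs.

Stages run in order — chromatography, identification, densitometry/MS1,
peak-to-lane matching, allocation, rollup — and any failure is re-raised
as a :class:`StageError` naming the stage.  Detected chromatogram peaks
are matched to gel lanes by retention/collection time (lanes carry an
``rt_min`` column), so a missed minor peak cannot shift the lane
assignment of every later peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as abundance_mod
from . import chromatography as chrom
from . import densitometry, digest, ms1 as ms1_mod, synthio, transcriptome
from .config import RunConfig
from .records import InputError

log = logging.getLogger("venomquant")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("[%s] starting", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@dataclass
class QuantResult:
    peaks: pd.DataFrame
    table: abundance_mod.AbundanceTable
    families: pd.Series
    family_map: dict  # toxin group representative -> family
    report: str


@_stage("chromatography")
def _run_chromatography(cfg: RunConfig):
    trace = chrom.read_trace(cfg.trace)
    baseline = chrom.estimate_baseline(trace, window=cfg.baseline_window)
    peaks = chrom.detect_peaks(
        trace, baseline,
        min_prominence=cfg.min_prominence,
        min_area_fraction=cfg.min_area_fraction,
    )
    peaks = chrom.integrate_peaks(trace, baseline, peaks)
    return trace, baseline, peaks


@_stage("identification")
def _run_identification(cfg: RunConfig):
    records = digest.read_database(cfg.fasta, cfg.annotations)
    groups = digest.collapse_proteoforms(
        records,
        identity_threshold=cfg.identity_threshold,
        max_internal_insertion=cfg.max_internal_insertion,
    )
    gmap = digest.group_map(groups)
    by_id = {r.id: r for r in records}
    family_map = {g.representative: by_id[g.representative].family for g in groups}

    peptides = pd.read_csv(cfg.peptides, sep="\t")
    band_toxins: dict = {}
    for (pid, band_id), grp in peptides.groupby(["peak_id", "band_id"]):
        matches = digest.match_peptides(
            grp["peptide"].tolist(), records,
            il_equivalent=cfg.il_equivalent, groups=gmap,
        )
        inferred = digest.infer_proteins(
            matches, min_unique_peptides=cfg.min_unique_peptides
        )
        reps = sorted({gmap[pid_] for pid_ in inferred})
        if reps:
            band_toxins[(pid, band_id)] = reps
    return records, gmap, family_map, band_toxins


@_stage("densitometry/ms1")
def _run_band_tables(cfg: RunConfig, gmap: dict):
    lanes = densitometry.read_lanes(cfg.lanes)
    ms1 = ms1_mod.read_ms1(cfg.ms1)
    # fold MS1 toxin ids onto their proteoform-group representatives
    ms1 = ms1.assign(toxin_id=[gmap.get(t, t) for t in ms1["toxin_id"]])
    partitions = ms1_mod.partition_all(ms1)
    return lanes, partitions


@_stage("peak matching")
def _match_peaks_to_lanes(cfg: RunConfig, peaks: pd.DataFrame, lanes: pd.DataFrame):
    """Relabel detected peaks with lane peak ids by apex/collection time."""
    peaks = peaks.copy()
    peaks["peak_id"] = [f"D{i + 1}" for i in range(len(peaks))]
    lane_rts = lanes.groupby("peak_id")["rt_min"].first() if "rt_min" in lanes else None
    if lane_rts is None:
        raise InputError("lanes table lacks rt_min; cannot match peaks to lanes")
    used = set()
    mapping = {}
    for lane_pid, rt in lane_rts.items():
        dist = (peaks["apex_min"] - rt).abs()
        cand = dist[dist <= cfg.rt_tolerance]
        cand = cand.drop(index=[i for i in cand.index if i in used], errors="ignore")
        if len(cand):
            idx = cand.idxmin()
            used.add(idx)
            mapping[idx] = lane_pid
    unmatched_lanes = set(lane_rts.index) - set(mapping.values())
    for lane_pid in sorted(unmatched_lanes):
        log.warning("[peak matching] lane %s has no detected peak", lane_pid)
    peaks["peak_id"] = [
        mapping.get(i, peaks.at[i, "peak_id"]) for i in peaks.index
    ]
    return peaks


@_stage("allocation")
def _run_allocation(cfg, peaks, lanes, partitions, band_toxins):
    if cfg.exclude:
        peaks = chrom.exclude_and_renormalize(peaks, cfg.exclude)
    table = abundance_mod.allocate(peaks, lanes, partitions, band_toxins)
    return peaks, table


@_stage("rollup")
def _run_rollup(table, family_map, decimals):
    families = abundance_mod.family_rollup(table, family_map)
    report = abundance_mod.report_text(table, family_map, decimals)
    return families, report


def end_to_end_quant(cfg: RunConfig) -> QuantResult:
    """Run the full quantification: trace → peaks → bands → toxins → families."""
    _trace, _baseline, peaks = _run_chromatography(cfg)
    _records, gmap, family_map, band_toxins = _run_identification(cfg)
    lanes, partitions = _run_band_tables(cfg, gmap)
    peaks = _match_peaks_to_lanes(cfg, peaks, lanes)
    peaks, table = _run_allocation(cfg, peaks, lanes, partitions, band_toxins)
    families, report = _run_rollup(table, family_map, cfg.report_decimals)
    total = math.fsum(table.fractions.values()) + table.uncharacterized
    log.info("[allocation] conservation residual %.3e", abs(total - 1.0))
    return QuantResult(
        peaks=peaks, table=table, families=families,
        family_map=family_map, report=report,
    )


def run_all(cfg: RunConfig, out_dir) -> dict:
    """Execute the configured run and write all artifacts to ``out_dir``.

    In fixture mode the synthetic inputs are generated first (deterministic
    in the fixture seed).  Returns the paths of the written artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.fixture is not None:
        fx = dict(cfg.fixture)
        name = fx.pop("name", "aa_fixture")
        if name != "aa_fixture":
            raise InputError(f"unknown fixture {name!r}")
        seed = int(fx.pop("seed"))
        exclude_impurities = fx.pop("exclude_impurities", True)
        gen = synthio.write_fixture(out / "inputs", seed=seed, **fx)
        for key, path in gen["paths"].items():
            if key != "manifest":
                setattr(cfg, key, path)
        if exclude_impurities and not cfg.exclude:
            cfg.exclude = list(gen["venom"].impurity_peaks)
        log.info("[simulate] fixture %s written (seed %d)", name, seed)

    result = end_to_end_quant(cfg)

    paths = {
        "peaks": out / "peaks.tsv",
        "abundance": out / "abundance.tsv",
        "families": out / "families.tsv",
        "report": out / "report.txt",
        "manifest": out / "run_manifest.yaml",
    }
    chrom.write_peak_table(result.peaks, paths["peaks"])
    result.table.to_frame(result.family_map).to_csv(
        paths["abundance"], sep="\t", index=False
    )
    fam_frame = result.families.rename_axis("family").reset_index()
    fam_frame.to_csv(paths["families"], sep="\t", index=False)
    paths["report"].write_text(result.report)

    if cfg.expression:
        expr = transcriptome.read_expression(cfg.expression)
        expr = transcriptome.classify_active(expr)
        summary = transcriptome.summarize(expr)
        paths["transcriptome"] = out / "transcriptome_summary.tsv"
        summary.to_csv(paths["transcriptome"], sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "exclude": list(cfg.exclude),
        "baseline_window": cfg.baseline_window,
        "min_area_fraction": cfg.min_area_fraction,
        "uncharacterized": float(result.table.uncharacterized),
        "n_toxins_quantified": len(result.table.fractions),
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
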