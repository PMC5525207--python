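"""End-to-end orchestration: parse -> orient/filter -> extract -> profiles ->
statistics -> report bundle.

The report bundle is a fixed layout of long-format TSV tables (one directory
per run), each carrying the dataset label, regime, sample sizes and the run's
config hash, so every number in a table can be traced to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import annotation_io
from .complexity import DEFAULT_BOUNDARY, ComplexityBoundary, classify_complexity
from .extraction import ExtractionLedger, FlankConfig, OrientedTMH, extract_cohort
from .profiles import (
    UndefinedProfileError,
    absolute_relative_occurrence,
    background_level,
    count_occurrences,
    flank_average,
    hydrophobicity_profile,
    net_charge_profile,
    relative_percentage,
)
from .records import ProteinRecord
from .scales import get_scale
from .stats import (
    CountPair,
    DegenerateTestError,
    acidic_content_test,
    inside_outside_skew,
    leaflet_asymmetry,
    position_distribution_test,
    positionwise_hydro_test,
)

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"

DEFAULT_RESIDUE_CLASSES = ("D", "E", "DE", "K", "R", "KR", "L", "W", "Y", "C", "P")


class EmptyDatasetError(RuntimeError):
    """Every record was removed; names the filter responsible."""


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    input_path: Optional[Union[str, Path]] = None
    input_format: str = "flatfile"  # "flatfile" | "segments"
    label: str = "dataset"
    flank_configs: tuple[FlankConfig, ...] = (
        FlankConfig(max_flank=10, regime="db_no_overlap"),
        FlankConfig(max_flank=10, regime="db_overlap"),
        FlankConfig(max_flank=10, regime="db_viable"),
        FlankConfig(max_flank=20, regime="central", central_half_width=20),
    )
    profile_config: FlankConfig = FlankConfig(
        max_flank=20, regime="central", central_half_width=30
    )
    residue_classes: tuple[str, ...] = DEFAULT_RESIDUE_CLASSES
    scales: tuple[str, ...] = ("kyte_doolittle",)
    hydro_window: int = 3
    hydro_tests: tuple[str, ...] = ("kruskal_wallis", "t_two_sample")
    min_len: int = 16
    max_len: int = 38
    outdir: Optional[Union[str, Path]] = None
    seed: int = 0
    strict: bool = False
    include_complexity: bool = False
    complexity_boundary: ComplexityBoundary = DEFAULT_BOUNDARY

    def __post_init__(self):
        if not self.label:
            raise ValueError("dataset label must be nonempty")
        if not self.flank_configs:
            raise ValueError("at least one flank regime is required")

    def hash(self) -> str:
        blob = json.dumps(
            {
                "label": self.label,
                "flank_configs": [vars(c) | {} for c in self.flank_configs],
                "profile_config": vars(self.profile_config) | {},
                "residue_classes": list(self.residue_classes),
                "scales": list(self.scales),
                "hydro_window": self.hydro_window,
                "hydro_tests": list(self.hydro_tests),
                "min_len": self.min_len,
                "max_len": self.max_len,
                "seed": self.seed,
                "strict": self.strict,
                "include_complexity": self.include_complexity,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_records(cfg: RunConfig) -> list[ProteinRecord]:
    if cfg.input_path is None:
        raise ValueError("RunConfig.input_path is not set")
    if cfg.input_format == "flatfile":
        result = annotation_io.read_flatfile(cfg.input_path, strict=cfg.strict)
    elif cfg.input_format == "segments":
        result = annotation_io.read_segment_table(cfg.input_path, strict=cfg.strict)
    else:
        raise ValueError(f"unknown input format {cfg.input_format!r}")
    for err in result.errors:
        logger.warning("record rejected: %s", err)
    if not result.records:
        raise EmptyDatasetError("parsing removed every record (see warnings)")
    return result.records


# ---------------------------------------------------------------------------
# per-helix counting helpers
# ---------------------------------------------------------------------------

def _flank_pair(seg: OrientedTMH, residue_class: str, cfg: FlankConfig) -> CountPair:
    """Inside/outside residue-class counts for one helix under one regime."""
    if cfg.regime == "central":
        w, hw = cfg.central_half_width, cfg.central_core_halfwidth
        inside = outside = 0
        for pos, aa in seg.central_positions(cfg.even_center):
            if aa in residue_class:
                if -w <= pos <= -hw:
                    inside += 1
                elif hw <= pos <= w:
                    outside += 1
        return CountPair(inside, outside)
    return CountPair(
        sum(seg.inside_flank.count(aa) for aa in residue_class),
        sum(seg.outside_flank.count(aa) for aa in residue_class),
    )


def _position_observations(
    segments: Sequence[OrientedTMH], residue_class: str, even_center: str = "lower"
) -> list[int]:
    """One aligned position per residue-class occurrence over a segment set."""
    obs: list[int] = []
    for seg in segments:
        for pos, aa in seg.central_positions(even_center):
            if aa in residue_class:
                obs.append(pos)
    return obs


def _tmh_count_class(n_tmh: int) -> str:
    return str(n_tmh) if n_tmh < 15 else "15+"


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    """All tables of one analysis run, plus run metadata."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def write(self, outdir: Union[str, Path]) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in sorted(self.tables.items()):
            frame.to_csv(
                out / f"{name}.tsv", sep="\t", index=False,
                float_format=_FLOAT_FORMAT,
            )
        (out / "run_meta.json").write_text(
            json.dumps(self.meta, indent=2, sort_keys=True) + "\n"
        )


def run_analysis(
    cfg: RunConfig, records: Optional[Sequence[ProteinRecord]] = None
) -> ReportBundle:
    """Run the full analysis and return (and optionally write) the bundle.

    Emits: the extraction ledger, a single- vs multi-pass core residue
    content comparison, per-regime inside/outside skew tables, leaflet
    asymmetry, q/p profile tables with background and flank averages, the
    net-charge profile, hydrophobicity curves stratified by TMH count with
    per-position p curves, and (optionally) complexity calls.
    """
    if records is None:
        records = load_records(cfg)
    records = list(records)
    bundle = ReportBundle()
    config_hash = cfg.hash()
    common = {"dataset": cfg.label, "config_hash": config_hash}

    ledger_rows: list[dict] = []
    segments_by_regime: dict[str, list[OrientedTMH]] = {}
    for fc in cfg.flank_configs:
        segments, ledger = extract_cohort(records, fc, cfg.min_len, cfg.max_len)
        segments_by_regime[fc.regime] = segments
        for row in ledger.rows:
            ledger_rows.append({**common, **row})
    bundle.tables["ledger"] = pd.DataFrame(ledger_rows)
    if all(not segs for segs in segments_by_regime.values()):
        raise EmptyDatasetError(
            "flank extraction kept no helix in any regime (orientation and "
            f"length {cfg.min_len}..{cfg.max_len} filters removed everything)"
        )

    profile_segments, _ = extract_cohort(
        records, cfg.profile_config, cfg.min_len, cfg.max_len
    )
    by_pass = {
        "single": [s for s in profile_segments if s.pass_class == "single"],
        "multi": [s for s in profile_segments if s.pass_class == "multi"],
    }

    bundle.tables["acidic_content"] = _acidic_content_table(by_pass, common)
    bundle.tables["skew"] = _skew_table(cfg, segments_by_regime, common)
    bundle.tables["leaflet"] = _leaflet_table(segments_by_regime, cfg, common)
    prof_frames = _profile_tables(cfg, by_pass, common)
    bundle.tables.update(prof_frames)
    hydro_frames = _hydro_tables(cfg, by_pass, common)
    bundle.tables.update(hydro_frames)
    if cfg.include_complexity:
        bundle.tables["complexity"] = _complexity_table(cfg, by_pass, common)

    bundle.meta = {
        "dataset": cfg.label,
        "config_hash": config_hash,
        "n_records": len(records),
        "n_helices_per_regime": {
            regime: len(segs) for regime, segs in segments_by_regime.items()
        },
        "ledger_decision_counts": {
            regime: ExtractionLedger(
                [r for r in ledger_rows if r["regime"] == regime]
            ).counts()
            for regime in segments_by_regime
        },
    }
    if cfg.outdir is not None:
        bundle.write(cfg.outdir)
    return bundle


def _acidic_content_table(by_pass, common) -> pd.DataFrame:
    rows = []
    for residue_class in ("D", "E", "DE"):
        sp = [
            sum(s.core.count(aa) for aa in residue_class) for s in by_pass["single"]
        ]
        mp = [sum(s.core.count(aa) for aa in residue_class) for s in by_pass["multi"]]
        row = {
            **common,
            "residue_class": residue_class,
            "n_single": len(sp),
            "n_multi": len(mp),
        }
        try:
            res = acidic_content_test(sp, mp)
        except DegenerateTestError as err:
            rows.append({**row, "skip_reason": str(err)})
            continue
        rows.append(
            {
                **row,
                "mu_sp": res.extra["mu_sp"],
                "mu_mp": res.extra["mu_mp"],
                "H": res.statistic,
                "p_value": res.p_value,
                "N": res.n,
                "bahadur_slope": res.bahadur_slope,
                "skip_reason": "",
            }
        )
    return pd.DataFrame(rows)


def _skew_table(cfg, segments_by_regime, common) -> pd.DataFrame:
    rows = []
    for fc in cfg.flank_configs:
        segments = segments_by_regime[fc.regime]
        for pass_class in ("single", "multi"):
            group = [s for s in segments if s.pass_class == pass_class]
            for residue_class in cfg.residue_classes:
                row = {
                    **common,
                    "regime": fc.regime,
                    "pass_class": pass_class,
                    "residue_class": residue_class,
                    "n_helices": len(group),
                }
                pairs = [_flank_pair(s, residue_class, fc) for s in group]
                try:
                    res = inside_outside_skew(pairs)
                except DegenerateTestError as err:
                    rows.append({**row, "skip_reason": str(err)})
                    continue
                rows.append(
                    {
                        **row,
                        "inside_total": res.extra["total_inside"],
                        "outside_total": res.extra["total_outside"],
                        "signed_H": res.statistic,
                        "p_value": res.p_value,
                        "N": res.n,
                        "bahadur_slope": res.bahadur_slope,
                        "direction": res.direction,
                        "skip_reason": "",
                    }
                )
    return pd.DataFrame(rows)


def _leaflet_table(segments_by_regime, cfg, common) -> pd.DataFrame:
    regime = cfg.flank_configs[0].regime
    segments = segments_by_regime[regime]
    rows = []
    for pass_class in ("single", "multi"):
        group = [s for s in segments if s.pass_class == pass_class]
        row = {
            **common,
            "regime": regime,
            "pass_class": pass_class,
            "residue_class": "L",
            "n_helices": len(group),
        }
        try:
            res = leaflet_asymmetry([s.core for s in group])
        except DegenerateTestError as err:
            rows.append({**row, "skip_reason": str(err)})
            continue
        rows.append(
            {
                **row,
                "inner_total": res.extra["total_inner"],
                "outer_total": res.extra["total_outer"],
                "percentage": res.extra["percentage"],
                "signed_H": res.statistic,
                "p_value": res.p_value,
                "N": res.n,
                "bahadur_slope": res.bahadur_slope,
                "skip_reason": "",
            }
        )
    return pd.DataFrame(rows)


def _profile_tables(cfg, by_pass, common) -> dict[str, pd.DataFrame]:
    q_rows, charge_rows = [], []
    w = cfg.profile_config.central_half_width
    for pass_class, group in by_pass.items():
        if not group:
            continue
        counts = count_occurrences(group, anchor="central",
                                   even_center=cfg.profile_config.even_center)
        for residue_class in cfg.residue_classes:
            for kind, fn in (("q_rel", relative_percentage),
                             ("p_abs", absolute_relative_occurrence)):
                try:
                    prof = fn(counts, residue_class)
                except UndefinedProfileError:
                    continue
                try:
                    bg = background_level(prof) if w >= 30 else np.nan
                except UndefinedProfileError:
                    bg = np.nan
                try:
                    inside_avg, outside_avg = flank_average(prof)
                except UndefinedProfileError:
                    inside_avg = outside_avg = np.nan
                for pos, val in zip(prof.positions, prof.values):
                    q_rows.append(
                        {
                            **common,
                            "regime": "central",
                            "pass_class": pass_class,
                            "kind": kind,
                            "residue_class": residue_class,
                            "position": int(pos),
                            "value": float(val),
                            "background": bg,
                            "inside_flank_avg": inside_avg,
                            "outside_flank_avg": outside_avg,
                            "n_segments": prof.n_segments,
                        }
                    )
        charge = net_charge_profile(counts)
        for pos, val in zip(charge.positions, charge.values):
            charge_rows.append(
                {
                    **common,
                    "regime": "central",
                    "pass_class": pass_class,
                    "position": int(pos),
                    "net_charge": float(val),
                    "n_segments": charge.n_segments,
                }
            )
    return {
        "profiles": pd.DataFrame(q_rows),
        "net_charge": pd.DataFrame(charge_rows),
    }


def _hydro_tables(cfg, by_pass, common) -> dict[str, pd.DataFrame]:
    hydro_rows, p_rows = [], []
    all_segments = by_pass["single"] + by_pass["multi"]
    for scale_name in cfg.scales:
        scale = get_scale(scale_name)
        strata: dict[str, list[OrientedTMH]] = {}
        for seg in all_segments:
            strata.setdefault(_tmh_count_class(seg.n_tmh), []).append(seg)
        profs = {}
        for stratum, segs in sorted(strata.items()):
            prof = hydrophobicity_profile(segs, scale, cfg.hydro_window,
                                          cfg.profile_config.even_center)
            profs[stratum] = prof
            for pos, val in zip(prof.positions, prof.mean):
                hydro_rows.append(
                    {
                        **common,
                        "scale": scale_name,
                        "tmh_count_class": stratum,
                        "position": int(pos),
                        "mean_hydrophobicity": float(val),
                        "n_segments": prof.n_segments,
                    }
                )
        if by_pass["single"] and by_pass["multi"]:
            sp_prof = hydrophobicity_profile(
                by_pass["single"], scale, cfg.hydro_window,
                cfg.profile_config.even_center,
            )
            mp_prof = hydrophobicity_profile(
                by_pass["multi"], scale, cfg.hydro_window,
                cfg.profile_config.even_center,
            )
            for test in cfg.hydro_tests:
                results = positionwise_hydro_test(
                    sp_prof.values_by_position, mp_prof.values_by_position, test
                )
                for pos, res in results.items():
                    p_rows.append(
                        {
                            **common,
                            "scale": scale_name,
                            "test": test,
                            "position": int(pos),
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "log10_p": float(np.log10(res.p_value))
                            if res.p_value > 0
                            else -np.inf,
                            "N": res.n,
                            "bahadur_slope": res.bahadur_slope,
                        }
                    )
    return {
        "hydrophobicity": pd.DataFrame(hydro_rows),
        "hydro_pvalues": pd.DataFrame(p_rows),
    }


def _complexity_table(cfg, by_pass, common) -> pd.DataFrame:
    rows = []
    for seg in by_pass["single"]:
        call = classify_complexity(seg.core, boundary=cfg.complexity_boundary)
        rows.append(
            {
                **common,
                "accession": seg.accession,
                "tmh_index": seg.tmh_index,
                "mean_hydrophobicity": call.mean_hydrophobicity,
                "shannon_entropy": call.shannon_entropy,
                "call": call.call,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparison (simple / complex / multi-pass)
# ---------------------------------------------------------------------------

def compare_groups(
    cfg: RunConfig,
    records: Optional[Sequence[ProteinRecord]] = None,
    grouping: str = "single_vs_multi",
    tests: tuple[str, ...] = ("chi_square", "kolmogorov_smirnov", "kruskal_wallis"),
    min_group_size: int = 5,
) -> pd.DataFrame:
    """Pairwise positional-distribution comparisons between segment groups.

    Uses centrally aligned segments with flanks up to +-10.  For
    ``grouping="simple_vs_complex_vs_multi"``, single-pass helices are split
    by the complexity classifier (twilight calls are left out of the
    pairwise comparisons).  Each row carries the p value, N and Bahadur
    slope for one residue class x test x group pair.
    """
    if records is None:
        records = load_records(cfg)
    fc = FlankConfig(max_flank=10, regime="central", central_half_width=20)
    segments, _ = extract_cohort(records, fc, cfg.min_len, cfg.max_len)
    single = [s for s in segments if s.pass_class == "single"]
    multi = [s for s in segments if s.pass_class == "multi"]
    if grouping == "single_vs_multi":
        groups = {"single": single, "multi": multi}
    elif grouping == "simple_vs_complex_vs_multi":
        groups = {"simple": [], "complex": [], "multi": multi}
        for seg in single:
            call = classify_complexity(seg.core, boundary=cfg.complexity_boundary).call
            if call in groups:
                groups[call].append(seg)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    names = list(groups)
    rows = []
    for residue_class in cfg.residue_classes:
        obs = {
            name: _position_observations(groups[name], residue_class)
            for name in names
        }
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                for test in tests:
                    row = {
                        "dataset": cfg.label,
                        "config_hash": cfg.hash(),
                        "residue_class": residue_class,
                        "test": test,
                        "group_a": a,
                        "group_b": b,
                        "n_a": len(groups[a]),
                        "n_b": len(groups[b]),
                    }
                    if len(groups[a]) < min_group_size or len(groups[b]) < min_group_size:
                        rows.append({**row, "skip_reason": "group below minimum size"})
                        continue
                    try:
                        res = position_distribution_test(obs[a], obs[b], test=test)
                    except DegenerateTestError as err:
                        rows.append({**row, "skip_reason": str(err)})
                        continue
                    rows.append(
                        {
                            **row,
                            "statistic": res.statistic,
                            "p_value": res.p_value,
                            "N": res.n,
                            "bahadur_slope": res.bahadur_slope,
                            "skip_reason": "",
                        }
                    )
    return pd.DataFrame(rows)
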