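"""Reproducible analysis runs driven by a single serializable config.

``run_report`` reads the input tables, executes the selected analyses and
writes plain TSV reports (a mapping/interference table in the layout of a
classical tetrad-analysis summary, a spore-viability table, adjacent-interval
interference results, and a gel-quantification summary).  Every artifact
embeds the config hash and seed in comment lines, and a rerun with an
identical config produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .errors import InputError
from .io import read_band_table, read_marker_map, read_tetrads
from .linkage import (
    NPDSEMethod,
    interference_ratio_analysis,
    npd_interference_ratio,
    percent_of_reference,
    perkins_map_distance,
    report_cm,
    report_percent,
    report_ratio,
)
from .pfge import summarize_timecourse
from .tetrads import RELAXED_POLICY, STRICT_POLICY, tabulate_interval, viability_summary

log = logging.getLogger("tetramap")

_ANALYSES = ("viability", "map", "interference", "ratio_interference", "pfge")


@dataclass
class RunConfig:
    markers: str
    tetrads: Optional[str] = None
    reference_tetrads: Optional[str] = None
    bands: Optional[str] = None
    intervals: list[list[str]] = field(default_factory=list)
    interference_pairs: list[dict] = field(default_factory=list)
    analyses: list[str] = field(default_factory=lambda: ["viability", "map", "interference"])
    policy: str = "strict"
    se_method: str = "poisson"
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "tetramap_out"

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(_ANALYSES)
        if unknown:
            raise InputError(f"unknown analyses {sorted(unknown)}; valid: {_ANALYSES}")
        if self.policy not in ("strict", "relaxed"):
            raise InputError("policy must be 'strict' or 'relaxed'")
        if self.se_method not in ("poisson", "delta"):
            raise InputError("se_method must be 'poisson' or 'delta'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise InputError(f"{path}: {exc}") from None

    def canonical_json(self) -> str:
        # out_dir is where results land, not what they are; keep it out of
        # the identity hash so relocated reruns stay comparable
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return json.dumps(payload, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _fmt(x: float, nd: int = 4) -> str:
    if isinstance(x, float) and not math.isfinite(x):
        return "n.d."
    return f"{x:.{nd}f}".rstrip("0").rstrip(".") if isinstance(x, float) else str(x)


def run_report(config: RunConfig) -> dict[str, Path]:
    """Execute the analyses selected in ``config``; returns artifact paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = [f"# tetramap_config={config.config_hash()}", f"# seed={config.seed}"]
    policy = STRICT_POLICY if config.policy == "strict" else RELAXED_POLICY
    se_method = NPDSEMethod(config.se_method)
    marker_map = read_marker_map(config.markers)
    artifacts: dict[str, Path] = {}

    (out_dir / "config.yaml").write_text(
        "\n".join(stamp) + "\n" + yaml.safe_dump(asdict(config), sort_keys=True)
    )
    artifacts["config"] = out_dir / "config.yaml"

    tetrads = None
    if config.tetrads is not None:
        tetrads = read_tetrads(config.tetrads, marker_map)
        log.info("read %d tetrads from %s", len(tetrads), config.tetrads)

    needs_tetrads = {"viability", "map", "interference", "ratio_interference"}
    if needs_tetrads & set(config.analyses) and tetrads is None:
        raise InputError("selected analyses require a tetrad table")

    if "viability" in config.analyses:
        vs = viability_summary(tetrads)
        lines = stamp + ["n_tetrads\t4sv\t3sv\t2sv\t1sv\t0sv\toverall_viability_pct"]
        lines.append(
            "\t".join(
                [str(vs.n_tetrads)]
                + [str(vs.sv_counts[k]) for k in (4, 3, 2, 1, 0)]
                + [_fmt(vs.overall_viability, 1)]
            )
        )
        path = out_dir / "viability.tsv"
        path.write_text("\n".join(lines) + "\n")
        artifacts["viability"] = path

    if {"map", "interference"} & set(config.analyses):
        if not config.intervals:
            raise InputError("map/interference analyses require at least one interval")
        ref_tetrads = (
            read_tetrads(config.reference_tetrads, marker_map)
            if config.reference_tetrads
            else None
        )
        lines = stamp + [
            "interval\tPD\tTT\tNPD\tTotal\tn_unscorable\tcM\tse_cM\tpct_reference\tNPD_obs\tNPD_exp\tNPD_ratio\tNPD_ratio_se\tflags"
        ]
        for pair in config.intervals:
            a, b = pair
            counts = tabulate_interval(tetrads, marker_map, a, b, policy)
            est = perkins_map_distance(counts)
            pct = ""
            if ref_tetrads is not None:
                ref_counts = tabulate_interval(ref_tetrads, marker_map, a, b, policy)
                pct = str(report_percent(percent_of_reference(est, perkins_map_distance(ref_counts))))
            npd = npd_interference_ratio(counts, se_method)
            flags = "low_npd" if npd.flag_low_npd else ""
            lines.append(
                "\t".join(
                    [
                        f"{counts.interval[0]}-{counts.interval[1]}",
                        str(counts.pd),
                        str(counts.tt),
                        str(counts.npd),
                        str(counts.n),
                        str(counts.n_unscorable),
                        _fmt(report_cm(est.cM), 1),
                        _fmt(est.se, 2),
                        pct,
                        str(npd.npd_obs),
                        _fmt(npd.npd_exp, 2),
                        _fmt(report_ratio(npd.ratio), 2),
                        _fmt(npd.se, 2),
                        flags,
                    ]
                )
            )
        path = out_dir / "mapping.tsv"
        path.write_text("\n".join(lines) + "\n")
        artifacts["mapping"] = path

    if "ratio_interference" in config.analyses:
        if not config.interference_pairs:
            raise InputError("ratio_interference requires interference_pairs")
        lines = stamp + [
            "reference\ttest\tcM_ref_PD\tcM_ref_REC\tratio\tchi2\tchi2_p\tmap_diff_p\tinterference_called\tdiagnostic"
        ]
        for pair in config.interference_pairs:
            res = interference_ratio_analysis(
                tetrads,
                marker_map,
                tuple(pair["reference"]),
                tuple(pair["test"]),
                alpha=config.alpha,
                policy=policy,
            )
            lines.append(
                "\t".join(
                    [
                        "-".join(res.reference_interval),
                        "-".join(res.test_interval),
                        _fmt(res.cm_pd.cM, 2) if res.cm_pd else "n.d.",
                        _fmt(res.cm_rec.cM, 2) if res.cm_rec else "n.d.",
                        _fmt(report_ratio(res.ratio), 2),
                        _fmt(res.chi2_stat, 3),
                        _fmt(res.chi2_p, 5),
                        _fmt(res.map_diff_p, 5),
                        str(res.interference_called).lower(),
                        res.diagnostic or "",
                    ]
                )
            )
        path = out_dir / "interference_ratio.tsv"
        path.write_text("\n".join(lines) + "\n")
        artifacts["interference_ratio"] = path

    if "pfge" in config.analyses:
        if config.bands is None:
            raise InputError("pfge analysis requires a band-intensity table")
        summary = summarize_timecourse(read_band_table(config.bands))
        lines = stamp + ["strain\ttimepoint_h\tmean_pct\tmin_pct\tmax_pct\tn_replicates"]
        for _, row in summary.iterrows():
            lines.append(
                "\t".join(
                    [
                        str(row["strain"]),
                        _fmt(float(row["timepoint_h"]), 1),
                        _fmt(float(row["mean"]), 2),
                        _fmt(float(row["min"]), 2),
                        _fmt(float(row["max"]), 2),
                        str(int(row["n_replicates"])),
                    ]
                )
            )
        path = out_dir / "pfge_summary.tsv"
        path.write_text("\n".join(lines) + "\n")
        artifacts["pfge"] = path

    log_lines = stamp + [
        f"# tetramap_version={__version__}",
        f"# policy={config.policy} se_method={config.se_method} alpha={config.alpha}",
        f"# analyses={','.join(config.analyses)}",
    ]
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = out_dir / "run_log.txt"
    return artifacts
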