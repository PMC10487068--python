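"""Study orchestration: from a config of per-replicate files to report tables.

The design is a two-group comparison (typically NDC vs DC, three replicate
cheeses each).  Per-replicate indices are computed first by the stage
modules, then aggregated to group mean ± SD (n = replicates), and finally
every variable present in both groups is compared with the variance-gated
t-test.  Outputs are plain CSV tables plus a YAML run log recording every
parameter, so a rerun of the same config is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import imaging, io, stats, texture
from .relaxometry import fit_multiexponential

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study"]


@dataclass
class StudyConfig:
    """Declarative description of one study run.

    ``assays`` maps assay name → {group label → list of file paths}:
    ``imaging`` (TIFF/PNG scans), ``relaxometry`` (decay CSVs), ``texture``
    (force–displacement CSVs), ``peaks`` (CZE peak-table CSVs); the
    optional ``summaries`` entry is a single long-format CSV of published
    or externally measured group summaries folded straight into the
    comparison table.
    """

    groups: list[str]
    assays: dict[str, Any] = field(default_factory=dict)
    resolution: float = 236.0
    min_area_mm2: float = 0.2
    n_components: int = 4
    alpha: float = 0.05
    h0_mm: float = 20.0
    probe_diameter_mm: float = 3.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "groups": list(self.groups),
            "assays": self.assays,
            "resolution": self.resolution,
            "min_area_mm2": self.min_area_mm2,
            "n_components": self.n_components,
            "alpha": self.alpha,
            "h0_mm": self.h0_mm,
            "probe_diameter_mm": self.probe_diameter_mm,
            "seed": self.seed,
        }


def _group_stats(values: dict[str, list[float]]) -> list[tuple[str, int, float, float]]:
    out = []
    for grp, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append((grp, int(arr.size), float(arr.mean()), sd))
    return out


def _imaging_stage(cfg: StudyConfig, files: dict[str, list], out: Path) -> pd.DataFrame:
    rows = []
    for grp, paths in files.items():
        for path in paths:
            img = io.load_slice_image(path, resolution=cfg.resolution)
            regions = imaging.segment_openings(img, min_area_mm2=cfg.min_area_mm2)
            if not regions:
                rows.append({"group": grp, "image": str(path), "n_openings": 0,
                             "porosity_pct": 0.0})
                continue
            summ = imaging.size_distribution(regions, img.section_area_mm2)
            rows.append({"group": grp, "image": str(path), **summ.__dict__})
    df = pd.DataFrame(rows)
    df.to_csv(out / "table1_openings.csv", index=False)
    return df


def _relaxometry_stage(cfg: StudyConfig, files: dict[str, list], out: Path) -> pd.DataFrame:
    rows = []
    for grp, paths in files.items():
        for path in paths:
            decay = io.read_decay_csv(path)
            fit = fit_multiexponential(decay, n_components=cfg.n_components, seed=cfg.seed)
            row: dict[str, Any] = {"group": grp, "decay": str(path), "converged": fit.converged}
            for pop in fit.populations:
                row[f"pop_{pop.label}_pct"] = pop.abundance_pct
                row[f"t2{pop.label}_ms"] = pop.t2_ms
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "table3_relaxometry.csv", index=False)
    return df


def _texture_stage(cfg: StudyConfig, files: dict[str, list], out: Path) -> pd.DataFrame:
    rows = []
    for grp, paths in files.items():
        for path in paths:
            curve = io.read_curve_csv(path, h0_mm=cfg.h0_mm, probe_diameter_mm=cfg.probe_diameter_mm)
            idx = texture.texture_indices(curve)
            rows.append(
                {
                    "group": grp,
                    "curve": str(path),
                    "young_modulus_MPa": idx.young_modulus_MPa,
                    "fracture_stress_MPa": idx.fracture_stress_MPa,
                    "fracture_strain": idx.fracture_strain,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "texture_indices.csv", index=False)
    return df


def _peaks_stage(cfg: StudyConfig, files: dict[str, list], out: Path) -> pd.DataFrame:
    rows = []
    for grp, paths in files.items():
        for path in paths:
            ratios = stats.casein_ratios(io.read_peaks_csv(path))
            rows.append({"group": grp, "peaks": str(path), **ratios.as_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(out / "table2_proteolysis.csv", index=False)
    return df


_MEASURED_VARS = {
    "imaging": ["porosity_pct", "d50_mm2", "mean_mm2", "max_mm2"],
    "relaxometry": None,  # every pop_*/t2* column
    "texture": ["young_modulus_MPa", "fracture_stress_MPa", "fracture_strain"],
    "peaks": list(stats.RATIO_NAMES),
}


def run_study(config: StudyConfig, out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Run every configured assay and write the report bundle to out_dir.

    Returns the tables also as DataFrames keyed by name.  A variable
    measured in only one group is reported but not compared (a warning is
    logged); nothing crashes on a partially filled design.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    per_variable: dict[str, dict[str, list[float]]] = {}

    stage_fns = {
        "imaging": _imaging_stage,
        "relaxometry": _relaxometry_stage,
        "texture": _texture_stage,
        "peaks": _peaks_stage,
    }
    for assay, fn in stage_fns.items():
        files = config.assays.get(assay)
        if not files:
            continue
        df = fn(config, files, out)
        tables[assay] = df
        want = _MEASURED_VARS[assay]
        cols = want if want is not None else [
            c for c in df.columns if c.startswith(("pop_", "t2"))
        ]
        for col in cols:
            if col not in df.columns:
                continue
            for grp, sub in df.groupby("group"):
                vals = sub[col].dropna().astype(float).tolist()
                if vals:
                    per_variable.setdefault(col, {}).setdefault(grp, []).extend(vals)

    summary_rows = []
    comparison_rows = []
    for var, groups in per_variable.items():
        for grp, n, mean, sd in _group_stats(groups):
            summary_rows.append({"variable": var, "group": grp, "n": n, "mean": mean, "sd": sd})

    # externally supplied summaries enter the comparison table directly
    if config.assays.get("summaries"):
        ext = io.read_summaries_csv(config.assays["summaries"])
        tables["summaries"] = ext
        for r in ext.itertuples():
            summary_rows.append(
                {"variable": r.variable, "group": r.group, "n": int(r.n),
                 "mean": float(r.mean), "sd": float(r.sd)}
            )

    summaries = pd.DataFrame(summary_rows)
    if not summaries.empty:
        summaries.to_csv(out / "group_summaries.csv", index=False)
        tables["group_summaries"] = summaries
        micro = summaries[summaries.variable.str.endswith("_logcfu")]
        if not micro.empty:
            micro.to_csv(out / "table4_microbiology.csv", index=False)
        for var, sub in summaries.groupby("variable"):
            grp_rows = {r.group: r for r in sub.itertuples()}
            if len(grp_rows) != 2:
                logger.warning("variable %s present in %d group(s); comparison skipped",
                               var, len(grp_rows))
                continue
            (ga, gb) = (grp_rows[g] for g in sorted(grp_rows))
            a = stats.GroupSummary(ga.group, int(ga.n), float(ga.mean), float(ga.sd), var)
            b = stats.GroupSummary(gb.group, int(gb.n), float(gb.mean), float(gb.sd), var)
            if a.n < 2 or b.n < 2:
                logger.warning("variable %s has n < 2; comparison skipped", var)
                continue
            res = stats.compare_groups(a, b, alpha=config.alpha)
            comparison_rows.append(
                {
                    "variable": var,
                    "group_a": a.label, "mean_a": a.mean, "sd_a": a.sd, "n_a": a.n,
                    "group_b": b.label, "mean_b": b.mean, "sd_b": b.sd, "n_b": b.n,
                    "f_ratio": res.f_ratio, "f_p": res.f_p, "test_used": res.test_used,
                    "t_stat": res.t_stat, "df": res.df, "p_value": res.p_value,
                    "significant": res.significant,
                }
            )
    comparisons = pd.DataFrame(comparison_rows)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    tables["comparisons"] = comparisons

    with open(out / "run_log.yml", "w") as fh:
        yaml.safe_dump({"config": config.to_dict()}, fh, sort_keys=True)
    return tables
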