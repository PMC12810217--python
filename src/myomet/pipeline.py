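"""End-to-end pipeline: generate -> morphometry -> jumps -> MRS -> stats.

One seeded, config-driven run producing per-stage CSV/JSON artifacts and a
markdown report: the per-muscle morphometry table, per-subject jump
results, MRS lipid quantifications, group statistics with pairwise tests,
the power-volume regressions per age group, and the dynapenia
decomposition for athletes and controls.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, mechanography, morphometry, spectroscopy, stats
from .morphometry import DEFAULT_EXCLUSION_FF, DEFAULT_SHELL_THICKNESS
from .synthetic import CohortBundle, CohortSpec, default_cohort_spec, generate_cohort

ALL_STAGES = ("cohort", "morphometry", "jumps", "mrs", "stats")

#: Group pairs compared in the stats stage (sport within age, age within sport).
PAIRWISE = (
    ("old_athlete", "old_control"),
    ("young_athlete", "young_control"),
    ("old_athlete", "young_athlete"),
    ("old_control", "young_control"),
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending subject."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    voxel_dims: tuple[float, float, float] = (2.34, 2.34, 10.0)
    n_per_group: dict | int | None = None
    shell_thickness_voxels: int = DEFAULT_SHELL_THICKNESS
    exclusion_ff_pct: float = DEFAULT_EXCLUSION_FF
    takeoff_threshold_n: float = 10.0
    write_raw: bool = False
    cohort_spec: CohortSpec | None = field(default=None, compare=False)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        if self.shell_thickness_voxels < 1 or self.exclusion_ff_pct <= 0 or (
            self.takeoff_threshold_n <= 0
        ):
            raise PipelineError("thresholds must be positive")
        if "stats" in self.stages and not {"morphometry", "jumps"} <= set(self.stages):
            raise PipelineError("stats stage requires morphometry and jumps stages")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "voxel_dims" in raw:
            raw["voxel_dims"] = tuple(raw["voxel_dims"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "stages": list(self.stages),
            "voxel_dims": list(self.voxel_dims),
            "n_per_group": self.n_per_group,
            "shell_thickness_voxels": self.shell_thickness_voxels,
            "exclusion_ff_pct": self.exclusion_ff_pct,
            "takeoff_threshold_n": self.takeoff_threshold_n,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _stage_cohort(cfg: RunConfig, out: Path) -> CohortBundle:
    spec = cfg.cohort_spec or default_cohort_spec(
        voxel_dims=cfg.voxel_dims, n_per_group=cfg.n_per_group, seed=cfg.seed
    )
    bundle = generate_cohort(spec)
    if "cohort" in cfg.stages:
        cdir = out / "cohort"
        cdir.mkdir(parents=True, exist_ok=True)
        _write_csv(bundle.table(), cdir / "subjects.csv")
        if cfg.write_raw:
            for s in bundle.subjects:
                for name, m in s.maps.items():
                    morphometry.write_voxel_table(m, cdir / f"{s.subject_id}_{name}.tsv")
                for j, tr in enumerate(s.jump_traces):
                    mechanography.write_force_trace(tr, cdir / f"{s.subject_id}_jump{j}.csv")
                spectroscopy.write_fid(s.fid, cdir / f"{s.subject_id}_fid.csv")
    return bundle


def _stage_morphometry(cfg: RunConfig, bundle: CohortBundle, out: Path) -> pd.DataFrame:
    rows = []
    for s in bundle.subjects:
        try:
            for name, m in s.maps.items():
                summ = morphometry.summarize(
                    m,
                    shell_thickness=cfg.shell_thickness_voxels,
                    exclusion_ff=cfg.exclusion_ff_pct,
                )
                rows.append(vars(summ))
            comp = morphometry.composite_muscles(
                list(s.maps.values()), name="jumping_composite"
            )
            rows.append(vars(morphometry.summarize(
                comp,
                shell_thickness=cfg.shell_thickness_voxels,
                exclusion_ff=cfg.exclusion_ff_pct,
            )))
        except Exception as exc:
            raise PipelineError(f"stage morphometry failed for {s.subject_id}: {exc}") from exc
    df = pd.DataFrame(rows)
    df["ff_delta_pct"] = df["ff_shell_pct"] - df["ff_centre_pct"]
    _write_csv(df, out / "morphometry.csv")
    return df


def _stage_jumps(cfg: RunConfig, bundle: CohortBundle, out: Path) -> pd.DataFrame:
    rows = []
    for s in bundle.subjects:
        try:
            results = [
                mechanography.peak_power(tr, takeoff_threshold_n=cfg.takeoff_threshold_n)
                for tr in s.jump_traces
            ]
            median = mechanography.median_peak_power(results)
            for j, r in enumerate(results):
                rows.append(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "jump": j,
                        "body_mass_kg": r.body_mass_kg,
                        "peak_power_kw": r.peak_power_kw,
                        "median_peak_power_kw": median,
                        "truth_peak_power_kw": s.jump_truths[j].peak_power_kw,
                    }
                )
        except Exception as exc:
            raise PipelineError(f"stage jumps failed for {s.subject_id}: {exc}") from exc
    df = pd.DataFrame(rows)
    _write_csv(df, out / "jumps.csv")
    return df


def _stage_mrs(cfg: RunConfig, bundle: CohortBundle, out: Path) -> pd.DataFrame:
    rows = []
    for s in bundle.subjects:
        try:
            model = spectroscopy.fit_three_peaks(s.fid, prior=None)
            quant = spectroscopy.lipid_fractions(model)
            truth = spectroscopy.lipid_fractions(s.mrs_truth)
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "emcl_pct": quant.emcl_pct,
                    "imcl_pct": quant.imcl_pct,
                    "fit_residual": quant.fit_residual,
                    "truth_emcl_pct": truth.emcl_pct,
                    "truth_imcl_pct": truth.imcl_pct,
                }
            )
        except Exception as exc:
            raise PipelineError(f"stage mrs failed for {s.subject_id}: {exc}") from exc
    df = pd.DataFrame(rows)
    _write_csv(df, out / "mrs.csv")
    return df


def _group_summaries(df: pd.DataFrame, value: str, variable: str) -> dict:
    out = {}
    for g, sub in df.groupby("group"):
        vals = sub[value].to_numpy()
        if len(vals) >= 2:
            out[g] = stats.GroupSummary(
                variable, g, float(vals.mean()), float(vals.std(ddof=1)), len(vals)
            )
    return out


def _stage_stats(
    cfg: RunConfig,
    morpho: pd.DataFrame,
    jumps: pd.DataFrame,
    out: Path,
) -> tuple[pd.DataFrame, dict]:
    morpho = morpho[~morpho["excluded"]]
    comp = morpho[morpho["muscle_name"] == "jumping_composite"]
    medians = jumps.drop_duplicates("subject_id")[
        ["subject_id", "group", "median_peak_power_kw"]
    ]
    per_subject = comp.merge(medians, on=["subject_id", "group"])

    rows = []
    tests = []
    for muscle, sub in morpho.groupby("muscle_name"):
        for variable, col in (("volume_ml", "volume_ml"), ("ff_mean_pct", "ff_mean_pct")):
            summ = _group_summaries(sub, col, variable)
            rows.extend(
                {
                    "muscle": muscle,
                    "variable": variable,
                    "group": g,
                    "mean": s.mean,
                    "sd": s.sd,
                    "n": s.n,
                }
                for g, s in summ.items()
            )
            pvals, meta = [], []
            for a, b in PAIRWISE:
                if a in summ and b in summ:
                    t, p = stats.two_sample_test(summ[a], summ[b])
                    d = stats.cohens_d(summ[a], summ[b])
                    pvals.append(p)
                    meta.append((a, b, t, d))
            adj = stats.bonferroni(pvals) if pvals else []
            for (a, b, t, d), p, pa in zip(meta, pvals, np.atleast_1d(adj)):
                tests.append(
                    {
                        "muscle": muscle,
                        "variable": variable,
                        "group_a": a,
                        "group_b": b,
                        "t": t,
                        "p": p,
                        "p_bonferroni": pa,
                        "cohens_d": d,
                    }
                )
    summaries_df = pd.DataFrame(rows)
    tests_df = pd.DataFrame(tests)
    _write_csv(summaries_df, out / "group_summaries.csv")
    _write_csv(tests_df, out / "stats.csv")

    regression = {}
    young = per_subject[per_subject["group"].str.startswith("young")]
    old = per_subject[per_subject["group"].str.startswith("old")]
    for age, sub in (("young", young), ("old", old)):
        for basis in ("volume_ml", "lean_volume_ml"):
            fit = stats.power_volume_regression(
                sub[basis], sub["median_peak_power_kw"]
            )
            regression[f"{age}_{basis}"] = {
                "intercept_kw": fit.intercept_kw,
                "slope_w_per_ml": fit.slope_w_per_ml,
                "pearson_r": fit.pearson_r,
                "n": fit.n,
                "residual_sd_kw": fit.residual_sd_kw,
                "p_value": fit.p_value,
            }
    f_stat, p_slope = stats.slope_difference_test(
        young["volume_ml"], young["median_peak_power_kw"],
        old["volume_ml"], old["median_peak_power_kw"],
    )
    regression["slope_difference"] = {"F": f_stat, "p": p_slope}

    slope = regression["young_volume_ml"]["slope_w_per_ml"]
    decomposition = {"slope_w_per_ml": slope}
    for sport in ("athlete", "control"):
        means = {}
        for age in ("young", "old"):
            sub = per_subject[per_subject["group"] == f"{age}_{sport}"]
            means[age] = stats.CompositeMeans(
                volume_ml=float(sub["volume_ml"].mean()),
                lean_volume_ml=float(sub["lean_volume_ml"].mean()),
                peak_power_kw=float(sub["median_peak_power_kw"].mean()),
            )
        dec = stats.dynapenia_decomposition(means["young"], means["old"], slope)
        decomposition[f"{sport}s"] = dec.as_dict()

    (out / "regression.json").write_text(json.dumps(regression, indent=2) + "\n")
    (out / "decomposition.json").write_text(json.dumps(decomposition, indent=2) + "\n")
    return tests_df, decomposition


def _report(out: Path, cfg: RunConfig, bundle, decomposition: dict | None) -> None:
    lines = [
        "# Pipeline run report",
        "",
        f"- package version: {__version__}",
        f"- seed: {cfg.seed}",
        f"- config hash: {cfg.config_hash()}",
        f"- stages: {', '.join(cfg.stages)}",
        f"- subjects: {len(bundle.subjects)}",
        f"- voxel grid (mm): {cfg.voxel_dims}",
        "",
    ]
    if decomposition:
        lines.append("## Dynapenia decomposition (group means, fitted young slope)")
        lines.append("")
        lines.append(f"slope: {decomposition['slope_w_per_ml']:.3f} W/ml")
        for sport in ("athletes", "controls"):
            d = decomposition[sport]
            lines.append(
                f"- {sport}: total decline {d['total_decline_w']:.0f} W = "
                f"sarcopenia {d['sarcopenia_w']:.0f} W + "
                f"myosteatosis {d['myosteatosis_w']:.0f} W + "
                f"sarcosthenia {d['sarcosthenia_w']:.0f} W "
                f"({d['pct_sarcosthenia']:.0f}% sarcosthenia)"
            )
    (out / "report.md").write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the in-memory artifacts.

    Writes per-stage outputs plus ``manifest.json`` and ``report.md`` into
    ``cfg.out_dir``.  Reruns with the same config are byte-identical.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    bundle = _stage_cohort(cfg, out)
    artifacts["cohort"] = bundle
    if "morphometry" in cfg.stages:
        artifacts["morphometry"] = _stage_morphometry(cfg, bundle, out)
    if "jumps" in cfg.stages:
        artifacts["jumps"] = _stage_jumps(cfg, bundle, out)
    if "mrs" in cfg.stages:
        artifacts["mrs"] = _stage_mrs(cfg, bundle, out)
    decomposition = None
    if "stats" in cfg.stages:
        artifacts["stats"], decomposition = _stage_stats(
            cfg, artifacts["morphometry"], artifacts["jumps"], out
        )
        artifacts["decomposition"] = decomposition
    manifest = {
        "package": "myomet",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": list(cfg.stages),
        "n_subjects": len(bundle.subjects),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    _report(out, cfg, bundle, decomposition)
    return artifacts
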