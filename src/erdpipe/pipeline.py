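"""End-to-end orchestration: simulate/read -> reject -> ERD -> model -> report.

A run produces a *bundle* directory containing the configuration echo, the
rejection report, the tidy ERD table, model results as JSON, figures and a
MANIFEST listing every artifact.  Outputs carry no timestamps so a re-run
with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from erdpipe import artifacts as ar  # noqa: E402
from erdpipe import modeling as md  # noqa: E402
from erdpipe import spectral as sp  # noqa: E402
from erdpipe import synthetic as syn  # noqa: E402
from erdpipe.io import epoch_trials, read_recording  # noqa: E402

logger = logging.getLogger(__name__)

MIN_SUBJECTS_FOR_MODELING = 6


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline failed at stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic-signal"  # synthetic-signal | synthetic-erd | data
    out_dir: str = "results/run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)       # CohortSpec overrides
    rejection: dict = field(default_factory=dict)    # RejectionConfig overrides
    bands: list[str] = field(default_factory=lambda: ["alpha"])
    erd_method: str = "per_trial"
    stage1_reml: bool = True
    stage1_correlated: bool = True
    data_dir: str | None = None
    log_level: str = "INFO"

    def cohort_spec(self) -> syn.CohortSpec:
        params = dict(self.cohort)
        params.setdefault("seed", self.seed)
        if "gamma" in params:
            params["gamma"] = tuple(params["gamma"])
        if "iti_range_s" in params:
            params["iti_range_s"] = tuple(params["iti_range_s"])
        return syn.CohortSpec(**params)

    def rejection_config(self) -> ar.RejectionConfig:
        params = dict(self.rejection)
        if "hf_band" in params:
            params["hf_band"] = tuple(params["hf_band"])
        return ar.RejectionConfig(**params)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))


def _bands(config: RunConfig) -> list[sp.BandDefinition]:
    out = []
    for b in config.bands:
        if isinstance(b, str):
            out.append(sp.PRESET_BANDS[b])
        else:
            out.append(sp.BandDefinition(b["name"], b["f_lo"], b["f_hi"]))
    return out


def _collect_signal_erd(config: RunConfig, cohort: syn.Cohort,
                        rej_cfg: ar.RejectionConfig):
    """Materialize every session, run the rejection cascade, extract ERD."""
    bands = _bands(config)
    reports, samples = [], []
    do_eog = cohort.spec.artifact_rates.get("eog_blink", 0) > 0
    for subject in sorted(cohort.lesion_sides):
        for session in range(cohort.n_sessions[subject]):
            rec = cohort.materialize_session(subject, session)
            removed = []
            if do_eog:
                rec, removed = ar.remove_eog(rec, rej_cfg)
            trials = epoch_trials(rec)
            rep = ar.run_detection(trials, rej_cfg, removed)
            reports.append(rep)
            if trials.n_trials - rep.trials_removed < 1:
                continue
            hemis = sp.map_hemispheres(rec.lesion_side)
            for band in bands:
                for hemi, chans in hemis.items():
                    samples.append(
                        sp.compute_erd(trials, band, chans, hemi,
                                       method=config.erd_method))
    report = ar.apply_exclusions(reports, rej_cfg)
    erd = sp.erd_table(samples)
    # drop excluded sessions/subjects from the analysis table
    excluded_sessions = {(r.subject, r.session_index)
                         for r in report.sessions if r.excluded}
    excluded_subjects = {s for s, e in report.subject_excluded.items() if e}
    keep = [
        not (row.subject in excluded_subjects
             or (row.subject, row.session) in excluded_sessions)
        for row in erd.itertuples(index=False)
    ]
    return erd[keep].reset_index(drop=True), report


def _collect_data_erd(config: RunConfig, rej_cfg: ar.RejectionConfig):
    """File-based input: a manifest.tsv drives reading and extraction."""
    data_dir = Path(config.data_dir)
    manifest = data_dir / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"{manifest} not found")
    table = pd.read_csv(manifest, sep="\t")
    bands = _bands(config)
    reports, samples = [], []
    for row in table.itertuples(index=False):
        rec = read_recording(
            data_dir / row.file, format=row.format,
            events=data_dir / row.events_file,
            subject_id=str(row.subject), session_index=int(row.session),
            lesion_side=str(row.lesion_side),
            channel_config=(data_dir / "channels.yaml"
                            if (data_dir / "channels.yaml").exists() else None),
        )
        removed = []
        if len(rec.pick("EOG")):
            rec, removed = ar.remove_eog(rec, rej_cfg)
        trials = epoch_trials(rec)
        rep = ar.run_detection(trials, rej_cfg, removed)
        reports.append(rep)
        if trials.n_trials - rep.trials_removed < 1:
            continue
        hemis = sp.map_hemispheres(rec.lesion_side)
        for band in bands:
            for hemi, chans in hemis.items():
                samples.append(sp.compute_erd(trials, band, chans, hemi,
                                              method=config.erd_method))
    report = ar.apply_exclusions(reports, rej_cfg)
    erd = sp.erd_table(samples)
    excluded_sessions = {(r.subject, r.session_index)
                         for r in report.sessions if r.excluded}
    excluded_subjects = {s for s, e in report.subject_excluded.items() if e}
    keep = [
        not (row.subject in excluded_subjects
             or (row.subject, row.session) in excluded_sessions)
        for row in erd.itertuples(index=False)
    ]
    return erd[keep].reset_index(drop=True), report


def _load_outcomes(config: RunConfig) -> pd.DataFrame:
    path = Path(config.data_dir) / "outcomes.tsv"
    df = pd.read_csv(path, sep="\t")
    df["subject"] = df.subject.astype(str)
    if "delta" not in df.columns:
        df["delta"] = df.post - (df.baseline1 + df.baseline2) / 2.0
    return df


def _model_band(erd: pd.DataFrame, outcomes: pd.DataFrame, band: str,
                config: RunConfig) -> dict:
    """Full stage-1/stage-2/pLC analysis for one band; returns a JSON-able dict."""
    fits = {}
    for hemi in ("ipsilesional", "contralesional"):
        fits[hemi] = md.fit_stage1(
            erd, hemi, band, reml=config.stage1_reml,
            correlated=config.stage1_correlated)
    stage2 = md.fit_stage2(fits["ipsilesional"].subjects, outcomes)
    strong, weak = md.median_split(fits["ipsilesional"].subjects)
    contra = fits["contralesional"].subjects
    sub_results = {}
    for name, grp in (("strong_initial_erd", strong), ("weak_initial_erd", weak)):
        sel = contra[contra.subject.isin(grp.subject)]
        try:
            sub_results[name] = md.fit_subgroup_contralesional(sel, outcomes).to_dict()
        except ValueError as exc:
            sub_results[name] = {"error": str(exc)}
    plc = md.compute_plc(fits["ipsilesional"].subjects, contra)
    plc_reg = md.fit_plc_regression(plc, outcomes)

    def _stage1_dict(f: md.LmemFit) -> dict:
        return {
            "beta0": f.beta0, "beta1": f.beta1, "sd_b0": f.sd_b0,
            "sd_b1": f.sd_b1, "corr_b": f.corr_b, "sigma": f.sigma,
            "llf": None if np.isnan(f.llf) else f.llf, "reml": f.reml,
            "n_params": f.n_params, "converged": f.converged,
            "downgraded": f.downgraded,
        }

    return {
        "band": band,
        "n_subjects": int(fits["ipsilesional"].subjects.subject.nunique()),
        "stage1": {h: _stage1_dict(f) for h, f in fits.items()},
        "median_initial_erd": float(
            fits["ipsilesional"].subjects.intercept.median()),
        "stage2_interaction": stage2.to_dict(),
        "subgroup_contralesional": sub_results,
        "plc_regression": plc_reg.to_dict(),
        "_tables": {
            "trajectories_ipsi": fits["ipsilesional"].subjects,
            "trajectories_contra": contra,
            "plc": plc,
            "strong": strong, "weak": weak,
        },
    }


def _figures(band_result: dict, outcomes: pd.DataFrame, out_dir: Path,
             band: str) -> list[str]:
    tables = band_result["_tables"]
    paths = []
    merged_out = outcomes.set_index("subject").delta

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, (name, grp) in zip(axes, (("strong", tables["strong"]),
                                      ("weak", tables["weak"]))):
        x = grp.set_index("subject").slope
        y = merged_out.loc[x.index]
        ax.scatter(x, y, color="tab:blue")
        if x.std() > 0:
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, a + b * xs, color="tab:red")
        ax.set_title(f"{name} initial ERD (ipsilesional slope)")
        ax.set_xlabel("ERD slope (%/session)")
    axes[0].set_ylabel("clinical change (points)")
    p = out_dir / f"fig_stage2_subgroups_{band}.png"
    fig.savefig(p, dpi=110, metadata={"Software": "erdpipe"})
    plt.close(fig)
    paths.append(p.name)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    contra = tables["trajectories_contra"].set_index("subject").slope
    for ax, (name, grp) in zip(axes, (("strong", tables["strong"]),
                                      ("weak", tables["weak"]))):
        x = contra.loc[[s for s in grp.subject if s in contra.index]]
        y = merged_out.loc[x.index]
        ax.scatter(x, y, color="tab:green")
        if x.std() > 0:
            b, a = np.polyfit(x, y, 1)
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, a + b * xs, color="tab:red")
        ax.set_title(f"{name}: contralesional slope")
        ax.set_xlabel("ERD slope (%/session)")
    axes[0].set_ylabel("clinical change (points)")
    p = out_dir / f"fig_contralesional_{band}.png"
    fig.savefig(p, dpi=110, metadata={"Software": "erdpipe"})
    plt.close(fig)
    paths.append(p.name)

    fig, ax = plt.subplots(figsize=(5, 4))
    plc = tables["plc"].set_index("subject").plc
    y = merged_out.loc[plc.index]
    ax.scatter(plc, y, color="tab:purple")
    if plc.std() > 0:
        b, a = np.polyfit(plc, y, 1)
        xs = np.linspace(plc.min(), plc.max(), 50)
        ax.plot(xs, a + b * xs, color="tab:red")
    ax.set_xlabel("pLC (%/session)")
    ax.set_ylabel("clinical change (points)")
    ax.axvline(0, color="gray", lw=0.5)
    p = out_dir / f"fig_plc_{band}.png"
    fig.savefig(p, dpi=110, metadata={"Software": "erdpipe"})
    plt.close(fig)
    paths.append(p.name)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the MANIFEST dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest = {"seed": config.seed, "mode": config.mode, "status": "running",
                "stage": None, "files": []}

    def _write_manifest():
        (out_dir / "MANIFEST.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))

    def _fail(stage: str, exc: Exception):
        manifest["status"] = "failed"
        manifest["stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest()
        raise PipelineError(stage, str(exc)) from exc

    config.to_yaml(out_dir / "config.yaml")
    manifest["files"].append("config.yaml")
    rej_cfg = config.rejection_config()

    # --- acquisition / rejection / ERD -----------------------------------
    try:
        if config.mode == "synthetic-erd":
            cohort = syn.simulate_cohort(config.cohort_spec())
            erd, report = cohort.erd.copy(), None
            outcomes = cohort.outcomes
        elif config.mode == "synthetic-signal":
            cohort = syn.simulate_cohort(config.cohort_spec())
            erd, report = _collect_signal_erd(config, cohort, rej_cfg)
            outcomes = cohort.outcomes
        elif config.mode == "data":
            erd, report = _collect_data_erd(config, rej_cfg)
            outcomes = _load_outcomes(config)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
    except PipelineError:
        raise
    except Exception as exc:
        _fail("acquisition/rejection", exc)

    erd.to_csv(out_dir / "erd_samples.tsv", sep="\t", index=False)
    manifest["files"].append("erd_samples.tsv")
    if report is not None:
        report.summary().to_csv(out_dir / "rejection_report.tsv", sep="\t",
                                index=False)
        summary = {
            "trials_in": int(sum(r.trials_in for r in report.sessions)),
            "trials_removed": int(sum(r.trials_removed for r in report.sessions)),
            "sessions_excluded": int(sum(r.excluded for r in report.sessions)),
            "subjects_excluded": sorted(
                s for s, e in report.subject_excluded.items() if e),
        }
        (out_dir / "rejection_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        manifest["files"] += ["rejection_report.tsv", "rejection_summary.json"]
    if config.mode.startswith("synthetic"):
        cohort.spec.to_yaml(out_dir / "cohort_spec.yaml")
        cohort.ground_truth.trajectories.to_csv(
            out_dir / "ground_truth_trajectories.tsv", sep="\t", index=False)
        outcomes.to_csv(out_dir / "outcomes.tsv", sep="\t", index=False)
        manifest["files"] += ["cohort_spec.yaml", "ground_truth_trajectories.tsv",
                              "outcomes.tsv"]

    # --- modeling ---------------------------------------------------------
    if not config.bands:
        models = {}
        manifest["note"] = "no bands analyzed"
    else:
        n_subjects = erd.subject.nunique() if len(erd) else 0
        if n_subjects < MIN_SUBJECTS_FOR_MODELING:
            _fail("stage1", ValueError(
                f"insufficient subjects after exclusion "
                f"({n_subjects} < {MIN_SUBJECTS_FOR_MODELING})"))
        models = {}
        for band in [b.name if not isinstance(b, str) else b
                     for b in config.bands]:
            try:
                models[band] = _model_band(erd, outcomes, band, config)
            except Exception as exc:
                _fail("stage2", exc)

    models_json = {}
    for band, res in models.items():
        tables = res.pop("_tables")
        models_json[band] = res
        tables["trajectories_ipsi"].to_csv(
            out_dir / f"trajectories_ipsi_{band}.tsv", sep="\t", index=False)
        tables["trajectories_contra"].to_csv(
            out_dir / f"trajectories_contra_{band}.tsv", sep="\t", index=False)
        tables["plc"].to_csv(out_dir / f"plc_{band}.tsv", sep="\t", index=False)
        manifest["files"] += [f"trajectories_ipsi_{band}.tsv",
                              f"trajectories_contra_{band}.tsv",
                              f"plc_{band}.tsv"]
        res["_tables"] = tables  # keep for figures
    (out_dir / "models.json").write_text(
        json.dumps({b: {k: v for k, v in r.items() if k != "_tables"}
                    for b, r in models.items()}, indent=2, sort_keys=True))
    manifest["files"].append("models.json")

    try:
        for band, res in models.items():
            manifest["files"] += _figures(res, outcomes, out_dir, band)
    except Exception as exc:
        _fail("figures", exc)

    manifest["status"] = "complete"
    _write_manifest()
    manifest["files"].append("MANIFEST.json")
    make_report(out_dir)
    return manifest


def make_report(bundle_dir) -> str:
    """Render a Markdown summary of a completed bundle; returns the path."""
    bundle_dir = Path(bundle_dir)
    manifest_path = bundle_dir / "MANIFEST.json"
    missing = [p for p in ("MANIFEST.json", "erd_samples.tsv", "models.json")
               if not (bundle_dir / p).exists()]
    if missing:
        raise FileNotFoundError(
            "bundle incomplete; missing members: " + ", ".join(missing))
    manifest = json.loads(manifest_path.read_text())
    erd = pd.read_csv(bundle_dir / "erd_samples.tsv", sep="\t")
    models = json.loads((bundle_dir / "models.json").read_text())

    lines = ["# Pipeline report", "",
             f"- mode: {manifest['mode']}",
             f"- seed: {manifest['seed']}",
             f"- status: {manifest['status']}", ""]
    if len(erd):
        lines += [f"- subjects analyzed: {erd.subject.nunique()}",
                  f"- ERD samples: {len(erd)}", ""]
    rej_path = bundle_dir / "rejection_summary.json"
    if rej_path.exists():
        rej = json.loads(rej_path.read_text())
        lines += ["## Artifact rejection", "",
                  f"- trials in: {rej['trials_in']}",
                  f"- trials removed: {rej['trials_removed']}",
                  f"- sessions excluded: {rej['sessions_excluded']}",
                  f"- subjects excluded: "
                  f"{', '.join(rej['subjects_excluded']) or 'none'}", ""]
    if not models:
        lines += ["## Models", "", "no bands analyzed", ""]
    for band, res in models.items():
        s2 = res["stage2_interaction"]
        plc = res["plc_regression"]
        lines += [
            f"## Band: {band}", "",
            f"- subjects: {res['n_subjects']}",
            f"- median initial ERD: {res['median_initial_erd']:.2f} %",
            f"- stage-1 fixed effects (ipsilesional): "
            f"{res['stage1']['ipsilesional']['beta0']:.2f} % initial, "
            f"{res['stage1']['ipsilesional']['beta1']:.3f} %/session",
            f"- stage-2 interaction model: F({s2['df'][0]}, {s2['df'][1]}) = "
            f"{s2['F']:.2f}, p = {s2['p']:.4f}, adj. r2 = {s2['adj_r2']:.2f}",
            f"- pLC regression: F({plc['df'][0]}, {plc['df'][1]}) = "
            f"{plc['F']:.2f}, p = {plc['p']:.4f}, adj. r2 = {plc['adj_r2']:.2f}",
            "",
        ]
        for name, sub in res["subgroup_contralesional"].items():
            if "error" in sub:
                lines.append(f"- subgroup {name}: {sub['error']}")
            else:
                lines.append(
                    f"- subgroup {name}: F({sub['df'][0]}, {sub['df'][1]}) = "
                    f"{sub['F']:.2f}, p = {sub['p']:.4f}")
        lines.append("")
        for fig in (f"fig_stage2_subgroups_{band}.png",
                    f"fig_contralesional_{band}.png", f"fig_plc_{band}.png"):
            if (bundle_dir / fig).exists():
                lines.append(f"![{fig}]({fig})")
        lines.append("")

    path = bundle_dir / "report.md"
    path.write_text("\n".join(lines))
    return str(path)
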