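"""Study-level orchestration: simulate / load, fit, derive, compare, report.

``run_pipeline`` takes a synthetic study (in memory or a directory written
by ``write_study``), fits every specimen, derives the working-point metric
set, summarizes vasoactive, echo, histology and survival data, runs group
comparisons and assembles the headline numbers.  Per-specimen failures are
isolated and listed; the run continues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from .cardiac import summarize_echo
from .exceptions import VesselMechError
from .fitting import fit_specimen
from .histology import replicate_average, segment_alizarin, segment_movat
from .io import (EchoRecord, read_specimen_dataset, write_specimen_dataset)
from .metrics import compute_metrics
from .stats import compare_groups, fold_change, percent_reduction, \
    survival_fraction
from .synthetic import StudyData, generate_cohorts, DEFAULT_STUDY
from .vasoactive import constriction_metrics, dilation_metrics

__all__ = ["ReportBundle", "run_pipeline", "write_study", "read_study"]


@dataclass
class ReportBundle:
    """Everything the pipeline produces for one study run."""

    fits: dict                      # specimen_id -> FitResult
    metric_table: pd.DataFrame      # long format: one metric value per row
    truth_metric_table: pd.DataFrame  # same metrics at the generator's true
                                      # parameters (synthetic studies only)
    vasoactive_table: pd.DataFrame
    echo_table: pd.DataFrame
    histology_table: pd.DataFrame
    survival_table: pd.DataFrame
    comparisons: list
    headline: dict
    failures: list = field(default_factory=list)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metric_table.to_csv(out / "metrics.csv", index=False)
        if len(self.truth_metric_table):
            self.truth_metric_table.to_csv(out / "metrics_generator_truth.csv",
                                           index=False)
        self.vasoactive_table.to_csv(out / "vasoactive.csv", index=False)
        self.echo_table.to_csv(out / "echo.csv", index=False)
        self.histology_table.to_csv(out / "histology.csv", index=False)
        self.survival_table.to_csv(out / "survival.csv", index=False)
        with open(out / "headline.json", "w") as fh:
            json.dump(self.headline, fh, indent=2, sort_keys=True)
        with open(out / "report.md", "w") as fh:
            fh.write(self.to_markdown())
        return out

    def to_markdown(self) -> str:
        lines = ["# Study report", "", "## Headline numbers", ""]
        for k, v in sorted(self.headline.items()):
            lines.append(f"- {k}: {v}")
        lines += ["", "## Group comparisons", ""]
        for c in self.comparisons:
            lines.append(f"### {c.metric} ({c.design} ANOVA: "
                         f"F={c.anova_F:.3g}, p={c.anova_p:.3g})")
            for g, (m, sem, n) in c.group_stats.items():
                lines.append(f"- {g}: {m:.4g} +/- {sem:.3g} (n={n})")
            for pair, p in c.pairwise.items():
                lines.append(f"- {pair[0]} vs {pair[1]}: "
                             f"p_adj={p:.3g} {c.stars[pair]}")
            lines.append("")
        if self.failures:
            lines += ["## Failures", ""]
            lines += [f"- {f}" for f in self.failures]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# study directory layout


def write_study(study: StudyData, path) -> Path:
    """Write a full synthetic study tree (specimens, echo, histology masks
    and images, survival) with a study.yaml index."""
    from imageio.v3 import imwrite

    path = Path(path)
    (path / "specimens").mkdir(parents=True, exist_ok=True)
    index = {"seed": study.seed, "specimens": [], "echo": {},
             "histology": {}, "survival": "survival.csv"}
    for ds, _truth in study.specimens:
        rec = ds.record
        write_specimen_dataset(ds, path / "specimens" / rec.specimen_id)
        index["specimens"].append({"id": rec.specimen_id, "group": rec.group,
                                   "age": rec.age, "vessel": rec.vessel})
    (path / "echo").mkdir(exist_ok=True)
    for group, animals in study.echo.items():
        rows = []
        for i, reps in enumerate(animals):
            for j, r in enumerate(reps):
                rows.append({"animal": i, "replicate": j, "LVIDd_mm": r.LVIDd,
                             "LVIDs_mm": r.LVIDs, "heart_rate_bpm": r.heart_rate,
                             "E_mm_s": r.E, "A_mm_s": r.A,
                             "e_prime_mm_s": r.e_prime, "DT_ms": r.DT,
                             "body_mass_g": r.body_mass})
        fname = f"echo/{group.replace('/', '_')}.csv"
        pd.DataFrame(rows).to_csv(path / fname, index=False)
        index["echo"][group] = fname
    (path / "histology").mkdir(exist_ok=True)
    for group, sections in study.histology.items():
        gdir = path / "histology" / group.replace("/", "_")
        gdir.mkdir(exist_ok=True)
        entries = []
        for sec in sections:
            stem = f"s{sec['specimen']}_r{sec['replicate']}"
            img, truth = sec["movat"]
            imwrite(gdir / f"{stem}_movat.png", img)
            imwrite(gdir / f"{stem}_media.png",
                    (truth["media_mask"] * np.uint8(255)))
            aimg, _ = sec["alizarin"]
            imwrite(gdir / f"{stem}_alizarin.png", aimg)
            entries.append({"specimen": sec["specimen"],
                            "replicate": sec["replicate"], "stem": stem})
        index["histology"][group] = entries
    surv_rows = [{"group": g, "n_total": v["n_total"],
                  "death_days": " ".join(str(d) for d in v["death_days"])}
                 for g, v in study.survival.items()]
    pd.DataFrame(surv_rows).to_csv(path / "survival.csv", index=False)
    with open(path / "study.yaml", "w") as fh:
        yaml.safe_dump(index, fh, sort_keys=False)
    return path


def read_study(path) -> StudyData:
    """Read a study tree written by :func:`write_study`."""
    from imageio.v3 import imread

    path = Path(path)
    if not (path / "study.yaml").exists():
        raise VesselMechError(f"not a study directory (no study.yaml): {path}")
    with open(path / "study.yaml") as fh:
        index = yaml.safe_load(fh)
    specimens = []
    for entry in index["specimens"]:
        ds = read_specimen_dataset(path / "specimens" / entry["id"])
        specimens.append((ds, None))
    echo = {}
    for group, fname in index.get("echo", {}).items():
        df = pd.read_csv(path / fname)
        animals = []
        for _, sub in df.groupby("animal"):
            animals.append([EchoRecord(
                LVIDd=r.LVIDd_mm, LVIDs=r.LVIDs_mm,
                heart_rate=r.heart_rate_bpm, E=r.E_mm_s, A=r.A_mm_s,
                e_prime=r.e_prime_mm_s, DT=r.DT_ms, body_mass=r.body_mass_g)
                for r in sub.itertuples()])
        echo[group] = animals
    histology = {}
    for group, entries in index.get("histology", {}).items():
        gdir = path / "histology" / group.replace("/", "_")
        sections = []
        for e in entries:
            stem = e["stem"]
            media = imread(gdir / f"{stem}_media.png") > 127
            sections.append({
                "specimen": e["specimen"], "replicate": e["replicate"],
                "movat": (imread(gdir / f"{stem}_movat.png"),
                          {"media_mask": media}),
                "alizarin": (imread(gdir / f"{stem}_alizarin.png"),
                             {"media_mask": media}),
            })
        histology[group] = sections
    surv = {}
    for r in pd.read_csv(path / "survival.csv").itertuples():
        days = [int(x) for x in str(r.death_days).split()] \
            if isinstance(r.death_days, str) and r.death_days.strip() else []
        surv[r.group] = {"n_total": int(r.n_total), "death_days": days}
    return StudyData(specimens=specimens, echo=echo, histology=histology,
                     survival=surv, config=None, seed=index.get("seed", 0))


# ---------------------------------------------------------------------------
# pipeline


def _metric_rows(rec, ms):
    base = {"specimen_id": rec.specimen_id, "group": rec.group,
            "age": rec.age, "vessel": rec.vessel}
    return [{**base, "metric": k, "value": v}
            for k, v in ms.to_dict().items()]


def run_pipeline(study: StudyData | None = None, study_dir=None,
                 config=None, seed: int = 0, fit_kwargs=None) -> ReportBundle:
    """Run the full analysis on a study (generated if none is given)."""
    if study is None:
        if study_dir is not None:
            study = read_study(study_dir)
        else:
            study = generate_cohorts(config or DEFAULT_STUDY, seed=seed)
    fit_kwargs = fit_kwargs or {}

    fits, rows, truth_rows, vaso_rows, failures = {}, [], [], [], []
    for ds, truth in study.specimens:
        rec = ds.record
        if truth is not None:
            # metrics at the generator's true parameters: the calibrated
            # cohort surface, free of estimation error
            try:
                ms_true = compute_metrics(
                    truth.params, rec.R_o, rec.H, rec.lam_iv,
                    working_pressure_mmhg=cal.WORKING_PRESSURE[rec.vessel])
                truth_rows.extend(_metric_rows(rec, ms_true))
            except Exception as exc:
                failures.append(f"{rec.specimen_id} (truth metrics): {exc}")
        try:
            fr = fit_specimen(ds, seed=seed, **fit_kwargs)
            fits[rec.specimen_id] = fr
            ms = compute_metrics(
                fr.params, rec.R_o, rec.H, rec.lam_iv,
                working_pressure_mmhg=cal.WORKING_PRESSURE[rec.vessel])
            rows.extend(_metric_rows(rec, ms))
        except Exception as exc:
            failures.append(f"{rec.specimen_id}: {exc}")
            continue
        try:
            traces = {t.stimulus: t for t in ds.active}
            if "KCl100mM" in traces:
                summ = constriction_metrics(traces["KCl100mM"])
                vrow = {"specimen_id": rec.specimen_id, "group": rec.group,
                        "age": rec.age, "vessel": rec.vessel,
                        "kcl_percent_constriction": summ.percent_constriction,
                        "kcl_t_half_s": summ.time_to_half_response}
                if {"PE1uM", "ACh10uM"} <= traces.keys():
                    pe = constriction_metrics(traces["PE1uM"])
                    ach = traces["ACh10uM"]
                    pct, flags = dilation_metrics(
                        pe.baseline_d, pe.plateau_d,
                        float(np.median(ach.outer_diameter[
                            ach.time >= ach.time[-1] - 30])))
                    vrow["ach_percent_dilation"] = pct
                    vrow["dilation_flags"] = ";".join(flags)
                vaso_rows.append(vrow)
        except Exception as exc:
            failures.append(f"{rec.specimen_id} (active): {exc}")

    metric_table = pd.DataFrame(rows)
    truth_metric_table = pd.DataFrame(truth_rows)
    vasoactive_table = pd.DataFrame(vaso_rows)

    echo_rows = []
    for group, animals in study.echo.items():
        for i, reps in enumerate(animals):
            cs = summarize_echo(reps)
            echo_rows.append({"group": group, "animal": i, **cs.to_dict()})
    echo_table = pd.DataFrame(echo_rows)

    hist_rows = []
    for group, sections in study.histology.items():
        per_spec = {}
        for sec in sections:
            img, truth = sec["movat"]
            seg = segment_movat(img, layer_mask=truth["media_mask"])
            aimg, atruth = sec["alizarin"]
            aseg = segment_alizarin(aimg, layer_mask=atruth["media_mask"])
            fr = dict(seg.layer_fractions)
            fr["calcified"] = aseg.layer_fractions["calcified"]
            per_spec.setdefault(sec["specimen"], []).append(fr)
        for spec_idx, reps in per_spec.items():
            means, spread, warns = replicate_average(reps)
            hist_rows.append({"group": group, "specimen": spec_idx,
                              **means, "warnings": ";".join(warns)})
    histology_table = pd.DataFrame(hist_rows)

    surv_rows = []
    for group, v in study.survival.items():
        deaths = np.asarray(v["death_days"], dtype=float)
        n = v["n_total"]
        alive_168 = int(n - (deaths <= 168).sum())
        alive_169 = int(n - (deaths <= 169).sum())
        surv_rows.append({
            "group": group, "n_total": n,
            "alive_P168": alive_168, "alive_P169": alive_169,
            "pct_P168": survival_fraction(alive_168, n),
            "pct_P169": survival_fraction(alive_169, n)})
    survival_table = pd.DataFrame(surv_rows)

    comparisons = []
    if not metric_table.empty:
        end_dta = metric_table[(metric_table.vessel == "DTA")
                               & (metric_table.age == 168)]
        for metric in ("pwv_mk_m_s", "C_tttt_mpa", "W_kpa",
                       "sigma_theta_kpa"):
            sub = end_dta[end_dta.metric == metric]
            counts = sub.groupby("group").size()
            if len(counts) >= 2 and (counts >= 2).all():
                comparisons.append(compare_groups(sub, metric="value"))
                comparisons[-1].metric = metric

    headline = _headline(metric_table, echo_table, histology_table,
                         survival_table)
    if len(truth_metric_table):
        for group, age, tag in (("WT", 168, "wt"), ("GG", 42, "gg_p42"),
                                ("GG", 168, "gg_p168"),
                                ("GG+L(P21)", 168, "gg_l21")):
            for metric, name in (("pwv_mk_m_s", "pwv_mk"),
                                 ("C_tttt_mpa", "stiffness_mpa"),
                                 ("W_kpa", "energy_kpa")):
                v = _group_mean(truth_metric_table, metric, group, age)
                if np.isfinite(v):
                    headline[f"{tag}_{name}_cohort"] = round(v, 3)
    return ReportBundle(fits=fits, metric_table=metric_table,
                        truth_metric_table=truth_metric_table,
                        vasoactive_table=vasoactive_table,
                        echo_table=echo_table,
                        histology_table=histology_table,
                        survival_table=survival_table,
                        comparisons=comparisons, headline=headline,
                        failures=failures)


def _group_mean(table, metric, group, age=None, vessel="DTA"):
    sub = table[(table.group == group) & (table.metric == metric)
                & (table.vessel == vessel)]
    if age is not None:
        sub = sub[sub.age == age]
    return float(sub.value.mean()) if len(sub) else float("nan")


def _headline(metrics, echo, hist, surv) -> dict:
    out = {}
    if len(metrics):
        for group, age, tag in (("WT", 168, "wt"), ("GG", 42, "gg_p42"),
                                ("GG", 168, "gg_p168"),
                                ("GG+L(P21)", 168, "gg_l21")):
            for metric, name in (("pwv_mk_m_s", "pwv_mk"),
                                 ("pwv_bh_m_s", "pwv_bh"),
                                 ("C_tttt_mpa", "stiffness_mpa"),
                                 ("W_kpa", "energy_kpa"),
                                 ("sigma_theta_kpa", "wall_stress_kpa")):
                v = _group_mean(metrics, metric, group, age)
                if np.isfinite(v):
                    out[f"{tag}_{name}"] = round(v, 3)
        if np.isfinite(out.get("gg_p42_pwv_mk", np.nan)) and \
                np.isfinite(out.get("gg_p168_pwv_mk", np.nan)):
            out["gg_pwv_fold_p42_to_p168"] = round(
                out["gg_p168_pwv_mk"] / out["gg_p42_pwv_mk"], 2)
    if len(echo):
        for group, sub in echo.groupby("group"):
            tag = {"WT": "wt", "GG": "gg", "GG+L(P21)": "gg_l21",
                   "GG+L+R": "gg_lr"}.get(group, group)
            out[f"{tag}_E_over_eprime"] = round(float(
                sub.E_over_eprime.mean()), 2)
            out[f"{tag}_CO_ml_min"] = round(float(sub.CO_ml_min.mean()), 2)
            out[f"{tag}_EF_pct"] = round(float(sub.EF_pct.mean()), 2)
    if len(hist):
        gmeans = hist.groupby("group").mean(numeric_only=True)
        if {"WT", "GG"} <= set(gmeans.index):
            out["proteoglycan_fold_gg_vs_wt"] = fold_change(
                gmeans.loc["GG", "proteoglycan"],
                gmeans.loc["WT", "proteoglycan"])
            out["cytoplasm_reduction_pct_gg"] = percent_reduction(
                gmeans.loc["WT", "cytoplasm"], gmeans.loc["GG", "cytoplasm"])
            out["collagen_reduction_pct_gg"] = percent_reduction(
                gmeans.loc["WT", "collagen"], gmeans.loc["GG", "collagen"])
        if {"WT", "GG+L(P21)"} <= set(gmeans.index):
            out["proteoglycan_fold_gg_l21_vs_wt"] = fold_change(
                gmeans.loc["GG+L(P21)", "proteoglycan"],
                gmeans.loc["WT", "proteoglycan"])
    for r in surv.itertuples():
        tag = {"WT": "wt", "GG": "gg", "GG+L(P21)": "gg_l21",
               "GG+L(P100)": "gg_l100", "GG+L+R": "gg_lr"}.get(r.group,
                                                               r.group)
        out[f"{tag}_survival_pct_P168"] = r.pct_P168
        out[f"{tag}_survival_pct_P169"] = r.pct_P169
    return out
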