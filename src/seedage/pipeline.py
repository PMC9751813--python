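"""End-to-end orchestration: simulate → kinetics → fits → screens → report.

The pipeline mirrors the analysis of a high-pressure-oxygen seed-aging
experiment: simulate (or load) a germination panel, extract germination
traits, apply the ΔEPPO pressure correction, fit the viability equation per
lot, summarise longevity per treatment, correlate P50 across treatments,
run the metabolomics screens on a focal accession, and write a delimited
report bundle.  Identical config + seed gives byte-identical tables.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import seedage
from seedage import annotation, kinetics, omics, simulate, viability

__all__ = ["PipelineError", "default_config", "run_pipeline"]

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def default_config() -> dict:
    """Baseline run configuration (simulation-backed)."""
    return {
        "seed": 0,
        "outdir": "seedage_run",
        "panel": {},  # PanelSpec overrides (replicates, storage_days, ...)
        "model": "reduced",  # "reduced" | "combined" | "auto" | {accession: ...}
        "controls": {"ambient": "ambient", "pressure": "EPPN", "days": 21},
        "correction_source": "EPPO",
        "focal_accession": "IRGC 117268",  # the lot profiled by metabolomics
        "omics": {},  # OmicsSpec overrides
        "thresholds": {
            "min_samples": 3,
            "min_abundance": 15000,
            "r_negative": -0.5,
            "r_positive": 0.5,
        },
        "p50_matrix_treatments": ["EPPO", "dEPPO", "CD"],
    }


def _merged_config(config: dict | None) -> dict:
    cfg = default_config()
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return _merged_config(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg):
    spec = simulate.default_panel_spec(seed=int(cfg["seed"]), **cfg["panel"])
    obs, truth = simulate.simulate_survival_panel(spec)
    courses = simulate.simulate_germination_timecourses(obs, spec)
    return spec, obs, truth, courses


def _stage_kinetics(courses: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for keys, grp in courses.groupby(
        ["accession", "treatment", "replicate", "storage_days"], sort=True
    ):
        grp = grp.sort_values("time_h")
        fit = kinetics.fit_germination_curve(
            grp["time_h"].to_numpy(),
            grp["cum_germinated"].to_numpy(),
            int(grp["total"].iloc[0]),
        )
        rows.append(
            dict(
                zip(["accession", "treatment", "replicate", "storage_days"], keys),
                Gmax=fit.gmax,
                Gmax_raw=fit.gmax_raw,
                t50=fit.t50,
                hill_h=fit.h,
                rss=fit.rss,
                left_censored=fit.left_censored,
            )
        )
    return pd.DataFrame(rows)


def _stage_delta_eppo(cfg, traits: pd.DataFrame) -> pd.DataFrame:
    controls = cfg["controls"]
    ctrl_day = float(controls.get("days", 21))
    source = cfg["correction_source"]

    def control_frame(label):
        sub = traits[
            (traits["treatment"] == label) & (traits["storage_days"] == ctrl_day)
        ]
        if sub.empty:
            raise PipelineError(
                "delta-eppo",
                f"no {ctrl_day:g}-day control observations for treatment "
                f"{label!r}; cannot apply the pressure correction",
            )
        return sub.rename(columns={"Gmax_raw": "value"})[
            ["accession", "replicate", "value"]
        ]

    eppo = traits[traits["treatment"] == source].rename(
        columns={"Gmax_raw": "value"}
    )[["accession", "replicate", "storage_days", "value"]]
    corrected = kinetics.delta_eppo_correct(
        eppo,
        control_frame(controls["ambient"]),
        control_frame(controls["pressure"]),
        percent=True,
    )
    return corrected.rename(columns={"value": "Gmax_raw"})


def _choose_model(cfg, accession: str) -> str:
    model = cfg["model"]
    if isinstance(model, dict):
        return model.get(accession, "reduced")
    return model


def _fit_lot(df: pd.DataFrame, model: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if model == "combined":
            return viability.fit_combined(df)
        if model == "auto":
            fit = viability.fit_combined(df)
            return fit if fit.dormancy_supported else viability.fit_viability(df)
        return viability.fit_viability(df)


def _stage_viability(cfg, obs: pd.DataFrame, corrected: pd.DataFrame):
    counts = corrected.copy()
    total = obs["total"].iloc[0]
    counts["total"] = int(total)
    counts["germinated"] = (
        (counts["Gmax_raw"] / 100.0 * total).round().astype(int)
    )
    frames = {
        trt: obs[obs["treatment"] == trt] for trt in obs["treatment"].unique()
    }
    frames["dEPPO"] = counts

    fits: dict[str, dict[str, viability.ViabilityFit]] = {}
    for trt, frame in frames.items():
        fits[trt] = {}
        for acc, grp in frame.groupby("accession", sort=True):
            try:
                fits[trt][acc] = _fit_lot(grp, _choose_model(cfg, acc))
            except viability.NonIdentifiableError:
                continue
    return fits


def _longevity_table(fits: dict[str, viability.ViabilityFit]) -> pd.DataFrame:
    table = viability.table_rows(fits)
    summary = viability.summarize_panel(
        pd.DataFrame(
            {
                "Ki": [f.Ki for f in fits.values()],
                "sigma_inv": [f.sigma_inv for f in fits.values()],
                "p50": [f.p50 for f in fits.values()],
            }
        )
    )
    summary = summary.round({"Ki": 2, "sigma_inv": 3, "p50": 1}).rename(
        columns={"p50": "P50"}
    )
    summary.insert(0, "accession", summary.index)
    return pd.concat([table, summary], ignore_index=True)


def _stage_p50_matrix(cfg, fits):
    treatments = [t for t in cfg["p50_matrix_treatments"] if t in fits]
    data = {}
    for trt in treatments:
        data[trt] = {
            acc: f.p50 for acc, f in fits[trt].items() if np.isfinite(f.p50)
        }
    wide = pd.DataFrame(data).dropna()
    if wide.shape[0] < 3 or wide.shape[1] < 2:
        raise PipelineError(
            "p50-matrix", "fewer than 3 lots with P50 defined across treatments"
        )
    return viability.p50_correlation_matrix(wide)


def _stage_omics(cfg, obs: pd.DataFrame):
    focal = cfg["focal_accession"]
    sub = obs[obs["accession"] == focal]
    if sub.empty:
        raise PipelineError("omics", f"focal accession {focal!r} not in panel")
    germ = (
        sub.assign(pct=100.0 * sub["germinated"] / sub["total"])
        .groupby(["treatment", "storage_days"], sort=True)["pct"]
        .mean()
        .reset_index()
    )
    germ["sample"] = [
        f"{t}_{int(d):02d}d" for t, d in zip(germ["treatment"], germ["storage_days"])
    ]
    sample_meta = germ.set_index("sample").rename(
        columns={"pct": "germination_pct"}
    )

    ospec = simulate.OmicsSpec(seed=int(cfg["seed"]) + 17, **cfg["omics"])
    table, truth = simulate.simulate_feature_table(ospec, sample_meta)

    thr = cfg["thresholds"]
    table = omics.filter_features(
        table, min_samples=thr["min_samples"], min_abundance=thr["min_abundance"]
    )
    table = omics.normalize_internal_standard(table)

    r_via = omics.correlate(table, "germination_pct")
    r_time = omics.correlate(table, "storage_days")
    screen = r_via.rename(columns={"r": "r_viability"}).join(
        r_time["r"].rename("r_storage_time")
    )

    neg = omics.select_top(screen, ("r_viability", "<", thr["r_negative"]))
    pos = omics.select_top(screen, ("r_viability", ">", thr["r_positive"]))
    neg.discard(table.is_channel)
    pos.discard(table.is_channel)

    pct = omics.percent_of_initial(table, "storage_days", 0)

    lib = annotation.build_tag_library()
    ann_rows = []
    for comp in sorted(neg | pos):
        meta = table.compound_meta.loc[comp]
        mz = meta.get("mz", np.nan)
        hits = (
            annotation.match_feature(float(mz), lib) if np.isfinite(mz) else []
        )
        best = hits[0] if hits else None
        ann_rows.append(
            {
                "compound": comp,
                "mz": mz,
                "rt_min": meta.get("rt_min", np.nan),
                "annotation": best.label if best else "unknown",
                "adduct": best.adduct if best else "",
                "theoretical_mz": best.theoretical_mz if best else np.nan,
                "ppm": best.ppm if best else np.nan,
                "r_viability": screen.loc[comp, "r_viability"],
                "r_storage_time": screen.loc[comp, "r_storage_time"],
                "direction": "negative" if comp in neg else "positive",
            }
        )
        for day in pct.index:
            ann_rows[-1][f"pct_of_initial_{int(day)}d"] = pct.loc[day, comp]
    screen_table = pd.DataFrame(ann_rows)

    # per-treatment storage-time screens feed the cross-condition comparison
    sets = {}
    for trt in sorted(table.sample_meta["treatment"].unique()):
        mask = table.sample_meta["treatment"] == trt
        sub_table = omics.FeatureTable(
            intensities=table.intensities[mask],
            sample_meta=table.sample_meta[mask],
            compound_meta=table.compound_meta,
            is_channel=table.is_channel,
        )
        rt = omics.correlate(sub_table, "storage_days")
        sets[trt] = omics.select_top(rt, ("r", ">", thr["r_positive"]))
        sets[trt].discard(table.is_channel)
    venn = omics.venn_sets(sets)
    return screen_table, venn, truth


# ---------------------------------------------------------------------------


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict with the artifact paths and the in-memory tables.  On a
    stage failure every file already written for this run is removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    cfg = _merged_config(config)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame, index=False):
        path = out / name
        df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
        written.append(path)
        return path

    try:
        spec, obs, truth, courses = _stage_simulate(cfg)
        emit("survival_observations.tsv", obs)
        emit("simulation_truth.tsv", truth)

        try:
            traits = _stage_kinetics(courses)
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("kinetics", str(exc)) from exc
        emit("germination_traits.tsv", traits)

        corrected = _stage_delta_eppo(cfg, traits)
        emit("delta_eppo_gmax.tsv", corrected)

        try:
            fits = _stage_viability(cfg, obs, corrected)
        except Exception as exc:
            raise PipelineError("viability", str(exc)) from exc
        longevity = {}
        for trt in ("EPPO", "dEPPO"):
            if trt in fits and fits[trt]:
                longevity[trt] = _longevity_table(fits[trt])
                emit(f"longevity_{trt}.tsv", longevity[trt])

        r, sig = _stage_p50_matrix(cfg, fits)
        emit("p50_correlation.tsv", r.round(3), index=True)
        emit("p50_correlation_significant.tsv", sig, index=True)

        try:
            screen_table, venn, omics_truth = _stage_omics(cfg, obs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("omics", str(exc)) from exc
        emit("correlation_screen.tsv", screen_table)
        emit("venn_partition.tsv", venn.assign(members=venn["members"].map(";".join)))
        emit("omics_truth.tsv", omics_truth, index=True)

        log = out / "run_log.txt"
        log.write_text(
            "\n".join(
                [
                    f"seedage version: {seedage.__version__}",
                    f"seed: {cfg['seed']}",
                    f"model: {cfg['model']}",
                    f"controls: {cfg['controls']}",
                    "t50 correction: additive, same replicate-wise rule as "
                    "percentage traits",
                    f"thresholds: {cfg['thresholds']}",
                    f"panel: {len(spec.accessions)} accessions x "
                    f"{len(spec.treatments)} treatments x "
                    f"{len(spec.storage_days)} days x {spec.replicates} reps",
                ]
            )
            + "\n"
        )
        written.append(log)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    return {
        "outdir": out,
        "paths": written,
        "fits": fits,
        "longevity": longevity,
        "p50_correlation": r,
    }
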