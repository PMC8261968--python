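"""End-to-end pipeline: files in, tables/figures out, driven by one config.

Stages: read epoch series (or raw recordings), apply night zeroing, non-wear
detection and validity rules; reduce to the 22-bin intensity spectrum and
cut-point summaries; z-score the risk-factor panel and build the MetS score;
run the four-model PLS suite per response with permutation tests; and write
group-profile and selectivity-ratio figures, each with a co-written data
table. Every run writes a manifest listing the artifacts, the seed and a
hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import processing as proc
from . import spectrum as spec_mod
from . import risk as risk_mod
from .suite import ModelSuite
from .synthetic import (ActivityProfile, CohortConfig, generate_epoch_cohort,
                        generate_outcomes, noise_sd_for_r2)
from .plotting import plot_group_profiles, plot_selectivity_ratio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_demo_data"]

#: responses analysed by default, in panel order
DEFAULT_RESPONSES = ("mets", "z_bmi", "z_sbp", "z_dbp", "z_hdl", "z_ir")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; YAML-loadable.

    Repetition counts default to full-scale inference (1000 CV repetitions,
    10^4 permutations, 10^4 bootstrap) and are reducible for quick runs.
    """

    epochs_dir: str = ""
    raw_dir: str = ""
    cohort_csv: str = ""
    out_dir: str = "pipeline_out"

    filter_low_hz: float = 0.29
    filter_high_hz: float = 10.0
    filter_order: int = 4
    epoch_s: int = 3
    night_start: str = "23:00"
    night_end: str = "06:00"
    nonwear_window_min: float = 60.0
    nonwear_allowance_min: float = 2.0
    cuts_mg: tuple = spec_mod.DEFAULT_CUTPOINTS_MG
    min_wear_min: float = 600.0
    min_valid_days: int = 4

    responses: tuple = DEFAULT_RESPONSES
    a_max: int = 10
    cv_reps: int = 1000
    n_perm: int = 10_000
    perm_reps: int = 100
    n_boot: int = 10_000
    holdout_fraction: float = 0.2
    cutoff_sd: float = 0.5
    min_complete_n: int = 50
    seed: int = 0
    #: optional mapping table rows {intensity_mg, MET or speed labels}
    secondary_axis: tuple = ()
    group_column: str = "country"

    def __post_init__(self) -> None:
        for name in ("cv_reps", "n_perm", "perm_reps", "n_boot", "a_max"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.holdout_fraction < 0.5:
            raise ValueError("holdout_fraction must be in (0, 0.5)")
        self.cuts_mg = tuple(self.cuts_mg)
        self.responses = tuple(self.responses)
        self.secondary_axis = tuple(self.secondary_axis)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def filter_spec(self) -> proc.FilterSpec:
        return proc.FilterSpec(self.filter_low_hz, self.filter_high_hz,
                               self.filter_order)


def _load_epoch_series(config: PipelineConfig) -> list[proc.EpochSeries]:
    if config.epochs_dir:
        root = Path(config.epochs_dir)
        if not root.is_dir():
            raise FileNotFoundError(f"epochs_dir not found: {root}")
        series = []
        for path in sorted(root.glob("*.parquet")) + sorted(root.glob("*.csv")):
            sid = path.stem
            if path.suffix == ".parquet":
                df = pd.read_parquet(path)
                t0 = np.datetime64(pd.Timestamp(df["timestamp"].iloc[0]).to_datetime64(), "s")
                series.append(proc.EpochSeries(sid, t0, df["vm_mg"].to_numpy(float),
                                               config.epoch_s))
            else:
                series.append(proc.read_epochs_csv(path, subject_id=sid))
        if not series:
            raise FileNotFoundError(f"no epoch files in {root}")
        return series
    if config.raw_dir:
        root = Path(config.raw_dir)
        if not root.is_dir():
            raise FileNotFoundError(f"raw_dir not found: {root}")
        fspec = config.filter_spec()
        series = []
        for path in sorted(root.glob("*.csv")):
            rec = proc.read_raw_csv(path, subject_id=path.stem)
            vm = proc.filter_and_vm(rec, fspec)
            series.append(proc.aggregate_epochs(vm, fs=rec.fs, epoch_s=config.epoch_s,
                                                t0=rec.t0, subject_id=path.stem))
        if not series:
            raise FileNotFoundError(f"no raw files in {root}")
        return series
    raise FileNotFoundError("config must set epochs_dir or raw_dir")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    Fails fast on missing inputs; artifacts of a failed run are removed.
    """
    cohort_path = Path(config.cohort_csv)
    if not cohort_path.is_file():
        raise FileNotFoundError(f"cohort table not found: {cohort_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save_df(df: pd.DataFrame, name: str, **kw) -> Path:
        path = out / name
        df.to_csv(path, **kw)
        written.append(path)
        return path

    try:
        manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                    "artifacts": {}}
        series = _load_epoch_series(config)
        logger.info("stage load: %d subjects", len(series))

        spectra, cut_rows, excluded = [], [], []
        for s in series:
            s = proc.zero_night(s, config.night_start, config.night_end)
            proc.detect_nonwear(s, config.nonwear_window_min,
                                config.nonwear_allowance_min,
                                lpa_cut_mg=config.cuts_mg[0])
            validity = proc.assess_validity(s, config.min_wear_min,
                                            config.min_valid_days)
            if not validity.is_valid:
                excluded.append(s.subject_id)
                logger.info("subject %s excluded: %d valid days",
                            s.subject_id, validity.n_valid_days)
                continue
            spectra.append(spec_mod.compute_spectrum(s, validity=validity))
            c = spec_mod.compute_cutpoint_summary(s, config.cuts_mg, validity)
            cut_rows.append({"subject_id": c.subject_id, "sed": c.sed,
                             "lpa": c.lpa, "mpa": c.mpa, "vpa": c.vpa,
                             "vvpa": c.vvpa, "mvpa": c.mvpa})
        logger.info("stage processing: %d valid, %d excluded",
                    len(spectra), len(excluded))
        if len(spectra) < 20:
            raise RuntimeError(f"only {len(spectra)} valid subjects; need >= 20")

        spec_table = spec_mod.spectrum_table(spectra)
        manifest["artifacts"]["spectrum_table"] = str(
            _save_df(spec_table, "spectrum_minutes.csv", index_label="subject_id"))
        cut_table = pd.DataFrame(cut_rows).set_index("subject_id")
        manifest["artifacts"]["cutpoint_table"] = str(
            _save_df(cut_table, "cutpoint_minutes.csv"))

        cohort = pd.read_csv(cohort_path).set_index("subject_id")
        cohort = cohort.loc[cohort.index.intersection(spec_table.index)]
        spec_table = spec_table.loc[cohort.index]
        logger.info("stage cohort merge: %d subjects with cohort data", len(cohort))

        zpanel = risk_mod.build_zpanel(cohort)
        manifest["artifacts"]["zpanel_table"] = str(
            _save_df(zpanel.drop(columns=["stratum"]), "zpanel_mets.csv",
                     index_label="subject_id"))

        spec_z = spec_mod.standardize_spectrum(spec_table)
        groups = cohort[config.group_column]
        profiles = spec_mod.group_profile(spec_z, groups, n_boot=config.n_boot,
                                          seed=config.seed, on_small="drop")
        manifest["artifacts"]["group_profile_table"] = str(
            _save_df(profiles, "group_profiles.csv", index=False))
        sec = pd.DataFrame(list(config.secondary_axis)) if config.secondary_axis else None
        ax = plot_group_profiles(profiles, spectra[0].definition, config.cuts_mg, sec,
                                 title="Standardized PA intensity spectrum by group")
        fig_path = out / "group_profiles.svg"
        ax.figure.savefig(fig_path)
        written.append(fig_path)
        manifest["artifacts"]["group_profile_figure"] = str(fig_path)
        logger.info("stage profiles: %d groups", groups.nunique())

        responses = zpanel[[r for r in config.responses if r in zpanel]]
        confounders = cohort[["age", "sex", "country", "income", "education"]]
        suite = ModelSuite(spec_z, confounders, responses,
                           categorical=["sex", "country", "income", "education"],
                           continuous=["age"],
                           min_complete_n=config.min_complete_n)
        results = suite.fit(a_max=config.a_max, cv_reps=config.cv_reps,
                            n_perm=config.n_perm, perm_reps=config.perm_reps,
                            holdout_fraction=config.holdout_fraction,
                            cutoff_sd=config.cutoff_sd, seed=config.seed)
        manifest["artifacts"]["model_suite_table"] = str(
            _save_df(results.to_frame(), "model_strengths.csv", index=False))
        txt_path = out / "model_strengths.txt"
        txt_path.write_text(results.summary() + "\n")
        written.append(txt_path)
        logger.info("stage models: %d model fits", len(results.cells))

        sr_paths = {}
        n_bins = spec_z.shape[1]
        for resp in responses.columns:
            key = (resp, "PA and confounders")
            if key not in results.fits:
                continue
            fit = results.fits[key]
            sr = fit.bootstrap_sr(n_boot=config.n_boot, seed=config.seed,
                                  overall="cv")
            frame = sr.to_frame()
            sr_paths[resp] = str(_save_df(frame, f"sr_{resp}.csv", index=False))
            fig = plot_selectivity_ratio(frame, n_bins, spectra[0].definition,
                                         config.cuts_mg, sec,
                                         title=f"Selectivity ratio: {resp}")
            fpath = out / f"sr_{resp}.svg"
            fig.savefig(fpath)
            written.append(fpath)
            sr_paths[resp + "_figure"] = str(fpath)
        manifest["artifacts"]["selectivity_ratio"] = sr_paths
        manifest["n_subjects_valid"] = len(spectra)
        manifest["n_subjects_excluded"] = len(excluded)

        man_path = out / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2))
        written.append(man_path)
        return manifest
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise


# ---------------------------------------------------------------------------
# bundled demo data

#: outcome effect vectors on the standardized spectrum: adverse factors load
#: negatively on the vigorous-intensity bins (1-based bins 10-14), HDL
#: positively; blood pressure spreads weakly across the whole spectrum
_DEMO_EFFECTS = {
    "bmi": (-1.0, (9, 14), 0.10),
    "mets": (-1.0, (9, 14), 0.08),
    "sbp": (-0.4, (1, 20), 0.02),
    "dbp": (-0.4, (1, 20), 0.02),
    "hdl": (+1.0, (11, 16), 0.04),
    "ir": (-1.0, (8, 13), 0.05),
}

_DEMO_UNITS = {  # mean, SD used to map z-outcomes to raw units
    "bmi": (19.1, 4.0), "waist": (67.0, 10.0), "sbp": (106.4, 9.2),
    "dbp": (64.7, 6.2), "hdl": (59.5, 13.7), "triglycerides": (80.0, 30.0),
}


def make_demo_data(
    outdir,
    seed: int = 0,
    n_subjects: int = 300,
    n_days: int = 7,
    group_shift_mg: dict | None = None,
    epochs_format: str = "parquet",
) -> dict:
    """Write a synthetic demo cohort with documented ground truth.

    Generates an epoch-level cohort, derives each subject's true standardized
    spectrum, builds risk factors from configurable spectrum effects plus
    confounder effects and noise, and writes: per-subject epoch files, a
    cohort table (confounders + raw risk factors), and a ground-truth
    manifest with the effect windows and true R² per response.
    """
    out = Path(outdir)
    ep_dir = out / "epochs"
    try:
        ep_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create demo output dir {out}: {exc}") from exc
    if group_shift_mg is None:
        group_shift_mg = {"SWE": 60.0, "ESP": 30.0, "ITA": -40.0}
    cohort_cfg = CohortConfig(n_subjects=n_subjects, n_days=n_days,
                              group_shift_mg=group_shift_mg, seed=seed)
    series, conf = generate_epoch_cohort(cohort_cfg)

    # true spectra via the actual processing chain
    spectra = []
    for s in series:
        s2 = proc.zero_night(s)
        proc.detect_nonwear(s2)
        spectra.append(spec_mod.compute_spectrum(s2))
    spec_table = spec_mod.spectrum_table(spectra)
    spec_z = spec_mod.standardize_spectrum(spec_table)
    # align confounders with subjects surviving the validity rules
    conf = (conf.set_index("subject_id").loc[spec_z.index]
            .rename_axis("subject_id").reset_index())
    n_subjects = len(conf)

    rng = np.random.default_rng(seed + 1)
    n_bins = spec_z.shape[1]
    age_z = (conf["age"] - conf["age"].mean()) / conf["age"].std(ddof=1)
    country_eff = conf["country"].map(
        {"ITA": 0.5, "HUN": 0.2, "GER": 0.1, "ESP": -0.1, "SWE": -0.3, "POL": 0.0})
    income_eff = conf["income"].map(
        {"low": 0.3, "low-mid": 0.15, "mid": 0.0, "mid-high": -0.15, "high": -0.3})
    design = np.column_stack([age_z, country_eff, income_eff])

    truth = {"seed": seed, "n_subjects": n_subjects, "responses": {}}
    z_out = {}
    for resp, (sign, (lo, hi), r2) in _DEMO_EFFECTS.items():
        beta = np.zeros(n_bins)
        beta[lo : hi + 1] = sign
        sd = noise_sd_for_r2(spec_z.to_numpy(), beta, r2)
        cfg = CohortConfig(n_subjects=n_subjects,
                           beta_spectrum=tuple(beta),
                           beta_confounders=(0.15 * sd, 0.6 * sd, 0.5 * sd),
                           noise_sd=sd, seed=seed)
        y, t = generate_outcomes(spec_z.to_numpy(), design, cfg, rng=rng)
        z = (y - y.mean()) / y.std(ddof=1)
        z_out[resp] = z
        truth["responses"][resp] = {
            "effect_bins_0based": [lo, hi], "effect_sign": sign,
            "target_spectrum_r2": r2, **t,
        }

    cohort = conf.copy()
    for col, (mu, sdv) in _DEMO_UNITS.items():
        src = {"waist": "bmi", "triglycerides": "mets"}.get(col, col)
        jitter = rng.normal(0, 0.3, size=n_subjects)
        cohort[col] = mu + sdv * (z_out.get(src, rng.normal(size=n_subjects)) + jitter) / np.sqrt(1.09)
    ir = 1.9 * np.exp(0.6 * z_out["ir"])
    cohort["glucose"] = rng.normal(90.0, 6.0, size=n_subjects)
    cohort["insulin"] = ir * 405.0 / cohort["glucose"]

    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)

    for s in series:
        if epochs_format == "parquet":
            pd.DataFrame({"timestamp": s.epoch_starts(), "vm_mg": s.vm_mg}
                         ).to_parquet(ep_dir / f"{s.subject_id}.parquet", index=False)
        else:
            proc.write_epochs_csv(s, ep_dir / f"{s.subject_id}.csv")

    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, default=float))
    return {"epochs_dir": str(ep_dir), "cohort_csv": str(cohort_path),
            "ground_truth": str(truth_path), "n_subjects": n_subjects}
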