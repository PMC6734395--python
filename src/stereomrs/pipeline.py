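"""End-to-end synthetic study: simulate → quantify → group stats → dynamics.

Produces, for one synthetic cohort, the full artifact set of the analysis:
per-subject GABA+:tCr and Glx:tCr quantifications with QC, static
condition comparisons (paired t, water-referenced controls), within-subject
correlation structure with dependent-correlation z tests, the
condition × order ANOVA, Vernier psychometrics, and (optionally) the
sliding-window cluster-mass dynamic analysis.  Every stage draws its
randomness from a seed derived deterministically from the run seed, so a
manifest plus config reproduces every output bit-for-bit.

All outputs are synthetic-cohort statistics; they exercise the method, not
the human data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import group_stats as gs
from .quant import TissueFractions, qc_report, quantify_acquisition
from .spectra_sim import (
    AcquisitionConfig,
    CohortConfig,
    simulate_cohort,
    simulate_vernier,
    simulate_water_acquisition,
    truth_table,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    acquisition: AcquisitionConfig = field(
        default_factory=lambda: AcquisitionConfig(
            noise_sd=0.02, freq_drift_sd=1.0, phase_drift_sd=5.0
        )
    )
    tissue: TissueFractions = field(
        default_factory=lambda: TissueFractions(0.49, 0.35, 0.16)
    )
    out_dir: str | Path | None = None
    run_dynamics: bool = True
    window_width: int = 128  # transients
    n_perm: int = 1000
    water_reference: bool = True
    vernier_trials_per_offset: int = 30
    make_plots: bool = False
    verbosity: int = 1


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(cfg: RunConfig, msg: str) -> None:
    if cfg.verbosity:
        print(f"[stereomrs] {msg}")


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole synthetic study; returns the manifest dict.

    When ``config.out_dir`` is set, writes ``cohort.csv``, ``truth.csv``,
    ``qc.csv``, ``group_stats.json``, ``dynamics.json`` (+ window CSVs),
    ``behaviour.csv`` and ``manifest.json`` there.
    """
    t_start = time.time()
    root = np.random.SeedSequence(config.seed)
    seed_cohort, seed_vernier, seed_dyn = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)
    )
    cohort_cfg = replace(config.cohort, seed=seed_cohort)

    # --- simulate + quantify -------------------------------------------------
    subjects, acq_iter = simulate_cohort(cohort_cfg, config.acquisition)
    correct_drift = (
        config.acquisition.freq_drift_sd > 0 or config.acquisition.phase_drift_sd > 0
    )
    rows, qc_results = [], []
    window_series: dict[str, dict[str, pd.DataFrame]] = {"single": {}, "mixed": {}}
    for s, acqs in acq_iter:
        _log(config, f"quantifying subject {s.subject_id}")
        wrng = np.random.default_rng(seed_cohort + hash(s.subject_id) % 10_000)
        for cond, acq in acqs.items():
            water = (
                simulate_water_acquisition(acq.config, rng=wrng)
                if config.water_reference
                else None
            )
            res = quantify_acquisition(
                acq, water_acq=water, tissue=config.tissue, correct_drift=correct_drift
            )
            rows.append(
                {
                    "subject": s.subject_id,
                    "order": s.order,
                    "condition": cond,
                    "gaba_tcr": res.gaba_tcr,
                    "glx_tcr": res.glx_tcr,
                    "gaba_water": res.gaba_water,
                    "glx_water": res.glx_water,
                    "valid": res.valid,
                }
            )
            qc_results.append(res)
            if config.run_dynamics and cond in ("single", "mixed"):
                ws = dyn.sliding_window_quant(
                    acq, width=config.window_width, correct_drift=correct_drift
                )
                window_series[cond][s.subject_id] = ws

    cohort_df = pd.DataFrame(rows)
    qc_df = qc_report(qc_results)
    qc_df.insert(0, "subject", cohort_df["subject"])

    # --- static group statistics --------------------------------------------
    wide = cohort_df.pivot(index="subject", columns="condition")
    orders = cohort_df.drop_duplicates("subject").set_index("subject")["order"]
    stats_out: dict = {}
    for metab in ("gaba", "glx"):
        col = f"{metab}_tcr"
        per = wide[col]
        block = {
            "single_vs_mixed": gs.paired_t(per["single"], per["mixed"])._asdict(),
            "rest_vs_single": gs.paired_t(per["rest1"], per["single"])._asdict(),
            "rest_vs_mixed": gs.paired_t(per["rest1"], per["mixed"])._asdict(),
            "rest1_vs_rest2": gs.paired_t(per["rest1"], per["rest2"])._asdict(),
        }
        if config.water_reference:
            perw = wide[f"{metab}_water"]
            block["single_vs_mixed_water"] = gs.paired_t(
                perw["single"], perw["mixed"]
            )._asdict()
        # active-active correlation vs rest-active correlations
        block["corr_single_mixed_vs_rest_single"] = gs.compare_dependent_correlations(
            per["single"], per["mixed"], per["rest1"]
        )
        block["corr_mixed_single_vs_rest_mixed"] = gs.compare_dependent_correlations(
            per["mixed"], per["single"], per["rest1"]
        )
        vals = per[["single", "mixed"]].to_numpy()
        block["anova_condition_order"] = {
            conv: gs.mixed_anova_2x2(vals, orders.loc[per.index].to_numpy(), conv)
            for conv in ("textbook", "pooled")
        }
        stats_out[metab] = block
    d_gaba = wide["gaba_tcr"]["single"] - wide["gaba_tcr"]["mixed"]
    d_glx = wide["glx_tcr"]["single"] - wide["glx_tcr"]["mixed"]
    stats_out["gaba_glx_change_correlation"] = dict(
        zip(("r", "p"), gs.pearson_r(d_gaba, d_glx))
    )

    # --- Vernier behaviour ---------------------------------------------------
    vrng = np.random.default_rng(seed_vernier)
    behav_rows = []
    for subject in wide.index:
        true_bias = vrng.normal(0.0, 0.8)
        true_sigma = float(np.exp(vrng.normal(np.log(2.0), 0.2)))
        for cond in ("single", "mixed"):
            trials = simulate_vernier(
                true_bias, true_sigma, offsets=None,
                n_per_offset=config.vernier_trials_per_offset, seed=vrng,
            )
            fit = gs.fit_cumulative_gaussian(trials)
            nonzero = trials[trials["offset_arcmin"] != 0]
            acc = float(
                (
                    (nonzero["offset_arcmin"] > 0)
                    == (nonzero["response_right"] == 1)
                ).mean()
            )
            rt = float(vrng.normal(0.55, 0.05))
            behav_rows.append(
                {
                    "subject": subject,
                    "condition": cond,
                    "accuracy": acc,
                    "response_time_s": rt,
                    "bias_arcmin": fit.bias,
                    "sigma_arcmin": fit.sigma,
                    "true_bias_arcmin": true_bias,
                }
            )
    behav_df = pd.DataFrame(behav_rows)
    bw = behav_df.pivot(index="subject", columns="condition")
    stats_out["vernier"] = {
        "accuracy": gs.paired_t(bw["accuracy"]["single"], bw["accuracy"]["mixed"])._asdict(),
        "response_time": gs.paired_t(
            bw["response_time_s"]["single"], bw["response_time_s"]["mixed"]
        )._asdict(),
        "bias_single_vs_mixed": gs.paired_t(
            bw["bias_arcmin"]["single"], bw["bias_arcmin"]["mixed"]
        )._asdict(),
    }

    # --- dynamic analysis ----------------------------------------------------
    dynamics_out = None
    if config.run_dynamics:
        dynamics_out = {}
        subj_ids = sorted(window_series["single"])
        for mi, metab in enumerate(("gaba_tcr", "glx_tcr")):
            mats = {}
            for cond in ("single", "mixed"):
                mat = np.vstack(
                    [window_series[cond][s][metab].to_numpy() for s in subj_ids]
                )
                mat, report = dyn.screen_outliers(mat)
                mats[cond] = mat
                dynamics_out[f"{metab}_{cond}_outliers_removed"] = report["n_removed"]
            result = dyn.cluster_permutation_test(
                mats["single"], mats["mixed"],
                n_perm=config.n_perm, seed=seed_dyn + mi,
            )
            dynamics_out[metab] = {
                "threshold": result.threshold,
                "n_perm": result.n_perm,
                "clusters": result.clusters,
                "n_surviving": len(result.surviving),
            }

    # --- outputs -------------------------------------------------------------
    manifest = {
        "config": _jsonable(config),
        "derived_seeds": {
            "cohort": seed_cohort,
            "vernier": seed_vernier,
            "dynamics": seed_dyn,
        },
        "headline": {
            "gaba_single_vs_mixed_t": stats_out["gaba"]["single_vs_mixed"]["t"],
            "gaba_single_vs_mixed_p": stats_out["gaba"]["single_vs_mixed"]["p"],
            "glx_single_vs_mixed_t": stats_out["glx"]["single_vs_mixed"]["t"],
            "glx_single_vs_mixed_p": stats_out["glx"]["single_vs_mixed"]["p"],
        },
        "group_stats": _jsonable(stats_out),
        "dynamics": _jsonable(dynamics_out),
        "elapsed_s": round(time.time() - t_start, 2),
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_df.to_csv(out / "cohort.csv", index=False)
        truth_table(subjects).to_csv(out / "truth.csv", index=False)
        qc_df.to_csv(out / "qc.csv", index=False)
        behav_df.to_csv(out / "behaviour.csv", index=False)
        (out / "group_stats.json").write_text(
            json.dumps(_jsonable(stats_out), indent=2)
        )
        if dynamics_out is not None:
            (out / "dynamics.json").write_text(
                json.dumps(_jsonable(dynamics_out), indent=2)
            )
            for cond in ("single", "mixed"):
                pd.concat(
                    {s: df for s, df in window_series[cond].items()},
                    names=["subject"],
                ).reset_index(0).to_csv(out / f"windows_{cond}.csv", index=False)
        if config.make_plots:
            _make_plots(out, cohort_df, window_series)
        files = sorted(p for p in out.iterdir() if p.suffix in (".csv", ".json"))
        manifest["files"] = {p.name: _sha256(p) for p in files if p.name != "manifest.json"}
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))

    _log(config, f"done in {manifest['elapsed_s']}s")
    return manifest


def _make_plots(out: Path, cohort_df: pd.DataFrame, window_series: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, metab in zip(axes, ("gaba_tcr", "glx_tcr")):
        wide = cohort_df.pivot(index="subject", columns="condition", values=metab)
        for _, row in wide.iterrows():
            ax.plot([0, 1], [row["single"], row["mixed"]], "o-", alpha=0.5, lw=0.8)
        ax.set_xticks([0, 1], ["single", "mixed"])
        ax.set_ylabel(metab)
    fig.tight_layout()
    fig.savefig(out / "condition_comparison.png", dpi=120)
    plt.close(fig)

    if window_series["single"]:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, metab in zip(axes, ("gaba_tcr", "glx_tcr")):
            for cond, color in (("single", "C0"), ("mixed", "C1")):
                mat = np.vstack(
                    [df[metab].to_numpy() for df in window_series[cond].values()]
                )
                m = np.nanmean(mat, axis=0)
                se = np.nanstd(mat, axis=0, ddof=1) / np.sqrt(mat.shape[0])
                xs = np.arange(m.size)
                ax.plot(xs, m, color=color, label=cond)
                ax.fill_between(xs, m - se, m + se, color=color, alpha=0.25)
            ax.set_xlabel("window")
            ax.set_ylabel(metab)
            ax.legend()
        fig.tight_layout()
        fig.savefig(out / "dynamics.png", dpi=120)
        plt.close(fig)
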