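"""End-to-end orchestration: simulate -> score -> gait -> EEG -> clusters -> stats.

``run_pipeline`` generates (or accepts) a synthetic cohort, scores the
Go/NoGo task per participant and motor condition, quantifies stride-to-stride
variability per cognitive load, rejects artifactual epochs and averages ERPs
per condition, classifies improvers, runs the cluster-based permutation
tests on walking-minus-sitting difference waveforms (whole cohort and per
classified subgroup), computes the scalar statistics, and applies the
combined two-stage FDR.  Failures inside one participant's stream are
quarantined with a log entry rather than aborting the run.

Everything is seeded through one integer; re-running with the same manifest
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import cluster as clu
from . import eeg
from . import gait as gt
from . import stats as st
from .config import SimCohortConfig, config_to_dict
from .errors import EmptySampleError
from .montage import get_biosemi64
from .synthetic import (
    EpochSet,
    NoiseSpec,
    default_templates,
    gen_epoch_set,
    gen_gait_trace,
    gen_responses,
    gen_trial_sequence,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_participant", "RunManifest", "PipelineResult"]

COGNITIVE_CONDITIONS = {
    "correct_rejection": ("stimulus_onset", (-100.0, 0.0)),
    "false_alarm": ("response_onset", (-400.0, -300.0)),
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    digests: dict
    started: str
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    scalar_tests: list
    cluster_results: dict
    fdr_table: pd.DataFrame
    fdr_mask: np.ndarray
    fdr_critical_p: float
    classification_threshold: float
    quarantined: list
    manifest: RunManifest
    report: dict


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def simulate_participant(cfg: SimCohortConfig, pid: str, group: str, seed_seq) -> dict:
    """Generate all three data streams for one participant.

    ``group`` is the generating (ground-truth) group: 'imp' or 'nimp'.
    Returns events (both motor conditions), gait traces per load, and the
    four epoch sets.
    """
    streams = seed_seq.spawn(3)
    rng_beh = np.random.default_rng(streams[0])
    rng_gait = np.random.default_rng(streams[1])
    rng_eeg = np.random.default_rng(streams[2])

    blocks = []
    for motor in ("sitting", "walking"):
        mean_ms, sd_ms = cfg.rt_params[group][motor]
        hr, far = cfg.rates[group][motor]
        for b in range(cfg.blocks_per_condition):
            seq = gen_trial_sequence(
                cfg.trials_per_block, cfg.nogo_fraction, cfg.soa_ms,
                seed=rng_beh, block_id=b, motor_condition=motor,
            )
            blocks.append(
                gen_responses(seq, hr, far, mean_ms, sd_ms, cfg.rt_floor_ms, seed=rng_beh)
            )
    events = pd.concat(blocks, ignore_index=True)

    traces = {}
    for load in ("ST", "DT"):
        jit = cfg.gait_jitter[group][load]
        traces[load] = {
            foot: gen_gait_trace(
                cfg.gait_duration_s, cfg.stride_period_s, jit, foot=foot, seed=rng_gait
            )
            for foot in ("left", "right")
        }

    noise = NoiseSpec(
        pink_sd_uv=cfg.noise_pink_sd_uv,
        white_sd_uv=cfg.noise_white_sd_uv,
        exponent=cfg.noise_exponent,
        spatial_sigma_rad=cfg.noise_spatial_sigma_rad,
    )
    epochs = {}
    for cognitive, (lock, _) in COGNITIVE_CONDITIONS.items():
        n_ep = cfg.n_cr_epochs if cognitive == "correct_rejection" else cfg.n_fa_epochs
        templates = default_templates(lock)
        for motor in ("sitting", "walking"):
            effects = None
            if motor == "walking" and group == "imp":
                windows = {
                    "stimulus_onset": ("N2", "P3"),
                    "response_onset": ("ERN", "PMP"),
                }[lock]
                effects = [e for e in cfg.erp_effect_map if e[0] in windows]
                effects = [(n, el, tuple(w), d) for n, el, w, d in effects]
            epochs[(cognitive, motor)] = gen_epoch_set(
                templates, n_ep, lock, cognitive, motor,
                effects=effects, noise=noise, sfreq=cfg.erp_sfreq, seed=rng_eeg,
            )
    return {"pid": pid, "group": group, "events": events, "gait": traces, "epochs": epochs}


def _baseline(epochs: EpochSet, baseline_ms: tuple[float, float]) -> EpochSet:
    mask = (epochs.times_ms >= baseline_ms[0]) & (epochs.times_ms <= baseline_ms[1])
    data = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return dataclasses.replace(epochs, data=data)


def analyze_participant(cfg: SimCohortConfig, stream: dict) -> dict:
    """Score one participant's streams into behavioral, gait and ERP summaries."""
    pid = stream["pid"]
    summaries = {
        s.motor_condition: s
        for s in bhv.summarize_participant(stream["events"], pid, cfg.min_rt_ms)
    }
    gait_out = {
        load: gt.analyze_gait(
            feet["left"], feet["right"], pid, load,
            cfg.heel_prominence_m, cfg.resample_n,
        )
        for load, feet in stream["gait"].items()
    }
    erp, n_rejected = {}, {}
    for (cognitive, motor), es in stream["epochs"].items():
        baseline_ms = COGNITIVE_CONDITIONS[cognitive][1]
        kept, log = eeg.reject_epochs(_baseline(es, baseline_ms))
        erp[(cognitive, motor)] = eeg.average_erp(kept)
        n_rejected[(cognitive, motor)] = len(log)
    diff = {
        cognitive: erp[(cognitive, "walking")].data - erp[(cognitive, "sitting")].data
        for cognitive in COGNITIVE_CONDITIONS
    }
    return {
        "pid": pid,
        "group": stream["group"],
        "behavior": summaries,
        "gait": gait_out,
        "erp": erp,
        "diff": diff,
        "n_rejected": n_rejected,
    }


def _cohort_table(analyses: list[dict]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        b_sit, b_walk = a["behavior"]["sitting"], a["behavior"]["walking"]
        rows.append(
            {
                "participant_id": a["pid"],
                "true_group": a["group"],
                "dprime_sitting": b_sit.dprime,
                "dprime_walking": b_walk.dprime,
                "delta_dprime": b_walk.dprime - b_sit.dprime,
                "avg_dprime": 0.5 * (b_walk.dprime + b_sit.dprime),
                "rt_sitting_ms": b_sit.mean_go_rt_ms,
                "rt_walking_ms": b_walk.mean_go_rt_ms,
                "mean_dtw_st_m": a["gait"]["ST"].mean_dtw_m,
                "mean_dtw_dt_m": a["gait"]["DT"].mean_dtw_m,
            }
        )
    return pd.DataFrame(rows)


def _gated_paired(x, y, name) -> st.TestResult:
    route = st.normality_gate(np.asarray(x) - np.asarray(y))
    if route == "nonparametric" and len(np.asarray(x)) >= 5:
        return st.wilcoxon_signed_rank(x, y, name=name)
    return st.paired_t(x, y, name=name)


def run_pipeline(cfg: SimCohortConfig, out_dir=None, seed: int | None = None) -> PipelineResult:
    """Execute the full synthetic-cohort analysis; see the module docstring."""
    started = datetime.datetime.now().isoformat(timespec="seconds")
    seed = cfg.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    groups = ["imp"] * cfg.n_imp + ["nimp"] * cfg.n_nimp
    child_seqs = root.spawn(len(groups))

    analyses, quarantined = [], []
    for i, (group, seq) in enumerate(zip(groups, child_seqs)):
        pid = f"P{i + 1:02d}"
        try:
            analyses.append(analyze_participant(cfg, simulate_participant(cfg, pid, group, seq)))
        except Exception as err:  # quarantine, do not abort the cohort
            logger.warning("participant %s quarantined: %s", pid, err)
            quarantined.append({"pid": pid, "error": str(err)})
    if len(analyses) < 3:
        raise EmptySampleError("fewer than 3 analyzable participants")

    cohort = _cohort_table(analyses)
    labels, threshold = st.classify_cohort(
        cohort["delta_dprime"].to_numpy(), cfg.classify_alpha
    )
    cohort["label"] = labels

    # ---- scalar statistics (normality-gated, mirroring the design) ----
    scalar: list[st.TestResult] = []
    scalar.append(
        _gated_paired(cohort["dprime_walking"], cohort["dprime_sitting"], "dprime_walk_vs_sit")
    )
    scalar.append(
        _gated_paired(cohort["rt_walking_ms"], cohort["rt_sitting_ms"], "go_rt_walk_vs_sit")
    )
    scalar.append(
        _gated_paired(cohort["mean_dtw_dt_m"], cohort["mean_dtw_st_m"], "dtw_dt_vs_st")
    )

    imp_mask = cohort["label"] == "IMP"
    anovas_ok = imp_mask.sum() >= 2 and (~imp_mask).sum() >= 2
    if anovas_ok:
        scalar.append(
            st.independent_t(
                cohort.loc[imp_mask, "avg_dprime"],
                cohort.loc[~imp_mask, "avg_dprime"],
                name="avg_dprime_imp_vs_nimp",
            )
        )
        rt_res, _ = st.anova_2x2_mixed(
            cohort["label"].to_numpy(),
            cohort[["rt_sitting_ms", "rt_walking_ms"]].to_numpy(),
            name="anova_rt",
        )
        dtw_res, _ = st.anova_2x2_mixed(
            cohort["label"].to_numpy(),
            cohort[["mean_dtw_st_m", "mean_dtw_dt_m"]].to_numpy(),
            name="anova_dtw",
        )
        scalar += list(rt_res.values()) + list(dtw_res.values())

    # ---- cluster-based permutation tests ----
    _, positions = get_biosemi64()
    adjacency = clu.build_adjacency(positions, cfg.neighbor_radius_rad)
    subgroup_masks = {
        "cohort": np.ones(len(cohort), dtype=bool),
        "imp": imp_mask.to_numpy(),
        "nimp": (~imp_mask).to_numpy(),
    }
    cluster_results: dict[str, clu.ClusterResult] = {}
    for gi, (gname, gmask) in enumerate(subgroup_masks.items()):
        for ci, cognitive in enumerate(COGNITIVE_CONDITIONS):
            if gmask.sum() < 5:
                logger.warning("skipping cluster test %s/%s: n=%d < 5", gname, cognitive,
                               gmask.sum())
                continue
            diffs = np.stack([a["diff"][cognitive] for a, m in zip(analyses, gmask) if m])
            cluster_results[f"{gname}_{cognitive}"] = clu.cluster_permutation_test(
                diffs, adjacency, n_perm=cfg.n_permutations,
                alpha=cfg.perm_alpha, cluster_alpha=cfg.cluster_alpha,
                seed=np.random.default_rng(np.random.SeedSequence([seed, 193, gi, ci])),
            )

    # ---- combined FDR ----
    fdr_table = st.aggregate_pvalues_for_fdr(scalar, cluster_results)
    fdr_mask, fdr_crit = st.bky_fdr(fdr_table["p"].to_numpy(), cfg.fdr_q)
    fdr_table["significant"] = fdr_mask

    report = {
        "n_participants": len(cohort),
        "n_quarantined": len(quarantined),
        "classification_threshold": float(threshold),
        "n_imp_labeled": int(imp_mask.sum()),
        "n_nimp_labeled": int((~imp_mask).sum()),
        "cohort": cohort.round(6).to_dict(orient="records"),
        "scalar_tests": [r.as_row() for r in scalar],
        "cluster_tests": {
            k: v.summary().round(6).to_dict(orient="records") for k, v in cluster_results.items()
        },
        "fdr": {
            "q": cfg.fdr_q,
            "critical_p": None if np.isnan(fdr_crit) else float(fdr_crit),
            "n_significant": int(fdr_mask.sum()),
            "set": fdr_table.round(8).to_dict(orient="records"),
        },
        "epoch_rejection": {
            f"{a['pid']}_{cog}_{mot}": int(n)
            for a in analyses
            for (cog, mot), n in a["n_rejected"].items()
        },
    }
    manifest = RunManifest(
        config=config_to_dict(cfg),
        seed=seed,
        version=_package_version(),
        digests={
            "cohort": _digest(report["cohort"]),
            "scalar_tests": _digest(report["scalar_tests"]),
            "cluster_tests": _digest(report["cluster_tests"]),
            "report": _digest(report),
        },
        started=started,
        finished=datetime.datetime.now().isoformat(timespec="seconds"),
    )

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "manifest.json").write_text(manifest.to_json())
        cohort.to_csv(out / "cohort.csv", index=False)
        (out / "summary.md").write_text(_summary_md(report))

    return PipelineResult(
        cohort=cohort,
        scalar_tests=scalar,
        cluster_results=cluster_results,
        fdr_table=fdr_table,
        fdr_mask=fdr_mask,
        fdr_critical_p=fdr_crit,
        classification_threshold=threshold,
        quarantined=quarantined,
        manifest=manifest,
        report=report,
    )


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("mobidt")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _summary_md(report: dict) -> str:
    lines = [
        "# Pipeline summary",
        "",
        f"Participants analyzed: {report['n_participants']} "
        f"(quarantined: {report['n_quarantined']})",
        f"Improver classification: {report['n_imp_labeled']} IMP / "
        f"{report['n_nimp_labeled']} nIMP "
        f"(threshold {report['classification_threshold']:.3f})",
        "",
        "## Scalar tests",
        "",
        "| test | statistic | p |",
        "|---|---|---|",
    ]
    for row in report["scalar_tests"]:
        lines.append(f"| {row['test']} | {row['statistic']:.3f} | {row['p']:.4f} |")
    lines += ["", "## Cluster tests (min cluster p)", "", "| comparison | clusters | min p |",
              "|---|---|---|"]
    for k, rows in report["cluster_tests"].items():
        minp = min((r["p_perm"] for r in rows), default=float("nan"))
        lines.append(f"| {k} | {len(rows)} | {minp:.4f} |")
    fdr = report["fdr"]
    crit = "none" if fdr["critical_p"] is None else f"{fdr['critical_p']:.4f}"
    lines += ["", f"FDR (q={fdr['q']}): {fdr['n_significant']} significant, critical p = {crit}"]
    return "\n".join(lines) + "\n"
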