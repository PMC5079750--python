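"""End-to-end orchestration: simulate datasets, analyse them, write reports.

A :class:`RunConfig` (YAML-serialisable) carries the seed and every module's
parameters.  ``run_simulate`` writes one directory of per-subject CSVs plus
the injected ground truth; ``run_analyze`` runs exclusions, behavioural
SDT/meta-d' modelling, physiological preprocessing, the trial-wise GLM and
group cluster-permutation tests, and writes tables plus a markdown report.
Both are deterministic given the config seed: per-subject random streams
are derived from (seed, subject, stream) tuples, so results do not depend
on execution order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm as glm_mod
from .behavior import apply_exclusions, condition_parameter_table, rm_anova_2x2
from .cardiac import compute_instantaneous_hr
from .physio_sim import PhysioGenParams, TrialTimeline, simulate_pupil_trace, simulate_rpeak_train, synthesize_ecg
from .pupil import PupilPreprocessor, blink_fraction_per_trial, detect_blinks_and_interpolate
from .simulate import ObserverParams, generate_behavior
from .staircase import StaircaseConfig
from .timeseries import PhysioTimeSeries, epoch_and_baseline

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulate", "run_analyze", "generate_experiment"]

PUPIL_WINDOW = (-500.0, 4166.0)  # ms around mask onset
PUPIL_BASELINE = (-500.0, 0.0)
HR_WINDOW = (-1000.0, 4166.0)
HR_BASELINE = (-1000.0, 0.0)


@dataclass
class RunConfig:
    """Complete, serialisable description of one simulation/analysis run."""

    seed: int = 0
    n_subjects: int = 5
    n_trials: int = 640
    n_blocks: int = 10
    pupil_fs: float = 100.0
    ecg_waveform: bool = False
    simulate_physio: bool = True
    observer: dict = field(default_factory=dict)
    physio: dict = field(default_factory=dict)
    staircase: dict = field(default_factory=dict)
    exclusions: dict = field(
        default_factory=lambda: {"burn_in_fraction": 0.25, "rt_z_threshold": 3.0}
    )
    pupil_preproc: dict = field(
        default_factory=lambda: {
            "blink_threshold": 600.0,
            "lowpass_hz": 30.0,
            "derivative_sd": 3.0,
            "blink_reject_fraction": 0.25,
        }
    )
    glm: dict = field(
        default_factory=lambda: {
            "t_height": 2.0,
            "n_perm": 500,
            "cluster_alpha": 0.05,
            "statistic": "extent",
            "include_cue_by_noise": True,
        }
    )
    m_bias_definition: str = "criterion_spread"

    def __post_init__(self) -> None:
        if self.n_trials % 4:
            raise ValueError("n_trials must be divisible by 4 (condition balance)")
        if self.n_trials % self.n_blocks:
            raise ValueError("n_trials must be divisible by n_blocks")

    def observer_params(self) -> ObserverParams:
        return ObserverParams(**self.observer)

    def physio_params(self) -> PhysioGenParams:
        return PhysioGenParams(**self.physio)

    def staircase_config(self) -> StaircaseConfig:
        return StaircaseConfig(**self.staircase)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _rng(seed: int, subject: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, subject, stream])


def run_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate a full synthetic dataset directory.

    Writes per subject: ``trials_sub<k>.csv`` (trial table with an extra
    ``onset_s`` column), ``pupil_sub<k>.csv``, ``rpeaks_sub<k>.csv``, and
    optionally ``ecg_sub<k>.csv``; plus ``ground_truth.json`` with every
    injected parameter and ``config.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    observer = config.observer_params()
    physio = config.physio_params()
    staircase = config.staircase_config()
    timeline = TrialTimeline()

    for k in range(config.n_subjects):
        trials = generate_behavior(
            n_trials=config.n_trials,
            observer=observer,
            staircase=staircase,
            n_blocks=config.n_blocks,
            seed=_rng(config.seed, k, 0),
        )
        onsets = timeline.onsets(len(trials), _rng(config.seed, k, 1))
        trials["onset_s"] = onsets
        trials.to_csv(out / f"trials_sub{k}.csv", index=False)

        if config.simulate_physio:
            pupil, _ = simulate_pupil_trace(
                trials, onsets, physio=physio, fs=config.pupil_fs,
                seed=_rng(config.seed, k, 2),
            )
            pd.DataFrame({"time_s": pupil.times, "pupil_au": pupil.samples}).to_csv(
                out / f"pupil_sub{k}.csv", index=False
            )
            rpeaks, _ = simulate_rpeak_train(
                trials, onsets, physio=physio, seed=_rng(config.seed, k, 3)
            )
            pd.DataFrame({"rpeak_time_s": rpeaks}).to_csv(
                out / f"rpeaks_sub{k}.csv", index=False
            )
            if config.ecg_waveform:
                ecg = synthesize_ecg(rpeaks, seed=_rng(config.seed, k, 4))
                pd.DataFrame({"time_s": ecg.times, "mv": ecg.samples}).to_csv(
                    out / f"ecg_sub{k}.csv", index=False
                )

    truth = {
        "seed": config.seed,
        "observer": {
            "sdt_sigma_internal": observer.sdt_sigma_internal,
            "n_eff_dots": observer.n_eff_dots,
            "criterion_c": observer.criterion_c,
            "conf_noise": observer.conf_noise,
            "cue_variance_c_shift": observer.cue_variance_c_shift.tolist(),
            "cue_variance_conf_shift": observer.cue_variance_conf_shift.tolist(),
        },
        "physio": {
            "pupil_amp": physio.pupil_amp,
            "pupil_betas": physio.pupil_betas,
            "pupil_noise_sd": physio.pupil_noise_sd,
            "hr_amp": physio.hr_amp,
            "hr_betas": physio.hr_betas,
            "hr_noise_sd": physio.hr_noise_sd,
            "baseline_hr": physio.baseline_hr,
        },
        "staircase": dataclasses.asdict(staircase),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    config.to_yaml(out / "config.yaml")
    return out


def generate_experiment(
    out_dir: str | Path,
    n_subjects: int = 5,
    n_trials: int = 640,
    observer: dict | None = None,
    physio: dict | None = None,
    seed: int = 0,
    **config_kwargs,
) -> Path:
    """Generate a complete synthetic experiment (behaviour + physiology).

    Convenience wrapper building a :class:`RunConfig` and calling
    :func:`run_simulate`.
    """
    config = RunConfig(
        seed=seed, n_subjects=n_subjects, n_trials=n_trials,
        observer=observer or {}, physio=physio or {}, **config_kwargs,
    )
    return run_simulate(config, out_dir)


def _analyze_subject_physio(config: RunConfig, data_dir: Path, k: int, trials_kept: pd.DataFrame):
    """Per-subject physiological chain -> (pupil betas, hr betas, times, report)."""
    pp = config.pupil_preproc
    report: dict = {}

    pupil_df = pd.read_csv(data_dir / f"pupil_sub{k}.csv")
    fs = 1.0 / float(np.median(np.diff(pupil_df["time_s"].to_numpy())))
    raw = PhysioTimeSeries(
        pupil_df["pupil_au"].to_numpy(), fs=fs,
        t0=float(pupil_df["time_s"].iloc[0]), channel="pupil_au",
    )
    cleaned, mask = detect_blinks_and_interpolate(raw, threshold=pp["blink_threshold"])
    onsets = trials_kept["onset_s"].to_numpy(dtype=float)
    epochs = epoch_and_baseline(cleaned, onsets, PUPIL_WINDOW, PUPIL_BASELINE)
    fracs = blink_fraction_per_trial(mask, epochs, t0=raw.t0, onsets=onsets)
    proc = PupilPreprocessor(
        lowpass_hz=pp["lowpass_hz"],
        derivative_sd=pp["derivative_sd"],
        blink_reject_fraction=pp["blink_reject_fraction"],
    )
    epochs = proc.fit(epochs).transform(epochs, blink_fractions=fracs)
    report["pupil"] = epochs.rejection_report()

    ok = ~epochs.rejected
    design = glm_mod.build_design_matrix(
        trials_kept[ok.tolist()], include_cue_by_noise=config.glm["include_cue_by_noise"]
    )
    fitter = glm_mod.TrialwiseGLM().fit(design.values, epochs.data[ok])
    pupil_betas = fitter.coef_
    pupil_times = epochs.times_ms

    rp = pd.read_csv(data_dir / f"rpeaks_sub{k}.csv")["rpeak_time_s"].to_numpy()
    cardiac = compute_instantaneous_hr(rp, fs_out=10.0)
    hr_epochs = epoch_and_baseline(cardiac.hr_10hz, onsets, HR_WINDOW, HR_BASELINE)
    report["hr"] = hr_epochs.rejection_report()
    ok_hr = ~hr_epochs.rejected
    design_hr = glm_mod.build_design_matrix(
        trials_kept[ok_hr.tolist()], include_cue_by_noise=config.glm["include_cue_by_noise"]
    )
    fitter_hr = glm_mod.TrialwiseGLM().fit(design_hr.values, hr_epochs.data[ok_hr])
    hr_betas = fitter_hr.coef_
    hr_times = hr_epochs.times_ms
    columns = design.columns
    return pupil_betas, pupil_times, hr_betas, hr_times, columns, report


def _cluster_table(betas: np.ndarray, times: np.ndarray, columns: list[str], cfg: dict, seed: int) -> pd.DataFrame:
    rows = []
    for j, name in enumerate(columns):
        if name == "intercept":
            continue
        res = glm_mod.group_cluster_permutation(
            betas[:, j, :], name, times_ms=times,
            t_height=cfg["t_height"], n_perm=cfg["n_perm"],
            cluster_alpha=cfg["cluster_alpha"], statistic=cfg["statistic"],
            random_state=seed,
        )
        for c in res.clusters:
            rows.append(
                dict(
                    regressor=name, sign=c.sign, start_ms=c.start_ms, end_ms=c.end_ms,
                    extent=c.extent, mass=c.mass, p_perm=c.p_perm,
                    peak_beta=c.peak_beta, peak_ms=c.peak_ms,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["regressor", "sign", "start_ms", "end_ms", "extent", "mass",
                 "p_perm", "peak_beta", "peak_ms"],
    )


def run_analyze(config: RunConfig, data_dir: str | Path, out_dir: str | Path) -> Path:
    """Run the full analysis chain on a dataset directory."""
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    excl = config.exclusions

    trials_by_subject: dict[int, pd.DataFrame] = {}
    exclusion_reports: dict[int, dict] = {}
    for k in range(config.n_subjects):
        path = data_dir / f"trials_sub{k}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing trial file: {path}")
        trials = pd.read_csv(path)
        kept, report = apply_exclusions(
            trials,
            burn_in_fraction=excl.get("burn_in_fraction"),
            burn_in_blocks=excl.get("burn_in_blocks"),
            rt_z_threshold=excl.get("rt_z_threshold", 3.0),
        )
        trials_by_subject[k] = kept.reset_index(drop=True)
        exclusion_reports[k] = report.as_dict()

    behaviour = condition_parameter_table(
        trials_by_subject, m_bias_definition=config.m_bias_definition
    )
    behaviour.to_csv(out / "behaviour_table.csv", index=False)

    anovas: dict[str, dict] = {}
    if config.n_subjects >= 3:
        for param in ("d_prime", "c", "m_ratio", "m_bias"):
            wide = behaviour.pivot_table(
                index="subject", columns=["cue", "variance"], values=param
            )
            cells = pd.DataFrame(
                {
                    "NL": wide[("neutral", "low")],
                    "NH": wide[("neutral", "high")],
                    "DL": wide[("disgust", "low")],
                    "DH": wide[("disgust", "high")],
                }
            ).dropna()
            if len(cells) >= 3:
                anovas[param] = rm_anova_2x2(cells)
    (out / "anova_results.json").write_text(json.dumps(anovas, indent=2, default=str))

    cluster_tables: dict[str, pd.DataFrame] = {}
    physio_reports: dict[int, dict] = {}
    have_physio = (data_dir / "pupil_sub0.csv").exists()
    if have_physio:
        pupil_stack, hr_stack, columns = [], [], None
        pupil_times = hr_times = None
        for k in range(config.n_subjects):
            try:
                pb, pt, hb, ht, cols, rep = _analyze_subject_physio(
                    config, data_dir, k, trials_by_subject[k]
                )
            except Exception as e:  # pragma: no cover - subject-level tolerance
                logger.warning("subject %d dropped from physio analysis: %s", k, e)
                physio_reports[k] = {"dropped": str(e)}
                continue
            pupil_stack.append(pb)
            hr_stack.append(hb)
            pupil_times, hr_times, columns = pt, ht, cols
            physio_reports[k] = rep
        if len(pupil_stack) >= 5:
            pupil_betas = np.stack(pupil_stack)  # (subj, regressors, times)
            hr_betas = np.stack(hr_stack)
            cluster_tables["pupil"] = _cluster_table(
                pupil_betas, pupil_times, columns, config.glm, config.seed
            )
            cluster_tables["hr"] = _cluster_table(
                hr_betas, hr_times, columns, config.glm, config.seed
            )
            for name, table in cluster_tables.items():
                table.to_csv(out / f"clusters_{name}.csv", index=False)
            np.savetxt(
                out / "group_mean_beta_pupil.csv",
                pupil_betas.mean(axis=0), delimiter=",",
            )
            _plot_grand_means(out, pupil_betas, pupil_times, hr_betas, hr_times)
        else:
            logger.warning("fewer than 5 subjects with physio: cluster tests skipped")

    provenance = {
        "config": dataclasses.asdict(config),
        "exclusions": exclusion_reports,
        "physio_preprocessing": physio_reports,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    _write_report(out, config, exclusion_reports, behaviour, anovas, cluster_tables,
                  data_dir)
    return out


def _plot_grand_means(out, pupil_betas, pupil_times, hr_betas, hr_times):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 3.5))
    axes[0].plot(pupil_times, pupil_betas.mean(axis=0)[0])
    axes[0].set(title="Grand-mean evoked pupil response", xlabel="time (ms)",
                ylabel="pupil (a.u., baseline-corrected)")
    axes[1].plot(hr_times, hr_betas.mean(axis=0)[0])
    axes[1].set(title="Grand-mean evoked heart rate", xlabel="time (ms)",
                ylabel="HR (bpm, baseline-corrected)")
    fig.tight_layout()
    fig.savefig(out / "grand_mean_responses.png", dpi=100)
    plt.close(fig)


def _write_report(out, config, exclusions, behaviour, anovas, cluster_tables, data_dir):
    lines = ["# metaphysio analysis report", ""]
    lines += ["## Exclusions", ""]
    for k, rep in exclusions.items():
        lines.append(
            f"- subject {k}: {rep['n_kept']}/{rep['n_input']} kept "
            f"(burn-in {rep['n_burn_in']}, missed {rep['n_missed']}, "
            f"RT outliers {rep['n_rt_outlier']})"
        )
    lines += ["", "## Behaviour (condition means across subjects)", ""]
    summary = behaviour.groupby(["cue", "variance"])[
        ["d_prime", "c", "m_ratio", "m_bias"]
    ].mean()
    lines.append(summary.round(3).to_markdown())
    lines += ["", "## 2x2 repeated-measures ANOVAs", ""]
    for param, res in anovas.items():
        inter = res["interaction"]
        lines.append(
            f"- {param}: interaction F(1,{inter['df'][1]}) = {inter['F']:.2f}, "
            f"p = {inter['p']:.3f}"
        )
    for name, table in cluster_tables.items():
        lines += ["", f"## Significant {name} clusters", ""]
        sig = table[table["p_perm"] <= config.glm["cluster_alpha"]]
        lines.append(sig.round(3).to_markdown(index=False) if len(sig) else "(none)")
    truth_path = Path(data_dir) / "ground_truth.json"
    if truth_path.exists() and cluster_tables:
        truth = json.loads(truth_path.read_text())
        lines += ["", "## Ground-truth recovery", ""]
        for signal_name, key in (("pupil", "pupil_betas"), ("hr", "hr_betas")):
            betas = truth["physio"].get(key, {})
            table = cluster_tables.get(signal_name)
            if table is None:
                continue
            for reg, injected in betas.items():
                sig = table[(table["regressor"] == reg) & (table["p_perm"] <= 0.05)]
                found = "detected" if len(sig) else "not detected"
                sign_ok = ""
                if len(sig):
                    sign_ok = (
                        " (sign matches)"
                        if np.sign(sig["peak_beta"].iloc[0]) == np.sign(injected)
                        else " (sign mismatch)"
                    )
                lines.append(f"- {signal_name} {reg}: injected {injected:+.2f}, {found}{sign_ok}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
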