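"""End-to-end analysis: simulate -> preprocess -> ERP + spectral -> stats.

The pipeline mirrors the study's Experiment-4 analysis. After amplitude
rejection (voltage domain) and the surface Laplacian, the data forks into
two branches: the ERP branch is band-pass filtered (0.05-25 Hz) and
baselined to the 200 ms before target onset, while the spectral branch
decomposes the unfiltered CSD signal with Morlet wavelets. Pre-target
alpha-band (8-14 Hz) percent-change time courses feed a cluster-corrected
permutation test per hemisphere; window-averaged alpha and P1 amplitudes
feed 2x2 (condition x hemisphere) repeated-measures ANOVAs, paired simple
effects, and across-subject Spearman correlations between the alpha and P1
condition effects with bootstrap confidence intervals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import erp as erp_mod
from . import preprocess as pre
from . import spectral as spec_mod
from . import stats as stats_mod
from .epochs import EpochSet
from .errors import AlphaP1Error, ConfigError
from .synthetic import (
    TRAINED,
    UNTRAINED,
    GroundTruth,
    SimConfig,
    draw_subject_effects,
    generate_subject,
)

HEMISPHERES = ("left_posterior", "right_posterior")


@dataclass
class PipelineConfig:
    """Everything needed to rerun an analysis from scratch."""

    sim: SimConfig = field(default_factory=SimConfig)
    reject_threshold: float = 75.0  # uV
    bad_channels: tuple[str, ...] = ()
    filter_band: tuple[float, float] = (0.05, 25.0)
    filter_order: int = 1
    spline_m: int = 4
    spline_lambda: float = 1e-5
    spline_n_legendre: int = 50
    p1_search: tuple[float, float] = (70.0, 150.0)  # ms post-target
    p1_half_window: float = 15.0  # ms (30 ms window total)
    band: tuple[float, float] = (8.0, 14.0)  # Hz
    pretarget_window: tuple[float, float] = (-500.0, 0.0)  # ms rel. target
    erp_baseline: tuple[float, float] = (-200.0, 0.0)  # ms rel. target
    tfr_baseline: tuple[float, float] = (-400.0, -100.0)  # ms rel. cue
    n_perm: int = 10_000
    n_boot: int = 20_000
    alpha: float = 0.05
    stats_seed: int = 0
    spectral_channels: str = "groups"  # "groups" | "all"
    spectral_freqs: str = "band"  # "band" | "full"
    spectral_dtype: str = "float32"  # working precision of the power tensors

    def config_hash(self) -> str:
        blob = json.dumps(_serialize(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in sim.items()})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(payload)


def _serialize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {}
        for f in dataclasses.fields(obj):
            if f.name == "montage":
                mont = getattr(obj, f.name)
                out["montage_channels"] = list(mont.names)
                continue
            out[f.name] = _serialize(getattr(obj, f.name))
        return out
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, list)):
        return [_serialize(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class RunReport:
    config_hash: str
    trial_counts: pd.DataFrame  # subject, n_total, n_kept
    p1_peak_latency_ms: float
    p1_window: tuple[float, float]
    p1_amplitudes: pd.DataFrame  # subject, hemisphere, condition, amplitude
    alpha_pretarget: pd.DataFrame  # subject, hemisphere, condition, power_pct
    alpha_times_rel_target: np.ndarray
    alpha_timecourses: dict  # hemisphere -> condition -> (n_subjects, T)
    cluster_results: dict  # hemisphere -> ClusterTestResult
    anova_alpha: pd.DataFrame
    anova_p1: pd.DataFrame
    simple_effects: pd.DataFrame  # measure, hemisphere, t, df, p, ci
    correlations: dict  # hemisphere -> SpearmanBootstrapResult
    correlation_difference: stats_mod.CorrelationDifferenceResult | None
    effect_table: pd.DataFrame  # subject, alpha_mod_left/right, p1_mod_left/right
    ground_truth: dict | None
    stage_log: list

    def summary_dict(self) -> dict:
        out = {
            "config_hash": self.config_hash,
            "p1_peak_latency_ms": self.p1_peak_latency_ms,
            "p1_window_ms": list(self.p1_window),
            "clusters": {h: r.to_dict() for h, r in self.cluster_results.items()},
            "anova_alpha": self.anova_alpha.to_dict(orient="records"),
            "anova_p1": self.anova_p1.to_dict(orient="records"),
            "simple_effects": self.simple_effects.to_dict(orient="records"),
            "correlations": {
                h: {"rho": r.rho, "p": r.p, "ci": [r.ci_low, r.ci_high]}
                for h, r in self.correlations.items()
            },
        }
        if self.correlation_difference is not None:
            cd = self.correlation_difference
            out["correlation_difference"] = {
                "delta_rho": cd.delta_rho, "p": cd.p, "ci": [cd.ci_low, cd.ci_high],
            }
        if self.ground_truth is not None:
            out["ground_truth"] = self.ground_truth
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2)


# --- per-subject stages ---------------------------------------------------


def preprocess_subject(epochs: EpochSet, cfg: PipelineConfig
                       ) -> tuple[EpochSet, pd.DataFrame]:
    """Rejection (uV domain) -> bad-channel interpolation -> Laplacian."""
    kept, log = pre.reject_epochs(epochs, cfg.reject_threshold)
    if cfg.bad_channels:
        kept = pre.interpolate_channels(kept, list(cfg.bad_channels),
                                        m=cfg.spline_m, lam=cfg.spline_lambda,
                                        n_legendre=cfg.spline_n_legendre)
    csd = pre.apply_laplacian(kept, m=cfg.spline_m, lam=cfg.spline_lambda,
                              n_legendre=cfg.spline_n_legendre)
    return csd, log


def erp_branch(csd: EpochSet, cfg: PipelineConfig) -> dict:
    """Filtered + baselined condition-average waveforms per hemisphere.

    Filtering is per-channel, so restricting to the ROI channels first is
    exact for the group-mean waveforms and much cheaper.
    """
    roi = [ch for hemi in HEMISPHERES for ch in csd.montage.groups[hemi]]
    csd = csd.select_channels(roi)
    filtered = pre.bandpass_filter(csd, *cfg.filter_band, order=cfg.filter_order)
    based = pre.baseline_subtract(filtered, cfg.erp_baseline, "target")
    waves = {}
    for hemi in HEMISPHERES:
        waves[hemi] = {
            cond: erp_mod.average_erp(based, hemi, cond)
            for cond in (TRAINED, UNTRAINED)
        }
        waves[hemi]["pooled"] = erp_mod.average_erp(based, hemi, None)
    return waves


def _spectral_family(cfg: PipelineConfig, sfreq: float) -> spec_mod.WaveletFamily:
    family = spec_mod.build_family(sfreq=sfreq)
    if cfg.spectral_freqs == "full":
        return family
    fidx = spec_mod.band_frequencies(family.freqs, cfg.band)
    return spec_mod.WaveletFamily(
        freqs=family.freqs[fidx], cycles=family.cycles[fidx], sfreq=family.sfreq,
        kernels=tuple(family.kernels[i] for i in fidx),
    )


def spectral_branch(csd: EpochSet, cfg: PipelineConfig,
                    family: spec_mod.WaveletFamily) -> dict:
    """Alpha-band percent-change time courses and pre-target means."""
    if cfg.spectral_channels == "all":
        channels = None
    else:
        channels = [ch for hemi in HEMISPHERES
                    for ch in csd.montage.groups[hemi]]
    tfr = spec_mod.decompose(csd, family, channels=channels,
                             dtype=np.dtype(cfg.spectral_dtype))
    pct = spec_mod.percent_change(tfr, cfg.tfr_baseline)
    clean = spec_mod.band_clean_mask(pct, cfg.band)
    t_rel = pct.times_rel_target()
    out = {"times_rel_target": t_rel, "clean": clean}
    for hemi in HEMISPHERES:
        tc = spec_mod.band_timecourse(pct, list(csd.montage.groups[hemi]), cfg.band)
        cond_means = {}
        pre_means = {}
        for cond in (TRAINED, UNTRAINED):
            sel = csd.condition_mask(cond)
            course = tc[sel].mean(axis=0)
            cond_means[cond] = course
            pre_means[cond] = float(spec_mod.window_mean(
                course[None, :], t_rel, cfg.pretarget_window, clean_mask=clean)[0])
        out[hemi] = {"timecourse": cond_means, "pretarget_mean": pre_means}
    return out


# --- cohort-level analysis ------------------------------------------------


def analyze_cohort(cohort: list[EpochSet], cfg: PipelineConfig,
                   ground_truth=None) -> RunReport:
    """Run the full analysis on an already-generated cohort."""
    t0 = time.perf_counter()
    stage_log = []
    n_sub = len(cohort)
    if n_sub < 2:
        raise ConfigError("cohort analysis needs at least 2 subjects")

    family = _spectral_family(cfg, cohort[0].sfreq)
    counts, erp_waves, spec_results = [], [], []
    for s, epochs in enumerate(cohort):
        try:
            csd, log = preprocess_subject(epochs, cfg)
            erp_waves.append(erp_branch(csd, cfg))
            spec_results.append(spectral_branch(csd, cfg, family))
        except AlphaP1Error as exc:
            raise type(exc)(f"subject {s}: {exc}") from exc
        counts.append((s, epochs.n_trials, int(log["kept"].sum())))
        stage_log.append({"stage": "subject", "subject": s,
                          "trials_in": epochs.n_trials,
                          "trials_out": int(log["kept"].sum())})
    trial_counts = pd.DataFrame(counts, columns=["subject", "n_total", "n_kept"])

    # grand-average P1 peak: pooled conditions, both hemispheres, all subjects
    times_rt = cohort[0].times_rel_target()
    grand = np.mean([w[h]["pooled"] for w in erp_waves for h in HEMISPHERES], axis=0)
    peak = erp_mod.find_grand_peak(grand, times_rt, cfg.p1_search)
    p1_window = (peak - cfg.p1_half_window, peak + cfg.p1_half_window)
    win_mask = (times_rt >= p1_window[0] - 1e-9) & (times_rt <= p1_window[1] + 1e-9)

    p1_rows, alpha_rows = [], []
    for s in range(n_sub):
        for hemi in HEMISPHERES:
            for cond in (TRAINED, UNTRAINED):
                p1_rows.append((s, hemi, cond,
                                float(erp_waves[s][hemi][cond][win_mask].mean())))
                alpha_rows.append((s, hemi, cond,
                                   spec_results[s][hemi]["pretarget_mean"][cond]))
    p1_amp = pd.DataFrame(p1_rows, columns=["subject", "hemisphere", "condition",
                                            "amplitude"])
    alpha_pre = pd.DataFrame(alpha_rows, columns=["subject", "hemisphere",
                                                  "condition", "power_pct"])

    # restrict alpha time courses to the pre-target window for the cluster test
    t_rel = spec_results[0]["times_rel_target"]
    lo, hi = cfg.pretarget_window
    tc_mask = (t_rel >= lo - 1e-9) & (t_rel <= hi + 1e-9)
    alpha_times = t_rel[tc_mask]
    timecourses, cluster_results = {}, {}
    rng = np.random.default_rng([cfg.stats_seed, 7])
    for hemi in HEMISPHERES:
        tc = {cond: np.stack([spec_results[s][hemi]["timecourse"][cond][tc_mask]
                              for s in range(n_sub)])
              for cond in (TRAINED, UNTRAINED)}
        timecourses[hemi] = tc
        cluster_results[hemi] = stats_mod.cluster_permutation_paired(
            tc[TRAINED], tc[UNTRAINED], alpha_times, n_perm=cfg.n_perm,
            alpha=cfg.alpha, seed=int(rng.integers(2**31)))
        stage_log.append({"stage": "cluster_test", "hemisphere": hemi,
                          "n_perm": cfg.n_perm})

    def _cell(df, value):
        return np.stack([
            df[(df.hemisphere == h) & (df.condition == c)]
            .sort_values("subject")[value].to_numpy()
            for h in HEMISPHERES for c in (TRAINED, UNTRAINED)
        ], axis=-1).reshape(n_sub, 2, 2)

    # (n, hemisphere, condition) cells; factor A = condition, B = hemisphere
    alpha_cells = _cell(alpha_pre, "power_pct").transpose(0, 2, 1)
    p1_cells = _cell(p1_amp, "amplitude").transpose(0, 2, 1)
    anova_alpha = stats_mod.rm_anova_2x2(alpha_cells).assign(measure="alpha")
    anova_p1 = stats_mod.rm_anova_2x2(p1_cells).assign(measure="p1")

    se_rows = []
    eff = {"subject": np.arange(n_sub)}
    for mi, (measure, cells) in enumerate((("alpha", alpha_cells),
                                           ("p1", p1_cells))):
        for hi_, hemi in enumerate(HEMISPHERES):
            tt = stats_mod.paired_t(cells[:, 0, hi_], cells[:, 1, hi_])
            se_rows.append((measure, hemi, tt.t, tt.df, tt.p, tt.mean_diff,
                            tt.ci_low, tt.ci_high))
            eff[f"{measure}_mod_{hemi}"] = cells[:, 0, hi_] - cells[:, 1, hi_]
    simple_effects = pd.DataFrame(se_rows, columns=["measure", "hemisphere", "t",
                                                    "df", "p", "mean_diff",
                                                    "ci_low", "ci_high"])
    effect_table = pd.DataFrame(eff)

    correlations = {}
    for hemi in HEMISPHERES:
        correlations[hemi] = stats_mod.spearman_bootstrap(
            effect_table[f"alpha_mod_{hemi}"].to_numpy(),
            effect_table[f"p1_mod_{hemi}"].to_numpy(),
            n_boot=cfg.n_boot, seed=int(rng.integers(2**31)))
    corr_diff = stats_mod.correlation_difference(
        effect_table["alpha_mod_left_posterior"].to_numpy(),
        effect_table["p1_mod_left_posterior"].to_numpy(),
        effect_table["p1_mod_right_posterior"].to_numpy(),
        n_boot=cfg.n_boot, seed=int(rng.integers(2**31)))

    gt_block = None
    if ground_truth is not None:
        true_a = ground_truth.effects["true_alpha_effect"].to_numpy()
        true_p = ground_truth.effects["true_p1_effect"].to_numpy()
        gt_block = {
            "true_effect_pearson": float(np.corrcoef(true_a, true_p)[0, 1])
            if np.ptp(true_a) > 0 and np.ptp(true_p) > 0 else None,
            "recovered_alpha_vs_true_rho": float(
                sps.spearmanr(true_a,
                              effect_table["alpha_mod_left_posterior"])[0]),
            "recovered_p1_vs_true_rho": float(
                sps.spearmanr(true_p,
                              effect_table["p1_mod_left_posterior"])[0]),
        }
    stage_log.append({"stage": "done", "wall_s": round(time.perf_counter() - t0, 3)})

    return RunReport(
        config_hash=cfg.config_hash(), trial_counts=trial_counts,
        p1_peak_latency_ms=peak, p1_window=p1_window, p1_amplitudes=p1_amp,
        alpha_pretarget=alpha_pre, alpha_times_rel_target=alpha_times,
        alpha_timecourses=timecourses, cluster_results=cluster_results,
        anova_alpha=anova_alpha, anova_p1=anova_p1,
        simple_effects=simple_effects, correlations=correlations,
        correlation_difference=corr_diff, effect_table=effect_table,
        ground_truth=gt_block, stage_log=stage_log,
    )


def run(cfg: PipelineConfig, outdir=None) -> RunReport:
    """Generate the configured cohort, analyze it, and optionally persist."""
    effects = draw_subject_effects(cfg.sim)
    cohort = []
    flags = {}
    for s in range(cfg.sim.n_subjects):
        epochs, fl = generate_subject(cfg.sim, s, effects=effects)
        cohort.append(epochs)
        flags[s] = fl
    gt = GroundTruth(effects=effects, artifact_flags=flags, seed=cfg.sim.seed)
    report = analyze_cohort(cohort, cfg, ground_truth=gt)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gt.to_csv(outdir / "ground_truth.csv")
        report.trial_counts.to_csv(outdir / "trial_counts.csv", index=False)
        report.p1_amplitudes.to_csv(outdir / "p1_amplitudes.csv", index=False)
        report.alpha_pretarget.to_csv(outdir / "alpha_pretarget.csv", index=False)
        report.effect_table.to_csv(outdir / "subject_effects.csv", index=False)
        _timecourse_table(report).to_csv(outdir / "alpha_timecourses.csv",
                                         index=False)
        report.to_json(outdir / "report.json")
    return report


def _timecourse_table(report: RunReport) -> pd.DataFrame:
    rows = []
    for hemi, tc in report.alpha_timecourses.items():
        for cond, arr in tc.items():
            for s in range(arr.shape[0]):
                for ti, t in enumerate(report.alpha_times_rel_target):
                    rows.append((s, hemi, cond, float(t), float(arr[s, ti])))
    return pd.DataFrame(rows, columns=["subject", "hemisphere", "condition",
                                       "time_ms", "value"])
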