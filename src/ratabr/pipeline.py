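"""End-to-end orchestration: simulate → extract → quantify → test → report.

``run(config)`` produces the full artifact bundle of an age-related hearing
loss analysis on a synthetic cohort: the thresholds table with per-frequency
ANOVAs and threshold shifts, per-wave amplitude/latency tables with their
ANOVAs, interpeak latencies, percent-variation summaries, and the
densitometry summary with field-level ANOVAs.  Every output table carries a
provenance header (package version, config hash, seed) and the bundle is
deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abr_features import (
    DEFAULT_ANALYSIS_WINDOW,
    DEFAULT_SEARCH_WINDOWS,
    detect_threshold,
    detect_waves,
    interpeak,
)
from .densitometry import aggregate, quantify_field
from .errors import ConfigurationError, PipelineError
from .group_stats import anova_table, percent_variation, summarize, threshold_shift
from .io import write_table
from .synthetic_data import (
    AgeEffect,
    CohortDataset,
    CohortDesign,
    FieldDesign,
    simulate_cohort,
    simulate_histology_cohort,
)

log = logging.getLogger("ratabr.pipeline")


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run.

    Defaults follow the module-level design choices: whole-trace threshold
    criterion, percentile normalisation, labelled-pixel mean gray.
    """

    seed: int = 0
    out_dir: str = "ratabr-run"
    # ABR cohort
    n_subjects: int = 8
    frequencies: List[float] = field(default_factory=lambda: [0.5, 1, 2, 4, 8, 16, 32])
    noise_sd: float = 0.35
    alpha: float = 0.05
    criterion_mode: str = "whole-trace"      # or "any-wave"
    analysis_window: List[float] = field(default_factory=lambda: list(DEFAULT_ANALYSIS_WINDOW))
    search_windows: Dict[str, List[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_SEARCH_WINDOWS.items()}
    )
    # Densitometry
    include_histology: bool = True
    histology_subjects: int = 8
    sections_per_subject: int = 4
    condition_factors: Dict[str, float] = field(
        default_factory=lambda: {"young": 1.0, "middle": 0.75, "old": 0.5}
    )
    subdivision: str = "AVCN"
    normalize_fields: bool = True
    mean_gray_mode: str = "labeled"          # or "whole-field"
    # Figures are optional artifacts, never canonical output
    figures: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: Optional[Path] = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "PipelineConfig":
        text = str(path_or_text)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Paths of the artifact bundle plus the in-memory tables."""

    out_dir: Path
    tables: Dict[str, pd.DataFrame]
    paths: Dict[str, Path]
    provenance: str


def features_frame(dataset: CohortDataset, config: PipelineConfig) -> pd.DataFrame:
    """Tidy per-wave features at 80 dB SPL for every subject × frequency."""
    windows = {k: tuple(v) for k, v in config.search_windows.items()}
    rows = []
    for (group, subject, freq) in sorted(dataset.series):
        series = dataset.series[(group, subject, freq)]
        rec80 = series.recordings[0]
        waves = detect_waves(rec80, windows)
        ip = interpeak(waves)
        for wf in waves:
            rows.append({
                "subject": subject, "group": group, "freq_khz": freq,
                "intensity_db": rec80.intensity_db, "wave": wf.wave_id,
                "amplitude_uV": wf.amplitude,
                "pos_latency_ms": round(wf.positive_latency, 2),
                "neg_latency_ms": round(wf.negative_latency, 2),
            })
        for name, val in (
            ("PI-PII", ip.PI_PII), ("PII-PIV", ip.PII_PIV), ("PI-PIV", ip.PI_PIV),
            ("NI-NII", ip.NI_NII), ("NII-NIV", ip.NII_NIV), ("NI-NIV", ip.NI_NIV),
        ):
            rows.append({
                "subject": subject, "group": group, "freq_khz": freq,
                "intensity_db": rec80.intensity_db, "wave": name,
                "amplitude_uV": np.nan,
                "pos_latency_ms": np.nan if val is None else round(val, 2),
                "neg_latency_ms": np.nan,
            })
    return pd.DataFrame(rows)


def thresholds_frame(dataset: CohortDataset, config: PipelineConfig) -> pd.DataFrame:
    """Detected thresholds per subject × frequency, joined with ground truth."""
    windows = {k: tuple(v) for k, v in config.search_windows.items()}
    rows = []
    for (group, subject, freq) in sorted(dataset.series):
        res = detect_threshold(
            dataset.series[(group, subject, freq)],
            analysis_window=tuple(config.analysis_window),
            criterion_mode=config.criterion_mode,
            search_windows=windows,
        )
        rows.append({
            "subject": subject, "group": group, "freq_khz": freq,
            "threshold_db": np.nan if res.threshold is None else res.threshold,
            "no_response": res.threshold is None,
        })
    df = pd.DataFrame(rows)
    return df.merge(dataset.truth, on=["group", "subject", "freq_khz"], how="left")


def threshold_shift_table(thresholds: pd.DataFrame, reference: str = "young") -> pd.DataFrame:
    """Per-frequency group means ± SD and shifts relative to the reference group."""
    rows = []
    for freq, sub in thresholds.groupby("freq_khz"):
        summaries = {
            g: summarize(vals["threshold_db"].dropna(), label=g, metric=f"threshold@{freq}")
            for g, vals in sub.groupby("group")
            if vals["threshold_db"].notna().sum() >= 2
        }
        ref = summaries.get(reference)
        for g, s in sorted(summaries.items()):
            rows.append({
                "freq_khz": freq, "group": g, "n": s.n,
                "mean_db": s.mean, "sd_db": s.sd,
                "sem_db": s.sd / np.sqrt(s.n),
                "shift_db": threshold_shift(ref, s) if ref else np.nan,
            })
    return pd.DataFrame(rows)


def percent_variation_table(features: pd.DataFrame, reference: str = "young") -> pd.DataFrame:
    """Percent change of group-mean wave amplitudes relative to the reference."""
    amp = features.dropna(subset=["amplitude_uV"])
    means = (
        amp.groupby(["wave", "freq_khz", "group"])["amplitude_uV"].mean().unstack("group")
    )
    rows = []
    for (wave, freq), r in means.iterrows():
        if reference not in r or np.isnan(r[reference]):
            continue
        for g in r.index:
            if g == reference or np.isnan(r[g]):
                continue
            rows.append({
                "wave": wave, "freq_khz": freq, "group": g,
                "percent_variation": percent_variation(r[reference], r[g]),
            })
    return pd.DataFrame(rows)


def _build_design(config: PipelineConfig) -> CohortDesign:
    freqs = tuple(float(f) for f in config.frequencies)
    groups = [
        (AgeEffect.young(freqs), config.n_subjects),
        (AgeEffect.middle(freqs), config.n_subjects),
        (AgeEffect.old(freqs), config.n_subjects),
    ]
    return CohortDesign(
        groups=groups, frequencies=freqs, noise_sd=config.noise_sd, seed=config.seed
    )


def run(config: PipelineConfig, out_dir: Optional[Path] = None) -> PipelineResult:
    """Run the full pipeline and write the artifact bundle.

    Any stage failure is re-raised as :class:`PipelineError` naming the
    stage.  Outputs are byte-identical across runs with the same (config,
    seed).
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    provenance = f"ratabr v{__version__} config={config.config_hash} seed={config.seed}"
    tables: Dict[str, pd.DataFrame] = {}
    paths: Dict[str, Path] = {}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("simulate")
        try:
            dataset = simulate_cohort(_build_design(config))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("simulate", str(e)) from e

        stage("thresholds")
        try:
            thr = thresholds_frame(dataset, config)
            tables["thresholds"] = thr
            tables["threshold_summary"] = threshold_shift_table(thr)
            anova_thr, posthoc_thr = anova_table(
                thr, value="threshold_db", row_col=None, alpha=config.alpha
            )
            tables["anova_thresholds"] = anova_thr.reset_index()
            tables["posthoc_thresholds"] = posthoc_thr
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("thresholds", str(e)) from e

        stage("features")
        try:
            feats = features_frame(dataset, config)
            tables["features"] = feats
            amp = feats[feats["amplitude_uV"].notna()]
            t3, ph3 = anova_table(amp, value="amplitude_uV", alpha=config.alpha)
            tables["anova_amplitudes"] = t3.reset_index()
            tables["posthoc_amplitudes"] = ph3
            t4p, _ = anova_table(amp, value="pos_latency_ms", alpha=config.alpha)
            t4n, _ = anova_table(amp, value="neg_latency_ms", alpha=config.alpha)
            ipk = feats[feats["amplitude_uV"].isna() & feats["pos_latency_ms"].notna()]
            t4i, _ = anova_table(ipk, value="pos_latency_ms", alpha=config.alpha)
            tables["anova_pos_latencies"] = t4p.reset_index()
            tables["anova_neg_latencies"] = t4n.reset_index()
            tables["anova_interpeak"] = t4i.reset_index()
            tables["percent_variation"] = percent_variation_table(feats)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("features", str(e)) from e

        if config.include_histology:
            stage("densitometry")
            try:
                designs = {
                    g: FieldDesign(condition_factor=cf)
                    for g, cf in config.condition_factors.items()
                }
                cohort = simulate_histology_cohort(
                    designs,
                    n_subjects=config.histology_subjects,
                    sections_per_subject=config.sections_per_subject,
                    subdivision=config.subdivision,
                    seed=config.seed,
                )
                results = [
                    quantify_field(
                        f, normalize=config.normalize_fields,
                        mean_gray_mode=config.mean_gray_mode,
                    )
                    for f in cohort.fields
                ]
                agg = aggregate(results)
                tables["densitometry_fields"] = agg["fields"]
                tables["densitometry_subjects"] = agg["subjects"]
                tables["densitometry_groups"] = agg["groups"]
                tables["densitometry_truth"] = cohort.truth
                ta, pa = anova_table(
                    agg["fields"], value="labeled_area_px",
                    row_col=None, col_col="subdivision", alpha=config.alpha,
                )
                tg, _ = anova_table(
                    agg["fields"], value="mean_gray",
                    row_col=None, col_col="subdivision", alpha=config.alpha,
                )
                tables["anova_labeled_area"] = ta.reset_index()
                tables["anova_mean_gray"] = tg.reset_index()
                tables["posthoc_labeled_area"] = pa
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001
                raise PipelineError("densitometry", str(e)) from e

        stage("write")
        for name, df in tables.items():
            paths[name] = write_table(df, out / f"{name}.csv", provenance=provenance)
        manifest = {
            "provenance": provenance,
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash,
            "tables": sorted(tables),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        config.to_yaml(out / "config.yaml")

        if config.figures:
            stage("figures")
            try:
                _make_figures(tables, out)
            except Exception as e:  # noqa: BLE001
                raise PipelineError("figures", str(e)) from e
    finally:
        log.removeHandler(handler)
        handler.close()

    return PipelineResult(out_dir=out, tables=tables, paths=paths, provenance=provenance)


def _make_figures(tables: Dict[str, pd.DataFrame], out: Path) -> None:
    """Optional PNG figures (threshold audiogram, amplitude-by-frequency)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    summ = tables.get("threshold_summary")
    if summ is not None and not summ.empty:
        fig, ax = plt.subplots(figsize=(5, 4))
        for g, sub in summ.groupby("group"):
            ax.errorbar(sub["freq_khz"], sub["mean_db"], yerr=sub["sd_db"],
                        marker="o", capsize=3, label=g)
        ax.set_xscale("log", base=2)
        ax.set_xlabel("Frequency (kHz)")
        ax.set_ylabel("Threshold (dB SPL)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / "thresholds.png", dpi=120)
        plt.close(fig)
    feats = tables.get("features")
    if feats is not None and not feats.empty:
        amp = feats[feats["amplitude_uV"].notna()]
        waves = [w for w in ["I", "II", "III", "IV", "V"] if (amp["wave"] == w).any()]
        fig, axes = plt.subplots(1, len(waves), figsize=(3 * len(waves), 3), sharey=True)
        for ax, w in zip(np.atleast_1d(axes), waves):
            sub = amp[amp["wave"] == w]
            for g, gs in sub.groupby("group"):
                m = gs.groupby("freq_khz")["amplitude_uV"].mean()
                ax.plot(m.index, m.values, marker="o", label=g)
            ax.set_xscale("log", base=2)
            ax.set_title(f"wave {w}")
        np.atleast_1d(axes)[0].set_ylabel("Amplitude (μV)")
        np.atleast_1d(axes)[-1].legend()
        fig.tight_layout()
        fig.savefig(figdir / "amplitudes.png", dpi=120)
        plt.close(fig)
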