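"""End-to-end orchestration: simulate -> preprocess -> envelope/burst ->
spectra -> canonical discriminant analysis -> statistics.

One :class:`PipelineConfig` drives everything.  Defaults equal the
analysis parameters of the study design wherever one is stated: 1 kHz
sampling, 60 Hz comb, order-12 / 2 dB / 1-200 Hz band-pass, 50-sample
RMS envelope window, 0.5% sliding window with 20% overlap, sub-bands
{[0,4), [4,10)} Hz on the envelope channel and {[1,60), [60,200)} Hz on
the burst channel, alpha = 5%, five animals per group.

Outputs are plain CSV/JSON artifacts; everything numeric is a pure
function of (config, seed), so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cda import (
    CLASS_ORDER,
    CDAModel,
    CentroidGeometry,
    DistanceContraction,
    build_feature_matrix,
    centroid_geometry,
    dimension_test,
    distance_contraction,
    fit_cda,
)
from .envelope import rms_envelope, hilbert_envelope
from .errors import ConfigError, StageError
from .preprocess import bandpass, comb_notch, resample
from .simulate import CONDITIONS, GROUPS, NERVES, Recording, default_config, generate_recording
from .spectral import (
    BURST_BANDS,
    ENVELOPE_BANDS,
    BandDefinition,
    PSDSet,
    Spectrogram,
    SpectralWindowing,
    band_power,
    mean_psd,
    sliding_psd,
)
from .stats import ComparisonDesign, compare_groups
from dataclasses import replace as dc_replace

log = logging.getLogger("snapipe.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    n_animals: int = 5
    duration: float = 600.0
    fs: float = 1000.0
    groups: tuple[str, ...] = GROUPS
    nerves: tuple[str, ...] = NERVES
    conditions: tuple[str, ...] = CONDITIONS
    convergence: float = 1.0
    windowing: SpectralWindowing = SpectralWindowing()
    envelope_method: str = "rms"  # 'rms' | 'hilbert'
    rms_window: int = 50
    envelope_range: tuple[float, float] = (0.0, 10.0)
    burst_range: tuple[float, float] = (1.0, 200.0)
    cda_k: int = 3
    cda_transform: str = "log10"
    alpha: float = 0.05
    paired: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @staticmethod
    def from_dict(payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        if "windowing" in payload and isinstance(payload["windowing"], dict):
            payload["windowing"] = SpectralWindowing(**payload["windowing"])
        for key in ("groups", "nerves", "conditions", "envelope_range", "burst_range"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        return PipelineConfig(**payload)

    @staticmethod
    def from_file(path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return PipelineConfig.from_dict(payload)


@dataclass
class ConditionAnalysis:
    """CDA artifacts for one (condition, channel) cell."""

    model: CDAModel
    wilks: pd.DataFrame
    geometry: CentroidGeometry


@dataclass
class AnalysisReport:
    config: PipelineConfig
    recordings: dict  # (group, nerve, condition) -> list[Recording] (preprocessed)
    spectrograms: list[Spectrogram]
    mean_psds: dict  # (class_label, condition, channel) -> PSDSet
    band_tables: dict[str, pd.DataFrame]  # channel -> band power table with contrasts
    cda: dict  # (condition, channel) -> ConditionAnalysis
    contraction: dict[str, DistanceContraction]  # channel -> BAS/BIC contraction
    out_dir: Path | None = None


def _class_seed(master_seed: int, idx: int) -> int:
    # distinct, stable, and well below 2**31 even for large master seeds
    return (master_seed * 1009 + idx * 104729) % (2**31 - 1)


def simulate_study(config: PipelineConfig) -> dict:
    """Generate the full synthetic study: every (group, nerve, condition) cohort."""
    cohorts = {}
    combos = [
        (g, n, c) for g in config.groups for n in config.nerves for c in config.conditions
    ]
    for idx, (g, nerve, cond) in enumerate(combos):
        base = _class_seed(config.seed, idx)
        recs = []
        for animal in range(1, config.n_animals + 1):
            gc = default_config(
                g,
                nerve,
                cond,
                convergence=config.convergence,
                duration=config.duration,
                fs=config.fs,
                seed=base + animal,
            )
            rec = generate_recording(gc)
            rec.labels = dc_replace(rec.labels, animal_id=animal)
            recs.append(rec)
        cohorts[(g, nerve, cond)] = recs
    return cohorts


def _preprocess_all(cohorts: dict, config: PipelineConfig) -> dict:
    out = {}
    for key, recs in cohorts.items():
        processed = []
        for rec in recs:
            r = resample(rec, 1000.0) if rec.fs != 1000.0 else rec
            r = comb_notch(r)
            r = bandpass(r)
            processed.append(r)
        out[key] = processed
    return out


def _spectra_all(cohorts: dict, config: PipelineConfig) -> list[Spectrogram]:
    sgs = []
    for recs in cohorts.values():
        for rec in recs:
            if config.envelope_method == "rms":
                env = rms_envelope(rec, config.rms_window)
            else:
                env = hilbert_envelope(rec)
            sgs.append(sliding_psd(env, config.windowing, channel="envelope"))
            sgs.append(sliding_psd(rec, config.windowing, channel="burst"))
    return sgs


def _mean_psds(spectrograms: list[Spectrogram]) -> dict:
    keyed: dict = {}
    for sg in spectrograms:
        key = (sg.labels.class_label(), sg.labels.condition, sg.channel)
        keyed.setdefault(key, []).append(sg)
    return {key: mean_psd(sgs) for key, sgs in keyed.items()}


def _band_tables(spectrograms: list[Spectrogram], config: PipelineConfig) -> dict:
    """Per-recording mean band powers with BAS/BIC contrasts per class and band."""
    per_rec: dict = {}
    for sg in spectrograms:
        bands = ENVELOPE_BANDS if sg.channel == "envelope" else BURST_BANDS
        for band in bands:
            key = (sg.channel, sg.labels.class_label(), band.name, sg.labels.condition)
            per_rec.setdefault(key, []).append(float(np.mean(band_power(sg, band))))
    tables = {}
    for channel in ("envelope", "burst"):
        bands = ENVELOPE_BANDS if channel == "envelope" else BURST_BANDS
        rows = []
        for cls in [c for c in CLASS_ORDER]:
            for band in bands:
                bas = per_rec.get((channel, cls, band.name, "BAS"))
                bic = per_rec.get((channel, cls, band.name, "BIC"))
                if bas is None or bic is None:
                    continue
                gate = "nonparametric" if min(len(bas), len(bic)) < 3 else None
                design = ComparisonDesign(
                    alpha=config.alpha, paired=config.paired, force_gate=gate
                )
                res = compare_groups({"BAS": bas, "BIC": bic}, design)
                rows.append(
                    {
                        "class": cls,
                        "band": band.name,
                        "mean_bas": float(np.mean(bas)),
                        "mean_bic": float(np.mean(bic)),
                        "test": res.test_name,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "significant": res.significant,
                    }
                )
        tables[channel] = pd.DataFrame(rows)
    return tables


def _cda_analyses(spectrograms: list[Spectrogram], config: PipelineConfig) -> dict:
    analyses = {}
    for channel, frange in (("envelope", config.envelope_range), ("burst", config.burst_range)):
        for cond in config.conditions:
            sgs = [sg for sg in spectrograms if sg.labels.condition == cond]
            fm = build_feature_matrix(sgs, channel, frange, config.cda_transform)
            model = fit_cda(fm, k=config.cda_k)
            wilks = dimension_test(model, alpha=config.alpha)
            geom = centroid_geometry(model, condition_tag=cond)
            analyses[(cond, channel)] = ConditionAnalysis(model, wilks, geom)
    return analyses


def run(config: PipelineConfig, out_dir: str | Path | None = None, plots: bool = False) -> AnalysisReport:
    """Run the full pipeline; write artifacts if ``out_dir`` is given."""
    stages = [
        ("simulate", lambda st: simulate_study(config)),
        ("preprocess", lambda st: _preprocess_all(st["simulate"], config)),
        ("spectra", lambda st: _spectra_all(st["preprocess"], config)),
    ]
    state: dict = {}
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            state[name] = fn(state)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, str(exc)) from exc
        log.info("stage %-10s %6.1f s", name, time.perf_counter() - t0)

    spectrograms = state["spectra"]
    try:
        psds = _mean_psds(spectrograms)
        band_tables = _band_tables(spectrograms, config)
    except Exception as exc:
        raise StageError("band_stats", str(exc)) from exc

    try:
        analyses = _cda_analyses(spectrograms, config)
        contraction = {}
        if "BAS" in config.conditions and "BIC" in config.conditions:
            for channel in ("envelope", "burst"):
                contraction[channel] = distance_contraction(
                    analyses[("BAS", channel)].geometry, analyses[("BIC", channel)].geometry
                )
    except Exception as exc:
        raise StageError("cda", str(exc)) from exc

    report = AnalysisReport(
        config=config,
        recordings=state["preprocess"],
        spectrograms=spectrograms,
        mean_psds=psds,
        band_tables=band_tables,
        cda=analyses,
        contraction=contraction,
    )
    if out_dir is not None:
        report.out_dir = Path(out_dir)
        write_report(report, report.out_dir, plots=plots)
    return report


# ---------------------------------------------------------------------------
# artifact writing


def _df_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def write_report(report: AnalysisReport, out_dir: Path, plots: bool = False) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = report.config

    manifest = {
        "package": "snapipe",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    # group-mean PSDs
    for (cls, cond, channel), psd in report.mean_psds.items():
        df = pd.DataFrame(
            {
                "freq_hz": psd.freqs,
                "mean_power": psd.mean_power,
                "ci_low": psd.ci_low,
                "ci_high": psd.ci_high,
            }
        )
        _df_csv(df, out_dir / f"psd_{channel}_{cond}_{cls}.csv")

    for channel, table in report.band_tables.items():
        _df_csv(table, out_dir / f"band_power_{channel}.csv")

    for (cond, channel), ana in report.cda.items():
        stem = f"cda_{channel}_{cond}"
        scores = pd.DataFrame(
            ana.model.scores, columns=[f"CAN{i + 1}" for i in range(ana.model.k)]
        )
        scores.insert(0, "class", ana.model.labels)
        _df_csv(scores, out_dir / f"{stem}_scores.csv")
        _df_csv(ana.wilks, out_dir / f"{stem}_wilks.csv")
        (out_dir / f"{stem}_eigenvalues.json").write_text(
            json.dumps({"eigenvalues": ana.model.eigenvalues_all.tolist()}, indent=2)
        )
        ana.geometry.distances_df().to_csv(
            out_dir / f"{stem}_centroid_distances.csv", float_format="%.17g"
        )

    for channel, contr in report.contraction.items():
        _df_csv(contr.table, out_dir / f"contraction_{channel}.csv")
        (out_dir / f"contraction_{channel}.json").write_text(
            json.dumps(
                {"max_ratio": contr.max_ratio, "has_infinite": contr.has_infinite}, indent=2
            )
        )

    if plots:
        from . import plotting

        for (cls, cond, channel), psd in report.mean_psds.items():
            fig = plotting.plot_mean_psd(psd, title=f"{channel} {cond} {cls}")
            fig.savefig(out_dir / f"psd_{channel}_{cond}_{cls}.png", dpi=100)
        for (cond, channel), ana in report.cda.items():
            fig = plotting.plot_canonical_scatter(ana.model, title=f"{channel} {cond}")
            fig.savefig(out_dir / f"cda_{channel}_{cond}_scatter.png", dpi=100)
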