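"""End-to-end study analysis: gating, per-sample summaries, time courses.

``run_study`` consumes a study directory produced by the generator (or by an
instrument exporting the same layout: one FCS file per sample plus a
``metadata.csv`` sheet with control-matching columns) and writes the derived
tables: per-sample/per-population summaries, the blister-neutrophil time
course with the paired endotoxin track, population-mean emission spectra with
recovered oxidized fractions (spectral mode), and MB-vs-marker rank
correlation matrices per context.

Population calls are marker-based (Siglec8-high eosinophils are flagged and
excluded from analysis by default; CD66b-high -> neutrophil; CD14-high ->
monocyte/macrophage split on forward scatter; remainder -> lymphocyte), so the
pipeline never sees the generator's latent truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cytometry import (
    ChannelMap,
    DEFAULT_CHANNEL_MAP,
    GateDefinition,
    MIN_FMO_EVENTS,
    classify_mb,
    fmo_threshold,
    geometric_mfi,
    merge_mb_channel,
    read_events,
    redshift_ratio,
    spectral_bin_columns,
    spectral_to_conventional,
)
from .spectra import (
    EmissionSpectrum,
    SpectralModel,
    default_model,
    normalize_spectrum,
    unmix_oxidized_fraction,
)

__all__ = [
    "StudyConfig",
    "classify_populations",
    "summarize_sample",
    "timecourse",
    "compare_redshift_spectra",
    "marker_correlations",
    "sign_agreement",
    "run_study",
]

log = logging.getLogger(__name__)

POPULATION_ORDER = ("neutrophil", "monocyte", "macrophage", "lymphocyte", "eosinophil")


@dataclass(frozen=True)
class StudyConfig:
    """Analysis settings for one study directory."""

    channel_map: ChannelMap = DEFAULT_CHANNEL_MAP
    fmo_percentile: float = 99.5
    min_events_for_stats: int = 20
    #: Red-shift / rho statistics need a real dye-bearing population: the
    #: MB-high fraction must clearly exceed the FMO gate's design
    #: false-positive rate (0.5% at the default percentile), else the "MB-high"
    #: subset is background and its spectrum carries no dye information.
    min_mbhi_fraction: float = 0.02
    exclude_eosinophils: bool = True
    classifier_thresholds: dict = field(default_factory=lambda: {
        "Siglec8": 200.0, "CD66b": 100.0, "CD14": 100.0, "FSC_macrophage": 650.0})
    correlation_method: str = "spearman"
    max_correlation_events: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cmap = ChannelMap(**raw.pop("channel_map")) if "channel_map" in raw else DEFAULT_CHANNEL_MAP
        return cls(channel_map=cmap, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["channel_map"] = asdict(self.channel_map)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def classify_populations(t: pd.DataFrame, config: StudyConfig = StudyConfig()) -> pd.Series:
    """Marker-based population call per event (exhaustive and exclusive)."""
    thr = config.classifier_thresholds
    n = len(t)
    pop = np.full(n, "lymphocyte", dtype=object)
    cd14_hi = t["CD14"].to_numpy() > thr["CD14"]
    pop[cd14_hi & (t["FSC"].to_numpy() <= thr["FSC_macrophage"])] = "monocyte"
    pop[cd14_hi & (t["FSC"].to_numpy() > thr["FSC_macrophage"])] = "macrophage"
    pop[t["CD66b"].to_numpy() > thr["CD66b"]] = "neutrophil"
    pop[t["Siglec8"].to_numpy() > thr["Siglec8"]] = "eosinophil"
    return pd.Series(pop, index=t.index, name="population_call")


def _prepare(t: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Derive conventional channels (spectral mode), merge MB, call populations."""
    if spectral_bin_columns(t):
        t = spectral_to_conventional(t, config.channel_map)
    t = merge_mb_channel(t, config.channel_map)
    t = t.assign(population_call=classify_populations(t, config))
    return t


def _safe_gmfi(values, floor_ok: bool = True) -> float:
    try:
        return geometric_mfi(values)
    except ValueError:
        return float("nan")


def _mean_bin_spectrum(t: pd.DataFrame) -> EmissionSpectrum:
    """Population-mean emission curve on the wavelength-bin centers."""
    bins = spectral_bin_columns(t)
    if not bins:
        raise ValueError("not a spectral-mode table (no wavelength-bin channels)")
    centers = np.array([(lo + hi) / 2.0 for _, lo, hi in bins])
    means = np.array([float(t[col].mean()) for col, _, _ in bins])
    order = np.argsort(centers)
    return EmissionSpectrum(centers[order], np.clip(means[order], 0.0, None))


def summarize_sample(
    events: pd.DataFrame,
    meta: dict,
    fmo_gates: dict[str, GateDefinition],
    control_mfis: dict[str, float],
    config: StudyConfig = StudyConfig(),
    model: SpectralModel | None = None,
) -> pd.DataFrame:
    """One summary row per population of a prepared sample.

    ``fmo_gates`` and ``control_mfis`` are keyed by population call and come
    from the sample's matched FMO / no-bacteria controls.  The red-shift ratio
    and the recovered oxidized fraction are computed on the MB-high subset
    (the dye-carrying cells), mirroring how emission spectra are gated.
    """
    cmap = config.channel_map
    model = model or default_model()
    rows = []
    for pop_name in POPULATION_ORDER:
        sub = events[events["population_call"] == pop_name]
        if sub.empty:
            continue
        gate = fmo_gates.get(pop_name)
        if gate is not None:
            labels, counts = classify_mb(sub, gate)
            hi = sub[labels == "MB_hi"]
            mbhi, mblo = counts["MB_hi"], counts["MB_lo"]
        else:
            hi = sub.iloc[0:0]
            mbhi, mblo = 0, len(sub)

        mb_mfi = _safe_gmfi(sub[cmap.merged])
        hi_ok = (len(hi) >= config.min_events_for_stats
                 and len(hi) / len(sub) >= config.min_mbhi_fraction)
        ratio = float("nan")
        rho = float("nan")
        if hi_ok:
            try:
                ratio = redshift_ratio(hi, cmap)
            except ValueError:
                pass
            if spectral_bin_columns(events):
                rho = unmix_oxidized_fraction(_mean_bin_spectrum(hi), model).rho
        hi_mfi = _safe_gmfi(hi[cmap.merged]) if mbhi else float("nan")
        fluor_intensity = hi_mfi * mbhi if mbhi else 0.0
        ctrl = control_mfis.get(pop_name, float("nan"))
        rows.append({
            "sample_id": meta["sample_id"],
            "compartment": meta.get("compartment", ""),
            "mode": meta.get("mode", "conventional"),
            "time_h": meta.get("time_h", float("nan")),
            "moi": meta.get("moi", float("nan")),
            "label": meta.get("label", ""),
            "genotype": meta.get("genotype", ""),
            "perturbation": meta.get("perturbation", ""),
            "volunteer": meta.get("volunteer", ""),
            "population": pop_name,
            "excluded": bool(config.exclude_eosinophils and pop_name == "eosinophil"),
            "n_events": int(len(sub)),
            "mb_mfi": mb_mfi,
            "af647_mfi": _safe_gmfi(sub[cmap.af647]),
            "af700_mfi": _safe_gmfi(sub[cmap.af700]),
            "apccy7_mfi": _safe_gmfi(sub[cmap.apccy7]),
            "redshift_ratio": ratio,
            "mbhi_count": mbhi,
            "mblo_count": mblo,
            "mbhi_fraction": mbhi / len(sub),
            "mb_fluorescence_intensity": fluor_intensity,
            "fold_change": mb_mfi / ctrl if ctrl and np.isfinite(ctrl) else float("nan"),
            "recovered_rho": rho,
            "endotoxin_eu_ml": meta.get("endotoxin_eu_ml", float("nan")),
        })
    return pd.DataFrame(rows)


def timecourse(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point aggregates (mean, sd, n) of one population/compartment.

    Distinct samples from the same volunteer at the same time point (bilateral
    replicates) are legitimate; the same sample appearing twice is not.
    """
    if rows.empty:
        raise ValueError("no rows to aggregate")
    for col in ("population", "compartment"):
        if rows[col].nunique() > 1:
            raise ValueError(f"timecourse rows must share one {col}")
    dup = rows.duplicated(subset=["volunteer", "time_h", "sample_id"])
    if dup.any():
        raise ValueError("duplicate (volunteer, time, sample) rows")
    metrics = ["mb_mfi", "mbhi_count", "mb_fluorescence_intensity",
               "redshift_ratio", "recovered_rho", "endotoxin_eu_ml"]
    agg = rows.groupby("time_h", sort=True).agg(
        n_samples=("sample_id", "size"),
        **{f"{m}_mean": (m, "mean") for m in metrics},
        **{f"{m}_sd": (m, "std") for m in metrics},
    ).reset_index()
    return agg


def compare_redshift_spectra(
    tables: dict[str, pd.DataFrame],
    meta_by_id: dict[str, dict],
    fmo_gates_by_id: dict[str, dict[str, GateDefinition]],
    config: StudyConfig = StudyConfig(),
    model: SpectralModel | None = None,
    population: str = "neutrophil",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalized population-mean emission curves + recovered rho per sample.

    The per-condition curve is the mean spectrum of the MB-high subset of the
    gated population, sum-normalized so conditions with different total MB
    content can be compared side by side; rho is recovered from that curve by
    constrained least squares against the two-state model.
    """
    model = model or default_model()
    curve_rows, rho_rows = [], []
    for sid, t in tables.items():
        meta = meta_by_id[sid]
        if meta.get("mode") != "spectral":
            raise ValueError(f"sample {sid} is not spectral mode")
        sub = t[t["population_call"] == population]
        n_pop = len(sub)
        gate = fmo_gates_by_id.get(sid, {}).get(population)
        if gate is not None and meta.get("label") == "MBEC":
            labels, _ = classify_mb(sub, gate)
            sub = sub[labels == "MB_hi"]
            if n_pop and len(sub) / n_pop < config.min_mbhi_fraction:
                log.info("sample %s: MB-high fraction %.3f below the floor; "
                         "no dye-bearing population to unmix", sid, len(sub) / n_pop)
                continue
        if len(sub) < config.min_events_for_stats:
            log.warning("sample %s: only %d %s events; spectrum skipped",
                        sid, len(sub), population)
            continue
        spec = normalize_spectrum(_mean_bin_spectrum(sub))
        result = unmix_oxidized_fraction(spec, model)
        for wl, it in zip(spec.wavelengths_nm, spec.intensities):
            curve_rows.append({"sample_id": sid, "time_h": meta.get("time_h"),
                               "wavelength_nm": wl, "normalized_intensity": it})
        rho_rows.append({"sample_id": sid, "compartment": meta.get("compartment"),
                         "time_h": meta.get("time_h"), "genotype": meta.get("genotype"),
                         "volunteer": meta.get("volunteer"), "n_events": int(len(sub)),
                         "rho": result.rho, "residual_norm": result.residual_norm})
    return pd.DataFrame(curve_rows), pd.DataFrame(rho_rows)


def marker_correlations(
    events_by_context: dict[str, pd.DataFrame],
    config: StudyConfig = StudyConfig(),
) -> pd.DataFrame:
    """Rank correlation of the merged MB signal against each surface marker.

    Returns one column per context (e.g. "in vivo" blister neutrophils vs
    "ex vivo" coculture neutrophils); constant columns yield NaN.
    """
    cmap = config.channel_map
    cols = {}
    for context, t in events_by_context.items():
        vals = {}
        mb = t[cmap.merged]
        for mk in cmap.markers:
            if mk not in t.columns or t[mk].nunique() <= 1 or mb.nunique() <= 1:
                vals[mk] = float("nan")
                continue
            vals[mk] = float(mb.corr(t[mk], method=config.correlation_method))
        cols[context] = pd.Series(vals)
    return pd.DataFrame(cols)


def sign_agreement(corr: pd.DataFrame, c1: str, c2: str) -> float:
    """Fraction of markers whose correlation sign agrees between two contexts."""
    a, b = corr[c1], corr[c2]
    ok = a.notna() & b.notna()
    if not ok.any():
        raise ValueError("no jointly defined correlations")
    return float((np.sign(a[ok]) == np.sign(b[ok])).mean())


# --- study driver -------------------------------------------------------------


def _population_gates(control: pd.DataFrame, config: StudyConfig) -> dict[str, GateDefinition]:
    gates: dict[str, GateDefinition] = {}
    for pop_name in POPULATION_ORDER:
        sub = control[control["population_call"] == pop_name]
        if len(sub) >= MIN_FMO_EVENTS:
            gates[pop_name] = fmo_threshold(sub, config.channel_map.merged,
                                            config.fmo_percentile)
        elif len(sub):
            log.warning("FMO control: %s has only %d events; no gate", pop_name, len(sub))
    return gates


def _population_mfis(control: pd.DataFrame, config: StudyConfig) -> dict[str, float]:
    out = {}
    for pop_name in POPULATION_ORDER:
        sub = control[control["population_call"] == pop_name]
        if len(sub) >= config.min_events_for_stats:
            out[pop_name] = _safe_gmfi(sub[config.channel_map.merged])
    return out


def run_study(
    study_dir: str | Path,
    out_dir: str | Path,
    config: StudyConfig = StudyConfig(),
    model: SpectralModel | None = None,
) -> dict[str, pd.DataFrame]:
    """Analyze a generated study directory and write the report bundle.

    Outputs (all CSV, deterministic for identical inputs): ``summary.csv``,
    ``timecourse.csv`` (blister neutrophils, when present), ``spectra.csv`` +
    ``spectra_rho.csv`` (spectral samples), ``correlations.csv``, and
    ``run_log.txt``.
    """
    study_dir = Path(study_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = model or default_model()

    meta_path = study_dir / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.csv in {study_dir}")
    metadata = pd.read_csv(meta_path, keep_default_na=True)
    metadata["volunteer"] = metadata.get("volunteer", "").fillna("")
    ids = set(metadata["sample_id"])
    for col in ("fmo_control_id", "foldchange_control_id"):
        for sid, cid in zip(metadata["sample_id"], metadata[col]):
            if isinstance(cid, str) and cid and cid not in ids:
                raise ValueError(f"sample {sid}: missing {col.replace('_id','')} {cid!r}")

    log_lines = [f"mbecflow {_pkg_version}", f"study: {study_dir.name}",
                 f"samples: {len(metadata)}", f"config seed: {config.seed}"]

    tables: dict[str, pd.DataFrame] = {}
    for rec in metadata.to_dict("records"):
        path = study_dir / rec["filename"]
        try:
            tables[rec["sample_id"]] = _prepare(read_events(path), config)
        except Exception as exc:
            raise RuntimeError(f"failed on sample {rec['sample_id']}: {exc}") from exc

    meta_by_id = {r["sample_id"]: r for r in metadata.to_dict("records")}
    gates_by_control = {cid: _population_gates(tables[cid], config)
                        for cid in metadata["fmo_control_id"].dropna().unique() if cid}
    mfis_by_control = {cid: _population_mfis(tables[cid], config)
                       for cid in metadata["foldchange_control_id"].dropna().unique() if cid}

    summaries = []
    for sid, t in tables.items():
        meta = meta_by_id[sid]
        summaries.append(summarize_sample(
            t, meta, gates_by_control.get(meta.get("fmo_control_id"), {}),
            mfis_by_control.get(meta.get("foldchange_control_id"), {}),
            config, model))
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(out_dir / "summary.csv", index=False)
    outputs = {"summary": summary}

    tc_rows = summary[(summary["compartment"] == "blister")
                      & (summary["population"] == "neutrophil")
                      & (summary["label"] == "MBEC")]
    if not tc_rows.empty:
        tc = timecourse(tc_rows)
        tc.to_csv(out_dir / "timecourse.csv", index=False)
        outputs["timecourse"] = tc

    spectral_ids = {sid for sid, m in meta_by_id.items() if m.get("mode") == "spectral"}
    if spectral_ids:
        fmo_by_sample = {sid: gates_by_control.get(meta_by_id[sid].get("fmo_control_id"), {})
                         for sid in spectral_ids}
        curves, rho = compare_redshift_spectra(
            {sid: tables[sid] for sid in sorted(spectral_ids)},
            meta_by_id, fmo_by_sample, config, model)
        curves.to_csv(out_dir / "spectra.csv", index=False)
        rho.to_csv(out_dir / "spectra_rho.csv", index=False)
        outputs["spectra"] = curves
        outputs["spectra_rho"] = rho

    contexts: dict[str, pd.DataFrame] = {}
    for context, mask_compartment in (("in vivo", "blister"), ("ex vivo", "coculture")):
        frames = []
        for sid, meta in sorted(meta_by_id.items()):
            if meta.get("compartment") == mask_compartment and meta.get("label") == "MBEC":
                sub = tables[sid]
                sub = sub[sub["population_call"] == "neutrophil"]
                frames.append(sub.head(config.max_correlation_events))
        if frames:
            contexts[context] = pd.concat(frames, ignore_index=True)
    if contexts:
        corr = marker_correlations(contexts, config)
        corr.to_csv(out_dir / "correlations.csv", index_label="marker")
        outputs["correlations"] = corr
        if len(corr.columns) == 2:
            c1, c2 = corr.columns
            log_lines.append(
                f"sign agreement ({c1} vs {c2}): {sign_agreement(corr, c1, c2):.3f}")

    log_lines.append(f"populations summarized: {summary['population'].nunique()}")
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return outputs
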