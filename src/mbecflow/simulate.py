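"""Synthetic spectral-cytometry studies of MBEC phagocytosis.

Generates fully labeled event-level data for the three study designs the
analysis pipeline is built for:

* ex vivo cocultures of leukocytes with methylene blue-labeled, UV-killed
  *E. coli* (MBEC) over time / MOI titrations, with cytochalasin-B,
  permeabilization, and macrophage-vs-monocyte comparisons;
* a CGD panel (healthy / X-linked carrier / affected) in which phagolysosomal
  oxidation — and therefore the red shift of the internalized dye — is absent
  in affected neutrophils and halved (lyonization) in carriers;
* an in vivo intradermal-injection design with paired blood and suction-
  blister samples at 3-24 h and a falling extracellular endotoxin track.

The forward model per cell is: a Poisson number of ingested bacteria, each
with a uniformly drawn ingestion time; first-order oxidation of the dye after
ingestion (rho = 1 - exp(-k_ox * residence)); a dye load proportional to
bacteria count and labeling concentration; per-channel signal = gain * band
integral of load * mixed emission basis, plus flat-spectrum autofluorescence,
all under multiplicative log-normal noise.

Every sample is written as an FCS 3.1 file; sample metadata (including the
control-matching columns the pipeline consumes) and a latent truth table
(bacteria counts, oxidized fractions, true population labels — never present
in the FCS files) are written as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import fcsio
from .spectra import BandPassChannel, SpectralModel, band_integral, default_model

__all__ = [
    "CellPopulationSpec",
    "SampleSpec",
    "DEFAULT_POPULATIONS",
    "simulate_bacteria_per_cell",
    "simulate_oxidation",
    "render_events",
    "render_fixed",
    "generate_study",
    "design_exvivo",
    "design_invivo",
    "design_cgd",
    "design_moi",
    "DESIGNS",
    "MB_CHANNELS",
    "MARKERS",
    "SPECTRAL_BIN_EDGES",
    "spectral_bin_channels",
    "LOAD_PER_BACTERIUM",
    "BLISTER_TIMES_H",
]

MB_CHANNELS = ("AF647", "AF700", "APC-Cy7")
MARKERS = ("CD11b", "CD66b", "CD45", "CD62L", "CD14", "CD16", "Siglec8")

#: Arbitrary fluorescence units of merged-range signal per ingested bacterium
#: at the reference 1% labeling concentration.
LOAD_PER_BACTERIUM = 150.0

#: Default multiplicative noise (coefficient of variation) on all channels.
DEFAULT_NOISE_CV = 0.25

#: Coculture ingestion saturates with time: t_sat = t / (t + T_HALF_COCULTURE).
T_HALF_COCULTURE_H = 0.5

#: Blister (in vivo) ingestion: cells arrive uniformly over the blister's
#: lifetime, start phagocytosing INGESTION_DELAY_H after arrival, and their
#: cumulative ingestion saturates with half-time T_HALF_BLISTER_H.  The delay
#: makes early blisters MB-low (freshly extravasated cells have not yet found
#: bacteria) while late blisters approach full labeling.
INGESTION_DELAY_H = 2.0
T_HALF_BLISTER_H = 4.0

#: Phagolysosomal oxidation rate of internalized dye in healthy phagocytes.
HEALTHY_K_OX = 0.5  # 1/h

#: Perturbation scale factors on the ingestion rate / retained dye load.
CYTOCHALASIN_B_LAMBDA_SCALE = 0.02
PERMEABILIZATION_LOAD_SCALE = 0.1

#: Marker response to ingestion (shared "internalization latent"): marker
#: value is scaled by (1 + bacteria_count) ** exponent.  Receptor markers are
#: internalized with the cargo; CD45 rises mildly with activation/ingestion.
INTERNALIZATION_EXPONENTS = {
    "CD11b": -0.15,
    "CD66b": -0.12,
    "CD14": -0.15,
    "CD16": -0.15,
    "CD62L": -0.12,
    "CD45": 0.08,
    "Siglec8": 0.0,
}

#: Activation (bacterial contact ex vivo, or extravasation into the blister):
#: CD11b/CD66b/CD45 are upregulated, CD62L is shed.  Identical for MBEC and
#: unlabeled E. coli — activation is label-independent.
ACTIVATION_FACTORS = {
    "CD11b": 4.0,
    "CD66b": 3.0,
    "CD45": 2.0,
    "CD62L": 0.3,
    "CD14": 1.0,
    "CD16": 1.0,
    "Siglec8": 1.0,
}

SPECTRAL_BIN_EDGES = np.arange(650.0, 821.0, 10.0)  # 17 bins of 10 nm


def spectral_bin_channels() -> tuple[BandPassChannel, ...]:
    """Wavelength-binned detector set used in "spectral" mode files."""
    return tuple(
        BandPassChannel(f"MB_{int(lo)}_{int(hi)}nm", float(lo), float(hi), 1.0)
        for lo, hi in zip(SPECTRAL_BIN_EDGES[:-1], SPECTRAL_BIN_EDGES[1:])
    )


@dataclass(frozen=True)
class CellPopulationSpec:
    """Generative parameters of one leukocyte population."""

    name: str
    phagocytic_rate: float  # mean bacteria ingested / cell / h / unit MOI
    oxidation_rate: float  # k_ox (1/h) in healthy cells
    autofluorescence_density: float  # a.u. per nm of detector window
    fsc_mean: float
    fsc_sd: float
    ssc_mean: float
    ssc_sd: float
    marker_means: dict[str, float] = field(default_factory=dict)
    is_myeloid: bool = True

    def __post_init__(self) -> None:
        if self.phagocytic_rate < 0 or self.oxidation_rate < 0:
            raise ValueError(f"{self.name}: rates must be nonnegative")


def _pop(name, rate, af, fsc, ssc, markers, myeloid=True, fsc_sd=None, ssc_sd=None):
    return CellPopulationSpec(
        name=name,
        phagocytic_rate=rate,
        oxidation_rate=HEALTHY_K_OX,
        autofluorescence_density=af,
        fsc_mean=fsc,
        fsc_sd=fsc_sd if fsc_sd is not None else fsc * 0.13,
        ssc_mean=ssc,
        ssc_sd=ssc_sd if ssc_sd is not None else ssc * 0.13,
        marker_means=markers,
        is_myeloid=myeloid,
    )


# Phagocytic ordering encodes the study's findings: neutrophils dominate,
# macrophages out-eat naive monocytes, lymphocytes do not phagocytose.
DEFAULT_POPULATIONS: dict[str, CellPopulationSpec] = {
    p.name: p
    for p in (
        _pop("neutrophil", 1.5, 0.20, 600, 600,
             {"CD11b": 150, "CD66b": 800, "CD45": 300, "CD62L": 400,
              "CD14": 20, "CD16": 600, "Siglec8": 8}),
        _pop("eosinophil", 0.2, 0.30, 620, 700,
             {"CD11b": 120, "CD66b": 500, "CD45": 300, "CD62L": 300,
              "CD14": 15, "CD16": 30, "Siglec8": 900}),
        _pop("monocyte", 0.4, 0.20, 450, 300,
             {"CD11b": 200, "CD66b": 15, "CD45": 400, "CD62L": 350,
              "CD14": 700, "CD16": 150, "Siglec8": 8}),
        _pop("macrophage", 1.0, 0.25, 850, 500,
             {"CD11b": 250, "CD66b": 15, "CD45": 400, "CD62L": 120,
              "CD14": 800, "CD16": 200, "Siglec8": 8}),
        _pop("T", 0.0, 0.10, 250, 150,
             {"CD11b": 40, "CD66b": 10, "CD45": 500, "CD62L": 500,
              "CD14": 8, "CD16": 30, "Siglec8": 5}, myeloid=False),
        _pop("B", 0.0, 0.10, 260, 160,
             {"CD11b": 35, "CD66b": 10, "CD45": 450, "CD62L": 450,
              "CD14": 8, "CD16": 25, "Siglec8": 5}, myeloid=False),
        _pop("NK", 0.0, 0.10, 280, 180,
             {"CD11b": 60, "CD66b": 10, "CD45": 480, "CD62L": 400,
              "CD14": 8, "CD16": 400, "Siglec8": 5}, myeloid=False),
    )
}

LYMPHOCYTE_NAMES = ("T", "B", "NK")


@dataclass(frozen=True)
class SampleSpec:
    """One simulated tube: cell mix, exposure conditions, and control links."""

    sample_id: str
    mode: str = "conventional"  # "conventional" | "spectral"
    compartment: str = "coculture"  # "coculture" | "blood" | "blister"
    time_h: float = 1.0
    moi: float = 10.0
    label: str = "MBEC"  # "MBEC" | "unlabeled_E_coli" | "none"
    label_concentration_pct: float = 1.0
    genotype: str = "healthy"  # "healthy" | "CGD_carrier" | "CGD_affected"
    perturbation: str = "none"  # "none" | "cytochalasinB" | "permeabilization"
    n_events: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    volunteer: str = ""
    fmo_control_id: str = ""
    foldchange_control_id: str = ""
    endotoxin_eu_ml: float = float("nan")
    noise_cv: float = DEFAULT_NOISE_CV

    def __post_init__(self) -> None:
        if self.time_h < 0 or self.moi < 0:
            raise ValueError("time_h and moi must be nonnegative")
        if self.mode not in ("conventional", "spectral"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.label not in ("MBEC", "unlabeled_E_coli", "none"):
            raise ValueError(f"unknown label {self.label!r}")


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def _coculture_lambda(pop: CellPopulationSpec, time_h: float, moi: float,
                      perturbation: str) -> float:
    t_sat = time_h / (time_h + T_HALF_COCULTURE_H) if time_h > 0 else 0.0
    lam = pop.phagocytic_rate * moi * t_sat
    if perturbation == "cytochalasinB":
        lam *= CYTOCHALASIN_B_LAMBDA_SCALE
    return lam


def simulate_bacteria_per_cell(
    pop: CellPopulationSpec,
    time_h: float,
    moi: float,
    perturbation: str = "none",
    seed: int | np.random.Generator = 0,
    n_cells: int = 1,
) -> np.ndarray:
    """Poisson bacteria counts for a coculture exposure.

    The Poisson mean is phagocytic_rate * MOI * t / (t + 0.5 h), nondecreasing
    in both time and MOI; cytochalasin B scales it by 0.02.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = _coculture_lambda(pop, time_h, moi, perturbation)
    if lam <= 0:
        return np.zeros(n_cells, dtype=np.int64)
    return rng.poisson(lam, size=n_cells)


def simulate_oxidation(
    ingestion_times: Sequence[np.ndarray],
    k_ox: float | np.ndarray,
    time_h: float,
) -> np.ndarray:
    """Per-cell mean oxidized fraction given each cell's ingestion times.

    Each ingested bacterium's dye oxidizes as 1 - exp(-k_ox * residence) with
    residence = time_h - ingestion time; a cell's rho is the mean over its
    bacteria (0 for cells with none).  k_ox = 0 gives rho = 0 exactly.
    """
    if time_h < 0:
        raise ValueError("time_h must be nonnegative")
    k = np.broadcast_to(np.asarray(k_ox, dtype=float), (len(ingestion_times),))
    if np.any(k < 0):
        raise ValueError("k_ox must be nonnegative")
    out = np.zeros(len(ingestion_times))
    for i, times in enumerate(ingestion_times):
        times = np.asarray(times, dtype=float)
        if times.size == 0:
            continue
        residence = np.clip(time_h - times, 0.0, None)
        out[i] = float(np.mean(1.0 - np.exp(-k[i] * residence)))
    return out


def _kox_per_cell(pop: CellPopulationSpec, genotype: str, n: int) -> np.ndarray:
    """Genotype -> per-cell oxidation rate; carriers are an exact 50/50 mosaic."""
    k = np.full(n, pop.oxidation_rate)
    if genotype == "CGD_affected":
        k[:] = 0.0
    elif genotype == "CGD_carrier":
        k[: n // 2] = 0.0
    elif genotype != "healthy":
        raise ValueError(f"unknown genotype {genotype!r}")
    return k


def _mb_channel_set(model: SpectralModel, mode: str) -> tuple[BandPassChannel, ...]:
    return model.channels if mode == "conventional" else spectral_bin_channels()


def _basis_band_integrals(model: SpectralModel, chans: Iterable[BandPassChannel]):
    i_red = np.array([band_integral(model.reduced_basis, c) for c in chans])
    i_oxi = np.array([band_integral(model.oxidized_basis, c) for c in chans])
    return i_red, i_oxi


def _ingestion_and_oxidation(
    rng: np.random.Generator,
    counts: np.ndarray,
    start: np.ndarray,
    time_h: float,
    k_cell: np.ndarray,
) -> np.ndarray:
    """Vectorized per-cell mean rho; ingestion times uniform on [start_i, t]."""
    n = counts.size
    total = int(counts.sum())
    rho = np.zeros(n)
    if total == 0 or time_h <= 0:
        return rho
    reps = np.repeat(np.arange(n), counts)
    ing = rng.uniform(start[reps], time_h)
    per_bact = 1.0 - np.exp(-k_cell[reps] * (time_h - ing))
    sums = np.zeros(n)
    np.add.at(sums, reps, per_bact)
    with np.errstate(invalid="ignore"):
        rho = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return rho


def render_events(
    sample: SampleSpec,
    model: SpectralModel | None = None,
    pops: dict[str, CellPopulationSpec] | None = None,
) -> pd.DataFrame:
    """Forward-model one sample to an event table (with latent truth columns).

    Columns: population (truth), FSC, SSC, the MB-detecting channels for the
    sample's mode, surface markers, and the latent columns bacteria_count and
    rho.  The latent and truth columns are stripped before FCS export.
    """
    model = model or default_model()
    pops = pops or DEFAULT_POPULATIONS
    chans = _mb_channel_set(model, sample.mode)
    i_red, i_oxi = _basis_band_integrals(model, chans)
    widths = np.array([c.width_nm for c in chans])
    gains = np.array([c.gain for c in chans])
    rng = np.random.default_rng(sample.seed)

    frames = []
    for name in sorted(sample.n_events):
        n = int(sample.n_events[name])
        if n < 0:
            raise ValueError(f"negative event count for population {name!r}")
        if n == 0:
            continue
        if name not in pops:
            raise KeyError(f"unknown population name {name!r}")
        pop = pops[name]

        # --- ingestion -----------------------------------------------------
        exposed = sample.label in ("MBEC", "unlabeled_E_coli")
        counts = np.zeros(n, dtype=np.int64)
        start = np.zeros(n)
        if exposed and sample.compartment in ("coculture", "blister") and sample.time_h > 0:
            if sample.compartment == "coculture":
                lam = np.full(n, _coculture_lambda(
                    pop, sample.time_h, sample.moi, sample.perturbation))
            else:
                arrival = rng.uniform(0.0, sample.time_h, size=n)
                active = np.clip(sample.time_h - arrival - INGESTION_DELAY_H, 0.0, None)
                lam = (pop.phagocytic_rate * sample.moi
                       * active / (active + T_HALF_BLISTER_H))
                if sample.perturbation == "cytochalasinB":
                    lam *= CYTOCHALASIN_B_LAMBDA_SCALE
                start = np.minimum(arrival + INGESTION_DELAY_H, sample.time_h)
            counts = rng.poisson(np.clip(lam, 0.0, None))

        k_cell = _kox_per_cell(pop, sample.genotype, n)
        rho = _ingestion_and_oxidation(rng, counts, start, sample.time_h, k_cell)

        # --- dye load and channel signal ----------------------------------
        load = np.zeros(n)
        if sample.label == "MBEC":
            load = counts * LOAD_PER_BACTERIUM * sample.label_concentration_pct
            if sample.perturbation == "permeabilization":
                load = load * PERMEABILIZATION_LOAD_SCALE
        basis_signal = np.outer(1.0 - rho, i_red) + np.outer(rho, i_oxi)
        af = pop.autofluorescence_density * widths
        signal = gains * (load[:, None] * basis_signal + af)
        noise = _lognormal_factor(rng, sample.noise_cv, n * len(chans)).reshape(n, -1)
        mb_values = signal * noise

        # --- scatter and markers ------------------------------------------
        fsc = np.clip(rng.normal(pop.fsc_mean, pop.fsc_sd, n), 0.0, None)
        ssc = np.clip(rng.normal(pop.ssc_mean, pop.ssc_sd, n), 0.0, None)
        activated = pop.is_myeloid and (
            sample.compartment == "blister"
            or (sample.compartment == "coculture" and exposed)
        )
        markers = {}
        for mk in MARKERS:
            base = pop.marker_means.get(mk, 0.0)
            act = ACTIVATION_FACTORS[mk] if activated else 1.0
            internal = (1.0 + counts) ** INTERNALIZATION_EXPONENTS[mk]
            markers[mk] = base * act * internal * _lognormal_factor(rng, sample.noise_cv, n)

        frame = {"population": np.repeat(name, n), "FSC": fsc, "SSC": ssc}
        for j, c in enumerate(chans):
            frame[c.name] = mb_values[:, j]
        frame.update(markers)
        frame["bacteria_count"] = counts
        frame["rho"] = rho
        frames.append(pd.DataFrame(frame))

    if not frames:
        cols = (["population", "FSC", "SSC"] + [c.name for c in chans]
                + list(MARKERS) + ["bacteria_count", "rho"])
        return pd.DataFrame({c: [] for c in cols})
    return pd.concat(frames, ignore_index=True)


def render_fixed(
    model: SpectralModel,
    rho: float,
    load: float,
    n_events: int,
    mode: str = "conventional",
    noise_cv: float = 0.0,
    autofluorescence_density: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Render events at a fixed oxidation state and dye load.

    The controlled counterpart of :func:`render_events`, used to check that
    the measured red-shift ratio reproduces the spectral model's closed form.
    """
    chans = _mb_channel_set(model, mode)
    i_red, i_oxi = _basis_band_integrals(model, chans)
    widths = np.array([c.width_nm for c in chans])
    gains = np.array([c.gain for c in chans])
    rng = np.random.default_rng(seed)
    base = gains * (load * ((1.0 - rho) * i_red + rho * i_oxi)
                    + autofluorescence_density * widths)
    noise = _lognormal_factor(rng, noise_cv, n_events * len(chans)).reshape(n_events, -1)
    return pd.DataFrame(np.broadcast_to(base, (n_events, len(chans))) * noise,
                        columns=[c.name for c in chans])


# --- study designs ------------------------------------------------------------

EXVIVO_TIMES_H = (0.0, 0.25, 0.5, 0.75, 1.0)
CGD_TIMES_H = (0.0, 0.75, 1.5, 2.25, 3.0)
BLISTER_TIMES_H = (3.0, 5.0, 7.0, 9.0, 24.0)
MOI_LEVELS = (1.0, 3.0, 10.0, 30.0, 100.0)

#: Blister cellularity over the sampled window: infiltration rises steeply to
#: a 9 h peak with a mild decline at 24 h (full resolution lies beyond 24 h).
BLISTER_NEUTROPHILS = {3.0: 800, 5.0: 2500, 7.0: 4500, 9.0: 6500, 24.0: 5500}
BLISTER_MONOCYTES = {3.0: 150, 5.0: 400, 7.0: 800, 9.0: 1200, 24.0: 1400}
BLISTER_LYMPHS = {3.0: (60, 25, 25), 5.0: (120, 40, 40), 7.0: (200, 70, 70),
                  9.0: (300, 100, 100), 24.0: (400, 130, 130)}

MIXED_LEUKOCYTES = {"neutrophil": 3000, "monocyte": 400, "T": 1200, "B": 400,
                    "NK": 300, "eosinophil": 150}
NEUTROPHILS_ONLY = {"neutrophil": 2500}

ENDOTOXIN_E0_EU_ML = 500.0
ENDOTOXIN_HALFLIFE_SCALE_H = 6.0


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def design_exvivo(seed: int = 0) -> list[SampleSpec]:
    """Coculture time series plus perturbation and macrophage/monocyte arms."""
    specs: list[SampleSpec] = []

    def add(**kw):
        specs.append(SampleSpec(**kw))

    mix = dict(MIXED_LEUKOCYTES)
    for t in EXVIVO_TIMES_H:
        add(sample_id=f"EX_MBEC_t{int(t * 60):03d}min", compartment="coculture",
            time_h=t, moi=10.0, label="MBEC", n_events=mix,
            fmo_control_id="EX_FMO", foldchange_control_id="EX_NONE")
    add(sample_id="EX_FMO", compartment="coculture", time_h=1.0, moi=10.0,
        label="unlabeled_E_coli", n_events=mix,
        fmo_control_id="EX_FMO", foldchange_control_id="EX_NONE")
    add(sample_id="EX_NONE", compartment="coculture", time_h=1.0, moi=0.0,
        label="none", n_events=mix,
        fmo_control_id="EX_FMO", foldchange_control_id="EX_NONE")
    for pert, sid in (("cytochalasinB", "EX_CYTB"), ("none", "EX_VEH"),
                      ("permeabilization", "EX_PERM")):
        add(sample_id=sid, compartment="coculture", time_h=1.0, moi=30.0,
            label="MBEC", perturbation=pert, n_events=mix,
            fmo_control_id="EX_FMO", foldchange_control_id="EX_NONE")
    for cell, prefix in (("macrophage", "MAC"), ("monocyte", "MON")):
        n_ev = {cell: 1500}
        for label, suffix in (("MBEC", "MBEC"), ("unlabeled_E_coli", "UNLAB"),
                              ("none", "NONE")):
            add(sample_id=f"{prefix}_{suffix}", compartment="coculture",
                time_h=1.0, moi=100.0 if label != "none" else 0.0, label=label,
                n_events=n_ev, fmo_control_id=f"{prefix}_UNLAB",
                foldchange_control_id=f"{prefix}_NONE")
    return [replace(sp, seed=s) for sp, s in zip(specs, _seeds(seed, len(specs)))]


def design_moi(seed: int = 0) -> list[SampleSpec]:
    """60 min coculture at an MOI titration."""
    specs = [
        SampleSpec(sample_id=f"MOI_{int(m):03d}", compartment="coculture",
                   time_h=1.0, moi=m, label="MBEC", n_events=dict(MIXED_LEUKOCYTES),
                   fmo_control_id="MOI_FMO", foldchange_control_id="MOI_NONE")
        for m in MOI_LEVELS
    ]
    specs.append(SampleSpec(sample_id="MOI_FMO", compartment="coculture", time_h=1.0,
                            moi=30.0, label="unlabeled_E_coli",
                            n_events=dict(MIXED_LEUKOCYTES),
                            fmo_control_id="MOI_FMO", foldchange_control_id="MOI_NONE"))
    specs.append(SampleSpec(sample_id="MOI_NONE", compartment="coculture", time_h=1.0,
                            moi=0.0, label="none", n_events=dict(MIXED_LEUKOCYTES),
                            fmo_control_id="MOI_FMO", foldchange_control_id="MOI_NONE"))
    return [replace(sp, seed=s) for sp, s in zip(specs, _seeds(seed, len(specs)))]


def design_cgd(seed: int = 0, modes: tuple[str, ...] = ("conventional", "spectral")) -> list[SampleSpec]:
    """Isolated-neutrophil coculture series across CGD genotypes, both modes."""
    specs: list[SampleSpec] = []
    for mode in modes:
        tag = "C" if mode == "conventional" else "S"
        for g, gshort in (("healthy", "HC"), ("CGD_carrier", "CAR"), ("CGD_affected", "AFF")):
            fmo = f"CGD_{gshort}_{tag}_FMO"
            for t in CGD_TIMES_H:
                specs.append(SampleSpec(
                    sample_id=f"CGD_{gshort}_{tag}_t{int(t * 60):03d}min", mode=mode,
                    compartment="coculture", time_h=t, moi=10.0, label="MBEC",
                    genotype=g, n_events=dict(NEUTROPHILS_ONLY),
                    fmo_control_id=fmo, foldchange_control_id=fmo))
            specs.append(SampleSpec(
                sample_id=fmo, mode=mode, compartment="coculture", time_h=3.0,
                moi=10.0, label="unlabeled_E_coli", genotype=g,
                n_events=dict(NEUTROPHILS_ONLY),
                fmo_control_id=fmo, foldchange_control_id=fmo))
    return [replace(sp, seed=s) for sp, s in zip(specs, _seeds(seed, len(specs)))]


def _blister_counts(t: float) -> dict[str, int]:
    lt, lb, lnk = BLISTER_LYMPHS[t]
    return {"neutrophil": BLISTER_NEUTROPHILS[t], "monocyte": BLISTER_MONOCYTES[t],
            "T": lt, "B": lb, "NK": lnk, "eosinophil": 60}

BLOOD_COUNTS = {"neutrophil": 3000, "monocyte": 400, "T": 1200, "B": 400,
                "NK": 300, "eosinophil": 150}
CONTROL_BLISTER_COUNTS = {"neutrophil": 3000, "monocyte": 800, "T": 600, "B": 300,
                          "NK": 300, "eosinophil": 100}

INVIVO_MOI = 2.0


def design_invivo(seed: int = 0) -> list[SampleSpec]:
    """Paired blood/blister time course, 19 volunteers, 38 blister data points.

    Volunteers contribute either a 3 h + 5 h, a 7 h + 9 h, or two 24 h
    blisters (7/7/8/8/8 samples per time point); one unlabeled-injection
    control volunteer per time point provides the fluorescence-minus-one pair.
    """
    assignments: list[tuple[str, float]] = []
    for v in range(1, 8):
        assignments += [(f"v{v:02d}", 3.0), (f"v{v:02d}", 5.0)]
    for v in range(8, 16):
        assignments += [(f"v{v:02d}", 7.0), (f"v{v:02d}", 9.0)]
    for v in range(16, 20):
        assignments += [(f"v{v:02d}", 24.0), (f"v{v:02d}", 24.0)]

    specs: list[SampleSpec] = []
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    for t in BLISTER_TIMES_H:
        cid = f"CTRL_BL_t{int(t):02d}h"
        specs.append(SampleSpec(sample_id=cid, mode="spectral", compartment="blister",
                                time_h=t, moi=INVIVO_MOI, label="unlabeled_E_coli",
                                n_events=dict(CONTROL_BLISTER_COUNTS),
                                volunteer=f"ctrl_t{int(t):02d}",
                                fmo_control_id=cid, foldchange_control_id=cid))
        cbd = f"CTRL_BD_t{int(t):02d}h"
        specs.append(SampleSpec(sample_id=cbd, mode="spectral", compartment="blood",
                                time_h=t, moi=INVIVO_MOI, label="unlabeled_E_coli",
                                n_events=dict(BLOOD_COUNTS),
                                volunteer=f"ctrl_t{int(t):02d}",
                                fmo_control_id=cbd, foldchange_control_id=cbd))
    seen: dict[tuple[str, float], int] = {}
    for vol, t in assignments:
        rep = seen.get((vol, t), 0) + 1
        seen[(vol, t)] = rep
        suffix = f"{vol}_t{int(t):02d}h" + (f"_r{rep}" if rep > 1 else "")
        endo = float(ENDOTOXIN_E0_EU_ML * np.exp(-t / ENDOTOXIN_HALFLIFE_SCALE_H)
                     * np.exp(rng.normal(0.0, 0.08)))
        blood_id = f"BD_{suffix}"
        specs.append(SampleSpec(sample_id=f"BL_{suffix}", mode="spectral",
                                compartment="blister", time_h=t, moi=INVIVO_MOI,
                                label="MBEC", n_events=_blister_counts(t),
                                volunteer=vol, endotoxin_eu_ml=endo,
                                fmo_control_id=f"CTRL_BL_t{int(t):02d}h",
                                foldchange_control_id=blood_id))
        specs.append(SampleSpec(sample_id=blood_id, mode="spectral",
                                compartment="blood", time_h=t, moi=INVIVO_MOI,
                                label="MBEC", n_events=dict(BLOOD_COUNTS),
                                volunteer=vol,
                                fmo_control_id=f"CTRL_BD_t{int(t):02d}h",
                                foldchange_control_id=blood_id))
    return [replace(sp, seed=s) for sp, s in zip(specs, _seeds(seed, len(specs)))]


DESIGNS = {
    "exvivo": design_exvivo,
    "invivo": design_invivo,
    "cgd": design_cgd,
    "moi": design_moi,
}

_TRUTH_COLS = ("population", "bacteria_count", "rho")


def generate_study(
    design: str | Sequence[SampleSpec],
    out_dir: str | Path,
    seed: int = 0,
    model: SpectralModel | None = None,
    pops: dict[str, CellPopulationSpec] | None = None,
) -> pd.DataFrame:
    """Simulate a study design and write FCS files + metadata + truth tables.

    Returns the metadata sheet (also written to ``metadata.csv``).  The truth
    table (``truth.csv``) carries the latent per-event columns which are never
    present in the FCS files.
    """
    if isinstance(design, str):
        try:
            specs = DESIGNS[design](seed)
        except KeyError:
            raise ValueError(f"unknown design {design!r}; choose from {sorted(DESIGNS)}")
    else:
        specs = list(design)
    model = model or default_model()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    meta_rows = []
    truth_frames = []
    for sp in specs:
        events = render_events(sp, model=model, pops=pops)
        fcs_cols = [c for c in events.columns if c not in _TRUTH_COLS]
        fname = f"{sp.sample_id}.fcs"
        fcsio.write_fcs(out_dir / fname, events[fcs_cols],
                        metadata={"SAMPLE_ID": sp.sample_id, "MODE": sp.mode})
        truth = events[list(_TRUTH_COLS)].copy()
        truth.insert(0, "sample_id", sp.sample_id)
        truth.insert(1, "event_index", np.arange(len(truth)))
        truth_frames.append(truth)
        meta_rows.append({
            "sample_id": sp.sample_id, "filename": fname, "mode": sp.mode,
            "compartment": sp.compartment, "time_h": sp.time_h, "moi": sp.moi,
            "label": sp.label, "label_concentration_pct": sp.label_concentration_pct,
            "genotype": sp.genotype, "perturbation": sp.perturbation,
            "volunteer": sp.volunteer, "fmo_control_id": sp.fmo_control_id,
            "foldchange_control_id": sp.foldchange_control_id,
            "endotoxin_eu_ml": sp.endotoxin_eu_ml, "seed": sp.seed,
        })
    metadata = pd.DataFrame(meta_rows)
    metadata.to_csv(out_dir / "metadata.csv", index=False)
    pd.concat(truth_frames, ignore_index=True).to_csv(out_dir / "truth.csv", index=False)
    return metadata
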