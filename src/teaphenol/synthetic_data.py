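"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the study conditions of a green-tea antioxidant
screen:

* negative-mode QqTOF MS/MS spectra built from the shipped compound library
  (precursor from the formula with ppm-scale Gaussian error, fragments with
  mDa-scale error, log-uniform intensities, optional decoy peaks);
* Hill-shaped dose–response curves on the five-dose assay grid
  0.78–12.5 µg/mL;
* logistic fluorescein-decay curves for ORAC whose midpoint shifts in
  proportion to Trolox-equivalents × concentration (so a TE of 0 reproduces
  the blank exactly);
* samples × metrics activity panels with a planted potency ranking.

All randomness flows from a single master seed; each operation derives an
independent substream by stably hashing its name (and entry id), so adding
generators never reshuffles existing output. Zero-noise settings reduce every
generator to an exact identity with the library / closed-form values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .bioassay_metrics import DoseResponse, OracCurve
from .activity_ranking import ActivityMatrix
from .formula_mass import deprotonated_mz
from .spectral_annotation import (
    AGLYCONES,
    CompoundLibraryEntry,
    MsmsSpectrum,
    Peak,
)

import pandas as pd

__all__ = [
    "SimulationConfig",
    "simulate_spectrum",
    "simulate_dose_response",
    "simulate_orac_decay",
    "simulate_panel",
]

#: Assay dose grid, µg/mL final concentration.
DEFAULT_DOSE_GRID = (0.78, 1.56, 3.125, 6.25, 12.5)

#: ORAC reading times: every 15 min for 120 min, t=0 included (9 readings).
DEFAULT_ORAC_TIMES = tuple(float(t) for t in range(0, 121, 15))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data generators (defaults = study conditions)."""

    seed: int = 0
    precursor_ppm_sd: float = 5.0        # ppm
    fragment_mda_sd: float = 10.0        # mDa
    n_decoy_peaks: int = 5
    decoy_intensity_max: float = 0.3     # fraction of base peak
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    hill_slope: float = 1.0
    response_noise_sd: float = 2.0       # percent-response units
    n_replicates: int = 3                # assay replicates averaged per point
    orac_times: tuple[float, ...] = DEFAULT_ORAC_TIMES
    orac_decay_midpoint: float = 25.0    # blank decay midpoint, min
    orac_decay_steepness: float = 0.2    # 1/min
    orac_midpoint_shift: float = 2.5     # min per (TE × concentration unit)
    orac_noise_sd: float = 0.0           # relative fluorescence noise

    def __post_init__(self) -> None:
        for name in ("precursor_ppm_sd", "fragment_mda_sd", "response_noise_sd",
                     "orac_noise_sd", "decoy_intensity_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_decoy_peaks < 0:
            raise ValueError("n_decoy_peaks must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def rng(self, stream: str, entry_id: int | str = 0) -> np.random.Generator:
        """Substream generator: master seed + stable hash of stream name/id."""
        tag = zlib.crc32(f"{stream}/{entry_id}".encode()) & 0x7FFFFFFF
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, tag])


_RADICAL_MZS = {ref.name: ref.radical_mz for ref in AGLYCONES
                if ref.radical_mz is not None}
_EVEN_MZS = {ref.name: ref.even_mz for ref in AGLYCONES}


def simulate_spectrum(entry: CompoundLibraryEntry,
                      cfg: SimulationConfig) -> MsmsSpectrum:
    """Simulate one MS/MS spectrum of a library compound.

    The precursor is the formula's [M−H]− m/z with Gaussian ppm error; the
    fragments are the library's expected fragments with Gaussian mDa error and
    log-uniform intensities on [0.05, 1] of the base peak. Where the library
    row contains a flavonol aglycone even/radical ion pair, the radical ion is
    forced to be the base peak (the hallmark of 3-O-glycosylation); its
    even-electron partner is capped below it. Decoy peaks are appended at
    uniform random m/z below the precursor.
    """
    if not entry.expected_fragments:
        raise ValueError("library entry has no expected fragments")
    rng = cfg.rng("spectrum", entry.peak_no)
    calc = deprotonated_mz(entry.formula)
    precursor = calc * (1.0 + rng.normal(0.0, cfg.precursor_ppm_sd) * 1e-6)
    frag_sd = cfg.fragment_mda_sd * 1e-3
    mzs = [f + rng.normal(0.0, frag_sd) if frag_sd > 0 else f
           for f in entry.expected_fragments]
    intensities = 10 ** rng.uniform(np.log10(0.05), 0.0, size=len(mzs))

    tol = 0.02
    if entry.aglycone in _RADICAL_MZS:
        rad_ref, even_ref = _RADICAL_MZS[entry.aglycone], _EVEN_MZS[entry.aglycone]
        rad_idx = [i for i, f in enumerate(entry.expected_fragments)
                   if abs(f - rad_ref) <= tol]
        even_idx = [i for i, f in enumerate(entry.expected_fragments)
                    if abs(f - even_ref) <= tol]
        if rad_idx and even_idx:
            intensities[rad_idx[0]] = 1.0
            intensities[even_idx[0]] = min(intensities[even_idx[0]], 0.5)

    peaks = [Peak(mz, inten) for mz, inten in zip(mzs, intensities)]
    base = max(intensities)
    for _ in range(cfg.n_decoy_peaks):
        mz = rng.uniform(80.0, max(100.0, precursor - 20.0))
        peaks.append(Peak(mz, rng.uniform(0.0, cfg.decoy_intensity_max * base)))
    return MsmsSpectrum(precursor_mz=precursor, peaks=peaks, rt=entry.rt,
                        sample_id=f"sim_peak_{entry.peak_no}")


def simulate_dose_response(id50_true: float, cfg: SimulationConfig,
                           *, sample_id: str = "sim", assay: str = "DPPH") -> DoseResponse:
    """Hill curve on the assay dose grid: R(d) = 100 d^h / (d^h + ID50^h) + noise.

    Noise is added per replicate and the replicates are averaged, mirroring
    the triplicate-measurement design of the assays; the replicate SD is
    carried along for reporting.
    """
    if id50_true <= 0:
        raise ValueError("id50_true must be positive")
    if cfg.hill_slope <= 0:
        raise ValueError("Hill slope must be positive")
    if cfg.n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = cfg.rng("dose_response", sample_id)
    doses = np.asarray(cfg.dose_grid, dtype=float)
    h = cfg.hill_slope
    clean = 100.0 * doses ** h / (doses ** h + id50_true ** h)
    if cfg.response_noise_sd > 0:
        reps = clean + rng.normal(0.0, cfg.response_noise_sd,
                                  (cfg.n_replicates, doses.size))
        responses = reps.mean(axis=0)
        sds = reps.std(axis=0, ddof=1) if cfg.n_replicates > 1 else None
    else:
        responses, sds = clean, None
    return DoseResponse(sample_id=sample_id, assay=assay, doses=doses,
                        responses=responses, sds=sds)


def _decay_curve(times: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    g = 1.0 / (1.0 + np.exp(steepness * (times - midpoint)))
    return g / g[0]


def simulate_orac_decay(
    te_true: float,
    conc_grid: Sequence[float],
    cfg: SimulationConfig,
    *,
    f0: float = 1000.0,
    sample_id: str = "sim",
) -> tuple[list[OracCurve], OracCurve]:
    """Simulate ORAC fluorescein-decay curves plus the matching blank.

    The decay is logistic in time; an antioxidant delays it by shifting the
    midpoint by ``orac_midpoint_shift × te_true × concentration`` minutes.
    ``te_true = 0`` reproduces the blank curve exactly (net AUC 0).
    """
    if te_true < 0:
        raise ValueError("te_true must be non-negative")
    times = np.asarray(cfg.orac_times, dtype=float)
    rng = cfg.rng("orac", sample_id)
    blank = OracCurve("blank", 0.0, times,
                      f0 * _decay_curve(times, cfg.orac_decay_midpoint,
                                        cfg.orac_decay_steepness))
    curves = []
    for conc in conc_grid:
        if conc < 0:
            raise ValueError("concentrations must be non-negative")
        midpoint = cfg.orac_decay_midpoint + cfg.orac_midpoint_shift * te_true * conc
        f = f0 * _decay_curve(times, midpoint, cfg.orac_decay_steepness)
        if cfg.orac_noise_sd > 0:
            noise = rng.normal(0.0, cfg.orac_noise_sd,
                               (cfg.n_replicates, times.size)).mean(axis=0)
            f = f * (1.0 + noise)
            f[0] = abs(f[0])  # keep the defining f(0) > 0
        curves.append(OracCurve(sample_id, float(conc), times.copy(), f))
    return curves, blank


def simulate_panel(
    n_samples: int,
    planted_ranking: Optional[Sequence[str]] = None,
    cfg: SimulationConfig = SimulationConfig(),
    *,
    noise_sd: float = 0.0,
) -> ActivityMatrix:
    """Activity panel (3 lower-better ID50 columns + 1 higher-better ORAC).

    Sample quality decreases along ``planted_ranking``: each step down the
    ranking doubles every ID50 and shrinks the ORAC column. With
    ``noise_sd = 0`` the oriented RACI ordering equals the planted ranking
    exactly; ``noise_sd`` adds multiplicative log-normal jitter.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if planted_ranking is None:
        planted_ranking = [f"sample_{i}" for i in range(n_samples)]
    if len(planted_ranking) != n_samples:
        raise ValueError("planted_ranking length must equal n_samples")
    rng = cfg.rng("panel")
    rank = np.arange(n_samples, dtype=float)
    columns = {
        "id50_dpph": 4.0 * 2.0 ** rank,
        "id50_abts": 1.2 * 2.0 ** rank,
        "id50_tbars": 0.2 * 2.0 ** rank,
        "orac_te": 3.8 * 0.85 ** rank,
    }
    values = pd.DataFrame(columns, index=list(planted_ranking))
    if noise_sd > 0:
        jitter = rng.normal(0.0, noise_sd, values.shape)
        values = values * np.exp(jitter)
    orientation = {"id50_dpph": "lower-better", "id50_abts": "lower-better",
                   "id50_tbars": "lower-better", "orac_te": "higher-better"}
    return ActivityMatrix(values=values, orientation=orientation)
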