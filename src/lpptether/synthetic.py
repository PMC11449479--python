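"""Ground-truth-known synthetic data emulating the pulse-chase labeling experiment.

Generates (i) tidy isotopologue intensity time courses over one generation
with replicate structure and multiplicative log-normal noise, and (ii)
matching MS1/MS2 peak lists with ppm-scale Gaussian mass error, so the whole
assignment -> quantification -> estimation chain is testable without the
deposited raw spectra.

What is emulated: four-isotopologue relative-abundance kinetics driven by the
ODE model, 3-5 biological replicates, positive heteroscedastic intensity
noise, and instrument mass error.  What is not: isotope envelopes, retention
time, chimeric spectra, fragmentation-efficiency differences (MS2 fragment
intensities are uniform; assignment uses masses only), and sub-100 % isotope
enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assignment import PEAKLIST_COLUMNS
from .chemistry import QUANT_KEYS, QUANT_ORDER, theoretical_table
from .kinetics import KineticParams, Trajectory, simulate, wild_type_params

__all__ = ["SyntheticConfig", "GroundTruth", "generate_timecourse", "generate_peaklists"]

#: Sampling grid: the medium switch plus four post-switch times (minutes).
DEFAULT_TIME_POINTS: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    ``cv`` is the coefficient of variation of the multiplicative log-normal
    intensity noise (default 10 %); ``mass_error_ppm`` the SD of the Gaussian
    relative mass error applied to every synthetic peak (default 5 ppm).
    A seed is mandatory: every output regenerates bit-identically from
    (config, seed).
    """

    params: KineticParams = field(default_factory=wild_type_params)
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    n_replicates: int = 4
    intensity_scale: float = 1e6
    cv: float = 0.10
    mass_error_ppm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.cv < 0 or self.mass_error_ppm < 0:
            raise ValueError("noise levels must be non-negative")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")
        if len(self.time_points) < 2 or any(np.diff(self.time_points) <= 0):
            raise ValueError("time_points must be strictly increasing")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    def replicates(self) -> list[str]:
        return [f"r{i + 1}" for i in range(self.n_replicates)]


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score a downstream analysis of the synthetic data."""

    config: SyntheticConfig
    trajectory: Trajectory
    noiseless_quant: pd.DataFrame  # time_min x (nn, oo, on, no), percent
    true_intensities: pd.DataFrame  # tidy: time_min, replicate, nn, oo, on, no


def _noiseless(config: SyntheticConfig) -> tuple[Trajectory, pd.DataFrame]:
    traj = simulate(config.params, np.asarray(config.time_points, dtype=float))
    quant = traj.quant[["time_min", "nn", "oo", "on", "no"]].reset_index(drop=True)
    return traj, quant


def generate_timecourse(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Tidy isotopologue intensity table with replicate log-normal noise.

    Intensities are ``intensity_scale * abundance/100`` perturbed by a
    mean-one log-normal factor per isotopologue/replicate/time (sigma chosen
    so the multiplicative coefficient of variation equals ``cv``; at cv = 0
    the noiseless trajectory is returned exactly).  Columns: ``time_min,
    replicate, nn, oo, on, no`` (intensities, arbitrary units).
    """
    rng = np.random.default_rng(config.seed)
    traj, quant = _noiseless(config)
    base = quant[["nn", "oo", "on", "no"]].to_numpy() / 100.0 * config.intensity_scale
    sigma = math.sqrt(math.log1p(config.cv**2))
    rows = []
    for i, t in enumerate(config.time_points):
        for rep in config.replicates():
            if sigma > 0:
                factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=4)
            else:
                factors = np.ones(4)
            rows.append([t, rep, *(base[i] * factors)])
    intensities = pd.DataFrame(rows, columns=["time_min", "replicate", "nn", "oo", "on", "no"])
    truth = GroundTruth(
        config=config,
        trajectory=traj,
        noiseless_quant=quant,
        true_intensities=intensities,
    )
    return intensities, truth


def generate_peaklists(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Matching MS1 and MS2 peak-list tables for the synthetic time course.

    For every sample (time, replicate) and every isotopologue with non-zero
    intensity there is one MS1 peak at the theoretical parental mass of that
    label state, perturbed by Gaussian relative error of SD
    ``mass_error_ppm``, carrying the noisy intensity; and seven MS2 peaks for
    the fragment ladder of the same label state (uniform intensities), tagged
    with the MS1 peak's m/z as ``precursor_mz``.  At zero noise and zero mass
    error the peak lists round-trip through assignment and quantification to
    the generating abundances exactly.
    """
    intensities, truth = generate_timecourse(config)
    table = theoretical_table()  # 7 fragments x 4 isotopologues, exact masses
    rng = np.random.default_rng(config.seed + 1)  # independent of intensity noise
    ppm = config.mass_error_ppm * 1e-6

    ms1_rows, ms2_rows = [], []
    key_to_iso = {QUANT_KEYS[iso]: iso for iso in QUANT_ORDER}
    for row in intensities.itertuples(index=False):
        for key in ("nn", "oo", "on", "no"):
            intensity = getattr(row, key)
            if intensity <= 0:
                continue
            iso = key_to_iso[key]
            masses = table[iso].to_numpy()
            errors = rng.normal(0.0, ppm, size=len(masses)) if ppm > 0 else np.zeros(len(masses))
            observed = masses * (1.0 + errors)
            ms1_rows.append(
                [observed[0], intensity, "MS1", row.time_min, row.replicate, np.nan]
            )
            for frag_mass in observed:
                ms2_rows.append(
                    [frag_mass, intensity, "MS2", row.time_min, row.replicate, observed[0]]
                )
    ms1 = pd.DataFrame(ms1_rows, columns=PEAKLIST_COLUMNS)
    ms2 = pd.DataFrame(ms2_rows, columns=PEAKLIST_COLUMNS)
    return ms1, ms2, truth
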