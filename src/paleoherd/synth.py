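"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates the statistical structure its downstream stage
assumes and emits the ground-truth parameters alongside the data, so any
estimate can be scored without external files:

- tooth sequences: a seasonal δ¹⁸O cosine plus Gaussian analytical noise,
  with δ¹³C produced by pushing a seasonal C₄-fraction curve through the
  enamel mixing equation (diet opposition: C₄ intake peaks at the δ¹⁸O
  winter minimum);
- collagen datasets: correlated bivariate-normal (δ¹³C, δ¹⁵N) with %C/%N
  drawn so the C:N atomic ratio sits in the preservation window;
- mortality counts: one multinomial draw over age classes;
- MALDI spectra: Gaussian marker and shared collagen peaks over a smooth
  decaying baseline with white noise.

Seeding: one integer seed fans out to per-object child generators through
``numpy.random.SeedSequence(entropy=seed, spawn_key=(index,))``, so
extending a dataset never reshuffles earlier objects.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import dietmix
from .herdprof import MortalityCounts, PAYNE_CLASSES
from .seqmodel import ToothSequence
from .zooms import MaldiSpectrum, default_marker_panel

__all__ = [
    "child_rng",
    "ToothTruth",
    "gen_tooth_sequence",
    "gen_phase_pair",
    "gen_collagen_dataset",
    "gen_mortality_counts",
    "gen_maldi_spectrum",
]


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-object generator derived from one master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class ToothTruth:
    """Ground truth for one simulated tooth."""

    A: float                  # δ¹⁸O amplitude (‰), half-range
    X: float                  # annual period (mm of crown)
    x0: float                 # position of δ¹⁸O maximum (mm from ERJ)
    M: float                  # δ¹⁸O mean (‰)
    sigma: float              # analytical noise sd (‰)
    summer_pct_c4: float = 0.0
    winter_pct_c4: float = 0.0
    sigma_c: float = 0.2      # δ¹³C noise sd (‰)
    seed: int = 0

    @property
    def x0_over_X(self) -> float:
        return (self.x0 % self.X) / self.X


def gen_tooth_sequence(
    truth: ToothTruth,
    step: float = 1.2,
    crown_length: float = 18.0,
    seed: int | None = None,
    specimen_id: str = "SIM",
) -> tuple[ToothSequence, ToothTruth]:
    """Simulate one sequentially sampled tooth.

    δ¹⁸O follows the seasonal cosine with iid Gaussian noise.  The C₄
    dietary fraction varies sinusoidally between the summer value (at the
    δ¹⁸O maximum) and the winter value (at the minimum) and is converted
    to δ¹³C through the enamel mixing equation, with its own noise — the
    diet signal is therefore in phase opposition to δ¹⁸O when winter C₄
    intake exceeds summer intake.
    """
    if step <= 0:
        raise ValueError("sampling step must be positive")
    if crown_length < 4 * step:
        raise ValueError("crown length must allow at least 4 increments")
    rng = child_rng(seed if seed is not None else truth.seed, 0)
    x = np.arange(0.0, crown_length + 1e-9, step)
    phase = 2 * np.pi * (x - truth.x0) / truth.X
    d18O = truth.A * np.cos(phase) + truth.M + rng.normal(0.0, truth.sigma, x.size)

    mid = 0.5 * (truth.summer_pct_c4 + truth.winter_pct_c4)
    amp = 0.5 * (truth.winter_pct_c4 - truth.summer_pct_c4)
    pct = mid + amp * (1 - np.cos(phase)) - amp   # = summer at phase 0, winter at π
    d13C = np.array([dietmix.d13c_from_pct_c4(p, "enamel") for p in pct])
    d13C = d13C + rng.normal(0.0, truth.sigma_c, x.size)
    seq = ToothSequence(specimen_id=specimen_id, distance_mm=x, d18O=d18O, d13C=d13C)
    return seq, truth


def gen_phase_pair(
    D: float = 25.0,
    offset_deg: float = 180.0,
    sigma: float = 0.2,
    A_O: float = 3.0,
    A_C: float = 1.5,
    M_O: float = -5.0,
    M_C: float = -8.0,
    step: float = 1.0,
    length: float = 30.0,
    seed: int = 0,
    specimen_id: str = "SIMPAIR",
) -> tuple[ToothSequence, float]:
    """Paired δ¹⁸O/δ¹³C sinusoids with a known phase offset (degrees).

    Returns the sequence and the true offset; used to validate phase-shift
    recovery.
    """
    rng = child_rng(seed, 1)
    d = np.arange(0.0, length + 1e-9, step)
    psi_o = 0.7         # arbitrary nonzero reference phase
    psi_c = psi_o + math.radians(offset_deg)
    d18O = A_O * np.sin(2 * np.pi * d / D + psi_o) + M_O + rng.normal(0, sigma, d.size)
    d13C = A_C * np.sin(2 * np.pi * d / D + psi_c) + M_C + rng.normal(0, sigma, d.size)
    seq = ToothSequence(specimen_id=specimen_id, distance_mm=d, d18O=d18O, d13C=d13C)
    return seq, offset_deg % 360.0


def gen_collagen_dataset(
    n: int,
    mean_d13C: float = -17.7,
    mean_d15N: float = 7.5,
    sd_d13C: float = 0.8,
    sd_d15N: float = 0.9,
    correlation: float = 0.0,
    cn_window: tuple[float, float] = (3.15, 3.35),
    pctC_range: tuple[float, float] = (42.0, 45.0),
    yield_range: tuple[float, float] = (1.1, 11.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a site collagen table (defaults mimic a well-preserved
    caprine assemblage with independent δ¹³C/δ¹⁵N)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (-1.0 <= correlation <= 1.0):
        raise ValueError("|correlation| must be <= 1")
    if sd_d13C < 0 or sd_d15N < 0:
        raise ValueError("sds must be non-negative")
    rng = child_rng(seed, 2)
    cov = np.array(
        [
            [sd_d13C**2, correlation * sd_d13C * sd_d15N],
            [correlation * sd_d13C * sd_d15N, sd_d15N**2],
        ]
    )
    iso = rng.multivariate_normal([mean_d13C, mean_d15N], cov, size=n)
    pctC = rng.uniform(*pctC_range, n)
    cn = rng.uniform(*cn_window, n)
    # invert the atomic ratio: %N = %C · 14.007 / (12.011 · C:N)
    pctN = pctC * 14.007 / (12.011 * cn)
    yields = rng.uniform(*yield_range, n)
    return pd.DataFrame(
        {
            "specimen_id": [f"SIMC{i:03d}" for i in range(n)],
            "d13C": iso[:, 0],
            "d15N": iso[:, 1],
            "pctC": pctC,
            "pctN": pctN,
            "yield": yields,
            "true_cn": cn,
        }
    )


def gen_mortality_counts(
    probs: Sequence[float],
    N: int,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> MortalityCounts:
    """One multinomial draw of age-class death counts."""
    p = np.asarray(list(probs), dtype=float)
    if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("probabilities must be non-negative and sum to 1")
    if N < 1:
        raise ValueError("N must be >= 1")
    if labels is None:
        labels = PAYNE_CLASSES[: p.size]
    if len(labels) != p.size:
        raise ValueError("labels/probabilities length mismatch")
    rng = child_rng(seed, 3)
    counts = rng.multinomial(N, p)
    return MortalityCounts(labels=tuple(labels), counts=counts.astype(float))


#: non-diagnostic collagen peptide masses shared by sheep and goat spectra
SHARED_PEPTIDE_MASSES = (1105.6, 1427.7, 1580.8, 2131.1, 2883.2)


def gen_maldi_spectrum(
    taxon: str,
    peak_snr: float = 20.0,
    mz_range: tuple[float, float] = (900.0, 4000.0),
    step: float = 0.25,
    noise_sigma: float = 1.0,
    baseline: bool = True,
    seed: int = 0,
    specimen_id: str = "SIMZ",
) -> MaldiSpectrum:
    """Simulate a linear-mode MALDI-ToF collagen fingerprint.

    Gaussian peaks are placed at the requested taxon's diagnostic marker
    masses and at shared non-diagnostic collagen masses; peak width scales
    with m/z as in linear mode.  ``peak_snr`` sets diagnostic peak height
    in units of the white-noise sd.  With ``noise_sigma=0`` and
    ``baseline=False`` the peak apexes sit exactly at the marker masses.
    """
    if peak_snr <= 0:
        raise ValueError("peak S/N must be positive")
    panel = default_marker_panel()
    marker_mz = [m.mz for m in panel.diagnostic() if m.taxon == taxon]
    if not marker_mz:
        raise ValueError(f"taxon {taxon!r} not in marker panel")
    rng = child_rng(seed, 4)
    mz = np.arange(mz_range[0], mz_range[1] + 1e-9, step)
    amp = peak_snr * (noise_sigma if noise_sigma > 0 else 1.0)
    y = np.zeros_like(mz)
    for center in marker_mz:
        width = center / 3000.0           # ≈1 Da FWHM/2.35 at m/z 3000
        y += amp * np.exp(-0.5 * ((mz - center) / width) ** 2)
    for center in SHARED_PEPTIDE_MASSES:
        width = center / 3000.0
        y += 1.3 * amp * np.exp(-0.5 * ((mz - center) / width) ** 2)
    if baseline:
        offset = 5.0 * (noise_sigma if noise_sigma > 0 else 1.0)
        y += 0.4 * amp * np.exp(-(mz - mz_range[0]) / 900.0) + offset
    if noise_sigma > 0:
        y += rng.normal(0.0, noise_sigma, mz.size)
    y = np.clip(y, 0.0, None)
    return MaldiSpectrum(specimen_id=specimen_id, mz=mz, intensity=y, metadata=f"synthetic:{taxon}")
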