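"""ZooMS: sheep/goat identification from collagen peptide mass fingerprints.

Sheep (*Ovis*) and goat (*Capra*) bone collagen yield nearly identical
tryptic peptide fingerprints in linear-mode MALDI-ToF, with the diagnostic
exception of the COL1α2 757(+16) peptide: m/z 3017.4 / 3033.4 in sheep vs
3077.4 / 3093.4 in goat.  This module processes raw profile spectra
(baseline estimation, Savitzky–Golay smoothing, peak picking with a local
signal-to-noise criterion) and calls the genus from marker matches within a
mass tolerance.

The COL1α2 375 peptide masses (m/z 1154, 2028, 2044) are caprine-informative
and are reported as supporting evidence but never decide a call.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as scisignal

__all__ = [
    "MaldiSpectrum",
    "ProcessingParams",
    "Peak",
    "MaldiPeakList",
    "Marker",
    "MarkerPanel",
    "default_marker_panel",
    "MarkerMatch",
    "TaxonCall",
    "process_spectrum",
    "call_taxon",
    "batch_report",
    "read_spectrum",
]


@dataclass
class MaldiSpectrum:
    """Profile-mode spectrum: strictly increasing m/z, intensities >= 0."""

    specimen_id: str
    mz: np.ndarray
    intensity: np.ndarray
    metadata: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size != self.intensity.size:
            raise ValueError("mz and intensity length mismatch")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class ProcessingParams:
    """Spectrum-processing tunables.

    The baseline is estimated by taking a low percentile
    (``baseline_percentile``) of the intensity in each of
    ``baseline_segments`` windows and interpolating between window
    centres.  Smoothing is Savitzky–Golay with a window expressed in m/z
    (converted to an odd point count) applied ``sg_cycles`` times.  Peaks
    must clear both a signal-to-noise threshold (noise = scaled MAD of the
    high-frequency residual) and a relative-intensity floor expressed in
    per-mille of the base peak.
    """

    baseline_segments: int = 15
    baseline_percentile: float = 25.0
    sg_window_mz: float = 0.3
    sg_cycles: int = 2
    sn_threshold: float = 3.5
    picking_height_permille: float = 75.0
    min_points: int = 100


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    snr: float


@dataclass
class MaldiPeakList:
    specimen_id: str
    peaks: list[Peak]
    noise: float

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])


def _estimate_baseline(mz: np.ndarray, y: np.ndarray, params: ProcessingParams) -> np.ndarray:
    edges = np.linspace(0, y.size, params.baseline_segments + 1).astype(int)
    centers, levels = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b <= a:
            continue
        centers.append(mz[(a + b - 1) // 2])
        levels.append(np.percentile(y[a:b], params.baseline_percentile))
    return np.interp(mz, centers, levels)


def process_spectrum(spec: MaldiSpectrum, params: ProcessingParams | None = None) -> MaldiPeakList:
    """Baseline-subtract, smooth and peak-pick a profile spectrum.

    Peak centroids are refined with an intensity-weighted mean over a few
    points around each apex; S/N is apex intensity over the robust noise
    estimate.  A flat (constant) spectrum yields an empty peak list.
    """
    params = params or ProcessingParams()
    if len(spec) < params.min_points:
        raise ValueError(f"spectrum too short ({len(spec)} points)")
    mz, raw = spec.mz, spec.intensity

    base = _estimate_baseline(mz, raw, params)
    y = raw - base

    step = float(np.median(np.diff(mz)))
    win = max(5, int(round(params.sg_window_mz / step)) | 1)
    if win >= y.size:
        raise ValueError("smoothing window exceeds spectrum length")
    smooth = y.copy()
    for _ in range(params.sg_cycles):
        smooth = scisignal.savgol_filter(smooth, window_length=win, polyorder=2)

    # robust raw-noise sd: first differences cancel peaks and baseline,
    # MAD/(sqrt(2)/1.4826) recovers sigma for white noise
    noise = float(1.4826 * np.median(np.abs(np.diff(y))) / math.sqrt(2.0))
    if noise <= 0:
        noise = max(float(np.std(y - smooth)), 1e-12)

    floor = params.picking_height_permille / 1000.0 * float(smooth.max(initial=0.0))
    # lenient pre-pick, final cut on the variance-reduced apex estimate below
    height = max(0.7 * params.sn_threshold * noise, floor, 1e-12)
    idx, _ = scisignal.find_peaks(smooth, height=height, distance=max(1, win // 2))

    peaks: list[Peak] = []
    for i in idx:
        centroid = float(mz[i])
        apex = float(smooth[i])
        if 0 < i < len(smooth) - 1:
            # apex height from the 3-point neighbourhood (lower variance than
            # the raw local maximum, which is upward-biased by noise)
            apex = float(smooth[i - 1 : i + 2].mean())
            # parabolic apex interpolation on the smoothed profile
            denom = smooth[i - 1] - 2 * smooth[i] + smooth[i + 1]
            if denom < 0:
                delta = 0.5 * (smooth[i - 1] - smooth[i + 1]) / denom
                if abs(delta) <= 1.0:
                    centroid = float(mz[i] + delta * (mz[i + 1] - mz[i]))
        snr = apex / noise
        if snr < params.sn_threshold or apex < floor:
            continue
        peaks.append(Peak(mz=centroid, intensity=apex, snr=float(snr)))
    return MaldiPeakList(specimen_id=spec.specimen_id, peaks=peaks, noise=noise)


@dataclass(frozen=True)
class Marker:
    name: str
    taxon: str | None        # None = caprine-informative, never decides a call
    mz: float


@dataclass(frozen=True)
class MarkerPanel:
    markers: tuple[Marker, ...]

    def diagnostic(self) -> tuple[Marker, ...]:
        return tuple(m for m in self.markers if m.taxon is not None)

    def supporting(self) -> tuple[Marker, ...]:
        return tuple(m for m in self.markers if m.taxon is None)


def default_marker_panel() -> MarkerPanel:
    """COL1α2 757(+16) sheep/goat markers plus the caprine-informative
    COL1α2 375 masses."""
    return MarkerPanel(
        markers=(
            Marker("COL1a2 757(+16) 3017.4", "Ovis", 3017.4),
            Marker("COL1a2 757(+16) 3033.4", "Ovis", 3033.4),
            Marker("COL1a2 757(+16) 3077.4", "Capra", 3077.4),
            Marker("COL1a2 757(+16) 3093.4", "Capra", 3093.4),
            Marker("COL1a2 375 1154", None, 1154.0),
            Marker("COL1a2 375 2028", None, 2028.0),
            Marker("COL1a2 375 2044", None, 2044.0),
        )
    )


@dataclass(frozen=True)
class MarkerMatch:
    marker: Marker
    observed_mz: float
    mass_error: float
    snr: float


@dataclass
class TaxonCall:
    specimen_id: str
    call: str                 # Ovis | Capra | Ambiguous | Indeterminate
    matches: list[MarkerMatch]
    supporting_matches: list[MarkerMatch] = field(default_factory=list)


def _match_markers(
    peaks: MaldiPeakList, markers: Iterable[Marker], tolerance: float
) -> list[MarkerMatch]:
    out = []
    mzs = peaks.mzs
    for m in markers:
        if mzs.size == 0:
            continue
        j = int(np.argmin(np.abs(mzs - m.mz)))
        err = float(mzs[j] - m.mz)
        if abs(err) <= tolerance:
            p = peaks.peaks[j]
            out.append(MarkerMatch(marker=m, observed_mz=p.mz, mass_error=err, snr=p.snr))
    return out


def call_taxon(
    peaks: MaldiPeakList, panel: MarkerPanel | None = None, tolerance: float = 0.5
) -> TaxonCall:
    """Call Ovis vs Capra from diagnostic marker matches.

    Ovis iff at least one sheep 757(+16) marker matches and no goat marker
    does (and symmetrically); both → Ambiguous; neither → Indeterminate.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    panel = panel or default_marker_panel()
    if not panel.markers:
        raise ValueError("empty marker panel")
    diag = _match_markers(peaks, panel.diagnostic(), tolerance)
    supp = _match_markers(peaks, panel.supporting(), tolerance)
    taxa = {m.marker.taxon for m in diag}
    if taxa == {"Ovis"}:
        call = "Ovis"
    elif taxa == {"Capra"}:
        call = "Capra"
    elif len(taxa) > 1:
        call = "Ambiguous"
    else:
        call = "Indeterminate"
    return TaxonCall(
        specimen_id=peaks.specimen_id, call=call, matches=diag, supporting_matches=supp
    )


def read_spectrum(path: str | Path, specimen_id: str | None = None) -> MaldiSpectrum:
    """Read a spectrum from mzML or two-column m/z–intensity text."""
    path = Path(path)
    sid = specimen_id or path.stem
    if path.suffix.lower() == ".mzml":
        from pyteomics import mzml as pymzml

        with pymzml.read(str(path)) as reader:
            entry = next(iter(reader))
        return MaldiSpectrum(
            specimen_id=sid,
            mz=np.asarray(entry["m/z array"], dtype=float),
            intensity=np.asarray(entry["intensity array"], dtype=float),
            metadata=f"mzML:{path.name}",
        )
    data = np.loadtxt(path, delimiter="," if path.suffix.lower() == ".csv" else None)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (m/z, intensity)")
    return MaldiSpectrum(
        specimen_id=sid, mz=data[:, 0], intensity=data[:, 1], metadata=f"text:{path.name}"
    )


def batch_report(
    spectra: Sequence[str | Path] | str | Path,
    panel: MarkerPanel | None = None,
    params: ProcessingParams | None = None,
    tolerance: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Process a directory (or list) of spectrum files and tabulate calls.

    Unreadable files are skipped and reported in the table with call
    ``ReadError``.  Returns (per-specimen table, summary counts by call).
    """
    if isinstance(spectra, (str, Path)):
        root = Path(spectra)
        paths = sorted(
            p for p in root.iterdir()
            if p.suffix.lower() in (".mzml", ".txt", ".csv", ".tsv", ".dat")
        )
        if not paths:
            raise ValueError(f"no readable spectra in {root}")
    else:
        paths = [Path(p) for p in spectra]
        if not paths:
            raise ValueError("no spectra supplied")
    rows = []
    for p in sorted(paths):
        try:
            spec = read_spectrum(p)
            call = call_taxon(process_spectrum(spec, params), panel, tolerance)
            rows.append(
                {
                    "specimen_id": call.specimen_id,
                    "call": call.call,
                    "n_marker_matches": len(call.matches),
                    "matched_markers": ";".join(m.marker.name for m in call.matches),
                    "file": p.name,
                }
            )
        except (OSError, ValueError) as exc:
            rows.append(
                {
                    "specimen_id": p.stem,
                    "call": "ReadError",
                    "n_marker_matches": 0,
                    "matched_markers": str(exc),
                    "file": p.name,
                }
            )
    table = pd.DataFrame(rows).sort_values("specimen_id").reset_index(drop=True)
    summary = table["call"].value_counts().to_dict()
    return table, {str(k): int(v) for k, v in summary.items()}
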