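"""Power spectra and band-power endpoints.

Spectra follow the convention of the centralised analysis: a Welch
periodogram (Hamming window, 50% overlap, 512 frequency values, i.e.
1024-sample segments at 100 Hz) rescaled so that the *sum* of all spectrum
values equals the mean squared value of the analysed signal.  On the
resulting grid (bin width 100/1024 Hz) the bins whose centres lie strictly
between 1 and 48 Hz form the 481-bin export grid running from ~1.074 to
~47.95 Hz; band powers and total power are sums over that grid.

Because every band power is a sum of spectrum values, multiplying the
signal by a gain g multiplies every raw power by g**2 and cancels exactly
in relative power and in raw-power percent change — the property that lets
heterogeneous recording hardware be compared at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .edf_io import Recording
from .errors import DegenerateSpectrumError, InsufficientDataError
from .preprocess import ArtifactMask, CleanSegmentSet

__all__ = [
    "Band",
    "BandScheme",
    "DEFAULT_SCHEME",
    "PowerSpectrum",
    "BandPowerRecord",
    "welch_psd",
    "psd_of_segments",
    "band_powers",
    "relative_band",
    "percent_change",
    "epoch_powers",
    "aggregate_bins",
]


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float


@dataclass(frozen=True)
class BandScheme:
    """Contiguous, non-overlapping frequency bands.

    Band membership is half-open on bin centres, [low, high), except the
    final band which is closed at its upper edge.  This reconciles the two
    ways band edges are conventionally written (e.g. "1-4 Hz" and
    "1-3.9 Hz").
    """

    bands: tuple[Band, ...]
    total_range: tuple[float, float] = (1.0, 48.0)

    def __post_init__(self) -> None:
        for a, b in zip(self.bands, self.bands[1:]):
            if a.high != b.low:
                raise ValueError(f"bands {a.name} and {b.name} are not contiguous")
        if any(b.low >= b.high for b in self.bands):
            raise ValueError("each band needs low < high")

    def __getitem__(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"unknown band {name!r}")

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def replace_band(self, name: str, low: float, high: float) -> "BandScheme":
        """A copy with one band's edges changed (used by local dialects).

        The result may be non-contiguous with its neighbours; dialect
        schemes are therefore rebuilt as standalone band lists.
        """
        bands = tuple(
            Band(b.name, low, high) if b.name == name else b for b in self.bands
        )
        obj = object.__new__(BandScheme)
        object.__setattr__(obj, "bands", bands)
        object.__setattr__(obj, "total_range", self.total_range)
        return obj


DEFAULT_SCHEME = BandScheme(
    bands=(
        Band("Delta", 1.0, 4.0),
        Band("Theta-1", 4.0, 6.0),
        Band("Theta-2", 6.0, 8.0),
        Band("Alpha-1", 8.0, 11.0),
        Band("Alpha-2", 11.0, 14.0),
        Band("Beta-1", 14.0, 18.0),
        Band("Beta-2", 18.0, 32.0),
        Band("Gamma-1", 32.0, 48.0),
    )
)


@dataclass
class PowerSpectrum:
    """Power per frequency bin under the sum-equals-mean-square convention.

    ``freqs``/``power`` cover the full one-sided FFT grid of the analysis
    (0 .. Nyquist); ``export_grid()`` restricts to the bins with centres
    strictly inside (1, 48) Hz, reproducing the 481-bin export layout.
    """

    freqs: np.ndarray
    power: np.ndarray
    segment_count: int
    normalization: str = "sum-equals-mean-square"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < -1e-12 * max(self.power.max(initial=0.0), 1.0)):
            raise ValueError("negative power")
        self.power = np.maximum(self.power, 0.0)

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def export_grid(
        self, low: float = 1.0, high: float = 48.0
    ) -> tuple[np.ndarray, np.ndarray]:
        """(freqs, power) restricted to bin centres strictly in (low, high)."""
        m = (self.freqs > low) & (self.freqs < high)
        return self.freqs[m], self.power[m]

    def band_sum(self, low: float, high: float, closed_high: bool = False) -> float:
        """Sum of power over bins with centre in [low, high) (or [low, high])."""
        if closed_high:
            m = (self.freqs >= low) & (self.freqs <= high)
        else:
            m = (self.freqs >= low) & (self.freqs < high)
        return float(self.power[m].sum())

    def range_sum(self, total_range: tuple[float, float]) -> float:
        """Total power: bins with centre strictly inside ``total_range``.

        For the default (1, 48) range this is exactly the export grid, so
        "total power from 1 to 48 Hz" and the sum over the eight bands
        coincide.
        """
        lo, hi = total_range
        m = (self.freqs > lo) & (self.freqs < hi)
        return float(self.power[m].sum())


@dataclass
class BandPowerRecord:
    """Raw and relative band power for one analysed window."""

    raw: dict[str, float]
    total: float
    relative: dict[str, float]
    meta: dict = field(default_factory=dict)


def _segment_matrix(x: np.ndarray, nperseg: int, noverlap: int) -> np.ndarray:
    """Consecutive (possibly overlapping) full segments of ``x``; may be empty."""
    step = nperseg - noverlap
    n_seg = 1 + (len(x) - nperseg) // step if len(x) >= nperseg else 0
    if n_seg <= 0:
        return np.empty((0, nperseg))
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    return x[idx]


def psd_of_segments(
    segments: list[np.ndarray],
    rate: float = 100.0,
    n_freq: int = 512,
    overlap: float = 0.5,
    window: str = "hamming",
) -> PowerSpectrum:
    """Welch periodogram over clean spans, sum-equals-mean-square scaled.

    Each span is tiled independently with 50%-overlapping Hamming-windowed
    segments of ``2 * n_freq`` samples (trailing partial segments dropped;
    segments never bridge artifact gaps).  Squared-magnitude FFTs are
    averaged over all segments of all spans and rescaled so the sum over
    the full one-sided grid equals the mean squared value of the analysed
    samples.
    """
    nperseg = 2 * n_freq
    noverlap = int(round(nperseg * overlap))
    win = get_window(window, nperseg, fftbins=True)

    mats = [
        _segment_matrix(np.asarray(x, dtype=float), nperseg, noverlap)
        for x in segments
    ]
    mats = [m for m in mats if m.size]
    if not mats:
        raise InsufficientDataError(
            f"no clean span holds a full {nperseg}-sample Welch segment"
        )
    segs = np.vstack(mats)
    spec = np.fft.rfft(segs * win, axis=1)
    pxx = np.mean(np.abs(spec) ** 2, axis=0)

    mean_square = float(np.mean(segs**2))
    total = float(pxx.sum())
    if total > 0:
        pxx = pxx * (mean_square / total)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / rate)
    return PowerSpectrum(freqs=freqs, power=pxx, segment_count=segs.shape[0])


def welch_psd(
    recording: Recording,
    clean: CleanSegmentSet,
    n_freq: int = 512,
    overlap: float = 0.5,
    window: str = "hamming",
) -> PowerSpectrum:
    """PSD of the artifact-free spans of a pre-processed recording."""
    return psd_of_segments(
        clean.extract(recording),
        rate=recording.sampling_rate,
        n_freq=n_freq,
        overlap=overlap,
        window=window,
    )


def band_powers(
    spectrum: PowerSpectrum,
    scheme: BandScheme = DEFAULT_SCHEME,
    meta: dict | None = None,
) -> BandPowerRecord:
    """Sum raw power into bands; relative power divides by the total.

    Band bins are selected by centre in [low, high) (final band closed at
    its top edge); the total is the sum over the scheme's ``total_range``.
    """
    raw = {}
    for i, b in enumerate(scheme.bands):
        closed = i == len(scheme.bands) - 1
        raw[b.name] = spectrum.band_sum(b.low, b.high, closed_high=closed)
    total = spectrum.range_sum(scheme.total_range)
    if total <= 0:
        raise DegenerateSpectrumError("total power is zero; relative power undefined")
    relative = {k: v / total for k, v in raw.items()}
    return BandPowerRecord(raw=raw, total=total, relative=relative, meta=meta or {})


def relative_band(
    spectrum: PowerSpectrum,
    band: str | tuple[float, float],
    scheme: BandScheme = DEFAULT_SCHEME,
    total_range: tuple[float, float] = (1.0, 48.0),
) -> float:
    """Band power divided by total power over a configurable range.

    ``total_range`` supports the analysis dialects seen across sites: the
    default (1, 48) Hz, and e.g. (0.5, 48) Hz for the ring-testing
    definition of relative gamma.  Widening the range can only grow the
    denominator, so the returned fraction never increases.
    """
    if isinstance(band, str):
        b = scheme[band]
        low, high = b.low, b.high
        closed = b.name == scheme.bands[-1].name
    else:
        low, high = band
        closed = True
    num = spectrum.band_sum(low, high, closed_high=closed)
    den = spectrum.range_sum(total_range)
    if den <= 0:
        raise DegenerateSpectrumError("total power is zero; relative power undefined")
    return num / den


def percent_change(
    post: BandPowerRecord,
    pre: BandPowerRecord,
    band: str,
    use: str = "raw",
) -> float:
    """Percent change from baseline: 100 * (post - pre) / pre.

    ``use`` selects raw power (the default, as in the central analysis) or
    relative power.  Raw-power percent change is invariant under any
    constant gain applied to the whole recording.
    """
    source = {"raw": (post.raw, pre.raw), "relative": (post.relative, pre.relative)}
    try:
        post_map, pre_map = source[use]
    except KeyError:
        raise ValueError(f"use must be 'raw' or 'relative', got {use!r}") from None
    if band not in pre_map:
        raise KeyError(f"unknown band {band!r}")
    p0 = pre_map[band]
    if p0 <= 0:
        raise DegenerateSpectrumError(f"baseline {band} power is zero")
    return 100.0 * (post_map[band] - p0) / p0


def epoch_powers(
    recording: Recording,
    mask: ArtifactMask,
    epoch_s: float = 10.0,
    scheme: BandScheme = DEFAULT_SCHEME,
    window: str = "hamming",
) -> list[BandPowerRecord]:
    """Per-epoch band powers (the local-analysis dialect).

    The recording is tiled into consecutive epochs of ``epoch_s``; epochs
    overlapping the artifact mask are skipped; each surviving epoch is a
    single Hamming-windowed periodogram segment (frequency resolution
    1/epoch_s) normalised sum-equals-mean-square.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    rate = recording.sampling_rate
    nper = int(round(epoch_s * rate))
    n_epochs = recording.n_samples // nper
    out: list[BandPowerRecord] = []
    for k in range(n_epochs):
        t0, t1 = k * epoch_s, (k + 1) * epoch_s
        if mask.overlaps(t0, t1):
            continue
        seg = recording.samples[k * nper : (k + 1) * nper]
        spec = psd_of_segments([seg], rate=rate, n_freq=nper // 2, window=window)
        rec = band_powers(spec, scheme, meta={"epoch": k, "start_s": t0})
        out.append(rec)
    return out


def aggregate_bins(
    epoch_records: list[BandPowerRecord],
    bin_width_s: float,
    epoch_s: float = 10.0,
):
    """Mean and SEM of band powers per time bin over surviving epochs.

    Returns a DataFrame with one row per (bin, band): mean/SEM of raw and
    relative power and the number of surviving epochs n (SEM = sd/sqrt(n),
    0 for n = 1).
    """
    import pandas as pd

    if bin_width_s % epoch_s != 0:
        raise ValueError("bin_width_s must be a multiple of epoch_s")
    per_bin = int(round(bin_width_s / epoch_s))
    rows = []
    groups: dict[int, list[BandPowerRecord]] = {}
    for rec in epoch_records:
        groups.setdefault(rec.meta["epoch"] // per_bin, []).append(rec)
    for bin_idx in sorted(groups):
        recs = groups[bin_idx]
        n = len(recs)
        for band in recs[0].raw:
            raw = np.array([r.raw[band] for r in recs])
            rel = np.array([r.relative[band] for r in recs])
            rows.append(
                {
                    "bin": bin_idx,
                    "start_s": bin_idx * bin_width_s,
                    "band": band,
                    "n": n,
                    "mean_raw": raw.mean(),
                    "sem_raw": raw.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                    "mean_relative": rel.mean(),
                    "sem_relative": rel.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)
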