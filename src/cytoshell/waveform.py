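"""Simplified multipeak transit waveforms and matched-filter event detection.

A particle crossing a column of electrode pairs produces one signal lobe
per pair with alternating polarity (differential wiring).  The simulator
renders each lobe as a Gaussian pulse of fixed temporal width centred at
(pair position)/velocity and adds white noise; the detector runs a
matched filter at a nominal velocity to find events, measures the lobe
spacing to estimate velocity (velocity = electrode pitch / spacing), and
recovers amplitude by a least-squares template fit at that velocity.
Velocity normalisation is what lets signal amplitude be compared across
particles with different transit speeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, find_peaks

__all__ = ["WaveformTemplate", "simulate_waveform", "detect_events", "render_template"]


@dataclass(frozen=True)
class WaveformTemplate:
    """Geometry and sampling of the electrode column."""

    n_electrode_pairs: int = 9
    pitch: float = 50e-6  # m, centre-to-centre pair spacing
    sample_rate: float = 230_000.0  # Hz
    lobe_width: float = 5e-5  # s, Gaussian sigma of one lobe
    polarity: tuple[int, ...] | None = None  # default alternating +1/-1

    def __post_init__(self) -> None:
        if self.n_electrode_pairs < 2:
            raise ValueError("need at least 2 electrode pairs")
        if self.sample_rate <= 0 or self.pitch <= 0 or self.lobe_width <= 0:
            raise ValueError("pitch, sample rate and lobe width must be positive")
        pol = self.polarity
        if pol is None:
            pol = tuple((-1) ** i for i in range(self.n_electrode_pairs))
        if len(pol) != self.n_electrode_pairs:
            raise ValueError("polarity pattern length must equal the number of pairs")
        object.__setattr__(self, "polarity", tuple(int(p) for p in pol))

    def span_s(self, velocity: float) -> float:
        """Temporal extent of one transit at the given velocity."""
        return (self.n_electrode_pairs - 1) * self.pitch / velocity + 8 * self.lobe_width


def render_template(
    template: WaveformTemplate, velocity: float, amplitude: float = 1.0
) -> np.ndarray:
    """Sampled noise-free transit waveform at the given velocity."""
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    dt = 1.0 / template.sample_rate
    span = template.span_s(velocity)
    t = np.arange(0.0, span, dt)
    t0 = 4 * template.lobe_width
    sig = np.zeros_like(t)
    for i, pol in enumerate(template.polarity):
        centre = t0 + i * template.pitch / velocity
        sig += pol * np.exp(-0.5 * ((t - centre) / template.lobe_width) ** 2)
    return amplitude * sig


def simulate_waveform(
    amplitude: float,
    velocity: float,
    template: WaveformTemplate,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int | None = None,
    event_starts: list[float] | None = None,
) -> np.ndarray:
    """White-noise record containing one or more transits.

    ``event_starts`` lists event start times in seconds (default: one
    event one transit-span into the record).  ``n_samples`` sets the
    record length (default: event extent plus padding).
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    dt = 1.0 / template.sample_rate
    pulse = render_template(template, velocity, amplitude)
    if event_starts is None:
        event_starts = [2.0 * template.span_s(velocity)]
    if n_samples is None:
        n_samples = int((max(event_starts) + 5 * template.span_s(velocity)) / dt)
    sig = rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 else np.zeros(n_samples)
    for start in event_starts:
        i0 = int(round(start / dt))
        i1 = min(i0 + len(pulse), n_samples)
        if i0 < n_samples:
            sig[i0:i1] += pulse[: i1 - i0]
    return sig


def _lobe_positions(window: np.ndarray, template: WaveformTemplate, dt: float) -> np.ndarray:
    """Sub-sample lobe-centre positions (in samples) via single-lobe filtering."""
    half = max(int(4 * template.lobe_width / dt), 1)
    tt = np.arange(-half, half + 1) * dt
    lobe = np.exp(-0.5 * (tt / template.lobe_width) ** 2)
    corr = fftconvolve(window, lobe[::-1], mode="same")
    # lobes alternate in sign: peak-pick on |corr|
    mag = np.abs(corr)
    peaks, props = find_peaks(mag, height=0.3 * mag.max(), distance=max(int(len(window) / (3 * template.n_electrode_pairs)), 1))
    # keep the strongest n_pairs peaks, in positional order
    if len(peaks) > template.n_electrode_pairs:
        keep = np.sort(np.argsort(props["peak_heights"])[-template.n_electrode_pairs:])
        peaks = peaks[keep]
    refined = []
    for p in peaks:
        if 0 < p < len(mag) - 1:
            y0, y1, y2 = mag[p - 1], mag[p], mag[p + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))
            refined.append(p + delta)
        else:
            refined.append(float(p))
    return np.asarray(refined)


def detect_events(
    signal: np.ndarray,
    template: WaveformTemplate,
    nominal_velocity: float = 0.2,
    threshold: float = 5.0,
) -> list[tuple[float, float]]:
    """Detect transits and estimate (amplitude, velocity) for each.

    Candidate events come from a velocity-insensitive envelope statistic:
    the magnitude of a single-lobe matched filter, averaged over one
    transit span (an alternating-polarity full-template filter would
    collapse under lobe-spacing mismatch when the true velocity differs
    from nominal).  Peaks exceeding ``threshold`` robust noise units mark
    events.  Around each, lobe centres are located and their median
    spacing gives the velocity (pitch / spacing); the amplitude is the
    least-squares scale of the re-rendered template at that velocity.
    """
    signal = np.asarray(signal, dtype=float)
    kernel = render_template(template, nominal_velocity)
    if len(signal) <= len(kernel):
        raise ValueError("signal must be longer than the template")
    dt = 1.0 / template.sample_rate
    half = max(int(4 * template.lobe_width / dt), 1)
    tt = np.arange(-half, half + 1) * dt
    lobe = np.exp(-0.5 * (tt / template.lobe_width) ** 2)
    span_n = max(int(template.span_s(nominal_velocity) / dt), 1)
    env = fftconvolve(np.abs(fftconvolve(signal, lobe[::-1], mode="same")), np.ones(span_n) / span_n, mode="same")
    # noise floor and scale from the lower quantiles: events are sparse in
    # time, so the bottom of the envelope distribution is noise-only.  The
    # envelope is heavily smoothed, so a half-width (P50-P16) scale tracks
    # its slow fluctuations far better than a point-wise MAD.
    p50, p16 = np.percentile(env, [50, 16])
    floor = p50
    sigma = (p50 - p16) or 1e-30
    min_sep = max(int(2 * span_n), 1)
    peaks, _ = find_peaks(
        env,
        height=floor + threshold * sigma,
        prominence=threshold * sigma,
        distance=min_sep,
    )

    events: list[tuple[float, float]] = []
    half_win = int(0.75 * template.span_s(nominal_velocity) / dt)
    for p in peaks:
        lo = max(p - half_win, 0)
        hi = min(p + half_win, len(signal))
        window = signal[lo:hi]
        lobes = _lobe_positions(window, template, dt)
        if len(lobes) < 2:
            continue
        spacing = float(np.median(np.diff(lobes))) * dt
        if spacing <= 0:
            continue
        velocity = template.pitch / spacing
        # least-squares amplitude of the template at the estimated velocity,
        # scanning alignment within the window
        pulse = render_template(template, velocity)
        if len(pulse) >= len(window):
            pad = len(pulse) - len(window) + 1
            window = signal[max(lo - pad // 2, 0): min(hi + pad, len(signal))]
        corr = fftconvolve(window, pulse[::-1], mode="valid")
        amp = float(corr[np.argmax(np.abs(corr))] / np.dot(pulse, pulse))
        events.append((amp, velocity))
    return events
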