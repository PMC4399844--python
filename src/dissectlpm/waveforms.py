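"""Periodic waveforms: synthesis, CSV I/O, resampling and pseudo-measured
pressure fixtures.

The bench inflow the circuit model was originally driven with is not part
of any public record, so a physiologically shaped stand-in is synthesised:
a half-sine ejection lobe over the systolic fraction of the cycle plus an
optional constant diastolic leak.  The shape is realised as a truncated
Fourier series with closed-form harmonic coefficients and a Lanczos sigma
taper, which makes it smooth (friendly to stiff integration), exactly
periodic, and keeps the cycle mean exactly at its closed form
``(2/pi)*peak*systolic_fraction + leak*(1 - systolic_fraction)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "WaveformFormatError",
    "PeriodicWaveform",
    "synth_inflow",
    "read_waveform",
    "write_waveform",
    "make_fixture",
]

MIN_SAMPLES = 16


class WaveformFormatError(ValueError):
    """Raised for malformed waveform CSV files."""


@dataclass
class PeriodicWaveform:
    """One period of a uniformly sampled periodic signal.

    ``samples[k]`` is the value at ``t = k*period/n``; the grid covers
    ``[0, period)`` and evaluation at arbitrary times wraps periodically
    using a periodic cubic spline.
    """

    samples: np.ndarray
    period: float
    kind: str = "flow"  # "flow" (ml/s) or "pressure" (mmHg)
    _spline: Optional[CubicSpline] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < MIN_SAMPLES:
            raise WaveformFormatError(
                f"a periodic waveform needs >= {MIN_SAMPLES} samples in one period, "
                f"got {self.samples.size}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise WaveformFormatError("waveform samples must be finite")
        if not (self.period > 0.0) or not math.isfinite(self.period):
            raise WaveformFormatError(f"period must be positive, got {self.period!r}")
        if self.kind not in ("flow", "pressure"):
            raise WaveformFormatError(f"kind must be 'flow' or 'pressure', got {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * (self.period / self.n_samples)

    def mean(self) -> float:
        """Cycle mean (the rectangle rule is the exact DC Fourier
        coefficient of the sampled signal)."""
        return float(self.samples.mean())

    def _get_spline(self) -> CubicSpline:
        if self._spline is None:
            t = np.append(self.time, self.period)
            v = np.append(self.samples, self.samples[0])
            self._spline = CubicSpline(t, v, bc_type="periodic")
        return self._spline

    def __call__(self, t):
        """Evaluate at time(s) ``t`` (s), wrapping periodically."""
        return self._get_spline()(np.mod(t, self.period))

    def resample(self, n: int) -> "PeriodicWaveform":
        """Resample to ``n`` uniform samples per period (periodic cubic
        interpolation)."""
        grid = np.arange(n) * (self.period / n)
        return PeriodicWaveform(self(grid), self.period, self.kind)


def _halfsine_coefficients(
    period: float, peak: float, systolic_fraction: float, n_harm: int
) -> np.ndarray:
    """Closed-form complex Fourier coefficients c_0..c_K of the raw lobe
    q(t) = peak*sin(pi t/ts) on [0, ts], 0 on (ts, T)."""
    ts = systolic_fraction * period
    a = math.pi / ts
    k = np.arange(n_harm + 1)
    w = 2.0 * math.pi * k / period
    # ejection lobe: int_0^ts sin(a t) e^{-i w t} dt = a (1 + e^{-i w ts})/(a^2 - w^2)
    denom = a * a - w * w
    resonant = np.abs(denom) < 1e-9 * a * a
    with np.errstate(divide="ignore", invalid="ignore"):
        lobe = a * (1.0 + np.exp(-1j * w * ts)) / denom
    lobe[resonant] = -0.5j * ts  # limit w -> a
    return peak * lobe / period


def synth_inflow(
    period: float = 1.0,
    peak_flow: float = 250.0,
    systolic_fraction: float = 0.35,
    diastolic_leak: float = 10.0,
    shape: str = "halfsine",
    n_samples: int = 1024,
    n_harmonics: int = 12,
) -> PeriodicWaveform:
    """Synthesise a pulsatile inflow waveform (ml/s).

    The default is a half-sine ejection over ``[0, systolic_fraction*T]``
    riding on a constant baseline of ``diastolic_leak`` (so the flow never
    falls to zero, as with a bench pump that idles at a small forward
    flow), smoothed by sigma-tapered Fourier truncation.  Cycle mean is
    exactly ``(2/pi)*peak_flow*systolic_fraction + diastolic_leak``.

    The 1 s default period puts the tear Womersley numbers of the modelled
    geometry near 5 (4 mm tear) and 13 (10 mm tear), the pulsatility regime
    of a resting adult aorta.  The 12-harmonic truncation reflects that
    pulsatile aortic signal power concentrates in the first ~10 harmonics.
    """
    if shape != "halfsine":
        raise ValueError(f"unknown inflow shape {shape!r}")
    if not (0.0 < systolic_fraction < 1.0):
        raise ValueError(f"systolic_fraction must lie in (0, 1), got {systolic_fraction}")
    if peak_flow < 0.0:
        raise ValueError(f"peak_flow must be non-negative, got {peak_flow}")
    if not (period > 0.0):
        raise ValueError(f"period must be positive, got {period}")
    n_harmonics = min(n_harmonics, n_samples // 2 - 1)
    c = _halfsine_coefficients(period, peak_flow, systolic_fraction, n_harmonics)
    c[0] += diastolic_leak
    # Lanczos sigma factors damp Gibbs ringing; sigma_0 = 1 keeps the mean exact
    k = np.arange(n_harmonics + 1)
    c = c * np.sinc(k / (n_harmonics + 1))
    t = np.arange(n_samples) * (period / n_samples)
    phase = np.exp(2j * math.pi * np.outer(t, k) / period)
    samples = c[0].real + 2.0 * np.real(phase[:, 1:] @ c[1:])
    return PeriodicWaveform(samples, period, "flow")


# --------------------------------------------------------------------------
# CSV dialect: header "time_s,<value column>", one full period, uniform grid


_VALUE_COLUMNS = {"flow": "flow_ml_s", "pressure": "pressure_mmHg"}


def write_waveform(waveform: PeriodicWaveform, path) -> None:
    """Write one period to CSV with columns ``time_s,<value>``."""
    col = _VALUE_COLUMNS[waveform.kind]
    df = pd.DataFrame({"time_s": waveform.time, col: waveform.samples})
    df.to_csv(path, index=False, float_format="%.12g")


def read_waveform(path, kind: str = "flow") -> PeriodicWaveform:
    """Read a single-period waveform CSV.

    The file must have a ``time_s`` header column plus exactly one value
    column, a strictly increasing uniform time grid starting at 0, and is
    taken to cover one full period (period = n * dt).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise WaveformFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if "time_s" not in df.columns or len(df.columns) != 2:
        raise WaveformFormatError(
            f"{path}: expected header 'time_s,<value>', got columns {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    v = df[[c for c in df.columns if c != "time_s"][0]].to_numpy(dtype=float)
    if t.size < 2:
        raise WaveformFormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    bad = np.where(dt <= 0)[0]
    if bad.size:
        raise WaveformFormatError(f"{path}: time not strictly increasing at row {bad[0] + 1}")
    step = (t[-1] - t[0]) / (t.size - 1)
    nonuniform = np.where(np.abs(dt - step) > 1e-6 * step)[0]
    if nonuniform.size:
        raise WaveformFormatError(f"{path}: non-uniform time step at row {nonuniform[0] + 1}")
    period = step * t.size
    return PeriodicWaveform(v, period, kind)


# --------------------------------------------------------------------------
# pseudo-measured pressure fixtures

#: SimulationResult attribute backing each pressure observable
OBSERVABLE_SIGNALS = {
    "p_tl_prox": "p_tl",
    "p_fl_prox": "p_fl",
    "p_tl_dist": "p_ph",
    "p_fl_dist": "p_dt",
}


def observables_for_model(model) -> list[str]:
    """Observable keys measurable on a scenario: pressures are recorded at
    tear sites, so a site contributes its TL and FL pressures only when its
    tear exists."""
    keys = []
    if model.has_proximal_tear:
        keys += ["p_tl_prox", "p_fl_prox"]
    if model.has_distal_tear:
        keys += ["p_tl_dist", "p_fl_dist"]
    return keys


def make_fixture(
    model,
    inflow: PeriodicWaveform,
    noise_sd: float = 0.0,
    seed: int = 0,
    settings=None,
):
    """Simulate ``model`` and return pseudo-measured pressure waveforms.

    Emulates catheter pressure recordings: the pressure observables at the
    tear sites with i.i.d. Gaussian noise of standard deviation ``noise_sd``
    (mmHg) added.  Returns ``(waveforms, manifest)`` where ``waveforms`` maps
    observable keys to PeriodicWaveform and ``manifest`` records the true
    generating parameters for recovery experiments.  Deterministic for a
    fixed seed.
    """
    from .simulate import simulate  # deferred: avoids an import cycle

    if noise_sd < 0.0:
        raise ValueError("noise_sd must be >= 0")
    result = simulate(model, inflow, settings)
    if not result.converged:
        raise RuntimeError(
            f"fixture simulation for {model.scenario_id} did not reach periodic steady state"
        )
    rng = np.random.default_rng(seed)
    waveforms = {}
    for key in observables_for_model(model):
        series = getattr(result, OBSERVABLE_SIGNALS[key]).copy()
        if noise_sd > 0.0:
            series = series + rng.normal(0.0, noise_sd, series.size)
        waveforms[key] = PeriodicWaveform(series, inflow.period, "pressure")
    manifest = {
        "scenario": model.scenario_id,
        "noise_sd_mmHg": noise_sd,
        "seed": seed,
        "truth": {
            "c_tl_ml_per_mmHg": model.tl_elements.compliance,
            "c_fl_ml_per_mmHg": model.fl_elements.compliance,
            "r_pt_mmHg_s_per_ml": model.proximal_tear.resistance if model.proximal_tear else None,
            "r_dt_mmHg_s_per_ml": model.distal_tear.resistance if model.distal_tear else None,
            "r_ph_mmHg_s_per_ml": model.peripheral.resistance,
            "outlet_pressure_mmHg": model.peripheral.outlet_pressure,
        },
    }
    return waveforms, manifest


def write_fixture_bundle(waveforms: dict, manifest: dict, inflow: PeriodicWaveform, outdir) -> None:
    """Write a fixture bundle: one CSV per observable, the inflow, and a
    JSON manifest of the true parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, wf in waveforms.items():
        write_waveform(wf, outdir / f"{key}.csv")
    write_waveform(inflow, outdir / "inflow.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_fixture_bundle(indir):
    """Read back a fixture bundle written by :func:`write_fixture_bundle`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    inflow = read_waveform(indir / "inflow.csv", "flow")
    waveforms = {}
    for key in OBSERVABLE_SIGNALS:
        p = indir / f"{key}.csv"
        if p.exists():
            waveforms[key] = read_waveform(p, "pressure")
    return waveforms, manifest, inflow
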