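"""Solvent-accessibility analysis of 3-pulse ESEEM (stimulated echo) time traces.

A nitroxide spin label close to D2O shows deuterium nuclear modulation on its
stimulated-echo decay.  The modulation depth ``k`` is proportional to the
number of nearby solvent deuterons and is therefore a per-residue measure of
water accessibility.  Two independent routes recover it from a trace:

1. *fit route* -- divide out the decaying echo background, then fit the
   nuclear modulation function with a damped harmonic oscillation,
2. *FT route* -- Hamming-apodize, zero-fill and Fourier-transform the
   modulation function and integrate the magnitude of the deuterium line.

Panels of residues are normalised to the most accessible site (100 %) and two
states are compared per residue as deprotected / protected / no change.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "EchoTrace",
    "ModulationFunction",
    "DepthFit",
    "FrequencySpectrum",
    "AccessibilityPanel",
    "TraceFormatError",
    "FitError",
    "load_trace",
    "correct_background",
    "fit_modulation",
    "spectrum_intensity",
    "normalize_panel",
    "compare_states",
]

#: MHz * ns -> cycles
_MHZ_NS = 1e-3

#: uncertainty floor on normalised accessibilities, percentage points
ERROR_FLOOR_PCT = 5.0


class TraceFormatError(ValueError):
    """Raised for malformed or non-uniform time-domain trace files."""


class FitError(RuntimeError):
    """Raised when a background or modulation fit does not converge."""


@dataclass
class EchoTrace:
    """One 3pESEEM time-domain record for a labeled residue/state.

    T is the variable inter-pulse delay in ns (uniform grid, by convention
    starting at 400 ns in 12 ns steps), amplitude the integrated echo in
    arbitrary units, tau the fixed first inter-pulse delay in ns.
    """

    T: np.ndarray
    amplitude: np.ndarray
    tau: float
    field_mT: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.T.ndim != 1 or self.T.shape != self.amplitude.shape:
            raise TraceFormatError("T and amplitude must be matching 1-D arrays")
        if self.T.size < 8:
            raise TraceFormatError("trace too short (< 8 points)")
        steps = np.diff(self.T)
        if np.any(steps <= 0):
            raise TraceFormatError("T grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise TraceFormatError("T grid must be uniform")
        if not (np.all(np.isfinite(self.T)) and np.all(np.isfinite(self.amplitude))):
            raise TraceFormatError("non-finite values in trace")
        if self.tau <= 0:
            raise TraceFormatError("tau must be positive (ns)")

    @property
    def t_step(self) -> float:
        return float(self.T[1] - self.T[0])

    @property
    def n_points(self) -> int:
        return int(self.T.size)

    def write(self, path) -> None:
        """Write as two-column ASCII with '#'-prefixed metadata header."""
        header = [f"# tau_ns = {self.tau!r}"]
        if self.field_mT is not None:
            header.append(f"# field_mT = {self.field_mT!r}")
        if self.label:
            header.append(f"# label = {self.label}")
        with open(path, "w") as fh:
            fh.write("\n".join(header) + "\n")
            for t, a in zip(self.T, self.amplitude):
                fh.write(f"{t:.6f} {a:.12e}\n")


@dataclass
class ModulationFunction:
    """Deconvoluted, normalised nuclear modulation: trace/background - 1."""

    T: np.ndarray
    value: np.ndarray
    tau: float
    background: np.ndarray
    background_model: str
    background_params: dict
    noise_estimate: float
    label: str = ""
    #: True when the mean over the trailing 10 % of the grid is within
    #: 3*noise of zero (diagnostic; large slow-damped depths fail it benignly)
    tail_converged: bool = True


@dataclass
class DepthFit:
    """Damped-harmonic-oscillation fit of a nuclear modulation function."""

    depth_k: float
    nu: float
    damping_time: float
    phase: float
    offset: float
    amplitude: float
    relative_sd: float
    covariance: np.ndarray | None
    residual_rms: float
    label: str = ""
    flags: tuple = ()


@dataclass
class FrequencySpectrum:
    """Magnitude FT of a modulation function (Hamming window, zero-filled)."""

    freq: np.ndarray
    magnitude: np.ndarray
    window: str = "hamming"
    zerofill_factor: int = 4


@dataclass
class AccessibilityPanel:
    """Per-residue accessibilities normalised to a reference site (=100 %)."""

    entries: pd.DataFrame  # label, value, sd, accessibility_pct, uncertainty_pct, method
    reference_label: str
    method: str = "fit"

    def __getitem__(self, label: str) -> pd.Series:
        rows = self.entries[self.entries["label"] == label]
        if rows.empty:
            raise KeyError(label)
        return rows.iloc[0]

    @property
    def labels(self) -> list[str]:
        return list(self.entries["label"])

    def write_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loading


def load_trace(path, dialect: str = "auto") -> EchoTrace:
    """Read a two-column ASCII/CSV echo trace.

    Header lines prefixed ``#`` may carry ``tau_ns``, ``field_mT`` and
    ``label`` metadata as ``# key = value``.  The T grid must be uniform and
    strictly increasing; offending lines are named in the error.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\w+)\s*[=:]\s*(.+)", line)
                if m:
                    meta[m.group(1)] = m.group(2).strip()
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 2:
                raise TraceFormatError(f"{path}: line {lineno}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path}: line {lineno}: non-numeric value {parts[:2]}"
                ) from exc
    if not rows:
        raise TraceFormatError(f"{path}: no data rows")
    T = np.array([r[0] for r in rows])
    amp = np.array([r[1] for r in rows])
    steps = np.diff(T)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 2
        raise TraceFormatError(f"{path}: line {bad}: T grid not strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        bad = int(np.argmax(~np.isclose(steps, steps[0], rtol=1e-6, atol=1e-9))) + 2
        raise TraceFormatError(f"{path}: line {bad}: non-uniform T step")
    tau = float(meta.get("tau_ns", "nan"))
    if not math.isfinite(tau):
        raise TraceFormatError(f"{path}: missing '# tau_ns =' metadata")
    field = float(meta["field_mT"]) if "field_mT" in meta else None
    return EchoTrace(T=T, amplitude=amp, tau=tau, field_mT=field,
                     label=meta.get("label", ""))


# ---------------------------------------------------------------------------
# background correction


def _stretched_exp(T, a, t0, beta):
    return a * np.exp(-np.power(np.clip(T, 0, None) / t0, beta))


def _fit_stretched_exp(T, y, mask=None):
    if mask is None:
        mask = np.ones_like(T, dtype=bool)
    span = T[-1] - T[0]
    p0 = (float(np.max(y[mask])), max(span, 1.0), 1.0)
    popt, _ = curve_fit(
        _stretched_exp, T[mask], y[mask], p0=p0,
        bounds=([1e-12, 1.0, 0.2], [np.inf, 1e9, 4.0]), maxfev=20000,
    )
    return popt


def _poly3_log(T, y, mask=None):
    if mask is None:
        mask = np.ones_like(T, dtype=bool)
    ylog = np.log(np.clip(y[mask], 1e-12, None))
    coeffs = np.polyfit(T[mask], ylog, 3)
    return coeffs


def _modulation_model(T, tau, amp, nu, damping, phase, offset):
    osc = 1.0 - np.cos(2 * np.pi * nu * (T + tau) * _MHZ_NS + phase)
    return -amp * np.exp(-T / damping) * osc + offset


def correct_background(
    trace: EchoTrace,
    model: str = "stretched_exp",
    refine: bool = True,
) -> ModulationFunction:
    """Divide out the echo decay and return the nuclear modulation function.

    The background is fitted to the oscillation-free upper envelope by
    iterative masking (fit to all points, then refit on the points lying at or
    above the first fit — deuterium modulation only ever dips *below* the
    envelope), optionally followed by a joint background x modulation
    refinement that deconvolutes the two exactly on synthetic traces.
    Modulation = amplitude / background - 1, invariant to overall scaling.
    """
    if model not in ("stretched_exp", "poly3"):
        raise ValueError(f"unknown background model {model!r}")
    T, y = trace.T, trace.amplitude
    if np.any(y <= 0):
        raise FitError("echo amplitudes must be positive for background fitting")

    try:
        if model == "stretched_exp":
            popt = _fit_stretched_exp(T, y)
            resid = y - _stretched_exp(T, *popt)
            mask = resid >= np.quantile(resid, 0.5)
            popt = _fit_stretched_exp(T, y, mask)
            bg = _stretched_exp(T, *popt)
            bg_params = {"a": popt[0], "t0": popt[1], "beta": popt[2]}
        else:
            coeffs = _poly3_log(T, y)
            resid = y - np.exp(np.polyval(coeffs, T))
            mask = resid >= np.quantile(resid, 0.5)
            coeffs = _poly3_log(T, y, mask)
            bg = np.exp(np.polyval(coeffs, T))
            bg_params = {"coeffs": list(coeffs)}
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise FitError(f"background fit did not converge: {exc}") from exc

    if refine and model == "stretched_exp":
        bg, bg_params = _joint_refine(trace, bg_params) or (bg, bg_params)

    modulation = y / bg - 1.0
    # noise estimated from the high-frequency part of the second difference
    noise = float(np.std(np.diff(modulation, 2)) / math.sqrt(6.0)) if len(modulation) > 4 else 0.0
    n_tail = max(1, len(T) // 10)
    tail_ok = bool(abs(float(np.mean(modulation[-n_tail:]))) <= max(3 * noise, 1e-9))
    return ModulationFunction(
        T=T, value=modulation, tau=trace.tau, background=bg,
        background_model=model, background_params=bg_params,
        noise_estimate=noise, label=trace.label, tail_converged=tail_ok,
    )


def _joint_refine(trace: EchoTrace, bg_params: dict):
    """Joint fit of background x (1 + modulation); returns refined background."""
    T, y, tau = trace.T, trace.amplitude, trace.tau
    bg0 = _stretched_exp(T, bg_params["a"], bg_params["t0"], bg_params["beta"])
    mod0 = y / bg0 - 1.0
    nu0 = _ft_peak_frequency(T, mod0)
    if nu0 is None:
        return None

    def full(T, a, t0, beta, amp, nu, damping, phase):
        bg = _stretched_exp(T, a, t0, beta)
        return bg * (1.0 + _modulation_model(T, tau, amp, nu, damping, phase, 0.0))

    amp0 = max(float(np.max(np.abs(mod0))) / 2.0, 1e-6)
    p0 = (bg_params["a"], bg_params["t0"], bg_params["beta"], amp0, nu0,
          (T[-1] - T[0]) / 3.0, 0.0)
    lower = [1e-12, 1.0, 0.2, 0.0, nu0 * 0.8, 10.0, -np.pi]
    upper = [np.inf, 1e9, 4.0, 1.0, nu0 * 1.2, 1e9, np.pi]
    try:
        popt, _ = curve_fit(full, T, y, p0=p0, bounds=(lower, upper), maxfev=40000)
    except Exception:
        return None
    bg = _stretched_exp(T, *popt[:3])
    return bg, {"a": popt[0], "t0": popt[1], "beta": popt[2]}


def _ft_peak_frequency(T, values, fmin: float = 0.5) -> float | None:
    """Frequency (MHz) of the dominant magnitude-FT peak above ``fmin``.

    The slowly decaying offset of the nuclear modulation leaks spectral
    weight below ~1 MHz and can bias the peak; a moving-average detrend
    (window ~ one deuterium period) suppresses it before the transform.
    """
    step = T[1] - T[0]
    w = min(37, max(len(values) // 8, 4))
    trend = np.convolve(values, np.ones(w) / w, mode="same")
    v = (values - trend) * np.hamming(len(values))
    n = int(2 ** math.ceil(math.log2(len(v) * 4)))
    mag = np.abs(np.fft.rfft(v, n))
    freq = np.fft.rfftfreq(n, d=step) / _MHZ_NS
    sel = freq >= fmin
    if not np.any(sel) or np.max(mag[sel]) <= 0:
        return None
    return float(freq[sel][np.argmax(mag[sel])])


# ---------------------------------------------------------------------------
# fit route


def fit_modulation(
    modfn: ModulationFunction,
    init_strategy: str = "auto",
    nu_prior: float | None = None,
) -> DepthFit:
    """Fit a damped harmonic oscillation to the modulation function.

    Model: -A*exp(-T/damping)*(1 - cos(2*pi*nu*(T+tau) + phase)) + offset, the
    closed form of a single effective deuterium line, so the modulation depth
    k = 4A / (1 - cos(2*pi*nu*tau)) round-trips exactly on simulated traces.
    Initialisation: nu from the FT peak, phase from quadrature projection,
    five damping starts log-spaced over the trace duration; best chi-square
    wins.  The fit is weighted by the fitted background (modulation noise
    grows as the echo decays).
    """
    T, v, tau = modfn.T, modfn.value, modfn.tau
    noise = max(modfn.noise_estimate, 1e-12)

    if float(np.max(np.abs(v - np.mean(v)))) < max(3 * noise, 1e-8):
        return DepthFit(
            depth_k=0.0, nu=float("nan"), damping_time=float("nan"), phase=0.0,
            offset=float(np.mean(v)), amplitude=0.0, relative_sd=float("nan"),
            covariance=None, residual_rms=float(np.std(v)), label=modfn.label,
            flags=("no deuterium modulation",),
        )

    nu0 = nu_prior if (init_strategy == "prior" and nu_prior) else _ft_peak_frequency(T, v)
    if nu0 is None:
        nu0 = nu_prior or 2.25

    # phase seed from quadrature projection at the FT frequency; the
    # oscillatory part of the modulation is +amp*e^(-T/d)*cos(carrier+phase)
    carrier = 2 * np.pi * nu0 * (T + tau) * _MHZ_NS
    w_tr = min(37, max(len(v) // 8, 4))
    vc = v - np.convolve(v, np.ones(w_tr) / w_tr, mode="same")
    phase0 = math.atan2(-np.sum(vc * np.sin(carrier)), np.sum(vc * np.cos(carrier)))

    weights = modfn.background / np.max(modfn.background)
    span = T[-1] - T[0]
    amp0 = max(float(np.max(np.abs(vc))) / 2.0, 1e-8)
    best = None
    for damping0 in np.geomspace(span / 20.0, span * 2.0, 5):
        params = lmfit.Parameters()
        params.add("amp", value=amp0, min=0.0, max=1.0)
        params.add("nu", value=nu0, min=nu0 * 0.7, max=nu0 * 1.3)
        # a damping shorter than one oscillation period only ever fits noise
        params.add("damping", value=max(damping0, 1e3 / nu0),
                   min=1e3 / nu0, max=1e9)
        params.add("phase", value=phase0, min=-np.pi, max=np.pi)
        params.add("offset", value=float(np.mean(v)), min=-1.0, max=1.0)

        def resid(p):
            m = _modulation_model(T, tau, p["amp"], p["nu"], p["damping"],
                                  p["phase"], p["offset"])
            return (v - m) * weights

        try:
            out = lmfit.minimize(resid, params, method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        raise FitError("damped-oscillation fit did not converge for any start")

    p = best.params
    amp = float(p["amp"].value)
    nu = float(p["nu"].value)
    blind = 1.0 - math.cos(2 * math.pi * nu * tau * _MHZ_NS)
    flags: list[str] = []
    if blind < 0.05:
        flags.append("tau near deuterium blind spot; depth ill-determined")
        depth = float("nan")
    else:
        depth = 4.0 * amp / blind
    amp_sd = p["amp"].stderr
    rel_sd = float(amp_sd / amp) if (amp_sd and amp > 0) else float("nan")
    resid_final = v - _modulation_model(T, tau, amp, nu, float(p["damping"].value),
                                        float(p["phase"].value), float(p["offset"].value))
    return DepthFit(
        depth_k=depth, nu=nu, damping_time=float(p["damping"].value),
        phase=float(p["phase"].value), offset=float(p["offset"].value),
        amplitude=amp, relative_sd=rel_sd,
        covariance=getattr(best, "covar", None),
        residual_rms=float(np.sqrt(np.mean(resid_final ** 2))),
        label=modfn.label, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# FT route


def spectrum_intensity(
    modfn: ModulationFunction,
    peak_center: float = 2.25,
    half_window: float = 0.75,
    zerofill_factor: int = 4,
) -> tuple[FrequencySpectrum, float]:
    """Magnitude ESEEM spectrum and integrated deuterium-peak intensity.

    The modulation function is mean-subtracted, Hamming-apodized, zero-filled
    (>= 4x) and Fourier-transformed; the intensity is the integral of the
    magnitude over [center - w, center + w] MHz.
    """
    if zerofill_factor < 4:
        zerofill_factor = 4
    T, v = modfn.T, modfn.value
    step = T[1] - T[0]
    nyquist = 0.5 / (step * _MHZ_NS)
    if not (0 < peak_center - half_window and peak_center + half_window < nyquist):
        raise ValueError(
            f"integration window [{peak_center - half_window}, "
            f"{peak_center + half_window}] MHz outside (0, {nyquist:.2f}) MHz"
        )
    w = (v - np.mean(v)) * np.hamming(len(v))
    n = int(2 ** math.ceil(math.log2(len(v) * zerofill_factor)))
    mag = np.abs(np.fft.rfft(w, n))
    freq = np.fft.rfftfreq(n, d=step) / _MHZ_NS
    spec = FrequencySpectrum(freq=freq, magnitude=mag, window="hamming",
                             zerofill_factor=zerofill_factor)
    sel = (freq >= peak_center - half_window) & (freq <= peak_center + half_window)
    intensity = float(np.trapezoid(mag[sel], freq[sel]))
    return spec, intensity


# ---------------------------------------------------------------------------
# panels


def normalize_panel(
    raw: Sequence[tuple[str, float, float]],
    reference: str = "max",
    method: str = "fit",
) -> AccessibilityPanel:
    """Normalise depths/intensities to a 0-100 % accessibility scale.

    ``reference='max'`` sets the most accessible residue to 100 % (the
    convention of presenting the panel relative to its most solvent-exposed
    site); an explicit residue label may be given instead.  Uncertainties are
    propagated in quadrature and floored at 5 percentage points of the
    reference, the conservative experimental error convention for this kind
    of measurement.
    """
    if len(raw) < 2:
        raise ValueError("panel needs at least 2 entries")
    labels = [r[0] for r in raw]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels in panel")
    values = np.array([float(r[1]) for r in raw])
    sds = np.array([float(r[2]) if len(r) > 2 else 0.0 for r in raw])
    if np.any(values < 0):
        raise ValueError("panel values must be >= 0")
    if reference == "max":
        iref = int(np.argmax(values))
    else:
        if reference not in labels:
            raise ValueError(f"reference label {reference!r} not in panel")
        iref = labels.index(reference)
    vref, sref = values[iref], sds[iref]
    if vref <= 0:
        raise ValueError("reference value must be positive")
    pct = 100.0 * values / vref
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(np.where(values > 0, (sds / np.where(values > 0, values, 1)) ** 2, 0.0)
                      + (sref / vref) ** 2)
    unc = np.maximum(pct * rel, ERROR_FLOOR_PCT)
    unc[iref] = max(100.0 * sref / vref, ERROR_FLOOR_PCT)
    df = pd.DataFrame({
        "label": labels,
        "value": values,
        "sd": sds,
        "accessibility_pct": pct,
        "uncertainty_pct": unc,
        "method": method,
    })
    return AccessibilityPanel(entries=df, reference_label=labels[iref], method=method)


def compare_states(
    panel_a: AccessibilityPanel,
    panel_b: AccessibilityPanel,
) -> pd.DataFrame:
    """Per-residue accessibility change between two states (a -> b).

    Each panel is normalised on its own scale.  A residue is 'no_change' when
    |delta| does not exceed the quadrature-combined uncertainty of the two
    entries (each floored at 5 points); otherwise 'deprotected' (more
    accessible in b) or 'protected'.  fold_change = pct_b / pct_a where the
    baseline is positive.
    """
    shared = [l for l in panel_a.labels if l in set(panel_b.labels)]
    if not shared:
        raise ValueError("panels share no labels")
    rows = []
    for label in shared:
        ea, eb = panel_a[label], panel_b[label]
        delta = float(eb["accessibility_pct"] - ea["accessibility_pct"])
        combined = math.hypot(float(ea["uncertainty_pct"]), float(eb["uncertainty_pct"]))
        if abs(delta) <= combined:
            cls = "no_change"
        elif delta > 0:
            cls = "deprotected"
        else:
            cls = "protected"
        fold = (float(eb["accessibility_pct"]) / float(ea["accessibility_pct"])
                if ea["accessibility_pct"] > 0 else float("nan"))
        rows.append((label, delta, combined, fold, cls))
    return pd.DataFrame(rows, columns=["label", "delta_pct", "combined_uncertainty_pct",
                                       "fold_change", "class"])


# ---------------------------------------------------------------------------
# convenience: full per-trace pipeline


def analyze_trace(trace: EchoTrace, background_model: str = "stretched_exp",
                  peak_center: float | None = None) -> tuple[DepthFit, float]:
    """Background-correct then run both routes; returns (fit, FT intensity)."""
    modfn = correct_background(trace, model=background_model)
    fit = fit_modulation(modfn)
    center = peak_center if peak_center is not None else (
        fit.nu if math.isfinite(fit.nu) else 2.25)
    _, intensity = spectrum_intensity(modfn, peak_center=center)
    return fit, intensity


def panel_from_traces(
    traces: Iterable[EchoTrace],
    method: str = "fit",
    reference: str = "max",
    background_model: str = "stretched_exp",
) -> AccessibilityPanel:
    """Process a set of traces into a normalised accessibility panel."""
    raw = []
    for tr in traces:
        fit, intensity = analyze_trace(tr, background_model=background_model)
        if method == "fit":
            value = fit.depth_k
            sd = fit.relative_sd * fit.depth_k if math.isfinite(fit.relative_sd) else 0.0
        elif method == "ft":
            value = intensity
            sd = (fit.relative_sd * intensity if math.isfinite(fit.relative_sd) else 0.0)
        else:
            raise ValueError(f"unknown method {method!r}")
        raw.append((tr.label or f"trace{len(raw)}", max(value, 0.0), sd))
    return normalize_panel(raw, reference=reference, method=method)
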