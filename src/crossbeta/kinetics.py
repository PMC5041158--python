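"""ThT aggregation-kinetics fitting and Congo-red difference-spectrum analysis.

Amyloid growth monitored by Thioflavin-T fluorescence follows either a
sigmoidal (nucleation + elongation, with a lag phase) or a mono-exponential
(seeded / lag-free) time course::

    sigmoid:      F(t) = A_i + (A_f - A_i) / (1 + exp((t_1/2 - t) * k_agg))
    exponential:  F(t) = A * (1 - exp(-k_agg * t))

Traces are baseline-corrected, normalized to the signal at a late anchor
time, and fitted by least squares; the fitted plateau feeds the inhibition
percentage against the untreated control.  The Congo-red assay is analysed
through the difference spectrum R = D - C - B, whose local maximum near
540 nm (the red shift of amyloid-bound dye) makes the amyloid call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from lmfit import Model as LmModel
from scipy.signal import find_peaks
from scipy.stats import median_abs_deviation

__all__ = [
    "KineticTrace",
    "SigmoidFit",
    "ExponentialFit",
    "ThTKineticsModel",
    "KineticsFit",
    "normalize_trace",
    "fit_sigmoid",
    "fit_exponential",
    "inhibition_percent",
    "SpectrumSet",
    "cr_difference",
]


@dataclass(frozen=True)
class KineticTrace:
    """Time-series fluorescence (time in hours, arbitrary units)."""

    time: np.ndarray
    values: np.ndarray
    baseline_corrected: bool = False
    anchor_time: float | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and values must be matching 1-D arrays")
        if len(t) < 2:
            raise ValueError("a trace needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "values", v)

    def baseline_correct(self, dye_only_signal: float) -> "KineticTrace":
        """Subtract the mean dye-only signal (performed before normalization)."""
        return replace(
            self, values=self.values - float(dye_only_signal), baseline_corrected=True
        )


def normalize_trace(trace: KineticTrace, anchor_time: float) -> KineticTrace:
    """Divide the trace by its value at the anchor time (nearest sample).

    Ties between two equally near samples resolve to the earlier one.  The
    normalized trace has value 1.0 at the anchor sample.
    """
    t = trace.time
    if not (t[0] <= anchor_time <= t[-1]):
        raise ValueError("anchor time outside the observed span")
    dist = np.abs(t - anchor_time)
    idx = int(np.argmin(dist))  # argmin takes the first (earlier) on ties
    anchor_value = trace.values[idx]
    if anchor_value == 0:
        raise ValueError("zero signal at the anchor point")
    return replace(
        trace, values=trace.values / anchor_value, anchor_time=float(t[idx])
    )


def _sigmoid(t, Ai, Af, t_half, k_agg):
    return Ai + (Af - Ai) / (1.0 + np.exp((t_half - t) * k_agg))


def _exponential(t, A, k_agg):
    return A * (1.0 - np.exp(-k_agg * t))


@dataclass(frozen=True)
class SigmoidFit:
    Ai: float
    Af: float
    t_half: float
    k_agg: float
    residual_norm: float
    converged: bool
    stderr: dict = field(default_factory=dict)

    @property
    def plateau(self) -> float:
        return self.Af


@dataclass(frozen=True)
class ExponentialFit:
    A: float
    k_agg: float
    residual_norm: float
    converged: bool
    stderr: dict = field(default_factory=dict)

    @property
    def plateau(self) -> float:
        return self.A


class ThTKineticsModel:
    """Aggregation-kinetics model bound to one normalized trace.

    ``fit()`` returns a :class:`KineticsFit` carrying the estimates, their
    standard errors and diagnostics; non-convergence is flagged on the
    result, never raised.
    """

    def __init__(self, trace: KineticTrace, model: Literal["sigmoid", "exponential"] = "sigmoid"):
        if model not in ("sigmoid", "exponential"):
            raise ValueError(f"unknown model {model!r}")
        if len(trace.time) < 5:
            raise ValueError("need at least 5 points for fitting")
        self.trace = trace
        self.model = model

    @classmethod
    def from_dataframe(cls, df, time_col="time", value_col="value", model="sigmoid"):
        trace = KineticTrace(df[time_col].to_numpy(), df[value_col].to_numpy())
        return cls(trace, model=model)

    def _initial_guesses(self):
        t, F = self.trace.time, self.trace.values
        lo, hi = float(F.min()), float(F.max())
        span = hi - lo if hi > lo else 1.0
        # time of half-range crossing and a 10-90% rise-time rate guess
        half = lo + 0.5 * span
        above = np.where(F >= half)[0]
        t_half = float(t[above[0]]) if len(above) else float(t[len(t) // 2])
        t10 = t[np.searchsorted(F, lo + 0.1 * span, side="left").clip(0, len(t) - 1)]
        t90 = t[np.searchsorted(F, lo + 0.9 * span, side="left").clip(0, len(t) - 1)]
        k0 = 4.0 / (t90 - t10) if t90 > t10 else 1.0 / max(t[-1] - t[0], 1e-6)
        return lo, hi, t_half, float(np.clip(k0, 1e-4, 10.0))

    def fit(self) -> "KineticsFit":
        t, F = self.trace.time, self.trace.values
        if self.model == "sigmoid":
            m = LmModel(_sigmoid)
            lo, hi, t_half, k0 = self._initial_guesses()
            params = m.make_params(Ai=lo, Af=hi, t_half=t_half, k_agg=k0)
            params["k_agg"].set(min=1e-9, max=10.0)
        else:
            m = LmModel(_exponential)
            k0 = self._initial_guesses()[3]
            params = m.make_params(A=float(F.max()), k_agg=k0)
            params["k_agg"].set(min=1e-9, max=10.0)
        try:
            res = m.fit(F, params, t=t)
            ok = bool(res.success)
        except Exception as exc:  # pathological data: flag, do not raise
            return KineticsFit(
                model=self.model, params={}, stderr={}, converged=False,
                residual_norm=float("nan"), message=str(exc), trace=self.trace,
            )
        stderr = {
            name: (p.stderr if p.stderr is not None else float("nan"))
            for name, p in res.params.items()
        }
        return KineticsFit(
            model=self.model,
            params={name: float(p.value) for name, p in res.params.items()},
            stderr=stderr,
            converged=ok,
            residual_norm=float(np.linalg.norm(res.residual)),
            message=res.message if isinstance(res.message, str) else "",
            trace=self.trace,
        )


@dataclass(frozen=True)
class KineticsFit:
    """Fitted aggregation kinetics: estimates, uncertainties, diagnostics."""

    model: str
    params: dict
    stderr: dict
    converged: bool
    residual_norm: float
    trace: KineticTrace | None = None
    message: str = ""

    @property
    def plateau(self) -> float:
        return self.params["Af" if self.model == "sigmoid" else "A"]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.model == "sigmoid":
            return _sigmoid(t, **self.params)
        return _exponential(t, **self.params)

    def summary(self) -> str:
        lines = [
            f"ThT kinetics fit ({self.model})",
            f"  converged: {self.converged}   residual norm: {self.residual_norm:.4g}",
            f"  {'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name, val in self.params.items():
            se = self.stderr.get(name, float("nan"))
            lines.append(f"  {name:<8}{val:>12.5g}{se:>12.3g}")
        lines.append(f"  plateau: {self.plateau:.5g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.trace is not None:
            ax.plot(self.trace.time, self.trace.values, ".", label="data")
            tt = np.linspace(self.trace.time[0], self.trace.time[-1], 200)
            ax.plot(tt, self.predict(tt), "-", label=f"{self.model} fit")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("normalized ThT fluorescence")
        ax.legend()
        return ax

    def as_sigmoid(self) -> SigmoidFit:
        p = self.params
        return SigmoidFit(
            Ai=p["Ai"], Af=p["Af"], t_half=p["t_half"], k_agg=p["k_agg"],
            residual_norm=self.residual_norm, converged=self.converged,
            stderr=self.stderr,
        )

    def as_exponential(self) -> ExponentialFit:
        p = self.params
        return ExponentialFit(
            A=p["A"], k_agg=p["k_agg"],
            residual_norm=self.residual_norm, converged=self.converged,
            stderr=self.stderr,
        )


def fit_sigmoid(trace: KineticTrace) -> SigmoidFit:
    """Least-squares Boltzmann-sigmoid fit of a normalized trace."""
    return ThTKineticsModel(trace, "sigmoid").fit().as_sigmoid()


def fit_exponential(trace: KineticTrace) -> ExponentialFit:
    """Least-squares mono-exponential (lag-free) fit of a normalized trace."""
    return ThTKineticsModel(trace, "exponential").fit().as_exponential()


def inhibition_percent(plateau_treated: float, plateau_control: float) -> float:
    """Percent reduction of the fitted plateau vs the untreated control."""
    if plateau_control <= 0:
        raise ValueError("control plateau must be positive")
    if plateau_treated < 0:
        raise ValueError("plateaus must be non-negative")
    return 100.0 * (1.0 - plateau_treated / plateau_control)


# ---------------------------------------------------------------------------
# Congo red


@dataclass(frozen=True)
class SpectrumSet:
    """Background-corrected CR assay spectra on a common 400-700 nm grid.

    B: buffer + aggregate, C: dye + solvent, D: dye + fibrils (each already
    minus the buffer blank A).  The amyloid test reads the difference
    spectrum R = D - C - B.
    """

    wavelength: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        for name in ("B", "C", "D"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != wl.shape:
                raise ValueError(f"spectrum {name} not on the common grid")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "wavelength", wl)


def cr_difference(
    spectra: SpectrumSet,
    peak_window: tuple = (530.0, 550.0),
    noise_band: tuple = (500.0, 600.0),
) -> tuple[np.ndarray, bool]:
    """Difference spectrum R = D - C - B and the amyloid call.

    Amyloid-positive iff R has a local maximum inside ``peak_window``
    (540 +- 10 nm, the red shift of amyloid-bound Congo red) that exceeds
    the noise floor: 3x the median absolute deviation of R outside
    ``noise_band``.
    """
    wl = spectra.wavelength
    R = spectra.D - spectra.C - spectra.B

    outside = (wl < noise_band[0]) | (wl > noise_band[1])
    floor = 3.0 * float(median_abs_deviation(R[outside])) if outside.any() else 0.0
    floor = max(floor, 1e-9)

    peaks, _ = find_peaks(R)
    in_window = [p for p in peaks if peak_window[0] <= wl[p] <= peak_window[1]]
    positive = any(R[p] > floor for p in in_window)
    return R, bool(positive)
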