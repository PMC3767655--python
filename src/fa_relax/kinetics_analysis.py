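"""Disassembly kinetics: survival/intensity curves, τ fits, K_dis, comparison.

After actomyosin relaxation every focal adhesion disassembles; two measured
summaries describe the process per protein:

* the survival curve — the fraction of the drug-time cohort of adhesions
  still present t minutes later, and
* the normalized intensity-decay curve — the cohort-mean fluorescence,
  each track normalized to its value at drug time (tracks that have died
  contribute 0, not a dropped sample, so the mean is not biased shallow).

Both are fit by a single exponential exp(−t/τ).  On the FRAP side the
disassembly statistic is K_dis = k_off − k_on (per minute at this layer); a
positive K_dis predicts the mono-exponential disassembly curve
y = exp(−K_dis·t), which reaches 1/e (≈37%) of its initial value at
t = 1/K_dis.  The predicted and measured curves are compared by RMS
difference on a common grid and by the ratio of implied rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from fa_relax.adhesion_tracking import AdhesionTrack

__all__ = [
    "DisassemblyCurve",
    "DecayFit",
    "KdisRecord",
    "ComparisonReport",
    "survival_curve",
    "intensity_decay_curve",
    "fit_single_exponential",
    "compute_kdis",
    "predicted_disassembly",
    "compare_disassembly",
    "ranking_concordance",
]


@dataclass
class DisassemblyCurve:
    """A normalized disassembly curve (value 1 at drug time)."""

    times: np.ndarray  # min since drug
    value: np.ndarray
    kind: str  # survival | intensity | predicted
    decaying: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.times.shape != self.value.shape:
            raise ValueError("times and value must have the same shape")
        if len(self.times) and (self.times[0] < 0 or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must be non-negative and increasing")


@dataclass
class DecayFit:
    """Single-exponential fit y = A·exp(−t/τ); A fixed to 1 by default."""

    tau: float  # min
    amplitude: float
    rss: float
    ci_tau: tuple[float, float] | None
    success: bool


@dataclass
class KdisRecord:
    """Per-protein kinetic state: K_dis = k_off − k_on (1/min)."""

    k_on: float
    k_off: float
    k_dis: float
    state: str  # assembly | stable | disassembly
    protein: str | None = None


@dataclass
class ComparisonReport:
    """Predicted-vs-measured agreement on a common grid."""

    rms: float
    rate_ratio: float  # predicted rate / measured rate
    n_points: int
    window_min: tuple[float, float]


# ---------------------------------------------------------------------------
# measured curves


def _cohort(tracks: list[AdhesionTrack], drug_frame: int) -> list[AdhesionTrack]:
    cohort = [t for t in tracks if t.alive_at(drug_frame)]
    if not cohort:
        raise ValueError("no tracks alive at the drug frame")
    return cohort


def survival_curve(
    tracks: list[AdhesionTrack],
    drug_frame: int,
    frame_interval: float,
    n_frames: int,
) -> DisassemblyCurve:
    """Fraction of the drug-time cohort still alive t minutes after the drug."""
    cohort = _cohort(tracks, drug_frame)
    offsets = np.arange(n_frames - drug_frame)
    frac = np.array([
        np.mean([tr.death_frame > drug_frame + j for tr in cohort]) for j in offsets
    ])
    return DisassemblyCurve(offsets * frame_interval, frac, kind="survival")


def intensity_decay_curve(
    tracks: list[AdhesionTrack],
    drug_frame: int,
    frame_interval: float,
    n_frames: int,
    bleach_factors: np.ndarray | None = None,
) -> DisassemblyCurve:
    """Cohort-mean fluorescence, each track normalized at drug time.

    Tracks that die contribute 0 after death (their fluorescence is genuinely
    gone); tracks with non-positive intensity at drug time are excluded with
    a warning.  ``bleach_factors`` (per movie frame) correct global
    photobleaching before normalization.
    """
    cohort = _cohort(tracks, drug_frame)
    offsets = np.arange(n_frames - drug_frame)

    def corrected(tr: AdhesionTrack, frame: int) -> float:
        v = tr.intensity_at(frame)
        if v is None:
            return 0.0
        if bleach_factors is not None:
            v *= bleach_factors[frame]
        return v

    series = []
    for tr in cohort:
        v0 = corrected(tr, drug_frame)
        if v0 <= 0:
            warnings.warn(f"track {tr.track_id} excluded: non-positive intensity at drug time")
            continue
        series.append([corrected(tr, drug_frame + int(j)) / v0 for j in offsets])
    if not series:
        raise ValueError("no usable tracks for the intensity decay curve")
    mean = np.asarray(series).mean(axis=0)
    return DisassemblyCurve(offsets * frame_interval, mean, kind="intensity")


# ---------------------------------------------------------------------------
# fits and predictions


def fit_single_exponential(curve: DisassemblyCurve, free_amplitude: bool = False) -> DecayFit:
    """Least-squares fit of exp(−t/τ) (amplitude fixed to 1 by default).

    τ is initialized from a log-linear regression on values above 0.05.
    A non-decaying curve returns ``success=False`` without raising.
    """
    t = curve.times
    y = curve.value
    if len(t) < 5:
        raise ValueError("need at least 5 points to fit a decay")
    pos = y > 0.05
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
    else:
        slope = 0.0
    if slope >= 0 or y[-1] >= y[0] - 1e-12:
        return DecayFit(np.nan, 1.0, np.inf, None, success=False)
    tau0 = -1.0 / slope

    from scipy.optimize import least_squares

    if free_amplitude:
        def resid(th):
            return th[1] * np.exp(-t / th[0]) - y
        sol = least_squares(resid, x0=[tau0, 1.0], bounds=([1e-6, 0.0], [1e6, 10.0]))
        tau, amp = sol.x
        n_par = 2
    else:
        def resid(th):
            return np.exp(-t / th[0]) - y
        sol = least_squares(resid, x0=[tau0], bounds=([1e-6], [1e6]))
        tau, amp = sol.x[0], 1.0
        n_par = 1
    rss = float(np.sum(sol.fun**2))
    ci = None
    try:
        jtj = sol.jac.T @ sol.jac
        var = np.linalg.inv(jtj)[0, 0] * rss / max(len(t) - n_par, 1)
        se = float(np.sqrt(var))
        ci = (tau - 1.96 * se, tau + 1.96 * se)
    except np.linalg.LinAlgError:
        pass
    return DecayFit(float(tau), float(amp), rss, ci, success=bool(sol.success))


def compute_kdis(k_on: float, k_off: float, tol: float = 1e-6,
                 protein: str | None = None) -> KdisRecord:
    """K_dis = k_off − k_on with the kinetic state classification.

    Rates must share units (1/min at this layer).  ``tol`` is the absolute
    rate difference below which the protein is called "stable"
    (k_on ≈ k_off); k_on > k_off is net assembly, k_on < k_off net
    disassembly.
    """
    if k_on < 0 or k_off < 0:
        raise ValueError("rates must be non-negative")
    k_dis = k_off - k_on
    if abs(k_dis) <= tol:
        state = "stable"
    elif k_dis > 0:
        state = "disassembly"
    else:
        state = "assembly"
    return KdisRecord(k_on=k_on, k_off=k_off, k_dis=k_dis, state=state, protein=protein)


def predicted_disassembly(k_dis: float, times: np.ndarray) -> DisassemblyCurve:
    """Theoretical disassembly curve y = exp(−K_dis·t) (t in min, K_dis in 1/min)."""
    times = np.asarray(times, dtype=float)
    decaying = k_dis > 0
    if not decaying:
        warnings.warn("K_dis <= 0: prediction does not disassemble")
    return DisassemblyCurve(times, np.exp(-k_dis * times), kind="predicted", decaying=decaying)


def compare_disassembly(
    predicted: DisassemblyCurve,
    measured: DisassemblyCurve,
    window_min: tuple[float, float] = (0.0, 60.0),
) -> ComparisonReport:
    """RMS difference and implied-rate ratio of predicted vs measured curves.

    The prediction is interpolated onto the measured grid restricted to the
    comparison window; the implied rates are the single-exponential rates of
    each curve, with the ratio reported as predicted/measured.
    """
    lo = max(window_min[0], predicted.times.min(), measured.times.min())
    hi = min(window_min[1], predicted.times.max(), measured.times.max())
    sel = (measured.times >= lo) & (measured.times <= hi)
    if hi <= lo or sel.sum() < 2:
        raise ValueError("predicted and measured curves do not overlap in the window")
    t = measured.times[sel]
    p = np.interp(t, predicted.times, predicted.value)
    m = measured.value[sel]
    rms = float(np.sqrt(np.mean((p - m) ** 2)))
    fit_p = fit_single_exponential(DisassemblyCurve(t, p, kind="predicted"))
    fit_m = fit_single_exponential(DisassemblyCurve(t, m, kind=measured.kind))
    if fit_p.success and fit_m.success:
        ratio = fit_m.tau / fit_p.tau  # rate_pred/rate_meas = tau_meas/tau_pred
    else:
        ratio = float("nan")
    return ComparisonReport(rms=rms, rate_ratio=float(ratio), n_points=int(sel.sum()),
                            window_min=(lo, hi))


def plot_disassembly(curves: list[DisassemblyCurve], path, title: str | None = None) -> None:
    """Write a comparison plot of disassembly curves (predicted vs measured)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    styles = {"predicted": "--", "survival": "-", "intensity": "-"}
    for c in curves:
        ax.plot(c.times, c.value, styles.get(c.kind, "-"), label=c.kind)
    ax.set_xlabel("time since drug (min)")
    ax.set_ylabel("normalized value")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ranking_concordance(rates_a: dict, rates_b: dict) -> float:
    """Kendall concordance of two per-protein rate rankings (shared keys)."""
    keys = sorted(set(rates_a) & set(rates_b))
    if len(keys) < 2:
        raise ValueError("need at least two shared proteins to rank")
    a = [rates_a[k] for k in keys]
    b = [rates_b[k] for k in keys]
    tau, _ = stats.kendalltau(a, b)
    return float(tau)
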