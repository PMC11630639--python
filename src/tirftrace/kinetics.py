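"""Residence-time kinetics from fitted step models.

From each spot's step model we count up/down event frequencies (fON, fOFF),
collect signed residence times tau of the stationary nonzero-occupancy
levels, fit the pooled |tau| distribution with one or two exponentials
(truncated at 30 s, where photobleaching dominates), correct the decay
rate for the photobleaching hazard measured on ligand-only controls, and
form the affinity index Ai = [ligand] * k_tau / fON, a heuristic stand-in
for a dissociation constant.

Sign convention: a level entered through an upward transition (binding)
contributes tau+, a level entered through a downward transition
(dissociation or photobleaching of a neighbor at higher occupancy)
contributes tau-.  Zero-occupancy intervals are not scored, and intervals
open at the record boundaries are censored and excluded from fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stepfind import StepModel

__all__ = [
    "ResidenceInterval",
    "ResidenceSet",
    "TauFit",
    "KineticsSummary",
    "event_frequencies",
    "residence_intervals",
    "fit_tau",
    "photobleach_correct",
    "affinity_index",
    "summarize_condition",
]


@dataclass(frozen=True)
class ResidenceInterval:
    spot_id: int
    occupancy_level: int      # >= 1
    tau_s: float              # signed by the entering transition
    entry_sign: int           # +1 bind-entered, -1 loss-entered, 0 unknown
    censored: bool


@dataclass
class ResidenceSet:
    intervals: List[ResidenceInterval]
    record_duration_s: float = float("nan")

    def uncensored(self) -> List[ResidenceInterval]:
        return [iv for iv in self.intervals if not iv.censored]

    def abs_taus(self, censored: bool = False) -> np.ndarray:
        ivs = self.intervals if censored else self.uncensored()
        return np.array([abs(iv.tau_s) for iv in ivs])

    def extend(self, other: "ResidenceSet") -> None:
        self.intervals.extend(other.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": [iv.spot_id for iv in self.intervals],
                "level": [iv.occupancy_level for iv in self.intervals],
                "tau_s": [iv.tau_s for iv in self.intervals],
                "entry_sign": [iv.entry_sign for iv in self.intervals],
                "censored": [iv.censored for iv in self.intervals],
            }
        )


def event_frequencies(model: StepModel, duration_s: float) -> tuple:
    """(f_on, f_off, sum_n_plus, sum_n_minus) from one spot record.

    Frequencies are multiplicity-weighted step counts per unit record time.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_plus = sum(s.multiplicity for s in model.steps if s.sign > 0)
    n_minus = sum(s.multiplicity for s in model.steps if s.sign < 0)
    return n_plus / duration_s, n_minus / duration_s, n_plus, n_minus


def _level_occupancies(model: StepModel) -> np.ndarray:
    """Integer occupancy per level.

    The cumulative signed step count fixes relative occupancies; the
    absolute scale is anchored by the calibrated step size, so records that
    never visit zero occupancy (e.g. a saturated assembly cycling between
    its top levels) are still labeled correctly.
    """
    occ = [0]
    for s in model.steps:
        occ.append(occ[-1] + s.sign * s.multiplicity)
    occ = np.asarray(occ)
    occ = occ - occ.min()
    from .occupancy import _intensity_anchor

    return occ + _intensity_anchor(model, occ)


def residence_intervals(model: StepModel) -> ResidenceSet:
    """Signed residence intervals of every stationary nonzero level."""
    occ = _level_occupancies(model)
    n_levels = len(model.levels)
    out: List[ResidenceInterval] = []
    for i, lev in enumerate(model.levels):
        if occ[i] < 1:
            continue
        dur = lev.end_s - lev.start_s
        entry = model.steps[i - 1].sign if i >= 1 else 0
        censored = i == 0 or i == n_levels - 1
        out.append(ResidenceInterval(
            spot_id=model.spot_id,
            occupancy_level=int(occ[i]),
            tau_s=(entry if entry else 1) * dur,
            entry_sign=entry,
            censored=censored,
        ))
    duration = (model.levels[-1].end_s - model.levels[0].start_s
                if model.levels else float("nan"))
    return ResidenceSet(out, record_duration_s=duration)


@dataclass
class TauFit:
    model: str                # "single" or "double"
    k_tau: float              # rate of the dominant component
    amp: float
    k_tau2: Optional[float] = None
    amp2: Optional[float] = None
    aic_single: float = float("nan")
    aic_double: float = float("nan")
    tau_gt_max_fraction: float = 0.0
    n_intervals: int = 0
    flags: set = field(default_factory=set)


def _aic_from_rss(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def fit_tau(
    intervals: ResidenceSet,
    tau_max: float = 30.0,
    bin_width: Optional[float] = None,
    model_selection: str = "aic",
    frame_interval_s: float = 0.2,
    min_intervals: int = 30,
    tau_min: Optional[float] = None,
) -> TauFit:
    """Exponential fit(s) to the binned |tau| distribution.

    Uncensored intervals with |tau| <= ``tau_max`` are histogrammed with bin
    width twice the per-channel frame interval and fitted by unweighted
    least squares with A*exp(-k*tau), and optionally a two-exponential sum;
    the model is chosen by AIC unless forced ("single"/"double").  The
    fraction of intervals beyond ``tau_max`` is reported but excluded.
    ``tau_min`` drops bins below the detector's dwell resolution from the
    fit (dead-time handling; an exponential rate is shift-invariant).
    """
    taus = intervals.abs_taus()
    if len(taus) < min_intervals:
        raise ValueError(f"need >= {min_intervals} uncensored intervals, "
                         f"got {len(taus)}")
    frac_long = float(np.mean(taus > tau_max))
    taus_fit = taus[taus <= tau_max]
    if bin_width is None:
        bin_width = 2 * frame_interval_s
    edges = np.arange(0.0, tau_max + bin_width, bin_width)
    counts, edges = np.histogram(taus_fit, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    use = counts > 0
    # keep at least the populated range; LSQ on all bins up to the last hit
    last = np.max(np.nonzero(use)) if use.any() else 0
    x, ycounts = centers[: last + 1], counts[: last + 1].astype(float)
    if tau_min is not None:
        keep = x >= tau_min
        if keep.sum() >= 3:
            x, ycounts = x[keep], ycounts[keep]

    k0 = 1.0 / max(np.mean(taus_fit), 1e-9)

    def single(t, A, k):
        return A * np.exp(-k * t)

    def double(t, A1, k1, A2, k2):
        return A1 * np.exp(-k1 * t) + A2 * np.exp(-k2 * t)

    p1, _ = curve_fit(single, x, ycounts, p0=[ycounts.max(), k0],
                      bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
    rss1 = float(np.sum((ycounts - single(x, *p1)) ** 2))
    aic1 = _aic_from_rss(rss1, len(x), 2)

    fit = TauFit(model="single", k_tau=float(p1[1]), amp=float(p1[0]),
                 aic_single=aic1, tau_gt_max_fraction=frac_long,
                 n_intervals=len(taus))
    aic2 = np.nan
    p2 = None
    if model_selection in ("aic", "double") and len(x) >= 5:
        try:
            p2, _ = curve_fit(
                double, x, ycounts,
                p0=[ycounts.max() * 0.7, k0 * 3, ycounts.max() * 0.3, k0 / 3],
                bounds=([0, 0, 0, 0], [np.inf] * 4), maxfev=20000,
            )
            rss2 = float(np.sum((ycounts - double(x, *p2)) ** 2))
            aic2 = _aic_from_rss(rss2, len(x), 4)
        except RuntimeError:
            p2 = None
    fit.aic_double = float(aic2) if np.isfinite(aic2) else float("nan")

    want_double = (
        model_selection == "double"
        or (model_selection == "aic" and p2 is not None and aic2 < aic1)
    )
    if want_double and p2 is not None:
        A1, k1, A2, k2 = p2
        if min(k1, k2) > 0 and max(k1, k2) / max(min(k1, k2), 1e-12) < 1.5:
            fit.flags.add("degenerate_biexponential")
        else:
            # dominant component = larger fitted amplitude
            if A2 > A1:
                A1, k1, A2, k2 = A2, k2, A1, k1
            fit = TauFit(model="double", k_tau=float(k1), amp=float(A1),
                         k_tau2=float(k2), amp2=float(A2),
                         aic_single=aic1, aic_double=float(aic2),
                         tau_gt_max_fraction=frac_long, n_intervals=len(taus))
    return fit


def photobleach_correct(k_tau: float, k_pb: float) -> float:
    """Remove the photobleaching hazard from the residence decay rate.

    Dissociation and photobleaching are independent competing exponential
    hazards, so the observed decay is their sum and the corrected rate is
    the difference; negative results clamp to zero.
    """
    corr = k_tau - k_pb
    if corr < 0:
        import warnings

        warnings.warn("k_pb exceeds k_tau; corrected rate clamped to 0",
                      stacklevel=2)
        return 0.0
    return float(corr)


def affinity_index(cam_conc: float, k_tau: float, f_on: float) -> float:
    """Ai = [ligand] * k_tau / f_on, in the units of ``cam_conc``."""
    if f_on <= 0:
        import warnings

        warnings.warn("f_on = 0: affinity index undefined (infinite)",
                      stacklevel=2)
        return float("inf")
    return float(cam_conc * k_tau / f_on)


@dataclass
class KineticsSummary:
    f_on: float
    f_off: float
    sum_n_plus: int
    sum_n_minus: int
    k_tau: float
    k_tau2: Optional[float]
    amp2: Optional[float]
    model: str
    k_pb: float
    k_tau_corr: float
    a_i: float
    tau_gt30_fraction: float
    n_intervals: int

    def to_dict(self) -> dict:
        return {
            "f_on": self.f_on, "f_off": self.f_off,
            "n_plus": self.sum_n_plus, "n_minus": self.sum_n_minus,
            "k_tau": self.k_tau, "k_tau2": self.k_tau2, "amp2": self.amp2,
            "model": self.model, "k_pb": self.k_pb,
            "k_tau_corr": self.k_tau_corr, "a_i": self.a_i,
            "tau_gt30_fraction": self.tau_gt30_fraction,
            "n_intervals": self.n_intervals,
        }


def summarize_condition(
    models: Sequence[StepModel],
    duration_s: float,
    cam_conc: float,
    k_pb: float = 0.0,
    tau_max: float = 30.0,
    frame_interval_s: float = 0.2,
    min_intervals: int = 30,
) -> KineticsSummary:
    """Pool spots from one experimental condition.

    Frequencies are computed per spot and averaged; residence intervals are
    pooled across spots before the exponential fit.
    """
    freqs = np.array([event_frequencies(m, duration_s) for m in models])
    pooled = ResidenceSet([], record_duration_s=duration_s)
    for m in models:
        pooled.extend(residence_intervals(m))
    fit = fit_tau(pooled, tau_max=tau_max, frame_interval_s=frame_interval_s,
                  min_intervals=min_intervals, tau_min=3 * frame_interval_s)
    f_on = float(freqs[:, 0].mean())
    f_off = float(freqs[:, 1].mean())
    k_corr = photobleach_correct(fit.k_tau, k_pb)
    return KineticsSummary(
        f_on=f_on, f_off=f_off,
        sum_n_plus=int(freqs[:, 2].sum()), sum_n_minus=int(freqs[:, 3].sum()),
        k_tau=fit.k_tau, k_tau2=fit.k_tau2, amp2=fit.amp2, model=fit.model,
        k_pb=k_pb, k_tau_corr=k_corr,
        a_i=affinity_index(cam_conc, fit.k_tau, f_on) if f_on > 0 else float("inf"),
        tau_gt30_fraction=fit.tau_gt_max_fraction,
        n_intervals=fit.n_intervals,
    )
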