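"""Ligand occupancy distributions and Poisson-family fits.

Each spot's rhodamine step model yields an integer bound-ligand trajectory
N_CAM(t); the population histogram of initial occupancies is fitted with a
Poisson law (independent per-subunit binding), a two-component Poisson
mixture (two kinetically distinct subpopulations), or a geometric
(discrete single-exponential) law, compared by AIC.  A stoichiometry-
matched comparison of the zero- and nonzero-occupancy subpopulations
(F-test then Welch t-test on the subunit counts) checks that empty spots
are not simply smaller assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .stepfind import StepModel

__all__ = [
    "OccupancyFit",
    "StoichiometryRecord",
    "occupancy_trajectory",
    "histogram_from_values",
    "fit_poisson",
    "fit_two_poisson",
    "fit_geometric",
    "compare_subpopulations",
    "stoichiometry_filter",
]


def _intensity_anchor(model: StepModel, occ_rel: np.ndarray) -> int:
    """Integer base offset aligning relative occupancies with intensity.

    Frame-weighted least squares over all levels: the offset is the rounded
    weighted mean of (level mean / step size - relative occupancy), floored
    at zero.  Using every level (rather than only the lowest) keeps a
    single merged or misread level from shifting the whole trajectory.
    """
    if not model.levels:
        return 0
    # per-spot unit amplitude: the global calibration is broadened by the
    # illumination profile, but within one spot the unit step is fixed
    if model.steps:
        unit = float(np.median([abs(s.delta_I) / s.multiplicity
                                for s in model.steps]))
    else:
        unit = model.params.step_mean
    if not np.isfinite(unit) or unit <= 0:
        unit = model.params.step_mean
    w = np.array([lev.n_frames for lev in model.levels], dtype=float)
    m = np.array([lev.mean_intensity for lev in model.levels])
    resid = m / unit - occ_rel[: len(m)]
    return max(int(round(float((w * resid).sum() / w.sum()))), 0)


def occupancy_trajectory(model: StepModel) -> np.ndarray:
    """Integer bound-ligand count per frame.

    The trajectory is the cumulative signed step multiplicity, anchored so
    the lowest fitted level sits at its calibrated occupancy
    (round(level mean / step size), floored at zero).  For fully bleached
    or ligand-cycling records this reduces to anchoring the minimum
    observed level at zero.
    """
    occ = [0]
    for s in model.steps:
        occ.append(occ[-1] + s.sign * s.multiplicity)
    occ = np.asarray(occ) - min(occ)
    occ = occ + _intensity_anchor(model, occ)
    frames = []
    for level, o in zip(model.levels, occ):
        frames.extend([int(o)] * level.n_frames)
    return np.asarray(frames, dtype=int)


def histogram_from_values(values: Sequence[int], s_max: Optional[int] = None) -> np.ndarray:
    """Counts per occupancy 0..s_max from per-spot occupancy values."""
    values = np.asarray(values, dtype=int)
    if np.any(values < 0):
        raise ValueError("occupancies must be nonnegative")
    hi = int(values.max()) if s_max is None else int(s_max)
    return np.bincount(values, minlength=hi + 1)


@dataclass
class OccupancyFit:
    model: str                       # "poisson", "two_poisson", "geometric"
    histogram: np.ndarray
    n_spots: int
    mean_occupancy: float
    se_mean: float
    lam: Optional[float] = None      # single Poisson / geometric mean
    w: Optional[float] = None        # mixture weight of component 1
    lam1: Optional[float] = None     # low-occupancy component
    lam2: Optional[float] = None     # high-occupancy component
    gof_chi2: float = float("nan")
    gof_p: float = float("nan")
    aic: float = float("nan")
    flags: set = field(default_factory=set)


def _chi2_gof(histogram: np.ndarray, pmf: np.ndarray, n_params: int) -> tuple:
    """Chi-square GOF with tail bins pooled to expected count >= 5."""
    n = histogram.sum()
    expected = n * pmf
    obs, exp = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(histogram, expected):
        acc_o += o
        acc_e += e
        if acc_e >= 5:
            obs.append(acc_o)
            exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp:
        obs[-1] += acc_o
        exp[-1] += acc_e
    obs, exp = np.asarray(obs), np.asarray(exp)
    # renormalize tiny truncation mismatch
    exp = exp * obs.sum() / exp.sum()
    dof = len(obs) - 1 - n_params
    if dof < 1:
        return float("nan"), float("nan")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return chi2, float(stats.chi2.sf(chi2, dof))


def _hist_stats(histogram: np.ndarray) -> tuple:
    histogram = np.asarray(histogram, dtype=float)
    n = histogram.sum()
    k = np.arange(len(histogram))
    mean = float((k * histogram).sum() / n) if n else 0.0
    var = float(((k - mean) ** 2 * histogram).sum() / max(n - 1, 1)) if n else 0.0
    se = float(np.sqrt(var / n)) if n else float("nan")
    return n, mean, se


def _loglik(histogram: np.ndarray, pmf: np.ndarray) -> float:
    sel = histogram > 0
    return float((histogram[sel] * np.log(np.clip(pmf[sel], 1e-300, None))).sum())


def fit_poisson(histogram: np.ndarray, min_spots: int = 20) -> OccupancyFit:
    """Maximum-likelihood single-Poisson fit (lambda = histogram mean)."""
    histogram = np.asarray(histogram, dtype=float)
    n, mean, se = _hist_stats(histogram)
    if n < min_spots:
        raise ValueError(f"need >= {min_spots} spots, got {int(n)}")
    fit = OccupancyFit(model="poisson", histogram=histogram, n_spots=int(n),
                       mean_occupancy=mean, se_mean=se, lam=mean)
    if mean == 0:
        fit.flags.add("all_zero")
        return fit
    k = np.arange(len(histogram))
    pmf = stats.poisson.pmf(k, mean)
    pmf[-1] += stats.poisson.sf(k[-1], mean)  # fold the tail into the top bin
    fit.gof_chi2, fit.gof_p = _chi2_gof(histogram, pmf, n_params=1)
    fit.aic = -2 * _loglik(histogram, pmf) + 2 * 1
    return fit


def fit_two_poisson(
    histogram: np.ndarray,
    min_spots: int = 50,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> OccupancyFit:
    """EM fit of a two-component Poisson mixture to the occupancy histogram.

    Ten seeded random restarts; reports the AIC against the single-Poisson
    fit and labels the components low/high by their means.  Degenerate
    solutions (vanishing weight or coincident means) fall back to the
    single Poisson, flagged ``degenerate_mixture``.
    """
    histogram = np.asarray(histogram, dtype=float)
    n, mean, se = _hist_stats(histogram)
    if n < min_spots:
        raise ValueError(f"need >= {min_spots} spots, got {int(n)}")
    single = fit_poisson(histogram, min_spots=min(min_spots, 20))
    k = np.arange(len(histogram))
    rng = np.random.default_rng(seed)

    best = None
    best_ll = -np.inf
    for _ in range(n_restarts):
        w = rng.uniform(0.2, 0.8)
        l1 = mean * rng.uniform(0.1, 0.9)
        l2 = mean * rng.uniform(1.1, 3.0)
        ll_prev = -np.inf
        for _it in range(max_iter):
            p1 = w * stats.poisson.pmf(k, max(l1, 1e-9))
            p2 = (1 - w) * stats.poisson.pmf(k, max(l2, 1e-9))
            tot = np.clip(p1 + p2, 1e-300, None)
            r1 = p1 / tot
            ll = float((histogram * np.log(tot)).sum())
            n1 = float((histogram * r1).sum())
            n2 = n - n1
            if n1 <= 0 or n2 <= 0:
                break
            w = n1 / n
            l1 = float((histogram * r1 * k).sum() / n1)
            l2 = float((histogram * (1 - r1) * k).sum() / n2)
            if abs(ll - ll_prev) < tol:
                break
            ll_prev = ll
        if ll > best_ll:
            best_ll = ll
            best = (w, l1, l2)

    w, l1, l2 = best
    if l1 > l2:
        w, l1, l2 = 1 - w, l2, l1
    aic2 = -2 * best_ll + 2 * 3
    degenerate = (
        w < 0.02 or w > 0.98
        or abs(l2 - l1) < 0.05 * max(l2, 1e-9)
    )
    if degenerate or aic2 >= single.aic:
        out = fit_poisson(histogram, min_spots=min(min_spots, 20))
        if degenerate:
            out.flags.add("degenerate_mixture")
        out.flags.add("mixture_rejected")
        # still expose the attempted mixture AIC for reporting
        out.aic = single.aic
        return out
    pmf = w * stats.poisson.pmf(k, l1) + (1 - w) * stats.poisson.pmf(k, l2)
    pmf[-1] += w * stats.poisson.sf(k[-1], l1) + (1 - w) * stats.poisson.sf(k[-1], l2)
    fit = OccupancyFit(model="two_poisson", histogram=histogram, n_spots=int(n),
                       mean_occupancy=mean, se_mean=se,
                       w=float(w), lam1=float(l1), lam2=float(l2), aic=float(aic2))
    fit.gof_chi2, fit.gof_p = _chi2_gof(histogram, pmf, n_params=3)
    return fit


def fit_geometric(histogram: np.ndarray, min_spots: int = 20) -> OccupancyFit:
    """Discrete single-exponential (geometric on 0,1,2,...) fit by MLE."""
    histogram = np.asarray(histogram, dtype=float)
    n, mean, se = _hist_stats(histogram)
    if n < min_spots:
        raise ValueError(f"need >= {min_spots} spots, got {int(n)}")
    p = 1.0 / (1.0 + mean)  # MLE for geometric starting at 0
    k = np.arange(len(histogram))
    pmf = p * (1 - p) ** k
    pmf[-1] += (1 - p) ** (k[-1] + 1)
    fit = OccupancyFit(model="geometric", histogram=histogram, n_spots=int(n),
                       mean_occupancy=mean, se_mean=se, lam=mean)
    fit.gof_chi2, fit.gof_p = _chi2_gof(histogram, pmf, n_params=1)
    fit.aic = -2 * _loglik(histogram, pmf) + 2 * 1
    return fit


@dataclass
class StoichiometryRecord:
    spot_id: int
    s_camkii: int            # Venus bleach-step subunit count
    n_cam: int               # initial bound-ligand occupancy
    venus_intensity: float = float("nan")  # projected, in ADU
    filter_pass: bool = True
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.s_camkii < 1:
            raise ValueError("s_camkii must be >= 1")
        if self.n_cam > self.s_camkii:
            self.flags.add("occupancy_exceeds_stoichiometry")


def compare_subpopulations(records: Sequence[StoichiometryRecord]) -> dict:
    """Compare S_CaMKII of the zero- vs nonzero-occupancy subpopulations.

    F-test for variance equality, then a two-sample Welch (unequal
    variance) t-test on the means.  Returns means, SDs, and both p-values.
    """
    zero = np.array([r.s_camkii for r in records if r.n_cam == 0], dtype=float)
    nonzero = np.array([r.s_camkii for r in records if r.n_cam > 0], dtype=float)
    if len(zero) < 3 or len(nonzero) < 3:
        raise ValueError("each subpopulation needs >= 3 spots")
    v0, v1 = np.var(zero, ddof=1), np.var(nonzero, ddof=1)
    f_stat = v0 / v1 if v1 > 0 else np.inf
    d0, d1 = len(zero) - 1, len(nonzero) - 1
    p_f = 2 * min(stats.f.sf(f_stat, d0, d1), stats.f.cdf(f_stat, d0, d1))
    t_res = stats.ttest_ind(zero, nonzero, equal_var=False)
    return {
        "mean_zero": float(zero.mean()), "sd_zero": float(zero.std(ddof=1)),
        "n_zero": len(zero),
        "mean_nonzero": float(nonzero.mean()),
        "sd_nonzero": float(nonzero.std(ddof=1)), "n_nonzero": len(nonzero),
        "p_f_test": float(min(p_f, 1.0)),
        "p_t_test": float(t_res.pvalue),
    }


def stoichiometry_filter(
    records: Sequence[StoichiometryRecord],
    monomer_intensity: float,
    band: Tuple[float, float] = (6.0, 28.0),
) -> tuple:
    """Keep spots whose Venus intensity falls inside a monomer-unit band.

    The default band [6, 28] monomer units accepts holoenzymes while
    rejecting monomers/dimers below and aggregates above.  Returns
    (passing records, report dict); every record's ``filter_pass`` is set.
    """
    if not np.isfinite(monomer_intensity) or monomer_intensity <= 0:
        raise ValueError("monomer intensity calibration required")
    lo, hi = band
    passed: List[StoichiometryRecord] = []
    n_below = n_above = 0
    for r in records:
        units = r.venus_intensity / monomer_intensity
        r.filter_pass = lo <= units <= hi
        if r.filter_pass:
            passed.append(r)
        elif units < lo:
            n_below += 1
        else:
            n_above += 1
    report = {
        "n_input": len(records), "n_pass": len(passed),
        "n_below_band": n_below, "n_above_band": n_above,
        "band_monomer_units": (lo, hi),
    }
    return passed, report
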