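"""Growth-kinetics tolerance statistics: mu_max, IIE and RSGR.

The tolerance ratio of a strain is T = mu_max(with solvent) / mu_max(without).
Two screen statistics compare a candidate strain (overexpression clone or
deletion mutant) with the wild type, each measured at 0% and at a challenge
concentration (0.5% v/v n-butanol by convention), with four biological
replicates:

    IIE  = (T_clone / T_wt - 1) * 100         "improvement in the inhibitory
                                               effect": percent gain in
                                               solvent tolerance over wild type
    RSGR = (mu_clone,0 / mu_wt,0 - 1) * 100   percent change of the
                                               solvent-free growth rate
                                               (negative = growth penalty)

mu_max is estimated as the maximal slope of ln(OD600) over sliding windows of
consecutive readings — an assumption-light estimator that needs no parametric
growth model. Significance of an IIE comes from a two-sample two-sided
Student's t-test on the per-replicate tolerance ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthdata import GrowthCurve

logger = logging.getLogger(__name__)


@dataclass
class GrowthFit:
    strain_id: str
    condition: float
    replicate: int
    mu_max: float  # 1/h
    window: tuple[float, float]  # (t_start, t_end) hours
    r_squared: float
    flat: bool = False  # set when OD never increases (mu_max forced to 0)


@dataclass
class ToleranceResult:
    gene_id: str
    mode: str  # 'overexpression' | 'deletion'
    iie: float  # percent
    iie_sd: float
    rsgr: float  # percent
    rsgr_sd: float
    p_value: float
    n_replicates: int
    significant: bool


def fit_mu_max(
    curve: GrowthCurve,
    window_points: int = 5,
    min_od: float = 0.02,
    blank: float = 0.0,
    smooth_points: int = 1,
    od_band: tuple[float, float] | None = None,
) -> GrowthFit:
    """Maximum specific growth rate by sliding-window log-linear regression.

    Blank-subtracted readings above ``min_od`` enter the fit; the slope of
    ln(OD) vs time is computed for every window of ``window_points``
    consecutive readings and the maximum is reported together with the
    winning window and its R². A curve that never increases yields
    mu_max = 0 with the ``flat`` flag set.

    ``smooth_points`` > 1 applies a centered moving average to the OD series
    first. During exponential growth a moving average multiplies OD by a
    constant factor, so it suppresses reader noise without biasing the
    slope; it is the standard pre-step for noisy plate-reader kinetics.

    ``od_band=(lo, hi)`` switches to a single log-linear fit over the
    readings with OD inside the band instead of the sliding-window maximum.
    Because saturating growth curves are time-rescaling invariant (the OD
    trajectory is a fixed function of mu*t), fitting every strain over the
    same OD band underestimates mu by the same multiplicative factor for
    all strains, which cancels exactly in ratio statistics such as the
    tolerance ratio and IIE; this is the preferred mode for replicate
    screens built on ratios.
    """
    if window_points < 2:
        raise ValueError("window_points must be >= 2")
    od = curve.od600 - blank
    if smooth_points > 1:
        k = smooth_points
        kernel = np.ones(k) / k
        od = np.convolve(od, kernel, mode="valid")
        # centered average is only defined where the full kernel fits
        half = (k - 1) // 2
        times_all = curve.times[half : half + len(od)]
    else:
        times_all = curve.times
    keep = od > min_od
    t = times_all[keep]
    od = od[keep]
    if od_band is not None:
        lo, hi = od_band
        if not (0 < lo < hi):
            raise ValueError("od_band must satisfy 0 < lo < hi")
        in_band = (od >= lo) & (od <= hi)
        if int(in_band.sum()) < 2:
            raise ValueError(
                f"only {int(in_band.sum())} readings inside od_band={od_band} (need >= 2)"
            )
        tt, yy = t[in_band], np.log(od[in_band])
        tc, yc = tt - tt.mean(), yy - yy.mean()
        sxx = float(tc @ tc)
        slope = float(tc @ yc) / sxx
        ss_tot = float(yc @ yc)
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - (ss_tot - slope * float(tc @ yc)) / ss_tot)
        flat = slope <= 0
        return GrowthFit(
            strain_id=curve.strain_id,
            condition=curve.condition,
            replicate=curve.replicate,
            mu_max=max(slope, 0.0),
            window=(float(tt[0]), float(tt[-1])),
            r_squared=r2,
            flat=flat,
        )
    if len(od) < window_points:
        raise ValueError(
            f"only {len(od)} usable readings above min_od={min_od} "
            f"(need >= {window_points})"
        )
    y = np.log(od)
    n = len(y)
    w = window_points
    best_slope, best_i, best_r2 = -np.inf, 0, 0.0
    for i in range(n - w + 1):
        tt, yy = t[i : i + w], y[i : i + w]
        tc = tt - tt.mean()
        yc = yy - yy.mean()
        sxx = float(tc @ tc)
        slope = float(tc @ yc) / sxx
        if slope > best_slope:
            ss_tot = float(yc @ yc)
            ss_res = ss_tot - slope * float(tc @ yc)
            r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
            best_slope, best_i, best_r2 = slope, i, r2
    flat = best_slope <= 0
    mu = max(best_slope, 0.0)
    if flat:
        logger.info("fit_mu_max(%s): OD never increases, mu_max set to 0", curve.strain_id)
    return GrowthFit(
        strain_id=curve.strain_id,
        condition=curve.condition,
        replicate=curve.replicate,
        mu_max=mu,
        window=(float(t[best_i]), float(t[best_i + w - 1])),
        r_squared=best_r2,
        flat=flat,
    )


def tolerance_ratio(mu_at_butanol: float, mu_at_zero: float) -> float:
    """T = mu_max(solvent) / mu_max(no solvent)."""
    if mu_at_zero <= 0:
        raise ValueError("mu_at_zero must be positive")
    return mu_at_butanol / mu_at_zero


def compute_iie(t_clone: float, t_wt: float) -> float:
    """Improvement in the Inhibitory Effect, percent; positive = more tolerant."""
    if t_wt <= 0:
        raise ValueError("wild-type tolerance ratio must be positive")
    return (t_clone / t_wt - 1.0) * 100.0


def compute_rsgr(mu_clone_0: float, mu_wt_0: float) -> float:
    """Percent change of the solvent-free growth rate vs wild type;
    negative values are a growth penalty of carrying/deleting the gene."""
    if mu_wt_0 <= 0:
        raise ValueError("wild-type mu at 0% must be positive")
    return (mu_clone_0 / mu_wt_0 - 1.0) * 100.0


def _mu_by_replicate(curves: list[GrowthCurve], condition: float, **fit_kwargs) -> dict[int, float]:
    out: dict[int, float] = {}
    for c in curves:
        if c.condition == condition:
            if c.replicate in out:
                raise ValueError(f"duplicate replicate {c.replicate} at condition {condition}")
            out[c.replicate] = fit_mu_max(c, **fit_kwargs).mu_max
    return out


def screen_gene(
    clone_curves: list[GrowthCurve],
    wt_curves: list[GrowthCurve],
    alpha: float = 0.05,
    gene_id: str | None = None,
    mode: str = "overexpression",
    butanol_condition: float | None = None,
    **fit_kwargs,
) -> ToleranceResult:
    """Score one candidate gene from clone and wild-type growth curves.

    Each strain must have curves at 0% and one challenge concentration
    (auto-detected unless ``butanol_condition`` is given). Replicate r of the
    clone is paired with replicate r of the wild type; per pairing the IIE
    and RSGR are computed and their mean ± sd reported. With unequal
    replicate counts the pairing falls back to comparing each clone replicate
    against the wild-type mean (warning logged). The p-value is a two-sample
    two-sided Student's t on the per-replicate tolerance ratios.
    """
    conds = sorted({c.condition for c in clone_curves} | {c.condition for c in wt_curves})
    if butanol_condition is None:
        nonzero = [c for c in conds if c > 0]
        if len(nonzero) != 1:
            raise ValueError(f"cannot auto-detect challenge condition from {conds}")
        butanol_condition = nonzero[0]
    if 0.0 not in conds:
        raise ValueError("curves at 0% solvent are required")

    mu_c0 = _mu_by_replicate(clone_curves, 0.0, **fit_kwargs)
    mu_cb = _mu_by_replicate(clone_curves, butanol_condition, **fit_kwargs)
    mu_w0 = _mu_by_replicate(wt_curves, 0.0, **fit_kwargs)
    mu_wb = _mu_by_replicate(wt_curves, butanol_condition, **fit_kwargs)

    reps_clone = sorted(set(mu_c0) & set(mu_cb))
    reps_wt = sorted(set(mu_w0) & set(mu_wb))
    if not reps_clone or not reps_wt:
        raise ValueError("each strain needs replicates at both conditions")

    t_clone = np.array([tolerance_ratio(mu_cb[r], mu_c0[r]) for r in reps_clone])
    t_wt = np.array([tolerance_ratio(mu_wb[r], mu_w0[r]) for r in reps_wt])

    if reps_clone == reps_wt:
        iie = np.array([compute_iie(tc, tw) for tc, tw in zip(t_clone, t_wt)])
        rsgr = np.array(
            [compute_rsgr(mu_c0[r], mu_w0[r]) for r in reps_clone]
        )
    else:
        logger.warning(
            "screen_gene(%s): unequal replicate counts (%d clone vs %d wt); "
            "pairing against the wild-type mean",
            gene_id, len(reps_clone), len(reps_wt),
        )
        iie = np.array([compute_iie(tc, float(t_wt.mean())) for tc in t_clone])
        mu_w0_mean = float(np.mean([mu_w0[r] for r in reps_wt]))
        rsgr = np.array([compute_rsgr(mu_c0[r], mu_w0_mean) for r in reps_clone])

    p = tolerance_ttest(t_clone, t_wt)
    gid = gene_id or (clone_curves[0].strain_id if clone_curves else "gene")
    return ToleranceResult(
        gene_id=gid,
        mode=mode,
        iie=float(iie.mean()),
        iie_sd=float(iie.std(ddof=1)) if len(iie) > 1 else 0.0,
        rsgr=float(rsgr.mean()),
        rsgr_sd=float(rsgr.std(ddof=1)) if len(rsgr) > 1 else 0.0,
        p_value=p,
        n_replicates=len(reps_clone),
        significant=p < alpha,
    )


def tolerance_ttest(t_clone: np.ndarray, t_wt: np.ndarray) -> float:
    """Two-sample two-sided Student's t (equal variances) on per-replicate
    tolerance ratios; this is the decision rule behind ``screen_gene``."""
    t_clone = np.asarray(t_clone, float)
    t_wt = np.asarray(t_wt, float)
    if np.ptp(t_clone) == 0 and np.ptp(t_wt) == 0:
        return 1.0 if t_clone.mean() == t_wt.mean() else 0.0
    return float(stats.ttest_ind(t_clone, t_wt).pvalue)
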