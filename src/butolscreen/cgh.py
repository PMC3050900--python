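"""Two-channel array normalization, enrichment profiles and differential calling.

The analysis chain mirrors a pooled-library comparative-hybridization screen:
per-array LOWESS normalization of the log-ratio (M) against mean log-intensity
(A) removes intensity-dependent dye bias; probe-level ratios are summarized to
per-gene enrichment profiles across the serial challenge steps; a one-sample
Student's t-test of each profile against zero calls enriched/depleted genes at
p < alpha; genes with the same call in the solvent-free control arm are then
subtracted as general growth-advantage artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .synthdata import ArrayScan, StepSchedule

logger = logging.getLogger(__name__)

ENRICHED = "enriched"
DEPLETED = "depleted"


@dataclass
class NormalizedScan:
    step: str
    arm: str
    data: pd.DataFrame  # columns: probe_id, A, M, M_norm
    n_dropped: int


def lowess_normalize(
    scan: ArrayScan, span: float = 0.3, fit_floor_quantile: float = 0.02
) -> NormalizedScan:
    """LOWESS-normalize one two-channel scan.

    M = log2(sample/reference), A = 0.5*log2(sample*reference); the returned
    ``M_norm`` is M minus the locally weighted regression of M on A with
    window fraction ``span`` (robustifying iterations on). Rows with a
    non-positive intensity are dropped and counted; more than 50% dropped is
    an error.

    Spots whose intensity in either channel falls below the
    ``fit_floor_quantile`` quantile of the reference channel are excluded
    from the trend *fit* (their trend value is interpolated and they are
    still normalized and returned): near-background spots cluster on a
    degenerate M(A) line and would otherwise drag the local fit, the usual
    reason array pipelines filter low-intensity features before
    normalization. Set to 0 to disable.
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    df = scan.data
    ok = (df["sample"] > 0) & (df["reference"] > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "lowess_normalize(%s/%s): dropped %d rows with non-positive intensity",
            scan.step, scan.arm, n_dropped,
        )
    if n_dropped > 0.5 * len(df):
        raise ValueError(
            f"more than 50% of rows ({n_dropped}/{len(df)}) have non-positive intensities"
        )
    sub = df.loc[ok]
    s = sub["sample"].to_numpy(float)
    r = sub["reference"].to_numpy(float)
    m = np.log2(s / r)
    a = 0.5 * np.log2(s * r)
    floor = np.quantile(r, fit_floor_quantile) if fit_floor_quantile > 0 else 0.0
    in_fit = (s >= floor) & (r >= floor)
    if in_fit.sum() < max(10, 0.25 * len(s)):
        in_fit = np.ones(len(s), dtype=bool)  # degenerate scan: fit on all
    fitted = lowess(m[in_fit], a[in_fit], frac=span, it=3, return_sorted=True)
    trend = np.interp(a, fitted[:, 0], fitted[:, 1])
    out = pd.DataFrame(
        {"probe_id": sub["probe_id"].to_numpy(), "A": a, "M": m, "M_norm": m - trend}
    )
    return NormalizedScan(scan.step, scan.arm, out, n_dropped)


def gene_profiles(
    scans: list[NormalizedScan],
    probe_map: pd.Series,
    schedule: StepSchedule | None = None,
) -> dict[str, pd.DataFrame]:
    """Summarize probe-level normalized ratios to per-gene step profiles.

    Per gene and step the value is the median of its probes' normalized
    log2 ratios (robust to single bad probes). Returns one gene x step matrix
    per arm. Probes without a gene mapping, and genes with no probe on some
    array, are omitted with a logged count. A scan whose step label is not in
    the schedule is an error.
    """
    schedule = schedule or StepSchedule()
    labels = schedule.labels
    by_arm: dict[str, dict[str, pd.Series]] = {}
    for ns in scans:
        if ns.step not in labels:
            raise ValueError(f"scan step {ns.step!r} not present in schedule {labels}")
        d = ns.data.copy()
        d["gene_id"] = d["probe_id"].map(probe_map)
        n_unmapped = int(d["gene_id"].isna().sum())
        if n_unmapped:
            logger.info(
                "gene_profiles(%s/%s): %d probes without gene mapping omitted",
                ns.step, ns.arm, n_unmapped,
            )
        med = d.dropna(subset=["gene_id"]).groupby("gene_id")["M_norm"].median()
        by_arm.setdefault(ns.arm, {})[ns.step] = med
    out: dict[str, pd.DataFrame] = {}
    for arm, cols in by_arm.items():
        mat = pd.DataFrame(cols).reindex(columns=[s for s in labels if s in cols])
        n_incomplete = int(mat.isna().any(axis=1).sum())
        if n_incomplete:
            logger.info("gene_profiles(%s): %d genes missing a step value omitted", arm, n_incomplete)
        out[arm] = mat.dropna()
        out[arm].index.name = "gene_id"
    return out


def detect_differential(
    profiles: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """One-sample two-sided Student's t of each gene's step values against 0.

    Challenge steps are treated as independent observations (a simplification:
    serial transfers are in fact dependent). Significant iff p < ``alpha``
    (after Benjamini-Hochberg adjustment when ``correction='bh'``); direction
    follows the sign of the mean. Zero-variance profiles with a nonzero mean
    are reported at p = 0 with ``degenerate_variance`` set; zero-variance
    zero-mean profiles are never called.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 challenge steps per profile for a t-test")
    if correction not in ("none", "bh"):
        raise ValueError("correction must be 'none' or 'bh'")
    vals = profiles.to_numpy(float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_1samp(vals, 0.0, axis=1)
    p = np.where(degenerate & (mean != 0), 0.0, p)
    p = np.where(degenerate & (mean == 0), 1.0, p)
    if correction == "bh":
        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        p_adj = p
    calls = pd.DataFrame(
        {
            "gene_id": profiles.index,
            "direction": np.where(mean > 0, ENRICHED, DEPLETED),
            "mean_log2": mean,
            "p_value": p,
            "p_adjusted": p_adj,
            "significant": (p_adj < alpha) & (mean != 0),
            "degenerate_variance": degenerate,
        }
    ).set_index("gene_id")
    return calls


def filter_control(butanol_calls: pd.DataFrame, control_calls: pd.DataFrame) -> pd.DataFrame:
    """Subtract control-arm hits from the challenged-arm calls.

    A challenged-arm call fails the filter when the same (gene, direction)
    pair is also significant in the solvent-free control arm — such genes
    reflect general growth advantage rather than tolerance. Returns the
    butanol calls with a ``passed_control_filter`` column; candidates are the
    rows with both ``significant`` and ``passed_control_filter``.
    """
    ctl_sig = control_calls.loc[control_calls["significant"]]
    ctl_pairs = set(zip(ctl_sig.index, ctl_sig["direction"]))
    out = butanol_calls.copy()
    out["passed_control_filter"] = [
        (g, d) not in ctl_pairs for g, d in zip(out.index, out["direction"])
    ]
    return out


def candidates(filtered_calls: pd.DataFrame, direction: str | None = None) -> pd.DataFrame:
    """Rows that are significant and survived the control-arm subtraction."""
    sel = filtered_calls["significant"] & filtered_calls["passed_control_filter"]
    if direction is not None:
        sel &= filtered_calls["direction"] == direction
    return filtered_calls.loc[sel]
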