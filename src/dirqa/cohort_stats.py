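"""Patient-level aggregation, median tables, Wilcoxon tests and volume ratios.

Metric records (one per scan and structure) are first averaged per patient
within each comparison arm; population tables then report the median over
patients.  Arm differences are tested with two-sided Wilcoxon signed-rank
tests on patient-paired values at the 5% level; no multiple-testing
correction is applied and raw p-values are reported.

The signed-rank test is implemented here rather than delegated: the exact
two-sided p-value is needed for small cohorts (n = 12 patients), including
tied and zero differences, and both the exact null distribution and a
high-accuracy approximation are exposed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("dsc", "msd", "hd")
ARM_PAIRS = (("CT_MR", "MR_MR"), ("CT_MR", "IOV"), ("MR_MR", "IOV"))


@dataclasses.dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs remaining after discarding zero differences
    mode: str
    all_zero: bool = False


def _signed_rank_null_counts(ranks2: np.ndarray) -> np.ndarray:
    """Unnormalised null distribution of 2·W+ over all sign assignments.

    ``ranks2`` are doubled midranks (integers).  Dynamic programming over
    subset sums: counts[s] = number of sign patterns with 2·W+ = s.  This is
    algebraically identical to enumerating all 2^n sign patterns.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "exact",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded before ranking (classic Wilcoxon, not
    Pratt); ties receive midranks.  ``exact`` enumerates the full null
    distribution of W+ (dynamic programming over doubled midranks, valid
    with ties); ``approximate`` uses a continuity-corrected normal
    approximation with tie-corrected variance and an Edgeworth
    fourth-cumulant term.  If all differences are zero the test is
    degenerate and p = 1 is returned with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1D sequences with n >= 1")
    if mode not in ("exact", "approximate"):
        raise ValueError(f"unknown mode {mode!r}")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, mode, all_zero=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())  # n(n+1)/2
    w_lo, w_hi = min(w_plus, total - w_plus), max(w_plus, total - w_plus)
    if mode == "exact":
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        counts = _signed_rank_null_counts(ranks2)
        probs = counts / counts.sum()
        s = np.arange(len(probs))
        # two-sided: mass at or beyond the observed statistic on either tail
        p = probs[s <= round(2 * w_lo)].sum() + probs[s >= round(2 * w_hi)].sum()
    else:
        mean = total / 2.0
        var = float((ranks**2).sum()) / 4.0  # tie-corrected: sum r_i^2 / 4
        if var == 0:
            return WilcoxonResult(w_plus, 1.0, n, mode)
        sd = np.sqrt(var)
        k4 = -float((ranks**4).sum()) / 8.0
        g2 = k4 / var**2

        def cdf(w: float) -> float:
            z = (w + 0.5 - mean) / sd  # continuity-corrected
            return float(stats.norm.cdf(z) - stats.norm.pdf(z) * (g2 / 24.0) * (z**3 - 3 * z))

        p = cdf(w_lo) + (1.0 - cdf(w_hi - 1.0))
    return WilcoxonResult(w_plus, float(min(1.0, max(0.0, p))), n, mode)


# ---------------------------------------------------------------------------
# Aggregation


def patient_scan_average(records: pd.DataFrame) -> pd.DataFrame:
    """Average DSC/MSD/HD over each patient's scans per (structure, arm).

    Failed records (status != 'ok') are excluded from the means but counted;
    groups with no valid record are kept with NaN metrics and n_scans = 0.
    """
    df = pd.DataFrame(records).copy()
    ok = df[df["status"] == "ok"]
    keys = ["patient_id", "structure", "arm"]
    all_groups = df.groupby(keys, sort=True).size().rename("n_records")
    means = ok.groupby(keys, sort=True)[list(METRICS)].mean()
    n_scans = ok.groupby(keys, sort=True).size().rename("n_scans")
    out = pd.concat([means, n_scans], axis=1).reindex(all_groups.index)
    out["n_scans"] = out["n_scans"].fillna(0).astype(int)
    out["n_failed"] = (all_groups - out["n_scans"]).astype(int)
    return out.reset_index()


def population_median_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Median of patient-level averages per (structure, arm, metric).

    Rows are structures, columns a (metric, arm) MultiIndex; cells with no
    contributing patient are NaN (missing), never zero.
    """
    df = summaries[summaries["n_scans"] > 0]
    med = df.groupby(["structure", "arm"], sort=True)[list(METRICS)].median()
    table = med.unstack("arm")
    table.columns.names = ["metric", "arm"]
    return table


@dataclasses.dataclass
class ComparisonResult:
    structure: str
    metric: str
    arm_a: str
    arm_b: str
    median_a: float
    median_b: float
    delta_of_medians: float
    median_of_differences: float
    p_value: float
    n_pairs: int
    untestable: bool = False

    @property
    def significant(self) -> bool:
        return (not self.untestable) and self.p_value < 0.05


def paired_comparison(
    summaries: pd.DataFrame,
    arm_a: str,
    arm_b: str,
    mode: str = "exact",
) -> list[ComparisonResult]:
    """Per structure and metric: arm medians, their difference, and the
    Wilcoxon signed-rank p-value on patient-paired summaries.

    Patients missing either arm are dropped pairwise.  Both the difference
    of medians (labelled default) and the median of paired differences are
    reported.  Fewer than 2 complete pairs flags the result untestable.
    """
    df = summaries[summaries["n_scans"] > 0]
    results: list[ComparisonResult] = []
    for structure in sorted(df["structure"].unique()):
        sub = df[df["structure"] == structure]
        a = sub[sub["arm"] == arm_a].set_index("patient_id")
        b = sub[sub["arm"] == arm_b].set_index("patient_id")
        paired = a.index.intersection(b.index)
        for metric in METRICS:
            xa = a.loc[paired, metric].astype(float)
            xb = b.loc[paired, metric].astype(float)
            valid = xa.notna() & xb.notna()
            xa, xb = xa[valid], xb[valid]
            n = len(xa)
            if n < 2:
                results.append(
                    ComparisonResult(structure, metric, arm_a, arm_b, np.nan, np.nan, np.nan, np.nan, np.nan, n, True)
                )
                continue
            res = wilcoxon_signed_rank(xa.to_numpy(), xb.to_numpy(), mode=mode)
            med_a, med_b = float(xa.median()), float(xb.median())
            results.append(
                ComparisonResult(
                    structure,
                    metric,
                    arm_a,
                    arm_b,
                    med_a,
                    med_b,
                    med_a - med_b,
                    float((xa - xb).median()),
                    res.p_value,
                    n,
                )
            )
    return results


def comparison_table(results: Sequence[ComparisonResult], metric: str) -> pd.DataFrame:
    """One metric's comparison results as a flat table (one row per structure
    and arm pair) suitable for CSV export in the published table layout."""
    rows = [dataclasses.asdict(r) for r in results if r.metric == metric]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Volume analysis


def volume_ratio_table(records: pd.DataFrame, gt_volumes: pd.DataFrame) -> pd.DataFrame:
    """Planning-to-daily volume ratio joined with propagation accuracy.

    ``ratio = V(planning ground truth) / V(ground truth of the day)`` where
    the planning scan is pCT for the CT_MR arm and pMR for the MR_MR arm.
    Records whose planning volume is unavailable are skipped and counted in
    the ``n_skipped`` attribute of the returned frame.
    """
    gt = gt_volumes.set_index(["patient_id", "scan_id", "structure"])["volume"]
    rows = []
    n_skipped = 0
    planning_scan = {"CT_MR": "pCT", "MR_MR": "pMR"}
    for rec in records.itertuples(index=False):
        src = planning_scan.get(rec.arm)
        if src is None:  # IOV has no planning source
            continue
        key = (rec.patient_id, src, rec.structure)
        if key not in gt.index or not np.isfinite(rec.volume_ref) or rec.volume_ref <= 0:
            n_skipped += 1
            continue
        rows.append(
            {
                "patient_id": rec.patient_id,
                "scan_id": rec.scan_id,
                "structure": rec.structure,
                "arm": rec.arm,
                "ratio": float(gt.loc[key]) / float(rec.volume_ref),
                "dsc": rec.dsc,
                "msd": rec.msd,
                "status": rec.status,
            }
        )
    out = pd.DataFrame(rows, columns=["patient_id", "scan_id", "structure", "arm", "ratio", "dsc", "msd", "status"])
    out.attrs["n_skipped"] = n_skipped
    return out


def planning_volume_comparison(gt_volumes: pd.DataFrame, mode: str = "exact") -> pd.DataFrame:
    """Per-structure planning-CT vs planning-MR volume comparison.

    Median and (min, max) range over patients on each planning scan, plus a
    paired Wilcoxon p-value, mirroring the published volume table.
    """
    df = gt_volumes[gt_volumes["scan_id"].isin(["pCT", "pMR"])]
    rows = []
    for structure in sorted(df["structure"].unique()):
        sub = df[df["structure"] == structure].pivot_table(
            index="patient_id", columns="scan_id", values="volume", aggfunc="first"
        )
        if not {"pCT", "pMR"}.issubset(sub.columns):
            continue
        paired = sub.dropna(subset=["pCT", "pMR"])
        row = {
            "structure": structure,
            "median_pCT": float(paired["pCT"].median()),
            "min_pCT": float(paired["pCT"].min()),
            "max_pCT": float(paired["pCT"].max()),
            "median_pMR": float(paired["pMR"].median()),
            "min_pMR": float(paired["pMR"].min()),
            "max_pMR": float(paired["pMR"].max()),
            "n_patients": len(paired),
        }
        if len(paired) >= 2:
            row["p_value"] = wilcoxon_signed_rank(paired["pCT"].to_numpy(), paired["pMR"].to_numpy(), mode=mode).p_value
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
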