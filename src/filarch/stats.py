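"""Kernel-density values for scatter maps and group-comparison wiring.

These are thin, explicit wrappers with a fixed reporting schema — the
scientific content lives in the geometry and architecture modules.  The
2D KDE standardizes both axes to unit variance first because the mapped
quantities (degrees vs nanometers) are incommensurate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import RecordTable

__all__ = ["kde_at_points", "group_compare"]


def kde_at_points(points: np.ndarray, bandwidth: float | str = "scott",
                  axis_names: tuple[str, str] = ("x", "y")) -> RecordTable:
    """Gaussian kernel density evaluated at each 2D data point.

    Axes are standardized to unit variance before evaluation (Scott's
    rule bandwidth by default); densities are reported on the
    standardized scale together with the bandwidth used.  Raises on a
    degenerate (all-identical) point set.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or len(p) < 2:
        raise ValueError("need an (n, 2) array with n >= 2")
    sd = p.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate point set: an axis has zero variance")
    z = (p - p.mean(axis=0)) / sd
    kde = sps.gaussian_kde(z.T, bw_method=bandwidth)
    dens = kde(z.T)
    df = pd.DataFrame({
        axis_names[0]: p[:, 0],
        axis_names[1]: p[:, 1],
        "density": dens,
    })
    return RecordTable("density_points", df, {
        "bandwidth_factor": float(kde.factor),
        "bandwidth_rule": bandwidth if isinstance(bandwidth, str) else "fixed",
        "standardized": True,
        "axes": list(axis_names),
    })


def _summaries(groups: dict[str, np.ndarray]) -> list[dict]:
    out = []
    for name, v in groups.items():
        v = np.asarray(v, dtype=float)
        out.append({
            "comparison": f"summary:{name}",
            "statistic": np.nan, "df1": np.nan, "df2": np.nan,
            "p_value": np.nan,
            "mean": float(v.mean()),
            "sem": float(v.std(ddof=1) / np.sqrt(len(v))),
            "n": int(len(v)),
        })
    return out


def group_compare(groups: dict[str, np.ndarray],
                  design: str = "anova_tukey") -> RecordTable:
    """Group comparison statistics with means and SEMs.

    ``anova_tukey``: one-way ANOVA followed by Tukey's HSD over all
    pairs (adjusted p-values).  ``ttest``: two-sample Student's t-test.
    ``ftest``: two-sample variance-ratio F-test.  Every group needs
    n >= 2.
    """
    groups = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} has n={len(v)} < 2")
    names = list(groups)
    rows = _summaries(groups)

    if design == "anova_tukey":
        if len(groups) < 2:
            raise ValueError("ANOVA needs >= 2 groups")
        vals = [groups[n] for n in names]
        F, p = sps.f_oneway(*vals)
        k = len(vals)
        N = sum(len(v) for v in vals)
        if np.isfinite(F):
            # guard the degenerate identical-groups case, where floating
            # cancellation can push F infinitesimally below zero
            F = max(float(F), 0.0)
            if not np.isfinite(p):
                p = float(sps.f.sf(F, k - 1, N - k))
        rows.append({"comparison": "anova", "statistic": float(F),
                     "df1": k - 1, "df2": N - k, "p_value": float(p),
                     "mean": np.nan, "sem": np.nan, "n": N})
        if len(groups) >= 2:
            res = sps.tukey_hsd(*vals)
            for i in range(k):
                for j in range(i + 1, k):
                    rows.append({
                        "comparison": f"tukey:{names[i]}|{names[j]}",
                        "statistic": float(res.statistic[i, j]),
                        "df1": np.nan, "df2": np.nan,
                        "p_value": float(res.pvalue[i, j]),
                        "mean": np.nan, "sem": np.nan, "n": N,
                    })
    elif design == "ttest":
        if len(groups) != 2:
            raise ValueError("t-test needs exactly 2 groups")
        a, b = (groups[n] for n in names)
        t, p = sps.ttest_ind(a, b)
        rows.append({"comparison": f"ttest:{names[0]}|{names[1]}",
                     "statistic": float(t), "df1": len(a) + len(b) - 2,
                     "df2": np.nan, "p_value": float(p),
                     "mean": np.nan, "sem": np.nan, "n": len(a) + len(b)})
    elif design == "ftest":
        if len(groups) != 2:
            raise ValueError("F-test needs exactly 2 groups")
        a, b = (groups[n] for n in names)
        F = float(np.var(a, ddof=1) / np.var(b, ddof=1))
        d1, d2 = len(a) - 1, len(b) - 1
        p = 2.0 * min(sps.f.cdf(F, d1, d2), sps.f.sf(F, d1, d2))
        rows.append({"comparison": f"ftest:{names[0]}|{names[1]}",
                     "statistic": F, "df1": d1, "df2": d2,
                     "p_value": float(min(p, 1.0)),
                     "mean": np.nan, "sem": np.nan, "n": len(a) + len(b)})
    else:
        raise ValueError(f"unknown design {design!r}")

    return RecordTable("group_stats", pd.DataFrame(rows), {"design": design})
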