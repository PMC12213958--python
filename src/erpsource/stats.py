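"""Group-level ROI statistics: paired t-tests on per-subject ROI CDR means
with Benjamini-Hochberg FDR control applied separately per correction
family (hemisphere x mask family x component)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .geometry import RoiMaskSet

__all__ = ["paired_t", "bh_fdr", "build_stat_report", "StatTable"]


@dataclass
class StatTable:
    """Per-ROI condition contrasts for one (component, family) analysis."""

    component: str
    family: str
    table: pd.DataFrame  # roi, hemisphere, n, mean_diff, t, df, p, q, significant


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float, float]:
    """Classical paired t-test.

    Returns (t, df, two-sided p, mean difference).  A zero-variance
    difference vector is degenerate: t and p are returned as NaN with the
    mean difference intact.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        return np.nan, df, np.nan, mean
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), df, p, mean


def bh_fdr(p_values: np.ndarray, family_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, per correction family.

    ``family_labels`` (same length as ``p_values``) partitions the tests;
    the step-up procedure runs independently within each family.  NaN
    p-values propagate to NaN q-values without affecting their family.
    """
    p = np.asarray(p_values, float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if family_labels is None:
        family_labels = np.zeros(p.size)
    family_labels = np.asarray(family_labels)
    for fam in pd.unique(family_labels):
        sel = (family_labels == fam) & valid
        if not np.any(sel):
            continue
        q[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return q


def build_stat_report(
    roi_cdr: pd.DataFrame,
    masks: RoiMaskSet,
    fdr_level: float = 0.05,
) -> tuple[list[StatTable], str]:
    """Paired condition contrasts per ROI with family-wise BH correction.

    ``roi_cdr`` is tidy: subject, component, roi, condition, cdr.  For the
    bilateral atlas family the left and right hemispheres form separate
    correction families; the fMRI-constrained group-mask family is
    corrected as one set, per component.  Returns one StatTable per
    (component, family) and a Markdown report of significant ROIs.
    """
    required = {"subject", "component", "roi", "condition", "cdr"}
    if not required.issubset(roi_cdr.columns):
        raise ValueError(f"roi_cdr must have columns {sorted(required)}")
    conds = sorted(roi_cdr["condition"].unique())
    if len(conds) != 2:
        raise ValueError("exactly two conditions are required")
    cond_a = "source_correct" if "source_correct" in conds else conds[0]
    cond_b = [c for c in conds if c != cond_a][0]

    tables: list[StatTable] = []
    lines = ["# ROI condition contrasts", ""]
    for component in sorted(roi_cdr["component"].unique()):
        sub = roi_cdr[roi_cdr["component"] == component]
        for family in ("MTL_atlas", "fMRI_constrained"):
            fam_masks = masks.family(family)
            if not fam_masks:
                continue
            rows = []
            for m in fam_masks:
                cell = sub[sub["roi"] == m.name]
                wide = cell.pivot(index="subject", columns="condition", values="cdr")
                if wide.isna().any().any() or wide.shape[1] != 2:
                    raise ValueError(
                        f"mismatched subject sets across conditions for {m.name!r}"
                    )
                t, df, p, mean_diff = paired_t(
                    wide[cond_a].to_numpy(), wide[cond_b].to_numpy()
                )
                rows.append(
                    {
                        "component": component,
                        "family": family,
                        "hemisphere": m.hemisphere,
                        "roi": m.name,
                        "n": wide.shape[0],
                        "mean_diff": mean_diff,
                        "t": t,
                        "df": df,
                        "p": p,
                    }
                )
            tab = pd.DataFrame(rows)
            if family == "MTL_atlas":
                fam_labels = tab["hemisphere"].to_numpy()
            else:
                fam_labels = np.repeat("group", len(tab))
            tab["q"] = bh_fdr(tab["p"].to_numpy(), fam_labels)
            tab["significant"] = tab["q"] < fdr_level
            tables.append(StatTable(component, family, tab))

            sig = tab[tab["significant"]]
            lines.append(f"## {component} / {family}")
            if sig.empty:
                lines.append("No ROI significant at q < %.2f." % fdr_level)
            else:
                for _, r in sig.iterrows():
                    direction = (
                        f"{cond_a} > {cond_b}" if r["mean_diff"] > 0
                        else f"{cond_b} > {cond_a}"
                    )
                    lines.append(
                        f"- {r['roi']}: t({r['df']}) = {r['t']:.2f}, "
                        f"p = {r['p']:.4f}, q = {r['q']:.4f} ({direction})"
                    )
            lines.append("")
    return tables, "\n".join(lines)
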