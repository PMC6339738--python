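"""Coupling ratios and cohort summary tables.

The coupling ratio (CR) of a finger in one grip is the per-subject ratio of
its DIP flexion angle to its PIP flexion angle.  Aggregation always averages
per-subject ratios (mean of ratios), never the ratio of cell means — on
heterogeneous cohorts the two differ.  Summaries report per-cell mean and
sample SD (n-1 denominator); marginal "All" rows are equal-weight means of
the collapsed cells, which is only well defined on balanced data and is
enforced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import IncompleteDesignError, UndefinedRatioError

RECORD_COLUMNS = ["subject", "diameter_mm", "finger", "joint", "angle_deg"]


def coupling_ratio(dip_deg: float, pip_deg: float) -> float:
    """DIP/PIP flexion-angle ratio; undefined for non-positive PIP."""
    if pip_deg <= 0:
        raise UndefinedRatioError(
            f"coupling ratio undefined for PIP angle {pip_deg} <= 0"
        )
    return float(dip_deg) / float(pip_deg)


def _check_balanced(counts: pd.Series, what: str):
    if counts.empty:
        raise IncompleteDesignError(f"no records for {what}")
    bad = counts[counts != counts.iloc[0]]
    if len(bad):
        raise IncompleteDesignError(
            f"unbalanced {what}: cell counts differ at "
            f"{list(bad.index[:5])} (expected {counts.iloc[0]})"
        )


def compute_cr(records: pd.DataFrame) -> pd.DataFrame:
    """Per-subject coupling ratios from a long joint-angle table.

    Records with PIP <= 0 yield a flagged row (``status="undefined"``,
    NaN cr) rather than being dropped.
    """
    wide = records.pivot_table(index=["subject", "diameter_mm", "finger"],
                               columns="joint", values="angle_deg",
                               aggfunc="first")
    for j in ("DIP", "PIP"):
        if j not in wide.columns:
            raise IncompleteDesignError(f"records missing joint {j}")
    if wide[["DIP", "PIP"]].isna().any().any():
        raise IncompleteDesignError("missing DIP/PIP angles for some cells")
    out = wide.reset_index()[["subject", "diameter_mm", "finger"]].copy()
    pip = wide["PIP"].to_numpy()
    dip = wide["DIP"].to_numpy()
    ok = pip > 0
    cr = np.full(len(pip), np.nan)
    cr[ok] = dip[ok] / pip[ok]
    out["cr"] = cr
    out["status"] = np.where(ok, "ok", "undefined")
    return out


def summarize_angles(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell (diameter x finger x joint) mean/SD/n of flexion angles.

    Requires a balanced subject set per cell; raises
    :class:`IncompleteDesignError` naming an offending cell otherwise.
    Rows are ordered diameter-major, then finger, then joint.
    """
    g = records.groupby(["diameter_mm", "finger", "joint"])["angle_deg"]
    counts = g.count()
    _check_balanced(counts, "angle design")
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)  # n=1 cells: SD reported as 0
    finger_order = {f: i for i, f in enumerate(("index", "middle", "ring", "small"))}
    joint_order = {"DIP": 0, "PIP": 1, "MP": 2}
    out = out.sort_values(
        ["diameter_mm", "finger", "joint"],
        key=lambda s: (s.map(finger_order) if s.name == "finger"
                       else s.map(joint_order) if s.name == "joint" else s),
    ).reset_index(drop=True)
    return out


def summarize_cr(cr_records: pd.DataFrame, policy: str = "strict") -> pd.DataFrame:
    """Per-(diameter, finger) CR summary with equal-weight "All" marginals.

    ``policy="strict"`` refuses flagged (undefined) ratios;
    ``policy="omit_flagged"`` excludes them from their cell and reports the
    reduced n.  Marginal rows/columns are labelled "All": each marginal
    mean is the equal-weight mean of its constituent cell means (exact on
    balanced data), and marginal SDs pool the underlying records.
    """
    recs = cr_records
    flagged = recs[recs.get("status", "ok") != "ok"] if "status" in recs else recs.iloc[0:0]
    if len(flagged):
        if policy == "strict":
            raise IncompleteDesignError(
                f"{len(flagged)} undefined coupling ratios present "
                "(PIP <= 0); use policy='omit_flagged' to exclude them"
            )
        if policy != "omit_flagged":
            raise ValueError(f"unknown policy {policy!r}")
        recs = recs[recs["status"] == "ok"]
    g = recs.groupby(["diameter_mm", "finger"])["cr"]
    counts = g.count()
    if policy == "strict":
        _check_balanced(counts, "CR design")
    if (counts == 0).any():
        raise IncompleteDesignError("empty CR cell after omitting flagged records")
    cells = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    cells["sd"] = cells["sd"].fillna(0.0)

    rows = [cells]
    # diameter marginals: collapse fingers
    for d, sub in cells.groupby("diameter_mm"):
        pooled = recs[recs["diameter_mm"] == d]["cr"]
        rows.append(pd.DataFrame([{
            "diameter_mm": d, "finger": "All", "mean": sub["mean"].mean(),
            "sd": pooled.std(ddof=1), "n": int(sub["n"].sum())}]))
    # finger marginals: collapse diameters
    for f, sub in cells.groupby("finger"):
        pooled = recs[recs["finger"] == f]["cr"]
        rows.append(pd.DataFrame([{
            "diameter_mm": "All", "finger": f, "mean": sub["mean"].mean(),
            "sd": pooled.std(ddof=1), "n": int(sub["n"].sum())}]))
    rows.append(pd.DataFrame([{
        "diameter_mm": "All", "finger": "All", "mean": cells["mean"].mean(),
        "sd": recs["cr"].std(ddof=1), "n": int(cells["n"].sum())}]))
    return pd.concat(rows, ignore_index=True)


def equal_weight_marginals(cell_means: dict) -> dict:
    """Equal-weight marginal means of a (diameter, finger) -> mean table.

    Returns ``{("diameter", d): m, ..., ("finger", f): m, ...,
    ("grand", "All"): m}``; valid as a summary of balanced designs only.
    """
    diameters = sorted({d for d, _ in cell_means})
    fingers = sorted({f for _, f in cell_means})
    out = {}
    for d in diameters:
        out[("diameter", d)] = float(np.mean([cell_means[(d, f)] for f in fingers]))
    for f in fingers:
        out[("finger", f)] = float(np.mean([cell_means[(d, f)] for d in diameters]))
    out[("grand", "All")] = float(np.mean(list(cell_means.values())))
    return out


# ---------------------------------------------------------------------------
# presentation

def render_angle_table(summary: pd.DataFrame) -> str:
    """Markdown table of mean (SD) flexion angles, 1 decimal place."""
    fingers = [f for f in ("index", "middle", "ring", "small")
               if f in set(summary["finger"])]
    joints = [j for j in ("DIP", "PIP", "MP") if j in set(summary["joint"])]
    header = ["Diameter"] + [f"{f} {j}" for f in fingers for j in joints]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    for d in sorted(summary["diameter_mm"].unique()):
        cells = [f"{d} mm"]
        for f in fingers:
            for j in joints:
                row = summary[(summary["diameter_mm"] == d)
                              & (summary["finger"] == f)
                              & (summary["joint"] == j)].iloc[0]
                cells.append(f"{row['mean']:.1f} ({row['sd']:.1f})")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def render_cr_table(summary: pd.DataFrame) -> str:
    """Markdown table of mean (SD) coupling ratios, 2 decimal places."""
    fingers = [f for f in ("index", "middle", "ring", "small", "All")
               if f in set(summary["finger"])]
    diameters = [d for d in summary["diameter_mm"].unique() if d != "All"]
    diameters = sorted(diameters) + (["All"] if "All" in set(summary["diameter_mm"]) else [])
    header = ["Diameter"] + [str(f) for f in fingers]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "---|" * len(header)]
    for d in diameters:
        label = f"{d} mm" if d != "All" else "All"
        cells = [label]
        for f in fingers:
            row = summary[(summary["diameter_mm"] == d) & (summary["finger"] == f)]
            r = row.iloc[0]
            cells.append(f"{r['mean']:.2f} ({r['sd']:.2f})")
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
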