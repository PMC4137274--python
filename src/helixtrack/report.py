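"""Summary statistics and report assembly for rotation datasets.

Implements the small statistical toolkit used to summarize helical-motility
datasets — mean ± SEM, Welch's two-sample t test, and the N−1 two-proportion
z test (the pooled two-proportion statistic scaled by sqrt((N−1)/N)) — and a
report builder that aggregates per-rotation tables into per-condition
summaries, pitch histograms and a rendered Markdown/JSON report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DatasetSummary",
    "mean_sem",
    "two_sample_t",
    "two_proportion_n_minus_1",
    "summarize_rotations",
    "build_report",
]

#: Pitch histogram default: 100 nm bins over 0-1500 nm.
DEFAULT_HIST_BINS = np.arange(0.0, 1500.0 + 100.0, 100.0)


def mean_sem(values) -> tuple[float, float, int]:
    """Arithmetic mean, standard error of the mean (n−1 SD / sqrt n), and n.

    For a single value the SEM is undefined and returned as NaN (flagged).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mean_sem requires at least one value")
    if v.size == 1:
        return float(v[0]), float("nan"), 1
    return float(np.mean(v)), float(np.std(v, ddof=1) / math.sqrt(v.size)), int(v.size)


def two_sample_t(
    values_a, values_b, sided: str = "two", welch: bool = True
) -> tuple[float, float]:
    """Two-sample t test (Welch's unequal-variance form by default).

    ``sided='two'`` is the default; ``sided='one'`` reports the one-sided
    p-value for mean(a) > mean(b).  Set ``welch=False`` for the pooled
    Student form.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    alternative = {"two": "two-sided", "one": "greater"}.get(sided)
    if alternative is None:
        raise ValueError("sided must be 'two' or 'one'")
    res = sps.ttest_ind(a, b, equal_var=not welch, alternative=alternative)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):  # degenerate zero-variance groups
        t, p = 0.0, 1.0
    return t, p


def two_proportion_n_minus_1(
    k1: int, n1: int, k2: int, n2: int, sided: str = "two"
) -> tuple[float, float]:
    """N−1 two-proportion test.

    The classical pooled two-proportion z statistic multiplied by
    sqrt((N−1)/N) with N = n1 + n2; the p-value is taken from the standard
    normal reference.  Degenerate pooled variance (both proportions 0 or
    both 1) yields (0, 1).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    N = n1 + n2
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / N
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(var) * math.sqrt((N - 1) / N)
    if sided == "two":
        p = 2.0 * sps.norm.sf(abs(z))
    elif sided == "one":
        p = float(sps.norm.sf(z))
    else:
        raise ValueError("sided must be 'two' or 'one'")
    return float(z), float(p)


@dataclass
class DatasetSummary:
    """Per-condition summary of a rotation dataset."""

    condition: str
    n_beads: int
    n_rotations: int
    n_left: int
    n_right: int
    fraction_left: float
    fraction_right: float
    pitch_nm: dict = field(default_factory=dict)  # key -> (mean, sem, n)
    pitch_corrected_nm: dict = field(default_factory=dict)
    speed_nm_per_s: dict = field(default_factory=dict)
    switch_count: int = 0

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_beads": self.n_beads,
            "n_rotations": self.n_rotations,
            "n_left": self.n_left,
            "n_right": self.n_right,
            "fraction_left": self.fraction_left,
            "fraction_right": self.fraction_right,
            "pitch_nm": self.pitch_nm,
            "pitch_corrected_nm": self.pitch_corrected_nm,
            "speed_nm_per_s": self.speed_nm_per_s,
            "switch_count": self.switch_count,
        }


def _group_stats(df: pd.DataFrame, col: str) -> dict:
    out = {}
    groups = [("all", df)] + [(h, df[df["handedness"] == h]) for h in ("left", "right")]
    for key, sub in groups:
        if col not in sub.columns:
            continue
        vals = sub[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            mean, sem, n = mean_sem(vals)
            # JSON-safe: SEM is undefined (NaN) for a single value
            out[key] = (mean, sem if np.isfinite(sem) else None, n)
        else:
            out[key] = (None, None, 0)
    return out


def summarize_rotations(
    rotations: pd.DataFrame,
    condition: str = "dataset",
    n_switches: int = 0,
) -> DatasetSummary:
    """Summarize one per-rotation table (rows = complete rotations).

    Expected columns: ``pitch_nm, handedness`` plus optional
    ``pitch_corrected_nm, speed_nm_per_s, bead_id``.  Every reported N is a
    row count of the input — nothing is silently dropped.
    """
    n = len(rotations)
    n_left = int((rotations["handedness"] == "left").sum()) if n else 0
    n_right = int((rotations["handedness"] == "right").sum()) if n else 0
    n_beads = rotations["bead_id"].nunique() if "bead_id" in rotations.columns and n else 0
    return DatasetSummary(
        condition=condition,
        n_beads=n_beads,
        n_rotations=n,
        n_left=n_left,
        n_right=n_right,
        fraction_left=n_left / n if n else float("nan"),
        fraction_right=n_right / n if n else float("nan"),
        pitch_nm=_group_stats(rotations, "pitch_nm") if n else {},
        pitch_corrected_nm=_group_stats(rotations, "pitch_corrected_nm") if n else {},
        speed_nm_per_s=_group_stats(rotations, "speed_nm_per_s") if n else {},
        switch_count=n_switches,
    )


def _fmt_stat(entry) -> str:
    mean, sem, n = entry
    if n == 0 or mean is None:
        return "-"
    if n == 1 or sem is None or not np.isfinite(sem):
        return f"{mean:.1f} (SEM undefined, N={n})"
    return f"{mean:.1f} +/- {sem:.1f} (SEM, N={n})"


def build_report(
    rotation_tables: dict[str, pd.DataFrame],
    switch_counts: Optional[dict[str, int]] = None,
    hist_bins: Optional[np.ndarray] = None,
    timestamp: Optional[str] = None,
) -> tuple[list[DatasetSummary], dict, str]:
    """Aggregate per-rotation tables into summaries, JSON and Markdown.

    Returns ``(summaries, json_payload, markdown)``.  The Markdown report is
    deterministic apart from the single timestamp header line (omitted when
    ``timestamp`` is None), so regenerating a report from the same CSVs is
    byte-identical.
    """
    if not rotation_tables:
        raise ValueError("at least one rotation table is required")
    if hist_bins is None:
        hist_bins = DEFAULT_HIST_BINS
    switch_counts = switch_counts or {}

    summaries = []
    histograms = {}
    for name, df in rotation_tables.items():
        summaries.append(summarize_rotations(df, name, switch_counts.get(name, 0)))
        pitches = df["pitch_nm"].to_numpy(dtype=float) if len(df) else np.array([])
        counts, _ = np.histogram(pitches[np.isfinite(pitches)], bins=hist_bins)
        histograms[name] = counts.tolist()

    payload = {
        "summaries": [s.to_dict() for s in summaries],
        "pitch_histogram_bins_nm": hist_bins.tolist(),
        "pitch_histograms": histograms,
    }

    lines = ["# Helical motility report", ""]
    if timestamp is not None:
        lines.append(f"generated: {timestamp}")
        lines.append("")
    for s in summaries:
        lines.append(f"## {s.condition}")
        lines.append("")
        if s.n_rotations == 0:
            lines.append("no rotations observed")
            lines.append("")
            continue
        lines.append(f"- rotations: {s.n_rotations}" + (f" ({s.n_beads} beads)" if s.n_beads else ""))
        lines.append(
            f"- handedness: {s.n_left} left ({100 * s.fraction_left:.0f}%), "
            f"{s.n_right} right ({100 * s.fraction_right:.0f}%)"
        )
        lines.append(f"- pitch (measured): {_fmt_stat(s.pitch_nm.get('all', (None, None, 0)))}")
        for h in ("left", "right"):
            entry = s.pitch_nm.get(h, (None, None, 0))
            if entry[2]:
                lines.append(f"  - {h}-handed: {_fmt_stat(entry)}")
        corr = s.pitch_corrected_nm.get("all", (None, None, 0))
        if corr[2]:
            lines.append(f"- pitch (supertwist-corrected): {_fmt_stat(corr)}")
        speed = s.speed_nm_per_s.get("all", (None, None, 0))
        if speed[2]:
            lines.append(f"- helical speed: {_fmt_stat(speed)} nm/s")
        lines.append(f"- handedness switches: {s.switch_count}")
        lines.append("")
    markdown = "\n".join(lines)
    return summaries, payload, markdown


def plot_pitch_histogram(rotations: pd.DataFrame, path, hist_bins: Optional[np.ndarray] = None):
    """Pitch-per-rotation histogram (left/right stacked), saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if hist_bins is None:
        hist_bins = DEFAULT_HIST_BINS
    fig, ax = plt.subplots(figsize=(5, 3.2))
    left = rotations.loc[rotations["handedness"] == "left", "pitch_nm"]
    right = rotations.loc[rotations["handedness"] == "right", "pitch_nm"]
    ax.hist([left, right], bins=hist_bins, stacked=True, label=["left", "right"],
            color=["tab:blue", "tab:red"])
    ax.set_xlabel("pitch per rotation (nm)")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
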