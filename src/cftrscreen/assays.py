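"""Functional-assay metrics: FLIPR, organoid swelling, Ussing, Western blot.

FLIPR membrane-potential traces quantify channel activation as the
maximum post-forskolin fluorescence over the pre-stimulation baseline
(Maximum F/F0) and channel inhibition as the peak immediately before
inhibitor addition over the post-inhibitor minimum (F1 / F-inh).
Forskolin-induced swelling of organoids is the trapezoidal area under
the relative-area curve above 100% out to t = 60 min.  Ussing-chamber
recordings yield the equivalent transepithelial current Ieq = Vte/Rte by
Ohm's law, with channel activity read as the Ieq step after forskolin.
Western-blot band intensities are expressed relative to the calnexin
loading control and as fold change versus a baseline condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reporting import significance_stars


@dataclass
class AssayTrace:
    """Time-ordered fluorescence (RFU) or relative-area (%) measurements.

    ``events`` are explicit ``(label, time)`` markers for drug additions
    (e.g. ``fsk``, ``vx770``, ``inhibitor``); they are recorded by the
    operator, never inferred from the signal.
    """

    times: np.ndarray
    values: np.ndarray
    events: list[tuple[str, float]] = field(default_factory=list)
    sample_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if (np.diff(self.times) < 0).any():
            raise ValueError("times must be ascending")
        for label, t in self.events:
            if not (self.times[0] <= t <= self.times[-1]):
                raise ValueError(f"event {label!r} at t={t} outside the trace")

    def event_time(self, label: str) -> float:
        for lab, t in self.events:
            if lab == label:
                return t
        raise ValueError(f"trace has no {label!r} event")

    def has_event(self, label: str) -> bool:
        return any(lab == label for lab, _ in self.events)


def load_traces(
    data_csv, events_csv=None, value_col: str = "value"
) -> dict[str, AssayTrace]:
    """Load per-sample traces from tidy CSV (sample_id,time,value).

    Multiple rows per (sample_id, time) — e.g. several read points per
    whole-well scan — are averaged into one value per scan.  Events come
    from a second CSV with columns sample_id,label,time.
    """
    data = pd.read_csv(data_csv)
    events = pd.read_csv(events_csv) if events_csv is not None else None
    traces = {}
    for sid, grp in data.groupby("sample_id"):
        per_scan = grp.groupby("time", as_index=False)[value_col].mean()
        per_scan = per_scan.sort_values("time")
        ev = []
        if events is not None:
            ev = [
                (row["label"], float(row["time"]))
                for _, row in events[events["sample_id"] == sid].iterrows()
            ]
        traces[sid] = AssayTrace(
            times=per_scan["time"].to_numpy(),
            values=per_scan[value_col].to_numpy(),
            events=ev,
            sample_id=str(sid),
        )
    return traces


def flipr_fsk_response(
    trace: AssayTrace, baseline: str = "mean", agonist: str = "fsk"
) -> float:
    """Maximum F/F0: peak post-agonist signal over the pre-agonist baseline.

    F0 is the mean of all scans strictly before the agonist event
    (``baseline="last"`` uses only the final pre-agonist scan).  The
    maximum is taken over scans after the agonist and before any
    inhibitor event.
    """
    t_fsk = trace.event_time(agonist)
    pre = trace.values[trace.times < t_fsk]
    if pre.size == 0:
        raise ValueError("no scans before the agonist event")
    f0 = float(pre[-1]) if baseline == "last" else float(pre.mean())
    if f0 <= 0:
        raise ValueError("non-physical baseline: F0 <= 0")
    t_end = (
        trace.event_time("inhibitor") if trace.has_event("inhibitor") else np.inf
    )
    post = trace.values[(trace.times > t_fsk) & (trace.times < t_end)]
    if post.size == 0:
        raise ValueError("no scans after the agonist event")
    return float(post.max() / f0)


def flipr_inhibitor_response(trace: AssayTrace, inhibitor: str = "inhibitor") -> float:
    """F1 / F-inh: peak right before the inhibitor over the post-inhibitor minimum.

    F1 is the value at the last scan before the inhibitor event; F-inh is
    the minimum reached from the inhibitor event to the end of the trace.
    """
    t_inh = trace.event_time(inhibitor)
    pre = trace.values[trace.times < t_inh]
    post = trace.values[trace.times > t_inh]
    if pre.size == 0 or post.size == 0:
        raise ValueError("inhibitor event must have scans on both sides")
    f1 = float(pre[-1])
    f_inh = float(post.min())
    if f_inh <= 0:
        raise ValueError("non-physical post-inhibitor minimum: F-inh <= 0")
    return f1 / f_inh


def pooled_t_test(a: np.ndarray, b: np.ndarray, welch: bool = False) -> tuple[float, float]:
    """Two-sided unpaired t-test; pooled-variance Student by default."""
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def normalize_and_test(
    metrics: pd.DataFrame,
    control_label: str,
    value_col: str = "value",
    condition_col: str = "condition",
    welch: bool = False,
) -> pd.DataFrame:
    """Normalize per-sample metrics to the control mean and t-test each condition.

    Every value is divided by the mean of the control group; each
    non-control condition is compared with the control by a two-sided
    unpaired t-test (pooled-variance Student by default, Welch via
    ``welch=True``).  Returns one row per condition with the fold versus
    control, t, p and significance stars.
    """
    groups = metrics.groupby(condition_col)[value_col]
    if control_label not in groups.groups:
        raise ValueError(f"control group {control_label!r} missing")
    control = groups.get_group(control_label).to_numpy(dtype=float)
    if control.size < 2:
        raise ValueError("control group needs >= 2 samples")
    control_mean = control.mean()
    rows = []
    for cond, vals in groups:
        vals = vals.to_numpy(dtype=float)
        fold = vals.mean() / control_mean
        if cond == control_label:
            t, p = 0.0, 1.0
        else:
            t, p = pooled_t_test(vals, control, welch=welch)
        rows.append((cond, len(vals), fold, t, p, significance_stars(p)))
    return pd.DataFrame(
        rows, columns=[condition_col, "n", "fold_vs_control", "t", "p_value", "stars"]
    )


def fis_auc(trace: AssayTrace, t_end: float = 60.0, baseline: float = 100.0) -> float:
    """Swelling AUC: trapezoidal integral of (area% - 100) from 0 to t_end.

    The series is the organoid area as % of its initial area, starting at
    stimulation (t = 0, value 100).  Shrinkage below baseline contributes
    negatively (no clipping).  A series ending before ``t_end``
    integrates to its last point with a warning.
    """
    times, values = trace.times, trace.values - baseline
    if times[0] != 0:
        raise ValueError("swelling series must start at t = 0 (stimulation)")
    if times[-1] < t_end:
        warnings.warn(
            f"series ends at t={times[-1]} < {t_end}; integrating to last point",
            stacklevel=2,
        )
        t_stop = times[-1]
    else:
        t_stop = t_end
    mask = times <= t_stop
    t_sel, v_sel = times[mask], values[mask]
    if t_sel[-1] < t_stop:  # interpolate the endpoint
        v_end = np.interp(t_stop, times, values)
        t_sel = np.append(t_sel, t_stop)
        v_sel = np.append(v_sel, v_end)
    return float(np.trapezoid(v_sel, t_sel))


@dataclass
class UssingRecording:
    """Transepithelial potential/resistance series with drug events.

    ``vte`` in mV, ``rte`` in Ohm*cm^2 (must be positive), times in
    seconds.  Ieq = Vte/Rte; with these units Ieq is in microA/cm^2
    after the mV -> V and A -> microA factors cancel to x1000.
    """

    times: np.ndarray
    vte: np.ndarray
    rte: np.ndarray
    events: list[tuple[str, float]] = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vte = np.asarray(self.vte, dtype=float)
        self.rte = np.asarray(self.rte, dtype=float)
        if not (self.times.shape == self.vte.shape == self.rte.shape):
            raise ValueError("times, vte, rte must have equal length")
        if (self.rte <= 0).any():
            raise ValueError("Rte must be positive throughout")

    def event_time(self, label: str) -> float:
        for lab, t in self.events:
            if lab == label:
                return t
        raise ValueError(f"recording has no {label!r} event")

    def has_event(self, label: str) -> bool:
        return any(lab == label for lab, _ in self.events)


@dataclass(frozen=True)
class UssingMetrics:
    ieq: np.ndarray  # microA/cm^2, pointwise Vte/Rte
    delta_ieq_fsk: float
    delta_ieq_inhibitor: float | None


def ussing_metrics(rec: UssingRecording) -> UssingMetrics:
    """Equivalent current series and the forskolin / inhibitor Ieq steps.

    Baseline Ieq is the median over the pre-forskolin window, restricted
    to after the amiloride event when one is present (ENaC block).  The
    forskolin delta is the median post-forskolin Ieq (up to any
    inhibitor event) minus baseline; the inhibitor delta is the median
    post-inhibitor Ieq minus the post-forskolin plateau.
    """
    if not rec.has_event("fsk"):
        raise ValueError("recording has no 'fsk' event")
    ieq = 1000.0 * rec.vte / rec.rte  # mV / (Ohm*cm^2) -> microA/cm^2
    t = rec.times
    t_fsk = rec.event_time("fsk")
    t_start = rec.event_time("amiloride") if rec.has_event("amiloride") else -np.inf
    base_mask = (t > t_start) & (t < t_fsk)
    if not base_mask.any():
        raise ValueError("no baseline window before the fsk event")
    t_inh = rec.event_time("inhibitor") if rec.has_event("inhibitor") else np.inf
    plateau_mask = (t > t_fsk) & (t < t_inh)
    if not plateau_mask.any():
        raise ValueError("no scans after the fsk event")
    baseline = float(np.median(ieq[base_mask]))
    plateau = float(np.median(ieq[plateau_mask]))
    delta_fsk = plateau - baseline
    delta_inh: float | None = None
    if np.isfinite(t_inh):
        post_inh = ieq[t > t_inh]
        if post_inh.size:
            delta_inh = float(np.median(post_inh)) - plateau
    return UssingMetrics(ieq=ieq, delta_ieq_fsk=delta_fsk, delta_ieq_inhibitor=delta_inh)


def wb_fold_change(
    quants: pd.DataFrame,
    baseline_label: str,
    condition_col: str = "condition",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Calnexin-normalized band intensities as fold change versus baseline.

    ``quants`` needs columns sample_id, condition, band_b, band_c,
    calnexin.  Each band is divided by its lane's calnexin and then by
    the baseline condition's mean normalized intensity.  Returns
    (per-sample fold changes, per-condition tests) where the tests frame
    carries the one-way ANOVA across conditions and, per band and
    condition, a pairwise Welch t versus baseline with BH adjustment
    (reported in place of a Dunnett post hoc; see docs).  Samples with
    zero calnexin are excluded with a warning.
    """
    from .fliers import bh_adjust

    df = quants.copy()
    bad = df["calnexin"] <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} sample(s) with non-positive calnexin",
            stacklevel=2,
        )
        df = df[~bad]
    if baseline_label not in set(df[condition_col]):
        raise ValueError(f"baseline condition {baseline_label!r} missing")
    for band in ("band_b", "band_c"):
        df[f"{band}_norm"] = df[band] / df["calnexin"]
    base = df[df[condition_col] == baseline_label]
    folds = df[["sample_id", condition_col]].copy()
    for band in ("band_b", "band_c"):
        folds[f"{band}_fold"] = df[f"{band}_norm"] / base[f"{band}_norm"].mean()

    test_rows = []
    for band in ("band_b", "band_c"):
        groups = [g.to_numpy() for _, g in df.groupby(condition_col)[f"{band}_norm"]]
        if len(groups) > 1 and all(len(g) > 1 for g in groups):
            f_stat, f_p = stats.f_oneway(*groups)
        else:
            f_stat, f_p = np.nan, np.nan
        conds = [c for c in df[condition_col].unique() if c != baseline_label]
        pvals = []
        for cond in conds:
            vals = df.loc[df[condition_col] == cond, f"{band}_norm"].to_numpy()
            ref = base[f"{band}_norm"].to_numpy()
            if len(vals) < 2 or len(ref) < 2:
                pvals.append(np.nan)  # not testable at n = 1
            else:
                _, p = pooled_t_test(vals, ref, welch=True)
                pvals.append(p)
        pvals_arr = np.array(pvals)
        padj = np.full_like(pvals_arr, np.nan)
        finite = np.isfinite(pvals_arr)
        if finite.any():
            padj[finite] = bh_adjust(pvals_arr[finite])
        for cond, p, pa in zip(conds, pvals_arr, padj):
            test_rows.append((band, cond, float(f_stat), float(f_p), float(p), float(pa)))
    tests = pd.DataFrame(
        test_rows,
        columns=["band", "condition", "anova_F", "anova_p", "p_vs_baseline", "p_adj"],
    )
    tests.attrs["posthoc"] = "welch_t_bh"  # substitute for Dunnett, see docs
    return folds, tests
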