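"""ACMA proton-flux trace analysis for liposome ion-channel assays.

In the assay, vesicles loaded with a high-KCl buffer are diluted into NaCl
buffer with the pH-sensitive dye ACMA. Adding valinomycin (a K+ ionophore)
sets an inside-negative membrane potential; if the reconstituted protein
conducts protons, proton influx quenches ACMA fluorescence. Adding the
protonophore CCCP at the end collapses the gradient completely, defining the
full-quench endpoint that normalizes channel-mediated quench between traces.

Outputs per trace: the fractional quench

    (1 - F_pre_cccp) / (1 - F_min_post_cccp)

(channel-mediated quench as a fraction of the CCCP-defined maximum), and an
optional single-exponential rate constant fitted on the valinomycin-to-CCCP
window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FluxTrace",
    "FluxResult",
    "normalize_trace",
    "fractional_quench",
    "fit_quench_rate",
    "summarize_replicates",
    "read_traces_csv",
    "write_traces_csv",
]


@dataclass
class FluxTrace:
    """One ACMA fluorescence time course with its event times."""

    times: np.ndarray  # seconds, strictly increasing
    fluorescence: np.ndarray  # arbitrary units (or normalized)
    t_valinomycin: float
    t_cccp: float
    condition: str = ""
    replicate: str | int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.shape != self.fluorescence.shape:
            raise ValueError("times and fluorescence differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (self.times[0] <= self.t_valinomycin < self.t_cccp <= self.times[-1]):
            raise ValueError(
                "need t_valinomycin < t_cccp inside the recorded span"
            )


@dataclass
class FluxResult:
    condition: str
    replicate: str | int
    fractional_quench: float
    k_quench: float | None = None
    f_plateau: float | None = None
    rmsd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fractional_quench <= 1.0:
            raise ValueError("fractional_quench outside [0, 1]")


def normalize_trace(trace: FluxTrace, baseline_window: tuple[float, float] | None = None) -> FluxTrace:
    """Divide by the mean fluorescence over the pre-valinomycin baseline.

    Default window is everything before ``t_valinomycin``; it must contain at
    least 3 samples. Any positive rescaling of the raw trace leaves the
    result unchanged.
    """
    t, f = trace.times, trace.fluorescence
    if baseline_window is None:
        sel = t < trace.t_valinomycin
    else:
        lo, hi = baseline_window
        if hi > trace.t_valinomycin:
            raise ValueError("baseline window must precede valinomycin addition")
        sel = (t >= lo) & (t <= hi)
    if sel.sum() < 3:
        raise ValueError("baseline window needs >= 3 samples")
    base = float(f[sel].mean())
    if base <= 0:
        raise ValueError("baseline mean is zero or negative")
    return replace(trace, fluorescence=f / base, normalized=True)


def fractional_quench(
    trace: FluxTrace, pre_cccp_window: float = 60.0
) -> float:
    """Channel-mediated quench as a fraction of the full CCCP collapse.

    ``(1 - F_pre) / (1 - F_min)`` where ``F_pre`` is the mean over the last
    ``pre_cccp_window`` seconds before CCCP and ``F_min`` the post-CCCP
    minimum; clamped to [0, 1] against measurement noise. A trace whose
    post-CCCP minimum never drops below baseline indicates a failed
    experiment (no collapse) and raises.
    """
    if not trace.normalized:
        raise ValueError("normalize the trace first")
    t, f = trace.times, trace.fluorescence
    pre = (t >= trace.t_cccp - pre_cccp_window) & (t < trace.t_cccp)
    post = t >= trace.t_cccp
    if pre.sum() == 0 or post.sum() == 0:
        raise ValueError("need samples both just before and after CCCP")
    f_pre = float(f[pre].mean())
    f_min = float(f[post].min())
    if f_min >= 1.0:
        raise ValueError("no CCCP collapse detected (F_min >= baseline)")
    q = (1.0 - f_pre) / (1.0 - f_min)
    return min(max(q, 0.0), 1.0)


def _quench_model(t, k, f_plateau):
    return f_plateau + (1.0 - f_plateau) * np.exp(-k * t)


def fit_quench_rate(trace: FluxTrace) -> tuple[float, float, float]:
    """Least-squares fit of a single-exponential quench on [t_val, t_cccp).

    Model: ``F(t) = f_plateau + (1 - f_plateau) * exp(-k (t - t_val))`` with
    bounds ``k >= 0`` and ``0 <= f_plateau <= 1``. The initializer comes from
    a log-linear seed fit, so the result is deterministic. Returns
    ``(k, f_plateau, rmsd)``.
    """
    if not trace.normalized:
        raise ValueError("normalize the trace first")
    t, f = trace.times, trace.fluorescence
    sel = (t >= trace.t_valinomycin) & (t < trace.t_cccp)
    if sel.sum() < 10:
        raise ValueError("need >= 10 samples between valinomycin and CCCP")
    tt = t[sel] - trace.t_valinomycin
    ff = f[sel]

    # log-linear seed: guess the plateau slightly below the window minimum,
    # regress log(F - plateau_guess) on t for k
    p0_plateau = min(max(float(ff.min()) - 0.02, 0.0), 1.0 - 1e-6)
    resid = np.clip(ff - p0_plateau, 1e-6, None)
    amp0 = max(1.0 - p0_plateau, 1e-6)
    y = np.log(resid / amp0)
    denom = float(np.dot(tt, tt))
    k0 = max(-float(np.dot(tt, y)) / denom, 1e-6) if denom > 0 else 1e-3

    if float(ff.std()) < 1e-12:
        # flat window: no decay to fit
        k, fp = 0.0, float(ff.mean())
        fitted = np.full_like(ff, fp)
        return k, min(max(fp, 0.0), 1.0), float(np.sqrt(np.mean((ff - fitted) ** 2)))

    try:
        popt, _ = curve_fit(
            _quench_model,
            tt,
            ff,
            p0=[k0, p0_plateau],
            bounds=([0.0, 0.0], [np.inf, 1.0]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"quench fit did not converge: {err}") from err
    k, fp = float(popt[0]), float(popt[1])
    rmsd = float(np.sqrt(np.mean((_quench_model(tt, k, fp) - ff) ** 2)))
    return k, fp, rmsd


def analyze_trace(
    trace: FluxTrace,
    *,
    pre_cccp_window: float = 60.0,
    fit_kinetics: bool = True,
) -> FluxResult:
    """Normalize (if needed), quantify fractional quench and fit kinetics."""
    tr = trace if trace.normalized else normalize_trace(trace)
    q = fractional_quench(tr, pre_cccp_window)
    k = fp = rmsd = None
    if fit_kinetics:
        k, fp, rmsd = fit_quench_rate(tr)
    return FluxResult(
        condition=tr.condition,
        replicate=tr.replicate,
        fractional_quench=q,
        k_quench=k,
        f_plateau=fp,
        rmsd=rmsd,
    )


def summarize_replicates(
    traces: list[FluxTrace],
    *,
    pre_cccp_window: float = 60.0,
    strict: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pointwise mean ± SEM curves and per-condition quench statistics.

    Traces are grouped by condition; each condition needs >= 2 replicates on
    a common time grid. Mismatched grids are linearly resampled onto the
    first replicate's grid with a warning (an error in strict mode).

    Returns ``(curves, table)``: ``curves`` has columns condition, time_s,
    mean, sem, n; ``table`` has per-condition mean/SEM of fractional_quench
    and k_quench.
    """
    import warnings

    by_cond: dict[str, list[FluxTrace]] = {}
    for tr in traces:
        by_cond.setdefault(tr.condition, []).append(
            tr if tr.normalized else normalize_trace(tr)
        )

    curve_rows, table_rows = [], []
    for cond, reps in sorted(by_cond.items()):
        if len(reps) < 2:
            raise ValueError(f"condition {cond!r} has < 2 replicates")
        grid = reps[0].times
        mat = []
        for tr in reps:
            if tr.times.shape == grid.shape and np.allclose(tr.times, grid):
                mat.append(tr.fluorescence)
            elif strict:
                raise ValueError(f"condition {cond!r}: mismatched time grids")
            else:
                warnings.warn(
                    f"condition {cond!r}: resampling replicate "
                    f"{tr.replicate!r} onto the common grid"
                )
                mat.append(np.interp(grid, tr.times, tr.fluorescence))
        mat = np.asarray(mat)
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        for t, m, s in zip(grid, mean, sem):
            curve_rows.append(
                {"condition": cond, "time_s": t, "mean": m, "sem": s, "n": mat.shape[0]}
            )

        results = [
            analyze_trace(tr, pre_cccp_window=pre_cccp_window) for tr in reps
        ]
        qs = np.array([r.fractional_quench for r in results])
        ks = np.array([r.k_quench for r in results], dtype=float)
        n = len(results)
        table_rows.append(
            {
                "condition": cond,
                "n": n,
                "fractional_quench_mean": qs.mean(),
                "fractional_quench_sem": qs.std(ddof=1) / np.sqrt(n),
                "k_quench_mean": ks.mean(),
                "k_quench_sem": ks.std(ddof=1) / np.sqrt(n),
            }
        )
    return pd.DataFrame(curve_rows), pd.DataFrame(table_rows)


def read_traces_csv(path) -> list[FluxTrace]:
    """Read long-format traces: columns time_s, fluorescence, condition,
    replicate, t_valinomycin, t_cccp."""
    df = pd.read_csv(path, comment="#")
    required = {"time_s", "fluorescence", "condition", "replicate",
                "t_valinomycin", "t_cccp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(
            FluxTrace(
                times=grp["time_s"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                t_valinomycin=float(grp["t_valinomycin"].iloc[0]),
                t_cccp=float(grp["t_cccp"].iloc[0]),
                condition=str(cond),
                replicate=rep,
            )
        )
    return traces


def write_traces_csv(traces: list[FluxTrace], path, header_lines: list[str] | None = None) -> None:
    rows = []
    for tr in traces:
        for t, f in zip(tr.times, tr.fluorescence):
            rows.append(
                {
                    "time_s": t,
                    "fluorescence": f,
                    "condition": tr.condition,
                    "replicate": tr.replicate,
                    "t_valinomycin": tr.t_valinomycin,
                    "t_cccp": tr.t_cccp,
                }
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
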