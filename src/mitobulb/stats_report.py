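"""Shared statistics (Welch/Student t, weighted mean/SE) and run-report
assembly.

The t statistics are computed from the explicit textbook formulas; p-values
are two-sided throughout and no multiplicity correction is applied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "RunReport",
    "welch_t",
    "student_t",
    "weighted_mean_se",
    "assemble_report",
]


@dataclass
class StatResult:
    statistic: float
    df: float
    p_value: float
    test_name: str
    n_x: int
    n_y: int
    degenerate: bool = False  # zero-variance input


def _prep(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    return x, y


def welch_t(x, y) -> StatResult:
    """Two-sample unequal-variance t with Welch-Satterthwaite df."""
    x, y = _prep(x, y)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        d = x.mean() - y.mean()
        t = 0.0 if d == 0 else float(np.sign(d) * np.inf)
        return StatResult(t, float(nx + ny - 2), 1.0 if t == 0 else 0.0,
                          "welch", nx, ny, degenerate=True)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult(float(t), float(df), float(p), "welch", nx, ny)


def student_t(x, y) -> StatResult:
    """Two-sample pooled-variance (Student's) t."""
    x, y = _prep(x, y)
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    denom = np.sqrt(sp2 * (1 / nx + 1 / ny))
    if denom == 0:
        d = x.mean() - y.mean()
        t = 0.0 if d == 0 else float(np.sign(d) * np.inf)
        return StatResult(t, float(df), 1.0 if t == 0 else 0.0,
                          "student", nx, ny, degenerate=True)
    t = (x.mean() - y.mean()) / denom
    p = 2 * sps.t.sf(abs(t), df)
    return StatResult(float(t), float(df), float(p), "student", nx, ny)


def weighted_mean_se(fractions, weights) -> tuple[float, float | None]:
    """Weighted mean and weighted between-observation SE.

    mean = sum(w f) / sum(w); SE = sqrt( sum(w (f - mean)^2) /
    ((M - 1) sum(w)) ) with M observations.  With weights equal to per-image
    counts the mean is exactly the pooled fraction.  SE is None for M = 1.
    """
    f = np.asarray(fractions, dtype=float)
    w = np.asarray(weights, dtype=float)
    if f.shape != w.shape or f.ndim != 1 or len(f) == 0:
        raise ValueError("fractions and weights must be equal-length 1D arrays")
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    mean = float((w * f).sum() / w.sum())
    if len(f) == 1:
        return mean, None
    se = float(np.sqrt((w * (f - mean) ** 2).sum() / ((len(f) - 1) * w.sum())))
    return mean, se


@dataclass
class RunReport:
    config: dict
    version: str
    seeds: dict
    tables: dict  # name -> list-of-dict rows
    figures: list[str]
    schema_version: int = 1


def _rows(obj) -> list[dict]:
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return [_plain(dataclasses.asdict(obj))]
    if isinstance(obj, dict):
        return [_plain(obj)]
    if isinstance(obj, (list, tuple)):
        out = []
        for item in obj:
            out.extend(_rows(item))
        return out
    raise TypeError(f"cannot tabulate {type(obj)!r}")


def _plain(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            for kk, vv in _plain(v).items():
                out[f"{k}.{kk}"] = vv
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        elif isinstance(v, (list, tuple, np.ndarray)):
            out[k] = json.dumps(np.asarray(v).tolist())
        else:
            out[k] = v
    return out


def assemble_report(stage_outputs: dict, config: dict, out_dir,
                    seeds: dict | None = None,
                    version: str | None = None) -> RunReport:
    """Assemble stage outputs into CSV tables, figures and a JSON summary.

    ``stage_outputs`` maps a stage name to a DataFrame, dataclass, dict, or
    a list of those; a missing (None) stage is listed as absent rather than
    failing.  A bulbs-per-cell histogram (PNG + CSV) is rendered for any
    stage that looks like a threshold-sweep report.  Output is deterministic:
    sorted keys, no timestamps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if version is None:
        from . import __version__ as version

    tables: dict = {}
    figures: list[str] = []
    absent: list[str] = []
    for name in sorted(stage_outputs):
        obj = stage_outputs[name]
        if obj is None:
            absent.append(name)
            continue
        rows = _rows(obj)
        tables[name] = rows
        pd.DataFrame(rows).to_csv(out_dir / f"{name}.csv", index=False)
        if rows and "area_thresholds" in rows[0]:
            figures.append(_sweep_figure(rows[0], name, out_dir))

    report = RunReport(config=config, version=str(version),
                       seeds=seeds or {}, tables=tables, figures=figures)
    doc = dataclasses.asdict(report)
    doc["absent_stages"] = absent
    (out_dir / "report.json").write_text(
        json.dumps(doc, indent=1, sort_keys=True, default=_json_default))
    return report


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)!r}")


def _sweep_figure(row: dict, name: str, out_dir: Path) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thr = json.loads(row["area_thresholds"]) \
        if isinstance(row["area_thresholds"], str) else row["area_thresholds"]
    vals = row.get("mean") or row.get("bulbs_per_cell")
    if isinstance(vals, str):
        vals = json.loads(vals)
    sd = row.get("sd")
    if isinstance(sd, str):
        sd = json.loads(sd)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar([str(t) for t in thr], vals,
           yerr=sd if sd is not None else None, color="#4878a8")
    ax.set_xlabel("area threshold (um$^2$)")
    ax.set_ylabel("mito-bulbs per cell")
    ax.set_title(name)
    fig.tight_layout()
    path = out_dir / f"{name}_sweep.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path.name
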