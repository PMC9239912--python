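"""Threshold-based IDP pass/fail evaluation and a self-contained HTML QC
report (tables + connectivity/time-series panels, images embedded as
base64 PNG so the file opens with no network access).
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from jinja2 import Template

from .func import FCMatrix, ROITimeSeriesMatrix, framewise_displacement
from .sc import Connectome

__all__ = [
    "ThresholdSpec",
    "QCRecord",
    "evaluate_thresholds",
    "render_report",
    "STATUS_PASS",
    "STATUS_FAIL",
    "STATUS_MISSING",
    "STATUS_NO_THRESHOLD",
]

STATUS_PASS = "pass"
STATUS_FAIL = "fail"
STATUS_MISSING = "missing"
STATUS_NO_THRESHOLD = "no-threshold"


@dataclass
class ThresholdSpec:
    """Per-IDP inclusive pass range; absent bounds are unbounded."""

    bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"threshold for {name!r}: lower {lo} > upper {hi}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ThresholdSpec":
        df = pd.read_csv(path, sep="\t")
        required = {"idp", "lower", "upper"}
        if not required <= set(df.columns):
            raise ValueError(f"threshold file needs columns {sorted(required)}")
        bounds = {}
        for _, row in df.iterrows():
            lo = None if pd.isna(row["lower"]) else float(row["lower"])
            hi = None if pd.isna(row["upper"]) else float(row["upper"])
            bounds[str(row["idp"])] = (lo, hi)
        return cls(bounds)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"idp": k, "lower": lo, "upper": hi}
            for k, (lo, hi) in self.bounds.items()
        ]
        pd.DataFrame(rows, columns=["idp", "lower", "upper"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class QCRecord:
    subject: str
    values: dict[str, float | None]
    status: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "idp": list(self.values),
                "value": [self.values[k] for k in self.values],
                "status": [self.status[k] for k in self.values],
            }
        )

    @property
    def n_pass(self) -> int:
        return sum(1 for s in self.status.values() if s == STATUS_PASS)

    @property
    def n_fail(self) -> int:
        return sum(1 for s in self.status.values() if s == STATUS_FAIL)


def evaluate_thresholds(
    values: dict, spec: ThresholdSpec, subject: str = "subject"
) -> QCRecord:
    """Classify each IDP value against its inclusive pass range.

    ``pass`` iff lower <= value <= upper (absent bound = unbounded);
    missing values give ``missing``; IDPs without a spec entry give
    ``no-threshold``.
    """
    status: dict[str, str] = {}
    clean: dict[str, float | None] = {}
    for name, value in values.items():
        if name not in spec.bounds:
            if value is not None and not _is_number(value):
                raise ValueError(f"IDP {name!r} has non-numeric value {value!r}")
            clean[name] = None if _is_missing(value) else float(value)
            status[name] = STATUS_NO_THRESHOLD
            continue
        if _is_missing(value):
            clean[name] = None
            status[name] = STATUS_MISSING
            continue
        if not _is_number(value):
            raise ValueError(
                f"thresholded IDP {name!r} has non-numeric value {value!r}"
            )
        v = float(value)
        clean[name] = v
        lo, hi = spec.bounds[name]
        ok = (lo is None or v >= lo) and (hi is None or v <= hi)
        status[name] = STATUS_PASS if ok else STATUS_FAIL
    return QCRecord(subject, clean, status)


def _is_missing(value) -> bool:
    if value is None:
        return True
    try:
        return bool(np.isnan(float(value)))
    except (TypeError, ValueError):
        return False


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# HTML report


def _fig_to_b64(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight")
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode("ascii")


def _panel_fc_matrix(fc: FCMatrix) -> str:
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(fc.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_title("Functional connectivity")
    fig.colorbar(im, ax=ax, shrink=0.8)
    return _fig_to_b64(fig)


def _panel_fc_hist(fc: FCMatrix) -> str:
    n = fc.values.shape[0]
    vals = fc.values[np.triu_indices(n, k=1)]
    vals = vals[np.isfinite(vals)]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(vals, bins=40, color="steelblue")
    ax.set_title("FC value distribution")
    ax.set_xlabel("Pearson r")
    return _fig_to_b64(fig)


def _panel_sc_matrix(conn: Connectome) -> str | None:
    w = conn.weights
    nz = w[w > 0]
    if nz.size == 0:
        return None
    eps = nz.min() / 10.0
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(np.log10(w + eps), cmap="viridis")
    ax.set_title("SC weights (log10)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    return _fig_to_b64(fig)


def _panel_sc_hist(conn: Connectome) -> str | None:
    n = conn.weights.shape[0]
    vals = conn.weights[np.triu_indices(n, k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return None
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(np.log10(vals), bins=40, color="darkorange")
    ax.set_title("Nonzero SC weights (log10)")
    ax.set_xlabel("log10 weight")
    return _fig_to_b64(fig)


def _panel_carpet(ts: ROITimeSeriesMatrix) -> str:
    vals = ts.values[:, ts.valid]
    z = vals - vals.mean(axis=0, keepdims=True)
    sd = vals.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = z / sd
    fig, ax = plt.subplots(figsize=(6, 2.5))
    ax.imshow(z.T, aspect="auto", cmap="gray", vmin=-2, vmax=2)
    ax.set_title("ROI time-series carpet plot")
    ax.set_xlabel("frame")
    ax.set_ylabel("ROI")
    return _fig_to_b64(fig)


def _panel_fd(motion: np.ndarray) -> str:
    fd, summary = framewise_displacement(motion)
    fig, ax = plt.subplots(figsize=(6, 2))
    ax.plot(fd, lw=0.8, color="crimson")
    ax.set_title(
        f"Framewise displacement (mean {summary['fd_mean']:.3f} mm, "
        f"max {summary['fd_max']:.3f} mm)"
    )
    ax.set_xlabel("frame")
    ax.set_ylabel("FD (mm)")
    return _fig_to_b64(fig)


_TEMPLATE = Template(
    """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>QC report — {{ subject }}</title>
<style>
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 4px 10px; }
tr.pass { background: #c8e6c9; }
tr.fail { background: #ffcdd2; }
tr.missing { background: #eeeeee; }
tr.no-threshold { background: #ffffff; }
.panel { display: inline-block; margin: 8px; vertical-align: top; }
.placeholder { color: #777; border: 1px dashed #aaa; padding: 2em; }
</style>
</head>
<body>
<h1>QC report — {{ subject }}</h1>
<h2>Imaging-derived phenotypes</h2>
<p>{{ n_pass }} pass / {{ n_fail }} fail</p>
<table id="idp-table">
<tr><th>IDP</th><th>value</th><th>status</th></tr>
{% for row in idp_rows %}
<tr class="{{ row.status }}"><td>{{ row.name }}</td>
<td>{{ row.value }}</td><td>{{ row.status }}</td></tr>
{% endfor %}
</table>
{% for title, img, note in panels %}
<div class="panel">
<h2>{{ title }}</h2>
{% if img %}<img alt="{{ title }}" src="data:image/png;base64,{{ img }}">
{% else %}<div class="placeholder">{{ note }}</div>{% endif %}
</div>
{% endfor %}
</body>
</html>
"""
)


def render_report(
    record: QCRecord,
    out_path: str | Path,
    fc: FCMatrix | None = None,
    connectome: Connectome | None = None,
    timeseries: ROITimeSeriesMatrix | None = None,
    motion: np.ndarray | None = None,
) -> Path:
    """Write a standalone single-file HTML QC report.

    The IDP table is always present; connectivity and time-series panels are
    added when the corresponding inputs are given.  Degenerate inputs (e.g.
    an empty connectome) render an explicit placeholder instead of failing.
    """
    idp_rows = [
        {
            "name": name,
            "value": "—" if record.values[name] is None
            else f"{record.values[name]:.6g}",
            "status": record.status[name],
        }
        for name in record.values
    ]
    panels: list[tuple[str, str | None, str]] = []
    if fc is not None:
        panels.append(("FC matrix", _panel_fc_matrix(fc), ""))
        panels.append(("FC histogram", _panel_fc_hist(fc), ""))
    if connectome is not None:
        img = _panel_sc_matrix(connectome)
        panels.append(("SC weights", img, "no data: connectome is empty"))
        img = _panel_sc_hist(connectome)
        panels.append(("SC weight histogram", img, "no data: connectome is empty"))
    if timeseries is not None:
        panels.append(("ROI time series", _panel_carpet(timeseries), ""))
    if motion is not None:
        panels.append(("Head motion", _panel_fd(np.asarray(motion)), ""))
    html = _TEMPLATE.render(
        subject=record.subject,
        idp_rows=idp_rows,
        n_pass=record.n_pass,
        n_fail=record.n_fail,
        panels=panels,
    )
    out_path = Path(out_path)
    out_path.write_text(html)
    return out_path
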