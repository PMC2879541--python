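"""End-to-end sample analysis: read events, fit both scales, pick the best N_crit.

Workflow per sample: fit the skew-Laplace by maximum likelihood on the linear
scale and — when every event is strictly positive — on the natural-log scale
(the log-skew-Laplace fit), compute N_crit for each, and report the scale
achieving the larger N_crit.  Reports mark the winning scale with the
conventional ``*`` (linear) / ``**`` (log) flags used when tabulating maximal
N_crit per strain and channel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .fcs import read_fcs
from .fitting import FitResult, fit_skew_laplace
from .gof import (
    DEFAULT_BINS,
    DEFAULT_THRESHOLDS,
    BinnedSample,
    GofResult,
    bin_sample,
    classify_fit,
    logfreq_surface,
    n_crit,
    qq_surface,
)

__all__ = ["SampleReport", "read_events", "analyze_sample", "write_report", "plot_sample"]

logger = logging.getLogger("skewlap")

SCALE_MARKERS = {"linear": "*", "log": "**"}


@dataclass
class SampleReport:
    """Per-sample result: both per-scale fits plus the winning scale."""

    sample_id: str
    channel: str
    fits: dict[str, FitResult]
    gofs: dict[str, GofResult]
    best_scale: str
    log_scale_skipped: Optional[str] = None
    surfaces: dict[str, Any] = field(default_factory=dict)

    @property
    def best_fit(self) -> FitResult:
        return self.fits[self.best_scale]

    @property
    def best_gof(self) -> GofResult:
        return self.gofs[self.best_scale]

    @property
    def best_n_crit(self) -> float:
        return self.best_gof.n_crit

    @property
    def best_fit_class(self) -> str:
        return self.best_gof.fit_class

    @property
    def marker(self) -> str:
        return SCALE_MARKERS[self.best_scale]

    def to_dict(self) -> dict[str, Any]:
        return {
            "sample_id": self.sample_id,
            "channel": self.channel,
            "best_scale": self.best_scale,
            "marker": self.marker,
            "log_scale_skipped": self.log_scale_skipped,
            "scales": {
                s: {"fit": self.fits[s].to_dict(), "gof": self.gofs[s].to_dict()}
                for s in self.fits
            },
        }


def read_events(path: Union[str, Path], channel: Optional[str] = None
                ) -> tuple[NDArray[np.float64], dict[str, Any]]:
    """Read one channel of event values from an FCS 3.0/3.1 or CSV/TSV file.

    ``channel`` selects the FCS parameter or the CSV column; by default the
    first (first numeric, for delimited files) channel is used.  Unknown
    channels raise an error naming those available.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such file: {p}")
    meta: dict[str, Any] = {"source": str(p)}
    if p.suffix.lower() in (".fcs", ".lmd"):
        events, kw = read_fcs(p)
        meta["format"] = "fcs"
        meta["keywords"] = {k: v for k, v in kw.items() if k in ("$TOT", "$PAR", "$DATATYPE")}
        frame = events
    else:
        sep = "\t" if p.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        frame = pd.read_csv(p, sep=sep)
        frame = frame.select_dtypes(include=[np.number])
        meta["format"] = "delimited"
        if frame.shape[1] == 0:
            raise ValueError(f"{p}: no numeric columns found")
    if channel is None:
        channel = str(frame.columns[0])
    if channel not in frame.columns:
        raise KeyError(
            f"channel {channel!r} not in {p.name}; available: {', '.join(map(str, frame.columns))}"
        )
    meta["channel"] = channel
    meta["n"] = int(frame.shape[0])
    return frame[channel].to_numpy(dtype=float), meta


def analyze_sample(
    values: Sequence[float],
    sample_id: str = "sample",
    channel: str = "FS",
    *,
    scale: str = "both",
    k: int = DEFAULT_BINS,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    surfaces: bool = False,
) -> SampleReport:
    """Fit and score one event sample, returning the per-scale results.

    With ``scale="both"`` (default) the linear fit is always performed and the
    log fit whenever all values are positive; ``"linear"``/``"log"`` restrict
    to one scale.  The best scale is the one with the larger N_crit.
    """
    x = np.asarray(values, dtype=float).ravel()
    fits: dict[str, FitResult] = {}
    gofs: dict[str, GofResult] = {}
    surf: dict[str, Any] = {}
    skipped = None

    wanted = ("linear", "log") if scale == "both" else (scale,)
    for s in wanted:
        if s == "log" and np.any(x <= 0.0):
            if scale == "log":
                raise ValueError("log-scale analysis requires strictly positive values")
            skipped = "non-positive values present; log-scale fit skipped"
            logger.warning("%s/%s: %s", sample_id, channel, skipped)
            continue
        # fit_skew_laplace applies the log transform itself; surfaces and
        # binning work on the transformed values the fit parameters describe
        data_s = np.log(x) if s == "log" else x
        fit = fit_skew_laplace(x, scale=s)
        binned = bin_sample(data_s, k=k)
        if binned.merged:
            logger.warning("%s/%s [%s]: tied quantile edges merged to k=%d",
                           sample_id, channel, s, binned.k)
        gof = n_crit(binned, fit, thresholds=thresholds)
        fits[s] = fit
        gofs[s] = gof
        if surfaces:
            surf[s] = {
                "qq": qq_surface(data_s, fit),
                "logfreq": logfreq_surface(binned, fit),
                "binned": binned,
            }
        logger.info("%s/%s [%s]: n=%d n_crit=%.1f class=%s",
                    sample_id, channel, s, fit.n, gof.n_crit, gof.fit_class)

    if not fits:
        raise ValueError("no scale could be analyzed")
    best = max(fits, key=lambda s: gofs[s].n_crit)
    return SampleReport(
        sample_id=sample_id,
        channel=channel,
        fits=fits,
        gofs=gofs,
        best_scale=best,
        log_scale_skipped=skipped,
        surfaces=surf,
    )


def write_report(reports: Iterable[SampleReport], out_dir: Union[str, Path],
                 *, stem: str = "report") -> dict[str, Path]:
    """Write a tidy summary CSV plus a full-detail JSON for a batch of samples.

    The CSV has one row per sample x channel with the winning scale marked
    ``*`` (skew-Laplace) or ``**`` (log-skew-Laplace); the JSON carries both
    per-scale fits in full.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in reports:
        p = r.best_fit.params
        rows.append({
            "sample_id": r.sample_id,
            "channel": r.channel,
            "scale_marker": r.marker,
            "mu": p.mu,
            "alpha": p.alpha,
            "beta": p.beta,
            "n": r.best_fit.n,
            "n_crit": r.best_n_crit,
            "fit_class": r.best_fit_class,
        })
    csv_path = out / f"{stem}.csv"
    json_path = out / f"{stem}.json"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    payload = {"samples": [r.to_dict() for r in reports]}
    json_path.write_text(json.dumps(payload, indent=2, allow_nan=False,
                                    default=_json_safe) + "\n")
    return {"csv": csv_path, "json": json_path}


def _json_safe(obj: Any) -> Any:
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    raise TypeError(f"not JSON serializable: {obj!r}")


def plot_sample(report: SampleReport, out_dir: Union[str, Path],
                fmt: str = "png") -> list[Path]:
    """Render histogram+fit, q-q and log-frequency diagnostics for one sample.

    Requires the report to have been built with ``surfaces=True``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .distributions import sl_pdf

    if not report.surfaces:
        raise ValueError("report was built without surfaces=True")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for s, surf in report.surfaces.items():
        fit = report.fits[s]
        binned: BinnedSample = surf["binned"]
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
        # histogram with fitted density overlay
        e = binned.edges
        grid = np.linspace(e[0] - 0.1 * (e[-1] - e[0]), e[-1] + 0.1 * (e[-1] - e[0]), 400)
        widths = np.diff(e)
        axes[0].bar(0.5 * (e[:-1] + e[1:]), binned.proportions[1:-1] / widths,
                    width=widths, color="0.8", edgecolor="0.6")
        axes[0].plot(grid, sl_pdf(grid, fit.params), "k-")
        axes[0].set_title(f"{report.sample_id} {report.channel} [{s}]")
        # q-q
        qq = surf["qq"]
        axes[1].plot(qq[:, 0], qq[:, 1], ".", ms=2)
        lim = [qq[:, 0].min(), qq[:, 0].max()]
        axes[1].plot(lim, lim, "k--", lw=1)
        axes[1].set_title(f"q-q (N_crit={report.gofs[s].n_crit:.0f})")
        # log-frequency
        lf = surf["logfreq"]
        axes[2].plot(lf["midpoints"], lf["log_density"], "o", ms=3)
        for (b0, b1) in (lf["left_line"], lf["right_line"]):
            axes[2].plot(grid, b0 + b1 * grid, "-", lw=1)
        axes[2].set_ylim(bottom=min(lf["log_density"]) - 1)
        axes[2].set_title("ln frequency")
        fig.tight_layout()
        path = out / f"{report.sample_id}_{report.channel}_{s}.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
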