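"""Binned proportion-positive profiles along metatranscript and landmark axes.

A profile counts, per bin, how many annotated sites pass a significance
predicate (e.g. stoichiometry > 10) out of all sites tested in that bin,
mirroring how average modification rates are computed in metagene-style
analyses.  Profiles feed a tricube local-linear (LOESS) trend with a 95%
confidence band and the plotting routines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import ANNOTATION_COLUMNS, AnnotatedSite

__all__ = [
    "SignificancePredicate",
    "PredicateColumnError",
    "TooFewPointsError",
    "annotated_frame",
    "read_annotated",
    "bin_metatranscript",
    "junction_profile",
    "codon_profile",
    "loess_trend",
    "render_profile",
]

PROFILE_COLUMNS = ("axis_value", "n_positive", "n_total", "proportion")

_COMPARATORS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
    "==": np.equal,
}


class PredicateColumnError(KeyError):
    """The predicate names a column absent from the annotated table."""


class TooFewPointsError(ValueError):
    """Not enough non-missing profile rows to fit a trend."""


@dataclass(frozen=True)
class SignificancePredicate:
    """Threshold test defining which sites count as positive.

    ``column`` is a column name or 1-based index into the annotated
    table; records with non-numeric values in that column are excluded
    from both numerator and denominator (counted in the profile's
    ``attrs['non_numeric_filtered']``).
    """

    column: str | int
    comparator: str
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(
                f"comparator must be one of {sorted(_COMPARATORS)}, got {self.comparator!r}"
            )

    def resolve(self, frame: pd.DataFrame) -> pd.Series:
        if isinstance(self.column, int) or (
            isinstance(self.column, str) and self.column.isdigit()
        ):
            idx = int(self.column) - 1
            if not (0 <= idx < frame.shape[1]):
                raise PredicateColumnError(
                    f"column index {self.column} out of range; table has "
                    f"{frame.shape[1]} columns: {list(frame.columns)}"
                )
            return frame.iloc[:, idx]
        if self.column not in frame.columns:
            raise PredicateColumnError(
                f"column {self.column!r} not found; available: {list(frame.columns)}"
            )
        return frame[self.column]

    def evaluate(self, frame: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        """Return (positive, tested) boolean masks over ``frame``."""
        values = pd.to_numeric(self.resolve(frame), errors="coerce")
        tested = values.notna()
        with np.errstate(invalid="ignore"):
            positive = _COMPARATORS[self.comparator](values, self.threshold) & tested
        return positive, tested


def _default_input_names(n: int) -> list[str]:
    names = ["transcript", "start", "end"]
    names += [f"field_{i}" for i in range(4, n + 1)]
    return names


def annotated_frame(sites: Iterable[AnnotatedSite]) -> pd.DataFrame:
    """Tabulate annotated sites: original columns first, then the 12
    annotation columns, matching the on-disk BEDn+12 layout."""
    sites = list(sites)
    if not sites:
        return pd.DataFrame(columns=_default_input_names(3) + list(ANNOTATION_COLUMNS))
    n_in = len(sites[0].fields()) - len(ANNOTATION_COLUMNS)
    names = _default_input_names(n_in) + list(ANNOTATION_COLUMNS)
    return pd.DataFrame([s.fields() for s in sites], columns=names)


def read_annotated(source) -> pd.DataFrame:
    """Read an annotated BEDn+12 table written by the annotate step.

    A leading '#'-prefixed line provides column names; without one, the
    last 12 columns are assumed to be the annotation columns and input
    columns receive positional names.
    """
    from .model import _open_text

    handle = _open_text(source)
    names: list[str] | None = None
    data_lines: list[str] = []
    for raw in handle:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            # the column-name header is the '#' line that is itself tabular
            if "\t" in line:
                names = line.lstrip("#").split("\t")
            continue
        if line.startswith(("track", "browser")):
            continue
        data_lines.append(line)
    if not data_lines:
        raise ValueError("annotated table contains no data rows")
    rows = [line.split("\t") for line in data_lines]
    n = len(rows[0])
    if n < len(ANNOTATION_COLUMNS) + 3:
        raise ValueError(
            f"annotated table needs >= {len(ANNOTATION_COLUMNS) + 3} columns, got {n}"
        )
    if names is None or len(names) != n:
        names = _default_input_names(n - len(ANNOTATION_COLUMNS)) + list(ANNOTATION_COLUMNS)
    return pd.DataFrame(rows, columns=names, dtype=str)


def _as_frame(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        return sites
    return annotated_frame(sites)


def _assemble(axis: np.ndarray, keys: np.ndarray, positive: np.ndarray) -> pd.DataFrame:
    """Aggregate per-key counts onto a fixed, strictly increasing axis."""
    n_total = np.zeros(len(axis), dtype=int)
    n_positive = np.zeros(len(axis), dtype=int)
    np.add.at(n_total, keys, 1)
    np.add.at(n_positive, keys, positive.astype(int))
    with np.errstate(invalid="ignore", divide="ignore"):
        proportion = np.where(n_total > 0, n_positive / np.maximum(n_total, 1), np.nan)
    return pd.DataFrame(
        {
            "axis_value": axis,
            "n_positive": n_positive,
            "n_total": n_total,
            "proportion": proportion,
        }
    )


def bin_metatranscript(
    sites, pred: SignificancePredicate, n_bins: int = 120
) -> pd.DataFrame:
    """Bin sites along the 0-3 metatranscript axis (default 120 bins of
    width 0.025) and compute the proportion positive per bin.

    Sites without a metacoordinate (noncoding isoforms) are excluded;
    the plotted axis value is the bin midpoint.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    frame = _as_frame(sites)
    positive, tested = pred.evaluate(frame)
    meta = pd.to_numeric(frame["transcript_metacoordinate"], errors="coerce")
    keep = meta.notna() & tested
    width = 3.0 / n_bins
    midpoints = (np.arange(n_bins) + 0.5) * width
    bins = np.minimum(np.floor(meta[keep].to_numpy() / width).astype(int), n_bins - 1)
    table = _assemble(midpoints, bins, positive[keep].to_numpy())
    table.attrs["non_numeric_filtered"] = int((meta.notna() & ~tested).sum())
    return table


def junction_profile(
    sites, pred: SignificancePredicate, window: int = 300
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-nucleotide proportion positive around the nearest splice
    junction on each side.

    The upstream table covers offsets [-window, -1] (feature 5' of its
    nearest downstream junction at distance d plots at -d), the
    downstream table [1, window].  Sites with no junction on a side, or
    beyond the window, are excluded from that side.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    frame = _as_frame(sites)
    positive, tested = pred.evaluate(frame)
    out = []
    for column, axis in (
        ("up_junc_dist", np.arange(-window, 0)),
        ("down_junc_dist", np.arange(1, window + 1)),
    ):
        dist = pd.to_numeric(frame[column], errors="coerce")
        keep = dist.notna() & tested & (dist <= window) & (dist >= 1)
        d = dist[keep].to_numpy().astype(int)
        keys = window - d if column == "up_junc_dist" else d - 1
        table = _assemble(axis, keys, positive[keep].to_numpy())
        table.attrs["non_numeric_filtered"] = int((dist.notna() & ~tested).sum())
        out.append(table)
    return out[0], out[1]


def codon_profile(
    sites, pred: SignificancePredicate, window: int = 100, anchor: str = "stop"
) -> pd.DataFrame:
    """Per-nucleotide proportion positive around the start or stop codon,
    keyed by the signed distance to the first (anchor='start') or last
    (anchor='stop') ORF base, restricted to [-window, window]."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if anchor not in ("start", "stop"):
        raise ValueError(f"anchor must be 'start' or 'stop', got {anchor!r}")
    frame = _as_frame(sites)
    positive, tested = pred.evaluate(frame)
    column = "abs_cds_start" if anchor == "start" else "abs_cds_end"
    dist = pd.to_numeric(frame[column], errors="coerce")
    keep = dist.notna() & tested & (dist >= -window) & (dist <= window)
    d = dist[keep].to_numpy().astype(int)
    axis = np.arange(-window, window + 1)
    table = _assemble(axis, d + window, positive[keep].to_numpy())
    table.attrs["non_numeric_filtered"] = int((dist.notna() & ~tested).sum())
    return table


def _loess_matrix(x: np.ndarray, span: float) -> np.ndarray:
    """Equivalent-kernel matrix L of a tricube-weighted degree-1 local
    regression evaluated at the data points: fit = L @ y."""
    n = len(x)
    k = max(2, int(math.ceil(span * n)))
    k = min(k, n)
    L = np.zeros((n, n))
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:k]
        dk = d[idx]
        dmax = dk[-1]
        if dmax == 0:
            w = np.ones(k)
        else:
            w = np.clip(1 - (dk / dmax) ** 3, 0, None) ** 3
            if w.sum() == 0:
                w = np.ones(k)
        dx = x[idx] - x[i]
        sw = w.sum()
        swx = (w * dx).sum()
        swx2 = (w * dx * dx).sum()
        denom = sw * swx2 - swx * swx
        if denom <= 1e-12 * max(sw * swx2, 1e-300):
            li = w / sw  # collinear neighborhood: weighted mean
        else:
            li = w * (swx2 - swx * dx) / denom
        L[i, idx] = li
    return L


def loess_trend(
    table: pd.DataFrame,
    span: float = 0.3,
    bootstrap: bool = False,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit a LOESS trend with a 95% confidence band to a profile table.

    The fit is a tricube-weighted local linear regression of proportion
    on axis_value over a ``span`` fraction of the data.  By default the
    band is the normal approximation fit +/- 1.96 se with pointwise
    standard errors from the equivalent kernel; with ``bootstrap`` the
    band comes from ``n_boot`` seeded case resamples instead (useful for
    small tables).  Rows with missing proportion (empty bins) are
    excluded.  ``fit_clipped`` restricts the fit to [0, 1] for display;
    the raw fit is retained.
    """
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    ok = table["proportion"].notna()
    x = table.loc[ok, "axis_value"].to_numpy(dtype=float)
    y = table.loc[ok, "proportion"].to_numpy(dtype=float)
    n = len(x)
    if n < 10:
        raise TooFewPointsError(f"need >= 10 non-missing rows for a trend, got {n}")
    L = _loess_matrix(x, span)
    fit = L @ y
    residual = y - fit
    # approximate df correction for the smoother (delta1 of local regression)
    delta1 = n - 2 * np.trace(L) + float((L * L).sum())
    sigma2 = float(residual @ residual) / max(delta1, 1e-8)
    if bootstrap:
        rng = np.random.default_rng(seed)
        fits = np.empty((n_boot, n))
        for b in range(n_boot):
            idx = np.sort(rng.integers(0, n, size=n))
            xb, yb = x[idx], y[idx]
            Lb = _loess_matrix(xb, span)
            fb = Lb @ yb
            fits[b] = np.interp(x, xb, fb)
        ci_low = np.percentile(fits, 2.5, axis=0)
        ci_high = np.percentile(fits, 97.5, axis=0)
        se = fits.std(axis=0, ddof=1)
    else:
        se = np.sqrt(sigma2 * (L * L).sum(axis=1))
        ci_low = fit - 1.96 * se
        ci_high = fit + 1.96 * se
    return pd.DataFrame(
        {
            "axis_value": x,
            "fit": fit,
            "se": se,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "fit_clipped": np.clip(fit, 0.0, 1.0),
        }
    )


def _write_profile_tsv(path: Path, tables: Sequence[tuple[str, pd.DataFrame]]) -> None:
    parts = []
    for label, table in tables:
        part = table.copy()
        if label:
            part.insert(0, "panel", label)
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )


def render_profile(
    table,
    trend,
    output_path,
    kind: str = "metatranscript",
    labels: dict | None = None,
    table_path=None,
) -> Path:
    """Render a profile plot (points + LOESS trend + 95% CI ribbon) and
    write the underlying table as TSV alongside the image.

    ``kind`` selects the layout: ``metatranscript`` draws region
    separators at meta = 1 and 2 labelled 5'UTR/ORF/3'UTR;
    ``metajunction`` expects ``table``/``trend`` to be (upstream,
    downstream) pairs rendered as two panels; ``metacodon`` marks the
    codon at offset 0.  Returns the image path.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if kind not in ("metatranscript", "metajunction", "metacodon"):
        raise ValueError(f"unknown plot kind {kind!r}")
    labels = labels or {}
    output_path = Path(output_path)

    if kind == "metajunction":
        tables = list(table)
        trends = list(trend) if trend is not None else [None, None]
    else:
        tables = [table]
        trends = [trend]
    if any(t is None or len(t) == 0 or int(t["n_total"].sum()) == 0 for t in tables):
        raise ValueError("profile table is empty; nothing to plot")

    ylab = labels.get("ylabel", "Proportion of positive sites")
    if kind == "metajunction":
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        panel_names = ("upstream", "downstream")
        xlabs = ("nt from nearest upstream junction", "nt to nearest downstream junction")
    else:
        fig, ax = plt.subplots(figsize=(7, 4.2))
        axes = [ax]
        panel_names = ("",)
        default_x = "Metatranscript coordinate" if kind == "metatranscript" else (
            f"nt from {labels.get('anchor', 'stop')} codon"
        )
        xlabs = (labels.get("xlabel", default_x),)

    for ax, tab, tr, xlab in zip(np.atleast_1d(axes).ravel(), tables, trends, xlabs):
        shown = tab[tab["proportion"].notna()]
        ax.scatter(shown["axis_value"], shown["proportion"], s=8, alpha=0.5, color="#35618f")
        if tr is not None and len(tr):
            ax.plot(tr["axis_value"], tr["fit_clipped"], color="#c23b22", lw=1.6)
            ax.fill_between(
                tr["axis_value"],
                np.clip(tr["ci_low"], 0, 1),
                np.clip(tr["ci_high"], 0, 1),
                color="#c23b22",
                alpha=0.2,
                lw=0,
            )
        ax.set_xlabel(xlab)
        ax.set_ylim(-0.02, min(1.02, max(0.1, float(np.nanmax(shown["proportion"])) * 1.25)))
    axes_flat = np.atleast_1d(axes).ravel()
    axes_flat[0].set_ylabel(ylab)
    if kind == "metatranscript":
        ax = axes_flat[0]
        for x0 in (1.0, 2.0):
            ax.axvline(x0, color="grey", lw=0.8, ls="--")
        ymax = ax.get_ylim()[1]
        for x0, name in ((0.5, "5'UTR"), (1.5, "ORF"), (2.5, "3'UTR")):
            ax.text(x0, ymax * 0.97, name, ha="center", va="top", fontsize=9, color="dimgrey")
    elif kind == "metacodon":
        axes_flat[0].axvline(0, color="grey", lw=0.8, ls="--")
    if "title" in labels:
        fig.suptitle(labels["title"])
    fig.tight_layout()

    if table_path is None:
        table_path = output_path.with_suffix(output_path.suffix + ".tsv")
    _write_profile_tsv(Path(table_path), list(zip(panel_names, tables)))
    fig.savefig(output_path, dpi=150)
    plt.close(fig)
    return output_path
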