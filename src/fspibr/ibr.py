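"""Integrated Biological Response index, version 2 (IBR_v2).

The index integrates a battery of biomarkers into a single per-individual
stress score against a reference (pre-exposure, day-6) condition, via the
reference-deviation scheme:

1. ``Y = log(B_D12 / mean(B_D6))`` per individual x biomarker — the log
   ratio of the exposed value to the species' reference mean;
2. ``Z = (Y - mu) / s`` — standardization of Y against its mean ``mu`` and
   sample standard deviation ``s``, computed per biomarker within a
   grouping (default: species x treatment);
3. ``Z_D6 = mean(log(B_D6 / mean(B_D6)))`` — the reference term, the mean
   log ratio of the day-6 individuals themselves (taken literally: it is
   not re-standardized);
4. ``A = Z - Z_D6`` — the deviation index per biomarker (positive = induced
   relative to reference, negative = inhibited);
5. ``IBR_v2 = sum_b |A_b|`` over the integrated biomarker set, per
   individual, summarized per condition as mean +/- SE.

Step 2 is invariant to the logarithm base (the base rescales Y, mu and s
together); step 3 is not, so the base (default 10) is explicit and
configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomarkers import INTEGRATED_BIOMARKERS, baseline_means, _check_panel

logger = logging.getLogger(__name__)

#: Fixed star-plot axis order (the integrated biomarker set).
STAR_AXIS_ORDER = INTEGRATED_BIOMARKERS


@dataclass(frozen=True)
class IbrResult:
    """Per-individual components and the aggregated index.

    ``components`` holds one row per individual x biomarker with Y, mu, s,
    Z, Z_D6 and A; ``individual`` one row per individual with its IBR_v2;
    ``summary`` the per-condition mean, SE and n.
    """

    components: pd.DataFrame
    individual: pd.DataFrame
    summary: pd.DataFrame
    biomarkers: tuple[str, ...]
    log_base: float


@dataclass(frozen=True)
class StarPlotData:
    """Mean deviation index A per biomarker per condition, fixed axis order."""

    table: pd.DataFrame  # index (species, treatment), columns = axes
    axes: tuple[str, ...]


def _log(x: np.ndarray, base: float) -> np.ndarray:
    return np.log(x) / math.log(base)


def log_ratio(panel: pd.DataFrame, d6: int | None = None,
              d12: int | None = None, log_base: float = 10.0) -> pd.DataFrame:
    """Per-individual log ratio Y of day-12 values to the day-6 mean.

    Returns the day-12 rows with a ``Y`` column.  Raises on non-positive
    values, naming the offending record, since the log is undefined there.
    """
    _check_panel(panel)
    days = sorted(panel["day"].unique())
    d6 = days[0] if d6 is None else d6
    d12 = days[-1] if d12 is None else d12

    _reject_nonpositive(panel)
    base = baseline_means(panel, d6=d6)
    out = panel[panel["day"] == d12].copy()
    ref = base.reindex(
        pd.MultiIndex.from_frame(out[["species", "biomarker"]])).to_numpy()
    if np.isnan(ref).any():
        bad = out.loc[np.isnan(ref), ["species", "biomarker"]]
        raise ValueError("missing day-6 baseline for "
                         f"{sorted(set(map(tuple, bad.to_numpy())))}")
    out["Y"] = _log(out["value"].to_numpy() / ref, log_base)
    return out


def standardize(y: pd.DataFrame,
                grouping: tuple[str, ...] = ("species", "treatment"),
                ddof: int = 1,
                zero_variance_guard: bool = True) -> pd.DataFrame:
    """Standardize Y to Z = (Y - mu) / s within biomarker x grouping cells.

    ``mu`` and ``s`` are the mean and sample SD (``ddof=1``) of Y per
    biomarker within each grouping cell (default species x treatment; the
    alternative per-species reading pools treatments).  Cells with zero
    variance set Z to NaN with a warning when the guard is enabled — their
    deviation contribution becomes zero downstream — and raise otherwise.
    """
    keys = list(grouping) + ["biomarker"]
    out = y.copy()
    grp = out.groupby(keys)["Y"]
    out["mu"] = grp.transform("mean")
    out["s"] = grp.transform(lambda v: v.std(ddof=ddof))
    zero = (out["s"] == 0) | out["s"].isna()
    if zero.any():
        if not zero_variance_guard:
            cells = sorted(set(map(tuple, out.loc[zero, keys].to_numpy())))
            raise ValueError(f"zero variance in cells {cells}")
        logger.warning(
            "zero variance in %d cell row(s); their deviation contribution "
            "is set to 0", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out["Z"] = np.where(zero, np.nan,
                            (out["Y"] - out["mu"]) / out["s"])
    return out


def baseline_term(panel: pd.DataFrame, d6: int | None = None,
                  log_base: float = 10.0) -> pd.Series:
    """Reference term Z_D6 per (species, biomarker).

    Z_D6 is the mean of the day-6 individuals' own log ratios
    log(B_D6 / mean(B_D6)); it is deliberately left unstandardized, so it
    is zero when all day-6 values are equal and depends on the log base.
    """
    _check_panel(panel)
    days = sorted(panel["day"].unique())
    d6 = days[0] if d6 is None else d6
    base = panel[panel["day"] == d6]
    if base.empty:
        raise ValueError(f"panel has no day-{d6} records")
    _reject_nonpositive(base)
    ref = base.groupby(["species", "biomarker"])["value"].transform("mean")
    y_d6 = _log(base["value"].to_numpy() / ref.to_numpy(), log_base)
    return (base.assign(Y_D6=y_d6)
            .groupby(["species", "biomarker"])["Y_D6"].mean()
            .rename("Z_D6"))


def deviation_index(z: pd.DataFrame, z_d6: pd.Series) -> pd.DataFrame:
    """Deviation index A = Z - Z_D6 per individual x biomarker.

    Rows whose Z was guarded to NaN (zero-variance cells) contribute A = 0.
    Raises if any (species, biomarker) lacks a reference term.
    """
    out = z.copy()
    ref = z_d6.reindex(
        pd.MultiIndex.from_frame(out[["species", "biomarker"]])).to_numpy()
    if np.isnan(ref).any():
        bad = out.loc[np.isnan(ref), ["species", "biomarker"]]
        raise ValueError("missing reference term for "
                         f"{sorted(set(map(tuple, bad.to_numpy())))}")
    out["Z_D6"] = ref
    out["A"] = np.where(out["Z"].isna(), 0.0, out["Z"] - ref)
    return out


def ibr_v2(a: pd.DataFrame,
           biomarkers: tuple[str, ...] = INTEGRATED_BIOMARKERS
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum |A| over the integrated biomarkers, per individual.

    Returns ``(individual, summary)``: the per-individual index and the
    per-condition mean +/- SE over individuals.
    """
    if len(biomarkers) == 0:
        raise ValueError("at least one biomarker is required")
    sub = a[a["biomarker"].isin(biomarkers)]
    missing = set(biomarkers) - set(sub["biomarker"].unique())
    if missing:
        raise ValueError(f"deviation table lacks biomarkers "
                         f"{sorted(missing)}")
    individual = (sub.assign(absA=sub["A"].abs())
                  .groupby(["species", "treatment", "aquarium_id",
                            "individual_id"], as_index=False)["absA"].sum()
                  .rename(columns={"absA": "IBRv2"}))
    g = individual.groupby(["species", "treatment"])["IBRv2"]
    summary = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    summary["se"] = summary["sd"] / np.sqrt(summary["n"])
    return individual, summary.reset_index()


def compute_ibr(panel: pd.DataFrame,
                biomarkers: tuple[str, ...] = INTEGRATED_BIOMARKERS,
                grouping: tuple[str, ...] = ("species", "treatment"),
                log_base: float = 10.0,
                ddof: int = 1,
                zero_variance_guard: bool = True) -> IbrResult:
    """Full IBR_v2 computation on a raw panel (with CEA already appended)."""
    y = log_ratio(panel, log_base=log_base)
    y = y[y["biomarker"].isin(biomarkers)]
    if y.empty:
        raise ValueError("panel contains none of the requested biomarkers")
    z = standardize(y, grouping=grouping, ddof=ddof,
                    zero_variance_guard=zero_variance_guard)
    z_d6 = baseline_term(panel, log_base=log_base)
    comp = deviation_index(z, z_d6)
    individual, summary = ibr_v2(comp, biomarkers=tuple(
        b for b in biomarkers if b in set(comp["biomarker"])))
    return IbrResult(components=comp, individual=individual, summary=summary,
                     biomarkers=tuple(biomarkers), log_base=log_base)


def star_plot_data(components: pd.DataFrame,
                   axes: tuple[str, ...] = STAR_AXIS_ORDER) -> StarPlotData:
    """Mean deviation index per biomarker per condition, fixed axis order."""
    sub = components[components["biomarker"].isin(axes)]
    table = (sub.pivot_table(index=["species", "treatment"],
                             columns="biomarker", values="A",
                             aggfunc="mean")
             .reindex(columns=list(axes)))
    return StarPlotData(table=table, axes=tuple(axes))


def plot_stars(data: StarPlotData, path: str | None = None):
    """Radar (star) plot of mean deviation indices, one panel per species."""
    import matplotlib
    matplotlib.use("Agg")
    matplotlib.rcParams["svg.hashsalt"] = "fspibr"  # reproducible SVG ids
    import matplotlib.pyplot as plt

    species = data.table.index.get_level_values("species").unique()
    n_ax = len(data.axes)
    angles = np.linspace(0, 2 * np.pi, n_ax, endpoint=False)
    fig, axs = plt.subplots(1, len(species), figsize=(5 * len(species), 5),
                            subplot_kw={"projection": "polar"}, squeeze=False)
    for ax, sp in zip(axs[0], species):
        for treatment, row in data.table.loc[sp].iterrows():
            vals = row.to_numpy(dtype=float)
            ang = np.concatenate([angles, angles[:1]])
            v = np.concatenate([vals, vals[:1]])
            ax.plot(ang, v, label=str(treatment))
            ax.fill(ang, v, alpha=0.15)
        ax.set_xticks(angles)
        ax.set_xticklabels(data.axes)
        ax.set_title(str(sp))
        ax.legend(loc="upper right", bbox_to_anchor=(1.2, 1.1))
    fig.tight_layout()
    if path is not None:
        kwargs = ({"metadata": {"Date": None}}
                  if str(path).endswith(".svg") else {})
        fig.savefig(path, **kwargs)
        plt.close(fig)
        return None
    return fig


def _reject_nonpositive(panel: pd.DataFrame) -> None:
    bad = panel[panel["value"] <= 0]
    if not bad.empty:
        r = bad.iloc[0]
        raise ValueError(
            f"non-positive biomarker value ({r['value']}) for "
            f"{r['species']}/{r['biomarker']} individual "
            f"{r['individual_id']} (day {r['day']}); log ratios are "
            "undefined")
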