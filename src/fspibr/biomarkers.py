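"""Per-individual biomarker post-processing.

Three steps sit between the raw assay panel and the integrated stress index:

* the energy budget — available energy Ea = protein + carbohydrate + lipid,
  consumed energy Ec = electron-transport-system (ETS) activity, and the
  cellular energy allocation CEA = Ea / Ec, computed per individual and
  appended to the panel as derived biomarkers so they flow through
  normalization and integration exactly like assayed ones;
* baseline normalization — every day-12 value is expressed as % change
  relative to the species' mean day-6 (pre-heat-wave) value,
  Bn = (B_D12 - mean(B_D6)) / mean(B_D6) * 100, making responses
  comparable between species regardless of assay units;
* the species x biomarker day-6 baseline means themselves.

Panels are long-format DataFrames with columns (aquarium_id, species,
treatment, day, individual_id, biomarker, value, unit).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import ENERGY_RESERVES, UNITS

PANEL_COLUMNS = ["aquarium_id", "species", "treatment", "day",
                 "individual_id", "biomarker", "value", "unit"]

#: The seven biomarkers integrated into the stress index (star-plot axes).
INTEGRATED_BIOMARKERS = ("SOD", "CAT", "DNAd", "LPO", "IDH", "LDH", "CEA")


def energy_available(protein: float, carbohydrate: float,
                     lipid: float) -> float:
    """Available energy Ea: sum of the three reserve fractions.

    All inputs must be non-negative and expressed in a common energy unit.
    """
    parts = np.asarray([protein, carbohydrate, lipid], dtype=float)
    if (parts < 0).any():
        raise ValueError("energy reserves must be non-negative")
    return float(parts.sum())


def cea(ea: float, ec: float) -> float:
    """Cellular energy allocation, CEA = Ea / Ec (Ec = ETS activity > 0)."""
    if ec <= 0:
        raise ValueError("energy consumption Ec must be positive")
    if ea < 0:
        raise ValueError("available energy Ea must be non-negative")
    return float(ea) / float(ec)


def add_energy_budget(panel: pd.DataFrame) -> pd.DataFrame:
    """Append per-individual Ea and CEA rows to a raw biomarker panel.

    Requires every individual to carry the three reserve fractions and ETS;
    the derived rows inherit the individual's grouping columns.
    """
    _check_panel(panel)
    wide = panel.pivot_table(
        index=["aquarium_id", "species", "treatment", "day", "individual_id"],
        columns="biomarker", values="value", aggfunc="first")
    needed = set(ENERGY_RESERVES) | {"ETS"}
    missing = needed - set(wide.columns)
    if missing:
        raise ValueError(f"panel lacks biomarkers needed for CEA: "
                         f"{sorted(missing)}")
    if wide[list(needed)].isna().any().any():
        raise ValueError("some individuals lack reserve or ETS measurements")

    ea = wide[list(ENERGY_RESERVES)].sum(axis=1)
    if (wide["ETS"] <= 0).any():
        raise ValueError("ETS (Ec) must be positive for every individual")
    derived = pd.DataFrame({"Ea": ea, "CEA": ea / wide["ETS"]})
    long = (derived.reset_index()
            .melt(id_vars=["aquarium_id", "species", "treatment", "day",
                           "individual_id"],
                  var_name="biomarker", value_name="value"))
    long["unit"] = long["biomarker"].map(UNITS)
    return pd.concat([panel, long[PANEL_COLUMNS]], ignore_index=True)


def baseline_mean(panel: pd.DataFrame, species: str,
                  biomarker: str, d6: int | None = None) -> float:
    """Mean day-6 (pre-heat-wave) raw value for one species x biomarker."""
    _check_panel(panel)
    if d6 is None:
        d6 = int(panel["day"].min())
    sel = panel[(panel["species"] == species)
                & (panel["biomarker"] == biomarker) & (panel["day"] == d6)]
    if sel.empty:
        raise ValueError(
            f"no day-{d6} records for species {species!r}, "
            f"biomarker {biomarker!r}")
    return float(sel["value"].mean())


def baseline_means(panel: pd.DataFrame, d6: int | None = None) -> pd.Series:
    """Day-6 mean raw value per (species, biomarker), as a Series."""
    _check_panel(panel)
    if d6 is None:
        d6 = int(panel["day"].min())
    base = panel[panel["day"] == d6]
    if base.empty:
        raise ValueError(f"panel has no day-{d6} baseline records")
    return base.groupby(["species", "biomarker"])["value"].mean()


def normalize(panel: pd.DataFrame, d6: int | None = None,
              d12: int | None = None) -> pd.DataFrame:
    """Express day-12 biomarker values as % change from the day-6 baseline.

    Bn(i, j) = (B_D12(i, j) - mean B_D6(i)) / mean B_D6(i) * 100 per
    individual, biomarker and species; the baseline mean is taken within
    species so the % change is unit-free and species-comparable.  Raises if
    any required baseline mean is zero.
    """
    _check_panel(panel)
    days = sorted(panel["day"].unique())
    if len(days) < 2:
        raise ValueError("panel must contain both sampling days")
    d6 = days[0] if d6 is None else d6
    d12 = days[-1] if d12 is None else d12

    base = baseline_means(panel, d6=d6)
    zero = base[base == 0]
    if not zero.empty:
        raise ValueError(
            "zero day-6 baseline mean for "
            + ", ".join(f"{sp}/{b}" for sp, b in zero.index))

    out = panel[panel["day"] == d12].copy()
    ref = base.reindex(
        pd.MultiIndex.from_frame(out[["species", "biomarker"]])).to_numpy()
    if np.isnan(ref).any():
        bad = out.loc[np.isnan(ref), ["species", "biomarker"]]
        pairs = sorted(set(map(tuple, bad.to_numpy())))
        raise ValueError(f"no day-{d6} baseline for {pairs}")
    out["percent_change"] = (out["value"].to_numpy() - ref) / ref * 100.0
    return out.drop(columns=["value", "unit"], errors="ignore")


def mean_change_ci(panel: pd.DataFrame, species: str, biomarker: str,
                   treatment: str | None = None,
                   level: float = 0.95) -> tuple[float, float, float]:
    """Estimated mean % change from day 6 with a delta-method CI.

    The estimator is the % change of the day-12 mean relative to the day-6
    mean; because the day-6 baseline is itself estimated, the CI propagates
    both means' sampling variances through the ratio (first-order delta
    method).  Returns ``(estimate, lower, upper)`` in percent.
    """
    from scipy import stats

    _check_panel(panel)
    days = sorted(panel["day"].unique())
    d6, d12 = days[0], days[-1]
    sel = (panel["species"] == species) & (panel["biomarker"] == biomarker)
    b = panel.loc[sel & (panel["day"] == d6), "value"].to_numpy()
    x12 = sel & (panel["day"] == d12)
    if treatment is not None:
        x12 &= panel["treatment"] == treatment
    x = panel.loc[x12, "value"].to_numpy()
    if len(b) < 2 or len(x) < 2:
        raise ValueError("need >= 2 observations on each day")
    mb, mx = b.mean(), x.mean()
    if mb == 0:
        raise ValueError(f"zero baseline mean for {species}/{biomarker}")
    ratio = mx / mb
    var_r = (x.var(ddof=1) / len(x) / mb**2
             + mx**2 * b.var(ddof=1) / len(b) / mb**4)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var_r)
    return ((ratio - 1) * 100.0, (ratio - 1 - half) * 100.0,
            (ratio - 1 + half) * 100.0)


def _check_panel(panel: pd.DataFrame) -> None:
    missing = set(PANEL_COLUMNS[:7]) - set(panel.columns)
    if missing:
        raise ValueError(f"panel is missing columns {sorted(missing)}")
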