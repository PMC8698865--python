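"""Independent brute-force oracles used to validate the pipeline.

Everything here is written as straight-line loops over plain records, with
no shared code or grouping machinery from the package, so agreement with
the pipeline is a genuine two-route check.
"""

from __future__ import annotations

import math
from collections import defaultdict


def ibr_v2_bruteforce(records, biomarkers, log_base=10.0):
    """Reference-deviation index computed the pedestrian way.

    ``records``: iterables of dicts with keys species, treatment, day,
    individual_id, biomarker, value.  Returns (per_individual, components)
    where per_individual maps individual_id -> index value and components
    maps (individual_id, biomarker) -> dict(Y, Z, Z_D6, A).
    """
    records = list(records)
    days = sorted({r["day"] for r in records})
    d6, d12 = days[0], days[-1]

    def log(x):
        return math.log(x) / math.log(log_base)

    # day-6 baseline mean per species x biomarker
    base_vals = defaultdict(list)
    for r in records:
        if r["day"] == d6:
            base_vals[(r["species"], r["biomarker"])].append(r["value"])
    base = {k: sum(v) / len(v) for k, v in base_vals.items()}

    # Y per day-12 record
    y = {}
    meta = {}
    for r in records:
        if r["day"] == d12 and r["biomarker"] in biomarkers:
            key = (r["individual_id"], r["biomarker"])
            y[key] = log(r["value"] / base[(r["species"], r["biomarker"])])
            meta[key] = (r["species"], r["treatment"])

    # mu and sample SD per biomarker within species x treatment
    cells = defaultdict(list)
    for key, val in y.items():
        sp, tr = meta[key]
        cells[(sp, tr, key[1])].append(val)
    mu, sd = {}, {}
    for cell, vals in cells.items():
        m = sum(vals) / len(vals)
        mu[cell] = m
        if len(vals) > 1:
            sd[cell] = math.sqrt(sum((v - m) ** 2 for v in vals)
                                 / (len(vals) - 1))
        else:
            sd[cell] = 0.0

    # reference term: mean day-6 log ratio per species x biomarker
    z_d6 = {}
    for (sp, b), vals in base_vals.items():
        m = base[(sp, b)]
        z_d6[(sp, b)] = sum(log(v / m) for v in vals) / len(vals)

    components = {}
    per_individual = defaultdict(float)
    for key, val in y.items():
        ind, b = key
        sp, tr = meta[key]
        s = sd[(sp, tr, b)]
        if s == 0:
            z = float("nan")
            a = 0.0
        else:
            z = (val - mu[(sp, tr, b)]) / s
            a = z - z_d6[(sp, b)]
        components[key] = {"Y": val, "Z": z, "Z_D6": z_d6[(sp, b)], "A": a}
        per_individual[ind] += abs(a)
    return dict(per_individual), components


def depth_metrics_bruteforce(mask, elevation, pixel_scale_um):
    """Reworking metrics by explicit iteration over mask pixels."""
    depths = []
    h, w = len(mask), len(mask[0])
    for row in range(h):
        for col in range(w):
            if mask[row][col]:
                depths.append(max(row - elevation[col], 0)
                              * pixel_scale_um / 1e4)
    if not depths:
        return None
    depths.sort()
    n = len(depths)
    median = (depths[n // 2] if n % 2 else
              0.5 * (depths[n // 2 - 1] + depths[n // 2]))
    sbr = (max(elevation) - min(elevation)) * pixel_scale_um / 1e4
    return {"L_mean": sum(depths) / n, "L_median": median,
            "L_max": depths[-1], "SBR": sbr}
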