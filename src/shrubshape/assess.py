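"""Mechanical-harvest suitability assessment and validation metrics.

An over-the-row harvester's catch plates close around the crown, so small
crowns reduce ground loss; a vase-shaped canopy (path-curve λ < 1) reduces
fruit dropping height. Published machinery requirements give two threshold
levels: *ideal* (crown < 20.32 cm, λ < 1) and *acceptable* (crown <
30.48 cm, λ < 1.1). Plotting each bush's crown size against ln(λ) with
threshold guide lines splits the plane into four quadrants; the lower left
holds bushes with both desired crown and desired shape.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HarvestCriteria",
    "ArchitectureClass",
    "classify_bush",
    "scatter_data",
    "plot_quadrants",
    "regression_metrics",
    "group_test",
]


@dataclass(frozen=True)
class HarvestCriteria:
    ideal_crown_cm: float = 20.32
    acceptable_crown_cm: float = 30.48
    ideal_lambda: float = 1.0
    acceptable_lambda: float = 1.1

    def __post_init__(self):
        if self.ideal_crown_cm > self.acceptable_crown_cm or \
                self.ideal_lambda > self.acceptable_lambda:
            raise ValueError("ideal thresholds must not exceed acceptable")


@dataclass(frozen=True)
class ArchitectureClass:
    quadrant: str   # lower_left | lower_right | upper_left | upper_right
    level: str      # ideal | acceptable | fail


def classify_bush(crown_cm: float, lam: float,
                  criteria: HarvestCriteria = HarvestCriteria(),
                  level: str = "ideal") -> ArchitectureClass:
    """Quadrant classification of one bush at the chosen threshold level.

    Left/right = crown below/above the crown threshold; lower/upper =
    λ below/above the shape threshold. Comparisons are strict, so boundary
    values fall on the non-desired side. The ``level`` field reports the
    best level whose lower-left quadrant the bush reaches.
    """
    if crown_cm <= 0 or lam <= 0:
        raise ValueError("crown_cm and lambda must be positive")
    if level == "ideal":
        c_thr, l_thr = criteria.ideal_crown_cm, criteria.ideal_lambda
    elif level == "acceptable":
        c_thr, l_thr = criteria.acceptable_crown_cm, criteria.acceptable_lambda
    else:
        raise ValueError(f"unknown level {level!r}")
    horiz = "left" if crown_cm < c_thr else "right"
    vert = "lower" if lam < l_thr else "upper"
    quadrant = f"{vert}_{horiz}"
    if crown_cm < criteria.ideal_crown_cm and lam < criteria.ideal_lambda:
        achieved = "ideal"
    elif crown_cm < criteria.acceptable_crown_cm and \
            lam < criteria.acceptable_lambda:
        achieved = "acceptable"
    else:
        achieved = "fail"
    return ArchitectureClass(quadrant=quadrant, level=achieved)


def scatter_data(records: pd.DataFrame,
                 criteria: HarvestCriteria = HarvestCriteria()
                 ) -> pd.DataFrame:
    """Plot-ready table: ln(λ), quadrant labels, per-group cluster centers.

    ``records`` needs columns ``crown_cm`` and ``lambda`` (optionally
    ``group``). Returns a copy with ``ln_lambda``, ``quadrant_ideal``,
    ``quadrant_acceptable``, and group-center columns ``center_crown_cm`` /
    ``center_ln_lambda`` (componentwise group means).
    """
    df = records.copy()
    if "group" not in df:
        df["group"] = "all"
    df["ln_lambda"] = np.log(df["lambda"].astype(float))
    df["quadrant_ideal"] = [
        classify_bush(c, l, criteria, "ideal").quadrant
        for c, l in zip(df["crown_cm"], df["lambda"])
    ]
    df["quadrant_acceptable"] = [
        classify_bush(c, l, criteria, "acceptable").quadrant
        for c, l in zip(df["crown_cm"], df["lambda"])
    ]
    centers = df.groupby("group")[["crown_cm", "ln_lambda"]].transform("mean")
    df["center_crown_cm"] = centers["crown_cm"]
    df["center_ln_lambda"] = centers["ln_lambda"]
    return df


def plot_quadrants(df: pd.DataFrame, path,
                   criteria: HarvestCriteria = HarvestCriteria()):
    """Crown-size vs ln(λ) scatter with both threshold levels marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, sub in df.groupby("group"):
        ax.scatter(sub["crown_cm"], sub["ln_lambda"], s=14, label=str(name))
        ax.scatter(sub["center_crown_cm"].iloc[0],
                   sub["center_ln_lambda"].iloc[0], s=90, marker="o",
                   edgecolor="black")
    ax.axvline(criteria.ideal_crown_cm, color="green", lw=1)
    ax.axvline(criteria.acceptable_crown_cm, color="olive", lw=1)
    ax.axhline(np.log(criteria.ideal_lambda), color="green", lw=1)
    ax.axhline(np.log(criteria.acceptable_lambda), color="olive", lw=1)
    ax.set_xlabel("crown size (cm)")
    ax.set_ylabel("ln λ")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def regression_metrics(estimates, references):
    """Validation metrics of estimates against reference measurements.

    Returns ``(R2, RMSE, MAE, MRE)``: simple linear-regression R², root
    mean square error, mean absolute error, and mean relative error
    |est − ref| / ref. Pairs with a zero reference are excluded from the
    MRE with a warning.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimates and references must be equal-length 1D")
    if len(est) < 2:
        raise ValueError("need at least 2 pairs")
    if np.allclose(est, est[0]) or np.allclose(ref, ref[0]):
        r2 = 1.0 if np.allclose(est, ref) else 0.0
    else:
        r2 = float(stats.linregress(ref, est).rvalue ** 2)
    err = est - ref
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    nz = ref != 0
    if not nz.all():
        warnings.warn(f"{int((~nz).sum())} zero-reference pairs excluded "
                      "from MRE")
    mre = float(np.mean(np.abs(err[nz]) / ref[nz])) if nz.any() else np.nan
    return r2, rmse, mae, mre


def group_test(values_by_group: dict) -> tuple[float, float]:
    """Kruskal-Wallis test across groups; returns (H, p)."""
    H, p = stats.kruskal(*values_by_group.values())
    return float(H), float(p)
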