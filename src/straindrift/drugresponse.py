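"""Drug-screen analysis: vehicle normalization, dose-response AUC, and the
drug-profile variability statistics used to compare strains.

Viability is normalized to the mean of the DMSO vehicle wells on the same
plate.  The per-compound AUC is the trapezoidal integral of viability
(clipped to [0, 1]) over log10 concentration normalized by the log10 span,
so 1 means completely insensitive and 0 fully killed at all doses.  Strain
variability is summarized by the Euclidean distance (ED) of each strain's
AUC profile to the cross-strain mean profile, the standard error of those
EDs, pairwise Spearman similarity of AUC profiles, viability at a fixed
dose, and the relative change in mean AUC between timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stats import spearman_rho

__all__ = [
    "PlateTable",
    "DoseResponseProfile",
    "EDStats",
    "SimilarityMatrix",
    "normalize_viability",
    "auc",
    "auc_table",
    "ed_stats",
    "profile_similarity",
    "fixed_dose_viability",
    "delta_auc",
]

REQUIRED_COLUMNS = ("compound", "conc_uM", "replicate", "signal", "is_vehicle")


@dataclass
class PlateTable:
    """Long-format plate readings.

    Columns: compound, conc_uM, replicate, signal, is_vehicle, and
    optionally plate (defaults to the replicate id: one plate per
    replicate) plus arbitrary metadata such as strain/timepoint.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table lacks columns {sorted(missing)}")
        if "plate" not in self.data.columns:
            self.data = self.data.copy()
            self.data["plate"] = self.data["replicate"]
        if not self.data["is_vehicle"].any():
            raise ValueError("no vehicle wells present")


@dataclass
class DoseResponseProfile:
    """Mean normalized viability per concentration for one compound."""

    compound: str
    conc_uM: np.ndarray
    viability: np.ndarray
    auc: float


@dataclass
class EDStats:
    """Euclidean distances of strain AUC profiles to the mean profile."""

    ed_by_strain: pd.Series
    se_of_ed: float
    se_auc_by_compound: pd.Series


@dataclass
class SimilarityMatrix:
    rho: pd.DataFrame
    median_rho: float = field(init=False)

    def __post_init__(self) -> None:
        vals = self.rho.to_numpy()
        iu = np.triu_indices(vals.shape[0], k=1)
        off = vals[iu]
        off = off[~np.isnan(off)]
        self.median_rho = float(np.median(off)) if off.size else float("nan")


def normalize_viability(pt: PlateTable) -> pd.DataFrame:
    """Divide each signal by the mean vehicle signal of its plate."""
    df = pt.data.copy()
    veh_mean = df[df["is_vehicle"]].groupby("plate")["signal"].mean()
    if (veh_mean <= 0).any():
        raise ValueError("vehicle mean signal is zero on some plate")
    missing = set(df["plate"].unique()) - set(veh_mean.index)
    if missing:
        raise ValueError(f"plates without vehicle wells: {sorted(missing)}")
    df["viability"] = df["signal"] / df["plate"].map(veh_mean)
    return df


def auc(conc_uM, viability, clip: bool = True) -> float:
    """Normalized area under the dose-response curve.

    Trapezoidal integral of viability over log10 concentration divided by
    the log10 span.  Duplicate concentrations (replicates) are averaged
    first.  ``clip=False`` integrates raw viabilities.
    """
    conc = np.asarray(conc_uM, dtype=float)
    v = np.asarray(viability, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    df = pd.DataFrame({"c": conc, "v": v}).groupby("c")["v"].mean()
    if len(df) < 2:
        raise ValueError("need >= 2 distinct concentrations")
    x = np.log10(df.index.to_numpy())
    y = df.to_numpy()
    if clip:
        y = np.clip(y, 0.0, 1.0)
    span = x[-1] - x[0]
    return float(np.trapezoid(y, x) / span)


def _hill(logc, log_ic50, slope, floor):
    return floor + (1.0 - floor) / (1.0 + 10.0 ** (slope * (logc - log_ic50)))


def auc_fitted(conc_uM, viability) -> float:
    """AUC of a fitted 3-parameter Hill curve (alternative to the
    empirical trapezoid), integrated on a fine log10-dose grid."""
    conc = np.asarray(conc_uM, dtype=float)
    v = np.clip(np.asarray(viability, dtype=float), 0.0, 1.2)
    logc = np.log10(conc)
    p0 = (float(np.median(logc)), 1.0, float(max(v.min(), 0.0)))
    try:
        popt, _ = curve_fit(
            _hill, logc, v, p0=p0,
            bounds=([logc.min() - 3, 0.1, 0.0], [logc.max() + 3, 10.0, 0.99]),
            maxfev=2000,
        )
    except RuntimeError:
        return auc(conc_uM, viability)
    grid = np.linspace(logc.min(), logc.max(), 200)
    y = np.clip(_hill(grid, *popt), 0.0, 1.0)
    return float(np.trapezoid(y, grid) / (grid[-1] - grid[0]))


def auc_table(normalized: pd.DataFrame, by=("strain",), clip: bool = True) -> pd.DataFrame:
    """AUC matrix (index = grouping key, columns = compounds).

    ``normalized`` is the output of :func:`normalize_viability`; vehicle
    wells are ignored.
    """
    df = normalized[~normalized["is_vehicle"]]
    by = list(by)
    rows = {}
    for key, grp in df.groupby(by[0] if len(by) == 1 else by):
        rows[key] = {
            comp: auc(g["conc_uM"], g["viability"], clip=clip)
            for comp, g in grp.groupby("compound")
        }
    return pd.DataFrame(rows).T.sort_index()


def ed_stats(auc_by_strain: pd.DataFrame) -> EDStats:
    """Euclidean distance of each strain's AUC profile to the mean profile.

    ``auc_by_strain`` is strains x compounds.  The entity-level variability
    is the standard error (sd/sqrt(n)) of the per-strain EDs, which keeps
    entities with different strain counts comparable; the per-compound
    standard error of AUC across strains is also reported.
    """
    if auc_by_strain.isna().any().any():
        raise ValueError("compound sets differ across strains")
    if auc_by_strain.shape[0] < 2:
        raise ValueError("need >= 2 strains")
    x = auc_by_strain.to_numpy(dtype=float)
    mean_profile = x.mean(axis=0)
    ed = np.sqrt(((x - mean_profile) ** 2).sum(axis=1))
    se = float(ed.std(ddof=1) / np.sqrt(ed.size))
    se_auc = auc_by_strain.std(axis=0, ddof=1) / np.sqrt(auc_by_strain.shape[0])
    return EDStats(
        ed_by_strain=pd.Series(ed, index=auc_by_strain.index, name="ED"),
        se_of_ed=se,
        se_auc_by_compound=se_auc,
    )


def profile_similarity(auc_by_strain: pd.DataFrame) -> SimilarityMatrix:
    """Pairwise Spearman correlation of strain AUC profiles.

    Pairs involving a constant profile are flagged undefined (NaN).
    """
    if auc_by_strain.shape[1] < 3:
        raise ValueError("need >= 3 compounds")
    strains = list(auc_by_strain.index)
    n = len(strains)
    rho = np.eye(n)
    x = auc_by_strain.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = spearman_rho(x[i], x[j])
            except ValueError:
                r = np.nan
            rho[i, j] = rho[j, i] = r
    return SimilarityMatrix(rho=pd.DataFrame(rho, index=strains, columns=strains))


def fixed_dose_viability(
    normalized: pd.DataFrame,
    dose_uM: float = 1.0,
    by=("timepoint",),
    nearest_fallback: bool = True,
) -> pd.DataFrame:
    """Mean normalized viability at one dose, per compound per group.

    When the requested dose is absent from the series, the nearest dose in
    log10 distance is used (flagged in the ``dose_used`` attribute of the
    returned frame) unless ``nearest_fallback`` is False.
    """
    df = normalized[~normalized["is_vehicle"]]
    doses = np.sort(df["conc_uM"].unique())
    if dose_uM in doses:
        used = float(dose_uM)
    elif nearest_fallback:
        used = float(doses[np.argmin(np.abs(np.log10(doses) - np.log10(dose_uM)))])
    else:
        raise ValueError(f"dose {dose_uM} uM not in series and fallback disabled")
    sub = df[df["conc_uM"] == used]
    out = sub.groupby(["compound", *by])["viability"].mean().unstack(list(by))
    out.attrs["dose_used"] = used
    out.attrs["fallback"] = used != dose_uM
    return out


def delta_auc(auc_ref: pd.Series, auc_alt: pd.Series) -> tuple[float, pd.Series]:
    """Relative change of mean AUC across compounds between timepoints.

    Returns |mean_alt - mean_ref| / mean_ref and the per-compound deltas
    (alt - ref).
    """
    if set(auc_ref.index) != set(auc_alt.index):
        raise ValueError("compound sets differ between timepoints")
    auc_alt = auc_alt.reindex(auc_ref.index)
    m_ref = float(auc_ref.mean())
    if m_ref == 0:
        raise ValueError("zero baseline mean AUC")
    rel = abs(float(auc_alt.mean()) - m_ref) / m_ref
    return rel, (auc_alt - auc_ref)
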