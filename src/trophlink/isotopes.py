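"""δ notation, C:N quality screening, and Post trophic levels.

A consumer's trophic level is estimated from its muscle δ¹⁵N relative to a
baseline organism of known trophic position (here the suspension-feeding
queen scallop, TL_B = 2):

    TL_i = TL_B + (δ¹⁵N_i − δ¹⁵N_B) / TDF,

with TDF = 3.4 ‰ per trophic level the classical nitrogen trophic
discrimination factor. The baseline δ¹⁵N_B is station-specific (observed or
kriged), because the isotopic baseline varies spatially. Lipid-rich tissue
biases δ¹³C; samples are screened on the C:N ratio (≤ 3.5 passes raw,
higher values are flagged but never silently corrected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diet import assign_size_class

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrophicParams:
    """Baseline trophic position and trophic discrimination factor (‰/level)."""

    TL_B: float = 2.0
    TDF: float = 3.4

    def __post_init__(self) -> None:
        if self.TDF <= 0:
            raise ValueError("TDF must be positive")


DEFAULT_CN_THRESHOLD = 3.5


def delta_value(r_sample: float, r_standard: float) -> float:
    """δ notation: (R_sample/R_standard − 1) × 10³, in ‰."""
    if r_standard <= 0:
        raise ValueError("R_standard must be positive")
    return (r_sample / r_standard - 1.0) * 1e3


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_value`."""
    if r_standard <= 0:
        raise ValueError("R_standard must be positive")
    return r_standard * (1.0 + delta / 1e3)


def cn_screen(
    measurements: pd.DataFrame, threshold: float = DEFAULT_CN_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split measurements into (passed, flagged) on the C:N ratio.

    Values at or below the threshold pass untouched (raw ratios are used, no
    lipid normalisation); higher values are flagged for inspection, never
    corrected.
    """
    if threshold <= 0:
        raise ValueError("C:N threshold must be positive")
    ok = measurements["cn_ratio"] <= threshold
    flagged = measurements.loc[~ok]
    if len(flagged):
        logger.warning("%d isotope measurements flagged for C:N > %.2f",
                       len(flagged), threshold)
    return measurements.loc[ok].copy(), flagged.copy()


def trophic_level(
    d15n: float | np.ndarray, d15n_baseline: float | np.ndarray,
    params: TrophicParams = TrophicParams(),
) -> float | np.ndarray:
    """Post equation: TL = TL_B + (δ¹⁵N − δ¹⁵N_B)/TDF."""
    return params.TL_B + (np.asarray(d15n) - np.asarray(d15n_baseline)) / params.TDF


def trophic_levels_table(
    isotopes: pd.DataFrame,
    fish: pd.DataFrame,
    station_baseline: Mapping[str, float] | pd.DataFrame,
    params: TrophicParams = TrophicParams(),
    pooled_baseline: bool = False,
) -> pd.DataFrame:
    """Per-fish trophic level using each fish's station baseline.

    ``isotopes`` needs fish_id, d13C, d15N, cn_ratio; ``fish`` needs
    fish_id, station_id, season and length_mm or size_class. With
    ``pooled_baseline=True`` every fish uses the mean baseline instead of
    its station's value (a sensitivity mode).
    """
    if isinstance(station_baseline, pd.DataFrame):
        station_baseline = dict(
            zip(station_baseline["station_id"].astype(str),
                station_baseline["d15N_baseline"]))
    fish = fish.copy()
    if "size_class" not in fish.columns:
        fish["size_class"] = [assign_size_class(l) for l in fish["length_mm"]]
    merged = isotopes.merge(
        fish[[c for c in ("fish_id", "station_id", "season", "size_class", "gape_mm")
              if c in fish.columns]],
        on="fish_id", how="inner", validate="one_to_one")
    missing = set(merged["station_id"].astype(str)) - set(station_baseline)
    if missing:
        raise ValueError(f"no baseline value for stations: {sorted(missing)}")
    if pooled_baseline:
        pooled = float(np.mean(list(station_baseline.values())))
        base = np.full(len(merged), pooled)
    else:
        base = merged["station_id"].astype(str).map(station_baseline).to_numpy(float)
    merged["d15N_B_used"] = base
    merged["TL"] = trophic_level(merged["d15N"].to_numpy(float), base, params)
    return merged


def summarize_isotopes(
    records: pd.DataFrame,
    value_cols: Sequence[str] = ("d13C", "d15N", "cn_ratio", "TL", "gape_mm"),
) -> pd.DataFrame:
    """Per-(season, size class) summary: n and mean ± SD of each value column.

    SD is the sample standard deviation (n − 1 denominator); cells with a
    single record report SD as missing, cells with no record are omitted
    with a log line.
    """
    value_cols = [c for c in value_cols if c in records.columns]
    rows = []
    for (season, size_class), g in records.groupby(["season", "size_class"], sort=True):
        if len(g) == 0:  # pragma: no cover - groupby drops empty groups
            continue
        row: dict[str, object] = {"season": season, "size_class": size_class, "n": len(g)}
        for c in value_cols:
            x = g[c].to_numpy(float)
            row[f"{c}_mean"] = float(np.mean(x))
            row[f"{c}_sd"] = float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)
    if out["n"].sum() != len(records):
        logger.info("summary covers %d of %d records", int(out["n"].sum()), len(records))
    return out
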