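"""Seeded synthetic study generator.

Builds a complete synthetic trawl-survey study — stations, a spatially
autocorrelated baseline δ¹⁵N field, fish with lengths and gapes, stomach
contents as prey parts, and muscle isotope values — with the statistical
structure the downstream analysis assumes, so the whole pipeline can be
exercised and validated without any data download.

The defaults emulate the published EEC-SNS whiting study structure: two
seasons (no fish below 15 cm in winter), 5-cm size classes with the
published per-cell sample sizes, a baseline field with mean 7.69 ‰ and SD
0.90 ‰ under a Gaussian spatial covariance, seasonal vacuity probabilities
of 0.16/0.07, an ontogenetic diet shift from pelagic crustaceans toward
fish and mollusks (with a strong winter copepod pulse in the 15–20 cm
class), and fish δ¹⁵N = station baseline + (TL − 2)·TDF + noise.

All randomness derives from one integer seed; per-stage substreams keep
every output reproducible and independent of the other stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .baseline import BaselineObservation, CovarianceModel, distance_matrix
from .diet import PreyItem, StomachRecord
from .isotopes import TrophicParams
from . import reference as ref

Cell = tuple[str, str]  # (season, size_class)

#: Benthic prey groups for the δ¹³C mixing fraction; the rest count as pelagic.
BENTHIC_GROUPS = frozenset({"benthic_crustacean", "mollusk", "other"})

_CLASS_INDEX = {lab: i for i, lab in enumerate(ref.SIZE_CLASS_LABELS)}

#: Default per-group Poisson means of prey individuals per non-empty stomach,
#: indexed by size class (10-15cm … 35+). Crustacean consumption falls and
#: fish/mollusk consumption rises with size; winter carries a large pelagic
#: copepod pulse in the 15-20cm class.
_DEFAULT_MEAN_ITEMS = {
    "autumn": {
        "fish": [0.2, 0.4, 0.7, 1.0, 1.3, 1.6],
        "benthic_crustacean": [2.0, 2.5, 3.0, 2.2, 1.4, 0.9],
        "pelagic_crustacean": [3.0, 1.5, 0.8, 0.4, 0.2, 0.1],
        "unidentified_crustacean": [1.0, 0.8, 0.6, 0.5, 0.4, 0.3],
        "mollusk": [0.1, 0.15, 0.25, 0.35, 0.45, 0.55],
        "other": [0.3] * 6,
    },
    "winter": {
        "fish": [np.nan, 0.4, 0.7, 1.1, 1.6, 2.0],
        "benthic_crustacean": [np.nan, 3.0, 3.5, 2.5, 1.5, 1.0],
        "pelagic_crustacean": [np.nan, 70.0, 5.0, 1.5, 0.5, 0.2],
        "unidentified_crustacean": [np.nan, 1.5, 1.2, 0.8, 0.6, 0.4],
        "mollusk": [np.nan, 0.15, 0.25, 0.4, 0.5, 0.6],
        "other": [np.nan, 0.3, 0.3, 0.3, 0.3, 0.3],
    },
}


def default_mean_items() -> dict[Cell, dict[str, float]]:
    out: dict[Cell, dict[str, float]] = {}
    for (season, size_class) in ref.N_SCA:
        i = _CLASS_INDEX[size_class]
        out[(season, size_class)] = {
            g: float(_DEFAULT_MEAN_ITEMS[season][g][i]) for g in ref.PREY_GROUPS
        }
    return out


@dataclass
class SyntheticConfig:
    """All parameters of the synthetic study; defaults mirror the survey."""

    seed: int = 0
    n_stations: int = 120
    #: (lat_min, lat_max, lon_min, lon_max), degrees; roughly the EEC-SNS box
    bbox: tuple[float, float, float, float] = (49.3, 51.6, -1.5, 3.2)
    baseline_mean: float = ref.BASELINE_MEAN_D15N   # ‰
    baseline_sd: float = ref.BASELINE_SD_D15N       # ‰
    baseline_range: float = 40.0                    # km, synthetic choice
    n_baseline_obs: int = ref.BASELINE_N
    seasons: tuple[str, ...] = ref.SEASONS
    #: fish per (season, size class) cell; default: published n SCA counts
    fish_per_class: Mapping[Cell, int] = dc_field(default_factory=lambda: dict(ref.N_SCA))
    class_edges: tuple[float, ...] = ref.CLASS_EDGES_MM
    max_length: float = ref.MAX_LENGTH_MM
    #: per-cell per-group Poisson mean of prey individuals in non-empty stomachs
    mean_items: Mapping[Cell, Mapping[str, float]] = dc_field(default_factory=default_mean_items)
    p_empty: Mapping[str, float] = dc_field(default_factory=lambda: {"autumn": 0.16, "winter": 0.07})
    tl_by_class: Mapping[Cell, float] = dc_field(default_factory=lambda: dict(ref.TL_BY_CELL))
    trophic: TrophicParams = dc_field(default_factory=TrophicParams)
    d15n_noise_sd: float = 0.35                     # ‰, individual + analytical
    #: (pelagic_mean, benthic_mean, noise_sd) ‰ for the δ¹³C two-source mixture
    d13c_params: tuple[float, float, float] = (-18.3, -15.8, 0.4)
    cn_mean: float = ref.CN_MEAN
    cn_sd: float = ref.CN_SD
    cn_bounds: tuple[float, float] = (3.0, 3.5)
    #: per-individual probability of leaving (whole, paired parts, remains only)
    part_type_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)
    #: probability that a stomach-taxon with countable parts also shows remains
    extra_remains_prob: float = 0.15

    def __post_init__(self) -> None:
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if lat_min >= lat_max or lon_min >= lon_max:
            raise ValueError(f"degenerate bbox {self.bbox}: zero area")
        if self.baseline_sd < 0 or self.d15n_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.baseline_range <= 0:
            raise ValueError("baseline_range must be positive")
        for season, p in self.p_empty.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"p_empty[{season!r}] = {p} outside [0, 1)")
        if abs(sum(self.part_type_probs) - 1.0) > 1e-9:
            raise ValueError("part_type_probs must sum to 1")
        for cell in self.cells():
            if cell not in self.mean_items:
                raise ValueError(f"mean_items missing for cell {cell}")
            if cell not in self.tl_by_class:
                raise ValueError(f"tl_by_class missing for cell {cell}")
            comp = self.diet_composition(cell)
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise AssertionError(f"diet composition for {cell} does not sum to 1")

    def cells(self) -> list[Cell]:
        return sorted(self.fish_per_class.keys())

    def diet_composition(self, cell: Cell) -> dict[str, float]:
        """Multinomial prey-group composition: normalised Poisson means."""
        lam = self.mean_items[cell]
        total = sum(lam.values())
        if total <= 0:
            raise ValueError(f"mean_items for cell {cell} sum to {total}; must be > 0")
        return {g: lam[g] / total for g in ref.PREY_GROUPS}

    def rng(self, stage: int) -> np.random.Generator:
        """Named substream for one pipeline stage, derived from the config seed."""
        return np.random.default_rng([int(self.seed), int(stage)])


# substream indices per stage
_STAGE_FIELD = 0
_STAGE_FISH = 1
_STAGE_BASELINE_SUBSET = 2


def make_baseline_field(config: SyntheticConfig) -> list[BaselineObservation]:
    """Simulate the baseline δ¹⁵N field at all station locations.

    Stations are uniform in the bbox; values are one draw of a Gaussian
    process with constant mean ``baseline_mean``, marginal variance
    ``baseline_sd²`` and Gaussian covariance sill·exp(−(h/range)²),
    generated by Cholesky factorisation of the full covariance matrix with
    a small diagonal jitter. The same config (seed) always yields the same
    field.
    """
    if config.n_stations < 2:
        raise ValueError("need at least 2 stations")
    rng = config.rng(_STAGE_FIELD)
    lat_min, lat_max, lon_min, lon_max = config.bbox
    lat = rng.uniform(lat_min, lat_max, config.n_stations)
    lon = rng.uniform(lon_min, lon_max, config.n_stations)
    normals = rng.standard_normal(config.n_stations)
    if config.baseline_sd == 0:
        z = np.full(config.n_stations, config.baseline_mean)
    else:
        model = CovarianceModel("gaussian", sill=config.baseline_sd**2,
                                range_km=config.baseline_range)
        C = np.asarray(model(distance_matrix(lat, lon)), dtype=float)
        np.fill_diagonal(C, config.baseline_sd**2 + 1e-8)
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance matrix not positive definite after jitter for "
                f"n_stations={config.n_stations}, range={config.baseline_range} km"
            ) from exc
        z = config.baseline_mean + L @ normals
    return [
        BaselineObservation(id=f"st_{k:03d}", lat=float(lat[k]), lon=float(lon[k]),
                            d15N=float(z[k]))
        for k in range(config.n_stations)
    ]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):  # simple rejection; bounds are ~4 SD wide
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_fish(
    config: SyntheticConfig, field: Sequence[BaselineObservation]
) -> tuple[pd.DataFrame, list[StomachRecord], pd.DataFrame]:
    """Simulate fish, stomach contents and isotope values on a baseline field.

    Each fish draws a station from the field, a length uniform within its
    size class (the open 35+ class spans [350, max_length) mm), and a gape
    roughly proportional to length. Its stomach is empty with the seasonal
    probability, otherwise each prey group's individual count is
    Poisson(mean_items) — with one guaranteed individual from the diet
    composition if all draws are zero — and each individual leaves whole,
    paired or unquantifiable parts. Muscle δ¹⁵N is the station's true
    baseline + (TL_cell − TL_B)·TDF + noise; δ¹³C is a benthic/pelagic
    two-source value from the cell's expected benthic prey fraction; C:N is
    a truncated normal.

    Returns (fish table, stomach records, isotope table). The fish table
    carries the per-group true individual counts (``true_<group>``) as
    ground truth for validation.
    """
    if not field:
        raise ValueError("baseline field is empty")
    rng = config.rng(_STAGE_FISH)
    edges = list(config.class_edges) + [config.max_length]
    groups = ref.PREY_GROUPS
    p_whole, p_paired, _p_remains = config.part_type_probs
    pel_mean, ben_mean, d13c_sd = config.d13c_params

    fish_rows: list[dict] = []
    stomachs: list[StomachRecord] = []
    iso_rows: list[dict] = []
    fid = 0
    for (season, size_class) in config.cells():
        n_fish = int(config.fish_per_class[(season, size_class)])
        ci = _CLASS_INDEX[size_class]
        lo, hi = edges[ci], edges[ci + 1]
        lam = config.mean_items[(season, size_class)]
        comp = config.diet_composition((season, size_class))
        comp_vec = np.array([comp[g] for g in groups])
        tl_true = config.tl_by_class[(season, size_class)]
        b_frac = sum(lam[g] for g in BENTHIC_GROUPS) / sum(lam.values())
        d13c_mu = ben_mean * b_frac + pel_mean * (1.0 - b_frac)
        p_empty = config.p_empty[season]
        for _ in range(n_fish):
            fid += 1
            fish_id = f"fish_{fid:04d}"
            station = field[int(rng.integers(len(field)))]
            length = float(rng.uniform(lo, hi))
            gape = float(np.round(0.1 * length + rng.normal(0.0, 1.5), 1))
            rec = StomachRecord(stomach_id=fish_id, fish_id=fish_id,
                                season=season, size_class=size_class)
            true_counts = dict.fromkeys(groups, 0)
            if rng.uniform() >= p_empty:
                counts = rng.poisson([lam[g] for g in groups])
                if counts.sum() == 0:
                    counts[rng.choice(len(groups), p=comp_vec)] += 1
                for g, k in zip(groups, counts):
                    if k == 0:
                        continue
                    true_counts[g] = int(k)
                    rec.items.extend(
                        _items_for_individuals(rng, fish_id, g, int(k),
                                               p_whole, p_paired,
                                               config.extra_remains_prob))
            stomachs.append(rec)
            row = {"fish_id": fish_id, "stomach_id": fish_id,
                   "station_id": station.id, "season": season,
                   "size_class": size_class, "length_mm": round(length, 1),
                   "gape_mm": gape}
            row.update({f"true_{g}": true_counts[g] for g in groups})
            fish_rows.append(row)
            d15n = station.d15N + (tl_true - config.trophic.TL_B) * config.trophic.TDF
            if config.d15n_noise_sd > 0:
                d15n += rng.normal(0.0, config.d15n_noise_sd)
            cn = float(_truncated_normal(rng, config.cn_mean, config.cn_sd,
                                         *config.cn_bounds, 1)[0])
            iso_rows.append({"fish_id": fish_id,
                             "d13C": float(d13c_mu + rng.normal(0.0, d13c_sd)),
                             "d15N": float(d15n), "cn_ratio": cn})
    return pd.DataFrame(fish_rows), stomachs, pd.DataFrame(iso_rows)


def _items_for_individuals(
    rng: np.random.Generator, stomach_id: str, group: str, k: int,
    p_whole: float, p_paired: float, extra_remains_prob: float,
) -> list[PreyItem]:
    """Turn k true individuals of one group into recovered-part records.

    Each individual leaves either its whole body, paired hard parts
    (usually both of a pair, sometimes just one), or only unquantifiable
    remains. The parsimonious enumeration downstream recovers whole and
    paired donors exactly and collapses remains-only evidence to one
    individual.
    """
    taxon = f"{group}_taxon"
    u = rng.uniform(size=k)
    n_whole = int(np.sum(u < p_whole))
    n_paired = int(np.sum((u >= p_whole) & (u < p_whole + p_paired)))
    n_remains = k - n_whole - n_paired
    items: list[PreyItem] = []
    if n_whole:
        items.append(PreyItem(stomach_id, taxon, group, "whole", n_whole))
    if n_paired:
        parts = int(2 * n_paired - rng.binomial(1, 0.3))  # occasionally one lost
        items.append(PreyItem(stomach_id, taxon, group, "paired_part", parts))
    if n_remains or (items and rng.uniform() < extra_remains_prob):
        items.append(PreyItem(stomach_id, taxon, group, "uncountable_remains", 1))
    return items


@dataclass
class SyntheticStudy:
    """All tables of one synthetic study, plus the generating config."""

    config: SyntheticConfig
    stations: pd.DataFrame        # station_id, lat, lon, d15N_baseline_true
    baseline_obs: pd.DataFrame    # id, lat, lon, d15N — the observed subset
    fish: pd.DataFrame
    stomachs: list[StomachRecord]
    prey_items: pd.DataFrame
    isotopes: pd.DataFrame

    @property
    def field(self) -> list[BaselineObservation]:
        return [BaselineObservation(id=str(r.station_id), lat=float(r.lat),
                                    lon=float(r.lon),
                                    d15N=float(r.d15N_baseline_true))
                for r in self.stations.itertuples(index=False)]


def prey_items_frame(stomachs: Sequence[StomachRecord]) -> pd.DataFrame:
    rows = [
        {"stomach_id": it.stomach_id, "taxon": it.taxon, "group": it.group,
         "part_type": it.part_type, "raw_count": it.raw_count}
        for s in stomachs for it in s.items
    ]
    return pd.DataFrame(rows, columns=["stomach_id", "taxon", "group",
                                       "part_type", "raw_count"])


def simulate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Full synthetic study: field, baseline-observation subset, fish, stomachs.

    The baseline invertebrate (queen scallop) is observed at a random
    subset of ``n_baseline_obs`` stations; the remaining stations hold out
    the true field value, which the kriging stage must reconstruct.
    """
    field = make_baseline_field(config)
    stations = pd.DataFrame(
        {"station_id": [o.id for o in field], "lat": [o.lat for o in field],
         "lon": [o.lon for o in field],
         "d15N_baseline_true": [o.d15N for o in field]})
    n_obs = min(config.n_baseline_obs, config.n_stations)
    idx = config.rng(_STAGE_BASELINE_SUBSET).choice(
        config.n_stations, size=n_obs, replace=False)
    obs = stations.iloc[np.sort(idx)]
    baseline_obs = pd.DataFrame(
        {"id": obs["station_id"], "lat": obs["lat"], "lon": obs["lon"],
         "d15N": obs["d15N_baseline_true"]}).reset_index(drop=True)
    fish, stomachs, isotopes = simulate_fish(config, field)
    return SyntheticStudy(config=config, stations=stations,
                          baseline_obs=baseline_obs, fish=fish,
                          stomachs=stomachs,
                          prey_items=prey_items_frame(stomachs),
                          isotopes=isotopes)
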