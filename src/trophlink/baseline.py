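"""Spatial δ¹⁵N baseline: covariogram estimation, WLS model fit, ordinary kriging.

The isotopic baseline (queen scallop muscle δ¹⁵N) varies spatially; fish
trophic levels therefore use a station-specific baseline. Stations without a
co-located scallop observation get an interpolated value: the empirical
spatial covariance of the observations is binned by great-circle distance,
a parametric covariance model (Gaussian by default, c(h) = nugget·1(h=0) +
sill·exp(−(h/range)²)) is fitted by weighted nonlinear least squares with
the number of point pairs per distance bin as weights, and ordinary kriging
with the fitted model predicts the baseline at the target stations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
#: diagonal jitter keeping covariance matrices positive definite
JITTER = 1e-8

COVARIANCE_FAMILIES = ("gaussian", "exponential", "spherical")


@dataclass(frozen=True)
class BaselineObservation:
    id: str
    lat: float
    lon: float
    d15N: float


@dataclass
class EmpiricalCovariogram:
    bin_mid: np.ndarray  # km
    cov_hat: np.ndarray  # ‰² (or semivariance if mode="semivariogram")
    n_pairs: np.ndarray
    mode: str = "covariogram"


@dataclass
class CovarianceModel:
    family: str
    sill: float
    range_km: float
    nugget: float = 0.0
    adj_r2: float = float("nan")

    def __call__(self, h: np.ndarray | float) -> np.ndarray | float:
        """Covariance at distance h (km); the nugget applies only at h == 0."""
        h = np.asarray(h, dtype=float)
        c = self.sill * _correlation(self.family, h, self.range_km)
        return c + self.nugget * (h == 0)


@dataclass
class KrigingResult:
    id: str
    lat: float
    lon: float
    d15N_pred: float
    krig_var: float
    weights: np.ndarray = field(repr=False, default=None)


def _correlation(family: str, h: np.ndarray, range_km: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    if family == "gaussian":
        return np.exp(-((h / range_km) ** 2))
    if family == "exponential":
        return np.exp(-h / range_km)
    if family == "spherical":
        u = np.clip(h / range_km, 0.0, 1.0)
        return 1.0 - 1.5 * u + 0.5 * u**3
    raise ValueError(f"unknown covariance family {family!r}; expected {COVARIANCE_FAMILIES}")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a 6371-km sphere."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def distance_matrix(lat: np.ndarray, lon: np.ndarray, lat2: np.ndarray | None = None,
                    lon2: np.ndarray | None = None) -> np.ndarray:
    """Pairwise haversine distances (km), vectorised."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if lat2 is None:
        lat2, lon2 = lat, lon
    else:
        lat2 = np.asarray(lat2, dtype=float)
        lon2 = np.asarray(lon2, dtype=float)
        if np.any(np.abs(lat2) > 90):
            raise ValueError("latitude outside [-90, 90]")
    p1 = np.radians(lat)[:, None]
    p2 = np.radians(lat2)[None, :]
    dphi = p2 - p1
    dlmb = np.radians(lon2)[None, :] - np.radians(lon)[:, None]
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def empirical_covariogram(
    obs: Sequence[BaselineObservation],
    bin_width: float = 10.0,
    max_lag: float | None = None,
    mode: str = "covariogram",
) -> EmpiricalCovariogram:
    """Binned spatial covariance (or semivariance) of the observations.

    For each distance bin, ``cov_hat`` is the mean over point pairs (i, j)
    in the bin of (z_i − z̄)(z_j − z̄) with z̄ the global mean; in
    semivariogram mode it is the mean of (z_i − z_j)²/2. Empty bins are
    dropped; n_pairs per bin are retained as the WLS weights.
    """
    if len(obs) < 2:
        raise ValueError("empirical_covariogram requires at least 2 observations")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if mode not in ("covariogram", "semivariogram"):
        raise ValueError(f"unknown mode {mode!r}")
    lat = np.array([o.lat for o in obs])
    lon = np.array([o.lon for o in obs])
    z = np.array([o.d15N for o in obs])
    D = distance_matrix(lat, lon)
    iu, ju = np.triu_indices(len(obs), k=1)
    d = D[iu, ju]
    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    keep = d <= max_lag
    if not np.any(keep):
        raise ValueError(f"all point pairs are beyond max_lag = {max_lag} km")
    d = d[keep]
    if mode == "covariogram":
        dev = z - z.mean()
        val = dev[iu[keep]] * dev[ju[keep]]
    else:
        val = 0.5 * (z[iu[keep]] - z[ju[keep]]) ** 2
    bins = np.floor(d / bin_width).astype(int)
    order = np.argsort(bins, kind="stable")
    bins, val = bins[order], val[order]
    uniq, start = np.unique(bins, return_index=True)
    sums = np.add.reduceat(val, start)
    counts = np.diff(np.append(start, len(val)))
    return EmpiricalCovariogram(
        bin_mid=(uniq + 0.5) * bin_width,
        cov_hat=sums / counts,
        n_pairs=counts,
        mode=mode,
    )


def fit_covariance(
    emp: EmpiricalCovariogram,
    family: str = "gaussian",
    fit_nugget: bool = False,
) -> CovarianceModel:
    """Fit a parametric covariance model by weighted nonlinear least squares.

    Minimises Σ_b n_pairs_b (cov_hat_b − c(h_b))² over (sill, range) — and
    the nugget if requested — with bounded optimisation from several starts.
    The quality of fit is reported as the adjusted R² of the weighted
    regression: adjR² = 1 − (1 − R²)(n − 1)/(n − p − 1).
    """
    _correlation(family, np.zeros(1), 1.0)  # validates family
    n_params = 3 if fit_nugget else 2
    h = np.asarray(emp.bin_mid, dtype=float)
    y = np.asarray(emp.cov_hat, dtype=float)
    w = np.asarray(emp.n_pairs, dtype=float)
    n = len(h)
    if n < n_params + 1:
        raise ValueError(f"need at least {n_params + 1} bins to fit, got {n}")
    if emp.mode == "semivariogram":
        # fit γ(h) = nugget + sill·(1 − ρ(h)); same parameters, mirrored shape
        def model(h_, sill, rng, nug=0.0):
            return nug + sill * (1.0 - _correlation(family, h_, rng))
    else:
        def model(h_, sill, rng, nug=0.0):
            return nug + sill * _correlation(family, h_, rng)

    sill0 = max(abs(y).max(), 1e-6)
    hspan = max(h.max(), 1e-3)
    sw = np.sqrt(w)

    def residuals(theta):
        return sw * (model(h, *theta) - y)

    starts = []
    for s_fac in (1.0, 0.5, 2.0):
        for r_fac in (0.25, 0.5, 1.0):
            theta0 = [sill0 * s_fac, hspan * r_fac]
            if fit_nugget:
                theta0.append(0.1 * sill0)
            starts.append(theta0)

    lower = [1e-12, 1e-6] + ([0.0] if fit_nugget else [])
    upper = [np.inf, np.inf] + ([np.inf] if fit_nugget else [])
    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(
                residuals, theta0, bounds=(lower, upper), method="trf", xtol=1e-14,
                ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(f"covariance fit failed to converge for family {family!r}")

    yhat = model(h, *best.x)
    ybar_w = np.average(y, weights=w)
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar_w) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1) if n > n_params + 1 else r2
    sill, rng = float(best.x[0]), float(best.x[1])
    nugget = float(best.x[2]) if fit_nugget else 0.0
    return CovarianceModel(family=family, sill=sill, range_km=rng, nugget=nugget,
                           adj_r2=float(adj_r2))


def _dedupe(obs: Sequence[BaselineObservation]) -> list[BaselineObservation]:
    """Average observations sharing exact coordinates (keeps kriging non-singular)."""
    groups: dict[tuple[float, float], list[BaselineObservation]] = {}
    for o in obs:
        groups.setdefault((o.lat, o.lon), []).append(o)
    out = []
    for (lat, lon), os in groups.items():
        if len(os) == 1:
            out.append(os[0])
        else:
            out.append(BaselineObservation(
                id="+".join(o.id for o in os), lat=lat, lon=lon,
                d15N=float(np.mean([o.d15N for o in os])),
            ))
    return out


def krige(
    obs: Sequence[BaselineObservation],
    model: CovarianceModel,
    targets: Sequence[tuple[float, float]],
    target_ids: Sequence[str] | None = None,
    dedupe: bool = True,
) -> list[KrigingResult]:
    """Ordinary kriging of the observations to the target locations.

    Weights λ solve the augmented system [[C, 1], [1ᵀ, 0]] [λ, μ] = [c₀, 1],
    where C is the observation covariance matrix (plus jitter) and c₀ the
    observation–target covariances; the Lagrange multiplier μ enforces
    Σλ = 1 (unbiasedness). Prediction is Σλᵢzᵢ; the kriging variance is
    sill + nugget − Σλᵢc(hᵢ₀) − μ. Duplicate observation locations are
    averaged first; targets with negative weights are logged, not clipped.
    """
    if len(obs) < 1:
        raise ValueError("krige requires at least one observation")
    if dedupe:
        obs = _dedupe(obs)
    if target_ids is None:
        target_ids = [f"target_{k}" for k in range(len(targets))]
    lat = np.array([o.lat for o in obs])
    lon = np.array([o.lon for o in obs])
    z = np.array([o.d15N for o in obs])
    n = len(obs)
    tlat = np.array([t[0] for t in targets], dtype=float)
    tlon = np.array([t[1] for t in targets], dtype=float)

    if n == 1:
        # Σλ = 1 forces λ = 1: prediction is the single observed value
        return [
            KrigingResult(id=tid, lat=la, lon=lo, d15N_pred=float(z[0]),
                          krig_var=float(model.sill + model.nugget -
                                         model(haversine_km(lat[0], lon[0], la, lo))),
                          weights=np.array([1.0]))
            for tid, la, lo in zip(target_ids, tlat, tlon)
        ]

    D = distance_matrix(lat, lon)
    C = np.asarray(model(D), dtype=float)
    np.fill_diagonal(C, model.sill + model.nugget + JITTER)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = C
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    try:
        lu = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular kriging system; deduplicate co-located observations by "
            "averaging before kriging"
        ) from exc

    D0 = distance_matrix(lat, lon, tlat, tlon)  # n × m
    C0 = np.asarray(model(D0), dtype=float)
    C0[D0 == 0] = model.sill + model.nugget  # exact co-location includes nugget
    rhs = np.vstack([C0, np.ones(len(targets))])
    sol = lu @ rhs
    lam = sol[:n, :]
    mu = sol[n, :]
    preds = lam.T @ z
    variances = model.sill + model.nugget - np.einsum("ij,ij->j", lam, C0) - mu

    n_neg = int(np.sum(np.any(lam < -1e-10, axis=0)))
    if n_neg:
        logger.info("%d of %d kriging targets have negative weights (smooth "
                    "covariance models allow them); predictions not clipped",
                    n_neg, len(targets))
    out = []
    for k, (tid, la, lo) in enumerate(zip(target_ids, tlat, tlon)):
        wk = lam[:, k]
        if np.any(wk < -1e-10):
            logger.debug("kriging target %s has negative weights (min %.3g); "
                         "prediction may leave the data range", tid, wk.min())
        out.append(KrigingResult(id=tid, lat=float(la), lon=float(lo),
                                 d15N_pred=float(preds[k]),
                                 krig_var=float(max(variances[k], 0.0)),
                                 weights=wk))
    return out


def baseline_for_stations(
    obs: Sequence[BaselineObservation],
    stations: pd.DataFrame,
    bin_width: float = 10.0,
    family: str = "gaussian",
    fit_nugget: bool = False,
    max_lag: float | None = None,
) -> tuple[pd.DataFrame, CovarianceModel]:
    """Station-specific baseline δ¹⁵N: observed where co-located, kriged elsewhere.

    ``stations`` needs columns station_id, lat, lon. Runs the full chain
    covariogram → WLS fit → ordinary kriging and returns a table with
    columns station_id, lat, lon, d15N_baseline, krig_var, source.
    """
    obs = _dedupe(obs)
    emp = empirical_covariogram(obs, bin_width=bin_width, max_lag=max_lag)
    model = fit_covariance(emp, family=family, fit_nugget=fit_nugget)
    logger.info("fitted %s covariance: sill=%.4g ‰², range=%.4g km, nugget=%.4g, adjR2=%.4f",
                model.family, model.sill, model.range_km, model.nugget, model.adj_r2)
    by_coord = {(o.lat, o.lon): o for o in obs}
    rows = []
    to_krige: list[tuple[int, tuple[float, float], str]] = []
    for idx, row in enumerate(stations.itertuples(index=False)):
        key = (float(row.lat), float(row.lon))
        if key in by_coord:
            rows.append({"station_id": row.station_id, "lat": key[0], "lon": key[1],
                         "d15N_baseline": by_coord[key].d15N, "krig_var": 0.0,
                         "source": "observed"})
        else:
            rows.append(None)
            to_krige.append((idx, key, str(row.station_id)))
    if to_krige:
        results = krige(obs, model, [k for _, k, _ in to_krige],
                        target_ids=[sid for _, _, sid in to_krige], dedupe=False)
        for (idx, key, sid), res in zip(to_krige, results):
            rows[idx] = {"station_id": sid, "lat": key[0], "lon": key[1],
                         "d15N_baseline": res.d15N_pred, "krig_var": res.krig_var,
                         "source": "kriged"}
    return pd.DataFrame(rows), model
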