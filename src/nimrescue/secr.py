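"""Maximum-likelihood spatially explicit capture–recapture (SECR) for proximity detectors.

Detection of an animal with activity center ``s`` at a detector located a
distance ``d`` away follows the half-normal form ``p(d) = g0 * exp(-d^2 / (2 sigma^2))``
per sampling occasion.  Activity centers are assumed to follow a homogeneous
Poisson process with intensity ``D`` over a discretized habitat mask, and the
full (Poisson-n) likelihood is maximized on transformed scales
(log D, logit g0, log sigma).  Sex enters as a known individual covariate on
``g0`` and/or ``sigma``; the sex proportion is then an additional (logit)
parameter, as in a hybrid mixture with known class membership.

Cameras and scat searches are both treated as binary proximity detectors; scat
detections are snapped to the centers of 1x1 km search grid cells before
fitting, mirroring how noninvasive scat surveys are commonly prepared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "CaptureData",
    "SecrFit",
    "AbundanceEstimate",
    "build_capthist",
    "make_mask",
    "snap_to_grid",
    "fit_secr",
    "aic_table",
    "extrapolate_abundance",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class CaptureData:
    """Capture histories for one survey session.

    Attributes
    ----------
    detectors : DataFrame with columns ``detector_id, x_km, y_km, kind``.
    detections : DataFrame with columns ``individual_id, sex, detector_id, occasion``
        (one row per binary detection; ``occasion`` is 0-based).
    n_occasions : number of sampling occasions.
    mask : DataFrame with columns ``x_km, y_km`` (habitat cell centers).
    cell_area_km2 : area of one mask cell.
    metadata : free-form dict (e.g. true generating parameters, warnings).
    """

    detectors: pd.DataFrame
    detections: pd.DataFrame
    n_occasions: int
    mask: pd.DataFrame | None = None
    cell_area_km2: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.detectors["detector_id"].duplicated().any():
            raise ValueError("duplicate detector ids")
        xy = self.detectors[["x_km", "y_km"]].to_numpy()
        if len(np.unique(xy, axis=0)) != len(xy):
            raise ValueError("detector coordinates must be unique")
        unknown = set(self.detections["detector_id"]) - set(self.detectors["detector_id"])
        if unknown:
            raise ValueError(f"detections reference unknown detectors: {sorted(unknown)}")

    @property
    def individuals(self) -> list:
        return sorted(self.detections["individual_id"].unique())

    @property
    def n_individuals(self) -> int:
        return self.detections["individual_id"].nunique()

    def count_matrix(self) -> tuple[np.ndarray, list, np.ndarray]:
        """Return (counts, individuals, sexes).

        ``counts[i, j]`` is the number of occasions individual ``i`` was
        detected at detector ``j`` (detector order = ``self.detectors`` order).
        """
        ids = self.individuals
        idx = {v: k for k, v in enumerate(ids)}
        didx = {v: k for k, v in enumerate(self.detectors["detector_id"])}
        counts = np.zeros((len(ids), len(self.detectors)), dtype=np.int64)
        for _, row in self.detections.iterrows():
            counts[idx[row["individual_id"]], didx[row["detector_id"]]] += 1
        sexes = np.array(
            [self.detections.loc[self.detections["individual_id"] == i, "sex"].iloc[0] for i in ids]
        )
        return counts, ids, sexes

    # -- plain-text round trip ---------------------------------------------
    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.detectors.to_csv(prefix.with_suffix(".detectors.csv"), index=False)
        det = self.detections.copy()
        det["n_occasions"] = self.n_occasions
        det.to_csv(prefix.with_suffix(".detections.csv"), index=False)
        if self.mask is not None:
            m = self.mask.copy()
            m["cell_area_km2"] = self.cell_area_km2
            m.to_csv(prefix.with_suffix(".mask.csv"), index=False)

    @classmethod
    def read(cls, prefix: str | Path) -> "CaptureData":
        prefix = Path(prefix)
        detectors = pd.read_csv(prefix.with_suffix(".detectors.csv"))
        det = pd.read_csv(prefix.with_suffix(".detections.csv"))
        n_occ = int(det["n_occasions"].iloc[0])
        det = det.drop(columns=["n_occasions"])
        mask = None
        area = None
        mask_path = prefix.with_suffix(".mask.csv")
        if mask_path.exists():
            m = pd.read_csv(mask_path)
            area = float(m["cell_area_km2"].iloc[0])
            mask = m[["x_km", "y_km"]]
        return cls(detectors=detectors, detections=det, n_occasions=n_occ,
                   mask=mask, cell_area_km2=area)


@dataclass
class SecrFit:
    """Result of a maximum-likelihood SECR fit."""

    model: str
    estimates: dict          # parameter -> point estimate (natural scale)
    se: dict                 # parameter -> standard error (natural scale)
    log_likelihood: float
    n_parameters: int
    aic: float
    esa_km2: float           # effective sampling area
    n_detected: int
    converged: bool
    hessian_ok: bool
    beta: np.ndarray = field(repr=False, default=None)
    cov_beta: np.ndarray | None = field(repr=False, default=None)
    data_tag: str = ""

    @property
    def density(self) -> float:
        """Density per 100 km^2."""
        return self.estimates["D"]

    def density_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Lognormal Wald interval for density per 100 km^2."""
        d, se = self.estimates["D"], self.se["D"]
        return lognormal_interval(d, se, alpha)


@dataclass
class AbundanceEstimate:
    n_hat: int
    n_point: float
    ci: tuple[float, float]
    density_per_100km2: float
    area_km2: float


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def snap_to_grid(x: np.ndarray, y: np.ndarray, grid_km: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Snap coordinates to the centers of a corner-anchored square grid.

    A point at (3.2, 7.9) with a 1-km grid falls in the cell [3,4)x[7,8) and is
    assigned the center (3.5, 7.5).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (np.floor(x / grid_km) + 0.5) * grid_km, (np.floor(y / grid_km) + 0.5) * grid_km


def make_mask(detectors: pd.DataFrame, buffer_km: float, spacing_km: float) -> tuple[pd.DataFrame, float]:
    """Build a habitat mask of square cells within ``buffer_km`` of any detector."""
    dx = detectors["x_km"].to_numpy()
    dy = detectors["y_km"].to_numpy()
    xs = np.arange(dx.min() - buffer_km, dx.max() + buffer_km + spacing_km, spacing_km)
    ys = np.arange(dy.min() - buffer_km, dy.max() + buffer_km + spacing_km, spacing_km)
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    d2 = (gx[:, None] - dx[None, :]) ** 2 + (gy[:, None] - dy[None, :]) ** 2
    keep = d2.min(axis=1) <= buffer_km ** 2
    mask = pd.DataFrame({"x_km": gx[keep], "y_km": gy[keep]})
    return mask, spacing_km ** 2


def _initial_sigma(capt: CaptureData) -> float:
    """Crude movement scale from between-detector recapture displacements."""
    counts, ids, _ = capt.count_matrix()
    xy = capt.detectors[["x_km", "y_km"]].to_numpy()
    disps = []
    for i in range(counts.shape[0]):
        used = np.flatnonzero(counts[i] > 0)
        if len(used) > 1:
            c = xy[used].mean(axis=0)
            disps.extend(np.sqrt(((xy[used] - c) ** 2).sum(axis=1)))
    if disps:
        s = float(np.sqrt(np.mean(np.square(disps))) * math.sqrt(2.0))
        return max(s, 0.5)
    # fall back to half the mean nearest-neighbour detector spacing
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.sqrt(d2.min(axis=1)).mean())


def build_capthist(
    detections: str | Path | pd.DataFrame,
    detectors: str | Path | pd.DataFrame,
    n_occasions: int | None = None,
    scat_grid_km: float = 1.0,
    buffer_km: float | None = None,
    mask_spacing_km: float | None = None,
) -> CaptureData:
    """Assemble a :class:`CaptureData` from detector and detection tables.

    Scat detectors (``kind == 'scat_grid'``) have their coordinates snapped to
    the centers of ``scat_grid_km`` cells.  If no mask is supplied the mask is
    auto-built with a buffer of ``4 * sigma_init`` around the detectors, where
    ``sigma_init`` comes from mean recapture displacement.
    """
    if not isinstance(detections, pd.DataFrame):
        detections = pd.read_csv(detections)
    if not isinstance(detectors, pd.DataFrame):
        detectors = pd.read_csv(detectors)
    detectors = detectors.copy()
    scat = detectors["kind"] == "scat_grid"
    if scat.any():
        sx, sy = snap_to_grid(detectors.loc[scat, "x_km"], detectors.loc[scat, "y_km"], scat_grid_km)
        detectors.loc[scat, "x_km"] = sx
        detectors.loc[scat, "y_km"] = sy
        # snapping may collapse several search points onto one cell center
        detectors = detectors.drop_duplicates(subset=["x_km", "y_km"]).reset_index(drop=True)
    if n_occasions is None:
        if "n_occasions" in detections.columns:
            n_occasions = int(detections["n_occasions"].iloc[0])
        else:
            n_occasions = int(detections["occasion"].max()) + 1
    capt = CaptureData(
        detectors=detectors,
        detections=detections[["individual_id", "sex", "detector_id", "occasion"]].copy(),
        n_occasions=n_occasions,
    )
    if buffer_km is None:
        buffer_km = 4.0 * _initial_sigma(capt)
    if mask_spacing_km is None:
        mask_spacing_km = buffer_km / 8.0
    capt.mask, capt.cell_area_km2 = make_mask(detectors, buffer_km, mask_spacing_km)
    return capt


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _parse_model(model: str | dict) -> tuple[bool, bool]:
    """Return (g0 sex-specific, sigma sex-specific)."""
    if isinstance(model, str):
        parts = dict(
            p.split("~") for p in model.replace(" ", "").split(",") if "~" in p
        )
    else:
        parts = {k: str(v).replace("~", "") for k, v in model.items()}
    g0_sex = parts.get("g0", "1").lstrip("~") == "sex"
    sig_sex = parts.get("sigma", "1").lstrip("~") == "sex"
    return g0_sex, sig_sex


class _SessionData:
    """Pre-computed arrays for one session's likelihood."""

    def __init__(self, capt: CaptureData):
        if capt.mask is None:
            raise ValueError("CaptureData has no habitat mask; use build_capthist")
        counts, ids, sexes = capt.count_matrix()
        if counts.shape[0] == 0:
            raise ValueError("no detected individuals")
        self.counts = counts.astype(float)
        self.sex_class = (np.asarray(sexes) == "F").astype(int)  # 0 = M, 1 = F
        self.K = capt.n_occasions
        det_xy = capt.detectors[["x_km", "y_km"]].to_numpy()
        mask_xy = capt.mask[["x_km", "y_km"]].to_numpy()
        self.d2 = ((mask_xy[:, None, :] - det_xy[None, :, :]) ** 2).sum(-1)  # cells x det
        self.cell_area = capt.cell_area_km2
        self.n = counts.shape[0]

    def class_terms(self, g0: float, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (log integral of Pr(omega_i | x) per individual, p-dot per cell)."""
        p = g0 * np.exp(-self.d2 / (2.0 * sigma ** 2))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        logp = np.log(p)
        log1mp = np.log1p(-p)
        # cells x individuals: sum_j  n_ij log p_j(x) + (K - n_ij) log(1 - p_j(x))
        log_pr = logp @ self.counts.T + log1mp @ (self.K - self.counts).T
        log_int = logsumexp(log_pr, axis=0) + math.log(self.cell_area)
        pdot = -np.expm1(self.K * log1mp.sum(axis=1))
        return log_int, pdot


def _neg_log_lik(beta: np.ndarray, sessions: list[_SessionData], g0_sex: bool, sig_sex: bool,
                 use_psi: bool) -> float:
    i = 0
    logD = beta[i]; i += 1
    D = math.exp(logD) / 100.0  # animals per km^2 (D parameterized per 100 km^2)
    g0 = 1.0 / (1.0 + math.exp(-beta[i])); i += 1
    g0b = 1.0 / (1.0 + math.exp(-beta[i])) if g0_sex else g0
    i += 1 if g0_sex else 0
    sigma = math.exp(beta[i]); i += 1
    sigmab = math.exp(beta[i]) if sig_sex else sigma
    i += 1 if sig_sex else 0
    psi = 1.0 / (1.0 + math.exp(-beta[i])) if use_psi else 0.5

    ll = 0.0
    for sd in sessions:
        if use_psi:
            li_m, pdot_m = sd.class_terms(g0, sigma)       # class 0 = M
            li_f, pdot_f = sd.class_terms(g0b, sigmab)     # class 1 = F
            lam = D * sd.cell_area * ((1 - psi) * pdot_m.sum() + psi * pdot_f.sum())
            cls = sd.sex_class
            log_int = np.where(cls == 1, li_f + math.log(psi), li_m + math.log(1 - psi))
        else:
            li, pdot = sd.class_terms(g0, sigma)
            lam = D * sd.cell_area * pdot.sum()
            log_int = li
        if lam <= 0 or not np.isfinite(lam):
            return 1e10
        ll += -lam + sd.n * math.log(D) + log_int.sum() - math.lgamma(sd.n + 1)
    if not np.isfinite(ll):
        return 1e10
    return -ll


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            ea = np.zeros(n); ea[a] = eps
            eb = np.zeros(n); eb[b] = eps
            H[a, b] = H[b, a] = (
                f(x + ea + eb) - f(x + ea - eb) - f(x - ea + eb) + f(x - ea - eb)
            ) / (4 * eps * eps)
    return H


def fit_secr(
    capt: CaptureData | list[CaptureData],
    model: str | dict = "g0~1, sigma~1",
    n_starts: int = 3,
    seed: int = 0,
) -> SecrFit:
    """Fit the half-normal proximity SECR model by maximum likelihood.

    ``capt`` may be a list of sessions; parameters are then shared and the
    log-likelihoods summed (multi-session fit).  ``model`` selects whether
    ``g0`` and/or ``sigma`` are sex-specific, e.g. ``"g0~sex, sigma~1"``.
    """
    capts = capt if isinstance(capt, list) else [capt]
    g0_sex, sig_sex = _parse_model(model)
    use_psi = g0_sex or sig_sex
    sessions = [_SessionData(c) for c in capts]
    if use_psi:
        for c, sd in zip(capts, sessions):
            if c.detections["sex"].isna().any():
                raise ValueError("sex must be known for all individuals in sex models")

    # starting values
    sig0 = float(np.mean([_initial_sigma(c) for c in capts]))
    hull_area = sum(
        (c.detectors["x_km"].max() - c.detectors["x_km"].min() + 2 * sig0)
        * (c.detectors["y_km"].max() - c.detectors["y_km"].min() + 2 * sig0)
        for c in capts
    )
    n_tot = sum(sd.n for sd in sessions)
    d0 = max(n_tot / hull_area * 100.0, 0.05)  # per 100 km^2
    base = [math.log(d0), math.log(0.05 / 0.95)]
    if g0_sex:
        base.append(math.log(0.05 / 0.95))
    base.append(math.log(sig0))
    if sig_sex:
        base.append(math.log(sig0))
    if use_psi:
        base.append(0.0)
    base = np.array(base)

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        x0 = base if k == 0 else base + rng.normal(0, 0.3, size=base.size)
        res = minimize(
            _neg_log_lik, x0, args=(sessions, g0_sex, sig_sex, use_psi),
            method="L-BFGS-B",
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    beta = best.x

    # covariance via inverse numerical Hessian of the negative log-likelihood
    H = _numerical_hessian(lambda b: _neg_log_lik(b, sessions, g0_sex, sig_sex, use_psi), beta)
    hess_ok = True
    try:
        cov = np.linalg.inv(H)
        if not np.all(np.diag(cov) > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.full((len(beta), len(beta)), np.nan)
        hess_ok = False

    # back-transform
    names, trans = ["D"], ["log"]
    names.append("g0.M" if g0_sex else "g0"); trans.append("logit")
    if g0_sex:
        names.append("g0.F"); trans.append("logit")
    names.append("sigma.M" if sig_sex else "sigma"); trans.append("log")
    if sig_sex:
        names.append("sigma.F"); trans.append("log")
    if use_psi:
        names.append("psi.F"); trans.append("logit")

    est, se = {}, {}
    for i, (nm, tr) in enumerate(zip(names, trans)):
        b, sb = beta[i], math.sqrt(cov[i, i]) if hess_ok else float("nan")
        if tr == "log":
            est[nm] = math.exp(b)
            se[nm] = est[nm] * sb
        else:
            est[nm] = 1.0 / (1.0 + math.exp(-b))
            se[nm] = est[nm] * (1 - est[nm]) * sb

    # effective sampling area at the MLE (mixture-weighted, summed over sessions)
    D_hat = est["D"] / 100.0
    esa = 0.0
    for sd in sessions:
        if use_psi:
            _, pm = sd.class_terms(est.get("g0.M", est.get("g0")), est.get("sigma.M", est.get("sigma")))
            _, pf = sd.class_terms(est.get("g0.F", est.get("g0")), est.get("sigma.F", est.get("sigma")))
            psi = est["psi.F"]
            esa += sd.cell_area * ((1 - psi) * pm.sum() + psi * pf.sum())
        else:
            _, pd_ = sd.class_terms(est["g0"], est["sigma"])
            esa += sd.cell_area * pd_.sum()

    ll = -best.fun
    k = len(beta)
    label = model if isinstance(model, str) else ",".join(f"{a}~{b}" for a, b in model.items())
    return SecrFit(
        model=label, estimates=est, se=se, log_likelihood=ll, n_parameters=k,
        aic=2 * k - 2 * ll, esa_km2=esa, n_detected=n_tot,
        converged=bool(best.success), hessian_ok=hess_ok, beta=beta, cov_beta=cov,
        data_tag=str(id(capts[0])),
    )


def aic_table(fits: list[SecrFit]) -> pd.DataFrame:
    """Rank fits by AIC, with delta-AIC and Akaike weights (sum to 1)."""
    if len({f.data_tag for f in fits}) > 1:
        raise ValueError("fits were made on different datasets")
    df = pd.DataFrame(
        {
            "model": [f.model for f in fits],
            "logLik": [f.log_likelihood for f in fits],
            "k": [f.n_parameters for f in fits],
            "AIC": [f.aic for f in fits],
        }
    ).sort_values("AIC", kind="stable").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    w = np.exp(-0.5 * df["dAIC"].to_numpy())
    df["weight"] = w / w.sum()
    return df


def lognormal_interval(d: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    """Lognormal Wald interval for a positive estimate (standard SECR practice)."""
    from scipy.stats import norm

    if d <= 0:
        raise ValueError("estimate must be positive")
    z = norm.ppf(1 - alpha / 2)
    c = math.exp(z * math.sqrt(math.log(1.0 + (se / d) ** 2)))
    return d / c, d * c


def extrapolate_abundance(density_per_100km2: float, area_km2: float,
                          se: float | None = None, alpha: float = 0.05) -> AbundanceEstimate:
    """Extrapolate a density estimate (per 100 km^2) to abundance over ``area_km2``.

    The point estimate is ``D * area / 100`` rounded to the nearest integer for
    reporting; the interval is a lognormal interval on D scaled by area.
    """
    if density_per_100km2 <= 0 or area_km2 <= 0:
        raise ValueError("density and area must be positive")
    n_point = density_per_100km2 * area_km2 / 100.0
    if se is not None and se > 0:
        lo, hi = lognormal_interval(density_per_100km2, se, alpha)
        ci = (lo * area_km2 / 100.0, hi * area_km2 / 100.0)
    else:
        ci = (n_point, n_point)
    return AbundanceEstimate(
        n_hat=int(round(n_point)), n_point=n_point, ci=ci,
        density_per_100km2=density_per_100km2, area_km2=area_km2,
    )
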