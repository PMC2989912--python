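"""Spatial point-process machinery: kernel intensity surfaces, Poisson
process fitting, bandwidth selection, thinning simulation and envelope
goodness-of-fit diagnostics.

The workflow mirrors standard point-pattern practice: a homogeneous Poisson
process is the null model (MLE: lambda = n / |A|); when it fails, the
intensity is modeled log-linearly in a spatial covariate,

    log lambda(s) = alpha + beta * Z(s),

with Z a Gaussian-kernel-smoothed density of (detected) conspecifics.  The
process likelihood  sum_i log lambda(s_i) - int_A lambda(s) ds  is maximized
by Berman-Turner quadrature expressed as a weighted Poisson GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import ndimage

from .io import PointPattern
from .window import SpatialWindow

__all__ = [
    "DensitySurface",
    "PoissonProcessResults",
    "HomogeneousPoissonProcess",
    "InhomogeneousPoissonProcess",
    "kernel_density_surface",
    "fit_homogeneous_poisson",
    "fit_inhomogeneous_poisson",
    "optimize_sigma",
    "simulate_poisson",
    "gof_envelope",
    "EnvelopeDiagnostic",
]


# ---------------------------------------------------------------------------
# Density surfaces
# ---------------------------------------------------------------------------

@dataclass
class DensitySurface:
    """Gridded intensity (trees/m^2) on a regular raster masked to a window.

    ``values[iy, ix]`` is the intensity at the center of the cell whose
    lower-left corner is ``(x0 + ix*cell, y0 + iy*cell)``.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray          # (ny, nx)
    mask: np.ndarray            # True inside the window
    window: Optional[SpatialWindow] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a shape")
        if np.any(self.values[self.mask] < 0):
            raise ValueError("intensity values must be >= 0")

    @property
    def shape(self):
        return self.values.shape

    def cell_centers(self):
        ny, nx = self.values.shape
        cx = self.x0 + (np.arange(nx) + 0.5) * self.cell
        cy = self.y0 + (np.arange(ny) + 0.5) * self.cell
        return cx, cy

    def integral(self) -> float:
        """Integral of the intensity over the masked window, in trees."""
        return float(self.values[self.mask].sum() * self.cell**2)

    def _bilinear(self, x, y):
        """Cell indices and fractional weights for bilinear interpolation
        (lower-left cell convention on edges)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        gx = (x - self.x0) / self.cell - 0.5
        gy = (y - self.y0) / self.cell - 0.5
        ny, nx = self.values.shape
        ix = np.clip(np.floor(gx).astype(int), 0, nx - 2) if nx > 1 else np.zeros(x.shape, int)
        iy = np.clip(np.floor(gy).astype(int), 0, ny - 2) if ny > 1 else np.zeros(y.shape, int)
        fx = np.clip(gx - ix, 0.0, 1.0) if nx > 1 else np.zeros(x.shape)
        fy = np.clip(gy - iy, 0.0, 1.0) if ny > 1 else np.zeros(y.shape)
        ix1 = np.minimum(ix + 1, nx - 1)
        iy1 = np.minimum(iy + 1, ny - 1)
        return iy, ix, iy1, ix1, fx, fy

    def interpolate(self, x, y) -> np.ndarray:
        """Bilinear interpolation between cell centers; constant extrapolation
        at the raster border."""
        iy, ix, iy1, ix1, fx, fy = self._bilinear(x, y)
        v = self.values
        return ((1 - fx) * (1 - fy) * v[iy, ix] + fx * (1 - fy) * v[iy, ix1]
                + (1 - fx) * fy * v[iy1, ix] + fx * fy * v[iy1, ix1])

    # -- ESRI ASCII grid -------------------------------------------------
    def to_ascii_grid(self, path, nodata: float = -9999.0) -> None:
        ny, nx = self.values.shape
        out = np.where(self.mask, self.values, nodata)
        header = (f"ncols {nx}\nnrows {ny}\nxllcorner {self.x0}\nyllcorner {self.y0}\n"
                  f"cellsize {self.cell}\nNODATA_value {nodata}\n")
        with open(path, "w") as fh:
            fh.write(header)
            for row in out[::-1]:       # ASCII grids run north to south
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_ascii_grid(cls, path, window: Optional[SpatialWindow] = None) -> "DensitySurface":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].lower() in {"ncols", "nrows", "xllcorner", "yllcorner",
                                        "cellsize", "nodata_value"}:
                    meta[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(p) for p in parts])
        values = np.asarray(rows)[::-1]
        nodata = meta.get("nodata_value", -9999.0)
        mask = values != nodata
        values = np.where(mask, values, 0.0)
        return cls(meta["xllcorner"], meta["yllcorner"], meta["cellsize"], values, mask, window)


def _grid_for_window(window: SpatialWindow, cell: float):
    xmin, ymin, xmax, ymax = window.bounds
    nx = max(int(np.ceil((xmax - xmin) / cell)), 1)
    ny = max(int(np.ceil((ymax - ymin) / cell)), 1)
    cx = xmin + (np.arange(nx) + 0.5) * cell
    cy = ymin + (np.arange(ny) + 0.5) * cell
    XX, YY = np.meshgrid(cx, cy)
    mask = window.contains(XX.ravel(), YY.ravel()).reshape(ny, nx)
    return xmin, ymin, nx, ny, cx, cy, mask


def _kernel_matrix(px, py, x, y, sigma: float) -> np.ndarray:
    """(n_points, n_eval) matrix of bivariate Gaussian kernel values."""
    px = np.asarray(px, float)[:, None]
    py = np.asarray(py, float)[:, None]
    x = np.atleast_1d(np.asarray(x, float))[None, :]
    y = np.atleast_1d(np.asarray(y, float))[None, :]
    d2 = (px - x) ** 2 + (py - y) ** 2
    return np.exp(-d2 / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)


def kernel_density_at(px, py, x, y, sigma: float, weights=None) -> np.ndarray:
    """Exact Gaussian kernel intensity of points (px, py) evaluated at (x, y):
    sum_k w_k (2 pi sigma^2)^-1 exp(-d^2 / 2 sigma^2)."""
    w = np.ones(np.asarray(px).size) if weights is None else np.asarray(weights, float)
    return w @ _kernel_matrix(px, py, x, y, sigma)


def kernel_density_surface(
    pattern: PointPattern,
    sigma: float,
    weights=None,
    cell: float = 25.0,
    edge_correct: bool = True,
    window: Optional[SpatialWindow] = None,
) -> DensitySurface:
    """Isotropic Gaussian kernel intensity estimate on a raster.

    Each point contributes a bivariate normal bump of total mass ``w_k``
    (default 1); with ``edge_correct`` the bump is renormalized by the kernel
    mass falling inside the window, so the surface integral over the window
    recovers the total weight.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    win = window or pattern.window
    x0, y0, nx, ny, cx, cy, mask = _grid_for_window(win, cell)
    n = pattern.n
    if n == 0:
        warnings.warn("empty point pattern: kernel surface is identically zero")
        return DensitySurface(x0, y0, cell, np.zeros((ny, nx)), mask, win)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be > 0")
    if edge_correct:
        # mass of each point's kernel inside the window, by quadrature on the grid
        XX, YY = np.meshgrid(cx, cy)
        K = _kernel_matrix(pattern.x, pattern.y,
                           XX.ravel()[mask.ravel()], YY.ravel()[mask.ravel()], sigma)
        mass = K.sum(axis=1) * cell**2
        w = w / np.clip(mass, 1e-12, None)
    XX, YY = np.meshgrid(cx, cy)
    vals = kernel_density_at(pattern.x, pattern.y, XX.ravel(), YY.ravel(), sigma, w)
    return DensitySurface(x0, y0, cell, vals.reshape(ny, nx), mask, win)


# ---------------------------------------------------------------------------
# Poisson process fits
# ---------------------------------------------------------------------------

@dataclass
class PoissonProcessResults:
    """Fitted Poisson point-process model."""

    kind: str                           # "homogeneous" | "inhomogeneous"
    lambda_hat: Optional[float] = None  # trees/m^2 (homogeneous)
    alpha: Optional[float] = None       # log-intensity intercept
    beta: Optional[float] = None        # log-intensity per covariate unit
    beta_se: Optional[float] = None
    alpha_se: Optional[float] = None
    loglik: float = np.nan
    covariate: Optional[DensitySurface] = None
    window: Optional[SpatialWindow] = None
    n_points: int = 0
    link: str = "log"
    quad_weights: Optional[np.ndarray] = field(default=None, repr=False)
    quad_z: Optional[np.ndarray] = field(default=None, repr=False)

    def intensity_surface(self) -> DensitySurface:
        """Fitted intensity on the covariate grid (or the window grid)."""
        if self.kind == "homogeneous":
            if self.covariate is not None:
                cov = self.covariate
                vals = np.full(cov.shape, self.lambda_hat)
                return DensitySurface(cov.x0, cov.y0, cov.cell, vals, cov.mask, cov.window)
            x0, y0, nx, ny, cx, cy, mask = _grid_for_window(self.window, 25.0)
            return DensitySurface(x0, y0, 25.0, np.full((ny, nx), self.lambda_hat),
                                  mask, self.window)
        cov = self.covariate
        if self.link == "log":
            vals = np.exp(self.alpha + self.beta * cov.values)
        else:  # proportional: lambda = beta * Z
            vals = np.clip(self.beta * cov.values, 0.0, None)
        return DensitySurface(cov.x0, cov.y0, cov.cell, vals, cov.mask, cov.window)

    def expected_count(self) -> float:
        """Expected number of points under the fit; for the inhomogeneous
        model the Berman-Turner quadrature rule itself is used, so the score
        identity (= observed n) holds to GLM convergence tolerance."""
        if self.kind == "inhomogeneous" and self.quad_weights is not None:
            lam = np.exp(self.alpha + self.beta * self.quad_z)
            return float(self.quad_weights @ lam)
        if self.kind == "homogeneous":
            return self.lambda_hat * self.window.area
        return self.intensity_surface().integral()

    def summary(self) -> str:
        if self.kind == "homogeneous":
            return (f"Homogeneous Poisson process: lambda = {self.lambda_hat:.6g} /m^2 "
                    f"(n = {self.n_points}), logLik = {self.loglik:.2f}")
        return (f"Inhomogeneous Poisson process (log link): alpha = {self.alpha:.4f} "
                f"(SE {self.alpha_se:.4f}), beta = {self.beta:.4f} (SE {self.beta_se:.4f}), "
                f"n = {self.n_points}, logLik = {self.loglik:.2f}")


class HomogeneousPoissonProcess:
    """Complete spatial randomness; MLE of the intensity is n / |A|."""

    def __init__(self, pattern: PointPattern):
        self.pattern = pattern

    def fit(self) -> PoissonProcessResults:
        pat = self.pattern
        area = pat.window.area
        lam = pat.n / area
        if pat.n == 0:
            warnings.warn("empty pattern: lambda_hat = 0")
            ll = -0.0
        else:
            ll = pat.n * np.log(lam) - lam * area
        return PoissonProcessResults(kind="homogeneous", lambda_hat=lam, loglik=float(ll),
                                     window=pat.window, n_points=pat.n)


class InhomogeneousPoissonProcess:
    """log lambda(s) = alpha + beta Z(s), fit by Berman-Turner quadrature.

    Quadrature nodes are the data points plus the masked covariate grid
    centers; each node carries the weight  w = A_cell / m_cell  where m_cell
    counts the nodes sharing its cell.  The weighted Poisson GLM score
    equations then reproduce the process likelihood equations, so at the MLE
    the expected count equals the observed count (score identity).
    """

    def __init__(self, pattern: PointPattern, covariate: DensitySurface, link: str = "log"):
        if link not in {"log", "proportional"}:
            raise ValueError("link must be 'log' or 'proportional'")
        self.pattern = pattern
        self.covariate = covariate
        self.link = link

    def _quadrature(self, z_data=None):
        pat, cov = self.pattern, self.covariate
        cx, cy = cov.cell_centers()
        XX, YY = np.meshgrid(cx, cy)
        qx = XX.ravel()[cov.mask.ravel()]
        qy = YY.ravel()[cov.mask.ravel()]
        x = np.concatenate([pat.x, qx])
        y = np.concatenate([pat.y, qy])
        is_data = np.zeros(x.size)
        is_data[:pat.n] = 1.0
        # count nodes per cell for Berman-Turner weights
        ix = np.floor((x - cov.x0) / cov.cell).astype(int)
        iy = np.floor((y - cov.y0) / cov.cell).astype(int)
        ny, nx = cov.shape
        ix = np.clip(ix, 0, nx - 1)
        iy = np.clip(iy, 0, ny - 1)
        flat = iy * nx + ix
        counts = np.bincount(flat, minlength=nx * ny)
        wts = cov.cell**2 / counts[flat]
        z = cov.interpolate(x, y)
        if z_data is not None:          # override covariate at the data points
            z[:pat.n] = z_data
        return x, y, is_data, wts, z

    def fit(self, z_data=None) -> PoissonProcessResults:
        pat, cov = self.pattern, self.covariate
        _, _, is_data, wts, z = self._quadrature(z_data)
        zmask = z[pat.n:]
        if np.ptp(zmask) < 1e-12 * max(1.0, np.abs(zmask).max()):
            warnings.warn("covariate is constant: beta unidentifiable; "
                          "falling back to the homogeneous model")
            res = HomogeneousPoissonProcess(pat).fit()
            res.covariate = cov
            return res
        X = sm.add_constant(z)
        offset = np.log(wts)
        glm = sm.GLM(is_data, X, family=sm.families.Poisson(), offset=offset).fit()
        alpha, beta = float(glm.params[0]), float(glm.params[1])
        lam_data = np.exp(alpha + beta * z[: pat.n])
        lam_grid = np.exp(alpha + beta * zmask)
        ll = float(np.sum(np.log(lam_data)) - np.sum(lam_grid * cov.cell**2)) if pat.n else np.nan
        return PoissonProcessResults(
            kind="inhomogeneous", alpha=alpha, beta=beta,
            alpha_se=float(glm.bse[0]), beta_se=float(glm.bse[1]),
            loglik=ll, covariate=cov, window=pat.window, n_points=pat.n, link=self.link,
            quad_weights=wts, quad_z=z,
        )


def fit_homogeneous_poisson(pattern: PointPattern) -> PoissonProcessResults:
    return HomogeneousPoissonProcess(pattern).fit()


def fit_inhomogeneous_poisson(pattern: PointPattern, covariate: DensitySurface) -> PoissonProcessResults:
    return InhomogeneousPoissonProcess(pattern, covariate).fit()


# ---------------------------------------------------------------------------
# Bandwidth selection
# ---------------------------------------------------------------------------

def optimize_sigma(
    pattern: PointPattern,
    detected: PointPattern,
    sigma_grid,
    weights=None,
    cell: float = 25.0,
    loo_tol: float = 1e-9,
):
    """Choose the kernel bandwidth by cross-validated process log-likelihood.

    For each sigma the covariate surface is built from *detected* (unweighted
    edge handling: only relative intensity matters for the fit); its value at
    each data point is the bilinear grid interpolation, with the (also
    interpolated) contribution of any detected point closer than ``loo_tol``
    — i.e. the point itself — subtracted.  The leave-one-out correction is
    what removes the degenerate sigma -> 0 optimum when the fitted pattern
    contains the detected points.  Returns the criterion-minimizing sigma and
    the full (sigma, criterion) profile, criterion = negative cross-validated
    log-likelihood.
    """
    sigma_grid = list(sigma_grid)
    if not sigma_grid:
        raise ValueError("sigma_grid must be nonempty")
    w_det = np.ones(detected.n) if weights is None else np.asarray(weights, float)
    profile = []
    best = (np.inf, None)
    for sigma in sigma_grid:
        surf = kernel_density_surface(detected, sigma, weights=weights, cell=cell,
                                      edge_correct=False, window=pattern.window)
        z = surf.interpolate(pattern.x, pattern.y)
        # leave-one-out: subtract each coincident detected point's own
        # (grid-interpolated, hence consistent) kernel contribution
        iy, ix, iy1, ix1, fx, fy = surf._bilinear(pattern.x, pattern.y)
        cx, cy = surf.cell_centers()
        for i in range(pattern.n):
            d2 = (detected.x - pattern.x[i]) ** 2 + (detected.y - pattern.y[i]) ** 2
            hit = np.nonzero(d2 < loo_tol**2)[0]
            if hit.size == 0:
                continue
            corners_x = np.array([cx[ix[i]], cx[ix1[i]], cx[ix[i]], cx[ix1[i]]])
            corners_y = np.array([cy[iy[i]], cy[iy[i]], cy[iy1[i]], cy[iy1[i]]])
            K = _kernel_matrix(detected.x[hit], detected.y[hit], corners_x, corners_y,
                               sigma)
            contrib = w_det[hit] @ K
            bw = np.array([(1 - fx[i]) * (1 - fy[i]), fx[i] * (1 - fy[i]),
                           (1 - fx[i]) * fy[i], fx[i] * fy[i]])
            z[i] -= float(contrib @ bw)
        z = np.clip(z, 0.0, None)
        fit = InhomogeneousPoissonProcess(pattern, surf).fit(z_data=z)
        crit = -fit.loglik if np.isfinite(fit.loglik) else np.inf
        profile.append((float(sigma), float(crit)))
        if crit < best[0]:
            best = (crit, float(sigma))
    if best[1] is None:
        raise RuntimeError("criterion non-finite at every sigma in the grid")
    return best[1], profile


# ---------------------------------------------------------------------------
# Simulation by thinning
# ---------------------------------------------------------------------------

def simulate_poisson(intensity, window: SpatialWindow, rng: np.random.Generator) -> PointPattern:
    """Simulate a Poisson process by rejection thinning.

    *intensity* may be a constant (trees/m^2) or a :class:`DensitySurface`.
    Points are proposed homogeneously at the maximal rate over the window's
    bounding box and retained with probability lambda(s)/lambda_max (zero
    outside the window), giving counts ~ Poisson(integral of lambda).
    """
    xmin, ymin, xmax, ymax = window.bounds
    bbox_area = (xmax - xmin) * (ymax - ymin)
    if np.isscalar(intensity):
        lam_max = float(intensity)
        lam_fun = None
    else:
        lam_max = float(intensity.values[intensity.mask].max()) if intensity.mask.any() else 0.0
        lam_fun = intensity.interpolate
    if lam_max < 0 or not np.isfinite(lam_max):
        raise ValueError("intensity must be finite and >= 0")
    if lam_max == 0:
        return PointPattern(np.empty(0), np.empty(0), window)
    n_prop = rng.poisson(lam_max * bbox_area)
    if n_prop == 0:
        return PointPattern(np.empty(0), np.empty(0), window)
    px = rng.uniform(xmin, xmax, n_prop)
    py = rng.uniform(ymin, ymax, n_prop)
    keep = window.contains(px, py)
    if lam_fun is not None:
        p = np.clip(lam_fun(px, py) / lam_max, 0.0, 1.0)
        keep &= rng.uniform(size=n_prop) < p
    elif not np.isscalar(intensity):
        pass
    return PointPattern(px[keep], py[keep], window)


# ---------------------------------------------------------------------------
# Envelope goodness-of-fit
# ---------------------------------------------------------------------------

@dataclass
class EnvelopeDiagnostic:
    """qq-plot envelope of smoothed residual-field quantiles."""

    observed: np.ndarray        # sorted observed smoothed-residual values
    mean_sim: np.ndarray        # mean of the sorted simulated curves
    lower: np.ndarray           # simultaneous 95% band, lower limit
    upper: np.ndarray           # simultaneous 95% band, upper limit
    n_sim: int
    inside: bool
    probs: np.ndarray = field(default=None)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"prob": self.probs, "observed": self.observed,
                             "mean_sim": self.mean_sim, "lower": self.lower,
                             "upper": self.upper})

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.mean_sim, self.observed, "k-", label="observed")
        ax.plot(self.mean_sim, self.mean_sim, "b:", label="mean simulated")
        ax.plot(self.mean_sim, self.lower, "r--", label="95% envelope")
        ax.plot(self.mean_sim, self.upper, "r--")
        ax.set_xlabel("mean simulated quantile")
        ax.set_ylabel("data quantile")
        ax.legend()
        return ax


def _residual_quantiles(pattern: PointPattern, fitted: DensitySurface, smooth_sigma: float,
                        probs: np.ndarray) -> np.ndarray:
    """Quantiles of the smoothed raw residual field (observed kernel intensity
    minus smoothed fitted intensity) over the masked grid."""
    cell = fitted.cell
    cx, cy = fitted.cell_centers()
    ny, nx = fitted.shape
    # binned observed counts -> gaussian smoothing (grid units)
    counts = np.zeros((ny, nx))
    if pattern.n:
        ix = np.clip(np.floor((pattern.x - fitted.x0) / cell).astype(int), 0, nx - 1)
        iy = np.clip(np.floor((pattern.y - fitted.y0) / cell).astype(int), 0, ny - 1)
        np.add.at(counts, (iy, ix), 1.0)
    obs_int = counts / cell**2
    s = smooth_sigma / cell
    m = fitted.mask.astype(float)
    sm_obs = ndimage.gaussian_filter(obs_int * m, s, mode="constant")
    sm_fit = ndimage.gaussian_filter(fitted.values * m, s, mode="constant")
    norm = ndimage.gaussian_filter(m, s, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = np.where(norm > 1e-10, (sm_obs - sm_fit) / norm, 0.0)
    vals = resid[fitted.mask]
    return np.quantile(vals, probs)


def gof_envelope(
    fit: PoissonProcessResults,
    pattern: PointPattern,
    n_sim: int = 100,
    rng: Optional[np.random.Generator] = None,
    smooth_sigma: Optional[float] = None,
    n_quantiles: int = 50,
) -> EnvelopeDiagnostic:
    """Simulation envelope for the qq-plot of smoothed residuals.

    The observed pattern's sorted smoothed-residual field values are compared
    quantile-by-quantile with the mean curve of ``n_sim`` patterns simulated
    from the fitted model, inside a simultaneous 95% critical band (the
    scaled-deviation global envelope, calibrated on the simulated curves
    themselves so that whole-curve coverage is nominal).  ``inside`` is true
    iff the observed curve lies within the band everywhere.
    """
    if n_sim < 20:
        raise ValueError("n_sim must be >= 20 for a meaningful envelope")
    rng = rng or np.random.default_rng()
    surf = fit.intensity_surface()
    if smooth_sigma is None:
        xmin, ymin, xmax, ymax = pattern.window.bounds
        smooth_sigma = 0.05 * max(xmax - xmin, ymax - ymin)
    probs = np.linspace(0.01, 0.99, n_quantiles)
    obs_q = _residual_quantiles(pattern, surf, smooth_sigma, probs)
    sims = np.empty((n_sim, n_quantiles))
    for k in range(n_sim):
        simpat = simulate_poisson(surf, pattern.window, rng)
        sims[k] = _residual_quantiles(simpat, surf, smooth_sigma, probs)
    mean_sim = sims.mean(axis=0)
    sd_sim = sims.std(axis=0, ddof=1)
    scale = np.where(sd_sim > 0, sd_sim, np.finfo(float).tiny)
    # simultaneous 95% band: critical multiple c from the max standardized
    # deviation of each simulated curve, so the whole-curve coverage is the
    # nominal 95% by exchangeability (not merely pointwise)
    t_sims = np.max(np.abs(sims - mean_sim) / scale, axis=1)
    t_obs = float(np.max(np.abs(obs_q - mean_sim) / scale))
    c = float(np.quantile(t_sims, 0.95, method="higher"))
    lower = mean_sim - c * sd_sim
    upper = mean_sim + c * sd_sim
    inside = bool(t_obs <= c)
    return EnvelopeDiagnostic(observed=obs_q, mean_sim=mean_sim, lower=lower,
                              upper=upper, n_sim=n_sim, inside=inside, probs=probs)
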