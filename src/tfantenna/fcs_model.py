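"""FCS autocorrelation model and global titration fitting for K_D.

The autocorrelation of a labeled protein titrated with unlabeled DNA is
modelled as the product G(t) = G_F(t) * G_T(t) * G_D(t):

- G_D: two-component 3D Gaussian-volume diffusion (free protein and
  protein-DNA complex), each component weighted by the squared product of
  brightness and species fraction, prefactor 1/<N>;
- G_T = 1 + (T/(1-T)) exp(-t/tau_T): fast triplet-state buildup;
- G_F = 1 + (Fr/(1-Fr)) exp(-t/tau_F): unbound-dye contribution.

Binding is two-state (each labeled molecule free or bound), so the free
fraction at DNA concentration c is P_prot = 1 / (1 + c / K_D).  A
titration series is fitted globally: one shared log10 K_D and shared
diffusion times, a local mean molecule number per decay.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)


def bound_fraction(dna_conc: float, kd: float) -> float:
    """Free-protein fraction P_prot = 1 / (1 + [DNA]/K_D)."""
    if kd <= 0:
        raise ValueError("K_D must be positive")
    if dna_conc < 0:
        raise ValueError("DNA concentration must be non-negative")
    return 1.0 / (1.0 + dna_conc / kd)


def diffusion_time(d_coefficient: float, omega_xy: float) -> float:
    """Mean diffusion time tau = omega_xy^2 / (4 D), in seconds.

    ``d_coefficient`` in um^2/s, ``omega_xy`` (lateral beam waist) in um.
    """
    if d_coefficient <= 0 or omega_xy <= 0:
        raise ValueError("diffusion coefficient and beam waist must be positive")
    return omega_xy**2 / (4.0 * d_coefficient)


@dataclass(frozen=True)
class FCSModelParams:
    """Parameters of the autocorrelation model.

    ``normalization='printed'`` uses the 1/<N> prefactor with
    brightness-squared component weights; ``'textbook'`` uses
    sum(eps_i^2 N_i) / (sum(eps_i N_i))^2.
    """

    n_mean: float = 1.0  # <N>, mean molecules in the confocal volume
    tau_prot: float = 1.28e-4  # s, free protein diffusion time
    tau_comp: float = 1.0e-3  # s, complex diffusion time
    aspect_ratio: float = 0.2  # omega_xy / omega_z
    brightness: float = 1.0  # eps * phi, a.u.
    p_prot: float = 1.0  # free-protein fraction
    triplet_fraction: float = 0.0  # T
    tau_triplet: float = 2e-6  # s
    free_dye_fraction: float = 0.0  # Fr
    tau_free_dye: float = 3e-5  # s
    normalization: str = "printed"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_prot <= 1.0):
            raise ValueError("p_prot must be in [0, 1]")
        for name in ("triplet_fraction", "free_dye_fraction"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        for name in ("n_mean", "tau_prot", "tau_comp", "tau_triplet", "tau_free_dye"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_prot > self.tau_comp:
            raise ValueError("complex must diffuse more slowly than free protein")
        if self.normalization not in ("printed", "textbook"):
            raise ValueError("normalization must be 'printed' or 'textbook'")

    def with_(self, **kwargs) -> "FCSModelParams":
        return replace(self, **kwargs)


@dataclass
class FCSDecay:
    """One autocorrelation decay at one DNA concentration."""

    lag: np.ndarray  # s, strictly increasing
    g: np.ndarray
    dna_conc: float  # mol/L
    replicate: str = "r1"

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lag.shape != self.g.shape:
            raise ValueError("lag and G grids must have equal length")
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("G values must be finite")


def _diffusion_component(t: np.ndarray, tau: float, aspect: float) -> np.ndarray:
    return (1.0 + t / tau) ** -1 * (1.0 + aspect**2 * t / tau) ** -0.5


def fcs_curve(t_grid: np.ndarray, params: FCSModelParams) -> np.ndarray:
    """Model autocorrelation G(t) on a lag grid."""
    t = np.asarray(t_grid, dtype=float)
    p = params
    eps = p.brightness
    w_free = (eps * p.p_prot) ** 2
    w_comp = (eps * (1.0 - p.p_prot)) ** 2
    g_free = _diffusion_component(t, p.tau_prot, p.aspect_ratio)
    g_comp = _diffusion_component(t, p.tau_comp, p.aspect_ratio)
    if p.normalization == "printed":
        g_d = (w_free * g_free + w_comp * g_comp) / p.n_mean
    else:
        n_free = p.n_mean * p.p_prot
        n_comp = p.n_mean * (1.0 - p.p_prot)
        num = eps**2 * (p.p_prot * g_free + (1.0 - p.p_prot) * g_comp) * p.n_mean
        den = (eps * (n_free + n_comp)) ** 2
        g_d = num / den
    a_t = p.triplet_fraction / (1.0 - p.triplet_fraction)
    g_t = 1.0 + a_t * np.exp(-t / p.tau_triplet)
    a_f = p.free_dye_fraction / (1.0 - p.free_dye_fraction)
    g_f = 1.0 + a_f * np.exp(-t / p.tau_free_dye)
    return g_f * g_t * g_d


def simulate_decay(
    params: FCSModelParams,
    t_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    dna_conc: float = 0.0,
    replicate: str = "r1",
) -> FCSDecay:
    """Model curve with multiplicative Gaussian noise, seeded."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    g = fcs_curve(t_grid, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g = g * (1.0 + rng.normal(0.0, noise_sd, size=g.shape))
    return FCSDecay(lag=np.asarray(t_grid, float), g=g, dna_conc=dna_conc,
                    replicate=replicate)


def default_lag_grid(n_points: int = 64, t_min: float = 1e-6, t_max: float = 1.0) -> np.ndarray:
    """Log-spaced lag grid typical of a hardware correlator."""
    return np.logspace(math.log10(t_min), math.log10(t_max), n_points)


def write_decay(decay: FCSDecay, path: str | Path) -> None:
    """Two-column whitespace file with '#' metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# dna_conc_M={decay.dna_conc:.6e}\n")
        fh.write(f"# replicate={decay.replicate}\n")
        fh.write("# lag_s\tG\n")
        for t, g in zip(decay.lag, decay.g):
            fh.write(f"{t:.8e}\t{g:.8e}\n")


def read_decay(path: str | Path) -> FCSDecay:
    meta = {}
    lag, g = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, val = body.split("=", 1)
                    meta[key.strip()] = val.strip()
                continue
            t_val, g_val = line.split()[:2]
            lag.append(float(t_val))
            g.append(float(g_val))
    return FCSDecay(
        lag=np.array(lag),
        g=np.array(g),
        dna_conc=float(meta.get("dna_conc_M", "nan")),
        replicate=meta.get("replicate", "r1"),
    )


@dataclass
class TitrationFit:
    """Result of a global fit of a titration series."""

    log10_kd: float
    interval95: float  # 2 sigma, log10 units
    kd: float
    n_mean_per_decay: list[float]
    rss: float
    converged: bool


def global_fit_titration(
    decays: list[FCSDecay],
    base_params: FCSModelParams,
    lag_floor: float = 1e-6,
    init_log10_kd: float | None = None,
) -> TitrationFit:
    """Fit one shared K_D (in log10) across a titration series.

    Diffusion times, aspect ratio, brightness, triplet and free-dye terms
    are taken from ``base_params`` and held fixed; the free parameters are
    the global log10 K_D and a local mean molecule number per decay.  Lags
    below ``lag_floor`` are excluded (after-pulsing region).  The 95%
    interval is two standard deviations from the covariance at the
    optimum.
    """
    if len(decays) < 3:
        raise ValueError("need at least 3 concentrations spanning the isotherm")
    concs = np.array([d.dna_conc for d in decays])
    if np.any(concs < 0) or np.all(concs == 0):
        raise ValueError("decays must carry DNA concentrations")

    grids = []
    targets = []
    for d in decays:
        keep = d.lag >= lag_floor
        grids.append(d.lag[keep])
        targets.append(d.g[keep])

    pos = concs[concs > 0]
    x0_kd = init_log10_kd if init_log10_kd is not None else float(
        np.log10(np.median(pos))
    )
    span = math.log10(pos.max() / pos.min()) if len(pos) > 1 else 0.0
    if span < 1.0:
        logger.warning(
            "titration spans %.2f decades; K_D may be ill-conditioned", span
        )
    x0 = np.concatenate([[x0_kd], np.full(len(decays), base_params.n_mean)])

    def residuals(x):
        log_kd = x[0]
        kd = 10.0**log_kd
        out = []
        for i, d in enumerate(decays):
            p = base_params.with_(
                p_prot=bound_fraction(d.dna_conc, kd), n_mean=max(x[1 + i], 1e-12)
            )
            out.append(fcs_curve(grids[i], p) - targets[i])
        return np.concatenate(out)

    lower = np.concatenate([[-15.0], np.full(len(decays), 1e-6)])
    upper = np.concatenate([[0.0], np.full(len(decays), 1e6)])
    sol = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
    if not sol.success:
        raise RuntimeError(f"global titration fit failed: {sol.message}")

    dof = sum(len(t) for t in targets) - len(x0)
    rss = float(sol.fun @ sol.fun)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / max(dof, 1)
        sigma_logkd = math.sqrt(max(cov[0, 0], 0.0))
    except np.linalg.LinAlgError:
        sigma_logkd = float("nan")
    return TitrationFit(
        log10_kd=float(sol.x[0]),
        interval95=2.0 * sigma_logkd,
        kd=10.0 ** float(sol.x[0]),
        n_mean_per_decay=[float(v) for v in sol.x[1:]],
        rss=rss,
        converged=bool(sol.success),
    )
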