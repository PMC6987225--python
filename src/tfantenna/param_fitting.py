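"""Global fitting of energy-model parameters to K_D titration tables.

Fits are performed in log10 K_D space (linear sampling of affinities
spanning decades).  The structure-based variant frees the four free
energies (consensus-core, degenerate-A/T, cooperative, electrostatic
prefactor); the PWM variant frees only the electrostatic prefactor.
Record uncertainties enter the loss as inverse-variance weights when
present.  Model variants are compared by a variance-ratio ("Fisher")
test, applied heuristically since the variants are not nested.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from tfantenna.binding_model import (
    EnergyModelParams,
    PWMMatrix,
    landscape,
    pwm_site_energy,
    site_feature_matrix,
)
from tfantenna.sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

STRUCTURE_PARAM_NAMES = ("dg_consensus_core", "dg_degenerate_at", "dg_cp", "dg_elec0")
PWM_PARAM_NAMES = ("dg_elec0",)
DG_BOUND = 50.0  # kJ/mol, |bound| on every fitted free energy


@dataclass(frozen=True)
class TitrationRecord:
    """One measured dissociation constant for one DNA construct."""

    construct_id: str
    seq_ref: str
    ionic_strength: float  # mol/L
    kd: float  # mol/L
    sigma_log10: float | None = None  # 95%-interval half-width in log10 units

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("K_D must be positive")
        if self.sigma_log10 is not None and self.sigma_log10 <= 0:
            raise ValueError("uncertainty must be positive")


@dataclass
class FitResult:
    """Outcome of a global least-squares fit in log10 K_D."""

    variant: str
    params: dict[str, float]
    param_sigmas: dict[str, float]
    rss: float  # residual sum of squares, log10 units (unweighted)
    dof: int
    predicted_kd: dict[str, float]
    record_ids: tuple[str, ...] = field(default_factory=tuple)
    converged: bool = True

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "variant": self.variant,
                    "params": self.params,
                    "param_sigmas": self.param_sigmas,
                    "rss_log10": self.rss,
                    "dof": self.dof,
                    "predicted_kd_M": self.predicted_kd,
                    "converged": self.converged,
                },
                fh,
                indent=2,
            )


def read_titration_table(path: str | Path) -> list[TitrationRecord]:
    """Read a TSV (construct_id, fasta_id, ionic_strength_M, kd_M, sigma_log10)."""
    table = pd.read_csv(path, sep="\t", comment="#",
                        names=["construct_id", "fasta_id", "ionic_strength_M",
                               "kd_M", "sigma_log10"],
                        header=0)
    records = []
    for row in table.itertuples(index=False):
        sigma = None if pd.isna(row.sigma_log10) else float(row.sigma_log10)
        records.append(
            TitrationRecord(
                construct_id=str(row.construct_id),
                seq_ref=str(row.fasta_id),
                ionic_strength=float(row.ionic_strength_M),
                kd=float(row.kd_M),
                sigma_log10=sigma,
            )
        )
    return records


def write_titration_table(records: list[TitrationRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#construct_id\tfasta_id\tionic_strength_M\tkd_M\tsigma_log10\n")
        fh.write("construct_id\tfasta_id\tionic_strength_M\tkd_M\tsigma_log10\n")
        for r in records:
            sig = "" if r.sigma_log10 is None else f"{r.sigma_log10:.6e}"
            fh.write(
                f"{r.construct_id}\t{r.seq_ref}\t{r.ionic_strength:.6e}\t"
                f"{r.kd:.6e}\t{sig}\n"
            )


def _predict_log10_kd_structure(
    theta: np.ndarray,
    features: list[np.ndarray],
    ionic: np.ndarray,
    base: EnergyModelParams,
) -> np.ndarray:
    """log10 K_D for every construct, linear-in-parameters fast path.

    ``theta = (dGc, dGd, dGcp, dGe0)``; the per-site energy is
    F @ (dGc, dGd, dGcp, dGe0 * exp(-sqrt(I))) with F the cached feature
    matrix, identical to the per-site path in ``landscape``.
    """
    rt = base.rt
    out = np.empty(len(features))
    for i, feats in enumerate(features):
        coef = np.array(
            [theta[0], theta[1], theta[2], theta[3] * math.exp(-math.sqrt(ionic[i]))]
        )
        energies = feats @ coef
        s = np.exp(-energies / rt).sum()
        out[i] = -math.log10(base.w0 * s)
    return out


def _predict_log10_kd_pwm(
    theta: np.ndarray,
    pwm_spec: list[np.ndarray],
    n_elec: list[np.ndarray],
    ionic: np.ndarray,
    base: EnergyModelParams,
) -> np.ndarray:
    rt = base.rt
    out = np.empty(len(pwm_spec))
    for i, spec in enumerate(pwm_spec):
        elec = n_elec[i] * theta[0] * math.exp(-math.sqrt(ionic[i]))
        s = np.exp(-(spec + elec) / rt).sum()
        out[i] = -math.log10(base.w0 * s)
    return out


def fit_energy_params(
    records: list[TitrationRecord],
    sequences: dict[str, SequenceRecord],
    variant: str = "structure",
    init: EnergyModelParams | None = None,
    pwm: PWMMatrix | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Globally fit the free energy parameters to a titration table.

    Least squares in log10 K_D with bounded quasi-Newton iterations
    (scipy ``least_squares`` with trf) and ``n_restarts`` seeded random
    multi-starts within +-50 kJ/mol.  Parameter 1-sigma errors come from
    the covariance at the optimum scaled by the reduced chi-square.
    """
    if variant not in ("structure", "pwm"):
        raise ValueError(f"unknown variant {variant!r}")
    init = init or EnergyModelParams()
    names = STRUCTURE_PARAM_NAMES if variant == "structure" else PWM_PARAM_NAMES
    n_free = len(names)
    if len(records) < n_free + 1:
        raise ValueError(
            f"under-determined: {len(records)} records for {n_free} free parameters"
        )
    if variant == "pwm" and pwm is None:
        raise ValueError("pwm variant requires a PWMMatrix")

    ionic = np.array([r.ionic_strength for r in records])
    target = np.array([math.log10(r.kd) for r in records])
    sigmas = [r.sigma_log10 for r in records]
    if all(s is not None for s in sigmas):
        weights = 1.0 / np.array(sigmas, dtype=float)
    else:
        if any(s is not None for s in sigmas):
            logger.info("incomplete uncertainties; falling back to unweighted loss")
        weights = np.ones(len(records))

    # cache per-construct site descriptors once
    if variant == "structure":
        features = []
        for r in records:
            seq = sequences[r.seq_ref]
            features.append(site_feature_matrix(seq, init))

        def predict(theta):
            return _predict_log10_kd_structure(theta, features, ionic, init)

        x0 = np.array([getattr(init, n) for n in names])
    else:
        pwm_spec = []
        n_elec = []
        for r in records:
            seq = sequences[r.seq_ref]
            feats = site_feature_matrix(seq, init)
            n_elec.append(feats[:, 3])
            scape = landscape(seq, init.with_(dg_elec0=0.0), "pwm", pwm)
            pwm_spec.append(np.array([s.dg_binding for s in scape.sites]))

        def predict(theta):
            return _predict_log10_kd_pwm(theta, pwm_spec, n_elec, ionic, init)

        x0 = np.array([init.dg_elec0])

    def residuals(theta):
        return weights * (predict(theta) - target)

    rng = np.random.default_rng(seed)
    bounds = (-DG_BOUND * np.ones(n_free), DG_BOUND * np.ones(n_free))
    starts = [np.clip(x0, *bounds)]
    starts += [rng.uniform(-DG_BOUND, DG_BOUND, n_free) for _ in range(n_restarts - 1)]

    best = None
    for k, start in enumerate(starts):
        try:
            sol = least_squares(residuals, start, bounds=bounds, method="trf")
        except Exception as exc:  # keep going across restarts
            logger.warning("restart %d failed: %s", k, exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        logger.debug("restart %d: cost %.6g", k, sol.cost)
    if best is None:
        raise RuntimeError("optimizer failed to converge from any restart")
    if not best.success:
        logger.warning("best solution did not report convergence; returning best-so-far")

    dof = len(records) - n_free
    res_w = best.fun
    rss_unweighted = float(np.sum((predict(best.x) - target) ** 2))
    # covariance of the optimum: (J^T J)^-1 * reduced chi-square
    jac = best.jac
    try:
        cov = np.linalg.inv(jac.T @ jac) * (res_w @ res_w) / dof
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        perr = np.full(n_free, np.nan)

    predicted = 10.0 ** predict(best.x)
    return FitResult(
        variant=variant,
        params=dict(zip(names, (float(x) for x in best.x))),
        param_sigmas=dict(zip(names, (float(e) for e in perr))),
        rss=rss_unweighted,
        dof=dof,
        predicted_kd={r.construct_id: float(p) for r, p in zip(records, predicted)},
        record_ids=tuple(r.construct_id for r in records),
        converged=bool(best.success),
    )


def model_compare_ftest(fit_a: FitResult, fit_b: FitResult) -> tuple[float, float]:
    """Variance-ratio test between two fits of the same records.

    ``fit_a`` should be the statistically simpler model.  Returns
    ``F = (RSS_A/dof_A) / (RSS_B/dof_B)`` and the upper-tail probability
    of an F(dof_A, dof_B) variate — the probability that the simpler model
    is statistically equivalent to the more complex one.  Applied to
    non-nested variants this is a heuristic, not an exact test.
    """
    if set(fit_a.record_ids) != set(fit_b.record_ids):
        raise ValueError("fits must be over identical record sets")
    f_stat = (fit_a.rss / fit_a.dof) / (fit_b.rss / fit_b.dof)
    p = float(stats.f.sf(f_stat, fit_a.dof, fit_b.dof))
    return float(f_stat), p


def weighted_mean_kd(
    estimates: list[tuple[float, float]]
) -> tuple[float, float]:
    """Inverse-variance weighted mean of log10 K_D estimates.

    ``estimates`` is a list of ``(log10_kd, uncertainty)`` pairs; weights
    are 1/sigma^2 normalized to unit sum.  Returns the weighted mean and
    the combined uncertainty ``sqrt(1 / sum(1/sigma^2))`` on the same
    (95% interval half-width) scale as the inputs.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    values = np.array([e[0] for e in estimates], dtype=float)
    sig = np.array([e[1] for e in estimates], dtype=float)
    if np.any(sig <= 0):
        raise ValueError("uncertainties must be positive")
    inv_var = 1.0 / sig**2
    weights = inv_var / inv_var.sum()
    mean = float(np.sum(weights * values))
    combined = float(math.sqrt(1.0 / inv_var.sum()))
    return mean, combined
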