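"""Ligand-bias analysis of G-alpha versus beta-arrestin assay tables.

The package ships the published assay table for ten adrenergic and ten
angiotensin-II ligands: the maximal G-alpha and beta-arrestin responses
(normalized to the reference receptor concentration R_ref) and the
log10 molar EC50 of each pathway, with "X" marking pathways whose EC50
could not be measured (censored).

The switch model turns these numbers into a three-parameter fit: R_ref
(the common saturation level), the EC50 of the first-activating switch,
and Delta_R (receptor not attached to any switch).  The first measured
EC50 pins the first activation threshold L_1 = K_L / (rho - 1) with
rho = R_T - Delta_R; depletion of the receptor pool then *predicts* the
second threshold L_2 = K_L / (rho - 2).  Bias trajectories are the
parametric (G-alpha, b-arr) response curves of the fitted staircase; a
ligand is balanced, G-alpha-biased, b-arr-biased or inactive according to
which pathway maxima clear a threshold on the normalized scale.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import KineticParameters, forward_ligand_sweep

__all__ = [
    "InactiveLigandError",
    "AssayRecord",
    "BoisFit",
    "BiasTrajectory",
    "TrueAssayParams",
    "RECEPTORS",
    "PATHWAYS",
    "load_assay_fixture",
    "load_assay_table",
    "fit_bois",
    "bias_trajectory",
    "classify_ligand",
    "generate_synthetic_assay",
]

RECEPTORS = ("adrenergic", "angiotensin")
PATHWAYS = ("g_alpha", "b_arr")
CENSORED = "X"


class InactiveLigandError(ValueError):
    """Every pathway EC50 is censored; there is no activation to fit."""


@dataclass
class AssayRecord:
    """One ligand's maximal responses and EC50s on both measured pathways.

    Maxima are in R_ref units; EC50s are log10 molar, or None when the
    assay could not determine one (censored, printed as "X").
    """

    receptor: str
    ligand: str
    g_alpha_max: float
    g_alpha_log_ec50: float | None
    barr_max: float
    barr_log_ec50: float | None

    def __post_init__(self) -> None:
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if self.g_alpha_max < 0 or self.barr_max < 0:
            raise ValueError("maximal responses must be non-negative")

    def log_ec50(self, pathway: str) -> float | None:
        return {"g_alpha": self.g_alpha_log_ec50, "b_arr": self.barr_log_ec50}[pathway]

    def max_response(self, pathway: str) -> float:
        return {"g_alpha": self.g_alpha_max, "b_arr": self.barr_max}[pathway]

    def measured_pathways(self) -> list[str]:
        """Pathways with an uncensored EC50, i.e. observed activations."""
        return [p for p in PATHWAYS if self.log_ec50(p) is not None]


@dataclass
class BoisFit:
    """Three-parameter switch-model fit for one ligand."""

    ligand: str
    receptor: str
    r_ref_hat: float  # common saturation level (R_ref estimate)
    ec50_first: float  # molar threshold of the first-activating switch
    first_pathway: str
    delta_r: float
    pool: float  # rho = R_T - Delta_R in R_ref units
    k_l: float  # ligand dissociation constant implied by the fit
    ec50_second_pred: float | None  # model-predicted second threshold
    second_pathway: str | None

    @property
    def log_ec50_first(self) -> float:
        return math.log10(self.ec50_first)


@dataclass
class BiasTrajectory:
    """Parametric (G-alpha, b-arr) response curve of a fitted ligand.

    Responses are the model's staircase in R_ref units, so endpoints sit
    on the corners {(0,0), (0,1), (1,0), (1,1)} up to the ON plateau.
    """

    ligand: str
    ligand_grid: np.ndarray
    g_alpha: np.ndarray
    b_arr: np.ndarray
    label: str

    @property
    def endpoint(self) -> tuple[float, float]:
        return float(self.g_alpha[-1]), float(self.b_arr[-1])


def _parse_table(df: pd.DataFrame) -> list[AssayRecord]:
    records = []
    for row in df.itertuples(index=False):
        def _ec50(v):
            if isinstance(v, str):
                v = v.strip()
                if v in (CENSORED, ""):
                    return None
                return float(v)
            return None if pd.isna(v) else float(v)

        records.append(
            AssayRecord(
                receptor=str(row.receptor),
                ligand=str(row.ligand),
                g_alpha_max=float(row.g_alpha_max),
                g_alpha_log_ec50=_ec50(row.g_alpha_log_ec50),
                barr_max=float(row.barr_max),
                barr_log_ec50=_ec50(row.barr_log_ec50),
            )
        )
    return records


def load_assay_table(path) -> list[AssayRecord]:
    """Read an assay table CSV (same schema as the packaged fixture)."""
    return _parse_table(pd.read_csv(path, dtype={"g_alpha_log_ec50": str, "barr_log_ec50": str}))


def load_assay_fixture(receptor: str) -> list[AssayRecord]:
    """The packaged published assay table, one receptor at a time."""
    if receptor not in RECEPTORS:
        raise ValueError(f"receptor must be one of {RECEPTORS}, got {receptor!r}")
    ref = importlib.resources.files("bois.data") / "assay_table.csv"
    with importlib.resources.as_file(ref) as path:
        records = load_assay_table(path)
    return [r for r in records if r.receptor == receptor]


def fit_bois(
    record: AssayRecord,
    n_switches: int = 2,
    r_t: float = 2.5,
    delta_r: float = 0.0,
    infer_pool: bool = False,
) -> BoisFit:
    """Fit the stepwise model to one ligand's assay measurements.

    The first-activating switch is the pathway with the smaller (more
    negative) measured log EC50, ties broken toward G-alpha.  Its measured
    EC50 is placed at the first activation threshold, which fixes
    K_L = EC50_1 * (rho - 1); the depleted pool then predicts the second
    threshold EC50_2 = K_L / (rho - 2).  R_ref is estimated from the
    common saturation level of the activated pathways.

    ``infer_pool=True`` additionally estimates rho (hence Delta_R) from
    the measured second EC50 when both pathways are uncensored, via
    EC50_2 / EC50_1 = (rho - 1) / (rho - 2).
    """
    measured = record.measured_pathways()
    if not measured:
        raise InactiveLigandError(
            f"{record.ligand}: every EC50 is censored; the ligand never activates"
        )
    if n_switches < 1:
        raise ValueError("n_switches must be >= 1")

    first = min(measured, key=lambda p: (record.log_ec50(p), PATHWAYS.index(p)))
    ec50_first = 10.0 ** record.log_ec50(first)
    others = [p for p in PATHWAYS if p != first]
    second = others[0] if (n_switches >= 2 and others) else None

    pool = r_t - delta_r
    if infer_pool and second in measured:
        ratio = 10.0 ** record.log_ec50(second) / ec50_first
        if ratio > 1:
            pool = (2.0 * ratio - 1.0) / (ratio - 1.0)
            delta_r = r_t - pool
    if pool <= 1.0:
        raise ValueError("receptor pool must exceed 1 R_ref unit for any activation")

    k_l = ec50_first * (pool - 1.0)
    ec50_second_pred = k_l / (pool - 2.0) if (second is not None and pool > 2.0) else None

    saturations = [record.max_response(p) for p in measured]
    r_ref_hat = float(np.mean(saturations))

    return BoisFit(
        ligand=record.ligand,
        receptor=record.receptor,
        r_ref_hat=r_ref_hat,
        ec50_first=ec50_first,
        first_pathway=first,
        delta_r=delta_r,
        pool=pool,
        k_l=k_l,
        ec50_second_pred=ec50_second_pred,
        second_pathway=second,
    )


def bias_trajectory(
    fit: BoisFit,
    record: AssayRecord | None = None,
    n_points: int = 200,
    threshold: float = 0.5,
) -> BiasTrajectory:
    """Parametric (G-alpha, b-arr) curve of the fitted activation staircase.

    Built from the kinetics module's forward ligand sweep with the fitted
    K_L and pool; the first activation event is assigned to the fitted
    first pathway, the second (if the second pathway's activation was
    observed, i.e. uncensored) to the other.  An ON switch contributes its
    plateau of 1 R_ref unit to its pathway's coordinate.
    """
    second_active = (
        fit.second_pathway is not None
        and record is not None
        and fit.second_pathway in record.measured_pathways()
    )
    if record is None and fit.second_pathway is not None:
        second_active = fit.ec50_second_pred is not None
    order = (fit.first_pathway, fit.second_pathway) if second_active else (fit.first_pathway,)
    params = KineticParameters(
        k_l_plus=1.0,
        k_l_minus=fit.k_l,
        r_t=fit.pool,
        delta_r=0.0,
        max_switch_pairs=len(order),
        activation_order=order,
        return_rates=(1.0,) * len(order),
    )
    last = params.activation_threshold(params.n_activatable) if params.n_activatable else fit.k_l
    curve = forward_ligand_sweep(params, l_max=10.0 * last, n_points=n_points)

    grid = curve.ligand_grid
    g = np.zeros_like(grid)
    b = np.zeros_like(grid)
    for i, pathway in enumerate(curve.switch_labels):
        if pathway == "g_alpha":
            g = g + curve.responses[i]
        elif pathway == "b_arr":
            b = b + curve.responses[i]
    label = classify_ligand(record, threshold) if record is not None else "unlabelled"
    return BiasTrajectory(fit.ligand, grid, g, b, label)


def trajectory_for_record(
    record: AssayRecord, threshold: float = 0.5, **fit_kwargs
) -> BiasTrajectory:
    """Fit-then-trace convenience; inactive ligands yield a flat curve at (0, 0)."""
    try:
        fit = fit_bois(record, **fit_kwargs)
    except InactiveLigandError:
        grid = np.linspace(0.0, 1.0, 2)
        zero = np.zeros_like(grid)
        return BiasTrajectory(record.ligand, grid, zero, zero, "inactive")
    return bias_trajectory(fit, record, threshold=threshold)


def classify_ligand(record: AssayRecord, threshold: float = 0.5) -> str:
    """Label a ligand by which pathway maxima clear ``threshold`` (R_ref units).

    balanced: both; g_alpha_biased / barr_biased: only one; inactive: neither.
    """
    g_on = record.g_alpha_max >= threshold
    b_on = record.barr_max >= threshold
    if g_on and b_on:
        return "balanced"
    if g_on:
        return "g_alpha_biased"
    if b_on:
        return "barr_biased"
    return "inactive"


@dataclass
class TrueAssayParams:
    """Ground truth for the synthetic assay generator.

    Defaults mirror the published study conditions: responses saturate at
    a common level R_ref, the receptor pool holds 2.5 R_ref units (two
    activatable switches), no unattached receptor, and first-pathway
    thresholds spread over the nanomolar range the assays report.
    """

    r_ref: float = 1.0
    r_t: float = 2.5
    delta_r: float = 0.0
    log_ec50_range: tuple[float, float] = (-9.5, -6.5)

    @property
    def pool(self) -> float:
        return self.r_t - self.delta_r

    def second_over_first(self) -> float:
        """EC50_2 / EC50_1 = (rho - 1)/(rho - 2) from pool depletion."""
        if self.pool <= 2.0:
            raise ValueError("pool must exceed 2 R_ref units for a second activation")
        return (self.pool - 1.0) / (self.pool - 2.0)


def generate_synthetic_assay(
    true_params: TrueAssayParams,
    n_ligands: int,
    noise_cv: float = 0.05,
    censor_rate: float = 0.2,
    rng: np.random.Generator | int | None = None,
    receptor: str = "adrenergic",
    return_truth: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Emit an assay table with the structure the stepwise model assumes.

    Each synthetic ligand activates G-alpha first at an EC50 drawn
    log-uniformly from ``log_ec50_range``; the b-arr threshold follows
    from pool depletion.  Maxima of activated pathways sit at R_ref under
    multiplicative log-normal noise (coefficient of variation
    ``noise_cv``); EC50s carry the same multiplicative jitter.  With
    probability ``censor_rate`` the b-arr pathway never activates: its
    EC50 is censored and its maximum is sub-threshold.

    Returns a DataFrame in the fixture schema (censored EC50s as "X");
    with ``return_truth=True`` also a per-ligand ground-truth table
    (noise-free thresholds) for recovery experiments.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if not 0.0 <= censor_rate <= 1.0:
        raise ValueError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))  # log-normal with CV = noise_cv
    lo, hi = true_params.log_ec50_range
    ratio = true_params.second_over_first()

    def jitter(n=None):
        if sigma == 0.0:
            return 1.0 if n is None else np.ones(n)
        return np.exp(rng.normal(0.0, sigma, size=n))

    rows = []
    truth_rows = []
    for i in range(n_ligands):
        ec50_1 = 10.0 ** rng.uniform(lo, hi)
        ec50_2 = ec50_1 * ratio
        censored = rng.random() < censor_rate
        g_max = true_params.r_ref * float(jitter())
        g_log = math.log10(ec50_1 * float(jitter()))
        if censored:
            barr_max = 0.15 * true_params.r_ref * float(jitter())
            b_log = CENSORED
        else:
            barr_max = true_params.r_ref * float(jitter())
            b_log = f"{math.log10(ec50_2 * float(jitter())):.17g}"
        rows.append(
            {
                "receptor": receptor,
                "ligand": f"SYN{i + 1:03d}",
                "g_alpha_max": g_max,
                "g_alpha_log_ec50": f"{g_log:.17g}",
                "barr_max": barr_max,
                "barr_log_ec50": b_log,
            }
        )
        truth_rows.append(
            {
                "ligand": f"SYN{i + 1:03d}",
                "r_ref": true_params.r_ref,
                "ec50_first": ec50_1,
                "ec50_second": ec50_2,
                "barr_censored": censored,
            }
        )
    table = pd.DataFrame(rows)
    if return_truth:
        return table, pd.DataFrame(truth_rows)
    return table
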