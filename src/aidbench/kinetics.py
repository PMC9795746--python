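"""Cytidine-deaminase enzymology: activity quantification and model fitting.

The central model is a Michaelis–Menten form with an explicit enzyme-site
concentration,

    v = Et * kcat * X / (Km + X)

where ``X`` is substrate concentration (nM), ``Et`` the concentration of
enzyme catalytic sites (nM; for a single-pocket deaminase equal to the
enzyme concentration), ``kcat`` the turnover number (min^-1) and ``Km`` the
substrate concentration at half-maximal velocity.  Fitting this form yields
kcat directly, and catalytic efficiency kcat/Km (min^-1 nM^-1) is the
quantity used to rank orthologs whose activities span several orders of
magnitude.

Also provided: saturation-binding fits (EMSA, v = Bmax*X/(Kd+X)), substrate
specificity panels, thermal/pH optimum estimation, and endpoint analysis of
limiting-dilution PCR detection series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight
from scipy.optimize import least_squares

__all__ = [
    "KineticsDataset",
    "MMFit",
    "BindingDataset",
    "BindingFit",
    "ThermalProfile",
    "OptimumResult",
    "SubstratePanelResult",
    "DilutionSeries",
    "SUBSTRATE_PANEL",
    "percent_deamination",
    "molecular_weight",
    "et_concentration",
    "fmol_to_nM",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "fold_change",
    "percent_reduction",
    "group_mean_efficiency",
    "relative_deamination_efficiency",
    "fit_binding",
    "estimate_optimum",
    "dilution_fold_difference",
]

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")

#: The six bubble-substrate motifs of the specificity panel: three WRC
#: hotspots and three non-WRC controls.
SUBSTRATE_PANEL = ("TGC", "AGC", "TAC", "GGC", "GTC", "GAC")


# ---------------------------------------------------------------------------
# datasets


@dataclass
class KineticsDataset:
    """Velocity-vs-substrate observations for one enzyme.

    ``observations`` holds (substrate_conc nM, velocity, replicate id)
    triples; ``et`` is the enzyme-site concentration in nM.  Velocities are
    in nM/min by internal convention (fmol-based units convert via the
    reaction volume).
    """

    enzyme_id: str
    observations: list[tuple[float, float, int]]
    et: float
    temperature: float | None = None
    ph: float | None = None

    def __post_init__(self) -> None:
        if self.et <= 0:
            raise ValueError("et must be positive")
        for x, v, _ in self.observations:
            if x <= 0:
                raise ValueError("substrate concentrations must be positive")
            if v < 0:
                raise ValueError("velocities must be non-negative")

    @property
    def x(self) -> np.ndarray:
        return np.array([o[0] for o in self.observations], dtype=float)

    @property
    def v(self) -> np.ndarray:
        return np.array([o[1] for o in self.observations], dtype=float)


@dataclass
class MMFit:
    """Result of the Et-explicit Michaelis–Menten fit."""

    enzyme_id: str
    kcat: float
    km: float
    et: float
    residual_ss: float
    converged: bool
    message: str = ""

    @property
    def vmax(self) -> float:
        return self.et * self.kcat

    @property
    def efficiency(self) -> float:
        return self.kcat / self.km

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.et * self.kcat * x / (self.km + x)


@dataclass
class BindingDataset:
    """EMSA observations: (free substrate nM, bound concentration)."""

    enzyme_id: str
    observations: list[tuple[float, float, int]]

    @property
    def x(self) -> np.ndarray:
        return np.array([o[0] for o in self.observations], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([o[1] for o in self.observations], dtype=float)


@dataclass
class BindingFit:
    enzyme_id: str
    bmax: float
    kd: float
    residual_ss: float
    converged: bool
    message: str = ""

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.bmax * x / (self.kd + x)


@dataclass
class ThermalProfile:
    """Replicate % deamination measurements over a temperature (or pH) grid."""

    enzyme_id: str
    points: list[tuple[float, float, int]]  # (axis value, % deamination, replicate)
    axis: str = "temperature"

    def __post_init__(self) -> None:
        for _, act, _ in self.points:
            if not (0 <= act <= 100):
                raise ValueError("% deamination must lie in [0, 100]")

    def grid(self) -> np.ndarray:
        return np.array(sorted({p[0] for p in self.points}), dtype=float)

    def replicate_means(self) -> tuple[np.ndarray, np.ndarray]:
        grid = self.grid()
        means = np.array(
            [np.mean([a for t, a, _ in self.points if t == g]) for g in grid]
        )
        return grid, means


@dataclass
class OptimumResult:
    """Estimated optimum of an activity profile (argmax of replicate means)."""

    enzyme_id: str
    optimum: float | None
    axis: str
    grid: np.ndarray
    normalized: np.ndarray  # replicate means rescaled so the peak is 100 %
    flat: bool = False
    boundary: bool = False


@dataclass
class SubstratePanelResult:
    """Mean activities and relative efficiencies over the 6-substrate panel."""

    enzyme_id: str
    mean_activity: dict[str, float]
    relative_efficiency: dict[str, float]


@dataclass
class DilutionSeries:
    """Detection outcomes of a serial-dilution PCR assay.

    ``detections[r][i]`` is True when replicate experiment ``r`` produced a
    band at dilution factor ``grid[i]``.
    """

    enzyme_id: str
    grid: list[float]
    detections: list[list[bool]]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("dilution grid must be strictly increasing")
        for row in self.detections:
            if len(row) != len(self.grid):
                raise ValueError("detection row length mismatch with grid")

    def endpoint(self, min_fraction: float = 0.5) -> float | None:
        """Largest dilution at which >= min_fraction of replicates are positive."""
        n = len(self.detections)
        endpoint = None
        for i, d in enumerate(self.grid):
            positive = sum(row[i] for row in self.detections)
            if positive / n >= min_fraction:
                endpoint = d
        return endpoint


# ---------------------------------------------------------------------------
# elementary quantities


def percent_deamination(cleaved_signal: float, uncleaved_signal: float) -> float:
    """Percent product from cleaved/uncleaved band signals of a cleavage assay."""
    if cleaved_signal < 0 or uncleaved_signal < 0:
        raise ValueError("signals must be non-negative")
    total = cleaved_signal + uncleaved_signal
    if total == 0:
        raise ValueError("percent deamination undefined: both signals zero")
    return 100.0 * cleaved_signal / total


def molecular_weight(protein_sequence: str) -> float:
    """Average molecular weight (Da) of a protein over the 20 standard residues."""
    protein_sequence = protein_sequence.upper()
    if not protein_sequence:
        raise ValueError("empty protein sequence")
    bad = sorted(set(protein_sequence) - _AA20)
    if bad:
        raise ValueError(f"non-standard residues: {bad}")
    return float(_bio_molecular_weight(protein_sequence, seq_type="protein"))


def et_concentration(enzyme_ug_per_ml: float, molecular_weight_da: float) -> float:
    """Enzyme-site concentration (nM) from mass concentration (µg/ml) and MW (Da).

    For a deaminase with one catalytic pocket the site concentration equals
    the molar enzyme concentration:  µg/ml / (g/mol) = 1e-3 mol/m^3? —
    explicitly, (µg/ml · 1e-3 g/l) / (Da g/mol) · 1e9 = nM.
    """
    if enzyme_ug_per_ml <= 0 or molecular_weight_da <= 0:
        raise ValueError("inputs must be positive")
    molar = enzyme_ug_per_ml * 1e-3 / molecular_weight_da  # mol/L
    return molar * 1e9


def fmol_to_nM(amount_fmol: float, volume_ul: float) -> float:
    """Convert a substrate amount in fmol to nM in a reaction of volume_ul µl."""
    if volume_ul <= 0:
        raise ValueError("reaction volume must be positive")
    return amount_fmol / volume_ul  # 1 fmol / 1 µl = 1e-15 mol / 1e-6 L = 1 nM


def fold_change(eff_a: float, eff_b: float) -> float:
    """Ratio of two catalytic efficiencies, a relative to b."""
    if eff_a <= 0 or eff_b <= 0:
        raise ValueError("efficiencies must be positive")
    return eff_a / eff_b


def percent_reduction(eff_from: float, eff_to: float) -> float:
    """Percent loss of catalytic efficiency going from eff_from to eff_to."""
    if eff_from <= 0 or eff_to <= 0:
        raise ValueError("efficiencies must be positive")
    return 100.0 * (1.0 - eff_to / eff_from)


def catalytic_efficiency(fit: MMFit) -> float:
    """kcat/Km (min^-1 nM^-1) of a successful fit."""
    if not fit.converged:
        raise ValueError(f"fit for {fit.enzyme_id} did not converge")
    return fit.efficiency


def group_mean_efficiency(
    efficiencies: Mapping[str, float], grouping: Mapping[str, str]
) -> dict[str, float]:
    """Arithmetic mean of member efficiencies per group.

    Catalytically dead enzymes enter with efficiency exactly 0; every member
    named in ``grouping`` must have an efficiency.
    """
    groups: dict[str, list[float]] = {}
    for member, group in grouping.items():
        if member not in efficiencies:
            raise KeyError(f"no efficiency recorded for {member}")
        groups.setdefault(group, []).append(efficiencies[member])
    if not groups:
        raise ValueError("empty grouping")
    return {g: float(np.mean(vals)) for g, vals in groups.items()}


def relative_deamination_efficiency(
    activities: Mapping[str, float], enzyme_id: str = ""
) -> SubstratePanelResult:
    """Activity on each panel substrate divided by the mean over all six.

    The relative efficiencies average to exactly 1, which makes substrate
    preference comparable between enzymes of very different absolute
    activity.
    """
    missing = [s for s in SUBSTRATE_PANEL if s not in activities]
    if missing:
        raise ValueError(f"panel substrates missing: {missing}")
    vals = {s: float(activities[s]) for s in SUBSTRATE_PANEL}
    mean = sum(vals.values()) / len(SUBSTRATE_PANEL)
    if mean <= 0:
        raise ValueError("panel mean activity is zero; relative efficiency undefined")
    rel = {s: v / mean for s, v in vals.items()}
    return SubstratePanelResult(enzyme_id=enzyme_id, mean_activity=vals, relative_efficiency=rel)


# ---------------------------------------------------------------------------
# saturation fits


def _fit_saturation(
    x: np.ndarray, y: np.ndarray, scale0: float, half0: float
) -> tuple[float, float, float, bool, str]:
    """Least-squares fit of y = scale * x / (half + x) in log-parameter space."""

    def residuals(logp: np.ndarray) -> np.ndarray:
        scale, half = np.exp(logp)
        return scale * x / (half + x) - y

    res = least_squares(
        residuals,
        x0=np.log([scale0, half0]),
        bounds=(np.log([scale0 * 1e-8, half0 * 1e-8]), np.log([scale0 * 1e8, half0 * 1e8])),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    scale, half = np.exp(res.x)
    return scale, half, float(np.sum(res.fun**2)), bool(res.success), res.message


def fit_michaelis_menten(data: KineticsDataset) -> MMFit:
    """Fit v = Et*kcat*X/(Km+X) with Et fixed, by nonlinear least squares.

    Parameters are optimized in log space with km initialized at the median
    substrate concentration and kcat at max(v)/Et, which is robust across
    the several-orders-of-magnitude efficiency range of AID orthologs.
    """
    x, v = data.x, data.v
    if len(np.unique(x)) < 4:
        warnings.warn(
            "fewer than 4 distinct substrate concentrations; Km poorly constrained",
            stacklevel=2,
        )
    vmax0 = max(float(v.max()), 1e-300)
    km0 = float(np.median(x))
    scale, half, ss, ok, msg = _fit_saturation(x, v, vmax0, km0)
    return MMFit(
        enzyme_id=data.enzyme_id,
        kcat=scale / data.et,
        km=half,
        et=data.et,
        residual_ss=ss,
        converged=ok,
        message=msg,
    )


def fit_binding(data: BindingDataset) -> BindingFit:
    """Fit the saturation-binding model bound = Bmax*X/(Kd+X) to EMSA data."""
    x, y = data.x, data.y
    bmax0 = max(float(y.max()), 1e-300)
    kd0 = float(np.median(x))
    scale, half, ss, ok, msg = _fit_saturation(x, y, bmax0, kd0)
    return BindingFit(
        enzyme_id=data.enzyme_id, bmax=scale, kd=half, residual_ss=ss, converged=ok, message=msg
    )


# ---------------------------------------------------------------------------
# profiles and dilution series


def estimate_optimum(profile: ThermalProfile) -> OptimumResult:
    """Optimum temperature (or pH): the grid value maximizing replicate means.

    Ties resolve to the lower axis value.  The profile is also returned
    rescaled to percent of the maximal mean activity.  Flat profiles yield
    an undetermined (None) optimum; an optimum on the first or last grid
    point is flagged as a boundary optimum.
    """
    grid, means = profile.replicate_means()
    if len(grid) < 3:
        raise ValueError("need at least 3 grid points")
    peak = float(means.max())
    if peak <= 0 or np.allclose(means, means[0]):
        return OptimumResult(
            enzyme_id=profile.enzyme_id,
            optimum=None,
            axis=profile.axis,
            grid=grid,
            normalized=np.full_like(means, 100.0) if peak > 0 else means * 0.0,
            flat=True,
        )
    idx = int(np.argmax(means))  # argmax returns the first (lowest) maximizer
    return OptimumResult(
        enzyme_id=profile.enzyme_id,
        optimum=float(grid[idx]),
        axis=profile.axis,
        grid=grid,
        normalized=means / peak * 100.0,
        boundary=idx in (0, len(grid) - 1),
    )


def dilution_fold_difference(
    a: DilutionSeries,
    b: DilutionSeries,
    min_fraction: float = 0.5,
) -> tuple[float, tuple[float, float]]:
    """Fold activity difference between two enzymes from detection endpoints.

    The endpoint of a series is the largest dilution still detected in at
    least ``min_fraction`` of replicate experiments; the fold difference is
    endpoint(a)/endpoint(b).  The returned interval [fold/step, fold*step]
    reflects the grid resolution (step = local ratio between neighboring
    dilution factors at a's endpoint).
    """
    if a.grid != b.grid:
        raise ValueError("series must share a dilution grid")
    ea, eb = a.endpoint(min_fraction), b.endpoint(min_fraction)
    if ea is None or eb is None:
        raise ValueError("endpoint undefined: series with no detected dilution")
    fold = ea / eb
    i = a.grid.index(ea)
    if i + 1 < len(a.grid):
        step = a.grid[i + 1] / a.grid[i]
    elif i > 0:
        step = a.grid[i] / a.grid[i - 1]
    else:
        step = 1.0
    return fold, (fold / step, fold * step)
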