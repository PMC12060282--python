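"""Solution-phase biophysics: CD conversion, concentration determination,
dye-binding fits, Job-plot stoichiometry, and quench-logic orientation
inference.

These are the computations used to characterise a barrel assembly in
solution without a crystal structure: circular-dichroism ellipticities are
put on the mean-residue-ellipticity scale; peptide concentrations come from
aromatic A280 or from backbone-amide A214 extinction; channel formation is
read out by fitting hyperbolic single-site binding of an environment-
sensitive dye (DPH); complex stoichiometry from a continuous-variation (Job)
plot; and helix orientation from a fluorophore/quencher proximity truth
table (a 4-cyanophenylalanine / selenomethionine pair quenches only when the
two labels end up adjacent in the assembled barrel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .sequences import HeptadSequence

EPS_PEPTIDE_BOND_214 = 923.0  # M^-1 cm^-1
EPS_TRP_280 = 5690.0  # M^-1 cm^-1
EPS_TYR_280 = 1280.0  # M^-1 cm^-1

DEFAULT_OLIGOMER_STATE = 6


class SolutionError(ValueError):
    """Invalid solution-phase input."""


class FitError(RuntimeError):
    """Non-convergent or ill-posed fit, with diagnostics."""


# ---------------------------------------------------------------------------
# spectroscopy conversions


def n_amide_bonds(seq: HeptadSequence) -> int:
    """Number of amide bonds: (len - 1) backbone bonds, + 1 for an N-acetyl
    cap, + 1 for a C-terminal amide."""
    n = len(seq.residues) - 1
    if seq.n_terminus == "acetyl":
        n += 1
    if seq.c_terminus == "amide":
        n += 1
    return n


def mre_convert(
    theta_mdeg: float, conc_uM: float, path_mm: float, n_bonds: int
) -> float:
    """Ellipticity (mdeg) → mean residue ellipticity (deg cm^2 dmol^-1
    res^-1): MRE = theta x 10^6 / (c_uM x l_mm x n_bonds)."""
    if conc_uM <= 0 or path_mm <= 0 or n_bonds <= 0:
        raise SolutionError("concentration, path length and bond count must be positive")
    return theta_mdeg * 1.0e6 / (conc_uM * path_mm * n_bonds)


def epsilon214(seq: HeptadSequence, aa_table: dict[str, float]) -> float:
    """Molar extinction at 214 nm: 923 M^-1 cm^-1 per amide bond plus the
    per-residue free-amino-acid contributions from ``aa_table``."""
    total = EPS_PEPTIDE_BOND_214 * n_amide_bonds(seq)
    for i, res in enumerate(seq.residues):
        if res not in aa_table:
            raise SolutionError(f"residue {res!r} (position {i}) missing from aa_table")
        if aa_table[res] < 0:
            raise SolutionError(f"negative extinction for residue {res!r}")
        total += aa_table[res]
    return total


def conc_from_A280(
    A280: float, n_trp: int, n_tyr: int, path_cm: float = 1.0
) -> float:
    """Beer-Lambert concentration (uM) from aromatic absorbance at 280 nm."""
    if n_trp + n_tyr < 1:
        raise SolutionError(
            "no Trp/Tyr chromophores: determine concentration via the "
            "amide A214 route (epsilon214) instead"
        )
    eps = EPS_TRP_280 * n_trp + EPS_TYR_280 * n_tyr
    return A280 / (eps * path_cm) * 1.0e6


def assembly_concentration(
    peptide_conc_uM: float, oligomer_state: int = DEFAULT_OLIGOMER_STATE
) -> float:
    """Peptide concentration → assembly concentration (divide by the
    oligomeric state; hexamer by default)."""
    if oligomer_state < 1:
        raise SolutionError("oligomer_state must be >= 1")
    return peptide_conc_uM / oligomer_state


# ---------------------------------------------------------------------------
# dye binding


@dataclass
class BindingSeries:
    """A dye-binding titration: assembly concentration (uM) vs fluorescence."""

    x: np.ndarray
    y: np.ndarray
    ligand: str = "DPH"
    ligand_conc_uM: float = 1.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise SolutionError("x and y must have equal length")
        if np.any(self.x <= 0):
            raise SolutionError("concentrations must be strictly positive")


def simulate_binding(
    KD: float,
    Bmax: float,
    x_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingSeries:
    """Synthetic saturation series y = Bmax x / (KD + x) + Gaussian noise."""
    if KD <= 0 or Bmax <= 0:
        raise SolutionError("KD and Bmax must be positive")
    x = np.asarray(x_grid, dtype=float)
    y = Bmax * x / (KD + x)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(x))
    return BindingSeries(x=x, y=y)


def _hyperbola(x, Bmax, KD):
    return Bmax * x / (KD + x)


@dataclass
class BindingFit:
    """Single-site binding fit results: estimates, fit quality, bootstrap CIs."""

    KD: float
    Bmax: float
    R2: float
    KD_ci: tuple[float, float]
    Bmax_ci: tuple[float, float]
    n_points: int
    residuals: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        return (
            f"Single-site binding fit ({self.n_points} points)\n"
            f"  KD   = {self.KD:.3g} uM   95% CI [{self.KD_ci[0]:.3g}, {self.KD_ci[1]:.3g}]\n"
            f"  Bmax = {self.Bmax:.4g}    95% CI [{self.Bmax_ci[0]:.4g}, {self.Bmax_ci[1]:.4g}]\n"
            f"  R^2  = {self.R2:.4f}"
        )


def fit_single_site(
    series: BindingSeries, n_boot: int = 1000, seed: int = 0
) -> BindingFit:
    """Least-squares fit of y = Bmax x / (KD + x).

    Initial values from the data (Bmax ~ max signal, KD ~ half-saturation
    abscissa); 95% confidence intervals by seeded case-resampling bootstrap.
    """
    x, y = series.x, series.y
    if len(x) < 3:
        raise SolutionError("need at least 3 titration points")
    p0 = [float(y.max()), float(np.interp(y.max() / 2.0, np.sort(y), np.sort(x)))]
    p0[1] = max(p0[1], 1e-6)
    try:
        popt, _ = curve_fit(_hyperbola, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(
            f"single-site fit did not converge: {exc}; p0={p0}, "
            f"x range [{x.min():.3g}, {x.max():.3g}]"
        ) from exc
    Bmax, KD = float(popt[0]), float(popt[1])
    if KD <= 0 or Bmax <= 0:
        raise FitError(f"non-physical estimates KD={KD:.3g}, Bmax={Bmax:.3g}")
    resid = y - _hyperbola(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    R2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    rng = np.random.default_rng(seed)
    kds, bmaxs = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, len(x), size=len(x))
        try:
            pb, _ = curve_fit(_hyperbola, x[idx], y[idx], p0=popt, maxfev=5000)
        except RuntimeError:
            continue
        if pb[1] > 0 and pb[0] > 0:
            bmaxs.append(pb[0])
            kds.append(pb[1])
    if kds:
        kd_ci = tuple(np.percentile(kds, [2.5, 97.5]))
        bmax_ci = tuple(np.percentile(bmaxs, [2.5, 97.5]))
    else:
        kd_ci = (KD, KD)
        bmax_ci = (Bmax, Bmax)
    return BindingFit(
        KD=KD, Bmax=Bmax, R2=R2, KD_ci=kd_ci, Bmax_ci=bmax_ci,
        n_points=len(x), residuals=resid,
    )


# ---------------------------------------------------------------------------
# Job plot (continuous variation)


@dataclass
class JobResult:
    """Continuous-variation result: mole fraction of maximal signal and the
    nearest small-integer stoichiometry."""

    x_max: float
    ratio: float
    stoichiometry: tuple[int, int]

    def summary(self) -> str:
        p, q = self.stoichiometry
        return (
            f"Job plot maximum at mole fraction {self.x_max:.3f} "
            f"(ratio {self.ratio:.3f}) -> {p}:{q} complex"
        )


def job_stoichiometry(
    fractions: np.ndarray, signal: np.ndarray, max_integer: int = 6
) -> JobResult:
    """Locate the composition of maximal signal by a local quadratic fit.

    The mole fraction x_hat of the maximum gives the stoichiometry ratio
    x_hat / (1 - x_hat), reported with the nearest small-integer p:q (a
    symmetric curve peaking at 0.5 is a 1:1 complex).  A maximum at the
    boundary means no complex-driven signal was detected and raises.
    """
    x = np.asarray(fractions, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(x) != len(y):
        raise SolutionError("fractions and signal must have equal length")
    if len(x) < 5:
        raise SolutionError("need at least 5 compositions")
    if np.any((x < 0) | (x > 1)):
        raise SolutionError("mole fractions must lie in [0, 1]")
    order = np.argsort(x)
    x, y = x[order], y[order]
    k = int(np.argmax(y))
    if k == 0 or k == len(x) - 1:
        raise SolutionError(
            "signal maximum at the composition boundary: no complex detected"
        )
    lo, hi = max(0, k - 1), min(len(x), k + 2)
    coeffs = np.polyfit(x[lo:hi], y[lo:hi], 2)
    if coeffs[0] >= 0:
        x_hat = x[k]  # no concave vertex; fall back to the empirical maximum
    else:
        x_hat = float(np.clip(-coeffs[1] / (2.0 * coeffs[0]), x[lo], x[hi - 1]))
    ratio = x_hat / (1.0 - x_hat)
    best = (1, 1)
    best_err = np.inf
    for p in range(1, max_integer + 1):
        for q in range(1, max_integer + 1):
            if gcd_pair(p, q) != 1:
                continue
            err = abs(x_hat - p / (p + q))
            if err < best_err:
                best_err, best = err, (p, q)
    return JobResult(x_max=x_hat, ratio=float(ratio), stoichiometry=best)


def gcd_pair(a: int, b: int) -> int:
    while b:
        a, b = b, a % b
    return a


# ---------------------------------------------------------------------------
# fluorophore/quencher orientation logic


@dataclass(frozen=True)
class QuenchObservation:
    """One labelled-pair experiment: label termini on the two chains and
    whether fluorescence was quenched."""

    label_A_terminus: str  # "n" | "c"
    label_B_terminus: str
    quenched: bool

    def __post_init__(self) -> None:
        for t in (self.label_A_terminus, self.label_B_terminus):
            if t not in ("n", "c"):
                raise SolutionError(f"terminus must be 'n' or 'c', got {t!r}")


def predict_quench(topology: str, terminus_a: str, terminus_b: str) -> bool:
    """Whether a fluorophore/quencher pair is quenched, i.e. adjacent.

    In a parallel assembly, neighbouring chains run the same way: labels at
    the *same* terminus sit side by side and quench, while an N/C combination
    fluoresces.  In an antiparallel assembly the chains are flipped, so
    *opposite*-terminus pairs are adjacent and quench.
    """
    if topology not in ("parallel", "antiparallel"):
        raise SolutionError(f"topology must be parallel/antiparallel, got {topology!r}")
    for t in (terminus_a, terminus_b):
        if t not in ("n", "c"):
            raise SolutionError(f"terminus must be 'n' or 'c', got {t!r}")
    same = terminus_a == terminus_b
    return same if topology == "parallel" else not same


def infer_orientation(observations: list[QuenchObservation]) -> str:
    """Topology consistent with all quench observations.

    Returns "parallel", "antiparallel", "ambiguous" (both consistent) or
    "inconsistent" (neither).
    """
    if not observations:
        raise SolutionError("need at least one observation")
    consistent = []
    for topo in ("parallel", "antiparallel"):
        ok = all(
            predict_quench(topo, o.label_A_terminus, o.label_B_terminus) == o.quenched
            for o in observations
        )
        if ok:
            consistent.append(topo)
    if len(consistent) == 2:
        return "ambiguous"
    if not consistent:
        return "inconsistent"
    return consistent[0]


# ---------------------------------------------------------------------------
# CSV I/O


def read_binding_csv(path: str | Path, **kwargs) -> BindingSeries:
    """Read a titration series from CSV with columns ``assembly_conc_uM``
    and ``fluorescence`` (optional ``ligand``, ``ligand_conc_uM``)."""
    df = pd.read_csv(path)
    for col in ("assembly_conc_uM", "fluorescence"):
        if col not in df.columns:
            raise SolutionError(f"binding CSV missing column {col!r}")
    meta = {}
    if "ligand" in df.columns:
        meta["ligand"] = str(df["ligand"].iloc[0])
    if "ligand_conc_uM" in df.columns:
        meta["ligand_conc_uM"] = float(df["ligand_conc_uM"].iloc[0])
    meta.update(kwargs)
    return BindingSeries(
        x=df["assembly_conc_uM"].to_numpy(),
        y=df["fluorescence"].to_numpy(),
        **meta,
    )


def read_job_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a Job-plot series from CSV with columns ``mole_fraction`` and
    ``signal``."""
    df = pd.read_csv(path)
    for col in ("mole_fraction", "signal"):
        if col not in df.columns:
            raise SolutionError(f"Job-plot CSV missing column {col!r}")
    return df["mole_fraction"].to_numpy(float), df["signal"].to_numpy(float)
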