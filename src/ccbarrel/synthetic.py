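"""Parametric construction of idealized n-helix barrels and noisy ensembles.

This is the package's synthetic-data arm: it builds straight-axis helical
bundles with prescribed per-chain orientation (parallel vs antiparallel),
axial offsets (Z-shift), Gaussian coordinate noise and assigned confidence
scores, emulating the statistical structure of multimer-prediction output
(hundreds of models per sequence, each with an ipTM / pLDDT sidecar) without
running a predictor.  Ground-truth topology is retained on every model so
downstream geometry and clustering can be tested as parameter recovery.

Geometry is Calpha-only by default: every metric consumed downstream
(Z-shift, TM-score, RMSD) is Calpha-based.  Helices are ideal alpha-helices
(1.5 A rise per residue, 3.6 residues per turn, so one full turn spans
5.4 A axially) placed on a circle about a common z axis; the straight-bundle
limit (infinite supercoil pitch) is the default because the Z-shift
definition only requires a common axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Calpha radius from the helix's own axis, ideal alpha-helix.
HELIX_CA_RADIUS = 2.3

DEFAULT_RISE = 1.5
DEFAULT_RESIDUES_PER_TURN = 3.6


class SyntheticError(ValueError):
    """Invalid bundle / ensemble parameters."""


@dataclass(frozen=True)
class BundleParams:
    """Parametric description of an n-helix assembly.

    ``orientation[i]`` is +1 for a helix running N→C along +z, -1 for a
    flipped (antiparallel) helix.  ``axial_offsets`` translate each chain
    along the bundle axis; an antiparallel barrel with A chains at +z/2 and
    B chains at -z/2 realises an inter-helix Z-shift of z.  ``supercoil_pitch``
    of ``inf`` is the straight-bundle limit.
    """

    n_helices: int = 6
    assembly_radius: float = 9.5
    rise_per_residue: float = DEFAULT_RISE
    residues_per_turn: float = DEFAULT_RESIDUES_PER_TURN
    n_res_per_helix: int = 21
    orientation: tuple[int, ...] = (1, 1, 1, 1, 1, 1)
    axial_offsets: tuple[float, ...] = (0.0,) * 6
    azimuthal_phases: tuple[float, ...] | None = None
    chain_types: tuple[str, ...] = ("A", "B", "A", "B", "A", "B")
    supercoil_pitch: float = math.inf

    def __post_init__(self) -> None:
        if self.n_helices < 2:
            raise SyntheticError("need at least 2 helices")
        if self.assembly_radius <= 0:
            raise SyntheticError("assembly_radius must be positive")
        if self.n_res_per_helix < 8:
            raise SyntheticError("need at least 8 residues per helix")
        for name in ("orientation", "axial_offsets", "chain_types"):
            vec = getattr(self, name)
            if len(vec) != self.n_helices:
                raise SyntheticError(
                    f"{name} has length {len(vec)}, expected {self.n_helices}"
                )
        if self.azimuthal_phases is not None and len(self.azimuthal_phases) != self.n_helices:
            raise SyntheticError("azimuthal_phases length mismatch")
        if any(abs(o) != 1 for o in self.orientation):
            raise SyntheticError("orientation entries must be +1 or -1")

    @property
    def phases_deg(self) -> tuple[float, ...]:
        if self.azimuthal_phases is not None:
            return tuple(self.azimuthal_phases)
        return tuple(360.0 * i / self.n_helices for i in range(self.n_helices))


@dataclass
class AssemblyModel:
    """Chains of Calpha coordinates plus confidence metadata.

    ``chains`` is an ordered list of ``(chain_id, chain_type, coords)`` with
    coords an (n, 3) float array in Angstroms.  ``scores`` mirrors a
    prediction score sidecar: iptm in [0, 1], plddt in [0, 100], seed and
    model_index.  ``topology_truth`` carries the generator's ground truth
    ("parallel" / "antiparallel" / "mixed") when the model is synthetic.
    """

    chains: list[tuple[str, str, np.ndarray]]
    scores: dict = field(default_factory=dict)
    provenance: str = "synthetic"
    model_id: str = ""
    topology_truth: str | None = None

    def __post_init__(self) -> None:
        for cid, ctype, xyz in self.chains:
            if len(xyz) == 0:
                raise SyntheticError(f"chain {cid} is empty")
            if not np.all(np.isfinite(xyz)):
                raise SyntheticError(f"chain {cid} has non-finite coordinates")
        iptm = self.scores.get("iptm")
        if iptm is not None and not (0.0 <= iptm <= 1.0):
            raise SyntheticError(f"iptm {iptm} outside [0, 1]")

    @property
    def n_residues(self) -> int:
        return sum(len(xyz) for _, _, xyz in self.chains)

    @property
    def coords(self) -> np.ndarray:
        """All Calpha coordinates, chains concatenated in order."""
        return np.concatenate([xyz for _, _, xyz in self.chains])


def build_ideal_helix(
    n_res: int,
    rise: float = DEFAULT_RISE,
    residues_per_turn: float = DEFAULT_RESIDUES_PER_TURN,
    radius: float = HELIX_CA_RADIUS,
) -> np.ndarray:
    """Calpha trace of an ideal alpha-helix along the local z axis.

    Consecutive residues are separated axially by ``rise`` and azimuthally by
    ``360 / residues_per_turn`` degrees, so one full turn (3.6 residues at
    1.5 A rise) spans 5.4 A.  The trace is centred axially on z = 0.
    """
    if n_res < 2:
        raise SyntheticError(f"need at least 2 residues, got {n_res}")
    i = np.arange(n_res, dtype=float)
    theta = 2.0 * np.pi * i / residues_per_turn
    z = i * rise
    z -= z.mean()
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def build_bundle(params: BundleParams) -> AssemblyModel:
    """Place ideal helices on a circle to realise the prescribed bundle.

    Helix i sits at azimuth ``phases_deg[i]`` on the circle of
    ``assembly_radius``; orientation -1 flips the helix (180 deg rotation
    about the local x axis, so N→C runs along -z); ``axial_offsets[i]``
    translates it along z.  Chain ids run A, B, C, ...; chain *types*
    alternate per ``chain_types``.
    """
    helix = build_ideal_helix(
        params.n_res_per_helix, params.rise_per_residue, params.residues_per_turn
    )
    chains: list[tuple[str, str, np.ndarray]] = []
    for i in range(params.n_helices):
        xyz = helix.copy()
        if params.orientation[i] == -1:
            xyz[:, 1] *= -1.0
            xyz[:, 2] *= -1.0
        phi = math.radians(params.phases_deg[i])
        center = np.array(
            [
                params.assembly_radius * math.cos(phi),
                params.assembly_radius * math.sin(phi),
                params.axial_offsets[i],
            ]
        )
        chains.append((_CHAIN_IDS[i], params.chain_types[i], xyz + center))
    return AssemblyModel(chains=chains, provenance="synthetic")


def perturb_model(model: AssemblyModel, sigma: float, seed: int) -> AssemblyModel:
    """Add i.i.d. zero-mean Gaussian displacement (s.d. ``sigma`` A per
    coordinate); deterministic for a fixed seed, identity at sigma = 0."""
    if sigma < 0:
        raise SyntheticError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return replace(model, chains=[(c, t, x.copy()) for c, t, x in model.chains])
    rng = np.random.default_rng(seed)
    chains = [
        (cid, ctype, xyz + rng.normal(0.0, sigma, size=xyz.shape))
        for cid, ctype, xyz in model.chains
    ]
    return replace(model, chains=chains)


@dataclass(frozen=True)
class ScoreRule:
    """How synthetic models receive confidence scores.

    ``beta`` mode draws ipTM from a two-component Beta mixture with
    topology-dependent means (``mean * conc`` / ``(1 - mean) * conc`` shape
    parameters), emulating prediction runs where both topologies score
    confidently.  ``constant`` assigns a fixed ipTM.  If
    ``n_high_confidence`` is set, exactly that many models receive scores
    above ``threshold`` (parallel models first — mirroring runs where the
    highest-confidence predictions were the minority topology — then a
    seeded random choice of the rest); all others score below it.
    """

    mode: str = "beta"
    mean_parallel: float = 0.88
    mean_antiparallel: float = 0.82
    concentration: float = 40.0
    constant: float | None = None
    n_high_confidence: int | None = None
    threshold: float = 0.7


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def _assign_scores(
    topologies: list[str], rule: ScoreRule, rng: np.random.Generator
) -> np.ndarray:
    n = len(topologies)
    if rule.mode == "constant":
        if rule.constant is None:
            raise SyntheticError("constant score rule needs a value")
        return np.full(n, float(rule.constant))
    if rule.mode != "beta":
        raise SyntheticError(f"unknown score rule mode {rule.mode!r}")
    if rule.n_high_confidence is not None:
        k = rule.n_high_confidence
        if not 0 <= k <= n:
            raise SyntheticError(f"n_high_confidence {k} outside [0, {n}]")
        parallel_idx = [i for i, t in enumerate(topologies) if t == "parallel"]
        other_idx = [i for i, t in enumerate(topologies) if t != "parallel"]
        high: list[int] = list(parallel_idx[:k])
        remaining = k - len(high)
        if remaining > 0:
            high += list(rng.choice(other_idx, size=remaining, replace=False))
        scores = 0.3 + 0.39 * rng.random(n)  # low block: (0.30, 0.69)
        high_scores = np.sort(0.705 + 0.29 * rng.random(len(high)))[::-1]
        # parallel models take the top of the high block
        for s, i in zip(high_scores, high):
            scores[i] = s
        return scores
    scores = np.empty(n)
    for i, topo in enumerate(topologies):
        mean = rule.mean_parallel if topo == "parallel" else rule.mean_antiparallel
        a, b = _beta_params(mean, rule.concentration)
        scores[i] = rng.beta(a, b)
    return scores


def make_ensemble(
    base: BundleParams,
    seeds: Sequence[int],
    n_variants: int = 5,
    parallel_fraction: float = 0.0,
    score_rule: ScoreRule | None = None,
    noise_sigma: float = 0.3,
    antiparallel_zshift: float = 5.6,
    rng_seed: int = 0,
) -> list[AssemblyModel]:
    """Generate a noisy model ensemble with planted topology mix and scores.

    ``len(seeds) * n_variants`` models are produced (five variants per seed
    by default, matching prediction runs that sample each of five network
    variants per random seed; 100 seeds then give 500 models).  A fraction
    ``parallel_fraction`` of models (rounded) are built all-parallel with
    zero offsets; the rest are antiparallel-alternating with A chains at
    +zshift/2 and B chains at -zshift/2.  Coordinates get Gaussian noise of
    s.d. ``noise_sigma``; ipTM / pLDDT come from ``score_rule``.  Bitwise
    reproducible for fixed seeds and ``rng_seed``.
    """
    if len(seeds) == 0:
        raise SyntheticError("seeds must be non-empty")
    if not 0.0 <= parallel_fraction <= 1.0:
        raise SyntheticError("parallel_fraction must be in [0, 1]")
    rule = score_rule or ScoreRule()
    n_models = len(seeds) * n_variants
    n_parallel = int(round(parallel_fraction * n_models))
    topologies = ["parallel"] * n_parallel + ["antiparallel"] * (n_models - n_parallel)

    par_params = replace(
        base,
        orientation=(1,) * base.n_helices,
        axial_offsets=(0.0,) * base.n_helices,
    )
    anti_params = replace(
        base,
        orientation=tuple((-1) ** i for i in range(base.n_helices)),
        axial_offsets=tuple(
            antiparallel_zshift / 2.0 if t == "A" else -antiparallel_zshift / 2.0
            for t in base.chain_types
        ),
    )
    ideal = {
        "parallel": build_bundle(par_params),
        "antiparallel": build_bundle(anti_params),
    }

    rng = np.random.default_rng(rng_seed)
    iptms = _assign_scores(topologies, rule, rng)
    plddts = np.clip(60.0 + 40.0 * iptms + rng.normal(0.0, 2.0, n_models), 0, 100)

    models: list[AssemblyModel] = []
    k = 0
    for seed in seeds:
        for variant in range(1, n_variants + 1):
            topo = topologies[k]
            noise_seed = int((seed * n_variants + variant + rng_seed) % (2**31))
            m = perturb_model(ideal[topo], noise_sigma, noise_seed)
            m.scores = {
                "iptm": float(iptms[k]),
                "plddt": float(plddts[k]),
                "seed": int(seed),
                "model_index": variant,
            }
            m.model_id = f"seed{seed:04d}_model{variant}"
            m.topology_truth = topo
            models.append(m)
            k += 1
    return models
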