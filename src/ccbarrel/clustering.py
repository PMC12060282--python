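"""Confidence filtering, multimer TM-score, and normalized-TM clustering.

Prediction ensembles for pseudo-symmetric A3B3 barrels are compared with a
TM-score maximised over both rigid superpositions and chain mappings: the
assembly has near-C3 symmetry, so a query's chains must be allowed to map
onto the reference's chains by any type-preserving rotation/reflection of
the azimuthal ring before scoring.  Scores are then normalised by the
fraction of residues aligned (normalized TM = TM-score x fraction aligned)
to punish incomplete alignments, and models are binned into clusters at a
normalized-TM similarity threshold (0.95 by default), visiting models in
descending confidence so each cluster's representative is its
highest-confidence member.

TM-score here follows the standard definition: with L the reference length
(chains concatenated) and d0 = 1.24 (L - 15)^(1/3) - 1.8 (clamped at 0.5 A),

    TM = max over superpositions of (1/L) sum_i 1 / (1 + (d_i / d0)^2),

the maximum searched by iterative inclusion from seed fragments: superpose
on a window, keep residues within a distance cutoff, re-superpose, repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import gcd

import numpy as np

from . import geometry
from .synthetic import AssemblyModel


class ClusteringError(ValueError):
    """Invalid clustering / scoring input."""


# ---------------------------------------------------------------------------
# superposition primitives


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R @ P_i + t ~ Q_i."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def tm_d0(L: int) -> float:
    """Length-dependent distance scale, clamped below at 0.5 A."""
    if L > 15:
        d0 = 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def _tm_from_distances(d2: np.ndarray, d0: float, L: int) -> float:
    return float(np.sum(1.0 / (1.0 + d2 / d0**2)) / L)


def _tm_search(Q: np.ndarray, R: np.ndarray, L_norm: int) -> float:
    """Maximise the TM-score of aligned coordinate arrays Q (query) onto
    R (reference) over rigid superpositions.

    Iterative-inclusion search: superpose on a seed window, score all aligned
    residues, re-superpose on the residues within a distance cutoff, iterate
    to convergence; repeat from seed fragments of lengths n, n/2 and n/4 at
    several offsets and over a small ladder of cutoffs, keeping the best.
    """
    n = len(Q)
    d0 = tm_d0(L_norm)
    best = 0.0
    seeds: list[np.ndarray] = []
    for frag in {n, max(n // 2, 4), max(n // 4, 4), 4}:
        step = max((n - frag) // 12, 1)
        for start in range(0, n - frag + 1, step):
            seeds.append(np.arange(start, start + frag))
    for seed in seeds:
        for d_cut in (d0, d0 + 1.0, d0 + 2.5, d0 + 4.0):
            subset = seed
            prev: np.ndarray | None = None
            for _ in range(30):
                rot, t = kabsch(Q[subset], R[subset])
                moved = Q @ rot.T + t
                d2 = np.sum((moved - R) ** 2, axis=1)
                score = _tm_from_distances(d2, d0, L_norm)
                if score > best:
                    best = score
                cut = d_cut
                new = np.flatnonzero(d2 < cut**2)
                while len(new) < 3:
                    cut += 0.5
                    new = np.flatnonzero(d2 < cut**2)
                if prev is not None and len(new) == len(subset) and np.array_equal(new, subset):
                    break
                prev = subset
                subset = new
    return best


# ---------------------------------------------------------------------------
# chain mapping


@dataclass
class ChainMapping:
    """Permutation of query chains onto reference chains with per-chain
    residue correspondence (index-wise, N→C, over the shorter chain)."""

    chain_pairs: list[tuple[int, int]]  # (query chain idx, reference chain idx)
    type_preserving: bool = True
    correspondence: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def aligned_count(self) -> int:
        return sum(len(q) for q, _ in self.correspondence)


def identity_mapping(query: AssemblyModel, reference: AssemblyModel) -> ChainMapping:
    """Map chain k of the query onto chain k of the reference, index-wise."""
    if len(query.chains) != len(reference.chains):
        raise ClusteringError("chain count mismatch for identity mapping")
    pairs = [(k, k) for k in range(len(query.chains))]
    return _with_correspondence(query, reference, pairs)


def _with_correspondence(
    query: AssemblyModel, reference: AssemblyModel, pairs: list[tuple[int, int]]
) -> ChainMapping:
    corr = []
    preserving = True
    for qi, ri in pairs:
        nq, nr = len(query.chains[qi][2]), len(reference.chains[ri][2])
        n = min(nq, nr)
        corr.append((np.arange(n), np.arange(n)))
        if query.chains[qi][1] != reference.chains[ri][1]:
            preserving = False
    return ChainMapping(chain_pairs=pairs, type_preserving=preserving, correspondence=corr)


def _aligned_coords(
    query: AssemblyModel, reference: AssemblyModel, mapping: ChainMapping
) -> tuple[np.ndarray, np.ndarray]:
    Q, R = [], []
    for (qi, ri), (qidx, ridx) in zip(mapping.chain_pairs, mapping.correspondence):
        Q.append(query.chains[qi][2][qidx])
        R.append(reference.chains[ri][2][ridx])
    return np.concatenate(Q), np.concatenate(R)


def tm_score(
    query: AssemblyModel, reference: AssemblyModel, mapping: ChainMapping
) -> float:
    """TM-score of the query onto the reference under a fixed chain mapping,
    normalised by the reference residue count (chains concatenated)."""
    if mapping.aligned_count == 0:
        raise ClusteringError("empty residue correspondence")
    Q, R = _aligned_coords(query, reference, mapping)
    return _tm_search(Q, R, reference.n_residues)


def _quick_tm(Q: np.ndarray, R: np.ndarray, L_norm: int) -> float:
    """One-shot Kabsch superposition TM estimate (no inclusion search);
    cheap lower bound used to rank candidate chain mappings."""
    rot, t = kabsch(Q, R)
    d2 = np.sum((Q @ rot.T + t - R) ** 2, axis=1)
    return _tm_from_distances(d2, tm_d0(L_norm), L_norm)


def _ring_mappings(query: AssemblyModel, reference: AssemblyModel) -> list[list[tuple[int, int]]]:
    """Candidate chain mappings: cyclic rotations x reflection of the
    azimuthal ring order (dihedral group of the ring, 2n mappings)."""
    q_order = geometry._ring_order(query, *geometry.bundle_axis(query))
    r_order = geometry._ring_order(reference, *geometry.bundle_axis(reference))
    n = len(q_order)
    out = []
    for reflect in (False, True):
        qo = list(reversed(q_order)) if reflect else q_order
        for k in range(n):
            out.append([(qo[(i + k) % n], r_order[i]) for i in range(n)])
    return out


def best_chain_mapping(query: AssemblyModel, reference: AssemblyModel) -> ChainMapping:
    """Type-preserving ring mapping (rotations x reflection) maximising the
    TM-score; candidates ranked by a single-superposition score, the best
    returned with its residue correspondence."""
    q_types = sorted(c[1] for c in query.chains)
    r_types = sorted(c[1] for c in reference.chains)
    if q_types != r_types:
        raise ClusteringError(
            f"chain-type multiset mismatch: {q_types} vs {r_types}"
        )
    best_map: list[tuple[int, int]] | None = None
    best_score = -1.0
    for pairs in _ring_mappings(query, reference):
        if any(query.chains[qi][1] != reference.chains[ri][1] for qi, ri in pairs):
            continue
        mapping = _with_correspondence(query, reference, pairs)
        Q, R = _aligned_coords(query, reference, mapping)
        s = _quick_tm(Q, R, reference.n_residues)
        if s > best_score:
            best_score, best_map = s, pairs
    if best_map is None:
        raise ClusteringError("no type-preserving ring mapping exists")
    return _with_correspondence(query, reference, best_map)


def normalized_tm(query: AssemblyModel, reference: AssemblyModel) -> float:
    """TM-score x fraction aligned, the fraction taken of the larger
    structure so that incomplete alignments are strictly penalised."""
    mapping = best_chain_mapping(query, reference)
    tm = tm_score(query, reference, mapping)
    fraction = mapping.aligned_count / max(query.n_residues, reference.n_residues)
    return tm * fraction


# ---------------------------------------------------------------------------
# filtering, ranking, clustering


def filter_confidence(
    models: list[AssemblyModel], iptm_min: float = 0.7
) -> list[AssemblyModel]:
    """Keep models with ipTM strictly above ``iptm_min``, preserving order."""
    missing = [m.model_id or f"#{i}" for i, m in enumerate(models) if "iptm" not in m.scores]
    if missing:
        raise ClusteringError(f"models missing ipTM scores: {', '.join(missing)}")
    return [m for m in models if m.scores["iptm"] > iptm_min]


def confidence_key(model: AssemblyModel) -> tuple:
    """Ranking key: ipTM, ties broken by mean pLDDT, then model index."""
    return (
        -model.scores.get("iptm", 0.0),
        -model.scores.get("plddt", 0.0),
        model.scores.get("model_index", 0),
    )


@dataclass
class ClusterSet:
    """Partition of a filtered ensemble into structure-similarity bins.

    ``clusters`` holds member model ids; ``representatives`` the
    highest-confidence member of each bin; ``topologies`` the orientation
    label of each representative.
    """

    clusters: list[list[str]]
    representatives: list[str]
    topologies: list[str]
    threshold: float

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def cluster_models(
    models: list[AssemblyModel],
    threshold: float = 0.95,
    method: str = "leader",
) -> ClusterSet:
    """Bin models into clusters at a normalized-TM similarity threshold.

    ``leader`` (default): models visited in descending confidence; a model
    joins the first cluster whose leader it matches at normalized_tm >=
    threshold, else founds a new cluster.  Deterministic given the confidence
    ranking, and the leader is by construction the highest-confidence member,
    i.e. the cluster representative.  ``complete`` does complete-linkage
    agglomeration on the full pairwise matrix (O(n^2) scoring; for small
    ensembles).
    """
    if not models:
        raise ClusteringError("need at least one model")
    ranked = sorted(models, key=confidence_key)
    if method == "leader":
        leaders: list[AssemblyModel] = []
        members: list[list[str]] = []
        for m in ranked:
            for k, leader in enumerate(leaders):
                if normalized_tm(m, leader) >= threshold:
                    members[k].append(m.model_id)
                    break
            else:
                leaders.append(m)
                members.append([m.model_id])
        reps = [ld.model_id for ld in leaders]
        topos = [geometry.orientation_topology(ld).simple for ld in leaders]
        return ClusterSet(members, reps, topos, threshold)
    if method == "complete":
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        n = len(ranked)
        if n == 1:
            m = ranked[0]
            return ClusterSet(
                [[m.model_id]],
                [m.model_id],
                [geometry.orientation_topology(m).simple],
                threshold,
            )
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                s = normalized_tm(ranked[i], ranked[j])
                dist[i, j] = dist[j, i] = 1.0 - s
        Z = linkage(squareform(dist, checks=False), method="complete")
        labels = fcluster(Z, t=1.0 - threshold, criterion="distance")
        members_by_label: dict[int, list[int]] = {}
        for i, lab in enumerate(labels):
            members_by_label.setdefault(lab, []).append(i)
        groups = sorted(members_by_label.values(), key=lambda g: g[0])
        members = [[ranked[i].model_id for i in g] for g in groups]
        reps = [ranked[g[0]].model_id for g in groups]
        topos = [geometry.orientation_topology(ranked[g[0]]).simple for g in groups]
        return ClusterSet(members, reps, topos, threshold)
    raise ClusteringError(f"unknown clustering method {method!r}")


@dataclass
class BiasReport:
    """Parallel vs antiparallel member counts and their reduced ratio."""

    n_parallel: int
    n_antiparallel: int
    ratio: str

    def __str__(self) -> str:
        return self.ratio


def orientation_bias(clusters: ClusterSet) -> BiasReport:
    """Count cluster members by topology and reduce the parallel:antiparallel
    ratio (e.g. 2 parallel vs 170 antiparallel → "1:85")."""
    n_par = sum(
        len(members)
        for members, topo in zip(clusters.clusters, clusters.topologies)
        if topo == "parallel"
    )
    n_anti = sum(
        len(members)
        for members, topo in zip(clusters.clusters, clusters.topologies)
        if topo == "antiparallel"
    )
    if n_par == 0:
        ratio = f"0:{n_anti} (no parallel models)"
    elif n_anti == 0:
        ratio = f"{n_par}:0 (no antiparallel models)"
    else:
        g = gcd(n_par, n_anti)
        ratio = f"{n_par // g}:{n_anti // g}"
    return BiasReport(n_par, n_anti, ratio)
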