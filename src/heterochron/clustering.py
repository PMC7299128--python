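"""Fuzzy c-means clustering of developmental expression profiles and
cross-species heterochronic-shift detection.

The core procedure: cluster one species' standardized stage profiles with
fuzzy c-means (FCM), project the other species' one-to-one ortholog profiles
onto the fixed centroids, condense the k minor clusters into three major
temporal clusters (early / mid / late sporophyte development) by centroid
peak stage, and call each ortholog pair conserved or heterochronic according
to whether its two genes land in the same major cluster.

FCM minimizes  J = sum_i sum_j u_ij^m ||x_i - c_j||^2  subject to
sum_j u_ij = 1, by alternating the membership update
u_ij = 1 / sum_l (d_ij / d_il)^(2/(m-1)) and the weighted-centroid update
c_j = sum_i u_ij^m x_i / sum_i u_ij^m.  The fuzzifier m is estimated from
the data dimensions with the empirical formula of the standard
fuzzifier-selection method for expression time courses.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import OrthologPair
from .homology import ContingencyResult, chi_square_2x2

MC_EARLY = "MC1_early"
MC_MID = "MC2_mid"
MC_LATE = "MC3_late"
UNASSIGNED = "unassigned"

CONSERVED = "conserved"
HETEROCHRONIC = "heterochronic"
EXCLUDED = "excluded"

MEMBERSHIP_MIN = 0.3  # confident-assignment floor for shift calls
BIMODAL_TOL = 0.1  # two non-adjacent local maxima closer than this -> unassigned

_FCM_TOL = 1e-6
_FCM_MAX_ITER = 500
_EPS = 1e-300


def estimate_fuzzifier(n_genes: int, n_stages: int) -> float:
    """Empirical fuzzifier estimate from the data dimensions.

    m = 1 + (1418/N + 22.05) D^-2 + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)
    with N genes and D stages; always > 1, non-increasing in N.
    """
    if n_genes < 2 or n_stages < 2:
        raise ValueError("need at least 2 genes and 2 stages")
    N, D = float(n_genes), float(n_stages)
    return (
        1.0
        + (1418.0 / N + 22.05) * D**-2
        + (12.33 / N + 0.243) * D ** (-0.0406 * math.log(N) - 0.1134)
    )


@dataclass
class ClusterModel:
    k: int
    fuzzifier_m: float
    centroids: pd.DataFrame  # k x stages, on the standardized scale
    memberships: pd.DataFrame  # genes x k, rows sum to 1
    objective: float
    objective_history: list[float] = field(default_factory=list)

    @property
    def stage_columns(self) -> list:
        return list(self.centroids.columns)

    def hard_assignments(self) -> pd.Series:
        """Argmax-membership cluster per gene (ties -> lowest cluster)."""
        return pd.Series(
            self.memberships.to_numpy().argmax(axis=1),
            index=self.memberships.index,
            name="cluster",
        )

    def max_memberships(self) -> pd.Series:
        return pd.Series(
            self.memberships.to_numpy().max(axis=1),
            index=self.memberships.index,
            name="max_membership",
        )


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """FCM membership update from squared distances (n x k).

    A profile coinciding with a centroid gets full membership there (split
    equally if it coincides with several).
    """
    zero = d2 <= 0.0
    # scale by the row minimum so the negative power cannot overflow
    row_min = d2.min(axis=1, keepdims=True)
    scale = np.where(row_min > 0, row_min, 1.0)
    # rows holding an exact zero are fully overwritten below, so numerical
    # noise from their power evaluation is irrelevant
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        u = (d2 / scale + _EPS) ** (-1.0 / (m - 1.0))
        u /= u.sum(axis=1, keepdims=True)
    rows = zero.any(axis=1)
    if rows.any():
        u[rows] = 0.0
        z = zero[rows].astype(float)
        u[rows] = z / z.sum(axis=1, keepdims=True)
    return u


def _sqdist(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    return ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)


def fcm_fit(
    profiles: pd.DataFrame,
    k: int,
    m: float,
    seed: int,
    n_restarts: int = 10,
    tol: float = _FCM_TOL,
    max_iter: int = _FCM_MAX_ITER,
    init_centroids: np.ndarray | None = None,
) -> ClusterModel:
    """Fit fuzzy c-means to standardized profiles (genes x stages).

    Runs ``n_restarts`` seeded fits (centroids initialized at k distinct
    profiles) and keeps the best objective.  Convergence: max membership
    change < ``tol`` or ``max_iter`` alternating updates.  The recorded
    objective history is non-increasing.  ``init_centroids`` pins the
    starting centroids of a single run (n_restarts is then ignored).
    """
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of genes ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    rng = np.random.default_rng(seed)
    best = None
    if init_centroids is not None:
        n_restarts = 1
    for _ in range(n_restarts):
        if init_centroids is not None:
            c = np.array(init_centroids, dtype=float)
            if c.shape != (k, x.shape[1]):
                raise ValueError("init_centroids must be (k, n_stages)")
        else:
            c = x[rng.choice(n, size=k, replace=False)]
        d2 = _sqdist(x, c)
        u_prev = None
        history: list[float] = []
        for _ in range(max_iter):
            u = _memberships(d2, m)
            w = u**m
            c = (w.T @ x) / w.sum(axis=0)[:, None]
            d2 = _sqdist(x, c)
            history.append(float((w * d2).sum()))
            if u_prev is not None and np.abs(u - u_prev).max() < tol:
                u_prev = u
                break
            u_prev = u
        objective = history[-1]
        if best is None or objective < best[0]:
            best = (objective, c, u_prev, history)
    objective, c, u, history = best
    stages = list(profiles.columns)
    return ClusterModel(
        k=k,
        fuzzifier_m=m,
        centroids=pd.DataFrame(c, index=range(k), columns=stages),
        memberships=pd.DataFrame(u, index=profiles.index, columns=range(k)),
        objective=objective,
        objective_history=history,
    )


def min_centroid_distance(centroids: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance among centroids (Dmin)."""
    k = centroids.shape[0]
    if k < 2:
        raise ValueError("Dmin needs at least two centroids")
    d = np.sqrt(_sqdist(centroids, centroids))
    return float(d[np.triu_indices(k, 1)].min())


def dmin_profile(
    profiles: pd.DataFrame,
    k_range: Sequence[int],
    m: float,
    seed: int,
    n_restarts: int = 3,
) -> dict[int, float]:
    """Dmin over a range of cluster numbers (the cluster-number selection
    curve: fit FCM per k and record the minimum pairwise centroid
    distance)."""
    profile = {}
    for i, k in enumerate(k_range):
        model = fcm_fit(profiles, k, m, seed + i, n_restarts=n_restarts)
        profile[k] = min_centroid_distance(model.centroids.to_numpy())
    return profile


def select_k(
    profile: Mapping[int, float],
    override: int | None = None,
    rel_drop: float = 0.1,
) -> int:
    """Choose the cluster number from a Dmin profile.

    With ``override`` given, return it.  Otherwise apply the elbow rule:
    the first k whose relative Dmin decrease to k+1 falls below
    ``rel_drop``; if no k qualifies, the largest k.
    """
    if override is not None:
        return override
    if not profile:
        raise ValueError("empty Dmin profile")
    ks = sorted(profile)
    for k, k_next in zip(ks, ks[1:]):
        d, d_next = profile[k], profile[k_next]
        decrease = 0.0 if d == 0 else (d - d_next) / d
        if decrease < rel_drop - 1e-9:  # strictly below, robust to rounding
            return k
    return ks[-1]


def project_profiles(
    model: ClusterModel, profiles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Membership of new standardized profiles to the model's fixed
    centroids, using the model's fuzzifier.

    Returns (memberships, hard assignments, max membership); hard assignment
    is argmax membership with ties broken by lowest cluster index.
    """
    if list(profiles.columns) != model.stage_columns:
        raise ValueError(
            f"stage columns {list(profiles.columns)} do not match the model's "
            f"{model.stage_columns}"
        )
    d2 = _sqdist(profiles.to_numpy(dtype=float), model.centroids.to_numpy())
    u = _memberships(d2, model.fuzzifier_m)
    memberships = pd.DataFrame(u, index=profiles.index, columns=range(model.k))
    hard = pd.Series(u.argmax(axis=1), index=profiles.index, name="cluster")
    return memberships, hard, pd.Series(u.max(axis=1), index=profiles.index,
                                        name="max_membership")


def _local_maxima(values: np.ndarray) -> list[int]:
    idx = []
    n = len(values)
    for i in range(n):
        left = values[i] > values[i - 1] if i > 0 else True
        right = values[i] > values[i + 1] if i < n - 1 else True
        if left and right:
            idx.append(i)
    return idx


def assign_major_clusters(model: ClusterModel) -> dict[int, str]:
    """Condense minor clusters into major temporal clusters by centroid
    peak: stage 1 -> early, stages 2-3 -> mid, stage 4 -> late.

    A bimodal centroid -- two local maxima at non-adjacent stages whose
    heights differ by less than BIMODAL_TOL -- cannot be placed and is
    left unassigned.
    """
    if model.centroids.shape[1] != 4:
        raise ValueError("major-cluster condensation expects 4 stages")
    mapping: dict[int, str] = {}
    peak_to_major = {0: MC_EARLY, 1: MC_MID, 2: MC_MID, 3: MC_LATE}
    for j in range(model.k):
        c = model.centroids.iloc[j].to_numpy(dtype=float)
        maxima = _local_maxima(c)
        bimodal = any(
            abs(c[a] - c[b]) < BIMODAL_TOL
            for ai, a in enumerate(maxima)
            for b in maxima[ai + 1:]
            if b - a > 1
        )
        mapping[j] = UNASSIGNED if bimodal else peak_to_major[int(np.argmax(c))]
    return mapping


def classify_shifts(
    assignments_a: pd.Series,
    max_membership_a: pd.Series,
    assignments_b: pd.Series,
    max_membership_b: pd.Series,
    major_map: Mapping[int, str],
    pairs: Sequence[OrthologPair],
    membership_min: float = MEMBERSHIP_MIN,
) -> tuple[pd.DataFrame, dict]:
    """Per ortholog pair, call conserved / heterochronic / excluded.

    A pair is excluded when either gene sits in an unassigned minor cluster
    or has max membership below ``membership_min``; otherwise the call is
    conserved iff both genes share the same major cluster.  Returns the
    shift table and a count/percentage summary (percentages over the
    non-excluded pairs, mirroring how the assigned set is reported).
    """
    rows = []
    for pair in pairs:
        if pair.gene_a not in assignments_a.index or pair.gene_b not in assignments_b.index:
            continue
        minor_a = int(assignments_a[pair.gene_a])
        minor_b = int(assignments_b[pair.gene_b])
        mem_a = float(max_membership_a[pair.gene_a])
        mem_b = float(max_membership_b[pair.gene_b])
        major_a = major_map[minor_a]
        major_b = major_map[minor_b]
        if (
            major_a == UNASSIGNED
            or major_b == UNASSIGNED
            or mem_a < membership_min
            or mem_b < membership_min
        ):
            call = EXCLUDED
        elif major_a == major_b:
            call = CONSERVED
        else:
            call = HETEROCHRONIC
        rows.append(
            {
                "gene_a": pair.gene_a,
                "gene_b": pair.gene_b,
                "minor_a": minor_a,
                "minor_b": minor_b,
                "major_a": major_a,
                "major_b": major_b,
                "max_membership_a": mem_a,
                "max_membership_b": mem_b,
                "call": call,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "minor_a", "minor_b", "major_a", "major_b",
            "max_membership_a", "max_membership_b", "call",
        ],
    )
    n_conserved = int((table["call"] == CONSERVED).sum())
    n_heterochronic = int((table["call"] == HETEROCHRONIC).sum())
    n_excluded = int((table["call"] == EXCLUDED).sum())
    n_assigned = n_conserved + n_heterochronic
    summary = {
        "n_pairs": len(table),
        "n_assigned": n_assigned,
        "n_excluded": n_excluded,
        "n_conserved": n_conserved,
        "n_heterochronic": n_heterochronic,
        "pct_conserved": 100.0 * n_conserved / n_assigned if n_assigned else float("nan"),
        "pct_heterochronic": 100.0 * n_heterochronic / n_assigned if n_assigned else float("nan"),
    }
    return table, summary


def tf_subset_comparison(
    shift_table: pd.DataFrame, tf_genes: Sequence[str]
) -> ContingencyResult:
    """Do transcription-factor orthologs shift between major clusters at a
    different rate than other genes?  2x2 chi-square (TF vs non-TF x
    conserved vs heterochronic) over the non-excluded pairs; a pair counts
    as TF if either member is on the list."""
    tf_set = set(tf_genes)
    called = shift_table[shift_table["call"].isin([CONSERVED, HETEROCHRONIC])]
    is_tf = called["gene_a"].isin(tf_set) | called["gene_b"].isin(tf_set)
    if not is_tf.any():
        raise ValueError("no transcription factor intersects the shift table")
    conserved = called["call"] == CONSERVED
    table = [
        [int((is_tf & conserved).sum()), int((is_tf & ~conserved).sum())],
        [int((~is_tf & conserved).sum()), int((~is_tf & ~conserved).sum())],
    ]
    return chi_square_2x2(table)
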