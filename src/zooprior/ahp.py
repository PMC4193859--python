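"""Analytic Hierarchy Process over prioritization criteria.

Each participant expresses the relative importance of every pair of
criteria on Saaty's ratio scale (1 = equally important ... 9 = extremely
more important; reciprocals for the reverse direction).  The judgments of
one participant form a positive reciprocal matrix ``A`` with ``A[i, j]``
the importance of criterion ``i`` relative to criterion ``j``.  Criterion
priorities are the normalized principal right eigenvector of ``A``
(Perron vector), or alternatively normalized row geometric means.

Coherence of a judgment set is summarised by the consistency ratio
``CR = CI / RI(n)`` with ``CI = (lambda_max - n) / (n - 1)`` and ``RI(n)``
the expected CI of a random reciprocal matrix of the same size.  A high CR
(conventionally above 0.1) triggers a warning but never a rejection.

Group priorities are obtained either by aggregating individual judgments
(AIJ: element-wise geometric mean of the matrices, then one eigenvector)
or by aggregating individual priorities (AIP: arithmetic mean of the
per-participant priority vectors).  The final criterion weights follow the
sequential-integer rule: the top-ranked of ``n`` criteria receives weight
``n``, the next ``n - 1``, down to 1.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConsistencyWarning,
    ConvergenceError,
    ScaleRangeWarning,
    ValidationError,
)

__all__ = [
    "SAATY_SCALE",
    "RANDOM_INDEX",
    "PairwiseMatrix",
    "ParticipantJudgment",
    "PriorityVector",
    "CriterionWeights",
    "matrix_from_pairs",
    "consistent_matrix",
    "priority_vector",
    "consistency_ratio",
    "aggregate_group",
    "assign_weights",
    "random_index",
]

#: The 17 admissible judgment values of Saaty's fundamental scale.
SAATY_SCALE = tuple(1.0 / k for k in range(9, 1, -1)) + tuple(
    float(k) for k in range(1, 10)
)

#: Random index RI(n): expected consistency index of a random reciprocal
#: matrix whose upper-triangle entries are drawn uniformly from the 17-value
#: Saaty scale.  Values follow the large-sample simulation estimates of the
#: AHP literature; each is cross-checked by a Monte-Carlo oracle in the test
#: suite.  RI(1) = RI(2) = 0 because matrices of size <= 2 are always
#: consistent.
RANDOM_INDEX = {
    1: 0.0,
    2: 0.0,
    3: 0.52,
    4: 0.89,
    5: 1.11,
    6: 1.25,
    7: 1.35,
    8: 1.40,
    9: 1.45,
}

_RI_MC_SAMPLES = 5000
_CR_WARN_THRESHOLD = 0.1
_POWER_TOL = 1e-12
_POWER_MAX_ITER = 10_000
_TIE_TOL = 1e-9

_ri_cache: dict[int, float] = {}


def random_index(n: int) -> float:
    """Return RI(n), the mean consistency index of random Saaty matrices.

    For ``n <= 9`` the packaged simulation-calibrated constants are used.
    For larger matrices (beyond the recommended 5-9 criteria) the value is
    estimated once per process by a deterministic seeded Monte-Carlo run and
    cached; a warning notes the estimation.
    """
    if n < 1:
        raise ValidationError(f"matrix size must be >= 1, got {n}")
    if n in RANDOM_INDEX:
        return RANDOM_INDEX[n]
    if n not in _ri_cache:
        warnings.warn(
            f"no packaged random index for n={n}; estimating by Monte-Carlo "
            f"({_RI_MC_SAMPLES} random Saaty-scale matrices)",
            UserWarning,
        )
        rng = np.random.default_rng(n)  # deterministic per size
        iu = np.triu_indices(n, 1)
        total = 0.0
        for _ in range(_RI_MC_SAMPLES):
            a = np.ones((n, n))
            vals = rng.choice(SAATY_SCALE, size=iu[0].size)
            a[iu] = vals
            a[iu[1], iu[0]] = 1.0 / vals
            lam = float(np.max(np.linalg.eigvals(a).real))
            total += (lam - n) / (n - 1)
        _ri_cache[n] = total / _RI_MC_SAMPLES
    return _ri_cache[n]


@dataclass(frozen=True)
class PairwiseMatrix:
    """A positive reciprocal pairwise-comparison matrix over criteria.

    ``values[i, j]`` is the judged importance of ``criteria_ids[i]``
    relative to ``criteria_ids[j]``; the diagonal is 1 and
    ``values[j, i] == 1 / values[i, j]``.
    """

    criteria_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        object.__setattr__(self, "criteria_ids", tuple(self.criteria_ids))
        n = len(self.criteria_ids)
        errors = []
        if a.shape != (n, n):
            raise ValidationError(
                [f"matrix shape {a.shape} does not match {n} criteria"]
            )
        if not np.all(a > 0):
            errors.append("all pairwise ratios must be strictly positive")
        else:
            if not np.allclose(np.diag(a), 1.0, atol=1e-12):
                errors.append("diagonal entries must equal 1")
            if not np.allclose(a * a.T, 1.0, rtol=1e-9):
                errors.append("matrix violates reciprocity A[j,i] = 1/A[i,j]")
        if errors:
            raise ValidationError(errors)

    @property
    def n(self) -> int:
        return len(self.criteria_ids)

    def permuted(self, order: list[int]) -> "PairwiseMatrix":
        """Return the matrix with criteria reordered by index list ``order``."""
        idx = np.asarray(order)
        return PairwiseMatrix(
            tuple(self.criteria_ids[i] for i in order),
            self.values[np.ix_(idx, idx)],
        )


@dataclass(frozen=True)
class ParticipantJudgment:
    """One participant's complete pairwise-comparison matrix."""

    participant_id: str
    matrix: PairwiseMatrix


@dataclass(frozen=True)
class PriorityVector:
    """Criterion priorities derived from a comparison matrix.

    ``priorities`` sums to 1.  ``lambda_max``, ``consistency_index`` and
    ``consistency_ratio`` are ``None`` when the vector was not derived from
    a single matrix (AIP aggregation of per-participant priorities).
    """

    criteria_ids: tuple[str, ...]
    priorities: np.ndarray
    lambda_max: float | None
    consistency_index: float | None
    consistency_ratio: float | None
    method: str = "eigenvector"

    def as_dict(self) -> dict[str, float]:
        return {c: float(p) for c, p in zip(self.criteria_ids, self.priorities)}


@dataclass(frozen=True)
class CriterionWeights:
    """Group ranking of criteria with sequential integer weights.

    ``ranking`` orders criteria from most to least important; ``weights``
    maps the top criterion of ``n`` to ``n``, the next to ``n - 1``, down
    to 1.  Near-ties in the underlying priorities (absolute difference
    below 1e-9) are broken by the configured criterion order and recorded
    in ``tie_notes``.
    """

    ranking: tuple[str, ...]
    priorities: dict[str, float]
    weights: dict[str, float]
    tie_notes: tuple[str, ...] = ()


def consistent_matrix(criteria_ids, latent: np.ndarray) -> PairwiseMatrix:
    """Build the perfectly consistent matrix ``A[i, j] = v[i] / v[j]``."""
    v = np.asarray(latent, dtype=float)
    if np.any(v <= 0):
        raise ValidationError("latent importance values must be positive")
    return PairwiseMatrix(tuple(criteria_ids), np.outer(v, 1.0 / v))


def matrix_from_pairs(pairs, criteria_ids) -> PairwiseMatrix:
    """Assemble a reciprocal matrix from per-pair judgments.

    Parameters
    ----------
    pairs : iterable of (str, str, float)
        ``(criterion_a, criterion_b, ratio)`` meaning *a is ratio times as
        important as b*.  Every unordered pair of distinct criteria must
        appear exactly once; reciprocals and the diagonal are filled in.
    criteria_ids : ordered collection of str
        Criterion order of the resulting matrix.

    Raises
    ------
    ValidationError
        On unknown criteria, non-positive ratios, duplicate pairs
        (conflicting or not), or missing pairs.  All violations are
        reported together.
    """
    ids = tuple(criteria_ids)
    index = {c: i for i, c in enumerate(ids)}
    n = len(ids)
    a = np.ones((n, n))
    seen: dict[frozenset, float] = {}
    errors = []
    out_of_scale = []
    for pa, pb, ratio in pairs:
        if pa not in index or pb not in index:
            unknown = [c for c in (pa, pb) if c not in index]
            errors.append(f"pair ({pa}, {pb}): unknown criterion {unknown}")
            continue
        if pa == pb:
            if not math.isclose(float(ratio), 1.0):
                errors.append(f"self-comparison ({pa}, {pa}) must have ratio 1")
            continue
        try:
            r = float(ratio)
        except (TypeError, ValueError):
            errors.append(f"pair ({pa}, {pb}): ratio {ratio!r} is not a number")
            continue
        if not math.isfinite(r) or r <= 0:
            errors.append(f"pair ({pa}, {pb}): ratio must be positive, got {ratio}")
            continue
        key = frozenset((pa, pb))
        # normalize to the orientation stored in the matrix
        oriented = r if index[pa] < index[pb] else 1.0 / r
        if key in seen:
            if math.isclose(seen[key], oriented, rel_tol=1e-9):
                errors.append(f"duplicate comparison for pair ({pa}, {pb})")
            else:
                errors.append(
                    f"conflicting duplicate comparison for pair ({pa}, {pb}): "
                    f"{seen[key]:g} vs {oriented:g} (matrix orientation)"
                )
            continue
        seen[key] = oriented
        if not (1.0 / 9 - 1e-12 <= r <= 9 + 1e-12):
            out_of_scale.append((pa, pb, r))
        i, j = index[pa], index[pb]
        a[i, j] = r
        a[j, i] = 1.0 / r
    missing = [
        (ids[i], ids[j])
        for i, j in itertools.combinations(range(n), 2)
        if frozenset((ids[i], ids[j])) not in seen
    ]
    if missing:
        errors.append(
            "missing pairwise comparisons: "
            + ", ".join(f"({x}, {y})" for x, y in missing)
        )
    if errors:
        raise ValidationError(errors)
    if out_of_scale:
        warnings.warn(
            "judgment ratios outside the Saaty range [1/9, 9]: "
            + ", ".join(f"({x}, {y}) = {r:g}" for x, y, r in out_of_scale),
            ScaleRangeWarning,
        )
    return PairwiseMatrix(ids, a)


def _principal_eigenvector(a: np.ndarray) -> tuple[np.ndarray, float]:
    """Power iteration for the Perron vector of a positive matrix."""
    n = a.shape[0]
    x = np.full(n, 1.0 / n)
    for _ in range(_POWER_MAX_ITER):
        y = a @ x
        y /= y.sum()
        residual = float(np.abs(y - x).sum())
        x = y
        if residual < _POWER_TOL:
            lam = float(np.mean((a @ x) / x))
            return x, lam
    raise ConvergenceError(
        f"power iteration did not converge in {_POWER_MAX_ITER} iterations",
        residual,
    )


def priority_vector(
    matrix: PairwiseMatrix, method: str = "eigenvector"
) -> PriorityVector:
    """Derive criterion priorities from one comparison matrix.

    ``method='eigenvector'`` returns the normalized principal right
    eigenvector (power iteration, L1 tolerance 1e-12); ``'geometric_mean'``
    returns normalized row geometric means.  Both populate ``lambda_max``,
    CI and CR; the two agree exactly on consistent matrices.
    """
    a = matrix.values
    n = matrix.n
    if method == "eigenvector":
        if n == 1:
            p, lam = np.array([1.0]), 1.0
        else:
            p, lam = _principal_eigenvector(a)
    elif method == "geometric_mean":
        gm = np.exp(np.mean(np.log(a), axis=1))
        p = gm / gm.sum()
        lam = float(np.mean((a @ p) / p))
    else:
        raise ValidationError(
            f"unknown method {method!r}: use 'eigenvector' or 'geometric_mean'"
        )
    ci = 0.0 if n <= 2 else (lam - n) / (n - 1)
    ri = random_index(n)
    cr = 0.0 if ri == 0.0 else ci / ri
    if cr > _CR_WARN_THRESHOLD:
        warnings.warn(
            f"consistency ratio {cr:.3f} exceeds 0.1; judgments over "
            f"{matrix.criteria_ids} may be incoherent",
            ConsistencyWarning,
        )
    return PriorityVector(
        matrix.criteria_ids, p, lam, ci, cr, method=method
    )


def consistency_ratio(matrix: PairwiseMatrix) -> float:
    """Consistency ratio CR = CI / RI(n) of one matrix (0 for n <= 2)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConsistencyWarning)
        return float(priority_vector(matrix).consistency_ratio)


def aggregate_group(
    judgments: list[ParticipantJudgment],
    method: str = "aij",
    priority_method: str = "eigenvector",
) -> PriorityVector:
    """Merge all participants' judgments into one group priority vector.

    ``method='aij'`` (default) takes the element-wise geometric mean of the
    individual matrices — itself a valid reciprocal matrix — and derives one
    priority vector from it, so the result carries a group consistency
    ratio.  ``method='aip'`` averages the individual priority vectors
    arithmetically and renormalizes; no group CR is defined for it.
    """
    if not judgments:
        raise ValidationError("at least one participant judgment is required")
    ids = judgments[0].matrix.criteria_ids
    mismatched = [
        j.participant_id for j in judgments if j.matrix.criteria_ids != ids
    ]
    if mismatched:
        raise ValidationError(
            [
                f"participant {p!r}: criteria do not match the first "
                f"participant's order {ids}"
                for p in mismatched
            ]
        )
    if method == "aij":
        logs = np.mean([np.log(j.matrix.values) for j in judgments], axis=0)
        merged = np.exp(logs)
        # rebuild from the upper triangle so reciprocity is exact in floats
        iu = np.triu_indices(len(ids), 1)
        a = np.ones_like(merged)
        a[iu] = merged[iu]
        a[iu[1], iu[0]] = 1.0 / merged[iu]
        return priority_vector(PairwiseMatrix(ids, a), method=priority_method)
    if method == "aip":
        vecs = [
            priority_vector(j.matrix, method=priority_method).priorities
            for j in judgments
        ]
        mean = np.mean(vecs, axis=0)
        mean /= mean.sum()
        return PriorityVector(ids, mean, None, None, None, method="aip")
    raise ValidationError(f"unknown aggregation method {method!r}: use 'aij' or 'aip'")


def assign_weights(
    group: PriorityVector, criteria_ids=None
) -> CriterionWeights:
    """Rank criteria by group priority and assign sequential weights n...1.

    ``criteria_ids`` gives the configured criterion order used to break
    ties; it defaults to the order carried by ``group``.  Priorities whose
    absolute difference is below 1e-9 are treated as tied: they keep the
    configured order and the tie is recorded in ``tie_notes`` and warned
    about, but each still receives a distinct sequential integer weight as
    the weighting rule requires.
    """
    ids = tuple(criteria_ids) if criteria_ids is not None else group.criteria_ids
    if set(ids) != set(group.criteria_ids):
        raise ValidationError(
            f"criteria_ids {ids} do not match the priority vector's "
            f"criteria {group.criteria_ids}"
        )
    config_pos = {c: i for i, c in enumerate(ids)}
    pri = group.as_dict()
    order = sorted(ids, key=lambda c: (-pri[c], config_pos[c]))
    # group near-ties and force configured order within each group
    ranking: list[str] = []
    tie_notes: list[str] = []
    i = 0
    while i < len(order):
        j = i + 1
        while j < len(order) and abs(pri[order[j]] - pri[order[j - 1]]) < _TIE_TOL:
            j += 1
        block = sorted(order[i:j], key=lambda c: config_pos[c])
        if len(block) > 1:
            tie_notes.append(
                "tied priorities among "
                + ", ".join(block)
                + "; broken by configured criterion order"
            )
        ranking.extend(block)
        i = j
    if tie_notes:
        warnings.warn("; ".join(tie_notes), UserWarning)
    n = len(ranking)
    weights = {c: float(n - r) for r, c in enumerate(ranking)}
    return CriterionWeights(
        ranking=tuple(ranking),
        priorities=pri,
        weights=weights,
        tie_notes=tuple(tie_notes),
    )
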