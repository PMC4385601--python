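"""Affinity propagation clustering of per-feature values.

Standard responsibility/availability message passing with damping.  Used to
derive exemplars ("sample centers"), per-cluster value ranges, and suggested
threshold cut points for each feature separately.

The implementation is fully deterministic: no noise is injected into the
similarity matrix and ties in exemplar selection resolve to the lowest
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigError, ValidationError

__all__ = [
    "APConfig",
    "APResult",
    "affinity_propagation",
    "cluster_feature",
    "suggest_thresholds",
]


@dataclass(frozen=True)
class APConfig:
    damping: float = 0.9
    max_iter: int = 1000
    convergence_iter: int = 50
    preference: float | str = "median"  # scalar, or "median" of off-diagonal

    def __post_init__(self) -> None:
        if not 0.5 <= self.damping < 1.0:
            raise ConfigError(f"damping must be in [0.5, 1), got {self.damping}")
        if not self.max_iter >= self.convergence_iter >= 1:
            raise ConfigError("need max_iter >= convergence_iter >= 1")
        if isinstance(self.preference, str) and self.preference != "median":
            raise ConfigError(f"unknown preference {self.preference!r}")


@dataclass
class APResult:
    """Clustering outcome.

    ``exemplars`` are sample keys (indices for raw matrices); ``labels``
    maps each sample key to a cluster number 0..k-1.  ``cluster_ranges``
    holds the (min, max) of member feature values per cluster and is filled
    only by :func:`cluster_feature`.
    """

    exemplars: list
    labels: dict
    cluster_ranges: list[tuple[float, float]] | None
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, cluster: int) -> list:
        return [k for k, c in self.labels.items() if c == cluster]


def _resolve_preference(S: np.ndarray, preference: float | str) -> float:
    if preference == "median":
        off = S[~np.eye(len(S), dtype=bool)]
        return float(np.median(off))
    return float(preference)


def affinity_propagation(similarity: np.ndarray, cfg: APConfig | None = None) -> APResult:
    """Cluster by message passing on a square similarity matrix.

    The diagonal is replaced by the preference.  Exemplars are the indices
    with positive net responsibility + availability after convergence
    (exemplar sets stable for ``convergence_iter`` rounds) or ``max_iter``
    sweeps, whichever comes first.
    """
    cfg = cfg or APConfig()
    S = np.array(similarity, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError(f"similarity must be square, got shape {S.shape}")
    n = S.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples")
    if not np.all(np.isfinite(S[~np.eye(n, dtype=bool)])):
        raise ValidationError("similarity contains non-finite entries")
    pref = _resolve_preference(S, cfg.preference)
    np.fill_diagonal(S, pref)

    off = S[~np.eye(n, dtype=bool)]
    if np.all(off == off[0]):
        # Degenerate: all pairs equally similar.  The message-passing fixed
        # point is all-singletons when the preference beats the similarity,
        # otherwise one cluster around the lowest index.
        if pref > off[0]:
            return APResult(
                exemplars=list(range(n)),
                labels={i: i for i in range(n)},
                cluster_ranges=None,
                n_iter=0,
                converged=True,
            )
        return APResult(
            exemplars=[0],
            labels={i: 0 for i in range(n)},
            cluster_ranges=None,
            n_iter=0,
            converged=True,
        )

    # Deterministic degeneracy breaking: near-twin points can otherwise
    # freeze into a symmetric state where both claim exemplarship.  A tiny
    # index-proportional preference offset resolves such ties toward the
    # lower index without randomness.
    spread = float(off.max() - off.min()) or 1.0
    np.fill_diagonal(S, pref - np.arange(n) * 1e-9 * spread)

    lam = cfg.damping
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    prev_exemplars: np.ndarray | None = None
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # responsibilities
        AS = A + S
        first_k = np.argmax(AS, axis=1)
        first = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[idx, first_k] = S[idx, first_k] - second
        R = lam * R + (1.0 - lam) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, np.diag(R))
        Anew = Rp.sum(axis=0)[None, :] - Rp
        dA = np.diag(Anew).copy()
        Anew = np.minimum(Anew, 0.0)
        np.fill_diagonal(Anew, dA)
        A = lam * A + (1.0 - lam) * Anew

        exemplars = np.flatnonzero(np.diag(A) + np.diag(R) > 0)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
        else:
            stable = 0
        prev_exemplars = exemplars
        if stable >= cfg.convergence_iter and exemplars.size > 0:
            converged = True
            break

    exemplars = prev_exemplars if prev_exemplars is not None else np.array([], int)
    if exemplars.size == 0:
        # best-effort: the point with the largest net self-message
        exemplars = np.array([int(np.argmax(np.diag(A) + np.diag(R)))])
        converged = False
    # assignment: nearest exemplar by similarity; exemplars own themselves.
    # argmax returns the first maximum, so ties go to the lower exemplar index.
    assign = exemplars[np.argmax(S[:, exemplars], axis=1)]
    assign[exemplars] = exemplars
    cluster_of = {int(e): c for c, e in enumerate(exemplars)}
    labels = {int(i): cluster_of[int(assign[i])] for i in range(n)}
    return APResult(
        exemplars=[int(e) for e in exemplars],
        labels=labels,
        cluster_ranges=None,
        n_iter=it,
        converged=converged,
    )


def cluster_feature(values: Mapping[Hashable, float], cfg: APConfig | None = None) -> APResult:
    """Cluster scalar feature values keyed by sample id.

    Similarity is the negative squared difference.  Clusters are reported
    in order of increasing range minimum; ``cluster_ranges`` holds the
    (min, max) of member values per cluster.
    """
    if len(values) < 2:
        raise ValidationError("need at least 2 samples to cluster")
    keys = list(values.keys())
    v = np.asarray([float(values[k]) for k in keys])
    if np.all(v == v[0]):
        return APResult(
            exemplars=[keys[0]],
            labels={k: 0 for k in keys},
            cluster_ranges=[(float(v[0]), float(v[0]))],
            n_iter=0,
            converged=True,
        )
    S = -((v[:, None] - v[None, :]) ** 2)
    res = affinity_propagation(S, cfg)
    # order clusters by their minimum member value
    raw_members: dict[int, list[int]] = {}
    for i, c in res.labels.items():
        raw_members.setdefault(c, []).append(i)
    order = sorted(raw_members, key=lambda c: v[raw_members[c]].min())
    remap = {old: new for new, old in enumerate(order)}
    labels = {keys[i]: remap[c] for i, c in res.labels.items()}
    exemplars = [keys[res.exemplars[old]] for old in order]
    ranges = [
        (float(v[raw_members[old]].min()), float(v[raw_members[old]].max()))
        for old in order
    ]
    return APResult(
        exemplars=exemplars,
        labels=labels,
        cluster_ranges=ranges,
        n_iter=res.n_iter,
        converged=res.converged,
    )


def suggest_thresholds(result: APResult, grid: float = 0.5) -> list[float]:
    """Cut points between adjacent cluster value ranges.

    Each cut is the midpoint of the gap between consecutive ranges, rounded
    half-up to the ``grid`` (0.5 suits ratio features, 10 suits 8-bit color
    channels).  Overlapping adjacent ranges draw a warning; the midpoint of
    the overlap is used.
    """
    if grid <= 0:
        raise ConfigError(f"rounding grid must be positive, got {grid}")
    if result.cluster_ranges is None:
        raise ValidationError("result has no cluster ranges (use cluster_feature)")
    ranges = sorted(result.cluster_ranges, key=lambda r: r[0])
    cuts: list[float] = []
    for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
        if lo2 < hi1:
            warnings.warn(
                f"adjacent cluster ranges overlap: ({lo1}, {hi1}) and ({lo2}, {hi2})",
                stacklevel=2,
            )
        mid = (hi1 + lo2) / 2.0
        cut = float(np.floor(mid / grid + 0.5) * grid)
        if not cuts or cut != cuts[-1]:
            cuts.append(cut)
    return cuts
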