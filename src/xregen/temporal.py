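"""Common rescaled clock, early/late phases, and temporal pattern classes.

Regeneration time courses sampled on heterogeneous grids (hours for
hydra/planarian, days for sea cucumber) are put on a shared [0, 1] clock
so that the final time points coincide.  Phases are assigned by index:
by default the early phase is the first two non-baseline time points and
the late phase the last two (a species sampled sparsely early, like the
sea cucumber, overrides early to its first point).  DE genes are then
classified into four recurrent patterns —

* ``EU`` / ``ED``: transiently up-/downregulated early, back to near
  baseline by the recovery time point;
* ``LU`` / ``LD``: sustained up-/downregulation persisting into the late
  phase;
* ``OTHER``: sign-mixed or unclassifiable trajectories —

and profiles are clustered by correlation distance for visual grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

__all__ = [
    "PhaseSpec",
    "PatternCall",
    "PATTERNS",
    "rescale_time",
    "assign_phases",
    "classify_pattern",
    "classify_all",
    "cluster_profiles",
]

PATTERNS = ("EU", "ED", "LU", "LD", "OTHER")


@dataclass(frozen=True)
class PhaseSpec:
    """Index-based early/late phase definition for one species.

    Indices refer to columns of the time course (0 = baseline).
    ``recovery_index`` is the time point by which transient (EU/ED)
    genes must have returned to near-baseline expression.
    """

    species: str
    early_indices: tuple[int, ...]
    late_indices: tuple[int, ...]
    recovery_index: int

    def __post_init__(self) -> None:
        if not self.early_indices or not self.late_indices:
            raise ValueError("early and late index sets must be non-empty")
        if set(self.early_indices) & set(self.late_indices):
            raise ValueError(
                f"early and late phases overlap: {self.early_indices} vs {self.late_indices}"
            )
        if self.recovery_index < max(self.early_indices):
            raise ValueError("recovery_index must not precede the early phase")


@dataclass(frozen=True)
class PatternCall:
    """Classified temporal pattern of one DE gene."""

    gene_id: str
    pattern: str
    peak_log2fc: float
    recovery_log2fc: float

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern '{self.pattern}'")


def rescale_time(time_points_h: Sequence[float] | np.ndarray) -> np.ndarray:
    """Affine map of a time grid onto [0, 1] (baseline -> 0, last -> 1)."""
    t = np.asarray(time_points_h, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two time points to rescale")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("final time point must exceed the baseline")
    return (t - t[0]) / span


def assign_phases(
    time_points_h: Sequence[float] | np.ndarray,
    species: str = "",
    *,
    early_indices: Sequence[int] | None = None,
    late_indices: Sequence[int] | None = None,
    recovery_index: int | None = None,
) -> PhaseSpec:
    """Default phase assignment with optional per-species overrides.

    Default: early = first two non-baseline indices, late = last two,
    recovery = last index.  With only two non-baseline points the rule
    degenerates to early = {1}, late = {last}.  Overrides replace the
    corresponding default wholesale; an override producing overlapping
    phases is a configuration error.
    """
    t = np.asarray(time_points_h, dtype=float)
    n = t.size
    if n < 2:
        raise ValueError("need at least two time points")
    n_nonbase = n - 1
    if early_indices is None:
        early_indices = (1,) if n_nonbase < 3 else (1, 2)
    if late_indices is None:
        # last two indices, dropping any already claimed by the early phase
        # (3 non-baseline points would otherwise overlap at the middle one)
        candidate = (n - 1,) if n_nonbase < 3 else (n - 2, n - 1)
        late_indices = tuple(i for i in candidate if i not in set(early_indices)) or (n - 1,)
    if recovery_index is None:
        recovery_index = n - 1
    return PhaseSpec(
        species=species,
        early_indices=tuple(int(i) for i in early_indices),
        late_indices=tuple(int(i) for i in late_indices),
        recovery_index=int(recovery_index),
    )


def classify_pattern(
    gene_id: str,
    log2fc: Sequence[float] | np.ndarray,
    is_de: Sequence[bool] | np.ndarray,
    phases: PhaseSpec,
    recovery_tol: float = 0.5,
) -> PatternCall:
    """Assign one of EU/ED/LU/LD/OTHER to a DE gene's trajectory.

    EU: DE with positive log2FC at >= 1 early index, all early DE calls
    sharing the positive sign, and |log2FC| <= recovery_tol at the
    recovery index (near-baseline again).  ED is the mirror image.
    LU: positive log2FC at every DE time point with DE persisting at
    >= 1 late index and no recovery.  LD mirrors LU.  Anything
    sign-mixed or matching no class is OTHER.  Classes are checked in
    the order EU/ED then LU/LD, so a recovered early pulse is never
    absorbed into the sustained classes.
    """
    fc = np.asarray(log2fc, dtype=float)
    de = np.asarray(is_de, dtype=bool)
    if fc.shape != de.shape:
        raise ValueError("log2fc and is_de must have equal length")
    if not de.any():
        raise ValueError(f"gene '{gene_id}' has no DE time point; classification undefined")

    de_idx = np.flatnonzero(de)
    peak = float(fc[de_idx][np.argmax(np.abs(fc[de_idx]))])
    recovery = float(fc[phases.recovery_index])
    recovered = abs(recovery) <= recovery_tol

    early = [i for i in phases.early_indices if i < fc.size]
    late = [i for i in phases.late_indices if i < fc.size]
    early_de = [i for i in early if de[i]]
    late_de = [i for i in late if de[i]]

    pattern = "OTHER"
    if early_de and recovered:
        signs = {np.sign(fc[i]) for i in early_de}
        if signs == {1.0}:
            pattern = "EU"
        elif signs == {-1.0}:
            pattern = "ED"
    if pattern == "OTHER" and late_de:
        de_signs = np.sign(fc[de_idx])
        if np.all(de_signs > 0) and not recovered:
            pattern = "LU"
        elif np.all(de_signs < 0) and not recovered:
            pattern = "LD"
    return PatternCall(
        gene_id=gene_id, pattern=pattern, peak_log2fc=peak, recovery_log2fc=recovery
    )


def classify_all(
    log2fc: np.ndarray,
    is_de: np.ndarray,
    gene_ids: Sequence[str],
    phases: PhaseSpec,
    recovery_tol: float = 0.5,
) -> pd.DataFrame:
    """Classify every gene DE at >= 1 time point; returns a tidy table."""
    rows = []
    for g, fc_row, de_row in zip(gene_ids, log2fc, is_de):
        if not np.any(de_row):
            continue
        call = classify_pattern(g, fc_row, de_row, phases, recovery_tol)
        rows.append(
            {
                "gene_id": call.gene_id,
                "pattern": call.pattern,
                "peak_log2fc": call.peak_log2fc,
                "recovery_log2fc": call.recovery_log2fc,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "pattern", "peak_log2fc", "recovery_log2fc"])


def cluster_profiles(
    log2fc: np.ndarray, k: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Agglomerative clustering of expression profiles.

    Distance is 1 - Pearson correlation between profiles, average
    linkage, cut at ``k`` clusters.  Zero-variance (constant) profiles
    have no defined correlation; they are assigned afterwards to the
    cluster with the nearest Euclidean mean profile and flagged.

    Returns ``(labels, mean_profiles, constant_flags)``; labels are
    0-based and deterministic given input order.
    """
    X = np.asarray(log2fc, dtype=float)
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} profiles, got {n}")
    const = X.std(axis=1) == 0
    var_idx = np.flatnonzero(~const)
    labels = np.full(n, -1, dtype=int)
    if var_idx.size == 0:
        raise ValueError("all profiles are constant; correlation clustering undefined")
    if var_idx.size == 1:
        labels[var_idx[0]] = 0
    else:
        d = pdist(X[var_idx], metric="correlation")
        Z = average(d)
        cut = fcluster(Z, t=min(k, var_idx.size), criterion="maxclust")
        # relabel to 0-based in order of first appearance for determinism
        seen: dict[int, int] = {}
        for i, c in enumerate(cut):
            labels[var_idx[i]] = seen.setdefault(int(c), len(seen))
    n_clusters = labels.max() + 1
    means = np.vstack([X[labels == c].mean(axis=0) for c in range(n_clusters)])
    for i in np.flatnonzero(const):
        labels[i] = int(np.argmin(((means - X[i]) ** 2).sum(axis=1)))
    means = np.vstack([X[labels == c].mean(axis=0) for c in range(labels.max() + 1)])
    return labels, means, const
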