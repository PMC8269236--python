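"""Accuracy metrics, small-database-effect quantification, and community
statistics.

``score_assignments`` does exact confusion bookkeeping against ground truth.
False-positive rates are reported per query class (target-derived, homolog,
unrelated) with their denominators stated, because a single pooled rate hides
which class leaks.

``small_db_effect`` measures how many reads that a targets-only ("small")
database assigns to gene families are absorbed by homolog decoys once those
decoys are present — the fraction of core-assigned reads that had a better
home among the homologs.

Community statistics are Bray-Curtis dissimilarity and classical PCoA
(metric multidimensional scaling).  PCoA applies no negative-eigenvalue
correction; negative eigenvalues are reported and their axes dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import ScoringScheme, SearchConfig
from .model import ReferenceDatabase
from .profiling import ReadAssignment, assign_reads


@dataclass(frozen=True)
class ConfusionSummary:
    n_target: int
    n_homolog: int
    n_unrelated: int
    tp: int                 # target-derived, assigned to the correct family
    fn: int                 # target-derived, unassigned/absorbed/wrong family
    fp_wrong_family: int    # target-derived but assigned to the wrong family
    fp_homolog: int         # homolog-derived query assigned to any family
    fp_unrelated: int       # unrelated query assigned to any family

    def __post_init__(self) -> None:
        if self.tp + self.fn != self.n_target:
            raise ValueError("TP + FN must equal the number of target-derived queries")

    @property
    def fp(self) -> int:
        return self.fp_wrong_family + self.fp_homolog + self.fp_unrelated

    @property
    def fn_rate(self) -> float:
        return self.fn / self.n_target if self.n_target else 0.0

    @property
    def fp_rate_homolog(self) -> float:
        return self.fp_homolog / self.n_homolog if self.n_homolog else 0.0

    @property
    def fp_rate_unrelated(self) -> float:
        return self.fp_unrelated / self.n_unrelated if self.n_unrelated else 0.0

    def to_dict(self) -> dict:
        return dict(
            n_target=self.n_target,
            n_homolog=self.n_homolog,
            n_unrelated=self.n_unrelated,
            tp=self.tp,
            fn=self.fn,
            fp=self.fp,
            fp_wrong_family=self.fp_wrong_family,
            fp_homolog=self.fp_homolog,
            fp_unrelated=self.fp_unrelated,
            fn_rate=self.fn_rate,
            fp_rate_homolog=self.fp_rate_homolog,
            fp_rate_unrelated=self.fp_rate_unrelated,
        )


def score_assignments(
    assignments: Sequence[ReadAssignment],
    truth: Mapping[str, tuple[str, Optional[str]]],
) -> ConfusionSummary:
    """Exact confusion bookkeeping of assignments against truth labels.

    Truth labels are ("target", family_id), ("decoy", group_id) or
    ("unrelated", None).  A target-derived query assigned to the wrong family
    counts as both a false positive (for the wrong family) and a false
    negative (for its own).
    """
    unknown = sorted(a.read_id for a in assignments if a.read_id not in truth)
    if unknown:
        raise KeyError(f"query ids missing from truth: {unknown}")
    n_target = sum(1 for t in truth.values() if t[0] == "target")
    n_homolog = sum(1 for t in truth.values() if t[0] == "decoy")
    n_unrelated = sum(1 for t in truth.values() if t[0] == "unrelated")
    tp = fp_wrong = fp_homolog = fp_unrelated = 0
    for a in assignments:
        kind, key = truth[a.read_id]
        if a.status == "assigned":
            if kind == "target":
                if a.family_id == key:
                    tp += 1
                else:
                    fp_wrong += 1
            elif kind == "decoy":
                fp_homolog += 1
            else:
                fp_unrelated += 1
    fn = n_target - tp
    return ConfusionSummary(
        n_target=n_target,
        n_homolog=n_homolog,
        n_unrelated=n_unrelated,
        tp=tp,
        fn=fn,
        fp_wrong_family=fp_wrong,
        fp_homolog=fp_homolog,
        fp_unrelated=fp_unrelated,
    )


@dataclass(frozen=True)
class SmallDbReport:
    n_core_assigned: int
    n_absorbed_under_full: int
    per_family_fractions: Mapping[str, float]

    @property
    def reassigned_fraction(self) -> float:
        if self.n_core_assigned == 0:
            return 0.0
        return self.n_absorbed_under_full / self.n_core_assigned


def small_db_effect(
    reads: Sequence[tuple[str, str]],
    core_db: ReferenceDatabase,
    full_db: ReferenceDatabase,
    config: SearchConfig = SearchConfig(),
    scheme: ScoringScheme = ScoringScheme(),
) -> SmallDbReport:
    """Quantify decoy absorption of reads a targets-only database assigns.

    Reads are assigned under the core (decoy-free) database; the core-assigned
    subset is re-assigned under the full database and the absorbed fraction is
    reported, both overall and per core family (the per-family view uses each
    family's own core-assigned reads as denominator).
    """
    if core_db.n_decoys:
        raise ValueError("core database must not contain decoy groups")
    core_assignments = assign_reads(reads, core_db, config, scheme)
    core_assigned = [a for a in core_assignments if a.status == "assigned"]
    by_id = dict(reads)
    n_absorbed = 0
    per_family_total: dict[str, int] = {}
    per_family_absorbed: dict[str, int] = {}
    for a in core_assigned:
        per_family_total[a.family_id] = per_family_total.get(a.family_id, 0) + 1
        full_a = assign_reads([(a.read_id, by_id[a.read_id])], full_db, config, scheme)[0]
        if full_a.status == "homolog_absorbed":
            n_absorbed += 1
            per_family_absorbed[a.family_id] = per_family_absorbed.get(a.family_id, 0) + 1
    fractions = {
        fam: per_family_absorbed.get(fam, 0) / total
        for fam, total in per_family_total.items()
    }
    return SmallDbReport(
        n_core_assigned=len(core_assigned),
        n_absorbed_under_full=n_absorbed,
        per_family_fractions=fractions,
    )


def bray_curtis(
    profile_p: Mapping[str, float], profile_q: Mapping[str, float]
) -> float:
    """Bray-Curtis dissimilarity, 1 - 2*sum(min)/(sum(p)+sum(q)), on the union
    key set (absent keys count as zero)."""
    keys = set(profile_p) | set(profile_q)
    p = np.array([profile_p.get(k, 0.0) for k in keys], dtype=float)
    q = np.array([profile_q.get(k, 0.0) for k in keys], dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = p.sum() + q.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero profiles")
    return float(1.0 - 2.0 * np.minimum(p, q).sum() / denom)


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray          # (n_samples, k) columns ordered by eigenvalue
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray # over the positive eigenvalues
    n_negative_eigenvalues: int
    negative_eigenvalue_mass: float

    def to_frame(self) -> pd.DataFrame:
        cols = {f"axis{i + 1}": self.coordinates[:, i] for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def pcoa(
    distance_matrix: np.ndarray,
    k: int = 2,
    sample_ids: Optional[Sequence[str]] = None,
) -> Ordination:
    """Classical metric scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of their eigenvalues.  Axes with negative eigenvalues (the
    signature of non-Euclidean distances such as Bray-Curtis) are dropped and
    reported; no Lingoes/Cailliez correction is applied.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")
    if k < 1:
        raise ValueError("k must be at least 1")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(eigvals).max()))
    positive = eigvals > tol
    negative = eigvals < -tol
    n_pos = int(positive.sum())
    k_eff = min(k, n_pos)
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    # enforce a deterministic sign convention per axis
    for j in range(k_eff):
        col = coords[:, j]
        pivot = np.argmax(np.abs(col))
        if col[pivot] < 0:
            coords[:, j] = -col
    pos_sum = float(eigvals[positive].sum()) if n_pos else 1.0
    proportion = (
        eigvals[:k_eff] / pos_sum if n_pos else np.zeros(0)
    )
    ids = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("sample_ids length must match the matrix size")
    return Ordination(
        sample_ids=ids,
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=np.asarray(proportion, dtype=float),
        n_negative_eigenvalues=int(negative.sum()),
        negative_eigenvalue_mass=float(-eigvals[negative].sum()) if negative.any() else 0.0,
    )


def distance_matrix(
    profiles: Sequence[Mapping[str, float]],
) -> np.ndarray:
    """Pairwise Bray-Curtis distances between abundance profiles."""
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(profiles[i], profiles[j])
    return D
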