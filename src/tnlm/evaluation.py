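"""Parcellation and task-map comparison metrics.

Two parcellations of the same vertex set are compared by first putting
their labels in one-to-one correspondence with the Gale-Shapley stable
matching algorithm (each side ranks the other side's labels by overlap
vertex count) and then measuring agreement:

- ``concordance``: fraction of vertices whose labels agree after the
  matched relabeling (used for test-retest reliability across sessions);
- ``agreement_fraction``: for a task-defined label, the fraction of its
  vertices captured by the resting-state parcel it is matched to.

Task label maps are built from per-vertex Z-score activation maps by
thresholding at Z >= 3.0 (one-tailed uncorrected p <= 0.00135), assigning
each supra-threshold vertex the most significant task, and removing
isolated labeled patches of 40 vertices or fewer.

Boundary maps count, per mesh triangle, how many parcellations in a family
(e.g. across K) place a parcel border through that triangle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from tnlm.mesh import SurfaceMesh, boundary_triangles, build_vertex_adjacency
from tnlm.parcellation import Parcellation

__all__ = [
    "MatchResult",
    "TaskLabelMap",
    "BoundaryCountMap",
    "stable_match",
    "concordance",
    "build_task_label_map",
    "agreement_fraction",
    "cumulative_boundary_map",
    "z_threshold_pvalue",
]


@dataclass
class MatchResult:
    """One-to-one correspondence between the labels of two parcellations.

    ``mapping`` maps a label of side A to its matched label of side B;
    ``overlap`` gives the shared vertex count per matched pair.  Labels of
    the larger side that found no partner are listed unmatched.
    """

    mapping: dict[int, int]
    overlap: dict[int, int]
    unmatched_a: list[int]
    unmatched_b: list[int]


@dataclass
class TaskLabelMap:
    """Per-vertex task label; 0 means unlabeled.

    Labels 1..n_tasks index the input Z-map list (task-pair contrasts).
    """

    labels: np.ndarray
    z_thresh: float
    min_patch: int
    legend: dict[int, str] = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]


@dataclass
class BoundaryCountMap:
    """Per-triangle count of boundary occurrences across parcellations."""

    counts: np.ndarray
    n_parcellations: int


def z_threshold_pvalue(z: float) -> float:
    """One-tailed uncorrected p-value of a Z-score threshold (upper tail)."""
    return float(scipy.stats.norm.sf(z))


def _labels_of(p) -> np.ndarray:
    return np.asarray(getattr(p, "labels", p), dtype=np.int64)


def _overlap_table(la: np.ndarray, lb: np.ndarray):
    """Contingency counts between two label arrays on the same vertices."""
    a_ids = np.unique(la)
    b_ids = np.unique(lb)
    a_pos = {int(a): i for i, a in enumerate(a_ids)}
    b_pos = {int(b): i for i, b in enumerate(b_ids)}
    tab = np.zeros((a_ids.size, b_ids.size), dtype=np.int64)
    np.add.at(
        tab,
        (
            np.searchsorted(a_ids, la),
            np.searchsorted(b_ids, lb),
        ),
        1,
    )
    return a_ids, b_ids, a_pos, b_pos, tab


def stable_match(parcA, parcB) -> MatchResult:
    """Gale-Shapley stable matching of labels by overlap vertex count.

    Both sides rank counterpart labels by decreasing overlap, ties broken
    by smaller label ID; side A proposes.  Deterministic.  The returned
    matching admits no blocking pair under these preference lists.
    """
    la, lb = _labels_of(parcA), _labels_of(parcB)
    if la.shape != lb.shape:
        raise ValueError(
            f"vertex sets differ: {la.shape[0]} vs {lb.shape[0]}"
        )
    a_ids, b_ids, a_pos, b_pos, tab = _overlap_table(la, lb)

    # preference order: overlap desc, then smaller counterpart label id
    def prefs(ids, scores):
        order = sorted(range(len(ids)), key=lambda j: (-scores[j], ids[j]))
        return [int(ids[j]) for j in order]

    a_prefs = {int(a): prefs(b_ids, tab[i]) for i, a in enumerate(a_ids)}
    b_rank = {
        int(b): {
            a: r for r, a in enumerate(prefs(a_ids, tab[:, j]))
        }
        for j, b in enumerate(b_ids)
    }

    free = list(map(int, a_ids))
    next_prop = {int(a): 0 for a in a_ids}
    engaged_b: dict[int, int] = {}  # b -> a
    while free:
        a = free.pop(0)
        if next_prop[a] >= len(a_prefs[a]):
            continue  # a exhausted its list (stays unmatched)
        b = a_prefs[a][next_prop[a]]
        next_prop[a] += 1
        if b not in engaged_b:
            engaged_b[b] = a
        else:
            rival = engaged_b[b]
            if b_rank[b][a] < b_rank[b][rival]:
                engaged_b[b] = a
                free.append(rival)
            else:
                free.append(a)
    mapping = {a: b for b, a in engaged_b.items()}
    overlap = {
        a: int(tab[a_pos[a], b_pos[b]]) for a, b in mapping.items()
    }
    unmatched_a = [int(a) for a in a_ids if int(a) not in mapping]
    matched_b = set(mapping.values())
    unmatched_b = [int(b) for b in b_ids if int(b) not in matched_b]
    return MatchResult(
        mapping=mapping,
        overlap=overlap,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
    )


def concordance(parcA, parcB) -> float:
    """Fraction of vertices agreeing after optimal one-to-one relabeling.

    The first-listed parcellation proposes in the matching.  Vertices
    carrying an unmatched label on either side count as disagreements.
    """
    la, lb = _labels_of(parcA), _labels_of(parcB)
    match = stable_match(parcA, parcB)
    relabeled = np.full_like(lb, -1)
    for a, b in match.mapping.items():
        relabeled[lb == b] = a
    return float(np.mean(la == relabeled))


def build_task_label_map(
    zmaps,
    mesh: SurfaceMesh,
    z_thresh: float = 3.0,
    min_patch: int = 40,
    legend: dict[int, str] | None = None,
) -> TaskLabelMap:
    """Merge per-task Z-score maps into a single labeled map.

    A vertex gets the label (1-based index into ``zmaps``) of its most
    significant supra-threshold activation, or 0 if no map reaches
    ``z_thresh`` there.  Isolated same-label patches (connected through
    mesh edges) of ``min_patch`` vertices or fewer are then removed.
    """
    if len(zmaps) == 0:
        raise ValueError("need at least one Z map")
    Z = np.vstack([np.asarray(z, dtype=np.float64) for z in zmaps])
    if Z.shape[1] != mesh.n_vertices:
        raise ValueError(
            f"Z maps cover {Z.shape[1]} vertices, mesh has {mesh.n_vertices}"
        )
    best = np.argmax(Z, axis=0)
    best_z = Z[best, np.arange(Z.shape[1])]
    labels = np.where(best_z >= z_thresh, best + 1, 0).astype(np.int64)
    labels = _remove_small_patches(labels, mesh, min_patch)
    return TaskLabelMap(
        labels=labels,
        z_thresh=z_thresh,
        min_patch=min_patch,
        legend=legend or {},
    )


def _remove_small_patches(
    labels: np.ndarray, mesh: SurfaceMesh, min_patch: int
) -> np.ndarray:
    """Set to 0 every same-label connected component of size <= min_patch."""
    import scipy.sparse.csgraph as csgraph

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # component warnings not relevant here
        adj = build_vertex_adjacency(mesh)
    out = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        idx = np.flatnonzero(labels == lab)
        sub = adj[idx][:, idx]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        sizes = np.bincount(comp, minlength=n_comp)
        for c in np.flatnonzero(sizes <= min_patch):
            out[idx[comp == c]] = 0
    return out


def agreement_fraction(task: TaskLabelMap, parc) -> dict[int, float]:
    """Per-task-label fraction captured by the matched resting-state parcel.

    The task map is side A of the stable match (unlabeled vertices,
    label 0, are excluded).  For task label l matched to parcel p the
    fraction is |{v: task(v)=l and parc(v)=p}| / |{v: task(v)=l}| -- a
    fraction of the task label, not of the parcel, so a task region fully
    inside a larger parcel still scores 1.
    """
    tl = task.labels
    pl = _labels_of(parc)
    if tl.shape != pl.shape:
        raise ValueError("task map and parcellation cover different vertices")
    labeled = tl > 0
    if not labeled.any():
        warnings.warn("task map has no labeled vertices", stacklevel=2)
        return {}
    match = stable_match(tl[labeled], pl[labeled])
    fractions: dict[int, float] = {}
    for lab, parcel in match.mapping.items():
        in_task = tl == lab
        n_task = int(in_task.sum())
        if n_task == 0:
            warnings.warn(f"task label {lab} has no vertices", stacklevel=2)
            continue
        fractions[int(lab)] = float(np.mean(pl[in_task] == parcel))
    return fractions


def cumulative_boundary_map(parcellations, mesh: SurfaceMesh) -> BoundaryCountMap:
    """Per-triangle count of boundary-triangle occurrences across inputs.

    Typically summarized across parcellations at
    K = 2..10, 15, 30, 40, 50, 60, 80 to show which borders persist across
    scales.
    """
    parcellations = list(parcellations)
    if not parcellations:
        raise ValueError("need at least one parcellation")
    counts = np.zeros(mesh.n_triangles, dtype=np.int64)
    for p in parcellations:
        counts += boundary_triangles(mesh, p)
    return BoundaryCountMap(counts=counts, n_parcellations=len(parcellations))
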