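"""Synthetic surface fields with planted functional regions.

Generates a flat square patch whose four quadrants carry internally
coherent, mutually decorrelated (or anti-correlated) time series -- the
design used to study how smoothing affects parcellation near functional
boundaries.  Each quadrant (or sub-block within a quadrant) is driven by a
latent AR(1) signal; vertices observe their region's latent plus
independent white noise, and series are standardized afterwards.

The latent model replaces region-representative recordings with a
parametric stand-in: only the correlation block structure between regions
matters to the boundary effects under study.  AR(1) with phi = 0.9 gives
the slow, low-pass character of BOLD fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from tnlm.filtering import TimeSeriesField, standardize
from tnlm.mesh import SurfaceMesh

__all__ = [
    "QuadrantSimSpec",
    "make_grid_mesh",
    "quadrant_labels",
    "simulate_quadrant_field",
    "simulate_session_pair",
]


@dataclass
class QuadrantSimSpec:
    """Parameters of the four-quadrant simulation.

    ``n``            vertices per grid edge (even, >= 4); the patch has n^2
                     vertices with unit (mm) spacing.
    ``T``            number of time samples per vertex.
    ``cross_corr``   target correlation between quadrant latent signals
                     (negative values give anti-correlated regions).
    ``noise_sd``     per-vertex white-noise standard deviation, relative to
                     the unit-variance latents (1.0 = 0 dB SNR).
    ``sub_blocks``   optional {quadrant: count} giving the number of
                     equal-width sub-blocks (split along x) whose latents
                     share the quadrant signal but are distinguishable.
    ``within_corr``  correlation between sub-block latents of the same
                     quadrant (only used when sub_blocks is set).
    ``ar_phi``       AR(1) coefficient of all latent signals.
    ``seed``         generator seed; the field is a pure function of it.
    """

    n: int = 20
    T: int = 300
    cross_corr: float = 0.0
    noise_sd: float = 1.0
    sub_blocks: dict[int, int] | None = None
    within_corr: float = 0.4
    ar_phi: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4 or self.n % 2:
            raise ValueError(f"n must be even and >= 4, got {self.n}")
        if abs(self.cross_corr) > 1:
            raise ValueError(f"|cross_corr| must be <= 1, got {self.cross_corr}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0 <= self.within_corr <= 1:
            raise ValueError("within_corr must be in [0, 1]")
        if self.sub_blocks:
            for q, c in self.sub_blocks.items():
                if q not in (0, 1, 2, 3) or c < 1:
                    raise ValueError(f"bad sub-block spec {q}: {c}")
        if self.T < 2 * self.total_latents:
            raise ValueError(
                f"T={self.T} too small for {self.total_latents} latents "
                f"(need >= {2 * self.total_latents})"
            )

    @property
    def total_latents(self) -> int:
        counts = [1, 1, 1, 1]
        if self.sub_blocks:
            for q, c in self.sub_blocks.items():
                counts[q] = c
        return sum(counts)


def make_grid_mesh(n: int, spacing: float = 1.0) -> SurfaceMesh:
    """Flat n x n vertex grid in the z = 0 plane, two triangles per cell.

    Every cell is split along the lower-left -> upper-right diagonal, so an
    interior vertex has exactly 6 neighbors and the triangulation is
    deterministic.  Vertex (row i, col j) has index i * n + j.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    vertices = np.column_stack(
        [jj.ravel() * spacing, ii.ravel() * spacing, np.zeros(n * n)]
    )
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            ll = i * n + j
            lr = ll + 1
            ul = ll + n
            ur = ul + 1
            tris.append((ll, lr, ur))
            tris.append((ll, ur, ul))
    return SurfaceMesh(vertices=vertices, triangles=np.array(tris))


def quadrant_labels(n: int) -> np.ndarray:
    """Quadrant index per grid vertex: 0 = lower-left, 1 = lower-right,
    2 = upper-left, 3 = upper-right (row-major vertex order)."""
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    return (2 * (ii >= n // 2) + (jj >= n // 2)).ravel().astype(np.int64)


def _region_labels(spec: QuadrantSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """(quadrant labels, region labels) where regions refine quadrants by
    the requested sub-block splits along x."""
    n = spec.n
    quad = quadrant_labels(n)
    region = quad.copy()
    if spec.sub_blocks:
        jj, ii = np.meshgrid(np.arange(n), np.arange(n))
        jj = jj.ravel()
        next_id = 4
        for q in sorted(spec.sub_blocks):
            c = spec.sub_blocks[q]
            if c == 1:
                continue
            in_q = quad == q
            x = jj[in_q]
            lo, hi = x.min(), x.max() + 1
            # equal-width bins along x within the quadrant
            block = np.minimum(
                ((x - lo) * c) // (hi - lo), c - 1
            )
            ids = np.concatenate([[q], next_id + np.arange(c - 1)])
            region[in_q] = ids[block]
            next_id += c - 1
    return quad, region


def _ar1(innov: np.ndarray, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) filtering of unit-variance
    innovations, column-wise over time (axis 0)."""
    T = innov.shape[0]
    out = np.empty_like(innov)
    scale = np.sqrt(1.0 - phi**2)
    out[0] = innov[0]
    for t in range(1, T):
        out[t] = phi * out[t - 1] + scale * innov[t]
    return out


def _latent_signals(spec: QuadrantSimSpec, rng: np.random.Generator):
    """Latent series per region: quadrant-level latents with the requested
    cross-correlation; sub-block latents mix the quadrant latent with an
    independent component to reach ``within_corr``."""
    T = spec.T
    c = spec.cross_corr
    C = np.full((4, 4), c)
    np.fill_diagonal(C, 1.0)
    # Cholesky of the quadrant innovation correlation (valid for c >= -1/3;
    # fall back to eigen decomposition otherwise)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(C)
        L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    quad_innov = rng.standard_normal((T, 4)) @ L.T
    quad_lat = _ar1(quad_innov, spec.ar_phi)

    quad, region = _region_labels(spec)
    region_ids = np.unique(region)
    latents = {}
    w = np.sqrt(spec.within_corr)
    w_ind = np.sqrt(1.0 - spec.within_corr)
    for rid in region_ids:
        q = int(quad[region == rid][0])
        n_blocks = (spec.sub_blocks or {}).get(q, 1)
        if n_blocks == 1:
            latents[int(rid)] = quad_lat[:, q]
        else:
            ind = _ar1(rng.standard_normal(T), spec.ar_phi)
            latents[int(rid)] = w * quad_lat[:, q] + w_ind * ind
    return latents, quad, region


def simulate_quadrant_field(
    mesh: SurfaceMesh, spec: QuadrantSimSpec
) -> tuple[TimeSeriesField, dict[str, np.ndarray]]:
    """Simulate the four-quadrant field on a grid mesh.

    Returns the standardized field and a truth dict with ``quadrant`` and
    ``region`` label arrays (regions = quadrants refined by sub-blocks).
    Bit-identical for identical seeds.
    """
    n2 = spec.n * spec.n
    if mesh.n_vertices != n2:
        raise ValueError(
            f"mesh has {mesh.n_vertices} vertices, spec.n={spec.n} needs {n2}"
        )
    rng = np.random.default_rng(spec.seed)
    latents, quad, region = _latent_signals(spec, rng)
    data = np.empty((n2, spec.T))
    for rid, sig in latents.items():
        data[region == rid] = sig
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal((n2, spec.T))
    fld = standardize(
        TimeSeriesField(data=data, mesh_checksum=mesh.checksum())
    )
    return fld, {"quadrant": quad, "region": region}


def simulate_session_pair(
    spec: QuadrantSimSpec, seed_a: int, seed_b: int
) -> tuple[TimeSeriesField, TimeSeriesField, dict[str, np.ndarray]]:
    """Two sessions with identical planted structure, independent
    realizations -- the desk-scale analogue of repeated resting scans for
    test-retest concordance experiments."""
    mesh = make_grid_mesh(spec.n)
    fa, truth = simulate_quadrant_field(mesh, replace(spec, seed=seed_a))
    fb, _ = simulate_quadrant_field(mesh, replace(spec, seed=seed_b))
    return fa, fb, truth
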