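# tnlm — temporal non-local means filtering of surface fMRI

`tnlm` denoises resting-state BOLD time series sampled on a triangulated
cortical surface while preserving the boundaries between functional
regions, and parcellates the result into functional networks. It is aimed
at researchers working with surface-sampled resting fMRI (e.g. HCP-style
`.surf.gii` / `.func.gii` data) who want edge-preserving denoising, a
linear-smoothing baseline to compare against, and quantitative evaluation
of the resulting parcellations.

## The method

Conventional smoothing on the cortex (heat-kernel / Laplace–Beltrami
filtering, the surface generalization of Gaussian smoothing) averages each
vertex with its spatial neighbors regardless of function, mixing signals
across the borders of functional areas. Temporal non-local means (tNLM)
instead weights each neighbor by the similarity of its *entire time
series*. For data d(s, τ) at vertex s and time τ the filtered signal is

    f(s, τ) = Σ_{r ∈ N(s)} d(r, τ) · w(s, r) / Σ_{r ∈ N(s)} w(s, r)

    w(s, r) = exp( −(1/T) ‖d(s) − d(r)‖² / h² )

where N(s) contains all vertices within a linked (mesh-hop) distance D of
s, and h sets how fast the weight decays with dissimilarity. Each vertex
series is first standardized to zero mean and unit variance, which makes
the squared distance equal to 2 − 2·corr(d(s), d(r)): the weight is a
monotone function of Pearson correlation, and the filter averages only
across functionally similar vertices. The weights are computed once from
the full series, so the effective kernel is identical at every time point.

Networks are identified by representing the data as a fully connected
graph with edge strength A(u, v) = exp(dᵀ(u) d(v) / T) = exp(corr(u, v))
and partitioning it with multiclass normalized cuts, which maximizes the
average normalized association

    Nassoc(V₁…V_K) = (1/K) Σᵢ [ Σ_{u,v ∈ Vᵢ} A(u,v) / Σ_{u ∈ Vᵢ, v ∈ V} A(u,v) ].

The evaluation stack puts two parcellations' labels in one-to-one
correspondence with Gale–Shapley stable matching (preference = overlap
vertex count), then measures concordance (fraction of agreeing vertices),
task-label agreement against thresholded activation maps (Z ≥ 3.0,
one-tailed p ≤ 0.00135, isolated patches of ≤ 40 vertices removed), and
cumulative boundary-triangle maps across K.

A synthetic module generates the four-quadrant simulation used to study
boundary behavior: a flat square patch whose quadrants (optionally refined
into sub-blocks) carry internally coherent, mutually decorrelated AR(1)
latent signals plus vertex-level noise, with ground-truth labels returned.

## Worked example

```python
import numpy as np
import tnlm

# four-quadrant patch: 20x20 vertices, 300 time samples, unit noise
mesh = tnlm.make_grid_mesh(20)
spec = tnlm.QuadrantSimSpec(n=20, T=300, noise_sd=1.0, seed=7)
field, truth = tnlm.simulate_quadrant_field(mesh, spec)

# tNLM filter: h = 0.72, neighborhoods of linked distance D = 5
nbrs = tnlm.linked_neighborhoods(mesh, D=5)
filtered = tnlm.standardize(
    tnlm.tnlm_filter(field, nbrs, tnlm.TNLMParams(h=0.72, D=5))
)

# N-cuts parcellation of the correlation-affinity graph into K = 4
graph = tnlm.affinity_matrix(filtered)
parc = tnlm.ncuts_partition(graph, K=4, seed=0)

from sklearn.metrics import adjusted_rand_score
print("normalized association:", round(parc.provenance["nassoc"], 4))
print("adjusted Rand vs truth:", adjusted_rand_score(truth["quadrant"], parc.labels))

boundary = tnlm.boundary_triangles(mesh, parc)
print("boundary triangles:", int(boundary.sum()), "of", mesh.n_triangles)
```

Output:

```
normalized association: 0.4307
adjusted Rand vs truth: 1.0
boundary triangles: 74 of 722
```

The normalized association is the N-cuts objective achieved by the
4-class partition; the adjusted Rand index of 1.0 means the four planted
quadrants were recovered exactly; the 74 boundary triangles are precisely
the ones straddling the two quadrant seams of the 20×20 patch.

The same pipeline is available from the shell:

```sh
tnlm simulate --n 20 --t-samples 300 --seed 7 --out sim.h5
tnlm filter --method tnlm --surface sim.mesh.h5 --field sim.h5 --h 0.72 --d 5 --out filt.h5
tnlm parcellate --surface sim.mesh.h5 --field filt.h5 --k 4 --out parc.tsv
tnlm evaluate concordance parcA.tsv parcB.tsv
```

Every command writes a `.run.json` reproducibility record (parameters,
seeds, mesh checksum). All vertex indices are 0-based, in files and in
memory.

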