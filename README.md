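# grainvuln

Grain-size scaling of climate-change vulnerability for species climatic
niches.

`grainvuln` is for macroecologists and conservation scientists who score
species' exposure-and-sensitivity to climate change from occurrence records
and gridded climate data, and who need to know how much that score depends
on the *grain size* (spatial resolution) of the environmental grids. The
package estimates a multivariate-normal climatic niche per species, scores
every location in the species' range, aggregates the climate grids across a
ladder of grain sizes (1–128 km by default), and measures how the
species-level score changes from fine to coarse grain. Everything is
validated end to end on synthetic landscapes and virtual species whose true
niches are known.

## The metric

A species' niche is summarised by its center μ and covariance Σ over n
climate variables (here: breeding-season temperature and precipitation).
For a location with current condition x_t0 and future condition x_t1, the
**vulnerability score** is the change in squared Mahalanobis distance from
the niche center:

    VS = (x_t1 − μ)ᵀ Σ⁻¹ (x_t1 − μ) − (x_t0 − μ)ᵀ Σ⁻¹ (x_t0 − μ)

Positive VS means the climate is moving the location away from the niche
center; a population already at the niche margin is penalised more than one
at the center for the same exposure (in one dimension with σ = 1, a +1
shift scores 1² − 0² = 1 at the center but 3² − 2² = 5 at 2σ out). VS
partitions additively into one term per variable,
(d²_{k,t1} − d²_{k,t0})/σ²_k, plus an **interaction** term contributed by
the correlations among niche axes.

Species-level vulnerability is the **expected vulnerability score**

    EVS = Σ_i w_i VS_i / Σ_i w_i,     w_i = exp(−MD²(x_{i,t0}))

over range pixels, with Gaussian-kernel suitability weights that discount
locations whose current climate is already implausible for the species
(likely false presences within coarse range maps). Because MD² of
multivariate-normal data follows a χ² law with n degrees of freedom, VS
increases from 0 have a probabilistic reading: 100·P(χ²_n ≤ VS) is the
percent suitability drop relative to the niche center.

**Grain dependence** is EVS at the finest grain minus EVS at the coarsest;
positive values mean coarse-grain data underestimate vulnerability.

## Worked example

```python
import grainvuln as gv
from grainvuln.scaling import GrainLadder, PipelineParams

# a synthetic world with a known specialist species on an autocorrelated
# temperature/precipitation landscape, plus its sampled occurrences
world, species, occ = gv.make_world("specialist", seed=1, dims=(32, 32))
rng_poly = gv.buffer_merge_range(None, occ[["x_km", "y_km"]].to_numpy(), 10.0)

params = PipelineParams(
    filter=gv.FilterParams(year_range=(2001, 2005)),
    n_reps=10, thin_km=0.0,
)
curve = gv.scaling_curve(
    "specialist", occ, world.stacks, world.t0, world.t1, rng_poly,
    GrainLadder((1, 2, 4, 8)), params, seed=1,
)
for grain, res in curve.results.items():
    print(f"grain {grain:>2} km  EVS = {res.evs:.3f}  "
          f"95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]  ({res.n_pixels} px)")
print(f"grain dependence (1 km − 8 km): {curve.grain_dependence:.3f}")
```

Output:

```
grain  1 km  EVS = 3.398  95% CI [2.889, 3.889]  (1024 px)
grain  2 km  EVS = 0.869  95% CI [0.620, 1.130]  (256 px)
grain  4 km  EVS = 0.511  95% CI [0.099, 0.832]  (64 px)
grain  8 km  EVS = 0.540  95% CI [-0.018, 1.291]  (16 px)
grain dependence (1 km − 8 km): 2.857
```

The narrow-niche specialist scores far higher at 1 km than at 8 km: the
positive grain dependence (≈2.9 vulnerability units) means a coarse-grain
assessment would substantially underestimate this species' vulnerability.
Each EVS is the suitability-weighted mean pixel score at that grain, with a
percentile-bootstrap 95% interval over pixels; the niche is re-estimated at
every grain from occurrences re-annotated on the aggregated grids.

A command-line interface mirrors the library
(`grainvuln synth make`, `grainvuln scale-run`, `grainvuln grids morani`,
…); see `grainvuln --help`.

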