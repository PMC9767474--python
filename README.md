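# allelewave

Spatiotemporal maximum-likelihood inference of the spread of a beneficial
allele from geolocated, time-stamped genotype data (ancient and modern).

The frequency surface p(x, y, t) of the allele evolves on a geographic
lat/lon grid under a diffusion–advection–reaction equation

```
∂p/∂t = ½σx² ∂²p/∂x² + ½σy² ∂²p/∂y² + vx ∂p/∂x + vy ∂p/∂y + γ(p, s, d)
```

with logistic-type local growth γ (additive selection d = 2s by default),
no-flux boundaries at coastlines, absorbing boundaries at the map edge, and
a founder frequency p₀ = 1/(2DA) in the origin cell. Genotype observations
— beagle-style genotype-likelihood triplets, hard diploid calls, or
pseudohaploid single-allele calls — are evaluated against the solved
surface under a Hardy–Weinberg sampling model, and selection (s), dispersal
(σx, σy), advection (vx, vy) and the origin cell are fitted by maximum
likelihood in two epochs (split at 5000 years BP by default) via Latin
hypercube starts → simulated annealing → L-BFGS-B, with Wald confidence
intervals from the observed Fisher information.

A spatially explicit individual-based forward simulator (local mate choice,
Gaussian offspring dispersal, local logistic regulation) and deterministic
surface-sampling designs generate validation data.

## Layout

| module | contents |
|---|---|
| `allelewave.landscape` | grid, land mask (ESRI ASCII topography), haversine metric, point→cell lookup |
| `allelewave.pde` | epoch parameters, method-of-lines solver (LSODA, analytic banded Jacobian), surface queries |
| `allelewave.likelihood` | observation types, genotype priors, dataset log-likelihood |
| `allelewave.inference` | bounds, LHS starts, simulated annealing, L-BFGS-B refinement, Fisher CIs, age profiling |
| `allelewave.simulate` | sampling designs, surface sampling, pseudohaploidisation, forward simulator |
| `allelewave.io` / `allelewave.cli` | sample tables, beagle GLs, NetCDF surface export, JSON results, YAML config, CLI |

## CLI

All subcommands take `--config run.yaml --seed N [--threads N] [--verbose]`:

```
allelewave surface     --config run.yaml --out surface.nc
allelewave sample      --config run.yaml --seed 1 --out samples.tsv
allelewave forward-sim --config run.yaml --seed 1 --out records.tsv \
                       --samples-out samples.tsv --n-samples 1040
allelewave fit         --config run.yaml --seed 1 --samples samples.tsv --out fit.json
allelewave profile-age --config run.yaml --samples samples.tsv \
                       --ages 6000,7441,9000 --out profile.json
```

A config file has `map` (bbox, resolution, optional ESRI ASCII topography,
land bridges), `model` (variant A/B/C, allele age, generation time, epoch
boundary, founder density, origin), optional `params` (epoch parameters for
surface/sample generation), `bounds`, `optimizer`, `design` and `forward`
sections; see `tests/test_io_cli.py` for a complete example.

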