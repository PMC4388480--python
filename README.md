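# coorient

Quantifying the **correlation and consistency of orientation** between two
co-localized biological constructs — e.g. sarcomeric Z-lines and actin
fibrils in cardiac tissue — from paired fields of axial (period-π) angles.

Colocalization tells you two constructs occupy the same space; it says
nothing about whether they are *oriented* with respect to each other.
`coorient` implements the co-orientational order parameter (COOP), an
extension of the classical orientational order parameter (OOP) from liquid
crystal physics, together with its analytic bounds, normalization, error
and power analysis, synthetic validation generators, and a grid-based
weighted pipeline for image-scale data.

## The model

Each construct is a set of pseudo-vectors (a direction without sense:
θ and θ + π are identical). For a single construct *K* with unit
pseudo-vectors **k**ᵢ = (cos θᵢ, sin θᵢ):

    𝕋_K  = 2⟨𝐤𝐤ᵀ⟩ − 𝕀            (mean order tensor)
    OOP_K = max eigenvalue(𝕋_K)     ∈ [0, 1]

OOP = 0 for an isotropic construct, 1 for a perfectly aligned one; the
corresponding eigenvector (the **director** n̂) is the mean orientation.

For two index-paired constructs *P* and *Q*, each pair contributes a
relative-orientation vector

    𝐟ᵢ = (𝐩ᵢ·𝐪ᵢ, |𝐩ᵢ×𝐪ᵢ|) = (cos(βᵢ−αᵢ), sin(βᵢ−αᵢ)),

and the COOP is the same eigenvalue construction applied to the field *F*:

    𝕋_PQ = 2⟨𝐟𝐟ᵀ⟩ − 𝕀,   COOP = max eigenvalue(𝕋_PQ) ∈ [0, 1].

The COOP is invariant to π-flips of any pseudo-vector, to swapping P and
Q, and to a global rotation of either field; its director encodes the mean
inter-construct angle θ₀. Two reference arrangements bound the "normal"
range:

* **uncorrelated** (P, Q independent): COOP_u = OOP_P · OOP_Q
* **correlated** (Q = P + independent random noise): COOP_c = min(OOP)/max(OOP)

and the **normalized COOP** = (COOP − COOP_u)/(COOP_c − COOP_u) places a
measurement on that slider: < 0 anti-correlated, 0 uncorrelated,
1 correlated, > 1 ultra-correlated. Structured counter-examples on both
sides exist (two-mode mixtures below COOP_u; sorted pairings above
COOP_c) and are provided as generators.

The `stats` module propagates OOP measurement error into the bounds
(delta method) and inverts a Welch two-sample t-test of COOP_u = COOP_c to
give the maximum tolerable OOP error at a given sample size and the
minimum sample size at a given error. The `grid` module implements the
image-scale pipeline: partition co-registered angle fields into grid
squares, take each square's director as its representative pseudo-vector,
and weight squares by W_i = OOP_P,i · OOP_Q,i · ρ_P,i · ρ_Q,i (ρ = angle
density) so sparse, disordered or partial squares are down-weighted.

## Worked example

```python
import numpy as np
import coorient as co
from coorient import synth

# a moderately organized construct plus calibrated noise (target OOP_Q = 0.4)
spec = synth.TruncatedGaussianSpec(mean=0.7, sigma=synth.sigma_for_oop(0.8))
pf = synth.gen_correlated_pair(spec, target_oop_q=0.4, n=100_000, seed=3)
r = co.coop(pf)
print(f"OOP_P={r.oop_p:.3f} OOP_Q={r.oop_q:.3f}")
print(f"COOP={r.coop:.3f} in [COOP_u={r.coop_u:.3f}, COOP_c={r.coop_c:.3f}]")
print(f"normalized COOP={r.normalized_coop:.3f}")
```

prints

```
OOP_P=0.800 OOP_Q=0.403
COOP=0.505 in [COOP_u=0.322, COOP_c=0.504]
normalized COOP=1.005
```

— the noise-coupled pair sits at its correlated bound (normalized COOP ≈ 1
up to sampling error), exactly what the construction promises: Q is P plus
independent noise, so the constructs are maximally correlated given their
individual organizations.

The same analysis is available from the shell:

```sh
coorient simulate truncated-gaussian-pair --correlated -n 100000 --seed 3 --out pair
coorient coop pair.csv
coorient power --spacing 0.01 -n 4 --sigma 0.04 --out power   # error/sample-size surfaces
```

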