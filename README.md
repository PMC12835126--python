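# dualobserver

Tools for choosing inter-electrode distances that maximize the number of
well-isolated single units per recording channel in extracellular
electrophysiology. The package implements the *dual observer model*: a
geometrical description of how spike-sorting yield depends on electrode
spacing, together with exact and Monte-Carlo coverage-volume computation,
the closed-form optimal pitch for linear probes, and a grid-search
procedure that recovers the model parameters from units-per-channel
measurements across spatially downsampled probe configurations. It is
aimed at electrophysiologists and probe designers deciding which subset of
a high-density array to record from, and at methodologists studying how
sorter performance varies with electrode density.

## The model

Each electrode observes a sphere of radius *R* (the observation radius)
within which a neuron's spikes are large enough to sort. For a layout of
*M* electrodes, let *V*<sub>single</sub> be the tissue volume covered by
exactly one sphere and *V*<sub>double</sub> the volume covered by at least
two. The expected number of well-isolated units is

&nbsp;&nbsp;&nbsp;&nbsp;*N* = *p*<sub>single</sub> (*V*<sub>single</sub> + 2*G* *V*<sub>double</sub>)

where *p*<sub>single</sub> is the density of sortable units (per mm³) and
*G* = *p*<sub>double</sub>/(2 *p*<sub>single</sub>) is the gain factor:
*G* = 0.5 means a second view of a neuron adds nothing, *G* > 1 means two
electrodes cooperating beat the volume lost to their overlap. Efficiency
*E* = *N*/(*p*<sub>single</sub> *M* *V*₁) compares a configuration to *M*
independent electrodes; for an evenly spaced linear array it has a closed
form in the equal-sphere lens volume *V*₂(*R*, *D*), and for *G* > 1 a
unique interior maximum at

&nbsp;&nbsp;&nbsp;&nbsp;*D*<sub>opt</sub> = *R* √[(4*MG* − 12*G* + 4)/(7*MG* − 3*M* − 15*G* + 7)]

which ranges from *R* (at *G* = 1) down to √(4/7) *R* ≈ 0.76 *R* for large
*G* and *M*. The peak efficiency is well approximated by
*E*<sub>opt</sub> ≈ 0.76 *G* + 0.16.

Fitting works on the *shape* of the units-per-channel profile across probe
configurations of different pitch: a cosine-similarity grid search over
(*R*, *G*) (defaults 1–200 μm × 0.01–4), with *p*<sub>single</sub>
recovered afterwards as the least-squares scale of the winning pattern.
Coverage volumes are exact for linear layouts and Monte-Carlo (seeded,
10⁷ points by default) for zig-zag layouts.

## Worked example

Generate a synthetic units-per-channel dataset from known parameters on
the rodent probe series (256/128/64/32/16 channels at 8.5–96 μm pitch),
then fit it back:

```bash
dualobserver simulate --r 42 --g 1.64 --p-single 2122 \
    --config-set rodent --n-recordings 6 --noise none --seed 7 \
    --mc-points 1000000 --out-csv yields.csv
dualobserver fit yields.csv --preset rodent --mc-points 1000000 --mc-seed 0
```

The fit report (abridged) is

```json
{
 "params": {"R_um": 42.0, "G": 1.64, "p_single_per_mm3": 2121.03},
 "similarity": 0.9999967,
 "per_M": [{"M": 32, "D_opt_um": 36.746, "D_opt_display": "37 um",
            "E_opt_approx": 1.4064, "E_opt_exact": 1.4302,
            "opt_units_per_channel": 0.926, "regime": "interior_optimum"}],
 "experimental": {"best_pitch_used_um": 48.0,
                  "high_density_units_per_channel": 0.251,
                  "max_units_per_channel_achieved": 0.851,
                  "improvement_vs_high_density": 3.687}
}
```

The generating parameters (R = 42 μm, G = 1.64, p = 2122/mm³) are
recovered on the grid cell they were drawn from (p to 0.05%; the residual
comes from independent Monte-Carlo seeds on the zig-zag configuration).
For a 32-channel linear probe these parameters give an optimal pitch of
37 μm, a peak efficiency of 1.41, and 0.93 units per channel — roughly
3.7× the per-channel yield of the densest (8.5 μm) configuration.

The closed-form optimum is also available directly:

```bash
$ dualobserver optimize --r 42 --g 1.64 --m 32 --p-single 2122
D_opt = 37 um (exact 36.75 um)
E_opt = 1.41 (approx; exact 1.43)
optimal units/channel = 0.93
```

Other subcommands: `downsample` (spatial downsampling of probe layouts
with a pitch table), `volumes` (coverage decomposition of a layout at a
given radius), `simulate` (synthetic datasets, lognormal or Poisson
noise). All of this is equally available as a Python API
(`import dualobserver`).

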