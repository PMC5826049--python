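# embryodyn

Quantitative analysis of cytoskeletal dynamics in syncytial *Drosophila*
embryos, built for experiments that acutely inactivate a motor protein
(e.g. by protease cleavage of an engineered site in its neck) and ask what
changes in interphase. The package quantifies four readouts from time-lapse
fluorescence recordings:

1. **Centrosome fluctuations** — the apparent diffusion of centrosomes
   about their slow drift, a proxy for the stiffness of the cortical
   microtubule-aster network.
2. **Nuclear-array topology** — neighbor-count distributions and the
   irregularity of internuclear distances in the near-hexagonal cortical
   nuclear array.
3. **Depletion kinetics** — the half-life of GFP-tagged protein loss after
   protease injection, and stripe-depletion ratios for striped protease
   expression along the body axis.
4. **Phenotype proportions** — per-embryo aggregation of classified
   spindle counts (normal/abnormal) with across-embryo mean ± s.d.

A seeded synthetic-data generator emulates each kind of recording with
known ground truth, so the full pipeline is testable without microscopy
data.

## The statistics at the core

**Fluctuation parameter.** For centrosome *i* sampled at positions
$\mathbf{r}_i(t_j)$ on a uniform grid ($\Delta t = 1$ s by default), the
slow drift $\bar{\mathbf{r}}_i(t_j)$ is a centred moving average over a
minute-scale window (60 s default). With residuals
$\mathbf{u}_i = \mathbf{r}_i - \bar{\mathbf{r}}_i$, the per-step
fluctuation at lag $\tau = \ell\,\Delta t$ is

$$D_i(t_j) = \frac{\lvert \mathbf{u}_i(t_j+\tau) - \mathbf{u}_i(t_j)\rvert^2}{4\tau},$$

and $D_i$ is its time average over steps whose drift window is
untruncated. $D_i$ has units of µm²/s and reads as the apparent 2-D
diffusion constant of the centrosome about its drift. Conditions are
compared by the fold change of the mean $D$ and a two-sided pooled-variance
Student's *t*-test; ensembles are summarised as box statistics (quartiles,
min/max whiskers).

**Nuclear-array regularity.** Neighbors are Delaunay-adjacent nuclei
(long spurious edges pruned at 2× the median edge length). Nuclei whose
Voronoi cell is unbounded or clipped by the field edge are excluded as
boundary. Reported are the proportions of interior nuclei with
{<5, 5, 6, 7, >7} neighbors and the irregularity

$$\sigma/\mu = \frac{\operatorname{sd}(\text{neighbor distances})}{\operatorname{mean}(\text{neighbor distances})},$$

which is 0 for a perfect lattice. Conditions are compared embryo-wise by
Student's *t*-test.

**Depletion kinetics.** Total background-subtracted fluorescence is fitted
with $I(t) = I_\infty + (I_0 - I_\infty)e^{-kt}$ and the half-life
$t_{1/2} = \ln 2 / k$ is reported.

## Worked example

Simulate a crosslinked ("control": tethered centrosomes, relaxation time
20 s) and a free ("depleted", threefold apparent diffusion) condition,
measure fluctuations, and compare:

```console
$ embryodyn simulate --kind trajectories --seed 7 --n-particles 100 \
    --tethered --true-d 0.01 --relaxation-time 20 --out control
$ embryodyn simulate --kind trajectories --seed 8 --n-particles 100 \
    --free --true-d 0.0293 --out depleted
$ embryodyn fluctuation --input control/trajectories.csv --out D_control.csv
100 particles analyzed, 0 excluded; mean D = 9.781e-03 µm²/s
$ embryodyn fluctuation --input depleted/trajectories.csv --out D_depleted.csv
100 particles analyzed, 0 excluded; mean D = 2.878e-02 µm²/s
$ embryodyn compare --a D_control.csv --b D_depleted.csv --out comparison.json
fold change = 2.942, t = -86.402, p = 3.73e-159
```

The control's mean D of 0.0098 µm²/s is the tether's *apparent* diffusion
at lag 1 s ($D\tau(1-e^{-\Delta t/\tau})/\Delta t$, slightly below the
microscopic 0.01 µm²/s), and the free condition was simulated at three
times that value; the measured fold change of 2.94 recovers it. Depletion
kinetics work the same way:

```console
$ embryodyn simulate --kind decay --seed 7 --half-life 1800 --out decay
$ embryodyn kinetics --input decay/decay.csv --out fit.json --no-plateau
t_half = 1805.3 s (30.1 min)
```

`embryodyn run --seed N --out DIR` executes every stage on synthetic
two-condition data and writes `report.json` plus per-stage tables; reruns
with the same seed are byte-identical. The equivalent library surface
lives in `embryodyn.synthetic_data`, `.tracking`, `.fluctuation`,
`.nuclear_array`, `.kinetics` and `.pipeline`.

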