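# cordquant

Quantifying neuronal survival in histological sections of the injured
spinal cord: neuron identification, multi-rater consensus, atlas
registration and region-wise survival statistics — with a synthetic
section generator so the entire chain is testable against known truth.

## The problem

After a contusive spinal cord injury (SCI), secondary neuronal death
spreads outward from the epicenter. The standard readout is
histological: transverse sections are stained for the neuronal marker
NeuN and the nuclear dye DAPI, neurons are identified and counted per
section, sections are registered to a reference atlas so counts can be
broken down by Rexed lamina (L1–L10) and named nuclei (Clarke's dorsal
nucleus D, intercalated ICI, intermediomedial IMM, intermediolateral
IML, lumbar dorsal commissural LDCom), and injured counts are expressed
as a percentage of the uninjured control. Every step of that chain has
methodological pitfalls — raters disagree, thresholds pick up
autofluorescent artifacts, registration is deformable — and `cordquant`
implements the chain together with the statistics that quantify those
pitfalls.

The package is aimed at labs doing section-level neuron counting who
want reproducible, scriptable versions of the usual semi-manual steps,
plus a simulation harness to validate parameter choices.

## What it computes

**Detection.** Two routes to a point set of neurons per section:
a threshold macro (histogram threshold on the NeuN channel → optional
nuclear-colocalisation requirement → grey-matter mask → 8-connected
components → optional watershed split → discard particles with area
≤ 25 µm²), and a probability-map rule for classifier output (particles
above 25 µm² composed of pixels above 50 % probability).

**Consensus.** K analyses of one section are overlapped by a greedy
distance-sorted matcher (one point per source per object, all points of
an object pairwise within the linking radius, default 10 µm). Each
object gets an agreement class k ∈ {0..K}; the consensus reference
count weights objects by k/K:

    RNN = Σ_objects k/K  =  (1/K) Σ_analysts count_a .

**Agreement statistics.** Bland–Altman limits of agreement for repeated
or cross-analyst counts, `bias ± 1.96·SD(a−b)`; Pearson correlation of
method counts against the consensus; OLS models of the count
disagreement against candidate explanatory variables compared by
F-tests and adjusted R².

**Registration.** Thin-plate-spline interpolation through landmark
pairs, `f(x) = A·x̃ + Σ wᵢ U(‖x−xᵢ‖)` with `U(r) = r² log r²`; atlas
regions are densified, warped into section space, and detections are
assigned by point-in-polygon with a deterministic boundary tie-break.

**Quantification.** Sections × regions count matrix; survival percent
`100 · count / median(control counts)` per region and for whole
sections; distance profiles of median survival; Kruskal–Wallis tests
(chi-square or permutation p).

**Simulation.** A toy atlas (butterfly grey matter, laminar bands plus
nuclei) and a generator that draws neurons as a per-region Poisson
process thinned by an injury survival gradient — defaults follow a
gradient of ~2.3 % survival at 0.6 mm from the epicenter rising ~20
percentage points per 0.2 mm to a 40 % plateau at 1.0–1.2 mm — renders
two-channel images with staining-gain variability, artifacts and noise,
and simulates imperfect observers (misses, false positives, jitter).

## Worked example

`examples/06_survival_gradient.py` runs the whole chain on a small
synthetic cohort (3 control sections, 2 injured individuals per
distance):

```
control reference: median 423.0 neurons/section

median whole-section survival vs distance to epicenter:
 distance_mm  median_total_survival_pct  increment_pct
         0.6                   2.718676            NaN
         0.8                  24.349882      21.631206
         1.0                  45.035461      20.685579
         1.2                  46.335697       1.300236

Kruskal-Wallis across distances: H = 6.00, p = 0.112
(generating curve: 2.3%, 20%, 40%, 40% at 0.6, 0.8, 1.0, 1.2 mm)
```

Reading it: neuronal loss is near-total at 0.6 mm (~2.7 % of the
control median), recovers by roughly 20 percentage points per 200 µm,
and plateaus around 45 % — the pipeline's estimate of the survival
gradient the cohort was generated with. The other examples each
demonstrate one capability (simulation, detection, consensus, agreement
statistics, registration) and print a line explaining their numbers.

A `cordquant` CLI mirrors the stages (`simulate`, `detect`, `probmap`,
`match`, `agree`, `stats`, `register`, `assign`, `quantify`, `run`);
`cordquant run config.yaml --out results/` drives a full study from a
YAML config and writes CSV/JSON outputs with provenance.

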