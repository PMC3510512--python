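# Methods

## Model and procedure

A gene with a tandem-UTR poly(A) site expresses a short isoform
(abundance S) and a long isoform (abundance L). An array probe lying
transcript-5′ of the internal cleavage position hybridizes to both
isoforms; its expected signal is proportional to S + L. A probe
between the internal (proximal, P-pA) and the terminal (distal, D-pA)
site sees only the long isoform, ∝ L. The within-array ratio of
region means,

    R = mean_prox / mean_dist  ∝  (S + L) / L,

is therefore a monotone readout of isoform mix, and the treated/control
contrast

    F = R_treated / R_control
      = [(S_t + L_t) / L_t] / [(S_c + L_c) / L_c]

isolates the change in mix: a pure expression change (S and L scaled
equally) gives F = 1, while a shift toward the proximal site gives
F > 1. Per-series folds from independent datasets are combined as
their product; the default flag rule additionally requires each series
to individually reach the threshold, so a single aberrant dataset can
neither create nor rescue a candidate.

Key modelling assumptions:

- **Linear hybridization.** Probe signal is proportional to target
  abundance times a probe-specific affinity. Affinities cancel within
  a region mean only approximately (they weight the mean), but cancel
  exactly in F because the same probes enter R in both conditions.
- **Raw intensities, no normalization.** R is a within-array ratio, so
  per-array multiplicative factors (labelling yield, scanner gain)
  cancel exactly; this is verified as an invariance test. Additive
  background is *not* modelled or corrected — strong background would
  compress R toward 1 and attenuate F (a known limitation).
- **Site handling.** Probes overlapping the cleavage position are
  excluded from both regions rather than assigned by midpoint, so the
  ratio never mixes isoform-specific with shared signal. Each internal
  site of a multi-site probe set is evaluated independently; the
  candidate table represents each probe set by its best-scoring site.

## Parameters

| Parameter | Default | Units / meaning |
|---|---|---|
| `threshold` | 1.5 | per-series fold ratio; the classical cutoff for calling a ratio change on expression arrays |
| `min_per_side` | 1 | probes required on each flank for a split; raise to 2+ for robustness (many real splits have only 2 distal probes) |
| `require_all_series` | True | consistency rule; `False` flags on product ≥ threshold^n_series |
| `region_summary` | mean | arithmetic mean on the linear scale; `median`/`trimmed` available for robustness studies |
| `group_summary` | geometric | replicate ratios are multiplicative, so the geometric mean is the natural location estimate; arithmetic available |

Coordinates are 0-based half-open (BED convention) internally; 1-based
fully-closed TSVs are converted on read (`one_based`/`--one-based`).
A position exactly at P-pA classifies as long-isoform-specific and one
exactly at D-pA as outside (`p_pa_inclusive` flips the former); both
conventions are explicit choices where annotation practice varies.

## Synthetic data

`SimConfig` defaults model the screen's intended operating regime:
three independent series (as when combining three expression datasets)
of 3 treated vs 3 control arrays; 200 probe sets of 11 tiled 25-mers;
every set carries an internal site and half carry a planted event
(`frac_event=0.5`); control abundances S = L = 200 intensity units;
treatment doubles total abundance (`effect_total=2`) and halves the
long-isoform fraction (`effect_long_frac=0.5`), giving closed-form
F = 2 — a realistic, detectable-but-not-trivial effect; log-normal
probe affinities with log-SD 0.3 and multiplicative log-normal noise
with CV 0.2, both typical inter-probe/inter-replicate spreads for 3′
arrays; per-array scale factors log-uniform in [0.5, 2].

Intensity of probe p on array a:

    I[p, a] = affinity_p · scale_a · abundance(p, condition(a)) · noise[p, a]

Affinities are drawn once (chip properties shared by all arrays and
series) and normalized to mean 1; noise CV is converted to a log-scale
SD via σ² = ln(1 + CV²) with mean-1 correction, so `noise_cv=0` and
`affinity_sd=0` reproduce the closed form to machine precision.

What the generator does **not** emulate: additive/optical background,
probe-sequence cross-hybridization, spatial artifacts, non-linear
saturation, inter-series platform differences, and genes whose two
isoforms change by mechanisms other than a fraction shift. Passing
tests therefore demonstrate the statistical behaviour of the
ratio-of-ratios screen under its own model — not performance on any
real dataset, where background and cross-hybridization will reduce
sensitivity.

`random_annotation` additionally generates irregular probe/site
geometries (overlapping probes, sites outside the probed span) solely
to stress-test the partition against a brute-force per-base oracle.

## Numerical and design choices

- Ratios and folds are computed in linear space; only diagnostics use
  logs. All quantities are finite because intensities are validated
  strictly positive (non-positive values fail loudly; nothing is
  imputed).
- Ranking ties are broken lexicographically by probe-set id
  (stable mergesort), making reports byte-identical across runs.
- The product combination treats series symmetrically and is
  permutation-invariant; with the all-series rule the product is a
  ranking statistic only.
- No multiple-testing correction is applied: the screen is a
  threshold/ranking filter by design. Operating characteristics
  (sensitivity, non-event flag rate) are measured by simulation in the
  acceptance script rather than derived analytically.
- Problem sizes in tests and the acceptance script (200 probe sets,
  100 randomized annotations, 3×3v3 arrays) were chosen as the
  smallest sizes at which the measured operating characteristics are
  stable across seeds.

## Known limitations

- Screens only what the chip design allows: probe sets with no probe
  between P-pA and D-pA are unsplittable, and two distal probes (a
  common real geometry) make R noisy — `min_per_side` exists for this.
- A fold threshold on F cannot distinguish 3′-UTR shortening from
  distal-probe-specific signal loss of other origin (e.g. alternative
  terminal exons); candidates need orthogonal confirmation, which is
  why the ΔΔCq and in-silico PCR utilities are included.
- The in-silico PCR is exact-match bookkeeping (no mismatches, no
  thermodynamics) and the ΔΔCq utility assumes externally supplied
  reaction efficiencies in (1, 2].
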