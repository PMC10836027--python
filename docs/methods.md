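# Methods

`cpdesign` implements a disorder-guided strategy for choosing where to open
the chain when designing circular permutants (CPs) of a globular protein,
together with the melting-curve analytics used to measure the stability of
the resulting variants. This note records the models, the numerical choices,
and what the synthetic generators do and do not emulate.

## The design model

A circular permutant joins a protein's native N- and C-termini through a
short linker and opens the backbone at a new position. The working
hypothesis is local: the destabilization caused by the cut is governed by
how strongly the cut region is held by intra-protein contacts, and a
per-residue intrinsic-disorder predictor — run on the *folded* protein's
sequence — reads out exactly that local "weakness". Cutting where the
disorder score is low should cost little stability; cutting where it is high
frees a poorly stabilized segment, sheds contacts and gains configurational
entropy. The package therefore ranks candidate cut sites by ascending
disorder score and predicts an inverse correlation between site score and
the measured melting temperature of the corresponding permutant.

### Circular profiles (the triplication trick)

Disorder predictors process linear chains and systematically inflate scores
near both termini — an artifact for a permutant, whose original termini are
covalently joined. `disorder.triplicate` builds a three-fold tandem repeat of
the sequence; the predictor is run on the repeat; and
`disorder.circularize_profile` reads back the central copy, every residue of
which sees a full sequence context on both sides. The resulting profile is
flagged `is_circular`, and windowed operations on it wrap around the join
rather than truncating. For any predictor whose score at a residue depends
only on a window of neighbours smaller than the chain, the circular profile
is exactly rotation-equivariant; the test suite checks this bitwise for the
bundled fallback predictor.

### Site selection

Candidate sites are restricted to glycines (no side-chain interactions are
lost at the new termini) in loops (no regular secondary-structure element is
cut). `sites.select_cleavage_sites` applies three ordered filters to the
glycine inventory — loop class, terminal exclusion, proximity
de-duplication — and every glycine is returned with its status and the first
filter that rejected it, so a selection is auditable.

Parameter defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `terminal_margin` | 12 residues | cuts this close to an original terminus barely change the topology and were excluded from the reference series |
| `min_separation` | 8 residues | two glycines in the same loop are duplicate candidates; one is kept |
| `proximity_keep` | `lowest_score` | the deterministic tie-break that best serves the stability objective; `lowest_position` is available |

Secondary structure comes from a DSSP file (8-class reduced as H,G,I→H;
E,B→E; everything else→L) or a plain H/E/L string. The loop filter is purely
geometric; no energetic criterion is applied.

### Permutant construction

`permute.build_permutant` places the cut immediately N-terminal to the
chosen residue, so the named glycine becomes the new N-terminus:
`parent[new_start..last] + linker + parent[first..new_start-1]`. The default
linker is Gly-Gly-Gly. One construct of the reference series opens one
residue upstream of its annotated glycine; this is reproduced through an
explicit per-site offset (`offsets={211: -1}`) rather than by changing the
cut convention, which matches the other five constructs. Bidirectional
coordinate maps are maintained; linker positions map to nothing in the
parent. No initiator methionine or cloning-level details are modelled.

## Thermal analytics

### CD melts

The half-transition temperature t<sub>1/2</sub> is extracted by a bounded
nonlinear least-squares fit of the two-state van't Hoff model with linear
folded/unfolded baselines:

y(T) = y_pre(T) + [y_post(T) − y_pre(T)]·f(T),  f(T) = 1 / (1 + exp[(ΔH_vH/R)(1/T − 1/T_half)])

with temperatures in kelvin inside the exponential (T_K = T_°C + 273.15,
R = 8.314 J mol⁻¹ K⁻¹) and results reported in °C. Initialization: t_half at
the steepest point of the Savitzky–Golay-smoothed curve (window 7, order 2),
ΔH_vH = 300 kJ/mol, baselines from the outer 15% temperature windows.
Bounds: t_half inside the data range, ΔH_vH ∈ [50, 2000] kJ/mol; up to four
ΔH_vH restarts before a `FitError`. A model-free alternative
(`half_transition_interp`: the 0.5 crossing of the baseline-normalized
curve, nearest the steepest point) is exposed for curves a two-state model
does not describe; the fit is the primary method because it uses all points.

Curve normalization to the 0–1 range is either min–max (idempotent;
constant signal is an error, not a silent zero) or fraction-unfolded from
the fitted pre/post baselines.

### DSC thermograms

Excess heat capacity is isolated by fitting linear baselines on the pre- and
post-transition windows (outer 15% of the temperature range by default, or
user-supplied) and joining them with a sigmoid progress baseline:
baseline(T) = y_pre(T)(1−α(T)) + y_post(T)α(T), where α is the normalized
running integral of the current excess. Starting from α given by the
min–max-normalized trace, the scheme is iterated to a fixed point
(max |Δexcess| < 10⁻⁶ · max excess, limit 50 iterations, error on
non-convergence). The correction is exactly invariant under adding any
global linear function to the trace. Residual undershoot from transition
tails leaking into the baseline windows is tolerated to 10⁻³ of the peak
height. Peaks of the excess curve (t_m per transition) are local maxima with
prominence ≥ 10% of the global maximum, refined by a parabola through the
three surrounding points. Multi-peak thermograms are reported as such; no
thermodynamic deconvolution of multi-state transitions is attempted.

## Synthetic data

`thermal.simulate_cd_melt` and `thermal.simulate_dsc` generate curves from
the same two-state model the analysis fits: 20–90 °C in 1 °C steps
(71 points, the standard acquisition grid), unit amplitude, Gaussian noise
of s.d. 0.02 signal units (2% of amplitude), ΔH_vH = 300 kJ/mol, all seeded
and deterministic. DSC thermograms sum `weight · ΔH · df/dT` per transition
onto linear instrument baselines joined by the overall progress; each
transition's excess integrates to its ΔH (checked to 1%). The
two-transition demonstrations use ΔH_vH = 800 kJ/mol per transition — the
sharpness at which peaks ~6 °C apart appear visibly distinct, matching the
bimodal phenomenology such thermograms show; at this width any pair
separated by more than 4 °C is resolved.

What the generators do **not** emulate: intermediate states and non-two-state
transitions, aggregation exotherms, scan-rate effects, baseline curvature
beyond linear, and correlated instrument noise. Passing parameter-recovery
tests therefore shows the estimators are correct *for the model class they
assume*, not that real multi-state melts are two-state.

The `synthetic` module builds a deterministic 142-residue stand-in domain
(numbered 192–333) with thirteen glycines laid out so that exactly six loop
glycines at positions 211, 244, 256, 269, 282 and 297 survive the filters.
Its inter-glycine sequence, secondary-structure cartoon and non-site scores
are invented; only the numbering, glycine geometry and the six published
per-site scores are meaningful. It exists so the end-to-end pipeline can run
and be graded offline; it is not the real apical-domain sequence.

## Fixtures and the correlation analysis

The packaged stability table (`data/ad_groel_table1.tsv`) holds the
published per-site disorder scores and measured stabilities of the
wild type and six permutants of the chaperonin apical domain. Conventions:
the wild type is included in every correlation (its score is read at the
joined termini); a variant missing a measurement under one method (cp256
melted without a usable DSC endotherm) is dropped from that method's
correlation only, giving n = 7 for both CD wavelengths and n = 6 for DSC;
cp297's bimodal thermogram contributes either its main (51.0 °C) or its
secondary (45.1 °C) peak, both exposed. The wild-type DSC value is stored as
71.1 °C. With these conventions the packaged table reproduces all four
published Pearson coefficients (−0.62, −0.65, −0.93, −0.95) to two decimals;
this membership was fixed by verifying that exactly it reproduces the
printed values. `pearson` delegates to `scipy.stats.pearsonr` after
validating length (≥ 3) and non-zero variance; r is rounded to 2 dp in
reports and kept at full precision internally. No significance testing is
done on n ≤ 7 points.

A second fixture (`data/s6_dg.tsv`) carries thirteen published unfolding
free energies of ribosomal protein S6 permutants from two independent series
with different linker designs, kept as printed (replicate determinations as
separate rows). Because per-site disorder scores for S6 are not packaged,
the S6 disorder–ΔG correlation is a user-driven computation — the package
never asserts a value for it.

## Known limitations

- The quantitative site scores in all reference results come from an
  external predictor's output; the bundled charge–hydropathy fallback is
  plumbing with its own constants (window 51, logistic steepness 10) and is
  deliberately excluded from every quantitative claim.
- The exact terminal margin and de-duplication choices of the reference
  six-site selection are not derivable from first principles; the selector
  exposes them as parameters rather than hard-coding a judgment.
- Correlations on ≤ 7 points quantify a tendency within one protein series;
  they are not evidence of a general law, and the package draws no
  cross-protein inference beyond the two packaged fixtures.
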