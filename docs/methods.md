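# Methods

## Two-state spectral model

Intracellular methylene blue (MB) emission is modeled as a convex mixture of
two fixed basis spectra on a 650–820 nm grid at 1 nm: a *reduced* basis with
its mode pinned at the dye's 696 nm primary emission peak and an *oxidized*
basis pinned at the 760 nm shoulder. The oxidized fraction ρ ∈ [0, 1] is the
single latent state variable; "red shift" is any statistic monotone in ρ.
The published spectra are graphical, so the basis *shapes* are a modeling
choice: a log-normal-in-wavelength core (origin 600 nm; σ = 0.35 reduced,
σ = 0.30 oxidized) mixed with a 30% broad Gaussian component (sd 120 nm,
renormalized on the grid). The broad component guarantees that each basis
carries ≥ 5% of its mass in each of the three detector bands, so every
channel stays informative for both states; the band masses at these defaults
are 0.22/0.35/0.20 (reduced) and 0.05/0.32/0.50 (oxidized) for
AF647/AF700/APC-Cy7. Because the oxidized basis has the larger
APC-Cy7:AF647 band ratio (9.7 vs 0.93), the predicted red-shift ratio is a
monotone Möbius function of ρ — strictly increasing by construction, not by
fit.

Detector channels are pure band-pass windows with multiplicative gain;
the absolute instrument voltages are treated as metadata. Band integrals are
trapezoidal with linear interpolation at window edges, making them additive
over adjacent sub-windows and linear in both intensities and gain.

Unmixing is one-parameter constrained least squares on sum-normalized
spectra. Both bases sum to 1, so the mixture does too and the box-constrained
minimizer has a closed form (projection of the normalized observation onto
the segment between the bases). Observations on a different grid (e.g. the
10 nm bins of spectral-mode files) resample the bases by linear
interpolation, renormalized, before fitting. Degenerate inputs fail loudly:
all-zero spectra cannot be normalized, equal-peak bases are rejected at model
construction, and a flat spectrum's "peak" is tie-broken to the grid start
with a warning (ties generally break to the shortest wavelength).

The absorbance side uses the same two-state machinery on a 560–780 nm grid
with the unoxidized curve peaking at 665 nm (which is why a red laser excites
the dye maximally). Hydrogen peroxide maps to ρ through a saturating curve
(Hill coefficient 1, half-saturation 5 mM); only the *direction* of the
dose–response is asserted anywhere, because the underlying experiment
demonstrates direction, not kinetic constants.

## Event-level statistics

* **Merged virtual MB channel**: the per-event *sum* of AF647 + AF700 +
  APC-Cy7 on the linear scale. Merging maximizes gathered light over the
  655–810 nm range and gives the testable property that the merged signal
  dominates each component per event (a mean or max convention would not add
  light). Negative inputs are clipped to zero with a logged count.
* **Geometric MFI**: exp(mean(log(max(v, 1)))). The 1 a.u. floor absorbs
  nonpositive values (e.g. after background subtraction) without discarding
  events; it is logged when it binds, and the statistic is scale-equivariant
  above the floor.
* **FMO gate**: the MB-high threshold is the 99.5th percentile (configurable)
  of the matched fluorescence-minus-one control — cells cocultured with
  *unlabeled* bacteria, gated to the same population — so ~0.5% of control
  events sit above the gate by design. Controls under 200 events are refused
  (the empirical quantile is too unstable).
* **Red-shift ratio and ρ recovery are computed on the MB-high subset.**
  A cell with no dye has no dye spectrum: at time 0 (or in blood samples) the
  "MB-high" events are exactly the gate's false-positive tail, and their flat
  autofluorescence spectrum carries no oxidation information. Summary rows
  therefore report these statistics only when the MB-high fraction clearly
  exceeds the gate's design false-positive rate (≥ 2%, configurable) and at
  least 20 events are available; otherwise NaN.

## Synthetic study generator

The generator exists so the full pipeline is exercisable and testable without
any deposited data. Its defaults encode the study conditions; they are not
tuning knobs. Per cell:

1. **Ingestion**: Poisson counts. Ex vivo (coculture), the mean is
   `phagocytic_rate × MOI × t/(t + 0.5 h)` — sublinear within the first hour,
   with half-time 0.5 h since exact kinetics are unpublished. Default rates
   (bacteria/cell/h per unit MOI): neutrophil 1.5 > macrophage 1.0 >
   monocyte 0.4 > eosinophil 0.2; T/B/NK = 0. Cytochalasin B multiplies the
   mean by 0.02.
2. **In vivo (blister) kinetics**: cells arrive uniformly over the blister's
   life, begin ingesting 2 h after arrival, and saturate with half-time 4 h
   at an effective tissue MOI of 2. The post-arrival delay makes early
   blisters dominated by freshly extravasated MB-low cells while late
   blisters approach full labeling — the feature behind rising MB-high
   counts. Blood cells have no MBEC contact (uptake 0).
3. **Oxidation**: each bacterium's dye oxidizes as 1 − exp(−k_ox · residence)
   from its ingestion time (drawn uniformly over the allowed window — only
   the marginal ρ distribution matters downstream); a cell's ρ is the mean
   over its bacteria. Healthy k_ox = 0.5/h; CGD-affected k_ox = 0; carriers
   are an exact 50/50 mosaic (the lyonized fraction is "approximately half",
   fixed at half to keep the intermediate phenotype sharp).
4. **Signal**: channel value = gain × band integral of (load × mixed basis)
   + autofluorescence, all under unit-mean log-normal noise (CV 25%, typical
   cytometer spread). Load = 150 a.u. × bacteria count × labeling
   concentration (linear in the 1%/0.5%/0.3% label, an assumption);
   permeabilization retains 10% of the load. Autofluorescence is a flat
   spectral density (0.1–0.3 a.u./nm by population), so unlabeled cells carry
   a featureless background.
5. **Markers**: log-normal levels per population; bacterial contact (or
   extravasation into the blister) multiplies CD11b ×4, CD66b ×3, CD45 ×2 and
   CD62L ×0.3 *independently of the label* — MBEC and unlabeled bacteria
   produce identical activation. A shared internalization latent scales
   receptor markers by (1 + count)^γ (γ = −0.12…−0.15 for
   CD11b/CD66b/CD14/CD16/CD62L, +0.08 for CD45), which is what makes the
   MB-vs-marker correlation signs agree between the ex vivo and in vivo
   contexts.

Study designs: an ex vivo 0–60 min series (MOI 10) with FMO, no-bacteria,
cytochalasin-B, permeabilization and macrophage/monocyte arms; an MOI
titration (1–100); a CGD panel (3 genotypes × 0–180 min, conventional and
spectral modes); and an in vivo design with 19 volunteers contributing 38
blister/blood pairs (7–8 per time point at 3/5/7/9/24 h) plus one
unlabeled-injection control volunteer per time point. Blister cellularity
rises steeply to a 9 h peak (800 → 6,500 neutrophils) with a mild decline at
24 h (5,500) — full resolution is placed beyond the sampled window so that
cumulative uptake statistics (MB-high counts, total MB fluorescence
intensity) rise monotonically across the sampled points. Blister endotoxin
decays exponentially (500 EU/mL, scale 6 h, 8% volunteer jitter). Fold
changes are referenced to the no-bacteria control where the design has one;
the in vivo designs use the paired blood sample instead (no "no-bacteria
blister" exists physically).

Everything is driven by a single seed through `numpy` SeedSequence spawning,
and identical seeds produce byte-identical output tables. Files are FCS 3.1
(list mode, float32, linear channels, no spillover — compensation is out of
scope); a CSV fallback carries the same tables. The latent truth columns
(population, bacteria count, ρ) live only in `truth.csv`, never in FCS.

**What the generator does not emulate** — and therefore what passing tests do
not show about real data: instrument artifacts (doublets, time drift,
carryover), spectral spillover and compensation error, autofluorescence
heterogeneity within a population, donor-to-donor kinetic variation beyond
the endotoxin jitter, cell death/apoptosis, and any spatial structure of the
dermis. The Poisson ingestion law and the linear label-concentration scaling
are assumptions, not measurements.

## Pipeline conventions

* Populations are called from markers (Siglec8-high → eosinophil, flagged and
  excluded from analysis; CD66b-high → neutrophil; CD14-high split on FSC
  into monocyte/macrophage; remainder → lymphocyte), never from the
  generator's truth. Population calls are exhaustive, so per-population event
  counts conserve the per-sample total.
* Per-condition emission curves average the per-event spectra of the gated
  (MB-high) population first, then normalize the mean curve — stable for the
  small late-blister populations (~10³ cells) — rather than normalizing
  per event.
* Fold change is a ratio of geometric MFIs (labeled / control), consistent
  with geometric MFI elsewhere.
* MB fluorescence intensity = merged-MB geometric MFI of the MB-high subset ×
  MB-high count (0 when the count is 0). Whether the gated or total
  population is used is configurable; gated is the default.
* Correlations are Spearman (rank) by default — the analysis is about
  monotone association, not linearity.
* Time-course aggregation accepts bilateral replicate blisters (same
  volunteer and time, distinct samples) and rejects the same sample appearing
  twice.
* Problem sizes: study designs total ~0.1–0.5 M events each; the pipeline and
  acceptance script run in seconds on one CPU.

## Known limitations

* The two-state mixture is operational: whether the 760 nm shoulder is a
  distinct chemical species or an environment effect is not resolved, and ρ
  should be read as "position along the observed spectral transition".
* The merged-channel *sum* convention and the 99.5% FMO percentile are
  documented choices where the original software operations are
  unspecified; both are configurable.
* Red-shift statistics are undefined (NaN) for samples without a genuine
  MB-high population — by design, not by accident.
* OD420 calibration is ordinary least squares on the linear scale and
  refuses to predict outside its calibrated range without a warning.
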