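# Methods

This note documents the models and procedures implemented in `shox4c`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Coordinates

All in-memory coordinates are 0-based half-open (BED convention). Printed,
human-facing coordinates (browser views, ISCN annotations) are 1-based
inclusive and are converted at the I/O boundary (`intervals.from_printed`,
`GenomicInterval.to_printed`). Sizes reported in whole kb are insensitive
to the ±1 bp inclusive/exclusive ambiguity of printed coordinates.

## Restriction fragment map and fragends

A 4C library is made by a primary digestion (DpnII, `GATC`, cutting at
offset 0) and ligation, followed by a secondary digestion (Csp6I, `GTAC`,
cutting at offset 1) and re-ligation. Recognition sites are matched exactly
by a sliding scan (overlapping occurrences allowed; `N` never matches); the
two default sites are reverse-complement palindromes, so one forward scan
finds all sites. Enzymes are configurable; degenerate IUPAC codes and
methylation sensitivity are out of scope.

Merged cut positions plus the chromosome ends tile each chromosome into
fragments, each flank labelled by the enzyme that produced it. Categories:

* **informative** — one primary and one secondary flank, length ≥ 40 bp;
* **blind** — both flanks from the same enzyme (no usable junction for the
  second digestion round);
* **too short** — mixed flanks but < 40 bp (40 is the only assay-fixed
  parameter: such fragments are effectively unmappable and are filtered
  with a strict boundary — 39 bp removed, 40 bp kept);
* **terminal** — touching a chromosome end (no ligation junction there).

Each informative fragment contributes exactly one **fragend**, anchored at
its primary cut site. This is one of two defensible conventions (the other
counts both ends of each primary fragment); it is the natural one after
blind-fragment removal, since every retained fragment has exactly one
primary end. Coincident primary/secondary cuts — impossible for the default
enzyme pair, possible for custom ones — collapse to a single boundary
labelled primary, a deterministic tie-break that avoids zero-length
fragments.

A viewpoint primer region is anchored to the fragend of the single
informative fragment it overlaps; if it falls in a non-informative
fragment, the nearest informative fragend is substituted and flagged;
overlap with two or more informative fragments is rejected as ambiguous.

## Contact profiles

Reads are assigned to the fragment containing their 5′-most coordinate
(start for `+`, end − 1 for `−`) — deterministic and appropriate for
fragend-proximal 4C chemistry. Reads in non-informative fragments are
removed with per-category accounting; `retained + removed + unassigned`
always equals the input read count and the pipeline asserts this balance.

* **Viewpoint mask** — the viewpoint fragend plus `mask_k = 2` fragends on
  each side are excluded everywhere (self-ligation and undigested-template
  artefacts dominate there).
* **Normalization** — reads per million over unmasked fragends (cis and
  trans). The per-million constant is the dominant convention for
  per-fragend units and makes the conservation invariant (Σ = 10⁶) exact.
* **Smoothing** — running mean over `window_size = 21` fragends, centred,
  computed per chromosome over unmasked fragends ordered by anchor.
  Windows are counted in fragend-index space, not bp, so the bandwidth
  adapts to restriction-site density, matching the per-fragend counting
  unit. At chromosome edges and next to masked runs the window truncates
  to what exists (no padding — no invented data). Window 1 is exactly the
  identity. 21 fragends ≈ 6 kb at the default synthetic site density:
  wide enough to stabilise domain extent, narrow relative to the
  ~0.5–1 Mb domains of interest. Peak-level questions want a narrower
  window (3–5); the tests use window 3 for planted-peak ranking.

### Domain calling

The domain-extent rule is an explicit operationalization of what is usually
read off a browser track by eye. The threshold is the
`background_quantile = 0.75` quantile of smoothed values over unmasked cis
fragends. The call is the maximal run of fragends containing the viewpoint
with smoothed signal ≥ threshold, bridging up to `gap_tolerance = 25`
consecutive sub-threshold fragends; the reported interval is the span of
the qualifying fragends' fragments (a closed cover — never zero-length),
and `signal_fraction` is the share of cis signal inside it.

On the gap default: when a genuine contact domain occupies roughly the top
quartile of fragends, the quantile threshold sits *inside* the domain's
sampling-noise band, so sub-threshold runs of length *g* occur within the
domain at rate ≈ n·2^(−g−1) per profile. A tolerance of 25 fragends (~7 kb
at default density) bridges these with negligible failure probability,
while it cannot inflate a call: the interval always ends at the last
above-threshold fragend, and background beyond a real domain edge sits far
below the threshold. Lowering the quantile can only widen a call
(monotonicity, tested).

Domain calling is descriptive, not inferential: no background model is
fitted and no significance is attached (interaction calling against a
fitted decay model is explicitly out of scope).

### Feature overlap

A feature overlaps a fragend when its interval intersects the fragend's
fragment (half-open). Mean and max smoothed signal are taken over unmasked
overlapped fragends and omitted when nothing is overlapped;
`inside_domain` is a plain interval-intersection test against the call.

## Synthetic 4C data

`make_genome` draws uniform random DNA and plants `GATC` / `GTAC` sites at
exponential (Poisson-process) spacings — defaults 4 and 1 sites/kb —
skipping collisions; accidental background occurrences (rate ≈ L/256 per
site) are genuine sites, since digestion is scan-based.

`simulate_4c_reads` samples a multinomial over informative fragends with
weight at cis fragment midpoint x:

    w(x) = max[ (1 + |x − v|/s)^(−α),  plateau inside the domain ]

plus a flat `trans_floor` everywhere; each model *peak* multiplies the
weight of the single informative fragend nearest its position by its
enrichment (discrete enhancer-like contacts on the fragment map; the peak
width only sizes the matching annotation feature). Reads are placed
uniformly inside the chosen fragment with random strand — fragment-level
assignment makes the within-fragment position irrelevant.

Default study conditions (2 Mb chromosome, viewpoint centred): decay α = 1,
scale s = 10 kb, a 500 kb plateau (central quarter of the chromosome) at
level 0.5, three peaks of 10-fold enrichment and 600 bp feature width
inside the domain, trans floor 10⁻⁴, 10⁵ reads. The plateau fraction
(25 % of cis fragends) deliberately matches the 0.75 calling quantile so
that recovery tests exercise the hardest, knife-edge case of the threshold
rule. `make_features` emits one feature per peak plus an equal number of
decoys ≥ 50 kb from any peak, names encoding the truth.

What the generator does **not** emulate: mappability and GC bias, PCR
duplicates, sequencing error, undigested/self-ligation artefact reads
(handled in real data by the viewpoint mask, which the simulator never
stresses), reads in blind/short fragments (simulated reads land only on
informative fragends, so the filter's removal counts are only exercised by
dedicated tests), trans-contact structure beyond a flat floor, and real
restriction-site clustering. Passing recovery tests therefore demonstrate
the correctness of the pipeline's arithmetic and calling logic under a
plausible contact model — not robustness to every artefact of real 4C
libraries.

## qPCR copy-number model

For each sample × amplicon with replicate quantification cycles Cq and
amplification efficiency E (fold per cycle, validated per amplicon):

    RQ  = E^(Cq_cal − mean Cq)          sd(RQ)/RQ = ln E · sd(Cq)
    NRQ = RQ_test / √(RQ_ref1 · RQ_ref2)
    CN  = CN_cal · NRQ / mean(NRQ over calibrators)

`Cq_cal` is the per-target mean over calibrator samples. The two reference
genes (*ZNF80*, *GPR15*) enter through a geometric mean, so a common
DNA-input shift cancels exactly (scale invariance, tested). Replicate SDs
propagate in log space and combine in quadrature (each reference at power
½). Error bars are reported as SDs and labelled as such. Failed
amplification (all-NaN Cq) yields RQ = 0 with a flag; a true copy number of
0 is thereby called a deletion rather than an error.

Classification rounds the CN estimate half-up (0.5 → 1); estimates within
±0.15 of a half-integer boundary are flagged ambiguous but still
classified — the band surfaces borderline calls instead of silently
deciding them. A sample is upstream-CNV-positive when ≥ 2 of the three
enhancer amplicons are non-normal **and** concordant in direction;
opposite-direction non-normal calls are flagged discordant for review. No
multiple-testing correction is applied: calls are deterministic quantities
with flags, not hypothesis tests. *SHOX* lies in pseudoautosomal region 1,
so expected CN is 2 in both sexes and no sex correction exists.

The plate simulator generates `Cq = base − log_E(CN/2) + δ_sample + ε`,
with replicate noise ε ~ N(0, cq_sd) and a per-sample DNA-input offset
δ ~ N(0, 0.2 cycles) that cancels through reference normalization (so
noiseless plates recover CN exactly while noisy plates exercise the
normalization path). References amplify independently of CN; calibrators
carry CN 2. It does not model inhibitors, efficiency mis-estimation,
pipetting outliers or plate-position effects.

Recovery under the default noise model (3 replicates, Cq SD 0.15,
E ∈ [1.85, 2.0]): the CN-estimate SD at CN 2 is ≈ 0.2, so integer rounding
recovers the truth in ≳ 98 % of entries; the test suite requires ≥ 95 %
over 20 seeded plates.

## ISCN, cohort and luciferase arithmetic

`parse_iscn` accepts `arr[build] band(start–end)xN [inheritance]` with
comma thousands separators and hyphen/en-/em-dash variants; malformed
strings fail with the offset where the structure breaks, and formatting
round-trips modulo dash/comma normalization. Lengths in kb are
`round((end − start)/1000)` on printed coordinates. Cohort frequency is a
percentage rounded to one decimal. Luciferase fold change is the ratio of
mean Renilla-normalized activities, sample over empty vector, with a
delta-method SD for the ratio of means.

## Numerical choices

* Running means use cumulative sums (O(n)); window 1 short-circuits to an
  exact copy so the identity property holds bit-for-bit.
* Quantile thresholds use linear interpolation (numpy default).
* CN rounding is floor(x + 0.5) — half-up, deterministic, no banker's
  rounding surprises at 2.5.
* All generators take explicit integer seeds (numpy `default_rng`) and are
  bit-reproducible; pipeline outputs contain no timestamps, so reruns are
  byte-identical.
* Problem sizes in tests (2 Mb genomes, 10⁵ reads, 10–20 seeds/plates)
  were chosen as the smallest at which the statistical properties under
  test are stable.

## Limitations

* Read alignment, demultiplexing and primer trimming are upstream of this
  package; it consumes mapped coordinates (BED6).
* Domain extent depends on the quantile/gap parameters; only the relative
  behaviour (monotonicity, recovery under the stated model) is guaranteed,
  and called boundaries on real data should be read as descriptive.
* The one-fragend-per-informative-fragment convention is documented, not
  the only possible reading of per-fragend units; switching conventions
  would rescale profiles but not change domain calls materially.
* ISCN parsing covers the array-CNV `arr[...]` form only, not the full
  ISCN grammar.
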