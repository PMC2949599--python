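# Methods

## The model

The input is a sparse boolean sequence: a support of `L` discrete
positions (base pairs along a chromosome, say) of which `N ≪ L` carry a
site — a gene's transcription start, a binding site, any point feature.
The question is whether the sites recur with some spatial period `P`,
and if so, which sites participate.

The detector wraps the support around a `P`-periodic solenoid: each
position `x` maps to the angle `θ = (x mod P)/P` on the unit circle.
Sites repeating with period `P` coincide on that circle; jittered sites
land nearby; unrelated sites scatter uniformly. Clustering of the
projected sites is therefore the signature of `P`-periodicity, and it is
scored with exact circular order statistics:

* For `N` points placed independently and uniformly on a circle of unit
  perimeter, the arc enclosing exactly `i` of the remaining points
  follows `Beta(i+1, N−1−i)`; equivalently the arc spanning `g` gaps
  follows `Beta(g, N−g)`.
* For each site `i` (in clockwise order after projection) and each
  neighbor depth `j = 1..J`, the normalized arc `x_{i,j}` between the
  j-th neighbors on either side of `i` encloses `2j−1` sites, so its
  null law is `Beta(2j, N−2j)`. The two-tailed p-value is approximated
  by `min(F, 1−F)` with `F` the regularized incomplete beta: small
  either when the neighborhood is unusually dense or unusually empty,
  both of which periodic clustering produces.
* The spectrum score at `P` is the average information content

      S(P) = −(1/(2JN)) Σ_i Σ_j log p_j^N(x_{i,j}^P),

  swept over a grid of candidate periods (the solenoidal spectrum).

Significance is calibrated by Monte Carlo: `R` site sets of the same `N`
are drawn uniformly on the continuous circle and scored with the same
machinery; the p-value of a period is the add-one exceedance estimate
`(1 + #{null ≥ observed})/(R+1)`. Uniform angles reduced modulo any
period are uniform on the circle, so one ensemble per `(N, J)` serves
the entire grid; a discrete variant (uniform integers mod `P`) is kept
behind `null_ensemble_discrete` for exactness studies and differs only
by `O(P/L)` edge effects. The spectrum of `−log10 p` is the quantity to
read peaks from. With `N_p` independent peaks, the family-wise
probability that at least one reaches `p*` is `1 − (1 − p*)^{N_p}`
(`family_correction`); the number of harmonic groups found is the
default estimate of `N_p`.

### Per-site positional scores

At a fixed period, each site `i` is scored by the straddling pairs of
its projected neighborhood: for every pair `(a, b)` with `a` among the
`J` nearest counterclockwise neighbors and `b` among the `J` nearest
clockwise neighbors, the probability that two uniform sites in the same
circular order relation (spanning `g = j_a + j_b` gaps) would be closer
than observed is `p_< = I_y(g, N−g)`. The site statistic is the largest
information content, `S′(i,P) = −log min p_<`, rewarding sites buried in
dense clusters. Its null distribution is sampled by redrawing whole
uniform configurations and recording one designated site's statistic;
`S_pos = −log10 p_v(S′)`. Plotting `10^{−S_pos}` at one period against
another separates sites belonging to different periodic trains
(assignment: smaller `p_v` wins; exact ties at the Monte-Carlo floor are
broken by the larger `S′`, since two saturated p-values can hide
statistics that differ by orders of magnitude).

The index conventions above (the `Beta(2j, N−2j)` law for the
neighbor-pair arc and `Beta(g, N−g)` for the `g`-gap arc) were pinned by
brute-force sampling oracles over 10⁵ uniform circular configurations;
the tests keep those oracles.

### A sampling subtlety in the positional null

"Record one site per uniform configuration" must designate a *point of
the process*, not the site of smallest angle: the arc that contains an
independent fixed point (the origin) is stochastically larger — the
waiting-time paradox — so ranking relative to the origin size-biases the
flanking arcs. `positional_null` therefore centers each null
configuration on the designated site (its angle set to 0, the other
`N−1` drawn uniformly). The spectrum score needs no such care because it
sums over all sites, and each site is an exchangeable designated point.

## Reading peaks: sub-harmonic aliasing

An exactly `P`-periodic pattern aligns *perfectly* not only at `P` but
at every divisor `P/m` inside the grid (the projected sites still
coincide, only the cluster angles change), and partially at rational
multiples `(m/q)P`. With a saturating Monte-Carlo p-value floor of
`1/(R+1)`, all of these can tie at maximal significance, so peak
post-processing must decide which period is the fundamental.
`find_peaks` proceeds in four steps:

1. **Local maxima** of `−log10 p` above `min_neglog10p` (default 2.0),
   with runs of equal significance (floor saturation) collapsed to the
   member of highest raw score.
2. **Dominance filter**: peaks with raw score below `dominance` (default
   0.25) times the strongest peak's are dropped. Near-rational aliases
   cluster far more weakly than the fundamental yet still saturate the
   p-value floor; the raw score separates them.
3. **Harmonic families**: connected components under the relation
   "larger period ≈ integer multiple of smaller" (relative tolerance
   `harmonic_tol`, default 0.02). Connectivity matters: the divisor
   aliases of one period are not pairwise integer-related (2500 vs 2000)
   but connect through their shared multiple.
4. **Fundamental per family**: when the site set is supplied, the
   fundamental is the largest family member with the maximal
   *exact-alignment multiplicity* — the count of score terms whose
   projected neighbors coincide exactly. Every integer divisor of a
   truly periodic pattern's period preserves that count, while
   harmonics `kP` and near-rational aliases split clusters and lose
   coincidences; meanwhile the raw score among the exactly-tied divisors
   differs only by accidental inter-cluster geometry and can favor an
   alias. Without the site set (or when nothing aligns exactly, as with
   jittered data) the fallback is the raw-score plateau: the largest
   member within `plateau_tol` (default 5%) of the family maximum.

Uncalibrated (raw-score) spectra go through the same machinery, which
makes the ideal-comb analysis fully deterministic: the comb's raw
maximum is an exact four-way tie across its grid divisors, and the
plateau rule returns the largest, i.e. the true spacing.

`modal_period` summarizes replicate analyses by binning fundamentals
into relative bins of width `tol` (default 2%) anchored at each bin's
first member — anchored, because chain-merging lets scattered failure
periods daisy-chain into one wide pseudo-cluster — and reporting the
median of the most populated bin.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `J` | `max(⌊N/16⌋, 1)`, capped so `2J−1 ≤ N−2` | neighbor depth; grows with `N` so dense regions keep being probed, keeps a spectrum `O(JN)` per period |
| `R` | 1000 | null replicates; p-value floor `1/(R+1) ≈ 10⁻³` |
| `eps` | 1e-300 | p-value floor so coincident sites (distance exactly 0) keep a finite logarithm |
| period grid | integers, `P_min=10` to `min(L/2, 40000)`, step spanning the range in ≤ 4000 steps | benchmark analyses use 2000..40000 step 10 |
| `min_neglog10p` | 2.0 | peak threshold, p < 0.01 |
| `harmonic_tol` | 0.02 | integer-ratio tolerance for family grouping |
| `dominance` | 0.25 | raw-score fraction below which saturated alias peaks are pruned |
| `plateau_tol` | 0.05 | raw-score band defining a family's top plateau |

Scores use natural logarithms (the information-content convention);
positional scores are reported in `−log10` units. Positions are 0-based
internally; BED starts are used as-is, GFF3 records are converted from
1-based with the strand-aware transcription start (`start` on `+`,
`end` on `−`).

## Baselines

Two standard comparison methods operate on the same inputs: the
pair-distance histogram (default bin 50) followed by a discrete Fourier
transform of the mean-subtracted counts (zero-padded 4×, reported on a
period axis), and the autocorrelation of the smoothed indicator
sequence (default: square window of length 1000; a Gaussian kernel is
available), normalized so `C(0) = 1`, likewise Fourier-transformed.
Only peak locations of these spectra are treated as meaningful; padding
and windowing conventions shift magnitudes, not peaks.

## Synthetic scenarios

The generator module produces Dirac combs; aperiodic multi-site motifs
repeated with a fixed period (offsets drawn with all pairwise circular
spacings distinct, so no internal spacing masquerades as a period);
uniform positional jitter (amplitude read as the *full* width of the
uniform law, so amplitude `0.1 P` means draws in `±0.05 P`; a half-width
mode exists); deletion of true sites with replacement by uniform
impostors; and labeled superpositions of two trains. The canonical
benchmark conditions are a 20-tooth comb of spacing 10000 on a 200 kb
support, a 5-site motif repeated 8 times at period 10000 (40 sites),
and two 3-site trains with repeat distances 7270 and 10000 laid down up
to position 80000 (57 sites).

What the generators do *not* emulate: realistic gene-length or operon
structure, chromosome-scale inhomogeneity of gene density, circular
chromosomes (distances are computed on the linear support), or
correlated annotation errors. Passing tests therefore demonstrate the
statistical machinery under the stated noise models, not performance on
any particular genome annotation.

## Problem sizes

The benchmark analyses sweep 3801 candidate periods for site sets of
20–57 sites with `R = 1000` null replicates; replicate studies (jitter
robustness, contamination, chance-level classification) use 50–100
replicates each. At these sizes a full calibrated spectrum takes well
under a second and the whole benchmark battery a few seconds on one
core. The score itself is `O(JN)` per period, i.e. roughly `O(N²/16)`,
which is comfortable for the small, sparse site sets the method is
designed for and becomes the limiting factor for thousands of sites.

## Known limitations

* The `min(F, 1−F)` two-tail approximation has a cusp at the
  distribution median; mid-range distances carry slightly distorted
  information content. This does not move peak locations, which is all
  the detector uses.
* A randomly drawn motif can, with non-negligible probability,
  concentrate its offsets modulo a low-order fraction of the period
  (e.g. mod `P/3`); such a motif genuinely carries sub-period structure
  and the detector will (correctly) report the sub-period under strong
  jitter. The distinct-spacings condition does not exclude this; the
  canonical benchmark motif is fixed precisely so that the scenario is
  the intended aperiodic one.
* Monte-Carlo p-values saturate at `1/(R+1)`; peaks beyond that
  significance are indistinguishable except through their raw scores,
  which the peak reader exploits but which are no longer calibrated.
* `N_p` for the family-wise correction is estimated as the number of
  harmonic groups; peak independence is an approximation.
* Multi-sequence inputs are analyzed per sequence; periodicity spanning
  sequences is out of scope.
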