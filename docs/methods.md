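# Methods

This note documents the models, estimators, numerical choices and known
limitations of `netreconf`, in the order data flows through the pipeline.

## Synthetic trial generator

**Signal model.**  Each planted community in a frequency band shares one
band-limited source per trial: white noise filtered with a 4th-order
zero-phase Butterworth band-pass (1 s of padding is generated on each side
of the epoch and trimmed, so filter transients never reach the analysis
window), normalized to unit variance.  Member node *i* receives the source
delayed by `lag_cycles_i / f_center` seconds (a frequency-domain phase
ramp, so fractional-sample delays are exact) and scaled by the coupling
amplitude; independent Gaussian noise of standard deviation `noise_sd` is
added to every node.  At the pulse sample the community assignment switches
from the pre-pulse to the post-pulse partition; the pulse has no other
signature (artifact waveforms are out of scope).

A *delayed shared source* was chosen over a dynamical system (Kuramoto or
similar) deliberately: it guarantees a nonzero imaginary cross-spectrum
within communities — precisely the quantity dwPLI measures — with an
analytically known limit (dwPLI → 1 as noise → 0 for a fixed nonzero lag),
so generator and estimator can be tested against each other.  Because a
pair whose relative lag is 0 or half a cycle has a vanishing imaginary
cross-spectrum, configurations in which all members of a community share
one lag are rejected, and `make_band_plan` assigns per-node lags in steps
of 0.2 cycles (nudged in 0.07-cycle increments until every within-community
pair, pre and post, is at least 0.03 cycles away from 0 and 0.5).

**What it does and does not emulate.**  It reproduces: narrowband
oscillatory sources with stable cross-trial phase lags inside communities,
cross-trial phase randomness between communities, additive sensor noise,
head-scale node geometry (uniform placement in a 0.15 m sphere), and a
mid-epoch coupling change.  It does **not** model: 1/f background spectra,
volume conduction / field spread, artifact waveforms, nonstationary
amplitude dynamics, or between-subject variability beyond independent
source and noise realizations.  Passing tests therefore demonstrate that
the analysis recovers planted coupling structure under realistic trial
counts and noise, not that it is robust to every pathology of real
recordings.

**Default study conditions** (`make_study_config`): 16 regions in 4
equal communities, alpha band 8–12 Hz, fs = 128 Hz, epochs −1.5…+1.5 s,
96 trials, 10 subjects (replicates differing only by seed, ladder
`seed + k`), coupling 0.8, noise_sd 0.5.  With a unit-variance narrowband
source, noise_sd 0.5 leaves the in-band per-bin SNR high (narrowband power
concentrates in ~8 bins while white noise spreads over the whole Nyquist
range), which matches the strong cross-trial phase locking the method
presumes.  In the perturbed design, half the members of community 1 defect
to community 2 after the pulse.  The region count and trial count are
deliberately desk-scale so a full multi-subject study runs in about a
minute; every estimator accepts the 68-region case unchanged.

## Sliding-window dwPLI

Windows are 0.5 s Hanning-tapered segments (64 samples at 128 Hz), demeaned
per trial and zero-padded to `fs / 0.5 Hz` points so the DFT lands exactly
on the 2–25 Hz, 0.5 Hz grid.  Centers sit at integer multiples of the
5-sample spacing within the retained ±1 s span — 51 windows, symmetric
about and including the pulse.  Windows may never extend past the recorded
epoch; data are never zero-filled.  A DPSS multitaper option exists behind
the `taper` switch (per-trial cross-spectra are averaged over tapers before
the imaginary part is taken); the single-taper Hanning periodogram is the
default.

The estimator is computed per window, frequency and pair from the per-trial
imaginary cross-spectra using the closed form
`(S² − ΣI²) / (S_abs² − ΣI²)`, algebraically equal to the sum over ordered
trial pairs.  A vanishing denominator (all `I_j = 0`, e.g. the diagonal,
or exactly zero-lag pairs) is defined as 0 and flagged degenerate rather
than propagating NaN.  Negative values are retained at this stage.  Band
averages are arithmetic means over bins inside the **closed** band; with
the default bands, 12.5 Hz belongs to neither.

Trials are processed in chunks of 32 so the transient (trials × freqs ×
N × N) cross-product arrays stay bounded at the 68-region scale.

## Multilayer modularity and the greedy optimizer

The quality function uses the Newman–Girvan configuration null per layer
scaled by γ, ordinal (adjacent-layer) interlayer coupling ω, and the
normalization 2μ = Σ_s 2m_s + 2ωN(L−1), i.e. interlayer weights are
included in μ.  Negative connectivity entries are clipped to zero when the
network is built — the configuration null presumes nonnegative weights —
and the clipped count is recorded on the network object.  All-to-all
interlayer coupling is intentionally not offered.

The optimizer operates on the dense supra-modularity matrix over
node-layer tuples: sweeps in seeded random order move each tuple to the
community with maximal strictly positive gain (tolerance 1e-12 scaled by
the largest |B| entry, so float ties never cycle); a tuple repelled by
every community, including its own, is isolated into a fresh singleton.
When no move improves, communities are aggregated into super-nodes and the
sweep repeats.  Every accepted move strictly increases Q and the result is
a local maximum by construction; exhaustive enumeration on ≤ 12-tuple
networks bounds it from above in tests.  Candidate communities are all
current communities, not only graph neighbors — with dense modularity
matrices the restriction would save nothing.

**Ensembles and consensus.**  Run *k* of an ensemble uses seed
`base_seed + k`, recorded in the partition for exact replay.  Agreement is
the fraction of run pairs identical up to relabeling.  The consensus is
the medoid member: maximal mean pairwise z-scored Rand similarity to the
rest (the closed-form permutation moments of the pair-count; degenerate
labelings with zero null variance score 0), ties broken by higher Q then
lowest seed.  With the high agreement observed on planted data the medoid
choice is inconsequential, which the tests assert rather than assume.

**Static communities.**  Community-level summaries need one label per node
from the unperturbed regime: consensus detection restricted to the
pre-pulse layers, collapsed to the per-node modal label across layers
(smallest label on ties; the collapse is exact when labels are constant,
the common case at moderate ω).  Which layer set defines "the" communities
is exposed as the `interval` parameter rather than hard-coded.

## Scale selection

The null destroys correlational structure but nothing else: within each
layer independently, the N(N−1)/2 upper-triangle weights are uniformly
permuted and mirrored, conserving each layer's weight multiset exactly
(asserted bitwise in tests) and hence the temporal profile of total
weight.  Per-layer (rather than epoch-pooled) shuffling is an
interpretation choice and is flagged as such.  One fresh shuffle is drawn
per subject and grid cell; observed and null use identical optimizer run
seeds per cell, so their difference is paired.

Default grids: γ from 0.8 to 1.6 in steps of 0.025 (the step implied by a
reference optimum of 1.025) and a log-like ω ladder 0.5 … 35; both
overridable, and the pipeline default uses a reduced 5 × 5 grid.  Selection
is the plain argmax of mean Q_obs − Q_null; ties break toward smaller ω
then smaller γ via an explicit sort, so the answer cannot depend on grid
iteration order; an all-equal surface warns and returns the tie-break cell.
No statistical test is attached to the surface — selection is a heuristic.
When no sweep is run, (γ = 1.025, ω = 9) is the documented operating
point.

## Reconfiguration metrics

Flexibility normalizes affiliation changes by L−1 possible transitions.
Allegiance counts co-assignments over layers and divides by **L** by
default, which keeps `P_ii = 1` and `P ≤ 1`; a literal L−1 mode exists
behind the `norm="transitions"` flag for comparability with texts that
normalize by transitions.  Pre/post differences are computed on the two
25-layer blocks of **one** partition of all 51 layers — not two separate
detections — so label identity is consistent across the pulse; the
pulse-centered layer belongs to neither block.  Both signed (post − pre)
and absolute differences are emitted rather than choosing one.

Distances are Euclidean, in meters, from the coordinate of the node
nearest the stimulation site (the stimulated node itself when it is in the
geometry); community distance is from the member-centroid.  The
top-percentile node selection uses the linear-interpolation percentile
(`numpy.percentile` default) with the threshold returned so plots are
bit-for-bit reproducible; nodes at or above the threshold are selected.
Homologous left/right stimulation results are merged by elementwise mean.

## Statistics

Two-sided one-sample and paired t tests throughout; a zero-variance sample
yields a degenerate flag with NaN statistic and p (never p = 0).
Family-wise control is strict Bonferroni (p < α/family; the 10-pair family
of 5 communities gives 0.005).  Discovery control is Benjamini–Yekutieli
step-up with the Σ1/i factor, applied within one edge family (all
N(N−1)/2 edges of a band × condition matrix); adjusted values are monotone
and clipped at 1.  Uncorrected and corrected flags are both reported.
SEMs are across subjects for metric summaries and would be across member
nodes for community distances; single-subject runs emit missing values.

## Pipeline and reproducibility

`run_pipeline` chains simulate → connect → (sweep) → detect → metrics →
stats and writes delimited tables whose headers carry a hash of the
simulation config; identical configs yield byte-identical tables (figures
are advisory).  Subject *s* derives detection seeds `seed + 10000(s+1)`
(+5000 for the static-community ensemble), keeping every stage's stream
independent and replayable.  Per-subject recovered communities are aligned
to the planted reference by Hungarian assignment on the label contingency
table before cross-subject summaries.

Default iteration counts (20 detection runs per subject, 2 per sweep cell)
are reduced from the 100 used at full scale; they are a speed/robustness
trade-off chosen for the desk-scale study, and the ensemble agreement is
reported so the cost of the reduction is visible.  `scripts/acceptance.py`
re-derives the package's principal quantities from scratch with seeded
inputs; see the README.

## Known limitations

- The generator's noise is white; with strong 1/f background the dwPLI
  SNR per bin would be lower than these tests exercise.
- Clipping negative dwPLI values discards (rare, small) systematic
  negative phase-lag consistency rather than modeling it.
- Modularity maximization inherits the usual resolution-limit and
  degeneracy caveats; the consensus-over-ensembles step mitigates run-to-run
  variance, not model misspecification.
- The dense supra-modularity matrix costs O((NL)²) memory — fine for
  68 × 51, not for thousands of node-layer tuples.
- z-Rand moments assume exchangeable relabelings with fixed block sizes;
  for near-degenerate partitions the score is defined as 0.
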