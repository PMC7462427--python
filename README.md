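# netreconf

Network-reconfiguration analysis for trial-based oscillatory recordings
around a perturbation pulse (e.g. source-space EEG around single-pulse
brain stimulation).

Perturbing one node of a coupled oscillatory system can reorganize which
nodes transiently form communities with which.  `netreconf` quantifies that
reorganization from region × sample × trial data in four steps:

1. **Connectivity.**  Cross-trial phase consistency between every region
   pair is estimated with the debiased weighted phase lag index (dwPLI) in
   short Hanning-tapered windows slid across the peri-pulse epoch.  For a
   pair at one frequency, with `I_j` the imaginary part of the trial-`j`
   cross-spectrum,

       dwPLI = Σ_{j≠k} I_j I_k / Σ_{j≠k} |I_j I_k| ,

   which is insensitive to zero-lag (volume-conducted) coupling and free
   of the sample-size bias of squared phase-lag indices.  Per-frequency
   estimates are averaged within closed bands (alpha 8–12 Hz, beta
   13–20 Hz), giving one N × N matrix per window.  At 128 Hz with
   5-sample spacing and ±1 s retained, that is 51 layers: 25 pre-pulse,
   the pulse-centered window, 25 post-pulse.

2. **Communities.**  The layer stack is treated as a multilayer network
   and partitioned by maximizing multilayer modularity

       Q = (1/2μ) Σ_{ijs} [A_ijs − γ k_is k_js / 2m_s] δ(g_is, g_js)
         + (1/2μ) 2ω Σ_{is} δ(g_is, g_i(s+1)) ,

   with structural resolution γ, ordinal interlayer coupling ω, and a
   Louvain-like greedy optimizer.  Because the optimizer is
   nondeterministic, seeded ensembles are reduced to a consensus partition
   (the medoid under pairwise z-scored Rand similarity).

3. **Scale selection.**  (γ, ω) are chosen by the *difference* heuristic:
   sweep a grid, compare mean Q of the observed pre-pulse networks with
   mean Q after uniformly permuting each layer's pairwise weights
   (destroying correlational structure while conserving the weight
   multiset), and take the argmax of Q_obs − Q_null.

4. **Reconfiguration metrics.**  From the consensus partition of the full
   epoch: per-node *flexibility* ξ_i = g_i/(L−1) (fraction of possible
   between-layer affiliation changes) and pairwise *allegiance*
   P_ij (fraction of layers in which i and j share a community).  Both are
   computed separately on the 25 pre- and 25 post-pulse layers (center
   window excluded); their differences, related to Euclidean distance from
   the stimulation site and summarized per community, with top-percentile
   node selection and paired-t/Bonferroni and Benjamini–Yekutieli FDR
   statistics, quantify where the network reorganized.

Because real stimulation datasets are rarely shareable, the package ships a
seeded generator (`netreconf.simulate`) that plants exactly the structure
the analysis assumes: per band, each planted community shares one
band-limited source received by its members at fixed nonzero phase lags,
plus independent noise, with the coupling partition switching at the pulse.
The generator is first-class, tested code: it is what makes every stage of
the pipeline falsifiable end to end.

## Worked example

```python
from netreconf import default_pipeline_config, run_pipeline

config = default_pipeline_config(seed=1)   # 10 synthetic subjects, 16 regions,
                                           # alpha-band plant, community 1
                                           # restructured after the pulse
report = run_pipeline(config, outdir="out")
print(report.selected_gamma, report.selected_omega)
print(int(report.recovery["perturbed_is_largest"].sum()), "of",
      len(report.recovery), "subjects")
print(report.enrichment)
```

prints

```
1.4 0.5
10 of 10 subjects
2.0
```

meaning: the null-calibrated sweep selected (γ = 1.4, ω = 0.5) for this
synthetic ensemble; in all ten subjects the community whose coupling was
restructured after the pulse showed the largest mean within-community
|Δ allegiance|; and its member nodes were 2.0× over-represented in the
85th-percentile set of node-level allegiance change (the maximum possible
enrichment at these community sizes).  `out/` contains the edge-, node- and
community-level tables (TSV), the Q surface, and a YAML summary.

The same chain is available from the shell:

```sh
netreconf run --out out --seed 1
netreconf simulate --config config.yaml --out sim/
netreconf connect --in sim/subject_00.h5 --band 8:12 --out conn.h5
netreconf detect --conn conn.h5 --gamma 1.025 --omega 9 --iters 100 --out det/
```

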