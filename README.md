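# ladkit

Analysis toolkit for genome–nuclear-lamina interaction profiling with
pA-DamID-style data: lamina-associated domain (LAD) calling, differential
LAD testing, spike-in calibration, and the downstream metrics used to
quantify genome de-partitioning.

## The problem

Large, megabase-scale chromosome segments — LADs — contact the nuclear
lamina (NL), while the intervening iLADs face the nuclear interior.
pA-DamID measures these contacts by directing a Dam methyltransferase to a
lamina protein (LMNB1, LMNB2, LBR) with an antibody and counting
methylated-fragment reads in fixed genomic bins (20 kb). Because raw counts
also reflect DNA accessibility and amplification bias, the antibody signal
is normalized to a freely diffusing Dam-only control:

    score(bin) = log2( (ab_cpm + 1) / (dam_cpm + 1) ),    cpm = counts · 10⁶ / library

Tracks are converted to z-scores (mean 0, SD 1 genome-wide) so experiments
with different dynamic ranges are comparable, and replicates are averaged.

On top of this, `ladkit` implements:

- **Segmentation** — a two-state hidden Markov model (Gaussian or robust
  Student-t emissions, Baum–Welch fit, Viterbi decoding) splits each
  chromosome into alternating LADs and iLADs; the per-domain **LAD score**
  is the mean z-scaled signal over the domain.
- **Differential LADs** — a precision-weighted, variance-moderated t-test
  per LAD between two conditions (a voom/limma-style analysis applied to
  continuous domain scores): a lowess mean–variance trend supplies weights,
  per-LAD variances are shrunk toward an empirical-Bayes prior estimated
  from the marginal law of log s², and calls are made at Benjamini–Hochberg
  adjusted p < 0.05.
- **Spike-in calibration** — a fixed second-species admixture (20% mouse
  cells) provides scaling factors (spike mean and SD of the log-ratio, in
  250-kb bins) that are applied to the target species, preserving genuine
  global dynamic-range differences that per-sample z-scaling would erase.
- **Border profiles** — consensus signal around LAD borders with
  chromosome-end and short-domain exclusion (50 kb) and closest-border
  assignment so each bin is counted once.
- **De-partitioning metrics** — the slope of the differential signal versus
  the control signal, bimodality of the signal distribution
  (Gaussian-mixture BIC + Ashman's D), LAD/iLAD score comparisons
  (Welch / Wilcoxon), genomic overlap with Fisher exact tests, and track
  correlations.
- **Nucleosome analysis** — linker-DNA lengths from dyad spacing (distance
  > 100 bp ⇒ subtract 147 bp of nucleosomal DNA; keep 1–100 bp) per domain
  class, and deepTools-style scale-regions pile-up matrices.
- **Synthetic data** — a generator with known ground truth (geometric
  domain lengths, log-normal accessibility background, negative-binomial
  counts, domain-level perturbations, spike-ins, nucleosome dyads) so the
  entire pipeline is testable without sequencing data.

## Worked example

```python
from ladkit import (SimulationConfig, PerturbationSpec, simulate_genome,
                    simulate_counts, normalize_log_ratio, zscale_track,
                    average_replicates, TwoStateHMM, segment_domains,
                    lad_score, differential_track, departition_slope)

cfg = SimulationConfig(
    chrom_sizes={"chr1": 20_000_000},
    perturbation=PerturbationSpec(departition_factor=0.3),
    seed=7,
)
truth = simulate_genome(cfg)
counts = simulate_counts(truth, cfg)

ztracks = {}
for cond in ("control", "perturbed"):
    reps = []
    for rep in (1, 2):
        s = counts.get(cond, rep)
        reps.append(zscale_track(normalize_log_ratio(s.antibody, s.dam)))
    ztracks[cond] = average_replicates(reps)

model = TwoStateHMM(emission="gaussian").fit(ztracks["control"])
domains = segment_domains(ztracks["control"], model, min_bins=2)
scored = lad_score(domains, ztracks["control"])
lads = scored.lads
print(f"called {len(lads)} LADs covering "
      f"{(lads['end'] - lads['start']).sum() / 1e6:.1f} Mb")
print(f"mean LAD score {lads['score'].mean():.2f}, "
      f"mean iLAD score {scored.ilads['score'].mean():.2f}")
diff = differential_track(ztracks["perturbed"], ztracks["control"])
res = departition_slope(ztracks["control"], diff)
print(f"de-partitioning slope {res.slope:.3f} (r = {res.r:.2f}, n = {res.n})")
```

Output:

```
called 12 LADs covering 12.1 Mb
mean LAD score 0.71, mean iLAD score -1.07
de-partitioning slope -0.210 (r = -0.36, n = 1000)
```

The HMM recovers a dozen LADs spanning roughly half of the 20-Mb synthetic
chromosome, their mean z-score sits well above the iLAD mean, and the
negative slope of the differential-vs-control regression quantifies the
partial collapse of LAD/iLAD partitioning injected into the perturbed
condition (on z-scored tracks the measured slope is attenuated relative to
the generative shrinkage factor; see `docs/methods.md`).

A `ladkit` console script exposes the same pipeline from the shell
(`ladkit simulate`, `normalize`, `call-lads`, `diff-lads`, `calibrate`,
`borders`, `metrics`, `linker`, `pileup`); run `ladkit --help`.

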