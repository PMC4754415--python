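# sdmnstates

Analysis pipeline for dyadic agonistic-interaction experiments in zebrafish:
from raw qPCR amplification curves, behavior logs and cortisol assays to
brain-region gene-expression contrasts and **neurogenomic states** —
co-expression matrices compared across treatments by quadratic assignment
procedure (QAP) permutation tests.

Because the raw data of the motivating experiment were never deposited, the
package ships a forward **synthetic-data generator** that emulates the full
measurement chain (latent expression with imposed correlation structure →
logistic amplification curves → cycle-threshold quantification), so every
stage can be validated against a known ground truth.

## The experiment and the model

Four treatments are compared: fish that **won** or **lost** a real dyadic
fight (paired within a dyad), fish that fought their **mirror** image
(unresolved interaction), and isolated **controls**. After the interaction,
six target genes (`bdnf`, `npas4`, `nlgn1`, `nlgn2`, `wnt3`, `neurod`) are
measured by qPCR in five brain nuclei of the social decision-making network
(`Dm`, `Dl`, `Vv`, `Vs`, `POA`), normalised to the reference gene
`eef1a1l1`.

The statistical chain:

1. **Quantification.** Each amplification curve is fitted with a
   four-parameter logistic; the cycle threshold is the cycle of maximum
   second derivative, `CT = midpoint − ln(2+√3)/slope`, and the
   amplification efficiency `E` comes from a logit-linear regression over
   the early exponential window. Input quantity is
   `R0 = (1+E)^(−CT)` (computed in the log domain), and expression is the
   ratio of target to reference `R0` per fish × nucleus.
2. **Screening.** Generalized extreme studentized deviate (gESD, Rosner)
   outlier removal per treatment × nucleus × gene cell, capped at
   ⌊0.2 n⌋ removals per cell.
3. **Univariate statistics.** Per gene, a linear mixed model on
   log-expression,

   `log y ~ treatment * nucleus + (1 | fish) + (1 | dyad)`,

   where the dyad intercept is shared only by the winner and loser of a
   real fight. Planned contrasts compare all six treatment pairs within
   each nucleus; effect sizes are Cohen's d (paired `d_z` for
   winner–loser, pooled `d_s` otherwise).
4. **Neurogenomic states.** Per treatment × nucleus, the 6 × 6 Pearson
   co-expression matrix across fish. Two matrices are "the same state"
   when their QAP correlation (Pearson r over the 15 off-diagonal pairs,
   null = simultaneous row + column permutation) is significant; states are
   the connected components of the similarity graph, reported as letters.
   For 6 genes the 720 permutations are enumerated exactly; larger
   problems fall back to Monte Carlo with an add-one p-value.

Behavior (latency to first bite, fight-resolution time, aggressive and
submissive acts in the last 5 minutes) and trunk cortisol are summarised
and tested alongside (Welch ANOVA, Tukey HSD, BH-adjusted correlation
screens).

## Worked example

```python
from sdmnstates import (
    simulate_study, quantify_curves, normalize_expression,
    screen_dataset, fit_lmm_contrasts, coexpression_matrices,
    partition_states, StudyDesign,
)

ds = simulate_study(seed=42)              # 45 fish, 70 875 curve rows
meas = quantify_curves(ds.curves)         # E, CT, R0 per reaction
expr = normalize_expression(meas, reference_gene="eef1a1l1",
                            fish_meta=ds.fish)
screened, log = screen_dataset(expr)      # 78 of 1350 values removed
con, omni = fit_lmm_contrasts(screened, "bdnf")
print(omni)
#        term          F  df1  df2         p
#   treatment   0.334781    3    7  0.800987
#     nucleus  22.945115    4  149  8.7e-15
# interaction   1.510881   12  149  0.125959
print(con.query("nucleus == 'Dm'").head(2))
# gene nucleus            pair  estimate       SE        z        p        d d_type magnitude
# bdnf      Dm  control-mirror  0.258691 0.264010 0.979853 0.327159 0.508626    d_s    medium
# bdnf      Dm  control-winner  0.106420 0.266039 0.400017 0.689144 0.150328    d_s negligible

design = StudyDesign()
mats = coexpression_matrices(screened, design.treatments, design.nuclei,
                             genes=design.genes)
part = partition_states({t: mats[(t, "Dm")] for t in design.treatments},
                        axis="treatment", seed=0, n_perm=720)
print(part.labels)
# {'control': 'A', 'mirror': 'B', 'winner': 'C', 'loser': 'D'}
```

Or run everything at once:

```bash
sdmnstates run-all --seed 42 --out runs/demo
```

which writes `expression.csv`, `contrasts.csv`, `omnibus.csv`,
`qap_results.csv`, `partitions.csv`, per-matrix heatmaps and a
`manifest.json` into a fresh run directory. `sdmnstates run-all` on real
data takes a YAML config with `mode: load` and a `paths:` map
(`fish`, `curves` or `expression`, optionally `behavior`, `resolution`,
`cortisol`); `sdmnstates validate` checks the tables first. Two runs with
the same config are byte-identical.

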