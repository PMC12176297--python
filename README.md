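# xiquant

Quantitative pipelines for studying X-chromosome inactivation: counting
XIST RNA foci in 3D confocal stacks, fitting FRAP recovery kinetics,
allele-specific expression analysis with an exact-test reactivation
screen, k-mer motif enrichment, and replicate-aware statistics. Every
pipeline ships with a matching synthetic-data generator, so each analysis
can be validated end to end against known ground truth.

## Scientific problem

The inactive X chromosome (Xi) is coated by the long noncoding RNA XIST.
Perturbations of the proteins that tether XIST — for example SAF-A/HNRNPU
and its SAP domain — disperse the XIST "cloud" into many separate foci,
change the mobility of the protein in the nucleus, and can partially
reactivate silenced X-linked genes. Quantifying those phenotypes needs
several independent measurements:

- **3D RNA-FISH focus counting** (`xiquant.foci`): how many resolvable
  XIST foci does each nucleus contain, and how does a perturbation change
  that number?
- **FRAP kinetics** (`xiquant.frap`): how fast does fluorescence recover
  after photobleaching (half-time `t_half = ln 2 / k`), and what fraction
  of the protein is immobile (`(1 - F_inf) / (1 - F0)` after normalizing
  the pre-bleach level to 1)?
- **Allele-specific counts** (`xiquant.allelic`): with SNPs distinguishing
  the two haplotypes, which genes are expressed from only one allele, and
  does a perturbation shift that skew (reactivation)?
- **k-mer enrichment** (`xiquant.kmers`): which short motifs are
  over-represented in an experimental sequence set versus a control set?
- **Replicate-aware statistics** (`xiquant.stats`): superplot summaries,
  one-way ANOVA with Tukey HSD (plus a Bonferroni-multiplied column),
  percent-positive scoring, and bootstrap fold-change intervals.

All of these are driven by the generators in `xiquant.simulate`, which
produce OME-TIFF image stacks with per-nucleus ground truth, noisy FRAP
traces, allele count tables with planted skew and reactivation, and
sequence sets with planted motifs.

## Worked example

```python
import numpy as np
from xiquant import simulate, foci
from xiquant.frap import fit_recovery, normalize_trace

# --- FRAP: simulate 25 noisy wild-type traces and fit them back ---
traces = simulate.sim_frap_traces(simulate.FrapSimParams(), 25, seed=11)
fits = [fit_recovery(normalize_trace(tr)) for tr in traces]
print("FRAP: mean t_half = %.2f s, mean immobile fraction = %.1f%%" % (
    np.mean([f.t_half for f in fits]),
    100 * np.mean([f.immobile_fraction for f in fits])))

# --- Imaging: two simulated stacks through the counting pipeline ---
params = simulate.preset_image_params("wt")
stacks, truths = simulate.sim_image_population(params, 2, seed=11)
counts = []
for stack in stacks:
    summaries, _, _, _ = foci.process_stack(stack)
    counts.extend(s.n_foci for s in summaries)
print("foci per nucleus (pipeline):", counts)
print("foci per nucleus (ground truth):",
      [n.n_resolvable for t in truths for n in t.nuclei])
```

Output:

```
FRAP: mean t_half = 2.59 s, mean immobile fraction = 18.2%
foci per nucleus (pipeline): [2, 3, 3, 3, 1, 2, 6, 4]
foci per nucleus (ground truth): [2, 3, 3, 3, 2, 4, 7, 1]
```

The FRAP generator's inputs were `t_half = 2.58 s` and an immobile
fraction of 18%; the fits recover both. The per-nucleus focus counts
track the geometric ground truth (nucleus ordering between the two lists
may differ, since segmentation discovers nuclei in label order).

The same workflows are available from the command line via the single
`xiquant` entry point — `xiquant simgen …` to generate data,
`xiquant foci3d --manifest …`, `xiquant frap --traces …`,
`xiquant allelic …`, `xiquant kmerscan …` and `xiquant report …` to
analyze it. Every command reads and writes plain CSV/TSV/FASTA/OME-TIFF
files.

## Layout

- `src/xiquant/foci.py` — 3D segmentation, focus assignment, batch runner
- `src/xiquant/frap.py` — trace normalization and exponential recovery fits
- `src/xiquant/allelic.py` — SNP/gene filters, a:b ratios, IgG subtraction,
  exact-test reactivation screen
- `src/xiquant/kmers.py` — k-mer counting and enrichment scores
- `src/xiquant/stats.py` — superplots, ANOVA/Tukey, percent-positive,
  bootstrap fold change
- `src/xiquant/simulate.py` — all synthetic-data generators and presets
- `src/xiquant/cli.py` — the `xiquant` command-line interface
- `docs/methods.md` — methods note: models, conventions, parameter choices
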