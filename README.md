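# chromadelta

Toolkit for analysing **stimulus-induced chromatin dynamics** in a
two-condition design — the canonical use case being primary human
macrophages before and after oxLDL exposure (macrophage → foam-cell
transformation), where the interesting biology lives in the *dynamic*
regulatory sites: regions whose open-chromatin (FAIRE-seq) or enhancer
(H3K27ac ChIP-seq) signal changes with the stimulus.

It is written for computational genomicists who want the published
analysis recipe as a tested, reusable library rather than a pile of
one-off scripts, and it ships a synthetic-data generator with known
ground truth so every stage can be validated without any sequencing data.

## What it computes

**Dynamic sites (differential signal).** Read midpoints are counted on a
sliding window grid (200 bp / 20 bp step for open chromatin, 500 bp /
50 bp for the enhancer mark) and each window's pooled counts
(*a*, *b*) are tested against library-size proportionality with the
likelihood-ratio G-test,

    E_a = (a+b)·N1/(N1+N2),   G = 2[a·ln(a/E_a) + b·ln(b/E_b)] ~ χ²(1),

windows below a minimum count are left untested (50-read minimum in
transcription-factor mode). Screened same-direction windows merge into
candidate sites, each site is re-tested on its pooled counts, and
Benjamini–Hochberg FDR is applied at the site level (reported at
q < 2.5 %). A Poisson tiling scan flags clusters of sites ("hotspots").

**Integration with expression.** Promoter/distal classification around
TSSs, ±300 bp intersection of dynamic chromatin with dynamic enhancer
sites with directional concordance, paired per-donor t-tests for
differential expression (BH q < 0.05), nearest-gene coupling of enhancer
fold to expression fold (Pearson r, r²), quartile concordance, quantile
normalization and TSS signal profiles.

**Super-enhancers.** Enhancer peaks within 12.5 kb are stitched, ranked
by total signal, and the cutoff is the point where the scaled
rank-signal curve's tangent reaches slope 1; everything above is a
super-enhancer.

**GWAS locus enrichment.** A locus = index SNP + high-LD proxies. The
observed number of loci with ≥ 1 SNP inside an annotation is compared to
locus-size-bin-matched draws from a background catalog (100,000
permutations by default), with an upper-tail binomial test at success
probability *expected/n* plus an empirical permutation p. A peak-shift
null (each site displaced uniformly within ±10 kb, 100 permutations)
serves for generic interval-vs-annotation enrichment.

**Allelic motif affinity.** PWMs are scanned over variant-centred allele
sequences in log2-odds space on both strands; the best match gets an
exact p-value from the discretised null score distribution
(position-wise convolution, Šidák-corrected over offsets and strands),
and motifs are ranked by `diff_logp = log10(p_risk) − log10(p_protective)`.

## Worked example

```python
import numpy as np
from chromadelta import SimulationConfig, run_differential, simulate_chromatin

cfg = SimulationConfig(seed=1)            # 2 x 2 Mb genome, 3 reps/condition,
reads, truth = simulate_chromatin(cfg)    # 20 planted 1 kb sites, |log2fc| = 2
stats, sites = run_differential(reads, cfg.genome, mode="chromatin")
```

Running `python examples/01_differential_sites.py` (the same analysis
with the recovery bookkeeping) prints:

```
windows tested: 199993
dynamic sites called at q < 0.025: 21
planted sites recovered with correct direction: 20/20
false sites: 0
  chr1:94040-95320 dir=+1 log2fc=+1.75 q=2.79e-52
```

All 20 planted differential sites are recovered with the right
direction of change; the called log2 fold (+1.75) estimates the planted
effect (+2, shrunk slightly because site boundaries extend into
background), and q is the site-level BH-adjusted significance. One extra
call overlapping a planted site was split in two — splitting a true site
is counted as recovery, not as a false positive.

The other `examples/*.py` scripts demonstrate expression integration,
super-enhancer calling, locus enrichment (a planted 4-fold enrichment is
recovered as `fold = 5.00, binomial p = 2.6e-11` at seed 4) and the
allelic motif scan, each printing a short annotated report.

A thin CLI wraps the same functions:

```bash
chromadelta simulate --seed 1 --out sim/
chromadelta run --seed 1 --out run/        # full synthetic end-to-end run
chromadelta allele-scan
```

## Layout

- `src/chromadelta/core_io.py` — interval types/algebra, BED/bedGraph/TSV I/O
- `src/chromadelta/synthetic.py` — ground-truth generators
- `src/chromadelta/differential.py` — windows, G-test, BH-FDR, dynamic sites
- `src/chromadelta/integration.py` — expression coupling, concordance, QN
- `src/chromadelta/super_enhancers.py` — stitching and tangent cutoff
- `src/chromadelta/enrichment.py` — locus permutation and shift nulls
- `src/chromadelta/motifs.py` — PWM scanning and allelic affinity
- `src/chromadelta/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
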