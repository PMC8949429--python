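# veincode

Finger-vein verification by **block-averaged center-symmetric local binary
patterns** (BACS-LBP) with minimum-Hamming-distance multi-template matching.

Finger-vein recognition matches people by the vessel pattern under the skin
of a finger, imaged in near infrared. Segmentation-based matchers are fragile
on low-contrast images, and per-pixel LBP descriptors are large and
redundant. `veincode` implements a compact alternative for researchers and
engineers evaluating vein-coding pipelines: pool the image into block means
(local *macro* structure), apply center-symmetric comparisons to the pooled
matrix (local *micro* structure), and match the resulting short binary
codewords positionally.

## The coder and matcher

Given a grayscale ROI image $I$ of size $A \times B$ and a block size
$a \times b$:

1. Zero-pad $I$ so both dimensions are block multiples, then form the
   block-mean matrix $I' \in \mathbb{R}^{p \times q}$ with
   $p = \lceil A/a \rceil$, $q = \lceil B/b \rceil$, where $I'_{ij}$ is the
   mean of block $I_{ij}$ (padding zeros included).
2. Partition $I'$ into non-overlapping $3 \times 3$ tiles (zero-padded at
   ragged boundaries), row-major.
3. For each tile, read its border entries $n_1,\dots,n_8$ clockwise from the
   top-left corner and emit four bits by the center-symmetric rule

   $$x_{i,j} = \begin{cases} 1, & n_j \ge n_{j+4} \\ 0, & n_j < n_{j+4} \end{cases} \qquad j = 1,\dots,4$$

4. Concatenate the tile codes: $x = x_1 \| x_2 \| \cdots \| x_m$, giving a
   codeword of length $L = 4\,\lceil p/3 \rceil \lceil q/3 \rceil$ bits
   (e.g. 2508 bits for a 513×256 image at 3×8 blocks).

Because only order relations between block means are used, the code is
invariant to positive affine intensity changes.

**Matching.** A subject enrolls the codes of its first $N$ images as
templates $\{x^{(n)}\}_{n=1}^N$. A probe $x$ scores

$$S_\text{matching} = \min_n \frac{\operatorname{sum}(x^{(n)} \oplus x)}{L}$$

and is accepted iff $S_\text{matching} \le DT$ (decision threshold; the
boundary accepts). **Evaluation** follows the standard verification
protocol: every remaining sample is one genuine (1:1) trial against its own
subject and one impostor (1:N) trial against each other subject; the package
reports FAR/FRR curves, the equal error rate (EER, linear interpolation on a
1001-point threshold grid), and intra/inter recognition rates at chosen DTs.

A seeded synthetic generator (dark spline-drawn vessels on a low-contrast
gradient background, with per-sample pose jitter and sensor noise) makes the
whole pipeline testable end to end without access to any vein database.

## Worked example

Generate a small synthetic dataset (8 fingers × 12 samples) and evaluate the
N = 6 protocol:

```sh
$ veincode synth --subjects 8 --samples 12 --size 120x240 --seed 42 --out demo/veins
wrote 96 images, manifest demo/veins/manifest.csv

$ veincode evaluate --dataset demo/veins --templates 6 --dt 0.25,0.30 --roc-out demo/roc.csv
{
  "n_templates": 6,
  "block_spec": "3x8",
  "n_genuine_trials": 48,
  "n_impostor_trials": 336,
  "eer": 0.02083333333333337,
  "eer_threshold": 0.3785,
  ...
}
```

With 8 fingers × 12 samples and 6 templates each there are 8 × 6 = 48
genuine trials and 48 × 7 = 336 impostor trials. The EER of ~2.1% means
that at the threshold 0.3785 about 2% of genuine probes are falsely rejected
and 2% of impostor probes falsely accepted; the `rates_at_dt` entries break
down false counts at the thresholds you pass via `--dt`. The other
subcommands (`encode`, `enroll`, `match`) expose the coder and matcher
directly on image files; `veincode --help` lists them.

The same pipeline is available as a library:

```python
from veincode import BlockSpec, SynthConfig, generate_arrays, run_protocol

data = generate_arrays(SynthConfig())           # 50 fingers x 12, seed 42
report = run_protocol(data, n_templates=6, spec=BlockSpec(3, 8))
print(report.n_genuine, report.n_impostor, report.eer)
```

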