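# msrbf

Multi-scale radial basis function (RBF) networks whose hidden nodes are
selected by **balancing global and local error statistics**, with a binary
**blocking layer** that shields successfully mapped neighborhoods from the
influence of later nodes. The package targets two tasks from remote
sensing — binary land-cover classification (labels coded +1/−1) and 1-D
waveform-LiDAR-style signal regression — but the method is generic.

## The problem

Greedy RBF training picks each kernel to minimize a *global* error, so
when a narrow pattern overlaps a wide one the first node lands on a
middle-of-the-road compromise and both patterns need many extra nodes to
repair. The idea here: score every candidate kernel by a weighted sum of
its global error and its *local* error (the same statistic restricted to
the kernel's receptive field), fit the well-resolved local structure
first, then *block* that neighborhood so later nodes see only the
remaining large-scale signal.

## The model

The network output is a linear combination of Gaussian kernel responses,

    f(x) = Σᵢ wᵢ φᵢ(x) + b,     φᵢ(x) = Aᵢ exp(−‖x − cᵢ‖² / (2σᵢ²)).

With n samples and k nodes, the responses form Φ (n×k). A binary matrix
B (n×k) encodes blocking: when node j's local error beats the target its
blocking node is activated, and every point inside node j's receptive
field has its entries zeroed in all later columns (j+1..k, never column
j itself); activated blocks compose by multiplication and column 1 is
all ones. The effective design matrix is H = Φ ∘ B (element-wise), and
the output weights solve min ‖[H 1](W, b) − y‖₂ by least squares.

Node selection at iteration k scores each candidate by

    S = w_local(k) · LE + (1 − w_local(k)) · GE + R,

where GE is the misclassification ratio (classification) or MAE
(regression) over all points, LE the same inside the candidate's
receptive field, w_local(k) follows a decaying schedule, and R penalizes
near-empty well-fitted neighborhoods. Two baselines share the loop: a
multi-kernel network (MKRBF: w_local ≡ 0, no blocking) and a
single-width network (SKRBF: one shared σ, free centers).

For waveform regression the initial local weight is chosen per signal by
an exhaustive grid over {1.0, 0.9, …, 0.0}, keeping the fit with the
lowest amplitude-normalized MAE (relMAE), ties broken by relSDE. For
classification, a genetic algorithm evolves (center, width) candidates
at each node iteration.

## Worked example

`python examples/two_scale_overlap.py` fits a noiseless signal that
superposes a wide Gaussian and a ten-times-narrower one on its flank:

```
generating components (center, width, amplitude):
  (0.0, 3.171, 1.0)
  (5.204, 0.317, 1.0)

recovered kernels (center, width):
  (0.127, 3.180)
  (5.201, 0.338)
best initial local weight w0 = 0.8

training MAE  multi-scale: 0.01373   multi-kernel: 0.01373
```

Both generating kernels are recovered to within a few percent in width
and well within one narrow-width in center, with only two nodes. The
other examples cover waveform decomposition with the noise-floor rule
and the w0 grid (`examples/waveform_decomposition.py`) and GA-assisted
classification reaching 100% test accuracy on separated clusters
(`examples/classify_clusters_ga.py`).

A thin CLI wraps the same library calls:

```sh
msrbf simulate --kind waveform --seed 0 --out wf.csv
msrbf train --config cfg.yaml --seed 0 --out run/
msrbf predict --model run/model_seed0.json --data wf.csv --task regress --out pred.csv
msrbf evaluate --truth wf.csv --pred pred.csv --task regress
msrbf compare --seed 0 --k-values 4,5
```

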