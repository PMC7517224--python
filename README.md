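# gwcine

Unsupervised **groupwise deformable registration** of 2D dynamic (cine)
image sequences — e.g. one slice of cine cardiac MRI over a cardiac cycle —
with a small convolutional network whose template is **co-estimated
iteratively** with the per-frame deformation fields, plus a proof-of-concept
**motion-compensated compressed-sensing reconstruction** built on top of the
registration.

It is written for researchers in dynamic medical-image analysis who need a
fast, trainable alternative to optimization-based groupwise registration,
and for reconstruction work that needs a cheap motion operator inside an
iterative solver.

## Method

Given a sequence of frames `m_n`, `n = 1..N`, groupwise registration seeks
per-frame transforms `T_n(x) = x + u_n(x)` on a common template grid that
make the registered sequence `m_n(T_n(x))` as static as possible. The
similarity criterion is the groupwise SSD

```
SSD(T) = sum_{x in X} (1/N) sum_n ( m_n(T_n(x)) - mean_n' m_n'(T_n'(x)) )^2
```

(optionally a windowed normalized cross-correlation against the template),
regularized by first/second-order spatial derivatives of `u`, first/second
circular (mod-N) temporal derivatives, and a periodicity constraint
penalizing the squared temporal-mean displacement — the motion over one
cycle should sum to zero.

A reduced U-net maps each (frame, template) pair to `u_n`; a bilinear
spatial transformer warps the frames; all loss terms are differentiable
through the warp. The pipeline is iterative: at iteration `l = 0` the
template is the **geodesic-medoid frame** of a residual-complexity kNN
graph; afterwards the template is the pointwise average of the registered
frames (SSD-optimal), for `L + 1` iterations (default `L = 5`). Training
takes one Adam step per sequence-iteration with batch size = N; prediction
runs the identical loop without updates.

For reconstruction, frames are recovered from row-undersampled k-space `y`
by a single outer motion-estimation/compensation iteration of

```
min_m  1/2 || y - E m ||_2^2 + lambda || Phi T m ||_1
```

with `E` the undersampled frame-wise Fourier transform and `Phi T m` the
circular temporal differences of the motion-compensated sequence.

The network, its backpropagation and the Adam optimizer are implemented
self-contained in NumPy (channels-last layout, im2col convolutions) and are
validated against finite differences; no deep-learning framework is
required.

## Worked example

```python
import numpy as np
from gwcine import GWConfig, generate_dataset, register, train
from gwcine.losses import ssd_loss

data = generate_dataset(10, seed=11)           # synthetic cine phantoms
cfg = GWConfig(epochs=3, seed=5)               # L=5, lr=1e-4, batch=N
net, log = train([seq for seq, _ in data], cfg)

seq, gt = generate_dataset(1, seed=999)[0]     # held-out phantom
result = register(net, seq, cfg)
print("SSD trace:", np.round(result.ssd_trace, 2))
print("unregistered SSD:", round(ssd_loss(seq), 2))
```

Output from this exact snippet (3 epochs only, so registration is partial):

```
SSD trace: [54.73 56.79 57.21 57.37 57.44 57.46]
unregistered SSD: 86.1
```

The trace lists the groupwise SSD of the registered sequence after each of
the six iterations; training to the default 10 epochs on 30 phantoms drives
the final SSD to roughly a fifth of the unregistered value, with recovered
fields within ~0.7 px of the ground-truth inverse motion (see
`scripts/acceptance.py` below). A command-line interface mirrors the
library: `gwcine phantom-generate`, `gwcine template-select`, `gwcine
train`, `gwcine register`, `gwcine evaluate`, `gwcine recon`.

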